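"""End-to-end analysis pipeline on a synthetic cohort.

Chains the stages exactly as the experimental analysis does: titrate every
(subject, frequency) pair, pool per-frequency thresholds with the censored
Gaussian-CDF fit, fit the hyperbolic strength-duration curve to the pooled
means at frequencies at or below the cutoff, rescale thresholds to infinite
pulse duration, and compare the threshold-minimum frequency against the
high-frequency thresholds with independent-samples t-tests.  The result is a
plain-dict bundle (JSON-serializable) carrying the seed, every stage's
numbers, and censoring bookkeeping.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from math import inf

import numpy as np

from . import sdc as sdc_mod
from .cohort import CohortSpec, sample_cohort, simulate_experiment
from .population import (
    PopulationFit,
    cohort_cv,
    compare_frequencies,
    percent_change,
    pooled_cdf_fit,
)
from .psychometric import TitrationProtocol
from .sdc import ScalingParams, fit_sdc, scale_to_duration

__all__ = ["RunConfig", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs; the seed is recorded in the bundle."""

    seed: int = 0
    cohort: CohortSpec | None = None  # None -> CohortSpec(seed=seed)
    protocol: TitrationProtocol = field(default_factory=TitrationProtocol)
    n_cycles: int = 256
    sdc_cutoff_hz: float = 10e3
    scaling: ScalingParams = field(default_factory=ScalingParams)
    reference_frequency: float = 25300.0
    comparison_frequencies: tuple[float, ...] = (49000.0, 66700.0, 88100.0)
    retest: bool = False


def run_pipeline(config: RunConfig) -> dict:
    """Run the full synthetic experiment + analysis; deterministic given seed."""
    spec = config.cohort if config.cohort is not None else CohortSpec(seed=config.seed)
    if spec.seed != config.seed:
        spec = dataclasses.replace(spec, seed=config.seed)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(b"cohort"[0],)))
    cohort = sample_cohort(spec, rng)
    exp = simulate_experiment(cohort, config.protocol, spec, retest=config.retest)

    per_freq: dict[float, PopulationFit | None] = {}
    censoring: dict[float, int] = {}
    for f in spec.frequencies:
        rows = [t for t in exp.thresholds if t.frequency == f]
        censoring[f] = sum(t.censored for t in rows)
        # a frequency where fewer than 2 subjects were measurable cannot be
        # pooled; it is reported as unpooled rather than aborting the run
        per_freq[f] = pooled_cdf_fit(rows) if len(rows) - censoring[f] >= 2 else None

    pooled = [f for f in spec.frequencies if per_freq[f] is not None]
    freqs = np.array(pooled)
    means = np.array([per_freq[f].mean for f in pooled])
    sdc_fit = fit_sdc(freqs, means, cutoff=config.sdc_cutoff_hz)

    scaled_means = {
        f: scale_to_duration(per_freq[f].mean, 1e3 * config.n_cycles / f, inf, config.scaling)
        for f in pooled
    }

    # Between-frequency tests enter censored subjects at their censoring bound
    # (they were stimulated nowhere below the amplifier maximum), a
    # conservative substitution that can only understate a high-frequency
    # threshold increase.
    def _group(f: float) -> list[float]:
        return [
            t.b_th if not t.censored else t.censored_at
            for t in exp.thresholds
            if t.frequency == f
        ]

    fref = config.reference_frequency
    ref_obs = _group(fref)
    comparisons = {}
    for fc in config.comparison_frequencies:
        obs = _group(fc)
        if len(ref_obs) < 2 or len(obs) < 2:
            comparisons[fc] = {"t": None, "p": None, "percent_change_of_means": None}
            continue
        t_stat, p = compare_frequencies(ref_obs, obs)
        comparisons[fc] = {
            "t": t_stat,
            "p": p,
            "percent_change_of_means": (
                percent_change(per_freq[fref].mean, per_freq[fc].mean)
                if per_freq[fref] and per_freq[fc] else None
            ),
        }

    min_freq = float(freqs[int(np.argmin(means))])

    bundle = {
        "seed": config.seed,
        "frequencies_hz": list(map(float, spec.frequencies)),
        "population_fits": {
            str(f): (
                {
                    "mean_mt": per_freq[f].mean,
                    "sd_mt": per_freq[f].sd,
                    "cv_percent": cohort_cv(per_freq[f]),
                    "n_observed": per_freq[f].n_observed,
                    "n_censored": per_freq[f].n_censored,
                }
                if per_freq[f] is not None
                else None
            )
            for f in spec.frequencies
        },
        "censored_counts": {str(f): int(c) for f, c in censoring.items()},
        "sdc": {
            "B_rheo_mt": sdc_fit.B_rheo,
            "tau_chron_s": sdc_fit.tau_chron,
            "cutoff_hz": sdc_fit.fit_cutoff,
            "residuals_mt": {str(f): r for f, r in zip(sdc_fit.frequencies, sdc_fit.residuals)},
        },
        "scaled_to_infinite_duration_mt": {str(f): v for f, v in scaled_means.items()},
        "threshold_minimum_hz": min_freq,
        "comparisons_vs_reference": {str(f): c for f, c in comparisons.items()},
        "retest_pairs": {str(f): p for f, p in exp.retest_pairs.items()} if config.retest else {},
    }
    return bundle
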