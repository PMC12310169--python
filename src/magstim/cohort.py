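"""Virtual-cohort generator: ground-truth subjects and full experiments.

Real per-subject threshold-vs-frequency curves fall with frequency like the
hyperbolic strength-duration curve but turn upward again above ~20 kHz.  The
generator emulates that shape with a two-factor curve

    B(f) = B_rheo * (1 + 1/(2 tau_chron f)) * (1 + a * max(0, ln(f/f_k))^q)

whose second (rise) factor is inactive below the knee frequency f_k and
vanishes entirely for a = 0, recovering the pure hyperbolic SDC.  The
default calibration (B_rheo = 4.4 mT, tau_chron = 405 us, f_k = 16.9 kHz,
a = 0.1756, q = 2) places the population threshold minimum between 16.9 and
25.3 kHz and a ~39% rise from 25.3 to 88.1 kHz.

Subjects vary multiplicatively: subject i's curve is the population curve
times a lognormal factor with median 1 and coefficient of variation
``inter_subject_cv`` (default 0.15, inside the 9-23% range observed across
frequencies).  Each (subject, frequency) response follows the logistic
psychometric curve with width = ``width_fraction`` x threshold (default 3%).
Amplifier ceilings censor subjects whose threshold exceeds the deliverable
amplitude; the default ceilings are placed at population quantiles chosen to
reproduce the observed censoring pattern (2/8 subjects at 600 Hz, 5/8 at
700 Hz and at 88.1 kHz).

Randomness: a single master seed; every (subject, frequency, run) titration
draws from its own `numpy` ``SeedSequence`` spawn, so any single titration is
reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import inf

import numpy as np
from scipy import stats

from .psychometric import (
    StimResponse,
    TitrationProtocol,
    TitrationResult,
    run_titration,
    sigmoid_probability,
)
from .population import SubjectThreshold

__all__ = [
    "TruthParams",
    "CohortSpec",
    "VirtualSubject",
    "ExperimentResult",
    "STUDY_FREQUENCIES",
    "true_threshold_curve",
    "default_ceilings",
    "sample_cohort",
    "simulate_experiment",
]

#: The 16 stimulus frequencies of the study protocol, Hz.
STUDY_FREQUENCIES = (
    200.0, 300.0, 400.0, 500.0, 600.0, 700.0,
    1760.0, 2590.0, 4040.0, 8050.0, 16900.0,
    25300.0, 35400.0, 49000.0, 66700.0, 88100.0,
)


@dataclass(frozen=True)
class TruthParams:
    """Ground-truth population threshold curve parameters."""

    B_rheo: float = 4.4  # mT
    tau_chron: float = 405e-6  # s
    rise_amplitude: float = 0.1756  # a; 0 disables the high-frequency rise
    rise_knee: float = 16900.0  # f_k, Hz
    rise_exponent: float = 2.0  # q

    def __post_init__(self) -> None:
        if min(self.B_rheo, self.tau_chron, self.rise_knee, self.rise_exponent) <= 0:
            raise ValueError("B_rheo, tau_chron, rise_knee, rise_exponent must be > 0")
        if self.rise_amplitude < 0:
            raise ValueError("rise_amplitude must be >= 0")


def true_threshold_curve(f, p: TruthParams):
    """Population ground-truth threshold (mT) at frequency f (vectorized)."""
    f = np.asarray(f, dtype=float)
    hyp = p.B_rheo * (1.0 + 1.0 / (2.0 * p.tau_chron * f))
    rise = 1.0 + p.rise_amplitude * np.maximum(0.0, np.log(f / p.rise_knee)) ** p.rise_exponent
    out = hyp * rise
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class CohortSpec:
    """Generative description of a virtual cohort and its measurement limits."""

    n_subjects: int = 8
    frequencies: tuple[float, ...] = STUDY_FREQUENCIES
    truth: TruthParams = field(default_factory=TruthParams)
    inter_subject_cv: float = 0.15
    width_fraction: float = 0.03  # B_width / B_th
    ceilings: dict[float, float] | None = None  # mT per frequency; None -> defaults
    seed: int = 0

    def __post_init__(self) -> None:
        freqs = tuple(float(f) for f in self.frequencies)
        if any(f <= 0 for f in freqs) or list(freqs) != sorted(freqs):
            raise ValueError("frequencies must be positive and ascending")
        object.__setattr__(self, "frequencies", freqs)
        if not 0.0 <= self.inter_subject_cv <= 0.5:
            raise ValueError("inter_subject_cv must lie in [0, 0.5]")
        if self.width_fraction <= 0:
            raise ValueError("width_fraction must be > 0")
        if self.ceilings is None:
            object.__setattr__(self, "ceilings", default_ceilings(self))
        if any(c <= 0 for c in self.ceilings.values()):
            raise ValueError("ceilings must be > 0")

    def sigma_log(self) -> float:
        """Lognormal shape parameter giving CV = inter_subject_cv."""
        return float(np.sqrt(np.log1p(self.inter_subject_cv**2)))


#: Cohort quantile at which the amplifier ceiling sits per censored frequency:
#: 6/8 of subjects below the ceiling at 600 Hz (2 censored), 3/8 at 700 Hz and
#: 88.1 kHz (5 censored).
_CENSOR_QUANTILES = {600.0: 0.75, 700.0: 0.375, 88100.0: 0.375}


def default_ceilings(spec: CohortSpec) -> dict[float, float]:
    """Amplifier ceilings reproducing the study's censoring pattern.

    The ceiling at a censored frequency is the population threshold quantile
    matching the expected fraction of measurable subjects; elsewhere the
    amplifier is never limiting (infinite ceiling).
    """
    sig = spec.sigma_log()
    out: dict[float, float] = {}
    for f in spec.frequencies:
        if f in _CENSOR_QUANTILES:
            z = stats.norm.ppf(_CENSOR_QUANTILES[f])
            out[f] = float(true_threshold_curve(f, spec.truth) * np.exp(sig * z))
        else:
            out[f] = inf
    return out


@dataclass(frozen=True)
class VirtualSubject:
    """One synthetic subject: the population curve times a personal factor."""

    subject_id: str
    scale: float
    truth: TruthParams
    width_fraction: float

    def threshold(self, f) -> float:
        return self.scale * true_threshold_curve(f, self.truth)

    def width(self, f) -> float:
        return self.width_fraction * self.threshold(f)

    def response_probability(self, f: float, B) -> float:
        """Probability of reporting a sensation to a pulse of amplitude B (mT)."""
        return sigmoid_probability(B, self.threshold(f), self.width(f))


def sample_cohort(spec: CohortSpec, rng: np.random.Generator) -> list[VirtualSubject]:
    """Draw the cohort's per-subject scale factors (lognormal, median 1)."""
    sig = spec.sigma_log()
    scales = np.exp(rng.normal(0.0, sig, size=spec.n_subjects)) if sig > 0 else np.ones(spec.n_subjects)
    return [
        VirtualSubject(f"S{i + 1}", float(s), spec.truth, spec.width_fraction)
        for i, s in enumerate(scales)
    ]


@dataclass(frozen=True)
class ExperimentResult:
    """Full synthetic experiment: raw responses plus per-titration outcomes."""

    responses: list[StimResponse]
    thresholds: list[SubjectThreshold]
    titrations: dict[tuple[str, float, str], TitrationResult]
    retest_pairs: dict[float, list[tuple[float, float]]]


def _titration_rng(seed: int, si: int, fi: int, run: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(si, fi, run)))


def simulate_experiment(
    cohort: list[VirtualSubject],
    protocol: TitrationProtocol,
    spec: CohortSpec,
    retest: bool = False,
    retest_frequencies: tuple[float, ...] = (1760.0, 25300.0),
    n_retest_subjects: int = 5,
) -> ExperimentResult:
    """Titrate every (subject, frequency) pair of the cohort.

    Each titration uses the protocol with the frequency's ceiling and its own
    derived random stream.  With ``retest=True`` the first
    ``n_retest_subjects`` subjects are re-titrated (fresh response streams,
    same true curve — no drift term) at ``retest_frequencies``, yielding
    (test, retest) threshold pairs for agreement analysis.
    """
    responses: list[StimResponse] = []
    thresholds: list[SubjectThreshold] = []
    titrations: dict[tuple[str, float, str], TitrationResult] = {}
    retest_pairs: dict[float, list[tuple[float, float]]] = {f: [] for f in retest_frequencies}

    def one_run(si: int, subject: VirtualSubject, fi: int, f: float, run: int) -> TitrationResult:
        rng = _titration_rng(spec.seed, si, fi, run)
        proto = TitrationProtocol(
            coarse_step_low_f=protocol.coarse_step_low_f,
            coarse_step_high_f=protocol.coarse_step_high_f,
            low_f_cutoff=protocol.low_f_cutoff,
            fine_divisor=protocol.fine_divisor,
            n_fine_pulses=protocol.n_fine_pulses,
            start_amplitude=protocol.start_amplitude,
            ceiling=spec.ceilings.get(f, inf),
        )
        run_id = f"run{run}"
        res = run_titration(
            lambda B: subject.response_probability(f, B),
            proto,
            rng,
            frequency=f,
            subject_id=subject.subject_id,
            run_id=run_id,
        )
        responses.extend(res.responses)
        titrations[(subject.subject_id, f, run_id)] = res
        return res

    for si, subject in enumerate(cohort):
        for fi, f in enumerate(spec.frequencies):
            res = one_run(si, subject, fi, f, run=0)
            if res.censored:
                thresholds.append(
                    SubjectThreshold(subject.subject_id, f, censored_at=res.censored_at)
                )
            else:
                # the estimate cannot exceed the amplifier range actually probed
                b_th = min(res.fit.B_th, spec.ceilings.get(f, inf))
                thresholds.append(
                    SubjectThreshold(subject.subject_id, f, b_th=b_th)
                )

    if retest:
        for si, subject in enumerate(cohort[:n_retest_subjects]):
            for f in retest_frequencies:
                fi = spec.frequencies.index(f)
                first = titrations.get((subject.subject_id, f, "run0"))
                second = one_run(si, subject, fi, f, run=1)
                if first and first.fit and second.fit and not (first.censored or second.censored):
                    retest_pairs[f].append((first.fit.B_th, second.fit.B_th))

    return ExperimentResult(responses, thresholds, titrations, retest_pairs)
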