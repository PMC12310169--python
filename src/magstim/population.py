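"""Censoring-aware population threshold statistics.

Per-subject thresholds at one frequency are modeled as draws from a Gaussian
N(mean, sd^2).  Subjects who felt nothing up to the amplifier ceiling are
right-censored: they enter the cohort denominator but contribute no threshold
value.  The population mean and SD are estimated by fitting the Gaussian CDF
Phi((B - mean)/sd) to the empirical fraction-of-cohort-stimulated curve
evaluated at the observed thresholds (midpoint plotting positions
(i - 1/2)/N over the *full* cohort size N), which implicitly corrects the
upward bias a censored-blind average would have.  A right-censored Gaussian
maximum-likelihood estimator is provided as an independent cross-check.

Also here: percent change between thresholds, independent-samples t
comparison between frequencies, Bland-Altman test-retest agreement, and the
cohort coefficient of variation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "SubjectThreshold",
    "PopulationFit",
    "BlandAltman",
    "pooled_cdf_fit",
    "censored_mle",
    "percent_change",
    "compare_frequencies",
    "test_retest",
    "cohort_cv",
    "SD_FLOOR",
]

#: Default SD floor (mT) keeping fits defined on degenerate cohorts.
SD_FLOOR = 1e-3


@dataclass(frozen=True)
class SubjectThreshold:
    """One subject's threshold at one frequency, or its censoring bound."""

    subject_id: str
    frequency: float  # Hz
    b_th: float | None = None  # mT, absent if censored
    censored_at: float | None = None  # ceiling in mT, present iff censored

    def __post_init__(self) -> None:
        if (self.b_th is None) == (self.censored_at is None):
            raise ValueError("exactly one of b_th / censored_at must be present")

    @property
    def censored(self) -> bool:
        return self.censored_at is not None


@dataclass(frozen=True)
class PopulationFit:
    frequency: float  # Hz
    mean: float  # mT
    sd: float  # mT
    n_observed: int
    n_censored: int


@dataclass(frozen=True)
class BlandAltman:
    """Test-retest agreement: mean difference, limits of agreement, % changes."""

    mean_difference: float
    loa_lower: float
    loa_upper: float
    percent_changes: tuple[float, ...]


def _split(thresholds) -> tuple[np.ndarray, np.ndarray, float]:
    obs = np.array([t.b_th for t in thresholds if not t.censored], dtype=float)
    cens = np.array([t.censored_at for t in thresholds if t.censored], dtype=float)
    freqs = {t.frequency for t in thresholds}
    if len(freqs) > 1:
        raise ValueError("thresholds must all belong to one frequency")
    return obs, cens, freqs.pop() if freqs else float("nan")


def pooled_cdf_fit(thresholds, sd_floor: float = SD_FLOOR) -> PopulationFit:
    """Fit N(mean, sd) to a cohort's thresholds via the Gaussian CDF.

    Observed thresholds are ranked within the full cohort of size N (censored
    bounds exceed every observed value by construction, so observed values
    occupy the lowest ranks); the empirical stimulated fraction at the i-th
    smallest observed threshold is (i - 1/2)/N, and (mean, sd) minimize the
    squared distance of Phi((B - mean)/sd) from those fractions.  When
    subjects are censored, the stimulated fraction is also known exactly at
    each ceiling (everyone censored there felt nothing), so one anchor point
    (ceiling, n_below/N) per distinct ceiling joins the fit; this matches the
    censored-MLE cross-check closely, while omitting it leaves the fit badly
    underdetermined at heavy censoring.

    Raises on an all-censored cohort or a single observation (sd is not
    identifiable); a degenerate cohort of identical thresholds returns that
    value with sd at the floor.
    """
    obs, cens, freq = _split(thresholds)
    n_obs, n_cens = obs.size, cens.size
    if n_obs == 0:
        raise ValueError("all subjects censored; population fit impossible")
    if n_obs < 2:
        raise ValueError("need at least 2 observed thresholds (sd unidentifiable)")
    if cens.size and np.min(cens) < np.max(obs):
        raise ValueError("censoring bound below an observed threshold is inconsistent")
    N = n_obs + n_cens
    x = np.sort(obs)
    frac = (np.arange(1, n_obs + 1) - 0.5) / N
    if n_cens:
        for c in np.unique(cens):
            x = np.append(x, c)
            frac = np.append(frac, np.sum(obs <= c) / N)
    s0 = float(np.std(obs, ddof=1))
    if s0 < sd_floor:
        return PopulationFit(freq, float(np.mean(obs)), sd_floor, n_obs, n_cens)
    p0 = (float(np.mean(obs)), s0)
    popt, _ = optimize.curve_fit(
        lambda B, mu, sd: stats.norm.cdf(B, loc=mu, scale=sd),
        x, frac, p0=p0,
        bounds=([-np.inf, sd_floor], [np.inf, np.inf]),
        maxfev=10000,
    )
    return PopulationFit(freq, float(popt[0]), float(max(popt[1], sd_floor)), n_obs, n_cens)


def censored_mle(thresholds, sd_floor: float = SD_FLOOR) -> tuple[float, float]:
    """Right-censored Gaussian maximum likelihood (mean, sd).

    Independent cross-check for :func:`pooled_cdf_fit`: observed values
    contribute the normal density, censored subjects the survival function at
    their ceiling.
    """
    obs, cens, _ = _split(thresholds)
    if obs.size < 2:
        raise ValueError("need at least 2 observed thresholds")

    def nll(p):
        mu, log_sd = p
        sd = np.exp(log_sd)
        ll = np.sum(stats.norm.logpdf(obs, mu, sd))
        if cens.size:
            ll += np.sum(stats.norm.logsf(cens, mu, sd))
        return -ll

    s0 = max(float(np.std(obs, ddof=1)), sd_floor)
    res = optimize.minimize(nll, [float(np.mean(obs)), np.log(s0)], method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    mu, log_sd = res.x
    return float(mu), float(max(np.exp(log_sd), sd_floor))


def percent_change(reference: float, value: float) -> float:
    """Relative change of ``value`` vs ``reference`` in percent: 100*(v/r - 1)."""
    if reference <= 0:
        raise ValueError("reference must be > 0")
    return 100.0 * (value / reference - 1.0)


def compare_frequencies(group_a, group_b, equal_var: bool = True) -> tuple[float, float]:
    """Two-sided independent-samples t-test between two threshold groups.

    Student (pooled-variance) by default, Welch with ``equal_var=False``.
    Two identical constant groups have no evidence of a difference and return
    (0.0, 1.0) rather than a 0/0 statistic.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return 0.0, 1.0
    with warnings.catch_warnings():
        # near-identical groups (e.g. heavy ceiling clustering) trip scipy's
        # precision-loss advisory; the degenerate exact-equality case is
        # already short-circuited above
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def test_retest(pairs) -> BlandAltman:
    """Bland-Altman agreement summary for (test, retest) threshold pairs.

    Differences are retest - test; limits of agreement are the mean
    difference +/- 1.96 times the population (ddof=0) SD of the differences.
    Per-pair percent change is relative to the test value.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 (test, retest) pairs")
    diff = arr[:, 1] - arr[:, 0]
    m = float(np.mean(diff))
    s = float(np.std(diff, ddof=0))
    pct = tuple(percent_change(t, r) for t, r in arr)
    return BlandAltman(m, m - 1.96 * s, m + 1.96 * s, pct)


# the leading "test" in the field's name for this analysis confuses pytest's
# collector when the function is imported into a test module
test_retest.__test__ = False  # type: ignore[attr-defined]


def cohort_cv(fit: PopulationFit) -> float:
    """Coefficient of variation of the cohort, 100*sd/mean, in percent."""
    if fit.mean <= 0:
        raise ValueError("mean must be > 0")
    return 100.0 * fit.sd / fit.mean
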