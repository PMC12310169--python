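"""Strength-duration-curve analysis and pulse-duration normalization.

The hyperbolic strength-duration curve (SDC) for sinusoidal stimuli relates
the threshold flux density to stimulus frequency,

    B_th(f) = B_rheo * (1 + 1/(2 * tau_chron * f)),

with rheobase B_rheo (high-frequency asymptote) and chronaxie tau_chron (the
duration at which the threshold is twice the rheobase).  ``fit_sdc``
estimates both from per-frequency mean thresholds, by convention using only
frequencies at or below a cutoff (default 10 kHz) where the hyperbolic model
is considered applicable, and reports residuals at every frequency so
high-frequency deviations can be examined.

Two duration conversions accompany the SDC:

* the IEC 60601-2-33 *effective stimulus duration* t_eff — peak-to-peak
  amplitude difference of the first two waveform extrema divided by the
  maximum slope in between — which equals 1/(pi f) for a sinusoid and the
  inter-plateau ramp time for a trapezoid, making thresholds comparable
  across waveform shapes;
* the empirical total-pulse-duration scaling B_norm(T) = 1 + alpha *
  exp(-(T/beta)^gamma) (alpha = 0.44, beta = 4.32 ms, gamma = 0.60), which
  converts thresholds measured with a fixed cycle count (hence
  frequency-dependent duration) to a common duration, e.g. the infinite-
  duration (continuous-wave) limit relevant to MPI drive fields.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import inf, pi

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "SDCFit",
    "ScalingParams",
    "EffectiveDuration",
    "hyperbolic_threshold",
    "fit_sdc",
    "effective_duration",
    "duration_norm",
    "scale_to_duration",
]


@dataclass(frozen=True)
class SDCFit:
    B_rheo: float  # mT
    tau_chron: float  # s
    fit_cutoff: float  # Hz
    frequencies: tuple[float, ...]  # all input frequencies, Hz
    residuals: tuple[float, ...]  # observed - model at every frequency, mT

    def predict(self, f):
        return hyperbolic_threshold(f, self.B_rheo, self.tau_chron)


@dataclass(frozen=True)
class ScalingParams:
    """Parameters of the total-pulse-duration threshold scaling."""

    alpha: float = 0.44
    beta_ms: float = 4.32  # ms
    gamma: float = 0.60

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta_ms <= 0 or not (0 < self.gamma <= 1):
            raise ValueError("require alpha >= 0, beta_ms > 0, 0 < gamma <= 1")


@dataclass(frozen=True)
class EffectiveDuration:
    t_eff: float  # s
    t_pulse: float  # s
    waveform_kind: str  # sinusoid | trapezoid | generic


def hyperbolic_threshold(f, B_rheo: float, tau_chron: float):
    """Hyperbolic SDC threshold at frequency f (vectorized)."""
    if B_rheo <= 0 or tau_chron <= 0:
        raise ValueError("B_rheo and tau_chron must be > 0")
    f = np.asarray(f, dtype=float)
    out = B_rheo * (1.0 + 1.0 / (2.0 * tau_chron * f))
    return float(out) if out.ndim == 0 else out


def fit_sdc(frequencies, mean_thresholds, cutoff: float = 10e3) -> SDCFit:
    """Least-squares (B_rheo, tau_chron) on thresholds with f <= cutoff.

    Unweighted nonlinear least squares; initialization B_rheo = min
    threshold, tau_chron = 200 us, both bounded positive.  Residuals
    (observed - fitted) are reported at *all* supplied frequencies, including
    those above the cutoff, where systematic positive residuals signal the
    breakdown of the hyperbolic model.
    """
    f = np.asarray(frequencies, dtype=float)
    th = np.asarray(mean_thresholds, dtype=float)
    if f.size != th.size:
        raise ValueError("frequencies and mean_thresholds must align")
    mask = f <= cutoff
    if mask.sum() < 3:
        raise ValueError("need at least 3 frequencies at or below the cutoff")
    p0 = (float(np.min(th[mask])), 200e-6)
    popt, _ = curve_fit(
        lambda x, b, tau: b * (1.0 + 1.0 / (2.0 * tau * x)),
        f[mask], th[mask], p0=p0,
        bounds=([1e-12, 1e-12], [np.inf, np.inf]),
        maxfev=20000,
    )
    B_rheo, tau = float(popt[0]), float(popt[1])
    resid = th - hyperbolic_threshold(f, B_rheo, tau)
    return SDCFit(B_rheo, tau, cutoff, tuple(f.tolist()), tuple(resid.tolist()))


def _generic_t_eff(times: np.ndarray, values: np.ndarray, plateau_tol: float) -> tuple[float, float, float]:
    """IEC effective duration from a sampled waveform.

    Extrema are located where the discrete derivative changes sign; slope
    magnitudes below ``plateau_tol`` times the maximum slope count as zero,
    so trapezoid plateaus register as (the start of) an extremum.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    dv = np.diff(v)
    dt = np.diff(t)
    slope = dv / dt
    smax = np.max(np.abs(slope))
    if smax == 0:
        raise ValueError("constant waveform has no extrema")
    s = np.where(np.abs(slope) < plateau_tol * smax, 0.0, np.sign(slope))
    # an extremum is a slope sign flip, or the start of a plateau after a ramp;
    # the ramp *leaving* an already-recorded plateau peak is not a new extremum
    extrema: list[int] = []
    prev = 0.0
    for i, si in enumerate(s):
        if prev != 0.0 and si != 0.0 and si != prev:
            extrema.append(i)
            prev = si
        elif prev != 0.0 and si == 0.0:
            extrema.append(i)
            prev = 0.0
        elif prev == 0.0 and si != 0.0:
            prev = si
        if len(extrema) == 2:
            break
    if len(extrema) < 2:
        raise ValueError("waveform must contain at least 2 extrema")
    i1, i2 = extrema
    dv_pk = abs(v[i2] - v[i1])
    smax_int = np.max(np.abs(slope[i1:i2])) if i2 > i1 else smax
    return dv_pk / smax_int, float(t[i1]), float(t[i2])


def effective_duration(
    frequency: float | None = None,
    t_pulse: float | None = None,
    waveform: tuple[np.ndarray, np.ndarray] | None = None,
    plateau_tol: float = 1e-3,
) -> EffectiveDuration:
    """IEC effective stimulus duration t_eff.

    Exactly one input form must be given:

    * ``frequency`` (Hz): analytic sinusoid value t_eff = 1/(pi f), with
      t_pulse = 1/(2f) (half period, peak to peak);
    * ``t_pulse`` (s): trapezoid convention t_eff = t_pulse;
    * ``waveform`` = (times, values): the generic sampled-waveform operator
      (first-two-peaks amplitude difference over maximum in-between slope).
    """
    given = [frequency is not None, t_pulse is not None, waveform is not None]
    if sum(given) != 1:
        raise ValueError("give exactly one of frequency, t_pulse, waveform")
    if frequency is not None:
        if frequency <= 0:
            raise ValueError("frequency must be > 0")
        tp = 1.0 / (2.0 * frequency)
        return EffectiveDuration(t_eff=(2.0 / pi) * tp, t_pulse=tp, waveform_kind="sinusoid")
    if t_pulse is not None:
        if t_pulse <= 0:
            raise ValueError("t_pulse must be > 0")
        return EffectiveDuration(t_eff=t_pulse, t_pulse=t_pulse, waveform_kind="trapezoid")
    times, values = waveform
    t_eff, t1, t2 = _generic_t_eff(times, values, plateau_tol)
    return EffectiveDuration(t_eff=float(t_eff), t_pulse=float(t2 - t1), waveform_kind="generic")


def duration_norm(T_pulse_ms: float, params: ScalingParams = ScalingParams()) -> float:
    """Rheobase-normalized threshold factor for total pulse duration T (ms).

    B_norm(T) = 1 + alpha * exp(-(T/beta)^gamma): monotonically decreasing in
    T, in (1, 1 + alpha], tending to 1 (the rheobase) as T goes to infinity.
    The argument is strictly in milliseconds (beta is in ms).
    """
    if T_pulse_ms <= 0:
        raise ValueError("T_pulse_ms must be > 0")
    return 1.0 + params.alpha * np.exp(-((T_pulse_ms / params.beta_ms) ** params.gamma))


def scale_to_duration(
    B_measured: float,
    T_measured_ms: float,
    T_target_ms: float = inf,
    params: ScalingParams = ScalingParams(),
) -> float:
    """Convert a threshold between total pulse durations.

    B(T_target) = B_measured * B_norm(T_target) / B_norm(T_measured); an
    infinite target duration divides by B_norm(T_measured) alone (continuous-
    wave limit).  Composes exactly: scaling A->B then B->C equals A->C.
    """
    if B_measured <= 0 or T_measured_ms <= 0 or T_target_ms <= 0:
        raise ValueError("inputs must be > 0")
    num = 1.0 if np.isinf(T_target_ms) else duration_norm(T_target_ms, params)
    return B_measured * num / duration_norm(T_measured_ms, params)
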