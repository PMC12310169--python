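"""Single-titration threshold estimation and the virtual titration protocol.

A subject's probability of reporting a sensation at peak field amplitude B
(mT at coil center) is modeled by the two-parameter logistic

    g(B) = 1 / (1 + exp(-(B - B_th) / B_width))

where B_th is the threshold (50% point) and B_width the transition width.
``fit_sigmoid`` estimates (B_th, B_width) from binary responses by penalized
maximum likelihood; ``run_titration`` reproduces the experimental protocol
against a virtual subject: a coarse amplitude ascent (~10 mT steps below
1 kHz, ~5 mT above) until the first reported sensation, then a fine up/down
staircase with step = 1/80th of the initial threshold estimate, refitting the
sigmoid after every response.  A subject whose threshold exceeds the
amplifier ceiling yields a censored record, not an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import inf

import numpy as np
from scipy.special import expit

__all__ = [
    "StimResponse",
    "SigmoidFit",
    "TitrationProtocol",
    "TitrationResult",
    "sigmoid_probability",
    "fit_sigmoid",
    "fit_sigmoid_arrays",
    "run_titration",
]


@dataclass(frozen=True)
class StimResponse:
    """One field pulse and the subject's binary response."""

    subject_id: str
    frequency: float  # Hz
    amplitude: float  # peak B at coil center, mT
    response: int  # 0 = no sensation, 1 = sensation
    run_id: str = ""

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        if self.response not in (0, 1):
            raise ValueError("response must be 0 or 1")


@dataclass(frozen=True)
class SigmoidFit:
    B_th: float  # mT
    B_width: float  # mT
    n_pulses: int
    converged: bool = True
    separation_flag: bool = False


@dataclass(frozen=True)
class TitrationProtocol:
    """Step sizes and limits of the titration procedure (amplitudes in mT)."""

    coarse_step_low_f: float = 10.0   # below low_f_cutoff
    coarse_step_high_f: float = 5.0   # at or above low_f_cutoff
    low_f_cutoff: float = 1000.0      # Hz
    fine_divisor: int = 80
    n_fine_pulses: int = 24
    start_amplitude: float | None = None  # default: one coarse step
    ceiling: float = inf              # amplifier limit, mT

    def __post_init__(self) -> None:
        if min(self.coarse_step_low_f, self.coarse_step_high_f) <= 0:
            raise ValueError("coarse steps must be > 0")
        if self.fine_divisor < 1 or self.n_fine_pulses < 1:
            raise ValueError("fine_divisor and n_fine_pulses must be >= 1")
        if self.ceiling <= 0:
            raise ValueError("ceiling must be > 0")

    def coarse_step(self, frequency: float) -> float:
        if frequency < self.low_f_cutoff:
            return self.coarse_step_low_f
        return self.coarse_step_high_f


@dataclass(frozen=True)
class TitrationResult:
    """Outcome of one titration: a fit, or a censoring marker at the ceiling."""

    responses: list[StimResponse]
    fit: SigmoidFit | None
    censored: bool = False
    censored_at: float | None = None


def sigmoid_probability(B, B_th: float, B_width: float):
    """Response probability of the logistic psychometric curve.

    Equals 0.5 at B = B_th; B_width sets the 25-75% span (0.75 is reached at
    B_th + B_width*ln 3).  Vectorized over B.
    """
    if B_width <= 0:
        raise ValueError("B_width must be > 0")
    out = expit((np.asarray(B, dtype=float) - B_th) / B_width)
    if np.isscalar(B) or np.ndim(B) == 0:
        return float(out)
    return out


def fit_sigmoid_arrays(
    amplitudes: np.ndarray,
    responses: np.ndarray,
    width_floor: float = 1e-6,
    ridge: float = 1e-4,
    max_iter: int = 60,
) -> SigmoidFit:
    """Penalized maximum-likelihood logistic fit on raw arrays.

    Amplitudes are standardized, and a tiny ridge on the slope (i.e. on
    1/B_width) keeps the likelihood bounded near separation; perfectly
    separable data short-circuit to the midpoint rule: B_th is the center of
    the separating gap and B_width = max(width_floor, gap/4), with
    ``separation_flag`` set (the unpenalized MLE diverges there).
    """
    B = np.asarray(amplitudes, dtype=float)
    y = np.asarray(responses, dtype=float)
    if B.size != y.size or B.size == 0:
        raise ValueError("amplitudes and responses must be equal-length, non-empty")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0:
        raise ValueError("cannot fit a sigmoid: no positive (stim) responses")
    if n_neg == 0:
        raise ValueError("cannot fit a sigmoid: no negative (no-stim) responses")

    hi_neg = float(np.max(B[y == 0]))
    lo_pos = float(np.min(B[y == 1]))
    if hi_neg < lo_pos:  # perfectly separable
        gap = lo_pos - hi_neg
        return SigmoidFit(
            B_th=0.5 * (hi_neg + lo_pos),
            B_width=max(width_floor, gap / 4.0),
            n_pulses=B.size,
            converged=True,
            separation_flag=True,
        )

    mB = float(np.mean(B))
    sB = float(np.std(B))
    if sB == 0.0:
        raise ValueError("all amplitudes identical with mixed responses; threshold undefined")
    z = (B - mB) / sB
    # Newton-Raphson on (a0, a1) for p = sigma(a0 + a1 z), ridge on a1
    a0, a1 = 0.0, 1.0
    converged = False
    for _ in range(max_iter):
        eta = a0 + a1 * z
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
        w = p * (1.0 - p) + 1e-12
        g0 = np.sum(p - y)
        g1 = np.sum((p - y) * z) + 2.0 * ridge * a1
        h00 = np.sum(w)
        h01 = np.sum(w * z)
        h11 = np.sum(w * z * z) + 2.0 * ridge
        det = h00 * h11 - h01 * h01
        if det <= 0:
            break
        d0 = (h11 * g0 - h01 * g1) / det
        d1 = (-h01 * g0 + h00 * g1) / det
        # damp large steps for stability far from optimum
        step = max(abs(d0), abs(d1))
        if step > 4.0:
            d0 *= 4.0 / step
            d1 *= 4.0 / step
        a0 -= d0
        a1 -= d1
        if max(abs(d0), abs(d1)) < 1e-10:
            converged = True
            break
    if a1 <= 0:
        # pathological labeling (response rate decreasing with amplitude)
        a1 = 1e-6
        converged = False
    B_th = mB - sB * a0 / a1
    B_width = max(width_floor, sB / a1)
    return SigmoidFit(B_th=float(B_th), B_width=float(B_width), n_pulses=B.size, converged=converged)


def fit_sigmoid(responses, width_floor: float = 1e-6) -> SigmoidFit:
    """Fit the psychometric sigmoid to a list of :class:`StimResponse`."""
    recs = list(responses)
    if not recs:
        raise ValueError("no responses to fit")
    B = np.array([r.amplitude for r in recs])
    y = np.array([r.response for r in recs])
    return fit_sigmoid_arrays(B, y, width_floor=width_floor)


def run_titration(
    true_curve,
    protocol: TitrationProtocol,
    rng: np.random.Generator,
    frequency: float = 1000.0,
    subject_id: str = "sim",
    run_id: str = "",
) -> TitrationResult:
    """Titrate a virtual subject whose response probability is ``true_curve``.

    Coarse phase: ascend from ``start_amplitude`` (default one coarse step) in
    frequency-appropriate steps, capping at the ceiling, until the first
    positive response.  Reaching the ceiling without any sensation returns a
    censored result.  Fine phase: an up/down staircase around the running
    threshold estimate with step = (first positive amplitude)/fine_divisor,
    refitting the sigmoid after every response; ``n_fine_pulses`` pulses.
    """
    step = protocol.coarse_step(frequency)
    start = protocol.start_amplitude if protocol.start_amplitude is not None else step
    if start >= protocol.ceiling:
        raise ValueError("start_amplitude must lie below the ceiling")

    responses: list[StimResponse] = []
    amps: list[float] = []
    ys: list[int] = []

    def pulse(B: float) -> int:
        y = int(rng.random() < true_curve(B))
        responses.append(
            StimResponse(subject_id=subject_id, frequency=frequency, amplitude=B, response=y, run_id=run_id)
        )
        amps.append(B)
        ys.append(y)
        return y

    # --- coarse ascent ---
    B = start
    first_positive = None
    while True:
        B_apply = min(B, protocol.ceiling)
        y = pulse(B_apply)
        if y:
            first_positive = B_apply
            break
        if B_apply >= protocol.ceiling:
            return TitrationResult(responses, fit=None, censored=True, censored_at=protocol.ceiling)
        B += step

    # --- fine staircase ---
    fine = first_positive / protocol.fine_divisor
    floor = fine / 10.0
    est = first_positive
    last = 1
    for _ in range(protocol.n_fine_pulses):
        if 0 in ys and 1 in ys:
            est = fit_sigmoid_arrays(np.array(amps), np.array(ys), width_floor=floor).B_th
        else:  # all positives so far (started at/above threshold): walk down
            est = amps[-1]
        # keep the staircase local: an ill-conditioned interim fit (e.g. one
        # lucky positive below many negatives) must not fling the next pulse
        # outside the amplitude region explored so far
        est = min(max(est, min(amps) - step), max(amps) + step)
        nxt = est - fine if last else est + fine
        nxt = min(max(nxt, fine), protocol.ceiling)
        last = pulse(nxt)

    if 0 in ys and 1 in ys:
        final = fit_sigmoid_arrays(np.array(amps), np.array(ys), width_floor=floor)
    else:
        final = SigmoidFit(B_th=float(np.min(amps)), B_width=floor, n_pulses=len(amps), converged=False)
    return TitrationResult(responses, fit=final, censored=False)
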