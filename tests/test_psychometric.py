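"""Psychometric sigmoid fitting and the virtual titration protocol."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from magstim.psychometric import (
    SigmoidFit,
    StimResponse,
    TitrationProtocol,
    fit_sigmoid,
    fit_sigmoid_arrays,
    run_titration,
    sigmoid_probability,
)


class TestSigmoidProbability:
    def test_midpoint_and_quartile_identities(self):
        assert sigmoid_probability(8.23, 8.23, 0.1) == pytest.approx(0.5)
        assert sigmoid_probability(8.23 + 0.1 * np.log(3), 8.23, 0.1) == pytest.approx(0.75)

    def test_tails(self):
        assert sigmoid_probability(0.01, 10.0, 0.1) < 1e-10
        assert sigmoid_probability(100.0, 10.0, 0.1) > 1 - 1e-10

    @given(
        st.floats(0.1, 100.0),
        st.floats(0.1, 100.0),
        st.floats(1e-3, 10.0),
        st.floats(1e-3, 10.0),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_monotone_and_scale_invariant(self, b1, b2, th, w):
        lo, hi = sorted((b1, b2))
        assert sigmoid_probability(lo, th, w) <= sigmoid_probability(hi, th, w)
        k = 1000.0  # e.g. mT -> uT relabeling
        assert sigmoid_probability(b1, th, w) == pytest.approx(
            sigmoid_probability(k * b1, k * th, k * w), rel=1e-12
        )

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            sigmoid_probability(1.0, 1.0, 0.0)


class TestFitSigmoid:
    def test_recovery_from_simulated_responses(self, rng):
        """200 pulses at width ~1% of threshold recover B_th within 2%."""
        B_th, B_w = 8.23, 0.0823
        B = np.linspace(B_th - 5 * B_w, B_th + 5 * B_w, 200)
        y = (rng.random(200) < sigmoid_probability(B, B_th, B_w)).astype(int)
        fit = fit_sigmoid_arrays(B, y)
        assert fit.B_th == pytest.approx(B_th, rel=0.02)

    def test_perfect_separation_midpoint_rule(self):
        recs = [
            StimResponse("s", 4040.0, a, 0) for a in [5.0, 5.1, 5.2, 5.3, 5.4]
        ] + [StimResponse("s", 4040.0, a, 1) for a in [5.5, 5.6, 5.7, 5.8, 5.9]]
        fit = fit_sigmoid(recs)
        assert fit.separation_flag
        assert fit.B_th == pytest.approx(5.45)
        assert fit.B_width == pytest.approx((5.5 - 5.4) / 4)

    @pytest.mark.parametrize("resp,missing", [(0, "positive"), (1, "negative")])
    def test_single_class_rejected_naming_missing_class(self, resp, missing):
        recs = [StimResponse("s", 1e3, a, resp) for a in (1.0, 2.0, 3.0)]
        with pytest.raises(ValueError, match=missing):
            fit_sigmoid(recs)

    def test_unit_round_trip_equivariance(self, rng):
        B = np.linspace(7.0, 9.0, 60)
        y = (rng.random(60) < sigmoid_probability(B, 8.0, 0.3)).astype(int)
        fit_mt = fit_sigmoid_arrays(B, y, width_floor=1e-9)
        fit_t = fit_sigmoid_arrays(B / 1000.0, y, width_floor=1e-12)
        assert fit_t.B_th * 1000.0 == pytest.approx(fit_mt.B_th, rel=1e-6)
        assert fit_t.B_width * 1000.0 == pytest.approx(fit_mt.B_width, rel=1e-4)

    def test_mle_beats_generating_parameters(self, rng):
        """The fitted point never has lower likelihood than the truth."""

        def loglik(B, y, th, w):
            p = sigmoid_probability(B, th, w)
            p = np.clip(p, 1e-12, 1 - 1e-12)
            return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))

        for _ in range(20):
            th, w = rng.uniform(3, 12), rng.uniform(0.05, 0.8)
            B = np.linspace(th - 3 * w, th + 3 * w, 50)
            y = (rng.random(50) < sigmoid_probability(B, th, w)).astype(int)
            if y.min() == y.max():
                continue
            fit = fit_sigmoid_arrays(B, y, width_floor=1e-9)
            if fit.separation_flag:
                continue
            assert loglik(B, y, fit.B_th, fit.B_width) >= loglik(B, y, th, w) - 1e-6


class TestRunTitration:
    def test_deterministic_subject_converges_to_threshold(self):
        proto = TitrationProtocol(coarse_step_high_f=5.0, start_amplitude=1.0)
        res = run_titration(
            lambda B: sigmoid_probability(B, 12.0, 1e-9),
            proto,
            np.random.default_rng(1),
            frequency=2000.0,
        )
        # first positive lands at 16 mT -> fine step 0.2 mT
        assert not res.censored
        assert res.fit.B_th == pytest.approx(12.0, abs=0.2)

    def test_ceiling_without_sensation_is_censored(self):
        proto = TitrationProtocol(ceiling=10.0, start_amplitude=5.0)
        res = run_titration(
            lambda B: sigmoid_probability(B, 15.0, 0.1),
            proto,
            np.random.default_rng(2),
            frequency=2000.0,
        )
        assert res.censored and res.censored_at == 10.0
        assert res.fit is None
        assert all(r.response == 0 for r in res.responses)
        assert max(r.amplitude for r in res.responses) == 10.0

    def test_stochastic_subject_recovery_rate(self):
        """Width 5% of threshold, 24 fine pulses: within 5% in >= 90/100 runs."""
        hits = 0
        for s in range(100):
            res = run_titration(
                lambda B: sigmoid_probability(B, 10.0, 0.5),
                TitrationProtocol(),
                np.random.default_rng(1000 + s),
                frequency=5000.0,
            )
            hits += res.fit is not None and abs(res.fit.B_th - 10.0) / 10.0 < 0.05
        assert hits >= 90

    def test_fine_phase_stays_local(self):
        """Fine-phase moves never exceed ~the protocol fine step."""
        proto = TitrationProtocol(coarse_step_high_f=5.0, start_amplitude=1.0)
        res = run_titration(
            lambda B: sigmoid_probability(B, 12.0, 1e-9),
            proto,
            np.random.default_rng(3),
            frequency=2000.0,
        )
        amps = [r.amplitude for r in res.responses]
        first_positive = next(a for a, r in zip(amps, res.responses) if r.response)
        fine = first_positive / proto.fine_divisor
        assert fine == pytest.approx(16.0 / 80)
        # once the bracket is established the staircase moves by at most one
        # fine step around an estimate that itself shifts by less than a step
        settled = amps[amps.index(first_positive) + 6:]
        assert np.max(np.abs(np.diff(settled))) <= 2 * fine + 1e-12

    def test_bias_vanishes_with_narrow_width_and_fine_step(self):
        """Titration bias shrinks as the subject sharpens and steps refine."""
        errs = []
        for divisor in (20, 320):
            proto = TitrationProtocol(fine_divisor=divisor, n_fine_pulses=40, start_amplitude=1.0)
            res = run_titration(
                lambda B: sigmoid_probability(B, 12.0, 1e-9),
                proto,
                np.random.default_rng(4),
                frequency=5000.0,
            )
            errs.append(abs(res.fit.B_th - 12.0))
        assert errs[1] < errs[0]
        assert errs[1] < 0.05

    def test_start_above_ceiling_rejected(self):
        with pytest.raises(ValueError):
            run_titration(
                lambda B: 0.5,
                TitrationProtocol(ceiling=4.0, start_amplitude=5.0),
                np.random.default_rng(0),
            )
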