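import numpy as np
import pytest

from wavecall.boundary_detection import (
    average_zero_profile,
    call_boundary,
    refine_boundary,
    rough_boundary,
)
from wavecall.genome_io import IntronSignal
from wavecall.signal_model import SmoothingSpec
from wavecall.simulator import SimGeneParams, simulate_gene

from conftest import make_signal


class TestAverageZeroProfile:
    def test_identical_replicates_average_to_each(self, rng):
        vals = rng.random(60) + 1.0
        sigs = [make_signal(values=vals, n_bins=60) for _ in range(4)]
        zero = average_zero_profile(sigs)
        np.testing.assert_allclose(zero.raw_mean, vals)
        assert zero.n_replicates == 4

    def test_elementwise_mean(self):
        a = make_signal(values=np.tile([0.0, 2.0], 30), n_bins=60)
        b = make_signal(values=np.tile([2.0, 0.0], 30), n_bins=60)
        zero = average_zero_profile([a, b])
        np.testing.assert_allclose(zero.raw_mean, 1.0)

    def test_single_replicate_warns(self):
        sig = make_signal(values=np.ones(60), n_bins=60)
        with pytest.warns(UserWarning, match="single 0-min replicate"):
            zero = average_zero_profile([sig])
        np.testing.assert_allclose(zero.raw_mean, 1.0)

    def test_mismatched_grids_rejected(self):
        a = make_signal(n_bins=60)
        b = make_signal(n_bins=60, start_kb=0.1)
        with pytest.raises(ValueError, match="grid"):
            average_zero_profile([a, b])

    def test_denominator_strictly_positive(self, rng):
        sigs = [make_signal(values=rng.poisson(0.3, 200).astype(float), n_bins=200)
                for _ in range(4)]
        zero = average_zero_profile(sigs)
        assert (zero.denominator > 0).all()


class TestRoughBoundary:
    def _offsets(self, n=200):
        return np.arange(n) * 0.1

    def test_sample_equal_zero_is_first_position(self):
        zero = np.ones(200)
        idx, status = rough_boundary(zero, zero, self._offsets())
        assert idx is None and status == "first-position"

    def test_sample_always_above_zero_is_no_boundary(self):
        zero = np.ones(200)
        idx, status = rough_boundary(1.2 * zero, zero, self._offsets())
        assert idx is None and status == "no-boundary"

    def test_wave_end_found_past_front(self):
        offs = self._offsets(400)
        zero = np.zeros(400)
        sample = np.maximum(0.0, 14.0 - offs) * 2.0  # wave ending at 14 Kb
        idx, status = rough_boundary(sample, zero, offs)
        assert status == "ok"
        assert offs[idx] == pytest.approx(14.0, abs=0.1)

    def test_tolerance_is_relative(self):
        offs = self._offsets(100)
        zero = np.ones(100)
        sample = np.full(100, 1.09)
        sample[:30] = 5.0  # wave over the first 3 Kb
        idx, status = rough_boundary(sample, zero, offs)
        assert status == "ok" and offs[idx] == pytest.approx(3.0)

    def test_translation_removed_by_background_correction(self, rng):
        # a constant offset on the raw signal is absorbed by the downstream-mode
        # background track, so the corrected signal (hence the rough call) is unchanged
        from wavecall.signal_model import background_correct, background_track, smooth

        raw = rng.poisson(2.0, 300).astype(float) + np.maximum(0.0, 10.0 - self._offsets(300))
        spec = SmoothingSpec()
        corr = background_correct(smooth(raw, spec), background_track(smooth(raw, spec)))
        shifted = background_correct(
            smooth(raw + 5.0, spec), background_track(smooth(raw + 5.0, spec))
        )
        np.testing.assert_allclose(corr, shifted, atol=1e-7)


class TestRefineBoundary:
    def test_flat_derivative_falls_back_to_rough(self):
        deriv = np.zeros(99)
        offs = np.arange(100) * 0.1
        idx, status = refine_boundary(deriv, 50, offs)
        assert idx == 50 and status == "refine-fallback"

    def test_plateau_mode_returns_first_zero_bin_at_front(self):
        # decline over the wave tail (deepest right before the front), exactly 0 past it
        deriv = np.concatenate([-0.05 - 1e-4 * np.arange(60), np.zeros(39)])
        offs = np.arange(100) * 0.1
        idx, status = refine_boundary(deriv, 62, offs, mode="plateau")
        assert status == "ok"
        assert idx == 60

    def test_midpoint_mode_lands_between_dip_and_plateau(self):
        deriv = np.zeros(99)
        deriv[40:60] = -0.05
        deriv[55] = -0.30  # deepest dip at 55, plateau resumes at 60
        offs = np.arange(100) * 0.1
        idx, status = refine_boundary(deriv, 70, offs, mode="midpoint")
        assert status == "ok"
        assert 55 <= idx <= 60

    def test_most_downstream_minimum_starts_search(self):
        deriv = np.zeros(99)
        deriv[20] = -0.05  # upstream dip
        deriv[40] = -0.03  # downstream dip: search anchors here
        offs = np.arange(100) * 0.1
        idx, _ = refine_boundary(deriv, 60, offs, mode="plateau")
        assert idx == 41

    def test_window_cap_two_kb_past_rough(self):
        # derivative stays below -0.002 everywhere after the dip
        deriv = np.full(99, -0.05)
        deriv[30] = -0.30
        offs = np.arange(100) * 0.1
        idx, status = refine_boundary(deriv, 40, offs)
        assert idx == 40 and status == "refine-fallback"

    def test_refined_never_beyond_rough_plus_window(self, rng):
        offs = np.arange(200) * 0.1
        for _ in range(50):
            deriv = rng.normal(0, 0.05, size=199)
            rough = int(rng.integers(30, 180))
            idx, _ = refine_boundary(deriv, rough, offs)
            assert offs[idx] <= offs[rough] + 2.0 + 1e-9


def _noiseless_calls(V, D, I=2.0, bg=1.0, length_kb=60.0):
    p = SimGeneParams("G", length_kb, I_true=I, V_true=V, D_true=D,
                      bg_mean=bg, bg_dispersion=np.inf)
    with pytest.warns(UserWarning):
        zero = average_zero_profile([simulate_gene(p, 0, 0)])
    calls = {
        t: call_boundary(simulate_gene(p, t, 0), zero, timepoint_min=t, replicate=1)
        for t in (4, 8)
    }
    return p, calls


class TestCallBoundary:
    def test_zero_against_itself_is_first_position(self):
        p = SimGeneParams("G", 60.0, I_true=2.0, V_true=3.0, D_true=1.0,
                          bg_mean=1.0, bg_dispersion=np.inf)
        sig0 = simulate_gene(p, 0, 0)
        with pytest.warns(UserWarning):
            zero = average_zero_profile([sig0])
        call = call_boundary(sig0, zero, timepoint_min=4, replicate=1)
        assert call.status == "first-position"
        assert call.rough_kb is None and call.refined_kb is None

    def test_front_beyond_gene_end_is_discarded_by_qc(self):
        # V=6, D=0: the 8-min front (48 Kb) runs past a 40 Kb gene, so no true
        # boundary exists inside it; any spurious call pins to the terminal bins
        # and the resulting fit fails the delay-time window
        from wavecall.elongation_rates import fit_rate, qc_filter

        p, calls = _noiseless_calls(V=6.0, D=0.0, length_kb=40.0)
        c8 = calls[8]
        assert c8.refined_kb is None or c8.refined_kb > 38.0
        if c8.refined_kb is not None and calls[4].refined_kb is not None:
            reps = [
                type(calls[4])("G", 4, r, calls[4].rough_kb, calls[4].refined_kb, "ok")
                for r in (1, 2)
            ] + [
                type(c8)("G", 8, r, c8.rough_kb, c8.refined_kb, "ok") for r in (1, 2, 3)
            ]
            res = fit_rate(reps)
            qc_filter([res], {"G": reps})
            assert not res.pass_qc

    def test_empty_signal_is_no_boundary(self):
        empty = IntronSignal("G", np.empty(0), np.empty(0))
        p = SimGeneParams("G", 60.0, I_true=2.0, V_true=3.0, D_true=1.0,
                          bg_mean=1.0, bg_dispersion=np.inf)
        with pytest.warns(UserWarning):
            zero = average_zero_profile([simulate_gene(p, 0, 0)])
        call = call_boundary(empty, zero, timepoint_min=8, replicate=1)
        assert call.status == "no-boundary"

    def test_monotonicity_noiseless_boundary_gap_is_4v(self):
        for V, D in [(2.0, 0.0), (3.0, 1.0), (4.5, 2.0)]:
            p, calls = _noiseless_calls(V=V, D=D, length_kb=80.0)
            b4, b8 = calls[4].refined_kb, calls[8].refined_kb
            assert b4 is not None and b8 is not None
            # the smoothing-induced front offset is common to both timepoints and
            # cancels in the difference up to refinement quantization (a few bins)
            assert b8 - b4 == pytest.approx(4.0 * V, abs=0.35)

    def test_refined_within_window_of_rough(self):
        p, calls = _noiseless_calls(V=3.0, D=1.0)
        for call in calls.values():
            assert call.refined_kb <= call.rough_kb + 2.0 + 1e-9

    def test_refined_at_least_as_close_as_rough_noiseless(self):
        for V in (2.0, 4.0, 6.0):
            for D in (0.0, 2.0):
                p, calls = _noiseless_calls(V=V, D=D, length_kb=80.0)
                true = p.front_kb(8)
                call = calls[8]
                assert abs(call.refined_kb - true) <= abs(call.rough_kb - true) + 1e-9
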