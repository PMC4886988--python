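import numpy as np
import pytest
from scipy import stats

from conftest import square_geometry
from detrunc.corrector import (
    assign_negatives,
    compute_offset,
    correct_frame,
    negative_value_counts,
)
from detrunc.exceptions import ModelInconsistencyError
from detrunc.image_io import ImageFrame
from detrunc.lognormal_model import LognormalParams, discrete_prob, prob_nonpositive
from detrunc.synthetic import SimulationSpec, graded_params, simulate_frame


def censored_params(censoring: float, tau: float, sigma: float) -> LognormalParams:
    """Parameters with an exact fraction of mass below +1/2."""
    mu = float(np.log(0.5 - tau) - stats.norm.ppf(censoring) * sigma)
    return LognormalParams(mu=mu, sigma=sigma, tau=tau)


class TestNegativeValueCounts:
    def test_no_zeros_means_empty_map(self):
        p = LognormalParams(mu=3.0, sigma=0.5, tau=-20.0)
        assert negative_value_counts(0, p) == {}

    def test_largest_remainder_hand_example(self, monkeypatch):
        """Conditional masses (0.5, 0.3, 0.2) at values (0, −1, −2) with
        four zeros give expectations (2.0, 1.2, 0.8), which must
        integerize to (2, 1, 1): the largest remainder gets the spare."""
        import detrunc.corrector as corr

        p = LognormalParams(mu=1.0, sigma=0.5, tau=-2.0)

        class FakeDist:
            def cdf(self, x):
                # piecewise cdf with conditional masses 0.5/0.3/0.2 at 0/−1/−2
                x = np.asarray(x, dtype=float)
                out = np.select(
                    [x >= 0.5, x >= -0.5, x >= -1.5, x >= -2.5],
                    [1.0, 0.5, 0.2, 0.0],
                    default=0.0,
                )
                return out if out.ndim else float(out)

        monkeypatch.setattr(LognormalParams, "frozen", lambda self: FakeDist())
        monkeypatch.setattr(corr, "prob_nonpositive", lambda p: 1.0)
        counts = corr.negative_value_counts(4, p)
        assert counts == {0: 2, -1: 1, -2: 1}

    def test_totals_and_proportionality(self):
        p = censored_params(0.25, tau=-60.0, sigma=0.45)
        for n_zero in (1, 7, 100, 12345):
            counts = negative_value_counts(n_zero, p)
            assert sum(counts.values()) == n_zero
            assert all(v <= 0 for v in counts)
            f_half = prob_nonpositive(p)
            for i, c in counts.items():
                expected = n_zero * float(discrete_prob(i, p)) / f_half
                assert abs(c - expected) <= 1.0

    def test_deterministic(self):
        p = censored_params(0.2, tau=-40.0, sigma=0.4)
        assert negative_value_counts(500, p) == negative_value_counts(500, p)

    def test_model_without_censored_mass_is_inconsistent(self):
        p = LognormalParams(mu=2.0, sigma=0.3, tau=10.0)  # support > 1/2
        with pytest.raises(ModelInconsistencyError):
            negative_value_counts(5, p)


class TestAssignNegatives:
    def _frame_with_zeros(self, seed=0):
        rng = np.random.default_rng(seed)
        pixels = rng.integers(1, 50, size=(16, 16)).astype(np.int32)
        zero_loc = np.argwhere(rng.random((16, 16)) < 0.2)
        pixels[zero_loc[:, 0], zero_loc[:, 1]] = 0
        return ImageFrame(pixels=pixels), np.argwhere(pixels == 0)

    def test_all_true_zeros_is_identity(self):
        frame, locs = self._frame_with_zeros()
        out = assign_negatives(frame, locs, {0: len(locs)}, seed=1)
        np.testing.assert_array_equal(out.pixels, frame.pixels)
        assert out.signed

    def test_value_multiset_is_exact_and_positives_untouched(self):
        frame, locs = self._frame_with_zeros(seed=2)
        n = len(locs)
        counts = {0: n - n // 2 - n // 3, -1: n // 2, -3: n // 3}
        out = assign_negatives(frame, locs, counts, seed=5)
        placed = out.pixels[locs[:, 0], locs[:, 1]]
        assert {int(v): int(c) for v, c in
                zip(*np.unique(placed, return_counts=True)) if c} == {
                    k: v for k, v in counts.items() if v}
        untouched = np.ones(frame.pixels.shape, dtype=bool)
        untouched[locs[:, 0], locs[:, 1]] = False
        np.testing.assert_array_equal(out.pixels[untouched], frame.pixels[untouched])

    def test_seed_contract(self):
        frame, locs = self._frame_with_zeros(seed=3)
        n = len(locs)
        counts = {0: n - n // 2, -2: n // 2}
        a = assign_negatives(frame, locs, counts, seed=7)
        b = assign_negatives(frame, locs, counts, seed=7)
        c = assign_negatives(frame, locs, counts, seed=8)
        np.testing.assert_array_equal(a.pixels, b.pixels)
        pa = np.sort(a.pixels[locs[:, 0], locs[:, 1]])
        pc = np.sort(c.pixels[locs[:, 0], locs[:, 1]])
        np.testing.assert_array_equal(pa, pc)  # same multiset
        assert not np.array_equal(a.pixels, c.pixels)  # different arrangement

    def test_count_mismatch_rejected(self):
        frame, locs = self._frame_with_zeros(seed=4)
        with pytest.raises(ValueError):
            assign_negatives(frame, locs, {0: len(locs) + 1}, seed=0)

    def test_spot_neighborhood_pattern(self):
        """A Bragg peak on a weak background: positive pixels survive
        bitwise, former zeros end up ≤ 0."""
        from detrunc.synthetic import GaussianSpot

        geom = square_geometry(32)
        spec = SimulationSpec(
            geometry=geom,
            params=[censored_params(0.3, tau=-30.0, sigma=0.4)],
            spots=[GaussianSpot(center=(16.0, 16.0), intensity=30000.0, width=1.5)],
            seed=42,
        )
        truth, observed = simulate_frame(spec)
        assert (observed.pixels == 0).any()
        corrected, _ = correct_frame(observed, geom, n_annuli=1, seed=9)
        was_positive = observed.pixels > 0
        np.testing.assert_array_equal(
            corrected.pixels[was_positive], observed.pixels[was_positive]
        )
        assert (corrected.pixels[observed.pixels == 0] <= 0).all()
        # the peak survives: brightest pixel unchanged
        peak = np.unravel_index(np.argmax(observed.pixels), observed.pixels.shape)
        assert corrected.pixels[peak] == observed.pixels[peak]


class TestCorrectFrame:
    def _spec(self, n_pixels=64, n_annuli=2, seed=0):
        geom = square_geometry(n_pixels)
        # inner annulus: higher mode, lighter censoring; outer: the reverse
        params = [
            censored_params(0.15, tau=-80.0, sigma=0.45),
            censored_params(0.25, tau=-50.0, sigma=0.40),
        ][:n_annuli]
        return SimulationSpec(geometry=geom, params=params, seed=seed)

    def test_zero_free_frame_is_bitwise_identity(self):
        geom = square_geometry(32)
        spec = SimulationSpec(
            geometry=geom, params=[LognormalParams(mu=5.0, sigma=0.3, tau=10.0)],
            seed=1,
        )
        truth, observed = simulate_frame(spec)
        assert (observed.pixels > 0).all()
        corrected, report = correct_frame(observed, geom, n_annuli=1, seed=4)
        np.testing.assert_array_equal(corrected.pixels, observed.pixels)
        assert report.total_assigned() == 0

    def test_positive_histogram_conserved_and_negative_matches_model(self):
        spec = self._spec(seed=5)
        truth, observed = simulate_frame(spec)
        corrected, report = correct_frame(observed, spec.geometry, n_annuli=2, seed=6)
        from detrunc.geometry import equal_area_annuli

        partition = equal_area_annuli(spec.geometry, 2, observed.valid_mask)
        for a in report.annuli:
            sel = partition.annulus_index == a.annulus
            before = observed.pixels[sel]
            after = corrected.pixels[sel]
            # positive side: bin-by-bin equality
            np.testing.assert_array_equal(
                np.bincount(before[before > 0]), np.bincount(after[after > 0])
            )
            # nonpositive side: exactly the integerized model frequencies
            vals, cnts = np.unique(after[after <= 0], return_counts=True)
            assert {int(v): int(c) for v, c in zip(vals, cnts)} == a.assigned
            assert sum(a.assigned.values()) == a.n_zero

    def test_correction_never_increases_pixels(self):
        spec = self._spec(seed=11)
        _, observed = simulate_frame(spec)
        corrected, _ = correct_frame(observed, spec.geometry, n_annuli=2, seed=2)
        assert (corrected.pixels <= observed.pixels).all()

    def test_mean_bias_reduction(self):
        """At ~20% censoring the corrected annulus mean must recover most
        of the truncation bias of the observed mean."""
        trunc_bias, corr_bias = [], []
        for seed in range(5):
            spec = SimulationSpec(
                geometry=square_geometry(96),
                params=[censored_params(0.2, tau=-100.0, sigma=0.4)],
                seed=seed,
            )
            truth, observed = simulate_frame(spec)
            corrected, _ = correct_frame(observed, spec.geometry, n_annuli=1,
                                         seed=seed)
            m_truth = truth.pixels.mean()
            trunc_bias.append(observed.pixels.mean() - m_truth)
            corr_bias.append(corrected.pixels.mean() - m_truth)
        assert np.mean(np.abs(corr_bias)) < 0.5 * np.mean(np.abs(trunc_bias))

    def test_reproducible_given_seed(self):
        spec = self._spec(seed=8)
        _, observed = simulate_frame(spec)
        c1, _ = correct_frame(observed, spec.geometry, n_annuli=2, seed=3)
        c2, _ = correct_frame(observed, spec.geometry, n_annuli=2, seed=3)
        np.testing.assert_array_equal(c1.pixels, c2.pixels)


class TestComputeOffset:
    def test_negated_sweep_minimum(self):
        a = ImageFrame(pixels=np.array([[5, -412]]), signed=True)
        b = ImageFrame(pixels=np.array([[-3, 7]]), signed=True)
        assert compute_offset([a, b]) == 412

    def test_clamped_at_zero_for_nonnegative_sweep(self):
        a = ImageFrame(pixels=np.array([[5, 2]]), signed=True)
        assert compute_offset([a]) == 0

    def test_monotone_in_added_frames(self):
        a = ImageFrame(pixels=np.array([[-10, 3]]), signed=True)
        b = ImageFrame(pixels=np.array([[-50, 0]]), signed=True)
        assert compute_offset([a, b]) >= compute_offset([a])

    def test_invalid_pixels_ignored(self):
        mask = np.array([[False, True]])
        a = ImageFrame(pixels=np.array([[-999, -7]]), valid_mask=mask, signed=True)
        assert compute_offset([a]) == 7
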