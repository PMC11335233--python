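"""Variance-stabilising transform, decay fit, z-scores, FDR and calling."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from loop4c.cis import (
    DecayFit,
    bh_fdr,
    call_interactions,
    compute_z,
    fit_decay,
    isotonic_decreasing,
    transform_counts,
)


def pava_decreasing(values):
    """O(n²) pool-adjacent-violators reference for non-increasing fits."""
    blocks = [[v] for v in values]
    merged = True
    while merged:
        merged = False
        for i in range(len(blocks) - 1):
            a = sum(blocks[i]) / len(blocks[i])
            b = sum(blocks[i + 1]) / len(blocks[i + 1])
            if a < b:  # violates non-increasing
                blocks[i] = blocks[i] + blocks[i + 1]
                del blocks[i + 1]
                merged = True
                break
    out = []
    for blk in blocks:
        out.extend([sum(blk) / len(blk)] * len(blk))
    return np.asarray(out)


def bh_stepup_reference(p):
    """Step-up definition computed literally."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        adjusted[i] = min(running_min, 1.0)
    return adjusted


class TestTransform:
    @pytest.mark.parametrize("x,expected", [(0, 0.0), (3, 2.0), (7, 3.0)])
    def test_values(self, x, expected):
        assert transform_counts(x) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            transform_counts(-0.5)

    def test_monotone(self):
        x = np.linspace(0, 100, 200)
        assert np.all(np.diff(transform_counts(x)) > 0)


class TestDecayFit:
    def test_feasible_input_unchanged(self):
        vals = np.array([5, 4, 4, 3, 3, 2.5, 2, 2, 1, 0.5])
        fit = fit_decay(vals, np.arange(1, 11) * 1000.0, "downstream")
        assert np.allclose(fit.fitted, vals)
        assert np.allclose(fit.residuals, 0)
        assert fit.sigma == pytest.approx(1e-6)  # floor on degenerate residuals

    def test_violator_pooled(self):
        assert np.allclose(isotonic_decreasing([1.0, 2.0], [3.0, 5.0]), [4.0, 4.0])

    def test_matches_pava_reference(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(2, 12))
            vals = rng.normal(0, 1, n)
            x = np.sort(rng.uniform(0, 1, n))
            # strictly increasing x so block structure is unambiguous
            x = x + np.arange(n) * 1e-6
            assert np.allclose(isotonic_decreasing(x, vals), pava_decreasing(vals), atol=1e-9)

    def test_recovers_known_decay(self):
        rng = np.random.default_rng(123)
        d = np.sort(rng.uniform(5_000, 2_000_000, 500))
        truth = 6 - np.log10(d) / 2
        vals = truth + rng.normal(0, 0.3, 500)
        fit = fit_decay(vals, d, "downstream")
        assert np.mean(np.abs(fit.fitted - truth)) < 0.15

    def test_too_few_fragments_errors(self):
        with pytest.raises(ValueError):
            fit_decay([1.0] * 5, [1e3] * 5, "upstream")

    def test_non_positive_distance_errors(self):
        with pytest.raises(ValueError):
            fit_decay(np.ones(12), np.arange(12.0), "upstream")  # includes 0


class TestComputeZ:
    @staticmethod
    def _fit(sigma=1.5):
        return DecayFit(
            "s", "downstream",
            log10_d=np.array([3.0, 6.0]), fitted=np.array([5.0, 5.0]), sigma=sigma,
        )

    def test_worked_example(self):
        z, _ = compute_z(np.array([8.0]), self._fit(), distances_bp=[10_000])
        assert z[0] == pytest.approx(2.0)

    def test_on_trend_is_half(self):
        z, p = compute_z(np.array([5.0]), self._fit(), distances_bp=[10_000])
        assert z[0] == pytest.approx(0.0)
        assert p[0] == pytest.approx(0.5)

    def test_tail_probability_against_numerical_integral(self):
        # one-sided upper tail at z = 1.6449 is ~0.05
        fit = self._fit(sigma=1.0)
        z, p = compute_z(np.array([5.0 + 1.6449]), fit, distances_bp=[10_000])
        tail, _ = integrate.quad(lambda t: np.exp(-t * t / 2) / np.sqrt(2 * np.pi), z[0], 50)
        assert p[0] == pytest.approx(tail, rel=1e-6)
        assert p[0] == pytest.approx(0.05, abs=2e-4)

    def test_interpolates_between_knots(self):
        fit = DecayFit("s", "d", np.array([3.0, 5.0]), np.array([6.0, 2.0]), 1.0)
        z, _ = compute_z(np.array([4.0]), fit, distances_bp=[10_000])  # log10 = 4 -> fitted 4
        assert z[0] == pytest.approx(0.0)

    def test_bad_sigma_errors(self):
        fit = self._fit()
        fit.sigma = 0.0
        with pytest.raises(ValueError):
            compute_z(np.array([1.0]), fit, distances_bp=[10_000])


class TestBhFdr:
    def test_worked_example(self):
        adj = bh_fdr([0.01, 0.02, 0.03, 0.04, 0.05])
        assert np.allclose(adj, 0.05)

    def test_single_p(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_all_ones(self):
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 1.5])

    def test_matches_stepup_reference_exhaustively(self):
        rng = np.random.default_rng(99)
        grid = np.round(rng.uniform(0, 1, 40), 3)
        for m in range(1, 9):
            for _ in range(30):
                p = rng.choice(grid, size=m)
                assert np.allclose(bh_fdr(p), bh_stepup_reference(p), atol=1e-12)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0, 1, 50)
        adj = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)


def _score_frame(z, fdr, start0=0):
    n = len(z)
    return pd.DataFrame(
        {
            "fragment_id": np.arange(n),
            "chrom": "c",
            "start": start0 + np.arange(n) * 10,
            "end": start0 + np.arange(1, n + 1) * 10,
            "distance": np.arange(n) * 10 + 5,
            "value": 0.0,
            "z": z,
            "p": 0.0,
            "fdr": fdr,
        }
    )


class TestCallInteractions:
    def test_significant_in_both_replicates(self):
        reps = [_score_frame([2.5], [0.01]), _score_frame([2.2], [0.03])]
        call = call_interactions(reps, z_threshold=2.0)
        assert call.fragments["significant"].tolist() == [True]

    def test_one_replicate_failing_blocks_call(self):
        reps = [_score_frame([2.5], [0.01]), _score_frame([1.9], [0.03])]
        call = call_interactions(reps, z_threshold=2.0)
        assert call.fragments["significant"].tolist() == [False]

    def test_relaxed_threshold_mode(self):
        reps = [_score_frame([1.6], [0.04]), _score_frame([1.7], [0.02])]
        assert call_interactions(reps, z_threshold=1.5).fragments["significant"].all()
        assert not call_interactions(reps, z_threshold=2.0).fragments["significant"].any()

    def test_merging_with_gap_tolerance(self):
        z = [3.0, 0.0, 3.0, 0.0, 0.0, 3.0]
        fdr = [0.01, 1.0, 0.01, 1.0, 1.0, 0.01]
        reps = [_score_frame(z, fdr)] * 2
        call = call_interactions(reps, merge_gap_fragments=1)
        # gap of 1 merges the first two; gap of 2 does not
        assert call.n_interactions == 2
        assert call.merged_intervals["n_fragments"].tolist() == [2, 1]
        call0 = call_interactions(reps, merge_gap_fragments=0)
        assert call0.n_interactions == 3

    def test_universe_mismatch_errors(self):
        a = _score_frame([1.0, 2.0], [0.5, 0.5])
        b = _score_frame([1.0], [0.5])
        with pytest.raises(ValueError):
            call_interactions([a, b])

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(21)
        reps = [
            _score_frame(rng.normal(1, 1.5, 300), rng.uniform(0, 0.2, 300))
            for _ in range(2)
        ]
        previous = None
        for zt in [1.0, 1.5, 2.0, 2.5, 3.0]:
            call = call_interactions(reps, z_threshold=zt)
            n = int(call.fragments["significant"].sum())
            if previous is not None:
                assert n <= previous
            previous = n


def test_end_to_end_null_scores_are_calibrated(default_fixture):
    """On planted data, non-planted fragments should have near-standard z."""
    from loop4c.cis import score_sample

    fmap, config, samples, truth = default_fixture
    scores = score_sample(samples[0], fmap, config.bait())
    planted = set(truth.cis["fragment_id"])
    null_z = scores.loc[~scores["fragment_id"].isin(planted), "z"]
    assert abs(null_z.mean()) < 0.2
    assert 0.5 < null_z.std() < 2.0
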