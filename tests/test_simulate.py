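"""The synthetic-data generator: determinism, statistical shape, truth."""

import json

import numpy as np
import pytest

import loop4c
from loop4c import PlantedCis, SimulationConfig
from loop4c.restriction import digest_genome, flag_blind_fragments
from loop4c.simulate import (
    build_fragment_maps,
    simulate_counts,
    simulate_genome,
    uniform_fragment_map,
    write_fixture_bundle,
)

from conftest import calibration_fixture

SMALL = dict(
    chrom_lengths={"chrA": 200_000, "chrB": 100_000},
    cis_chrom="chrA",
    bait_position=100_000,
    planted_cis=(),
    planted_trans=(),
)


class TestSimulateGenome:
    def test_deterministic_given_seed(self):
        g1, m1 = simulate_genome(SimulationConfig(seed=5, **SMALL))
        g2, m2 = simulate_genome(SimulationConfig(seed=5, **SMALL))
        assert g1 == g2
        assert all(np.array_equal(m1[c].starts, m2[c].starts) for c in g1)

    def test_different_seed_differs(self):
        g1, _ = simulate_genome(SimulationConfig(seed=5, **SMALL))
        g2, _ = simulate_genome(SimulationConfig(seed=6, **SMALL))
        assert g1 != g2

    def test_motif_rate_near_background(self):
        """A six-cutter site occurs about once per 4^6 bases of uniform DNA."""
        total_sites = 0
        total_len = 0
        for seed in range(20):
            cfg = SimulationConfig(seed=seed, **SMALL)
            genome, maps = simulate_genome(cfg)
            for chrom, seq in genome.items():
                total_sites += len(maps[chrom]) - 1
                total_len += len(seq)
        expect = total_len / 4**6
        sd = np.sqrt(expect)
        assert abs(total_sites - expect) < 3 * sd

    def test_emitted_map_matches_digestion_module(self):
        cfg = SimulationConfig(seed=11, **SMALL)
        genome, expected = simulate_genome(cfg)
        maps = digest_genome(genome, cfg.primary_enzyme)
        for chrom in genome:
            assert np.array_equal(maps[chrom].starts, expected[chrom].starts)
            assert np.array_equal(maps[chrom].ends, expected[chrom].ends)


class TestSimulateCounts:
    def test_mean_rpkm_decays_with_distance(self):
        """Binned empirical mean RPKM is non-increasing without planting."""
        binned = np.zeros(10)
        for seed in range(20):
            fmap, config, samples, _ = calibration_fixture(seed, planted=False)
            s = samples[0]
            cis = s.frame[~s.frame["fragment_id"].isin(s.excluded_fragment_ids)]
            d = np.abs(((cis["start"] + cis["end"]) // 2) - 2_000_000)
            keep = d > 10_000
            qs = np.quantile(d[keep], np.linspace(0, 1, 11))
            idx = np.clip(np.searchsorted(qs, d[keep], side="right") - 1, 0, 9)
            binned += np.array(
                [cis["rpkm"].to_numpy()[keep.to_numpy()][idx == b].mean() for b in range(10)]
            )
        assert np.all(np.diff(binned) < 0)

    def test_planted_fold_reflected_in_mean_counts(self):
        """A fold-4 planted fragment draws ~4x the baseline mean."""
        ratios = []
        for seed in range(60):
            fmap, config, samples, truth = calibration_fixture(seed, fold=4.0)
            fmap0, _, samples0, _ = calibration_fixture(seed, planted=False)
            fid = truth.cis["fragment_id"].iloc[5]
            a = samples[0].frame.set_index("fragment_id").loc[fid, "raw"]
            b = samples0[0].frame.set_index("fragment_id").loc[fid, "raw"]
            ratios.append((a + 1) / (b + 1))
        mean_ratio = np.mean(ratios)
        se = np.std(ratios) / np.sqrt(len(ratios))
        assert abs(mean_ratio - 4.0) < 3 * se + 0.3

    def test_large_dispersion_approaches_poisson(self):
        """variance/mean -> 1 as the NB shape grows (fixed fragment map)."""
        rng = np.random.default_rng(777)
        fmap = uniform_fragment_map("chr1", 4_000_000, 2000, rng)
        draws = []
        for seed in range(40):
            cfg = SimulationConfig(
                seed=seed, cis_chrom="chr1", bait_position=2_000_000,
                dispersion=1e9, planted_cis=(), planted_trans=(),
                diets=("CD",), timepoints=("ZT6",), n_replicates=1,
            )
            maps = loop4c.locate_bait({"chr1": fmap}, cfg.bait())
            samples, _ = simulate_counts(maps, cfg)
            draws.append(int(samples[0].frame["raw"].iloc[500]))
        draws = np.array(draws)
        ratio = draws.var() / draws.mean()
        assert 0.5 < ratio < 2.0

    def test_blind_fragments_zero_counts(self):
        cfg = SimulationConfig(seed=2, **{**SMALL, "planted_cis": ()})
        genome, maps = build_fragment_maps(cfg)
        samples, _ = simulate_counts(maps, cfg)
        frame = samples[0].frame
        assert (frame.loc[frame["blind"], "raw"] == 0).all()

    def test_invalid_dispersion_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, dispersion=0.0)

    def test_planted_fold_must_exceed_one(self):
        with pytest.raises(ValueError):
            PlantedCis(10, 1.0, (("CD", "ZT6"),))

    def test_condition_masks_respected(self):
        """A contact planted only under HF/ZT18 leaves other conditions flat."""
        planted = (PlantedCis(50, 8.0, (("HF", "ZT18"),)),)
        rng = np.random.default_rng(123)
        fmap = uniform_fragment_map("chr1", 4_000_000, 2000, rng)
        cfg = SimulationConfig(
            seed=5, cis_chrom="chr1", bait_position=2_000_000,
            planted_cis=planted, planted_trans=(),
        )
        maps = loop4c.locate_bait({"chr1": fmap}, cfg.bait())
        totals = {}
        samples, truth = simulate_counts(maps, cfg)
        fid = truth.cis["fragment_id"].iloc[0]
        for s in samples:
            key = (s.diet, s.timepoint)
            totals[key] = totals.get(key, 0) + int(
                s.frame.set_index("fragment_id").loc[fid, "raw"]
            )
        background = [v for k, v in totals.items() if k != ("HF", "ZT18")]
        assert totals[("HF", "ZT18")] > 3 * max(background)


class TestFixtureBundle:
    def test_bundle_deterministic(self, tmp_path):
        cfg = SimulationConfig(seed=9, **SMALL)
        d1 = write_fixture_bundle(cfg, tmp_path / "a")
        d2 = write_fixture_bundle(cfg, tmp_path / "b")
        m1 = json.loads((d1 / "manifest.json").read_text())
        m2 = json.loads((d2 / "manifest.json").read_text())
        assert m1["checksums"] == m2["checksums"]

    def test_truth_bookkeeping(self, tmp_path):
        cfg = SimulationConfig(seed=4)
        out = write_fixture_bundle(cfg, tmp_path / "fx")
        truth_lines = (out / "truth_cis.tsv").read_text().strip().splitlines()
        assert len(truth_lines) - 1 == len(cfg.planted_cis)
        trans_lines = (out / "truth_trans.bed").read_text().strip().splitlines()
        assert len(trans_lines) == len(cfg.planted_trans)
        manifest = json.loads((out / "manifest.json").read_text())
        assert manifest["seed"] == 4
        assert len(manifest["samples"]) == 8


def test_dose_response_sensitivity_non_decreasing():
    """Caller sensitivity rises with the planted fold (1.5 -> 8)."""
    from loop4c.cis import call_interactions, score_sample

    mean_sens = []
    for fold in (1.5, 2.0, 4.0, 8.0):
        sens = []
        for seed in range(3):
            fmap, config, samples, truth = calibration_fixture(seed, fold=fold)
            scores = [score_sample(s, fmap, config.bait()) for s in samples]
            call = call_interactions(scores)
            planted = set(truth.cis["fragment_id"])
            sens.append(len(planted & call.significant_fragment_ids) / len(planted))
        mean_sens.append(np.mean(sens))
    assert all(b >= a for a, b in zip(mean_sens, mean_sens[1:]))
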