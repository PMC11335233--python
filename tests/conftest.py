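"""Shared builders for synthetic test fixtures.

Everything is generated programmatically at test time; the calibration
fixture used by the caller tests is the direct-route map with exactly
2,000 fragments, bait centred, every fragment inside the ±2 Mb window.
"""

from __future__ import annotations

import numpy as np
import pytest

from loop4c import PlantedCis, SimulationConfig
from loop4c.restriction import locate_bait
from loop4c.simulate import simulate_counts, uniform_fragment_map

# planted offsets (in fragments from the bait) spread over both sides,
# clear of the excluded bait-proximal zone
PLANTED_OFFSETS = [20, 60, 120, 200, 300, 420, 560, 700, 820, 900]


def calibration_fixture(
    seed: int,
    *,
    fold: float = 4.0,
    planted: bool = True,
    dispersion: float | None = None,
    diets: tuple[str, ...] = ("CD",),
    timepoints: tuple[str, ...] = ("ZT6",),
    n_fragments: int = 2000,
):
    """2,000-fragment single-chromosome fixture for caller calibration.

    Returns (fragment_map, config, samples, truth).  With ``planted`` a
    fold enrichment is placed at 20 fragments active in every condition.
    """
    rng = np.random.default_rng(seed + 10_000)
    fmap = uniform_fragment_map("chr1", 4_000_000, n_fragments, rng)
    conditions = tuple((d, t) for d in diets for t in timepoints)
    planted_cis = (
        tuple(
            PlantedCis(o, fold, conditions)
            for o in PLANTED_OFFSETS + [-o for o in PLANTED_OFFSETS]
        )
        if planted
        else ()
    )
    kwargs = dict(
        seed=seed,
        cis_chrom="chr1",
        bait_position=2_000_000,
        planted_cis=planted_cis,
        planted_trans=(),
        diets=diets,
        timepoints=timepoints,
    )
    if dispersion is not None:
        kwargs["dispersion"] = dispersion
    config = SimulationConfig(**kwargs)
    maps = locate_bait({"chr1": fmap}, config.bait())
    samples, truth = simulate_counts(maps, config)
    return maps["chr1"], config, samples, truth


@pytest.fixture(scope="session")
def default_fixture():
    """One planted calibration dataset shared across tests."""
    return calibration_fixture(0)


@pytest.fixture(scope="session")
def small_genome_maps():
    """Genome-route maps on small chromosomes, with bait located."""
    import loop4c

    config = SimulationConfig(
        seed=3,
        chrom_lengths={"chrA": 300_000, "chrB": 120_000},
        cis_chrom="chrA",
        bait_position=150_000,
        planted_cis=(),
        planted_trans=(),
    )
    genome, maps = loop4c.build_fragment_maps(config)
    return genome, maps, config
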