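"""Synthetic bait-anchored 4C datasets with known planted structure.

The generator emulates the statistical shape of fragment-level 4C data:
a monotone power-law decay of expected signal with distance from the bait,
negative-binomial (overdispersed) counting noise, two replicates for each
diet × timepoint condition, and planted enrichments — individual cis
fragments at a fold increase over the decay trend, and window runs on a
trans chromosome over a flat background.  Ground truth is carried alongside
every dataset so recovery can be measured without reading any prose.

Two routes produce the fragment coordinate system:

* the genome route — uniform random DNA digested in silico, exercising the
  restriction machinery end to end, with motif sites at their background
  rate (one six-cutter site per ~4 kb);
* the direct route (:func:`uniform_fragment_map`) — a fragment tiling drawn
  without a genome, used when a fixture needs an exact fragment count.

Every output is a pure function of (config, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .enzymes import CSP6I, HINDIII, EnzymeSpec
from .quant import SampleCounts, exclude_bait_proximal, normalize_rpkm
from .restriction import BaitConfig, FragmentMap, GenomeMap, digest_genome, flag_blind_fragments, locate_bait

DNA = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class PlantedCis:
    """One enriched cis fragment: offset in fragments from the bait, its fold
    increase over the decay mean, and the (diet, timepoint) pairs where it is on."""

    offset: int
    fold: float
    active_conditions: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if self.fold <= 1:
            raise ValueError("planted fold must be > 1")


@dataclass(frozen=True)
class PlantedTrans:
    """A run of enriched windows on a trans chromosome (window units of k fragments)."""

    chrom: str
    start_window: int
    n_windows: int
    fold: float
    active_conditions: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if self.fold <= 1:
            raise ValueError("planted fold must be > 1")


def default_planted_cis() -> tuple[PlantedCis, ...]:
    """20 planted fragments at fold 4, active in every condition.

    Offsets are spread over both sides of the bait, clear of the excluded
    bait-proximal zone, mirroring discrete enhancer contacts within the
    analysis window.
    """
    all_conditions = tuple((d, t) for d in ("CD", "HF") for t in ("ZT6", "ZT18"))
    offsets = [10, 30, 60, 100, 150, 200, 260, 330, 400, 440]
    offsets = offsets + [-o for o in offsets]
    return tuple(PlantedCis(o, 4.0, all_conditions) for o in offsets)


@dataclass
class SimulationConfig:
    """Study conditions for the generator.

    Defaults mirror the study design: 2 diets × 2 timepoints × 2 replicates,
    a 5 Mb cis chromosome with the bait at its centre and a 2 Mb trans
    chromosome, HindIII/Csp6I digestion, power-law decay of expected RPKM
    with exponent 1, negative-binomial noise with shape 20 (variance
    mu + mu²/20, a DESeq2-style dispersion of 0.05 typical of replicate 4C
    libraries), and 1 M mapped reads per library of which ~70% map cis.
    """

    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 2_000_000}
    )
    cis_chrom: str = "chr1"
    bait_position: int = 2_500_000
    bait_name: str = "Dbp"
    primary_enzyme: EnzymeSpec = HINDIII
    secondary_enzyme: EnzymeSpec = CSP6I
    n_replicates: int = 2
    diets: tuple[str, ...] = ("CD", "HF")
    timepoints: tuple[str, ...] = ("ZT6", "ZT18")
    decay_a: float = 1.0
    decay_alpha: float = 1.0
    dispersion: float = 20.0
    library_size: int = 1_000_000
    cis_read_share: float = 0.7
    window_bp: int = 2_000_000
    n_exclude: int = 2
    trans_window_k: int = 20
    planted_cis: tuple[PlantedCis, ...] = field(default_factory=default_planted_cis)
    planted_trans: tuple[PlantedTrans, ...] = field(
        default_factory=lambda: (
            PlantedTrans("chr2", 10, 3, 6.0, (("CD", "ZT6"), ("HF", "ZT6"), ("CD", "ZT18"), ("HF", "ZT18"))),
        )
    )

    def __post_init__(self) -> None:
        if self.decay_alpha <= 0:
            raise ValueError("decay_alpha must be > 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if not 0 < self.cis_read_share <= 1:
            raise ValueError("cis_read_share must be in (0, 1]")

    @property
    def conditions(self) -> list[tuple[str, str]]:
        return [(d, t) for d in self.diets for t in self.timepoints]

    def bait(self) -> BaitConfig:
        return BaitConfig(
            name=self.bait_name,
            chrom=self.cis_chrom,
            position=self.bait_position,
            primary_enzyme=self.primary_enzyme,
            secondary_enzyme=self.secondary_enzyme,
            window_bp=self.window_bp,
        )


@dataclass
class SimulationTruth:
    """Planted structure in genomic coordinates, serialised with every fixture."""

    cis: pd.DataFrame    # chrom, start, end, fragment_id, fold, active
    trans: pd.DataFrame  # chrom, start, end, fold, active


def _rng(config: SimulationConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, *stream]))


def _naive_motif_starts(seq: str, motif: str) -> list[int]:
    """Position-by-position scan; the independent digestion oracle."""
    m = len(motif)
    return [i for i in range(len(seq) - m + 1) if seq[i:i + m] == motif]


def simulate_genome(config: SimulationConfig) -> tuple[dict[str, str], GenomeMap]:
    """Uniform random DNA plus the expected fragment map from a naive scan.

    The returned map is computed with an all-positions scan independent of
    the digestion module, so it can serve as a digestion oracle.
    """
    rng = _rng(config, 0)
    genome: dict[str, str] = {}
    for chrom, length in config.chrom_lengths.items():
        genome[chrom] = rng.choice(DNA, size=length).tobytes().decode("ascii")

    motif, off = config.primary_enzyme.motif, config.primary_enzyme.cut_offset
    expected: GenomeMap = {}
    next_id = 0
    for chrom, seq in genome.items():
        cuts = sorted(
            c for c in (s + off for s in _naive_motif_starts(seq, motif)) if 0 < c < len(seq)
        )
        bounds = [0] + cuts + [len(seq)]
        n = len(bounds) - 1
        expected[chrom] = FragmentMap(
            chrom=chrom,
            starts=np.asarray(bounds[:-1]),
            ends=np.asarray(bounds[1:]),
            ids=np.arange(next_id, next_id + n),
        )
        next_id += n
    return genome, expected


def build_fragment_maps(config: SimulationConfig) -> tuple[dict[str, str], GenomeMap]:
    """Genome route: simulate DNA, digest, flag blind fragments, locate bait."""
    genome, _ = simulate_genome(config)
    maps = digest_genome(genome, config.primary_enzyme)
    maps = flag_blind_fragments(maps, genome, config.secondary_enzyme)
    maps = locate_bait(maps, config.bait())
    return genome, maps


def uniform_fragment_map(
    chrom: str,
    chrom_length: int,
    n_fragments: int,
    rng: np.random.Generator,
    *,
    id_offset: int = 0,
) -> FragmentMap:
    """Direct route: a random gap-free tiling with an exact fragment count."""
    cuts = np.sort(rng.choice(np.arange(1, chrom_length), size=n_fragments - 1, replace=False))
    bounds = np.concatenate([[0], cuts, [chrom_length]])
    return FragmentMap(
        chrom=chrom,
        starts=bounds[:-1],
        ends=bounds[1:],
        ids=np.arange(id_offset, id_offset + n_fragments),
    )


def _expected_weights(
    maps: GenomeMap, config: SimulationConfig
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-fragment baseline relative weights (before planting), plus metadata."""
    cis_map = maps[config.cis_chrom]
    if cis_map.bait_fragment_id is None:
        raise ValueError("bait not located on the cis fragment map")
    bait_idx = cis_map.index_of(cis_map.bait_fragment_id)
    bait_mid = float(cis_map.midpoints[bait_idx])

    rows = []
    for chrom, fmap in maps.items():
        is_cis = chrom == config.cis_chrom
        mids = fmap.midpoints.astype(float)
        length_kb = fmap.lengths / 1000.0
        if is_cis:
            # decay law lives on mean RPKM, so expected counts carry the
            # fragment length: E[raw] ∝ mean_rpkm(d) × length_kb
            # distances floored at 1 kb (sub-fragment scale); the self-ligation
            # peak is excluded from analysis downstream and is not emulated
            d_kb = np.maximum(np.abs(mids - bait_mid), 1000.0) / 1000.0
            w = config.decay_a * d_kb ** (-config.decay_alpha) * length_kb
        else:
            w = np.full(len(fmap), np.nan)  # filled below to hit cis_read_share
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "fragment_id": fmap.ids,
                    "start": fmap.starts,
                    "end": fmap.ends,
                    "blind": fmap.blind,
                    "weight": w,
                    "offset": (np.arange(len(fmap)) - bait_idx) if is_cis else 0,
                }
            )
        )
    frame = pd.concat(rows, ignore_index=True)
    frame.loc[frame["blind"], "weight"] = 0.0

    cis_mask = (frame["chrom"] == config.cis_chrom).to_numpy()
    cis_total = float(frame.loc[cis_mask, "weight"].sum())
    fill = (frame["weight"].isna() & ~frame["blind"]).to_numpy()
    if fill.any() and config.cis_read_share < 1:
        # flat trans background at constant expected RPKM: weight ∝ length
        trans_total = cis_total * (1 - config.cis_read_share) / config.cis_read_share
        length_kb = ((frame["end"] - frame["start"]) / 1000.0).to_numpy()
        frame.loc[fill, "weight"] = trans_total * length_kb[fill] / length_kb[fill].sum()
    frame["weight"] = frame["weight"].fillna(0.0)
    return frame, frame["weight"].to_numpy().copy()


def _apply_planting(
    frame: pd.DataFrame,
    base_weight: np.ndarray,
    maps: GenomeMap,
    config: SimulationConfig,
    condition: tuple[str, str],
) -> np.ndarray:
    weight = base_weight.copy()
    cis_map = maps[config.cis_chrom]
    bait_idx = cis_map.index_of(cis_map.bait_fragment_id)
    cis_rows = np.flatnonzero((frame["chrom"] == config.cis_chrom).to_numpy())
    for planted in config.planted_cis:
        if condition not in planted.active_conditions:
            continue
        idx = bait_idx + planted.offset
        if not 0 <= idx < len(cis_map):
            raise ValueError(f"planted offset {planted.offset} falls off the cis chromosome")
        weight[cis_rows[idx]] *= planted.fold
    k = config.trans_window_k
    for planted in config.planted_trans:
        if condition not in planted.active_conditions:
            continue
        rows = np.flatnonzero((frame["chrom"] == planted.chrom).to_numpy())
        live = rows[~frame["blind"].to_numpy()[rows]]
        lo = planted.start_window * k
        hi = min(len(live), (planted.start_window + planted.n_windows) * k)
        weight[live[lo:hi]] *= planted.fold
    return weight


def simulate_counts(
    maps: GenomeMap, config: SimulationConfig
) -> tuple[list[SampleCounts], SimulationTruth]:
    """Draw one negative-binomial library per (condition, replicate).

    Expected counts are the planted-adjusted decay weights rescaled to the
    library size; each library is an independent draw with NB shape
    ``config.dispersion`` (variance mu + mu²/shape).  Blind fragments get 0.
    Counts come back RPKM-normalised with the bait-proximal exclusion set.
    """
    frame, base_weight = _expected_weights(maps, config)
    cis_map = maps[config.cis_chrom]
    r = config.dispersion
    samples: list[SampleCounts] = []
    for c_idx, (diet, zt) in enumerate(config.conditions):
        weight = _apply_planting(frame, base_weight, maps, config, (diet, zt))
        mu = weight / weight.sum() * config.library_size
        for rep in range(1, config.n_replicates + 1):
            rng = _rng(config, 1, c_idx, rep)
            # NB via gamma-Poisson mixture; mu == 0 stays exactly 0
            lam = np.where(mu > 0, rng.gamma(r, np.maximum(mu, 1e-300) / r), 0.0)
            raw = rng.poisson(lam)
            counts = SampleCounts(
                sample_id=f"{config.bait_name}_{diet}_{zt}_rep{rep}",
                bait_name=config.bait_name,
                frame=frame[["chrom", "fragment_id", "start", "end", "blind"]].assign(
                    raw=raw, rpkm=0.0
                ),
                total_mapped_reads=int(raw.sum()),
                diet=diet,
                timepoint=zt,
                replicate=rep,
            )
            normalize_rpkm(counts)
            exclude_bait_proximal(counts, cis_map, config.n_exclude)
            samples.append(counts)

    truth = _truth_table(frame, maps, config)
    return samples, truth


def _truth_table(frame: pd.DataFrame, maps: GenomeMap, config: SimulationConfig) -> SimulationTruth:
    cis_map = maps[config.cis_chrom]
    bait_idx = cis_map.index_of(cis_map.bait_fragment_id)
    cis_rows = []
    for planted in config.planted_cis:
        idx = bait_idx + planted.offset
        cis_rows.append(
            {
                "chrom": config.cis_chrom,
                "start": int(cis_map.starts[idx]),
                "end": int(cis_map.ends[idx]),
                "fragment_id": int(cis_map.ids[idx]),
                "fold": planted.fold,
                "active": ";".join(f"{d}_{t}" for d, t in planted.active_conditions),
            }
        )
    k = config.trans_window_k
    trans_rows = []
    for planted in config.planted_trans:
        fmap = maps[planted.chrom]
        live = np.flatnonzero(~fmap.blind)
        lo = planted.start_window * k
        hi = min(len(live), (planted.start_window + planted.n_windows) * k) - 1
        trans_rows.append(
            {
                "chrom": planted.chrom,
                "start": int(fmap.starts[live[lo]]),
                "end": int(fmap.ends[live[hi]]),
                "fold": planted.fold,
                "active": ";".join(f"{d}_{t}" for d, t in planted.active_conditions),
            }
        )
    return SimulationTruth(
        cis=pd.DataFrame(cis_rows, columns=["chrom", "start", "end", "fragment_id", "fold", "active"]),
        trans=pd.DataFrame(trans_rows, columns=["chrom", "start", "end", "fold", "active"]),
    )


def simulate_tads(maps: GenomeMap, config: SimulationConfig) -> pd.DataFrame:
    """Synthetic TAD intervals: 1–3 Mb domains tiling each chromosome, with
    one domain arranged to contain the bait."""
    rng = _rng(config, 2)
    rows = []
    i = 0
    for chrom, fmap in maps.items():
        pos = 0
        length = fmap.chrom_length
        while pos < length:
            size = int(rng.integers(1_000_000, 3_000_001))
            end = min(pos + size, length)
            rows.append({"chrom": chrom, "start": pos, "end": end, "name": f"TAD{i}"})
            i += 1
            pos = end
    return pd.DataFrame(rows)


def write_fixture_bundle(config: SimulationConfig, outdir: str | Path) -> Path:
    """Emit a complete no-download test surface into *outdir*.

    Files: genome.fa, fragments.bed, one counts TSV per sample,
    truth_cis.tsv / truth_trans.bed, tads.bed and manifest.json (seed,
    config and per-file SHA-256 checksums).  Bit-identical across re-runs
    with the same config.
    """
    from .quant import write_counts
    from .restriction import write_fragment_bed

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, maps = build_fragment_maps(config)

    fasta = outdir / "genome.fa"
    with open(fasta, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    write_fragment_bed(maps, outdir / "fragments.bed")

    samples, truth = simulate_counts(maps, config)
    for s in samples:
        write_counts(s, outdir / f"{s.sample_id}.tsv")
    truth.cis.to_csv(outdir / "truth_cis.tsv", sep="\t", index=False)
    with open(outdir / "truth_trans.bed", "w") as fh:
        for _, row in truth.trans.iterrows():
            fh.write(
                f"{row['chrom']}\t{row['start']}\t{row['end']}\ttrans_fold{row['fold']:g}\t0\t.\n"
            )
    simulate_tads(maps, config).to_csv(outdir / "tads.bed", sep="\t", index=False, header=False)

    study = {
        "fragments": "fragments.bed",
        "n_replicates": config.n_replicates,
        "diets": list(config.diets),
        "timepoints": list(config.timepoints),
        "baits": {
            config.bait_name: {
                "chrom": config.cis_chrom,
                "position": config.bait_position,
                "primary_enzyme": config.primary_enzyme.name,
                "secondary_enzyme": config.secondary_enzyme.name,
                "z_threshold": 1.5 if config.bait_name == "Srebp1c" else 2.0,
                "window_bp": config.window_bp,
            }
        },
        "samples": [
            {
                "bait": s.bait_name,
                "diet": s.diet,
                "timepoint": s.timepoint,
                "replicate": s.replicate,
                "path": f"{s.sample_id}.tsv",
            }
            for s in samples
        ],
        "thresholds": {"fdr": 0.05, "ratio": 1.5, "merge_gap_fragments": 1},
        "trans": {"k": config.trans_window_k, "n_required": 2, "seed": config.seed},
    }
    import yaml as _yaml

    (outdir / "study.yaml").write_text(_yaml.safe_dump(study, sort_keys=True))

    manifest = {
        "seed": config.seed,
        "bait": config.bait_name,
        "config": _config_dict(config),
        "samples": [s.sample_id for s in samples],
        "checksums": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(outdir.iterdir())
            if p.name != "manifest.json"
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir


def _config_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["primary_enzyme"] = config.primary_enzyme.name
    d["secondary_enzyme"] = config.secondary_enzyme.name
    return d
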