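"""In-silico restriction digestion and the fragment coordinate system.

Every downstream quantity in a 4C experiment lives on the restriction
fragments of the primary enzyme: counts, z-scores, interaction calls.  This
module digests a genome into an ordered, gap-free tiling of fragments
(0-based half-open coordinates, BED convention), flags *blind* fragments
(those lacking a secondary-enzyme site, which cannot form the nested
ligation circle and therefore yield no valid 4C signal), and locates the
fragment containing the bait.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .enzymes import EnzymeSpec, get_enzyme


@dataclass(frozen=True)
class BaitConfig:
    """A 4C viewpoint: where it is, which enzymes cut around it, how it is called.

    ``z_threshold`` defaults to 2.0; baits in low-complexity or weak-signal
    regions may use a relaxed 1.5 cutoff.  ``window_bp`` is the half-width of
    the symmetric cis analysis window around the bait (default 2 Mb).
    """

    name: str
    chrom: str
    position: int
    primary_enzyme: EnzymeSpec
    secondary_enzyme: EnzymeSpec
    z_threshold: float = 2.0
    window_bp: int = 2_000_000

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"bait {self.name}: negative position")
        if self.z_threshold <= 0:
            raise ValueError(f"bait {self.name}: z_threshold must be > 0")
        if self.window_bp <= 0:
            raise ValueError(f"bait {self.name}: window_bp must be > 0")


@dataclass
class FragmentMap:
    """Ordered restriction fragments of one chromosome.

    Fragments tile the chromosome without gaps or overlaps; ``ids`` are
    strictly increasing in coordinate order and globally unique when several
    chromosomes are digested together (consecutive across chromosomes in
    input order).
    """

    chrom: str
    starts: np.ndarray
    ends: np.ndarray
    ids: np.ndarray
    blind: np.ndarray = field(default=None)  # type: ignore[assignment]
    bait_fragment_id: int | None = None
    bait_name: str | None = None

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.ids = np.asarray(self.ids, dtype=np.int64)
        if self.blind is None:
            self.blind = np.zeros(len(self.starts), dtype=bool)
        self.blind = np.asarray(self.blind, dtype=bool)
        self._validate()

    def _validate(self) -> None:
        n = len(self.starts)
        if not (len(self.ends) == len(self.ids) == len(self.blind) == n):
            raise ValueError("fragment arrays have inconsistent lengths")
        if n == 0:
            raise ValueError(f"{self.chrom}: empty fragment map")
        if np.any(self.starts >= self.ends):
            raise ValueError(f"{self.chrom}: fragment with start >= end")
        if np.any(self.starts[1:] != self.ends[:-1]) or self.starts[0] != 0:
            raise ValueError(f"{self.chrom}: fragments do not tile the chromosome")
        if np.any(np.diff(self.ids) <= 0):
            raise ValueError(f"{self.chrom}: fragment ids not strictly increasing")

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) // 2

    @property
    def chrom_length(self) -> int:
        return int(self.ends[-1])

    def fragment_at(self, position: int) -> int:
        """Return the id of the fragment with start <= position < end."""
        if not 0 <= position < self.chrom_length:
            raise ValueError(
                f"position {position} outside {self.chrom}:[0,{self.chrom_length})"
            )
        idx = int(np.searchsorted(self.ends, position, side="right"))
        return int(self.ids[idx])

    def index_of(self, fragment_id: int) -> int:
        idx = int(np.searchsorted(self.ids, fragment_id))
        if idx >= len(self.ids) or self.ids[idx] != fragment_id:
            raise KeyError(f"fragment id {fragment_id} not on {self.chrom}")
        return idx

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.starts,
                "end": self.ends,
                "fragment_id": self.ids,
                "blind": self.blind.astype(int),
                "strand": ".",
            }
        )


GenomeMap = dict[str, FragmentMap]


def find_cut_sites(sequence: str, enzyme: EnzymeSpec) -> np.ndarray:
    """All forward-strand cut positions of *enzyme* in *sequence*.

    Overlap-adjacent motif occurrences are found by resuming the scan one
    base after each hit, so e.g. GTACGTAC yields both GTAC sites.
    """
    cuts = []
    motif, off = enzyme.motif, enzyme.cut_offset
    i = sequence.find(motif)
    while i != -1:
        cuts.append(i + off)
        i = sequence.find(motif, i + 1)
    return np.asarray(cuts, dtype=np.int64)


def digest_genome(genome: Mapping[str, str], enzyme: EnzymeSpec) -> GenomeMap:
    """Digest every chromosome with *enzyme* into a gap-free fragment tiling.

    Fragments are the intervals between consecutive cut sites plus the
    chromosome ends; ids are assigned consecutively across chromosomes in
    input order.  Cut sites at position 0 or at the chromosome end are
    ignored (they would create empty fragments).
    """
    if not genome:
        raise ValueError("empty genome")
    maps: GenomeMap = {}
    next_id = 0
    for chrom, seq in genome.items():
        if not seq:
            raise ValueError(f"{chrom}: empty chromosome sequence")
        seq = seq.upper()
        cuts = find_cut_sites(seq, enzyme)
        cuts = cuts[(cuts > 0) & (cuts < len(seq))]
        bounds = np.concatenate([[0], cuts, [len(seq)]])
        starts, ends = bounds[:-1], bounds[1:]
        n = len(starts)
        fmap = FragmentMap(
            chrom=chrom,
            starts=starts,
            ends=ends,
            ids=np.arange(next_id, next_id + n),
        )
        assert int(fmap.lengths.sum()) == len(seq), "tiling invariant violated"
        maps[chrom] = fmap
        next_id += n
    return maps


def flag_blind_fragments(
    maps: GenomeMap, genome: Mapping[str, str], secondary: EnzymeSpec
) -> GenomeMap:
    """Mark fragments with no secondary-enzyme motif as blind.

    Blind fragments cannot circularise after the second digestion and are
    excluded from statistics downstream.  Coordinates are unchanged.
    """
    out: GenomeMap = {}
    for chrom, fmap in maps.items():
        if chrom not in genome:
            raise ValueError(f"{chrom} present in fragment map but not in genome")
        seq = genome[chrom].upper()
        if len(seq) != fmap.chrom_length:
            raise ValueError(
                f"{chrom}: genome length {len(seq)} != fragment map span {fmap.chrom_length}"
            )
        sites = find_cut_sites(seq, secondary) - secondary.cut_offset  # motif starts
        blind = np.ones(len(fmap), dtype=bool)
        if len(sites):
            # a fragment is non-blind iff a motif start falls fully inside it
            frag_idx = np.searchsorted(fmap.ends, sites, side="right")
            inside = sites + len(secondary.motif) <= fmap.ends[frag_idx]
            blind[np.unique(frag_idx[inside])] = False
        out[chrom] = replace(fmap, blind=blind)
    return out


def locate_bait(maps: GenomeMap, bait: BaitConfig) -> GenomeMap:
    """Set ``bait_fragment_id`` on the bait chromosome's map."""
    if bait.chrom not in maps:
        raise ValueError(f"bait chromosome {bait.chrom!r} not in fragment map")
    fmap = maps[bait.chrom]
    frag_id = fmap.fragment_at(bait.position)
    out = dict(maps)
    out[bait.chrom] = replace(fmap, bait_fragment_id=frag_id, bait_name=bait.name)
    return out


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (multi-record, wrapped or unwrapped) FASTA into plain strings."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fragment_bed(maps: GenomeMap, path: str | Path) -> None:
    """Write the fragment map as 6-column BED-like TSV."""
    frame = pd.concat([m.to_frame() for m in maps.values()], ignore_index=True)
    frame.to_csv(path, sep="\t", header=False, index=False)


def read_fragment_bed(path: str | Path) -> GenomeMap:
    """Read a fragment map written by :func:`write_fragment_bed`."""
    frame = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "fragment_id", "blind", "strand"],
    )
    maps: GenomeMap = {}
    for chrom, grp in frame.groupby("chrom", sort=False):
        maps[str(chrom)] = FragmentMap(
            chrom=str(chrom),
            starts=grp["start"].to_numpy(),
            ends=grp["end"].to_numpy(),
            ids=grp["fragment_id"].to_numpy(),
            blind=grp["blind"].to_numpy(dtype=bool),
        )
    return maps


def bait_from_dict(cfg: Mapping, *, name: str | None = None) -> BaitConfig:
    """Build a :class:`BaitConfig` from a plain dict (e.g. parsed YAML)."""
    def enzyme(v):
        if isinstance(v, EnzymeSpec):
            return v
        if isinstance(v, str):
            return get_enzyme(v)
        return EnzymeSpec(v["name"], v["motif"], int(v["cut_offset"]))

    return BaitConfig(
        name=name or cfg["name"],
        chrom=cfg["chrom"],
        position=int(cfg["position"]),
        primary_enzyme=enzyme(cfg["primary_enzyme"]),
        secondary_enzyme=enzyme(cfg["secondary_enzyme"]),
        z_threshold=float(cfg.get("z_threshold", 2.0)),
        window_bp=int(cfg.get("window_bp", 2_000_000)),
    )
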