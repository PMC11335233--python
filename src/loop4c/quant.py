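"""Per-fragment read counting, RPKM normalisation and library QC.

Reads are assigned to the restriction fragment containing their 5'
alignment position (4C reads start at restriction sites, so the 5' end is
the unambiguous anchor).  Duplicates are kept.  Counts are normalised to
RPKM using the fragment length and the total mapped reads of the library.
The bait fragment plus its immediate neighbours are excluded from all
statistics: self-ligation and incomplete digestion dominate the signal
there.  Library quality is summarised by the cis fraction — the share of
mapped reads on the bait chromosome — with a 40% floor typical for a clean
4C template.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .restriction import BaitConfig, FragmentMap, GenomeMap

CIS_FRACTION_FLOOR = 0.40


@dataclass
class SampleCounts:
    """Fragment-level counts for one 4C library.

    ``frame`` has one row per fragment with columns
    (chrom, fragment_id, start, end, raw, rpkm).  ``excluded_fragment_ids``
    collects bait-proximal fragments that never enter decay fitting,
    z-scores or calls.
    """

    sample_id: str
    bait_name: str
    frame: pd.DataFrame
    total_mapped_reads: int
    diet: str = ""
    timepoint: str = ""
    replicate: int = 1
    off_map_reads: int = 0
    excluded_fragment_ids: set[int] = field(default_factory=set)

    def on_chrom(self, chrom: str) -> pd.DataFrame:
        return self.frame[self.frame["chrom"] == chrom]


def _empty_frame(maps: GenomeMap) -> pd.DataFrame:
    parts = []
    for fmap in maps.values():
        parts.append(
            pd.DataFrame(
                {
                    "chrom": fmap.chrom,
                    "fragment_id": fmap.ids,
                    "start": fmap.starts,
                    "end": fmap.ends,
                    "blind": fmap.blind,
                }
            )
        )
    frame = pd.concat(parts, ignore_index=True)
    frame["raw"] = 0
    frame["rpkm"] = 0.0
    return frame


def count_reads(
    alignments: Iterable[tuple[str, int]],
    maps: GenomeMap,
    *,
    sample_id: str = "sample",
    bait_name: str = "",
    **labels,
) -> SampleCounts:
    """Count mapped reads per fragment from an iterable of (chrom, 5'-position).

    Reads on chromosomes absent from the map are tallied as off-map (reported,
    not fatal) but still count toward ``total_mapped_reads`` for QC.
    """
    frame = _empty_frame(maps)
    per_chrom: dict[str, list[int]] = {c: [] for c in maps}
    off_map = 0
    total = 0
    for chrom, pos in alignments:
        total += 1
        fmap = maps.get(chrom)
        if fmap is None or not 0 <= pos < fmap.chrom_length:
            off_map += 1
            continue
        per_chrom[chrom].append(pos)
    counts = np.zeros(len(frame), dtype=np.int64)
    offset = 0
    for chrom, fmap in maps.items():
        positions = np.asarray(per_chrom[chrom], dtype=np.int64)
        if len(positions):
            idx = np.searchsorted(fmap.ends, positions, side="right")
            counts[offset:offset + len(fmap)] = np.bincount(idx, minlength=len(fmap))
        offset += len(fmap)
    frame["raw"] = counts
    return SampleCounts(
        sample_id=sample_id,
        bait_name=bait_name,
        frame=frame,
        total_mapped_reads=total,
        off_map_reads=off_map,
        **labels,
    )


def count_bam(
    bam_path: str | Path,
    maps: GenomeMap,
    *,
    sample_id: str = "sample",
    bait_name: str = "",
    **labels,
) -> SampleCounts:
    """Count reads from a BAM/SAM file (mapped primary alignments, 5' position)."""
    import pysam

    def aligned():
        with pysam.AlignmentFile(str(bam_path)) as bam:
            for read in bam.fetch(until_eof=True):
                if read.is_unmapped or read.is_secondary or read.is_supplementary:
                    continue
                pos = read.reference_end - 1 if read.is_reverse else read.reference_start
                yield read.reference_name, pos

    return count_reads(
        aligned(), maps, sample_id=sample_id, bait_name=bait_name, **labels
    )


def counts_from_table(
    path: str | Path,
    maps: GenomeMap,
    *,
    bait_name: str = "",
    **labels,
) -> SampleCounts:
    """Load a plain count table (columns: sample_id, fragment_id, raw_count,
    total_mapped_reads), bypassing alignment machinery entirely."""
    table = pd.read_csv(path, sep="\t")
    required = {"sample_id", "fragment_id", "raw_count", "total_mapped_reads"}
    if not required.issubset(table.columns):
        raise ValueError(f"count table missing columns {required - set(table.columns)}")
    frame = _empty_frame(maps)
    lookup = dict(zip(table["fragment_id"], table["raw_count"]))
    frame["raw"] = frame["fragment_id"].map(lookup).fillna(0).astype(np.int64)
    return SampleCounts(
        sample_id=str(table["sample_id"].iloc[0]),
        bait_name=bait_name,
        frame=frame,
        total_mapped_reads=int(table["total_mapped_reads"].iloc[0]),
        **labels,
    )


def normalize_rpkm(counts: SampleCounts, *, unit_length: bool = False) -> SampleCounts:
    """Fill the rpkm column: raw / (fragment_kb × total_mapped_millions).

    With ``unit_length`` every fragment counts as 1 kb (reads-per-million
    only), for data produced under a unit-length convention.
    """
    if counts.total_mapped_reads <= 0:
        raise ValueError("cannot normalise: total mapped reads is zero")
    frame = counts.frame
    length_kb = 1.0 if unit_length else (frame["end"] - frame["start"]) / 1_000.0
    millions = counts.total_mapped_reads / 1_000_000.0
    counts.frame = frame.assign(rpkm=frame["raw"] / (length_kb * millions))
    return counts


def exclude_bait_proximal(
    counts: SampleCounts, fmap: FragmentMap, n_exclude: int = 2
) -> SampleCounts:
    """Exclude the bait fragment and *n_exclude* fragments on each side.

    Exclusion is silent at chromosome ends (fewer neighbours exist).
    """
    if fmap.bait_fragment_id is None:
        raise ValueError("fragment map has no bait located")
    idx = fmap.index_of(fmap.bait_fragment_id)
    lo = max(0, idx - n_exclude)
    hi = min(len(fmap), idx + n_exclude + 1)
    counts.excluded_fragment_ids |= {int(i) for i in fmap.ids[lo:hi]}
    return counts


def cis_fraction(counts: SampleCounts, bait: BaitConfig) -> float:
    """Share of mapped reads on the bait chromosome (cis), in [0, 1]."""
    if counts.total_mapped_reads <= 0:
        raise ValueError("zero mapped reads")
    cis = int(counts.on_chrom(bait.chrom)["raw"].sum())
    return cis / counts.total_mapped_reads


def qc_report(
    samples: Sequence[SampleCounts], bait: BaitConfig, floor: float = CIS_FRACTION_FLOOR
) -> pd.DataFrame:
    """Per-sample cis-fraction table with a pass/flag column."""
    rows = []
    for s in samples:
        frac = cis_fraction(s, bait)
        rows.append(
            {
                "sample_id": s.sample_id,
                "diet": s.diet,
                "timepoint": s.timepoint,
                "replicate": s.replicate,
                "total_mapped_reads": s.total_mapped_reads,
                "cis_fraction": frac,
                "pass_qc": int(frac >= floor),
            }
        )
    return pd.DataFrame(rows)


def read_counts(
    path: str | Path,
    maps: GenomeMap,
    *,
    sample_id: str | None = None,
    bait_name: str = "",
    **labels,
) -> SampleCounts:
    """Load a per-sample TSV written by :func:`write_counts`.

    Blind flags are taken from the fragment map (the TSV does not carry
    them); total mapped reads is the raw-count sum plus nothing — off-map
    reads are not round-tripped.
    """
    table = pd.read_csv(path, sep="\t")
    frame = _empty_frame(maps)
    frame["raw"] = (
        frame["fragment_id"].map(dict(zip(table["fragment_id"], table["raw"]))).fillna(0).astype(np.int64)
    )
    frame["rpkm"] = (
        frame["fragment_id"].map(dict(zip(table["fragment_id"], table["rpkm"]))).fillna(0.0)
    )
    excluded = set(table.loc[table["excluded"] == 1, "fragment_id"].astype(int))
    return SampleCounts(
        sample_id=sample_id or Path(path).stem,
        bait_name=bait_name,
        frame=frame,
        total_mapped_reads=int(frame["raw"].sum()),
        excluded_fragment_ids=excluded,
        **labels,
    )


def write_counts(counts: SampleCounts, path: str | Path) -> None:
    """Per-sample TSV: fragment_id, chrom, start, end, raw, rpkm, excluded."""
    frame = counts.frame.copy()
    frame["excluded"] = frame["fragment_id"].isin(counts.excluded_fragment_ids).astype(int)
    cols = ["fragment_id", "chrom", "start", "end", "raw", "rpkm", "excluded"]
    frame[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")
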