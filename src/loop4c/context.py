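"""Genomic context: TAD containment and Hi-C matrix comparison.

Called interactions in liver are expected to stay within the topologically
associating domain (TAD) of their bait.  Containment is tested against
tolerance-expanded TAD intervals (default 200 kb each side), reflecting the
fuzziness of TAD boundary calls; TADs and subTADs may nest, so all
qualifying TADs are returned.  Two normalised (e.g. ICED) contact matrices
on a common bin grid are compared by an elementwise log2 ratio with a
pseudocount.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cis import InteractionCall
from .restriction import BaitConfig

DEFAULT_TOLERANCE_BP = 200_000


@dataclass
class TadSet:
    """TAD/subTAD intervals; nesting allowed, so no disjointness is assumed."""

    intervals: pd.DataFrame  # chrom, start, end, name

    def __post_init__(self) -> None:
        if np.any(self.intervals["start"] >= self.intervals["end"]):
            raise ValueError("TAD with start >= end")

    @classmethod
    def from_bed(cls, path: str | Path) -> "TadSet":
        frame = pd.read_csv(path, sep="\t", header=None, comment="#")
        frame = frame.iloc[:, :4] if frame.shape[1] >= 4 else frame.iloc[:, :3]
        frame.columns = ["chrom", "start", "end", "name"][: frame.shape[1]]
        if "name" not in frame.columns:
            frame["name"] = [f"TAD{i}" for i in range(len(frame))]
        return cls(intervals=frame)

    def on_chrom(self, chrom: str) -> pd.DataFrame:
        return self.intervals[self.intervals["chrom"] == chrom]


def tad_overlap(
    interaction: tuple[str, int, int],
    tads: TadSet,
    tolerance_bp: int = DEFAULT_TOLERANCE_BP,
    *,
    containment: bool = True,
) -> list[str]:
    """Names of TADs containing the interaction interval within tolerance.

    With ``containment`` (default) the interval must lie inside
    [tad.start − tol, tad.end + tol]; with ``containment=False`` a >= 1 bp
    intersection with the expanded TAD suffices.
    """
    chrom, start, end = interaction
    cand = tads.on_chrom(chrom)
    if cand.empty:
        return []
    lo = cand["start"].to_numpy() - tolerance_bp
    hi = cand["end"].to_numpy() + tolerance_bp
    if containment:
        hit = (start >= lo) & (end <= hi)
    else:
        hit = (start < hi) & (end > lo)
    return [str(n) for n in cand["name"].to_numpy()[hit]]


def fraction_in_bait_tad(
    call: InteractionCall,
    tads: TadSet,
    bait: BaitConfig,
    tolerance_bp: int = DEFAULT_TOLERANCE_BP,
) -> float:
    """Fraction of merged interaction intervals inside a TAD containing the bait."""
    bait_tads = tads.on_chrom(bait.chrom)
    bait_tads = bait_tads[
        (bait_tads["start"] <= bait.position) & (bait.position < bait_tads["end"])
    ]
    if bait_tads.empty:
        raise ValueError(f"bait {bait.name} at {bait.chrom}:{bait.position} lies in no TAD")
    intervals = call.merged_intervals
    if intervals.empty:
        return 0.0
    lo = bait_tads["start"].to_numpy() - tolerance_bp
    hi = bait_tads["end"].to_numpy() + tolerance_bp
    inside = 0
    for _, row in intervals.iterrows():
        if row["chrom"] != bait.chrom:
            continue
        if np.any((row["start"] >= lo) & (row["end"] <= hi)):
            inside += 1
    return inside / len(intervals)


@dataclass
class ContactMatrix:
    """A binned contact matrix with its genomic bin intervals."""

    bins: pd.DataFrame  # chrom, start, end
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.bins), len(self.bins)):
            raise ValueError("matrix dimensions do not match bin list")
        if np.any(self.values < 0):
            raise ValueError("contact matrix has negative entries")

    @property
    def bin_size(self) -> int:
        return int((self.bins["end"] - self.bins["start"]).iloc[0])

    @classmethod
    def from_dense(cls, matrix_path, bins_path) -> "ContactMatrix":
        values = np.loadtxt(matrix_path, delimiter="\t", ndmin=2)
        return cls(bins=_read_bins(bins_path), values=values)

    @classmethod
    def from_coo(cls, coo_path, bins_path) -> "ContactMatrix":
        bins = _read_bins(bins_path)
        n = len(bins)
        coo = pd.read_csv(coo_path, sep="\t", header=None, names=["i", "j", "value"])
        values = np.zeros((n, n))
        values[coo["i"], coo["j"]] = coo["value"]
        values[coo["j"], coo["i"]] = coo["value"]  # symmetric fill
        return cls(bins=bins, values=values)


def _read_bins(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", header=None, comment="#")
    frame = frame.iloc[:, :3]
    frame.columns = ["chrom", "start", "end"]
    return frame


def log2_ratio(a: ContactMatrix, b: ContactMatrix, pseudocount: float = 1.0) -> np.ndarray:
    """Elementwise log2((A + pc) / (B + pc)) on a shared bin grid."""
    if not a.bins.reset_index(drop=True).equals(b.bins.reset_index(drop=True)):
        raise ValueError("contact matrices have different bin grids")
    if pseudocount <= 0 and (np.any(a.values == 0) or np.any(b.values == 0)):
        raise ValueError("pseudocount <= 0 with zero entries would be undefined")
    return np.log2((a.values + pseudocount) / (b.values + pseudocount))


def increased_bins(
    ratio: np.ndarray, bins: pd.DataFrame, threshold: float = 1.0
) -> pd.DataFrame:
    """Bin pairs whose log2 ratio reaches the threshold, as a BEDPE-like table.

    The threshold marking "increased" contacts is a configurable stand-in
    (default log2 ratio >= 1, i.e. a two-fold gain); only the upper triangle
    is reported for symmetric input.
    """
    ii, jj = np.where(np.triu(ratio >= threshold))
    rows = []
    for i, j in zip(ii, jj):
        bi, bj = bins.iloc[i], bins.iloc[j]
        rows.append(
            {
                "chrom1": bi["chrom"], "start1": int(bi["start"]), "end1": int(bi["end"]),
                "chrom2": bj["chrom"], "start2": int(bj["start"]), "end2": int(bj["end"]),
                "log2_ratio": float(ratio[i, j]),
            }
        )
    return pd.DataFrame(
        rows, columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2", "log2_ratio"]
    )
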