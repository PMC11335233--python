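"""Cis interaction calling against a monotone distance-decay background.

Contact frequency in 4C falls monotonically with genomic distance from the
bait.  The caller transforms RPKM with a variance-stabilising log2(x+1),
fits an isotonic (monotone non-increasing) regression of the transformed
signal on log10 distance separately on each side of the bait, and scores
each fragment by how many robust standard deviations (MAD-based sigma of
the residuals) it sits above the fitted trend.  One-sided normal p-values
are Benjamini–Hochberg adjusted within the analysis window, and a fragment
is a significant interaction only when it passes both the z and the FDR
threshold in every replicate.  Adjacent significant fragments merge into
interaction intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression
from statsmodels.stats.multitest import multipletests

from .quant import SampleCounts
from .restriction import BaitConfig, FragmentMap

SIGMA_FLOOR = 1e-6
MIN_SIDE_FRAGMENTS = 10


def transform_counts(rpkm):
    """Variance-stabilising transform: log2(rpkm + 1). Monotone, 0 at 0."""
    rpkm = np.asarray(rpkm, dtype=float)
    if np.any(rpkm < 0):
        raise ValueError("negative value passed to transform_counts")
    return np.log2(rpkm + 1.0)


def transform_sqrt(rpkm):
    """Alternative variance-stabilising transform (square root)."""
    rpkm = np.asarray(rpkm, dtype=float)
    if np.any(rpkm < 0):
        raise ValueError("negative value passed to transform_sqrt")
    return np.sqrt(rpkm)


@dataclass
class DecayFit:
    """Monotone decay trend on one side of the bait for one sample.

    ``fitted`` are the isotonic values at the training points ``log10_d``;
    prediction at new distances interpolates between them (clipped at the
    range ends).  ``sigma`` is 1.4826 × median absolute residual, floored at
    a tiny positive value so flat degenerate profiles cannot produce
    infinite z-scores.
    """

    sample_id: str
    side: str
    log10_d: np.ndarray
    fitted: np.ndarray
    sigma: float
    residuals: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def predict(self, distance_bp) -> np.ndarray:
        logd = np.log10(np.asarray(distance_bp, dtype=float))
        order = np.argsort(self.log10_d)
        return np.interp(logd, self.log10_d[order], self.fitted[order])


def isotonic_decreasing(x, values) -> np.ndarray:
    """Least-squares monotone non-increasing fit of ``values`` on ``x``.

    This is the pool-adjacent-violators core of :func:`fit_decay`, exposed
    without the minimum-size guard so tiny inputs can be fitted directly.
    """
    iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
    return np.asarray(
        iso.fit_transform(np.asarray(x, dtype=float), np.asarray(values, dtype=float)),
        dtype=float,
    )


def fit_decay(values, distances_bp, side: str, sample_id: str = "sample") -> DecayFit:
    """Isotonic non-increasing fit of transformed signal vs log10 distance."""
    values = np.asarray(values, dtype=float)
    distances_bp = np.asarray(distances_bp, dtype=float)
    if len(values) != len(distances_bp):
        raise ValueError("values and distances differ in length")
    if len(values) < MIN_SIDE_FRAGMENTS:
        raise ValueError(
            f"{side}: need >= {MIN_SIDE_FRAGMENTS} fragments to fit decay, got {len(values)}"
        )
    if np.any(distances_bp <= 0):
        raise ValueError("distances must be strictly positive")
    logd = np.log10(distances_bp)
    fitted = isotonic_decreasing(logd, values)
    residuals = values - fitted
    sigma = max(1.4826 * float(np.median(np.abs(residuals))), SIGMA_FLOOR)
    return DecayFit(
        sample_id=sample_id,
        side=side,
        log10_d=logd,
        fitted=np.asarray(fitted, dtype=float),
        sigma=sigma,
        residuals=residuals,
    )


def compute_z(values, fit: DecayFit, distances_bp=None) -> tuple[np.ndarray, np.ndarray]:
    """z = (value − fitted)/sigma and its one-sided upper-tail normal p.

    With ``distances_bp`` given, the trend is interpolated there; otherwise
    the training-point fit is used directly.
    """
    if fit.sigma <= 0:
        raise ValueError("decay fit has non-positive sigma")
    values = np.asarray(values, dtype=float)
    expected = fit.predict(distances_bp) if distances_bp is not None else fit.fitted
    z = (values - expected) / fit.sigma
    p = stats.norm.sf(z)
    return z, p


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def score_sample(
    counts: SampleCounts,
    fmap: FragmentMap,
    bait: BaitConfig,
    *,
    include_blind: bool = False,
    transform=transform_counts,
) -> pd.DataFrame:
    """Per-fragment (z, p, fdr) for one library within the cis window.

    Returns one row per analysable fragment on the bait chromosome within
    ``bait.window_bp`` of the bait: non-excluded, and non-blind unless
    ``include_blind``.  The decay trend is fitted per side of the bait; BH
    adjustment pools both sides (the full analysis window of this sample).
    """
    if fmap.bait_fragment_id is None:
        raise ValueError("bait not located on fragment map")
    cis = counts.on_chrom(bait.chrom).copy()
    bait_idx = fmap.index_of(fmap.bait_fragment_id)
    bait_mid = int(fmap.midpoints[bait_idx])
    mid = ((cis["start"] + cis["end"]) // 2).to_numpy()
    cis["distance"] = mid - bait_mid  # signed, bait-midpoint to fragment-midpoint

    keep = ~cis["fragment_id"].isin(counts.excluded_fragment_ids)
    keep &= cis["distance"].abs() <= bait.window_bp
    keep &= cis["distance"] != 0
    if not include_blind:
        keep &= ~cis["blind"].astype(bool)
    win = cis[keep].copy()
    win["value"] = transform(win["rpkm"].to_numpy())

    win["z"] = np.nan
    win["p"] = np.nan
    for side, mask in (("upstream", win["distance"] < 0), ("downstream", win["distance"] > 0)):
        sub = win[mask]
        fit = fit_decay(
            sub["value"].to_numpy(),
            sub["distance"].abs().to_numpy(),
            side,
            counts.sample_id,
        )
        z, p = compute_z(sub["value"].to_numpy(), fit)
        win.loc[mask, "z"] = z
        win.loc[mask, "p"] = p
    win["fdr"] = bh_fdr(win["p"].to_numpy())
    cols = ["fragment_id", "chrom", "start", "end", "distance", "value", "z", "p", "fdr"]
    return win[cols].reset_index(drop=True)


@dataclass
class InteractionCall:
    """Replicate-concordant interaction calls for one bait × condition."""

    bait_name: str
    diet: str
    timepoint: str
    fragments: pd.DataFrame  # fragment_id, distance, z_rep*, fdr_rep*, significant
    merged_intervals: pd.DataFrame  # chrom, start, end, n_fragments, mean_z
    z_threshold: float
    fdr_threshold: float

    @property
    def n_interactions(self) -> int:
        return len(self.merged_intervals)

    @property
    def significant_fragment_ids(self) -> set[int]:
        sig = self.fragments[self.fragments["significant"]]
        return {int(i) for i in sig["fragment_id"]}


def call_interactions(
    replicate_scores: Sequence[pd.DataFrame],
    *,
    bait_name: str = "",
    diet: str = "",
    timepoint: str = "",
    z_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
    merge_gap_fragments: int = 1,
) -> InteractionCall:
    """Fragments significant in every replicate, merged into intervals.

    A fragment is significant iff z >= z_threshold and fdr <= fdr_threshold
    in ALL replicates.  Runs of significant fragments separated by at most
    ``merge_gap_fragments`` non-significant fragments merge into a single
    reported interaction interval, scored by the cross-replicate mean z of
    its significant fragments.
    """
    if not replicate_scores:
        raise ValueError("no replicate score tables given")
    universe = replicate_scores[0]["fragment_id"].to_numpy()
    for rep in replicate_scores[1:]:
        if not np.array_equal(rep["fragment_id"].to_numpy(), universe):
            raise ValueError("replicate fragment universes differ")

    base = replicate_scores[0][["fragment_id", "chrom", "start", "end", "distance"]].copy()
    significant = np.ones(len(base), dtype=bool)
    zs = []
    for r, rep in enumerate(replicate_scores, start=1):
        z = rep["z"].to_numpy()
        fdr = rep["fdr"].to_numpy()
        base[f"z_rep{r}"] = z
        base[f"fdr_rep{r}"] = fdr
        significant &= (z >= z_threshold) & (fdr <= fdr_threshold)
        zs.append(z)
    base["mean_z"] = np.mean(zs, axis=0)
    base["significant"] = significant
    base = base.sort_values("start", kind="stable").reset_index(drop=True)

    merged = _merge_significant(base, merge_gap_fragments)
    return InteractionCall(
        bait_name=bait_name,
        diet=diet,
        timepoint=timepoint,
        fragments=base,
        merged_intervals=merged,
        z_threshold=z_threshold,
        fdr_threshold=fdr_threshold,
    )


def _merge_significant(frame: pd.DataFrame, merge_gap: int) -> pd.DataFrame:
    """Merge coordinate-ordered significant fragments with a gap tolerance."""
    sig_idx = np.flatnonzero(frame["significant"].to_numpy())
    rows = []
    if len(sig_idx):
        run_start = sig_idx[0]
        prev = sig_idx[0]
        for idx in list(sig_idx[1:]) + [None]:
            if idx is not None and idx - prev - 1 <= merge_gap:
                prev = idx
                continue
            members = frame.iloc[run_start:prev + 1]
            members = members[members["significant"]]
            rows.append(
                {
                    "chrom": members["chrom"].iloc[0],
                    "start": int(members["start"].min()),
                    "end": int(members["end"].max()),
                    "n_fragments": int(len(members)),
                    "mean_z": float(members["mean_z"].mean()),
                }
            )
            if idx is not None:
                run_start = prev = idx
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_fragments", "mean_z"])


def write_bedpe(call: InteractionCall, fmap: FragmentMap, path) -> None:
    """Merged interactions as BEDPE: anchor1 = bait fragment, anchor2 = interval."""
    if fmap.bait_fragment_id is None:
        raise ValueError("bait not located")
    i = fmap.index_of(fmap.bait_fragment_id)
    with open(path, "w") as fh:
        for _, row in call.merged_intervals.iterrows():
            fh.write(
                "\t".join(
                    [
                        fmap.chrom,
                        str(int(fmap.starts[i])),
                        str(int(fmap.ends[i])),
                        str(row["chrom"]),
                        str(int(row["start"])),
                        str(int(row["end"])),
                        f"{call.bait_name}:{call.diet}_{call.timepoint}",
                        f"{row['mean_z']:.4f}",
                    ]
                )
                + "\n"
            )
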