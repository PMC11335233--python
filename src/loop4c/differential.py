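"""Diet-differential contact calling by the average z-score-ratio rule.

A fragment gains a contact under one diet when the ratio of its
replicate-averaged z-scores between the two diets reaches the threshold
(default 1.5) AND the gaining diet itself calls the fragment significant
(z and FDR thresholds in every replicate).  The significance requirement
keeps ratios between two noise fragments from being reported.  Non-positive
mean z-scores are clipped to a small epsilon before forming the ratio, so
the ratio is always defined and non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cis import InteractionCall

EPSILON = 0.1


def average_z(z_per_replicate) -> float:
    """Arithmetic mean of replicate z-scores."""
    z = np.asarray(z_per_replicate, dtype=float)
    if z.size == 0:
        raise ValueError("no replicate z-scores given")
    return float(z.mean())


def zscore_ratio(mean_z_num: float, mean_z_den: float, epsilon: float = EPSILON) -> float:
    """max(num, eps) / max(den, eps): the diet-contrast ratio for one orientation."""
    return max(mean_z_num, epsilon) / max(mean_z_den, epsilon)


def call_differential(
    calls_hf: InteractionCall,
    calls_cd: InteractionCall,
    *,
    ratio_threshold: float = 1.5,
    epsilon: float = EPSILON,
) -> pd.DataFrame:
    """Per-fragment differential table between HF and CD at one timepoint.

    Columns: fragment_id, mean_z_HF, mean_z_CD, ratio (in the gaining
    orientation), direction (HF_gain / CD_gain / ""), differential.
    A fragment is HF_gain iff ratio(HF/CD) >= threshold and it is
    significant in HF; symmetrically for CD_gain.  Both orientations can
    never fire at once for ratio_threshold > 1 since the ratios are
    reciprocal-ordered.
    """
    if calls_hf.bait_name != calls_cd.bait_name:
        raise ValueError("differential calls require the same bait")
    if calls_hf.timepoint != calls_cd.timepoint:
        raise ValueError("differential calls require the same timepoint")
    hf = calls_hf.fragments
    cd = calls_cd.fragments
    if not np.array_equal(hf["fragment_id"].to_numpy(), cd["fragment_id"].to_numpy()):
        raise ValueError("fragment universes differ between conditions")

    mean_hf = hf["mean_z"].to_numpy()
    mean_cd = cd["mean_z"].to_numpy()
    sig_hf = hf["significant"].to_numpy()
    sig_cd = cd["significant"].to_numpy()

    num_hf = np.maximum(mean_hf, epsilon)
    num_cd = np.maximum(mean_cd, epsilon)
    ratio_hf = num_hf / num_cd
    ratio_cd = num_cd / num_hf

    hf_gain = (ratio_hf >= ratio_threshold) & sig_hf
    cd_gain = (ratio_cd >= ratio_threshold) & sig_cd & ~hf_gain

    direction = np.full(len(hf), "", dtype=object)
    direction[hf_gain] = "HF_gain"
    direction[cd_gain] = "CD_gain"
    ratio = np.where(cd_gain, ratio_cd, ratio_hf)

    return pd.DataFrame(
        {
            "fragment_id": hf["fragment_id"].to_numpy(),
            "chrom": hf["chrom"].to_numpy(),
            "start": hf["start"].to_numpy(),
            "end": hf["end"].to_numpy(),
            "mean_z_HF": mean_hf,
            "mean_z_CD": mean_cd,
            "ratio": ratio,
            "direction": direction,
            "differential": hf_gain | cd_gain,
        }
    )


def write_differential(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out["differential"] = out["differential"].astype(int)
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")
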