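"""Trans interaction domains from smoothed window counts.

Signal on non-bait chromosomes is too sparse for fragment-level calls, so
fragments are pooled into fixed windows of k consecutive analysable
fragments (k = 20 by default), the summed RPKM is log-transformed, and a
3-state Gaussian hidden Markov model segments each replicate's window track
into no/low/high signal.  States are relabelled by ascending emission mean
so "high" is initialisation-invariant, and a window becomes part of an
interaction domain only when labelled high in the required number of
replicates (n = 2 by default).  Maximal runs of such windows are the
reported trans domains.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM

from .quant import SampleCounts
from .restriction import FragmentMap

DEFAULT_K = 20
DEFAULT_N_REQUIRED = 2
N_STATES = 3
N_RESTARTS = 10


@dataclass
class WindowTrack:
    """Fixed-size fragment windows on one trans chromosome."""

    chrom: str
    starts: np.ndarray
    ends: np.ndarray
    summed_rpkm: np.ndarray
    log_signal: np.ndarray
    k: int

    def __len__(self) -> int:
        return len(self.starts)


@dataclass
class TransDomain:
    """A maximal run of replicate-supported high-signal windows."""

    chrom: str
    start: int
    end: int
    mean_signal: float
    supported_replicates: int


def make_windows(
    counts: SampleCounts,
    fmap: FragmentMap,
    k: int = DEFAULT_K,
    *,
    include_blind: bool = False,
) -> WindowTrack:
    """Pool consecutive blocks of k analysable fragments into windows.

    Blind and excluded fragments are dropped before chunking.  The last
    window may span fewer than k fragments; a chromosome with fewer than k
    analysable fragments yields a single window over all of them.
    """
    frame = counts.on_chrom(fmap.chrom)
    keep = ~frame["fragment_id"].isin(counts.excluded_fragment_ids)
    if not include_blind:
        keep &= ~frame["blind"].astype(bool)
    frame = frame[keep].sort_values("start")
    if frame.empty:
        raise ValueError(f"{fmap.chrom}: no analysable fragments")
    starts = frame["start"].to_numpy()
    ends = frame["end"].to_numpy()
    rpkm = frame["rpkm"].to_numpy()
    n = len(frame)
    edges = list(range(0, n, k)) + [n]
    win_start, win_end, win_sum = [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        win_start.append(int(starts[lo]))
        win_end.append(int(ends[hi - 1]))
        win_sum.append(float(rpkm[lo:hi].sum()))
    summed = np.asarray(win_sum)
    return WindowTrack(
        chrom=fmap.chrom,
        starts=np.asarray(win_start, dtype=np.int64),
        ends=np.asarray(win_end, dtype=np.int64),
        summed_rpkm=summed,
        log_signal=np.log2(summed + 1.0),
        k=k,
    )


def segment_hmm(
    track: WindowTrack | np.ndarray,
    n_states: int = N_STATES,
    seed: int = 0,
    *,
    n_restarts: int = N_RESTARTS,
) -> np.ndarray:
    """Viterbi state path of a Gaussian HMM over the window log-signal.

    For each candidate state count (2 … ``n_states``) the model is fitted by
    EM from ``n_restarts`` seeded initialisations (seeds seed, seed+1, …),
    keeping the max-likelihood converged fit; the state count is then chosen
    by BIC, so a track with only two signal levels is not force-split into
    three.  States are relabelled by ascending emission mean and the top
    state is always reported as label ``n_states − 1`` ("high"), with the
    remaining states packed from 0 upward — so the high label is invariant
    to both EM initialisation and the selected state count.  A constant
    signal yields a single state (all zeros).
    """
    signal = track.log_signal if isinstance(track, WindowTrack) else np.asarray(track, float)
    if len(signal) < 10:
        raise ValueError(f"need >= 10 windows to segment, got {len(signal)}")
    x = signal.reshape(-1, 1)
    if np.ptp(signal) == 0:
        return np.zeros(len(signal), dtype=int)

    import logging

    logging.getLogger("hmmlearn.base").setLevel(logging.ERROR)
    best = None  # (bic, k, path, means)
    diagnostics = []
    for k in range(min(2, n_states), n_states + 1):
        k_best = None
        for restart in range(n_restarts):
            model = GaussianHMM(
                n_components=k,
                covariance_type="diag",
                n_iter=200,
                random_state=seed + restart,
                min_covar=1e-3,
            )
            try:
                # EM on short or quantised tracks can leave unreachable
                # states (zero transition rows); treat the restart as failed
                model.fit(x)
                if not model.monitor_.converged:
                    raise RuntimeError("EM did not converge")
                if not np.allclose(model.transmat_.sum(axis=1), 1.0, atol=1e-6):
                    raise RuntimeError("degenerate transition matrix")
                score = model.score(x)
                path = model.predict(x)
            except Exception as exc:
                diagnostics.append(f"k={k} restart {restart}: {exc}")
                continue
            if np.isfinite(score) and (k_best is None or score > k_best[0]):
                k_best = (score, path, model.means_.ravel())
        if k_best is None:
            continue
        n_params = k * k + 2 * k - 1  # start, transitions, means, variances
        bic = -2.0 * k_best[0] + n_params * np.log(len(signal))
        if best is None or bic < best[0]:
            best = (bic, k, k_best[1], k_best[2])
    if best is None:
        raise RuntimeError(
            "HMM segmentation failed on all restarts: " + "; ".join(diagnostics)
        )
    _, k, path, means = best
    order = np.argsort(means, kind="stable")
    rank = np.empty(k, dtype=int)
    rank[order] = np.arange(k)
    # top state -> n_states-1; lower states keep their ascending rank
    relabel = np.where(rank == k - 1, n_states - 1, rank)
    return relabel[path]


def viterbi_fixed(
    signal,
    means,
    variances,
    startprob,
    transmat,
) -> np.ndarray:
    """Viterbi state path under a fully specified Gaussian HMM (no fitting).

    Useful for checking a segmentation against a hand-specified chain.
    """
    model = GaussianHMM(n_components=len(means), covariance_type="diag", init_params="")
    model.startprob_ = np.asarray(startprob, dtype=float)
    model.transmat_ = np.asarray(transmat, dtype=float)
    model.means_ = np.asarray(means, dtype=float).reshape(-1, 1)
    model.covars_ = np.asarray(variances, dtype=float).reshape(-1, 1)
    return model.predict(np.asarray(signal, dtype=float).reshape(-1, 1))


def call_trans_domains(
    paths: Sequence[np.ndarray],
    track: WindowTrack,
    n_required: int = DEFAULT_N_REQUIRED,
    *,
    n_states: int = N_STATES,
) -> list[TransDomain]:
    """Intersect per-replicate high-state windows into maximal domains."""
    high = n_states - 1
    support = np.zeros(len(track), dtype=int)
    for path in paths:
        if len(path) != len(track):
            raise ValueError("state path length does not match window grid")
        support += np.asarray(path) == high
    eligible = support >= n_required

    domains: list[TransDomain] = []
    idx = np.flatnonzero(eligible)
    if len(idx) == 0:
        return domains
    run_start = idx[0]
    prev = idx[0]
    for i in list(idx[1:]) + [None]:
        if i is not None and i == prev + 1:
            prev = i
            continue
        members = slice(run_start, prev + 1)
        domains.append(
            TransDomain(
                chrom=track.chrom,
                start=int(track.starts[run_start]),
                end=int(track.ends[prev]),
                mean_signal=float(track.log_signal[members].mean()),
                supported_replicates=n_required,
            )
        )
        if i is not None:
            run_start = prev = i
    return domains


def windows_frame(track: WindowTrack, paths: Sequence[np.ndarray]) -> pd.DataFrame:
    """Per-window TSV-ready table with one state column per replicate."""
    frame = pd.DataFrame(
        {
            "chrom": track.chrom,
            "start": track.starts,
            "end": track.ends,
            "log_signal": track.log_signal,
        }
    )
    for r, path in enumerate(paths, start=1):
        frame[f"state_rep{r}"] = np.asarray(path, dtype=int)
    return frame


def write_domains_bed(domains: Sequence[TransDomain], path, name: str = "trans") -> None:
    with open(path, "w") as fh:
        for d in domains:
            fh.write(f"{d.chrom}\t{d.start}\t{d.end}\t{name}\t{d.mean_signal:.4f}\t.\n")


def link_table(
    domains: Sequence[TransDomain], bait_chrom: str, bait_start: int, bait_end: int
) -> pd.DataFrame:
    """Inter-chromosomal link pairs (bait interval <-> domain interval)."""
    return pd.DataFrame(
        [
            {
                "chrom1": bait_chrom,
                "start1": bait_start,
                "end1": bait_end,
                "chrom2": d.chrom,
                "start2": d.start,
                "end2": d.end,
                "score": d.mean_signal,
            }
            for d in domains
        ],
        columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2", "score"],
    )
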