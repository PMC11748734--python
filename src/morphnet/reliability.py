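"""Test-retest reliability of network edges.

Each edge's similarity value, measured across repeated scan sessions, is
scored with the one-way random-effects intraclass correlation

    ICC = (MS_b - MS_w) / (MS_b + (k - 1) MS_w)

where MS_b and MS_w are the between- and within-subject mean squares of a
one-way ANOVA on subjects and k is the number of repeated observations.
Values are binned poor / low / fair / good / excellent, and gyral vs
sulcal edge reliability is compared with a two-sample permutation test
over pooled edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .network import MorphNetwork, extract_subcomponents

__all__ = [
    "ICC_BINS",
    "ICCResult",
    "icc",
    "edgewise_icc",
    "classify_icc",
    "compare_reliability",
    "block_edge_vector",
]

# half-open [lo, hi) bins; anything <= 0 is poor, 1.0 is excellent
ICC_BINS = (
    (0.25, "poor"),
    (0.40, "low"),
    (0.60, "fair"),
    (0.75, "good"),
    (np.inf, "excellent"),
)


def icc(measurements: np.ndarray) -> float:
    """One-way random-effects ICC(1,1) of a subjects-by-sessions table.

    May be negative when within-subject variance exceeds between-subject
    variance.  Raises on missing cells or zero total variance.
    """
    x = np.asarray(measurements, dtype=float)
    if x.ndim != 2:
        raise ValueError("measurements must be a 2-D subject x session table")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 sessions")
    if not np.all(np.isfinite(x)):
        raise ValueError("missing or non-finite cells in the measurement table")
    if np.ptp(x) == 0:
        raise ValueError("zero total variance: ICC undefined")
    subj_means = x.mean(axis=1)
    grand = x.mean()
    ms_b = k * ((subj_means - grand) ** 2).sum() / (n - 1)
    ms_w = ((x - subj_means[:, None]) ** 2).sum() / (n * (k - 1))
    return float((ms_b - ms_w) / (ms_b + (k - 1) * ms_w))


def block_edge_vector(net: MorphNetwork, block: str) -> np.ndarray:
    """Unique-edge vector of one subnetwork block.

    For the square ``gg``/``ss`` blocks this is the upper triangle; for
    the rectangular ``gs`` block every entry is a distinct edge.
    """
    gg, ss, gs = extract_subcomponents(net)
    if block == "gg":
        return gg[np.triu_indices(gg.shape[0], k=1)]
    if block == "ss":
        return ss[np.triu_indices(ss.shape[0], k=1)]
    if block == "gs":
        return gs.ravel()
    if block == "gsgs":
        return net.weights[np.triu_indices(net.n_nodes, k=1)]
    raise ValueError(f"unknown block {block!r}")


@dataclass
class ICCResult:
    """Per-edge ICC values for one block, with reliability bin labels."""

    values: np.ndarray
    k: int
    block: str
    bins: list[str]

    @property
    def n_edges(self) -> int:
        return self.values.size


def edgewise_icc(
    session_networks: Sequence[Sequence[MorphNetwork]],
    block: str = "gg",
    session_pair: tuple[int, int] | None = None,
) -> ICCResult:
    """ICC of every unique edge across sessions.

    ``session_networks[t][s]`` is subject ``s``'s network in session
    ``t``; all sessions must cover the same subjects.  With more than two
    sessions, pass ``session_pair`` to score a specific pair (reliability
    over long intervals is usually reported per session pair).

    Edges with zero variance across all subjects and sessions are assigned
    NaN with a warning rather than aborting the whole block.
    """
    if len(session_networks) < 2:
        raise ValueError("need at least 2 sessions")
    n_subj = len(session_networks[0])
    if any(len(sess) != n_subj for sess in session_networks):
        raise ValueError("sessions cover different numbers of subjects")
    if session_pair is not None:
        session_networks = [session_networks[t] for t in session_pair]

    # data[subject, session, edge]
    data = np.stack(
        [
            np.stack([block_edge_vector(net, block) for net in sess])
            for sess in session_networks
        ],
        axis=1,
    )
    n, k, _ = data.shape
    subj_means = data.mean(axis=1)
    grand = data.mean(axis=(0, 1))
    ms_b = k * ((subj_means - grand) ** 2).sum(axis=0) / (n - 1)
    ms_w = ((data - subj_means[:, None, :]) ** 2).sum(axis=(0, 1)) / (n * (k - 1))
    denom = ms_b + (k - 1) * ms_w
    degenerate = denom == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} edge(s) with zero total variance; ICC set to NaN",
            UserWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(degenerate, np.nan, (ms_b - ms_w) / denom)
    bins = [classify_icc(v) if np.isfinite(v) else "undefined" for v in values]
    return ICCResult(values=values, k=k, block=block, bins=bins)


def classify_icc(value: float) -> str:
    """Reliability bin of an ICC value.

    Bins are half-open [lo, hi): poor (< 0.25, including negatives), low
    [0.25, 0.4), fair [0.4, 0.6), good [0.6, 0.75), excellent [0.75, 1].
    """
    if value > 1:
        raise ValueError("ICC cannot exceed 1")
    for hi, label in ICC_BINS:
        if value < hi:
            return label
    return "excellent"  # pragma: no cover


def compare_reliability(
    icc_a: np.ndarray,
    icc_b: np.ndarray,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Two-sample permutation test on mean edge reliability.

    Statistic: mean(icc_a) - mean(icc_b).  The null pools both edge lists
    and re-splits at the original sizes; the two-tailed p-value uses the
    add-one convention (1 + #extreme) / (1 + n_perm).
    """
    a = np.asarray(icc_a, dtype=float)
    b = np.asarray(icc_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both edge lists must be non-empty")
    observed = a.mean() - b.mean()
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        stat = perm[: a.size].mean() - perm[a.size :].mean()
        if abs(stat) >= abs(observed):
            count += 1
    p = (1 + count) / (1 + n_perm)
    return float(observed), float(p)
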