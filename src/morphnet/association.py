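"""Behavioral variance explained by network similarity.

The variance component model treats the behavior matrix Y (subjects x
phenotypes) as Y = B + E with B ~ N(0, sigma_b^2 M) and
E ~ N(0, sigma_e^2 I), where M is the between-subject correlation matrix
of network edge profiles.  The fraction of behavioral variance explained
by the networks is

    V = tr(Sigma_B) / (tr(Sigma_B) + tr(Sigma_E))

estimated per phenotype by a method-of-moments (Haseman-Elston-type)
solve of the two trace equations, with significance from a permutation
null that shuffles subjects' behavior rows, and BH-FDR across domains.
Edgewise Pearson correlations localize significant associations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .network import MorphNetwork
from .reliability import block_edge_vector

__all__ = [
    "NonIdentifiableError",
    "BehaviorTable",
    "SubjectSimilarity",
    "VarianceEstimate",
    "EdgewiseResult",
    "standardize_and_aggregate",
    "edge_matrix",
    "subject_similarity_matrix",
    "estimate_variance_explained",
    "permutation_pvalue_V",
    "bh_fdr",
    "edgewise_correlation",
]


class NonIdentifiableError(ValueError):
    """The variance components cannot be separated for this M."""


@dataclass
class BehaviorTable:
    """Standardized items and domain-aggregated scores."""

    items: pd.DataFrame  # z-scored items, subjects x items
    domains: pd.DataFrame  # subjects x domains (mean of member z-items)
    domain_map: dict[str, str]
    dropped_items: list[str]


def standardize_and_aggregate(
    raw_items: pd.DataFrame, domain_map: Mapping[str, str]
) -> BehaviorTable:
    """Z-score each item across subjects and average items within domains.

    Zero-variance items are dropped with a warning.  Every item column
    must be assigned to exactly one domain.
    """
    if raw_items.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    unmapped = [c for c in raw_items.columns if c not in domain_map]
    if unmapped:
        raise ValueError(f"items without a domain assignment: {unmapped}")

    dropped = []
    z = {}
    for col in raw_items.columns:
        x = raw_items[col].astype(float)
        sd = x.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            dropped.append(col)
            continue
        z[col] = (x - x.mean()) / sd
    if dropped:
        warnings.warn(
            f"dropped zero-variance item(s): {dropped}", UserWarning, stacklevel=2
        )
    items = pd.DataFrame(z, index=raw_items.index)
    domains_order = list(dict.fromkeys(domain_map[c] for c in items.columns))
    domains = pd.DataFrame(
        {
            dom: items[[c for c in items.columns if domain_map[c] == dom]].mean(axis=1)
            for dom in domains_order
        }
    )
    return BehaviorTable(
        items=items,
        domains=domains,
        domain_map=dict(domain_map),
        dropped_items=dropped,
    )


def edge_matrix(
    networks: Sequence[MorphNetwork], block: str = "gsgs"
) -> np.ndarray:
    """Stack each subject's unique-edge vector: subjects x edges."""
    return np.stack([block_edge_vector(net, block) for net in networks])


@dataclass
class SubjectSimilarity:
    """Between-subject correlation of network edge profiles."""

    m: np.ndarray
    block: str
    n_edges_used: int
    n_edges_dropped: int


def subject_similarity_matrix(
    networks: Sequence[MorphNetwork], block: str = "gsgs"
) -> SubjectSimilarity:
    """Correlation matrix M of network profiles between participants.

    Each subject's block is vectorized over unique edges; each edge is
    z-scored across subjects (so high-variance edges do not dominate),
    and M[i, j] is the Pearson correlation between subjects i and j's
    standardized edge vectors.  Edges constant across subjects are dropped
    with a warning.  The diagonal is set to exactly 1.
    """
    if len(networks) < 3:
        raise ValueError("need at least 3 subjects")
    edges = edge_matrix(networks, block)
    sd = edges.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = int((~keep).sum())
    if dropped:
        warnings.warn(
            f"dropped {dropped} edge(s) with zero cross-subject variance",
            UserWarning,
            stacklevel=2,
        )
    z = (edges[:, keep] - edges[:, keep].mean(axis=0)) / sd[keep]
    m = np.corrcoef(z)
    m = 0.5 * (m + m.T)  # corrcoef is symmetric only up to float rounding
    np.fill_diagonal(m, 1.0)
    return SubjectSimilarity(
        m=m, block=block, n_edges_used=int(keep.sum()), n_edges_dropped=dropped
    )


@dataclass
class VarianceEstimate:
    """Variance components and the explained-variance fraction V."""

    sigma_b: np.ndarray  # per phenotype, clamped at 0
    sigma_e: np.ndarray
    sigma_b_raw: np.ndarray  # unclamped moment solutions
    sigma_e_raw: np.ndarray
    tr_b: float
    tr_e: float
    v: float
    n_clamped: int


def estimate_variance_explained(
    y: np.ndarray | pd.DataFrame,
    m: np.ndarray,
    cond_threshold: float = 1e8,
) -> VarianceEstimate:
    """Method-of-moments fit of the variance component model.

    For each (column-centered) phenotype y the two trace equations

        [tr(M^2)  tr(M)] [sigma_b^2]   [y' M y]
        [tr(M)    n    ] [sigma_e^2] = [y' y  ]

    are solved; negative estimates are clamped to zero before summing
    components across phenotypes into tr(Sigma_B) and tr(Sigma_E), and
    V = tr(Sigma_B) / (tr(Sigma_B) + tr(Sigma_E)).  With M = I the system
    is singular (network and environmental variance are indistinguishable)
    and a :class:`NonIdentifiableError` is raised.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    m = np.asarray(m, dtype=float)
    n = y.shape[0]
    if n < 10:
        raise ValueError("need at least 10 subjects")
    if m.shape != (n, n):
        raise ValueError("similarity matrix does not match the subject count")

    tr_m = float(np.trace(m))
    tr_m2 = float((m * m.T).sum())
    a = np.array([[tr_m2, tr_m], [tr_m, n]], dtype=float)
    if np.linalg.cond(a) > cond_threshold:
        raise NonIdentifiableError(
            "trace equations are (near-)singular; sigma_b and sigma_e "
            "cannot be separated for this M"
        )

    yc = y - y.mean(axis=0)
    my = m @ yc
    quad = (yc * my).sum(axis=0)
    total = (yc * yc).sum(axis=0)
    raw = np.linalg.solve(a, np.vstack([quad, total]))
    sigma_b_raw, sigma_e_raw = raw[0], raw[1]
    sigma_b = np.clip(sigma_b_raw, 0.0, None)
    sigma_e = np.clip(sigma_e_raw, 0.0, None)
    n_clamped = int((sigma_b_raw < 0).sum() + (sigma_e_raw < 0).sum())
    tr_b = float(sigma_b.sum())
    tr_e = float(sigma_e.sum())
    denom = tr_b + tr_e
    v = tr_b / denom if denom > 0 else 0.0
    return VarianceEstimate(
        sigma_b=sigma_b,
        sigma_e=sigma_e,
        sigma_b_raw=sigma_b_raw,
        sigma_e_raw=sigma_e_raw,
        tr_b=tr_b,
        tr_e=tr_e,
        v=float(v),
        n_clamped=n_clamped,
    )


def permutation_pvalue_V(
    y: np.ndarray | pd.DataFrame,
    m: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
) -> float:
    """Permutation p-value for V by shuffling behavior rows.

    Subject rows of Y are shuffled jointly across phenotypes, breaking the
    link to M while preserving the phenotype covariance.  One-sided:
    p = (1 + #{V_perm >= V_obs}) / (1 + n_perm).
    """
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    v_obs = estimate_variance_explained(y, m).v
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(y.shape[0])
        if estimate_variance_explained(y[perm], m).v >= v_obs:
            count += 1
    return (1 + count) / (1 + n_perm)


def bh_fdr(
    pvalues: np.ndarray, q: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control.

    Returns ``(significant mask, adjusted p-values)``; adjusted values are
    monotone non-decreasing in the p-value ranks.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    adjusted = np.empty(n)
    adjusted[order] = adjusted_sorted
    significant = adjusted <= q
    return significant, adjusted


@dataclass
class EdgewiseResult:
    """Edgewise correlations with a behavior score."""

    r: np.ndarray
    p: np.ndarray
    significant: np.ndarray
    kept: np.ndarray  # mask of edges that were testable (non-constant)
    node_counts: np.ndarray | None = None


def edgewise_correlation(
    edges: np.ndarray,
    score: np.ndarray,
    q: float = 0.05,
    edge_pairs: np.ndarray | None = None,
    n_nodes: int | None = None,
) -> EdgewiseResult:
    """Pearson correlation of every edge with a domain score.

    Two-tailed p-values from the t distribution; BH-FDR across edges.
    Constant edges are excluded with a warning (their r/p are NaN and they
    can never be significant).  When ``edge_pairs`` (edge index -> node
    pair) and ``n_nodes`` are given, significant edges are attributed to
    both endpoint nodes and counted per node.
    """
    edges = np.asarray(edges, dtype=float)
    score = np.asarray(score, dtype=float)
    n = edges.shape[0]
    if n < 4:
        raise ValueError("need at least 4 subjects")
    if score.shape != (n,):
        raise ValueError("score length does not match the subject count")
    if score.std() == 0:
        raise ValueError("constant behavior score")

    sc = score - score.mean()
    ec = edges - edges.mean(axis=0)
    sd = ec.std(axis=0)
    kept = sd > 0
    if (~kept).any():
        warnings.warn(
            f"excluded {int((~kept).sum())} constant edge(s)",
            UserWarning,
            stacklevel=2,
        )
    r = np.full(edges.shape[1], np.nan)
    num = ec[:, kept].T @ sc
    den = np.sqrt((ec[:, kept] ** 2).sum(axis=0) * (sc**2).sum())
    r[kept] = np.clip(num / den, -1.0, 1.0)

    p = np.full(edges.shape[1], np.nan)
    rk = r[kept]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rk * np.sqrt((n - 2) / (1.0 - rk**2))
    pk = 2 * stats.t.sf(np.abs(t), df=n - 2)
    pk[np.isclose(np.abs(rk), 1.0)] = 0.0
    p[kept] = pk

    significant = np.zeros(edges.shape[1], dtype=bool)
    sig_kept, _ = bh_fdr(p[kept], q=q)
    significant[kept] = sig_kept

    node_counts = None
    if edge_pairs is not None and n_nodes is not None:
        edge_pairs = np.asarray(edge_pairs, dtype=int)
        node_counts = np.bincount(
            edge_pairs[significant].ravel(), minlength=n_nodes
        )
    return EdgewiseResult(
        r=r, p=p, significant=significant, kept=kept, node_counts=node_counts
    )
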