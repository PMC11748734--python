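"""Group comparisons of network summaries.

Patient-vs-control contrasts (e.g. depression cohorts) residualize the
per-subject summary on age and sex with an ordinary least-squares model
and permute group labels; within-subject contrasts (between subnetwork
blocks, or a region's intra-class vs inter-class similarity) use paired
sign-flip permutations, since the compared summaries come from the same
subjects.  All permutation p-values use the add-one convention and are
exactly reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association import bh_fdr
from .network import MorphNetwork

__all__ = [
    "ComparisonResult",
    "adjust_covariates",
    "permutation_group_test",
    "paired_subcomponent_test",
    "nodal_class_contrast",
    "clinical_correlation",
]


@dataclass
class ComparisonResult:
    """Observed statistic and two-tailed permutation p-value."""

    statistic: float
    p: float
    direction: str  # 'a>b', 'a<b', or 'none'
    n_perm: int
    seed: int | None


def adjust_covariates(y: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """OLS residuals of ``y`` on an intercept plus the covariate columns."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(covariates, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    design = np.column_stack([np.ones(len(y)), x])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError("covariate design matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def _direction(stat: float) -> str:
    if stat > 0:
        return "a>b"
    if stat < 0:
        return "a<b"
    return "none"


def permutation_group_test(
    values: np.ndarray,
    labels: np.ndarray,
    covariates: np.ndarray | None = None,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> ComparisonResult:
    """Covariate-adjusted two-sample permutation test.

    ``labels`` holds exactly two group labels (e.g. patient/control); the
    statistic is the mean difference of covariate-adjusted residuals,
    first-label group minus second.  The null shuffles group labels.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(uniq)}")
    mask_a = labels == uniq[0]
    if mask_a.sum() < 2 or (~mask_a).sum() < 2:
        raise ValueError("each group needs at least 2 subjects")
    resid = (
        adjust_covariates(values, covariates) if covariates is not None
        else values - values.mean()
    )
    observed = resid[mask_a].mean() - resid[~mask_a].mean()
    rng = np.random.default_rng(seed)
    count = 0
    n_a = int(mask_a.sum())
    for _ in range(n_perm):
        perm = rng.permutation(resid)
        stat = perm[:n_a].mean() - perm[n_a:].mean()
        if abs(stat) >= abs(observed):
            count += 1
    p = (1 + count) / (1 + n_perm)
    return ComparisonResult(
        statistic=float(observed),
        p=float(p),
        direction=_direction(observed),
        n_perm=n_perm,
        seed=seed,
    )


def paired_subcomponent_test(
    values_a: np.ndarray,
    values_b: np.ndarray,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> ComparisonResult:
    """Paired sign-flip permutation test on per-subject differences.

    The compared summaries (e.g. a subject's mean G-G vs mean S-S
    similarity) are paired by subject, so the null randomly flips the sign
    of each subject's difference.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    observed = d.mean()
    rng = np.random.default_rng(seed)
    signs = rng.choice((-1.0, 1.0), size=(n_perm, d.size))
    null = (signs * d).mean(axis=1)
    count = int((np.abs(null) >= abs(observed)).sum())
    p = (1 + count) / (1 + n_perm)
    return ComparisonResult(
        statistic=float(observed),
        p=float(p),
        direction=_direction(observed),
        n_perm=n_perm,
        seed=seed,
    )


def nodal_class_contrast(
    networks: Sequence[MorphNetwork],
    n_perm: int = 10_000,
    seed: int | None = None,
    q: float = 0.05,
) -> pd.DataFrame:
    """Per-region intra-class vs inter-class similarity contrast.

    For each retained region and subject, the mean similarity to the
    other regions of its own class (excluding itself) is compared to its
    mean similarity to all regions of the other class, with a paired
    sign-flip permutation per region.  BH-FDR is applied separately
    within the gyral and within the sulcal regions.

    Returns a DataFrame with one row per region: region_id, class, mean
    intra/inter similarity, the contrast, p, FDR significance, direction.
    """
    if len(networks) < 5:
        raise ValueError("need at least 5 subjects")
    ref = networks[0]
    classes = ref.classes
    n_nodes = ref.n_nodes
    for cls in ("gyral", "sulcal"):
        if (classes == cls).sum() < 2:
            raise ValueError(f"need at least 2 {cls} regions")

    same = classes[:, None] == classes[None, :]
    np.fill_diagonal(same, False)
    other = classes[:, None] != classes[None, :]
    intra_n = same.sum(axis=1)
    inter_n = other.sum(axis=1)

    intra = np.stack([(net.weights * same).sum(axis=1) / intra_n for net in networks])
    inter = np.stack([(net.weights * other).sum(axis=1) / inter_n for net in networks])
    d = intra - inter  # subjects x regions
    observed = d.mean(axis=0)

    rng = np.random.default_rng(seed)
    signs = rng.choice((-1.0, 1.0), size=(n_perm, len(networks)))
    null = signs @ d / len(networks)  # n_perm x regions
    count = (np.abs(null) >= np.abs(observed)[None, :]).sum(axis=0)
    p = (1 + count) / (1 + n_perm)

    significant = np.zeros(n_nodes, dtype=bool)
    for cls in ("gyral", "sulcal"):
        mask = classes == cls
        sig, _ = bh_fdr(p[mask], q=q)
        significant[mask] = sig

    return pd.DataFrame(
        {
            "region_id": ref.region_ids,
            "region_class": classes,
            "mean_intra": intra.mean(axis=0),
            "mean_inter": inter.mean(axis=0),
            "contrast": observed,
            "p": p,
            "significant": significant,
            "direction": np.where(
                observed > 0, "intra>inter", np.where(observed < 0, "intra<inter", "none")
            ),
        }
    )


def clinical_correlation(
    measure: np.ndarray,
    clinical: np.ndarray,
    method: str = "pearson",
) -> tuple[float, float]:
    """Correlation of a network measure with a clinical score.

    Pearson by default (Spearman via ``method='spearman'``); returns
    ``(r, two-tailed p)``.  Requires at least 4 patients and non-constant
    finite vectors.
    """
    x = np.asarray(measure, dtype=float)
    y = np.asarray(clinical, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be matching 1-D vectors")
    if x.size < 4:
        raise ValueError("need at least 4 patients")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one of the vectors")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)
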