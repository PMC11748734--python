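"""Synthetic cohorts with known ground truth.

The generator emulates vertex-wise cortical feature maps with the
statistical structure the analysis stages assume:

* region means and distribution shapes drawn once per cohort around
  class-level bases (gyral regions systematically thicker than sulcal in
  the default, CT-like, parameterization), giving class-structured
  inter-region similarity with realistic shape diversity;
* a stable subject-by-region effect (variance ``subject_sd**2``) plus
  session-specific noise (variance ``session_sd**2``), so the true
  edgewise test-retest reliability ratio
  ``subject_sd**2 / (subject_sd**2 + session_sd**2)`` is known;
* an optional patient group whose sulcal region means receive an extra
  subject-stable perturbation of scale ``group_effect`` — added
  dispersion, which lowers sulci-sulci similarity monotonically in the
  effect size (a uniform shift of all sulcal means would leave pairwise
  similarity unchanged);
* behavior tables generated under the variance component model
  ``Y = B + E`` with a known fraction ``V_true`` of variance explained by
  the between-subject network similarity ``M``.

Identical configuration and seed give bit-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import validate_region_table

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "CohortSample",
    "make_default_atlas",
    "simulate_cohort",
    "simulate_behavior",
    "write_cohort",
    "read_feature_map",
]


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    Units are arbitrary feature units (think millimetres of cortical
    thickness): class base means 2.5 (gyral) / 2.0 (sulcal), class-level
    spread of region means ``tau_* = 0.35``, within-region vertex SD 0.5.
    Subject and session SDs default to 0.1 and 0.05 — stable individual
    differences several times larger than scan-to-scan noise, i.e. a true
    reliability ratio of 0.8.
    """

    n_subjects: int = 20
    n_sessions: int = 1
    vertices_per_region: int = 200
    tau_gyral: float = 0.2
    tau_sulcal: float = 0.2
    within_region_sd: float = 0.5
    subject_sd: float = 0.1
    session_sd: float = 0.05
    group_effect: float = 0.0
    n_patients: int = 0
    gyral_mean: float = 2.5
    sulcal_mean: float = 2.0
    shape_gap_sd: float = 0.3
    sigma_log_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_sessions < 1:
            raise ValueError("need at least one subject and one session")
        if self.vertices_per_region < 1:
            raise ValueError("vertices_per_region must be positive")
        if self.within_region_sd <= 0:
            raise ValueError("within_region_sd must be positive")
        for name in (
            "tau_gyral", "tau_sulcal", "subject_sd", "session_sd",
            "shape_gap_sd", "sigma_log_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0 <= self.n_patients <= self.n_subjects:
            raise ValueError("n_patients must be between 0 and n_subjects")


@dataclass
class GroundTruth:
    """What the generator actually used, for parameter-recovery tests."""

    region_means: np.ndarray
    true_reliability: float
    group_effect: float
    config: SimulationConfig


@dataclass
class CohortSample:
    """Simulated cohort: values[subject, session, region, vertex]."""

    values: np.ndarray
    region_ids: np.ndarray
    region_classes: np.ndarray
    groups: np.ndarray  # 'patient' / 'control' per subject
    covariates: pd.DataFrame  # columns: age, sex
    ground_truth: GroundTruth

    def feature_map(self, subject: int, session: int = 0) -> dict[int, np.ndarray]:
        """Region-id -> vertex sample mapping for one scan."""
        return {
            int(rid): self.values[subject, session, r]
            for r, rid in enumerate(self.region_ids)
        }


def make_default_atlas(
    n_gyral_per_hemi: int = 29,
    n_sulcal_per_hemi: int = 31,
    n_ambiguous_per_hemi: int = 14,
) -> pd.DataFrame:
    """Bilateral region table with synthetic names.

    Defaults mirror a Destrieux-style parcellation: per hemisphere 29
    gyral, 31 sulcal, and 14 ambiguous regions (74 per hemisphere, 60
    retained), i.e. 58 gyral + 62 sulcal retained bilaterally.
    """
    for n in (n_gyral_per_hemi, n_sulcal_per_hemi, n_ambiguous_per_hemi):
        if n < 0:
            raise ValueError("region counts must be nonnegative")
    rows = []
    rid = 0
    for hemi in ("L", "R"):
        for cls, count, prefix in (
            ("gyral", n_gyral_per_hemi, "G"),
            ("sulcal", n_sulcal_per_hemi, "S"),
            ("ambiguous", n_ambiguous_per_hemi, "A"),
        ):
            for k in range(count):
                rows.append(
                    {
                        "region_id": rid,
                        "name": f"{hemi}_{prefix}{k + 1:02d}",
                        "hemisphere": hemi,
                        "region_class": cls,
                    }
                )
                rid += 1
    table = pd.DataFrame(rows, columns=["region_id", "name", "hemisphere", "region_class"])
    return validate_region_table(table)


def simulate_cohort(config: SimulationConfig, atlas: pd.DataFrame) -> CohortSample:
    """Draw a cohort of vertex-wise feature maps.

    Vertex values for region r, subject s, session t are drawn around
    ``mu_r + g_{s,r} + delta_{s,r} + eps_{s,r,t}`` with
    ``mu_r ~ class base + Normal(0, tau_class)``,
    ``delta ~ Normal(0, subject_sd**2)``,
    ``eps ~ Normal(0, session_sd**2)``, and — for patient subjects and
    sulcal regions only — ``g ~ Normal(0, group_effect**2)``.

    Each region additionally has a cohort-level distribution *shape*: a
    two-component Gaussian location mixture (half-separation
    ``|Normal(0, shape_gap_sd)|``, mixture weight uniform in [0.3, 0.7],
    offsets arranged so the region mean stays exactly ``mu_r``) and a
    region-specific spread ``within_region_sd * LogNormal(0, sigma_log_sd)``.
    Morphological similarity then depends on distribution shape as well as
    location — as in real cortex, where this shape diversity is what makes
    thresholded similarity networks small-world rather than lattice-like.
    Setting ``shape_gap_sd = sigma_log_sd = 0`` recovers a plain
    ``Normal(mu_r + ..., within_region_sd)`` model.

    Region means and shapes are drawn once per cohort so the
    inter-regional similarity structure is a cohort-level property;
    subject, session, and group effects shift location only.  The vertex
    pattern itself is drawn once per (subject, region) — it is stable
    anatomy — and sessions apply the ``eps`` shift to it, so with
    ``session_sd = 0`` repeated sessions are bit-identical and every
    downstream edge ICC is exactly 1.
    """
    atlas = validate_region_table(atlas)
    rng = np.random.default_rng(config.seed)
    region_ids = atlas["region_id"].to_numpy()
    classes = atlas["region_class"].to_numpy()
    n_regions = len(region_ids)

    base = np.empty(n_regions)
    tau = np.empty(n_regions)
    base[classes == "gyral"] = config.gyral_mean
    base[classes == "sulcal"] = config.sulcal_mean
    base[classes == "ambiguous"] = 0.5 * (config.gyral_mean + config.sulcal_mean)
    tau[classes == "gyral"] = config.tau_gyral
    tau[classes == "sulcal"] = config.tau_sulcal
    tau[classes == "ambiguous"] = 0.5 * (config.tau_gyral + config.tau_sulcal)
    mu = base + rng.normal(0.0, 1.0, n_regions) * tau
    # cohort-level region shapes: mixture gap/weight and per-region spread
    gap = np.abs(rng.normal(0.0, 1.0, n_regions)) * config.shape_gap_sd
    weight = rng.uniform(0.3, 0.7, n_regions)
    sigma = config.within_region_sd * np.exp(
        rng.normal(0.0, 1.0, n_regions) * config.sigma_log_sd
    )

    ns, nt, nv = config.n_subjects, config.n_sessions, config.vertices_per_region
    groups = np.array(
        ["patient"] * config.n_patients
        + ["control"] * (ns - config.n_patients)
    )
    group_shift = np.zeros((ns, n_regions))
    if config.group_effect != 0 and config.n_patients > 0:
        sulcal = classes == "sulcal"
        group_shift[: config.n_patients, sulcal] = rng.normal(
            0.0, abs(config.group_effect), (config.n_patients, int(sulcal.sum()))
        )

    delta = rng.normal(0.0, config.subject_sd, (ns, n_regions))
    eps = rng.normal(0.0, config.session_sd, (ns, nt, n_regions))
    centers = mu[None, :] + group_shift + delta  # subject-stable, (ns, n_regions)
    # mean-preserving mixture offsets: w * low + (1 - w) * high = 0
    low = -2.0 * (1.0 - weight) * gap
    high = 2.0 * weight * gap
    in_low = rng.random((ns, n_regions, nv)) < weight[None, :, None]
    offsets = np.where(in_low, low[None, :, None], high[None, :, None])
    # the vertex-level pattern is subject-stable anatomy; sessions shift it
    anatomy = rng.normal(
        centers[..., None] + offsets, sigma[None, :, None], (ns, n_regions, nv)
    )
    values = anatomy[:, None, :, :] + eps[..., None]

    age = np.round(rng.uniform(20, 36, ns)).astype(int)
    sex = rng.integers(0, 2, ns)
    covariates = pd.DataFrame({"age": age, "sex": sex})

    denom = config.subject_sd**2 + config.session_sd**2
    true_rel = config.subject_sd**2 / denom if denom > 0 else float("nan")
    truth = GroundTruth(
        region_means=mu,
        true_reliability=true_rel,
        group_effect=config.group_effect,
        config=config,
    )
    return CohortSample(
        values=values,
        region_ids=region_ids,
        region_classes=classes,
        groups=groups,
        covariates=covariates,
        ground_truth=truth,
    )


def _repair_psd(m: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues to zero and renormalize the diagonal to 1."""
    vals, vecs = np.linalg.eigh(m)
    vals = np.clip(vals, 0.0, None)
    repaired = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    d[d == 0] = 1.0
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired


def simulate_behavior(
    m: np.ndarray,
    n_items: int,
    v_true: float,
    seed: int | None = None,
    item_prefix: str = "item",
) -> pd.DataFrame:
    """Behavior items under the variance component model Y = B + E.

    Each item column is drawn as ``sqrt(V_true) * L z + sqrt(1 - V_true) e``
    where ``L L' = M`` (after PSD repair of the sample similarity matrix),
    i.e. network variance ``sigma_b**2 = V_true`` and environmental
    variance ``sigma_e**2 = 1 - V_true``.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("similarity matrix must be square")
    if not 0 <= v_true <= 1:
        raise ValueError("V_true must be in [0, 1]")
    n = m.shape[0]
    rng = np.random.default_rng(seed)
    repaired = _repair_psd(0.5 * (m + m.T))
    vals, vecs = np.linalg.eigh(repaired)
    root = vecs * np.sqrt(np.clip(vals, 0.0, None))
    b = root @ rng.standard_normal((n, n_items))
    e = rng.standard_normal((n, n_items))
    y = np.sqrt(v_true) * b + np.sqrt(1.0 - v_true) * e
    return pd.DataFrame(
        y, columns=[f"{item_prefix}{k + 1:02d}" for k in range(n_items)]
    )


def write_cohort(cohort: CohortSample, out_dir: str | Path) -> None:
    """Write a cohort as plain-text tables.

    One TSV per (subject, session) named ``sub-SSS_ses-T.tsv`` with a
    ``region_id`` column followed by vertex values, plus ``covariates.tsv``
    (subject, group, age, sex) and ``ground_truth.yaml``.
    """
    import yaml

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ns, nt, nr, nv = cohort.values.shape
    for s in range(ns):
        for t in range(nt):
            df = pd.DataFrame(
                cohort.values[s, t],
                columns=[f"v{k}" for k in range(nv)],
            )
            df.insert(0, "region_id", cohort.region_ids)
            df.to_csv(out / f"sub-{s:03d}_ses-{t + 1}.tsv", sep="\t", index=False)
    cov = cohort.covariates.copy()
    cov.insert(0, "subject", [f"sub-{s:03d}" for s in range(ns)])
    cov.insert(1, "group", cohort.groups)
    cov.to_csv(out / "covariates.tsv", sep="\t", index=False)
    truth = {
        "true_reliability": float(cohort.ground_truth.true_reliability),
        "group_effect": float(cohort.ground_truth.group_effect),
        "region_means": [float(v) for v in cohort.ground_truth.region_means],
        "config": asdict(cohort.ground_truth.config),
    }
    (out / "ground_truth.yaml").write_text(yaml.safe_dump(truth, sort_keys=False))


def read_feature_map(path: str | Path) -> dict[int, np.ndarray]:
    """Read one scan's ``region_id`` + vertex-value TSV back into a map."""
    df = pd.read_csv(path, sep="\t")
    if "region_id" not in df.columns:
        raise ValueError(f"{path}: missing region_id column")
    return {
        int(row[0]): np.asarray(row[1:], dtype=float)
        for row in df.itertuples(index=False)
    }
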