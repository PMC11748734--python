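"""End-to-end orchestration with a reproducibility manifest.

A pipeline run goes: simulate a cohort -> build per-scan similarity
networks -> (optionally) small-world topology on the cohort-mean G-G and
S-S networks, edgewise test-retest ICC, behavioral variance components,
and group comparison.  Analysis defaults match the reference settings of
the method (256 density sample points, sparsity 0.08-0.40 step 0.02, 100
rewired nulls, 1000-shuffle variance-component permutation, q = 0.05).

One master seed deterministically spawns per-stage seeds, so stages can
be reproduced in isolation while the whole run stays bit-reproducible; a
YAML manifest records the parameters actually used, per-stage warnings,
and SHA-256 hashes of every output file.
"""

from __future__ import annotations

import hashlib
import logging
import time
import warnings
from dataclasses import dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association as assoc
from . import atlas as atlas_mod
from . import groups as groups_mod
from . import network as net_mod
from . import reliability as rel_mod
from . import topology as topo_mod
from .simulate import SimulationConfig, make_default_atlas, simulate_behavior, simulate_cohort

__all__ = ["ConfigError", "PipelineError", "PipelineConfig", "load_config", "run_pipeline"]

logger = logging.getLogger("morphnet.pipeline")

DEFAULTS: dict[str, dict] = {
    "atlas": {
        "n_gyral_per_hemi": 29,
        "n_sulcal_per_hemi": 31,
        "n_ambiguous_per_hemi": 14,
    },
    "simulate": {
        "n_subjects": 6,
        "n_sessions": 2,
        "vertices_per_region": 200,
        "tau_gyral": 0.2,
        "tau_sulcal": 0.2,
        "within_region_sd": 0.5,
        "subject_sd": 0.1,
        "session_sd": 0.05,
        "group_effect": 0.0,
        "n_patients": 0,
        "gyral_mean": 2.5,
        "sulcal_mean": 2.0,
        "shape_gap_sd": 0.3,
        "sigma_log_sd": 0.2,
    },
    "network": {"n_points": 256, "feature": "CT"},
    "topology": {
        "enabled": True,
        "sparsity_min": 0.08,
        "sparsity_max": 0.40,
        "sparsity_step": 0.02,
        "n_null": 100,
    },
    "reliability": {"enabled": False, "n_perm": 10000},
    "association": {
        "enabled": False,
        "n_items": 12,
        "n_domains": 6,
        "v_true": 0.3,
        "n_perm": 1000,
        "q": 0.05,
    },
    "groups": {"enabled": False, "n_perm": 10000},
}


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


class PipelineError(RuntimeError):
    """A pipeline stage failed."""


@dataclass
class PipelineConfig:
    atlas: dict = field(default_factory=dict)
    simulate: dict = field(default_factory=dict)
    network: dict = field(default_factory=dict)
    topology: dict = field(default_factory=dict)
    reliability: dict = field(default_factory=dict)
    association: dict = field(default_factory=dict)
    groups: dict = field(default_factory=dict)

    def sparsities(self) -> np.ndarray:
        t = self.topology
        lo, hi, step = t["sparsity_min"], t["sparsity_max"], t["sparsity_step"]
        n = int(round((hi - lo) / step)) + 1
        return np.round(lo + step * np.arange(n), 10)


def _merge_section(name: str, overrides: dict) -> dict:
    base = dict(DEFAULTS[name])
    for key, value in overrides.items():
        if key not in base:
            raise ConfigError(f"unknown key {name}.{key!r}")
        default = base[key]
        if isinstance(default, bool):
            ok = isinstance(value, bool)
        elif isinstance(default, int):
            ok = isinstance(value, int) and not isinstance(value, bool)
        elif isinstance(default, float):
            ok = isinstance(value, (int, float)) and not isinstance(value, bool)
        else:
            ok = isinstance(value, type(default))
        if not ok:
            raise ConfigError(
                f"key {name}.{key!r}: expected {type(default).__name__}, "
                f"got {type(value).__name__}"
            )
        base[key] = value
    return base


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a YAML config merged over the documented defaults.

    An empty or absent file yields pure defaults.  Unknown sections or
    keys, and values of the wrong type, raise :class:`ConfigError` naming
    the offending key.
    """
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config root must be a mapping")
    unknown = set(raw) - set(DEFAULTS)
    if unknown:
        raise ConfigError(f"unknown section(s): {sorted(unknown)}")
    sections = {}
    for name in DEFAULTS:
        overrides = raw.get(name, {})
        if not isinstance(overrides, dict):
            raise ConfigError(f"section {name!r} must be a mapping")
        sections[name] = _merge_section(name, overrides)
    cfg = PipelineConfig(**sections)
    _preflight(cfg)
    return cfg


def _preflight(cfg: PipelineConfig) -> None:
    if cfg.reliability["enabled"] and cfg.simulate["n_sessions"] < 2:
        raise ConfigError(
            "reliability stage needs at least 2 sessions (simulate.n_sessions)"
        )
    if cfg.association["enabled"]:
        if cfg.association["n_items"] < cfg.association["n_domains"]:
            raise ConfigError("association.n_items must cover every domain")
        if cfg.simulate["n_subjects"] < 10:
            raise ConfigError("association stage needs at least 10 subjects")
    if cfg.groups["enabled"] and cfg.simulate["n_patients"] < 2:
        raise ConfigError("groups stage needs simulate.n_patients >= 2")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: PipelineConfig, out_dir: str | Path, seed: int = 0
) -> dict:
    """Run all enabled stages and write outputs plus a manifest.

    Returns the manifest dictionary (also written to ``manifest.yaml``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_seeds = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(
            ("simulate", "behavior", "topology", "reliability", "groups"),
            np.random.SeedSequence(seed).spawn(5),
        )
    }
    manifest: dict = {
        "package": {"name": "morphnet", "version": _pkg_version("morphnet")},
        "master_seed": seed,
        "stage_seeds": stage_seeds,
        "parameters": {
            "atlas": config.atlas,
            "simulate": config.simulate,
            "network": config.network,
            "topology": config.topology,
            "reliability": config.reliability,
            "association": config.association,
            "groups": config.groups,
        },
        "stages": [],
        "warnings": [],
        "outputs": {},
    }

    captured: list[str] = []

    def _stage(name):
        logger.info("stage %s: start", name)
        return time.perf_counter()

    def _done(name, t0):
        logger.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
        manifest["stages"].append(name)

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        try:
            t0 = _stage("simulate")
            atlas = make_default_atlas(**config.atlas)
            atlas_mod.write_region_table(atlas, out / "atlas.tsv")
            sim_cfg = SimulationConfig(**config.simulate, seed=stage_seeds["simulate"])
            cohort = simulate_cohort(sim_cfg, atlas)
            cov = cohort.covariates.copy()
            cov.insert(0, "subject", [f"sub-{s:03d}" for s in range(sim_cfg.n_subjects)])
            cov.insert(1, "group", cohort.groups)
            cov.to_csv(out / "covariates.tsv", sep="\t", index=False)
            _done("simulate", t0)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage 'simulate' failed: {exc}") from exc

        try:
            t0 = _stage("networks")
            net_dir = out / "networks"
            net_dir.mkdir(exist_ok=True)
            networks: list[list[net_mod.MorphNetwork]] = []
            for t in range(sim_cfg.n_sessions):
                sess = []
                for s in range(sim_cfg.n_subjects):
                    net = net_mod.build_network(
                        cohort.feature_map(s, t),
                        atlas,
                        n_points=config.network["n_points"],
                        feature=config.network["feature"],
                    )
                    labels = [str(r) for r in net.region_ids]
                    atlas_mod.write_matrix(
                        net.weights,
                        net_dir / f"sub-{s:03d}_ses-{t + 1}.tsv",
                        row_labels=labels,
                        col_labels=labels,
                    )
                    sess.append(net)
                networks.append(sess)
            session0 = networks[0]
            _done("networks", t0)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage 'networks' failed: {exc}") from exc

        if config.topology["enabled"]:
            try:
                t0 = _stage("topology")
                mean_w = np.mean([n.weights for n in session0], axis=0)
                ref = session0[0]
                blocks = {
                    "gg": mean_w[np.ix_(ref.gyral_mask, ref.gyral_mask)],
                    "ss": mean_w[np.ix_(ref.sulcal_mask, ref.sulcal_mask)],
                }
                for name, w in blocks.items():
                    res = topo_mod.sparsity_sweep(
                        w,
                        sparsities=config.sparsities(),
                        n_null=config.topology["n_null"],
                        seed=stage_seeds["topology"],
                    )
                    pd.DataFrame(
                        {
                            "sparsity": res.sparsities,
                            "cp": res.cp,
                            "lp": res.lp,
                            "cp_rand": res.cp_rand,
                            "lp_rand": res.lp_rand,
                            "gamma": res.gamma,
                            "lambda": res.lam,
                            "disconnected": res.disconnected.astype(int),
                        }
                    ).to_csv(out / f"topology_{name}.tsv", sep="\t", index=False)
                _done("topology", t0)
            except Exception as exc:  # noqa: BLE001
                raise PipelineError(f"stage 'topology' failed: {exc}") from exc

        if config.reliability["enabled"]:
            try:
                t0 = _stage("reliability")
                rows = []
                icc_by_block = {}
                for block in ("gg", "ss"):
                    res = rel_mod.edgewise_icc(networks, block=block)
                    icc_by_block[block] = res
                    finite = res.values[np.isfinite(res.values)]
                    rows.append(
                        {
                            "block": block,
                            "n_edges": res.n_edges,
                            "mean_icc": float(finite.mean()),
                            "median_icc": float(np.median(finite)),
                        }
                    )
                diff, p = rel_mod.compare_reliability(
                    icc_by_block["gg"].values,
                    icc_by_block["ss"].values,
                    n_perm=config.reliability["n_perm"],
                    seed=stage_seeds["reliability"],
                )
                pd.DataFrame(rows).to_csv(out / "icc_summary.tsv", sep="\t", index=False)
                manifest["reliability_contrast"] = {"gg_minus_ss": diff, "p": p}
                _done("reliability", t0)
            except Exception as exc:  # noqa: BLE001
                raise PipelineError(f"stage 'reliability' failed: {exc}") from exc

        if config.association["enabled"]:
            try:
                t0 = _stage("association")
                sim = assoc.subject_similarity_matrix(session0, block="gsgs")
                items = simulate_behavior(
                    sim.m,
                    n_items=config.association["n_items"],
                    v_true=config.association["v_true"],
                    seed=stage_seeds["behavior"],
                )
                domain_map = {
                    col: f"domain{(i % config.association['n_domains']) + 1}"
                    for i, col in enumerate(items.columns)
                }
                behavior = assoc.standardize_and_aggregate(items, domain_map)
                behavior.domains.to_csv(out / "behavior_domains.tsv", sep="\t", index=False)
                records = []
                for j, dom in enumerate(behavior.domains.columns):
                    y = behavior.domains[dom].to_numpy()[:, None]
                    est = assoc.estimate_variance_explained(y, sim.m)
                    p = assoc.permutation_pvalue_V(
                        y,
                        sim.m,
                        n_perm=config.association["n_perm"],
                        seed=stage_seeds["behavior"] + j + 1,
                    )
                    records.append({"domain": dom, "V": est.v, "p": p})
                table = pd.DataFrame(records)
                sig, adj = assoc.bh_fdr(
                    table["p"].to_numpy(), q=config.association["q"]
                )
                table["q_value"] = adj
                table["significant"] = sig
                table.to_csv(out / "association.tsv", sep="\t", index=False)
                _done("association", t0)
            except Exception as exc:  # noqa: BLE001
                raise PipelineError(f"stage 'association' failed: {exc}") from exc

        if config.groups["enabled"]:
            try:
                t0 = _stage("groups")
                records = []
                for block, square in (
                    ("gsgs", True), ("gg", True), ("ss", True), ("gs", False),
                ):
                    per_subject = np.array(
                        [
                            rel_mod.block_edge_vector(net, block).mean()
                            for net in session0
                        ]
                    )
                    res = groups_mod.permutation_group_test(
                        per_subject,
                        cohort.groups,
                        covariates=cohort.covariates[["age", "sex"]].to_numpy(float),
                        n_perm=config.groups["n_perm"],
                        seed=stage_seeds["groups"],
                    )
                    records.append(
                        {
                            "block": block,
                            "statistic": res.statistic,
                            "p": res.p,
                            "direction": res.direction,
                        }
                    )
                pd.DataFrame(records).to_csv(
                    out / "group_comparison.tsv", sep="\t", index=False
                )
                _done("groups", t0)
            except Exception as exc:  # noqa: BLE001
                raise PipelineError(f"stage 'groups' failed: {exc}") from exc

        captured = [str(w.message) for w in wlist]

    manifest["warnings"] = captured
    for path in sorted(out.rglob("*.tsv")):
        manifest["outputs"][str(path.relative_to(out))] = _sha256(path)
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest
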