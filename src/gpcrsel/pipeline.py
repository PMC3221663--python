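"""End-to-end orchestration: alignment -> admission -> tree -> model fits ->
LRTs -> omega profiles -> random cohorts -> diversity, per subgroup.

Stages write their outputs under ``outdir/sg_<id>/`` and are skipped on
re-runs when their outputs already exist (unless forced). A run manifest
records the config snapshot, per-stage status, seeds, and output paths so
every reported number is traceable to a stage file. Failure in one subgroup
does not abort the others.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .codon_alignment import (
    build_codon_alignment,
    classify_subgroup,
    load_position_map,
    load_subgroups,
    read_cds_fasta,
    read_protein_alignment,
)
from .diversity import diversity_profile, diversity_vs_selection
from .pairwise_rates import pairwise_rate_table, subgroup_admission
from .phylogeny import nj_tree, read_newick, write_newick
from .selection_profiles import (
    category_comparison,
    cohort_null,
    profile_table,
    site_omega_profile,
    trend_report,
)
from .site_models import fit_nested_pair, fixed_sites_fit, neb_site_report

DEFAULTS = {
    "alpha": 0.05,
    "freq_scheme": "F3x4",
    "branch_mode": "optimize",
    "n_restarts": 2,
    "n_cohorts": 200,
    "cohort_size": 10,
    "fs_df": 1,
    "distance_model": "JTT-ML",
    "seed": 1,
}

TESTS = {
    "test1": ("M1a", "M2a", 2),
    "test2": ("M7", "M8", 2),
    "test4": ("M0", "M3", 4),
}


class ConfigError(ValueError):
    pass


@dataclass
class RunManifest:
    config: dict
    version: str = __version__
    stages: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    failures: dict = field(default_factory=dict)

    def record(self, subgroup: str, stage: str, status: str, path: str | None = None):
        self.stages.setdefault(subgroup, {})[stage] = status
        if path:
            self.outputs.setdefault(subgroup, {})[stage] = str(path)

    def to_json(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, default=str))

    @property
    def ok(self) -> bool:
        return not self.failures


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    if "subgroups" not in cfg or not cfg["subgroups"]:
        raise ConfigError("config needs a non-empty 'subgroups' list")
    if "outdir" not in cfg:
        raise ConfigError("config needs 'outdir'")
    for sg in cfg["subgroups"]:
        for key in ("id", "protein_fasta", "cds_fasta", "position_map"):
            if key not in sg:
                raise ConfigError(f"subgroup entry missing {key!r}")
        for key in ("protein_fasta", "cds_fasta", "position_map"):
            if not Path(sg[key]).exists():
                raise ConfigError(f"missing input file {sg[key]}")
    merged = {**DEFAULTS, **cfg}
    return merged


def _stage_done(path: Path, force: bool) -> bool:
    return path.exists() and not force


def run_subgroup(sg_cfg: dict, cfg: dict, manifest: RunManifest, force: bool = False) -> dict:
    """All stages for one subgroup; returns the per-subgroup summary row."""
    sg_id = str(sg_cfg["id"])
    outdir = Path(cfg["outdir"]) / f"sg_{sg_id}"
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    alpha = float(cfg["alpha"])

    protein = read_protein_alignment(sg_cfg["protein_fasta"])
    cds = read_cds_fasta(sg_cfg["cds_fasta"])
    alignment = build_codon_alignment(protein, cds)
    pos_map = load_position_map(sg_cfg["position_map"])
    key_columns = pos_map.key_columns
    manifest.record(sg_id, "alignment", "ok")

    # admission
    admission_path = outdir / "admission.json"
    if _stage_done(admission_path, force):
        admission = json.loads(admission_path.read_text())
        manifest.record(sg_id, "admission", "skipped", admission_path)
    else:
        table = pairwise_rate_table(alignment)
        report = subgroup_admission(table)
        admission = report.to_dict()
        pd.DataFrame(table.dN, index=table.labels, columns=table.labels).to_csv(
            outdir / "dN.tsv", sep="\t"
        )
        pd.DataFrame(table.dS, index=table.labels, columns=table.labels).to_csv(
            outdir / "dS.tsv", sep="\t"
        )
        admission_path.write_text(json.dumps(admission, indent=2))
        manifest.record(sg_id, "admission", "ok", admission_path)
    retained = admission["retained_labels"]
    if len(retained) < len(alignment.labels):
        alignment = alignment.subset(retained)
        protein = alignment.to_protein()

    # tree
    tree_path = outdir / "tree.nwk"
    if _stage_done(tree_path, force):
        tree = read_newick(tree_path)
        manifest.record(sg_id, "tree", "skipped", tree_path)
    else:
        tree = nj_tree(alignment.to_protein(), model=cfg["distance_model"])
        write_newick(tree, tree_path)
        manifest.record(sg_id, "tree", "ok", tree_path)

    # model fits + LRTs
    fits_path = outdir / "fits.json"
    profile_path = outdir / "site_profile.tsv"
    if _stage_done(fits_path, force) and _stage_done(profile_path, force):
        fits_info = json.loads(fits_path.read_text())
        site_df = pd.read_csv(profile_path, sep="\t")
        manifest.record(sg_id, "fits", "skipped", fits_path)
    else:
        fit_kwargs = dict(
            freq_scheme=cfg["freq_scheme"],
            n_restarts=int(cfg["n_restarts"]),
            seed=seed,
        )
        branch_mode = cfg["branch_mode"]
        fits = {}
        lrts = {}
        if branch_mode == "fixed-at-m0":
            from .site_models import fit_model

            m0 = fit_model(alignment, tree, "M0", branch_mode="optimize", **fit_kwargs)
            from .phylogeny import Tree

            tree = Tree.from_newick(m0.tree_newick)
            fit_kwargs["branch_mode"] = "fixed"
            fits["M0"] = m0
        for test, (null_id, alt_id, df) in TESTS.items():
            if null_id in fits:
                null_fit = fits[null_id]
                from .site_models import fit_model

                alt_fit = fit_model(alignment, tree, alt_id, **fit_kwargs)
                from .site_models import likelihood_ratio_test

                lrt = likelihood_ratio_test(
                    null_fit.lnl,
                    max(alt_fit.lnl, null_fit.lnl),
                    df=df,
                    alpha=alpha,
                    null_model=null_id,
                    alt_model=alt_id,
                )
            else:
                null_fit, alt_fit, lrt = fit_nested_pair(
                    alignment, tree, null_id, alt_id, df=df, alpha=alpha, **fit_kwargs
                )
            fits[null_id] = null_fit
            fits[alt_id] = alt_fit
            lrts[test] = lrt.to_dict()
        fs_a, fs_b, fs_lrt = fixed_sites_fit(
            alignment,
            tree,
            key_columns,
            freq_scheme=cfg["freq_scheme"],
            branch_mode="optimize" if branch_mode == "optimize" else "fixed",
            df=int(cfg["fs_df"]),
            alpha=alpha,
            seed=seed,
        )
        fits["FS-A"], fits["FS-B"] = fs_a, fs_b
        lrts["test3"] = fs_lrt.to_dict()

        fits_info = {
            "models": {mid: f.to_dict() for mid, f in fits.items()},
            "lrts": lrts,
            "df_convention": {"test1": 2, "test2": 2, "test3": int(cfg["fs_df"]), "test4": 4},
        }
        fits_path.write_text(json.dumps(fits_info, indent=2))

        # per-site report: M8 profile when Test 2 rejects, else M7
        profile_model = "M8" if lrts["test2"]["tenable_model"] == "M8" else "M7"
        site_df = neb_site_report(fits[profile_model], pos_map)
        site_df["profile_model"] = profile_model
        for mid in ("M7", "M8"):
            site_df[f"neb_omega_{mid}"] = fits[mid].neb_omega
            site_df[f"p_positive_{mid}"] = fits[mid].posterior_positive()
        site_df.to_csv(profile_path, sep="\t", index=False)
        manifest.record(sg_id, "fits", "ok", fits_path)
    manifest.record(sg_id, "lrt", "ok", fits_path)

    # cohorts
    cohorts_path = outdir / "cohorts.json"
    profile_model = site_df["profile_model"].iloc[0]
    profile = site_df[f"neb_omega_{profile_model}"].to_numpy(dtype=float)
    if _stage_done(cohorts_path, force):
        cohorts = json.loads(cohorts_path.read_text())
        manifest.record(sg_id, "cohorts", "skipped", cohorts_path)
    else:
        comparison = cohort_null(
            profile,
            key_columns,
            n_cohorts=int(cfg["n_cohorts"]),
            cohort_size=int(cfg["cohort_size"]),
            seed=seed,
            subgroup_id=sg_id,
        )
        cohorts = comparison.to_dict()
        cohorts["random_means"] = comparison.random_means.tolist()
        cohorts_path.write_text(json.dumps(cohorts, indent=2))
        manifest.record(sg_id, "cohorts", "ok", cohorts_path)

    # diversity
    diversity_path = outdir / "diversity.json"
    if _stage_done(diversity_path, force):
        diversity = json.loads(diversity_path.read_text())
        manifest.record(sg_id, "diversity", "skipped", diversity_path)
    else:
        dp = diversity_profile(protein, key_columns)
        diversity = {
            "entropy_key_mean": dp["entropy_key_mean"],
            "blo80_key_mean": dp["blo80_key_mean"],
            "D_key": dp["D_key"],
            "neg_log10_D_key": None
            if not np.isfinite(dp["neg_log10_D_key"])
            else dp["neg_log10_D_key"],
        }
        diversity_path.write_text(json.dumps(diversity, indent=2))
        manifest.record(sg_id, "diversity", "ok", diversity_path)

    category = sg_cfg.get("category", "")
    if not category and sg_cfg.get("subgroup_table"):
        subgroups = load_subgroups(sg_cfg["subgroup_table"])
        if sg_id in subgroups:
            category = classify_subgroup(subgroups[sg_id])

    return {
        "subgroup_id": sg_id,
        "category": category,
        "omega_key_mean": cohorts["omega_key_mean"],
        "random_mean": cohorts["random_mean"],
        "random_sd": cohorts["random_sd"],
        "z_offset": cohorts["z_offset"],
        "outside_2sigma": cohorts["outside_2sigma"],
        "ratio": cohorts["ratio"],
        "omega_gt_0.1": cohorts["omega_gt_0.1"],
        "admission_flags": ",".join(admission["flags"]),
        "entropy_key_mean": diversity["entropy_key_mean"],
        "blo80_key_mean": diversity["blo80_key_mean"],
        "neg_log10_D_key": diversity["neg_log10_D_key"],
        "profile_model": profile_model,
        "lrts": fits_info["lrts"],
    }


def run_pipeline(config_path: str | Path, force: bool = False, seed: int | None = None) -> RunManifest:
    """Execute every stage for every configured subgroup."""
    cfg = load_config(config_path)
    if seed is not None:
        cfg["seed"] = int(seed)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config={k: v for k, v in cfg.items()})
    rows = []
    for sg_cfg in cfg["subgroups"]:
        sg_id = str(sg_cfg["id"])
        try:
            rows.append(run_subgroup(sg_cfg, cfg, manifest, force=force))
        except Exception as exc:  # noqa: BLE001 - stage isolation by design
            manifest.failures[sg_id] = f"{type(exc).__name__}: {exc}"
            manifest.record(sg_id, "failed", str(exc))
    if rows:
        summary = pd.DataFrame(
            [{k: v for k, v in r.items() if k != "lrts"} for r in rows]
        )
        summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)
        analysis = {}
        by_cat: dict[str, list[float]] = {}
        for r in rows:
            if r["category"]:
                by_cat.setdefault(r["category"], []).append(r["omega_key_mean"])
        if len([v for v in by_cat.values() if len(v) >= 2]) >= 2:
            analysis["category_comparison"] = category_comparison(by_cat)
        (outdir / "analysis.json").write_text(json.dumps(analysis, indent=2))
    manifest.to_json(outdir / "manifest.json")
    return manifest
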