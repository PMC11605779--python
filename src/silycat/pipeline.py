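"""End-to-end orchestration: simulate/load → filter → annotate → kinetics →
metabolome statistics → ecology → integration, with a provenance manifest.

Every stage is a pure function of (inputs, config); the manifest records the
effective value of every parameter, the seed, package versions and the
SHA-256 of each written report, so re-running a config reproduces the run
bit-for-bit for the deterministic stages and stream-for-stream for the
seeded ones.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import annotate_catabolites, annotation_table, filter_treatment_features
from .ecology import alpha_diversity_contrast, bray_curtis_matrix, permanova, shannon, simpson
from .integration import (
    DEFAULT_KEEPX,
    clr_transform,
    edge_table,
    fit_block_component,
    group_contrast_taxa,
    relevance_network,
)
from .kinetics import feature_kinetics
from .metabolome_stats import effect_table
from .synthetic_data import CohortDesign, SimulatedCohort, simulate_cohort

__all__ = ["RunConfig", "run_all", "load_table", "load_meta"]


@dataclass
class RunConfig:
    """Parameters of one pipeline run; every field lands in the manifest."""

    outdir: str = "silycat_run"
    seed: int = 0
    simulate: bool = True
    features_path: str | None = None
    meta_path: str | None = None
    metabolites_path: str | None = None
    taxa_genus_path: str | None = None
    taxa_meta_path: str | None = None
    alpha: float = 0.05
    mz_tolerance_da: float = 0.005
    reaction_max_steps: int = 2
    detection_threshold: float = 0.0
    n_permutations: int = 9999
    keepx: dict = field(default_factory=lambda: dict(DEFAULT_KEEPX))
    network_cutoff: float = 0.6
    network_method: str = "similarity"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def load_table(path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, index_col=0)


def load_meta(path) -> pd.DataFrame:
    meta = load_table(path)
    required = {"donor", "arm", "timepoint"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata lacks columns: {sorted(missing)}")
    return meta


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.6g")


def run_all(config: RunConfig) -> dict:
    """Run the whole analysis; returns a report bundle (paths + key results)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulate:
        cohort = simulate_cohort(CohortDesign(seed=config.seed))
        features, meta = cohort.features, cohort.meta
        metabolites = cohort.metabolites
        taxa_genus, taxa_meta = cohort.taxa_genus, cohort.taxa_meta
    else:
        if not (config.features_path and config.meta_path):
            raise FileNotFoundError("features_path and meta_path are required")
        features = load_table(config.features_path)
        meta = load_meta(config.meta_path)
        metabolites = (
            load_table(config.metabolites_path) if config.metabolites_path else None
        )
        taxa_genus = (
            load_table(config.taxa_genus_path) if config.taxa_genus_path else None
        )
        taxa_meta = load_meta(config.taxa_meta_path) if config.taxa_meta_path else None
        cohort = None

    results: dict = {"warnings": []}
    empty_input = features.drop(columns=["mz", "rt"], errors="ignore").empty

    # ---- treatment-response filter + annotation
    if empty_input:
        warnings.warn("empty feature table: emitting empty reports", UserWarning)
        results["warnings"].append("empty feature table")
        retained, per_tp = [], {}
        catabolites, parent_hits = [], {}
        filter_log = pd.DataFrame(columns=["timepoint", "features_in", "retained"])
    else:
        filt = filter_treatment_features(features, meta, alpha=config.alpha)
        retained, per_tp = filt["retained"], filt["per_timepoint"]
        filter_log = pd.DataFrame(
            [
                {"timepoint": t, "features_in": len(features), "retained": len(ids)}
                for t, ids in per_tp.items()
            ]
        )
        catabolites, parent_hits = annotate_catabolites(
            features,
            retained,
            max_steps=config.reaction_max_steps,
            tolerance_da=config.mz_tolerance_da,
        )

    # ---- kinetics on the catabolite features
    cat_ids = [c.feature_id for c in catabolites]
    if cat_ids:
        kin = feature_kinetics(
            features.loc[cat_ids],
            meta,
            arm="treatment",
            detection_threshold=config.detection_threshold,
        )
        for c in catabolites:
            c.relative_auc = float(kin.loc[c.feature_id, "relative_auc_pct"])
            c.kinetic_class = str(kin.loc[c.feature_id, "kinetic_class"])
    else:
        kin = pd.DataFrame()

    catabolite_report = annotation_table(catabolites)
    parent_report = _parent_report(features, meta, parent_hits)

    # ---- metabolome effect statistics
    if metabolites is not None and not metabolites.empty:
        effects = effect_table(metabolites, meta)
    else:
        effects = pd.DataFrame()

    # ---- ecology: alpha diversity contrast at 24 h + PERMANOVA (age) on
    # catabolite AUC profiles
    ecology_summary: dict = {}
    if taxa_genus is not None and taxa_meta is not None and len(taxa_genus):
        ecology_summary["alpha_diversity"] = _alpha_contrasts(taxa_genus, taxa_meta)
    if cat_ids and parent_hits and "age_group" in meta.columns:
        auc_cols = [c for c in kin.columns if c.startswith("auc_")]
        donor_auc = kin[auc_cols].T
        donor_auc.index = [c[len("auc_") :] for c in auc_cols]
        group = meta.drop_duplicates("donor").set_index("donor")["age_group"]
        if group.nunique() == 2:
            res = permanova(
                bray_curtis_matrix(donor_auc),
                group.loc[donor_auc.index],
                n_permutations=config.n_permutations,
                seed=config.seed,
            )
            ecology_summary["permanova_age"] = {
                "pseudo_F": res.pseudo_f,
                "R2": res.r_squared,
                "p": res.p,
                "n_permutations": res.n_permutations,
            }

    # ---- integration
    edges = pd.DataFrame()
    taxa_contrast = pd.DataFrame()
    if (
        taxa_genus is not None
        and taxa_meta is not None
        and cat_ids
        and parent_hits
        and "age_group" in meta.columns
    ):
        blocks, groups = _build_blocks(kin, parent_hits, features, meta, taxa_genus, taxa_meta)
        keepx = {
            b: min(config.keepx.get(b, X.shape[1]), X.shape[1])
            for b, X in blocks.items()
        }
        model = fit_block_component(blocks, groups, keepx=keepx, seed=config.seed)
        edges = edge_table(
            relevance_network(
                model, blocks, cutoff=config.network_cutoff, method=config.network_method
            )
        )
        tax24 = _treatment_24h(taxa_genus, taxa_meta)
        taxa_contrast = group_contrast_taxa(
            tax24.T, _donor_groups(taxa_meta, tax24.columns)
        )
        results["block_model"] = model

    # ---- write reports + manifest
    paths = {
        "parents": out / "parents.tsv",
        "catabolites": out / "catabolites.tsv",
        "metabolite_effects": out / "metabolite_effects.tsv",
        "filter_log": out / "filter_log.tsv",
        "network_edges": out / "network_edges.tsv",
        "taxa_contrast": out / "taxa_contrast.tsv",
        "ecology": out / "ecology.json",
        "manifest": out / "manifest.json",
    }
    _write(parent_report, paths["parents"])
    _write(catabolite_report, paths["catabolites"])
    _write(effects, paths["metabolite_effects"])
    _write(filter_log, paths["filter_log"])
    _write(edges, paths["network_edges"])
    _write(taxa_contrast, paths["taxa_contrast"])
    paths["ecology"].write_text(json.dumps(ecology_summary, indent=2, sort_keys=True))

    manifest = {
        "package": "silycat",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": asdict(config),
        "n_features_in": int(len(features)),
        "n_retained": len(retained),
        "n_parents": len(parent_hits),
        "n_catabolites": len(cat_ids),
        "outputs": {},
    }
    for name, p in paths.items():
        if name != "manifest" and p.exists():
            manifest["outputs"][name] = _sha256(p)
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))

    results.update(
        {
            "paths": {k: str(v) for k, v in paths.items()},
            "parents": parent_report,
            "catabolites": catabolite_report,
            "metabolite_effects": effects,
            "ecology": ecology_summary,
            "edges": edges,
            "taxa_contrast": taxa_contrast,
            "manifest": manifest,
            "cohort": cohort,
        }
    )
    return results


def _parent_report(features, meta, parent_hits) -> pd.DataFrame:
    """Parent assignments with relative % in the mixture from t = 0 treatment
    intensities (MS peak-area convention)."""
    if not parent_hits:
        return pd.DataFrame(columns=["feature_id", "parent", "mz", "rt", "relative_pct"])
    t0_wells = meta[(meta["arm"] == "treatment") & (meta["timepoint"] == 0)].index
    t0_wells = [w for w in t0_wells if w in features.columns]
    rows = []
    for fid, pname in parent_hits.items():
        mean0 = float(features.loc[fid, t0_wells].mean()) if t0_wells else np.nan
        rows.append(
            {
                "feature_id": fid,
                "parent": pname,
                "mz": features.loc[fid, "mz"],
                "rt": features.loc[fid, "rt"],
                "intensity_t0": mean0,
            }
        )
    df = pd.DataFrame(rows)
    total = df["intensity_t0"].sum()
    df["relative_pct"] = 100.0 * df["intensity_t0"] / total if total > 0 else np.nan
    return df.sort_values("relative_pct", ascending=False).reset_index(drop=True)


def _alpha_contrasts(taxa_genus, taxa_meta) -> dict:
    """Paired treatment-vs-control Shannon/Simpson contrasts at 24 h."""
    sel = taxa_meta[taxa_meta["timepoint"] == 24.0]
    donors = sorted(sel["donor"].unique())
    out = {}
    for index_name, fn in (("shannon", shannon), ("simpson", simpson)):
        trt, ctl = [], []
        for d in donors:
            tw = sel[(sel["donor"] == d) & (sel["arm"] == "treatment")].index
            cw = sel[(sel["donor"] == d) & (sel["arm"] == "control")].index
            if len(tw) == 1 and len(cw) == 1:
                trt.append(fn(taxa_genus[tw[0]]))
                ctl.append(fn(taxa_genus[cw[0]]))
        if len(trt) >= 2:
            t_stat, p = alpha_diversity_contrast(trt, ctl)
            out[index_name] = {
                "treatment_mean": float(np.mean(trt)),
                "control_mean": float(np.mean(ctl)),
                "t": t_stat,
                "p": p,
                "n": len(trt),
            }
    return out


def _treatment_24h(taxa_genus, taxa_meta) -> pd.DataFrame:
    sel = taxa_meta[(taxa_meta["arm"] == "treatment") & (taxa_meta["timepoint"] == 24.0)]
    cols = [s for s in sel.index if s in taxa_genus.columns]
    return taxa_genus[cols]


def _donor_groups(taxa_meta, samples) -> list:
    return [taxa_meta.loc[s, "age_group"] for s in samples]


def _build_blocks(kin, parent_hits, features, meta, taxa_genus, taxa_meta):
    """Assemble the clr-taxa / parent-AUC / catabolite-AUC blocks on a shared
    donor axis, plus the per-donor age-group labels."""
    tax24 = _treatment_24h(taxa_genus, taxa_meta)
    donor_of = {s: taxa_meta.loc[s, "donor"] for s in tax24.columns}
    tax = tax24.T
    tax.index = [donor_of[s] for s in tax.index]

    auc_cols = [c for c in kin.columns if c.startswith("auc_")]
    cat = kin[auc_cols].T
    cat.index = [c[len("auc_") :] for c in auc_cols]

    par_kin = feature_kinetics(features.loc[list(parent_hits)], meta, arm="treatment")
    pcols = [c for c in par_kin.columns if c.startswith("auc_")]
    par = par_kin[pcols].T
    par.index = [c[len("auc_") :] for c in pcols]

    donors = [d for d in cat.index if d in tax.index and d in par.index]
    blocks = {
        "taxa": clr_transform(tax.loc[donors], pseudocount=1.0),
        "parents": par.loc[donors],
        "catabolites": cat.loc[donors],
    }
    group_map = meta.drop_duplicates("donor").set_index("donor")["age_group"]
    return blocks, list(group_map.loc[donors])
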