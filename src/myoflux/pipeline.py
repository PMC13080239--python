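"""End-to-end pipeline driver: instantiate -> capacities -> statistics.

Each stage writes TSV tables under the output directory; a manifest
(config hash, seed, versions, collected warnings) makes the run
reproducible.  The stats stage can be re-run from cached capacity tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .capacity import (
    BUILTIN_PROFILES,
    RampConfig,
    TitrationConfig,
    atp_load_scan,
    individualized_scan,
    substrate_capacity,
    whole_heart_capacity,
    SUBSTRATE_CLASSES,
)
from .instantiate import EnzymeMapping, ProteinAbundanceMatrix, instantiate_cohort
from .io import (
    RunConfig,
    read_abundance,
    read_metadata,
    read_plasma_panels,
    read_profiles,
    read_protein_list,
    write_manifest,
    write_table,
)
from .network import NetworkModel, build_reference_model, load_default_model
from .stats import (
    compare_groups,
    correlation_ledger,
    marker_regression,
    pathway_score,
    pca,
    score_capacity_regression,
    volcano,
    zscore_cluster,
)
from .synthetic import CAPACITY_PATHWAYS

logger = logging.getLogger(__name__)


@dataclass
class ReportBundle:
    outdir: Path
    tables: dict[str, Path] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def _load_inputs(config: RunConfig):
    model = (
        build_reference_model(config.model) if config.model else load_default_model()
    )
    metadata = read_metadata(config.metadata) if config.metadata else None
    matrix = read_abundance(config.matrix, metadata)
    plasma = read_plasma_panels(config.plasma) if config.plasma else None
    mapping = (
        EnzymeMapping.from_tsv(config.mapping)
        if config.mapping
        else EnzymeMapping.from_model(model)
    )
    profiles = read_profiles(config.profile_config)
    return model, mapping, matrix, metadata, plasma, profiles


def compute_capacity_table(
    instances,
    metadata: pd.DataFrame | None,
    plasma: pd.DataFrame | None,
    profiles,
    titration: TitrationConfig | None = None,
    ramp: RampConfig | None = None,
) -> pd.DataFrame:
    """Per-sample capacity panel as a flat table (mM/min/g; whole-heart in
    mM/min per heart)."""
    rows = []
    for inst in instances:
        row: dict[str, float] = {}
        fasted = profiles.get("fasted", BUILTIN_PROFILES["fasted"])
        for s in SUBSTRATE_CLASSES:
            row[f"cap_{s}"] = substrate_capacity(inst, s, fasted, titration)
        for label, prof in profiles.items():
            scan = atp_load_scan(inst, prof, ramp)
            row[f"max_atp_{label}"] = scan.max_atp
            row[f"atp_o2_{label}"] = scan.atp_o2_at_max
        if plasma is not None and inst.sample_id in plasma.index:
            panel = plasma.loc[inst.sample_id].to_dict()
            scan = individualized_scan(inst, panel, fasted, ramp)
            row["max_atp_individualized"] = scan.max_atp
            row["atp_o2_individualized"] = scan.atp_o2_at_max
        if metadata is not None and inst.sample_id in metadata.index:
            hw = metadata.loc[inst.sample_id].get("heart_weight_mg", np.nan)
            if np.isfinite(hw) and hw > 0:
                row["whole_heart_max_atp"] = whole_heart_capacity(
                    row["max_atp_fasted"], float(hw)
                )
        row["n_missing"] = inst.n_missing
        rows.append(pd.Series(row, name=inst.sample_id))
    return pd.DataFrame(rows)


def run_stats_stage(
    config: RunConfig,
    matrix: ProteinAbundanceMatrix,
    metadata: pd.DataFrame | None,
    plasma: pd.DataFrame | None,
    capacities: pd.DataFrame,
    model: NetworkModel,
    outdir: Path,
    bundle: ReportBundle,
) -> None:
    groups = sorted({g for g in matrix.group.values() if g != config.control_group})
    mapped = sorted({p for r in model.reactions for p in r.proteins})
    metabolic = [
        p for p in matrix.proteins if p in mapped or str(p).startswith("MET")
    ]

    # volcano: whole proteome and metabolic subset, per group vs control
    vol_rows = []
    for g in groups:
        for subset_name, subset in (("all", None), ("metabolic", metabolic or None)):
            v = volcano(
                matrix,
                config.control_group,
                g,
                subset=subset,
                fc_low=config.fc_low,
                fc_high=config.fc_high,
                alpha=config.alpha,
            )
            out = v.table.copy()
            out.insert(0, "group", g)
            out.insert(1, "subset", subset_name)
            vol_rows.append(out)
            bundle.summary.setdefault("volcano", {})[f"{g}/{subset_name}"] = {
                "fraction_up": v.fraction_up,
                "fraction_down": v.fraction_down,
                "n_tested": v.n_tested,
            }
    if vol_rows:
        vt = pd.concat(vol_rows)
        vt.index.name = "protein"
        path = outdir / "volcano.tsv"
        write_table(vt, path, units="log2 fold change; two-sided p")
        bundle.tables["volcano"] = path

    # group tests on capacities
    test_rows = []
    for col in capacities.columns:
        if col == "n_missing":
            continue
        ctrl = capacities.loc[
            [s for s in capacities.index if matrix.group.get(s) == config.control_group],
            col,
        ]
        for g in groups:
            vals = capacities.loc[
                [s for s in capacities.index if matrix.group.get(s) == g], col
            ]
            if len(ctrl) < 3 or len(vals) < 3:
                continue
            res = compare_groups(ctrl, vals, config.alpha, config.alpha_norm)
            test_rows.append(
                {
                    "feature": col,
                    "group": g,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "test_used": res.test_used,
                }
            )
    if test_rows:
        tt = pd.DataFrame(test_rows).set_index("feature")
        path = outdir / "group_tests.tsv"
        write_table(tt, path, units="test statistic; two-sided p")
        bundle.tables["group_tests"] = path

    # marker regression per capacity class
    marker_rows = []
    pathway_proteins = {
        cap: sorted(
            {
                p
                for r in model.reactions
                if r.pathway in tags
                for p in r.proteins
            }
        )
        for cap, tags in CAPACITY_PATHWAYS.items()
    }
    cap_col = {
        "glucose": "cap_glucose",
        "ffa": "cap_ffa",
        "lactate": "cap_lactate",
        "ketones": "cap_ketones",
        "bcaa": "cap_bcaa",
        "atp": "max_atp_fasted",
    }
    for cap, prots in pathway_proteins.items():
        col = cap_col[cap]
        if col not in capacities.columns or not prots:
            continue
        res = marker_regression(
            capacities[col], matrix, prots, alpha=config.alpha, pathway=cap
        )
        out = res.table.copy()
        out.insert(0, "pathway", cap)
        marker_rows.append(out)
        bundle.summary.setdefault("markers", {})[cap] = {
            "n_significant": res.n_significant,
            "n_total": res.n_total,
        }
    if marker_rows:
        mt = pd.concat(marker_rows)
        path = outdir / "marker_regression.tsv"
        write_table(mt, path, units="OLS slope; R^2; two-sided p")
        bundle.tables["marker_regression"] = path

    # pathway shares (collagen / inflammation) and share-capacity regression
    set_lists = {}
    for name, cfg_path, prefix in (
        ("collagen", getattr(config, "collagen_list", None), "COL"),
        ("inflammation", getattr(config, "inflammation_list", None), "INFL"),
    ):
        if cfg_path:
            set_lists[name] = read_protein_list(cfg_path)
        else:
            set_lists[name] = [p for p in matrix.proteins if str(p).startswith(prefix)]
    score_tables = []
    for name, prots in set_lists.items():
        if not prots:
            continue
        score = pathway_score(matrix, prots)
        score.name = f"{name}_share"
        score_tables.append(score)
        reg = score_capacity_regression(
            score, capacities.drop(columns=["n_missing"], errors="ignore"), config.alpha
        )
        path = outdir / f"{name}_capacity_regression.tsv"
        write_table(reg, path, units="OLS slope; R^2; two-sided p")
        bundle.tables[f"{name}_capacity_regression"] = path
        bundle.summary.setdefault("pathway_scores", {})[name] = {
            "mean_share": float(score.mean())
        }
    if score_tables:
        st = pd.concat(score_tables, axis=1)
        path = outdir / "pathway_scores.tsv"
        write_table(st, path, units="share of total intensity")
        bundle.tables["pathway_scores"] = path

    # correlation ledger: capacities x plasma x masses x echo
    feats = capacities.drop(columns=["n_missing"], errors="ignore").copy()
    provenance = {c: "model-derived" for c in feats.columns}
    if plasma is not None:
        for c in plasma.columns:
            feats[f"plasma_{c}"] = plasma[c]
            provenance[f"plasma_{c}"] = "measured"
    if metadata is not None:
        for c in metadata.columns:
            if c == "group":
                continue
            feats[c] = pd.to_numeric(metadata[c], errors="coerce")
            provenance[c] = "measured"
    if len(feats) >= 4:
        ledger = correlation_ledger(feats, alpha=config.alpha, provenance=provenance)
        path = outdir / "correlation_r.tsv"
        write_table(ledger.r, path, units="Pearson r")
        bundle.tables["correlation_r"] = path
        path = outdir / "correlation_signed.tsv"
        write_table(ledger.signed, path, units="-1/0/+1 at p<alpha")
        bundle.tables["correlation_signed"] = path
        bundle.summary["correlation"] = {
            "n_features": int(ledger.r.shape[0]),
            "n_significant_pairs": int(ledger.mask.to_numpy().sum() // 2),
        }

    # PCA + clustering of metabolic proteins
    if len(metabolic) >= 2 and len(matrix.samples) >= 3:
        p = pca(matrix, subset=metabolic)
        path = outdir / "pca_scores.tsv"
        write_table(p.scores, path, units="PC scores (z-scored intensities)")
        bundle.tables["pca_scores"] = path
        bundle.summary["pca"] = {
            "explained_variance_ratio": [
                float(x) for x in p.explained_variance_ratio
            ]
        }
        cl = zscore_cluster(matrix, subset=metabolic)
        order = pd.DataFrame(
            {"sample": cl.col_order, "position": range(len(cl.col_order))}
        ).set_index("sample")
        path = outdir / "cluster_sample_order.tsv"
        write_table(order, path, units="dendrogram leaf order")
        bundle.tables["cluster_sample_order"] = path


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the configured stages and write the report bundle."""
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(outdir=outdir)
    model, mapping, matrix, metadata, plasma, profiles = _load_inputs(config)

    cap_path = outdir / "capacities.tsv"
    if config.run_capacities:
        instances = instantiate_cohort(model, mapping, matrix, config.control_group)
        capacities = compute_capacity_table(instances, metadata, plasma, profiles)
        write_table(capacities, cap_path, units="mM ATP/min/g; whole-heart mM/min")
        bundle.tables["capacities"] = cap_path
    elif cap_path.exists():
        capacities = pd.read_csv(cap_path, sep="\t", index_col=0, comment="#")
        logger.info("stats-only rerun: capacities loaded from %s", cap_path)
    else:
        raise FileNotFoundError(
            f"run_capacities=False but no cached table at {cap_path}"
        )

    if config.run_stats:
        run_stats_stage(
            config, matrix, metadata, plasma, capacities, model, outdir, bundle
        )

    summary_path = outdir / "summary.json"
    summary_path.write_text(json.dumps(bundle.summary, indent=2, sort_keys=True) + "\n")
    bundle.tables["summary"] = summary_path
    write_manifest(config, outdir, bundle.warnings)
    return bundle
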