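"""End-to-end pipeline: simulate -> preprocess -> BMD -> discovery -> correlation.

Writes a run directory with one subfolder per stage, all tables as TSV, and
a machine-readable manifest (config echo, seed, per-stage feature counts
whose containment always reconciles: features in >= viable models >=
endogenous subset >= annotated subset).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .chem import MassShiftLibrary, formula_mass
from .config import PipelineConfig
from .containers import FeatureTable
from .design import DEFAULT_DESIGN, DoseDesign
from .preprocessing import (QcFilterThresholds, glog_transform, knn_impute,
                            optimize_lambda, pca_overview, pqn_normalize,
                            qc_filter)
from .synthetic import generate_study
from .workflow import (accumulation_data, combine_assays, lowest_bmd_report,
                       results_frame, run_two_pass, summarize)
from .xeno import discover, study_floor
from .correlation import correlate

log = logging.getLogger("metabmd")


def preprocess_table(table: FeatureTable, cfg: PipelineConfig,
                     is_nmr: bool | None = None):
    """QC filter -> PQN -> kNN imputation for one assay table.

    Returns (model-ready table, PQN coefficients, QC report).  NMR tables
    (no blanks, optionally no QC rules) disable the blank rule
    automatically.
    """
    pc = cfg.preprocess
    if is_nmr is None:
        is_nmr = len(table.sample_ids("blank")) == 0
    th = QcFilterThresholds(pc.qc_presence_min, pc.qc_rsd_max,
                            pc.blank_ratio_max, pc.study_presence_min)
    rules = (pc.apply_qc_rules, pc.apply_qc_rules,
             pc.apply_qc_rules and not is_nmr, True)
    filtered, report = qc_filter(table, th, rules=rules)
    normalized, coeffs = pqn_normalize(filtered, reference_mode=pc.pqn_reference)
    imputed = knn_impute(normalized, k=pc.knn_k)
    return imputed, coeffs, report


def run_pipeline(config: PipelineConfig, outdir,
                 design: DoseDesign = DEFAULT_DESIGN) -> Path:
    """Execute the full pipeline into ``outdir``; returns the run directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "stages": {},
    }
    stage = "simulate"
    try:
        tables, genes, truth = generate_study(design, config.simulate,
                                              seed=config.seed)
        sim_dir = out / "simulate"
        sim_dir.mkdir(exist_ok=True)
        for t in tables:
            slug = t.assay.replace(" ", "_")
            t.to_tsv(sim_dir / f"features_{slug}.tsv",
                     sim_dir / f"samples_{slug}.tsv")
        genes.to_csv(sim_dir / "genes.tsv", sep="\t")
        truth.to_tsv(sim_dir / "ground_truth.tsv")
        manifest["stages"]["simulate"] = {
            "n_assays": len(tables),
            "n_features": {t.assay: t.n_features for t in tables},
        }
        log.info("simulate: %d assays", len(tables))

        stage = "preprocess"
        pre_dir = out / "preprocess"
        pre_dir.mkdir(exist_ok=True)
        nmr_label = config.simulate.nmr_assay
        floor = study_floor([t for t in tables if t.assay != nmr_label])
        processed, coeffs_by_assay = [], {}
        for t in tables:
            imputed, coeffs, report = preprocess_table(
                t, config, is_nmr=(t.assay == nmr_label))
            slug = t.assay.replace(" ", "_")
            imputed.to_tsv(pre_dir / f"features_{slug}.tsv",
                           pre_dir / f"samples_{slug}.tsv")
            report.table.to_csv(pre_dir / f"qc_report_{slug}.tsv", sep="\t")
            try:
                lam = optimize_lambda(imputed)
                scores, ev = pca_overview(glog_transform(imputed, lam))
                scores.to_csv(pre_dir / f"pca_scores_{slug}.tsv", sep="\t")
                ev.to_csv(pre_dir / f"pca_variance_{slug}.tsv", sep="\t")
            except ValueError:
                pass
            processed.append(imputed)
            coeffs_by_assay[t.assay] = coeffs
            log.info("preprocess %s: %d -> %d features", t.assay,
                     t.n_features, imputed.n_features)
        manifest["stages"]["preprocess"] = {
            t.assay: p.n_features for t, p in zip(tables, processed)}

        stage = "bmd"
        bmd_dir = out / "bmd"
        bmd_dir.mkdir(exist_ok=True)
        per_assay = [run_two_pass(p, design, config.bmd) for p in processed]
        combined = combine_assays(per_assay, [design] * len(per_assay))
        frame = results_frame(combined)
        frame.to_csv(bmd_dir / "feature_results.tsv", sep="\t", index=False)
        accumulation_data(combined).to_csv(bmd_dir / "accumulation.tsv",
                                           sep="\t", index=False)
        summarize(combined).to_csv(bmd_dir / "class_summary.tsv", sep="\t",
                                   index=False)
        n_viable = int(frame["passed"].sum())
        log.info("bmd: %d/%d features with viable models", n_viable, len(frame))

        stage = "xeno"
        xeno_dir = out / "xeno"
        xeno_dir.mkdir(exist_ok=True)
        parent_mass = formula_mass(config.xeno.parent_formula)
        library = MassShiftLibrary()
        library.to_tsv(xeno_dir / "mass_shift_library.tsv")
        xeno_ids: set[str] = set()
        reps_frames, groups_frames = [], []
        for t in tables:
            if t.assay == nmr_label:
                continue
            res = discover(
                t, design, parent_mass,
                pqn_coefficients=coeffs_by_assay[t.assay], floor=floor,
                library=library, fc_factor=config.xeno.fold_change_factor,
                slope_range=(config.xeno.slope_min, config.xeno.slope_max),
                rt_tolerance_s=config.xeno.rt_tolerance_s,
                corr_threshold=config.xeno.corr_threshold,
                ppm_tolerance=config.xeno.ppm_tolerance)
            xeno_ids.update(res.filtered.intensities.index)
            if len(res.compounds):
                # the distinct annotated compounds (parent + each
                # biotransformation) carry forward to the correlation stage
                reps = res.compounds.copy()
                reps["assay"] = t.assay
                reps["_levels"] = [
                    res.filtered.intensities.loc[fid,
                                                 res.filtered.sample_ids("study")]
                    for fid in reps["feature_id"]]
                reps_frames.append(reps)
            if len(res.groups):
                g = res.groups.copy()
                g["assay"] = t.assay
                groups_frames.append(g.reset_index())
        reps_all = (pd.concat(reps_frames, ignore_index=True)
                    if reps_frames else pd.DataFrame(
                        columns=["group_id", "feature_id", "annotation",
                                 "ppm_error", "median_intensity", "assay",
                                 "_levels"]))
        reps_all.drop(columns=["_levels"]).to_csv(
            xeno_dir / "representatives.tsv", sep="\t", index=False)
        if groups_frames:
            pd.concat(groups_frames, ignore_index=True).to_csv(
                xeno_dir / "groups.tsv", sep="\t", index=False)
        log.info("xeno: %d features retained, %d representatives",
                 len(xeno_ids), len(reps_all))

        stage = "correlate"
        corr_dir = out / "correlate"
        corr_dir.mkdir(exist_ok=True)
        corr_summary = None
        if len(reps_all):
            feat_levels = pd.DataFrame(
                {r["feature_id"]: r["_levels"] for _, r in reps_all.iterrows()}).T
            corr = correlate(feat_levels, genes,
                             p_cutoff=config.correlation.p_cutoff,
                             strong_cutoff=config.correlation.strong_cutoff)
            corr.summary.to_csv(corr_dir / "gene_summary.tsv", sep="\t")
            corr.rho.to_csv(corr_dir / "rho_matrix.tsv", sep="\t")
            corr.p.to_csv(corr_dir / "p_matrix.tsv", sep="\t")
            corr_summary = corr

        # Table-1-style containment counts: features in >= viable >=
        # endogenous (non-xenobiotic) subset >= annotated subset
        viable_ids = set(frame.loc[frame["passed"], "feature_id"])
        endo_ids = viable_ids - xeno_ids
        annotated_ids = {fid for fid in endo_ids
                         if frame.set_index("feature_id").loc[fid, "lipid_class"]
                         not in ("", "nan")} if "lipid_class" in frame else set()
        manifest["stages"]["bmd"] = {
            "features_in": int(len(frame)),
            "viable_models": len(viable_ids),
            "endogenous_subset": len(endo_ids),
            "annotated_subset": len(annotated_ids),
            "lowest_bmd": lowest_bmd_report(combined, design),
            "censoring_cutoff_mg_per_kg": design.censoring_cutoff,
        }
        manifest["stages"]["xeno"] = {
            "features_retained": len(xeno_ids),
            "representatives": int(len(reps_all)),
        }
        if corr_summary is not None:
            s = corr_summary.summary
            manifest["stages"]["correlate"] = {
                "n_genes": int(len(s)),
                "pct_strong": float(100.0 * s["strong"].mean()),
                "pct_all_features_significant": float(
                    100.0 * (s["n_significant_features"]
                             == corr_summary.rho.shape[1]).mean()),
            }
    except Exception as exc:  # partial outputs retained on disk
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out
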