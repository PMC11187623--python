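"""Two-pass benchmark-dose analysis over whole feature tables.

Pass 1 ("prefilter") fits all seven model families to every feature at a
BMR of 3 residual SDs, selects the best model by AIC and applies the three
post-filters (BMD below the highest tested dose, BMD/BMDL ratio below 20,
lack-of-fit p above 1e-4).  Only the surviving features are re-evaluated at
the final BMR of 1 SD, with identical settings, and post-filtered again.
Survivors across assays are then combined, BMDs below the lower limit of
extrapolation (lowest tested dose / 3) are censored for reporting, and
accumulation-plot and per-class summary outputs are produced.

The maximum-likelihood fit of each family does not depend on the BMR — only
the derived BMD/BMDL/BMDU do — so the engine fits each feature once and
recomputes the benchmark quantities per pass, which is exactly equivalent to
refitting with the same settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import FeatureTable
from .design import DoseDesign
from . import models as M


@dataclass
class BmdSettings:
    """Engine settings; defaults are the standard continuous-BMDS choices."""

    bmr_prefilter_sd: float = 3.0
    bmr_final_sd: float = 1.0
    max_iterations: int = 250
    confidence_level: float = 0.95
    selection_p_cutoff: float = 0.05
    postfilter_bmd_bmdl_ratio_max: float = 20.0
    postfilter_fit_p_min: float = 1e-4
    families: tuple[str, ...] = M.FAMILIES


@dataclass
class FeatureBmdResult:
    """Fate of one feature through the two-pass analysis."""

    feature_id: str
    assay: str
    pass1_best: M.ModelFit | None = None
    pass1_ok: bool = False
    pass1_reasons: list[str] = field(default_factory=list)
    best: M.ModelFit | None = None       # final (1 SD) best model
    passed_postfilters: bool = False
    postfilter_reasons: list[str] = field(default_factory=list)
    censored: bool = False
    reported_bmd: str = ""
    annotation: str = ""
    lipid_class: str = ""

    @property
    def survived(self) -> bool:
        return self.passed_postfilters


def apply_postfilters(fit: M.ModelFit | None, highest_dose: float,
                      settings: BmdSettings | None = None
                      ) -> tuple[bool, list[str]]:
    """The three post-filters, strict inequalities.

    best BMD < highest dose; best BMD/BMDL < 20; best fit p-value > 0.0001.
    Undefined quantities fail with an explicit reason.
    """
    s = settings or BmdSettings()
    reasons: list[str] = []
    if fit is None:
        return False, ["no viable model"]
    if fit.bmd is None:
        reasons.append("BMD undefined")
    elif not fit.bmd < highest_dose:
        reasons.append("BMD >= highest dose")
    if fit.bmdl is None:
        reasons.append(f"BMDL undefined ({fit.bmdl_reason or 'no reason'})")
    elif fit.bmd is not None and fit.bmdl > 0 and \
            not fit.bmd / fit.bmdl < s.postfilter_bmd_bmdl_ratio_max:
        reasons.append("BMD/BMDL ratio >= 20")
    if fit.fit_p_value is None:
        reasons.append("fit p-value undefined")
    elif not fit.fit_p_value > s.postfilter_fit_p_min:
        reasons.append("fit p-value <= 0.0001")
    return (len(reasons) == 0), reasons


def _evaluate_at_bmr(fits: list[M.ModelFit], y, d, design: DoseDesign,
                     bmr: float, settings: BmdSettings,
                     sides: tuple[str, ...] = ("lower", "upper")
                     ) -> M.ModelFit | None:
    """Attach BMD at the given BMR, select the best model, profile its CI."""
    import copy

    staged = []
    for f in fits:
        g = copy.deepcopy(f)
        M.compute_bmd(g, bmr, design.highest_dose)
        staged.append(g)
    best = M.select_best_model(staged, design.lowest_nonzero_dose,
                               p_screen=settings.selection_p_cutoff)
    if best is None:
        return None
    M.profile_bmdl_bmdu(best, y, d, confidence=settings.confidence_level,
                        max_dose=design.highest_dose, sides=sides)
    return best


def run_feature(values, doses, design: DoseDesign,
                settings: BmdSettings | None = None,
                feature_id: str = "", assay: str = "") -> FeatureBmdResult:
    """Two-pass analysis of a single feature."""
    s = settings or BmdSettings()
    res = FeatureBmdResult(feature_id=feature_id, assay=assay)
    y = np.asarray(values, dtype=float)
    d = np.asarray(doses, dtype=float)
    fits = M.fit_all_models(y, d, max_iter=s.max_iterations, families=s.families)
    for f in fits:
        if f.converged:
            M.fit_p_value(f, y, d)

    # the prefilter's post-filters use BMD, BMDL and p only; BMDU is not needed
    best1 = _evaluate_at_bmr(fits, y, d, design, s.bmr_prefilter_sd, s,
                             sides=("lower",))
    res.pass1_best = best1
    ok1, reasons1 = apply_postfilters(best1, design.highest_dose, s)
    res.pass1_ok, res.pass1_reasons = ok1, reasons1
    if not ok1:
        return res

    best2 = _evaluate_at_bmr(fits, y, d, design, s.bmr_final_sd, s)
    res.best = best2
    ok2, reasons2 = apply_postfilters(best2, design.highest_dose, s)
    res.passed_postfilters, res.postfilter_reasons = ok2, reasons2
    return res


def run_two_pass(table: FeatureTable, design: DoseDesign,
                 settings: BmdSettings | None = None) -> list[FeatureBmdResult]:
    """Two-pass BMD analysis of every feature in a preprocessed table.

    Expects a normalized, imputed table (no missing study values).  Returns
    one result per input feature, with the censoring field filled in.
    """
    s = settings or BmdSettings()
    study_ids = table.sample_ids("study")
    doses = table.samples.loc[study_ids, "dose_mg_per_kg"].to_numpy(dtype=float)
    results = []
    annot_cols = [c for c in ("annotation", "lipid_class")
                  if c in table.features.columns]
    for fid in table.intensities.index:
        y = table.intensities.loc[fid, study_ids].to_numpy(dtype=float)
        r = run_feature(y, doses, design, s, feature_id=str(fid),
                        assay=str(table.features.loc[fid, "assay"]))
        for c in annot_cols:
            val = table.features.loc[fid, c]
            setattr(r, c, "" if pd.isna(val) else str(val))
        results.append(r)
    return censor_low_bmds(results, design)


def censor_low_bmds(results: list[FeatureBmdResult],
                    design: DoseDesign) -> list[FeatureBmdResult]:
    """Report BMDs below (lowest nonzero dose)/3 as "< cutoff".

    The numeric value is retained on the fit; only the reporting field
    changes.  A BMD exactly at the cutoff is not censored.
    """
    cutoff = design.censoring_cutoff
    for r in results:
        if r.best is not None and r.best.bmd is not None:
            r.censored = bool(r.best.bmd < cutoff)
            r.reported_bmd = f"<{cutoff:g}" if r.censored else f"{r.best.bmd:.6g}"
        else:
            r.censored = False
            r.reported_bmd = ""
    return results


def combine_assays(per_assay: list[list[FeatureBmdResult]],
                   designs: list[DoseDesign] | None = None
                   ) -> list[FeatureBmdResult]:
    """Concatenate per-assay result lists, preserving assay provenance."""
    if designs is not None and len(set(designs)) > 1:
        raise ValueError("assays were run under conflicting dose designs")
    combined: list[FeatureBmdResult] = []
    for results in per_assay:
        combined.extend(results)
    return combined


def results_frame(results: list[FeatureBmdResult]) -> pd.DataFrame:
    """Flat per-feature table of the final-pass outcome."""
    rows = []
    for r in results:
        b = r.best
        rows.append({
            "feature_id": r.feature_id, "assay": r.assay,
            "best_model": b.family if b else "",
            "bmd": b.bmd if b else np.nan,
            "bmdl": b.bmdl if b else np.nan,
            "bmdu": b.bmdu if b else np.nan,
            "fit_p": b.fit_p_value if b else np.nan,
            "aic": b.aic if b else np.nan,
            "passed": r.passed_postfilters,
            "censored": r.censored,
            "reported_bmd": r.reported_bmd,
            "annotation": r.annotation,
            "lipid_class": r.lipid_class,
        })
    return pd.DataFrame(rows)


def accumulation_data(results: list[FeatureBmdResult]) -> pd.DataFrame:
    """Sorted (rank, BMD) pairs over surviving features — accumulation plot."""
    bmds = sorted(r.best.bmd for r in results
                  if r.passed_postfilters and r.best and r.best.bmd is not None)
    return pd.DataFrame({"rank": np.arange(1, len(bmds) + 1), "bmd": bmds})


def summarize(results: list[FeatureBmdResult], grouping: str = "lipid_class"
              ) -> pd.DataFrame:
    """Per-group median BMD and BMDL over annotated survivors.

    Medians use the uncensored numeric values; the censoring token is a
    reporting convention only.
    """
    rows = []
    for r in results:
        if not r.passed_postfilters or r.best is None or r.best.bmd is None:
            continue
        g = getattr(r, grouping, "")
        if not g:
            continue
        rows.append({"group": g, "bmd": r.best.bmd, "bmdl": r.best.bmdl})
    if not rows:
        return pd.DataFrame(columns=["group", "n", "median_bmd", "median_bmdl"])
    df = pd.DataFrame(rows)
    out = df.groupby("group").agg(
        n=("bmd", "size"), median_bmd=("bmd", "median"),
        median_bmdl=("bmdl", "median")).reset_index()
    return out.sort_values("median_bmd").reset_index(drop=True)


def lowest_bmd_report(results: list[FeatureBmdResult],
                      design: DoseDesign) -> dict:
    """Most sensitive surviving BMD with the censoring convention applied."""
    surv = [(r.best.bmd, r.feature_id) for r in results
            if r.passed_postfilters and r.best and r.best.bmd is not None]
    if not surv:
        return {"reported": "", "actual": np.nan, "feature_id": ""}
    bmd, fid = min(surv)
    cutoff = design.censoring_cutoff
    reported = f"<{cutoff:g} (actual lowest BMD value = {bmd:.3g})" \
        if bmd < cutoff else f"{bmd:.4g}"
    return {"reported": reported, "actual": bmd, "feature_id": fid}
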