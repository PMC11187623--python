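"""Discovery of exposure-chemical-related features (parent + biotransformation products).

Implements the two-step screen that separates xenobiotic-related features
from the endogenous metabolome, the structural-missingness imputation rule
for vehicle controls, ion-form grouping by retention time / intensity
correlation / accurate-mass spacing, biotransformation annotation against a
mass-shift library, and the reduction of each ion-form group to a single
representative feature.

The two-step screen:

1. fold-change filter — median intensity in the highest dose group at least
   ``fc_factor`` times the control-group median (missing values count as 0;
   a zero control median with nonzero top signal is an infinite fold change
   and is retained: structural absence in controls is the defining signature
   of a xenobiotic);
2. dose-response filter — ordinary least squares of the feature scaled by
   its top-dose median against dose scaled by the highest dose; an ideal
   dose-proportional compound has slope exactly 1, and slopes within
   ``slope_range`` (inclusive) are retained.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .chem import (ISOTOPOLOGUE_SPACING, MassShiftLibrary, adducts_for_polarity,
                   ppm_error)
from .containers import FeatureTable
from .design import DoseDesign
from .preprocessing import knn_impute


# ----------------------------------------------------------------------
# two-step filter
# ----------------------------------------------------------------------
def two_step_filter(table: FeatureTable, design: DoseDesign,
                    fc_factor: float = 10.0,
                    slope_range: tuple[float, float] = (0.5, 1.5)
                    ) -> tuple[FeatureTable, pd.DataFrame]:
    """Retain putative xenobiotic-related features from a raw feature table.

    Returns the retained sub-table and a per-feature statistics frame
    (fold_change, normalized_slope, per-rule outcomes) covering every input
    feature.  Requires >= 2 control and >= 2 highest-dose study samples.
    """
    study_ids = table.sample_ids("study")
    doses = table.samples.loc[study_ids, "dose_mg_per_kg"].to_numpy(float)
    if (doses > 0).sum() == 0:
        raise ValueError("no nonzero dose groups")
    top = design.highest_dose
    ctrl_ids = [s for s, d in zip(study_ids, doses) if d == 0]
    top_ids = [s for s, d in zip(study_ids, doses) if d == top]
    if len(ctrl_ids) < 2 or len(top_ids) < 2:
        raise ValueError("need >= 2 control and >= 2 highest-dose samples")

    X = table.intensities[study_ids].to_numpy(float)
    X0 = np.nan_to_num(X, nan=0.0)  # missing = non-detected = 0 signal
    ctrl_idx = [study_ids.index(s) for s in ctrl_ids]
    top_idx = [study_ids.index(s) for s in top_ids]

    med_ctrl = np.median(X0[:, ctrl_idx], axis=1)
    med_top = np.median(X0[:, top_idx], axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(med_ctrl > 0, med_top / med_ctrl,
                      np.where(med_top > 0, np.inf, 0.0))
    pass_fc = fc >= fc_factor

    x = doses / top
    slopes = np.full(X.shape[0], np.nan)
    ok = med_top > 0
    ys = X0[ok] / med_top[ok, None]
    xc = x - x.mean()
    slopes[ok] = (ys - ys.mean(axis=1, keepdims=True)) @ xc / (xc @ xc)
    pass_slope = (slopes >= slope_range[0]) & (slopes <= slope_range[1])

    retained = pass_fc & pass_slope
    stats = pd.DataFrame({
        "fold_change": fc, "pass_fold_change": pass_fc,
        "normalized_slope": slopes, "pass_slope": pass_slope,
        "retained": retained,
    }, index=table.intensities.index)
    return table.subset_features(table.intensities.index[retained]), stats


# ----------------------------------------------------------------------
# structural-missingness imputation
# ----------------------------------------------------------------------
def impute_xeno_matrix(table: FeatureTable, study_floor: float,
                       k: int = 5) -> FeatureTable:
    """Impute the xenobiotic-feature matrix.

    Missing values in vehicle-control samples — where the compound is
    structurally absent — are set to half the lowest intensity observed in
    the whole study (``study_floor``); missing values in dosed samples are
    filled by feature-wise kNN as in preprocessing.
    """
    if study_floor <= 0:
        raise ValueError("study_floor must be > 0")
    out = table.copy()
    study_ids = out.sample_ids("study")
    doses = out.samples.loc[study_ids, "dose_mg_per_kg"]
    ctrl_ids = [s for s in study_ids if doses[s] == 0]
    block = out.intensities[ctrl_ids]
    out.intensities[ctrl_ids] = block.where(block.notna(), study_floor / 2.0)
    if out.intensities.isna().to_numpy().any():
        out = knn_impute(out, k=k)
    return out


def study_floor(tables: list[FeatureTable]) -> float:
    """Lowest detected intensity across all features of all given tables."""
    lo = np.inf
    for t in tables:
        vals = t.intensities.to_numpy(float)
        pos = vals[np.isfinite(vals) & (vals > 0)]
        if pos.size:
            lo = min(lo, float(pos.min()))
    if not np.isfinite(lo):
        raise ValueError("no detected intensities in the study")
    return lo


# ----------------------------------------------------------------------
# ion-form grouping
# ----------------------------------------------------------------------
def group_features(table: FeatureTable, rt_tolerance_s: float = 5.0,
                   corr_threshold: float = 0.7, ppm_tolerance: float = 5.0
                   ) -> pd.DataFrame:
    """Group co-eluting, co-varying features and annotate their ion forms.

    Two features connect when |delta RT| <= ``rt_tolerance_s`` AND the
    Pearson correlation of their intensities across study samples exceeds
    ``corr_threshold``; connected components form groups.  Within a group,
    each feature's m/z is tested against neutral-mass + adduct (+ optional
    isotopologue spacing) hypotheses; the assignment explaining the most
    members fixes the group's neutral mass.  Groups whose best assignments
    tie on incompatible neutral masses are left unlabeled with an ambiguity
    flag.
    """
    fids = list(table.intensities.index)
    rt = table.features["rt_seconds"].to_numpy(float)
    mz = table.features["mz"].to_numpy(float)
    study_ids = table.sample_ids("study")
    X = table.intensities[study_ids].to_numpy(float)

    G = nx.Graph()
    G.add_nodes_from(range(len(fids)))
    with np.errstate(invalid="ignore"):
        C = np.corrcoef(X)
    for i in range(len(fids)):
        for j in range(i + 1, len(fids)):
            if abs(rt[i] - rt[j]) <= rt_tolerance_s and C[i, j] > corr_threshold:
                G.add_edge(i, j)

    polarity = "negative" if "negative" in str(table.assay).lower() else "positive"
    adducts = adducts_for_polarity(polarity)
    rows = []
    comps = sorted(nx.connected_components(G), key=lambda c: min(fids[i] for i in c))
    for gid, comp in enumerate(comps, start=1):
        members = sorted(comp, key=lambda i: fids[i])
        # hypothesis search: anchors tried lightest-first, adducts in
        # priority order, so the protonated/deprotonated reading of the
        # lowest-mass member wins when several hypotheses explain the whole
        # series equally well (the usual single-adduct underdetermination)
        best = None
        for anchor in sorted(members, key=lambda i: mz[i]):
            for ad in adducts:
                M = mz[anchor] - ad.mass_offset
                if M <= 0:
                    continue
                labels = {}
                for m in members:
                    for ad2 in adducts:
                        for j_iso in (0, 1, 2):
                            pred = M + ad2.mass_offset + j_iso * ISOTOPOLOGUE_SPACING
                            if abs(ppm_error(mz[m], pred)) <= ppm_tolerance:
                                lab = ad2.name + (f" +{j_iso}" if j_iso else "")
                                labels[m] = (lab, pred)
                                break
                        if m in labels:
                            break
                score = len(labels)
                if best is None or score > best[0]:
                    best = (score, M, labels)
        score, M, labels = best if best else (0, np.nan, {})
        if score == 0:
            for m in members:
                rows.append({"feature_id": fids[m], "group_id": gid,
                             "ion_form": "", "neutral_mass": np.nan,
                             "ambiguous": True})
            continue
        # refine the neutral mass over the explained members
        est = [mz[m] - (labels[m][1] - M) for m in labels]
        M_ref = float(np.mean(est))
        for m in members:
            rows.append({"feature_id": fids[m], "group_id": gid,
                         "ion_form": labels.get(m, ("", np.nan))[0],
                         "neutral_mass": M_ref, "ambiguous": False})
    return pd.DataFrame(rows).set_index("feature_id")


# ----------------------------------------------------------------------
# biotransformation annotation
# ----------------------------------------------------------------------
def enumerate_candidates(parent_mass: float, library: MassShiftLibrary,
                         max_chain: int = 2) -> list[tuple[tuple[str, ...], float]]:
    """All parent +/- chains of up to ``max_chain`` library shifts.

    The identity chain (the parent itself) is included.  Chains are emitted
    shortest first so exact-mass ties resolve to the simpler annotation.
    """
    cands: list[tuple[tuple[str, ...], float]] = [((), parent_mass)]
    shifts = list(library)
    for s in shifts:
        cands.append(((s.name,), parent_mass + s.mass_delta))
    for s1, s2 in itertools.combinations_with_replacement(shifts, 2):
        cands.append(((s1.name, s2.name), parent_mass + s1.mass_delta + s2.mass_delta))
    return cands


def annotate_btp(groups: pd.DataFrame, parent_mass: float,
                 library: MassShiftLibrary | None = None,
                 ppm_tolerance: float = 5.0, max_chain: int = 2) -> pd.DataFrame:
    """Match each group's neutral mass against biotransformation candidates.

    Candidates are the parent mass plus chains of up to ``max_chain`` library
    shifts; the closest candidate within ``ppm_tolerance`` wins (shorter
    chains preferred on ties).  Unmatched groups are annotated "unknown".
    """
    lib = library or MassShiftLibrary()
    cands = enumerate_candidates(parent_mass, lib, max_chain=max_chain)
    rows = []
    for gid, sub in groups.groupby("group_id"):
        M = sub["neutral_mass"].dropna()
        M = float(M.iloc[0]) if len(M) else np.nan
        ann, err, chain_len = "unknown", np.nan, np.inf
        if np.isfinite(M):
            best = None
            for chain, mass in cands:
                e = ppm_error(M, mass)
                if abs(e) <= ppm_tolerance:
                    key = (len(chain), abs(e))
                    if best is None or key < best[0]:
                        best = (key, chain, e)
            if best is not None:
                _, chain, e = best
                ann = "+".join(chain) if chain else "parent"
                err = e
        rows.append({"group_id": gid, "annotation": ann, "ppm_error": err,
                     "neutral_mass": M})
    return pd.DataFrame(rows).set_index("group_id")


# ----------------------------------------------------------------------
# representative selection
# ----------------------------------------------------------------------
def select_representative(group_members: pd.DataFrame) -> str:
    """Pick one representative feature per ion-form group.

    Hard filters: experimental MS/MS measured and retention time > 30 s
    (outside the solvent front).  Survivors rank by fragment-match fraction
    (desc) then median study intensity (desc); feature_id breaks exact ties
    deterministically.  If the hard filters empty the group, ranking falls
    back to intensity over all members.
    """
    if group_members.empty:
        raise ValueError("group is empty")
    df = group_members
    hard = df[(df["has_msms"].astype(bool)) & (df["rt_seconds"] > 30.0)]
    pool = hard if not hard.empty else df
    pool = pool.sort_values(
        by=["msms_fragment_match_fraction", "median_intensity", "feature_id"],
        ascending=[False, False, True])
    return str(pool.iloc[0]["feature_id"])


# ----------------------------------------------------------------------
# end-to-end discovery
# ----------------------------------------------------------------------
@dataclass
class XenoDiscoveryResult:
    filtered: FeatureTable
    stats: pd.DataFrame
    groups: pd.DataFrame
    annotations: pd.DataFrame
    representatives: pd.DataFrame  # one row per group: feature, annotation
    compounds: pd.DataFrame = None  # one row per distinct annotated compound


def discover(table: FeatureTable, design: DoseDesign, parent_mass: float,
             pqn_coefficients: pd.Series | None = None,
             floor: float | None = None,
             library: MassShiftLibrary | None = None,
             fc_factor: float = 10.0,
             slope_range: tuple[float, float] = (0.5, 1.5),
             rt_tolerance_s: float = 5.0, corr_threshold: float = 0.7,
             ppm_tolerance: float = 5.0) -> XenoDiscoveryResult:
    """Full discovery pipeline for one LC-MS assay.

    two-step filter -> PQN with coefficients carried over from the
    endogenous matrix -> structural/kNN imputation -> ion-form grouping ->
    biotransformation annotation -> representative selection.
    """
    from .preprocessing import apply_coefficients

    filtered, stats = two_step_filter(table, design, fc_factor, slope_range)
    work = filtered
    if pqn_coefficients is not None and len(filtered.intensities):
        work = apply_coefficients(work, pqn_coefficients)
    if floor is None:
        floor = study_floor([table])
        if pqn_coefficients is not None:
            floor = floor / float(pqn_coefficients.max())
    if len(work.intensities):
        work = impute_xeno_matrix(work, floor)
        groups = group_features(work, rt_tolerance_s, corr_threshold, ppm_tolerance)
        annotations = annotate_btp(groups, parent_mass, library, ppm_tolerance)
    else:
        groups = pd.DataFrame(columns=["group_id", "ion_form", "neutral_mass",
                                       "ambiguous"])
        annotations = pd.DataFrame(columns=["annotation", "ppm_error",
                                            "neutral_mass"])

    reps = []
    study_ids = work.sample_ids("study") if len(work.intensities) else []
    for gid, sub in groups.groupby("group_id"):
        members = pd.DataFrame({
            "feature_id": sub.index,
            "rt_seconds": work.features.loc[sub.index, "rt_seconds"].to_numpy(float),
            "has_msms": work.features.loc[sub.index].get(
                "has_msms", pd.Series(False, index=sub.index)).to_numpy(),
            "msms_fragment_match_fraction": work.features.loc[sub.index].get(
                "msms_fragment_match_fraction",
                pd.Series(0.0, index=sub.index)).to_numpy(float),
            "median_intensity": work.intensities.loc[sub.index, study_ids]
                .median(axis=1).to_numpy(float),
        })
        rep = select_representative(members)
        reps.append({"group_id": gid, "feature_id": rep,
                     "annotation": annotations.loc[gid, "annotation"],
                     "ppm_error": annotations.loc[gid, "ppm_error"],
                     "median_intensity": float(
                         work.intensities.loc[rep, study_ids].median())})
    representatives = pd.DataFrame(reps)
    # one representative per distinct annotated compound (parent + each
    # biotransformation); the most intense group wins when several groups
    # carry the same annotation
    if len(representatives):
        annotated = representatives[representatives["annotation"] != "unknown"]
        compounds = (annotated.sort_values("median_intensity", ascending=False)
                     .drop_duplicates("annotation")
                     .sort_values("annotation").reset_index(drop=True))
    else:
        compounds = pd.DataFrame(columns=["group_id", "feature_id",
                                          "annotation", "ppm_error",
                                          "median_intensity"])
    return XenoDiscoveryResult(filtered=work, stats=stats, groups=groups,
                               annotations=annotations,
                               representatives=representatives,
                               compounds=compounds)
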