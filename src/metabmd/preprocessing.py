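"""Feature quality filtering, normalization, imputation and transformation.

The cascade applied to each assay's feature table before dose-response
modeling:

1. four-rule QC filter on raw peak areas (QC presence > 90%, QC RSD < 30%,
   blank:QC ratio < 5%, study presence > 50%),
2. probabilistic quotient normalization (PQN) against a median reference
   profile, to correct per-sample dilution,
3. k-nearest-neighbour imputation of remaining missing values (k = 5,
   feature-wise neighbours),
4. generalized-log transform y = ln((x + sqrt(x^2 + lambda)) / 2) with
   lambda optimized to stabilize QC variances, used for PCA overviews.

"Present" throughout means non-missing AND > 0: a peak area of zero is a
non-detection in deconvolution output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.decomposition import PCA

from .containers import FeatureTable


@dataclass(frozen=True)
class QcFilterThresholds:
    """The four quality rules, in the order they are reported."""

    qc_presence_min: float = 90.0   # % of QC samples, strict >
    qc_rsd_max: float = 30.0        # % RSD across QCs, strict <
    blank_ratio_max: float = 5.0    # % mean blank / mean QC, strict <
    study_presence_min: float = 50.0  # % of study samples, strict >


@dataclass
class QcFilterReport:
    """Per-feature outcome of each quality rule with its computed statistic."""

    table: pd.DataFrame  # columns: the 4 statistics, 4 pass flags, retained
    n_retained: int
    n_rejected: int


def qc_filter(table: FeatureTable,
              thresholds: QcFilterThresholds | None = None,
              rules: tuple[bool, bool, bool, bool] = (True, True, True, True),
              ) -> tuple[FeatureTable, QcFilterReport]:
    """Apply the four-rule feature quality filter on raw intensities.

    A feature is retained iff every enabled rule passes.  Rules may be
    disabled individually (NMR tables carry no blanks, so the blank rule is
    switched off for them).  Requires >= 1 QC sample while either QC rule is
    enabled.
    """
    th = thresholds or QcFilterThresholds()
    qc_ids = table.sample_ids("qc")
    blank_ids = table.sample_ids("blank")
    study_ids = table.sample_ids("study")
    if (rules[0] or rules[1]) and len(qc_ids) == 0:
        raise ValueError("QC rules enabled but the table has no QC samples; "
                         "disable them explicitly for QC-free assays")
    if rules[2] and len(blank_ids) == 0:
        raise ValueError("blank rule enabled but the table has no blank samples")

    present = table.present()
    qc = table.intensities[qc_ids]
    qc_present_frac = present[qc_ids].mean(axis=1) * 100.0 if qc_ids else pd.Series(
        np.nan, index=table.intensities.index)

    # RSD over QC injections, computed on detected values
    qc_vals = qc.where(present[qc_ids])
    qc_mean = qc_vals.mean(axis=1)
    qc_sd = qc_vals.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        qc_rsd = (qc_sd / qc_mean * 100.0).where(qc_mean > 0)

    # blank:QC ratio; a missing blank value counts as 0 signal
    if blank_ids:
        blank_mean = table.intensities[blank_ids].fillna(0.0).mean(axis=1)
    else:
        blank_mean = pd.Series(0.0, index=table.intensities.index)
    qc_mean_all = qc.fillna(0.0).mean(axis=1) if qc_ids else pd.Series(
        np.nan, index=table.intensities.index)
    with np.errstate(invalid="ignore", divide="ignore"):
        blank_ratio = (blank_mean / qc_mean_all * 100.0).where(qc_mean_all > 0,
                                                               np.inf)

    study_present_frac = present[study_ids].mean(axis=1) * 100.0

    pass1 = (qc_present_frac > th.qc_presence_min) if rules[0] else pd.Series(
        True, index=table.intensities.index)
    pass2 = (qc_rsd < th.qc_rsd_max).fillna(False) if rules[1] else pd.Series(
        True, index=table.intensities.index)
    pass3 = (blank_ratio < th.blank_ratio_max) if rules[2] else pd.Series(
        True, index=table.intensities.index)
    pass4 = (study_present_frac > th.study_presence_min) if rules[3] else pd.Series(
        True, index=table.intensities.index)
    retained = pass1 & pass2 & pass3 & pass4

    report = QcFilterReport(
        table=pd.DataFrame({
            "qc_presence_pct": qc_present_frac, "pass_qc_presence": pass1,
            "qc_rsd_pct": qc_rsd, "pass_qc_rsd": pass2,
            "blank_ratio_pct": blank_ratio, "pass_blank_ratio": pass3,
            "study_presence_pct": study_present_frac, "pass_study_presence": pass4,
            "retained": retained,
        }),
        n_retained=int(retained.sum()),
        n_rejected=int((~retained).sum()),
    )
    return table.subset_features(table.intensities.index[retained]), report


# ----------------------------------------------------------------------
# PQN
# ----------------------------------------------------------------------
def pqn_normalize(table: FeatureTable, reference_mode: str = "study",
                  min_shared: int = 10) -> tuple[FeatureTable, pd.Series]:
    """Probabilistic quotient normalization.

    The reference profile is the per-feature median over study samples (or
    over QC samples, ``reference_mode="qc"``), on detected values.  Each
    sample is divided by the median of its feature-wise quotients against
    the reference, taken over features detected in both.  Samples sharing
    fewer than ``min_shared`` features with the reference get a NaN
    coefficient and are left unscaled (flagged for the caller).
    """
    if table.intensities.shape[1] < 2:
        raise ValueError("PQN needs at least 2 samples")
    if reference_mode not in ("study", "qc"):
        raise ValueError("reference_mode must be 'study' or 'qc'")
    ref_ids = table.sample_ids(reference_mode)
    if not ref_ids:
        raise ValueError(f"no {reference_mode} samples to build the reference")
    present = table.present()
    ref = table.intensities[ref_ids].where(present[ref_ids]).median(axis=1)

    coeffs = {}
    for sid in table.intensities.columns:
        col = table.intensities[sid]
        mask = present[sid] & ref.notna() & (ref > 0)
        if int(mask.sum()) < min_shared:
            coeffs[sid] = np.nan
            continue
        coeffs[sid] = float((col[mask] / ref[mask]).median())
    coeffs = pd.Series(coeffs, name="pqn_coefficient")
    scaled = table.intensities.div(coeffs.replace(0, np.nan).fillna(1.0), axis=1)
    return table.with_intensities(scaled), coeffs


def apply_coefficients(target: FeatureTable, coefficients: pd.Series) -> FeatureTable:
    """Divide each sample column by its previously derived PQN coefficient.

    Used to carry coefficients computed on the (feature-rich) endogenous
    matrix onto the sparse xenobiotic-feature matrix of the same samples.
    """
    missing = [s for s in target.intensities.columns if s not in coefficients.index
               or pd.isna(coefficients[s])]
    if missing:
        raise ValueError(f"no PQN coefficient for sample(s): {missing}")
    scaled = target.intensities.div(coefficients[target.intensities.columns], axis=1)
    return target.with_intensities(scaled)


# ----------------------------------------------------------------------
# kNN imputation
# ----------------------------------------------------------------------
def knn_impute(table: FeatureTable, k: int = 5) -> FeatureTable:
    """Impute missing values from the k nearest neighbouring features.

    Neighbour distance is the root-mean-square difference over samples where
    both features are observed; for each missing cell the unweighted mean of
    the k nearest features observed in that sample is imputed.  Distance
    ties break by feature_id order.  A feature with no co-observed partner
    falls back to its own observed mean; a feature observed nowhere is an
    error.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = table.intensities.to_numpy(dtype=float)
    obs = ~np.isnan(X)
    if (~obs).sum() == 0:
        return table.copy()
    if (obs.sum(axis=1) == 0).any():
        bad = table.intensities.index[obs.sum(axis=1) == 0].tolist()
        raise ValueError(f"feature(s) missing in all samples, cannot impute: {bad}")

    # order features by id so argsort tie-breaks lexicographically
    order = np.argsort(table.intensities.index.to_numpy())
    rank_of = np.empty_like(order)
    rank_of[order] = np.arange(len(order))

    Xo = np.where(obs, X, 0.0)
    n_shared = obs.astype(float) @ obs.T.astype(float)
    # sum over shared samples of (xi - xj)^2, via the standard expansion
    sq = Xo * Xo
    cross = Xo @ Xo.T
    si = sq @ obs.T.astype(float)
    d2 = si + si.T - 2.0 * cross
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.sqrt(np.maximum(d2, 0.0) / n_shared)
    dist[n_shared == 0] = np.inf
    np.fill_diagonal(dist, np.inf)

    out = X.copy()
    feat_mean = np.nanmean(np.where(obs, X, np.nan), axis=1)
    miss_rows, miss_cols = np.where(~obs)
    for i, j in zip(miss_rows, miss_cols):
        cand = np.where(obs[:, j])[0]
        cand = cand[np.isfinite(dist[i, cand])]
        if cand.size == 0:
            out[i, j] = feat_mean[i]
            continue
        key = np.lexsort((rank_of[cand], dist[i, cand]))
        chosen = cand[key[:k]]
        out[i, j] = X[chosen, j].mean()
    new = pd.DataFrame(out, index=table.intensities.index,
                       columns=table.intensities.columns)
    return table.with_intensities(new)


# ----------------------------------------------------------------------
# glog
# ----------------------------------------------------------------------
def glog_transform(table: FeatureTable, lam: float) -> FeatureTable:
    """Generalized log: y = ln((x + sqrt(x^2 + lambda)) / 2), lambda > 0."""
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    X = table.intensities.to_numpy(dtype=float)
    Y = np.log((X + np.sqrt(X * X + lam)) / 2.0)
    return table.with_intensities(pd.DataFrame(
        Y, index=table.intensities.index, columns=table.intensities.columns))


def _qc_variance_spread(table: FeatureTable, lam: float, qc_ids) -> float:
    X = table.intensities[qc_ids].to_numpy(dtype=float)
    Y = np.log((X + np.sqrt(X * X + lam)) / 2.0)
    v = np.nanvar(Y, axis=1, ddof=1)
    return float(np.nanstd(v, ddof=1))


def optimize_lambda(table: FeatureTable, grid_points: int = 200,
                    lam_range: tuple[float, float] = (1e-2, 1e10)) -> float:
    """Lambda minimizing the spread of per-feature QC variances after glog.

    Coarse search over a log-spaced grid followed by golden-section
    refinement between the bracketing grid neighbours.  Needs >= 3 QC
    samples for the variance estimates to be meaningful.
    """
    qc_ids = table.sample_ids("qc")
    if len(qc_ids) < 3:
        raise ValueError("lambda optimization needs >= 3 QC samples")
    grid = np.geomspace(lam_range[0], lam_range[1], grid_points)
    vals = [_qc_variance_spread(table, lam, qc_ids) for lam in grid]
    i = int(np.nanargmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda t: _qc_variance_spread(table, float(np.exp(t)), qc_ids),
        bounds=(np.log(lo), np.log(hi)), method="bounded",
        options={"xatol": 1e-6})
    lam = float(np.exp(res.x))
    return lam if _qc_variance_spread(table, lam, qc_ids) <= vals[i] else float(grid[i])


# ----------------------------------------------------------------------
# PCA overview
# ----------------------------------------------------------------------
def pca_overview(table: FeatureTable, n_components: int = 2
                 ) -> tuple[pd.DataFrame, pd.Series]:
    """Mean-centered PCA scores per sample, for QC dashboards.

    Expects a glog-transformed, fully imputed table.  Requests beyond the
    matrix rank are truncated.
    """
    X = table.intensities.to_numpy(dtype=float).T  # samples x features
    if np.isnan(X).any():
        raise ValueError("impute before PCA")
    max_rank = min(X.shape[0], X.shape[1])
    k = min(n_components, max_rank)
    pca = PCA(n_components=k)
    scores = pca.fit_transform(X - X.mean(axis=0))
    cols = [f"PC{i + 1}" for i in range(k)]
    return (pd.DataFrame(scores, index=table.intensities.columns, columns=cols),
            pd.Series(pca.explained_variance_ratio_ * 100.0, index=cols,
                      name="explained_variance_pct"))
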