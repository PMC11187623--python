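"""The feature-table container shared by every pipeline stage.

A :class:`FeatureTable` holds a features x samples intensity matrix (NaN marks
a missing / non-detected value) together with per-feature metadata (m/z and
retention time for LC-MS assays, chemical-shift bin for NMR) and per-sample
metadata (role and dose).  It round-trips to the TSV dialect used by the CLI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SAMPLE_ROLES = ("study", "qc", "blank")

#: feature-metadata columns written before the sample columns
_FEATURE_COLS = ("feature_id", "assay", "mz", "rt_seconds", "bin_ppm")


@dataclass
class FeatureTable:
    """Feature x sample intensity matrix with metadata.

    Attributes
    ----------
    intensities
        DataFrame indexed by feature_id with one column per sample_id;
        values are non-negative peak areas, NaN where not detected.
    features
        DataFrame indexed by feature_id; columns include ``assay`` and either
        ``mz`` + ``rt_seconds`` (MS) or ``bin_ppm`` (NMR), plus any
        annotation columns (e.g. ``has_msms``, ``lipid_class``).
    samples
        DataFrame indexed by sample_id with columns ``role`` (study/qc/blank)
        and ``dose_mg_per_kg`` (NaN for qc and blank samples).
    """

    intensities: pd.DataFrame
    features: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.intensities.index.is_unique:
            raise ValueError("feature_ids must be unique")
        if not self.intensities.columns.is_unique:
            raise ValueError("sample_ids must be unique")
        if not self.intensities.index.equals(self.features.index):
            raise ValueError("intensities and feature metadata must share index")
        if list(self.intensities.columns) != list(self.samples.index):
            raise ValueError("intensities columns must match sample metadata index")
        bad_role = set(self.samples["role"]) - set(SAMPLE_ROLES)
        if bad_role:
            raise ValueError(f"unknown sample roles: {sorted(bad_role)}")
        vals = self.intensities.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("intensities must be >= 0 where present")
        study = self.samples["role"] == "study"
        if self.samples.loc[study, "dose_mg_per_kg"].isna().any():
            raise ValueError("every study sample needs a dose")

    # ------------------------------------------------------------------
    @property
    def n_features(self) -> int:
        return self.intensities.shape[0]

    @property
    def assay(self) -> str:
        """Assay label (single-assay tables only)."""
        labels = self.features["assay"].unique()
        if len(labels) != 1:
            raise ValueError("table spans multiple assays")
        return str(labels[0])

    def sample_ids(self, role: str) -> list[str]:
        return list(self.samples.index[self.samples["role"] == role])

    @property
    def study_doses(self) -> pd.Series:
        """Dose per study sample, in sample order."""
        ids = self.sample_ids("study")
        return self.samples.loc[ids, "dose_mg_per_kg"].astype(float)

    def study_matrix(self) -> pd.DataFrame:
        return self.intensities[self.sample_ids("study")]

    def qc_matrix(self) -> pd.DataFrame:
        return self.intensities[self.sample_ids("qc")]

    def blank_matrix(self) -> pd.DataFrame:
        return self.intensities[self.sample_ids("blank")]

    def present(self) -> pd.DataFrame:
        """Boolean detection mask: non-missing AND > 0."""
        return self.intensities.notna() & (self.intensities > 0)

    def subset_features(self, feature_ids) -> "FeatureTable":
        ids = list(feature_ids)
        return FeatureTable(
            intensities=self.intensities.loc[ids].copy(),
            features=self.features.loc[ids].copy(),
            samples=self.samples.copy(),
        )

    def with_intensities(self, new: pd.DataFrame) -> "FeatureTable":
        return FeatureTable(
            intensities=new, features=self.features.copy(), samples=self.samples.copy()
        )

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.intensities.copy(), self.features.copy(), self.samples.copy()
        )

    # ------------------------------------------------------------------
    # TSV dialect: feature metadata columns first, then one column per sample;
    # a companion sample-metadata TSV carries roles and doses.
    def to_tsv(self, features_path, samples_path) -> None:
        meta_cols = [c for c in _FEATURE_COLS if c in self.features.columns or c == "feature_id"]
        extra = [c for c in self.features.columns if c not in _FEATURE_COLS]
        out = self.features.reset_index()
        if "feature_id" not in out.columns:
            out = out.rename(columns={out.columns[0]: "feature_id"})
        out = out[[c for c in meta_cols if c in out.columns] + extra]
        out = pd.concat([out.reset_index(drop=True),
                         self.intensities.reset_index(drop=True)], axis=1)
        out.to_csv(features_path, sep="\t", index=False)
        smeta = self.samples.reset_index()
        smeta = smeta.rename(columns={smeta.columns[0]: "sample_id"})
        smeta.to_csv(samples_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, features_path, samples_path) -> "FeatureTable":
        raw = pd.read_csv(features_path, sep="\t")
        smeta = pd.read_csv(samples_path, sep="\t").set_index("sample_id")
        sample_ids = [c for c in raw.columns if c in smeta.index]
        meta_cols = [c for c in raw.columns if c not in sample_ids]
        features = raw[meta_cols].set_index("feature_id")
        intensities = raw[["feature_id"] + sample_ids].set_index("feature_id")
        intensities = intensities.astype(float)
        intensities.columns.name = None
        return cls(intensities=intensities, features=features,
                   samples=smeta.loc[sample_ids])
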