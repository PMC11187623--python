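import numpy as np
import pandas as pd
import pytest

from metabmd.containers import FeatureTable
from metabmd.design import DEFAULT_DESIGN
from metabmd.synthetic import GeneratorConfig, generate_study


@pytest.fixture(scope="session")
def design():
    return DEFAULT_DESIGN


@pytest.fixture(scope="session")
def small_study():
    """A compact multi-assay study with ground truth, shared across tests."""
    cfg = GeneratorConfig(n_null=30, n_responsive=12, n_contaminant=4)
    return generate_study(DEFAULT_DESIGN, cfg, seed=42)


def make_table(intensities: np.ndarray, roles: list[str],
               doses: list[float] | None = None,
               feature_ids: list[str] | None = None,
               mz: np.ndarray | None = None,
               rt: np.ndarray | None = None,
               assay: str = "HILIC positive",
               extra_feature_cols: dict | None = None) -> FeatureTable:
    """Hand-rolled FeatureTable builder for fixtures."""
    n_feat, n_samp = intensities.shape
    fids = feature_ids or [f"F{i:04d}" for i in range(n_feat)]
    sids = [f"X{i:02d}" for i in range(n_samp)]
    if doses is None:
        doses = [np.nan] * n_samp
    samples = pd.DataFrame(
        {"role": roles,
         "dose_mg_per_kg": [d if r == "study" else np.nan
                            for d, r in zip(doses, roles)]},
        index=pd.Index(sids, name="sample_id"))
    feats = pd.DataFrame({"assay": assay}, index=pd.Index(fids, name="feature_id"))
    rng = np.random.default_rng(0)
    feats["mz"] = mz if mz is not None else rng.uniform(100, 900, n_feat)
    feats["rt_seconds"] = rt if rt is not None else rng.uniform(31, 800, n_feat)
    if extra_feature_cols:
        for k, v in extra_feature_cols.items():
            feats[k] = v
    intens = pd.DataFrame(intensities, index=feats.index, columns=sids)
    return FeatureTable(intensities=intens, features=feats, samples=samples)


@pytest.fixture
def table_factory():
    return make_table
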