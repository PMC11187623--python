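"""Synthetic dose-response metabolomics studies with known ground truth.

Generates complete multi-assay studies with the statistical structure the
downstream analysis assumes: dose-responsive endogenous features drawn from
the seven continuous model shapes, null features, blank contaminants, pooled
QC injections, extraction blanks, spiked xenobiotic (exposure-chemical)
features that are structurally absent in vehicle controls and rise
proportionally with dose, and a gene-expression panel monotonically coupled
to the xenobiotic levels.  Every emitted feature carries exactly one
ground-truth record so each pipeline stage can be scored against what was
actually simulated.

The default configuration mirrors a 4-day oral-gavage rat study: doses 0,
55, 110, 220, 441 and 881 mg/kg with three animals per group (two at 441),
four LC-MS assay modes plus one NMR assay, and a parent compound (triphenyl
phosphate) spiked together with 11 distinct biotransformation products.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import (MassShiftLibrary, TPHP_FORMULA, ISOTOPOLOGUE_SPACING,
                   adducts_for_polarity, formula_mass)
from .containers import FeatureTable
from .design import DEFAULT_DESIGN, DoseDesign
from .models import bmd_from_params, mean_function

#: biotransformation chains spiked by default: the parent compound plus 11
#: distinct products (three phase I, conjugates, and sequential phase I->II)
#: cap on the top-dose fold change of unbounded (linear/power/exponential)
#: generating curves; strongly induced metabolites rarely exceed this
_MAX_FOLD = 100.0

DEFAULT_BTP_CHAINS: tuple[tuple[str, ...], ...] = (
    ("aryl loss",),
    ("hydroxylation",),
    ("dihydroxylation",),
    ("aryl loss", "hydroxylation"),
    ("glucuronidation",),
    ("sulfation",),
    ("hydroxylation", "glucuronidation"),
    ("hydroxylation", "sulfation"),
    ("glutathione conjugation",),
    ("N-acetylcysteine conjugation",),
    ("aryl loss", "glucuronidation"),
)


@dataclass
class GeneratorConfig:
    """Settings of the synthetic-study generator (per-assay feature counts,
    noise structure, xenobiotic spiking, and the coupled gene panel)."""

    ms_assays: tuple[str, ...] = ("HILIC positive", "HILIC negative",
                                  "LIPIDS positive", "LIPIDS negative")
    include_nmr: bool = True
    nmr_assay: str = "NMR"
    n_null: int = 150
    n_responsive: int = 60
    n_contaminant: int = 8
    noise_model: str = "lognormal"  # "lognormal" | "additive"
    cv_range: tuple[float, float] = (0.05, 0.15)
    qc_cv: float = 0.08
    blank_level: float = 0.005
    missing_rate: float = 0.02
    baseline_range: tuple[float, float] = (1e4, 1e7)
    true_bmd_range: tuple[float, float] = (20.0, 500.0)
    effect_sd_range: tuple[float, float] = (4.0, 10.0)
    parent_formula: str = TPHP_FORMULA
    spike_xenobiotics: bool = True
    btp_chains: tuple[tuple[str, ...], ...] = DEFAULT_BTP_CHAINS
    xeno_top_range: tuple[float, float] = (1e5, 1e7)
    iso_fraction: float = 0.2
    xeno_cv: float = 0.05
    n_genes: int = 58
    gene_coupled_fraction: float = 0.62
    gene_noise_sd: float = 0.25
    #: fraction of endogenous features in lipid assays given a class label
    annotated_fraction: float = 0.15
    lipid_classes: tuple[str, ...] = ("LPC", "PG", "SM", "TG", "PC", "PE",
                                      "PS", "PI")

    def validate(self, design: DoseDesign) -> None:
        if sum(r < 2 for r in design.replicates) > 1:
            raise ValueError(
                "fewer than 2 replicates at more than one dose: "
                "SD-based benchmark responses are undefined")
        if min(self.cv_range) < 0 or self.qc_cv < 0 or self.xeno_cv < 0:
            raise ValueError("noise SD / CV values must be >= 0")
        if self.noise_model not in ("lognormal", "additive"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if not (0 <= self.gene_coupled_fraction <= 1):
            raise ValueError("gene_coupled_fraction must be in [0, 1]")


@dataclass
class GroundTruth:
    """One record per emitted feature plus the gene-coupling map."""

    table: pd.DataFrame            # per-feature: class, family, sigma, BMD, ...
    params: dict[str, tuple[str, dict[str, float], float]]  # fid -> (family, params, sigma)
    gene_coupling: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------------
# generating-curve construction
# ----------------------------------------------------------------------
def solve_params_for_bmd(family: str, baseline: float, sigma: float,
                         true_bmd: float, effect_sd: float, direction: int,
                         shape: float = 1.5) -> dict[str, float]:
    """Generating-curve parameters with an exactly known 1-SD benchmark dose.

    Given the family's shape parameter(s) and the plateau effect size (in
    residual-SD units, for the saturating families), the scale parameter is
    solved in closed form so that |mu(true_bmd) - mu(0)| = sigma.
    """
    s = float(direction)
    if sigma <= 0 or true_bmd <= 0:
        raise ValueError("sigma and true_bmd must be positive")
    if family == "linear":
        return {"b0": baseline, "b1": s * sigma / true_bmd}
    if family == "power":
        return {"g": baseline, "beta": s * sigma / true_bmd**shape, "delta": shape}
    if family == "hill":
        if effect_sd <= 1:
            raise ValueError("hill plateau must exceed 1 SD for the BMD to exist")
        v = s * effect_sd * sigma
        k = true_bmd * (effect_sd - 1.0) ** (1.0 / shape)
        return {"g": baseline, "v": v, "n": shape, "k": k}
    if family == "exp2":
        r = sigma / baseline
        if s > 0:
            b = math.log1p(r) / true_bmd
        else:
            if r >= 1:
                raise ValueError("decreasing exp2 needs sigma < baseline")
            b = -math.log1p(-r) / true_bmd
        return {"a": baseline, "b": b, "s": s}
    if family == "exp3":
        r = sigma / baseline
        arg = math.log1p(r) if s > 0 else -math.log1p(-r)
        return {"a": baseline, "b": arg ** (1.0 / shape) / true_bmd,
                "c": shape, "s": s}
    if family in ("exp4", "exp5"):
        if effect_sd <= 1:
            raise ValueError("saturating plateau must exceed 1 SD")
        amp = effect_sd * sigma  # |a*(c-1)| = plateau departure
        if s < 0 and amp >= baseline:
            raise ValueError("decreasing plateau exceeds baseline")
        c = 1.0 + s * amp / baseline
        arg = -math.log1p(-1.0 / effect_sd)
        if family == "exp4":
            return {"a": baseline, "b": arg / true_bmd, "c": c}
        return {"a": baseline, "b": arg ** (1.0 / shape) / true_bmd,
                "c": c, "g": shape}
    raise ValueError(f"unknown family {family!r}")


def effective_sigma(family: str, params: dict[str, float], cv: float,
                    study_doses: np.ndarray) -> float:
    """Constant-variance projection of multiplicative noise over a design.

    A lognormal measurement error with coefficient of variation ``cv`` has
    per-sample SD cv * mu(d); the single sigma that a constant-variance
    normal likelihood identifies is its root mean square over the study
    samples.  The recorded "true 1-SD BMD" uses this sigma so that a
    consistent constant-variance estimator targets the recorded value.
    """
    mu = mean_function(family, params, study_doses)
    return float(cv * math.sqrt(float(np.mean(mu * mu))))


def draw_responsive_feature(rng: np.random.Generator, cfg: GeneratorConfig,
                            design: DoseDesign,
                            family: str | None = None) -> dict:
    """Draw one dose-responsive generating curve.

    Returns a record {family, params, cv, sigma, true_bmd} where ``sigma``
    is the residual SD the recorded true BMD refers to: the drawn SD itself
    for additive noise, or the design-RMS projection of the multiplicative
    noise (see :func:`effective_sigma`), in which case the scale parameter
    is iterated so the recorded BMD still lands on the drawn target.
    Directions and shapes are drawn at random; unbounded decreasing curves
    that would cross zero within the tested range are flipped to increasing.
    """
    families = ("linear", "power", "hill", "exp2", "exp3", "exp4", "exp5")
    fam = family if family is not None else families[rng.integers(len(families))]
    baseline = math.exp(rng.uniform(*np.log(cfg.baseline_range)))
    cv = rng.uniform(*cfg.cv_range)
    sigma_b = cv * baseline
    lo, hi = cfg.true_bmd_range
    target = math.exp(rng.uniform(math.log(lo), math.log(hi)))
    effect = rng.uniform(*cfg.effect_sd_range)
    direction = 1 if rng.random() < 0.5 else -1
    shape = rng.uniform(1.0, 3.0)
    dmax = design.highest_dose
    if fam in ("linear", "power") and direction < 0:
        # keep the curve positive over the tested range
        shp = shape if fam == "power" else 1.0
        drop = sigma_b * (dmax / target) ** shp
        if drop > 0.9 * baseline:
            direction = 1
    if fam in ("exp4", "exp5", "hill") and direction < 0:
        if effect * sigma_b >= 0.9 * baseline:
            effect = 0.9 / cv
    # cap the top-dose fold change of the unbounded families at a realistic
    # maximum by limiting the shape exponent (the saturating families are
    # bounded by their plateau already)
    ratio = dmax / target
    if ratio > 1:
        if fam == "power" and direction > 0:
            cap = math.log((_MAX_FOLD - 1.0) / cv) / math.log(ratio)
            shape = min(shape, max(1.0, cap))
        if fam == "exp3":
            r = cv if direction > 0 else -cv
            cap_arg = math.log(_MAX_FOLD) / abs(math.log1p(r))
            cap = math.log(max(cap_arg, 1.0)) / math.log(ratio)
            shape = min(shape, max(1.0, cap))
    params = solve_params_for_bmd(fam, baseline, sigma_b, target, effect,
                                  direction, shape)
    if cfg.noise_model == "additive":
        return {"family": fam, "params": params, "cv": cv, "sigma": sigma_b,
                "true_bmd": target}
    # multiplicative noise: the truth is recorded against the RMS-projected
    # sigma (what a constant-variance fit identifies), re-solved numerically
    doses = np.array(design.sample_doses())
    sig = effective_sigma(fam, params, cv, doses)
    actual = bmd_from_params(fam, params, sig, 1.0, dmax, bracket_factor=50.0)
    if actual is None:
        actual = target
        sig = sigma_b
    return {"family": fam, "params": params, "cv": cv, "sigma": sig,
            "true_bmd": float(actual)}


# ----------------------------------------------------------------------
# study generation
# ----------------------------------------------------------------------
def _apply_noise(rng, mu: np.ndarray, sigma: float, baseline: float,
                 model: str) -> np.ndarray:
    if model == "additive":
        return mu + rng.normal(0.0, sigma, size=mu.shape)
    cv = sigma / baseline
    sdlog = math.sqrt(math.log1p(cv * cv))
    return mu * rng.lognormal(-0.5 * sdlog * sdlog, sdlog, size=mu.shape)


def _sample_ids(design: DoseDesign, blanks: bool) -> tuple[list, pd.DataFrame]:
    ids, roles, doses = [], [], []
    for i, d in enumerate(design.sample_doses(), start=1):
        ids.append(f"S{i:02d}")
        roles.append("study")
        doses.append(d)
    for i in range(1, design.qc_count + 1):
        ids.append(f"QC{i:02d}")
        roles.append("qc")
        doses.append(np.nan)
    if blanks:
        for i in range(1, design.blank_count + 1):
            ids.append(f"BLK{i:02d}")
            roles.append("blank")
            doses.append(np.nan)
    samples = pd.DataFrame({"role": roles, "dose_mg_per_kg": doses},
                           index=pd.Index(ids, name="sample_id"))
    return ids, samples


def _assay_polarity(assay: str) -> str:
    return "negative" if "negative" in assay.lower() else "positive"


def generate_study(design: DoseDesign = DEFAULT_DESIGN,
                   config: GeneratorConfig | None = None,
                   seed: int = 0) -> tuple[list[FeatureTable], pd.DataFrame, GroundTruth]:
    """Generate a complete synthetic multi-assay study.

    Returns one :class:`FeatureTable` per configured assay (MS assays first,
    then NMR), a genes x samples expression table, and the ground-truth
    ledger.  Identical (design, config, seed) inputs give identical outputs.
    """
    cfg = config if config is not None else GeneratorConfig()
    cfg.validate(design)
    library = MassShiftLibrary()
    parent_mass = formula_mass(cfg.parent_formula)

    study_doses = np.array(design.sample_doses())
    n_study = len(study_doses)

    # assign spiked compounds (parent + each biotransformation chain) to MS
    # assays round-robin
    compounds = ([("parent", ())] + [
        (f"M{i + 2}", chain) for i, chain in enumerate(cfg.btp_chains)
    ]) if cfg.spike_xenobiotics else []
    per_assay_compounds: dict[str, list] = {a: [] for a in cfg.ms_assays}
    for i, comp in enumerate(compounds):
        per_assay_compounds[cfg.ms_assays[i % len(cfg.ms_assays)]].append(comp)

    tables: list[FeatureTable] = []
    truth_rows: list[dict] = []
    truth_params: dict[str, tuple[str, dict, float]] = {}
    xeno_study_levels: dict[str, np.ndarray] = {}

    assay_list = list(cfg.ms_assays) + ([cfg.nmr_assay] if cfg.include_nmr else [])
    for a_idx, assay in enumerate(assay_list):
        is_nmr = cfg.include_nmr and assay == cfg.nmr_assay
        rng = np.random.default_rng([seed, a_idx])
        ids, samples = _sample_ids(design, blanks=not is_nmr)
        n_blank = 0 if is_nmr else design.blank_count
        prefix = f"A{a_idx}"
        rows, meta = [], []

        def add_feature(fid, values_study, qc_mean, blank_vals, mz, rt,
                        truth: dict, extra_meta=None):
            qc = _apply_noise(rng, np.full(design.qc_count, qc_mean),
                              cfg.qc_cv * qc_mean if qc_mean > 0 else 0.0,
                              max(qc_mean, 1e-12), "lognormal")
            row = np.concatenate([values_study, qc, blank_vals[:n_blank]])
            rows.append(row)
            m = {"feature_id": fid, "assay": assay}
            if is_nmr:
                m["bin_ppm"] = rt
            else:
                m["mz"] = mz
                m["rt_seconds"] = rt
            if extra_meta:
                m.update(extra_meta)
            meta.append(m)
            truth = {"feature_id": fid, "assay": assay, **truth}
            truth_rows.append(truth)

        # --- null features
        for j in range(cfg.n_null):
            fid = f"{prefix}_null_{j:04d}"
            baseline = math.exp(rng.uniform(*np.log(cfg.baseline_range)))
            cv = rng.uniform(*cfg.cv_range)
            vals = _apply_noise(rng, np.full(n_study, baseline), cv * baseline,
                                baseline, cfg.noise_model)
            mz = rng.uniform(80.0, 1000.0)
            rt = rng.uniform(0.3, 9.9) if is_nmr else rng.uniform(31.0, 880.0)
            blanks = np.full(design.blank_count, cfg.blank_level * baseline)
            add_feature(fid, vals, baseline, blanks, mz, rt,
                        {"class_label": "null", "family": "", "true_sigma": cv * baseline,
                         "true_bmd": np.nan, "shift_chain": "", "compound_id": ""})
            truth_params[fid] = ("", {}, cv * baseline)

        # --- dose-responsive endogenous features
        for j in range(cfg.n_responsive):
            fid = f"{prefix}_resp_{j:04d}"
            rec = draw_responsive_feature(rng, cfg, design)
            fam, params = rec["family"], rec["params"]
            sigma, bmd = rec["sigma"], rec["true_bmd"]
            mu = mean_function(fam, params, study_doses)
            baseline = abs(params.get("b0", params.get("g", params.get("a", 1.0))))
            vals = _apply_noise(rng, mu, rec["cv"] * baseline, baseline,
                                cfg.noise_model)
            vals = np.maximum(vals, 0.0)
            qc_mean = float(np.mean(mu))
            mz = rng.uniform(80.0, 1000.0)
            rt = rng.uniform(0.3, 9.9) if is_nmr else rng.uniform(31.0, 880.0)
            blanks = np.full(design.blank_count, cfg.blank_level * qc_mean)
            extra = None
            if "LIPIDS" in assay and rng.random() < cfg.annotated_fraction:
                lc = cfg.lipid_classes[rng.integers(len(cfg.lipid_classes))]
                acyl = f"{rng.integers(14, 23)}:{rng.integers(0, 7)}"
                extra = {"lipid_class": lc, "annotation": f"{lc}({acyl})"}
            add_feature(fid, vals, qc_mean, blanks, mz, rt,
                        {"class_label": "endogenous-responsive", "family": fam,
                         "true_sigma": sigma, "true_bmd": bmd,
                         "shift_chain": "", "compound_id": ""},
                        extra_meta=extra)
            truth_params[fid] = (fam, params, sigma)

        # --- blank contaminants (MS only): high blank signal, flat in study
        if not is_nmr:
            for j in range(cfg.n_contaminant):
                fid = f"{prefix}_cont_{j:04d}"
                baseline = math.exp(rng.uniform(*np.log(cfg.baseline_range)))
                cv = rng.uniform(*cfg.cv_range)
                vals = _apply_noise(rng, np.full(n_study, baseline),
                                    cv * baseline, baseline, cfg.noise_model)
                blanks = np.full(design.blank_count, 0.5 * baseline)
                add_feature(fid, vals, baseline, blanks,
                            rng.uniform(80.0, 1000.0), rng.uniform(31.0, 880.0),
                            {"class_label": "blank-contaminant", "family": "",
                             "true_sigma": cv * baseline, "true_bmd": np.nan,
                             "shift_chain": "", "compound_id": ""})
                truth_params[fid] = ("", {}, cv * baseline)

        # --- spiked xenobiotic features (MS only)
        if not is_nmr:
            polarity = _assay_polarity(assay)
            adduct = adducts_for_polarity(polarity)[0]
            used_rts: list[float] = []
            for comp_id, chain in per_assay_compounds[assay]:
                mass = parent_mass + sum(library.by_name(s).mass_delta
                                         for s in chain)
                top = math.exp(rng.uniform(*np.log(cfg.xeno_top_range)))
                # distinct compounds resolve chromatographically: keep their
                # apices well outside the grouping tolerance of each other
                for _ in range(200):
                    rt = rng.uniform(40.0, 800.0)
                    if all(abs(rt - u) > 20.0 for u in used_rts):
                        break
                used_rts.append(rt)
                base_levels = top * study_doses / design.highest_dose
                chain_str = "+".join(chain)
                for ion_idx, (ion_label, mz_off, frac, has_msms, match) in enumerate([
                    (adduct.name, adduct.mass_offset, 1.0, True,
                     round(rng.uniform(0.6, 0.95), 3)),
                    (adduct.name + " +1", adduct.mass_offset + ISOTOPOLOGUE_SPACING,
                     cfg.iso_fraction, False, 0.0),
                ]):
                    fid = f"{prefix}_xeno_{comp_id}_{ion_idx}"
                    mu = base_levels * frac
                    vals = _apply_noise(rng, mu, cfg.xeno_cv * top * frac,
                                        top * frac, "lognormal")
                    vals = np.where(study_doses == 0, np.nan, np.maximum(vals, 0.0))
                    mz = (mass + mz_off) * (1.0 + rng.uniform(-1e-6, 1e-6))
                    qc_mean = float(np.nanmean(np.where(study_doses == 0, 0.0, mu)))
                    blanks = np.full(design.blank_count, np.nan)
                    add_feature(fid, vals, qc_mean, blanks, mz, rt,
                                {"class_label": "xenobiotic", "family": "",
                                 "true_sigma": np.nan, "true_bmd": np.nan,
                                 "shift_chain": chain_str, "compound_id": comp_id},
                                extra_meta={"has_msms": has_msms,
                                            "msms_fragment_match_fraction": match})
                    truth_params[fid] = ("", {}, float("nan"))
                    if ion_idx == 0:
                        xeno_study_levels[fid] = mu.copy()

        # --- missingness (study samples, endogenous classes only)
        mat = np.vstack(rows) if rows else np.zeros((0, len(ids)))
        if cfg.missing_rate > 0 and len(rows):
            mask = rng.random((len(rows), n_study)) < cfg.missing_rate
            is_xeno = np.array([r["class_label"] == "xenobiotic"
                                for r in truth_rows[-len(rows):]])
            mask[is_xeno] = False
            mat[:, :n_study][mask] = np.nan

        intens = pd.DataFrame(mat, index=[m["feature_id"] for m in meta],
                              columns=ids)
        intens.index.name = "feature_id"
        features = pd.DataFrame(meta).set_index("feature_id")
        tables.append(FeatureTable(intensities=intens, features=features,
                                   samples=samples))

    # --- coupled gene panel
    if xeno_study_levels:
        xeno_df = pd.DataFrame(xeno_study_levels).T
        xeno_df.columns = [f"S{i + 1:02d}" for i in range(n_study)]
        genes, coupling = spike_gene_panel(xeno_df, cfg, seed=seed + 10_000)
    else:
        genes = pd.DataFrame(columns=[f"S{i + 1:02d}" for i in range(n_study)])
        genes.index.name = "gene"
        coupling = pd.DataFrame(columns=["gene", "source_feature", "coupled"])

    truth = GroundTruth(table=pd.DataFrame(truth_rows), params=truth_params,
                        gene_coupling=coupling)
    return tables, genes, truth


def spike_gene_panel(xeno_intensities: pd.DataFrame, config: GeneratorConfig,
                     seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genes x samples expression table coupled to xenobiotic feature levels.

    A configured fraction of genes are noisy, strictly monotone transforms of
    one xenobiotic feature's per-sample level (log-compressed, so the rank
    structure is preserved exactly in the noise-free limit); the remainder
    are independent Gaussian noise.  Returns (gene table, coupling map).
    """
    if xeno_intensities.shape[0] < 1:
        raise ValueError("at least one xenobiotic feature is required")
    rng = np.random.default_rng([seed, 77])
    n_genes = config.n_genes
    n_coupled = int(round(config.gene_coupled_fraction * n_genes))
    sample_ids = list(xeno_intensities.columns)
    sources = list(xeno_intensities.index)
    rows, coup = [], []
    for gi in range(n_genes):
        gene = f"gene_{gi + 1:03d}"
        if gi < n_coupled:
            src = sources[gi % len(sources)]
            x = xeno_intensities.loc[src].to_numpy(dtype=float)
            scale = np.nanmax(x) if np.nanmax(x) > 0 else 1.0
            expr = np.log1p(x / scale * 100.0)
            expr = expr + rng.normal(0.0, config.gene_noise_sd, size=expr.size)
            coup.append({"gene": gene, "source_feature": src, "coupled": True})
        else:
            expr = rng.normal(0.0, 1.0, size=len(sample_ids))
            coup.append({"gene": gene, "source_feature": "", "coupled": False})
        rows.append(expr)
    genes = pd.DataFrame(np.vstack(rows),
                         index=pd.Index([c["gene"] for c in coup], name="gene"),
                         columns=sample_ids)
    return genes, pd.DataFrame(coup)


def true_bmd_check(truth: GroundTruth, design: DoseDesign,
                   bmr_factor: float = 1.0) -> pd.DataFrame:
    """Numerically re-solve each generating curve for its benchmark dose.

    Independent closure check of the recorded ground truth: bracketed root
    finding of |mu(d) - mu(0)| = bmr * sigma on the generating curve, which
    must reproduce the recorded true BMD.
    """
    out = []
    for _, row in truth.table.iterrows():
        if row["class_label"] != "endogenous-responsive":
            continue
        fam, params, sigma = truth.params[row["feature_id"]]
        solved = bmd_from_params(fam, params, sigma, bmr_factor,
                                 design.highest_dose, bracket_factor=50.0)
        out.append({"feature_id": row["feature_id"], "recorded": row["true_bmd"],
                    "solved": solved})
    return pd.DataFrame(out)
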