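"""Seeded synthetic cohorts for end-to-end pipeline testing.

Three generators emulate the statistical structure the analysis assumes,
with ground-truth labels attached:

* :func:`simulate_preclinical` — a two-group (control vs LPL-inhibited)
  plasma lipidomics table, 126 metabolites, n = 10 per group, with
  multiplicative group effects planted on an 11-lipid signature;
* :func:`simulate_urine_null` — a 43-metabolite urine-like table with no
  group signal and per-sample dilution factors (the branch a validation
  step must reject);
* :func:`simulate_human_cohort` — a 140-subject cohort with a latent
  at-risk class that carries the signature shift on its metabolome and
  coupled mean shifts on clinical lipids (TG, TC, LDL, ApoB).

Noise model: abundances are log-normal, the log-scale SD derived from a
target coefficient of variation, so values are strictly positive and the
SEM/mean ratio is scale-proportional. Features of one lipid class share a
single Gaussian factor (equicorrelation) because lipid classes
co-regulate and discriminant-model behaviour depends on collinearity.
Identical (spec, seed) always reproduces identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import FeatureTable, TruthTable

# ---------------------------------------------------------------------------
# Feature panels
# ---------------------------------------------------------------------------

#: The 11-lipid predictive signature with its multiplicative group effects
#: (case/control fold changes) and control-group mean abundances
#: (internal-standard response ratios).
SIGNATURE_EFFECTS: dict[str, float] = {
    "PC 38:4": 1.46,
    "LPC 18:0": 1.17,
    "PC 36:4": 1.29,
    "DG 36:4": 1.33,
    "DG 34:3": 1.50,
    "DG 34:2": 1.24,
    "TG 46:0": 1.37,
    "ChoE (17:0)": 1.28,
    "ChoE (18:0)": 1.51,
    "ChoE (16:0)": 1.18,
    "ChoE (18:1)": 1.41,
}

SIGNATURE_BASELINES: dict[str, float] = {
    "PC 38:4": 14.02,
    "LPC 18:0": 50.40,
    "PC 36:4": 13.76,
    "DG 36:4": 1.53,
    "DG 34:3": 0.20,
    "DG 34:2": 0.85,
    "TG 46:0": 0.84,
    "ChoE (17:0)": 0.13,
    "ChoE (18:0)": 0.12,
    "ChoE (16:0)": 2.02,
    "ChoE (18:1)": 2.52,
}

_AMINO_ACIDS = [
    "Alanine", "Proline", "Valine", "Leucine", "Isoleucine", "Glycine", "Serine",
    "Threonine", "Methionine", "Phenylalanine", "Tyrosine", "Tryptophan", "Lysine",
    "Histidine", "Arginine", "Glutamine", "Glutamate", "Aspartate", "Asparagine",
    "Cysteine",
]

_OTHER_PLASMA = [
    "Glucose", "Lactate", "Citrate", "Pyruvate", "3-hydroxybutyric acid", "Creatinine",
    "Carnitine", "Acetylcarnitine", "Choline", "Betaine", "Taurine", "Uric acid",
    "Cholesterol",
]


def plasma_feature_panel() -> dict[str, str]:
    """Default 126-metabolite plasma panel: name -> lipid/compound class."""
    panel: dict[str, str] = {}
    for name in SIGNATURE_EFFECTS:
        panel[name] = feature_class(name)
    tg = [f"TG {c}:{d}" for c, d in [
        (44, 1), (44, 2), (46, 1), (46, 2), (48, 0), (48, 1), (48, 2), (48, 3),
        (50, 1), (50, 2), (50, 3), (50, 4), (52, 1), (52, 2), (52, 3), (52, 4),
        (52, 5), (54, 2), (54, 3), (54, 4), (54, 5), (54, 6), (54, 7), (56, 3),
        (56, 5), (56, 6), (56, 7), (58, 6), (58, 8), (58, 9),
    ]]
    dg = [f"DG {c}:{d}" for c, d in [
        (32, 0), (32, 1), (34, 0), (34, 1), (36, 1), (36, 2), (36, 3), (38, 4),
        (38, 5), (38, 6),
    ]]
    pc = [f"PC {c}:{d}" for c, d in [
        (30, 0), (32, 0), (32, 1), (32, 2), (34, 1), (34, 2), (34, 3), (36, 1),
        (36, 2), (36, 3), (36, 5), (38, 3), (38, 5), (38, 6), (40, 5), (40, 6),
        (40, 7), (42, 5), (42, 6), (44, 6),
    ]]
    lpc = [f"LPC {c}:{d}" for c, d in [
        (14, 0), (16, 0), (16, 1), (18, 1), (18, 2), (20, 3), (20, 4), (22, 6),
    ]]
    sm = [f"SM {c}:{d}" for c, d in [
        (32, 1), (34, 1), (34, 2), (36, 1), (36, 2), (38, 1), (40, 1), (41, 1),
        (42, 2), (42, 3),
    ]]
    choe = ["ChoE (18:2)", "ChoE (20:4)", "ChoE (20:5)", "ChoE (22:6)"]
    for name in tg + dg + pc + lpc + sm + choe + _AMINO_ACIDS + _OTHER_PLASMA:
        panel[name] = feature_class(name)
    assert len(panel) == 126
    return panel


def urine_feature_panel() -> dict[str, str]:
    """Default 43-metabolite urine panel (NMR-detectable small molecules)."""
    names = [
        "TMAO", "Phenylacetylglycine", "2-deoxycytidine", "Leucine", "Creatinine",
        "Citrate", "Hippurate", "Taurine", "Betaine", "Dimethylamine", "Allantoin",
        "Urea", "Glycine", "Alanine", "Lactate", "Acetate", "Succinate",
        "2-oxoglutarate", "Formate", "Fumarate", "Trigonelline",
        "N-methylnicotinamide", "Creatine", "Choline", "Methylamine", "Sarcosine",
        "Glucose", "myo-Inositol", "Threonine", "Valine", "Isoleucine", "Pyruvate",
        "Acetoacetate", "3-hydroxybutyrate", "Ethanolamine", "Histidine", "Tyrosine",
        "Phenylalanine", "Tryptophan", "Indoxyl sulfate", "Pantothenate",
        "Ascorbate", "Malonate",
    ]
    assert len(names) == 43
    return {n: "urine" for n in names}


def feature_class(name: str) -> str:
    """Lipid/compound class from a metabolite name (``TG 54:2``-style)."""
    for prefix, cls in [("TG ", "TG"), ("DG ", "DG"), ("PC ", "PC"), ("LPC ", "LPC"),
                        ("SM ", "SM"), ("ChoE", "ChoE")]:
        if name.startswith(prefix):
            return cls
    if name in _AMINO_ACIDS:
        return "amino-acid"
    return "other"


# ---------------------------------------------------------------------------
# Cohort specifications
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Parameters of a two-group preclinical simulation.

    ``effect_map`` defaults to 1.0 (no effect) for unlisted metabolites;
    ``cv_noise`` may be a scalar, a (low, high) range sampled per
    metabolite, or a per-metabolite mapping. ``within_class_corr`` is the
    equicorrelation among features of one lipid class.
    """

    n_per_group: int = 10
    feature_names: dict[str, str] | None = None   # name -> class; None = plasma panel
    effect_map: dict[str, float] = field(default_factory=dict)
    cv_noise: float | tuple[float, float] | dict[str, float] = (0.10, 0.15)
    within_class_corr: float = 0.4
    n_blocks: int = 1
    block_drift: dict | None = None               # block id -> factor
    qc_per_block: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 3:
            raise ValueError("n_per_group must be >= 3")
        if not (0 <= self.within_class_corr < 1):
            raise ValueError("within_class_corr must lie in [0, 1)")
        for m, e in self.effect_map.items():
            if e <= 0:
                raise ValueError(f"effect for {m!r} must be > 0 (got {e})")

    def resolve_features(self) -> dict[str, str]:
        return dict(self.feature_names) if self.feature_names else plasma_feature_panel()


def default_preclinical_spec(seed: int = 0, **overrides) -> CohortSpec:
    """The study conditions of the preclinical experiment: 2 x 10 animals,
    126 plasma metabolites, the 11-lipid signature effects planted."""
    kw = dict(n_per_group=10, effect_map=dict(SIGNATURE_EFFECTS), seed=seed)
    kw.update(overrides)
    return CohortSpec(**kw)


def default_urine_spec(seed: int = 0, **overrides) -> CohortSpec:
    """Null urine-like conditions: 43 metabolites, no group signal,
    wider biological CV typical of spot urine."""
    kw = dict(n_per_group=10, feature_names=urine_feature_panel(),
              effect_map={}, cv_noise=(0.20, 0.40), within_class_corr=0.0, seed=seed)
    kw.update(overrides)
    return CohortSpec(**kw)


@dataclass
class HumanCohortSpec:
    """Parameters of the human-cohort simulation.

    ``signature_effect`` is the multiplicative shift applied to signature
    metabolites in latent at-risk subjects; ``clinical_coupling`` shifts
    the at-risk means of clinical lipids (mmol/L, ApoB in g/L).
    """

    n_subjects: int = 140
    prevalence_at_risk: float = 0.5
    signature_effect: float = 1.4
    clinical_coupling: dict[str, float] = field(default_factory=lambda: {
        "tg_mmol_l": 0.5, "tc_mmol_l": 0.4, "ldl_mmol_l": 0.35, "apob_g_l": 0.12,
    })
    tg_guideline_threshold: float = 1.7
    cv_noise: float | tuple[float, float] = (0.25, 0.35)
    within_class_corr: float = 0.4
    feature_names: dict[str, str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.prevalence_at_risk < 1):
            raise ValueError("prevalence_at_risk must lie in (0, 1)")
        if self.signature_effect <= 0:
            raise ValueError("signature_effect must be > 0")

    def resolve_features(self) -> dict[str, str]:
        return dict(self.feature_names) if self.feature_names else plasma_feature_panel()


# ---------------------------------------------------------------------------
# Internal machinery
# ---------------------------------------------------------------------------

def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


def _resolve_cv(cv_noise, features: list[str], rng) -> np.ndarray:
    if isinstance(cv_noise, dict):
        cv = np.array([cv_noise[f] for f in features], dtype=float)
    elif isinstance(cv_noise, (tuple, list)):
        lo, hi = cv_noise
        cv = rng.uniform(lo, hi, size=len(features))
    else:
        cv = np.full(len(features), float(cv_noise))
    if np.any(cv <= 0):
        bad = [f for f, c in zip(features, cv) if c <= 0]
        raise ValueError(f"coefficient of variation must be > 0 for {bad}")
    return cv


def _baseline_means(features: list[str], rng) -> np.ndarray:
    """Control-group means: signature lipids anchored to their reference
    abundances, everything else drawn log-uniformly over 0.1-50."""
    means = np.empty(len(features))
    for j, f in enumerate(features):
        if f in SIGNATURE_BASELINES:
            means[j] = SIGNATURE_BASELINES[f]
        else:
            means[j] = 10.0 ** rng.uniform(-1.0, 1.7)
    return means


def _lognormal_matrix(n: int, means: np.ndarray, cv: np.ndarray, classes: list[str],
                      rho: float, rng) -> np.ndarray:
    """Log-normal draws with target arithmetic means and CVs; equicorrelated
    within compound class via one shared Gaussian factor per class."""
    sigma = np.sqrt(np.log1p(cv**2))
    mu = np.log(means) - 0.5 * sigma**2
    uniq = sorted(set(classes))
    class_z = {c: rng.standard_normal(n) for c in uniq}
    eps = rng.standard_normal((n, len(means)))
    z = np.empty_like(eps)
    for j, c in enumerate(classes):
        z[:, j] = np.sqrt(rho) * class_z[c] + np.sqrt(1.0 - rho) * eps[:, j]
    return np.exp(mu + sigma * z)


def _append_qc(samples: pd.DataFrame, values: pd.DataFrame, cohort: str,
               n_blocks: int, qc_per_block: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Interleave deterministic QC samples (pooled-sample mean spectrum)."""
    pooled = values.mean(axis=0)
    qc_rows, qc_meta = [], []
    k = 0
    for b in range(1, n_blocks + 1):
        for _ in range(qc_per_block):
            k += 1
            qc_rows.append(pooled)
            qc_meta.append({"cohort": cohort, "group": "QC", "block": b, "is_qc": True})
    qc_index = pd.Index([f"QC{i:02d}" for i in range(1, k + 1)])
    samples = pd.concat([samples, pd.DataFrame(qc_meta, index=qc_index)])
    values = pd.concat([values, pd.DataFrame(qc_rows, index=qc_index)])
    return samples, values


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def simulate_preclinical(spec: CohortSpec) -> tuple[FeatureTable, TruthTable]:
    """Two-group preclinical plasma table with planted group effects.

    Group-2 ("case") means equal group-1 ("control") means times the
    effect map; QC samples (the pooled mean spectrum) are interleaved per
    run-day block, and optional block drift is applied multiplicatively.
    """
    panel = spec.resolve_features()
    features = list(panel)
    classes = [panel[f] for f in features]
    unknown = [m for m in spec.effect_map if m not in panel]
    if unknown:
        raise ValueError(f"effect_map names metabolites absent from the panel: {unknown}")

    rng = _rng(spec.seed, 1)
    cv = _resolve_cv(spec.cv_noise, features, rng)
    base = _baseline_means(features, rng)
    effects = np.array([spec.effect_map.get(f, 1.0) for f in features])

    n = spec.n_per_group
    X_ctrl = _lognormal_matrix(n, base, cv, classes, spec.within_class_corr, rng)
    X_case = _lognormal_matrix(n, base * effects, cv, classes, spec.within_class_corr, rng)

    ids = [f"rat{i:02d}" for i in range(1, 2 * n + 1)]
    groups = ["control"] * n + ["case"] * n
    blocks = [(i % spec.n_blocks) + 1 for i in range(2 * n)]
    samples = pd.DataFrame(
        {"cohort": "preclinical", "group": groups, "block": blocks, "is_qc": False},
        index=pd.Index(ids),
    )
    values = pd.DataFrame(np.vstack([X_ctrl, X_case]), index=samples.index, columns=features)
    samples, values = _append_qc(samples, values, "preclinical", spec.n_blocks, spec.qc_per_block)
    table = FeatureTable(samples, values)

    if spec.block_drift and any(f != 1.0 for f in spec.block_drift.values()):
        table = inject_run_day_drift(table, spec.block_drift)

    truth = TruthTable(
        labels=samples["group"].copy(),
        effects=pd.Series(effects, index=features, name="true_effect"),
    )
    return table, truth


def simulate_urine_null(spec: CohortSpec) -> tuple[FeatureTable, TruthTable]:
    """Urine-like table with no class signal and per-sample dilution factors.

    Dilution (log-normal, CV ~ 30%) multiplies every metabolite of a
    sample, emulating variable urine concentration; the true factors are
    recorded so quotient normalization can be tested against them.
    """
    nontrivial = [m for m, e in spec.effect_map.items() if abs(e - 1.0) > 1e-9]
    if len(nontrivial) > 4:
        raise ValueError(
            f"urine generator is a null branch; at most 4 non-unit effects allowed, got {len(nontrivial)}"
        )
    if spec.feature_names is None:
        spec = CohortSpec(**{**spec.__dict__, "feature_names": urine_feature_panel()})
    table, truth = simulate_preclinical(spec)

    rng = _rng(spec.seed, 2)
    study = ~table.samples["is_qc"]
    dilution = pd.Series(1.0, index=table.sample_ids, name="dilution_factor")
    dilution.loc[study] = np.exp(rng.normal(0.0, 0.3, size=int(study.sum())))
    values = table.values.mul(dilution, axis=0)
    out = FeatureTable(table.samples, values)
    truth.sample_factors = dilution.to_frame()
    return out, truth


CLINICAL_HEALTHY = {
    # column: (mean, SD, floor) — fasting values for a guideline-normal adult
    "tg_mmol_l": (1.1, 0.45, 0.2),
    "tc_mmol_l": (5.0, 0.90, 2.0),
    "hdl_mmol_l": (1.4, 0.30, 0.5),
    "ldl_mmol_l": (3.0, 0.80, 0.8),
    "apob_g_l": (1.0, 0.22, 0.3),
    "glucose_mg_dl": (95.0, 10.0, 60.0),
    "insulin_ug_l": (1.0, 0.35, 0.15),
    "nefa_mmol_l": (0.5, 0.15, 0.1),
    "lpl_activity": (5.4, 1.0, 0.5),
}


def simulate_human_cohort(
    spec: HumanCohortSpec, signature
) -> tuple[FeatureTable, pd.DataFrame, TruthTable]:
    """Human cohort with a latent at-risk class coupled to clinical lipids.

    ``signature`` is a list of metabolite names (or an object exposing
    ``members``); latent at-risk subjects carry ``signature_effect`` on
    those metabolites and the ``clinical_coupling`` mean shifts on their
    clinical lipids. Returns (features, clinical table, truth).
    """
    members = list(getattr(signature, "members", signature))
    if not members:
        raise ValueError("signature must be non-empty")
    panel = spec.resolve_features()
    missing = [m for m in members if m not in panel]
    if missing:
        raise ValueError(f"signature metabolites absent from the human panel: {missing}")

    features = list(panel)
    classes = [panel[f] for f in features]
    rng = _rng(spec.seed, 3)
    cv = _resolve_cv(spec.cv_noise, features, rng)
    base = _baseline_means(features, rng)
    at_risk = rng.random(spec.n_subjects) < spec.prevalence_at_risk

    effect = np.array([spec.signature_effect if f in members else 1.0 for f in features])
    n_risk = int(at_risk.sum())
    n_healthy = spec.n_subjects - n_risk
    X = np.empty((spec.n_subjects, len(features)))
    X[~at_risk] = _lognormal_matrix(n_healthy, base, cv, classes, spec.within_class_corr, rng)
    X[at_risk] = _lognormal_matrix(n_risk, base * effect, cv, classes, spec.within_class_corr, rng)

    ids = [f"subj{i:03d}" for i in range(1, spec.n_subjects + 1)]
    samples = pd.DataFrame(
        {"cohort": "human", "group": "unlabeled", "block": 1, "is_qc": False},
        index=pd.Index(ids),
    )
    table = FeatureTable(samples, pd.DataFrame(X, index=samples.index, columns=features))

    clin = pd.DataFrame(index=samples.index)
    clin["sex"] = rng.choice(["F", "M"], size=spec.n_subjects)
    clin["age"] = rng.integers(43, 66, size=spec.n_subjects)
    clin["bmi"] = np.maximum(rng.normal(26.0, 3.5, size=spec.n_subjects), 17.0)
    for col, (mean, sd, floor) in CLINICAL_HEALTHY.items():
        shift = spec.clinical_coupling.get(col, 0.0)
        mu = np.where(at_risk, mean + shift, mean)
        clin[col] = np.maximum(rng.normal(mu, sd), floor)

    truth = TruthTable(
        labels=pd.Series(np.where(at_risk, "at_risk", "healthy"), index=samples.index, name="latent_class"),
        effects=pd.Series(effect, index=features, name="true_effect"),
    )
    return table, clin, truth


def inject_run_day_drift(table: FeatureTable, factors: dict) -> FeatureTable:
    """Multiply every value by its run-day block's drift factor.

    ``factors`` maps block id to a scalar (all metabolites) or a
    per-metabolite Series. QC samples drift identically with their block.

    Raises
    ------
    ValueError
        If a block has no QC sample (drift would be uncorrectable) or a
        sample's block has no factor.
    """
    blocks = table.samples["block"]
    is_qc = table.samples["is_qc"]
    for b in blocks.unique():
        if not is_qc[blocks == b].any():
            raise ValueError(f"block {b!r} has no QC sample; refusing to inject uncorrectable drift")
        if b not in factors:
            raise ValueError(f"no drift factor supplied for block {b!r}")
    values = table.values.copy()
    for b, f in factors.items():
        mask = (blocks == b).to_numpy()
        values.loc[mask] = values.loc[mask] * f
    return FeatureTable(table.samples, values)
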