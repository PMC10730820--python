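"""Signature selection and cross-cohort model translation.

The workflow: select the predictive metabolite signature from the
univariate screen and VIP scores; reconcile feature names between the
training (preclinical) and target (human) panels; refit the discriminant
model on the matched features and project it onto the target cohort,
standardized within-cohort; classify subjects; compare model classes with
guideline triglyceride thresholds through a confusion matrix; and
characterize the discordant subgroup (guideline-normal but model
at-risk).

The largest interpretive choice here is deliberate and documented: the
target cohort is z-scored with its own means and SDs, not the training
scaler, because abundance scales differ across species and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .opls import OPLSDA, OPLSDAResults
from .screen import UnivariateResult, bh_adjust, mann_whitney, screen_features, volcano_select
from .simulate import feature_class
from .tables import FeatureTable


# ---------------------------------------------------------------------------
# Signature
# ---------------------------------------------------------------------------

@dataclass
class Signature:
    """Ordered predictive-metabolite signature (VIP descending)."""

    table: pd.DataFrame  # index metabolite; columns vip, q_value, fold_change, lipid_class
    q_max: float
    vip_min: float

    @property
    def members(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="metabolite")


def select_signature(
    univ: UnivariateResult, vips: pd.Series, q_max: float = 0.05, vip_min: float = 1.0
) -> Signature:
    """Intersection rule: q < q_max (strict) and VIP > vip_min (strict).

    An empty selection is a valid outcome, not an error; disjoint feature
    sets are.
    """
    u = univ.table
    common = u.index.intersection(vips.index)
    if len(common) == 0:
        raise ValueError("univariate results and VIP scores share no features")
    u = u.loc[common]
    v = vips.loc[common]
    selected = (u["q_value"] < q_max) & (v > vip_min)
    out = pd.DataFrame({
        "vip": v[selected],
        "q_value": u.loc[selected, "q_value"],
        "fold_change": u.loc[selected, "fold_change"],
        "lipid_class": [feature_class(m) for m in u.index[selected]],
    }).sort_values("vip", ascending=False)
    return Signature(table=out, q_max=q_max, vip_min=vip_min)


# ---------------------------------------------------------------------------
# Feature matching
# ---------------------------------------------------------------------------

def _normalize_name(name: str) -> str:
    return " ".join(str(name).casefold().split())


@dataclass
class FeatureMatch:
    mapping: dict[str, str]      # model feature -> cohort feature
    missing: list[str]
    coverage: float


def match_features(model_features, cohort_features) -> FeatureMatch:
    """Case-normalized exact-name reconciliation between two panels."""
    model_features = list(model_features)
    lookup = {_normalize_name(c): c for c in cohort_features}
    mapping, missing = {}, []
    for f in model_features:
        key = _normalize_name(f)
        if key in lookup:
            mapping[f] = lookup[key]
        else:
            missing.append(f)
    coverage = len(mapping) / len(model_features) if model_features else 0.0
    return FeatureMatch(mapping=mapping, missing=missing, coverage=coverage)


# ---------------------------------------------------------------------------
# Projection
# ---------------------------------------------------------------------------

def project_cohort(
    train_table: FeatureTable,
    target_table: FeatureTable,
    mode: str = "full",
    signature: Signature | list[str] | None = None,
    min_coverage: float = 0.8,
    n_pred: int = 1,
    n_ortho: int = 1,
    case: str = "case",
    control: str = "control",
) -> tuple[OPLSDAResults, pd.DataFrame]:
    """Refit on matched features and project onto the target cohort.

    ``mode='full'`` uses every training feature matched in the target
    panel; ``mode='signature-only'`` restricts to signature members. The
    target cohort is standardized with its own statistics before the
    model's linear form is applied; subjects are classified by the
    midpoint (0.5) threshold on the coded scale.

    Returns the refit model results and a per-subject classification
    frame (``score``, ``model_class``, ``at_risk``).
    """
    if mode not in {"full", "signature-only"}:
        raise ValueError(f"mode must be 'full' or 'signature-only', got {mode!r}")
    features = train_table.feature_names
    if mode == "signature-only":
        if signature is None:
            raise ValueError("signature-only mode requires a signature")
        features = list(getattr(signature, "members", signature))

    match = match_features(features, target_table.feature_names)
    if match.coverage < min_coverage:
        raise ValueError(
            f"target covers only {match.coverage:.0%} of model features "
            f"(minimum {min_coverage:.0%}); missing: {match.missing}"
        )
    model_feats = list(match.mapping)
    target_feats = [match.mapping[f] for f in model_feats]

    train = train_table.non_qc().subset_features(model_feats)
    results = OPLSDA.from_feature_table(train, positive=case).fit(n_pred=n_pred, n_ortho=n_ortho)

    target = target_table.non_qc()
    Xt = target.values[target_feats].to_numpy(dtype=float)
    sd = Xt.std(axis=0, ddof=1)
    zero = [target_feats[j] for j in np.flatnonzero(sd == 0)]
    if zero:
        raise ValueError(f"target features with zero SD cannot be standardized: {zero}")
    Z = (Xt - Xt.mean(axis=0)) / sd
    score = Z @ results.coef + results.intercept
    at_risk = score >= 0.5
    classification = pd.DataFrame(
        {
            "score": score,
            "model_class": np.where(at_risk, "at-risk", "healthy"),
            "at_risk": at_risk,
        },
        index=target.sample_ids,
    )
    return results, classification


# ---------------------------------------------------------------------------
# Guideline thresholds
# ---------------------------------------------------------------------------

@dataclass
class GuidelineConfig:
    """Fasting-TG categories (mmol/L) per European dyslipidaemia guidelines."""

    tg_normal_max: float = 1.7
    tg_borderline_max: float = 2.3
    tg_high_max: float = 5.6

    def __post_init__(self) -> None:
        if not (self.tg_normal_max < self.tg_borderline_max < self.tg_high_max):
            raise ValueError("guideline thresholds must be strictly increasing")


def guideline_classify(tg_mmol_l, config: GuidelineConfig | None = None):
    """TG category and binary risk flag by guideline thresholds.

    Categories: normal < 1.7 <= borderline < 2.3 <= high < 5.6 <= severe;
    binary risk is TG >= 1.7 (the boundary counts as at-risk so the
    normal/at-risk split partitions all values). Vectorized over arrays.
    """
    cfg = config or GuidelineConfig()
    tg = np.asarray(tg_mmol_l, dtype=float)
    scalar = tg.ndim == 0
    tg = np.atleast_1d(tg)
    if np.any(tg <= 0):
        raise ValueError("TG must be > 0 mmol/L")
    category = np.select(
        [tg < cfg.tg_normal_max, tg < cfg.tg_borderline_max, tg < cfg.tg_high_max],
        ["normal", "borderline", "high"],
        default="severe",
    )
    risk = tg >= cfg.tg_normal_max
    if scalar:
        return str(category[0]), bool(risk[0])
    return category, risk


# ---------------------------------------------------------------------------
# Confusion matrix
# ---------------------------------------------------------------------------

@dataclass
class ConfusionReport:
    """2x2 agreement of model class vs guideline risk (positive = at-risk)."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    def to_dict(self) -> dict:
        return {
            "TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn, "N": self.n,
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def confusion_report(model_at_risk, guideline_at_risk) -> ConfusionReport:
    """Tally model predictions against the guideline reference condition."""
    pred = np.asarray(model_at_risk, dtype=bool)
    ref = np.asarray(guideline_at_risk, dtype=bool)
    if pred.shape != ref.shape:
        raise ValueError(f"label vectors differ in length: {pred.shape} vs {ref.shape}")
    return ConfusionReport(
        tp=int(np.sum(pred & ref)),
        fp=int(np.sum(pred & ~ref)),
        tn=int(np.sum(~pred & ~ref)),
        fn=int(np.sum(~pred & ref)),
    )


# ---------------------------------------------------------------------------
# Discordant-subgroup characterization
# ---------------------------------------------------------------------------

#: Clinical columns compared between subgroups (numeric, per subject).
CLINICAL_TEST_COLUMNS = [
    "tg_mmol_l", "tc_mmol_l", "hdl_mmol_l", "ldl_mmol_l", "apob_g_l",
    "glucose_mg_dl", "insulin_ug_l", "nefa_mmol_l", "lpl_activity", "bmi", "age",
]


@dataclass
class SubgroupReport:
    """Guideline-normal subjects split by model class: tests and sizes."""

    n_concordant_healthy: int   # guideline-normal, model-healthy
    n_discordant_at_risk: int   # guideline-normal but model at-risk
    clinical_tests: pd.DataFrame | None = None
    metabolite_screen: UnivariateResult | None = None
    volcano: pd.DataFrame | None = None
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        out = {
            "n_concordant_healthy": self.n_concordant_healthy,
            "n_discordant_at_risk": self.n_discordant_at_risk,
            "warnings": self.warnings,
        }
        if self.clinical_tests is not None:
            out["clinical_tests"] = self.clinical_tests.to_dict(orient="index")
        if self.metabolite_screen is not None:
            out["metabolite_screen"] = self.metabolite_screen.summary_dict()
        if self.volcano is not None:
            out["n_volcano_selected"] = int(self.volcano["selected"].sum())
        return out


def subgroup_compare(
    classification: pd.DataFrame,
    clinical: pd.DataFrame,
    features: FeatureTable,
    fc_min: float = 2.0,
    fdr_max: float = 0.1,
) -> SubgroupReport:
    """Characterize guideline-normal subjects the model calls at-risk.

    Restricts to guideline-normal subjects, splits them by model class,
    and runs Mann-Whitney + BH on clinical variables and on the
    metabolome (with the volcano selection applied to the latter).
    """
    _, guideline_risk = guideline_classify(clinical["tg_mmol_l"].to_numpy())
    normal_ids = clinical.index[~guideline_risk]
    cls = classification.loc[normal_ids]
    disc_ids = cls.index[cls["at_risk"]]
    conc_ids = cls.index[~cls["at_risk"]]
    report = SubgroupReport(
        n_concordant_healthy=len(conc_ids), n_discordant_at_risk=len(disc_ids)
    )
    if len(disc_ids) < 3 or len(conc_ids) < 3:
        report.warnings.append(
            f"subgroup too small for testing (discordant={len(disc_ids)}, concordant={len(conc_ids)})"
        )
        return report

    rows = []
    for col in CLINICAL_TEST_COLUMNS:
        if col not in clinical.columns:
            continue
        a = clinical.loc[disc_ids, col].dropna().to_numpy(dtype=float)
        b = clinical.loc[conc_ids, col].dropna().to_numpy(dtype=float)
        u, p = mann_whitney(a, b)
        rows.append({
            "variable": col,
            "mean_discordant": float(a.mean()),
            "mean_concordant": float(b.mean()),
            "u_statistic": u,
            "p_value": p,
        })
    clin_tests = pd.DataFrame(rows).set_index("variable")
    clin_tests["q_value"] = bh_adjust(clin_tests["p_value"].to_numpy())
    clin_tests["significant_fdr"] = clin_tests["q_value"] < 0.05
    report.clinical_tests = clin_tests

    sub = features.non_qc()
    keep = sub.sample_ids.isin(normal_ids)
    samples = sub.samples.loc[keep].copy()
    samples["group"] = np.where(samples.index.isin(disc_ids), "discordant", "concordant")
    metab_table = FeatureTable(samples, sub.values.loc[keep])
    screen = screen_features(metab_table, case="discordant", control="concordant")
    report.metabolite_screen = screen
    report.volcano = volcano_select(screen, fc_min=fc_min, fdr_max=fdr_max)
    return report
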