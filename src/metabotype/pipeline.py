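"""End-to-end pipeline: simulate/load -> preprocess -> screen -> fit ->
select -> project -> evaluate, with a machine-readable run report.

Stages mirror the translational workflow: a preclinical two-group plasma
table trains and validates an OPLS-DA model; a urine-like table exercises
the model-rejection rule; the accepted model's signature is projected
onto a human cohort and judged against guideline TG thresholds.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .opls import OPLSDA, model_quality
from .preprocess import qc_block_normalize
from .screen import mann_whitney, screen_features
from .simulate import (
    HumanCohortSpec,
    default_preclinical_spec,
    default_urine_spec,
    simulate_human_cohort,
    simulate_preclinical,
    simulate_urine_null,
)
from .tables import FeatureTable
from .translate import (
    confusion_report,
    guideline_classify,
    project_cohort,
    select_signature,
    subgroup_compare,
)

DEFAULT_CONFIG = {
    "seed": 0,
    "alpha": 0.05,
    "q_max": 0.05,
    "vip_min": 1.0,
    "fc_min": 2.0,
    "fdr_max": 0.1,
    "folds": 7,
    "n_perm": 199,
    "n_pred": 1,
    "n_ortho": 1,
    "tg_threshold": 1.7,
    "mode": "full",
    "min_coverage": 0.8,
    "prevalence_at_risk": 0.5,
    "signature_effect": 1.4,
    "n_subjects": 140,
}


def resolve_config(overrides: dict | None = None) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    if overrides:
        unknown = set(overrides) - set(DEFAULT_CONFIG)
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        cfg.update({k: v for k, v in overrides.items() if v is not None})
    return cfg


@dataclass
class RunReport:
    """Per-stage summaries plus config echo; serializes to JSON."""

    config: dict
    stages: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def add_stage(self, name: str, summary: dict, elapsed: float) -> None:
        self.stages[name] = {**summary, "wall_time_s": round(elapsed, 3)}

    def to_dict(self) -> dict:
        return {
            "version": __version__,
            "config": self.config,
            "stages": self.stages,
            "warnings": self.warnings,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def run_pipeline(config: dict | None = None, outdir=None) -> RunReport:
    """Run the full seeded workflow on synthetic cohorts.

    Returns a :class:`RunReport`; when ``outdir`` is given, all stage
    tables and the fitted model are also written there as CSV/JSON.
    """
    cfg = resolve_config(config)
    seed = int(cfg["seed"])
    report = RunReport(config=cfg)
    out = _StageWriter(outdir)

    # -- simulate -------------------------------------------------------
    t0 = time.perf_counter()
    plasma, plasma_truth = simulate_preclinical(default_preclinical_spec(seed=seed))
    urine, _ = simulate_urine_null(default_urine_spec(seed=seed))
    report.add_stage("simulate", {
        "plasma_samples": plasma.n_samples, "plasma_features": plasma.n_features,
        "urine_samples": urine.n_samples, "urine_features": urine.n_features,
    }, time.perf_counter() - t0)
    out.table("plasma_raw", plasma)
    out.table("urine_raw", urine)

    # -- preprocess -----------------------------------------------------
    t0 = time.perf_counter()
    plasma_norm, norm_report = qc_block_normalize(plasma)
    report.add_stage("preprocess", {
        "dropped_features": len(norm_report.dropped_features),
        "blocks": int(plasma.samples["block"].nunique()),
    }, time.perf_counter() - t0)
    out.table("plasma_normalized", plasma_norm)

    # -- univariate screen ----------------------------------------------
    t0 = time.perf_counter()
    screen = screen_features(plasma_norm)
    report.add_stage("screen", screen.summary_dict(), time.perf_counter() - t0)
    out.csv("univariate_screen", screen.table)

    # -- fit + validate plasma model -------------------------------------
    t0 = time.perf_counter()
    res = OPLSDA.from_feature_table(plasma_norm).fit(
        n_pred=cfg["n_pred"], n_ortho=cfg["n_ortho"]
    )
    res.cross_validate(folds=cfg["folds"], seed=seed)
    res.permutation_test(n_perm=cfg["n_perm"], folds=cfg["folds"], seed=seed)
    plasma_diag = res.diagnostics.to_dict()
    report.add_stage("fit_plasma", plasma_diag, time.perf_counter() - t0)
    out.json("plasma_model", res.to_dict())

    # -- urine branch: expect rejection ----------------------------------
    t0 = time.perf_counter()
    urine_res = OPLSDA.from_feature_table(urine).fit(
        n_pred=cfg["n_pred"], n_ortho=cfg["n_ortho"]
    )
    urine_res.cross_validate(folds=cfg["folds"], seed=seed)
    urine_res.permutation_test(n_perm=cfg["n_perm"], folds=cfg["folds"], seed=seed)
    urine_diag = urine_res.diagnostics.to_dict()
    report.add_stage("fit_urine", urine_diag, time.perf_counter() - t0)
    if not urine_diag["rejected"]:
        report.warnings.append("urine null branch was not rejected under this seed")

    # -- signature -------------------------------------------------------
    t0 = time.perf_counter()
    signature = select_signature(screen, res.vip(), q_max=cfg["q_max"], vip_min=cfg["vip_min"])
    planted = plasma_truth.effects[plasma_truth.effects != 1.0].index
    recovered = len(set(signature.members) & set(planted))
    report.add_stage("select", {
        "signature_size": len(signature),
        "planted_effects": int(len(planted)),
        "planted_recovered": recovered,
    }, time.perf_counter() - t0)
    out.csv("signature", signature.table)

    # -- human cohort + projection ---------------------------------------
    t0 = time.perf_counter()
    human_spec = HumanCohortSpec(
        n_subjects=cfg["n_subjects"], prevalence_at_risk=cfg["prevalence_at_risk"],
        signature_effect=cfg["signature_effect"], seed=seed,
    )
    human, clinical, human_truth = simulate_human_cohort(human_spec, signature)
    proj_model, classification = project_cohort(
        plasma_norm, human, mode=cfg["mode"], signature=signature,
        min_coverage=cfg["min_coverage"], n_pred=cfg["n_pred"], n_ortho=cfg["n_ortho"],
    )
    category, guideline_risk = guideline_classify(clinical["tg_mmol_l"].to_numpy())
    classification["guideline_category"] = category
    classification["guideline_risk"] = guideline_risk
    truth_risk = (human_truth.labels == "at_risk").to_numpy()
    model_risk = classification["at_risk"].to_numpy()
    bal_acc = 0.5 * (
        np.mean(model_risk[truth_risk]) + np.mean(~model_risk[~truth_risk])
    )
    report.add_stage("project", {
        "n_subjects": int(len(classification)),
        "model_at_risk": int(model_risk.sum()),
        "model_healthy": int((~model_risk).sum()),
        "balanced_accuracy_vs_truth": float(bal_acc),
    }, time.perf_counter() - t0)
    out.csv("human_classification", classification)
    out.csv("human_clinical", clinical)

    # -- evaluate vs guidelines ------------------------------------------
    t0 = time.perf_counter()
    confusion = confusion_report(model_risk, guideline_risk)
    subgroup = subgroup_compare(classification, clinical, human,
                                fc_min=cfg["fc_min"], fdr_max=cfg["fdr_max"])
    report.add_stage("evaluate", {
        "confusion": confusion.to_dict(),
        "subgroup": subgroup.to_dict(),
    }, time.perf_counter() - t0)

    out.json("run_report", report.to_dict())
    return report


class _StageWriter:
    """Optional CSV/JSON persistence of stage artifacts."""

    def __init__(self, outdir):
        self.outdir = outdir
        if outdir is not None:
            import os
            os.makedirs(outdir, exist_ok=True)

    def _path(self, name, ext):
        import os
        return os.path.join(self.outdir, f"{name}.{ext}")

    def table(self, name: str, table: FeatureTable) -> None:
        if self.outdir is not None:
            table.to_csv(self._path(name, "csv"))

    def csv(self, name: str, frame: pd.DataFrame) -> None:
        if self.outdir is not None:
            frame.to_csv(self._path(name, "csv"))

    def json(self, name: str, doc: dict) -> None:
        if self.outdir is not None:
            with open(self._path(name, "json"), "w") as fh:
                json.dump(doc, fh, indent=2, default=_jsonable)


# ---------------------------------------------------------------------------
# Cohort summary (biometrics-style table)
# ---------------------------------------------------------------------------

def cohort_summary(
    clinical: pd.DataFrame,
    groups: pd.Series,
    metabolite_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Mean ± SEM per group with a between-group test per variable.

    Clinical/biometric variables use Welch's two-sample t-test;
    metabolite-derived columns (listed in ``metabolite_columns``) use the
    Mann-Whitney test. Zero-variance variables get a missing p with a
    warning flag.
    """
    labels = groups.loc[clinical.index]
    uniq = list(pd.unique(labels))
    if len(uniq) != 2:
        raise ValueError(f"expected two groups, found {uniq}")
    metabolite_columns = set(metabolite_columns or [])
    g1 = clinical.loc[labels == uniq[0]]
    g2 = clinical.loc[labels == uniq[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs >= 2 subjects")
    rows = []
    for col in clinical.columns:
        if not pd.api.types.is_numeric_dtype(clinical[col]):
            continue
        a = g1[col].dropna().to_numpy(dtype=float)
        b = g2[col].dropna().to_numpy(dtype=float)
        row = {
            "variable": col,
            f"mean_{uniq[0]}": a.mean(),
            f"sem_{uniq[0]}": a.std(ddof=1) / np.sqrt(len(a)),
            f"mean_{uniq[1]}": b.mean(),
            f"sem_{uniq[1]}": b.std(ddof=1) / np.sqrt(len(b)),
        }
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            row["p_value"] = np.nan
            row["test"] = "skipped (zero variance)"
        elif col in metabolite_columns:
            _, p = mann_whitney(a, b)
            row["p_value"] = p
            row["test"] = "mann-whitney"
        else:
            _, p = stats.ttest_ind(a, b, equal_var=False)
            row["p_value"] = float(p)
            row["test"] = "welch-t"
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable")
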