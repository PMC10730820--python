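"""Per-metabolite two-group statistics and clinical metabolic indices.

The univariate screen applies the Mann-Whitney U test per metabolite,
Benjamini-Hochberg FDR correction across metabolites, and fold change
(case mean / control mean); :func:`volcano_select` then applies the
joint fold-change / FDR selection rule. Fasting-state insulin indices
(HOMA-IR, HOMA-beta, R-QUICKI) are computed by :func:`clinical_indices`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import FeatureTable

_P_FLOOR = np.finfo(float).tiny  # p-values are never reported as 0


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    U counts pairs with ``x_i > y_j`` plus half-ties. The p-value is the
    exact enumeration when the pooled sample is small (n1 + n2 <= 12) and
    untied, otherwise the tie-corrected normal approximation with
    continuity correction.

    Returns
    -------
    (U, p) : floats; p in (0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney requires non-empty groups")
    if x.size < 2 or y.size < 2:
        raise ValueError("mann_whitney requires at least 2 observations per group")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (pooled.size <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    p = min(float(res.pvalue), 1.0)
    return float(res.statistic), max(p, _P_FLOOR)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Input order is preserved; q is capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def fold_change(mean_case: float, mean_ctrl: float) -> float:
    """Fold change of the case group relative to control: case / control."""
    if mean_ctrl <= 0:
        raise ValueError(f"control mean must be > 0 for a fold change (got {mean_ctrl})")
    return float(mean_case) / float(mean_ctrl)


@dataclass
class UnivariateResult:
    """Per-metabolite screen output.

    ``table`` has one row per metabolite: group means and SEMs, U, p, q,
    FC (case/control) and the selection flags. ``case`` / ``control`` echo
    the group labels that defined the FC direction.
    """

    table: pd.DataFrame
    case: str
    control: str

    @property
    def n_significant_raw(self) -> int:
        return int(self.table["significant_raw"].sum())

    @property
    def n_significant_fdr(self) -> int:
        return int(self.table["significant_fdr"].sum())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="metabolite")

    def summary_dict(self) -> dict:
        return {
            "case": self.case,
            "control": self.control,
            "n_features": int(len(self.table)),
            "n_significant_raw": self.n_significant_raw,
            "n_significant_fdr": self.n_significant_fdr,
        }


def screen_features(
    table: FeatureTable, case: str = "case", control: str = "control"
) -> UnivariateResult:
    """Mann-Whitney + BH + fold change for every metabolite of a two-group table.

    QC samples are excluded. Metabolites with all values missing in either
    group are dropped with a warning; otherwise missing values are excluded
    pairwise.
    """
    data = table.non_qc()
    groups = set(data.group_labels().unique())
    if groups != {case, control}:
        if len(groups) > 2:
            raise ValueError(f"expected exactly two groups, found {sorted(map(str, groups))}")
        raise ValueError(f"groups {sorted(map(str, groups))} do not match case={case!r}, control={control!r}")
    mask_case = (data.group_labels() == case).to_numpy()
    mask_ctrl = (data.group_labels() == control).to_numpy()
    if mask_case.sum() < 3 or mask_ctrl.sum() < 3:
        raise ValueError("each group needs >= 3 samples")

    rows, names = [], []
    for m in data.feature_names:
        col = data.values[m].to_numpy()
        xc = col[mask_case]
        xk = col[mask_ctrl]
        xc = xc[~np.isnan(xc)]
        xk = xk[~np.isnan(xk)]
        if xc.size < 2 or xk.size < 2:
            warnings.warn(f"metabolite {m!r} dropped: insufficient non-missing values")
            continue
        u, p = mann_whitney(xc, xk)
        mean_case = float(xc.mean())
        mean_ctrl = float(xk.mean())
        fc = fold_change(mean_case, mean_ctrl) if mean_ctrl > 0 else np.nan
        rows.append({
            "mean_case": mean_case,
            "mean_ctrl": mean_ctrl,
            "sem_case": float(xc.std(ddof=1) / np.sqrt(xc.size)),
            "sem_ctrl": float(xk.std(ddof=1) / np.sqrt(xk.size)),
            "u_statistic": u,
            "p_value": p,
            "fold_change": fc,
        })
        names.append(m)

    out = pd.DataFrame(rows, index=pd.Index(names, name="metabolite"))
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    out["significant_raw"] = out["p_value"] < 0.05
    out["significant_fdr"] = out["q_value"] < 0.05
    return UnivariateResult(table=out, case=case, control=control)


def volcano_select(
    result: UnivariateResult, fc_min: float = 2.0, fdr_max: float = 0.1
) -> pd.DataFrame:
    """Joint fold-change / FDR selection (volcano-plot rule).

    A metabolite is selected iff ``FC >= fc_min`` or ``FC <= 1/fc_min``
    (two-sided, boundary inclusive) and ``q < fdr_max``. The direction is
    recorded relative to the case group.
    """
    t = result.table
    fc = t["fold_change"]
    passes_fc = (fc >= fc_min) | (fc <= 1.0 / fc_min)
    selected = passes_fc & (t["q_value"] < fdr_max)
    direction = np.where(fc >= 1.0, "up", "down")
    out = t[["fold_change", "q_value"]].copy()
    out["selected"] = selected
    out["direction"] = direction
    return out


@dataclass
class ClinicalIndices:
    """Fasting insulin-resistance indices (arbitrary units)."""

    homa_ir: float
    homa_beta: float | None
    r_quicki: float | None


def clinical_indices(
    glucose_mg_dl: float, insulin_ug_l: float, nefa_mmol_l: float | None = None
) -> ClinicalIndices:
    """HOMA-IR, HOMA-beta and R-QUICKI from fasting measurements.

    Glucose is converted mg/dL -> mmol/L (divide by 18); insulin is used in
    ug/L as measured. With G = glucose [mmol/L] and I = insulin [ug/L]:

    * HOMA-IR   = G * I / 22.5
    * HOMA-beta = 20 * I / (G - 3.5); undefined (None) when G <= 3.5
    * R-QUICKI  = 1 / (log10(glucose) + log10(insulin) + log10(NEFA));
      None when NEFA is not supplied.

    Note: under this convention R-QUICKI for typical fasting inputs lands
    near 0.55 rather than the ~0.59 often tabulated; published R-QUICKI
    values are sensitive to the insulin unit convention, which assays
    rarely state. The formula here is the standard literature definition
    applied to the stated units.
    """
    if glucose_mg_dl <= 0 or insulin_ug_l <= 0:
        raise ValueError("glucose and insulin must be > 0")
    g_mmol = glucose_mg_dl / 18.0
    homa_ir = g_mmol * insulin_ug_l / 22.5
    homa_beta = 20.0 * insulin_ug_l / (g_mmol - 3.5) if g_mmol > 3.5 else None
    r_quicki = None
    if nefa_mmol_l is not None:
        if nefa_mmol_l <= 0:
            raise ValueError("NEFA must be > 0")
        r_quicki = 1.0 / (np.log10(glucose_mg_dl) + np.log10(insulin_ug_l) + np.log10(nefa_mmol_l))
    return ClinicalIndices(homa_ir=float(homa_ir), homa_beta=homa_beta, r_quicki=r_quicki)
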