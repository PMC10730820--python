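"""Normalizations applied before statistics.

Three stages are exposed, each returning a new table plus a
:class:`NormalizationReport` describing exactly what was applied:

* :func:`qc_block_normalize` — multiplicative run-day drift correction for
  MS tables, anchoring each (block, metabolite) to the global QC mean;
* :func:`pqn_normalize` — probabilistic quotient normalization, the
  standard dilution correction for urine-like tables;
* :func:`zscore_columns` — per-metabolite standardization (sample SD,
  n-1 divisor).

Missing values are excluded pairwise from QC means and PQN ratios and are
never imputed here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import FeatureTable


@dataclass
class NormalizationReport:
    """Record of the correction factors a normalization applied."""

    method: str
    #: per-block, per-metabolite multiplicative factors (blocks x metabolites)
    block_factors: pd.DataFrame | None = None
    #: per-sample PQN dilution coefficients
    dilution_coefficients: pd.Series | None = None
    dropped_features: list[dict] = field(default_factory=list)
    dropped_samples: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        out: dict = {"method": self.method, "dropped_features": self.dropped_features,
                     "dropped_samples": self.dropped_samples}
        if self.block_factors is not None:
            out["block_factors"] = {str(b): row.to_dict() for b, row in self.block_factors.iterrows()}
        if self.dilution_coefficients is not None:
            out["dilution_coefficients"] = self.dilution_coefficients.to_dict()
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def qc_block_normalize(table: FeatureTable) -> tuple[FeatureTable, NormalizationReport]:
    """Correct inter-day (block) drift proportionately using QC samples.

    Each value is multiplied by ``global QC mean / block QC mean`` for its
    metabolite, so after correction the QC means agree across blocks. A
    metabolite whose QC mean is zero in some block cannot be anchored there
    and is dropped (recorded in the report).

    Raises
    ------
    ValueError
        If any block contains no QC sample.
    """
    samples, values = table.samples, table.values
    is_qc = samples["is_qc"].to_numpy()
    blocks = samples["block"]
    block_ids = blocks.unique()
    for b in block_ids:
        if not is_qc[(blocks == b).to_numpy()].any():
            raise ValueError(f"block {b!r} contains no QC sample; cannot anchor drift correction")

    qc_values = values.loc[is_qc]
    qc_blocks = blocks.loc[is_qc]
    # pairwise-complete means: NaN excluded
    block_means = qc_values.groupby(qc_blocks, sort=False).mean()
    global_means = qc_values.mean(axis=0)

    dropped = []
    keep = []
    for m in values.columns:
        if (block_means[m] == 0).any() or block_means[m].isna().any():
            bad = block_means.index[(block_means[m] == 0) | block_means[m].isna()].tolist()
            dropped.append({"feature": m, "reason": f"QC mean zero or undefined in block(s) {bad}"})
        else:
            keep.append(m)

    factors = global_means[keep] / block_means[keep]  # blocks x kept metabolites
    corrected = values[keep].copy()
    for b in block_ids:
        mask = (blocks == b).to_numpy()
        corrected.loc[mask] = corrected.loc[mask] * factors.loc[b]

    report = NormalizationReport(method="qc_block", block_factors=factors, dropped_features=dropped)
    return FeatureTable(samples, corrected), report


def pqn_normalize(
    table: FeatureTable, reference: str | pd.Series = "median"
) -> tuple[FeatureTable, NormalizationReport]:
    """Probabilistic quotient normalization.

    Each sample is divided by the median of its elementwise ratios to a
    reference spectrum, computed over features strictly positive in both.
    The reference defaults to the median spectrum of the non-QC samples;
    pass a sample id or an explicit spectrum to override.

    Raises
    ------
    ValueError
        If the reference has <= 50% positive entries, or a sample shares
        fewer than 3 positive features with it.
    """
    values = table.values
    if isinstance(reference, pd.Series):
        ref = reference.reindex(values.columns)
    elif reference == "median":
        ref = table.non_qc().values.median(axis=0)
    else:  # a sample id
        if reference not in values.index:
            raise KeyError(f"reference sample {reference!r} not in table")
        ref = values.loc[reference]
    ref = ref.astype(float)
    if (ref > 0).sum() <= 0.5 * len(ref):
        raise ValueError("PQN reference must have > 50% positive entries")

    coeffs = {}
    normalized = values.copy()
    for sid, row in values.iterrows():
        shared = (row > 0) & (ref > 0)
        if shared.sum() < 3:
            raise ValueError(f"sample {sid!r} shares < 3 positive features with the PQN reference")
        coeff = float(np.median(row[shared] / ref[shared]))
        coeffs[sid] = coeff
        normalized.loc[sid] = row / coeff

    report = NormalizationReport(
        method="pqn", dilution_coefficients=pd.Series(coeffs, name="dilution_coefficient")
    )
    return FeatureTable(table.samples, normalized), report


def zscore_columns(table: FeatureTable) -> FeatureTable:
    """Standardize each metabolite to mean 0, sample SD 1 (n-1 divisor).

    Raises
    ------
    ValueError
        Naming the offending column if its SD is zero.

    Notes
    -----
    The result is no longer an abundance table (values go negative), but
    keeps the FeatureTable layout for downstream export; the non-negativity
    check is bypassed deliberately.
    """
    values = table.values
    sd = values.std(axis=0, ddof=1)
    bad = sd.index[(sd == 0) | sd.isna()].tolist()
    if bad:
        raise ValueError(f"constant column(s), cannot z-score: {bad}")
    z = (values - values.mean(axis=0)) / sd
    out = FeatureTable.__new__(FeatureTable)  # skip non-negativity validation
    out.samples = table.samples.copy()
    out.values = z
    return out
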