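"""Tabular containers shared across the pipeline.

A :class:`FeatureTable` couples a samples-by-metabolites abundance matrix
(semi-quantified internal-standard response ratios, non-negative) with
per-sample metadata: cohort, group label, run-day block and QC flag.
Missing measurements are encoded as NaN, never as silent zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Metadata columns stored ahead of the abundance matrix in CSV exports.
METADATA_COLUMNS = ["cohort", "group", "block", "is_qc"]


@dataclass
class FeatureTable:
    """Samples x metabolites abundance matrix with sample metadata.

    Parameters
    ----------
    samples : pandas.DataFrame
        Indexed by sample id; columns ``cohort``, ``group``, ``block``,
        ``is_qc``. Missing metadata columns are filled with defaults.
    values : pandas.DataFrame
        Indexed by sample id (same order as ``samples``); one float column
        per metabolite. Values must be non-negative or NaN.
    """

    samples: pd.DataFrame
    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.samples = self.samples.copy()
        self.values = self.values.astype(float).copy()
        if not self.samples.index.equals(self.values.index):
            raise ValueError("samples and values must share an identical sample-id index")
        if self.samples.index.duplicated().any():
            dup = self.samples.index[self.samples.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate metabolite names: {dup}")
        for col, default in (("cohort", "unknown"), ("group", ""), ("block", 1), ("is_qc", False)):
            if col not in self.samples.columns:
                self.samples[col] = default
        self.samples = self.samples[METADATA_COLUMNS]
        self.samples["is_qc"] = self.samples["is_qc"].astype(bool)
        arr = self.values.to_numpy()
        if np.nanmin(arr, initial=np.inf) < 0:
            raise ValueError("FeatureTable abundances must be non-negative (use NaN for missing)")

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> pd.Index:
        return self.samples.index

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def non_qc(self) -> "FeatureTable":
        """Table restricted to study (non-QC) samples."""
        keep = ~self.samples["is_qc"]
        return FeatureTable(self.samples.loc[keep], self.values.loc[keep])

    def qc_only(self) -> "FeatureTable":
        keep = self.samples["is_qc"].astype(bool)
        return FeatureTable(self.samples.loc[keep], self.values.loc[keep])

    def subset_features(self, names: list[str]) -> "FeatureTable":
        missing = [n for n in names if n not in self.values.columns]
        if missing:
            raise KeyError(f"features not in table: {missing}")
        return FeatureTable(self.samples, self.values[names])

    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def group_labels(self) -> pd.Series:
        return self.samples["group"]

    # -- I/O -------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Flat frame: sample_id index, metadata columns first, then features."""
        return pd.concat([self.samples, self.values], axis=1)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="sample_id")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FeatureTable":
        meta_cols = [c for c in METADATA_COLUMNS if c in frame.columns]
        feature_cols = [c for c in frame.columns if c not in METADATA_COLUMNS]
        return cls(frame[meta_cols], frame[feature_cols])

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        frame = pd.read_csv(path, index_col="sample_id")
        frame.index.name = None
        return cls.from_frame(frame)


@dataclass
class TruthTable:
    """Ground truth attached to a simulated cohort.

    ``labels`` maps sample id to its latent class; ``effects`` maps
    metabolite name to the true multiplicative group effect. Extra
    per-sample nuisance parameters (e.g. urine dilution factors) live in
    ``sample_factors``.
    """

    labels: pd.Series
    effects: pd.Series
    sample_factors: pd.DataFrame | None = field(default=None)

    def to_csv(self, path) -> None:
        frame = self.labels.rename("latent_class").to_frame()
        if self.sample_factors is not None:
            frame = frame.join(self.sample_factors)
        frame.to_csv(path, index_label="sample_id")
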