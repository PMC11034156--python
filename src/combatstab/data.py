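"""Participant-by-feature container shared by every pipeline stage.

A :class:`FeatureTable` pairs a covariate frame (site, age, sex, diagnosis,
race, education, APOE2/4 status) with a dense participants x features value
matrix of ROI-level scalars (e.g. mean FA per white-matter region).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: covariate columns every table carries, in canonical order
COVARIATE_COLUMNS = [
    "participant_id",
    "site",
    "age",
    "sex",
    "diagnosis",
    "race",
    "education",
    "apoe2",
    "apoe4",
]


@dataclass
class FeatureTable:
    """Two-site cohort: covariates plus a participants x features matrix.

    Parameters
    ----------
    covariates
        One row per participant; must contain :data:`COVARIATE_COLUMNS`.
    values
        Float matrix, shape ``(n_participants, n_features)``, no missing
        entries.
    feature_names
        Column labels for ``values`` (default ``feat_001`` ...).
    """

    covariates: pd.DataFrame
    values: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (participants x features)")
        if len(self.covariates) != self.values.shape[0]:
            raise ValueError(
                f"covariate rows ({len(self.covariates)}) != value rows "
                f"({self.values.shape[0]})"
            )
        missing = [c for c in COVARIATE_COLUMNS if c not in self.covariates.columns]
        if missing:
            raise ValueError(f"missing covariate columns: {missing}")
        ids = self.covariates["participant_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate participant_id: {dup!r}")
        if np.isnan(self.values).any():
            raise ValueError("values matrix contains missing entries")
        if not self.feature_names:
            self.feature_names = [
                f"feat_{j + 1:03d}" for j in range(self.values.shape[1])
            ]
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError("feature_names length != number of feature columns")
        self.covariates = self.covariates.reset_index(drop=True)

    # -- derived quantities -------------------------------------------------

    @property
    def n_participants(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def sites(self) -> list:
        """Site labels in order of first appearance."""
        return list(pd.unique(self.covariates["site"]))

    def n_per_site(self) -> dict:
        """Participant count per site, ``{site: n_s}``."""
        counts = self.covariates["site"].value_counts()
        return {s: int(counts[s]) for s in self.sites}

    def site_mask(self, site) -> np.ndarray:
        return (self.covariates["site"] == site).to_numpy()

    def subset(self, row_index: np.ndarray) -> "FeatureTable":
        """Row-subset by positional index, preserving order of ``row_index``."""
        idx = np.asarray(row_index)
        return FeatureTable(
            covariates=self.covariates.iloc[idx].reset_index(drop=True),
            values=self.values[idx],
            feature_names=list(self.feature_names),
        )

    # -- CSV round trip -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        feat = pd.DataFrame(self.values, columns=self.feature_names)
        return pd.concat(
            [self.covariates[COVARIATE_COLUMNS].reset_index(drop=True), feat], axis=1
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FeatureTable":
        feature_names = [c for c in frame.columns if c not in COVARIATE_COLUMNS]
        return cls(
            covariates=frame[COVARIATE_COLUMNS].copy(),
            values=frame[feature_names].to_numpy(dtype=float),
            feature_names=feature_names,
        )

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        return cls.from_frame(pd.read_csv(path))
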