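"""Cohort-level expression containers and their on-disk TSV representation.

A cohort (one study / one platform) is held as an :class:`ExpressionDataset`:
a log-scale expression matrix (features x samples) together with per-sample
clinical annotations.  Features may be probes or genes; the probe module
collapses the former to the latter.  All pipeline stages exchange these
objects, or the TSV files they round-trip through.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

#: canonical condition labels
CONDITION_CASE = "PD"
CONDITION_CONTROL = "control"
SEXES = ("F", "M")

REQUIRED_SAMPLE_COLUMNS = ("condition", "sex")


@dataclass
class ExpressionDataset:
    """One cohort's log-scale expression matrix plus sample annotations.

    Parameters
    ----------
    dataset_id:
        Unique cohort identifier.
    expression:
        DataFrame of log2-scale intensities, rows = features (probes or
        genes), columns = sample ids.
    samples:
        DataFrame indexed by sample id with at least ``condition``
        (``"PD"`` / ``"control"``) and ``sex`` (``"F"`` / ``"M"``);
        optionally ``age`` (years), ``batch`` (categorical) and
        ``subject`` (pairing/blocking identifier).
    """

    dataset_id: str
    expression: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.samples.index = self.samples.index.astype(str)
        self.expression.columns = self.expression.columns.astype(str)
        self.validate()

    def validate(self) -> None:
        if self.samples.index.has_duplicates:
            raise ValueError(f"{self.dataset_id}: duplicate sample ids")
        for col in REQUIRED_SAMPLE_COLUMNS:
            if col not in self.samples.columns:
                raise ValueError(f"{self.dataset_id}: missing sample column {col!r}")
            if self.samples[col].isna().any():
                raise ValueError(f"{self.dataset_id}: missing values in {col!r}")
        bad = set(self.samples["condition"]) - {CONDITION_CASE, CONDITION_CONTROL}
        if bad:
            raise ValueError(f"{self.dataset_id}: unknown condition labels {bad}")
        bad = set(self.samples["sex"]) - set(SEXES)
        if bad:
            raise ValueError(f"{self.dataset_id}: unknown sex labels {bad}")
        if set(self.expression.columns) != set(self.samples.index):
            raise ValueError(
                f"{self.dataset_id}: expression columns and sample metadata disagree"
            )
        if self.expression.index.has_duplicates:
            raise ValueError(f"{self.dataset_id}: duplicate feature ids")

    # -- convenience -------------------------------------------------------

    @property
    def features(self) -> pd.Index:
        return self.expression.index

    def sex_samples(self, sex: str) -> pd.Index:
        """Sample ids of the given sex, in metadata order."""
        return self.samples.index[self.samples["sex"] == sex]

    def group_sizes(self, sex: str) -> tuple[int, int]:
        """(#PD, #control) among samples of ``sex``."""
        sub = self.samples[self.samples["sex"] == sex]
        return (
            int((sub["condition"] == CONDITION_CASE).sum()),
            int((sub["condition"] == CONDITION_CONTROL).sum()),
        )

    def subset_features(self, features: Iterable[str]) -> "ExpressionDataset":
        feats = [f for f in features if f in self.expression.index]
        return ExpressionDataset(
            dataset_id=self.dataset_id,
            expression=self.expression.loc[feats],
            samples=self.samples.copy(),
        )

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, expression_path: str | Path, samples_path: str | Path) -> None:
        Path(expression_path).parent.mkdir(parents=True, exist_ok=True)
        self.expression.to_csv(expression_path, sep="\t", index_label="feature")
        self.samples.to_csv(samples_path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(
        cls,
        dataset_id: str,
        expression_path: str | Path,
        samples_path: str | Path,
    ) -> "ExpressionDataset":
        expr = pd.read_csv(expression_path, sep="\t", index_col=0)
        samples = pd.read_csv(samples_path, sep="\t", index_col=0)
        return cls(dataset_id=dataset_id, expression=expr, samples=samples)
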