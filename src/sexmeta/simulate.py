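"""Synthetic multi-cohort expression generator with planted sex effects.

The generator emulates the structure of a multi-study case/control
transcriptome collection: several cohorts with heterogeneous per-sex
patient/control counts, platform-specific gene coverage (whole genes
absent from individual cohorts), log-scale Gaussian intensities and
optional age / batch covariate effects.  Each gene carries a known
effect class so that every downstream stage (stratified DE, weighted
meta-analysis, sex-specificity classification) can be validated against
ground truth without any external download.

Effect classes
--------------
``null``
    no PD/control difference in either sex.
``shared``
    the same nonzero log2 effect in both sexes.
``female_specific`` / ``male_specific``
    a nonzero log2 effect in exactly one sex.
``dimorphic``
    nonzero effects of opposite sign in the two sexes.

Reproducibility: one :class:`numpy.random.SeedSequence` child per cohort
index (plus one for the ground truth) is spawned from the master seed, so
re-running with the same config is bit-identical and appending cohorts
does not perturb earlier ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .datasets import CONDITION_CASE, CONDITION_CONTROL, SEXES, ExpressionDataset

TRUTH_CLASSES = ("null", "shared", "female_specific", "male_specific", "dimorphic")
#: prediction label used by the classifier for the dimorphic truth class
_PREDICTED_ALIASES = {"candidate_dimorphic": "dimorphic"}
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class EffectClass:
    """Planted effect description: fraction of genes and per-sex log2 effects."""

    fraction: float
    lfc_female: float
    lfc_male: float


def _check_effect_class(name: str, spec: EffectClass) -> None:
    f, m = spec.lfc_female, spec.lfc_male
    if name == "shared" and (f == 0 or m == 0 or math.copysign(1, f) != math.copysign(1, m)):
        raise ValueError("shared effects must be nonzero with equal sign")
    if name == "female_specific" and not (f != 0 and m == 0):
        raise ValueError("female_specific effects must be nonzero only in females")
    if name == "male_specific" and not (m != 0 and f == 0):
        raise ValueError("male_specific effects must be nonzero only in males")
    if name == "dimorphic" and not (f * m < 0):
        raise ValueError("dimorphic effects must be nonzero with opposite signs")


Counts = Mapping[tuple[str, str], int]


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of a synthetic multi-cohort collection.

    Parameters
    ----------
    n_datasets:
        Number of cohorts.
    n_genes:
        Gene universe size ``G``.
    counts:
        Samples per (sex, condition) cell; either one mapping applied to
        every cohort or a sequence of ``n_datasets`` mappings.  Keys are
        ``(sex, condition)`` with sex in {"F","M"} and condition in
        {"PD","control"}.
    effect_classes:
        Mapping class name -> :class:`EffectClass`; fractions must sum to
        <= 1, the remainder of the genes is null.
    noise_sd:
        Log-scale Gaussian noise SD (> 0).
    missing_gene_fraction:
        Per-cohort fraction of genes dropped entirely (platform coverage);
        scalar or one value per cohort, each in [0, 1).
    age_slope:
        Log2 expression change per year of age (0 disables the age column).
    batch_offset:
        If nonzero, each cohort is split into two batches and the second
        batch is shifted by this log2 amount (0 disables the batch column).
    baseline_range:
        Per-gene baseline mean expression drawn uniformly from this
        log2-scale interval.
    seed:
        Master seed for all randomness.
    """

    n_datasets: int = 12
    n_genes: int = 2000
    counts: Counts | Sequence[Counts] = field(
        default_factory=lambda: {
            ("F", CONDITION_CASE): 8,
            ("F", CONDITION_CONTROL): 8,
            ("M", CONDITION_CASE): 16,
            ("M", CONDITION_CONTROL): 16,
        }
    )
    effect_classes: Mapping[str, EffectClass] = field(default_factory=dict)
    noise_sd: float = 0.5
    missing_gene_fraction: float | Sequence[float] = 0.0
    age_slope: float = 0.0
    batch_offset: float = 0.0
    baseline_range: tuple[float, float] = (4.0, 12.0)
    seed: int = 0

    # -- derived views -----------------------------------------------------

    def counts_for(self, index: int) -> Counts:
        if isinstance(self.counts, Mapping):
            return self.counts
        return self.counts[index]

    def missing_for(self, index: int) -> float:
        if np.isscalar(self.missing_gene_fraction):
            return float(self.missing_gene_fraction)  # type: ignore[arg-type]
        return float(self.missing_gene_fraction[index])  # type: ignore[index]

    def validate(self) -> None:
        if self.n_datasets < 1 or self.n_genes < 1:
            raise ValueError("n_datasets and n_genes must be positive")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be > 0")
        if not isinstance(self.counts, Mapping) and len(self.counts) != self.n_datasets:
            raise ValueError("per-dataset counts must have one entry per dataset")
        total = 0.0
        for name, spec in self.effect_classes.items():
            if name not in TRUTH_CLASSES or name == "null":
                raise ValueError(f"unknown effect class {name!r}")
            if not 0 <= spec.fraction <= 1:
                raise ValueError("effect-class fractions must be in [0, 1]")
            _check_effect_class(name, spec)
            total += spec.fraction
        if total > 1 + 1e-12:
            raise ValueError("effect-class fractions must sum to <= 1")
        for d in range(self.n_datasets):
            cells = self.counts_for(d)
            for sex in SEXES:
                for cond in (CONDITION_CASE, CONDITION_CONTROL):
                    n = cells.get((sex, cond), 0)
                    if n < 0:
                        raise ValueError("sample counts must be >= 0")
                    if n == 0:
                        raise ValueError(
                            f"dataset {d}: zero samples in required cell ({sex}, {cond})"
                        )
            miss = self.missing_for(d)
            if not 0 <= miss < 1:
                raise ValueError("missing_gene_fraction must be in [0, 1)")

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "n_datasets": self.n_datasets,
            "n_genes": self.n_genes,
            "counts": (
                {f"{s}:{c}": int(n) for (s, c), n in self.counts.items()}
                if isinstance(self.counts, Mapping)
                else [{f"{s}:{c}": int(n) for (s, c), n in cell.items()} for cell in self.counts]
            ),
            "effect_classes": {
                name: {
                    "fraction": spec.fraction,
                    "lfc_female": spec.lfc_female,
                    "lfc_male": spec.lfc_male,
                }
                for name, spec in self.effect_classes.items()
            },
            "noise_sd": self.noise_sd,
            "missing_gene_fraction": (
                float(self.missing_gene_fraction)
                if np.isscalar(self.missing_gene_fraction)
                else [float(x) for x in self.missing_gene_fraction]
            ),
            "age_slope": self.age_slope,
            "batch_offset": self.batch_offset,
            "baseline_range": list(self.baseline_range),
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        doc = yaml.safe_load(Path(path).read_text())

        def parse_cells(d: Mapping[str, int]) -> Counts:
            return {tuple(k.split(":")): int(v) for k, v in d.items()}  # type: ignore[misc]

        counts = doc["counts"]
        counts = (
            parse_cells(counts) if isinstance(counts, Mapping) else [parse_cells(c) for c in counts]
        )
        classes = {
            name: EffectClass(spec["fraction"], spec["lfc_female"], spec["lfc_male"])
            for name, spec in doc.get("effect_classes", {}).items()
        }
        return cls(
            n_datasets=doc["n_datasets"],
            n_genes=doc["n_genes"],
            counts=counts,
            effect_classes=classes,
            noise_sd=doc["noise_sd"],
            missing_gene_fraction=doc.get("missing_gene_fraction", 0.0),
            age_slope=doc.get("age_slope", 0.0),
            batch_offset=doc.get("batch_offset", 0.0),
            baseline_range=tuple(doc.get("baseline_range", (4.0, 12.0))),
            seed=doc.get("seed", 0),
        )


@dataclass
class GroundTruth:
    """Per-gene planted class label and true per-sex log2 effects."""

    labels: pd.Series  # gene -> class name
    lfc_female: pd.Series
    lfc_male: pd.Series

    @property
    def genes(self) -> pd.Index:
        return self.labels.index

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.labels,
                "true_lfc_f": self.lfc_female,
                "true_lfc_m": self.lfc_male,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GroundTruth":
        df = pd.read_csv(path, sep="\t", index_col="gene")
        return cls(df["label"], df["true_lfc_f"], df["true_lfc_m"])


# ---------------------------------------------------------------------------
# generation


def _gene_names(n: int) -> pd.Index:
    width = max(4, len(str(n - 1)))
    return pd.Index([f"G{i:0{width}d}" for i in range(n)], name="gene")


def generate_cohorts(
    config: SimulationConfig,
) -> tuple[list[ExpressionDataset], GroundTruth]:
    """Simulate a multi-cohort collection with known per-gene effects.

    Returns one :class:`ExpressionDataset` per cohort (gene-level features)
    and the :class:`GroundTruth`.  Deterministic given ``config`` (including
    its ``seed``).
    """
    config.validate()
    master = np.random.SeedSequence(config.seed)
    children = master.spawn(config.n_datasets + 1)
    truth_rng = np.random.default_rng(children[0])

    genes = _gene_names(config.n_genes)
    G = config.n_genes

    # class assignment: contiguous blocks of a random permutation
    labels = np.array(["null"] * G, dtype=object)
    lfc_f = np.zeros(G)
    lfc_m = np.zeros(G)
    order = truth_rng.permutation(G)
    start = 0
    for name, spec in config.effect_classes.items():
        k = int(round(spec.fraction * G))
        idx = order[start : start + k]
        labels[idx] = name
        lfc_f[idx] = spec.lfc_female
        lfc_m[idx] = spec.lfc_male
        start += k
    truth = GroundTruth(
        labels=pd.Series(labels, index=genes, name="label"),
        lfc_female=pd.Series(lfc_f, index=genes, name="true_lfc_f"),
        lfc_male=pd.Series(lfc_m, index=genes, name="true_lfc_m"),
    )

    lo, hi = config.baseline_range
    baseline = truth_rng.uniform(lo, hi, size=G)

    datasets: list[ExpressionDataset] = []
    for d in range(config.n_datasets):
        rng = np.random.default_rng(children[d + 1])
        ds_id = f"sim{d:02d}"
        cells = config.counts_for(d)

        sample_ids: list[str] = []
        sexes: list[str] = []
        conditions: list[str] = []
        for sex in SEXES:
            for cond in (CONDITION_CASE, CONDITION_CONTROL):
                n = int(cells[(sex, cond)])
                for k in range(n):
                    sample_ids.append(f"{ds_id}_{sex}_{cond}_{k:03d}")
                    sexes.append(sex)
                    conditions.append(cond)
        n_samples = len(sample_ids)

        meta = pd.DataFrame(
            {"condition": conditions, "sex": sexes},
            index=pd.Index(sample_ids, name="sample_id"),
        )
        covariate_shift = np.zeros(n_samples)
        if config.age_slope != 0.0:
            age = rng.normal(70.0, 8.0, size=n_samples)
            meta["age"] = np.round(age, 1)
            covariate_shift += config.age_slope * (meta["age"].to_numpy() - 70.0)
        if config.batch_offset != 0.0:
            batch = rng.integers(0, 2, size=n_samples)
            meta["batch"] = np.where(batch == 1, "b1", "b0")
            covariate_shift += config.batch_offset * batch

        is_case = (meta["condition"] == CONDITION_CASE).to_numpy()
        is_female = (meta["sex"] == "F").to_numpy()
        effect = np.where(is_female, lfc_f[:, None], lfc_m[:, None]) * is_case[None, :]

        values = (
            baseline[:, None]
            + effect
            + covariate_shift[None, :]
            + rng.normal(0.0, config.noise_sd, size=(G, n_samples))
        )
        expr = pd.DataFrame(values, index=genes, columns=sample_ids)

        miss = config.missing_for(d)
        if miss > 0:
            n_drop = int(round(miss * G))
            dropped = rng.choice(G, size=n_drop, replace=False)
            keep = np.setdiff1d(np.arange(G), dropped)
            expr = expr.iloc[keep]

        datasets.append(ExpressionDataset(dataset_id=ds_id, expression=expr, samples=meta))

    return datasets, truth


# ---------------------------------------------------------------------------
# canonical study conditions


def null_config(seed: int = 0, n_datasets: int = 6, n_genes: int = 2000) -> SimulationConfig:
    """All-null collection used for calibration checks: 6 cohorts, G=2000,
    20 samples per sex x condition cell, no planted effects."""
    counts = {
        (s, c): 20 for s in SEXES for c in (CONDITION_CASE, CONDITION_CONTROL)
    }
    return SimulationConfig(
        n_datasets=n_datasets,
        n_genes=n_genes,
        counts=counts,
        effect_classes={},
        noise_sd=0.5,
        seed=seed,
    )


def recovery_config(seed: int = 0) -> SimulationConfig:
    """Planted-effect collection used for end-to-end recovery checks.

    6 cohorts, 40 samples per sex x condition cell, noise SD 0.5, and 50
    genes in each of the four non-null classes with |log2 effect| = 1,
    out of G = 1200 genes.  The gene universe is kept deliberately compact
    so that planted effects occupy a realistic fraction of the ranked list
    while the simulation stays desk-scale.
    """
    G = 1200
    frac = 50 / G
    classes = {
        "shared": EffectClass(frac, 1.0, 1.0),
        "female_specific": EffectClass(frac, 1.0, 0.0),
        "male_specific": EffectClass(frac, 0.0, 1.0),
        "dimorphic": EffectClass(frac, -1.0, 1.0),
    }
    counts = {
        (s, c): 40 for s in SEXES for c in (CONDITION_CASE, CONDITION_CONTROL)
    }
    return SimulationConfig(
        n_datasets=6,
        n_genes=G,
        counts=counts,
        effect_classes=classes,
        noise_sd=0.5,
        missing_gene_fraction=0.1,
        seed=seed,
    )


def study_like_config(seed: int = 0) -> SimulationConfig:
    """Default study-shaped collection: 12 cohorts with heterogeneous,
    male-skewed sample counts and platform-specific gene coverage."""
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    counts = []
    for _ in range(12):
        f_pd = int(rng.integers(3, 9))
        f_ct = int(rng.integers(3, 9))
        counts.append(
            {
                ("F", CONDITION_CASE): f_pd,
                ("F", CONDITION_CONTROL): f_ct,
                ("M", CONDITION_CASE): int(rng.integers(6, 18)),
                ("M", CONDITION_CONTROL): int(rng.integers(6, 18)),
            }
        )
    frac = 50 / 2000
    classes = {
        "shared": EffectClass(frac, 1.0, 1.0),
        "female_specific": EffectClass(frac, 1.0, 0.0),
        "male_specific": EffectClass(frac, 0.0, 1.0),
        "dimorphic": EffectClass(frac, -1.0, 1.0),
    }
    return SimulationConfig(
        n_datasets=12,
        n_genes=2000,
        counts=counts,
        effect_classes=classes,
        noise_sd=0.5,
        missing_gene_fraction=[float(x) for x in rng.uniform(0.0, 0.25, size=12)],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# evaluation against truth


def truth_confusion(
    predicted: Mapping[str, str] | pd.Series,
    truth: GroundTruth,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Confusion matrix and per-class sensitivity / false-discovery rate.

    ``predicted`` maps every gene of the truth universe to a predicted
    label (classifier labels; ``candidate_dimorphic`` is matched to the
    ``dimorphic`` truth class, missing/NaN counts as unclassified).

    Returns
    -------
    confusion:
        rows = true classes, columns = predicted classes + "unclassified";
        row sums equal true class sizes.
    summary:
        per non-null class: n_true, n_predicted, sensitivity, fdr.
    """
    pred = pd.Series(predicted).astype(object)
    if set(pred.index) != set(truth.genes):
        raise ValueError("predicted labels and ground truth cover different gene universes")
    pred = pred.reindex(truth.genes)
    pred = pred.where(pred.notna(), UNCLASSIFIED)
    pred = pred.replace(_PREDICTED_ALIASES)

    pred_cols = list(TRUTH_CLASSES) + [UNCLASSIFIED]
    pred = pred.where(pred.isin(pred_cols), UNCLASSIFIED)
    confusion = pd.crosstab(truth.labels, pred).reindex(
        index=list(TRUTH_CLASSES), columns=pred_cols, fill_value=0
    )
    confusion.index.name = "true"
    confusion.columns.name = "predicted"

    rows = {}
    for cls in TRUTH_CLASSES:
        if cls == "null":
            continue
        n_true = int(confusion.loc[cls].sum())
        n_pred = int(confusion[cls].sum())
        tp = int(confusion.loc[cls, cls])
        rows[cls] = {
            "n_true": n_true,
            "n_predicted": n_pred,
            "sensitivity": tp / n_true if n_true else float("nan"),
            "fdr": (n_pred - tp) / n_pred if n_pred else float("nan"),
        }
    return confusion, pd.DataFrame(rows).T


def write_cohorts(
    datasets: Sequence[ExpressionDataset],
    truth: GroundTruth,
    config: SimulationConfig,
    outdir: str | Path,
) -> Path:
    """Write a simulated collection as TSV files plus a YAML config copy.

    Layout: ``<outdir>/<dataset_id>.expression.tsv``,
    ``<outdir>/<dataset_id>.samples.tsv``, ``truth.tsv``, ``config.yaml``.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for ds in datasets:
        ds.to_tsv(out / f"{ds.dataset_id}.expression.tsv", out / f"{ds.dataset_id}.samples.tsv")
    truth.to_tsv(out / "truth.tsv")
    config.to_yaml(out / "config.yaml")
    return out
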