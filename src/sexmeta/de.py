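"""Per-cohort, per-sex differential expression on log-scale intensities.

The engine is a gene-wise ordinary least-squares linear model

    expression ~ condition (+ age + batch + subject)

fit simultaneously for all genes of one cohort using only samples of the
requested sex.  The reported statistics are exactly what the integration
layer consumes: the condition coefficient (log2 fold change, PD minus
control), its two-sided t-test p-value, and the mean expression.

Optional empirical-Bayes variance moderation (``moderated=True``)
shrinks per-gene residual variances toward a pooled prior fitted by
moment matching on the log variances, increasing the residual degrees
of freedom accordingly — useful for small cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .datasets import CONDITION_CASE, CONDITION_CONTROL, ExpressionDataset

KNOWN_COVARIATES = ("age", "batch", "subject")


@dataclass
class SexStratifiedDEResult:
    """Differential expression summary for one (dataset, sex) analysis.

    ``table`` is indexed by gene with columns ``lfc`` (log2, PD minus
    control), ``p`` (two-sided; NaN for degenerate genes) and
    ``mean_expr``.
    """

    dataset_id: str
    sex: str
    table: pd.DataFrame
    n_case: int
    n_control: int
    model_terms: tuple[str, ...]

    @property
    def effective_n(self) -> int:
        return min(self.n_case, self.n_control)

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out["n_case"] = self.n_case
        out["n_control"] = self.n_control
        out.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, path: str | Path, dataset_id: str, sex: str) -> "SexStratifiedDEResult":
        df = pd.read_csv(path, sep="\t", index_col="gene")
        n_case = int(df["n_case"].iloc[0])
        n_control = int(df["n_control"].iloc[0])
        return cls(
            dataset_id=dataset_id,
            sex=sex,
            table=df[["lfc", "p", "mean_expr"]],
            n_case=n_case,
            n_control=n_control,
            model_terms=("condition",),
        )


def compute_effective_n(dataset: ExpressionDataset, sex: str) -> int:
    """min(#PD, #control) among samples of the given sex (0 if a group is empty)."""
    n_case, n_control = dataset.group_sizes(sex)
    return min(n_case, n_control)


# ---------------------------------------------------------------------------
# design matrix


def _design_matrix(meta: pd.DataFrame, covariates: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    cols: list[np.ndarray] = [np.ones(len(meta))]
    names = ["intercept"]
    cols.append((meta["condition"] == CONDITION_CASE).to_numpy(float))
    names.append("condition")
    for term in covariates:
        if term not in meta.columns:
            raise ValueError(f"covariate {term!r} not present in sample metadata")
        if meta[term].isna().any():
            raise ValueError(f"covariate {term!r} has missing values")
        if term == "age":
            age = meta[term].to_numpy(float)
            cols.append(age - age.mean())
            names.append("age")
        else:
            # categorical blocking factor: one dummy per non-reference level
            values = meta[term].astype(str)
            levels = sorted(values.unique())
            for level in levels[1:]:
                cols.append((values == level).to_numpy(float))
                names.append(f"{term}[{level}]")
    return np.column_stack(cols), names


# ---------------------------------------------------------------------------
# empirical-Bayes variance moderation (moment matching on log variances)


def _trigamma_inverse(y: float) -> float:
    # Newton on trigamma(x) = y; trigamma is decreasing and convex on (0, inf)
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        step = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + step
        if abs(step) < 1e-10 * x:
            break
    return float(x)


def _squeeze_var(s2: np.ndarray, df: float) -> tuple[np.ndarray, float]:
    """Shrink per-gene variances toward a fitted scaled-F prior.

    Returns posterior variances and the prior degrees of freedom ``d0``
    (np.inf when the observed log variances are under-dispersed relative
    to pure chi-square sampling noise).
    """
    ok = s2 > 0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) if e.size > 1 else 0.0
    rhs = e_var - float(special.polygamma(1, df / 2.0))
    if rhs > 0:
        d0 = 2.0 * _trigamma_inverse(rhs)
        s02 = np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
        post = (d0 * s02 + df * s2) / (d0 + df)
    else:
        d0 = np.inf
        s02 = np.exp(e_mean)
        post = np.full_like(s2, s02)
    return post, d0


# ---------------------------------------------------------------------------
# main fit


def run_stratified_de(
    dataset: ExpressionDataset,
    sex: str,
    covariates: Sequence[str] = (),
    moderated: bool = False,
) -> SexStratifiedDEResult:
    """Fit gene-wise linear models on the samples of one sex.

    Parameters
    ----------
    dataset:
        Cohort with gene- (or probe-) level log expression.
    sex:
        "F" or "M"; only samples of this sex enter the model.
    covariates:
        Optional metadata terms: ``age`` (numeric, centered), ``batch``
        and/or ``subject`` (categorical dummies; ``subject`` implements
        paired designs as a fixed blocking factor).
    moderated:
        Apply empirical-Bayes variance moderation before the t-test.

    Raises
    ------
    ValueError
        On fewer than 2 PD or 2 control samples of the sex, a singular
        design, or more model parameters than samples.
    """
    samples = dataset.samples[dataset.samples["sex"] == sex]
    n_case = int((samples["condition"] == CONDITION_CASE).sum())
    n_control = int((samples["condition"] == CONDITION_CONTROL).sum())
    if n_case < 2 or n_control < 2:
        raise ValueError(
            f"{dataset.dataset_id}/{sex}: need >=2 PD and >=2 control samples "
            f"(got {n_case}/{n_control})"
        )

    X, names = _design_matrix(samples, covariates)
    n, p = X.shape
    if n <= p:
        raise ValueError(
            f"{dataset.dataset_id}/{sex}: {n} samples cannot identify {p} model parameters"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValueError(
            f"{dataset.dataset_id}/{sex}: singular design matrix "
            "(is condition constant within every block?)"
        )

    Y = dataset.expression[samples.index].to_numpy(float)  # G x n
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = (XtX_inv @ (X.T @ Y.T)).T  # G x p
    resid = Y - beta @ X.T
    df = n - p
    s2 = (resid**2).sum(axis=1) / df

    ci = names.index("condition")
    lfc = beta[:, ci]
    c_var = XtX_inv[ci, ci]

    if moderated:
        s2_used, d0 = _squeeze_var(s2, df)
        df_used = df + d0 if np.isfinite(d0) else np.inf
    else:
        s2_used, df_used = s2, df

    se = np.sqrt(s2_used * c_var)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / se
    if np.isfinite(df_used):
        pvals = 2.0 * stats.t.sf(np.abs(t), df_used)
    else:
        pvals = 2.0 * stats.norm.sf(np.abs(t))

    zero_var = s2_used <= 0
    if zero_var.any():
        warnings.warn(
            f"{dataset.dataset_id}/{sex}: {int(zero_var.sum())} gene(s) with zero "
            "residual variance; p reported as missing",
            RuntimeWarning,
            stacklevel=2,
        )
        pvals = np.where(zero_var, np.nan, pvals)
    # numerically exact p of 0 cannot occur for finite t; clip away from 0
    pvals = np.where(np.isnan(pvals), np.nan, np.clip(pvals, 5e-324, 1.0))

    table = pd.DataFrame(
        {"lfc": lfc, "p": pvals, "mean_expr": Y.mean(axis=1)},
        index=dataset.expression.index.copy(),
    )
    return SexStratifiedDEResult(
        dataset_id=dataset.dataset_id,
        sex=sex,
        table=table,
        n_case=n_case,
        n_control=n_control,
        model_terms=tuple(names),
    )
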