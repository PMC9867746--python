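"""Weighted cross-study integration of per-cohort DE statistics.

For each sex the per-cohort (LFC, p) pairs are combined into a single
cross-study record per gene:

* cohort weights  w_d = sqrt(n_d / sum_delta n_delta)  with
  n_d = min(#patients, #controls) for the sex — so sum of w^2 is 1;
* a consensus direction from a weighted vote over the per-cohort LFC
  signs;
* a combined p-value by weighted inverse-normal (Stouffer) combination
  restricted to the cohorts whose LFC agrees with the consensus
  direction, renormalized so the statistic is standard normal under the
  null;
* a consistency score (weighted fraction of measuring cohorts agreeing
  with the consensus) and a reliability score (weighted fraction of
  cohorts measuring the gene at all);
* Benjamini-Hochberg FDR computed once over the pooled male + female
  p-values.

Sidedness of the combination is configurable.  The default
(``sidedness="two_sided"``) feeds each consistent cohort's two-sided p
into the normal-quantile transform; because a cohort's two-sided p is
independent of its effect sign under the null, restricting to
sign-consistent cohorts leaves the combined statistic exactly N(0, 1)
and the combined p uniform.  The alternative (``"one_sided"``) halves
each consistent p first; it makes the single-study identity p/2 hold but
is anti-conservative under the null, since cohorts are selected into the
combination by sign agreement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .datasets import ExpressionDataset
from .de import SexStratifiedDEResult, compute_effective_n, run_stratified_de

Sidedness = Literal["two_sided", "one_sided"]
DEFAULT_SIDEDNESS: Sidedness = "two_sided"

_P_FLOOR = 5e-324  # smallest positive subnormal double
_Z_CAP = 37.5  # |z| beyond which the normal tail underflows


@dataclass(frozen=True)
class DatasetWeight:
    dataset_id: str
    sex: str
    effective_n: int
    weight: float


def compute_weights(
    datasets: Sequence[ExpressionDataset] | Sequence[SexStratifiedDEResult],
    sex: str,
) -> list[DatasetWeight]:
    """Cohort weights w_d = sqrt(n_d / sum n) for one sex.

    ``n_d`` is min(#patients, #controls) of that sex; cohorts with
    ``n_d = 0`` receive weight 0.  The weights satisfy sum(w^2) = 1 over
    the cohorts with positive n.
    """
    ns: list[tuple[str, int]] = []
    for ds in datasets:
        if isinstance(ds, SexStratifiedDEResult):
            ns.append((ds.dataset_id, ds.effective_n))
        else:
            ns.append((ds.dataset_id, compute_effective_n(ds, sex)))
    total = sum(n for _, n in ns)
    if total == 0:
        raise ValueError(f"no dataset with samples for sex {sex!r}")
    return [
        DatasetWeight(dataset_id=d, sex=sex, effective_n=n, weight=float(np.sqrt(n / total)))
        for d, n in ns
    ]


def consensus_direction(
    lfcs: np.ndarray, weights: np.ndarray
) -> tuple[int, bool]:
    """Weighted vote over LFC signs.

    Returns (direction in {+1, -1}, tie_flag).  Zero LFCs vote for
    neither side.  Exact weight ties are broken toward +1 and flagged.

    The tie-break deliberately depends on the *signs only*: any rule
    that consults the effect magnitudes (e.g. the sign of the mean LFC)
    selects the stronger-looking side of a tied gene into the p-value
    combination and measurably inflates the combined statistic under
    the null.
    """
    lfcs = np.asarray(lfcs, float)
    weights = np.asarray(weights, float)
    if lfcs.size == 0:
        raise ValueError("gene must be measured in at least one dataset")
    pos = float(weights[lfcs > 0].sum())
    neg = float(weights[lfcs < 0].sum())
    if pos > neg:
        return 1, False
    if neg > pos:
        return -1, False
    return 1, True


def combine_pvalues(
    pvalues: np.ndarray,
    lfcs: np.ndarray,
    weights: np.ndarray,
    direction: int,
    sidedness: Sidedness = DEFAULT_SIDEDNESS,
) -> float:
    """Weighted inverse-normal combination over direction-consistent cohorts.

    S = sum(w_d z_d) / sqrt(sum w_d^2) over cohorts with
    sign(LFC_d) == direction, with z_d = Phi^-1(1 - p_d') and
    p_d' = p_d (two_sided) or p_d / 2 (one_sided).  Returns the upper
    normal tail of S, floored at the smallest positive double.

    Raises ValueError when no cohort is consistent with the direction.
    """
    p = np.asarray(pvalues, float)
    lfc = np.asarray(lfcs, float)
    w = np.asarray(weights, float)
    mask = (np.sign(lfc) == direction) & np.isfinite(p)
    if not mask.any():
        raise ValueError("no dataset consistent with the consensus direction")
    p = p[mask]
    w = w[mask]
    if sidedness == "one_sided":
        p = p / 2.0
    elif sidedness != "two_sided":
        raise ValueError(f"unknown sidedness {sidedness!r}")
    z = -special.ndtri(np.clip(p, 1e-310, 1.0))  # Phi^-1(1 - p)
    z = np.clip(z, -_Z_CAP, _Z_CAP)
    s = float((w * z).sum() / np.sqrt((w**2).sum()))
    return float(max(special.ndtr(-s), _P_FLOOR))


def cross_study_lfc(
    lfcs: np.ndarray, weights: np.ndarray, direction: int
) -> float:
    """Weighted mean of the direction-consistent per-cohort LFCs."""
    lfc = np.asarray(lfcs, float)
    w = np.asarray(weights, float)
    mask = np.sign(lfc) == direction
    if not mask.any():
        raise ValueError("no dataset consistent with the consensus direction")
    return float((w[mask] * lfc[mask]).sum() / w[mask].sum())


def consistency_score(
    lfcs: np.ndarray, weights: np.ndarray, direction: int
) -> float:
    """Weighted fraction of measuring cohorts whose LFC sign matches
    the consensus direction (Cst in [0, 1])."""
    lfc = np.asarray(lfcs, float)
    w = np.asarray(weights, float)
    denom = float(w.sum())
    if denom == 0:
        return 0.0
    return float(w[np.sign(lfc) == direction].sum() / denom)


def reliability_score(present: np.ndarray, weights: np.ndarray) -> float:
    """Weighted fraction of all cohorts in which the gene is measured.

    R = 1 with no missing value, 0 when missing everywhere.  The
    downstream filter removes genes with R strictly below its threshold.
    """
    w = np.asarray(weights, float)
    if w.size == 0:
        raise ValueError("empty weight list")
    denom = float(w.sum())
    return float(w[np.asarray(present, bool)].sum() / denom) if denom else 0.0


def adjust_fdr_pooled(
    p_female: pd.Series, p_male: pd.Series
) -> tuple[pd.Series, pd.Series]:
    """One Benjamini-Hochberg pass over the concatenated F + M p-values.

    The two analyses are adjusted jointly (a single step-up over both
    gene lists) and the adjusted values are mapped back per sex.  NaN
    entries are excluded from the pool and stay NaN.
    """
    pooled = np.concatenate([p_female.to_numpy(float), p_male.to_numpy(float)])
    fdr = np.full_like(pooled, np.nan)
    ok = np.isfinite(pooled)
    if ok.any():
        fdr[ok] = multipletests(pooled[ok], method="fdr_bh")[1]
    nf = len(p_female)
    return (
        pd.Series(fdr[:nf], index=p_female.index, name="fdr"),
        pd.Series(fdr[nf:], index=p_male.index, name="fdr"),
    )


# ---------------------------------------------------------------------------
# per-sex driver


def meta_analyze(
    results: Sequence[SexStratifiedDEResult],
    weights: Sequence[DatasetWeight] | None = None,
    sidedness: Sidedness = DEFAULT_SIDEDNESS,
) -> pd.DataFrame:
    """Integrate the per-cohort DE tables of one sex.

    Returns a DataFrame indexed by gene with columns ``direction`` (+1 /
    -1), ``lfc`` (cross-study log2 FC), ``p`` (combined nominal),
    ``cst``, ``reliability``, ``n_datasets`` and ``tie`` (direction
    decided by tie-break).  Genes with no direction-consistent cohort
    (e.g. all LFCs exactly 0) are dropped with a warning.
    """
    if not results:
        raise ValueError("no DE results to integrate")
    sexes = {r.sex for r in results}
    if len(sexes) != 1:
        raise ValueError(f"mixed sexes in one meta-analysis: {sexes}")
    if weights is None:
        weights = compute_weights(results, results[0].sex)
    wmap = {w.dataset_id: w.weight for w in weights}
    missing = [r.dataset_id for r in results if r.dataset_id not in wmap]
    if missing:
        raise ValueError(f"no weight for dataset(s) {missing}")

    genes = sorted(set().union(*(set(r.table.index) for r in results)))
    D = len(results)
    w_all = np.array([wmap[r.dataset_id] for r in results])

    LFC = np.full((len(genes), D), np.nan)
    P = np.full((len(genes), D), np.nan)
    gi = {g: i for i, g in enumerate(genes)}
    for j, r in enumerate(results):
        idx = np.fromiter((gi[g] for g in r.table.index), int, len(r.table))
        LFC[idx, j] = r.table["lfc"].to_numpy(float)
        P[idx, j] = r.table["p"].to_numpy(float)

    rows = []
    dropped = 0
    for i, gene in enumerate(genes):
        measured = ~np.isnan(LFC[i])
        lfc_d = LFC[i, measured]
        p_d = P[i, measured]
        w_d = w_all[measured]
        direction, tie = consensus_direction(lfc_d, w_d)
        consistent = np.sign(lfc_d) == direction
        if not consistent.any():
            dropped += 1
            continue
        # genes whose consistent cohorts all lack a p-value are unusable
        if not np.isfinite(p_d[consistent]).any():
            dropped += 1
            continue
        rows.append(
            {
                "gene": gene,
                "direction": direction,
                "lfc": cross_study_lfc(lfc_d, w_d, direction),
                "p": combine_pvalues(p_d, lfc_d, w_d, direction, sidedness),
                "cst": consistency_score(lfc_d, w_d, direction),
                "reliability": reliability_score(measured, w_all),
                "n_datasets": int(measured.sum()),
                "tie": tie,
            }
        )
    if dropped:
        warnings.warn(
            f"{dropped} gene(s) dropped: no usable direction-consistent dataset",
            RuntimeWarning,
            stacklevel=2,
        )
    out = pd.DataFrame(rows).set_index("gene")
    return out


def run_sex_meta_analysis(
    datasets: Sequence[ExpressionDataset],
    covariates: Mapping[str, Sequence[str]] | None = None,
    sidedness: Sidedness = DEFAULT_SIDEDNESS,
    moderated: bool = False,
    min_group: int = 2,
) -> dict[str, pd.DataFrame]:
    """Full DE + integration for both sexes with pooled FDR.

    ``covariates`` maps dataset_id -> covariate terms for its linear
    models.  Cohorts with fewer than ``min_group`` samples in a (sex,
    condition) cell are skipped for that sex.  Returns
    ``{"F": table, "M": table}``; each table carries the ``fdr`` column
    from the pooled male + female adjustment.
    """
    covariates = covariates or {}
    tables: dict[str, pd.DataFrame] = {}
    for sex in ("F", "M"):
        results = []
        for ds in datasets:
            n_case, n_control = ds.group_sizes(sex)
            if min(n_case, n_control) < min_group:
                continue
            results.append(
                run_stratified_de(
                    ds, sex, covariates.get(ds.dataset_id, ()), moderated=moderated
                )
            )
        if not results:
            raise ValueError(f"no dataset with enough samples for sex {sex!r}")
        weights = compute_weights(results, sex)
        tables[sex] = meta_analyze(results, weights, sidedness)
    fdr_f, fdr_m = adjust_fdr_pooled(tables["F"]["p"], tables["M"]["p"])
    tables["F"]["fdr"] = fdr_f
    tables["M"]["fdr"] = fdr_m
    return tables


# ---------------------------------------------------------------------------
# male subsampling robustness


@dataclass
class SubsampleRun:
    table: pd.DataFrame  # male meta table of the subset run
    sign_agreement: float  # vs full male analysis, significant genes
    sign_agreement_all: float
    rank_correlation: float  # Spearman of cross-study LFC


def subsample_robustness(
    datasets: Sequence[ExpressionDataset],
    n_subsets: int = 3,
    seed: int = 0,
    covariates: Mapping[str, Sequence[str]] | None = None,
    sidedness: Sidedness = DEFAULT_SIDEDNESS,
    alpha: float = 0.05,
) -> tuple[list[SubsampleRun], pd.DataFrame]:
    """Re-run the male meta-analysis on female-sized male subsamples.

    For each of ``n_subsets`` draws, male PD and control samples of each
    cohort are subsampled without replacement to that cohort's female
    counts (cohorts whose female count exceeds the male count are used
    in full and flagged with a warning).  Concordance with the full male
    analysis is summarized by the sign-agreement rate of the cross-study
    LFC — over all shared genes and over the genes significant in the
    full analysis (combined p < alpha) — and the Spearman correlation of
    the cross-study LFCs.
    """
    covariates = covariates or {}
    full = run_sex_meta_analysis(datasets, covariates, sidedness)["M"]
    significant = full.index[full["p"] < alpha]

    ss = np.random.SeedSequence(seed)
    runs: list[SubsampleRun] = []
    for child in ss.spawn(n_subsets):
        rng = np.random.default_rng(child)
        sub_datasets = []
        for ds in datasets:
            keep = list(ds.samples.index[ds.samples["sex"] == "F"])
            for cond in ("PD", "control"):
                males = ds.samples.index[
                    (ds.samples["sex"] == "M") & (ds.samples["condition"] == cond)
                ]
                females = ds.samples.index[
                    (ds.samples["sex"] == "F") & (ds.samples["condition"] == cond)
                ]
                target = len(females)
                if target > len(males):
                    warnings.warn(
                        f"{ds.dataset_id}: female {cond} count exceeds male count; "
                        "using all male samples",
                        RuntimeWarning,
                        stacklevel=2,
                    )
                    chosen = list(males)
                else:
                    chosen = list(rng.choice(males, size=target, replace=False))
                keep.extend(chosen)
            sub_datasets.append(
                ExpressionDataset(
                    dataset_id=ds.dataset_id,
                    expression=ds.expression[keep],
                    samples=ds.samples.loc[keep],
                )
            )
        sub = run_sex_meta_analysis(sub_datasets, covariates, sidedness)["M"]
        shared = full.index.intersection(sub.index)
        agree = np.sign(full.loc[shared, "lfc"]) == np.sign(sub.loc[shared, "lfc"])
        sig_shared = significant.intersection(shared)
        rho = stats.spearmanr(
            full.loc[shared, "lfc"], sub.loc[shared, "lfc"]
        ).statistic
        runs.append(
            SubsampleRun(
                table=sub,
                sign_agreement=float(agree.loc[sig_shared].mean()) if len(sig_shared) else np.nan,
                sign_agreement_all=float(agree.mean()),
                rank_correlation=float(rho),
            )
        )
    summary = pd.DataFrame(
        {
            "sign_agreement_significant": [r.sign_agreement for r in runs],
            "sign_agreement_all": [r.sign_agreement_all for r in runs],
            "rank_correlation": [r.rank_correlation for r in runs],
        },
        index=pd.Index(range(len(runs)), name="subset"),
    )
    return runs, summary


def weights_table(weights: Sequence[DatasetWeight]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "dataset_id": [w.dataset_id for w in weights],
            "sex": [w.sex for w in weights],
            "n_eff": [w.effective_n for w in weights],
            "weight": [w.weight for w in weights],
        }
    ).set_index("dataset_id")
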