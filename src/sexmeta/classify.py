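"""Sex-specificity scoring and gene categorization.

The male and female meta-analyses have very different detection power
(male cohorts are larger), so comparing raw FDR values across sexes
would call almost every male hit "male-specific".  Instead each gene is
scored per sex by a pi-value — the product of -log10(nominal combined
p) and the absolute cross-study log2 fold change — and the *rank* of
that pi-value within its own sex's ranking is what is compared across
sexes:

    Spe_g = rank_ratio(pi_F,g) - rank_ratio(pi_M,g)

with rank 1 = largest pi (strongest signal) and rank ratio = rank / G.
Negative Spe means the gene ranks better (stronger) in females.  A
small epsilon replaces p = 1 so pi never collapses to exactly 0.

Categories (mutually exclusive):

``shared``
    FDR < 0.05 in both sexes with the same LFC sign (excluded from the
    sex-related lists).
``candidate_dimorphic``
    opposite LFC signs, at least one sex significant, and
    |cross-study LFC| >= 0.25 in both sexes.
``female_specific`` / ``male_specific``
    significant in that sex, not shared/dimorphic, and a rank-ratio
    advantage of at least the margin tau in that sex (Spe < -tau,
    resp. Spe > +tau) so that the other sex is "not approaching
    significance".
``unclassified``
    everything else, including genes that fail the reliability filter in
    either sex.

The weighted consistency score gates each sex's *significance claim*: a
gene counts as a DEG in a sex only with FDR below the threshold and at
least 60% weighted sign-consistency there.  A gene that is null in one
sex routinely shows an even split of per-cohort signs in that sex
(Cst around 0.5), so consistency in the non-significant sex is *not*
required for a sex-specific call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

LABELS = (
    "female_specific",
    "male_specific",
    "candidate_dimorphic",
    "shared",
    "unclassified",
)


@dataclass(frozen=True)
class ClassificationThresholds:
    """Decision thresholds; defaults follow the integration conventions."""

    fdr_max: float = 0.05
    lfc_min: float = 0.25  # inclusive bound on |cross-study LFC| for dimorphic
    cst_min: float = 0.6  # genes below 60% weighted consistency are excluded
    reliability_min: float = 2.0 / 3.0  # strictly-below genes are excluded
    spe_margin: float = 0.2  # tau: rank-ratio margin for sex-specific calls
    epsilon: float = 1e-12  # p-hat = p - epsilon at p = 1

    def validate(self) -> None:
        if not 0 < self.fdr_max < 1:
            raise ValueError("fdr_max must be in (0, 1)")
        if self.lfc_min < 0:
            raise ValueError("lfc_min must be >= 0")
        if not 0 <= self.cst_min <= 1 or not 0 <= self.reliability_min <= 1:
            raise ValueError("cst_min and reliability_min must be in [0, 1]")
        if not 0 <= self.spe_margin < 1:
            raise ValueError("spe_margin must be in [0, 1)")
        if not 0 < self.epsilon < 1e-3:
            raise ValueError("epsilon must be a small positive constant")


DEFAULT_THRESHOLDS = ClassificationThresholds()


def pi_value(p: float, lfc: float, epsilon: float = DEFAULT_THRESHOLDS.epsilon) -> float:
    """pi = -log10(p-hat) * |LFC| with p-hat = p - epsilon when p = 1.

    Strictly positive for any lfc != 0 (and >= 0 always); raises on
    p <= 0 or p > 1.
    """
    if not 0 < p <= 1:
        raise ValueError(f"p must be in (0, 1], got {p}")
    p_hat = p - epsilon if p == 1.0 else p
    return -math.log10(p_hat) * abs(lfc)


def pi_values(
    p: pd.Series, lfc: pd.Series, epsilon: float = DEFAULT_THRESHOLDS.epsilon
) -> pd.Series:
    """Vectorized :func:`pi_value` over aligned gene series."""
    pv = p.to_numpy(float)
    if np.any(~np.isfinite(pv)) or np.any(pv <= 0) or np.any(pv > 1):
        raise ValueError("p-values must be finite and in (0, 1]")
    p_hat = np.where(pv == 1.0, pv - epsilon, pv)
    return pd.Series(
        -np.log10(p_hat) * np.abs(lfc.to_numpy(float)), index=p.index, name="pi"
    )


def rank_ratio(pi: pd.Series) -> pd.Series:
    """Rank ratio of pi-values: rank 1 = largest pi, ratio = rank / G.

    Ties receive average ranks; the result lies in (0, 1]."""
    if len(pi) == 0:
        raise ValueError("empty pi vector")
    ranks = stats.rankdata(-pi.to_numpy(float), method="average")
    return pd.Series(ranks / len(pi), index=pi.index, name="rank_ratio")


def specificity_index(rank_ratio_f: pd.Series, rank_ratio_m: pd.Series) -> pd.Series:
    """Spe = rank_ratio_F - rank_ratio_M over genes present in both sexes."""
    shared = rank_ratio_f.index.intersection(rank_ratio_m.index)
    return pd.Series(
        rank_ratio_f.loc[shared] - rank_ratio_m.loc[shared], name="spe"
    )


def categorize(
    lfc_f: float,
    fdr_f: float,
    lfc_m: float,
    fdr_m: float,
    spe: float | None,
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
    cst_f: float | None = None,
    cst_m: float | None = None,
) -> str:
    """Label one gene from its per-sex cross-study LFC and FDR plus Spe.

    ``spe`` may be None (e.g. the gene lacks a ranking in one sex); the
    sex-specific branches then cannot fire and the fallback is
    ``unclassified``.  When consistency scores are supplied they gate the
    per-sex significance claims (a DEG needs Cst >= cst_min in its sex).
    Callers are expected to have applied the reliability filter already.
    """
    t = thresholds
    for v in (lfc_f, fdr_f, lfc_m, fdr_m):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return "unclassified"
    sig_f = fdr_f < t.fdr_max and (cst_f is None or cst_f >= t.cst_min)
    sig_m = fdr_m < t.fdr_max and (cst_m is None or cst_m >= t.cst_min)
    opposite = lfc_f * lfc_m < 0
    if (
        opposite
        and (sig_f or sig_m)
        and abs(lfc_f) >= t.lfc_min
        and abs(lfc_m) >= t.lfc_min
    ):
        return "candidate_dimorphic"
    if sig_f and sig_m and lfc_f * lfc_m > 0:
        return "shared"
    if spe is not None and not (isinstance(spe, float) and math.isnan(spe)):
        if sig_f and spe < -t.spe_margin:
            return "female_specific"
        if sig_m and spe > t.spe_margin:
            return "male_specific"
    return "unclassified"


def classify_genes(
    female: pd.DataFrame,
    male: pd.DataFrame,
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Categorize every gene from the two per-sex meta-analysis tables.

    ``female`` / ``male`` are meta tables indexed by gene with columns
    ``lfc``, ``p``, ``fdr``, ``cst``, ``reliability``.  Genes below the
    reliability threshold in a sex are treated as missing for that sex;
    genes missing in either sex end up unclassified.  The consistency
    score gates each sex's significance claim inside :func:`categorize`
    but does not remove the gene from the ranking.  pi-value rankings
    are computed over the genes that pass the reliability filter in
    *both* sexes, so the two sexes' rank ratios refer to the same gene
    universe and Spe is exactly antisymmetric under swapping the sexes.

    Returns a DataFrame indexed by gene with the label and the per-sex
    statistics used for the decision.
    """
    thresholds.validate()

    def passing(df: pd.DataFrame) -> pd.Index:
        ok = df["reliability"].ge(thresholds.reliability_min) & df["p"].notna()
        return df.index[ok]

    ok_f, ok_m = passing(female), passing(male)
    both = ok_f.intersection(ok_m).sort_values()

    pi_f = pi_values(female.loc[both, "p"], female.loc[both, "lfc"], thresholds.epsilon)
    pi_m = pi_values(male.loc[both, "p"], male.loc[both, "lfc"], thresholds.epsilon)
    rr_f = rank_ratio(pi_f) if len(both) else pd.Series(dtype=float)
    rr_m = rank_ratio(pi_m) if len(both) else pd.Series(dtype=float)
    spe = specificity_index(rr_f, rr_m)

    universe = female.index.union(male.index).sort_values()
    out = pd.DataFrame(index=universe)
    out.index.name = "gene"
    for name, df in (("f", female), ("m", male)):
        for col in ("lfc", "p", "fdr", "cst", "reliability"):
            out[f"{col}_{name}"] = df[col].reindex(universe)
    out["pi_f"] = pi_f.reindex(universe)
    out["pi_m"] = pi_m.reindex(universe)
    out["rank_ratio_f"] = rr_f.reindex(universe)
    out["rank_ratio_m"] = rr_m.reindex(universe)
    out["spe"] = spe.reindex(universe)

    labels = []
    for gene in universe:
        if gene not in both:
            labels.append("unclassified")
            continue
        labels.append(
            categorize(
                out.at[gene, "lfc_f"],
                out.at[gene, "fdr_f"],
                out.at[gene, "lfc_m"],
                out.at[gene, "fdr_m"],
                out.at[gene, "spe"],
                thresholds,
                cst_f=out.at[gene, "cst_f"],
                cst_m=out.at[gene, "cst_m"],
            )
        )
    out["label"] = labels
    return out


def category_lists(classified: pd.DataFrame) -> Mapping[str, list[str]]:
    """Per-category gene lists (sorted), excluding ``unclassified``."""
    return {
        label: sorted(classified.index[classified["label"] == label])
        for label in LABELS
        if label != "unclassified"
    }
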