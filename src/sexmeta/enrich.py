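"""Over-representation analysis and TF-regulon activity scoring.

Two downstream readouts of the classified gene lists:

* :func:`fisher_ora` — classical one-sided Fisher / hypergeometric
  over-representation of a gene list against a gene-set collection, with
  the background restricted to genes that passed the reliability filter
  and BH adjustment within each collection.

* :func:`regulon_activity` — a transparent proxy for transcription
  factor activity: the mean of the targets' signed differential
  statistics (inhibitory edges flip the sign), standardized against a
  permutation null over gene labels.  A TF whose activating targets are
  coherently up-regulated scores positive.  Computed per sex; the
  female - male difference ranks TFs by sex-dependent activity.

* :func:`filter_consistent_interactions` — sign-consistency filter on a
  signed TF->target network: activating edges must connect genes moving
  in the same direction, inhibitory edges genes moving in opposite
  directions.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

# ---------------------------------------------------------------------------
# gene sets


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file: name <tab> description <tab> member genes..."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        name, _desc, *members = fields
        members = [m for m in members if m]
        if not members:
            raise ValueError(f"empty gene set {name!r}")
        sets[name] = set(members)
    return sets


def fisher_ora(
    deg_genes: Iterable[str],
    background_genes: Iterable[str],
    collection: Mapping[str, set[str]],
) -> pd.DataFrame:
    """One-sided over-representation of ``deg_genes`` in each gene set.

    ``background_genes`` is the reliable-profile gene universe;
    ``deg_genes`` must be a subset of it.  For each set the p-value is
    the hypergeometric upper tail P(X >= overlap) of the 2x2 table;
    BH adjustment is applied across the sets of this collection.  The
    ``gene_ratio`` column follows the convention overlap / (number of
    DEGs annotated with any set of the collection).
    """
    deg = set(deg_genes)
    background = set(background_genes)
    if not deg <= background:
        raise ValueError("DEG list must be a subset of the background")
    if not deg:
        warnings.warn("empty DEG list: all enrichment p-values are 1", RuntimeWarning, stacklevel=2)
    N = len(background)
    n = len(deg)
    annotated = set().union(*collection.values()) if collection else set()
    annotated_degs = len(deg & annotated & background)

    rows = []
    for name, members in collection.items():
        mem = members & background
        K = len(mem)
        k = len(deg & mem)
        # P(X >= k) under sampling n genes from N with K annotated
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if n else 1.0
        p = min(max(p, 5e-324), 1.0)
        a, b = k, n - k
        c, d = K - k, N - n - (K - k)
        odds = (a * d) / (b * c) if b * c > 0 else np.inf
        rows.append(
            {
                "set": name,
                "overlap": k,
                "set_size": K,
                "deg_count": n,
                "background_size": N,
                "annotated_degs": annotated_degs,
                "gene_ratio": f"{k}/{annotated_degs}" if annotated_degs else f"{k}/0",
                "odds_ratio": odds,
                "p": p,
            }
        )
    out = pd.DataFrame(rows).set_index("set")
    if len(out):
        out["fdr"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    else:
        out["fdr"] = pd.Series(dtype=float)
    return out.sort_values("p")


# ---------------------------------------------------------------------------
# signed regulatory network


def read_network(path: str | Path) -> pd.DataFrame:
    """Read a signed TF->target table: columns source, target, sign {+,-},
    evidence {A..E} (extra columns preserved)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"source", "target", "sign"}
    if not required <= set(df.columns):
        raise ValueError(f"network table needs columns {sorted(required)}")
    if not set(df["sign"]) <= {"+", "-"}:
        raise ValueError("sign column must contain only '+' or '-'")
    return df


def _drop_ambiguous(network: pd.DataFrame) -> pd.DataFrame:
    """Remove edges reported with both signs (self-contradictory duplicates)."""
    signs = network.groupby(["source", "target"])["sign"].nunique()
    ambiguous = set(signs.index[signs > 1])
    if not ambiguous:
        return network.drop_duplicates(subset=["source", "target", "sign"])
    keep = [
        (s, t) not in ambiguous for s, t in zip(network["source"], network["target"])
    ]
    return network.loc[keep].drop_duplicates(subset=["source", "target", "sign"])


def regulons_from_network(
    network: pd.DataFrame, min_size: int = 5
) -> dict[str, list[tuple[str, int]]]:
    """Group a signed edge table into TF -> [(target, +1/-1), ...] regulons.

    Ambiguous duplicate edges are excluded; regulons smaller than
    ``min_size`` are kept here (the size filter is applied against
    *scored* targets in :func:`regulon_activity`)."""
    net = _drop_ambiguous(network)
    out: dict[str, list[tuple[str, int]]] = {}
    for source, target, sign in zip(net["source"], net["target"], net["sign"]):
        out.setdefault(source, []).append((target, 1 if sign == "+" else -1))
    return out


def signed_score(meta_table: pd.DataFrame) -> pd.Series:
    """Signed evidence per gene: sign(cross-study LFC) * -log10(combined p)."""
    p = meta_table["p"].to_numpy(float)
    return pd.Series(
        np.sign(meta_table["lfc"].to_numpy(float)) * -np.log10(np.clip(p, 1e-310, 1.0)),
        index=meta_table.index,
        name="score",
    )


def regulon_activity(
    regulons: Mapping[str, Sequence[tuple[str, int]]],
    stats_by_sex: Mapping[str, pd.Series],
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 5,
) -> pd.DataFrame:
    """Permutation-standardized regulon activity per TF and sex.

    For each TF the raw activity in one sex is the mean over its scored
    targets of (edge sign x target signed statistic); the reported
    activity is the z-score of that mean against ``n_perm`` draws of the
    same number of statistics sampled from the sex's gene universe
    (label permutation null).  TFs with fewer than ``min_size`` scored
    targets in a sex are skipped for that sex.  The output is ranked by
    the absolute female - male activity difference.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    sexes = list(stats_by_sex)
    rows: dict[str, dict[str, float]] = {}
    # one permutation index matrix per (universe size, regulon size), shared
    # across TFs and sexes: identical per-sex statistics then yield exactly
    # identical activities (difference 0)
    cache: dict[tuple[int, int], np.ndarray] = {}
    for sex in sexes:
        series = stats_by_sex[sex]
        values = series.to_numpy(float)
        index = {g: i for i, g in enumerate(series.index)}
        for tf, targets in regulons.items():
            scored = [(index[t], s) for t, s in targets if t in index]
            k = len(scored)
            if k < min_size:
                continue
            idx = np.array([i for i, _ in scored])
            sgn = np.array([s for _, s in scored], float)
            raw = float((values[idx] * sgn).mean())
            key = (len(values), k)
            if key not in cache:
                cache[key] = rng.integers(0, len(values), size=(n_perm, k))
            null = (values[cache[key]] * sgn).mean(axis=1)
            sd = float(null.std(ddof=1))
            z = (raw - float(null.mean())) / sd if sd > 0 else np.nan
            rows.setdefault(tf, {})[f"activity_{sex.lower()}"] = z
            rows[tf][f"n_targets_{sex.lower()}"] = k
    out = pd.DataFrame(rows).T
    out.index.name = "tf"
    if {"activity_f", "activity_m"} <= set(out.columns):
        out["difference"] = out["activity_f"] - out["activity_m"]
        out = out.reindex(out["difference"].abs().sort_values(ascending=False).index)
    return out


def filter_consistent_interactions(
    network: pd.DataFrame, lfc: pd.Series
) -> pd.DataFrame:
    """Keep only sign-consistent edges for one sex context.

    Activation edges survive iff source and target LFCs share a sign;
    inhibition edges iff the signs differ.  Edges touching a gene with a
    missing or zero LFC are dropped.  Idempotent; never adds edges.
    """
    net = _drop_ambiguous(network)
    lfc_map = lfc.dropna()
    src = net["source"].map(lfc_map)
    tgt = net["target"].map(lfc_map)
    product = np.sign(src) * np.sign(tgt)
    keep = np.where(net["sign"] == "+", product > 0, product < 0)
    keep &= src.notna() & tgt.notna()
    return net.loc[keep.to_numpy(bool)].reset_index(drop=True)
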