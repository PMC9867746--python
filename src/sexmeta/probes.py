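"""Probe-to-gene map cleaning and probe selection for gene-level integration.

Microarray probes can hit several genes; before cross-platform
integration the probe universe is cleaned so that only interpretable
signals remain, and each gene is represented by a single probe per sex
context (the probe with the highest average expression, low signal being
less reliable).

Filtering rules applied by :func:`filter_probes`:

(a) probes matching five genes or more are discarded;
(b) a multi-gene probe is discarded when another probe matches a strict
    subset of its genes (e.g. a probe for A+B is dropped if some probe
    matches only A);
(c) multi-gene probes whose gene sets partially overlap (share a gene
    while neither set contains the other) are all discarded, regardless
    of any single-gene probes for the shared genes.

All three rules are evaluated against the same input map and the marked
probes are removed in one sweep, which makes the filter idempotent.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .datasets import ExpressionDataset

MAX_GENES_PER_PROBE = 5  # probes at or above this many genes are dropped

ProbeMap = dict[str, frozenset[str]]


def read_probe_map(path: str | Path) -> ProbeMap:
    """Read a 2-column TSV (probe_id, gene_id; one row per pair)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("probe map must have two columns: probe_id, gene_id")
    probe_col, gene_col = df.columns[:2]
    out: dict[str, set[str]] = {}
    for probe, gene in zip(df[probe_col], df[gene_col]):
        out.setdefault(probe, set()).add(gene)
    return {p: frozenset(g) for p, g in out.items()}


def as_probe_map(mapping: Mapping[str, Sequence[str] | frozenset[str]]) -> ProbeMap:
    out = {str(p): frozenset(map(str, genes)) for p, genes in mapping.items()}
    if any(len(g) == 0 for g in out.values()):
        raise ValueError("probe map entries must have non-empty gene sets")
    return out


def filter_probes(probe_map: Mapping[str, frozenset[str]]) -> ProbeMap:
    """Apply the three ambiguity-removal rules; see module docstring."""
    pm = as_probe_map(probe_map)
    if not pm:
        raise ValueError("empty probe map")

    # rule (a)
    pm = {p: g for p, g in pm.items() if len(g) < MAX_GENES_PER_PROBE}

    gene_sets = list(pm.items())
    removed: set[str] = set()
    # rules (b) and (c), marked simultaneously against the (a)-filtered map
    multi = [(p, g) for p, g in gene_sets if len(g) > 1]
    for p, genes in multi:
        for q, other in gene_sets:
            if q == p:
                continue
            if other < genes:  # strict subset -> (b)
                removed.add(p)
                break
    for (p, gp), (q, gq) in itertools.combinations(multi, 2):
        if gp & gq and not (gp <= gq or gq <= gp):  # partial overlap -> (c)
            removed.add(p)
            removed.add(q)

    return {p: g for p, g in pm.items() if p not in removed}


@dataclass
class GeneProbeSelection:
    """Chosen probe per gene per sex context, with cross-context exclusions.

    ``chosen[sex]`` maps (dataset_id, gene) -> probe_id; ``excluded_genes``
    are genes whose selected probe differs between the male and female
    contexts in at least one dataset — these are dropped from all reports.
    """

    chosen: dict[str, dict[tuple[str, str], str]]
    excluded_genes: set[str] = field(default_factory=set)

    def genes(self, sex: str) -> set[str]:
        return {
            gene for (_, gene) in self.chosen[sex] if gene not in self.excluded_genes
        }

    def write_exclusions(self, path: str | Path) -> None:
        pd.Series(sorted(self.excluded_genes), name="gene").to_csv(
            path, sep="\t", index=False
        )


def select_probe_per_gene(
    datasets: Sequence[ExpressionDataset],
    probe_map: Mapping[str, frozenset[str]],
    sexes: Sequence[str] = ("F", "M"),
) -> GeneProbeSelection:
    """Pick, per gene / dataset / sex context, the measured probe with the
    highest average expression.

    The average is the unweighted mean over all samples of the given sex
    pooled across every dataset in which the probe is measured.  Ties are
    broken by lexicographic probe id.  Genes whose chosen probe differs
    between the two sex contexts in any dataset enter ``excluded_genes``.
    """
    pm = as_probe_map(probe_map)

    # pooled per-sex mean expression of each surviving probe
    mean_expr: dict[str, dict[str, float]] = {sex: {} for sex in sexes}
    for sex in sexes:
        total: dict[str, float] = {}
        count: dict[str, int] = {}
        for ds in datasets:
            cols = ds.sex_samples(sex)
            if len(cols) == 0:
                continue
            present = ds.expression.index.intersection(list(pm))
            block = ds.expression.loc[present, cols]
            sums = block.sum(axis=1)
            for probe in present:
                total[probe] = total.get(probe, 0.0) + float(sums[probe])
                count[probe] = count.get(probe, 0) + len(cols)
        mean_expr[sex] = {p: total[p] / count[p] for p in total if count[p] > 0}

    chosen: dict[str, dict[tuple[str, str], str]] = {sex: {} for sex in sexes}
    for ds in datasets:
        probes_here = [p for p in pm if p in ds.expression.index]
        by_gene: dict[str, list[str]] = {}
        for probe in probes_here:
            for gene in pm[probe]:
                by_gene.setdefault(gene, []).append(probe)
        for sex in sexes:
            means = mean_expr[sex]
            for gene, probes in by_gene.items():
                scored = [p for p in probes if p in means]
                if not scored:
                    continue
                # highest mean; ties by lexicographic probe id
                best = min(scored, key=lambda p: (-means[p], p))
                chosen[sex][(ds.dataset_id, gene)] = best

    excluded: set[str] = set()
    if len(sexes) == 2:
        a, b = sexes
        for key, probe in chosen[a].items():
            other = chosen[b].get(key)
            if other is not None and other != probe:
                excluded.add(key[1])

    return GeneProbeSelection(chosen=chosen, excluded_genes=excluded)


def collapse_to_genes(
    dataset: ExpressionDataset,
    selection: GeneProbeSelection,
    sex: str,
) -> ExpressionDataset:
    """Gene-level expression for one dataset in one sex context.

    Rows are genes; each gene's values are those of its selected probe.
    Genes in ``excluded_genes`` (probe choice differs between contexts)
    are dropped.
    """
    rows: dict[str, str] = {}
    for (ds_id, gene), probe in selection.chosen[sex].items():
        if ds_id == dataset.dataset_id and gene not in selection.excluded_genes:
            rows[gene] = probe
    genes = sorted(rows)
    expr = dataset.expression.loc[[rows[g] for g in genes]].copy()
    expr.index = pd.Index(genes, name="gene")
    return ExpressionDataset(
        dataset_id=dataset.dataset_id,
        expression=expr,
        samples=dataset.samples.copy(),
    )
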