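"""End-to-end orchestration: DE -> integration -> classification -> enrichment.

Stages communicate exclusively through TSV files inside the run
directory, so any stage can be inspected or re-run from persisted
intermediates.  A machine-readable manifest (config hash, seed, package
version) and a summary report (category counts, top genes) are written
alongside.

Run directory layout::

    de/<dataset>.<sex>.tsv        per-cohort per-sex DE tables
    meta/weights.tsv              cohort weights per sex
    meta/meta.F.tsv, meta.M.tsv   cross-study tables with pooled FDR
    classify/classified.tsv       per-gene labels and statistics
    classify/<label>.txt          per-category gene lists
    enrich/<sex>.<collection>.tsv ORA tables (when GMTs configured)
    enrich/regulon_activity.tsv   TF activity per sex (when network given)
    network/filtered.<sex>.tsv    sign-consistent edges (when network given)
    manifest.json, summary.json
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .classify import ClassificationThresholds, category_lists, classify_genes
from .datasets import ExpressionDataset
from .de import run_stratified_de
from .enrich import (
    fisher_ora,
    filter_consistent_interactions,
    read_gmt,
    read_network,
    regulon_activity,
    regulons_from_network,
    signed_score,
)
from .meta import (
    DEFAULT_SIDEDNESS,
    Sidedness,
    adjust_fdr_pooled,
    compute_weights,
    meta_analyze,
    weights_table,
)
from .probes import collapse_to_genes, filter_probes, read_probe_map, select_probe_per_gene

log = logging.getLogger("sexmeta")


@dataclass
class DatasetSpec:
    dataset_id: str
    expression: Path
    samples: Path
    covariates: tuple[str, ...] = ()


@dataclass
class PipelineConfig:
    """Everything one run needs; loadable from YAML (see ``from_yaml``)."""

    datasets: list[DatasetSpec]
    outdir: Path
    thresholds: ClassificationThresholds = field(default_factory=ClassificationThresholds)
    probe_map: Path | None = None
    gene_sets: Mapping[str, Path] = field(default_factory=dict)
    network: Path | None = None
    n_perm: int = 1000
    min_regulon_size: int = 5
    sidedness: Sidedness = DEFAULT_SIDEDNESS
    moderated: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text())
        base = Path(path).parent
        datasets = [
            DatasetSpec(
                dataset_id=d["id"],
                expression=base / d["expression"],
                samples=base / d["samples"],
                covariates=tuple(d.get("covariates", ())),
            )
            for d in doc["datasets"]
        ]
        thr = ClassificationThresholds(**doc.get("thresholds", {}))
        return cls(
            datasets=datasets,
            outdir=base / doc.get("outdir", "run"),
            thresholds=thr,
            probe_map=(base / doc["probe_map"]) if doc.get("probe_map") else None,
            gene_sets={k: base / v for k, v in doc.get("gene_sets", {}).items()},
            network=(base / doc["network"]) if doc.get("network") else None,
            n_perm=doc.get("n_perm", 1000),
            min_regulon_size=doc.get("min_regulon_size", 5),
            sidedness=doc.get("sidedness", DEFAULT_SIDEDNESS),
            moderated=doc.get("moderated", False),
            seed=doc.get("seed", 0),
        )

    def digest(self) -> str:
        blob = json.dumps(
            {
                "datasets": [
                    [d.dataset_id, str(d.expression), str(d.samples), list(d.covariates)]
                    for d in self.datasets
                ],
                "thresholds": vars(self.thresholds),
                "probe_map": str(self.probe_map),
                "gene_sets": {k: str(v) for k, v in self.gene_sets.items()},
                "network": str(self.network),
                "n_perm": self.n_perm,
                "min_regulon_size": self.min_regulon_size,
                "sidedness": self.sidedness,
                "moderated": self.moderated,
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_datasets(config: PipelineConfig) -> list[ExpressionDataset]:
    return [
        ExpressionDataset.from_tsv(d.dataset_id, d.expression, d.samples)
        for d in config.datasets
    ]


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage; returns the run directory.

    A stage failure raises with the stage name in the message; outputs
    of completed stages are retained on disk.
    """
    config.thresholds.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    covariates = {d.dataset_id: d.covariates for d in config.datasets}

    stage = "load"
    try:
        datasets = _load_datasets(config)

        # -- probe collapsing (optional) -----------------------------------
        stage = "probes"
        per_sex_datasets: dict[str, list[ExpressionDataset]] = {}
        if config.probe_map is not None:
            pmap = filter_probes(read_probe_map(config.probe_map))
            selection = select_probe_per_gene(datasets, pmap)
            selection.write_exclusions(out / "excluded_genes.tsv")
            for sex in ("F", "M"):
                per_sex_datasets[sex] = [
                    collapse_to_genes(ds, selection, sex) for ds in datasets
                ]
        else:
            per_sex_datasets = {"F": datasets, "M": datasets}

        # -- per-cohort stratified DE --------------------------------------
        stage = "de"
        (out / "de").mkdir(exist_ok=True)
        de_results: dict[str, list] = {"F": [], "M": []}
        for sex in ("F", "M"):
            for ds in per_sex_datasets[sex]:
                n_case, n_control = ds.group_sizes(sex)
                if min(n_case, n_control) < 2:
                    log.warning("%s/%s skipped: too few samples", ds.dataset_id, sex)
                    continue
                res = run_stratified_de(
                    ds, sex, covariates.get(ds.dataset_id, ()), moderated=config.moderated
                )
                res.to_tsv(out / "de" / f"{ds.dataset_id}.{sex}.tsv")
                de_results[sex].append(res)
            if not de_results[sex]:
                raise ValueError(f"no dataset with enough samples for sex {sex!r}")

        # -- meta-analysis --------------------------------------------------
        stage = "meta"
        (out / "meta").mkdir(exist_ok=True)
        meta_tables: dict[str, pd.DataFrame] = {}
        wtables = []
        for sex in ("F", "M"):
            weights = compute_weights(de_results[sex], sex)
            wtables.append(weights_table(weights))
            meta_tables[sex] = meta_analyze(de_results[sex], weights, config.sidedness)
        pd.concat(wtables).to_csv(out / "meta" / "weights.tsv", sep="\t")
        fdr_f, fdr_m = adjust_fdr_pooled(meta_tables["F"]["p"], meta_tables["M"]["p"])
        meta_tables["F"]["fdr"] = fdr_f
        meta_tables["M"]["fdr"] = fdr_m
        for sex in ("F", "M"):
            meta_tables[sex].to_csv(out / "meta" / f"meta.{sex}.tsv", sep="\t")

        # -- classification --------------------------------------------------
        stage = "classify"
        (out / "classify").mkdir(exist_ok=True)
        classified = classify_genes(meta_tables["F"], meta_tables["M"], config.thresholds)
        classified.to_csv(out / "classify" / "classified.tsv", sep="\t")
        lists = category_lists(classified)
        for label, genes in lists.items():
            (out / "classify" / f"{label}.txt").write_text(
                "".join(f"{g}\n" for g in genes)
            )

        # -- enrichment (optional) -------------------------------------------
        stage = "enrich"
        if config.gene_sets:
            (out / "enrich").mkdir(exist_ok=True)
            for sex, key in (("F", "female_specific"), ("M", "male_specific")):
                degs = set(lists[key]) | set(lists["candidate_dimorphic"])
                background = set(
                    meta_tables[sex].index[
                        meta_tables[sex]["reliability"] >= config.thresholds.reliability_min
                    ]
                )
                degs &= background
                for name, path in config.gene_sets.items():
                    table = fisher_ora(degs, background, read_gmt(path))
                    table.to_csv(out / "enrich" / f"{sex}.{name}.tsv", sep="\t")

        stage = "network"
        if config.network is not None:
            (out / "enrich").mkdir(exist_ok=True)
            (out / "network").mkdir(exist_ok=True)
            network = read_network(config.network)
            regulons = regulons_from_network(network)
            activity = regulon_activity(
                regulons,
                {sex: signed_score(meta_tables[sex]) for sex in ("F", "M")},
                n_perm=config.n_perm,
                seed=config.seed,
                min_size=config.min_regulon_size,
            )
            activity.to_csv(out / "enrich" / "regulon_activity.tsv", sep="\t")
            for sex in ("F", "M"):
                filtered = filter_consistent_interactions(network, meta_tables[sex]["lfc"])
                filtered.to_csv(out / "network" / f"filtered.{sex}.tsv", sep="\t", index=False)

        # -- reporting --------------------------------------------------------
        stage = "report"
        counts = {label: len(genes) for label, genes in lists.items()}
        counts["unclassified"] = int((classified["label"] == "unclassified").sum())
        top = {
            label: genes[:10] for label, genes in lists.items()
        }
        summary = {"category_counts": counts, "top_genes": top}
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        manifest = {
            "package_version": __version__,
            "config_hash": config.digest(),
            "seed": config.seed,
            "sidedness": config.sidedness,
            "n_datasets": len(config.datasets),
            "thresholds": vars(config.thresholds),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception as exc:  # noqa: BLE001 - re-raise with stage attribution
        log.error("pipeline stage %r failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out


def manifest_for_cohorts(
    cohort_dir: str | Path, outdir: str | Path, **overrides
) -> PipelineConfig:
    """Build a PipelineConfig for a simulated cohort directory
    (as written by :func:`sexmeta.simulate.write_cohorts`)."""
    cohort_dir = Path(cohort_dir)
    specs = [
        DatasetSpec(
            dataset_id=p.name.removesuffix(".expression.tsv"),
            expression=p,
            samples=p.with_name(p.name.replace(".expression.", ".samples.")),
        )
        for p in sorted(cohort_dir.glob("*.expression.tsv"))
    ]
    if not specs:
        raise ValueError(f"no cohort TSVs found in {cohort_dir}")
    return PipelineConfig(datasets=specs, outdir=Path(outdir), **overrides)
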