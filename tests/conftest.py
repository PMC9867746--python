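import numpy as np
import pandas as pd
import pytest

import sexmeta as sm
from sexmeta.datasets import ExpressionDataset
from sexmeta.de import run_stratified_de
from sexmeta.meta import adjust_fdr_pooled, compute_weights, meta_analyze


def make_dataset(
    dataset_id="ds",
    n_f_case=4,
    n_f_control=4,
    n_m_case=4,
    n_m_control=4,
    n_genes=10,
    seed=0,
    features=None,
):
    """Small cohort with Gaussian noise and no planted effect."""
    rng = np.random.default_rng(seed)
    rows = []
    for sex, cond, n in (
        ("F", "PD", n_f_case),
        ("F", "control", n_f_control),
        ("M", "PD", n_m_case),
        ("M", "control", n_m_control),
    ):
        rows += [(f"{dataset_id}_{sex}_{cond}_{i}", cond, sex) for i in range(n)]
    meta = pd.DataFrame(rows, columns=["sample_id", "condition", "sex"]).set_index("sample_id")
    feats = features if features is not None else [f"g{i}" for i in range(n_genes)]
    expr = pd.DataFrame(
        rng.normal(8, 1, size=(len(feats), len(meta))), index=feats, columns=meta.index
    )
    return ExpressionDataset(dataset_id=dataset_id, expression=expr, samples=meta)


@pytest.fixture(scope="session")
def null_run():
    """All-null collection (6 cohorts, G=2000, 20 per sex x condition cell):
    per-cohort DE results and per-sex integrated tables."""
    datasets, truth = sm.generate_cohorts(sm.null_config(seed=3))
    de = {
        sex: [run_stratified_de(ds, sex) for ds in datasets] for sex in ("F", "M")
    }
    tables = {}
    for sex in ("F", "M"):
        tables[sex] = meta_analyze(de[sex], compute_weights(de[sex], sex))
    fdr_f, fdr_m = adjust_fdr_pooled(tables["F"]["p"], tables["M"]["p"])
    tables["F"]["fdr"] = fdr_f
    tables["M"]["fdr"] = fdr_m
    return {"datasets": datasets, "truth": truth, "de": de, "tables": tables}


@pytest.fixture(scope="session")
def recovery_run():
    """Planted-effect collection (|log2 effect| = 1, noise SD 0.5, 6 cohorts,
    40 per cell, 50 genes per class) run through the full analysis."""
    config = sm.recovery_config(seed=1)
    datasets, truth = sm.generate_cohorts(config)
    tables = sm.run_sex_meta_analysis(datasets)
    classified = sm.classify_genes(tables["F"], tables["M"])
    labels = classified["label"].reindex(truth.genes).fillna("unclassified")
    confusion, summary = sm.truth_confusion(labels, truth)
    return {
        "config": config,
        "datasets": datasets,
        "truth": truth,
        "tables": tables,
        "classified": classified,
        "confusion": confusion,
        "summary": summary,
    }
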