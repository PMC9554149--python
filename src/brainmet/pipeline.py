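"""End-to-end orchestration: simulate → DE → membrane features → aggregate
→ gene-set score → enzyme selection → classification → reaction accounting.

Each stage writes plain TSV/JSON artifacts into the output directory and
reads its inputs back from disk, so a run is resumable stage by stage and
fully auditable.  A single integer seed drives every stochastic step.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .aggregate import aggregate_sample_features, group_medians
from .classify import ClassifierSpec, run_classifier, svm_rfe_rank, select_top_k
from .expression import (
    ExpressionMatrix,
    differential_expression,
    gene_set_score,
    read_gmt,
)
from .io import read_labels, read_protein_records
from .membrane import compute_feature_vectors, DEFAULT_MIN_SEGMENT_LENGTH
from .reactions import bundled_reactions, load_reaction_table
from .synthetic import CohortConfig, SyntheticTruth, write_cohort, POSITIVE_CLASS, NEGATIVE_CLASS

logger = logging.getLogger(__name__)

STAGES = ("simulate", "de", "features", "aggregate", "fenton", "select", "classify", "reactions")


@dataclass
class PipelineConfig:
    """Paths, thresholds, and the seed for a full run."""

    outdir: str = "brainmet_run"
    fc_threshold: float = 1.0
    p_threshold: float = 0.05
    pcc_threshold: float = 0.6
    pcc_p_threshold: float = 1e-4
    enrich_p_threshold: float = 1e-4
    min_segment: int = DEFAULT_MIN_SEGMENT_LENGTH
    k_enzymes: int = 20
    folds: int = 5
    seed: int = 0
    reactions_path: str | None = None  # None -> packaged reaction table
    cohort: CohortConfig = field(default_factory=CohortConfig)

    def __post_init__(self) -> None:
        if isinstance(self.cohort, dict):
            self.cohort = CohortConfig(**self.cohort)
        for name in ("fc_threshold", "p_threshold", "pcc_threshold",
                     "pcc_p_threshold", "enrich_p_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_segment < 1:
            raise ValueError("min_segment must be >= 1")
        if self.k_enzymes < 1:
            raise ValueError("k_enzymes must be >= 1")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        self.cohort.seed = self.seed

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        from .io import read_yaml

        return cls(**(read_yaml(path) or {}))


class _Run:
    """Shared state for one pipeline invocation."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)

    def path(self, name: str) -> Path:
        return self.outdir / name


def stage_simulate(run: _Run) -> dict:
    paths = write_cohort(run.outdir, run.config.cohort)
    return {"artifacts": {k: str(v) for k, v in paths.items()}}


def _load_core(run: _Run):
    counts = ExpressionMatrix.from_tsv(run.path("counts.tsv"), "count")
    tpm = ExpressionMatrix.from_tsv(run.path("tpm.tsv"), "tpm")
    labels = read_labels(run.path("labels.tsv"))
    mask = labels["class"].isin([POSITIVE_CLASS, NEGATIVE_CLASS])
    return counts, tpm, labels, labels.index[mask]


def stage_de(run: _Run) -> dict:
    counts, _, labels, core = _load_core(run)
    sub = ExpressionMatrix(counts.data[core], "count")
    de = differential_expression(
        sub,
        labels.loc[core, "class"],
        fc_threshold=run.config.fc_threshold,
        p_threshold=run.config.p_threshold,
        positive_class=POSITIVE_CLASS,
    )
    de.to_csv(run.path("de.tsv"), sep="\t", index_label="gene_id")
    return {"n_deg": int(de["is_deg"].sum())}


def stage_features(run: _Run) -> dict:
    records = read_protein_records(run.path("proteins.fasta"), run.path("topology.tsv"))
    vectors = compute_feature_vectors(records, min_len=run.config.min_segment)
    vectors.to_csv(run.path("feature_vectors.tsv"), sep="\t")
    return {"n_proteins": len(vectors)}


def stage_aggregate(run: _Run) -> dict:
    _, tpm, labels, core = _load_core(run)
    vectors = pd.read_csv(run.path("feature_vectors.tsv"), sep="\t", index_col="protein_id")
    de = pd.read_csv(run.path("de.tsv"), sep="\t", index_col="gene_id")
    deg = set(de.index[de["is_deg"]])
    used = vectors[vectors["gene_id"].isin(deg)]
    if used.empty:
        raise RuntimeError("no differentially expressed transmembrane proteins to aggregate")
    feats = aggregate_sample_features(ExpressionMatrix(tpm.data, "tpm"), used)
    feats.to_csv(run.path("sample_features.tsv"), sep="\t")
    medians = group_medians(feats, labels)
    medians.to_csv(run.path("group_medians.tsv"), sep="\t")
    return {"n_proteins_used": len(used), "groups": medians.index.tolist()}


def stage_fenton(run: _Run) -> dict:
    _, tpm, labels, core = _load_core(run)
    out = {}
    scores_df = {}
    for gs in read_gmt(run.path("gene_sets.gmt")):
        scores = gene_set_score(tpm, gs)
        scores_df[gs.name] = scores
        pos = scores[labels.loc[scores.index, "class"] == POSITIVE_CLASS]
        neg = scores[labels.loc[scores.index, "class"] == NEGATIVE_CLASS]
        t, p = stats.ttest_ind(pos, neg, equal_var=False)
        out[gs.name] = {"mean_pos": float(pos.mean()), "mean_neg": float(neg.mean()),
                        "p_value": float(p)}
    pd.DataFrame(scores_df).to_csv(run.path("gene_set_scores.tsv"), sep="\t",
                                   index_label="sample_id")
    return out


def stage_select(run: _Run) -> dict:
    _, tpm, labels, core = _load_core(run)
    truth = SyntheticTruth.from_json(run.path("truth.json"))
    X = tpm.data.loc[truth.enzyme_gene_ids, core].T
    y = (labels.loc[core, "class"] == POSITIVE_CLASS).astype(int)
    spec = ClassifierSpec(seed=run.config.seed)
    ranking = svm_rfe_rank(X, y, spec)
    ranking.to_csv(run.path("enzyme_ranking.tsv"), sep="\t", index_label="gene_id")
    selected = select_top_k(ranking, run.config.k_enzymes)
    run.path("selected_enzymes.txt").write_text("\n".join(selected) + "\n")
    return {"selected": selected}


def stage_classify(run: _Run) -> dict:
    _, tpm, labels, core = _load_core(run)
    truth = SyntheticTruth.from_json(run.path("truth.json"))
    feats = pd.read_csv(run.path("sample_features.tsv"), sep="\t", index_col="sample_id")
    physical = feats.loc[core]
    enzymes = tpm.data.loc[truth.enzyme_gene_ids, core].T
    y = labels.loc[core, "class"]
    spec = ClassifierSpec(seed=run.config.seed)
    k = run.config.k_enzymes

    results = {}
    configs = {
        "physical": dict(features=physical, select_k=None),
        "enzyme": dict(features=enzymes, select_k=k, select_within=list(enzymes.columns)),
        "combined": dict(
            features=pd.concat([physical, enzymes], axis=1),
            select_k=k,
            select_within=list(enzymes.columns),
        ),
    }
    for name, kw in configs.items():
        cv = run_classifier(kw["features"], y, spec, k_folds=run.config.folds,
                            positive_label=POSITIVE_CLASS, select_k=kw["select_k"],
                            select_within=kw.get("select_within"))
        cv.roc.to_csv(run.path(f"roc_{name}.tsv"), sep="\t", index=False)
        cv.scores.rename("score").to_frame().assign(fold=cv.fold_ids).to_csv(
            run.path(f"scores_{name}.tsv"), sep="\t", index_label="sample_id"
        )
        results[name] = {"auc": cv.auc}
    return results


def stage_reactions(run: _Run) -> dict:
    if run.config.reactions_path:
        table = load_reaction_table(run.config.reactions_path)
    else:
        table = bundled_reactions()
    table.to_csv(run.path("reaction_labels.tsv"), sep="\t", index=False)
    counts = table["label"].value_counts().to_dict()
    return {"n_reactions": len(table),
            "counts": {k: int(v) for k, v in counts.items()}}


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "de": stage_de,
    "features": stage_features,
    "aggregate": stage_aggregate,
    "fenton": stage_fenton,
    "select": stage_select,
    "classify": stage_classify,
    "reactions": stage_reactions,
}


def run_pipeline(config: PipelineConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Run the requested stages in order and write a JSON run report.

    Any stage failure aborts the run with an error naming the stage.
    """
    run = _Run(config)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "fc": config.fc_threshold,
            "p": config.p_threshold,
            "pcc": config.pcc_threshold,
            "pcc_p": config.pcc_p_threshold,
            "enrich_p": config.enrich_p_threshold,
            "min_segment": config.min_segment,
            "k_enzymes": config.k_enzymes,
            "folds": config.folds,
        },
        "stages": {},
    }
    for name in stages:
        if name not in _STAGE_FUNCS:
            raise ValueError(f"unknown stage {name!r}")
        t0 = time.perf_counter()
        logger.info("stage %s: start", name)
        try:
            result = _STAGE_FUNCS[name](run)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        elapsed = time.perf_counter() - t0
        logger.info("stage %s: done in %.2fs", name, elapsed)
        report["stages"][name] = {"result": result, "seconds": round(elapsed, 3)}
    run.path("report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
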