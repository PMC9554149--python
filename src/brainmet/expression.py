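"""Expression statistics: differential expression, co-expression screening,
rank-based gene-set scoring, and hypergeometric enrichment.

Differential expression follows a self-contained count pipeline: DESeq-style
median-of-ratios size factors, then a two-sided Welch t-test on
log2(normalized + 1), with |log2FC| >= 1 (inclusive) and p < 0.05 (strict)
as the default gene-selection rule.  P-values are used raw, matching the
stated thresholds — deliberately no multiple-testing correction (see
docs/methods.md).

The gene-set score is an ssGSEA-style rank-weighted running sum: per sample,
genes are ranked by expression and the score is the cumulative enrichment of
the set members' (weighted) ranks against the non-members.  It depends on
within-sample ranks only, so it is invariant under any monotone transform of
a sample's expression values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

EXPRESSION_SCALES = ("count", "tpm")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a scale tag.

    ``data`` is a DataFrame with gene ids as the index and sample ids as
    columns; ``scale`` is "count" or "tpm".  Values must be non-negative.
    """

    data: pd.DataFrame
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in EXPRESSION_SCALES:
            raise ValueError(f"scale must be one of {EXPRESSION_SCALES}, got {self.scale!r}")
        if (self.data.values < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise ValueError("gene and sample ids must be unique")

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path: str | Path, scale: str) -> "ExpressionMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col="gene_id"), scale)


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")


def median_of_ratios_size_factors(counts: pd.DataFrame) -> pd.Series:
    """DESeq-style per-sample size factors.

    Reference is the per-gene geometric mean over samples, restricted to
    genes expressed in every sample; each sample's factor is the median of
    its count/reference ratios.  Falls back to library-size factors if no
    gene is expressed everywhere.
    """
    everywhere = (counts > 0).all(axis=1)
    if everywhere.sum() == 0:
        lib = counts.sum(axis=0)
        return lib / np.exp(np.log(lib).mean())
    sub = counts.loc[everywhere]
    log_ref = np.log(sub).mean(axis=1)
    ratios = np.log(sub).sub(log_ref, axis=0)
    return np.exp(ratios.median(axis=0))


def differential_expression(
    counts: ExpressionMatrix,
    labels: pd.Series,
    fc_threshold: float = 1.0,
    p_threshold: float = 0.05,
    positive_class: str | None = None,
) -> pd.DataFrame:
    """Per-gene differential expression between two sample classes.

    Returns a DataFrame indexed by gene with log2FC (positive class over
    negative class, on normalized means with a +1 pseudocount), Welch
    p_value, is_deg (|log2FC| >= fc_threshold and p < p_threshold, the
    first inclusive and the second strict), and direction ("up"/"down" in
    the positive class).
    """
    if counts.scale != "count":
        raise ValueError("differential_expression requires a count-scale matrix")
    labels = labels.reindex(counts.sample_ids)
    if labels.isna().any():
        raise ValueError("every sample must be labeled")
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError(f"expected exactly 2 classes, got {classes}")
    if positive_class is None:
        positive_class = classes[0]
    sizes = labels.value_counts()
    if (sizes < 2).any():
        raise ValueError("each class needs at least 2 samples")

    sf = median_of_ratios_size_factors(counts.data)
    norm = counts.data.div(sf, axis=1)
    logn = np.log2(norm + 1.0)

    pos = labels == positive_class
    x = logn.loc[:, pos.values].values
    y = logn.loc[:, (~pos).values].values
    with warnings.catch_warnings():
        # constant genes yield 0/0 in the Welch statistic; p becomes NaN -> 1
        warnings.simplefilter("ignore", RuntimeWarning)
        _, pvals = stats.ttest_ind(x, y, axis=1, equal_var=False)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)

    mean_pos = norm.loc[:, pos.values].mean(axis=1)
    mean_neg = norm.loc[:, (~pos).values].mean(axis=1)
    log2fc = np.log2(mean_pos + 1.0) - np.log2(mean_neg + 1.0)

    out = pd.DataFrame(
        {
            "log2FC": log2fc,
            "p_value": pvals,
        },
        index=counts.gene_ids,
    )
    out["is_deg"] = (out["log2FC"].abs() >= fc_threshold) & (out["p_value"] < p_threshold)
    out["direction"] = np.where(out["log2FC"] > 0, "up", "down")
    return out


def pearson_coexpression(
    expr: ExpressionMatrix,
    anchors: Sequence[str],
    candidates: Sequence[str],
    pcc_threshold: float = 0.6,
    p_threshold: float = 1e-4,
) -> pd.DataFrame:
    """Anchor-candidate pairs that are statistically co-expressed.

    Retains pairs with PCC strictly above ``pcc_threshold`` (one-sided:
    positive correlation only) and p strictly below ``p_threshold``.
    Constant-expression genes are skipped with a warning; self-pairs are
    skipped.
    """
    missing = (set(anchors) | set(candidates)) - set(expr.gene_ids)
    if missing:
        raise KeyError(f"genes absent from matrix: {sorted(missing)}")
    n = expr.data.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples for correlation")

    X = expr.data.loc[list(anchors)].values.astype(float)
    Y = expr.data.loc[list(candidates)].values.astype(float)
    const_a = X.std(axis=1) == 0
    const_c = Y.std(axis=1) == 0
    for name, mask, ids in (("anchor", const_a, anchors), ("candidate", const_c, candidates)):
        if mask.any():
            warnings.warn(
                f"constant-expression {name} genes skipped: "
                f"{[g for g, m in zip(ids, mask) if m]}"
            )

    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ Yc.T) / np.outer(
            np.sqrt((Xc**2).sum(axis=1)), np.sqrt((Yc**2).sum(axis=1))
        )
    r = np.clip(r, -1.0, 1.0)

    rows = []
    for i, a in enumerate(anchors):
        if const_a[i]:
            continue
        for j, c in enumerate(candidates):
            if const_c[j] or a == c:
                continue
            rij = r[i, j]
            if rij <= pcc_threshold:
                continue
            # two-sided p from the exact t transform of the correlation
            if abs(rij) == 1.0:
                p = 0.0
            else:
                t = rij * np.sqrt((n - 2) / (1 - rij**2))
                p = 2 * stats.t.sf(abs(t), df=n - 2)
            if p < p_threshold:
                rows.append({"anchor": a, "candidate": c, "pcc": rij, "p_value": p})
    return pd.DataFrame(rows, columns=["anchor", "candidate", "pcc", "p_value"])


def gene_set_score(
    expr: ExpressionMatrix, gene_set: GeneSet, weight: float = 0.25
) -> pd.Series:
    """Per-sample rank-weighted enrichment score for a gene set.

    Within each sample, genes are ranked by expression (average ranks on
    ties, highest expression = highest rank).  The score is the summed
    difference between the cumulative weighted-rank distribution of set
    members and the cumulative uniform distribution of non-members, walking
    from the most- to the least-expressed gene.  Higher member ranks give a
    higher score.
    """
    members = gene_set.members & set(expr.gene_ids)
    if not members:
        raise ValueError(f"gene set {gene_set.name!r} has no genes in the matrix")
    is_member = expr.gene_ids.isin(members).astype(bool)
    values = expr.data.values
    n_genes = values.shape[0]
    n_miss = max(n_genes - is_member.sum(), 1)

    scores = {}
    for j, sample in enumerate(expr.sample_ids):
        col = values[:, j]
        ranks = stats.rankdata(col)  # 1 = lowest expression
        order = np.argsort(-ranks, kind="stable")  # descending expression
        hit = is_member[order]
        w = ranks[order] ** weight
        hit_w = np.where(hit, w, 0.0)
        p_hit = np.cumsum(hit_w) / hit_w.sum()
        p_miss = np.cumsum(~hit) / n_miss
        scores[sample] = float(np.sum(p_hit - p_miss) / n_genes)
    return pd.Series(scores, name=gene_set.name)


def enrichment_test(
    query: Iterable[str],
    collection: Sequence[GeneSet],
    universe: Iterable[str],
    p_threshold: float = 1e-4,
) -> pd.DataFrame:
    """Hypergeometric over-representation of the query in each gene set.

    Upper-tail p of the observed overlap given the universe; only sets with
    p strictly below ``p_threshold`` are flagged enriched.  Returns all sets
    with their p-values and an ``enriched`` flag.
    """
    universe = set(universe)
    query = set(query)
    if not query or not universe:
        raise ValueError("query and universe must be non-empty")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    M = len(universe)
    N = len(query)
    rows = []
    for gs in collection:
        members = gs.members & universe
        if not members:
            continue
        K = len(members)
        k = len(query & members)
        p = float(stats.hypergeom.sf(k - 1, M, K, N))
        rows.append(
            {"set_name": gs.name, "overlap": k, "set_size": K, "p_value": p,
             "enriched": p < p_threshold}
        )
    return pd.DataFrame(rows, columns=["set_name", "overlap", "set_size", "p_value", "enriched"])


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, members...)."""
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        sets.append(GeneSet(parts[0], frozenset(g for g in parts[2:] if g)))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    lines = [
        "\t".join([gs.name, "na", *sorted(gs.members)]) for gs in sets
    ]
    Path(path).write_text("\n".join(lines) + "\n")
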