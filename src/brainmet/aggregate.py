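"""Expression-weighted per-sample physical features.

Given per-protein extracellular feature vectors (EP, EN, EW, EH) and a
per-sample expression matrix, each sample's feature is the expression-
weighted sum over the protein set:

    S_EP(sample) = sum_i P_i(sample) * EP(i)

and analogously for S_EN, S_EW, S_EH, where P_i is the expression of the
gene encoding the i-th protein.  The sums are linear in expression, hence
homogeneous under global expression scaling and additive over disjoint
protein subsets.  The intended weights are TPM-scale; count-scale input is
accepted with a warning.
"""

from __future__ import annotations

import warnings

import pandas as pd

from .expression import ExpressionMatrix

SAMPLE_FEATURES = ["S_EP", "S_EN", "S_EW", "S_EH"]
_PROTEIN_FEATURES = ["EP", "EN", "EW", "EH"]


def aggregate_sample_features(
    expr: ExpressionMatrix, vectors: pd.DataFrame
) -> pd.DataFrame:
    """Per-sample S_EP, S_EN, S_EW, S_EH over the provided protein set.

    ``vectors`` is the feature table from
    :func:`brainmet.membrane.compute_feature_vectors` (indexed by protein,
    with a ``gene_id`` column linking to expression rows).  The protein set
    is taken as given — typically the differentially expressed
    transmembrane proteins — and is not filtered here.
    """
    if expr.scale != "tpm":
        warnings.warn(
            f"sample features are defined on TPM-scale expression; got {expr.scale!r}"
        )
    missing = [g for g in vectors["gene_id"] if g not in set(expr.gene_ids)]
    if missing:
        raise KeyError(f"feature-vector genes absent from expression matrix: {missing}")
    weights = expr.data.loc[vectors["gene_id"]].T.values  # samples x proteins
    feats = vectors[_PROTEIN_FEATURES].values  # proteins x 4
    out = pd.DataFrame(
        weights @ feats,
        index=expr.sample_ids,
        columns=SAMPLE_FEATURES,
    )
    out.index.name = "sample_id"
    return out


def group_medians(features: pd.DataFrame, labels: pd.DataFrame) -> pd.DataFrame:
    """Median of each sample feature per group.

    Groups are the label classes plus, for samples with a ``subgroup``
    column, class-subgroup combinations (e.g. NBMP-bone).  Raises on
    unlabeled samples or empty groups.
    """
    labels = labels.reindex(features.index)
    if labels["class"].isna().any():
        unlabeled = features.index[labels["class"].isna()].tolist()
        raise ValueError(f"unlabeled samples: {unlabeled}")
    rows = {}
    for cls, g in features.groupby(labels["class"]):
        if g.empty:
            raise ValueError(f"empty group {cls}")
        rows[cls] = g.median()
    if "subgroup" in labels.columns:
        combo = labels["class"] + "-" + labels["subgroup"].astype(str)
        for name, g in features.groupby(combo):
            cls, sub = name.split("-", 1)
            if sub in ("brain", "gbm", "nan"):  # class-level groups already cover these
                continue
            rows[name] = g.median()
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "group"
    return out
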