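"""Seeded synthetic inputs for the brain-metastasis analysis.

Emulates the statistical structure the pipeline assumes: a heavily
imbalanced two-class primary-tumor cohort (44 brain-metastasized vs 529
otherwise-metastasized samples by default), overdispersed negative-binomial
read counts with log-normal gene means, ~100 planted differentially
expressed transmembrane genes (almost all downregulated in the positive
class), and a small planted set of enzyme genes with elevated expression in
the positive class.  Also generates protein topology records for the
transmembrane genes and reaction-string fixtures with known net proton
production.

Everything is driven by a single integer seed; identical configurations
produce byte-identical outputs.
"""

from __future__ import annotations

import json
import math
import string
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .membrane import ProteinTopologyRecord, Segment
from .expression import ExpressionMatrix, GeneSet, write_gmt

POSITIVE_CLASS = "BMP"
NEGATIVE_CLASS = "NBMP"

#: Destination-organ mix of the negative class.  The source cohort counts
#: 113 bone / 215 liver / 261 lung metastases (multi-destination samples
#: counted once per organ); normalized here to exclusive proportions.
DEFAULT_SUBGROUPS: Mapping[str, float] = {
    "bone": 113 / 589,
    "liver": 215 / 589,
    "lung": 261 / 589,
}

_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

# Residue sampling weights proportional to exp(0.1 * hydropathy), giving the
# generated domains a mildly positive mean hydropathy (~ +0.4 per residue).
# This keeps all four expression-weighted sample features positive in
# expectation, so planted downregulation lowers every one of them in the
# positive class.  Real extracellular domains are typically hydrophilic;
# see docs/methods.md for what the generator does and does not emulate.
def _residue_probabilities() -> np.ndarray:
    from .properties import KYTE_DOOLITTLE

    w = np.exp(0.1 * np.array([KYTE_DOOLITTLE[r] for r in _RESIDUES]))
    return w / w.sum()


_RESIDUE_P = _residue_probabilities()


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the study conditions: 44 positive vs 529 negative
    samples, 100 planted differentially expressed transmembrane genes with
    97% downregulated in the positive class, and 20 informative enzymes
    (upregulated in the positive class) hidden among the enzyme genes.
    ``effect_log2fc`` is the planted absolute log2 fold change; 1.5 by
    default so planted genes sit clearly beyond the |log2FC| >= 1 selection
    threshold (an effect exactly at the threshold is recovered only ~half
    the time under sampling noise).
    """

    n_pos: int = 44
    n_neg: int = 529
    subgroup_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBGROUPS)
    )
    n_genes: int = 2000
    n_tm_de: int = 100
    frac_tm_down: float = 0.97
    n_enzymes: int = 200
    n_enzyme_signal: int = 20
    effect_log2fc: float = 1.5
    nb_dispersion: float = 0.2
    mean_log_mu: float = math.log(100.0)
    mean_log_sigma: float = 1.0
    library_log_sigma: float = 0.15
    n_gbm: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_pos", "n_neg", "n_genes", "n_tm_de", "n_enzymes", "n_enzyme_signal"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("frac_tm_down",):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.effect_log2fc < 0:
            raise ValueError("effect_log2fc must be non-negative")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.n_gbm < 0:
            raise ValueError("n_gbm must be non-negative")
        total = sum(self.subgroup_proportions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"subgroup proportions must sum to 1, got {total}")
        if self.n_tm_de + self.n_enzymes > self.n_genes:
            raise ValueError("planted gene groups exceed the gene universe")


@dataclass
class SyntheticTruth:
    """Ground truth of the planted signal."""

    de_gene_ids: dict[str, str]  # gene -> planted direction in positive class
    informative_enzyme_ids: list[str]
    enzyme_gene_ids: list[str]
    base_mean: dict[str, float]
    log2fc: dict[str, float]  # positive over negative class, 0 for background

    def __post_init__(self) -> None:
        if set(self.de_gene_ids) & set(self.informative_enzyme_ids):
            raise ValueError("planted transmembrane and enzyme sets must be disjoint")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


def generate_protein_records(
    n: int,
    seed: int,
    length_range: tuple[int, int] = (80, 400),
    gene_ids: Sequence[str] | None = None,
) -> list[ProteinTopologyRecord]:
    """Random transmembrane protein records with alternating topology.

    Each record carries at least one segment; topology alternates
    non-membrane and transmembrane segments starting on a random side.
    Extracellular segment lengths are drawn from 3-80 residues, so sets of
    a few dozen records contain segments on both sides of the 10-residue
    filtering threshold.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = length_range
    if lo > hi or lo < 30:
        raise ValueError(f"invalid length_range {length_range}")
    if gene_ids is not None and len(gene_ids) != n:
        raise ValueError("gene_ids length must equal n")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        target = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(list(_RESIDUES), size=target, p=_RESIDUE_P))
        side = "extracellular" if rng.random() < 0.5 else "intracellular"
        segments: list[Segment] = []
        pos = 1
        while pos <= target:
            if side == "transmembrane":
                length = int(rng.integers(18, 26))
            else:
                length = int(rng.integers(3, 81))
            end = min(pos + length - 1, target)
            segments.append(Segment(side, pos, end))
            pos = end + 1
            if side == "transmembrane":
                side = "extracellular" if segments[-2].type == "intracellular" else "intracellular"
            else:
                side = "transmembrane"
        pid = f"P{i + 1:04d}"
        gid = gene_ids[i] if gene_ids is not None else f"G{i + 1:04d}"
        records.append(ProteinTopologyRecord(pid, gid, seq, segments))
    return records


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    # variance = mean + dispersion * mean^2
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def generate_cohort(
    config: CohortConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, pd.DataFrame, SyntheticTruth]:
    """Simulate read counts, a TPM-like matrix, sample labels, and truth.

    Counts are negative binomial with log-normal gene means and log-normal
    per-sample library factors.  Planted transmembrane genes get a
    ``2**effect_log2fc`` mean shift in the positive class (down for
    ``frac_tm_down`` of them, up for the rest); planted enzymes shift
    upward in the positive class.  The TPM-like matrix divides counts by
    simulated gene lengths and rescales every column to sum to 1e6.
    """
    rng = np.random.default_rng(config.seed)
    n_samples = config.n_pos + config.n_neg + config.n_gbm
    genes = [f"G{i + 1:06d}" for i in range(config.n_genes)]

    # first block: planted TM DE genes; second block: enzyme genes
    tm_genes = genes[: config.n_tm_de]
    enzyme_genes = genes[config.n_tm_de : config.n_tm_de + config.n_enzymes]
    signal_enzymes = enzyme_genes[: config.n_enzyme_signal]

    n_down = int(round(config.frac_tm_down * config.n_tm_de))
    tm_direction = {g: ("down" if i < n_down else "up") for i, g in enumerate(tm_genes)}

    base_mean = np.exp(rng.normal(config.mean_log_mu, config.mean_log_sigma, config.n_genes))
    log2fc = np.zeros(config.n_genes)
    for i, g in enumerate(tm_genes):
        log2fc[i] = -config.effect_log2fc if tm_direction[g] == "down" else config.effect_log2fc
    for g in signal_enzymes:
        log2fc[genes.index(g)] = config.effect_log2fc

    sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]
    classes = (
        [POSITIVE_CLASS] * config.n_pos
        + [NEGATIVE_CLASS] * config.n_neg
        + ["GBM"] * config.n_gbm
    )
    subgroup_names = list(config.subgroup_proportions)
    probs = np.array([config.subgroup_proportions[s] for s in subgroup_names])
    subgroups = ["brain"] * config.n_pos + [
        subgroup_names[k] for k in rng.choice(len(subgroup_names), size=config.n_neg, p=probs)
    ] + ["gbm"] * config.n_gbm
    labels = pd.DataFrame(
        {"sample_id": sample_ids, "class": classes, "subgroup": subgroups}
    ).set_index("sample_id")

    lib = np.exp(rng.normal(0.0, config.library_log_sigma, n_samples))
    is_pos = np.array([c == POSITIVE_CLASS for c in classes])
    mean_matrix = np.outer(base_mean, lib)
    mean_matrix[:, is_pos] *= (2.0 ** log2fc)[:, None]
    counts = _nb_draw(rng, mean_matrix, config.nb_dispersion).astype(np.int64)
    counts_df = pd.DataFrame(counts, index=genes, columns=sample_ids)

    gene_length = rng.integers(500, 5001, size=config.n_genes).astype(float)
    rate = counts_df.div(gene_length, axis=0)
    col_sums = rate.sum(axis=0)
    col_sums = col_sums.replace(0, 1.0)
    tpm_df = rate.div(col_sums, axis=1) * 1e6

    truth = SyntheticTruth(
        de_gene_ids=tm_direction,
        informative_enzyme_ids=list(signal_enzymes),
        enzyme_gene_ids=list(enzyme_genes),
        base_mean=dict(zip(genes, base_mean.tolist())),
        log2fc=dict(zip(genes, log2fc.tolist())),
    )
    return (
        ExpressionMatrix(counts_df, "count"),
        ExpressionMatrix(tpm_df, "tpm"),
        labels,
        truth,
    )


def generate_reaction_fixtures(seed: int) -> list[tuple[str, int]]:
    """Reaction strings with known net proton production.

    Always includes producing, consuming, and neutral cases, a coefficient
    greater than one on the proton term, and a species with an internal
    '+' sign; the seed shuffles order and varies coefficients.
    """
    rng = np.random.default_rng(seed)
    k = int(rng.integers(2, 5))
    fixtures = [
        ("A + B → C", 0),
        ("ATP + L-seryl-[protein] → ADP + H+ + O-phospho-L-seryl-[protein]", 1),
        (f"L-lysyl-[histone] + {k} S-adenosyl-L-methionine → {k} H+ + product", k),
        ("H+ + NADH + urate → H2O + NAD+ + xanthine", -1),
        ("O2- + H2O2 → OH- + HO. + O2", 0),
        ("2 H+ + X → Y + H^+^", -1),
        ("substrate → H⁺ + product", 1),
    ]
    order = rng.permutation(len(fixtures))
    return [fixtures[i] for i in order]


def write_cohort(
    outdir: str | Path,
    config: CohortConfig,
) -> dict[str, Path]:
    """Generate a cohort plus protein records and write all artifacts.

    Writes counts/TPM TSVs, a label TSV, protein FASTA + topology TSV for
    the planted transmembrane genes, a GMT with the planted gene sets, and
    the truth JSON.  Returns the paths keyed by artifact name.
    """
    from .io import write_fasta, write_topology

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts, tpm, labels, truth = generate_cohort(config)
    records = generate_protein_records(
        config.n_tm_de, seed=config.seed + 1, gene_ids=sorted(truth.de_gene_ids)
    )
    paths = {
        "counts": outdir / "counts.tsv",
        "tpm": outdir / "tpm.tsv",
        "labels": outdir / "labels.tsv",
        "fasta": outdir / "proteins.fasta",
        "topology": outdir / "topology.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
        "truth": outdir / "truth.json",
    }
    counts.to_tsv(paths["counts"])
    tpm.to_tsv(paths["tpm"])
    labels.to_csv(paths["labels"], sep="\t")
    write_fasta(records, paths["fasta"])
    write_topology(records, paths["topology"])
    write_gmt(
        [
            GeneSet("planted_tm_de", frozenset(truth.de_gene_ids)),
            GeneSet("planted_enzyme_signal", frozenset(truth.informative_enzyme_ids)),
        ],
        paths["gene_sets"],
    )
    truth.to_json(paths["truth"])
    return paths
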