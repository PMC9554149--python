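import numpy as np
import pandas as pd
import pytest

import brainmet as bm


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size synthetic cohort shared across tests (seed 7)."""
    cfg = bm.CohortConfig(seed=7)
    counts, tpm, labels, truth = bm.generate_cohort(cfg)
    return cfg, counts, tpm, labels, truth


@pytest.fixture(scope="session")
def small_cohort():
    """A scaled-down cohort for fast classifier-path tests."""
    cfg = bm.CohortConfig(
        n_pos=20, n_neg=80, n_genes=300, n_tm_de=30, n_enzymes=40,
        n_enzyme_signal=5, seed=3,
    )
    counts, tpm, labels, truth = bm.generate_cohort(cfg)
    return cfg, counts, tpm, labels, truth


@pytest.fixture(scope="session")
def physical_features(default_cohort):
    """Per-sample S_EP/S_EN/S_EW/S_EH from planted transmembrane proteins."""
    cfg, counts, tpm, labels, truth = default_cohort
    records = bm.generate_protein_records(
        cfg.n_tm_de, seed=cfg.seed + 1, gene_ids=sorted(truth.de_gene_ids)
    )
    vectors = bm.compute_feature_vectors(records)
    return bm.aggregate_sample_features(tpm, vectors)


def random_protein_record(rng, protein_id="P0001", gene_id="G0001"):
    """A random topology record mixing segment types and lengths."""
    residues = list("ACDEFGHIKLMNPQRSTVWY")
    n = int(rng.integers(60, 300))
    seq = "".join(rng.choice(residues, size=n))
    segments = []
    pos = 1
    types = ["extracellular", "transmembrane", "intracellular"]
    while pos <= n:
        t = types[int(rng.integers(0, 3))]
        length = int(rng.integers(3, 60))
        end = min(pos + length - 1, n)
        segments.append(bm.Segment(t, pos, end))
        pos = end + 1
    return bm.ProteinTopologyRecord(protein_id, gene_id, seq, segments)
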