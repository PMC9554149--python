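"""Readers and writers for the plain-text interchange formats.

Sequences travel as FASTA (via Biopython); topology, expression, label,
feature and reaction tables as TSV; gene sets as GMT; configuration as
YAML.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .membrane import ProteinTopologyRecord, Segment

TOPOLOGY_COLUMNS = ["protein_id", "gene_id", "segment_type", "start", "end"]


def write_fasta(records: Sequence[ProteinTopologyRecord], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.protein_id, description="") for r in records),
        str(path),
        "fasta",
    )


def write_topology(records: Sequence[ProteinTopologyRecord], path: str | Path) -> None:
    rows = [
        {
            "protein_id": r.protein_id,
            "gene_id": r.gene_id,
            "segment_type": seg.type,
            "start": seg.start,
            "end": seg.end,
        }
        for r in records
        for seg in sorted(r.segments, key=lambda s: s.start)
    ]
    pd.DataFrame(rows, columns=TOPOLOGY_COLUMNS).to_csv(path, sep="\t", index=False)


def read_protein_records(
    fasta_path: str | Path, topology_path: str | Path
) -> list[ProteinTopologyRecord]:
    """Join a FASTA of sequences with a topology TSV into protein records.

    The topology TSV uses 1-based inclusive coordinates (UniProt
    convention) with columns protein_id, gene_id, segment_type, start, end.
    """
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    topo = pd.read_csv(topology_path, sep="\t")
    missing_cols = set(TOPOLOGY_COLUMNS) - set(topo.columns)
    if missing_cols:
        raise ValueError(f"topology table missing columns: {sorted(missing_cols)}")
    records = []
    for (pid, gid), g in topo.groupby(["protein_id", "gene_id"], sort=False):
        if pid not in seqs:
            raise KeyError(f"protein {pid} has topology but no sequence in the FASTA")
        segments = [
            Segment(row.segment_type, int(row.start), int(row.end))
            for row in g.itertuples()
        ]
        records.append(ProteinTopologyRecord(pid, gid, seqs[pid], segments))
    return records


def read_labels(path: str | Path) -> pd.DataFrame:
    """Sample label table: index sample_id, columns class and subgroup."""
    df = pd.read_csv(path, sep="\t").set_index("sample_id")
    if "class" not in df.columns:
        raise ValueError("label table must have a 'class' column")
    return df


def read_yaml(path: str | Path) -> dict:
    import yaml

    with open(path) as fh:
        return yaml.safe_load(fh)


def write_yaml(obj: dict, path: str | Path) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
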