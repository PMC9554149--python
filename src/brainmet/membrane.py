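"""Extracellular physicochemical features of transmembrane proteins.

For each protein with an annotated membrane topology, five features are
computed over its extracellular segments (segments shorter than a minimum
length, 10 residues by default, are discarded as too close to the membrane
to matter):

* ``EP`` — number of positively charged residues (R, H, K),
* ``EN`` — number of negatively charged residues (D, E),
* ``EC`` — net charge, ``EP - EN``,
* ``EW`` — total molecular weight (Da), the inner product of the weight
  vector W with the residue-composition vector,
* ``EH`` — total hydropathy, the inner product of the hydropathy vector H
  with the composition vector.

All five depend only on residue composition, so they are additive over
segments and invariant to permuting residues within a segment.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .properties import (
    AMBIGUOUS_RESIDUES,
    DEFAULT_PROPERTY_TABLE,
    STANDARD_RESIDUES,
    AminoAcidPropertyTable,
)

logger = logging.getLogger(__name__)

SEGMENT_TYPES = ("extracellular", "transmembrane", "intracellular")

#: Segments shorter than this many residues sit too close to the membrane
#: and are omitted from the extracellular feature computation.
DEFAULT_MIN_SEGMENT_LENGTH = 10


@dataclass(frozen=True)
class Segment:
    """One topology segment, 1-based inclusive coordinates (UniProt style)."""

    type: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.type not in SEGMENT_TYPES:
            raise ValueError(f"unknown segment type {self.type!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid segment coordinates ({self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class ProteinTopologyRecord:
    """Amino-acid sequence plus typed topology segments for one protein."""

    protein_id: str
    gene_id: str
    sequence: str
    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.segments = [s if isinstance(s, Segment) else Segment(*s) for s in self.segments]
        n = len(self.sequence)
        for seg in self.segments:
            if seg.end > n:
                raise ValueError(
                    f"protein {self.protein_id}: segment {seg.type} "
                    f"[{seg.start}, {seg.end}] exceeds sequence length {n}"
                )
        ordered = sorted(self.segments, key=lambda s: s.start)
        for a, b in zip(ordered, ordered[1:]):
            if a.end >= b.start:
                raise ValueError(
                    f"protein {self.protein_id}: overlapping segments "
                    f"[{a.start},{a.end}] and [{b.start},{b.end}]"
                )
        bad = set(self.sequence) - STANDARD_RESIDUES - AMBIGUOUS_RESIDUES
        if bad:
            raise ValueError(
                f"protein {self.protein_id}: sequence contains invalid letters {sorted(bad)}"
            )


@dataclass(frozen=True)
class ExtracellularFeatureVector:
    """EP, EN, EC, EW, EH for one protein, plus bookkeeping."""

    ep: int
    en: int
    ec: int
    ew: float
    eh: float
    n_segments_used: int
    residue_counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ec != self.ep - self.en:
            raise ValueError("EC must equal EP - EN")


def extract_extracellular_segments(
    record: ProteinTopologyRecord, min_len: int = DEFAULT_MIN_SEGMENT_LENGTH
) -> list[str]:
    """Return extracellular subsequences with at least ``min_len`` residues.

    Segments are returned in sequence order.  Exactly ``min_len`` residues
    qualifies; only strictly shorter segments are omitted.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    out = []
    for seg in sorted(record.segments, key=lambda s: s.start):
        if seg.type != "extracellular":
            continue
        if seg.length < min_len:
            continue
        out.append(record.sequence[seg.start - 1 : seg.end])
    return out


def _composition(
    segments: Iterable[str], protein_id: str | None = None
) -> Counter:
    counts: Counter = Counter()
    for seg in segments:
        counts.update(seg)
    ambiguous = {r: c for r, c in counts.items() if r in AMBIGUOUS_RESIDUES}
    if ambiguous:
        logger.warning(
            "protein %s: %d ambiguous residues (%s) excluded from features",
            protein_id or "<unknown>",
            sum(ambiguous.values()),
            ",".join(sorted(ambiguous)),
        )
        for r in ambiguous:
            del counts[r]
    bad = set(counts) - STANDARD_RESIDUES
    if bad:
        raise ValueError(f"invalid residue letters {sorted(bad)} in segments")
    return counts


def charge_counts(
    segments: Sequence[str],
    table: AminoAcidPropertyTable = DEFAULT_PROPERTY_TABLE,
) -> tuple[int, int, int]:
    """Count charged residues over segments: returns (EP, EN, EC)."""
    counts = _composition(segments)
    ep = sum(c for r, c in counts.items() if r in table.positive_set)
    en = sum(c for r, c in counts.items() if r in table.negative_set)
    return ep, en, ep - en


def physchem_sums(
    segments: Sequence[str],
    table: AminoAcidPropertyTable = DEFAULT_PROPERTY_TABLE,
) -> tuple[float, float]:
    """Total molecular weight and hydropathy over segments: (EW, EH)."""
    counts = _composition(segments)
    ew = sum(table.weights[r] * c for r, c in counts.items())
    eh = sum(table.hydropathy[r] * c for r, c in counts.items())
    return ew, eh


def feature_vector(
    record: ProteinTopologyRecord,
    table: AminoAcidPropertyTable = DEFAULT_PROPERTY_TABLE,
    min_len: int = DEFAULT_MIN_SEGMENT_LENGTH,
) -> ExtracellularFeatureVector:
    """Compute the extracellular feature vector for one protein."""
    segs = extract_extracellular_segments(record, min_len=min_len)
    counts = _composition(segs, record.protein_id)
    ep = sum(c for r, c in counts.items() if r in table.positive_set)
    en = sum(c for r, c in counts.items() if r in table.negative_set)
    ew = sum(table.weights[r] * c for r, c in counts.items())
    eh = sum(table.hydropathy[r] * c for r, c in counts.items())
    return ExtracellularFeatureVector(
        ep=ep, en=en, ec=ep - en, ew=ew, eh=eh,
        n_segments_used=len(segs), residue_counts=dict(counts),
    )


def compute_feature_vectors(
    records: Sequence[ProteinTopologyRecord],
    table: AminoAcidPropertyTable = DEFAULT_PROPERTY_TABLE,
    min_len: int = DEFAULT_MIN_SEGMENT_LENGTH,
) -> pd.DataFrame:
    """Feature table for a list of proteins.

    Returns a DataFrame indexed by ``protein_id`` with columns ``gene_id``,
    ``EP``, ``EN``, ``EC``, ``EW``, ``EH``, ``n_segments_used``.
    """
    ids = [r.protein_id for r in records]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValueError(f"duplicate protein_ids: {sorted(dupes)}")
    rows = []
    for rec in records:
        v = feature_vector(rec, table=table, min_len=min_len)
        rows.append(
            {
                "protein_id": rec.protein_id,
                "gene_id": rec.gene_id,
                "EP": v.ep,
                "EN": v.en,
                "EC": v.ec,
                "EW": v.ew,
                "EH": v.eh,
                "n_segments_used": v.n_segments_used,
            }
        )
    return pd.DataFrame(rows).set_index("protein_id")


def summarize_feature_table(
    vectors: pd.DataFrame, direction: Mapping[str, str]
) -> pd.DataFrame:
    """Per-direction summary: counts of strictly charged / hydropathic
    proteins and the median molecular weight.

    ``direction`` maps protein_id to ``"up"`` or ``"down"`` (regulation in
    the positive vs negative class).  Proteins with EC == 0 or EH == 0 are
    counted in neither strict bucket.
    """
    if vectors.empty:
        raise ValueError("empty feature table")
    missing = set(vectors.index) - set(direction)
    if missing:
        raise ValueError(f"no direction for proteins: {sorted(missing)}")
    rows = {}
    groups = vectors.groupby(vectors.index.map(direction.__getitem__))
    for name, g in groups:
        rows[name] = {
            "n_EC_positive": int((g["EC"] > 0).sum()),
            "n_EC_negative": int((g["EC"] < 0).sum()),
            "n_EH_positive": int((g["EH"] > 0).sum()),
            "n_EH_negative": int((g["EH"] < 0).sum()),
            "median_EW": float(g["EW"].median()),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
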