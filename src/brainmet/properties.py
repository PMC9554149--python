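"""Per-residue physicochemical property tables.

The extracellular feature engine needs, for each of the 20 standard amino
acids, a molecular weight and a hydropathy index, plus the sets of residues
treated as charge carriers.  Defaults: average molecular masses of the free
amino acids (Da) and the Kyte-Doolittle hydropathy scale.  Both are
configurable, e.g. to residue (dehydrated) masses or an alternative
hydropathy scale, via :meth:`AminoAcidPropertyTable.from_tsv`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Ambiguity / non-standard one-letter codes tolerated in sequences.  They are
#: excluded from charge counts and contribute zero weight and hydropathy.
AMBIGUOUS_RESIDUES = frozenset("XBZJUO*")

#: Residues carrying a positive charge: arginine, histidine, lysine.
#: Histidine is included even though it is only partially protonated at
#: physiological pH; see docs/methods.md.
POSITIVE_RESIDUES = frozenset("RHK")

#: Residues carrying a negative charge: aspartate, glutamate.
NEGATIVE_RESIDUES = frozenset("DE")

# Average molecular masses of the free amino acids (Da).
FREE_AMINO_ACID_WEIGHTS: Mapping[str, float] = {
    "A": 89.09, "R": 174.20, "N": 132.12, "D": 133.10, "C": 121.16,
    "E": 147.13, "Q": 146.15, "G": 75.07, "H": 155.15, "I": 131.17,
    "L": 131.17, "K": 146.19, "M": 149.21, "F": 165.19, "P": 115.13,
    "S": 105.09, "T": 119.12, "W": 204.23, "Y": 181.19, "V": 117.15,
}

# Kyte-Doolittle hydropathy indices (positive = hydrophobic).
KYTE_DOOLITTLE: Mapping[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "E": -3.5, "Q": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


@dataclass(frozen=True)
class AminoAcidPropertyTable:
    """Charge sets plus weight vector W and hydropathy vector H.

    Invariants enforced at construction: W and H each key exactly the 20
    standard residues, the charge sets are disjoint subsets of them, and all
    weights are positive.
    """

    positive_set: frozenset = POSITIVE_RESIDUES
    negative_set: frozenset = NEGATIVE_RESIDUES
    weights: Mapping[str, float] = field(default_factory=lambda: dict(FREE_AMINO_ACID_WEIGHTS))
    hydropathy: Mapping[str, float] = field(default_factory=lambda: dict(KYTE_DOOLITTLE))

    def __post_init__(self) -> None:
        for name, table in (("weights", self.weights), ("hydropathy", self.hydropathy)):
            if set(table) != set(STANDARD_RESIDUES):
                raise ValueError(
                    f"{name} must key exactly the 20 standard residues; "
                    f"got {len(table)} keys"
                )
        if self.positive_set & self.negative_set:
            raise ValueError("positive and negative charge sets overlap")
        for s in (self.positive_set, self.negative_set):
            if not s <= STANDARD_RESIDUES:
                raise ValueError(f"charge set {sorted(s)} contains non-standard residues")
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("all molecular weights must be positive")

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        positive_set: frozenset = POSITIVE_RESIDUES,
        negative_set: frozenset = NEGATIVE_RESIDUES,
    ) -> "AminoAcidPropertyTable":
        """Load a table from a TSV with columns residue, weight, hydropathy."""
        import pandas as pd

        df = pd.read_csv(path, sep="\t", dtype={"residue": str})
        weights = dict(zip(df["residue"], df["weight"].astype(float)))
        hydro = dict(zip(df["residue"], df["hydropathy"].astype(float)))
        return cls(frozenset(positive_set), frozenset(negative_set), weights, hydro)

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        residues = sorted(STANDARD_RESIDUES)
        pd.DataFrame(
            {
                "residue": residues,
                "weight": [self.weights[r] for r in residues],
                "hydropathy": [self.hydropathy[r] for r in residues],
            }
        ).to_csv(path, sep="\t", index=False)


DEFAULT_PROPERTY_TABLE = AminoAcidPropertyTable()
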