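"""Enzymatic reaction equations and net proton accounting.

Parses free-text reaction equations of the form

    ``H2O + NAD+ + xanthine → H+ + NADH + urate``

into stoichiometric substrate/product term lists and computes the net
stoichiometric coefficient of the proton species (products minus
substrates).  A reaction with net H+ > 0 is classified as proton-producing;
this is the bookkeeping behind the observation that most enzymes selected
as discriminative for brain-metastasized primaries catalyze
proton-producing reactions.

Only explicit proton species count: water and hydroxide are never
decomposed into H+.  Accepted proton spellings: ``H+``, ``H^+^``, ``H⁺``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

# Arrows are recognized only as standalone tokens (space-delimited), so a
# species-internal linkage such as "(1<->1')" is never mistaken for one.
_ARROW_RE = re.compile(r"(?:^|\s)(→|->)(?:\s|$)")
_BIDIRECTIONAL_RE = re.compile(r"(?:^|\s)(⇌|<->|<=>|↔)(?:\s|$)")

#: Spellings normalized to the canonical proton species "H+".
PROTON_SPELLINGS = frozenset({"H+", "H^+^", "H⁺"})

_COEFF_RE = re.compile(r"^(\d+)\s+(.+)$")


@dataclass(frozen=True)
class ReactionEquation:
    """Stoichiometric substrate and product term lists for one reaction."""

    substrates: tuple[tuple[int, str], ...]
    products: tuple[tuple[int, str], ...]
    raw_text: str = ""

    def __post_init__(self) -> None:
        if not self.substrates or not self.products:
            raise ValueError("both reaction sides must be non-empty")
        for coeff, species in (*self.substrates, *self.products):
            if coeff < 1:
                raise ValueError(f"coefficient for {species!r} must be >= 1")

    def reversed(self) -> "ReactionEquation":
        return ReactionEquation(self.products, self.substrates, self.raw_text)

    def render(self) -> str:
        def side(terms):
            return " + ".join(
                species if coeff == 1 else f"{coeff} {species}" for coeff, species in terms
            )

        return f"{side(self.substrates)} → {side(self.products)}"


def _normalize_species(name: str) -> str:
    name = re.sub(r"\s+", " ", name.replace("**", "")).strip()
    if name in PROTON_SPELLINGS:
        return "H+"
    return name


def _parse_term(term: str) -> tuple[int, str]:
    term = term.strip()
    if not term:
        raise ValueError("empty term in reaction")
    m = _COEFF_RE.match(term)
    if m:
        coeff = int(m.group(1))
        if coeff < 1:
            raise ValueError(f"malformed coefficient in term {term!r}")
        return coeff, _normalize_species(m.group(2))
    return 1, _normalize_species(term)


def _parse_side(side: str) -> tuple[tuple[int, str], ...]:
    # " + " separates terms; a species-internal "+" (NAD+, H+) has no
    # surrounding spaces and therefore survives the split.
    terms = [t for t in re.split(r"\s\+\s", f" {side} ")]
    parsed = tuple(_parse_term(t) for t in terms)
    return parsed


def parse_reaction(text: str) -> ReactionEquation:
    """Parse one reaction string into a :class:`ReactionEquation`.

    The string must contain exactly one forward arrow (``→`` or ``->``);
    bidirectional arrows are rejected.
    """
    if _BIDIRECTIONAL_RE.search(text):
        raise ValueError(f"bidirectional arrow not supported: {text!r}")
    hits = list(_ARROW_RE.finditer(text))
    if not hits:
        raise ValueError(f"no reaction arrow in {text!r}")
    if len(hits) > 1:
        raise ValueError(f"multiple reaction arrows in {text!r}")
    m = hits[0]
    lhs, rhs = text[: m.start(1)], text[m.end(1) :]
    if not lhs.strip() or not rhs.strip():
        raise ValueError(f"empty reaction side in {text!r}")
    return ReactionEquation(_parse_side(lhs), _parse_side(rhs), raw_text=text)


def net_proton_coefficient(rxn: ReactionEquation) -> int:
    """Net stoichiometric H+ production: product minus substrate coefficients."""
    produced = sum(c for c, s in rxn.products if s == "H+")
    consumed = sum(c for c, s in rxn.substrates if s == "H+")
    return produced - consumed


def classify_h_producing(
    rxns: list[ReactionEquation],
) -> tuple[list[str], dict[str, int]]:
    """Label each reaction producing / consuming / neutral by net H+ sign.

    Returns the per-reaction labels and a label -> count summary.
    """
    labels = []
    for rxn in rxns:
        net = net_proton_coefficient(rxn)
        labels.append("producing" if net > 0 else "consuming" if net < 0 else "neutral")
    counts = {lab: labels.count(lab) for lab in ("producing", "consuming", "neutral")}
    return labels, counts


def load_reaction_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV with a ``reaction`` column (extra columns such as enzyme
    names pass through) and append parsed net_H and label columns."""
    df = pd.read_csv(path, sep="\t")
    if "reaction" not in df.columns:
        raise ValueError("reaction table must have a 'reaction' column")
    parsed = [parse_reaction(t) for t in df["reaction"]]
    df["net_H"] = [net_proton_coefficient(r) for r in parsed]
    df["label"] = ["producing" if n > 0 else "consuming" if n < 0 else "neutral" for n in df["net_H"]]
    return df


def bundled_reactions() -> pd.DataFrame:
    """The packaged table of proton-producing reactions catalyzed by enzymes
    upregulated in brain-metastasized primary tumors (enzyme, group-median
    TPMs, reaction string), with net_H and label columns appended."""
    with resources.as_file(
        resources.files("brainmet.data").joinpath("bmp_enzyme_reactions.tsv")
    ) as p:
        return load_reaction_table(p)
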