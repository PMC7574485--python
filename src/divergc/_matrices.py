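"""Derivation of the bundled amino-acid dissimilarity tables.

Two classical dissimilarity measures are provided:

* A Sneath-style index (after Sneath 1966): the dissimilarity between two
  residues is the percentage of binary side-chain attributes in which they
  differ.  Symmetric by construction, zero on the diagonal.
* An Epstein-style coefficient of difference (after Epstein 1967): built
  from differences in side-chain polarity and size.  Replacements that
  *increase* side-chain size are penalised more than those that shrink it,
  so the coefficient is direction-dependent (ancestral -> derived).

The original publications print neither table in machine-readable form, so
the constants bundled under ``data/`` are generated from the curated
attribute table and formula below (see ``scripts/derive_matrices.py``); the
construction principles follow the cited originals.  All downstream results
that matter here (ranking, enrichment) depend on relative, not absolute,
dissimilarity values.
"""

from __future__ import annotations

import math

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Binary side-chain attributes (Taylor-style classification plus a few
# structural features).  Order is irrelevant; only membership matters.
SNEATH_ATTRIBUTES: dict[str, frozenset[str]] = {
    "aliphatic": frozenset("AGVLIP"),
    "aromatic": frozenset("FYWH"),
    "polar": frozenset("STCYNQDEKRH"),
    "charged": frozenset("DEKRH"),
    "positive": frozenset("KRH"),
    "negative": frozenset("DE"),
    "small": frozenset("AGSCTPNDV"),
    "tiny": frozenset("AGS"),
    "hydrophobic": frozenset("ACFILMVWY"),
    "hydroxyl": frozenset("STY"),
    "sulfur": frozenset("CM"),
    "amide": frozenset("NQ"),
    "branched": frozenset("VIT"),
    "ring": frozenset("PFYWH"),
    "guanidinium": frozenset("R"),
    "nitrogenous": frozenset("NQKRHW"),
}

# Side-chain polarity class: 1.0 charged, 0.5 polar uncharged, 0.0 nonpolar.
_POLARITY: dict[str, float] = {}
for _aa in AMINO_ACIDS:
    if _aa in "DEKRH":
        _POLARITY[_aa] = 1.0
    elif _aa in "STNQYCW":
        _POLARITY[_aa] = 0.5
    else:
        _POLARITY[_aa] = 0.0

# Residue volumes in cubic angstroms (Zamyatnin 1972).
_VOLUME: dict[str, float] = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}
_VMIN = min(_VOLUME.values())
_VMAX = max(_VOLUME.values())

# Minimum coefficient for any true substitution: polarity and size are the
# only two axes the Epstein construction sees, and e.g. Leu/Ile tie on both;
# distinct residues are never chemically identical, so a small positive
# floor keeps every off-diagonal entry strictly positive.
EPSTEIN_FLOOR = 1.0


def _size(aa: str) -> float:
    return (_VOLUME[aa] - _VMIN) / (_VMAX - _VMIN)


def derive_sneath(a: str, b: str) -> float:
    """Percentage of binary attributes in which residues a and b differ."""
    if a == b:
        return 0.0
    n_diff = sum(
        1 for members in SNEATH_ATTRIBUTES.values() if (a in members) != (b in members)
    )
    return round(100.0 * n_diff / len(SNEATH_ATTRIBUTES), 2)


def derive_epstein(from_aa: str, to_aa: str) -> float:
    """Directed coefficient of difference for the change from_aa -> to_aa.

    sqrt(dp^2 + (c*ds)^2) scaled to a 0-100 range, with c = 1 when the
    side chain grows and c = 0.5 when it shrinks (steric insertion is the
    harder perturbation to accommodate).
    """
    if from_aa == to_aa:
        return 0.0
    dp = _POLARITY[to_aa] - _POLARITY[from_aa]
    ds = _size(to_aa) - _size(from_aa)
    c = 1.0 if ds > 0 else 0.5
    raw = 100.0 / math.sqrt(2.0) * math.sqrt(dp * dp + (c * ds) ** 2)
    return round(max(raw, EPSTEIN_FLOOR), 2)


def derive_matrix(name: str) -> dict[tuple[str, str], float]:
    """Full 20x20 table for 'sneath' or 'epstein'."""
    if name == "sneath":
        fn = derive_sneath
    elif name == "epstein":
        fn = derive_epstein
    else:
        raise ValueError(f"unknown matrix {name!r}")
    return {(a, b): fn(a, b) for a in AMINO_ACIDS for b in AMINO_ACIDS}


def format_matrix_tsv(name: str) -> str:
    """Render the table as TSV with a citation header (rows = from, cols = to)."""
    values = derive_matrix(name)
    citation = {
        "sneath": "# Sneath-style dissimilarity index (construction after Sneath 1966, J Theor Biol 12:157).",
        "epstein": "# Epstein-style coefficient of difference (construction after Epstein 1967, Nature 215:355).",
    }[name]
    lines = [
        citation,
        "# Generated by scripts/derive_matrices.py; rows = from-residue, columns = to-residue.",
        "\t".join(["aa"] + list(AMINO_ACIDS)),
    ]
    for a in AMINO_ACIDS:
        row = [a] + [format(values[(a, b)], "g") for b in AMINO_ACIDS]
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"
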