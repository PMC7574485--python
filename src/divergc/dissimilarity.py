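"""Amino-acid dissimilarity scoring at outgroup-conserved positions.

For each requested species, the dissimilarity of its residue to the outgroup
consensus is looked up in a 20x20 table (Sneath-style index or Epstein-style
coefficient of difference, bundled under ``data/``) at every conserved
position and summed; dividing the sum by the parsed alignment length gives
the adjusted dissimilarity value used for ranking.

The Epstein-style coefficient is direction-dependent; it is always evaluated
consensus -> focal, i.e. ancestral state to derived state, since the shared
outgroup residue is taken as the ancestral rodent state.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import pandas as pd

from ._matrices import AMINO_ACIDS
from .alignment import CodonAlignment, ConservedMask, translate_codon


class UnknownResidueError(KeyError):
    """Residue outside the 20 canonical amino acids."""


@dataclass(frozen=True)
class AADissimMatrix:
    """A 20x20 amino-acid dissimilarity table (rows = from, cols = to)."""

    name: str
    values: dict[tuple[str, str], float]
    symmetric: bool

    def __call__(self, from_aa: str, to_aa: str) -> float:
        try:
            return self.values[(from_aa, to_aa)]
        except KeyError:
            bad = from_aa if from_aa not in AMINO_ACIDS else to_aa
            raise UnknownResidueError(f"non-canonical residue {bad!r}") from None

    def validate(self) -> None:
        for a in AMINO_ACIDS:
            assert self.values[(a, a)] == 0.0, f"{self.name}: nonzero diagonal at {a}"
            for b in AMINO_ACIDS:
                v = self.values[(a, b)]
                assert v >= 0.0, f"{self.name}: negative entry {a}->{b}"
                if self.symmetric:
                    assert v == self.values[(b, a)], f"{self.name}: asymmetric {a},{b}"


def _load_matrix(name: str, symmetric: bool) -> AADissimMatrix:
    ref = importlib.resources.files("divergc").joinpath(f"data/{name}.tsv")
    with ref.open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#", index_col=0)
    values = {
        (a, b): float(df.at[a, b]) for a in AMINO_ACIDS for b in AMINO_ACIDS
    }
    m = AADissimMatrix(name=name, values=values, symmetric=symmetric)
    m.validate()
    return m


SNEATH: AADissimMatrix = _load_matrix("sneath", symmetric=True)
EPSTEIN: AADissimMatrix = _load_matrix("epstein", symmetric=False)

MATRICES: dict[str, AADissimMatrix] = {"sneath": SNEATH, "epstein": EPSTEIN}


def sneath_distance(a: str, b: str) -> float:
    """Symmetric Sneath-style dissimilarity between residues a and b."""
    return SNEATH(a, b)


def epstein_distance(from_aa: str, to_aa: str) -> float:
    """Directed Epstein-style coefficient for the change from_aa -> to_aa."""
    return EPSTEIN(from_aa, to_aa)


@dataclass
class DissimilarityScore:
    """Raw and length-adjusted dissimilarity of one species in one gene."""

    gene_id: str
    species: str
    metric: str
    raw_sum: float
    parsed_length: int
    n_conserved: int
    n_diff: int
    n_skipped: int = 0  # conserved columns with a non-canonical focal residue

    @property
    def adjusted(self) -> float:
        return self.raw_sum / self.parsed_length


def score_protein(
    aln: CodonAlignment,
    mask: ConservedMask,
    focal: str,
    matrix: AADissimMatrix | str = SNEATH,
) -> DissimilarityScore:
    """Sum matrix(consensus, focal residue) over conserved positions.

    ``aln`` is the site-filtered alignment that produced ``mask``.  Conserved
    columns where the focal residue is non-canonical (possible in degenerate
    inputs) are skipped and counted in ``n_skipped`` rather than scored.
    """
    if isinstance(matrix, str):
        matrix = MATRICES[matrix]
    if mask.excluded:
        raise ValueError(f"{aln.gene_id}: mask excluded (<{mask.min_sites} conserved)")
    local_of = {orig: local for local, orig in enumerate(mask.columns_kept)}
    row = aln.row(focal)
    raw = 0.0
    n_diff = 0
    n_skipped = 0
    for orig, consensus_aa in zip(mask.conserved, mask.consensus):
        local = local_of[orig]
        codon = row[3 * local : 3 * local + 3]
        aa = translate_codon(codon)
        if aa not in AMINO_ACIDS:
            n_skipped += 1
            continue
        if aa != consensus_aa:
            n_diff += 1
            raw += matrix(consensus_aa, aa)
    return DissimilarityScore(
        gene_id=aln.gene_id,
        species=focal,
        metric=matrix.name,
        raw_sum=raw,
        parsed_length=mask.parsed_length,
        n_conserved=mask.n_conserved,
        n_diff=n_diff,
        n_skipped=n_skipped,
    )


def score_table(
    genes: list[tuple[CodonAlignment, ConservedMask]],
    species: list[str],
    metrics: tuple[str, ...] = ("sneath", "epstein"),
) -> pd.DataFrame:
    """Per-gene x species x metric adjusted-score table.

    Genes with an excluded mask, or missing one of the requested species,
    are dropped.
    """
    rows = []
    for aln, mask in genes:
        if mask.excluded:
            continue
        if not set(species) <= set(aln.taxa):
            continue
        for metric in metrics:
            for sp in species:
                s = score_protein(aln, mask, sp, MATRICES[metric])
                rows.append(
                    {
                        "gene_id": s.gene_id,
                        "species": sp,
                        "metric": metric,
                        "raw": s.raw_sum,
                        "parsed_length": s.parsed_length,
                        "adjusted": s.adjusted,
                        "n_conserved": s.n_conserved,
                        "n_diff": s.n_diff,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "species", "metric", "raw", "parsed_length",
            "adjusted", "n_conserved", "n_diff",
        ],
    )
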