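"""Codon-alignment parsing, curation filters and conserved-position masks.

A per-gene codon-aware nucleotide alignment is curated in three steps:

1. :func:`filter_gappy_sequences` drops any sequence whose gap count exceeds
   70% of the non-gap length of the longest sequence in the alignment.
2. :func:`filter_sites` removes every amino-acid column in which any species
   shows a stop codon, an unknown residue or a missing residue.
3. :func:`conserved_mask` marks the columns at which three nested outgroup
   species (chosen by :func:`select_outgroups` with documented fallbacks)
   share a single residue; these "conserved positions" are taken as the
   ancestral rodent state and are the only positions scored downstream.

Column coordinates are 0-based amino-acid positions in the post-parse
alignment; masks always reference pre-site-filter coordinates so scores can
be mapped back to the original alignment.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Data import CodonTable

GAP = "-"

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)
#: codon -> one-letter residue for the 61 sense codons of the standard code
CODON_TO_AA: dict[str, str] = dict(_STANDARD_TABLE.forward_table)


class MalformedAlignmentError(ValueError):
    """Rows of unequal length, or other structural FASTA problems."""


class FrameError(ValueError):
    """Alignment length is not a multiple of three."""


class InsufficientTaxaError(ValueError):
    """Fewer than four taxa (overall or after filtering)."""


class EmptyAlignmentError(ValueError):
    """No alignment columns survive site filtering."""


class NoOutgroupError(ValueError):
    """No outgroup fallback tier is satisfiable for this alignment."""


def translate_codon(codon: str) -> str:
    """Translate one aligned codon; '-' for all-gap, 'X' for anything odd.

    A codon containing a mixture of gaps and bases, an ambiguity code, or a
    character outside ACGT is reported as 'X' (unknown residue); stop codons
    translate to '*'.
    """
    codon = codon.upper()
    if codon == GAP * 3:
        return GAP
    if codon in STOP_CODONS:
        return "*"
    aa = CODON_TO_AA.get(codon)
    return aa if aa is not None else "X"


@dataclass
class CodonAlignment:
    """One gene's aligned coding sequences across species."""

    gene_id: str
    taxa: list[str]
    rows: list[str]
    source_path: str = ""

    def __post_init__(self) -> None:
        self.rows = [r.upper() for r in self.rows]
        self.validate()

    def validate(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise MalformedAlignmentError(
                f"{self.gene_id}: {len(self.taxa)} labels but {len(self.rows)} rows"
            )
        if len(set(self.taxa)) != len(self.taxa):
            raise MalformedAlignmentError(f"{self.gene_id}: duplicate taxon labels")
        if len(self.taxa) < 4:
            raise InsufficientTaxaError(
                f"{self.gene_id}: need >=4 taxa, got {len(self.taxa)}"
            )
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise MalformedAlignmentError(
                f"{self.gene_id}: unequal row lengths {sorted(lengths)}"
            )
        if self.length % 3 != 0:
            raise FrameError(
                f"{self.gene_id}: alignment length {self.length} not a multiple of 3"
            )

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def n_codons(self) -> int:
        return self.length // 3

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def codon(self, taxon: str, column: int) -> str:
        """Codon of `taxon` at amino-acid column `column` (0-based)."""
        seq = self.row(taxon)
        return seq[3 * column : 3 * column + 3]

    def residue(self, taxon: str, column: int) -> str:
        return translate_codon(self.codon(taxon, column))

    def subset_taxa(self, keep: list[str]) -> "CodonAlignment":
        idx = [self.taxa.index(t) for t in keep]
        return CodonAlignment(
            self.gene_id, [self.taxa[i] for i in idx], [self.rows[i] for i in idx],
            self.source_path,
        )

    def subset_columns(self, columns: list[int]) -> "CodonAlignment":
        rows = [
            "".join(r[3 * c : 3 * c + 3] for c in columns) for r in self.rows
        ]
        return CodonAlignment(self.gene_id, list(self.taxa), rows, self.source_path)


@dataclass(frozen=True)
class OutgroupTriple:
    """Three outgroup species and the fallback tier (1-4) that produced them."""

    species: tuple[str, str, str]
    tier: int


@dataclass
class ConservedMask:
    """Outgroup-conserved positions of one site-filtered gene alignment.

    ``columns_kept`` and ``conserved`` are pre-site-filter amino-acid column
    indices; ``consensus[i]`` is the shared outgroup residue at
    ``conserved[i]``.  ``parsed_length`` is the number of surviving columns
    and is the denominator of adjusted dissimilarity scores.
    """

    gene_id: str
    columns_kept: list[int]
    conserved: list[int]
    consensus: list[str]
    outgroups: OutgroupTriple | None = None
    min_sites: int = 50
    excluded: bool = field(init=False)

    def __post_init__(self) -> None:
        kept = set(self.columns_kept)
        if not set(self.conserved) <= kept:
            raise ValueError(f"{self.gene_id}: conserved columns outside columns_kept")
        if len(self.consensus) != len(self.conserved):
            raise ValueError(f"{self.gene_id}: consensus/conserved length mismatch")
        self.excluded = len(self.conserved) < self.min_sites

    @property
    def parsed_length(self) -> int:
        return len(self.columns_kept)

    @property
    def n_conserved(self) -> int:
        return len(self.conserved)


# Outgroup fallback tiers, in preference order.
OUTGROUP_TIERS: tuple[tuple[str, str, str], ...] = (
    ("human", "guinea_pig", "squirrel"),
    ("human", "degu", "chinchilla"),
    ("human", "guinea_pig", "jerboa"),
    ("human", "squirrel", "degu"),
)


def parse_codon_alignment(path: str | os.PathLike, gene_id: str | None = None) -> CodonAlignment:
    """Read one gene's FASTA codon alignment and validate its structure."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise MalformedAlignmentError(f"{path}: no FASTA records")
    if gene_id is None:
        gene_id = os.path.splitext(os.path.basename(str(path)))[0]
    return CodonAlignment(
        gene_id=gene_id,
        taxa=[r.id for r in records],
        rows=[str(r.seq) for r in records],
        source_path=str(path),
    )


def write_codon_alignment(aln: CodonAlignment, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for taxon, row in zip(aln.taxa, aln.rows):
            fh.write(f">{taxon}\n{row}\n")


def filter_gappy_sequences(aln: CodonAlignment, frac: float = 0.7) -> CodonAlignment:
    """Drop sequences whose gaps exceed ``frac`` of the longest non-gap length.

    The reference length (non-gap length of the longest sequence) is computed
    once, before any removal; the comparison is strictly greater-than, so a
    sequence with gaps exactly at the threshold is retained.
    """
    longest = max(len(r) - r.count(GAP) for r in aln.rows)
    keep = [t for t, r in zip(aln.taxa, aln.rows) if r.count(GAP) <= frac * longest]
    if len(keep) == len(aln.taxa):
        return aln
    if len(keep) < 4:
        raise InsufficientTaxaError(
            f"{aln.gene_id}: only {len(keep)} taxa left after gap filtering"
        )
    return aln.subset_taxa(keep)


def filter_sites(aln: CodonAlignment) -> tuple[CodonAlignment, list[int]]:
    """Remove amino-acid columns with a stop, unknown or missing residue.

    Whole codons are removed.  Returns the filtered alignment and the kept
    column indices in pre-filter amino-acid coordinates.  Ambiguity codes
    other than N are treated as unknown residues too.
    """
    columns_kept: list[int] = []
    for col in range(aln.n_codons):
        ok = True
        for row in aln.rows:
            aa = translate_codon(row[3 * col : 3 * col + 3])
            if aa in ("*", "X", GAP):
                ok = False
                break
        if ok:
            columns_kept.append(col)
    if not columns_kept:
        raise EmptyAlignmentError(f"{aln.gene_id}: no columns survive site filtering")
    return aln.subset_columns(columns_kept), columns_kept


def select_outgroups(
    aln: CodonAlignment,
    preference: tuple[tuple[str, str, str], ...] = OUTGROUP_TIERS,
) -> OutgroupTriple:
    """First fallback tier whose three outgroup species are all present."""
    present = set(aln.taxa)
    for tier, triple in enumerate(preference, start=1):
        if set(triple) <= present:
            return OutgroupTriple(species=triple, tier=tier)
    raise NoOutgroupError(f"{aln.gene_id}: no outgroup tier satisfiable")


def conserved_mask(
    aln: CodonAlignment,
    triple: OutgroupTriple,
    min_sites: int = 50,
    columns_kept: list[int] | None = None,
) -> ConservedMask:
    """Columns where the three outgroups share one residue.

    ``aln`` must already be site-filtered; ``columns_kept`` supplies the
    pre-filter coordinates of its columns (defaults to 0..n-1).
    """
    if columns_kept is None:
        columns_kept = list(range(aln.n_codons))
    if len(columns_kept) != aln.n_codons:
        raise ValueError(f"{aln.gene_id}: columns_kept does not match alignment width")
    og_rows = [aln.row(sp) for sp in triple.species]
    conserved: list[int] = []
    consensus: list[str] = []
    for local, orig in enumerate(columns_kept):
        residues = {translate_codon(r[3 * local : 3 * local + 3]) for r in og_rows}
        if len(residues) == 1:
            aa = residues.pop()
            conserved.append(orig)
            consensus.append(aa)
    return ConservedMask(
        gene_id=aln.gene_id,
        columns_kept=list(columns_kept),
        conserved=conserved,
        consensus=consensus,
        outgroups=triple,
        min_sites=min_sites,
    )


@dataclass
class CuratedGene:
    """Result of running the full curation pipeline on one gene."""

    alignment: CodonAlignment  # site-filtered
    mask: ConservedMask
    skipped: str | None = None  # reason, when the gene cannot be used


def curate_gene(
    aln: CodonAlignment,
    gap_frac: float = 0.7,
    min_sites: int = 50,
    preference: tuple[tuple[str, str, str], ...] = OUTGROUP_TIERS,
) -> CuratedGene:
    """Gap filter -> site filter -> outgroup selection -> conserved mask."""
    aln = filter_gappy_sequences(aln, gap_frac)
    filtered, columns_kept = filter_sites(aln)
    triple = select_outgroups(filtered, preference)
    mask = conserved_mask(filtered, triple, min_sites=min_sites, columns_kept=columns_kept)
    return CuratedGene(alignment=filtered, mask=mask,
                       skipped="excluded_lt_min_sites" if mask.excluded else None)
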