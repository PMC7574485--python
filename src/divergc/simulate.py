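"""Synthetic codon-alignment datasets with planted gBGC islands.

The generator evolves per-gene codon sequences along a 13-taxon rodent-like
species tree by a Gillespie process at nucleotide resolution and emits every
file the analysis pipeline reads (per-gene FASTA alignments, the Newick
tree, a gene-locus TSV, a high-GC region BED) together with a truth table of
every substitution event.

Model, per site and branch (rate of a single-nucleotide change, per unit
branch length):

    rate = mu/3 * f_selection * f_gbgc

* Changes creating a stop codon are rejected (rate 0).
* Nonsynonymous changes are scaled by ``omega`` (< 1, purifying selection);
  at "constrained" codons (a per-gene fraction ``conserved_fraction``) they
  are further scaled by ``constrained_omega``, and on branches outside the
  murid-gerbil clade they are forbidden outright, which guarantees the
  outgroup-conserved positions that the scoring stage requires.
* GC-biased gene conversion acts on weak-to-strong changes on
  gerbil-lineage branches of island genes as an additional fixation route:
  their rate is mu/3 * (f_selection + (gbgc_lambda - 1)).  At
  ``gbgc_lambda`` = 1 the model reduces exactly to the neutral/purifying
  process; at large ``gbgc_lambda`` conversion overrides selection, fixing
  weak-to-strong changes that purifying selection would have purged -- the
  regime that produces radically divergent proteins inside GC islands.

Island genes are placed contiguously on a synthetic chromosome inside the
emitted high-GC interval; all other genes are placed uniformly elsewhere.
A fixed seed yields bitwise-identical outputs.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .alignment import CODON_TO_AA, STOP_CODONS, CodonAlignment, write_codon_alignment
from .regions import RegionSet, add_midpoints
from .spectra import NUCS, SpeciesTree, classify_nt_change

# 12 rodents + human; branch lengths in neutral substitutions/site, in
# proportion to published divergence times (gerbil/murid split deeper than
# either crown group, gerbil stem longer than the gerbil terminals).
DEFAULT_TREE_NEWICK = (
    "(human:0.30,(squirrel:0.24,((guinea_pig:0.17,(naked_mole_rat:0.15,"
    "(chinchilla:0.11,degu:0.11)chin_degu:0.04)hystrico_inner:0.02)hystricomorpha:0.05,"
    "(kangaroo_rat:0.21,(jerboa:0.19,(blind_mole_rat:0.16,((mouse:0.060,rat:0.060)"
    "murids:0.065,(sand_rat:0.050,mongolian_jird:0.050)gerbils:0.075)muridae:0.035)"
    "eumuroida:0.025)myomorpha:0.02)mouse_related:0.02)rodentia_core:0.02)rodentia:0.04)root;"
)

GERBIL_TAXA = ("sand_rat", "mongolian_jird")
MURID_TAXA = ("mouse", "rat")

# synthetic genome layout (bp)
ISLAND_CHROM = "chrS1"
OTHER_CHROM = "chrS2"
ISLAND_START = 10_000_000
ISLAND_GENE_SPACING = 60_000
ISLAND_MARGIN = 25_000
CHROM_LENGTH = 120_000_000
ISLAND_EXCLUSION = 1_000_000  # keep non-island genes this far from the island


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset."""

    tree_newick: str = DEFAULT_TREE_NEWICK
    n_genes: int = 300
    island_fraction: float = 0.1
    gbgc_lambda: float = 5.0
    mean_gene_length: int = 200  # codons
    base_mutation_rate: float = 1.0  # scales branch lengths
    omega: float = 0.2  # nonsyn/syn rate ratio, purifying
    constrained_omega: float = 0.05  # extra nonsyn penalty at constrained codons
    conserved_fraction: float = 0.6  # fraction of codons constrained
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.island_fraction <= 1.0:
            raise ValueError("island_fraction must be in [0, 1]")
        if self.gbgc_lambda < 1.0:
            raise ValueError("gbgc_lambda must be >= 1")
        if self.omega <= 0:
            raise ValueError("omega must be > 0")
        if min(self.base_mutation_rate, self.constrained_omega) < 0:
            raise ValueError("rates must be >= 0")
        if self.mean_gene_length < 1:
            raise ValueError("mean_gene_length must be >= 1")

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class Event:
    """One substitution event in the truth table."""

    branch: str  # label of the child node of the edge
    codon_index: int
    pos: int  # 0-2 within the codon
    from_codon: str
    to_codon: str
    syn: bool
    category: str


@dataclass
class GeneTruth:
    """Everything needed to replay one gene's simulation exactly."""

    gene_id: str
    island: bool
    root_seq: str
    constrained: list[int]
    events_by_branch: dict[str, list[Event]] = field(default_factory=dict)

    @property
    def n_events(self) -> int:
        return sum(len(v) for v in self.events_by_branch.values())


# ---------------------------------------------------------------------------
# Precomputed codon-change tables (64 codons x 3 positions x 4 target bases)

_N_CODONS = 64


def _codon_str(c: int) -> str:
    return NUCS[(c >> 4) & 3] + NUCS[(c >> 2) & 3] + NUCS[c & 3]


def _codon_int(s: str) -> int:
    i = {b: k for k, b in enumerate(NUCS)}
    return (i[s[0]] << 4) | (i[s[1]] << 2) | i[s[2]]


CODON_STRS = [_codon_str(c) for c in range(_N_CODONS)]
IS_STOP = np.array([CODON_STRS[c] in STOP_CODONS for c in range(_N_CODONS)])
_AA = [None if IS_STOP[c] else CODON_TO_AA[CODON_STRS[c]] for c in range(_N_CODONS)]

_ALLOWED = np.zeros((_N_CODONS, 3, 4), dtype=bool)  # real, non-stop change
_SYN = np.zeros((_N_CODONS, 3, 4), dtype=bool)
_WS = np.zeros((_N_CODONS, 3, 4), dtype=bool)
_TARGET = np.zeros((_N_CODONS, 3, 4), dtype=np.int16)
_CATEGORY = np.zeros((_N_CODONS, 3, 4), dtype="U2")
for _c in range(_N_CODONS):
    if IS_STOP[_c]:
        continue
    s = CODON_STRS[_c]
    for _pos in range(3):
        for _alt in range(4):
            t = s[:_pos] + NUCS[_alt] + s[_pos + 1 :]
            ti = _codon_int(t)
            _TARGET[_c, _pos, _alt] = ti
            if t == s or IS_STOP[ti]:
                continue
            _ALLOWED[_c, _pos, _alt] = True
            _SYN[_c, _pos, _alt] = _AA[ti] == _AA[_c]
            cat = classify_nt_change(s[_pos], NUCS[_alt])
            _CATEGORY[_c, _pos, _alt] = cat
            _WS[_c, _pos, _alt] = cat == "WS"

SENSE_CODONS = np.flatnonzero(~IS_STOP)


def _codon_rates(
    codons: np.ndarray,
    constrained: np.ndarray,
    mu: float,
    omega: float,
    phi: float,
    gbgc_lambda: float,
    gbgc_branch: bool,
    outgroup_branch: bool,
) -> np.ndarray:
    """Per-(codon, position, target-base) event rates for one branch."""
    allowed = _ALLOWED[codons]
    syn = _SYN[codons]
    factor = np.where(allowed, 1.0, 0.0)
    nonsyn = allowed & ~syn
    factor[nonsyn] *= omega
    cmask = constrained[:, None, None] & nonsyn
    factor[cmask] *= 0.0 if outgroup_branch else phi
    if gbgc_branch and gbgc_lambda > 1.0:
        # conversion is an additional fixation route for W->S changes,
        # independent of the selection filter
        ws = _WS[codons] & allowed
        factor[ws] += gbgc_lambda - 1.0
    return (mu / 3.0) * factor


def _gc3(seq: str) -> float:
    thirds = seq[2::3]
    return sum(1 for b in thirds if b in "GC") / len(thirds)


def simulate_gene(
    config: SimulationConfig,
    island: bool,
    rng: np.random.Generator,
    tree: SpeciesTree | None = None,
    gene_id: str = "gene",
    n_codons: int | None = None,
) -> tuple[CodonAlignment, GeneTruth]:
    """Evolve one gene along the tree; returns alignment + truth record."""
    if tree is None:
        tree = SpeciesTree.from_newick(config.tree_newick, is_path=False)
    if n_codons is None:
        n_codons = max(60, int(round(rng.gamma(6.0, config.mean_gene_length / 6.0))))
    if n_codons < 1:
        raise ValueError("zero-length gene")

    n_constrained = int(round(config.conserved_fraction * n_codons))
    constrained_idx = np.sort(rng.choice(n_codons, size=n_constrained, replace=False))
    constrained = np.zeros(n_codons, dtype=bool)
    constrained[constrained_idx] = True

    root_codons = rng.choice(SENSE_CODONS, size=n_codons)
    gerbil_clade = _clade_nodes(tree, GERBIL_TAXA)
    murid_gerbil_clade = _clade_nodes(tree, MURID_TAXA + GERBIL_TAXA, default_all=True)

    truth = GeneTruth(
        gene_id=gene_id,
        island=island,
        root_seq="".join(CODON_STRS[c] for c in root_codons),
        constrained=[int(i) for i in constrained_idx],
    )

    seqs: dict = {tree.tree.seed_node: root_codons}
    for node in tree.tree.preorder_node_iter():
        if node is tree.tree.seed_node:
            continue
        parent_codons = seqs[node.parent_node]
        codons = parent_codons.copy()
        t_branch = float(node.edge.length or 0.0)
        label = tree.node_label(node)
        events: list[Event] = []
        gbgc_branch = island and (node in gerbil_clade)
        outgroup_branch = node not in murid_gerbil_clade
        if t_branch > 0 and config.base_mutation_rate > 0:
            rates = _codon_rates(
                codons, constrained, config.base_mutation_rate, config.omega,
                config.constrained_omega, config.gbgc_lambda, gbgc_branch,
                outgroup_branch,
            )
            total = rates.sum()
            t = 0.0
            while total > 0:
                t += rng.exponential(1.0 / total)
                if t > t_branch:
                    break
                flat = rates.reshape(-1)
                u = rng.random() * total
                k = int(np.searchsorted(np.cumsum(flat), u))
                k = min(k, flat.size - 1)
                ci, pos, alt = np.unravel_index(k, rates.shape)
                from_codon = CODON_STRS[codons[ci]]
                to_int = int(_TARGET[codons[ci], pos, alt])
                events.append(
                    Event(
                        branch=label,
                        codon_index=int(ci),
                        pos=int(pos),
                        from_codon=from_codon,
                        to_codon=CODON_STRS[to_int],
                        syn=bool(_SYN[codons[ci], pos, alt]),
                        category=str(_CATEGORY[codons[ci], pos, alt]),
                    )
                )
                codons[ci] = to_int
                rates[ci] = _codon_rates(
                    codons[ci : ci + 1], constrained[ci : ci + 1],
                    config.base_mutation_rate, config.omega,
                    config.constrained_omega, config.gbgc_lambda, gbgc_branch,
                    outgroup_branch,
                )[0]
                total = rates.sum()
        seqs[node] = codons
        if events:
            truth.events_by_branch[label] = events

    taxa, rows = [], []
    for leaf in tree.tree.leaf_node_iter():
        taxa.append(leaf.taxon.label)
        rows.append("".join(CODON_STRS[c] for c in seqs[leaf]))
    aln = CodonAlignment(gene_id=gene_id, taxa=taxa, rows=rows, source_path="simulated")
    return aln, truth


def _clade_nodes(
    tree: SpeciesTree, tip_labels: tuple[str, ...], default_all: bool = False
) -> set:
    """All nodes in the clade spanned by tip_labels (MRCA subtree, MRCA
    included).  When fewer than two of the tips are in the tree (custom
    trees without the rodent taxa) returns all nodes or none, per
    ``default_all``."""
    try:
        mrca = tree.mrca(list(tip_labels))
    except ValueError:
        return set(tree.tree.preorder_node_iter()) if default_all else set()
    return set(mrca.preorder_iter())


def replay_gene(truth: GeneTruth, tree: SpeciesTree) -> dict[str, str]:
    """Re-apply truth events from the root; returns tip label -> sequence."""
    out: dict[str, str] = {}
    for leaf in tree.tree.leaf_node_iter():
        path = []
        node = leaf
        while node is not None:
            path.append(node)
            node = node.parent_node
        seq = list(truth.root_seq)
        for node in reversed(path[:-1]):  # root's own edge carries no events
            for ev in truth.events_by_branch.get(tree.node_label(node), []):
                i = 3 * ev.codon_index + ev.pos
                seq[i] = ev.to_codon[ev.pos]
        out[leaf.taxon.label] = "".join(seq)
    return out


@dataclass
class SimulatedDataset:
    """In-memory result of :func:`simulate_dataset`."""

    config: SimulationConfig
    tree: SpeciesTree
    alignments: dict[str, CodonAlignment]
    truths: dict[str, GeneTruth]
    loci: pd.DataFrame  # 0-based half-open, with midpoint
    regions: RegionSet
    island_genes: list[str]

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for gene_id, truth in self.truths.items():
            for events in truth.events_by_branch.values():
                for ev in events:
                    rows.append(
                        {
                            "gene_id": gene_id,
                            "island": truth.island,
                            "branch": ev.branch,
                            "codon_index": ev.codon_index,
                            "pos": ev.pos,
                            "from_codon": ev.from_codon,
                            "to_codon": ev.to_codon,
                            "syn": ev.syn,
                            "category": ev.category,
                        }
                    )
        return pd.DataFrame(
            rows,
            columns=[
                "gene_id", "island", "branch", "codon_index", "pos",
                "from_codon", "to_codon", "syn", "category",
            ],
        )

    def write(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        aln_dir = os.path.join(outdir, "alignments")
        os.makedirs(aln_dir, exist_ok=True)
        for gene_id, aln in self.alignments.items():
            write_codon_alignment(aln, os.path.join(aln_dir, f"{gene_id}.fasta"))
        with open(os.path.join(outdir, "species_tree.nwk"), "w") as fh:
            fh.write(self.config.tree_newick + "\n")
        self.regions.to_bed(os.path.join(outdir, "high_gc_regions.bed"))
        loci = self.loci.copy()
        loci["start"] = loci["start"] + 1  # written 1-based inclusive
        loci[["gene_id", "chrom", "start", "end", "island"]].to_csv(
            os.path.join(outdir, "gene_loci.tsv"), sep="\t", index=False
        )
        self.truth_table().to_csv(
            os.path.join(outdir, "truth_table.tsv"), sep="\t", index=False
        )
        self.config.to_yaml(os.path.join(outdir, "config.yaml"))


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Simulate ``config.n_genes`` genes plus coordinates, regions and truth."""
    tree = SpeciesTree.from_newick(config.tree_newick, is_path=False)
    n_island = int(round(config.island_fraction * config.n_genes))
    if config.island_fraction > 0 and n_island == 0:
        warnings.warn("island_fraction * n_genes < 1; simulating zero islands")

    seed_seq = np.random.SeedSequence(config.seed)
    gene_seeds = seed_seq.spawn(config.n_genes)
    placement_rng = np.random.default_rng(seed_seq.spawn(1)[0])

    gene_ids = [f"g{i + 1:04d}" for i in range(config.n_genes)]
    island_flags = [i < n_island for i in range(config.n_genes)]

    alignments: dict[str, CodonAlignment] = {}
    truths: dict[str, GeneTruth] = {}
    for gid, island, gseed in zip(gene_ids, island_flags, gene_seeds):
        rng = np.random.default_rng(gseed)
        aln, truth = simulate_gene(config, island, rng, tree=tree, gene_id=gid)
        alignments[gid] = aln
        truths[gid] = truth

    # coordinates: island genes contiguous inside one high-GC interval
    loci_rows = []
    cursor = ISLAND_START
    for gid, island in zip(gene_ids, island_flags):
        gene_bp = alignments[gid].length
        if island:
            loci_rows.append((gid, ISLAND_CHROM, cursor, cursor + gene_bp, True))
            cursor += ISLAND_GENE_SPACING
    island_end = cursor - ISLAND_GENE_SPACING + (
        alignments[gene_ids[n_island - 1]].length if n_island else 0
    )
    if n_island:
        regions = RegionSet(
            intervals=[(ISLAND_CHROM, ISLAND_START - ISLAND_MARGIN,
                        island_end + ISLAND_MARGIN)],
            label="high-GC",
        )
        excl_lo = ISLAND_START - ISLAND_EXCLUSION
        excl_hi = island_end + ISLAND_EXCLUSION
    else:
        regions = RegionSet(intervals=[], label="high-GC")
        excl_lo = excl_hi = ISLAND_START
    for gid, island in zip(gene_ids, island_flags):
        if island:
            continue
        gene_bp = alignments[gid].length
        chrom = ISLAND_CHROM if placement_rng.random() < 0.5 else OTHER_CHROM
        while True:
            start = int(placement_rng.integers(0, CHROM_LENGTH - gene_bp))
            if chrom != ISLAND_CHROM or not (excl_lo - gene_bp < start < excl_hi):
                break
        loci_rows.append((gid, chrom, start, start + gene_bp, False))
    loci = pd.DataFrame(
        loci_rows, columns=["gene_id", "chrom", "start", "end", "island"]
    )
    loci = loci.set_index("gene_id").loc[gene_ids].reset_index()
    loci = add_midpoints(loci)

    return SimulatedDataset(
        config=config,
        tree=tree,
        alignments=alignments,
        truths=truths,
        loci=loci,
        regions=regions,
        island_genes=[g for g, f in zip(gene_ids, island_flags) if f],
    )

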