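"""Category-partitioned substitution counting along a phylogeny.

This stage attributes synonymous and nonsynonymous substitutions on the
branches between the murid-gerbil ancestor and a chosen tip to four directed
base-class categories:

* WS (weak to strong): A or T replaced by C or G
* SW (strong to weak): C or G replaced by A or T
* WW: A <-> T,  SS: C <-> G

Ancestral codon states are inferred by marginal maximum likelihood under a
JC69 nucleotide model on the fixed input tree (parsimony-free, but a simple
codon-agnostic approximation to full codon-model stochastic mapping; see
docs/methods.md).  Codon changes touching more than one position are
decomposed over all minimal single-step paths that avoid stop codons, each
path weighted equally.  Rates divide category counts by Nei-Gojobori
synonymous / nonsynonymous site opportunities computed on the tip sequence;
all four categories share the same denominator, so category rates sum to
the total dS (or dN).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import permutations

import dendropy
import numpy as np
import pandas as pd

from .alignment import CODON_TO_AA, STOP_CODONS, CodonAlignment

logger = logging.getLogger(__name__)

NUCS = "ACGT"
_NUC_INDEX = {b: i for i, b in enumerate(NUCS)}
WEAK = frozenset("AT")
STRONG = frozenset("CG")
CATEGORIES = ("WS", "SW", "WW", "SS")

#: taxa whose MRCA defines the murid-gerbil ancestor (span start)
MURID_GERBIL_TAXA = ("mouse", "rat", "sand_rat", "mongolian_jird")

OUTLIER_MULTIPLIER = 2.5


class NoChangeError(ValueError):
    """classify_nt_change called with identical bases."""


class UndefinedRateError(ValueError):
    """Zero synonymous or nonsynonymous opportunity."""


def classify_nt_change(from_base: str, to_base: str) -> str:
    """Directed base-class category of a single nucleotide change."""
    if from_base == to_base:
        raise NoChangeError(f"{from_base}->{to_base} is not a change")
    if from_base not in NUCS or to_base not in NUCS:
        raise ValueError(f"non-ACGT base in {from_base}->{to_base}")
    fw, tw = from_base in WEAK, to_base in WEAK
    if fw and not tw:
        return "WS"
    if not fw and tw:
        return "SW"
    return "WW" if fw else "SS"


def _translate(codon: str) -> str:
    if codon in STOP_CODONS:
        return "*"
    return CODON_TO_AA[codon]


def classify_codon_change(
    from_codon: str, to_codon: str
) -> list[tuple[bool, str, float]]:
    """Decompose a codon change into weighted single-nucleotide steps.

    Returns a list of (synonymous, category, weight) entries.  Multi-position
    changes are averaged over every minimal single-step path that avoids
    intermediate stop codons; when no stop-free path exists, all paths are
    used (logged).
    """
    from_codon, to_codon = from_codon.upper(), to_codon.upper()
    for c in (from_codon, to_codon):
        if c in STOP_CODONS:
            raise ValueError(f"stop codon {c} passed to classify_codon_change")
        if len(c) != 3 or any(b not in NUCS for b in c):
            raise ValueError(f"invalid codon {c!r}")
    diffs = [i for i in range(3) if from_codon[i] != to_codon[i]]
    if not diffs:
        return []
    paths: list[list[tuple[bool, str]]] = []
    stop_free: list[bool] = []
    for order in permutations(diffs):
        current = from_codon
        steps: list[tuple[bool, str]] = []
        ok = True
        for pos in order:
            nxt = current[:pos] + to_codon[pos] + current[pos + 1 :]
            syn = _translate(current) == _translate(nxt) and "*" not in (
                _translate(current), _translate(nxt)
            )
            steps.append((syn, classify_nt_change(current[pos], nxt[pos])))
            if nxt in STOP_CODONS:
                ok = False
            current = nxt
        paths.append(steps)
        stop_free.append(ok)
    if any(stop_free):
        chosen = [p for p, ok in zip(paths, stop_free) if ok]
    else:
        logger.debug("no stop-free path for %s->%s; using all paths", from_codon, to_codon)
        chosen = paths
    w = 1.0 / len(chosen)
    return [(syn, cat, w) for p in chosen for syn, cat in p]


# ---------------------------------------------------------------------------
# Species tree


@dataclass
class SpeciesTree:
    """Rooted species tree with branch lengths (substitutions/site)."""

    tree: dendropy.Tree

    @classmethod
    def from_newick(cls, source: str, is_path: bool | None = None) -> "SpeciesTree":
        if is_path is None:
            is_path = not source.strip().startswith("(")
        kwargs = dict(
            schema="newick",
            preserve_underscores=True,
            rooting="force-rooted",
            suppress_internal_node_taxa=False,
        )
        if is_path:
            tree = dendropy.Tree.get(path=source, **kwargs)
        else:
            tree = dendropy.Tree.get(data=source, **kwargs)
        st = cls(tree=tree)
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError("negative branch length in species tree")
        if len(st.tip_labels) != len(set(st.tip_labels)):
            raise ValueError("duplicate tip labels in species tree")
        # unlabeled internal nodes get deterministic labels so that branch
        # identities (truth tables, logs) are stable
        for i, node in enumerate(tree.preorder_node_iter()):
            if node.taxon is None and not node.label:
                node.label = f"nd{i}"
        return st

    @staticmethod
    def node_label(node: dendropy.Node) -> str:
        if node.taxon is not None:
            return node.taxon.label
        return node.label or ""

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def leaf(self, label: str) -> dendropy.Node:
        for node in self.tree.leaf_node_iter():
            if node.taxon.label == label:
                return node
        raise KeyError(f"tip {label!r} not in tree")

    def mrca(self, labels: list[str]) -> dendropy.Node:
        present = [l for l in labels if l in self.tip_labels]
        if len(present) < 2:
            raise ValueError(f"need >=2 of {labels} in tree to take an MRCA")
        return self.tree.mrca(taxon_labels=present)

    def span_node(self, span_taxa: tuple[str, ...] = MURID_GERBIL_TAXA) -> dendropy.Node:
        """The murid-gerbil ancestor: MRCA of the murid and gerbil tips."""
        return self.mrca(list(span_taxa))

    def path_to_tip(self, start: dendropy.Node, tip_label: str) -> list[dendropy.Node]:
        """Nodes from ``start`` down to the tip, inclusive of both ends."""
        node = self.leaf(tip_label)
        path = [node]
        while node is not start:
            node = node.parent_node
            if node is None:
                raise ValueError(f"tip {tip_label!r} is not a descendant of the span node")
            path.append(node)
        return list(reversed(path))


# ---------------------------------------------------------------------------
# Marginal-ML ancestral reconstruction (JC69, per nucleotide site)


def _jc69_P(t: float) -> np.ndarray:
    t = max(float(t or 0.0), 1e-9)
    e = np.exp(-4.0 * t / 3.0)
    P = np.full((4, 4), 0.25 * (1.0 - e))
    np.fill_diagonal(P, 0.25 + 0.75 * e)
    return P


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_NUC_INDEX.get(b, 4) for b in seq), dtype=np.int8, count=len(seq))


def reconstruct_ancestral(
    aln: CodonAlignment, tree: SpeciesTree
) -> dict[dendropy.Node, np.ndarray]:
    """Marginal-ML nucleotide states at every internal node.

    Each site is treated independently under JC69 with the tree's branch
    lengths.  Tips with an unknown character at a site contribute a flat
    likelihood there.  Returns, per node, the argmax state index array
    (tips included, as observed); ties resolve to the first base in ACGT
    order, deterministically.
    """
    taxa = set(aln.taxa)
    missing = [l for l in tree.tip_labels if l not in taxa]
    if missing:
        raise ValueError(f"tree tips absent from alignment: {missing}")
    n_sites = aln.length
    root = tree.tree.seed_node

    partial: dict[dendropy.Node, np.ndarray] = {}
    msg: dict[dendropy.Node, np.ndarray] = {}  # child message to its parent
    tip_states: dict[dendropy.Node, np.ndarray] = {}

    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            states = _encode(aln.row(node.taxon.label))
            tip_states[node] = states
            L = np.zeros((n_sites, 4))
            known = states < 4
            L[known, states[known]] = 1.0
            L[~known] = 1.0
        else:
            L = np.ones((n_sites, 4))
            for child in node.child_nodes():
                L *= msg[child]
        partial[node] = L
        if node is not root:
            P = _jc69_P(node.edge.length)
            msg[node] = L @ P.T  # msg[s, parent_state]

    outside: dict[dendropy.Node, np.ndarray] = {root: np.full((n_sites, 4), 0.25)}
    states_out: dict[dendropy.Node, np.ndarray] = {}
    for node in tree.tree.preorder_node_iter():
        if node.is_leaf():
            states_out[node] = tip_states[node]
            continue
        marginal = outside[node] * partial[node]
        # guard against all-zero rows (cannot happen with JC69 P > 0)
        states_out[node] = np.argmax(marginal, axis=1).astype(np.int8)
        for child in node.child_nodes():
            sib = outside[node].copy()
            for other in node.child_nodes():
                if other is not child:
                    sib *= msg[other]
            P = _jc69_P(child.edge.length)
            outside[child] = sib @ P
    return states_out


# ---------------------------------------------------------------------------
# Counting and rates


@dataclass
class SubstitutionTally:
    """Per-gene category substitution counts along the span to one tip."""

    gene_id: str
    species: str
    counts: dict[tuple[str, str], float]  # ("syn"|"nonsyn", category) -> count
    syn_opportunity: float
    nonsyn_opportunity: float
    n_codons_used: int = 0
    n_codons_skipped: int = 0

    def total(self, kind: str) -> float:
        return sum(self.counts[(kind, c)] for c in CATEGORIES)


def empty_counts() -> dict[tuple[str, str], float]:
    return {(k, c): 0.0 for k in ("syn", "nonsyn") for c in CATEGORIES}


def ng86_opportunities(seq: str) -> tuple[float, float, int]:
    """Nei-Gojobori fractional synonymous / nonsynonymous site counts.

    Codons containing a non-ACGT character or a stop are skipped.  Changes
    that create a stop codon count as nonsynonymous.  Returns
    (syn_sites, nonsyn_sites, n_codons_used).
    """
    syn = 0.0
    used = 0
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if any(b not in NUCS for b in codon) or codon in STOP_CODONS:
            continue
        used += 1
        aa = CODON_TO_AA[codon]
        for pos in range(3):
            n_syn = 0
            for alt in NUCS:
                if alt == codon[pos]:
                    continue
                mut = codon[:pos] + alt + codon[pos + 1 :]
                if mut not in STOP_CODONS and CODON_TO_AA[mut] == aa:
                    n_syn += 1
            syn += n_syn / 3.0
    return syn, 3.0 * used - syn, used


def _states_to_str(states: np.ndarray) -> str:
    return "".join(NUCS[k] if k < 4 else "N" for k in states)


def reconstruct_and_count(
    aln: CodonAlignment,
    tree: SpeciesTree,
    tip: str,
    span_taxa: tuple[str, ...] = MURID_GERBIL_TAXA,
    ancestral: dict[dendropy.Node, np.ndarray] | None = None,
) -> SubstitutionTally:
    """Category substitution counts from the murid-gerbil ancestor to a tip.

    ``ancestral`` may carry a precomputed :func:`reconstruct_ancestral`
    result so several tips can share one reconstruction.
    """
    if tip not in tree.tip_labels:
        raise KeyError(f"tip {tip!r} not in tree")
    if ancestral is None:
        ancestral = reconstruct_ancestral(aln, tree)
    start = tree.span_node(span_taxa)
    path = tree.path_to_tip(start, tip)

    counts = empty_counts()
    skipped = 0
    for parent, child in zip(path[:-1], path[1:]):
        pseq = _states_to_str(ancestral[parent])
        cseq = _states_to_str(ancestral[child])
        for i in range(0, aln.length - 2, 3):
            fc, tc = pseq[i : i + 3], cseq[i : i + 3]
            if "N" in fc or "N" in tc or fc in STOP_CODONS or tc in STOP_CODONS:
                skipped += 1
                continue
            for syn, cat, w in classify_codon_change(fc, tc):
                counts[("syn" if syn else "nonsyn", cat)] += w

    tip_seq = aln.row(tip)
    syn_opp, nonsyn_opp, used = ng86_opportunities(tip_seq)
    return SubstitutionTally(
        gene_id=aln.gene_id,
        species=tip,
        counts=counts,
        syn_opportunity=syn_opp,
        nonsyn_opportunity=nonsyn_opp,
        n_codons_used=used,
        n_codons_skipped=skipped,
    )


@dataclass
class RateSet:
    """Category substitution rates and the dS_ws/dS_sw GC-bias ratio."""

    gene_id: str
    species: str
    rates: dict[tuple[str, str], float]
    ratio_ws_sw: float = field(init=False)
    ratio_defined: bool = field(init=False)

    def __post_init__(self) -> None:
        ds_sw = self.rates[("syn", "SW")]
        if ds_sw > 0:
            self.ratio_ws_sw = self.rates[("syn", "WS")] / ds_sw
            self.ratio_defined = True
        else:
            self.ratio_ws_sw = float("nan")
            self.ratio_defined = False

    def __getattr__(self, name: str):
        # dS_ws, dN_ss, ... convenience accessors
        if name.startswith("dS_") or name.startswith("dN_"):
            kind = "syn" if name[1] == "S" else "nonsyn"
            cat = name[3:].upper()
            if cat in CATEGORIES:
                return self.rates[(kind, cat)]
        raise AttributeError(name)


def compute_rates(tally: SubstitutionTally) -> RateSet:
    """Counts / opportunity per category; shared denominators per kind."""
    if tally.syn_opportunity <= 0 or tally.nonsyn_opportunity <= 0:
        raise UndefinedRateError(f"{tally.gene_id}: zero site opportunity")
    rates = {
        (kind, cat): tally.counts[(kind, cat)]
        / (tally.syn_opportunity if kind == "syn" else tally.nonsyn_opportunity)
        for kind in ("syn", "nonsyn")
        for cat in CATEGORIES
    }
    return RateSet(gene_id=tally.gene_id, species=tally.species, rates=rates)


def rates_table(rate_sets: list[RateSet]) -> pd.DataFrame:
    rows = []
    for rs in rate_sets:
        row = {"gene_id": rs.gene_id, "species": rs.species}
        for kind, prefix in (("syn", "dS"), ("nonsyn", "dN")):
            for cat in CATEGORIES:
                row[f"{prefix}_{cat.lower()}"] = rs.rates[(kind, cat)]
        row["ratio_ws_sw"] = rs.ratio_ws_sw
        rows.append(row)
    cols = ["gene_id", "species"]
    cols += [f"dS_{c.lower()}" for c in CATEGORIES]
    cols += [f"dN_{c.lower()}" for c in CATEGORIES]
    cols += ["ratio_ws_sw"]
    return pd.DataFrame(rows, columns=cols)


def flag_outliers(
    rates: pd.DataFrame, multiplier: float = OUTLIER_MULTIPLIER
) -> pd.DataFrame:
    """Flag genes whose category dS exceeds ``multiplier`` x the dataset mean.

    Adds one boolean ``outlier_<cat>`` column per synonymous category;
    strictly greater-than.
    """
    if len(rates) < 2:
        raise ValueError("outlier flagging needs at least two genes")
    out = rates.copy()
    for cat in CATEGORIES:
        col = f"dS_{cat.lower()}"
        out[f"outlier_{cat.lower()}"] = out[col] > multiplier * out[col].mean()
    return out
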