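"""End-to-end convenience wrappers tying the pipeline stages together."""

from __future__ import annotations

import logging

import pandas as pd

from .alignment import (
    CodonAlignment,
    CuratedGene,
    EmptyAlignmentError,
    InsufficientTaxaError,
    NoOutgroupError,
    curate_gene,
)
from .dissimilarity import score_table
from .ranking import rank_table
from .regions import ContingencyResult, RegionSet, fisher_enrichment, map_genes_to_regions
from .spectra import (
    SpeciesTree,
    compute_rates,
    rates_table,
    reconstruct_ancestral,
    reconstruct_and_count,
)

logger = logging.getLogger(__name__)


def curate_alignments(
    alignments: dict[str, CodonAlignment],
    gap_frac: float = 0.7,
    min_sites: int = 50,
) -> tuple[dict[str, CuratedGene], pd.DataFrame]:
    """Run the curation pipeline per gene; skipped genes go to the log only."""
    curated: dict[str, CuratedGene] = {}
    log_rows = []
    for gene_id, aln in alignments.items():
        status = "ok"
        try:
            cg = curate_gene(aln, gap_frac=gap_frac, min_sites=min_sites)
            if cg.skipped:
                status = cg.skipped
            else:
                curated[gene_id] = cg
            n_taxa, n_cols, n_cons, tier = (
                len(cg.alignment.taxa), cg.mask.parsed_length,
                cg.mask.n_conserved, cg.mask.outgroups.tier,
            )
        except (InsufficientTaxaError, EmptyAlignmentError, NoOutgroupError) as exc:
            status = type(exc).__name__
            n_taxa = n_cols = n_cons = tier = None
            logger.info("skipping %s: %s", gene_id, exc)
        log_rows.append(
            {
                "gene_id": gene_id, "status": status, "n_taxa": n_taxa,
                "columns_kept": n_cols, "n_conserved": n_cons, "outgroup_tier": tier,
            }
        )
    return curated, pd.DataFrame(log_rows)


def score_curated(
    curated: dict[str, CuratedGene],
    species: list[str],
    metrics: tuple[str, ...] = ("sneath", "epstein"),
) -> pd.DataFrame:
    genes = [(cg.alignment, cg.mask) for cg in curated.values()]
    return score_table(genes, species, metrics)


def divergence_ranking(
    alignments: dict[str, CodonAlignment],
    focal: str | list[str] = "sand_rat",
    reference: list[str] = ("mouse", "rat"),
    metric: str = "sneath",
    **rank_kwargs,
) -> pd.DataFrame:
    """Curate, score and rank in one call."""
    curated, _ = curate_alignments(alignments)
    focal_set = [focal] if isinstance(focal, str) else list(focal)
    scores = score_curated(curated, focal_set + list(reference), metrics=(metric,))
    return rank_table(scores, focal, list(reference), metric=metric, **rank_kwargs)


def spectra_table(
    alignments: dict[str, CodonAlignment],
    tree: SpeciesTree,
    tips: list[str] = ("mouse", "rat", "sand_rat", "mongolian_jird"),
) -> pd.DataFrame:
    """Per-gene x tip category rates; one ancestral reconstruction per gene."""
    rate_sets = []
    for aln in alignments.values():
        anc = reconstruct_ancestral(aln, tree)
        for tip in tips:
            tally = reconstruct_and_count(aln, tree, tip, ancestral=anc)
            rate_sets.append(compute_rates(tally))
    return rates_table(rate_sets)


def region_enrichment_test(
    ranking: pd.DataFrame,
    loci: pd.DataFrame,
    regions: RegionSet,
    divergent_genes: list[str] | None = None,
) -> ContingencyResult:
    """Fisher enrichment of divergent genes inside a region set.

    ``divergent_genes`` defaults to the genes classed divergent/extreme in
    the ranking table.
    """
    if divergent_genes is None:
        divergent_genes = list(ranking.loc[ranking["klass"] != "normal", "gene_id"])
    ranked_genes = set(ranking["gene_id"])
    loci = loci[loci["gene_id"].isin(ranked_genes)].reset_index(drop=True)
    member = map_genes_to_regions(loci, regions)
    is_div = loci["gene_id"].isin(set(divergent_genes))
    k_in = int((member & is_div).sum())
    k_out = int((~member & is_div).sum())
    n_in = int((member & ~is_div).sum())
    n_out = int((~member & ~is_div).sum())
    return fisher_enrichment(k_in, k_out, n_in, n_out)
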