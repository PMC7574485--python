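"""Genomic-interval membership, Fisher enrichment, clusters, sampling null.

Genes are mapped to previously delimited high-GC regions by the midpoint of
their locus (half-open [start, end) intervals, 0-based internally; BED input
is taken as-is, gene-locus TSVs are declared 1-based inclusive and converted
on read).  Enrichment of divergent genes inside regions is tested with a
two-sided Fisher exact test; a seeded random-sampling null re-draws sets of
k genes and records how many fall in regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class DegenerateTableError(ValueError):
    """A 2x2 table with an all-zero margin."""


@dataclass
class RegionSet:
    """Labelled genomic intervals, merged per chromosome, half-open."""

    intervals: list[tuple[str, int, int]]
    label: str = "high-GC"
    _by_chrom: dict[str, np.ndarray] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if start >= end:
                raise ValueError(f"{self.label}: empty interval {chrom}:{start}-{end}")
        merged: dict[str, list[list[int]]] = {}
        for chrom, start, end in sorted(self.intervals):
            runs = merged.setdefault(chrom, [])
            if runs and start <= runs[-1][1]:
                runs[-1][1] = max(runs[-1][1], end)
            else:
                runs.append([start, end])
        self.intervals = [
            (chrom, s, e) for chrom, runs in sorted(merged.items()) for s, e in runs
        ]
        self._by_chrom = {
            chrom: np.array([[s, e] for c, s, e in self.intervals if c == chrom])
            for chrom in {c for c, _, _ in self.intervals}
        }

    @classmethod
    def from_bed(cls, path: str, label: str = "high-GC") -> "RegionSet":
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None, usecols=[0, 1, 2],
            names=["chrom", "start", "end"],
        )
        return cls(
            intervals=[(r.chrom, int(r.start), int(r.end)) for r in df.itertuples()],
            label=label,
        )

    def to_bed(self, path: str) -> None:
        with open(path, "w") as fh:
            for chrom, s, e in self.intervals:
                fh.write(f"{chrom}\t{s}\t{e}\t{self.label}\n")

    def contains(self, chrom: str, position: int) -> bool:
        runs = self._by_chrom.get(chrom)
        if runs is None or len(runs) == 0:
            return False
        i = int(np.searchsorted(runs[:, 0], position, side="right")) - 1
        return i >= 0 and position < runs[i, 1]


def read_gene_loci(path: str) -> pd.DataFrame:
    """Gene-locus TSV (gene_id, chrom, start, end; 1-based inclusive) ->
    internal 0-based half-open frame with a midpoint column."""
    df = pd.read_csv(path, sep="\t", comment="#")
    df = df.rename(columns=str.lower)
    df["start"] = df["start"].astype(int) - 1
    df["end"] = df["end"].astype(int)
    return add_midpoints(df)


def add_midpoints(loci: pd.DataFrame) -> pd.DataFrame:
    loci = loci.copy()
    if (loci["start"] >= loci["end"]).any():
        raise ValueError("gene locus with start >= end")
    loci["midpoint"] = (loci["start"] + loci["end"]) // 2
    return loci


def map_genes_to_regions(loci: pd.DataFrame, regions: RegionSet) -> pd.Series:
    """Boolean membership per gene: midpoint inside any region interval."""
    flags = [
        regions.contains(chrom, int(mid))
        for chrom, mid in zip(loci["chrom"], loci["midpoint"])
    ]
    return pd.Series(flags, index=loci.index, name="in_region")


@dataclass
class ContingencyResult:
    """A 2x2 table with its odds ratio and two-sided Fisher exact p."""

    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float
    zero_cell: bool


def fisher_enrichment(k_in: int, k_out: int, n_in: int, n_out: int) -> ContingencyResult:
    """Two-sided Fisher exact test on ((k_in, k_out), (n_in, n_out)).

    Row 1 is the divergent gene set (inside / outside regions), row 2 the
    remaining genes.  Two-sidedness follows the point-probability rule (sum
    of hypergeometric outcomes no more probable than the observed table).
    """
    cells = (k_in, k_out, n_in, n_out)
    if any(c < 0 for c in cells):
        raise ValueError("negative cell count")
    # an empty row (no divergent or no background genes) is untestable; an
    # empty column (no gene in regions anywhere) is fine and gives p = 1
    if k_in + k_out == 0 or n_in + n_out == 0:
        raise DegenerateTableError(f"degenerate row margin in {cells}")
    table = ((k_in, k_out), (n_in, n_out))
    _, p = stats.fisher_exact(table, alternative="two-sided")
    zero_cell = k_out == 0 or n_in == 0
    if k_in * n_out == 0 and k_out * n_in == 0:
        odds = float("nan")
    elif zero_cell:
        odds = float("inf")
    else:
        odds = (k_in * n_out) / (k_out * n_in)
    return ContingencyResult(table=table, odds_ratio=odds, p_value=float(p),
                             zero_cell=zero_cell)


def detect_clusters(
    divergent_loci: pd.DataFrame, window: int = 1_000_000, min_genes: int = 3
) -> list[dict]:
    """Maximal runs of divergent genes with consecutive midpoints < window apart.

    Returns one dict per cluster: chrom, start/end midpoints, gene_ids.
    """
    clusters = []
    for chrom, grp in divergent_loci.groupby("chrom", sort=True):
        grp = grp.sort_values(["midpoint", "gene_id"], kind="mergesort")
        mids = grp["midpoint"].to_numpy()
        genes = grp["gene_id"].to_numpy()
        run_start = 0
        for i in range(1, len(mids) + 1):
            if i == len(mids) or mids[i] - mids[i - 1] >= window:
                if i - run_start >= min_genes:
                    clusters.append(
                        {
                            "chrom": chrom,
                            "start": int(mids[run_start]),
                            "end": int(mids[i - 1]),
                            "n_genes": i - run_start,
                            "gene_ids": list(genes[run_start:i]),
                        }
                    )
                run_start = i
    return clusters


@dataclass
class SamplingNull:
    """Null distribution of in-region counts over random gene samples."""

    counts: np.ndarray
    observed: int
    p_value: float
    n_samples: int


def sampling_null(
    all_loci: pd.DataFrame,
    regions: RegionSet,
    observed: int,
    k: int = 50,
    n_samples: int = 10_000,
    seed: int = 0,
) -> SamplingNull:
    """Random-location null: draw k genes without replacement n_samples times.

    The statistic per draw is the number of sampled genes whose midpoint lies
    in a region.  The empirical p uses add-one smoothing:
    (1 + #{draws >= observed}) / (n_samples + 1).
    """
    n = len(all_loci)
    if k > n:
        raise ValueError(f"sample size {k} exceeds population {n}")
    member = map_genes_to_regions(all_loci, regions).to_numpy()
    rng = np.random.default_rng(seed)
    counts = np.empty(n_samples, dtype=np.int64)
    for i in range(n_samples):
        idx = rng.choice(n, size=k, replace=False)
        counts[i] = int(member[idx].sum())
    p = (1 + int((counts >= observed).sum())) / (n_samples + 1)
    return SamplingNull(counts=counts, observed=observed, p_value=p, n_samples=n_samples)
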