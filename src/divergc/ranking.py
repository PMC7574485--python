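"""Dissimilarity-difference ranking and classification of divergent proteins.

For each gene the focal species' adjusted dissimilarity is compared with the
mean adjusted dissimilarity of a reference species set (e.g. mouse + rat);
the difference is ranked from largest to smallest and genes are classed as
"divergent" above one threshold (default 1.80) and "extreme" above a second
(default 3.0), both strict inequalities.  The thresholds are configuration
values; :func:`suggest_gap_cut` offers a largest-gap heuristic but is never
applied automatically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dissimilarity import DissimilarityScore

DIVERGENT_CUT = 1.80
EXTREME_CUT = 3.0


class MetricMismatchError(ValueError):
    """Focal and reference scores computed under different metrics."""


class UndefinedCorrelationError(ValueError):
    """Fewer than three paired genes."""


@dataclass
class DivergenceRecord:
    """Focal-vs-reference adjusted-dissimilarity difference for one gene."""

    gene_id: str
    metric: str
    focal_adjusted: float
    reference_adjusted: float  # mean over the reference species set

    @property
    def diff(self) -> float:
        return self.focal_adjusted - self.reference_adjusted


def dissimilarity_difference(
    focal: DissimilarityScore | list[DissimilarityScore],
    reference: list[DissimilarityScore],
) -> DivergenceRecord:
    """Difference between focal (or mean-of-focal-set) and reference mean.

    Passing a list as ``focal`` averages the focal species set first (used
    for the averaged-gerbil analysis).
    """
    focal_set = focal if isinstance(focal, list) else [focal]
    if not reference or not focal_set:
        raise ValueError("focal and reference sets must be non-empty")
    scores = focal_set + reference
    metrics = {s.metric for s in scores}
    if len(metrics) != 1:
        raise MetricMismatchError(f"mixed metrics {sorted(metrics)}")
    genes = {s.gene_id for s in scores}
    if len(genes) != 1:
        raise ValueError(f"mixed genes {sorted(genes)}")
    return DivergenceRecord(
        gene_id=scores[0].gene_id,
        metric=metrics.pop(),
        focal_adjusted=float(np.mean([s.adjusted for s in focal_set])),
        reference_adjusted=float(np.mean([s.adjusted for s in reference])),
    )


def rank_and_classify(
    records: list[DivergenceRecord],
    divergent_cut: float = DIVERGENT_CUT,
    extreme_cut: float = EXTREME_CUT,
) -> pd.DataFrame:
    """Rank records by descending difference and classify against the cuts.

    Ties are broken by gene_id lexicographic order, so output is
    deterministic under input shuffling.  Classification is strict (>):
    a difference of exactly 1.80 is "normal".
    """
    if not records:
        return pd.DataFrame(
            columns=["gene_id", "metric", "focal", "reference_mean", "diff", "rank", "klass"]
        )
    metrics = {r.metric for r in records}
    if len(metrics) != 1:
        raise MetricMismatchError(f"mixed metrics {sorted(metrics)}")
    df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "metric": [r.metric for r in records],
            "focal": [r.focal_adjusted for r in records],
            "reference_mean": [r.reference_adjusted for r in records],
            "diff": [r.diff for r in records],
        }
    )
    df = df.sort_values(["diff", "gene_id"], ascending=[False, True], kind="mergesort")
    df = df.reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df["klass"] = "normal"
    df.loc[df["diff"] > divergent_cut, "klass"] = "divergent"
    df.loc[df["diff"] > extreme_cut, "klass"] = "extreme"
    return df


def rank_table(
    scores: pd.DataFrame,
    focal: str | list[str],
    reference: list[str],
    metric: str = "sneath",
    divergent_cut: float = DIVERGENT_CUT,
    extreme_cut: float = EXTREME_CUT,
) -> pd.DataFrame:
    """Build and rank divergence records from a :func:`score_table` frame.

    Genes missing the focal or any reference species are dropped.
    """
    focal_set = [focal] if isinstance(focal, str) else list(focal)
    needed = set(focal_set) | set(reference)
    sub = scores[scores["metric"] == metric]
    records = []
    for gene_id, g in sub.groupby("gene_id", sort=False):
        by_sp = dict(zip(g["species"], g["adjusted"]))
        if not needed <= set(by_sp):
            continue
        records.append(
            DivergenceRecord(
                gene_id=gene_id,
                metric=metric,
                focal_adjusted=float(np.mean([by_sp[s] for s in focal_set])),
                reference_adjusted=float(np.mean([by_sp[s] for s in reference])),
            )
        )
    return rank_and_classify(records, divergent_cut, extreme_cut)


def correlate_scores(a: pd.Series, b: pd.Series) -> float:
    """Pearson r between two species' per-gene adjusted scores.

    Inputs are indexed by gene_id; only genes present in both are used.
    """
    common = a.index.intersection(b.index)
    if len(common) < 3:
        raise UndefinedCorrelationError(f"only {len(common)} paired genes")
    r, _ = stats.pearsonr(a.loc[common], b.loc[common])
    return float(r)


def suggest_gap_cut(diffs: "pd.Series | np.ndarray", top_n: int = 100) -> float:
    """Largest-gap discontinuity suggestion among the top-ranked differences.

    Returns the midpoint of the widest gap between consecutive sorted
    differences within the top ``top_n``; advisory only.
    """
    arr = np.sort(np.asarray(diffs, dtype=float))[::-1][:top_n]
    if len(arr) < 2:
        raise ValueError("need at least two differences")
    gaps = arr[:-1] - arr[1:]
    i = int(np.argmax(gaps))
    return float((arr[i] + arr[i + 1]) / 2.0)
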