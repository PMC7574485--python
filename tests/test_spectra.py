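"""Category classification, ancestral counting and rate computation."""

from itertools import permutations, product

import numpy as np
import pandas as pd
import pytest

from divergc import (
    CodonAlignment,
    classify_codon_change,
    classify_nt_change,
    compute_rates,
    flag_outliers,
    ng86_opportunities,
    rates_table,
    reconstruct_and_count,
)
from divergc.alignment import CODON_TO_AA, STOP_CODONS
from divergc.spectra import (
    CATEGORIES,
    NoChangeError,
    SpeciesTree,
    SubstitutionTally,
    UndefinedRateError,
    empty_counts,
)


class TestClassifyNtChange:
    def test_definitions(self):
        assert classify_nt_change("A", "G") == "WS"
        assert classify_nt_change("C", "T") == "SW"
        assert classify_nt_change("A", "T") == "WW"
        assert classify_nt_change("C", "G") == "SS"

    def test_identical_raises(self):
        with pytest.raises(NoChangeError):
            classify_nt_change("A", "A")

    def test_exhaustive_partition_4_4_2_2(self):
        """All 12 ordered base pairs partition into 4 WS, 4 SW, 2 WW, 2 SS."""
        weak = {"A", "T"}  # independent definition for the oracle
        tally = {c: 0 for c in CATEGORIES}
        for a, b in product("ACGT", repeat=2):
            if a == b:
                continue
            cat = classify_nt_change(a, b)
            expected = (
                "WS" if a in weak and b not in weak
                else "SW" if a not in weak and b in weak
                else "WW" if a in weak
                else "SS"
            )
            assert cat == expected
            tally[cat] += 1
        assert tally == {"WS": 4, "SW": 4, "WW": 2, "SS": 2}


def _translate(codon):
    return "*" if codon in STOP_CODONS else CODON_TO_AA[codon]


class TestClassifyCodonChange:
    def test_no_change_empty(self):
        assert classify_codon_change("AAA", "AAA") == []

    def test_single_synonymous_ws(self):
        assert classify_codon_change("AAA", "AAG") == [(True, "WS", 1.0)]

    def test_two_nt_change_matches_hand_enumeration(self):
        # TTA (Leu) -> CTG (Leu): both orders stop-free
        # path1: TTA->CTA (syn WS) -> CTG (syn WS)
        # path2: TTA->TTG (syn WS) -> CTG (syn WS)
        out = classify_codon_change("TTA", "CTG")
        assert len(out) == 4
        assert all(w == pytest.approx(0.5) for _, _, w in out)
        assert all(syn and cat == "WS" for syn, cat, _ in out)

    def test_stop_intermediate_path_excluded(self):
        # TAC (Tyr) -> TGG (Trp): changing position 2 first gives TAG (stop),
        # so only the path via TGC survives, with unit weights
        out = classify_codon_change("TAC", "TGG")
        assert len(out) == 2
        assert all(w == pytest.approx(1.0) for _, _, w in out)
        # TAC->TGC is Tyr->Cys (nonsyn, A->G = WS); TGC->TGG Cys->Trp (C->G = SS)
        assert out == [(False, "WS", 1.0), (False, "SS", 1.0)]

    def test_stop_codon_input_rejected(self):
        with pytest.raises(ValueError):
            classify_codon_change("TAA", "AAA")

    def test_total_weight_equals_hamming_distance(self, rng):
        sense = [c for c in map("".join, product("ACGT", repeat=3))
                 if c not in STOP_CODONS]
        for _ in range(80):
            a, b = rng.choice(sense, 2)
            out = classify_codon_change(a, b)
            k = sum(x != y for x, y in zip(a, b))
            assert sum(w for _, _, w in out) == pytest.approx(k)

    def test_matches_bruteforce_path_oracle(self, rng):
        """Weighted per-step categories equal explicit path enumeration."""
        sense = [c for c in map("".join, product("ACGT", repeat=3))
                 if c not in STOP_CODONS]
        for _ in range(40):
            a, b = rng.choice(sense, 2)
            diffs = [i for i in range(3) if a[i] != b[i]]
            paths = []
            for order in permutations(diffs):
                cur, steps, ok = a, [], True
                for pos in order:
                    nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
                    syn = _translate(cur) == _translate(nxt) != "*"
                    steps.append((syn, classify_nt_change(cur[pos], nxt[pos])))
                    if nxt in STOP_CODONS:
                        ok = False
                    cur = nxt
                paths.append((steps, ok))
            kept = [s for s, ok in paths if ok] or [s for s, _ in paths]
            expected = {}
            for steps in kept:
                for syn, cat in steps:
                    expected[(syn, cat)] = expected.get((syn, cat), 0.0) + 1 / len(kept)
            got = {}
            for syn, cat, w in classify_codon_change(a, b):
                got[(syn, cat)] = got.get((syn, cat), 0.0) + w
            assert got.keys() == expected.keys()
            for k in expected:
                assert got[k] == pytest.approx(expected[k])


class TestNg86Opportunities:
    def test_known_codons(self):
        # TTT (Phe): only position 3 offers one synonymous change (TTC)
        syn, nonsyn, used = ng86_opportunities("TTT")
        assert syn == pytest.approx(1 / 3)
        assert nonsyn == pytest.approx(3 - 1 / 3)
        assert used == 1

    def test_fourfold_codon(self):
        # GGA (Gly): position 3 fully synonymous
        syn, _, _ = ng86_opportunities("GGA")
        assert syn == pytest.approx(1.0)

    def test_skips_invalid_codons(self):
        syn_a, _, used_a = ng86_opportunities("TTTNNNTAA")
        syn_b, _, used_b = ng86_opportunities("TTT")
        assert used_a == used_b == 1
        assert syn_a == syn_b


def _aln(rows, taxa=("A", "B", "C", "focal")):
    return CodonAlignment("t", list(taxa), list(rows))


class TestReconstructAndCount:
    SPAN = ("A", "B", "C", "focal")

    def test_zero_change_alignment(self, star_tree):
        aln = _aln(["ATGGCTAAA"] * 4)
        tally = reconstruct_and_count(aln, star_tree, "focal", span_taxa=self.SPAN)
        assert all(v == 0 for v in tally.counts.values())

    def test_single_synonymous_ws_on_terminal_branch(self, star_tree):
        # focal differs by one synonymous A->G at codon 3 (AAA->AAG)
        base = "ATGGCTAAA"
        aln = _aln([base, base, base, "ATGGCTAAG"])
        tally = reconstruct_and_count(aln, star_tree, "focal", span_taxa=self.SPAN)
        assert tally.counts[("syn", "WS")] == pytest.approx(1.0)
        assert sum(tally.counts.values()) == pytest.approx(1.0)

    def test_k_synonymous_changes_counted_exactly(self, star_tree):
        # one synonymous change per four-fold codon, one per category:
        # GGA->GGC (WS), GTC->GTT (SW), CCG->CCC (SS), GCA->GCT (WW)
        base = "GGAGTCCCGGCA"
        focal = "GGCGTTCCCGCT"
        aln = _aln([base, base, base, focal])
        tally = reconstruct_and_count(aln, star_tree, "focal", span_taxa=self.SPAN)
        assert tally.total("syn") == pytest.approx(4.0)
        assert tally.total("nonsyn") == 0.0
        for cat in CATEGORIES:
            assert tally.counts[("syn", cat)] == pytest.approx(1.0)

    def test_missing_tip_raises(self, star_tree):
        aln = _aln(["ATGGCTAAA"] * 4)
        with pytest.raises(KeyError):
            reconstruct_and_count(aln, star_tree, "nope", span_taxa=self.SPAN)


class TestRates:
    def _tally(self, counts=None, syn_opp=100.0, nonsyn_opp=200.0):
        c = empty_counts()
        if counts:
            c.update(counts)
        return SubstitutionTally(
            gene_id="g", species="s", counts=c,
            syn_opportunity=syn_opp, nonsyn_opportunity=nonsyn_opp,
        )

    def test_zero_counts_zero_rates_undefined_ratio(self):
        rs = compute_rates(self._tally())
        assert all(v == 0 for v in rs.rates.values())
        assert not rs.ratio_defined
        assert np.isnan(rs.ratio_ws_sw)

    def test_rate_arithmetic(self):
        rs = compute_rates(self._tally({("syn", "WS"): 2.0}))
        assert rs.dS_ws == pytest.approx(0.02)

    def test_zero_opportunity_raises(self):
        with pytest.raises(UndefinedRateError):
            compute_rates(self._tally(syn_opp=0.0))

    def test_category_rates_sum_to_total(self, rng):
        for _ in range(20):
            counts = {
                (kind, cat): float(rng.integers(0, 20))
                for kind in ("syn", "nonsyn") for cat in CATEGORIES
            }
            t = self._tally(counts)
            rs = compute_rates(t)
            total_ds = sum(rs.rates[("syn", c)] for c in CATEGORIES)
            assert total_ds == pytest.approx(t.total("syn") / t.syn_opportunity)


class TestOutliers:
    def _df(self, ws):
        n = len(ws)
        base = {
            f"dS_{c.lower()}": np.linspace(0.01, 0.02, n) for c in CATEGORIES
        }
        base["dS_ws"] = np.asarray(ws, dtype=float)
        base["gene_id"] = [f"g{i}" for i in range(n)]
        return pd.DataFrame(base)

    def test_identical_rates_no_outliers(self):
        out = flag_outliers(self._df([0.5] * 6))
        assert not out["outlier_ws"].any()

    def test_single_large_value_flagged(self):
        out = flag_outliers(self._df([0.0, 0.0, 0.0, 1.0]))
        assert list(out["outlier_ws"]) == [False, False, False, True]

    def test_matches_bruteforce(self, rng):
        for _ in range(15):
            vals = rng.exponential(0.05, size=12)
            out = flag_outliers(self._df(vals))
            expected = vals > 2.5 * vals.mean()
            assert list(out["outlier_ws"]) == list(expected)


def test_category_partition_on_simulated_events(small_dataset):
    """Every simulated substitution falls in exactly one category and the
    recorded category matches independent reclassification."""
    tt = small_dataset.truth_table()
    assert len(tt) > 0
    for row in tt.itertuples():
        pos = row.pos
        assert row.from_codon[pos] != row.to_codon[pos]
        assert row.category == classify_nt_change(row.from_codon[pos], row.to_codon[pos])
        assert row.category in CATEGORIES


def test_ratio_monotone_in_lambda_for_islands(lambda_datasets):
    """Mean island dS_ws/dS_sw rises with gBGC strength (chimney pattern)."""
    means = {}
    for lam, ds in lambda_datasets.items():
        ratios = []
        for gid in ds.island_genes:
            rs = compute_rates(
                reconstruct_and_count(ds.alignments[gid], ds.tree, "sand_rat")
            )
            if rs.ratio_defined:
                ratios.append(rs.ratio_ws_sw)
        means[lam] = float(np.mean(ratios))
    assert means[1.0] < means[2.0] < means[5.0]
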