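"""Interval genes, local alignment, and reciprocal-best-hit orthology."""

import numpy as np
import pandas as pd
import pytest
from Bio.Align import substitution_matrices

from gravqtl import orthology as orth
from gravqtl import simdata

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def sw_affine_oracle(a, b, gap_open=11, gap_extend=1):
    """Brute-force affine-gap Smith-Waterman score (BLAST gap convention:
    a gap of length L costs gap_open + L * gap_extend)."""
    n, m = len(a), len(b)
    NEG = -1e9
    M = np.full((n + 1, m + 1), 0.0)  # best ending in a match state
    X = np.full((n + 1, m + 1), NEG)  # gap in b (deletion)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a (insertion)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = BLOSUM62[a[i - 1], b[j - 1]]
            M[i, j] = max(0.0, max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s)
            # opening a length-1 gap costs open + extend
            X[i, j] = max(M[i - 1, j] - gap_open - gap_extend, X[i - 1, j] - gap_extend)
            Y[i, j] = max(M[i, j - 1] - gap_open - gap_extend, Y[i, j - 1] - gap_extend)
            best = max(best, M[i, j], X[i, j], Y[i, j])
    return best


ANCHORS = pd.DataFrame(
    {
        "chrom": ["1", "1", "2", "2", "2"],
        "cM": [0.0, 100.0, 0.0, 50.0, 100.0],
        "bp": [1, 100_000_000, 0, 10_000_000, 100_000_000],
    }
)


class TestCmToBp:
    def test_linear_interpolation(self):
        _, lo, hi, clamped = orth.cm_to_bp(("1", 25.0, 75.0), ANCHORS)
        assert lo == pytest.approx(25_000_000, rel=1e-6)
        assert hi == pytest.approx(75_000_000, rel=1e-6)
        assert not clamped

    def test_endpoint_at_anchor(self):
        _, lo, _, _ = orth.cm_to_bp(("1", 0.0, 50.0), ANCHORS)
        assert lo == 1

    def test_piecewise_segments(self):
        _, _, hi, _ = orth.cm_to_bp(("2", 10.0, 75.0), ANCHORS)
        assert hi == 55_000_000

    def test_outside_span_clamped(self):
        _, lo, hi, clamped = orth.cm_to_bp(("1", -5.0, 120.0), ANCHORS)
        assert clamped and lo == 1 and hi == 100_000_000

    def test_non_monotone_anchors_rejected(self):
        bad = pd.DataFrame({"chrom": ["1"] * 3, "cM": [0, 50, 100], "bp": [0, 100, 50]})
        with pytest.raises(ValueError, match="monotone"):
            orth.cm_to_bp(("1", 10.0, 20.0), bad)


GENES = pd.DataFrame(
    {
        "gene": ["g1", "g2", "g3"],
        "chrom": ["1", "1", "1"],
        "start": [100, 210, 300],
        "end": [200, 240, 400],
        "strand": ["+", "-", "+"],
    }
)


class TestGenesInInterval:
    def test_whole_chromosome(self):
        assert orth.genes_in_interval(GENES, ("1", 1, 10_000)) == ["g1", "g2", "g3"]

    def test_partial_overlap_counts(self):
        assert orth.genes_in_interval(GENES, ("1", 150, 250)) == ["g1", "g2"]

    def test_intergenic_interval_empty(self):
        assert orth.genes_in_interval(GENES, ("1", 201, 209)) == []

    def test_unknown_chromosome_warns(self):
        with pytest.warns(UserWarning, match="not in annotation"):
            assert orth.genes_in_interval(GENES, ("9", 1, 100)) == []


class TestAlignProteins:
    def test_self_alignment_scores_diagonal_sum(self):
        seq = "MKVLAWGHE"
        res = orth.align_proteins(seq, seq)
        assert res.percent_identity == 100.0
        assert res.score == sum(float(BLOSUM62[c, c]) for c in seq)

    def test_disjoint_alphabets_zero_identity(self):
        res = orth.align_proteins("AAAA", "CCCC")
        assert res.identities == 0
        assert res.percent_identity == 0.0

    def test_score_symmetry(self):
        a, b = "MKVLAWGHE", "MKVIAWHHE"
        assert orth.align_proteins(a, b).score == orth.align_proteins(b, a).score

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            orth.align_proteins("", "MKV")

    def test_matches_dp_oracle_on_short_sequences(self):
        rng = np.random.default_rng(0)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(20):
            a = "".join(rng.choice(aas, size=rng.integers(3, 13)))
            b = "".join(rng.choice(aas, size=rng.integers(3, 13)))
            assert orth.align_proteins(a, b).score == pytest.approx(sw_affine_oracle(a, b))


class TestBestHit:
    PROTEOME = {"p1": "MKVLAWGHERTYMKVL", "p2": "MKVLAWGHERTYMKVA", "p3": "WWWWHHHHGGGG"}

    def test_identical_query_wins(self):
        hit = orth.best_hit("MKVLAWGHERTYMKVL", self.PROTEOME, min_score=10)
        assert hit.subject == "p1"

    def test_tie_broken_deterministically(self):
        prot = {"b": "MKVLAWGHERTY", "a": "MKVLAWGHERTY"}
        hit = orth.best_hit("MKVLAWGHERTY", prot, min_score=10)
        assert hit.subject == "a"  # equal score/identity -> lexicographic

    def test_below_min_score_is_no_hit(self):
        assert orth.best_hit("AAAA", {"x": "CCCC"}, min_score=50) is None

    def test_equals_exhaustive_maximum(self):
        aligner = orth.make_aligner()
        q = "MKVLAWGHERTYMKVV"
        hit = orth.best_hit(q, self.PROTEOME, min_score=10)
        scores = {k: aligner.score(q, v) for k, v in self.PROTEOME.items()}
        assert hit.score == max(scores.values())


class TestFindBBH:
    def test_identity_pairing_on_identical_proteomes(self):
        prot = {f"g{i}": seq for i, seq in enumerate(["MKVLAWGHERTY", "WWHHGGAARRTT", "PPQQLLMMKKVV"])}
        ig = {g: "q1" for g in prot}
        pairs = orth.find_bbh(ig, ig, prot, prot, min_score=10)
        assert {(p.gene_a, p.gene_b) for p in pairs} == {(g, g) for g in prot}
        assert all(p.percent_identity == 100.0 for p in pairs)

    def test_synthetic_truth_recovered_exactly(self):
        prot = simdata.simulate_proteomes(n_genes=30, divergence=0.2, seed=7)
        pairs, _ = orth.run_orthology(
            prot.genes_a, prot.proteins_a, prot.anchors_a, prot.intervals_a,
            prot.genes_b, prot.proteins_b, prot.anchors_b, prot.intervals_b,
        )
        assert {(p.gene_a, p.gene_b) for p in pairs} == set(prot.truth.in_interval_pairs)

    def test_symmetry_under_species_swap(self):
        prot = simdata.simulate_proteomes(n_genes=15, divergence=0.2, seed=8)
        ig_a = orth._interval_gene_map(prot.genes_a, prot.anchors_a, prot.intervals_a)
        ig_b = orth._interval_gene_map(prot.genes_b, prot.anchors_b, prot.intervals_b)
        fwd = orth.find_bbh(ig_a, ig_b, prot.proteins_a, prot.proteins_b)
        rev = orth.find_bbh(ig_b, ig_a, prot.proteins_b, prot.proteins_a)
        assert {(p.gene_a, p.gene_b) for p in fwd} == {(p.gene_b, p.gene_a) for p in rev}

    def test_pairs_form_partial_matching(self):
        prot = simdata.simulate_proteomes(n_genes=20, seed=9)
        ig_a = orth._interval_gene_map(prot.genes_a, prot.anchors_a, prot.intervals_a)
        ig_b = orth._interval_gene_map(prot.genes_b, prot.anchors_b, prot.intervals_b)
        pairs = orth.find_bbh(ig_a, ig_b, prot.proteins_a, prot.proteins_b)
        assert len({p.gene_a for p in pairs}) == len(pairs)
        assert len({p.gene_b for p in pairs}) == len(pairs)


class TestReport:
    def test_empty_table_has_header(self):
        table = orth.report_candidates([])
        assert list(table.columns) == ["qtl_a", "gene_a", "qtl_b", "gene_b", "percent_identity", "name"]
        assert len(table) == 0

    def test_duplicate_pair_rejected(self):
        res = orth.AlignmentResult("a", "b", 100.0, 10, 10)
        pair = orth.BBHPair("ga", "gb", res, res, "q1", "q2")
        with pytest.raises(ValueError, match="duplicate"):
            orth.report_candidates([pair, pair])

    def test_sorted_by_species_a_qtl(self):
        res = orth.AlignmentResult("a", "b", 100.0, 8, 10)
        pairs = [
            orth.BBHPair("g2", "h2", res, res, "q2", "x"),
            orth.BBHPair("g1", "h1", res, res, "q1", "x"),
        ]
        table = orth.report_candidates(pairs)
        assert table["qtl_a"].tolist() == ["q1", "q2"]
        assert table["percent_identity"].iloc[0] == 80.0
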