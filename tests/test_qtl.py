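"""Genotype probabilities, scans, thresholds, stepwise models, tracks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gravqtl import qtl, simdata
from gravqtl.qtl import AA, BB, MISSING, GeneticMap, Genotypes


def tiny_cross(calls, positions=(0.0, 10.0), chrom="1"):
    markers = [f"m{i}" for i in range(len(positions))]
    gmap = GeneticMap(
        pd.DataFrame({"marker": markers, "chrom": [chrom] * len(positions), "pos": list(positions)})
    )
    calls = np.asarray(calls, dtype=np.int8)
    geno = Genotypes([f"i{k}" for k in range(calls.shape[0])], markers, calls)
    return gmap, geno


class TestGenoprob:
    def test_observed_marker_is_certain_without_error(self):
        gmap, geno = tiny_cross([[AA, BB], [BB, AA]])
        probs = qtl.calc_genoprob(geno, gmap, step_cM=0.0, error_prob=0.0)
        p = probs.probs["1"]
        assert p[0, 0, 0] == pytest.approx(1.0)
        assert p[0, 1, 1] == pytest.approx(1.0)

    def test_all_missing_gives_uniform(self):
        gmap, geno = tiny_cross([[MISSING, MISSING]])
        probs = qtl.calc_genoprob(geno, gmap, step_cM=5.0)
        assert np.allclose(probs.probs["1"], 0.5)

    def test_midpoint_matches_path_enumeration_oracle(self):
        # 20-cM interval flanked by AA and AA, pseudomarker at 10 cM:
        # brute force over the 2-state path space on 3 positions
        gmap, geno = tiny_cross([[AA, AA]], positions=(0.0, 20.0))
        probs = qtl.calc_genoprob(geno, gmap, step_cM=10.0, error_prob=0.0)
        gpos = probs.grid["1"][0]
        k = int(np.where(gpos == 10.0)[0][0])
        r = float(qtl.haldane(10.0))
        # P(path AA-s-AA) ∝ T(AA,s) * T(s,AA)
        w_aa = (1 - r) * (1 - r)
        w_bb = r * r
        expected = w_aa / (w_aa + w_bb)
        assert probs.probs["1"][0, k, 0] == pytest.approx(expected, abs=1e-12)

    def test_pairs_sum_to_one(self, ten_chrom_cross):
        _, _, probs = ten_chrom_cross
        for chrom in probs.grid:
            s = probs.probs[chrom].sum(axis=2)
            assert np.allclose(s, 1.0, atol=1e-12)

    def test_marker_order_mismatch_rejected(self):
        gmap, geno = tiny_cross([[AA, BB]])
        geno.markers = list(reversed(geno.markers))
        with pytest.raises(ValueError, match="marker order"):
            qtl.calc_genoprob(geno, gmap)

    def test_imputation_marginals_match_probabilities(self):
        gmap, geno = tiny_cross([[AA, MISSING, BB]], positions=(0.0, 15.0, 30.0))
        probs = qtl.calc_genoprob(geno, gmap, step_cM=0.0)
        draws = qtl.sim_geno(probs, n_draws=256, seed=1)["1"]
        freq_bb = (draws == BB).mean(axis=0)[0]
        p_bb = probs.probs["1"][0, :, 1]
        se = np.sqrt(p_bb * (1 - p_bb) / 256)
        assert np.all(np.abs(freq_bb - p_bb) <= 3 * se + 1e-12)


class TestScanone:
    def test_hand_computed_lod(self):
        gmap, geno = tiny_cross([[AA, AA], [AA, AA], [BB, BB], [BB, BB]])
        probs = qtl.calc_genoprob(geno, gmap, step_cM=0.0, error_prob=0.0)
        res = qtl.scanone_hk(probs, [1.0, 1.1, 2.0, 2.1])
        # RSS0 = 1.01, RSS1 = 0.01 -> LOD = 2 log10(101)
        assert res.max_lod() == pytest.approx(2 * np.log10(1.01 / 0.01), abs=1e-9)

    def test_constant_phenotype_gives_zero(self, ten_chrom_cross):
        _, _, probs = ten_chrom_cross
        res = qtl.scanone_hk(probs, np.full(200, 3.0))
        assert np.all(res.table["lod"] == 0.0)

    def test_matches_regression_oracle(self, ten_chrom_cross):
        _, _, probs = ten_chrom_cross
        rng = np.random.default_rng(3)
        y = rng.normal(size=200)
        res = qtl.scanone_hk(probs, y)
        D = probs.dosages()
        n = y.size
        rss0 = float(((y - y.mean()) ** 2).sum())
        for j in range(0, D.shape[1], 37):  # spot-check a grid subset
            X = np.column_stack([np.ones(n), D[:, j]])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss1 = float(((y - X @ beta) ** 2).sum())
            lod = n / 2 * np.log10(rss0 / rss1)
            assert res.table["lod"].iloc[j] == pytest.approx(lod, abs=1e-8)

    def test_missing_phenotypes_dropped(self, ten_chrom_cross):
        _, _, probs = ten_chrom_cross
        rng = np.random.default_rng(4)
        y = rng.normal(size=200)
        y[:20] = np.nan
        res = qtl.scanone_hk(probs, y)
        assert np.isfinite(res.table["lod"]).all()


@settings(derandomize=True, max_examples=10)
@given(
    scale=st.floats(min_value=0.1, max_value=50.0),
    shift=st.floats(min_value=-100.0, max_value=100.0),
)
def test_lod_affine_invariance(scale, shift, ten_chrom_cross):
    """LOD profiles are invariant under affine phenotype transformations."""
    _, _, probs = ten_chrom_cross
    rng = np.random.default_rng(11)
    y = rng.normal(size=200)
    base = qtl.scanone_hk(probs, y).table["lod"].to_numpy()
    trans = qtl.scanone_hk(probs, scale * y + shift).table["lod"].to_numpy()
    assert np.allclose(base, trans, atol=1e-8)


class TestPermutationThreshold:
    def test_alpha_one_is_minimum_of_null_maxima(self, ten_chrom_cross):
        _, _, probs = ten_chrom_cross
        rng = np.random.default_rng(5)
        y = rng.normal(size=200)
        thr = qtl.permutation_threshold(probs, y, 100, alpha=1.0, seed=0)
        thr95 = qtl.permutation_threshold(probs, y, 100, alpha=0.05, seed=0)
        assert thr < thr95

    def test_seed_determinism(self, ten_chrom_cross):
        _, _, probs = ten_chrom_cross
        rng = np.random.default_rng(6)
        y = rng.normal(size=200)
        t1 = qtl.permutation_threshold(probs, y, 120, seed=9)
        t2 = qtl.permutation_threshold(probs, y, 120, seed=9)
        assert t1 == t2

    def test_too_few_permutations_rejected(self, ten_chrom_cross):
        _, _, probs = ten_chrom_cross
        with pytest.raises(ValueError, match="n_perm"):
            qtl.permutation_threshold(probs, np.zeros(200), 50)


class TestStepwise:
    def test_noiseless_two_qtl_recovered_exactly(self, ten_chrom_cross):
        _, _, probs = ten_chrom_cross
        D = probs.dosages()
        cp = probs.chrom_pos()
        i1, i2 = cp.index(("3", 40.0)), cp.index(("7", 60.0))
        y = 1.0 * D[:, i1] + 0.8 * D[:, i2]
        model = qtl.stepwise_qtl(probs, y, penalty=3.0)
        found = {(q.chrom, q.pos) for q in model.qtl}
        assert found == {("3", 40.0), ("7", 60.0)}
        effects = {q.chrom: q.effect for q in model.qtl}
        assert effects["3"] == pytest.approx(1.0, abs=1e-6)
        assert effects["7"] == pytest.approx(0.8, abs=1e-6)

    def test_plod_accounting(self, ten_chrom_cross):
        _, _, probs = ten_chrom_cross
        D = probs.dosages()
        y = 1.0 * D[:, 100] + np.random.default_rng(0).normal(0, 0.5, 200)
        model = qtl.stepwise_qtl(probs, y, penalty=3.0)
        assert model.plod == pytest.approx(model.lod - model.n_qtl * 3.0)

    def test_nonpositive_penalty_rejected(self, ten_chrom_cross):
        _, _, probs = ten_chrom_cross
        with pytest.raises(ValueError):
            qtl.stepwise_qtl(probs, np.zeros(200), penalty=0.0)

    def test_support_interval_contains_peak(self, ten_chrom_cross):
        _, _, probs = ten_chrom_cross
        D = probs.dosages()
        cp = probs.chrom_pos()
        i1 = cp.index(("3", 40.0))
        y = 1.0 * D[:, i1] + np.random.default_rng(1).normal(0, 1.0, 200)
        model = qtl.stepwise_qtl(probs, y, penalty=3.0)
        for q in model.qtl:
            lo, hi = q.interval
            assert lo <= q.pos <= hi


class TestSupportInterval:
    def make_scan(self, lods, spacing=10.0):
        pos = np.arange(len(lods)) * spacing
        return qtl.ScanResult(
            "t", pd.DataFrame({"chrom": "1", "pos": pos, "lod": lods})
        )

    def test_lod_drop_rule(self):
        scan = self.make_scan([0, 1, 3, 5, 3, 1, 0])
        chrom, lo, hi = qtl.support_interval(scan, ("1", 30.0), drop=1.5)
        assert (lo, hi) == (20.0, 40.0)

    def test_boundary_peak_one_sided(self):
        scan = self.make_scan([0, 1, 2, 3, 4, 5])
        _, lo, hi = qtl.support_interval(scan, ("1", 50.0), drop=1.5)
        assert hi == 50.0 and lo < 50.0

    def test_zero_drop_degenerate(self):
        scan = self.make_scan([0, 1, 3, 5, 3, 1, 0])
        _, lo, hi = qtl.support_interval(scan, ("1", 30.0), drop=0.0)
        assert (lo, hi) == (20.0, 40.0)  # expanded to flanking grid points

    def test_flat_profile_whole_chromosome(self):
        scan = self.make_scan([2, 2, 2, 2])
        _, lo, hi = qtl.support_interval(scan, ("1", 10.0))
        assert (lo, hi) == (0.0, 30.0)


def make_model(peaks, trait="t"):
    fits = [qtl.QTLFit(chrom=c, pos=p, effect=1.0, se=0.1) for c, p in peaks]
    return qtl.QTLModel(trait=trait, qtl=fits, lod=10.0, plod=5.0, penalty=2.5)


class TestTracks:
    def test_duration_is_run_length_times_frame(self):
        models = {t: make_model([("9", 50.0)]) for t in (3.0, 6.0, 9.0, 12.0, 15.0)}
        tracks = qtl.link_tqtl_over_time(models, frame_min=3.0)
        assert len(tracks) == 1
        assert tracks[0].duration == 15.0
        assert tracks[0].onset == 3.0

    def test_gap_splits_runs(self):
        models = {t: make_model([("9", 50.0)]) for t in (3.0, 6.0, 12.0, 15.0)}
        models[9.0] = make_model([])
        tracks = qtl.link_tqtl_over_time(models, frame_min=3.0)
        assert sorted(tr.duration for tr in tracks) == [6.0, 6.0]

    def test_peak_drift_beyond_link_distance_breaks_run(self):
        models = {3.0: make_model([("9", 50.0)]), 6.0: make_model([("9", 62.0)])}
        tracks = qtl.link_tqtl_over_time(models, link_dist_cM=10.0, frame_min=3.0)
        assert len(tracks) == 2

    def test_matching_by_chromosome_and_distance(self):
        tracks = qtl.link_tqtl_over_time(
            {t: make_model([("3", 40.0)]) for t in (3.0, 6.0, 9.0)}, frame_min=3.0
        )
        pq = {"mu": make_model([("3", 45.0)], trait="mu")}
        matched, unmatched, summary = qtl.match_tqtl_pqtl(tracks, pq)
        assert len(matched) == 1 and not unmatched
        assert matched[0].matched_pqtl == ["mu"]
        assert summary["matched"]["mean_duration"] == 9.0

    def test_wrong_chromosome_unmatched(self):
        tracks = qtl.link_tqtl_over_time(
            {3.0: make_model([("3", 40.0)]), 6.0: make_model([("3", 40.0)])},
            frame_min=3.0,
        )
        pq = {"A": make_model([("9", 40.0)], trait="A")}
        matched, unmatched, _ = qtl.match_tqtl_pqtl(tracks, pq)
        assert not matched and len(unmatched) == 1

    def test_empty_inputs(self):
        matched, unmatched, summary = qtl.match_tqtl_pqtl([], {})
        assert summary["matched"]["n"] == 0
        assert np.isnan(summary["unmatched"]["mean_duration"])


class TestMapTqtl:
    def test_skips_mostly_missing_time_points(self, ten_chrom_cross):
        _, _, probs = ten_chrom_cross
        rng = np.random.default_rng(8)
        mat = pd.DataFrame(
            {3.0: rng.normal(size=200), 6.0: np.full(200, np.nan)},
        )
        mat.iloc[:80, 1] = rng.normal(size=80)  # 60% missing
        scans, models, heat = qtl.map_tqtl(probs, mat, n_perm=100, seed=0)
        assert 3.0 in models and 6.0 not in models
        assert heat.shape[1] == 2
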