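"""HMM genotype probabilities, Haley–Knott scans, thresholds, QTL search."""

import numpy as np
import pandas as pd
import pytest

from fvtqtl.qtl import (
    GeneticMap,
    QTLModel,
    RILGenotypes,
    ScanError,
    collapse_colocalized,
    genotype_probabilities,
    haldane,
    lod_from_pve,
    lod_support_interval,
    permutation_threshold,
    pve_from_lod,
    scan_hk,
    stepwise_qtl_search,
)


@pytest.fixture(scope="module")
def dense_probs(small_map_genos):
    return genotype_probabilities(*small_map_genos, step=2.0)


def three_point_oracle(d1_cm, d2_cm, obs, error_rate):
    """Brute-force forward–backward on a 3-position chain (marker, query,
    marker) by enumerating all 8 hidden-state paths.

    ``obs`` is (code_at_first, code_at_last) with codes in {0, 1, None};
    returns P(state=1 at the middle position).
    """
    r1, r2 = haldane(d1_cm), haldane(d2_cm)

    def trans(a, b, r):
        return 1 - r if a == b else r

    def emit(state, code):
        if code is None:
            return 1.0
        return 1 - error_rate if state == code else error_rate

    num = 0.0
    den = 0.0
    for s0 in (0, 1):
        for s1 in (0, 1):
            for s2 in (0, 1):
                p = (0.5 * emit(s0, obs[0]) * trans(s0, s1, r1)
                     * trans(s1, s2, r2) * emit(s2, obs[1]))
                den += p
                if s1 == 1:
                    num += p
    return num / den


def two_marker_setup(codes, d_cm=20.0, step=10.0, error_rate=0.0):
    gmap = GeneticMap(pd.DataFrame(
        {"marker": ["m1", "m2"], "chrom": ["A01", "A01"], "pos_cm": [0.0, d_cm]}
    ))
    calls = pd.DataFrame({"m1": [codes[0]], "m2": [codes[1]]},
                         index=pd.Index(["L1"], name="line"))
    genos = RILGenotypes(calls)
    return genotype_probabilities(gmap, genos, step=step, error_rate=error_rate)


class TestGenotypeProbabilities:
    def test_observed_marker_certain_without_error(self):
        probs = two_marker_setup(("AA", "BB"), error_rate=0.0)
        p = probs.probs["A01"]
        assert p[0, 0, 0] == pytest.approx(1.0)  # AA at first marker
        assert p[0, -1, 1] == pytest.approx(1.0)  # BB at last marker

    def test_midpoint_between_matching_flanks(self):
        # AA----10cM----?----10cM----AA, error 0:
        # P(AA) = (1-r)^2 / ((1-r)^2 + r^2) with r = Haldane(10 cM)
        probs = two_marker_setup(("AA", "AA"), d_cm=20.0, step=10.0)
        grid = probs.positions["A01"]
        k = int(np.where(grid == 10.0)[0][0])
        p_aa = probs.probs["A01"][0, k, 0]
        r = haldane(10.0)
        expected = (1 - r) ** 2 / ((1 - r) ** 2 + r**2)
        assert expected == pytest.approx(0.990, abs=5e-4)
        assert p_aa == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize("obs,codes", [
        ((0, 1), ("AA", "BB")), ((1, 1), ("BB", "BB")), ((0, None), ("AA", None)),
    ])
    @pytest.mark.parametrize("error_rate", [0.0, 0.001, 0.05])
    def test_matches_enumeration_oracle(self, obs, codes, error_rate):
        probs = two_marker_setup(codes, d_cm=20.0, step=10.0,
                                 error_rate=error_rate)
        grid = probs.positions["A01"]
        k = int(np.where(grid == 10.0)[0][0])
        got = probs.probs["A01"][0, k, 1]
        want = three_point_oracle(10.0, 10.0, obs, error_rate)
        assert got == pytest.approx(want, rel=1e-9)

    def test_probabilities_normalized(self, small_map_genos):
        probs = genotype_probabilities(*small_map_genos, step=2.0,
                                       error_rate=0.001)
        for chrom, arr in probs.probs.items():
            np.testing.assert_allclose(arr.sum(axis=2), 1.0, rtol=1e-9)

    def test_marker_mismatch_rejected(self, small_map_genos):
        gmap, genos = small_map_genos
        bad = RILGenotypes(genos.calls.iloc[:, :5].copy())
        with pytest.raises(ValueError):
            genotype_probabilities(gmap, bad)


class TestScanHK:
    def test_explicit_least_squares_example(self):
        # n=4, y=[1.0,1.2,3.0,2.8], marker split [A,A,B,B]:
        # RSS0=3.28, RSS1=0.04, LOD = 2*log10(82) = 3.83
        gmap = GeneticMap(pd.DataFrame(
            {"marker": ["m1"], "chrom": ["A01"], "pos_cm": [0.0]}
        ))
        genos = RILGenotypes(pd.DataFrame(
            {"m1": ["AA", "AA", "BB", "BB"]},
            index=pd.Index([f"L{i}" for i in range(4)], name="line"),
        ))
        probs = genotype_probabilities(gmap, genos, step=0.0, error_rate=0.0)
        sc = scan_hk(probs, [1.0, 1.2, 3.0, 2.8])
        assert sc.table["lod"].iloc[0] == pytest.approx(
            2 * np.log10(3.28 / 0.04), rel=1e-9
        )
        assert round(float(sc.table["lod"].iloc[0]), 2) == 3.83

    def test_equals_marker_regression_at_markers(self, small_map_genos):
        gmap, genos = small_map_genos
        probs = genotype_probabilities(gmap, genos, step=0.0, error_rate=0.0)
        rng = np.random.default_rng(3)
        dos = genos.dosage(gmap)
        y = 5 + 1.5 * dos[:, 4] + rng.normal(0, 1, dos.shape[0])
        sc = scan_hk(probs, y)
        n = len(y)
        for j in [0, 4, 10]:
            X = np.column_stack([np.ones(n), dos[:, j]])
            b, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss1 = float(np.sum((y - X @ b) ** 2))
            rss0 = float(np.sum((y - y.mean()) ** 2))
            lod = (n / 2) * np.log10(rss0 / rss1)
            assert sc.table["lod"].iloc[j] == pytest.approx(lod, rel=1e-9)

    def test_too_few_lines(self, small_map_genos):
        probs = genotype_probabilities(*small_map_genos, step=0.0)
        y = np.full(len(probs.lines), np.nan)
        y[:2] = [1.0, 2.0]
        with pytest.raises(ScanError):
            scan_hk(probs, y)


class TestPermutationThreshold:
    @pytest.fixture()
    def probs(self, dense_probs):
        return dense_probs

    def test_quantile_monotone_and_deterministic(self, probs):
        rng = np.random.default_rng(4)
        y = rng.normal(0, 1, len(probs.lines))
        t95, maxima = permutation_threshold(probs, y, n_perm=500, seed=9,
                                            return_maxima=True)
        t90 = float(np.quantile(maxima, 0.90))
        assert t95 >= t90
        again = permutation_threshold(probs, y, n_perm=500, seed=9)
        assert again == t95

    def test_minimum_permutations_enforced(self, probs):
        y = np.random.default_rng(5).normal(size=len(probs.lines))
        with pytest.raises(ValueError):
            permutation_threshold(probs, y, n_perm=50)

    def test_null_scan_rarely_exceeds_threshold(self, probs):
        rng = np.random.default_rng(6)
        exceed = 0
        for rep in range(40):
            y = rng.normal(0, 1, len(probs.lines))
            thr = permutation_threshold(probs, y, n_perm=250, seed=rep)
            exceed += scan_hk(probs, y).max_lod() > thr
        assert exceed <= 6  # ~5% expected; binomial slack at 40 reps


class TestPVE:
    def test_paper_scale_value(self):
        assert round(pve_from_lod(10, 119), 1) == 32.1

    def test_zero_lod(self):
        assert pve_from_lod(0, 50) == 0.0

    def test_direct_evaluation(self):
        assert pve_from_lod(3, 100) == pytest.approx(12.90, abs=5e-3)

    def test_round_trip(self):
        for lod, n in [(2.5, 119), (7.0, 60), (0.3, 200)]:
            assert lod_from_pve(pve_from_lod(lod, n), n) == pytest.approx(
                lod, rel=1e-10
            )

    def test_domain(self):
        with pytest.raises(ValueError):
            pve_from_lod(3, 0)
        with pytest.raises(ValueError):
            pve_from_lod(-1, 10)


class TestSupportInterval:
    def test_triangular_curve(self):
        pos = np.arange(0.0, 101.0)
        lod = np.maximum(0.0, 6.0 - 0.3 * np.abs(pos - 50.0))
        lo, hi = lod_support_interval(pos, lod, 50, drop=1.5)
        assert (lo, hi) == (45.0, 55.0)

    def test_flat_curve_spans_chromosome(self):
        pos = np.arange(0.0, 51.0)
        lod = np.full(pos.size, 4.2)
        assert lod_support_interval(pos, lod, 25) == (0.0, 50.0)

    @pytest.mark.parametrize("peak", [0, 17, 50])
    def test_contains_peak(self, peak):
        rng = np.random.default_rng(peak)
        pos = np.arange(0.0, 51.0)
        lod = rng.uniform(0, 3, pos.size)
        lod[peak] = 5.0
        lo, hi = lod_support_interval(pos, lod, peak)
        assert lo <= pos[peak] <= hi


class TestStepwiseSearch:
    @pytest.fixture()
    def probs(self, dense_probs):
        return dense_probs

    def test_null_phenotype_empty_model(self, probs):
        rng = np.random.default_rng(7)
        y = rng.normal(0, 1, len(probs.lines))
        thr = permutation_threshold(probs, y, n_perm=300, seed=1)
        model = stepwise_qtl_search(probs, y, thr)
        # a 0.95 threshold is exceeded ~5% of the time under the null
        assert len(model) <= 1

    def test_single_qtl_matches_scan_peak(self, small_map_genos, probs):
        gmap, genos = small_map_genos
        rng = np.random.default_rng(8)
        d = (genos.calls["A02m006"] == "BB").to_numpy(float)
        y = 10 + 3.0 * d + rng.normal(0, 1, len(d))
        model = stepwise_qtl_search(probs, y, threshold=3.0)
        sc = scan_hk(probs, y)
        pk = sc.peak()
        assert len(model) >= 1
        top = model.loci.sort_values("lod", ascending=False).iloc[0]
        assert top["chrom"] == pk["chrom"]
        assert top["pos_cm"] == pytest.approx(pk["pos_cm"], abs=2.0)
        # effect is the additive half-difference; direction -1 because the
        # second parent's allele (BB) raises the trait here
        assert top["effect"] == pytest.approx(1.5, abs=0.4)
        assert top["direction"] == -1
        assert top["ci_lo"] <= top["pos_cm"] <= top["ci_hi"]

    def test_two_qtl_recovered(self, small_map_genos, probs):
        gmap, genos = small_map_genos
        rng = np.random.default_rng(9)
        d1 = (genos.calls["A01m006"] == "BB").to_numpy(float)
        d2 = (genos.calls["A03m004"] == "BB").to_numpy(float)
        y = 10 + 2.5 * d1 - 2.0 * d2 + rng.normal(0, 1, len(d1))
        thr = permutation_threshold(probs, y, n_perm=300, seed=2)
        model = stepwise_qtl_search(probs, y, thr)
        found = {
            (row["chrom"], row["ci_lo"] <= truth_pos <= row["ci_hi"])
            for truth_chrom, truth_pos in [("A01", 50.0), ("A03", 30.0)]
            for _, row in model.loci.iterrows()
            if row["chrom"] == truth_chrom
        }
        assert ("A01", True) in found and ("A03", True) in found


class TestColocalization:
    @staticmethod
    def model(rows):
        cols = ["chrom", "pos_cm", "nearest_marker", "lod", "effect",
                "direction", "pve", "ci_lo", "ci_hi", "_coef"]
        return QTLModel(loci=pd.DataFrame(rows, columns=cols),
                        model_lod=0.0, threshold=3.0, n=100)

    def test_overlapping_same_direction_collapse(self):
        m1 = self.model([("A01", 50.0, "m", 6.0, 1.0, 1, 20.0, 45.0, 55.0, -2.0)])
        m2 = self.model([("A01", 52.0, "m", 4.0, 0.9, 1, 15.0, 48.0, 58.0, -1.8)])
        out = collapse_colocalized({"UN2011": m1, "UN2012": m2})
        assert len(out) == 1
        assert out.iloc[0]["lod"] == 6.0  # highest-LOD representative kept

    def test_opposite_direction_not_collapsed(self):
        m1 = self.model([("A01", 50.0, "m", 6.0, 1.0, 1, 20.0, 45.0, 55.0, -2.0)])
        m2 = self.model([("A01", 52.0, "m", 4.0, 0.9, -1, 15.0, 48.0, 58.0, 1.8)])
        out = collapse_colocalized({"UN2011": m1, "UN2012": m2})
        assert len(out) == 2

    def test_disjoint_intervals_not_collapsed(self):
        m1 = self.model([("A01", 20.0, "m", 6.0, 1.0, 1, 20.0, 15.0, 25.0, -2.0)])
        m2 = self.model([("A01", 80.0, "m", 4.0, 0.9, 1, 15.0, 70.0, 90.0, -1.8)])
        out = collapse_colocalized({"UN2011": m1, "UN2012": m2})
        assert len(out) == 2
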