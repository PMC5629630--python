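import itertools

import numpy as np
import pytest
from sklearn.base import clone

from trigamete.data_model import (
    DegenerateInputError,
    GameteFreqs,
    NormalizedGameteFreqs,
    ThetaMatrix,
)
from trigamete.mapping import (
    AmbiguousTripleError,
    LinkageMapper,
    analyze_triple,
    infer_order_phase,
    linkage_chisq,
    normalize,
    order_map,
    pairwise_theta,
    triple_recomb_fractions,
)
from trigamete.simulate import LinkageMapSpec, haldane, simulate_f2
from conftest import coupling_triple_q


def nf(p, ids=("a", "b", "c")):
    return NormalizedGameteFreqs(p=np.asarray(p, float), locus_ids=tuple(ids))


class TestNormalize:
    @pytest.mark.parametrize(
        "q, expected",
        [
            ((0.2, 0.1, 0.1, 0.1), (0.2, 0.1, 0.1, 0.1)),
            ((0.4, 0.2, 0.2, 0.2), (0.2, 0.1, 0.1, 0.1)),
            ((0.3, 0.05, 0.1, 0.05), (0.3, 0.05, 0.1, 0.05)),
        ],
    )
    def test_rescales_to_half(self, q, expected):
        out = normalize(GameteFreqs(q=np.array(q), locus_ids=("a", "b", "c")))
        assert np.allclose(out.p, expected)
        assert out.p.sum() == pytest.approx(0.5, abs=1e-15)

    def test_all_zero_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            normalize(GameteFreqs(q=np.zeros(4), locus_ids=("a", "b", "c")))


class TestOrderPhase:
    def test_published_triple_123_orders_2_1_3_in_coupling(self):
        p = nf((0.208668, 0.086162, 0.094698, 0.110472), ids=("1", "2", "3"))
        res = infer_order_phase(p)
        assert res.ordered_loci == ("2", "1", "3")
        assert res.phase == "coupling"
        assert res.parental_class == 1 and res.double_co_class == 2

    def test_repulsion_geometry_with_class1_as_double_crossover(self):
        # parental aBc/AbC (class 4), rarest class abc/ABC: middle locus is b,
        # giving order a-b-c with the middle locus in repulsion
        res = infer_order_phase(nf((0.05, 0.125, 0.126, 0.199)))
        assert res.ordered_loci == ("a", "b", "c")
        assert res.phase == "repulsion"
        assert res.parental_class == 4 and res.double_co_class == 1

    def test_tied_frequencies_flag_ambiguous(self):
        res = infer_order_phase(nf((0.125, 0.125, 0.125, 0.125)))
        assert res.ambiguous and res.phase == "ambiguous"
        with pytest.raises(AmbiguousTripleError):
            triple_recomb_fractions(res, nf((0.125,) * 4))


class TestTripleFractions:
    # published frequency rows and the recombination fractions derived
    # from them (outer1-mid, mid-outer2, outer1-outer2)
    TABLE = [
        (("1", "2", "3"), (0.208668, 0.086162, 0.094698, 0.110472),
         (0.39326, 0.36172, 0.41034)),
        (("1", "2", "5"), (0.200976, 0.080676, 0.108494, 0.109854),
         (0.38106, 0.37834, 0.43669)),
        (("1", "3", "5"), (0.209093, 0.065783, 0.122370, 0.102753),
         (0.33707, 0.37631, 0.45024)),
        (("2", "3", "5"), (0.202566, 0.085775, 0.112098, 0.099561),
         (0.37067, 0.39575, 0.42332)),
    ]

    @pytest.mark.parametrize("ids, p, expected", TABLE)
    def test_published_rows_reproduce_printed_fractions(self, ids, p, expected):
        res = analyze_triple(nf(p, ids=ids))
        got = (res.r_outer1_mid, res.r_mid_outer2, res.r_outer1_outer2)
        assert got == pytest.approx(expected, abs=1e-5)

    def test_near_complete_linkage_gives_near_zero_fractions(self):
        res = analyze_triple(nf((0.499994, 1e-6, 2e-6, 3e-6)))
        for r in (res.r_outer1_mid, res.r_mid_outer2, res.r_outer1_outer2):
            assert r == pytest.approx(0.0, abs=2e-5)

    def test_role_rule_special_cases(self, rng):
        """With parental class 1 and double-CO class 4 the role rule reduces to
        r_ab = 2(p2+p4), r_bc = 2(p3+p4), r_ac = 2(p2+p3); with parental 4 and
        double-CO 1 it reduces to r_ab = 2(p3+p1), r_bc = 2(p2+p1), r_ac = 2(p3+p2)."""
        for _ in range(25):
            x = np.sort(rng.random(2) * 0.08)
            # coupling: p1 largest, p4 smallest
            p = np.array([0.5 - 0.1 - x[1] - x[0], 0.1, x[1], x[0]])
            res = analyze_triple(nf(p))
            assert res.ordered_loci == ("a", "b", "c")
            assert res.r_outer1_mid == pytest.approx(2 * (p[1] + p[3]))
            assert res.r_mid_outer2 == pytest.approx(2 * (p[2] + p[3]))
            assert res.r_outer1_outer2 == pytest.approx(2 * (p[1] + p[2]))
            # repulsion mirror: p4 largest, p1 smallest
            p = p[::-1].copy()
            res = analyze_triple(nf(p))
            assert res.ordered_loci == ("a", "b", "c")
            assert res.r_outer1_mid == pytest.approx(2 * (p[2] + p[0]))
            assert res.r_mid_outer2 == pytest.approx(2 * (p[1] + p[0]))
            assert res.r_outer1_outer2 == pytest.approx(2 * (p[2] + p[1]))

    @pytest.mark.parametrize("r1, r2", [(0.05, 0.2), (0.1648, 0.1293), (0.3, 0.25)])
    def test_haldane_self_consistency(self, r1, r2):
        """Noise-free gamete classes under independent crossovers return the
        true adjacent fractions exactly, and the double-CO class frequency
        is r1*r2/2."""
        q = coupling_triple_q(r1, r2)
        res = analyze_triple(nf(q))
        assert q[3] == pytest.approx(r1 * r2 / 2)
        assert res.ordered_loci == ("a", "b", "c")
        assert res.r_outer1_mid == pytest.approx(r1, abs=1e-12)
        assert res.r_mid_outer2 == pytest.approx(r2, abs=1e-12)
        assert res.r_outer1_outer2 == pytest.approx(r1 + r2 - 2 * r1 * r2, abs=1e-12)


class TestLinkageChisq:
    def test_uniform_classes_fit_perfectly(self):
        stat, p = linkage_chisq(nf((0.125,) * 4), 200)
        assert stat == 0.0 and p == 1.0

    def test_two_missing_classes(self):
        stat, p = linkage_chisq(nf((0.25, 0.25, 0.0, 0.0)), 100)
        assert stat == pytest.approx(200.0)
        assert p < 1e-3

    def test_matches_hand_computed_statistic(self):
        p_vec = (0.15, 0.10, 0.125, 0.125)
        counts = np.rint(2 * 200 * 2 * np.array(p_vec))
        expected_stat = ((counts - counts.sum() / 4) ** 2 / (counts.sum() / 4)).sum()
        stat, _ = linkage_chisq(nf(p_vec), 200)
        assert stat == pytest.approx(expected_stat)


class TestPairwiseTheta:
    def _results(self):
        rows = TestTripleFractions.TABLE
        return [analyze_triple(nf(p, ids=ids)) for ids, p, _ in rows]

    def test_published_averages(self):
        theta = pairwise_theta(self._results(), ["1", "2", "3", "5"])
        frame = theta.to_frame()
        assert frame.loc["1", "2"] == pytest.approx(0.387164, abs=1e-6)
        assert frame.loc["3", "5"] == pytest.approx(0.436782, abs=1e-6)
        assert (theta.n_refs[~np.eye(4, dtype=bool)] == 2).all()
        assert np.allclose(theta.theta, theta.theta.T)

    def test_mean_of_identical_references_is_that_value(self):
        q = coupling_triple_q(0.2, 0.2)
        results = [
            analyze_triple(nf(q, ids=("a", "b", ref))) for ref in ("c", "d")
        ]
        theta = pairwise_theta(results, ["a", "b", "c", "d"])
        assert theta.theta[0, 1] == pytest.approx(0.2, abs=1e-12)

    def test_linked_filter_drops_unscreened_triples(self):
        results = self._results()
        pvals = {frozenset(r.locus_ids): 1.0 for r in results}
        pvals[frozenset(("1", "2", "3"))] = 1e-6
        theta = pairwise_theta(
            results, ["1", "2", "3", "5"], filter="linked", screen_pvalues=pvals
        )
        assert theta.n_refs[0, 1] == 1  # only triple (1,2,3) survives for pair 1-2
        assert np.isnan(theta.theta[0, 3])  # pair 1-5 has no surviving reference


class TestOrderMap:
    def test_three_locus_worked_example(self):
        markers = ["1", "2", "3"]
        t = np.array([[0, 0.387, 0.349], [0.387, 0, 0.391], [0.349, 0.391, 0]])
        tm = ThetaMatrix(markers=markers, theta=t, n_refs=np.ones((3, 3), int))
        assert order_map(tm) == ["2", "1", "3"]

    def test_equidistant_line_recovered_and_reversal_invariant(self):
        d = 15.0
        markers = [f"L{i}" for i in range(4)]
        t = np.zeros((4, 4))
        for i, j in itertools.combinations(range(4), 2):
            t[i, j] = t[j, i] = haldane(d * abs(i - j))
        tm = ThetaMatrix(markers=markers, theta=t, n_refs=np.ones((4, 4), int))
        assert order_map(tm) == markers
        rev = ThetaMatrix(
            markers=markers[::-1], theta=t[::-1, ::-1], n_refs=np.ones((4, 4), int)
        )
        assert order_map(rev) == markers

    def test_two_loci_rejected(self):
        tm = ThetaMatrix(
            markers=["a", "b"], theta=np.zeros((2, 2)), n_refs=np.ones((2, 2), int)
        )
        with pytest.raises(ValueError, match="at least 3"):
            order_map(tm)

    def test_missing_entries_reported(self):
        t = np.zeros((3, 3))
        t[0, 2] = t[2, 0] = np.nan
        tm = ThetaMatrix(markers=["a", "b", "c"], theta=t, n_refs=np.ones((3, 3), int))
        with pytest.raises(ValueError, match="undefined"):
            order_map(tm)


class TestLinkageMapper:
    def test_els_pipeline_on_simulated_data(self):
        spec = LinkageMapSpec(
            locus_names=["A", "B", "C", "D"],
            adjacent_distances=[15.0, 20.0, 15.0],
            marker_type="dominant",
        )
        matrix, _ = simulate_f2(spec, 500, seed=5)
        mapper = LinkageMapper(method="els").fit(matrix.calls, markers=matrix.markers)
        assert mapper.theta_.theta.shape == (4, 4)
        assert len(mapper.triple_results_) == 4
        assert mapper.order_ in (["A", "B", "C", "D"],)

    def test_em_pipeline_on_codominant_data(self):
        spec = LinkageMapSpec(
            locus_names=["A", "B", "C"],
            adjacent_distances=[20.0, 20.0],
            marker_type="codominant",
        )
        matrix, _ = simulate_f2(spec, 400, seed=6)
        mapper = LinkageMapper(method="em", marker_type="codominant").fit(
            matrix.calls, markers=matrix.markers
        )
        assert np.isfinite(mapper.theta_.theta).all()
        assert mapper.order_ == ["A", "B", "C"]

    def test_sklearn_clone(self):
        est = LinkageMapper(method="bat", alpha=0.01)
        assert clone(est).get_params() == est.get_params()
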