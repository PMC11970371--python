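import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from haploscreen.core import DiseaseHaplotype, HMMParams, MarkerPanel
from haploscreen.hmm import (
    chain_llr,
    emission_prob,
    score_against_set,
    score_matrix,
    score_pair,
    transition_probs,
)
from haploscreen.simulate import implant_case, synth_cohort, derive_disease_haplotypes

from conftest import make_uniform_panel, random_instance
from oracles import enumerate_chain_llr


class TestEmission:
    @pytest.mark.parametrize(
        "d,t,f,g,state,expected",
        [
            (1, 1, 0.2, 0.01, "IBD", 0.99),
            (1, 0, 0.2, 0.01, "IBD", 0.01),
            (0, 1, 0.2, 0.3, "nonIBD", 0.2),
            (0, 0, 0.2, 0.3, "nonIBD", 0.8),
        ],
    )
    def test_values(self, d, t, f, g, state, expected):
        assert emission_prob(d, t, f, g, state) == pytest.approx(expected)

    def test_missing_allele_is_contract_violation(self):
        with pytest.raises(ValueError):
            emission_prob(-1, 1, 0.2, 0.01, "IBD")

    @given(
        st.sampled_from([0, 1]),
        st.sampled_from([0, 1]),
        st.floats(0.01, 0.99),
        st.floats(0.001, 0.49),
        st.sampled_from(["IBD", "nonIBD"]),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_probabilities_in_open_unit_interval(self, d, t, f, g, state):
        assert 0.0 < emission_prob(d, t, f, g, state) < 1.0


class TestTransition:
    def test_zero_distance_identity(self, params):
        np.testing.assert_allclose(transition_probs(0.0, 0.0, params), np.eye(3))

    def test_exponential_decay_closed_form(self):
        p = HMMParams(decay_meioses=20.0, switch_rate_per_bp=0.0)
        k = transition_probs(0.01, 1e6, p)
        assert k[0, 0] == pytest.approx(np.exp(-0.2))
        assert k[0, 2] == pytest.approx(1 - np.exp(-0.2))

    def test_large_distance_absorbs(self, params):
        k = transition_probs(10.0, 0.0, params)
        assert k[0, 2] == pytest.approx(1.0)

    def test_switch_probability_capped(self):
        p = HMMParams(switch_rate_per_bp=1e-3)
        k = transition_probs(0.0, 1e9, p)
        assert k[0, 1] == pytest.approx(1.0)  # decay 1, s capped at 1

    @given(st.floats(0.0, 5.0), st.floats(0.0, 1e9))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_rows_sum_to_one(self, dm, db):
        k = transition_probs(dm, db, HMMParams())
        np.testing.assert_allclose(k.sum(axis=1), 1.0, atol=1e-12)
        assert (k >= 0).all()


def _disease_on(panel, alleles):
    return DiseaseHaplotype("h0", "v", alleles, "1", panel.dcv_pos_bp)


class TestChain:
    def test_perfect_sharing_runs_to_window_edge(self, params):
        panel = make_uniform_panel(n_markers=41, alt_freq=0.5)
        hapA = np.ones(41, dtype=np.int8)
        hapB = np.zeros(41, dtype=np.int8)
        disease = _disease_on(panel, np.ones(41, dtype=np.int8))
        right = chain_llr(disease, hapA, hapB, panel, "right", params)
        left = chain_llr(disease, hapA, hapB, panel, "left", params)
        assert right.llr > 0 and left.llr > 0
        assert right.end_index == 40
        assert left.end_index == 0

    def test_matches_path_enumeration_with_missing_data(self):
        rng = np.random.default_rng(7)
        for _ in range(15):
            panel, disease, hapA, hapB, params = random_instance(rng)
            for direction, inc in [("right", True), ("left", False)]:
                res = chain_llr(
                    disease, hapA, hapB, panel, direction, params,
                    include_origin=inc, drop_threshold=np.inf,
                    return_trajectory=True,
                )
                expected = enumerate_chain_llr(
                    disease.alleles, hapA, hapB, panel, params, direction, inc
                )
                got = res.trajectory[-1] if res.trajectory.size else 0.0
                assert got == pytest.approx(expected, abs=1e-9)

    def test_chain_value_is_running_maximum(self, params):
        # share 1 cM to the right of the DCV, then nothing: the chain value
        # must be the peak at the sharing boundary, not the final LLR
        panel = make_uniform_panel(n_markers=81, spacing_cm=0.1, alt_freq=0.5)
        rng = np.random.default_rng(3)
        d = rng.integers(0, 2, 81).astype(np.int8)
        hapA = 1 - d
        hapB = 1 - d
        share = slice(40, 51)
        hapA[share] = d[share]
        disease = _disease_on(panel, d)
        res = chain_llr(
            disease, hapA, hapB, panel, "right", params,
            drop_threshold=np.inf, return_trajectory=True,
        )
        assert res.llr == pytest.approx(res.trajectory.max())
        assert 44 <= res.end_index <= 52

    def test_mirror_symmetry_about_origin(self, params):
        rng = np.random.default_rng(11)
        m = 21
        panel = make_uniform_panel(n_markers=m, alt_freq=0.3)
        half = rng.integers(0, 2, 10).astype(np.int8)
        d = np.concatenate([half[::-1], [1], half]).astype(np.int8)
        a_half = rng.integers(0, 2, 10).astype(np.int8)
        b_half = rng.integers(0, 2, 10).astype(np.int8)
        hapA = np.concatenate([a_half[::-1], [1], a_half]).astype(np.int8)
        hapB = np.concatenate([b_half[::-1], [1], b_half]).astype(np.int8)
        disease = _disease_on(panel, d)
        left = chain_llr(disease, hapA, hapB, panel, "left", params,
                         include_origin=False)
        right = chain_llr(disease, hapA, hapB, panel, "right", params,
                          include_origin=False)
        assert left.llr == pytest.approx(right.llr, abs=1e-10)

    def test_missing_disease_allele_at_dcv_rejected(self, params):
        panel = make_uniform_panel(n_markers=5)
        d = np.ones(5, dtype=np.int8)
        d[panel.dcv_index] = -1
        with pytest.raises(ValueError, match="missing at the DCV"):
            chain_llr(_disease_on(panel, d), d, d, panel, "right", params)

    def test_rarer_matching_alleles_contribute_more(self):
        # with g -> 0 and perfect sharing, per-marker gain ~ ln(stay/f)
        params = HMMParams(g=1e-6)
        scores = {}
        for f in (0.1, 0.4):
            panel = make_uniform_panel(n_markers=21, alt_freq=f)
            hap = np.ones(21, dtype=np.int8)
            rec = score_pair(_disease_on(panel, hap), hap, hap.copy(),
                             panel, params)
            scores[f] = rec.ibd_score
        assert scores[0.1] > scores[0.4]

    def test_relabel_ref_alt_invariance(self, params):
        rng = np.random.default_rng(5)
        panel, disease, hapA, hapB, _ = random_instance(rng, n_markers=12)
        base = score_pair(disease, hapA, hapB, panel, params)
        # flip coding at a handful of markers, complementing alt_freq
        flip = rng.random(12) < 0.5
        freq2 = panel.alt_freq.copy()
        freq2[flip] = 1 - freq2[flip]
        panel2 = MarkerPanel("1", panel.pos_bp, panel.cm, panel.ref, panel.alt,
                             freq2, dcv_pos_bp=panel.dcv_pos_bp)

        def reflip(h):
            h = h.copy()
            sel = flip & (h != -1)
            h[sel] = 1 - h[sel]
            return h

        disease2 = _disease_on(panel2, reflip(disease.alleles))
        rec = score_pair(disease2, reflip(hapA), reflip(hapB), panel2, params)
        assert rec.ibd_score == pytest.approx(base.ibd_score, abs=1e-10)

    def test_skipping_marker_equals_deleting_it(self, params):
        rng = np.random.default_rng(9)
        for _ in range(10):
            panel, disease, hapA, hapB, p = random_instance(
                rng, n_markers=10, missing_rate=0.0
            )
            j = int(rng.integers(10))
            if j == panel.dcv_index:
                continue
            a2, b2 = hapA.copy(), hapB.copy()
            a2[j] = -1
            b2[j] = -1
            skipped = score_pair(disease, a2, b2, panel, p)
            keep = np.arange(10) != j
            panel_d = panel.subset(keep)
            panel_d.set_dcv(panel.dcv_pos_bp)
            disease_d = DiseaseHaplotype("h0", "v", disease.alleles[keep], "1",
                                         panel.dcv_pos_bp)
            deleted = score_pair(disease_d, hapA[keep], hapB[keep], panel_d, p)
            assert skipped.ibd_score == pytest.approx(deleted.ibd_score, abs=1e-10)

    def test_single_missing_haplotype_is_marginalized_not_skipped(self, params):
        panel = make_uniform_panel(n_markers=9, alt_freq=0.2)
        d = np.ones(9, dtype=np.int8)
        hapA = np.ones(9, dtype=np.int8)
        hapB = np.zeros(9, dtype=np.int8)
        full = score_pair(_disease_on(panel, d), hapA, hapB, panel, params)
        b_missing = hapB.copy()
        b_missing[6] = -1
        partial = score_pair(_disease_on(panel, d), hapA, b_missing, panel, params)
        assert partial.n_markers_used == full.n_markers_used
        assert partial.ibd_score != pytest.approx(full.ibd_score)


class TestScorePair:
    def test_additivity_of_chains(self, params):
        rng = np.random.default_rng(13)
        panel, disease, hapA, hapB, p = random_instance(rng, n_markers=14)
        rec = score_pair(disease, hapA, hapB, panel, p)
        left = chain_llr(disease, hapA, hapB, panel, "left", p)
        right = chain_llr(disease, hapA, hapB, panel, "right", p)
        assert rec.ibd_score == pytest.approx(left.llr + right.llr)
        assert rec.left_end_index <= panel.dcv_index <= rec.right_end_index

    def test_random_haplotypes_score_below_perfect_match(self, params):
        panel = make_uniform_panel(n_markers=51, alt_freq=0.5)
        rng = np.random.default_rng(17)
        d = rng.integers(0, 2, 51).astype(np.int8)
        disease = _disease_on(panel, d)
        perfect = score_pair(disease, d, 1 - d, panel, params).ibd_score
        rand_scores = [
            score_pair(
                disease,
                rng.integers(0, 2, 51).astype(np.int8),
                rng.integers(0, 2, 51).astype(np.int8),
                panel,
                params,
            ).ibd_score
            for _ in range(30)
        ]
        assert np.mean(rand_scores) < perfect

    def test_longer_implanted_sharing_scores_higher_on_average(self, params):
        # >=100 simulated pairs: 5 cM implants vs 0.5 cM implants
        cohort, panel = synth_cohort(
            n_individuals=120, n_markers=700, seed=21, marker_spacing_cm=0.01
        )
        haps, donors = derive_disease_haplotypes(
            cohort, panel, "single", n_haps=1, core_length_cm=5.0, seed=22
        )
        test = cohort.drop(donors)
        means = {}
        for length in (0.5, 5.0):
            scores = []
            for i in range(100):
                alleles, _ = implant_case(
                    test.alleles[i], haps[0], panel, length, seed=1000 + i
                )
                scores.append(
                    score_pair(haps[0], alleles[0], alleles[1], panel, params
                               ).ibd_score
                )
            means[length] = np.mean(scores)
        assert means[5.0] > means[0.5]


class TestScoreAgainstSet:
    def test_singleton_equals_score_pair(self, params):
        rng = np.random.default_rng(19)
        panel, disease, hapA, hapB, p = random_instance(rng, n_markers=10)
        single = score_against_set([disease], hapA, hapB, panel, p)
        pair = score_pair(disease, hapA, hapB, panel, p)
        assert single.ibd_score == pair.ibd_score
        assert single.hap_id == pair.hap_id

    def test_returns_maximum_and_set_monotonicity(self, params):
        rng = np.random.default_rng(23)
        panel, d0, hapA, hapB, p = random_instance(rng, n_markers=12,
                                                   missing_rate=0.0)
        haps = [d0]
        for k in (1, 2):
            alleles = rng.integers(0, 2, 12).astype(np.int8)
            haps.append(DiseaseHaplotype(f"h{k}", "v", alleles, "1",
                                         panel.dcv_pos_bp))
        best2 = score_against_set(haps[:2], hapA, hapB, panel, p)
        best3 = score_against_set(haps, hapA, hapB, panel, p)
        assert best3.ibd_score >= best2.ibd_score
        expected = max(
            score_pair(h, hapA, hapB, panel, p).ibd_score for h in haps
        )
        assert best3.ibd_score == pytest.approx(expected)

    def test_tie_breaks_to_lowest_hap_id(self, params):
        panel = make_uniform_panel(n_markers=7)
        alleles = np.ones(7, dtype=np.int8)
        hb = DiseaseHaplotype("b", "v", alleles, "1", panel.dcv_pos_bp)
        ha = DiseaseHaplotype("a", "v", alleles.copy(), "1", panel.dcv_pos_bp)
        rec = score_against_set([hb, ha], alleles, alleles, panel, params)
        assert rec.hap_id == "a"

    def test_empty_set_rejected(self, uniform_panel, params):
        with pytest.raises(ValueError, match="empty"):
            score_against_set([], np.ones(21, dtype=np.int8),
                              np.ones(21, dtype=np.int8), uniform_panel, params)


class TestScoreMatrix:
    def test_chunking_does_not_change_scores(self, params):
        cohort, panel = synth_cohort(n_individuals=40, n_markers=300, seed=31)
        haps, _ = derive_disease_haplotypes(cohort, panel, "multiple",
                                            n_haps=3, core_length_cm=2.0,
                                            seed=32)
        whole = score_matrix(haps, cohort, panel, params)
        chunked = score_matrix(haps, cohort, panel, params, chunk_size=7)
        np.testing.assert_array_equal(whole.to_numpy(), chunked.to_numpy())
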