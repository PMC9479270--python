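"""Key-lncRNA ranking, correlation statistics, and network construction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from lncnet.exceptions import DataError, ParameterError
from lncnet.network import (NetworkThresholds, build_network,
                            correlation_pvalue, pearson_r, select_key_lncrnas,
                            spearman_r)
from lncnet.synthetic import SimulationConfig, simulate_study
from tests.conftest import build_study


def pearson_oracle(x, y):
    """Covariance-formula Pearson correlation, coded independently."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)


class TestSelectKeyLncrnas:
    def test_top9_of_published_table(self, reversal_table):
        top = select_key_lncrnas(reversal_table, 9)
        assert top[0] == "uc.361−"
        by_id = {r.transcript_id: r for r in reversal_table}
        fcs = [by_id[t].fc_bzxd_vs_cia for t in top]
        assert fcs == sorted(fcs, reverse=True)
        assert fcs[0] == 111.56
        directions = [by_id[t].reg_bzxd_vs_cia for t in top]
        assert directions.count("Down") == 5
        assert directions.count("Up") == 4

    def test_k_equals_record_count_returns_all_sorted(self, reversal_table):
        ordered = select_key_lncrnas(reversal_table, len(reversal_table))
        assert len(ordered) == 33
        by_id = {r.transcript_id: r for r in reversal_table}
        fcs = [by_id[t].fc_bzxd_vs_cia for t in ordered]
        assert fcs == sorted(fcs, reverse=True)

    def test_toy_ordering(self):
        picked = select_key_lncrnas([("a", 5.0), ("b", 2.0), ("c", 9.0)], 2)
        assert picked == ["c", "a"]

    def test_ties_broken_by_id(self):
        picked = select_key_lncrnas([("b", 3.0), ("a", 3.0), ("c", 1.0)], 2)
        assert picked == ["a", "b"]

    def test_k_too_large_is_parameter_error(self):
        with pytest.raises(ParameterError):
            select_key_lncrnas([("a", 1.0)], 2)


class TestPearson:
    def test_perfect_positive_linear(self):
        x = np.arange(1.0, 9.0)
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0, abs=1e-14)

    def test_perfect_negative(self):
        x = np.arange(1.0, 9.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0, abs=1e-14)

    def test_matches_covariance_formula_oracle(self):
        x, y = [1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 5.0]
        assert pearson_r(x, y) == pytest.approx(pearson_oracle(x, y), abs=1e-12)
        assert pearson_r(x, y) == pytest.approx(stats.pearsonr(x, y).statistic,
                                                abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(DataError, match="constant"):
            pearson_r([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])

    def test_too_short_rejected(self):
        with pytest.raises(ParameterError):
            pearson_r([1.0, 2.0], [3.0, 4.0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=4, max_size=12, unique=True),
           st.floats(0.1, 10.0), st.floats(-5.0, 5.0))
    def test_symmetry_and_affine_invariance(self, xs, slope, shift):
        ys = [2.5 * v - 1.0 for v in xs]
        r = pearson_r(xs, ys)
        assert pearson_r(ys, xs) == pytest.approx(r, abs=1e-12)
        scaled = [slope * v + shift for v in xs]
        assert pearson_r(xs, scaled) == pytest.approx(1.0, abs=1e-9)
        flipped = [-slope * v + shift for v in xs]
        assert pearson_r(xs, flipped) == pytest.approx(-1.0, abs=1e-9)

    def test_spearman_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=10)
        y = x + rng.normal(0, 0.3, 10)
        assert spearman_r(np.exp(x), y) == pytest.approx(spearman_r(x, y),
                                                         abs=1e-12)


class TestCorrelationPvalue:
    def test_zero_correlation_p_is_one(self):
        for n in (3, 5, 12, 50):
            assert correlation_pvalue(0.0, n) == 1.0

    def test_perfect_correlation_p_is_zero(self):
        assert correlation_pvalue(1.0, 12) == 0.0
        assert correlation_pvalue(-1.0, 12) == 0.0

    def test_matches_t_cdf_oracle(self):
        r, n = 0.98, 12
        t = r * math.sqrt((n - 2) / (1 - r * r))
        expected = 2 * (1 - stats.t.cdf(t, n - 2))
        assert correlation_pvalue(r, n) == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("r", [-0.99, -0.5, 0.2, 0.7, 0.95, 0.999])
    @pytest.mark.parametrize("n", [4, 12, 30])
    def test_oracle_grid(self, r, n):
        t = abs(r) * math.sqrt((n - 2) / (1 - r * r))
        expected = 2 * stats.t.sf(t, n - 2)
        assert correlation_pvalue(r, n) == pytest.approx(expected, abs=1e-10)

    def test_r_threshold_implies_p_threshold_at_n12(self):
        """At n = 12 every correlation passing |r| >= 0.98 passes p < 0.05."""
        assert correlation_pvalue(0.98, 12) < 0.05
        # analytically: p is decreasing in |r|, so the boundary case suffices
        assert correlation_pvalue(0.98, 12) < 1e-6

    def test_small_n_rejected(self):
        with pytest.raises(ParameterError):
            correlation_pvalue(0.5, 2)


class TestBuildNetwork:
    def test_empty_mrna_side_gives_empty_network(self, small_study):
        study, truth = small_study
        lnc = sorted(truth.reversal_lncrna)
        net = build_network(study, lnc, [])
        assert net.n_edges == 0 and not net.lncrna_nodes

    def test_recovers_planted_edges_exactly_with_decoys(self):
        """Tightly coupled planted pairs plus null decoy mRNAs: the called
        edge set equals the planted pairing."""
        cfg = SimulationConfig(n_lncrna=30, n_mrna=260, n_reversal_lncrna=2,
                               targets_per_lncrna=5, n_reversal_mrna=0,
                               coupling_sd=0.01, seed=17)
        study, truth = simulate_study(cfg)
        lnc = sorted(truth.reversal_lncrna)
        decoys = [t for t in study.transcripts_of("mRNA")
                  if t not in truth.reversal_mrna][:200]
        candidates = sorted(truth.reversal_mrna) + decoys
        net = build_network(study, lnc, candidates)
        assert net.edge_pairs() == {(l, m) for l, m, _ in truth.planted_edges}
        for e in net.edges:
            sign = {s for l, m, s in truth.planted_edges
                    if (l, m) == (e.lncrna_id, e.mrna_id)}.pop()
            assert np.sign(e.r) == sign

    def test_maximal_stringency_empties_noisy_network(self, small_study):
        study, truth = small_study
        lnc = sorted(truth.reversal_lncrna)
        decoys = sorted(set(study.transcripts_of("mRNA")) - truth.reversal_mrna)[:50]
        net = build_network(study, lnc, decoys,
                            NetworkThresholds(min_abs_r=1.0, max_p=0.05))
        assert net.n_edges == 0

    def test_bipartite_and_no_orphans(self, small_study):
        study, truth = small_study
        lnc = sorted(truth.reversal_lncrna)
        mrna = sorted(truth.reversal_mrna)
        net = build_network(study, lnc, mrna)
        assert net.lncrna_nodes == {e.lncrna_id for e in net.edges}
        assert net.mrna_nodes == {e.mrna_id for e in net.edges}
        assert not (net.lncrna_nodes & net.mrna_nodes)
        g = net.to_networkx()
        import networkx as nx
        assert nx.is_bipartite(g)

    def test_edge_statistics_match_scalar_functions(self, small_study):
        study, truth = small_study
        lnc = sorted(truth.reversal_lncrna)
        net = build_network(study, lnc, sorted(truth.reversal_mrna))
        log2 = study.log2_matrix()
        for e in list(net.edges)[:10]:
            r = pearson_r(log2.loc[e.lncrna_id], log2.loc[e.mrna_id])
            assert e.r == pytest.approx(r, abs=1e-10)
            assert e.p_value == pytest.approx(correlation_pvalue(r, e.n), abs=1e-12)

    def test_unknown_transcript_rejected(self, small_study):
        study, _ = small_study
        with pytest.raises(DataError, match="GHOST"):
            build_network(study, ["GHOST"], [])

    def test_constant_transcript_skipped_not_edged(self):
        study = build_study({"L0": [4.0] * 12,
                             "M0": [1.0, 2.0, 3.0, 4.0] * 3},
                            biotypes={"L0": "lncRNA"})
        net = build_network(study, ["L0"], ["M0"])
        assert net.n_edges == 0
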