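import math

import numpy as np
import pytest
from scipy import stats

from icossy.io import ChipMap, GeneNetwork
from icossy.network import MIS
from icossy.scoring import (
    NoMappedProbesets,
    entropy_score,
    iqr_t,
    rank_mis,
    select_representatives,
    welch_t,
)

from conftest import identity_chip, make_labels, make_matrix


class TestWelch:
    def test_identical_groups_degenerate(self):
        d = welch_t([1, 2, 3, 4], [1, 2, 3, 4])
        assert d.t_value == pytest.approx(0.0)
        assert d.p_value == pytest.approx(1.0)

    def test_shifted_group_matches_textbook_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = x + 10.0
        # independent arithmetic: equal variances 5/3, n=4 each
        se = math.sqrt((5 / 3) / 4 + (5 / 3) / 4)
        expected_t = -10.0 / se
        expected_df = 6.0
        d = welch_t(x, y)
        assert d.t_value == pytest.approx(expected_t, rel=1e-12)
        assert d.df == pytest.approx(expected_df, rel=1e-12)
        assert d.p_value == pytest.approx(2 * stats.t.sf(abs(expected_t), 6), rel=1e-10)
        assert d.fold_difference == pytest.approx(-10.0)

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=8), rng.normal(loc=1, size=9)
        d1, d2 = welch_t(x, y), welch_t(y, x)
        assert d1.t_value == pytest.approx(-d2.t_value)
        assert d1.p_value == pytest.approx(d2.p_value)

    def test_sign_matches_fold_difference(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x, y = rng.normal(size=6), rng.normal(size=6)
            d = welch_t(x, y)
            assert math.copysign(1, d.t_value) == math.copysign(1, d.fold_difference)

    def test_zero_variance_unequal_means_flagged(self):
        d = welch_t([2.0, 2.0], [5.0, 5.0])
        assert d.p_value == 0.0 and d.t_value == -math.inf

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(12345)
        pvals = [
            welch_t(rng.normal(size=10), rng.normal(size=10)).p_value for _ in range(2000)
        ]
        ks = stats.kstest(pvals, "uniform").statistic
        assert ks < 0.05


class TestIqrT:
    def test_identical_groups_zero(self):
        assert iqr_t([1, 2, 3, 4], [1, 2, 3, 4]).t_value == pytest.approx(0.0)

    def test_close_to_welch_on_clean_normal_samples(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, size=50)
        y = rng.normal(1, 1, size=50)
        tw = abs(welch_t(x, y).t_value)
        tr = abs(iqr_t(x, y).t_value)
        assert abs(tr - tw) / tw < 0.25

    def test_more_robust_to_single_outlier_than_welch(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, size=30)
        y = rng.normal(1, 1, size=30)
        x_out = np.append(x, 50.0)
        welch_shift = abs(abs(welch_t(x_out, y).t_value) - abs(welch_t(x, y).t_value))
        iqr_shift = abs(abs(iqr_t(x_out, y).t_value) - abs(iqr_t(x, y).t_value))
        assert iqr_shift < welch_shift


def _mis_with_probes(gene_probe_counts):
    """An MIS over the given genes plus a chip mapping n probes to each."""
    import networkx as nx

    genes = list(gene_probe_counts)
    g = nx.Graph()
    g.add_nodes_from(genes)
    g.add_edges_from((genes[i], genes[i + 1]) for i in range(len(genes) - 1))
    mis = MIS.from_nodes(g, genes)
    chip = ChipMap(
        {f"{gene}_pr{j}": gene for gene, n in gene_probe_counts.items() for j in range(n)}
    )
    return mis, chip


class TestRepresentatives:
    def _setup(self, n_probes_total, n_per_class=4, seed=0):
        gene_counts = {}
        remaining = n_probes_total
        i = 0
        while remaining > 0:
            take = min(2, remaining)
            gene_counts[f"G{i}"] = take
            remaining -= take
            i += 1
        mis, chip = _mis_with_probes(gene_counts)
        rng = np.random.default_rng(seed)
        probes = sorted(chip.probe_to_gene)
        m = make_matrix(
            rng.random((len(probes), 2 * n_per_class)), row_ids=probes
        )
        return mis, chip, m, make_labels(n_per_class)

    def test_exactly_five_from_eight_candidates(self):
        mis, chip, m, labels = self._setup(8)
        reps = select_representatives(mis, m, chip, labels)
        assert len(reps) == 5
        pvals = [r.p_value for r in reps]
        assert pvals == sorted(pvals)

    def test_three_candidates_all_returned(self):
        mis, chip, m, labels = self._setup(3)
        assert len(select_representatives(mis, m, chip, labels)) == 3

    def test_tie_broken_by_t_then_id(self):
        mis, chip = _mis_with_probes({"G0": 2})
        # identical rows -> identical p and |t|; order falls to probeset id
        values = np.tile([0.1, 0.2, 0.8, 0.9], (2, 1))
        m = make_matrix(values, row_ids=sorted(chip.probe_to_gene))
        reps = select_representatives(mis, m, chip, make_labels(2))
        assert [r.probeset_id for r in reps] == ["G0_pr0", "G0_pr1"]

    def test_no_mapped_probesets_raises(self):
        mis, chip, m, labels = self._setup(4)
        empty_chip = ChipMap({})
        with pytest.raises(NoMappedProbesets):
            select_representatives(mis, m, empty_chip, labels)


class TestEntropy:
    def test_perfect_separation_gives_zero(self):
        labels = make_labels(5)
        values = np.tile([1.0] * 5 + [0.0] * 5, (3, 1))
        m = make_matrix(values)
        reps = [welch_t(values[i, :5], values[i, 5:], probeset_id=f"p{i}") for i in range(3)]
        h, assignment = entropy_score(reps, m, labels, seed=0)
        assert h == pytest.approx(0.0)
        assert len(set(assignment.values())) == 2

    def test_bounded_by_one_bit(self):
        rng = np.random.default_rng(9)
        for seed in range(10):
            labels = make_labels(6)
            values = rng.random((4, 12))
            m = make_matrix(values)
            reps = [welch_t(values[i, :6], values[i, 6:], probeset_id=f"p{i}") for i in range(4)]
            h, _ = entropy_score(reps, m, labels, seed=seed)
            assert 0.0 <= h <= 1.0 + 1e-12

    def test_null_labels_large_n_near_one_bit(self):
        # labels independent of expression, balanced classes, N = 200
        rng = np.random.default_rng(100)
        entropies = []
        for seed in range(20):
            labels = make_labels(100)
            values = rng.random((5, 200))
            m = make_matrix(values)
            reps = [
                welch_t(values[i, :100], values[i, 100:], probeset_id=f"p{i}")
                for i in range(5)
            ]
            h, _ = entropy_score(reps, m, labels, seed=seed)
            entropies.append(h)
        assert np.mean(entropies) == pytest.approx(1.0, abs=0.1)

    def test_constant_expressions_degenerate_but_defined(self):
        labels = make_labels(3)
        values = np.full((2, 6), 0.5)
        m = make_matrix(values)
        reps = [welch_t(values[i, :3], values[i, 3:], probeset_id=f"p{i}") for i in range(2)]
        h, _ = entropy_score(reps, m, labels, seed=0)
        assert 0.0 <= h <= 1.0


class TestRankMis:
    def _two_mis_setup(self, seed=0):
        net = GeneNetwork.from_edges(
            [("A1", "A2"), ("A2", "A3"), ("B1", "B2"), ("B2", "B3")]
        )
        mis_a = MIS.from_nodes(net.graph, {"A1", "A2", "A3"})
        mis_b = MIS.from_nodes(net.graph, {"B1", "B2", "B3"})
        probes = ["A1_p", "A2_p", "A3_p", "B1_p", "B2_p", "B3_p"]
        chip = ChipMap({p: p[:-2] for p in probes})
        labels = make_labels(5)
        rng = np.random.default_rng(seed)
        values = rng.random((6, 10))
        values[:3, :5] = 0.9 + 0.05 * rng.random((3, 5))  # A separates classes
        values[:3, 5:] = 0.1 * rng.random((3, 5))
        m = make_matrix(values, row_ids=probes)
        return [mis_a, mis_b], m, chip, labels, mis_a

    def test_separating_mis_ranks_first(self):
        mis_list, m, chip, labels, mis_a = self._two_mis_setup()
        scores = rank_mis(mis_list, m, chip, labels, seed=0)
        assert scores[0].mis_id == mis_a.mis_id
        assert scores[0].entropy < scores[1].entropy

    def test_output_is_permutation_and_deterministic(self):
        mis_list, m, chip, labels, _ = self._two_mis_setup()
        s1 = rank_mis(mis_list, m, chip, labels, seed=3)
        s2 = rank_mis(mis_list, m, chip, labels, seed=3)
        assert {s.mis_id for s in s1} == {mis.mis_id for mis in mis_list}
        assert [(s.mis_id, s.entropy) for s in s1] == [(s.mis_id, s.entropy) for s in s2]

    def test_label_swap_invariance(self):
        mis_list, m, chip, labels, _ = self._two_mis_setup()
        swapped_names = (labels.class_names[1], labels.class_names[0])
        swapped = type(labels)(labels.sample_ids, swapped_names, dict(labels.assignment))
        s1 = rank_mis(mis_list, m, chip, labels, seed=1)
        s2 = rank_mis(mis_list, m, chip, swapped, seed=1)
        assert [(s.mis_id, pytest.approx(s.entropy)) for s in s1] == [
            (s.mis_id, s.entropy) for s in s2
        ]

    def test_unmappable_mis_skipped_with_log(self, caplog):
        mis_list, m, chip, labels, mis_a = self._two_mis_setup()
        partial_chip = ChipMap({p: g for p, g in chip.probe_to_gene.items() if g.startswith("A")})
        with caplog.at_level("INFO", logger="icossy"):
            scores = rank_mis(mis_list, m, partial_chip, labels, seed=0)
        assert len(scores) == 1 and scores[0].mis_id == mis_a.mis_id
        assert any("skipping" in rec.message for rec in caplog.records)
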