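import math

import numpy as np
import pytest
from scipy import stats

from mirisk.association_targets import (
    consensus_targets,
    correlation_screen,
    fisher_exact_2x2,
    global_association,
    group_tests,
    variance_filter,
    wilcoxon_rank_sum,
)
from mirisk.datamodel import ExpressionMatrix, PredictionTable, Scale
from mirisk.errors import AssociationError, GroupingError
from mirisk.synthetic_data import generate_prediction_table, simulate_survival


def _matrix(values, prefix="p"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        [f"{prefix}{i:03d}" for i in range(values.shape[0])],
        [f"s{j:03d}" for j in range(values.shape[1])],
        values,
        Scale.LOG2,
    )


class TestVarianceFilter:
    def test_559_probes_keep_20_percent_gives_112(self):
        rng = np.random.default_rng(0)
        m = _matrix(rng.normal(size=(559, 10)))
        out = variance_filter(m, 0.2)
        assert out.n_probes == 112  # ceil(0.2 * 559)

    def test_keep_fraction_one_is_identity(self, toy_matrix):
        out = variance_filter(toy_matrix, 1.0)
        assert out.probe_ids == toy_matrix.probe_ids
        np.testing.assert_array_equal(out.values, toy_matrix.values)

    def test_constant_probes_dropped_first(self):
        rng = np.random.default_rng(1)
        values = np.vstack([np.zeros((5, 8)), rng.normal(size=(5, 8))])
        m = _matrix(values)
        out = variance_filter(m, 0.5)
        assert set(out.probe_ids) == {f"p{i:03d}" for i in range(5, 10)}

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        m = _matrix(rng.normal(size=(50, 6)))
        once = variance_filter(m, 0.3)
        twice = variance_filter(once, 1.0)
        assert once.probe_ids == twice.probe_ids

    def test_output_subset_of_input(self):
        rng = np.random.default_rng(3)
        m = _matrix(rng.normal(size=(31, 5)))
        out = variance_filter(m, 0.4)
        assert set(out.probe_ids) <= set(m.probe_ids)
        assert out.n_probes == math.ceil(0.4 * 31)

    def test_bad_fraction_rejected(self, toy_matrix):
        with pytest.raises(AssociationError):
            variance_filter(toy_matrix, 0.0)


class TestConsensusTargets:
    def _table(self, counts):
        genes = [f"g{i}" for i in range(len(counts))]
        calls = np.zeros((len(counts), 7), dtype=bool)
        for i, c in enumerate(counts):
            calls[i, :c] = True
        return PredictionTable(genes, [f"tool{k}" for k in range(7)], calls)

    def test_six_of_seven_retained(self):
        t = self._table([6])
        assert consensus_targets(t, "mir-1").gene_ids == {"g0"}

    def test_five_of_seven_excluded(self):
        t = self._table([5])
        assert consensus_targets(t, "mir-1").gene_ids == set()

    def test_seven_of_seven_retained(self):
        t = self._table([7])
        assert consensus_targets(t, "mir-1").gene_ids == {"g0"}

    def test_min_tools_zero_keeps_all(self):
        t = self._table([0, 3, 7])
        assert consensus_targets(t, "mir-1", min_tools=0).gene_ids == {"g0", "g1", "g2"}

    def test_monotone_in_min_tools(self):
        t = self._table([0, 2, 4, 5, 6, 7])
        prev = None
        for k in range(8):
            cur = consensus_targets(t, "m", min_tools=k).gene_ids
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_min_tools_above_count_rejected(self):
        with pytest.raises(AssociationError):
            consensus_targets(self._table([7]), "m", min_tools=8)

    def test_generated_table_extremes(self):
        table = generate_prediction_table(
            {"t1", "t2"}, {"d1", "d2", "d3"}, p_hit_true=1.0, p_hit_decoy=0.0, seed=0
        )
        assert consensus_targets(table, "m").gene_ids == {"t1", "t2"}


class TestCorrelationScreen:
    def _planted_pair(self, seed, n=56, r=0.7):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        y = r * x + math.sqrt(1 - r * r) * rng.normal(size=n)
        mirna = _matrix(np.vstack([x, rng.normal(size=(4, n))]), prefix="mir")
        mrna = _matrix(np.vstack([y, rng.normal(size=(9, n))]), prefix="ps")
        return mirna, mrna

    def test_planted_link_recovered(self):
        recovered = 0
        n_seeds = 20
        for seed in range(n_seeds):
            mirna, mrna = self._planted_pair(seed)
            hits = correlation_screen(mirna, mrna, r_threshold=0.6, alpha=0.05)
            match = [
                h for h in hits if h.mirna_id == "mir000" and h.mrna_probeset == "ps000"
            ]
            if match and abs(match[0].r - 0.7) <= 0.15:
                recovered += 1
        assert recovered / n_seeds >= 0.9

    def test_self_correlation_r_one_no_influence(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=20)
        mirna = _matrix(x[None, :], prefix="mir")
        mrna = _matrix(np.vstack([x, rng.normal(size=(3, 20))]), prefix="ps")
        hits = correlation_screen(mirna, mrna)
        top = [h for h in hits if h.mrna_probeset == "ps000"][0]
        assert top.r == pytest.approx(1.0)
        assert not top.influence_flag

    def test_single_sample_leverage_flagged(self):
        # one outlier sample manufactures the correlation
        rng = np.random.default_rng(5)
        n = 20
        x = np.append(rng.normal(size=n - 1) * 0.1, 10.0)
        y = np.append(rng.normal(size=n - 1) * 0.1, 10.0)
        mirna = _matrix(x[None, :], prefix="mir")
        mrna = _matrix(np.vstack([y, rng.normal(size=(3, n))]), prefix="ps")
        hits = correlation_screen(mirna, mrna)
        lead = [h for h in hits if h.mrna_probeset == "ps000"]
        assert lead and lead[0].influence_flag

    def test_null_false_hit_rate_bh_controlled(self):
        counts = []
        for seed in range(50):
            rng = np.random.default_rng(seed + 100)
            mirna = _matrix(rng.normal(size=(6, 56)), prefix="mir")
            mrna = _matrix(rng.normal(size=(20, 56)), prefix="ps")
            counts.append(len(correlation_screen(mirna, mrna)))
        # BH at 0.05 over a null family: false hits are rare
        assert np.mean(counts) <= 0.05 * 6 * 20

    def test_sign_symmetric_retention(self):
        rng = np.random.default_rng(6)
        n = 56
        x = rng.normal(size=n)
        eps = rng.normal(size=n)
        y_pos = 0.75 * x + math.sqrt(1 - 0.75**2) * eps
        mirna = _matrix(x[None, :], prefix="mir")
        mrna = _matrix(np.vstack([y_pos, -y_pos, rng.normal(size=(3, n))]), prefix="ps")
        hits = correlation_screen(mirna, mrna)
        ids = {h.mrna_probeset for h in hits}
        assert {"ps000", "ps001"} <= ids
        by_id = {h.mrna_probeset: h for h in hits}
        assert by_id["ps000"].r == pytest.approx(-by_id["ps001"].r)

    def test_too_few_shared_samples(self):
        mirna = _matrix(np.random.default_rng(7).normal(size=(2, 4)), prefix="mir")
        mrna = _matrix(np.random.default_rng(8).normal(size=(2, 4)), prefix="ps")
        with pytest.raises(AssociationError):
            correlation_screen(mirna, mrna)


class TestGlobalAssociation:
    def test_null_calibration(self):
        rej = 0
        n_seeds = 60
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            m = _matrix(rng.normal(size=(5, 40)))
            y = rng.normal(size=40)
            _, p = global_association(m, y, n_perm=400, seed=seed + 1)
            rej += p < 0.05
        assert 0.0 <= rej / n_seeds <= 0.11

    def test_power_on_linear_combination(self):
        hits = 0
        n_seeds = 15
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed + 300)
            m = _matrix(rng.normal(size=(5, 50)))
            y = m.values[0] + m.values[2] + 0.3 * rng.normal(size=50)
            _, p = global_association(m, y, n_perm=1000, seed=seed)
            hits += p < 0.01
        assert hits / n_seeds >= 0.93

    def test_survival_outcome_power(self):
        rng = np.random.default_rng(9)
        m = _matrix(rng.normal(size=(4, 60)))
        out = simulate_survival(m.values[1], loghr=1.2, censor_rate=0.2, seed=10)
        _, p = global_association(m, out, n_perm=1000, seed=11)
        assert p < 0.01

    def test_single_feature_consistent_with_univariate(self):
        agree = 0
        n_seeds = 30
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed + 700)
            x = rng.normal(size=(2, 40))
            x[1] = x[0] + 1e-9 * rng.normal(size=40)  # effectively one feature
            beta = 0.8 if seed % 2 else 0.0
            y = beta * x[0] + rng.normal(size=40)
            m = _matrix(x)
            _, p_global = global_association(m, y, n_perm=600, seed=seed)
            p_uni = stats.pearsonr(x[0], y).pvalue
            agree += (p_global < 0.05) == (p_uni < 0.05)
        assert agree / n_seeds >= 0.9

    def test_constant_outcome_rejected(self):
        m = _matrix(np.random.default_rng(12).normal(size=(3, 20)))
        with pytest.raises(AssociationError):
            global_association(m, np.ones(20))


class TestGroupTests:
    def test_wilcoxon_null_calibration(self):
        rej = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=30)
            g = np.arange(30) < 15
            _, p = wilcoxon_rank_sum(x, g)
            rej += p <= 0.05
        assert rej / n_seeds <= 0.07

    def test_fisher_hand_enumerated(self):
        # table [[3,1],[1,3]]: two-sided p = sum of hypergeometric outcomes
        # with probability <= P(a=3): (1 + 16 + 16 + 1) / 70
        _, p = fisher_exact_2x2(np.array([[3, 1], [1, 3]]))
        assert p == pytest.approx(34 / 70, abs=1e-12)

    def test_empty_margin_rejected(self):
        with pytest.raises(GroupingError):
            fisher_exact_2x2(np.array([[0, 0], [1, 3]]))

    def test_dispatch_continuous_and_categorical(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=20)
        g = np.arange(20) < 10
        stat, p = group_tests(x, g, kind="continuous")
        assert 0 <= p <= 1
        f = rng.random(20) < 0.5
        stat, p = group_tests(f, g, kind="categorical")
        assert 0 <= p <= 1

    def test_single_group_rejected(self):
        with pytest.raises(GroupingError):
            wilcoxon_rank_sum([1.0, 2.0], [True, True])
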