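"""Fisher tests, event-type composition shifts, rank-sum comparisons and
the quadrant-concordance binomial test."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from splicecore.set_stats import (bh_adjust, event_type_shift,
                                  fc_distribution_shift, fisher_2x2,
                                  quadrant_concordance)

from helpers import oracle_fisher_two_sided


class TestFisher:
    def test_balanced_table(self):
        res = fisher_2x2(5, 5, 5, 5)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_two_sided == pytest.approx(1.0)

    def test_extreme_table_closed_form(self):
        res = fisher_2x2(10, 0, 0, 10)
        assert res.p_two_sided == pytest.approx(2 / math.comb(20, 10))

    def test_small_tables_match_enumeration_oracle(self):
        for a, b, c, d in itertools.product(range(5), repeat=4):
            if a + b == 0 or c + d == 0:
                continue
            res = fisher_2x2(a, b, c, d)
            assert res.p_two_sided == pytest.approx(
                oracle_fisher_two_sided(a, b, c, d)), (a, b, c, d)

    def test_symmetric_under_double_swap(self):
        res1 = fisher_2x2(3, 7, 8, 2)
        res2 = fisher_2x2(2, 8, 7, 3)   # swap rows and columns
        assert res1.p_two_sided == pytest.approx(res2.p_two_sided)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_2x2(-1, 2, 3, 4)


class TestEventTypeShift:
    def _types(self, counts):
        labels = [t for t, n in counts.items() for _ in range(n)]
        ids = [f"e{i}" for i in range(len(labels))]
        return pd.Series(labels, index=ids), ids

    def test_identical_composition_not_significant(self):
        types, ids = self._types({"IR": 20, "ES": 20})
        res = event_type_shift(set(ids), set(ids), types)
        for r in res.values():
            assert r.p_two_sided == pytest.approx(1.0)

    def test_counts_reproduce_marginals(self):
        types, ids = self._types({"IR": 6, "ES": 4, "ALTA": 2})
        core, bg = set(ids[:5]), set(ids[5:])
        res = event_type_shift(core, bg, types)
        for etype, r in res.items():
            (a, b), (c, d) = r.table
            assert a + b == len(core) and c + d == len(bg)
            assert a + c == (types == etype).sum()

    def test_planted_ir_depletion_detected(self):
        rng = np.random.default_rng(0)
        # background 50% IR; core IR odds scaled by 0.3 -> ~23% IR
        bg_types = ["IR" if rng.random() < 0.5 else "ES" for _ in range(500)]
        core_types = ["IR" if rng.random() < 0.231 else "ES" for _ in range(500)]
        labels = pd.Series(core_types + bg_types,
                           index=[f"e{i}" for i in range(1000)])
        core = {f"e{i}" for i in range(500)}
        bg = {f"e{i}" for i in range(500, 1000)}
        res = event_type_shift(core, bg, labels)
        assert res["IR"].p_two_sided < 0.05
        assert res["IR"].odds_ratio < 1.0


class TestQuadrantConcordance:
    def test_all_concordant_closed_form(self):
        pairs = [(20.0, 30.0)] * 12 + [(-25.0, -40.0)] * 8
        res = quadrant_concordance(pairs)
        assert (res.n_concordant, res.n_total) == (20, 20)
        assert res.p == pytest.approx(0.5 ** 20)

    def test_partial_concordance_enumeration(self):
        pairs = [(20.0, 30.0)] * 15 + [(20.0, -30.0)] * 5
        res = quadrant_concordance(pairs)
        expected = sum(math.comb(20, k) for k in range(15, 21)) * 0.5 ** 20
        assert res.p == pytest.approx(expected)

    def test_threshold_filters_pairs(self):
        pairs = [(20.0, 30.0)] * 3 + [(10.0, 30.0), (20.0, 14.9)]
        res = quadrant_concordance(pairs)
        assert res.n_total == 3

    def test_sign_flip_invariance(self):
        rng = np.random.default_rng(5)
        pairs = [(float(rng.uniform(-60, 60)), float(rng.uniform(-60, 60)))
                 for _ in range(100)]
        flipped = [(-x, -y) for x, y in pairs]
        r1, r2 = quadrant_concordance(pairs), quadrant_concordance(flipped)
        assert (r1.n_concordant, r1.n_total, r1.p) == \
               (r2.n_concordant, r2.n_total, r2.p)

    def test_independent_signs_near_half_concordant(self):
        rng = np.random.default_rng(6)
        fracs = []
        for _ in range(30):
            pairs = [(float(rng.choice([-30, 30])), float(rng.choice([-30, 30])))
                     for _ in range(100)]
            res = quadrant_concordance(pairs)
            fracs.append(res.n_concordant / res.n_total)
        assert abs(np.mean(fracs) - 0.5) < 0.05

    def test_no_qualifying_pairs_rejected(self):
        with pytest.raises(ValueError):
            quadrant_concordance([(5.0, 5.0)])


class TestRankSumAndBH:
    def test_fc_shift_detects_planted_upregulation(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(400)]
        fc = pd.Series(rng.normal(0, 1, 400), index=genes)
        fc.iloc[:100] += 1.0
        res = fc_distribution_shift(genes[:100], genes[100:], fc)
        assert res["p"] < 1e-6
        assert res["median_set"] > res["median_background"]

    def test_bh_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(8)
        ps = rng.uniform(0, 1, 40).tolist()
        ours = bh_adjust(ps)
        _, theirs, *_ = multipletests(ps, method="fdr_bh")
        assert np.allclose(ours, theirs)
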