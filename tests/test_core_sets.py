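"""Stress and tissue core-set calling (AS and GE layers) plus controls."""

import math

import numpy as np
import pandas as pd
import pytest

from splicecore.core_sets import (GeParams, StressAsParams,
                                  as_nr_set, common_controls, directions,
                                  genome_background, members, set_overlaps,
                                  stress_as_core, stress_ge_core,
                                  tissue_as_core, tissue_ge_core)
from splicecore.types import ExpressionTable

from helpers import (mk_design, mk_psi_table, oracle_stress_members,
                     oracle_tissue_members, random_small_table)

NAN = math.nan


def stress_table(deltas, base=50.0, event_type=None, host=None, extra=None):
    """One event with given treated-control deltas across 5 abiotic
    experiments (None -> uncovered experiment)."""
    psi = {"E": {}}
    for i, d in enumerate(deltas, start=1):
        if d is None:
            continue
        psi["E"][f"abiotic{i}_ctl"] = base
        psi["E"][f"abiotic{i}_trt"] = base + d
    psi.update(extra or {})
    return mk_psi_table(psi, event_type=event_type, host=host,
                        samples=list(DESIGN.frame.index))


DESIGN = mk_design(n_experiments=5, classes=("abiotic",))


class TestStressAsCore:
    def test_two_supporting_experiments_up(self):
        t = stress_table([20, 18, 3, None, -2])
        calls = stress_as_core(t, DESIGN, "abiotic")
        assert members(calls) == {"E"}
        assert directions(calls)["E"] == "up"

    def test_opposite_directions_ambiguous(self):
        t = stress_table([20, -20, 18, 0, 0])
        calls = stress_as_core(t, DESIGN, "abiotic")
        assert members(calls) == set()
        assert any(c.ambiguous for c in calls)

    def test_threshold_is_strict(self):
        t = stress_table([15, 15, 0, 0, 0])
        assert members(stress_as_core(t, DESIGN, "abiotic")) == set()
        t2 = stress_table([15.1, 15.1, 0, 0, 0])
        assert members(stress_as_core(t2, DESIGN, "abiotic")) == {"E"}

    def test_single_supporting_experiment_insufficient(self):
        t = stress_table([40, 0, 0, 0, 0])
        assert members(stress_as_core(t, DESIGN, "abiotic")) == set()

    def test_min_alt_use_filters_low_host_exon(self):
        def alt_table(host_psi):
            extra = {"HOST": {f"abiotic{i}_{k}": host_psi
                              for i in range(1, 6) for k in ("ctl", "trt")}}
            return stress_table([30, 30, 0, 0, 0], event_type={"E": "ALTA"},
                                host={"E": "HOST"}, extra=extra)
        assert members(stress_as_core(alt_table(20.0), DESIGN, "abiotic")) == set()
        assert "E" in members(stress_as_core(alt_table(30.0), DESIGN, "abiotic"))

    def test_unknown_stress_class_rejected(self):
        with pytest.raises(ValueError):
            stress_as_core(stress_table([0] * 5), DESIGN, "biotic")

    def test_anti_monotone_in_thresholds(self, noisy_ds):
        t, d = noisy_ds.psi, noisy_ds.design
        base = members(stress_as_core(t, d, "abiotic"))
        stricter = members(stress_as_core(
            t, d, "abiotic", StressAsParams(dpsi_thresh=30)))
        more_exp = members(stress_as_core(
            t, d, "abiotic", StressAsParams(min_experiments=4)))
        assert stricter <= base and more_exp <= base

    def test_agrees_with_bruteforce_oracle_on_random_tables(self):
        rng = np.random.default_rng(9)
        design = mk_design(n_experiments=5)
        for _ in range(20):
            t = random_small_table(rng, n_events=6, design=design)
            for cls in ("abiotic", "biotic"):
                got = directions(stress_as_core(t, design, cls))
                assert got == oracle_stress_members(t, design, cls)


def tissue_table(target_mean, other_means, reps=2, tissues=None):
    tissues = tissues or ["t0", "t1", "t2", "t3", "t4"]
    psi = {"E": {}}
    for i, t in enumerate(tissues):
        m = target_mean if i == 0 else other_means[i - 1]
        if m is None:
            continue
        n = reps if i == 0 else 2
        for r in range(1, n + 1):
            psi["E"][f"{t}_r{r}"] = m
    return mk_psi_table(psi, samples=list(TDESIGN.frame.index))


TDESIGN = mk_design(tissues={f"t{i}": 3 for i in range(5)}, n_experiments=0,
                    classes=())


class TestTissueAsCore:
    def test_clear_target_shift_up(self):
        t = tissue_table(80.0, [20.0, 25.0, 30.0, 15.0])
        calls = tissue_as_core(t, TDESIGN)
        assert members(calls) == {"E"}
        call = [c for c in calls if not c.ambiguous][0]
        assert (call.direction, call.target_tissue) == ("up", "t0")

    def test_single_small_difference_disqualifies(self):
        t = tissue_table(60.0, [50.0, 20.0, 20.0, 20.0])
        assert members(tissue_as_core(t, TDESIGN)) == set()

    def test_single_replicate_not_evaluable(self):
        t = tissue_table(80.0, [20.0, 25.0, 30.0, 15.0], reps=1)
        assert members(tissue_as_core(t, TDESIGN)) == set()

    def test_global_dpsi_threshold(self):
        # every pairwise diff > 15 but global mean diff <= 25
        t = tissue_table(50.0, [26.0, 26.0, 26.0, 26.0])
        assert members(tissue_as_core(t, TDESIGN)) == set()
        t2 = tissue_table(52.0, [26.0, 26.0, 26.0, 26.0])
        assert members(tissue_as_core(t2, TDESIGN)) == {"E"}

    def test_related_tissue_excluded_from_comparison(self):
        related_design = mk_design(tissues={f"t{i}": 3 for i in range(5)},
                                   n_experiments=0, classes=(),
                                   related=[("t0", "t1")])
        # t1 is close to the target t0 but declared related: ignored
        t = tissue_table(80.0, [75.0, 25.0, 30.0, 15.0])
        assert members(tissue_as_core(t, related_design)) == {"E"}
        assert members(tissue_as_core(t, TDESIGN)) == set()

    def test_agrees_with_bruteforce_oracle(self):
        rng = np.random.default_rng(13)
        design = mk_design(tissues={f"t{i}": 3 for i in range(5)},
                           n_experiments=0, classes=())
        for _ in range(15):
            t = random_small_table(rng, n_events=6, design=design)
            calls = tissue_as_core(t, design)
            got = {}
            for c in calls:
                got.setdefault(c.item_id, []).append((c.target_tissue, c.direction))
            oracle = oracle_tissue_members(t, design)
            assert {e: sorted(v) for e, v in got.items()} == \
                   {e: sorted(v) for e, v in oracle.items()}


def _expr(values, design):
    samples = list(design.frame.index)
    crpkm = pd.DataFrame({s: [values.get(s, 20.0)] for s in samples},
                         index=pd.Index(["G"], name="gene_id"))
    return ExpressionTable(crpkm, (crpkm * 20).round())


class TestStressGeCore:
    DESIGN = mk_design(n_experiments=5, classes=("abiotic",))

    def _fc_table(self, fcs, base=20.0):
        vals = {}
        for i, fc in enumerate(fcs, start=1):
            vals[f"abiotic{i}_ctl"] = base
            vals[f"abiotic{i}_trt"] = base * fc if fc is not None else base
        return _expr(vals, self.DESIGN)

    def test_member_up(self):
        calls = stress_ge_core(self._fc_table([2.5, 3.0, 1.1, None, 0.9]),
                               self.DESIGN, "abiotic")
        assert directions(calls) == {"G": "up"}

    def test_opposite_directions_ambiguous(self):
        calls = stress_ge_core(self._fc_table([2.5, 0.2, 2.2, 1, 1]),
                               self.DESIGN, "abiotic")
        assert members(calls) == set()
        assert any(c.ambiguous for c in calls)

    def test_low_expression_ineligible(self):
        from splicecore.core_sets import _ge_eligible
        expr = self._fc_table([1, 1, 1, 1, 1], base=4.0)   # cRPKM 4 everywhere
        assert not _ge_eligible(expr, self.DESIGN, "abiotic", GeParams()).at["G"]
        assert members(stress_ge_core(expr, self.DESIGN, "abiotic")) == set()
        # the epsilon-stabilized ratios alone would not trigger membership
        # anyway, so also check a clearly expressed gene stays eligible
        expr2 = self._fc_table([1, 1, 1, 1, 1], base=20.0)
        assert _ge_eligible(expr2, self.DESIGN, "abiotic", GeParams()).at["G"]


class TestTissueGeCore:
    DESIGN = mk_design(tissues={f"t{i}": 3 for i in range(5)},
                       n_experiments=0, classes=())

    def _expr(self, medians):
        vals = {}
        for i, m in enumerate(medians):
            for r in range(1, 4):
                vals[f"t{i}_r{r}"] = m
        return _expr(vals, self.DESIGN)

    def test_member_up(self):
        calls = tissue_ge_core(self._expr([50, 10, 8, 9, 6]), self.DESIGN)
        assert directions(calls) == {"G": "up"}

    def test_below_median_floor_ineligible(self):
        calls = tissue_ge_core(self._expr([4.9, 0.1, 0.1, 0.1, 0.1]), self.DESIGN)
        assert members(calls) == set()

    def test_single_weak_fold_change_disqualifies(self):
        calls = tissue_ge_core(self._expr([30, 11, 2, 2, 2]), self.DESIGN)
        assert members(calls) == set()


class TestControls:
    DESIGN = mk_design(n_experiments=5, classes=("abiotic",))

    def test_flat_alternative_event_is_nr(self):
        t = stress_table([1, -1, 0.5, 0, -0.5])
        assert as_nr_set(t, self.DESIGN, "abiotic") == {"E"}

    def test_single_dpsi_of_6_excluded(self):
        t = stress_table([6, 0, 0, 0, 0])
        assert as_nr_set(t, self.DESIGN, "abiotic") == set()

    def test_constitutive_event_excluded(self):
        t = stress_table([0, 0, 0, 0, 0], base=100.0)
        assert as_nr_set(t, self.DESIGN, "abiotic") == set()

    def test_genome_needs_two_evaluable_experiments(self):
        t = stress_table([0, None, None, None, None])
        assert genome_background(t, self.DESIGN, "abiotic") == set()
        t2 = stress_table([0, 0, None, None, None])
        assert genome_background(t2, self.DESIGN, "abiotic") == {"E"}

    def test_two_of_three_rule_and_core_discard(self):
        nr = {"abiotic": {"a", "b", "c"}, "biotic": {"a", "b"}, "tissue": {"c"}}
        genome = {"abiotic": {"a", "b", "c", "d"}, "biotic": {"a", "b", "d"},
                  "tissue": {"d"}}
        cores = {"abiotic": set(), "biotic": set(), "tissue": {"b"}}
        common_genome, common_nr = common_controls(genome, nr, cores)
        assert common_genome == {"a", "b", "d"}
        # "a"/"c" are in 2 NR sets and no core; "b" is in 2 NR sets but
        # belongs to the tissue core, so it is discarded
        assert common_nr == {"a", "c"}

    def test_core_and_nr_disjoint_on_synthetic_data(self, noisy_ds):
        t, d = noisy_ds.psi, noisy_ds.design
        for cls in ("abiotic", "biotic"):
            core = members(stress_as_core(t, d, cls))
            nr = as_nr_set(t, d, cls)
            assert core.isdisjoint(nr)


class TestOverlaps:
    def test_disjoint_and_identical(self):
        res = set_overlaps({"a": {1, 2}, "b": {3, 4}, "c": {5}})
        assert all(v == 0 for v in res["intersections"].values())
        res2 = set_overlaps({"a": {1, 2}, "b": {1, 2}, "c": {1, 2}})
        assert res2["intersections"]["a&b&c"] == 2

    def test_gene_level_collapse(self):
        gm = {"e1": "G", "e2": "G", "e3": "H"}
        res = set_overlaps({"a": {"e1"}, "b": {"e2"}}, gene_map=gm)
        assert res["intersections"]["a&b"] == 0
        assert res["gene_level"]["intersections"]["a&b"] == 1
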