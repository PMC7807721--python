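"""Generator contracts: determinism, structural validity, planted-truth
consistency and graceful degradation under noise."""

import numpy as np
import pytest

from splicecore.core_sets import (members, stress_as_core, stress_ge_core,
                                  tissue_as_core, tissue_ge_core)
from splicecore.io_formats import read_gene_models, spliced_cds
from splicecore.genomics import translate_from
from splicecore.synthetic_data import (SyntheticConfig, generate,
                                       precision_recall)


class TestStructure:
    def test_psi_in_range_and_tier_n_iff_missing(self, noisy_ds):
        t = noisy_ds.psi
        t.validate()
        vals = t.psi.to_numpy(float)
        assert np.nanmin(vals) >= 0 and np.nanmax(vals) <= 100
        assert ((t.tier == "N") == t.psi.isna()).all().all()

    def test_emitted_gtf_fasta_reload_to_same_models(self, noisy_ds, tmp_path):
        paths = noisy_ds.write(tmp_path)
        models = read_gene_models(paths["gtf"], paths["fasta"])
        assert len(models) == len(noisy_ds.models)
        for gid, m in noisy_ds.models.models.items():
            m2 = models[gid]
            assert (m2.exons, m2.cds_tx, m2.strand) == (m.exons, m.cds_tx, m.strand)

    def test_every_planted_cds_translates_stop_free(self, noisy_ds):
        models = noisy_ds.models
        for m in models:
            cds = spliced_cds(m, models.genome)
            _, stop_end = translate_from(cds, 0)
            assert stop_end == len(cds) - 1, m.gene_id

    def test_design_structure(self, noisy_ds):
        d = noisy_ds.design
        assert len(d.tissue_types()) == 6
        for cls in ("abiotic", "biotic"):
            pairs = d.stress_pairs(cls)
            assert len(pairs) == 5
            assert all(None not in p for p in pairs.values())

    def test_infeasible_config_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(tissue_dpsi=150.0)
        with pytest.raises(ValueError, match="null events"):
            generate(SyntheticConfig(n_null_events=5, n_ge_stress=30))


class TestDeterminism:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        cfg = SyntheticConfig(seed=21, n_tissue_as=6, n_stress_as=6, n_panas=4,
                              n_null_events=60, n_ge_stress=8, n_ge_tissue=8,
                              n_lowexpr_genes=4)
        p1 = generate(cfg).write(tmp_path / "a")
        p2 = generate(cfg).write(tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key

    def test_different_seeds_differ(self, tmp_path):
        base = dict(n_tissue_as=6, n_stress_as=6, n_panas=4, n_null_events=60,
                    n_ge_stress=8, n_ge_tissue=8, n_lowexpr_genes=4)
        a = generate(SyntheticConfig(seed=1, **base))
        b = generate(SyntheticConfig(seed=2, **base))
        assert not np.allclose(a.psi.psi.to_numpy(float),
                               b.psi.psi.to_numpy(float), equal_nan=True)


class TestRecovery:
    def test_noise_free_pipeline_recovers_planted_sets_exactly(self, noisefree_ds):
        ds = noisefree_ds
        t, e, d = ds.psi, ds.expression, ds.design
        recovered = {
            "abiotic_AS": members(stress_as_core(t, d, "abiotic")),
            "biotic_AS": members(stress_as_core(t, d, "biotic")),
            "tissue_AS": members(tissue_as_core(t, d)),
            "abiotic_GE": members(stress_ge_core(e, d, "abiotic")),
            "biotic_GE": members(stress_ge_core(e, d, "biotic")),
            "tissue_GE": members(tissue_ge_core(e, d)),
        }
        for name, got in recovered.items():
            assert got == ds.truth.members(name), name

    def test_recall_degrades_gracefully_with_noise(self):
        """Mean recall of planted stress events is non-increasing in the PSI
        noise sd (scaled-down version of the generator contract)."""
        sds = [0.0, 8.0, 25.0]
        mean_recalls = []
        for sd in sds:
            recalls = []
            for seed in range(3):
                cfg = SyntheticConfig(seed=100 + seed, n_tissue_as=4,
                                      n_stress_as=12, n_panas=4,
                                      n_null_events=60, n_ge_stress=6,
                                      n_ge_tissue=6, n_lowexpr_genes=2,
                                      psi_noise_sd=sd,
                                      coverage_dropout_rate=0.0,
                                      ir_imbalance_rate=0.0)
                ds = generate(cfg)
                called = members(stress_as_core(ds.psi, ds.design, "abiotic"))
                _, rec = precision_recall(called, ds.truth.members("abiotic_AS"))
                recalls.append(rec)
            mean_recalls.append(np.mean(recalls))
        for lo, hi in zip(mean_recalls[1:], mean_recalls[:-1]):
            assert lo <= hi + 0.02
        assert mean_recalls[0] == 1.0

    def test_planted_ir_imbalance_reduces_ir_coverage(self):
        base = dict(seed=5, n_tissue_as=4, n_stress_as=6, n_panas=4,
                    n_null_events=60, n_ge_stress=6, n_ge_tissue=6,
                    n_lowexpr_genes=2, psi_noise_sd=0.0,
                    coverage_dropout_rate=0.0)
        from splicecore.coverage_qc import coverage_mask
        clean = generate(SyntheticConfig(**base, ir_imbalance_rate=0.0))
        dirty = generate(SyntheticConfig(**base, ir_imbalance_rate=0.5))
        ir = clean.psi.events["event_type"] == "IR"
        n_clean = coverage_mask(clean.psi).loc[ir].to_numpy().sum()
        n_dirty = coverage_mask(dirty.psi).loc[ir].to_numpy().sum()
        assert n_dirty < n_clean
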