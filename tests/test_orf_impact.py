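"""Event location, six-way ORF-impact classification, NMD/truncation rules,
and 5'-UTR / uORF enrichment tests."""

import numpy as np
import pytest
from scipy.stats import fisher_exact

from splicecore.orf_impact import (classify_impact, event_isoforms,
                                   exclude_region, include_region,
                                   impact_profile, locate_event,
                                   uorf_enrichment, utr5_enrichment)
from splicecore.synthetic_data import N_TEMPLATES
from splicecore.types import AsEvent, GeneModel, GeneModelSet

from helpers import oracle_fisher_two_sided


class TestIntervalArithmetic:
    def test_include_merges_adjacent(self):
        assert include_region([(1, 10), (31, 40)], (11, 20)) == [(1, 20), (31, 40)]
        assert include_region([(1, 10), (31, 40)], (11, 30)) == [(1, 40)]

    def test_exclude_trims_and_removes(self):
        assert exclude_region([(1, 10), (31, 40)], (31, 40)) == [(1, 10)]
        assert exclude_region([(1, 40)], (11, 20)) == [(1, 10), (21, 40)]

    def test_isoforms_roundtrip(self):
        exons = [(1, 10), (31, 40), (61, 70)]
        ev = AsEvent("E", "G", "ES", "c", 31, 40, "+")
        model = GeneModel("G", "G.1", "c", "+", exons)
        inc, exc = event_isoforms(ev, model)
        assert inc == exons
        assert exc == [(1, 10), (61, 70)]


class TestLocateEvent:
    def _model(self, strand):
        # 3 exons; CDS occupies genomic 121..240 on either strand (the
        # minus-strand gene is the mirror image, CDS at the start of its tx)
        exons = [(1, 40), (101, 140), (201, 240)]
        cds_tx = (61, 120) if strand == "+" else (1, 60)
        return GeneModel("G", "G.1", "c", strand, exons, cds_tx=cds_tx)

    def test_intron_upstream_of_cds_plus(self):
        ev = AsEvent("E", "G", "IR", "c", 41, 100, "+")
        assert locate_event(ev, self._model("+")) == "UTR5"

    def test_same_coordinates_minus_strand_is_utr3(self):
        ev = AsEvent("E", "G", "IR", "c", 41, 100, "-")
        assert locate_event(ev, self._model("-")) == "UTR3"

    def test_event_straddling_cds_start_spans(self):
        ev = AsEvent("E", "G", "ES", "c", 101, 140, "+")
        assert locate_event(ev, self._model("+")) == "spanning"

    def test_event_outside_transcript_rejected(self):
        ev = AsEvent("E", "G", "ES", "c", 500, 550, "+")
        with pytest.raises(ValueError, match="outside"):
            locate_event(ev, self._model("+"))


def _bank_event(events, eid):
    row = events.loc[eid]
    return AsEvent(eid, row["gene_id"], row["event_type"], row["chrom"],
                   int(row["start"]), int(row["end"]), row["strand"])


class TestClassifyImpact:
    def test_fixture_bank_labels_and_nmd(self, bank):
        models, events, labels, nmd = bank
        for eid in events.index:
            imp = classify_impact(_bank_event(events, eid), models)
            assert imp.category == labels[eid], eid
            assert imp.nmd_predicted == nmd[eid], eid

    def test_strand_flip_invariance(self, bank):
        """The same template built on + and - strands classifies identically."""
        models, events, labels, nmd = bank
        by_template = {}
        for i, eid in enumerate(events.index):
            by_template.setdefault(i % N_TEMPLATES, []).append(eid)
        for tmpl, eids in by_template.items():
            strands = {events.at[e, "strand"] for e in eids}
            assert strands == {"+", "-"}
            cats = {classify_impact(_bank_event(events, e), models).category
                    for e in eids}
            assert len(cats) == 1, (tmpl, cats)

    def test_truncation_fields_populated_for_disrupt(self, bank):
        models, events, labels, _ = bank
        disrupt = [e for e in events.index if labels[e].startswith("DISRUPT")]
        assert disrupt
        for eid in disrupt:
            imp = classify_impact(_bank_event(events, eid), models)
            assert imp.truncation_fraction is not None
            assert 0.0 <= imp.truncation_fraction <= 1.0
            assert imp.introduces_stop or imp.introduces_frameshift

    def test_annotated_isoform_evidence_wins(self, bank):
        """If both isoform junction chains are annotated transcripts, the
        event is ALT_PROTEIN even when the scan sees a disruption."""
        models, events, labels, _ = bank
        eid = next(e for e in events.index
                   if labels[e] == "DISRUPT_ON_EXCLUSION"
                   and events.at[e, "event_type"] == "ES")
        ev = _bank_event(events, eid)
        model = models[ev.gene_id]
        inc_exons, exc_exons = event_isoforms(ev, model)
        from splicecore.orf_impact import junction_chain
        patched = GeneModelSet(
            models.models, models.genome,
            {**models.alt_chains,
             ev.gene_id: [junction_chain(inc_exons), junction_chain(exc_exons)]})
        assert classify_impact(ev, patched).category == "ALT_PROTEIN"

    def test_missing_cds_is_uncertain(self):
        model = GeneModel("G", "G.1", "c", "+", [(1, 30), (61, 90)])
        models = GeneModelSet({"G": model}, {"c": "A" * 200})
        ev = AsEvent("E", "G", "IR", "c", 31, 60, "+")
        assert classify_impact(ev, models).category == "UNCERTAIN_CDS"


class TestProfilesAndEnrichment:
    def test_profile_proportions_sum_to_one(self, bank):
        models, events, labels, _ = bank
        impacts = {e: classify_impact(_bank_event(events, e), models)
                   for e in events.index}
        prof = impact_profile(list(events.index), events, impacts)
        for _, grp in prof.groupby("direction"):
            assert grp["proportion"].sum() == pytest.approx(1.0)
        assert "UNCERTAIN_CDS" not in set(prof["category"])

    def test_enrichment_matches_hypergeometric_closed_form(self):
        # core: 10/10 in 5' UTR; genome: 10/20
        class FakeImpact:
            def __init__(self, cat):
                self.category = cat
        impacts = {f"c{i}": FakeImpact("UTR5") for i in range(10)}
        impacts.update({f"g{i}": FakeImpact("UTR5" if i < 10 else "UTR3")
                        for i in range(20)})
        res = utr5_enrichment([f"c{i}" for i in range(10)],
                              [f"g{i}" for i in range(20)], impacts)
        _, expected = fisher_exact([[10, 0], [10, 10]], alternative="greater")
        assert res["p"] == pytest.approx(expected)
        assert oracle_fisher_two_sided(10, 0, 10, 10) <= 1.0  # oracle sane

    def test_identical_composition_is_not_enriched(self):
        uorf = {f"g{i}" for i in range(0, 50, 2)}
        genes = [f"g{i}" for i in range(50)]
        res = uorf_enrichment(genes, genes, uorf)
        assert res["p"] > 0.5

    def test_planted_odds_ratio_detected_across_seeds(self):
        """Odds ratio 4 at n=200 per group is significant in >=90% of seeds."""
        n, hits = 60, 0
        for seed in range(n):
            rng = np.random.default_rng(seed)
            core = [f"c{i}" for i in range(200)]
            genome = [f"g{i}" for i in range(200)]
            uorf = {g for g in core if rng.random() < 0.5}
            uorf |= {g for g in genome if rng.random() < 0.2}  # OR = 4
            if uorf_enrichment(core, genome, uorf)["p"] < 0.05:
                hits += 1
        assert hits / n >= 0.9
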