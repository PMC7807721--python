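"""PWM construction, percentage-of-maximum site scoring, event features."""

import numpy as np
import pytest

from splicecore.genomics import revcomp
from splicecore.splice_features import (BASES, build_pwms, compare_feature,
                                        event_features, gene_min_site_scores,
                                        score_site)
from splicecore.types import AsEvent, GeneModel, GeneModelSet

DONOR_CONSENSUS = "CAGGTAAGT"          # 3 exonic + 6 intronic
ACCEPTOR_CONSENSUS = "T" * 15 + "TTCAGGTT"  # 20 intronic + 3 exonic


def _degenerate_models(n_genes=4):
    """Every intron carries the same donor/acceptor context sequences."""
    models, genome = {}, {}
    for g in range(n_genes):
        # exon1(30) intron(60) exon2(30); donor/acceptor windows planted
        exon1 = "A" * 27 + DONOR_CONSENSUS[:3]
        intron = (DONOR_CONSENSUS[3:] + "C" * (60 - 6 - 20)
                  + ACCEPTOR_CONSENSUS[:20])
        exon2 = ACCEPTOR_CONSENSUS[20:] + "A" * 27
        seq = exon1 + intron + exon2
        chrom = f"chr{g}"
        genome[chrom] = seq
        models[f"G{g}"] = GeneModel(f"G{g}", f"G{g}.1", chrom, "+",
                                    [(1, 30), (91, 120)])
    return GeneModelSet(models, genome)


class TestBuildPwms:
    def test_degenerate_corpus_has_consensus_frequencies(self):
        donor, acceptor = build_pwms(_degenerate_models())
        # 4 sites, pseudocount 1: consensus base frequency (4+1)/(4+4)
        for p, base in enumerate(DONOR_CONSENSUS):
            assert donor.freq[p, BASES.index(base)] == pytest.approx(5 / 8)
        for p, base in enumerate(ACCEPTOR_CONSENSUS):
            assert acceptor.freq[p, BASES.index(base)] == pytest.approx(5 / 8)

    def test_frequencies_sum_to_one(self, bank):
        models, *_ = bank
        for pwm in build_pwms(models):
            assert np.allclose(pwm.freq.sum(axis=1), 1.0)

    def test_hand_tallied_three_site_fixture(self):
        models, genome = {}, {}
        donors = ["CAGGTAAGT", "AAGGTAAGT", "CAGGTCAGT"]
        for i, d in enumerate(donors):
            exon1 = "C" * 27 + d[:3]
            intron = d[3:] + "T" * 30 + "T" * 18 + "AG"
            exon2 = "GTT" + "C" * 27
            chrom = f"c{i}"
            genome[chrom] = exon1 + intron + exon2
            models[f"G{i}"] = GeneModel(f"G{i}", f"G{i}.1", chrom, "+",
                                        [(1, 30), (87, 116)])
        mset = GeneModelSet(models, genome)
        donor, _ = build_pwms(mset)
        # position 0: C,A,C observed -> freq(C) = (2+1)/(3+4), freq(A) = (1+1)/7
        assert donor.freq[0, BASES.index("C")] == pytest.approx(3 / 7)
        assert donor.freq[0, BASES.index("A")] == pytest.approx(2 / 7)
        assert donor.freq[0, BASES.index("G")] == pytest.approx(1 / 7)

    def test_minus_strand_sites_reverse_complemented(self):
        plus = _degenerate_models(2)
        minus_models, minus_genome = {}, {}
        for g, m in plus.models.items():
            seq = plus.genome[m.chrom]
            minus_genome[m.chrom] = revcomp(seq)
            L = len(seq)
            exons = sorted((L - e + 1, L - s + 1) for s, e in m.exons)
            minus_models[g] = GeneModel(g, m.transcript_id, m.chrom, "-", exons)
        d_plus, a_plus = build_pwms(plus)
        d_minus, a_minus = build_pwms(GeneModelSet(minus_models, minus_genome))
        assert np.allclose(d_plus.freq, d_minus.freq)
        assert np.allclose(a_plus.freq, a_minus.freq)

    def test_no_introns_rejected(self):
        m = GeneModel("G", "G.1", "c", "+", [(1, 30)])
        with pytest.raises(ValueError):
            build_pwms(GeneModelSet({"G": m}, {"c": "A" * 40}))


class TestScoreSite:
    @pytest.fixture()
    def pwms(self, bank):
        models, *_ = bank
        return build_pwms(models)

    def test_consensus_window_scores_100(self, pwms):
        for pwm in pwms:
            consensus = "".join(BASES[i] for i in pwm.freq.argmax(axis=1))
            assert score_site(consensus, pwm) == pytest.approx(100.0)

    def test_random_windows_match_formula(self, pwms):
        rng = np.random.default_rng(0)
        for pwm in pwms:
            denom = pwm.freq.max(axis=1).sum()
            for _ in range(200):
                win = "".join(rng.choice(list(BASES), pwm.window))
                expected = 100 * sum(pwm.freq[p, BASES.index(b)]
                                     for p, b in enumerate(win)) / denom
                assert score_site(win, pwm) == pytest.approx(expected)

    def test_non_acgt_contributes_zero(self, pwms):
        donor = pwms[0]
        consensus = "".join(BASES[i] for i in donor.freq.argmax(axis=1))
        masked = "N" + consensus[1:]
        assert score_site(masked, donor) < 100.0

    def test_monotone_under_base_improvement(self, pwms):
        rng = np.random.default_rng(1)
        donor = pwms[0]
        for _ in range(50):
            win = list("".join(rng.choice(list(BASES), donor.window)))
            p = int(rng.integers(donor.window))
            best = BASES[int(donor.freq[p].argmax())]
            improved = win.copy()
            improved[p] = best
            assert score_site("".join(improved), donor) >= \
                score_site("".join(win), donor) - 1e-12

    def test_length_mismatch_rejected(self, pwms):
        with pytest.raises(ValueError):
            score_site("ACGT", pwms[0])


class TestGeneScoresAndFeatures:
    def test_single_intron_gene_min_is_its_site(self, bank):
        models, *_ = bank
        donor, acceptor = build_pwms(models)
        scores = gene_min_site_scores(models, donor, acceptor)
        single = [m for m in models if len(m.exons) == 2]
        from splicecore.splice_features import gene_site_scores
        for m in single[:5]:
            d, a = gene_site_scores(m, models, donor, acceptor)
            assert scores.at[m.gene_id, "min_donor_score"] == pytest.approx(min(d))
            assert scores.at[m.gene_id, "min_acceptor_score"] == pytest.approx(min(a))

    def test_event_features_ir(self, bank):
        models, events, labels, _ = bank
        eid = next(e for e in events.index
                   if events.at[e, "event_type"] == "IR")
        row = events.loc[eid]
        ev = AsEvent(eid, row["gene_id"], "IR", row["chrom"],
                     int(row["start"]), int(row["end"]), row["strand"])
        feats = event_features(ev, models[ev.gene_id], models)
        assert feats["alt_length"] == ev.length
        assert 0.0 <= feats["gc_alt"] <= 1.0
        assert feats["up_exon_length"] > 0 and feats["down_exon_length"] > 0


class TestCompareFeature:
    def test_planted_shift_detected_across_seeds(self):
        """A 0.5-sd location shift at n=200 is detected in >=90% of seeds."""
        hits, n = 0, 40
        for seed in range(n):
            rng = np.random.default_rng(seed)
            a = rng.normal(0.0, 1.0, 200)
            b = rng.normal(0.5, 1.0, 200)
            if compare_feature(a, b)["p"] < 0.05:
                hits += 1
        assert hits / n >= 0.9

    def test_identical_distributions_not_significant_on_average(self):
        rng = np.random.default_rng(3)
        ps = [compare_feature(rng.normal(size=80), rng.normal(size=80))["p"]
              for _ in range(40)]
        assert np.mean(ps) > 0.3
        assert min(ps) >= 0.0 and max(ps) <= 1.0
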