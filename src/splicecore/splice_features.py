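"""Annotation-derived splice-site strength (PWMs) and basic event features.

Position frequency matrices are tallied over every annotated splice site of
the reference gene models: donors over 3 exonic + 6 intronic nt (9
positions) and acceptors over 20 intronic + 3 exonic nt (23 positions),
with minus-strand sites reverse-complemented into transcript orientation
and a pseudocount of 1 per base per position.  A site's strength is its
percentage-of-maximum PWM similarity:

    score = 100 * sum_p f_p(base_p) / sum_p max_b f_p(b)

so the consensus window scores exactly 100.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .genomics import gc_fraction, revcomp
from .types import AsEvent, GeneModel, GeneModelSet

log = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
DONOR_EXONIC, DONOR_INTRONIC = 3, 6
ACCEPTOR_INTRONIC, ACCEPTOR_EXONIC = 20, 3
PSEUDOCOUNT = 1.0


@dataclass(frozen=True)
class Pwm:
    """Per-position base frequencies over a fixed splice-site window."""

    site_kind: str          # "donor" or "acceptor"
    freq: np.ndarray        # shape (window, 4), rows sum to 1

    def __post_init__(self):
        expected = {"donor": DONOR_EXONIC + DONOR_INTRONIC,
                    "acceptor": ACCEPTOR_INTRONIC + ACCEPTOR_EXONIC}[self.site_kind]
        if self.freq.shape != (expected, 4):
            raise ValueError(f"{self.site_kind} PWM must be {expected} x 4")
        if not np.allclose(self.freq.sum(axis=1), 1.0):
            raise ValueError("per-position frequencies must sum to 1")

    @property
    def window(self) -> int:
        return self.freq.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.freq, columns=list(BASES))


def _site_windows(model: GeneModel, chrom_seq: str):
    """Yield (donor_window, acceptor_window) strings for each intron,
    in transcript orientation; sites too close to contig ends or inside
    too-short introns are skipped (logged)."""
    for g_intron_start, g_intron_end in model.introns:
        ilen = g_intron_end - g_intron_start + 1
        if model.strand == "+":
            d_lo = g_intron_start - DONOR_EXONIC
            d_hi = g_intron_start + DONOR_INTRONIC - 1
            a_lo = g_intron_end - ACCEPTOR_INTRONIC + 1
            a_hi = g_intron_end + ACCEPTOR_EXONIC
        else:
            d_lo = g_intron_end - DONOR_INTRONIC + 1
            d_hi = g_intron_end + DONOR_EXONIC
            a_lo = g_intron_start - ACCEPTOR_EXONIC
            a_hi = g_intron_start + ACCEPTOR_INTRONIC - 1
        donor = acceptor = None
        if ilen >= DONOR_INTRONIC and d_lo >= 1 and d_hi <= len(chrom_seq):
            donor = chrom_seq[d_lo - 1:d_hi]
            if model.strand == "-":
                donor = revcomp(donor)
        else:
            log.debug("%s: donor site skipped (intron %dnt)", model.gene_id, ilen)
        if ilen >= ACCEPTOR_INTRONIC and a_lo >= 1 and a_hi <= len(chrom_seq):
            acceptor = chrom_seq[a_lo - 1:a_hi]
            if model.strand == "-":
                acceptor = revcomp(acceptor)
        else:
            log.debug("%s: acceptor site skipped (intron %dnt)", model.gene_id, ilen)
        yield donor, acceptor


def build_pwms(models: GeneModelSet) -> tuple[Pwm, Pwm]:
    """Tally donor and acceptor PWMs over all annotated internal splice
    sites of the reference models (pseudocount 1 per base per position)."""
    d_counts = np.zeros((DONOR_EXONIC + DONOR_INTRONIC, 4))
    a_counts = np.zeros((ACCEPTOR_INTRONIC + ACCEPTOR_EXONIC, 4))
    n_sites = 0
    for model in models:
        chrom_seq = models.genome[model.chrom]
        for donor, acceptor in _site_windows(model, chrom_seq):
            n_sites += 1
            for win, counts in ((donor, d_counts), (acceptor, a_counts)):
                if win is None:
                    continue
                for p, base in enumerate(win):
                    if base in BASES:
                        counts[p, BASES.index(base)] += 1
    if n_sites == 0:
        raise ValueError("no annotated introns; cannot build PWMs")

    def normalize(counts):
        c = counts + PSEUDOCOUNT
        return c / c.sum(axis=1, keepdims=True)

    return Pwm("donor", normalize(d_counts)), Pwm("acceptor", normalize(a_counts))


def score_site(window: str, pwm: Pwm) -> float:
    """Percentage-of-maximum PWM similarity of one site window, in [0, 100].

    Positions with a non-ACGT base contribute 0 (logged at debug level).
    """
    if len(window) != pwm.window:
        raise ValueError(f"window length {len(window)} != PWM window {pwm.window}")
    num = 0.0
    for p, base in enumerate(window.upper()):
        if base in BASES:
            num += pwm.freq[p, BASES.index(base)]
        else:
            log.debug("non-ACGT base %r at position %d scores 0", base, p)
    return 100.0 * num / pwm.freq.max(axis=1).sum()


def gene_site_scores(model: GeneModel, models: GeneModelSet,
                     donor_pwm: Pwm, acceptor_pwm: Pwm) -> tuple[list, list]:
    chrom_seq = models.genome[model.chrom]
    donors, acceptors = [], []
    for d, a in _site_windows(model, chrom_seq):
        if d is not None:
            donors.append(score_site(d, donor_pwm))
        if a is not None:
            acceptors.append(score_site(a, acceptor_pwm))
    return donors, acceptors


def gene_min_site_scores(models: GeneModelSet, donor_pwm: Pwm,
                         acceptor_pwm: Pwm) -> pd.DataFrame:
    """Per-gene minimum donor and acceptor scores (the weakest site of each
    gene, the quantity compared between core sets).  Intron-less genes are
    omitted."""
    rows = {}
    for model in models:
        d, a = gene_site_scores(model, models, donor_pwm, acceptor_pwm)
        if d or a:
            rows[model.gene_id] = {"min_donor_score": min(d) if d else np.nan,
                                   "min_acceptor_score": min(a) if a else np.nan}
    return pd.DataFrame.from_dict(rows, orient="index")


def compare_feature(values_a: np.ndarray, values_b: np.ndarray) -> dict:
    """Two-sided Wilcoxon rank-sum comparison of a feature between two sets."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    stat, p = mannwhitneyu(a, b, alternative="two-sided")
    return {"statistic": float(stat), "p": float(p),
            "median_a": float(np.median(a)), "median_b": float(np.median(b)),
            "n_a": len(a), "n_b": len(b)}


def event_features(event: AsEvent, model: GeneModel,
                   models: GeneModelSet) -> dict:
    """Basic genomic features of one event on its reference model.

    Lengths/GC of the alternative sequence and its flanking exons and
    introns (transcript orientation), plus gene-level intron count and gene
    body length.
    """
    chrom_seq = models.genome[model.chrom]
    from .orf_impact import event_isoforms
    if event.event_type == "IR":
        # the retained intron exists in the reference (spliced) structure
        base_exons = list(model.exons)
    else:
        base_exons, _ = event_isoforms(event, model)
    order = base_exons if model.strand == "+" else list(reversed(base_exons))
    introns = [(e1 + 1, s2 - 1)
               for (_, e1), (s2, _) in zip(base_exons, base_exons[1:])]
    introns_order = introns if model.strand == "+" else list(reversed(introns))

    def seq(iv):
        s, e = iv
        sub = chrom_seq[s - 1:e]
        return revcomp(sub) if model.strand == "-" else sub

    feats = {"alt_length": event.length,
             "gc_alt": gc_fraction(seq((event.start, event.end))),
             "n_introns_in_gene": len(model.exons) - 1,
             "gene_body_length": model.span[1] - model.span[0] + 1}
    host_idx = None
    if event.event_type == "IR":
        for i, iv in enumerate(introns_order):
            if iv[0] <= event.start and event.end <= iv[1]:
                host_idx = i
                break
        if host_idx is not None:
            up_ex, down_ex = order[host_idx], order[host_idx + 1]
            feats.update(up_exon_length=up_ex[1] - up_ex[0] + 1,
                         down_exon_length=down_ex[1] - down_ex[0] + 1,
                         gc_up=gc_fraction(seq(up_ex)),
                         gc_down=gc_fraction(seq(down_ex)))
    else:
        for i, iv in enumerate(order):
            if iv[0] <= event.start and event.end <= iv[1]:
                host_idx = i
                break
        if host_idx is not None:
            if host_idx > 0:
                up_in = introns_order[host_idx - 1]
                feats.update(up_intron_length=up_in[1] - up_in[0] + 1,
                             gc_up=gc_fraction(seq(up_in)))
            if host_idx < len(introns_order):
                down_in = introns_order[host_idx]
                feats.update(down_intron_length=down_in[1] - down_in[0] + 1,
                             gc_down=gc_fraction(seq(down_in)))
    return feats
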