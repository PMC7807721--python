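"""Predicted consequence of each AS event on its host transcript's ORF.

Every event is classified into six categories by comparing the two isoforms
it generates (alternative sequence included vs excluded) against the
reference transcript's annotated CDS:

* ``UTR5`` / ``UTR3`` -- alternative sequence entirely in an untranslated
  region; no effect on the protein.
* ``ALT_PROTEIN`` -- both isoforms translate into full-length proteins
  ending at the annotated stop (an in-frame insertion/deletion).
* ``DISRUPT_ON_INCLUSION`` / ``DISRUPT_ON_EXCLUSION`` -- one isoform
  frameshifts the ORF or introduces a premature termination codon (PTC).
* ``UNCERTAIN_CDS`` -- the alternative sequence straddles a CDS boundary or
  both isoforms disrupt the ORF (complex events); excluded from profiles.

NMD is predicted by the 50-nt rule: the PTC must lie more than 50 nt
upstream of the isoform's last exon-exon junction.  ES events that affect
the last junction and escape NMD are called disruptive only when the
truncation removes > 20% of the reference protein or > 300 amino acids;
otherwise they are treated as producing a tolerated alternative protein.

Isoforms whose splice-junction chains both match annotated transcripts of
the gene are accepted as ALT_PROTEIN on annotation evidence, regardless of
the de novo stop/frameshift scan (logged when the two disagree).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy.stats import fisher_exact

from .genomics import (genomic_position, junction_tx_positions, spliced_sequence,
                       translate_from, tx_position)
from .types import AsEvent, GeneModel, GeneModelSet

log = logging.getLogger(__name__)

CATEGORIES = ("UTR5", "UTR3", "ALT_PROTEIN", "DISRUPT_ON_INCLUSION",
              "DISRUPT_ON_EXCLUSION", "UNCERTAIN_CDS")

NMD_RULE_NT = 50
TRUNCATION_FRACTION = 0.20
TRUNCATION_AA = 300


@dataclass(frozen=True)
class OrfImpact:
    category: str
    nmd_predicted: bool = False
    truncation_fraction: float | None = None
    truncated_aa: int | None = None
    introduces_frameshift: bool = False
    introduces_stop: bool = False


# ---------------------------------------------------------------------------
# Isoform construction (interval arithmetic on exon lists)
# ---------------------------------------------------------------------------

def include_region(exons: list[tuple[int, int]], region: tuple[int, int]) -> list[tuple[int, int]]:
    """Exon list with ``region`` exonized (adjacent/overlapping exons merged)."""
    ivs = sorted(exons + [region])
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def exclude_region(exons: list[tuple[int, int]], region: tuple[int, int]) -> list[tuple[int, int]]:
    """Exon list with ``region`` spliced out (exons trimmed/split/removed)."""
    rs, re_ = region
    out = []
    for s, e in exons:
        if e < rs or s > re_:
            out.append((s, e))
            continue
        if s < rs:
            out.append((s, rs - 1))
        if e > re_:
            out.append((re_ + 1, e))
    return out


def event_isoforms(event: AsEvent, model: GeneModel) -> tuple[list, list]:
    """(inclusion exons, exclusion exons) for an event on its reference model."""
    region = (event.start, event.end)
    return include_region(model.exons, region), exclude_region(model.exons, region)


def junction_chain(exons: list[tuple[int, int]]) -> tuple:
    return tuple((e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(exons, exons[1:]))


# ---------------------------------------------------------------------------
# Region location
# ---------------------------------------------------------------------------

def locate_event(event: AsEvent, model: GeneModel) -> str:
    """Position of the alternative sequence relative to the CDS.

    Returns one of ``UTR5``, ``CDS``, ``UTR3``, ``spanning``; strand-aware.
    An event outside the transcript span is an error; a model without CDS
    yields ``spanning`` (classified UNCERTAIN_CDS downstream).
    """
    gs, ge = model.span
    if event.end < gs or event.start > ge:
        raise ValueError(f"{event.event_id}: outside transcript of {model.gene_id}")
    if model.cds_tx is None:
        return "spanning"
    g_start_codon = genomic_position(model.exons, model.strand, model.cds_tx[0])
    g_stop_end = genomic_position(model.exons, model.strand, model.cds_tx[1])
    if model.strand == "+":
        cds_lo, cds_hi = g_start_codon, g_stop_end
        if event.end < cds_lo:
            return "UTR5"
        if event.start > cds_hi:
            return "UTR3"
    else:
        cds_lo, cds_hi = g_stop_end, g_start_codon
        if event.end < cds_lo:
            return "UTR3"
        if event.start > cds_hi:
            return "UTR5"
    if cds_lo <= event.start and event.end <= cds_hi:
        # Fully between start and stop codons (introns included): coding.
        if event.start <= cds_lo + 2 or event.end >= cds_hi - 2:
            return "spanning"  # overlaps the start or stop codon itself
        return "CDS"
    return "spanning"


# ---------------------------------------------------------------------------
# ORF evaluation per isoform
# ---------------------------------------------------------------------------

@dataclass
class _OrfState:
    intact: bool
    premature_stop_tx: int | None      # tx coord of last base of the PTC
    last_junction_tx: int | None
    protein_len: int
    frameshift: bool
    stop_lost: bool


def _evaluate_isoform(exons: list[tuple[int, int]], model: GeneModel,
                      genome: dict[str, str], ref_cds_len: int) -> _OrfState | None:
    """Translate one isoform from the annotated start codon.

    Returns None when the start codon does not survive in the isoform.
    The isoform is intact when the first in-frame stop falls at the
    annotated stop codon's genomic position.
    """
    chrom_seq = genome[model.chrom]
    g_start = genomic_position(model.exons, model.strand, model.cds_tx[0])
    g_stop_end = genomic_position(model.exons, model.strand, model.cds_tx[1])
    t_start = tx_position(exons, model.strand, g_start)
    if t_start is None:
        return None
    seq = spliced_sequence(exons, chrom_seq, model.strand)
    pep, stop_end0 = _translate(seq, t_start - 1)
    junctions = junction_tx_positions(exons, model.strand)
    last_j = junctions[-1] if junctions else None
    if stop_end0 is None:
        return _OrfState(False, None, last_j, len(pep), True, True)
    stop_end_tx = stop_end0 + 1
    g_stop_found = genomic_position(exons, model.strand, stop_end_tx)
    intact = (g_stop_found == g_stop_end)
    frameshift = not intact and _is_frameshift(exons, model, ref_cds_len)
    return _OrfState(intact, None if intact else stop_end_tx, last_j,
                     len(pep), frameshift, False)


def _translate(seq: str, start0: int):
    return translate_from(seq, start0)


def _is_frameshift(exons: list[tuple[int, int]], model: GeneModel,
                   ref_cds_len: int) -> bool:
    """Did this isoform change the CDS length by a non-multiple of 3?"""
    g_start = genomic_position(model.exons, model.strand, model.cds_tx[0])
    g_stop = genomic_position(model.exons, model.strand, model.cds_tx[1])
    t1 = tx_position(exons, model.strand, g_start)
    t2 = tx_position(exons, model.strand, g_stop)
    if t1 is None or t2 is None:
        return True
    return (t2 - t1 + 1 - ref_cds_len) % 3 != 0


def classify_impact(event: AsEvent, models: GeneModelSet) -> OrfImpact:
    """Six-way ORF-impact classification of one event (see module docstring)."""
    if event.gene_id not in models:
        return OrfImpact("UNCERTAIN_CDS")
    model = models[event.gene_id]
    if model.cds_tx is None:
        return OrfImpact("UNCERTAIN_CDS")
    region = locate_event(event, model)
    if region in ("UTR5", "UTR3"):
        return OrfImpact(region)
    if region == "spanning":
        return OrfImpact("UNCERTAIN_CDS")

    inc_exons, exc_exons = event_isoforms(event, model)
    genome = models.genome
    ref_cds_len = model.cds_tx[1] - model.cds_tx[0] + 1
    inc = _evaluate_isoform(inc_exons, model, genome, ref_cds_len)
    exc = _evaluate_isoform(exc_exons, model, genome, ref_cds_len)
    if inc is None or exc is None:
        return OrfImpact("UNCERTAIN_CDS")

    # Annotation evidence: both isoform junction chains match annotated
    # transcripts -> alternative protein isoforms, regardless of the scan.
    chains = set(models.alt_chains.get(event.gene_id, []))
    if chains and junction_chain(inc_exons) in chains \
            and junction_chain(exc_exons) in chains:
        if not (inc.intact and exc.intact):
            log.info("%s: annotated at both states but ORF scan flags a "
                     "disruption; annotation evidence wins", event.event_id)
        return OrfImpact("ALT_PROTEIN")

    if inc.intact and exc.intact:
        return OrfImpact("ALT_PROTEIN")
    if not inc.intact and not exc.intact:
        return OrfImpact("UNCERTAIN_CDS")

    disrupted, disrupted_exons = (inc, inc_exons) if not inc.intact else (exc, exc_exons)
    on_inclusion = not inc.intact

    ref_protein_len = ref_cds_len // 3 - 1  # minus the stop codon
    trunc_aa = max(ref_protein_len - disrupted.protein_len, 0)
    trunc_frac = trunc_aa / ref_protein_len if ref_protein_len else None

    nmd = False
    if disrupted.premature_stop_tx is not None and disrupted.last_junction_tx is not None:
        nmd = (disrupted.last_junction_tx - disrupted.premature_stop_tx) > NMD_RULE_NT

    category = "DISRUPT_ON_INCLUSION" if on_inclusion else "DISRUPT_ON_EXCLUSION"
    if event.event_type == "ES" and not nmd and _affects_last_junction(event, inc_exons):
        if not (trunc_frac is not None
                and (trunc_frac > TRUNCATION_FRACTION or trunc_aa > TRUNCATION_AA)):
            return OrfImpact("ALT_PROTEIN", introduces_frameshift=disrupted.frameshift,
                             introduces_stop=True)
    return OrfImpact(category, nmd_predicted=nmd,
                     truncation_fraction=trunc_frac, truncated_aa=trunc_aa,
                     introduces_frameshift=disrupted.frameshift,
                     introduces_stop=disrupted.premature_stop_tx is not None
                     or disrupted.stop_lost)


def _affects_last_junction(event: AsEvent, inc_exons: list[tuple[int, int]]) -> bool:
    """Does skipping this exon change the isoform's final exon-exon junction?"""
    order = inc_exons if event.strand == "+" else list(reversed(inc_exons))
    for i, (s, e) in enumerate(order):
        if s <= event.start and event.end <= e:
            return i >= len(order) - 2
    return False


# ---------------------------------------------------------------------------
# Set-level profiles and enrichments
# ---------------------------------------------------------------------------

def impact_profile(event_ids: list[str], events_meta: pd.DataFrame,
                   impacts: dict[str, OrfImpact],
                   directions: dict[str, str] | None = None) -> pd.DataFrame:
    """Per-category proportions for a set, optionally split by direction.

    UNCERTAIN_CDS events are excluded from the denominators (mirroring their
    exclusion from the published profiles); proportions sum to 1 per group.
    """
    rows = []
    for eid in event_ids:
        imp = impacts.get(eid)
        if imp is None or imp.category == "UNCERTAIN_CDS":
            continue
        rows.append({"event_id": eid, "category": imp.category,
                     "direction": (directions or {}).get(eid, "all")})
    if not rows:
        return pd.DataFrame(columns=["direction", "category", "proportion", "n"])
    df = pd.DataFrame(rows)
    out = []
    for direction, grp in df.groupby("direction"):
        counts = grp["category"].value_counts()
        for cat in CATEGORIES:
            if cat == "UNCERTAIN_CDS":
                continue
            out.append({"direction": direction, "category": cat,
                        "proportion": counts.get(cat, 0) / len(grp),
                        "n": int(counts.get(cat, 0))})
    return pd.DataFrame(out)


def _one_sided_fisher(k_set: int, n_set: int, k_bg: int, n_bg: int):
    """Enrichment (greater) one-sided Fisher of a feature fraction in a set
    vs the background; returns (odds_ratio, p)."""
    table = [[k_set, n_set - k_set], [k_bg, n_bg - k_bg]]
    odds, p = fisher_exact(table, alternative="greater")
    return odds, p


def utr5_enrichment(core_ids: list[str], genome_ids: list[str],
                    impacts: dict[str, OrfImpact]) -> dict:
    """One-sided Fisher test: 5'-UTR fraction in a core set vs Genome."""
    k_set = sum(1 for e in core_ids if impacts[e].category == "UTR5")
    k_bg = sum(1 for e in genome_ids if impacts[e].category == "UTR5")
    odds, p = _one_sided_fisher(k_set, len(core_ids), k_bg, len(genome_ids))
    return {"k_set": k_set, "n_set": len(core_ids), "k_background": k_bg,
            "n_background": len(genome_ids), "odds_ratio": odds, "p": p}


def uorf_enrichment(core_genes: list[str], genome_genes: list[str],
                    uorf_genes: set[str]) -> dict:
    """One-sided Fisher test: uORF-gene fraction in a core set vs Genome."""
    k_set = sum(1 for g in core_genes if g in uorf_genes)
    k_bg = sum(1 for g in genome_genes if g in uorf_genes)
    odds, p = _one_sided_fisher(k_set, len(core_genes), k_bg, len(genome_genes))
    return {"k_set": k_set, "n_set": len(core_genes), "k_background": k_bg,
            "n_background": len(genome_genes), "odds_ratio": odds, "p": p}
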