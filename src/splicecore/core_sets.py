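"""Regulated core sets and their controls.

Six regulated sets are called: abiotic/biotic/tissue-specific cores at the
splicing (AS) layer and at the transcription (GE) layer, plus two control
groups per AS context:

* **Genome** -- events/genes passing the same coverage and eligibility
  filters as the corresponding core set, with no regulation requirement.
* **AS-NR** -- alternatively spliced but non-regulated events
  (|delta-PSI| < 5 in every evaluable comparison of the context).

Stress cores compare treated vs control within each of five independent
experiments per stress class and require a consistent |delta-PSI| > 15
(AS) or fold change > 2 (GE) in at least two experiments, with opposite-
direction responders flagged ambiguous and excluded.  Tissue cores compare
each tissue against every other tissue with sufficient replicate coverage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coverage_qc import CoverageRule, coverage_mask
from .types import ExpressionTable, PsiTable, SampleDesign

log = logging.getLogger(__name__)

AS_SETS = ("abiotic_AS", "biotic_AS", "tissue_AS")
GE_SETS = ("abiotic_GE", "biotic_GE", "tissue_GE")


@dataclass(frozen=True)
class StressAsParams:
    dpsi_thresh: float = 15.0
    min_experiments: int = 2
    n_experiments: int = 5
    min_alt_use: float = 25.0

    def __post_init__(self):
        if self.min_experiments > self.n_experiments:
            raise ValueError("min_experiments > n_experiments")


@dataclass(frozen=True)
class TissueAsParams:
    min_dpsi: float = 15.0
    global_dpsi: float = 25.0
    min_replicates: int = 2
    min_other_tissues: int = 3


@dataclass(frozen=True)
class GeParams:
    stress_fc: float = 2.0
    min_crpkm: float = 5.0
    min_reads: float = 50.0
    tissue_fc_each: float = 3.0
    tissue_fc_global: float = 5.0
    tissue_min_median: float = 5.0
    epsilon: float = 1.0  # pseudo-cRPKM stabilizing fold changes near zero


@dataclass
class CoreSetCall:
    """Membership record for one event/gene in one regulated set.

    Sign convention: delta-PSI and fold changes are treated - control
    (stress) or target tissue - others (tissue).  ``ambiguous`` records are
    reported for transparency but are not members of the set.
    """

    item_id: str
    set_name: str
    direction: str | None
    target_tissue: str | None = None
    supporting_contrasts: list[tuple[str, float]] = field(default_factory=list)
    ambiguous: bool = False


def members(calls: list[CoreSetCall]) -> set[str]:
    """Item ids of non-ambiguous calls."""
    return {c.item_id for c in calls if not c.ambiguous}


def directions(calls: list[CoreSetCall]) -> dict[str, str]:
    return {c.item_id: c.direction for c in calls if not c.ambiguous}


# ---------------------------------------------------------------------------
# Stress AS core
# ---------------------------------------------------------------------------

def stress_dpsi_matrix(table: PsiTable, design: SampleDesign, stress_class: str,
                       params: StressAsParams = StressAsParams(),
                       rule: CoverageRule = CoverageRule()) -> pd.DataFrame:
    """Events x experiments delta-PSI (treated - control).

    NaN marks experiments where the event is not evaluable: either sample
    below the coverage rule, or (for ALTA/ALTD with a known host exon) host
    exon PSI below ``min_alt_use`` in either sample.
    """
    pairs = design.stress_pairs(stress_class)
    if not pairs:
        raise ValueError(f"stress class {stress_class!r} absent from design")
    mask = coverage_mask(table, rule)
    warned = False
    out = pd.DataFrame(np.nan, index=table.events.index, columns=list(pairs))
    host_ids = table.events["host_exon_id"]
    for exp, (ctl, trt) in pairs.items():
        ok = mask[ctl] & mask[trt]
        alt = table.events["event_type"].isin(["ALTA", "ALTD"])
        for eid in table.events.index[alt & ok]:
            host = host_ids.at[eid]
            if host is None or (isinstance(host, float) and math.isnan(host)):
                continue
            if host not in table.events.index:
                if not warned:
                    log.warning("host exon id not in table; min_ALT_use filter "
                                "skipped for such events")
                    warned = True
                continue
            for s in (ctl, trt):
                hp = table.psi.at[host, s]
                if math.isnan(hp) or hp < params.min_alt_use:
                    ok.at[eid] = False
                    break
        d = table.psi[trt] - table.psi[ctl]
        out[exp] = d.where(ok)
    return out


def _consistent_call(item_id: str, set_name: str, deltas: dict[str, float],
                     thresh: float, min_support: int,
                     down_is_reciprocal: bool = False) -> CoreSetCall | None:
    """Shared same-direction / ambiguity logic for stress AS and GE cores.

    ``deltas`` holds the per-experiment statistic; exceedance is > ``thresh``
    upward and, depending on ``down_is_reciprocal``, < 1/thresh (fold
    changes) or < -thresh (delta-PSI) downward.
    """
    up = {e: v for e, v in deltas.items()
          if not math.isnan(v) and v > thresh}
    lo = (1.0 / thresh) if down_is_reciprocal else -thresh
    down = {e: v for e, v in deltas.items()
            if not math.isnan(v) and v < lo}
    if up and down:
        return CoreSetCall(item_id, set_name, None,
                           supporting_contrasts=sorted(up.items()) + sorted(down.items()),
                           ambiguous=True)
    if len(up) >= min_support:
        return CoreSetCall(item_id, set_name, "up",
                           supporting_contrasts=sorted(up.items()))
    if len(down) >= min_support:
        return CoreSetCall(item_id, set_name, "down",
                           supporting_contrasts=sorted(down.items()))
    return None


def stress_as_core(table: PsiTable, design: SampleDesign, stress_class: str,
                   params: StressAsParams = StressAsParams(),
                   rule: CoverageRule = CoverageRule()) -> list[CoreSetCall]:
    """AS events responding consistently to one stress class.

    Membership: |delta-PSI| > ``dpsi_thresh`` in the same direction in at
    least ``min_experiments`` evaluable experiments, with no evaluable
    experiment exceeding the threshold in the opposite direction (such
    events are reported with ``ambiguous=True``).
    """
    dmat = stress_dpsi_matrix(table, design, stress_class, params, rule)
    set_name = f"{stress_class}_AS"
    calls = []
    for eid, row in dmat.iterrows():
        call = _consistent_call(eid, set_name, row.to_dict(),
                                params.dpsi_thresh, params.min_experiments)
        if call is not None:
            calls.append(call)
    return calls


# ---------------------------------------------------------------------------
# Tissue AS core
# ---------------------------------------------------------------------------

def tissue_mean_psi(table: PsiTable, design: SampleDesign,
                    params: TissueAsParams = TissueAsParams(),
                    rule: CoverageRule = CoverageRule()) -> pd.DataFrame:
    """Events x tissue-types mean PSI over covered replicates.

    NaN marks tissues with fewer than ``min_replicates`` covered replicates
    (the tissue is then not valid for that event).
    """
    mask = coverage_mask(table, rule)
    groups = design.tissue_samples()
    out = pd.DataFrame(np.nan, index=table.events.index, columns=list(groups))
    for tissue, samples in groups.items():
        sub = table.psi[samples].where(mask[samples])
        n = sub.notna().sum(axis=1)
        mean = sub.mean(axis=1)
        out[tissue] = mean.where(n >= params.min_replicates)
    return out


def tissue_as_core(table: PsiTable, design: SampleDesign,
                   params: TissueAsParams = TissueAsParams(),
                   rule: CoverageRule = CoverageRule()) -> list[CoreSetCall]:
    """Tissue-specific AS events (one call per qualifying event x tissue).

    For a target tissue with valid coverage and >= ``min_other_tissues``
    valid unrelated tissues, the event qualifies when the target mean PSI
    differs from EVERY other valid unrelated tissue mean by more than
    ``min_dpsi`` with a single sign, and the difference between the target
    mean and the unweighted mean of the other tissues' means exceeds
    ``global_dpsi``.  Tissues declared related to the target are left out of
    the comparison entirely.
    """
    means = tissue_mean_psi(table, design, params, rule)
    tissues = list(means.columns)
    if len(tissues) < 4:
        raise ValueError("tissue core requires >= 4 tissue types in the design")
    calls = []
    for eid, row in means.iterrows():
        for target in tissues:
            tmean = row[target]
            if math.isnan(tmean):
                continue
            excluded = design.related_to(target)
            others = [t for t in tissues
                      if t != target and t not in excluded and not math.isnan(row[t])]
            if len(others) < params.min_other_tissues:
                continue
            diffs = np.array([tmean - row[t] for t in others])
            if (diffs > params.min_dpsi).all():
                direction = "up"
            elif (diffs < -params.min_dpsi).all():
                direction = "down"
            else:
                continue
            global_d = tmean - float(np.mean([row[t] for t in others]))
            if abs(global_d) > params.global_dpsi:
                calls.append(CoreSetCall(
                    eid, "tissue_AS", direction, target_tissue=target,
                    supporting_contrasts=[(t, float(tmean - row[t])) for t in others]))
    return calls


# ---------------------------------------------------------------------------
# GE cores
# ---------------------------------------------------------------------------

def _ge_eligible(expr: ExpressionTable, design: SampleDesign, stress_class: str,
                 params: GeParams) -> pd.Series:
    """Genes with cRPKM and raw-read floors met in >= 2 samples of >= 2
    experiments of the class."""
    pairs = design.stress_pairs(stress_class)
    ok_exp = []
    for exp, (ctl, trt) in pairs.items():
        cells = ((expr.crpkm[[ctl, trt]] >= params.min_crpkm)
                 & (expr.raw_reads[[ctl, trt]] >= params.min_reads))
        ok_exp.append(cells.sum(axis=1))
    counts = pd.concat(ok_exp, axis=1)
    return ((counts.sum(axis=1) >= 2) & ((counts >= 1).sum(axis=1) >= 2))


def stress_ge_core(expr: ExpressionTable, design: SampleDesign, stress_class: str,
                   params: GeParams = GeParams()) -> list[CoreSetCall]:
    """Genes transcriptionally responding to one stress class.

    Fold change per experiment is (cRPKM_treated + eps) / (cRPKM_control +
    eps); membership mirrors the AS logic with thresholds FC > ``stress_fc``
    (up) or FC < 1/``stress_fc`` (down).
    """
    pairs = design.stress_pairs(stress_class)
    if not pairs:
        raise ValueError(f"stress class {stress_class!r} absent from design")
    eligible = _ge_eligible(expr, design, stress_class, params)
    eps = params.epsilon
    set_name = f"{stress_class}_GE"
    calls = []
    for gene in expr.genes:
        if not eligible.at[gene]:
            continue
        fcs = {exp: (expr.crpkm.at[gene, trt] + eps) / (expr.crpkm.at[gene, ctl] + eps)
               for exp, (ctl, trt) in pairs.items()}
        call = _consistent_call(gene, set_name, fcs, params.stress_fc,
                                2, down_is_reciprocal=True)
        if call is not None:
            calls.append(call)
    return calls


def tissue_median_crpkm(expr: ExpressionTable, design: SampleDesign) -> pd.DataFrame:
    groups = design.tissue_samples()
    return pd.DataFrame({t: expr.crpkm[s].median(axis=1) for t, s in groups.items()})


def tissue_ge_core(expr: ExpressionTable, design: SampleDesign,
                   params: GeParams = GeParams()) -> list[CoreSetCall]:
    """Tissue-specific genes on per-tissue median cRPKM.

    Eligibility: median cRPKM >= ``tissue_min_median`` in >= 1 tissue.
    Membership: fold change >= ``tissue_fc_each`` in the same direction
    against every other tissue and >= ``tissue_fc_global`` against the
    median of the other tissues (epsilon-stabilized ratios).
    """
    med = tissue_median_crpkm(expr, design)
    tissues = list(med.columns)
    eps = params.epsilon
    calls = []
    for gene, row in med.iterrows():
        if row.max() < params.tissue_min_median:
            continue
        for target in tissues:
            others = [t for t in tissues if t != target]
            ratios = np.array([(row[target] + eps) / (row[t] + eps) for t in others])
            global_r = (row[target] + eps) / (float(np.median([row[t] for t in others])) + eps)
            if (ratios >= params.tissue_fc_each).all() and global_r >= params.tissue_fc_global:
                direction = "up"
            elif (ratios <= 1.0 / params.tissue_fc_each).all() \
                    and global_r <= 1.0 / params.tissue_fc_global:
                direction = "down"
            else:
                continue
            calls.append(CoreSetCall(gene, "tissue_GE", direction,
                                     target_tissue=target,
                                     supporting_contrasts=[(t, float(r)) for t, r
                                                           in zip(others, ratios)]))
    return calls


# ---------------------------------------------------------------------------
# Controls
# ---------------------------------------------------------------------------

def genome_background(table: PsiTable, design: SampleDesign, context: str,
                      as_params: StressAsParams = StressAsParams(),
                      tissue_params: TissueAsParams = TissueAsParams(),
                      rule: CoverageRule = CoverageRule()) -> set[str]:
    """Events passing a context's coverage/eligibility filters (no PSI rule).

    Stress contexts: evaluable (both samples covered, ALT-use filter) in at
    least ``min_experiments`` experiments of the class.  Tissue context:
    valid replicate coverage in >= 1 + ``min_other_tissues`` tissue types.
    """
    if context in ("abiotic", "biotic"):
        dmat = stress_dpsi_matrix(table, design, context, as_params, rule)
        n_eval = dmat.notna().sum(axis=1)
        return set(n_eval.index[n_eval >= as_params.min_experiments])
    if context == "tissue":
        means = tissue_mean_psi(table, design, tissue_params, rule)
        n_valid = means.notna().sum(axis=1)
        return set(n_valid.index[n_valid >= 1 + tissue_params.min_other_tissues])
    raise ValueError(f"unknown context {context!r}")


def as_nr_set(table: PsiTable, design: SampleDesign, context: str,
              nr_dpsi: float = 5.0, lo: float = 10.0, hi: float = 90.0,
              as_params: StressAsParams = StressAsParams(),
              tissue_params: TissueAsParams = TissueAsParams(),
              rule: CoverageRule = CoverageRule()) -> set[str]:
    """Alternatively spliced, non-regulated control events for one context.

    Stress contexts: Genome-eligible events with PSI within [lo, hi] in at
    least one covered sample of the class's experiments and |delta-PSI| <
    ``nr_dpsi`` in every evaluable experiment.  Tissue context: Genome-
    eligible events with mean PSI within [lo, hi] in >= 2 valid tissues and
    each valid tissue's mean within ``nr_dpsi`` of the mean of the others.
    """
    genome = genome_background(table, design, context, as_params, tissue_params, rule)
    out = set()
    if context in ("abiotic", "biotic"):
        dmat = stress_dpsi_matrix(table, design, context, as_params, rule)
        mask = coverage_mask(table, rule)
        class_samples = [s for pair in design.stress_pairs(context).values()
                         for s in pair]
        psi_cov = table.psi[class_samples].where(mask[class_samples])
        for eid in genome:
            v = psi_cov.loc[eid].dropna().to_numpy()
            if not ((v >= lo) & (v <= hi)).any():
                continue
            d = dmat.loc[eid].dropna().to_numpy()
            if len(d) and (np.abs(d) < nr_dpsi).all():
                out.add(eid)
        return out
    means = tissue_mean_psi(table, design, tissue_params, rule)
    for eid in genome:
        row = means.loc[eid].dropna()
        n_alt = int(((row >= lo) & (row <= hi)).sum())
        if n_alt < 2:
            continue
        flat = True
        for t in row.index:
            others = row.drop(t)
            if abs(row[t] - others.mean()) >= nr_dpsi:
                flat = False
                break
        if flat:
            out.add(eid)
    return out


def common_controls(genome_sets: dict[str, set], as_nr_sets: dict[str, set],
                    core_sets: dict[str, set]) -> tuple[set, set]:
    """2-of-3 common Genome and common AS-NR sets across contexts.

    An item belongs to a common set when it is in the per-context set for at
    least two of the three contexts; an item in two AS-NR groups that is a
    member of the remaining core set is discarded from the common AS-NR set.
    """
    def two_of_three(sets: dict[str, set]) -> set:
        all_items = set().union(*sets.values()) if sets else set()
        return {x for x in all_items
                if sum(x in s for s in sets.values()) >= 2}

    common_genome = two_of_three(genome_sets)
    in_any_core = set().union(*core_sets.values()) if core_sets else set()
    common_nr = two_of_three(as_nr_sets) - in_any_core
    return common_genome, common_nr


def set_overlaps(sets: dict[str, set], gene_map: dict[str, str] | None = None) -> dict:
    """Pairwise and 3-way intersection cardinalities.

    With ``gene_map`` (item -> gene) the same counts are also reported after
    collapsing items to their host genes.
    """
    names = list(sets)
    out = {"sizes": {n: len(s) for n, s in sets.items()}, "intersections": {}}
    import itertools
    for r in (2, 3):
        for combo in itertools.combinations(names, r):
            inter = set.intersection(*(sets[n] for n in combo))
            out["intersections"]["&".join(combo)] = len(inter)
    if gene_map is not None:
        gsets = {n: {gene_map[x] for x in s if x in gene_map} for n, s in sets.items()}
        out["gene_level"] = set_overlaps(gsets)
    return out
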