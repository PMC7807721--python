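"""Shared builders and independent brute-force oracles for the test suite.

The oracles re-evaluate the calling definitions directly from per-cell
quality records and plain loops, independently of the vectorized
implementation paths they check.
"""

from __future__ import annotations

import math

import pandas as pd
from scipy.stats import binomtest

from splicecore.types import PsiTable, SampleDesign, TIER_RANK


def mk_design(tissues: dict[str, int] | None = None,
              n_experiments: int = 5,
              classes=("abiotic", "biotic"),
              related: list | None = None) -> SampleDesign:
    """Design with ``tissues`` (name -> replicate count) and stress pairs."""
    rows = []
    for t, n in (tissues or {}).items():
        for r in range(1, n + 1):
            rows.append((f"{t}_r{r}", "tissue", t, None, None, t))
    for cls in classes:
        for e in range(1, n_experiments + 1):
            exp = f"{cls}{e}"
            rows.append((f"{exp}_ctl", "stress_control", None, exp, cls, exp))
            rows.append((f"{exp}_trt", "stress_treated", None, exp, cls, exp))
    frame = pd.DataFrame(rows, columns=["sample_id", "role", "tissue_type",
                                        "experiment_id", "stress_class",
                                        "replicate_of"]).set_index("sample_id")
    return SampleDesign(frame, [frozenset(g) for g in (related or [])])


def mk_psi_table(psi: dict[str, dict[str, float]],
                 event_type: dict[str, str] | None = None,
                 tier: dict[str, dict[str, str]] | None = None,
                 ir_reads: dict[str, dict[str, tuple]] | None = None,
                 host: dict[str, str] | None = None,
                 gene: dict[str, str] | None = None,
                 samples: list[str] | None = None) -> PsiTable:
    """Hand-built PsiTable: ``psi[event][sample]`` (NaN -> tier N).

    Counts default to a depth of 100 reads consistent with the PSI; IR
    events get balanced junction reads unless ``ir_reads`` overrides them.
    ``samples`` forces the column set (absent cells are tier N).
    """
    eids = list(psi)
    samples = samples or sorted({s for row in psi.values() for s in row})
    etype = {e: (event_type or {}).get(e, "ES") for e in eids}
    events = pd.DataFrame(
        {"gene_id": [(gene or {}).get(e, f"G_{e}") for e in eids],
         "event_type": [etype[e] for e in eids],
         "chrom": "Chr1", "start": 100, "end": 200, "strand": "+",
         "host_exon_id": [(host or {}).get(e) for e in eids]},
        index=pd.Index(eids, name="event_id"))
    table = PsiTable.empty_like(events, samples)
    for e in eids:
        for s in samples:
            v = psi[e].get(s, math.nan)
            t = (tier or {}).get(e, {}).get(s)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                continue
            inc = round(v)
            table.psi.at[e, s] = float(v)
            table.tier.at[e, s] = t or "OK"
            table.inc.at[e, s] = float(inc)
            table.exc.at[e, s] = float(100 - inc)
            if etype[e] == "IR":
                a, b = (ir_reads or {}).get(e, {}).get(
                    s, (max(inc // 2, 1), max(inc - inc // 2, 1)))
                table.ir_a.at[e, s] = float(a)
                table.ir_b.at[e, s] = float(b)
    table.validate()
    return table


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------

def oracle_is_alternative(values, lo=10.0, hi=90.0, frac=0.10,
                          range_thresh=25.0, min_covered=3) -> bool:
    v = [x for x in values if not math.isnan(x)]
    if len(v) < min_covered:
        return False
    n_mid = sum(1 for x in v if lo <= x <= hi)
    if n_mid >= max(math.ceil(frac * len(v) - 1e-9), 1):
        return True
    return (max(v) - min(v)) >= range_thresh


def oracle_ir_balance_p(a: int, b: int) -> float:
    """Two-sided exact binomial by direct enumeration of point masses."""
    n = a + b
    p_obs = math.comb(n, a) * 0.5 ** n
    return sum(math.comb(n, k) * 0.5 ** n for k in range(n + 1)
               if math.comb(n, k) * 0.5 ** n <= p_obs * (1 + 1e-12))


def oracle_fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher by enumerating the hypergeometric support."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, c1)

    def pmf(x):
        if x < max(0, c1 - r2) or x > min(r1, c1):
            return 0.0
        return math.comb(r1, x) * math.comb(r2, c1 - x) / denom

    p_obs = pmf(a)
    return sum(pmf(x) for x in range(min(r1, c1) + 1)
               if pmf(x) <= p_obs * (1 + 1e-9))


def _cell_passes(table: PsiTable, e: str, s: str, min_tier="VLOW",
                 ir_alpha=0.05) -> bool:
    q = table.quality(e, s)
    if TIER_RANK[q.tier] < TIER_RANK[min_tier]:
        return False
    if table.events.at[e, "event_type"] == "IR":
        if q.ir_junction_reads is None or sum(q.ir_junction_reads) == 0:
            return False
        a, b = q.ir_junction_reads
        return binomtest(a, a + b, 0.5).pvalue > ir_alpha
    return True


def oracle_stress_members(table: PsiTable, design: SampleDesign, cls: str,
                          dpsi=15.0, min_exp=2, min_alt_use=25.0) -> dict[str, str]:
    """event -> direction for the stress core, by direct per-cell loops."""
    out = {}
    pairs = design.stress_pairs(cls)
    for e in table.event_ids:
        up = down = 0
        for ctl, trt in pairs.values():
            if not (_cell_passes(table, e, ctl) and _cell_passes(table, e, trt)):
                continue
            if table.events.at[e, "event_type"] in ("ALTA", "ALTD"):
                h = table.events.at[e, "host_exon_id"]
                if h is not None and h in table.events.index:
                    hv = [table.psi.at[h, s] for s in (ctl, trt)]
                    if any(math.isnan(x) or x < min_alt_use for x in hv):
                        continue
            d = table.psi.at[e, trt] - table.psi.at[e, ctl]
            if d > dpsi:
                up += 1
            elif d < -dpsi:
                down += 1
        if up and down:
            continue
        if up >= min_exp:
            out[e] = "up"
        elif down >= min_exp:
            out[e] = "down"
    return out


def oracle_tissue_members(table: PsiTable, design: SampleDesign,
                          min_dpsi=15.0, global_dpsi=25.0, min_reps=2,
                          min_others=3) -> dict[str, list]:
    """event -> [(tissue, direction)] for the tissue core, by direct loops."""
    groups = design.tissue_samples()
    out: dict[str, list] = {}
    for e in table.event_ids:
        means = {}
        for t, ss in groups.items():
            vals = [table.psi.at[e, s] for s in ss if _cell_passes(table, e, s)]
            if len(vals) >= min_reps:
                means[t] = sum(vals) / len(vals)
        for target, tm in means.items():
            others = {t: m for t, m in means.items()
                      if t != target and t not in design.related_to(target)}
            if len(others) < min_others:
                continue
            diffs = [tm - m for m in others.values()]
            if all(d > min_dpsi for d in diffs):
                direction = "up"
            elif all(d < -min_dpsi for d in diffs):
                direction = "down"
            else:
                continue
            if abs(tm - sum(others.values()) / len(others)) > global_dpsi:
                out.setdefault(e, []).append((target, direction))
    return out


def random_small_table(rng, n_events=8, design: SampleDesign | None = None) -> PsiTable:
    """Random table with NA cells, mixed tiers, and imbalanced IR cells,
    for oracle-equivalence checks."""
    design = design or mk_design(n_experiments=5)
    samples = list(design.frame.index)
    psi, etypes, tiers, ir = {}, {}, {}, {}
    values = [0, 5, 12, 20, 35, 50, 64, 66, 80, 88, 95, 100]
    for i in range(n_events):
        e = f"EV{i}"
        etypes[e] = ["ES", "IR", "ALTA", "ALTD"][i % 4]
        psi[e], tiers[e], ir[e] = {}, {}, {}
        for s in samples:
            if rng.random() < 0.15:
                continue            # tier-N cell
            psi[e][s] = float(rng.choice(values))
            tiers[e][s] = str(rng.choice(["VLOW", "LOW", "OK"]))
            if etypes[e] == "IR":
                if rng.random() < 0.2:
                    ir[e][s] = (30, 0)      # imbalanced: should be filtered
                else:
                    ir[e][s] = (10, 12)
    return mk_psi_table(psi, etypes, tiers, ir, samples=samples)
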