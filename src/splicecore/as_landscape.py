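"""Genome-wide AS prevalence: AS calling, AS-gene percentages, PanAS,
saturation subsampling.

An event is called alternatively spliced when, over samples with sufficient
coverage, either (i) its PSI lies within [lo, hi] (default 10-90) in at
least ``min_frac_samples`` of the covered samples (count rounded up), or
(ii) its PSI range (max - min) reaches ``range_thresh`` (default 25).  At
least ``min_covered_samples`` covered samples (default 3) are required for
an event to be evaluated at all.

PanAS events are those alternatively spliced nearly everywhere: covered in
at least ``min_covered`` samples (default 20) of the tissue/development
panel and within [lo, hi] in strictly more than ``frac`` (default 80%) of
the covered samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coverage_qc import CoverageRule, coverage_mask
from .types import PsiTable


@dataclass(frozen=True)
class AsCallParams:
    lo: float = 10.0
    hi: float = 90.0
    min_frac_samples: float = 0.10
    range_thresh: float = 25.0
    min_covered_samples: int = 3

    def __post_init__(self):
        if not (0 <= self.lo < self.hi <= 100):
            raise ValueError("need 0 <= lo < hi <= 100")
        if not (0 < self.min_frac_samples <= 1):
            raise ValueError("min_frac_samples must be in (0, 1]")


#: Relaxed single-sample definition used for upper-bound AS estimates.
RELAXED_PARAMS = AsCallParams(lo=5.0, hi=95.0, min_frac_samples=1e-9,
                              range_thresh=math.inf, min_covered_samples=1)


@dataclass(frozen=True)
class PanAsParams:
    min_covered: int = 20
    frac: float = 0.80
    lo: float = 10.0
    hi: float = 90.0

    def __post_init__(self):
        if not (0 <= self.lo < self.hi <= 100):
            raise ValueError("need 0 <= lo < hi <= 100")
        if not (0 < self.frac < 1):
            raise ValueError("frac must be in (0, 1)")


def is_alternative(psi_covered: np.ndarray,
                   params: AsCallParams = AsCallParams()) -> bool:
    """Apply the AS definition to one event's covered PSI values.

    ``psi_covered`` must already be restricted to covered cells.  The
    fraction-of-samples count rounds up to a whole sample.
    """
    v = np.asarray(psi_covered, float)
    v = v[~np.isnan(v)]
    n = len(v)
    if n < params.min_covered_samples:
        return False
    n_mid = int(np.sum((v >= params.lo) & (v <= params.hi)))
    need = math.ceil(params.min_frac_samples * n - 1e-9)
    if n_mid >= max(need, 1):
        return True
    return bool(np.ptp(v) >= params.range_thresh) if n else False


def _covered_psi(table: PsiTable, rule: CoverageRule) -> pd.DataFrame:
    mask = coverage_mask(table, rule)
    return table.psi.where(mask)


def alternative_events(table: PsiTable, params: AsCallParams = AsCallParams(),
                       rule: CoverageRule = CoverageRule()) -> list[str]:
    psi = _covered_psi(table, rule)
    return [eid for eid in table.event_ids
            if is_alternative(psi.loc[eid].to_numpy(), params)]


def percent_as_genes(table: PsiTable, params: AsCallParams = AsCallParams(),
                     rule: CoverageRule = CoverageRule()) -> dict:
    """Percent of (evaluable) genes with at least one AS event.

    Denominator: genes with >= 1 event covered in >= ``min_covered_samples``
    samples.  Numerator: genes with >= 1 event passing the AS definition.
    Returns a dict with ``percent``, ``n_as_genes``, ``n_genes`` and a
    per-event-type count of AS events (``by_type``).
    """
    psi = _covered_psi(table, rule)
    n_cov = psi.notna().sum(axis=1)
    eligible = n_cov >= params.min_covered_samples
    genes_eligible = set(table.events.loc[eligible[eligible].index, "gene_id"])
    if not genes_eligible:
        raise ValueError("no gene passes the coverage requirement")
    as_events = [eid for eid in table.event_ids
                 if is_alternative(psi.loc[eid].to_numpy(), params)]
    as_genes = set(table.events.loc[as_events, "gene_id"])
    by_type = table.events.loc[as_events, "event_type"].value_counts().to_dict()
    return {"percent": 100.0 * len(as_genes) / len(genes_eligible),
            "n_as_genes": len(as_genes), "n_genes": len(genes_eligible),
            "as_events": as_events, "by_type": by_type}


def strong_as_genes(table: PsiTable, range_thresh: float = 50.0,
                    rule: CoverageRule = CoverageRule(),
                    min_covered_samples: int = 3) -> set[str]:
    """Genes with >= 1 event of extreme quantitative regulation.

    An event qualifies when its covered-PSI range (largest pairwise delta-PSI
    across samples) reaches ``range_thresh`` (default 50).
    """
    psi = _covered_psi(table, rule)
    out = set()
    for eid in table.event_ids:
        v = psi.loc[eid].dropna().to_numpy()
        if len(v) >= min_covered_samples and np.ptp(v) >= range_thresh:
            out.add(table.events.at[eid, "gene_id"])
    return out


def detect_panas(table: PsiTable, params: PanAsParams = PanAsParams(),
                 rule: CoverageRule = CoverageRule()) -> set[str]:
    """PanAS events on the tissue/development sample panel.

    Requires coverage in >= ``min_covered`` samples and PSI within
    [lo, hi] in strictly more than ``frac`` of the covered samples.
    """
    psi = _covered_psi(table, rule)
    out = set()
    for eid in table.event_ids:
        v = psi.loc[eid].dropna().to_numpy()
        if len(v) < params.min_covered:
            continue
        n_mid = int(np.sum((v >= params.lo) & (v <= params.hi)))
        if n_mid > params.frac * len(v):
            out.add(eid)
    return out


def saturation_curve(table: PsiTable, sizes: list[int], iterations: int = 100,
                     seed: int = 0, params: AsCallParams = AsCallParams(),
                     rule: CoverageRule = CoverageRule()) -> pd.DataFrame:
    """Percent-AS-genes saturation over random sample subsets.

    For each subset size, draws ``iterations`` uniform subsets of samples
    without replacement (seeded) and reports the median and quartiles of the
    percent of AS genes.  The cross-species variant is obtained by passing
    tighter ``params`` bounds (20-80, 30-70) and ``min_covered_samples=5``.
    """
    samples = table.samples
    rng = np.random.default_rng(seed)
    mask = coverage_mask(table, rule)
    psi_cov = table.psi.where(mask)
    rows = []
    for size in sizes:
        if size > len(samples):
            raise ValueError(f"subset size {size} > {len(samples)} samples")
        vals = []
        for _ in range(iterations):
            pick = list(rng.choice(samples, size=size, replace=False))
            sub = psi_cov[pick]
            n_cov = sub.notna().sum(axis=1)
            eligible_genes = set(
                table.events.loc[n_cov[n_cov >= params.min_covered_samples].index,
                                 "gene_id"])
            if not eligible_genes:
                vals.append(np.nan)
                continue
            as_eids = [eid for eid in table.event_ids
                       if is_alternative(sub.loc[eid].to_numpy(), params)]
            as_genes = set(table.events.loc[as_eids, "gene_id"])
            vals.append(100.0 * len(as_genes) / len(eligible_genes))
        arr = np.asarray(vals, float)
        rows.append({"size": size,
                     "median": float(np.nanmedian(arr)),
                     "q1": float(np.nanpercentile(arr, 25)),
                     "q3": float(np.nanpercentile(arr, 75))})
    return pd.DataFrame(rows).set_index("size")
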