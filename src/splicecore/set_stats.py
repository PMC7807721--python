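"""Recurring statistics: Fisher proportion tests, rank-sum distribution
comparisons, and the quadrant-concordance binomial test.

The concordance test asks whether two perturbations (e.g., an abiotic
stress and a splicing-factor mutant) move the same AS events in the same
direction: among event pairs where both |delta-PSI| exceed a threshold,
same-signed pairs (scatterplot quadrants I and III) are counted against a
one-sided binomial null of p = 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest, fisher_exact, mannwhitneyu


@dataclass(frozen=True)
class ContingencyResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_one_sided: float
    p_two_sided: float


@dataclass(frozen=True)
class ConcordanceResult:
    n_concordant: int
    n_total: int
    p: float


def fisher_2x2(a: int, b: int, c: int, d: int,
               sided: str = "two") -> ContingencyResult:
    """Exact Fisher test of the 2x2 table [[a, b], [c, d]].

    Both p-values are always reported; ``sided`` selects which one callers
    treating the result as a single p should read ("two" or "greater").
    """
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    table = [[a, b], [c, d]]
    odds, p2 = fisher_exact(table, alternative="two-sided")
    _, p1 = fisher_exact(table, alternative="greater" if sided != "less" else "less")
    return ContingencyResult(((a, b), (c, d)), float(odds), float(p1), float(p2))


def event_type_shift(core_ids: set[str], background_ids: set[str],
                     event_types: pd.Series) -> dict[str, ContingencyResult]:
    """Per-event-type composition shift of a core set vs a control set.

    For each AS type, tests the 2x2 table (in core / in background) x (this
    type / other types); a low odds ratio for IR, for instance, means IR is
    depleted from the core set relative to the control.
    """
    out = {}
    core_types = event_types.loc[sorted(core_ids)]
    bg_types = event_types.loc[sorted(background_ids)]
    for etype in sorted(event_types.unique()):
        a = int((core_types == etype).sum())
        b = len(core_types) - a
        c = int((bg_types == etype).sum())
        d = len(bg_types) - c
        out[etype] = fisher_2x2(a, b, c, d)
    return out


def fc_distribution_shift(set_genes: list[str], background_genes: list[str],
                          log2_fc: pd.Series) -> dict:
    """Rank-sum comparison of log2 fold changes (e.g., NMD-mutant vs WT)
    between a gene set and a background set."""
    a = log2_fc.reindex(set_genes).dropna().to_numpy()
    b = log2_fc.reindex(background_genes).dropna().to_numpy()
    stat, p = mannwhitneyu(a, b, alternative="two-sided")
    return {"statistic": float(stat), "p": float(p),
            "median_set": float(np.median(a)), "median_background": float(np.median(b)),
            "n_set": len(a), "n_background": len(b)}


def quadrant_concordance(dpsi_pairs: list[tuple[float, float]],
                         thresh: float = 15.0) -> ConcordanceResult:
    """One-sided binomial test of direction concordance between two contrasts.

    Pairs with both |delta-PSI| > ``thresh`` are retained; concordant pairs
    are those with equal signs (quadrants I and III).  The p-value is the
    upper tail of Binomial(n_total, 0.5) at n_concordant.
    """
    kept = [(x, y) for x, y in dpsi_pairs
            if abs(x) > thresh and abs(y) > thresh]
    if not kept:
        raise ValueError("no pairs exceed the threshold in both contrasts")
    n_conc = sum(1 for x, y in kept if (x > 0) == (y > 0))
    p = binomtest(n_conc, len(kept), 0.5, alternative="greater").pvalue
    return ConcordanceResult(n_conc, len(kept), float(p))


def bh_adjust(pvalues: list[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values (optional; raw p by default
    everywhere else, matching per-test reporting)."""
    p = np.asarray(pvalues, float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = n - rank_from_end
        running = min(running, p[idx] * n / rank)
        adj[idx] = running
    return adj.tolist()
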