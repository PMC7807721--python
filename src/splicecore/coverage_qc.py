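"""Per-cell coverage decisions and the IR read-imbalance filter.

A PSI value is usable when its coverage tier reaches a configurable minimum
(default VLOW) and, for intron-retention events, when the reads supporting
the two exon-intron junctions are not significantly imbalanced (two-sided
exact binomial test against p = 0.5; cells with P <= alpha are discarded,
keeping only introns supported at both boundaries).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .types import PsiTable, TIER_RANK


@dataclass(frozen=True)
class CoverageRule:
    """Minimum tier plus IR-imbalance settings for usable PSI cells."""

    min_tier: str = "VLOW"
    require_ir_balance: bool = True
    ir_alpha: float = 0.05

    def __post_init__(self):
        if not 0.0 < self.ir_alpha < 1.0:
            raise ValueError("ir_alpha must be in (0, 1)")
        if self.min_tier not in TIER_RANK:
            raise ValueError(f"unknown tier {self.min_tier!r}")


def ir_balance_p(reads_a: int, reads_b: int) -> float:
    """Two-sided exact binomial p-value for junction-read imbalance.

    Under balanced retention the reads at the 5' exon-intron and 3'
    intron-exon junctions are Binomial(n, 0.5) splits of the total; the
    two-sided p-value sums all outcomes whose point probability does not
    exceed that of the observed split.
    """
    if reads_a < 0 or reads_b < 0:
        raise ValueError("negative read count")
    n = reads_a + reads_b
    if n == 0:
        raise ValueError("ir_balance_p undefined for (0, 0) reads")
    return binomtest(reads_a, n, 0.5, alternative="two-sided").pvalue


def passes_coverage(event_id: str, sample: str, table: PsiTable,
                    rule: CoverageRule = CoverageRule()) -> bool:
    """Is the (event, sample) cell usable under ``rule``?

    Missing cells (tier N) never pass.  IR events additionally require a
    non-significant junction imbalance; IR cells whose junction reads are
    absent or both zero are treated as insufficient coverage.
    """
    tier = table.tier.at[event_id, sample]
    if TIER_RANK[tier] < TIER_RANK[rule.min_tier]:
        return False
    if table.events.at[event_id, "event_type"] == "IR" and rule.require_ir_balance:
        a = table.ir_a.at[event_id, sample]
        b = table.ir_b.at[event_id, sample]
        if math.isnan(a) or math.isnan(b) or (a == 0 and b == 0):
            return False
        return ir_balance_p(int(a), int(b)) > rule.ir_alpha
    return True


def coverage_mask(table: PsiTable, rule: CoverageRule = CoverageRule()) -> pd.DataFrame:
    """Boolean events x samples mask of cells passing ``rule`` (vectorized)."""
    rank = np.vectorize(TIER_RANK.__getitem__)(table.tier.to_numpy(str))
    mask = pd.DataFrame(rank >= TIER_RANK[rule.min_tier],
                        index=table.psi.index, columns=table.psi.columns)
    if rule.require_ir_balance:
        is_ir = (table.events["event_type"] == "IR").to_numpy()
        if is_ir.any():
            a = table.ir_a.to_numpy(float)[is_ir]
            b = table.ir_b.to_numpy(float)[is_ir]
            sub = mask.to_numpy()
            ir_ok = np.zeros_like(a, dtype=bool)
            cache: dict[tuple[int, int], float] = {}
            rows, cols = a.shape
            for i in range(rows):
                for j in range(cols):
                    x, y = a[i, j], b[i, j]
                    if math.isnan(x) or math.isnan(y) or (x == 0 and y == 0):
                        continue
                    key = (int(min(x, y)), int(x + y))
                    if key not in cache:
                        cache[key] = binomtest(key[0], key[1], 0.5).pvalue
                    ir_ok[i, j] = cache[key] > rule.ir_alpha
            sub[is_ir] = sub[is_ir] & ir_ok
            mask = pd.DataFrame(sub, index=mask.index, columns=mask.columns)
    return mask
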