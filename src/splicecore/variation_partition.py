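"""Decompose each event's global PSI variation into tissue vs stress axes.

For each AS event three non-negative components are measured: the PSI range
across tissue types (difference between the highest and lowest per-tissue
median PSI), the largest |delta-PSI| among the abiotic experiments, and the
largest |delta-PSI| among the biotic experiments.  Their sum is the global
PSI variation and each component's share of it (in percent) quantifies the
relative contribution of that regulatory axis.  Events without sufficient
coverage (>= 4 tissue types, >= 4 abiotic and >= 4 biotic experiments with
both samples covered) or with global variation below 10 PSI units are
filtered out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_sets import stress_dpsi_matrix, StressAsParams
from .coverage_qc import CoverageRule, coverage_mask
from .types import PsiTable, SampleDesign


@dataclass(frozen=True)
class VariationPartition:
    event_id: str
    tissue_range: float
    abiotic_max: float
    biotic_max: float

    @property
    def global_variation(self) -> float:
        return self.tissue_range + self.abiotic_max + self.biotic_max

    @property
    def pct_tissue(self) -> float:
        return 100.0 * self.tissue_range / self.global_variation

    @property
    def pct_abiotic(self) -> float:
        return 100.0 * self.abiotic_max / self.global_variation

    @property
    def pct_biotic(self) -> float:
        return 100.0 * self.biotic_max / self.global_variation


def tissue_median_psi(table: PsiTable, design: SampleDesign,
                      rule: CoverageRule = CoverageRule(),
                      min_replicates: int = 1) -> pd.DataFrame:
    """Events x tissue-types median PSI over covered replicates.

    A tissue counts as covered for an event when at least ``min_replicates``
    replicates pass the coverage rule (default 1; pass 2 to re-impose the
    core-set replicate rule).
    """
    mask = coverage_mask(table, rule)
    groups = design.tissue_samples()
    out = pd.DataFrame(np.nan, index=table.events.index, columns=list(groups))
    for tissue, samples in groups.items():
        sub = table.psi[samples].where(mask[samples])
        n = sub.notna().sum(axis=1)
        out[tissue] = sub.median(axis=1).where(n >= min_replicates)
    return out


def partition_variation(table: PsiTable, design: SampleDesign,
                        rule: CoverageRule = CoverageRule(),
                        min_tissues: int = 4, min_experiments: int = 4,
                        min_global: float = 10.0, min_replicates: int = 1,
                        exclude_tissues: list[str] | None = None
                        ) -> list[VariationPartition]:
    """Per-event tissue/abiotic/biotic variation partition (filtered).

    ``exclude_tissues`` removes named tissue types from the tissue-range
    computation (they still do not count toward the tissue-coverage filter).
    """
    classes = design.stress_classes()
    for needed in ("abiotic", "biotic"):
        if needed not in classes:
            raise ValueError(f"design lacks {needed} stress experiments")
    med = tissue_median_psi(table, design, rule, min_replicates)
    if exclude_tissues:
        med = med.drop(columns=[t for t in exclude_tissues if t in med.columns])
    dmat = {cls: stress_dpsi_matrix(table, design, cls, StressAsParams(), rule)
            for cls in ("abiotic", "biotic")}
    out = []
    for eid in table.event_ids:
        meds = med.loc[eid].dropna()
        if len(meds) < min_tissues:
            continue
        d_ab = dmat["abiotic"].loc[eid].dropna()
        d_bi = dmat["biotic"].loc[eid].dropna()
        if len(d_ab) < min_experiments or len(d_bi) < min_experiments:
            continue
        tissue_range = float(meds.max() - meds.min())
        ab = float(d_ab.abs().max())
        bi = float(d_bi.abs().max())
        if tissue_range + ab + bi < min_global:
            continue
        out.append(VariationPartition(eid, tissue_range, ab, bi))
    return out


def partitions_frame(partitions: list[VariationPartition]) -> pd.DataFrame:
    rows = [{"event_id": p.event_id, "tissue_range": p.tissue_range,
             "abiotic_max": p.abiotic_max, "biotic_max": p.biotic_max,
             "global_variation": p.global_variation, "pct_tissue": p.pct_tissue,
             "pct_abiotic": p.pct_abiotic, "pct_biotic": p.pct_biotic}
            for p in partitions]
    return pd.DataFrame(rows, columns=["event_id", "tissue_range", "abiotic_max",
                                       "biotic_max", "global_variation",
                                       "pct_tissue", "pct_abiotic", "pct_biotic"])


def partition_summary(partitions: list[VariationPartition], n_bins: int = 10
                      ) -> dict[str, pd.DataFrame]:
    """Binned counts of pct_tissue vs pct_abiotic and vs pct_biotic.

    Returns two ``n_bins x n_bins`` grids over the percentage simplex; bin
    edges are uniform on [0, 100] with the right edge inclusive.
    """
    edges = np.linspace(0.0, 100.0, n_bins + 1)
    t = np.array([p.pct_tissue for p in partitions])
    out = {}
    for name, other in (("tissue_vs_abiotic", [p.pct_abiotic for p in partitions]),
                        ("tissue_vs_biotic", [p.pct_biotic for p in partitions])):
        grid, _, _ = np.histogram2d(t, np.asarray(other), bins=[edges, edges])
        labels = [f"{edges[i]:.0f}-{edges[i+1]:.0f}" for i in range(n_bins)]
        out[name] = pd.DataFrame(grid.astype(int), index=labels, columns=labels)
    return out
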