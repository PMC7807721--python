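"""Core in-memory containers for the splicing pipeline.

The central objects are :class:`PsiTable` (events x samples PSI matrix with a
per-cell read-support record), :class:`ExpressionTable` (genes x samples cRPKM
and raw mapped-read counts), :class:`SampleDesign` (which sample is which
tissue / stress experiment) and :class:`GeneModel` (one reference transcript
per gene with CDS annotation, used for ORF-impact prediction and splice-site
extraction).

Conventions
-----------
* PSI values live on the 0-100 scale; a missing PSI is NaN and is equivalent
  to coverage tier ``N``.
* Genomic coordinates are 1-based inclusive (GTF convention) everywhere.
* Coverage tiers are ordered ``N < VLOW < LOW < OK < SOK``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Ordered coverage tiers; N means "no usable coverage, PSI undefined".
TIERS = ("N", "VLOW", "LOW", "OK", "SOK")
TIER_RANK = {t: i for i, t in enumerate(TIERS)}

EVENT_TYPES = ("ES", "IR", "ALTA", "ALTD")

#: Minimum summed junction reads for each tier (exclusive upper bound is the
#: next tier's floor).  The tier labels themselves come from the upstream
#: quantifier; these cutoffs are only used when pooling replicates.
TIER_READ_FLOORS = {"VLOW": 5, "LOW": 10, "OK": 20, "SOK": 50}


def tier_from_reads(total_reads: float) -> str:
    """Coverage tier implied by a summed junction read count."""
    if total_reads >= TIER_READ_FLOORS["SOK"]:
        return "SOK"
    if total_reads >= TIER_READ_FLOORS["OK"]:
        return "OK"
    if total_reads >= TIER_READ_FLOORS["LOW"]:
        return "LOW"
    if total_reads >= TIER_READ_FLOORS["VLOW"]:
        return "VLOW"
    return "N"


@dataclass(frozen=True)
class AsEvent:
    """One alternative-splicing event (ES, IR, ALTA or ALTD).

    ``start``/``end`` delimit the alternative sequence itself (the cassette
    exon, the retained intron, or the extension between the two competing
    splice sites), 1-based inclusive.  ``host_exon_id`` optionally names the
    ES-style event on the exon whose splice sites an ALTA/ALTD event varies.
    """

    event_id: str
    gene_id: str
    event_type: str
    chrom: str
    start: int
    end: int
    strand: str
    host_exon_id: str | None = None

    def __post_init__(self):
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if self.start > self.end:
            raise ValueError(f"{self.event_id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.event_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class QualityRecord:
    """Read support behind a single PSI value.

    ``inc_reads``/``exc_reads`` are inclusion/exclusion junction reads.  For
    IR events ``ir_junction_reads`` carries the (5' exon-intron, 3'
    intron-exon) junction read pair used by the read-imbalance filter.
    """

    tier: str
    inc_reads: float = math.nan
    exc_reads: float = math.nan
    ir_junction_reads: tuple[int, int] | None = None
    ir_balance_p: float | None = None

    def __post_init__(self):
        if self.tier not in TIERS:
            raise ValueError(f"unknown tier {self.tier!r}")


class PsiTable:
    """Events x samples PSI matrix plus aligned per-cell quality matrices.

    Parameters
    ----------
    events : pandas.DataFrame
        Indexed by ``event_id`` with columns ``gene_id, event_type, chrom,
        start, end, strand, host_exon_id``.
    psi : pandas.DataFrame
        float matrix in [0, 100]; NaN marks missing cells (tier ``N``).
    tier, inc, exc, ir_a, ir_b : pandas.DataFrame
        Same shape as ``psi``; ``tier`` holds tier labels, the rest hold read
        counts (NaN where not applicable).
    """

    EVENT_COLUMNS = ("gene_id", "event_type", "chrom", "start", "end",
                     "strand", "host_exon_id")

    def __init__(self, events: pd.DataFrame, psi: pd.DataFrame,
                 tier: pd.DataFrame, inc: pd.DataFrame, exc: pd.DataFrame,
                 ir_a: pd.DataFrame, ir_b: pd.DataFrame, validate: bool = True):
        self.events = events
        self.psi = psi
        self.tier = tier
        self.inc = inc
        self.exc = exc
        self.ir_a = ir_a
        self.ir_b = ir_b
        if validate:
            self.validate()

    # -- construction helpers -------------------------------------------------
    @classmethod
    def empty_like(cls, events: pd.DataFrame, samples: list[str]) -> "PsiTable":
        shape = (len(events), len(samples))
        nanf = pd.DataFrame(np.full(shape, np.nan), index=events.index, columns=samples)
        tier = pd.DataFrame("N", index=events.index, columns=samples)
        return cls(events, nanf.copy(), tier, nanf.copy(), nanf.copy(),
                   nanf.copy(), nanf.copy(), validate=False)

    # -- basic accessors ------------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return list(self.psi.columns)

    @property
    def event_ids(self) -> list[str]:
        return list(self.events.index)

    def event(self, event_id: str) -> AsEvent:
        row = self.events.loc[event_id]
        host = row["host_exon_id"]
        return AsEvent(event_id, row["gene_id"], row["event_type"], row["chrom"],
                       int(row["start"]), int(row["end"]), row["strand"],
                       None if (host is None or (isinstance(host, float) and math.isnan(host))) else host)

    def quality(self, event_id: str, sample: str) -> QualityRecord:
        ir = None
        a, b = self.ir_a.at[event_id, sample], self.ir_b.at[event_id, sample]
        if not (math.isnan(a) or math.isnan(b)):
            ir = (int(a), int(b))
        return QualityRecord(self.tier.at[event_id, sample],
                             self.inc.at[event_id, sample],
                             self.exc.at[event_id, sample],
                             ir_junction_reads=ir)

    def subset_samples(self, samples: list[str]) -> "PsiTable":
        return PsiTable(self.events, self.psi[samples], self.tier[samples],
                        self.inc[samples], self.exc[samples],
                        self.ir_a[samples], self.ir_b[samples], validate=False)

    def subset_events(self, event_ids: list[str]) -> "PsiTable":
        return PsiTable(self.events.loc[event_ids], self.psi.loc[event_ids],
                        self.tier.loc[event_ids], self.inc.loc[event_ids],
                        self.exc.loc[event_ids], self.ir_a.loc[event_ids],
                        self.ir_b.loc[event_ids], validate=False)

    # -- validation -----------------------------------------------------------
    def validate(self) -> None:
        if self.events.index.duplicated().any():
            dup = self.events.index[self.events.index.duplicated()][0]
            raise ValueError(f"duplicate event_id {dup!r}")
        for frame in (self.psi, self.tier, self.inc, self.exc, self.ir_a, self.ir_b):
            if frame.shape != self.psi.shape or list(frame.index) != list(self.psi.index):
                raise ValueError("matrix shape/index mismatch")
        if list(self.events.index) != list(self.psi.index):
            raise ValueError("events index does not match matrix index")
        bad_type = set(self.events["event_type"]) - set(EVENT_TYPES)
        if bad_type:
            raise ValueError(f"unknown event types {sorted(bad_type)}")
        if (self.events["start"] > self.events["end"]).any():
            raise ValueError("event with start > end")
        vals = self.psi.to_numpy(float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals, initial=0.0) < 0 or np.nanmax(vals, initial=100.0) > 100:
                raise ValueError("PSI outside [0, 100]")
        missing = self.psi.isna().to_numpy()
        tier_n = (self.tier == "N").to_numpy()
        if (missing != tier_n).any():
            raise ValueError("PSI missing <-> tier N violated")
        non_ir = self.events["event_type"] != "IR"
        if non_ir.any():
            has_ir_reads = (~self.ir_a.loc[non_ir].isna()).to_numpy().any() or \
                           (~self.ir_b.loc[non_ir].isna()).to_numpy().any()
            if has_ir_reads:
                raise ValueError("IR junction reads on a non-IR event")


@dataclass
class ExpressionTable:
    """Genes x samples cRPKM values and raw mapped-read counts."""

    crpkm: pd.DataFrame
    raw_reads: pd.DataFrame

    def __post_init__(self):
        if self.crpkm.shape != self.raw_reads.shape:
            raise ValueError("crpkm/raw_reads shape mismatch")
        if (self.crpkm.to_numpy(float) < 0).any():
            raise ValueError("negative cRPKM")
        if (self.raw_reads.to_numpy(float) < 0).any():
            raise ValueError("negative raw read count")

    @property
    def samples(self) -> list[str]:
        return list(self.crpkm.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.crpkm.index)


STRESS_CLASSES = ("abiotic", "biotic")
ROLES = ("tissue", "stress_control", "stress_treated")


@dataclass
class SampleDesign:
    """Maps samples to tissue types or (experiment, condition) stress pairs.

    ``frame`` is indexed by sample id with columns ``role, tissue_type,
    experiment_id, stress_class, replicate_of``.  ``related_tissues`` lists
    groups of tissue types that the tissue-specificity caller must not treat
    as mutually independent (default: none, all tissues unrelated).
    """

    frame: pd.DataFrame
    related_tissues: list[frozenset] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        bad = set(self.frame["role"]) - set(ROLES)
        if bad:
            raise ValueError(f"unknown roles {sorted(bad)}")
        if self.frame.index.duplicated().any():
            raise ValueError("duplicate sample id in design")
        for cls in self.stress_classes():
            for exp, pair in self.stress_pairs(cls).items():
                if pair[0] is None or pair[1] is None:
                    raise ValueError(f"experiment {exp}: needs one control and one treated sample")

    # -- views ----------------------------------------------------------------
    def tissue_samples(self) -> dict[str, list[str]]:
        """tissue_type -> ordered sample ids with role ``tissue``."""
        sub = self.frame[self.frame["role"] == "tissue"]
        out: dict[str, list[str]] = {}
        for sid, row in sub.iterrows():
            out.setdefault(row["tissue_type"], []).append(sid)
        return out

    def tissue_types(self) -> list[str]:
        return list(self.tissue_samples())

    def stress_classes(self) -> list[str]:
        sub = self.frame[self.frame["role"] != "tissue"]
        seen: list[str] = []
        for cls in sub["stress_class"]:
            if cls not in seen and isinstance(cls, str):
                seen.append(cls)
        return seen

    def stress_pairs(self, stress_class: str) -> dict[str, tuple[str, str]]:
        """experiment_id -> (control sample, treated sample) for one class."""
        sub = self.frame[(self.frame["role"] != "tissue")
                         & (self.frame["stress_class"] == stress_class)]
        pairs: dict[str, list] = {}
        for sid, row in sub.iterrows():
            slot = pairs.setdefault(row["experiment_id"], [None, None])
            slot[0 if row["role"] == "stress_control" else 1] = sid
        return {e: (c, t) for e, (c, t) in pairs.items()}

    def related_to(self, tissue: str) -> set[str]:
        """Tissue types declared related to ``tissue`` (excluding itself)."""
        out: set[str] = set()
        for group in self.related_tissues:
            if tissue in group:
                out |= set(group) - {tissue}
        return out


@dataclass
class GeneModel:
    """One reference transcript of a gene, with CDS in transcript coordinates.

    ``exons`` are genomic (start, end) 1-based inclusive intervals in
    ascending genomic order; transcript order is the reverse on the minus
    strand.  ``cds_tx`` is the (start, end) of the CDS in 1-based transcript
    coordinates (start codon first base .. stop codon last base), or None for
    non-coding models.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_tx: tuple[int, int] | None = None

    def __post_init__(self):
        ex = sorted(self.exons)
        if ex != self.exons:
            raise ValueError(f"{self.gene_id}: exons must be in ascending genomic order")
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        if self.cds_tx is not None:
            s, e = self.cds_tx
            if not (1 <= s <= e <= self.tx_length):
                raise ValueError(f"{self.gene_id}: CDS outside transcript")

    @property
    def tx_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def exons_tx_order(self) -> list[tuple[int, int]]:
        """Exons in 5'->3' transcript order."""
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Introns in ascending genomic order."""
        return [(e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])]

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


class GeneModelSet:
    """Reference gene models plus the genome they live on.

    ``alt_chains`` maps gene_id to the intron (junction) chains of every
    annotated transcript of the gene, used as annotation evidence when
    classifying ORF impact.
    """

    def __init__(self, models: dict[str, GeneModel], genome: dict[str, str],
                 alt_chains: dict[str, list[tuple]] | None = None):
        self.models = models
        self.genome = {c: s.upper() for c, s in genome.items()}
        self.alt_chains = alt_chains or {}
        for m in models.values():
            if m.chrom not in self.genome:
                raise ValueError(f"{m.gene_id}: contig {m.chrom} missing from genome")
            if m.span[1] > len(self.genome[m.chrom]):
                raise ValueError(f"{m.gene_id}: coordinates beyond contig end")

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.models[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.models

    def __iter__(self):
        return iter(self.models.values())

    def __len__(self):
        return len(self.models)
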