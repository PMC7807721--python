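"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emits a complete, internally consistent bundle: a toy genome
(4 chromosomes) with compact multi-exon genes whose CDSs translate stop-free
and whose introns are canonical GT..AG; one AS event per gene, constructed
so that its ORF-impact category (and NMD prediction) is known by design; a
PSI table over a tissue/development panel (six tissue types, the study's
organs) plus five abiotic and five biotic stress experiments (control,
treated); an expression table; the sample-design table; a per-gene
annotation table; and a :class:`GroundTruth` record of every planted set.

Planted regulation groups:

* tissue-specific events -- target tissue mean PSI shifted by
  ``tissue_dpsi`` (default 40) against a flat baseline;
* stress-responsive events -- treated - control shifted by ``stress_dpsi``
  (default 40) in 3-5 of the five experiments of one class;
* PanAS events -- mid-range PSI (40-60) everywhere;
* null events -- a constant baseline drawn from [5, 95].

Observed PSI is drawn from a beta distribution centred on the planted mean
whose concentration is set so that the between-sample sd equals
``psi_noise_sd`` at mean 50 (sd shrinks towards the PSI bounds, keeping
values in range).  Junction read counts are derived consistently from the
stored PSI at a Poisson read depth; coverage tiers derive from the summed
counts, a configurable fraction of cells drop out to tier N, and a fraction
of IR cells receive fully imbalanced junction reads (which the IR filter
should remove).  Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genomics import revcomp
from .io_formats import (write_design, write_expression_table, write_gene_models,
                         write_psi_table)
from .types import (ExpressionTable, GeneModel, GeneModelSet, PsiTable,
                    SampleDesign, tier_from_reads)

# Frame-0-clean 12-mer with stop codons at both shifted reading frames:
# any +-1/+-2 frameshift upstream of it terminates translation within it.
CASSETTE = "ATAACAACTAAC"

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"
SAFE_CODONS = sorted({a + b + c for a in _BASES for b in _BASES for c in _BASES}
                     - _STOPS)

TISSUE_TYPES = ("inflorescence", "leaf", "root", "seed", "silique", "embryo")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; the defaults are the study conditions emulated."""

    seed: int = 0
    tissue_types: tuple = TISSUE_TYPES
    replicates_per_tissue: int = 4
    n_experiments_per_stress: int = 5
    # planted AS sets (counts are events; stress counts are per class)
    n_tissue_as: int = 30
    n_stress_as: int = 30
    n_panas: int = 20
    n_null_events: int = 220
    tissue_dpsi: float = 40.0
    stress_dpsi: float = 40.0
    stress_support: tuple = (3, 5)   # experiments responding, drawn uniformly
    # noise / coverage channels
    psi_noise_sd: float = 3.0
    coverage_dropout_rate: float = 0.05
    ir_imbalance_rate: float = 0.05
    read_depth_mean: float = 50.0
    # expression layer (gene counts per class)
    n_ge_stress: int = 30
    n_ge_tissue: int = 30
    ge_fc: float = 4.0
    tissue_ge_fc: float = 10.0
    n_lowexpr_genes: int = 10
    expr_noise_sd: float = 0.15      # ln-scale multiplicative sd

    def __post_init__(self):
        if not (0 < self.tissue_dpsi < 100 and 0 < self.stress_dpsi < 100):
            raise ValueError("effect sizes must be in (0, 100) PSI units")
        for r in (self.coverage_dropout_rate, self.ir_imbalance_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must be in [0, 1]")


@dataclass
class GroundTruth:
    """Planted memberships, labels and per-event variation components."""

    core_sets: dict[str, dict[str, dict]] = field(default_factory=dict)
    panas: set = field(default_factory=set)
    true_as_events: set = field(default_factory=set)
    orf_category: dict[str, str] = field(default_factory=dict)
    nmd: dict[str, bool] = field(default_factory=dict)
    variation: dict[str, tuple] = field(default_factory=dict)
    null_events: set = field(default_factory=set)
    null_genes: set = field(default_factory=set)
    event_gene: dict[str, str] = field(default_factory=dict)

    def members(self, set_name: str) -> set:
        return set(self.core_sets.get(set_name, {}))

    def to_json(self) -> str:
        enc = {"core_sets": self.core_sets,
               "panas": sorted(self.panas),
               "true_as_events": sorted(self.true_as_events),
               "orf_category": self.orf_category,
               "nmd": self.nmd,
               "variation": {k: list(v) for k, v in self.variation.items()},
               "null_events": sorted(self.null_events),
               "null_genes": sorted(self.null_genes),
               "event_gene": self.event_gene}
        return json.dumps(enc, indent=1, sort_keys=True)


def precision_recall(called: set, truth: set) -> tuple[float, float]:
    tp = len(called & truth)
    precision = tp / len(called) if called else 1.0
    recall = tp / len(truth) if truth else 1.0
    return precision, recall


# ===========================================================================
# Locus construction
# ===========================================================================

def _codons(rng, n: int) -> str:
    return "".join(rng.choice(SAFE_CODONS) for _ in range(n))


def _rand_seq(rng, n: int) -> str:
    return "".join(rng.choice(list(_BASES)) for _ in range(n))


def _mk_cds(rng, total: int, cassette_at: int | None = None) -> str:
    """Stop-free CDS 'ATG'...'TAA' of length ``total`` (multiple of 3);
    optionally overwrite the frameshift-trap cassette at a codon boundary."""
    assert total % 3 == 0 and total >= 18
    body = _codons(rng, total // 3 - 2)
    seq = "ATG" + body + "TAA"
    if cassette_at is not None:
        assert cassette_at % 3 == 0 and 3 <= cassette_at <= total - 15
        seq = seq[:cassette_at] + CASSETTE + seq[cassette_at + len(CASSETTE):]
    assert len(seq) == total
    return seq


def _mk_intron(rng, length: int, stop_at: int | None = None) -> str:
    """Codon-structured canonical intron GTC ... CAG, stop-free in the frame
    of retention except for an optional planted TAA at offset ``stop_at``."""
    assert length % 3 == 0 and length >= 9
    n = length // 3
    cods = ["GTC"] + [rng.choice(SAFE_CODONS) for _ in range(n - 2)] + ["CAG"]
    if stop_at is not None:
        assert stop_at % 3 == 0 and 3 <= stop_at <= length - 6
        cods[stop_at // 3] = "TAA"
    return "".join(cods)


def _rand_intron(rng, length: int) -> str:
    assert length >= 6
    return "GT" + _rand_seq(rng, length - 4) + "AG"


class _Assembler:
    """Accumulates exon/intron segments of one plus-strand gene."""

    def __init__(self):
        self.seq: list[str] = []
        self.pos = 0                     # gene-local 0-based length so far
        self.exons: list[list[int]] = []  # 1-based inclusive
        self._open = False

    def _add(self, seq: str) -> tuple[int, int]:
        start = self.pos + 1
        self.seq.append(seq)
        self.pos += len(seq)
        return start, self.pos

    def exonic(self, seq: str) -> tuple[int, int]:
        iv = self._add(seq)
        if self._open:
            self.exons[-1][1] = iv[1]
        else:
            self.exons.append([iv[0], iv[1]])
            self._open = True
        return iv

    def intron(self, seq: str) -> tuple[int, int]:
        self._open = False
        return self._add(seq)

    def finish(self):
        return "".join(self.seq), [(s, e) for s, e in self.exons]


@dataclass
class _Locus:
    """One built gene with its single planted event (plus-strand local)."""

    seq: str
    exons: list[tuple[int, int]]
    cds_tx: tuple[int, int]
    event_iv: tuple[int, int]
    event_type: str
    category: str
    nmd: bool


def _scaffold(rng, chunks: list[int], intron_specs: list, u5: int = 57,
              u3: int = 60, cassette_at: int | None = None,
              u5_intron: str | None = None) -> tuple[_Assembler, list, list, tuple]:
    """Shared coding-gene scaffold.

    ``chunks`` are CDS chunk lengths, separated by ``intron_specs`` (one
    fewer or equal; each an intron sequence or a callable on rng).  Returns
    the assembler, exon intervals of each CDS chunk, intron intervals, and
    cds_tx.  The first chunk shares its exon with the 5' UTR, the last with
    the 3' UTR.
    """
    total = sum(chunks)
    cds = _mk_cds(rng, total, cassette_at)
    a = _Assembler()
    tx_utr5 = 0
    if u5_intron is not None:
        a.exonic(_rand_seq(rng, u5 // 2))
        a.intron(u5_intron)
        a.exonic(_rand_seq(rng, u5 - u5 // 2))
        tx_utr5 = u5
    else:
        a.exonic(_rand_seq(rng, u5))
        tx_utr5 = u5
    chunk_ivs, intron_ivs = [], []
    off = 0
    for i, ln in enumerate(chunks):
        chunk_ivs.append(a.exonic(cds[off:off + ln]))
        off += ln
        if i < len(intron_specs):
            spec = intron_specs[i]
            seq = spec(rng) if callable(spec) else spec
            intron_ivs.append(a.intron(seq))
    a.exonic(_rand_seq(rng, u3))
    cds_tx = (tx_utr5 + 1, tx_utr5 + total)
    return a, chunk_ivs, intron_ivs, cds_tx


def _first_boundary(offset: int) -> int:
    """First codon-boundary CDS offset at or after ``offset``."""
    return offset + (-offset) % 3


def _build_template(rng, idx: int) -> _Locus:
    """Construct locus template ``idx`` (see the catalogue in the code)."""
    I60 = lambda r: _mk_intron(r, 60)
    I81 = lambda r: _mk_intron(r, 81)
    I90 = lambda r: _mk_intron(r, 90)

    if idx == 0:    # IR event in the 5' UTR
        a, _, _, cds_tx = _scaffold(rng, [120, 120], [I90],
                                    u5_intron=_rand_intron(rng, 81))
        # the UTR intron is the first intron added: recover its interval
        iv = (a.exons[0][1] + 1, a.exons[1][0] - 1)
        return _Locus(*a.finish(), cds_tx, iv, "IR", "UTR5", False)
    if idx == 1:    # ES event in the 5' UTR (cassette UTR exon in reference)
        a = _Assembler()
        a.exonic(_rand_seq(rng, 30))
        a.intron(_rand_intron(rng, 60))
        alt = a.exonic(_rand_seq(rng, 45))
        a.intron(_rand_intron(rng, 66))
        cds = _mk_cds(rng, 240)
        a.exonic(_rand_seq(rng, 27))
        a.exonic(cds)
        a.exonic(_rand_seq(rng, 60))
        cds_tx = (30 + 45 + 27 + 1, 30 + 45 + 27 + 240)
        return _Locus(*a.finish(), cds_tx, alt, "ES", "UTR5", False)
    if idx in (2, 3):   # ALTD / ALTA extension in the 5' UTR
        a = _Assembler()
        e1 = a.exonic(_rand_seq(rng, 39))
        a.intron(_rand_intron(rng, 72))
        e2 = a.exonic(_rand_seq(rng, 27))
        cds = _mk_cds(rng, 240)
        a.exonic(cds)
        a.exonic(_rand_seq(rng, 60))
        cds_tx = (39 + 27 + 1, 39 + 27 + 240)
        if idx == 2:
            iv = (e1[1] - 8, e1[1])     # donor-side extension, last 9 nt
            return _Locus(*a.finish(), cds_tx, iv, "ALTD", "UTR5", False)
        iv = (e2[0], e2[0] + 8)         # acceptor-side extension, first 9 nt
        return _Locus(*a.finish(), cds_tx, iv, "ALTA", "UTR5", False)
    if idx == 4:    # IR event in the 3' UTR
        a = _Assembler()
        a.exonic(_rand_seq(rng, 57))
        cds = _mk_cds(rng, 240)
        a.exonic(cds[:120])
        a.intron(_mk_intron(rng, 90))
        a.exonic(cds[120:])
        a.exonic(_rand_seq(rng, 30))
        iv_start = a.pos + 1
        a.intron(_rand_intron(rng, 75))
        iv = (iv_start, a.pos)
        a.exonic(_rand_seq(rng, 30))
        cds_tx = (58, 57 + 240)
        return _Locus(*a.finish(), cds_tx, iv, "IR", "UTR3", False)
    if idx == 5:    # ES event in the 3' UTR
        a = _Assembler()
        a.exonic(_rand_seq(rng, 57))
        cds = _mk_cds(rng, 240)
        a.exonic(cds)
        a.exonic(_rand_seq(rng, 30))
        a.intron(_rand_intron(rng, 60))
        alt = a.exonic(_rand_seq(rng, 45))
        a.intron(_rand_intron(rng, 66))
        a.exonic(_rand_seq(rng, 30))
        cds_tx = (58, 57 + 240)
        return _Locus(*a.finish(), cds_tx, alt, "ES", "UTR3", False)
    if idx in (6,):     # ES, in-frame 90-nt CDS exon -> alternative protein
        a, chunks, _, cds_tx = _scaffold(rng, [120, 90, 120], [I60, I90])
        return _Locus(*a.finish(), cds_tx, chunks[1], "ES", "ALT_PROTEIN", False)
    if idx == 7:    # IR, in-frame stop-free 81-nt CDS intron -> alt protein
        a, _, introns, cds_tx = _scaffold(rng, [120, 120], [lambda r: _mk_intron(r, 81)])
        return _Locus(*a.finish(), cds_tx, introns[0], "IR", "ALT_PROTEIN", False)
    if idx in (8, 9):   # ALTD / ALTA, in-frame 9-nt extension -> alt protein
        if idx == 8:
            a, chunks, _, cds_tx = _scaffold(rng, [129, 120], [I90])
            iv = (chunks[0][1] - 8, chunks[0][1])
            return _Locus(*a.finish(), cds_tx, iv, "ALTD", "ALT_PROTEIN", False)
        a, chunks, _, cds_tx = _scaffold(rng, [120, 129], [I90])
        iv = (chunks[1][0], chunks[1][0] + 8)
        return _Locus(*a.finish(), cds_tx, iv, "ALTA", "ALT_PROTEIN", False)
    if idx == 10:   # IR, planted in-frame PTC in CDS intron -> disrupt+NMD
        a, _, introns, cds_tx = _scaffold(
            rng, [120, 120, 120],
            [lambda r: _mk_intron(r, 81, stop_at=12), I90])
        return _Locus(*a.finish(), cds_tx, introns[0], "IR",
                      "DISRUPT_ON_INCLUSION", True)
    if idx == 11:   # ES, frameshifting 74-nt exon hidden in an intron
        alt_seq = _codons(rng, 24) + "CA"          # 74 nt, stop-free in frame
        def intron_with_exon(r):
            return _mk_intron(r, 60) + alt_seq + _mk_intron(r, 63)
        a, chunks, introns, cds_tx = _scaffold(
            rng, [120, 120, 120], [intron_with_exon, I90], cassette_at=120)
        iv = (introns[0][0] + 60, introns[0][0] + 60 + 73)
        return _Locus(*a.finish(), cds_tx, iv, "ES", "DISRUPT_ON_INCLUSION", True)
    if idx == 12:   # ALTD, 8-nt donor extension inside the intron -> disrupt
        ext = "GTCAACCA"
        def intron_ext5(r):
            return ext + _mk_intron(r, 60)
        a, _, introns, cds_tx = _scaffold(
            rng, [120, 120, 120], [intron_ext5, I90], cassette_at=120)
        iv = (introns[0][0], introns[0][0] + 7)
        return _Locus(*a.finish(), cds_tx, iv, "ALTD", "DISRUPT_ON_INCLUSION", True)
    if idx == 13:   # ALTA, 8-nt acceptor extension inside the intron
        ext = "CAACCAAG"
        def intron_ext3(r):
            return _mk_intron(r, 60) + ext
        a, _, introns, cds_tx = _scaffold(
            rng, [120, 120, 120], [intron_ext3, I90], cassette_at=120)
        iv = (introns[0][1] - 7, introns[0][1])
        return _Locus(*a.finish(), cds_tx, iv, "ALTA", "DISRUPT_ON_INCLUSION", True)
    if idx == 14:   # ES, 74-nt frameshifting exon IN the reference -> NMD
        a, chunks, _, cds_tx = _scaffold(
            rng, [120, 74, 120, 91], [I60, lambda r: _mk_intron(r, 63), I90],
            cassette_at=_first_boundary(194))
        return _Locus(*a.finish(), cds_tx, chunks[1], "ES",
                      "DISRUPT_ON_EXCLUSION", True)
    if idx == 15:   # ALTD, 8-nt extension IN the reference exon -> disrupt
        a, chunks, _, cds_tx = _scaffold(
            rng, [128, 120, 121], [I60, I90],
            cassette_at=_first_boundary(128))
        iv = (chunks[0][1] - 7, chunks[0][1])
        return _Locus(*a.finish(), cds_tx, iv, "ALTD", "DISRUPT_ON_EXCLUSION", True)
    if idx == 16:   # ES at the last junction, truncation 66% -> disrupt, no NMD
        a, chunks, _, cds_tx = _scaffold(
            rng, [120, 74, 202], [I60, lambda r: _mk_intron(r, 63)],
            cassette_at=_first_boundary(194))
        return _Locus(*a.finish(), cds_tx, chunks[1], "ES",
                      "DISRUPT_ON_EXCLUSION", False)
    if idx == 17:   # ES at the last junction, tolerated ~14% truncation
        a, chunks, _, cds_tx = _scaffold(
            rng, [1200, 74, 127], [I60, lambda r: _mk_intron(r, 63)],
            cassette_at=_first_boundary(1274))
        return _Locus(*a.finish(), cds_tx, chunks[1], "ES", "ALT_PROTEIN", False)
    if idx in (18, 19):     # IR 50-nt-rule boundary: PTC 50 / 51 nt from junction
        b = 32 if idx == 18 else 33
        tail = 121 if idx == 18 else 120
        a, _, introns, cds_tx = _scaffold(
            rng, [120, b, tail],
            [lambda r: _mk_intron(r, 81, stop_at=60), I90])
        return _Locus(*a.finish(), cds_tx, introns[0], "IR",
                      "DISRUPT_ON_INCLUSION", idx == 19)
    if idx == 20:   # ES exon straddling the start codon -> uncertain
        a = _Assembler()
        a.exonic(_rand_seq(rng, 30))
        a.intron(_rand_intron(rng, 60))
        cds = _mk_cds(rng, 240)
        alt_start = a.pos + 1
        a.exonic(_rand_seq(rng, 15))
        a.exonic(cds[:60])
        alt = (alt_start, a.pos)
        a.intron(_mk_intron(rng, 90))
        a.exonic(cds[60:])
        a.exonic(_rand_seq(rng, 60))
        cds_tx = (30 + 15 + 1, 30 + 15 + 240)
        return _Locus(*a.finish(), cds_tx, alt, "ES", "UNCERTAIN_CDS", False)
    if idx == 21:   # ALTD extension in the 3' UTR
        a = _Assembler()
        a.exonic(_rand_seq(rng, 57))
        cds = _mk_cds(rng, 240)
        a.exonic(cds)
        e = a.exonic(_rand_seq(rng, 39))
        a.intron(_rand_intron(rng, 72))
        a.exonic(_rand_seq(rng, 30))
        cds_tx = (58, 57 + 240)
        iv = (e[1] - 8, e[1])
        return _Locus(*a.finish(), cds_tx, iv, "ALTD", "UTR3", False)
    raise ValueError(f"unknown template {idx}")


N_TEMPLATES = 22


def _flip_iv(length: int, iv: tuple[int, int]) -> tuple[int, int]:
    return length - iv[1] + 1, length - iv[0] + 1


def build_locus(rng, idx: int, strand: str) -> _Locus:
    """Template ``idx`` on either strand (minus-strand loci are the exact
    reverse complement, with flipped intervals)."""
    loc = _build_template(rng, idx % N_TEMPLATES)
    if strand == "+":
        return loc
    L = len(loc.seq)
    exons = sorted(_flip_iv(L, iv) for iv in loc.exons)
    return _Locus(revcomp(loc.seq), exons, loc.cds_tx,
                  _flip_iv(L, loc.event_iv), loc.event_type, loc.category, loc.nmd)


_EVENT_PREFIX = {"ES": "EX", "IR": "IN", "ALTD": "AD", "ALTA": "AA"}


def build_locus_bank(n: int, seed: int, gap: int = 200):
    """``n`` single-event genes cycling through the template catalogue on
    alternating strands, packed onto 4 chromosomes.

    Returns (GeneModelSet, events DataFrame, orf labels, nmd flags).
    """
    rng = np.random.default_rng(seed)
    chrom_seqs = {f"Chr{i}": [] for i in range(1, 5)}
    chrom_len = {c: 0 for c in chrom_seqs}
    models, ev_rows, labels, nmd = {}, [], {}, {}
    for i in range(n):
        # alternate strands and, on each pass through the template
        # catalogue, flip the parity so every template occurs on both
        strand = "-" if (i + i // N_TEMPLATES) % 2 else "+"
        loc = build_locus(rng, i, strand)
        chrom = f"Chr{i % 4 + 1}"
        pad = _rand_seq(rng, gap)
        offset = chrom_len[chrom] + gap
        chrom_seqs[chrom] += [pad, loc.seq]
        chrom_len[chrom] = offset + len(loc.seq)
        gid = f"SCG{i:05d}"
        tid = f"{gid}.1"
        exons = [(s + offset, e + offset) for s, e in loc.exons]
        models[gid] = GeneModel(gid, tid, chrom, strand, exons, loc.cds_tx)
        eid = f"Syn{_EVENT_PREFIX[loc.event_type]}{i:05d}"
        ev_rows.append((eid, gid, loc.event_type, chrom,
                        loc.event_iv[0] + offset, loc.event_iv[1] + offset,
                        strand, None))
        labels[eid] = loc.category
        nmd[eid] = loc.nmd
    genome = {c: "".join(parts) for c, parts in chrom_seqs.items()}
    chains = {gid: [tuple((e1 + 1, s2 - 1) for (_, e1), (s2, _)
                          in zip(m.exons, m.exons[1:]))]
              for gid, m in models.items()}
    events = pd.DataFrame([r[1:] for r in ev_rows],
                          index=pd.Index([r[0] for r in ev_rows], name="event_id"),
                          columns=list(PsiTable.EVENT_COLUMNS))
    return GeneModelSet(models, genome, chains), events, labels, nmd


def orf_fixture_bank(seed: int = 0):
    """The full two-strand template catalogue (44 events) with known labels."""
    return build_locus_bank(2 * N_TEMPLATES, seed)


# ===========================================================================
# Full dataset generation
# ===========================================================================

@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    psi: PsiTable
    expression: ExpressionTable
    design: SampleDesign
    models: GeneModelSet
    annotations: pd.DataFrame
    truth: GroundTruth

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {"psi": outdir / "psi.tsv",
                 "expression": outdir / "expression.tsv",
                 "design": outdir / "design.tsv",
                 "gtf": outdir / "annotation.gtf",
                 "fasta": outdir / "genome.fa",
                 "annotations": outdir / "gene_annotations.tsv",
                 "truth": outdir / "ground_truth.json"}
        write_psi_table(self.psi, paths["psi"])
        write_expression_table(self.expression, paths["expression"])
        write_design(self.design, paths["design"])
        write_gene_models(self.models, paths["gtf"], paths["fasta"])
        self.annotations.to_csv(paths["annotations"], sep="\t",
                                float_format="%.3f")
        paths["truth"].write_text(self.truth.to_json())
        return paths


def _make_design(cfg: SyntheticConfig) -> SampleDesign:
    rows = []
    for t in cfg.tissue_types:
        for r in range(1, cfg.replicates_per_tissue + 1):
            rows.append((f"{t}_r{r}", "tissue", t, None, None, t))
    for cls in ("abiotic", "biotic"):
        for e in range(1, cfg.n_experiments_per_stress + 1):
            exp = f"{cls}{e}"
            rows.append((f"{exp}_ctl", "stress_control", None, exp, cls, exp))
            rows.append((f"{exp}_trt", "stress_treated", None, exp, cls, exp))
    frame = pd.DataFrame(rows, columns=["sample_id", "role", "tissue_type",
                                        "experiment_id", "stress_class",
                                        "replicate_of"]).set_index("sample_id")
    return SampleDesign(frame)


def _beta_psi(rng, mean_pct: np.ndarray, sd_pct: float) -> np.ndarray:
    """Beta draws (0-100 scale) around planted means; exact at sd 0."""
    if sd_pct <= 0:
        return mean_pct.copy()
    mu = np.clip(mean_pct / 100.0, 0.005, 0.995)
    s = sd_pct / 100.0
    conc = 0.25 / (s * s) - 1.0          # sd matches at mean 50
    a, b = mu * conc, (1.0 - mu) * conc
    return 100.0 * rng.beta(a, b)


def generate(config: SyntheticConfig = SyntheticConfig()) -> SyntheticDataset:
    """Generate the full synthetic bundle (see module docstring)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    design = _make_design(cfg)
    samples = list(design.frame.index)
    tissue_groups = design.tissue_samples()
    tissues = list(tissue_groups)
    n_events = cfg.n_tissue_as + 2 * cfg.n_stress_as + cfg.n_panas + cfg.n_null_events

    models, events, orf_labels, nmd_flags = build_locus_bank(n_events, cfg.seed + 1)
    eids = list(events.index)
    truth = GroundTruth(orf_category=orf_labels, nmd=nmd_flags,
                        event_gene=events["gene_id"].to_dict())
    truth.core_sets = {name: {} for name in
                       ("abiotic_AS", "biotic_AS", "tissue_AS",
                        "abiotic_GE", "biotic_GE", "tissue_GE")}

    # ---- planted mean PSI matrix -----------------------------------------
    n_s = len(samples)
    col = {s: j for j, s in enumerate(samples)}
    mean = np.empty((n_events, n_s))
    pos = 0

    def assign(n):
        nonlocal pos
        sl = slice(pos, pos + n)
        pos += n
        return sl

    # tissue-specific events
    sl = assign(cfg.n_tissue_as)
    for k, i in enumerate(range(sl.start, sl.stop)):
        direction = "up" if k % 2 == 0 else "down"
        target = tissues[k % len(tissues)]
        base = rng.uniform(20, 55) if direction == "up" else rng.uniform(45, 80)
        mean[i, :] = base
        delta = cfg.tissue_dpsi if direction == "up" else -cfg.tissue_dpsi
        for s in tissue_groups[target]:
            mean[i, col[s]] = base + delta
        truth.core_sets["tissue_AS"][eids[i]] = {"direction": direction,
                                                 "tissue": target}
    # stress-responsive events
    lo_sup, hi_sup = cfg.stress_support
    for cls in ("abiotic", "biotic"):
        pairs = design.stress_pairs(cls)
        exps = list(pairs)
        sl = assign(cfg.n_stress_as)
        for k, i in enumerate(range(sl.start, sl.stop)):
            direction = "up" if k % 2 == 0 else "down"
            base = rng.uniform(45, 55)
            mean[i, :] = base
            n_sup = int(rng.integers(lo_sup, hi_sup + 1))
            chosen = list(rng.choice(exps, size=n_sup, replace=False))
            delta = cfg.stress_dpsi if direction == "up" else -cfg.stress_dpsi
            for exp in chosen:
                mean[i, col[pairs[exp][1]]] = base + delta
            truth.core_sets[f"{cls}_AS"][eids[i]] = {
                "direction": direction, "experiments": sorted(chosen)}
    # PanAS events
    sl = assign(cfg.n_panas)
    mean[sl, :] = rng.uniform(40, 60, size=(cfg.n_panas, 1))
    truth.panas = set(eids[sl])
    # null events
    sl = assign(cfg.n_null_events)
    mean[sl, :] = rng.uniform(5, 95, size=(cfg.n_null_events, 1))
    truth.null_events = set(eids[sl])
    assert pos == n_events

    # planted truth for AS calling and variation partitioning --------------
    tissue_cols = {t: [col[s] for s in ss] for t, ss in tissue_groups.items()}
    for i, eid in enumerate(eids):
        v = mean[i]
        mid = np.sum((v >= 10) & (v <= 90))
        if mid >= np.ceil(0.10 * n_s) or np.ptp(v) >= 25:
            truth.true_as_events.add(eid)
        med = [float(np.median(v[cols])) for cols in tissue_cols.values()]
        t_range = max(med) - min(med)
        comp = {}
        for cls in ("abiotic", "biotic"):
            ds = [abs(v[col[trt]] - v[col[ctl]])
                  for ctl, trt in design.stress_pairs(cls).values()]
            comp[cls] = max(ds)
        truth.variation[eid] = (t_range, comp["abiotic"], comp["biotic"])

    # ---- observed PSI + read counts --------------------------------------
    psi = _beta_psi(rng, mean, cfg.psi_noise_sd)
    depth = rng.poisson(cfg.read_depth_mean, size=psi.shape).astype(float)
    inc = np.rint(psi / 100.0 * depth)
    exc = depth - inc
    tiers = np.vectorize(tier_from_reads)(depth)
    if cfg.coverage_dropout_rate > 0:
        drop = rng.random(psi.shape) < cfg.coverage_dropout_rate
        tiers = np.where(drop, "N", tiers)
    is_ir = (events["event_type"] == "IR").to_numpy()
    ir_a = np.full(psi.shape, np.nan)
    ir_b = np.full(psi.shape, np.nan)
    ir_rows = np.where(is_ir)[0]
    if len(ir_rows):
        a = np.ceil(inc[ir_rows] / 2.0)
        b = inc[ir_rows] - a
        if cfg.ir_imbalance_rate > 0:
            imb = rng.random(a.shape) < cfg.ir_imbalance_rate
            a = np.where(imb, inc[ir_rows], a)
            b = np.where(imb, 0.0, b)
        ir_a[ir_rows] = a
        ir_b[ir_rows] = b
    blank = tiers == "N"
    psi = np.where(blank, np.nan, psi)
    inc = np.where(blank, np.nan, inc)
    exc = np.where(blank, np.nan, exc)
    ir_a = np.where(blank, np.nan, ir_a)
    ir_b = np.where(blank, np.nan, ir_b)

    def frame(arr, dtype=float):
        return pd.DataFrame(arr, index=events.index, columns=samples).astype(dtype)

    table = PsiTable(events, frame(psi), frame(tiers, object), frame(inc),
                     frame(exc), frame(ir_a), frame(ir_b))

    # ---- expression layer -------------------------------------------------
    genes = list(events["gene_id"])
    n_g = len(genes)
    need = 2 * cfg.n_ge_stress + cfg.n_ge_tissue + cfg.n_lowexpr_genes
    null_gene_pool = [truth.event_gene[e] for e in sorted(truth.null_events)]
    if need > len(null_gene_pool):
        raise ValueError("not enough null events to host the planted GE sets; "
                         "increase n_null_events")
    base = rng.uniform(10, 60, size=n_g)
    expr_mean = np.tile(base[:, None], (1, n_s))
    gidx = {g: i for i, g in enumerate(genes)}
    pool = iter(null_gene_pool)
    for cls in ("abiotic", "biotic"):
        pairs = design.stress_pairs(cls)
        exps = list(pairs)
        for k in range(cfg.n_ge_stress):
            g = next(pool)
            i = gidx[g]
            direction = "up" if k % 2 == 0 else "down"
            n_sup = int(rng.integers(lo_sup, hi_sup + 1))
            chosen = list(rng.choice(exps, size=n_sup, replace=False))
            fc = cfg.ge_fc if direction == "up" else 1.0 / cfg.ge_fc
            for exp in chosen:
                expr_mean[i, col[pairs[exp][1]]] = base[i] * fc
            truth.core_sets[f"{cls}_GE"][g] = {"direction": direction,
                                               "experiments": sorted(chosen)}
    for k in range(cfg.n_ge_tissue):
        g = next(pool)
        i = gidx[g]
        direction = "up" if k % 2 == 0 else "down"
        target = tissues[k % len(tissues)]
        b0 = float(rng.uniform(15, 40))
        expr_mean[i, :] = b0
        fc = cfg.tissue_ge_fc if direction == "up" else 1.0 / cfg.tissue_ge_fc
        for s in tissue_groups[target]:
            expr_mean[i, col[s]] = b0 * fc
        truth.core_sets["tissue_GE"][g] = {"direction": direction,
                                           "tissue": target}
    for _ in range(cfg.n_lowexpr_genes):
        g = next(pool)
        expr_mean[gidx[g], :] = 2.0      # below the cRPKM eligibility floor
    planted_ge = set().union(*(truth.core_sets[s] for s in
                               ("abiotic_GE", "biotic_GE", "tissue_GE")))
    truth.null_genes = set(genes) - planted_ge

    if cfg.expr_noise_sd > 0:
        crpkm = expr_mean * np.exp(rng.normal(0.0, cfg.expr_noise_sd,
                                              size=expr_mean.shape))
    else:
        crpkm = expr_mean.copy()
    raw = np.rint(crpkm * 20.0)
    expression = ExpressionTable(
        pd.DataFrame(crpkm, index=pd.Index(genes, name="gene_id"), columns=samples),
        pd.DataFrame(raw, index=pd.Index(genes, name="gene_id"), columns=samples))

    # ---- per-gene annotations ---------------------------------------------
    utr5_stress_genes = {truth.event_gene[e]
                         for s in ("abiotic_AS", "biotic_AS")
                         for e in truth.core_sets[s]
                         if orf_labels.get(e) == "UTR5"}
    ann_rows = []
    for g in genes:
        p_uorf = 0.6 if g in utr5_stress_genes else 0.15
        ann_rows.append({
            "gene_id": g,
            "uorf": int(rng.random() < p_uorf),
            "rbp": int(rng.random() < 0.08),
            "tf": int(rng.random() < 0.08),
            "promoter_length": float(rng.gamma(4.0, 250.0)),
            "n_tfbs": int(rng.poisson(8)),
            "half_life_h": float(rng.lognormal(1.2, 0.5)),
        })
    annotations = pd.DataFrame(ann_rows).set_index("gene_id")

    return SyntheticDataset(cfg, table, expression, design, models,
                            annotations, truth)
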