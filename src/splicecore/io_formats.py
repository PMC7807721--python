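"""Read and write every table and sequence format the pipeline touches.

Tabular dialects (all TSV, ``#`` comment headers, ``NA`` for missing):

* **PSI table** -- one row per AS event; fixed columns ``EVENT GENE TYPE
  CHROM START END STRAND HOST_EXON`` followed by two columns per sample:
  the PSI value and a quality string ``TIER@inc,exc`` (IR events append the
  two intron-boundary junction read counts: ``TIER@inc,exc@irA,irB``).  A
  bare ``N`` marks a cell with no usable coverage.  Real vast-tools
  INCLUSION_LEVELS output uses a more verbose per-sample quality record; a
  thin converter to this dialect is all that is needed to analyse it.
* **Expression table** -- ``GENE`` plus, per sample, a cRPKM column and a
  ``<sample>.READS`` raw mapped-read-count column.
* **Sample design** -- ``SAMPLE ROLE TISSUE_TYPE EXPERIMENT_ID STRESS_CLASS
  REPLICATE_OF``; groups of related tissue types may be declared in
  ``#related_tissues:`` header lines.

Gene models are read from a GTF (with explicit ``gene``/``transcript``
feature lines; CDS features include the stop codon) plus a genome FASTA.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .genomics import spliced_sequence, tx_position
from .types import (EVENT_TYPES, ExpressionTable, GeneModel, GeneModelSet,
                    PsiTable, SampleDesign, TIERS, tier_from_reads, TIER_RANK)

log = logging.getLogger(__name__)

_PSI_FIXED = ["EVENT", "GENE", "TYPE", "CHROM", "START", "END", "STRAND", "HOST_EXON"]


def _fmt(x, pattern="%.2f"):
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    return pattern % x


def _header_comment(kind: str) -> str:
    return f"# splicecore {kind} v{__version__}\n"


# ---------------------------------------------------------------------------
# PSI tables
# ---------------------------------------------------------------------------

def _parse_quality(raw: str, event_id: str, event_type: str):
    """-> (tier, inc, exc, ir_a, ir_b) with NaN for absent fields."""
    parts = raw.split("@")
    tier = parts[0]
    if tier not in TIERS:
        raise ValueError(f"{event_id}: unknown coverage tier {tier!r}")
    inc = exc = ir_a = ir_b = math.nan
    if len(parts) > 1 and parts[1] != "NA,NA":
        inc_s, exc_s = parts[1].split(",")
        inc, exc = float(inc_s), float(exc_s)
        if inc < 0 or exc < 0:
            raise ValueError(f"{event_id}: negative junction read count")
    if len(parts) > 2:
        if event_type != "IR":
            raise ValueError(f"{event_id}: IR junction fields on a {event_type} event")
        a_s, b_s = parts[2].split(",")
        ir_a, ir_b = float(a_s), float(b_s)
    return tier, inc, exc, ir_a, ir_b


def read_psi_table(path: str | Path) -> PsiTable:
    """Parse a PSI table in the dialect described in the module docstring."""
    path = Path(path)
    lines = [l.rstrip("\n") for l in path.read_text().splitlines()
             if l and not l.startswith("#")]
    if not lines:
        raise ValueError(f"{path}: empty PSI table")
    header = lines[0].split("\t")
    if header[:len(_PSI_FIXED)] != _PSI_FIXED:
        raise ValueError(f"{path}: malformed header")
    sample_cols = header[len(_PSI_FIXED):]
    if len(sample_cols) % 2 != 0:
        raise ValueError(f"{path}: odd number of sample columns")
    samples = sample_cols[::2]

    ev_rows, psi_rows, tier_rows, inc_rows, exc_rows, a_rows, b_rows = \
        [], [], [], [], [], [], []
    for line in lines[1:]:
        f = line.split("\t")
        if len(f) != len(header):
            raise ValueError(f"{path}: row with {len(f)} fields, header has {len(header)}")
        eid, gene, etype = f[0], f[1], f[2]
        if etype not in EVENT_TYPES:
            raise ValueError(f"{eid}: unknown event type {etype!r}")
        host = None if f[7] == "NA" else f[7]
        ev_rows.append((eid, gene, etype, f[3], int(f[4]), int(f[5]), f[6], host))
        psis, tiers, incs, excs, iras, irbs = [], [], [], [], [], []
        for i in range(len(samples)):
            psi_s = f[len(_PSI_FIXED) + 2 * i]
            qual_s = f[len(_PSI_FIXED) + 2 * i + 1]
            tier, inc, exc, ira, irb = _parse_quality(qual_s, eid, etype)
            psi = math.nan if psi_s == "NA" else float(psi_s)
            if not math.isnan(psi) and not (0.0 <= psi <= 100.0):
                raise ValueError(f"{eid}: PSI {psi} outside [0, 100]")
            if (tier == "N") != math.isnan(psi):
                raise ValueError(f"{eid}: tier-N / missing-PSI mismatch")
            psis.append(psi); tiers.append(tier); incs.append(inc)
            excs.append(exc); iras.append(ira); irbs.append(irb)
        psi_rows.append(psis); tier_rows.append(tiers); inc_rows.append(incs)
        exc_rows.append(excs); a_rows.append(iras); b_rows.append(irbs)

    idx = pd.Index([r[0] for r in ev_rows], name="event_id")
    events = pd.DataFrame([r[1:] for r in ev_rows], index=idx,
                          columns=list(PsiTable.EVENT_COLUMNS))

    def frame(rows, dtype=float):
        return pd.DataFrame(rows, index=idx, columns=samples).astype(dtype)

    return PsiTable(events, frame(psi_rows), frame(tier_rows, object),
                    frame(inc_rows), frame(exc_rows), frame(a_rows), frame(b_rows))


def write_psi_table(table: PsiTable, path: str | Path) -> None:
    path = Path(path)
    samples = table.samples
    out = [_header_comment("psi-table")]
    head = _PSI_FIXED + [c for s in samples for c in (s, f"{s}.Q")]
    out.append("\t".join(head) + "\n")
    for eid in table.event_ids:
        row = table.events.loc[eid]
        host = row["host_exon_id"]
        host = "NA" if (host is None or (isinstance(host, float) and math.isnan(host))) else host
        fields = [eid, row["gene_id"], row["event_type"], row["chrom"],
                  str(int(row["start"])), str(int(row["end"])), row["strand"], host]
        for s in samples:
            tier = table.tier.at[eid, s]
            psi = table.psi.at[eid, s]
            inc, exc = table.inc.at[eid, s], table.exc.at[eid, s]
            ira, irb = table.ir_a.at[eid, s], table.ir_b.at[eid, s]
            if tier == "N" and math.isnan(inc) and math.isnan(ira):
                qual = "N"
            else:
                counts = ("NA,NA" if math.isnan(inc)
                          else f"{int(inc)},{int(exc)}")
                qual = f"{tier}@{counts}"
                if not math.isnan(ira):
                    qual += f"@{int(ira)},{int(irb)}"
            fields += [_fmt(psi), qual]
        out.append("\t".join(fields) + "\n")
    path.write_text("".join(out))


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------

def read_expression_table(path: str | Path) -> ExpressionTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    samples = [c for c in df.columns if not c.endswith(".READS")]
    crpkm = df[samples].astype(float)
    reads = df[[f"{s}.READS" for s in samples]].astype(float)
    reads.columns = samples
    crpkm.index.name = reads.index.name = "gene_id"
    return ExpressionTable(crpkm, reads)


def write_expression_table(expr: ExpressionTable, path: str | Path) -> None:
    path = Path(path)
    out = [_header_comment("expression-table")]
    samples = expr.samples
    head = ["GENE"] + [c for s in samples for c in (s, f"{s}.READS")]
    out.append("\t".join(head) + "\n")
    for g in expr.genes:
        fields = [g]
        for s in samples:
            fields.append(_fmt(expr.crpkm.at[g, s], "%.3f"))
            fields.append(str(int(expr.raw_reads.at[g, s])))
        out.append("\t".join(fields) + "\n")
    path.write_text("".join(out))


# ---------------------------------------------------------------------------
# Sample design
# ---------------------------------------------------------------------------

_DESIGN_COLS = ["SAMPLE", "ROLE", "TISSUE_TYPE", "EXPERIMENT_ID",
                "STRESS_CLASS", "REPLICATE_OF"]


def read_design(path: str | Path) -> SampleDesign:
    path = Path(path)
    related = []
    rows = []
    header_seen = False
    for line in path.read_text().splitlines():
        if line.startswith("#related_tissues:"):
            group = frozenset(t.strip() for t in line.split(":", 1)[1].split(","))
            related.append(group)
            continue
        if line.startswith("#") or not line.strip():
            continue
        f = line.split("\t")
        if not header_seen:
            if f != _DESIGN_COLS:
                raise ValueError(f"{path}: malformed design header")
            header_seen = True
            continue
        rows.append([None if x == "NA" else x for x in f])
    frame = pd.DataFrame(rows, columns=_DESIGN_COLS)
    frame = frame.set_index("SAMPLE")
    frame.index.name = "sample_id"
    frame.columns = ["role", "tissue_type", "experiment_id", "stress_class",
                     "replicate_of"]
    return SampleDesign(frame, related)


def write_design(design: SampleDesign, path: str | Path) -> None:
    path = Path(path)
    out = [_header_comment("sample-design")]
    for group in design.related_tissues:
        out.append("#related_tissues: " + ",".join(sorted(group)) + "\n")
    out.append("\t".join(_DESIGN_COLS) + "\n")
    for sid, row in design.frame.iterrows():
        fields = [sid] + ["NA" if v is None else str(v) for v in row.tolist()]
        out.append("\t".join(fields) + "\n")
    path.write_text("".join(out))


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Generic per-gene annotation join table (uORF/RBP/TF flags etc.)."""
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)


# ---------------------------------------------------------------------------
# Gene models (GTF + FASTA)
# ---------------------------------------------------------------------------

def read_gene_models(gtf_path: str | Path, fasta_path: str | Path) -> GeneModelSet:
    """Build per-gene reference models from a GTF and a genome FASTA.

    The reference transcript of a gene is its (unique) coding transcript; if
    several transcripts carry a CDS the one with the longest CDS is taken and
    the others contribute annotation evidence (junction chains) only.
    """
    genome = {rec.id: str(rec.seq).upper()
              for rec in SeqIO.parse(str(fasta_path), "fasta")}
    db = gffutils.create_db(str(gtf_path), ":memory:", force=True,
                            keep_order=True, disable_infer_genes=True,
                            disable_infer_transcripts=True)
    models: dict[str, GeneModel] = {}
    alt_chains: dict[str, list[tuple]] = {}
    for gene in db.features_of_type("gene"):
        gid = gene.id
        if gene.seqid not in genome:
            raise ValueError(f"{gid}: transcript references missing contig {gene.seqid}")
        candidates = []
        for tr in db.children(gene, featuretype="transcript", order_by="start"):
            exons = [(e.start, e.end)
                     for e in db.children(tr, featuretype="exon", order_by="start")]
            cds_feats = [(c.start, c.end)
                         for c in db.children(tr, featuretype="CDS", order_by="start")]
            chain = tuple((e1 + 1, s2 - 1)
                          for (_, e1), (s2, _) in zip(exons, exons[1:]))
            alt_chains.setdefault(gid, []).append(chain)
            candidates.append((tr.id, exons, cds_feats))
        if not candidates:
            continue
        coding = [c for c in candidates if c[2]] or candidates
        tid, exons, cds_feats = max(
            coding, key=lambda c: sum(e - s + 1 for s, e in c[2]))
        cds_tx = None
        if cds_feats:
            gmin = min(s for s, _ in cds_feats)
            gmax = max(e for _, e in cds_feats)
            if gene.strand == "+":
                t5, t3 = tx_position(exons, "+", gmin), tx_position(exons, "+", gmax)
            else:
                t5, t3 = tx_position(exons, "-", gmax), tx_position(exons, "-", gmin)
            if t5 is None or t3 is None:
                raise ValueError(f"{gid}: CDS outside exons")
            if (t3 - t5 + 1) % 3 != 0:
                raise ValueError(f"{gid}: CDS length not divisible by 3")
            cds_tx = (t5, t3)
        models[gid] = GeneModel(gid, tid, gene.seqid, gene.strand, exons, cds_tx)
    return GeneModelSet(models, genome, alt_chains)


def write_gene_models(modelset: GeneModelSet, gtf_path: str | Path,
                      fasta_path: str | Path) -> None:
    """Emit models as GTF (gene/transcript/exon/CDS lines) + genome FASTA."""
    lines = []
    for m in sorted(modelset, key=lambda m: (m.chrom, m.span[0])):
        attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
        gs, ge = m.span

        def row(feat, s, e):
            return (f"{m.chrom}\tsplicecore\t{feat}\t{s}\t{e}\t.\t"
                    f"{m.strand}\t.\t{attrs}\n")

        lines.append(row("gene", gs, ge))
        lines.append(row("transcript", gs, ge))
        for s, e in m.exons:
            lines.append(row("exon", s, e))
        if m.cds_tx is not None:
            from .genomics import genomic_position
            g5 = genomic_position(m.exons, m.strand, m.cds_tx[0])
            g3 = genomic_position(m.exons, m.strand, m.cds_tx[1])
            lo, hi = min(g5, g3), max(g5, g3)
            for s, e in m.exons:
                cs, ce = max(s, lo), min(e, hi)
                if cs <= ce:
                    lines.append(row("CDS", cs, ce))
    Path(gtf_path).write_text("".join(lines))
    records = [SeqRecord(Seq(seq), id=chrom, description="")
               for chrom, seq in modelset.genome.items()]
    SeqIO.write(records, str(fasta_path), "fasta")


def spliced_cds(model: GeneModel, genome: dict[str, str]) -> str:
    """Spliced CDS sequence (start codon through stop codon) of a model."""
    if model.cds_tx is None:
        raise ValueError(f"{model.gene_id}: no CDS annotated")
    tx = spliced_sequence(model.exons, genome[model.chrom], model.strand)
    s, e = model.cds_tx
    return tx[s - 1:e]


# ---------------------------------------------------------------------------
# Numerical table operations
# ---------------------------------------------------------------------------

def quantile_normalize(expr: ExpressionTable) -> ExpressionTable:
    """Quantile-normalize cRPKM columns to a common (mean-quantile) distribution.

    After normalization every sample has an identical sorted value vector --
    the mean of the per-sample sorted vectors -- while within-sample ranks
    are preserved (ties get the average of the tied reference quantiles).
    Raw read counts are passed through unchanged.
    """
    vals = expr.crpkm.to_numpy(float)
    if vals.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    if np.isnan(vals).any():
        raise ValueError("missing values not allowed in expression table")
    n = vals.shape[0]
    ref = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    from scipy.stats import rankdata
    for j in range(vals.shape[1]):
        ranks = rankdata(vals[:, j], method="average")
        out[:, j] = np.interp(ranks, np.arange(1, n + 1), ref)
    crpkm = pd.DataFrame(out, index=expr.crpkm.index, columns=expr.crpkm.columns)
    return ExpressionTable(crpkm, expr.raw_reads.copy())


def merge_replicates(table: PsiTable, groups: dict[str, list[str]]) -> PsiTable:
    """Pool replicate samples by summing junction read counts.

    For each group with >= 2 members the pooled inclusion/exclusion (and IR
    junction) read counts are the sums over members, pooled PSI is
    ``100 * inc / (inc + exc)`` recomputed from the summed counts, and the
    pooled coverage tier is re-derived from the summed total.  Cells that are
    tier N in every member pool to N.  A single-member group passes its cell
    through unchanged.  If a covered member lacks read counts the pooled PSI
    falls back to a coverage-tier-weighted mean of member PSIs (logged).
    """
    members_all = [m for ms in groups.values() for m in ms]
    if sorted(members_all) != sorted(table.samples):
        raise ValueError("groups must partition the sample list")
    for name, ms in groups.items():
        if not ms:
            raise ValueError(f"empty replicate group {name!r}")

    idx = table.events.index
    new_samples = list(groups)
    out = PsiTable.empty_like(table.events, new_samples)
    warned = False
    for name, ms in groups.items():
        if len(ms) == 1:
            s = ms[0]
            out.psi[name] = table.psi[s]
            out.tier[name] = table.tier[s]
            out.inc[name] = table.inc[s]
            out.exc[name] = table.exc[s]
            out.ir_a[name] = table.ir_a[s]
            out.ir_b[name] = table.ir_b[s]
            continue
        tiers = table.tier[ms]
        covered = (tiers != "N")
        any_cov = covered.any(axis=1)
        counts_missing = (table.inc[ms].isna() & covered).any(axis=1) & any_cov

        inc = table.inc[ms].fillna(0.0).sum(axis=1)
        exc = table.exc[ms].fillna(0.0).sum(axis=1)
        total = inc + exc
        tier = pd.Series([tier_from_reads(t) for t in total], index=idx)
        tier[~any_cov] = "N"
        psi = pd.Series(np.nan, index=idx)
        ok = (tier != "N") & (total > 0) & ~counts_missing
        psi[ok] = 100.0 * inc[ok] / total[ok]
        tier[~ok & ~counts_missing] = "N"

        if counts_missing.any():
            if not warned:
                log.warning("merge_replicates: read counts absent for some cells; "
                            "falling back to coverage-tier-weighted mean PSI")
                warned = True
            for eid in idx[counts_missing]:
                w, v = [], []
                best = "N"
                for s in ms:
                    t = table.tier.at[eid, s]
                    if t == "N":
                        continue
                    w.append(TIER_RANK[t]); v.append(table.psi.at[eid, s])
                    if TIER_RANK[t] > TIER_RANK[best]:
                        best = t
                psi[eid] = float(np.average(v, weights=w)) if sum(w) else np.nan
                tier[eid] = best if not math.isnan(psi[eid]) else "N"
                inc[eid] = exc[eid] = np.nan

        ira = table.ir_a[ms].sum(axis=1, min_count=1)
        irb = table.ir_b[ms].sum(axis=1, min_count=1)
        blank = tier == "N"
        out.psi[name] = psi.where(~blank, np.nan)
        out.tier[name] = tier
        out.inc[name] = inc.where(any_cov & ~counts_missing, np.nan)
        out.exc[name] = exc.where(any_cov & ~counts_missing, np.nan)
        out.ir_a[name] = ira
        out.ir_b[name] = irb
    out.validate()
    return out
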