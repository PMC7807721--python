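"""Strand-aware sequence and coordinate helpers shared across modules.

All genomic coordinates are 1-based inclusive; transcript ("tx") coordinates
are 1-based positions along the spliced sequence in 5'->3' orientation.
"""

from __future__ import annotations

from Bio.Seq import Seq

STOP_CODONS = ("TAA", "TAG", "TGA")


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def fetch(genome: dict[str, str], chrom: str, start: int, end: int,
          strand: str = "+") -> str:
    """Genomic slice, reverse-complemented on the minus strand."""
    s = genome[chrom][start - 1:end]
    return revcomp(s) if strand == "-" else s


def spliced_sequence(exons: list[tuple[int, int]], chrom_seq: str, strand: str) -> str:
    """Concatenate exon sequences in transcript order.

    ``exons`` are ascending genomic intervals; on the minus strand the exons
    are traversed 3'->5' genomically and each slice reverse-complemented.
    """
    parts = [chrom_seq[s - 1:e] for s, e in exons]
    if strand == "-":
        return "".join(revcomp(p) for p in reversed(parts))
    return "".join(parts)


def tx_position(exons: list[tuple[int, int]], strand: str, gpos: int) -> int | None:
    """Map a genomic position into 1-based transcript coordinates.

    Returns None when ``gpos`` falls in an intron or outside the transcript.
    """
    offset = 0
    order = exons if strand == "+" else list(reversed(exons))
    for s, e in order:
        if s <= gpos <= e:
            return offset + (gpos - s + 1 if strand == "+" else e - gpos + 1)
        offset += e - s + 1
    return None


def genomic_position(exons: list[tuple[int, int]], strand: str, tpos: int) -> int:
    """Inverse of :func:`tx_position` (``tpos`` must be within the transcript)."""
    offset = 0
    order = exons if strand == "+" else list(reversed(exons))
    for s, e in order:
        length = e - s + 1
        if tpos <= offset + length:
            within = tpos - offset
            return s + within - 1 if strand == "+" else e - within + 1
        offset += length
    raise ValueError(f"transcript position {tpos} beyond transcript end")


def junction_tx_positions(exons: list[tuple[int, int]], strand: str) -> list[int]:
    """Transcript coordinate of the last base of each exon but the final one.

    These are the exon-exon junction positions used by the 50-nt NMD rule.
    """
    order = exons if strand == "+" else list(reversed(exons))
    out, offset = [], 0
    for s, e in order[:-1]:
        offset += e - s + 1
        out.append(offset)
    return out


def translate_from(seq: str, start: int) -> tuple[str, int | None]:
    """Translate ``seq`` from 0-based offset ``start`` to the first stop.

    Returns (peptide without stop, 0-based offset of the last base of the
    stop codon) or (peptide, None) when no in-frame stop is reached.
    """
    aa = []
    i = start
    while i + 3 <= len(seq):
        codon = seq[i:i + 3]
        if codon in STOP_CODONS:
            return "".join(aa), i + 2
        aa.append(str(Seq(codon).translate()))
        i += 3
    return "".join(aa), None


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)
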