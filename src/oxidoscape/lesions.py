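"""8-oxoguanine lesion extraction from capture-sequencing alignments.

Lesion-capture protocols report one damaged guanine per read. The extractor
keeps only cleanly aligned full-length reads (CIGAR exactly ``<read_length>M``,
flag exactly 0 or 16, canonical contigs), maps each read to a single
candidate base — the read's 5' alignment column on the top strand for flag 0,
or the rightmost column for flag 16 (read 5' end on the bottom strand) — and
retains the candidate only when the strand-specific reference base is G.
The final G filter removes capture false positives and makes the position
convention self-validating: a systematically wrong offset collapses the
retained fraction toward the genomic G frequency.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Iterator

import pysam

from .genome import Genome, complement

#: default contig whitelist (human autosomes + sex chromosomes)
CANONICAL_CONTIGS = frozenset(
    [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY"]
)


@dataclass(frozen=True)
class LesionRead:
    contig: str
    flag: int
    pos: int  # 1-based leftmost alignment position, as in SAM
    cigar: str
    read_length: int


@dataclass(frozen=True)
class Lesion:
    contig: str
    pos: int  # 0-based
    strand: str  # '+' or '-'
    context: str | None = None  # top-strand trinucleotide

    @property
    def key(self):
        return (self.contig, self.pos, self.strand)


def parse_sam_records(path) -> Iterator[LesionRead]:
    """Stream mapped-field tuples from a SAM file (filters applied later)."""
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            cigar = rec.cigarstring or "*"
            contig = rec.reference_name or "*"
            yield LesionRead(
                contig=contig,
                flag=rec.flag,
                pos=(rec.reference_start + 1) if rec.reference_start is not None and rec.reference_start >= 0 else 0,
                cigar=cigar,
                read_length=rec.query_length or 0,
            )


def reads_to_lesions(
    reads: Iterable[LesionRead],
    genome: Genome,
    read_length: int = 150,
    offset: int = 0,
    canonical_contigs: Iterable[str] | None = None,
) -> tuple[list[Lesion], Counter]:
    """Apply the lesion filters and return (lesions, rejection counts).

    Rejection reasons: ``flag`` (not exactly 0/16), ``cigar`` (not
    ``<read_length>M``), ``contig`` (off the whitelist), ``bounds``
    (candidate outside the contig), ``not_g`` (strand-specific base not G).
    ``retained`` + sum of rejections = records in.
    """
    whitelist = frozenset(canonical_contigs) if canonical_contigs is not None else CANONICAL_CONTIGS
    want_cigar = f"{read_length}M"
    lesions: list[Lesion] = []
    tally: Counter = Counter()
    for r in reads:
        if r.flag not in (0, 16):
            tally["flag"] += 1
            continue
        if r.cigar != want_cigar:
            tally["cigar"] += 1
            continue
        if r.contig not in whitelist:
            tally["contig"] += 1
            continue
        if r.flag == 0:
            pos = (r.pos - 1) + offset
            strand = "+"
        else:
            pos = (r.pos - 1) + read_length - 1 - offset
            strand = "-"
        if r.contig not in genome or not (0 <= pos < genome.length(r.contig)):
            tally["bounds"] += 1
            continue
        base = genome.base(r.contig, pos)
        if (strand == "+" and base != "G") or (strand == "-" and base != "C"):
            tally["not_g"] += 1
            continue
        lesions.append(Lesion(r.contig, pos, strand, genome.trinucleotide(r.contig, pos)))
        tally["retained"] += 1
    lesions.sort(key=lambda l: l.key)
    return lesions, tally


def extract_lesions(sam_path, genome: Genome, **kwargs) -> tuple[list[Lesion], Counter]:
    return reads_to_lesions(parse_sam_records(sam_path), genome, **kwargs)


def write_lesions(lesions: Iterable[Lesion], path, fmt: str = "bed", genome: Genome | None = None) -> None:
    """Write lesions as BED6, or as a minimal VCF so downstream profiling
    accepts lesions and mutations through the same readers."""
    if fmt == "bed":
        with open(path, "w") as fh:
            for l in lesions:
                fh.write(f"{l.contig}\t{l.pos}\t{l.pos + 1}\t.\t0\t{l.strand}\n")
    elif fmt == "vcf":
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            if genome is not None:
                for name in genome.names:
                    fh.write(f"##contig=<ID={name},length={genome.length(name)}>\n")
            fh.write('##INFO=<ID=STRAND,Number=1,Type=String,Description="Lesion strand">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for l in lesions:
                ref = "G" if l.strand == "+" else "C"
                fh.write(f"{l.contig}\t{l.pos + 1}\t.\t{ref}\t.\t.\t.\tSTRAND={l.strand}\n")
    else:
        raise ValueError(f"unknown lesion output format: {fmt}")


def read_lesions_bed(path, genome: Genome | None = None) -> list[Lesion]:
    lesions = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            contig, start, strand = parts[0], int(parts[1]), parts[5]
            ctx = genome.trinucleotide(contig, start) if genome is not None else None
            lesions.append(Lesion(contig, start, strand, ctx))
    return lesions


def lesion_event_strand_context(lesion: Lesion) -> str | None:
    """Trinucleotide read on the lesion's own strand (G-centered)."""
    if lesion.context is None:
        return None
    if lesion.strand == "+":
        return lesion.context
    return "".join(complement(b) for b in reversed(lesion.context))
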