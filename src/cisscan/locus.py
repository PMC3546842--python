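"""Gene locus model and coordinate frame.

Reads sequence (FASTA) and annotation (BED12 or GFF3), defines the analysis
window (gene span plus flanking DNA) and provides the coordinate services used
by every downstream stage: transcription-start-site (TSS) relative offsets and
exon/intron/upstream region labels.

Conventions
-----------
Internal coordinates are 1-based inclusive; BED is consumed and emitted as
0-based half-open.  TSS offsets are signed base pairs with 0 at the TSS and
negative values 5' (upstream) of the gene in its reading direction, so a site
31,000 bp upstream reports -31000 and formats as ``-31 kb``.  Exons and
introns are numbered strand-aware: intron k lies immediately 3' of exon k in
the gene's reading direction, whichever genomic strand the gene is on.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from Bio import SeqIO

from .errors import (
    DuplicateSequenceIdError,
    EmptyFastaError,
    ExonLayoutError,
    GeneCountError,
    InvalidSequenceError,
    StrandMissingError,
    WindowOutsideSequenceError,
)

#: IUPAC nucleotide alphabet accepted on input sequences.
IUPAC_ALPHABET = frozenset("ACGTRYSWKMBDHVN")

DEFAULT_FLANK_BP = 50_000


@dataclass(frozen=True)
class LocusModel:
    """A single-gene locus: span, strand, TSS and exon structure.

    Coordinates are 1-based inclusive on ``chrom``.  ``flank_bp`` is the
    amount of surrounding DNA (per side) included in the analysis window.
    """

    locus_id: str
    chrom: str
    span_start: int
    span_end: int
    gene_strand: str
    tss: int
    exons: tuple[tuple[int, int], ...]
    flank_bp: int = DEFAULT_FLANK_BP

    def __post_init__(self) -> None:
        if self.gene_strand not in ("+", "-"):
            raise StrandMissingError(
                f"gene strand must be '+' or '-', got {self.gene_strand!r}"
            )
        if not (1 <= self.span_start <= self.span_end):
            raise ExonLayoutError(
                f"bad gene span {self.span_start}..{self.span_end}"
            )
        if not (self.span_start <= self.tss <= self.span_end):
            raise ExonLayoutError(
                f"TSS {self.tss} outside gene span "
                f"{self.span_start}..{self.span_end}"
            )
        if not self.exons:
            raise ExonLayoutError("locus must have at least one exon")
        prev_end = 0
        for start, end in self.exons:
            if start > end:
                raise ExonLayoutError(f"exon {start}..{end} reversed")
            if start <= prev_end:
                raise ExonLayoutError("exons unsorted or overlapping")
            if start < self.span_start or end > self.span_end:
                raise ExonLayoutError(
                    f"exon {start}..{end} outside gene span "
                    f"{self.span_start}..{self.span_end}"
                )
            prev_end = end
        if self.flank_bp < 0:
            raise ExonLayoutError("flank_bp must be non-negative")
        first = self.strand_ordered_exons()[0]
        anchor = first[0] if self.gene_strand == "+" else first[1]
        if self.tss != anchor:
            raise ExonLayoutError(
                f"TSS {self.tss} does not coincide with the strand-aware "
                f"start of exon 1 ({anchor})"
            )

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def strand_ordered_exons(self) -> tuple[tuple[int, int], ...]:
        """Exons in the gene's reading order (exon 1 first)."""
        if self.gene_strand == "+":
            return self.exons
        return tuple(reversed(self.exons))

    def intron_interval(self, k: int) -> tuple[int, int]:
        """Genomic interval of intron ``k`` (strand-aware, 1-based)."""
        ordered = self.strand_ordered_exons()
        if not (1 <= k <= len(ordered) - 1):
            raise ExonLayoutError(f"no intron {k} in a {len(ordered)}-exon gene")
        a, b = ordered[k - 1], ordered[k]
        if self.gene_strand == "+":
            return (a[1] + 1, b[0] - 1)
        return (b[1] + 1, a[0] - 1)


@dataclass(frozen=True)
class AnalysisWindow:
    """A stretch of uppercase DNA anchored on the chromosome.

    ``origin`` is the 1-based chromosomal position of ``sequence[0]``.
    """

    sequence: str
    origin: int
    chrom: str = ""

    def __post_init__(self) -> None:
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise InvalidSequenceError(
                f"analysis window restricted to A/C/G/T/N, found {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def end(self) -> int:
        """1-based chromosomal position of the last base."""
        return self.origin + self.length - 1


# --- FASTA -----------------------------------------------------------------

def parse_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into ``{record_id: uppercase DNA}``.

    RNA 'U' is mapped to 'T'.  Raises :class:`EmptyFastaError`,
    :class:`DuplicateSequenceIdError` or :class:`InvalidSequenceError`.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise DuplicateSequenceIdError(
                f"duplicate FASTA record id {record.id!r}"
            )
        seq = str(record.seq).upper().replace("U", "T")
        bad = set(seq) - IUPAC_ALPHABET
        if bad:
            raise InvalidSequenceError(
                f"record {record.id!r} contains non-IUPAC characters "
                f"{sorted(bad)}"
            )
        sequences[record.id] = seq
    if not sequences:
        raise EmptyFastaError(f"no FASTA records in {path}")
    return sequences


# --- annotation ------------------------------------------------------------

def parse_annotation(
    path: str | os.PathLike,
    format: str | None = None,
    flank_bp: int = DEFAULT_FLANK_BP,
) -> LocusModel:
    """Read a one-gene annotation (BED12 or GFF3) into a :class:`LocusModel`.

    ``format`` is 'bed', 'gff3' or None (guessed from the file extension).
    """
    path = str(path)
    if format is None:
        lower = path.lower()
        if lower.endswith((".bed", ".bed12")):
            format = "bed"
        elif lower.endswith((".gff", ".gff3")):
            format = "gff3"
        else:
            raise GeneCountError(
                f"cannot guess annotation format from {path!r}; pass format="
            )
    format = format.lower()
    if format == "bed":
        return _parse_bed12(path, flank_bp)
    if format == "gff3":
        return _parse_gff3(path, flank_bp)
    raise GeneCountError(f"unknown annotation format {format!r}")


def _parse_bed12(path: str, flank_bp: int) -> LocusModel:
    lines = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            lines.append(line)
    if len(lines) != 1:
        raise GeneCountError(
            f"expected exactly one BED record, found {len(lines)} in {path}"
        )
    fields = lines[0].split("\t")
    if len(fields) < 6:
        raise StrandMissingError("BED record has fewer than 6 columns")
    chrom = fields[0]
    chrom_start = int(fields[1])  # 0-based
    chrom_end = int(fields[2])
    name = fields[3] if len(fields) > 3 else "locus"
    strand = fields[5]
    if strand not in ("+", "-"):
        raise StrandMissingError(f"BED strand must be +/-, got {strand!r}")
    span_start = chrom_start + 1
    span_end = chrom_end
    if len(fields) >= 12:
        n_blocks = int(fields[9])
        sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
        starts = [int(x) for x in fields[11].rstrip(",").split(",")]
        if not (len(sizes) == len(starts) == n_blocks):
            raise ExonLayoutError("BED12 block count/sizes/starts disagree")
        exons = tuple(
            (span_start + off, span_start + off + size - 1)
            for off, size in zip(starts, sizes)
        )
    else:
        exons = ((span_start, span_end),)
    tss = span_start if strand == "+" else span_end
    return LocusModel(
        locus_id=name,
        chrom=chrom,
        span_start=span_start,
        span_end=span_end,
        gene_strand=strand,
        tss=tss,
        exons=exons,
        flank_bp=flank_bp,
    )


def _parse_gff3(path: str, flank_bp: int) -> LocusModel:
    import gffutils

    db = gffutils.create_db(
        path, dbfn=":memory:", keep_order=True,
        merge_strategy="create_unique",
    )
    genes = list(db.features_of_type("gene"))
    if len(genes) != 1:
        raise GeneCountError(
            f"expected exactly one gene feature, found {len(genes)} in {path}"
        )
    gene = genes[0]
    if gene.strand not in ("+", "-"):
        raise StrandMissingError(f"gene strand missing in {path}")
    exons = sorted(
        (f.start, f.end)
        for f in db.children(gene, featuretype="exon")
    )
    if not exons:
        exons = [(gene.start, gene.end)]
    for start, end in exons:
        if start < gene.start or end > gene.end:
            raise ExonLayoutError(
                f"exon {start}..{end} outside gene span "
                f"{gene.start}..{gene.end}"
            )
    tss = exons[0][0] if gene.strand == "+" else exons[-1][1]
    return LocusModel(
        locus_id=gene.id,
        chrom=gene.seqid,
        span_start=gene.start,
        span_end=gene.end,
        gene_strand=gene.strand,
        tss=tss,
        exons=tuple(exons),
        flank_bp=flank_bp,
    )


def locus_to_bed12(locus: LocusModel) -> str:
    """Serialise a locus as a single BED12 line (round-trips with
    :func:`parse_annotation`)."""
    sizes = ",".join(str(end - start + 1) for start, end in locus.exons)
    starts = ",".join(str(start - locus.span_start) for start, _ in locus.exons)
    fields = [
        locus.chrom,
        str(locus.span_start - 1),
        str(locus.span_end),
        locus.locus_id,
        "0",
        locus.gene_strand,
        str(locus.span_start - 1),
        str(locus.span_end),
        "0",
        str(locus.n_exons),
        sizes + ",",
        starts + ",",
    ]
    return "\t".join(fields) + "\n"


# --- analysis window -------------------------------------------------------

def build_window(
    locus: LocusModel,
    sequence_source: dict[str, str],
    flank_bp: int | None = None,
) -> AnalysisWindow:
    """Cut the analysis window (gene span +/- flank, clipped to the sequence)
    out of ``sequence_source[locus.chrom]``."""
    if flank_bp is None:
        flank_bp = locus.flank_bp
    if locus.chrom not in sequence_source:
        raise WindowOutsideSequenceError(
            f"no sequence for chromosome {locus.chrom!r}"
        )
    seq = sequence_source[locus.chrom]
    start = max(1, locus.span_start - flank_bp)
    end = min(len(seq), locus.span_end + flank_bp)
    if start > len(seq) or end < 1 or start > end:
        raise WindowOutsideSequenceError(
            f"window {start}..{end} outside sequence of length {len(seq)}"
        )
    sub = seq[start - 1:end].upper().replace("U", "T")
    bad = set(sub) - set("ACGTN")
    if bad:
        # degenerate codes in genomic sequence are treated as unknown
        table = str.maketrans({c: "N" for c in bad})
        sub = sub.translate(table)
    return AnalysisWindow(sequence=sub, origin=start, chrom=locus.chrom)


def window_to_fasta(window: AnalysisWindow, locus_id: str = "window") -> str:
    """FASTA text for a window; the header encodes origin and coordinates."""
    header = f">{locus_id} {window.chrom}:{window.origin}-{window.end}\n"
    body = "\n".join(
        window.sequence[i:i + 70] for i in range(0, window.length, 70)
    )
    return header + body + "\n"


# --- coordinate services ---------------------------------------------------

def to_tss_offset(position: int, locus: LocusModel) -> int:
    """Signed TSS-relative offset of a chromosomal position.

    0 at the TSS; negative upstream (5' of the gene in reading direction).
    """
    if locus.gene_strand == "+":
        return position - locus.tss
    return locus.tss - position


def from_tss_offset(offset: int, locus: LocusModel) -> int:
    """Inverse of :func:`to_tss_offset`."""
    if locus.gene_strand == "+":
        return locus.tss + offset
    return locus.tss - offset


def format_kb(offset_bp: int | float, ndigits: int = 0) -> str:
    """Format a TSS offset in kb with explicit sign, e.g. ``-31 kb``,
    ``+0.147 kb`` (ndigits=3)."""
    kb = offset_bp / 1000.0
    if ndigits == 0:
        value = round(kb)
        text = f"{abs(value):d}"
        sign = "-" if value < 0 else ("+" if value > 0 else "")
    else:
        value = round(kb, ndigits)
        text = f"{abs(value):.{ndigits}f}".rstrip("0").rstrip(".")
        sign = "-" if value < 0 else ("+" if value > 0 else "")
    return f"{sign}{text} kb"


def _point_label(position: int, locus: LocusModel) -> str:
    """Region label for a single position (total partition of the axis)."""
    ordered = locus.strand_ordered_exons()
    plus = locus.gene_strand == "+"
    # outside the gene span
    if position < locus.span_start:
        return "upstream" if plus else "downstream"
    if position > locus.span_end:
        return "downstream" if plus else "upstream"
    # inside the span: locate relative to strand-ordered exons
    for k, (start, end) in enumerate(ordered, start=1):
        if start <= position <= end:
            return f"exon_{k}"
    # in a gap between exons (or 5'/3' of them within the span)
    for k in range(1, len(ordered)):
        istart, iend = locus.intron_interval(k)
        if istart <= position <= iend:
            return f"intron_{k}"
    # within the span but 5' of exon 1 or 3' of the last exon
    first = ordered[0]
    before_first = position < first[0] if plus else position > first[1]
    return "upstream" if before_first else "downstream"


def classify_region(
    position_interval: tuple[int, int], locus: LocusModel
) -> str:
    """Label an interval as upstream / downstream / exon_k / intron_k, or
    ``boundary`` if it straddles a feature edge."""
    start, end = position_interval
    if start > end:
        start, end = end, start
    a = _point_label(start, locus)
    b = _point_label(end, locus)
    return a if a == b else "boundary"
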