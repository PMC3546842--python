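"""Both-strand consensus binding-site scanning.

Finds every exact occurrence of a consensus word (IUPAC degenerate codes
honoured in the motif, never in the genomic window) on the forward strand and,
via the reverse complement, on the reverse strand.  Overlapping occurrences
are all reported.  Near-matches — a single deviation confined to a terminal
position of the consensus, i.e. at least L-1 consecutive identities — are
reported separately.

Self-reverse-complementary (palindromic) motifs match both strands at every
occurrence; those are collapsed to a single '+' hit per genomic interval so
that both-strand censuses do not double-count palindromes.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, replace

import pandas as pd
import yaml
from Bio.Seq import Seq

from .errors import (
    HitOutsideWindowError,
    InvalidMotifError,
    InvalidSequenceError,
    MotifTooLongError,
    ScanParameterError,
)
from .locus import (
    IUPAC_ALPHABET,
    AnalysisWindow,
    LocusModel,
    classify_region,
    to_tss_offset,
)

#: IUPAC code -> set of concrete bases it stands for.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"),
    "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"),
    "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

MIN_MOTIF_LENGTH = 4


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement (an involution: R<->Y, etc.)."""
    seq = seq.upper()
    bad = set(seq) - IUPAC_ALPHABET
    if bad:
        raise InvalidSequenceError(
            f"cannot reverse-complement non-IUPAC characters {sorted(bad)}"
        )
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class ConsensusMotif:
    """A named consensus binding-site word of length L.

    ``bases`` may contain IUPAC degenerate codes; the per-position sets they
    denote are what the scanner matches against.
    """

    name: str
    bases: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "bases", self.bases.upper())
        bad = set(self.bases) - IUPAC_ALPHABET
        if bad:
            raise InvalidMotifError(
                f"motif {self.name!r} contains non-IUPAC characters "
                f"{sorted(bad)}"
            )
        if len(self.bases) < MIN_MOTIF_LENGTH:
            raise InvalidMotifError(
                f"motif {self.name!r} shorter than {MIN_MOTIF_LENGTH} bases"
            )

    @property
    def length(self) -> int:
        return len(self.bases)

    @property
    def reverse_complement_bases(self) -> str:
        return reverse_complement(self.bases)

    @property
    def self_complementary(self) -> bool:
        """True when the motif equals its own reverse complement (the set of
        words it denotes is closed under reverse complementation)."""
        return self.bases == self.reverse_complement_bases

    @property
    def degenerate(self) -> bool:
        return any(b not in "ACGT" for b in self.bases)


@dataclass(frozen=True)
class SiteHit:
    """One strand-aware match of a consensus motif.

    ``start``/``end`` are 1-based inclusive chromosomal coordinates;
    ``mismatch_position`` is the 1-based index within the motif of the
    deviating base (near matches only).  ``tss_offset`` and ``region`` are
    filled in by :func:`annotate_hits`.
    """

    motif_name: str
    start: int
    end: int
    strand: str
    match_kind: str = "exact"
    mismatch_position: int | None = None
    tss_offset: int | None = None
    region: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ScanParameterError(f"bad strand {self.strand!r}")
        if self.match_kind not in ("exact", "near"):
            raise ScanParameterError(f"bad match_kind {self.match_kind!r}")
        if self.match_kind == "exact" and self.mismatch_position is not None:
            raise ScanParameterError(
                "exact hits cannot carry a mismatch position"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


# --- matching machinery ----------------------------------------------------

def _char_class(code: str) -> str:
    bases = sorted(IUPAC_SETS[code])
    return bases[0] if len(bases) == 1 else "[" + "".join(bases) + "]"


def _overlap_pattern(word: str) -> re.Pattern[str]:
    """Regex that finds every (overlapping) start of an IUPAC word.

    Degenerate window bases (incl. N) never match because the classes list
    concrete bases only.
    """
    body = "".join(_char_class(c) for c in word)
    return re.compile(f"(?=({body}))")


def _find_starts(sequence: str, word: str) -> list[int]:
    """0-based start indices of all (overlapping) matches of ``word``."""
    return [m.start() for m in _overlap_pattern(word).finditer(sequence)]


def iupac_match(fragment: str, word: str) -> bool:
    """True when a concrete DNA fragment matches an IUPAC word exactly."""
    if len(fragment) != len(word):
        return False
    return all(b in IUPAC_SETS[c] for b, c in zip(fragment, word))


def _strand_flags(strands: str, motif: ConsensusMotif) -> tuple[bool, bool]:
    if strands not in ("forward", "reverse", "both"):
        raise ScanParameterError(f"strands must be forward/reverse/both, got {strands!r}")
    do_f = strands in ("forward", "both")
    do_r = strands in ("reverse", "both")
    # palindromes: forward and reverse matches coincide interval-by-interval;
    # report each interval once, as '+'
    if motif.self_complementary and strands == "both":
        do_r = False
    return do_f, do_r


def scan_exact(
    window: AnalysisWindow,
    motif: ConsensusMotif,
    strands: str = "both",
) -> list[SiteHit]:
    """All exact occurrences of ``motif`` in ``window`` on the requested
    strand(s); overlapping occurrences all reported."""
    L = motif.length
    if L > window.length:
        raise MotifTooLongError(
            f"motif {motif.name!r} (L={L}) longer than window "
            f"({window.length} bp)"
        )
    do_f, do_r = _strand_flags(strands, motif)
    hits: list[SiteHit] = []
    if do_f:
        for i in _find_starts(window.sequence, motif.bases):
            start = window.origin + i
            hits.append(SiteHit(motif.name, start, start + L - 1, "+"))
    if do_r:
        for i in _find_starts(window.sequence, motif.reverse_complement_bases):
            start = window.origin + i
            hits.append(SiteHit(motif.name, start, start + L - 1, "-"))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def scan_near(
    window: AnalysisWindow,
    motif: ConsensusMotif,
    min_consecutive: int | None = None,
    strands: str = "both",
    mismatch_positions: str = "terminal",
) -> list[SiteHit]:
    """Near-matches: length-L windows matching the consensus at >=
    ``min_consecutive`` consecutive positions (default L-1, i.e. one deviation
    at the first or last base).  Exact matches are excluded here — they are
    reported by :func:`scan_exact`.

    ``mismatch_positions`` is ``"terminal"`` (the single end-base rule) or
    ``"any"`` (any single mismatching position; sensitivity-analysis mode).
    """
    L = motif.length
    if L > window.length:
        raise MotifTooLongError(
            f"motif {motif.name!r} (L={L}) longer than window "
            f"({window.length} bp)"
        )
    if min_consecutive is None:
        min_consecutive = L - 1
    if not (L - 1 <= min_consecutive <= L):
        raise ScanParameterError(
            f"min_consecutive must be L-1 or L (got {min_consecutive}, L={L})"
        )
    if min_consecutive == L:
        return []
    if mismatch_positions not in ("terminal", "any"):
        raise ScanParameterError(
            f"mismatch_positions must be terminal/any, got {mismatch_positions!r}"
        )
    positions = (
        sorted({1, L}) if mismatch_positions == "terminal" else list(range(1, L + 1))
    )
    do_f, do_r = _strand_flags(strands, motif)
    found: dict[tuple[int, str], SiteHit] = {}

    def _variant(word: str, pos: int) -> str:
        return word[: pos - 1] + "N" + word[pos:]

    if do_f:
        for p in positions:
            for i in _find_starts(window.sequence, _variant(motif.bases, p)):
                fragment = window.sequence[i:i + L]
                if iupac_match(fragment, motif.bases):
                    continue  # exact; reported by scan_exact
                start = window.origin + i
                found.setdefault(
                    (start, "+"),
                    SiteHit(motif.name, start, start + L - 1, "+",
                            match_kind="near", mismatch_position=p),
                )
    if do_r:
        rc = motif.reverse_complement_bases
        for p in positions:
            # a deviation at motif position p reads as position L-p+1 on the
            # reverse-complement word laid on the forward strand
            j = L - p + 1
            for i in _find_starts(window.sequence, _variant(rc, j)):
                fragment = window.sequence[i:i + L]
                if iupac_match(fragment, rc):
                    continue
                start = window.origin + i
                found.setdefault(
                    (start, "-"),
                    SiteHit(motif.name, start, start + L - 1, "-",
                            match_kind="near", mismatch_position=p),
                )
    hits = sorted(found.values(), key=lambda h: (h.start, h.strand))
    return hits


def annotate_hits(hits: list[SiteHit], locus: LocusModel) -> list[SiteHit]:
    """Fill ``tss_offset`` and ``region`` on every hit (stable order).

    Raises :class:`HitOutsideWindowError` for hits outside the locus analysis
    window (gene span +/- flank).
    """
    lo = max(1, locus.span_start - locus.flank_bp)
    hi = locus.span_end + locus.flank_bp
    annotated = []
    for hit in hits:
        if hit.start < lo or hit.end > hi:
            raise HitOutsideWindowError(
                f"hit {hit.start}..{hit.end} outside window {lo}..{hi}"
            )
        annotated.append(
            replace(
                hit,
                tss_offset=to_tss_offset(hit.start, locus),
                region=classify_region((hit.start, hit.end), locus),
            )
        )
    annotated.sort(key=lambda h: (h.start, h.strand))
    return annotated


# --- serialisation ---------------------------------------------------------

def hits_to_table(hits: list[SiteHit]) -> pd.DataFrame:
    """Tabulate hits (one row per site; TSS offset and region included)."""
    return pd.DataFrame(
        [
            {
                "motif": h.motif_name,
                "start": h.start,
                "end": h.end,
                "strand": h.strand,
                "match_kind": h.match_kind,
                "mismatch_position": h.mismatch_position,
                "tss_offset": h.tss_offset,
                "region": h.region,
            }
            for h in hits
        ],
        columns=[
            "motif", "start", "end", "strand", "match_kind",
            "mismatch_position", "tss_offset", "region",
        ],
    )


def hits_to_bed6(hits: list[SiteHit], chrom: str) -> str:
    """BED6 text: name = motif, score = 0 for exact / 1 for near."""
    lines = []
    for h in hits:
        score = 0 if h.match_kind == "exact" else 1
        lines.append(
            f"{chrom}\t{h.start - 1}\t{h.end}\t{h.motif_name}\t{score}\t{h.strand}"
        )
    return "\n".join(lines) + ("\n" if lines else "")


def load_motifs(path: str | os.PathLike) -> list[ConsensusMotif]:
    """Read a motif configuration (YAML).

    Accepts either ``{name: consensus}`` or
    ``motifs: [{name: ..., consensus: ...}, ...]``.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        raise InvalidMotifError(f"empty motif configuration {path}")
    if isinstance(data, dict) and "motifs" in data:
        data = data["motifs"]
    motifs: list[ConsensusMotif] = []
    if isinstance(data, dict):
        for name, bases in data.items():
            motifs.append(ConsensusMotif(str(name), str(bases)))
    elif isinstance(data, list):
        for entry in data:
            motifs.append(
                ConsensusMotif(str(entry["name"]), str(entry["consensus"]))
            )
    else:
        raise InvalidMotifError(f"unrecognised motif configuration in {path}")
    if not motifs:
        raise InvalidMotifError(f"no motifs defined in {path}")
    return motifs


def save_motifs(motifs: list[ConsensusMotif], path: str | os.PathLike) -> None:
    data = {"motifs": [{"name": m.name, "consensus": m.bases} for m in motifs]}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
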