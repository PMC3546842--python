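"""Synthetic loci, planted binding sites and simulated qPCR Ct tables.

Everything the pipeline consumes can be generated here with known ground
truth: an i.i.d. background sequence (uniform base composition at GC 0.5,
matching the (1/4)-per-base null), a gene model with exon/intron structure,
planted consensus-site occurrences and clusters at chosen TSS offsets, and
long-format Ct tables produced by inverting the percent-input formula with
additive Gaussian Ct noise.

Two presets mirror the geometries the pipeline is designed around:

* ``appb_like_spec`` — a ~160 kb window: a 60-kb, 14-exon gene on '+' with
  50-kb flanks, a trio of E4BP4 sites planted at -31 kb and lone E4BP4/XFD1
  sites in intron 1.
* ``app_like_spec`` — a ~100 kb window: a 60-kb, 18-exon gene on '-' with
  20-kb flanks and a quartet of E4BP4 sites planted in intron 4.

Default consensus words: E4BP4 = GTTACGTAAC (the classic pseudo-palindromic
TTACGTAA-core bZIP site; self-reverse-complementary, so both-strand censuses
single-count it) and XFD1 = TGTTTATTT (an A/T-rich Forkhead-like 9-mer, the
length at which the 8-of-9 near-match rule applies).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import OverlappingPlantingError, PlantingError
from .locus import AnalysisWindow, LocusModel, from_tss_offset
from .qpcr import QPCR_COLUMNS
from .scan import IUPAC_SETS, ConsensusMotif, SiteHit, reverse_complement
from .enrichment import expected_count

DEFAULT_MOTIFS: tuple[ConsensusMotif, ...] = (
    ConsensusMotif("E4BP4", "GTTACGTAAC"),
    ConsensusMotif("XFD1", "TGTTTATTT"),
)

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def generate_background(length: int, gc_fraction: float = 0.5, seed=0) -> str:
    """i.i.d. random DNA with P(G)+P(C) = ``gc_fraction`` split evenly.

    Same seed, same sequence.  ``seed`` may be an int, SeedSequence or
    Generator.
    """
    if length <= 0:
        raise PlantingError("background length must be positive")
    if not (0.0 <= gc_fraction <= 1.0):
        raise PlantingError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    idx = rng.choice(4, size=length, p=[at, gc, gc, at])
    return _BASE_BYTES[idx].tobytes().decode("ascii")


@dataclass(frozen=True)
class Planting:
    """One site to plant: locate it by absolute 1-based position or by TSS
    offset (of its genomic start), on either strand, exact or near."""

    motif_name: str
    position: int | None = None
    tss_offset: int | None = None
    strand: str = "+"
    kind: str = "exact"

    def __post_init__(self) -> None:
        if (self.position is None) == (self.tss_offset is None):
            raise PlantingError(
                "specify exactly one of position / tss_offset"
            )
        if self.strand not in ("+", "-"):
            raise PlantingError(f"bad strand {self.strand!r}")
        if self.kind not in ("exact", "near"):
            raise PlantingError(f"bad planting kind {self.kind!r}")

    def resolve(self, locus: LocusModel) -> int:
        if self.position is not None:
            return self.position
        return from_tss_offset(self.tss_offset, locus)


@dataclass(frozen=True)
class SyntheticLocusSpec:
    """Blueprint for one synthetic locus: geometry, composition, plantings."""

    locus: LocusModel
    total_length: int
    gc_fraction: float = 0.5
    planted: tuple[Planting, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.locus.span_end > self.total_length:
            raise PlantingError("gene span exceeds total sequence length")
        if not (0.0 < self.gc_fraction < 1.0):
            raise PlantingError("gc_fraction must be in (0, 1)")


@dataclass(frozen=True)
class TruthTable:
    """Ground truth emitted alongside a synthetic locus."""

    planted: tuple[SiteHit, ...]
    expected_background: dict[str, float] = field(default_factory=dict)
    qpcr_true_folds: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class SyntheticLocus:
    """A realised synthetic locus: sequence, gene model, window, truth."""

    spec: SyntheticLocusSpec
    locus: LocusModel
    window: AnalysisWindow
    truth: TruthTable

    @property
    def sequence(self) -> str:
        return self.window.sequence


def _concrete_word(motif: ConsensusMotif, rng: np.random.Generator) -> str:
    """Resolve degenerate motif positions to concrete bases."""
    return "".join(
        b if b in "ACGT" else rng.choice(sorted(IUPAC_SETS[b]))
        for b in motif.bases
    )


def _near_word(
    word: str, motif: ConsensusMotif, rng: np.random.Generator
) -> tuple[str, int]:
    """Mutate one terminal base of a concrete motif word to a base outside
    the consensus at that position; returns (word, mismatch_position)."""
    L = motif.length
    pos = int(rng.choice([1, L]))
    allowed = IUPAC_SETS[motif.bases[pos - 1]]
    choices = sorted(set("ACGT") - allowed)
    if not choices:  # position is N in the consensus: no mismatch possible
        raise PlantingError(
            f"cannot plant a near site at fully degenerate position {pos} "
            f"of motif {motif.name!r}"
        )
    base = str(rng.choice(choices))
    mutated = word[: pos - 1] + base + word[pos:]
    return mutated, pos


def plant_sites(
    background: str,
    spec: SyntheticLocusSpec,
    motifs: list[ConsensusMotif] | tuple[ConsensusMotif, ...] = DEFAULT_MOTIFS,
    seed=None,
) -> tuple[str, TruthTable]:
    """Write the planted sites into the background sequence.

    Returns the modified sequence and a truth table recording every planting
    (chromosomal coordinates, strand, kind) plus the analytic expected chance
    count per motif.  Overlapping plantings raise
    :class:`OverlappingPlantingError`.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    by_name = {m.name: m for m in motifs}
    seq = bytearray(background, "ascii")
    occupied: list[tuple[int, int]] = []
    planted_hits: list[SiteHit] = []
    for planting in spec.planted:
        if planting.motif_name not in by_name:
            raise PlantingError(
                f"planting references unknown motif {planting.motif_name!r}"
            )
        motif = by_name[planting.motif_name]
        L = motif.length
        start = planting.resolve(spec.locus)
        end = start + L - 1
        if start < 1 or end > len(background):
            raise OverlappingPlantingError(
                f"planting {planting.motif_name} at {start}..{end} out of "
                f"bounds 1..{len(background)}"
            )
        for a, b in occupied:
            if start <= b and end >= a:
                raise OverlappingPlantingError(
                    f"planting {planting.motif_name} at {start}..{end} "
                    f"overlaps an earlier planting at {a}..{b}"
                )
        occupied.append((start, end))
        word = _concrete_word(motif, rng)
        mismatch = None
        if planting.kind == "near":
            word, mismatch = _near_word(word, motif, rng)
        if planting.strand == "-":
            word = reverse_complement(word)
        seq[start - 1:end] = word.encode("ascii")
        strand = planting.strand
        if motif.self_complementary and planting.kind == "exact":
            strand = "+"  # the scanner single-counts palindromes as '+'
        planted_hits.append(
            SiteHit(
                motif_name=motif.name,
                start=start,
                end=end,
                strand=strand,
                match_kind=planting.kind,
                mismatch_position=mismatch,
            )
        )
    final = seq.decode("ascii")
    window = AnalysisWindow(sequence=final, origin=1, chrom=spec.locus.chrom)
    expected = {
        m.name: expected_count(window, m, strands=2) for m in motifs
    }
    truth = TruthTable(
        planted=tuple(planted_hits), expected_background=expected
    )
    return final, truth


def generate_locus(
    spec: SyntheticLocusSpec,
    motifs: list[ConsensusMotif] | tuple[ConsensusMotif, ...] = DEFAULT_MOTIFS,
    seed: int | None = None,
) -> SyntheticLocus:
    """Background + plantings in one step, fully deterministic per seed.

    The single seed fans out to independent child streams for the background
    and the planting randomisation.
    """
    master = np.random.SeedSequence(spec.seed if seed is None else seed)
    bg_seed, plant_seed = master.spawn(2)
    background = generate_background(
        spec.total_length, spec.gc_fraction, seed=bg_seed
    )
    sequence, truth = plant_sites(background, spec, motifs, seed=plant_seed)
    window = AnalysisWindow(sequence=sequence, origin=1, chrom=spec.locus.chrom)
    return SyntheticLocus(spec=spec, locus=spec.locus, window=window, truth=truth)


# --- preset geometries -----------------------------------------------------

def _exon_layout(
    span_start: int, span_end: int, n_exons: int, exon_len: int
) -> tuple[tuple[int, int], ...]:
    """Evenly spaced exons flush with both span edges."""
    total = span_end - span_start + 1
    n_introns = n_exons - 1
    intron_total = total - n_exons * exon_len
    if n_introns <= 0 or intron_total <= 0:
        raise PlantingError("gene too short for the requested exon layout")
    base = intron_total // n_introns
    extra = intron_total % n_introns
    exons = []
    pos = span_start
    for i in range(n_exons):
        exons.append((pos, pos + exon_len - 1))
        pos += exon_len
        if i < n_introns:
            pos += base + (1 if i < extra else 0)
    assert exons[-1][1] == span_end
    return tuple(exons)


def appb_like_spec(seed: int = 0) -> SyntheticLocusSpec:
    """Zebrafish-like setting: 60-kb 14-exon '+' gene, 50-kb flanks
    (160 kb total), a 3-site E4BP4 cluster at -31 kb and lone E4BP4/XFD1
    sites in intron 1."""
    flank = 50_000
    span_start, span_end = flank + 1, flank + 60_000
    exons = _exon_layout(span_start, span_end, n_exons=14, exon_len=150)
    locus = LocusModel(
        locus_id="appb_like",
        chrom="chrSim1",
        span_start=span_start,
        span_end=span_end,
        gene_strand="+",
        tss=span_start,
        exons=exons,
        flank_bp=flank,
    )
    intron1 = locus.intron_interval(1)
    planted = (
        Planting("E4BP4", tss_offset=-31_200),
        Planting("E4BP4", tss_offset=-31_000),
        Planting("E4BP4", tss_offset=-30_800),
        Planting("E4BP4", position=intron1[0] + 500),
        Planting("XFD1", position=intron1[0] + 1000),
    )
    return SyntheticLocusSpec(
        locus=locus,
        total_length=span_end + flank,
        gc_fraction=0.5,
        planted=planted,
        seed=seed,
    )


def app_like_spec(seed: int = 0) -> SyntheticLocusSpec:
    """Human-like setting: 60-kb 18-exon '-' gene, 20-kb flanks (100 kb
    total), a 4-site E4BP4 cluster in intron 4 plus one exact and one
    near XFD1 site."""
    flank = 20_000
    span_start, span_end = flank + 1, flank + 60_000
    exons = _exon_layout(span_start, span_end, n_exons=18, exon_len=150)
    locus = LocusModel(
        locus_id="app_like",
        chrom="chrSim2",
        span_start=span_start,
        span_end=span_end,
        gene_strand="-",
        tss=span_end,
        exons=exons,
        flank_bp=flank,
    )
    i4_start, i4_end = locus.intron_interval(4)
    center = (i4_start + i4_end) // 2
    i2_start, _ = locus.intron_interval(2)
    planted = (
        Planting("E4BP4", position=center - 300),
        Planting("E4BP4", position=center - 100),
        Planting("E4BP4", position=center + 100),
        Planting("E4BP4", position=center + 300),
        Planting("XFD1", position=i2_start + 400),
        Planting("XFD1", position=i2_start + 900, kind="near"),
    )
    return SyntheticLocusSpec(
        locus=locus,
        total_length=span_end + flank,
        gc_fraction=0.5,
        planted=planted,
        seed=seed,
    )


# --- qPCR simulation -------------------------------------------------------

#: Default panel of true fold enrichments used by the fixture generator:
#: a strong positive-control region, the clustered-site region, a housekeeping
#: promoter, and three unenriched negative-control introns.
DEFAULT_QPCR_TRUE_FOLDS: dict[str, float] = {
    "intron_2": 180.0,
    "intron_4": 120.0,
    "IkBa_promoter": 150.0,
    "intron_15_1": 1.0,
    "intron_15_2": 1.0,
    "intron_18": 1.0,
}


def simulate_qpcr(
    true_fold: float,
    base_percent_igg: float = 0.05,
    ct_noise_sd: float = 0.2,
    n_experiments: int = 3,
    n_duplicates: int = 2,
    input_fraction: float = 0.01,
    efficiency: float = 2.0,
    seed=0,
    region_name: str = "region",
    input_ct: float = 20.0,
) -> pd.DataFrame:
    """Long-format Ct table for one region with a known true fold.

    Ct values are constructed by inverting the percent-input formula: the IgG
    control recovers ``base_percent_igg`` percent of input, the specific
    antibody ``true_fold`` times that; each replicate then receives additive
    Gaussian noise of SD ``ct_noise_sd`` cycles.  Deterministic per seed.
    """
    if true_fold <= 0:
        raise PlantingError("true_fold must be positive")
    if ct_noise_sd < 0:
        raise PlantingError("ct_noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    log_eff = math.log(efficiency)
    adj_input = input_ct - math.log(1.0 / input_fraction) / log_eff
    ct_true = {
        "input": input_ct,
        "control_igg": adj_input - math.log(base_percent_igg / 100.0) / log_eff,
        "specific": adj_input
        - math.log(true_fold * base_percent_igg / 100.0) / log_eff,
    }
    rows = []
    for exp in range(1, n_experiments + 1):
        for antibody in ("specific", "control_igg", "input"):
            for rep in range(1, n_duplicates + 1):
                noise = float(rng.normal(0.0, ct_noise_sd)) if ct_noise_sd else 0.0
                rows.append(
                    {
                        "region": region_name,
                        "antibody": antibody,
                        "experiment": exp,
                        "replicate": rep,
                        "ct": ct_true[antibody] + noise,
                        "input_fraction": input_fraction,
                    }
                )
    return pd.DataFrame(rows, columns=QPCR_COLUMNS)


def simulate_qpcr_panel(
    true_folds: dict[str, float] | None = None,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Ct tables for a panel of regions (one child seed per region)."""
    if true_folds is None:
        true_folds = DEFAULT_QPCR_TRUE_FOLDS
    master = np.random.SeedSequence(seed)
    children = master.spawn(len(true_folds))
    frames = [
        simulate_qpcr(
            fold, seed=child, region_name=region, **kwargs
        )
        for (region, fold), child in zip(true_folds.items(), children)
    ]
    return pd.concat(frames, ignore_index=True)


def truth_to_table(truth: TruthTable) -> pd.DataFrame:
    """Tabulate the planted sites of a truth table."""
    return pd.DataFrame(
        [
            {
                "motif": h.motif_name,
                "start": h.start,
                "end": h.end,
                "strand": h.strand,
                "match_kind": h.match_kind,
                "mismatch_position": h.mismatch_position,
            }
            for h in truth.planted
        ],
        columns=["motif", "start", "end", "strand", "match_kind",
                 "mismatch_position"],
    )
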