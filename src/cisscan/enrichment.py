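"""Motif over-representation under a uniform-base null.

Under the null model every position carries each nucleotide independently
with probability 1/4, so a non-degenerate consensus of length L occurs at a
given position with probability (1/4)^L.  The expected count over a window is
that probability times the number of scannable positions (window length -
L + 1) times the number of strands censused, and fold over-representation is
the ratio of the observed census to this expectation.  An exact binomial
upper-tail p-value complements the fold ratio.

For self-reverse-complementary motifs the two strand censuses coincide and
are deduplicated by the scanner, so the expectation is forced to single
strand for consistency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy.stats import binom

from .errors import EnrichmentParameterError
from .locus import AnalysisWindow
from .scan import IUPAC_SETS, ConsensusMotif, SiteHit


@dataclass(frozen=True)
class EnrichmentResult:
    """Observed vs expected site counts for one motif over one window."""

    motif_name: str
    window_length: int
    n_positions_scanned: int
    strands_counted: int
    observed: int
    expected: float
    fold: float  # NaN when expected == 0
    p_value: float
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {
            "motif": self.motif_name,
            "window_length": self.window_length,
            "n_positions_scanned": self.n_positions_scanned,
            "strands_counted": self.strands_counted,
            "observed": self.observed,
            "expected": self.expected,
            "fold": self.fold,
            "p_value": self.p_value,
            "degenerate": self.degenerate,
        }


def expected_site_probability(motif: ConsensusMotif) -> float:
    """Per-position match probability under the uniform null.

    (1/4)^L for a non-degenerate motif; for IUPAC motifs the product over
    positions of |allowed bases|/4 (flagged as degenerate in output).
    """
    p = 1.0
    for code in motif.bases:
        p *= len(IUPAC_SETS[code]) / 4.0
    return p


def expected_site_probability_composition(
    motif: ConsensusMotif, window: AnalysisWindow
) -> float:
    """Optional composition-aware null: product over motif positions of the
    summed mononucleotide frequencies of the allowed bases in the window."""
    counts = {b: window.sequence.count(b) for b in "ACGT"}
    total = sum(counts.values())
    if total == 0:
        return 0.0
    freqs = {b: counts[b] / total for b in "ACGT"}
    p = 1.0
    for code in motif.bases:
        p *= sum(freqs[b] for b in IUPAC_SETS[code])
    return p


def n_scannable_positions(window: AnalysisWindow, motif: ConsensusMotif) -> int:
    """Offsets with a full motif length remaining (edge positions with fewer
    than L bases left are not trials)."""
    return max(0, window.length - motif.length + 1)


def expected_count(
    window: AnalysisWindow,
    motif: ConsensusMotif,
    strands: int = 2,
    background: str = "uniform",
) -> float:
    """Expected number of chance occurrences over the window.

    ``strands`` is 1 or 2; forced to 1 for self-complementary motifs (their
    both-strand census is single-counted by the scanner).
    """
    if strands not in (1, 2):
        raise EnrichmentParameterError(f"strands must be 1 or 2, got {strands}")
    if motif.self_complementary:
        strands = 1
    if background == "uniform":
        p = expected_site_probability(motif)
    elif background == "composition":
        p = expected_site_probability_composition(motif, window)
    else:
        raise EnrichmentParameterError(
            f"background must be uniform/composition, got {background!r}"
        )
    return strands * n_scannable_positions(window, motif) * p


def fold_overrepresentation(observed: int, expected: float) -> float:
    """observed / expected; NaN (reported as NA) when expected == 0."""
    if expected < 0:
        raise EnrichmentParameterError("expected count cannot be negative")
    if expected == 0:
        return math.nan
    return observed / expected


def enrichment_pvalue(
    observed: int, n_positions: int, p_per_position: float
) -> float:
    """Exact binomial upper tail P[X >= observed], X ~ Binomial(n, p)."""
    if not (0.0 <= p_per_position <= 1.0):
        raise EnrichmentParameterError(
            f"p_per_position must be in [0,1], got {p_per_position}"
        )
    if observed < 0 or n_positions < 0:
        raise EnrichmentParameterError("counts must be non-negative")
    if observed > n_positions:
        raise EnrichmentParameterError(
            f"observed ({observed}) exceeds number of trials ({n_positions})"
        )
    if observed == 0:
        return 1.0
    return float(binom.sf(observed - 1, n_positions, p_per_position))


def enrich(
    window: AnalysisWindow,
    motif: ConsensusMotif,
    hits: list[SiteHit],
    strands: int = 2,
    include_near: bool = False,
    background: str = "uniform",
) -> EnrichmentResult:
    """Assemble the full over-representation record for one motif.

    ``hits`` is the annotated or raw hit list from the scanner; near matches
    are excluded from the census unless ``include_near``.
    """
    observed = sum(
        1
        for h in hits
        if h.motif_name == motif.name
        and (include_near or h.match_kind == "exact")
    )
    strands_eff = 1 if motif.self_complementary else strands
    n_pos = n_scannable_positions(window, motif)
    expected = expected_count(window, motif, strands=strands, background=background)
    if background == "uniform":
        p = expected_site_probability(motif)
    else:
        p = expected_site_probability_composition(motif, window)
    trials = strands_eff * n_pos
    observed_capped = min(observed, trials)  # overlap counting can exceed trials only pathologically
    return EnrichmentResult(
        motif_name=motif.name,
        window_length=window.length,
        n_positions_scanned=n_pos,
        strands_counted=strands_eff,
        observed=observed,
        expected=expected,
        fold=fold_overrepresentation(observed, expected),
        p_value=enrichment_pvalue(observed_capped, trials, p),
        degenerate=motif.degenerate,
    )


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    """TSV-ready table: motif, window, strands, observed, expected, fold,
    p_value."""
    return pd.DataFrame(
        [r.as_dict() for r in results],
        columns=[
            "motif", "window_length", "n_positions_scanned", "strands_counted",
            "observed", "expected", "fold", "p_value", "degenerate",
        ],
    )
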