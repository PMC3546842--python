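"""Binding-site cluster calling.

A cluster is a maximal run of same-motif hits chained by single linkage:
consecutive member start positions at most ``window_bp`` apart, with at least
``min_sites`` members.  Clusters are the units carried forward to reporting
(e.g. a trio of sites ~31 kb upstream of the TSS, or a quartet inside an
intron) and, experimentally, to ChIP validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ScanParameterError
from .locus import LocusModel, classify_region, format_kb, to_tss_offset
from .scan import SiteHit


@dataclass(frozen=True)
class SiteCluster:
    """A maximal group of >= min_sites same-motif hits under the gap rule."""

    motif_name: str
    members: tuple[SiteHit, ...]
    window_bp: int

    @property
    def n_sites(self) -> int:
        return len(self.members)

    @property
    def span_start(self) -> int:
        return self.members[0].start

    @property
    def span_end(self) -> int:
        return max(h.end for h in self.members)

    @property
    def center(self) -> int:
        return (self.span_start + self.span_end) // 2


def find_clusters(
    hits: list[SiteHit],
    window_bp: int = 1000,
    min_sites: int = 3,
    mixed_motifs: bool = False,
    dedup_overlaps: bool = False,
) -> list[SiteCluster]:
    """Single-linkage chaining of hits into clusters.

    Hits are grouped per motif (or pooled when ``mixed_motifs``), sorted by
    start, and chained while consecutive start positions differ by at most
    ``window_bp``.  Maximal chains with >= ``min_sites`` members are returned,
    ordered by span start.  With ``dedup_overlaps`` hits sharing an identical
    interval (overlap double-counts) collapse to one member.
    """
    if window_bp <= 0:
        raise ScanParameterError("window_bp must be positive")
    if min_sites < 2:
        raise ScanParameterError("min_sites must be >= 2")
    groups: dict[str, list[SiteHit]] = {}
    for hit in hits:
        key = "*" if mixed_motifs else hit.motif_name
        groups.setdefault(key, []).append(hit)
    clusters: list[SiteCluster] = []
    for key in groups:
        members = sorted(groups[key], key=lambda h: (h.start, h.end, h.strand))
        if dedup_overlaps:
            deduped: list[SiteHit] = []
            seen: set[tuple[int, int]] = set()
            for h in members:
                if (h.start, h.end) not in seen:
                    seen.add((h.start, h.end))
                    deduped.append(h)
            members = deduped
        chain: list[SiteHit] = []
        for h in members:
            if chain and h.start - chain[-1].start > window_bp:
                if len(chain) >= min_sites:
                    clusters.append(
                        SiteCluster(key, tuple(chain), window_bp)
                    )
                chain = []
            chain.append(h)
        if len(chain) >= min_sites:
            clusters.append(SiteCluster(key, tuple(chain), window_bp))
    clusters.sort(key=lambda c: (c.span_start, c.motif_name))
    return clusters


def summarize_cluster(cluster: SiteCluster, locus: LocusModel) -> dict:
    """Report row: motif, size, genomic span, kb-formatted TSS offset of the
    cluster centre, and the region label(s) of its members."""
    regions = []
    for h in cluster.members:
        label = h.region or classify_region((h.start, h.end), locus)
        if label not in regions:
            regions.append(label)
    offset = to_tss_offset(cluster.center, locus)
    return {
        "motif": cluster.motif_name,
        "n_sites": cluster.n_sites,
        "span_start": cluster.span_start,
        "span_end": cluster.span_end,
        "tss_offset_of_center": offset,
        "tss_offset_kb": format_kb(offset),
        "region_summary": ",".join(regions),
    }


def clusters_to_table(
    clusters: list[SiteCluster], locus: LocusModel
) -> pd.DataFrame:
    return pd.DataFrame(
        [summarize_cluster(c, locus) for c in clusters],
        columns=[
            "motif", "n_sites", "span_start", "span_end",
            "tss_offset_of_center", "tss_offset_kb", "region_summary",
        ],
    )


def clusters_to_bed(clusters: list[SiteCluster], chrom: str) -> str:
    """BED lines, thickStart/thickEnd marking the member extremes."""
    lines = []
    for c in clusters:
        lines.append(
            "\t".join(
                [
                    chrom,
                    str(c.span_start - 1),
                    str(c.span_end),
                    f"{c.motif_name}_cluster_n{c.n_sites}",
                    str(c.n_sites),
                    ".",
                    str(c.span_start - 1),
                    str(c.span_end),
                ]
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")
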