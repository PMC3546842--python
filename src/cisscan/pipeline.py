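"""End-to-end orchestration: locus -> scan -> enrichment -> clusters -> ChIP.

A single declarative config drives the run; every effective parameter is
echoed into the machine-readable summary so the under-specified knobs
(window flank, strand convention, cluster rule) stay auditable.  Identical
config and inputs produce byte-identical outputs.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .clusters import clusters_to_bed, clusters_to_table, find_clusters
from .enrichment import enrich, enrichment_table
from .errors import CisscanError, ConfigError, PipelineError
from .locus import build_window, parse_annotation, parse_fasta, window_to_fasta
from .qpcr import analyze_qpcr_table, read_qpcr_csv
from .scan import annotate_hits, hits_to_bed6, hits_to_table, load_motifs, scan_exact, scan_near


@dataclass
class PipelineConfig:
    """Paths and parameters for one pipeline run."""

    fasta: str
    annotation: str
    motifs: str
    qpcr: str | None = None
    out_dir: str = "cisscan_out"
    annotation_format: str | None = None
    flank_bp: int = 50_000
    strands: str = "both"
    scan_near_sites: bool = True
    min_consecutive: int | None = None
    near_positions: str = "terminal"
    cluster_window_bp: int = 1000
    cluster_min_sites: int = 3
    cluster_include_near: bool = False
    background_model: str = "uniform"
    include_near_in_counts: bool = False
    qpcr_efficiency: float = 2.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigError(f"unknown config keys {sorted(unknown)}")
        try:
            config = cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc
        # relative paths resolve against the config file's directory
        base = Path(path).parent
        for attr in ("fasta", "annotation", "motifs", "qpcr"):
            value = getattr(config, attr)
            if value is not None and not os.path.isabs(value):
                setattr(config, attr, str(base / value))
        if not os.path.isabs(config.out_dir):
            config.out_dir = str(base / config.out_dir)
        return config

    def validate(self) -> None:
        for attr in ("fasta", "annotation", "motifs"):
            path = getattr(self, attr)
            if not path or not os.path.exists(path):
                raise ConfigError(f"{attr} path {path!r} does not exist")
        if self.qpcr is not None and not os.path.exists(self.qpcr):
            raise ConfigError(f"qpcr path {self.qpcr!r} does not exist")
        if self.strands not in ("forward", "reverse", "both"):
            raise ConfigError(f"strands must be forward/reverse/both")
        if self.flank_bp < 0:
            raise ConfigError("flank_bp must be non-negative")
        if self.cluster_window_bp <= 0 or self.cluster_min_sites < 2:
            raise ConfigError("bad cluster parameters")


def _stage(name: str):
    """Decorator: re-raise stage failures with the stage name attached."""
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except CisscanError as exc:
                raise PipelineError(f"[{name}] {exc}") from exc
        return inner
    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write hit/enrichment/cluster/ChIP tables plus a
    machine-readable summary into ``config.out_dir``.  Returns the summary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    sequences = _stage("locus")(parse_fasta)(config.fasta)
    locus = _stage("locus")(parse_annotation)(
        config.annotation, config.annotation_format, flank_bp=config.flank_bp
    )
    window = _stage("locus")(build_window)(locus, sequences, config.flank_bp)
    motifs = _stage("scan")(load_motifs)(config.motifs)

    (out / "window.fa").write_text(window_to_fasta(window, locus.locus_id))

    all_hits = []
    per_motif = {}
    for motif in motifs:
        exact = _stage("scan")(scan_exact)(window, motif, config.strands)
        near = []
        if config.scan_near_sites:
            near = _stage("scan")(scan_near)(
                window, motif,
                min_consecutive=config.min_consecutive,
                strands=config.strands,
                mismatch_positions=config.near_positions,
            )
        hits = _stage("annotate")(annotate_hits)(exact + near, locus)
        per_motif[motif.name] = hits
        all_hits.extend(hits)
        table = hits_to_table(hits)
        table.to_csv(out / f"hits_{motif.name}.tsv", sep="\t", index=False)
        (out / f"hits_{motif.name}.bed").write_text(
            hits_to_bed6(hits, locus.chrom)
        )

    # expected counts reported at both strand conventions for auditability
    results = []
    for motif in motifs:
        hits = per_motif[motif.name]
        for strands_counted in (2, 1):
            results.append(
                _stage("enrichment")(enrich)(
                    window, motif, hits,
                    strands=strands_counted,
                    include_near=config.include_near_in_counts,
                    background=config.background_model,
                )
            )
    enr_table = enrichment_table(results)
    enr_table.to_csv(out / "enrichment.tsv", sep="\t", index=False)

    cluster_input = [
        h for h in all_hits
        if config.cluster_include_near or h.match_kind == "exact"
    ]
    clusters = _stage("clusters")(find_clusters)(
        cluster_input,
        window_bp=config.cluster_window_bp,
        min_sites=config.cluster_min_sites,
    )
    cluster_table = clusters_to_table(clusters, locus)
    cluster_table.to_csv(out / "clusters.tsv", sep="\t", index=False)
    (out / "clusters.bed").write_text(clusters_to_bed(clusters, locus.chrom))

    qpcr_rows = None
    if config.qpcr is not None:
        ct_table = _stage("chip")(read_qpcr_csv)(config.qpcr)
        qpcr_result = _stage("chip")(analyze_qpcr_table)(
            ct_table, efficiency=config.qpcr_efficiency
        )
        qpcr_result.to_csv(out / "chip_enrichment.tsv", sep="\t", index=False)
        qpcr_rows = qpcr_result.to_dict(orient="records")

    # the output directory is where the summary itself lives; leaving it out
    # keeps summaries of identical analyses byte-identical
    config_echo = {k: v for k, v in asdict(config).items() if k != "out_dir"}
    summary = {
        "cisscan_version": __version__,
        "config": config_echo,
        "locus": {
            "locus_id": locus.locus_id,
            "chrom": locus.chrom,
            "span": [locus.span_start, locus.span_end],
            "strand": locus.gene_strand,
            "tss": locus.tss,
            "n_exons": locus.n_exons,
        },
        "window": {
            "origin": window.origin,
            "length": window.length,
        },
        "hit_counts": {
            name: {
                "exact": sum(1 for h in hits if h.match_kind == "exact"),
                "near": sum(1 for h in hits if h.match_kind == "near"),
            }
            for name, hits in per_motif.items()
        },
        "enrichment": [r.as_dict() for r in results],
        "clusters": cluster_table.to_dict(orient="records"),
        "qpcr": qpcr_rows,
    }
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=float) + "\n"
    )
    log_lines = [
        f"cisscan {__version__}",
        f"seed {config.seed}",
        f"window {window.origin}..{window.end} ({window.length} bp)",
    ]
    for name, hits in per_motif.items():
        n_exact = sum(1 for h in hits if h.match_kind == "exact")
        n_near = len(hits) - n_exact
        log_lines.append(f"{name}: {n_exact} exact, {n_near} near hits")
    log_lines.append(f"{len(clusters)} cluster(s)")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return summary
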