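"""End-to-end pipeline wiring: scan, screen, summarize, render.

The pipeline is deterministic: rerunning with the same configuration
and inputs reproduces byte-identical TSV/BED outputs. A JSON manifest
records the configuration echo, package and library versions and the
seed, so every output is derivable from inputs + manifest alone.

For an input ``clone.fasta`` an optional annotation sidecar
``clone.gff3`` (CDS + rRNA features) is picked up automatically; rRNA
intervals additionally mask windows during region calling when no
explicit mask file is given.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import scipy
import yaml

from . import __version__
from .annotation import CloneSummary, build_summary, correlate_clones
from .io import FeatureInterval, SequenceRecord, read_fasta, read_intervals
from .rflp import DEFAULT_PRIMERS, HHAI_CUT_OFFSET, HHAI_SITE, PrimerPair, digest, screen_clone
from .tetra import (
    CorrelationMatrix,
    DEFAULT_MIN_RUN,
    WindowSpec,
    call_low_correlation_regions,
    correlation_matrix,
    window_scores,
)
from .viz import render_boxplot_summary, render_heatmap

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated pipeline configuration; flags win over the config file."""

    window: int = 300
    step: int = 100
    mode: str = "per_window_rc"
    primer_forward: str = DEFAULT_PRIMERS.forward
    primer_reverse: str = DEFAULT_PRIMERS.reverse
    max_mismatch: int = 2
    enzyme_site: str = HHAI_SITE
    enzyme_offset: int = HHAI_CUT_OFFSET
    tolerance_frac: float = 0.05
    threshold: float | None = None
    min_run: int = DEFAULT_MIN_RUN
    mask_path: str | None = None
    host_16s_path: str | None = None
    seed: int = 0
    outdir: str = "tetrascan_out"
    figures: bool = True

    @classmethod
    def from_yaml(cls, path: str | None, **overrides) -> "RunConfig":
        data: dict = {}
        if path:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        WindowSpec(self.window, self.step, self.mode)  # raises on bad values
        for label, p in (("mask", self.mask_path), ("host 16S", self.host_16s_path)):
            if p is not None and not os.path.exists(p):
                raise FileNotFoundError(f"{label} file not found: {p}")

    @property
    def window_spec(self) -> WindowSpec:
        return WindowSpec(self.window, self.step, self.mode)

    @property
    def primers(self) -> PrimerPair:
        return PrimerPair(self.primer_forward, self.primer_reverse, max_mismatch=self.max_mismatch)


def _fmt(x: float) -> str:
    return f"{x:.6f}"


def write_matrix_tsv(matrix: CorrelationMatrix, path: str) -> None:
    labels = [f"{w.start}-{w.end}" for w in matrix.windows]
    with open(path, "w") as fh:
        fh.write("window\t" + "\t".join(labels) + "\n")
        for label, row in zip(labels, matrix.r):
            fh.write(label + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


def write_windows_tsv(
    matrix: CorrelationMatrix, path: str, mask: list[FeatureInterval] | None = None
) -> None:
    scores, masked = window_scores(matrix, mask)
    with open(path, "w") as fh:
        fh.write("index\tstart\tend\tmean_r_vs_rest\tmasked\n")
        for w, s, m in zip(matrix.windows, scores, masked):
            val = "NA" if not np.isfinite(s) else _fmt(s)
            fh.write(f"{w.index}\t{w.start}\t{w.end}\t{val}\t{int(m)}\n")


def write_regions_bed(regions, path: str) -> None:
    """Called regions as BED (0-based half-open, converted here)."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions, 1):
            fh.write(
                f"{r.seq_id}\t{r.start - 1}\t{r.end}\tlow_corr_{i}\t"
                f"{_fmt(r.mean_r_inside)}\n"
            )


def write_clone_summaries(summaries: list[CloneSummary], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tlength\tgc_percent\tn_orfs\tcoding_percent\tmean_r\tsd_r\n")
        for s in summaries:
            fh.write(
                f"{s.seq_id}\t{s.length}\t{s.gc_percent:.1f}\t{s.n_orfs}\t"
                f"{s.coding_percent:.1f}\t{_fmt(s.mean_r)}\t{_fmt(s.sd_r)}\n"
            )


def _sidecar_intervals(fasta_path: str, lengths: dict[str, int]) -> list[FeatureInterval]:
    base, _ = os.path.splitext(fasta_path)
    gff = base + ".gff3"
    if os.path.exists(gff):
        return read_intervals(gff, "gff3", lengths)
    return []


def run_pipeline(config: RunConfig, fasta_paths: list[str]) -> dict:
    """Run scan (+ optional screen) and summarize over a set of clones.

    Returns the manifest dictionary (also written to the output tree).
    Any stage failure aborts with the stage name and offending input id.
    """
    config.validate()
    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    explicit_mask = (
        read_intervals(config.mask_path, "gff3") if config.mask_path else None
    )
    control = None
    if config.host_16s_path:
        host16s = read_fasta(config.host_16s_path)[0]
        control = digest(
            host16s.seq, config.enzyme_site, config.enzyme_offset, amplicon_id=host16s.id
        )

    summaries: list[CloneSummary] = []
    matrices: list[CorrelationMatrix] = []
    screen_rows: list[tuple] = []
    for path in fasta_paths:
        for record in read_fasta(path):
            stage = "scan"
            try:
                log.info("[%s] start %s (%d bp)", stage, record.id, len(record.seq))
                intervals = _sidecar_intervals(path, {record.id: len(record.seq)})
                mask = explicit_mask
                if mask is None:
                    mask = [iv for iv in intervals if iv.kind == "rRNA"] or None
                matrix = correlation_matrix(record, config.window_spec)
                matrices.append(matrix)
                regions = call_low_correlation_regions(
                    matrix, threshold=config.threshold, min_run=config.min_run, mask=mask
                )
                write_matrix_tsv(matrix, os.path.join(outdir, f"{record.id}.matrix.tsv"))
                write_windows_tsv(
                    matrix, os.path.join(outdir, f"{record.id}.windows.tsv"), mask
                )
                write_regions_bed(regions, os.path.join(outdir, f"{record.id}.regions.bed"))
                if config.figures:
                    render_heatmap(
                        matrix,
                        os.path.join(outdir, "figures", f"{record.id}.heatmap.png"),
                        intervals or None,
                    )
                summaries.append(build_summary(record, intervals, matrix))
                log.info(
                    "[%s] done %s: %d windows, mean_r=%.3f, %d region(s)",
                    stage, record.id, len(matrix.windows), matrix.mean_r, len(regions),
                )
                if control is not None:
                    stage = "screen"
                    log.info("[%s] start %s", stage, record.id)
                    result = screen_clone(
                        record,
                        config.primers,
                        control,
                        config.enzyme_site,
                        config.enzyme_offset,
                        config.tolerance_frac,
                    )
                    coords = (
                        f"{result.amplicons[0].start}-{result.amplicons[0].end}"
                        if result.amplicons
                        else "NA"
                    )
                    frags = (
                        ",".join(map(str, result.profiles[0].fragment_lengths))
                        if result.profiles
                        else "NA"
                    )
                    screen_rows.append((record.id, result.verdict, coords, frags))
                    log.info("[%s] done %s: %s", stage, record.id, result.verdict)
            except Exception as exc:
                raise RuntimeError(f"stage {stage!r} failed on {record.id!r}: {exc}") from exc

    stage = "summarize"
    write_clone_summaries(summaries, os.path.join(outdir, "clones.tsv"))
    report = None
    with_cds = [s for s in summaries if s.n_orfs > 0]
    if len(with_cds) >= 3:
        try:
            report = correlate_clones(with_cds, "coding_percent", "mean_r")
            with open(os.path.join(outdir, "correlation_report.tsv"), "w") as fh:
                fh.write("n\tr\tp\tvariable_x\tvariable_y\n")
                fh.write(
                    f"{report.n}\t{_fmt(report.r)}\t{_fmt(report.p)}\t"
                    f"{report.variable_x}\t{report.variable_y}\n"
                )
        except ValueError as exc:
            log.warning("[%s] correlation skipped: %s", stage, exc)
    if screen_rows:
        with open(os.path.join(outdir, "screen.tsv"), "w") as fh:
            fh.write("seq_id\tverdict\tamplicon\tfragments\n")
            for row in screen_rows:
                fh.write("\t".join(row) + "\n")
    if config.figures and matrices:
        render_boxplot_summary(matrices, os.path.join(outdir, "figures", "boxplot.png"))

    manifest = {
        "tetrascan_version": __version__,
        "numpy_version": np.__version__,
        "scipy_version": scipy.__version__,
        "config": dataclasses.asdict(config),
        "inputs": [os.path.basename(p) for p in fasta_paths],
        "n_clones": len(summaries),
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
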