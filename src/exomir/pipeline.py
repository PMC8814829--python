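"""End-to-end orchestration: simulate → qc → quant → de → annotate → targets.

:func:`run_pipeline` executes the stages in order against either a
user-supplied sample sheet + references or (by default) a synthetic
dataset generated from the config seed, writes every result table as
TSV under the output directory, and records a :class:`RunManifest` with
SHA-256 hashes of all outputs.  Outputs are deterministic for a fixed
config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotation import assign_families, clusters_table, families_table, find_clusters
from .differential import run_differential
from .io import read_fastq
from .quantify import CountMatrix, align_reads, count_mature, mapping_stats
from .readqc import ContaminantIndex, clean_library
from .simulate import ADAPTER, default_truth, make_reference, simulate_libraries
from .targets import predict_targets, summarize_targets

__all__ = ["PipelineConfig", "RunManifest", "ConfigError", "run_pipeline", "validate_formats"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    """All thresholds and paths for one pipeline run.

    Threshold defaults are the analysis contract: length bounds 18/34 nt,
    α = 0.05, fold tiers 2× and 10×, 10 kb cluster gap, ΔG < −20 kcal/mol.
    """

    out_dir: str = "exomir_run"
    seed: int = 0
    adapter: str = ADAPTER
    min_len: int = 18
    max_len: int = 34
    alpha: float = 0.05
    fc2: float = 2.0
    fc10: float = 10.0
    max_gap: int = 10_000
    dg_max: float = -20.0
    pseudo_reads: float = 0.5
    condition_a: str = "milk"
    condition_b: str = "exosome"
    # synthetic-data knobs (used when no sample sheet is supplied)
    n_hairpins: int = 30
    n_utrs: int = 10
    depth: int = 20_000
    n_replicates: int = 3
    dispersion: float = 0.05

    def validate(self) -> None:
        if not (0 < self.min_len <= self.max_len):
            raise ConfigError("length bounds require 0 < min_len <= max_len")
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must lie in (0, 1)")
        if not (self.fc10 >= self.fc2 > 1):
            raise ConfigError("fold tiers require fc10 >= fc2 > 1")
        if self.max_gap < 0:
            raise ConfigError("max_gap must be >= 0")
        if self.dg_max >= 0:
            raise ConfigError("dg_max must be negative (kcal/mol)")
        if self.pseudo_reads <= 0:
            raise ConfigError("pseudo_reads must be > 0")
        if min(self.n_hairpins, self.n_utrs, self.n_replicates) < 1 or self.depth < 0:
            raise ConfigError("synthetic-data sizes must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg


@dataclass
class RunManifest:
    """Stage-by-stage record of one run: outputs, hashes, config snapshot."""

    version: str
    config: dict
    started: str
    stages: list[dict] = field(default_factory=list)

    def add_stage(self, name: str, outputs: dict[str, str]) -> None:
        self.stages.append(
            {
                "stage": name,
                "outputs": {
                    key: {"path": path, "sha256": _sha256(path)}
                    for key, path in outputs.items()
                },
            }
        )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path) -> str:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return str(path)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every stage; any stage failure halts with stage context."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        version=__version__,
        config=asdict(config),
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )

    stage = "simulate"
    try:
        ref = make_reference(config.n_hairpins, config.n_utrs, seed=config.seed)
        truth = default_truth(
            ref,
            seed=config.seed,
            depth=config.depth,
            n_replicates=config.n_replicates,
            dispersion=config.dispersion,
        )
        sim = simulate_libraries(ref, truth, out / "libraries")
        manifest.add_stage(stage, {"truth": sim["truth"], "sample_sheet": sim["sample_sheet"]})

        stage = "qc"
        contaminants = ContaminantIndex(ref.contaminants)
        clean_by_sample = {}
        qc_rows = []
        for sample, info in sorted(sim["samples"].items()):
            reads, report = clean_library(
                info["fastq"],
                adapter=config.adapter,
                contaminants=contaminants,
                min_len=config.min_len,
                max_len=config.max_len,
            )
            clean_by_sample[sample] = reads
            qc_rows.append({"sample": sample, **report.to_dict()})
            logger.info("[qc] %s: %d -> %d reads", sample, report.input_reads, report.surviving_reads)
        qc_path = _write(pd.DataFrame(qc_rows), out / "qc_report.tsv")
        manifest.add_stage(stage, {"qc_report": qc_path})

        stage = "quant"
        parts = []
        for sample, reads in clean_by_sample.items():
            alignments, _ = align_reads((r.sequence for r in reads), ref.hairpins)
            parts.append(count_mature(alignments, ref.matures, sample=sample))
        cm = CountMatrix.concat(parts)
        counts_path = str(out / "counts.tsv")
        cm.counts.rename_axis("mirna").to_csv(counts_path, sep="\t")
        stats_path = _write(mapping_stats(cm), out / "mapping_stats.tsv")
        manifest.add_stage(stage, {"counts": counts_path, "mapping_stats": stats_path})

        stage = "de"
        labels = {s: info["condition"] for s, info in sim["samples"].items()}
        results, volcano = run_differential(
            cm,
            labels,
            condition_a=config.condition_a,
            condition_b=config.condition_b,
            alpha=config.alpha,
            fc2=config.fc2,
            fc10=config.fc10,
            pseudo_reads=config.pseudo_reads,
        )
        de_path = _write(results, out / "de_results.tsv")
        volcano_path = _write(volcano, out / "volcano.tsv")
        manifest.add_stage(stage, {"de_results": de_path, "volcano": volcano_path})

        stage = "annotate"
        up = set(results.loc[results["mark2"] == "UP", "mirna"])
        up_matures = [m for m in ref.matures if m.name in up]
        up_hairpins = {m.hairpin for m in up_matures}
        intervals = [h.genomic for h in ref.hairpins if h.name in up_hairpins and h.genomic]
        clusters = find_clusters(intervals, max_gap=config.max_gap)
        families = assign_families(up_matures)
        clusters_path = _write(clusters_table(clusters), out / "clusters.tsv")
        families_path = _write(families_table(families), out / "families.tsv")
        manifest.add_stage(stage, {"clusters": clusters_path, "families": families_path})

        stage = "targets"
        sites = predict_targets(
            {m.name: m.sequence for m in up_matures}, ref.utrs, dg_max=config.dg_max
        )
        summary = summarize_targets(sites)
        sites_df = pd.DataFrame(
            [
                {
                    "mirna": s.mirna, "gene": s.gene, "transcript": s.transcript,
                    "start": s.start, "end": s.end, "site_class": s.site_class,
                    "dg_kcal_mol": s.dg,
                }
                for s in sites
            ],
            columns=["mirna", "gene", "transcript", "start", "end", "site_class", "dg_kcal_mol"],
        )
        sites_path = _write(sites_df, out / "target_sites.tsv")
        summary_path = _write(summary.per_gene, out / "target_summary.tsv")
        hist_path = _write(summary.histogram, out / "target_histogram.tsv")
        manifest.add_stage(
            stage,
            {"sites": sites_path, "summary": summary_path, "histogram": hist_path},
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest.write(out / "run_manifest.json")
    return manifest


# ------------------------------------------------------------- validation


def validate_formats(paths: dict[str, str]) -> list[dict]:
    """Light structural validation of input files.

    ``paths`` maps kind ('fastq' | 'fasta' | 'gff3' | 'bed') to a path.
    Returns one report dict per file: {path, kind, ok, message}.
    """
    reports = []
    for kind, path in paths.items():
        ok, message = True, "ok"
        try:
            if kind == "fastq":
                for _ in read_fastq(path):
                    pass
            elif kind == "fasta":
                with open(path) as fh:
                    saw_header = False
                    for lineno, line in enumerate(fh, start=1):
                        if line.startswith(">"):
                            saw_header = True
                        elif not saw_header and line.strip():
                            raise ValueError(f"{path}:{lineno}: sequence before header")
            elif kind == "gff3":
                with open(path) as fh:
                    for lineno, line in enumerate(fh, start=1):
                        line = line.rstrip("\n")
                        if not line or line.startswith("#"):
                            continue
                        fields = line.split("\t")
                        if len(fields) != 9:
                            raise ValueError(f"{path}:{lineno}: expected 9 columns")
                        if int(fields[3]) > int(fields[4]):
                            raise ValueError(f"{path}:{lineno}: start > end")
            elif kind == "bed":
                with open(path) as fh:
                    for lineno, line in enumerate(fh, start=1):
                        line = line.rstrip("\n")
                        if not line or line.startswith(("#", "track", "browser")):
                            continue
                        fields = line.split("\t")
                        if len(fields) < 6:
                            raise ValueError(f"{path}:{lineno}: expected >= 6 columns")
                        if int(fields[1]) >= int(fields[2]):
                            raise ValueError(f"{path}:{lineno}: start >= end")
            else:
                ok, message = False, f"unknown kind {kind!r}"
        except Exception as exc:  # reporting operation: never raises
            ok, message = False, str(exc)
        reports.append({"path": str(path), "kind": kind, "ok": ok, "message": message})
    return reports
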