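"""End-to-end driver: scan -> score -> landscape stats, with a run manifest.

``run_pipeline`` consumes a FASTA of transcript sequences, a counts TSV
and a sample sheet, and writes the motif BED/feature table, the
enrichment table, a stats report (regressions, top/bottom contrasts,
ligand-list overlap) and a JSON manifest recording the package version,
thresholds, seed and input checksums. Each stage logs to stderr and a
failure aborts with the stage name.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import io as g4io
from .enrichment import (
    ABUNDANT_MEAN,
    DES_THRESHOLD,
    MIN_MEAN,
    PSEUDOCOUNT,
    EnrichmentTable,
    score_dataset,
)
from .landscape import feature_regression, list_overlap, top_bottom_comparison
from .motifs import TranscriptRecord, get_preset, scan_pg4, scan_pg4_both_strands

logger = logging.getLogger("g4rp")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Paths, thresholds and flags for one pipeline run."""

    fasta: str
    counts: str
    samples: str
    out_dir: str
    presets: tuple[str, ...] = ("G3L1-7", "G3L1-5", "G2L1-10")
    reference: str = "untreated"
    pseudocount: float = PSEUDOCOUNT
    min_mean: float = MIN_MEAN
    abundant_mean: float = ABUNDANT_MEAN
    des_threshold: float = DES_THRESHOLD
    strict_abundant: bool = False
    welch: bool = False
    both_strands: bool = False
    pooled_input: bool = False
    des_mode: str = "es_ratio"
    regression_subset: str = "abundant"  # or "expressed"
    top_k: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pseudocount", "min_mean", "abundant_mean", "des_threshold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.regression_subset not in ("abundant", "expressed"):
            raise ValueError("regression_subset must be 'abundant' or 'expressed'")
        self.presets = tuple(self.presets)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["presets"] = list(self.presets)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if isinstance(d.get("presets"), list):
            d["presets"] = tuple(d["presets"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _stage(name: str):
    def decorator(fn):
        def wrapper(*args, **kwargs):
            logger.info("[%s] starting", name)
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:
                logger.error("[%s] failed: %s", name, exc)
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("[%s] done", name)
            return result

        return wrapper

    return decorator


@_stage("scan")
def _scan_stage(cfg: PipelineConfig, out: Path) -> list[TranscriptRecord]:
    sequences = g4io.read_fasta(cfg.fasta)
    records = [
        TranscriptRecord.from_sequence(rid, seq, presets=cfg.presets)
        for rid, seq in sequences
    ]
    scanner = scan_pg4_both_strands if cfg.both_strands else scan_pg4
    hits = []
    primary = get_preset(cfg.presets[0])
    for rid, seq in sequences:
        hits.extend(scanner(seq, primary, transcript_id=rid))
    g4io.write_features(records, out / "transcript_features.tsv")
    from .motifs import write_bed

    write_bed(hits, out / f"motifs_{primary.name}.bed")
    return records


@_stage("score")
def _score_stage(cfg: PipelineConfig, out: Path) -> EnrichmentTable:
    cm = g4io.read_counts(cfg.counts, cfg.samples)
    table = score_dataset(
        cm,
        reference=cfg.reference,
        pseudocount=cfg.pseudocount,
        min_mean=cfg.min_mean,
        abundant_mean=cfg.abundant_mean,
        des_threshold=cfg.des_threshold,
        strict_abundant=cfg.strict_abundant,
        pooled_input=cfg.pooled_input,
        des_mode=cfg.des_mode,
    )
    g4io.write_enrichment_table(table, out / "enrichment_table.tsv")
    return table


def landscape_report(
    table: EnrichmentTable,
    features: pd.DataFrame,
    presets: tuple[str, ...] = ("G3L1-7",),
    subset: str = "abundant",
    top_k: int = 100,
    welch: bool = False,
) -> dict:
    """Regressions, top/bottom contrasts and ligand-list overlap for a run.

    Regressions use the ``subset`` flag of the enrichment table (the
    abundant subset by default). Analyses that are undefined on the given
    data (too few genes, constant covariates) are reported as skipped
    rather than aborting the run.
    """
    frame = table.frame.join(features, how="inner")
    sub = frame[frame[subset]]
    report: dict = {"subset": subset, "n_subset": int(len(sub)), "analyses": {}}

    def _try(name, fn):
        try:
            report["analyses"][name] = fn()
        except ValueError as exc:
            report["analyses"][name] = {"skipped": str(exc)}

    ref = table.reference
    for feat in ("gc_fraction", "length", "mean_count"):
        _try(
            f"es_{ref}_vs_{feat}",
            lambda feat=feat: feature_regression(sub[f"es_{ref}"], sub[feat]).to_dict(),
        )
    for preset in presets:
        col = f"pg4_density_{preset}"
        if col in sub.columns:
            _try(
                f"es_{ref}_vs_{col}",
                lambda col=col: feature_regression(sub[f"es_{ref}"], sub[col]).to_dict(),
            )
    for lig in table.ligands:
        for feat in ("gc_fraction", "mean_count"):
            _try(
                f"des_{lig}_vs_{feat}",
                lambda lig=lig, feat=feat: feature_regression(
                    sub[f"des_{lig}"], sub[feat]
                ).to_dict(),
            )

    density_col = f"pg4_density_{presets[0]}"
    k = min(top_k, len(sub) // 2)
    if k >= 2 and density_col in sub.columns:
        ranked_es = sub.sort_values(
            [f"rank_es_{ref}"], kind="mergesort"
        ).index.tolist()
        report["analyses"][f"top_bottom_{density_col}_by_es"] = top_bottom_comparison(
            ranked_es, sub[density_col], k=k, equal_var=not welch
        ).to_dict()
        for lig in table.ligands:
            ranked_des = sub[sub[f"des_{lig}"].notna()].sort_values(
                [f"rank_des_{lig}"], kind="mergesort"
            ).index.tolist()
            if len(ranked_des) >= 2 * k:
                report["analyses"][f"top_bottom_{density_col}_by_des_{lig}"] = (
                    top_bottom_comparison(
                        ranked_des, sub[density_col], k=k, equal_var=not welch
                    ).to_dict()
                )
    if len(table.ligands) >= 2:
        a, b = table.ligands[0], table.ligands[1]
        ov = list_overlap(
            frame.index[frame[f"top_{a}"]], frame.index[frame[f"top_{b}"]]
        )
        report["analyses"][f"overlap_top_{a}_vs_{b}"] = ov.to_dict()
    return report


@_stage("stats")
def _stats_stage(cfg: PipelineConfig, out: Path, table: EnrichmentTable) -> dict:
    features = g4io.read_features(out / "transcript_features.tsv")
    report = landscape_report(
        table,
        features,
        presets=cfg.presets,
        subset=cfg.regression_subset,
        top_k=cfg.top_k,
        welch=cfg.welch,
    )
    g4io.write_json(report, out / "stats_report.json")
    return report


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute scan -> score -> stats and write the run manifest.

    Returns a dict with the output paths, the enrichment table and the
    stats report. Deterministic given identical inputs and config.
    """
    out = g4io.ensure_dir(cfg.out_dir)
    for name in ("fasta", "counts", "samples"):
        path = getattr(cfg, name)
        if not Path(path).exists():
            raise PipelineError(f"stage 'validate' failed: missing {name} file {path!r}")
    _scan_stage(cfg, out)
    table = _score_stage(cfg, out)
    report = _stats_stage(cfg, out, table)
    outputs = sorted(
        str(p.name) for p in out.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "g4rp_version": __version__,
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "inputs": {
            name: g4io.sha256_file(getattr(cfg, name))
            for name in ("fasta", "counts", "samples")
        },
        "outputs": {name: g4io.sha256_file(out / name) for name in outputs},
    }
    g4io.write_json(manifest, out / "manifest.json")
    return {"out_dir": str(out), "table": table, "report": report, "manifest": manifest}
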