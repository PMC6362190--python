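"""End-to-end pipeline: ingest -> aggregate -> normalize -> blank-filter ->
outlier test -> summarize -> cluster -> group comparison.

`run_pipeline` is deterministic given its inputs and writes every stage
output under a run directory with fixed file names, plus a manifest
recording parameters, input digests and per-stage timings.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .abundance import CountMatrix, aggregate_matrix, compute_hr
from .blank_filter import BlankFilterError, exclude_artifacts
from .cluster import cluster_hr, plot_heatmap
from .detect import (
    DEFAULT_HR_THRESHOLD,
    DEFAULT_PSEUDOCOUNT,
    DEFAULT_Q_THRESHOLD,
    DEFAULT_SD_FLOOR,
    call_candidates,
    per_sample_candidate_lists,
    summarize_candidates,
)
from .group_stats import group_fraction_comparison
from .ingest import ReferenceCatalog, count_sam_file
from .taxonomy import TaxonomyTree, rank_summary

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Paths and stage parameters for one pipeline run."""

    alignments_dir: str
    catalog: str
    taxonomy_nodes: str
    taxonomy_names: str
    taxonomy_seqmap: str
    samples: str  # TSV: sample_id, group, run, hq_pairs
    out_dir: str
    mapq_min: int = 10
    ranks: tuple[str, ...] = ("genus", "family")
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    q_threshold: float = DEFAULT_Q_THRESHOLD
    hr_threshold: float = DEFAULT_HR_THRESHOLD
    read_min: int = 100
    sd_floor: float = DEFAULT_SD_FLOOR
    bh_family: str = "per-sample"
    apply_blank_filter: bool = True
    blank_scope: str = "global"
    make_heatmap: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "ranks" in raw:
            raw["ranks"] = tuple(raw["ranks"])
        return cls(**raw)

    def validate(self) -> None:
        for name in ("alignments_dir", "catalog", "taxonomy_nodes",
                     "taxonomy_names", "taxonomy_seqmap", "samples"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")
        if self.mapq_min < 0:
            raise ValueError(f"mapq_min must be >= 0, got {self.mapq_min}")
        if self.pseudocount <= 0:
            raise ValueError(f"pseudocount must be > 0, got {self.pseudocount}")
        if not 0 < self.q_threshold <= 1:
            raise ValueError(f"q_threshold must be in (0, 1], got {self.q_threshold}")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest dictionary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "parameters": {k: v for k, v in asdict(config).items()},
        "inputs": {},
        "stages": {},
    }
    for name in ("catalog", "taxonomy_nodes", "taxonomy_names", "taxonomy_seqmap", "samples"):
        manifest["inputs"][name] = _sha256(getattr(config, name))

    def stage(name):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                dt = time.perf_counter() - self_inner.t0
                if exc is not None:
                    logger.error("stage %s failed after %.2fs: %s", name, dt, exc)
                    raise PipelineError(f"stage {name!r} failed: {exc}") from exc
                manifest["stages"][name] = {"seconds": round(dt, 3)}
                logger.info("stage %s: done in %.2fs", name, dt)

        return _Timer()

    # ---------------------------------------------------------------- ingest
    with stage("ingest"):
        catalog = ReferenceCatalog.read(config.catalog)
        meta = pd.read_csv(config.samples, sep="\t", index_col="sample_id")
        summaries = []
        for sample in meta.index:
            sam_path = Path(config.alignments_dir) / f"{sample}.sam"
            if not sam_path.exists():
                raise FileNotFoundError(f"no alignment file for sample {sample!r}: {sam_path}")
            s = count_sam_file(
                sam_path,
                catalog,
                mapq_min=config.mapq_min,
                sample_id=str(sample),
                hq_pairs=int(meta.loc[sample, "hq_pairs"]),
            )
            summaries.append(s)
        cm_seq = CountMatrix.from_summaries(summaries, meta, catalog.sequence_ids)
        cm_seq.write(out / "counts_sequence.tsv", out / "samples.tsv")
        tallies = {s.sample_id: s.tallies() for s in summaries}
        (out / "ingest_tallies.json").write_text(json.dumps(tallies, indent=2))
        manifest["stages"].setdefault("ingest", {})
        total_excluded = sum(t["mapq_filtered_pairs"] for t in tallies.values())
        logger.info("pairs excluded by MAPQ across samples: %d", total_excluded)

    with stage("taxonomy"):
        tree = TaxonomyTree.read(
            config.taxonomy_nodes, config.taxonomy_names, config.taxonomy_seqmap
        )

    rank_matrices: dict[str, CountMatrix] = {}
    results: dict[str, dict] = {}
    for rank in config.ranks:
        with stage(f"aggregate:{rank}"):
            cm_rank, unranked = aggregate_matrix(cm_seq, tree, rank)
            cm_rank.write(out / f"counts_{rank}.tsv", out / f"samples_{rank}.tsv")
            rank_matrices[rank] = cm_rank
        with stage(f"normalize:{rank}"):
            hr = compute_hr(cm_rank)
            hr.write(out / f"hr_{rank}.tsv", out / f"samples_hr_{rank}.tsv")
        if config.apply_blank_filter:
            with stage(f"blank-filter:{rank}"):
                hr, report = exclude_artifacts(hr, scope=config.blank_scope)
                report.write(out / f"exclusion_report_{rank}.tsv")
        else:
            logger.warning("blank filter bypassed for rank %s", rank)
        with stage(f"detect:{rank}"):
            table = call_candidates(
                hr,
                q_threshold=config.q_threshold,
                hr_threshold=config.hr_threshold,
                pseudocount=config.pseudocount,
                sd_floor=config.sd_floor,
                family=config.bh_family,
            )
            table.to_csv(out / f"candidates_{rank}.tsv", sep="\t", index=False)
            summary = summarize_candidates(
                table, cm_rank, read_min=config.read_min, q_threshold=config.q_threshold
            )
            summary.to_csv(out / f"candidate_summary_{rank}.tsv", sep="\t", index=False)
            per_sample = per_sample_candidate_lists(table)
            per_sample.to_csv(out / f"per_sample_candidates_{rank}.tsv", sep="\t", index=False)
            results[rank] = {
                "n_candidate_pairs": int(table["is_candidate"].sum()),
                "n_candidate_taxa": int(table.loc[table["is_candidate"], "taxon_id"].nunique()),
            }
        cand_taxa = sorted(table.loc[table["is_candidate"], "taxon_id"].unique())
        if len(cand_taxa) >= 2:
            with stage(f"cluster:{rank}"):
                display = hr.samples_in_group("MS") + hr.samples_in_group("control")
                clust = cluster_hr(
                    hr, taxa=cand_taxa, samples=display, pseudocount=config.pseudocount
                )
                clust.write(out, prefix=f"cluster_{rank}")
                if config.make_heatmap:
                    plot_heatmap(clust, out / f"heatmap_{rank}.png")
        else:
            logger.info("rank %s: fewer than 2 candidate taxa, skipping clustering", rank)

    with stage("rank-summary"):
        summary_df = rank_summary({"sequence": cm_seq, **rank_matrices})
        summary_df.to_csv(out / "rank_summary.tsv", sep="\t", index=False)

    with stage("group-stats"):
        comparison = group_fraction_comparison(cm_seq, "MS", "control")
        comparison.write(out / "group_comparison.json")
        results["group_comparison"] = {
            "mean_MS": comparison.mean_a,
            "mean_control": comparison.mean_b,
            "p": comparison.p,
        }

    manifest["results"] = results
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
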