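"""Taxa x samples count matrices and pairs-per-million normalization.

Sequencing depth differs between libraries, so raw concordant-pair counts are
normalized to hit rates (HR) in pairs per million (PPM): the count divided by
the sample's total high-quality read pairs, in millions.  The denominator is
the total HQ-pair yield of the library (including human-mapping pairs), taken
from upstream QC metadata, never recomputed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .ingest import SampleAlignmentSummary
from .taxonomy import TaxonomyTree, UnknownNodeError, UnknownRankError, RANKS

__all__ = [
    "GROUPS",
    "CountMatrix",
    "HRMatrix",
    "compute_hr",
    "microbial_fraction",
    "aggregate_matrix",
]

GROUPS = ("MS", "control", "OND", "blank")

_REL_TOL = 1e-9


def _validate_axes(
    values: pd.DataFrame, hq_pairs: pd.Series, meta: pd.DataFrame
) -> None:
    if list(values.columns) != list(hq_pairs.index):
        raise ValueError("hq_pairs index does not match matrix samples")
    if list(values.columns) != list(meta.index):
        raise ValueError("metadata index does not match matrix samples")
    bad = hq_pairs[~(hq_pairs > 0)]
    if len(bad):
        raise ValueError(
            "nonpositive hq_pairs for sample(s): " + ", ".join(map(str, bad.index))
        )
    for col in ("group", "run"):
        if col not in meta.columns:
            raise ValueError(f"sample metadata lacks required column {col!r}")
        if meta[col].isna().any():
            missing = meta.index[meta[col].isna()]
            raise ValueError(
                f"{col} undefined for sample(s): " + ", ".join(map(str, missing))
            )
    unknown = set(meta["group"]) - set(GROUPS)
    if unknown:
        raise ValueError(
            f"unknown group label(s) {sorted(unknown)}; expected one of {GROUPS}"
        )


@dataclass
class CountMatrix:
    """Concordant-pair counts for taxa (rows) by samples (columns), with the
    per-sample HQ-pair totals and group / sequencing-run metadata needed by
    normalization, the blank filter and the outlier test.

    ``rank`` labels the taxonomic level of the rows (``sequence`` for the
    per-reference matrix produced by ingestion).
    """

    counts: pd.DataFrame
    hq_pairs: pd.Series
    meta: pd.DataFrame
    rank: str = "sequence"

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        _validate_axes(self.counts, self.hq_pairs, self.meta)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.index)

    def samples_in_group(self, group: str, run: int | None = None) -> list[str]:
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
        mask = self.meta["group"] == group
        if run is not None:
            mask &= self.meta["run"] == run
        return list(self.meta.index[mask])

    # ------------------------------------------------------------------ I/O

    def write(self, matrix_path: str | Path, samples_path: str | Path) -> None:
        out = self.counts.copy()
        out.index.name = "taxon_id"
        out.to_csv(matrix_path, sep="\t")
        meta = self.meta.copy()
        meta["hq_pairs"] = self.hq_pairs
        meta.index.name = "sample_id"
        meta.to_csv(samples_path, sep="\t")

    @classmethod
    def read(
        cls,
        matrix_path: str | Path,
        samples_path: str | Path,
        rank: str = "sequence",
    ) -> "CountMatrix":
        counts = pd.read_csv(matrix_path, sep="\t", index_col=0)
        counts.index = counts.index.astype(str)
        meta = pd.read_csv(samples_path, sep="\t", index_col=0)
        meta.index = meta.index.astype(str)
        meta = meta.loc[list(counts.columns)]
        hq = meta.pop("hq_pairs")
        return cls(counts, hq, meta, rank=rank)

    @classmethod
    def from_summaries(
        cls,
        summaries: Iterable[SampleAlignmentSummary],
        meta: pd.DataFrame,
        sequence_ids: Mapping[str, str] | None = None,
    ) -> "CountMatrix":
        """Assemble the sequence-level matrix from per-sample ingest output.

        ``sequence_ids`` optionally maps reference ids to taxonomy sequence
        ids (identity when omitted).  ``meta`` must be indexed by sample id
        with columns ``group``, ``run``; HQ-pair totals come from each
        summary (or a ``hq_pairs`` metadata column as fallback).
        """
        summaries = list(summaries)
        cols = {}
        hq = {}
        for s in summaries:
            remap: dict[str, int] = {}
            for ref, n in s.counts.items():
                seq = sequence_ids.get(ref, ref) if sequence_ids else ref
                remap[seq] = remap.get(seq, 0) + n
            cols[s.sample_id] = remap
            if s.hq_pairs is not None:
                hq[s.sample_id] = s.hq_pairs
            elif "hq_pairs" in meta.columns:
                hq[s.sample_id] = int(meta.loc[s.sample_id, "hq_pairs"])
            else:
                raise ValueError(f"no hq_pairs known for sample {s.sample_id!r}")
        counts = pd.DataFrame(cols).fillna(0).astype(int)
        counts = counts.sort_index()
        order = [s.sample_id for s in summaries]
        counts = counts[order]
        meta = meta.loc[order, ["group", "run"]]
        return cls(counts, pd.Series(hq)[order], meta)


@dataclass
class HRMatrix:
    """Normalized hit rates in PPM, same axes and metadata as the count
    matrix they came from."""

    hr: pd.DataFrame
    hq_pairs: pd.Series
    meta: pd.DataFrame
    rank: str = "sequence"

    def __post_init__(self) -> None:
        _validate_axes(self.hr, self.hq_pairs, self.meta)

    @property
    def samples(self) -> list[str]:
        return list(self.hr.columns)

    @property
    def taxa(self) -> list[str]:
        return list(self.hr.index)

    samples_in_group = CountMatrix.samples_in_group

    def write(self, matrix_path: str | Path, samples_path: str | Path) -> None:
        out = self.hr.copy()
        out.index.name = "taxon_id"
        out.to_csv(matrix_path, sep="\t")
        meta = self.meta.copy()
        meta["hq_pairs"] = self.hq_pairs
        meta.index.name = "sample_id"
        meta.to_csv(samples_path, sep="\t")


def compute_hr(cm: CountMatrix) -> HRMatrix:
    """Elementwise ``counts / hq_pairs * 1e6`` -> PPM hit rates."""
    hr = cm.counts.astype(float).div(cm.hq_pairs.astype(float), axis=1) * 1e6
    return HRMatrix(hr, cm.hq_pairs, cm.meta, rank=cm.rank)


def microbial_fraction(cm: CountMatrix, sample_id: str) -> float:
    """Total microbial concordant pairs of one sample over its HQ pairs,
    in PPM."""
    if sample_id not in cm.counts.columns:
        raise KeyError(f"unknown sample {sample_id!r}")
    return float(cm.counts[sample_id].sum()) / float(cm.hq_pairs[sample_id]) * 1e6


def aggregate_matrix(
    cm: CountMatrix, tree: TaxonomyTree, rank: str
) -> tuple[CountMatrix, pd.DataFrame]:
    """Aggregate a sequence-level matrix to ``rank``.

    Returns the rank-level matrix plus a DataFrame of rows for sequences
    unranked at that level (conserving total mass).  Aggregation always
    starts from the sequence level so that analyses at different ranks stay
    independent of one another.
    """
    if cm.rank != "sequence":
        raise ValueError(
            f"aggregation starts from the sequence-level matrix, got rank {cm.rank!r}"
        )
    if rank not in RANKS:
        raise UnknownRankError(rank)
    missing = [s for s in cm.taxa if s not in tree.sequence_to_node]
    if missing:
        raise UnknownNodeError(
            "sequence ids missing from taxonomy: " + ", ".join(sorted(missing))
        )
    mapping = {seq: tree.sequence_ancestor(seq, rank) for seq in cm.taxa}
    ranked = [s for s, t in mapping.items() if t is not None]
    unranked = [s for s, t in mapping.items() if t is None]
    agg = (
        cm.counts.loc[ranked]
        .groupby([mapping[s] for s in ranked])
        .sum()
        .sort_index()
        if ranked
        else cm.counts.iloc[0:0]
    )
    out = CountMatrix(agg.astype(int), cm.hq_pairs, cm.meta, rank=rank)
    return out, cm.counts.loc[unranked]
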