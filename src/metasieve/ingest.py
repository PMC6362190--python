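"""Filtered concordant-pair counting from paired-end alignment records.

A read pair contributes one count to a microbial reference sequence iff both
mates align to that same reference (a concordant pair), the reference is
microbial (not human or PhiX spike-in), and both mates pass the MAPQ cutoff.
MAPQ is Phred-scaled, so a single retained mate at MAPQ >= 10 has a > 90%
probability of being correctly placed and a concordant pair at that cutoff a
> 99% probability.  Pairs touching a human or PhiX reference are tallied
separately and excluded from microbial counts; every input pair lands in
exactly one bucket of the partition tally.

Secondary and supplementary alignment records are ignored throughout: the
expected input is single-best-hit aligner output where each mate appears at
most once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
import pysam

__all__ = [
    "AlignmentRecord",
    "ReferenceCatalog",
    "SampleAlignmentSummary",
    "MalformedInputError",
    "count_concordant_pairs",
    "count_sam_file",
    "read_sam",
    "mapq_to_probability",
    "pair_probability",
    "coverage_profile",
]

SOURCE_CLASSES = ("human", "phix", "microbial")


class MalformedInputError(ValueError):
    """Structurally invalid alignment input."""


@dataclass(frozen=True)
class AlignmentRecord:
    """One aligned read mate.

    ``position`` is the 1-based leftmost coordinate (SAM convention); an
    unmapped mate carries ``unmapped=True`` and is never counted.
    """

    read_id: str
    mate: int  # 1 or 2
    reference_id: str | None
    position: int
    mapq: int
    sample_id: str = ""
    unmapped: bool = False

    def __post_init__(self) -> None:
        if self.mate not in (1, 2):
            raise MalformedInputError(f"mate index must be 1 or 2, got {self.mate}")
        if not 0 <= self.mapq <= 255:
            raise MalformedInputError(f"MAPQ {self.mapq} outside [0, 255]")
        if not self.unmapped and self.position < 1:
            raise MalformedInputError(
                f"mapped record {self.read_id!r} has position {self.position} < 1"
            )


@dataclass
class ReferenceCatalog:
    """Classification of every reference sequence in the alignment database.

    ``classes`` maps reference id -> one of ``human`` / ``phix`` /
    ``microbial``; microbial references additionally carry the taxonomy
    sequence id in ``sequence_ids`` and may carry a length (bp) used by
    coverage profiling.
    """

    classes: dict[str, str]
    sequence_ids: dict[str, str] = field(default_factory=dict)
    lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ref, cls in self.classes.items():
            if cls not in SOURCE_CLASSES:
                raise ValueError(
                    f"reference {ref!r} has unknown source class {cls!r}; "
                    f"expected one of {SOURCE_CLASSES}"
                )

    def write(self, path: str | Path) -> None:
        pd.DataFrame(
            [
                {
                    "reference_id": ref,
                    "source_class": cls,
                    "sequence_id": self.sequence_ids.get(ref, ""),
                    "length": self.lengths.get(ref, ""),
                }
                for ref, cls in self.classes.items()
            ]
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "ReferenceCatalog":
        df = pd.read_csv(path, sep="\t", dtype={"reference_id": str, "sequence_id": str})
        classes = dict(zip(df["reference_id"], df["source_class"]))
        seq_ids = {
            r.reference_id: r.sequence_id
            for r in df.itertuples()
            if isinstance(r.sequence_id, str) and r.sequence_id
        }
        lengths = {
            r.reference_id: int(r.length)
            for r in df.itertuples()
            if not pd.isna(r.length) and r.length != ""
        }
        return cls(classes, seq_ids, lengths)


@dataclass
class SampleAlignmentSummary:
    """Per-sample pair partition tallies and filtered per-reference counts.

    ``counts`` holds concordant microbial pairs passing the MAPQ filter, per
    reference sequence.  The tallies partition every input pair exactly once:
    ``unmapped + human + phix + discordant + orphan + mapq_filtered +
    microbial_postfilter == total``.
    """

    sample_id: str
    hq_pairs: int | None = None
    counts: dict[str, int] = field(default_factory=dict)
    total_pairs: int = 0
    unmapped_pairs: int = 0
    human_pairs: int = 0
    phix_pairs: int = 0
    discordant_pairs: int = 0
    orphan_pairs: int = 0
    mapq_filtered_pairs: int = 0

    @property
    def microbial_pairs_prefilter(self) -> int:
        """Concordant microbial pairs before the MAPQ cutoff."""
        return self.mapq_filtered_pairs + self.microbial_pairs_postfilter

    @property
    def microbial_pairs_postfilter(self) -> int:
        return sum(self.counts.values())

    def tallies(self) -> dict[str, int]:
        return {
            "total_pairs": self.total_pairs,
            "unmapped_pairs": self.unmapped_pairs,
            "human_pairs": self.human_pairs,
            "phix_pairs": self.phix_pairs,
            "discordant_pairs": self.discordant_pairs,
            "orphan_pairs": self.orphan_pairs,
            "mapq_filtered_pairs": self.mapq_filtered_pairs,
            "microbial_pairs_prefilter": self.microbial_pairs_prefilter,
            "microbial_pairs_postfilter": self.microbial_pairs_postfilter,
        }

    def write_counts(self, path: str | Path) -> None:
        pd.DataFrame(
            sorted(self.counts.items()),
            columns=["reference_id", "concordant_pairs"],
        ).to_csv(path, sep="\t", index=False)


def mapq_to_probability(mapq: int) -> float:
    """Probability that a single alignment at ``mapq`` is correctly placed,
    under the Phred convention: ``1 - 10**(-mapq / 10)``."""
    if mapq < 0:
        raise ValueError(f"MAPQ must be >= 0, got {mapq}")
    return 1.0 - 10.0 ** (-mapq / 10.0)


def pair_probability(mapq1: int, mapq2: int) -> float:
    """Probability that a concordant pair is correctly placed: the complement
    of both mates being mismapped, assuming independent mate errors."""
    if mapq1 < 0 or mapq2 < 0:
        raise ValueError(f"MAPQ must be >= 0, got ({mapq1}, {mapq2})")
    return 1.0 - 10.0 ** (-(mapq1 + mapq2) / 10.0)


def _group_pairs(
    records: Iterable[AlignmentRecord],
) -> Iterator[tuple[str, dict[int, AlignmentRecord]]]:
    by_read: dict[str, dict[int, AlignmentRecord]] = {}
    for rec in records:
        mates = by_read.setdefault(rec.read_id, {})
        if rec.mate in mates:
            raise MalformedInputError(
                f"multiple primary records for read {rec.read_id!r} mate {rec.mate}"
            )
        mates[rec.mate] = rec
    yield from by_read.items()


def count_concordant_pairs(
    records: Iterable[AlignmentRecord],
    catalog: ReferenceCatalog,
    mapq_min: int = 10,
    sample_id: str = "",
    hq_pairs: int | None = None,
) -> SampleAlignmentSummary:
    """Tally read pairs into the partition buckets and count concordant
    microbial pairs passing the MAPQ cutoff.

    Bucket precedence per pair: unmapped mate -> ``unmapped``; single mate
    present -> ``orphan``; any human mate -> ``human``; any PhiX mate ->
    ``phix``; mates on different references -> ``discordant``; concordant
    microbial with a sub-threshold mate -> ``mapq_filtered``; otherwise one
    count for the shared reference.
    """
    if mapq_min < 0:
        raise ValueError(f"mapq_min must be >= 0, got {mapq_min}")
    summary = SampleAlignmentSummary(sample_id=sample_id, hq_pairs=hq_pairs)
    for read_id, mates in _group_pairs(records):
        summary.total_pairs += 1
        recs = list(mates.values())
        for rec in recs:
            if not rec.unmapped and rec.reference_id not in catalog.classes:
                raise MalformedInputError(
                    f"reference {rec.reference_id!r} (read {read_id!r}) "
                    "absent from catalog"
                )
        if any(r.unmapped for r in recs):
            summary.unmapped_pairs += 1
            continue
        if len(recs) == 1:
            summary.orphan_pairs += 1
            continue
        classes = {catalog.classes[r.reference_id] for r in recs}
        if "human" in classes:
            summary.human_pairs += 1
            continue
        if "phix" in classes:
            summary.phix_pairs += 1
            continue
        r1, r2 = recs
        if r1.reference_id != r2.reference_id:
            summary.discordant_pairs += 1
            continue
        if r1.mapq < mapq_min or r2.mapq < mapq_min:
            summary.mapq_filtered_pairs += 1
            continue
        ref = r1.reference_id
        summary.counts[ref] = summary.counts.get(ref, 0) + 1
    return summary


def read_sam(path: str | Path, sample_id: str = "") -> Iterator[AlignmentRecord]:
    """Yield primary alignment records from a SAM file.

    Only QNAME, FLAG (mate / unmapped bits), RNAME, POS and MAPQ are used;
    secondary and supplementary records are skipped.
    """
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_secondary or aln.is_supplementary:
                continue
            mate = 2 if aln.is_read2 else 1
            if aln.is_unmapped:
                yield AlignmentRecord(
                    read_id=aln.query_name,
                    mate=mate,
                    reference_id=None,
                    position=0,
                    mapq=aln.mapping_quality,
                    sample_id=sample_id,
                    unmapped=True,
                )
            else:
                yield AlignmentRecord(
                    read_id=aln.query_name,
                    mate=mate,
                    reference_id=aln.reference_name,
                    position=aln.reference_start + 1,
                    mapq=aln.mapping_quality,
                    sample_id=sample_id,
                )


def count_sam_file(
    path: str | Path,
    catalog: ReferenceCatalog,
    mapq_min: int = 10,
    sample_id: str = "",
    hq_pairs: int | None = None,
) -> SampleAlignmentSummary:
    """Convenience wrapper: :func:`read_sam` piped into
    :func:`count_concordant_pairs`."""
    return count_concordant_pairs(
        read_sam(path, sample_id), catalog, mapq_min, sample_id, hq_pairs
    )


def coverage_profile(
    records: Iterable[AlignmentRecord],
    reference_id: str,
    bin_width: int,
    catalog: ReferenceCatalog,
    mapq_min: int = 0,
) -> pd.DataFrame:
    """Histogram of concordant pairs along one reference.

    Each counted pair contributes 1 to the bin containing the leftmost mapped
    position of the pair; bins of ``bin_width`` bp tile ``[1, length]``.
    The default ``mapq_min=0`` profiles all concordant pairs, the convention
    for genome-mapping figures made before quality filtering.
    """
    if bin_width < 1:
        raise ValueError(f"bin_width must be >= 1, got {bin_width}")
    if reference_id not in catalog.classes:
        raise MalformedInputError(f"unknown reference {reference_id!r}")
    if reference_id not in catalog.lengths:
        raise ValueError(f"no length recorded for reference {reference_id!r}")
    length = catalog.lengths[reference_id]
    n_bins = math.ceil(length / bin_width)
    counts = [0] * n_bins
    for read_id, mates in _group_pairs(records):
        recs = list(mates.values())
        if len(recs) != 2 or any(r.unmapped for r in recs):
            continue
        r1, r2 = recs
        if r1.reference_id != reference_id or r2.reference_id != reference_id:
            continue
        if r1.mapq < mapq_min or r2.mapq < mapq_min:
            continue
        left = min(r1.position, r2.position)
        counts[(left - 1) // bin_width] += 1
    return pd.DataFrame(
        {
            "bin_start": [1 + i * bin_width for i in range(n_bins)],
            "pairs": counts,
        }
    )
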