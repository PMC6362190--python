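"""Taxonomic hierarchy handling and count aggregation.

The reference catalog maps every microbial reference sequence to a node in a
rank-labeled parent-pointer tree.  Analyses run at a chosen rank (typically
genus or family), so per-sequence concordant-pair counts must be summed over
all sequences whose lineage passes through the same taxon at that rank.
Sequences whose lineage has no ancestor at the requested rank (e.g. viruses at
the phylum level) are reported in an explicit "unaggregated" bucket rather
than dropped, so total mass is conserved.

The on-disk format is a deliberate subset of the NCBI taxonomy dump layout:
a nodes TSV (node_id / parent_id / rank), a names TSV (node_id / name) and a
sequence-map TSV (sequence_id / node_id).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "RANKS",
    "TaxonNode",
    "TaxonomyTree",
    "TaxonomyError",
    "UnknownNodeError",
    "UnknownRankError",
    "aggregate_counts",
    "rank_summary",
]

#: Analyzed rank levels, most specific first.  Intermediate ranks present in
#: an input taxonomy but absent from this vocabulary are skipped during
#: ancestor walks.
RANKS: tuple[str, ...] = (
    "sequence",
    "species",
    "genus",
    "family",
    "order",
    "class",
    "phylum",
    "superkingdom",
)

_RANK_INDEX = {r: i for i, r in enumerate(RANKS)}


class TaxonomyError(ValueError):
    """Malformed taxonomy input (cycles, dangling parents, bad ranks)."""


class UnknownNodeError(KeyError):
    """A node or sequence id was not found in the tree."""


class UnknownRankError(ValueError):
    """A rank outside the analyzed vocabulary was requested."""

    def __init__(self, rank: str) -> None:
        super().__init__(
            f"unknown rank {rank!r}; valid ranks are {', '.join(RANKS)}"
        )
        self.rank = rank


@dataclass(frozen=True)
class TaxonNode:
    """One node of the taxonomy: an id, a display name, a rank label and a
    parent pointer (``None`` at a root)."""

    node_id: str
    name: str
    rank: str
    parent_id: str | None = None


class TaxonomyTree:
    """Rank-labeled parent-pointer tree plus a sequence -> node map.

    Construction validates that every parent pointer resolves, that parent
    walks terminate (no cycles), that ranks never invert along a lineage
    (a node's ranked ancestor is always less specific than the node), and
    that every reference sequence id maps to exactly one node.
    """

    def __init__(
        self,
        nodes: Iterable[TaxonNode],
        sequence_to_node: Mapping[str, str],
    ) -> None:
        self.nodes: dict[str, TaxonNode] = {}
        for node in nodes:
            if node.node_id in self.nodes:
                raise TaxonomyError(f"duplicate node id {node.node_id!r}")
            self.nodes[node.node_id] = node
        for node in self.nodes.values():
            if node.parent_id is not None and node.parent_id not in self.nodes:
                raise TaxonomyError(
                    f"node {node.node_id!r} has unknown parent {node.parent_id!r}"
                )
        self._check_acyclic_and_ordered()
        self.sequence_to_node: dict[str, str] = {}
        for seq_id, node_id in sequence_to_node.items():
            if node_id not in self.nodes:
                raise TaxonomyError(
                    f"sequence {seq_id!r} maps to unknown node {node_id!r}"
                )
            self.sequence_to_node[str(seq_id)] = str(node_id)

    def _check_acyclic_and_ordered(self) -> None:
        done: set[str] = set()
        for start in self.nodes:
            seen: list[str] = []
            cur: str | None = start
            while cur is not None and cur not in done:
                if cur in seen:
                    raise TaxonomyError(f"cycle in taxonomy at node {cur!r}")
                seen.append(cur)
                cur = self.nodes[cur].parent_id
            done.update(seen)
        # rank ordering: nearest ranked ancestor must be strictly less specific
        for node in self.nodes.values():
            if node.rank not in _RANK_INDEX:
                continue
            cur = node.parent_id
            while cur is not None:
                anc = self.nodes[cur]
                if anc.rank in _RANK_INDEX:
                    if _RANK_INDEX[anc.rank] <= _RANK_INDEX[node.rank]:
                        raise TaxonomyError(
                            f"rank inversion: {node.node_id!r} ({node.rank}) has "
                            f"ancestor {anc.node_id!r} ({anc.rank})"
                        )
                    break
                cur = anc.parent_id

    # ------------------------------------------------------------------ I/O

    @classmethod
    def read(
        cls,
        nodes_path: str | Path,
        names_path: str | Path,
        seqmap_path: str | Path,
    ) -> "TaxonomyTree":
        """Load a tree from nodes / names / sequence-map TSVs."""
        nodes_df = pd.read_csv(nodes_path, sep="\t", dtype=str)
        names_df = pd.read_csv(names_path, sep="\t", dtype=str)
        seq_df = pd.read_csv(seqmap_path, sep="\t", dtype=str)
        names = dict(zip(names_df["node_id"], names_df["name"]))
        nodes = [
            TaxonNode(
                node_id=row.node_id,
                name=names.get(row.node_id, row.node_id),
                rank=row.rank,
                parent_id=None if pd.isna(row.parent_id) else row.parent_id,
            )
            for row in nodes_df.itertuples()
        ]
        seqmap = dict(zip(seq_df["sequence_id"], seq_df["node_id"]))
        return cls(nodes, seqmap)

    def write(
        self,
        nodes_path: str | Path,
        names_path: str | Path,
        seqmap_path: str | Path,
    ) -> None:
        pd.DataFrame(
            [
                {"node_id": n.node_id, "parent_id": n.parent_id, "rank": n.rank}
                for n in self.nodes.values()
            ]
        ).to_csv(nodes_path, sep="\t", index=False)
        pd.DataFrame(
            [{"node_id": n.node_id, "name": n.name} for n in self.nodes.values()]
        ).to_csv(names_path, sep="\t", index=False)
        pd.DataFrame(
            [
                {"sequence_id": s, "node_id": n}
                for s, n in self.sequence_to_node.items()
            ]
        ).to_csv(seqmap_path, sep="\t", index=False)

    # ------------------------------------------------------------- queries

    def ancestor_at_rank(self, node_id: str, rank: str) -> str | None:
        """Return the id of the ancestor (or self) at ``rank``, or ``None``
        when the lineage has no node at that rank ("unranked at level").

        Raises :class:`UnknownNodeError` for an unknown node id and
        :class:`UnknownRankError` for a rank outside :data:`RANKS`.
        """
        if rank not in _RANK_INDEX:
            raise UnknownRankError(rank)
        if node_id not in self.nodes:
            raise UnknownNodeError(f"unknown node id {node_id!r}")
        target = _RANK_INDEX[rank]
        cur: str | None = node_id
        while cur is not None:
            node = self.nodes[cur]
            idx = _RANK_INDEX.get(node.rank)
            if idx is not None:
                if idx == target:
                    return cur
                if idx > target:
                    return None  # walked past the level without hitting it
            cur = node.parent_id
        return None

    def sequence_ancestor(self, sequence_id: str, rank: str) -> str | None:
        """Ancestor at ``rank`` for a reference sequence id."""
        if sequence_id not in self.sequence_to_node:
            raise UnknownNodeError(f"unknown sequence id {sequence_id!r}")
        return self.ancestor_at_rank(self.sequence_to_node[sequence_id], rank)

    def name(self, node_id: str) -> str:
        if node_id not in self.nodes:
            raise UnknownNodeError(f"unknown node id {node_id!r}")
        return self.nodes[node_id].name


def aggregate_counts(
    counts: Mapping[str, int],
    tree: TaxonomyTree,
    rank: str,
) -> tuple[dict[str, int], dict[str, int]]:
    """Sum per-sequence counts up to ``rank``.

    Returns ``(aggregated, unaggregated)`` where ``aggregated`` maps taxon id
    at the requested rank to the summed count and ``unaggregated`` holds, per
    sequence id, counts of sequences with no ancestor at that rank.  Total
    mass is conserved: ``sum(aggregated.values()) + sum(unaggregated.values())
    == sum(counts.values())`` in exact integer arithmetic.
    """
    if rank not in _RANK_INDEX:
        raise UnknownRankError(rank)
    missing = [s for s in counts if s not in tree.sequence_to_node]
    if missing:
        raise UnknownNodeError(
            "sequence ids missing from taxonomy: " + ", ".join(sorted(missing))
        )
    aggregated: dict[str, int] = {}
    unaggregated: dict[str, int] = {}
    for seq_id, count in counts.items():
        taxon = tree.sequence_ancestor(seq_id, rank)
        if taxon is None:
            unaggregated[seq_id] = unaggregated.get(seq_id, 0) + int(count)
        else:
            aggregated[taxon] = aggregated.get(taxon, 0) + int(count)
    return aggregated, unaggregated


def rank_summary(matrices: Mapping[str, "object"]) -> pd.DataFrame:
    """Count, per rank, the taxa with at least one aligned pair in at least
    one sample.

    ``matrices`` maps a rank label to a count matrix (anything exposing a
    ``counts`` DataFrame of taxa x samples).  All matrices must share one
    sample set.
    """
    sample_sets = {
        rank: tuple(m.counts.columns) for rank, m in matrices.items()
    }
    if len({frozenset(s) for s in sample_sets.values()}) > 1:
        raise ValueError("rank matrices do not share the same sample set")
    rows = []
    for rank, m in matrices.items():
        detected = int((m.counts.sum(axis=1) > 0).sum())
        rows.append({"rank": rank, "taxa_detected": detected})
    return pd.DataFrame(rows)
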