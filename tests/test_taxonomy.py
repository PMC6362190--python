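import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from metasieve.abundance import aggregate_matrix
from metasieve.simulate import SimulationConfig, generate_counts
from metasieve.taxonomy import (
    RANKS,
    TaxonNode,
    TaxonomyError,
    TaxonomyTree,
    UnknownNodeError,
    UnknownRankError,
    aggregate_counts,
    rank_summary,
)


class TestAncestorAtRank:
    @pytest.mark.parametrize(
        "node,rank,expected",
        [
            ("X", "genus", "X"),  # identity: node already at the rank
            ("gi1", "genus", "X"),  # walk up through species
            ("gi3", "family", "F2"),
            ("gi1", "phylum", "P1"),
            ("Vg", "genus", "Vg"),
            ("giv", "phylum", None),  # viral lineage has no phylum
            ("giv", "family", "VF"),
        ],
    )
    def test_lookup(self, toy_tree, node, rank, expected):
        assert toy_tree.ancestor_at_rank(node, rank) == expected

    def test_unknown_node_names_the_id(self, toy_tree):
        with pytest.raises(UnknownNodeError, match="nope"):
            toy_tree.ancestor_at_rank("nope", "genus")

    def test_unknown_rank_lists_valid_ranks(self, toy_tree):
        with pytest.raises(UnknownRankError, match="genus"):
            toy_tree.ancestor_at_rank("X", "tribe")

    def test_idempotent(self, toy_tree):
        for node in ("gi1", "gi2", "gi3", "giv"):
            for rank in ("species", "genus", "family"):
                anc = toy_tree.ancestor_at_rank(node, rank)
                if anc is not None:
                    assert toy_tree.ancestor_at_rank(anc, rank) == anc


class TestTreeValidation:
    def test_cycle_rejected(self):
        nodes = [
            TaxonNode("a", "a", "genus", "b"),
            TaxonNode("b", "b", "family", "a"),
        ]
        with pytest.raises(TaxonomyError, match="cycle"):
            TaxonomyTree(nodes, {})

    def test_dangling_parent_rejected(self):
        with pytest.raises(TaxonomyError, match="unknown parent"):
            TaxonomyTree([TaxonNode("a", "a", "genus", "ghost")], {})

    def test_rank_inversion_rejected(self):
        nodes = [
            TaxonNode("g", "g", "genus", None),
            TaxonNode("f", "f", "family", "g"),  # family below genus
        ]
        with pytest.raises(TaxonomyError, match="rank inversion"):
            TaxonomyTree(nodes, {})

    def test_sequence_mapping_to_unknown_node_rejected(self, toy_tree):
        with pytest.raises(TaxonomyError, match="ghost"):
            TaxonomyTree(list(toy_tree.nodes.values()), {"giX": "ghost"})

    def test_tsv_round_trip(self, toy_tree, tmp_path):
        toy_tree.write(tmp_path / "n.tsv", tmp_path / "na.tsv", tmp_path / "s.tsv")
        back = TaxonomyTree.read(tmp_path / "n.tsv", tmp_path / "na.tsv", tmp_path / "s.tsv")
        assert back.nodes == toy_tree.nodes
        assert back.sequence_to_node == toy_tree.sequence_to_node


def _brute_force_aggregate(counts, tree, rank):
    """Independent oracle: walk every sequence's parents by hand."""
    from metasieve.taxonomy import _RANK_INDEX

    agg, unagg = {}, {}
    for seq, c in counts.items():
        cur = tree.sequence_to_node[seq]
        hit = None
        while cur is not None:
            node = tree.nodes[cur]
            if node.rank == rank:
                hit = cur
                break
            cur = node.parent_id
        if hit is None:
            unagg[seq] = unagg.get(seq, 0) + c
        else:
            agg[hit] = agg.get(hit, 0) + c
    return agg, unagg


class TestAggregateCounts:
    def test_two_sequences_one_genus(self, toy_tree):
        agg, unagg = aggregate_counts({"gi1": 3, "gi2": 5}, toy_tree, "genus")
        assert agg == {"X": 8} and unagg == {}

    def test_empty(self, toy_tree):
        assert aggregate_counts({}, toy_tree, "genus") == ({}, {})

    def test_matches_parent_walk_oracle(self, toy_tree):
        counts = {"gi1": 4, "gi2": 6, "gi3": 1, "giv": 2}
        for rank in ("species", "genus", "family", "phylum"):
            assert aggregate_counts(counts, toy_tree, rank) == _brute_force_aggregate(
                counts, toy_tree, rank
            )

    def test_viral_counts_go_to_unaggregated_at_phylum(self, toy_tree):
        agg, unagg = aggregate_counts({"gi1": 1, "giv": 7}, toy_tree, "phylum")
        assert agg == {"P1": 1} and unagg == {"giv": 7}

    def test_missing_sequence_listed_in_error(self, toy_tree):
        with pytest.raises(UnknownNodeError, match="giZ"):
            aggregate_counts({"gi1": 1, "giZ": 2}, toy_tree, "genus")

    @settings(
        deadline=None,
        derandomize=True,
        suppress_health_check=[HealthCheck.function_scoped_fixture],
    )
    @given(
        counts=st.dictionaries(
            st.sampled_from(["gi1", "gi2", "gi3", "giv"]),
            st.integers(min_value=0, max_value=10_000),
        ),
        rank=st.sampled_from(["species", "genus", "family", "order", "phylum"]),
    )
    def test_conservation(self, toy_tree, counts, rank):
        agg, unagg = aggregate_counts(counts, toy_tree, rank)
        assert sum(agg.values()) + sum(unagg.values()) == sum(counts.values())


class TestRankSummary:
    def test_counts_taxa_with_any_signal(self):
        from types import SimpleNamespace

        genus = SimpleNamespace(
            counts=pd.DataFrame([[0, 0], [1, 2], [3, 4]], columns=["s1", "s2"])
        )
        out = rank_summary({"genus": genus})
        assert out.loc[out["rank"] == "genus", "taxa_detected"].item() == 2

    def test_all_zero_matrix(self):
        from types import SimpleNamespace

        m = SimpleNamespace(counts=pd.DataFrame(0, index=["a", "b"], columns=["s1"]))
        out = rank_summary({"genus": m, "family": m})
        assert (out["taxa_detected"] == 0).all()

    def test_species_collapse_to_genera(self):
        """5 detected species collapsing into 2 genera."""
        from types import SimpleNamespace

        species = SimpleNamespace(
            counts=pd.DataFrame({"s1": [1, 2, 1, 1, 3]}, index=list("abcde"))
        )
        genus = SimpleNamespace(counts=pd.DataFrame({"s1": [4, 4]}, index=["X", "Y"]))
        out = rank_summary({"species": species, "genus": genus}).set_index("rank")
        assert out.loc["species", "taxa_detected"] == 5
        assert out.loc["genus", "taxa_detected"] == 2

    def test_mismatched_samples_rejected(self):
        from types import SimpleNamespace

        a = SimpleNamespace(counts=pd.DataFrame({"s1": [1]}))
        b = SimpleNamespace(counts=pd.DataFrame({"s2": [1]}))
        with pytest.raises(ValueError, match="sample set"):
            rank_summary({"genus": a, "family": b})


def test_detected_taxa_monotone_down_the_ranks():
    """On fully ranked synthetic data the number of detected taxa cannot
    increase from species to phylum."""
    cfg = SimulationConfig(seed=11, branching=(3, 2, 1, 2, 3), hq_pairs=300_000,
                           n_spiked_genera=3, n_contaminant_genera=3)
    cm, tree, _ = generate_counts(cfg)
    detected = []
    for rank in ("species", "genus", "family", "order", "class", "phylum"):
        cm_rank, unranked = aggregate_matrix(cm, tree, rank)
        assert unranked.empty  # fully ranked taxonomy
        detected.append(int((cm_rank.counts.sum(axis=1) > 0).sum()))
    assert all(a >= b for a, b in zip(detected, detected[1:]))
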