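import numpy as np
import pandas as pd
import pytest

from metasieve.abundance import CountMatrix, HRMatrix
from metasieve.taxonomy import TaxonNode, TaxonomyTree


@pytest.fixture
def toy_tree() -> TaxonomyTree:
    """Two fully ranked genera (X with gi1+gi2, Y with gi3) plus a viral
    genus Vg whose lineage skips the phylum level entirely."""
    nodes = [
        TaxonNode("sk", "Bacteria", "superkingdom", None),
        TaxonNode("P1", "Phylum1", "phylum", "sk"),
        TaxonNode("C1", "Class1", "class", "P1"),
        TaxonNode("O1", "Order1", "order", "C1"),
        TaxonNode("F1", "Family1", "family", "O1"),
        TaxonNode("F2", "Family2", "family", "O1"),
        TaxonNode("X", "GenusX", "genus", "F1"),
        TaxonNode("Y", "GenusY", "genus", "F2"),
        TaxonNode("sx1", "SpeciesX1", "species", "X"),
        TaxonNode("sy1", "SpeciesY1", "species", "Y"),
        TaxonNode("gi1", "gi1", "sequence", "sx1"),
        TaxonNode("gi2", "gi2", "sequence", "sx1"),
        TaxonNode("gi3", "gi3", "sequence", "sy1"),
        # viral branch: no phylum/class/order in the lineage
        TaxonNode("skv", "Viruses", "superkingdom", None),
        TaxonNode("VF", "VirFamily", "family", "skv"),
        TaxonNode("Vg", "VirGenus", "genus", "VF"),
        TaxonNode("vsp", "VirSpecies", "species", "Vg"),
        TaxonNode("giv", "giv", "sequence", "vsp"),
    ]
    seqmap = {s: s for s in ("gi1", "gi2", "gi3", "giv")}
    return TaxonomyTree(nodes, seqmap)


def make_count_matrix(counts: dict, hq: dict, groups: dict, runs: dict,
                      rank: str = "genus") -> CountMatrix:
    """Build a CountMatrix from {taxon: {sample: count}} dicts."""
    df = pd.DataFrame(counts).T.fillna(0).astype(int)
    samples = list(df.columns)
    meta = pd.DataFrame({"group": pd.Series(groups), "run": pd.Series(runs)}).loc[samples]
    return CountMatrix(df, pd.Series(hq)[samples], meta, rank=rank)


def make_hr_matrix(hr: dict, groups: dict, runs: dict, hq: float = 1e6,
                   rank: str = "genus") -> HRMatrix:
    """Build an HRMatrix directly from {taxon: {sample: ppm}} dicts."""
    df = pd.DataFrame(hr).T.astype(float)
    samples = list(df.columns)
    meta = pd.DataFrame({"group": pd.Series(groups), "run": pd.Series(runs)}).loc[samples]
    return HRMatrix(df, pd.Series(hq, index=samples), meta, rank=rank)


@pytest.fixture
def small_study_hr() -> HRMatrix:
    """A 3-taxon study layout: 2 case, 4 controls (2 per run), 1 blank."""
    groups = {"MS-1": "MS", "MS-2": "MS", "C-1": "control", "C-2": "control",
              "C-3": "control", "C-4": "control", "B-1": "blank"}
    runs = {"MS-1": 1, "MS-2": 2, "C-1": 1, "C-2": 1, "C-3": 2, "C-4": 2, "B-1": 2}
    hr = {
        "t1": {"MS-1": 50.0, "MS-2": 1.0, "C-1": 2.0, "C-2": 4.0, "C-3": 3.0, "C-4": 5.0, "B-1": 0.0},
        "t2": {"MS-1": 0.5, "MS-2": 0.2, "C-1": 0.1, "C-2": 0.4, "C-3": 0.2, "C-4": 0.3, "B-1": 0.0},
        "contam": {"MS-1": 1.0, "MS-2": 8.0, "C-1": 1.0, "C-2": 2.0, "C-3": 9.0, "C-4": 7.0, "B-1": 30.0},
    }
    return make_hr_matrix(hr, groups, runs)
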