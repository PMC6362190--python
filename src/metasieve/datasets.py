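"""Bundled reference tables.

``ms_candidate_genera`` is the published genus-level MS microbial candidate
list from the brain-specimen metatranscriptomic study this pipeline models:
the genera significantly overrepresented (q < 0.05) in at least one MS
specimen that accumulated at least 100 mapped read pairs across the MS
group, with their phylum and family labels, MS- and control-group mapped
read totals, and the number of MS specimens significantly increased.  It is
the worked example for the candidate-summary filters and a regression
fixture for their arithmetic.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_ms_candidate_genera",
    "candidate_genus_summary",
]

_FUNGAL_PHYLA = {"Ascomycota", "Basidiomycota", "Chytridiomycota", "Mucoromycota", "Zygomycota"}


def load_ms_candidate_genera() -> pd.DataFrame:
    """The bundled candidate-genus table, one row per genus.

    Columns: phylum, family, genus, ms_mapped_reads, control_mapped_reads,
    ms_specimens_increased, pathogen, ecology, kingdom.  ``kingdom`` is
    derived from the phylum label by a standard classification (fungal phyla
    -> fungi, the "Viruses" label -> viruses, everything else bacteria;
    viral candidates carry no true phylum).
    """
    with resources.files(__package__).joinpath("data/ms_candidate_genera.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df["kingdom"] = [
        "viruses" if p == "Viruses" else ("fungi" if p in _FUNGAL_PHYLA else "bacteria")
        for p in df["phylum"]
    ]
    return df


def candidate_genus_summary(read_min: int = 100) -> dict[str, int]:
    """Headline counts over the bundled candidate table after applying the
    minimum case-group mapped-read rule (non-strict, "at least")."""
    df = load_ms_candidate_genera()
    kept = df[df["ms_mapped_reads"] >= read_min]
    return {
        "n_candidate_genera": int(len(kept)),
        "n_distinct_phyla": int(kept["phylum"].nunique()),
        "n_bacterial_genera": int((kept["kingdom"] == "bacteria").sum()),
        "n_fungal_genera": int((kept["kingdom"] == "fungi").sum()),
        "n_viral_genera": int((kept["kingdom"] == "viruses").sum()),
    }
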