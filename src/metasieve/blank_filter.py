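"""Run-artifact exclusion using blank (paraffin-only, no-tissue) specimens.

Reagent and run-specific contamination shows up in blanks, which contain no
tissue and so no genuine signal.  A taxon is excluded when its hit rate in
one or both blanks exceeds the mean hit rate of that taxon over the Run-1
control samples — Run 1 controls serve as the clean baseline because the
observed artifact was Run-2 specific.  The comparison uses a strict
inequality, so ties (in particular the all-zero 0 > 0 case) are retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .abundance import HRMatrix

__all__ = ["ExclusionReport", "BlankFilterError", "exclude_artifacts"]

logger = logging.getLogger(__name__)


class BlankFilterError(ValueError):
    """The filter cannot be applied (no blanks or no Run-1 controls)."""


@dataclass
class ExclusionReport:
    """Excluded taxa with the evidence behind each exclusion.

    ``excluded`` has one row per removed taxon: its maximum blank HR, each
    blank's HR, and the Run-1 control mean it exceeded.  ``retained`` is the
    number of taxa kept.
    """

    excluded: pd.DataFrame
    retained: int

    def write(self, path: str | Path) -> None:
        self.excluded.to_csv(path, sep="\t", index=False)


def exclude_artifacts(
    hr: HRMatrix,
    scope: str = "global",
) -> tuple[HRMatrix, ExclusionReport]:
    """Remove artifact taxa flagged by the blank-vs-Run-1-control rule.

    ``scope='global'`` (default) drops a flagged taxon from every sample.
    ``scope='run2'`` is a documented variant that instead masks the flagged
    taxon's values to NaN in Run-2 non-blank samples only; downstream
    z-scoring treats NaN as missing.
    """
    if scope not in ("global", "run2"):
        raise ValueError(f"scope must be 'global' or 'run2', got {scope!r}")
    blanks = hr.samples_in_group("blank")
    run1_controls = hr.samples_in_group("control", run=1)
    if not blanks:
        raise BlankFilterError("no blank samples in metadata; cannot apply filter")
    if not run1_controls:
        raise BlankFilterError(
            "no Run-1 control samples in metadata; cannot apply filter"
        )
    blank_hr = hr.hr[blanks]
    control_mean = hr.hr[run1_controls].mean(axis=1)
    flagged = blank_hr.max(axis=1) > control_mean  # strict: ties retained
    excluded_taxa = list(hr.hr.index[flagged])

    report_rows = []
    for t in excluded_taxa:
        row = {
            "taxon_id": t,
            "max_blank_hr": float(blank_hr.loc[t].max()),
            "run1_control_mean_hr": float(control_mean.loc[t]),
        }
        for b in blanks:
            row[f"blank_hr:{b}"] = float(blank_hr.loc[t, b])
        report_rows.append(row)
    report = ExclusionReport(
        excluded=pd.DataFrame(
            report_rows,
            columns=["taxon_id", "max_blank_hr", "run1_control_mean_hr"]
            + [f"blank_hr:{b}" for b in blanks],
        ),
        retained=int((~flagged).sum()),
    )
    if excluded_taxa:
        logger.info(
            "blank filter excluded %d of %d taxa (scope=%s)",
            len(excluded_taxa),
            hr.hr.shape[0],
            scope,
        )
    if scope == "global":
        filtered = hr.hr.loc[~flagged]
    else:
        filtered = hr.hr.copy()
        run2 = hr.meta.index[(hr.meta["run"] == 2) & (hr.meta["group"] != "blank")]
        filtered.loc[excluded_taxa, list(run2)] = np.nan
    out = HRMatrix(filtered, hr.hq_pairs, hr.meta, rank=hr.rank)
    return out, report
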