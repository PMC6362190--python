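"""Per-sample taxon outlier detection against a control cohort.

The core statistic: for each case sample, each taxon's log2-transformed hit
rate is scored against the distribution of the same taxon's log2 hit rates
across the control samples,

    z[t] = (x_case[t] - mean_controls[t]) / sd_controls[t],

with the sample standard deviation (n-1 denominator).  Because only
overrepresentation is of interest, z converts to a one-tailed upper-tail
normal p-value, and the p-values within one case sample's test family are
adjusted by the Benjamini-Hochberg step-up.  A (sample, taxon) pair is a
candidate when q < 0.05 and the sample's own (untransformed) hit rate
exceeds 1.0 PPM.

Hit rates can be zero, so the log2 transform adds a pseudocount (default
1 PPM, the same scale as the candidate HR threshold, so absent taxa sit at
log2(1) = 0).  Taxa whose control sd falls below ``sd_floor`` are flagged
untestable rather than producing infinite z; they are excluded from the BH
family and can never be candidates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .abundance import CountMatrix, HRMatrix

__all__ = [
    "log2_transform",
    "sample_zscores",
    "one_tailed_p",
    "bh_qvalues",
    "call_candidates",
    "summarize_candidates",
    "per_sample_candidate_lists",
]

DEFAULT_PSEUDOCOUNT = 1.0  # PPM
DEFAULT_SD_FLOOR = 1e-6  # log2 units
DEFAULT_Q_THRESHOLD = 0.05
DEFAULT_HR_THRESHOLD = 1.0  # PPM


def log2_transform(hr: pd.DataFrame | HRMatrix, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """Elementwise ``log2(hr + pseudocount)``; monotone in hr."""
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be > 0, got {pseudocount}")
    values = hr.hr if isinstance(hr, HRMatrix) else hr
    return np.log2(values + pseudocount)


def sample_zscores(
    transformed: pd.DataFrame,
    case_sample_id: str,
    control_sample_ids: Sequence[str],
    sd_floor: float = DEFAULT_SD_FLOOR,
) -> tuple[pd.Series, pd.Series]:
    """Per-taxon z of one case sample against the control distribution.

    Returns ``(z, testable)``.  ``testable`` is False where the control sd is
    below ``sd_floor`` (degenerate, e.g. all-zero control rows) or where
    values are missing; there z is NaN.  Control statistics use nan-aware
    mean and the n-1 standard deviation.
    """
    controls = list(control_sample_ids)
    if case_sample_id in controls:
        raise ValueError(
            f"case sample {case_sample_id!r} must not be among the controls"
        )
    if len(controls) < 3:
        raise ValueError(f"need >= 3 control samples, got {len(controls)}")
    x = transformed[case_sample_id]
    ctrl = transformed[controls]
    mean = ctrl.mean(axis=1)
    sd = ctrl.std(axis=1, ddof=1)
    testable = (sd >= sd_floor) & x.notna() & sd.notna()
    z = (x - mean) / sd
    z[~testable] = np.nan
    return z, testable


def one_tailed_p(z: pd.Series | np.ndarray | float) -> pd.Series | np.ndarray | float:
    """Upper-tail standard normal probability (overrepresentation only)."""
    p = stats.norm.sf(z)
    if isinstance(z, pd.Series):
        return pd.Series(p, index=z.index)
    if np.isscalar(z):
        return float(p)
    return p


def bh_qvalues(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_candidates(
    hr: HRMatrix,
    case_samples: Sequence[str] | None = None,
    control_samples: Sequence[str] | None = None,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    hr_threshold: float = DEFAULT_HR_THRESHOLD,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    sd_floor: float = DEFAULT_SD_FLOOR,
    family: str = "per-sample",
) -> pd.DataFrame:
    """Score every (case sample, taxon) pair and flag candidates.

    Defaults: case samples are the MS group, controls the control group,
    taken from the matrix metadata.  ``family`` selects the BH test family:
    ``"per-sample"`` (default) adjusts within each case sample's testable
    taxa; ``"pooled"`` adjusts across all case samples jointly.

    Returns a long-format table with columns ``sample_id, taxon_id, hr,
    log2_hr, z, p, q, is_candidate``; untestable taxa keep NaN z/p/q and are
    never candidates.
    """
    if family not in ("per-sample", "pooled"):
        raise ValueError(f"family must be 'per-sample' or 'pooled', got {family!r}")
    if case_samples is None:
        case_samples = hr.samples_in_group("MS")
    if control_samples is None:
        control_samples = hr.samples_in_group("control")
    transformed = log2_transform(hr, pseudocount)
    frames = []
    for sample in case_samples:
        z, testable = sample_zscores(transformed, sample, control_samples, sd_floor)
        p = pd.Series(np.nan, index=z.index)
        p[testable] = stats.norm.sf(z[testable])
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": sample,
                    "taxon_id": z.index,
                    "hr": hr.hr[sample].to_numpy(),
                    "log2_hr": transformed[sample].to_numpy(),
                    "z": z.to_numpy(),
                    "p": p.to_numpy(),
                    "testable": testable.to_numpy(),
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    table["q"] = np.nan
    if family == "per-sample":
        for sample in case_samples:
            mask = (table["sample_id"] == sample) & table["testable"]
            if mask.any():
                table.loc[mask, "q"] = bh_qvalues(table.loc[mask, "p"].to_numpy())
    else:
        mask = table["testable"]
        if mask.any():
            table.loc[mask, "q"] = bh_qvalues(table.loc[mask, "p"].to_numpy())
    table["is_candidate"] = (
        table["testable"]
        & (table["q"] < q_threshold)
        & (table["hr"] > hr_threshold)
    )
    return table.drop(columns="testable")


def summarize_candidates(
    table: pd.DataFrame,
    counts: CountMatrix,
    read_min: int = 100,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
) -> pd.DataFrame:
    """Cross-sample summary of candidate taxa.

    For every taxon flagged candidate in at least one case sample: total
    mapped pairs over the case-group samples and over the control group,
    the number of case specimens significantly increased (q < threshold),
    and whether the case-group total meets ``read_min`` (non-strict, "at
    least").  Read totals are raw filtered concordant-pair counts, not PPM.
    """
    case_samples = [s for s in table["sample_id"].unique()]
    control_samples = counts.samples_in_group("control")
    cand_taxa = sorted(table.loc[table["is_candidate"], "taxon_id"].unique())
    rows = []
    for taxon in cand_taxa:
        sub = table[table["taxon_id"] == taxon]
        case_total = int(counts.counts.loc[taxon, case_samples].sum())
        control_total = int(counts.counts.loc[taxon, control_samples].sum())
        n_increased = int((sub["q"] < q_threshold).sum())
        rows.append(
            {
                "taxon_id": taxon,
                "case_mapped_pairs": case_total,
                "control_mapped_pairs": control_total,
                "n_specimens_increased": n_increased,
                "passes_read_filter": case_total >= read_min,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "taxon_id",
            "case_mapped_pairs",
            "control_mapped_pairs",
            "n_specimens_increased",
            "passes_read_filter",
        ],
    )


def per_sample_candidate_lists(table: pd.DataFrame) -> pd.DataFrame:
    """Candidate taxa listed per case sample (long format, sorted by q)."""
    cands = table[table["is_candidate"]].copy()
    return cands.sort_values(["sample_id", "q", "taxon_id"]).reset_index(drop=True)[
        ["sample_id", "taxon_id", "hr", "z", "p", "q"]
    ]
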