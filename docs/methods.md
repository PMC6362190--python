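# Methods

## Statistical model

The detector treats each taxon's normalized hit rate as approximately
log-normal across control samples. For a case sample *s* and taxon *t*, with
x = log₂(HR + c) and the control cohort providing the expected distribution,

    z_t(s) = (x_t(s) − mean_controls(x_t)) / sd_controls(x_t)

where sd is the sample standard deviation (n − 1 denominator): the controls
are a finite sample estimating the control population, not the population
itself. z converts to an upper-tail standard normal p (only
overrepresentation is biologically interesting here), and p-values are
adjusted by the Benjamini–Hochberg step-up. A (sample, taxon) pair is a
candidate iff q < 0.05 **and** the case sample's own untransformed HR
exceeds 1.0 PPM; both inequalities strict.

Assumptions worth stating plainly:

- control log₂ HRs are roughly normal per taxon — at very shallow counts the
  distribution is dominated by Poisson zeros and the normal tail probability
  is approximate; the FDR behaviour under this approximation is measured
  empirically (see the null simulation) rather than assumed;
- mate mapping errors are independent, so a concordant pair at MAPQs
  (m₁, m₂) is correctly placed with probability 1 − 10^(−(m₁+m₂)/10);
- the blank specimens carry the run's contamination profile but no tissue
  signal.

## Test family

The BH family is, by default, all testable taxa within one case sample at
one rank ("each specimen was compared to the set of controls"). A pooled
family across all case samples is available (`family="pooled"`), which is
more conservative per test when many samples are scored. OND samples are
never part of the control distribution; they can be scored as case samples
on request.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `mapq_min` | 10 | Phred | ≥ 90% single-alignment, ≥ 99% pair correctness; a pair is kept only if **both** mates pass, consistent with the pair-probability interpretation |
| `pseudocount` | 1.0 | PPM | bounds log₂ at 0 for absent taxa and matches the candidate HR threshold's scale |
| `q_threshold` | 0.05 | — | conventional FDR level |
| `hr_threshold` | 1.0 | PPM | excludes significant-but-negligible hits driven by a handful of pairs |
| `read_min` | 100 | pairs | the candidate-summary floor on raw case-group concordant pairs (not PPM), non-strict |
| `sd_floor` | 1e-6 | log₂ units | control rows with sd below it (typically all-zero) are *untestable*, not infinite z, and leave the BH family |

## Numerical and procedural choices

- **PPM denominator** — the sample's *total* HQ-pair yield, including
  human-mapping pairs, taken from upstream QC metadata (read trimming and
  alignment are upstream tools, not reimplemented).
- **Blank filter** — strict inequality (`max(blank HR) > mean(Run-1 control
  HR)`); ties, in particular 0 > 0, are retained. Exclusion is global (all
  samples, both runs) by default; a run-2-only variant masks the affected
  run-2 entries as missing, and the NaN-aware z-scoring then drops them.
  The filter runs independently at each analyzed rank, after aggregation
  and before the HR > 1 PPM arm is evaluated.
- **Rank aggregation** — always restarts from the sequence-level matrix, so
  genus- and family-level analyses are independent; lineages lacking the
  requested rank go to an explicit unaggregated bucket (mass conservation is
  tested exactly in integer arithmetic). Intermediate unnamed ranks are
  skipped during ancestor walks.
- **Coverage profiles** — each concordant pair contributes once at the
  leftmost mapped mate position, 1-based SAM coordinates; bins tile
  [1, reference length]. Unfiltered (MAPQ ≥ 0) by default, the convention
  for genome-mapping plots.
- **Mann–Whitney** — U counts (x > y) pairs plus half the ties (midranks);
  two-sided p by default as the conservative choice. The exact branch uses
  the exact null distribution of U for tie-free data and full enumeration
  over label assignments with ties; the asymptotic branch applies the tie
  correction and a continuity correction. `auto` switches at n₁·n₂ ≤ 400.
- **Clustering** — Pearson correlation distance (1 − r) with average
  linkage on both axes of the row-centered log₂ matrix, restricted to taxa
  significant in ≥ 1 case sample. Zero-variance items get distance 1 to all
  others (and a logged warning) instead of NaN. Merge ties break
  deterministically by cluster index, so runs are reproducible.
- **BH step-up** — delegated to `statsmodels` and verified against a
  brute-force step-up reference to 1e-12 on random vectors in the tests.

## What the synthetic generator emulates — and what it does not

`SimulationConfig` defaults mirror the emulated study design: 12 case, 15
control, 3 OND and 2 blank libraries over two sequencing runs (blanks on
run 2), a fully ranked taxonomy of 5 phyla branching to 200 genera and 400
reference sequences, and 10⁶ HQ pairs per library — a desk-scale depth,
roughly two orders of magnitude below real deep-sequencing yields, chosen so
full Monte-Carlo suites run in seconds. Per-sequence baseline abundances are
log-uniform over [−2, 2] log₂ PPM with per-sample log₂ noise of sd 0.5 and
negative-binomial count dispersion 10; spikes add +4 log₂ PPM to 10 genera
in 4 of the 12 case samples; 10 contaminant genera appear at +3 log₂ PPM in
run-2 samples and at 20 PPM in blanks. SAM emission adds human, PhiX and
sub-threshold-MAPQ decoy pairs so the ingest filters are exercised, with an
exact round-trip guarantee for the retained-MAPQ subset.

The generator does **not** emulate: read sequences or base-call errors
(records carry positions and MAPQs, not bases), compositional coupling
between taxa, batch effects beyond the single run-2 contaminant class,
cross-contamination between wells, or reference-database incompleteness.
Passing recovery tests therefore demonstrate that the *statistics* behave
as intended under the stated noise model — not that the pipeline is robust
to misalignment or database artifacts in real data.

## Problem sizes in the test and acceptance suites

Null FDR behaviour: 200 spike-free datasets (200 genera × 27 scored
samples); spike recovery: 50 replicates of the full blank-filter +
detection chain; round-trip: 20 random emission configs; blank-filter
recovery: 20 seeds; BH oracle: 1,000 random p-vectors up to length 200;
exact Mann–Whitney: every two-group split of n ≤ 8. These sizes keep each
suite deterministic (seeded) and fast while keeping Monte-Carlo error well
inside the asserted margins.

## Known limitations

- Normal tail p-values from 15-control z-scores are approximate (a t-like
  statistic is treated as normal); the empirical null rate is far below the
  nominal 0.05 in the simulations precisely because shallow counts make the
  log scale granular.
- The bundled published candidate-genus table is a printed summary; the full
  84-genus significant list behind it was not published, so the candidate
  arithmetic is verified on the filtered table.
- Multi-mapped reference sequences are assumed to resolve to one taxonomy
  node each; taxid merging/deprecation is out of scope.
- Blank identity comes from sample metadata; it is not re-derived from the
  human-mapping fraction.
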