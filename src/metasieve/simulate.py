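"""Ground-truthed synthetic datasets with the structure the pipeline assumes.

The generator emulates a two-run FFPE brain-specimen study: case, control,
OND and blank libraries; a fully ranked taxonomy; negative-binomial
concordant-pair counts whose expected hit rates are log-normal on the PPM
scale; taxa spiked (on the log2 scale) into designated case samples; and
run-restricted contaminant taxa that dominate the blanks.  Blank libraries
carry only contaminant signal plus sampling noise — no background, no spikes
— mirroring paraffin-only specimens.  Optionally each counted pair can be
emitted as a pair of SAM records with realistic MAPQ values plus human/PhiX
and low-MAPQ decoys, so the ingest stage can be exercised end to end.

Default sizes mirror the emulated study design (12 case / 15 control /
3 OND / 2 blank samples over 2 runs) at desk scale: 200 genera over 400
reference sequences and 10^6 HQ pairs per library.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .abundance import CountMatrix
from .ingest import ReferenceCatalog
from .taxonomy import TaxonNode, TaxonomyTree

__all__ = ["SimulationConfig", "TruthTable", "generate_counts", "emit_alignments"]


@dataclass
class SimulationConfig:
    """All knobs of the generator; the seed fully determines the output."""

    # cohort design
    n_case: int = 12
    n_control: int = 15
    n_ond: int = 3
    n_blank: int = 2
    # taxonomy branching: phyla, classes/phylum, orders/class, families/order,
    # genera/family; then species per genus and sequences per species
    branching: tuple[int, int, int, int, int] = (5, 2, 2, 2, 5)
    species_per_genus: int = 1
    sequences_per_species: int = 2
    # library size (HQ read pairs per sample)
    hq_pairs: int = 1_000_000
    # background abundance: per-sequence baseline log2-PPM mean drawn uniform
    # from this range; per-taxon log2 sd; NB dispersion (None -> Poisson)
    baseline_log2ppm_range: tuple[float, float] = (-2.0, 2.0)
    taxon_sd: float = 0.5
    nb_dispersion: float | None = 10.0
    # spike design: each spiked genus is raised by spike_log2_effect in a
    # random subset of case samples (or give explicit (genus, samples, effect)
    # triples in spike_design)
    n_spiked_genera: int = 10
    n_spiked_case_samples: int = 4
    spike_log2_effect: float = 4.0
    spike_design: list[tuple[str, tuple[str, ...], float]] | None = None
    # contaminant design: run-restricted artifact taxa, present in blanks
    n_contaminant_genera: int = 10
    contaminant_run: int = 2
    contaminant_blank_hr: float = 20.0  # genus-level PPM in blanks
    contaminant_run_log2_effect: float = 3.0
    contaminant_genera: list[str] | None = None
    # alignment emission
    mapq_min: int = 10
    mapq_max: int = 42
    low_mapq_fraction: float = 0.1
    human_decoy_fraction: float = 0.3
    phix_decoy_fraction: float = 0.01
    reference_length: int = 10_000
    read_length: int = 125
    seed: int = 0


@dataclass
class TruthTable:
    """Every non-background signal injected into a simulated dataset."""

    spikes: pd.DataFrame  # genus_id, sample_id, log2_effect
    contaminants: pd.DataFrame  # genus_id, run
    expected_fraction: pd.Series  # per-sample expected microbial fraction (PPM)

    @property
    def spiked_genera(self) -> list[str]:
        return sorted(self.spikes["genus_id"].unique())

    @property
    def contaminant_genera(self) -> list[str]:
        return sorted(self.contaminants["genus_id"].unique())

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        self.spikes.to_csv(out_dir / "truth_spikes.tsv", sep="\t", index=False)
        self.contaminants.to_csv(out_dir / "truth_contaminants.tsv", sep="\t", index=False)
        self.expected_fraction.rename("expected_fraction_ppm").to_csv(
            out_dir / "truth_expected_fraction.tsv", sep="\t"
        )


def _build_taxonomy(config: SimulationConfig) -> tuple[TaxonomyTree, pd.DataFrame]:
    """Fully ranked tree plus a per-sequence lineage table."""
    n_ph, n_cl, n_or, n_fa, n_ge = config.branching
    nodes = [TaxonNode("sk_1", "Superkingdom_1", "superkingdom", None)]
    lineage_rows = []
    seqmap: dict[str, str] = {}
    gi = 0
    seq_i = 0
    sp_i = 0
    counters = {"class": 0, "order": 0, "family": 0}
    for p in range(1, n_ph + 1):
        pid = f"ph_{p}"
        nodes.append(TaxonNode(pid, f"Phylum_{p}", "phylum", "sk_1"))
        for _c in range(n_cl):
            counters["class"] += 1
            cid = f"cl_{counters['class']}"
            nodes.append(TaxonNode(cid, f"Class_{counters['class']}", "class", pid))
            for _o in range(n_or):
                counters["order"] += 1
                oid = f"or_{counters['order']}"
                nodes.append(TaxonNode(oid, f"Order_{counters['order']}", "order", cid))
                for _f in range(n_fa):
                    counters["family"] += 1
                    fid = f"fa_{counters['family']}"
                    nodes.append(TaxonNode(fid, f"Family_{counters['family']}", "family", oid))
                    for _g in range(n_ge):
                        gi += 1
                        gid = f"ge_{gi}"
                        nodes.append(TaxonNode(gid, f"Genus_{gi}", "genus", fid))
                        for _s in range(config.species_per_genus):
                            sp_i += 1
                            sid = f"sp_{sp_i}"
                            nodes.append(TaxonNode(sid, f"Species_{sp_i}", "species", gid))
                            for _q in range(config.sequences_per_species):
                                seq_i += 1
                                qid = f"seq_{seq_i:05d}"
                                nodes.append(TaxonNode(qid, qid, "sequence", sid))
                                seqmap[qid] = qid
                                lineage_rows.append(
                                    {"sequence_id": qid, "genus_id": gid, "family_id": fid}
                                )
    tree = TaxonomyTree(nodes, seqmap)
    return tree, pd.DataFrame(lineage_rows).set_index("sequence_id")


def _sample_frame(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for i in range(config.n_case):
        rows.append({"sample_id": f"MS-{i + 1:02d}", "group": "MS", "run": 1 + i % 2})
    for i in range(config.n_control):
        rows.append({"sample_id": f"C-{i + 1:02d}", "group": "control", "run": 1 + i % 2})
    for i in range(config.n_ond):
        rows.append({"sample_id": f"OND-{i + 1:02d}", "group": "OND", "run": 1 + i % 2})
    for i in range(config.n_blank):
        rows.append({"sample_id": f"BLANK-{i + 1:02d}", "group": "blank", "run": 2})
    return pd.DataFrame(rows).set_index("sample_id")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float | None) -> np.ndarray:
    """Counts with the given means: Poisson, or NB with var = m + m^2/k."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if not pos.any():
        return out
    if dispersion is None:
        out[pos] = rng.poisson(mean[pos])
    else:
        k = float(dispersion)
        p = k / (k + mean[pos])
        out[pos] = rng.negative_binomial(k, p)
    return out


def generate_counts(
    config: SimulationConfig,
) -> tuple[CountMatrix, TaxonomyTree, TruthTable]:
    """Draw one ground-truthed sequence-level count matrix.

    Expected log2 hit rate of a sequence in a non-blank sample is its
    baseline mean, plus the spike effect where (genus, sample) is spiked,
    plus the contaminant effect in samples of the contaminant run; each
    sample's realized log2 HR adds N(0, taxon_sd) noise, and counts are
    drawn negative-binomially around HR * hq_pairs / 1e6.
    """
    rng = np.random.default_rng(config.seed)
    tree, lineage = _build_taxonomy(config)
    meta = _sample_frame(config)
    sequences = list(lineage.index)
    genera = sorted(lineage["genus_id"].unique(), key=lambda g: int(g.split("_")[1]))
    case_samples = list(meta.index[meta["group"] == "MS"])
    blank_samples = list(meta.index[meta["group"] == "blank"])
    seqs_per_genus = lineage.groupby("genus_id").size()

    # baseline per-sequence log2 PPM
    lo, hi = config.baseline_log2ppm_range
    baseline = rng.uniform(lo, hi, size=len(sequences))

    # choose contaminants, then spikes, from disjoint genus sets
    if config.contaminant_genera is None and config.spike_design is None:
        needed = config.n_contaminant_genera + config.n_spiked_genera
        if needed > len(genera):
            raise ValueError(
                f"{config.n_contaminant_genera} contaminant + "
                f"{config.n_spiked_genera} spiked genera requested but the "
                f"taxonomy has only {len(genera)} genera"
            )
    if config.contaminant_genera is not None:
        contaminant_genera = list(config.contaminant_genera)
        unknown = set(contaminant_genera) - set(genera)
        if unknown:
            raise ValueError(f"unknown contaminant genera: {sorted(unknown)}")
    else:
        contaminant_genera = list(
            rng.choice(genera, size=config.n_contaminant_genera, replace=False)
        )
    if config.spike_design is not None:
        spike_design = [
            (g, tuple(samples), float(effect))
            for g, samples, effect in config.spike_design
        ]
        for g, samples, _ in spike_design:
            if g not in set(genera):
                raise ValueError(f"spike refers to unknown genus {g!r}")
            bad = set(samples) - set(case_samples)
            if bad:
                raise ValueError(f"spike refers to unknown case sample(s): {sorted(bad)}")
    else:
        eligible = [g for g in genera if g not in set(contaminant_genera)]
        spiked = rng.choice(eligible, size=config.n_spiked_genera, replace=False)
        spike_design = [
            (
                g,
                tuple(rng.choice(case_samples, size=config.n_spiked_case_samples, replace=False)),
                config.spike_log2_effect,
            )
            for g in spiked
        ]

    genus_of_seq = lineage["genus_id"].to_numpy()
    is_contam_seq = np.isin(genus_of_seq, contaminant_genera)
    spike_map: dict[tuple[str, str], float] = {}
    for g, samples, effect in spike_design:
        for s in samples:
            spike_map[(g, s)] = spike_map.get((g, s), 0.0) + effect

    counts = np.zeros((len(sequences), len(meta)), dtype=np.int64)
    ln2 = np.log(2.0)
    lognorm_corr = np.exp((config.taxon_sd * ln2) ** 2 / 2.0)
    expected_fraction = {}
    for j, (sample, row) in enumerate(meta.iterrows()):
        if row["group"] == "blank":
            mu = np.full(len(sequences), -np.inf)
            per_seq_blank = config.contaminant_blank_hr / seqs_per_genus.reindex(
                genus_of_seq
            ).to_numpy().astype(float)
            mu[is_contam_seq] = np.log2(per_seq_blank[is_contam_seq])
        else:
            mu = baseline.copy()
            if row["run"] == config.contaminant_run:
                mu[is_contam_seq] += config.contaminant_run_log2_effect
            for g, s in list(spike_map):
                if s == sample:
                    mu[genus_of_seq == g] += spike_map[(g, s)]
        x = np.where(np.isfinite(mu), mu + rng.normal(0.0, config.taxon_sd, len(mu)), -np.inf)
        hr = np.where(np.isfinite(x), np.exp2(x), 0.0)
        mean_counts = hr * config.hq_pairs / 1e6
        counts[:, j] = _nb_draw(rng, mean_counts, config.nb_dispersion)
        expected_fraction[sample] = float(
            np.sum(np.where(np.isfinite(mu), np.exp2(mu), 0.0) * lognorm_corr)
        )

    cm = CountMatrix(
        pd.DataFrame(counts, index=sequences, columns=list(meta.index)),
        pd.Series(config.hq_pairs, index=meta.index, dtype=int),
        meta[["group", "run"]],
        rank="sequence",
    )
    truth = TruthTable(
        spikes=pd.DataFrame(
            [
                {"genus_id": g, "sample_id": s, "log2_effect": e}
                for g, samples, e in spike_design
                for s in samples
            ],
            columns=["genus_id", "sample_id", "log2_effect"],
        ),
        contaminants=pd.DataFrame(
            {"genus_id": sorted(contaminant_genera), "run": config.contaminant_run}
        ),
        expected_fraction=pd.Series(expected_fraction),
    )
    return cm, tree, truth


# ------------------------------------------------------------ SAM emission

HUMAN_REF = "human_decoy"
PHIX_REF = "phix_decoy"


def _catalog_for(cm: CountMatrix, config: SimulationConfig) -> ReferenceCatalog:
    classes = {seq: "microbial" for seq in cm.taxa}
    classes[HUMAN_REF] = "human"
    classes[PHIX_REF] = "phix"
    lengths = {ref: config.reference_length for ref in classes}
    return ReferenceCatalog(classes, {seq: seq for seq in cm.taxa}, lengths)


def emit_alignments(
    cm: CountMatrix,
    config: SimulationConfig,
    out_dir: str | Path,
    seed: int | None = None,
) -> tuple[dict[str, Path], ReferenceCatalog]:
    """Write one SAM file per sample realizing the count matrix.

    Every counted pair becomes two mate records on its reference at random
    positions with MAPQ drawn from ``[mapq_min, mapq_max]``.  Decoy pairs —
    human, PhiX and sub-threshold-MAPQ microbial — are added at the
    configured rates so the ingest filters have work to do.  Re-ingesting
    with ``mapq_min`` reproduces ``cm.counts`` exactly.
    """
    if config.reference_length < config.read_length:
        raise ValueError(
            f"reference_length {config.reference_length} shorter than "
            f"read_length {config.read_length}"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([seed if seed is not None else config.seed, 17])
    catalog = _catalog_for(cm, config)
    refs = list(catalog.classes)
    ref_index = {r: i for i, r in enumerate(refs)}
    microbial_refs = [r for r in refs if catalog.classes[r] == "microbial"]
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": r, "LN": catalog.lengths[r]} for r in refs],
        }
    )
    max_pos = config.reference_length - config.read_length + 1
    paths: dict[str, Path] = {}

    def make_pair(qname: str, ref: str, mapq1: int, mapq2: int) -> list[pysam.AlignedSegment]:
        recs = []
        positions = rng.integers(1, max_pos + 1, size=2)
        for mate, (pos, mq) in enumerate(zip(positions, (mapq1, mapq2)), start=1):
            a = pysam.AlignedSegment(header)
            a.query_name = qname
            a.flag = 0x1 | (0x40 if mate == 1 else 0x80)
            a.reference_id = ref_index[ref]
            a.reference_start = int(pos) - 1
            a.mapping_quality = int(mq)
            a.cigarstring = f"{config.read_length}M"
            a.next_reference_id = ref_index[ref]
            a.next_reference_start = int(positions[2 - mate]) - 1
            recs.append(a)
        return recs

    for sample in cm.samples:
        path = out_dir / f"{sample}.sam"
        paths[sample] = path
        col = cm.counts[sample]
        total = int(col.sum())
        n_low = int(rng.poisson(total * config.low_mapq_fraction)) if total else 0
        f_h = config.human_decoy_fraction
        f_x = config.phix_decoy_fraction
        n_human = int(rng.poisson(total * f_h / (1 - f_h))) if total and f_h else 0
        n_phix = int(rng.poisson(total * f_x / (1 - f_x))) if total and f_x else 0
        with pysam.AlignmentFile(str(path), "w", header=header) as sam:
            i = 0
            for ref, c in col.items():
                for _ in range(int(c)):
                    i += 1
                    mq = rng.integers(config.mapq_min, config.mapq_max + 1, size=2)
                    for rec in make_pair(f"{sample}:pair{i:07d}", ref, mq[0], mq[1]):
                        sam.write(rec)
            for k in range(n_low):
                ref = microbial_refs[int(rng.integers(len(microbial_refs)))]
                mq1 = int(rng.integers(0, config.mapq_min))  # guarantees exclusion
                mq2 = int(rng.integers(0, config.mapq_max + 1))
                for rec in make_pair(f"{sample}:low{k:07d}", ref, mq1, mq2):
                    sam.write(rec)
            for k in range(n_human):
                mq = rng.integers(0, config.mapq_max + 1, size=2)
                for rec in make_pair(f"{sample}:hum{k:07d}", HUMAN_REF, mq[0], mq[1]):
                    sam.write(rec)
            for k in range(n_phix):
                mq = rng.integers(0, config.mapq_max + 1, size=2)
                for rec in make_pair(f"{sample}:phx{k:07d}", PHIX_REF, mq[0], mq[1]):
                    sam.write(rec)
    return paths, catalog
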