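"""End-to-end pipeline driver, configuration, and the reporter assays.

``run_pipeline`` wires the stages together on simulated inputs: simulate ->
trim -> contaminant filter -> align -> periodicity QC -> A-site assignment
-> occupancy -> condition ratios -> translation efficiency -> stretch
analysis (plus an optional bisulfite branch), writing every stage's table as
TSV together with a machine-readable run log. Re-running with the same
configuration and seed is byte-identical.

Also home to the beta-galactosidase misreading activity calculation
(Miller-style units) and the between-group error-rate comparison.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import codon_occupancy as co
from . import footprint_processing as fp
from . import translation_efficiency as te
from . import trna_methylation as tm
from .core import ReadSet, write_fasta
from .synthetic_data import (
    BisulfiteTruth,
    DwellConfig,
    contaminant_reference,
    generate_transcriptome,
    simulate_bisulfite_reads,
    simulate_footprints,
    simulate_rnaseq,
)

# ---------------------------------------------------------------------------
# beta-galactosidase misreading assay
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BetaGalMeasurement:
    """One ONPG assay measurement: absorbances, culture volume and time."""

    od420: float
    od600: float
    volume: float  # ml of culture harvested
    time: float  # incubation minutes

    def __post_init__(self) -> None:
        if self.od420 < 0:
            raise ValueError("od420 must be >= 0")
        for name in ("od600", "volume", "time"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def beta_gal_activity(m: BetaGalMeasurement) -> float:
    """Activity = 1000 x OD420 / (V x t x OD600).

    Volume, time and OD600 all sit in the denominator (the standard
    Miller-unit grouping): activity per cell density per unit time must not
    grow with incubation time.
    """
    return 1000.0 * m.od420 / (m.volume * m.time * m.od600)


def compare_error_rates(
    groups: dict[str, list[float]],
    pairs: list[tuple[str, str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group summaries (mean, SD, n) and two-sided t-tests per group pair.

    Pairs default to all label combinations. Groups with fewer than 3
    measurements are summarized without a p-value.
    """
    summary = pd.DataFrame(
        {
            label: {
                "mean": float(np.mean(vals)),
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
                "n": len(vals),
            }
            for label, vals in groups.items()
        }
    ).T
    labels = list(groups)
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1 :]]
    rows = []
    for a, b in pairs:
        xa, xb = groups[a], groups[b]
        diff = float(np.mean(xa) - np.mean(xb))
        if len(xa) < 3 or len(xb) < 3:
            p = np.nan
        elif np.std(xa) == 0 and np.std(xb) == 0:
            p = 1.0 if diff == 0 else 0.0
        else:
            p = float(stats.ttest_ind(xa, xb, equal_var=False).pvalue)
        rows.append((a, b, diff, p))
    tests = pd.DataFrame(rows, columns=["group_a", "group_b", "mean_difference", "p"])
    return summary, tests


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def _default_conditions() -> dict[str, dict[str, float]]:
    # the queuosine experiment: Q loss slows C-ending Asp/His codons and
    # speeds U-ending Asn/Tyr codons relative to the fully modified control
    return {
        "noQ": {"GAC": 1.5, "CAC": 1.5, "AAT": 0.7, "TAT": 0.7},
        "withQ": {},
    }


@dataclass
class PipelineConfig:
    """All tunable parameters of the simulated end-to-end run.

    Unknown keys in a YAML config are rejected; every threshold is validated
    against its documented domain.
    """

    seed: int = 0
    # synthetic transcriptome
    n_genes: int = 20
    length_range: tuple[int, int] = (100, 200)
    utr5_length: int = 0
    abundance_sigma: float = 1.0
    # simulated libraries
    n_replicates: int = 3
    depth_footprint: int = 20000
    depth_rnaseq: int = 20000
    contaminant_fraction: float = 0.1
    error_rate: float = 0.0
    rnaseq_read_length: int = 50
    conditions: dict[str, dict[str, float]] = field(default_factory=_default_conditions)
    comparison: tuple[str, str] = ("noQ", "withQ")
    # read processing
    adapter: str = fp.DEFAULT_ADAPTER
    min_quality: int = 30
    size_min: int = 25
    size_max: int = 35
    contaminant_min_match: int = 20
    max_mismatches: int = 2
    # periodicity QC; the initiation-peak position check is off by default
    # because the simulator models elongating ribosomes only (no 5' UTR, no
    # initiation pausing), so a -12 nt peak cannot exist in its output
    periodicity_min_reads: int = 100
    periodicity_threshold: float = 0.6
    periodicity_peak_offset: int | None = None
    # occupancy
    a_site_offset: int = 15
    min_codon_count: int = 30
    usage_mode: str = "local"  # or "transcriptome"
    ratio_mode: str = "paired"  # or "all-pairs" / "ratio-of-means"
    # translation efficiency
    min_rna_count: int = 10
    pseudocount: float = 0.5
    stretch_statistic: str = "delta"
    # bisulfite branch
    bisulfite_enabled: bool = False
    bisulfite_depth: int = 5000
    bisulfite_position: int = 38
    bisulfite_methylation_fraction: float = 0.8
    bisulfite_non_conversion: float = 0.01

    def __post_init__(self) -> None:
        self.length_range = tuple(self.length_range)
        self.comparison = tuple(self.comparison)
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 0.0 <= self.contaminant_fraction < 1.0:
            raise ValueError("contaminant_fraction must be in [0,1)")
        if not 0.0 <= self.periodicity_threshold <= 1.0:
            raise ValueError("periodicity_threshold must be in [0,1]")
        if self.usage_mode not in ("local", "transcriptome"):
            raise ValueError("usage_mode must be 'local' or 'transcriptome'")
        if self.ratio_mode not in ("paired", "all-pairs", "ratio-of-means"):
            raise ValueError("unknown ratio_mode")
        if not set(self.comparison) <= set(self.conditions):
            raise ValueError("comparison labels must name configured conditions")
        if not 0.0 <= self.bisulfite_methylation_fraction <= 1.0:
            raise ValueError("bisulfite_methylation_fraction must be in [0,1]")
        if not 0.0 <= self.bisulfite_non_conversion < 1.0:
            raise ValueError("bisulfite_non_conversion must be in [0,1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["length_range"] = list(d["length_range"])
        d["comparison"] = list(d["comparison"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------


def _synthetic_trna_ref(position: int, seed: int = 4111) -> tuple[str, str]:
    """A synthetic ~76 nt tRNA-like reference with a C at *position*."""
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(list("ACGT"), size=73)) + ["C", "C", "A"]
    seq[position] = "C"
    return "tRNA-Asp-synthetic", "".join(seq)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute the full simulated analysis and write all stage outputs.

    Returns the run log (also written as ``run_log.json``). Every source of
    randomness derives from ``config.seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": config.seed, "stages": []}

    def stage(name: str, **info):
        log["stages"].append({"stage": name, **info})

    ss = np.random.SeedSequence(config.seed)
    child_seeds = [int(s) for s in ss.generate_state(4 * config.n_replicates * max(2, len(config.conditions)) + 8)]
    seed_iter = iter(child_seeds)

    tx = generate_transcriptome(
        config.n_genes,
        config.length_range,
        seed=next(seed_iter),
        utr5_length=config.utr5_length,
        abundance_sigma=config.abundance_sigma,
    )
    tx.to_fasta(out / "transcriptome.fasta")
    decoy = contaminant_reference()
    write_fasta(out / "contaminants.fasta", [decoy])
    stage("simulate_transcriptome", n_genes=len(tx))

    profiles: dict[str, list[co.OccupancyProfile]] = {}
    te_tables: dict[str, list[pd.DataFrame]] = {}
    fp_gene_counts: dict[str, list[pd.Series]] = {}
    for cond, dwell_spec in config.conditions.items():
        dwell = DwellConfig(dwell_spec)
        profiles[cond] = []
        te_tables[cond] = []
        fp_gene_counts[cond] = []
        for rep in range(config.n_replicates):
            sample = f"{cond}_rep{rep}"
            sim = simulate_footprints(
                tx,
                dwell,
                condition=sample,
                depth=config.depth_footprint,
                contaminant_fraction=config.contaminant_fraction,
                error_rate=config.error_rate,
                seed=next(seed_iter),
            )
            sim.write(out / f"{sample}.fastq", out / f"{sample}.truth.tsv")
            reads, trim_counts = fp.trim_and_filter(
                sim.reads, config.adapter, config.min_quality, config.size_min, config.size_max
            )
            stage("trim_and_filter", sample=sample, **trim_counts)
            reads, cont_counts = fp.filter_contaminants(reads, [decoy], config.contaminant_min_match)
            stage("filter_contaminants", sample=sample, **cont_counts)
            aln, aln_counts = fp.align_to_transcripts(reads, tx, config.max_mismatches)
            aln.to_csv(out / f"{sample}.alignments.tsv", sep="\t", index=False)
            stage("align_to_transcripts", sample=sample, **aln_counts)
            qc = fp.assess_periodicity(
                aln,
                tx,
                min_reads=config.periodicity_min_reads,
                threshold=config.periodicity_threshold,
                peak_offset=config.periodicity_peak_offset,
            )
            qc.summary.to_csv(out / f"{sample}.periodicity.tsv", sep="\t")
            qc.histograms.to_csv(out / f"{sample}.offset_histograms.tsv", sep="\t")
            accepted = qc.accepted_lengths
            stage("assess_periodicity", sample=sample, accepted_lengths=accepted)
            try:
                asites, asite_counts = fp.assign_a_sites(aln, tx, accepted, config.a_site_offset)
            except ValueError as exc:
                raise StageError("assign_a_sites", str(exc)) from exc
            asites.to_csv(out / f"{sample}.asites.tsv", sep="\t", index=False)
            stage("assign_a_sites", sample=sample, **asite_counts)
            if config.usage_mode == "local":
                usage = co.local_codon_usage(asites, tx)
            else:
                usage = co.transcriptome_usage(tx, gene_ids=sorted(set(asites["gene_id"])))
            profile = co.bulk_codon_occupancy(asites, usage, sample, config.min_codon_count)
            profile.table.to_csv(out / f"{sample}.occupancy.tsv", sep="\t")
            profiles[cond].append(profile)
            fp_gene_counts[cond].append(te.count_reads_per_gene(aln, tx.gene_ids))

            rna = simulate_rnaseq(
                tx,
                depth=config.depth_rnaseq,
                read_length=config.rnaseq_read_length,
                seed=next(seed_iter),
                condition=f"{sample}_rna",
            )
            rna_reads, _ = fp.filter_contaminants(rna.reads, [decoy], config.contaminant_min_match)
            rna_aln, rna_counts = fp.align_to_transcripts(rna_reads, tx, config.max_mismatches)
            stage("align_rnaseq", sample=sample, **rna_counts)
            te_table = te.compute_te(
                fp_gene_counts[cond][-1],
                te.count_reads_per_gene(rna_aln, tx.gene_ids),
                config.min_rna_count,
            )
            te_table.to_csv(out / f"{sample}.te.tsv", sep="\t")
            te_tables[cond].append(te_table)

    num_label, den_label = config.comparison
    ratios = co.occupancy_ratio(profiles[num_label], profiles[den_label], config.ratio_mode)
    ratios.to_csv(out / "occupancy_ratios.tsv", sep="\t")
    cu = co.c_vs_u_ratio(ratios)
    cu.to_csv(out / "c_vs_u_ratios.tsv", sep="\t", index=False)
    stage("occupancy_ratio", comparison=list(config.comparison), n_codons=len(ratios))

    tai = co.compute_tai(co.load_tai_parameters())
    tai.to_csv(out / "tai.tsv", sep="\t")
    control = profiles[den_label]
    mean_occ = pd.concat([p.occupancy for p in control], axis=1).mean(axis=1)
    mean_profile = co.OccupancyProfile(
        f"{den_label}_mean", pd.DataFrame({"occupancy": mean_occ})
    )
    rho, pval = co.occupancy_tai_correlation(mean_profile, tai["tai"])
    stage("occupancy_tai_correlation", rho=rho, p=pval)

    diff = te.differential_te(te_tables[num_label], te_tables[den_label], config.pseudocount)
    diff.to_csv(out / "differential_te.tsv", sep="\t")
    stage("differential_te", n_genes=len(diff), n_excluded=diff.attrs["n_excluded"])
    ann = te.annotate_stretches(tx)
    ann.to_csv(out / "stretch_annotation.tsv", sep="\t")
    stretch = te.stretch_te_comparison(
        te_tables[num_label], te_tables[den_label], ann,
        statistic=config.stretch_statistic, pseudocount=config.pseudocount,
    )
    stretch.to_csv(out / "stretch_te.tsv", sep="\t")
    stage("stretch_te_comparison", n_flagged=int(ann.any(axis=1).sum()))

    if config.bisulfite_enabled:
        ref = _synthetic_trna_ref(config.bisulfite_position)
        write_fasta(out / "trna_ref.fasta", [ref])
        truth = BisulfiteTruth(
            ref[0],
            {config.bisulfite_position: config.bisulfite_methylation_fraction},
            non_conversion_rate=config.bisulfite_non_conversion,
        )
        bs = simulate_bisulfite_reads(ref, truth, config.bisulfite_depth, next(seed_iter))
        aln_bs, bs_counts = tm.bisulfite_align(bs.reads, [ref])
        stage("bisulfite_align", **bs_counts)
        known = {
            ref[0]: [i for i, b in enumerate(ref[1]) if b == "C" and i != config.bisulfite_position]
        }
        aln_bs, _ = tm.collapse_duplicates(aln_bs, mode="keep")
        aln_bs, filt_counts = tm.filter_unconversion_artifacts(aln_bs, known)
        stage("filter_unconversion_artifacts", **filt_counts)
        calls = tm.call_methylation(aln_bs, "estimate", known)
        calls.to_csv(out / "methylation_calls.tsv", sep="\t", index=False)
        quant = tm.quantify_position(calls, ref[0], config.bisulfite_position)
        stage(
            "quantify_position",
            position=config.bisulfite_position,
            percent=quant.percent,
            coverage=quant.coverage,
            status=quant.status,
        )

    config.to_yaml(out / "config_echo.yaml")
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True, default=str))
    return log
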