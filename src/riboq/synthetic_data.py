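"""Seeded generators for toy transcriptomes and simulated reads.

Every generator records a per-read ground-truth table alongside the FASTQ
records it emits, so each downstream stage of the analysis can be validated
against known answers:

* :func:`generate_transcriptome` — random coding transcriptomes with
  controllable codon composition and lognormal mRNA abundances.
* :func:`simulate_footprints` — ribosome footprints whose A-site codon is
  drawn with probability proportional to a per-codon dwell-time multiplier,
  with the 5' end placed exactly 15 nt upstream of the A-site codon and
  lengths drawn from the 28-31 nt gel cut.
* :func:`simulate_rnaseq` — abundance-proportional mRNA fragments.
* :func:`simulate_bisulfite_reads` — bisulfite-converted tRNA reads with a
  configurable per-site methylation fraction and non-conversion error rate.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    BASES,
    SENSE_CODONS,
    STOP_CODONS,
    ReadSet,
    Transcript,
    TranscriptomeFixture,
    normalize_codon,
    warn,
)

TRUTH_COLUMNS = ["read_id", "gene_id", "a_site_codon_index", "length", "is_contaminant"]

#: default footprint lengths (nt), the 28-31 nt gel cut
FOOTPRINT_LENGTHS = (28, 29, 30, 31)

#: distance (nt) from the footprint 5' end to the A-site codon's first base
A_SITE_OFFSET = 15

#: Phred+33 character for the default constant base quality (Q40)
_Q40 = chr(40 + 33)

_CONTAMINANT_ID = "decoy_rRNA"
_CONTAMINANT_SEED = 7002
_CONTAMINANT_LENGTH = 2000


@dataclass
class DwellConfig:
    """Per-codon ribosome dwell-time multipliers for one condition.

    Unlisted codons dwell at the default 1.0. Only sense codons may carry a
    multiplier, and every multiplier must be positive.
    """

    multipliers: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, float] = {}
        for codon, mult in self.multipliers.items():
            c = normalize_codon(codon)
            if c in STOP_CODONS:
                raise ValueError(f"stop codon {codon} cannot carry a dwell multiplier")
            if not mult > 0:
                raise ValueError(f"dwell multiplier for {codon} must be > 0")
            clean[c] = float(mult)
        self.multipliers = clean

    def get(self, codon: str) -> float:
        return self.multipliers.get(codon, 1.0)


@dataclass
class SimulatedReadSet:
    """FASTQ records plus the per-read ground truth that produced them."""

    reads: ReadSet
    truth: pd.DataFrame
    condition: str = "sim"

    def __post_init__(self) -> None:
        if len(self.reads) != len(self.truth):
            raise ValueError("truth table and read set differ in record count")

    def __len__(self) -> int:
        return len(self.reads)

    def write(self, fastq_path, truth_path) -> None:
        self.reads.to_fastq(fastq_path)
        self.truth.to_csv(truth_path, sep="\t", index=False)


@dataclass
class BisulfiteTruth:
    """Ground truth for one simulated bisulfite library.

    ``methylation`` maps 0-based reference positions (which must be cytosines
    in the reference) to the true methylation fraction at that site.
    """

    trna_id: str
    methylation: dict[int, float] = field(default_factory=dict)
    non_conversion_rate: float = 0.01
    seq_error_rate: float = 0.0

    def __post_init__(self) -> None:
        for pos, frac in self.methylation.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"methylation fraction at {pos} outside [0,1]")
        if not 0.0 <= self.non_conversion_rate < 1.0:
            raise ValueError("non_conversion_rate must be in [0,1)")
        if not 0.0 <= self.seq_error_rate < 1.0:
            raise ValueError("seq_error_rate must be in [0,1)")


def contaminant_reference() -> tuple[str, str]:
    """The bundled synthetic rRNA decoy: 2 kb of fixed-seed random sequence.

    A synthetic stand-in for a real rRNA reference; the contaminant filter
    only needs a decoy sequence that simulated contaminant reads are drawn
    from.
    """
    rng = np.random.default_rng(_CONTAMINANT_SEED)
    seq = "".join(rng.choice(list(BASES), size=_CONTAMINANT_LENGTH))
    return _CONTAMINANT_ID, seq


def _codon_weight_vector(codon_weights) -> np.ndarray:
    if codon_weights is None:
        return np.full(len(SENSE_CODONS), 1.0 / len(SENSE_CODONS))
    if isinstance(codon_weights, dict):
        vec = np.zeros(len(SENSE_CODONS))
        for codon, wgt in codon_weights.items():
            c = normalize_codon(codon)
            if c in STOP_CODONS:
                raise ValueError("stop codons cannot carry codon weights")
            vec[SENSE_CODONS.index(c)] = wgt
    else:
        vec = np.asarray(codon_weights, dtype=float)
    if vec.shape != (len(SENSE_CODONS),):
        raise ValueError(f"codon_weights must have {len(SENSE_CODONS)} entries")
    if (vec < 0).any():
        raise ValueError("codon_weights must be non-negative")
    if vec.sum() == 0:
        raise ValueError("codon_weights must not be all zero")
    return vec / vec.sum()


def generate_transcriptome(
    n_genes: int,
    length_range: tuple[int, int] = (100, 200),
    codon_weights=None,
    seed: int = 0,
    utr5_length: int = 0,
    utr3_length: int = 0,
    abundance_sigma: float = 1.0,
) -> TranscriptomeFixture:
    """Generate a random coding transcriptome.

    ``length_range`` is the inclusive range of total codons per gene,
    counting the start and stop codons. Internal codons are drawn from
    ``codon_weights`` over the 61 sense codons (uniform by default). Gene
    abundances are lognormal with the given sigma (sigma=0 gives equal
    abundances).
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    lo, hi = length_range
    if lo < 10 or hi < lo:
        raise ValueError("length_range minimum is 10 codons")
    weights = _codon_weight_vector(codon_weights)
    rng = np.random.default_rng(seed)
    codon_arr = np.array(SENSE_CODONS)
    transcripts = []
    abundance = {}
    for i in range(n_genes):
        gene_id = f"g{i:04d}"
        n_cod = int(rng.integers(lo, hi + 1))
        internal = rng.choice(codon_arr, size=n_cod - 2, p=weights)
        stop = STOP_CODONS[int(rng.integers(len(STOP_CODONS)))]
        cds = "ATG" + "".join(internal) + stop
        utr5 = "".join(rng.choice(list(BASES), size=utr5_length))
        utr3 = "".join(rng.choice(list(BASES), size=utr3_length))
        transcripts.append(Transcript(gene_id, cds, utr5, utr3))
        abundance[gene_id] = float(np.exp(rng.normal(0.0, abundance_sigma))) if abundance_sigma > 0 else 1.0
    return TranscriptomeFixture(transcripts, abundance)


def _apply_substitution_errors(seqs: list[str], error_rate: float, rng) -> list[str]:
    if error_rate <= 0:
        return seqs
    out = []
    base_idx = {b: i for i, b in enumerate(BASES)}
    for seq in seqs:
        n_err = rng.binomial(len(seq), error_rate)
        if n_err == 0:
            out.append(seq)
            continue
        pos = rng.choice(len(seq), size=n_err, replace=False)
        chars = list(seq)
        for p in pos:
            # substitute with one of the three other bases
            shift = 1 + int(rng.integers(3))
            chars[p] = BASES[(base_idx.get(chars[p], 0) + shift) % 4]
        out.append("".join(chars))
    return out


def simulate_footprints(
    tx: TranscriptomeFixture,
    dwell: DwellConfig | None = None,
    condition: str = "sim",
    depth: int = 10000,
    contaminant_fraction: float = 0.0,
    error_rate: float = 0.0,
    seed: int = 0,
    lengths: tuple[int, ...] = FOOTPRINT_LENGTHS,
    contaminant: tuple[str, str] | None = None,
) -> SimulatedReadSet:
    """Simulate ribosome footprints with known A-site ground truth.

    Each mRNA read picks a gene with probability proportional to
    abundance x (sum of dwell multipliers over its eligible codons), then an
    A-site codon proportional to its dwell multiplier. The 5' end sits 15 nt
    upstream of that codon; the length varies only at the 3' end within the
    28-31 nt cut, truncated so reads never extend past the transcript end.
    Codons whose read would run off either transcript end are simply not
    eligible (the resampling rule, applied up front).
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if not 0.0 <= contaminant_fraction < 1.0:
        raise ValueError("contaminant_fraction must be in [0,1)")
    dwell = dwell or DwellConfig()
    rng = np.random.default_rng(seed)
    min_len = min(lengths)
    max_len = max(lengths)
    if tuple(sorted(lengths)) != tuple(range(min_len, max_len + 1)):
        raise ValueError("lengths must be a contiguous range")

    # enumerate eligible (gene, codon) positions with their sampling weight
    genes: list[str] = []
    codon_idx: list[int] = []
    five_primes: list[int] = []
    weights: list[float] = []
    max_allowed: list[int] = []
    for t in tx:
        tlen = len(t.sequence)
        first_ci = max(0, -((t.cds_start - A_SITE_OFFSET) // 3))  # ceil((15-cds_start)/3)
        abund = tx.abundance[t.gene_id]
        for ci in range(first_ci, t.n_codons - 1):  # sense codons only
            five = t.cds_start + 3 * ci - A_SITE_OFFSET
            if five < 0 or five + min_len > tlen:
                continue
            genes.append(t.gene_id)
            codon_idx.append(ci)
            five_primes.append(five)
            weights.append(abund * dwell.get(t.codon_at(ci)))
            max_allowed.append(min(max_len, tlen - five))
    if depth == 0:
        return SimulatedReadSet(
            ReadSet([]), pd.DataFrame(columns=TRUTH_COLUMNS), condition
        )
    if not genes:
        raise ValueError("no eligible footprint positions in transcriptome")

    w = np.asarray(weights)
    n_cont = int(rng.binomial(depth, contaminant_fraction))
    n_mrna = depth - n_cont
    pick = rng.choice(len(w), size=n_mrna, p=w / w.sum())

    max_allowed_arr = np.asarray(max_allowed)[pick]
    n_choices = max_allowed_arr - min_len + 1
    read_len = min_len + (rng.random(n_mrna) * n_choices).astype(int)

    seqs = []
    by_gene = {t.gene_id: t.sequence for t in tx}
    genes_arr = np.asarray(genes)
    fives_arr = np.asarray(five_primes)
    for k in range(n_mrna):
        i = pick[k]
        s = by_gene[genes_arr[i]]
        five = fives_arr[i]
        seqs.append(s[five : five + read_len[k]])

    cont_id, cont_seq = contaminant or contaminant_reference()
    cont_len = min_len + (rng.random(n_cont) * len(lengths)).astype(int)
    cont_start = (rng.random(n_cont) * (len(cont_seq) - cont_len + 1)).astype(int)
    cont_seqs = [cont_seq[s : s + l] for s, l in zip(cont_start, cont_len)]

    all_seqs = _apply_substitution_errors(seqs + cont_seqs, error_rate, rng)
    gene_ids = list(genes_arr[pick]) + [cont_id] * n_cont
    a_idx = list(np.asarray(codon_idx)[pick]) + [-1] * n_cont
    lens = list(read_len) + list(cont_len)
    is_cont = [False] * n_mrna + [True] * n_cont

    order = rng.permutation(depth)
    read_ids = [f"{condition}_r{i:07d}" for i in range(depth)]
    records = [(read_ids[j], all_seqs[i], _Q40 * len(all_seqs[i])) for j, i in enumerate(order)]
    truth = pd.DataFrame(
        {
            "read_id": read_ids,
            "gene_id": [gene_ids[i] for i in order],
            "a_site_codon_index": [int(a_idx[i]) for i in order],
            "length": [int(lens[i]) for i in order],
            "is_contaminant": [is_cont[i] for i in order],
        }
    )
    return SimulatedReadSet(ReadSet(records), truth, condition)


def truth_to_asites(tx: TranscriptomeFixture, truth: pd.DataFrame) -> pd.DataFrame:
    """Ground-truth A-site table for the non-contaminant reads of a simulation.

    Bypasses read processing entirely: used to exercise the occupancy stages
    against the generative truth, and as the reference when scoring the read
    pipeline's assignments.
    """
    t = truth[~truth["is_contaminant"]]
    codons = {g: tx.get(g).codons for g in set(t["gene_id"])}
    return pd.DataFrame(
        {
            "read_id": t["read_id"].to_numpy(),
            "gene_id": t["gene_id"].to_numpy(),
            "a_site_codon_index": t["a_site_codon_index"].to_numpy(),
            "codon": [
                codons[g][i]
                for g, i in zip(t["gene_id"], t["a_site_codon_index"])
            ],
        }
    )


def simulate_rnaseq(
    tx: TranscriptomeFixture,
    depth: int = 10000,
    read_length: int = 50,
    error_rate: float = 0.0,
    seed: int = 0,
    condition: str = "rna",
) -> SimulatedReadSet:
    """Simulate RNA-seq fragments: gene ~ abundance x length, start uniform."""
    if read_length < 25:
        raise ValueError("read_length must be >= 25 (the RNA-seq analysis floor)")
    rng = np.random.default_rng(seed)
    usable = [t for t in tx if len(t.sequence) >= read_length]
    skipped = [t.gene_id for t in tx if len(t.sequence) < read_length]
    if skipped:
        warn(f"transcripts shorter than read length excluded: {', '.join(skipped)}")
    if depth == 0 or not usable:
        return SimulatedReadSet(ReadSet([]), pd.DataFrame(columns=TRUTH_COLUMNS), condition)
    w = np.array([tx.abundance[t.gene_id] * len(t.sequence) for t in usable])
    pick = rng.choice(len(usable), size=depth, p=w / w.sum())
    seqs = []
    gene_ids = []
    for i in pick:
        t = usable[i]
        start = int(rng.integers(0, len(t.sequence) - read_length + 1))
        seqs.append(t.sequence[start : start + read_length])
        gene_ids.append(t.gene_id)
    seqs = _apply_substitution_errors(seqs, error_rate, rng)
    read_ids = [f"{condition}_r{i:07d}" for i in range(depth)]
    records = [(rid, s, _Q40 * len(s)) for rid, s in zip(read_ids, seqs)]
    truth = pd.DataFrame(
        {
            "read_id": read_ids,
            "gene_id": gene_ids,
            "a_site_codon_index": -1,
            "length": read_length,
            "is_contaminant": False,
        }
    )
    return SimulatedReadSet(ReadSet(records), truth, condition)


def simulate_bisulfite_reads(
    ref: tuple[str, str],
    truth: BisulfiteTruth,
    depth: int = 1000,
    seed: int = 0,
) -> SimulatedReadSet:
    """Simulate full-length bisulfite-converted reads over one tRNA reference.

    Each reference cytosine is emitted as C with probability
    f + (1-f) * non_conversion_rate (f = its methylation fraction, 0 where
    unlisted) and as T otherwise. Non-C bases are copied subject to the
    sequencing error rate.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    ref_id, ref_seq = ref
    if truth.trna_id != ref_id:
        raise ValueError("truth.trna_id does not match reference id")
    for pos in truth.methylation:
        if pos < 0 or pos >= len(ref_seq) or ref_seq[pos] != "C":
            raise ValueError(f"methylation fraction at non-cytosine position {pos}")
    rng = np.random.default_rng(seed)
    n = len(ref_seq)
    c_mask = np.frombuffer(ref_seq.encode(), dtype="S1") == b"C"
    p_c = np.zeros(n)
    eps = truth.non_conversion_rate
    for i in np.flatnonzero(c_mask):
        f = truth.methylation.get(int(i), 0.0)
        p_c[i] = f + (1.0 - f) * eps

    base_idx = {b: i for i, b in enumerate(BASES)}
    template = np.array(list(ref_seq))
    records = []
    read_ids = [f"{ref_id}_bs{i:06d}" for i in range(depth)]
    for rid in read_ids:
        chars = template.copy()
        u = rng.random(n)
        chars[c_mask] = np.where(u[c_mask] < p_c[c_mask], "C", "T")
        if truth.seq_error_rate > 0:
            non_c = np.flatnonzero(~c_mask)
            err = non_c[rng.random(len(non_c)) < truth.seq_error_rate]
            for p in err:
                shift = 1 + int(rng.integers(3))
                chars[p] = BASES[(base_idx[chars[p]] + shift) % 4]
        seq = "".join(chars)
        records.append((rid, seq, _Q40 * n))
    truth_df = pd.DataFrame(
        {
            "read_id": read_ids,
            "gene_id": ref_id,
            "a_site_codon_index": -1,
            "length": n,
            "is_contaminant": False,
        }
    )
    return SimulatedReadSet(ReadSet(records), truth_df, condition="bisulfite")
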