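"""Bulk per-codon A-site occupancy, condition ratios, tAI and enrichment.

Bulk codon occupancy for a sample is the proportion of A-site assignments
landing on each sense codon divided by that codon's background usage. The
primary usage normalizer is *local*: the codon proportions over the three
codons directly 3' of each read's A-site. For single-sample analyses a
transcriptome-wide usage compiled from the CDSs represented in the
footprints is available as an alternative.

Condition comparisons divide occupancy in one condition by occupancy in a
control condition, replicate by replicate, reporting mean +/- SEM.

The tRNA adaptation index (tAI) weighs each codon's decoding tRNA gene copy
numbers by codon:anticodon pairing efficiencies (1 - s); tAI is the weight
normalized by the maximum over codons. The bundled s-values are the standard
published wobble penalties; the bundled gene-copy table is a synthetic
stand-in (see ``data/tgcn_synthetic.tsv``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    GENETIC_CODE,
    SENSE_CODONS,
    TranscriptomeFixture,
    normalize_codon,
    revcomp,
    warn,
)

#: synonymous C-ending / U-ending queuosine codon pairs (Asp, His, Asn, Tyr)
Q_CODON_PAIRS = [("GAC", "GAT"), ("CAC", "CAT"), ("AAC", "AAT"), ("TAC", "TAT")]

DEFAULT_MIN_CODON_COUNT = 30


@dataclass
class OccupancyProfile:
    """Per-codon A-site occupancy for one sample.

    ``table`` is indexed by the 61 sense codons with columns ``n`` (A-site
    count), ``proportion``, ``usage`` and ``occupancy``; occupancy is NaN for
    codons with zero usage or fewer than the minimum A-site count.
    """

    sample_id: str
    table: pd.DataFrame

    @property
    def occupancy(self) -> pd.Series:
        return self.table["occupancy"]


def _codon_series(counts: dict[str, float]) -> pd.Series:
    s = pd.Series(0.0, index=list(SENSE_CODONS))
    for codon, n in counts.items():
        if codon in s.index:
            s[codon] += n
    return s


def local_codon_usage(asites: pd.DataFrame, tx: TranscriptomeFixture) -> pd.Series:
    """Usage as proportions over the 3 codons 3' of each read's A-site.

    The context is truncated at the last sense codon (the stop codon never
    contributes); reads near the stop contribute fewer context codons.
    """
    if len(asites) == 0:
        raise ValueError("empty A-site table")
    counts: dict[str, float] = {}
    codons_of = {t.gene_id: t.codons for t in tx}
    n_codons = {t.gene_id: t.n_codons for t in tx}
    grouped = asites.groupby(["gene_id", "a_site_codon_index"]).size()
    for (gene, ci), n in grouped.items():
        cods = codons_of[gene]
        last_sense = n_codons[gene] - 2
        for j in range(int(ci) + 1, min(int(ci) + 3, last_sense) + 1):
            c = cods[j]
            counts[c] = counts.get(c, 0.0) + n
    usage = _codon_series(counts)
    total = usage.sum()
    if total == 0:
        raise ValueError("no downstream context codons found")
    return usage / total


def transcriptome_usage(
    tx: TranscriptomeFixture,
    gene_ids: list[str] | None = None,
    weights: pd.Series | None = None,
) -> pd.Series:
    """Usage compiled from CDS sequences (optionally weighted per gene)."""
    counts: dict[str, float] = {}
    for t in tx:
        if gene_ids is not None and t.gene_id not in set(gene_ids):
            continue
        w = float(weights.get(t.gene_id, 0.0)) if weights is not None else 1.0
        if w == 0.0 and weights is not None:
            continue
        for c in t.codons[:-1]:
            counts[c] = counts.get(c, 0.0) + w
    usage = _codon_series(counts)
    return usage / usage.sum()


def bulk_codon_occupancy(
    asites: pd.DataFrame,
    usage: pd.Series,
    sample_id: str = "sample",
    min_count: int = DEFAULT_MIN_CODON_COUNT,
) -> OccupancyProfile:
    """Divide A-site codon proportions by usage proportions.

    Codons with zero usage or fewer than ``min_count`` A-site reads are
    reported as missing (NaN), never infinite.
    """
    if len(asites) == 0:
        raise ValueError("empty A-site table")
    n = _codon_series(asites["codon"].value_counts().to_dict())
    proportion = n / n.sum()
    usage = usage.reindex(list(SENSE_CODONS)).fillna(0.0)
    occupancy = proportion.where(usage > 0) / usage.where(usage > 0)
    occupancy[n < min_count] = np.nan
    table = pd.DataFrame(
        {
            "amino_acid": [GENETIC_CODE[c] for c in SENSE_CODONS],
            "n": n.astype(int),
            "proportion": proportion,
            "usage": usage,
            "occupancy": occupancy,
        }
    )
    table.index.name = "codon"
    return OccupancyProfile(sample_id, table)


def occupancy_ratio(
    numerator: list[OccupancyProfile],
    denominator: list[OccupancyProfile],
    mode: str = "paired",
) -> pd.DataFrame:
    """Per-codon occupancy ratio between two replicated conditions.

    ``paired`` (default) divides replicate i of the numerator condition by
    replicate i of the denominator and reports mean +/- SEM over the pairs;
    ``all-pairs`` uses every numerator x denominator combination;
    ``ratio-of-means`` divides the replicate-mean occupancies, with
    first-order error propagation. Codons missing (or zero) in any involved
    replicate are omitted.
    """
    if len(numerator) != len(denominator):
        raise ValueError("unequal replicate counts")
    if not numerator:
        raise ValueError("no replicates")
    num = pd.concat([p.occupancy for p in numerator], axis=1)
    den = pd.concat([p.occupancy for p in denominator], axis=1)
    if (den.fillna(1.0) <= 0).any().any():
        warn("zero occupancy in a denominator replicate; affected codons omitted")
        den = den.where(den > 0)
    n_rep = len(numerator)
    if mode == "paired":
        ratios = num.to_numpy() / den.to_numpy()
        valid = (~np.isnan(ratios)).sum(axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.where(valid == n_rep, np.nanmean(ratios, axis=1), np.nan)
            sem = np.where(
                valid == n_rep, np.nanstd(ratios, axis=1, ddof=1) / np.sqrt(n_rep), np.nan
            )
        n_out = n_rep
    elif mode == "all-pairs":
        pairs = [
            num.iloc[:, i].to_numpy() / den.iloc[:, j].to_numpy()
            for i in range(n_rep)
            for j in range(n_rep)
        ]
        ratios = np.column_stack(pairs)
        complete = (~np.isnan(ratios)).all(axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.where(complete, np.nanmean(ratios, axis=1), np.nan)
            sem = np.where(
                complete,
                np.nanstd(ratios, axis=1, ddof=1) / np.sqrt(ratios.shape[1]),
                np.nan,
            )
        n_out = n_rep * n_rep
    elif mode == "ratio-of-means":
        complete = num.notna().all(axis=1) & den.notna().all(axis=1)
        mnum, mden = num.mean(axis=1), den.mean(axis=1)
        snum = num.std(axis=1, ddof=1) / np.sqrt(n_rep)
        sden = den.std(axis=1, ddof=1) / np.sqrt(n_rep)
        mean = (mnum / mden).where(complete).to_numpy()
        sem = (
            (mnum / mden) * np.sqrt((snum / mnum) ** 2 + (sden / mden) ** 2)
        ).where(complete).to_numpy()
        n_out = n_rep
    else:
        raise ValueError(f"unknown pairing mode: {mode}")
    out = pd.DataFrame(
        {"mean": mean, "sem": sem, "n_replicates": n_out}, index=num.index
    )
    out.index.name = "codon"
    return out.dropna(subset=["mean"])


def c_vs_u_ratio(
    ratios: pd.DataFrame, codon_pairs: list[tuple[str, str]] | None = None
) -> pd.DataFrame:
    """Relative ratio of C-ending over U-ending synonymous codon pairs."""
    pairs = codon_pairs or Q_CODON_PAIRS
    rows = []
    for c_codon, u_codon in pairs:
        c, u = normalize_codon(c_codon), normalize_codon(u_codon)
        if c[:2] != u[:2] or c[2] != "C" or u[2] != "T" or GENETIC_CODE.get(c) != GENETIC_CODE.get(u):
            raise ValueError(f"not a synonymous C/U-ending pair: {c_codon}/{u_codon}")
        if c not in ratios.index or u not in ratios.index:
            raise ValueError(f"codon missing from ratio table: {c_codon}/{u_codon}")
        rc, ru = ratios.loc[c], ratios.loc[u]
        value = rc["mean"] / ru["mean"]
        sem = value * np.sqrt(
            (rc["sem"] / rc["mean"]) ** 2 + (ru["sem"] / ru["mean"]) ** 2
        )
        rows.append((c, u, value, sem))
    return pd.DataFrame(rows, columns=["c_codon", "u_codon", "ratio", "sem"])


# ---------------------------------------------------------------------------
# tRNA adaptation index
# ---------------------------------------------------------------------------


@dataclass
class TAIParameters:
    """tRNA gene copy numbers by anticodon plus wobble pairing penalties.

    ``tgcn`` maps anticodons (5'->3', DNA) to non-negative gene copy counts;
    ``s_values`` maps pairing classes (anticodon-34 base : codon-3 base, with
    A34 read as inosine I) to penalties in [0, 1].
    """

    tgcn: dict[str, int]
    s_values: dict[str, float]

    def __post_init__(self) -> None:
        self.tgcn = {normalize_codon(a): int(n) for a, n in self.tgcn.items()}
        if any(n < 0 for n in self.tgcn.values()):
            raise ValueError("tRNA gene copy numbers must be non-negative")
        if any(not 0.0 <= s <= 1.0 for s in self.s_values.values()):
            raise ValueError("s-values must lie in [0,1]")


def load_tai_parameters(tgcn_path=None, s_path=None) -> TAIParameters:
    """Load tGCN and s-value TSVs (bundled defaults when paths are omitted)."""
    data = resources.files("riboq") / "data"
    tgcn_df = pd.read_csv(tgcn_path or data / "tgcn_synthetic.tsv", sep="\t", comment="#")
    s_df = pd.read_csv(s_path or data / "wobble_s_values.tsv", sep="\t", comment="#")
    return TAIParameters(
        tgcn=dict(zip(tgcn_df["anticodon"], tgcn_df["gene_copy_number"])),
        s_values=dict(zip(s_df["pairing"], s_df["s"])),
    )


def _decoding_anticodons(codon: str) -> list[tuple[str, str]]:
    """(anticodon, pairing class) pairs that can decode *codon*.

    Watson-Crick plus the standard eukaryotic wobble: G34 reads NNU, A34
    (as inosine) reads NNU/NNC/NNA, U34 reads NNG. ATG and TGG are decoded
    only by their Watson-Crick anticodons.
    """
    if codon == "ATG":
        return [("CAT", "C:G")]
    if codon == "TGG":
        return [("CCA", "C:G")]
    wc = revcomp(codon)
    third = codon[2]
    if third == "T":
        return [(wc, "I:U"), (revcomp(codon[:2] + "C"), "G:U")]
    if third == "C":
        return [(wc, "G:C"), (revcomp(codon[:2] + "T"), "I:C")]
    if third == "A":
        return [(wc, "U:A"), (revcomp(codon[:2] + "T"), "I:A")]
    return [(wc, "C:G"), (revcomp(codon[:2] + "A"), "U:G")]


def compute_tai(params: TAIParameters) -> pd.DataFrame:
    """Per-codon tAI: pairing-weighted gene copy sums, normalized to max 1.

    w[codon] = sum over decoding anticodons of (1 - s) * tGCN(anticodon).
    Codons with no decoding tRNA receive the geometric mean of the nonzero
    weights before normalization (flagged in the ``imputed`` column), which
    keeps 1/tAI finite.
    """
    w = {}
    for codon in SENSE_CODONS:
        total = 0.0
        for anticodon, cls in _decoding_anticodons(codon):
            if cls not in params.s_values:
                raise ValueError(f"no s-value for pairing class {cls}")
            total += (1.0 - params.s_values[cls]) * params.tgcn.get(anticodon, 0)
        w[codon] = total
    ws = pd.Series(w)
    imputed = ws == 0.0
    if imputed.any():
        ws[imputed] = stats.gmean(ws[~imputed])
    tai = ws / ws.max()
    out = pd.DataFrame({"w": ws, "tai": tai, "imputed": imputed})
    out.index.name = "codon"
    return out


def occupancy_tai_correlation(
    profile: OccupancyProfile, tai: pd.Series
) -> tuple[float, float]:
    """Spearman correlation between 1/tAI and A-site codon occupancy."""
    occ = profile.occupancy.dropna()
    common = occ.index.intersection(tai.dropna().index)
    if len(common) < 10:
        raise ValueError("need at least 10 codons present in both vectors")
    inv_tai = 1.0 / tai[common]
    if occ[common].nunique() == 1 or inv_tai.nunique() == 1:
        warn("constant vector; Spearman correlation undefined")
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(inv_tai, occ[common])
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# relative enrichment around the A-site
# ---------------------------------------------------------------------------


def relative_enrichment_profile(
    asites: pd.DataFrame,
    tx: TranscriptomeFixture,
    target_codons: list[str],
    max_offset: int = 90,
) -> pd.DataFrame:
    """Mean relative enrichment of codons at offsets around the A-site.

    For each offset k in [-max_offset, +max_offset], the proportion of reads
    whose codon at (A-site index + k) is the target codon, divided by the
    expected proportion if each read's A-site were uniform over its gene's
    sense codons (read-count weighted). Offsets never eligible for any read
    are missing.
    """
    targets = [normalize_codon(c) for c in target_codons]
    offsets = np.arange(-max_offset, max_offset + 1)
    codons_of = {t.gene_id: np.array(t.codons[:-1]) for t in tx}  # sense codons
    grouped = asites.groupby(["gene_id", "a_site_codon_index"]).size()
    gene_reads = asites.groupby("gene_id").size()

    num = pd.DataFrame(0.0, index=targets, columns=offsets)
    num_total = pd.Series(0.0, index=offsets)
    for (gene, ci), n in grouped.items():
        cods = codons_of[gene]
        ks = offsets[(offsets + int(ci) >= 0) & (offsets + int(ci) < len(cods))]
        at = cods[ks + int(ci)]
        num_total[ks] += n
        for c in targets:
            num.loc[c, ks[at == c]] += n

    den = pd.DataFrame(0.0, index=targets, columns=offsets)
    den_total = pd.Series(0.0, index=offsets)
    for gene, n in gene_reads.items():
        cods = codons_of[gene]
        L = len(cods)
        w = n / L  # uniform A-site placement over sense codons
        for k in offsets:
            lo, hi = max(0, k), min(L, L + k)  # eligible positions at offset k
            if hi <= lo:
                continue
            window = cods[lo:hi]
            den_total[k] += w * len(window)
            for c in targets:
                den.loc[c, k] += w * (window == c).sum()

    with np.errstate(invalid="ignore", divide="ignore"):
        num_prop = num.div(num_total, axis=1)
        den_prop = den.div(den_total, axis=1)
        enrich = num_prop / den_prop
    enrich.index.name = "codon"
    enrich.columns.name = "offset"
    return enrich
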