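"""Per-gene translation efficiency, differential TE and Q-codon stretches.

Translation efficiency (TE) is the library-size-normalized footprint count
divided by the library-size-normalized mRNA count. Differential TE between
conditions is assessed with an explicit log-ratio Welch t-test with
Benjamini-Hochberg adjustment (a documented substitute for external
differential-TE engines), keeping the conventional reporting thresholds
(p < 0.05 unadjusted, adjusted p < 0.1).

The stretch analysis flags genes carrying runs of queuosine-decoded codons
(at least 2 consecutive codons of the same Q amino acid - Asp, His, Asn or
Tyr - or at least 3 consecutive codons from the 8-codon Q set) and compares
the median TE change of flagged versus unflagged genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import GENETIC_CODE, Q_AMINO_ACIDS, Q_CODONS, TranscriptomeFixture, warn

DEFAULT_MIN_RNA_COUNT = 10
DEFAULT_PSEUDOCOUNT = 0.5

STRETCH_FLAGS = ["asp_run2", "his_run2", "asn_run2", "tyr_run2", "q_run3"]
_AA_FLAG = {"D": "asp_run2", "H": "his_run2", "N": "asn_run2", "Y": "tyr_run2"}


def count_reads_per_gene(
    aln: pd.DataFrame, gene_universe: list[str] | None = None
) -> pd.Series:
    """Aligned-read counts per gene (zero-filled over the gene universe)."""
    counts = aln.groupby("gene_id").size() if len(aln) else pd.Series(dtype=int)
    if gene_universe is not None:
        counts = counts.reindex(gene_universe, fill_value=0)
    return counts.astype(int).rename("count")


def compute_te(
    fp_counts: pd.Series,
    rna_counts: pd.Series,
    min_rna: int = DEFAULT_MIN_RNA_COUNT,
) -> pd.DataFrame:
    """TE = (footprint count / fp library size) / (rna count / rna library size).

    Library sizes are the count sums over the shared gene universe. Genes
    with an mRNA count below ``min_rna`` get a missing TE.
    """
    genes = fp_counts.index.union(rna_counts.index)
    fp = fp_counts.reindex(genes, fill_value=0).astype(float)
    rna = rna_counts.reindex(genes, fill_value=0).astype(float)
    if fp.sum() == 0 or rna.sum() == 0:
        raise ValueError("zero total counts")
    with np.errstate(invalid="ignore", divide="ignore"):
        te = (fp / fp.sum()) / (rna / rna.sum())
    te[rna < min_rna] = np.nan
    out = pd.DataFrame({"fp_count": fp.astype(int), "rna_count": rna.astype(int), "te": te})
    out.index.name = "gene_id"
    return out


def _log2_te(te_tables: list[pd.DataFrame], pseudocount: float) -> pd.DataFrame:
    """Per-replicate log2 TE with a pseudocount, median-centered per replicate.

    Total-count library normalization is composition-sensitive: a handful of
    strongly shifted genes drags every other gene's apparent TE in the
    opposite direction. Centering each replicate's log2 TE on its median
    recalibrates the library under the standard assumption that most genes
    are unchanged (the same idea as median-of-ratios size factors).
    """
    cols = {}
    for i, t in enumerate(te_tables):
        fp, rna = t["fp_count"].astype(float), t["rna_count"].astype(float)
        log2te = (
            np.log2(fp + pseudocount)
            - np.log2(fp.sum())
            - np.log2(rna + pseudocount)
            + np.log2(rna.sum())
        )
        log2te[t["te"].isna()] = np.nan
        cols[f"rep{i}"] = log2te - np.nanmedian(log2te)
    return pd.DataFrame(cols)


def differential_te(
    te_cond_a: list[pd.DataFrame],
    te_cond_b: list[pd.DataFrame],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Welch t-test on per-replicate log2 TE between two conditions.

    Returns per gene: log2 fold change (A over B), the two-sided p-value,
    the Benjamini-Hochberg adjusted p-value, and flags at the conventional
    thresholds. Genes with a missing TE in any replicate are excluded.
    """
    if len(te_cond_a) < 2 or len(te_cond_b) < 2:
        raise ValueError("need >= 2 replicates per condition")
    a = _log2_te(te_cond_a, pseudocount)
    b = _log2_te(te_cond_b, pseudocount)
    genes = a.index.intersection(b.index)
    a, b = a.loc[genes], b.loc[genes]
    complete = a.notna().all(axis=1) & b.notna().all(axis=1)
    n_excluded = int((~complete).sum())
    a, b = a[complete], b[complete]
    am, bm = a.to_numpy(), b.to_numpy()
    log2fc = am.mean(axis=1) - bm.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(am, bm, axis=1, equal_var=False)
    # zero within-group variance: identical means -> p=1, different -> p=0
    degenerate = np.isnan(p)
    p = np.where(degenerate & (log2fc == 0), 1.0, p)
    p = np.where(degenerate & (log2fc != 0), 0.0, p)
    p_adj = multipletests(p, method="fdr_bh")[1] if len(p) else np.array([])
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": p,
            "p_adj": p_adj,
            "sig_p05": p < 0.05,
            "sig_adj01": p_adj < 0.1,
        },
        index=a.index,
    )
    out.index.name = "gene_id"
    out.attrs["n_excluded"] = n_excluded
    out.attrs["test"] = "welch_t_log2te"
    return out


def annotate_stretches(tx: TranscriptomeFixture) -> pd.DataFrame:
    """Flag genes with runs of queuosine-decoded codons.

    ``asp_run2`` .. ``tyr_run2``: at least one run of >= 2 consecutive codons
    for the same Q amino acid (synonymous codons count as the same run);
    ``q_run3``: at least one run of >= 3 consecutive codons drawn from the
    full 8-codon Q set. Recomputable from the CDS alone.
    """
    q_set = set(Q_CODONS)
    rows = []
    for t in tx:
        codons = t.codons[:-1]
        aas = [GENETIC_CODE[c] for c in codons]
        flags = dict.fromkeys(STRETCH_FLAGS, False)
        run_aa, run_aa_len = None, 0
        run_q_len = 0
        for codon, aa in zip(codons, aas):
            if aa == run_aa:
                run_aa_len += 1
            else:
                run_aa, run_aa_len = aa, 1
            if aa in Q_AMINO_ACIDS and run_aa_len >= 2:
                flags[_AA_FLAG[aa]] = True
            run_q_len = run_q_len + 1 if codon in q_set else 0
            if run_q_len >= 3:
                flags["q_run3"] = True
        rows.append({"gene_id": t.gene_id, **flags})
    return pd.DataFrame(rows).set_index("gene_id")


def stretch_te_comparison(
    te_cond_a: list[pd.DataFrame],
    te_cond_b: list[pd.DataFrame],
    annotation: pd.DataFrame,
    statistic: str = "delta",
    min_group: int = 5,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Median TE difference of stretch-flagged vs unflagged genes.

    With ``statistic='delta'`` (default) the per-gene quantity is the mean
    log2 TE change between the two conditions; ``'te'`` uses condition A's
    mean log2 TE alone. Per flag class: median(flagged) - median(unflagged),
    a two-sided rank-sum p-value, and BH adjustment over the flag classes.
    Groups smaller than ``min_group`` get no p-value.
    """
    a = _log2_te(te_cond_a, pseudocount)
    b = _log2_te(te_cond_b, pseudocount)
    genes = a.index.intersection(b.index).intersection(annotation.index)
    a, b = a.loc[genes], b.loc[genes]
    complete = a.notna().all(axis=1) & b.notna().all(axis=1)
    genes = genes[complete]
    if statistic == "delta":
        value = a.loc[genes].mean(axis=1) - b.loc[genes].mean(axis=1)
    elif statistic == "te":
        value = a.loc[genes].mean(axis=1)
    else:
        raise ValueError(f"unknown statistic: {statistic}")
    ann = annotation.loc[genes]
    rows = []
    for flag in STRETCH_FLAGS:
        flagged = value[ann[flag]]
        unflagged = value[~ann[flag]]
        if len(flagged) == 0:
            warn(f"no genes carry flag {flag}; result missing")
            rows.append((flag, 0, len(unflagged), np.nan, np.nan))
            continue
        diff = float(flagged.median() - unflagged.median())
        if len(flagged) < min_group or len(unflagged) < min_group:
            warn(f"group below {min_group} genes for {flag}; no p-value")
            p = np.nan
        elif flagged.nunique() == 1 and unflagged.nunique() == 1 and diff == 0:
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(flagged, unflagged, alternative="two-sided").pvalue)
        rows.append((flag, len(flagged), len(unflagged), diff, p))
    out = pd.DataFrame(
        rows, columns=["flag", "n_flagged", "n_unflagged", "median_diff", "p"]
    ).set_index("flag")
    tested = out["p"].notna()
    out["p_adj"] = np.nan
    if tested.any():
        out.loc[tested, "p_adj"] = multipletests(out.loc[tested, "p"], method="fdr_bh")[1]
    out.attrs["statistic"] = statistic
    out.attrs["test"] = "two-sided rank-sum, BH over flag classes"
    return out
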