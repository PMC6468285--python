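"""Cytosine-5 methylation calling for tRNAs from bisulfite sequencing.

Bisulfite treatment deaminates unmethylated cytosines to uracil (sequenced
as T) while methylated cytosines resist conversion, so residual C at a
reference C position signals methylation. Reads are aligned in converted
space (both read and reference C->T collapsed, exhaustive ungapped scan over
the small tRNA reference set), duplicate collapsed sequences are summarized,
incompletely converted reads are filtered out, and per-position methylation
is called with a Poisson test against the background non-conversion rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import ReadSet, warn

DEFAULT_MIN_COVERAGE = 10
DEFAULT_ALPHA = 0.05
DEFAULT_FRACTION_FLOOR = 0.1


@dataclass
class BisulfiteAlignment:
    """Converted-space alignments plus per-reference-C observed states.

    ``reads``: one row per retained read (read_id, trna_id, offset,
    collapsed_seq). ``states``: one row per (read, reference C position)
    with state C (unconverted), T (converted) or N (other).
    """

    reads: pd.DataFrame
    states: pd.DataFrame
    refs: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.reads)


def _collapse(seq: str) -> str:
    return seq.replace("C", "T")


def bisulfite_align(
    reads: ReadSet,
    refs: list[tuple[str, str]],
    max_mismatches: int = 2,
) -> tuple[BisulfiteAlignment, dict[str, int]]:
    """Exhaustive ungapped alignment in C->T collapsed space.

    Each read is matched full-length at every offset of every reference with
    both sequences C->T collapsed; the unique best (fewest collapsed
    mismatches) placement is kept. Reads tied between references are dropped
    as ambiguous. The original read then records the C/T state at each
    reference C position it covers.
    """
    if not refs:
        raise ValueError("contaminant-free tRNA reference set must be non-empty")
    collapsed_refs = [(rid, seq, _collapse(seq)) for rid, seq in refs]
    counts = {"input": len(reads), "aligned": 0, "unaligned": 0, "ambiguous": 0}
    read_rows = []
    state_rows = []
    for rid, seq, _ in reads:
        cread = _collapse(seq)
        L = len(cread)
        best_mm = max_mismatches + 1
        hits: list[tuple[str, int]] = []
        for ref_id, _, cref in collapsed_refs:
            for off in range(0, len(cref) - L + 1):
                mm = 0
                for a, b in zip(cread, cref[off : off + L]):
                    if a != b:
                        mm += 1
                        if mm > best_mm:
                            break
                if mm < best_mm:
                    best_mm = mm
                    hits = [(ref_id, off)]
                elif mm == best_mm and mm <= max_mismatches:
                    hits.append((ref_id, off))
        if best_mm > max_mismatches:
            counts["unaligned"] += 1
            continue
        if len({r for r, _ in hits}) > 1:
            counts["ambiguous"] += 1
            continue
        ref_id, off = min(hits)
        counts["aligned"] += 1
        read_rows.append((rid, ref_id, off, cread))
        orig = next(s for r, s in refs if r == ref_id)
        for pos in range(off, off + L):
            if orig[pos] == "C":
                base = seq[pos - off]
                state = base if base in ("C", "T") else "N"
                state_rows.append((rid, ref_id, pos, state))
    aln = BisulfiteAlignment(
        pd.DataFrame(read_rows, columns=["read_id", "trna_id", "offset", "collapsed_seq"]),
        pd.DataFrame(state_rows, columns=["read_id", "trna_id", "position", "state"]),
        refs=dict(refs),
    )
    return aln, counts


def collapse_duplicates(
    aln: BisulfiteAlignment, mode: str = "keep"
) -> tuple[BisulfiteAlignment, dict[str, int]]:
    """Summarize reads identical after C->T collapse at the same placement.

    ``keep`` (default) retains all reads: removing collapse-identical reads
    would bias methylation fractions, since reads differing only in C/T
    state collapse to the same sequence. ``remove`` keeps one representative
    per (reference, offset, collapsed sequence) group, reproducing the
    summarization that treats such reads as duplicates.
    """
    n_groups = int(
        aln.reads.groupby(["trna_id", "offset", "collapsed_seq"]).ngroups
    ) if len(aln.reads) else 0
    counts = {"input": len(aln.reads), "groups": n_groups, "output": len(aln.reads)}
    if mode == "keep" or len(aln.reads) == 0:
        return aln, counts
    if mode != "remove":
        raise ValueError(f"unknown duplicate mode: {mode}")
    kept = aln.reads.drop_duplicates(subset=["trna_id", "offset", "collapsed_seq"], keep="first")
    states = aln.states[aln.states["read_id"].isin(set(kept["read_id"]))]
    counts["output"] = len(kept)
    return BisulfiteAlignment(kept.reset_index(drop=True), states.reset_index(drop=True), aln.refs), counts


def filter_unconversion_artifacts(
    aln: BisulfiteAlignment,
    known_unmethylated: dict[str, list[int]] | None,
    max_unconverted_fraction: float = 0.5,
) -> tuple[BisulfiteAlignment, dict[str, int]]:
    """Drop reads that look incompletely bisulfite-converted.

    A read is removed when its fraction of unconverted Cs at the configured
    known-unmethylated reference positions exceeds the threshold. Without
    configured positions the filter is skipped with a warning.
    """
    if not 0.0 < max_unconverted_fraction <= 1.0:
        raise ValueError("max_unconverted_fraction must be in (0,1]")
    counts = {"input": len(aln.reads), "removed": 0, "output": len(aln.reads)}
    if not known_unmethylated:
        warn("no known-unmethylated positions configured; unconversion filter skipped")
        return aln, counts
    keys = {
        (trna, pos) for trna, positions in known_unmethylated.items() for pos in positions
    }
    st = aln.states
    mask = [
        (t, p) in keys for t, p in zip(st["trna_id"], st["position"])
    ]
    at_known = st[np.array(mask, dtype=bool)] if len(st) else st
    informative = at_known[at_known["state"].isin(["C", "T"])]
    frac = informative.groupby("read_id")["state"].agg(lambda s: (s == "C").mean())
    bad = set(frac.index[frac > max_unconverted_fraction])
    counts["removed"] = len(bad)
    kept = aln.reads[~aln.reads["read_id"].isin(bad)].reset_index(drop=True)
    states = aln.states[~aln.states["read_id"].isin(bad)].reset_index(drop=True)
    counts["output"] = len(kept)
    return BisulfiteAlignment(kept, states, aln.refs), counts


def call_methylation(
    aln: BisulfiteAlignment,
    background_rate="estimate",
    known_unmethylated: dict[str, list[int]] | None = None,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    alpha: float = DEFAULT_ALPHA,
    fraction_floor: float = DEFAULT_FRACTION_FLOOR,
) -> pd.DataFrame:
    """Per-position Poisson test of unconverted counts against background.

    The background non-conversion rate lambda is either supplied or
    estimated as the pooled unconverted fraction over the configured
    known-unmethylated positions. For each reference C with coverage >=
    ``min_coverage``, the p-value is the upper tail P(X >= n_unconverted)
    of a Poisson with mean n_reads * lambda. Status is ``methylated`` when
    p < alpha and the fraction exceeds ``fraction_floor``, ``unmethylated``
    when the count is background-consistent (p >= alpha), else ``ambiguous``.
    """
    st = aln.states[aln.states["state"].isin(["C", "T"])]
    if background_rate == "estimate":
        if not known_unmethylated:
            raise ValueError("background_rate='estimate' needs known_unmethylated positions")
        keys = {
            (t, p) for t, positions in known_unmethylated.items() for p in positions
        }
        mask = np.array([(t, p) in keys for t, p in zip(st["trna_id"], st["position"])], dtype=bool) if len(st) else np.array([], dtype=bool)
        at_known = st[mask]
        if len(at_known) == 0:
            raise ValueError("no coverage at known-unmethylated positions")
        lam = float((at_known["state"] == "C").mean())
        lam = max(lam, 1e-6)
    else:
        lam = float(background_rate)
        if not 0.0 < lam < 1.0:
            raise ValueError("background rate must be in (0,1)")
    grouped = st.groupby(["trna_id", "position"])["state"]
    n_reads = grouped.size()
    n_unconv = grouped.agg(lambda s: int((s == "C").sum()))
    rows = []
    for (trna, pos), n in n_reads.items():
        if n < min_coverage:
            continue
        k = int(n_unconv[(trna, pos)])
        frac = k / n
        p = float(stats.poisson.sf(k - 1, n * lam))  # P(X >= k)
        if p < alpha and frac >= fraction_floor:
            status = "methylated"
        elif p >= alpha:
            status = "unmethylated"
        else:
            status = "ambiguous"
        rows.append((trna, int(pos), int(n), k, frac, p, status))
    calls = pd.DataFrame(
        rows,
        columns=[
            "trna_id", "position", "n_reads", "n_unconverted",
            "fraction", "p_value", "status",
        ],
    )
    calls.attrs["background_rate"] = lam
    calls.attrs["alpha"] = alpha
    calls.attrs["fraction_floor"] = fraction_floor
    return calls


def adjust_calls(calls: pd.DataFrame, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Benjamini-Hochberg adjustment of the per-position Poisson p-values.

    Re-derives the methylation status from the adjusted p-values using the
    same fraction floor; useful when scanning many positions for de novo
    methylation rather than quantifying a known site.
    """
    out = calls.copy()
    if len(out) == 0:
        out["p_adj"] = []
        return out
    out["p_adj"] = multipletests(out["p_value"], method="fdr_bh")[1]
    floor = calls.attrs.get("fraction_floor", DEFAULT_FRACTION_FLOOR)
    out["status_adj"] = np.where(
        (out["p_adj"] < alpha) & (out["fraction"] >= floor),
        "methylated",
        np.where(out["p_adj"] >= alpha, "unmethylated", "ambiguous"),
    )
    out.attrs.update(calls.attrs)
    return out


@dataclass
class PositionQuantification:
    trna_id: str
    position: int
    percent: float
    coverage: int
    status: str


def quantify_position(
    calls: pd.DataFrame,
    trna_id: str,
    position: int,
    numbering_map: dict[int, int] | None = None,
) -> PositionQuantification:
    """Methylation percent at one tRNA position (e.g. m5C38).

    ``numbering_map`` translates conventional tRNA numbering to 0-based
    reference offsets when the reference includes variable loops or CCA
    tails; by default the position is taken as the reference offset.
    """
    ref_pos = numbering_map.get(position, position) if numbering_map else position
    sel = calls[(calls["trna_id"] == trna_id) & (calls["position"] == ref_pos)]
    if len(sel) == 0:
        raise KeyError(
            f"no methylation call at {trna_id} position {position} (offset {ref_pos}): "
            "position uncovered or below minimum coverage"
        )
    row = sel.iloc[0]
    return PositionQuantification(
        trna_id, position, 100.0 * float(row["fraction"]), int(row["n_reads"]), str(row["status"])
    )
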