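"""Raw FASTQ to per-read A-site codon assignments.

The stage order mirrors the analysis: adapter/quality trimming with size
selection, contaminant removal against rRNA/tRNA decoys, ungapped unique-best
alignment to the coding transcriptome, per-length 3-nt periodicity QC around
start codons, and finally A-site assignment at read start +15 nt with the
+1 nt frame correction.

Every stage returns its survivors together with a count ledger so that
``input = output + sum(removal causes)`` holds throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ReadSet, TranscriptomeFixture, revcomp, warn

ALIGNMENT_COLUMNS = ["read_id", "gene_id", "start", "length", "mismatches"]
ASITE_COLUMNS = ["read_id", "gene_id", "a_site_codon_index", "codon"]

DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCT"
MIN_ADAPTER_OVERLAP = 6
A_SITE_OFFSET = 15
_SEED_K = 8


# ---------------------------------------------------------------------------
# trimming and size selection
# ---------------------------------------------------------------------------


def _find_adapter(seq: str, adapter: str, seed: str) -> int:
    """Earliest 3'-anchored exact match of the adapter prefix; -1 if none."""
    alen = len(adapter)
    pos = seq.find(seed)
    while pos != -1:
        k = min(alen, len(seq) - pos)
        if seq[pos : pos + k] == adapter[:k]:
            return pos
        pos = seq.find(seed, pos + 1)
    return -1


def trim_and_filter(
    raw: ReadSet,
    adapter: str = DEFAULT_ADAPTER,
    min_quality: int = 30,
    size_min: int = 25,
    size_max: int = 35,
) -> tuple[ReadSet, dict[str, int]]:
    """Remove adapters, trim low-quality 3' ends, and size-select.

    The adapter is matched 3'-anchored: the earliest position where the read
    suffix equals an adapter prefix of at least ``MIN_ADAPTER_OVERLAP`` nt
    (a full internal adapter occurrence also qualifies). Bases with quality
    below ``min_quality`` are then trimmed from the 3' end, and reads outside
    ``[size_min, size_max]`` are discarded.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if not 0 < size_min <= size_max:
        raise ValueError("require 0 < size_min <= size_max")
    seed = adapter[:MIN_ADAPTER_OVERLAP]
    qcut = chr(min_quality + 33)
    counts = {
        "input": len(raw),
        "adapter_trimmed": 0,
        "quality_trimmed": 0,
        "too_short": 0,
        "too_long": 0,
        "passed": 0,
    }
    out = []
    for rid, seq, qual in raw:
        cut = _find_adapter(seq, adapter, seed)
        if cut != -1:
            counts["adapter_trimmed"] += 1
            seq, qual = seq[:cut], qual[:cut]
        end = len(qual)
        while end > 0 and qual[end - 1] < qcut:
            end -= 1
        if end < len(qual):
            counts["quality_trimmed"] += 1
            seq, qual = seq[:end], qual[:end]
        if len(seq) < size_min:
            counts["too_short"] += 1
        elif len(seq) > size_max:
            counts["too_long"] += 1
        else:
            counts["passed"] += 1
            out.append((rid, seq, qual))
    return ReadSet(out), counts


# ---------------------------------------------------------------------------
# contaminant removal
# ---------------------------------------------------------------------------


def filter_contaminants(
    reads: ReadSet,
    contaminant_refs: list[tuple[str, str]],
    min_match: int = 20,
) -> tuple[ReadSet, dict[str, int]]:
    """Drop reads sharing an exact ``min_match``-mer with any contaminant.

    A dependency-free stand-in for seeded alignment against rRNA/tRNA
    references: a read is treated as contaminant-derived if any of its
    k-mers occurs on either strand of any contaminant sequence.
    """
    counts = {"input": len(reads), "removed": 0, "passed": len(reads)}
    if not contaminant_refs:
        warn("no contaminant references supplied; filter is a no-op")
        return reads, counts
    kmers: set[str] = set()
    for _, seq in contaminant_refs:
        for s in (seq, revcomp(seq)):
            for i in range(len(s) - min_match + 1):
                kmers.add(s[i : i + min_match])
    out = []
    for rec in reads:
        seq = rec[1]
        hit = any(
            seq[i : i + min_match] in kmers for i in range(len(seq) - min_match + 1)
        )
        if hit:
            counts["removed"] += 1
        else:
            out.append(rec)
    counts["passed"] = len(out)
    return ReadSet(out), counts


# ---------------------------------------------------------------------------
# transcript alignment
# ---------------------------------------------------------------------------


def _build_seed_index(tx: TranscriptomeFixture, k: int) -> dict[str, list[tuple[int, int]]]:
    index: dict[str, list[tuple[int, int]]] = {}
    for gi, t in enumerate(tx):
        seq = t.sequence
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i : i + k], []).append((gi, i))
    return index


def _mismatches(read: str, ref: str, start: int, limit: int) -> int:
    n = 0
    for a, b in zip(read, ref[start : start + len(read)]):
        if a != b:
            n += 1
            if n > limit:
                return n
    return n


def align_to_transcripts(
    reads: ReadSet,
    tx: TranscriptomeFixture,
    max_mismatches: int = 2,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Ungapped full-length alignment to the transcriptome, unique best hit.

    Candidate locations come from exact seed k-mers at three disjoint read
    offsets (pigeonhole: with at most ``max_mismatches`` <= 2 substitutions,
    one seed is error-free), then verified base-by-base. Reads whose best
    mismatch count is tied between different genes are dropped as ambiguous;
    ties within one gene resolve to the leftmost offset.
    """
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    k = _SEED_K
    index = _build_seed_index(tx, k)
    seqs = [t.sequence for t in tx]
    gene_ids = tx.gene_ids
    counts = {"input": len(reads), "aligned": 0, "unaligned": 0, "ambiguous": 0}
    rows = []
    for rid, read, _ in reads:
        L = len(read)
        if L < k:
            counts["unaligned"] += 1
            continue
        offsets = [0, k, 2 * k] if L >= 3 * k else [0, k, L - k]
        candidates: set[tuple[int, int]] = set()
        for off in offsets:
            for gi, pos in index.get(read[off : off + k], ()):
                start = pos - off
                if 0 <= start and start + L <= len(seqs[gi]):
                    candidates.add((gi, start))
        best_mm = max_mismatches + 1
        hits: list[tuple[int, int]] = []
        for gi, start in sorted(candidates):
            mm = _mismatches(read, seqs[gi], start, best_mm)
            if mm < best_mm:
                best_mm = mm
                hits = [(gi, start)]
            elif mm == best_mm and mm <= max_mismatches:
                hits.append((gi, start))
        if best_mm > max_mismatches:
            counts["unaligned"] += 1
        elif len({gi for gi, _ in hits}) > 1:
            counts["ambiguous"] += 1
        else:
            gi, start = min(hits)
            rows.append((rid, gene_ids[gi], start, L, best_mm))
            counts["aligned"] += 1
    aln = pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)
    return aln, counts


# ---------------------------------------------------------------------------
# periodicity QC
# ---------------------------------------------------------------------------


@dataclass
class LengthQCReport:
    """Per-read-length start-codon offset histograms and accept/reject calls.

    ``summary`` has one row per length (n_window, periodicity_score,
    modal_offset, accepted); ``histograms`` is offsets x lengths.
    """

    summary: pd.DataFrame
    histograms: pd.DataFrame
    threshold: float
    peak_offset: int | None

    @property
    def accepted_lengths(self) -> list[int]:
        return [int(l) for l in self.summary.index[self.summary["accepted"]]]


def assess_periodicity(
    aln: pd.DataFrame,
    tx: TranscriptomeFixture,
    lengths: list[int] | None = None,
    min_reads: int = 100,
    threshold: float = 0.6,
    peak_offset: int | None = -12,
    window: int = 20,
) -> LengthQCReport:
    """Score 3-nt periodicity of 5' ends around start codons, per length.

    For each read length the 5'-offset histogram relative to the start codon
    is built over ``[-window, +window]`` nt; the periodicity score is the
    fraction of window reads whose offset falls in the modal reading frame.
    A length is accepted iff score >= threshold, the window holds at least
    ``min_reads`` reads, and (when ``peak_offset`` is not None) the single
    largest bin sits at that offset — by default -12 nt, the initiation peak
    expected when the A-site of an initiating ribosome is codon 1.
    """
    if lengths is None:
        lengths = sorted(set(aln["length"])) if len(aln) else []
        lengths = [l for l in lengths if 25 <= l <= 32]
    cds_start = {t.gene_id: t.cds_start for t in tx}
    offs = aln["start"].to_numpy() - aln["gene_id"].map(cds_start).to_numpy() if len(aln) else np.array([], dtype=int)
    offsets_axis = np.arange(-window, window + 1)
    hist = {}
    rows = []
    for L in lengths:
        sel = offs[(aln["length"].to_numpy() == L)] if len(aln) else offs
        sel = sel[(sel >= -window) & (sel <= window)]
        h = np.bincount(sel + window, minlength=2 * window + 1)
        hist[L] = h
        total = int(h.sum())
        if total == 0:
            rows.append((L, 0, np.nan, np.nan, False))
            continue
        frame_counts = [h[(offsets_axis % 3) == f].sum() for f in range(3)]
        score = max(frame_counts) / total
        modal = int(offsets_axis[int(np.argmax(h))])
        accepted = (
            score >= threshold
            and total >= min_reads
            and (peak_offset is None or modal == peak_offset)
        )
        rows.append((L, total, score, modal, accepted))
    summary = pd.DataFrame(
        rows, columns=["length", "n_window", "periodicity_score", "modal_offset", "accepted"]
    ).set_index("length")
    histograms = pd.DataFrame(hist, index=offsets_axis)
    histograms.index.name = "offset"
    if len(summary) and not summary["accepted"].any() and summary["n_window"].sum() == 0:
        warn("no reads near any start codon; all lengths rejected")
    return LengthQCReport(summary, histograms, threshold, peak_offset)


# ---------------------------------------------------------------------------
# A-site assignment
# ---------------------------------------------------------------------------


def assign_a_sites(
    aln: pd.DataFrame,
    tx: TranscriptomeFixture,
    accepted_lengths: list[int],
    offset: int = A_SITE_OFFSET,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Assign each QC-passing read an A-site codon at read start +15 nt.

    The A-site nucleotide is alignment start + ``offset``. When it lands one
    nucleotide before a frame boundary (phase 2 relative to the CDS) the
    +1 nt correction is applied; phase-1 reads are discarded and counted, as
    are reads whose A-site falls outside the CDS or on the stop codon.
    """
    if not accepted_lengths:
        raise ValueError(
            "accepted_lengths is empty: no read length passed periodicity QC; "
            "refusing to assign A-sites on unvetted lengths"
        )
    accepted = set(int(l) for l in accepted_lengths)
    counts = {
        "input": len(aln),
        "length_rejected": 0,
        "phase1_discarded": 0,
        "outside_cds": 0,
        "assigned": 0,
    }
    cds_start = {t.gene_id: t.cds_start for t in tx}
    n_codons = {t.gene_id: t.n_codons for t in tx}
    codon_of = {t.gene_id: t.codons for t in tx}
    rows = []
    for rid, gene, start, length in zip(
        aln["read_id"], aln["gene_id"], aln["start"], aln["length"]
    ):
        if int(length) not in accepted:
            counts["length_rejected"] += 1
            continue
        rel = int(start) + offset - cds_start[gene]
        phase = rel % 3
        if phase == 1:
            counts["phase1_discarded"] += 1
            continue
        if phase == 2:
            rel += 1
        ci = rel // 3
        if ci < 0 or ci >= n_codons[gene] - 1:  # outside CDS or stop codon
            counts["outside_cds"] += 1
            continue
        rows.append((rid, gene, ci, codon_of[gene][ci]))
        counts["assigned"] += 1
    asites = pd.DataFrame(rows, columns=ASITE_COLUMNS)
    return asites, counts
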