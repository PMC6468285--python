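"""Shared codon tables, sequence containers and FASTA/FASTQ IO.

Coordinates are 0-based and half-open everywhere. Codons are stored as DNA
trinucleotides (``GAT`` not ``GAU``); :func:`normalize_codon` accepts RNA
spelling so that user-facing tables may use either alphabet.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = "ACGT"

#: codon -> amino acid (one letter), sense codons only
GENETIC_CODE: dict[str, str] = dict(standard_dna_table.forward_table)

STOP_CODONS: tuple[str, ...] = tuple(sorted(standard_dna_table.stop_codons))

#: the 61 sense codons in lexicographic order; the canonical axis of all
#: occupancy vectors in this package
SENSE_CODONS: tuple[str, ...] = tuple(sorted(GENETIC_CODE))

#: the eight queuosine-decoded codons: Asp, His, Asn, Tyr (NAC/NAU families)
Q_CODONS: tuple[str, ...] = ("GAC", "GAT", "CAC", "CAT", "AAC", "AAT", "TAC", "TAT")

#: amino acids carried by Q-decoded tRNAs
Q_AMINO_ACIDS: tuple[str, ...] = ("D", "H", "N", "Y")

START_CODON = "ATG"


def normalize_codon(codon: str) -> str:
    """Return the DNA-uppercase form of *codon* (accepts RNA spelling)."""
    c = codon.upper().replace("U", "T")
    if len(c) != 3 or any(b not in BASES for b in c):
        raise ValueError(f"not a codon: {codon!r}")
    return c


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate_codons(codons: list[str]) -> str:
    return "".join(GENETIC_CODE.get(c, "*") for c in codons)


# ---------------------------------------------------------------------------
# transcript containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Transcript:
    """One coding transcript: a CDS with optional untranslated regions.

    ``cds`` must be a complete reading frame (ATG ... stop). ``utr5``/``utr3``
    default to empty, in which case the transcript is the bare CDS.
    """

    gene_id: str
    cds: str
    utr5: str = ""
    utr3: str = ""

    def __post_init__(self) -> None:
        if len(self.cds) % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length not divisible by 3")
        if not self.cds.startswith(START_CODON):
            raise ValueError(f"{self.gene_id}: CDS does not start with ATG")
        codons = self.codons
        if codons[-1] not in STOP_CODONS:
            raise ValueError(f"{self.gene_id}: CDS does not end with a stop codon")
        if any(c in STOP_CODONS for c in codons[:-1]):
            raise ValueError(f"{self.gene_id}: internal stop codon")

    @property
    def sequence(self) -> str:
        return self.utr5 + self.cds + self.utr3

    @property
    def cds_start(self) -> int:
        """Transcript coordinate of the first CDS nucleotide."""
        return len(self.utr5)

    @property
    def n_codons(self) -> int:
        """Total codons including start and stop."""
        return len(self.cds) // 3

    @property
    def codons(self) -> list[str]:
        return [self.cds[i : i + 3] for i in range(0, len(self.cds), 3)]

    def codon_at(self, index: int) -> str:
        if not 0 <= index < self.n_codons:
            raise IndexError(f"{self.gene_id}: codon index {index} outside CDS")
        return self.cds[3 * index : 3 * index + 3]


@dataclass
class TranscriptomeFixture:
    """A toy coding transcriptome with known per-gene mRNA abundances.

    The coordinate ground truth for both simulation and occupancy analysis.
    Abundances are relative mRNA copy numbers and must be strictly positive.
    """

    transcripts: list[Transcript]
    abundance: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [t.gene_id for t in self.transcripts]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gene ids")
        if not self.abundance:
            self.abundance = {g: 1.0 for g in ids}
        if set(self.abundance) != set(ids):
            raise ValueError("abundance keys do not match gene ids")
        if any(a <= 0 for a in self.abundance.values()):
            raise ValueError("abundances must be strictly positive")
        self._by_id = {t.gene_id: t for t in self.transcripts}

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self):
        return iter(self.transcripts)

    def get(self, gene_id: str) -> Transcript:
        return self._by_id[gene_id]

    @property
    def gene_ids(self) -> list[str]:
        return [t.gene_id for t in self.transcripts]

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(t.sequence), id=t.gene_id,
                      description=f"cds_start={t.cds_start} cds_len={len(t.cds)}")
            for t in self.transcripts
        ]
        SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# read containers and IO
# ---------------------------------------------------------------------------


@dataclass
class ReadSet:
    """Sequencing reads as (read_id, sequence, Phred+33 quality) triples."""

    records: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for rid, seq, qual in self.records:
            if len(seq) != len(qual):
                raise ValueError(f"{rid}: sequence and quality lengths differ")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_fastq(self, path) -> None:
        with open(path, "w") as fh:
            for rid, seq, qual in self.records:
                fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")

    @classmethod
    def from_fastq(cls, path) -> "ReadSet":
        records = []
        for rec in SeqIO.parse(str(path), "fastq"):
            quals = rec.letter_annotations["phred_quality"]
            qual = "".join(chr(q + 33) for q in quals)
            records.append((rec.id, str(rec.seq).upper(), qual))
        return cls(records)


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path, records: list[tuple[str, str]]) -> None:
    SeqIO.write(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in records],
        str(path),
        "fasta",
    )


def warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=3)
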