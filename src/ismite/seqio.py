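"""Sequence I/O, coordinate conventions, translation and genome segmentation.

Coordinates are 0-based half-open everywhere inside the package; they are
converted to 1-based inclusive only when writing GFF3.

The genetic code defaults to translation table 11 (bacteria/archaea).
Genome segmentation uses 5 kb windows with a 300 nt overlap by default so
that a transposase ORF straddling a window boundary is still seen intact in
one of the two windows; duplicated hits are deduplicated downstream by
genome coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from Bio import AlignIO, SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

NT_ALPHABET = set("ACGTN")
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class AlphabetError(ValueError):
    """Sequence contains characters outside the declared alphabet."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide or peptide sequence; the package's I/O currency."""

    id: str
    seq: str
    alphabet: str = "nt"  # "nt" or "aa"

    def __post_init__(self):
        if not self.id:
            raise ValueError("empty sequence id")
        if not self.seq:
            raise ValueError(f"empty sequence for {self.id!r}")
        if any(c.isspace() for c in self.seq):
            raise ValueError(f"whitespace in sequence {self.id!r}")
        allowed = NT_ALPHABET if self.alphabet == "nt" else AA_ALPHABET
        bad = set(self.seq.upper()) - allowed
        if bad:
            raise AlphabetError(
                f"sequence {self.id!r}: characters {sorted(bad)} not in {self.alphabet} alphabet"
            )
        object.__setattr__(self, "seq", self.seq.upper())

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GenomeSegment:
    """A fixed-size window of a parent nucleotide sequence."""

    parent_id: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    seq: str

    @property
    def id(self) -> str:
        return f"{self.parent_id}|{self.start}-{self.end}"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError("invalid segment interval")
        if len(self.seq) != self.end - self.start:
            raise ValueError("segment sequence length does not match interval")


@dataclass(frozen=True)
class FrameTranslation:
    """One of six reading-frame translations of a segment.

    ``frame`` is +1/+2/+3 for the forward strand (codon 1 starting at offset
    0/1/2 of the segment) and -1/-2/-3 for the reverse complement, offsets
    taken on the reverse-complemented sequence.
    """

    segment_ref: str
    frame: int
    peptide: str
    nt_offset: int


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement; N maps to N."""
    s = seq.upper()
    bad = set(s) - NT_ALPHABET
    if bad:
        raise AlphabetError(f"non-nucleotide characters {sorted(bad)}")
    return s.translate(_COMPLEMENT)[::-1]


def _codon_map(table: int) -> dict:
    tbl = CodonTable.unambiguous_dna_by_id[table]
    m = dict(tbl.forward_table)
    for stop in tbl.stop_codons:
        m[stop] = "*"
    return m


def translate(seq: str, table: int = 11) -> str:
    """Translate a nucleotide string codon by codon; trailing bases dropped.

    Stop codons render as '*'; any codon containing N renders as 'X'.
    """
    codons = _codon_map(table)
    s = seq.upper()
    return "".join(
        codons.get(s[i : i + 3], "X") for i in range(0, len(s) - len(s) % 3, 3)
    )


def six_frame_translate(seq: str, table: int = 11, segment_ref: str = "") -> list[FrameTranslation]:
    """Translate a nucleotide sequence in all six reading frames.

    Frames +1..+3 read the forward strand from offsets 0, 1, 2; frames
    -1..-3 read the reverse complement from offsets 0, 1, 2.
    """
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    out: list[FrameTranslation] = []
    rc = reverse_complement(seq)
    for strand, s in ((1, seq.upper()), (-1, rc)):
        for off in range(3):
            pep = translate(s[off:], table)
            out.append(
                FrameTranslation(
                    segment_ref=segment_ref,
                    frame=strand * (off + 1),
                    peptide=pep,
                    nt_offset=off,
                )
            )
    if all(not f.peptide for f in out):
        raise ValueError("all six frames empty")
    return out


def segment_genome(rec: SequenceRecord, window: int = 5000, overlap: int = 300) -> list[GenomeSegment]:
    """Cut a genome into fixed windows with the given overlap.

    Segments start at multiples of ``window - overlap``; the last segment is
    truncated at the sequence end. The union of segments covers the genome.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if not (0 <= overlap < window):
        raise ValueError("require window > overlap >= 0")
    n = len(rec.seq)
    step = window - overlap
    segs: list[GenomeSegment] = []
    start = 0
    while True:
        end = min(start + window, n)
        segs.append(GenomeSegment(rec.id, start, end, rec.seq[start:end]))
        if end >= n:
            break
        start += step
    return segs


# ---------------------------------------------------------------------------
# FASTA / alignment I/O


def _infer_alphabet(seq: str) -> str:
    return "nt" if set(seq.upper()) <= NT_ALPHABET else "aa"


def read_fasta(path, alphabet: str | None = None) -> list[SequenceRecord]:
    """Read a (multi-record, wrapped or unwrapped) FASTA file.

    When ``alphabet`` is None it is inferred per record; a file mixing clear
    peptide records with nucleotide records raises a format error.
    """
    recs = []
    for r in SeqIO.parse(str(path), "fasta"):
        s = str(r.seq).upper()
        ab = alphabet or _infer_alphabet(s)
        recs.append(SequenceRecord(r.id, s, ab))
    if not recs:
        raise ValueError(f"no FASTA records in {path}")
    if alphabet is None and len({r.alphabet for r in recs}) > 1:
        raise ValueError(f"mixed nucleotide/peptide records in {path}")
    return recs


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 70) -> None:
    SeqIO.write(
        (_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records),
        str(path),
        "fasta",
    )


def read_msa(path, fmt: str | None = None) -> "list[MSARow]":
    """Read a multiple alignment (Stockholm or aligned FASTA).

    Gap characters '-' and '.' are normalised to '-'; rows keep their
    aligned length. Format is guessed from the first line when not given.
    """
    path = str(path)
    if fmt is None:
        with open(path) as fh:
            first = fh.readline()
        fmt = "stockholm" if first.startswith("# STOCKHOLM") else "fasta"
    aln = AlignIO.read(path, fmt)
    out = []
    lengths = set()
    for r in aln:
        s = str(r.seq).upper().replace(".", "-")
        lengths.add(len(s))
        out.append((r.id, s))
    if len(lengths) > 1:
        raise ValueError("ragged alignment")
    # aligned rows may contain '-' which SequenceRecord rejects; keep as tuples
    return [MSARow(i, s) for i, s in out]


@dataclass(frozen=True)
class MSARow:
    """One aligned peptide row; '-' marks gaps."""

    id: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)
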