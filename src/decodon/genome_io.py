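"""Nucleotide input, chunking, and coordinate-mapped six-frame translation.

Coordinates are 0-based and half-open, and are always expressed on the
forward strand of the sequence they refer to; a codon is identified by
(record id, start, strand). The preliminary translation uses the standard
genetic code with stop codons emitted as 'X', which the downstream homology
search treats as an unknown residue. Codons containing any non-ACGT base
(IUPAC ambiguity codes are legal input) also emit 'X' and are never counted
as codon instances downstream.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .codons import STANDARD_TABLE, revcomp

IUPAC_NT = set("ACGTNRYSWKMBDHV")

DEFAULT_CHUNK_LEN = 100_000
DEFAULT_MIN_ORF_LEN = 50


@dataclass
class NucleotideSequence:
    """A nucleotide record or a chunk of one.

    ``source_offset`` is the 0-based position of this chunk in its parent
    record (0 for an unchunked record).
    """

    id: str
    seq: str
    source_offset: int = 0

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.source_offset < 0:
            raise ValueError("source_offset must be >= 0")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class FramedTranslation:
    """One reading frame of a chunk, with a map back to genomic codons.

    Frames 0-2 read the forward strand at offsets 0, 1, 2; frames 3-5 read
    the reverse complement at offsets 0, 1, 2. ``codon_starts[p]`` is the
    forward-strand coordinate (within the parent chunk) of the 5'-most
    forward-strand base of the codon encoding ``peptide[p]``.
    """

    parent_id: str
    frame: int
    peptide: str
    codon_starts: list[int] = field(repr=False)
    strand: str = "+"

    def __post_init__(self) -> None:
        if len(self.codon_starts) != len(self.peptide):
            raise ValueError("codon_starts must parallel the peptide")


def _open_maybe_gzip(path: str | Path) -> io.TextIOBase:
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


def read_fasta(path: str | Path) -> list[NucleotideSequence]:
    """Read a FASTA (or gzipped FASTA) file of nucleotide sequences.

    Sequences are upper-cased and U is mapped to T, so RNA input is
    accepted. Raises ``ValueError`` on an empty file or on any character
    outside the IUPAC nucleotide alphabet, naming the record and position.
    """
    records: list[NucleotideSequence] = []
    with _open_maybe_gzip(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            seq = str(rec.seq).upper().replace("U", "T")
            bad = next((i for i, ch in enumerate(seq) if ch not in IUPAC_NT), None)
            if bad is not None:
                raise ValueError(
                    f"record {rec.id!r}: non-IUPAC nucleotide {seq[bad]!r} "
                    f"at position {bad}"
                )
            records.append(NucleotideSequence(id=rec.id, seq=seq))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def chunk_sequence(
    rec: NucleotideSequence, chunk_len: int = DEFAULT_CHUNK_LEN
) -> list[NucleotideSequence]:
    """Split a record into nonoverlapping chunks of ``chunk_len`` nt.

    The concatenation of the chunk sequences equals the input; every chunk
    except possibly the last has length ``chunk_len``. Codons that straddle
    a chunk boundary are lost to translation (an accepted edge loss of at
    most two codons per boundary per frame).
    """
    if chunk_len < 3:
        raise ValueError("chunk_len must be >= 3")
    if len(rec) <= chunk_len:
        return [rec]
    return [
        NucleotideSequence(
            id=rec.id,
            seq=rec.seq[off : off + chunk_len],
            source_offset=rec.source_offset + off,
        )
        for off in range(0, len(rec), chunk_len)
    ]


def _translate_frame(seq: str, offset: int) -> tuple[str, list[int]]:
    pep = []
    starts = []
    for s in range(offset, len(seq) - 2, 3):
        codon = seq[s : s + 3]
        aa = STANDARD_TABLE.get(codon, "X")
        pep.append("X" if aa == "*" else aa)
        starts.append(s)
    return "".join(pep), starts


def six_frame_translate(rec: NucleotideSequence) -> list[FramedTranslation]:
    """Translate a chunk in all six frames under the standard code.

    Stop codons and codons containing a non-ACGT base are emitted as 'X'.
    Reverse-frame codon starts are mapped back to forward-strand
    coordinates of the codon's 5'-most forward-strand base.
    """
    out: list[FramedTranslation] = []
    L = len(rec)
    for f in range(3):
        pep, starts = _translate_frame(rec.seq, f)
        out.append(FramedTranslation(rec.id, f, pep, starts, "+"))
    rc = revcomp(rec.seq)
    for f in range(3, 6):
        o = f - 3
        pep, rc_starts = _translate_frame(rc, o)
        starts = [L - s - 3 for s in rc_starts]
        out.append(FramedTranslation(rec.id, f, pep, starts, "-"))
    return out


def codon_at(rec: NucleotideSequence, start: int, strand: str) -> str:
    """The codon read at a (start, strand) coordinate of a chunk.

    ``start`` is the forward-strand coordinate of the codon's 5'-most
    forward-strand base; for '-' codons the forward triplet is
    reverse-complemented.
    """
    triplet = rec.seq[start : start + 3]
    if len(triplet) != 3:
        raise IndexError(f"codon at {start} extends past the sequence end")
    return triplet if strand == "+" else revcomp(triplet)


def orf_translate(
    rec: NucleotideSequence,
    code,
    min_len: int = DEFAULT_MIN_ORF_LEN,
) -> list[str]:
    """Translate all six-frame ORFs longer than ``min_len`` codons.

    Stops are the standard stop codons that ``code`` has not reassigned to
    an amino acid; codons whose table entry is '?' (candidate reassigned
    codons) are emitted as 'X', as are ambiguous codons.
    """
    stops = set(code.stop_codons())
    peptides: list[str] = []
    for seq in (rec.seq, revcomp(rec.seq)):
        for off in range(3):
            run: list[str] = []
            for s in range(off, len(seq) - 2, 3):
                codon = seq[s : s + 3]
                if codon in stops:
                    if len(run) > min_len:
                        peptides.append("".join(run))
                    run = []
                    continue
                aa = code.table.get(codon, "X")
                run.append("X" if aa == "?" else aa)
            if len(run) > min_len:
                peptides.append("".join(run))
    return peptides


class SixFrameIndex:
    """Index from six-frame query ids back to genomic codons.

    Query headers follow the grammar ``<parent>|chunk<k>|frame<f>``.
    """

    def __init__(self) -> None:
        self._entries: dict[str, tuple[NucleotideSequence, FramedTranslation]] = {}

    @staticmethod
    def query_id(parent_id: str, chunk_index: int, frame: int) -> str:
        return f"{parent_id}|chunk{chunk_index}|frame{frame}"

    def add(
        self,
        chunk: NucleotideSequence,
        chunk_index: int,
        translation: FramedTranslation,
    ) -> str:
        qid = self.query_id(translation.parent_id, chunk_index, translation.frame)
        self._entries[qid] = (chunk, translation)
        return qid

    def __contains__(self, qid: str) -> bool:
        return qid in self._entries

    def codon_at(self, qid: str, pep_pos: int) -> tuple[str, str, int, str]:
        """Resolve a 0-based peptide position to its genomic codon.

        Returns (codon string as read 5'→3', parent record id, absolute
        forward-strand start, strand).
        """
        try:
            chunk, tr = self._entries[qid]
        except KeyError:
            raise KeyError(f"unknown query id: {qid!r}") from None
        start = tr.codon_starts[pep_pos]
        codon = codon_at(chunk, start, tr.strand)
        return codon, chunk.id, chunk.source_offset + start, tr.strand


def translate_genome(
    records: list[NucleotideSequence], chunk_len: int = DEFAULT_CHUNK_LEN
) -> tuple[list[tuple[str, str]], SixFrameIndex]:
    """Chunk and six-frame translate a genome.

    Returns the peptide FASTA entries as (query id, peptide) pairs plus the
    coordinate index used to map alignments back to genomic codons.
    """
    index = SixFrameIndex()
    peptides: list[tuple[str, str]] = []
    for rec in records:
        for k, chunk in enumerate(chunk_sequence(rec, chunk_len)):
            for tr in six_frame_translate(chunk):
                qid = index.add(chunk, k, tr)
                if tr.peptide:
                    peptides.append((qid, tr.peptide))
    return peptides, index


def write_peptides(peptides: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for qid, pep in peptides:
            fh.write(f">{qid}\n{pep}\n")


def write_coordinate_map(
    index: SixFrameIndex, path: str | Path
) -> None:
    """Sidecar TSV of every peptide position's genomic codon coordinate."""
    with open(path, "w") as fh:
        fh.write("query_id\tpep_pos\trecord_id\tstart\tstrand\n")
        for qid, (chunk, tr) in index._entries.items():
            for p, s in enumerate(tr.codon_starts):
                fh.write(
                    f"{qid}\t{p}\t{chunk.id}\t{chunk.source_offset + s}\t{tr.strand}\n"
                )
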