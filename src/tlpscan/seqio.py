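"""Sequence IO, six-frame translation, and peptide<->genome coordinate maps.

Internally every coordinate is 0-based half-open; user-facing reports (GFF3,
residue numbers) are 1-based inclusive.  Six-frame translation follows the
EMBOSS ``transeq`` convention: frames +1..+3 translate the forward strand at
offsets 0..2, frames -1..-3 translate the reverse complement at offsets
0..2, and trailing partial codons are dropped.  Full-frame translations are
split at stop codons into :class:`PeptideSegment` objects because stops have
no amino-acid emission; a domain pair separated by an in-frame stop can
therefore never share a segment, which mirrors the screen's requirement that
co-located domains sit on one uninterrupted reading frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")
FRAMES = (1, 2, 3, -1, -2, -3)

#: genetic-code ids accepted by :func:`six_frame_translate`
GENETIC_CODES = {"Standard": 1, "Bacterial": 11, 1: 1, 11: 11, "1": 1, "11": 11}


class SeqIOError(ValueError):
    """Raised on malformed FASTA input or invalid coordinates."""


@dataclass
class GenomeRecord:
    """A single FASTA record (nucleotide contig or protein sequence)."""

    id: str
    sequence: str
    species: str | None = None
    taxon_group: str | None = None

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PeptideSegment:
    """A stop-free run of a full-frame translation.

    ``pep_offset`` is the 0-based index of the segment's first residue within
    the full-frame translation (counting the residues that stop symbols would
    occupy), which is what anchors the genomic coordinate map.
    """

    peptide: str
    pep_offset: int

    def __len__(self) -> int:
        return len(self.peptide)


@dataclass
class TranslatedFrame:
    """One of the six conceptual translations of a genome record."""

    genome_id: str
    frame: int  # +1,+2,+3,-1,-2,-3
    genome_length: int
    segments: list[PeptideSegment] = field(default_factory=list)


def _normalize_nucleotide(seq: str, record_id: str) -> str:
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - NUCLEOTIDE_ALPHABET
    if bad:
        raise SeqIOError(
            f"record {record_id!r}: illegal nucleotide character(s) {sorted(bad)}"
        )
    return seq


def _normalize_protein(seq: str, record_id: str) -> str:
    seq = seq.upper()
    bad = set(seq) - PROTEIN_ALPHABET
    if bad:
        raise SeqIOError(
            f"record {record_id!r}: illegal amino-acid character(s) {sorted(bad)}"
        )
    return seq


def read_fasta(path: str | Path, kind: str = "nucleotide") -> list[GenomeRecord]:
    """Read a FASTA file into :class:`GenomeRecord` objects.

    ``kind`` selects alphabet validation: ``"nucleotide"`` (A/C/G/T/N after
    uppercasing and U->T) or ``"protein"``.  Duplicate ids, empty sequences
    and illegal characters raise :class:`SeqIOError` naming the record.
    """
    if kind not in ("nucleotide", "protein"):
        raise ValueError(f"unknown kind {kind!r}")
    normalize = _normalize_nucleotide if kind == "nucleotide" else _normalize_protein
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SeqIOError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if not seq:
            raise SeqIOError(f"record {rec.id!r}: empty sequence")
        records.append(GenomeRecord(id=rec.id, sequence=normalize(seq, rec.id)))
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path, width: int = 60) -> None:
    """Write records as wrapped FASTA (round-trips with :func:`read_fasta`)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a genome metadata table (TSV: genome_id, species, taxon_group)."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"genome_id", "species", "taxon_group"}
    missing = required - set(meta.columns)
    if missing:
        raise SeqIOError(f"metadata missing column(s): {sorted(missing)}")
    return meta


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _codon_table(table: str | int) -> int:
    try:
        table_id = GENETIC_CODES[table]
    except KeyError:
        raise SeqIOError(f"unsupported genetic code table {table!r}") from None
    # validates the id is known to Biopython as well
    CodonTable.unambiguous_dna_by_id[table_id]
    return table_id


def translate_frame(sequence: str, frame: int, table: str | int = "Standard") -> str:
    """Full-frame translation (stops as ``*``) of one of the six frames."""
    if frame not in FRAMES:
        raise SeqIOError(f"frame must be one of {FRAMES}, got {frame}")
    table_id = _codon_table(table)
    strand_seq = sequence if frame > 0 else reverse_complement(sequence)
    offset = abs(frame) - 1
    sub = strand_seq[offset:]
    sub = sub[: len(sub) - len(sub) % 3]  # drop trailing partial codon
    return str(Seq(sub).translate(table=table_id))


def split_at_stops(full_translation: str, min_segment_len: int) -> list[PeptideSegment]:
    """Split a full-frame translation at ``*`` into segments >= min length."""
    segments = []
    start = 0
    n = len(full_translation)
    for i in range(n + 1):
        if i == n or full_translation[i] == "*":
            if i - start >= min_segment_len:
                segments.append(PeptideSegment(full_translation[start:i], start))
            start = i + 1
    return segments


def six_frame_translate(
    genome: GenomeRecord,
    table: str | int = "Standard",
    min_segment_len: int = 30,
) -> list[TranslatedFrame]:
    """Translate a genome record in all six frames with stop-splitting.

    Codons containing ``N`` translate to ``X`` (scored as background by the
    profile HMMs downstream).
    """
    frames = []
    for frame in FRAMES:
        full = translate_frame(genome.sequence, frame, table)
        frames.append(
            TranslatedFrame(
                genome_id=genome.id,
                frame=frame,
                genome_length=len(genome.sequence),
                segments=split_at_stops(full, min_segment_len),
            )
        )
    return frames


def map_to_genome(
    frame: TranslatedFrame,
    segment: PeptideSegment,
    pep_start: int,
    pep_end: int,
) -> tuple[int, int, str]:
    """Map a peptide slice of a segment to forward-strand genome coordinates.

    Returns ``(genomic_start, genomic_end, strand)`` with a 0-based half-open
    interval of length ``3 * (pep_end - pep_start)`` reported on the forward
    strand.  Round-trips with :func:`six_frame_translate`: re-translating the
    interval on the stated strand/frame reproduces the peptide slice.
    """
    if not (0 <= pep_start < pep_end <= len(segment)):
        raise SeqIOError(
            f"peptide slice [{pep_start},{pep_end}) out of range for segment of "
            f"length {len(segment)}"
        )
    offset = abs(frame.frame) - 1
    fs = segment.pep_offset + pep_start
    fe = segment.pep_offset + pep_end
    if frame.frame > 0:
        return offset + 3 * fs, offset + 3 * fe, "+"
    n = frame.genome_length
    return n - (offset + 3 * fe), n - (offset + 3 * fs), "-"


def extract_peptide(
    sequence: str,
    genomic_start: int,
    genomic_end: int,
    strand: str,
    table: str | int = "Standard",
) -> str:
    """Translate a mapped genomic interval back to its peptide (oracle helper)."""
    sub = sequence[genomic_start:genomic_end]
    if strand == "-":
        sub = reverse_complement(sub)
    return str(Seq(sub).translate(table=_codon_table(table)))
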