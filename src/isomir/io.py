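"""Input/output for small-RNA modification analysis.

Handles the external formats the pipeline touches: mature-miRNA FASTA
catalogs (miRBase-style headers), raw small-RNA reads in FASTA / FASTQ /
two-column ``sequence<TAB>count`` form, the collapsed-FASTA representation
the classifier consumes, and genome alignment files (Bowtie legacy map
format or SAM) from which the set of perfectly genome-matching read
sequences is extracted.

All sequences are normalized to uppercase DNA (``U`` -> ``T``) on input so
RNA- and DNA-alphabet files interoperate.  Read counts are never rescaled:
collapsing merges identical sequences and sums their abundances, nothing
more.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pysam
from Bio import SeqIO

__all__ = [
    "ParseError",
    "MatureMiRNA",
    "MiRNACatalog",
    "CollapsedRead",
    "CollapsedReadSet",
    "AlignedSet",
    "normalize_seq",
    "collapse_reads",
    "write_collapsed_fasta",
    "read_collapsed_fasta",
    "parse_alignments",
    "read_mirna_fasta",
    "read_target_fasta",
]


class ParseError(ValueError):
    """Raised when an input file violates its declared format."""


_VALID_INPUT = set("ACGTU")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def normalize_seq(seq: str) -> str:
    """Uppercase and convert RNA ``U`` to DNA ``T``.

    Idempotent; raises :class:`ParseError` on characters outside
    ``{A, C, G, T, U}`` (case-insensitive).
    """
    s = seq.strip().upper().replace("U", "T")
    if not s:
        raise ParseError("empty sequence")
    bad = set(s) - set("ACGT")
    if bad:
        raise ParseError(f"invalid nucleotide(s) {sorted(bad)} in sequence {seq!r}")
    return s


def _is_clean(seq: str) -> bool:
    return bool(seq) and not (set(seq.upper()) - _VALID_INPUT)


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MatureMiRNA:
    """A named reference mature miRNA sequence (5'->3', DNA alphabet)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", normalize_seq(self.seq))


class MiRNACatalog:
    """Catalog of mature miRNAs with unique ids and fast lookups.

    ``by_seq`` maps a mature sequence to the sorted tuple of ids carrying
    it — distinct miRBase entries may share one mature sequence.
    """

    def __init__(self, mirnas: Iterable[MatureMiRNA]):
        self.mirnas: list[MatureMiRNA] = list(mirnas)
        self.by_id: dict[str, MatureMiRNA] = {}
        by_seq: dict[str, list[str]] = {}
        for m in self.mirnas:
            if m.id in self.by_id:
                raise ParseError(f"duplicate miRNA id {m.id!r}")
            self.by_id[m.id] = m
            by_seq.setdefault(m.seq, []).append(m.id)
        self.by_seq: dict[str, tuple[str, ...]] = {
            s: tuple(sorted(ids)) for s, ids in by_seq.items()
        }

    def __len__(self) -> int:
        return len(self.mirnas)

    def __iter__(self) -> Iterator[MatureMiRNA]:
        return iter(self.mirnas)

    def __contains__(self, mirna_id: str) -> bool:
        return mirna_id in self.by_id


@dataclass(frozen=True)
class CollapsedRead:
    """A unique read sequence with its summed abundance."""

    uid: str
    seq: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"count must be >= 1, got {self.count}")


class CollapsedReadSet:
    """Deduplicated read sequences with counts, in first-seen order.

    ``n_rejected`` counts raw records dropped for containing characters
    outside the ``{A,C,G,T,U}`` alphabet (e.g. ``N`` calls); the
    conservation identity is ``sum(counts) + n_rejected == raw records``
    (or the sum of tab-file counts).
    """

    def __init__(self, n_rejected: int = 0):
        self._by_seq: dict[str, int] = {}
        self.n_rejected = n_rejected

    def add(self, seq: str, count: int = 1) -> None:
        if count < 1:
            raise ParseError(f"count must be >= 1, got {count}")
        self._by_seq[seq] = self._by_seq.get(seq, 0) + count

    @property
    def reads(self) -> list[CollapsedRead]:
        return [
            CollapsedRead(uid=f"read_{i}", seq=s, count=c)
            for i, (s, c) in enumerate(self._by_seq.items(), start=1)
        ]

    def count_of(self, seq: str) -> int:
        return self._by_seq.get(seq, 0)

    def total_count(self) -> int:
        return sum(self._by_seq.values())

    def __len__(self) -> int:
        return len(self._by_seq)

    def __contains__(self, seq: str) -> bool:
        return seq in self._by_seq

    def __iter__(self) -> Iterator[CollapsedRead]:
        return iter(self.reads)


def collapse_reads(source, fmt: str = "fasta") -> CollapsedReadSet:
    """Collapse raw reads into unique sequences with summed counts.

    Parameters
    ----------
    source
        A path or open text handle.
    fmt
        ``"fasta"``, ``"fastq"`` or ``"tab"`` (lines of
        ``sequence<TAB>count``).

    No count normalization is performed: identical sequences are merged
    and their abundances summed, after character normalization (uppercase,
    U->T).  Records with characters outside ``{A,C,G,T,U}`` are dropped
    and tallied in ``n_rejected``.
    """
    if fmt not in ("fasta", "fastq", "tab"):
        raise ValueError(f"unknown read format {fmt!r}")
    out = CollapsedReadSet()
    if fmt == "tab":
        handle = open(source) if isinstance(source, (str, os.PathLike)) else source
        try:
            for lineno, line in enumerate(handle, start=1):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 2:
                    raise ParseError(
                        f"line {lineno}: expected 'sequence<TAB>count', got {line!r}"
                    )
                seq_raw, count_raw = parts
                try:
                    count = int(count_raw)
                except ValueError:
                    raise ParseError(
                        f"line {lineno}: non-integer count {count_raw!r}"
                    ) from None
                if count < 1:
                    raise ParseError(f"line {lineno}: count must be >= 1, got {count}")
                if not _is_clean(seq_raw):
                    out.n_rejected += count
                    continue
                out.add(normalize_seq(seq_raw), count)
        finally:
            if isinstance(source, (str, os.PathLike)):
                handle.close()
    else:
        try:
            for rec in SeqIO.parse(source, fmt):
                seq_raw = str(rec.seq)
                if not _is_clean(seq_raw):
                    out.n_rejected += 1
                    continue
                out.add(normalize_seq(seq_raw), 1)
        except ValueError as exc:
            raise ParseError(f"malformed {fmt} input: {exc}") from exc
    if len(out) == 0 and out.n_rejected == 0:
        raise ParseError("empty input: no reads parsed")
    return out


_COLLAPSED_HEADER = re.compile(r"^(?P<uid>.+)_x(?P<count>\d+)$")


def write_collapsed_fasta(readset: CollapsedReadSet, dest) -> None:
    """Write collapsed reads as FASTA with ``>{uid}_x{count}`` headers.

    The ``_x<count>`` suffix follows the miRDeep2 collapsed-read
    convention; :func:`read_collapsed_fasta` inverts it losslessly.
    """
    if len(readset) == 0:
        raise ValueError("refusing to write an empty collapsed read set")
    handle = open(dest, "w") if isinstance(dest, (str, os.PathLike)) else dest
    try:
        for r in readset:
            handle.write(f">{r.uid}_x{r.count}\n{r.seq}\n")
    finally:
        if isinstance(dest, (str, os.PathLike)):
            handle.close()


def read_collapsed_fasta(path) -> CollapsedReadSet:
    """Parse a collapsed FASTA written by :func:`write_collapsed_fasta`."""
    out = CollapsedReadSet()
    for rec in SeqIO.parse(path, "fasta"):
        m = _COLLAPSED_HEADER.match(rec.id)
        if m is None:
            raise ParseError(
                f"header {rec.id!r} lacks the '_x<count>' collapsed-read suffix"
            )
        out.add(normalize_seq(str(rec.seq)), int(m.group("count")))
    if len(out) == 0:
        raise ParseError("empty collapsed FASTA")
    return out


class AlignedSet:
    """Read sequences having >= 1 perfect, full-length genome alignment.

    Membership is exact on the normalized sequence string.  Immutable
    after construction.
    """

    def __init__(self, seqs: Iterable[str]):
        self._seqs = frozenset(seqs)

    def __contains__(self, seq: str) -> bool:
        return seq in self._seqs

    def __len__(self) -> int:
        return len(self._seqs)

    def __iter__(self) -> Iterator[str]:
        return iter(self._seqs)

    def __eq__(self, other) -> bool:
        return isinstance(other, AlignedSet) and self._seqs == other._seqs

    def __hash__(self) -> int:
        return hash(self._seqs)


_CIGAR_PERFECT = re.compile(r"^\d+[M=]$")


def _sniff_dialect(path) -> str:
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            if line.startswith("@"):
                return "sam"
            fields = line.rstrip("\n").split("\t")
            if len(fields) >= 11 and fields[1].isdigit():
                return "sam"
            return "bowtie-legacy"
    raise ParseError(f"{path}: empty alignment file")


def parse_alignments(path, dialect: str | None = None) -> AlignedSet:
    """Extract perfectly aligned read sequences from an alignment file.

    A read enters the set iff it has at least one reported alignment with
    zero mismatches over its full length:

    * Bowtie legacy map format: the mismatch-descriptor field (8th) is
      empty or absent;
    * SAM: not FLAG 0x4 (unmapped), CIGAR entirely match ops (``M``/``=``),
      and ``NM:i:0`` when the tag is present.

    Hits on either strand count; minus-strand records are
    reverse-complemented back to the read's original orientation before
    the sequence is stored.
    """
    if dialect is None:
        dialect = _sniff_dialect(path)
    if dialect == "sam":
        return _parse_sam(path)
    if dialect == "bowtie-legacy":
        return _parse_bowtie_legacy(path)
    raise ValueError(f"unknown alignment dialect {dialect!r}")


def _parse_bowtie_legacy(path) -> AlignedSet:
    seqs: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            # name, strand, ref, 0-based offset, seq, quals, #other hits,
            # mismatch descriptor (empty/absent for a perfect hit)
            if len(fields) < 7:
                raise ParseError(
                    f"{path}: line {lineno}: expected >= 7 tab fields, got "
                    f"{len(fields)}"
                )
            strand = fields[1]
            if strand not in "+-":
                raise ParseError(
                    f"{path}: line {lineno}: bad strand field {strand!r}"
                )
            mismatch_desc = fields[7] if len(fields) > 7 else ""
            if mismatch_desc.strip():
                continue
            seq = normalize_seq(fields[4])
            if strand == "-":
                seq = revcomp(seq)  # bowtie prints minus hits revcomp'd
            seqs.add(seq)
    return AlignedSet(seqs)


def _parse_sam(path) -> AlignedSet:
    seqs: set[str] = set()
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            if aln.query_sequence is None:
                raise ParseError(
                    f"{path}: SAM record {aln.query_name!r} has no sequence "
                    "(field '*'); re-run the aligner emitting sequences or "
                    "supply the reads"
                )
            cigar = aln.cigarstring or ""
            if not all(
                op in (0, 7) for op, _ in (aln.cigartuples or [])
            ) or not cigar:
                continue
            nm = aln.get_tag("NM") if aln.has_tag("NM") else 0
            if nm != 0:
                continue
            seq = normalize_seq(aln.query_sequence)
            if aln.is_reverse:
                seq = revcomp(seq)
            seqs.add(seq)
    return AlignedSet(seqs)


def read_mirna_fasta(path) -> MiRNACatalog:
    """Load a mature-miRNA FASTA catalog.

    The id is the first whitespace token of the header (miRBase headers
    carry the accession after it); sequences are normalized to uppercase
    DNA.  Duplicate ids or empty sequences raise :class:`ParseError`.
    """
    mirnas = []
    for rec in SeqIO.parse(path, "fasta"):
        if not str(rec.seq):
            raise ParseError(f"miRNA {rec.id!r} has an empty sequence")
        mirnas.append(MatureMiRNA(id=rec.id, seq=str(rec.seq)))
    if not mirnas:
        raise ParseError(f"{path}: no miRNA records parsed")
    return MiRNACatalog(mirnas)


def read_target_fasta(path) -> list[tuple[str, str]]:
    """Load target sequences (e.g. 3' UTRs) as ``(id, DNA seq)`` pairs."""
    targets = []
    for rec in SeqIO.parse(path, "fasta"):
        targets.append((rec.id, normalize_seq(str(rec.seq))))
    if not targets:
        raise ParseError(f"{path}: no target records parsed")
    return targets


def write_mirna_fasta(catalog: MiRNACatalog, dest) -> None:
    """Write a catalog back out as plain FASTA."""
    handle = open(dest, "w") if isinstance(dest, (str, os.PathLike)) else dest
    try:
        for m in catalog:
            handle.write(f">{m.id}\n{m.seq}\n")
    finally:
        if isinstance(dest, (str, os.PathLike)):
            handle.close()
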