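"""Classification of collapsed reads into terminal miRNA modifications.

Each read is compared with every catalog mature miRNA and classified into
one of four single-end modification classes:

* ``ADD3`` — non-templated 3' addition: read = miRNA + tail
* ``ADD5`` — non-templated 5' addition: read = head + miRNA
* ``TRIM3`` — 3' trimming: miRNA = read + trimmed tail
* ``TRIM5`` — 5' trimming: miRNA = trimmed head + read

Two alignment criteria gate the calls.  First, catalog miRNAs are assumed
to align perfectly to the reference genome (optionally validated against a
user-supplied miRNA-vs-genome alignment).  Second, a read carrying a
mono- or poly-nucleotide terminal addition must NOT align perfectly to the
genome — an extension matching the genomic flank ("templated") aligns and
is excluded, leaving only genuinely non-templated tails.  Trimmed reads
are genomic substrings by construction, so trimming calls are emitted
regardless of genome alignment.

A read equal to a catalog mature sequence is booked as unmodified and
preempts all modification calls (prevents an annotated miRNA being
reported as an isomiR of a paralog).  Reads altered at both ends, or
internal substrings, fall outside the four classes and are tallied as
unclassified so read counts stay fully auditable.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace

from .io import AlignedSet, CollapsedRead, CollapsedReadSet, MiRNACatalog

__all__ = [
    "ModificationType",
    "ModificationCall",
    "DetectionParams",
    "ModificationCatalog",
    "classify_read",
    "resolve_primary",
    "detect_all",
    "validate_catalog_alignment",
]


class ModificationType(enum.Enum):
    """The four terminal modification classes."""

    ADD3 = "ADD3"
    ADD5 = "ADD5"
    TRIM3 = "TRIM3"
    TRIM5 = "TRIM5"

    @property
    def is_addition(self) -> bool:
        return self in (ModificationType.ADD3, ModificationType.ADD5)

    @property
    def is_trimming(self) -> bool:
        return not self.is_addition

    @property
    def end(self) -> str:
        """Which miRNA terminus is altered: ``"5p"`` or ``"3p"``."""
        return "3p" if self in (ModificationType.ADD3, ModificationType.TRIM3) else "5p"


@dataclass(frozen=True)
class ModificationCall:
    """One (read, miRNA) modification classification event.

    ``delta_seq`` holds the added or trimmed nucleotides, 5'->3' in the
    genomic orientation of the miRNA.  ``is_primary`` marks the single
    preferred call among a read's candidates (see :func:`resolve_primary`).
    """

    mirna_id: str
    mtype: ModificationType
    delta_seq: str
    read_seq: str
    read_count: int
    is_primary: bool = False

    @property
    def delta_len(self) -> int:
        return len(self.delta_seq)

    def reconstruct_read(self, mirna_seq: str) -> str:
        """Re-derive the read from the miRNA sequence and the delta."""
        t = self.mtype
        if t is ModificationType.ADD3:
            return mirna_seq + self.delta_seq
        if t is ModificationType.ADD5:
            return self.delta_seq + mirna_seq
        if t is ModificationType.TRIM3:
            assert mirna_seq.endswith(self.delta_seq)
            return mirna_seq[: len(mirna_seq) - len(self.delta_seq)]
        assert mirna_seq.startswith(self.delta_seq)
        return mirna_seq[len(self.delta_seq):]


@dataclass(frozen=True)
class DetectionParams:
    """Detector thresholds.

    min_read_count : minimum collapsed abundance for a read to be
        considered (default 10, the tool's default read-count threshold).
    max_delta : longest addition/trimming called, in nt (default 5;
        longer events are left unclassified).
    min_read_len, max_read_len : read-length window in nt (default 18-30;
        typical small-RNA evaluations use 19-25).
    """

    min_read_count: int = 10
    max_delta: int = 5
    min_read_len: int = 18
    max_read_len: int = 30

    def __post_init__(self) -> None:
        if not (1 <= self.max_delta <= 10):
            raise ValueError(f"max_delta must be in [1, 10], got {self.max_delta}")
        if self.min_read_len > self.max_read_len:
            raise ValueError("min_read_len must be <= max_read_len")
        if self.min_read_count < 1:
            raise ValueError("min_read_count must be >= 1")


@dataclass
class ModificationCatalog:
    """Aggregate result of :func:`detect_all` over one library.

    ``calls`` retains every candidate (read, miRNA) call, with exactly one
    ``is_primary`` per read sequence; ``totals`` sums read counts of
    primary calls per type.  Conservation over reads passing filters:
    ``sum(unmodified.values()) + sum(primary counts) + unclassified_reads
    == considered_reads``.
    """

    calls: list[ModificationCall] = field(default_factory=list)
    unmodified: dict[str, int] = field(default_factory=dict)
    totals: dict[ModificationType, int] = field(
        default_factory=lambda: {t: 0 for t in ModificationType}
    )
    input_total_reads: int = 0
    considered_reads: int = 0
    filtered_reads: int = 0
    unclassified_reads: int = 0

    @property
    def primary_calls(self) -> list[ModificationCall]:
        return [c for c in self.calls if c.is_primary]

    def total_modified_reads(self) -> int:
        return sum(self.totals.values())

    def conservation_holds(self) -> bool:
        return (
            sum(self.unmodified.values())
            + self.total_modified_reads()
            + self.unclassified_reads
            == self.considered_reads
        )


def classify_read(
    read: CollapsedRead,
    catalog: MiRNACatalog,
    aligned: AlignedSet,
    params: DetectionParams = DetectionParams(),
) -> list[ModificationCall]:
    """Enumerate all candidate modification calls for one collapsed read.

    Returns every (miRNA, type) call whose string relation holds with
    ``1 <= delta_len <= max_delta``.  Addition calls are emitted only when
    the read is absent from ``aligned`` (the non-templated criterion);
    trimming calls are emitted regardless.  An exact match to any catalog
    sequence returns ``[]`` (the caller books it as unmodified).  Primary
    flags are set via :func:`resolve_primary`.
    """
    if len(catalog) == 0:
        raise ValueError("miRNA catalog is empty")
    seq = read.seq
    if seq in catalog.by_seq:
        return []
    non_templated = seq not in aligned
    calls: list[ModificationCall] = []
    for m in catalog:
        n, k = len(m.seq), len(seq)
        if k > n:  # candidate addition
            if not non_templated or k - n > params.max_delta:
                continue
            if seq.startswith(m.seq):
                calls.append(
                    ModificationCall(m.id, ModificationType.ADD3, seq[n:], seq, read.count)
                )
            if seq.endswith(m.seq):
                calls.append(
                    ModificationCall(m.id, ModificationType.ADD5, seq[: k - n], seq, read.count)
                )
        elif k < n:  # candidate trimming
            if n - k > params.max_delta:
                continue
            if m.seq.startswith(seq):
                calls.append(
                    ModificationCall(m.id, ModificationType.TRIM3, m.seq[k:], seq, read.count)
                )
            if m.seq.endswith(seq):
                calls.append(
                    ModificationCall(m.id, ModificationType.TRIM5, m.seq[: n - k], seq, read.count)
                )
        # k == n with seq != m.seq: substitution territory, out of scope
    return resolve_primary(calls)


def _primary_rank(call: ModificationCall) -> tuple:
    # smallest delta first; trimming (templated explanation) over addition;
    # then deterministic id / type tie-breaks
    return (call.delta_len, 0 if call.mtype.is_trimming else 1, call.mirna_id, call.mtype.value)


def resolve_primary(calls: list[ModificationCall]) -> list[ModificationCall]:
    """Flag exactly one call per read as primary.

    Ranking: smallest ``delta_len``; tie -> trimming before addition; tie
    -> lexicographically smallest miRNA id; tie -> type name.  All calls
    are retained with their flags.
    """
    if not calls:
        return []
    if len({c.read_seq for c in calls}) != 1:
        raise ValueError("resolve_primary expects calls sharing one read_seq")
    best = min(calls, key=_primary_rank)
    return [replace(c, is_primary=(c is best)) for c in calls]


def detect_all(
    reads: CollapsedReadSet,
    catalog: MiRNACatalog,
    aligned: AlignedSet,
    params: DetectionParams = DetectionParams(),
) -> ModificationCatalog:
    """Classify every collapsed read in a library.

    Reads outside the length window or below the count threshold are
    tallied as filtered.  The result is independent of read order and
    deterministic for fixed inputs.
    """
    result = ModificationCatalog(input_total_reads=reads.total_count())
    per_read: list[tuple[CollapsedRead, list[ModificationCall]]] = []
    for read in sorted(reads, key=lambda r: r.seq):
        if (
            not (params.min_read_len <= len(read.seq) <= params.max_read_len)
            or read.count < params.min_read_count
        ):
            result.filtered_reads += read.count
            continue
        result.considered_reads += read.count
        if read.seq in catalog.by_seq:
            # booked once, to the alphabetically first id sharing the sequence
            first_id = catalog.by_seq[read.seq][0]
            result.unmodified[first_id] = result.unmodified.get(first_id, 0) + read.count
            continue
        calls = classify_read(read, catalog, aligned, params)
        if not calls:
            result.unclassified_reads += read.count
            continue
        per_read.append((read, calls))
    for read, calls in per_read:
        result.calls.extend(calls)
        primary = next(c for c in calls if c.is_primary)
        result.totals[primary.mtype] += read.count
    return result


def validate_catalog_alignment(
    catalog: MiRNACatalog, mirna_aligned: AlignedSet
) -> MiRNACatalog:
    """Enforce the first criterion: catalog miRNAs must align perfectly.

    Given an alignment of the catalog itself against the reference genome,
    drop (with a warning) entries lacking a perfect hit.  When no such
    alignment is supplied the catalog is trusted as-is.
    """
    kept = [m for m in catalog if m.seq in mirna_aligned]
    dropped = [m.id for m in catalog if m.seq not in mirna_aligned]
    if dropped:
        warnings.warn(
            f"{len(dropped)} catalog miRNA(s) lack a perfect genome alignment "
            f"and were excluded: {', '.join(dropped[:5])}"
            + ("..." if len(dropped) > 5 else ""),
            stacklevel=2,
        )
    if not kept:
        raise ValueError("no catalog miRNA aligns perfectly to the genome")
    return MiRNACatalog(kept)
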