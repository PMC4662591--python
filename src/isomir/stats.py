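"""Library-level statistics over a modification catalog.

Provides the per-miRNA modification-tendency Z-score, per-type frequency
tables of added/trimmed nucleotide patterns, library summaries, length
distributions, miRNA->miRNA conversion detection, and TSV/JSON report
writers.

The score for miRNA *i* is ``s_i = n_i * r_i`` where ``n_i`` is the number
of distinct modification events observed for it (distinct
(type, delta, read sequence) combinations) and ``r_i`` the total count of
its modified reads.  Standardizing over the scores of all modified miRNAs,
``z_i = (s_i - mean(S)) / sd(S)`` with the population standard deviation,
ranks each miRNA's relative tendency to get modified in the library.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detect import ModificationCall, ModificationCatalog, ModificationType
from .io import MiRNACatalog

__all__ = [
    "MiRNAModProfile",
    "ScoreSet",
    "FrequencyTable",
    "LibrarySummary",
    "Mirna2MirnaEvent",
    "compute_scores",
    "frequency_table",
    "summarize_library",
    "detect_conversions",
    "write_reports",
    "read_details",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MiRNAModProfile:
    mirna_id: str
    n_modifications: int
    total_modified_reads: int
    s: float
    z: float


@dataclass
class ScoreSet:
    """Per-miRNA scores with their standardization constants."""

    profiles: list[MiRNAModProfile]
    mu: float
    sigma: float

    def __iter__(self):
        return iter(self.profiles)

    def __len__(self):
        return len(self.profiles)


def compute_scores(catalog: ModificationCatalog) -> ScoreSet:
    """Score and Z-standardize every miRNA with >= 1 primary call.

    ``z = (s_i - mu(S)) / sigma(S)`` with population sigma; when sigma is
    zero (all scores equal, e.g. a single modified miRNA) every z is set
    to 0 and a warning is logged.  Profiles are returned sorted by
    descending z, ties broken by id.
    """
    events: dict[str, set[tuple]] = {}
    reads: dict[str, int] = {}
    for c in catalog.primary_calls:
        events.setdefault(c.mirna_id, set()).add((c.mtype.value, c.delta_seq, c.read_seq))
        reads[c.mirna_id] = reads.get(c.mirna_id, 0) + c.read_count
    if not events:
        return ScoreSet(profiles=[], mu=float("nan"), sigma=float("nan"))
    ids = sorted(events)
    s = np.array([len(events[i]) * reads[i] for i in ids], dtype=float)
    mu = float(s.mean())
    sigma = float(s.std(ddof=0))
    if sigma == 0.0:
        logger.warning(
            "all %d miRNA scores are equal (s = %g); Z-scores set to 0", len(ids), mu
        )
        z = np.zeros_like(s)
    else:
        z = (s - mu) / sigma
    profiles = [
        MiRNAModProfile(i, len(events[i]), reads[i], float(si), float(zi))
        for i, si, zi in zip(ids, s, z)
    ]
    profiles.sort(key=lambda p: (-p.z, p.mirna_id))
    return ScoreSet(profiles=profiles, mu=mu, sigma=sigma)


@dataclass
class FrequencyTable:
    """Percentage occurrence of each added/trimmed pattern for one type.

    Read-count weighted by default (``by_unique`` computes the unweighted
    variant over distinct calls).  Rows sum to 100 together with the
    optional "Others" bucket.
    """

    mtype: ModificationType
    rows: dict[str, float] = field(default_factory=dict)
    other_bucket: float = 0.0

    def total(self) -> float:
        return sum(self.rows.values()) + self.other_bucket

    def __bool__(self) -> bool:
        return bool(self.rows) or self.other_bucket > 0


def frequency_table(
    catalog: ModificationCatalog,
    mtype: ModificationType,
    other_threshold: float = 0.0,
    by_unique: bool = False,
) -> FrequencyTable:
    """Tabulate percent occurrence of each delta pattern of one type.

    ``percent(delta) = 100 * reads with that delta / all reads of mtype``
    over primary calls.  Patterns under ``other_threshold`` percent are
    folded into the "Others" bucket (default 0: no folding).
    """
    weights: dict[str, float] = {}
    for c in catalog.primary_calls:
        if c.mtype is not mtype:
            continue
        w = 1 if by_unique else c.read_count
        weights[c.delta_seq] = weights.get(c.delta_seq, 0) + w
    total = sum(weights.values())
    if total == 0:
        return FrequencyTable(mtype=mtype)
    percents = {d: 100.0 * w / total for d, w in weights.items()}
    rows = {d: p for d, p in percents.items() if p >= other_threshold}
    other = sum(p for d, p in percents.items() if d not in rows)
    rows = dict(sorted(rows.items(), key=lambda kv: (-kv[1], kv[0])))
    return FrequencyTable(mtype=mtype, rows=rows, other_bucket=other)


@dataclass
class LibrarySummary:
    totals: dict[ModificationType, int]
    percent_modified_reads: float
    top_mirna: tuple[str, int] | None
    n_modified_mirnas: int
    n_catalog_mirnas_detected: int
    length_histogram: dict[ModificationType, dict[int, int]]
    input_total_reads: int
    unmodified_reads: int
    unclassified_reads: int
    filtered_reads: int


def summarize_library(catalog: ModificationCatalog) -> LibrarySummary:
    """Gross per-library summary of modification abundance.

    ``percent_modified_reads`` is 100 x (primary modified read count) /
    (total input reads, pre-filter).  ``top_mirna`` is the miRNA with the
    most modified reads (alphabetical tie-break), ``length_histogram``
    maps delta length -> modified read count per type.
    """
    if catalog.input_total_reads == 0:
        raise ValueError("catalog holds no input reads")
    reads_per_mirna: dict[str, int] = {}
    hist: dict[ModificationType, dict[int, int]] = {t: {} for t in ModificationType}
    for c in catalog.primary_calls:
        reads_per_mirna[c.mirna_id] = reads_per_mirna.get(c.mirna_id, 0) + c.read_count
        h = hist[c.mtype]
        h[c.delta_len] = h.get(c.delta_len, 0) + c.read_count
    top = None
    if reads_per_mirna:
        top_id = min(reads_per_mirna, key=lambda i: (-reads_per_mirna[i], i))
        top = (top_id, reads_per_mirna[top_id])
    modified_total = catalog.total_modified_reads()
    detected = set(reads_per_mirna) | set(catalog.unmodified)
    return LibrarySummary(
        totals=dict(catalog.totals),
        percent_modified_reads=100.0 * modified_total / catalog.input_total_reads,
        top_mirna=top,
        n_modified_mirnas=len(reads_per_mirna),
        n_catalog_mirnas_detected=len(detected),
        length_histogram=hist,
        input_total_reads=catalog.input_total_reads,
        unmodified_reads=sum(catalog.unmodified.values()),
        unclassified_reads=catalog.unclassified_reads,
        filtered_reads=catalog.filtered_reads,
    )


@dataclass(frozen=True)
class Mirna2MirnaEvent:
    """A trimming that converts one annotated miRNA into another."""

    source_id: str
    product_id: str
    trimmed_end: str  # "5p" or "3p"
    trimmed_seq: str


def detect_conversions(
    mirnas: MiRNACatalog,
    calls: list[ModificationCall] | None = None,
    max_delta: int = 5,
) -> list[Mirna2MirnaEvent]:
    """Find miRNA->miRNA conversions by terminal trimming.

    In catalog-only mode (``calls=None``) every prefix/suffix containment
    among catalog sequences up to ``max_delta`` nt is enumerated: if
    trimming up to ``max_delta`` nt off one end of miRNA X yields exactly
    miRNA Y's sequence, X is convertible into Y.  Given ``calls``, only
    trimming calls whose product read equals another catalog sequence are
    reported (the conversions actually observed in the library).
    """
    events: list[Mirna2MirnaEvent] = []
    if calls is None:
        for x in mirnas:
            for y in mirnas:
                if x.id == y.id or x.seq == y.seq:
                    continue
                d = len(x.seq) - len(y.seq)
                if not (1 <= d <= max_delta):
                    continue
                if x.seq.startswith(y.seq):
                    events.append(Mirna2MirnaEvent(x.id, y.id, "3p", x.seq[len(y.seq):]))
                if x.seq.endswith(y.seq):
                    events.append(Mirna2MirnaEvent(x.id, y.id, "5p", x.seq[:d]))
    else:
        seen = set()
        for c in calls:
            if not c.mtype.is_trimming:
                continue
            for pid in mirnas.by_seq.get(c.read_seq, ()):
                if pid == c.mirna_id:
                    continue
                end = c.mtype.end
                key = (c.mirna_id, pid, end, c.delta_seq)
                if key in seen:
                    continue
                seen.add(key)
                events.append(Mirna2MirnaEvent(c.mirna_id, pid, end, c.delta_seq))
    events.sort(key=lambda e: (e.source_id, e.product_id, e.trimmed_end))
    return events


_DETAILS_COLS = ["mirna_id", "type", "delta_seq", "read_seq", "read_count", "is_primary"]


def write_reports(
    catalog: ModificationCatalog,
    summary: LibrarySummary,
    scores: ScoreSet,
    tables: dict[ModificationType, FrequencyTable],
    conversions: list[Mirna2MirnaEvent],
    dest_dir,
) -> list[str]:
    """Write all report files into ``dest_dir``.

    Emits ``summary.json``, ``details.tsv``, ``frequency_<type>.tsv``
    (rows in descending percent, percents to 2 decimals),
    ``zscores.tsv`` (z to 3 decimals) and ``conversions.tsv``.  Returns
    the list of paths written.
    """
    os.makedirs(dest_dir, exist_ok=True)
    written = []

    path = os.path.join(dest_dir, "summary.json")
    payload = {
        "input_total_reads": summary.input_total_reads,
        "percent_modified_reads": round(summary.percent_modified_reads, 2),
        "totals": {t.value: n for t, n in summary.totals.items()},
        "top_mirna": (
            {"id": summary.top_mirna[0], "modified_reads": summary.top_mirna[1]}
            if summary.top_mirna
            else None
        ),
        "n_modified_mirnas": summary.n_modified_mirnas,
        "n_catalog_mirnas_detected": summary.n_catalog_mirnas_detected,
        "unmodified_reads": summary.unmodified_reads,
        "unclassified_reads": summary.unclassified_reads,
        "filtered_reads": summary.filtered_reads,
        "length_histogram": {
            t.value: {str(k): v for k, v in sorted(h.items())}
            for t, h in summary.length_histogram.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
    written.append(path)

    path = os.path.join(dest_dir, "details.tsv")
    df = pd.DataFrame(
        [
            {
                "mirna_id": c.mirna_id,
                "type": c.mtype.value,
                "delta_seq": c.delta_seq,
                "read_seq": c.read_seq,
                "read_count": c.read_count,
                "is_primary": c.is_primary,
            }
            for c in catalog.calls
        ],
        columns=_DETAILS_COLS,
    )
    df.to_csv(path, sep="\t", index=False)
    written.append(path)

    for t in ModificationType:
        path = os.path.join(dest_dir, f"frequency_{t.value.lower()}.tsv")
        table = tables.get(t, FrequencyTable(mtype=t))
        rows = [{"delta_seq": d, "percent": f"{p:.2f}"} for d, p in table.rows.items()]
        if table.other_bucket > 0:
            rows.append({"delta_seq": "Others", "percent": f"{table.other_bucket:.2f}"})
        pd.DataFrame(rows, columns=["delta_seq", "percent"]).to_csv(
            path, sep="\t", index=False
        )
        written.append(path)

    path = os.path.join(dest_dir, "zscores.tsv")
    pd.DataFrame(
        [
            {
                "mirna_id": p.mirna_id,
                "n_modifications": p.n_modifications,
                "total_modified_reads": p.total_modified_reads,
                "score": p.s,
                "z": f"{p.z:.3f}",
            }
            for p in scores
        ],
        columns=["mirna_id", "n_modifications", "total_modified_reads", "score", "z"],
    ).to_csv(path, sep="\t", index=False)
    written.append(path)

    path = os.path.join(dest_dir, "conversions.tsv")
    pd.DataFrame(
        [
            {
                "source_id": e.source_id,
                "product_id": e.product_id,
                "trimmed_end": e.trimmed_end,
                "trimmed_seq": e.trimmed_seq,
            }
            for e in conversions
        ],
        columns=["source_id", "product_id", "trimmed_end", "trimmed_seq"],
    ).to_csv(path, sep="\t", index=False)
    written.append(path)
    return written


def read_details(path) -> list[ModificationCall]:
    """Reload a ``details.tsv`` into modification calls (round-trip)."""
    df = pd.read_csv(
        path, sep="\t", dtype={"delta_seq": str, "read_seq": str},
        keep_default_na=False,
    )
    return [
        ModificationCall(
            mirna_id=row.mirna_id,
            mtype=ModificationType(row.type),
            delta_seq=row.delta_seq,
            read_seq=row.read_seq,
            read_count=int(row.read_count),
            is_primary=bool(row.is_primary),
        )
        for row in df.itertuples(index=False)
    ]
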