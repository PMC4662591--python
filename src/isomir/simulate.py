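"""Synthetic small-RNA libraries with planted terminal modifications.

Generates a toy genome with mature miRNAs embedded at recorded loci, then
draws collapsed reads per miRNA with a configurable mix of unmodified
reads, non-templated 3'/5' additions, 3'/5' trimmings, and templated-
extension decoys, together with the matching perfect-alignment set and a
truth table keyed by read sequence.

Planted additions are made non-templated *by construction*: the tail
nucleotide adjacent to the miRNA locus is drawn to mismatch the genomic
flank base, so the extended read cannot align perfectly anywhere it was
planted.  Templated decoys do the opposite — they extend the miRNA with
its true genomic flank and are placed in the aligned set, exercising the
detector's genome-alignment exclusion without running a real aligner.

Collapsed abundances are drawn log-normal (heavy-tailed, like real sRNA
libraries) and floored at the detector's default count threshold so that
noise-free simulations sit entirely inside detector limits; sequencing
errors, quality strings and adapters are out of scope.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .io import (
    AlignedSet,
    CollapsedReadSet,
    MatureMiRNA,
    MiRNACatalog,
    write_collapsed_fasta,
    write_mirna_fasta,
)

__all__ = [
    "SimulationProfile",
    "TruthRecord",
    "TruthTable",
    "simulate_reference",
    "simulate_library",
    "write_bundle",
]

NUCS = "ACGT"

#: Read classes the simulator can plant.
CLASSES = ("UNMOD", "ADD3", "ADD5", "TRIM3", "TRIM5", "TEMPLATED_DECOY")


@dataclass(frozen=True)
class SimulationProfile:
    """All knobs of one synthetic library.

    type_probs must sum to 1 over the six read classes; tail_dist governs
    added tails (non-templated by construction), trim_len_dist the length
    of trimmed ends.  count_mu / count_sigma parameterize the log-normal
    abundance draw, floored at count_floor (default: the detector's
    default read-count threshold, 10).
    """

    n_mirnas: int = 50
    mirna_len_range: tuple[int, int] = (21, 25)
    genome_len: int = 50_000
    n_reads: int = 400
    type_probs: dict[str, float] = field(
        default_factory=lambda: {
            "UNMOD": 0.6,
            "ADD3": 0.2,
            "ADD5": 0.05,
            "TRIM3": 0.1,
            "TRIM5": 0.05,
            "TEMPLATED_DECOY": 0.0,
        }
    )
    tail_dist: dict[str, float] = field(
        default_factory=lambda: {"A": 0.7, "T": 0.2, "AT": 0.1}
    )
    trim_len_dist: dict[int, float] = field(
        default_factory=lambda: {1: 0.7, 2: 0.2, 3: 0.1}
    )
    count_mu: float = 3.0
    count_sigma: float = 1.0
    count_floor: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        probs = {c: self.type_probs.get(c, 0.0) for c in CLASSES}
        if any(p < 0 for p in probs.values()):
            raise ValueError("type_probs must be non-negative")
        if not math.isclose(sum(probs.values()), 1.0, abs_tol=1e-9):
            raise ValueError(f"type_probs must sum to 1, got {sum(probs.values())}")
        if not math.isclose(sum(self.tail_dist.values()), 1.0, abs_tol=1e-9):
            raise ValueError("tail_dist must sum to 1")
        if not math.isclose(sum(self.trim_len_dist.values()), 1.0, abs_tol=1e-9):
            raise ValueError("trim_len_dist must sum to 1")
        if self.mirna_len_range[0] > self.mirna_len_range[1]:
            raise ValueError("mirna_len_range must be (min, max)")


@dataclass(frozen=True)
class TruthRecord:
    seq: str
    count: int
    true_mirna: str
    true_type: str  # one of CLASSES
    true_delta: str  # added/trimmed nucleotides ("" for UNMOD)


class TruthTable:
    """Ground truth per emitted unique read sequence (bijective)."""

    def __init__(self):
        self._by_seq: dict[str, TruthRecord] = {}

    def add(self, rec: TruthRecord) -> None:
        if rec.seq in self._by_seq:
            raise ValueError(f"duplicate truth record for {rec.seq}")
        self._by_seq[rec.seq] = rec

    def __getitem__(self, seq: str) -> TruthRecord:
        return self._by_seq[seq]

    def __contains__(self, seq: str) -> bool:
        return seq in self._by_seq

    def __len__(self) -> int:
        return len(self._by_seq)

    def __iter__(self):
        return iter(self._by_seq.values())

    def records(self) -> list[TruthRecord]:
        return list(self._by_seq.values())

    def count_by_type(self) -> dict[str, int]:
        out = {c: 0 for c in CLASSES}
        for r in self:
            out[r.true_type] += r.count
        return out


@dataclass(frozen=True)
class ReferenceInfo:
    """Embedded miRNA loci: id -> (start, end) on the toy genome."""

    genome: str
    loci: dict[str, tuple[int, int]]

    def flank5(self, mirna_id: str) -> str:
        start, _ = self.loci[mirna_id]
        return self.genome[start - 1] if start > 0 else ""

    def flank3(self, mirna_id: str) -> str:
        _, end = self.loci[mirna_id]
        return self.genome[end] if end < len(self.genome) else ""


def _rand_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(NUCS), size=length))


def simulate_reference(profile: SimulationProfile) -> tuple[ReferenceInfo, MiRNACatalog]:
    """Random toy genome with unique miRNAs embedded at disjoint loci.

    Where the tail alphabet allows it, the base immediately flanking each
    locus is drawn from nucleotides that can never begin (3' side) or end
    (5' side) a planted tail, so additions are non-templated by
    construction without distorting the planted tail distribution.  When
    tails cover all four bases the flank stays random and the library
    generator falls back to per-draw resampling.
    """
    rng = np.random.default_rng(profile.seed)
    lo, hi = profile.mirna_len_range
    slot = hi + 10  # miRNA plus flanking context per locus
    if profile.n_mirnas * slot > profile.genome_len:
        raise ValueError(
            f"{profile.n_mirnas} miRNAs of <= {hi} nt do not fit a "
            f"{profile.genome_len} nt genome"
        )
    genome = list(_rand_seq(rng, profile.genome_len))
    starts = np.sort(
        rng.choice(profile.genome_len // slot, size=profile.n_mirnas, replace=False)
    ) * slot + 5
    tail_first = {t[0] for t in profile.tail_dist}
    tail_last = {t[-1] for t in profile.tail_dist}
    safe_3p = [b for b in NUCS if b not in tail_first]
    safe_5p = [b for b in NUCS if b not in tail_last]
    mirnas, loci, seen = [], {}, set()
    for i, start in enumerate(starts, start=1):
        length = int(rng.integers(lo, hi + 1))
        while True:
            seq = _rand_seq(rng, length)
            if seq not in seen:
                break
        seen.add(seq)
        mid = f"sim-miR-{i:03d}"
        genome[start:start + length] = list(seq)
        if safe_5p:
            genome[start - 1] = safe_5p[int(rng.integers(len(safe_5p)))]
        if safe_3p:
            genome[start + length] = safe_3p[int(rng.integers(len(safe_3p)))]
        loci[mid] = (int(start), int(start) + length)
        mirnas.append(MatureMiRNA(id=mid, seq=seq))
    return ReferenceInfo(genome="".join(genome), loci=loci), MiRNACatalog(mirnas)


def _draw(rng: np.random.Generator, dist: dict) -> object:
    keys = sorted(dist, key=str)
    p = np.array([dist[k] for k in keys], dtype=float)
    return keys[int(rng.choice(len(keys), p=p / p.sum()))]


def _draw_count(rng: np.random.Generator, profile: SimulationProfile) -> int:
    c = int(round(float(rng.lognormal(profile.count_mu, profile.count_sigma))))
    return max(profile.count_floor, c)


def _nontemplated_tail(rng: np.random.Generator, profile: SimulationProfile,
                       flank: str, side: str) -> str:
    """Draw a tail whose flank-adjacent base mismatches the genomic flank."""
    for _ in range(100):
        tail = str(_draw(rng, profile.tail_dist))
        adjacent = tail[0] if side == "3p" else tail[-1]
        if adjacent != flank:
            return tail
    raise RuntimeError(
        f"tail_dist only offers the genomic flank base {flank!r}; "
        "cannot plant a non-templated addition at this locus"
    )


def simulate_library(
    profile: SimulationProfile,
    reference: ReferenceInfo,
    catalog: MiRNACatalog,
) -> tuple[CollapsedReadSet, AlignedSet, TruthTable]:
    """Draw a collapsed library with planted modifications plus its truth.

    ``n_reads`` planting draws each pick a miRNA uniformly and a class
    from ``type_probs``.  Unmodified, trimmed and templated-decoy reads
    enter the aligned set (they are genomic substrings / flank-templated
    extensions); non-templated additions never do.  A draw reproducing an
    already-planted (sequence, truth) merges its abundance into the
    existing collapsed read; a sequence collision with a *different*
    truth, or with a catalog sequence, is resampled so the truth table
    stays bijective.
    """
    rng = np.random.default_rng(profile.seed + 1)
    ids = [m.id for m in catalog]
    reads = CollapsedReadSet()
    truth = TruthTable()
    aligned: set[str] = set()
    catalog_seqs = set(catalog.by_seq)
    pending: dict[str, TruthRecord] = {}

    def plant(seq: str, rec_type: str, mirna_id: str, delta: str, in_aligned: bool) -> bool:
        count = _draw_count(rng, profile)
        if seq in pending:
            prev = pending[seq]
            if (prev.true_type, prev.true_mirna, prev.true_delta) != (
                rec_type, mirna_id, delta
            ):
                return False  # ambiguous collision; caller resamples
            pending[seq] = TruthRecord(
                seq, prev.count + count, mirna_id, rec_type, delta
            )
            return True
        if rec_type != "UNMOD" and seq in catalog_seqs:
            return False
        pending[seq] = TruthRecord(seq, count, mirna_id, rec_type, delta)
        if in_aligned:
            aligned.add(seq)
        return True

    n_planted = 0
    attempts = 0
    while n_planted < profile.n_reads:
        attempts += 1
        if attempts > 50 * profile.n_reads:
            raise RuntimeError("simulator failed to plant enough unique reads")
        mid = ids[int(rng.integers(len(ids)))]
        mseq = catalog.by_id[mid].seq
        cls = str(_draw(rng, profile.type_probs))
        if cls == "UNMOD":
            ok = plant(mseq, "UNMOD", mid, "", True)
        elif cls == "ADD3":
            tail = _nontemplated_tail(rng, profile, reference.flank3(mid), "3p")
            ok = plant(mseq + tail, "ADD3", mid, tail, False)
        elif cls == "ADD5":
            head = _nontemplated_tail(rng, profile, reference.flank5(mid), "5p")
            ok = plant(head + mseq, "ADD5", mid, head, False)
        elif cls == "TRIM3":
            k = int(_draw(rng, profile.trim_len_dist))
            if len(mseq) - k < 1:
                continue
            ok = plant(mseq[:-k], "TRIM3", mid, mseq[-k:], True)
        elif cls == "TRIM5":
            k = int(_draw(rng, profile.trim_len_dist))
            if len(mseq) - k < 1:
                continue
            ok = plant(mseq[k:], "TRIM5", mid, mseq[:k], True)
        else:  # TEMPLATED_DECOY: extend with the true genomic flank
            k = int(_draw(rng, profile.trim_len_dist))
            start, end = reference.loci[mid]
            if rng.random() < 0.5 and end + k <= len(reference.genome):
                seq = mseq + reference.genome[end:end + k]
                delta = reference.genome[end:end + k]
            elif start - k >= 0:
                seq = reference.genome[start - k:start] + mseq
                delta = reference.genome[start - k:start]
            else:
                continue
            ok = plant(seq, "TEMPLATED_DECOY", mid, delta, True)
        if ok:
            n_planted += 1

    for rec in pending.values():
        reads.add(rec.seq, rec.count)
        truth.add(rec)
    return reads, AlignedSet(aligned), truth


def write_bowtie_legacy(reads: CollapsedReadSet, aligned: AlignedSet, dest) -> None:
    """Emit the aligned subset as a synthetic Bowtie legacy map file.

    Positions are placeholders (membership is what downstream consumes);
    the empty 8th field marks every hit as mismatch-free.
    """
    with open(dest, "w") as fh:
        for r in reads:
            if r.seq in aligned:
                fh.write(
                    f"{r.uid}_x{r.count}\t+\ttoy\t100\t{r.seq}\t"
                    f"{'I' * len(r.seq)}\t0\t\n"
                )


def write_bundle(
    profile: SimulationProfile,
    outdir,
) -> dict[str, str]:
    """Simulate reference + library and write the full fixture bundle.

    Emits ``genome.fa``, ``mirnas.fa``, ``reads_collapsed.fa``,
    ``alignments.bwt`` (Bowtie legacy dialect), ``truth.tsv`` and a
    ``manifest.json`` echoing the profile.  Returns path map.
    """
    os.makedirs(outdir, exist_ok=True)
    reference, catalog = simulate_reference(profile)
    reads, aligned, truth = simulate_library(profile, reference, catalog)
    paths = {
        "genome": os.path.join(outdir, "genome.fa"),
        "mirnas": os.path.join(outdir, "mirnas.fa"),
        "reads": os.path.join(outdir, "reads_collapsed.fa"),
        "alignments": os.path.join(outdir, "alignments.bwt"),
        "truth": os.path.join(outdir, "truth.tsv"),
        "manifest": os.path.join(outdir, "manifest.json"),
    }
    with open(paths["genome"], "w") as fh:
        fh.write(">toy\n")
        g = reference.genome
        for i in range(0, len(g), 70):
            fh.write(g[i:i + 70] + "\n")
    write_mirna_fasta(catalog, paths["mirnas"])
    write_collapsed_fasta(reads, paths["reads"])
    write_bowtie_legacy(reads, aligned, paths["alignments"])
    with open(paths["truth"], "w") as fh:
        fh.write("seq\tcount\ttrue_mirna\ttrue_type\ttrue_delta\n")
        for rec in truth:
            fh.write(
                f"{rec.seq}\t{rec.count}\t{rec.true_mirna}\t"
                f"{rec.true_type}\t{rec.true_delta}\n"
            )
    manifest = {"profile": asdict(profile)}
    manifest["profile"]["trim_len_dist"] = {
        str(k): v for k, v in profile.trim_len_dist.items()
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    return paths
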