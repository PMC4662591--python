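"""Guide:target hybridization energies and target-variation analysis.

Compares the predicted binding of a reference mature miRNA and of its
modified form against the same target sequence (e.g. a 3' UTR), reporting
the minimum free energy (MFE) of each duplex, the energy change, and
whether the binding site or the seed-paired positions move.

Two interchangeable engines are provided:

* ``external-rnahybrid`` shells out to an RNAhybrid executable with its
  default parameters and parses the best hit;
* ``internal-duplex`` is a self-contained intermolecular duplex model:
  dynamic programming over Watson-Crick and G:U wobble pairs scored with
  Turner 2004 nearest-neighbor stacking free energies (kcal/mol, 37 C),
  affine penalties for internal loops and bulges, and no intramolecular
  structure.  It deliberately omits the duplex-initiation term and target
  accessibility, so absolute energies are duplex-only approximations; the
  reference-vs-modified comparison subtracts any constant offset anyway.

Sequences are handled in the DNA alphabet throughout the package; the
T->U conversion needed for RNA:RNA energetics is internal to this module.
"""

from __future__ import annotations

import re
import shutil
import subprocess
from dataclasses import dataclass

from .io import MatureMiRNA, ParseError

__all__ = [
    "STACK_ENERGIES",
    "HybridResult",
    "TargetComparison",
    "hybridize",
    "compare_targets",
]

# Turner 2004 nearest-neighbor stacking free energies at 37 C, kcal/mol.
# Key ((g1, t1), (g2, t2)) reads 5'-g1 g2-3' on the guide over
# 3'-t1 t2-5' on the target; g1:t1 is the outer pair, g2:t2 the inner.
STACK_ENERGIES: dict[tuple[str, str], float] = {
    ("AU", "AU"): -0.9,
    ("AU", "CG"): -2.2,
    ("AU", "GC"): -2.1,
    ("AU", "GU"): -0.6,
    ("AU", "UA"): -1.1,
    ("AU", "UG"): -1.4,
    ("CG", "AU"): -2.1,
    ("CG", "CG"): -3.3,
    ("CG", "GC"): -2.4,
    ("CG", "GU"): -1.4,
    ("CG", "UA"): -2.1,
    ("CG", "UG"): -2.1,
    ("GC", "AU"): -2.4,
    ("GC", "CG"): -3.4,
    ("GC", "GC"): -3.3,
    ("GC", "GU"): -1.5,
    ("GC", "UA"): -2.2,
    ("GC", "UG"): -2.5,
    ("GU", "AU"): -1.3,
    ("GU", "CG"): -2.5,
    ("GU", "GC"): -2.1,
    ("GU", "GU"): -0.5,
    ("GU", "UA"): -1.4,
    ("GU", "UG"): 1.3,
    ("UA", "AU"): -1.3,
    ("UA", "CG"): -2.4,
    ("UA", "GC"): -2.1,
    ("UA", "GU"): -1.0,
    ("UA", "UA"): -0.9,
    ("UA", "UG"): -1.3,
    ("UG", "AU"): -1.0,
    ("UG", "CG"): -1.5,
    ("UG", "GC"): -1.4,
    ("UG", "GU"): 0.3,
    ("UG", "UA"): -0.6,
    ("UG", "UG"): -0.5,
}

#: Allowed base pairs (guide base + target base), RNA alphabet.
PAIRABLE = frozenset({"AU", "UA", "CG", "GC", "GU", "UG"})

#: Affine penalty for an internal loop or bulge between consecutive pairs:
#: ``LOOP_OPEN + LOOP_EXTEND * total unpaired nucleotides`` (kcal/mol).
LOOP_OPEN = 3.0
LOOP_EXTEND = 0.5

#: Largest number of unpaired nucleotides bridged on either strand.
MAX_LOOP = 10

_INF = float("inf")


@dataclass(frozen=True)
class HybridResult:
    """Best duplex of one guide against one target.

    ``target_pos`` is the 1-based position on the target of the 5'-most
    paired target nucleotide; ``pairs`` lists (guide_pos, target_pos)
    1-based pairs 5'->3' along the guide; ``structure`` is a
    dot-bracket-style string ``guide&target`` over the duplex span.
    """

    guide_id: str
    target_id: str
    mfe: float
    target_pos: int
    structure: str
    pairs: tuple[tuple[int, int], ...]


def _to_rna(seq: str) -> str:
    s = seq.strip().upper().replace("T", "U")
    if set(s) - set("ACGU"):
        raise ParseError(
            f"ambiguity codes unsupported in hybridization input: {seq!r}"
        )
    return s


def _duplex_dp(guide: str, target: str) -> tuple[float, list[tuple[int, int]]] | None:
    """Minimum-energy intermolecular duplex by dynamic programming.

    ``best[i][j]`` is the lowest energy of a duplex whose 3'-most guide
    pair is (i, j); the guide runs 5'->3' while paired target positions
    decrease (antiparallel).  Transitions: adjacent pairs add the stacking
    term, non-adjacent pairs add the affine loop/bulge penalty.  Ties are
    broken toward the smallest final target position, then toward the
    lexicographically smallest pair list, so results are deterministic.
    """
    n, m = len(guide), len(target)
    best = [[_INF] * m for _ in range(n)]
    back: list[list[tuple[int, int] | None]] = [[None] * m for _ in range(n)]
    pairable = [
        [guide[i] + target[j] in PAIRABLE for j in range(m)] for i in range(n)
    ]
    for i in range(n):
        for j in range(m):
            if not pairable[i][j]:
                continue
            e, prev = 0.0, None
            for pi in range(max(0, i - MAX_LOOP - 1), i):
                gi_un = i - pi - 1
                for pj in range(j + 1, min(m, j + MAX_LOOP + 2)):
                    if best[pi][pj] == _INF:
                        continue
                    tj_un = pj - j - 1
                    if gi_un == 0 and tj_un == 0:
                        step = STACK_ENERGIES[(guide[pi] + target[pj], guide[i] + target[j])]
                    else:
                        step = LOOP_OPEN + LOOP_EXTEND * (gi_un + tj_un)
                    cand = best[pi][pj] + step
                    if cand < e - 1e-12:
                        e, prev = cand, (pi, pj)
            best[i][j] = e
            back[i][j] = prev
    # pick the global minimum; tie-break smallest 5'-most target position,
    # which for antiparallel pairing is the final (smallest) j
    end, mfe = None, 0.0
    for i in range(n):
        for j in range(m):
            if best[i][j] == _INF:
                continue
            better = best[i][j] < mfe - 1e-12
            tie = abs(best[i][j] - mfe) <= 1e-12 and end is not None and j < end[1]
            if better or tie:
                mfe, end = best[i][j], (i, j)
    if end is None or mfe >= -1e-12:
        return None
    pairs: list[tuple[int, int]] = []
    cur: tuple[int, int] | None = end
    while cur is not None:
        pairs.append(cur)
        cur = back[cur[0]][cur[1]]
    pairs.reverse()
    return mfe, pairs


def _structure_string(guide: str, target: str, pairs: list[tuple[int, int]]) -> str:
    g0, g1 = pairs[0][0], pairs[-1][0]
    tlo, thi = pairs[-1][1], pairs[0][1]
    gset = {i for i, _ in pairs}
    tset = {j for _, j in pairs}
    gpart = "".join("(" if i in gset else "." for i in range(g0, g1 + 1))
    tpart = "".join(")" if j in tset else "." for j in range(tlo, thi + 1))
    return f"{gpart}&{tpart}"


def hybridize(
    guide: str,
    target: str,
    engine: str = "internal-duplex",
    guide_id: str = "guide",
    target_id: str = "target",
    rnahybrid_path: str | None = None,
    max_target_len: int = 2000,
) -> HybridResult | None:
    """Best (lowest-MFE) hybridization of a guide against one target.

    Returns ``None`` when no duplex with negative free energy exists
    (e.g. a poly-A target with nothing to pair).  The internal engine
    caps the target at ``max_target_len`` nt; longer targets should be
    windowed by the caller.
    """
    if not guide or not target:
        raise ValueError("guide and target must be non-empty")
    if engine in ("internal", "internal-duplex"):
        if len(target) > max_target_len:
            raise ValueError(
                f"target {target_id!r} exceeds the internal engine cap "
                f"({len(target)} > {max_target_len} nt); split it into windows"
            )
        g, t = _to_rna(guide), _to_rna(target)
        hit = _duplex_dp(g, t)
        if hit is None:
            return None
        mfe, pairs = hit
        pairs_1b = tuple((i + 1, j + 1) for i, j in pairs)
        return HybridResult(
            guide_id=guide_id,
            target_id=target_id,
            mfe=round(mfe, 1),
            target_pos=pairs[-1][1] + 1,
            structure=_structure_string(g, t, pairs),
            pairs=pairs_1b,
        )
    if engine in ("external", "external-rnahybrid"):
        return _rnahybrid(guide, target, guide_id, target_id, rnahybrid_path)
    raise ValueError(f"unknown hybridization engine {engine!r}")


def _rnahybrid(
    guide: str, target: str, guide_id: str, target_id: str, exe: str | None
) -> HybridResult | None:
    exe = exe or shutil.which("RNAhybrid")
    if exe is None:
        raise FileNotFoundError(
            "RNAhybrid executable not found on PATH; install it or use "
            "engine='internal-duplex'"
        )
    proc = subprocess.run(
        [exe, "-c", target, guide],
        capture_output=True,
        text=True,
        check=True,
    )
    # compact output: target:len:mirna:len:mfe:pvalue:pos:structure fields
    line = proc.stdout.strip().splitlines()[0]
    fields = line.split(":")
    if len(fields) < 7:
        raise ParseError(f"unexpected RNAhybrid output: {line!r}")
    mfe = float(fields[4])
    pos = int(fields[6])
    if mfe >= 0:
        return None
    return HybridResult(
        guide_id=guide_id,
        target_id=target_id,
        mfe=round(mfe, 1),
        target_pos=pos,
        structure=":".join(fields[7:]) if len(fields) > 7 else "",
        pairs=(),
    )


def _seed_positions(result: HybridResult | None) -> frozenset[int]:
    """Target positions paired to guide seed positions 2-8."""
    if result is None:
        return frozenset()
    return frozenset(j for i, j in result.pairs if 2 <= i <= 8)


@dataclass(frozen=True)
class TargetComparison:
    """Reference-vs-modified hybridization against one target."""

    mirna_id: str
    modified_seq: str
    target_id: str
    mfe_ref: float
    mfe_mod: float
    delta_mfe: float
    site_shifted: bool
    seed_site_changed: bool


def compare_targets(
    mirna: MatureMiRNA,
    modified_seqs: list[str],
    targets: list[tuple[str, str]],
    engine: str = "internal-duplex",
    **engine_kw,
) -> list[TargetComparison]:
    """Target-variation analysis for one miRNA.

    For each modified sequence and each target, both guide forms are
    hybridized with the same engine; ``delta_mfe = mfe_mod - mfe_ref``
    (negative: the modification strengthens predicted binding),
    ``site_shifted`` flags a change of the best-site position, and
    ``seed_site_changed`` flags any change of the target positions paired
    to guide seed nucleotides 2-8.  A form with no reported duplex enters
    with MFE 0.
    """
    out: list[TargetComparison] = []
    ref_cache: dict[str, HybridResult | None] = {}
    for target_id, target_seq in targets:
        if target_id not in ref_cache:
            ref_cache[target_id] = hybridize(
                mirna.seq, target_seq, engine=engine,
                guide_id=mirna.id, target_id=target_id, **engine_kw,
            )
        ref = ref_cache[target_id]
        for mod_seq in modified_seqs:
            mod = hybridize(
                mod_seq, target_seq, engine=engine,
                guide_id=f"{mirna.id}|modified", target_id=target_id, **engine_kw,
            )
            mfe_ref = ref.mfe if ref else 0.0
            mfe_mod = mod.mfe if mod else 0.0
            pos_ref = ref.target_pos if ref else None
            pos_mod = mod.target_pos if mod else None
            out.append(
                TargetComparison(
                    mirna_id=mirna.id,
                    modified_seq=mod_seq,
                    target_id=target_id,
                    mfe_ref=mfe_ref,
                    mfe_mod=mfe_mod,
                    delta_mfe=round(mfe_mod - mfe_ref, 1),
                    site_shifted=pos_ref != pos_mod,
                    seed_site_changed=_seed_positions(ref) != _seed_positions(mod),
                )
            )
    return out
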