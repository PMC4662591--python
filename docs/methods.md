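# Methods

## Classification model

The detector assumes a catalog of mature miRNA sequences that align
perfectly to the reference genome (optionally enforced with
`validate_catalog_alignment` when a catalog-vs-genome alignment is
supplied; otherwise the catalog is trusted), and a genome alignment of
the collapsed reads from which the set of perfectly, end-to-end aligned
read sequences is taken. Classification is purely string-based against
the catalog:

* additions: read = miRNA + δ (3′) or δ + miRNA (5′), emitted only if
  the read is **absent** from the perfect-alignment set — the read-level
  operationalization of "non-templated". Templated extensions (flank
  matches) align perfectly and are thereby excluded.
* trimmings: miRNA = read + δ (3′) or δ + read (5′), emitted regardless
  of alignment, since a trimmed read is a genomic substring by
  construction.

Only these four single-end classes are called. Reads shortened or
extended at *both* ends, internal substrings, and |δ| > `max_delta`
events are counted as unclassified rather than silently dropped, so
the conservation identity

    unmodified + Σ primary-call counts + unclassified = reads passing filters

is checkable on every run. An exact match to any catalog sequence
preempts modification calls (otherwise every annotated paralog would be
reported as an isomiR of its relatives); trimming relations *between*
catalog entries are reported separately as miRNA→miRNA conversions.
Substitution/editing detection and novel-miRNA discovery are out of
scope.

When one read admits several (miRNA, class, δ) explanations, all are
retained in `details.tsv` and exactly one is flagged primary:
smallest |δ| first, then trimming before addition (the more
parsimonious, templated explanation), then alphabetical miRNA id. All
aggregate counts (per-class totals, Z-scores, frequency tables) use
primary calls, making them additive in read counts. The
non-templated test is applied per unique sequence, not per read copy.

### Parameters

| parameter | default | meaning |
|-----------|---------|---------|
| `min_read_count` | 10 | minimum collapsed abundance considered (the tool's default read-count threshold) |
| `max_delta` | 5 nt | longest addition/trimming called; mono- and di-nucleotide events dominate real libraries, a small poly tail remains |
| `min_read_len` / `max_read_len` | 18 / 30 nt | read-length window; typical evaluations of animal sRNA data use 19–25 |

## Scoring and tables

s_i multiplies the number of **distinct modification events** of miRNA
i (distinct (class, δ, read sequence) triples) by its total modified
read count; both quantities are reported alongside. σ(S) is the
population standard deviation (divisor N); with one modified miRNA or
all-equal scores σ = 0, in which case all Z are defined as 0 and a
warning is logged. Z-scores are computed over modified miRNAs only — a
relative ranking among miRNAs that do get modified; wholly unmodified
miRNAs carry no score rather than a misleading strongly negative one.
An alternative reading of "number of modifications" (distinct classes
only) would compress s_i to at most 4 × reads; the event-level count is
used because events and modified reads are reported as separate
quantities throughout.

Frequency tables are read-count weighted (abundance-dominated patterns
such as miR-122 3′ adenylation are the signal of interest); the
`--by-unique` flag / `by_unique=True` computes the unweighted variant.
Percentages are printed to 2 decimals and always sum to 100 together
with the optional "Others" bucket (display threshold, default off).

## Duplex engine

The target-variation analysis needs the same hybridization applied to a
reference and a modified guide. The external engine wraps an RNAhybrid
executable (default parameters, best hit). The internal engine is a
self-contained intermolecular duplex model:

* pairs: Watson–Crick plus G:U wobble (sequences are stored as DNA and
  converted T→U inside the module);
* energies: Turner 2004 nearest-neighbor stacking free energies at
  37 °C (kcal/mol), embedded as data, for adjacent pairs; an affine
  penalty `3.0 + 0.5 × unpaired nt` for internal loops and bulges,
  capped at 10 unpaired nt per strand; no intramolecular structure and
  no target-accessibility term;
* the duplex-initiation term is deliberately omitted: it is a constant
  offset that cancels in ΔMFE = MFE_mod − MFE_ref, and its omission
  makes the fully-complementary limit exactly the sum of stacking
  terms, which the tests exploit as a closed-form check. Absolute MFEs
  are therefore systematically lower than full Turner-model values and
  should be read comparatively, not thermodynamically.

The dynamic program tracks the best duplex ending at each (guide,
target) pair position, O(n·m·L²) with loop cap L; ties are broken
toward the smallest target position, making results deterministic.
Energies are reported to 0.1 kcal/mol (all model terms are multiples of
0.05, so rounding is essentially exact). A hit is reported only when
MFE < 0; otherwise a sentinel "no duplex" is returned and enters
comparisons with MFE 0. "Target-site alteration" is operationalized as
two flags: `site_shifted` (the 1-based position of the 5′-most paired
target nucleotide differs between reference and modified guide) and
`seed_site_changed` (the set of target positions paired to guide
nucleotides 2–8 differs). The internal engine caps targets at 2 000 nt;
longer sequences must be windowed by the caller.

## Synthetic libraries

The simulator emulates the pipeline's inputs end to end: a random toy
genome (default 50 kb) with `n_mirnas` (50) unique mature sequences of
21–25 nt embedded at disjoint recorded loci, and a collapsed library
drawn by repeated planting: each draw picks a miRNA uniformly and a
class from `type_probs` (defaults UNMOD 0.6, ADD3 0.2, ADD5 0.05,
TRIM3 0.1, TRIM5 0.05, decoys 0). Tails come from `tail_dist`
(A/T/AT = 0.7/0.2/0.1), trim lengths from `trim_len_dist`
(1/2/3 nt = 0.7/0.2/0.1, mono ≫ poly as in real data). Abundances are
log-normal (μ=3, σ=1 on the log scale, heavy-tailed like real sRNA
libraries) floored at 10 copies so a noise-free library sits entirely
inside the detector's default thresholds and exact recovery is
well-posed. Draws that reproduce an existing (sequence, truth) merge
their counts; sequence collisions with a different truth are resampled,
keeping the truth table bijective with the read set.

Non-templatedness is guaranteed structurally: the genomic base flanking
each locus is chosen, at reference-construction time, from nucleotides
that no tail in `tail_dist` can abut (possible whenever the tail
alphabet leaves a base free; otherwise the generator falls back to
per-draw resampling, which skews the realized tail mix and is therefore
only a fallback). Templated decoys do the opposite — they extend a
miRNA with its true genomic flank — and, like unmodified and trimmed
reads, are placed in the emitted perfect-alignment set (also written as
a synthetic Bowtie-legacy map file, exercising that parser). Planted
addition reads are never placed in it.

What the simulator does **not** model: sequencing errors and quality
values, adapter read-through, internal editing, expression correlation
between paralogs, multi-locus miRNA genes, and cross-mapping between
near-identical family members. Passing recovery tests therefore
demonstrates the correctness of the classification logic and
bookkeeping under clean planted truth — not robustness to real-library
noise, where imperfect reads would land in the filtered or unclassified
tallies rather than corrupt calls.

## Numerical and procedural choices

* All sequence handling is on normalized uppercase DNA (U→T on input);
  normalization is idempotent and records with other characters are
  dropped and counted (`n_rejected`) rather than aborting a run.
* Detection iterates reads in sorted sequence order, so results are
  independent of input order; reruns are byte-identical.
* Frequency-table and Z-score ties, primary-call ties, and top-miRNA
  ties all break alphabetically — deterministic outputs everywhere.
* The frequency-recovery tests compare against the planted mix with a
  3-standard-error band of the read-count-weighted estimator,
  SE = √(deff · p(1−p)/n_draws), where deff = E[w²]/E[w]² is the design
  effect of the log-normal abundance weights — the correct sampling
  error for a weighted proportion.
* Desk-scale problem sizes: recovery runs use 50 miRNAs and ~1–3 × 10⁵
  read copies (400–3 000 unique reads), the duplex oracle uses guides
  ≤ 9 nt and targets ≤ 14 nt over 200 seeded cases — sizes at which the
  independent enumeration oracles are exact and fast.

## Known limitations

* Multi-mapping reads are classified against every compatible miRNA but
  counted once via the primary flag; no probabilistic re-assignment.
* The read-level non-templated criterion cannot distinguish a tail that
  happens to match *another* genomic locus end-to-end; such reads are
  (correctly, per the criterion) not called as additions.
* The internal duplex engine is a comparative tool; for publication-
  grade absolute energies use the external RNAhybrid engine.
* Catalog entries sharing one mature sequence are booked once (first id
  alphabetically) in the unmodified tally.
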