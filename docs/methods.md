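# Methods

## Substitution model

The model is a general time-reversible Markov chain on the 20 amino
acids in the fixed order `A R N D C Q E G H I L K M F P S T W Y V`.
`Q_ij = S_ij·π_j` for `i ≠ j`, with `S` the symmetric WAG
exchangeability matrix (Whelan & Goldman 2001), embedded verbatim as
`src/lipevol/data/wag.dat` to avoid transcription drift. `Q` is scaled
so `−Σ_i π_i Q_ii = 1`: branch lengths are expected substitutions per
site. Two frequency modes exist and are used consistently across tree
likelihood and ancestral reconstruction: `wag_default` (the published
frequencies) and `empirical_plus_F` (frequencies counted from the
analyzed alignment over non-gap, non-X characters, floored at `1e-4`
and renormalized so zero-count residues keep the chain irreducible).

`P(t) = exp(Qt)` is computed from the eigendecomposition of the
symmetric matrix `Π^{1/2} Q Π^{-1/2}` — exact and stable for reversible
models; rows are clipped to `[0,1]` and renormalized against rounding.
No among-site rate variation is modelled (no Γ categories): the
pipeline fixes the model rather than selecting one.

## Alignment

Pairwise alignment is global affine-gap Needleman–Wunsch–Gotoh
(BLOSUM62, gap open 10, extend 0.5 by default; a gap run of length `k`
costs `open + extend·(k−1)`), with a deterministic tie-break
(match/mismatch preferred over a gap in the first sequence over a gap
in the second). Percent identity is identical-residue columns divided
by all aligned columns holding at least one residue — a stated
convention, since published identity figures rarely define one.

The progressive multiple aligner (UPGMA guide tree on `1 − identity`
distances, profile–profile Needleman–Wunsch with mean-of-pairs scoring
and a linear gap cost of `open/2`) is an explicit convenience
substitute for an external MSA tool; every downstream stage accepts a
precomputed aligned FASTA instead.

## Screening

Criteria are evaluated in a fixed order purely for stable reason
reporting (identity → signal → motifs → lid); all are always evaluated
and every failure is recorded. The signal-peptide heuristic stands in
for an external predictor and is deliberately transparent: the sequence
must start with Met and some 8-residue window beginning within the
first 35 residues must reach mean Kyte–Doolittle hydropathy ≥ 1.6; the
cleavage guess is the best window's end + 5, capped at residue 40.
Externally computed signal flags can be injected per record. The
sequence-length criterion has no published numeric bound and defaults
to off (configurable min/max). Lid length is measured by globally
aligning the candidate to a reference with annotated lid coordinates
and counting candidate residues inside the reference's lid columns.

## Phylogeny

Pairwise distances maximize `Σ_sites log(π_x P_xy(t))` over
`t ∈ [0, 20]` (coarse grid then bounded Brent; gap/X columns skipped).
Topology is Saitou–Nei neighbor joining with the Studier–Keppler
criterion, lexicographic tie-breaks and negative branch estimates
clamped to zero — NJ is exact on additive matrices, which the tests
exploit. Branch lengths are then refit by coordinate-wise bounded
scalar ML on the fixed topology (sweeps until the log-likelihood gains
< 1e−6 or 50 sweeps; the trace is non-decreasing by construction).
A full ML topology search is out of scope; a user-supplied Newick
topology is accepted everywhere a tree is consumed. Rooting places the
root at the midpoint of the outgroup's pendant edge; under
reversibility this does not change the likelihood (tested) and the
default outgroup is the most divergent sequence (largest total
ML distance). Bootstrap support is site resampling with replacement,
NJ per replicate, and per-bipartition frequencies.

Likelihoods use Felsenstein pruning with per-site rescaling of partial
vectors (scalers accumulated in log space), so long trees and many taxa
cannot underflow. Gap and `X` characters contribute all-ones partials —
missing data.

## Ancestral reconstruction

Marginal posteriors come from one up–down pass: `D_v` (pruning partial
below `v`) and `O_v` (outside likelihood joint with the prior,
`O_root = π`, children updated via the sibling-message product), with
`p_vs(a) ∝ O_v(a)·D_v(a)` normalized per site. This equals re-rooting
at each node under reversibility — verified against exhaustive
enumeration over all internal-state assignments on small trees, and by
the invariance of non-root marginals to root placement. MAP ties break
on the lowest alphabet index, making reconstructions deterministic.

Gaps-as-missing is the deliberate reading of the "no gaps" reconstruction
setting: columns are never deleted, so ancestral sequences are defined
at every alignment column. This is what makes ancestral lids span the
full lid block regardless of extant gap content — and what makes
posterior-threshold trimming meaningful, since gap-dominated columns
reconstruct with diffuse posteriors.

## Lid analysis

The lid column block is the contiguous span of alignment columns
containing the reference's annotated lid residues (insertion columns
inside the span included). Trimming keeps exactly the residues with
maximum posterior ≥ θ — "below threshold" is strict, ties are kept, and
the operation is idempotent and monotone in θ (both property-tested).
The default thresholds are 0.65, 0.70, 0.75, 0.80, 0.85, 0.90.

"Hydrophobic" defaults to positive Kyte–Doolittle hydropathy
{I, V, L, F, C, M, A}; the set is configurable and recorded in outputs.
The percentage is **truncated** (floored) to one decimal using integer
arithmetic — 5/12 → 41.6, 22/35 → 62.8, 23/36 → 63.8 — because that is
the only convention consistent with such published value patterns;
rounding is available as an option.

## Habitat statistics

Counts are summarized as mean ± SEM (sample SD/√n; SEM is the chosen
reading of published "mean ± value" tables, with SD available via a
switch). The default comparison is Welch's t-test; the alternative is a
permutation test that permutes group labels exhaustively when the
number of assignments is small (≤ 1e5) and uses seeded resampling
otherwise. The permutation statistic is the Welch t itself
(studentized), the standard recommendation under unequal variances.
On small discrete samples the exact permutation law is genuinely not a
t distribution: the measured Welch-vs-permutation gap reaches ~0.13 at
group sizes 5–8 while averaging below 0.05, which is what the
cross-method consistency test asserts.

## Synthetic families

The simulator emulates the structure of a versatile-lipase family while
staying fully ground-truthed:

* **Tree**: Yule topology (random lineage splitting to `n` leaves) with
  i.i.d. exponential branch lengths of configurable mean, or a fixed
  user Newick. Default mean 0.1 substitutions/site.
* **Root sequence**: drawn from π, except an invariant initiator Met, a
  hydrophobic signal block (residues from {L,I,V,F}, 18 aa), and
  planted `GGGF` / `GESAG` motif blocks.
* **Rates**: lid columns ×3, signal and motif blocks ×0.1 (the
  initiator Met ×0 — translation starts are effectively invariant),
  everything else ×1.
* **Indels**: deletions only, restricted to the lid block — per branch
  each surviving lid position starts a deletion with probability 0.05,
  geometric run length with mean 2. The root therefore defines the
  alignment's column space, homology is exact, extant lid lengths vary
  while ancestors stay defined at all lid columns. Insertions (and
  hence TKF-style insertion homology tracking) are deliberately not
  modelled; this is the one respect in which the generator is simpler
  than real lid evolution, and alignments of real data will contain
  insertion columns the tests do not exercise.
* **Defaults**: 8–16 leaves, 300 columns with a 52-column lid — a
  desk-scale family that simulates in well under a second. The default
  52-column lid matches the full-length lid block of the real protein
  family, and the deletion process yields extant lids roughly in the
  observed 23–52 range.

What passing tests show — and do not show. Recovery tests prove the
inference machinery is correct and well-calibrated *under the
generating model* (WAG, known tree or NJ tree, exact homology). They do
not address alignment error on real sequences, model misspecification
(rate variation, composition shifts), or insertion-rich lids.

The recovery experiments (`lipevol.recovery`) use an 8-leaf, 200-column
family that preserves the default family's composition (a 35-column lid,
the same ~17% share of columns as 52/300), so per-column difficulty
matches the standard study family at a smaller problem size. Median
root MAP accuracy is ≈ 0.9 at mean branch length 0.1 and decays with
divergence (≈ 0.96 / 0.74 / 0.45 at 0.05 / 0.3 / 1.0); with lid
deletions active, the root's θ = 0.85 trimmed lid is reliably shorter
than the extant mean lid — the mechanism behind "older ancestors show
shorter confidently-reconstructed lids".

## Numerical choices and degenerate inputs

* Per-site rescaling bounds: partials divided by their per-site max;
  log-scalers accumulated; probability floors at 1e−300 before logs.
* `t = 0` transition matrix is exactly the identity; negative branch
  lengths are rejected at parse time with the offending edge named.
* Zero-variation alignments drive all optimized branch lengths to 0;
  empty alignments, duplicate ids, zero-length sequences and malformed
  Newick raise format errors naming the offender.
* All coordinates are 0-based half-open internally and 1-based
  inclusive in every user-facing report; all writers emit UTF-8 with LF
  endings; reruns of the pipeline with identical config and inputs are
  byte-identical.

## Known limitations

No ML topology search, no rate heterogeneity, no joint (as opposed to
marginal) ancestral reconstruction, no insertion modelling in the
simulator, no nucleotide/codon support, and no structural validation of
candidates — the screening criteria are purely sequence-based.
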