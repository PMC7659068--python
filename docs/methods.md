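# Methods

## Problem and data model

The package tests for co-diversification between a host lineage complex and
its parasites using genetic distances only — no resolved trees are needed
on the parasite side, which matters because parasite barcode data typically
mix fragment lengths. The in-memory model is a *partial alignment*: every
sequence lives on one alignment coordinate system and carries a half-open
coverage interval `[start, end)`; characters outside coverage are the
padding character `?` ("not sequenced"), while `-` inside coverage is an
indel. Coordinates are 0-based half-open throughout. On input, leading and
trailing gaps are normalized to padding, since outer `-` in exported
alignments almost always means missing data, not deletion.

## TN93 distances

Distances use the Tamura–Nei (1993) model, which separates the two
transition types (A↔G, C↔T) from transversions and allows unequal base
frequencies. For a pair of sequences, only columns inside both coverages
with both characters in {A, C, G, T} are *comparable* (pairwise deletion).
With proportions P1 (A↔G), P2 (C↔T), Q (transversions) and pooled
frequencies g<sub>A</sub>…g<sub>T</sub>, g<sub>R</sub>=g<sub>A</sub>+g<sub>G</sub>,
g<sub>Y</sub>=g<sub>C</sub>+g<sub>T</sub>:

d = −(2g<sub>A</sub>g<sub>G</sub>/g<sub>R</sub>)·ln(1 − g<sub>R</sub>P1/(2g<sub>A</sub>g<sub>G</sub>) − Q/(2g<sub>R</sub>))
−(2g<sub>T</sub>g<sub>C</sub>/g<sub>Y</sub>)·ln(1 − g<sub>Y</sub>P2/(2g<sub>T</sub>g<sub>C</sub>) − Q/(2g<sub>Y</sub>))
−2(g<sub>R</sub>g<sub>Y</sub> − g<sub>A</sub>g<sub>G</sub>g<sub>Y</sub>/g<sub>R</sub> − g<sub>T</sub>g<sub>C</sub>g<sub>R</sub>/g<sub>Y</sub>)·ln(1 − Q/(2g<sub>R</sub>g<sub>Y</sub>))

Design choices:

* **Per-pair pooled frequencies** (over the comparable sites of both
  sequences), not alignment-wide frequencies. This is the robust choice
  when fragments cover different regions; it also means the fourth decimal
  can differ from tools using other frequency conventions.
* **Pairwise deletion, not complete deletion** — complete deletion would
  discard most columns in a dataset deliberately retaining short fragments.
* **Saturation is soft by default**: a log argument ≤ 0 yields a missing
  (NaN) entry with a warning. The distance step stays total; the ordination
  refuses incomplete matrices, so the pipeline fails exactly where a
  complete matrix is first required. `strict=True` turns saturation and
  zero-overlap into immediate errors.

## Haplogrouping

Haplogroups are clusters separated from all other clusters by at least one
variable site within shared coverage. The clustering is greedy and
deterministic: sequences sorted by coverage length descending (ties broken
lexicographically by label) are compared against each existing haplogroup's
representative over their comparable sites. At least one mismatch against
every representative with positive overlap founds a new haplogroup; a
perfect match with exactly one joins it; perfect matches with several yield
an *ambiguous* assignment — the sequence carries a candidate set and is a
member of no group, so representatives always carry full information. A
sequence overlapping no representative at all is an error. Diagnostic sites
are recomputed at the end: for each group, the columns at which its
representative differs from every other representative comparable there.

Longest-first seeding is one defensible reading of haplogroup definition by
diagnostic sites; a different processing order could in principle merge or
split chains of compatible fragments differently, so inventories from other
implementations may differ by ±1 group on pathological inputs.

Species assignment replaces likelihood tree placement with the nearest
labeled reference by TN93 distance (threshold 0.10 substitutions/site,
configurable; ties broken by the smaller mean distance to each tied
species' references). This is a standard, testable surrogate when tree
inference is out of scope.

## The Procrustean co-phylogeny test

1. **PCoA** of each distance matrix: Gower double-centering of −½d²,
   eigendecomposition, axes retained while the eigenvalue exceeds 1e-8 of
   the largest. Negative eigenvalues (non-Euclidean matrices) are dropped —
   the common practice for this test; a Cailliez correction is available
   behind `correction="cailliez"` but off by default.
2. **Link expansion**: one row per association link (host coordinates in
   X*, parasite coordinates in Y*), the narrower matrix zero-padded to the
   common axis count, both column-centered.
3. **Procrustes superimposition** of Y* onto X* with rotation (reflection
   allowed, R = UVᵀ from the SVD of Y*ᵀX*) and scale c = (Σσᵢ)/tr(Y*ᵀY*).
   The global statistic m²_XY is the residual sum of squares, computed both
   as the explicit sum of per-link squared residuals and by the closed form
   tr(X*ᵀX*) − (Σσᵢ)²/tr(Y*ᵀY*); the implementation asserts their agreement
   to 1e-9.
4. **Permutation null**: each permutation applies a uniform random
   permutation to the host components of the link list (parasite components
   fixed — preserving the number of links and each parasite's link count),
   rebuilds X* and recomputes m². Because permuting rows leaves the row
   multiset, the centering, and tr(X*ᵀX*) unchanged, only the SVD pairing
   term is recomputed, in vectorized batches. The p-value uses the add-one
   convention p = (1 + #{m²_perm ≤ m²_obs})/(N + 1), ties counting toward
   the numerator, so p ≥ 1/(N+1) > 0. Fewer than 99 permutations are
   refused unless forced.
5. **Jackknife link residuals**: PCoA is computed once per matrix — the
   permutations and deletions act on links, not distances. For each deleted
   link j the remaining rows are re-centered and refit; pseudovalues
   ν_ij = L·r²ᵢ(full) − (L−1)·r²ᵢ(−j) averaged over j≠i give each link's
   estimate (truncated below at 0), with a one-sided upper bound
   estimate + t(0.95, L−2)·SE(ν_i·). Small estimates mark links supporting
   co-phylogeny; the largest mark candidate host shifts.
6. **Ambiguity**: an infection table with multi-candidate observations
   expands into the Cartesian product of candidate choices, capped at 64
   alternatives. Each alternative runs with its own sub-seed derived
   deterministically from the user seed; the reported result is the
   maximum-P alternative (conservative), with all alternatives retained.
   An alternative may omit a parasite that only enters via the other
   candidate of an ambiguous observation; each run uses exactly the labels
   its own link set covers.

All randomness flows from one user-visible integer seed through fixed
derivations (`numpy.random.SeedSequence`), so results are bit-reproducible.

## Synthetic scenarios

The simulator provides ground truth for every stage:

* **Host tree**: Yule (pure birth), rescaled so every root-to-tip path
  equals `depth` (default 0.15 substitutions/site — deep intraspecific
  divergence typical of old cryptic species complexes).
* **Parasite tree**: a copy of the host tree (perfect co-divergence),
  branch lengths multiplied by a parasite/host rate ratio (default 1.0; no
  reliable prior favors faster or slower parasite substitution here), then
  perturbed by `n_shifts` tip-SPR moves. Each move prunes a distinct random
  tip and regrafts it onto a random branch outside its former sibling's
  edge — guaranteeing a topology change — at an ultrametricity-preserving
  height. Moved tips are the planted host shifts; SPR on a copied tree
  reproduces exactly the incongruence signature that host shifts leave,
  with a single interpretable knob.
* **Sequences**: root drawn from the equilibrium frequencies, then
  site-independent TN93 evolution (matrix exponential of the normalized
  rate matrix per branch). Defaults: transition/transversion rate ratio 4,
  equal base frequencies, 800 bp — a generic ribosomal-marker regime.
* **Fragments**: parasite sequences truncated to 5'-anchored fragments
  drawn from a mixture of 17% ~350 bp, 17% ~530 bp, 66% full length —
  enough short fragments for haplogroup ambiguity to occur without
  dominating. Anchoring is one-sided because nested amplicons share the
  forward primer.

What the simulator does *not* emulate: rate variation across sites and
lineages, indels and alignment error, recombination, within-host parasite
diversity, sampling biases, and non-ultrametric trees. Passing tests
therefore demonstrate correctness of the statistical machinery under the
model's own assumptions, not robustness to every feature of real surveys.

## Verification problem sizes

The statistical checks run at desk scale, chosen to finish in seconds to
minutes while leaving clear Monte-Carlo margins: type-I error from 500
randomized-link replicates at 199 permutations (binomial SE ≈ 0.01 around
0.05); power from 100 congruent scenarios (n = 16 tips) at 999
permutations; host-shift diagnosis from 100 scenarios with 3 shifts.
Production analyses would typically use 10⁵–10⁶ permutations; the
permutation kernel is vectorized and chunked, so a million permutations on
~45 links takes on the order of a minute.

## Known limitations

* TN93 here has no gamma rate heterogeneity (by design; the distance step
  mirrors the simple model, not its +G extension).
* The greedy haplogrouping order effect noted above.
* PACo's permutation scheme is one reading of "assigning hosts randomly to
  parasites"; other null models (e.g. permuting within host clades) are not
  implemented. The report header records the scheme used.
* The jackknife upper bound assumes approximately normal pseudovalues; with
  very few links (L close to 4) the bound is only indicative.
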