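# Methods

## The procedure

The pipeline asks, for a candidate protein pair (A, B), whether any
member of a library of two-chain template complexes is a *structural
precedent*: a dimer (X, Y) whose chains are each globally similar to one
monomer.  Similarity is the TM-score, a length-normalized superposition
score in (0, 1] that discounts local deviations through the distance
scale d₀(L) = max(0.5, 1.24·(L−15)^⅓ − 1.8).  Pair-level similarity is
TMmin — the minimum of the two per-chain scores, maximized over the two
possible chain assignments — so a precedent requires *both* monomers to
match.  Hits above a TMmin threshold are ranked by decreasing TMmin (ties
broken lexicographically by template id, then assignment) and the first
hit whose superposition-built model passes the interface check (≥ 20
pooled interface residues at a 5 Å atom cutoff, at most 2 inter-chain
Cα–Cα pairs under 3.0 Å) is retained.  Detection rates over pair
populations, measured per TMmin threshold, feed a completeness-corrected
extrapolation: the rate for interacting pairs proxies the completeness of
the template library, so the corrected negative rate is
100·r₋/r₊; the chance expectation under pure false-negative contamination
is r₊·(network density), and the enrichment factor is the ratio of the
observed negative rate to that expectation.

## The structural aligner

The aligner is a fragment-seeded iterative method in the TM-align family,
not a re-implementation of any particular executable; parity with
published tools is explicitly not claimed, and the aligner is validated
against oracles instead (brute-force enumeration of sequential mappings
on small chains, a quaternion superposition oracle, analytic TM-score
limits).  Seeds come from gapless threading at every offset and from
15-residue fragment superpositions; each round superposes on the current
mapping (re-superposing on the close subset to sharpen the transform),
scores all residue pairs by 1/(1+(d/d₀)²), and re-aligns by sequential
dynamic programming with an affine gap cost (opening −0.6, no extension,
free end gaps, ties toward the diagonal), until the mapping repeats or 20
rounds pass.  The returned score is the TM-score of the final mapping
maximized over rigid transforms by a fragment-seeded superposition
search.  TM-scores are normalized by the query (first) chain length; the
partner-normalized score is recorded on every result so either convention
can be recomputed downstream.  Alignments are sequential only.

## Synthetic data: what it emulates and what it does not

All stages run on generated data, so the generators define the study
conditions:

- **Chains** are backbone+CB traces built from ideal α-helix (1.5 Å
  rise, 100°/residue, 2.3 Å radius) and extended-strand (3.3 Å rise)
  segments joined by random turns, with consecutive Cα–Cα distances near
  3.8 Å and no two Cα closer than 3.6 Å.  Side chains are represented by
  CB only, so every 5 Å atom-contact rule operates on backbone+CB; full
  rotamer building is out of scope.
- **Template dimers** are rigid-body docked along a random contact axis
  until the inter-chain residue contact count at 5 Å reaches the target
  (default 25, comfortably above the >10 library inclusion rule) with a
  pooled interface of at least 24 residues and no Cα clash.  The extra
  interface-size floor mirrors the fact that real dimer libraries are
  dominated by interfaces large enough to pass the 20-residue validity
  rule; without it most planted precedents would be rejected for a
  reason that has no analogue in experimental complexes.
- **Monomer models** are noise-perturbed (default σ = 0.3 Å per
  coordinate, emulating close-template homology models) and arbitrarily
  re-posed copies of template chains.  Positive pairs copy both chains of
  one dimer; *structure-compatible negatives* (default 20% of negatives)
  do the same but are labelled non-interacting — the phenomenon under
  study, pairs that resemble an experimental complex without a functional
  interaction; the remaining negatives are unrelated fresh folds.
- Planted templates are assigned round-robin (positives) or at even
  strides (compatible negatives) over the library.  Balanced coverage is
  the natural design for a planted benchmark and keeps the
  thinned-library completeness study estimable at desk scale: cutting the
  library to a prefix fraction f removes a predictable share of planted
  precedents on both sides of the correction.
- **Networks** are preferential-attachment graphs (heavy-tailed degrees);
  the two-community variant joins two such graphs by a few bridges.
  **Annotations** draw localizations from five compartments (~15%
  bi-localized), abundance classes from log-normal draws cut at quartiles
  (bottom 25% low, top 25% high), and term sets with popularity weights.

What passing tests on this world do *not* show: realistic fold space or
sequence-structure coupling (chains are geometric, not physical),
homology detection (negatives are either planted copies or entirely
unrelated — there is no twilight zone), detection-method noise, or the
composition of real template libraries.  The pipeline's discrimination
numbers on synthetic data are therefore cleaner than anything achievable
on real proteomes; the tests establish correctness of the machinery and
the internal consistency of the extrapolation logic, not field
performance.

## Interface descriptors

Accessible surface area is Shrake–Rupley sphere sampling (Fibonacci
spiral, default 960 points/atom, probe 1.4 Å) with an NACCESS-like radius
set (C 1.87, N 1.65, O 1.40, S 1.85 Å).  Buried area per residue is
max(0, ASA_isolated − ASA_complexed); interface ASA uses the symmetric
ΔASA/2 convention; hydrophobicity is the buried-area share of
{A,V,L,I,P,F,M,W,C}.  Gap volume lays a regular grid (default 1 Å) over
the inter-chain region and counts voxels outside every expanded atom
sphere (radius + 1.4 Å) yet within a 5 Å shell of both chains; the gap
index divides by interface ASA.  This grid quantity is *comparable to but
not identical with* the sphere-based published descriptor, and outputs
are labelled accordingly.  Note a geometric consequence of the
definition: between two flat facing sheets the expanded spheres occlude
the slit up to ~6.5 Å separation and the two-chain shell caps it above
~7 Å, so monotone growth of gap volume with separation only holds in the
open regime (the tests exercise 7–9 Å with a widened shell).

Contact signatures count inter-chain residue pairs with Cα–Cα < 12 Å in
a symmetric 7×7 matrix over the classes {V,I,M,C,L}, {A,S,P,T}, {G},
{Y,F,W}, {K,R,H}, {D,E}, {N,Q}; nonstandard residues are kept for
geometry but excluded from class-based counts.  The signature distance is
the cosine distance on the flattened upper triangle — the simplest form
meeting both boundary conditions (0 for identical interfaces up to
scale, 1 for disjoint contact types).  It is isolated behind one function
so an alternative (e.g. normalized L1) can be swapped in.

## Network analysis

Graphs are simple and undirected; paths are unweighted hop counts.  Each
candidate pair is added separately to the native network and the extra
edge's betweenness (Brandes accumulation, fractional credit across tied
shortest paths) is compared with the (1 − 0.10) quantile of the edge
betweenness values of its own augmented graph; a flag switches the
threshold to the native graph's quantile.  Per-category enrichment is
log₂(observed bottleneck fraction / 0.10) — the base and exact form of
the published log-odds are unstated, so these values are treated as
qualitative — with a chi-squared test on the category × bottleneck
contingency and standardized-residual p-values.

## Pair datasets

Negative sampling implements five strategies: uniform non-edge sampling;
degree-preserving (balanced) sampling by stub matching with rejection of
self-loops, duplicates and native edges and up to 1000 restarts —
infeasibility is reported as an error, and genuinely infeasible inputs
exist (a hub whose native degree exceeds its number of non-neighbours,
or the 4-cycle, admit no degree-preserving non-edge set); filtering to
pairs with network distance strictly greater than 10 (disconnected pairs
kept); non-colocalized filtering (exactly one, differing, localization
each — multi-localized or unannotated proteins disqualify a pair); and
direct-evidence filtering on detection-method terms (Two-hybrid, PCA,
Biochemical Activity, Co-crystal Structure, Reconstituted Complex, Far
Western, FRET).  Pair abundance is the lower of the two proteins'
classes: a scarce partner limits complex formation.

## Statistics

Rate curves divide pairs with a valid precedent at TMmin ≥ t by pairs
with available models.  The Fisher exact test is two-sided by the
probability-mass rule.  The Cramér two-sample test uses the
Baringhaus–Franz statistic with φ(z) = |z|/2 and a label-permutation
bootstrap (vectorized over permutations; an ordinary bootstrap is
available by flag); its null calibration (type-I error 0.05 ± 0.02 at
m = n = 30) is verified by simulation in the test suite.  Term
enrichment is upper-tail hypergeometric with Benjamini–Hochberg
correction at α = 0.05.  Percentages are carried as reals; rounding
helpers match printed table precision.

## Problem sizes and numerical choices

The default study uses 8 template dimers, 16 positive and 20 negative
pairs with chain lengths 30–60 — sizes chosen so a full screen (all
pairs × templates × both assignments, with a shared per-chain alignment
cache) completes in well under a minute while leaving every rate
estimable.  The dynamic programming kernel is numba-compiled; Kabsch
superposition rejects collinear point sets; d₀ is floored at 0.5 Å for
short chains; degenerate descriptor inputs (no buried area, empty
signatures) raise explicit flagged errors rather than returning zeros.
Interface validity reads "at least 20 residues" as the pooled count over
both chains (per-chain counts are recorded alongside), "less than three
clashes" as clash_count ≤ 2, and uses a 3.0 Å Cα clash cutoff — below
any physical Cα–Cα approach.

## Known limitations

The aligner trades exactness for speed and has no non-sequential mode;
TM-scores near the 0.4 threshold can differ from other implementations.
The gap index is grid-based, not sphere-shrinking.  The binding-affinity
stage is a plug-in point only (any callable mapping a model to a
ΔG-like scalar can be attached to the descriptor tables); no force field
ships with the package.  mmCIF, assemblies, hydrogens and multi-fragment
homology models are out of scope; models are assumed single-fragment.
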