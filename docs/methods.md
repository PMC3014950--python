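# Methods

## Translation strings and decodability

A global pairwise alignment (x̂, ŷ) of length λ is re-encoded column by
column over nine symbols: `0` (identical letters), `A/C/G/T` (letter
inserted into y where x̂ has a gap), `-` (letter of x deleted), `1`
(transition A↔G or C↔T), `2` (transversion A↔C or T↔G), `3` (transversion
A↔T or G↔C).  Substitution codes are *relative* — each letter has exactly
one partner per class, so `1` maps A to G and G to A — which is what makes
decoding conditional on x possible.  The encoding is exactly invertible:
`decode(x, t(x→y)) = y` for every valid alignment (fuzz-tested over
thousands of simulated indel-bearing pairs).  Gap columns break the
directional symmetry: an insertion must spell its letter while a deletion
is a bare marker, so t(x→y) ≠ t(y→x) whenever the alignment has gaps,
mirroring the asymmetry of conditional information.  Which transversion
pair carries code `2` versus `3` is an arbitrary labelling; every
downstream quantity is invariant to it, and the assignment above is fixed
as this package's canonical convention.  Byte values of the nine symbols
are fixed (`0ACGT-123`) so compressed sizes are reproducible bit-for-bit.

## Compression-based MI

`csize` reports 8 × (compressed byte count) for a registered codec —
DEFLATE, bzip2 or LZMA (default: LZMA, the strongest of the three on this
alphabet).  Conditional size C(t|x) is realised as the concatenation
difference C(x ∥ SEP ∥ t) − C(x) with a one-byte separator outside both
alphabets, floored at 0; general-purpose codecs expose no native
conditioning interface, and this difference captures whatever
cross-correlations the codec window finds.  The alignment estimator is

    Î_align(x:y) = C(x) − C(t(x→y)|x)   (directional),

symmetrised as the mean of the two directions; the alignment-free
estimator is Î_concat = C(x) + C(y) − C(xy), averaged over both orders.
Negative estimates (meaningless alignments) are reported, not clamped.
Directional values are retained in every `MIEstimate` for auditability.

Known estimator biases, measured on independent 16 kb uniform sequences
and accepted rather than corrected:

* every adaptive codec pays its model warm-up once for a concatenation but
  twice for the parts, so Î_concat of *independent* pairs is positive —
  about 7 % of C(x) for LZMA, 3 % for DEFLATE, 2 % for bzip2 at 16 kb.
  Specialised DNA compressors with explicit repeat models shrink this but
  are outside the dependency set of this package;
* the conditional variant of Î_align inherits the same amortisation
  (≈ +5 % at 16 kb); the unconditional variant is nearly unbiased there
  (within ±0.5 %);
* imperfect codecs more likely under- than over-estimate MI for related
  pairs; no correction is attempted.

## Shannon MI and the joint frequency matrix

Block entropies H_n are plain plug-in estimates (0·log 0 = 0, no
pseudocounts, log₂, n ≤ 8 as a memory guard).  The single-letter MI of an
alignment comes from the 4×4 matrix of aligned column frequencies after
dropping indel columns (a 5-letter variant keeps the gap as a symbol, but
indels cluster, so the per-site independence assumption is weaker there —
it is provided and flagged, not used by default).  Plug-in MI is biased
*upward* by ≈ (k−1)²/(2N′ ln 2) bits for an N′-site sample — about
6.5·10⁻⁴ bits at N′ = 10⁴ — and this matters when comparing an estimate
against an exact analytic value such as the 1 bit/site of the
counter-example construction: finite-sample estimates straddle 1.0 from
*above* roughly three times out of four.

## Distances

NCD and NSD normalise MI by the larger single-sequence complexity or
entropy; both saturate at 1 for unrelated pairs and are therefore convex
in evolutionary time (long-branch attraction risk).  The log-MI transform
−log₂(I/max(Hx,Hy)) is linear in time exactly when MI decays as
H·e^(−ct).  For any 4-state reversible substitution model the decay is a
sum of exponential modes with combined prefactor A = (#modes)/(2 ln 2) ≠ H,
so log-MI carries a constant additivity defect −log₂(A/H) ≈ −0.12
(measured −0.13 on K2P chains at 0.15+0.15 substitutions/site,
independent of the transition/transversion ratio).  It is *approximately*
additive — much closer than NSD, whose defect on the same chains is −0.19
and grows with depth — but not exactly so; the package audits additivity
rather than assuming it.  log-MI also fails the triangle inequality on the
constructed bit-resampled triple (d(y,z) = ∞ with both legs finite), which
the `triangle_audit` helper reproduces; NSD keeps the inequality there.

The log-det/paralinear distance uses the 1/4 normalisation (alphabet
size), natural log, and returns +∞ when det F ≤ 0 rather than failing; a
zero marginal raises (degenerate composition).  It is exactly additive in
expectation under stationary Markov evolution, which the chain study
confirms to within sampling error.  PC-p, −ln(1−p), is the crude Poisson
correction: under Jukes-Cantor evolution it is *inconsistent*: p converges to
3/4·(1−e^(−4t/3)), so PC-p converges to −ln(1/4 + 3/4·e^(−4t/3)) < t
(0.1931 at t = 0.2, a −3.5 % bias), unlike Kimura-1 and log-det which are consistent
there.  Kimura-1 is the classic −½ ln[(1−2P−Q)√(1−2Q)].  Kimura-2 — the
likelihood-flavoured variant — is implemented as the log-MI form on the
three-class coarse-graining {identical, transition, transversion} against
the independence-induced class distribution; its exact published form was
not available, and the reconstruction preserves the documented reading
(a coarse-grained MI with substitutions lumped).  It is flagged
"reconstructed" in the docstring.

## Aligner

Three-state Gotoh affine recursion; gap_open is the cost of the first
gapped position (defaults +1/−1/−4/−1, conventional DNA values — the MI
estimates are upper bounds whose tightness, not validity, depends on the
scoring).  Ties are broken substitution > gap-in-y > gap-in-x at every
cell and at the final state, making alignments byte-reproducible.  Scores
are verified exactly against exhaustive enumeration of all affine-gap
global alignments (lengths ≤ 8) and against an independent implementation
on longer pairs.  A banded mode restricts the dynamic program to a
corridor around the straight-line diagonal for long, collinear sequences
(the corridor always contains a monotone path, so banding tightens, never
empties, the search space); end gaps are penalised by default with a
free-end-gap option.

## Quartets

From sorted pairing sums s₁ ≤ s₂ ≤ s₃: topology = split attaining s₁,
internal edge (s₂−s₁)/2, violation s₃−s₂; ties break to the
lexicographically smallest split.  The significance of a call is scored as
(s₂−s₁)/(v + 0.01·scale) with scale = mean off-diagonal distance; the
regulariser keeps additive quartets finite and the raw (ℓ, v) pair is
always emitted so any alternative score can be recomputed.  This score is
a reconstruction that preserves its two design ingredients (four-point
violation and relative central-edge length); no published closed form was
available.  Quartets containing non-finite distances are declared
unresolvable instead of being ranked.  The triangle audit uses a 10⁻⁹
relative tolerance.

## Simulator: what it does and does not emulate

Substitutions are i.i.d. per site via exp(Qt) with Q normalised to one
expected substitution per site per unit branch length; roots are drawn
from the stationary distribution; each branch evolves independently.
Defaults chosen once: κ = 2 for K2P/HKY (conservative textbook value),
indel events Poisson with rate per site and geometric lengths of mean 3,
applied after substitution with no overlapping-event bookkeeping.  The
compositional-bias mode (AT-rich HKY) reproduces the qualitative effect
seen in insect mitochondrial data: single-sequence entropy drops below
2 bits while substitution-driven MI decay is unchanged.

Not modelled: rate heterogeneity across sites, codon structure,
genome rearrangement (ORF shuffling), correlated indel bursts beyond the
geometric-length model, and base-composition drift along a branch.
Passing the validation studies therefore demonstrates correctness of the
estimators and the inference machinery under homogeneous Markov
evolution; it does not certify behaviour on rearranged or
rate-heterogeneous genomes, where the alignment step itself is the main
failure mode.

## Study sizes

The validation studies use: 1000 pairs of length ~120 (round trip), 500
pairs of length ≤ 8 (aligner oracle), 100 fuzzed strings/matrices
(Shannon oracle), length 10⁴ (counter-example), 100 replicates × 10⁴
sites (JC recovery and chain additivity), 200 quartets × 5000 sites
(recovery; 200 × 100 sites for the short-length contrast), and 50 pairs ×
16 kb (compression-estimator agreement, banded alignment with half-width
50, divergences evenly spaced in t ∈ [0.02, 0.6] — the within-class range
typical of the mitochondrial comparisons this mirrors).  These sizes give
standard errors comfortably below the effects being tested while keeping
the full suite inside a few minutes on one CPU.
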