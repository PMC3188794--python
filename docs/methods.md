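# Methods

## Codon weights

Per-codon relative adaptiveness follows the classical tRNA-adaptation scheme:
each sense codon is decoded by its Watson–Crick anticodon plus one wobble
anticodon at the third position, with pairing classes keyed
`<codon base>:<anticodon base>` and default selective constraints
s(U:G) = 0.41, s(C:I) = 0.28, s(A:I) = 0.9999, s(G:U) = 0.68 (A34 treated as
inosine against C- and A-ending codons; Watson–Crick pairs carry s = 0).
Absolute adaptiveness W = Σ (1 − s)·tGCN is max-normalized to w ∈ (0, 1].

Two repairs are applied, in this order:

1. **CGA override.** CGA is read only through the near-forbidden I:A wobble,
   so its computed weight (~7·10⁻⁵ with the bundled table) would dwarf every
   other time value. Its weight is fixed to 0.1333 by default. The override
   is applied at the *weight* level, not by editing an s-value: only the
   resulting weight is well determined, and with the bundled tRNA repertoire
   the two formulations affect no other codon.
2. **Zero-weight imputation.** Codons left with W = 0 (AUA under the bundled
   table, whose lysidine-modified Ile2 tRNA is deliberately excluded because
   the generic wobble rules would credit it to AUG) are imputed with the
   geometric mean of the non-zero weights. The override precedes imputation
   so CGA enters the mean at 0.1333 rather than at its degenerate raw value.

The bundled anticodon copy-number table approximates the E. coli K-12
repertoire and is package data, not a deposited dataset; any pool/s-value
pair can be supplied as TSV.

## Bottleneck scan

The bottleneck is the length-*n* window minimizing the harmonic mean of w —
identically the window maximizing Σ 1/w, which is how it is computed. Window
sums are evaluated per window (not as cumulative-sum differences) so that
near-ties resolve bit-identically to independent slice summation; ties break
to the leftmost (most proximal) window, a convention chosen to make results
deterministic. Locations are 1-based so relative location = k/(ℓ − n + 1)
spans (0, 1]. Genes shorter than the window raise an error in single-gene
use and are skipped with a warning in batch scans. n defaults to 21 codons =
round(21.6 nm / 0.34 nm·base⁻¹ / 3); setting H (jam window) equal to n links
the scan to the traffic-jam condition, which is evaluated with strict
inequality — at Tw(k,H) = Tw(1,H) + B the trailing ribosome arrives exactly
on time and no jam is declared. B, the assembly time on the start codon, has
no canonical value and stays a free parameter.

On near-flat time profiles (e.g. synonymous variants of one backbone drawn
uniformly) the argmin window is weakly identified and its location can move
with n; with a genuine bottleneck the location is stable across n = 14–30
(rank correlation > 0.9 in the test suite). This is a property of the
statistic, not of the implementation.

## Library statistics

Per-cell abundance is bulk abundance divided by OD; constant-OD designs
bypass the division via a flag. Correlations are Pearson and Spearman
(average ranks on ties) with two-sided p-values; zero-variance inputs yield
an undefined-flagged result rather than an exception, mirroring
constant-count codons. Partial correlation uses the first-order formula
r_xy·z = (r_xy − r_xz·r_yz)/√((1 − r_xz²)(1 − r_yz²)) with a t-test at n − 3
degrees of freedom; the rank variant applies the same formula to
rank-transformed data (a large-sample approximation, also used for Spearman
p-values). The proximal band defaults to relative locations 0.16–0.28,
inclusive; band analyses with fewer than 3 members are skipped with a
warning.

The codon screen correlates each sense codon's copy number with OD and
classifies at α = 0.05/61 (Bonferroni over the 61 sense codons, even though
single-codon amino acids never vary in a synonymous library — they are
reported as `constant`). The ranking procedure keeps negatively correlated
codons, builds the full matrix M(i,j) of partial correlations of codon i
with OD given codon j, and ranks by min_j |M(i,j)| descending; a codon with
no valid controlling partner falls back to |raw r| (min over an empty set).

## Genome survey

Genes longer than 100 codons (≥ 101) enter the survey. Quadrants of
relative location are half-open, [0, 0.25) … [0.75, 1], so "first quadrant"
means relative location < 0.25; "strong" means relative strength strictly
above 1.3. Hypergeometric tail probabilities are computed by summing the pmf
over the tail range (both tails include the observed count); this keeps
p-values of order 10⁻⁹ accurate, which a 1 − cdf formulation would lose to
cancellation. Expression classes take the top and bottom 500 recorded genes,
ties resolved by (level descending, gene id ascending), then intersect with
the length-filtered table.

## Synthetic libraries

The generator back-translates a fixed 239-residue GFP-like protein (an
avGFP-derived synthetic fixture with 11 Ser and 10 His, so the penalty codons
UCA and CAU can vary) under three policies: uniform over synonyms,
speed-weighted, or planted-bottleneck. Planting fixes a target window from
the requested relative location; inside it each position takes its slowest
synonym with probability q and outside its fastest with probability 0.8,
where q is solved by bisection so the *expected* relative strength matches
the target (unreachable targets warn and use q = 1). Translation fidelity is
checked for every variant; everything is reproducible from the seed.

Measurements follow
log per-cell abundance = 3.0 − 0.7·relloc + 2.4·(relstr − 1.3)·1[relloc ≤ 0.28]
+ 0.08·F + N(0, 0.35), with folding energy F ~ N(−8, 2) kcal/mol drawn as an
independent covariate (secondary-structure prediction is out of scope, and
independence lets tests toggle confounding); OD = 1.5 − 0.05·#UCA − 0.04·#CAU
+ N(0, 0.08), floored at 0.05 (an error if the floor hits > 10% of variants);
protein abundance = per-cell abundance × OD, so the normalization step is
exactly invertible in expectation. Referencing the strength term to a
typical relative strength (1.3) makes the proximal indicator contribute a
slope rather than a step. Effect sizes were chosen once so that at 150
variants the recovered correlations sit at moderate magnitudes
(location r ≈ −0.45, in-band strength r ≈ +0.38, penalty-codon r ≈ −0.5).

Because the amino-acid backbone is fixed, uniform-synonymous variants
concentrate their bottlenecks in a Ser/His-rich proximal stretch (about
two-thirds fall in the 0.16–0.28 band) — a convenient echo of real GFP
libraries, but it means the generator does not emulate arbitrary location
distributions, promoter/UTR variation, mRNA stability differences, or
measurement nonlinearity. Passing tests therefore demonstrate correctness of
the statistical machinery on the assumed generative structure, not that real
libraries obey that structure.

## Problem sizes and tolerances

Oracle-equivalence checks run on 1,000 random genes of 25–300 codons
(bottleneck scan, harmonic-mean identity at float-value resolution) and 500
random profiles (jam condition, including engineered equality cases);
hypergeometric tails are checked against integer-arithmetic brute force to
1e-12 for populations up to 200. Planted-effect recovery uses 100 replicate
libraries of 150 variants; null calibration uses 50. These sizes make the
full suite run in well under a minute of compute per component while keeping
every Monte Carlo rate estimate stable to a few percent.
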