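# Methods

This note documents the models, algorithms and numerical choices behind
`cavemap`, and what the synthetic-data experiments do and do not demonstrate.

## The cross and the genotype model

The design is an F2 intercross between two inbred-like morphotype lines
("surface" and "cave"), genotyped at biallelic SNPs embedded in 64-bp GBS
tag sequences. Calls use IUPAC codes: homozygotes are nucleotides,
heterozygotes the two-base ambiguity codes (M, R, W, S, Y, K), missing is
`NA`. After coding against the assigned parental alleles, each F2 genotype
is `a` (*SS*), `h` (*SC*) or `b` (*CC*); under Mendelian segregation these
occur 1 : 2 : 1.

Founder alleles are assigned by panel consensus: with the default panel of
four individuals, a nucleotide seen in ≥ 3 of 4 calls wins (missing calls
and heterozygote codes count against; a 2–2 split is `NA` with no
tie-breaking). The same 3-of-4 rule confirms the F1 heterozygote code. For
non-default panel sizes the threshold generalizes to ⌈3n/4⌉. When exactly
one parental consensus is `NA`, the missing allele is inferred from the F1
heterozygote code when that code contains the assigned allele; markers whose
allele pair cannot be completed fall under the no-parental-assignment
discard, since coding requires both alleles. F1 confirmation is otherwise
advisory (a flag; `require_f1` upgrades it to a discard), because the
screening protocol defines exactly three discard rules: no parental
assignment, identical parental genotypes, and uninformativeness (a single
genotype class across the cohort), followed by the distortion filter.

The distortion filter computes Pearson χ² of the (a, h, b) counts against
(n/4, n/2, n/4) and discards markers with χ² > 50. Missing calls are
excluded from n — the alternative (counting them) is ill-defined — and F2
calls inconsistent with both assigned alleles are coded missing and
counted in the QC report. Under clean segregation at n = 170 this filter's
false-discard rate is ~χ²₂ tail mass beyond 50, i.e. ~10⁻¹¹; the acceptance
suite measures it empirically over 10,000 simulated markers.

## Two-point statistics and the map

**Recombination fractions.** For a codominant marker pair in coupling phase
the nine joint genotype probabilities are polynomials in r; every cell has a
known recombinant-gamete count except the double heterozygote, which mixes
the parental-type and recombinant-type gamete pairs with weights
q²/(p² + q²) and p²/(p² + q²) (p = r, q = 1 − r). EM iterates
r ← (n₁ + 2n₂ + 2n_hh·p²/(p²+q²)) / 2N from r₀ = 0.25 until |Δr| < 1e−8 or
200 iterations, clipped to [0, 0.5]. Estimates match a 1e−4 likelihood grid
search to 1e−3 (tested over random tables). The linkage LOD is
log₁₀ L(r̂) − log₁₀ L(0.5); the grouping statistic is the independence LOD
G²/(2 ln 10) from the 3×3 contingency test, which stays calibrated under
segregation distortion (the likelihood model assumes 1:2:1 margins; the
independence test does not).

**Grouping.** Single-linkage connected components at an integer threshold
ladder 1..50. The working threshold is chosen from the ladder's most stable
plateau: the number of components with ≥ `min_group_size` markers rises as
fused chromosomes separate, sits on a long plateau at the true chromosome
number, and rises again when chains fragment at very high thresholds; the
longest constant-count run (ties → higher count, then lower threshold)
identifies the plateau, and zero-count runs are ignored. On the default
simulation the plateau spans LOD ≈ 7–44 at exactly 25 groups, consistent
with grouping thresholds in the 7–21 range being adequate for this design.

**Ordering.** Incremental insertion: seed with the highest-linkage-LOD pair,
then repeatedly insert the unplaced marker with the strongest linkage to the
current order at the slot minimizing Σ w_ij (d_ij(order) − d(r̂_ij))², with
w_ij = linkage LOD and candidate positions from cumulative adjacent Kosambi
distances. A sliding-window polish (all permutations of width-3 windows)
accepts improvements after each insertion and again at the end. Final
positions re-fit all pairwise Kosambi distances with r̂ < 0.4 by
nonnegative weighted least squares on the inter-marker gaps. Orientation of
a group is arbitrary; it is canonicalized with the lexicographically smaller
terminal marker first. Tie-breaks are everywhere lexicographic in marker id,
making the whole construction deterministic.

**Protocol.** `build_map` runs a configurable number of rounds (default 3):
order groups; drop groups that are too small (< 10 markers) or too sparse
(mean gap > 4 cM); split unusually large groups — candidates must have at
least twice the round's minimum part size (20, then 10) *and* at least 1.5×
the median group size, the latter guard keeping clean single chromosomes,
which can fragment into two valid halves at some ladder threshold, from
being split; splitting picks the lowest ladder threshold producing exactly
two parts above the minimum size; finally trim distal markers whose terminal
gap exceeds max(10 cM, 3× the group's mean gap), re-ordering what changed.
Every elimination is recorded in an audit log, and placed + eliminated =
input markers.

**Known bias.** The simulator (below) recombines each inter-marker interval
independently, with per-interval r from the Kosambi inverse. Under interval
independence the composite recombination fraction over several intervals
follows the Haldane-style composition r₁₃ = r₁₂ + r₂₃ − 2r₁₂r₂₃, which is
smaller than the Kosambi composition; converting long-pair r̂ through the
Kosambi function therefore underestimates long distances, and the
least-squares fit mixes these with adjacent distances. The net effect on the
default simulation is a map ~15–20% shorter than the generating truth (the
recovery criterion allows 25%), with genotyping error pushing mildly in the
other direction. Adjacent-interval distances are unbiased, and marker order
is unaffected.

## QTL scans

Genotype probabilities come from a forward–backward pass over a
three-state Markov chain per linkage group, with transition matrices built
from the Kosambi inverse of inter-position distances (per-interval
independence, i.e. no crossover interference between evaluation intervals)
and an emission error ε (correct class 1 − ε, each other class ε/2; missing
calls emit uniformly). Defaults: 1 cM grid step, ε = 0.001.

The binary phenotype (0 = pigmented, 1 = albino) is analyzed under the
Gaussian working model, matching the standard scan of a 0/1-coded trait —
this choice reproduces the ~20-LOD scale such scans report for a Mendelian
trait, whereas a logistic variant is out of scope. MR regresses the
phenotype on genotype class at typed markers only, dropping
missing-genotype individuals; HK regresses on P(SC) and P(CC) at every grid
position; both use LOD = (n/2) log₁₀(RSS₀/RSS₁). EM maximizes a
three-component Gaussian mixture with per-individual class weights from the
grid, initialized from the HK fit, common variance, stopping at Δ log L <
1e−6 or 100 iterations. With complete-data indicator probabilities HK is
algebraically identical to MR (verified to 1e−9), and EM short-circuits to
HK at positions of complete certainty to avoid degenerate mixtures. Two
floors guard the degenerate perfect-fit case a fully penetrant trait
creates: RSS is floored at 1e−12 and the mixture variance at 1e−4 (on the
0/1 phenotype scale), capping rather than overflowing the LOD; thresholds
and scans share the floors, so comparisons remain internally consistent.

Permutation thresholds permute phenotype labels (seeded), record the
genome-wide maximum LOD per permutation per method, and return empirical
(1 − α) quantiles (the `higher` order statistic); requesting α below 1/n_perm
is an error. The permutation scans are vectorized across permutations
(QR projections for MR/HK; a batched EM with per-permutation convergence
masking).

## Synteny resolution

Tabular 12-column alignments are filtered at e-value ≤ 10, then collapsed to
one hit per marker–target pairing by lowest e-value; since both allele
variants of a tag share the marker id, this also collapses the allele pair.
Tie-breaks beyond e-value are: higher identity, longer alignment, then
lexicographic target position — additions for determinism. Resolution is
two-pass and order-independent: markers with exactly one collapsed hit are
"single robust" and their targets form each linkage group's support set
("support" means target identity, not positional proximity); multi-hit
markers then retain their top hit (lowest e-value, identity breaking ties)
if supported or if nothing is supported, a supported non-top hit otherwise,
and are discarded as unresolved only when the top hit is undeterminable
(e-value and identity tied across targets) and no support exists. Per-route
results are combined by re-running the same resolution on the ≤ 3 per-route
retained candidates, with route priority genomic > transcriptomic > direct
as the final tie-break. Genomic flanks are ~2000-bp windows centered on the
64-bp tag, clipped at scaffold ends while preserving width. The resolver is
verified against an exhaustively enumerated decision table over all ≤ 3-hit
× ≤ 2-support configurations.

Per-chromosome statistics report link counts, represented linkage groups
(flagging groups carrying ≥ 5 links), links/Mb, and a pooled-variance
two-sample t test of links/Mb between chromosomes with and without a
≥ 10-link concentration on a single group; outputs include an Oxford count
matrix and a Circos-format link file.

## Scaffold anchoring

Scaffolds are assigned the modal linkage group of their mapped markers (a
tie is ambiguous and counts as non-colocalized). The headline
colocalization percentage uses scaffolds with ≥ 2 mapped markers as the
denominator — singletons are trivially colocalized and would inflate the
statistic — but the all-scaffold variant is also reported since either
convention is defensible. Colinearity is tie-adjusted Kendall τ between
scaffold bp and map cM positions of the modal group's markers; orientation
is the sign of τ. Figure-style output restricts to scaffolds with ≥ 4
mapped markers. Map comparisons report integer-percent ratios
100·(new/old) per metric, with zero denominators flagged rather than
computed.

## The synthetic-data generator

`simcross` emulates: 25 chromosomes of 84 cM with evenly spaced markers
(40/chromosome by default — a ~2100 cM genome at ~0.5 marker/cM); founder
panels of 4 fixed for alternate alleles; heterozygous F1s; 170 F2
individuals produced by independent meioses through the Markov model above;
symmetric call-swap genotyping error (default 0.5%) followed by independent
missingness (default 2%) — the study's real error rates are unpublished, so
these are free parameters set to values typical of filtered GBS matrices;
planted QC artifacts at configurable fractions (scrambled founder panels,
monomorphic cohorts, segregation distortion by resampling with the *CC*
class down-weighted by 1 − s); chromosomes tiled by 5-Mb scaffolds at
550 kb/cM with random planted orientations; and a fully penetrant monogenic
recessive trait (albinism is Mendelian recessive in the emulated system) at
a configurable locus simulated as a latent position in the meiosis chain.
Alignment-hit tables place a conserved fraction of markers on a fictitious
25-chromosome target genome with known truth, plus 1–2 higher-e-value
paralog decoys per affected marker (≤ 3 targets/query); a fraction of
decoys are "strong" paralogs that outrank the true hit, the failure mode the
support logic corrects. All randomness flows from a single seed; identical
seeds give byte-identical outputs.

What passing tests show — and what they do not: the generator matches the
analysis's own assumptions (no crossover interference beyond the
per-interval Kosambi parameterization, independent errors, evenly spaced
markers, no linked paralog tags, no allele-specific dropout). Recovery
results therefore validate internal correctness and calibration, not
robustness to real GBS pathologies such as restriction-site polymorphism,
depth-dependent heterozygote undercalling, or reference bias.

## Validation experiment sizes

The acceptance experiments use: 1,000 random 9-cell tables for the EM/grid
comparison; the full default simulation (25 × 40 markers, n = 170) for
parameter recovery; a 3-chromosome × 15-marker genome (n = 170,
markers-only grid) with 1,000-permutation thresholds at α = 0.001 for the
100-replicate power experiment; and ten default simulations (10,000
markers) for the null-filter calibration. These sizes keep the whole
validation run to a few minutes on one CPU while leaving each check's
binomial uncertainty well inside its margin.
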