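# Methods

This note records the statistical models hapgeo implements, the estimator
variants and numerical choices behind them, what the bundled synthetic data
does and does not emulate, and the known limitations. It documents the code;
every number quoted here is one the test suite or `scripts/acceptance.py`
computes.

## Haplotype definition and distances

Sequences are collapsed into haplotypes after removing, alignment-wide, every
column that contains a gap (`-`, `.`, `?`), an `N`, or (by default) any IUPAC
ambiguity code in *any* record — the same substitution-only convention DnaSP
uses. Two sequences share a haplotype iff they are identical at all retained
columns; haplotypes are labelled `H1, H2, …` in order of first appearance, so
labels depend on input order while the partition itself does not (a property
test asserts this). The inter-haplotype distance *d<sub>ij</sub>* is the
Hamming distance of representatives over retained columns: a true metric,
bounded by the segregating-site count, which is what the downstream AMOVA,
N<sub>ST</sub>, mismatch and network machinery assume. A
`pairwise_complete` policy is available (all columns kept, per-pair distances
skip sites with missing data in either sequence); it is honest about indel-rich
loci but forfeits the metric guarantee and is not the default.

With this column-exclusion rule the ITS fixture's two indel columns vanish
before ribotype definition, which is why a 604–606 bp locus still yields
ribotypes defined purely by 4 substitutions.

## Diversity estimators

Per sampling unit with counts *c<sub>i</sub>*, *n* = Σ*c<sub>i</sub>*,
*p<sub>i</sub>* = *c<sub>i</sub>*/*n*:

- gene diversity *h* = *n*/(*n*−1)·(1 − Σ*p<sub>i</sub>*²); its SD from
  Nei's (1987) sampling variance
  V(*h*) = 2/(*n*(*n*−1))·{2(*n*−2)(Σ*p*³ − (Σ*p*²)²) + Σ*p*² − (Σ*p*²)²}.
- nucleotide diversity *π* = *n*/(*n*−1)·Σ<sub>i≠j</sub>
  *p<sub>i</sub>p<sub>j</sub>d<sub>ij</sub>*/*L*, equal to the mean pairwise
  difference per site over all sequence pairs (a brute-force oracle test
  checks the identity); its SD uses the no-recombination approximation
  V(*π*) = (*n*+1)/(3(*n*−1)*L*)·*π* + 2(*n*²+*n*+3)/(9*n*(*n*−1))·*π*².

SDs are reported but deliberately not treated as precision guarantees; the
no-recombination variance is an upper-bound-flavoured approximation.

## Differentiation (PERMUT-style)

H<sub>S</sub> is the **unweighted** mean over populations of the unbiased
per-population gene diversity (sample-size weighting is an option,
`weighted_hs=True`). H<sub>T</sub> is computed two ways and both are
reported: the Nei–Chesser-corrected estimator
1 − Σ p̄<sub>i</sub>² + H<sub>S</sub>/(ñ·s) from unweighted mean frequencies
p̄ and the harmonic mean sample size ñ (default, used in G<sub>ST</sub>),
and the uncorrected plugin 1 − Σ p̄<sub>i</sub>². v<sub>S</sub>,
v<sub>T</sub>, N<sub>ST</sub> are the same constructions with every frequency
cross-product weighted by *d<sub>ij</sub>*, so when all off-diagonal
distances are equal N<sub>ST</sub> reduces to G<sub>ST</sub> *exactly* — an
identity the suite asserts at 1e−12, as it does G<sub>ST</sub> ≡ 1 −
H<sub>S</sub>/H<sub>T</sub>.

Two honest caveats, both visible in the tests rather than hidden: (i) with
unbiased H<sub>S</sub> and few, identical populations G<sub>ST</sub> can be
slightly negative at finite n (it vanishes from below as samples grow — the
suite checks this at n = 500 per population); (ii) the exact H<sub>T</sub> a
given PERMUT build prints is estimator-variant-sensitive, which is why this
package pins H<sub>S</sub> (0.049 cpDNA / 0.142 ITS on the fixture) but
reports both H<sub>T</sub> variants without asserting a published value.

The N<sub>ST</sub> > G<sub>ST</sub> test permutes haplotype identities by
random simultaneous row/column relabelling of *d<sub>ij</sub>* (B = 1000 by
default, seedable), with one-sided p = (1 + #{Δ<sub>perm</sub> ≥
Δ<sub>obs</sub>})/(B+1). Note the test's resolution is limited by the
automorphism group of the distance matrix: with very few haplotypes many
relabellings leave *d* invariant and p cannot fall below the invariant
fraction. This is a property of the test itself, not an implementation limit.

## AMOVA

Squared molecular distance between individuals is the substitution count
between their haplotypes. Sums of squares use the pairwise identity
SS(set) = Σ<sub>x<y</sub> δ²<sub>xy</sub>/|set|; variance components come
from the nested moments equations with the standard unequal-sample-size
coefficients; Φ statistics are ratios of components. The implementation is
validated to 1e−9 against an exact-rational (Fraction) oracle that evaluates
the same moments equations from literal double loops. Degenerate inputs
(zero total variance, singleton groups) yield flagged NaNs instead of
exceptions. Permutation schemes follow the Arlequin conventions per
statistic — Φ<sub>ST</sub>: individuals among populations; Φ<sub>SC</sub>:
individuals among populations within groups; Φ<sub>CT</sub>: whole
populations among groups — each with the +1 p-value convention.

## SAMOVA

The K-group search initialises geographically: K seed populations drawn at
random, every other population joining its nearest seed by great-circle
distance (haversine, R = 6371 km). Simulated annealing then proposes moving
one population to another group (donor must stay non-empty), accepting by the
Metropolis rule on ΔΦ<sub>CT</sub>; the initial temperature is set from the
median |ΔΦ<sub>CT</sub>| of a pilot sample of proposals (so roughly half of
early proposals accept) and cools geometrically (0.95 every 100 proposals).
Defaults are 100 restarts × 10,000 proposals — far more than small problems
need; the suite shows 6 restarts × 400 proposals already match exhaustive
bipartition search on 6-population instances 20/20. Contiguity is encouraged
by the initialisation but not enforced during search. K = P short-circuits
to the every-population-its-own-group partition, whose Φ<sub>CT</sub> equals
the ungrouped Φ<sub>ST</sub> (asserted). K is selected by a plateau rule:
the smallest K whose Φ<sub>CT</sub> is within 1% (configurable) of the
running maximum over all larger K; a strictly rising trajectory returns the
largest K with a warning.

## Isolation by distance

The Mantel statistic is the Pearson correlation of upper-triangle entries,
with simultaneous row/column permutations of one matrix and a one-sided
(r > 0) +1-convention p-value; a two-sided option exists. Population-level
genetic distance defaults to linearized pairwise Φ<sub>ST</sub>/(1 −
Φ<sub>ST</sub>) (Slatkin), with plain Φ<sub>ST</sub> as an option — fixed
population pairs have Φ<sub>ST</sub> = 1 and linearize to +inf, so with many
fixed populations the plain variant is the usable one. The statistic is
cross-checked against scikit-bio's mantel in the suite.

## Mismatch distribution and sudden expansion

The observed histogram is exact pair counting from haplotype counts and
distances. The sudden-expansion model: a population at equilibrium θ₀ jumps
to θ₁ at mutational time τ before present; writing
F̂<sub>j</sub>(θ) = θ<sup>j</sup>/(1+θ)<sup>j+1</sup>, the class
probabilities are

F<sub>j</sub>(τ, θ₀, θ₁) = F̂<sub>j</sub>(θ₁) + e^(−τ(θ₁+1)/θ₁) ·
Σ<sub>i≤j</sub> (τ<sup>i</sup>/i!)·[F̂<sub>j−i</sub>(θ₀) − F̂<sub>j−i</sub>(θ₁)]

(the pair-coalescence integral: pairs coalescing since the expansion sit at
the θ₁ equilibrium; survivors carry Poisson(τ) extra differences over the θ₀
equilibrium). The τ-kernel is evaluated in log space; probabilities sum to 1
within 1e−6 at sufficient truncation (asserted). Fitting minimises
SSD = Σ(obs − exp)² over observed classes with a coarse grid refined by
Nelder–Mead; the box is τ ∈ [0, 2·max class], θ₀, θ₁ ∈ [0, 10⁴], with 10⁴
operationally "infinite" (SSD is flat in θ₁ beyond that, and an unbounded θ₁
would make the parametric bootstrap simulate absurdly diverse samples). A
θ₁-profiled two-parameter fit (`theta1_infinite=True`) reproduces the
classical form. Degenerate one-class histograms return τ = 0, flagged.

Raggedness uses the padded convention r = Σ<sub>i=0</sub><sup>d+1</sup>
(F<sub>i</sub> − F<sub>i−1</sub>)² with F<sub>−1</sub> = F<sub>d+1</sub> = 0,
i.e. the rise into class 0 and the fall after the last class both count; the
two-class example r([½, ½]) = ½ pins the convention.

Goodness-of-fit p-values are parametric-bootstrap: B coalescent simulations
under the fitted (τ, θ₀, θ₁), each refitted, p = (1 + #{stat ≥ obs})/(B+1).

## Neutrality tests

Tajima's D uses the standard a₁…e₂ coefficient chain (checked against an
independently written textbook implementation at 1e−12) with the
beta-distribution approximation for p (D rescaled to [D<sub>min</sub>,
D<sub>max</sub>]); on neutral coalescent data the nominal 5% level rejects at
≈4% (n = 25; the approximation grows conservative for larger n — calibration
asserted in the suite at bounds 2–9%).

Fu's Fs computes S′ = P(K ≥ k₀ | θ<sub>π</sub>, n) exactly from the Ewens
sampling distribution using a log-space recursion for unsigned Stirling
numbers of the first kind (validated against exact rational arithmetic;
Fs(5, 2, θ=1) = ln 4), then Fs = ln(S′/(1−S′)); S′ underflow/overflow is
flagged as ±inf. The simulation p-value regenerates neutral samples at
θ<sub>π</sub> and counts Fs ≤ observed. Following Fu (1997), "significant at
5%" corresponds to p ≤ 0.02 — the calibration test confirms that convention
rejects ≈5% of neutral replicates, while naively thresholding at p ≤ 0.05
would reject ≈10%.

## Expansion dating and strict clock

t = τ/(2u) with u = μ·k·g (μ substitution rate per site per year, k aligned
length in bp, g generation time in years) is reported both in generations
(the formula's natural unit) and in years (×g), since mixing the two is an
easy way to mis-state the date by a factor of g. The strict-clock helper
dates a split as T = d<sub>net</sub>/(2μ) from the net between-group distance
d<sub>net</sub> = d̄<sub>between</sub> − (d̄<sub>within,1</sub> +
d̄<sub>within,2</sub>)/2 per site; negative net distances clamp to zero with
a warning. This is a closed-form point estimate only — no rate priors, no
uncertainty intervals.

## Haplotype network

Kruskal MST with lexicographic tie-breaking, plus every non-tree edge whose
weight ties the bottleneck (maximum edge) on the MST path between its
endpoints — the ε = 0 minimum spanning network. Median (Steiner) vectors are
deliberately not inferred: for ≤10 observed haplotypes the MSN conveys the
same relationships without introducing an unconstrained ε parameter. MST
total weight is validated against exhaustive spanning-tree enumeration.

## Synthetic data

Two generators, with different jobs:

**Fixture** (`make_study_fixture`): a deterministic dataset with the exact
published shape — per-population haplotype/ribotype counts, coordinates
(parsed from printed degree/minute/second strings, including two entries
whose seconds field overflows 60 and is converted arithmetically with a
warning), 1531 bp / 7 segregating sites / 6 haplotypes, 606 columns / 4
substitution sites + 2 indel columns / 6 ribotypes. The haplotype
*sequences* are a constructed stand-in, since none are published: site
patterns make H3–H6 a one-step pair at least two steps from everything else,
H1 two steps from the widespread H2 (which pins the one published
per-population π that is sensitive to a single distance), and R2 the most
divergent ribotype. Counts, coordinates and everything derived from counts
alone (h, H<sub>S</sub>, occupancy) are exact reproductions; anything
touching *d<sub>ij</sub>* (π totals, N<sub>ST</sub>, AMOVA percentages, τ,
Mantel r) is fixture-conditional. Binary site patterns also impose parity
constraints (d(H5,H4) must have the parity of d(H5,H2)+d(H2,H4)), so some
printed π values are unreachable by any integer-distance construction; the
fixture gets within rounding of the reachable ones. On this fixture the
K = 4 SAMOVA isolates ML and pairs DD-1/DD-2 with ≈94% of variance among
groups, and the cpDNA Mantel p sits at ≈0.056 — both consistent with the
qualitative published pattern, neither a pinned reproduction. The ITS
stand-in, by contrast, does show a spatial correlation (its most divergent
ribotype happens to sit in the geographic southeast), a reminder that
distance-dependent results on constructed sequences are illustrations, not
evidence.

**Simulator** (`simulate_dataset`, `simulate_sudden_expansion`): a minimal
structured coalescent — Kingman within demes, island-model migration
(per-lineage rate, uniformly chosen destination), piecewise-constant size,
infinite-sites mutations at rate θ/2 per lineage per unit of 2N<sub>present</sub>
generations, so E[pairwise diff] = θ and E[S] = θ·a₁ (both asserted). The
sudden-expansion variant places the size change at scaled time τ/θ₁. It is
cross-checked against msprime on E[S] and mean pairwise diversity. What it
does **not** emulate about real data: recombination (none — appropriate for
organelle loci, optimistic for ITS), selection, sequencing error, indel
evolution, or uneven per-population sampling designs beyond what the caller
specifies. Calibration tests passing on these simulations therefore certify
the statistics under the model assumed by the methods, not robustness to
violations of it.

Problem sizes in the suite are chosen to exercise the asymptotics the claims
need while staying exhaustive where exhaustiveness is the oracle: AMOVA
oracle instances ≤20 individuals, SAMOVA exhaustive checks at 6 populations,
τ-recovery at n = 200 sequences × 51 replicates (median relative error ≤
25%), neutrality calibration at 500 replicates of n = 25, super-uniformity
checks at 200–300 datasets × 99 permutations.

## Known limitations

- Haplotype-level resolution only: within-haplotype sequence variation at
  excluded columns is invisible by design.
- The Nei–Chesser H<sub>T</sub> correction does not reproduce every
  historical PERMUT build's printed totals; both variants are exposed.
- The beta approximation for Tajima's D is conservative for large n; a
  simulation p-value is available via the same machinery as Fu's Fs if exact
  calibration matters.
- SAMOVA does not enforce group contiguity during search and, like the
  original, can return supported but non-contiguous optima.
- The spatial (range) expansion mismatch model is not implemented; only the
  demographic (stepwise) model is. The two can fit similar histograms, so
  "expansion" here always means the sudden-growth model.
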