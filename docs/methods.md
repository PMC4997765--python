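# Methods

This note documents the models and procedures implemented in `pedimpute`,
the numerical and design choices that were genuinely open, what the
synthetic-data generator does and does not emulate, and the known
limitations.

## Pedigree model and descent machinery

A pedigree of `n` members with `f` founders defines `m = 2(n − f)`
meioses. Each individual carries two allele *slots* (paternal, maternal);
the *inheritance vector* (IV) at a locus holds one bit per meiosis: 0 when
the parent transmitted its own paternally inherited copy, 1 for the
maternal one. Conditional on an IV, every slot maps deterministically to
one of the `2f` *founder genes* (the descent partition), computed by a
single topological pass (`descent.build_descent`).

Both-parents-or-none is enforced — a half-specified parent would silently
change `m` and the likelihood, so it is an error. Inbred pedigrees are
rejected (kinship of every mating pair is checked at construction); loop
handling is out of scope. Sex is carried through I/O but unused: the
machinery covers autosomes only.

### Single-locus likelihood

Given a descent partition, observed unphased dosages constrain founder
genes: a homozygote forces both of its genes to one allele; a heterozygote
imposes an exclusive-or between its two genes. The likelihood
`Σ_assignments Π_genes freq · Π_individuals 1[consistent]` is therefore
computed exactly with a parity-carrying union–find over founder genes:
each connected component retains the prior weights of its (at most two)
consistent colorings, forced components collapse to one branch, and the
likelihood is the product of component weight sums. This is linear in the
number of observations rather than exponential in the number of genes, and
is verified in the tests against the explicit `2^G` sum. Framework
genotypes are treated as error-free by this likelihood; Mendelian
pre-screening (`pedio.mendelian_errors`) is the documented remedy for
inconsistent data.

### IV chain along a chromosome

Adjacent markers at genetic distance `d` cM recombine with the Haldane
fraction `θ = (1 − e^(−2d/100))/2` (no interference), and the `m` meioses
are independent, so the IV transition kernel factorizes as
`θ^k (1 − θ)^(m−k)` over `k` flipped bits. When no empirical genetic map
is supplied, a constant 1 cM/Mb map is used (the conventional mammalian
average; configurable).

For `m ≤ m_max` (default 16) the posterior over IVs given framework
genotypes is computed exactly by forward–backward over the `2^m` states,
applying the transition kernel as an `m`-fold Kronecker product in
`O(m 2^m)` per step; joint samples come from backward sampling.

### MCMC sampler

Larger pedigrees use a Gibbs sampler whose basic move resamples one
meiosis' entire bit path from its conditional two-state HMM (all other
meioses fixed). Two further moves proved necessary for correctness, not
merely speed:

* **Meiosis-pair path updates** (4-state forward–backward over a random
  pair). Constraints such as opposite homozygous siblings couple two
  meioses so tightly that no single-meiosis move has positive probability;
  the pure single-meiosis sampler is reducible and froze on a quartet.
* **Founder-phase flips.** Swapping a founder's two (exchangeable) gene
  labels flips whole meiosis rows at every locus simultaneously and leaves
  both likelihood and chain prior invariant. Locus-local moves cross
  between these symmetry modes only through paths of probability `~θ^m`,
  so without explicit flips the chain samples a single phase orbit and
  per-state marginals are off by up to total variation 0.5. The flip is
  proposed for each founder every sweep and always accepted.

For pedigrees with `m ≤ 8` an exact locus-wise joint update over all `2^m`
states is interleaved as well, which makes the sampler irreducible
outright; the test battery verifies total-variation agreement (< 0.02)
with the exact posterior on pedigrees up to `m = 6`.

The starting configuration is found per locus: random IVs are
rejection-sampled against the locus likelihood, with a bounded greedy
bit-flip repair as fallback (joint rejection over hundreds of markers has
vanishing acceptance probability). Defaults: 1000 retained samples after
1000 burn-in sweeps, thinning 5; all exposed in configuration, since the
appropriate values depend on panel density and pedigree size.

## Dense imputation

At a dense position, each meiosis' bit is interpolated from the flanking
framework markers:
`P(b | b_left, b_right) ∝ P(b_left → b) · P(b → b_right)` with Haldane
transitions (single-interval transition outside the framework span). For
every retained framework IV realization, `k_dense` (default 1) dense IVs
are drawn per meiosis, the descent partition is built, and founder-gene
alleles are conditioned on the observed donor genotypes with the same
union–find machinery; unconstrained genes follow Bernoulli(allele
frequency) priors. Each realization contributes with weight equal to the
likelihood of the donor genotypes under it (realizations that contradict
the donors get weight zero; sites contradicted by *every* realization are
counted and skipped, since real data contain caller errors). This
likelihood weighting is what makes the estimator agree with the full
joint-likelihood brute force on small instances to 1e−9; an exact
enumeration mode over dense IVs exists for such verification.

### Calling

* **Most likely:** argmax of P(RR), P(RA), P(AA); ties resolve toward the
  genotype carrying the population-major allele, then lexicographically.
  Always emits a full genotype.
* **Threshold (default strict preset):** a full genotype is called when
  its posterior reaches `t_both = 0.99`; otherwise a single allele `a` is
  called when the probability that the unordered genotype *contains* `a`
  reaches `t_single = 0.98` (reported as a half-call). The relaxed preset
  lowers `t_both` to 0.95. The containment formulation matters: a rule on
  the two phased slots is not invariant under the arbitrary phase labeling
  of founder haplotypes — the exact posterior for a founder target is
  slot-symmetric, and a slot-based rule suppresses all of its half-calls —
  whereas P(genotype contains a) = P(RA) + P(aa) is a well-defined
  observable. Lowering thresholds never removes a call.

## Selecting individuals for sequencing

The coverage of a donor set `S` is the expected fraction of allele copies
in the pedigree identical by descent with a copy carried by `S`, at a
single unlinked locus ("genome-wide mode": only the pedigree enters). Two
metrics are provided:

* **descent** (default for `expected_coverage`): a slot is covered when
  its founder gene is carried by a selected individual. Exact enumeration
  over all `2^m` IVs when feasible, Monte-Carlo gene drops otherwise. For
  a trio this gives the closed values 2/3 for the child and 1/2 for a
  parent.
* **genotype** (default for the greedy ranking): additionally requires the
  allele to be *determined* by the donors' unordered genotypes —
  homozygous donors force both their genes, and a heterozygous donor
  resolves one gene only once the other is forced; allele frequency is
  integrated uniformly over (0.05, 0.95). This refinement is what the
  downstream called fraction actually tracks: the descent metric prefers
  deep, unphasable donors whose nominal coverage does not convert into
  calls.

The greedy ranking adds at each step the candidate maximizing coverage of
the augmented set, with common random numbers across evaluations and ties
broken by id; a candidate subset (e.g. the animals for which sequencing is
on the table) can be imposed. The two comparison heuristics are
founders-only (ranked by descendant count) and most-recent-generation
(childless members ranked by ancestor count), both honoring the same
candidate restriction.

## GBS panel design

`digest` scans IUPAC motifs case-insensitively with overlapping matches
(sequence `N` never matches); palindromic motifs are scanned on the
forward strand only, non-palindromic ones on both strands with positions
merged. The cut position is motif start + top-strand cut offset — for
fragment counting the offset is immaterial but must be consistent. A
contig with `k` internal cuts yields `k + 1` fragments tiling it exactly
(terminal fragments retained). Size selection keeps 200–500 bp inclusive;
repeat filtering uses the soft-masked (lowercase) fraction with a default
threshold of 0.5, since no numeric repeat criterion is standard. Enzymes
are ranked toward a 60,000–100,000 target window of usable fragments,
preferring more captured base pairs inside the window and proximity to it
outside.

`panel` builds framework panels deterministically: callable in at least
50 % of individuals at ≥ 20× site depth ("majority of libraries" is
implemented as the same 50 % threshold, the natural reading when no number
is given), sample MAF strictly above 0.25, strict GBS/WGS concordance
(any single discordant genotype rejects by default; a rate-based option
exists), then greedy left-to-right spacing anchored at the leftmost
candidate. Dense markers are spacing-selected from the WGS site pool
excluding framework positions. Allele-frequency estimation counts alleles
over non-missing calls with an optional pseudo-count clamp to
`[1/(2N+2), 1 − 1/(2N+2)]` for proper priors.

## The synthetic-data generator

The generator defines the study conditions the experiments run under.

* **Pedigree:** a fixed 16-member, two-offspring-generation colony
  pedigree (ids A–P, six founders A–E and O). Only structural constraints
  are documented for the real family, so the shipped topology is one
  consistent instantiation: it contains parent/offspring, half-sibling,
  half-avuncular, half-cousin and grandparent/grandchild pairs and no full
  siblings (harem-style matings); K is a child of D; M, P and K are
  childless; founder E is related only to members outside the
  WGS-designated nine (B, H, J, F, M, K, P, C, D), making it the lone
  founder without sequenced kin; B's lineage is central while C and D are
  peripheral founders. Alternative instantiations satisfying only the
  structural constraints can invert the donor-strategy ordering, so the
  shipped one was additionally required to reproduce the documented
  qualitative behaviors (central most-informative founder, poorly imputed
  D and E).
* **Gene dropping:** founder alleles are independent Bernoulli draws at
  the stated frequencies (linkage equilibrium among founders — the same
  assumption the imputation model makes), transmission is a Markov
  crossover process over adjacent markers with Haldane fractions (no
  interference, matching the inference HMM), and true IVs are recorded.
  Everything is bit-reproducible given the seed.
* **Sequencing observation:** per cell, depth ~ Poisson(λ), alt reads ~
  Binomial(depth, μ) with μ = ε, 0.5, 1 − ε for 0/1/2 true copies; the
  call is the flat-prior argmax of the three binomial likelihoods with
  GQ = round(−10·log10(1 − posterior)) capped at 99, and cells with
  depth < 10 or GQ < 20 become missing. The flat (frequency-naive) prior
  keeps population information out of calling so that it enters only
  through imputation.
* **GBS sparsity:** per-cell random missingness at a 69 % call rate
  emulates the observed per-site callability of the sparse assay.
* **Scenario defaults** mirror the chromosome-scale test case: 833
  framework markers at ~65 kb spacing (MAF drawn uniformly above 0.25)
  and 5,010 dense markers at ~10 kb on one ~54 Mb chromosome at 1 cM/Mb.
  Dense minor-allele frequencies follow a neutral-like 1/x spectrum with
  floor 1/30 (the singleton frequency of the reference panel), and dense
  sites are *ascertained*: only sites whose alt allele segregates among
  the nine WGS-designated members exist, since undiscovered sites cannot
  be imputation targets. Imputation priors are raw frequency estimates
  from a simulated external reference of 15 unrelated individuals (30
  chromosomes; also the rare-variant singleton panel), clipped to
  [1e−4, 1 − 1e−4]: small-panel tables with near-zero entries are exactly
  what a preliminary colony resource provides, and they are responsible
  for the characteristic behavior of members unrelated to any donor
  (many confident reference-allele calls, slightly lower accuracy).
* **Not emulated:** read-level artifacts (alignment, site-level filters,
  allelic dropout from restriction-site polymorphism), genotyping error
  inside the imputation likelihood, crossover interference, X chromosome,
  indels and multi-allelic sites. Passing tests therefore demonstrate
  correctness of the descent/imputation machinery and the qualitative
  experimental structure, not robustness to those real-data pathologies.

## Evaluation

Accuracy is allele-level: a 2-allele call against truth contributes the
multiset intersection (so RA against true AA counts 1 correct of 2
attempted), a half-call is correct when its allele occurs in the true
pair; attempted counts only cells with truth. Three "how much was
imputed" figures are reported per individual: fraction of markers with at
least one allele called, fraction of allele copies called (the headline
figure — it is the quantity the coverage statistic predicts, and the only
one of the three that is informative under the strict thresholds, where
≥1-allele saturates and full-genotype calls are rare), and fraction of
full genotype calls. The median across individuals is the summary
statistic. Frequency stratification assigns every true allele copy to the
half-open bins [0, 0.25), [0.25, 0.5), [0.5, 0.75), [0.75, 1], with
reference singletons reported as a separate rare row.

The three experiment drivers share simulated truth and inferred IVs
within a replicate, so strategy and donor-count comparisons are paired.
In the donor-number sweep, monotonicity should be judged on the fixed set
of never-donor individuals: the "remaining members" pool shrinks as
donors are added, and removing an above-median recipient produces
composition dips unrelated to information content.

## Numerical choices and degenerate inputs

* Genotype posteriors are renormalized per site; normalization error is
  bounded by 1e−9 in tests.
* θ = 0 (coincident genetic positions) is handled exactly by the HMM; the
  simulator then never recombines between the markers.
* Zero-likelihood framework data raise a Mendelian-inconsistency error at
  IV inference; zero-likelihood dense sites are skipped and counted.
* Exact ties in calling resolve toward the population-major allele, then
  lexicographically (RR < RA < AA).
* Sampler scale choices in the shipped experiment configurations (e.g.
  300 burn-in sweeps, thinning 1 for the chromosome-scale scenario; 0.3×
  marker counts for replicated sweeps) reflect the mixing behavior of the
  path-resampling moves, which equilibrate in tens of sweeps on these
  panel densities.

## Known limitations

* Exact IV inference is exponential in meioses (`m_max` guard); the MCMC
  sampler's pair moves handle two-meiosis couplings but constraints
  coupling three or more meioses on large pedigrees could still mix
  slowly.
* No founder-phase symmetry reduction in the exact engine (correctness
  first); it costs a factor ≤ 2^f in state space.
* The coverage metric conditions on fixed IVs; with IVs *inferred* from a
  sparse panel, realized called fractions fall below the metric,
  uniformly enough that rankings are preserved.
* Skipped (donor-contradicted) sites grow with donor count because a
  finite IV sample must satisfy more constraints; with 1,000 realizations
  this affects well under 1 % of sites at four donors.
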