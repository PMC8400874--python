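# Methods

## Model

Each diploid genome is modelled as an unobserved alternating sequence of
homozygous-by-descent (HBD) and non-HBD segments along every chromosome. The
hidden state at marker *t* is one of *C* HBD classes or the non-HBD class
(default *C* = 9, ten states total). Class *k* has an exponential
segment-length distribution with rate *R_k* Morgans⁻¹ (expected length
1/*R_k*); the default ladder is *R* = 2, 4, 8, …, 512, with the non-HBD class
sharing the oldest rate (512). Because an HBD segment traces back to a common
ancestor roughly *R_k*/2 generations ago, the ladder spans inbreeding from
parents (*R* = 2 → 1 generation) to ~256 generations.

Across a gap of *d* Morgans the current segment of class *c* survives with
probability e^(−R_c d); on termination a fresh segment's class is drawn from
the mixing proportions *m* (a point on the simplex), giving the transition
kernel

    A[c, c'] = e^(−R_c d)·[c = c'] + (1 − e^(−R_c d))·m_c' .

Chromosomes are independent; each starts from *m*.

Emissions use the coded-allele frequency *p* at each marker. Inside HBD both
copies descend from one ancestral allele, so with a single
error-and-mutation nuisance probability ε:

    P(2 | HBD) = (1−ε)p + εp²,   P(1 | HBD) = ε·2p(1−p),
    P(0 | HBD) = (1−ε)(1−p) + ε(1−p)² ,

while non-HBD emissions are plain Hardy–Weinberg (p², 2p(1−p), (1−p)²).
ε perturbs only the HBD side — its essential role is to let genuinely
heterozygous calls appear inside HBD segments; default ε = 0.001. Missing
genotypes emit likelihood 1 in every state.

## Inference

Per individual, a scaled forward–backward pass yields per-marker posterior
state probabilities γ. The transition kernel's rank-one reset structure lets
both recursions run in O(S) per marker. **Realized autozygosity** per class
is the genome average of γ; the **inbreeding coefficient** is
F = 1 − realized(non-HBD) = Σ realized(HBD classes).

Mixing proportions are estimated per individual by EM with the rates held
fixed on their ladder. The M-step sets *m* proportional to the expected
number of segment starts of each class: chromosome-start occupancies γ₁ plus
the expected within-chromosome reset events, computed from the forward and
backward variables together with the per-gap termination probabilities.
Because a reset may re-enter the same class, the reset expectation is
accumulated separately from the diagonal "survive" path; this makes the
update an exact EM step and the log-likelihood provably non-decreasing
(asserted at every iteration; a decrease beyond 1e−9·(1+|ll|) raises).
Stopping: |Δ log-likelihood| < 1e−6 or 1000 iterations. Mixing initializes
uniform.

Segment calls come from log-space Viterbi decoding per chromosome, ties
broken toward the lowest state index (the most recent class), then maximal
runs of a constant HBD class become segment records bounded by the first and
last marker of the run (1-based inclusive bp; no extension toward flanking
markers, so SNP counts and lengths refer to observed markers). Runs of
different HBD classes are never merged. Posterior-based realized
autozygosity and Viterbi-based segments are reported side by side and
labelled as such.

Numerics: per-marker scaling constants in forward–backward; probabilities
floored at 1e−300; Viterbi entirely in log space. All kernels are
numba-compiled.

## Genotype handling

PLINK PED/MAP, binary BED/BIM/FAM (SNP-major) and a plain TSV dosage matrix
are read and written natively; genotypes are coded-allele dosages with a
single missing sentinel preserved through all I/O. Markers are sorted by
(chromosome, bp) on read, genotype columns permuted consistently. QC is the
marker-wise call-rate filter only (default: drop markers with <95% calls) —
no sample-wise or MAF filtering. Allele frequencies use non-missing calls
only and are computed within analysis group when labels are available
(pooled otherwise), since emissions in breed-stratified data are better
calibrated within group. When no genetic map is supplied, positions convert
at a constant 1 cM/Mb (overridable); an explicit cM column always wins.
Physical coordinates are 1-based inclusive (BIM convention); feature
intervals for overlap are 0-based half-open (BED convention) with segments
converted as (start−1, end] and any non-empty intersection counting.

## Synthetic data

The generator draws latent state paths at marker resolution through the same
transition kernel the inference uses — each step first tests termination,
then redraws the class from *m*, recording resets (including same-class
re-entries) as fresh segments — and then samples genotypes from the class
emission distributions. This makes it the exact generative counterpart of
the inference model, which is what parameter-recovery and oracle tests
require. At spacings δ with R·δ ≪ 1 the discrete run-length law converges to
the exponential one (mean run length δ/(1−e^(−Rδ)) ≈ 1/R + δ/2).

Defaults: 10 chromosomes × 1,000 markers at uniform 0.001 Morgan spacing
(≈ the density of a ~60k porcine array over a ~23 Morgan genome), allele
frequencies i.i.d. Uniform(0.05, 0.95), physical positions at 1 Mb per cM.
The default truth model places a pig-like occupancy profile: total
autozygosity 0.23 with the largest contribution from the *R* = 128 class and
non-HBD occupancy 0.77, mirroring intensively selected purebred populations;
mixing is derived from occupancy via m_c ∝ occupancy_c·R_c (stationary
occupancy of the kernel is ∝ m_c/R_c). The outcross generator draws one
allele per marker from each of two independent frequency pools — F1-like
individuals with no recent autozygosity.

Not emulated: linkage disequilibrium, array ascertainment bias, genotyping
batch effects, pedigree-based recombination. Passing recovery tests
therefore shows correctness of the inference under its own assumptions, not
robustness to violations of them.

## Validation design and problem sizes

* Forward log-likelihood, posteriors and Viterbi best-path probability are
  checked against exhaustive enumeration over all state sequences on ≤8
  marker, 3-state instances (agreement to 1e−10 relative).
* EM monotonicity is asserted on every fit and checked explicitly on 20
  simulated individuals (2 chromosomes × 400 markers).
* Inbreeding recovery uses 20 individuals at 10 chromosomes × 1,000 markers
  from the uniform-mixing default model with ε = 0.001; mean absolute error
  of fitted vs true F must be ≤ 0.03.
* The segment-length law is checked for R ∈ {2, 32, 512} with spacing
  0.004/R and 10 × 100,000 markers per individual, so chromosomes span 400×
  the expected segment length (end-censored runs, which are dropped, are
  negligible and discretization sits well below the Monte-Carlo error);
  ~4,000 uncensored segments put the empirical mean within 2 standard errors
  of 1/R.
* The outcross contrast (fitted F lower than with 25% planted HBD mass) is
  required in each of 10 replicates at 4 chromosomes × 500 markers.
* I/O round-trips, the call-rate filter, summary tables and interval
  overlap are compared with independent brute-force oracles (the overlap
  oracle is a quadratic all-pairs scan; the implementation uses an interval
  tree).

## Degenerate inputs and edge behaviour

All-missing individuals decode to the chain marginals (F equals the
mixing-implied occupancy). A panel whose markers all fail QC raises rather
than returning an empty panel. Single-individual panels cannot estimate
their own allele frequencies meaningfully (estimates collapse to
{0, ½, 1}, making homozygosity uninformative); frequencies should come from
a reference panel or, in simulations, the generator truth. `em_fit` with
tol = ∞ performs exactly one update and returns.

## Known limitations

Fitted F shrinks slightly toward the prior at realistic marker densities
because very short segments of the oldest classes are barely
distinguishable from chance homozygosity; the effect is visible as a mild
downward bias (~0.03–0.05 at 4,000–8,000 markers) and disappears as density
grows. Rates are never estimated (fixed ladder by design). The model is
unphased and ignores LD between markers, so allele frequencies are treated
as independent per marker. Mixing is estimated per individual; group-level
mixing estimation is not implemented.
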