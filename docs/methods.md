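# Methods

## Scope and assumptions

`clonalmix` models each genomic region of a bulk tumor as a **two-way
mixture**: one aberrant population with integer allele-specific copy number
(n_b minor, n_t total, n_a = n_t − n_b major) mixed with euploid cells.
Different regions may belong to different (sub)clones — the mixing fraction
*p* (sAGP) is local — but at any one sCNA only one aberrant state is
assumed present. This holds for genomes with relatively sparse copy-number
change and breaks down under whole-genome doubling or layered local
aberrations; segments violating it are reported with missing sAGP rather
than forced into the model. Somatic mutations are assumed to arise once
(maximal parsimony: no recurrent or back mutation), and SNVs and small
indels are treated identically.

## sAGP inference

Inputs are five-column allele-count tables (SNP id, chromosome, position,
A count, B count) for tumor and matched normal; counts may be real-valued
array intensities. Per shared site, BAF = b_T/(a_T + b_T) and
LRR = log2((a_T + b_T)/(a_N + b_N)). The field convention for LRR
normalization of raw counts is not standardized; we median-center LRR
genome-wide so the euploid mode sits near zero, and let the fitted baseline
(x0, y0) absorb any residual offset. Heterozygous sites are called from the
normal BAF within 0.5 ± 0.2 (configurable); the model otherwise assumes
germline genotypes are known.

Segments are either fixed-count bins (default 500 heterozygous SNPs; a
trailing partial bin is kept when it holds at least half a bin of het
markers, else merged) or change-point segments. Change points are detected
independently on the LRR and folded-BAF (|BAF − 0.5|, het markers only)
series by recursive binary splitting: the split maximizing the standardized
mean-difference statistic is accepted when its permutation p-value (1000
permutations) is below 0.01 and both children keep at least 5 markers. A
BAF change point within 5 markers of an LRR change point is discarded as a
less precisely placed duplicate (het markers are sparser); the merge window
never crosses chromosomes. Per segment we summarize the **median** LRR over
all markers and the median folded BAF over het markers — medians for
robustness against outlier probes.

The baseline (x0, y0) is the densest kernel-density mode of med_LRR among
segments with med_fBAF < 0.1; its scatter (MAD × 1.4826 per axis, floored
at 1e-4 so noiseless input keeps a usable threshold) sets the assignment
threshold T = 2·sqrt(sd_BAF² + sd_LRR²). Fitting proceeds per segment:

1. segments within T of (x0, y0) are euploid, p = 0;
2. for every candidate state (0 ≤ n_b ≤ n_t/2, n_t ≤ 6, excluding (1,2)),
   the closest point on its canonical line is found by a 101-point grid
   scan plus bounded 1-D refinement (the fold in BAF makes the distance
   non-convex, hence the grid seed);
3. criterion (a): lines with residual ≤ T survive; none surviving means
   the segment fails the two-way-mixing hypothesis → missing sAGP;
4. criterion (b): among survivors, minimize
   F = |n̄_t(state, p̂) − ploidy| + |p_s − p̂|.

Criterion (b) matters because canonical lines genuinely overlap: every
n_b = 1 state traces the same (BAF, LRR) curve re-parameterized by average
copy number, so a point on the (1,3) line is also on the (1,4) and (1,5)
lines at smaller p. The global quantities it needs are themselves derived
from sAGP, so fitting is two-pass: a provisional pass resolves exact
line-overlap ties by parsimony (fewest total copies), p_s is then the
largest kernel-density peak of the per-sCNA p̂ distribution and ploidy the
length-weighted mean of n̄_t, and a second selection pass re-applies
criterion (b) with those values (cached line fits are reused, nothing is
re-optimized). The distance metric is unweighted Euclidean, matching the
single combined threshold; a per-axis standardized metric is available
behind a flag. An optional AB-vs-AABB baseline check refits all segments
with the origin reinterpreted as balanced tetraploid and keeps the
interpretation with the smaller total residual; it is off by default since
the genome-doubled regime is outside the validated conditions.

## CCF inference

For a mutation with S somatic reads out of N inside an sCNA with known
(n_b, n_t, p), four lineage scenarios are possible, each implying three
coexisting populations r0 (neither event), r1, r2 with r0 + r1 + r2 = 1:

| scenario | order | mutant copies in r2 cells | CCF expression |
|---|---|---|---|
| A1 | mutation first, on the amplified/retained allele | n_a | n̄·f − p·n_a + p |
| A2 | mutation first, on the other allele | n_b | n̄·f − p·n_b + p (n_b ≥ 1); n̄·f (n_b = 0) |
| B | sCNA first | 1 | n̄·f |
| C | independent lineages | 0 (r1 carries it) | n̄·f |

with n̄ = 2(1 − p) + n_t·p. CCF counts cells physically carrying at least
one mutant copy; for states that lost an allele (n_b = 0), a mutation on
the subsequently lost chromosome (A2) survives only in the r1 population,
which collapses A2 onto the B/C expression and zone. For LOH states and
balanced gains the A2 branch duplicates another scenario's population
structure outright and the admissible set is {A1, B, C}; heterozygous
amplification and hemizygous deletion keep all four. In diploid regions
CCF = 2f with no scenario machinery.

Each scenario bounds the attainable SAF: A1/A2 give
f ∈ [m·p/n̄, (1 − p + m·p)/n̄] with m the mutant multiplicity, B gives
[0, p/n̄], C gives [0, (1 − p)/n̄]. Scenario likelihoods integrate
Binomial(S | N, f₀) over the zone, evaluated in closed form:
∫ₐᵇ C(N,S) f^S (1−f)^(N−S) df = [I_b − I_a](S+1, N−S+1)/(N+1) with I the
regularized incomplete beta function. Probabilities are normalized over the
admissible set (equal scenario priors, as implied by the flat prior on f);
when every zone integral underflows (observed f incompatible with all
zones, possible under read noise) the variant is flagged and reported with
the shared B/C expression at low confidence. Scenario assignment searches
singles, then pairs, triples, and the full set, within each size in
decreasing summed probability (exact ties lexicographic), returning the
first combination with probability ≥ 0.95 (re-normalized probabilities;
the full set is the terminal fallback). A CCF point estimate exists when
all scenarios in the assigned set share one expression — always true for
deletion, true for any A1-free set elsewhere — and is clipped to [0, 1]
with the pre-clip value retained for QC; conflicting sets yield a missing
CCF with the candidate values kept as annotations.

Posterior moments use a uniform prior on CCF = x ∈ [0, 1], likelihood
Binomial(S | N, G(x)) with G the scenario's inverse expression clipped to
[0, 1], integrated by Simpson's rule on 2001 fixed points; a degenerate G
or underflowed normalizer is flagged.

Default variant filters in the end-to-end pipeline are depth ≥ 20 and
SAF ≥ 0.05 (typical discard thresholds for exome data); the validation
protocols below use all simulated variants.

## Clonal structure

The per-bin sAGP vector is filtered before clustering: bins with median
folded BAF ≤ 0.04 and |median LRR| ≤ 0.16 are treated as euploid (sAGP 0),
missing values are dropped, and values ≤ 0.05 removed (short true sCNAs
diluted by flanking euploid sequence accumulate there). Samples with fewer
than 50 surviving values are flagged unanalyzable. The same machinery
accepts CCF vectors, minus the euploid rule.

Model-1 maximizes l = Σ ln(A/range(Y) + (1 − A)·Normal(y_i; μ, σ)) with
A, μ ∈ (0, 1), by multi-start L-BFGS-B (μ at the quartiles of Y,
A ∈ {0.1, 0.5, 0.9}, two σ starts). Model-2 is a Dirichlet-process mixture
of normals fitted by collapsed Gibbs sampling (CRP assignments with
Student-t predictives under a normal–inverse-gamma base measure — the 1-D
specialization of normal/inverse-Wishart), with the base-measure precision
scale k0 given a Gamma(τ1/2, τ2/2) prior and the concentration α a
Gamma(a0, b0) prior updated by the Escobar–West auxiliary scheme. Defaults:
μ1 = mean(Y), ν1 = 4, ψ1 = var(Y), τ1 = τ2 = a0 = b0 = 1 — a deliberately
conservative (peak-insensitive) setting — with 10000 sweeps, 2000 burn-in,
thinning 5. Input is sorted before sampling so the chain is invariant to
permutations of Y under a fixed seed. The reported state is the
posterior-mode number of occupied clusters, then the retained sample of
that size with the highest data log-density; a warning flag is raised when
the occupied-cluster count has not stabilized over the last quarter of the
chain. Peaks are counted as modes of the fitted mixture density over
components with ≥ 5% mass — the DP routinely shreds one tight population
into co-located clusters, which a mode count (unlike a cluster count)
correctly reads as one peak. BIC (k = 3 for Model-1 against k = 7 for
Model-2's hyperparameters, smaller wins) selects the reported model; the
two models are not nested, since a DP mixture imitates a uniform background
with many peaks rather than one.

## Synthetic data

The generator emulates a tumor whose genome mixes euploid segments and
sCNAs carried by a dominant and a minor clone. Segment-level observables
are drawn as fBAF = |0.5 − (p·n_b + 1 − p)/n̄| + N(0, σ_BAF) and
LRR = log2 n̄ − 1 + N(0, σ_LRR); the defaults σ_BAF = 0.01, σ_LRR = 0.04
correspond to the per-segment standard error of a ~36-marker segment on a
dense SNP array (per-SNP scatter ≈ 0.05 / 0.25). Noise is added to the
*folded* BAF, so observed values can be slightly negative; the distance
metric is indifferent to this. Default composition: 200 euploid + 200 sCNA
segments of equal length (so the genome is half euploid), the sCNAs split
133/67 between dominant and minor clone, states drawn at ratios 2/7
deletion (0,1), 2/7 CN-LOH (0,2), 2/7 heterozygous amplification (1,3),
1/7 balanced doubling (2,4).

Variants (default 4000 per sample) pick hosts length-weighted among
segments with a usable sAGP estimate. Hosts estimated euploid give
f ~ U(0, 0.5) and true CCF = 2f; sCNA hosts draw a scenario uniformly from
the admissible set, f uniformly inside that scenario's zone, and the true
CCF from the scenario expression. Read counts are N ~ Poisson(coverage)
with zeros redrawn and S ~ Binomial(N, f). Variant truth is deliberately
built from the *estimated* (p, n_b, n_t) of the host, so the CCF score
isolates the read-count/scenario half of the problem from sAGP estimation
error — matching the validation design this generator reproduces. Two
intentionally mis-specified estimators accompany the comparison protocol
for bias context: one assumes mutation and sCNA always co-occur (ignores
the r1 population; underestimates A1/A2), one applies the A1 inversion to
every variant.

What the generator does **not** emulate: marker-level wave/GC artifacts,
segmentation uncertainty feeding into sAGP (segment truth is generated at
segment level for the validation protocols), sequencing error in S, mapping
bias, more than two aberrant populations per locus, and whole-genome
doubling. Passing validation therefore demonstrates correctness of the
estimators under their own model assumptions, not robustness to array
artifacts or violated mixing assumptions. A separate marker-level generator
(`simulate_marker_series`, `simulate_snp_level_sample`) produces per-SNP
series and allele-count tables for exercising segmentation and the
end-to-end pipeline.

## Validation protocols and expected numbers

`run_ccf_validation` runs four (p_dom, p_sub) settings — (0.9, 0.8),
(0.9, 0.4), (0.5, 0.3), (0.3, 0.1) — at coverages 50 and 100. Observed
Spearman correlations between true and estimated CCF are ≈ 0.94–0.95 at
coverage 50 and ≈ 0.97 at coverage 100. The coverage-50 values sit against
a hard noise floor: euploid-hosted variants (half of each case) are
estimated by exactly 2S/N, and binomial sampling alone pins that stratum's
rank correlation near 0.93 at depth 50 (the suite computes this floor
directly). `run_comparison_protocol` (200 CNAs with p ~ U(0,1), 1000
mutations, coverage 50) yields Pearson r ≈ 0.95 for in-sCNA mutations.
The 55-pair (p_dom, p_sub) grid exercises sAGP recovery across the clonal
spectrum; state errors and sAGP deviations concentrate where sAGP is small,
where canonical positions crowd the euploid noise ellipse.

Problem sizes throughout (400 segments, 4000 variants per case, 1000-point
permutation tests, the MCMC lengths above) are the package's defaults for a
desk-scale replication; tests use shorter chains (2500–3000 sweeps) where
the posterior is well-separated.

## Known limitations

* The AB-vs-AABB (genome doubling) disambiguation is a residual-comparison
  heuristic, not a full near-origin genotype ascertainment; doubled genomes
  are outside the validated regime.
* sd_BAF/sd_LRR are sample-wide; long segments are not given tighter
  per-segment thresholds.
* Scenario probabilities use equal priors over admissible scenarios;
  unequal priors are configurable but unvalidated.
* Bins violate sAGP independence (long sCNAs span several bins) and sCNAs
  violate identical distribution (lengths vary); the clonal-structure
  fits inherit whichever compromise the chosen spatial unit makes.
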