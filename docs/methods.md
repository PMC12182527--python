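# Methods

This note documents the models behind `wildqtl`, the defaults and why they
were chosen, what the synthetic data does and does not emulate, and the
numerical choices that matter for reproducing results.

## Scope and model overview

The package answers a design question: *given a genotyped population of an
outcrossing crop wild relative, which crossing scheme yields a mapping
population with the best power/false-detection trade-off for minor QTL of a
quantitative trait?* It does so entirely in simulation. Each experiment
run draws a trait architecture, develops mapping-population entries through
one of nine crossing designs, phenotypes them at a set heritability, scans
them with a mixed-model association test, and scores detection against the
known truth.

All genetics is additive. Dominance and epistasis are deliberately out of
scope: with ≤50% donor genome in testcross progeny the additive variance
dominates, and testcross designs have little power for epistasis anyway.
No negative wild effects are simulated; the wild genome's inferior
performance is expressed through its lower effect total, not through
deleterious alleles.

## Meiosis and genome representation

Gametes follow the Haldane model: per chromosome of map length L cM the
crossover count is Poisson(L/100), crossover positions are i.i.d. uniform,
the starting strand is fair, and there is no interference and no obligate
chiasma. This keeps every recombination oracle closed-form (recombinant
fraction r(d) = (1 − e^(−2d/100))/2) and matches the convention of standard
breeding simulators. Chromosomes may pass through meiosis intact.

Every allele copy carries an integer *origin id* naming the founder
haplotype it descends from (wild ids ≥ 0, elite pool < 0). Origin ids are
copied, never mutated, through meiosis. Two derived statistics summarize
introgression state:

* **wild-genome fraction** — share of allele copies with wild origin;
* **wild-haplotype coverage** — mean per-locus count of *distinct* wild
  founder haplotypes (0–2). A wild plant scores 2, its DH scores 1, a
  backcross-derived DH scores 0.25 in expectation.

Association scans, in contrast, see only origin-blind 0/1/2 dosages — a SNP
array cannot distinguish identical-by-state wild and elite alleles, and
this masking is part of what the simulation measures.

## Synthetic wild populations

The generator emulates the statistical fingerprint of a natural outcrossing
CWR population as seen on a fixed SNP array:

* an L-shaped minor-allele-frequency spectrum with a target mean MAF
  (default 10.5%, the middle of the 7.68–13.22% range typical of such
  populations);
* mean per-individual heterozygosity targeted at 14% (middle of 11.00–17.18%);
* linkage disequilibrium that is strong between tightly linked markers and
  decays to background within ~5–10 cM.

Mechanism: per-marker allele frequencies are drawn as q = x/2 with
x ~ Beta(a, b); the Beta moments are solved from the target mean MAF and
heterozygosity (for a mean μ = 2·MAF and concentration s = a + b, the
expected Hardy–Weinberg heterozygosity is μ − μ²/2 − μ(1−μ)/(2(s+1))).
Founder haplotypes start in linkage equilibrium; LD is then built by a
random-mating burn-in at a reduced effective size (default N_e = 40 for 60
generations), after which the requested census size is produced by one more
round of random mating. The burn-in creates LD with the drift–recombination
profile of a finite outcrossing population — accumulated r² ≈ 1/(1 + 8·N_e·c)
for recombination fraction c — which at the defaults gives r² ≈ 0.5 below
0.5 cM decaying to ~0.05 beyond 10 cM, and simultaneously creates the
haploblock sharing that makes rarity-based subset selection meaningful.
Twenty generations at full census size would leave the population essentially
LD-free (E[r²] ≈ t/2N) and no marker would ever tag a QTL.

Because drift during the burn-in erodes diversity in a spectrum-dependent
way, the initial Beta law is inflated and re-calibrated in a short loop
(≤4 regenerations) until realized heterozygosity and MAF are within 1.5
percentage points of target; the generator raises a calibration error if
the residual error exceeds 3 points. Two feasibility bounds are enforced up
front: heterozygosity can be at most ≈2·MAF·(1−MAF) and, under
Hardy–Weinberg, at least the mean MAF (2q(1−q) ≥ q for q ≤ ½) — target
pairs outside that band are rejected rather than silently missed.

The elite line is a homozygous draw (marker-wise, following the wild
population's major alleles when provided) with exactly ⌊0.01·M⌋ loci made
heterozygous, so its heterozygosity never exceeds the 1% bound that defines
"almost fully inbred" here. The tester is the F1 of two homozygous
elite-pool lines differing at 24.44% of loci, reproducing the reported
heterozygosity of a within-pool two-way hybrid; both carry elite origin
tags, so the tester contributes no wild genome and — because elite effects
are uniform per copy — every tester gamete has exactly the same haploid
value, contributing no genetic variance between entries.

What the generator does **not** emulate: geographic substructure among
sampling sites, genotyping/phasing error, inbreeding excess over
Hardy–Weinberg, and any non-neutral site-frequency features. Passing tests
on synthetic data therefore demonstrates correctness of the machinery and
the qualitative design ranking under a realistic LD/diversity regime, not
quantitative transferability to any particular field population.

## Subset selection

Haploblocks are consecutive non-overlapping windows of five markers (short
trailing blocks at chromosome ends are kept; blocks never span
chromosomes). Selection is two-stage: 25 seeds with the highest rarity
score (Σ 1/occurrences over both haplotypes and all blocks), then greedy
addition of the individual covering the most block haplotypes not yet
represented, counting only haplotypes seen at least twice in the population
(singletons are likely artefacts). "Coverage" counts block haplotypes, not
single SNP alleles. All ties break toward the lowest individual index, so
selection is deterministic.

## Trait architecture

Let E be the haploid elite effect total (100 arbitrary units). Every
marker carries E/M on elite-origin copies of either allele (infinitesimal
elite genome). The wild haploid total is exactly E/2 — elite material
performs twice as well — split between n QTL with geometric effects
e_i = e_max(1/2)^(i−1) (e_max defaults to 5% of E) and a uniform background
of (E/2 − Σe_i)/(M − n) on every non-QTL marker, attached to wild-origin
copies of either allele. QTL markers are drawn fresh each run from markers
polymorphic in the selected subset, with the effect allele chosen uniformly
from the two alleles present; the other allele's effect is 0. QTL markers
are distinct within a run.

Genotypic values sum per-copy effects; an entry's value is the mean over
its testcross progeny. The genetic variance v_g is the realized variance
of entry values (recomputed per run and design), and one Gaussian noise
draw per entry with v_e = v_g(1 − h²)/h² yields the phenotype. An entry
population whose values are all identical has no defined noise scale and
raises a degenerate-variance error, which the runner records as a failed
run with TPR 0 and FD 1.

## Association scan

Kinship uses the frequency-weighted allele-sharing estimator
K_ij = ½·mean_m (g_im − 2p_m)(g_jm − 2p_m)/(2p_m(1−p_m)) over polymorphic
markers (≈0.5 self-kinship for non-inbred individuals); a plain IBS option
exists behind a flag. The polygenic model y = μ + Xβ + G + e,
Var(G) = σ²_G Φ, Var(e) = σ²_e I is fit by maximum likelihood through one
eigendecomposition of Φ and a bounded scalar search on the heritability
ratio h = σ²_G/(σ²_G + σ²_e) in [0, 1) with tolerance 1e−8; μ, β and the
total variance are profiled out in closed form. A diagonal jitter of
1e−6 × mean diagonal is added only if Φ is numerically non-PSD.

The per-marker score statistic is

    T = ((G − E[G])ᵀ V⁻¹ y*)² / ((G − E[G])ᵀ V⁻¹ (G − E[G])),  T ~ χ²₁,

with y* the *fixed-effect* residuals y − μ̂ − Xβ̂ and V the fitted
covariance. This is the classical mixed-model score test: population and
family structure are adjusted through V⁻¹. The alternative of plugging in
the family-adjusted residuals y − μ̂ − Ĝ instead is a documented trap: a
trait driven by one marker projects onto a marker-based kinship exactly
like a fully heritable polygenic trait (the expectation of zzᵀ over random
standardized markers is proportional to K), so the ML fit drives σ²_e → 0
and the BLUP Ĝ absorbs the entire signal, zeroing every statistic. Both
residual vectors are exposed on the fit object.

Markers carrying simulated QTL effects are excluded from the scan — a
causal polymorphism is normally not itself on the array — so detection must
come from linked markers. Constant-dosage markers are flagged untestable.

## Detection and evaluation

P-values are Benjamini–Hochberg adjusted and thresholded at
−log10(p) > 3 (strict). The threshold is applied to adjusted p-values by
default — the single most consequential reading of the evaluation rules — 
and a `threshold_on_raw_p` flag provides the alternative. Significant
markers are clustered per chromosome, splitting where consecutive
significant markers are ≥5 cM apart; a cluster becomes a QTL region if any
5 cM window anchored at a member marker holds ≥5 of its markers. A QTL
counts as detected when a region overlaps its ±2.5 cM window; a region
overlapping no QTL window is false. FD = false/total regions, defined as
100% when QTL were simulated but no region was called; FD counts regions,
not markers. A region overlapping two QTL windows detects both and is not
false.

## Experiment orchestration and problem sizes

Runs are coordinates (population, design, n_QTL, replicate); sub-seeds
derive from the master seed and the coordinates, so results are independent
of execution order. Within a run the genetic realization is shared across
the h² grid and only the noise is redrawn, isolating the heritability
effect. Progeny genomes are streamed: because genotypic values are
additive over allele copies, each progeny's value is the sum of its two
gamete values, and gametes are simulated in vectorized batches and
discarded. At full scale (300 entries × 594 progeny × 16,076 markers)
retaining progeny would need tens of GB; streaming needs none of it.

Default full-scale conditions are 16,076 markers on 9 × 69.4 cM
chromosomes, N = 300 selected from ~1,000, 594 testcross progeny per entry
and 1,000 replicates. The package's own test and acceptance runs use desk
scale: 2,000 markers on 9 chromosomes totalling 200 cM, 100 selected from
200, 100 progeny per entry, 50 replicates. The 200 cM length is a
deliberate choice: it keeps marker spacing (0.1 cM) small relative to the
generator's LD range, as in the full-scale setting (0.0389 cM spacing),
so the ≥5-markers-in-5-cM region rule remains attainable; stretching 2,000
markers over 625 cM would leave only 1–3 markers in strong LD with any QTL
and no region could ever be called, regardless of signal strength. Power
at desk scale is substantially below full scale (a third of the entries,
one sixth of the progeny), so desk-scale results are read for their
ordering — M1 > M4 > M9, power increasing with h² — not their absolute
rates.

## Known limitations

* The Beta/burn-in calibration matches means, not full distributions; the
  realized MAF histogram is L-shaped but not fitted to any specific array.
* The kinship normalization follows the frequency-weighted convention
  documented above; it is versioned behavior, not a claimed byte-for-byte
  match to any external implementation.
* ML (not REML) variance components are used, matching the two-stage scan
  design; with Φ ≈ I the variance split is unidentifiable and only the
  total is meaningful.
* The evaluation never assigns confidence intervals to QTL positions and
  performs no LD clumping; regions are purely rule-based.
* Practical breeding constraints (self-incompatibility, sterility, seed
  supply, phenotyping feasibility of high-wild-fraction material) are
  outside the simulation.
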