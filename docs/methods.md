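# Methods

## Model

Each chromosome c is modelled as a concatenation of R_c independent
stationary segments ("regions") separated by change points
w_c ⊂ {1..L_c−1}.  Within region r, the hidden indicator
θ_l ∈ {0 = null, 1 = disease-associated} follows a two-state Markov
chain with exit rates a01 = P(0→1), a10 = P(1→0), started from its
stationary law π0 = a10/(a01+a10) (π is always derived from the
transition matrix, never stored separately).  Conditional on the state,
the observed z-value is

* θ = 0: N(0, 1) — fixed, never re-estimated, because z-values obtained
  from the upper-tail transform z = Φ⁻¹(1−p) of valid p-values are
  standard normal under the null;
* θ = 1: Σᵢ₌₁..m ξᵢ N(μᵢ, σᵢ²), with region-specific weights, means and
  sds and a chromosome-wide component count m.

Regions are treated as mutually independent, so the chromosome
log-likelihood is the sum of region log-likelihoods, and a partition
with |w| change points and mixture size m has
D(m, w) = (|w|+1)·(3m+1) free parameters per chromosome (per region:
two exit rates, m means, m sds, m−1 weights).

## Estimation

Baum–Welch with scaled (normalized) forward–backward recursions; the
scaling constants accumulate into the log-likelihood, keeping the pass
stable for chains of 10⁶ sites.  The E-step computes state posteriors
and, nested within state 1, component responsibilities; the M-step
updates a01, a10, ξ, μ, σ.  Numerical guards: exit rates clamped to
[1e−6, 1−1e−6]; component sds floored at `sigma_floor` (default 0.05);
components whose responsibility mass collapses keep their previous
location and are logged.  Starting values: exits (0.05, 0.3), means at
quantiles of the upper 20% tail of z, unit sds, uniform weights;
restarts jitter the exits log-normally and the means by N(0, 0.5), and
the best final log-likelihood wins.  Convergence: relative
log-likelihood improvement below `em_tol` (default 1e−6) or `max_iter`
(500).

Because the chain is started from its stationary distribution, the
transition M-step is the standard count ratio and ignores the implicit
dependence of the initial distribution on (a01, a10); this is the usual
stationary-HMM approximation and can in principle produce log-likelihood
decreases on the order of the stationarity mismatch.  In practice the
ascent is monotone to ~1e−6 relative, which is what the tests assert.

## Change-point search and penalty calibration

Candidate change points come from a uniform grid with spacing `L_min`
(default 300) — `{L_min·i : L_min·i ≤ L − L_min}` — or from the user.
For each m ≤ m_max, the cost of every candidate segment,
−max_Ψ log P(segment | Ψ, m), is computed by EM (2 restarts inside the
search; the final selected regions are refit with 3).  Segment costs do
not depend on λ, so one table per m serves the entire calibration.  A
Bellman recursion over suffixes then yields, for every k ≤ K_max, the
exact minimum total cost over partitions with k change points drawn
from the candidates; ties are broken to the lexicographically smallest
change-point set, then smallest k, then smallest m.

λ is calibrated by a sliding-window dimension jump.  On a log-spaced
grid of T = 50 values spanning [ln L/(2T), 10·ln L] (bracketing the BIC
value ln(L)/2 by more than an order of magnitude each way), the selected
dimension D(λ) is non-increasing; the windowed jumps
J_t = D(λ_t) − D(λ_{t+h}) aggregate up to h successive drops, guarding
against staircases of small jumps (h = 1 is the plain dimension-jump
method; h above ~10 over-aggregates and triggers a warning).  The
largest jump — earliest on ties — locates λ_jump = λ_{t*+h}, and the
operational penalty is λ_opt = 2·λ_jump (the usual
"jump-then-double" slope-heuristics convention; the factor is
`lambda_factor` in the config).  A flat trace falls back to the BIC
value with a warning.  BICP mode skips calibration and uses λ = ln(L)/2
directly.

## Pooled decision rule

Each fitted region contributes LIS_l = P(θ_l = 0 | region z), computed
by forward–backward.  All values are pooled across regions and
chromosomes, sorted ascending (stable tie-break by chromosome id, then
index, for deterministic output), and the procedure rejects
H_(1..l) with l = max{i : (1/i)·Σ_{j≤i} LIS_(j) ≤ α}.  The running mean
of the smallest LIS values estimates the false discovery proportion of
that rejection set, so the rule controls the global FDR at α; the
rejected set is by construction a prefix of the ranking and grows
monotonically with α.

## Simulation designs

* **Five-region selection benchmark** (single chromosome, region length
  L0 ∈ {600, 900, 1200}): all regions share a01 = 0.02; non-null exit
  rates (0.20, 0.95, 0.45, 0.15, 0.15); two-component unit-sd non-null
  mixtures (0.1N(1)+0.9N(3), 0.8N(1.5)+0.2N(4.5), 0.4N(1.5)+0.6N(3.5),
  0.2N(1)+0.8N(3) twice).  True change points {i·L0, i=1..4};
  candidates every 300; scored by change-point sensitivity/specificity
  and the rate of selecting m = 2 (K_max = 8, m_max = 5, h = 2).
* **Two-chromosome FDR benchmark** (2 chromosomes × 2 regions × 2000
  SNPs; K_max = 4, m_max = 3, h = 2): single-component non-null
  emissions; either the region-2 exit rates are perturbed by υ₁
  (dependence sweep, means chained as μ21 = μ11+1.5 on chromosome 1,
  μ11' = μ11+0.5, μ21' = μ11'+2.0) or all transitions are fixed and the
  mean separation υ₂ varies.  Scored by empirical FDR/FNR/sensitivity
  of RSPLIS vs PLIS at α = 0.1.
* **Genotype benchmark**: subjects drawn from a haplotype pool; status
  from a logistic model on eight causal SNPs (per-allele odds ratio
  1.5; four well-separated, four spaced by 3); sampling continues until
  1000 cases and 1000 controls (rejection sampling, capped at 10⁷
  draws); causal SNPs are removed and the 39 flanking SNPs (±3 of each
  causal, deduplicated) form the relevant set; methods are scored by
  top-M sensitivity.

The haplotype pool is synthetic (no external panel is bundled): binary
haplotypes with per-SNP allele frequencies uniform on [0.1, 0.5] and
first-order Markov within-block dependence (allele l copies allele l−1
with the block copy probability, default 0.9 over 25-SNP blocks; blocks
independent).  This reproduces blockwise LD and bounded MAFs but not
recombination-hotspot geometry, allele-frequency spectra, or
population stratification — so passing tests demonstrate correct
method behaviour under blockwise LD, not calibrated performance on real
genotype panels.  The printed logistic intercept −9.5425 targets a 3%
disease rate under a particular reference panel; prevalence depends on
the genotype distribution, so by default the intercept is re-solved by
Monte Carlo + Brent's method for the pool in use.

Every generator is bit-reproducible from its seed (NumPy
`SeedSequence` spawning; one child stream per replication).

## Problem sizes

The bundled studies run at 20 replications (L0 = 600 selection
benchmark), 25 (L0 = 1200), and 20 (FDR benchmark, υ₁ = 0.15,
μ11 = 1.0) — enough for the Monte-Carlo standard errors used in the
checks while keeping a full run in the tens of minutes on one core.
Replication counts are plain arguments (`reps`) for larger runs.

## Known limitations

* **The fourth benchmark change point is information-free.**  In the
  five-region design, regions 4 and 5 have identical transition
  matrices and identical non-null mixtures, so no likelihood-based
  method can detect the boundary between them above chance.
  Change-point sensitivity in that design is therefore capped near
  0.75 plus a chance contribution, independent of the selection
  procedure.
* **Component count is weakly identified under free variances.**  The
  benchmark's two-component mixtures (e.g. 0.1N(1,1)+0.9N(3,1)) are
  close, in Kullback–Leibler terms, to a single normal with inflated
  variance.  With σ estimated freely, the m = 1 fit absorbs the
  overdispersion and the m = 2 likelihood advantage is a few nats per
  chromosome — of the same order as the fitting noise — so m = 2
  selection rates are intrinsically modest at these sample sizes, for
  ACP and (especially) BICP alike.  We verified this is a property of
  the likelihood surface, not the optimizer: EM started at the
  generating parameters moves to a higher-likelihood ridge with merged
  components.  Substantially higher selection rates would require
  constraining the component sds (e.g. pinning them at the null scale),
  which this package deliberately does not do, since the model declares
  them free parameters (they are counted in D_m = 3m+1).
* Related: at L = 5×10⁴ the exit rates are recovered to ~0.01 but
  component-wise mixture means are not; the identifiable functional is
  the overall non-null mean Σξμ (recovered to ~0.05 in the tests).
* The plug-in LIS procedure controls FDR asymptotically; with estimated
  parameters the empirical FDR on small designs fluctuates around, and
  occasionally slightly above, the nominal level.
* Candidate change points must come from a grid or the user; no
  haplotype-block detection is included.  Genotype input supports
  diploid biallelic dosages only; missing genotypes are dropped per SNP
  (no imputation).
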