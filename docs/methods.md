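# Methods

## Likelihood

A phased case-parent trio determines four equally likely transmissions.
Writing the affected child's genotype as `g_0n` (additive minor-allele
counts, the sum of the two transmitted haplotype vectors) and the three
pseudo-siblings as `g_in`, the retrospective likelihood of the observed
transmission is a 1:3 matched conditional logistic model,

    ℓ(ω) = Σ_n log [ exp(g_0n ω) / Σ_{j=0..3} exp(g_jn ω) ]
         = − Σ_n log ( 1 + Σ_{i=1..3} exp(−x_in ω) ),   x_in = g_0n − g_in,

with ω = (β, α) stacking S common and L rare coefficients (rare columns
grouped contiguously by region).  Conditioning on the parents removes
population-structure nuisance parameters; parental haplotype
frequencies never enter.  All evaluations use log-sum-exp
stabilization, so the likelihood is finite for any finite ω.

Conventions: genotypes are additive 0/1/2 counts of the dataset-level
minor allele (the less frequent allele among the parental haplotypes;
a tie at 0.5 stays on the VCF ALT allele).  The likelihood itself only
sees contrasts, so allele orientation affects sign conventions, not
fit quality.  Families whose four configurations coincide contribute a
constant and are retained.  Mendelian-inconsistent or unphased trios
are dropped with a logged warning naming the offending sites.

## Priors

Common coefficient: β_s | γ_s ~ N(0, v₁) if γ_s = 1 else N(0, v₀),
γ_s ~ Bern(π₁).  Rare coefficient: α_rj ~ N(0, v₃) when η_r λ_rj = 1,
else N(0, v₂); η_r ~ Bern(π₂) is a region (gene) indicator and
λ_rj | η_r = 1 ~ Bern(π₃) a within-region indicator (λ degenerate at 0
when the region is excluded).  π_i ~ Beta(a_i, b_i) with defaults
a_i = 1 and b = (S, R, L): prior inclusion odds scale inversely with
the number of candidate terms, a standard multiplicity control.

Slab variances are fixed at v₁ = 0.4 and v₃ = 0.5 so that the 95%
prior coverage of an included effect spans odds ratios ≈ [0.29, 3.45]
(common) and [0.27, 4.3] (rare).  The spike (exclusion) variances
default to v₀ = v₂ = (log 1.05 / 1.96)² ≈ 6.2e-4 by the mirrored
device: odds ratios inside [0.95, 1.05] are treated as clinically
irrelevant, and the spike's 95% mass covers exactly that band.  The
defaults are a starting point; v₀ and v₂ are the selection dials and
are normally tuned (below).

## EM with deterministic annealing

Indicators are missing data.  With current (β, α, π) the E-step is
exact and closed-form (all in log space):

* p_s  = σ(log[π₁ N(β_s; 0, v₁)] − log[(1−π₁) N(β_s; 0, v₀)]),
* q_rj = σ(log[π₃ N(α_rj; 0, v₃)] − log[(1−π₃) N(α_rj; 0, v₂)]),
  the within-region inclusion probability *conditional on* η_r = 1,
* g_r  = σ(log e_r − log f_r) with e_r = π₂ Π_j [π₃ N(α;0,v₃) +
  (1−π₃) N(α;0,v₂)] and f_r = (1−π₂) Π_j N(α; 0, v₂).

The M-step minimizes the strongly convex penalized loss
Σ_n log(1 + Σ_i e^{−x_in ω}) + ½ ω′P ω with diagonal P:
(1−p_s)/v₀ + p_s/v₁ for common entries and, for rare entries,
(1−w_rj)/v₂ + w_rj/v₃ with w_rj = g_r·q_rj, the full indicator
expectation E[η_r λ_rj].  Using the conditional q_rj alone in P (an
alternative retained as `penalty_form="conditional"`) is not an exact
E-step and can decrease the observed-data objective by ~1e-8 per
iteration; with the joint form the ascent property holds to machine
precision, which is why it is the default.  Mixing weights update in
closed form, e.g. π₁ ← (Σ p_s + a₁ − 1)/(S + a₁ + b₁ − 2), reducing to
Σ p_s / (2S − 1) at the defaults; π₃ uses the g-weighted counts
Σ_r g_r Σ_j q_rj over Σ_r g_r J_r + L − 1.  Empty classes (S = 0 or
R = 0) hold their weight fixed.

Convergence is declared when the observed-data log-posterior (computed
directly by marginalizing the indicators, equivalent to the Q − R
decomposition) moves by less than ε = 1e-4; the iteration cap is 500,
after which the state is returned flagged unconverged.

Annealing tempers every E-step two-way posterior with exponent
t: p = a^t/(a^t + b^t).  One EM sweep runs at each t = 0.1, 0.2, …,
1.0, then iteration continues at t = 1 to convergence.  Coefficients
start at 0.5 and mixing weights at their prior means a_i/(a_i + b_i);
π updates can reach the boundary (exactly 0) through probability
underflow, which is treated as a legitimate absorbing mode — log-space
arithmetic keeps every quantity finite.

### M-step solvers

The penalized objective has a unique minimizer, so the solver is a
contract, not an algorithm.  The default is a damped Newton method with
backtracking (Hessian `X′ diag(u) X − Σ_n m_n m_n′ + P`, Cholesky
solve); its stopping rule is a gradient ∞-norm below 1e-9·√N inside
EM (1e-8·√N standalone), with a machine-precision guard in the line
search.  An independent stochastic dual coordinate ascent solver
maximizes the dual Σ_n H(u_n) − ½ v′P⁻¹v over per-family simplex
blocks (the conjugate of the matched-set log-sum-exp loss is a
4-category negative entropy), visiting families in a seeded random
order and re-optimizing each 3-vector block by damped fixed-point
iteration on u = softmax(−(K_n u + c)); it terminates on a primal-dual
gap below the Newton tolerance.  The two agree to |Δω|∞ < 1e-4 on
random instances (tested), and either can be selected with
`solver="newton" | "sdca"`.

## Selection

The final decision rule thresholds posterior inclusion probabilities
at 0.5 (the EMVS posterior-mode convention): a common variant is
selected iff p_s ≥ 0.5, a rare variant iff g_r·q_rj ≥ 0.5 — the joint
product, so an excluded region suppresses its members — and a region
iff g_r ≥ 0.5 or any member variant is selected.  Coefficients are
reported from the converged ω.

## Tuning v₀ and v₂

One full cold-started fit per grid value over the default 11-point
log-spaced grid 1e-4 … 0.1 (all below the slabs).  Stage 1 ties
v₀ = v₂ and stage 2 re-sweeps v₂ with v₀ fixed.  Adjacent grid points
are *compatible* when they select the identical variant set and every
selected coefficient moves by < 10% relatively; the chosen value is
the smallest inside the first maximal run of ≥ 3 compatible points,
falling back to the longest run (flagged unstable) if none exists.
Cold starts are deliberate: the tuned value is later used in cold
fits, and warm-started paths exhibit hysteresis (a dense-selection
basin persists along the grid) that misrepresents cold-fit behavior; a
warm mode exists for fast exploratory sweeps.  Stage-1 stability is
judged on all variants jointly.  With no rare variants stage 2 is
skipped and v₂ tracks v₀.

Small-panel behavior, stated openly: on panels of ~10² rare variants
the identical-set stability criterion tends to land on the fully
sparse plateau that begins immediately after the exclusion boundary of
the strongest rare variant, because intermediate operating points have
flickering marginal members and are never 3-point stable.  Tuned fits
on such panels therefore favor specificity: weakly-supported rare
variants (association z ≈ 4 and below) sit at or past the tuned
exclusion boundary and are selected only sporadically.  On large
panels (thousands of rare variants) the stable operating point sits at
smaller v₂ and retains such variants; the default (untuned) spikes
correspond to that more sensitive operating point.  Users of small
panels who care about borderline rare variants should inspect the
stage-2 path rather than trust the automatic window.

## Synthetic data

The generator emulates an admixed population at the level that matters
for the method: per-site allele frequencies in two subpopulations
(25% / 75% admixture weights), with the *weighted MAF* (admixture-
weighted, folded to ≤ 0.5) driving rare/common classification and
effect sizes.  Defaults: 12 regions of 2,700 bp; per region 4 common
sites (weighted MAF ~ U(0.05, 0.5)) and 8 rare sites (3 log-uniform in
[1e-4, 1e-3), 3 in [1e-3, 1e-2), 2 in [1e-2, 5e-2)); one region-1 rare
site pinned at weighted MAF 0.026.  Subpopulation frequencies spread
multiplicatively around the target (±50%) with the second
subpopulation absorbing the remainder so the weighted MAF is exact.

Disease: logit P(y=1) = α₀ + Σ β_i G_i with α₀ = −2.2 (prevalence
≈ 10%).  The causal architecture places +0.9 on the most common site
of region 3 and −0.9 on that of region 6 (the most common site, so
that ascertainment-induced allele-frequency shifts cannot push a
designed common variant below the 0.05 classification threshold), and
rare effects ±0.4·|log₁₀ MAF| — rarer variants act more strongly.  By
default each of regions 1–6 receives two causal rare sites (one per
sub-0.01 bin) plus the pinned MAF-0.026 site (risk-increasing), giving
6 causal and 6 null regions; a pool-wide rule selecting a 5% fraction
of all sites with weighted MAF < 3% is available instead
(`rare_scheme="fraction"`).  Signs split equally, with a seeded coin
for odd counts.

Trios are ascertained on the affected child by rejection sampling with
the *exact* logistic probability (no rare-disease approximation): both
parents are drawn from one subpopulation (admixture acts at the family
level, i.e. between families), one haplotype per parent is
transmitted, and the candidate is accepted with probability P(y=1).
A master seed spawns one independent stream per family, so datasets
are reproducible and order-independent.  Sample MAFs and polymorphism
flags come from the 4N parental haplotypes.

What the generator does *not* emulate: linkage disequilibrium is off
by default (an optional founder-copying mode exists for block-LD
experiments), so false positives caused by high LD with causal sites —
a real failure mode on dense panels — do not appear in these tests;
the frequency spectrum is parametric rather than coalescent, with no
recombination map or demographic history; and panels are two orders of
magnitude smaller than a sequencing region.  Passing tests therefore
demonstrate correctness of the machinery and calibration of the study
design at desk scale, not field performance on dense real data.

## Replicate-study protocol and metrics

`run_study` fixes one pool and causal model, simulates seeded
replicates, classifies variants by the **median** in-sample MAF across
replicates (threshold 0.05, strict `<` for rare) so every replicate
shares one layout, tunes (v₀, v₂) on the first replicate, and fits the
rest with the tuned prior.  Metrics: WACAP = ½[mean_r P(selected |
associated) + mean_r P(unselected | unassociated)] with per-region
probabilities estimated across replicates; ATPR/AFPR average
per-replicate rates whose denominators count only variants polymorphic
in that replicate (or in every replicate, for the cross-dataset
convention); zero-denominator replicates are skipped with a warning.
A MAF-stratified table reports both rates in bins (0, 0.01), [0.01,
0.05), [0.05, ∞).

The acceptance script runs this protocol at desk scale: 10 replicates
of 1,500 trios (tuned) for common-variant selection, 25 replicates of
350 trios (tuned) for region-level WACAP, and 25 replicates of 1,500
trios under the default priors for the pinned MAF-0.026 rare variant —
the default spikes, not the tuned ones, because on this panel size the
tuned operating point is the sparse plateau (see tuning, above).
Problem sizes were chosen so the full suite runs in minutes on one
CPU.

## Numerical choices

Probabilities are computed in log space end-to-end; clipping is used
only for display.  Beta hyper-prior terms with unit hyper-parameters
are skipped in the objective so boundary mixing weights cannot produce
0·(−∞).  The observed objective omits constant Beta normalizers (only
differences matter).  Monomorphic columns are flagged only when the
allele is entirely absent (all-zero contrasts with alleles present are
merely uninformative and kept).  Region maps accept variant-id TSV or
0-based half-open BED against 1-based VCF positions.  A `--min-mac`
flag can drop singleton/doubleton/tripleton sites (default keeps
everything).
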