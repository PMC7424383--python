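# Methods

## Scope and data model

The package operates on three genes × samples count matrices (mRNA, lncRNA,
miRNA) with tumor/normal labels, a clinical table (sample, overall-survival
days, event flag) and a miRNA→target interaction table with class-tagged
targets. Biotype annotation and interaction prediction are deliberately out
of scope: the caller supplies lncRNA and mRNA matrices separately, and the
interaction table replaces any online binding-site matching. When assays
profile different sample sets (typical for RNA-seq vs miRNA-seq), any
cross-assay computation uses the intersection of sample ids and requires at
least 3 shared samples; the intersection size is logged.

## Differential expression

Counts are transformed to logCPM with a half-count offset,
log2((c+0.5)/(L+1)·10⁶), which keeps zeros finite and is exact enough for
two-group testing without precision weights (weighting is an efficiency
refinement; the test structure and thresholds are what matter here). Per
gene, the tumor−normal mean difference on logCPM is the logFC (so "up"
means higher in tumor), with pooled residual variance s²_g on
d = n₁+n₂−2 df. Variances are shrunk by empirical Bayes: assuming
s²_g ~ s₀²·F(d, d₀), the moments of log s² give d₀ via the trigamma inverse
(Newton iteration) and s₀² via the digamma-corrected mean. When the observed
spread of log s² does not exceed chi-square sampling noise, d₀ = ∞ and every
gene collapses to the mean variance — the moderated t then equals the
ordinary t. P-values use Student t on d + d₀ df (normal reference when
d₀ = ∞); adjustment is Benjamini–Hochberg. Calls require adj.P < 0.01 and
|logFC| > 1; both gates are configurable (`RunConfig.de_adj_p`,
`de_abs_logfc`).

## ceRNA pair scoring

Candidate pairs are every (DE lncRNA, DE mRNA) sharing at least one miRNA
in the interaction table; pairs with zero shared miRNAs are never scored.

- **Overlap test.** With universe size N, K miRNAs targeting the lncRNA,
  n targeting the mRNA, k shared: p = P(X ≥ k), X ~ Hypergeometric(N, K, n),
  used raw at 0.05 (a BH option exists but is off, keeping the published
  cut-off semantics). The default universe is the miRNAs of the
  interaction table after restriction to DE miRNAs, matching the
  DE-first pipeline order; `universe="all"` uses the whole table instead.
- **Co-expression.** Pearson r over the matched tumor samples (pooled
  samples optional), two-sided p from t = r√((n−2)/(1−r²)); the pair needs
  r > 0 and p < 0.05. Tumor-only is the default because ceRNA activity is
  asserted in the tumor state.
- **Regulation similarity.** For the M shared miRNAs,
  regsim = 1 − (1/M)·Σ_k [|r_lk − r_gk| / (|r_lk| + |r_gk|)]^M with
  r_lk = corr(m_k, l), r_gk = corr(m_k, g). A 0/0 term counts as 0
  (identical null profiles); a miRNA with zero expression variance is
  dropped with a warning, reducing M. The score lies in [0, 1]: 1 for
  identical correlation profiles, 0 when every shared miRNA correlates with
  opposite sign and equal magnitude. The exponent M is the published form;
  `regsim_exponent="1"` gives the plain normalized-distance average for
  sensitivity analysis. The pass rule is regsim > 0, so only exactly
  opposite profiles are excluded — the discriminating filters in practice
  are the overlap and co-expression gates.
- No sign constraint is placed on the miRNA–target correlations by default
  (`require_negative_mirna_corr` adds the canonical both-negative
  constraint as an option).

Passing pairs expand into an undirected graph with miRNA–lncRNA and
miRNA–mRNA edges (every edge has a miRNA endpoint by construction, so the
graph is bipartite between miRNAs and targets). Hubs are the top
`hub_k`=10 nodes by degree, ties broken lexicographically for determinism.
Triplet extraction returns all (lncRNA, m_k, mRNA) of passing pairs, each
flagged by whether all three members are hubs (the hub sub-network view).

## Survival analysis

- **Median split:** high = strictly above the median, ties to low
  (a deterministic convention; with continuous scores the groups differ by
  at most one patient).
- **Kaplan–Meier:** product-limit Ŝ(t) = Π(1 − d_t/n_t) over distinct event
  times, exactly the brute-force risk-table product (tested as such).
- **Log-rank:** (ΣO₁t − E₁t)² / ΣV_t with E₁t = d_t·n₁t/n_t and
  hypergeometric variance V_t = d_t(n_t−d_t)n₁t·n₂t/(n_t²(n_t−1)); p from
  χ²₁. Cross-checked against lifelines.
- **Cox model:** partial likelihood with Breslow tie handling (ties are
  measure-zero in the continuous-time generator), maximized by
  Newton–Raphson with step-halving, tolerance ‖grad‖ < 1e-8, at most 100
  iterations. The step acceptance tolerates ~1e-10 relative likelihood
  noise so the iteration terminates cleanly at machine precision. Exact
  collinearity is detected up front from the covariate covariance rank and
  reported with the offending feature; diverging coefficients (|β| > 50 on
  standardized covariates) raise a separation error. Coefficients agree
  with lifelines to ~1e-7 on continuous-time data.
- **Triplet risk analysis:** the three covariates are the tumor-sample
  logCPM of the lncRNA, miRNA and mRNA, standardized (mean 0, sd 1) over
  the ≥ 20 patients with clinical records; risk score RS = Σβᵢxᵢ; median
  split; log-rank. No clinical covariates enter the model, matching the
  risk-score formula's content. Single-RNA (hub) survival uses a median
  split on that RNA's expression — the field-standard choice where the
  cut-point method is otherwise unstated.

## Enrichment

Over-representation of a DE list in user-supplied flat gene sets (GMT):
each set is intersected with the universe (default: all genes of the
expression matrix), p = P(X ≥ k) from the same hypergeometric tail used for
pair overlap (one code path), q by BH across the tested sets, and
significance gated at q < 0.01 with raw p retained. Ontology structure is
ignored; outputs are flat term lists.

## Synthetic cohorts

`simulate_cohort` emulates the *structure* of a paired tumor/normal
RNA-seq + miRNA-seq study, not any particular dataset:

- **Counts:** negative binomial via gamma–Poisson with Var = μ + φμ²,
  φ = 0.2 (typical bulk RNA-seq overdispersion); baseline log2 means
  uniform on [3, 9] (≈8–512 counts).
- **Differential expression:** 10% of genes per class get a ±2 log2 shift
  in tumor samples (sign random); these and the triplet members are the DE
  truth.
- **Planted triplets:** each planted pair shares 3 miRNAs — real ceRNA
  pairs share several response elements, and a single shared miRNA can
  never reach overlap significance in a small universe. A per-tumor-sample
  latent factor A_s ~ N(0,1) enters the log2 mean with +1·A_s for the
  lncRNA and mRNA and −1·A_s for the shared miRNAs, inducing positive
  lncRNA–mRNA and negative miRNA–target correlations while keeping NB
  count marginals approximately intact. Triplet members additionally carry
  the ±2 DE shift (lncRNA/mRNA up, miRNAs down) so they survive the
  DE-first restriction.
- **Decoy interactions:** 50 random miRNA–target records drawn from a pool
  of 15 decoy miRNAs. The pool concentrates targeting the way real
  miRNAs do (hundreds of targets each), which guarantees decoy pairs with
  shared miRNAs actually exist at desk scale to exercise the filters.
- **Survival:** exponential with hazard h₀·exp(Σβᵢxᵢ), h₀ = 10⁻³/day
  (median ≈ 693 days), β = (0.8, −0.8, 0.8) on the standardized logCPM of
  the first triplet's members; censoring independent uniform on
  [0, 3.2/h₀], giving ≈30% censoring. With no triplets or zero β the
  hazard is flat (null cohort).
- Defaults are 100 tumor / 50 normal samples and 400/150/80
  mRNA/lncRNA/miRNA genes — a deliberate desk-scale cohort on which every
  stage completes in seconds while keeping group sizes large enough for
  stable variance estimation and ≥ 60 observed events.

What the generator does **not** emulate: library-size and GC biases, batch
effects, count correlation beyond the planted latent factors, non-
proportional hazards, informative censoring. Passing tests therefore show
the machinery is correct and calibrated under the stated model, not that
the biological filters are well-powered on any real cohort.

## Validation design and known limitations

- The combinatorial primitives (hypergeometric tail, KM product-limit) are
  tested for exact agreement with enumeration/brute-force oracles; the
  fitted procedures (moderated t, log-rank, Cox) are tested by calibration
  under the null and recovery of planted effects, with lifelines as an
  independent reference implementation where one exists.
- Per-seed Cox estimates at n = 500 have SE ≈ 0.06, so single-seed checks
  use ~3-SE bands while the headline bias/RMSE criteria aggregate 50 seeds
  at n = 1000.
- **Refit-then-split optimism.** The triplet analysis fits β on the same
  cohort whose fitted risk score is then median-split and log-rank tested.
  Because the fitted score is the covariate direction most associated with
  the observed survival — including its noise — the log-rank p on that
  split is anti-conservative: under a survival-independent null the
  measured rejection rate at α = 0.05 is ≈ 0.2 with three covariates (a
  ~3-df maximization referred to a 1-df reference), while a non-fitted
  single-gene median split on the same cohorts is calibrated (≈ 0.05).
  This optimism is inherent to the published procedure, which the package
  reproduces faithfully; treat triplet log-rank p-values as descriptive
  ranking scores, not calibrated tests, or validate β on held-out data.
- Degenerate inputs fail loudly and specifically: all-zero libraries,
  constant splitting variables, collinear Cox designs, empty filter
  output, zero-variance correlation vectors each raise a dedicated error.
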