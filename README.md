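# cerna-prognost

Competing-endogenous-RNA (ceRNA) network discovery and survival prognosis
for tumor/normal expression cohorts.

lncRNAs can act as molecular sponges: a lncRNA and an mRNA that share miRNA
response elements compete for the same miRNAs, so the lncRNA indirectly
de-represses the mRNA. This package identifies such lncRNA–miRNA–mRNA axes
from bulk RNA-seq + miRNA-seq tumor cohorts (the setting of TCGA-style lung
adenocarcinoma studies) and asks whether they carry prognostic information.
It is a library first — `import cerna_prognost` — with a thin
`cerna-prognost` CLI and narrative scripts under `examples/`.

## The method

1. **Differential expression.** Counts are normalized to
   logCPM = log2((count + 0.5)/(libsize + 1) × 10⁶) and each gene is tested
   tumor-vs-normal with a moderated t-statistic: per-gene variances s²_g are
   shrunk toward an empirical-Bayes prior (d₀, s₀²) estimated by method of
   moments on log s², giving t̃_g = logFC_g / (s̃_g·√(1/n₁+1/n₂)) on
   d_g + d₀ df. Genes pass at BH-adjusted P < 0.01 and |logFC| > 1.
2. **ceRNA pair scoring.** For each DE lncRNA l and DE mRNA g sharing ≥ 1
   miRNA in the interaction table, three filters apply:
   - *shared-miRNA overlap*: P(X ≥ k), X ~ Hypergeometric(N, K, n) over the
     miRNA universe, p < 0.05;
   - *co-expression*: Pearson r(l, g) > 0 with p < 0.05 over tumor samples;
   - *regulation similarity* over the M shared miRNAs m_k:

     ```
     regsim(l, g) = 1 − (1/M) Σ_k [ |corr(m_k,l) − corr(m_k,g)|
                                    / (|corr(m_k,l)| + |corr(m_k,g)|) ]^M
     ```

     required > 0 (1 = identical correlation profiles).
3. **Network & hubs.** Passing pairs expand into miRNA–lncRNA and
   miRNA–mRNA edges; hubs are the top-k nodes by degree.
4. **Prognosis.** For a triplet (l, m, g), a multivariate Cox
   proportional-hazards model (Breslow ties, Newton–Raphson) on the
   standardized tumor expressions gives β; patients are split at the median
   risk score RS = Σᵢ βᵢxᵢ and compared by the log-rank test. Single hub
   RNAs get a median-split Kaplan–Meier analysis.

A synthetic-cohort generator (`simulate_cohort`) provides negative-binomial
counts with planted DE genes, planted ceRNA triplets (latent-factor coupled)
and triplet-driven exponential survival, so every stage has a recoverable
ground truth.

## Worked example

```python
from cerna_prognost import (CeRNATriplet, log_cpm, simulate_cohort,
                            triplet_risk_analysis)

matrices, db, clinical, truth = simulate_cohort(seed=4)
logcpm = {cls: log_cpm(m) for cls, m in matrices.items()}
lnc, mir, mrna = truth.planted_triplets[truth.designated_triplet]
model = triplet_risk_analysis(CeRNATriplet(lnc, mir, mrna),
                              logcpm["lncRNA"], logcpm["miRNA"],
                              logcpm["mRNA"], clinical)
print(model.betas, model.logrank_p)
```

prints (see `examples/04_triplet_prognosis.py`):

```
beta[LNC00000] = +0.933
beta[miR-0000] = -0.776
beta[MRNA00000] = +0.828
log-rank chi2 = 65.18, p = 6.85e-16
```

Survival in this cohort was generated from that triplet with coefficients
(+0.8, −0.8, +0.8); the fit recovers the sign pattern and the high/low
median-risk groups separate sharply. `examples/` contains one such script
per capability (simulation, DE, network, prognosis, enrichment), and

```sh
cerna-prognost --seed 7 --out-dir run run-all --simulate
```

runs every stage end-to-end, writing result TSVs and a deterministic
`run_summary.json`.

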