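"""Cox risk-score prognosis of a ceRNA triplet.

Fits a multivariate Cox model on the triplet's standardized tumor
expressions, computes risk scores RS = sum_i beta_i * x_i, splits patients
at the median risk and compares survival with the log-rank test.
"""
from cerna_prognost import CeRNATriplet, log_cpm, simulate_cohort, triplet_risk_analysis

matrices, _, clinical, truth = simulate_cohort(seed=4)
logcpm = {cls: log_cpm(m) for cls, m in matrices.items()}

lnc, mir, mrna = truth.planted_triplets[truth.designated_triplet]
model = triplet_risk_analysis(
    CeRNATriplet(lnc, mir, mrna),
    logcpm["lncRNA"], logcpm["miRNA"], logcpm["mRNA"], clinical,
)

for feature, beta in zip(model.features, model.betas):
    print(f"beta[{feature}] = {beta:+.3f}")
print(f"median risk score: {model.median_rs:.3f}")
print(f"high-risk group: {len(model.split.high)} patients, "
      f"low-risk: {len(model.split.low)}")
print(f"log-rank chi2 = {model.logrank_stat:.2f}, p = {model.logrank_p:.2e}")
# Survival in this cohort was generated from this triplet, so the fitted
# betas echo the generator's (+, -, +) pattern and the high/low risk groups
# separate sharply (small log-rank p).
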