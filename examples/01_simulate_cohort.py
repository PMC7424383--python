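"""Generate a synthetic tumor/normal multi-omic cohort with known truth.

The generator emulates a paired RNA-seq + miRNA-seq tumor study: negative-
binomial counts, planted differentially expressed genes, planted ceRNA
triplets (shared miRNAs, positive lncRNA-mRNA coupling) and survival times
driven by the first triplet.
"""
from cerna_prognost import simulate_cohort

matrices, db, clinical, truth = simulate_cohort(
    n_tumor=60, n_normal=30, n_mrna=200, n_lncrna=80, n_mirna=40,
    n_triplets=2, seed=1,
)

for cls, m in matrices.items():
    print(f"{cls}: {m.n_genes} genes x {m.n_samples} samples "
          f"({len(m.samples_in_group('tumor'))} tumor)")
print(f"interaction DB: {len(db)} miRNA-target records")
print(f"clinical: {len(clinical.df)} patients, "
      f"{int(clinical.df['event'].sum())} deaths observed")
print(f"planted triplets (lncRNA, miRNA, mRNA): {truth.planted_triplets}")
# The planted triplets are the ground truth the downstream stages should
# recover; the first one also drives the simulated survival times.
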