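"""Synthetic tumor/normal multi-omic cohort with known ground truth.

The generator emulates the structure of a paired bulk RNA-seq + miRNA-seq
tumor study: negative-binomial counts (Var = mu + phi*mu^2) for mRNA, lncRNA
and miRNA matrices, a fraction of genes per class with a planted tumor-vs-
normal log2 fold change, planted ceRNA triplets coupled through a per-tumor-
sample latent factor (raising lncRNA and mRNA means, lowering the shared
miRNA's mean, hence positive lncRNA-mRNA and negative miRNA-target
correlations), and exponential survival times driven by one designated
triplet's standardized expressions with independent uniform censoring.

All randomness flows from a single integer seed, so identical seeds give
bitwise-identical cohorts.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ClinicalTable, ExpressionMatrix, InteractionDB
from .diffexpr import log_cpm
from .errors import ConfigError


@dataclass
class SimulationParams:
    """Knobs of the cohort generator.

    dispersion: NB overdispersion phi in Var = mu + phi*mu^2 (0.2 is typical
    for bulk RNA-seq). base_log2_mean_range: baseline per-gene log2 mean
    counts, drawn uniformly. de_fraction / de_logfc: fraction of each class
    with a planted tumor shift of +/- de_logfc (log2). latent_sd and
    latent_loading: per-tumor-sample latent factor A_s ~ N(0, latent_sd^2)
    enters the log2 mean with +loading for lncRNA/mRNA and -loading for the
    shared miRNAs of a planted triplet. Each planted pair shares
    mirnas_per_triplet miRNAs, since real ceRNA pairs share several response
    elements and a single shared miRNA is never a significant hypergeometric
    overlap in a small universe. n_decoys random interactions are drawn
    from a small pool of promiscuous decoy miRNAs (real miRNAs target many
    transcripts, and a pool guarantees decoy pairs that share a miRNA exist
    at desk scale). cox_betas drive the exponential hazard
    h0 * exp(sum beta_i x_i) of the designated (first) triplet; censoring is
    uniform on [0, censor_max] chosen for roughly 30% censoring.
    """

    dispersion: float = 0.2
    base_log2_mean_range: tuple[float, float] = (3.0, 9.0)
    de_fraction: float = 0.1
    de_logfc: float = 2.0
    latent_sd: float = 1.0
    latent_loading: float = 1.0
    mirnas_per_triplet: int = 3
    n_decoys: int = 50
    decoy_mirna_pool: int = 15
    cox_betas: tuple[float, float, float] = (0.8, -0.8, 0.8)
    baseline_hazard: float = 1e-3  # per day; median survival ~693 days
    censor_max_factor: float = 3.2  # censor_max = factor / baseline_hazard


@dataclass
class SimulationTruth:
    """Ground truth of one simulated cohort."""

    de_genes: dict[str, dict[str, float]]  # class -> {gene: signed logFC}
    planted_triplets: list[tuple[str, str, str]]  # (lncRNA, first miRNA, mRNA)
    triplet_mirnas: list[list[str]]  # all shared miRNAs per planted pair
    designated_triplet: int  # index of the survival-driving triplet (or -1)
    cox_betas: tuple[float, ...]
    rng_seed: int
    latent_factors: pd.DataFrame = field(default_factory=pd.DataFrame)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """NB(mu, phi) with Var = mu + phi*mu^2 via the gamma-Poisson mixture."""
    if phi <= 0:
        return rng.poisson(mu)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mu))


def simulate_cohort(
    n_tumor: int = 100,
    n_normal: int = 50,
    n_mrna: int = 400,
    n_lncrna: int = 150,
    n_mirna: int = 80,
    n_triplets: int = 3,
    params: SimulationParams | None = None,
    seed: int = 0,
) -> tuple[
    dict[str, ExpressionMatrix], InteractionDB, ClinicalTable, SimulationTruth
]:
    """Generate a full cohort: three count matrices, interactions, survival.

    Returns ({'mRNA': m, 'lncRNA': m, 'miRNA': m}, InteractionDB,
    ClinicalTable, SimulationTruth). With ``n_triplets = 0`` or all-zero
    ``cox_betas`` survival is independent of expression (a null cohort).
    """
    params = params or SimulationParams()
    if n_tumor < 3 or n_normal < 3:
        raise ConfigError("need >=3 tumor and >=3 normal samples")
    if n_triplets < 0:
        raise ConfigError("n_triplets must be >= 0")
    n_planted_mirs = n_triplets * params.mirnas_per_triplet
    if n_triplets > min(n_mrna, n_lncrna) or n_planted_mirs > n_mirna:
        raise ConfigError(
            f"n_triplets={n_triplets} (x{params.mirnas_per_triplet} miRNAs) "
            "exceeds a class size"
        )
    rng = np.random.default_rng(seed)
    tumor_ids = [f"T{i:04d}" for i in range(n_tumor)]
    normal_ids = [f"N{i:04d}" for i in range(n_normal)]
    samples = tumor_ids + normal_ids
    group = pd.Series(
        ["tumor"] * n_tumor + ["normal"] * n_normal, index=samples
    )
    ids = {
        "mRNA": [f"MRNA{i:05d}" for i in range(n_mrna)],
        "lncRNA": [f"LNC{i:05d}" for i in range(n_lncrna)],
        "miRNA": [f"miR-{i:04d}" for i in range(n_mirna)],
    }
    sizes = {"mRNA": n_mrna, "lncRNA": n_lncrna, "miRNA": n_mirna}

    # planted triplet members come first within each class id list; triplet j
    # owns miRNAs [j*mpt, (j+1)*mpt) and is named after the first of them
    mpt = params.mirnas_per_triplet
    shared_mirs = [
        ids["miRNA"][j * mpt : (j + 1) * mpt] for j in range(n_triplets)
    ]
    triplets = [
        (ids["lncRNA"][j], shared_mirs[j][0], ids["mRNA"][j])
        for j in range(n_triplets)
    ]
    planted = {
        "lncRNA": [t[0] for t in triplets],
        "miRNA": [m for ms in shared_mirs for m in ms],
        "mRNA": [t[2] for t in triplets],
    }

    # per-tumor-sample latent factor, one per triplet
    latent = pd.DataFrame(
        rng.normal(0.0, params.latent_sd, size=(n_triplets, n_tumor)),
        index=[f"triplet{j}" for j in range(n_triplets)],
        columns=tumor_ids,
    )

    de_truth: dict[str, dict[str, float]] = {c: {} for c in ids}
    matrices: dict[str, ExpressionMatrix] = {}
    for cls in ("mRNA", "lncRNA", "miRNA"):
        n_genes = sizes[cls]
        lo, hi = params.base_log2_mean_range
        base = rng.uniform(lo, hi, size=n_genes)
        # log2 mean per gene x sample
        log2_mu = np.tile(base[:, None], (1, len(samples)))
        is_tumor = np.array([g == "tumor" for g in group])

        # planted triplet members: fixed DE shift plus latent coupling
        sign = -1.0 if cls == "miRNA" else 1.0
        per_triplet = mpt if cls == "miRNA" else 1
        for j in range(n_triplets):
            shift = sign * params.de_logfc
            a_j = latent.iloc[j].to_numpy()
            for gi in range(j * per_triplet, (j + 1) * per_triplet):
                log2_mu[gi, is_tumor] += shift
                log2_mu[gi, is_tumor] += (
                    sign * params.latent_loading * a_j
                )
                de_truth[cls][ids[cls][gi]] = shift

        # ordinary DE genes among the remainder
        pool_start = n_triplets * per_triplet
        n_de = int(round(params.de_fraction * n_genes))
        pool = np.arange(pool_start, n_genes)
        n_de = min(n_de, len(pool))
        if n_de > 0 and params.de_logfc != 0:
            de_idx = rng.choice(pool, size=n_de, replace=False)
            signs = rng.choice([-1.0, 1.0], size=n_de)
            for gi, s in zip(de_idx, signs):
                log2_mu[gi, is_tumor] += s * params.de_logfc
                de_truth[cls][ids[cls][gi]] = s * params.de_logfc

        mu = np.exp2(log2_mu)
        counts = _nb_draw(rng, mu, params.dispersion)
        matrices[cls] = ExpressionMatrix(
            values=pd.DataFrame(counts, index=ids[cls], columns=samples),
            rna_class=cls,
            group=group,
            scale="counts",
        )

    # interaction DB: planted records plus random decoys
    records = []
    for j, (lnc, _mir, mrna) in enumerate(triplets):
        for mir in shared_mirs[j]:
            records.append((mir, lnc, "lncRNA"))
            records.append((mir, mrna, "mRNA"))
    decoy_mirs = [m for m in ids["miRNA"] if m not in planted["miRNA"]]
    pool_n = min(params.decoy_mirna_pool, len(decoy_mirs))
    if params.n_decoys > 0 and pool_n > 0:
        pool_mirs = list(rng.choice(decoy_mirs, size=pool_n, replace=False))
        free = {
            "lncRNA": [g for g in ids["lncRNA"] if g not in planted["lncRNA"]],
            "mRNA": [g for g in ids["mRNA"] if g not in planted["mRNA"]],
        }
        seen = set()
        attempts = 0
        while len(seen) < params.n_decoys and attempts < params.n_decoys * 20:
            attempts += 1
            mir = pool_mirs[rng.integers(len(pool_mirs))]
            cls = "lncRNA" if rng.random() < 0.5 else "mRNA"
            tgt = free[cls][rng.integers(len(free[cls]))]
            if (mir, tgt) in seen:
                continue
            seen.add((mir, tgt))
            records.append((mir, tgt, cls))
    db = InteractionDB(
        pd.DataFrame(records, columns=["mirna", "target", "target_class"])
    )

    # survival for tumor samples, driven by the designated (first) triplet
    h0 = params.baseline_hazard
    betas = np.asarray(params.cox_betas, dtype=float)
    if n_triplets > 0 and np.any(betas != 0):
        designated = 0
        lnc, mir, mrna = triplets[0]
        feats = []
        for gid, cls in ((lnc, "lncRNA"), (mir, "miRNA"), (mrna, "mRNA")):
            lc = log_cpm(matrices[cls]).values.loc[gid, tumor_ids]
            feats.append((lc - lc.mean()) / lc.std(ddof=1))
        x = np.vstack([f.to_numpy() for f in feats]).T  # n_tumor x 3
        hazard = h0 * np.exp(x @ betas)
    else:
        designated = -1
        hazard = np.full(n_tumor, h0)
    t_event = rng.exponential(1.0 / hazard)
    c_max = params.censor_max_factor / h0
    t_cens = rng.uniform(0.0, c_max, size=n_tumor)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-3)  # time_days must be strictly positive
    clin = ClinicalTable(
        pd.DataFrame(
            {"time_days": time, "event": event},
            index=pd.Index(tumor_ids, name="sample_id"),
        )
    )

    truth = SimulationTruth(
        de_genes=de_truth,
        planted_triplets=triplets,
        triplet_mirnas=shared_mirs,
        designated_triplet=designated,
        cox_betas=tuple(betas),
        rng_seed=seed,
        latent_factors=latent,
    )
    return matrices, db, clin, truth


def simulate_survival(
    x: np.ndarray,
    betas: np.ndarray,
    baseline_hazard: float = 1e-3,
    censor_max_factor: float = 3.2,
    seed: int = 0,
) -> ClinicalTable:
    """Exponential survival with hazard h0*exp(x @ beta), uniform censoring.

    A small helper for calibration studies: ``x`` is patients x covariates
    (already standardized), returns a ClinicalTable for patients P0000...
    """
    rng = np.random.default_rng(seed)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != len(np.atleast_1d(betas)):
        x = x.T
    hazard = baseline_hazard * np.exp(x @ np.asarray(betas, dtype=float))
    t_event = rng.exponential(1.0 / hazard)
    t_cens = rng.uniform(0.0, censor_max_factor / baseline_hazard, size=len(hazard))
    time = np.maximum(np.minimum(t_event, t_cens), 1e-3)
    event = (t_event <= t_cens).astype(int)
    ids = [f"P{i:04d}" for i in range(len(hazard))]
    return ClinicalTable(
        pd.DataFrame(
            {"time_days": time, "event": event}, index=pd.Index(ids, name="sample_id")
        )
    )


def truth_table(truth: SimulationTruth) -> pd.DataFrame:
    """Flatten the ground truth for TSV export."""
    rows = []
    for cls, genes in truth.de_genes.items():
        for gid, lfc in sorted(genes.items()):
            rows.append({"kind": "de_gene", "id": gid, "detail": cls,
                         "value": lfc})
    for j, (l, m, g) in enumerate(truth.planted_triplets):
        rows.append({
            "kind": "triplet", "id": f"{l}|{m}|{g}",
            "detail": "designated" if j == truth.designated_triplet else "planted",
            "value": float(j),
        })
    return pd.DataFrame(rows, columns=["kind", "id", "detail", "value"])
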