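"""Differential expression between tumor and normal samples.

Counts are normalized to log2 counts-per-million (logCPM) and each gene is
tested with a moderated t-statistic: per-gene residual variances are shrunk
toward a common prior estimated by empirical Bayes, which stabilises the
denominator at small sample sizes. Genes are called up/down at the configured
adjusted-p and |logFC| cut-offs (defaults: adj.P < 0.01, |logFC| > 1, with
logFC = tumor minus normal on the log2 scale).
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import t as t_dist

from .containers import ExpressionMatrix, RunConfig
from .errors import NormalizationError, ValidationError
from .stats import bh_adjust


def log_cpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2((count + 0.5) / (library size + 1) * 1e6), per sample.

    The half-count offset keeps zeros finite; the +1 on the library keeps the
    transform defined for tiny libraries.
    """
    if m.scale != "counts":
        raise ValidationError("log_cpm expects a counts-scale matrix")
    lib = m.values.sum(axis=0)
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise NormalizationError(f"all-zero sample columns: {bad[:5]}")
    vals = np.log2((m.values + 0.5) / (lib + 1.0) * 1e6)
    return ExpressionMatrix(
        values=vals, rna_class=m.rna_class, group=m.group, scale="logCPM"
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _fit_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Empirical-Bayes prior (d0, s0^2) for gene variances.

    Assumes s2_g ~ s0^2 * F(df, d0); moments of log s2 give d0 via the
    trigamma inverse and s0^2 via the digamma-corrected mean (method of
    moments on the log scale).
    """
    pos = s2[s2 > 0]
    if pos.size < 2:
        return np.inf, float(pos.mean()) if pos.size else 1.0
    z = np.log(pos)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    evar = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(np.mean(e) + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # no excess spread beyond chi-square sampling noise: variances are
        # effectively common, so shrink all the way to their mean
        d0 = np.inf
        s0_sq = float(pos.mean())
    return d0, s0_sq


def moderated_t_test(m: ExpressionMatrix) -> pd.DataFrame:
    """Two-group moderated t-test per gene on a logCPM matrix.

    Returns a DataFrame (gene_id, logFC, stat, p) where logFC is the
    tumor-minus-normal mean difference, stat the moderated t and p its
    two-sided p-value on df + d0 degrees of freedom.
    """
    if m.scale != "logCPM":
        raise ValidationError("moderated_t_test expects a logCPM matrix")
    m.require_two_per_group()
    x_t = m.values[m.samples_in_group("tumor")].to_numpy()
    x_n = m.values[m.samples_in_group("normal")].to_numpy()
    n1, n2 = x_t.shape[1], x_n.shape[1]
    df = n1 + n2 - 2
    if df < 1:
        raise ValidationError("zero residual df: need >=2 samples per group")
    logfc = x_t.mean(axis=1) - x_n.mean(axis=1)
    ss = x_t.var(axis=1, ddof=1) * (n1 - 1) + x_n.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / df
    d0, s0_sq = _fit_variance_prior(s2, df)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = 1e6  # effectively normal reference
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = df + d0
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    stat = logfc / se
    p = 2.0 * t_dist.sf(np.abs(stat), df_total)
    return pd.DataFrame(
        {"gene_id": m.gene_ids, "logFC": logfc, "stat": stat, "p": p}
    )


def call_de(m: ExpressionMatrix, cfg: RunConfig | None = None) -> pd.DataFrame:
    """Full DE table with BH-adjusted p and up/down/ns status.

    Accepts counts (normalized internally) or a ready logCPM matrix. Status:
    up if adj_p < de_adj_p and logFC > de_abs_logfc, down if adj_p < de_adj_p
    and logFC < -de_abs_logfc, else ns. All genes are returned.
    """
    cfg = cfg or RunConfig()
    if m.scale == "counts":
        m = log_cpm(m)
    res = moderated_t_test(m)
    res["adj_p"] = bh_adjust(res["p"].to_numpy())
    sig = res["adj_p"] < cfg.de_adj_p
    res["status"] = "ns"
    res.loc[sig & (res["logFC"] > cfg.de_abs_logfc), "status"] = "up"
    res.loc[sig & (res["logFC"] < -cfg.de_abs_logfc), "status"] = "down"
    return res


def de_gene_sets(de_table: pd.DataFrame) -> dict[str, set[str]]:
    """Split a DE table into {'up': ..., 'down': ..., 'de': union} id sets."""
    up = set(de_table.loc[de_table["status"] == "up", "gene_id"])
    down = set(de_table.loc[de_table["status"] == "down", "gene_id"])
    return {"up": up, "down": down, "de": up | down}
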