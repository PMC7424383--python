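"""Gene-set over-representation analysis (ORA).

A DE gene list is tested against each user-supplied gene set with the same
hypergeometric upper tail used for ceRNA pair overlap; q-values are BH across
all tested sets and the default significance gate is q < 0.01 (raw p is
retained in the output).
"""
from __future__ import annotations

import pandas as pd

from .containers import RunConfig
from .errors import ValidationError
from .stats import bh_adjust, hypergeom_tail


def ora(
    de_genes: set[str],
    sets: dict[str, set[str]],
    universe: set[str],
    cfg: RunConfig | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``de_genes`` in each set.

    Per set: p = P(X >= k), X ~ Hypergeom(|universe|, |set & universe|,
    |de_genes|). Returns a DataFrame sorted by p with columns
    (set_name, overlap_k, set_size, list_size, universe_size, p, q,
    significant).
    """
    cfg = cfg or RunConfig()
    if not universe:
        raise ValidationError("empty universe")
    if not de_genes:
        raise ValidationError("empty DE gene list")
    if not de_genes <= universe:
        extra = sorted(de_genes - universe)
        raise ValidationError(f"DE genes outside universe: {extra[:5]}")
    rows = []
    for name in sorted(sets):
        members = sets[name] & universe
        k = len(de_genes & members)
        p = hypergeom_tail(len(universe), len(members), len(de_genes), k)
        rows.append(
            {
                "set_name": name,
                "overlap_k": k,
                "set_size": len(members),
                "list_size": len(de_genes),
                "universe_size": len(universe),
                "p": p,
            }
        )
    res = pd.DataFrame(rows)
    if res.empty:
        return res
    res["q"] = bh_adjust(res["p"].to_numpy())
    res["significant"] = res["q"] < cfg.enrich_q
    return res.sort_values(["p", "set_name"], kind="stable").reset_index(drop=True)
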