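"""End-to-end orchestration: DE -> ceRNA network -> hubs -> triplet prognosis.

``run_all`` executes the stages in their canonical order — differential
expression per RNA class first, interactions restricted to the DE RNAs, pair
scoring, network/hub extraction, then per-triplet Cox risk-score survival —
writing every result table to the run directory plus a machine-readable JSON
summary. The summary is a pure function of (inputs, config, seed): identical
runs are byte-identical.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

from . import io as cio
from .cerna import (
    build_network,
    extract_triplets,
    pair_table,
    score_pairs,
    triplet_table,
)
from .containers import ClinicalTable, ExpressionMatrix, InteractionDB, RunConfig
from .diffexpr import call_de, de_gene_sets, log_cpm
from .enrichment import ora
from .errors import CernaError
from .prognosis import triplet_risk_analysis
from .simulate import SimulationParams, simulate_cohort, truth_table

log = logging.getLogger("cerna_prognost")


def _stage(name: str):
    """Decorator-free stage guard: re-raise with the stage name attached."""
    class _Ctx:
        def __enter__(self):
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, CernaError):
                raise type(exc)(f"[stage {name}] {exc}") from exc
            log.info("stage %s: done", name)
            return False

    return _Ctx()


def run_all(
    cfg: RunConfig,
    out_dir: str | Path,
    matrices: dict[str, ExpressionMatrix] | None = None,
    db: InteractionDB | None = None,
    clin: ClinicalTable | None = None,
    gene_sets: dict[str, set[str]] | None = None,
    simulate: bool = False,
    sim_params: SimulationParams | None = None,
    sim_sizes: dict | None = None,
) -> dict:
    """Run the full workflow and return the run summary dict.

    Either pass the three expression matrices, the interaction DB and the
    clinical table, or set ``simulate=True`` to generate a synthetic cohort
    with ``cfg.rng_seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": cfg.to_dict()}

    if simulate:
        with _stage("simulate"):
            sizes = sim_sizes or {}
            matrices, db, clin, truth = simulate_cohort(
                params=sim_params, seed=cfg.rng_seed, **sizes
            )
            for cls, m in matrices.items():
                cio.write_expression(m, out / f"counts_{cls}.tsv")
            cio.write_interactions(db, out / "interactions.tsv")
            cio.write_clinical(clin, out / "clinical.tsv")
            cio.write_table(truth_table(truth), out / "truth.tsv")
            summary["simulated"] = True
    if matrices is None or db is None or clin is None:
        raise CernaError("run_all needs matrices+db+clin or simulate=True")

    with _stage("diffexpr"):
        logcpm = {cls: log_cpm(m) for cls, m in matrices.items()}
        de_sets: dict[str, set[str]] = {}
        de_counts: dict[str, dict[str, int]] = {}
        for cls, m in matrices.items():
            table = call_de(logcpm[cls], cfg)
            cio.write_table(table, out / f"de_{cls}.tsv")
            sets = de_gene_sets(table)
            de_sets[cls] = sets["de"]
            de_counts[cls] = {"up": len(sets["up"]), "down": len(sets["down"])}
        summary["de_counts"] = de_counts

    with _stage("cerna"):
        if cfg.universe == "de":
            db_used = db.restrict(
                mirnas=de_sets["miRNA"],
                targets=de_sets["lncRNA"] | de_sets["mRNA"],
            )
        else:
            db_used = db
        universe = db_used.mirna_ids
        pairs = score_pairs(
            db_used, universe, logcpm["lncRNA"], logcpm["mRNA"],
            logcpm["miRNA"], cfg,
        )
        cio.write_table(pair_table(pairs), out / "pairs.tsv")
        n_shared = len(pairs)
        n_overlap = sum(p.overlap_p < cfg.pair_p for p in pairs)
        n_pcc = sum(
            p.overlap_p < cfg.pair_p and p.pcc_r > 0 and p.pcc_p < cfg.pcc_p
            for p in pairs
        )
        n_pass = sum(p.passes for p in pairs)
        summary["pair_filter_counts"] = {
            "shared_mirna": n_shared,
            "overlap_p": n_overlap,
            "positive_pcc": n_pcc,
            "regsim": n_pass,
        }

    with _stage("network"):
        net = build_network(pairs, cfg)
        cio.write_network(net, out / "edges.tsv", out / "nodes.tsv")
        summary["network"] = {
            "n_nodes": len(net.nodes),
            "n_edges": net.n_edges,
            "class_counts": net.class_counts(),
            "hubs": list(net.hubs),
        }

    with _stage("triplets"):
        triplets = extract_triplets(net, pairs)
        cio.write_table(triplet_table(triplets), out / "triplets.tsv")
        summary["n_triplets"] = len(triplets)
        summary["n_hub_triplets"] = sum(t.in_hub_subnetwork for t in triplets)

    with _stage("prognosis"):
        surv = {}
        rows = []
        for t in triplets:
            key = f"{t.lncrna_id}|{t.mirna_id}|{t.mrna_id}"
            try:
                rm = triplet_risk_analysis(
                    t, logcpm["lncRNA"], logcpm["miRNA"], logcpm["mRNA"],
                    clin, cfg,
                )
            except CernaError as exc:
                log.warning("triplet %s not analysable: %s", key, exc)
                surv[key] = None
                continue
            surv[key] = {
                "chi_square": round(rm.logrank_stat, 10),
                "logrank_p": round(rm.logrank_p, 12),
                "betas": [round(float(b), 10) for b in rm.betas],
            }
            rows.append({"triplet": key, "chi_square": rm.logrank_stat,
                         "logrank_p": rm.logrank_p})
        if rows:
            import pandas as pd

            cio.write_table(pd.DataFrame(rows), out / "triplet_survival.tsv")
        summary["triplet_survival"] = surv

    if gene_sets:
        with _stage("enrichment"):
            universe_genes = set(matrices["mRNA"].gene_ids)
            res = ora(de_sets["mRNA"] & universe_genes, gene_sets,
                      universe_genes, cfg)
            cio.write_table(res, out / "enrichment.tsv")
            summary["enrichment"] = {
                "n_sets": int(len(res)),
                "n_significant": int(res["significant"].sum()) if len(res) else 0,
            }

    text = json.dumps(summary, indent=2, sort_keys=True)
    (out / "run_summary.json").write_text(text + "\n", encoding="utf-8")
    cio.write_config(cfg, out / "config_used.yaml")
    return summary
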