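"""ceRNA pair scoring and network construction.

A candidate lncRNA-mRNA pair is kept when it clears three filters:

1. the two transcripts share significantly more miRNAs than chance
   (hypergeometric upper tail over a miRNA universe, p < 0.05);
2. the pair is positively co-expressed (Pearson r > 0, p < 0.05);
3. the shared miRNAs correlate with the lncRNA and the mRNA in a similar
   way, as measured by the regulation similarity score

       regsim = 1 - (1/M) * sum_k [ |corr(m_k, l) - corr(m_k, g)|
                                    / (|corr(m_k, l)| + |corr(m_k, g)|) ]^M

   over the M shared miRNAs, required to be > 0. regsim is 1 when the two
   correlation profiles are identical and 0 when every shared miRNA
   correlates with opposite sign and equal magnitude.

Passing pairs are expanded into a bipartite-by-construction network whose
edges always have a miRNA endpoint; hubs are the top-k nodes by degree.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, InteractionDB, RunConfig
from .errors import EmptyNetworkError, ScoringError, ValidationError
from .stats import bh_adjust, hypergeom_tail, pearson

log = logging.getLogger("cerna_prognost")


@dataclass
class CeRNAPair:
    """A scored lncRNA-mRNA candidate pair."""

    lncrna_id: str
    mrna_id: str
    shared_mirnas: tuple[str, ...]
    overlap_p: float
    pcc_r: float = np.nan
    pcc_p: float = np.nan
    regsim: float = np.nan
    passes: bool = False

    @property
    def M(self) -> int:
        return len(self.shared_mirnas)


@dataclass
class CeRNATriplet:
    """One lncRNA-miRNA-mRNA interaction from a passing pair."""

    lncrna_id: str
    mirna_id: str
    mrna_id: str
    in_hub_subnetwork: bool = False


def correlation_samples(
    matrices: list[ExpressionMatrix], cfg: RunConfig
) -> list[str]:
    """Shared sample ids across assays, restricted per config.

    Different assays (RNA-seq vs miRNA-seq) rarely profile identical sample
    sets, so correlations use the intersection; with the default tumor-only
    setting only tumor samples enter.
    """
    shared = set(matrices[0].sample_ids)
    for m in matrices[1:]:
        shared &= set(m.sample_ids)
    if cfg.correlation_sample_set == "tumor":
        shared &= set(matrices[0].group.index[matrices[0].group == "tumor"])
    samples = sorted(shared)
    if len(samples) < cfg.min_group_overlap:
        raise ValidationError(
            f"only {len(samples)} shared samples across assays; "
            f"need >= {cfg.min_group_overlap}"
        )
    return samples


def shared_mirna_test(
    lnc: str, mrna: str, db: InteractionDB, universe: set[str]
) -> tuple[set[str], float | None]:
    """Shared miRNAs of a pair and the hypergeometric overlap p-value.

    With N = |universe|, K = miRNAs targeting the lncRNA, n = miRNAs
    targeting the mRNA and k = |shared|, returns P(X >= k) for
    X ~ Hypergeometric(N, K, n). Pairs with k = 0 (or K = 0 / n = 0) are not
    scored: returns (shared, None).
    """
    if not universe:
        raise ValidationError("empty miRNA universe")
    mir_l = db.mirnas_of(lnc) & universe
    mir_g = db.mirnas_of(mrna) & universe
    shared = mir_l & mir_g
    if not mir_l or not mir_g:
        log.debug("pair (%s, %s) skipped: no in-universe miRNAs on one side",
                  lnc, mrna)
        return shared, None
    if not shared:
        return shared, None
    p = hypergeom_tail(len(universe), len(mir_l), len(mir_g), len(shared))
    return shared, p


def coexpression(
    lnc: str,
    mrna: str,
    lnc_m: ExpressionMatrix,
    mrna_m: ExpressionMatrix,
    cfg: RunConfig | None = None,
) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) of a pair over matched samples."""
    cfg = cfg or RunConfig()
    samples = correlation_samples([lnc_m, mrna_m], cfg)
    x = lnc_m.values.loc[lnc, samples].to_numpy()
    y = mrna_m.values.loc[mrna, samples].to_numpy()
    return pearson(x, y)


def regsim_from_correlations(
    corr_pairs: "list[tuple[float, float]]", exponent: str = "M"
) -> float:
    """Regulation similarity from precomputed (corr(m_k, l), corr(m_k, g)).

    regsim = 1 - (1/M) * sum_k [|r_lk - r_gk| / (|r_lk| + |r_gk|)]^e with
    e = M (published form) or 1; a 0/0 term counts as 0.
    """
    if not corr_pairs:
        raise ScoringError("regulation similarity needs >=1 correlation pair")
    m = len(corr_pairs)
    expo = m if exponent == "M" else 1
    total = 0.0
    for r_l, r_g in corr_pairs:
        denom = abs(r_l) + abs(r_g)
        term = 0.0 if denom == 0 else abs(r_l - r_g) / denom
        total += term**expo
    return min(max(1.0 - total / m, 0.0), 1.0)


def regulation_similarity(
    shared_mirnas: "set[str] | tuple[str, ...]",
    lnc: str,
    mrna: str,
    mir_m: ExpressionMatrix,
    lnc_m: ExpressionMatrix,
    mrna_m: ExpressionMatrix,
    cfg: RunConfig | None = None,
) -> float:
    """Regulation similarity score in [0, 1] over the shared miRNAs.

    A term whose two correlations are both exactly zero contributes 0
    (identical null profiles). A miRNA with zero expression variance on the
    matched samples is dropped with a warning, reducing M; if no term remains
    the score is undefined.
    """
    cfg = cfg or RunConfig()
    if not shared_mirnas:
        raise ScoringError("regulation similarity needs >=1 shared miRNA")
    samples = correlation_samples([mir_m, lnc_m, mrna_m], cfg)
    lv = lnc_m.values.loc[lnc, samples].to_numpy(dtype=float)
    gv = mrna_m.values.loc[mrna, samples].to_numpy(dtype=float)
    corr_pairs = []
    for mk in sorted(shared_mirnas):
        mv = mir_m.values.loc[mk, samples].to_numpy(dtype=float)
        try:
            r_l, _ = pearson(mv, lv)
            r_g, _ = pearson(mv, gv)
        except ValidationError as exc:
            log.warning("dropping shared miRNA %s from regsim(%s, %s): %s",
                        mk, lnc, mrna, exc)
            continue
        corr_pairs.append((r_l, r_g))
    if not corr_pairs:
        raise ScoringError(
            f"no computable correlation term for pair ({lnc}, {mrna})"
        )
    return regsim_from_correlations(corr_pairs, cfg.regsim_exponent)


def mirna_target_correlations(
    shared_mirnas, target: str, target_m: ExpressionMatrix,
    mir_m: ExpressionMatrix, cfg: RunConfig,
) -> dict[str, float]:
    """Pearson r of each shared miRNA with one target over matched samples."""
    samples = correlation_samples([mir_m, target_m], cfg)
    tv = target_m.values.loc[target, samples].to_numpy(dtype=float)
    out = {}
    for mk in sorted(shared_mirnas):
        mv = mir_m.values.loc[mk, samples].to_numpy(dtype=float)
        try:
            out[mk], _ = pearson(mv, tv)
        except ValidationError:
            continue
    return out


def candidate_pairs(db: InteractionDB) -> list[tuple[str, str]]:
    """All (lncRNA, mRNA) pairs sharing at least one miRNA in the DB."""
    pairs = set()
    for mir in db.mirna_ids:
        lncs = db.targets_of(mir, "lncRNA")
        mrnas = db.targets_of(mir, "mRNA")
        pairs.update((l, g) for l in lncs for g in mrnas)
    return sorted(pairs)


def score_pairs(
    db: InteractionDB,
    universe: set[str],
    lnc_m: ExpressionMatrix,
    mrna_m: ExpressionMatrix,
    mir_m: ExpressionMatrix,
    cfg: RunConfig | None = None,
) -> list[CeRNAPair]:
    """Score every candidate pair and apply the three-filter pass rule."""
    cfg = cfg or RunConfig()
    pairs: list[CeRNAPair] = []
    for lnc, mrna in candidate_pairs(db):
        if lnc not in lnc_m.values.index or mrna not in mrna_m.values.index:
            continue
        shared, overlap_p = shared_mirna_test(lnc, mrna, db, universe)
        if overlap_p is None:
            continue
        pair = CeRNAPair(
            lncrna_id=lnc, mrna_id=mrna,
            shared_mirnas=tuple(sorted(shared)), overlap_p=overlap_p,
        )
        try:
            pair.pcc_r, pair.pcc_p = coexpression(lnc, mrna, lnc_m, mrna_m, cfg)
            pair.regsim = regulation_similarity(
                shared, lnc, mrna, mir_m, lnc_m, mrna_m, cfg
            )
        except (ValidationError, ScoringError) as exc:
            log.warning("pair (%s, %s) unscoreable: %s", lnc, mrna, exc)
            pairs.append(pair)
            continue
        pairs.append(pair)
    overlap_p_eff = np.array([p.overlap_p for p in pairs])
    if cfg.adjust_pair_p and len(pairs):
        overlap_p_eff = bh_adjust(overlap_p_eff)
    for pair, op in zip(pairs, overlap_p_eff):
        ok = (
            op < cfg.pair_p
            and np.isfinite(pair.pcc_r)
            and pair.pcc_r > 0
            and pair.pcc_p < cfg.pcc_p
            and np.isfinite(pair.regsim)
            and pair.regsim > cfg.regsim_min
        )
        if ok and cfg.require_negative_mirna_corr:
            rl = mirna_target_correlations(
                pair.shared_mirnas, pair.lncrna_id, lnc_m, mir_m, cfg)
            rg = mirna_target_correlations(
                pair.shared_mirnas, pair.mrna_id, mrna_m, mir_m, cfg)
            ok = all(v < 0 for v in rl.values()) and all(
                v < 0 for v in rg.values())
        pair.passes = bool(ok)
    log.info("scored %d candidate pairs, %d pass all filters",
             len(pairs), sum(p.passes for p in pairs))
    return pairs


def pair_table(pairs: list[CeRNAPair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lncrna_id": [p.lncrna_id for p in pairs],
            "mrna_id": [p.mrna_id for p in pairs],
            "M": [p.M for p in pairs],
            "shared_mirnas": [";".join(p.shared_mirnas) for p in pairs],
            "overlap_p": [p.overlap_p for p in pairs],
            "pcc_r": [p.pcc_r for p in pairs],
            "pcc_p": [p.pcc_p for p in pairs],
            "regsim": [p.regsim for p in pairs],
            "passes": [p.passes for p in pairs],
        }
    )


@dataclass
class CeRNANetwork:
    """Undirected typed graph of passing pairs plus the degree-ranked hubs."""

    graph: nx.Graph
    hubs: list[str] = field(default_factory=list)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, node: str) -> int:
        return int(self.graph.degree[node])

    def node_table(self) -> pd.DataFrame:
        rows = [
            {
                "id": n,
                "class": self.graph.nodes[n]["rna_class"],
                "degree": self.graph.degree[n],
                "is_hub": n in self.hubs,
            }
            for n in self.nodes
        ]
        return pd.DataFrame(rows)

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v, "edge_type": d["edge_type"]}
            for u, v, d in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(rows, columns=["source", "target", "edge_type"])

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for n in self.graph.nodes:
            c = self.graph.nodes[n]["rna_class"]
            counts[c] = counts.get(c, 0) + 1
        return counts


def build_network(pairs: list[CeRNAPair], cfg: RunConfig | None = None) -> CeRNANetwork:
    """Expand passing pairs into miRNA-lncRNA / miRNA-mRNA edges and rank hubs.

    Edges are deduplicated; hubs are the top ``cfg.hub_k`` nodes by degree
    with ties broken lexicographically by id.
    """
    cfg = cfg or RunConfig()
    passing = [p for p in pairs if p.passes]
    if not passing:
        raise EmptyNetworkError(
            "no ceRNA pair passed all filters; relax thresholds or check inputs"
        )
    g = nx.Graph()
    for p in passing:
        g.add_node(p.lncrna_id, rna_class="lncRNA")
        g.add_node(p.mrna_id, rna_class="mRNA")
        for mk in p.shared_mirnas:
            g.add_node(mk, rna_class="miRNA")
            g.add_edge(mk, p.lncrna_id, edge_type="miRNA-lncRNA")
            g.add_edge(mk, p.mrna_id, edge_type="miRNA-mRNA")
    ranked = sorted(g.nodes, key=lambda n: (-g.degree[n], n))
    return CeRNANetwork(graph=g, hubs=ranked[: cfg.hub_k])


def extract_triplets(
    net: CeRNANetwork, pairs: list[CeRNAPair]
) -> list[CeRNATriplet]:
    """All lncRNA-miRNA-mRNA triplets of passing pairs.

    Every triplet whose pair passed is returned; those with all three members
    in the hub set carry ``in_hub_subnetwork=True`` (the hub-restricted
    sub-network view).
    """
    hubs = set(net.hubs)
    seen = set()
    triplets: list[CeRNATriplet] = []
    for p in pairs:
        if not p.passes:
            continue
        for mk in p.shared_mirnas:
            key = (p.lncrna_id, mk, p.mrna_id)
            if key in seen:
                continue
            seen.add(key)
            triplets.append(
                CeRNATriplet(
                    lncrna_id=p.lncrna_id,
                    mirna_id=mk,
                    mrna_id=p.mrna_id,
                    in_hub_subnetwork=set(key) <= hubs,
                )
            )
    return triplets


def triplet_table(triplets: list[CeRNATriplet]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lncrna_id": [t.lncrna_id for t in triplets],
            "mirna_id": [t.mirna_id for t in triplets],
            "mrna_id": [t.mrna_id for t in triplets],
            "in_hub_subnetwork": [t.in_hub_subnetwork for t in triplets],
        }
    )
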