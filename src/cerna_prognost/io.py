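"""Readers and writers for all on-disk formats.

Everything is plain UTF-8 TSV with a header row (GMT excepted, which follows
the usual set-name / description / members convention). Readers validate and
reject; they never coerce. Writer/reader pairs round-trip.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .containers import ClinicalTable, ExpressionMatrix, InteractionDB, RunConfig
from .errors import FormatError, MappingError

log = logging.getLogger("cerna_prognost")


def read_expression(
    path: str | Path, rna_class: str, group_map: Mapping[str, str]
) -> ExpressionMatrix:
    """Read a genes x samples count TSV; first column gene ids, header samples.

    Every sample in the file must appear in ``group_map`` (sample -> label in
    {tumor, normal}); unmapped samples are rejected, not dropped.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # malformed TSV
        raise FormatError(f"cannot parse expression TSV {path}: {exc}") from exc
    if df.empty:
        raise FormatError(f"empty expression table: {path}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise FormatError(f"non-numeric values in sample column {col!r}")
    if df.isna().any().any():
        raise FormatError(f"missing values in expression table {path}")
    missing = [s for s in df.columns if s not in group_map]
    if missing:
        raise MappingError(f"samples missing from group_map: {missing[:5]}")
    group = pd.Series({s: group_map[s] for s in df.columns})
    m = ExpressionMatrix(values=df, rna_class=rna_class, group=group)
    log.info(
        "read %s expression %s: %d genes x %d samples (%d tumor / %d normal)",
        rna_class, path, m.n_genes, m.n_samples,
        len(m.samples_in_group("tumor")), len(m.samples_in_group("normal")),
    )
    return m


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    m.values.to_csv(path, sep="\t", index_label="gene_id")


def read_interactions(path: str | Path) -> InteractionDB:
    """Read a (mirna, target, target_class) TSV into a deduplicated DB."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"mirna", "target", "target_class"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"interaction TSV needs header columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    db = InteractionDB(df)
    counts = db.records["target_class"].value_counts().to_dict()
    log.info("read interactions %s: %d records by class %s", path, len(db), counts)
    return db


def write_interactions(db: InteractionDB, path: str | Path) -> None:
    db.records.to_csv(path, sep="\t", index=False)


def read_clinical(path: str | Path) -> ClinicalTable:
    """Read (sample_id, time_days, event) survival records."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "time_days", "event"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"clinical TSV needs header columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    clin = ClinicalTable(df.set_index("sample_id")[["time_days", "event"]])
    log.info("read clinical %s: %d patients, %d events",
             path, len(clin.df), int(clin.df["event"].sum()))
    return clin


def write_clinical(clin: ClinicalTable, path: str | Path) -> None:
    clin.df.to_csv(path, sep="\t", index_label="sample_id")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: set-name <tab> description <tab> members..."""
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has <3 fields")
            name, _desc, *members = parts
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = set(m for m in members if m)
    log.info("read GMT %s: %d sets", path, len(sets))
    return sets


def write_gmt(sets: Mapping[str, set[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sets:
            fh.write("\t".join([name, "na", *sorted(sets[name])]) + "\n")


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write any result table as TSV."""
    df.to_csv(path, sep="\t", index=index)


def write_network(net, edge_path: str | Path, node_path: str | Path) -> None:
    """Write a CeRNANetwork as an edge-list TSV plus a node-attribute TSV."""
    write_table(net.edge_table(), edge_path)
    write_table(net.node_table(), node_path)


def read_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML key: value file."""
    with open(path, encoding="utf-8") as fh:
        d = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(d)


def write_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
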