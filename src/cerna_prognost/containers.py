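"""Core in-memory containers: expression matrices, clinical tables,
miRNA-target interaction databases and run configuration.

All containers validate their invariants at construction time and are treated
as immutable by the rest of the package (operations return new objects).
"""
from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, ConsistencyError, FormatError, ValidationError

RNA_CLASSES = ("mRNA", "lncRNA", "miRNA")
GROUPS = ("tumor", "normal")
SCALES = ("counts", "logCPM")


@dataclass
class ExpressionMatrix:
    """Expression of one RNA class, genes x samples, with group labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample. Raw
        non-negative integer counts when ``scale == 'counts'``, real
        log2 counts-per-million when ``scale == 'logCPM'``.
    rna_class
        One of ``mRNA``, ``lncRNA``, ``miRNA``.
    group
        Per-sample label, ``tumor`` or ``normal``, aligned to the columns.
    """

    values: pd.DataFrame
    rna_class: str
    group: pd.Series
    scale: str = "counts"

    def __post_init__(self) -> None:
        if self.rna_class not in RNA_CLASSES:
            raise ValidationError(f"unknown rna_class {self.rna_class!r}")
        if self.scale not in SCALES:
            raise ValidationError(f"unknown scale {self.scale!r}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise FormatError(f"duplicate gene ids: {list(dups)[:5]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique()
            raise FormatError(f"duplicate sample ids: {list(dups)[:5]}")
        self.group = pd.Series(self.group)
        if list(self.group.index) != list(self.values.columns):
            self.group = self.group.reindex(self.values.columns)
        if self.group.isna().any():
            missing = self.group.index[self.group.isna()]
            raise ValidationError(f"samples without group label: {list(missing)[:5]}")
        bad = set(self.group.unique()) - set(GROUPS)
        if bad:
            raise ValidationError(f"unknown group labels: {sorted(bad)}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("expression values must be numeric")
        if self.scale == "counts":
            if (arr < 0).any():
                raise FormatError("counts must be non-negative")
            if not np.allclose(arr, np.round(arr)):
                raise FormatError("counts must be integral")

    # -- convenience views -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_in_group(self, group: str) -> list[str]:
        if group not in GROUPS:
            raise ValidationError(f"unknown group {group!r}")
        return list(self.group.index[self.group == group])

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = [s for s in sample_ids if s in self.values.columns]
        return ExpressionMatrix(
            values=self.values.loc[:, ids],
            rna_class=self.rna_class,
            group=self.group.loc[ids],
            scale=self.scale,
        )

    def require_two_per_group(self) -> None:
        """Raise unless both tumor and normal have at least 2 samples."""
        for g in GROUPS:
            if len(self.samples_in_group(g)) < 2:
                raise ValidationError(
                    f"need >=2 samples in group {g!r}, "
                    f"got {len(self.samples_in_group(g))}"
                )


@dataclass
class ClinicalTable:
    """Overall-survival records: sample id, follow-up time (days), event flag.

    ``event == 1`` marks an observed death, ``event == 0`` censoring at
    ``time_days``.
    """

    df: pd.DataFrame  # columns: time_days, event; index: sample_id

    def __post_init__(self) -> None:
        df = self.df
        if df.index.duplicated().any():
            raise ValidationError("duplicate sample ids in clinical table")
        if (df["time_days"] <= 0).any():
            bad = df.index[df["time_days"] <= 0]
            raise ValidationError(f"time_days must be > 0 (samples {list(bad)[:5]})")
        if not df["event"].isin([0, 1]).all():
            raise ValidationError("event indicator must be 0 or 1")
        self.df = df.astype({"time_days": float, "event": int})

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    def subset(self, sample_ids: Iterable[str]) -> "ClinicalTable":
        ids = [s for s in sample_ids if s in self.df.index]
        return ClinicalTable(self.df.loc[ids].copy())

    def times_events(self) -> tuple[np.ndarray, np.ndarray]:
        return self.df["time_days"].to_numpy(), self.df["event"].to_numpy()


class InteractionDB:
    """miRNA -> target interaction table with class-tagged targets.

    Records are deduplicated on (mirna, target); a target id appearing under
    two different classes is a consistency error.
    """

    def __init__(self, records: pd.DataFrame):
        required = {"mirna", "target", "target_class"}
        if not required.issubset(records.columns):
            raise FormatError(
                f"interaction table needs columns {sorted(required)}, "
                f"got {list(records.columns)}"
            )
        bad = set(records["target_class"].unique()) - {"lncRNA", "mRNA"}
        if bad:
            raise FormatError(f"unknown target_class tokens: {sorted(bad)}")
        records = records.drop_duplicates(subset=["mirna", "target"]).reset_index(
            drop=True
        )
        classes = records.groupby("target")["target_class"].nunique()
        inconsistent = classes.index[classes > 1]
        if len(inconsistent):
            raise ConsistencyError(
                f"targets under two classes: {list(inconsistent)[:5]}"
            )
        self.records = records[["mirna", "target", "target_class"]].copy()
        self._targets_of: dict[str, set[str]] = {}
        self._mirnas_of: dict[str, set[str]] = {}
        self._class_of: dict[str, str] = {}
        for mir, tgt, cls in self.records.itertuples(index=False):
            self._targets_of.setdefault(mir, set()).add(tgt)
            self._mirnas_of.setdefault(tgt, set()).add(mir)
            self._class_of[tgt] = cls

    def __len__(self) -> int:
        return len(self.records)

    @property
    def mirna_ids(self) -> set[str]:
        return set(self._targets_of)

    def targets_of(self, mirna: str, target_class: str | None = None) -> set[str]:
        tgts = self._targets_of.get(mirna, set())
        if target_class is None:
            return set(tgts)
        return {t for t in tgts if self._class_of[t] == target_class}

    def mirnas_of(self, target: str) -> set[str]:
        return set(self._mirnas_of.get(target, set()))

    def target_class(self, target: str) -> str | None:
        return self._class_of.get(target)

    def targets(self, target_class: str | None = None) -> set[str]:
        if target_class is None:
            return set(self._class_of)
        return {t for t, c in self._class_of.items() if c == target_class}

    def restrict(
        self,
        mirnas: Iterable[str] | None = None,
        targets: Iterable[str] | None = None,
    ) -> "InteractionDB":
        """New DB keeping only records whose miRNA/target is in the given sets."""
        rec = self.records
        if mirnas is not None:
            rec = rec[rec["mirna"].isin(set(mirnas))]
        if targets is not None:
            rec = rec[rec["target"].isin(set(targets))]
        return InteractionDB(rec.reset_index(drop=True))


@dataclass
class RunConfig:
    """Thresholds and knobs for a full pipeline run.

    Defaults are the published cut-offs: DE at adj.P < 0.01 and |logFC| > 1,
    ceRNA pair overlap p < 0.05, co-expression p < 0.05 with positive r,
    regulation similarity > 0, enrichment q < 0.01.
    """

    de_adj_p: float = 0.01
    de_abs_logfc: float = 1.0
    pair_p: float = 0.05
    pcc_p: float = 0.05
    regsim_min: float = 0.0
    enrich_q: float = 0.01
    alpha: float = 0.05
    correlation_sample_set: str = "tumor"  # or "all"
    universe: str = "de"  # hypergeometric universe: "de" or "all" DB miRNAs
    regsim_exponent: str = "M"  # "M" (published form) or "1"
    require_negative_mirna_corr: bool = False
    adjust_pair_p: bool = False
    hub_k: int = 10
    min_group_overlap: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("de_adj_p", "pair_p", "pcc_p", "enrich_q", "alpha"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ConfigError(f"{name} must lie in (0, 1], got {v}")
        if self.hub_k < 1:
            raise ConfigError("hub_k must be >= 1")
        if self.correlation_sample_set not in ("tumor", "all"):
            raise ConfigError("correlation_sample_set must be 'tumor' or 'all'")
        if self.universe not in ("de", "all"):
            raise ConfigError("universe must be 'de' or 'all'")
        if self.regsim_exponent not in ("M", "1"):
            raise ConfigError("regsim_exponent must be 'M' or '1'")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(d))
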