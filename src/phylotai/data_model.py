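"""Core typed tables, TSV readers/writers, and shared validation.

All tabular interchange is tab-separated UTF-8 with a header row and
fixed column names.  Timepoints are always carried as decimal hours and
ordered numerically, never lexicographically.  Missing Ka/Ks values are
explicit missing (empty field or ``NA``), never zero: zero is a legal
divergence value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "GeneCatalog",
    "InductionTable",
    "ExpressionMatrix",
    "StagePartition",
    "TraitSeries",
    "bh_adjust",
    "load_gene_catalog",
    "load_induction_table",
]


class ValidationError(ValueError):
    """An input table violates one of its invariants."""


# ---------------------------------------------------------------------------
# GeneCatalog
# ---------------------------------------------------------------------------

@dataclass
class GeneCatalog:
    """Per-gene phylostratum and Ka/Ks divergence.

    Parameters
    ----------
    table
        Columns ``gene_id`` (unique), ``ps`` (integer phylostratum,
        1 = most ancient .. ``n_strata`` = species-specific), ``kaks``
        and ``ks`` (nonnegative floats, NaN for missing).
    n_strata
        Number of phylostrata on the focal lineage (default 13).
    """

    table: pd.DataFrame
    n_strata: int = 13

    def __post_init__(self) -> None:
        t = self.table
        required = ["gene_id", "ps", "kaks", "ks"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise ValidationError(f"gene catalog missing columns: {missing}")
        if t["gene_id"].duplicated().any():
            dup = t.loc[t["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValidationError(f"duplicate gene_id in catalog: {dup!r}")
        ps = t["ps"]
        bad = t.loc[(ps < 1) | (ps > self.n_strata), "gene_id"]
        if len(bad):
            raise ValidationError(
                f"ps outside 1..{self.n_strata} for gene(s) {list(bad[:3])}"
            )
        if (t["kaks"].dropna() < 0).any():
            raise ValidationError("negative kaks in catalog")
        # kaks must be missing whenever ks is missing
        orphan = t["ks"].isna() & t["kaks"].notna()
        if orphan.any():
            g = t.loc[orphan, "gene_id"].iloc[0]
            raise ValidationError(f"kaks present but ks missing for {g!r}")
        self.table = t.reset_index(drop=True)

    @property
    def gene_ids(self) -> pd.Series:
        return self.table["gene_id"]

    def ps_map(self) -> pd.Series:
        """gene_id -> phylostratum, as a float Series."""
        return self.table.set_index("gene_id")["ps"].astype(float)

    def kaks_map(self) -> pd.Series:
        """gene_id -> Ka/Ks (NaN where undefined)."""
        return self.table.set_index("gene_id")["kaks"].astype(float)

    def write(self, path: str | Path) -> None:
        out = self.table.copy()
        out["ps"] = out["ps"].astype(int)
        out.to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def read(cls, path: str | Path, n_strata: int = 13) -> "GeneCatalog":
        t = pd.read_csv(
            path, sep="\t", na_values=["NA", ""], keep_default_na=False,
            dtype={"gene_id": str},
        )
        if "ps" in t.columns:
            t["ps"] = pd.to_numeric(t["ps"], errors="raise").astype(int)
        for c in ("kaks", "ks"):
            if c in t.columns:
                t[c] = pd.to_numeric(t[c], errors="raise")
        return cls(t, n_strata=n_strata)


def load_gene_catalog(path: str | Path, n_strata: int = 13) -> GeneCatalog:
    """Read a gene catalog TSV (columns gene_id/ps/kaks/ks)."""
    return GeneCatalog.read(path, n_strata=n_strata)


# ---------------------------------------------------------------------------
# InductionTable
# ---------------------------------------------------------------------------

@dataclass
class InductionTable:
    """Per-gene, per-condition, per-timepoint log2 fold-change and padj.

    One row per (gene, condition, timepoint); ``timepoint`` is decimal
    hours post treatment; ``padj`` lies in [0, 1].
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = ["gene_id", "condition", "timepoint", "log2fc", "padj"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise ValidationError(f"induction table missing columns: {missing}")
        t = t.copy()
        t["timepoint"] = pd.to_numeric(t["timepoint"], errors="raise")
        key = ["gene_id", "condition", "timepoint"]
        dup = t.duplicated(subset=key)
        if dup.any():
            k = tuple(t.loc[dup, key].iloc[0])
            raise ValidationError(f"duplicate (gene, condition, timepoint) row: {k}")
        bad = (t["padj"] < 0) | (t["padj"] > 1)
        if bad.any():
            row = t.loc[bad].iloc[0]
            raise ValidationError(
                f"padj outside [0,1] for gene {row['gene_id']!r}: {row['padj']}"
            )
        # canonical numeric ordering of timepoints
        self.table = t.sort_values(key).reset_index(drop=True)

    @property
    def timepoints(self) -> np.ndarray:
        """Sorted unique timepoints in hours."""
        return np.sort(self.table["timepoint"].unique())

    @property
    def conditions(self) -> list[str]:
        return sorted(self.table["condition"].unique())

    def for_condition(self, condition: str) -> pd.DataFrame:
        sub = self.table[self.table["condition"] == condition]
        if sub.empty:
            raise ValidationError(f"no rows for condition {condition!r}")
        return sub

    def abs_fc_matrix(self, condition: str, genes: Sequence[str] | None = None,
                      timepoints: Sequence[float] | None = None) -> pd.DataFrame:
        """|log2FC| as a genes x timepoints matrix (absent rows -> 0)."""
        sub = self.for_condition(condition)
        mat = sub.pivot(index="gene_id", columns="timepoint", values="log2fc").abs()
        if timepoints is not None:
            mat = mat.reindex(columns=list(timepoints))
        if genes is not None:
            mat = mat.reindex(index=list(genes))
        return mat.fillna(0.0)

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def read(cls, path: str | Path) -> "InductionTable":
        t = pd.read_csv(
            path, sep="\t", na_values=["NA", ""], keep_default_na=False,
            dtype={"gene_id": str, "condition": str},
        )
        return cls(t)


def load_induction_table(path: str | Path) -> InductionTable:
    """Read an induction TSV (gene_id/condition/timepoint/log2fc/padj)."""
    return InductionTable.read(path)


# ---------------------------------------------------------------------------
# ExpressionMatrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Nonnegative TPM matrix (genes x samples) with tagged samples.

    ``values`` is indexed by gene_id; ``samples`` is indexed by the same
    sample names as the columns of ``values`` and carries ``condition``,
    ``timepoint`` (hours) and ``replicate`` tags.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValidationError("negative TPM values in expression matrix")
        if self.values.columns.duplicated().any():
            raise ValidationError("duplicate sample tags")
        for c in ("condition", "timepoint", "replicate"):
            if c not in self.samples.columns:
                raise ValidationError(f"sample sheet missing column {c!r}")
        if set(self.values.columns) != set(self.samples.index):
            raise ValidationError("sample sheet does not match matrix columns")
        self.samples = self.samples.loc[self.values.columns]

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    def subset_samples(self, condition: str | None = None) -> "ExpressionMatrix":
        keep = self.samples.index
        if condition is not None:
            keep = self.samples.index[self.samples["condition"] == condition]
        return ExpressionMatrix(self.values[keep], self.samples.loc[keep])

    def write(self, path: str | Path) -> None:
        """Single TSV; sample tags encoded as condition:hours:replicate."""
        out = self.values.copy()
        out.columns = [
            f"{r.condition}:{r.timepoint:g}:{r.replicate}"
            for r in self.samples.itertuples()
        ]
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def read(cls, path: str | Path) -> "ExpressionMatrix":
        vals = pd.read_csv(path, sep="\t", index_col="gene_id")
        tags = []
        for col in vals.columns:
            parts = col.split(":")
            if len(parts) != 3:
                raise ValidationError(
                    f"sample column {col!r} is not condition:hours:replicate"
                )
            tags.append((col, parts[0], float(parts[1]), parts[2]))
        samples = pd.DataFrame(
            tags, columns=["sample", "condition", "timepoint", "replicate"]
        ).set_index("sample")
        return cls(vals, samples)


# ---------------------------------------------------------------------------
# StagePartition
# ---------------------------------------------------------------------------

_STAGES = ("early", "mid", "late")


@dataclass(frozen=True)
class StagePartition:
    """Assignment of ordered timepoints to early / mid / late stages.

    Stages must be non-empty and contiguous in time order.  The default
    partition for a 0.5/1/5/11 h design is early={0.5, 1}, mid={5},
    late={11}.
    """

    early: tuple[float, ...]
    mid: tuple[float, ...]
    late: tuple[float, ...]

    def __post_init__(self) -> None:
        for name in _STAGES:
            if not getattr(self, name):
                raise ValidationError(f"stage {name!r} has no timepoints")
        all_t = [*self.early, *self.mid, *self.late]
        if len(set(all_t)) != len(all_t):
            raise ValidationError("a timepoint is assigned to more than one stage")
        if sorted(all_t) != all_t:
            raise ValidationError("stages are not contiguous in time order")

    @classmethod
    def default(cls) -> "StagePartition":
        return cls(early=(0.5, 1.0), mid=(5.0,), late=(11.0,))

    @property
    def timepoints(self) -> tuple[float, ...]:
        return (*self.early, *self.mid, *self.late)

    def stage_of(self, t: float) -> str:
        for name in _STAGES:
            if t in getattr(self, name):
                return name
        raise ValidationError(f"timepoint {t} not covered by the stage partition")

    def indices(self, timepoints: Sequence[float]) -> dict[str, np.ndarray]:
        """Positional indices of each stage within an ordered timepoint axis."""
        tp = list(timepoints)
        out: dict[str, np.ndarray] = {}
        for name in _STAGES:
            members = getattr(self, name)
            idx = [tp.index(t) for t in members if t in tp]
            if not idx:
                raise ValidationError(
                    f"stage {name!r} has no timepoint in the profile axis {tp}"
                )
            out[name] = np.asarray(idx, dtype=int)
        return out


# ---------------------------------------------------------------------------
# TraitSeries
# ---------------------------------------------------------------------------

@dataclass
class TraitSeries:
    """Per-sample trait values (e.g. jasmonic acid level, ng g^-1)."""

    values: pd.Series
    name: str = "trait"

    def __post_init__(self) -> None:
        self.values = pd.Series(self.values, dtype=float)
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate sample tags in trait series")

    def aligned_to(self, expr: ExpressionMatrix) -> pd.Series:
        missing = set(self.values.index) - set(expr.values.columns)
        if missing:
            raise ValidationError(
                f"trait samples absent from expression matrix: {sorted(missing)[:3]}"
            )
        return self.values

    def write(self, path: str | Path) -> None:
        df = self.values.rename(self.name).rename_axis("sample").reset_index()
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "TraitSeries":
        df = pd.read_csv(path, sep="\t")
        name = df.columns[1]
        return cls(df.set_index("sample")[name], name=name)


# ---------------------------------------------------------------------------
# Multiple-testing adjustment
# ---------------------------------------------------------------------------

def bh_adjust(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Provided as plumbing for differential-expression tables whose raw
    p-values are supplied unadjusted.  Output is monotone over the
    sorted input and capped at 1.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out
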