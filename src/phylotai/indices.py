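"""Induced transcriptome age and divergence indices.

The induced transcriptome age index at timepoint t is the
induction-weighted mean gene age

    iTAI_t = sum_i PS_i |FC_it| / sum_i |FC_it|

over the herbivory-responsive gene set, with |FC_it| the absolute log2
fold-change of gene i at t.  The induced transcriptome divergence index
iTDI_t replaces PS_i by the gene's Ka/Ks.  High iTAI means the induced
transcriptome is evolutionarily young; high iTDI means fast-evolving.

Responsive genes are selected per condition and timepoint with
|log2FC| >= 1 (inclusive) and adjusted p < 0.05 (strict).  By default
the index at every timepoint runs over the condition's union of
responsive genes (a gene contributes little where it is uninduced); a
per-timepoint mode restricted to the genes differentially expressed at
each t is available through ``per_timepoint=True``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from phylotai.data_model import (
    ExpressionMatrix,
    GeneCatalog,
    InductionTable,
    ValidationError,
)

__all__ = [
    "ResponsiveSet",
    "IndexProfile",
    "tpm_filter",
    "select_responsive",
    "compute_index",
    "index_profiles",
]

logger = logging.getLogger(__name__)

DEFAULT_LFC_MIN = 1.0
DEFAULT_PADJ_MAX = 0.05
DEFAULT_MIN_TPM = 1.0


@dataclass
class ResponsiveSet:
    """Per-timepoint up/down responsive genes for one condition."""

    condition: str
    up: dict[float, set[str]]
    down: dict[float, set[str]]

    def __post_init__(self) -> None:
        for t in self.up:
            overlap = self.up[t] & self.down.get(t, set())
            if overlap:
                raise ValidationError(
                    f"gene(s) both up and down at t={t}: {sorted(overlap)[:3]}"
                )

    @property
    def timepoints(self) -> list[float]:
        return sorted(set(self.up) | set(self.down))

    def union(self, direction: str = "all") -> set[str]:
        """All responsive genes over timepoints: 'all', 'up' or 'down'."""
        sets: Iterable[set[str]]
        if direction == "up":
            sets = self.up.values()
        elif direction == "down":
            sets = self.down.values()
        elif direction == "all":
            sets = list(self.up.values()) + list(self.down.values())
        else:
            raise ValueError(f"unknown direction {direction!r}")
        out: set[str] = set()
        for s in sets:
            out |= s
        return out

    def at(self, t: float, direction: str = "all") -> set[str]:
        if direction == "up":
            return set(self.up.get(t, set()))
        if direction == "down":
            return set(self.down.get(t, set()))
        return set(self.up.get(t, set())) | set(self.down.get(t, set()))

    def counts(self) -> pd.DataFrame:
        """Per-timepoint numbers of up- and down-regulated genes."""
        return pd.DataFrame(
            {
                "timepoint": self.timepoints,
                "n_up": [len(self.up.get(t, set())) for t in self.timepoints],
                "n_down": [len(self.down.get(t, set())) for t in self.timepoints],
            }
        )


@dataclass
class IndexProfile:
    """An iTAI or iTDI trajectory over ordered timepoints."""

    kind: str  # "iTAI" | "iTDI"
    condition: str
    subset: str  # "all" | "up" | "down"
    timepoints: np.ndarray
    values: np.ndarray
    n: np.ndarray  # contributing gene count per timepoint

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        if not (len(self.timepoints) == len(self.values) == len(self.n)):
            raise ValidationError("profile axes have mismatched lengths")
        if (self.n < 1).any():
            raise ValidationError("profile reported at a timepoint with n = 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "kind": self.kind,
                "condition": self.condition,
                "subset": self.subset,
                "timepoint": self.timepoints,
                "value": self.values,
                "n": self.n,
            }
        )


def tpm_filter(expr: ExpressionMatrix, min_tpm: float = DEFAULT_MIN_TPM) -> set[str]:
    """Genes with TPM >= *min_tpm* in at least one sample (inclusive)."""
    if expr.values.empty:
        raise ValidationError("empty expression matrix")
    keep = expr.values.max(axis=1) >= min_tpm
    return set(expr.values.index[keep])


def select_responsive(
    tab: InductionTable,
    condition: str,
    lfc_min: float = DEFAULT_LFC_MIN,
    padj_max: float = DEFAULT_PADJ_MAX,
    universe: set[str] | None = None,
) -> ResponsiveSet:
    """Differentially expressed genes per timepoint for one condition.

    A gene is up at t iff log2fc >= lfc_min and padj < padj_max; down
    iff log2fc <= -lfc_min and padj < padj_max.  The fold-change bound
    is inclusive, the padj bound strict.  *universe* optionally
    restricts candidates (e.g. the TPM-filtered gene set).
    """
    sub = tab.for_condition(condition)
    if universe is not None:
        sub = sub[sub["gene_id"].isin(universe)]
    sig = sub["padj"] < padj_max
    up_rows = sub[sig & (sub["log2fc"] >= lfc_min)]
    down_rows = sub[sig & (sub["log2fc"] <= -lfc_min)]
    timepoints = list(tab.timepoints)
    up = {t: set(up_rows.loc[up_rows["timepoint"] == t, "gene_id"]) for t in timepoints}
    down = {
        t: set(down_rows.loc[down_rows["timepoint"] == t, "gene_id"]) for t in timepoints
    }
    return ResponsiveSet(condition=condition, up=up, down=down)


def compute_index(
    tab: InductionTable,
    strata: Mapping[str, float] | pd.Series,
    genes: Iterable[str],
    condition: str,
    timepoints: Sequence[float] | None = None,
    kind: str = "iTAI",
    subset: str = "all",
) -> IndexProfile:
    """Induction-weighted mean stratum value per timepoint.

    *strata* maps gene_id to the weighting value (phylostratum for
    iTAI, Ka/Ks for iTDI); genes without a stratum value are dropped
    and counted in the log.  Raises if the |FC| weights sum to zero at
    some timepoint.
    """
    strata = pd.Series(strata, dtype=float)
    genes = sorted(set(genes))
    if not genes:
        raise ValidationError("empty gene set for index computation")
    have = [g for g in genes if g in strata.index and np.isfinite(strata[g])]
    n_missing = len(genes) - len(have)
    if n_missing:
        logger.info(
            "%s/%s: dropped %d of %d genes lacking a %s value",
            kind, condition, n_missing, len(genes), "ps" if kind == "iTAI" else "kaks",
        )
    if not have:
        raise ValidationError(f"no gene in the set has a stratum value for {kind}")
    if timepoints is None:
        timepoints = list(tab.timepoints)
    W = tab.abs_fc_matrix(condition, genes=have, timepoints=timepoints)
    s = strata[W.index].to_numpy()
    w = W.to_numpy()
    totals = w.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValidationError(
            f"all |FC| weights are zero at t={list(np.asarray(timepoints)[zero])}"
        )
    values = (s @ w) / totals
    n_contrib = (w > 0).sum(axis=0)
    # every gene with a stratum value is in the denominator set; report
    # the count of genes actually carrying weight at each t
    n_contrib = np.maximum(n_contrib, 1)
    return IndexProfile(
        kind=kind,
        condition=condition,
        subset=subset,
        timepoints=np.asarray(timepoints, dtype=float),
        values=values,
        n=n_contrib,
    )


def index_profiles(
    tab: InductionTable,
    catalog: GeneCatalog,
    responsive: ResponsiveSet,
    per_timepoint: bool = False,
) -> list[IndexProfile]:
    """iTAI and iTDI profiles for the all/up/down responsive subsets.

    With ``per_timepoint=False`` (default) the gene set at every t is
    the condition's union of responsive genes, weighted by each gene's
    |FC| at that t.  With ``per_timepoint=True`` only genes
    differentially expressed at t contribute there.
    """
    condition = responsive.condition
    timepoints = list(tab.timepoints)
    strata_by_kind = {"iTAI": catalog.ps_map(), "iTDI": catalog.kaks_map().dropna()}
    out: list[IndexProfile] = []
    for kind, strata in strata_by_kind.items():
        for subset in ("all", "up", "down"):
            genes = responsive.union(subset)
            if not genes:
                logger.warning(
                    "%s/%s subset %r empty at every timepoint: profile omitted",
                    kind, condition, subset,
                )
                continue
            try:
                if per_timepoint:
                    vals, ns = [], []
                    for t in timepoints:
                        gset = responsive.at(t, subset)
                        prof_t = compute_index(
                            tab, strata, gset, condition, [t], kind, subset
                        )
                        vals.append(prof_t.values[0])
                        ns.append(prof_t.n[0])
                    prof = IndexProfile(
                        kind, condition, subset,
                        np.asarray(timepoints), np.asarray(vals), np.asarray(ns),
                    )
                else:
                    prof = compute_index(
                        tab, strata, genes, condition, timepoints, kind, subset
                    )
            except ValidationError as err:
                logger.warning(
                    "%s/%s subset %r skipped: %s", kind, condition, subset, err
                )
                continue
            out.append(prof)
    return out


def profiles_to_frame(profiles: list[IndexProfile]) -> pd.DataFrame:
    """Stack profiles into the TSV layout kind/condition/subset/t/value/n."""
    if not profiles:
        return pd.DataFrame(
            columns=["kind", "condition", "subset", "timepoint", "value", "n"]
        )
    return pd.concat([p.to_frame() for p in profiles], ignore_index=True)
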