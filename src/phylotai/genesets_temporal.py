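"""Downstream gene-set analyses of the induced time course.

Covers the steps that follow co-expression module construction:
metabolism classification from EC annotations, module eigengenes and
their correlation with a hormone trait, membership filtering, z-scored
temporal trajectories and per-stage condition contrasts.  Module
assignments themselves are an input (network construction is out of
scope); the synthetic generator produces ground-truth modules so every
operation here is testable end to end.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from phylotai.data_model import (
    ExpressionMatrix,
    StagePartition,
    TraitSeries,
    ValidationError,
)

__all__ = [
    "classify_metabolism",
    "module_eigengene",
    "module_membership",
    "module_trait_correlation",
    "trajectory_zscore",
    "stage_condition_contrast",
    "significance_tier",
]

logger = logging.getLogger(__name__)

GENE_SET_LABELS = ("defense_signaling", "primary_metabolism", "specialized_metabolism")

_EC_RE = re.compile(r"^\d+\.(\d+|-)\.(\d+|-)\.(\d+|-)$")

DEFAULT_MEMBERSHIP = 0.75


def _valid_ec(ec: str) -> bool:
    return bool(_EC_RE.match(ec.strip()))


def classify_metabolism(
    ec_annotations: Mapping[str, Iterable[str]],
    pathway_classes: Mapping[str, str],
) -> pd.Series:
    """Label genes primary_metabolism / specialized_metabolism from ECs.

    A gene mapping to both classes is labeled specialized (the
    discriminative subset); genes with no classifiable EC are omitted.
    Malformed EC strings are skipped with a warning.
    """
    labels: dict[str, str] = {}
    for gene, ecs in ec_annotations.items():
        classes = set()
        for ec in ecs:
            if not _valid_ec(ec):
                logger.warning("gene %s: malformed EC %r skipped", gene, ec)
                continue
            cls = pathway_classes.get(ec.strip())
            if cls is not None:
                classes.add(cls)
        if not classes:
            continue
        if "specialized" in classes:
            if len(classes) > 1:
                logger.info("gene %s maps to both classes; labeled specialized", gene)
            labels[gene] = "specialized_metabolism"
        else:
            labels[gene] = "primary_metabolism"
    return pd.Series(labels, name="gene_set", dtype=object)


def _standardized_log(expr: ExpressionMatrix, genes: Sequence[str]) -> pd.DataFrame:
    """log2(TPM+1), per-gene standardized, genes x samples."""
    sub = expr.values.loc[list(genes)]
    x = np.log2(sub + 1.0)
    mu = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    if (sd == 0).any():
        raise ValidationError(
            f"constant expression for gene(s) {list(sub.index[sd == 0])[:3]}"
        )
    return x.sub(mu, axis=0).div(sd, axis=0)


def module_eigengene(expr: ExpressionMatrix, module_genes: Sequence[str]) -> pd.Series:
    """First principal component of a module over samples.

    Expression is log2(TPM+1)-transformed and per-gene standardized
    before the decomposition.  The returned score series has unit
    variance and is sign-oriented so that the mean correlation with
    member genes is positive.
    """
    module_genes = list(module_genes)
    if len(module_genes) < 2:
        raise ValidationError("module needs at least 2 genes")
    if expr.values.shape[1] < 3:
        raise ValidationError("eigengene needs at least 3 samples")
    z = _standardized_log(expr, module_genes)
    # SVD of the genes x samples matrix: right singular vector = scores
    _, _, vt = np.linalg.svd(z.to_numpy(), full_matrices=False)
    scores = vt[0]
    scores = scores / scores.std(ddof=1)
    eig = pd.Series(scores, index=z.columns, name="eigengene")
    mean_r = z.T.corrwith(eig).mean()
    if mean_r < 0:
        eig = -eig
    return eig


def module_membership(
    expr: ExpressionMatrix,
    eigengene: pd.Series,
    genes: Sequence[str] | None = None,
    threshold: float = DEFAULT_MEMBERSHIP,
) -> pd.Series:
    """Genes whose correlation with the eigengene exceeds *threshold*.

    Membership is the Pearson correlation between the gene's
    log2(TPM+1) profile and the eigengene over shared samples;
    retention is strict (> threshold).  Returns the membership values
    of retained genes.
    """
    genes = list(genes) if genes is not None else list(expr.values.index)
    prof = np.log2(expr.values.loc[genes, eigengene.index] + 1.0)
    r = prof.T.corrwith(eigengene)
    return r[r > threshold]


def module_trait_correlation(
    expr: ExpressionMatrix,
    modules: Mapping[str, str] | pd.Series,
    trait: TraitSeries,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene-trait correlations summarized per module, with WMW contrasts.

    Per gene: Pearson correlation of the log2(TPM+1) profile with the
    trait over shared samples.
    Per module: mean and standard error of member correlations.  The
    module with the highest mean is contrasted against every other
    module with the Wilcoxon-Mann-Whitney rank-sum test.

    Returns (summary, contrasts): summary has module/mean_r/se_r/n
    sorted by mean_r descending; contrasts has module/p_wmw for the
    top module against each other.
    """
    modules = pd.Series(modules, dtype=object)
    tr = trait.aligned_to(expr)
    if tr.size < 3:
        raise ValidationError("trait must cover at least 3 samples")
    sub = np.log2(expr.values[tr.index] + 1.0)
    r_gene = sub.T.corrwith(tr)

    rows = []
    per_module: dict[str, np.ndarray] = {}
    for mod, genes in modules.groupby(modules).groups.items():
        rs = r_gene.reindex(genes).dropna().to_numpy()
        if rs.size < 2:
            logger.warning("module %s has < 2 correlated genes; excluded", mod)
            continue
        per_module[str(mod)] = rs
        rows.append(
            {
                "module": str(mod),
                "mean_r": float(rs.mean()),
                "se_r": float(rs.std(ddof=1) / np.sqrt(rs.size)),
                "n": int(rs.size),
            }
        )
    if not rows:
        raise ValidationError("no module with >= 2 genes")
    summary = pd.DataFrame(rows).sort_values("mean_r", ascending=False, ignore_index=True)
    top = summary.loc[0, "module"]
    contrasts = []
    for mod, rs in per_module.items():
        if mod == top:
            continue
        stat = stats.mannwhitneyu(per_module[top], rs, alternative="two-sided")
        contrasts.append({"module": mod, "p_wmw": float(stat.pvalue)})
    return summary, pd.DataFrame(contrasts)


def trajectory_zscore(
    expr: ExpressionMatrix,
    genes: Sequence[str],
    condition: str,
    timepoints: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Per-gene z-scored log2(median TPM + 1) trajectories.

    For each gene: the median TPM over replicates at each timepoint is
    log2(median + 1)-transformed, then z-scored across timepoints.  A
    gene constant across timepoints gets an all-zero row (flagged in
    the log).  Returns genes x timepoints; the gene-set profile is the
    column mean.
    """
    sub = expr.subset_samples(condition=condition)
    if timepoints is None:
        timepoints = sorted(sub.samples["timepoint"].unique())
    if len(timepoints) < 2:
        raise ValidationError("trajectory needs >= 2 timepoints")
    med = pd.DataFrame(index=pd.Index(list(genes), name="gene_id"),
                       columns=list(timepoints), dtype=float)
    for t in timepoints:
        cols = sub.samples.index[sub.samples["timepoint"] == t]
        if len(cols) == 0:
            raise ValidationError(f"no samples at timepoint {t} for {condition!r}")
        med[t] = sub.values.loc[list(genes), cols].median(axis=1)
    logm = np.log2(med + 1.0)
    mu = logm.mean(axis=1)
    sd = logm.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        logger.warning(
            "%d gene(s) constant across timepoints; z set to 0", int(flat.sum())
        )
    sd = sd.replace(0.0, np.inf)  # constant rows -> z = 0
    return logm.sub(mu, axis=0).div(sd, axis=0)


def significance_tier(p: float) -> str:
    """Tier labels matching the conventional < .05/.01/.001/.0001 cuts."""
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def stage_condition_contrast(
    z_by_condition: Mapping[str, pd.DataFrame],
    stages: StagePartition,
) -> pd.DataFrame:
    """Welch t-tests comparing per-gene z values between two conditions.

    *z_by_condition* maps each condition to its genes x timepoints
    z-matrix (see :func:`trajectory_zscore`).  For each stage, each
    gene's z values are averaged over the stage's timepoints and the
    two conditions are compared with an unequal-variance t-test.
    Returns stage/t/p/tier rows; a stage where a condition has < 2
    genes is skipped.
    """
    conds = list(z_by_condition)
    if len(conds) != 2:
        raise ValidationError(f"need exactly 2 conditions, got {conds}")
    a, b = (z_by_condition[c] for c in conds)
    rows = []
    for stage in ("early", "mid", "late"):
        tps = [t for t in getattr(stages, stage)]
        xa = a[[t for t in tps if t in a.columns]].mean(axis=1).dropna()
        xb = b[[t for t in tps if t in b.columns]].mean(axis=1).dropna()
        if len(xa) < 2 or len(xb) < 2:
            logger.warning("stage %s: a condition has < 2 genes; test skipped", stage)
            continue
        res = stats.ttest_ind(xa, xb, equal_var=False)
        rows.append(
            {
                "stage": stage,
                "condition_a": conds[0],
                "condition_b": conds[1],
                "t": float(res.statistic),
                "p": float(res.pvalue),
                "tier": significance_tier(float(res.pvalue)),
            }
        )
    return pd.DataFrame(rows)
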