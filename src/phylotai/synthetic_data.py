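"""Synthetic inputs with the statistical structure the analysis assumes.

The generator emulates a wounding/herbivory time-course experiment on a
plant with a stratified gene catalog:

* a catalog split into a *young/divergent* pool (high phylostrata,
  high Ka/Ks) and an *ancient/conserved* pool (low strata, low Ka/Ks),
  building in the age-divergence coupling that lets one induction
  scenario drive both the age and the divergence index;
* condition- and time-dependent induction: under an *hourglass*
  scenario the genes induced at early and late timepoints are drawn
  mostly from the young pool and the mid-timepoint genes from the
  ancient pool; a *vase* scenario swaps the pools; a *flat* scenario
  draws pool-blind;
* replicate TPM expression with co-expression modules, one of which is
  coupled to a hormone-like trait;
* homology hits consistent with each gene's true stratum, plus
  optional viral and above-cutoff decoys;
* orthologous CDS pairs mutated toward each gene's target Ks and
  Ka/Ks.

Every output is a pure function of the configuration and its seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from phylotai.data_model import (
    ExpressionMatrix,
    GeneCatalog,
    InductionTable,
    StagePartition,
    TraitSeries,
    ValidationError,
)
from phylotai.divergence import CODON_TO_AA, SENSE_CODONS, CodonAlignment
from phylotai.phylostrata import HitTable, Lineage

__all__ = [
    "ScenarioConfig",
    "toy_lineage_and_taxonomy",
    "simulate_catalog",
    "simulate_induction",
    "simulate_expression",
    "simulate_homology_hits",
    "simulate_cds_pairs",
]

logger = logging.getLogger(__name__)

PATTERNS = ("hourglass", "vase", "flat")


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one synthetic study.

    Defaults mirror a two-condition wounding time course sampled at
    0.5, 1, 5 and 11 h with 13 phylostrata: an hourglass-patterned
    control condition, a vase-patterned stressed condition, ~15% of
    genes induced per timepoint with mean |log2FC| 2, and a gene pool
    split in which young genes (strata 9-13) carry Ka/Ks 0.4-1.2 and
    ancient genes (strata 1-4) carry Ka/Ks 0.05-0.3.
    """

    seed: int
    n_genes: int = 2000
    n_strata: int = 13
    timepoints: tuple[float, ...] = (0.5, 1.0, 5.0, 11.0)
    patterns: Mapping[str, str] = field(
        default_factory=lambda: {"CT": "hourglass", "HT": "vase"}
    )
    stages: StagePartition = field(default_factory=StagePartition.default)
    effect_size: float = 2.0
    effect_sd: float = 0.5
    frac_induced: float = 0.15
    up_fraction: float = 0.5
    pool_bias: float = 0.9  # induced genes drawn from the favored pool
    young_fraction: float = 0.5
    young_ps: tuple[int, int] = (9, 13)
    young_kaks: tuple[float, float] = (0.4, 1.2)
    ancient_ps: tuple[int, int] = (1, 4)
    ancient_kaks: tuple[float, float] = (0.05, 0.3)
    noise_sd: float = 0.3  # log2FC noise on non-induced genes
    n_replicates: int = 3
    expr_noise_sd: float = 0.5
    n_modules: int = 4
    module_size: int = 50
    trait_module: str = "M1"
    trait_noise_sd: float = 0.2

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("a seed is mandatory")
        for name in ("frac_induced", "up_fraction", "pool_bias", "young_fraction"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValidationError(f"{name} must lie in (0, 1], got {v}")
        for name in ("young_ps", "ancient_ps"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi <= self.n_strata):
                raise ValidationError(f"{name}={lo, hi} outside 1..{self.n_strata}")
        for cond, pat in self.patterns.items():
            if pat not in PATTERNS:
                raise ValidationError(
                    f"unknown pattern {pat!r} for {cond!r}; choices: {PATTERNS}"
                )


# ---------------------------------------------------------------------------
# Gene catalog
# ---------------------------------------------------------------------------

def simulate_catalog(cfg: ScenarioConfig) -> GeneCatalog:
    """Catalog with young/divergent and ancient/conserved gene pools.

    The returned table carries a ground-truth ``pool`` column.  Ks
    values are drawn inside the conventional retention window so no
    gene is lost to the Ks filter by construction.
    """
    rng = np.random.default_rng([cfg.seed, 11])
    n_young = int(round(cfg.n_genes * cfg.young_fraction))
    n_ancient = cfg.n_genes - n_young
    if n_young == 0 or n_ancient == 0:
        raise ValidationError("both gene pools must be non-empty")
    width = int(math.ceil(math.log10(max(cfg.n_genes, 10))))
    gene_ids = [f"g{i:0{width}d}" for i in range(cfg.n_genes)]
    pool = np.array(["young"] * n_young + ["ancient"] * n_ancient)
    rng.shuffle(pool)
    ps = np.where(
        pool == "young",
        rng.integers(cfg.young_ps[0], cfg.young_ps[1] + 1, cfg.n_genes),
        rng.integers(cfg.ancient_ps[0], cfg.ancient_ps[1] + 1, cfg.n_genes),
    )
    kaks = np.where(
        pool == "young",
        rng.uniform(cfg.young_kaks[0], cfg.young_kaks[1], cfg.n_genes),
        rng.uniform(cfg.ancient_kaks[0], cfg.ancient_kaks[1], cfg.n_genes),
    )
    ks = rng.uniform(0.1, 0.7, cfg.n_genes)
    table = pd.DataFrame(
        {"gene_id": gene_ids, "ps": ps, "kaks": kaks, "ks": ks, "pool": pool}
    )
    return GeneCatalog(table, n_strata=cfg.n_strata)


# ---------------------------------------------------------------------------
# Induction tables
# ---------------------------------------------------------------------------

def _favored_pool(pattern: str, stage: str) -> str | None:
    if pattern == "flat":
        return None
    if pattern == "hourglass":
        return "ancient" if stage == "mid" else "young"
    return "young" if stage == "mid" else "ancient"  # vase


def simulate_induction(cfg: ScenarioConfig, catalog: GeneCatalog) -> InductionTable:
    """Per-condition log2FC/padj tables with the configured patterns.

    At each timepoint a fraction of genes is induced with folded-normal
    |log2FC| (mean ``effect_size``) and padj < 0.01; under non-flat
    patterns a ``pool_bias`` share of the induced genes comes from the
    stage's favored pool.  Non-induced genes get Gaussian log2FC noise
    and uniform padj.
    """
    n_induced = int(round(cfg.frac_induced * cfg.n_genes))
    if n_induced < 10:
        logger.warning(
            "only %d induced genes per timepoint: downstream tests underpowered",
            n_induced,
        )
    rng = np.random.default_rng([cfg.seed, 23])
    genes = catalog.table["gene_id"].to_numpy()
    pool = catalog.table["pool"].to_numpy() if "pool" in catalog.table else None
    if pool is None:
        raise ValidationError("catalog lacks the generator's pool column")
    idx_young = np.flatnonzero(pool == "young")
    idx_ancient = np.flatnonzero(pool == "ancient")

    frames = []
    for cond, pattern in cfg.patterns.items():
        for t in cfg.timepoints:
            stage = cfg.stages.stage_of(t)
            favored = _favored_pool(pattern, stage)
            if favored is None:
                chosen = rng.choice(len(genes), size=n_induced, replace=False)
            else:
                fav_idx = idx_young if favored == "young" else idx_ancient
                oth_idx = idx_ancient if favored == "young" else idx_young
                n_fav = min(int(round(cfg.pool_bias * n_induced)), len(fav_idx))
                n_oth = n_induced - n_fav
                chosen = np.concatenate(
                    [
                        rng.choice(fav_idx, size=n_fav, replace=False),
                        rng.choice(oth_idx, size=n_oth, replace=False),
                    ]
                )
            induced = np.zeros(len(genes), dtype=bool)
            induced[chosen] = True

            log2fc = rng.normal(0.0, cfg.noise_sd, len(genes))
            magnitude = np.abs(rng.normal(cfg.effect_size, cfg.effect_sd, n_induced))
            sign = np.where(rng.random(n_induced) < cfg.up_fraction, 1.0, -1.0)
            log2fc[chosen] = sign * magnitude
            padj = rng.uniform(0.0, 1.0, len(genes))
            padj[chosen] = rng.uniform(0.0, 0.01, n_induced)
            frames.append(
                pd.DataFrame(
                    {
                        "gene_id": genes,
                        "condition": cond,
                        "timepoint": t,
                        "log2fc": log2fc,
                        "padj": padj,
                    }
                )
            )
    return InductionTable(pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# Expression + trait + modules
# ---------------------------------------------------------------------------

def simulate_expression(
    cfg: ScenarioConfig, catalog: GeneCatalog
) -> tuple[ExpressionMatrix, TraitSeries, pd.Series]:
    """Replicate TPM matrix, hormone-like trait, ground-truth modules.

    TPM = 2^latent with latent = module signal (shared per module) +
    gene offset + Gaussian noise; the trait is an affine function of
    the trait-coupled module's per-sample signal plus noise.
    """
    if cfg.n_replicates < 2:
        raise ValidationError("need at least 2 replicates")
    rng = np.random.default_rng([cfg.seed, 37])
    genes = list(catalog.table["gene_id"])
    needed = cfg.n_modules * cfg.module_size
    if needed > len(genes):
        raise ValidationError(
            f"{cfg.n_modules} modules x {cfg.module_size} genes exceed the catalog"
        )
    member_genes = rng.choice(len(genes), size=needed, replace=False)
    modules = pd.Series(
        {
            genes[g]: f"M{k + 1}"
            for k, block in enumerate(np.split(member_genes, cfg.n_modules))
            for g in block
        },
        name="module",
    )

    samples = []
    for cond in cfg.patterns:
        for t in cfg.timepoints:
            for r in range(1, cfg.n_replicates + 1):
                samples.append((f"{cond}:{t:g}:R{r}", cond, t, f"R{r}"))
    sample_df = pd.DataFrame(
        samples, columns=["sample", "condition", "timepoint", "replicate"]
    ).set_index("sample")
    n_samples = len(sample_df)

    # per-module temporal signals, shared by replicates; orthogonal across
    # (condition, timepoint) cells so modules are statistically separable
    module_names = [f"M{k + 1}" for k in range(cfg.n_modules)]
    cells = [(cond, t) for cond in cfg.patterns for t in cfg.timepoints]
    if cfg.n_modules > len(cells):
        raise ValidationError(
            f"{cfg.n_modules} modules need at least as many condition x "
            f"timepoint cells (have {len(cells)})"
        )
    q, _ = np.linalg.qr(rng.normal(size=(len(cells), cfg.n_modules)))
    amps = rng.uniform(1.0, 2.0, cfg.n_modules)
    signals = {}
    for k, m in enumerate(module_names):
        per_cell = dict(zip(cells, q[:, k] * amps[k] * math.sqrt(len(cells))))
        signals[m] = np.array(
            [per_cell[(row.condition, row.timepoint)] for row in sample_df.itertuples()]
        )

    base = rng.uniform(2.0, 6.0, len(genes))  # log2 baseline abundance
    latent = np.tile(base[:, None], (1, n_samples))
    for i, g in enumerate(genes):
        m = modules.get(g)
        if m is not None:
            latent[i] += signals[m]
    latent += rng.normal(0.0, cfg.expr_noise_sd, latent.shape)
    values = pd.DataFrame(
        np.power(2.0, latent), index=pd.Index(genes, name="gene_id"),
        columns=sample_df.index,
    )
    expr = ExpressionMatrix(values, sample_df)

    sig = signals[cfg.trait_module]
    trait_vals = 10.0 + 4.0 * sig + rng.normal(0.0, cfg.trait_noise_sd, n_samples)
    trait = TraitSeries(pd.Series(trait_vals, index=sample_df.index), name="JA")
    return expr, trait, modules


# ---------------------------------------------------------------------------
# Homology hits
# ---------------------------------------------------------------------------

def toy_lineage_and_taxonomy(
    n_strata: int = 13,
) -> tuple[Lineage, dict[str, str], list[str]]:
    """A small nested taxonomy with one leaf taxon branching per stratum.

    Returns (lineage, child->parent taxonomy, per-stratum leaf taxa):
    ``leaves[k-1]`` maps to stratum k.  The leaf of the last stratum is
    the focal species itself.
    """
    clades = ["cellular organisms"] + [f"clade_{i}" for i in range(2, n_strata)] + [
        "focal_species"
    ]
    lineage = Lineage(tuple(clades))
    taxonomy: dict[str, str] = {}
    for parent, child in zip(clades, clades[1:]):
        taxonomy[child] = parent
    leaves = []
    for k, clade in enumerate(clades, start=1):
        if k == n_strata:
            leaves.append(clade)  # focal species itself
            continue
        leaf = f"taxon_ps{k}"
        taxonomy[leaf] = clade
        leaves.append(leaf)
    return lineage, taxonomy, leaves


def simulate_homology_hits(
    catalog: GeneCatalog,
    lineage: Lineage,
    taxonomy: Mapping[str, str],
    leaves: Sequence[str],
    seed: int,
    n_extra_hits: int = 3,
    decoy_above_cutoff: bool = False,
    decoy_viral: bool = False,
) -> HitTable:
    """Hits consistent with each gene's true stratum, plus optional decoys.

    Every gene receives one anchoring hit to a taxon of its true
    stratum and extra hits to taxa at equal-or-younger strata, all at
    e-values well below the conventional cutoff.  Decoy options add an
    above-cutoff hit to the oldest stratum (e-value 1e-03) and a viral
    hit, neither of which must change any assignment.
    """
    rng = np.random.default_rng(seed)
    rows = []
    n_strata = lineage.n_strata
    for gene, ps in zip(catalog.table["gene_id"], catalog.table["ps"]):
        rows.append((gene, leaves[ps - 1], float(rng.uniform(1e-30, 1e-06)), False))
        if ps < n_strata:
            extra = rng.integers(ps, n_strata + 1, size=n_extra_hits)
            for s in extra:
                rows.append((gene, leaves[s - 1], float(rng.uniform(1e-30, 1e-06)), False))
        if decoy_above_cutoff:
            rows.append((gene, leaves[0], 1e-03, False))
        if decoy_viral:
            rows.append((gene, "synthetic_virus", float(rng.uniform(1e-80, 1e-40)), True))
    table = pd.DataFrame(rows, columns=["gene_id", "subject_taxon", "evalue", "viral"])
    return HitTable(table)


# ---------------------------------------------------------------------------
# CDS pairs
# ---------------------------------------------------------------------------

_SENSE = sorted(SENSE_CODONS)
_BASES = "ACGT"


def _neighbors(codon: str, synonymous: bool) -> list[str]:
    aa = CODON_TO_AA[codon]
    out = []
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut not in CODON_TO_AA:
                continue  # stop codons never introduced
            if (CODON_TO_AA[mut] == aa) == synonymous:
                out.append(mut)
    return out


def _inverse_jc(d: float) -> float:
    """Difference proportion that the JC distance *d* corrects to."""
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


def simulate_cds_pairs(
    catalog: GeneCatalog,
    seed: int,
    n_codons: int = 300,
    genes: Sequence[str] | None = None,
) -> dict[str, CodonAlignment]:
    """Orthologous CDS pairs mutated toward each gene's target Ks and Ka/Ks.

    One random sense-codon sequence per gene is copied and hit with
    Poisson numbers of synonymous and nonsynonymous single-base codon
    changes whose expectations match the gene's target divergence
    (after undoing the multiple-hit correction).  No stop codons are
    ever introduced.  Genes whose targets are saturated (proportion
    >= 3/4) are skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    sub = catalog.table if genes is None else catalog.table[
        catalog.table["gene_id"].isin(set(genes))
    ]
    out: dict[str, CodonAlignment] = {}
    for row in sub.itertuples():
        ks = float(row.ks) if np.isfinite(row.ks) else 0.0
        kaks = float(row.kaks) if np.isfinite(row.kaks) else 0.0
        ka = kaks * ks
        ps_prop, pn_prop = _inverse_jc(ks), _inverse_jc(ka)
        if ps_prop >= 0.75 or pn_prop >= 0.75:
            logger.warning("gene %s: target divergence saturated; skipped", row.gene_id)
            continue
        codons = [str(_SENSE[i]) for i in rng.integers(0, len(_SENSE), n_codons)]
        mutated = list(codons)
        # ~1/4 of codon positions are synonymous sites under the code
        n_syn = rng.poisson(ps_prop * 0.25 * 3 * n_codons)
        n_non = rng.poisson(pn_prop * 0.75 * 3 * n_codons)
        for synonymous, count in ((True, n_syn), (False, n_non)):
            applied = 0
            attempts = 0
            while applied < count and attempts < 20 * (count + 1):
                attempts += 1
                j = int(rng.integers(0, n_codons))
                nb = _neighbors(mutated[j], synonymous)
                if nb:
                    mutated[j] = nb[int(rng.integers(0, len(nb)))]
                    applied += 1
        out[str(row.gene_id)] = CodonAlignment("".join(codons), "".join(mutated))
    return out


def write_cds_pairs(pairs: Mapping[str, CodonAlignment], path: str | Path) -> None:
    """Write pairs as FASTA with ids ``<gene>|focal`` / ``<gene>|outgroup``."""
    with open(path, "w") as fh:
        for gene, aln in pairs.items():
            fh.write(f">{gene}|focal\n{aln.seq_a}\n>{gene}|outgroup\n{aln.seq_b}\n")
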