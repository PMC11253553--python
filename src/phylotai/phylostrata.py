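"""Phylostratigraphic gene-age assignment.

A gene's phylostratum (PS) is the rank of the oldest clade on the focal
species' lineage that contains a detectable homolog: PS 1 corresponds to
the root of cellular life (most ancient), PS ``n_strata`` to the focal
species itself (youngest).  Assignment follows the standard
min-stratum convention: filter homology hits by e-value, exclude viral
and non-cellular subjects, map each remaining subject taxon onto the
lineage, and take the minimum stratum index over the mapped hits.
Genes with no surviving non-self hit are species-specific.

The taxonomy is supplied as a small child -> parent mapping so that
tests and simulations need no external taxonomy dump; an adapter for a
full NCBI-style taxonomy can be layered on top of the same mapping
interface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from phylotai.data_model import GeneCatalog, ValidationError

__all__ = [
    "Lineage",
    "HitTable",
    "map_taxon_to_stratum",
    "assign_phylostrata",
    "read_hit_table",
]

logger = logging.getLogger(__name__)

DEFAULT_EVALUE_CUTOFF = 1e-05


@dataclass(frozen=True)
class Lineage:
    """Ordered clades from the root of cellular life to the focal species.

    ``clades[0]`` is the most ancient clade (stratum 1), ``clades[-1]``
    the focal species (stratum ``n_strata``).
    """

    clades: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.clades) < 2:
            raise ValidationError("lineage needs at least root and focal species")
        if len(set(self.clades)) != len(self.clades):
            raise ValidationError("lineage clade labels must be unique")

    @property
    def n_strata(self) -> int:
        return len(self.clades)

    @property
    def root(self) -> str:
        return self.clades[0]

    @property
    def focal(self) -> str:
        return self.clades[-1]


@dataclass
class HitTable:
    """Homology hits: query gene, subject taxon, e-value, viral flag."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["gene_id", "subject_taxon", "evalue"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValidationError(f"hit table missing columns: {missing}")
        if (self.table["evalue"] < 0).any():
            raise ValidationError("negative e-value in hit table")
        if "viral" not in self.table.columns:
            self.table = self.table.assign(viral=False)
        self.table["viral"] = self.table["viral"].astype(bool)

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def read_hit_table(path: str | Path) -> HitTable:
    """Read hits from a headered TSV or headerless BLAST outfmt-6 file.

    The headered form uses columns gene_id / subject_taxon / evalue
    (optional viral).  The outfmt-6 form takes qseqid from column 1,
    the subject taxon label from column 2 and evalue from column 11.
    """
    with open(path) as fh:
        first = fh.readline()
    cols = first.rstrip("\n").split("\t")
    if "gene_id" in cols:
        t = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "subject_taxon": str})
        return HitTable(t)
    if len(cols) >= 12:  # BLAST tabular without header
        raw = pd.read_csv(path, sep="\t", header=None)
        t = pd.DataFrame(
            {
                "gene_id": raw[0].astype(str),
                "subject_taxon": raw[1].astype(str),
                "evalue": raw[10].astype(float),
            }
        )
        return HitTable(t)
    raise ValidationError(
        f"unrecognized hit-table layout in {path}: expected a gene_id header "
        "or >= 12 tab-separated columns"
    )


def _ancestry(taxon: str, taxonomy: Mapping[str, str]) -> set[str]:
    """The taxon and all its ancestors under the child -> parent mapping."""
    seen = {taxon}
    node = taxon
    while node in taxonomy and taxonomy[node] != node:
        node = taxonomy[node]
        if node in seen:
            raise ValidationError(f"taxonomy cycle at {node!r}")
        seen.add(node)
    return seen


def map_taxon_to_stratum(
    taxon: str, lineage: Lineage, taxonomy: Mapping[str, str]
) -> int:
    """Stratum index (1-based) of the deepest lineage clade containing *taxon*.

    Raises if the taxon is neither a lineage clade nor present in the
    taxonomy mapping.
    """
    if taxon not in taxonomy and taxon not in lineage.clades:
        raise ValidationError(f"taxon not in taxonomy: {taxon!r}")
    anc = _ancestry(taxon, taxonomy)
    best = 0
    for i, clade in enumerate(lineage.clades, start=1):
        if clade in anc:
            best = i
    if best == 0:
        raise ValidationError(
            f"taxon {taxon!r} shares no clade with the focal lineage "
            "(non-cellular subject?)"
        )
    return best


def assign_phylostrata(
    hits: HitTable,
    lineage: Lineage,
    taxonomy: Mapping[str, str],
    genes: Sequence[str],
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
) -> pd.Series:
    """Assign each gene in *genes* its phylostratum from homology hits.

    Hits with e-value above the cutoff and viral or non-cellular
    subjects are discarded; each surviving subject taxon is mapped to a
    lineage stratum and the gene receives the minimum (oldest) stratum.
    Genes with no surviving hit get ``lineage.n_strata``
    (species-specific).  Returns a gene_id -> ps integer Series.
    """
    n_strata = lineage.n_strata
    t = hits.table
    if t.empty:
        logger.warning("empty hit table: all %d genes set to ps=%d", len(genes), n_strata)
        return pd.Series(n_strata, index=pd.Index(genes, name="gene_id"), name="ps")

    kept = t[(t["evalue"] <= evalue_cutoff) & ~t["viral"]]
    n_dropped = len(t) - len(kept)
    if n_dropped:
        logger.info("dropped %d hits (e-value > %g or viral)", n_dropped, evalue_cutoff)

    strata_cache: dict[str, int | None] = {}

    def stratum_of(taxon: str) -> int | None:
        if taxon not in strata_cache:
            try:
                strata_cache[taxon] = map_taxon_to_stratum(taxon, lineage, taxonomy)
            except ValidationError:
                if taxon not in taxonomy and taxon not in lineage.clades:
                    raise
                strata_cache[taxon] = None  # non-cellular: excluded
        return strata_cache[taxon]

    mapped = kept["subject_taxon"].map(stratum_of)
    kept = kept.assign(stratum=mapped).dropna(subset=["stratum"])
    per_gene = kept.groupby("gene_id")["stratum"].min().astype(int)

    out = per_gene.reindex(pd.Index(genes, name="gene_id")).fillna(n_strata).astype(int)
    out.name = "ps"
    n_orphan = int((~pd.Index(genes).isin(per_gene.index)).sum())
    if n_orphan:
        logger.info("%d genes without qualifying hits set to ps=%d", n_orphan, n_strata)
    return out


def write_lineage(lineage: Lineage, path: str | Path) -> None:
    Path(path).write_text("\n".join(lineage.clades) + "\n")


def read_lineage(path: str | Path) -> Lineage:
    clades = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    return Lineage(tuple(clades))


def write_taxonomy(taxonomy: Mapping[str, str], path: str | Path) -> None:
    df = pd.DataFrame(sorted(taxonomy.items()), columns=["child", "parent"])
    df.to_csv(path, sep="\t", index=False)


def read_taxonomy(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["child"], df["parent"]))


def catalog_from_hits(
    hits: HitTable,
    lineage: Lineage,
    taxonomy: Mapping[str, str],
    genes: Sequence[str],
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
) -> GeneCatalog:
    """Convenience wrapper building a GeneCatalog (ps only, Ka/Ks missing)."""
    ps = assign_phylostrata(hits, lineage, taxonomy, genes, evalue_cutoff)
    table = pd.DataFrame(
        {
            "gene_id": ps.index,
            "ps": ps.values,
            "kaks": float("nan"),
            "ks": float("nan"),
        }
    )
    return GeneCatalog(table, n_strata=lineage.n_strata)
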