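"""Pairwise Ka/Ks estimation between orthologous coding sequences.

Implements the Nei-Gojobori (1986) counting estimator with the
Jukes-Cantor multiple-hit correction on gapless codon alignments:

* synonymous/nonsynonymous *site* counts per codon, with mutations to
  stop codons excluded from the per-position denominator so that the
  site fractions of every sense codon sum exactly to 3;
* synonymous/nonsynonymous *difference* counts per codon pair averaged
  with equal weight over all minimal mutational pathways that avoid
  stop-codon intermediates;
* proportions corrected by d = -(3/4) ln(1 - 4p/3).

The estimator is symmetric in sequence order and closed-form, so small
alignments can be checked against exhaustive enumeration.  Precomputed
Ka/Ks tables from an external maximum-likelihood tool can be supplied
instead through :func:`read_divergence_table`.
"""

from __future__ import annotations

import functools
import itertools
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Data.CodonTable import unambiguous_dna_by_id

__all__ = [
    "CodonAlignment",
    "DivergenceRecord",
    "SaturationError",
    "ng86_site_counts",
    "ng86_codon_differences",
    "ng86_pairwise",
    "filter_by_ks",
    "read_paired_fasta",
    "write_divergence_table",
    "read_divergence_table",
]

_TABLE = unambiguous_dna_by_id[1]  # standard genetic code
STOP_CODONS = frozenset(_TABLE.stop_codons)
_BASES = "ACGT"

CODON_TO_AA = dict(_TABLE.forward_table)
SENSE_CODONS = frozenset(CODON_TO_AA)


class SaturationError(ValueError):
    """Observed difference proportion >= 3/4: the JC correction diverges."""


@dataclass(frozen=True)
class CodonAlignment:
    """Two gapless, codon-aligned nucleotide sequences of equal length."""

    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        a, b = self.seq_a.upper(), self.seq_b.upper()
        object.__setattr__(self, "seq_a", a)
        object.__setattr__(self, "seq_b", b)
        if len(a) != len(b):
            raise ValueError("aligned sequences differ in length")
        if len(a) % 3 != 0:
            raise ValueError(f"alignment length {len(a)} not divisible by 3")
        for name, s in (("a", a), ("b", b)):
            bad = set(s) - set(_BASES)
            if bad:
                raise ValueError(f"sequence {name} has non-ACGT characters: {bad}")
            for i in range(0, len(s), 3):
                if s[i : i + 3] in STOP_CODONS:
                    raise ValueError(
                        f"internal stop codon {s[i:i+3]} at position {i} in sequence {name}"
                    )

    def codons(self) -> list[tuple[str, str]]:
        return [
            (self.seq_a[i : i + 3], self.seq_b[i : i + 3])
            for i in range(0, len(self.seq_a), 3)
        ]


@dataclass
class DivergenceRecord:
    """Ka, Ks and their ratio for one gene pair; kaks is NaN when Ks = 0."""

    gene_id: str
    ka: float
    ks: float

    @property
    def kaks(self) -> float:
        if self.ks > 0:
            return self.ka / self.ks
        return float("nan")


def _site_fractions(codon: str) -> float:
    """Synonymous site fraction of a sense codon (stop targets excluded)."""
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            valid += 1
            if CODON_TO_AA[mutant] == aa:
                syn += 1
        if valid:
            s += syn / valid
    return s


_SITE_CACHE: dict[str, float] = {c: _site_fractions(c) for c in SENSE_CODONS}


def ng86_site_counts(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one sense codon.

    The two counts sum to 3 exactly; mutations creating stop codons do
    not enter the per-position denominators.
    """
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no site counts")
    if codon not in SENSE_CODONS:
        raise ValueError(f"not a valid codon: {codon!r}")
    s = _SITE_CACHE[codon]
    return s, 3.0 - s


def _pathway_steps(start: str, end: str, order: tuple[int, ...]) -> list[tuple[str, str]] | None:
    """Codon steps along one mutational pathway; None if it hits a stop."""
    steps = []
    cur = start
    for pos in order:
        nxt = cur[:pos] + end[pos] + cur[pos + 1 :]
        if nxt in STOP_CODONS:
            return None
        steps.append((cur, nxt))
        cur = nxt
    return steps


@functools.lru_cache(maxsize=None)
def ng86_codon_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts for one codon pair.

    Counts are averaged with equal weight over all minimal mutational
    pathways that avoid stop-codon intermediates.  If every pathway
    passes through a stop, all pathways are used (each stop-crossing
    step counted as nonsynonymous) so the total stays equal to the
    number of differing positions.
    """
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0
    valid: list[tuple[float, float]] = []
    fallback: list[tuple[float, float]] = []
    for order in itertools.permutations(diff):
        steps = _pathway_steps(codon_a, codon_b, order)
        if steps is None:
            # re-walk without pruning for the fallback average
            cur = codon_a
            sd = nd = 0.0
            for pos in order:
                nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
                if (
                    cur not in STOP_CODONS
                    and nxt not in STOP_CODONS
                    and CODON_TO_AA[cur] == CODON_TO_AA[nxt]
                ):
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            fallback.append((sd, nd))
            continue
        sd = sum(1.0 for a, b in steps if CODON_TO_AA[a] == CODON_TO_AA[b])
        valid.append((sd, len(diff) - sd))
    paths = valid if valid else fallback
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        raise SaturationError(
            f"difference proportion {p:.3f} >= 3/4: Jukes-Cantor correction undefined"
        )
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86_pairwise(aln: CodonAlignment, gene_id: str = "") -> DivergenceRecord:
    """Nei-Gojobori Ka and Ks for a codon alignment.

    Site counts are averaged over the two sequences; the result is
    symmetric in sequence order.
    """
    S = N = 0.0
    Sd = Nd = 0.0
    for ca, cb in aln.codons():
        sa, _ = ng86_site_counts(ca)
        sb, _ = ng86_site_counts(cb)
        S += 0.5 * (sa + sb)
        sd, nd = ng86_codon_differences(ca, cb)
        Sd += sd
        Nd += nd
    N = 3.0 * (len(aln.seq_a) // 3) - S
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    return DivergenceRecord(gene_id=gene_id, ka=_jukes_cantor(pn), ks=_jukes_cantor(ps))


def filter_by_ks(
    records: list[DivergenceRecord], low: float = 0.05, high: float = 1.0
) -> tuple[list[DivergenceRecord], dict[str, int]]:
    """Retain records with ``low < ks < high`` (both bounds strict).

    Returns the retained records and a report counting the drops on
    either side of the window.
    """
    kept: list[DivergenceRecord] = []
    report = {"retained": 0, "dropped_low": 0, "dropped_high": 0}
    for r in records:
        if r.ks <= low:
            report["dropped_low"] += 1
        elif r.ks >= high:
            report["dropped_high"] += 1
        else:
            kept.append(r)
            report["retained"] += 1
    return kept, report


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_paired_fasta(path: str | Path) -> dict[str, CodonAlignment]:
    """Read gene-paired CDS FASTA with ids ``<gene>|<tag>`` (two per gene)."""
    groups: dict[str, list[str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        gene = rec.id.rsplit("|", 1)[0]
        groups.setdefault(gene, []).append(str(rec.seq))
    out = {}
    for gene, seqs in groups.items():
        if len(seqs) != 2:
            raise ValueError(f"gene {gene!r} has {len(seqs)} records, expected 2")
        out[gene] = CodonAlignment(seqs[0], seqs[1])
    return out


def write_divergence_table(records: list[DivergenceRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "ka": [r.ka for r in records],
            "ks": [r.ks for r in records],
            "kaks": [r.kaks for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_divergence_table(path: str | Path) -> list[DivergenceRecord]:
    """Read a gene_id/ka/ks TSV, e.g. exported from an external ML tool."""
    df = pd.read_csv(path, sep="\t", na_values=["NA", ""], keep_default_na=False)
    return [
        DivergenceRecord(gene_id=str(r.gene_id), ka=float(r.ka), ks=float(r.ks))
        for r in df.itertuples()
    ]
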