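"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation modules' internals: codon
translation goes through Bio.Seq, pathway enumeration is a recursive
depth-first walk, and the weighted-mean index is a plain Python loop.
"""

from __future__ import annotations

import math

from Bio.Seq import Seq

STOPS = {"TAA", "TAG", "TGA"}


def translate(codon: str) -> str:
    return str(Seq(codon).translate())


def oracle_site_counts(codon: str) -> tuple[float, float]:
    """Enumerate all 9 point mutations; stop targets leave the denominator."""
    aa = translate(codon)
    syn = 0.0
    for pos in range(3):
        muts = [
            codon[:pos] + b + codon[pos + 1 :]
            for b in "ACGT"
            if b != codon[pos]
        ]
        sense = [m for m in muts if m not in STOPS]
        if sense:
            syn += sum(translate(m) == aa for m in sense) / len(sense)
    return syn, 3.0 - syn


def _enumerate_paths(a: str, b: str):
    """All stop-free orderings of the differing positions, as step lists."""
    diff = [i for i in range(3) if a[i] != b[i]]

    def walk(cur, remaining, steps):
        if not remaining:
            yield steps
            return
        for i, pos in enumerate(remaining):
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in STOPS:
                continue
            yield from walk(nxt, remaining[:i] + remaining[i + 1 :], steps + [(cur, nxt)])

    return list(walk(a, diff, []))


def oracle_codon_diffs(a: str, b: str) -> tuple[float, float]:
    paths = _enumerate_paths(a, b)
    if not paths:  # all pathways stop-blocked: count every step nonsynonymous
        ndiff = sum(x != y for x, y in zip(a, b))
        return 0.0, float(ndiff)
    sd = nd = 0.0
    for steps in paths:
        for x, y in steps:
            if translate(x) == translate(y):
                sd += 1
            else:
                nd += 1
    return sd / len(paths), nd / len(paths)


def oracle_ng86(seq_a: str, seq_b: str) -> tuple[float, float]:
    """(ka, ks) by exhaustive enumeration with Jukes-Cantor correction."""
    S = Sd = Nd = 0.0
    n_codons = len(seq_a) // 3
    for i in range(n_codons):
        ca, cb = seq_a[3 * i : 3 * i + 3], seq_b[3 * i : 3 * i + 3]
        S += (oracle_site_counts(ca)[0] + oracle_site_counts(cb)[0]) / 2
        sd, nd = oracle_codon_diffs(ca, cb)
        Sd += sd
        Nd += nd
    N = 3 * n_codons - S
    ps = Sd / S if S else 0.0
    pn = Nd / N if N else 0.0
    jc = lambda p: -0.75 * math.log(1 - 4 * p / 3)
    return jc(pn), jc(ps)


SENSE = sorted(
    "".join(c) for c in __import__("itertools").product("ACGT", repeat=3)
    if "".join(c) not in STOPS
)


def mutated_pair(rng, n_codons: int) -> tuple[str, str]:
    """A random sense-codon sequence and a point-mutated sense copy."""
    a_codons = [SENSE[i] for i in rng.integers(0, len(SENSE), n_codons)]
    b_codons = []
    for codon in a_codons:
        n_mut = rng.choice([0, 1, 2, 3], p=[0.45, 0.35, 0.15, 0.05])
        mut = codon
        for _ in range(50):
            cand = list(codon)
            for pos in rng.choice(3, size=n_mut, replace=False):
                cand[pos] = "ACGT"[rng.integers(0, 4)]
            cand = "".join(cand)
            if cand not in STOPS:
                mut = cand
                break
        b_codons.append(mut)
    return "".join(a_codons), "".join(b_codons)


def oracle_weighted_index(strata: dict, fc: dict, genes, timepoints) -> list[float]:
    """Plain-loop induction-weighted mean over a gene set."""
    out = []
    for t in timepoints:
        num = den = 0.0
        for g in genes:
            w = abs(fc.get((g, t), 0.0))
            num += strata[g] * w
            den += w
        out.append(num / den)
    return out
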