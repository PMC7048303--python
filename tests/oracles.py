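"""Independent brute-force oracles used by the test suite.

These deliberately re-derive everything from first principles — Biopython
translation, itertools enumeration, exact rational arithmetic — sharing no
counting code with the package, so that agreement is informative.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

from Bio.Seq import Seq

BASES = "ACGT"


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())  # '*' for stops


def brute_site_counts(codon: str) -> tuple[float, float]:
    """NG86 site counts by direct neighbour enumeration via Bio.Seq."""
    aa = _aa(codon)
    assert aa != "*"
    s = 0.0
    for pos in range(3):
        neighbours = [
            codon[:pos] + b + codon[pos + 1 :] for b in BASES if b != codon[pos]
        ]
        non_stop = [n for n in neighbours if _aa(n) != "*"]
        if non_stop:
            s += sum(_aa(n) == aa for n in non_stop) / len(non_stop)
    return s, 3.0 - s


def brute_pair_differences(a: str, b: str) -> tuple[float, float]:
    """Pathway-averaged difference counts by permutation enumeration."""
    positions = [i for i in range(3) if a[i] != b[i]]
    if not positions:
        return 0.0, 0.0
    clean, blocked = [], []
    for order in itertools.permutations(positions):
        cur, sd, nd, crosses = a, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if _aa(nxt) == "*":
                crosses = True
            if _aa(cur) != "*" and _aa(nxt) != "*" and _aa(cur) == _aa(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        (blocked if crosses else clean).append((sd, nd))
    pool = clean or blocked
    return (
        sum(p[0] for p in pool) / len(pool),
        sum(p[1] for p in pool) / len(pool),
    )


def brute_pairwise_divergence(cds_a: str, cds_b: str):
    """Whole-pair NG86+JC estimate from the brute-force primitives.

    Assumes gap-free, equal-length, in-register CDS; columns with a stop
    codon in either sequence are skipped (as the alignment builder does).
    """
    assert len(cds_a) == len(cds_b) and len(cds_a) % 3 == 0
    S = N = sd = nd = 0.0
    used = 0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i : i + 3], cds_b[i : i + 3]
        if _aa(ca) == "*" or _aa(cb) == "*":
            continue
        used += 1
        sa, na = brute_site_counts(ca)
        sb, nb = brute_site_counts(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        d_s, d_n = brute_pair_differences(ca, cb)
        sd += d_s
        nd += d_n
    ps, pn = sd / S, nd / N

    def jc(p):
        return -0.75 * math.log(1 - 4 * p / 3) if p < 0.75 else math.nan

    return {"S": S, "N": N, "sd": sd, "nd": nd, "ps": ps, "pn": pn,
            "ds": jc(ps), "dn": jc(pn), "used": used}


def exact_fisher_two_sided(table) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration.

    Exact rational probabilities; the two-sided p sums every table (same
    margins) whose probability does not exceed the observed one.
    """
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = math.comb(n, c1)
    support = range(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = {k: Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), denom) for k in support}
    observed = pmf[a]
    return float(sum(p for p in pmf.values() if p <= observed))


def exact_binom_two_sided(k: int, n: int, p0: float) -> float:
    """Two-sided exact binomial p by small-p summation (enumeration)."""
    pmf = [math.comb(n, i) * p0**i * (1 - p0) ** (n - i) for i in range(n + 1)]
    # tolerate float noise when comparing tied outcome probabilities
    cut = pmf[k] * (1 + 1e-12)
    return min(1.0, sum(p for p in pmf if p <= cut))
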