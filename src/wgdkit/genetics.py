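"""Standard-genetic-code codon bookkeeping shared by the divergence estimators.

All lookup tables are derived once, at import time, from Biopython's standard
codon table (NCBI table 1) and exposed either as plain dicts keyed by codon
string or as numpy arrays keyed by the 0..60 sense-codon index.  Everything
here is deterministic combinatorics on the code itself; no sequence data is
touched.

Site and difference counting follow the Nei–Gojobori (NG86) conventions:

* a codon position contributes a *synonymous site fraction* equal to the
  fraction of its single-nucleotide neighbours that preserve the amino acid,
  with neighbours that create a stop codon excluded from the denominator;
* differences between two codons are classified per mutational step, and when
  the codons differ at 2–3 positions the classification is averaged over all
  orderings of the steps, excluding orderings that pass through a stop codon
  (unless every ordering does, in which case all are used).
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]

BASES = "ACGT"
PURINES = frozenset("AG")
STOP_CODONS = frozenset(_TABLE.stop_codons)
ALL_CODONS = tuple("".join(c) for c in itertools.product(BASES, repeat=3))
SENSE_CODONS = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
N_SENSE = len(SENSE_CODONS)

#: codon -> one-letter amino acid (stop codons absent)
AMINO_ACID = dict(_TABLE.forward_table)


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def is_valid_codon(codon: str) -> bool:
    """True for a 3-mer over ACGT (stop codons included)."""
    return len(codon) == 3 and all(b in BASES for b in codon)


def is_transition(b1: str, b2: str) -> bool:
    """Purine<->purine or pyrimidine<->pyrimidine change."""
    return b1 != b2 and (b1 in PURINES) == (b2 in PURINES)


def is_transversion(b1: str, b2: str) -> bool:
    return b1 != b2 and (b1 in PURINES) != (b2 in PURINES)


@lru_cache(maxsize=None)
def codon_site_counts(codon: str) -> tuple[float, float]:
    """NG86 synonymous/nonsynonymous site counts (s, n) of one codon.

    Each position contributes the fraction of its non-stop single-base
    neighbours that are synonymous; n is defined as 3 - s so that
    s + n == 3 exactly for every sense codon.
    """
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no site counts")
    if not is_valid_codon(codon):
        raise ValueError(f"invalid codon {codon!r}")
    aa = AMINO_ACID[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        denom = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            neighbour = codon[:pos] + b + codon[pos + 1 :]
            if neighbour in STOP_CODONS:
                continue
            denom += 1
            if AMINO_ACID[neighbour] == aa:
                syn += 1
        if denom:
            s += syn / denom
    return s, 3.0 - s


def _step_is_synonymous(c1: str, c2: str) -> bool:
    # steps through stops (only reachable in the all-paths-blocked fallback)
    # count as nonsynonymous
    if c1 in STOP_CODONS or c2 in STOP_CODONS:
        return False
    return AMINO_ACID[c1] == AMINO_ACID[c2]


@lru_cache(maxsize=None)
def codon_pair_differences(a: str, b: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) difference counts.

    0 differing positions -> (0, 0); 1 -> classified directly; 2-3 -> the
    per-step classification is averaged over all orderings of the steps.
    Orderings whose intermediate codon is a stop are excluded; if every
    ordering is blocked, all orderings are averaged anyway.
    """
    for c in (a, b):
        if c in STOP_CODONS:
            raise ValueError(f"stop codon {c} in pair ({a}, {b})")
        if not is_valid_codon(c):
            raise ValueError(f"invalid codon {c!r}")
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    clean: list[tuple[int, int]] = []
    blocked: list[tuple[int, int]] = []
    for order in itertools.permutations(diff):
        cur = a
        sd = nd = 0
        crosses_stop = False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                crosses_stop = True
            if _step_is_synonymous(cur, nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        (blocked if crosses_stop else clean).append((sd, nd))
    pool = clean or blocked
    sd = sum(p[0] for p in pool) / len(pool)
    nd = sum(p[1] for p in pool) / len(pool)
    return sd, nd


#: 2-base prefixes whose four completions all encode the same amino acid
FOURFOLD_PREFIXES = frozenset(
    p
    for p in ("".join(x) for x in itertools.product(BASES, repeat=2))
    if all(p + b not in STOP_CODONS for b in BASES)
    and len({AMINO_ACID[p + b] for b in BASES}) == 1
)


def _build_arrays():
    s = np.empty(N_SENSE)
    for c, i in CODON_INDEX.items():
        s[i] = codon_site_counts(c)[0]
    sd = np.empty((N_SENSE, N_SENSE))
    nd = np.empty((N_SENSE, N_SENSE))
    for ca, ia in CODON_INDEX.items():
        for cb, ib in CODON_INDEX.items():
            sd[ia, ib], nd[ia, ib] = codon_pair_differences(ca, cb)
    return s, sd, nd


#: per-sense-codon synonymous sites, indexed by CODON_INDEX
S_SITES, SD_MATRIX, ND_MATRIX = _build_arrays()
N_SITES = 3.0 - S_SITES


def codons_of(cds: str) -> list[str]:
    """Split an in-frame CDS into codons (length must be a multiple of 3)."""
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]


def translate_cds(cds: str) -> str:
    """Translate an in-frame CDS; N-containing codons become X, stops '*'."""
    out = []
    for codon in codons_of(cds):
        if codon in STOP_CODONS:
            out.append("*")
        elif is_valid_codon(codon):
            out.append(AMINO_ACID[codon])
        else:
            out.append("X")
    return "".join(out)
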