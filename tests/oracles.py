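"""Independent oracles used by the test suite.

Deliberately written as plain recursions / enumerations, structured
differently from the package's dynamic programs so that agreement is
evidence, not tautology.
"""

from __future__ import annotations

import math
from functools import lru_cache
from itertools import permutations

from Bio.Align import substitution_matrices
from Bio.Seq import Seq

_B62 = substitution_matrices.load("BLOSUM62")

STOPS = {"TAA", "TAG", "TGA"}


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


# ---------------------------------------------------------------------------
# alignment score oracles (affine gaps: gap of length L costs open + ext*L)


def local_score_oracle(a: str, b: str, gap_open: float = 11.0, gap_ext: float = 1.0) -> float:
    """Best local alignment score by recursive path enumeration."""

    @lru_cache(maxsize=None)
    def extend(i: int, j: int, state: str) -> float:
        best = 0.0  # stop here
        if i < len(a) and j < len(b):
            best = max(best, _B62[a[i], b[j]] + extend(i + 1, j + 1, "M"))
        if i < len(a):
            cost = gap_ext if state == "U" else gap_open + gap_ext
            best = max(best, -cost + extend(i + 1, j, "U"))
        if j < len(b):
            cost = gap_ext if state == "L" else gap_open + gap_ext
            best = max(best, -cost + extend(i, j + 1, "L"))
        return best

    best = 0.0
    for i in range(len(a)):
        for j in range(len(b)):
            best = max(best, _B62[a[i], b[j]] + extend(i + 1, j + 1, "M"))
    return best


def global_score_oracle(a: str, b: str, gap_open: float = 11.0, gap_ext: float = 1.0) -> float:
    """Best global alignment score (end gaps penalized) by recursion."""

    @lru_cache(maxsize=None)
    def go(i: int, j: int, state: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = -math.inf
        if i < len(a) and j < len(b):
            best = max(best, _B62[a[i], b[j]] + go(i + 1, j + 1, "M"))
        if i < len(a):
            cost = gap_ext if state == "U" else gap_open + gap_ext
            best = max(best, -cost + go(i + 1, j, "U"))
        if j < len(b):
            cost = gap_ext if state == "L" else gap_open + gap_ext
            best = max(best, -cost + go(i, j + 1, "L"))
        return best

    return go(0, 0, "M")


# ---------------------------------------------------------------------------
# NG86 oracle


def ng86_sites_oracle(codon: str) -> float:
    """Fractional synonymous site count; changes to stops are nonsynonymous."""
    syn = 0.0
    for k in range(3):
        for b in "ACGT":
            if b == codon[k]:
                continue
            alt = codon[:k] + b + codon[k + 1 :]
            if alt not in STOPS and _translate(alt) == _translate(codon):
                syn += 1 / 3
    return syn


def ng86_changes_oracle(ca: str, cb: str) -> tuple[float, float]:
    """Pathway-averaged (syn, nonsyn) change counts by explicit enumeration
    of every ordering of the differing positions."""
    diff = [k for k in range(3) if ca[k] != cb[k]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff):
        cur = ca
        steps = []
        for k in order:
            nxt = cur[:k] + cb[k] + cur[k + 1 :]
            steps.append((cur, nxt))
            cur = nxt
        paths.append(steps)
    valid = [p for p in paths if all(y not in STOPS for _, y in p)]
    use, stops_ok = (valid, False) if valid else (paths, True)
    sd = nd = 0.0
    for steps in use:
        for x, y in steps:
            if (x in STOPS or y in STOPS) and stops_ok:
                nd += 1
            elif _translate(x) == _translate(y):
                sd += 1
            else:
                nd += 1
    return sd / len(use), nd / len(use)


def ng86_pair_oracle(codons_a, codons_b):
    """Full NG86 pair counts (Sd, Nd, S_sites, N_sites), no correction."""
    s_sites = n_sites = sd = nd = 0.0
    for a, b in zip(codons_a, codons_b):
        if "-" in a or "-" in b:
            continue
        sa, sb = ng86_sites_oracle(a), ng86_sites_oracle(b)
        s_sites += (sa + sb) / 2
        n_sites += (3 - sa + 3 - sb) / 2
        ds, dn = ng86_changes_oracle(a, b)
        sd += ds
        nd += dn
    return sd, nd, s_sites, n_sites


# ---------------------------------------------------------------------------
# exact binomial tails (integer counts)


def binom_tail_geq(k: int, n: int, p: float) -> float:
    return sum(math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1))


def binom_tail_leq(k: int, n: int, p: float) -> float:
    return sum(math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(0, k + 1))
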