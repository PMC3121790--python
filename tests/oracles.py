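"""Independent brute-force oracles used to validate the dynamic programs.

Everything here enumerates explicitly: secondary structures are generated as
explicit pair sets and scored directly from the pair set; hybridization
duplexes are enumerated by triple loop; quantiles, OLS and PSSM tail
probabilities are computed from first principles.
"""

from __future__ import annotations

import math
from functools import lru_cache

from sdscan._thermo import ALL_PAIRS, RT37, stack_table, to_rna

_MIN_LOOP = 3  # unpaired nt in a hairpin loop


def _pairable(x: str, y: str) -> bool:
    return (x, y) in ALL_PAIRS


def enumerate_structures(seq: str) -> list[frozenset]:
    """All pair sets valid under the baseline model's rules.

    Rules: canonical (WC + GU) nested pairs; every helix is a maximal run of
    >= 2 stacked pairs; a pair directly enclosing only unpaired bases holds
    >= 3 of them.  Each structure is produced exactly once.
    """
    s = to_rna(seq)
    n = len(s)

    @lru_cache(maxsize=None)
    def region(i: int, j: int) -> tuple:
        if i > j:
            return (frozenset(),)
        out = list(region(i + 1, j))  # i unpaired
        for k in range(i + 6, j + 1):
            helix = []
            l = 0
            while True:
                a, b = i + l, k - l
                if b - a < 2 or not _pairable(s[a], s[b]):
                    break
                helix.append((a, b))
                l += 1
                if l < 2:
                    continue
                inner_lo, inner_hi = i + l, k - l
                interior = inner_hi - inner_lo + 1
                if interior < 0:
                    break
                for content in region(inner_lo, inner_hi):
                    if (inner_lo, inner_hi) in content:
                        continue  # would extend this helix; counted at larger l
                    if not content and interior < _MIN_LOOP:
                        continue  # hairpin loop too small
                    for rest in region(k + 1, j):
                        out.append(frozenset(helix) | content | rest)
        return tuple(out)

    return list(region(0, n - 1))


def structure_energy(seq: str, pairs) -> float:
    """Energy of a pair set: sum of stacks over adjacent pairs present."""
    s = to_rna(seq)
    table = stack_table()
    e = 0.0
    for (a, b) in pairs:
        if (a + 1, b - 1) in pairs:
            e += table[(s[a] + s[a + 1], s[b] + s[b - 1])]
    return e


def brute_mfe(seq: str) -> float:
    structs = enumerate_structures(seq)
    return min(structure_energy(seq, p) for p in structs)


def brute_unpaired_probability(seq: str, span: tuple[int, int]) -> float:
    """Exact Boltzmann probability that all span positions are unpaired."""
    lo, hi = span  # half-open
    z = zu = 0.0
    for p in enumerate_structures(seq):
        w = math.exp(-structure_energy(seq, p) / RT37)
        z += w
        if not any(lo <= x < hi for pair in p for x in pair):
            zu += w
    return zu / z


def brute_scan(window: str, asd: str, init_dg: float = 4.09) -> float:
    """Minimum duplex energy by explicit (offset, start, end) enumeration."""
    w, a = to_rna(window), to_rna(asd)
    table = stack_table()
    ra = a[::-1]
    best = math.inf
    L = len(a)
    for o in range(-(L - 1), len(w)):
        lo, hi = max(0, -o), min(L, len(w) - o)
        for s in range(lo, hi - 1):
            for e in range(s + 1, hi):
                if not all(_pairable(w[o + m], ra[m]) for m in range(s, e + 1)):
                    continue
                dg = init_dg + sum(
                    table[(w[o + m] + w[o + m + 1], ra[m] + ra[m + 1])]
                    for m in range(s, e)
                )
                best = min(best, dg)
    return best


def brute_quantile(values, q: float) -> float:
    """Type-7 (linear interpolation) quantile computed from first principles."""
    v = sorted(values)
    if len(v) == 1:
        return float(v[0])
    h = (len(v) - 1) * q
    lo = math.floor(h)
    return v[lo] + (h - lo) * (v[min(lo + 1, len(v) - 1)] - v[lo])


def brute_ols(x, y):
    """Closed-form simple linear regression: slope, intercept, r^2."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxx = sum((xi - mx) ** 2 for xi in x)
    sxy = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    syy = sum((yi - my) ** 2 for yi in y)
    slope = sxy / sxx
    intercept = my - slope * mx
    r2 = 0.0 if syy == 0 else (sxy * sxy) / (sxx * syy)
    return slope, intercept, r2


def brute_pssm_tail(pssm, score: float) -> float:
    """P(window score >= score) by enumerating all 4^width windows, at the
    same integer discretization as the scanner's DP."""
    import itertools

    from sdscan.motifs import _BIDX, _int_scores

    S = _int_scores(pssm)
    target = int(round(score * 1000))
    total = 0.0
    for window in itertools.product("ACGT", repeat=pssm.width):
        sc = sum(S[_BIDX[b], k] for k, b in enumerate(window))
        if sc >= target:
            total += math.prod(pssm.background[_BIDX[b]] for b in window)
    return total
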