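"""Baseline RNA secondary-structure engine.

A stack-energy dynamic program: structures are sets of nested helices
(contiguous runs of >= 2 stacked canonical pairs), hairpin loops hold >= 3
unpaired nucleotides, and the only energy terms are nearest-neighbor stack
free energies — no loop, bulge or multiloop penalties.  The open chain scores
0, so the minimum free energy is always <= 0.  A McCaskill-style partition
function over the same structure space yields unpaired probabilities.

Matrix semantics (intervals inclusive, energies kcal/mol):

``W[i,j]``   best energy over all structures on [i, j] (>= empty = 0)
``WNO[i,j]`` as W but excluding structures that pair i with j
``VH[i,j]``  i.j paired as the OUTER pair of a helix (forces one stack)
``VC[i,j]``  i.j paired with an outer neighbor; helix extends or ends here

The decomposition is unambiguous — every structure has exactly one parse and
every stack present in a structure is scored — so the partition-function
variant counts each structure exactly once at its full Boltzmann weight.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from ._thermo import RT37, encode_rna, pair_matrix, stack_array

INF = 1e18

# minimal span of a helix: 2 pairs + 3-nt hairpin loop
_MIN_HELIX_SPAN = 7


@njit(cache=False)
def _fill_mfe(enc, can, S, allowed):
    n = enc.shape[0]
    W = np.zeros((n + 1, n + 1))
    WNO = np.zeros((n + 1, n + 1))
    VH = np.full((n, n), INF)
    VC = np.full((n, n), INF)
    for span in range(1, n):
        for i in range(0, n - span):
            j = i + span
            a, b = enc[i], enc[j]
            ok_ij = can[a, b] and allowed[i] and allowed[j]
            # VH: outer pair of a helix -> must stack on (i+1, j-1)
            if ok_ij and span >= 2:
                c, d = enc[i + 1], enc[j - 1]
                if can[c, d] and allowed[i + 1] and allowed[j - 1]:
                    s = S[a, b, c, d]
                    if VC[i + 1, j - 1] < INF:
                        VH[i, j] = s + VC[i + 1, j - 1]
            # VC: continue helix (== VH) or end it closing a loop
            if ok_ij:
                best = VH[i, j]
                if span - 1 >= 3:
                    # loop content on [i+1, j-1] without pair (i+1, j-1)
                    e = WNO[i + 1, j - 1]
                    if e < best:
                        best = e
                VC[i, j] = best
            # W / WNO: left-to-right juxtaposition of helices
            w = W[i + 1, j]  # i unpaired (W indexed with i+1<=n guard via size)
            wno = w
            for k in range(i + _MIN_HELIX_SPAN - 1, j + 1):
                if VH[i, k] < INF:
                    v = VH[i, k] + W[k + 1, j]
                    if v < w:
                        w = v
                    if k < j and v < wno:
                        wno = v
            W[i, j] = w
            WNO[i, j] = wno
    return W, WNO, VH, VC


@njit(cache=False)
def _fill_pf(enc, can, S, allowed, rt):
    n = enc.shape[0]
    ZW = np.ones((n + 1, n + 1))
    ZWNO = np.ones((n + 1, n + 1))
    ZH = np.zeros((n, n))
    ZC = np.zeros((n, n))
    for span in range(1, n):
        for i in range(0, n - span):
            j = i + span
            a, b = enc[i], enc[j]
            ok_ij = can[a, b] and allowed[i] and allowed[j]
            if ok_ij and span >= 2:
                c, d = enc[i + 1], enc[j - 1]
                if can[c, d] and allowed[i + 1] and allowed[j - 1]:
                    ZH[i, j] = np.exp(-S[a, b, c, d] / rt) * ZC[i + 1, j - 1]
            if ok_ij:
                z = ZH[i, j]
                if span - 1 >= 3:
                    z += ZWNO[i + 1, j - 1]
                ZC[i, j] = z
            zw = ZW[i + 1, j]
            zwno = zw
            for k in range(i + _MIN_HELIX_SPAN - 1, j + 1):
                if ZH[i, k] > 0.0:
                    v = ZH[i, k] * ZW[k + 1, j]
                    zw += v
                    if k < j:
                        zwno += v
            ZW[i, j] = zw
            ZWNO[i, j] = zwno
    return ZW[0, n - 1] if n > 0 else 1.0


def _prep(seq: str, forbidden=()):
    enc = encode_rna(seq)
    allowed = np.ones(enc.shape[0], dtype=np.bool_)
    for p in forbidden:
        allowed[p] = False
    return enc, pair_matrix(), stack_array(), allowed


def mfe_energy(seq: str) -> float:
    """Minimum free energy (kcal/mol) without structure recovery."""
    if len(seq) == 0:
        raise ValueError("empty sequence")
    if len(seq) < _MIN_HELIX_SPAN:
        return 0.0
    enc, can, S, allowed = _prep(seq)
    W, _, _, _ = _fill_mfe(enc, can, S, allowed)
    return float(W[0, len(seq) - 1])


def mfe_structure(seq: str) -> tuple[str, float]:
    """Minimum free energy and one optimal dot-bracket structure."""
    n = len(seq)
    if n == 0:
        raise ValueError("empty sequence")
    if n < _MIN_HELIX_SPAN:
        return "." * n, 0.0
    enc, can, S, allowed = _prep(seq)
    W, WNO, VH, VC = _fill_mfe(enc, can, S, allowed)
    pairs: list[tuple[int, int]] = []
    TOL = 1e-9

    def close(x, y):
        return abs(x - y) < TOL

    def trace_W(i, j, no_outer=False):
        while i <= j:
            target = WNO[i, j] if no_outer else W[i, j]
            if close(target, W[i + 1, j] if i + 1 <= j else 0.0):
                i += 1
                no_outer = False
                continue
            hi = j - 1 if no_outer else j
            for k in range(i + _MIN_HELIX_SPAN - 1, hi + 1):
                if VH[i, k] < INF and close(target, VH[i, k] + W[k + 1, j]):
                    trace_VH(i, k)
                    i = k + 1
                    no_outer = False
                    break
            else:  # pragma: no cover - defensive
                raise AssertionError("traceback failed")

    def trace_VH(i, j):
        # outer pair, then walk inward along VC
        pairs.append((i, j))
        a, b = i + 1, j - 1
        while True:
            pairs.append((a, b))
            if close(VC[a, b], VH[a, b]) and VH[a, b] < INF:
                a, b = a + 1, b - 1
                continue
            # helix ends: loop content without pair (a+1, b-1)
            if b - a - 1 >= 3:
                trace_W(a + 1, b - 1, no_outer=True)
            return

    trace_W(0, n - 1)
    db = ["."] * n
    for i, j in pairs:
        db[i], db[j] = "(", ")"
    return "".join(db), float(W[0, n - 1])


def partition_function(seq: str, forbidden=()) -> float:
    """Boltzmann partition function at 37 C over the engine's structure space.

    ``forbidden`` positions are held single-stranded.  The open chain
    contributes weight 1, so Z >= 1.
    """
    if len(seq) == 0:
        raise ValueError("empty sequence")
    if len(seq) < _MIN_HELIX_SPAN:
        return 1.0
    enc, can, S, allowed = _prep(seq, forbidden)
    return float(_fill_pf(enc, can, S, allowed, RT37))


def prob_unpaired(seq: str, span: tuple[int, int]) -> float:
    """Probability that all positions in half-open ``span`` are unpaired."""
    s, e = span
    if not (0 <= s < e <= len(seq)):
        raise ValueError("span outside sequence")
    z = partition_function(seq)
    zu = partition_function(seq, forbidden=range(s, e))
    return zu / z
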