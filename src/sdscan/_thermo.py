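"""Shared nearest-neighbor thermodynamics: alphabet handling and the stack
free-energy table used by both the RNA:RNA hybridization scanner and the
baseline secondary-structure engine.

Conventions
-----------
Sequences are stored internally in the DNA alphabet (A/C/G/T); conversion to
RNA (T->U) happens here, at the energetic boundary.  A stack is written
``top/bottom`` with the top strand 5'->3' and the bottom strand 3'->5',
left-to-right aligned, so ``top[k]`` pairs ``bottom[k]``.  The table is
strand-complement symmetric: ``dG(x1x2/y1y2) == dG(y2y1/x2x1)``.
"""

from __future__ import annotations

import functools
from importlib import resources

import numpy as np

RT37 = 0.0019872 * 310.15  # kcal/mol at 37 C

_RNA_BASES = "ACGU"
_ENCODE = {b: i for i, b in enumerate(_RNA_BASES)}

#: canonical pairs (Watson-Crick + wobble)
WC_PAIRS = frozenset({("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")})
GU_PAIRS = frozenset({("G", "U"), ("U", "G")})
ALL_PAIRS = WC_PAIRS | GU_PAIRS


def to_rna(seq: str) -> str:
    """Uppercase and convert T->U; reject non-nucleotide characters."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - set(_RNA_BASES)
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return s


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def encode_rna(seq: str) -> np.ndarray:
    """Integer-encode an RNA string (A=0, C=1, G=2, U=3) for the kernels."""
    return np.array([_ENCODE[b] for b in to_rna(seq)], dtype=np.int8)


def _read_stack_rows():
    text = (
        resources.files("sdscan.data").joinpath("rna_stacks.tsv").read_text()
    )
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("top\t"):
            continue
        top, bottom, dg = line.split("\t")
        rows.append((top, bottom, float(dg)))
    return rows


@functools.lru_cache(maxsize=None)
def stack_table() -> dict[tuple[str, str], float]:
    """Full 36-entry stack table keyed by ``(top, bottom)`` dinucleotides.

    Expanded from the packaged 21 unique rows by strand-complement symmetry.
    """
    table: dict[tuple[str, str], float] = {}
    for top, bottom, dg in _read_stack_rows():
        sym = (bottom[1] + bottom[0], top[1] + top[0])
        for key in ((top, bottom), sym):
            if key in table and abs(table[key] - dg) > 1e-9:
                raise ValueError(f"inconsistent stack entry {key}")
            table[key] = dg
    # sanity: every entry must consist of two canonical pairs
    for (top, bottom) in table:
        for k in range(2):
            if (top[k], bottom[k]) not in ALL_PAIRS:
                raise ValueError(f"non-canonical stack {top}/{bottom}")
    return table


@functools.lru_cache(maxsize=None)
def pair_matrix() -> np.ndarray:
    """4x4 boolean matrix of canonical (WC + wobble) pairs."""
    can = np.zeros((4, 4), dtype=np.bool_)
    for a, b in ALL_PAIRS:
        can[_ENCODE[a], _ENCODE[b]] = True
    return can


@functools.lru_cache(maxsize=None)
def stack_array() -> np.ndarray:
    """Stack energies as a 4x4x4x4 array for the folding kernels.

    ``S[a, b, c, d]`` is the free energy of stacking inner pair ``c.d`` on
    outer pair ``a.b``: outer top base ``a`` at i, outer bottom ``b`` at j,
    inner top ``c`` at i+1, inner bottom ``d`` at j-1 — i.e. the stack
    ``ac/bd`` in the table's notation.  Non-canonical combinations hold +inf.
    """
    S = np.full((4, 4, 4, 4), np.inf, dtype=np.float64)
    for (top, bottom), dg in stack_table().items():
        a, c = _ENCODE[top[0]], _ENCODE[top[1]]
        b, d = _ENCODE[bottom[0]], _ENCODE[bottom[1]]
        S[a, b, c, d] = dg
    return S


def stack_energy(top: str, bottom: str) -> float:
    """Energy of a single stack given aligned top (5'->3') and bottom (3'->5')."""
    return stack_table()[(to_rna(top), to_rna(bottom))]
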