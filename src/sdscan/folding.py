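"""Folding contract used by every downstream stage.

Three operations — MFE folding, sliding-window MFE, and start-codon
accessibility (probability that a short span is simultaneously unpaired) —
are served by a pluggable engine:

``baseline``
    The in-repo stack-energy dynamic program (:mod:`sdscan._baseline_engine`).
    Self-contained, exactly testable against exhaustive enumeration.
``vienna``
    Adapter to the ViennaRNA thermodynamic engine (RNAfold/RNAplfold
    equivalents through its Python bindings), for paper-style energies.

Engines differ in absolute energies; analyses in this package depend on
contrasts, which the two backends rank-agree on.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

from . import _baseline_engine as _bl
from ._thermo import to_rna

logger = logging.getLogger(__name__)

DEFAULT_BACKEND = "baseline"


@dataclass(frozen=True)
class FoldResult:
    structure: str  # dot-bracket, same length as the sequence
    energy: float  # kcal/mol, <= 0
    backend: str


@dataclass(frozen=True)
class AccessibilityResult:
    p_unpaired: float  # in [0, 1]
    span: tuple[int, int]  # half-open target interval (the start codon)
    window_size: int
    u: int
    backend: str


def _vienna():
    try:
        import RNA  # ViennaRNA python bindings
    except ImportError as exc:  # pragma: no cover - environment-dependent
        raise ImportError(
            "the 'vienna' backend requires the ViennaRNA python bindings"
        ) from exc
    return RNA


def vienna_available() -> bool:
    try:
        _vienna()
        return True
    except ImportError:  # pragma: no cover
        return False


def mfe_fold(seq: str, backend: str = DEFAULT_BACKEND) -> FoldResult:
    """Minimum-free-energy structure of ``seq`` (RNA alphabet after T->U)."""
    rna = to_rna(seq)  # validates characters
    if backend == "baseline":
        db, e = _bl.mfe_structure(rna)
        return FoldResult(db, e, backend)
    if backend == "vienna":
        RNA = _vienna()
        db, e = RNA.fold(rna)
        return FoldResult(db, float(e), backend)
    raise ValueError(f"unknown folding backend {backend!r}")


def mfe_energy(seq: str, backend: str = DEFAULT_BACKEND) -> float:
    """MFE in kcal/mol; skips structure recovery on the baseline engine."""
    rna = to_rna(seq)
    if backend == "baseline":
        return _bl.mfe_energy(rna)
    return mfe_fold(rna, backend).energy


def window_mfe(
    seq: str, window: int, step: int = 1, backend: str = DEFAULT_BACKEND
) -> list[tuple[int, float]]:
    """MFE of every fully-contained ``window``-nt substring, as (start, energy)."""
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    rna = to_rna(seq)
    if window > len(rna):
        warnings.warn(
            f"window {window} exceeds sequence length {len(rna)}; no windows"
        )
        return []
    return [
        (s, mfe_energy(rna[s : s + window], backend))
        for s in range(0, len(rna) - window + 1, step)
    ]


def unpaired_probability(
    seq: str,
    span: tuple[int, int],
    window_size: int = 50,
    u: int = 3,
    backend: str = DEFAULT_BACKEND,
) -> AccessibilityResult:
    """Equilibrium probability that every position of ``span`` is unpaired.

    ``span`` is a half-open interval of length ``u`` (the start codon by
    default: u=3, local window 50 nt).  The baseline engine folds the single
    ``window_size``-nt window centered on the span (clipped at the sequence
    ends); the vienna backend uses its local-folding (RNAplfold-style)
    sliding average.
    """
    s, e = span
    if not (0 <= s < e <= len(seq)):
        raise ValueError("span outside sequence")
    if e - s != u:
        raise ValueError(f"span length {e - s} != u = {u}")
    rna = to_rna(seq)
    if backend == "baseline":
        # single window centered on the span (documented simplification)
        mid = (s + e) // 2
        lo = max(0, min(mid - window_size // 2, len(rna) - window_size))
        hi = min(len(rna), lo + window_size)
        p = _bl.prob_unpaired(rna[lo:hi], (s - lo, e - lo))
        return AccessibilityResult(float(p), span, window_size, u, backend)
    if backend == "vienna":
        RNA = _vienna()
        # RNAplfold-style: mean over local windows of P(u-mer unpaired)
        up = RNA.pfl_fold_up(rna, u, min(window_size, len(rna)), min(window_size, len(rna)))
        # up[i][u] = P(segment of length u ending at position i (1-based) unpaired)
        p = up[e][u]
        return AccessibilityResult(float(p), span, window_size, u, backend)
    raise ValueError(f"unknown folding backend {backend!r}")
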