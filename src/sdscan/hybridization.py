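"""Anti-Shine-Dalgarno : 5'UTR hybridization energetics.

The 16S rRNA 3' tail is modeled as the hexamer anti-SD (ASD) ``CCUCCU``.  The
scanner slides the ASD along a 5'UTR window in antiparallel orientation and
scores every contiguous helix of >= 2 base pairs with the nearest-neighbor
stack model plus a duplex initiation penalty; the minimum free energy over all
alignments and helices is the gene's hybridization energy.  Genes are then
classified SD+/SD-/excluded under a strict scheme (presence below -4.4
kcal/mol, absence above 0) or a relaxed scheme (presence at <= 0).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._thermo import stack_table, to_rna, ALL_PAIRS

ASD_SEQ = "CCUCCU"

#: strict SD-presence threshold, kcal/mol
STRICT_PRESENT = -4.4
#: SD-absence threshold, kcal/mol (shared by both schemes)
ABSENT_ABOVE = 0.0

NO_DUPLEX = math.inf


@dataclass(frozen=True)
class EnergyModelParams:
    """Nearest-neighbor RNA:RNA duplex model parameters (37 C).

    ``stack_dg`` maps aligned ``(top, bottom)`` dinucleotides (top 5'->3',
    bottom 3'->5') to stack free energies.  The default table makes the
    tetramer sites GAGG, AGGA and GGAG exactly degenerate at -3.60 kcal/mol,
    which is what pins the model variant: terminal-AU penalties would split
    AGGA away from the other two, so they are off by default.
    """

    stack_dg: Mapping[tuple[str, str], float] = field(default_factory=stack_table)
    init_dg: float = 4.09
    use_terminal_au_penalty: bool = False
    terminal_au_dg: float = 0.45
    use_dangles: bool = False
    allow_gu: bool = True

    def __post_init__(self):
        if self.use_dangles:
            raise ValueError(
                "dangling-end terms are not part of this model; "
                "use_dangles must remain False"
            )

    def pairable(self, x: str, y: str) -> bool:
        if (x, y) not in ALL_PAIRS:
            return False
        if not self.allow_gu and {x, y} == {"G", "U"}:
            return False
        return True


_DEFAULT_MODEL: EnergyModelParams | None = None


def default_model() -> EnergyModelParams:
    global _DEFAULT_MODEL
    if _DEFAULT_MODEL is None:
        _DEFAULT_MODEL = EnergyModelParams()
    return _DEFAULT_MODEL


@dataclass(frozen=True)
class HybridizationResult:
    """Best scanning duplex of the ASD against one target window.

    ``dg`` is +inf when no helix of >= 2 pairs exists anywhere (classified as
    energy > 0).  ``offset`` is the window index aligned with the ASD 3' end;
    ``helix_span`` is the closed interval of paired window positions;
    ``paired_mask`` marks which ASD positions (5'->3') are paired.
    """

    dg: float
    offset: int | None = None
    helix_span: tuple[int, int] | None = None
    paired_mask: tuple[bool, ...] | None = None

    @property
    def duplex(self) -> bool:
        return math.isfinite(self.dg)


class SDClass(enum.Enum):
    SD_PLUS = "SD_PLUS"
    SD_MINUS = "SD_MINUS"
    EXCLUDED = "EXCLUDED"


@dataclass(frozen=True)
class SDCall:
    gene_id: str
    energy: float
    call: SDClass
    scheme: str


def scan_asd(
    window: str,
    asd: str = ASD_SEQ,
    model: EnergyModelParams | None = None,
) -> HybridizationResult:
    """Minimum scanning hybridization free energy of ``asd`` vs ``window``.

    Both sequences are converted to RNA.  For every antiparallel alignment,
    every contiguous run of >= 2 canonical pairs is scored as
    ``init_dg + sum(stacks)`` (+ optional terminal-AU/GU penalties); all
    sub-runs are considered because wobble stacks can be destabilizing.
    Deterministic; ties broken by smallest offset, then longest helix.
    """
    model = model or default_model()
    w = to_rna(window)
    a = to_rna(asd)
    if len(w) < 2:
        raise ValueError("window must be at least 2 nt")
    L = len(a)
    ra = a[::-1]  # ASD 3'->5', aligned left-to-right under the window

    best = HybridizationResult(NO_DUPLEX)
    best_key = None
    for offset in range(-(L - 1), len(w)):
        lo = max(0, -offset)
        hi = min(L, len(w) - offset)  # ASD-reversed indices m in [lo, hi)
        if hi - lo < 2:
            continue
        ok = [model.pairable(w[offset + m], ra[m]) for m in range(lo, hi)]
        # maximal runs of pairable positions, then all sub-runs of length >= 2
        m = 0
        while m < len(ok):
            if not ok[m]:
                m += 1
                continue
            run_start = m
            while m < len(ok) and ok[m]:
                m += 1
            run_end = m  # exclusive
            for s in range(run_start, run_end - 1):
                for e in range(s + 1, run_end):  # inclusive end, >= 2 pairs
                    dg = model.init_dg
                    for k in range(s, e):
                        mt = lo + k
                        top = w[offset + mt] + w[offset + mt + 1]
                        bot = ra[mt] + ra[mt + 1]
                        dg += model.stack_dg[(top, bot)]
                    if model.use_terminal_au_penalty:
                        # one penalty per terminal A.U or G.U pair
                        for mt in (lo + s, lo + e):
                            if "U" in (w[offset + mt], ra[mt]):
                                dg += model.terminal_au_dg
                    n_pairs = e - s + 1
                    key = (dg, offset, -n_pairs)
                    if best_key is None or key < best_key:
                        best_key = key
                        span_lo = offset + lo + s
                        span_hi = offset + lo + e
                        mask = [False] * L
                        for mm in range(lo + s, lo + e + 1):
                            mask[L - 1 - mm] = True
                        best = HybridizationResult(
                            dg, offset, (span_lo, span_hi), tuple(mask)
                        )
    return best


def classify_sd(energy: float, scheme: str = "strict") -> SDClass:
    """Map a hybridization energy to an SD presence call.

    strict: SD+ iff energy < -4.4; SD- iff energy > 0; boundary values and the
    intermediate band are EXCLUDED.  relaxed: SD+ iff energy <= 0.  The
    no-duplex sentinel (+inf) is SD- under both schemes.
    """
    if math.isnan(energy):
        raise ValueError("energy must be a finite value or the +inf sentinel")
    if scheme == "strict":
        if energy < STRICT_PRESENT:
            return SDClass.SD_PLUS
        if energy > ABSENT_ABOVE:
            return SDClass.SD_MINUS
        return SDClass.EXCLUDED
    if scheme == "relaxed":
        return SDClass.SD_PLUS if energy <= ABSENT_ABOVE else SDClass.SD_MINUS
    raise ValueError(f"unknown scheme {scheme!r}")


def call_genes(
    regions,
    scheme: str = "strict",
    asd: str = ASD_SEQ,
    model: EnergyModelParams | None = None,
) -> list[SDCall]:
    """Scan and classify a collection of GeneRegions.

    Genes without an intact -22..-2 window are EXCLUDED (energy = nan) and
    should be dropped from hybridization-based analyses.
    """
    from .regions import sd_search_window

    calls = []
    for g in regions:
        window = sd_search_window(g)
        if window is None:
            calls.append(SDCall(g.gene_id, math.nan, SDClass.EXCLUDED, scheme))
            continue
        res = scan_asd(window, asd=asd, model=model)
        calls.append(SDCall(g.gene_id, res.dg, classify_sd(res.dg, scheme), scheme))
    return calls


@dataclass(frozen=True)
class EnergyDistribution:
    bin_edges: np.ndarray  # len n_bins + 1
    density: np.ndarray  # sums to 1 together with no_duplex_fraction
    no_duplex_fraction: float
    peaks: tuple[float, ...]  # bin centers of local density maxima


def energy_distribution(
    energies: Sequence[float], bin_width: float = 0.2
) -> EnergyDistribution:
    """Normalized histogram of hybridization energies with detected peaks.

    No-duplex sentinels are tallied in a dedicated rightmost category rather
    than a numeric bin.  Peaks are bins whose density is >= both neighbors and
    strictly exceeds at least one (edges compared one-sided).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    arr = np.asarray(list(energies), dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one energy")
    finite = arr[np.isfinite(arr)]
    n_nodup = arr.size - finite.size
    if finite.size == 0:
        return EnergyDistribution(
            np.array([0.0, bin_width]), np.array([0.0]), 1.0, ()
        )
    lo = math.floor(finite.min() / bin_width) * bin_width
    hi = math.ceil(finite.max() / bin_width) * bin_width
    n_bins = max(1, int(round((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(finite, bins=edges)
    density = counts / arr.size
    centers = (edges[:-1] + edges[1:]) / 2.0
    peaks = []
    for i in range(n_bins):
        d = density[i]
        if d <= 0:
            continue
        left = density[i - 1] if i > 0 else None
        right = density[i + 1] if i < n_bins - 1 else None
        ge_all = all(d >= v for v in (left, right) if v is not None)
        gt_one = any(d > v for v in (left, right) if v is not None)
        if ge_all and (gt_one or (left is None and right is None)):
            peaks.append(float(centers[i]))
    return EnergyDistribution(edges, density, n_nodup / arr.size, tuple(peaks))


def sd_prevalence(calls: Iterable[SDCall]) -> float:
    """Fraction of SD_PLUS among relaxed-scheme calls."""
    calls = list(calls)
    if not calls:
        raise ValueError("no calls")
    return sum(c.call is SDClass.SD_PLUS for c in calls) / len(calls)
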