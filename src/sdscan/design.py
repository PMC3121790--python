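"""Stochastic design of reporter 5' regions with prescribed structure and SD
targets.

A bounded editable region around the start codon is mutated by a
simulated-annealing search whose score is the weighted absolute deviation
from two targets: the MFE of the start-codon region (-25..+21) and the
anti-SD hybridization energy of the -22..-2 window.  Coding positions are
only ever replaced by synonymous codons (sampled from codon usage), so the
encoded protein is invariant; non-coding positions take point mutations or a
dicodon-preserving shuffle.
"""

from __future__ import annotations

import functools
import itertools
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .folding import mfe_energy
from .hybridization import ASD_SEQ, EnergyModelParams, default_model, scan_asd
from .motifs import dicodon_shuffle

#: large finite stand-in for the no-duplex sentinel when a finite
#: hybridization target is requested (kcal/mol)
NO_DUPLEX_PENALTY_ENERGY = 10.0


@functools.lru_cache(maxsize=None)
def load_codon_usage() -> dict[str, float]:
    """Packaged E. coli codon usage (frequency per 1000)."""
    text = resources.files("sdscan.data").joinpath("ecoli_codon_usage.tsv").read_text()
    out = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("codon\t"):
            continue
        codon, f = line.split("\t")
        out[codon] = float(f)
    return out


@functools.lru_cache(maxsize=None)
def _synonyms() -> dict[str, tuple[str, ...]]:
    """codon -> synonymous codons (same amino acid, standard table)."""
    fwd = CodonTable.unambiguous_dna_by_id[1].forward_table
    by_aa: dict[str, list[str]] = {}
    for codon, aa in fwd.items():
        by_aa.setdefault(aa, []).append(codon)
    return {c: tuple(sorted(by_aa[aa])) for c, aa in fwd.items()}


@dataclass(frozen=True)
class DesignSpec:
    """Geometry, targets and move policy for one design problem.

    Biological coordinates have 0 at the first start-codon nucleotide.
    ``editable`` is a closed interval, e.g. (-25, 20): 25 non-coding
    positions plus the first 21 coding nucleotides (codons 1..6 after the
    fixed start codon).  ``target_hyb=None`` requests the SD-free state (no
    favorable duplex); a finite value requests that hybridization energy.
    """

    base_seq: str
    start_index: int
    editable: tuple[int, int]
    target_mfe: float
    target_hyb: float | None
    noncoding_move: str = "point_mutation"
    codon_usage: Mapping[str, float] = field(default_factory=load_codon_usage)
    w_mfe: float = 1.0
    w_hyb: float = 1.0
    mfe_region: tuple[int, int] = (-25, 21)
    hyb_region: tuple[int, int] = (-22, -2)
    asd: str = ASD_SEQ

    def __post_init__(self):
        lo, hi = self.editable
        if not (0 <= self.start_index + lo and self.start_index + hi < len(self.base_seq)):
            raise ValueError("editable region outside base sequence")
        if hi < 0 or lo > 0:
            pass  # purely non-coding or purely coding regions are allowed
        if hi >= 0 and (hi + 1) % 3:
            raise ValueError("coding part of editable region must cover whole codons")
        if self.base_seq[self.start_index : self.start_index + 3] != "ATG":
            raise ValueError("start codon at start_index must be ATG")
        if not (math.isfinite(self.target_mfe)):
            raise ValueError("target_mfe must be finite")
        if self.noncoding_move not in ("point_mutation", "dicodon_shuffle"):
            raise ValueError(f"unknown noncoding_move {self.noncoding_move!r}")

    def idx(self, bio: int) -> int:
        return self.start_index + bio

    def region_seq(self, seq: str, region: tuple[int, int]) -> str:
        lo, hi = region
        return seq[max(0, self.idx(lo)) : self.idx(hi) + 1]


@dataclass(frozen=True)
class DesignResult:
    sequence: str
    score: float
    trace: tuple[tuple[int, float], ...]  # (iteration, best score) at improvements
    seed: int | None = None


def hybridization_energy(seq: str, spec: DesignSpec,
                         model: EnergyModelParams | None = None) -> float:
    """Scanning ASD energy of the -22..-2 window (+inf if no duplex)."""
    return scan_asd(spec.region_seq(seq, spec.hyb_region), spec.asd, model).dg


def design_score(
    seq: str,
    spec: DesignSpec,
    model: EnergyModelParams | None = None,
    backend: str = "baseline",
) -> float:
    """w_mfe * |MFE - target_mfe| + w_hyb * hybridization deviation (lower is
    better; 0 at both targets)."""
    mfe = mfe_energy(spec.region_seq(seq, spec.mfe_region), backend)
    e = hybridization_energy(seq, spec, model)
    if spec.target_hyb is None:
        # SD-free target: any favorable duplex is penalized by its depth
        hyb_term = max(0.0, -e) if math.isfinite(e) else 0.0
    else:
        e_eff = e if math.isfinite(e) else NO_DUPLEX_PENALTY_ENERGY
        hyb_term = abs(e_eff - spec.target_hyb)
    return spec.w_mfe * abs(mfe - spec.target_mfe) + spec.w_hyb * hyb_term


def propose_move(
    seq: str, spec: DesignSpec, rng: np.random.Generator, max_retries: int = 20
) -> str:
    """One random edit of the editable region preserving protein and flanks.

    Non-coding position: per ``spec.noncoding_move`` either a substitution to
    one of the other three bases or one dicodon-preserving shuffle of the
    non-coding editable stretch (read as triplets from its 5' end, remainder
    fixed).  Coding position: the containing codon is replaced by a synonymous
    codon sampled proportionally to codon usage (the current codon is
    allowed; the start codon is never mutated).
    """
    lo, hi = spec.editable
    for _ in range(max_retries):
        bio = int(rng.integers(lo, hi + 1))
        if bio < 0:
            if spec.noncoding_move == "dicodon_shuffle":
                a, b = spec.idx(lo), spec.idx(min(hi, -1)) + 1
                sub = seq[a:b]
                rem = len(sub) % 3
                body, tail = (sub[: len(sub) - rem], sub[len(sub) - rem :])
                if len(body) < 6:
                    continue
                shuffled = dicodon_shuffle(body, rng)
                return seq[:a] + shuffled + tail + seq[b:]
            i = spec.idx(bio)
            alt = [b for b in "ACGT" if b != seq[i]]
            return seq[:i] + alt[rng.integers(3)] + seq[i + 1 :]
        codon_i = bio // 3
        if codon_i == 0:
            continue  # start codon never mutated; resample position
        a = spec.idx(3 * codon_i)
        codon = seq[a : a + 3]
        syn = _synonyms().get(codon)
        if syn is None or len(syn) == 1:
            continue  # stop codon in frame (shouldn't happen) or Met/Trp
        w = np.array([spec.codon_usage.get(c, 0.0) for c in syn])
        if w.sum() <= 0:
            w = np.ones(len(syn))
        new = syn[rng.choice(len(syn), p=w / w.sum())]
        return seq[:a] + new + seq[a + 3 :]
    return seq  # identity move after bounded retries


def anneal(
    spec: DesignSpec,
    seed: int | None = None,
    n_iter: int = 10_000,
    t0: float = 2.0,
    cooling: float = 0.999,
    model: EnergyModelParams | None = None,
    backend: str = "baseline",
    rng: np.random.Generator | None = None,
) -> DesignResult:
    """Metropolis search with geometric cooling; returns the best-so-far.

    Reproducible under a fixed seed; the trace records (iteration, best
    score) at every improvement, so its score column is non-increasing.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    model = model or default_model()
    cur = spec.base_seq
    cur_score = design_score(cur, spec, model, backend)
    best, best_score = cur, cur_score
    trace = [(0, best_score)]
    temp = t0
    for it in range(1, n_iter + 1):
        cand = propose_move(cur, spec, rng)
        if cand != cur:
            cand_score = design_score(cand, spec, model, backend)
            delta = cand_score - cur_score
            if delta <= 0 or rng.random() < math.exp(-delta / max(temp, 1e-9)):
                cur, cur_score = cand, cand_score
                if cur_score < best_score:
                    best, best_score = cur, cur_score
                    trace.append((it, best_score))
        temp *= cooling
        if best_score == 0.0:
            break
    return DesignResult(best, best_score, tuple(trace), seed)


def design_batch(
    spec: DesignSpec,
    n: int = 100,
    keep: int = 10,
    seed: int | None = None,
    n_iter: int = 10_000,
    **kwargs,
) -> list[DesignResult]:
    """``n`` independent anneal runs; the ``keep`` best, sorted by score."""
    if keep > n:
        raise ValueError("keep must be <= n")
    ss = np.random.SeedSequence(seed)
    results = []
    for child in ss.spawn(n):
        run_seed = int(child.generate_state(1)[0] % (2**31))
        results.append(anneal(spec, seed=run_seed, n_iter=n_iter, **kwargs))
    results.sort(key=lambda r: r.score)
    return results[:keep]


def translate_coding(seq: str, spec: DesignSpec) -> str:
    """Protein of the in-frame coding part from the start codon onward."""
    coding = seq[spec.start_index :]
    coding = coding[: len(coding) - len(coding) % 3]
    return str(Seq(coding).translate())


def design_diagnostics(
    result: DesignResult,
    spec: DesignSpec,
    backend: str = "baseline",
) -> dict[str, float]:
    """Report-style diagnostics replacing manual inspection of designs:
    region MFE, hybridization energy, start-codon accessibility, GC content
    and longest homopolymer run."""
    from .folding import unpaired_probability

    seq = result.sequence
    mfe = mfe_energy(spec.region_seq(seq, spec.mfe_region), backend)
    hyb = hybridization_energy(seq, spec)
    acc = unpaired_probability(
        seq, (spec.start_index, spec.start_index + 3), backend=backend
    ).p_unpaired
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    longest = max(len(list(g)) for _, g in itertools.groupby(seq))
    return {
        "score": result.score,
        "mfe_kcal_mol": mfe,
        "hyb_kcal_mol": hyb if math.isfinite(hyb) else float("nan"),
        "accessibility": acc,
        "gc_fraction": gc,
        "max_homopolymer": float(longest),
    }
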