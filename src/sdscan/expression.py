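"""Construct-evaluation covariates: RSCU/CAI, AU content, tRNA-abundance
expected expression, and the accessibility-activity correlation."""

from __future__ import annotations

import functools
import logging
import math
import warnings
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable
from scipy import stats as sps

from ._thermo import to_dna

logger = logging.getLogger(__name__)

#: floor for the relative-adaptiveness weight of a zero-RSCU codon
W_EPSILON = 1e-4


@functools.lru_cache(maxsize=None)
def _codon_families() -> dict[str, tuple[str, ...]]:
    """amino acid -> synonymous codons (standard table, stops excluded)."""
    fwd = CodonTable.unambiguous_dna_by_id[1].forward_table
    fams: dict[str, list[str]] = {}
    for codon, aa in fwd.items():
        fams.setdefault(aa, []).append(codon)
    return {aa: tuple(sorted(cs)) for aa, cs in fams.items()}


@functools.lru_cache(maxsize=None)
def default_codon_trna_map() -> dict[str, str]:
    text = resources.files("sdscan.data").joinpath("codon_trna_map.tsv").read_text()
    out = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("codon\t"):
            continue
        codon, trna = line.split("\t")
        out[codon] = trna
    return out


def _codons(cds: str) -> list[str]:
    cds = to_dna(cds)
    if len(cds) % 3:
        raise ValueError("coding sequence length must be divisible by 3")
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]


def rscu(cds_set: Sequence[str]) -> dict[str, float]:
    """Relative synonymous codon usage over a set of coding sequences.

    RSCU = observed codon frequency / frequency expected under equal usage of
    its synonyms, so the family mean is 1.  Codons of amino acids never
    observed are returned as nan (flagged with a warning); stop codons are
    excluded.
    """
    counts: Counter = Counter()
    for cds in cds_set:
        counts.update(_codons(cds))
    table: dict[str, float] = {}
    for aa, fam in _codon_families().items():
        total = sum(counts.get(c, 0) for c in fam)
        if total == 0:
            logger.warning("amino acid %s never observed; RSCU undefined", aa)
            for c in fam:
                table[c] = math.nan
            continue
        for c in fam:
            table[c] = counts.get(c, 0) * len(fam) / total
    return table


def relative_adaptiveness(table: Mapping[str, float]) -> dict[str, float]:
    """w = RSCU / max RSCU among synonyms, floored at W_EPSILON."""
    w = {}
    for aa, fam in _codon_families().items():
        vals = [table.get(c, math.nan) for c in fam]
        mx = np.nanmax(vals) if not all(math.isnan(v) for v in vals) else math.nan
        for c, v in zip(fam, vals):
            w[c] = math.nan if math.isnan(v) or not mx else v / mx
    return w


def cai(cds: str, table: Mapping[str, float]) -> float:
    """Codon Adaptation Index: geometric mean of relative adaptiveness.

    The start codon, stop codons and single-codon families (Met, Trp) are
    excluded; zero-weight codons are floored at W_EPSILON with a warning.
    """
    w = relative_adaptiveness(table)
    single = {fam[0] for fam in _codon_families().values() if len(fam) == 1}
    logs = []
    for k, codon in enumerate(_codons(cds)):
        if k == 0 or codon in single or codon not in w:
            continue  # start codon, Met/Trp, stops
        wk = w[codon]
        if math.isnan(wk):
            continue
        if wk <= 0:
            warnings.warn(f"zero-RSCU codon {codon}; weight floored at {W_EPSILON}")
            wk = W_EPSILON
        logs.append(math.log(wk))
    if not logs:
        raise ValueError("no scorable codons")
    return math.exp(sum(logs) / len(logs))


def au_content(
    seq: str, start_index: int | None = None, region: tuple[int, int] = (-30, -5)
) -> float:
    """A+U(T) fraction of a biological interval (default -30..-5).

    With ``start_index=None`` the whole sequence is scored.  A region
    extending past the sequence start is clipped with a warning.
    """
    s = to_dna(seq)
    if start_index is not None:
        lo, hi = region
        a, b = start_index + lo, start_index + hi + 1
        if a < 0:
            warnings.warn("AU-content region clipped at sequence start")
            a = 0
        if not 0 <= a < b <= len(s):
            raise ValueError("region outside sequence")
        s = s[a:b]
    if not s:
        raise ValueError("empty region")
    return (s.count("A") + s.count("T")) / len(s)


def trna_expected_expression(
    cds: str,
    abundance: Mapping[str, float],
    mapping: Mapping[str, str] | None = None,
) -> float:
    """Geometric mean of cognate tRNA abundances across codons.

    ``mapping`` (codon -> tRNA identifier) defaults to the packaged
    wobble-rule table; every codon must resolve to an abundance entry.
    """
    mapping = mapping if mapping is not None else default_codon_trna_map()
    missing, logs = [], []
    for codon in _codons(cds):
        trna = mapping.get(codon)
        if trna is None or trna not in abundance:
            missing.append(codon)
            continue
        logs.append(math.log(abundance[trna]))
    if missing:
        raise ValueError(f"codons without tRNA abundance: {sorted(set(missing))}")
    return math.exp(sum(logs) / len(logs))


@dataclass(frozen=True)
class CorrelationReport:
    slope: float
    intercept: float
    r_squared: float
    p_value: float  # two-sided test of zero slope
    stderr: float
    n: int


def correlate(x: Sequence[float], y: Sequence[float]) -> CorrelationReport:
    """Ordinary least squares of activity on a covariate."""
    x = np.asarray(list(x), float)
    y = np.asarray(list(y), float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in x")
    res = sps.linregress(x, y)
    r2 = float(res.rvalue**2)
    p = float(res.pvalue)
    if not math.isfinite(r2):  # constant response: zero slope, no fit
        r2, p = 0.0, 1.0
    return CorrelationReport(
        float(res.slope), float(res.intercept), r2, p, float(res.stderr), int(x.size)
    )
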