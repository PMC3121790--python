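"""Null models and statistics for 5'UTR motif searches.

Contents: exact dinucleotide- and dicodon-preserving shuffles (Euler-path
construction), PSSM building/scanning with exact tail p-values computed by
dynamic programming over the background score distribution, k-mer enrichment
with max-statistic label-permutation correction, and abstract RNA shape
statistics against dinucleotide-preserving structural nulls.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._thermo import to_dna
from .folding import mfe_fold

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# exact-count-preserving shuffles


def _euler_shuffle(tokens: Sequence[str], rng: np.random.Generator) -> list[str]:
    """Random Euler path over the token-adjacency multigraph.

    Altschul-Erickson construction: preserves the exact multiset of adjacent
    token pairs and the first and last tokens.
    """
    n = len(tokens)
    if n <= 2:
        return list(tokens)
    adj: dict[str, list[str]] = defaultdict(list)
    for a, b in zip(tokens, tokens[1:]):
        adj[a].append(b)
    last = tokens[-1]
    vertices = [v for v in adj if v != last]

    # choose a random last-exit edge per vertex until they form an arborescence
    # converging on the final token
    for _ in range(10_000):
        last_edge = {v: adj[v][rng.integers(len(adj[v]))] for v in vertices}
        ok = True
        for v in vertices:
            seen = {v}
            cur = v
            while cur != last:
                cur = last_edge.get(cur)
                if cur is None or cur in seen:  # dead end or cycle
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - probabilistically unreachable
        raise RuntimeError("failed to sample an Eulerian arrangement")

    order: dict[str, list[str]] = {}
    for v, targets in adj.items():
        rest = list(targets)
        if v in last_edge:
            rest.remove(last_edge[v])
        perm = [rest[i] for i in rng.permutation(len(rest))] if rest else []
        order[v] = perm + ([last_edge[v]] if v in last_edge else [])

    walk = [tokens[0]]
    ptr = {v: 0 for v in order}
    cur = tokens[0]
    for _ in range(n - 1):
        nxt = order[cur][ptr[cur]]
        ptr[cur] += 1
        walk.append(nxt)
        cur = nxt
    return walk


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle preserving the exact dinucleotide count table (and endpoints)."""
    if len(seq) < 2:
        raise ValueError("need at least 2 nucleotides")
    return "".join(_euler_shuffle(list(seq), rng))


def dicodon_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Codon-level Euler shuffle preserving adjacent codon-pair counts.

    The sequence is read as consecutive triplets; a trailing remainder not
    divisible by 3 is held fixed with a warning.
    """
    rem_len = len(seq) % 3
    body, rem = (seq[:-rem_len], seq[-rem_len:]) if rem_len else (seq, "")
    if rem:
        warnings.warn("sequence length not divisible by 3; trailing remainder held fixed")
    codons = [body[i : i + 3] for i in range(0, len(body), 3)]
    if len(codons) < 2:
        return seq
    return "".join(_euler_shuffle(codons, rng)) + rem


# ---------------------------------------------------------------------------
# PSSM construction and scanning with exact p-values

_BASES = "ACGT"
_BIDX = {b: i for i, b in enumerate(_BASES)}
#: integer scale for exact tail-probability DP over discretized scores
_SCORE_SCALE = 1000
#: floor for log-odds of zero-frequency cells (pseudocount 0)
_NEG_FLOOR = -10.0


@dataclass(frozen=True)
class PSSM:
    width: int
    log_odds: np.ndarray  # 4 x width, log2(freq / background)
    background: np.ndarray  # length 4, sums to 1
    pseudocount: float

    def score(self, window: str) -> float:
        w = to_dna(window)
        if len(w) != self.width:
            raise ValueError("window length != PSSM width")
        return float(sum(self.log_odds[_BIDX[b], k] for k, b in enumerate(w)))


@dataclass(frozen=True)
class PSSMMatch:
    position: int
    score: float
    p_value: float


@dataclass(frozen=True)
class MotifStat:
    motif: str
    observed: float
    expected: float
    p_value: float
    p_corrected: float | None = None


def build_pssm(
    sites: Sequence[str],
    pseudocount: float = 0.5,
    background: Sequence[float] | None = None,
) -> PSSM:
    """Log-odds PSSM from aligned equal-length sites with additive pseudocount."""
    if not sites:
        raise ValueError("need at least one site")
    sites = [to_dna(s) for s in sites]
    width = len(sites[0])
    if any(len(s) != width for s in sites):
        raise ValueError("sites must have equal lengths")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    bg = bg / bg.sum()
    counts = np.zeros((4, width))
    for s in sites:
        for k, b in enumerate(s):
            counts[_BIDX[b], k] += 1
    freq = (counts + pseudocount * bg[:, None]) / (len(sites) + pseudocount)
    with np.errstate(divide="ignore"):
        lo = np.log2(freq / bg[:, None])
    lo[np.isneginf(lo)] = _NEG_FLOOR
    return PSSM(width, lo, bg, pseudocount)


def _int_scores(pssm: PSSM) -> np.ndarray:
    return np.round(pssm.log_odds * _SCORE_SCALE).astype(np.int64)


def pssm_score_distribution(pssm: PSSM) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of the window score under i.i.d. background.

    Scores are discretized to 1/_SCORE_SCALE units; returns (int_scores,
    tail) where ``tail[k]`` = P(score >= int_scores[k]) and int_scores are
    ascending.  Complexity O(width * range * 4) by dense convolution.
    """
    S = _int_scores(pssm)
    dist = np.array([1.0])  # point mass at 0, relative to the running offset
    offset = 0
    for k in range(pssm.width):
        col = S[:, k]
        clo, chi = int(col.min()), int(col.max())
        new = np.zeros(dist.size + (chi - clo))
        for b in range(4):
            new[col[b] - clo : col[b] - clo + dist.size] += (
                pssm.background[b] * dist
            )
        dist = new
        offset += clo
    scores = offset + np.arange(dist.size)
    tail = np.cumsum(dist[::-1])[::-1]
    return scores, tail


def pssm_pvalue(pssm: PSSM, score: float) -> float:
    """Exact P(background window score >= ``score``) at DP discretization."""
    # distribution cached on the (frozen) PSSM instance itself
    dist = getattr(pssm, "_dist", None)
    if dist is None:
        dist = pssm_score_distribution(pssm)
        object.__setattr__(pssm, "_dist", dist)
    scores, tail = dist
    s = int(round(score * _SCORE_SCALE))
    k = np.searchsorted(scores, s, side="left")
    if k >= scores.size:
        return 0.0 if s > scores[-1] else float(tail[-1])
    return float(tail[k])


def pssm_scan(
    pssm: PSSM, seq: str, p_threshold: float = 0.01
) -> list[PSSMMatch]:
    """All windows matching the PSSM with p < ``p_threshold``."""
    s = to_dna(seq)
    if len(s) < pssm.width:
        return []
    out = []
    for pos in range(len(s) - pssm.width + 1):
        sc = pssm.score(s[pos : pos + pssm.width])
        p = pssm_pvalue(pssm, sc)
        if p < p_threshold:
            out.append(PSSMMatch(pos, sc, p))
    return out


def pssm_best_match(pssm: PSSM, seq: str) -> PSSMMatch:
    """Best-scoring window of ``seq`` (for presence/absence screening)."""
    s = to_dna(seq)
    if len(s) < pssm.width:
        raise ValueError("sequence shorter than PSSM width")
    best_pos, best_sc = 0, -np.inf
    for pos in range(len(s) - pssm.width + 1):
        sc = pssm.score(s[pos : pos + pssm.width])
        if sc > best_sc:
            best_pos, best_sc = pos, sc
    return PSSMMatch(best_pos, best_sc, pssm_pvalue(pssm, best_sc))


# ---------------------------------------------------------------------------
# k-mer enrichment with permutation correction


def generate_background(
    seqs: Sequence[str], n_copies: int = 5, rng: np.random.Generator | None = None
) -> list[str]:
    """Mononucleotide-preserving shuffles, ``n_copies`` per input sequence."""
    if not seqs:
        raise ValueError("need at least one sequence")
    rng = rng or np.random.default_rng()
    out = []
    for s in seqs:
        chars = np.array(list(s))
        for _ in range(n_copies):
            out.append("".join(chars[rng.permutation(len(chars))]))
    return out


def _kmer_sets(seqs, k):
    return [
        frozenset(s[i : i + k] for i in range(len(s) - k + 1)) for s in seqs
    ]


def kmer_enrichment(
    target: Sequence[str],
    background: Sequence[str],
    k: int,
    n_label_permutations: int = 20,
    rng: np.random.Generator | None = None,
) -> list[MotifStat]:
    """Per-k-mer enrichment of target vs background sequence sets.

    observed = fraction of target sequences containing the k-mer; expected
    from the background fraction; raw p is the binomial upper tail; the
    corrected p applies the max-statistic label-permutation method: the
    fraction of label permutations in which ANY k-mer reaches a raw p at
    least as small as the observed one (+1-corrected, never zero).
    """
    if not background:
        raise ValueError("background must be non-empty")
    rng = rng or np.random.default_rng()
    from scipy.stats import binom

    tsets = _kmer_sets([to_dna(s) for s in target], k)
    bsets = _kmer_sets([to_dna(s) for s in background], k)
    nt, nb = len(tsets), len(bsets)
    universe = sorted(set().union(*tsets)) if tsets else []

    def raw_pvals(tg, bg):
        t_count = Counter(itertools.chain.from_iterable(tg))
        b_count = Counter(itertools.chain.from_iterable(bg))
        out = {}
        for m in universe:
            obs = t_count.get(m, 0)
            # continuity-adjusted background rate avoids p_bg = 0
            p_bg = (b_count.get(m, 0) + 1) / (len(bg) + 2)
            out[m] = (obs, p_bg, float(binom.sf(obs - 1, len(tg), p_bg)))
        return out

    observed = raw_pvals(tsets, bsets)
    pool = tsets + bsets
    min_null = []
    for _ in range(n_label_permutations):
        perm = rng.permutation(len(pool))
        tg = [pool[i] for i in perm[:nt]]
        bg = [pool[i] for i in perm[nt:]]
        null = raw_pvals(tg, bg)
        min_null.append(min(p for _, _, p in null.values()))

    stats = []
    for m in universe:
        obs, p_bg, p_raw = observed[m]
        hits = sum(mp <= p_raw for mp in min_null)
        p_corr = (1 + hits) / (1 + n_label_permutations)
        # observed and expected as fractions of target sequences containing m
        stats.append(MotifStat(m, obs / nt, p_bg, p_raw, p_corr))
    stats.sort(key=lambda s: (s.p_corrected, s.p_value))
    return stats


# ---------------------------------------------------------------------------
# abstract RNA shapes


def _parse_pairs(structure: str) -> list[tuple[int, int]]:
    stack, pairs = [], []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket structure")
            pairs.append((stack.pop(), i))
        elif ch != ".":
            raise ValueError(f"invalid dot-bracket character {ch!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket structure")
    return sorted(pairs)


def abstract_shape(structure: str, level: str = "drop-hairpin") -> str:
    """Reduce a dot-bracket structure to its abstract shape over ``[ ] _``.

    Each maximal uninterrupted helix becomes one ``[ ]`` pair.  Unpaired runs:
    at the default ``drop-hairpin`` level hairpin-loop runs are omitted and
    every other maximal run (bulge, internal, multiloop, between top-level
    helices) becomes a single ``_``; leading/trailing external runs are
    trimmed.  ``keep-all`` keeps hairpin loops too; ``drop-all-unpaired``
    drops every unpaired run.
    """
    if level not in ("drop-hairpin", "keep-all", "drop-all-unpaired"):
        raise ValueError(f"unknown abstraction level {level!r}")
    pairs = _parse_pairs(structure)
    pair_set = set(pairs)
    partner = {}
    for i, j in pairs:
        partner[i] = j
        partner[j] = i

    def emit(lo: int, hi: int, external: bool) -> list[str]:
        """Shape tokens for region [lo, hi], external=True at top level."""
        tokens: list[str] = []
        i = lo
        saw_helix = False
        while i <= hi:
            if i in partner and partner[i] > i:
                # outer pair of a helix; follow stacked pairs inward
                a, b = i, partner[i]
                while (a + 1, b - 1) in pair_set:
                    a, b = a + 1, b - 1
                inner = emit(a + 1, b - 1, external=False)
                if not inner:  # hairpin loop
                    body = ["_"] if level == "keep-all" else []
                else:
                    body = inner
                tokens.append("[")
                tokens.extend(body)
                tokens.append("]")
                saw_helix = True
                i = partner[i] + 1
            else:
                # maximal unpaired run
                run_start = i
                while i <= hi and i not in partner:
                    i += 1
                keep = level != "drop-all-unpaired"
                if external and (run_start == lo or i > hi):
                    keep = False  # trim external flanks
                if keep:
                    tokens.append("_")
        # a pure-unpaired region yields nothing at hairpin level
        if not saw_helix and not external:
            return []
        return tokens

    return "".join(emit(0, len(structure) - 1, external=True))


def sub_shapes(shape: str) -> set[str]:
    """All balanced contiguous sub-shapes (flank-trimmed, non-empty)."""
    out = set()
    n = len(shape)
    for i in range(n):
        depth = 0
        for j in range(i, n):
            ch = shape[j]
            if ch == "[":
                depth += 1
            elif ch == "]":
                depth -= 1
                if depth < 0:
                    break
            if depth == 0:
                cand = shape[i : j + 1].strip("_")
                if cand:
                    out.add(cand)
    return out


def shape_motif_test(
    regions: Sequence[str],
    n_iter: int = 1000,
    rng: np.random.Generator | None = None,
    coding_len: int = 25,
    backend: str = "baseline",
    level: str = "drop-hairpin",
) -> list[MotifStat]:
    """Abstract-shape motif statistics for start-codon regions (-25..+25).

    Folds each 50-nt region, reduces the MFE structure to its shape and
    enumerates all balanced sub-shapes; the null repeats this ``n_iter``
    times with the non-coding (5') part dinucleotide-shuffled and the coding
    3' ``coding_len`` nt held fixed.  p_empirical uses the +1-corrected upper
    tail ``(1 + #{null count >= observed}) / (1 + n_iter)`` and is never 0.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = rng or np.random.default_rng()
    regs = []
    for r in regions:
        r = to_dna(r)
        if len(r) > 2 * coding_len:
            warnings.warn("region longer than expected; clipped to 2*coding_len")
            r = r[-2 * coding_len :]
        regs.append(r)

    def motif_count(seqs):
        counts = Counter()
        for s in seqs:
            shape = abstract_shape(mfe_fold(s, backend).structure, level)
            for m in sub_shapes(shape):
                counts[m] += 1
        return counts

    obs = motif_count(regs)
    null_ge = Counter()
    null_sum = Counter()
    for _ in range(n_iter):
        shuffled = [
            dinucleotide_shuffle(r[:-coding_len], rng) + r[-coding_len:]
            if len(r) > coding_len + 1
            else r
            for r in regs
        ]
        nc = motif_count(shuffled)
        for m in obs:
            null_sum[m] += nc.get(m, 0)
            if nc.get(m, 0) >= obs[m]:
                null_ge[m] += 1
    stats = [
        MotifStat(
            m,
            obs[m],
            null_sum[m] / n_iter,
            (1 + null_ge[m]) / (1 + n_iter),
        )
        for m in obs
    ]
    stats.sort(key=lambda s: s.p_value)
    return stats
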