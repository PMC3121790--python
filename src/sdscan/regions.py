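"""Gene-region extraction from annotated genomes.

Every downstream stage works on :class:`GeneRegion`: a gene's coding-strand
sequence split into 5'UTR, CDS and downstream parts, with one documented
coordinate convention — biological position 0 is the first nucleotide of the
start codon, -1 the last UTR nucleotide (no gap), so biological position of
internal index ``i`` is ``i - start_codon_pos``.

Extraction rules: UTRs/downstreams are trimmed at 125 nt, clipped at any
overlapping neighbor CDS, and genes whose extracted region contains an
ambiguity code are dropped.  Reverse-strand genes are reverse-complemented to
coding-strand orientation before any window arithmetic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

DEFAULT_TRIM = 125
DEFAULT_START_CODONS = ("ATG", "GTG", "TTG")

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class GeneRegion:
    """One gene's coding-strand sequence with UTR/CDS/downstream split."""

    gene_id: str
    genome_id: str
    utr_seq: str
    cds_seq: str
    downstream_seq: str = ""

    def __post_init__(self):
        for name in ("utr_seq", "cds_seq", "downstream_seq"):
            s = getattr(self, name)
            if set(s) - _ACGT:
                raise ValueError(f"{name} contains non-ACGT characters")
        if len(self.utr_seq) > DEFAULT_TRIM or len(self.downstream_seq) > DEFAULT_TRIM:
            raise ValueError("UTR/downstream exceed the 125-nt trimming bound")
        if len(self.cds_seq) < 3 or len(self.cds_seq) % 3:
            raise ValueError("cds_seq must be a non-empty multiple of 3")

    @property
    def seq(self) -> str:
        """Full coding-strand sequence utr + cds + downstream."""
        return self.utr_seq + self.cds_seq + self.downstream_seq

    @property
    def start_codon_pos(self) -> int:
        """Internal index of the first start-codon nucleotide."""
        return len(self.utr_seq)

    @property
    def start_codon(self) -> str:
        return self.cds_seq[:3]

    def index_of(self, bio_pos: int) -> int:
        """Internal 0-based index of biological position ``bio_pos``."""
        return self.start_codon_pos + bio_pos

    def bio_slice(self, lo: int, hi: int) -> str:
        """Subsequence at biological coordinates ``lo..hi`` inclusive.

        Raises ValueError if the interval is not fully covered.
        """
        i, j = self.index_of(lo), self.index_of(hi)
        if i < 0 or j >= len(self.seq) or i > j:
            raise ValueError(
                f"biological interval {lo}..{hi} outside extracted region "
                f"of {self.gene_id}"
            )
        return self.seq[i : j + 1]


def _clip_upstream(s: int, intervals, limit: int) -> int:
    """Forward-coordinate start of the UTR for a CDS starting at ``s``."""
    lo = max(0, s - limit)
    for os_, oe in intervals:
        if oe > lo and os_ < s:  # overlaps the candidate [lo, s)
            lo = max(lo, min(oe, s))
    return lo


def _clip_downstream(e: int, intervals, limit: int, genome_len: int) -> int:
    hi = min(genome_len, e + limit)
    for os_, oe in intervals:
        if os_ < hi and oe > e:
            hi = min(hi, max(os_, e))
    return hi


def extract_gene_regions(
    genome,
    upstream_max: int = DEFAULT_TRIM,
    downstream_max: int = DEFAULT_TRIM,
    start_codons: Sequence[str] = DEFAULT_START_CODONS,
) -> list[GeneRegion]:
    """Extract per-gene regions from an annotated genome record.

    ``genome`` is a Bio.SeqRecord with CDS features (as parsed from a GenBank
    flat file).  Each gene yields a GeneRegion whose UTR stops at the nearer
    of ``upstream_max`` nt or the boundary of the closest overlapping
    annotated CDS; the downstream region is handled symmetrically after the
    stop codon.  Genes are skipped (with a logged warning) when the CDS is a
    compound/joined location, is not a multiple of 3, does not begin with an
    accepted start codon, or the extracted region contains ambiguity codes.
    """
    seq = str(genome.seq).upper()
    feats = []
    for f in genome.features:
        if f.type != "CDS":
            continue
        if f.location is None:
            logger.warning("CDS without coordinates in %s; skipped", genome.id)
            continue
        feats.append(f)
    intervals = [(int(f.location.start), int(f.location.end)) for f in feats]

    out = []
    for f in feats:
        q = f.qualifiers
        gene_id = (
            q.get("locus_tag", q.get("gene", [None]))[0]
            or f"CDS_{int(f.location.start)}"
        )
        if len(f.location.parts) > 1:
            logger.warning("%s: compound CDS location; skipped", gene_id)
            continue
        s, e = int(f.location.start), int(f.location.end)
        others = [iv for iv in intervals if iv != (s, e)]
        region = _extract_one(
            seq, s, e, int(f.location.strand or 1), others,
            upstream_max, downstream_max,
        )
        reg = _finalize(region, gene_id, genome.id, start_codons)
        if reg is not None:
            out.append(reg)
    return out


def extract_from_table(
    table: pd.DataFrame,
    genome_seqs: Mapping[str, str],
    upstream_max: int = DEFAULT_TRIM,
    downstream_max: int = DEFAULT_TRIM,
    start_codons: Sequence[str] = DEFAULT_START_CODONS,
) -> list[GeneRegion]:
    """Extract regions from a gene table (genome_id, gene_id, start, end, strand).

    ``start``/``end`` are 1-based inclusive forward-strand coordinates (as in
    GenBank feature tables); ``strand`` is ``+``/``-``.
    """
    out = []
    for genome_id, grp in table.groupby("genome_id", sort=False):
        seq = genome_seqs[genome_id].upper()
        rows = []
        for _, r in grp.iterrows():
            if pd.isna(r["start"]) or pd.isna(r["end"]):
                logger.warning("%s: missing CDS coordinates; skipped", r["gene_id"])
                continue
            rows.append(r)
        intervals = [(int(r["start"]) - 1, int(r["end"])) for r in rows]
        for r, (s, e) in zip(rows, intervals):
            others = [iv for iv in intervals if iv != (s, e)]
            strand = 1 if str(r["strand"]) in ("+", "1") else -1
            region = _extract_one(
                seq, s, e, strand, others, upstream_max, downstream_max
            )
            reg = _finalize(region, str(r["gene_id"]), str(genome_id), start_codons)
            if reg is not None:
                out.append(reg)
    return out


def _extract_one(seq, s, e, strand, others, upstream_max, downstream_max):
    if strand >= 0:
        u0 = _clip_upstream(s, others, upstream_max)
        d1 = _clip_downstream(e, others, downstream_max, len(seq))
        return seq[u0:s], seq[s:e], seq[e:d1]
    # reverse strand: biological upstream is forward-downstream
    u1 = _clip_downstream(e, others, upstream_max, len(seq))
    d0 = _clip_upstream(s, others, downstream_max)
    rc = lambda x: str(Seq(x).reverse_complement())
    return rc(seq[e:u1]), rc(seq[s:e]), rc(seq[d0:s])


def _finalize(parts, gene_id, genome_id, start_codons):
    utr, cds, down = parts
    if len(cds) < 3 or len(cds) % 3:
        logger.warning("%s: CDS length %d not divisible by 3; skipped", gene_id, len(cds))
        return None
    if cds[:3] not in start_codons:
        logger.warning("%s: start codon %s not in accepted set; skipped", gene_id, cds[:3])
        return None
    if set(utr + cds + down) - _ACGT:
        logger.warning("%s: ambiguous nucleotides; excluded", gene_id)
        return None
    return GeneRegion(gene_id, genome_id, utr, cds, down)


def sd_search_window(gene: GeneRegion) -> str | None:
    """The 21-nt subsequence at biological coordinates -22..-2, or None.

    Genes whose UTR is shorter than 22 nt lack an intact -22..-2 region and
    are excluded from hybridization-based analyses.
    """
    if len(gene.utr_seq) < 22:
        return None
    return gene.bio_slice(-22, -2)


def prevalence_filter(
    gene_sets: Mapping[str, Iterable[str]], threshold: float = 0.5
) -> set[str]:
    """Gene names present in at least ``threshold`` of the genomes (inclusive)."""
    sets = {g: set(names) for g, names in gene_sets.items()}
    if not sets:
        return set()
    n = len(sets)
    counts: dict[str, int] = {}
    for names in sets.values():
        for name in names:
            counts[name] = counts.get(name, 0) + 1
    return {name for name, c in counts.items() if c / n >= threshold}


def sample_genes(
    regions: Sequence[GeneRegion], n: int, seed: int, replace: bool = False
) -> list[GeneRegion]:
    """Uniform random sample of genes, reproducible under a fixed seed."""
    if n > len(regions) and not replace:
        raise ValueError(f"cannot sample {n} of {len(regions)} without replacement")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(regions), size=n, replace=replace)
    return [regions[i] for i in idx]


# ---------------------------------------------------------------------------
# round-trippable FASTA + manifest output


def write_regions_fasta(regions: Iterable[GeneRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in regions:
            fh.write(
                f">{g.gene_id}|{g.genome_id}|{len(g.utr_seq)}|{len(g.cds_seq)}\n"
            )
            fh.write(g.seq + "\n")


def read_regions_fasta(path: str | Path) -> list[GeneRegion]:
    out = []
    header, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if header is not None:
                    out.append(_from_fasta(header, "".join(chunks)))
                header, chunks = line[1:], []
            elif line:
                chunks.append(line)
    if header is not None:
        out.append(_from_fasta(header, "".join(chunks)))
    return out


def _from_fasta(header: str, seq: str) -> GeneRegion:
    gene_id, genome_id, utr_len, cds_len = header.split("|")
    u, c = int(utr_len), int(cds_len)
    return GeneRegion(gene_id, genome_id, seq[:u], seq[u : u + c], seq[u + c :])


def regions_manifest(regions: Iterable[GeneRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "genome_id": g.genome_id,
                "utr_len": len(g.utr_seq),
                "cds_len": len(g.cds_seq),
                "downstream_len": len(g.downstream_seq),
                "start_codon": g.start_codon,
            }
            for g in regions
        ]
    )
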