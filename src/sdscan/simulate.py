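"""Synthetic gene sets and reporter construct panels with known ground truth.

The generator emulates the statistical structure the analyses assume, so
every pipeline stage is testable without genome downloads: controllable SD
prevalence with the conserved 4-9 nt spacing, planted unstructured or
stem-loop windows around the start codon, internal AUGs embedded in hairpins
inside the CDS, and a reporter panel whose simulated activity is linear in
start-codon accessibility for SD-less constructs and flat for SD-containing
ones.

Backgrounds are i.i.d. with a configurable AT content (dinucleotide realism
is unnecessary for planted-feature recovery and keeps the truth exact).
Unstructured windows use A/C-biased composition rather than forbidding pairs
outright, so the folding engine — not the generator — certifies
accessibility.  Genes without a planted SD have the -22..-2 window scrubbed
of G so that their SD- status is guaranteed rather than probabilistic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from Bio.Seq import Seq

from .design import DesignResult, DesignSpec, anneal, design_score
from .folding import mfe_energy, unpaired_probability
from .hybridization import classify_sd, scan_asd, SDClass
from .regions import GeneRegion

logger = logging.getLogger(__name__)

_STOPS = {"TAA", "TAG", "TGA"}
_SENSE = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
)
_AC_CODONS = tuple(a + b + c for a in "AC" for b in "AC" for c in "AC")

DEFAULT_SD_MOTIFS = (
    ("AGGAGG", 1.0),
    ("GGAGG", 1.0),
    ("GGAG", 1.0),
    ("GAGG", 1.0),
    ("AGGA", 1.0),
)


@dataclass(frozen=True)
class SyntheticParams:
    n_genomes: int = 1
    genes_per_genome: int = 100
    p_sd: float = 0.5
    sd_motifs: tuple[tuple[str, float], ...] = DEFAULT_SD_MOTIFS
    sd_spacing: tuple[int, int] = (4, 9)  # nt between SD 3' end and start
    at_content: float = 0.5
    start_window_mode: str = "none"  # none | unstructured | structured
    start_window_width: int = 50
    hairpin_stem: int = 10  # bp, planted stem-loops
    hairpin_loop: int = 4
    n_internal_augs: int = 0
    internal_aug_frame: str = "in_frame"  # or out_of_frame
    utr_len: int = 125
    cds_codons: int = 60  # including start and stop
    downstream_len: int = 125
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.p_sd <= 1:
            raise ValueError("p_sd must be in [0, 1]")
        lo, hi = self.sd_spacing
        if not (4 <= lo <= hi <= 9):
            raise ValueError("sd_spacing must lie within the conserved 4..9 nt range")
        if self.start_window_mode not in ("none", "unstructured", "structured"):
            raise ValueError(f"unknown start_window_mode {self.start_window_mode!r}")
        if self.start_window_width // 2 > self.utr_len:
            raise ValueError("start window wider than the UTR can accommodate")
        if self.start_window_mode == "structured":
            need = 2 * self.hairpin_stem + self.hairpin_loop + 3
            if need > 3 * (self.cds_codons - 1):
                raise ValueError("planted stem-loop does not fit in the CDS")


@dataclass(frozen=True)
class GeneTruth:
    gene_id: str
    sd_planted: bool
    sd_motif: str | None
    sd_spacing: int | None
    structure_mode: str
    internal_aug_bios: tuple[int, ...]
    planted_hairpin_mfe: float | None  # start-overlapping stem-loop, kcal/mol


@dataclass(frozen=True)
class SyntheticTruth:
    params: SyntheticParams
    genes: dict[str, GeneTruth] = field(default_factory=dict)


def _bg(rng, n, at):
    return "".join(
        rng.choice(list("ATCG"), size=n, p=[at / 2, at / 2, (1 - at) / 2, (1 - at) / 2])
    ) if n else ""


def _rc(s: str) -> str:
    return str(Seq(s).reverse_complement())


def _has_inframe_stop(cds: str) -> bool:
    return any(cds[i : i + 3] in _STOPS for i in range(3, len(cds) - 3, 3))


def _make_gene(rng: np.random.Generator, params: SyntheticParams, gene_id: str,
               genome_id: str) -> tuple[GeneRegion, GeneTruth]:
    p = params
    utr = list(_bg(rng, p.utr_len, p.at_content))
    down = _bg(rng, p.downstream_len, p.at_content)
    codons = ["ATG"] + [
        _SENSE[rng.integers(len(_SENSE))] for _ in range(p.cds_codons - 2)
    ] + ["TAA"]

    hairpin_mfe = None
    occupied_cds = 3  # cds prefix that later planting must not touch
    if p.start_window_mode == "unstructured":
        # A-tract with an optional short C-tract abutting the start codon:
        # the only {A,C} composition free of the CA dinucleotide, which is
        # the unique pairing partner of the start codon's obligatory UG
        # under the wobble-inclusive pair set.
        w = p.start_window_width
        w_up = w // 2
        b = int(rng.integers(0, 5))
        for k in range(p.utr_len - w_up, p.utr_len):
            utr[k] = "C" if k >= p.utr_len - b else "A"
        n_cod = -(-(w - w_up) // 3) + 1  # +1 codon of margin past the window
        for c in range(1, min(n_cod, p.cds_codons - 1)):
            codons[c] = "AAA"
        occupied_cds = 3 * n_cod
    elif p.start_window_mode == "structured":
        s, l = p.hairpin_stem, p.hairpin_loop
        for _ in range(500):
            cds = "".join(codons)
            arm1 = cds[:s]
            loop = "".join("AC"[rng.integers(2)] for _ in range(l))
            new = arm1 + loop + _rc(arm1) + cds[2 * s + l :]
            if not _has_inframe_stop(new[: 2 * s + l + 3]):
                codons = [new[i : i + 3] for i in range(0, len(new), 3)]
                hairpin_mfe = mfe_energy(arm1 + loop + _rc(arm1))
                break
            # resample the codons feeding the first arm and retry
            for c in range(1, -(-s // 3)):
                codons[c] = _SENSE[rng.integers(len(_SENSE))]
        else:  # pragma: no cover
            raise RuntimeError("could not plant a stop-free stem-loop")
        occupied_cds = 2 * s + l

    sd_planted = bool(rng.random() < p.p_sd)
    sd_motif = sd_spacing = None
    if sd_planted:
        motifs, weights = zip(*p.sd_motifs)
        wts = np.array(weights, float)
        sd_motif = motifs[rng.choice(len(motifs), p=wts / wts.sum())]
        sd_spacing = int(rng.integers(p.sd_spacing[0], p.sd_spacing[1] + 1))
        end = p.utr_len - sd_spacing - 1  # index of motif 3' end (bio -(spacing+1))
        for k, base in enumerate(sd_motif):
            utr[end - len(sd_motif) + 1 + k] = base
    else:
        for k in range(max(0, p.utr_len - 22), p.utr_len - 1):
            if utr[k] == "G":
                utr[k] = "ACT"[rng.integers(3)]

    aug_bios: list[int] = []
    if p.n_internal_augs:
        s, l = p.hairpin_stem, p.hairpin_loop
        first_codon = occupied_cds // 3 + 2
        span_codons = -(-(2 * s + l + 2) // 3) + 1
        last_codon = p.cds_codons - 1 - span_codons
        if last_codon < first_codon:
            raise ValueError("CDS too short to plant internal AUG hairpins")
        starts = np.linspace(first_codon, last_codon, p.n_internal_augs).astype(int)
        for c0 in starts:
            pos = 3 * c0 + (0 if p.internal_aug_frame == "in_frame" else 1)
            for _ in range(500):
                cds = "".join(codons)
                arm1 = "ATG" + "".join(
                    "ACGT"[rng.integers(4)] for _ in range(s - 3)
                )
                loop = "".join("AC"[rng.integers(2)] for _ in range(l))
                patch = arm1 + loop + _rc(arm1)
                new = cds[:pos] + patch + cds[pos + len(patch) :]
                lo = pos - pos % 3  # codon-aligned start of the affected range
                hi = min(pos + len(patch) + 3, 3 * (p.cds_codons - 1))
                if not any(
                    new[i : i + 3] in _STOPS for i in range(max(3, lo), hi - 2, 3)
                ):
                    codons = [new[i : i + 3] for i in range(0, len(new), 3)]
                    aug_bios.append(pos)
                    break
            else:  # pragma: no cover
                raise RuntimeError("could not plant a stop-free internal AUG hairpin")

    cds = "".join(codons)
    assert cds[:3] == "ATG" and not _has_inframe_stop(cds)
    region = GeneRegion(gene_id, genome_id, "".join(utr), cds, down)
    truth = GeneTruth(
        gene_id, sd_planted, sd_motif, sd_spacing, p.start_window_mode,
        tuple(aug_bios), hairpin_mfe,
    )
    return region, truth


def generate_gene_set(params: SyntheticParams) -> tuple[list[GeneRegion], SyntheticTruth]:
    """Generate ``n_genomes x genes_per_genome`` genes with known truth.

    Bit-identical under a fixed ``params.seed``.
    """
    ss = np.random.SeedSequence(params.seed)
    regions: list[GeneRegion] = []
    truth = SyntheticTruth(params)
    children = ss.spawn(params.n_genomes * params.genes_per_genome)
    k = 0
    for g in range(params.n_genomes):
        genome_id = f"synth{g:02d}"
        for i in range(params.genes_per_genome):
            rng = np.random.default_rng(children[k])
            k += 1
            gene_id = f"{genome_id}.g{i:04d}"
            region, gt = _make_gene(rng, params, gene_id, genome_id)
            regions.append(region)
            truth.genes[gene_id] = gt
    return regions, truth


@dataclass(frozen=True)
class ContrastSet:
    """SD-/unstructured vs SD+/structured gene sets for profile recovery."""

    regions: list[GeneRegion]
    truth_minus: SyntheticTruth
    truth_plus: SyntheticTruth
    planted_contrast: float  # kcal/mol, > 0


def generate_contrast_set(
    n_per_class: int = 200, seed: int = 0, **overrides
) -> ContrastSet:
    """Two-class set: SD- genes with planted unstructured start windows and
    SD+ genes (strict-callable AGGAGG) with stem-loops over the start codon.

    ``planted_contrast`` is the magnitude of the planted start-overlapping
    stem-loop MFE (mean over SD+ genes): the expected between-class
    difference in window MFE at position 0 up to background folding.
    """
    minus, tm = generate_gene_set(
        SyntheticParams(
            genes_per_genome=n_per_class, p_sd=0.0,
            start_window_mode="unstructured", seed=seed, **overrides,
        )
    )
    plus, tp = generate_gene_set(
        SyntheticParams(
            genes_per_genome=n_per_class, p_sd=1.0,
            sd_motifs=(("AGGAGG", 1.0),),
            start_window_mode="structured", seed=seed + 1, **overrides,
        )
    )
    plus = [replace(g, gene_id="plus." + g.gene_id, genome_id="plus") for g in plus]
    tp = SyntheticTruth(
        tp.params, {"plus." + k: v for k, v in tp.genes.items()}
    )
    hp = [t.planted_hairpin_mfe for t in tp.genes.values()]
    return ContrastSet(minus + plus, tm, tp, -float(np.mean(hp)))


# ---------------------------------------------------------------------------
# reporter construct panel

BASE_UTR = "CAGCTACTGCATCCTACGCTTCACTACTCACTA"  # 33 nt, no SD
# start + 8 codons (M T K K K K K K S); the A-rich editable codons leave the
# designer a reachable unstructured extreme as well as deep-stem solutions
BASE_CDS = "ATGACT" + "A" * 18 + "AGC"
BASE_CONSTRUCT = BASE_UTR + BASE_CDS
START_INDEX = len(BASE_UTR)


@dataclass(frozen=True)
class PanelTruth:
    sd_status: bool
    beta: float
    sigma: float
    mu: float
    target_mfes: tuple[float, ...]


@dataclass(frozen=True)
class ConstructPanel:
    sequences: list[str]
    results: list[DesignResult]
    accessibility: np.ndarray
    activities: np.ndarray
    truth: PanelTruth
    start_index: int = START_INDEX

    def draw_activities(self, seed: int) -> np.ndarray:
        """Fresh simulated activities for the same designed constructs."""
        rng = np.random.default_rng(seed)
        return simulate_activities(
            self.accessibility, self.truth.sd_status, self.truth.beta,
            self.truth.sigma, self.truth.mu, rng,
        )


def simulate_activities(accessibility, sd_status, beta, sigma, mu, rng):
    acc = np.asarray(accessibility, float)
    noise = rng.normal(0.0, sigma, acc.size)
    return (mu + noise) if sd_status else (beta * acc + noise)


def sd_target_energy() -> float:
    """Hybridization energy of a canonical AGGAGG site (design target)."""
    return scan_asd("CUCUCUCAGGAGGCUCUCUCU").dg


def generate_construct_panel(
    n_constructs: int = 12,
    sd_status: bool = False,
    beta: float = 1.0,
    sigma: float | None = None,
    mu: float = 1.0,
    seed: int = 0,
    design_iters: int = 10_000,
    mfe_ladder: tuple[float, float] = (0.0, -14.0),
    backend: str = "baseline",
) -> ConstructPanel:
    """Design a ladder of constructs and simulate their reporter activities.

    Constructs share BASE_CONSTRUCT and an editable -25..+20 region; target
    MFEs span ``mfe_ladder``.  Activities are beta * accessibility + N(0,
    sigma^2) without an SD and mu + N(0, sigma^2) with one.  ``sigma=None``
    picks the noise so the planted coefficient of determination is 0.6
    (the regime the reporter experiments operate in).  Rungs that miss their
    MFE target by > 1.5 kcal/mol or the requested SD status are dropped with
    a warning.
    """
    if n_constructs < 3:
        raise ValueError("need at least 3 constructs")
    ss = np.random.SeedSequence(seed)
    targets = np.linspace(*mfe_ladder, n_constructs)
    child = ss.spawn(n_constructs + 1)
    results, seqs, kept_targets = [], [], []
    for t, cs in zip(targets, child[:-1]):
        spec = DesignSpec(
            base_seq=BASE_CONSTRUCT,
            start_index=START_INDEX,
            editable=(-25, 20),
            target_mfe=float(t),
            target_hyb=(sd_target_energy() if sd_status else None),
        )
        run_seed = int(cs.generate_state(1)[0] % (2**31))
        res = anneal(spec, seed=run_seed, n_iter=design_iters, backend=backend)
        mfe = mfe_energy(spec.region_seq(res.sequence, spec.mfe_region), backend)
        call = classify_sd(
            scan_asd(spec.region_seq(res.sequence, spec.hyb_region)).dg, "relaxed"
        )
        if abs(mfe - t) > 1.5 or (call is SDClass.SD_PLUS) != sd_status:
            logger.warning("design rung %.1f kcal/mol unmet; dropped", t)
            continue
        results.append(res)
        seqs.append(res.sequence)
        kept_targets.append(float(t))
    if len(seqs) < 3:
        raise RuntimeError("designer failed to populate the MFE ladder")
    acc = np.array(
        [
            unpaired_probability(s, (START_INDEX, START_INDEX + 3), backend=backend).p_unpaired
            for s in seqs
        ]
    )
    if sigma is None:
        r2 = 0.6
        sigma = float(beta * acc.std(ddof=1) * math.sqrt((1 - r2) / r2))
    rng = np.random.default_rng(child[-1])
    activities = simulate_activities(acc, sd_status, beta, sigma, mu, rng)
    truth = PanelTruth(sd_status, beta, float(sigma), mu, tuple(kept_targets))
    return ConstructPanel(seqs, results, acc, activities, truth)
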