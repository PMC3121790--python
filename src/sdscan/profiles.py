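"""Start-codon-centered structure profiles and the start/internal AUG contrast.

``mfe_profile`` slides a folding window over biological positions around the
start codon and reports the running mean +- SEM of window MFE per SD class;
``enumerate_augs``/``aug_window_mfe`` compare annotated start codons with
internal AUG triplets; ``box_stats`` provides Tukey boxplot statistics.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .folding import mfe_energy
from .hybridization import SDCall, SDClass
from .regions import GeneRegion

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MFEProfile:
    positions: np.ndarray  # biological coordinates
    mean_mfe: np.ndarray  # kcal/mol (nan where n == 0)
    sem: np.ndarray  # sample sd / sqrt(n); nan where n < 2
    n: np.ndarray
    window: int
    sd_class: SDClass


class FrameClass(enum.Enum):
    START = "start"
    IN_FRAME = "in_frame"
    OUT_OF_FRAME = "out_of_frame"


@dataclass(frozen=True)
class AUGRecord:
    gene_id: str
    bio_position: int  # first nucleotide of the AUG
    frame_class: FrameClass
    window_mfe: float | None = None


@dataclass(frozen=True)
class BoxStats:
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]


def mfe_profile(
    genes: Sequence[GeneRegion],
    calls: Iterable[SDCall],
    window: int = 50,
    region: tuple[int, int] = (-100, 100),
    backend: str = "baseline",
) -> dict[SDClass, MFEProfile]:
    """Per-position running mean and SEM of window MFE, stratified by SD class.

    ``calls`` are strict-scheme calls; EXCLUDED genes are dropped.  The energy
    of each window is assigned to its central position (offset ``window // 2``
    from the window start); a gene contributes to a position only when the
    full window fits inside its extracted sequence, so ``n`` shrinks near the
    edges instead of being imputed.
    """
    call_by_gene = {c.gene_id: c.call for c in calls}
    lo, hi = region
    positions = np.arange(lo, hi + 1)
    acc = {
        cls: [np.zeros(positions.size), np.zeros(positions.size), np.zeros(positions.size)]
        for cls in (SDClass.SD_PLUS, SDClass.SD_MINUS)
    }
    for g in genes:
        cls = call_by_gene.get(g.gene_id, SDClass.EXCLUDED)
        if cls is SDClass.EXCLUDED:
            continue
        seq = g.seq
        scp = g.start_codon_pos
        tot, tot2, cnt = acc[cls]
        for k, pos in enumerate(positions):
            start = scp + int(pos) - window // 2
            if start < 0 or start + window > len(seq):
                continue
            e = mfe_energy(seq[start : start + window], backend)
            tot[k] += e
            tot2[k] += e * e
            cnt[k] += 1
    out = {}
    for cls, (tot, tot2, cnt) in acc.items():
        if cnt.sum() == 0:
            logger.warning("no genes with class %s; profile absent", cls.value)
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan)
            var = np.where(
                cnt > 1,
                (tot2 - cnt * mean**2) / np.maximum(cnt - 1, 1),
                np.nan,
            )
            sem = np.sqrt(np.maximum(var, 0.0)) / np.sqrt(np.maximum(cnt, 1))
        out[cls] = MFEProfile(
            positions.copy(), mean, sem, cnt.astype(int), window, cls
        )
    return out


def profile_frame(profiles: Mapping[SDClass, MFEProfile]) -> pd.DataFrame:
    """Tidy table (class, position, mean_mfe, sem, n) ready for plotting."""
    rows = []
    for cls, p in profiles.items():
        for k in range(p.positions.size):
            rows.append(
                {
                    "sd_class": cls.value,
                    "position": int(p.positions[k]),
                    "mean_mfe_kcal_mol": p.mean_mfe[k],
                    "sem_kcal_mol": p.sem[k],
                    "n": int(p.n[k]),
                    "window_nt": p.window,
                }
            )
    return pd.DataFrame(rows)


def plot_profiles(profiles: Mapping[SDClass, MFEProfile], path) -> None:
    """Render mean-MFE curves with shaded SEM bands."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for cls, p in profiles.items():
        ax.plot(p.positions, p.mean_mfe, label=cls.value)
        ax.fill_between(
            p.positions, p.mean_mfe - p.sem, p.mean_mfe + p.sem, alpha=0.3
        )
    ax.set_xlabel("position relative to start codon (nt)")
    ax.set_ylabel(f"mean window MFE (kcal/mol)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def enumerate_augs(gene: GeneRegion, require_atg_start: bool = True) -> list[AUGRecord]:
    """Every ATG occurrence in utr+cds+downstream with its frame class.

    start: biological position 0.  in_frame: position > 0, divisible by 3 and
    fully inside the CDS.  Everything else — including upstream (UTR) AUGs,
    which are not annotated starts — is out_of_frame.
    """
    if require_atg_start and gene.start_codon != "ATG":
        return []
    seq = gene.seq
    scp = gene.start_codon_pos
    cds_len = len(gene.cds_seq)
    recs = []
    idx = seq.find("ATG")
    while idx != -1:
        bio = idx - scp
        if bio == 0:
            fc = FrameClass.START
        elif bio > 0 and bio % 3 == 0 and bio + 3 <= cds_len:
            fc = FrameClass.IN_FRAME
        else:
            fc = FrameClass.OUT_OF_FRAME
        recs.append(AUGRecord(gene.gene_id, bio, fc))
        idx = seq.find("ATG", idx + 1)
    return recs


def aug_window_mfe(
    gene: GeneRegion,
    records: Sequence[AUGRecord],
    window: int = 50,
    backend: str = "baseline",
) -> list[AUGRecord]:
    """Fill ``window_mfe`` with the MFE of the window centered on each AUG.

    Records whose window does not fit inside the extracted sequence are
    dropped with a warning.
    """
    seq = gene.seq
    scp = gene.start_codon_pos
    out = []
    for r in records:
        start = scp + r.bio_position - window // 2
        if start < 0 or start + window > len(seq):
            logger.warning(
                "%s: %d-nt window around AUG at %+d does not fit; dropped",
                gene.gene_id, window, r.bio_position,
            )
            continue
        e = mfe_energy(seq[start : start + window], backend)
        out.append(replace(r, window_mfe=e))
    return out


def aug_frame(records: Iterable[AUGRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "bio_position": r.bio_position,
                "frame_class": r.frame_class.value,
                "window_mfe_kcal_mol": r.window_mfe,
            }
            for r in records
        ]
    )


def box_stats(values: Sequence[float]) -> BoxStats:
    """Tukey boxplot statistics: quartiles by linear interpolation, whiskers
    at the most extreme points within 1.5 x IQR of the box."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one value")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])  # linear (type-7)
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = arr[(arr >= lo_fence) & (arr <= hi_fence)]
    wl, wh = float(inside.min()), float(inside.max())
    outliers = tuple(float(v) for v in arr[(arr < lo_fence) | (arr > hi_fence)])
    return BoxStats(float(med), float(q1), float(q3), wl, wh, outliers)
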