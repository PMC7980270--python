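"""Joint outlier scan for selective sweeps and gene annotation of candidates.

Candidate windows are those simultaneously in the upper tail of both
windowed FST and the theta_pi ratio (reference over focal group); Tajima's
D is carried along as corroborative output rather than used as a filter.
Flagged windows are merged into candidate regions and intersected with a
gene annotation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .panel import GenomicInterval
from .winstats import WindowStats

__all__ = [
    "Region",
    "JointOutlierResult",
    "joint_outlier_windows",
    "merge_and_score",
    "annotate_genes",
    "unique_genes",
]


@dataclass
class Region:
    """A merged candidate region with provenance scores and gene overlaps."""

    chrom: str
    start: int
    end: int
    n_windows: int
    fst_max: float
    pi_ratio_max: float
    tajima_focal_min: float | None
    genes: list[str] = field(default_factory=list)

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)

    # duck-typed for io_formats.write_bed
    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @property
    def score(self) -> float:
        return self.fst_max


@dataclass(frozen=True)
class JointOutlierResult:
    """Flagged windows plus the empirical thresholds that selected them."""

    flagged: tuple[WindowStats, ...]
    fst_threshold: float
    pi_ratio_threshold: float
    n_rankable: int
    q: float


def joint_outlier_windows(
    window_stats: Sequence[WindowStats],
    q: float = 0.05,
) -> JointOutlierResult:
    """Windows in BOTH the top-q tails of FST and the theta_pi ratio.

    Thresholds are empirical: the k-th largest value with
    ``k = max(1, floor(q * n))`` over rankable windows; boundary ties are
    included (``>= threshold``), keeping the cut deterministic.  Requires
    at least 20 rankable windows for the quantiles to be meaningful.
    """
    if not (0.0 < q < 1.0):
        raise ValueError("q must be in (0, 1)")
    rankable = [w for w in window_stats if w.rankable]
    n = len(rankable)
    if n < 20:
        raise ValueError(
            f"only {n} rankable windows; need >= 20 for a quantile cut"
        )
    k = max(1, math.floor(q * n))
    fst_vals = np.sort(np.array([w.fst for w in rankable]))[::-1]
    ratio_vals = np.sort(np.array([w.pi_ratio for w in rankable]))[::-1]
    fst_thr = float(fst_vals[k - 1])
    ratio_thr = float(ratio_vals[k - 1])
    flagged = tuple(
        w for w in rankable if w.fst >= fst_thr and w.pi_ratio >= ratio_thr
    )
    return JointOutlierResult(
        flagged=flagged,
        fst_threshold=fst_thr,
        pi_ratio_threshold=ratio_thr,
        n_rankable=n,
        q=q,
    )


def merge_and_score(
    flagged: Sequence[WindowStats],
    merge_gap: int = 0,
) -> list[Region]:
    """Merge overlapping/nearby flagged windows into scored regions.

    Windows on the same chromosome whose gap is at most ``merge_gap`` bp
    (overlapping or adjacent included) are merged; each region carries the
    max FST, max theta_pi ratio and min focal-group Tajima's D of its
    windows.
    """
    ordered = sorted(flagged, key=lambda w: (w.interval.chrom, w.interval.start))
    regions: list[Region] = []
    for w in ordered:
        iv = w.interval
        if (
            regions
            and regions[-1].chrom == iv.chrom
            and iv.start - regions[-1].end <= merge_gap
        ):
            r = regions[-1]
            r.end = max(r.end, iv.end)
            r.n_windows += 1
            r.fst_max = max(r.fst_max, w.fst)
            r.pi_ratio_max = max(r.pi_ratio_max, w.pi_ratio)
            if w.tajima_focal is not None:
                r.tajima_focal_min = (
                    w.tajima_focal
                    if r.tajima_focal_min is None
                    else min(r.tajima_focal_min, w.tajima_focal)
                )
        else:
            regions.append(
                Region(
                    chrom=iv.chrom,
                    start=iv.start,
                    end=iv.end,
                    n_windows=1,
                    fst_max=w.fst,
                    pi_ratio_max=w.pi_ratio,
                    tajima_focal_min=w.tajima_focal,
                )
            )
    return regions


def _strip_chr(name: str) -> str:
    return name[3:] if name.lower().startswith("chr") else name


def annotate_genes(
    regions: Sequence[Region],
    annotation: Sequence[GenomicInterval],
    chr_normalize: bool = False,
) -> list[Region]:
    """Attach overlapping gene names (>= 1 bp, half-open) to each region.

    With ``chr_normalize`` both namespaces are compared after stripping a
    leading "chr".  A complete chromosome-name mismatch between non-empty
    region and annotation sets is fatal, with a hint to normalise.
    """
    if regions and annotation:
        norm = _strip_chr if chr_normalize else (lambda s: s)
        rc = {norm(r.chrom) for r in regions}
        ac = {norm(g.chrom) for g in annotation}
        if not rc & ac:
            raise ValueError(
                "no chromosome names shared between regions and annotation "
                f"({sorted(rc)[:3]}... vs {sorted(ac)[:3]}...); "
                "try chr_normalize=True"
            )
    norm = _strip_chr if chr_normalize else (lambda s: s)
    out: list[Region] = []
    for r in regions:
        genes = [
            g.attributes.get("name", "?")
            for g in annotation
            if norm(g.chrom) == norm(r.chrom) and g.start < r.end and r.start < g.end
        ]
        r2 = Region(
            chrom=r.chrom, start=r.start, end=r.end, n_windows=r.n_windows,
            fst_max=r.fst_max, pi_ratio_max=r.pi_ratio_max,
            tajima_focal_min=r.tajima_focal_min, genes=sorted(set(genes)),
        )
        out.append(r2)
    return out


def unique_genes(regions: Sequence[Region]) -> list[str]:
    """Genome-wide unique gene list across all annotated regions."""
    seen: set[str] = set()
    for r in regions:
        seen.update(r.genes)
    return sorted(seen)
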