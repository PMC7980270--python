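"""Per-window population-genetic statistics.

Implements the metric set of a joint selection/introgression scan:
nucleotide diversity theta_pi, the Weir & Cockerham (1984) FST variance
components with ratio-of-sums windowing, Tajima's (1989) D, absolute
divergence Dxy, and the theta_pi ratio between a reference and a focal
group.  Per-bp statistics divide by the window length in bp (the VCFtools
sliding-window convention), so invariant sites need not be present.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .panel import (
    GenomicInterval,
    HaplotypePanel,
    WindowSpec,
    make_windows,
)

__all__ = [
    "SiteFstComponents",
    "TajimaParts",
    "WindowStats",
    "site_pi",
    "window_pi",
    "wc_fst_site",
    "window_fst",
    "tajimas_d",
    "tajima_constants",
    "dxy",
    "pi_ratio",
    "scan_windows",
]


# ----------------------------------------------------------- per-site core

def _called_freq(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (called haplotype count, derived count) for a hap matrix."""
    called = mat >= 0
    n = called.sum(axis=1)
    d = (mat == 1).sum(axis=1)
    return n, d


def _pi_per_site(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unbiased per-site pi ``2p(1-p) n/(n-1)``; mask of usable sites (n>=2)."""
    n, d = _called_freq(mat)
    ok = n >= 2
    pi = np.zeros(len(n), dtype=float)
    nn = n[ok].astype(float)
    dd = d[ok].astype(float)
    pi[ok] = 2.0 * dd * (nn - dd) / (nn * (nn - 1.0))
    return pi, ok


def _freq_per_site(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site derived frequency among called haplotypes; mask n>=1."""
    n, d = _called_freq(mat)
    ok = n >= 1
    p = np.full(len(n), np.nan)
    p[ok] = d[ok] / n[ok]
    return p, ok


def site_pi(
    panel: HaplotypePanel, population: str | Sequence[str], chrom: str, site_index: int
) -> float:
    """Unbiased nucleotide diversity of one site within one population.

    Raises if fewer than 2 haplotypes are called at the site.
    """
    mat = panel.alleles[chrom][site_index : site_index + 1][
        :, panel.hap_indices(population)
    ]
    pi, ok = _pi_per_site(mat)
    if not ok[0]:
        raise ValueError("fewer than 2 called haplotypes at site")
    return float(pi[0])


def window_pi(
    panel: HaplotypePanel,
    population: str | Sequence[str],
    interval: GenomicInterval,
) -> float:
    """Per-bp theta_pi over a window: sum of site pi / window length."""
    mat = panel.window_matrix(interval)[:, panel.hap_indices(population)]
    pi, _ = _pi_per_site(mat)
    return float(pi.sum() / interval.length)


# -------------------------------------------------------------------- FST

@dataclass(frozen=True)
class SiteFstComponents:
    """Weir & Cockerham per-site variance components and intermediates."""

    a: float
    b: float
    c: float
    p_i: tuple[float, ...]
    n_i: tuple[int, ...]
    h_i: tuple[float, ...]
    r: int
    n_bar: float
    n_c: float
    p_bar: float
    s2: float
    h_bar: float

    @property
    def fst(self) -> float | None:
        denom = self.a + self.b + self.c
        return None if denom == 0.0 else self.a / denom


def _wc_components_vec(
    genotype_mats: Sequence[np.ndarray],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, dict]:
    """Vectorised W&C (a, b, c) over sites for ``r`` diploid groups.

    Each element of ``genotype_mats`` is an ``(S, n_ind, 2)`` allele array
    for one group.  A site is usable when every group has >= 1 called
    individual (both alleles) and the mean sample size exceeds 1.  Returns
    (a, b, c, usable, intermediates).
    """
    r = len(genotype_mats)
    S = genotype_mats[0].shape[0]
    n_i = np.empty((r, S))
    p_i = np.empty((r, S))
    h_i = np.empty((r, S))
    for g, mat in enumerate(genotype_mats):
        called = (mat >= 0).all(axis=2)  # (S, n_ind)
        n = called.sum(axis=1).astype(float)
        der = np.where(called, (mat == 1).sum(axis=2), 0).sum(axis=1)
        het = np.where(called, mat[:, :, 0] != mat[:, :, 1], False).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            p_i[g] = der / (2.0 * n)
            h_i[g] = het / n
        n_i[g] = n
    n_bar = n_i.mean(axis=0)
    usable = (n_i >= 1).all(axis=0) & (n_bar > 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        n_c = (r * n_bar - (n_i**2).sum(axis=0) / (r * n_bar)) / (r - 1)
        p_bar = (n_i * p_i).sum(axis=0) / (r * n_bar)
        s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
        h_bar = (n_i * h_i).sum(axis=0) / (r * n_bar)
        inner = p_bar * (1.0 - p_bar) - ((r - 1.0) / r) * s2
        a = (n_bar / n_c) * (s2 - (inner - h_bar / 4.0) / (n_bar - 1.0))
        b = (n_bar / (n_bar - 1.0)) * (
            inner - ((2.0 * n_bar - 1.0) / (4.0 * n_bar)) * h_bar
        )
        c = h_bar / 2.0
    a = np.where(usable, a, 0.0)
    b = np.where(usable, b, 0.0)
    c = np.where(usable, c, 0.0)
    inter = {
        "n_i": n_i, "p_i": p_i, "h_i": h_i, "n_bar": n_bar, "n_c": n_c,
        "p_bar": p_bar, "s2": s2, "h_bar": h_bar,
    }
    return a, b, c, usable, inter


def _group_genotype_mats(
    panel: HaplotypePanel,
    groups: Mapping[str, Sequence[str] | str],
    chrom: str,
    lo: int,
    hi: int,
) -> list[np.ndarray]:
    mats = []
    for pops in groups.values():
        samp = panel.sample_indices(pops)
        cols = np.empty(2 * len(samp), dtype=np.intp)
        cols[0::2] = 2 * samp
        cols[1::2] = 2 * samp + 1
        sub = panel.alleles[chrom][lo:hi][:, cols]
        mats.append(sub.reshape(sub.shape[0], len(samp), 2))
    return mats


def wc_fst_site(
    panel: HaplotypePanel,
    groups: Mapping[str, Sequence[str] | str],
    chrom: str,
    site_index: int,
) -> SiteFstComponents:
    """Weir & Cockerham variance components (a, b, c) for one site."""
    mats = _group_genotype_mats(panel, groups, chrom, site_index, site_index + 1)
    a, b, c, usable, it = _wc_components_vec(mats)
    if not usable[0]:
        raise ValueError("site unusable for FST (a group has no called individuals)")
    r = len(mats)
    return SiteFstComponents(
        a=float(a[0]), b=float(b[0]), c=float(c[0]),
        p_i=tuple(float(it["p_i"][g, 0]) for g in range(r)),
        n_i=tuple(int(it["n_i"][g, 0]) for g in range(r)),
        h_i=tuple(float(it["h_i"][g, 0]) for g in range(r)),
        r=r,
        n_bar=float(it["n_bar"][0]),
        n_c=float(it["n_c"][0]),
        p_bar=float(it["p_bar"][0]),
        s2=float(it["s2"][0]),
        h_bar=float(it["h_bar"][0]),
    )


def window_fst(
    panel: HaplotypePanel,
    groups: Mapping[str, Sequence[str] | str],
    interval: GenomicInterval,
) -> float | None:
    """Weighted (ratio-of-sums) W&C FST over a window; None if undefined.

    Not clamped: small negative values are legitimate sampling outcomes.
    """
    lo, hi = panel.site_range(interval.chrom, interval.start, interval.end)
    mats = _group_genotype_mats(panel, groups, interval.chrom, lo, hi)
    a, b, c, usable, _ = _wc_components_vec(mats)
    if not usable.any():
        return None
    denom = (a + b + c)[usable].sum()
    if denom == 0.0:
        return None
    return float(a[usable].sum() / denom)


# --------------------------------------------------------------- Tajima's D

def tajima_constants(n: int) -> dict[str, float]:
    """Tajima (1989) normalising constants for ``n`` haplotypes."""
    if n < 2:
        raise ValueError("n >= 2 required")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
            "e1": e1, "e2": e2}


@dataclass(frozen=True)
class TajimaParts:
    """Tajima's D with its ingredients; ``d`` is None when undefined."""

    n: int
    s: int
    k_hat: float
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float
    d: float | None
    reason: str | None = None


def tajimas_d(
    panel: HaplotypePanel,
    population: str | Sequence[str],
    interval: GenomicInterval,
) -> TajimaParts:
    """Tajima's D for one population over a window.

    Only sites fully called in the population are used so the haplotype
    count ``n`` is constant, as the normalising constants assume.  ``k_hat``
    is the mean pairwise difference count (not per-bp), computed in its
    frequency form which equals explicit pair counting.  D is missing when
    S = 0, or when fewer than 4 haplotypes are available.
    """
    haps = panel.hap_indices(population)
    n = len(haps)
    zero = dict.fromkeys(
        ("a1", "a2", "b1", "b2", "c1", "c2", "e1", "e2"), float("nan")
    )
    if n < 4:
        return TajimaParts(n=n, s=0, k_hat=0.0, d=None, reason="n<4", **zero)
    mat = panel.window_matrix(interval)[:, haps]
    full = (mat >= 0).all(axis=1)
    mat = mat[full]
    d_counts = (mat == 1).sum(axis=1)
    seg = (d_counts > 0) & (d_counts < n)
    s = int(seg.sum())
    const = tajima_constants(n)
    dd = d_counts[seg].astype(float)
    k_hat = float((2.0 * dd * (n - dd) / (n * (n - 1.0))).sum())
    if s == 0:
        return TajimaParts(n=n, s=0, k_hat=0.0, d=None, reason="S=0", **const)
    var = const["e1"] * s + const["e2"] * s * (s - 1.0)
    d_stat = (k_hat - s / const["a1"]) / math.sqrt(var)
    return TajimaParts(n=n, s=s, k_hat=k_hat, d=float(d_stat), **const)


# --------------------------------------------------------------------- Dxy

def dxy(
    panel: HaplotypePanel,
    pop_a: str | Sequence[str],
    pop_b: str | Sequence[str],
    interval: GenomicInterval,
) -> float:
    """Per-bp absolute divergence between two populations over a window.

    Per site ``p_A(1-p_B) + p_B(1-p_A)`` over sites with >= 1 called
    haplotype in each population, divided by window length in bp.
    """
    mat = panel.window_matrix(interval)
    pa, oka = _freq_per_site(mat[:, panel.hap_indices(pop_a)])
    pb, okb = _freq_per_site(mat[:, panel.hap_indices(pop_b)])
    ok = oka & okb
    val = pa[ok] * (1.0 - pb[ok]) + pb[ok] * (1.0 - pa[ok])
    return float(val.sum() / interval.length)


# ----------------------------------------------------------------- pi ratio

def pi_ratio(
    theta_ref: float | None, theta_focal: float | None
) -> tuple[float | None, float | None]:
    """theta_pi(reference) / theta_pi(focal) and its log2; None if undefined.

    High values flag windows where the focal (extreme-environment) group
    lost diversity relative to the reference.
    """
    if theta_ref is None or theta_focal is None or theta_focal == 0.0:
        return None, None
    ratio = theta_ref / theta_focal
    log2 = math.log2(ratio) if ratio > 0.0 else None
    return ratio, log2


# ------------------------------------------------------------------- scan

@dataclass
class WindowStats:
    """One genomic window's worth of scan statistics."""

    interval: GenomicInterval
    n_sites: int
    pi_ref: float
    pi_focal: float
    pi_ratio: float | None
    pi_ratio_log2: float | None
    fst: float | None
    tajima_ref: float | None
    tajima_focal: float | None
    dxy: float | None
    n_sites_fst: int
    n_full_ref: int
    n_full_focal: int
    rankable: bool


def _cumsum0(x: np.ndarray) -> np.ndarray:
    out = np.zeros(len(x) + 1)
    np.cumsum(x, out=out[1:])
    return out


def scan_windows(
    panel: HaplotypePanel,
    ref_pops: Sequence[str] | str,
    focal_pops: Sequence[str] | str,
    spec: WindowSpec,
) -> list[WindowStats]:
    """Sliding-window scan contrasting a reference and a focal group.

    Each group pools one or more populations (e.g. breeds grouped by
    environment).  Emits one :class:`WindowStats` per window in
    deterministic order; windows with fewer than ``spec.min_sites``
    variant sites are flagged unrankable.
    """
    ref_haps = panel.hap_indices(ref_pops)
    focal_haps = panel.hap_indices(focal_pops)
    if len(ref_haps) < 4 or len(focal_haps) < 4:
        raise ValueError("each group needs at least 2 diploid individuals")
    groups = {"ref": ref_pops, "focal": focal_pops}

    out: list[WindowStats] = []
    const_ref = tajima_constants(len(ref_haps))
    const_focal = tajima_constants(len(focal_haps))
    for chrom in panel.chrom_names:
        mat = panel.alleles[chrom]
        pos = panel.positions[chrom]
        S = len(pos)
        mref = mat[:, ref_haps]
        mfoc = mat[:, focal_haps]
        pi_r, _ = _pi_per_site(mref)
        pi_f, _ = _pi_per_site(mfoc)
        # Tajima ingredients on fully-called sites per group
        parts = {}
        for tag, m, nh in (("ref", mref, len(ref_haps)), ("focal", mfoc, len(focal_haps))):
            fullmask = (m >= 0).all(axis=1)
            dcnt = (m == 1).sum(axis=1)
            seg = fullmask & (dcnt > 0) & (dcnt < nh)
            site_k = np.where(
                seg, 2.0 * dcnt * (nh - dcnt) / (nh * (nh - 1.0)), 0.0
            )
            parts[tag] = (
                _cumsum0(seg.astype(float)),
                _cumsum0(site_k),
                _cumsum0(fullmask.astype(float)),
                nh,
            )
        gm = _group_genotype_mats(panel, groups, chrom, 0, S)
        a, b, c, usable, _ = _wc_components_vec(gm)
        pa, oka = _freq_per_site(mref)
        pb, okb = _freq_per_site(mfoc)
        okd = oka & okb
        dxy_site = np.where(
            okd,
            np.nan_to_num(pa) * (1.0 - np.nan_to_num(pb))
            + np.nan_to_num(pb) * (1.0 - np.nan_to_num(pa)),
            0.0,
        )

        cum_pi_r = _cumsum0(pi_r)
        cum_pi_f = _cumsum0(pi_f)
        cum_a = _cumsum0(a)
        cum_abc = _cumsum0(a + b + c)
        cum_use = _cumsum0(usable.astype(float))
        cum_dxy = _cumsum0(dxy_site)

        for w in make_windows({chrom: panel.chrom_lengths[chrom]}, spec):
            lo, hi = panel.site_range(chrom, w.start, w.end)
            n_sites = hi - lo
            L = w.length
            p_ref = (cum_pi_r[hi] - cum_pi_r[lo]) / L
            p_foc = (cum_pi_f[hi] - cum_pi_f[lo]) / L
            ratio, log2r = pi_ratio(p_ref, p_foc)
            n_use = int(cum_use[hi] - cum_use[lo])
            denom = cum_abc[hi] - cum_abc[lo]
            fst = (cum_a[hi] - cum_a[lo]) / denom if (n_use and denom != 0.0) else None
            taj = {}
            nfull = {}
            for tag, const in (("ref", const_ref), ("focal", const_focal)):
                cs, ck, cf, nh = parts[tag]
                s_w = int(cs[hi] - cs[lo])
                nfull[tag] = int(cf[hi] - cf[lo])
                if nh < 4 or s_w == 0:
                    taj[tag] = None
                else:
                    k_hat = ck[hi] - ck[lo]
                    var = const["e1"] * s_w + const["e2"] * s_w * (s_w - 1.0)
                    taj[tag] = float((k_hat - s_w / const["a1"]) / math.sqrt(var))
            dxy_w = (cum_dxy[hi] - cum_dxy[lo]) / L
            out.append(
                WindowStats(
                    interval=w,
                    n_sites=n_sites,
                    pi_ref=p_ref,
                    pi_focal=p_foc,
                    pi_ratio=ratio,
                    pi_ratio_log2=log2r,
                    fst=fst,
                    tajima_ref=taj["ref"],
                    tajima_focal=taj["focal"],
                    dxy=dxy_w,
                    n_sites_fst=n_use,
                    n_full_ref=nfull["ref"],
                    n_full_focal=nfull["focal"],
                    rankable=(
                        n_sites >= spec.min_sites
                        and fst is not None
                        and ratio is not None
                    ),
                )
            )
    return out
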