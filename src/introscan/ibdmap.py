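"""Shared-haplotype (IBD) detection and the windowed rIBD introgression scan.

True IBD inference (fastIBD-style HMMs) is out of scope; long
near-identical IBS runs between phased haplotypes stand in for IBD
segments, and externally inferred segments can be supplied instead via
:func:`introscan.io_formats.read_ibd_segments`.

The rIBD statistic per window is ``f_control - f_donor`` where ``f_X`` is
the fraction of recipient×X haplotype pairs sharing at least one segment
overlapping the window.  Sharing is binary per pair (not chunk counts), so
``f`` is in [0, 1] and rIBD in [-1, 1]; negative rIBD means the recipient
shares more with the donor than with the controls, i.e. candidate donor
introgression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .panel import (
    GenomicInterval,
    HaplotypePanel,
    IBDSegment,
    WindowSpec,
    make_windows,
)

__all__ = [
    "RibdWindow",
    "haplotype_pair_universe",
    "detect_ibs_segments",
    "window_ibd_frequency",
    "ribd_scan",
    "extract_introgression_regions",
]

#: default sliding-window layout for the rIBD scan (20 kb / 10 kb)
RIBD_WINDOWS = WindowSpec(size=20_000, step=10_000, min_sites=1)


def haplotype_pair_universe(
    panel: HaplotypePanel,
    pops_a: str | Sequence[str],
    pops_b: str | Sequence[str],
) -> list[tuple[int, int]]:
    """All order-normalised haplotype pairs between two population sets."""
    ha = panel.hap_indices(pops_a)
    hb = panel.hap_indices(pops_b)
    if set(ha.tolist()) & set(hb.tolist()):
        raise ValueError("pair universe requires disjoint haplotype sets")
    return sorted(
        (int(a), int(b)) if a < b else (int(b), int(a)) for a in ha for b in hb
    )


def _pair_runs(
    mism_idx: np.ndarray,
    n_sites: int,
    max_mismatch_frac: float,
) -> list[tuple[int, int, int]]:
    """Greedy left-to-right run split: (start_site, end_site, n_mismatch).

    A run may absorb a mismatch while mismatches stay within
    ``max_mismatch_frac`` of the run's site count; otherwise it is closed
    at the last matching site and a new run starts after the mismatch.
    Runs start and end at matching sites.
    """
    runs: list[tuple[int, int, int]] = []
    s0 = 0
    m_start = 0  # index into mism_idx of first mismatch in current run

    def close(end_excl: int, m_stop: int) -> None:
        # trim trailing mismatches so the run ends on a match
        end = end_excl - 1
        k = m_stop - 1
        m = m_stop - m_start
        while k >= m_start and mism_idx[k] == end:
            end -= 1
            k -= 1
            m -= 1
        if end >= s0:
            runs.append((s0, end, m))

    for k in range(len(mism_idx)):
        i = int(mism_idx[k])
        m_in_run = k - m_start
        if (m_in_run + 1) <= max_mismatch_frac * (i - s0 + 1):
            continue  # absorb this mismatch
        close(i, k)
        s0 = i + 1
        m_start = k + 1
    if n_sites > 0:
        close(n_sites, len(mism_idx))
    return runs


def detect_ibs_segments(
    panel: HaplotypePanel,
    pops_a: str | Sequence[str],
    pops_b: str | Sequence[str],
    min_length_bp: int = 50_000,
    min_sites: int = 25,
    max_mismatch_frac: float = 0.02,
) -> list[IBDSegment]:
    """Detect long near-identical IBS runs between cross-population pairs.

    For each haplotype pair, maximal left-to-right greedy runs of sites
    whose mismatch count stays within ``max_mismatch_frac`` of the run's
    site count are kept when they span at least ``min_length_bp`` AND
    contain at least ``min_sites`` sites.  Sites where either haplotype is
    missing count as matches.  Segment bp bounds extend from the first/last
    matching site half-way to the neighbouring site outside the run,
    clipped at chromosome ends.  Output is deterministic.
    """
    pairs = haplotype_pair_universe(panel, pops_a, pops_b)
    segments: list[IBDSegment] = []
    for chrom in panel.chrom_names:
        mat = panel.alleles[chrom]
        pos = panel.positions[chrom]
        S = len(pos)
        if S == 0:
            continue
        clen = panel.chrom_lengths[chrom]
        for a, b in pairs:
            col_a = mat[:, a]
            col_b = mat[:, b]
            mism = (col_a != col_b) & (col_a >= 0) & (col_b >= 0)
            mism_idx = np.flatnonzero(mism)
            for start, end, n_mm in _pair_runs(mism_idx, S, max_mismatch_frac):
                # half-extension to neighbouring sites (0-based bp)
                left = 0 if start == 0 else (int(pos[start - 1]) + int(pos[start])) // 2 - 1
                right = clen if end == S - 1 else (int(pos[end]) + int(pos[end + 1])) // 2
                n_run = end - start + 1
                if right - left >= min_length_bp and n_run >= min_sites:
                    segments.append(
                        IBDSegment(
                            hap_a=a, hap_b=b, chrom=chrom,
                            start=left, end=right,
                            n_sites=n_run, n_mismatch=n_mm,
                        )
                    )
    return segments


def window_ibd_frequency(
    segments: Iterable[IBDSegment],
    pair_universe: Sequence[tuple[int, int]],
    windows: Sequence[GenomicInterval],
) -> np.ndarray:
    """Fraction of pairs with >= 1 overlapping segment, per window.

    Sharing is binary per pair per window.  Segments whose pair is not in
    the universe are ignored.  Returns NaN everywhere if the universe is
    empty.
    """
    n_win = len(windows)
    if len(pair_universe) == 0:
        return np.full(n_win, np.nan)
    universe = {p: i for i, p in enumerate(pair_universe)}
    # group windows by chromosome, keeping original indices
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in {w.chrom for w in windows}:
        idx = np.array([i for i, w in enumerate(windows) if w.chrom == chrom])
        starts = np.array([windows[i].start for i in idx])
        ends = np.array([windows[i].end for i in idx])
        by_chrom[chrom] = (idx, starts, ends)

    covered = np.zeros((len(pair_universe), n_win), dtype=bool)
    for seg in segments:
        j = universe.get(seg.pair)
        if j is None or seg.chrom not in by_chrom:
            continue
        idx, starts, ends = by_chrom[seg.chrom]
        i_hi = int(np.searchsorted(starts, seg.end, side="left"))
        i_lo = int(np.searchsorted(ends, seg.start, side="right"))
        if i_lo < i_hi:
            covered[j, idx[i_lo:i_hi]] = True
    return covered.sum(axis=0) / len(pair_universe)


@dataclass(frozen=True)
class RibdWindow:
    """One window of the rIBD scan."""

    interval: GenomicInterval
    f_donor: float
    f_control: float
    ribd: float | None
    n_donor_pairs: int
    n_control_pairs: int


def ribd_scan(
    panel: HaplotypePanel,
    donor: str | Sequence[str],
    recipient: str | Sequence[str],
    controls: str | Sequence[str],
    spec: WindowSpec = RIBD_WINDOWS,
    segments: Sequence[IBDSegment] | None = None,
    min_length_bp: int = 50_000,
    min_sites: int = 25,
    max_mismatch_frac: float = 0.02,
    flip_sign: bool = False,
) -> list[RibdWindow]:
    """Windowed rIBD scan: ``rIBD = f_control - f_donor`` per window.

    Negative rIBD flags candidate donor→recipient introgression.  If
    ``segments`` is None the built-in IBS-run detector is used for both
    the donor×recipient and control×recipient pair sets; otherwise the
    supplied segments (e.g. Beagle fastIBD output read from file, or
    simulator truth segments) are partitioned by pair universe.
    ``flip_sign`` emits the opposite sign convention.
    """
    donor_set = {donor} if isinstance(donor, str) else set(donor)
    recip_set = {recipient} if isinstance(recipient, str) else set(recipient)
    ctrl_set = {controls} if isinstance(controls, str) else set(controls)
    if (donor_set & recip_set) or (donor_set & ctrl_set) or (recip_set & ctrl_set):
        raise ValueError("donor, recipient and control populations must be disjoint")

    pairs_d = haplotype_pair_universe(panel, donor, recipient)
    pairs_c = haplotype_pair_universe(panel, controls, recipient)
    if segments is None:
        segs = detect_ibs_segments(
            panel, donor, recipient, min_length_bp, min_sites, max_mismatch_frac
        ) + detect_ibs_segments(
            panel, controls, recipient, min_length_bp, min_sites, max_mismatch_frac
        )
    else:
        segs = list(segments)
    windows = make_windows(
        {c: panel.chrom_lengths[c] for c in panel.chrom_names}, spec
    )
    f_d = window_ibd_frequency(segs, pairs_d, windows)
    f_c = window_ibd_frequency(segs, pairs_c, windows)
    out: list[RibdWindow] = []
    for i, w in enumerate(windows):
        if np.isnan(f_d[i]) or np.isnan(f_c[i]):
            ribd = None
        else:
            ribd = float(f_c[i] - f_d[i])
            if flip_sign:
                ribd = -ribd
        out.append(
            RibdWindow(
                interval=w,
                f_donor=float(f_d[i]) if not np.isnan(f_d[i]) else float("nan"),
                f_control=float(f_c[i]) if not np.isnan(f_c[i]) else float("nan"),
                ribd=ribd,
                n_donor_pairs=len(pairs_d),
                n_control_pairs=len(pairs_c),
            )
        )
    return out


def extract_introgression_regions(
    ribd_windows: Sequence[RibdWindow],
    threshold: float = 0.0,
    min_run: int = 3,
    merge_gap: int | None = None,
) -> list[GenomicInterval]:
    """Group sub-threshold rIBD windows into candidate regions.

    Windows with ``ribd < threshold`` are grouped into runs of at least
    ``min_run`` consecutive flagged windows per chromosome; runs whose
    union spans are separated by at most ``merge_gap`` bp (default: the
    window step) are merged.  Each region carries ``score`` = minimum rIBD
    inside and ``n_windows``.  Deterministic.
    """
    if merge_gap is None:
        steps = [
            b.interval.start - a.interval.start
            for a, b in zip(ribd_windows, ribd_windows[1:])
            if a.interval.chrom == b.interval.chrom
        ]
        merge_gap = min((s for s in steps if s > 0), default=0)

    # collect flagged runs per chromosome (windows arrive in scan order)
    raw: list[tuple[str, int, int, float, int]] = []
    run: list[RibdWindow] = []

    def close_run() -> None:
        if len(run) >= min_run:
            raw.append(
                (
                    run[0].interval.chrom,
                    min(w.interval.start for w in run),
                    max(w.interval.end for w in run),
                    min(w.ribd for w in run),
                    len(run),
                )
            )
        run.clear()

    prev_chrom = None
    for w in ribd_windows:
        flagged = w.ribd is not None and w.ribd < threshold
        if w.interval.chrom != prev_chrom:
            close_run()
            prev_chrom = w.interval.chrom
        if flagged:
            run.append(w)
        else:
            close_run()
    close_run()

    merged: list[list] = []
    for chrom, start, end, score, n_win in raw:
        if (
            merged
            and merged[-1][0] == chrom
            and start - merged[-1][2] <= merge_gap
        ):
            merged[-1][2] = max(merged[-1][2], end)
            merged[-1][3] = min(merged[-1][3], score)
            merged[-1][4] += n_win
        else:
            merged.append([chrom, start, end, score, n_win])
    return [
        GenomicInterval(
            chrom, start, end,
            {"score": score, "n_windows": n_win, "name": f"introgression_{i + 1}"},
        )
        for i, (chrom, start, end, score, n_win) in enumerate(merged)
    ]
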