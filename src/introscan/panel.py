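"""Core containers: phased haplotype panels, genomic intervals, window specs.

Coordinate conventions used throughout the package:

* internal genomic intervals are 0-based half-open ``[start, end)``;
* VCF/GFF3 1-based coordinates are converted at the I/O boundary;
* site positions stored on a panel are the original 1-based VCF ``POS``
  values (a site at POS ``p`` occupies base ``p - 1`` in internal
  coordinates).

A :class:`HaplotypePanel` holds phased biallelic genotypes as per-chromosome
``(n_sites, n_haplotypes)`` matrices of ``{0, 1, MISSING}``.  Haplotype
columns come in sample order, two per sample, with haplotype 0 the left
allele of the VCF GT field.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

#: sentinel for a missing allele call
MISSING: int = -1


@dataclass
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window layout: ``size``/``step`` in bp plus a ranking floor.

    ``min_sites`` is the minimum number of variant sites for a window to
    receive ranked statistics (quantile cuts); windows below it are still
    reported but flagged unrankable.
    """

    size: int
    step: int
    min_sites: int = 10

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError("window size must be positive")
        if not (0 < self.step <= self.size):
            raise ValueError("require 0 < step <= size")
        if self.min_sites < 1:
            raise ValueError("min_sites must be >= 1")


@dataclass(frozen=True)
class IBDSegment:
    """One shared haplotype segment between two haplotype columns.

    ``hap_a``/``hap_b`` are panel haplotype column indices (normalised so
    that ``hap_a < hap_b``); ``start``/``end`` are 0-based half-open bp.
    """

    hap_a: int
    hap_b: int
    chrom: str
    start: int
    end: int
    n_sites: int = 0
    n_mismatch: int = 0
    score: float | None = None

    def __post_init__(self) -> None:
        if self.hap_a == self.hap_b:
            raise ValueError("IBD segment must join two distinct haplotypes")
        if self.start >= self.end:
            raise ValueError(
                f"inverted IBD segment interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def pair(self) -> tuple[int, int]:
        a, b = self.hap_a, self.hap_b
        return (a, b) if a < b else (b, a)

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


@dataclass
class HaplotypePanel:
    """Phased biallelic allele matrices with a sample→population map."""

    chrom_names: list[str]
    chrom_lengths: dict[str, int]
    positions: dict[str, np.ndarray]
    alleles: dict[str, np.ndarray]
    sample_ids: list[str]
    popmap: dict[str, str]
    ref_alleles: dict[str, np.ndarray] | None = None
    alt_alleles: dict[str, np.ndarray] | None = None

    # ------------------------------------------------------------------ sizes
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_haplotypes(self) -> int:
        return 2 * len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return int(sum(len(self.positions[c]) for c in self.chrom_names))

    @property
    def haplotype_labels(self) -> list[str]:
        return [f"{s}|{k}" for s in self.sample_ids for k in (0, 1)]

    @property
    def haplotype_sample_index(self) -> np.ndarray:
        """Sample index of each haplotype column."""
        return np.repeat(np.arange(self.n_samples), 2)

    # ------------------------------------------------------------- populations
    def populations(self) -> list[str]:
        """Population labels in order of first appearance in sample order."""
        seen: list[str] = []
        for s in self.sample_ids:
            p = self.popmap[s]
            if p not in seen:
                seen.append(p)
        return seen

    def _pop_list(self, pops: str | Iterable[str]) -> list[str]:
        if isinstance(pops, str):
            pops = [pops]
        pops = list(pops)
        known = set(self.popmap.values())
        unknown = [p for p in pops if p not in known]
        if unknown:
            raise KeyError(f"unknown population(s): {', '.join(unknown)}")
        return pops

    def sample_indices(self, pops: str | Iterable[str]) -> np.ndarray:
        pops = set(self._pop_list(pops))
        return np.array(
            [i for i, s in enumerate(self.sample_ids) if self.popmap[s] in pops],
            dtype=np.intp,
        )

    def hap_indices(self, pops: str | Iterable[str]) -> np.ndarray:
        """Haplotype column indices of all samples in the given population(s)."""
        samp = self.sample_indices(pops)
        return np.concatenate([2 * samp, 2 * samp + 1]) if len(samp) else np.array(
            [], dtype=np.intp
        )

    # --------------------------------------------------------------- windowing
    def site_range(self, chrom: str, start: int, end: int) -> tuple[int, int]:
        """Index range ``[lo, hi)`` of sites in 0-based interval [start, end)."""
        pos = self.positions[chrom]
        # 1-based POS p occupies internal base p-1: in window iff start <= p-1 < end
        lo = int(np.searchsorted(pos, start + 1, side="left"))
        hi = int(np.searchsorted(pos, end, side="right"))
        return lo, hi

    def window_matrix(self, interval: GenomicInterval) -> np.ndarray:
        lo, hi = self.site_range(interval.chrom, interval.start, interval.end)
        return self.alleles[interval.chrom][lo:hi]

    # -------------------------------------------------------------- validation
    def validate(self) -> None:
        if set(self.chrom_names) != set(self.positions) or set(self.chrom_names) != set(
            self.alleles
        ):
            raise ValueError("chromosome bookkeeping out of sync")
        missing_pop = [s for s in self.sample_ids if s not in self.popmap]
        if missing_pop:
            raise ValueError(
                "samples without a population assignment: " + ", ".join(missing_pop)
            )
        for c in self.chrom_names:
            pos = self.positions[c]
            mat = self.alleles[c]
            if mat.shape != (len(pos), self.n_haplotypes):
                raise ValueError(f"allele matrix shape mismatch on {c}")
            if len(pos) and (np.diff(pos) <= 0).any():
                raise ValueError(f"positions not strictly increasing on {c}")
            if len(pos) and (pos[0] < 1 or pos[-1] > self.chrom_lengths[c]):
                raise ValueError(f"positions outside chromosome bounds on {c}")
            bad = ~np.isin(mat, (0, 1, MISSING))
            if bad.any():
                raise ValueError(f"allele values outside {{0,1,missing}} on {c}")

    def copy(self) -> "HaplotypePanel":
        return HaplotypePanel(
            chrom_names=list(self.chrom_names),
            chrom_lengths=dict(self.chrom_lengths),
            positions={c: self.positions[c].copy() for c in self.chrom_names},
            alleles={c: self.alleles[c].copy() for c in self.chrom_names},
            sample_ids=list(self.sample_ids),
            popmap=dict(self.popmap),
            ref_alleles=None
            if self.ref_alleles is None
            else {c: self.ref_alleles[c].copy() for c in self.chrom_names},
            alt_alleles=None
            if self.alt_alleles is None
            else {c: self.alt_alleles[c].copy() for c in self.chrom_names},
        )


def make_windows(
    chrom_lengths: Mapping[str, int] | Sequence[tuple[str, int]],
    spec: WindowSpec,
) -> list[GenomicInterval]:
    """Tile each chromosome with sliding windows.

    Windows are ``[k*step, k*step + size)`` for ``k = 0, 1, ...`` while
    ``k*step < length``; the trailing windows are truncated at the
    chromosome end and flagged with ``attributes['truncated'] = True``.
    Order is deterministic: chromosome order, then start.
    """
    if not isinstance(chrom_lengths, Mapping):
        chrom_lengths = dict(chrom_lengths)
    out: list[GenomicInterval] = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            continue
        k = 0
        while k * spec.step < length:
            start = k * spec.step
            end = min(start + spec.size, length)
            out.append(
                GenomicInterval(
                    chrom, start, end, attributes={"truncated": end - start < spec.size}
                )
            )
            k += 1
    return out
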