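"""Shared test fixtures helpers: hand-built and random haplotype panels."""

from __future__ import annotations

import numpy as np

from introscan.panel import HaplotypePanel


def build_panel(
    mat,
    positions=None,
    samples=None,
    popmap=None,
    length=None,
    chrom="chr1",
) -> HaplotypePanel:
    """Build a single-chromosome panel from an (S, H) allele matrix."""
    mat = np.asarray(mat, dtype=np.int8)
    n_sites, n_haps = mat.shape
    assert n_haps % 2 == 0
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 10
    positions = np.asarray(positions, dtype=np.int64)
    if length is None:
        length = int(positions[-1]) + 10 if n_sites else 100
    if samples is None:
        samples = [f"s{i}" for i in range(n_haps // 2)]
    if popmap is None:
        popmap = {s: "pop" for s in samples}
    return HaplotypePanel(
        chrom_names=[chrom],
        chrom_lengths={chrom: length},
        positions={chrom: positions},
        alleles={chrom: mat},
        sample_ids=list(samples),
        popmap=dict(popmap),
    )


def random_panel(
    rng: np.random.Generator,
    n_samples: int = 6,
    n_sites: int = 40,
    length: int = 100_000,
    n_pops: int = 2,
    missing_frac: float = 0.05,
) -> HaplotypePanel:
    """Random panel with uniform allele draws and optional missingness."""
    positions = np.sort(
        rng.choice(np.arange(1, length + 1), size=n_sites, replace=False)
    ).astype(np.int64)
    mat = rng.integers(0, 2, size=(n_sites, 2 * n_samples)).astype(np.int8)
    if missing_frac > 0:
        mask = rng.random(mat.shape) < missing_frac
        mat[mask] = -1
    samples = [f"s{i}" for i in range(n_samples)]
    popmap = {s: f"pop{i % n_pops}" for i, s in enumerate(samples)}
    return build_panel(mat, positions, samples, popmap, length=length)
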