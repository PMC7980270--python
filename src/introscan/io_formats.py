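"""Readers and writers for the external formats the pipeline touches.

Supported formats: phased VCF 4.2 (GT only) read via cyvcf2 and written by a
minimal text emitter, two-column popmap TSV, a Beagle-fastIBD-like tabular
segment dialect, BED / GFF3 gene annotations, and the TSV window tables /
BED region files the scans emit.  All coordinates are converted to the
package-internal 0-based half-open convention at this boundary.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .panel import (
    MISSING,
    GenomicInterval,
    HaplotypePanel,
    IBDSegment,
    make_windows,
)

__all__ = [
    "make_windows",
    "read_popmap",
    "read_phased_vcf",
    "write_phased_vcf",
    "read_ibd_segments",
    "read_gene_annotation",
    "write_window_table",
    "read_window_table",
    "write_bed",
]

_NUCS = {"A", "C", "G", "T"}


def read_popmap(path: str | Path) -> dict[str, str]:
    """Read a two-column (sample, population) TSV into a dict."""
    popmap: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: expected 'sample<TAB>population'")
            popmap[parts[0]] = parts[1]
    return popmap


def read_phased_vcf(
    path: str | Path,
    popmap: str | Path | Mapping[str, str],
    allow_unphased: bool = False,
) -> HaplotypePanel:
    """Load phased biallelic SNPs from a VCF into a :class:`HaplotypePanel`.

    Multiallelic and non-SNP records are skipped with a single summary
    warning.  Unphased ("/") non-missing genotypes are fatal unless
    ``allow_unphased`` is set.  Every VCF sample must appear in the popmap.
    """
    if not isinstance(popmap, Mapping):
        popmap = read_popmap(popmap)

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    absent = [s for s in samples if s not in popmap]
    if absent:
        raise ValueError(
            "samples missing from popmap: " + ", ".join(absent)
        )

    # chromosome names/lengths from header contigs when available
    chrom_names: list[str] = []
    chrom_lengths: dict[str, int] = {}
    try:
        header_names = list(vcf.seqnames)
        header_lens = list(vcf.seqlens)
    except Exception:  # no contig header lines
        header_names, header_lens = [], []
    for name, ln in zip(header_names, header_lens):
        chrom_names.append(name)
        chrom_lengths[name] = int(ln)

    pos: dict[str, list[int]] = {c: [] for c in chrom_names}
    mats: dict[str, list[np.ndarray]] = {c: [] for c in chrom_names}
    refs: dict[str, list[str]] = {c: [] for c in chrom_names}
    alts: dict[str, list[str]] = {c: [] for c in chrom_names}
    n_skipped = 0

    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        if v.REF.upper() not in _NUCS or v.ALT[0].upper() not in _NUCS:
            n_skipped += 1
            continue
        chrom = v.CHROM
        if chrom not in mats:
            chrom_names.append(chrom)
            pos[chrom], mats[chrom], refs[chrom], alts[chrom] = [], [], [], []
        row = np.full(2 * len(samples), MISSING, dtype=np.int8)
        for i, gt in enumerate(v.genotypes):
            if len(gt) != 3:
                raise ValueError(
                    f"malformed GT for sample {samples[i]} at {chrom}:{v.POS}: "
                    "expected diploid genotype"
                )
            a, b, phased = gt
            if a >= 0:
                row[2 * i] = a
            if b >= 0:
                row[2 * i + 1] = b
            if (a >= 0 or b >= 0) and not phased and not allow_unphased:
                raise ValueError(
                    f"unphased genotype for sample {samples[i]} at {chrom}:{v.POS}; "
                    "pass allow_unphased=True to accept"
                )
        pos[chrom].append(v.POS)
        mats[chrom].append(row)
        refs[chrom].append(v.REF.upper())
        alts[chrom].append(v.ALT[0].upper())

    if n_skipped:
        warnings.warn(
            f"skipped {n_skipped} non-biallelic-SNP record(s) in {path}",
            stacklevel=2,
        )

    positions = {
        c: np.asarray(pos[c], dtype=np.int64) for c in chrom_names
    }
    alleles = {
        c: (
            np.vstack(mats[c])
            if mats[c]
            else np.empty((0, 2 * len(samples)), dtype=np.int8)
        )
        for c in chrom_names
    }
    for c in chrom_names:
        if c not in chrom_lengths:
            chrom_lengths[c] = int(positions[c][-1]) if len(positions[c]) else 1

    panel = HaplotypePanel(
        chrom_names=chrom_names,
        chrom_lengths=chrom_lengths,
        positions=positions,
        alleles=alleles,
        sample_ids=samples,
        popmap={s: popmap[s] for s in samples},
        ref_alleles={c: np.asarray(refs[c], dtype="U1") for c in chrom_names},
        alt_alleles={c: np.asarray(alts[c], dtype="U1") for c in chrom_names},
    )
    panel.validate()
    return panel


def write_phased_vcf(panel: HaplotypePanel, path: str | Path) -> None:
    """Write a minimal phased VCF 4.2 (GT-only FORMAT, "|" separator).

    ``read_phased_vcf(write_phased_vcf(p))`` reproduces alleles, positions
    and sample order exactly.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=introscan\n")
        for c in panel.chrom_names:
            fh.write(f"##contig=<ID={c},length={panel.chrom_lengths[c]}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.sample_ids)
            + "\n"
        )
        for c in panel.chrom_names:
            pos = panel.positions[c]
            mat = panel.alleles[c]
            refs = (
                panel.ref_alleles[c]
                if panel.ref_alleles is not None
                else np.full(len(pos), "A", dtype="U1")
            )
            alts = (
                panel.alt_alleles[c]
                if panel.alt_alleles is not None
                else np.full(len(pos), "C", dtype="U1")
            )
            for j in range(len(pos)):
                row = mat[j]
                gts = "\t".join(
                    f"{_gt(row[2 * i])}|{_gt(row[2 * i + 1])}"
                    for i in range(panel.n_samples)
                )
                fh.write(
                    f"{c}\t{pos[j]}\t.\t{refs[j]}\t{alts[j]}\t.\t.\t.\tGT\t{gts}\n"
                )


def _gt(a: int) -> str:
    return "." if a == MISSING else str(int(a))


def read_ibd_segments(
    path: str | Path,
    panel: HaplotypePanel,
    max_score: float | None = None,
) -> list[IBDSegment]:
    """Read a fastIBD-like whitespace-delimited segment file.

    Columns: sample1, hap_index1 (0/1), sample2, hap_index2, chrom,
    start_bp, end_bp, score.  Segments are validated against the panel and
    haplotype ids resolved to panel columns.  ``max_score`` optionally
    filters segments with score above the cutoff (fastIBD scores are
    smaller-is-better).
    """
    sample_index = {s: i for i, s in enumerate(panel.sample_ids)}
    segments: list[IBDSegment] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 8:
                raise ValueError(f"{path}:{ln}: expected 8 columns, got {len(parts)}")
            s1, h1, s2, h2, chrom, start, end, score = parts[:8]
            for s in (s1, s2):
                if s not in sample_index:
                    raise ValueError(f"{path}:{ln}: unknown sample {s!r}")
            start_i, end_i = int(start), int(end)
            if start_i >= end_i:
                raise ValueError(
                    f"{path}:{ln}: inverted interval {start_i} >= {end_i}"
                )
            if chrom not in panel.chrom_lengths:
                raise ValueError(f"{path}:{ln}: unknown chromosome {chrom!r}")
            score_f = float(score)
            if max_score is not None and score_f > max_score:
                continue
            a = 2 * sample_index[s1] + int(h1)
            b = 2 * sample_index[s2] + int(h2)
            if a > b:
                a, b = b, a
            segments.append(
                IBDSegment(
                    hap_a=a, hap_b=b, chrom=chrom, start=start_i, end=end_i,
                    score=score_f,
                )
            )
    return segments


def read_gene_annotation(
    path: str | Path,
    feature_types: Sequence[str] = ("gene",),
) -> list[GenomicInterval]:
    """Read gene intervals from BED (0-based half-open) or GFF3 (1-based).

    GFF3 coordinates are converted by ``start - 1``; only records whose
    type is in ``feature_types`` are kept.  Output intervals carry a
    ``name`` attribute.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    out: list[GenomicInterval] = []
    if suffix == ".bed":
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split()
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                if start < 0:
                    raise ValueError(f"{path}:{ln}: negative coordinate")
                name = parts[3] if len(parts) > 3 else f"feature_{ln}"
                out.append(GenomicInterval(chrom, start, end, {"name": name}))
    elif suffix in (".gff", ".gff3"):
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 9:
                    raise ValueError(f"{path}:{ln}: expected 9 GFF3 columns")
                chrom, _src, ftype, start, end = parts[0], parts[1], parts[2], int(
                    parts[3]
                ), int(parts[4])
                if ftype not in feature_types:
                    continue
                if start < 1:
                    raise ValueError(f"{path}:{ln}: negative/zero GFF3 coordinate")
                name = _gff3_name(parts[8]) or f"feature_{ln}"
                out.append(GenomicInterval(chrom, start - 1, end, {"name": name}))
    else:
        raise ValueError(
            f"unknown annotation extension {suffix!r} (expected .bed/.gff/.gff3)"
        )
    return out


def _gff3_name(attr_col: str) -> str | None:
    fields = dict(
        kv.split("=", 1) for kv in attr_col.strip().split(";") if "=" in kv
    )
    for key in ("Name", "gene_name", "gene_id", "ID"):
        if key in fields:
            return fields[key]
    return None


# ------------------------------------------------------------------ tables

_WINDOW_COLUMNS = [
    "chrom", "start", "end", "n_sites", "truncated", "pi_ref", "pi_focal",
    "pi_ratio", "pi_ratio_log2", "fst", "tajima_ref", "tajima_focal", "dxy",
    "rankable",
]


def _fmt(x) -> str:
    if x is None:
        return "NA"
    if isinstance(x, (bool, np.bool_)):
        return "1" if x else "0"
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    xf = float(x)
    if np.isnan(xf):
        return "NA"
    return format(xf, ".10g")


def write_window_table(rows: Iterable, path: str | Path) -> None:
    """Write window statistics as a TSV with an ``NA`` missing policy.

    ``rows`` is an iterable of :class:`introscan.winstats.WindowStats`.
    Output is byte-stable for identical input.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(_WINDOW_COLUMNS) + "\n")
        for w in rows:
            iv = w.interval
            vals = [
                iv.chrom, iv.start, iv.end, w.n_sites,
                bool(iv.attributes.get("truncated", False)),
                w.pi_ref, w.pi_focal, w.pi_ratio, w.pi_ratio_log2, w.fst,
                w.tajima_ref, w.tajima_focal, w.dxy, w.rankable,
            ]
            fh.write("\t".join(v if isinstance(v, str) else _fmt(v) for v in vals))
            fh.write("\n")


def read_window_table(path: str | Path) -> pd.DataFrame:
    """Read a window TSV written by :func:`write_window_table`."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    df["truncated"] = df["truncated"].astype(bool)
    df["rankable"] = df["rankable"].astype(bool)
    return df


def write_bed(regions: Iterable, path: str | Path) -> None:
    """Write regions as BED (chrom, start, end, name, score).

    Accepts :class:`GenomicInterval` (name/score read from attributes) or
    any object with ``chrom``/``start``/``end`` and optional ``name``,
    ``score`` attributes.
    """
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            if isinstance(r, GenomicInterval):
                name = r.attributes.get("name", f"region_{i + 1}")
                score = r.attributes.get("score", 0.0)
            else:
                name = getattr(r, "name", f"region_{i + 1}")
                score = getattr(r, "score", 0.0)
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t{_fmt(float(score))}\n"
            )


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED file back into intervals (name/score into attributes)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            attrs: dict = {}
            if len(parts) > 3:
                attrs["name"] = parts[3]
            if len(parts) > 4:
                attrs["score"] = float(parts[4])
            out.append(
                GenomicInterval(parts[0], int(parts[1]), int(parts[2]), attrs)
            )
    return out
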