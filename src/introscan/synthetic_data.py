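"""Multi-population coalescent haplotype simulator with known ground truth.

The generator emulates the post-calling product of a resequencing study of
diverged cattle-like lineages plus a deeply split donor species: phased
biallelic SNP panels for a donor population, a recipient carrying
donor-derived tracts, and control lineages, with optional locally swept
regions.

Model: per-locus Hudson coalescent without migration.  Within each
population, ``k`` lineages coalesce at rate ``k(k-1)/2`` per ``2*N_e``
generations; populations merge (backward in time) at the configured split
times.  Mutations follow the infinite-sites model: the per-locus count is
Poisson with mean ``(theta_locus / 2) * T_total`` where ``T_total`` is the
total branch length in units of ``2*N_ref`` generations, each mutation
lands on a branch with probability proportional to its length, at a unique
uniform bp position.  There is no recombination within a locus and free
recombination between loci; loci are tiled left-to-right into chromosomes.

Introgression and sweeps are deterministic overlays applied after the
neutral simulation, with their coordinates reported in a :class:`TruthSet`
so recovery can be scored against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .panel import MISSING, GenomicInterval, HaplotypePanel, IBDSegment

__all__ = [
    "DemographyConfig",
    "TruthSet",
    "IntrogressionTract",
    "SweepRegion",
    "RecoverySummary",
    "simulate_locus",
    "simulate_genome",
    "inject_introgression",
    "inject_sweep",
    "admix_population",
    "evaluate_recovery",
    "truth_ibd_segments",
    "introgression_demography",
    "sweep_demography",
    "single_population_demography",
]


# ----------------------------------------------------------------- config

@dataclass(frozen=True)
class DemographyConfig:
    """Demography + mutation parameters for the per-locus coalescent.

    ``samples`` maps population label to haploid sample size (must be even:
    haplotypes are paired into diploid individuals).  ``merges`` is the
    split tree as backward-in-time merge events ``(time_generations,
    (child_pops...), parent_pop)``, sorted by time; the last event creates
    the root population.  ``theta_locus`` is ``4 * N_ref * mu * L`` with
    ``N_ref`` the effective size of the root population.
    """

    samples: dict[str, int]
    ne: dict[str, float]
    merges: tuple[tuple[float, tuple[str, ...], str], ...]
    theta_locus: float
    locus_length: int
    loci_per_chrom: int
    n_chroms: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValueError("at least one sampled population required")
        for pop, n in self.samples.items():
            if n < 2 or n % 2:
                raise ValueError(
                    f"haploid sample size for {pop!r} must be even and >= 2"
                )
        if self.theta_locus <= 0:
            raise ValueError("theta_locus must be > 0")
        if self.locus_length <= 0 or self.loci_per_chrom <= 0 or self.n_chroms <= 0:
            raise ValueError("locus/chromosome dimensions must be positive")
        # merge tree consistency: every sampled pop merges into a single root
        active = set(self.samples)
        last_t = 0.0
        for t, children, parent in self.merges:
            if t <= 0 or t < last_t:
                raise ValueError("merge times must be positive and sorted")
            last_t = t
            for c in children:
                if c not in active:
                    raise ValueError(f"merge child {c!r} not active at t={t}")
                active.discard(c)
            if parent in active:
                raise ValueError(f"merge parent {parent!r} already active")
            active.add(parent)
        if len(active) != 1:
            raise ValueError(
                f"split tree must resolve to one root, got {sorted(active)}"
            )
        for pop in set(self.samples) | {p for _, _, p in self.merges}:
            if pop not in self.ne or self.ne[pop] <= 0:
                raise ValueError(f"missing/invalid N_e for population {pop!r}")

    @property
    def root(self) -> str:
        return self.merges[-1][2] if self.merges else next(iter(self.samples))

    @property
    def n_ref(self) -> float:
        """Reference size scaling theta: N_e of the root population."""
        return self.ne[self.root]

    @property
    def n_haplotypes(self) -> int:
        return sum(self.samples.values())

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.locus_length * self.loci_per_chrom for c in self.chrom_names}

    def sample_layout(self) -> tuple[list[str], dict[str, str]]:
        """Sample ids (two haplotypes each, population-blocked) and popmap."""
        sample_ids: list[str] = []
        popmap: dict[str, str] = {}
        for pop, n in self.samples.items():
            for i in range(n // 2):
                sid = f"{pop}_{i + 1}"
                sample_ids.append(sid)
                popmap[sid] = pop
        return sample_ids, popmap


# -------------------------------------------------------------- truth set

@dataclass(frozen=True)
class IntrogressionTract:
    chrom: str
    start: int
    end: int
    recipient_haps: tuple[int, ...]
    donor_hap: int

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


@dataclass(frozen=True)
class SweepRegion:
    chrom: str
    start: int
    end: int
    population: str
    intensity: float

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


@dataclass
class TruthSet:
    """Simulator-emitted ground truth for recovery evaluation."""

    tracts: list[IntrogressionTract] = field(default_factory=list)
    sweeps: list[SweepRegion] = field(default_factory=list)

    def tract_intervals(self) -> list[GenomicInterval]:
        return [t.interval for t in self.tracts]

    def sweep_intervals(self) -> list[GenomicInterval]:
        return [s.interval for s in self.sweeps]


# ------------------------------------------------------------ coalescent

def _simulate_genealogy(config: DemographyConfig, rng: np.random.Generator):
    """Simulate one genealogy; return (branches, total_length_generations).

    ``branches`` is a list of ``(leaf_indices, length_in_generations)`` for
    every non-root branch; leaf indices follow the population-blocked
    haplotype layout of :meth:`DemographyConfig.sample_layout`.
    """
    # node = list of descendant leaf indices; per-population lineage pools
    pools: dict[str, list[list[int]]] = {}
    node_time: dict[int, float] = {}
    next_leaf = 0
    nodes: list[list[int]] = []
    for pop, n in config.samples.items():
        pools[pop] = []
        for _ in range(n):
            nodes.append([next_leaf])
            node_time[len(nodes) - 1] = 0.0
            pools[pop].append(len(nodes) - 1)
            next_leaf += 1

    branches: list[tuple[list[int], float]] = []
    pending = list(config.merges)
    t = 0.0
    n_live = sum(len(v) for v in pools.values())
    while n_live > 1:
        rates = {
            pop: len(lin) * (len(lin) - 1) / (4.0 * config.ne[pop])
            for pop, lin in pools.items()
            if len(lin) >= 2
        }
        total = sum(rates.values())
        t_next_merge = pending[0][0] if pending else np.inf
        if total == 0.0:
            wait = np.inf
        else:
            wait = rng.exponential(1.0 / total)
        if t + wait >= t_next_merge:
            # population merge event
            t_ev, children, parent = pending.pop(0)
            t = t_ev
            merged: list[int] = []
            for c in children:
                merged.extend(pools.pop(c, []))
            merged.extend(pools.pop(parent, []))
            pools[parent] = merged
            continue
        t += wait
        # pick population proportional to its coalescence rate
        u = rng.random() * total
        acc = 0.0
        for pop, rate in rates.items():
            acc += rate
            if u < acc:
                break
        lin = pools[pop]
        i, j = rng.choice(len(lin), size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        nj = lin.pop(j)
        ni = lin.pop(i)
        branches.append((nodes[ni], t - node_time[ni]))
        branches.append((nodes[nj], t - node_time[nj]))
        nodes.append(nodes[ni] + nodes[nj])
        node_time[len(nodes) - 1] = t
        lin.append(len(nodes) - 1)
        n_live -= 1
    total_length = sum(b for _, b in branches)
    return branches, total_length


def simulate_locus(
    config: DemographyConfig,
    locus_index: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one locus: (1-based positions within locus, allele matrix).

    Positions lie in ``[1, locus_length]`` before any tiling offset; the
    allele matrix is ``(n_sites, n_haplotypes)`` of {0, 1} with derived
    allele 1 for the descendants of each mutated branch.  Infinite sites:
    position collisions are resampled, keeping every site biallelic.
    """
    del locus_index  # loci are exchangeable; index kept for interface clarity
    branches, total_gen = _simulate_genealogy(config, rng)
    t_2n = total_gen / (2.0 * config.n_ref)
    n_mut = int(rng.poisson(0.5 * config.theta_locus * t_2n))
    n_hap = config.n_haplotypes
    if n_mut == 0:
        return (
            np.empty(0, dtype=np.int64),
            np.empty((0, n_hap), dtype=np.int8),
        )
    lengths = np.array([b for _, b in branches])
    cum = np.cumsum(lengths)
    used: set[int] = set()
    muts: list[tuple[int, list[int]]] = []
    for _ in range(n_mut):
        b = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
        b = min(b, len(branches) - 1)
        while True:
            p = int(rng.integers(1, config.locus_length + 1))
            if p not in used:
                used.add(p)
                break
        muts.append((p, branches[b][0]))
    muts.sort(key=lambda m: m[0])
    positions = np.array([m[0] for m in muts], dtype=np.int64)
    mat = np.zeros((len(muts), n_hap), dtype=np.int8)
    for row, (_, leaves) in enumerate(muts):
        mat[row, leaves] = 1
    return positions, mat


def simulate_genome(
    config: DemographyConfig,
    rng: np.random.Generator | None = None,
) -> HaplotypePanel:
    """Simulate a full panel: independent loci tiled into chromosomes.

    Locus ``i`` of a chromosome occupies ``[i*L, (i+1)*L)``; its site
    positions are offset accordingly.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sample_ids, popmap = config.sample_layout()
    positions: dict[str, np.ndarray] = {}
    alleles: dict[str, np.ndarray] = {}
    locus_counter = 0
    for chrom in config.chrom_names:
        pos_parts: list[np.ndarray] = []
        mat_parts: list[np.ndarray] = []
        for i in range(config.loci_per_chrom):
            p, m = simulate_locus(config, locus_counter, rng)
            locus_counter += 1
            if len(p):
                pos_parts.append(p + i * config.locus_length)
                mat_parts.append(m)
        positions[chrom] = (
            np.concatenate(pos_parts)
            if pos_parts
            else np.empty(0, dtype=np.int64)
        )
        alleles[chrom] = (
            np.vstack(mat_parts)
            if mat_parts
            else np.empty((0, config.n_haplotypes), dtype=np.int8)
        )
    panel = HaplotypePanel(
        chrom_names=config.chrom_names,
        chrom_lengths=config.chrom_lengths,
        positions=positions,
        alleles=alleles,
        sample_ids=sample_ids,
        popmap=popmap,
        ref_alleles={c: np.full(len(positions[c]), "A", dtype="U1") for c in config.chrom_names},
        alt_alleles={c: np.full(len(positions[c]), "C", dtype="U1") for c in config.chrom_names},
    )
    panel.validate()
    return panel


# --------------------------------------------------------------- overlays

def _merge_intervals(
    intervals: list[tuple[str, int, int]]
) -> list[tuple[str, int, int]]:
    out: list[tuple[str, int, int]] = []
    for chrom, start, end in sorted(intervals):
        if out and out[-1][0] == chrom and start <= out[-1][2]:
            out[-1] = (chrom, out[-1][1], max(out[-1][2], end))
        else:
            out.append((chrom, start, end))
    return out


def inject_introgression(
    panel: HaplotypePanel,
    donor: str,
    recipient: str,
    rng: np.random.Generator,
    n_tracts: int = 10,
    tract_length: int | tuple[int, int] = 200_000,
    haps_per_tract: int = 3,
    tracts: Sequence[GenomicInterval] | None = None,
) -> tuple[HaplotypePanel, TruthSet]:
    """Copy donor haplotype tracts onto recipient haplotypes.

    Tract intervals are either supplied explicitly or placed uniformly at
    random (chromosomes weighted by length); overlapping requested tracts
    are merged before copying so each base is copied once.  For each tract
    one donor haplotype is chosen and copied onto ``haps_per_tract``
    distinct recipient haplotypes over every site in the tract; sites
    outside tracts are untouched.  Returns a new panel and the truth set.
    """
    donor_haps = panel.hap_indices(donor)
    recip_haps = panel.hap_indices(recipient)
    if len(donor_haps) == 0:
        raise ValueError(f"donor population {donor!r} is empty")
    if len(recip_haps) < haps_per_tract:
        raise ValueError("fewer recipient haplotypes than haps_per_tract")

    raw: list[tuple[str, int, int]] = []
    if tracts is not None:
        for iv in tracts:
            if iv.end > panel.chrom_lengths[iv.chrom]:
                raise ValueError(f"tract {iv} exceeds chromosome bounds")
            raw.append((iv.chrom, iv.start, iv.end))
    else:
        chroms = panel.chrom_names
        weights = np.array([panel.chrom_lengths[c] for c in chroms], dtype=float)
        weights /= weights.sum()
        for _ in range(n_tracts):
            if isinstance(tract_length, tuple):
                tl = int(rng.integers(tract_length[0], tract_length[1] + 1))
            else:
                tl = int(tract_length)
            chrom = chroms[int(rng.choice(len(chroms), p=weights))]
            clen = panel.chrom_lengths[chrom]
            if tl > clen:
                raise ValueError(f"tract length {tl} exceeds chromosome {chrom}")
            start = int(rng.integers(0, clen - tl + 1))
            raw.append((chrom, start, start + tl))

    out = panel.copy()
    truth = TruthSet()
    for chrom, start, end in _merge_intervals(raw):
        d = int(donor_haps[rng.integers(len(donor_haps))])
        rs = rng.choice(recip_haps, size=haps_per_tract, replace=False)
        lo, hi = out.site_range(chrom, start, end)
        for r in sorted(int(x) for x in rs):
            out.alleles[chrom][lo:hi, r] = out.alleles[chrom][lo:hi, d]
        truth.tracts.append(
            IntrogressionTract(
                chrom=chrom, start=start, end=end,
                recipient_haps=tuple(sorted(int(x) for x in rs)),
                donor_hap=d,
            )
        )
    return out, truth


def inject_sweep(
    panel: HaplotypePanel,
    region: GenomicInterval,
    population: str,
    theta_recovery: float,
    rng: np.random.Generator,
    locus_length: int = 20_000,
) -> tuple[HaplotypePanel, TruthSet]:
    """Overlay a hard selective sweep (star genealogy) on one region.

    Within the region every haplotype of the target population is replaced
    by a copy of one randomly chosen sweeping haplotype; each haplotype
    then receives new singleton mutations, Poisson with mean
    ``theta_recovery`` per ``locus_length`` of region, at fresh positions
    (post-sweep mutational recovery).  The region then shows reduced
    within-group diversity, negative Tajima's D and elevated FST against
    other populations.  Other populations are untouched at pre-existing
    sites; recovery singletons are ancestral (0) in every other haplotype.
    """
    if region.chrom not in panel.chrom_lengths:
        raise ValueError(f"unknown chromosome {region.chrom!r}")
    if region.end > panel.chrom_lengths[region.chrom]:
        raise ValueError(f"sweep region {region} exceeds chromosome bounds")
    haps = panel.hap_indices(population)
    if len(haps) == 0:
        raise ValueError(f"target population {population!r} is empty")

    out = panel.copy()
    chrom = region.chrom
    lo, hi = out.site_range(chrom, region.start, region.end)
    sweeper = int(haps[rng.integers(len(haps))])
    swept_column = out.alleles[chrom][lo:hi, sweeper].copy()
    for h in haps:
        out.alleles[chrom][lo:hi, int(h)] = swept_column

    # post-sweep recovery singletons at fresh infinite-sites positions
    lam = theta_recovery * region.length / locus_length
    used = set(int(p) for p in out.positions[chrom])
    new_sites: list[tuple[int, int]] = []  # (position, haplotype column)
    for h in haps:
        for _ in range(int(rng.poisson(lam))):
            while True:
                p = int(rng.integers(region.start + 1, region.end + 1))
                if p not in used:
                    used.add(p)
                    break
            new_sites.append((p, int(h)))
    if new_sites:
        new_sites.sort()
        pos = out.positions[chrom]
        mat = out.alleles[chrom]
        add_pos = np.array([p for p, _ in new_sites], dtype=np.int64)
        add_rows = np.zeros((len(new_sites), out.n_haplotypes), dtype=np.int8)
        for k, (_, h) in enumerate(new_sites):
            add_rows[k, h] = 1
        insert_at = np.searchsorted(pos, add_pos)
        out.positions[chrom] = np.insert(pos, insert_at, add_pos)
        out.alleles[chrom] = np.insert(mat, insert_at, add_rows, axis=0)
        if out.ref_alleles is not None:
            out.ref_alleles[chrom] = np.insert(
                out.ref_alleles[chrom], insert_at, np.full(len(add_pos), "A")
            )
        if out.alt_alleles is not None:
            out.alt_alleles[chrom] = np.insert(
                out.alt_alleles[chrom], insert_at, np.full(len(add_pos), "C")
            )
    out.validate()
    truth = TruthSet(
        sweeps=[
            SweepRegion(
                chrom=chrom, start=region.start, end=region.end,
                population=population, intensity=theta_recovery,
            )
        ]
    )
    return out, truth


def admix_population(
    panel: HaplotypePanel,
    target: str,
    sources: Sequence[str],
    rng: np.random.Generator,
    locus_length: int,
    proportions: Sequence[float] | None = None,
) -> HaplotypePanel:
    """Rebuild a target population as a per-locus mosaic of source copies.

    For every locus tile ``[i*L, (i+1)*L)`` each target haplotype is
    replaced by a copy of a random haplotype from a source population
    chosen with the given proportions (default equal).  Emulates admixture
    with free recombination between loci; used for f3-test fixtures.
    """
    if proportions is None:
        proportions = [1.0 / len(sources)] * len(sources)
    props = np.asarray(proportions, dtype=float)
    props = props / props.sum()
    tgt = panel.hap_indices(target)
    src_haps = [panel.hap_indices(s) for s in sources]
    out = panel.copy()
    for chrom in out.chrom_names:
        clen = out.chrom_lengths[chrom]
        for start in range(0, clen, locus_length):
            lo, hi = out.site_range(chrom, start, min(start + locus_length, clen))
            if hi == lo:
                continue
            for h in tgt:
                s = int(rng.choice(len(sources), p=props))
                d = int(src_haps[s][rng.integers(len(src_haps[s]))])
                out.alleles[chrom][lo:hi, int(h)] = panel.alleles[chrom][lo:hi, d]
    return out


# ----------------------------------------------------------- evaluation

@dataclass(frozen=True)
class RecoverySummary:
    """Window-level confusion summary plus bp-level Jaccard."""

    sensitivity: float | None
    false_positive_rate: float | None
    jaccard_bp: float
    n_truth_windows: int
    n_flagged_windows: int
    n_true_positive_windows: int
    n_false_positive_windows: int
    n_windows: int


def _union_bp(intervals: Iterable[GenomicInterval]) -> dict[str, list[tuple[int, int]]]:
    per: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        per.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom, ivs in per.items():
        merged: list[tuple[int, int]] = []
        for s, e in sorted(ivs):
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        out[chrom] = merged
    return out


def evaluate_recovery(
    truth: Sequence[GenomicInterval],
    called: Sequence[GenomicInterval],
    windows: Sequence[GenomicInterval],
) -> RecoverySummary:
    """Score called regions against truth intervals at window resolution.

    A window is truth-overlapping / flagged when it overlaps (>= 1 bp) any
    truth / called interval.  Sensitivity = flagged truth windows over all
    truth windows; FPR = flagged non-truth windows over all non-truth
    windows; a bp-level Jaccard of the two merged interval unions is also
    reported.
    """
    def overlaps_any(w: GenomicInterval, ivs: Sequence[GenomicInterval]) -> bool:
        return any(w.overlaps(iv) for iv in ivs)

    n_truth = n_flag = tp = fp = 0
    for w in windows:
        is_truth = overlaps_any(w, truth)
        is_flag = overlaps_any(w, called)
        n_truth += is_truth
        n_flag += is_flag
        tp += is_truth and is_flag
        fp += is_flag and not is_truth
    n_non_truth = len(windows) - n_truth
    sens = tp / n_truth if n_truth else None
    fpr = fp / n_non_truth if n_non_truth else None

    tu = _union_bp(truth)
    cu = _union_bp(called)
    inter = 0
    for chrom in set(tu) & set(cu):
        ti = tu[chrom]
        for s, e in cu[chrom]:
            for ts, te in ti:
                inter += max(0, min(e, te) - max(s, ts))
    t_bp = sum(e - s for ivs in tu.values() for s, e in ivs)
    c_bp = sum(e - s for ivs in cu.values() for s, e in ivs)
    union = t_bp + c_bp - inter
    jac = inter / union if union else 1.0
    return RecoverySummary(
        sensitivity=sens,
        false_positive_rate=fpr,
        jaccard_bp=jac,
        n_truth_windows=n_truth,
        n_flagged_windows=n_flag,
        n_true_positive_windows=tp,
        n_false_positive_windows=fp,
        n_windows=len(windows),
    )


def truth_ibd_segments(truth: TruthSet) -> list[IBDSegment]:
    """Expand introgression tracts into donor×recipient IBD segments."""
    segs: list[IBDSegment] = []
    for t in truth.tracts:
        for r in t.recipient_haps:
            a, b = (t.donor_hap, r) if t.donor_hap < r else (r, t.donor_hap)
            segs.append(
                IBDSegment(hap_a=a, hap_b=b, chrom=t.chrom, start=t.start, end=t.end)
            )
    return segs


# ------------------------------------------------------- default scenarios

#: mutation rate used to set theta defaults (per bp per generation)
MUTATION_RATE = 1.26e-8
#: default effective population size for all lineages
DEFAULT_NE = 10_000.0


def introgression_demography(
    seed: int | None = None,
    loci_per_chrom: int = 1000,
    locus_length: int = 20_000,
) -> DemographyConfig:
    """Default donor/recipient/control scenario for the rIBD scan.

    6 donor + 3 recipient + 24 control diploids; the recipient/control
    (taurine/indicine-like) split is 2,000 generations before sampling and
    the donor (yak-like outgroup) split 40,000 generations, a desk-scale
    reduction of the cattle/yak history.  theta_locus = 4*N_ref*mu*L.
    """
    theta = 4.0 * DEFAULT_NE * MUTATION_RATE * locus_length
    return DemographyConfig(
        samples={"donor": 12, "recipient": 6, "control": 48},
        ne={
            "donor": DEFAULT_NE,
            "recipient": DEFAULT_NE,
            "control": DEFAULT_NE,
            "cattle_anc": DEFAULT_NE,
            "root": DEFAULT_NE,
        },
        merges=(
            (2_000.0, ("recipient", "control"), "cattle_anc"),
            (40_000.0, ("cattle_anc", "donor"), "root"),
        ),
        theta_locus=theta,
        locus_length=locus_length,
        loci_per_chrom=loci_per_chrom,
        seed=seed,
    )


def sweep_demography(
    seed: int | None = None,
    loci_per_chrom: int = 1000,
    locus_length: int = 10_000,
) -> DemographyConfig:
    """Two-group (extreme/non-extreme environment) scenario for sweep scans.

    15 + 15 diploids split 400 generations ago (weak background
    differentiation so genealogies are largely shared and the pi-ratio
    baseline is tight)."""
    theta = 4.0 * DEFAULT_NE * MUTATION_RATE * locus_length
    return DemographyConfig(
        samples={"extreme": 30, "nonextreme": 30},
        ne={"extreme": DEFAULT_NE, "nonextreme": DEFAULT_NE, "root": DEFAULT_NE},
        merges=((400.0, ("extreme", "nonextreme"), "root"),),
        theta_locus=theta,
        locus_length=locus_length,
        loci_per_chrom=loci_per_chrom,
        seed=seed,
    )


def single_population_demography(
    n_haplotypes: int,
    theta_locus: float,
    loci_per_chrom: int,
    locus_length: int = 10_000,
    seed: int | None = None,
) -> DemographyConfig:
    """Single constant-size population; used for neutral calibration."""
    return DemographyConfig(
        samples={"pop": n_haplotypes},
        ne={"pop": DEFAULT_NE},
        merges=(),
        theta_locus=theta_locus,
        locus_length=locus_length,
        loci_per_chrom=loci_per_chrom,
        seed=seed,
    )
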