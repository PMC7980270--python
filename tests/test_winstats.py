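"""Windowed statistics vs. independent pair-loop and formula oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from helpers import build_panel, random_panel
from oracles import (
    dxy_sum_pair_loop,
    pi_sum_pair_loop,
    tajima_from_matrix,
    wc_abc_direct,
)
from introscan import winstats as ws
from introscan.panel import GenomicInterval, WindowSpec


TWO_POPS = {"a1": "P1", "a2": "P1", "b1": "P2", "b2": "P2"}


def two_pop_panel(mat, **kw):
    return build_panel(mat, samples=["a1", "a2", "b1", "b2"], popmap=TWO_POPS, **kw)


# -------------------------------------------------------------------- pi

@pytest.mark.parametrize(
    "row,expected",
    [
        ([1, 1, 0, 0], 2 / 3),   # doubleton among four haplotypes
        ([0, 0, 0, 0], 0.0),     # monomorphic
        ([1, 0, -1, -1], 1.0),   # n = 2 differing haplotypes
    ],
)
def test_site_pi_formula(row, expected):
    panel = build_panel([row], samples=["s0", "s1"])
    assert ws.site_pi(panel, "pop", "chr1", 0) == pytest.approx(expected, abs=1e-12)


def test_window_pi_per_bp():
    panel = build_panel([[1, 1, 0, 0]], positions=[50], length=100)
    iv = GenomicInterval("chr1", 0, 100)
    assert ws.window_pi(panel, "pop", iv) == pytest.approx(2 / 3 / 100, rel=1e-12)
    empty = GenomicInterval("chr1", 60, 100)
    assert ws.window_pi(panel, "pop", empty) == 0.0


def test_window_pi_matches_pair_loop_oracle(rng):
    for _ in range(10):
        panel = random_panel(rng, n_samples=10, n_sites=80, missing_frac=0.1,
                             n_pops=1)
        iv = GenomicInterval("chr1", 0, panel.chrom_lengths["chr1"])
        mine = ws.window_pi(panel, "pop0", iv)
        oracle = pi_sum_pair_loop(panel.alleles["chr1"]) / iv.length
        assert mine == pytest.approx(oracle, rel=1e-12, abs=1e-15)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_pi_invariant_to_haplotype_permutation(seed):
    r = np.random.default_rng(seed)
    panel = random_panel(r, n_samples=6, n_sites=30, n_pops=1)
    iv = GenomicInterval("chr1", 0, panel.chrom_lengths["chr1"])
    base = ws.window_pi(panel, "pop0", iv)
    perm = r.permutation(12)
    panel.alleles["chr1"] = panel.alleles["chr1"][:, perm]
    assert ws.window_pi(panel, "pop0", iv) == pytest.approx(base, rel=1e-12)


# ------------------------------------------------------------------- FST

def test_wc_site_fixed_difference_is_one():
    panel = two_pop_panel([[1, 1, 1, 1, 0, 0, 0, 0]])
    comp = ws.wc_fst_site(panel, {"g1": "P1", "g2": "P2"}, "chr1", 0)
    assert comp.a == pytest.approx(0.5, abs=1e-12)
    assert comp.b == pytest.approx(0.0, abs=1e-12)
    assert comp.c == pytest.approx(0.0, abs=1e-12)
    assert comp.fst == pytest.approx(1.0, abs=1e-12)


def test_wc_site_identical_groups_nonpositive_a():
    panel = two_pop_panel([[1, 0, 1, 0, 1, 0, 1, 0]])
    comp = ws.wc_fst_site(panel, {"g1": "P1", "g2": "P2"}, "chr1", 0)
    assert comp.s2 == pytest.approx(0.0, abs=1e-12)
    assert comp.a <= 0.0


def test_wc_components_match_dual_implementation(rng):
    """Vectorised components equal a separately coded scalar derivation."""
    for _ in range(20):
        panel = random_panel(rng, n_samples=8, n_sites=1, missing_frac=0.15)
        mat = panel.alleles["chr1"][0]
        groups = [[], []]
        for i, s in enumerate(panel.sample_ids):
            g = 0 if panel.popmap[s] == "pop0" else 1
            groups[g].append((int(mat[2 * i]), int(mat[2 * i + 1])))
        oracle = wc_abc_direct(groups)
        try:
            comp = ws.wc_fst_site(panel, {"x": "pop0", "y": "pop1"}, "chr1", 0)
        except ValueError:
            assert oracle is None
            continue
        assert oracle is not None
        a, b, c = oracle
        assert comp.a == pytest.approx(a, rel=1e-12, abs=1e-12)
        assert comp.b == pytest.approx(b, rel=1e-12, abs=1e-12)
        assert comp.c == pytest.approx(c, rel=1e-12, abs=1e-12)


def test_window_fst_reductions():
    panel = two_pop_panel(
        [[1, 1, 1, 1, 0, 0, 0, 0], [1, 1, 1, 1, 0, 0, 0, 0]]
    )
    iv = GenomicInterval("chr1", 0, 100)
    assert ws.window_fst(panel, {"a": "P1", "b": "P2"}, iv) == pytest.approx(1.0)
    # single usable site reduces to a / (a+b+c)
    single = two_pop_panel([[1, 0, 1, 1, 0, 0, 1, 0]])
    comp = ws.wc_fst_site(single, {"a": "P1", "b": "P2"}, "chr1", 0)
    assert ws.window_fst(single, {"a": "P1", "b": "P2"}, iv) == pytest.approx(
        comp.a / (comp.a + comp.b + comp.c), rel=1e-12
    )


def test_window_fst_label_swap_invariant(rng):
    panel = random_panel(rng, n_samples=10, n_sites=60)
    iv = GenomicInterval("chr1", 0, panel.chrom_lengths["chr1"])
    f1 = ws.window_fst(panel, {"a": "pop0", "b": "pop1"}, iv)
    f2 = ws.window_fst(panel, {"a": "pop1", "b": "pop0"}, iv)
    assert f1 == pytest.approx(f2, rel=1e-12)


def test_panmictic_split_fst_small(rng):
    """A random split of one population gives |FST| < 0.05 at n=20/20."""
    mat = (rng.random((500, 80)) < rng.random((500, 1))).astype(np.int8)
    samples = [f"s{i}" for i in range(40)]
    popmap = {s: ("A" if i < 20 else "B") for i, s in enumerate(samples)}
    panel = build_panel(mat, samples=samples, popmap=popmap)
    iv = GenomicInterval("chr1", 0, panel.chrom_lengths["chr1"])
    f = ws.window_fst(panel, {"a": "A", "b": "B"}, iv)
    assert abs(f) < 0.05


# --------------------------------------------------------------- Tajima D

def test_tajima_micro_examples_match_direct_oracle():
    """n=4 doubleton and singleton windows hit the known D values."""
    iv = GenomicInterval("chr1", 0, 100)
    doubleton = build_panel([[1, 1, 0, 0]], samples=["s0", "s1"])
    parts = ws.tajimas_d(doubleton, "pop", iv)
    _, _, _, oracle = tajima_from_matrix(doubleton.alleles["chr1"])
    assert parts.d == pytest.approx(oracle, rel=1e-12)
    assert parts.d == pytest.approx(1.6329931618, rel=1e-9)
    assert parts.k_hat == pytest.approx(2 / 3, rel=1e-12)

    singleton = build_panel([[1, 0, 0, 0]], samples=["s0", "s1"])
    parts = ws.tajimas_d(singleton, "pop", iv)
    _, _, _, oracle = tajima_from_matrix(singleton.alleles["chr1"])
    assert parts.d == pytest.approx(oracle, rel=1e-12)
    assert parts.d == pytest.approx(-0.6123724357, rel=1e-9)
    assert parts.k_hat == pytest.approx(0.5, rel=1e-12)


def test_tajima_missing_policies():
    iv = GenomicInterval("chr1", 0, 100)
    mono = build_panel([[0, 0, 0, 0]], samples=["s0", "s1"])
    parts = ws.tajimas_d(mono, "pop", iv)
    assert parts.d is None and parts.reason == "S=0"
    small = build_panel([[1, 0]], samples=["s0"])
    parts = ws.tajimas_d(small, "pop", iv)
    assert parts.d is None and parts.reason == "n<4"


def test_tajima_sign_from_frequency_spectrum():
    """All-singleton window: D < 0; all-intermediate window: D > 0."""
    n = 10
    singles = np.zeros((8, 2 * n), dtype=np.int8)
    for i in range(8):
        singles[i, i] = 1
    panel = build_panel(singles, samples=[f"s{i}" for i in range(n)])
    iv = GenomicInterval("chr1", 0, 200)
    assert ws.tajimas_d(panel, "pop", iv).d < 0
    inter = np.zeros((8, 2 * n), dtype=np.int8)
    inter[:, :n] = 1
    panel = build_panel(inter, samples=[f"s{i}" for i in range(n)])
    assert ws.tajimas_d(panel, "pop", iv).d > 0


def test_tajima_matches_pair_count_oracle_random(rng):
    for _ in range(10):
        panel = random_panel(rng, n_samples=8, n_sites=50, missing_frac=0.1,
                             n_pops=1)
        iv = GenomicInterval("chr1", 0, panel.chrom_lengths["chr1"])
        parts = ws.tajimas_d(panel, "pop0", iv)
        n, s, k_hat, d = tajima_from_matrix(panel.alleles["chr1"])
        assert parts.s == s
        assert parts.k_hat == pytest.approx(k_hat, rel=1e-10, abs=1e-12)
        if d is None:
            assert parts.d is None
        else:
            assert parts.d == pytest.approx(d, rel=1e-10)


# ------------------------------------------------------------------- Dxy

def test_dxy_examples():
    iv = GenomicInterval("chr1", 0, 100)
    panel = two_pop_panel([[1, 1, 1, 1, 0, 0, 0, 0]])
    assert ws.dxy(panel, "P1", "P2", iv) == pytest.approx(0.01, rel=1e-12)
    panel = two_pop_panel([[0, 0, 0, 0, 0, 0, 0, 0]])
    assert ws.dxy(panel, "P1", "P2", iv) == 0.0


def test_dxy_matches_cross_pair_oracle(rng):
    for _ in range(10):
        panel = random_panel(rng, n_samples=10, n_sites=60, missing_frac=0.1)
        iv = GenomicInterval("chr1", 0, panel.chrom_lengths["chr1"])
        a = panel.alleles["chr1"][:, panel.hap_indices("pop0")]
        b = panel.alleles["chr1"][:, panel.hap_indices("pop1")]
        oracle = dxy_sum_pair_loop(a, b) / iv.length
        assert ws.dxy(panel, "pop0", "pop1", iv) == pytest.approx(
            oracle, rel=1e-12, abs=1e-15
        )


def test_dxy_of_population_halves_approximates_pi(rng):
    """Dxy between two halves of one population ~ its theta_pi."""
    mat = (rng.random((400, 40)) < 0.3).astype(np.int8)
    samples = [f"s{i}" for i in range(20)]
    popmap = {s: ("A" if i < 10 else "B") for i, s in enumerate(samples)}
    panel = build_panel(mat, samples=samples, popmap=popmap)
    iv = GenomicInterval("chr1", 0, panel.chrom_lengths["chr1"])
    d = ws.dxy(panel, "A", "B", iv)
    pi = ws.window_pi(panel, ["A", "B"], iv)
    assert d == pytest.approx(pi, rel=0.05)


# -------------------------------------------------------------- pi ratio

@pytest.mark.parametrize(
    "ref,focal,expected",
    [(0.002, 0.001, 2.0), (0.001, 0.0, None), (0.003, 0.003, 1.0)],
)
def test_pi_ratio(ref, focal, expected):
    ratio, log2 = ws.pi_ratio(ref, focal)
    if expected is None:
        assert ratio is None and log2 is None
    else:
        assert ratio == pytest.approx(expected)
        assert log2 == pytest.approx(np.log2(expected))


# ------------------------------------------------------------------ scan

def test_scan_window_count_matches_tiling(sweep_fixture):
    from introscan.panel import make_windows

    _, neutral, _, _ = sweep_fixture
    spec = WindowSpec(50_000, 10_000, 10)
    stats = ws.scan_windows(neutral, ["nonextreme"], ["extreme"], spec)
    assert len(stats) == len(make_windows(neutral.chrom_lengths, spec))


def test_scan_flags_swept_windows(sweep_fixture):
    """Swept windows exceed the genome median FST and pi-ratio."""
    _, _, swept, truth = sweep_fixture
    region = truth.sweeps[0].interval
    spec = WindowSpec(50_000, 10_000, 10)
    stats = ws.scan_windows(swept, ["nonextreme"], ["extreme"], spec)
    med_fst = np.median([w.fst for w in stats if w.fst is not None])
    med_ratio = np.median([w.pi_ratio for w in stats if w.pi_ratio is not None])
    inside = [
        w for w in stats
        if w.interval.overlaps(region) and region.start <= w.interval.start
        and w.interval.end <= region.end
    ]
    assert inside
    assert all(w.fst > med_fst for w in inside)
    assert all(w.pi_ratio is None or w.pi_ratio > med_ratio for w in inside)


def test_scan_neutral_d_mostly_moderate(sweep_fixture):
    """Neutral panel: fewer than 10% of windows show |D| > 2."""
    _, neutral, _, _ = sweep_fixture
    spec = WindowSpec(50_000, 50_000, 10)
    stats = ws.scan_windows(neutral, ["nonextreme"], ["extreme"], spec)
    dvals = [w.tajima_focal for w in stats if w.tajima_focal is not None]
    assert len(dvals) > 100
    assert np.mean(np.abs(dvals) > 2) < 0.10


def test_scan_rejects_tiny_groups(rng):
    panel = random_panel(rng, n_samples=3, n_sites=30)  # pop1 has one diploid
    with pytest.raises(ValueError, match="2 diploid"):
        ws.scan_windows(panel, ["pop0"], ["pop1"], WindowSpec(1000, 1000, 1))
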