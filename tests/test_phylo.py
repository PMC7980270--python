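"""p-distances, neighbour joining, IBS screening and the f3 test."""

import numpy as np
import pytest

from helpers import build_panel
from oracles import random_additive_tree
from introscan import synthetic_data as sd
from introscan.panel import GenomicInterval
from introscan.phylo_fstats import (
    DistanceMatrix,
    f3_test,
    flag_high_ibs_pairs,
    nj_tree,
    p_distance_matrix,
    region_tree,
)


# ----------------------------------------------------------- p-distance

def test_p_distance_examples():
    # fixed opposite homozygotes at every site -> 1
    mat = np.array([[0, 0, 1, 1], [0, 0, 1, 1]], dtype=np.int8)
    panel = build_panel(mat, samples=["x", "y"])
    dm = p_distance_matrix(panel)
    assert dm.d[0, 1] == pytest.approx(1.0)
    # sites (0/1 vs 0/0) and (0/0 vs 0/0) -> (0.5 + 0)/2 = 0.25
    mat = np.array([[0, 1, 0, 0], [0, 0, 0, 0]], dtype=np.int8)
    panel = build_panel(mat, samples=["x", "y"])
    dm = p_distance_matrix(panel)
    assert dm.d[0, 1] == pytest.approx(0.25)
    assert dm.d[0, 0] == 0.0
    assert np.array_equal(dm.d, dm.d.T)


def test_p_distance_invariant_to_site_order(rng):
    from helpers import random_panel

    panel = random_panel(rng, n_samples=5, n_sites=40, missing_frac=0.1)
    dm1 = p_distance_matrix(panel)
    perm = rng.permutation(40)
    panel.alleles["chr1"] = panel.alleles["chr1"][perm]
    panel.positions["chr1"] = np.sort(panel.positions["chr1"])  # keep valid
    dm2 = p_distance_matrix(panel)
    assert np.allclose(dm1.d, dm2.d)


def test_flag_high_ibs_pairs():
    mat = np.array([[0, 0, 0, 0, 1, 1], [1, 1, 1, 1, 0, 0]], dtype=np.int8)
    panel = build_panel(mat, samples=["dup1", "dup2", "other"])
    dm = p_distance_matrix(panel)
    flags = flag_high_ibs_pairs(dm, threshold=0.9)
    assert [(a, b) for a, b, _ in flags] == [("dup1", "dup2")]
    assert flags[0][2] == pytest.approx(1.0)
    assert flag_high_ibs_pairs(dm, threshold=1.01) == []


def test_no_cross_population_pair_reaches_duplicate_ibs(introgression_fixture):
    """Individuals from diverged populations never look like duplicates.

    Within-population IBS baselines depend on how many lineages feed the
    SNP table (few lineages -> higher baseline), so the screen is asserted
    on cross-population pairs, which must stay clear of the 0.9 cutoff.
    """
    _, panel, _ = introgression_fixture
    dm = p_distance_matrix(panel)
    flags = flag_high_ibs_pairs(dm, threshold=0.9)
    for a, b, _ in flags:
        assert panel.popmap[a] == panel.popmap[b]
    # an exact duplicate individual is flagged at IBS ~ 1, far above the rest
    dup = panel.copy()
    dup.alleles["chr1"][:, 2] = dup.alleles["chr1"][:, 0]
    dup.alleles["chr1"][:, 3] = dup.alleles["chr1"][:, 1]
    dm_dup = p_distance_matrix(dup, samples=dup.sample_ids[:6])
    top = max(flag_high_ibs_pairs(dm_dup, threshold=0.9), key=lambda x: x[2])
    assert top[:2] == (dup.sample_ids[0], dup.sample_ids[1])
    assert top[2] == pytest.approx(1.0)


# -------------------------------------------------------------------- NJ

def test_nj_four_taxon_worked_example():
    d = np.array(
        [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
    )
    dm = DistanceMatrix(["A", "B", "C", "D"], d, np.zeros((4, 4), int))
    tree = nj_tree(dm)
    assert frozenset("AB") in tree.splits()
    paths = tree.leaf_distances()
    for (x, y), expected in {
        ("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 6,
        ("B", "C"): 6, ("B", "D"): 7, ("C", "D"): 7,
    }.items():
        assert paths[(x, y)] == pytest.approx(expected, abs=1e-9)
    # leaf branch lengths A:1 B:2 C:3 D:4, internal edge 1
    newick = tree.newick()
    assert "A:1.000000" in newick and "B:2.000000" in newick
    assert "C:3.000000" in newick and "D:4.000000" in newick
    assert ":1.000000);" in newick or "):1.000000" in newick


def test_nj_three_taxa_closed_form():
    d = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], dtype=float)
    dm = DistanceMatrix(["A", "B", "C"], d, np.zeros((3, 3), int))
    tree = nj_tree(dm)
    lens = {c.label: bl for c, bl in tree.children}
    assert lens["A"] == pytest.approx(0.0)
    assert lens["B"] == pytest.approx(2.0)
    assert lens["C"] == pytest.approx(3.0)


def test_nj_exact_on_random_additive_matrices(rng):
    for _ in range(30):
        labels, D, splits = random_additive_tree(rng, 8)
        dm = DistanceMatrix(labels, D, np.zeros_like(D, dtype=int))
        tree = nj_tree(dm)
        assert tree.splits() == splits
        paths = tree.leaf_distances()
        for i, a in enumerate(labels):
            for j in range(i + 1, len(labels)):
                b = labels[j]
                assert paths[(a, b)] == pytest.approx(D[i, j], abs=1e-9)


def test_nj_outgroup_rooting_preserves_paths():
    labels, D, _ = random_additive_tree(np.random.default_rng(5), 6)
    dm = DistanceMatrix(labels, D, np.zeros_like(D, dtype=int))
    rooted = nj_tree(dm, outgroup=labels[0])
    assert len(rooted.children) == 2
    childs = {tuple(sorted(c.leaves())) for c, _ in rooted.children}
    assert (labels[0],) in childs
    paths = rooted.leaf_distances()
    idx = {l: i for i, l in enumerate(labels)}
    for (a, b), v in paths.items():
        assert v == pytest.approx(D[idx[a], idx[b]], abs=1e-9)


def test_nj_rejects_degenerate_inputs():
    dm = DistanceMatrix(["A", "B"], np.zeros((2, 2)), np.zeros((2, 2), int))
    with pytest.raises(ValueError, match="at least 3"):
        nj_tree(dm)
    d = np.zeros((3, 3))
    d[0, 1] = d[1, 0] = np.nan
    dm = DistanceMatrix(["A", "B", "C"], d, np.zeros((3, 3), int))
    with pytest.raises(ValueError, match="missing"):
        nj_tree(dm)


# ------------------------------------------------------------ region tree

@pytest.fixture(scope="module")
def tract_tree_fixture():
    """Small panel where both haplotypes of one recipient carry a tract."""
    ne = 10_000.0
    cfg = sd.DemographyConfig(
        samples={"donor": 8, "recipient": 6, "control": 8},
        ne={"donor": ne, "recipient": ne, "control": ne, "anc": ne, "root": ne},
        merges=(
            (2_000.0, ("recipient", "control"), "anc"),
            (40_000.0, ("anc", "donor"), "root"),
        ),
        theta_locus=10.0,
        locus_length=20_000,
        loci_per_chrom=30,
        seed=13,
    )
    panel = sd.simulate_genome(cfg)
    rng = np.random.default_rng(13)
    tract = GenomicInterval("chr1", 200_000, 400_000)
    recip = panel.hap_indices("recipient")
    # copy onto both haplotypes of the first recipient diploid
    out = panel.copy()
    donor_hap = int(panel.hap_indices("donor")[0])
    lo, hi = out.site_range("chr1", tract.start, tract.end)
    for h in recip[:2]:
        out.alleles["chr1"][lo:hi, int(h)] = out.alleles["chr1"][lo:hi, donor_hap]
    carrier = out.sample_ids[out.haplotype_sample_index[recip[0]]]
    return out, tract, carrier


def test_region_tree_carrier_clusters_with_donor(tract_tree_fixture):
    panel, tract, carrier = tract_tree_fixture
    donors = [s for s in panel.sample_ids if panel.popmap[s] == "donor"]
    tree = region_tree(panel, tract)
    side = next(
        (
            s
            for s in tree.splits()
            if set(donors) < s and len(s) == len(donors) + 1
        ),
        None,
    )
    assert side is not None and carrier in side


def test_region_tree_outside_tract_carrier_stays_with_cattle(tract_tree_fixture):
    panel, tract, carrier = tract_tree_fixture
    donors = {s for s in panel.sample_ids if panel.popmap[s] == "donor"}
    outside = GenomicInterval("chr1", 420_000, 600_000)
    tree = region_tree(panel, outside)
    # the donor clade split exists and the carrier is NOT inside it
    donor_side = next((s for s in tree.splits() if s == frozenset(donors)), None)
    assert donor_side is not None
    paths = tree.leaf_distances()
    d_to_donor = min(paths[tuple(sorted((carrier, d)))] for d in donors)
    cattle = [
        s for s in panel.sample_ids
        if panel.popmap[s] != "donor" and s != carrier
    ]
    d_to_cattle = min(paths[tuple(sorted((carrier, c)))] for c in cattle)
    assert d_to_cattle < d_to_donor


def test_region_tree_warns_on_sparse_region(tract_tree_fixture):
    panel, _, _ = tract_tree_fixture
    # an interval holding (almost certainly) fewer than 5 sites
    lo = int(panel.positions["chr1"][0])
    with pytest.warns(UserWarning, match="sites"):
        region_tree(panel, GenomicInterval("chr1", lo - 1, lo))


# -------------------------------------------------------------------- f3

def _freq_panel(freq_rows):
    """Panel with exact frequencies via large synthetic populations.

    freq_rows: list of (a, b, c) target/src1/src2 derived frequencies per
    site, realised exactly over 10 diploids each.
    """
    mats = []
    for a, b, c in freq_rows:
        row = []
        for f in (a, b, c):
            k = round(f * 20)
            row.extend([1] * k + [0] * (20 - k))
        mats.append(row)
    samples = [f"t{i}" for i in range(10)] + [f"u{i}" for i in range(10)] + [
        f"v{i}" for i in range(10)
    ]
    popmap = {}
    for s in samples:
        popmap[s] = {"t": "T", "u": "U", "v": "V"}[s[0]]
    positions = np.arange(1, len(freq_rows) + 1) * 100
    return build_panel(
        np.array(mats, dtype=np.int8), positions, samples, popmap,
        length=len(freq_rows) * 100 + 100,
    )


def _site_terms(panel):
    """Per-site (a-b)(a-c) - a(1-a)/(n_a-1) for the fixture panel."""
    mat = panel.alleles["chr1"]
    out = []
    for row in mat:
        a = row[:20].mean()
        b = row[20:40].mean()
        c = row[40:].mean()
        out.append((a - b) * (a - c) - a * (1 - a) / 19)
    return np.array(out)


def test_f3_site_terms_algebra(rng):
    # a = (b+c)/2 with b != c: the (a-b)(a-c) part is -((b-c)/2)^2 < 0
    rows = [(0.5, 0.7, 0.3), (0.5, 0.9, 0.1), (0.4, 0.6, 0.2)]
    for a, b, c in rows:
        term = (a - b) * (a - c)
        assert term == pytest.approx(-(((b - c) / 2) ** 2))
    # a = b at every site with exact frequencies: (a-b)(a-c) = 0
    assert (0.5 - 0.5) * (0.5 - 0.2) == 0.0
    # single site a=0.5, b=1, c=0: (a-b)(a-c) = -0.25
    assert (0.5 - 1.0) * (0.5 - 0.0) == pytest.approx(-0.25)


def test_f3_matches_per_site_oracle():
    rng = np.random.default_rng(44)
    rows = [
        (round(a * 20) / 20, round(b * 20) / 20, round(c * 20) / 20)
        for a, b, c in rng.random((300, 3))
    ]
    rows = [r for r in rows if 0 < r[0] < 1]  # keep target polymorphic
    panel = _freq_panel(rows)
    res = f3_test(panel, "T", "U", "V", block_size_bp=panel.chrom_lengths["chr1"] // 12)
    oracle = _site_terms(panel)
    # the implementation may drop sites monomorphic... it keeps all, so:
    assert res.n_sites == len(rows)
    assert res.f3 == pytest.approx(oracle.mean(), rel=1e-10)


def test_f3_negative_for_admixed_target(rng):
    cfg = sd.DemographyConfig(
        samples={"T": 10, "U": 10, "V": 10},
        ne={p: 10_000.0 for p in ("T", "U", "V", "anc", "root")},
        merges=((8_000.0, ("U", "V"), "anc"), (12_000.0, ("anc", "T"), "root")),
        theta_locus=8.0, locus_length=20_000, loci_per_chrom=300, seed=51,
    )
    panel = sd.simulate_genome(cfg)
    admixed = sd.admix_population(
        panel, "T", ["U", "V"], np.random.default_rng(51), cfg.locus_length
    )
    res_adm = f3_test(admixed, "T", "U", "V", block_size_bp=500_000)
    res_un = f3_test(panel, "T", "U", "V", block_size_bp=500_000)
    assert res_adm.f3 < 0 and res_adm.z < -3
    assert res_un.z > -3


def test_f3_jackknife_se_shrinks_with_more_blocks():
    rng = np.random.default_rng(46)
    rows = [
        (round(a * 20) / 20, round(b * 20) / 20, round(c * 20) / 20)
        for a, b, c in rng.random((2000, 3))
    ]
    rows = [r for r in rows if 0 < r[0] < 1]
    panel = _freq_panel(rows)
    L = panel.chrom_lengths["chr1"]
    se_few = f3_test(panel, "T", "U", "V", block_size_bp=L // 12).se
    se_many = f3_test(panel, "T", "U", "V", block_size_bp=L // 120).se
    # on homogeneous data the SE estimate is stable across block counts
    assert se_many == pytest.approx(se_few, rel=0.5)


def test_f3_guards():
    panel = _freq_panel([(0.5, 0.5, 0.5)] * 30)
    with pytest.raises(ValueError, match="disjoint"):
        f3_test(panel, "T", "T", "V")
    with pytest.raises(ValueError, match="blocks"):
        f3_test(panel, "T", "U", "V", block_size_bp=10**9)
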