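import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import introscan as isc
from introscan.errors import ConfigError
from introscan.popgen import jackknife_ratio, pattern_arrays

from _oracles import (
    brute_d,
    brute_fd,
    brute_jackknife,
    brute_site_frequencies,
)
from conftest import random_genotype_matrix


def _freqs(sites):
    p = np.array(sites, dtype=float)
    return isc.SiteFrequencies(p1=p[:, 0], p2=p[:, 1], p3=p[:, 2], p4=p[:, 3])


# ---------------------------------------------------------------------------
# derived frequencies


def _toy_geno(rows, groups):
    n_sites = len(rows)
    samples = [m for ms in groups.values() for m in ms]
    pos = np.arange(1, n_sites + 1) * 10
    return (
        isc.GenotypeMatrix(
            np.full(n_sites, "chr1", dtype=object), pos,
            np.full(n_sites, "A", dtype=object), np.full(n_sites, "G", dtype=object),
            np.array(rows, dtype=np.int8), tuple(samples),
        ),
        isc.PopulationMap(groups),
    )


def test_derived_frequency_counting_and_polarization():
    groups = {"p1": ["a", "b"], "p2": ["c", "d"], "p3": ["e", "f", "g"], "og": ["o"]}
    # site 1: outgroup homRef -> derived is ALT; p2 = {het, missing} -> 0.5
    # site 2: p3 = {homAlt, homAlt, het} -> 5/6
    rows = [
        [0, 0, 1, -1, 0, 0, 0, 0],
        [0, 0, 0, 0, 2, 2, 1, 0],
    ]
    geno, pops = _toy_geno(rows, groups)
    f = isc.derived_frequencies(geno, pops, "p1", "p2", "p3", "og")
    assert f.p2[0] == pytest.approx(0.5)
    assert f.p3[1] == pytest.approx(5 / 6)


def test_outgroup_tie_polarizes_toward_alt():
    groups = {"p1": ["a"], "p2": ["b"], "p3": ["c"], "og": ["o"]}
    rows = [[2, 2, 2, 1]]  # outgroup het: freq 0.5/0.5 tie
    geno, pops = _toy_geno(rows, groups)
    f = isc.derived_frequencies(geno, pops, "p1", "p2", "p3", "og")
    assert f.p1[0] == 1.0  # homAlt counted as derived => ALT chosen


def test_sites_with_uncalled_group_are_excluded_and_counted():
    groups = {"p1": ["a"], "p2": ["b"], "p3": ["c"], "og": ["o"]}
    rows = [[0, 1, 1, 0], [0, -1, 1, 0]]
    geno, pops = _toy_geno(rows, groups)
    f = isc.derived_frequencies(geno, pops, "p1", "p2", "p3", "og")
    assert f.n_sites == 1 and f.n_excluded == 1


def test_overlapping_groups_rejected():
    groups = {"p1": ["a"], "p2": ["b"], "p3": ["c"], "og": ["o"]}
    geno, pops = _toy_geno([[0, 0, 0, 0]], groups)
    with pytest.raises(ConfigError):
        isc.derived_frequencies(geno, pops, "p1", "p1", "p3", "og")


# ---------------------------------------------------------------------------
# D and f_d worked values


def test_d_statistic_worked_values():
    assert isc.d_statistic(_freqs([(0, 1, 1, 0)]))[0] == pytest.approx(1.0)
    D, sums = isc.d_statistic(_freqs([(0.2, 0.8, 0.6, 0.0)]))
    assert sums.sum_abba == pytest.approx(0.384)
    assert sums.sum_baba == pytest.approx(0.024)
    assert D == pytest.approx(0.36 / 0.408)  # 0.88235...
    assert D == pytest.approx(brute_d([(0.2, 0.8, 0.6, 0.0)]))


def test_d_is_zero_when_p1_equals_p2():
    sites = [(0.3, 0.3, 0.9, 0.1), (0.7, 0.7, 0.5, 0.0)]
    assert isc.d_statistic(_freqs(sites))[0] == pytest.approx(0.0)


def test_d_undefined_without_pattern_weight():
    D, _ = isc.d_statistic(_freqs([(0.5, 0.5, 0.0, 0.0)]))
    assert np.isnan(D)


def test_fd_worked_values():
    # single-site derivation: P_D = P2, denominator 0.512 - 0.032 = 0.48
    assert isc.fd_value(_freqs([(0.2, 0.8, 0.6, 0.0)])) == pytest.approx(0.75)
    # p2 == p3 with positive numerator -> f_d = 1
    assert isc.fd_value(_freqs([(0.1, 0.9, 0.9, 0.0)])) == pytest.approx(1.0)
    # non-positive ABBA excess floors at 0
    assert isc.fd_value(_freqs([(0.9, 0.1, 0.9, 0.0)])) == 0.0


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(*[st.floats(0, 1, allow_nan=False) for _ in range(4)]),
        min_size=1,
        max_size=20,
    )
)
def test_swapping_p1_p2_negates_d(sites):
    f = _freqs(sites)
    swapped = isc.SiteFrequencies(p1=f.p2, p2=f.p1, p3=f.p3, p4=f.p4)
    D1, _ = isc.d_statistic(f)
    D2, _ = isc.d_statistic(swapped)
    if not np.isnan(D1):
        assert D2 == pytest.approx(-D1, abs=1e-12)


def test_streaming_matches_bruteforce_on_random_matrices():
    rng = np.random.default_rng(42)
    for _ in range(10):
        geno, pops = random_genotype_matrix(rng)
        sites = brute_site_frequencies(geno, pops, "g1", "g2", "g3", "og")
        f = isc.derived_frequencies(geno, pops, "g1", "g2", "g3", "og")
        D, _ = isc.d_statistic(f)
        assert D == pytest.approx(brute_d(sites), abs=1e-12)
        assert isc.fd_value(f) == pytest.approx(brute_fd(sites), abs=1e-12)


# ---------------------------------------------------------------------------
# f4 and the f4-ratio


def test_f4_single_site_component():
    assert isc.f4_component([0.9], [0.1], [0.7], [0.2]) == pytest.approx(0.40)


def test_f4_ratio_full_admixture_limit(quartet_tree):
    """P2 sampled from the same population as P3 estimates alpha ~= 1."""
    cfg = isc.SimConfig(
        species_tree=quartet_tree, n_individuals={"P1": 4, "P2": 1, "P3": 8, "OUT": 4},
        n_sites=30_000, seed=23,
    )
    geno, pops, _ = isc.simulate_genotypes(cfg)
    members = pops.groups["P3"]
    split = isc.PopulationMap(
        {
            "P1": pops.groups["P1"],
            "P2x": members[:4],
            "P3x": members[4:],
            "OUT": pops.groups["OUT"],
        }
    )
    alpha = isc.f4_ratio(geno, split, "P1", "P2x", "P3x", "OUT", seed=1)
    assert alpha == pytest.approx(1.0, abs=0.1)


def test_f4_ratio_null_is_zero(quartet_tree):
    ests = [
        isc.f4_ratio(
            *isc.simulate_genotypes(
                isc.SimConfig(species_tree=quartet_tree, n_sites=20_000, seed=s)
            )[:2],
            "P1", "P2", "P3", "OUT", seed=s + 100,
        )
        for s in range(5)
    ]
    assert abs(float(np.mean(ests))) < 0.05


def test_d_increases_with_retention_probability(quartet_tree):
    ds = []
    for rho in (0.0, 0.5, 1.0):
        events = (
            [] if rho == 0
            else [isc.IntrogressionEvent("P3", "P2", (1, 1_000_000), rho=rho)]
        )
        cfg = isc.SimConfig(
            species_tree=quartet_tree, n_sites=20_000, seed=29, events=events
        )
        geno, pops, _ = isc.simulate_genotypes(cfg)
        f = isc.derived_frequencies(geno, pops, "P1", "P2", "P3", "OUT")
        ds.append(isc.d_statistic(f)[0])
    assert ds[0] < ds[1] < ds[2]


# ---------------------------------------------------------------------------
# block jackknife


def test_jackknife_two_block_toy_matches_closed_form():
    num = np.array([0.4, 0.2, 0.1, 0.3])
    den = np.array([0.5, 0.4, 0.3, 0.6])
    informative = np.ones(4, dtype=bool)
    theta, se, z, nb = jackknife_ratio(num, den, informative, n_blocks=2)
    bt, bse = brute_jackknife([0.6, 0.4], [0.9, 0.9])
    assert theta == pytest.approx(bt)
    assert se == pytest.approx(bse)
    assert z == pytest.approx(theta / se)


def test_jackknife_degenerate_variance_flags_z_undefined():
    num = np.tile([0.1, 0.2], 10)
    den = np.tile([0.2, 0.4], 10)
    theta, se, z, _ = jackknife_ratio(num, den, np.ones(20, bool), n_blocks=10)
    assert se == pytest.approx(0.0)
    assert np.isnan(z)


def test_jackknife_requires_enough_informative_sites():
    with pytest.raises(ConfigError):
        jackknife_ratio(np.ones(5), np.ones(5), np.ones(5, bool), n_blocks=10)


def test_genome_stat_site_accounting(small_sim):
    geno, pops, _ = small_sim
    st_ = isc.genome_stat(geno, pops, "P1", "P2", "P3", "OUT", n_blocks=50, seed=1)
    f = isc.derived_frequencies(geno, pops, "P1", "P2", "P3", "OUT")
    abba, baba, _, _ = pattern_arrays(f)
    assert st_.n_sites_used == int(((abba + baba) > 0).sum())
    assert -1 <= st_.D <= 1
    assert st_.se >= 0


def test_dstat_matrix_mode(quartet_tree):
    """Pairwise matrix: D in the upper triangle, f4-ratio in the lower."""
    cfg = isc.SimConfig(species_tree=quartet_tree, n_individuals=3, n_sites=3_000,
                        seed=37)
    geno, pops, _ = isc.simulate_genotypes(cfg)
    from introscan.popgen import dstat_matrix

    mat = dstat_matrix(geno, pops, ["P1", "P2", "P3"], "OUT", n_blocks=10)
    assert np.isfinite(mat.loc["P1", "P2"])  # D for the (P1, P2) pair
    assert np.isfinite(mat.loc["P2", "P1"])  # f4-ratio mirrored below
    assert np.isnan(np.diag(mat.to_numpy(float))).all()


def test_jackknife_point_estimate_equals_plain_ratio(small_sim):
    """The jackknife's point estimate must be the plain ratio of sums over
    all sites, including sites with a zero denominator term."""
    geno, pops, _ = small_sim
    st_ = isc.genome_stat(geno, pops, "P1", "P2", "P3", "OUT", n_blocks=50, seed=9)
    direct = isc.f4_ratio(geno, pops, "P1", "P2", "P3", "OUT", seed=9)
    assert st_.f4_ratio == pytest.approx(direct, abs=1e-12)
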