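import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import introscan as isc
from introscan.errors import ConfigError
from introscan.genomescan import _majority_state


# ---------------------------------------------------------------------------
# windowed f_d


def test_window_tiling_and_snp_accounting(small_sim):
    geno, pops, _ = small_sim
    wins = isc.windowed_fd(
        geno, pops, "P1", "P2", "P3", "OUT",
        w=10_000, min_snps=1, chrom_sizes={"chr1": 1_000_000},
    )
    assert len(wins) == 100
    assert (wins["end"] - wins["start"] == 10_000).all()
    f = isc.derived_frequencies(geno, pops, "P1", "P2", "P3", "OUT")
    assert wins["n_snps"].sum() == f.n_sites


def test_sparse_windows_report_na(small_sim):
    geno, pops, _ = small_sim
    wins = isc.windowed_fd(
        geno, pops, "P1", "P2", "P3", "OUT", w=10_000, min_snps=10_000
    )
    assert wins["fd"].isna().all()


def test_window_size_must_be_positive(small_sim):
    geno, pops, _ = small_sim
    with pytest.raises(ConfigError):
        isc.windowed_fd(geno, pops, "P1", "P2", "P3", "OUT", w=0)


def test_planted_tract_window_has_maximal_fd(quartet_tree):
    cfg = isc.SimConfig(
        species_tree=quartet_tree, n_sites=20_000, seed=31,
        events=[isc.IntrogressionEvent("P3", "P2", (500_001, 510_000), rho=0.9)],
    )
    geno, pops, _ = isc.simulate_genotypes(cfg)
    wins = isc.windowed_fd(
        geno, pops, "P1", "P2", "P3", "OUT", chrom_sizes={"chr1": 1_000_000}
    )
    assert int(wins.loc[wins["fd"].idxmax(), "start"]) == 500_000


# ---------------------------------------------------------------------------
# outlier calling


def _wins(values):
    n = len(values)
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(n) * 10_000,
            "end": (np.arange(n) + 1) * 10_000,
            "n_snps": 50,
            "fd": values,
        }
    )


def test_quantile_flagging_counts():
    wins = _wins(np.linspace(0, 1, 10_000))
    out = isc.call_outliers(wins, q=0.999)
    assert out["flagged"].sum() == 10  # exactly ceil((1-q)*n) absent ties


def test_all_equal_values_flag_everything():
    out = isc.call_outliers(_wins(np.full(50, 0.3)), q=0.999)
    assert out["flagged"].all()


def test_gene_proximity_annotation():
    vals = np.zeros(100)
    vals[42] = 0.9
    out = isc.call_outliers(
        _wins(vals), q=0.99, gene_interval=("chr1", 425_000, 426_000), proximity=10_000
    )
    flagged = out[out["flagged"]]
    assert list(flagged["start"]) == [420_000]
    assert flagged["within_proximity"].all()
    far = isc.call_outliers(
        _wins(vals), q=0.99, gene_interval=("chr1", 900_000, 910_000), proximity=10_000
    )
    assert not far[far["flagged"]]["within_proximity"].any()


def test_quantile_bounds_validated():
    with pytest.raises(ConfigError):
        isc.call_outliers(_wins(np.ones(5)), q=1.5)


# ---------------------------------------------------------------------------
# diagnostic sites


def _toy(rows, groups):
    samples = [m for ms in groups.values() for m in ms]
    n = len(rows)
    return (
        isc.GenotypeMatrix(
            np.full(n, "chr1", dtype=object), np.arange(1, n + 1) * 100,
            np.full(n, "A", dtype=object), np.full(n, "G", dtype=object),
            np.array(rows, dtype=np.int8), tuple(samples),
        ),
        isc.PopulationMap(groups),
    )


DONOR3 = ["d1", "d2", "d3"]
BG3 = ["b1", "b2", "b3"]


def test_fixed_difference_site_passes():
    geno, pops = _toy([[2, 2, 2, 0, 0, 0]], {"don": DONOR3, "bg": BG3})
    spec = isc.FilterSpec("don", "bg", 0.9, 0.9, 0.4, 0.4)
    sites = isc.diagnostic_sites(geno, pops, spec)
    assert len(sites) == 1 and sites["donor_allele"].iloc[0] == "alt"


def test_frequency_below_threshold_excluded():
    # donor 5/6 ALT = 0.833 < 0.9
    geno, pops = _toy([[2, 2, 1, 0, 0, 0]], {"don": DONOR3, "bg": BG3})
    spec = isc.FilterSpec("don", "bg", 0.9, 0.9, 0.4, 0.4)
    assert len(isc.diagnostic_sites(geno, pops, spec)) == 0


def test_missingness_cap_enforced():
    donor10 = [f"d{i}" for i in range(10)]
    rows = [[2] * 8 + [-1, -1] + [0, 0, 0]]  # 2/10 donors missing = 20%
    geno, pops = _toy(rows, {"don": donor10, "bg": BG3})
    strict = isc.FilterSpec("don", "bg", 0.9, 0.9, 0.099, 0.4)
    loose = isc.FilterSpec("don", "bg", 0.9, 0.9, 0.2, 0.4)
    assert len(isc.diagnostic_sites(geno, pops, strict)) == 0
    assert len(isc.diagnostic_sites(geno, pops, loose)) == 1


def test_filter_symmetric_under_group_swap(small_sim):
    geno, pops, _ = small_sim
    ab = isc.diagnostic_sites(geno, pops, isc.FilterSpec("P2", "P3", 0.9, 0.9, 0.4, 0.4))
    ba = isc.diagnostic_sites(geno, pops, isc.FilterSpec("P3", "P2", 0.9, 0.9, 0.4, 0.4))
    assert ab["pos"].tolist() == ba["pos"].tolist()


def test_raising_tau_never_adds_sites(small_sim):
    geno, pops, _ = small_sim
    loose = isc.diagnostic_sites(geno, pops, isc.FilterSpec("P2", "P3", 0.9, 0.9, 0.4, 0.4))
    strict = isc.diagnostic_sites(geno, pops, isc.FilterSpec("P2", "P3", 1.0, 1.0, 0.4, 0.4))
    assert len(strict) <= len(loose)
    assert set(strict["pos"]) <= set(loose["pos"])


def test_tau_and_cap_ranges_validated():
    with pytest.raises(ConfigError):
        isc.FilterSpec("a", "b", tau_a=0.4)
    with pytest.raises(ConfigError):
        isc.FilterSpec("a", "b", miss_a=1.0)


# ---------------------------------------------------------------------------
# painting and blocks


def _painting(states, positions=None):
    n = len(states)
    pos = positions if positions is not None else np.arange(1, n + 1) * 100
    return pd.DataFrame(
        {"chrom": np.full(n, "chr1", dtype=object), "pos": pos, "R": states}
    )


def test_block_run_definition_gap_zero():
    blocks = isc.call_blocks(_painting([2, 2, 0, 2]), gap_tolerance=0)
    assert [(b.start_site, b.end_site) for b in blocks] == [(100, 200), (400, 400)]


def test_gap_tolerance_bridges_single_gap():
    blocks = isc.call_blocks(_painting([2, 2, 0, 2]), gap_tolerance=1)
    assert [(b.start_site, b.end_site) for b in blocks] == [(100, 400)]


def test_missing_sites_neither_extend_nor_break():
    blocks = isc.call_blocks(_painting([2, -1, 2, 0, 2]), gap_tolerance=0)
    assert [(b.start_site, b.end_site) for b in blocks] == [(100, 300), (500, 500)]


def test_majority_vote_species_state():
    stack = np.array([[2, 2, 0], [1, 0, -1], [0, 0, 2], [-1, -1, -1], [2, 0, -1]])
    states = _majority_state(stack)
    assert states.tolist() == [2, 1, 0, -1, 1]  # last row: 2 vs 0 tie -> het


def test_block_donor_fraction():
    blocks = isc.call_blocks(_painting([2, 1, 2]))
    assert blocks[0].donor_allele_fraction == pytest.approx(5 / 6)


# ---------------------------------------------------------------------------
# shared core


def test_shared_core_intersection():
    mk = lambda s, e: isc.HaplotypeBlock("chr1", s, e, "x", 3, 1.0)
    assert isc.shared_core([mk(100, 300), mk(150, 280), mk(140, 208)]) == (150, 208)
    assert isc.shared_core([mk(100, 200), mk(300, 400)]) is None


def test_shared_core_rejects_mixed_chromosomes():
    b1 = isc.HaplotypeBlock("chr1", 100, 300, "x", 3, 1.0)
    b2 = isc.HaplotypeBlock("chr2", 150, 280, "y", 3, 1.0)
    with pytest.raises(ConfigError):
        isc.shared_core([b1, b2])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(st.integers(1, 500), st.integers(0, 200)),
        min_size=2, max_size=6,
    )
)
def test_shared_core_contained_in_every_block(intervals):
    blocks = [
        isc.HaplotypeBlock("chr1", s, s + w, f"b{i}", 1, 1.0)
        for i, (s, w) in enumerate(intervals)
    ]
    core = isc.shared_core(blocks)
    if core is not None:
        for b in blocks:
            assert b.start_site <= core[0] and core[1] <= b.end_site


def test_blocks_lie_on_diagnostic_sites(small_sim):
    geno, pops, _ = small_sim
    spec = isc.FilterSpec("P3", "P1", 0.9, 0.9, 0.4, 0.4)
    sites = isc.diagnostic_sites(geno, pops, spec)
    _, blocks = isc.paint_and_call_blocks(sites, geno, pops.groups["P2"])
    site_pos = set(sites["pos"])
    for b in blocks:
        assert b.start_site in site_pos and b.end_site in site_pos
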