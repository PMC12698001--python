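"""Windowed f_d scanning, percentile outlier calls, and introgression
haplotype localization via diagnostic-site filtering and genotype painting.

Windows tile each chromosome from coordinate 0 in non-overlapping steps of
``w`` bp (default 10 kb); windows with fewer informative SNPs than
``min_snps`` report NA.  Outliers are windows at or above an empirical
quantile of the non-NA f_d distribution (linear-interpolation quantile,
ties flagged inclusively).

Localization follows the fixed-difference logic: diagnostic sites are SNPs
at which two lineages are fixed or nearly fixed (frequency >= tau per
group) for different alleles under per-group missingness caps; recipient
genotypes are painted by their dosage of the donor-diagnostic allele, and
haplotype blocks are maximal runs of diagnostic sites carrying at least one
donor allele.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import GenotypeMatrix, HaplotypeBlock, PopulationMap
from .errors import ConfigError, PreconditionError, ReferenceLookupError
from .popgen import derived_frequencies, pattern_arrays

# painting states: donor-allele dosage; -1 missing
BACKGROUND_HOM, DONOR_HET, DONOR_HOM, PAINT_MISSING = 0, 1, 2, -1


@dataclass(frozen=True)
class FilterSpec:
    """Fixed-difference filter between two lineages.

    ``tau_*`` is the minimum within-group frequency of the group's majority
    allele (1.0 means strictly fixed); ``miss_*`` caps the fraction of
    individuals with missing genotypes per group.
    """

    group_a: str
    group_b: str
    tau_a: float = 0.90
    tau_b: float = 0.90
    miss_a: float = 0.10
    miss_b: float = 0.10

    def __post_init__(self) -> None:
        for tau in (self.tau_a, self.tau_b):
            if not 0.5 < tau <= 1.0:
                raise ConfigError("tau must be in (0.5, 1.0]")
        for cap in (self.miss_a, self.miss_b):
            if not 0.0 <= cap < 1.0:
                raise ConfigError("missingness caps must be in [0, 1)")


# ---------------------------------------------------------------------------
# windowed f_d


def windowed_fd(
    geno: GenotypeMatrix,
    pops: PopulationMap,
    p1g: str,
    p2g: str,
    p3g: str,
    og: str,
    w: int = 10_000,
    min_snps: int = 10,
    chrom_sizes: dict | None = None,
) -> pd.DataFrame:
    """f_d in non-overlapping ``w``-bp windows tiled from coordinate 0.

    Returns a DataFrame with columns chrom, start, end (0-based half-open),
    n_snps, fd.  ``chrom_sizes`` (chrom -> length in bp) controls how far
    tiling extends; by default it reaches the last observed SNP.
    """
    if w <= 0:
        raise ConfigError("window size must be positive")
    freqs = derived_frequencies(geno, pops, p1g, p2g, p3g, og)
    _, _, num, den = pattern_arrays(freqs)
    rows = []
    for chrom in dict.fromkeys(geno.chrom):
        on_chrom = freqs.chrom == chrom
        pos = freqs.pos[on_chrom]
        cn, cd = num[on_chrom], den[on_chrom]
        length = (chrom_sizes or {}).get(chrom, int(pos.max()) if pos.size else w)
        n_windows = max(int(np.ceil(length / w)), 1)
        widx = (pos - 1) // w  # 1-based position -> 0-anchored window
        counts = np.bincount(widx, minlength=n_windows)
        num_sums = np.bincount(widx, weights=cn, minlength=n_windows)
        den_sums = np.bincount(widx, weights=cd, minlength=n_windows)
        for k in range(n_windows):
            if counts[k] < min_snps:
                fd = np.nan
            elif num_sums[k] <= 0:
                fd = 0.0
            elif abs(den_sums[k]) < 1e-12:
                fd = np.nan
            else:
                fd = num_sums[k] / den_sums[k]
            rows.append(
                {
                    "chrom": chrom,
                    "start": k * w,
                    "end": min((k + 1) * w, length) if chrom_sizes else (k + 1) * w,
                    "n_snps": int(counts[k]),
                    "fd": fd,
                }
            )
    return pd.DataFrame(rows)


def call_outliers(
    windows: pd.DataFrame,
    q: float = 0.999,
    gene_interval: tuple | None = None,
    proximity: int = 10_000,
) -> pd.DataFrame:
    """Flag windows with f_d at or above the empirical q-quantile.

    ``gene_interval`` is (chrom, start, end) in 0-based half-open
    coordinates; flagged windows overlapping the interval expanded by
    ``proximity`` bp on each side are annotated ``within_proximity``.
    """
    if not 0.0 < q < 1.0:
        raise ConfigError("quantile must be in (0, 1)")
    fd = windows["fd"].to_numpy(dtype=float)
    ok = ~np.isnan(fd)
    if not ok.any():
        raise PreconditionError("no non-NA windows to rank")
    threshold = float(np.quantile(fd[ok], q, method="linear"))
    out = windows.copy()
    out["flagged"] = ok & (fd >= threshold)
    out["within_proximity"] = False
    if gene_interval is not None:
        gchrom, gstart, gend = gene_interval
        lo, hi = gstart - proximity, gend + proximity
        overlap = (
            (out["chrom"] == gchrom)
            & (out["start"] < hi)
            & (out["end"] > lo)
        )
        out["within_proximity"] = out["flagged"] & overlap
    out.attrs["threshold"] = threshold
    return out


# ---------------------------------------------------------------------------
# diagnostic sites


def diagnostic_sites(
    geno: GenotypeMatrix, pops: PopulationMap, spec: FilterSpec
) -> pd.DataFrame:
    """Sites fixed or nearly fixed for different alleles between two groups.

    A site is retained when group A carries its majority allele at frequency
    >= tau_a, group B carries the *other* allele at frequency >= tau_b, and
    each group's fraction of missing genotypes is <= its cap.  The
    ``donor_allele`` column records which allele (``"ref"``/``"alt"``) is
    diagnostic of group A (the donor lineage in the painting convention).

    Returns a DataFrame with columns site_index, chrom, pos, donor_allele.
    """
    a_members = pops.members(spec.group_a)
    b_members = pops.members(spec.group_b)
    if not a_members or not b_members:
        raise ConfigError("filter groups must be non-empty")
    if set(a_members) & set(b_members):
        raise ConfigError("filter groups overlap")

    def group_stats(members):
        g = geno.genotypes[:, geno.sample_index(members)]
        called = g >= 0
        alt = np.where(called, g, 0).sum(axis=1)
        n = 2 * called.sum(axis=1)
        miss_frac = 1.0 - called.sum(axis=1) / len(members)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq_alt = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
        return freq_alt, miss_frac, n

    fa, miss_a, na = group_stats(a_members)
    fb, miss_b, nb = group_stats(b_members)

    a_major_is_alt = fa >= 0.5
    fa_major = np.where(a_major_is_alt, fa, 1.0 - fa)
    fb_other = np.where(a_major_is_alt, 1.0 - fb, fb)  # B's freq of the other allele
    keep = (
        (na > 0)
        & (nb > 0)
        & (fa_major >= spec.tau_a)
        & (fb_other >= spec.tau_b)
        & (miss_a <= spec.miss_a)
        & (miss_b <= spec.miss_b)
    )
    idx = np.nonzero(keep)[0]
    return pd.DataFrame(
        {
            "site_index": idx,
            "chrom": geno.chrom[idx],
            "pos": geno.pos[idx],
            "donor_allele": np.where(a_major_is_alt[idx], "alt", "ref"),
        }
    )


# ---------------------------------------------------------------------------
# painting and block calling


def _individual_states(geno: GenotypeMatrix, sites: pd.DataFrame, name: str):
    col = geno.sample_index([name])[0]
    g = geno.genotypes[sites["site_index"].to_numpy(), col].astype(np.int8)
    donor_is_alt = (sites["donor_allele"] == "alt").to_numpy()
    states = np.where(g < 0, PAINT_MISSING, np.where(donor_is_alt, g, 2 - g))
    return states.astype(np.int8)


def paint_recipients(
    sites: pd.DataFrame,
    geno: GenotypeMatrix,
    recipients: Sequence[str],
    pops: PopulationMap | None = None,
) -> pd.DataFrame:
    """Donor-allele dosage painting at diagnostic sites.

    Each recipient may be an individual name or (when ``pops`` is given) a
    species/group label; species-level states are the majority state across
    the group's individuals (missing excluded, ties -> heterozygous).

    Returns a DataFrame indexed like ``sites`` with one int8 column per
    recipient holding states {0, 1, 2, -1}.
    """
    cols = {}
    sample_set = set(geno.samples)
    for r in recipients:
        if r in sample_set:
            cols[r] = _individual_states(geno, sites, r)
        elif pops is not None and r in pops.groups:
            members = pops.members(r)
            stack = np.stack(
                [_individual_states(geno, sites, m) for m in members], axis=1
            )
            cols[r] = _majority_state(stack)
        else:
            raise ReferenceLookupError(f"recipient {r!r} not an individual or group")
    out = pd.DataFrame(cols)
    out.insert(0, "chrom", sites["chrom"].to_numpy())
    out.insert(1, "pos", sites["pos"].to_numpy())
    return out


def _majority_state(stack: np.ndarray) -> np.ndarray:
    """Majority of {0,1,2} states per row, missing excluded; tie -> het."""
    n_sites = stack.shape[0]
    counts = np.zeros((n_sites, 3), dtype=np.int64)
    for s in (0, 1, 2):
        counts[:, s] = (stack == s).sum(axis=1)
    total = counts.sum(axis=1)
    best = counts.max(axis=1)
    winners = counts == best[:, None]
    n_winners = winners.sum(axis=1)
    state = np.argmax(counts, axis=1).astype(np.int8)
    state[n_winners > 1] = DONOR_HET
    state[total == 0] = PAINT_MISSING
    return state


def call_blocks(
    painting: pd.DataFrame,
    recipients: Sequence[str] | None = None,
    gap_tolerance: int = 0,
) -> list:
    """Maximal runs of diagnostic sites carrying >=1 donor allele.

    Runs may bridge up to ``gap_tolerance`` consecutive donor-free
    (state 0) sites; missing sites neither extend nor break a run.  Returns
    a list of :class:`HaplotypeBlock`.
    """
    if gap_tolerance < 0:
        raise ConfigError("gap tolerance must be >= 0")
    recipients = recipients or [
        c for c in painting.columns if c not in ("chrom", "pos")
    ]
    blocks = []
    for chrom in dict.fromkeys(painting["chrom"]):
        sub = painting[painting["chrom"] == chrom]
        pos = sub["pos"].to_numpy()
        for r in recipients:
            states = sub[r].to_numpy()
            blocks.extend(_runs_to_blocks(chrom, pos, states, r, gap_tolerance))
    return blocks


def _runs_to_blocks(chrom, pos, states, label, g):
    blocks = []
    run_idx: list = []
    gap = 0
    for i, s in enumerate(states):
        if s >= 1:
            run_idx.append(i)
            gap = 0
        elif s == 0:
            gap += 1
            if run_idx and gap > g:
                blocks.append(_make_block(chrom, pos, states, run_idx, label))
                run_idx = []
        # missing (-1): neither extends nor breaks
    if run_idx:
        blocks.append(_make_block(chrom, pos, states, run_idx, label))
    return blocks


def _make_block(chrom, pos, states, run_idx, label):
    first, last = run_idx[0], run_idx[-1]
    span = states[first : last + 1]
    called = span >= 0
    donor_alleles = span[called].sum()
    frac = float(donor_alleles) / (2 * int(called.sum())) if called.any() else 0.0
    return HaplotypeBlock(
        chrom=str(chrom),
        start_site=int(pos[first]),
        end_site=int(pos[last]),
        label=str(label),
        n_sites=int(last - first + 1),
        donor_allele_fraction=frac,
    )


def paint_and_call_blocks(
    sites: pd.DataFrame,
    geno: GenotypeMatrix,
    recipients: Sequence[str],
    pops: PopulationMap | None = None,
    gap_tolerance: int = 0,
):
    """Convenience wrapper: painting matrix plus called blocks."""
    painting = paint_recipients(sites, geno, recipients, pops=pops)
    blocks = call_blocks(painting, recipients, gap_tolerance)
    return painting, blocks


def shared_core(blocks: Sequence[HaplotypeBlock]):
    """Coordinate intersection of blocks across species; None when empty."""
    if len(blocks) < 2:
        raise ConfigError("need at least two blocks to intersect")
    chroms = {b.chrom for b in blocks}
    if len(chroms) > 1:
        raise ConfigError(f"blocks span multiple chromosomes: {sorted(chroms)}")
    start = max(b.start_site for b in blocks)
    end = min(b.end_site for b in blocks)
    if start > end:
        return None
    return (start, end)
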