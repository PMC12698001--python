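"""Site-pattern introgression statistics: D, f_d, f4-ratio, block jackknife.

All statistics are frequency-weighted (population-sample) versions of the
four-taxon site-pattern tests for the taxon arrangement ((P1, P2), P3, O):
an excess of ABBA over BABA patterns indicates gene flow between P2 and the
donor P3.  Per-site pattern weights are

    C_ABBA = (1 - p1) * p2 * p3 * (1 - p4)
    C_BABA = p1 * (1 - p2) * p3 * (1 - p4)

with p_i the derived-allele frequency in taxon i.  The D-statistic is
``sum(C_ABBA - C_BABA) / sum(C_ABBA + C_BABA)``.  f_d rescales the same
numerator by the value it would take if the donor-like population
(whichever of P2/P3 has the higher derived frequency at each site) occupied
both the P2 and P3 positions, yielding a window-stable estimate of the
introgressed fraction.  The f4-ratio estimates the genome-wide admixture
proportion by splitting the donor sample's alleles into two random halves.

Derived-allele polarization: the derived allele at a site is the allele at
lower frequency in the outgroup, ties broken toward ALT.  Sites where any
of the four groups has zero called alleles are excluded (and counted).

Uncertainty comes from a delete-one block jackknife over contiguous blocks
holding equal numbers of informative sites.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import GenotypeMatrix, PopulationMap
from .errors import ConfigError

DENOM_EPS = 1e-12


@dataclass
class SiteFrequencies:
    """Per-site derived-allele frequencies for (P1, P2, P3/donor, outgroup)."""

    p1: np.ndarray
    p2: np.ndarray
    p3: np.ndarray
    p4: np.ndarray
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None
    n_called: np.ndarray | None = None  # shape (n_sites, 4), called alleles
    n_excluded: int = 0

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "p3", "p4"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.min(initial=0.0) < 0 or arr.max(initial=0.0) > 1:
                raise ConfigError(f"{name} outside [0, 1]")
            setattr(self, name, arr)

    @property
    def n_sites(self) -> int:
        return int(self.p1.shape[0])


@dataclass
class PatternSums:
    sum_abba: float
    sum_baba: float
    sum_num_fd: float
    sum_den_fd: float


@dataclass
class GenomeStat:
    """Genome-wide statistic bundle with jackknife uncertainty."""

    D: float
    Z: float
    se: float
    n_blocks: int
    n_sites_used: int
    f4_ratio: float = float("nan")
    f4_se: float = float("nan")
    f4_z: float = float("nan")


# ---------------------------------------------------------------------------
# frequencies


def _group_allele_counts(geno: GenotypeMatrix, pops: PopulationMap, group: str):
    """(ALT allele count, called allele count) arrays for one group."""
    idx = geno.sample_index(pops.members(group))
    g = geno.genotypes[:, idx]
    called = g >= 0
    alt = np.where(called, g, 0).sum(axis=1)
    n = 2 * called.sum(axis=1)
    return alt.astype(np.int64), n.astype(np.int64)


def _check_disjoint(pops: PopulationMap, labels: Sequence[str]) -> None:
    seen: set = set()
    for lab in labels:
        members = set(pops.members(lab))
        if members & seen:
            raise ConfigError(f"groups overlap at {sorted(members & seen)}")
        seen |= members


def derived_frequencies(
    geno: GenotypeMatrix,
    pops: PopulationMap,
    p1g: str,
    p2g: str,
    p3g: str,
    og: str,
) -> SiteFrequencies:
    """Per-site derived-allele frequencies for the four taxa.

    The derived allele is the outgroup's minor allele (tie toward ALT).
    Sites where any group has zero called alleles are excluded and counted
    in ``n_excluded``.
    """
    labels = (p1g, p2g, p3g, og)
    _check_disjoint(pops, labels)
    alt = np.empty((geno.n_sites, 4), dtype=np.int64)
    n = np.empty((geno.n_sites, 4), dtype=np.int64)
    for j, lab in enumerate(labels):
        alt[:, j], n[:, j] = _group_allele_counts(geno, pops, lab)
    keep = (n > 0).all(axis=1)
    alt, n = alt[keep], n[keep]
    with np.errstate(invalid="ignore"):
        freq_alt = alt / n
    # derived = lower-frequency allele in outgroup; tie -> ALT
    derived_is_alt = freq_alt[:, 3] <= 0.5
    p = np.where(derived_is_alt[:, None], freq_alt, 1.0 - freq_alt)
    return SiteFrequencies(
        p1=p[:, 0], p2=p[:, 1], p3=p[:, 2], p4=p[:, 3],
        chrom=geno.chrom[keep], pos=geno.pos[keep], n_called=n,
        n_excluded=int((~keep).sum()),
    )


# ---------------------------------------------------------------------------
# per-site pattern arrays


def pattern_arrays(freqs: SiteFrequencies):
    """Per-site (C_ABBA, C_BABA, f_d numerator, f_d denominator) arrays."""
    p1, p2, p3, p4 = freqs.p1, freqs.p2, freqs.p3, freqs.p4
    abba = (1 - p1) * p2 * p3 * (1 - p4)
    baba = p1 * (1 - p2) * p3 * (1 - p4)
    pd_ = np.maximum(p2, p3)  # donor-like population at each site
    abba_d = (1 - p1) * pd_ * pd_ * (1 - p4)
    baba_d = p1 * (1 - pd_) * pd_ * (1 - p4)
    return abba, baba, abba - baba, abba_d - baba_d


def d_statistic(freqs: SiteFrequencies):
    """Genome/region D statistic.  Returns (D, PatternSums); D is NaN when
    no site carries pattern weight (undefined statistic)."""
    abba, baba, num, den = pattern_arrays(freqs)
    sums = PatternSums(
        float(abba.sum()), float(baba.sum()), float(num.sum()), float(den.sum())
    )
    total = sums.sum_abba + sums.sum_baba
    if total <= 0:
        return float("nan"), sums
    return (sums.sum_abba - sums.sum_baba) / total, sums


def fd_value(freqs: SiteFrequencies) -> float:
    """f_d for a region: numerator-over-donor-like-denominator, reported as
    0 when the ABBA excess is non-positive, NaN when the denominator
    vanishes with a positive numerator."""
    _, _, num, den = pattern_arrays(freqs)
    num_sum, den_sum = float(num.sum()), float(den.sum())
    if num_sum <= 0:
        return 0.0
    if abs(den_sum) < DENOM_EPS:
        return float("nan")
    return num_sum / den_sum


# ---------------------------------------------------------------------------
# f4 and f4-ratio


def f4_component(pa, pb, pc, pd_) -> float:
    """f4(A,B;C,D) = sum over sites of (pA - pB)(pC - pD)."""
    pa, pb, pc, pd_ = (np.asarray(x, dtype=float) for x in (pa, pb, pc, pd_))
    return float(((pa - pb) * (pc - pd_)).sum())


def _f4_ratio_site_terms(
    geno: GenotypeMatrix,
    pops: PopulationMap,
    p1g: str,
    p2g: str,
    p3g: str,
    og: str,
    rng: np.random.Generator,
):
    """Per-site numerator/denominator terms of the f4-ratio.

    alpha-hat = f4(P1,P2;P3a,O) / f4(P1,P3b;P3a,O) with P3a/P3b disjoint
    random halves of P3's called alleles, re-drawn per site.
    """
    labels = (p1g, p2g, p3g, og)
    _check_disjoint(pops, labels)
    alt = np.empty((geno.n_sites, 4), dtype=np.int64)
    n = np.empty((geno.n_sites, 4), dtype=np.int64)
    for j, lab in enumerate(labels):
        alt[:, j], n[:, j] = _group_allele_counts(geno, pops, lab)
    keep = (n[:, [0, 1, 3]] > 0).all(axis=1) & (n[:, 2] >= 2)
    alt, n = alt[keep], n[keep]
    with np.errstate(invalid="ignore"):
        freq_alt = alt / n
    derived_is_alt = freq_alt[:, 3] <= 0.5
    p = np.where(derived_is_alt[:, None], freq_alt, 1.0 - freq_alt)
    d3 = np.where(derived_is_alt, alt[:, 2], n[:, 2] - alt[:, 2])
    n3 = n[:, 2]
    na = n3 // 2
    nb = n3 - na
    da = rng.hypergeometric(d3, n3 - d3, na)
    p3a = da / na
    p3b = (d3 - da) / nb
    num = (p[:, 0] - p[:, 1]) * (p3a - p[:, 3])
    den = (p[:, 0] - p3b) * (p3a - p[:, 3])
    return num, den, keep


def f4_ratio(
    geno: GenotypeMatrix,
    pops: PopulationMap,
    p1g: str,
    p2g: str,
    p3g: str,
    og: str,
    seed: int | np.random.Generator = 0,
) -> float:
    """Admixture-proportion estimate alpha-hat via the f4-ratio.

    NaN when the denominator sum is numerically zero (undefined statistic).
    """
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    num, den, _ = _f4_ratio_site_terms(geno, pops, p1g, p2g, p3g, og, rng)
    den_sum = float(den.sum())
    if abs(den_sum) < DENOM_EPS:
        return float("nan")
    return float(num.sum()) / den_sum


# ---------------------------------------------------------------------------
# block jackknife


def jackknife_ratio(num: np.ndarray, den: np.ndarray, informative: np.ndarray,
                    n_blocks: int = 200):
    """Delete-one block jackknife for a ratio statistic theta = sum(num)/sum(den).

    Blocks are contiguous runs holding equal numbers of informative sites.
    Returns (theta, se, z, n_blocks).  With zero jackknife variance the
    Z-score is NaN (undefined), matching the degenerate-variance convention.
    """
    if n_blocks < 2:
        raise ConfigError("need at least 2 jackknife blocks")
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    idx = np.nonzero(informative)[0]
    if idx.size < n_blocks:
        raise ConfigError(
            f"only {idx.size} informative sites for {n_blocks} blocks; "
            "reduce n_blocks"
        )
    num_tot, den_tot = float(num.sum()), float(den.sum())
    if abs(den_tot) < DENOM_EPS:
        return float("nan"), float("nan"), float("nan"), n_blocks
    theta = num_tot / den_tot
    # block boundaries: equal informative-site counts, but each block spans
    # every site between its first informative site and the next block's
    # (so low-signal sites still contribute to the leave-one-out sums)
    starts = [blk[0] for blk in np.array_split(idx, n_blocks)]
    starts[0] = 0
    bounds = starts + [num.shape[0]]
    loo = np.empty(n_blocks)
    for i in range(n_blocks):
        sl = slice(bounds[i], bounds[i + 1])
        bn, bd = float(num[sl].sum()), float(den[sl].sum())
        d = den_tot - bd
        loo[i] = (num_tot - bn) / d if abs(d) >= DENOM_EPS else np.nan
    if np.isnan(loo).any():
        return theta, float("nan"), float("nan"), n_blocks
    se = float(np.sqrt((n_blocks - 1) / n_blocks * ((loo - loo.mean()) ** 2).sum()))
    z = theta / se if se > 0 else float("nan")
    return theta, se, z, n_blocks


def genome_stat(
    geno: GenotypeMatrix,
    pops: PopulationMap,
    p1g: str,
    p2g: str,
    p3g: str,
    og: str,
    n_blocks: int = 200,
    compute_f4_ratio: bool = True,
    seed: int = 0,
) -> GenomeStat:
    """Genome-wide D (with jackknife Z) and optionally the f4-ratio."""
    freqs = derived_frequencies(geno, pops, p1g, p2g, p3g, og)
    abba, baba, num, _ = pattern_arrays(freqs)
    informative = (abba + baba) > 0
    D, se, z, nb = jackknife_ratio(num, abba + baba, informative, n_blocks)
    stat = GenomeStat(
        D=D, Z=z, se=se, n_blocks=nb, n_sites_used=int(informative.sum())
    )
    if compute_f4_ratio:
        rng = np.random.default_rng(seed)
        fnum, fden, _ = _f4_ratio_site_terms(geno, pops, p1g, p2g, p3g, og, rng)
        finf = np.abs(fden) > 0
        if int(finf.sum()) >= n_blocks:
            a, fse, fz, _ = jackknife_ratio(fnum, fden, finf, n_blocks)
        else:
            a = f4_ratio(geno, pops, p1g, p2g, p3g, og, seed=np.random.default_rng(seed))
            fse = fz = float("nan")
        stat.f4_ratio, stat.f4_se, stat.f4_z = a, fse, fz
    return stat


def dstat_matrix(
    geno: GenotypeMatrix,
    pops: PopulationMap,
    species: Sequence[str],
    outgroup: str,
    n_blocks: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Pairwise D (upper triangle) and f4-ratio (lower triangle) matrix.

    For each unordered pair (A, B), P1 is chosen from the remaining listed
    species to maximize D (mirroring the convention of reporting the
    strongest configuration per pair); A is P2 and B is P3.
    """
    species = list(species)
    mat = pd.DataFrame(np.nan, index=species, columns=species)
    for i, a in enumerate(species):
        for j, b in enumerate(species):
            if i >= j:
                continue
            best = None
            for p1 in species:
                if p1 in (a, b):
                    continue
                try:
                    st = genome_stat(
                        geno, pops, p1, a, b, outgroup,
                        n_blocks=n_blocks, seed=seed,
                    )
                except ConfigError:
                    continue
                if best is None or (st.D == st.D and st.D > best.D):
                    best = st
            if best is not None:
                mat.iloc[i, j] = best.D
                mat.iloc[j, i] = best.f4_ratio
    return mat
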