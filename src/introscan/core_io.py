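"""Genotype data model and I/O: VCF, population maps, BED block export.

The in-memory genotype container is a dense sites x individuals matrix of
ALT-allele dosages (0, 1, 2) with -1 for missing calls.  Coordinates are
1-based inclusive throughout the package (the VCF convention); BED output
converts to 0-based half-open at the boundary.  Phasing is ignored: ``0|1``
and ``0/1`` both map to a heterozygous call, because every statistic in the
package is genotype/frequency based.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConsistencyError, FormatError, ReferenceLookupError

logger = logging.getLogger(__name__)

#: genotype states: ALT dosage for called genotypes, -1 for missing
HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1

_SNP_ALLELES = frozenset("ACGT")


@dataclass
class GenotypeMatrix:
    """Biallelic diploid SNP calls at sorted sites on named chromosomes.

    Attributes
    ----------
    chrom : array of str, per site
    pos : array of int, 1-based coordinate per site (VCF convention)
    ref, alt : arrays of single-base alleles per site
    genotypes : int8 array, shape (n_sites, n_samples); ALT dosage or -1
    samples : ordered individual names
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    genotypes: np.ndarray
    samples: tuple

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.samples = tuple(self.samples)
        n = self.pos.shape[0]
        if not (self.chrom.shape[0] == self.ref.shape[0] == self.alt.shape[0] == n):
            raise ConsistencyError("per-site arrays have unequal lengths")
        if self.genotypes.shape != (n, len(self.samples)):
            raise ConsistencyError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{n} sites x {len(self.samples)} samples"
            )
        bad = ~np.isin(self.genotypes, (HOM_REF, HET, HOM_ALT, MISSING))
        if bad.any():
            raise ConsistencyError("genotype states must be one of {0,1,2,-1}")
        for c in dict.fromkeys(self.chrom):
            p = self.pos[self.chrom == c]
            if p.size > 1 and not (np.diff(p) > 0).all():
                raise ConsistencyError(f"positions not strictly increasing on {c}")
        for r, a in zip(self.ref, self.alt):
            if r not in _SNP_ALLELES or a not in _SNP_ALLELES or r == a:
                raise ConsistencyError(f"non-biallelic-SNP alleles {r}/{a}")

    @property
    def n_sites(self) -> int:
        return int(self.pos.shape[0])

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, names: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[n] for n in names], dtype=np.intp)
        except KeyError as exc:
            raise ReferenceLookupError(f"unknown individual {exc.args[0]!r}") from exc

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.chrom[index], self.pos[index], self.ref[index],
            self.alt[index], self.genotypes[index], self.samples,
        )


@dataclass
class PopulationMap:
    """Assignment of individuals to disjoint species/group labels."""

    groups: dict = field(default_factory=dict)  # label -> ordered individual list

    def __post_init__(self) -> None:
        seen: dict = {}
        for label, members in self.groups.items():
            members = list(members)
            if not members:
                raise ConsistencyError(f"group {label!r} is empty")
            for m in members:
                if m in seen:
                    raise ConsistencyError(
                        f"individual {m!r} assigned to both {seen[m]!r} and {label!r}"
                    )
                seen[m] = label
            self.groups[label] = members
        self._assignment = seen

    @property
    def assignment(self) -> Mapping[str, str]:
        return dict(self._assignment)

    @property
    def individuals(self) -> list:
        return [m for members in self.groups.values() for m in members]

    def members(self, label: str) -> list:
        try:
            return list(self.groups[label])
        except KeyError as exc:
            raise ReferenceLookupError(f"unknown group {label!r}") from exc


@dataclass(frozen=True)
class HaplotypeBlock:
    """Contiguous run of donor-diagnostic alleles in one individual/species.

    ``start_site``/``end_site`` are the 1-based positions of the first and
    last diagnostic sites in the run (inclusive).
    """

    chrom: str
    start_site: int
    end_site: int
    label: str
    n_sites: int
    donor_allele_fraction: float

    def __post_init__(self) -> None:
        if self.start_site > self.end_site:
            raise ConsistencyError("block start after end")
        if self.n_sites < 1:
            raise ConsistencyError("block must contain at least one site")
        if not 0.0 <= self.donor_allele_fraction <= 1.0:
            raise ConsistencyError("donor_allele_fraction outside [0,1]")

    @property
    def length(self) -> int:
        """Spanned length in bp (1-based inclusive)."""
        return self.end_site - self.start_site + 1


# ---------------------------------------------------------------------------
# popmap I/O


def load_popmap(path) -> PopulationMap:
    """Read a two-column delimited (individual TAB group) population map."""
    groups: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected two columns")
            indiv, group = parts
            groups.setdefault(group, []).append(indiv)
    if not groups:
        raise FormatError(f"{path}: empty population map")
    return PopulationMap(groups)


def write_popmap(pops: PopulationMap, path) -> None:
    with open(path, "w") as fh:
        for label, members in pops.groups.items():
            for m in members:
                fh.write(f"{m}\t{label}\n")


# ---------------------------------------------------------------------------
# VCF I/O


def load_genotypes(vcf_path, popmap_path):
    """Load biallelic SNP genotypes and the accompanying population map.

    Multiallelic and non-SNP records are skipped (count logged).  ``./.`` and
    ``.|.`` genotypes become missing.  The VCF and popmap must describe the
    same individuals: a popmap individual absent from the VCF is a reference
    error, and a VCF individual absent from the popmap is rejected.

    Returns
    -------
    (GenotypeMatrix, PopulationMap)
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    samples = list(vcf.samples)
    if not samples:
        raise FormatError(f"{vcf_path}: no sample columns / GT data")
    has_gt = any(
        h["HeaderType"] == "FORMAT" and h["ID"] == "GT" for h in vcf.header_iter()
    )
    if not has_gt:
        raise FormatError(f"{vcf_path}: missing GT FORMAT field")

    pops = load_popmap(popmap_path)
    vcf_set, pop_set = set(samples), set(pops.individuals)
    if pop_set - vcf_set:
        missing = sorted(pop_set - vcf_set)
        raise ReferenceLookupError(f"popmap individuals not in VCF: {missing}")
    if vcf_set - pop_set:
        extra = sorted(vcf_set - pop_set)
        raise ConsistencyError(f"VCF individuals absent from popmap: {extra}")

    chroms, poss, refs, alts, rows = [], [], [], [], []
    n_skipped = 0
    for var in vcf:
        if (
            len(var.ALT) != 1
            or len(var.REF) != 1
            or var.REF not in _SNP_ALLELES
            or var.ALT[0] not in _SNP_ALLELES
        ):
            n_skipped += 1
            continue
        gt = var.gt_types.astype(np.int8)  # gts012: 0/1/2 dosage, 3 unknown
        gt[gt == 3] = MISSING
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        rows.append(gt)
    if n_skipped:
        logger.info("skipped %d multiallelic/non-SNP records", n_skipped)
    geno = GenotypeMatrix(
        np.array(chroms, dtype=object),
        np.array(poss, dtype=np.int64),
        np.array(refs, dtype=object),
        np.array(alts, dtype=object),
        np.array(rows, dtype=np.int8) if rows else np.zeros((0, len(samples)), np.int8),
        tuple(samples),
    )
    return geno, pops


_GT_STRING = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Write a minimal VCF v4.2 (GT-only) representation of the matrix."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=introscan\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in dict.fromkeys(geno.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.samples)
            + "\n"
        )
        for i in range(geno.n_sites):
            gts = "\t".join(_GT_STRING[int(g)] for g in geno.genotypes[i])
            fh.write(
                f"{geno.chrom[i]}\t{geno.pos[i]}\t.\t{geno.ref[i]}\t"
                f"{geno.alt[i]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# BED export


def export_blocks(blocks: Sequence[HaplotypeBlock], path) -> None:
    """Write haplotype blocks as BED6 (0-based half-open).

    Score encodes the donor-allele fraction scaled to 0-1000.  Overlapping
    blocks for the same label are rejected.
    """
    by_label: dict = {}
    for b in blocks:
        by_label.setdefault((b.label, b.chrom), []).append(b)
    for (label, chrom), bl in by_label.items():
        bl.sort(key=lambda b: b.start_site)
        for prev, nxt in zip(bl, bl[1:]):
            if nxt.start_site <= prev.end_site:
                raise ConsistencyError(
                    f"overlapping blocks for {label!r} on {chrom}"
                )
    ordered = sorted(blocks, key=lambda b: (b.chrom, b.start_site, b.label))
    with open(path, "w") as fh:
        for b in ordered:
            score = int(round(b.donor_allele_fraction * 1000))
            fh.write(
                f"{b.chrom}\t{b.start_site - 1}\t{b.end_site}\t{b.label}\t"
                f"{score}\t.\n"
            )


def load_blocks_bed(path) -> list:
    """Read BED6 blocks written by :func:`export_blocks` back into memory."""
    blocks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected >=4 BED columns")
            chrom, start, end, label = parts[0], int(parts[1]), int(parts[2]), parts[3]
            frac = int(parts[4]) / 1000 if len(parts) > 4 and parts[4] != "." else 0.0
            blocks.append(
                HaplotypeBlock(chrom, start + 1, end, label, max(end - start, 1), frac)
            )
    return blocks
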