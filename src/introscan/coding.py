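"""Exon splicing, translation, and diagnostic-residue detection.

Supports the coding-substitution analysis: splice a gene model out of a
genomic sequence (reverse-complementing minus-strand models), translate
with the standard genetic code (codons containing N or other ambiguity
translate to X), and scan an amino-acid alignment for residues shared by a
focal species set and absent from all background species.
"""
from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio.Seq import Seq

from .errors import ConfigError, ConsistencyError, FormatError

_VALID_NT = set("ACGTNRYSWKMBDHVacgtnryswkmbdhv")


@dataclass(frozen=True)
class GeneModel:
    """Exon structure of one gene.

    ``exons`` are 1-based inclusive genomic intervals ordered 5'->3' in
    transcript orientation (descending genomic coordinates for minus-strand
    models).  A spliced length not divisible by 3 marks a partial CDS; the
    trailing partial codon is dropped at translation with a warning.
    """

    chrom: str
    exons: tuple
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ConfigError("strand must be '+' or '-'")
        ivals = sorted((int(s), int(e)) for s, e in self.exons)
        if not ivals:
            raise ConfigError("gene model needs at least one exon")
        for (s, e) in ivals:
            if s > e or s < 1:
                raise ConfigError(f"bad exon interval ({s}, {e})")
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            if s2 <= e1:
                raise ConfigError("exons overlap")
        object.__setattr__(self, "exons", tuple((int(s), int(e)) for s, e in self.exons))

    @property
    def spliced_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def is_partial(self) -> bool:
        return self.spliced_length % 3 != 0


def splice_cds(genome_seq: str, model: GeneModel) -> str:
    """Concatenate exon sequences in transcript orientation.

    Minus-strand exons are reverse-complemented before concatenation.
    """
    n = len(genome_seq)
    parts = []
    for s, e in model.exons:
        if e > n:
            raise ConsistencyError(f"exon ({s}, {e}) beyond sequence length {n}")
        part = genome_seq[s - 1 : e]
        bad = set(part) - _VALID_NT
        if bad:
            raise FormatError(f"invalid nucleotide characters {sorted(bad)}")
        if model.strand == "-":
            part = str(Seq(part).reverse_complement())
        parts.append(part)
    return "".join(parts).upper()


def translate_cds(cds: str) -> str:
    """Standard-genetic-code translation; ambiguous codons give X, and a
    trailing partial codon is dropped with a warning."""
    cds = cds.upper()
    trailing = len(cds) % 3
    if trailing:
        warnings.warn(
            f"dropping trailing partial codon of {trailing} nt", stacklevel=2
        )
        cds = cds[: len(cds) - trailing]
    out = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        try:
            aa = str(Seq(codon).translate())
        except Exception:
            aa = "X"
        out.append(aa if aa else "X")
    return "".join(out)


def splice_and_translate(genome_seq: str, model: GeneModel):
    """(CDS, protein) for one species' genomic sequence and gene model."""
    cds = splice_cds(genome_seq, model)
    return cds, translate_cds(cds)


# ---------------------------------------------------------------------------
# diagnostic residues


@dataclass(frozen=True)
class DiagnosticResidue:
    """An alignment column where the focal set carries a private residue."""

    position: int  # 1-based alignment column
    focal_residue: str
    background_residues: tuple  # sorted (residue, count) pairs

    @property
    def background_multiset(self) -> Counter:
        return Counter(dict(self.background_residues))


_MISSING_RESIDUES = set("X-.?*")


def diagnostic_residues(
    alignment: Mapping[str, str],
    focal_set: Sequence[str],
    tolerance: int = 0,
) -> list:
    """Alignment positions where all non-missing focal species share one
    residue that no background species carries.

    ``X`` and gaps are treated as missing (within-species polymorphism is
    expected to be pre-collapsed to X); ``tolerance`` is the maximum number
    of focal species allowed to be missing at a reported position.
    """
    species = list(alignment)
    if not species:
        raise ConfigError("empty alignment")
    lengths = {len(alignment[s]) for s in species}
    if len(lengths) != 1:
        raise ConsistencyError("alignment sequences have unequal lengths")
    focal = list(dict.fromkeys(focal_set))
    unknown = set(focal) - set(species)
    if unknown:
        raise ConfigError(f"focal species not in alignment: {sorted(unknown)}")
    background = [s for s in species if s not in set(focal)]
    if not focal or not background:
        raise ConfigError("focal and background sets must both be non-empty")

    (length,) = lengths
    results = []
    for col in range(length):
        focal_res = [alignment[s][col] for s in focal]
        present = [r for r in focal_res if r not in _MISSING_RESIDUES]
        n_missing = len(focal_res) - len(present)
        if not present or n_missing > tolerance:
            continue
        if len(set(present)) != 1:
            continue
        residue = present[0]
        bg = [
            alignment[s][col]
            for s in background
            if alignment[s][col] not in _MISSING_RESIDUES
        ]
        if residue in bg:
            continue
        results.append(
            DiagnosticResidue(
                position=col + 1,
                focal_residue=residue,
                background_residues=tuple(sorted(Counter(bg).items())),
            )
        )
    return results
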