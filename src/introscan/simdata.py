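"""Synthetic multi-species genotype data with planted introgression tracts.

The generator emulates the statistical structure a fixed-difference /
site-pattern introgression analysis relies on, without a full coalescent
model: per-site ancestral allele frequencies drawn from a Beta distribution
evolve along a species tree by truncated-Gaussian drift (variance =
``drift_scale`` x branch length, clamped to [0, 1]), and diploid genotypes
are sampled binomially from each species' tip frequency.  Introgression is
modeled as frequency replacement: within a planted tract, each site
independently (probability ``rho``) has the recipient's tip frequency
replaced by the donor's.  A ``polymorphic`` fixation mode instead assigns a
configured number of donor-haplotype copies to individual carriers, to
emulate introgression that has not progressed to fixation (heterozygous
carriers).

Everything is driven by one :class:`numpy.random.Generator`, so identical
seeds give bitwise-identical output, including the written VCF text.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np

from . import trees as _trees
from .core_io import GenotypeMatrix, PopulationMap, write_popmap, write_vcf
from .errors import ConfigError, ReferenceLookupError


@dataclass(frozen=True)
class IntrogressionEvent:
    """A planted donor -> recipient transfer of a genomic tract.

    rho is the per-site retention probability inside the tract.  fixation
    ``"fixed"`` replaces the recipient's allele frequency with the donor's;
    ``"polymorphic"`` assigns donor-haplotype copy numbers to individual
    carriers via ``carriers`` = mapping {copies: n_individuals}.
    """

    donor: str
    recipient: str
    tract: tuple  # (start, end), 1-based inclusive bp
    rho: float = 1.0
    fixation: str = "fixed"
    carriers: Mapping[int, int] | None = None


@dataclass(frozen=True)
class DisplacementEvent:
    """Gene-tree grafting event: recipients move inside the donor clade."""

    donor_clade: tuple  # leaf labels
    recipients: tuple  # leaf labels
    loci: tuple | None = None  # locus indices affected; None = all


@dataclass
class SimConfig:
    """Parameters of the genotype simulator.

    species_tree : Newick string with branch lengths; leaf labels are the
        species/group names.
    n_individuals : diploid individuals per species (int or per-species map).
    drift_scale : variance of allele-frequency change per unit branch length.
        The default (0.1, with inter-group branches of order 1) produces
        abundant near-fixed differences between groups on long branches --
        the divergence structure fixed-difference introgression analyses
        assume between genera.
    root_beta : (a, b) of the Beta distribution of ancestral frequencies.
    missing_rate : per-genotype missingness probability.
    round_tip_freqs : round every tip frequency to 0/1 (fully sorted
        lineages).  This is the noiseless fixed-difference condition used
        for exact haplotype-localization checks.
    """

    species_tree: str
    n_individuals: int | Mapping[str, int] = 4
    chrom_length: int = 1_000_000
    n_sites: int = 20_000
    drift_scale: float = 0.1
    root_beta: tuple = (0.8, 0.8)
    events: Sequence[IntrogressionEvent] = field(default_factory=tuple)
    outgroup: str | None = None
    chrom_name: str = "chr1"
    missing_rate: float = 0.0
    round_tip_freqs: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ConfigError("n_sites must be >= 1")
        if self.n_sites > self.chrom_length:
            raise ConfigError("n_sites exceeds number of distinct positions")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must be in [0, 1)")
        for ev in self.events:
            if ev.donor == ev.recipient:
                raise ConfigError("event recipient equals donor")
            s, e = ev.tract
            if not (1 <= s <= e <= self.chrom_length):
                raise ConfigError(f"tract {ev.tract} outside [1, chrom_length]")
            if not 0.0 <= ev.rho <= 1.0:
                raise ConfigError("rho must be in [0, 1]")
            if ev.fixation not in ("fixed", "polymorphic"):
                raise ConfigError("fixation must be 'fixed' or 'polymorphic'")
            if ev.fixation == "polymorphic" and not ev.carriers:
                raise ConfigError("polymorphic fixation requires carriers")

    def individuals_of(self, species: str) -> int:
        if isinstance(self.n_individuals, Mapping):
            return int(self.n_individuals.get(species, 0))
        return int(self.n_individuals)


@dataclass
class TruthSet:
    """Planted truth emitted alongside simulated data, for recovery tests."""

    tracts: dict  # recipient -> list of (start, end)
    events: list  # IntrogressionEvent list
    displacement_events: list  # DisplacementEvent list
    species_tree: str  # Newick
    gene_trees: list = field(default_factory=list)  # Newick strings

    def manifest(self) -> dict:
        return {
            "tracts": {k: [list(t) for t in v] for k, v in self.tracts.items()},
            "events": [
                {
                    "donor": e.donor,
                    "recipient": e.recipient,
                    "tract": list(e.tract),
                    "rho": e.rho,
                    "fixation": e.fixation,
                    "carriers": dict(e.carriers) if e.carriers else None,
                }
                for e in self.events
            ],
            "displacement_events": [
                {
                    "donor_clade": list(e.donor_clade),
                    "recipients": list(e.recipients),
                    "loci": list(e.loci) if e.loci is not None else None,
                }
                for e in self.displacement_events
            ],
            "species_tree": self.species_tree,
            "n_gene_trees": len(self.gene_trees),
        }


# ---------------------------------------------------------------------------


def _tip_frequencies(
    tree: dendropy.Tree, root_freq: np.ndarray, drift_scale: float,
    rng: np.random.Generator,
) -> dict:
    """Evolve per-site frequencies from the root to every tip by clamped
    Gaussian drift with variance drift_scale * branch length."""
    freqs = {tree.seed_node: root_freq}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent = freqs[node.parent_node]
        bl = node.edge.length or 0.0
        if drift_scale > 0 and bl > 0:
            step = rng.normal(0.0, np.sqrt(drift_scale * bl), size=parent.shape)
            freqs[node] = np.clip(parent + step, 0.0, 1.0)
        else:
            freqs[node] = parent.copy()
    return {
        leaf.taxon.label: freqs[leaf] for leaf in tree.leaf_node_iter()
    }


def simulate_genotypes(config: SimConfig):
    """Simulate genotypes, population map, and planted truth.

    Returns
    -------
    (GenotypeMatrix, PopulationMap, TruthSet)
    """
    rng = np.random.default_rng(config.seed)
    tree = _trees.parse_newick(config.species_tree)
    species = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    for ev in config.events:
        for name in (ev.donor, ev.recipient):
            if name not in species:
                raise ReferenceLookupError(f"event names unknown species {name!r}")

    # unique sorted 1-based positions
    pos = np.sort(rng.choice(config.chrom_length, size=config.n_sites, replace=False))
    pos = pos.astype(np.int64) + 1

    a, b = config.root_beta
    root_freq = rng.beta(a, b, size=config.n_sites)
    tip_freq = _tip_frequencies(tree, root_freq, config.drift_scale, rng)
    if config.round_tip_freqs:
        tip_freq = {sp: (f >= 0.5).astype(float) for sp, f in tip_freq.items()}
    pre_event_freq = {sp: f.copy() for sp, f in tip_freq.items()}

    # apply frequency-replacement events; remember polymorphic assignments
    poly_plans = []  # (event, site_mask, donor_allele per site)
    tracts: dict = {}
    for ev in config.events:
        s, e = ev.tract
        in_tract = (pos >= s) & (pos <= e)
        replaced = in_tract & (rng.random(config.n_sites) < ev.rho)
        tracts.setdefault(ev.recipient, []).append((int(s), int(e)))
        if ev.fixation == "fixed":
            tip_freq[ev.recipient] = np.where(
                replaced, tip_freq[ev.donor], tip_freq[ev.recipient]
            )
        else:
            donor_allele = (tip_freq[ev.donor] >= 0.5).astype(np.int8)
            poly_plans.append((ev, replaced, donor_allele))

    # diploid genotypes per species/individual
    sample_names: list = []
    columns: list = []
    groups: dict = {}
    sample_offset: dict = {}
    for sp in species:
        n = SimConfig.individuals_of(config, sp)
        if n < 1:
            raise ConfigError(f"species {sp!r} has no individuals configured")
        sample_offset[sp] = len(sample_names)
        names = [f"{sp}_{k + 1}" for k in range(n)]
        groups[sp] = names
        sample_names.extend(names)
        g = rng.binomial(2, tip_freq[sp][:, None], size=(config.n_sites, n))
        columns.append(g.astype(np.int8))
    genotypes = np.concatenate(columns, axis=1)

    # polymorphic-mode carrier overrides
    for ev, replaced, donor_allele in poly_plans:
        members = groups[ev.recipient]
        assignments = []
        for copies, count in sorted(ev.carriers.items(), reverse=True):
            if copies not in (0, 1, 2):
                raise ConfigError("carrier copy numbers must be 0, 1, or 2")
            assignments.extend([copies] * count)
        if len(assignments) > len(members):
            raise ConfigError("more carriers configured than individuals")
        bg = pre_event_freq[ev.recipient]
        col0 = sample_offset[ev.recipient]
        idx = np.nonzero(replaced)[0]
        for j, copies in enumerate(assignments):
            bg_alt = rng.binomial(2 - copies, bg[idx])
            genotypes[idx, col0 + j] = (copies * donor_allele[idx] + bg_alt).astype(
                np.int8
            )

    if config.missing_rate > 0:
        mask = rng.random(genotypes.shape) < config.missing_rate
        genotypes[mask] = -1

    # REF/ALT alleles: deterministic rotation over bases, ALT != REF
    bases = np.array(list("ACGT"), dtype=object)
    ref = bases[pos % 4]
    alt = bases[(pos + 1 + rng.integers(0, 3, size=config.n_sites)) % 4]
    clash = alt == ref
    alt[clash] = bases[(pos[clash] + 1) % 4]

    geno = GenotypeMatrix(
        np.full(config.n_sites, config.chrom_name, dtype=object),
        pos, ref, alt, genotypes, tuple(sample_names),
    )
    pops = PopulationMap(groups)
    truth = TruthSet(
        tracts=tracts,
        events=list(config.events),
        displacement_events=[],
        species_tree=_trees.write_newick(tree),
    )
    return geno, pops, truth


# ---------------------------------------------------------------------------
# gene trees


def _graft_leaf_inside_clade(
    tree: dendropy.Tree, donor_clade, taxon_label: str, rng: np.random.Generator
) -> None:
    """Prune ``taxon_label`` and re-attach it on a uniformly chosen edge
    inside the donor clade's subtree."""
    taxon = tree.taxon_namespace.get_taxon(taxon_label)
    if taxon is None:
        raise ReferenceLookupError(f"recipient {taxon_label!r} not in tree")
    tree.prune_taxa([taxon], suppress_unifurcations=True)
    mrca = tree.mrca(taxon_labels=list(donor_clade))
    edges = [
        node.edge
        for node in mrca.preorder_iter()
        if node is not mrca and node.edge.length is not None
    ]
    if not edges:
        raise ConfigError("donor clade has no internal structure to graft into")
    edge = edges[rng.integers(len(edges))]
    child, parent = edge.head_node, edge.tail_node
    total = edge.length or 0.0
    frac = float(rng.uniform(0.1, 0.9))
    split = dendropy.Node()
    parent.remove_child(child)
    parent.add_child(split)
    split.edge.length = total * frac
    split.add_child(child)
    child.edge.length = total * (1.0 - frac)
    leaf = dendropy.Node(taxon=taxon)
    split.add_child(leaf)
    leaf.edge.length = total * (1.0 - frac)
    tree.update_bipartitions(suppress_unifurcations=True)


def simulate_gene_trees(
    species_tree: dendropy.Tree | str,
    displacement_events: Sequence[DisplacementEvent],
    n_loci: int,
    seed: int,
    jitter: float = 0.05,
) -> list:
    """Per-locus gene trees: species-tree copies with lognormal branch-length
    jitter; at displaced loci the recipients are pruned and re-grafted on a
    uniformly chosen edge inside the donor clade."""
    if isinstance(species_tree, str):
        species_tree = _trees.parse_newick(species_tree)
    labels = _trees.leaf_labels(species_tree)
    for ev in displacement_events:
        unknown = (set(ev.donor_clade) | set(ev.recipients)) - labels
        if unknown:
            raise ReferenceLookupError(f"taxa not in species tree: {sorted(unknown)}")
        if set(ev.donor_clade) & set(ev.recipients):
            raise ConfigError("recipients overlap donor clade")
    rng = np.random.default_rng(seed)
    out = []
    for locus in range(n_loci):
        gt = _trees.parse_newick(_trees.write_newick(species_tree))
        if jitter > 0:
            for edge in gt.preorder_edge_iter():
                if edge.length is not None:
                    edge.length = float(
                        edge.length * np.exp(rng.normal(0.0, jitter))
                    )
        for ev in displacement_events:
            if ev.loci is not None and locus not in ev.loci:
                continue
            for r in ev.recipients:
                _graft_leaf_inside_clade(gt, ev.donor_clade, r, rng)
        out.append(gt)
    return out


# ---------------------------------------------------------------------------
# on-disk bundle


def write_simulation(out_dir, geno, pops, truth: TruthSet) -> dict:
    """Write VCF + popmap + truth BED + Newick + JSON manifest; return paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out_dir / "sim.vcf",
        "popmap": out_dir / "popmap.tsv",
        "tracts_bed": out_dir / "truth_tracts.bed",
        "species_tree": out_dir / "species_tree.nwk",
        "gene_trees": out_dir / "gene_trees.nwk",
        "manifest": out_dir / "truth.json",
    }
    write_vcf(geno, paths["vcf"])
    write_popmap(pops, paths["popmap"])
    with open(paths["tracts_bed"], "w") as fh:
        for recipient, tracts in truth.tracts.items():
            for s, e in tracts:
                fh.write(f"{geno.chrom[0]}\t{s - 1}\t{e}\t{recipient}\t0\t.\n")
    paths["species_tree"].write_text(truth.species_tree + "\n")
    with open(paths["gene_trees"], "w") as fh:
        for nwk in truth.gene_trees:
            fh.write(nwk + "\n")
    with open(paths["manifest"], "w") as fh:
        json.dump(truth.manifest(), fh, indent=2)
    return {k: str(v) for k, v in paths.items()}
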