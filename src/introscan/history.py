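"""Serial-introgression bookkeeping and introgressed-tract decay.

Three scenario shapes describe how one donor haplotype can reach several
recipient species: ``independent`` (one event per recipient, directly from
the donor), ``hub`` (one recipient receives the haplotype and passes it to
each of the others), and ``chain`` (recipient-to-recipient relay).  The
event count per recipient species is the number of introgression pulses its
haplotype has been through.

Each pulse exposes the tract to fresh recombination in a hybrid background,
so under selection that retains a focal donor site, higher-order recipients
are expected to carry progressively shorter surviving tracts.  The Monte
Carlo decay simulator makes that premise quantitative: crossover
breakpoints accumulate along the tract as a homogeneous Poisson process
with intensity ``r * t`` per unit length, and the surviving tract is the
interval between the nearest breakpoints flanking the focal (selected)
site.  Unlinked donor DNA is ignored: only the tract containing the
selected site is tracked.  One-sided flanks of available length ``f``
survive with mean length ``(1 - exp(-r t f)) / (r t)``, which serves as
the analytic oracle for the simulator.

``infer_transfer_order`` inverts the logic heuristically: recipients ranked
by surviving block length, longest first, approximate the transfer order.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_io import HaplotypeBlock
from .errors import ConfigError, ReferenceLookupError

SCENARIO_KINDS = ("independent", "hub", "chain")


@dataclass(frozen=True)
class Scenario:
    """One hypothesis for how a donor haplotype reached several recipients."""

    kind: str
    donor: str
    recipients: tuple

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise ConfigError(f"kind must be one of {SCENARIO_KINDS}")
        rec = tuple(self.recipients)
        if not rec:
            raise ConfigError("scenario needs at least one recipient")
        if len(set(rec)) != len(rec) or self.donor in rec:
            raise ConfigError("recipients must be distinct and exclude the donor")
        object.__setattr__(self, "recipients", rec)


def scenario_event_counts(s: Scenario) -> dict:
    """Introgression events behind each recipient's haplotype.

    independent: every recipient's haplotype comes from one direct event.
    hub: the first recipient is first-order (1 event); all others received
        the haplotype from it (2 events).
    chain: the k-th recipient in the relay is a k-th-order recipient.
    """
    if s.kind == "independent":
        return {r: 1 for r in s.recipients}
    if s.kind == "hub":
        return {r: (1 if i == 0 else 2) for i, r in enumerate(s.recipients)}
    return {r: i + 1 for i, r in enumerate(s.recipients)}


def infer_transfer_order(blocks: Sequence[HaplotypeBlock]) -> list:
    """Rank recipients by surviving block length, longest first.

    Returns a list of tie groups (lists of labels); rank 1 is the putative
    first-order recipient.  This is a heuristic under the tract-decay model
    above, not a formal estimator.
    """
    if len(blocks) < 2:
        raise ConfigError("need blocks for at least two recipients")
    labels = [b.label for b in blocks]
    if len(set(labels)) != len(labels):
        raise ReferenceLookupError("expected exactly one block per recipient")
    by_len: dict = {}
    for b in blocks:
        by_len.setdefault(b.length, []).append(b.label)
    return [sorted(by_len[ln]) for ln in sorted(by_len, reverse=True)]


# ---------------------------------------------------------------------------
# tract decay


@dataclass(frozen=True)
class DecayParams:
    """Parameters of the tract-decay simulation.

    Units are abstract: only the products ``r * t * length`` matter, so any
    consistent mapping of length to bp or Morgans works.
    """

    L0: float  # initial tract length
    focal_pos: float  # selected site position within [0, L0]
    r: float  # recombination rate per unit length per generation
    t: float  # generations per introgression pulse
    reps: int = 10_000
    seed: int | None = None
    rounds: int = 1  # chained pulses; each acts on the surviving tract

    def __post_init__(self) -> None:
        if self.L0 <= 0 or self.t <= 0 or self.reps < 1 or self.rounds < 1:
            raise ConfigError("L0, t, reps, rounds must be positive")
        if self.r < 0:
            raise ConfigError("recombination rate must be >= 0")
        if not 0.0 <= self.focal_pos <= self.L0:
            raise ConfigError("focal position must lie inside the tract")


@dataclass
class DecayResult:
    mean_length: float
    lengths: np.ndarray

    @property
    def se(self) -> float:
        return float(self.lengths.std(ddof=1) / np.sqrt(self.lengths.size))


def expected_flank_length(r: float, t: float, flank: float) -> float:
    """Closed-form mean surviving one-sided flank of available length
    ``flank``: E[min(Exp(rt), flank)] = (1 - exp(-r t flank)) / (r t)."""
    lam = r * t
    if lam == 0:
        return flank
    return (1.0 - np.exp(-lam * flank)) / lam


def simulate_tract_decay(p: DecayParams) -> DecayResult:
    """Monte Carlo surviving tract length around the selected focal site.

    Per replicate and round, breakpoint count ~ Poisson(r * t * tract
    length) with uniform positions; the surviving tract is bounded by the
    nearest breakpoints flanking the focal site (or the tract ends).
    """
    rng = np.random.default_rng(p.seed)
    reps = p.reps
    left = np.zeros(reps)
    right = np.full(reps, float(p.L0))
    f = float(p.focal_pos)
    lam = p.r * p.t
    for _ in range(p.rounds):
        if lam == 0:
            break
        tract_len = right - left
        counts = rng.poisson(lam * tract_len)
        total = int(counts.sum())
        if total == 0:
            continue
        rep_ids = np.repeat(np.arange(reps), counts)
        u = rng.random(total)
        pts = left[rep_ids] + u * tract_len[rep_ids]
        left_side = pts <= f
        np.maximum.at(left, rep_ids[left_side], pts[left_side])
        np.minimum.at(right, rep_ids[~left_side], pts[~left_side])
    lengths = right - left
    return DecayResult(mean_length=float(lengths.mean()), lengths=lengths)
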