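"""Facilitated-diffusion target search by AGO:siRNA complexes.

Each complex carries one siRNA that matches exactly one RdDM locus.  A
free complex encounters a molecule: with probability ``p_on_target`` an
RdDM-locus molecule (50% for RNA targets, 10% for DNA, reflecting the
fraction of molecules that derive from siRNA-producing loci), otherwise
an anonymous off-target molecule.  An on-target landing hits the
complex's cognate locus with probability ``p_self_target`` — the
sequence-guided component of the search, without which a complex would
sample its one locus among a thousand far too rarely to reinforce it
within a cell cycle — and otherwise a uniformly chosen locus.  On a non-matching
molecule the complex scans a 1-D lattice: per step it exits with
``p_exit_scan``, else jumps to a fresh encounter with ``p_jump`` (10%),
else slides one position left or right (50/50); sliding off either end
is an exit.  Landing on its matching locus, the complex binds if the
locus holds fewer than ``max_occupancy`` (10) complexes, drawing an
exponential dwell with rate ``k_off_match``; a full locus scores an
occupancy rejection — the model's self-inhibition at high siRNA
production.  The search clock ticks every 1 s for RNA and
every 0.3 s for DNA, encoding the ~3x faster DNA on-rate.

Matched bound time ("dwell") is the currency later converted into CHH
methylation gain by the methylation engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from ._kernel import BOUND, FREE, NO_MOLECULE, OFF_TARGET, SCANNING

__all__ = [
    "SearchKinetics",
    "ComplexPopulation",
    "encounter",
    "scan_step",
    "attempt_bind",
    "draw_dwell",
    "advance",
    "FREE",
    "SCANNING",
    "BOUND",
    "OFF_TARGET",
    "NO_MOLECULE",
]

_SEED_MAX = 2**31 - 1


@dataclass(frozen=True)
class SearchKinetics:
    """Kinetic constants of the AGO:siRNA target search.

    ``p_exit_scan`` is the per-step dissociation probability of weak
    (non-matched) scanning contacts, set from the measured off-rates of
    imperfect AGO contacts (0.02/s on RNA, 0.03/s on DNA, times the
    step interval).  ``k_off_match`` is the off-rate of full
    seed-plus-supplementary pairing at the cognate locus; like the
    dwell-to-methylation exchange rate it is internally set (no direct
    measurement exists) so that a searching complex spends roughly a
    tenth of its time bound, giving the median locus thousands of
    reinforcement events per cycle while leaving headroom below the
    occupancy cap for all but the most productive loci.
    """

    target_type: str = "RNA"
    step_interval: float = 1.0  # seconds per shuttling step
    k_off_match: float = 0.5  # 1/s, matched (cognate) binding off-rate
    p_on_target: float = 0.5  # chance an encounter is an RdDM-locus molecule
    p_self_target: float = 1.0  # chance an on-target landing is the cognate locus
    p_jump: float = 0.10
    p_exit_scan: float = 0.02  # per-step exit of weak scanning contacts
    molecule_length: int = 50  # lattice positions per molecule
    max_occupancy: int = 10

    def __post_init__(self) -> None:
        for name in ("p_on_target", "p_self_target", "p_jump", "p_exit_scan"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.step_interval <= 0 or self.k_off_match <= 0:
            raise ValueError("step_interval and k_off_match must be positive")
        if self.molecule_length < 1 or self.max_occupancy < 1:
            raise ValueError("molecule_length and max_occupancy must be >= 1")

    @classmethod
    def rna(cls, **overrides) -> "SearchKinetics":
        """RNA-target kinetics: 1 s steps, 50% on-target, scan exit 0.02/step."""
        kw = dict(
            target_type="RNA", step_interval=1.0, p_on_target=0.5,
            p_exit_scan=0.02, k_off_match=0.5,
        )
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def dna(cls, **overrides) -> "SearchKinetics":
        """DNA-target kinetics: 0.3 s steps, 10% on-target, scan exit 0.03/s.

        The matched off-rate keeps dwell at a DNA target site shorter
        than at an RNA target site.
        """
        kw = dict(
            target_type="DNA", step_interval=0.3, p_on_target=0.1,
            p_exit_scan=0.009, k_off_match=0.75,
        )
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def for_target(cls, target_type: str, **overrides) -> "SearchKinetics":
        t = target_type.upper()
        if t == "RNA":
            return cls.rna(**overrides)
        if t == "DNA":
            return cls.dna(**overrides)
        raise ValueError(f"unknown target type {target_type!r}")


@dataclass
class ComplexPopulation:
    """Structure-of-arrays container for the AGO:siRNA complexes.

    ``target`` is each complex's unique matching locus; ``state`` is
    FREE/SCANNING/BOUND; ``molecule`` the current molecule (locus id,
    OFF_TARGET, or NO_MOLECULE); ``position`` the lattice offset; and
    ``remaining_dwell`` the seconds of matched binding left.
    """

    target: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    state: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    molecule: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    position: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    remaining_dwell: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.float64))

    @classmethod
    def from_targets(cls, targets: np.ndarray) -> "ComplexPopulation":
        """Create a population of free complexes matching ``targets``."""
        n = len(targets)
        return cls(
            target=np.asarray(targets, dtype=np.int64).copy(),
            state=np.full(n, FREE, dtype=np.int64),
            molecule=np.full(n, NO_MOLECULE, dtype=np.int64),
            position=np.zeros(n, dtype=np.int64),
            remaining_dwell=np.zeros(n, dtype=np.float64),
        )

    @property
    def size(self) -> int:
        return self.target.size

    def state_counts(self) -> dict[str, int]:
        return {
            "free": int(np.sum(self.state == FREE)),
            "scanning": int(np.sum(self.state == SCANNING)),
            "bound": int(np.sum(self.state == BOUND)),
        }

    def extend(self, other: "ComplexPopulation") -> "ComplexPopulation":
        """Concatenate two populations (used at steady production events)."""
        return ComplexPopulation(
            target=np.concatenate([self.target, other.target]),
            state=np.concatenate([self.state, other.state]),
            molecule=np.concatenate([self.molecule, other.molecule]),
            position=np.concatenate([self.position, other.position]),
            remaining_dwell=np.concatenate([self.remaining_dwell, other.remaining_dwell]),
        )

    def subset(self, idx: np.ndarray) -> "ComplexPopulation":
        return ComplexPopulation(
            target=self.target[idx],
            state=self.state[idx],
            molecule=self.molecule[idx],
            position=self.position[idx],
            remaining_dwell=self.remaining_dwell[idx],
        )


# ---------------------------------------------------------------------------
# elementary moves (the model's documented transition rules)


def encounter(
    kinetics: SearchKinetics,
    n_loci: int,
    rng: np.random.Generator,
    target_locus: int | None = None,
) -> tuple[int, int]:
    """Sample one encounter landing.

    Returns ``(molecule, position)``.  With probability ``p_on_target``
    the landing is an RdDM-locus molecule — the complex's cognate locus
    ``target_locus`` with probability ``p_self_target`` (the
    sequence-guided component of the search), otherwise a uniformly
    chosen locus; with the remaining probability it is an anonymous
    off-target molecule (``OFF_TARGET``).
    """
    pos = int(rng.integers(0, kinetics.molecule_length))
    if rng.random() < kinetics.p_on_target:
        if target_locus is not None and rng.random() < kinetics.p_self_target:
            return int(target_locus), pos
        return int(rng.integers(0, n_loci)), pos
    return OFF_TARGET, pos


def scan_step(kinetics: SearchKinetics, rng: np.random.Generator) -> str:
    """Sample one scanning event: exit, jump, slide_left or slide_right."""
    if rng.random() < kinetics.p_exit_scan:
        return "exit"
    if rng.random() < kinetics.p_jump:
        return "jump"
    return "slide_left" if rng.random() < 0.5 else "slide_right"


def attempt_bind(
    locus_id: int,
    target_id: int,
    occupancy: np.ndarray,
    rejections: np.ndarray,
    kinetics: SearchKinetics,
) -> str:
    """Attempt matched binding at ``locus_id``.

    Binds only if the locus is the complex's unique match and holds
    fewer than ``max_occupancy`` complexes; a matched-but-full locus
    scores an occupancy rejection.  Returns ``"bound"``,
    ``"rejected_occupancy"`` or ``"no_match"`` and updates the
    occupancy/rejection counters on a bind or rejection.
    """
    if locus_id != target_id:
        return "no_match"
    if occupancy[locus_id] >= kinetics.max_occupancy:
        rejections[locus_id] += 1
        return "rejected_occupancy"
    occupancy[locus_id] += 1
    return "bound"


def draw_dwell(k_off_match: float, rng: np.random.Generator) -> float:
    """Exponential matched-binding dwell time with rate ``k_off_match``."""
    if k_off_match <= 0:
        raise ValueError("k_off_match must be positive")
    return float(rng.exponential(1.0 / k_off_match))


# ---------------------------------------------------------------------------
# population stepping


def advance(
    population: ComplexPopulation,
    loci,
    kinetics: SearchKinetics,
    dt: float | None = None,
    rng: np.random.Generator | None = None,
    n_steps: int = 1,
    dwell_per_percent: float = 0.0,
) -> np.ndarray:
    """Advance the search ``n_steps`` steps of ``dt`` (default the kinetic step).

    Per step, in this order: bound complexes are credited this step's
    matched dwell and released when their dwell expires (searching again
    from the next step); free complexes encounter; scanning complexes
    take one scan event, a jump triggering a fresh encounter within the
    same step.  Binding respects the occupancy cap; within a step,
    complexes act in index order.  ``loci`` must expose ``occupancy``,
    ``chh``, ``cycle_dwell`` and ``occupancy_rejections`` arrays; when
    ``dwell_per_percent > 0`` CHH methylation is continuously updated
    from each step's dwell.  Returns the matched dwell credited per
    locus over the call.
    """
    if dt is None:
        dt = kinetics.step_interval
    if rng is None:
        raise ValueError("an explicit random generator is required")
    seed = int(rng.integers(_SEED_MAX))
    return _kernel.run_steps(
        seed,
        n_steps,
        float(dt),
        population.target,
        population.state,
        population.molecule,
        population.position,
        population.remaining_dwell,
        loci.occupancy,
        loci.chh,
        loci.cycle_dwell,
        loci.occupancy_rejections,
        kinetics.p_on_target,
        kinetics.p_self_target,
        kinetics.p_jump,
        kinetics.p_exit_scan,
        kinetics.molecule_length,
        kinetics.max_occupancy,
        kinetics.k_off_match,
        float(dwell_per_percent),
        loci.chh.size,
    )
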