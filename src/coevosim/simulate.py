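"""In-silico evolution of an MSA with exact coevolution bookkeeping.

A single ancestral sequence is expanded down a copy-tree: each branching
level appends copies of every current lineage, and between expansions every
lineage undergoes cycles of (a) per-position point mutations, (b) forced
covarion-pair co-mutations drawn from a joint residue-pair distribution, and
(c) zone recombination, where a block of columns delimited by fixed
crossover points is copied in from another lineage.

Every cycle the changed-position sets are counted into four symmetric
matrices:

* ``mut_cov`` — pairs of non-covarion positions changed together by point
  mutation;
* ``cov_cov`` — covarion pairs that changed, plus the cross pairs between
  positions of *distinct* covarion pairs changing in the same cycle (two
  pairs co-mutating are indistinguishable, to any detector, from four);
* ``rec_cov`` — pairs of positions changed together by recombination,
  including pairs mixing a point mutation with a recombination change;
* ``tot_cov`` — every counted pair, accumulated in parallel; it equals the
  elementwise sum of the other three by construction, and the equality is a
  standing regression check on the bookkeeping.

The record is the "external observer" of the evolutionary history: a
coevolution detector run on the final alignment can be scored against
``cov_cov`` (the true covarions plus their cross counts) with no appeal to
external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, NamedTuple

import numpy as np

from coevosim.alignment import Alignment, AMINO_ACIDS, N_SYMBOLS


class ConfigError(ValueError):
    """Raised for an invalid simulation configuration."""


@dataclass
class RecombinationMap:
    """Half-open 1-based column intervals delimited by crossover points."""

    zones: list[tuple[int, int]]
    n_pos: int

    @property
    def n_zones(self) -> int:
        return len(self.zones)


def zones_from_crossovers(points: Iterable[int], n_pos: int) -> RecombinationMap:
    """Partition columns 1..n_pos into zones at interior crossover points.

    ``points`` must be strictly increasing and lie strictly inside the
    sequence (2 <= p <= n_pos).  k points produce k+1 zones
    [1, p1), [p1, p2), ..., [pk, n_pos+1).
    """
    pts = [int(p) for p in points]
    if any(b <= a for a, b in zip(pts, pts[1:])):
        raise ConfigError(f"crossover points not strictly increasing: {pts}")
    if pts and (pts[0] < 2 or pts[-1] > n_pos):
        raise ConfigError(f"crossover points out of range (2..{n_pos}): {pts}")
    bounds = [1] + pts + [n_pos + 1]
    zones = list(zip(bounds[:-1], bounds[1:]))
    return RecombinationMap(zones=zones, n_pos=n_pos)


class Event(NamedTuple):
    level: int
    cycle: int
    lineage: int
    mechanism: str
    positions: tuple[int, ...]  # 0-based columns


@dataclass
class EvolutionRecord:
    """Ground-truth count matrices and event log of one simulation."""

    tot_cov: np.ndarray
    mut_cov: np.ndarray
    cov_cov: np.ndarray
    rec_cov: np.ndarray
    events: list[Event] = field(default_factory=list)

    @classmethod
    def zeros(cls, n_pos: int) -> "EvolutionRecord":
        return cls(*(np.zeros((n_pos, n_pos), dtype=np.int64) for _ in range(4)))

    def additivity_holds(self) -> bool:
        """tot_cov == mut_cov + cov_cov + rec_cov, elementwise and exactly."""
        return bool(
            np.array_equal(self.tot_cov, self.mut_cov + self.cov_cov + self.rec_cov)
        )


@dataclass
class SimulationConfig:
    """Parameters of one simulated evolution run.

    Attributes
    ----------
    n_pos : int
        Alignment length (fixed; no indels).
    branching : tuple of int
        Copy counts per level: level 1 makes ``b1`` copies of the ancestor;
        each later level appends ``b_k`` copies of every current lineage.
    cycles_per_level : int or tuple of int
        Mutation/recombination cycles run on every lineage within a level;
        a tuple gives one count per branching level (decreasing counts make
        long internal and short terminal branches, the shape of real
        families in which some sequence pairs stay nearly identical).
    mutation_prob : float
        Per-position, per-cycle probability of a point-mutation draw at
        non-covarion positions.  A draw samples the position's emission
        profile and may return the current residue (silent, not counted).
    covarion_pairs : tuple of (int, int)
        Disjoint 1-based position pairs forced to co-vary.
    covarion_mut_prob : float
        Per-pair, per-cycle probability of a joint co-mutation draw.
    covarion_joint : dict mapping pair -> (21, 21) array, optional
        Joint residue-pair distribution per covarion pair; pairs without an
        entry get a two-state perfectly coupled distribution drawn once from
        the run's RNG.
    crossover_points : tuple of int
        Interior crossover points defining the recombination zones.
    recombination_prob : float
        Per-lineage, per-cycle probability of receiving one zone from a
        uniformly chosen other lineage.
    n_seq : int, optional
        Subsample the final population to this many rows (uniform, without
        replacement, in drawn order); ``None`` keeps every lineage.
    profile : (n_pos, 20) array, optional
        Position-specific amino-acid emission probabilities for the ancestor
        and mutation draws; uniform 1/20 when absent.
    seed : int, optional
        Default RNG seed; an explicit seed passed to :func:`evolve` wins.
    """

    n_pos: int
    branching: tuple[int, ...] = (3, 2, 4)
    cycles_per_level: int | tuple[int, ...] = 10
    mutation_prob: float = 0.01
    covarion_pairs: tuple[tuple[int, int], ...] = ()
    covarion_mut_prob: float = 0.05
    covarion_joint: dict[tuple[int, int], np.ndarray] | None = None
    crossover_points: tuple[int, ...] = ()
    recombination_prob: float = 0.1
    n_seq: int | None = None
    profile: np.ndarray | None = None
    seed: int | None = None

    def validate(self) -> None:
        if self.n_pos < 2:
            raise ConfigError("n_pos must be at least 2")
        if not self.branching or any(b < 1 for b in self.branching):
            raise ConfigError("branching levels must be positive")
        if isinstance(self.cycles_per_level, tuple):
            if len(self.cycles_per_level) != len(self.branching):
                raise ConfigError(
                    "cycles_per_level tuple must have one entry per branching level"
                )
            if any(c < 0 for c in self.cycles_per_level):
                raise ConfigError("cycle counts must be nonnegative")
        elif self.cycles_per_level < 0:
            raise ConfigError("cycles_per_level must be nonnegative")
        for name in ("mutation_prob", "covarion_mut_prob", "recombination_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}={p} outside [0, 1]")
        seen: set[int] = set()
        for i, j in self.covarion_pairs:
            if i == j:
                raise ConfigError(f"covarion pair ({i},{j}) is degenerate")
            if not (1 <= i <= self.n_pos and 1 <= j <= self.n_pos):
                raise ConfigError(f"covarion pair ({i},{j}) out of range")
            if i in seen or j in seen:
                raise ConfigError(
                    f"covarion position reused in pair ({i},{j}); pairs must be disjoint"
                )
            seen.update((i, j))
        zones_from_crossovers(self.crossover_points, self.n_pos)
        if self.profile is not None:
            prof = np.asarray(self.profile, dtype=float)
            if prof.shape != (self.n_pos, len(AMINO_ACIDS)):
                raise ConfigError(
                    f"profile shape {prof.shape} != ({self.n_pos}, {len(AMINO_ACIDS)})"
                )
            if not np.allclose(prof.sum(axis=1), 1.0):
                raise ConfigError("profile rows must each sum to 1")


def _resolved_profile(cfg: SimulationConfig) -> np.ndarray:
    if cfg.profile is not None:
        return np.asarray(cfg.profile, dtype=float)
    return np.full((cfg.n_pos, len(AMINO_ACIDS)), 1.0 / len(AMINO_ACIDS))


def sample_ancestor(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw one ancestral sequence, one residue per position from the profile."""
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    profile = _resolved_profile(cfg)
    cum = profile.cumsum(axis=1)
    u = rng.random(cfg.n_pos)
    codes = np.array(
        [int(np.searchsorted(cum[p], u[p])) for p in range(cfg.n_pos)],
        dtype=np.uint8,
    )
    return np.minimum(codes, len(AMINO_ACIDS) - 1).astype(np.uint8)


def coupled_pair_distribution(
    state_a: tuple[int, int], state_b: tuple[int, int], p: float = 0.5
) -> np.ndarray:
    """Two-state joint residue-pair distribution: state_a with prob p, else state_b."""
    joint = np.zeros((N_SYMBOLS, N_SYMBOLS))
    joint[state_a] = p
    joint[state_b] += 1.0 - p
    return joint


def mutate_covarion_pair(
    joint_dist: np.ndarray, rng: np.random.Generator
) -> tuple[int, int]:
    """Sample one residue pair jointly from a (21, 21) probability table."""
    joint = np.asarray(joint_dist, dtype=float)
    flat = joint.reshape(-1)
    idx = int(np.searchsorted(flat.cumsum(), rng.random()))
    idx = min(idx, flat.size - 1)
    return idx // N_SYMBOLS, idx % N_SYMBOLS


def recombine(
    acceptor: np.ndarray,
    donor: np.ndarray,
    rmap: RecombinationMap,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Replace one uniformly chosen zone of ``acceptor`` with the donor's block.

    Returns the recombinant sequence and the 0-based positions inside the
    zone where the donor actually differed.
    """
    if acceptor.shape != donor.shape:
        raise ValueError("acceptor and donor must have the same length")
    start, stop = rmap.zones[int(rng.integers(rmap.n_zones))]
    lo, hi = start - 1, stop - 1  # to 0-based half-open
    out = acceptor.copy()
    changed = lo + np.nonzero(donor[lo:hi] != acceptor[lo:hi])[0]
    out[lo:hi] = donor[lo:hi]
    return out, changed


def _add_pairs_within(matrices: list[np.ndarray], positions: np.ndarray) -> None:
    if len(positions) < 2:
        return
    iu = np.triu_indices(len(positions), 1)
    a, b = positions[iu[0]], positions[iu[1]]
    for m in matrices:
        np.add.at(m, (a, b), 1)
        np.add.at(m, (b, a), 1)


def _add_pairs_cross(
    matrices: list[np.ndarray], pos_a: np.ndarray, pos_b: np.ndarray
) -> None:
    if len(pos_a) == 0 or len(pos_b) == 0:
        return
    a = np.repeat(pos_a, len(pos_b))
    b = np.tile(pos_b, len(pos_a))
    keep = a != b
    a, b = a[keep], b[keep]
    for m in matrices:
        np.add.at(m, (a, b), 1)
        np.add.at(m, (b, a), 1)


def _count_cycle(
    record: EvolutionRecord,
    mut_positions: np.ndarray,
    changed_cov_pairs: list[tuple[int, int]],
    rec_positions: np.ndarray,
) -> None:
    """Apply the per-cycle counting contract for one lineage.

    Point-mutation pairs go to mut_cov; changed covarion pairs and the cross
    pairs between distinct changed covarion pairs go to cov_cov; pairs within
    the recombined block, and pairs mixing a point mutation with a
    recombination change, go to rec_cov.  tot_cov receives every increment.
    """
    _add_pairs_within([record.mut_cov, record.tot_cov], mut_positions)
    for k, (p, q) in enumerate(changed_cov_pairs):
        _add_pairs_within(
            [record.cov_cov, record.tot_cov], np.array([p, q], dtype=np.intp)
        )
        for p2, q2 in changed_cov_pairs[k + 1 :]:
            _add_pairs_cross(
                [record.cov_cov, record.tot_cov],
                np.array([p, q], dtype=np.intp),
                np.array([p2, q2], dtype=np.intp),
            )
    _add_pairs_within([record.rec_cov, record.tot_cov], rec_positions)
    _add_pairs_cross([record.rec_cov, record.tot_cov], mut_positions, rec_positions)


def evolve(
    cfg: SimulationConfig,
    seed: int | None = None,
    on_cycle_end: Callable[[EvolutionRecord, int, int], None] | None = None,
) -> tuple[Alignment, EvolutionRecord]:
    """Run one seeded simulation.

    Parameters
    ----------
    seed : int, optional
        Overrides ``cfg.seed``; all randomness flows from this one seed.
    on_cycle_end : callable, optional
        Called as ``on_cycle_end(record, level, cycle)`` after every cycle,
        e.g. to verify record invariants mid-run.

    Returns
    -------
    (Alignment, EvolutionRecord)
        The final alignment (subsampled to ``cfg.n_seq`` if requested, in
        drawn order, so the row order carries no residual tree structure)
        and the ground-truth record.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n_pos = cfg.n_pos
    profile = _resolved_profile(cfg)
    cum_profile = profile.cumsum(axis=1)

    ancestor = sample_ancestor(cfg, rng)
    cov_pairs = [(i - 1, j - 1) for i, j in cfg.covarion_pairs]
    non_cov_mask = np.ones(n_pos, dtype=bool)
    for p, q in cov_pairs:
        non_cov_mask[[p, q]] = False

    joints: dict[tuple[int, int], np.ndarray] = {}
    for (p1, q1), (p0, q0) in zip(cov_pairs, cfg.covarion_pairs):
        given = (cfg.covarion_joint or {}).get((p0, q0))
        if given is not None:
            joint = np.asarray(given, dtype=float)
            if joint.shape != (N_SYMBOLS, N_SYMBOLS) or not np.isclose(joint.sum(), 1):
                raise ConfigError(f"bad joint distribution for pair ({p0},{q0})")
        else:
            aa = len(AMINO_ACIDS)
            a1, a2 = rng.choice(aa, size=2, replace=False)
            b1, b2 = rng.choice(aa, size=2, replace=False)
            joint = coupled_pair_distribution((int(a1), int(b1)), (int(a2), int(b2)))
        joints[(p1, q1)] = joint

    rmap = zones_from_crossovers(cfg.crossover_points, n_pos)
    record = EvolutionRecord.zeros(n_pos)
    population: list[np.ndarray] = []

    cycles = (
        cfg.cycles_per_level
        if isinstance(cfg.cycles_per_level, tuple)
        else tuple(cfg.cycles_per_level for _ in cfg.branching)
    )
    for level, b in enumerate(cfg.branching, start=1):
        if not population:
            population = [ancestor.copy() for _ in range(b)]
        else:
            population = population + [s.copy() for s in population for _ in range(b)]
        for cycle in range(cycles[level - 1]):
            n_lin = len(population)
            for li in range(n_lin):
                seq = population[li]

                draw = (rng.random(n_pos) < cfg.mutation_prob) & non_cov_mask
                mut_positions: list[int] = []
                for p in np.nonzero(draw)[0]:
                    new = int(np.searchsorted(cum_profile[p], rng.random()))
                    new = min(new, len(AMINO_ACIDS) - 1)
                    if new != seq[p]:
                        seq[p] = new
                        mut_positions.append(int(p))

                changed_pairs: list[tuple[int, int]] = []
                for p, q in cov_pairs:
                    if rng.random() < cfg.covarion_mut_prob:
                        a, b_res = mutate_covarion_pair(joints[(p, q)], rng)
                        if a != seq[p] or b_res != seq[q]:
                            changed_pairs.append((p, q))
                        seq[p], seq[q] = a, b_res

                rec_positions = np.empty(0, dtype=np.intp)
                if n_lin > 1 and rng.random() < cfg.recombination_prob:
                    donor_i = int(rng.integers(n_lin - 1))
                    if donor_i >= li:
                        donor_i += 1
                    new_seq, rec_positions = recombine(
                        seq, population[donor_i], rmap, rng
                    )
                    population[li] = new_seq

                mut_arr = np.asarray(mut_positions, dtype=np.intp)
                _count_cycle(record, mut_arr, changed_pairs, rec_positions)
                if mut_positions:
                    record.events.append(
                        Event(level, cycle, li, "mutation", tuple(mut_positions))
                    )
                for p, q in changed_pairs:
                    record.events.append(Event(level, cycle, li, "covarion", (p, q)))
                if rec_positions.size:
                    record.events.append(
                        Event(level, cycle, li, "recombination",
                              tuple(int(p) for p in rec_positions))
                    )
            if on_cycle_end is not None:
                on_cycle_end(record, level, cycle)

    indices = np.arange(len(population))
    if cfg.n_seq is not None and cfg.n_seq < len(population):
        indices = rng.choice(len(population), size=cfg.n_seq, replace=False)
    rows = np.stack([population[i] for i in indices])
    ids = [f"seq{int(i) + 1:04d}" for i in indices]
    return Alignment(ids, rows), record


#: Benchmark family geometries: alignment length, covarion count and the
#: interior crossover points used for the corresponding simulations.
FAMILY_PRESETS: dict[str, dict] = {
    "KDO8PS": {
        "n_seq": 348, "n_pos": 280, "n_covarions": 28,
        "crossover_points": (20, 61, 89, 167, 193, 216, 235, 259),
    },
    "ArsA": {
        "n_seq": 202, "n_pos": 583, "n_covarions": 87,
        "crossover_points": (19, 45, 86, 114, 148, 206, 228, 280, 302, 337,
                             361, 388, 423, 453, 503, 519, 567),
    },
    "ArsC": {
        "n_seq": 294, "n_pos": 141, "n_covarions": 21,
        "crossover_points": (9, 12, 34, 65, 93, 107, 127, 137),
    },
    "PHBH": {
        "n_seq": 183, "n_pos": 394, "n_covarions": 59,
        "crossover_points": (12, 45, 69, 102, 159, 184, 210, 237, 269, 293,
                             343, 385),
    },
    "PDR": {
        "n_seq": 271, "n_pos": 321, "n_covarions": 48,
        "crossover_points": (13, 43, 57, 81, 103, 123, 145, 171, 199, 223,
                             245, 277, 291, 309),
    },
    "MDH": {
        "n_seq": 391, "n_pos": 353, "n_covarions": 53,
        "crossover_points": (22, 48, 76, 106, 126, 153, 213, 228, 252, 286,
                             305, 335),
    },
    "Atp11p": {
        "n_seq": 178, "n_pos": 205, "n_covarions": 31,
        "crossover_points": (10, 29, 43, 64, 91, 107, 124, 137, 162, 184),
    },
    "Atp12p": {
        "n_seq": 230, "n_pos": 236, "n_covarions": 24,
        "crossover_points": (12, 37, 57, 70, 103, 122, 142, 178, 211),
    },
}


def preset_config(
    family: str,
    pair_rng: np.random.Generator,
    n_seq: int | None = None,
) -> SimulationConfig:
    """Simulation config mirroring a benchmark family's geometry.

    Alignment length, covarion count and crossover points come from
    :data:`FAMILY_PRESETS`; the tree uses four branching levels (315
    lineages) with decreasing cycle counts (16, 10, 4, 2) so that internal
    branches are long and terminal branches short, the branch-length shape
    of real families.  Covarion pair positions are drawn from ``pair_rng``.
    """
    p = FAMILY_PRESETS[family]
    return SimulationConfig(
        n_pos=p["n_pos"],
        branching=(3, 2, 4, 6),
        cycles_per_level=(16, 10, 4, 2),
        mutation_prob=0.02,
        covarion_pairs=random_disjoint_pairs(p["n_pos"], p["n_covarions"], pair_rng),
        covarion_mut_prob=0.05,
        crossover_points=p["crossover_points"],
        recombination_prob=0.1,
        n_seq=p["n_seq"] if n_seq is None else n_seq,
    )


def random_disjoint_pairs(
    n_pos: int, n_pairs: int, rng: np.random.Generator
) -> tuple[tuple[int, int], ...]:
    """Draw ``n_pairs`` disjoint 1-based position pairs uniformly."""
    if 2 * n_pairs > n_pos:
        raise ConfigError(f"{n_pairs} disjoint pairs need at least {2 * n_pairs} positions")
    chosen = rng.choice(n_pos, size=2 * n_pairs, replace=False) + 1
    return tuple(
        (int(min(a, b)), int(max(a, b)))
        for a, b in zip(chosen[0::2], chosen[1::2])
    )
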