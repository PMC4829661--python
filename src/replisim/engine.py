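"""Event-driven stochastic DNA replication kinetics.

The model: ``N_0`` potential origins are placed uniformly at random on the
genome. Origins fire either *spontaneously* (chromatin-class probabilities
``p_eu >= p_fac >= p_con``) or *induced* by proximity to an active fork (a
Gaussian of distance with s.d. ``sigma``, cut off below ``induced_cutoff``).
Firing closer than the inhibition distance ``d_i`` to an active fork is
forbidden. Each firing creates a bidirectional fork pair and consumes two
units of a diffusible *limiting factor* whose availability grows as
``L(t) = L_max (1 - exp(-t/tau))``; fork collisions free two factors, fork
arrival at a chromosome barrier frees one. Fork speed ramps linearly from 0
to ``nu`` over the first 2.8 h of S-phase and is constant afterwards.

Implementation notes
--------------------
All forks move with the same global speed schedule ``v(t)``, so a fork is
fully described by a *motion invariant*: ``position(t) = c + s(t)`` for a
right-moving fork and ``c - s(t)`` for a left-moving one, where ``s(t)`` is
the cumulative per-fork travel distance. Replicated DNA is held as an ordered
list of disjoint *blocks* whose moving boundaries are exactly the active
forks; block order never changes, collisions occur only between facing
boundaries of adjacent blocks, and every collision/barrier time has a closed
form in ``s``. A binary event heap pops events in chronological order; events
whose forks have died in the meantime are discarded as stale.

Firing attempts follow a rejection-sampling drain loop: whenever at least two
factors are free, uniformly random unfired origins are offered (without
replacement within one attempt round, via partial Fisher-Yates on the live
candidate pool); an origin inside already-replicated DNA is lazily marked
passively replicated, otherwise it fires if a uniform draw falls below its
relative probability ``max(p_class, p_induced)``. A round ends when fewer
than two factors remain free or every candidate has been offered once.

Randomness: one ``numpy.random.Generator`` per run. Draw order: origin
placement, then (induced-only variant) one initial origin choice per
euchromatic zone in zone order, then alternating candidate-index/uniform
draws in event order.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from enum import IntEnum
from heapq import heappop, heappush
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .genome import ChromatinClass, GenomeLayout

__all__ = [
    "ReplicationParams",
    "SpeedSchedule",
    "EventKind",
    "Event",
    "FiringMode",
    "SimulationResult",
    "place_origins",
    "limiting_factor",
    "fork_speed",
    "induced_probability",
    "firing_probability",
    "collision_time",
    "schedule_factor_releases",
    "run_simulation",
    "run_model_variant",
]

@dataclass(frozen=True)
class ReplicationParams:
    """Replication-kinetics parameters (defaults are the HeLa calibration).

    Units: base pairs, seconds, bp/s. ``p_eu/p_fac/p_con`` are *relative*
    firing probabilities in [0, 1] per offer, not rates.
    """

    n_potential_origins: int = 500_000
    limiting_factor_max: int = 12_000
    factor_timescale: float = 900.0  # tau, s (15 min)
    max_fork_speed: float = 28.0  # nu, bp/s
    speed_ramp_duration: float = 10_080.0  # 2.8 h
    induced_sigma: float = 240_000.0  # bp
    induced_cutoff: float = 0.1
    inhibition_distance: float = 55_000.0  # d_i, bp
    p_eu: float = 0.8
    p_fac: float = 0.05
    p_con: float = 0.0
    seed: int = 0
    recording_interval: float = 300.0  # s

    def __post_init__(self) -> None:
        if self.n_potential_origins < 1:
            raise ValueError("n_potential_origins must be >= 1")
        for name in (
            "limiting_factor_max",
            "factor_timescale",
            "max_fork_speed",
            "speed_ramp_duration",
            "induced_sigma",
            "inhibition_distance",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not (0.0 < self.induced_cutoff < 1.0):
            raise ValueError("induced_cutoff must be in (0, 1)")
        if not (0.0 <= self.p_con <= self.p_fac <= self.p_eu <= 1.0):
            raise ValueError("need 0 <= p_con <= p_fac <= p_eu <= 1")

    @property
    def spontaneous_probabilities(self) -> tuple[float, float, float]:
        return (self.p_eu, self.p_fac, self.p_con)

    @property
    def induced_range(self) -> float:
        """Maximum distance at which induced firing is possible (cutoff radius)."""
        return self.induced_sigma * math.sqrt(-2.0 * math.log(self.induced_cutoff))


class SpeedSchedule:
    """Fork speed ``v(t) = nu * min(t/ramp, 1)`` with exact path integrals.

    Provides the cumulative per-fork travel distance ``s(t)`` and its inverse,
    which turn every collision/barrier prediction into a closed form.
    """

    def __init__(self, max_speed: float, ramp_duration: float) -> None:
        self.max_speed = float(max_speed)
        self.ramp = float(ramp_duration)
        self._s_ramp = 0.5 * self.max_speed * self.ramp

    def speed(self, t: float) -> float:
        if t < 0:
            raise ValueError("time must be nonnegative")
        if self.ramp == 0.0 or t >= self.ramp:
            return self.max_speed
        return self.max_speed * t / self.ramp

    def distance(self, t: float) -> float:
        """s(t): distance travelled by one fork from time 0 to t."""
        if t < 0:
            raise ValueError("time must be nonnegative")
        if self.ramp == 0.0:
            return self.max_speed * t
        if t < self.ramp:
            return 0.5 * self.max_speed * t * t / self.ramp
        return self._s_ramp + self.max_speed * (t - self.ramp)

    def time_at_distance(self, s: float) -> float:
        """Inverse of :meth:`distance` (s >= 0)."""
        if s < 0:
            raise ValueError("distance must be nonnegative")
        if self.ramp == 0.0:
            return s / self.max_speed
        if s < self._s_ramp:
            return math.sqrt(2.0 * self.ramp * s / self.max_speed)
        return self.ramp + (s - self._s_ramp) / self.max_speed


def fork_speed(t: float, max_speed: float = 28.0, ramp_duration: float = 10_080.0) -> float:
    """Instantaneous fork speed (bp/s) under the linear early-S ramp."""
    return SpeedSchedule(max_speed, ramp_duration).speed(t)


def limiting_factor(t: float, l_max: int = 12_000, tau: float = 900.0) -> int:
    """Available limiting-factor count ``floor(L_max (1 - e^{-t/tau}))``."""
    if t < 0:
        raise ValueError("time must be nonnegative")
    if tau == 0.0:
        return int(l_max)
    return int(math.floor(l_max * (1.0 - math.exp(-t / tau))))


def schedule_factor_releases(l_max: int = 12_000, tau: float = 900.0) -> np.ndarray:
    """Times at which ``floor(L(t))`` increments, k = 1..L_max.

    The k-th factor becomes available at ``t_k = -tau ln(1 - k/L_max)``. The
    final increment (k = L_max) lies at infinity; it is granted at the time
    where ``L(t) = L_max - 1/2``, i.e. ``tau ln(2 L_max)``.
    """
    k = np.arange(1, l_max + 1, dtype=float)
    with np.errstate(divide="ignore"):
        t = -tau * np.log1p(-k / l_max)
    t[-1] = tau * math.log(2.0 * l_max)
    return t


def induced_probability(
    distance: float,
    sigma: float = 240_000.0,
    cutoff: float = 0.1,
    inhibition_distance: float = 55_000.0,
) -> float:
    """Relative probability of fork-induced firing at the given distance.

    Gaussian ``exp(-d^2 / 2 sigma^2)``, zero inside the inhibition distance
    (strictly below ``d_i``; at exactly ``d_i`` firing is allowed) and zero
    when the Gaussian falls strictly below the cutoff (at exactly the cutoff
    it is kept).
    """
    if distance < 0:
        raise ValueError("distance must be nonnegative")
    if distance < inhibition_distance:
        return 0.0
    if sigma == 0.0:
        return 0.0 if distance > 0 else 1.0
    g = math.exp(-0.5 * (distance / sigma) ** 2)
    return g if g >= cutoff else 0.0


def firing_probability(
    spontaneous_p: float,
    fork_distances: np.ndarray | list[float],
    params: ReplicationParams,
) -> tuple[float, FiringMode]:
    """Relative firing probability of an unfired origin, with mode attribution.

    ``fork_distances`` are distances to all active forks on the origin's own
    chromosome (induced firing never crosses barriers). The probability is
    the maximum of the spontaneous and the per-fork induced terms; it is zero
    outright if any such fork is closer than the inhibition distance. The
    mode is spontaneous iff the spontaneous term attains the maximum (ties
    count as spontaneous).
    """
    d = np.asarray(fork_distances, dtype=float)
    if d.size and float(d.min()) < params.inhibition_distance:
        return 0.0, FiringMode.SPONTANEOUS
    induced = 0.0
    if d.size:
        induced = induced_probability(
            float(d.min()), params.induced_sigma, params.induced_cutoff, params.inhibition_distance
        )
    if spontaneous_p >= induced:
        return spontaneous_p, FiringMode.SPONTANEOUS
    return induced, FiringMode.INDUCED


def collision_time(gap: float, schedule: SpeedSchedule, t_ref: float = 0.0) -> float:
    """Time at which two facing forks separated by ``gap`` at ``t_ref`` meet.

    Solves ``gap = 2 (s(t) - s(t_ref))`` exactly via the inverse path
    integral (exact also during the speed ramp).
    """
    if gap < 0:
        raise ValueError("gap must be nonnegative")
    return schedule.time_at_distance(schedule.distance(t_ref) + 0.5 * gap)


def place_origins(layout: GenomeLayout, n_origins: int, seed_or_rng) -> np.ndarray:
    """Uniformly random, sorted potential-origin positions on the global axis."""
    if n_origins < 1:
        raise ValueError("n_origins must be >= 1")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    pos = rng.random(n_origins) * layout.total_length
    pos.sort()
    return pos


class EventKind(IntEnum):
    """Chronological event types; the value doubles as the same-time priority."""

    FORK_COLLISION = 0
    BARRIER_ARRIVAL = 1
    ZONE_CROSSING = 2  # bookkeeping only; never alters dynamics
    FACTOR_RELEASE = 3
    RECORD = 4
    RETRY_FIRING = 5


@dataclass(frozen=True)
class Event:
    time: float
    kind: EventKind
    position: float = 0.0
    payload: tuple = ()


class FiringMode(IntEnum):
    SPONTANEOUS = 0
    INDUCED = 1


class _Block:
    """A maximal replicated interval; moving boundaries are active forks."""

    __slots__ = (
        "chrom",
        "l_moving", "l_val", "l_fork", "l_origin", "l_attrib",
        "r_moving", "r_val", "r_fork", "r_origin", "r_attrib",
    )

    def __init__(self, chrom, l_val, l_fork, r_val, r_fork, origin, pos):
        self.chrom = chrom
        self.l_moving = True
        self.l_val = l_val  # invariant: pos = l_val - s(t)
        self.l_fork = l_fork
        self.l_origin = origin
        self.l_attrib = pos
        self.r_moving = True
        self.r_val = r_val  # invariant: pos = r_val + s(t)
        self.r_fork = r_fork
        self.r_origin = origin
        self.r_attrib = pos

    def left_pos(self, s: float) -> float:
        return self.l_val - s if self.l_moving else self.l_val

    def right_pos(self, s: float) -> float:
        return self.r_val + s if self.r_moving else self.r_val


@dataclass
class SimulationResult:
    """Complete output of one replication run."""

    variant: str
    seed: int
    completion_time: float
    firing_positions: np.ndarray
    firing_times: np.ndarray
    firing_modes: np.ndarray  # FiringMode values
    firing_classes: np.ndarray  # ChromatinClass values
    replicons: pd.DataFrame  # origin, t_fire, left, right
    timeseries: pd.DataFrame
    fork_snapshots: dict[float, np.ndarray]
    barriers: np.ndarray
    total_length: float
    params: ReplicationParams

    @property
    def n_firings(self) -> int:
        return len(self.firing_positions)

    @property
    def spontaneous_fraction(self) -> float:
        if self.n_firings == 0:
            return float("nan")
        return float(np.mean(self.firing_modes == FiringMode.SPONTANEOUS))

    def replicated_fraction_at(self, t: float) -> float:
        """Total replicated fraction at time t, interpolated from the exact
        per-record totals (records are exact; between records the total is
        piecewise smooth, so linear interpolation is used)."""
        ts = self.timeseries
        return float(
            np.interp(t, ts["time"].to_numpy(), ts["replicated_total"].to_numpy())
            / self.total_length
        )

    # -- persistence ---------------------------------------------------------

    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {
                "position": self.firing_positions,
                "time": self.firing_times,
                "mode": [FiringMode(m).name.lower() for m in self.firing_modes],
                "chromatin_class": [ChromatinClass(c).name for c in self.firing_classes],
            }
        ).to_csv(path / "firings.csv", index=False)
        self.replicons.to_csv(path / "replicons.csv", index=False)
        self.timeseries.to_csv(path / "timeseries.csv", index=False)
        snaps = {f"{t:.6f}": snap.tolist() for t, snap in self.fork_snapshots.items()}
        meta = {
            "variant": self.variant,
            "seed": self.seed,
            "completion_time": self.completion_time,
            "total_length": self.total_length,
            "barriers": self.barriers.tolist(),
            "params": {k: v for k, v in self.params.__dict__.items()},
            "fork_snapshots": snaps,
        }
        (path / "summary.json").write_text(json.dumps(meta))

    @classmethod
    def from_dir(cls, path: str | Path) -> "SimulationResult":
        path = Path(path)
        meta = json.loads((path / "summary.json").read_text())
        firings = pd.read_csv(path / "firings.csv")
        return cls(
            variant=meta["variant"],
            seed=meta["seed"],
            completion_time=meta["completion_time"],
            firing_positions=firings["position"].to_numpy(),
            firing_times=firings["time"].to_numpy(),
            firing_modes=np.array(
                [FiringMode[m.upper()] for m in firings["mode"]], dtype=np.int8
            ),
            firing_classes=np.array(
                [ChromatinClass[c] for c in firings["chromatin_class"]], dtype=np.int8
            ),
            replicons=pd.read_csv(path / "replicons.csv"),
            timeseries=pd.read_csv(path / "timeseries.csv"),
            fork_snapshots={
                float(t): np.asarray(v) for t, v in meta["fork_snapshots"].items()
            },
            barriers=np.asarray(meta["barriers"]),
            total_length=meta["total_length"],
            params=ReplicationParams(**meta["params"]),
        )


class ReplicationSimulator:
    """One seeded replication run over a genome layout.

    Use :func:`run_simulation` / :func:`run_model_variant` unless you need
    step-level access (the brute-force cross-check tests do).
    """

    def __init__(
        self,
        layout: GenomeLayout,
        params: ReplicationParams,
        variant: str = "combined",
        snapshot_times: tuple[float, ...] | None = None,
        record_decisions: bool = False,
        invariant_hook: Callable | None = None,
    ) -> None:
        if variant not in ("combined", "spontaneous_only", "induced_only"):
            raise ValueError(f"unknown variant {variant!r}")
        self.layout = layout
        self.params = params
        self.variant = variant
        self.schedule = SpeedSchedule(params.max_fork_speed, params.speed_ramp_duration)
        self.rng = np.random.default_rng(params.seed)
        self.record_decisions = record_decisions
        self.decision_log: list[tuple] = []
        self.invariant_hook = invariant_hook

        self.use_induced = variant != "spontaneous_only"
        if variant == "induced_only":
            self.p_class = (0.0, 0.0, 0.0)
        else:
            self.p_class = params.spontaneous_probabilities
        self.induced_range = params.induced_range if self.use_induced else 0.0

        # static genome arrays
        self.total_length = layout.total_length
        self.barriers = layout.barriers
        self._barrier_list = layout.barriers.tolist()
        self.zone_starts = layout.zone_starts
        self.zone_class_arr = layout.zone_class

        opos = place_origins(layout, params.n_potential_origins, self.rng)
        self.origin_pos_arr = opos
        self.origin_class_arr = np.asarray(layout.class_at(opos), dtype=np.int8)
        self.origin_chrom_arr = np.asarray(layout.chromosome_index_at(opos), dtype=np.int32)
        self.opos = opos.tolist()
        self.oclass = self.origin_class_arr.tolist()
        self.ochrom = self.origin_chrom_arr.tolist()
        n0 = params.n_potential_origins
        self.origin_state = np.zeros(n0, dtype=np.int8)  # 0 unfired, 1 fired, 2 passive
        self.pool = list(range(n0))
        self.m = n0  # live candidates in pool[:m]

        # dynamic state
        self.blocks: list[_Block] = []
        self.forks: dict[int, tuple[_Block, int]] = {}  # fork id -> (block, side 0=left 1=right)
        self._next_fork_id = 0
        self.free_factors = 0
        self.n_released = 0
        self.moving_forks = 0
        self.cov_const = 0.0  # replicated(t) = cov_const + moving_forks * s(t)
        self.class_replicated = [0.0, 0.0, 0.0]
        self.t = 0.0
        self.s = 0.0
        self.completed = False
        self.completion_time = math.nan
        self._suppress_until_s = -1.0

        # outputs
        self.f_pos: list[float] = []
        self.f_time: list[float] = []
        self.f_mode: list[int] = []
        self.f_class: list[int] = []
        self.rep_origin: list[float] = []
        self.rep_t: list[float] = []
        self.rep_left: list[float] = []
        self.rep_right: list[float] = []
        self._rep_index: dict[int, int] = {}  # origin index -> replicon row
        self.ts_rows: list[tuple] = []
        self.fork_snapshots: dict[float, np.ndarray] = {}
        self._snapshot_times = tuple(snapshot_times or ())

        # event heap
        self.heap: list[tuple] = []
        self._seq = 0
        self._n_dynamic = 0  # pending collision/barrier/factor/retry events
        for t_k in schedule_factor_releases(params.limiting_factor_max, params.factor_timescale):
            self._push(t_k, EventKind.FACTOR_RELEASE, 0.0, ())
        if params.recording_interval > 0:
            self._push(params.recording_interval, EventKind.RECORD, 0.0, ())
        for t_snap in self._snapshot_times:
            self._push(t_snap, EventKind.RECORD, 0.0, ("snapshot",))

        if variant == "induced_only":
            self._fire_initial_euchromatic_origins()
        self._record_row()  # t = 0 baseline

    # ------------------------------------------------------------------ heap

    def _push(self, t: float, kind: EventKind, pos: float, payload: tuple) -> None:
        self._seq += 1
        heappush(self.heap, (t, int(kind), pos, self._seq, payload))
        if kind in (
            EventKind.FORK_COLLISION,
            EventKind.BARRIER_ARRIVAL,
            EventKind.FACTOR_RELEASE,
            EventKind.RETRY_FIRING,
        ):
            self._n_dynamic += 1

    # --------------------------------------------------------- block queries

    def _find_block_left_of(self, x: float) -> int:
        """Index of rightmost block whose left boundary is <= x, else -1."""
        blocks = self.blocks
        s = self.s
        lo, hi = 0, len(blocks)
        while lo < hi:
            mid = (lo + hi) // 2
            b = blocks[mid]
            lp = b.l_val - s if b.l_moving else b.l_val
            if lp <= x:
                lo = mid + 1
            else:
                hi = mid
        return lo - 1

    def is_replicated(self, x: float) -> bool:
        i = self._find_block_left_of(x)
        if i < 0:
            return False
        b = self.blocks[i]
        rp = b.r_val + self.s if b.r_moving else b.r_val
        return x <= rp

    def active_fork_positions(self) -> np.ndarray:
        out = []
        s = self.s
        for b in self.blocks:
            if b.l_moving:
                out.append(b.l_val - s)
            if b.r_moving:
                out.append(b.r_val + s)
        return np.asarray(sorted(out))

    # ----------------------------------------------------------- bookkeeping

    def _attribute(self, a: float, b: float) -> None:
        """Credit replicated interval [a, b) to per-class totals."""
        if b <= a:
            return
        zs = self.zone_starts
        ia = int(np.searchsorted(zs, a, side="right")) - 1
        ib = int(np.searchsorted(zs, b, side="right")) - 1
        cls = self.zone_class_arr
        if ia == ib:
            self.class_replicated[cls[ia]] += b - a
            return
        self.class_replicated[cls[ia]] += zs[ia + 1] - a
        for i in range(ia + 1, ib):
            self.class_replicated[cls[i]] += zs[i + 1] - zs[i]
        self.class_replicated[cls[ib]] += b - zs[ib]

    def _record_row(self, snapshot: bool = False) -> None:
        s = self.s
        fork_pos = []
        for b in self.blocks:
            if b.l_moving:
                p = b.l_val - s
                self._attribute(p, b.l_attrib)
                b.l_attrib = p
                fork_pos.append(p)
            if b.r_moving:
                p = b.r_val + s
                self._attribute(b.r_attrib, p)
                b.r_attrib = p
                fork_pos.append(p)
        fork_pos_arr = np.asarray(fork_pos)
        counts = [0, 0, 0]
        if len(fork_pos):
            fc = self.zone_class_arr[
                np.searchsorted(self.zone_starts, fork_pos_arr, side="right") - 1
            ]
            for c in range(3):
                counts[c] = int(np.sum(fc == c))
        self.ts_rows.append(
            (
                self.t,
                self.cov_const + self.moving_forks * s,
                self.class_replicated[0],
                self.class_replicated[1],
                self.class_replicated[2],
                counts[0],
                counts[1],
                counts[2],
                self.moving_forks,
                self.free_factors,
                len(self.f_pos),
            )
        )
        if snapshot:
            fork_pos_arr.sort()
            self.fork_snapshots[self.t] = fork_pos_arr

    # ---------------------------------------------------------------- firing

    def _new_fork_id(self) -> int:
        self._next_fork_id += 1
        return self._next_fork_id

    def _fire(self, oi: int, insert_at: int, mode: int) -> None:
        """Fire origin ``oi``; create a block at pool insertion index."""
        pos = self.opos[oi]
        chrom = self.ochrom[oi]
        s = self.s
        self.origin_state[oi] = 1
        self.f_pos.append(pos)
        self.f_time.append(self.t)
        self.f_mode.append(mode)
        self.f_class.append(self.oclass[oi])
        self._rep_index[oi] = len(self.rep_origin)
        self.rep_origin.append(pos)
        self.rep_t.append(self.t)
        self.rep_left.append(math.nan)
        self.rep_right.append(math.nan)

        lf, rf = self._new_fork_id(), self._new_fork_id()
        blk = _Block(chrom, pos + s, lf, pos - s, rf, oi, pos)
        self.blocks.insert(insert_at, blk)
        self.forks[lf] = (blk, 0)
        self.forks[rf] = (blk, 1)
        self.moving_forks += 2
        self.cov_const -= 2.0 * s
        self.free_factors -= 2

        # schedule next event for each new fork
        left_nb = self.blocks[insert_at - 1] if insert_at > 0 else None
        if left_nb is not None and left_nb.chrom == chrom and left_nb.r_moving:
            s_c = 0.5 * (blk.l_val - left_nb.r_val)
            self._push(
                self.schedule.time_at_distance(s_c),
                EventKind.FORK_COLLISION,
                left_nb.r_val + s_c,
                (left_nb.r_fork, lf),
            )
        else:
            bpos = self._barrier_list[chrom]
            self._push(
                self.schedule.time_at_distance(blk.l_val - bpos),
                EventKind.BARRIER_ARRIVAL,
                bpos,
                (lf,),
            )
        right_nb = self.blocks[insert_at + 1] if insert_at + 1 < len(self.blocks) else None
        if right_nb is not None and right_nb.chrom == chrom and right_nb.l_moving:
            s_c = 0.5 * (right_nb.l_val - blk.r_val)
            self._push(
                self.schedule.time_at_distance(s_c),
                EventKind.FORK_COLLISION,
                blk.r_val + s_c,
                (rf, right_nb.l_fork),
            )
        else:
            bpos = self._barrier_list[chrom + 1]
            self._push(
                self.schedule.time_at_distance(bpos - blk.r_val),
                EventKind.BARRIER_ARRIVAL,
                bpos,
                (rf,),
            )

    def _fire_initial_euchromatic_origins(self) -> None:
        """Induced-only variant: one random origin per euchromatic zone at t=0."""
        zs, ze = self.layout.zone_starts, self.layout.zone_ends
        for zi in np.flatnonzero(self.zone_class_arr == ChromatinClass.EU):
            lo = int(np.searchsorted(self.origin_pos_arr, zs[zi], side="left"))
            hi = int(np.searchsorted(self.origin_pos_arr, ze[zi], side="left"))
            if hi <= lo:
                continue  # zone holds no potential origin
            oi = int(self.rng.integers(lo, hi))
            if self.origin_state[oi] != 0:
                continue
            insert_at = self._find_block_left_of(self.opos[oi]) + 1
            self._fire(oi, insert_at, FiringMode.INDUCED)
        # remove fired origins from the candidate pool lazily is fine, but the
        # pool is still fully populated: drop them now to keep it consistent.
        fired = set(np.flatnonzero(self.origin_state == 1).tolist())
        if fired:
            self.pool = [i for i in self.pool if i not in fired]
            self.m = len(self.pool)

    def _evaluate(self, oi: int) -> tuple[float, int, int, float]:
        """(probability, mode, insert_index, excess) for an uncovered origin.

        ``excess`` is how much farther the nearest same-chromosome fork is
        than the induced range (inf when no fork can ever reach the origin by
        movement alone); it powers the no-candidate retry bound.
        """
        x = self.opos[oi]
        chrom = self.ochrom[oi]
        s = self.s
        i = self._find_block_left_of(x)
        d_min = math.inf
        if i >= 0:
            b = self.blocks[i]
            if b.chrom == chrom and b.r_moving:
                d_min = x - (b.r_val + s)
        if i + 1 < len(self.blocks):
            b = self.blocks[i + 1]
            if b.chrom == chrom and b.l_moving:
                d = (b.l_val - s) - x
                if d < d_min:
                    d_min = d
        spont = self.p_class[self.oclass[oi]]
        if math.isfinite(d_min):
            if d_min < self.params.inhibition_distance:
                return 0.0, FiringMode.SPONTANEOUS, i + 1, 0.0
            induced = 0.0
            if self.use_induced and d_min <= self.induced_range:
                g = math.exp(-0.5 * (d_min / self.params.induced_sigma) ** 2)
                if g >= self.params.induced_cutoff:
                    induced = g
            excess = max(d_min - self.induced_range, 0.0)
            if spont >= induced:
                return spont, FiringMode.SPONTANEOUS, i + 1, excess
            return induced, FiringMode.INDUCED, i + 1, excess
        return spont, FiringMode.SPONTANEOUS, i + 1, math.inf

    def attempt_firings(self) -> int:
        """Drain-loop firing attempts; returns the number of origins fired."""
        if self.m == 0 or self.free_factors < 2:
            return 0
        if self.s < self._suppress_until_s:
            return 0
        rng = self.rng
        pool = self.pool
        opos = self.opos
        oclass = self.oclass
        ochrom = self.ochrom
        blocks = self.blocks
        p_class = self.p_class
        d_i = self.params.inhibition_distance
        sigma = self.params.induced_sigma
        cutoff = self.params.induced_cutoff
        rng_int = rng.integers
        rng_u = rng.random
        remaining = self.m
        fired = 0
        round_max_p = 0.0
        min_excess = math.inf
        while self.free_factors >= 2 and remaining > 0:
            j = int(rng_int(remaining)) if remaining > 1 else 0
            oi = pool[j]
            remaining -= 1
            pool[j] = pool[remaining]
            pool[remaining] = oi
            x = opos[oi]
            s = self.s
            # binary search: rightmost block with left boundary <= x
            lo, hi = 0, len(blocks)
            while lo < hi:
                mid = (lo + hi) // 2
                b = blocks[mid]
                if (b.l_val - s if b.l_moving else b.l_val) <= x:
                    lo = mid + 1
                else:
                    hi = mid
            i = lo - 1
            chrom = ochrom[oi]
            d_min = math.inf
            if i >= 0:
                b = blocks[i]
                if b.r_moving:
                    rp = b.r_val + s
                    if x <= rp:
                        # lazily mark passively replicated, drop from pool
                        self.origin_state[oi] = 2
                        self.m -= 1
                        pool[remaining] = pool[self.m]
                        pool[self.m] = oi
                        continue
                    if b.chrom == chrom:
                        d_min = x - rp
                elif x <= b.r_val:
                    self.origin_state[oi] = 2
                    self.m -= 1
                    pool[remaining] = pool[self.m]
                    pool[self.m] = oi
                    continue
            if i + 1 < len(blocks):
                b = blocks[i + 1]
                if b.chrom == chrom and b.l_moving:
                    d = (b.l_val - s) - x
                    if d < d_min:
                        d_min = d
            # relative firing probability: max(spontaneous, induced), with
            # hard inhibition inside d_i of the nearest same-chromosome fork
            spont = p_class[oclass[oi]]
            if d_min < math.inf:
                if d_min < d_i:
                    continue  # inhibited: probability zero
                induced = 0.0
                if self.use_induced and d_min <= self.induced_range:
                    g = math.exp(-0.5 * (d_min / sigma) ** 2)
                    if g >= cutoff:
                        induced = g
                if induced > spont:
                    p, mode = induced, FiringMode.INDUCED
                else:
                    p, mode = spont, FiringMode.SPONTANEOUS
                if p <= 0.0:
                    e = d_min - self.induced_range
                    if e < min_excess:
                        min_excess = e if e > 0.0 else 0.0
                    continue
            else:
                p, mode = spont, FiringMode.SPONTANEOUS
                if p <= 0.0:
                    continue  # no fork on this chromosome can ever reach it
            round_max_p = p if p > round_max_p else round_max_p
            u = rng_u()
            if self.record_decisions:
                self.decision_log.append((oi, u))
            if u < p:
                self.m -= 1
                pool[remaining] = pool[self.m]
                pool[self.m] = oi
                self._fire(oi, i + 1, mode)
                fired += 1
        if (
            fired == 0
            and remaining == 0
            and round_max_p == 0.0
            and self.free_factors >= 2
            and self.m > 0
        ):
            # nothing can fire until some fork has travelled min_excess further
            if math.isfinite(min_excess):
                self._suppress_until_s = self.s + min_excess
                self._push(
                    self.schedule.time_at_distance(self._suppress_until_s),
                    EventKind.RETRY_FIRING,
                    0.0,
                    (),
                )
            else:
                self._suppress_until_s = math.inf
        elif fired:
            self._suppress_until_s = -1.0
        return fired

    # ---------------------------------------------------------------- events

    def _die_fork(self, blk: _Block, side: int, pos: float) -> None:
        """Freeze one boundary fork at ``pos``; updates attribution/replicons."""
        if side == 1:
            self._attribute(blk.r_attrib, pos)
            blk.r_attrib = pos
            del self.forks[blk.r_fork]
            blk.r_moving = False
            blk.r_val = pos
            ri = self._rep_index[blk.r_origin]
            self.rep_right[ri] = pos
        else:
            self._attribute(pos, blk.l_attrib)
            blk.l_attrib = pos
            del self.forks[blk.l_fork]
            blk.l_moving = False
            blk.l_val = pos
            ri = self._rep_index[blk.l_origin]
            self.rep_left[ri] = pos
        self.moving_forks -= 1
        self.cov_const += self.s

    def _handle_collision(self, payload: tuple) -> bool:
        fa, fb = payload
        forks = self.forks
        if fa not in forks or fb not in forks:
            return False  # stale: a participant annihilated earlier
        X, sa = forks[fa]
        Y, sb = forks[fb]
        assert sa == 1 and sb == 0, "collision event must pair facing boundaries"
        s_c = 0.5 * (Y.l_val - X.r_val)
        pos = X.r_val + s_c
        self._die_fork(X, 1, pos)
        self._die_fork(Y, 0, pos)
        # merge Y into X
        X.r_moving = Y.r_moving
        X.r_val = Y.r_val
        X.r_fork = Y.r_fork
        X.r_origin = Y.r_origin
        X.r_attrib = Y.r_attrib
        if Y.r_moving:
            forks[Y.r_fork] = (X, 1)
        yi = self._find_block_index(Y)
        self.blocks.pop(yi)
        self.free_factors += 2
        return True

    def _find_block_index(self, blk: _Block) -> int:
        lp = blk.l_val - self.s if blk.l_moving else blk.l_val
        i = self._find_block_left_of(lp + 1e-9)
        while i >= 0 and self.blocks[i] is not blk:
            i -= 1
        if i < 0:
            raise RuntimeError("internal inconsistency: block not found")
        return i

    def _handle_barrier(self, payload: tuple, pos: float) -> bool:
        (f,) = payload
        if f not in self.forks:
            return False
        blk, side = self.forks[f]
        self._die_fork(blk, side, pos)
        self.free_factors += 1
        return True

    def _check_completion(self) -> None:
        """Completion is structural: one fully frozen block per chromosome,
        each spanning exactly [barrier, barrier) (frozen values are assigned
        from the barrier list, so the comparison is exact)."""
        if self.moving_forks != 0 or self.completed:
            return
        if len(self.blocks) != self.layout.n_chromosomes:
            return
        barriers = self._barrier_list
        for i, b in enumerate(self.blocks):
            if b.l_moving or b.r_moving:
                return
            if b.chrom != i or b.l_val != barriers[i] or b.r_val != barriers[i + 1]:
                return
        self.completed = True
        self.completion_time = self.t

    def step(self) -> Event | None:
        """Process the next event; returns it, or None when the run is over."""
        while self.heap:
            t, kind, pos, _seq, payload = heappop(self.heap)
            kind = EventKind(kind)
            if kind in (
                EventKind.FORK_COLLISION,
                EventKind.BARRIER_ARRIVAL,
                EventKind.FACTOR_RELEASE,
                EventKind.RETRY_FIRING,
            ):
                self._n_dynamic -= 1
            self.t = t
            self.s = self.schedule.distance(t)
            if kind == EventKind.FORK_COLLISION:
                if not self._handle_collision(payload):
                    continue
                self._check_completion()
                if self.invariant_hook is not None:
                    self.invariant_hook(self)
                if not self.completed:
                    self.attempt_firings()
            elif kind == EventKind.BARRIER_ARRIVAL:
                if not self._handle_barrier(payload, pos):
                    continue
                self._check_completion()
                if self.invariant_hook is not None:
                    self.invariant_hook(self)
                if not self.completed:
                    self.attempt_firings()
            elif kind == EventKind.FACTOR_RELEASE:
                self.n_released += 1
                self.free_factors += 1
                if self.invariant_hook is not None:
                    self.invariant_hook(self)
                if not self.completed and self.free_factors >= 2:
                    self.attempt_firings()
            elif kind == EventKind.RETRY_FIRING:
                self._suppress_until_s = -1.0
                if not self.completed:
                    self.attempt_firings()
            elif kind == EventKind.RECORD:
                if payload == ("snapshot",):
                    self._record_row(snapshot=True)
                else:
                    self._record_row()
                    if not self.completed:
                        self._push(
                            t + self.params.recording_interval, EventKind.RECORD, 0.0, ()
                        )
                if (
                    not self.completed
                    and self._n_dynamic == 0
                    and self.moving_forks == 0
                ):
                    raise RuntimeError(
                        "no progress possible: unreplicated DNA remains but no "
                        "active forks and no origin has positive firing probability"
                    )
            return Event(t, kind, pos, payload)
        if not self.completed:
            raise RuntimeError(
                "event heap exhausted before genome completion: unreplicated DNA "
                "remains and no origin can ever fire (diagnostic: "
                f"replicated {self.cov_const:.0f} of {self.total_length:.0f} bp)"
            )
        return None

    def run(self) -> SimulationResult:
        while not self.completed:
            self.step()
        self._record_row()  # final row at completion time
        return self._result()

    def _result(self) -> SimulationResult:
        ts = pd.DataFrame(
            self.ts_rows,
            columns=[
                "time",
                "replicated_total",
                "replicated_eu",
                "replicated_fac",
                "replicated_con",
                "forks_eu",
                "forks_fac",
                "forks_con",
                "forks_total",
                "free_factors",
                "n_fired",
            ],
        )
        replicons = pd.DataFrame(
            {
                "origin": self.rep_origin,
                "t_fire": self.rep_t,
                "left": self.rep_left,
                "right": self.rep_right,
            }
        ).sort_values("origin", ignore_index=True)
        return SimulationResult(
            variant=self.variant,
            seed=self.params.seed,
            completion_time=self.completion_time,
            firing_positions=np.asarray(self.f_pos),
            firing_times=np.asarray(self.f_time),
            firing_modes=np.asarray(self.f_mode, dtype=np.int8),
            firing_classes=np.asarray(self.f_class, dtype=np.int8),
            replicons=replicons,
            timeseries=ts,
            fork_snapshots=self.fork_snapshots,
            barriers=self.barriers.copy(),
            total_length=self.total_length,
            params=self.params,
        )


def run_simulation(
    layout: GenomeLayout,
    params: ReplicationParams,
    variant: str = "combined",
    snapshot_times: tuple[float, ...] | None = None,
    **kwargs,
) -> SimulationResult:
    """Run one full replication simulation until every bp is replicated.

    ``snapshot_times`` requests exact fork-position snapshots (e.g. at the
    end of the speed ramp for cluster analysis); a time series is always
    recorded at ``params.recording_interval``.
    """
    sim = ReplicationSimulator(layout, params, variant, snapshot_times, **kwargs)
    return sim.run()


def run_model_variant(
    layout: GenomeLayout,
    params: ReplicationParams,
    variant: str,
    **kwargs,
) -> SimulationResult:
    """Run the combined, spontaneous-only or induced-only model variant.

    ``spontaneous_only`` forces the induced probability to zero;
    ``induced_only`` forces the spontaneous probabilities to zero and fires
    one origin in every euchromatic zone at t=0.
    """
    alias = {"spontaneous": "spontaneous_only", "induced": "induced_only"}
    return run_simulation(layout, params, alias.get(variant, variant), **kwargs)
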