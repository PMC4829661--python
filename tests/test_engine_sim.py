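"""Whole-simulation behaviour: conservation, factor accounting, invariants,
variants, and equivalence with a brute-force fixed-timestep oracle."""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pytest

from replisim.engine import (
    EventKind,
    FiringMode,
    ReplicationParams,
    ReplicationSimulator,
    SpeedSchedule,
    limiting_factor,
    run_model_variant,
    run_simulation,
)
from replisim.genome import ChromatinClass, GenomeLayout, SyntheticGenomeParams, generate_synthetic_genome


class TestConservation:
    def test_replicons_partition_genome(self, toy_result, toy_layout):
        """At completion the replicon intervals tile every chromosome exactly."""
        rep = toy_result.replicons
        assert rep.notna().all().all()
        assert (rep["right"] > rep["left"]).all()
        # total coverage equals genome length with no overlap
        assert (rep["right"] - rep["left"]).sum() == pytest.approx(
            toy_layout.total_length, abs=1e-6
        )
        chrom = np.searchsorted(toy_layout.barriers, rep["origin"].to_numpy(), side="right") - 1
        for ci in range(toy_layout.n_chromosomes):
            sub = rep[chrom == ci].sort_values("left")
            assert sub["left"].iloc[0] == toy_layout.barriers[ci]
            assert sub["right"].iloc[-1] == toy_layout.barriers[ci + 1]
            np.testing.assert_allclose(
                sub["left"].iloc[1:].to_numpy(), sub["right"].iloc[:-1].to_numpy()
            )

    def test_origin_inside_own_replicon(self, toy_result):
        rep = toy_result.replicons
        assert ((rep["origin"] >= rep["left"]) & (rep["origin"] <= rep["right"])).all()

    def test_firing_counts_match(self, toy_result):
        assert len(toy_result.replicons) == toy_result.n_firings

    def test_timeseries_monotone_and_complete(self, toy_result, toy_layout):
        ts = toy_result.timeseries
        assert (np.diff(ts["replicated_total"]) >= -1e-6).all()
        assert ts["replicated_total"].iloc[-1] == pytest.approx(toy_layout.total_length)
        per_class_final = ts.iloc[-1][["replicated_eu", "replicated_fac", "replicated_con"]]
        assert per_class_final.sum() == pytest.approx(toy_layout.total_length, rel=1e-9)


class TestFactorAccounting:
    def test_forks_plus_free_equals_released(self, toy_layout, toy_params):
        """At every event, active forks + free factors == released factors,
        released factors == floor(L(t)), and forks never exceed L_max."""
        checks = []

        def hook(sim):
            checks.append(
                (
                    sim.t,
                    sim.moving_forks,
                    sim.free_factors,
                    sim.n_released,
                )
            )
            assert sim.moving_forks + sim.free_factors == sim.n_released
            assert sim.moving_forks <= sim.params.limiting_factor_max

        sim = ReplicationSimulator(toy_layout, toy_params, invariant_hook=hook)
        sim.run()
        assert len(checks) >= 30
        p = toy_params
        for t, forks, free, released in checks[::7]:
            expect = limiting_factor(t, p.limiting_factor_max, p.factor_timescale)
            # the final factor is granted early by design (at L = L_max - 1/2)
            assert released in (expect, expect + 1)

    def test_pairing(self, toy_layout, toy_params):
        """Forks are created in pairs and removed in pairs except at barriers."""
        sim = ReplicationSimulator(toy_layout, toy_params)
        collisions = barriers = 0
        while not sim.completed:
            ev = sim.step()
            if ev.kind == EventKind.FORK_COLLISION:
                collisions += 1
            elif ev.kind == EventKind.BARRIER_ARRIVAL:
                barriers += 1
        assert barriers == 2 * toy_layout.n_chromosomes
        assert 2 * collisions + barriers == 2 * len(sim.f_pos)

    def test_chronology(self, toy_layout, toy_params):
        sim = ReplicationSimulator(toy_layout, toy_params)
        last = -1.0
        while not sim.completed:
            ev = sim.step()
            assert ev.time >= last - 1e-9
            last = ev.time


class TestInhibition:
    def test_firing_respects_inhibition_distance(self, toy_layout, toy_params):
        """At the moment of firing, every active same-chromosome fork is at
        least d_i away from the fired origin."""
        violations = []
        sim = ReplicationSimulator(toy_layout, toy_params)
        original_fire = sim._fire

        def checked_fire(oi, insert_at, mode):
            x = sim.opos[oi]
            chrom = sim.ochrom[oi]
            pos = sim.active_fork_positions()
            if len(pos):
                pchrom = np.searchsorted(sim.barriers, pos, side="right") - 1
                same = pos[pchrom == chrom]
                if len(same) and np.abs(same - x).min() < toy_params.inhibition_distance:
                    violations.append((sim.t, x))
            original_fire(oi, insert_at, mode)

        sim._fire = checked_fire
        sim.run()
        assert not violations

    def test_forks_never_cross_barriers(self, toy_result, toy_layout):
        for t, pos in toy_result.fork_snapshots.items():
            assert np.all(pos >= 0) and np.all(pos <= toy_layout.total_length)


class TestVariants:
    def test_spontaneous_only_modes(self, toy_layout, toy_params):
        res = run_model_variant(toy_layout, toy_params, "spontaneous_only")
        assert np.all(res.firing_modes == FiringMode.SPONTANEOUS)
        assert res.completion_time > 0

    def test_induced_only_initial_firings(self, toy_layout, toy_params):
        res = run_model_variant(toy_layout, toy_params, "induced_only")
        n_eu_zones = int(np.sum(toy_layout.zone_class == ChromatinClass.EU))
        at_zero = res.firing_times == 0.0
        assert at_zero.sum() == n_eu_zones  # one initial origin per EU zone
        eu_cls = res.firing_classes[at_zero]
        assert np.all(eu_cls == ChromatinClass.EU)
        # heterochromatin still completes via fork fronts
        assert res.replicons.notna().all().all()

    def test_combined_has_both_modes(self, desk_result):
        modes = desk_result.firing_modes
        assert (modes == FiringMode.SPONTANEOUS).any()
        assert (modes == FiringMode.INDUCED).any()

    def test_unknown_variant_rejected(self, toy_layout, toy_params):
        with pytest.raises(ValueError):
            run_model_variant(toy_layout, toy_params, "nonsense")


class TestDeterminismAndMonotonicity:
    def test_bit_identical_reruns(self, toy_layout, toy_params):
        a = run_simulation(toy_layout, toy_params)
        b = run_simulation(toy_layout, toy_params)
        assert a.completion_time == b.completion_time
        np.testing.assert_array_equal(a.firing_positions, b.firing_positions)
        np.testing.assert_array_equal(a.firing_times, b.firing_times)

    def test_seeds_differ(self, toy_layout, toy_params):
        a = run_simulation(toy_layout, toy_params)
        b = run_simulation(toy_layout, replace(toy_params, seed=toy_params.seed + 1))
        assert not np.array_equal(a.firing_positions, b.firing_positions)

    @pytest.mark.parametrize("param,values", [
        ("limiting_factor_max", (6, 16, 48)),
        ("max_fork_speed", (10.0, 28.0, 80.0)),
    ])
    def test_completion_monotone_in_throughput(self, toy_layout, toy_params, param, values):
        """Mean completion time decreases with more factors / faster forks."""
        means = []
        for v in values:
            times = []
            for ds in range(3):
                p = replace(toy_params, seed=500 + ds, **{param: v})
                times.append(run_simulation(toy_layout, p).completion_time)
            means.append(np.mean(times))
        assert means[0] >= means[1] >= means[2]


class TestErrorPaths:
    def test_unreplicable_genome_diagnosed(self):
        """All-CON genome: no origin can ever fire -> diagnostic error."""
        layout = GenomeLayout(
            ["c0"], [1e6], [[0.0, 1e6]], [[ChromatinClass.CON]]
        )
        params = ReplicationParams(
            n_potential_origins=50, limiting_factor_max=4, seed=0
        )
        with pytest.raises(RuntimeError, match="no progress|never fire"):
            run_simulation(layout, params)

    def test_persistence_round_trip(self, toy_result, tmp_path):
        toy_result.to_dir(tmp_path / "run")
        from replisim.engine import SimulationResult

        again = SimulationResult.from_dir(tmp_path / "run")
        assert again.completion_time == toy_result.completion_time
        np.testing.assert_allclose(again.firing_positions, toy_result.firing_positions)
        np.testing.assert_array_equal(again.firing_modes, toy_result.firing_modes)
        assert again.params == toy_result.params


# ---------------------------------------------------------------------------
# brute-force fixed-timestep oracle
# ---------------------------------------------------------------------------


class BruteForceSimulator:
    """Independent fixed-timestep replication simulator.

    Replays the recorded (origin, uniform) decision stream of an event-driven
    run; everything else — fork motion, collisions, barriers, factor release,
    passive replication, firing probabilities — is recomputed from scratch on
    a time grid. Used only as a cross-check oracle.
    """

    def __init__(self, layout, params, decisions, dt=0.05):
        self.layout = layout
        self.p = params
        self.dt = dt
        self.decisions = list(decisions)
        self.cursor = 0
        self.sched = SpeedSchedule(params.max_fork_speed, params.speed_ramp_duration)
        rng = np.random.default_rng(params.seed)
        pos = rng.random(params.n_potential_origins) * layout.total_length
        pos.sort()
        self.opos = pos
        self.oclass = np.asarray(layout.class_at(pos))
        self.ochrom = np.asarray(layout.chromosome_index_at(pos))
        self.barriers = layout.barriers
        self.state = np.zeros(len(pos), dtype=int)
        from replisim.engine import schedule_factor_releases

        self.releases = schedule_factor_releases(
            params.limiting_factor_max, params.factor_timescale
        )
        self.release_idx = 0
        self.free = 0
        # forks: list of [position, direction(+1/-1), chromosome, replicon id]
        self.forks: list[list] = []
        self.intervals: list[list] = []  # replicated [left, right] intervals
        self.firing_times: dict[int, float] = {}
        self.collision_log: list[tuple[float, float]] = []
        self.t = 0.0
        self.induced_range = params.induced_range
        self._next_rid = 0

    def covered(self, x):
        return any(a <= x <= b for a, b in self.intervals)

    def probability(self, oi):
        x = self.opos[oi]
        chrom = self.ochrom[oi]
        dmin = math.inf
        for fpos, fdir, fchrom, _rid in self.forks:
            if fchrom == chrom:
                dmin = min(dmin, abs(fpos - x))
        spont = (self.p.p_eu, self.p.p_fac, self.p.p_con)[self.oclass[oi]]
        if dmin < self.p.inhibition_distance:
            return 0.0
        induced = 0.0
        if dmin <= self.induced_range:
            g = math.exp(-0.5 * (dmin / self.p.induced_sigma) ** 2)
            if g >= self.p.induced_cutoff:
                induced = g
        return max(spont, induced)

    def try_firings(self):
        while self.free >= 2 and self.cursor < len(self.decisions):
            oi, u = self.decisions[self.cursor]
            if self.state[oi] != 0 or self.covered(self.opos[oi]):
                # event-driven run only logged offers with positive
                # probability; a covered origin here signals divergence
                self.state[oi] = 2
                self.cursor += 1
                continue
            p = self.probability(oi)
            self.cursor += 1
            if u < p:
                self.state[oi] = 1
                self.firing_times[oi] = self.t
                x = self.opos[oi]
                c = self.ochrom[oi]
                rid = self._next_rid
                self._next_rid += 1
                self.forks.append([x, -1, c, rid])
                self.forks.append([x, +1, c, rid])
                self.intervals.append([x, x])
                self.free -= 2

    def step(self):
        dt = self.dt
        v = self.sched.speed(self.t + dt / 2)
        self.t += dt
        moved = v * dt
        # detect collisions on pre-move positions (approaching pairs whose
        # gap closes within this step), then advance the survivors
        self._resolve_collisions(moved)
        for f in self.forks:
            f[0] += f[1] * moved
        self._resolve_barriers()
        while (
            self.release_idx < len(self.releases)
            and self.releases[self.release_idx] <= self.t
        ):
            self.free += 1
            self.release_idx += 1
        self.try_firings()

    def _resolve_barriers(self):
        keep = []
        for f in self.forks:
            fpos, fdir, fchrom, _rid = f
            lo, hi = self.barriers[fchrom], self.barriers[fchrom + 1]
            if fpos <= lo or fpos >= hi:
                f[0] = lo if fpos <= lo else hi
                self._extend_cover(f)
                self.free += 1
            else:
                keep.append(f)
        self.forks = keep

    def _resolve_collisions(self, moved):
        # annihilate approaching adjacent pairs whose gap closes this step
        changed = True
        while changed:
            changed = False
            self.forks.sort(key=lambda f: f[0])
            for k in range(len(self.forks) - 1):
                a, b = self.forks[k], self.forks[k + 1]
                if (
                    a[1] == +1
                    and b[1] == -1
                    and b[0] - a[0] <= 2 * moved + 1e-9
                    and a[2] == b[2]
                    and a[3] != b[3]  # a replicon's own pair never collides
                ):
                    meet = 0.5 * (a[0] + b[0])
                    a[0] = b[0] = meet
                    self._extend_cover(a)
                    self._extend_cover(b)
                    self.collision_log.append((self.t, meet))
                    del self.forks[k + 1]
                    del self.forks[k]
                    self.free += 2
                    changed = True
                    break

    def _extend_cover(self, fork):
        fpos, fdir = fork[0], fork[1]
        # merge into interval bookkeeping
        best = None
        for itv in self.intervals:
            if fdir > 0 and itv[1] <= fpos + 1e-6 and (best is None or itv[1] > best[1]):
                best = itv
            if fdir < 0 and itv[0] >= fpos - 1e-6 and (best is None or itv[0] < best[0]):
                best = itv
        if best is not None:
            if fdir > 0:
                best[1] = max(best[1], fpos)
            else:
                best[0] = min(best[0], fpos)

    def run_until(self, t_end):
        while self.t < t_end:
            self.step()
            # keep the replicated intervals in sync with live forks
            self.sync_intervals()

    def sync_intervals(self):
        for f in self.forks:
            self._extend_cover(f)
        # merge overlapping intervals
        self.intervals.sort()
        merged = []
        for itv in self.intervals:
            if merged and itv[0] <= merged[-1][1] + 1e-6:
                merged[-1][1] = max(merged[-1][1], itv[1])
            else:
                merged.append(itv)
        self.intervals = merged


class TestBruteForceOracle:
    def test_firing_and_collision_times_match(self):
        """The event-driven engine and a fixed-timestep replay of the same
        random decisions agree on all firing times within 2*dt."""
        layout = GenomeLayout(
            ["oA", "oB"],
            [3.5e6, 2.5e6],
            [[0.0, 1.2e6, 2.0e6, 3.5e6], [0.0, 1.0e6, 2.5e6]],
            [
                [ChromatinClass.EU, ChromatinClass.CON, ChromatinClass.FAC],
                [ChromatinClass.EU, ChromatinClass.CON],
            ],
        )
        params = ReplicationParams(
            n_potential_origins=300,
            limiting_factor_max=8,
            seed=77,
            recording_interval=0.0,
            speed_ramp_duration=600.0,
        )
        sim = ReplicationSimulator(layout, params, record_decisions=True)
        result = sim.run()

        dt = 0.05
        brute = BruteForceSimulator(layout, params, sim.decision_log, dt=dt)
        brute.run_until(result.completion_time + 10 * dt)

        # same origins fired, at the same times up to grid quantization
        # (release + collision stamps each quantize to the grid, so the
        # worst-case skew of a firing stamp is a few timesteps)
        event_fired = {
            int(np.searchsorted(brute.opos, p)): t
            for p, t in zip(result.firing_positions, result.firing_times)
        }
        assert set(brute.firing_times) == set(event_fired)
        for oi, t_brute in brute.firing_times.items():
            assert abs(t_brute - event_fired[oi]) <= 4 * dt + 1e-9

        # every event-engine collision is mirrored, at the same genomic point
        n_collisions_event = (len(result.firing_positions) * 2
                              - 2 * layout.n_chromosomes) // 2
        assert len(brute.collision_log) == n_collisions_event
        rep = result.replicons
        interior = set(rep["left"].tolist()) | set(rep["right"].tolist())
        interior -= set(layout.barriers.tolist())
        engine_points = np.sort(np.asarray(sorted(interior)))
        brute_points = np.sort([p for _, p in brute.collision_log])
        np.testing.assert_allclose(brute_points, engine_points, atol=3 * dt * 28.0)
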