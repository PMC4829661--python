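"""Derived replication statistics.

Inter-origin distance samples (the simulated analogue of DNA-combing
measurements), 1D replication-fork clusters and their front speed,
chromosome-scale replication-timing profiles, and the comparison machinery
used to calibrate the inhibition distance: chi-square / Kullback-Leibler
histogram distances and a bootstrap test of the mean inter-origin distance
against an experimental reference value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import ReplicationParams, SimulationResult, SpeedSchedule, run_simulation
from .genome import GenomeLayout

__all__ = [
    "InterOriginSample",
    "ClusterSnapshot",
    "TimingProfile",
    "inter_origin_distances",
    "identify_clusters",
    "cluster_series",
    "cluster_front_speed",
    "timing_profile",
    "profile_correlation",
    "bootstrap_mean_test",
    "distribution_distance",
    "sweep_inhibition_distance",
]

#: Adjacent active forks closer than this belong to one 1D cluster (bp).
DEFAULT_CLUSTER_THRESHOLD = 1_000_000.0


@dataclass(frozen=True)
class InterOriginSample:
    """Distances between adjacent fired origins on the same chromosome (bp)."""

    distances: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        if d.size and d.min() <= 0:
            raise ValueError("inter-origin distances must be positive")
        object.__setattr__(self, "distances", d)

    @property
    def mean(self) -> float:
        return float(self.distances.mean()) if self.distances.size else math.nan


@dataclass(frozen=True)
class ClusterSnapshot:
    """1D fork clusters at one instant: (fork count, genomic span bp) pairs."""

    time: float
    clusters: tuple[tuple[int, float], ...]
    threshold: float = DEFAULT_CLUSTER_THRESHOLD

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def n_forks(self) -> int:
        return sum(c[0] for c in self.clusters)

    @property
    def mean_span(self) -> float:
        if not self.clusters:
            return math.nan
        return float(np.mean([c[1] for c in self.clusters]))


@dataclass(frozen=True)
class TimingProfile:
    """Replication times (s) at sampling positions on one chromosome.

    ``times`` may contain NaN where a position was never replicated in an
    incomplete run.
    """

    positions: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.times):
            raise ValueError("positions/times length mismatch")


def inter_origin_distances(result: SimulationResult) -> InterOriginSample:
    """Distances between adjacent fired origins, never across barriers.

    Mirrors the DNA-combing readout: per chromosome, fired-origin positions
    are sorted and successive differences emitted.
    """
    pos = np.sort(result.firing_positions)
    if pos.size < 2:
        return InterOriginSample(np.empty(0))
    chrom = np.searchsorted(result.barriers, pos, side="right") - 1
    d = np.diff(pos)
    same = chrom[1:] == chrom[:-1]
    return InterOriginSample(d[same & (d > 0)])


def identify_clusters(
    fork_positions: np.ndarray,
    barriers: np.ndarray,
    threshold: float = DEFAULT_CLUSTER_THRESHOLD,
    time: float = math.nan,
) -> ClusterSnapshot:
    """Group sorted fork positions into 1D clusters.

    Two adjacent forks belong to one cluster iff their distance is strictly
    below ``threshold`` and no chromosome barrier lies between them. Cluster
    size is the genomic span between its outermost forks (0 for singletons).
    """
    pos = np.asarray(fork_positions, dtype=float)
    if np.any(np.diff(pos) < 0):
        raise ValueError("fork positions must be sorted")
    if pos.size == 0:
        return ClusterSnapshot(time, (), threshold)
    chrom = np.searchsorted(np.asarray(barriers, dtype=float), pos, side="right") - 1
    breaks = (np.diff(pos) >= threshold) | (chrom[1:] != chrom[:-1])
    idx = np.flatnonzero(breaks) + 1
    clusters = []
    for seg in np.split(pos, idx):
        clusters.append((len(seg), float(seg[-1] - seg[0])))
    return ClusterSnapshot(time, tuple(clusters), threshold)


def cluster_series(
    result: SimulationResult, threshold: float = DEFAULT_CLUSTER_THRESHOLD
) -> list[ClusterSnapshot]:
    """Cluster snapshots at every stored fork-position snapshot time."""
    out = []
    for t in sorted(result.fork_snapshots):
        out.append(identify_clusters(result.fork_snapshots[t], result.barriers, threshold, t))
    return out


def cluster_front_speed(max_fork_speed: float, l_max: int, n_clusters: int) -> float:
    """Cluster-front ("wave") speed ``v_w = nu * L_max / (2 N_c)`` in bp/s.

    With all ``L_max`` forks active and distributed over ``N_c`` clusters,
    each cluster replicates ``nu L_max / N_c`` bp per second; while a cluster
    consists of two outward fronts each front advances at half that rate.
    """
    if n_clusters < 1:
        raise ValueError("cluster count must be >= 1")
    return max_fork_speed * l_max / (2.0 * n_clusters)


def timing_profile(
    results: SimulationResult | list[SimulationResult],
    positions: np.ndarray,
) -> TimingProfile:
    """Replication time of each sampling position, averaged over runs.

    Within the replicon of an origin fired at ``t0``, position ``x`` is
    replicated when the fork has travelled ``|x - o|``, i.e. at
    ``t = s^{-1}(s(t0) + |x - o|)`` under the global speed schedule.
    Positions outside every replicon of an incomplete run are NaN.
    """
    if isinstance(results, SimulationResult):
        results = [results]
    positions = np.asarray(positions, dtype=float)
    acc = np.zeros(len(positions))
    cnt = np.zeros(len(positions))
    for res in results:
        sched = SpeedSchedule(res.params.max_fork_speed, res.params.speed_ramp_duration)
        rep = res.replicons.dropna()
        left = rep["left"].to_numpy()
        right = rep["right"].to_numpy()
        origin = rep["origin"].to_numpy()
        t0 = rep["t_fire"].to_numpy()
        order = np.argsort(left)
        left, right, origin, t0 = left[order], right[order], origin[order], t0[order]
        idx = np.searchsorted(left, positions, side="right") - 1
        ok = (idx >= 0) & (positions <= right[np.clip(idx, 0, None)])
        for j in np.flatnonzero(ok):
            i = idx[j]
            s_arrive = sched.distance(t0[i]) + abs(positions[j] - origin[i])
            acc[j] += sched.time_at_distance(s_arrive)
            cnt[j] += 1
    times = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    return TimingProfile(positions, times)


def profile_correlation(a: TimingProfile, b: TimingProfile) -> float:
    """Pearson correlation between two profiles on their common positions.

    Replication *time* and experimental *timing score* conventions may be
    anticorrelated; compare ``abs(r)`` when the sign convention of the inputs
    differs. Returns NaN (flagged undefined) when either profile has zero
    variance.
    """
    common, ia, ib = np.intersect1d(a.positions, b.positions, return_indices=True)
    x, y = a.times[ia], b.times[ib]
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 common positions")
    if np.std(x) == 0 or np.std(y) == 0:
        return math.nan
    return float(np.corrcoef(x, y)[0, 1])


def bootstrap_mean_test(
    sample: InterOriginSample,
    reference_mean: float = 188_000.0,
    subset_size: int = 50,
    repetitions: int = 10_000,
    seed: int = 0,
) -> float:
    """Bootstrap significance test of the simulated inter-origin distances.

    Repeatedly draws a random subset (without replacement within a subset,
    independently across repetitions) of ``subset_size`` distances, takes its
    mean, and reports ``P = min(frac below, frac above)`` the reference mean;
    subset means exactly equal to the reference contribute half to each side.
    When one side is empty the result is below resolution and ``1/(2*reps)``
    is returned (read as "P < 1/repetitions").
    """
    d = sample.distances
    if d.size < subset_size:
        raise ValueError(f"sample of {d.size} smaller than subset size {subset_size}")
    rng = np.random.default_rng(seed)
    means = np.empty(repetitions)
    for r in range(repetitions):
        means[r] = d[rng.choice(d.size, size=subset_size, replace=False)].mean()
    below = float(np.mean(means < reference_mean))
    above = float(np.mean(means > reference_mean))
    ties = 1.0 - below - above
    below += 0.5 * ties
    above += 0.5 * ties
    p = min(below, above)
    return p if p > 0 else 0.5 / repetitions


def distribution_distance(
    observed_counts: np.ndarray,
    simulated_counts: np.ndarray,
    measure: str = "chi2",
    pseudo_count: float = 0.5,
) -> float:
    """Chi-square or Kullback-Leibler distance between two histograms.

    Both histograms must share a binning. ``chi2`` scales the simulated
    counts to the observed total and computes ``sum (o-e)^2/e`` over bins
    with nonzero expectation; ``kl`` computes ``sum p ln(p/q)`` on
    frequencies, adding ``pseudo_count`` to every empty simulated bin first.
    """
    o = np.asarray(observed_counts, dtype=float)
    s = np.asarray(simulated_counts, dtype=float)
    if o.shape != s.shape:
        raise ValueError("histograms must share a common binning")
    if measure == "chi2":
        e = s * (o.sum() / s.sum())
        mask = e > 0
        if np.any(o[~mask] > 0):
            # observed mass where expectation is zero: chi2 diverges
            return math.inf
        return float(np.sum((o[mask] - e[mask]) ** 2 / e[mask]))
    if measure == "kl":
        q = s.copy()
        q[q == 0] += pseudo_count
        p = o / o.sum()
        q = q / q.sum()
        mask = p > 0
        return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))
    raise ValueError(f"unknown measure {measure!r}")


def histogram_distances(
    distances: np.ndarray,
    bin_width: float = 20_000.0,
    upper: float = 800_000.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Default inter-origin-distance binning: ``bin_width`` bins on [0, upper]."""
    edges = np.arange(0.0, upper + bin_width, bin_width)
    counts, _ = np.histogram(np.clip(distances, None, upper - 1e-9), bins=edges)
    return counts, edges


def sweep_inhibition_distance(
    layout: GenomeLayout,
    params: ReplicationParams,
    observed_counts: np.ndarray,
    bin_edges: np.ndarray,
    d_i_values: np.ndarray | None = None,
    n_seeds: int = 1,
) -> pd.DataFrame:
    """Calibrate the inhibition distance against an observed distance histogram.

    Runs ``n_seeds`` simulations per ``d_i`` (default: 5 kbp steps over
    [0, 120] kbp), bins the pooled simulated inter-origin distances like the
    observed histogram, and reports chi-square, KL divergence and the mean
    total number of origins fired.
    """
    from dataclasses import replace

    if d_i_values is None:
        d_i_values = np.arange(0.0, 120_000.0 + 1, 5_000.0)
    rows = []
    for d_i in d_i_values:
        pooled = []
        firings = []
        for k in range(n_seeds):
            p = replace(params, inhibition_distance=float(d_i), seed=params.seed + 1000 * k)
            res = run_simulation(layout, p)
            pooled.append(inter_origin_distances(res).distances)
            firings.append(res.n_firings)
        dist = np.concatenate(pooled)
        sim_counts, _ = np.histogram(np.clip(dist, None, bin_edges[-1] - 1e-9), bins=bin_edges)
        rows.append(
            (
                float(d_i),
                distribution_distance(observed_counts, sim_counts, "chi2"),
                distribution_distance(observed_counts, sim_counts, "kl"),
                float(np.mean(firings)),
            )
        )
    return pd.DataFrame(rows, columns=["d_i", "chi2", "kl", "total_firings"])


def read_timing_bedgraph(stream, chromosome: str | None = None) -> TimingProfile:
    """Read a bedGraph / 2-column CSV timing profile (position, value)."""
    close = False
    if isinstance(stream, str):
        stream, close = open(stream), True
    try:
        pos, val = [], []
        for line in stream:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.replace(",", "\t").split("\t")
            if len(fields) >= 4:  # bedGraph: chrom start end value
                if chromosome is not None and fields[0] != chromosome:
                    continue
                pos.append(0.5 * (float(fields[1]) + float(fields[2])))
                val.append(float(fields[3]))
            else:  # 2-column: position value
                pos.append(float(fields[0]))
                val.append(float(fields[1]))
        return TimingProfile(np.asarray(pos), np.asarray(val))
    finally:
        if close:
            stream.close()


def write_timing_bedgraph(profile: TimingProfile, stream, chromosome: str = "chr1") -> None:
    close = False
    if isinstance(stream, str):
        stream, close = open(stream, "w"), True
    try:
        for p, t in zip(profile.positions, profile.times):
            if math.isfinite(t):
                stream.write(f"{chromosome}\t{p:.0f}\t{p:.0f}\t{t:.3f}\n")
    finally:
        if close:
            stream.close()
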