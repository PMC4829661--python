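"""Random-loop polymer model of nuclear chromatin folding.

Each chromosome is a Gaussian bead-spring chain (no volume exclusion, one
bead per ``bead_size`` bp) with chromatin-class-specific spring constants
(euchromatin soft, constitutive heterochromatin stiff), plus random
intra-chromosome harmonic loop connections that confine each chromosome to a
territory. Beads move inside an oblate ellipsoidal nucleus containing two
spherical nucleoli the chain may not enter. Two pseudo-gravitational terms
shape the large-scale arrangement: a weak inverse-distance repulsion between
chromosome centres (keeps territories apart) and a periphery term attracting
facultative heterochromatin to the nearest of the nuclear envelope or a
nucleolar surface (constitutive heterochromatin feels the reversed sign at
half strength, pushing it into the bulk). Conformations are sampled with the
standard single-bead Metropolis algorithm.

Units
-----
Positions are in micrometres and energies in units of k_B T at the reservoir
temperature, i.e. the Metropolis acceptance is ``min(1, exp(-dU))`` with
``dU`` dimensionless. The chain/loop spring constants are interpreted in
k_B T per nm^2 (so the default euchromatin kappa of 1e-8 gives an essentially
confinement-dominated chain, while 3e-6 compacts constitutive
heterochromatin to ~1 um bond scale); the gravitational strengths are in
k_B T times um. These unit pairings are a documented reconstruction — only
the orderings and the qualitative compaction they produce are constrained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import ChromatinClass, GenomeLayout

__all__ = [
    "FoldingParams",
    "BeadChain",
    "LoopSet",
    "Conformation",
    "build_chains",
    "sample_loops",
    "energy",
    "metropolis_step",
    "relax",
    "map_position_to_3d",
]

_NM_PER_UM = 1_000.0


@dataclass(frozen=True)
class FoldingParams:
    """Random-loop model parameters (defaults: HeLa-scale nucleus)."""

    bead_size: float = 100_000.0  # bp per bead
    kappa_eu: float = 1e-8  # k_B T / nm^2
    kappa_fac: float = 5e-7
    kappa_con: float = 3e-6
    kappa_loop: float = 5e-7
    total_loops: int = 5_000
    mean_loop_size: float = 2_000_000.0  # bp
    kappa_repulsion: float = 1e-4  # k_B T * um per bead-pair weight
    kappa_periphery_fac: float = 30.0  # k_B T * um, attractive
    kappa_periphery_con: float = 15.0  # k_B T * um, repulsive (reversed sign)
    softening_radius: float = 1.0  # um
    semi_axes: tuple[float, float, float] = (7.5, 5.0, 3.5)  # um
    nucleolus_radius: float = 1.35  # um
    nucleolus_centers: tuple[tuple[float, float, float], ...] = (
        (3.75, 0.0, 0.0),
        (-3.75, 0.0, 0.0),
    )
    temperature: float = 290.0  # K (energies are expressed in k_B T units)
    step_sigma: float = 0.3  # um, initial proposal scale (auto-tuned)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "kappa_eu", "kappa_fac", "kappa_con", "kappa_loop",
            "kappa_repulsion", "kappa_periphery_fac", "kappa_periphery_con",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        rx, ry, rz = self.semi_axes
        for c in self.nucleolus_centers:
            if (c[0] / rx) ** 2 + (c[1] / ry) ** 2 + (c[2] / rz) ** 2 > 1.0:
                raise ValueError("nucleolus centre outside the nuclear ellipsoid")

    @property
    def kappa_by_class(self) -> tuple[float, float, float]:
        return (self.kappa_eu, self.kappa_fac, self.kappa_con)


@dataclass
class BeadChain:
    """One chromosome as a chain of class-labelled beads."""

    chromosome_index: int
    name: str
    bead_class: np.ndarray  # ChromatinClass per bead
    bead_starts: np.ndarray  # genomic start (local bp) per bead
    length: float  # bp

    @property
    def n_beads(self) -> int:
        return len(self.bead_class)

    @property
    def weight(self) -> int:
        """Chromosome weight W = bead count (enters the repulsion term)."""
        return self.n_beads


@dataclass(frozen=True)
class LoopSet:
    """Random intra-chromosome loop connections (bead-index pairs, global)."""

    pairs: np.ndarray  # (n, 2) global bead indices

    @property
    def n_loops(self) -> int:
        return len(self.pairs)


def build_chains(layout: GenomeLayout, bead_size: float = 100_000.0) -> list[BeadChain]:
    """One chain per chromosome, ``ceil(length / bead_size)`` beads each.

    Each bead is labelled with the majority chromatin class of its genomic
    interval (the last bead of a chromosome may be shorter than bead_size).
    """
    chains = []
    for ci in range(layout.n_chromosomes):
        start = layout.barriers[ci]
        length = layout.chromosome_length(ci)
        n = int(math.ceil(length / bead_size))
        starts = np.arange(n) * bead_size
        ends = np.minimum(starts + bead_size, length)
        classes = np.empty(n, dtype=np.int8)
        for i in range(n):
            classes[i] = _majority_class(layout, start + starts[i], start + ends[i])
        chains.append(BeadChain(ci, layout.chromosome_names[ci], classes, starts, length))
    return chains


def _majority_class(layout: GenomeLayout, a: float, b: float) -> int:
    """Chromatin class holding the largest share of the interval [a, b)."""
    zs = layout.zone_starts
    ia = int(np.searchsorted(zs, a, side="right")) - 1
    ib = int(np.searchsorted(zs, b - 1e-9, side="right")) - 1
    if ia == ib:
        return int(layout.zone_class[ia])
    share = [0.0, 0.0, 0.0]
    for i in range(ia, ib + 1):
        lo = max(a, zs[i])
        hi = min(b, zs[i + 1] if i + 1 < len(zs) else layout.total_length)
        share[layout.zone_class[i]] += hi - lo
    return int(np.argmax(share))


def sample_loops(
    chains: list[BeadChain],
    total_loops: int = 5_000,
    mean_loop_size: float = 2_000_000.0,
    bead_size: float = 100_000.0,
    seed: int = 0,
) -> LoopSet:
    """Random non-adjacent intra-chromosome loop connections.

    Loops are allocated to chromosomes proportionally to length; spans are
    geometric with mean ``mean_loop_size / bead_size`` beads, minimum 2 beads
    (non-adjacent), anchors uniform. Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    eligible = [c for c in chains if c.n_beads >= 3]
    if not eligible:
        raise ValueError("no chain long enough to host a loop (need >= 3 beads)")
    weights = np.array([c.length for c in eligible], dtype=float)
    weights /= weights.sum()
    counts = rng.multinomial(total_loops, weights)
    mean_span = max(mean_loop_size / bead_size, 2.0)
    offsets = np.concatenate([[0], np.cumsum([c.n_beads for c in chains])])
    pairs = []
    for chain, n_loops in zip(eligible, counts):
        off = offsets[chain.chromosome_index]
        nb = chain.n_beads
        for _ in range(int(n_loops)):
            # geometric span >= 2 with mean `mean_span` (memoryless linking)
            span = 1 + rng.geometric(min(1.0, 1.0 / (mean_span - 1.0)))
            span = min(int(span), nb - 1)
            a = int(rng.integers(0, nb - span))
            pairs.append((off + a, off + a + span))
    return LoopSet(np.asarray(pairs, dtype=np.int64))


class Conformation:
    """Bead positions of all chromosomes plus cached energy bookkeeping."""

    def __init__(
        self,
        chains: list[BeadChain],
        loops: LoopSet,
        params: FoldingParams,
        positions: np.ndarray | None = None,
        rng: np.random.Generator | None = None,
    ) -> None:
        self.chains = chains
        self.loops = loops
        self.params = params
        self.n_beads = sum(c.n_beads for c in chains)
        self.offsets = np.concatenate([[0], np.cumsum([c.n_beads for c in chains])])
        self.bead_chain = np.concatenate(
            [np.full(c.n_beads, i, dtype=np.int32) for i, c in enumerate(chains)]
        )
        self.bead_class = np.concatenate([c.bead_class for c in chains])
        # per-bond spring constant: softer of the two bead classes at a
        # class boundary (bond i connects bead i and i+1 within a chain)
        kappa = np.asarray(params.kappa_by_class)
        kb = np.minimum(kappa[self.bead_class[:-1]], kappa[self.bead_class[1:]])
        kb[np.flatnonzero(np.diff(self.bead_chain) != 0)] = 0.0  # no inter-chromosome bond
        self.bond_kappa = kb
        # loop adjacency per bead
        self._loops_by_bead: dict[int, list[int]] = {}
        for a, b in loops.pairs:
            self._loops_by_bead.setdefault(int(a), []).append(int(b))
            self._loops_by_bead.setdefault(int(b), []).append(int(a))

        if rng is None:
            rng = np.random.default_rng(params.seed)
        if positions is None:
            positions = _random_positions(self.n_beads, params, rng)
        self.x = np.asarray(positions, dtype=float).copy()
        if not np.all(self._allowed(self.x)):
            raise ValueError("initial bead positions violate the hard constraints")
        self.centers = np.array(
            [self.x[self.offsets[i] : self.offsets[i + 1]].mean(axis=0) for i in range(len(chains))]
        )
        self.weights = np.array([c.weight for c in chains], dtype=float)

    # -- geometry -------------------------------------------------------------

    def _allowed(self, pts: np.ndarray) -> np.ndarray:
        p = self.params
        pts = np.atleast_2d(pts)
        rx, ry, rz = p.semi_axes
        inside = (pts[:, 0] / rx) ** 2 + (pts[:, 1] / ry) ** 2 + (pts[:, 2] / rz) ** 2 <= 1.0
        for c in p.nucleolus_centers:
            inside &= np.linalg.norm(pts - np.asarray(c), axis=1) >= p.nucleolus_radius
        return inside

    def periphery_distance(self, pt: np.ndarray) -> float:
        """Distance (um) to the nearest of nuclear envelope / nucleolar surface.

        The envelope distance uses the effective-radius approximation
        ``r_eff (1 - |scaled pt|)`` with the ellipsoid scaled to a unit
        sphere, exact for a sphere and smooth everywhere.
        """
        p = self.params
        rx, ry, rz = p.semi_axes
        u = math.sqrt((pt[0] / rx) ** 2 + (pt[1] / ry) ** 2 + (pt[2] / rz) ** 2)
        r_eff = (rx * ry * rz) ** (1.0 / 3.0)
        d = r_eff * max(1.0 - u, 0.0)
        for c in p.nucleolus_centers:
            d = min(d, abs(np.linalg.norm(pt - np.asarray(c)) - p.nucleolus_radius))
        return d

    # -- energy ---------------------------------------------------------------

    def _bead_local_energy(self, bead: int, pos: np.ndarray) -> float:
        """Chain + loop + periphery energy terms touching one bead."""
        u = 0.0
        nm2 = _NM_PER_UM * _NM_PER_UM
        if bead > 0 and self.bond_kappa[bead - 1] > 0:
            d2 = float(np.sum((pos - self.x[bead - 1]) ** 2))
            u += 0.5 * self.bond_kappa[bead - 1] * d2 * nm2
        if bead < self.n_beads - 1 and self.bond_kappa[bead] > 0:
            d2 = float(np.sum((pos - self.x[bead + 1]) ** 2))
            u += 0.5 * self.bond_kappa[bead] * d2 * nm2
        for other in self._loops_by_bead.get(bead, ()):
            d2 = float(np.sum((pos - self.x[other]) ** 2))
            u += 0.5 * self.params.kappa_loop * d2 * nm2
        u += self._periphery_energy(bead, pos)
        return u

    def _periphery_energy(self, bead: int, pos: np.ndarray) -> float:
        cls = self.bead_class[bead]
        p = self.params
        if cls == ChromatinClass.FAC and p.kappa_periphery_fac > 0:
            return -p.kappa_periphery_fac / (self.periphery_distance(pos) + p.softening_radius)
        if cls == ChromatinClass.CON and p.kappa_periphery_con > 0:
            return +p.kappa_periphery_con / (self.periphery_distance(pos) + p.softening_radius)
        return 0.0

    def _repulsion_for_chain(self, ci: int, center: np.ndarray) -> float:
        """Centre-of-geometry repulsion of chromosome ci against all others."""
        p = self.params
        if p.kappa_repulsion == 0 or len(self.chains) < 2:
            return 0.0
        d = np.linalg.norm(self.centers - center, axis=1)
        d[ci] = math.inf
        d = np.maximum(d, 1e-6)  # guard the singular coincident-centre case
        return float(p.kappa_repulsion * self.weights[ci] * np.sum(self.weights / d))

    def total_energy(self) -> dict[str, float]:
        """Full recomputation of all four potential terms (k_B T units)."""
        nm2 = _NM_PER_UM * _NM_PER_UM
        dx = self.x[1:] - self.x[:-1]
        u_chain = 0.5 * float(np.sum(self.bond_kappa * np.sum(dx * dx, axis=1))) * nm2
        u_loop = 0.0
        if self.loops.n_loops:
            dl = self.x[self.loops.pairs[:, 0]] - self.x[self.loops.pairs[:, 1]]
            u_loop = 0.5 * self.params.kappa_loop * float(np.sum(dl * dl)) * nm2
        u_rep = 0.0
        p = self.params
        for i in range(len(self.chains)):
            for j in range(i + 1, len(self.chains)):
                d = max(float(np.linalg.norm(self.centers[i] - self.centers[j])), 1e-6)
                u_rep += p.kappa_repulsion * self.weights[i] * self.weights[j] / d
        u_grav = 0.0
        for b in range(self.n_beads):
            u_grav += self._periphery_energy(b, self.x[b])
        return {
            "chain": u_chain,
            "loop": u_loop,
            "repulsion": u_rep,
            "periphery": u_grav,
            "total": u_chain + u_loop + u_rep + u_grav,
        }

    def to_pdb(self, stream) -> None:
        """Write bead positions as PDB-like HETATM records for 3D viewers.

        Coordinates are emitted in Angstrom-sized display units (um * 10),
        one chain per chromosome, element letter by chromatin class
        (C = EU, N = FAC, O = CON).
        """
        close = False
        if isinstance(stream, str):
            stream, close = open(stream, "w"), True
        element = {0: "C", 1: "N", 2: "O"}
        try:
            serial = 1
            for ci, chain in enumerate(self.chains):
                cid = chr(ord("A") + ci % 26)
                o = self.offsets[ci]
                for b in range(chain.n_beads):
                    x, y, z = self.x[o + b] * 10.0
                    el = element[int(chain.bead_class[b])]
                    stream.write(
                        f"HETATM{serial % 100000:5d}  {el}   BEA {cid}{(b + 1) % 10000:4d}    "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {el:>2}\n"
                    )
                    serial += 1
                stream.write("TER\n")
            stream.write("END\n")
        finally:
            if close:
                stream.close()

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for ci, chain in enumerate(self.chains):
            o = self.offsets[ci]
            for b in range(chain.n_beads):
                rows.append(
                    (
                        chain.name,
                        b,
                        ChromatinClass(int(chain.bead_class[b])).name,
                        *self.x[o + b],
                    )
                )
        return pd.DataFrame(rows, columns=["chromosome", "bead", "class", "x", "y", "z"])


def _random_positions(n: int, params: FoldingParams, rng: np.random.Generator) -> np.ndarray:
    """Uniform random points inside the allowed region (rejection sampling)."""
    rx, ry, rz = params.semi_axes
    out = np.empty((n, 3))
    filled = 0
    while filled < n:
        cand = (rng.random((2 * (n - filled) + 16, 3)) * 2 - 1) * (rx, ry, rz)
        ok = (cand[:, 0] / rx) ** 2 + (cand[:, 1] / ry) ** 2 + (cand[:, 2] / rz) ** 2 <= 1.0
        for c in params.nucleolus_centers:
            ok &= np.linalg.norm(cand - np.asarray(c), axis=1) >= params.nucleolus_radius
        cand = cand[ok]
        take = min(len(cand), n - filled)
        out[filled : filled + take] = cand[:take]
        filled += take
    return out


def energy(conformation: Conformation) -> dict[str, float]:
    """Total potential and per-term breakdown (chain/loop/repulsion/periphery)."""
    return conformation.total_energy()


def metropolis_step(
    conformation: Conformation,
    rng: np.random.Generator,
    step_sigma: float | None = None,
    bead: int | None = None,
) -> bool:
    """One single-bead Metropolis move; returns True if accepted.

    An isotropic Gaussian displacement is proposed; moves leaving the
    ellipsoid or entering a nucleolus are rejected outright, otherwise the
    move is accepted with ``min(1, exp(-dU))`` (energies in k_B T).
    """
    c = conformation
    if bead is None:
        bead = int(rng.integers(c.n_beads))
    sigma = c.params.step_sigma if step_sigma is None else step_sigma
    new = c.x[bead] + rng.normal(0.0, sigma, 3)
    if not c._allowed(new[None, :])[0]:
        return False
    ci = int(c.bead_chain[bead])
    old_center = c.centers[ci].copy()
    new_center = old_center + (new - c.x[bead]) / c.weights[ci]
    du = (
        c._bead_local_energy(bead, new)
        - c._bead_local_energy(bead, c.x[bead])
        + c._repulsion_for_chain(ci, new_center)
        - c._repulsion_for_chain(ci, old_center)
    )
    if du > 0 and rng.random() >= math.exp(-du):
        return False
    c.x[bead] = new
    c.centers[ci] = new_center
    return True


@dataclass
class RelaxResult:
    conformation: Conformation
    energy_trace: np.ndarray
    acceptance_rate: float
    step_sigma: float
    converged: bool


def relax(
    conformation: Conformation,
    n_sweeps: int,
    rng: np.random.Generator | None = None,
    tune: bool = True,
) -> RelaxResult:
    """Metropolis relaxation: ``n_sweeps`` sweeps of one move per bead.

    During the first 20% of sweeps (burn-in) the proposal sigma is auto-tuned
    toward a 30-50% acceptance rate. Convergence is flagged when the linear
    energy slope over the last 20% of sweeps is statistically indistinguishable
    from zero (|slope| below 2 standard errors).
    """
    if n_sweeps < 1:
        raise ValueError("n_sweeps must be >= 1")
    c = conformation
    if rng is None:
        rng = np.random.default_rng(c.params.seed + 1)
    sigma = c.params.step_sigma
    trace = np.empty(n_sweeps)
    accepted = proposed = 0
    burn_in = max(1, n_sweeps // 5)
    for sweep in range(n_sweeps):
        acc = 0
        for _ in range(c.n_beads):
            if metropolis_step(c, rng, step_sigma=sigma):
                acc += 1
        accepted += acc
        proposed += c.n_beads
        if tune and sweep < burn_in:
            rate = acc / c.n_beads
            if rate < 0.30:
                sigma *= 0.8
            elif rate > 0.50:
                sigma *= 1.25
        trace[sweep] = c.total_energy()["total"]
    tail = trace[-max(2, n_sweeps // 5):]
    converged = False
    if len(tail) >= 3:
        t = np.arange(len(tail), dtype=float)
        slope, intercept = np.polyfit(t, tail, 1)
        resid = tail - (slope * t + intercept)
        se = np.sqrt(np.sum(resid**2) / max(len(tail) - 2, 1) / np.sum((t - t.mean()) ** 2))
        converged = abs(slope) < 2 * se if se > 0 else True
    return RelaxResult(c, trace, accepted / max(proposed, 1), sigma, converged)


def map_position_to_3d(conformation: Conformation, position: float) -> np.ndarray:
    """3D coordinates (um) of a genomic position on the global axis.

    Linear interpolation between the centres of the flanking beads; positions
    in the outer half of a terminal bead are clamped to that bead's centre.
    """
    return map_positions_to_3d(conformation, np.asarray([position], dtype=float))[0]


def map_positions_to_3d(conformation: Conformation, positions: np.ndarray) -> np.ndarray:
    """Vectorized :func:`map_position_to_3d` for many global positions."""
    c = conformation
    chains = c.chains
    chain_starts = np.concatenate([[0.0], np.cumsum([ch.length for ch in chains])])
    positions = np.asarray(positions, dtype=float)
    if np.any(positions < 0) or np.any(positions >= chain_starts[-1]):
        raise ValueError("position outside the layout")
    ci = np.searchsorted(chain_starts, positions, side="right") - 1
    out = np.empty((len(positions), 3))
    bead_size = c.params.bead_size
    for k in range(len(positions)):
        chain = chains[ci[k]]
        local = positions[k] - chain_starts[ci[k]]
        o = c.offsets[ci[k]]
        # bead centres at (i + 0.5) * bead_size; interpolate between them,
        # clamping the outer halves of the terminal beads to their centres
        f = local / bead_size - 0.5
        if f <= 0.0 or chain.n_beads == 1:
            out[k] = c.x[o]
        elif f >= chain.n_beads - 1:
            out[k] = c.x[o + chain.n_beads - 1]
        else:
            i0 = int(math.floor(f))
            w = f - i0
            out[k] = (1.0 - w) * c.x[o + i0] + w * c.x[o + i0 + 1]
    return out
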