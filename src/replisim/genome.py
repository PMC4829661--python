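"""Chromatin-zone genome layouts.

The replication engine runs on a one-dimensional genome in which every base
pair belongs to exactly one chromatin zone of class euchromatin (EU),
facultative heterochromatin (FAC) or constitutive heterochromatin (CON).
Chromosomes are concatenated on a single global coordinate axis and separated
by *barriers* that replication forks cannot cross.

Layouts can be built three ways:

* parsed from a UCSC ``cytoBand.txt``-style table (Giemsa stain intensity is
  the proxy for chromatin class),
* expanded to an aneuploid karyotype (e.g. the 76-chromosome HeLa complement)
  with optional inactive-X reclassification, or
* generated synthetically from target class fractions and a lognormal zone
  size distribution (most zones 1-6 Mbp), which emulates the HeLa-like genome
  without any external data.

Coordinates are 0-based, half-open and *continuous* (fractional base pairs
are allowed internally because fork speed is non-integer).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import IntEnum
from typing import IO, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ChromatinClass",
    "ChromatinZone",
    "ChromosomeTemplate",
    "KaryotypeSpec",
    "GenomeLayout",
    "SyntheticGenomeParams",
    "parse_cytoband",
    "serialize_cytoband",
    "read_karyotype_csv",
    "apply_karyotype",
    "generate_synthetic_genome",
]


class ChromatinClass(IntEnum):
    """Chromatin compaction class, ordered from open to compact."""

    EU = 0
    FAC = 1
    CON = 2


#: Giemsa stain value -> chromatin class. Unstained bands are euchromatin,
#: lightly stained bands facultative and all strongly staining / special
#: bands constitutive heterochromatin.
STAIN_TO_CLASS: Mapping[str, ChromatinClass] = {
    "gneg": ChromatinClass.EU,
    "gpos25": ChromatinClass.FAC,
    "gpos50": ChromatinClass.FAC,
    "gpos75": ChromatinClass.CON,
    "gpos100": ChromatinClass.CON,
    "acen": ChromatinClass.CON,
    "gvar": ChromatinClass.CON,
    "stalk": ChromatinClass.CON,
}

#: Representative stain used when writing a layout back out as cytoband text.
CLASS_TO_STAIN = {
    ChromatinClass.EU: "gneg",
    ChromatinClass.FAC: "gpos25",
    ChromatinClass.CON: "gpos100",
}


@dataclass(frozen=True)
class ChromatinZone:
    """A half-open interval ``[start, end)`` of one chromatin class."""

    chromosome_index: int
    start: float
    end: float
    chromatin_class: ChromatinClass

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError(f"zone end must exceed start, got [{self.start}, {self.end})")

    @property
    def length(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class ChromosomeTemplate:
    """A named chromosome tiled exactly by an ordered list of zones."""

    name: str
    length: float
    zones: tuple[ChromatinZone, ...]

    def __post_init__(self) -> None:
        pos = 0.0
        for z in self.zones:
            if z.start != pos:
                raise ValueError(
                    f"{self.name}: zones must tile contiguously; expected start {pos}, got {z.start}"
                )
            pos = z.end
        if pos != self.length:
            raise ValueError(f"{self.name}: zones cover {pos} bp but length is {self.length}")


@dataclass(frozen=True)
class KaryotypeSpec:
    """Copy numbers per chromosome template plus inactive-X bookkeeping.

    ``inactive_X_copies`` of the X chromosome (template ``x_name``) are
    reclassified to a single facultative-heterochromatin zone, mirroring the
    fact that the inactive X replicates like facultative heterochromatin.
    """

    copy_numbers: Mapping[str, int]
    inactive_X_copies: int = 0
    x_name: str = "chrX"

    def __post_init__(self) -> None:
        for name, n in self.copy_numbers.items():
            if n < 1:
                raise ValueError(f"copy number for {name} must be >= 1, got {n}")
        if self.inactive_X_copies < 0:
            raise ValueError("inactive_X_copies must be >= 0")
        if self.inactive_X_copies and self.copy_numbers.get(self.x_name, 0) < self.inactive_X_copies:
            raise ValueError("more inactive X copies requested than X copies present")

    @property
    def total_copies(self) -> int:
        return sum(self.copy_numbers.values())


class GenomeLayout:
    """Concatenated chromosomes tiled by typed chromatin zones.

    Internally the layout is held as flat numpy arrays for O(log n) position
    queries: ``barriers`` (chromosome boundaries on the global axis, length
    ``n_chromosomes + 1``), ``zone_starts`` / ``zone_ends`` / ``zone_class`` /
    ``zone_chrom`` (one entry per zone, globally sorted).
    """

    def __init__(
        self,
        chromosome_names: Sequence[str],
        chromosome_lengths: Sequence[float],
        zone_bounds: Sequence[Sequence[float]],
        zone_classes: Sequence[Sequence[int]],
    ) -> None:
        if len(chromosome_names) != len(chromosome_lengths):
            raise ValueError("names/lengths mismatch")
        self.chromosome_names = list(chromosome_names)
        lengths = np.asarray(chromosome_lengths, dtype=float)
        self.barriers = np.concatenate([[0.0], np.cumsum(lengths)])
        self.total_length = float(self.barriers[-1])

        starts, ends, classes, chroms = [], [], [], []
        for ci, (bounds, cls) in enumerate(zip(zone_bounds, zone_classes)):
            bounds = np.asarray(bounds, dtype=float)
            if len(bounds) != len(cls) + 1:
                raise ValueError("zone bounds must have one more entry than classes")
            if bounds[0] != 0.0 or bounds[-1] != lengths[ci]:
                raise ValueError(f"chromosome {ci}: zones do not tile [0, length)")
            if np.any(np.diff(bounds) <= 0):
                raise ValueError(f"chromosome {ci}: zone bounds not strictly increasing")
            offset = self.barriers[ci]
            starts.append(bounds[:-1] + offset)
            ends.append(bounds[1:] + offset)
            classes.append(np.asarray(cls, dtype=np.int8))
            chroms.append(np.full(len(cls), ci, dtype=np.int32))
        self.zone_starts = np.concatenate(starts)
        self.zone_ends = np.concatenate(ends)
        self.zone_class = np.concatenate(classes)
        self.zone_chrom = np.concatenate(chroms)

    # -- basic facts ---------------------------------------------------------

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosome_names)

    @property
    def n_zones(self) -> int:
        return len(self.zone_starts)

    def chromosome_length(self, index: int) -> float:
        return float(self.barriers[index + 1] - self.barriers[index])

    def zone_counts(self) -> dict[ChromatinClass, int]:
        return {c: int(np.sum(self.zone_class == c)) for c in ChromatinClass}

    def class_fractions(self) -> np.ndarray:
        """Fraction of total genome length per chromatin class (EU, FAC, CON)."""
        lengths = self.zone_ends - self.zone_starts
        out = np.zeros(3)
        for c in ChromatinClass:
            out[c] = lengths[self.zone_class == c].sum() / self.total_length
        return out

    # -- position queries ----------------------------------------------------

    def zone_index_at(self, position) -> np.ndarray | int:
        """Index of the zone containing each (global) position."""
        pos = np.asarray(position, dtype=float)
        if np.any(pos < 0) or np.any(pos >= self.total_length):
            raise ValueError("position outside [0, total_length)")
        idx = np.searchsorted(self.zone_starts, pos, side="right") - 1
        return idx if pos.ndim else int(idx)

    def zone_at(self, position: float) -> ChromatinZone:
        """The unique zone whose half-open interval contains ``position``."""
        i = self.zone_index_at(float(position))
        ci = int(self.zone_chrom[i])
        off = self.barriers[ci]
        return ChromatinZone(
            chromosome_index=ci,
            start=float(self.zone_starts[i] - off),
            end=float(self.zone_ends[i] - off),
            chromatin_class=ChromatinClass(int(self.zone_class[i])),
        )

    def class_at(self, position) -> np.ndarray | int:
        idx = self.zone_index_at(position)
        out = self.zone_class[idx]
        return out if np.ndim(idx) else int(out)

    def chromosome_index_at(self, position) -> np.ndarray | int:
        pos = np.asarray(position, dtype=float)
        if np.any(pos < 0) or np.any(pos >= self.total_length):
            raise ValueError("position outside [0, total_length)")
        idx = np.searchsorted(self.barriers, pos, side="right") - 1
        return idx if pos.ndim else int(idx)

    # -- IO ------------------------------------------------------------------

    def to_bed(self, stream: IO[str] | str) -> None:
        """Write zones as BED: chrom, start, end, class name (local coords)."""
        close = False
        if isinstance(stream, str):
            stream, close = open(stream, "w"), True
        try:
            for i in range(self.n_zones):
                ci = int(self.zone_chrom[i])
                off = self.barriers[ci]
                stream.write(
                    f"{self.chromosome_names[ci]}\t{self.zone_starts[i] - off:.0f}"
                    f"\t{self.zone_ends[i] - off:.0f}\t{ChromatinClass(int(self.zone_class[i])).name}\n"
                )
        finally:
            if close:
                stream.close()

    @classmethod
    def from_bed(cls, stream: IO[str] | str) -> "GenomeLayout":
        close = False
        if isinstance(stream, str):
            stream, close = open(stream), True
        try:
            names: list[str] = []
            per_chrom_bounds: list[list[float]] = []
            per_chrom_classes: list[list[int]] = []
            for line in stream:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                chrom, start, end, cname = line.split("\t")[:4]
                if not names or names[-1] != chrom:
                    if chrom in names:
                        raise ValueError(f"chromosome {chrom} rows are not contiguous")
                    names.append(chrom)
                    per_chrom_bounds.append([float(start)])
                    per_chrom_classes.append([])
                if float(start) != per_chrom_bounds[-1][-1]:
                    raise ValueError(f"gap or overlap at {chrom}:{start}")
                per_chrom_bounds[-1].append(float(end))
                per_chrom_classes[-1].append(ChromatinClass[cname])
            lengths = [b[-1] for b in per_chrom_bounds]
            return cls(names, lengths, per_chrom_bounds, per_chrom_classes)
        finally:
            if close:
                stream.close()


# ---------------------------------------------------------------------------
# cytoBand parsing
# ---------------------------------------------------------------------------


def parse_cytoband(stream: IO[str] | str | Iterable[str]) -> list[ChromosomeTemplate]:
    """Parse UCSC cytoBand text (chrom, start, end, band, stain) to templates.

    Bands of one chromosome must tile it contiguously from 0; unknown stain
    values and gapped/overlapping bands are rejected with the offending row.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    order: list[str] = []
    rows: dict[str, list[tuple[float, float, ChromatinClass]]] = {}
    for ln, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 5:
            raise ValueError(f"line {ln}: expected 5 tab-separated columns, got {len(fields)}")
        chrom, start, end, band, stain = fields
        if stain not in STAIN_TO_CLASS:
            raise ValueError(f"line {ln} ({chrom}:{band}): unknown stain value {stain!r}")
        if chrom not in rows:
            order.append(chrom)
            rows[chrom] = []
        rows[chrom].append((float(start), float(end), STAIN_TO_CLASS[stain]))

    templates = []
    for chrom in order:
        bands = sorted(rows[chrom])
        pos = 0.0
        zones = []
        for start, end, cls in bands:
            if start != pos:
                kind = "gap" if start > pos else "overlap"
                raise ValueError(f"{chrom}: {kind} at position {min(start, pos):.0f}")
            zones.append(ChromatinZone(0, start, end, cls))
            pos = end
        templates.append(ChromosomeTemplate(chrom, pos, tuple(zones)))
    return templates


def serialize_cytoband(templates: Sequence[ChromosomeTemplate]) -> str:
    """Inverse of :func:`parse_cytoband` up to stain representative choice."""
    out = []
    for t in templates:
        for i, z in enumerate(t.zones):
            out.append(
                f"{t.name}\t{z.start:.0f}\t{z.end:.0f}\tz{i}\t{CLASS_TO_STAIN[z.chromatin_class]}"
            )
    return "\n".join(out) + "\n"


def read_karyotype_csv(stream: IO[str] | str, inactive_X_copies: int = 0) -> KaryotypeSpec:
    """Read a 2-column CSV (chromosome name, copy number)."""
    close = False
    if isinstance(stream, str):
        stream, close = open(stream), True
    try:
        copies: dict[str, int] = {}
        for line in stream:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("name,"):
                continue
            name, n = [f.strip() for f in line.split(",")[:2]]
            copies[name] = int(n)
        return KaryotypeSpec(copies, inactive_X_copies=inactive_X_copies)
    finally:
        if close:
            stream.close()


def apply_karyotype(
    templates: Sequence[ChromosomeTemplate], karyotype: KaryotypeSpec
) -> GenomeLayout:
    """Expand templates to an aneuploid layout on the global axis.

    Each template is replicated per its copy number (copies are suffixed
    ``.0``, ``.1``, ...). The last ``inactive_X_copies`` copies of the X
    template are reclassified as one single FAC zone spanning the chromosome.
    """
    by_name = {t.name: t for t in templates}
    for name in karyotype.copy_numbers:
        if name not in by_name:
            raise KeyError(f"karyotype names chromosome {name!r} with no matching template")

    names, lengths, bounds, classes = [], [], [], []
    for name, n_copies in karyotype.copy_numbers.items():
        t = by_name[name]
        for copy in range(n_copies):
            names.append(f"{name}.{copy}")
            lengths.append(t.length)
            inactive = (
                name == karyotype.x_name and copy >= n_copies - karyotype.inactive_X_copies
            )
            if inactive:
                bounds.append([0.0, t.length])
                classes.append([ChromatinClass.FAC])
            else:
                bounds.append([z.start for z in t.zones] + [t.length])
                classes.append([z.chromatin_class for z in t.zones])
    return GenomeLayout(names, lengths, bounds, classes)


# ---------------------------------------------------------------------------
# synthetic genomes
# ---------------------------------------------------------------------------


@dataclass
class SyntheticGenomeParams:
    """Parameters of the HeLa-like synthetic genome generator.

    Defaults emulate the aneuploid HeLa complement used throughout: 76
    chromosomes, ~10.36 Gbp, chromatin-class length fractions 42/22/36%
    (EU/FAC/CON) and lognormal zone sizes with most mass between 1 and 6 Mbp.
    ``zone_size_median`` / ``zone_size_sigma`` give the lognormal location
    (Mbp) and log-scale per class.
    """

    n_chromosomes: int = 76
    target_total_length: float = 10.36e9
    class_fractions: tuple[float, float, float] = (0.42, 0.22, 0.36)
    zone_size_median: tuple[float, float, float] = (2.7e6, 2.7e6, 4.8e6)
    zone_size_sigma: tuple[float, float, float] = (0.55, 0.55, 0.50)
    chromosome_length_sigma: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        f = np.asarray(self.class_fractions, dtype=float)
        if np.any(f < 0) or not np.isclose(f.sum(), 1.0):
            raise ValueError("class_fractions must be nonnegative and sum to 1")
        if self.target_total_length <= 0:
            raise ValueError("target_total_length must be > 0")
        if self.n_chromosomes < 1:
            raise ValueError("n_chromosomes must be >= 1")
        if min(self.zone_size_median) <= 0 or min(self.zone_size_sigma) < 0:
            raise ValueError("invalid zone size distribution parameters")


def generate_synthetic_genome(params: SyntheticGenomeParams) -> GenomeLayout:
    """Generate a chromatin-zone genome without external data.

    Zone classes strictly alternate between euchromatin and heterochromatin
    (banding order EU, het, EU, het, ...), with the heterochromatin flavour
    (FAC vs CON) of each het zone drawn proportionally to its remaining
    length quota. Zone sizes are lognormal per class; after generation the
    per-class sizes are rescaled by a single factor each (a few percent) so
    realized class fractions match the requested ones, then chromosome
    boundaries are snapped to zone boundaries near equal-weight cut points.
    Deterministic for a given seed.
    """
    rng = np.random.default_rng(params.seed)
    fractions = np.asarray(params.class_fractions, dtype=float)
    total = params.target_total_length

    if fractions[0] == 1.0:
        # degenerate all-EU genome: one zone per chromosome
        lengths = _chromosome_lengths(rng, params)
        return GenomeLayout(
            [f"synth{i}" for i in range(params.n_chromosomes)],
            lengths,
            [[0.0, L] for L in lengths],
            [[ChromatinClass.EU] for L in lengths],
        )
    if fractions[0] == 0.0 and (fractions[1] == 0.0 or fractions[2] == 0.0):
        cls = ChromatinClass.FAC if fractions[1] == 1.0 else ChromatinClass.CON
        lengths = _chromosome_lengths(rng, params)
        return GenomeLayout(
            [f"synth{i}" for i in range(params.n_chromosomes)],
            lengths,
            [[0.0, L] for L in lengths],
            [[cls] for L in lengths],
        )

    med = np.asarray(params.zone_size_median, dtype=float)
    sig = np.asarray(params.zone_size_sigma, dtype=float)
    target_len = fractions * total

    sizes: list[float] = []
    classes: list[int] = []
    placed = np.zeros(3)
    start_with_eu = bool(rng.integers(2))
    next_is_eu = start_with_eu
    while placed.sum() < total:
        if next_is_eu and fractions[0] > 0:
            c = 0
        else:
            # heterochromatin flavour by remaining length deficit
            deficit = np.maximum(target_len[1:] - placed[1:], 0.0)
            if deficit.sum() <= 0:
                deficit = fractions[1:]
            if deficit.sum() <= 0:
                c = 0
            else:
                c = 1 + int(rng.random() < deficit[1] / deficit.sum())
        size = float(rng.lognormal(np.log(med[c]), sig[c]))
        sizes.append(size)
        classes.append(c)
        placed[c] += size
        next_is_eu = not next_is_eu if fractions[0] > 0 else False

    sizes_arr = np.asarray(sizes)
    classes_arr = np.asarray(classes)
    # exact class fractions via per-class rescale (shape-preserving)
    for c in range(3):
        mask = classes_arr == c
        if mask.any() and target_len[c] > 0:
            sizes_arr[mask] *= target_len[c] / sizes_arr[mask].sum()
    bounds_global = np.concatenate([[0.0], np.cumsum(sizes_arr)])

    # chromosome cut points snapped to zone boundaries
    weights = np.exp(rng.normal(0.0, params.chromosome_length_sigma, params.n_chromosomes))
    cuts_target = np.cumsum(weights) / weights.sum() * total
    cut_idx = [0]
    for ct in cuts_target[:-1]:
        i = int(np.searchsorted(bounds_global, ct))
        i = max(cut_idx[-1] + 2, min(i, len(bounds_global) - 1 - 2 * (params.n_chromosomes - len(cut_idx))))
        cut_idx.append(i)
    cut_idx.append(len(bounds_global) - 1)
    if len(set(cut_idx)) != len(cut_idx):
        raise ValueError("infeasible zone sizes: too few zones for requested chromosome count")

    names, lengths_out, bounds_out, classes_out = [], [], [], []
    for k in range(params.n_chromosomes):
        lo, hi = cut_idx[k], cut_idx[k + 1]
        b = bounds_global[lo : hi + 1] - bounds_global[lo]
        names.append(f"synth{k}")
        lengths_out.append(float(b[-1]))
        bounds_out.append(b)
        classes_out.append(classes_arr[lo:hi])
    return GenomeLayout(names, lengths_out, bounds_out, classes_out)


def _chromosome_lengths(rng: np.random.Generator, params: SyntheticGenomeParams) -> np.ndarray:
    w = np.exp(rng.normal(0.0, params.chromosome_length_sigma, params.n_chromosomes))
    return w / w.sum() * params.target_total_length


def hela_like_layout(seed: int = 0, scale: float = 1.0) -> GenomeLayout:
    """Convenience: the default HeLa-like synthetic layout, optionally scaled.

    ``scale < 1`` shrinks total genome length and chromosome count together
    (zone sizes keep their absolute 1-6 Mbp scale), which is the desk-scale
    configuration used by fast tests.
    """
    n_chrom = max(2, int(round(76 * scale)))
    return generate_synthetic_genome(
        SyntheticGenomeParams(
            n_chromosomes=n_chrom,
            target_total_length=10.36e9 * scale,
            seed=seed,
        )
    )
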