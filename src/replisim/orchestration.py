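"""Batch execution: multi-seed ensembles, configuration and figure pipelines.

All randomness in a run is funnelled through one seeded generator (draw
order documented in :mod:`replisim.engine`); ensembles assign one distinct
seed per member, so re-running a config is bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import ReplicationParams, SimulationResult, run_simulation
from .folding import FoldingParams
from .genome import GenomeLayout, SyntheticGenomeParams, generate_synthetic_genome
from . import stats as rstats

__all__ = ["RunConfig", "EnsembleSummary", "run_ensemble", "reproduce_figures"]

RAMP_END = 10_080.0  # end of the early-S fork-speed ramp (s)


@dataclass
class RunConfig:
    """One ensemble configuration.

    ``layout`` may be a GenomeLayout, a path to a BED layout, or None (then a
    synthetic HeLa-like genome is generated from ``genome_params``).
    """

    layout: GenomeLayout | str | None = None
    genome_params: SyntheticGenomeParams = field(default_factory=SyntheticGenomeParams)
    replication_params: ReplicationParams = field(default_factory=ReplicationParams)
    folding_params: FoldingParams = field(default_factory=FoldingParams)
    variant: str = "combined"
    seeds: tuple[int, ...] = (0,)
    snapshot_times: tuple[float, ...] = (RAMP_END,)
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if len(self.seeds) < 1:
            raise ValueError("ensemble needs at least one seed")
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("ensemble seeds must be distinct")

    def resolve_layout(self) -> GenomeLayout:
        if isinstance(self.layout, GenomeLayout):
            return self.layout
        if isinstance(self.layout, str):
            return GenomeLayout.from_bed(self.layout)
        return generate_synthetic_genome(self.genome_params)


@dataclass
class EnsembleSummary:
    """Per-seed results plus ensemble means/s.d. of the headline quantities."""

    results: list[SimulationResult]
    failures: dict[int, str]
    table: pd.DataFrame  # one row per successful seed

    def mean(self, column: str) -> float:
        return float(self.table[column].mean())

    def std(self, column: str) -> float:
        return float(self.table[column].std(ddof=1)) if len(self.table) > 1 else 0.0

    def to_json(self) -> dict:
        out = {"n_seeds": len(self.table), "failures": self.failures}
        for col in self.table.columns:
            if col == "seed":
                continue
            out[col] = {"mean": self.mean(col), "sd": self.std(col)}
        return out


def summarize_run(res: SimulationResult) -> dict:
    """Headline scalars of one run (times in hours where marked)."""
    sp = res.spontaneous_fraction
    eu_share = np.nan
    spont_mask = res.firing_modes == 0
    if spont_mask.any():
        eu_share = float(np.mean(res.firing_classes[spont_mask] == 0))
    row = {
        "seed": res.seed,
        "completion_h": res.completion_time / 3600.0,
        "total_firings": res.n_firings,
        "spontaneous_fraction": sp,
        "eu_share_of_spontaneous": eu_share,
        "replicated_fraction_at_ramp_end": res.replicated_fraction_at(RAMP_END),
    }
    if RAMP_END in res.fork_snapshots:
        snap = res.fork_snapshots[RAMP_END]
        if len(snap):
            cl = rstats.identify_clusters(snap, res.barriers)
            row["n_clusters_at_ramp_end"] = cl.n_clusters
            row["cluster_front_speed"] = rstats.cluster_front_speed(
                res.params.max_fork_speed, res.params.limiting_factor_max, cl.n_clusters
            )
    return row


def run_ensemble(config: RunConfig, progress: bool = False) -> EnsembleSummary:
    """Run one simulation per seed; failed seeds are reported, others kept."""
    layout = config.resolve_layout()
    results: list[SimulationResult] = []
    failures: dict[int, str] = {}
    rows = []
    for seed in config.seeds:
        params = replace(config.replication_params, seed=int(seed))
        try:
            res = run_simulation(
                layout, params, config.variant, snapshot_times=config.snapshot_times
            )
        except Exception as exc:  # noqa: BLE001 - per-seed isolation is the point
            failures[int(seed)] = str(exc)
            continue
        results.append(res)
        rows.append(summarize_run(res))
        if progress:
            print(f"seed {seed}: completion {res.completion_time / 3600:.2f} h, "
                  f"{res.n_firings} firings")
        if config.output_dir:
            res.to_dir(Path(config.output_dir) / f"seed_{seed}")
    table = pd.DataFrame(rows)
    summary = EnsembleSummary(results, failures, table)
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "ensemble_table.csv", index=False)
        (out / "ensemble_summary.json").write_text(json.dumps(summary.to_json(), indent=2))
    return summary


def averaged_timing_profile(
    summary: EnsembleSummary, positions: np.ndarray
) -> "rstats.TimingProfile":
    """Replication-timing profile averaged over all ensemble members."""
    return rstats.timing_profile(summary.results, positions)


def reproduce_figures(summary: EnsembleSummary, which: str, out_dir: str | Path) -> list[Path]:
    """Write CSV + plot analogues of the headline figure panels.

    ``which``: ``f2c`` replicated fraction per class over time, ``f2d`` fork
    counts per class over time, ``f3f`` cluster number/size over time,
    ``timing`` an averaged chromosome timing profile, ``fig4`` in-silico
    microscopy stills (requires a folding run; desk scale).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not summary.results:
        raise ValueError("no successful runs to plot; missing ensemble inputs")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written: list[Path] = []
    if which in ("f2c", "f2d"):
        frames = [r.timeseries.assign(seed=r.seed) for r in summary.results]
        ts = pd.concat(frames).groupby("time").mean().reset_index()
        csv = out_dir / f"{which}.csv"
        ts.to_csv(csv, index=False)
        written.append(csv)
        fig, ax = plt.subplots()
        total = summary.results[0].total_length
        fr = summary.results[0].params
        if which == "f2c":
            genome_cls = _class_lengths(summary.results[0])
            for cls, col in (("eu", "tab:blue"), ("fac", "tab:green"), ("con", "tab:red")):
                ax.plot(ts["time"] / 3600, ts[f"replicated_{cls}"] / genome_cls[cls], col, label=cls)
            ax.plot(ts["time"] / 3600, ts["replicated_total"] / total, "k", label="total")
            ax.set_ylabel("replicated fraction")
        else:
            for cls, col in (("eu", "tab:blue"), ("fac", "tab:green"), ("con", "tab:red")):
                ax.plot(ts["time"] / 3600, ts[f"forks_{cls}"], col, label=cls)
            ax.set_ylabel("active forks")
        ax.set_xlabel("time (h)")
        ax.legend()
        png = out_dir / f"{which}.png"
        fig.savefig(png, dpi=150)
        plt.close(fig)
        written.append(png)
    elif which == "f3f":
        rows = []
        for r in summary.results:
            for snap in rstats.cluster_series(r):
                rows.append((r.seed, snap.time, snap.n_clusters, snap.mean_span))
        df = pd.DataFrame(rows, columns=["seed", "time", "n_clusters", "mean_span"])
        agg = df.groupby("time")[["n_clusters", "mean_span"]].mean().reset_index()
        csv = out_dir / "f3f.csv"
        agg.to_csv(csv, index=False)
        written.append(csv)
        fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True)
        ax1.plot(agg["time"] / 3600, agg["n_clusters"])
        ax1.set_ylabel("1D clusters")
        ax2.plot(agg["time"] / 3600, agg["mean_span"] / 1e6)
        ax2.set_ylabel("mean span (Mbp)")
        ax2.set_xlabel("time (h)")
        png = out_dir / "f3f.png"
        fig.savefig(png, dpi=150)
        plt.close(fig)
        written.append(png)
    elif which == "timing":
        res0 = summary.results[0]
        chrom_end = float(res0.barriers[1])
        positions = np.linspace(0, chrom_end, 500, endpoint=False)
        prof = rstats.timing_profile(summary.results, positions)
        df = pd.DataFrame({"position": prof.positions, "time_s": prof.times})
        csv = out_dir / "timing_profile.csv"
        df.to_csv(csv, index=False)
        written.append(csv)
        fig, ax = plt.subplots()
        ax.plot(prof.positions / 1e6, prof.times / 3600)
        ax.set_xlabel("position on first chromosome (Mbp)")
        ax.set_ylabel("replication time (h)")
        ax.invert_yaxis()
        png = out_dir / "timing_profile.png"
        fig.savefig(png, dpi=150)
        plt.close(fig)
        written.append(png)
    else:
        raise ValueError(f"unknown figure key {which!r} (fig4 requires the render pipeline; "
                         "see replisim.render and examples/render_foci.py)")
    return written


def _class_lengths(res: SimulationResult) -> dict[str, float]:
    ts = res.timeseries
    # final row: everything replicated, so per-class totals equal class lengths
    last = ts.iloc[-1]
    return {"eu": last["replicated_eu"], "fac": last["replicated_fac"], "con": last["replicated_con"]}
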