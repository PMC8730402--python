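"""Reproducible multi-stage runs: simulate -> invert -> classify -> report.

A run is driven by a single declarative :class:`RunConfig` (YAML on
disk), executes its stages in dependency order into one run directory,
and records a manifest with the package version, every seed, and SHA-256
hashes of the files each stage produced.  Stages communicate only
through files, so any stage can be re-run independently; an identical
config reproduces identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, kinetics, rhythm, simulate
from .timeseries import TimeSeries

__all__ = ["RunConfig", "run_pipeline", "report"]

log = logging.getLogger("chronospeckle")

_STAGES = ("simulate", "kp", "rhythm", "report")


@dataclass(frozen=True)
class RunConfig:
    """Declarative description of a synthetic end-to-end run.

    Generator settings mirror the two-day design (2-h sampling, 48 h);
    the simulated genes carry a ~12-h processing-rate rhythm with
    per-gene random phase.
    """

    seed: int = 0
    stages: tuple[str, ...] = _STAGES
    # sampling design
    t0: float = 0.0
    dt: float = 2.0
    n_samples: int = 24
    noise_sd: float = 0.0  # log2-scale sd on simulated p and m
    # generator: processing-rate rhythm
    n_genes: int = 50
    kp_baseline: float = 0.2
    kp_rel_amplitude: float = 0.5
    kp_period: float = 12.0
    p_baseline: float = 1.0
    kd: float = 0.1
    # inversion
    p_floor: float | None = None
    smoothing: str | float | None = None
    # rhythm detection
    detrend_degree: int | None = None
    fdr_permutations: int = 0  # 0 disables the permutation FDR stage

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        object.__setattr__(self, "stages", tuple(self.stages))

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls(**d)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _wide_to_series(df: pd.DataFrame) -> dict[str, TimeSeries]:
    times = np.array([float(c) for c in df.columns])
    return {gid: TimeSeries(times, row.to_numpy(float)) for gid, row in df.iterrows()}


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Execute the configured stages into ``outdir``; returns the path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(outdir / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    manifest: dict = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "outputs": {},
    }
    manifest["config"]["stages"] = list(config.stages)
    try:
        produced: list[Path] = []
        if "simulate" in config.stages:
            produced += _stage_simulate(config, outdir)
        if "kp" in config.stages:
            produced += _stage_kp(config, outdir)
        if "rhythm" in config.stages:
            produced += _stage_rhythm(config, outdir)
        if "report" in config.stages:
            produced += report(outdir)
        for p in produced:
            manifest["outputs"][p.name] = _sha256(p)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    finally:
        log.removeHandler(fh)
        fh.close()
    return outdir


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing {path.name}; run the '{producer}' stage first"
        )
    return path


def _stage_simulate(config: RunConfig, outdir: Path) -> list[Path]:
    log.info("simulate: %d genes, %d samples at %.2g h", config.n_genes, config.n_samples, config.dt)
    ss = np.random.SeedSequence(config.seed)
    phase_rng = np.random.default_rng(ss.spawn(1)[0])
    rows_p, rows_m, rows_kp, phases = [], [], [], []
    for i in range(config.n_genes):
        phase = float(phase_rng.uniform(-np.pi, np.pi))
        phases.append(phase)
        scen = simulate.SimScenario(
            t0=config.t0,
            dt=config.dt,
            n_samples=config.n_samples,
            noise_sd=config.noise_sd,
            seed=int(np.random.default_rng(ss.spawn(1)[0]).integers(2**31)),
        )
        kp_spec = simulate.SignalSpec(
            (
                simulate.ComponentSpec(
                    config.kp_baseline * config.kp_rel_amplitude,
                    config.kp_period,
                    1.0,
                    phase,
                ),
            ),
            config.kp_baseline,
        )
        p_spec = simulate.SignalSpec((), config.p_baseline)
        tc, kp_true = simulate.gen_expression_timecourse(
            kp_spec, p_spec, config.kd, scen, gene_id=f"g{i:04d}"
        )
        rows_p.append(tc.pre.values)
        rows_m.append(tc.mature.values)
        rows_kp.append(kp_true.values)
    times = config.t0 + config.dt * np.arange(config.n_samples)
    idx = [f"g{i:04d}" for i in range(config.n_genes)]
    cols = [f"{t:g}" for t in times]
    out = []
    for name, rows in (("pre", rows_p), ("mature", rows_m), ("kp_true", rows_kp)):
        df = pd.DataFrame(rows, index=idx, columns=cols)
        df.index.name = "gene_id"
        path = outdir / f"{name}.csv"
        df.to_csv(path, float_format="%.10g")
        out.append(path)
    pd.DataFrame({"gene_id": idx, "true_phase_rad": phases}).to_csv(
        outdir / "true_phases.csv", index=False, float_format="%.10g"
    )
    out.append(outdir / "true_phases.csv")
    return out


def _stage_kp(config: RunConfig, outdir: Path) -> list[Path]:
    pre = pd.read_csv(_require(outdir / "pre.csv", "simulate"), index_col=0)
    mat = pd.read_csv(_require(outdir / "mature.csv", "simulate"), index_col=0)
    pre_s, mat_s = _wide_to_series(pre), _wide_to_series(mat)
    log.info("kp: inverting %d genes (kd=%.3g)", len(pre_s), config.kd)
    dense_rows, summaries = {}, []
    for gid in pre.index:
        tc = kinetics.ExpressionTimecourse(gid, pre_s[gid], mat_s[gid])
        prs = kinetics.estimate_processing_rate(
            tc, kd=config.kd, p_floor=config.p_floor, smoothing=config.smoothing
        )
        dense_rows[gid] = prs.kp.values
        try:
            summaries.append(kinetics.kp_rhythm_summary(prs))
        except ValueError:
            summaries.append(
                kinetics.KpRhythmSummary(gid, float("nan"), float("nan"), float("nan"), "other")
            )
    dense_times = next(iter(dense_rows.values()))
    # all genes share the grid; recompute from the first series
    first_gid = next(iter(dense_rows))
    tc0 = kinetics.ExpressionTimecourse(first_gid, pre_s[first_gid], mat_s[first_gid])
    grid = kinetics.estimate_processing_rate(
        tc0, kd=config.kd, p_floor=config.p_floor, smoothing=config.smoothing
    ).kp.times
    df = pd.DataFrame(dense_rows, index=[f"{t:g}" for t in grid]).T
    df.index.name = "gene_id"
    kp_path = outdir / "kp_dense.csv"
    df.to_csv(kp_path, float_format="%.10g")
    sdf = pd.DataFrame(
        {
            "gene_id": [s.gene_id for s in summaries],
            "kp_mean": [s.kp_mean for s in summaries],
            "kp12_amplitude_log2": [s.amplitude_log2 for s in summaries],
            "acrophase_h": [s.acrophase_h for s in summaries],
            "label": [s.label for s in summaries],
        }
    )
    sum_path = outdir / "kp_summary.tsv"
    sdf.to_csv(sum_path, sep="\t", index=False, float_format="%.8g")
    return [kp_path, sum_path]


def _stage_rhythm(config: RunConfig, outdir: Path) -> list[Path]:
    mat = pd.read_csv(_require(outdir / "mature.csv", "simulate"), index_col=0)
    series = _wide_to_series(mat)
    log.info("rhythm: classifying %d mature-mRNA series", len(series))
    rows = []
    for gid, ts in series.items():
        call = rhythm.classify_series(ts, detrend_degree=config.detrend_degree)
        dom = call.dominant
        rows.append(
            {
                "id": gid,
                "amplitude": dom.amplitude if dom else float("nan"),
                "period_h": dom.period if dom else float("nan"),
                "decay_per_sample": dom.decay_per_sample if dom else float("nan"),
                "phase_rad": dom.phase if dom else float("nan"),
                "label": call.label,
            }
        )
    df = pd.DataFrame(rows)
    path = outdir / "rhythm_components.tsv"
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")
    out = [path]
    if config.fdr_permutations >= 100:
        fdr = rhythm.permutation_fdr(
            list(series.values()),
            "ultradian12",
            B=config.fdr_permutations,
            seed=config.seed,
            detrend_degree=config.detrend_degree,
        )
        fdr_path = outdir / "rhythm_fdr.json"
        fdr_path.write_text(json.dumps({"label": "ultradian12", "fdr": fdr}))
        out.append(fdr_path)
    return out


def report(run_dir) -> list[Path]:
    """Summarize a run: period histogram and acrophase distribution.

    Every plotted number is also written as CSV.  Idempotent; an empty
    run directory produces an empty report with a warning.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run_dir = Path(run_dir)
    out: list[Path] = []
    sum_path = run_dir / "kp_summary.tsv"
    comp_path = run_dir / "rhythm_components.tsv"
    if not sum_path.exists() and not comp_path.exists():
        log.warning("report: nothing to report in %s", run_dir)
        (run_dir / "report_empty.txt").write_text("no stage outputs found\n")
        return [run_dir / "report_empty.txt"]

    if comp_path.exists():
        comp = pd.read_csv(comp_path, sep="\t")
        periods = comp["period_h"].dropna()
        periods = periods[np.isfinite(periods)]
        edges = np.arange(0.0, 36.1, 1.0)
        counts, _ = np.histogram(periods, bins=edges)
        hist = pd.DataFrame({"period_lo_h": edges[:-1], "period_hi_h": edges[1:], "count": counts})
        p = run_dir / "report_period_hist.csv"
        hist.to_csv(p, index=False)
        out.append(p)
        fig, ax = plt.subplots(figsize=(5, 3))
        ax.bar(edges[:-1], counts, width=1.0, align="edge")
        ax.set_xlabel("dominant period (h)")
        ax.set_ylabel("genes")
        fig.tight_layout()
        fig.savefig(run_dir / "report_period_hist.png", dpi=120)
        plt.close(fig)
        out.append(run_dir / "report_period_hist.png")

    if sum_path.exists():
        sdf = pd.read_csv(sum_path, sep="\t")
        peaks = sdf["acrophase_h"].dropna().to_numpy()
        if peaks.size:
            dist = rhythm.phase_distribution(peaks, period=12.0)
            pol = pd.DataFrame(
                {
                    "bin_lo_h": dist.bin_edges[:-1],
                    "bin_hi_h": dist.bin_edges[1:],
                    "count": dist.counts,
                }
            )
            p = run_dir / "report_phase_polar.csv"
            pol.to_csv(p, index=False)
            out.append(p)
            ang = 2 * np.pi * (dist.bin_edges[:-1] + np.diff(dist.bin_edges) / 2) / 12.0
            fig = plt.figure(figsize=(4, 4))
            ax = fig.add_subplot(polar=True)
            ax.bar(ang, dist.counts, width=2 * np.pi / len(dist.counts))
            ax.set_title("k_p acrophase (h mod 12)")
            fig.tight_layout()
            fig.savefig(run_dir / "report_phase_polar.png", dpi=120)
            plt.close(fig)
            out.append(run_dir / "report_phase_polar.png")
        label_counts = sdf["label"].value_counts().rename_axis("label").reset_index(name="count")
        p = run_dir / "report_labels.csv"
        label_counts.to_csv(p, index=False)
        out.append(p)
    return out
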