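"""Readers, writers, run configuration and the end-to-end pipeline.

CSV with documented headers is the interchange format for every stage
(trajectories, traces, event tables, cohort tables); JSON carries configs,
simulation-parameter sidecars, model reports and the run manifest. Readers
validate schema and monotonicity and report the offending file and row.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .constants import (
    DEFAULT_ALPHA,
    DEFAULT_BLOOD_VOLUME_UL,
    DEFAULT_CHAMBER_VOLUME_ML,
    DEFAULT_COLLINEARITY_THRESHOLD,
    DEFAULT_FLUX_WINDOW_S,
    DEFAULT_FPS,
    DEFAULT_SETTLE_S,
    DEFAULT_SPEED_THRESHOLD,
    DEFAULT_WINDOW_LENGTH,
)
from .errors import ParseError
from .kinematics import FrameSeries, takeoff_energy
from .respirometry import O2Trace, TitrationEvent, TitrationProtocol, process_trace
from .schema import (
    COHORT_COLUMNS,
    EVENT_COLUMNS,
    EVENT_KINDS,
    TRACE_COLUMNS,
    TRAJECTORY_COLUMNS,
)
from . import stats as _stats

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "read_trajectory",
    "write_trajectory",
    "read_trace",
    "write_trace",
    "read_cohort",
    "write_cohort",
    "run_pipeline",
    "format_run_summary",
]


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All pipeline parameters; defaults mirror the per-module documented ones.

    Round-trips losslessly through JSON via to_json/from_json.
    """

    # inputs (either a ready cohort CSV, or per-stage raw inputs)
    cohort_csv: str | None = None
    trajectory_dir: str | None = None
    trace_dir: str | None = None
    phenotypes_csv: str | None = None
    out_dir: str = "mitoflight_out"
    seed: int = 0
    # kinematics
    fps: float = DEFAULT_FPS
    window_length: int = DEFAULT_WINDOW_LENGTH
    speed_threshold: float = DEFAULT_SPEED_THRESHOLD
    smooth: bool = False
    # respirometry
    settle: float = DEFAULT_SETTLE_S
    window: float = DEFAULT_FLUX_WINDOW_S
    chamber_volume_ml: float = DEFAULT_CHAMBER_VOLUME_ML
    blood_volume_ul: float = DEFAULT_BLOOD_VOLUME_UL
    # statistics
    collinearity_threshold: float = DEFAULT_COLLINEARITY_THRESHOLD
    cooks_threshold: float | None = None     # None -> 4/n
    alpha: float = DEFAULT_ALPHA
    verbosity: int = 1

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ParseError(path, f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def sha256(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(canon).hexdigest()


# --------------------------------------------------------------------------
# readers / writers
# --------------------------------------------------------------------------

def _read_csv(path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(path, "file does not exist")
    try:
        # round_trip parsing so write-then-read preserves every float exactly
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # malformed CSV
        raise ParseError(path, f"could not parse CSV: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(path, f"missing required column(s) {missing}; header is {list(df.columns)}")
    if len(df) == 0:
        raise ParseError(path, "file holds a header but no data rows")
    return df


def _require_numeric(df: pd.DataFrame, cols: list[str], path) -> None:
    for c in cols:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = coerced.isna() & df[c].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(path, f"non-numeric value {df[c].iloc[row]!r} in column {c!r}", row=row + 2)
        df[c] = coerced


def write_trajectory(path, frames: FrameSeries) -> None:
    """CSV `frame,x_m,y_m,z_m` (0-based frames) + a metadata JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(frames.coords, columns=["x_m", "y_m", "z_m"])
    df.insert(0, "frame", np.arange(frames.n_frames))
    df.to_csv(path, index=False)
    meta = {"bird_id": frames.bird_id, "mass_kg": frames.mass, "fps": frames.fps}
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2) + "\n")


def read_trajectory(path, mass: float | None = None, fps: float | None = None,
                    bird_id: str | None = None) -> FrameSeries:
    """Read a trajectory CSV; mass/fps come from arguments or the sidecar."""
    path = Path(path)
    df = _read_csv(path, TRAJECTORY_COLUMNS)
    _require_numeric(df, TRAJECTORY_COLUMNS, path)
    meta_path = path.with_suffix(".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    mass = mass if mass is not None else meta.get("mass_kg")
    fps = fps if fps is not None else meta.get("fps")
    bird_id = bird_id if bird_id is not None else meta.get("bird_id", path.stem)
    if mass is None or fps is None:
        raise ParseError(path, "mass and fps must be given as arguments or via a .meta.json sidecar")
    frames = df["frame"].to_numpy()
    if not np.array_equal(frames, np.arange(len(frames))):
        row = int(np.flatnonzero(frames != np.arange(len(frames)))[0])
        raise ParseError(path, f"frame indices must be 0,1,2,... (got {frames[row]})", row=row + 2)
    return FrameSeries(
        coords=df[["x_m", "y_m", "z_m"]].to_numpy(dtype=float),
        fps=float(fps), mass=float(mass), bird_id=str(bird_id),
    )


def write_trace(trace: O2Trace, trace_path, events_path) -> None:
    pd.DataFrame({"time_s": trace.time, "o2_um": trace.o2_um}).to_csv(trace_path, index=False)
    pd.DataFrame(
        {"time_s": [e.time_s for e in trace.events.events],
         "event": [e.kind for e in trace.events.events]}
    ).to_csv(events_path, index=False)


def read_trace(
    trace_path, events_path,
    chamber_volume_ml: float = DEFAULT_CHAMBER_VOLUME_ML,
    blood_volume_ul: float = DEFAULT_BLOOD_VOLUME_UL,
    sample_id: str | None = None,
) -> O2Trace:
    """Read a trace CSV + events CSV pair into a validated O2Trace."""
    tdf = _read_csv(trace_path, TRACE_COLUMNS)
    _require_numeric(tdf, TRACE_COLUMNS, trace_path)
    t = tdf["time_s"].to_numpy(dtype=float)
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        raise ParseError(trace_path, f"time not strictly increasing at t = {t[bad[0] + 1]}",
                         row=int(bad[0]) + 3)
    edf = _read_csv(events_path, EVENT_COLUMNS)
    _require_numeric(edf, ["time_s"], events_path)
    for i, kind in enumerate(edf["event"]):
        if kind not in EVENT_KINDS:
            raise ParseError(events_path, f"unknown event kind {kind!r}", row=i + 2)
    protocol = TitrationProtocol(
        [TitrationEvent(float(r.time_s), str(r.event)) for r in edf.itertuples()]
    )
    return O2Trace(
        time=t, o2_um=tdf["o2_um"].to_numpy(dtype=float), events=protocol,
        chamber_volume_ml=chamber_volume_ml, blood_volume_ul=blood_volume_ul,
        sample_id=sample_id or Path(trace_path).stem,
    )


def write_cohort(table: pd.DataFrame, path, params: dict | None = None) -> None:
    """Cohort CSV (documented header) + optional simulation-parameter sidecar."""
    path = Path(path)
    table.to_csv(path, index=False)
    params = params if params is not None else table.attrs.get("params")
    if params is not None:
        clean = {k: (v if not isinstance(v, np.generic) else v.item())
                 for k, v in params.items()}
        path.with_suffix(".params.json").write_text(json.dumps(clean, indent=2) + "\n")


def read_cohort(path) -> pd.DataFrame:
    df = _read_csv(path, COHORT_COLUMNS)
    numeric = [c for c in COHORT_COLUMNS if c != "bird_id"]
    _require_numeric(df, numeric, path)
    return df


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------

def _assemble_cohort(config: RunConfig) -> pd.DataFrame:
    """Merge per-bird take-off, respirometry and phenotype inputs."""
    pheno = _read_csv(config.phenotypes_csv,
                      ["bird_id", "body_mass_g", "blood_cell_count_per_ul", "endurance_s"])
    _require_numeric(pheno, ["body_mass_g", "blood_cell_count_per_ul", "endurance_s"],
                     config.phenotypes_csv)
    rows = []
    for r in pheno.itertuples():
        bird = str(r.bird_id)
        traj = Path(config.trajectory_dir) / f"{bird}.csv"
        frames = read_trajectory(traj, mass=r.body_mass_g / 1000.0, fps=config.fps,
                                 bird_id=bird)
        takeoff = takeoff_energy(
            frames, window_length=config.window_length,
            speed_threshold=config.speed_threshold, smooth=config.smooth,
        )
        trace = read_trace(
            Path(config.trace_dir) / f"{bird}_trace.csv",
            Path(config.trace_dir) / f"{bird}_events.csv",
            chamber_volume_ml=config.chamber_volume_ml,
            blood_volume_ul=config.blood_volume_ul,
            sample_id=bird,
        )
        states, ratios = process_trace(trace, settle=config.settle, window=config.window)
        rows.append({
            "bird_id": bird,
            "body_mass_g": float(r.body_mass_g),
            "blood_cell_count_per_ul": float(r.blood_cell_count_per_ul),
            "endurance_s": float(r.endurance_s),
            "takeoff_energy_j": takeoff.takeoff_energy,
            "routine_c": states.routine_c,
            "leak_c": states.leak_c,
            "oxphos_c": states.oxphos_c,
            "ets_c": states.ets_c,
            "coupling_efficiency": ratios.coupling_efficiency,
            "reserve_capacity": ratios.reserve_capacity,
        })
    return pd.DataFrame(rows)[COHORT_COLUMNS]


def format_run_summary(report: dict) -> str:
    """Plain-text run summary suitable for logging."""
    lines = [
        f"mitoflight {report['version']} run (seed {report['seed']})",
        f"cohort rows: {report['n_rows']}",
        f"independence pre-check: slope p = {report['independence']['p_value']:.3f}"
        + ("  ** responses correlated **" if report['independence']['warning'] else ""),
        f"strong mito correlations (|r| > {report['collinearity']['threshold']}): "
        f"{len(report['collinearity']['flagged'])} pair(s) -> separate models",
        f"models fitted: {len(report['models'])}",
    ]
    for m in report["models"]:
        infl = m.get("influence") or {}
        tag = infl.get("classification") or "-"
        lines.append(
            f"  {m['response']} ~ {m['predictor']}: b = {m['coef']:.3f} ± {m['se']:.3f}, "
            f"F = {m['partial_f']:.3f}, p = {m['p_value']:.3f}, R2 = {m['r_squared']:.2f}, "
            f"n = {m['nobs']}, influence: {tag}"
        )
    return "\n".join(lines) + "\n"


def run_pipeline(config: RunConfig) -> dict:
    """Execute take-off -> respirometry -> merge -> statistics, write outputs.

    With `cohort_csv` set the raw stages are skipped and the table is read
    directly. Writes cohort.csv, models.csv, models.json, run_summary.txt and
    manifest.json into the output directory and returns the report dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.cohort_csv is not None:
        table = read_cohort(config.cohort_csv)
    elif config.trajectory_dir and config.trace_dir and config.phenotypes_csv:
        table = _assemble_cohort(config)
    else:
        raise ParseError(config.out_dir,
                         "config needs either cohort_csv or all of trajectory_dir, "
                         "trace_dir and phenotypes_csv")

    indep = _stats.response_independence_check(table, alpha=config.alpha)
    coll = _stats.collinearity_screen(table, threshold=config.collinearity_threshold)
    fits = _stats.fit_all_models(table)
    model_reports = []
    for fit in fits:
        entry = fit.to_dict()
        diag = _stats.residual_diagnostics(fit, alpha=config.alpha)
        entry["diagnostics"] = {
            "shapiro_p": diag.shapiro_p,
            "breusch_pagan_p": diag.breusch_pagan_p,
            "n_outliers": diag.n_outliers,
            "passed": diag.passed,
            "notes": diag.notes,
        }
        if fit.nobs >= 6:
            entry["influence"] = _stats.influence_refit(
                fit, cooks_threshold=config.cooks_threshold, alpha=config.alpha,
            ).to_dict()
        else:
            entry["influence"] = None
        model_reports.append(entry)

    report = {
        "version": __version__,
        "seed": config.seed,
        "config_sha256": config.sha256(),
        "n_rows": int(len(table)),
        "independence": asdict(indep),
        "collinearity": {
            "threshold": coll.threshold,
            "flagged": [list(f) for f in coll.flagged],
            "corr": coll.corr.round(6).to_dict(),
        },
        "models": model_reports,
    }

    write_cohort(table, out / "cohort.csv")
    flat = pd.DataFrame([
        {k: v for k, v in m.items() if not isinstance(v, dict) or k in ()}
        for m in model_reports
    ])
    flat.drop(columns=[c for c in ("covariates", "covariate_p", "diagnostics", "influence")
                       if c in flat.columns], inplace=True)
    flat.to_csv(out / "models.csv", index=False)
    (out / "models.json").write_text(json.dumps(report, indent=2, default=str) + "\n")
    (out / "run_summary.txt").write_text(format_run_summary(report))
    manifest = {
        "package": "mitoflight",
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_sha256": config.sha256(),
        "outputs": ["cohort.csv", "models.csv", "models.json", "run_summary.txt"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    logger.info("pipeline complete: %d models written to %s", len(model_reports), out)
    return report
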