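"""Session file formats, configuration and the end-to-end pipeline.

A session on disk is a directory of plain-text artifacts:

* ``spectra.csv`` — one wide table, rows = timestamps, columns = wavelengths
  (header ``timestamp_s,<nm>,<nm>,...``), raw counts;
* ``calibration.csv`` — columns ``wavelength_nm,reference_counts,dark_counts``;
* ``session.json`` — sidecar with integration time, roles and provenance;
* optional ``truth.csv`` for simulated sessions.

``run_pipeline`` ties the stages together deterministically for a given
config + seed: simulate (or read) a session, leak QC, calibrate, fit the
time series, run the protocol summary, and emit ``series.csv``,
``summary.json``/``summary.csv``, the resolved config and a log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .calibration import (
    CalibrationPair,
    CalibratedSpectrum,
    RawSpectrum,
    calibrate,
    leak_snr,
)
from .fitting import FitOptions, HemodynamicTimeSeries, fit_timeseries
from .optics import (
    TissueConfig,
    load_chromophore_table,
    load_scattering_table,
)
from .protocol import (
    ProtocolWindows,
    SessionSummary,
    summarize_behavior,
    summarize_hypercapnia,
    summarize_rotarod,
)
from .simulate import (
    InstrumentModel,
    TrajectoryParams,
    TruthTrajectory,
    make_trajectory,
    qc_counts,
    simulate_session,
)
from .state import HemodynamicState

__all__ = [
    "SessionConfig",
    "SessionReadError",
    "write_session",
    "read_session",
    "write_series",
    "read_series",
    "run_pipeline",
]

log = logging.getLogger("hemospec")


class SessionReadError(ValueError):
    """A session directory is missing pieces or contains malformed rows."""


def _fmt(x: float) -> str:
    return repr(float(x))


def write_session(
    directory: str | pathlib.Path,
    spectra: Sequence[RawSpectrum],
    cal: CalibrationPair,
    meta: Optional[dict] = None,
    truth: Optional[TruthTrajectory] = None,
) -> pathlib.Path:
    """Write a session to a directory of delimited-text files (bit-exact
    round trip through :func:`read_session`)."""
    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    grid = spectra[0].wavelength_nm

    with open(directory / "spectra.csv", "w") as fh:
        fh.write("timestamp_s," + ",".join(_fmt(w) for w in grid) + "\n")
        for s in spectra:
            if not np.array_equal(s.wavelength_nm, grid):
                raise ValueError("all spectra in a session must share a grid")
            fh.write(_fmt(s.timestamp_s) + "," + ",".join(_fmt(c) for c in s.counts) + "\n")

    with open(directory / "calibration.csv", "w") as fh:
        fh.write("wavelength_nm,reference_counts,dark_counts\n")
        for w, r, d in zip(grid, cal.reference.counts, cal.dark.counts):
            fh.write(f"{_fmt(w)},{_fmt(r)},{_fmt(d)}\n")

    sidecar = {
        "format": "hemospec-session-v1",
        "n_spectra": len(spectra),
        "wavelength_nm": [float(grid[0]), float(grid[-1])],
        "integration_time_ms": spectra[0].integration_time_ms,
        "roles": {"spectra.csv": "raw", "calibration.csv": "reference+dark"},
    }
    sidecar.update(meta or {})
    (directory / "session.json").write_text(json.dumps(sidecar, indent=2) + "\n")

    if truth is not None:
        df = pd.DataFrame(
            {
                "timestamp_s": truth.timestamps_s,
                "cbvf": truth.cbvf,
                "so2": truth.so2,
                "decoupled": truth.decoupled.astype(int),
                "behavior": truth.behavior if truth.behavior is not None else "resting",
            }
        )
        df.to_csv(directory / "truth.csv", index=False)
    return directory


def _parse_csv(path: pathlib.Path) -> Tuple[List[str], np.ndarray]:
    with open(path) as fh:
        header = fh.readline().strip().split(",")
        rows = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.strip().split(",")
            if len(parts) != len(header):
                raise SessionReadError(
                    f"{path.name}:{lineno}: expected {len(header)} fields, got {len(parts)}"
                )
            try:
                rows.append([float(v) for v in parts])
            except ValueError as exc:
                raise SessionReadError(f"{path.name}:{lineno}: {exc}") from None
    return header, np.array(rows, dtype=float)


def read_session(
    directory: str | pathlib.Path,
) -> Tuple[List[RawSpectrum], CalibrationPair, dict]:
    """Read and validate a session directory."""
    directory = pathlib.Path(directory)
    spath = directory / "spectra.csv"
    cpath = directory / "calibration.csv"
    if not spath.exists():
        raise SessionReadError(f"missing {spath}")
    if not cpath.exists():
        raise SessionReadError(f"missing calibration file {cpath}")

    header, data = _parse_csv(spath)
    if header[0] != "timestamp_s":
        raise SessionReadError("spectra.csv must start with a timestamp_s column")
    grid = np.array([float(h) for h in header[1:]])
    meta = {}
    if (directory / "session.json").exists():
        meta = json.loads((directory / "session.json").read_text())
    it_ms = float(meta.get("integration_time_ms", 1000.0))
    spectra = [
        RawSpectrum(grid, row[1:], integration_time_ms=it_ms, timestamp_s=row[0])
        for row in data
    ]

    cheader, cdata = _parse_csv(cpath)
    if cheader != ["wavelength_nm", "reference_counts", "dark_counts"]:
        raise SessionReadError("calibration.csv has an unexpected header")
    if not np.array_equal(cdata[:, 0], grid):
        raise SessionReadError(
            "calibration and spectra wavelength grids do not match"
        )
    cal = CalibrationPair(
        reference=RawSpectrum(grid, cdata[:, 1], integration_time_ms=it_ms),
        dark=RawSpectrum(grid, cdata[:, 2], integration_time_ms=it_ms),
    )
    return spectra, cal, meta


def write_series(path: str | pathlib.Path, series: HemodynamicTimeSeries) -> None:
    series.to_dataframe().to_csv(path, index=False)


def read_series(path: str | pathlib.Path) -> HemodynamicTimeSeries:
    df = pd.read_csv(path)
    return HemodynamicTimeSeries(
        timestamps_s=df["timestamp_s"].to_numpy(float),
        cbvf_percent=df["cbvf_percent"].to_numpy(float),
        so2_fraction=df["so2_fraction"].to_numpy(float),
        quality=df["quality"].to_numpy(object),
        rel_residual=df["rel_residual"].to_numpy(float),
    )


@dataclass
class SessionConfig:
    """Everything one reproducible run needs; fully serializable."""

    out_dir: str
    seed: int = 0
    scenario: Optional[str] = None        # simulate when set
    session_dir: Optional[str] = None     # read an existing session when set
    protocol: Optional[str] = None        # resting | rotarod | hypercapnia | behavior
    trajectory: dict = field(default_factory=dict)
    instrument: dict = field(default_factory=dict)
    tissue: dict = field(default_factory=dict)
    fit: dict = field(default_factory=dict)
    windows: dict = field(default_factory=dict)
    enforce_leak_qc: bool = True
    smooth: int = 5

    def __post_init__(self) -> None:
        if self.scenario is None and self.session_dir is None:
            raise ValueError("config must set either scenario (simulate) or session_dir")

    @classmethod
    def from_yaml(cls, path: str | pathlib.Path) -> "SessionConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def resolved(self) -> dict:
        """Config plus the fully resolved component settings actually used."""
        out = self.to_dict()
        out["resolved"] = {
            "trajectory": dataclasses.asdict(self.trajectory_params()),
            "instrument": dataclasses.asdict(self.instrument_model()),
            "tissue": dataclasses.asdict(self.tissue_config()),
            "fit": dataclasses.asdict(self.fit_options()),
            "windows": dataclasses.asdict(self.protocol_windows()),
        }
        return out

    def trajectory_params(self) -> TrajectoryParams:
        d = dict(self.trajectory)
        if "decouple_interval_s" in d:
            d["decouple_interval_s"] = tuple(d["decouple_interval_s"])
        return TrajectoryParams(**d)

    def instrument_model(self) -> InstrumentModel:
        d = dict(self.instrument)
        if "exposure_window_nm" in d:
            d["exposure_window_nm"] = tuple(d["exposure_window_nm"])
        return InstrumentModel(**d)

    def tissue_config(self) -> TissueConfig:
        return TissueConfig(**self.tissue)

    def fit_options(self) -> FitOptions:
        d = dict(self.fit)
        if "fit_window_nm" in d:
            d["fit_window_nm"] = tuple(d["fit_window_nm"])
        return FitOptions(**d)

    def protocol_windows(self) -> ProtocolWindows:
        name = self.protocol or self.scenario or "resting"
        if self.windows:
            d = {k: tuple(v) if isinstance(v, (list, tuple)) else v
                 for k, v in self.windows.items()}
            return ProtocolWindows(**d)
        if name == "rotarod":
            return ProtocolWindows.rotarod()
        return ProtocolWindows.hypercapnia()


def _summary_to_row(summary: SessionSummary) -> dict:
    return {k: v for k, v in dataclasses.asdict(summary).items()}


def run_pipeline(config: SessionConfig) -> Dict[str, object]:
    """Run simulate/read -> QC -> calibrate -> fit -> summarize.

    Deterministic given config + seed. Returns the artifact paths plus the
    in-memory series and summary. Aborts with :class:`RuntimeError` when the
    probe leak QC fails and ``enforce_leak_qc`` is set.
    """
    out = pathlib.Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    chrom = load_chromophore_table()
    scat = load_scattering_table()
    tissue = config.tissue_config()
    opts = config.fit_options()
    artifacts: Dict[str, object] = {}
    truth = None

    try:
        log.info("seed=%d scenario=%s", config.seed, config.scenario)
        if config.scenario is not None:
            params = config.trajectory_params()
            instrument = config.instrument_model()
            truth = make_trajectory(config.scenario, params, seed=config.seed)
            spectra, cal, _ = simulate_session(
                truth, instrument, tissue, chrom, scat, seed=config.seed
            )
            session_dir = write_session(
                out / "session", spectra, cal,
                meta={"seed": config.seed, "scenario": config.scenario},
                truth=truth,
            )
            artifacts["session_dir"] = str(session_dir)
            # leak QC on the simulated probe at the session's starting state
            r1, r2 = qc_counts(
                HemodynamicState(truth.cbvf[0], truth.so2[0]),
                instrument, tissue, chrom, scat,
            )
            ratio, ok = leak_snr(r1, r2)
            log.info("leak QC ratio=%.1f pass=%s", ratio, ok)
            artifacts["leak_qc_ratio"] = ratio
            if config.enforce_leak_qc and not ok:
                raise RuntimeError(
                    f"probe leak QC failed: tissue-to-leak ratio {ratio:.1f} < 60"
                )
        else:
            spectra, cal, meta = read_session(config.session_dir)
            artifacts["session_dir"] = str(config.session_dir)

        calibrated = [calibrate(s, cal) for s in spectra]
        series = fit_timeseries(calibrated, opts, tissue, chrom, scat)
        write_series(out / "series.csv", series)
        artifacts["series_csv"] = str(out / "series.csv")
        artifacts["series"] = series
        n_dec = int((np.asarray(series.quality) == "decoupled").sum())
        log.info("fitted %d spectra (%d decoupled)", len(calibrated), n_dec)

        protocol = config.protocol or config.scenario or "resting"
        windows = config.protocol_windows()
        summary: Optional[SessionSummary] = None
        if protocol == "rotarod":
            summary = summarize_rotarod(series, windows, smooth=config.smooth)
        elif protocol == "hypercapnia":
            summary = summarize_hypercapnia(series, windows, smooth=config.smooth)
        elif protocol in ("resting", "decoupling", "behavior"):
            ok_mask = series.ok
            summary = SessionSummary(
                baseline_mean_cbvf_pct=float(series.cbvf_percent[ok_mask].mean()),
                baseline_mean_so2=float(series.so2_fraction[ok_mask].mean()),
                n_ok=int(ok_mask.sum()),
                n_total=len(series.timestamps_s),
            )
        else:
            raise ValueError(f"unknown protocol {protocol!r}")
        if truth is not None and truth.behavior is not None and protocol == "behavior":
            artifacts["behavior"] = summarize_behavior(series, truth.behavior)

        row = _summary_to_row(summary)
        pd.DataFrame([row]).to_csv(out / "summary.csv", index=False)
        (out / "summary.json").write_text(json.dumps(row, indent=2) + "\n")
        artifacts["summary"] = summary
        artifacts["summary_json"] = str(out / "summary.json")

        (out / "resolved_config.yaml").write_text(yaml.safe_dump(config.resolved()))
        log.info("done: %s", out)
    finally:
        log.removeHandler(handler)
        handler.close()
    return artifacts
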