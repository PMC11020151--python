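"""Readers/writers for trajectory CSVs, dose-response CSVs and YAML fit
documents, plus the combined run report.

CSV dialect: comma-separated, ``.`` decimal, UTF-8, no thousands
separators. Every writer embeds its run configuration as ``# key: value``
comment lines at the top of the file; readers skip them. Floats are written
at 12 significant digits so round trips preserve fitted coefficients.
"""

from __future__ import annotations

import io as _io
from dataclasses import asdict

import numpy as np
import pandas as pd
import yaml

from .fitting import LinearModel, PolyModel, Trajectory, VelocityReport
from .hfpn import SimulationResult
from .hill import DOSE_COLUMNS, KiEstimate

FLOAT_FMT = "%.12g"


def _provenance_lines(provenance: dict | None) -> str:
    if not provenance:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in provenance.items())


def write_trajectory_csv(result, path, provenance: dict | None = None) -> None:
    """Write a multi-place simulation result or a single Trajectory.

    Header is ``time,<place_id_1>,...`` (or ``time,<observable>`` for a
    single trajectory), one row per sample.
    """
    if isinstance(result, SimulationResult):
        frame = result.to_frame()
    elif isinstance(result, Trajectory):
        frame = pd.DataFrame({"time": result.times, result.observable: result.values})
    else:
        frame = result
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance_lines(provenance))
        frame.to_csv(fh, index=False, float_format=FLOAT_FMT)


def _read_csv_checked(path) -> pd.DataFrame:
    """Read a CSV with `#` provenance lines, reporting bad cells by file line."""
    with open(path, encoding="utf-8") as fh:
        raw = fh.readlines()
    header_line = None
    data_lines: list[tuple[int, str]] = []  # (1-based file line number, text)
    for i, line in enumerate(raw, start=1):
        if line.lstrip().startswith("#") or not line.strip():
            continue
        if header_line is None:
            header_line = (i, line)
        else:
            data_lines.append((i, line))
    if header_line is None:
        raise ValueError(f"{path}: no header row found")
    frame = pd.read_csv(_io.StringIO(header_line[1] + "".join(t for _, t in data_lines)))
    for col in frame.columns:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: non-numeric value {frame[col].iloc[row]!r} in column "
                f"{col!r} at line {data_lines[row][0]}")
        frame[col] = coerced
    frame.attrs["line_numbers"] = [n for n, _ in data_lines]
    return frame


def read_trajectory_frame(path) -> pd.DataFrame:
    """Read a trajectory CSV (header ``time,<columns...>``) with validation."""
    frame = _read_csv_checked(path)
    if "time" not in frame.columns:
        raise ValueError(f"{path}: header must start with a 'time' column")
    t = frame["time"].to_numpy()
    bad = np.flatnonzero(np.diff(t) <= 0)
    if len(bad):
        line = frame.attrs["line_numbers"][int(bad[0]) + 1]
        raise ValueError(f"{path}: time not strictly increasing at line {line}")
    return frame


def read_trajectory_csv(path, observable: str | None = None,
                        condition: str = "", replicate: int | None = None) -> Trajectory:
    """Read one observable's time course from a trajectory CSV.

    With a multi-column file, ``observable`` selects the column; a
    single-value file needs no selector.
    """
    frame = read_trajectory_frame(path)
    value_cols = [c for c in frame.columns if c != "time"]
    if observable is None:
        if len(value_cols) != 1:
            raise ValueError(f"{path}: multiple value columns {value_cols}; "
                             "specify the observable")
        observable = value_cols[0]
    if observable not in frame.columns:
        raise ValueError(f"{path}: no column {observable!r} (has {value_cols})")
    return Trajectory(observable=observable, condition=condition,
                      times=frame["time"].to_numpy(),
                      values=frame[observable].to_numpy(), replicate=replicate)


def write_replicates_csv(trajs: list[Trajectory], path, provenance: dict | None = None) -> None:
    """Long-format replicate table: time, value, replicate."""
    frame = pd.concat(
        [pd.DataFrame({"time": tr.times, tr.observable: tr.values,
                       "replicate": tr.replicate}) for tr in trajs],
        ignore_index=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance_lines(provenance))
        frame.to_csv(fh, index=False, float_format=FLOAT_FMT)


def read_replicates_csv(path, observable: str | None = None, condition: str = "") -> list[Trajectory]:
    frame = _read_csv_checked(path)
    value_cols = [c for c in frame.columns if c not in ("time", "replicate")]
    if observable is None:
        if len(value_cols) != 1:
            raise ValueError(f"{path}: specify the observable among {value_cols}")
        observable = value_cols[0]
    out = []
    for rep, group in frame.groupby("replicate", sort=True):
        out.append(Trajectory(observable=observable, condition=condition,
                              times=group["time"].to_numpy(),
                              values=group[observable].to_numpy(), replicate=int(rep)))
    return out


def write_doseresponse_csv(data: pd.DataFrame, path, provenance: dict | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance_lines(provenance))
        data.to_csv(fh, index=False, float_format=FLOAT_FMT)


def read_doseresponse_csv(path) -> pd.DataFrame:
    frame = _read_csv_checked(path)
    missing = [c for c in DOSE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: dose-response table lacks column(s) {missing}")
    return frame


# ---------------------------------------------------------------------------
# fitted-model YAML documents
# ---------------------------------------------------------------------------

def model_to_dict(model) -> dict:
    if isinstance(model, PolyModel):
        return {"type": "polynomial", "coefficients": list(model.coefficients),
                "degree": model.degree, "r_squared": model.r_squared,
                "valid_interval": list(model.valid_interval)}
    if isinstance(model, LinearModel):
        return {"type": "linear", "slope": model.slope, "intercept": model.intercept,
                "interval": list(model.interval), "r_squared": model.r_squared}
    raise TypeError(f"cannot serialize {type(model).__name__}")


def model_from_dict(doc: dict):
    if doc["type"] == "polynomial":
        return PolyModel(coefficients=tuple(doc["coefficients"]),
                         r_squared=doc.get("r_squared"),
                         valid_interval=tuple(doc.get("valid_interval", (0.0, 15.0))))
    if doc["type"] == "linear":
        return LinearModel(slope=doc["slope"], intercept=doc["intercept"],
                           interval=tuple(doc["interval"]), r_squared=doc.get("r_squared"))
    raise ValueError(f"unknown model type {doc['type']!r}")


def write_fits_yaml(fits: dict, path, provenance: dict | None = None) -> None:
    """Serialize a mapping of fit names to models (full precision + R^2)."""
    doc = {"provenance": provenance or {},
           "fits": {name: model_to_dict(m) for name, m in fits.items()}}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_fits_yaml(path) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return {name: model_from_dict(d) for name, d in doc["fits"].items()}


# ---------------------------------------------------------------------------
# run report
# ---------------------------------------------------------------------------

def run_report(
    fits_by_condition: dict[str, dict[str, object]],
    reference_coefficients: dict[str, dict[str, tuple[float, ...]]] | None = None,
    velocities: dict[str, VelocityReport] | None = None,
    ki: KiEstimate | None = None,
    warnings: list[str] | None = None,
) -> dict:
    """Assemble the combined report document.

    Tabulates, per observable and condition, the fitted model next to the
    reference (generating) coefficients with R^2; appends the initial
    velocity table, the Ki estimate when dose-response data was supplied
    (marked absent otherwise), and accumulated clamp/filter warnings.
    Missing inputs are listed; a partial report is still produced.
    """
    missing: list[str] = []
    observables: dict[str, dict] = {}
    for cond, fits in fits_by_condition.items():
        for obs, model in fits.items():
            entry = observables.setdefault(obs, {})
            row = model_to_dict(model)
            if reference_coefficients:
                ref = reference_coefficients.get(cond, {}).get(obs)
                if ref is not None:
                    row["reference_coefficients"] = list(ref)
            entry[cond] = row
    if not fits_by_condition:
        missing.append("fits")

    vel_section: dict | str = "absent"
    if velocities:
        vel_section = {cond: {**{k: getattr(v, k) for k in ("V0_NO", "V0_Ca", "V0_EP")},
                              "provenance": v.provenance}
                       for cond, v in velocities.items()}
    else:
        missing.append("velocities")

    ki_section: dict | str = "absent"
    if ki is not None:
        ki_section = {"Ki_nM": ki.ki_nM, "SE_nM": ki.ki_se_nM,
                      "hill_slope": ki.hill_slope, "r_squared": ki.r_squared,
                      "n_replicates": ki.n_replicates,
                      "per_replicate": [asdict(f) for f in ki.per_replicate]}

    return {"observables": observables, "initial_velocities": vel_section,
            "ki": ki_section, "warnings": list(warnings or []),
            "missing_inputs": missing}
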