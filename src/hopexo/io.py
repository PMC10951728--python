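"""Readers and writers: TRC markers, force CSVs, spring tables, trial
bundles and tidy result tables.

All pipeline coordinates are sagittal-plane (x forward, y up).  TRC files
are 3D; on load the mediolateral axis (Z) is dropped, with a logged
warning if the out-of-plane excursion is large.  C3D binary input is not
parsed — export to TRC upstream.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .springs import SpringProfile, SpringValidationError, tabulated_profile

logger = logging.getLogger("hopexo")

FORCE_COLUMNS = ("time_s", "fz_N", "fx_N", "cop_x_m")

__all__ = [
    "ParseError",
    "read_trc",
    "write_trc",
    "read_forces_csv",
    "write_forces_csv",
    "read_spring_table",
    "write_spring_table",
    "write_trial",
    "load_trial",
    "write_tables",
]


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# TRC
# ---------------------------------------------------------------------------

def write_trc(path, markers: Dict[str, np.ndarray], rate: float, units: str = "mm") -> None:
    """Write sagittal marker trajectories as a 3D TRC file (Z = 0)."""
    path = Path(path)
    names = list(markers)
    n = next(iter(markers.values())).shape[0]
    scale = 1000.0 if units == "mm" else 1.0
    with path.open("w") as fh:
        fh.write(f"PathFileType\t4\t(X/Y/Z)\t{path.name}\n")
        fh.write(
            "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
            "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n"
        )
        fh.write(f"{rate:g}\t{rate:g}\t{n}\t{len(names)}\t{units}\t{rate:g}\t1\t{n}\n")
        fh.write("Frame#\tTime\t" + "\t\t\t".join(names) + "\t\t\t\n")
        axes = "\t".join(f"X{i+1}\tY{i+1}\tZ{i+1}" for i in range(len(names)))
        fh.write("\t\t" + axes + "\n\n")
        for i in range(n):
            row = [f"{i+1}", f"{i / rate:.6f}"]
            for name in names:
                x, y = markers[name][i]
                row += [f"{x * scale:.6f}", f"{y * scale:.6f}", "0.000000"]
            fh.write("\t".join(row) + "\n")


def read_trc(path) -> Tuple[Dict[str, np.ndarray], float]:
    """Read a TRC file into sagittal (x forward, y up) metre trajectories."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 5 or not lines[0].startswith("PathFileType"):
        raise ParseError(f"{path}: not a TRC file (bad header line 1)")
    header_keys = lines[1].split("\t")
    header_vals = lines[2].split("\t")
    header = dict(zip(header_keys, header_vals))
    try:
        rate = float(header["DataRate"])
        n_markers = int(header["NumMarkers"])
        units = header["Units"]
    except (KeyError, ValueError) as err:
        raise ParseError(f"{path}: malformed TRC header line 3 ({err})") from err
    if units not in ("mm", "m"):
        raise ParseError(f"{path}: unsupported units {units!r} (line 3)")
    scale = 1e-3 if units == "mm" else 1.0
    names = [s for s in lines[3].split("\t")[2:] if s.strip()]
    if len(names) != n_markers:
        raise ParseError(
            f"{path}: header declares {n_markers} markers, found {len(names)} (line 4)"
        )
    data_rows = []
    for ln, line in enumerate(lines[5:], start=6):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2 + 3 * n_markers:
            raise ParseError(f"{path}: short data row at line {ln}")
        data_rows.append([float(v) for v in parts[2:2 + 3 * n_markers]])
    data = np.asarray(data_rows) * scale
    markers = {}
    z_span = 0.0
    y_all = data[:, 1::3]
    for i, name in enumerate(names):
        xyz = data[:, 3 * i:3 * i + 3]
        markers[name] = xyz[:, :2].copy()
        z_span = max(z_span, float(np.ptp(xyz[:, 2])))
    vertical_extent = float(np.ptp(y_all)) or 1.0
    if z_span > 0.05 * vertical_extent:
        logger.warning(
            "%s: out-of-plane (Z) excursion %.3f m exceeds 5%% of the vertical "
            "extent; sagittal projection may be inaccurate", path, z_span
        )
    return markers, rate


# ---------------------------------------------------------------------------
# forces / spring tables
# ---------------------------------------------------------------------------

def write_forces_csv(path, df: pd.DataFrame) -> None:
    missing = [c for c in FORCE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"force frame lacks required column(s) {missing}")
    df.loc[:, FORCE_COLUMNS].to_csv(path, index=False)


def read_forces_csv(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    for col in FORCE_COLUMNS:
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    t = df["time_s"].to_numpy()
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ParseError(f"{path}: time_s must be strictly increasing")
    return df


def write_spring_table(path, profile: SpringProfile, n: int = 101) -> None:
    """Tabulate a profile's loading (and unloading) branches to CSV."""
    from .springs import spring_force

    d_max = profile.reference_displacement if profile.kind != "tabulated" else profile.table[0][-1]
    d = np.linspace(0.0, d_max, n)
    fl = spring_force(profile, d, "loading")
    fu = spring_force(profile, d, "unloading")
    pd.DataFrame(
        {"displacement_m": d, "force_N": fl,
         "displacement_unload_m": d, "force_unload_N": fu}
    ).to_csv(path, index=False)


def read_spring_table(path, hysteresis_fraction: float = 0.0,
                      rest_length: float = 0.0) -> SpringProfile:
    path = Path(path)
    df = pd.read_csv(path)
    if "displacement_m" not in df.columns or "force_N" not in df.columns:
        raise ParseError(f"{path}: spring table needs displacement_m,force_N columns")
    kwargs = {}
    if "displacement_unload_m" in df.columns and "force_unload_N" in df.columns:
        kwargs = dict(
            displacement_unload=df["displacement_unload_m"].to_numpy(),
            force_unload=df["force_unload_N"].to_numpy(),
        )
    try:
        return tabulated_profile(
            df["displacement_m"].to_numpy(), df["force_N"].to_numpy(),
            hysteresis_fraction=hysteresis_fraction, rest_length=rest_length,
            **kwargs,
        )
    except SpringValidationError as err:
        raise ParseError(f"{path}: {err}") from err


# ---------------------------------------------------------------------------
# trial bundles
# ---------------------------------------------------------------------------

def write_trial(trial, outdir, ground_truth=None) -> Path:
    """Write one trial as TRC + per-leg force CSVs + a YAML manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_trc(outdir / "markers.trc", trial.markers, trial.marker_rate)
    for leg, df in trial.grf.items():
        write_forces_csv(outdir / f"forces_{leg}.csv", df)
    manifest = {
        "condition": trial.condition,
        "participant": dict(trial.participant),
        "marker_rate": trial.marker_rate,
        "grf_rate": trial.grf_rate,
        "exo_leg_mass": trial.exo_leg_mass,
        "meta": {k: (float(v) if isinstance(v, np.floating) else v)
                 for k, v in trial.meta.items()},
    }
    if trial.spring is not None:
        manifest["spring"] = {
            "kind": trial.spring.kind,
            "reference_force": trial.spring.reference_force,
            "reference_displacement": trial.spring.reference_displacement,
            "exponent": trial.spring.exponent,
            "hysteresis_fraction": trial.spring.hysteresis_fraction,
            "rest_length": trial.spring.rest_length,
        }
    with (outdir / "manifest.yaml").open("w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    if ground_truth is not None:
        gt = ground_truth
        df = pd.DataFrame(
            {"time_s": gt.time, "contact": gt.contact_mask.astype(int),
             "displacement_m": gt.displacement, "force_N": gt.force,
             "com_y_m": gt.com_y}
        )
        for j, arr in gt.moments.items():
            df[f"moment_{j}_Nm"] = arr
        for j, arr in gt.arms.items():
            df[f"arm_{j}_m"] = arr
        df.to_csv(outdir / "ground_truth.csv", index=False)
    return outdir


def load_trial(trial_dir):
    """Resolve a written trial bundle back into a HopTrial."""
    from .hopper import HopTrial  # deferred: io must not depend on simulation at import

    trial_dir = Path(trial_dir)
    manifest_path = trial_dir / "manifest.yaml"
    if not manifest_path.exists():
        raise ParseError(f"{trial_dir}: manifest.yaml not found")
    manifest = yaml.safe_load(manifest_path.read_text())
    markers, rate = read_trc(trial_dir / "markers.trc")
    if abs(rate - manifest["marker_rate"]) > 1e-6:
        raise ParseError(
            f"{trial_dir}: TRC rate {rate} does not match manifest "
            f"marker_rate {manifest['marker_rate']}"
        )
    grf = {}
    for leg in ("left", "right"):
        p = trial_dir / f"forces_{leg}.csv"
        if p.exists():
            grf[leg] = read_forces_csv(p)
    if not grf:
        raise ParseError(f"{trial_dir}: no force files found")
    spring = None
    if "spring" in manifest:
        s = manifest["spring"]
        spring = SpringProfile(
            kind=s["kind"], reference_force=s["reference_force"],
            reference_displacement=s["reference_displacement"],
            exponent=s["exponent"], hysteresis_fraction=s["hysteresis_fraction"],
            rest_length=s["rest_length"],
        )
    return HopTrial(
        markers=markers, marker_rate=manifest["marker_rate"], grf=grf,
        grf_rate=manifest["grf_rate"], participant=manifest["participant"],
        condition=manifest["condition"], spring=spring,
        exo_leg_mass=manifest.get("exo_leg_mass", 0.0),
        meta=manifest.get("meta", {}),
    )


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def write_tables(results: pd.DataFrame, outdir, config: Optional[dict] = None,
                 seed: Optional[int] = None, name: str = "results") -> Path:
    """Tidy result CSV plus a JSON run manifest (config hash, versions)."""
    import hopexo

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / f"{name}.csv"
    results.to_csv(csv_path, index=False)
    cfg_json = json.dumps(config or {}, sort_keys=True, default=str)
    manifest = {
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest()[:16],
        "seed": seed,
        "versions": {
            "hopexo": hopexo.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "tables": [csv_path.name],
    }
    with (outdir / f"{name}_manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2)
    return csv_path
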