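"""CSV dialects and config parsing for the command-line workflows.

All files are plain UTF-8 CSV with a header; column names carry their units
(``*_uM``, ``*_nM``, ``time_min``) so a mis-scaled input is visible at the
file level.  Config files are YAML with the same convention.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .binding_equilibrium import FluorescenceTitration
from .channeling import AssayPoint, BufferingDataset, MichaelisParams
from .errors import InvalidInputError
from .rate_extraction import ProgressCurve
from .sedimentation import RadialScan

TITRATION_COLUMNS = ("mode", "ligand_uM", "signal", "site_conc_uM")
PROGRESS_COLUMNS = ("time_min", "abs340")
BUFFERING_COLUMNS = ("design", "nadh_total_uM", "gapdh_sites_uM", "ldh_nM", "v_measured_U_mg")
SCAN_COLUMNS = ("time_s", "radius_cm", "abs280")


def _require_columns(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{path}: missing columns {missing}")


def read_titration_csv(path) -> FluorescenceTitration:
    """One titration per file: mode, ligand_uM, signal, site_conc_uM."""
    df = pd.read_csv(path)
    _require_columns(df, TITRATION_COLUMNS, path)
    modes = df["mode"].unique()
    if len(modes) != 1:
        raise InvalidInputError(f"{path}: expected a single mode, found {list(modes)}")
    sites = df["site_conc_uM"].unique()
    if len(sites) != 1:
        raise InvalidInputError(f"{path}: site_conc_uM must be constant")
    order = np.argsort(df["ligand_uM"].to_numpy())
    return FluorescenceTitration(
        mode=str(modes[0]),
        site_conc=float(sites[0]),
        ligand_concs=df["ligand_uM"].to_numpy(float)[order],
        signals=df["signal"].to_numpy(float)[order],
    )


def write_titration_csv(path, titration: FluorescenceTitration) -> None:
    pd.DataFrame(
        {
            "mode": titration.mode,
            "ligand_uM": titration.ligand_concs,
            "signal": titration.signals,
            "site_conc_uM": titration.site_conc,
        }
    ).to_csv(path, index=False)


def read_progress_csv(path, **curve_kwargs) -> ProgressCurve:
    df = pd.read_csv(path)
    _require_columns(df, PROGRESS_COLUMNS, path)
    return ProgressCurve(
        times=df["time_min"].to_numpy(float),
        absorbance=df["abs340"].to_numpy(float),
        **curve_kwargs,
    )


def write_progress_csv(path, curve: ProgressCurve) -> None:
    pd.DataFrame({"time_min": curve.times, "abs340": curve.absorbance}).to_csv(
        path, index=False
    )


def read_buffering_csv(path, kd_gapdh: float, acceptor_mm: MichaelisParams) -> BufferingDataset:
    """Buffering dataset CSV plus the externally supplied constants."""
    df = pd.read_csv(path)
    _require_columns(df, BUFFERING_COLUMNS, path)
    designs = df["design"].unique()
    if len(designs) != 1:
        raise InvalidInputError(f"{path}: expected a single design, found {list(designs)}")
    points = tuple(
        AssayPoint(
            nadh_total=float(row.nadh_total_uM),
            gapdh_sites=float(row.gapdh_sites_uM),
            ldh_conc=float(row.ldh_nM),
            v_measured=float(row.v_measured_U_mg),
            kd_gapdh=kd_gapdh,
        )
        for row in df.itertuples()
    )
    return BufferingDataset(design=str(designs[0]), points=points, acceptor_mm=acceptor_mm)


def write_buffering_csv(path, dataset: BufferingDataset) -> None:
    pd.DataFrame(
        {
            "design": dataset.design,
            "nadh_total_uM": [p.nadh_total for p in dataset.points],
            "gapdh_sites_uM": [p.gapdh_sites for p in dataset.points],
            "ldh_nM": [p.ldh_conc for p in dataset.points],
            "v_measured_U_mg": [p.v_measured for p in dataset.points],
        }
    ).to_csv(path, index=False)


def read_scans_csv(path) -> list[RadialScan]:
    """Scan blocks keyed by time_s, long format."""
    df = pd.read_csv(path)
    _require_columns(df, SCAN_COLUMNS, path)
    scans = []
    for t, block in df.groupby("time_s", sort=True):
        block = block.sort_values("radius_cm")
        scans.append(
            RadialScan(
                time=float(t),
                radii=block["radius_cm"].to_numpy(float),
                signal=block["abs280"].to_numpy(float),
            )
        )
    return scans


def write_scans_csv(path, scans) -> None:
    frames = [
        pd.DataFrame({"time_s": sc.time, "radius_cm": sc.radii, "abs280": sc.signal})
        for sc in scans
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def load_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise InvalidInputError(f"{path}: config must be a YAML mapping")
    return cfg


def michaelis_from_config(cfg: dict) -> MichaelisParams:
    try:
        return MichaelisParams(
            vmax=float(cfg["vmax_U_mg"]),
            km=float(cfg["km_uM"]),
            vmax_err=float(cfg.get("vmax_err_U_mg", 0.0)),
            km_err=float(cfg.get("km_err_uM", 0.0)),
        )
    except KeyError as exc:
        raise InvalidInputError(f"config missing Michaelis key {exc}") from exc
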