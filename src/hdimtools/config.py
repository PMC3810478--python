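"""Run configuration loading, validation and report writing.

Configurations are YAML or JSON with ``fluorophores`` blocks
(``tau_ns, r0, theta_ns, peak_nm, fwhm_nm, brightness``), an optional
``grid`` block (``T_ns``, ``n_time_gates`` or ``time_edges_ns``,
``wavelength_edges_nm`` or ``wavelength_range_nm`` + ``n_spectral_bins``,
``polarizations``), and optional ``optimization`` / ``simulation`` blocks.
Missing grid fields default to the reference acquisition: 64 time gates
over 12.5 ns, 16 spectral bins over 440-630 nm, two polarization channels.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DomainError
from .models import DetectionGrid, FluorophoreModel, HDSS

__all__ = ["RunConfig", "load_config", "save_config", "write_report", "hdss_to_frame"]

_GRID_DEFAULTS = {
    "T_ns": 12.5,
    "n_time_gates": 64,
    "wavelength_range_nm": (440.0, 630.0),
    "n_spectral_bins": 16,
    "polarizations": ("parallel", "perpendicular"),
}


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration: fluorophores, grid and numeric blocks."""

    fluorophores: tuple[FluorophoreModel, ...]
    grid: DetectionGrid
    optimization: dict = field(default_factory=dict)
    simulation: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "fluorophores": [
                {
                    "tau_ns": f.lifetime_tau,
                    "r0": f.limiting_anisotropy_r0,
                    "theta_ns": f.rot_corr_theta,
                    "peak_nm": f.spectral_peak,
                    "fwhm_nm": f.spectral_fwhm,
                    "brightness": f.brightness,
                    "name": f.name,
                }
                for f in self.fluorophores
            ],
            "grid": {
                "T_ns": self.grid.laser_period_T,
                "time_edges_ns": list(self.grid.time_edges),
                "wavelength_edges_nm": list(self.grid.wavelength_edges),
                "polarizations": list(self.grid.polarization_states),
            },
            "optimization": dict(self.optimization),
            "simulation": dict(self.simulation),
        }

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _parse_fluorophore(block: dict, index: int) -> FluorophoreModel:
    if not isinstance(block, dict):
        raise ConfigError(f"fluorophores[{index}] must be a mapping")
    try:
        return FluorophoreModel(
            lifetime_tau=float(block["tau_ns"]),
            limiting_anisotropy_r0=float(block.get("r0", 0.0)),
            rot_corr_theta=float(block.get("theta_ns", 1.0)),
            spectral_peak=float(block.get("peak_nm", 500.0)),
            spectral_fwhm=float(block.get("fwhm_nm", 50.0)),
            brightness=float(block.get("brightness", 1.0)),
            name=str(block.get("name", f"fluor{index}")),
        )
    except KeyError as e:
        raise ConfigError(f"fluorophores[{index}]: missing required field {e}") from e
    except DomainError as e:
        raise ConfigError(f"fluorophores[{index}]: {e}") from e


def _parse_grid(block: dict) -> DetectionGrid:
    block = dict(block or {})
    T = float(block.get("T_ns", _GRID_DEFAULTS["T_ns"]))
    if "time_edges_ns" in block:
        time_edges = tuple(float(t) for t in block["time_edges_ns"])
    else:
        n = int(block.get("n_time_gates", _GRID_DEFAULTS["n_time_gates"]))
        time_edges = tuple(np.linspace(0.0, T, n + 1))
    if "wavelength_edges_nm" in block:
        wl_edges = tuple(float(w) for w in block["wavelength_edges_nm"])
    else:
        lo, hi = block.get(
            "wavelength_range_nm", _GRID_DEFAULTS["wavelength_range_nm"]
        )
        n = int(block.get("n_spectral_bins", _GRID_DEFAULTS["n_spectral_bins"]))
        wl_edges = tuple(np.linspace(float(lo), float(hi), n + 1))
    pol = tuple(block.get("polarizations", _GRID_DEFAULTS["polarizations"]))
    try:
        return DetectionGrid(
            time_edges=time_edges,
            laser_period_T=T,
            wavelength_edges=wl_edges,
            polarization_states=pol,
        )
    except (DomainError, ValueError) as e:
        raise ConfigError(f"grid: {e}") from e


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    fluor_blocks = raw.get("fluorophores")
    if not fluor_blocks:
        raise ConfigError("fluorophores: at least one fluorophore block required")
    fluors = tuple(
        _parse_fluorophore(b, i) for i, b in enumerate(fluor_blocks)
    )
    grid = _parse_grid(raw.get("grid", {}))
    return RunConfig(
        fluorophores=fluors,
        grid=grid,
        optimization=dict(raw.get("optimization", {})),
        simulation=dict(raw.get("simulation", {})),
    )


def save_config(config: RunConfig, path) -> None:
    path = Path(path)
    data = config.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def hdss_to_frame(hdss: HDSS) -> pd.DataFrame:
    """Tidy per-channel table of a signature: one row per channel with
    polarization label, wavelength bin, time gate (ns) and fraction."""
    g = hdss.grid
    rows = []
    for ip, pol in enumerate(g.polarization_states):
        for il in range(g.n_wavelength):
            for it in range(g.n_time):
                rows.append(
                    {
                        "pol_label": pol,
                        "lambda_lo_nm": g.wavelength_edges[il],
                        "lambda_hi_nm": g.wavelength_edges[il + 1],
                        "t_lo_ns": g.time_edges[it],
                        "t_hi_ns": g.time_edges[it + 1],
                        "fraction": hdss.fractions[ip, il, it],
                    }
                )
    return pd.DataFrame(rows)


def write_report(results: dict, out_dir, seed=None, config: RunConfig | None = None):
    """Write result tables as CSV plus a JSON manifest.

    ``results`` maps table names to DataFrames (or dicts, written into the
    manifest).  The manifest records the package version, seed and config
    hash so a run can be reproduced bit-for-bit.
    """
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "software": "hdimtools",
        "version": __version__,
        "seed": seed,
        "config_hash": config.content_hash() if config is not None else None,
        "tables": [],
        "scalars": {},
    }
    for name, value in results.items():
        if isinstance(value, pd.DataFrame):
            csv_path = out_dir / f"{name}.csv"
            value.to_csv(csv_path, index=False)
            manifest["tables"].append(csv_path.name)
        else:
            manifest["scalars"][name] = value
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out_dir / "manifest.json"
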