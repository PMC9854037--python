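"""Packaged reference tables of the published GZP3 Co-60 dosimetric data.

Ships the printed consensus tables as CSV package data: the dose-rate
constant comparison across sources/codes, radial dose functions per channel
and code, 2D anisotropy functions with the 1D anisotropy row, and the
along-away QA dose-rate grids.  Values are stored verbatim (missing entries
as NaN, never zero); cells that deviate more than 25% from all their grid
neighbours are flagged as anomalies (isolated outliers such as the F = 1.331
entry at r = 2 cm, theta = 80 deg for channel 3) so downstream use can mask
them — the loader itself never alters a value.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .engine import TG43ParameterSet

__all__ = ["FixtureSet", "load_fixtures", "anomaly_flags", "reference_parameters"]

_ACTIVE_LENGTH = {"1_2": 0.1, "3": 0.2}


def _data_path(name: str):
    return resources.files("brachydose").joinpath(f"data/tables/{name}")


def _read(name: str) -> pd.DataFrame:
    ref = _data_path(name)
    with resources.as_file(ref) as path:
        expected = json.loads(_data_path("checksums.json").read_text())[name]
        actual = hashlib.sha256(path.read_bytes()).hexdigest()
        if actual != expected:
            raise IOError(f"package data {name} is corrupted (checksum mismatch)")
        return pd.read_csv(path, float_precision="round_trip")


def anomaly_flags(values: np.ndarray, threshold: float = 0.25) -> np.ndarray:
    """Flag cells deviating more than ``threshold`` from every neighbour.

    Neighbours are the adjacent finite cells along both grid axes; a cell is
    flagged only when it deviates from all of them (at least two required).
    """
    v = np.asarray(values, dtype=float)
    flags = np.zeros(v.shape, dtype=bool)
    nr, nc = v.shape
    for i in range(nr):
        for j in range(nc):
            if not np.isfinite(v[i, j]):
                continue
            devs = []
            for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                ii, jj = i + di, j + dj
                if 0 <= ii < nr and 0 <= jj < nc and np.isfinite(v[ii, jj]):
                    devs.append(abs(v[i, j] - v[ii, jj]) / abs(v[ii, jj]))
            if len(devs) >= 2 and all(d > threshold for d in devs):
                flags[i, j] = True
    return flags


@dataclass
class FixtureSet:
    """All packaged reference tables, with per-cell anomaly flags."""

    dose_rate_constants: pd.DataFrame  # source, code, this_work, lambda, unc
    radial_dose: pd.DataFrame  # r_cm + one column per channel/code
    anisotropy: dict[str, pd.DataFrame]  # channel -> theta_deg + r columns
    anisotropy_flags: dict[str, np.ndarray]
    phi_an: dict[str, pd.DataFrame]  # channel -> one row, r columns
    along_away: dict[str, pd.DataFrame]  # channel -> z_cm + y columns
    along_away_flags: dict[str, np.ndarray]

    def f_table(self, channel: str) -> pd.DataFrame:
        return self.anisotropy[channel]

    def g_column(self, channel: str, code: str = "geant4") -> pd.DataFrame:
        key = f"ch{channel.replace('_', '')}_{code.lower()}"
        return self.radial_dose[["r_cm", key]].rename(columns={key: "g"})


def load_fixtures() -> FixtureSet:
    """Load the complete packaged fixture set (checksum-verified)."""
    anis = {ch: _read(f"anisotropy_ch{ch.replace('_', '')}_F.csv")
            for ch in ("1_2", "3")}
    phi = {ch: _read(f"anisotropy_ch{ch.replace('_', '')}_phian.csv")
           for ch in ("1_2", "3")}
    aa = {ch: _read(f"alongaway_ch{ch.replace('_', '')}.csv")
          for ch in ("1_2", "3")}
    return FixtureSet(
        dose_rate_constants=_read("lambda_comparison.csv"),
        radial_dose=_read("radial_dose.csv"),
        anisotropy=anis,
        anisotropy_flags={ch: anomaly_flags(df.iloc[:, 1:].to_numpy())
                          for ch, df in anis.items()},
        phi_an=phi,
        along_away=aa,
        along_away_flags={ch: anomaly_flags(df.iloc[:, 1:].to_numpy())
                          for ch, df in aa.items()},
    )


def reference_parameters(channel: str, fixtures: FixtureSet | None = None,
                         code: str = "Geant4") -> TG43ParameterSet:
    """Published TG-43 parameter set for a channel, as a usable object.

    Combines the fixture dose-rate constant, radial dose function and
    anisotropy tables into a :class:`TG43ParameterSet` for the forward engine.
    """
    fx = fixtures or load_fixtures()
    lam_df = fx.dose_rate_constants
    row = lam_df[(lam_df["source"] == f"GZP3_ch{channel.replace('_', '')}")
                 & (lam_df["code"] == code)]
    if row.empty:
        raise ValueError(f"no fixture dose-rate constant for channel {channel!r}")
    gdf = fx.g_column(channel, code.lower())
    fdf = fx.anisotropy[channel]
    cols = [c for c in fdf.columns if c != "theta_deg"]
    phi_df = fx.phi_an[channel]
    phi = phi_df.iloc[0].to_numpy(dtype=float)
    phi_r = np.array([float(c) for c in phi_df.columns])
    ok = np.isfinite(phi)
    return TG43ParameterSet(
        channel=channel, code_label=code,
        L=_ACTIVE_LENGTH[channel],
        dose_rate_constant=float(row["lambda_cgy_h_u"].iloc[0]),
        g_r=gdf["r_cm"].to_numpy(), g=gdf["g"].to_numpy(),
        F_r=np.array([float(c) for c in cols]),
        F_theta=fdf["theta_deg"].to_numpy(dtype=float),
        F=fdf[cols].to_numpy(dtype=float),
        phi_r=phi_r[ok], phi_an=phi[ok],
    )
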