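"""Plain-text I/O for pipeline inputs and outputs.

Recharge curves travel as two-column CSV (``t_s``, ``head_m``) with the auger
hole geometry embedded in ``#``-prefixed header comments; census and catchment
tables are ordinary CSV with the documented column schemas.  Rasters use the
ESRI ASCII grid functions in :mod:`crustflux.dem`.
"""

from __future__ import annotations

import io as _io

import pandas as pd

from .hydraulics import AugerHole, RechargeCurve

__all__ = [
    "write_recharge_csv",
    "read_recharge_csv",
    "write_census_csv",
    "read_census_csv",
]


def write_recharge_csv(curve: RechargeCurve, path) -> None:
    hole = curve.hole
    with open(path, "w") as fh:
        fh.write(f"# r={hole.r}\n# R={hole.R}\n# L={hole.L}\n# h0={hole.h0}\n")
        fh.write("t_s,head_m\n")
        for t, h in zip(curve.t, curve.h):
            fh.write(f"{t:.6g},{h:.8g}\n")


def read_recharge_csv(path) -> RechargeCurve:
    meta: dict[str, float] = {}
    body: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                meta[key.strip()] = float(value)
            else:
                body.append(line)
    df = pd.read_csv(_io.StringIO("".join(body)))
    hole = AugerHole(
        r=meta.get("r", 0.025),
        R=meta.get("R"),
        L=meta.get("L", 0.20),
        h0=meta.get("h0", 0.30),
    )
    return RechargeCurve(t=df["t_s"].to_numpy(), h=df["head_m"].to_numpy(), hole=hole)


def write_census_csv(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, index=False)


def read_census_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "total_cells_per_ml" not in df.columns:
        raise ValueError("census CSV must have a total_cells_per_ml column")
    return df
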