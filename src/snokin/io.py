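"""Readers and writers for the package's CSV/JSON interchange formats.

Trace CSV: columns ``time_s,absorbance``; metadata either as ``# key=value``
header lines or in a JSON sidecar (``<name>.json`` next to the CSV) — the
reader accepts both, with header lines taking precedence.

Dataset CSV: columns ``x,k_obs,sd`` with ``# kind=``, ``# pH=``,
``# temp_C=``, ``# NO_M=`` metadata headers.

Configs are JSON or YAML; temperatures may be given in Celsius (``temp_C``)
and are converted to kelvin on load.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .constants import celsius_to_kelvin, kelvin_to_celsius
from .equilibria import TitrationSeries
from .kinetics import Trace
from .regressions import KobsDataset


class FormatError(ValueError):
    pass


def _parse_headers(path: Path) -> tuple[dict, int]:
    """Read ``# key=value`` lines; returns (metadata, number of header lines)."""
    meta: dict = {}
    n = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith("#"):
                break
            n += 1
            body = line.lstrip("#").strip()
            if not body:
                continue
            if "=" not in body:
                raise FormatError(f"{path}:{lineno}: malformed header line {line.strip()!r} "
                                  "(expected '# key=value')")
            key, val = (s.strip() for s in body.split("=", 1))
            try:
                meta[key] = json.loads(val)
            except json.JSONDecodeError:
                meta[key] = val
    return meta, n


def _read_table(path: Path, required: tuple[str, ...]) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    meta, n_header = _parse_headers(path)
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = {**json.loads(sidecar.read_text()), **meta}
    df = pd.read_csv(path, skiprows=n_header, float_precision="round_trip")
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return df, meta


def write_trace(trace: Trace, path: str | Path, sidecar: bool = False) -> None:
    path = Path(path)
    meta = {
        "wavelength_nm": trace.wavelength_nm,
        "NO_M": trace.no,
        "RS_T_M": trace.rs_total,
        "pH": trace.ph,
        "temp_C": kelvin_to_celsius(trace.temperature),
        "heme_M": trace.heme_total,
        **trace.meta,
    }
    with open(path, "w") as fh:
        if not sidecar:
            for k, v in meta.items():
                fh.write(f"# {k}={json.dumps(v)}\n")
        fh.write("time_s,absorbance\n")
        for t, a in zip(trace.time, trace.absorbance):
            fh.write(f"{t:.17g},{a:.17g}\n")
    if sidecar:
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_trace(path: str | Path) -> Trace:
    df, meta = _read_table(Path(path), ("time_s", "absorbance"))
    known = {"wavelength_nm", "NO_M", "RS_T_M", "pH", "temp_C", "heme_M"}
    return Trace(
        time=df["time_s"].to_numpy(),
        absorbance=df["absorbance"].to_numpy(),
        wavelength_nm=float(meta.get("wavelength_nm", 413.0)),
        no=float(meta.get("NO_M", 0.0)),
        rs_total=float(meta.get("RS_T_M", 0.0)),
        ph=float(meta.get("pH", 7.4)),
        temperature=celsius_to_kelvin(float(meta.get("temp_C", 5.0))),
        heme_total=float(meta.get("heme_M", 5e-6)),
        meta={k: v for k, v in meta.items() if k not in known},
    )


def write_dataset(data: KobsDataset, path: str | Path) -> None:
    with open(Path(path), "w") as fh:
        fh.write(f"# kind={data.kind}\n")
        fh.write(f"# pH={data.ph}\n")
        fh.write(f"# temp_C={kelvin_to_celsius(data.temperature)}\n")
        fh.write(f"# NO_M={data.no}\n")
        fh.write("x,k_obs,sd\n")
        sd = data.sd if data.sd is not None else np.full(len(data.x), np.nan)
        for x, k, s in zip(data.x, data.k_obs, sd):
            fh.write(f"{x:.17g},{k:.17g},{s:.17g}\n")


def read_dataset(path: str | Path) -> KobsDataset:
    df, meta = _read_table(Path(path), ("x", "k_obs"))
    if "kind" not in meta:
        raise FormatError(f"{path}: missing '# kind=' header")
    sd = df["sd"].to_numpy() if "sd" in df.columns else None
    if sd is not None and np.all(np.isnan(sd)):
        sd = None
    return KobsDataset(
        x=df["x"].to_numpy(),
        k_obs=df["k_obs"].to_numpy(),
        sd=sd,
        kind=str(meta["kind"]),
        ph=float(meta.get("pH", 7.4)),
        temperature=celsius_to_kelvin(float(meta.get("temp_C", 5.0))),
        no=float(meta.get("NO_M", np.nan)),
    )


def write_titration(series: TitrationSeries, path: str | Path) -> None:
    with open(Path(path), "w") as fh:
        fh.write(f"# ligand_scale={series.ligand_scale}\n")
        fh.write(f"# pH={series.ph}\n")
        fh.write(f"# temp_C={kelvin_to_celsius(series.temperature)}\n")
        fh.write(f"# NO_M={series.no}\n")
        fh.write(f"# heme_M={series.heme_total}\n")
        fh.write("ligand_M,absorbance\n")
        for lg, a in zip(series.ligand, series.absorbance):
            fh.write(f"{lg:.17g},{a:.17g}\n")


def read_titration(path: str | Path) -> TitrationSeries:
    df, meta = _read_table(Path(path), ("ligand_M", "absorbance"))
    return TitrationSeries(
        ligand=df["ligand_M"].to_numpy(),
        absorbance=df["absorbance"].to_numpy(),
        ligand_scale=str(meta.get("ligand_scale", "thiolate")),
        ph=float(meta.get("pH", 7.4)),
        temperature=celsius_to_kelvin(float(meta.get("temp_C", 5.0))),
        no=float(meta.get("NO_M", np.nan)),
        heme_total=float(meta.get("heme_M", 5e-6)),
    )


def load_config(path: str | Path) -> dict:
    """Load a JSON or YAML config; ``temp_C``/``*_temp_C`` keys become kelvin.

    The original Celsius value is kept under its key; a parallel
    ``temperature``/``*_temperature`` key in kelvin is added.
    """
    path = Path(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    out = dict(cfg)
    for key, val in cfg.items():
        if key == "temp_C":
            out["temperature"] = celsius_to_kelvin(float(val))
        elif key.endswith("_temp_C"):
            out[key[: -len("_temp_C")] + "_temperature"] = celsius_to_kelvin(float(val))
    return out
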