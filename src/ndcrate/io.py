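"""File formats, run configuration, and the end-to-end workflow.

Formats are plain delimited text with ``#`` metadata/comment headers:

* mode table — columns ``mode,freq_cm1,g,f`` (``f_au`` accepted as an alias
  for the NDC-projection column), comma- or whitespace-delimited;
* spectral-density table — ``omega_cm1,J,J_D,J_F`` (continuous parts);
* correlation table — ``t_ps,Re_g,Im_g,Re_F,Im_F,Re_D,Im_D``;
* rate-scan table — ``gap,k,k_condon,ln_k_scaled,converged``.

Every writer emits a metadata header sufficient to reproduce the file.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import fixtures
from .bath import DiscreteModeSet, SpectralTriple, parametric_triple, triple_from_modes
from .correlations import (
    CorrelationSet,
    TimeGrid,
    add_ohmic_damping,
    corr_closed_form,
    corr_from_discrete,
    corr_from_spectrum,
)
from .errors import ValidationError
from .rate import gap_scan
from .units import EV_TO_CM, PHYSICAL, REDUCED, ThermoState

__all__ = [
    "read_modes",
    "write_modes",
    "write_spectral_table",
    "write_correlation",
    "write_scan",
    "parse_energy",
    "load_config",
    "run",
]


def write_modes(modes: DiscreteModeSet, path, comment: str = "") -> None:
    """Write a mode table; full float precision so round trips are exact."""
    path = Path(path)
    with path.open("w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("mode,freq_cm1,g,f\n")
        for i in range(len(modes)):
            label = modes.labels[i] if modes.labels else str(i + 1)
            fh.write(f"{label},{modes.omega[i]:.17g},{modes.g[i]:.17g},{modes.f[i]:.17g}\n")


def read_modes(path) -> DiscreteModeSet:
    """Read a mode table (comma- or whitespace-delimited, ``#`` comments)."""
    path = Path(path)
    labels, omega, g, f = [], [], [], []
    header_seen = False
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = [p for p in re.split(r"[,\s]+", line) if p]
            if not header_seen:
                header_seen = True
                low = [p.lower() for p in parts]
                if (
                    len(low) == 4
                    and low[:3] == ["mode", "freq_cm1", "g"]
                    and low[3] in ("f", "f_au")
                ):
                    continue
                raise ValidationError(
                    f"{path}:{lineno}: expected header 'mode,freq_cm1,g,f', got {line!r}"
                )
            if len(parts) != 4:
                raise ValidationError(f"{path}:{lineno}: expected 4 fields, got {len(parts)}")
            try:
                vals = [float(p) for p in parts[1:]]
            except ValueError:
                raise ValidationError(f"{path}:{lineno}: non-numeric field in {line!r}") from None
            if vals[0] <= 0:
                raise ValidationError(f"{path}:{lineno}: frequency must be > 0, got {vals[0]:g}")
            labels.append(parts[0])
            omega.append(vals[0])
            g.append(vals[1])
            f.append(vals[2])
    if not header_seen:
        raise ValidationError(f"{path}: empty mode table")
    return DiscreteModeSet(np.array(omega), np.array(g), np.array(f), labels=labels)


def _meta_header(meta: dict) -> str:
    return "".join(f"# {k}: {v}\n" for k, v in meta.items())


def write_spectral_table(triple: SpectralTriple, omega: np.ndarray, path, meta=None) -> None:
    """Tabulate the continuous densities on ``omega`` with a metadata header.

    Delta peaks are recorded in the header as (position, weight) triples,
    never spiked onto the grid.
    """
    meta = dict(meta or {})
    meta.setdefault("units", triple.units.name)
    meta.setdefault("kind", triple.kind)
    if triple.deltas:
        meta["delta_peaks"] = "; ".join(
            f"omega={p.omega:g} s_fc={p.s_fc:g} s_d={p.s_d:g} s_f={p.s_f:g}" for p in triple.deltas
        )
    om = np.asarray(omega, float)
    arr = np.column_stack([om, triple.J(om), triple.J_D(om), triple.J_F(om)])
    with Path(path).open("w") as fh:
        fh.write(_meta_header(meta))
        fh.write("omega_cm1,J,J_D,J_F\n")
        np.savetxt(fh, arr, delimiter=",", fmt="%.12g")


def write_correlation(corr: CorrelationSet, path, meta=None) -> None:
    meta = dict(meta or {})
    meta.setdefault("units", corr.meta.get("units", PHYSICAL).name)
    meta.setdefault("method", corr.method)
    meta.setdefault("source", corr.meta.get("source", ""))
    th = corr.meta.get("thermo")
    if th is not None:
        meta.setdefault("temperature", th.temperature)
    arr = np.column_stack(
        [corr.t, corr.g.real, corr.g.imag, corr.F.real, corr.F.imag, corr.D.real, corr.D.imag]
    )
    with Path(path).open("w") as fh:
        fh.write(_meta_header(meta))
        fh.write("t_ps,Re_g,Im_g,Re_F,Im_F,Re_D,Im_D\n")
        np.savetxt(fh, arr, delimiter=",", fmt="%.12g")


def write_scan(df: pd.DataFrame, path, meta=None) -> None:
    out = df.rename(columns={"ln_k": "ln_k_scaled"})
    with Path(path).open("w") as fh:
        fh.write(_meta_header(dict(meta or {})))
        out.to_csv(fh, index=False, float_format="%.12g")


_ENERGY_UNITS = {"cm-1": 1.0, "cm^-1": 1.0, "cm1": 1.0, "ev": EV_TO_CM, "mev": EV_TO_CM / 1000.0}


def parse_energy(value: Union[str, float], reduced: bool = False) -> float:
    """Parse an energy with an explicit unit into cm^-1 (or pass through).

    Accepted: bare numbers (cm^-1 in physical mode, dimensionless in reduced
    mode) or strings like ``"1.7816 eV"``, ``"200 cm-1"``.
    """
    if isinstance(value, (int, float)):
        return float(value)
    m = re.fullmatch(r"\s*([-+0-9.eE]+)\s*([A-Za-z^\-0-9]*)\s*", str(value))
    if not m:
        raise ValidationError(f"cannot parse energy {value!r}")
    num, unit = float(m.group(1)), m.group(2).lower()
    if not unit:
        return num
    if reduced:
        raise ValidationError("reduced-unit quantities must be dimensionless")
    try:
        return num * _ENERGY_UNITS[unit]
    except KeyError:
        raise ValidationError(f"unknown energy unit {unit!r} in {value!r}") from None


def load_config(path) -> dict:
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    return cfg


def _build_corr(cfg: dict) -> tuple[CorrelationSet, dict]:
    """Construct the correlation set described by a run configuration."""
    units = REDUCED if cfg.get("units") == "reduced" else PHYSICAL
    reduced = units.reduced
    bath = cfg.get("bath") or {}
    sources = [k for k in ("case", "modes", "params") if k in bath]
    if len(sources) != 1:
        raise ValidationError("config must name exactly one bath source: case | modes | params")
    thermo_cfg = cfg.get("thermo") or {}
    if "theta" in thermo_cfg:
        thermo = ThermoState.from_theta(float(thermo_cfg["theta"]))
        units = REDUCED
        reduced = True
    else:
        thermo = ThermoState(float(thermo_cfg.get("temperature", 300.0)), units)
    integ = cfg.get("integration") or {}
    brd = cfg.get("broadening") or {}
    gamma = brd.get("gamma")
    ohmic = brd.get("ohmic")

    if "case" in bath:
        case = fixtures.table2_case(str(bath["case"]))
        thermo = thermo if "theta" in thermo_cfg else case.thermo
        grid = TimeGrid(float(integ.get("t_max", 40.0)), float(integ.get("dt", 0.01)))
        corr = corr_closed_form(case.params, thermo, grid)
        desc = {"bath": f"case {case.id}", "theta": 1.0 / thermo.temperature}
        return corr, desc
    if "modes" in bath:
        modes = read_modes(bath["modes"])
        desc = {"bath": f"modes file {bath['modes']}"}
    else:
        p = dict(bath["params"])
        from .bath import OhmicDeltaParams

        params = OhmicDeltaParams(**{k: parse_energy(v, reduced) for k, v in p.items()})
        grid = TimeGrid(float(integ.get("t_max", 40.0)), float(integ.get("dt", 0.01)))
        corr = corr_closed_form(params, thermo, grid)
        return corr, {"bath": "parametric"}
    grid = TimeGrid(float(integ.get("t_max", 2.0)), float(integ.get("dt", 1e-4)))
    if gamma is not None:
        triple = triple_from_modes(modes, broadening=parse_energy(gamma, reduced), units=units)
        corr = corr_from_spectrum(triple, thermo, grid)
        desc["broadening"] = f"BO gamma={gamma}"
    else:
        corr = corr_from_discrete(modes, thermo, grid, units=units)
    if ohmic:
        eta = float(ohmic["eta"])
        nu_c = parse_energy(ohmic.get("nu_c", ohmic.get("omega_c")), reduced)
        corr = add_ohmic_damping(corr, eta, nu_c)
        desc["ohmic_addon"] = f"eta={eta}, nu_c={nu_c}"
    return corr, desc


def _gap_grid(cfg: dict, reduced: bool) -> np.ndarray:
    gap = cfg.get("gap")
    if gap is None:
        raise ValidationError("config must provide a gap value or grid")
    if isinstance(gap, dict):
        lo = parse_energy(gap["min"], reduced)
        hi = parse_energy(gap["max"], reduced)
        n = int(gap.get("n", 21))
        return np.linspace(lo, hi, n)
    return np.array([parse_energy(gap, reduced)])


def run(cfg: dict, outdir) -> dict:
    """Execute a full configuration: correlation functions, then rates.

    Writes ``corr.csv`` and ``scan.csv`` under ``outdir`` plus a ``run.log``
    echoing the configuration and diagnostics; returns the scan DataFrame
    and correlation set.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    units_name = cfg.get("units", "physical")
    corr, desc = _build_corr(cfg)
    gaps = _gap_grid(cfg, units_name == "reduced" or "theta" in (cfg.get("thermo") or {}))
    sigma = (cfg.get("integration") or {}).get("gaussian_sigma")
    df = gap_scan(corr, gaps, gaussian_sigma=None if sigma is None else float(sigma))
    write_correlation(corr, outdir / "corr.csv", meta=desc)
    write_scan(df, outdir / "scan.csv", meta={**desc, "units": units_name})
    with (outdir / "run.log").open("w") as fh:
        fh.write(f"config: {cfg}\n")
        fh.write(f"bath: {desc}\n")
        fh.write(f"points: {len(df)}, converged: {int(df['converged'].sum())}\n")
    return {"scan": df, "corr": corr}
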