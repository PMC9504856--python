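"""Reading and writing spectra tables.

Two dialects are supported:

* Wide CSV — columns ``sample_id,polymer,water_fraction,preparation,
  measurement,mode`` followed by one numeric column per wavenumber
  (header = cm^-1, UTF-8, "." decimal).  ``mode`` is optional and defaults
  to absorbance.
* JCAMP-DX — single-spectrum files with an ``##XYDATA=(X++(Y..Y))`` block in
  AFFN (plain decimal) form, the common fixed-resolution FT-NIR export.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import (MODE_ABSORBANCE, MODE_REFLECTANCE, SampleMeta,
                   SpectraError, SpectraSet, Spectrum, WavenumberGrid)

_META_COLS = ["sample_id", "polymer", "water_fraction", "preparation",
              "measurement"]


def write_spectra_table(spectra: SpectraSet, path: str | Path) -> None:
    """Write a SpectraSet as a wide CSV (one row per spectrum)."""
    df = pd.DataFrame({
        "sample_id": [m.sample_id for m in spectra.meta],
        "polymer": [m.polymer for m in spectra.meta],
        "water_fraction": [m.water_fraction for m in spectra.meta],
        "preparation": [m.preparation for m in spectra.meta],
        "measurement": [m.measurement for m in spectra.meta],
        "mode": spectra.mode,
    })
    wide = pd.DataFrame(spectra.matrix,
                        columns=[f"{v:g}" for v in spectra.grid.values])
    pd.concat([df, wide], axis=1).to_csv(path, index=False)


def read_spectra_table(path: str | Path) -> SpectraSet:
    """Read a wide CSV; wavenumber columns are sorted to a monotone grid."""
    df = pd.read_csv(path)
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise SpectraError(f"{path}: missing metadata columns {missing}")
    wn_cols = [c for c in df.columns
               if c not in _META_COLS and c != "mode"]
    try:
        wn = np.array([float(c) for c in wn_cols])
    except ValueError as exc:
        raise SpectraError(f"{path}: non-numeric wavenumber header: {exc}")
    order = np.argsort(wn)
    grid = WavenumberGrid(wn[order])
    sub = df[list(np.array(wn_cols)[order])]
    bad = sub.isna()
    if bad.to_numpy().any():
        r = int(bad.any(axis=1).idxmax())
        c = bad.columns[int(bad.loc[r].to_numpy().argmax())]
        raise SpectraError(f"{path}: missing value at row {r}, column {c}")
    try:
        matrix = sub.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise SpectraError(f"{path}: non-numeric cell: {exc}")
    mode = MODE_ABSORBANCE
    if "mode" in df.columns:
        modes = set(df["mode"].astype(str))
        if len(modes) > 1:
            raise SpectraError(f"{path}: mixed modes {sorted(modes)}")
        mode = modes.pop()
    meta = [SampleMeta(polymer=str(r.polymer),
                       water_fraction=float(r.water_fraction),
                       preparation=int(r.preparation),
                       measurement=int(r.measurement),
                       sample_id=str(r.sample_id))
            for r in df.itertuples()]
    return SpectraSet(grid, matrix, meta, mode)


# ---------------------------------------------------------------------------
# JCAMP-DX (single spectrum, XYDATA=(X++(Y..Y)), AFFN)


def read_jcamp(path: str | Path) -> Spectrum:
    """Read one spectrum from a JCAMP-DX file with an AFFN XYDATA block."""
    lines = Path(path).read_text().splitlines()
    fields: dict[str, str] = {}
    data_start = None
    for i, line in enumerate(lines):
        if line.startswith("##"):
            key, _, val = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            fields[key] = val.strip()
            if key == "XYDATA":
                data_start = i + 1
    if data_start is None:
        raise SpectraError(f"{path}: no ##XYDATA block")
    xfac = float(fields.get("XFACTOR", "1"))
    yfac = float(fields.get("YFACTOR", "1"))
    xs, ys = [], []
    for line in lines[data_start:]:
        if line.startswith("##"):
            break
        parts = line.replace(",", " ").split()
        if not parts:
            continue
        x0 = float(parts[0]) * xfac
        yvals = [float(p) * yfac for p in parts[1:]]
        xs.append(x0)
        ys.append(yvals)
    if not xs:
        raise SpectraError(f"{path}: empty XYDATA block")
    ny = sum(len(y) for y in ys)
    last_x = float(fields["LASTX"]) * xfac if "LASTX" in fields else None
    if last_x is None:
        # infer spacing from consecutive line starts
        step = (xs[1] - xs[0]) / len(ys[0]) if len(xs) > 1 else 1.0
        last_x = xs[0] + step * (ny - 1)
    x = np.linspace(xs[0], last_x, ny)
    y = np.concatenate([np.asarray(v) for v in ys])
    order = np.argsort(x)
    grid = WavenumberGrid(x[order])
    yunits = fields.get("YUNITS", "ABSORBANCE").upper()
    mode = MODE_REFLECTANCE if "REFLECT" in yunits else MODE_ABSORBANCE
    title = fields.get("TITLE", Path(path).stem)
    return Spectrum(grid, y[order], mode,
                    SampleMeta(polymer=title, water_fraction=0.0,
                               sample_id=title))


def write_jcamp(spectrum: Spectrum, path: str | Path,
                title: str | None = None) -> None:
    """Write one spectrum as a minimal AFFN JCAMP-DX file."""
    g = spectrum.grid.values
    y = spectrum.intensity
    title = title or (spectrum.meta.sample_id if spectrum.meta else "spectrum")
    yunits = ("REFLECTANCE" if spectrum.mode == MODE_REFLECTANCE
              else "ABSORBANCE")
    out = [
        f"##TITLE={title}", "##JCAMP-DX=4.24", "##DATA TYPE=INFRARED SPECTRUM",
        "##XUNITS=1/CM", f"##YUNITS={yunits}",
        "##XFACTOR=1", "##YFACTOR=1",
        f"##FIRSTX={g[0]:.6g}", f"##LASTX={g[-1]:.6g}",
        f"##NPOINTS={g.size}", "##XYDATA=(X++(Y..Y))",
    ]
    per_line = 6
    for i in range(0, g.size, per_line):
        chunk = y[i:i + per_line]
        out.append(" ".join([f"{g[i]:.6g}"] + [f"{v:.8g}" for v in chunk]))
    out.append("##END=")
    Path(path).write_text("\n".join(out) + "\n")
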