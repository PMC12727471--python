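"""Spectrum readers/writers (CSV, JCAMP-DX) and run configuration.

The canonical on-disk formats are a two-column CSV (``ppm,intensity``
with header) and JCAMP-DX with AFFN-encoded ``##XYDATA=(X++(Y..Y))``
tables (the simple NTUPLES dialect with a single real data table is
also read). Compressed JCAMP ordinate forms (SQZ/DIF/DUP) are not
supported — spectra written by this package always use AFFN.

Reading normalises every spectrum to the canonical high-to-low ppm
orientation.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import yaml

from .types import PpmInterval, Spectrum

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "RunConfig",
    "load_run_config",
]


class SpectrumParseError(ValueError):
    """Raised with line context when a spectrum file cannot be parsed."""


def _canonical(axis: np.ndarray, y: np.ndarray, meta: dict) -> Spectrum:
    if axis.size and axis[0] < axis[-1]:
        axis, y = axis[::-1].copy(), y[::-1].copy()
    return Spectrum(axis=axis, intensities=y, meta=meta)


# ---------------------------------------------------------------- CSV

def _read_csv(path: Path) -> Spectrum:
    data = np.genfromtxt(path, delimiter=",", names=True)
    if data.dtype.names is None or len(data.dtype.names) < 2:
        raise SpectrumParseError(
            f"{path}: expected a header line and two columns (ppm, intensity)")
    cols = data.dtype.names
    axis = np.atleast_1d(data[cols[0]]).astype(float)
    y = np.atleast_1d(data[cols[1]]).astype(float)
    if np.isnan(axis).any() or np.isnan(y).any():
        raise SpectrumParseError(f"{path}: non-numeric values in data columns")
    return _canonical(axis, y, {"format": "csv", "path": str(path)})


def _write_csv(spec: Spectrum, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("ppm,intensity\n")
        for x, y in zip(spec.axis, spec.intensities):
            fh.write(f"{x:.12e},{y:.12e}\n")


# ---------------------------------------------------------------- JCAMP-DX

_LDR = re.compile(r"^##(?P<label>[^=]*)=\s*(?P<value>.*)$")
_NUM = re.compile(r"[+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?")


def _parse_affn_table(lines: list[str], start: int, path: Path
                      ) -> tuple[np.ndarray, np.ndarray, int]:
    """Parse an (X++(Y..Y)) AFFN table starting after its LDR line."""
    xs: list[float] = []
    ys: list[float] = []
    i = start
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("##"):
            break
        if line and not line.startswith("$$"):
            nums = _NUM.findall(line)
            if len(nums) < 2:
                raise SpectrumParseError(
                    f"{path}:{i + 1}: expected 'x y1 y2 ...', got {line!r}")
            vals = [float(v) for v in nums]
            xs.append(vals[0])
            ys.append(vals[1:])
        i += 1
    if not xs:
        raise SpectrumParseError(f"{path}:{start + 1}: empty data table")
    return np.array(xs), ys, i


def _read_jcamp(path: Path) -> Spectrum:
    lines = path.read_text().splitlines()
    headers: dict[str, str] = {}
    table = None
    i = 0
    while i < len(lines):
        m = _LDR.match(lines[i].strip())
        if m:
            label = m.group("label").strip().upper().replace(" ", "")
            value = m.group("value").strip()
            if label in ("XYDATA", "DATATABLE"):
                if "X++(Y..Y)" not in value.replace(" ", ""):
                    raise SpectrumParseError(
                        f"{path}:{i + 1}: unsupported data table form {value!r}")
                table = _parse_affn_table(lines, i + 1, path)
                i = table[2]
                continue
            headers[label] = value
        i += 1
    if table is None:
        raise SpectrumParseError(f"{path}: no XYDATA/DATA TABLE block found")

    xs, yrows, _ = table
    xfac = float(headers.get("XFACTOR", 1.0))
    yfac = float(headers.get("YFACTOR", 1.0))
    axis_parts: list[np.ndarray] = []
    y_parts: list[np.ndarray] = []
    # each row is a starting X plus consecutive Y values at the grid spacing
    npoints = int(float(headers.get("NPOINTS", sum(len(r) for r in yrows))))
    firstx = float(headers.get("FIRSTX", xs[0] * xfac))
    lastx = float(headers.get("LASTX", xs[-1] * xfac))
    step = (lastx - firstx) / (npoints - 1) if npoints > 1 else 0.0
    for x0, row in zip(xs, yrows):
        start = x0 * xfac
        axis_parts.append(start + step * np.arange(len(row)))
        y_parts.append(np.array(row) * yfac)
    axis = np.concatenate(axis_parts)
    y = np.concatenate(y_parts)
    meta = {"format": "jcamp-dx", "path": str(path),
            "title": headers.get("TITLE", "")}
    if "$NSCANS" in headers:
        meta["n_scans"] = int(float(headers["$NSCANS"]))
    if ".OBSERVEFREQUENCY" in headers:
        meta["spectrometer_freq_mhz"] = float(headers[".OBSERVEFREQUENCY"])
    return _canonical(axis, y, meta)


def _write_jcamp(spec: Spectrum, path: Path) -> None:
    axis, y = spec.axis, spec.intensities
    with open(path, "w") as fh:
        fh.write("##TITLE=" + str(spec.meta.get("title", "lfnmr spectrum")) + "\n")
        fh.write("##JCAMP-DX=5.00\n")
        fh.write("##DATA TYPE=NMR SPECTRUM\n")
        fh.write("##XUNITS=PPM\n##YUNITS=ARBITRARY UNITS\n")
        freq = spec.meta.get("spectrometer_freq_mhz")
        if freq:
            fh.write(f"##.OBSERVE FREQUENCY={freq}\n")
        if spec.meta.get("n_scans"):
            fh.write(f"##$NSCANS={spec.meta['n_scans']}\n")
        fh.write("##XFACTOR=1.0\n##YFACTOR=1.0\n")
        fh.write(f"##FIRSTX={axis[0]:.12e}\n##LASTX={axis[-1]:.12e}\n")
        fh.write(f"##NPOINTS={axis.size}\n")
        fh.write("##XYDATA=(X++(Y..Y))\n")
        per_line = 4
        for k in range(0, axis.size, per_line):
            ys = " ".join(f"{v:.12e}" for v in y[k:k + per_line])
            fh.write(f"{axis[k]:.12e} {ys}\n")
        fh.write("##END=\n")


# ---------------------------------------------------------------- dispatch

def _resolve_format(path: Path, fmt: str | None) -> str:
    if fmt:
        return fmt.lower()
    suffix = path.suffix.lower()
    if suffix in (".jdx", ".dx", ".jcamp"):
        return "jcamp-dx"
    return "csv"


def read_spectrum(path: str | Path, fmt: str | None = None) -> Spectrum:
    """Read a spectrum, normalised to decreasing-ppm orientation.

    Format is inferred from the extension (.jdx/.dx/.jcamp are JCAMP-DX,
    anything else CSV) unless given explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _resolve_format(path, fmt)
    if fmt in ("jcamp-dx", "jcamp", "jdx"):
        return _read_jcamp(path)
    if fmt == "csv":
        return _read_csv(path)
    raise ValueError(f"unknown spectrum format {fmt!r}")


def write_spectrum(spec: Spectrum, path: str | Path,
                   fmt: str | None = None) -> Path:
    """Write a spectrum as CSV or JCAMP-DX (full double precision)."""
    path = Path(path)
    fmt = _resolve_format(path, fmt)
    if fmt in ("jcamp-dx", "jcamp", "jdx"):
        _write_jcamp(spec, path)
    elif fmt == "csv":
        _write_csv(spec, path)
    else:
        raise ValueError(f"unknown spectrum format {fmt!r}")
    return path


# ---------------------------------------------------------------- config

class RunConfig(dict):
    """A validated run configuration (mixture, profile, scans, noise, seed).

    Thin mapping with attribute access; ``regions`` values are
    :class:`PpmInterval`. Defaults follow the reference mixed-sample
    study conditions.
    """

    def __getattr__(self, item):
        try:
            return self[item]
        except KeyError as exc:
            raise AttributeError(item) from exc


_DEFAULT_CONFIG = {
    "mixture": {"glucose": 10.0, "lactate": 2.0, "citrate": 0.2},
    "reference_concentration": 0.1,
    "profile": "zg30",
    "scans": [2 ** k for k in range(9)],
    "noise_sigma": None,  # None -> package default
    "seed": 0,
    "thresholds": {"LOD": 3.0, "LOQ": 10.0},
    "regions": {
        "glucose": [3.19, 3.98],
        "lactate": [1.17, 1.50],
        "citrate": [2.37, 2.82],
    },
    "noise_region": [-2.0, -1.0],
}


def load_run_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML run configuration, filling defaults for missing keys."""
    cfg = dict(_DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"{path}: config must be a mapping")
        cfg.update(user)
    from .library import load_metabolite_library
    library = load_metabolite_library()
    for name in cfg["mixture"]:
        if name not in library:
            raise ValueError(f"config names unknown species {name!r}")
    cfg["regions"] = {k: PpmInterval(*v) for k, v in cfg["regions"].items()}
    cfg["noise_region"] = PpmInterval(*cfg["noise_region"])
    return RunConfig(cfg)
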