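"""Reading and writing infrared spectra in JCAMP-DX.

Scope: the uncompressed AFFN dialects ``##XYDATA=(X++(Y..Y))`` and
``##XYPOINTS=(XY..XY)``. ASDF-compressed payloads (SQZ/DIF/DUP pseudo-digit
encodings) are rejected with :class:`UnsupportedDialectError` rather than
misread. Wavelength axes in micrometers are converted to wavenumbers
(``nu = 1e4 / lambda_um``) and every spectrum is returned with a strictly
ascending axis, regardless of storage order on disk.

Intensity units are taken from ``##YUNITS``. :func:`to_absorbance` converts
transmittance spectra to absorbance (``A = -log10 T``); percent transmittance
is detected by a max-value heuristic because headers in wild data are
unreliable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import JcampParseError, UnitResolutionError, UnsupportedDialectError

__all__ = ["RawSpectrum", "read_jcampdx", "write_jcampdx", "to_absorbance"]

ABSORBANCE = "absorbance"
TRANSMITTANCE = "transmittance"
UNKNOWN = "unknown"

#: floor for T before taking -log10, so opaque samples stay finite
_LOG_EPS = 1e-6

_NUM_RE = re.compile(r"[+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?")
# SQZ digits @A-Ia-i, DIF digits %J-Rj-r, DUP digits S-Zs. Presence of any
# alphabetic character outside an exponent marks a compressed payload.
_ASDF_RE = re.compile(r"[@A-DF-Za-df-z%]|[eE](?![+-]?\d)")


@dataclass
class RawSpectrum:
    """A spectrum as measured: axis in cm^-1, intensities in native units."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    y_units: str = UNKNOWN
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=np.float64)
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.wavenumbers.shape != self.intensities.shape:
            raise ValueError("wavenumbers and intensities must have equal length")
        if self.wavenumbers.size < 2:
            raise ValueError("spectrum needs at least 2 points")
        if not (np.all(np.isfinite(self.wavenumbers)) and np.all(np.isfinite(self.intensities))):
            raise ValueError("spectrum contains non-finite values")
        if not np.all(np.diff(self.wavenumbers) > 0):
            raise ValueError("wavenumbers must be strictly ascending")
        if self.y_units not in (ABSORBANCE, TRANSMITTANCE, UNKNOWN):
            raise ValueError(f"bad y_units: {self.y_units!r}")


def _normalize_yunits(raw: str | None) -> str:
    if raw is None:
        return UNKNOWN
    u = raw.strip().upper()
    if "ABSORBANCE" in u:
        return ABSORBANCE
    if "TRANSMITTANCE" in u or u in ("%T", "T"):
        return TRANSMITTANCE
    return UNKNOWN


def _parse_headers(lines: list[str]) -> tuple[dict, int | None, str | None]:
    """Collect ##KEY=value records; find the data LDR start and its kind."""
    headers: dict[str, str] = {}
    data_start = None
    data_kind = None
    for i, line in enumerate(lines):
        line = line.split("$$")[0].rstrip()
        if not line.startswith("##"):
            continue
        if "=" not in line:
            continue
        key, _, value = line[2:].partition("=")
        key = re.sub(r"[\s_-]", "", key).upper()
        value = value.strip()
        if key in ("XYDATA", "XYPOINTS", "PEAKTABLE"):
            data_start = i
            data_kind = key
            headers[key] = value
        elif key not in headers:  # first block wins
            headers[key] = value
    return headers, data_start, data_kind


def _numbers(line: str, path: Path) -> list[float]:
    cleaned = line.split("$$")[0]
    if _ASDF_RE.search(cleaned):
        raise UnsupportedDialectError(
            f"{path}: compressed (SQZ/DIF/DUP) JCAMP-DX data is not supported"
        )
    toks = _NUM_RE.findall(cleaned)
    leftover = _NUM_RE.sub("", cleaned)
    if re.search(r"[^\s,;]", leftover):
        raise JcampParseError(f"{path}: non-numeric payload in data line: {line!r}")
    return [float(t) for t in toks]


def read_jcampdx(path: str | Path) -> RawSpectrum:
    """Parse a JCAMP-DX file into a :class:`RawSpectrum`.

    The axis is converted to cm^-1 if stored in micrometers and reordered to
    be strictly ascending. ``y_units`` reflects ``##YUNITS`` (``unknown`` if
    absent or unrecognized).
    """
    path = Path(path)
    text = path.read_text(errors="replace")
    lines = text.splitlines()
    headers, data_start, data_kind = _parse_headers(lines)
    if data_start is None:
        raise JcampParseError(f"{path}: no XYDATA/XYPOINTS block found")

    data_lines = []
    for line in lines[data_start + 1 :]:
        stripped = line.split("$$")[0].strip()
        if stripped.startswith("##"):
            break
        if stripped:
            data_lines.append(stripped)
    if not data_lines:
        raise JcampParseError(f"{path}: empty data block")

    xfactor = float(headers.get("XFACTOR", "1"))
    yfactor = float(headers.get("YFACTOR", "1"))

    if data_kind == "XYDATA":
        form = headers.get("XYDATA", "").replace(" ", "").upper()
        if "X++(Y..Y)" not in form:
            raise UnsupportedDialectError(f"{path}: unsupported XYDATA form {form!r}")
        ys: list[float] = []
        for line in data_lines:
            vals = _numbers(line, path)
            if len(vals) < 2:
                raise JcampParseError(f"{path}: XYDATA line with no Y values: {line!r}")
            ys.extend(vals[1:])  # first value is the line's abscissa
        try:
            firstx = float(headers["FIRSTX"])
            lastx = float(headers["LASTX"])
            npoints = int(float(headers["NPOINTS"]))
        except KeyError as e:
            raise JcampParseError(f"{path}: missing required header ##{e.args[0]}") from None
        if npoints != len(ys):
            raise JcampParseError(
                f"{path}: NPOINTS={npoints} but {len(ys)} Y values present"
            )
        x = np.linspace(firstx, lastx, npoints)
        y = np.array(ys) * yfactor
    else:  # XYPOINTS / PEAKTABLE: explicit (x, y) pairs
        flat: list[float] = []
        for line in data_lines:
            flat.extend(_numbers(line, path))
        if len(flat) < 4 or len(flat) % 2:
            raise JcampParseError(f"{path}: XYPOINTS payload is not an even-length pair list")
        arr = np.array(flat).reshape(-1, 2)
        x = arr[:, 0] * xfactor
        y = arr[:, 1] * yfactor

    xunits = headers.get("XUNITS", "").upper()
    if "MICROMETER" in xunits or "MICRON" in xunits:
        with np.errstate(divide="ignore"):
            x = 1e4 / x
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    if np.any(np.diff(x) <= 0):
        raise JcampParseError(f"{path}: duplicate abscissa values")

    meta = {
        "title": headers.get("TITLE", ""),
        "source_file": str(path),
    }
    if "TIME" in headers or "LONGDATE" in headers:
        meta["timestamp"] = headers.get("LONGDATE", headers.get("TIME", ""))
    if "RESOLUTION" in headers:
        meta["resolution"] = headers["RESOLUTION"]

    return RawSpectrum(x, y, _normalize_yunits(headers.get("YUNITS")), meta)


def write_jcampdx(path: str | Path, spectrum: RawSpectrum, title: str = "") -> None:
    """Serialize to ``##XYDATA=(X++(Y..Y))`` AFFN on an even grid.

    The spectrum's axis must be (close to) evenly spaced, which holds for
    everything this package produces. Y values are written with enough digits
    for 1e-6 round-trip fidelity.
    """
    path = Path(path)
    x, y = spectrum.wavenumbers, spectrum.intensities
    step = np.diff(x)
    if not np.allclose(step, step[0], rtol=1e-6, atol=1e-9):
        raise ValueError("write_jcampdx requires an evenly spaced axis")
    yunits = {ABSORBANCE: "ABSORBANCE", TRANSMITTANCE: "TRANSMITTANCE"}.get(
        spectrum.y_units, "ARBITRARY UNITS"
    )
    out = [
        f"##TITLE={title or spectrum.meta.get('title', '')}",
        "##JCAMP-DX=4.24",
        "##DATA TYPE=INFRARED SPECTRUM",
        "##XUNITS=1/CM",
        f"##YUNITS={yunits}",
        "##XFACTOR=1.0",
        "##YFACTOR=1.0",
        f"##FIRSTX={x[0]:.6f}",
        f"##LASTX={x[-1]:.6f}",
        f"##NPOINTS={x.size}",
        f"##FIRSTY={y[0]:.8g}",
        "##XYDATA=(X++(Y..Y))",
    ]
    per_line = 6
    for i in range(0, x.size, per_line):
        chunk = y[i : i + per_line]
        out.append(f"{x[i]:.4f} " + " ".join(f"{v:.8g}" for v in chunk))
    out.append("##END=")
    path.write_text("\n".join(out) + "\n")


def to_absorbance(raw: RawSpectrum) -> RawSpectrum:
    """Return an absorbance spectrum, converting from transmittance if needed.

    Transmittance is converted via ``A = -log10(max(T, 1e-6))``; values above
    1.5 are taken as percent transmittance and divided by 100 first. When
    ``y_units`` is unknown the scale is inferred: values exceeding 1.5 imply
    %T; otherwise a median above 0.5 implies fractional transmittance (IR
    transmittance baselines sit near 1) and a median below 0.2 implies
    absorbance (baselines near 0). Anything in between is ambiguous and
    raises :class:`UnitResolutionError`.
    """
    y = raw.intensities
    units = raw.y_units
    if units == UNKNOWN:
        med = float(np.median(y))
        if float(y.max()) > 1.5 or med > 0.5:
            units = TRANSMITTANCE
        elif med < 0.2 and float(y.min()) >= -0.5:
            units = ABSORBANCE
        else:
            raise UnitResolutionError(
                "cannot decide absorbance vs transmittance "
                f"(median={med:.3g}, max={y.max():.3g})"
            )
    if units == ABSORBANCE:
        if raw.y_units == ABSORBANCE:
            return raw
        return RawSpectrum(raw.wavenumbers, y, ABSORBANCE, dict(raw.meta))
    t = y / 100.0 if float(y.max()) > 1.5 else y
    a = -np.log10(np.maximum(t, _LOG_EPS))
    return RawSpectrum(raw.wavenumbers, a, ABSORBANCE, dict(raw.meta))
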