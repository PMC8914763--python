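"""Reading and writing temperature-matrix files.

A thermogram is stored as plain delimited text: one image row per line,
values in °C, comma- or whitespace-separated.  Optional ``# key: value``
header lines carry the patient id and the view (``face`` or ``mouth``).
Coordinates are 0-based ``(row, col)`` with row 0 at the image top; all
downstream geometry uses this frame.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import numpy as np

from .config import PipelineConfig
from .exceptions import ThermogramFormatError, ThermogramValidationError

__all__ = ["Thermogram", "read_thermogram", "write_thermogram"]

VIEWS = ("face", "mouth")

#: text format used on disk; 6 decimal places keeps >= 7 significant digits
#: for any physically plausible skin/ambient temperature.
_FLOAT_FMT = "%.6f"


@dataclasses.dataclass
class Thermogram:
    """A rectangular grid of surface temperatures in °C.

    ``values`` is row-major with row 0 at the top of the image.  The nominal
    acquisition size is 240 x 320 but any 2-D grid is accepted; individual
    operations state their own minimum-size requirements.
    """

    values: np.ndarray
    view: str = "face"
    id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ThermogramValidationError("temperature grid must be 2-D and nonempty")
        if self.view not in VIEWS:
            raise ThermogramValidationError(f"view must be one of {VIEWS}, got {self.view!r}")
        bad = np.argwhere(~np.isfinite(self.values))
        if bad.size:
            r, c = bad[0]
            raise ThermogramValidationError(
                f"non-finite temperature at (row={r}, col={c})"
            )

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def validate_window(self, min_temp_c: float, max_temp_c: float) -> None:
        """Check every value against the physical plausibility window."""
        bad = np.argwhere((self.values < min_temp_c) | (self.values > max_temp_c))
        if bad.size:
            r, c = bad[0]
            raise ThermogramValidationError(
                f"temperature {self.values[r, c]:.3f} °C at (row={r}, col={c}) "
                f"outside physical window [{min_temp_c}, {max_temp_c}] °C"
            )


def _parse_header(lines: Iterable[str]) -> dict[str, str]:
    meta: dict[str, str] = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if ":" in body:
            key, _, val = body.partition(":")
            meta[key.strip()] = val.strip()
    return meta


def read_thermogram(
    path: str | Path,
    view: str | None = None,
    config: PipelineConfig | None = None,
) -> Thermogram:
    """Read a delimited-text temperature matrix.

    Parameters
    ----------
    path:
        File of one image row per line, comma- or whitespace-delimited
        numeric fields, with optional leading ``# key: value`` header lines.
    view:
        ``"face"`` or ``"mouth"``; overrides any view recorded in the file
        header.  Defaults to the header value, else ``"face"``.
    config:
        Supplies the physical plausibility window; defaults are the camera's
        rated range of -20 °C to +250 °C.

    Raises
    ------
    ThermogramFormatError
        If rows have differing numbers of fields or a field is not numeric.
    ThermogramValidationError
        If any value is non-finite or outside the plausibility window; the
        message names the offending (row, col).
    """
    config = config or PipelineConfig()
    path = Path(path)
    header_lines: list[str] = []
    rows: list[list[float]] = []
    n_fields: int | None = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                header_lines.append(stripped)
                continue
            fields = stripped.replace(",", " ").split()
            try:
                row = [float(f) for f in fields]
            except ValueError as exc:
                raise ThermogramFormatError(f"{path}:{lineno}: non-numeric field ({exc})") from None
            if n_fields is None:
                n_fields = len(row)
            elif len(row) != n_fields:
                raise ThermogramFormatError(
                    f"{path}:{lineno}: ragged row ({len(row)} fields, expected {n_fields})"
                )
            rows.append(row)
    if not rows:
        raise ThermogramFormatError(f"{path}: no data rows")
    meta = _parse_header(header_lines)
    tg = Thermogram(
        np.array(rows, dtype=float),
        view=view or meta.get("view", "face"),
        id=meta.get("id", path.stem),
    )
    tg.validate_window(config.min_temp_c, config.max_temp_c)
    return tg


def write_thermogram(tg: Thermogram, path: str | Path, delimiter: str = ",") -> None:
    """Write a thermogram as delimited text re-readable by :func:`read_thermogram`.

    Validation runs before the file is opened, so an invalid grid (e.g.
    containing NaN) writes no bytes.  The text round-trips exactly: writing a
    grid that was itself read from text reproduces the fields bit for bit.
    """
    if not isinstance(tg, Thermogram):
        raise TypeError("expected a Thermogram")
    # re-run invariant checks: the array may have been mutated after init
    Thermogram(tg.values, view=tg.view, id=tg.id)
    path = Path(path)
    lines = [f"# id: {tg.id}", f"# view: {tg.view}"]
    for row in tg.values:
        lines.append(delimiter.join(_FLOAT_FMT % v for v in row))
    path.write_text("\n".join(lines) + "\n")
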