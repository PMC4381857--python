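"""Read-only JCAMP-DX 4.24 support for wavenumber spectra.

Only the subset needed to exchange NIR spectra is implemented: single- or
multi-block files whose data appear as ``##XYDATA=(X++(Y..Y))`` with
x-units of 1/CM. Ordinates may be written in AFFN (plain numbers) or in the
ASDF compressed forms SQZ, DIF and DUP; ``XFACTOR``/``YFACTOR`` scaling is
applied and the DIF line-checkpoint convention (first ordinate of a line
following a DIF line repeats the previous value) is honoured.
"""

from __future__ import annotations

import re

import numpy as np

from .core import SpectraSet
from .errors import SpectraFormatError, UnsupportedUnitError

_SQZ = {"@": 0}
_SQZ.update({chr(ord("A") + i): i + 1 for i in range(9)})
_SQZ.update({chr(ord("a") + i): -(i + 1) for i in range(9)})
_DIF = {"%": 0}
_DIF.update({chr(ord("J") + i): i + 1 for i in range(9)})
_DIF.update({chr(ord("j") + i): -(i + 1) for i in range(9)})
_DUP = {chr(ord("S") + i): i + 2 for i in range(8)}  # S=2 ... Z=9

_TOKEN_RE = re.compile(
    r"[+-]?\d+\.?\d*(?:[eE][+-]?\d+)?"  # AFFN number
    r"|[@A-Ia-i%J-Rj-r][0-9]*\.?[0-9]*"  # SQZ / DIF with appended digits
    r"|[S-Z][0-9]*"  # DUP with appended digits
)


def _decode_line(line: str, prev_y: float | None, dif_pending: bool):
    """Decode one ``X++(Y..Y)`` data line.

    Returns (ordinates, last_y, line_ends_in_dif). ``dif_pending`` signals
    that the first ordinate is a checkpoint duplicating ``prev_y``.
    """
    tokens = _TOKEN_RE.findall(line)
    if not tokens:
        return [], prev_y, False
    ys: list[float] = []
    y = prev_y
    last_mode = None  # "value" | "dif"
    last_dif = 0.0
    for k, tok in enumerate(tokens):
        if k == 0:
            continue  # leading abscissa value
        head = tok[0]
        if head in _SQZ:
            digit = _SQZ[head]
            rest = tok[1:]
            mag = float(f"{abs(digit)}{rest}" if rest else str(abs(digit)))
            y = mag if digit >= 0 else -mag
            if digit == 0 and rest:
                y = float(rest)
            ys.append(y)
            last_mode, last_dif = "value", 0.0
        elif head in _DIF:
            digit = _DIF[head]
            rest = tok[1:]
            mag = float(f"{abs(digit)}{rest}" if rest else str(abs(digit)))
            d = mag if digit >= 0 else -mag
            if digit == 0 and rest:
                d = float(rest)
            if y is None:
                raise SpectraFormatError("DIF ordinate with no preceding value")
            y = y + d
            ys.append(y)
            last_mode, last_dif = "dif", d
        elif head in _DUP:
            rest = tok[1:]
            count = int(f"{_DUP[head]}{rest}" if rest else str(_DUP[head]))
            if last_mode is None:
                raise SpectraFormatError("DUP token with no preceding ordinate")
            for _ in range(count - 1):
                if last_mode == "dif":
                    y = y + last_dif
                ys.append(y)
        else:  # plain AFFN ordinate
            y = float(tok)
            ys.append(y)
            last_mode, last_dif = "value", 0.0
    if dif_pending and ys:
        check = ys.pop(0)
        if prev_y is not None and abs(check - prev_y) > 1e-6 * max(1.0, abs(prev_y)):
            raise SpectraFormatError(
                f"DIF checkpoint mismatch: {check} != previous ordinate {prev_y}"
            )
    return ys, y, last_mode == "dif"


def _parse_block(text: str) -> tuple[str, np.ndarray, np.ndarray]:
    """Parse one JCAMP data block into (title, x, y)."""
    ldrs: dict[str, str] = {}
    data_lines: list[str] = []
    in_data = False
    for raw in text.splitlines():
        line = raw.split("$$", 1)[0].rstrip()
        if not line.strip():
            continue
        if line.lstrip().startswith("##"):
            label, _, value = line.lstrip()[2:].partition("=")
            key = re.sub(r"[\s_-]", "", label).upper()
            if key == "XYDATA":
                in_data = value.strip().replace(" ", "") == "(X++(Y..Y))"
                if not in_data:
                    raise SpectraFormatError(f"unsupported XYDATA form: {value.strip()!r}")
                continue
            in_data = False
            ldrs[key] = value.strip()
        elif in_data:
            data_lines.append(line)
    if not data_lines:
        raise SpectraFormatError("JCAMP block contains no XYDATA table")
    xunits = ldrs.get("XUNITS", "").upper().replace(" ", "")
    if xunits not in {"1/CM", "CM-1", "CM^-1"}:
        raise UnsupportedUnitError(f"unsupported or missing ##XUNITS: {ldrs.get('XUNITS')!r}")
    try:
        firstx = float(ldrs["FIRSTX"])
        lastx = float(ldrs["LASTX"])
        npoints = int(float(ldrs["NPOINTS"]))
    except KeyError as exc:
        raise SpectraFormatError(f"missing required JCAMP label ##{exc.args[0]}") from None
    yfactor = float(ldrs.get("YFACTOR", "1"))

    ys: list[float] = []
    prev_y: float | None = None
    dif_pending = False
    for line in data_lines:
        decoded, prev_y, dif_pending = _decode_line(line, prev_y, dif_pending)
        ys.extend(decoded)
    if len(ys) != npoints:
        raise SpectraFormatError(f"decoded {len(ys)} ordinates, ##NPOINTS says {npoints}")
    x = np.linspace(firstx, lastx, npoints)
    y = yfactor * np.asarray(ys, dtype=float)
    return ldrs.get("TITLE", "spectrum"), x, y


def read_jcamp(path) -> SpectraSet:
    """Read a JCAMP-DX file (one spectrum per data block) as a SpectraSet.

    All blocks must share one wavenumber grid; ascending grids are flipped
    to the package's decreasing convention.
    """
    with open(path, encoding="utf-8", errors="replace") as fh:
        text = fh.read()
    # Split into blocks on ##END=; keep blocks that contain an XYDATA table.
    chunks = [c for c in re.split(r"##END=.*", text) if "##XYDATA" in c.upper()]
    if not chunks:
        raise SpectraFormatError(f"{path}: no XYDATA blocks found")
    titles: list[str] = []
    grids: list[np.ndarray] = []
    rows: list[np.ndarray] = []
    for chunk in chunks:
        title, x, y = _parse_block(chunk)
        titles.append(title)
        grids.append(x)
        rows.append(y)
    ref = grids[0]
    for g in grids[1:]:
        if g.shape != ref.shape or not np.allclose(g, ref):
            raise SpectraFormatError(f"{path}: data blocks use different wavenumber grids")
    mat = np.vstack(rows)
    if ref.size >= 2 and ref[0] < ref[-1]:
        ref = ref[::-1].copy()
        mat = mat[:, ::-1].copy()
    return SpectraSet(titles, ref, mat, meta={"source": str(path), "format": "jcamp-dx"})
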