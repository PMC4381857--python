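"""Core containers and plain-text I/O for NIR spectra and reference attributes.

The pipeline works on diffuse-reflectance near-infrared spectra recorded as
absorbance ``log10(1/R)`` on a wavenumber grid spanning 10,000-4,000 cm^-1,
together with a per-sample table of eight quality attributes (two
diterpenoid-quinone contents, five powder-physics descriptors, moisture).

Conventions
-----------
* Wavenumber grids are stored strictly decreasing (10,000 -> 4,000 cm^-1),
  matching the FT-NIR export convention, one point per 8 cm^-1 by default.
* Spectra CSV files are comma-separated UTF-8 with a header row
  ``sample_id,<wn_1>,...,<wn_p>``; floats are rendered with shortest
  round-trip precision so read(write(s)) is bitwise lossless.
* Attribute CSV files carry the fixed column set of :data:`ATTRIBUTE_COLUMNS`
  plus ``sample_id`` and ``group``.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, SpectraFormatError

#: Quality-attribute columns, in canonical order. Units: mg/g, mg/g,
#: m^2/g, um, um, um, g/cm^3, percent.
ATTRIBUTE_COLUMNS = (
    "cryptotanshinone",
    "tanshinone_iia",
    "specific_surface_area",
    "d10",
    "d50",
    "d90",
    "tapped_density",
    "moisture",
)

GROUPS = ("homemade", "commercial")


def default_wavenumber_grid(
    high: float = 10_000.0, low: float = 4_000.0, step: float = 8.0
) -> np.ndarray:
    """Decreasing wavenumber grid [high, ..., low] with the given spacing.

    The default reproduces the instrument range 10,000-4,000 cm^-1 at one
    point per 8 cm^-1, i.e. 751 points.
    """
    n = int(round((high - low) / step)) + 1
    return high - step * np.arange(n, dtype=float)


@dataclass
class SpectraSet:
    """A set of NIR spectra sharing one wavenumber grid.

    Parameters
    ----------
    sample_ids : list of str
        Opaque per-spectrum labels, one per row of ``absorbance``.
    wavenumbers : ndarray, shape (n_points,)
        Strictly decreasing grid in cm^-1.
    absorbance : ndarray, shape (n_samples, n_points)
        Unitless log10(1/R) values (or pretreated derivatives thereof).
    meta : dict
        Free-form provenance. The ``"pretreatments"`` key holds an
        append-only list of applied pretreatment records.
    """

    sample_ids: list[str]
    wavenumbers: np.ndarray
    absorbance: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        if self.absorbance.shape != (len(self.sample_ids), self.wavenumbers.size):
            raise SpectraFormatError(
                f"absorbance shape {self.absorbance.shape} does not match "
                f"{len(self.sample_ids)} sample ids x {self.wavenumbers.size} grid points"
            )
        if self.wavenumbers.size >= 2 and not np.all(np.diff(self.wavenumbers) < 0):
            raise SpectraFormatError("wavenumber grid must be strictly decreasing")
        if not np.all(np.isfinite(self.absorbance)):
            raise SpectraFormatError("absorbance contains NaN or Inf")
        if not np.all(np.isfinite(self.wavenumbers)):
            raise SpectraFormatError("wavenumbers contain NaN or Inf")
        self.meta.setdefault("pretreatments", [])

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_points(self) -> int:
        return self.wavenumbers.size

    @property
    def lineage(self) -> tuple:
        """Hashable record of the pretreatment history (name, params) pairs."""
        return tuple(
            (rec["name"], tuple(sorted(rec.get("params", {}).items())))
            for rec in self.meta.get("pretreatments", [])
        )

    def with_absorbance(self, new_a: np.ndarray, record: dict | None = None) -> "SpectraSet":
        """Copy with replaced absorbance, appending ``record`` to the
        pretreatment history (history is append-only by construction)."""
        meta = {k: v for k, v in self.meta.items() if k != "pretreatments"}
        meta["pretreatments"] = list(self.meta.get("pretreatments", []))
        if record is not None:
            meta["pretreatments"].append(record)
        return SpectraSet(list(self.sample_ids), self.wavenumbers.copy(), np.asarray(new_a, float), meta)

    def subset(self, indices: Sequence[int]) -> "SpectraSet":
        """Row subset (e.g. a calibration split), preserving lineage."""
        idx = list(indices)
        meta = dict(self.meta)
        meta["pretreatments"] = list(self.meta.get("pretreatments", []))
        return SpectraSet(
            [self.sample_ids[i] for i in idx],
            self.wavenumbers.copy(),
            self.absorbance[idx, :].copy(),
            meta,
        )


@dataclass
class AttributeTable:
    """Per-sample reference values for the eight quality attributes.

    ``table`` columns: ``sample_id``, the eight :data:`ATTRIBUTE_COLUMNS`,
    and ``group`` (``homemade`` or ``commercial``). These reference vectors
    are the C_i against which spectral predictions are evaluated.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "group", *ATTRIBUTE_COLUMNS}
        missing = required - set(self.table.columns)
        if missing:
            raise SpectraFormatError(f"attribute table missing columns: {sorted(missing)}")
        self.table = self.table.reset_index(drop=True)
        vals = self.table[list(ATTRIBUTE_COLUMNS)].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise SpectraFormatError("attribute table contains NaN or Inf")
        if np.any(vals <= 0):
            raise SpectraFormatError("all attribute values must be strictly positive")
        d = self.table[["d10", "d50", "d90"]].to_numpy(dtype=float)
        if np.any(d[:, 0] > d[:, 1]) or np.any(d[:, 1] > d[:, 2]):
            raise SpectraFormatError("particle-size quantiles must satisfy d10 <= d50 <= d90")
        if np.any(self.table["moisture"].to_numpy(dtype=float) >= 100):
            raise SpectraFormatError("moisture must be below 100 percent")
        bad = set(self.table["group"]) - set(GROUPS)
        if bad:
            raise SpectraFormatError(f"unknown group labels: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.table["sample_id"]]

    @property
    def n_samples(self) -> int:
        return len(self.table)

    def values(self, attribute: str) -> np.ndarray:
        if attribute not in ATTRIBUTE_COLUMNS:
            raise KeyError(f"unknown attribute {attribute!r}; expected one of {ATTRIBUTE_COLUMNS}")
        return self.table[attribute].to_numpy(dtype=float)

    def subset(self, indices: Sequence[int]) -> "AttributeTable":
        return AttributeTable(self.table.iloc[list(indices)].reset_index(drop=True))

    def to_csv(self, path) -> None:
        cols = ["sample_id", *ATTRIBUTE_COLUMNS, "group"]
        self.table[cols].to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "AttributeTable":
        return cls(pd.read_csv(path))


@dataclass
class Dataset:
    """Aligned pair of spectra and reference attributes."""

    spectra: SpectraSet
    attributes: AttributeTable

    def __post_init__(self) -> None:
        if self.spectra.sample_ids != self.attributes.sample_ids:
            raise AlignmentError("spectra and attribute sample ids are not aligned in order")

    @property
    def n_samples(self) -> int:
        return self.spectra.n_samples

    def subset(self, indices: Sequence[int]) -> "Dataset":
        return Dataset(self.spectra.subset(indices), self.attributes.subset(indices))


# ---------------------------------------------------------------------------
# Spectra CSV I/O
# ---------------------------------------------------------------------------

def write_spectra_csv(s: SpectraSet, path) -> None:
    """Write a spectra matrix as CSV (header: sample_id + wavenumbers).

    Floats are rendered with ``repr`` (shortest round-trip form), so a
    subsequent :func:`read_spectra_csv` reproduces the matrix bitwise.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", *[repr(float(v)) for v in s.wavenumbers]])
        for sid, row in zip(s.sample_ids, s.absorbance):
            w.writerow([sid, *[repr(float(v)) for v in row]])


def read_spectra_csv(path) -> SpectraSet:
    """Read a spectra matrix CSV written in the package convention.

    The first column holds sample ids, the remaining headers must parse as
    wavenumbers. The grid is sorted to decreasing order on load; duplicate
    wavenumber columns, ragged rows and non-numeric cells are rejected with
    a located error.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise SpectraFormatError(f"{path}: empty file")
    header = rows[0]
    if len(header) < 2:
        raise SpectraFormatError(f"{path}: header must contain sample_id plus wavenumbers")
    try:
        wn = np.array([float(h) for h in header[1:]], dtype=float)
    except ValueError as exc:
        raise SpectraFormatError(f"{path}: non-numeric wavenumber header: {exc}") from None
    if np.unique(wn).size != wn.size:
        raise SpectraFormatError(f"{path}: duplicate wavenumber columns")
    ids: list[str] = []
    data = np.empty((len(rows) - 1, wn.size), dtype=float)
    for r, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise SpectraFormatError(
                f"{path}: row {r} has {len(row)} fields, expected {len(header)}"
            )
        ids.append(row[0])
        for c, cell in enumerate(row[1:], start=2):
            try:
                v = float(cell)
            except ValueError:
                raise SpectraFormatError(
                    f"{path}: non-numeric cell at row {r}, column {c}: {cell!r}"
                ) from None
            if not math.isfinite(v):
                raise SpectraFormatError(f"{path}: non-finite value at row {r}, column {c}")
            data[r - 2, c - 2] = v
    order = np.argsort(-wn, kind="stable")
    return SpectraSet(ids, wn[order], data[:, order])


def join_attributes(s: SpectraSet, a: AttributeTable) -> Dataset:
    """Join spectra with attributes, reordering attribute rows to spectra order.

    The id sets must match exactly; missing or extra ids raise an
    :class:`AlignmentError` naming the offenders instead of silently
    dropping rows.
    """
    s_ids, a_ids = list(s.sample_ids), list(a.sample_ids)
    missing = [i for i in s_ids if i not in set(a_ids)]
    extra = [i for i in a_ids if i not in set(s_ids)]
    if missing or extra:
        raise AlignmentError(
            f"sample id mismatch: missing from attributes {missing}; "
            f"not present in spectra {extra}"
        )
    if len(set(s_ids)) != len(s_ids):
        raise AlignmentError("duplicate sample ids in spectra")
    tab = a.table.set_index("sample_id").loc[s_ids].reset_index()
    return Dataset(s, AttributeTable(tab))
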