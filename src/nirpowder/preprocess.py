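"""Spectral pretreatment operators and their registry.

Ten named pretreatments are screened by the pipeline: raw (identity),
vector normalization, polynomial baseline correction, Savitzky-Golay
smoothing and its 1st/2nd-derivative variants (smoothing + differentiation
in a single filter pass), spectroscopic transformation (absorbance ->
reflectance -> Kubelka-Munk), multiplicative scatter correction, standard
normal variate, and wavelet denoising.

All operators are pure transforms on a :class:`~nirpowder.core.SpectraSet`
preserving shape and sample order. MSC is the only data-dependent
("fitted") pretreatment: its reference spectrum is learned once, on the
calibration set, and applied unchanged to new data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy.signal import savgol_filter

from .core import SpectraSet
from .errors import DegenerateInputError, DomainError, ParameterError

# ---------------------------------------------------------------------------
# Pure transforms
# ---------------------------------------------------------------------------


def snv(s: SpectraSet) -> SpectraSet:
    """Standard normal variate: per spectrum subtract the mean and divide by
    the sample standard deviation (n-1 denominator)."""
    a = s.absorbance
    mean = a.mean(axis=1, keepdims=True)
    sd = a.std(axis=1, ddof=1, keepdims=True)
    degenerate = np.flatnonzero(sd.ravel() < 1e-300)
    if degenerate.size:
        names = [s.sample_ids[i] for i in degenerate]
        raise DegenerateInputError(f"constant spectrum (SNV undefined) for samples {names}")
    return s.with_absorbance((a - mean) / sd, {"name": "snv", "params": {}})


def msc(s: SpectraSet, reference: np.ndarray | None = None,
        slope_tol: float = 1e-8) -> tuple[SpectraSet, np.ndarray]:
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum x is regressed as x ~ a + b*ref (ordinary least squares)
    and corrected to (x - a)/b. If ``reference`` is None the mean spectrum
    of ``s`` is used (and returned for reuse on new data).
    """
    a = s.absorbance
    ref = a.mean(axis=0) if reference is None else np.asarray(reference, dtype=float)
    if ref.shape != (s.n_points,):
        raise ParameterError("MSC reference must live on the same wavenumber grid")
    ref_c = ref - ref.mean()
    denom = float(ref_c @ ref_c)
    if denom < 1e-300:
        raise DegenerateInputError("MSC reference spectrum is constant")
    b = (a - a.mean(axis=1, keepdims=True)) @ ref_c / denom
    small = np.flatnonzero(np.abs(b) < slope_tol)
    if small.size:
        names = [s.sample_ids[i] for i in small]
        raise DegenerateInputError(f"MSC slope below tolerance for samples {names}")
    intercept = a.mean(axis=1) - b * ref.mean()
    corrected = (a - intercept[:, None]) / b[:, None]
    return s.with_absorbance(corrected, {"name": "msc", "params": {}}), ref


def savgol(s: SpectraSet, window: int = 11, polyorder: int = 2, deriv: int = 0) -> SpectraSet:
    """Savitzky-Golay moving least-squares polynomial filter.

    Derivatives are taken with respect to wavenumber (scaled by the grid
    step, so first-derivative units are per cm^-1); edges are handled by
    polynomial extrapolation of the terminal window. Smoothing and
    differentiation happen in one filter pass.
    """
    if window % 2 == 0:
        raise ParameterError("Savitzky-Golay window must be odd")
    if window <= polyorder:
        raise ParameterError("window must exceed polyorder")
    if deriv not in (0, 1, 2):
        raise ParameterError("deriv must be 0, 1 or 2")
    if polyorder < deriv:
        raise ParameterError("polyorder must be >= deriv")
    if window > s.n_points:
        raise ParameterError("window exceeds number of grid points")
    step = float(abs(s.wavenumbers[0] - s.wavenumbers[1])) if s.n_points > 1 else 1.0
    out = savgol_filter(s.absorbance, window, polyorder, deriv=deriv,
                        delta=step, axis=1, mode="interp")
    if deriv % 2 == 1:
        out = -out  # grid stored decreasing: d/d(index) = -d/d(nu) * step
    return s.with_absorbance(out, {"name": f"savgol_d{deriv}",
                                   "params": {"window": window, "polyorder": polyorder,
                                              "deriv": deriv}})


def normalize(s: SpectraSet, mode: str = "vector") -> SpectraSet:
    """Per-spectrum normalization: unit Euclidean norm (default), unit
    maximum absolute value, or unit integrated area over wavenumber."""
    a = s.absorbance
    if mode == "vector":
        denom = np.linalg.norm(a, axis=1)
    elif mode == "max":
        denom = np.max(np.abs(a), axis=1)
    elif mode == "area":
        denom = np.abs(np.trapezoid(a, x=s.wavenumbers, axis=1))
    else:
        raise ParameterError(f"unknown normalization mode {mode!r}")
    bad = np.flatnonzero(denom < 1e-300)
    if bad.size:
        names = [s.sample_ids[i] for i in bad]
        raise DegenerateInputError(f"zero norm (cannot normalize) for samples {names}")
    return s.with_absorbance(a / denom[:, None], {"name": "normalization",
                                                 "params": {"mode": mode}})


def baseline_correct(s: SpectraSet, order: int = 1) -> SpectraSet:
    """Subtract a least-squares polynomial of the given order in wavenumber
    from each spectrum (order 0 = mean subtraction, 1 = linear detrend)."""
    if order < 0:
        raise ParameterError("baseline order must be >= 0")
    if order >= s.n_points:
        raise ParameterError("baseline order must be below the number of grid points")
    x = (s.wavenumbers - s.wavenumbers.mean())
    span = np.abs(x).max()
    x = x / span if span > 0 else x
    V = np.vander(x, order + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(V, s.absorbance.T, rcond=None)
    fitted = (V @ coef).T
    return s.with_absorbance(s.absorbance - fitted,
                             {"name": "baseline", "params": {"order": order}})


def spectro_transform(s: SpectraSet, mode: str = "kubelka_munk",
                      tol: float = 1e-9) -> SpectraSet:
    """Spectroscopic transformation of absorbance data.

    Absorbance A = log10(1/R) is inverted to reflectance R = 10**(-A);
    ``mode="to_reflectance"`` returns R, ``mode="kubelka_munk"`` returns
    f(R) = (1-R)^2 / (2R), which is linear in absorber concentration under
    the Kubelka-Munk diffuse-reflectance model. Requires R in (0, 1] up to
    a clipping tolerance (i.e. A >= 0).
    """
    if mode not in ("to_reflectance", "kubelka_munk"):
        raise ParameterError(f"unknown spectroscopic transform mode {mode!r}")
    a = s.absorbance
    if np.any(a < -tol):
        raise DomainError("negative absorbance implies reflectance > 1; "
                          "spectroscopic transform undefined")
    r = np.power(10.0, -np.maximum(a, 0.0))
    if mode == "to_reflectance":
        out = r
    else:
        out = (1.0 - r) ** 2 / (2.0 * r)
    return s.with_absorbance(out, {"name": "spectro_transform", "params": {"mode": mode}})


def wavelet_denoise(s: SpectraSet, wavelet: str = "db4", level: int = 4,
                    threshold: float | str = "universal") -> SpectraSet:
    """Discrete-wavelet soft-threshold denoising.

    Detail coefficients are soft-thresholded at the universal threshold
    sigma * sqrt(2 ln N), with the noise scale sigma estimated from the
    median absolute deviation of the finest detail level; pass a numeric
    ``threshold`` to override (0 reproduces the input up to reconstruction
    round-off). Output length equals input length.
    """
    if wavelet not in pywt.wavelist(kind="discrete"):
        raise ParameterError(f"unknown discrete wavelet {wavelet!r}")
    max_level = pywt.dwt_max_level(s.n_points, pywt.Wavelet(wavelet).dec_len)
    if not (1 <= level <= max_level):
        raise ParameterError(f"level must be in [1, {max_level}] for {s.n_points} points")
    out = np.empty_like(s.absorbance)
    n = s.n_points
    for i, row in enumerate(s.absorbance):
        coeffs = pywt.wavedec(row, wavelet, level=level, mode="symmetric")
        if threshold == "universal":
            finest = coeffs[-1]
            sigma = np.median(np.abs(finest - np.median(finest))) / 0.6744897501960817
            thr = sigma * np.sqrt(2.0 * np.log(n))
        else:
            thr = float(threshold)
        if thr > 0.0:
            denoised = [coeffs[0]] + [pywt.threshold(c, thr, mode="soft")
                                      for c in coeffs[1:]]
        else:
            denoised = coeffs
        out[i] = pywt.waverec(denoised, wavelet, mode="symmetric")[:n]
    return s.with_absorbance(out, {"name": "wavelet_denoise",
                                   "params": {"wavelet": wavelet, "level": level,
                                              "threshold": threshold}})


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

@dataclass
class Pretreatment:
    """A named pretreatment with parameters and (optional) fitted state.

    ``fit`` learns data-dependent state (only MSC has any: its reference
    spectrum) and is intended to see the calibration set only; ``transform``
    never refits, so a fitted pretreatment applied twice to the same input
    gives identical output.
    """

    name: str
    params: dict = field(default_factory=dict)
    fitted_state: dict = field(default_factory=dict)

    def fit(self, s: SpectraSet) -> "Pretreatment":
        if self.name == "msc" and "reference" not in self.fitted_state:
            _, ref = msc(s, **self.params)
            self.fitted_state["reference"] = ref
        return self

    def transform(self, s: SpectraSet) -> SpectraSet:
        name = self.name
        if name == "raw":
            return s.with_absorbance(s.absorbance.copy(), {"name": "raw", "params": {}})
        if name == "normalization":
            return normalize(s, **self.params)
        if name == "baseline":
            return baseline_correct(s, **self.params)
        if name == "sg_smooth":
            return savgol(s, deriv=0, **self.params)
        if name == "sg_1st":
            return savgol(s, deriv=1, **self.params)
        if name == "sg_2nd":
            return savgol(s, deriv=2, **self.params)
        if name == "spectro_transform":
            return spectro_transform(s, **self.params)
        if name == "snv":
            return snv(s)
        if name == "wavelet_denoise":
            return wavelet_denoise(s, **self.params)
        if name == "msc":
            ref = self.fitted_state.get("reference")
            if ref is None:
                raise DegenerateInputError("MSC pretreatment must be fitted before transform")
            out, _ = msc(s, reference=ref, **self.params)
            return out
        raise LookupError(f"unknown pretreatment {name!r}")

    def fit_transform(self, s: SpectraSet) -> SpectraSet:
        return self.fit(s).transform(s)


#: Canonical registry order mirrors the screening-table row inventory.
REGISTRY: tuple[str, ...] = (
    "raw", "sg_smooth", "normalization", "spectro_transform", "msc",
    "sg_1st", "sg_2nd", "baseline", "snv", "wavelet_denoise",
)

#: Report abbreviations for each registry entry.
ABBREVIATIONS: dict[str, str] = {
    "raw": "Raw",
    "sg_smooth": "S-G smooth",
    "normalization": "Normalization",
    "spectro_transform": "S-T",
    "msc": "MSC",
    "sg_1st": "S-G 1st",
    "sg_2nd": "S-G 2nd",
    "baseline": "Baseline",
    "snv": "SNV",
    "wavelet_denoise": "WDS",
}

_ALIASES = {abbrev.lower(): name for name, abbrev in ABBREVIATIONS.items()}

_DEFAULT_PARAMS: dict[str, dict] = {
    "raw": {},
    "sg_smooth": {"window": 11, "polyorder": 2},
    "normalization": {"mode": "vector"},
    "spectro_transform": {"mode": "kubelka_munk"},
    "msc": {},
    "sg_1st": {"window": 11, "polyorder": 2},
    "sg_2nd": {"window": 11, "polyorder": 2},
    "baseline": {"order": 1},
    "snv": {},
    "wavelet_denoise": {"wavelet": "db4", "level": 4},
}


def list_registry() -> list[str]:
    """The ten registered pretreatment names, in screening order."""
    return list(REGISTRY)


def get_pretreatment(name: str, **params) -> Pretreatment:
    """Look up a pretreatment by canonical name or report abbreviation,
    with parameter overrides merged over the defaults."""
    canonical = _ALIASES.get(name.lower(), name)
    if canonical not in REGISTRY:
        raise LookupError(
            f"unknown pretreatment {name!r}; valid names: {', '.join(REGISTRY)}")
    merged = dict(_DEFAULT_PARAMS[canonical])
    merged.update(params)
    return Pretreatment(canonical, merged)
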