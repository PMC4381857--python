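"""Synthetic 50-batch NIR dataset generator and extraction design schedule.

The generator emulates the statistical structure the calibration study
assumes: two sample groups (20 "homemade" ground extracts, 30 "commercial"
spray-dried extracts) whose attribute distributions match the reported
group means and spreads; mixture spectra built from Gaussian band models
under Beer-Lambert additivity; particle-size-driven multiplicative scatter;
moisture combination/overtone bands; a random polynomial baseline whose
offset grows with median particle size; and iid detector noise.

Two of the eight attributes - tapped density and specific surface area -
are tied to the spectra only through a smooth *nonlinear* function of the
scatter coordinate 1/D50 and the composition: a Hermite quadratic plus a
size-composition interaction. Both nonlinear parts are invisible to every
linear functional of the spectra, so linear calibrations (PLS) hit a
residual floor on these two attributes that a kernel method (LS-SVM) does
not; the six remaining attributes are linearly encoded. This is the
structural hook that lets the pipeline reproduce the observed
PLS-vs-LS-SVM contrast.

A central-composite-design schedule generator for the three extraction
factors (ethanol concentration, ethanol volume, decoction time) is included
because the homemade half of the sample set is defined by that design.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    ATTRIBUTE_COLUMNS,
    AttributeTable,
    Dataset,
    SpectraSet,
    default_wavenumber_grid,
)
from .errors import ParameterError

#: z-score of the 90th percentile; D10/D90 are the 10%/90% quantiles of a
#: per-sample (piecewise) log-normal particle-size distribution.
_Z90 = 1.2815515655446004


# ---------------------------------------------------------------------------
# Band model
# ---------------------------------------------------------------------------

@dataclass
class BandModel:
    """Gaussian band sets (center cm^-1, sigma cm^-1, height a.u.) per
    mixture component. Components: the two quantified diterpenoids, the bulk
    extract matrix, and water."""

    bands: dict[str, list[tuple[float, float, float]]]

    def __post_init__(self) -> None:
        for comp, rows in self.bands.items():
            for c, w, h in rows:
                if not (4000.0 <= c <= 10_000.0):
                    raise ParameterError(f"{comp}: band center {c} outside [4000, 10000] cm^-1")
                if h < 0 or w <= 0:
                    raise ParameterError(f"{comp}: band width/height must be positive")

    def profile(self, component: str, wavenumbers: np.ndarray) -> np.ndarray:
        """Pure-component absorbance profile on the given grid."""
        out = np.zeros_like(wavenumbers, dtype=float)
        for c, w, h in self.bands[component]:
            out += h * np.exp(-0.5 * ((wavenumbers - c) / w) ** 2)
        return out


def default_band_model() -> BandModel:
    """Band positions used by the default generator.

    The two diterpenoids get four distinct bands each in the information-rich
    4,000-7,000 cm^-1 combination region; water sits at its classical
    ~5,155 and ~6,900 cm^-1 combination/overtone bands; the matrix is a set
    of broad overlapping bands giving the baseline absorbance level that a
    dense extract powder shows across the NIR.
    """
    return BandModel(
        bands={
            "cryptotanshinone": [
                (4320.0, 45.0, 15.0),
                (4730.0, 60.0, 12.0),
                (5620.0, 55.0, 10.0),
                (6110.0, 70.0, 7.5),
            ],
            "tanshinone_iia": [
                (4460.0, 50.0, 15.0),
                (4880.0, 55.0, 12.0),
                (5840.0, 60.0, 10.0),
                (6310.0, 75.0, 7.5),
            ],
            "matrix": [
                (4400.0, 900.0, 0.35),
                (5600.0, 1200.0, 0.30),
                (7400.0, 1500.0, 0.25),
                (8600.0, 1200.0, 0.15),
                (9500.0, 900.0, 0.12),
            ],
            "water": [
                (5155.0, 80.0, 2.2),
                (6900.0, 120.0, 1.4),
            ],
        }
    )


# ---------------------------------------------------------------------------
# Simulation configuration
# ---------------------------------------------------------------------------

def _default_group_params() -> dict:
    """Group-wise attribute distribution parameters.

    The targets are the reported per-group statistics of the sample set's
    physical and chemical attribute tables. Chemical contents are drawn
    from log-normals truncated to the observed content range, so the
    *pre-truncation* (mean, sd) pairs stored here are inflated relative to
    the targets; they were calibrated once so the truncated draws reproduce
    the tabulated group means/SDs. D50 draws are truncated to the reported
    group ranges. The particle-size log-widths sigma_lo/sigma_hi are
    back-computed exactly from the group mean D10/D50/D90 (so with all SDs
    zeroed the quantile triple reproduces the group means) and co-vary with
    the batch log-median through the coupling slopes k_lo/k_hi, which were
    calibrated to the tabulated D10/D90 spreads: grinding yields coarse
    batches with highly variable fine tails, spray drying uniform fines
    with variable coarse tails.
    """
    hm = {
        "cryptotanshinone": (22.06, 27.45),
        "tanshinone_iia": (29.03, 44.67),
        "moisture": (3.01, 1.22),
        "d50": (52.52, 12.36),
        "d50_bounds": (35.52, 83.33),
        "ln_d50_median": math.log(52.52 / math.sqrt(1.0 + (12.36 / 52.52) ** 2)),
        "sigma_lo": math.log(52.52 / 12.05) / _Z90,
        "sigma_hi": math.log(126.1 / 52.52) / _Z90,
        "k_lo": 0.57,
        "k_hi": 0.32,
        "tapped_density": 0.72,
        "specific_surface_area": 0.240,
        "dt_noise_sd": 0.018,
        "ssa_noise_sd": 0.035,
    }
    cm = {
        "cryptotanshinone": (18.34, 20.01),
        "tanshinone_iia": (25.0, 250.0),
        "moisture": (3.21, 0.846),
        "d50": (27.49, 11.57),
        "d50_bounds": (15.34, 57.17),
        "ln_d50_median": math.log(27.49 / math.sqrt(1.0 + (11.57 / 27.49) ** 2)),
        "sigma_lo": math.log(27.49 / 6.917) / _Z90,
        "sigma_hi": math.log(101.0 / 27.49) / _Z90,
        "k_lo": -0.46,
        "k_hi": 0.21,
        "tapped_density": 0.73,
        "specific_surface_area": 0.317,
        "dt_noise_sd": 0.012,
        "ssa_noise_sd": 0.010,
    }
    return {"homemade": hm, "commercial": cm}


@dataclass
class SimConfig:
    """Knobs of the synthetic dataset generator.

    Attributes
    ----------
    n_homemade, n_commercial : int
        Group sizes; defaults 20 and 30 reproduce the 50-batch sample set.
    group_params : dict
        Per-group attribute distribution parameters (see
        :func:`_default_group_params`).
    chem_bounds : (float, float)
        Truncation bounds (mg/g) for the log-normal content draws.
    moisture_bounds : (float, float)
        Truncation bounds (%) for the moisture draws.
    sigma_jitter_lo, sigma_jitter_hi : float
        SD of the per-sample jitter on the particle-size log-widths; this
        is spread of the size-distribution *shape* that is not encoded in
        the spectra and therefore floors D10/D90 predictability.
    u_center, u_scale : float
        Standardisation constants for the scatter coordinate u = 1/D50
        (1/um); frozen population-level values, not data-derived.
    scatter_slope : float
        Multiplicative scatter factor m = 1 + scatter_slope*(u - u_center);
        affine in 1/D50, smaller particles scattering more strongly.
    baseline_order, baseline_amplitude : int, float
        Random-coefficient polynomial baseline per spectrum.
    baseline_d50_coeff : float
        Additive baseline offset per um of D50 (larger particles raise the
        apparent absorbance level), the linear spectral encoding of the
        median size.
    baseline_d10_coeff : float
        Baseline tilt (per um of D10, along the scaled wavenumber
        coordinate) encoding the fine fraction: finer tails scatter short
        wavelengths more strongly.
    noise_sd : float
        iid Gaussian detector noise (absorbance units).
    comp_center, comp_scale : float
        Standardisation constants for the composition coordinate
        v = (total diterpenoid content - comp_center)/comp_scale (mg/g).
    nonlinearity : float in [0, 1]
        Weight w of the nonlinear part of the tapped-density / specific-
        surface-area link - an equal mix of the Hermite quadratic (z^2-1)
        and the size-composition interaction z*v; w = 0 makes both
        attributes linearly encoded.
    link_scale_dt, link_scale_ssa : float
        Amplitude (g/cm^3, m^2/g) of the link term around the group means;
        the per-group unencoded residual spread lives in ``group_params``
        (``dt_noise_sd`` / ``ssa_noise_sd``).
    nonlinear_residual_floor : float
        Declared lower bound on the fraction of link variance that no
        linear functional of the spectra can explain (~= w^2).
    assay_sd_chem : float
        Absolute measurement error (mg/g) of the HPLC content assays.
    assay_cv_psd, assay_cv_ssa, assay_cv_dt : float
        Relative measurement error of the laser-diffraction, BET and
        tapping reference methods, applied by :func:`add_assay_noise`.
    assay_sd_moisture : float
        Absolute measurement error (%) of loss-on-drying moisture.
    seed : int
        Default random seed; overridable per call.
    """

    n_homemade: int = 20
    n_commercial: int = 30
    group_params: dict = field(default_factory=_default_group_params)
    chem_bounds: tuple[float, float] = (0.5, 160.0)
    moisture_bounds: tuple[float, float] = (0.5, 15.0)
    sigma_jitter_lo: float = 0.10
    sigma_jitter_hi: float = 0.05
    u_center: float = 0.031
    u_scale: float = 0.012
    comp_center: float = 37.0
    comp_scale: float = 32.0
    scatter_slope: float = 0.5
    baseline_order: int = 2
    baseline_amplitude: float = 0.004
    baseline_d50_coeff: float = 0.008
    baseline_d10_coeff: float = 0.004
    noise_sd: float = 0.001
    nonlinearity: float = 0.8
    link_scale_dt: float = 0.075
    link_scale_ssa: float = 0.06
    nonlinear_residual_floor: float = 0.15
    assay_sd_chem: float = 0.5
    assay_cv_psd: float = 0.02
    assay_cv_ssa: float = 0.03
    assay_cv_dt: float = 0.01
    assay_sd_moisture: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_homemade < 0 or self.n_commercial < 0:
            raise ParameterError("group sizes must be non-negative")
        if not (0.0 <= self.nonlinearity <= 1.0):
            raise ParameterError("nonlinearity weight must lie in [0, 1]")
        for name in ("sigma_jitter_lo", "sigma_jitter_hi", "noise_sd",
                     "assay_sd_chem", "assay_cv_psd", "assay_cv_ssa", "assay_cv_dt",
                     "assay_sd_moisture"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")


# ---------------------------------------------------------------------------
# Central composite design
# ---------------------------------------------------------------------------

DESIGN_FACTORS = ("ethanol_concentration", "ethanol_volume", "decoction_time")
DESIGN_BOUNDS = {"ethanol_concentration": (80.0, 100.0),
                 "ethanol_volume": (4.0, 6.0),
                 "decoction_time": (0.5, 3.0)}


def generate_ccd_design(
    bounds: dict[str, tuple[float, float]] | None = None,
    alpha: float = 1.0,
    n_center_rows: int = 6,
) -> pd.DataFrame:
    """Three-factor central composite design schedule.

    Rows are emitted in the deterministic order factorial (2^3, last factor
    varying fastest), axial (2 per factor), center (``n_center_rows``
    replicates). With ``alpha = 1`` the axial points coincide with the face
    centers. Returns a DataFrame with run index, coded levels and natural
    levels.
    """
    if alpha <= 0:
        raise ParameterError("alpha must be positive")
    if n_center_rows < 0:
        raise ParameterError("n_center_rows must be >= 0")
    bounds = dict(DESIGN_BOUNDS if bounds is None else bounds)
    if set(bounds) != set(DESIGN_FACTORS):
        raise ParameterError(f"bounds must cover exactly the factors {DESIGN_FACTORS}")
    center = {f: (lo + hi) / 2.0 for f, (lo, hi) in bounds.items()}
    half = {f: (hi - lo) / 2.0 for f, (lo, hi) in bounds.items()}

    coded_rows: list[tuple[float, float, float]] = []
    coded_rows.extend(itertools.product((-1.0, 1.0), repeat=3))
    for i in range(3):
        for sign in (-1.0, 1.0):
            row = [0.0, 0.0, 0.0]
            row[i] = sign * alpha
            coded_rows.append(tuple(row))
    coded_rows.extend([(0.0, 0.0, 0.0)] * n_center_rows)

    records = []
    for run, coded in enumerate(coded_rows, start=1):
        rec = {"run": run}
        for f, c in zip(DESIGN_FACTORS, coded):
            rec[f"coded_{f}"] = c
            rec[f] = center[f] + c * half[f]
        records.append(rec)
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Attribute sampling
# ---------------------------------------------------------------------------

def _lognormal_mean_sd(mean: float, sd: float, rng: np.random.Generator,
                       size: int, bounds: tuple[float, float]) -> np.ndarray:
    """Truncated log-normal draws parameterised by arithmetic mean/SD."""
    if sd == 0.0:
        return np.full(size, mean)
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.lognormal(mu, math.sqrt(sigma2), size=2 * (size - filled))
        ok = draw[(draw >= bounds[0]) & (draw <= bounds[1])]
        take = min(ok.size, size - filled)
        out[filled:filled + take] = ok[:take]
        filled += take
    return out


def _truncated_normal(mean: float, sd: float, rng: np.random.Generator,
                      size: int, bounds: tuple[float, float]) -> np.ndarray:
    if sd == 0.0:
        return np.full(size, mean)
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=2 * (size - filled))
        ok = draw[(draw >= bounds[0]) & (draw <= bounds[1])]
        take = min(ok.size, size - filled)
        out[filled:filled + take] = ok[:take]
        filled += take
    return out


def _link_terms(cfg: SimConfig, d50: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Linear (z) and quadratic Hermite (z^2-1)/sqrt(2) parts of the
    scatter-coordinate link, both ~unit variance over the mixed population.

    The raw coordinate (1/D50 - u0)/s_u is smoothly saturated with tanh so
    extreme fine-particle batches do not dominate the link variance."""
    z_raw = (1.0 / d50 - cfg.u_center) / cfg.u_scale
    z = 2.0 * np.tanh(z_raw / 2.0)
    return z, (z * z - 1.0) / math.sqrt(2.0)


def sample_attributes(cfg: SimConfig, seed: int | np.random.SeedSequence | None = None) -> AttributeTable:
    """Draw the true (assay-noise-free) attribute table.

    Contents are truncated log-normal per group; moisture truncated normal;
    D50 truncated log-normal within the reported group range; D10/D90 are
    the 10%/90% quantiles of a per-sample piecewise log-normal size
    distribution (independent lower/upper log-widths), so d10 < d50 < d90
    holds by construction. Tapped density and specific surface area follow
    the nonlinear scatter-coordinate link described in the module docstring.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    frames = []
    w = cfg.nonlinearity
    lin_w = math.sqrt(1.0 - w * w)
    for group, n, prefix in (("homemade", cfg.n_homemade, "HM"),
                             ("commercial", cfg.n_commercial, "CM")):
        if n == 0:
            continue
        p = cfg.group_params[group]
        crypto = _lognormal_mean_sd(*p["cryptotanshinone"], rng, n, cfg.chem_bounds)
        iia = _lognormal_mean_sd(*p["tanshinone_iia"], rng, n, cfg.chem_bounds)
        moisture = _truncated_normal(*p["moisture"], rng, n, cfg.moisture_bounds)
        d50 = _lognormal_mean_sd(*p["d50"], rng, n, p["d50_bounds"])
        # Tail log-widths co-vary with the batch log-median (coupling slopes
        # calibrated to the tabulated D10/D90 spreads) plus unencoded jitter.
        dev = np.log(d50) - p["ln_d50_median"]
        sig_lo = np.maximum(0.05, p["sigma_lo"] - p["k_lo"] * dev
                            + cfg.sigma_jitter_lo * rng.standard_normal(n))
        sig_hi = np.maximum(0.05, p["sigma_hi"] - p["k_hi"] * dev
                            + cfg.sigma_jitter_hi * rng.standard_normal(n))
        d10 = d50 * np.exp(-_Z90 * sig_lo)
        d90 = d50 * np.exp(_Z90 * sig_hi)

        # Nonlinear link: Hermite quadratic in the scatter coordinate plus a
        # size-composition interaction, both invisible to any linear
        # functional of the (linearly encoded) spectra.
        z, q = _link_terms(cfg, d50)
        v = (crypto + iia - cfg.comp_center) / cfg.comp_scale
        nl_dt = (q + z * v) / math.sqrt(2.0)
        nl_ssa = (q - z * v) / math.sqrt(2.0)
        dt = (p["tapped_density"]
              + cfg.link_scale_dt * (lin_w * z + w * nl_dt)
              + p["dt_noise_sd"] * rng.standard_normal(n))
        ssa = (p["specific_surface_area"]
               + cfg.link_scale_ssa * (lin_w * z + w * nl_ssa)
               + p["ssa_noise_sd"] * rng.standard_normal(n))
        dt = np.maximum(dt, 0.2)
        ssa = np.maximum(ssa, 0.02)

        frames.append(pd.DataFrame({
            "sample_id": [f"{prefix}{i + 1:02d}" for i in range(n)],
            "cryptotanshinone": crypto,
            "tanshinone_iia": iia,
            "specific_surface_area": ssa,
            "d10": d10,
            "d50": d50,
            "d90": d90,
            "tapped_density": dt,
            "moisture": moisture,
            "group": group,
        }))
    if not frames:
        raise ParameterError("at least one group must have samples")
    return AttributeTable(pd.concat(frames, ignore_index=True))


def add_assay_noise(attrs: AttributeTable, cfg: SimConfig,
                    seed: int | np.random.SeedSequence | None = None) -> AttributeTable:
    """Overlay reference-method measurement error on a true attribute table.

    Contents and moisture get absolute errors; particle sizes, surface
    area and tapped density get relative errors, the particle-size triple
    sharing one scale error per sample so the quantile ordering survives.
    """
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    t = attrs.table.copy()
    n = len(t)
    for col in ("cryptotanshinone", "tanshinone_iia"):
        t[col] = np.maximum(t[col] + cfg.assay_sd_chem * rng.standard_normal(n), 1e-3)
    psd_eps = 1.0 + cfg.assay_cv_psd * rng.standard_normal(n)
    for col in ("d10", "d50", "d90"):
        t[col] = np.maximum(t[col] * psd_eps, 1e-3)
    t["specific_surface_area"] = np.maximum(
        t["specific_surface_area"] * (1.0 + cfg.assay_cv_ssa * rng.standard_normal(n)), 1e-4)
    t["tapped_density"] = np.maximum(
        t["tapped_density"] * (1.0 + cfg.assay_cv_dt * rng.standard_normal(n)), 1e-3)
    t["moisture"] = np.clip(
        t["moisture"] + cfg.assay_sd_moisture * rng.standard_normal(n), 0.05, 99.0)
    return AttributeTable(t)


# ---------------------------------------------------------------------------
# Spectra rendering
# ---------------------------------------------------------------------------

def render_spectra(attrs: AttributeTable, bands: BandModel | None = None,
                   cfg: SimConfig | None = None,
                   seed: int | np.random.SeedSequence | None = None) -> SpectraSet:
    """Render mixture spectra from (true) attributes.

    A(nu) = m(D50) * [sum_k f_k * pure_k(nu)] + baseline(nu) + noise, with
    mass fractions f from the contents (mg/g -> fraction), moisture (% ->
    fraction) and the matrix remainder; m affine in 1/D50; and a random
    low-order polynomial baseline whose constant term grows with D50.
    """
    cfg = cfg or SimConfig()
    bands = bands or default_band_model()
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    wn = default_wavenumber_grid()
    for comp, rows in bands.bands.items():
        for c, _, _ in rows:
            if not (wn.min() <= c <= wn.max()):
                raise ParameterError(f"{comp}: band center {c} outside the wavenumber grid")

    profiles = {comp: bands.profile(comp, wn) for comp in bands.bands}
    f_c = attrs.values("cryptotanshinone") / 1000.0
    f_i = attrs.values("tanshinone_iia") / 1000.0
    f_w = attrs.values("moisture") / 100.0
    f_m = np.maximum(1.0 - f_c - f_i - f_w, 0.0)
    clean = (np.outer(f_c, profiles["cryptotanshinone"])
             + np.outer(f_i, profiles["tanshinone_iia"])
             + np.outer(f_w, profiles["water"])
             + np.outer(f_m, profiles["matrix"]))

    d50 = attrs.values("d50")
    m = 1.0 + cfg.scatter_slope * (1.0 / d50 - cfg.u_center)
    x = (wn - wn.mean()) / (0.5 * (wn.max() - wn.min()))  # scaled to [-1, 1]
    n = attrs.n_samples
    baseline = np.outer(cfg.baseline_d50_coeff * d50, np.ones_like(wn))
    baseline += np.outer(cfg.baseline_d10_coeff * attrs.values("d10"), x)
    for order in range(cfg.baseline_order + 1):
        coef = cfg.baseline_amplitude * rng.standard_normal(n)
        baseline += np.outer(coef, x ** order)
    noise = cfg.noise_sd * rng.standard_normal((n, wn.size))
    absorbance = m[:, None] * clean + baseline + noise
    return SpectraSet(attrs.sample_ids, wn, absorbance,
                      meta={"generator": "nirpowder.simulate.render_spectra"})


def generate_dataset(cfg: SimConfig | None = None, seed: int | None = None) -> Dataset:
    """Compose attribute sampling, spectra rendering and assay noise into a
    fully reproducible Dataset (default: 50 samples x 751 grid points).

    A single seed feeds independent substreams for the three stages, so any
    stage can be regenerated on its own. Spectra are rendered from the
    *true* attributes; the returned attribute table carries the measured
    (assay-noise) values, as a real reference dataset would.
    """
    cfg = cfg or SimConfig()
    root = np.random.SeedSequence(cfg.seed if seed is None else seed)
    ss_attrs, ss_spectra, ss_assay = root.spawn(3)
    true_attrs = sample_attributes(cfg, ss_attrs)
    spectra = render_spectra(true_attrs, None, cfg, ss_spectra)
    measured = add_assay_noise(true_attrs, cfg, ss_assay)
    echo = dataclasses.asdict(cfg)
    spectra.meta["sim_config"] = echo
    spectra.meta["seed"] = int(root.entropy) if seed is None else int(seed)
    return Dataset(spectra, measured)
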