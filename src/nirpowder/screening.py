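"""End-to-end pretreatment x model screening.

For each quality attribute the pipeline runs every registered pretreatment
with both calibration families (PLS with LOO/PRESS latent-variable
selection; LS-SVM with simplex-tuned RBF hyperparameters), evaluates each
cell on a Kennard-Stone calibration/validation split, and assembles the
comparison tables from which a best method per attribute is selected
(maximal RPD, ties broken by minimal RMSEP, then minimal model complexity).

Splitting vs. fitted pretreatments: Kennard-Stone distances are computed on
the pretreated spectra actually fed to the model. Pretreatment is
unsupervised, so for the purpose of *splitting* the data-dependent
pretreatment state (MSC reference) may see all samples; for *modeling*,
state is refit on the calibration rows only and applied unchanged to the
validation rows, keeping validation honest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import ATTRIBUTE_COLUMNS, Dataset
from .errors import NirPowderError, ParameterError
from .lssvm import fit_lssvm, tune_lssvm
from .metrics import evaluate
from .pls import select_lv
from .preprocess import ABBREVIATIONS, get_pretreatment, list_registry
from .simulate import SimConfig, generate_dataset
from .split import kennard_stone

logger = logging.getLogger(__name__)

#: Column order of the per-attribute comparison tables.
TABLE_HEADERS = ["Preprocessing method", "LVs", "r_cal", "RMSEC", "RMSECV",
                 "BIAS_cal", "r_pre", "RMSEP", "RPD", "BIAS_pre"]


@dataclass
class RunConfig:
    """Configuration of one screening run.

    Either ``sim`` (a :class:`~nirpowder.simulate.SimConfig`) or a
    pre-built :class:`~nirpowder.core.Dataset` must be provided.
    """

    sim: SimConfig | None = None
    dataset: Dataset | None = None
    attributes: tuple[str, ...] = ATTRIBUTE_COLUMNS
    pretreatments: tuple[str, ...] = tuple(list_registry())
    models: tuple[str, ...] = ("pls", "lssvm")
    n_cal: int = 40
    max_lv: int = 15
    criterion: str = "rpd"
    seed: int = 0
    fixed_split: bool = False
    lssvm_n_grid: int = 4
    lssvm_n_starts: int = 3
    lssvm_maxiter: int = 200

    def __post_init__(self) -> None:
        unknown = set(self.attributes) - set(ATTRIBUTE_COLUMNS)
        if unknown:
            raise ParameterError(f"unknown attributes: {sorted(unknown)}")
        unknown = set(self.models) - {"pls", "lssvm"}
        if unknown:
            raise ParameterError(f"unknown model families: {sorted(unknown)}")


@dataclass
class ScreeningTable:
    """Screening result: one row per (attribute, pretreatment, model) cell,
    failed cells logged with their error message, plus the per-cell
    LV-selection curves and tuning traces for plotting."""

    frame: pd.DataFrame
    failures: list[dict] = field(default_factory=list)
    curves: dict = field(default_factory=dict)
    traces: dict = field(default_factory=dict)
    config: RunConfig | None = None


def _complexity(row: pd.Series) -> float:
    if row["model"] == "pls":
        return float(row["n_lv"])
    return float("inf")  # kernel models keep every calibration sample


def run_screening(cfg: RunConfig) -> ScreeningTable:
    """Run the full pretreatment x model sweep.

    Deterministic given the config and seed. Cell failures (degenerate
    pretreatment, singular kernel system, ...) are recorded and never abort
    the sweep; a run with zero successful cells raises.
    """
    if cfg.dataset is not None:
        dataset = cfg.dataset
    else:
        dataset = generate_dataset(cfg.sim or SimConfig(), seed=cfg.seed)
    n = dataset.n_samples
    if not (2 <= cfg.n_cal < n):
        raise ParameterError(f"n_cal must be in [2, {n - 1}]")

    rows: list[dict] = []
    failures: list[dict] = []
    curves: dict = {}
    traces: dict = {}
    raw_split = kennard_stone(dataset.spectra.absorbance, cfg.n_cal)

    for pret_name in cfg.pretreatments:
        label = ABBREVIATIONS.get(pret_name, pret_name)
        try:
            # Split on the pretreated spectra (state fit on all samples:
            # unsupervised), then refit state on calibration rows only.
            if cfg.fixed_split:
                split = raw_split
            else:
                all_pre = get_pretreatment(pret_name).fit_transform(dataset.spectra)
                split = kennard_stone(all_pre.absorbance, cfg.n_cal)
            cal_raw = dataset.spectra.subset(split.calibration_indices)
            val_raw = dataset.spectra.subset(split.validation_indices)
            pre = get_pretreatment(pret_name).fit(cal_raw)
            s_cal = pre.transform(cal_raw)
            s_val = pre.transform(val_raw)
        except NirPowderError as exc:
            for attr in cfg.attributes:
                for fam in cfg.models:
                    failures.append({"attribute": attr, "pretreatment": pret_name,
                                     "model": fam, "error": str(exc)})
            logger.warning("pretreatment %s failed: %s", pret_name, exc)
            continue
        X_cal, X_val = s_cal.absorbance, s_val.absorbance
        for attr in cfg.attributes:
            y = dataset.attributes.values(attr)
            y_cal = y[split.calibration_indices]
            y_val = y[split.validation_indices]
            for fam in cfg.models:
                desc = {"attribute": attr, "pretreatment": pret_name,
                        "pretreatment_label": label,
                        "pretreatment_params": json.dumps(pre.params, sort_keys=True),
                        "model": fam,
                        "n_lv": np.nan, "gam": np.nan, "sig2": np.nan}
                try:
                    if fam == "pls":
                        model, curve = select_lv(X_cal, y_cal, cfg.max_lv,
                                                 lineage=s_cal.lineage)
                        desc["n_lv"] = model.n_lv
                        rep = evaluate(model, X_cal, y_cal, X_val, y_val,
                                       rmsecv=float(curve.rmsecv[model.n_lv - 1]),
                                       descriptor=desc)
                        curves[(attr, pret_name)] = curve
                    else:
                        tuned = tune_lssvm(X_cal, y_cal, n_grid=cfg.lssvm_n_grid,
                                           n_starts=cfg.lssvm_n_starts,
                                           maxiter=cfg.lssvm_maxiter)
                        model = fit_lssvm(X_cal, y_cal, tuned.gam, tuned.sig2,
                                          lineage=s_cal.lineage)
                        desc["gam"], desc["sig2"] = tuned.gam, tuned.sig2
                        rep = evaluate(model, X_cal, y_cal, X_val, y_val,
                                       rmsecv=float(np.sqrt(tuned.loo_mse)),
                                       descriptor=desc)
                        traces[(attr, pret_name)] = tuned.trace
                    rows.append(rep.to_row())
                    logger.info("cell %s | %s | %s: RPD=%.3g",
                                attr, pret_name, fam, rep.rpd)
                except NirPowderError as exc:
                    failures.append({**desc, "error": str(exc)})
                    logger.warning("cell %s | %s | %s failed: %s",
                                   attr, pret_name, fam, exc)
    if not rows:
        raise NirPowderError("screening produced zero successful cells")
    frame = pd.DataFrame(rows)
    return ScreeningTable(frame, failures, curves, traces, cfg)


def select_best(table: ScreeningTable | pd.DataFrame, criterion: str = "rpd") -> pd.DataFrame:
    """Best row per attribute: maximal RPD, ties to minimal RMSEP, then to
    minimal model complexity (LV count; kernel models rank last)."""
    frame = table.frame if isinstance(table, ScreeningTable) else table
    if criterion != "rpd":
        raise ParameterError("only the 'rpd' selection criterion is implemented")
    best_rows = []
    for attr, grp in frame.groupby("attribute", sort=False):
        g = grp.copy()
        g["_cplx"] = g.apply(_complexity, axis=1)
        g = g.sort_values(["rpd", "rmsep", "_cplx"],
                          ascending=[False, True, True], kind="stable")
        best_rows.append(g.iloc[0].drop("_cplx"))
    return pd.DataFrame(best_rows).reset_index(drop=True)


def _format_table(frame: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame({
        "Preprocessing method": frame["pretreatment_label"],
        "LVs": frame["n_lv"],
        "r_cal": frame["r_cal"],
        "RMSEC": frame["rmsec"],
        "RMSECV": frame["rmsecv"],
        "BIAS_cal": frame["bias_cal"],
        "r_pre": frame["r_pre"],
        "RMSEP": frame["rmsep"],
        "RPD": frame["rpd"],
        "BIAS_pre": frame["bias_pre"],
    })
    return out


def render_report(table: ScreeningTable, outdir) -> list[Path]:
    """Write the run artifacts: one comparison CSV per (attribute, model
    family), a combined best-methods CSV, LV-selection and tuning-trace
    plots for the best cells, and a JSON run manifest."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    frame = table.frame
    for (attr, fam), grp in frame.groupby(["attribute", "model"], sort=False):
        path = outdir / f"comparison_{attr}_{fam}.csv"
        _format_table(grp).to_csv(path, index=False, float_format="%.6g")
        written.append(path)

    best = select_best(table)
    best_path = outdir / "best_methods.csv"
    cols = ["attribute", "model", "pretreatment_label", "n_lv", "gam", "sig2",
            "r_cal", "rmsec", "rmsecv", "bias_cal", "r_pre", "rmsep", "rpd", "bias_pre"]
    best[[c for c in cols if c in best.columns]].to_csv(
        best_path, index=False, float_format="%.6g")
    written.append(best_path)

    for attr in frame["attribute"].unique():
        pls_best = frame[(frame["attribute"] == attr) & (frame["model"] == "pls")]
        if len(pls_best):
            row = select_best(pls_best.assign(), criterion="rpd").iloc[0]
            curve = table.curves.get((attr, row["pretreatment"]))
            if curve is not None:
                fig, ax = plt.subplots(figsize=(5, 3.5))
                ax.plot(curve.n_lv_candidates, curve.rmsec, "o-", label="RMSEC")
                ax.plot(curve.n_lv_candidates, curve.rmsecv, "s-", label="RMSECV")
                ax.axvline(curve.chosen_n_lv, color="gray", ls="--", lw=0.8)
                ax.set_xlabel("latent variables")
                ax.set_ylabel(f"error ({attr})")
                ax.legend()
                fig.tight_layout()
                p = outdir / f"lv_curve_{attr}.png"
                fig.savefig(p, dpi=120)
                plt.close(fig)
                written.append(p)
        trace_keys = [k for k in table.traces if k[0] == attr]
        if trace_keys:
            tr = np.array(table.traces[trace_keys[0]])
            fig, ax = plt.subplots(figsize=(5, 3.5))
            sc = ax.scatter(tr[:, 0], tr[:, 1], c=np.log10(np.maximum(tr[:, 2], 1e-300)),
                            s=12, cmap="viridis")
            fig.colorbar(sc, ax=ax, label="log10 LOO-MSE")
            ax.set_xlabel("log10 gam")
            ax.set_ylabel("log10 sig2")
            fig.tight_layout()
            p = outdir / f"tuning_trace_{attr}.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            written.append(p)

    manifest = {
        "package": "nirpowder",
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": table.config.seed if table.config else None,
        "config": _config_echo(table.config) if table.config else None,
        "n_rows": int(len(frame)),
        "n_failures": len(table.failures),
        "failures": table.failures,
    }
    man_path = outdir / "manifest.json"
    man_path.write_text(json.dumps(manifest, indent=2, default=str))
    written.append(man_path)
    return written


def _config_echo(cfg: RunConfig) -> dict:
    echo = {f.name: getattr(cfg, f.name) for f in dataclasses.fields(cfg)
            if f.name != "dataset"}
    if echo.get("sim") is not None:
        echo["sim"] = dataclasses.asdict(echo["sim"])
    return echo
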