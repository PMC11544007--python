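"""Voxelwise nonlinear estimation of kinetic parameters and ROI aggregation.

Each voxel's concentration curve is fitted by bounded nonlinear least squares
(`scipy.optimize.least_squares`, trust-region reflective).  The objective is
multimodal for the distributed-parameter model (notably in the F/PS plane),
so fitting is multi-start: the residual sum of squares is evaluated on a
fixed lattice of initial values (3 per parameter, log-spaced for the rate
parameters), the best ``n_refine`` lattice points are refined locally, and
the lowest final RSS wins (ties break toward the earlier lattice point).

ROI medians are taken per parameter over the valid in-mask voxels, with the
derived quantities — the efflux rate kep = Ktrans/ve and the first-pass
extraction E = 1 - exp(-PS/F) — computed per voxel *before* the median, and
are reported in conventional clinical units (volumes and flows x100, E in
percent).
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import math
from typing import Dict, Sequence

import numpy as np
from scipy.optimize import least_squares

from . import kinetic_models as km
from .exceptions import InvalidInputError

logger = logging.getLogger(__name__)

#: multiplicative factors from internal (fraction, 1/min) to reported units
REPORTED_SCALE: Dict[str, float] = {
    "Ktrans": 1.0, "Kep": 1.0, "Ve": 100.0, "Vp": 100.0,
    "F": 100.0, "PS": 100.0, "E": 100.0,
}

TOFTS_PARAM_NAMES = ("ktrans", "ve", "vp")
DP_PARAM_NAMES = ("f", "ps", "vp", "ve")


@dataclasses.dataclass(frozen=True)
class FitConfig:
    """Bounds, lattice and optimizer settings (internal fractional units)."""

    tofts_bounds: tuple = ((0.0, 2.0), (1e-4, 1.0), (0.0, 0.5))
    dp_bounds: tuple = ((1e-3, 4.0), (0.0, 2.0), (1e-4, 0.5), (1e-4, 1.0))
    n_lattice: int = 3
    n_refine: int = 3
    dt_internal: float = km.DEFAULT_INTERNAL_DT
    max_nfev: int = 200
    #: voxels with final RSS above this (mM^2) are excluded from aggregation
    rss_threshold: float = math.inf

    def bounds(self, model: str):
        if model == "tofts":
            return self.tofts_bounds
        if model == "dp":
            return self.dp_bounds
        raise InvalidInputError(f"unknown model {model!r} (expected 'tofts' or 'dp')")


def initial_lattice(model: str, config: FitConfig) -> np.ndarray:
    """The fixed multi-start lattice: ``n_lattice`` values per parameter,
    geometrically spaced across each parameter's bounds.

    Log spacing is used for the volumes too (not only the rates): the
    physiologic volume fractions sit two orders of magnitude below the upper
    bounds, so linear spacing would place no start anywhere near them and
    the screening stage would hand the optimizer only far-off basins.
    """
    axes = []
    for lo, hi in config.bounds(model):
        lo_eff = lo if lo > 0 else hi * 1e-4
        axes.append(np.geomspace(lo_eff, hi, config.n_lattice))
    return np.array(list(itertools.product(*axes)))


@dataclasses.dataclass(frozen=True)
class FitResult:
    """One voxel's fit: parameters, residual sum of squares (mM²),
    evaluation count, convergence flag and the initial point used."""

    params: object
    rss: float
    n_iter: int
    converged: bool
    init_used: np.ndarray


def _evaluator(model: str, aif: km.AIFCurve, config: FitConfig):
    if model == "tofts":
        return km.ToftsEvaluator(aif, config.dt_internal)
    return km.DPEvaluator(aif, config.dt_internal)


def _make_params(model: str, x: np.ndarray):
    x = np.asarray(x, dtype=float)
    if model == "tofts":
        ktrans, ve, vp = x
        if ve + vp > 1.0:  # bounds allow the corner; renormalise the rare violator
            scale = (1.0 - 1e-9) / (ve + vp)
            ve, vp = ve * scale, vp * scale
        return km.ToftsParams(ktrans=float(ktrans), ve=float(ve), vp=float(vp))
    f, ps, vp, ve = x
    if ve + vp > 1.0:
        scale = (1.0 - 1e-9) / (ve + vp)
        ve, vp = ve * scale, vp * scale
    return km.DPParams(f=float(f), ps=float(ps), vp=float(max(vp, 1e-9)), ve=float(ve))


def fit_curve(
    ct: km.TissueCurve,
    aif: km.AIFCurve,
    model: str = "tofts",
    config: FitConfig | None = None,
    evaluator=None,
) -> FitResult:
    """Fit one concentration curve by multi-start bounded least squares.

    ``evaluator`` may be passed to reuse the internal AIF resampling across
    many voxels sharing the same AIF (as :func:`fit_roi` does).
    """
    config = config or FitConfig()
    if ct.grid.n != aif.grid.n or not np.allclose(ct.grid.t, aif.grid.t):
        raise InvalidInputError("tissue curve and AIF must share one time grid")
    if ct.grid.n < 20:
        raise InvalidInputError("need at least 20 samples to fit a kinetic model")
    ev = evaluator if evaluator is not None else _evaluator(model, aif, config)
    y = ct.ct

    def resid(x):
        return ev.ct(*x) - y

    lattice = initial_lattice(model, config)
    rss0 = np.array([float(np.sum(resid(x) ** 2)) for x in lattice])
    order = np.argsort(rss0, kind="stable")[: config.n_refine]
    lo = np.array([b[0] for b in config.bounds(model)])
    hi = np.array([b[1] for b in config.bounds(model)])
    best = None
    best_rss = math.inf
    best_init = lattice[order[0]]
    n_eval = int(lattice.shape[0])
    converged = False
    for k in order:
        try:
            res = least_squares(
                resid, lattice[k], bounds=(lo, hi), method="trf",
                max_nfev=config.max_nfev, xtol=1e-10, ftol=1e-10, gtol=1e-10,
            )
        except Exception as exc:  # pragma: no cover - optimizer robustness
            logger.debug("least_squares failed from start %s: %s", lattice[k], exc)
            continue
        n_eval += int(res.nfev)
        rss = float(2.0 * res.cost)
        if rss < best_rss - 0.0:  # strict improvement; ties keep earlier start
            best, best_rss, best_init = res, rss, lattice[k]
            converged = bool(res.status > 0)
    if best is None:  # every refinement failed: best-effort lattice point
        x = lattice[order[0]]
        return FitResult(_make_params(model, x), float(rss0[order[0]]), n_eval, False, x)
    # the optimizer never does worse than its own start
    if best_rss > float(rss0[order[0]]) + 1e-12:
        x = lattice[order[0]]
        return FitResult(_make_params(model, x), float(rss0[order[0]]), n_eval, False, x)
    return FitResult(_make_params(model, best.x), best_rss, n_eval, converged, best_init)


_MAP_NAMES = {"tofts": ("Ktrans", "Ve", "Vp", "Kep"), "dp": ("F", "PS", "Vp", "Ve", "E")}


@dataclasses.dataclass
class ROIFitOutput:
    """Parameter maps (internal units, NaN outside valid voxels), a validity
    map and exclusion counts for one ROI fit."""

    model: str
    maps: Dict[str, np.ndarray]
    valid: np.ndarray
    n_fitted: int
    n_excluded: int
    results: list


def fit_roi(
    conc_4d: np.ndarray,
    mask: np.ndarray,
    aif: km.AIFCurve,
    model: str = "tofts",
    config: FitConfig | None = None,
    voxel_ok: np.ndarray | None = None,
) -> ROIFitOutput:
    """Fit every in-mask voxel of a 4D concentration volume.

    Voxels that are all-zero/non-finite, flagged bad by ``voxel_ok``
    (e.g. failed SPGR inversion), non-convergent, or above the configured RSS
    threshold are excluded from the validity map and counted.
    """
    config = config or FitConfig()
    conc_4d = np.asarray(conc_4d, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if conc_4d.shape[:-1] != mask.shape:
        raise InvalidInputError("mask shape does not match the dynamic volume")
    if not mask.any():
        raise InvalidInputError("ROI mask selects no voxels")
    ev = _evaluator(model, aif, config)
    names = _MAP_NAMES[model]
    maps = {n: np.full(mask.shape, np.nan) for n in names}
    valid = np.zeros(mask.shape, dtype=bool)
    results = []
    n_excluded = 0
    for idx in map(tuple, np.argwhere(mask)):
        curve = conc_4d[idx]
        if (voxel_ok is not None and not voxel_ok[idx]) or not np.all(np.isfinite(curve)) \
                or float(np.max(np.abs(curve))) == 0.0:
            n_excluded += 1
            results.append(None)
            continue
        fr = fit_curve(km.TissueCurve(aif.grid, curve), aif, model, config, evaluator=ev)
        results.append(fr)
        if not fr.converged or fr.rss > config.rss_threshold:
            n_excluded += 1
            continue
        p = fr.params
        if model == "tofts":
            vals = (p.ktrans, p.ve, p.vp, p.kep)
        else:
            vals = (p.f, p.ps, p.vp, p.ve, p.extraction)
        for name, v in zip(names, vals):
            maps[name][idx] = v
        valid[idx] = True
    n_fitted = int(valid.sum())
    if n_excluded:
        logger.info("ROI fit (%s): %d voxels fitted, %d excluded", model, n_fitted, n_excluded)
    return ROIFitOutput(model=model, maps=maps, valid=valid,
                        n_fitted=n_fitted, n_excluded=n_excluded, results=results)


def aggregate_roi_median(maps: Dict[str, np.ndarray], valid: np.ndarray) -> Dict[str, float]:
    """Median of each parameter map over valid voxels, in reported units
    (volumes/flows x100 mL/100 mL, E in percent, rates in 1/min)."""
    valid = np.asarray(valid, dtype=bool)
    if not valid.any():
        raise InvalidInputError("no valid voxels to aggregate")
    out = {}
    for name, arr in maps.items():
        vals = np.asarray(arr, dtype=float)[valid]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise InvalidInputError(f"no valid voxels for parameter {name}")
        out[name] = float(np.median(vals)) * REPORTED_SCALE.get(name, 1.0)
    return out


#: cohort-table column names, one per model/parameter
COHORT_COLUMNS = {
    "tofts": {"Ktrans": "ExTofts_Ktrans", "Ve": "ExTofts_Ve",
              "Vp": "ExTofts_Vp", "Kep": "ExTofts_Kep"},
    "dp": {"F": "DP_F", "PS": "DP_PS", "Vp": "DP_Vp", "Ve": "DP_Ve", "E": "DP_E"},
}


def fit_patient(
    conc_4d: np.ndarray,
    mask: np.ndarray,
    aif: km.AIFCurve,
    config: FitConfig | None = None,
    models: Sequence[str] = ("tofts", "dp"),
    voxel_ok: np.ndarray | None = None,
) -> Dict[str, float]:
    """Fit the requested models over one patient's ROI and return a cohort
    table row of ROI-median parameters (reported units) plus voxel counts."""
    row: Dict[str, float] = {}
    for model in models:
        out = fit_roi(conc_4d, mask, aif, model, config, voxel_ok=voxel_ok)
        med = aggregate_roi_median(out.maps, out.valid)
        for name, col in COHORT_COLUMNS[model].items():
            row[col] = med[name]
        row[f"n_voxels_used_{model}"] = out.n_fitted
        row[f"n_voxels_excluded_{model}"] = out.n_excluded
    return row
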