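"""Variable-flip-angle T1 mapping and SPGR signal/concentration conversion.

The dynamic series is a spoiled-gradient-echo (SPGR) acquisition:

    S = M0 sin(α) (1 - E1) / (1 - E1 cos(α)),   E1 = exp(-TR/T1),

with TE decay neglected (TE ~ 1 ms).  Pre-contrast T1 and M0 come from a
linearised (DESPOT1-style) fit over the multi-flip-angle scans: plotting
``S/sin α`` against ``S/tan α`` gives a line of slope E1 and intercept
``M0 (1 - E1)``; the fit is exact on noiseless data and orders of magnitude
faster than per-voxel nonlinear fitting, which is adequate at three angles.

Gadolinium shortens T1 through the longitudinal relaxivity ``r1``
(L·mmol⁻¹·s⁻¹): ``1/T1(t) = 1/T10 + r1 C(t)``, so signal inverts to
concentration frame by frame.  B1 inhomogeneity is out of scope; flip angles
are taken as nominal.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .exceptions import InvalidInputError

logger = logging.getLogger(__name__)

DEFAULT_R1 = 3.6      # L mmol^-1 s^-1, configurable (contrast-agent dependent)
DEFAULT_TR_MS = 3.03
DEFAULT_DYN_FLIP_DEG = 9.0
DEFAULT_VFA_FLIPS_DEG = (3.0, 6.0, 9.0)


def spgr_signal(m0, t1_ms, tr_ms, alpha_deg):
    """Steady-state SPGR signal for equilibrium signal ``m0`` and T1 (ms)."""
    a = np.deg2rad(alpha_deg)
    e1 = np.exp(-np.asarray(tr_ms, dtype=float) / np.asarray(t1_ms, dtype=float))
    return np.asarray(m0, dtype=float) * np.sin(a) * (1.0 - e1) / (1.0 - e1 * np.cos(a))


@dataclasses.dataclass(frozen=True)
class VFASet:
    """Pre-contrast signals at several flip angles, one volume per angle.

    ``signals`` has shape ``(n_angles, ...)`` where the trailing axes are the
    voxel grid.
    """

    flip_angles_deg: np.ndarray
    tr_ms: float
    signals: np.ndarray

    def __post_init__(self):
        ang = np.asarray(self.flip_angles_deg, dtype=float)
        sig = np.asarray(self.signals, dtype=float)
        if ang.ndim != 1 or np.unique(ang).size < 2:
            raise InvalidInputError("need at least two distinct flip angles")
        if np.any(ang <= 0) or np.any(ang > 90):
            raise InvalidInputError("flip angles must lie in (0, 90] degrees")
        if sig.shape[0] != ang.size:
            raise InvalidInputError("signals first axis must index the flip angles")
        if np.any(sig < 0):
            raise InvalidInputError("signals must be nonnegative")
        if self.tr_ms <= 0:
            raise InvalidInputError("tr_ms must be positive")
        object.__setattr__(self, "flip_angles_deg", ang)
        object.__setattr__(self, "signals", sig)


@dataclasses.dataclass(frozen=True)
class T1Map:
    """Per-voxel pre-contrast T1 (ms), equilibrium signal and validity flag."""

    t1_ms: np.ndarray
    m0: np.ndarray
    fit_ok: np.ndarray


def fit_t1_vfa(vfa: VFASet) -> T1Map:
    """Linearised VFA (DESPOT1) fit of T1 and M0 per voxel.

    Voxels whose regression slope E1 falls outside (0, 1), with a
    non-positive intercept, or with all-zero signals are flagged
    ``fit_ok = False`` (no exception is raised for them).
    """
    a = np.deg2rad(vfa.flip_angles_deg).reshape((-1,) + (1,) * (vfa.signals.ndim - 1))
    s = vfa.signals
    y = s / np.sin(a)
    x = s / np.tan(a)
    k = s.shape[0]
    sx = x.sum(axis=0)
    sy = y.sum(axis=0)
    sxx = (x * x).sum(axis=0)
    sxy = (x * y).sum(axis=0)
    denom = sxx - sx * sx / k
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(denom > 0, (sxy - sx * sy / k) / denom, np.nan)
        intercept = (sy - slope * sx) / k
        ok = (
            np.isfinite(slope) & (slope > 0) & (slope < 1)
            & np.isfinite(intercept) & (intercept > 0)
            & (s.max(axis=0) > 0)
        )
        t1 = np.where(ok, -vfa.tr_ms / np.log(np.where(ok, slope, 0.5)), np.nan)
        m0 = np.where(ok, intercept / (1.0 - np.where(ok, slope, 0.5)), np.nan)
    return T1Map(t1_ms=t1, m0=m0, fit_ok=ok)


def concentration_to_signal(
    conc_mM: np.ndarray,
    t1map: T1Map,
    r1: float = DEFAULT_R1,
    tr_ms: float = DEFAULT_TR_MS,
    alpha_deg: float = DEFAULT_DYN_FLIP_DEG,
) -> np.ndarray:
    """Forward SPGR signal for a concentration series (trailing time axis)."""
    conc = np.asarray(conc_mM, dtype=float)
    t10 = np.asarray(t1map.t1_ms, dtype=float)[..., None]
    m0 = np.asarray(t1map.m0, dtype=float)[..., None]
    r1_per_ms = r1 / 1000.0  # 1/(mM ms)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1_t = 1.0 / (1.0 / t10 + r1_per_ms * conc)
    return spgr_signal(m0, t1_t, tr_ms, alpha_deg)


def signal_to_concentration(
    dyn_signal: np.ndarray,
    t1map: T1Map,
    r1: float = DEFAULT_R1,
    tr_ms: float = DEFAULT_TR_MS,
    alpha_deg: float = DEFAULT_DYN_FLIP_DEG,
    n_baseline: int = 10,
    max_invalid_fraction: float = 0.1,
):
    """Invert a dynamic SPGR series to concentration (mM).

    The equilibrium signal is re-anchored to the dynamic baseline: the first
    ``n_baseline`` frames define S0, and M0 is rescaled so the SPGR model at
    the VFA-fitted T10 reproduces S0 exactly (this absorbs receive-gain
    differences between the VFA and dynamic scans).  Each frame is then
    inverted for T1(t) and converted via ``C = (1/r1)(1/T1 - 1/T10)``.

    Returns ``(conc, voxel_ok)``.  Concentrations are floored at zero (the
    sub-floor magnitude is logged).  Frames whose signal implies E1 outside
    (0, 1) are invalid: isolated invalid frames are linearly interpolated
    from their neighbours; voxels with more than ``max_invalid_fraction``
    invalid frames (or an invalid T1 fit) get ``voxel_ok = False``.
    """
    if n_baseline < 1:
        raise InvalidInputError("n_baseline must be >= 1")
    s = np.asarray(dyn_signal, dtype=float)
    if s.shape[:-1] != np.shape(t1map.t1_ms):
        raise InvalidInputError("dynamic volume and T1 map voxel grids do not match")
    n_t = s.shape[-1]
    if n_baseline > n_t:
        raise InvalidInputError("n_baseline exceeds the number of frames")
    a = np.deg2rad(alpha_deg)
    t10 = np.asarray(t1map.t1_ms, dtype=float)[..., None]
    s0 = s[..., :n_baseline].mean(axis=-1)[..., None]
    with np.errstate(divide="ignore", invalid="ignore"):
        e10 = np.exp(-tr_ms / t10)
        factor = np.sin(a) * (1.0 - e10) / (1.0 - e10 * np.cos(a))
        m0_eff = s0 / factor
        y = s / (m0_eff * np.sin(a))
        e1 = (1.0 - y) / (1.0 - y * np.cos(a))
        frame_ok = np.isfinite(e1) & (e1 > 0) & (e1 < 1)
        t1_t = np.where(frame_ok, -tr_ms / np.log(np.where(frame_ok, e1, 0.5)), np.nan)
        conc = 1000.0 * (1.0 / t1_t - 1.0 / t10) / r1
    sub_floor = conc[frame_ok & (conc < 0)]
    if sub_floor.size:
        logger.debug(
            "floored %d negative concentrations (largest magnitude %.3g mM)",
            sub_floor.size, float(-sub_floor.min()),
        )
    conc = np.clip(conc, 0.0, None)
    voxel_ok = np.asarray(t1map.fit_ok, dtype=bool) & (
        (~frame_ok).sum(axis=-1) <= max(1, int(max_invalid_fraction * n_t))
    )
    # interpolate invalid frames from valid neighbours where possible
    bad_voxels = np.argwhere(~frame_ok.all(axis=-1) & voxel_ok)
    idx = np.arange(n_t)
    for vox in bad_voxels:
        key = tuple(vox)
        good = frame_ok[key]
        if good.sum() >= 2:
            conc[key][~good] = np.interp(idx[~good], idx[good], conc[key][good])
        else:
            voxel_ok[key] = False
    return conc, voxel_ok
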