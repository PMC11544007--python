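"""Forward tracer-kinetic models for DCE-MRI.

Two models of the tissue response to an arterial input function (AIF) are
implemented:

* the **extended Tofts** model,

  ``ct(t) = vp * cp(t) + Ktrans * (cp ⊗ exp(-kep t))``,  ``kep = Ktrans/ve``;

* the **distributed-parameter (DP)** model of Sangren & Sheppard, in which a
  plug-flow capillary with transit time ``Tc = vp/F`` exchanges tracer with
  the interstitium through a permeability-surface-area product ``PS``.  Its
  residue function is

  ``R(t) = 1``                                    for ``0 <= t < Tc``,
  ``R(t) = 1 - e^{-PS/F} [1 + ∫_0^{t-Tc} e^{-(PS/ve)τ}
            sqrt((PS/ve)(PS/F)/τ) I1(2 sqrt((PS/ve)(PS/F) τ)) dτ]``  otherwise,

  and the tissue curve is ``ct = F * (cp ⊗ R)``.

Units
-----
Internally every volume is a per-mL-tissue *fraction* and every rate is in
``1/min`` (so ``F`` is mL blood / min / mL tissue).  Values reported to
clinicians follow the mL/100 mL and percent conventions, i.e. ``x100``; that
conversion happens only at aggregation/reporting time (see
:mod:`dcekinetics.model_fitting`).

The convolutions are evaluated on a uniform internal grid (default 0.5 s):
the DP residue has a jump discontinuity at ``Tc`` that aliases badly at a 2 s
acquisition spacing, so the residue enters the quadrature through its exact
cell averages (integrals over internal cells), which treats the jump by area
rather than by point sampling.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Mapping

import numpy as np
from scipy import integrate, special

from .exceptions import DegenerateParameterError, InvalidInputError, NumericalError

logger = logging.getLogger(__name__)

#: default internal convolution step, minutes (0.5 s)
DEFAULT_INTERNAL_DT = 0.5 / 60.0


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise InvalidInputError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclasses.dataclass(frozen=True)
class TimeGrid:
    """Strictly increasing sample times in minutes, ``t[0] >= 0``."""

    t: np.ndarray

    def __post_init__(self):
        t = _as_float_array(self.t, "t")
        if t.size < 2:
            raise InvalidInputError("time grid needs at least two samples")
        if t[0] < 0:
            raise InvalidInputError("time grid must start at t >= 0")
        if not np.all(np.diff(t) > 0):
            raise InvalidInputError("time grid must be strictly increasing")
        object.__setattr__(self, "t", t)

    @property
    def n(self) -> int:
        return self.t.size

    @property
    def span(self) -> float:
        return float(self.t[-1] - self.t[0])

    @classmethod
    def uniform(cls, n_frames: int, dt_s: float, t0_min: float = 0.0) -> "TimeGrid":
        """Uniform grid of ``n_frames`` samples spaced ``dt_s`` seconds apart."""
        return cls(t0_min + np.arange(n_frames) * dt_s / 60.0)


@dataclasses.dataclass(frozen=True)
class AIFCurve:
    """Plasma contrast-agent concentration (mM) on a time grid."""

    grid: TimeGrid
    cp: np.ndarray

    def __post_init__(self):
        cp = _as_float_array(self.cp, "cp")
        if cp.size != self.grid.n:
            raise InvalidInputError("cp length does not match the time grid")
        if not np.all(np.isfinite(cp)):
            raise InvalidInputError("cp must be finite everywhere")
        if np.any(cp < -1e-12):
            raise InvalidInputError("cp must be nonnegative")
        object.__setattr__(self, "cp", np.clip(cp, 0.0, None))

    def scaled(self, factor: float) -> "AIFCurve":
        return AIFCurve(self.grid, self.cp * float(factor))


@dataclasses.dataclass(frozen=True)
class TissueCurve:
    """Tissue contrast-agent concentration (mM) on a time grid."""

    grid: TimeGrid
    ct: np.ndarray

    def __post_init__(self):
        ct = _as_float_array(self.ct, "ct")
        if ct.size != self.grid.n:
            raise InvalidInputError("ct length does not match the time grid")
        if not np.all(np.isfinite(ct)):
            raise InvalidInputError("ct must be finite everywhere")
        object.__setattr__(self, "ct", ct)


@dataclasses.dataclass(frozen=True)
class ToftsParams:
    """Extended-Tofts parameters in internal units (fractions, 1/min)."""

    ktrans: float
    ve: float
    vp: float

    def __post_init__(self):
        if not (self.ktrans >= 0 and np.isfinite(self.ktrans)):
            raise InvalidInputError("ktrans must be a finite nonnegative rate")
        if not (0.0 <= self.ve <= 1.0):
            raise InvalidInputError("ve must be a fraction in [0, 1]")
        if not (0.0 <= self.vp <= 1.0):
            raise InvalidInputError("vp must be a fraction in [0, 1]")
        if self.ve + self.vp > 1.0 + 1e-9:
            raise InvalidInputError("ve + vp must not exceed 1")

    @property
    def kep(self) -> float:
        """Efflux rate constant ktrans/ve (1/min)."""
        return kep_from(self.ktrans, self.ve)


@dataclasses.dataclass(frozen=True)
class DPParams:
    """Distributed-parameter model parameters in internal units.

    ``f``: blood flow (mL/min per mL tissue), ``ps``: permeability-surface
    product (mL/min per mL tissue), ``vp``/``ve``: fractional volumes.
    """

    f: float
    ps: float
    vp: float
    ve: float

    def __post_init__(self):
        if not (self.f >= 0 and np.isfinite(self.f)):
            raise InvalidInputError("f must be a finite nonnegative rate")
        if not (self.ps >= 0 and np.isfinite(self.ps)):
            raise InvalidInputError("ps must be a finite nonnegative rate")
        if not (0.0 < self.vp <= 1.0):
            raise InvalidInputError("vp must be a fraction in (0, 1]")
        if not (0.0 <= self.ve <= 1.0):
            raise InvalidInputError("ve must be a fraction in [0, 1]")
        if self.ve + self.vp > 1.0 + 1e-9:
            raise InvalidInputError("ve + vp must not exceed 1")

    @property
    def tc(self) -> float:
        """Capillary transit time vp/f (min)."""
        if self.f <= 0:
            raise DegenerateParameterError("transit time undefined for f <= 0")
        return self.vp / self.f

    @property
    def extraction(self) -> float:
        """First-pass extraction fraction 1 - exp(-PS/F), dimensionless."""
        if self.f <= 0:
            raise DegenerateParameterError("extraction undefined for f <= 0")
        return float(-np.expm1(-self.ps / self.f))


# ---------------------------------------------------------------------------
# derived scalar quantities
# ---------------------------------------------------------------------------

def kep_from(ktrans: float, ve: float) -> float:
    """Efflux rate constant ``kep = ktrans/ve`` in 1/min.

    ``ktrans = 0`` gives 0 without forming the ratio; ``ve <= 0`` with a
    positive ``ktrans`` is degenerate.
    """
    if ktrans == 0:
        return 0.0
    if ve <= 0:
        raise DegenerateParameterError("kep undefined: ve <= 0 with ktrans > 0")
    return float(ktrans) / float(ve)


def extraction_fraction(f: float, ps: float) -> float:
    """First-pass extraction ratio ``E = 100 (1 - exp(-PS/F))`` in percent.

    ``f`` and ``ps`` may be given in any consistent flow units (only their
    ratio matters), e.g. both in mL/min/100 mL.
    """
    if f <= 0:
        raise DegenerateParameterError("extraction undefined for f <= 0")
    if ps < 0:
        raise InvalidInputError("ps must be nonnegative")
    return float(-100.0 * np.expm1(-ps / f))


# ---------------------------------------------------------------------------
# population AIF
# ---------------------------------------------------------------------------

#: Parker-form population AIF coefficients (two Gaussians plus a
#: sigmoid-modulated exponential tail), plasma concentration in mM, time in
#: minutes from bolus arrival.
PARKER_AIF: Mapping[str, float] = {
    "a1": 0.809, "a2": 0.330,          # mmol min
    "t1": 0.17046, "t2": 0.365,        # min
    "sigma1": 0.0563, "sigma2": 0.132,  # min
    "alpha": 1.050,                    # mmol
    "beta": 0.1685,                    # 1/min
    "s": 38.078,                       # 1/min
    "tau": 0.483,                      # min
}


def parker_aif_values(t_min: np.ndarray, params: Mapping[str, float] | None = None) -> np.ndarray:
    """Evaluate the Parker population AIF at times ``t_min`` (minutes from
    bolus arrival); zero for negative times."""
    p = dict(PARKER_AIF)
    if params:
        p.update(params)
    t = np.asarray(t_min, dtype=float)
    cp = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    for a, mu, sig in ((p["a1"], p["t1"], p["sigma1"]), (p["a2"], p["t2"], p["sigma2"])):
        cp[pos] += a / (sig * math.sqrt(2 * math.pi)) * np.exp(-((tp - mu) ** 2) / (2 * sig**2))
    cp[pos] += p["alpha"] * np.exp(-p["beta"] * tp) / (1 + np.exp(-p["s"] * (tp - p["tau"])))
    return cp


def population_aif(
    grid: TimeGrid,
    bolus_arrival: float = 0.5,
    dose_scale: float = 1.0,
    params: Mapping[str, float] | None = None,
) -> AIFCurve:
    """Parker-form population AIF on ``grid``, zero before ``bolus_arrival``.

    ``dose_scale`` linearly rescales the whole curve (1.0 = the standard
    0.1 mmol/kg bolus the coefficients were calibrated for).
    """
    if not (grid.t[0] <= bolus_arrival <= grid.t[-1]):
        raise InvalidInputError("bolus_arrival must lie within the grid span")
    cp = dose_scale * parker_aif_values(grid.t - bolus_arrival, params)
    return AIFCurve(grid, cp)


def load_aif_csv(path, hematocrit: float | None = None) -> AIFCurve:
    """Read a measured AIF from a two-column CSV ``time_s, concentration_mM``
    (header required).

    If ``hematocrit`` is given the curve is treated as whole-blood
    concentration and converted to plasma via ``cp = cb / (1 - Hct)``.
    """
    data = np.genfromtxt(path, delimiter=",", names=True)
    if data.dtype.names is None or len(data.dtype.names) < 2:
        raise InvalidInputError(f"AIF file {path} must have a two-column header")
    t_s = np.asarray(data[data.dtype.names[0]], dtype=float)
    cp = np.asarray(data[data.dtype.names[1]], dtype=float)
    if hematocrit is not None:
        if not (0.0 <= hematocrit < 1.0):
            raise InvalidInputError("hematocrit must be in [0, 1)")
        cp = cp / (1.0 - hematocrit)
    return AIFCurve(TimeGrid(t_s / 60.0), cp)


# ---------------------------------------------------------------------------
# internal uniform-grid machinery
# ---------------------------------------------------------------------------

def _internal_times(grid: TimeGrid, dt_max: float):
    """Uniform internal grid covering ``grid`` exactly (last point = t[-1])."""
    n = max(2, int(math.ceil(grid.span / dt_max)))
    dt = grid.span / n
    return grid.t[0] + dt * np.arange(n + 1), dt


class ToftsEvaluator:
    """Repeated extended-Tofts forward evaluations against one AIF.

    Resamples the AIF once onto a uniform internal grid; each :meth:`ct`
    call is then a single discrete trapezoid convolution.
    """

    def __init__(self, aif: AIFCurve, dt_internal: float = DEFAULT_INTERNAL_DT):
        self.aif = aif
        self.tu, self.dt = _internal_times(aif.grid, dt_internal)
        self.cp_u = np.interp(self.tu, aif.grid.t, aif.cp)
        self.t_rel = self.tu - self.tu[0]

    def ct(self, ktrans: float, ve: float, vp: float) -> np.ndarray:
        """Tissue curve (mM) sampled on the AIF acquisition grid."""
        if ktrans == 0:
            return vp * self.aif.cp
        if ve <= 0:
            raise DegenerateParameterError("ve = 0 with ktrans > 0 has no finite kep")
        kep = ktrans / ve
        kern = ktrans * np.exp(-kep * self.t_rel)
        conv = np.convolve(self.cp_u, kern)[: self.cp_u.size] * self.dt
        conv -= 0.5 * self.dt * (self.cp_u[0] * kern + self.cp_u * kern[0])
        leak = np.interp(self.aif.grid.t, self.tu, conv)
        return vp * self.aif.cp + leak


def tofts_forward(p: ToftsParams, aif: AIFCurve, dt_internal: float = DEFAULT_INTERNAL_DT) -> TissueCurve:
    """Extended-Tofts tissue curve ``ct = vp cp + ktrans cp ⊗ e^{-kep t}``."""
    return TissueCurve(aif.grid, ToftsEvaluator(aif, dt_internal).ct(p.ktrans, p.ve, p.vp))


# ---------------------------------------------------------------------------
# distributed-parameter model
# ---------------------------------------------------------------------------

def _exchange_integrand_u(u: np.ndarray, ke: float, kf: float) -> np.ndarray:
    """``e^{-kf}`` times the DP back-flux integrand after the substitution
    τ = u².

    The substitution removes the integrable 1/sqrt(τ) endpoint singularity,
    and pre-multiplying by the ``e^{-PS/F}`` factor of the residue makes the
    evaluation unconditionally stable: with ``b = 2 sqrt(ke kf)`` and the
    exponentially scaled Bessel function ``i1e`` the integrand is
    ``b e^{-(sqrt(ke) u - sqrt(kf))²} i1e(b u)``, whose exponent is never
    positive (no overflow however large PS/F gets).
    """
    u = np.asarray(u, dtype=float)
    z = 2.0 * math.sqrt(ke * kf) * u
    expo = -np.square(math.sqrt(ke) * u - math.sqrt(kf))
    return 2.0 * math.sqrt(ke * kf) * np.exp(expo) * special.i1e(z)


def _check_dp(f: float, ps: float, vp: float, ve: float) -> None:
    if f <= 0 or vp <= 0:
        raise DegenerateParameterError("DP model requires f > 0 and vp > 0")
    if ps < 0:
        raise InvalidInputError("ps must be nonnegative")
    if ps > 0 and ve <= 0:
        raise DegenerateParameterError("ps > 0 with ve = 0 has no finite exchange rate")


def dp_impulse_response(p: DPParams, t, *, tol: float = 1e-8):
    """DP residue function R(t) (dimensionless) by adaptive quadrature.

    Piecewise: a plateau of 1 on ``[0, Tc)``, a drop to the extraction
    fraction ``E = 1 - e^{-PS/F}`` at ``Tc``, then monotone decay to 0 as the
    extracted tracer washes back out of the interstitium.

    Accepts a scalar or an array of times; the inner integral uses
    ``scipy.integrate.quad`` on the substituted (singularity-free) integrand
    with absolute and relative tolerance ``tol``.
    """
    _check_dp(p.f, p.ps, p.vp, p.ve)
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise InvalidInputError("t must be nonnegative")
    tc = p.tc
    out = np.ones_like(t_arr)
    late = t_arr >= tc
    if p.ps == 0:
        out[late] = 0.0
    else:
        ke = p.ps / p.ve
        kf = p.ps / p.f
        e_neg = math.exp(-kf)
        for idx in np.flatnonzero(late):
            tau = t_arr[idx] - tc
            if tau == 0.0:
                out[idx] = -math.expm1(-kf)
                continue
            j, err = integrate.quad(
                _exchange_integrand_u, 0.0, math.sqrt(tau), args=(ke, kf),
                epsabs=tol, epsrel=tol, limit=200,
            )
            if err > 1e4 * tol * (1.0 + abs(j)):
                raise NumericalError(
                    f"DP residue quadrature did not converge at t={t_arr[idx]:g} "
                    f"(ke={ke:g}, kf={kf:g}, estimated error {err:g})"
                )
            r = 1.0 - e_neg - j  # integrand already carries the e^{-kf} factor
            if r < -1e-6:
                raise NumericalError(f"DP residue evaluated to {r:g} < 0 at t={t_arr[idx]:g}")
            out[idx] = max(r, 0.0)
    return out if np.ndim(t) else float(out[0])


class DPEvaluator:
    """Repeated distributed-parameter forward evaluations against one AIF.

    The residue enters the convolution through its exact average over each
    internal cell (computed from the analytic running integral of R), so the
    plateau-edge discontinuity at Tc contributes by area rather than by point
    sampling; the scheme is second-order in the internal step for the smooth
    parts of the curve.
    """

    def __init__(self, aif: AIFCurve, dt_internal: float = DEFAULT_INTERNAL_DT,
                 n_u: int = 512, refine: int = 4):
        self.aif = aif
        self.tu, self.dt = _internal_times(aif.grid, dt_internal)
        self.cp_u = np.interp(self.tu, aif.grid.t, aif.cp)
        self.cpm = 0.5 * (self.cp_u[:-1] + self.cp_u[1:])  # midpoint samples
        self.n_cells = self.tu.size - 1
        self.edges = self.dt * np.arange(self.n_cells + 1)
        self.n_u = n_u
        self.refine = refine
        self.tc_clamped = 0  # diagnostic counter

    def residue_cell_averages(self, f: float, ps: float, vp: float, ve: float) -> np.ndarray:
        """Average of R over each internal cell ``[k dt, (k+1) dt]``."""
        _check_dp(f, ps, vp, ve)
        tc = vp / f
        if tc < self.dt:
            # degenerate plug-flow phase shorter than one internal step
            self.tc_clamped += 1
            logger.debug("Tc = %.3g min below internal step %.3g min; clamped", tc, self.dt)
            tc = self.dt
        plateau = np.minimum(self.edges, tc)
        if ps == 0 or tc >= self.edges[-1]:
            cum = plateau
        else:
            ke, kf = ps / ve, ps / f
            t_max = self.edges[-1] - tc
            u_max = math.sqrt(t_max)
            # refine the u-grid when the integrand is sharply peaked (large ke)
            n_u = min(8192, max(self.n_u, int(8 * u_max * math.sqrt(ke))))
            u = np.linspace(0.0, u_max, n_u)
            j_cum = integrate.cumulative_trapezoid(_exchange_integrand_u(u, ke, kf), u, initial=0.0)
            tau_f = np.linspace(0.0, t_max, self.refine * self.n_cells + 1)
            j_f = np.interp(np.sqrt(tau_f), u, j_cum)
            k_f = integrate.cumulative_trapezoid(j_f, tau_f, initial=0.0)
            tk = np.clip(self.edges - tc, 0.0, None)
            # k_f is the running integral of e^{-kf} J, so no extra factor here
            q = tk * (1.0 - math.exp(-kf)) - np.interp(tk, tau_f, k_f)
            cum = plateau + q
        return np.clip(np.diff(cum) / self.dt, 0.0, 1.0)

    def ct(self, f: float, ps: float, vp: float, ve: float) -> np.ndarray:
        """Tissue curve ``f (cp ⊗ R)`` (mM) on the AIF acquisition grid."""
        rbar = self.residue_cell_averages(f, ps, vp, ve)
        conv = np.convolve(self.cpm, rbar)[: self.n_cells]
        ct_u = np.empty(self.n_cells + 1)
        ct_u[0] = 0.0
        ct_u[1:] = f * self.dt * conv
        return np.interp(self.aif.grid.t, self.tu, ct_u)


def dp_forward(p: DPParams, aif: AIFCurve, dt_internal: float = DEFAULT_INTERNAL_DT) -> TissueCurve:
    """Distributed-parameter tissue curve ``ct = F (cp ⊗ R)``."""
    ev = DPEvaluator(aif, dt_internal)
    ct = ev.ct(p.f, p.ps, p.vp, p.ve)
    if ev.tc_clamped:
        logger.warning(
            "capillary transit time vp/f = %.3g min below the internal step "
            "%.3g min; clamped to one step (quasi plug-flow)", p.vp / p.f, ev.dt,
        )
    return TissueCurve(aif.grid, ct)
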