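"""Synthetic glioma DCE-MRI cohort with known kinetic ground truth.

No patient-level imaging is publicly deposited for the kind of study this
pipeline targets, so every stage is exercised against a fully synthetic
cohort whose *statistical* structure matches the clinical setting:

* three molecular subtypes — IDH wild-type glioblastoma, IDH-mutant
  1p/19q-intact astrocytoma, IDH-mutant 1p/19q-codeleted oligodendroglioma —
  with default sizes 24/9/15 (a 48-patient cohort);
* per-group log-normal distributions of the distributed-parameter ground
  truth (F, PS, Vp, Ve) calibrated to published per-group median/IQR values;
  a Gaussian copula ties the Vp and F ranks (Spearman 0.56 by default);
* extended-Tofts truth derived from the same physiology
  (``Ktrans = E * F``, shared ``ve``/``vp``), so both models describe one
  tissue, as in a real analysis;
* a Ki-67 proliferation index rank-linked to the true interstitial fraction
  Ve through a Gaussian copula (Spearman 0.62 by default);
* within-tumor heterogeneity as multiplicative log-normal voxel jitter
  (sigma 0.15) around each patient's value — enough to make ROI medians
  meaningful without modelling spatial texture;
* rendering of each patient to a miniature acquisition: multi-flip-angle
  pre-contrast volumes, a 4D dynamic SPGR series (tissue curves via the DP
  forward model, signals via the SPGR equation), an ROI mask and the AIF,
  with Rician noise on signal or Gaussian noise on concentration.

Everything is reproducible from ``(config, seed)``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from pathlib import Path
from typing import Dict, Mapping

import numpy as np
import pandas as pd
from scipy import stats as st

from . import kinetic_models as km
from . import relaxometry as rx
from .exceptions import InvalidInputError

Z75 = float(st.norm.ppf(0.75))  # 0.674489...

#: per-group (median, q25, q75) of the distributed-parameter ground truth in
#: reported units (F, PS in mL/min/100 mL; Vp, Ve in mL/100 mL), emulating a
#: 48-patient glioma cohort with three molecular subtypes
GROUP_CALIBRATION: Mapping[str, Mapping[str, tuple]] = {
    "wildtype": {
        "F": (7.454, 6.308, 13.777), "PS": (2.445, 1.769, 3.527),
        "Vp": (0.897, 0.600, 1.508), "Ve": (6.739, 3.558, 11.505),
    },
    "intact": {
        "F": (6.607, 5.196, 6.997), "PS": (1.437, 0.281, 2.257),
        "Vp": (0.380, 0.149, 0.542), "Ve": (0.276, 0.182, 4.969),
    },
    "codeleted": {
        "F": (8.963, 8.320, 12.418), "PS": (0.872, 0.457, 1.245),
        "Vp": (0.283, 0.215, 0.679), "Ve": (0.415, 0.247, 3.201),
    },
}

GROUP_LABELS = {
    "wildtype": ("wild-type", "not-applicable"),
    "intact": ("mutation", "intact"),
    "codeleted": ("mutation", "codeleted"),
}

_PARAM_ORDER = ("F", "PS", "Vp", "Ve")


@dataclasses.dataclass(frozen=True)
class LognormalSpec:
    """Log-normal distribution parameterised by (mu, sigma) of log-values."""

    mu: float
    sigma: float

    @property
    def median(self) -> float:
        return math.exp(self.mu)

    @property
    def q25(self) -> float:
        return math.exp(self.mu - Z75 * self.sigma)

    @property
    def q75(self) -> float:
        return math.exp(self.mu + Z75 * self.sigma)

    def ppf(self, q):
        return np.exp(self.mu + self.sigma * st.norm.ppf(q))


def lognormal_from_median_iqr(median: float, q25: float, q75: float) -> LognormalSpec:
    """Log-normal spec matching a printed ``median (q25, q75)`` summary.

    ``mu = ln median`` reproduces the median exactly; ``sigma`` is chosen so
    the quartile *ratio* q75/q25 is reproduced exactly.  (A two-parameter
    log-normal cannot additionally honour an asymmetric quartile pair, i.e.
    one with ``q25 q75 != median²``.)
    """
    if not (0 < q25 < median < q75):
        raise InvalidInputError("need 0 < q25 < median < q75")
    return LognormalSpec(mu=math.log(median), sigma=math.log(q75 / q25) / (2 * Z75))


def spearman_to_pearson(rho_s: float) -> float:
    """Gaussian-copula Pearson correlation giving Spearman ``rho_s``."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


@dataclasses.dataclass(frozen=True)
class CohortConfig:
    """Study-design knobs of the synthetic cohort.

    Defaults are the emulated study's conditions: 24/9/15 patients per
    subtype, acquisition of 10 baseline + 180 dynamic frames at 2 s with
    flip angles 3/6/9 degrees and TR 3.03 ms, SNR 20, and the copula
    rank-correlation targets 0.56 (Vp-F) and 0.62 (Ki-67-Ve).
    """

    n_wildtype: int = 24
    n_intact: int = 9
    n_codeleted: int = 15
    calibration: Mapping = dataclasses.field(
        default_factory=lambda: GROUP_CALIBRATION)
    vp_f_rank_corr: float = 0.56
    ki67_rank_corr: float = 0.62
    ki67_median: float = 15.0
    ki67_sigma: float = 0.8
    voxel_jitter_sigma: float = 0.15
    snr: float = 20.0
    noise: str = "rician"  # 'rician' (on signal), 'gaussian_conc', or 'none'
    n_dynamic: int = 180
    n_baseline: int = 10
    dt_s: float = 2.0
    flip_angles_deg: tuple = rx.DEFAULT_VFA_FLIPS_DEG
    dyn_flip_deg: float = rx.DEFAULT_DYN_FLIP_DEG
    tr_ms: float = rx.DEFAULT_TR_MS
    r1: float = rx.DEFAULT_R1
    roi_shape: tuple = (6, 6, 3)
    margin: int = 2
    t10_tumor_ms: float = 1400.0
    t10_background_ms: float = 1000.0
    m0: float = 1000.0

    def __post_init__(self):
        if min(self.n_wildtype, self.n_intact, self.n_codeleted) < 1:
            raise InvalidInputError("every group needs at least one patient")
        if self.snr <= 0:
            raise InvalidInputError("snr must be positive")
        if self.noise not in ("rician", "gaussian_conc", "none"):
            raise InvalidInputError("noise must be 'rician', 'gaussian_conc' or 'none'")
        for group, spec in self.calibration.items():
            for name, (med, q25, q75) in spec.items():
                if not (0 < q25 <= med <= q75):
                    raise InvalidInputError(
                        f"calibration median outside IQR for {group}/{name}")

    @property
    def grid(self) -> km.TimeGrid:
        return km.TimeGrid.uniform(self.n_baseline + self.n_dynamic, self.dt_s)

    @property
    def bolus_arrival_min(self) -> float:
        return self.n_baseline * self.dt_s / 60.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["calibration"] = {g: {k: list(v) for k, v in s.items()}
                            for g, s in self.calibration.items()}
        return d


def config_from_dict(d: Mapping) -> CohortConfig:
    """Build a :class:`CohortConfig` from a parsed YAML/JSON mapping,
    rejecting unknown keys."""
    known = {f.name for f in dataclasses.fields(CohortConfig)}
    unknown = set(d) - known
    if unknown:
        raise InvalidInputError(f"unknown config keys: {sorted(unknown)}")
    d = dict(d)
    for key in ("flip_angles_deg", "roi_shape"):
        if key in d:
            d[key] = tuple(d[key])
    if "calibration" in d:
        d["calibration"] = {g: {k: tuple(v) for k, v in s.items()}
                            for g, s in d["calibration"].items()}
    return CohortConfig(**d)


def config_hash(config: CohortConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth of one sampled cohort.

    ``patients``: per-patient labels, patient-level kinetic parameters
    (internal fractional units, ``*_frac`` columns) and Ki-67.
    ``cohort_table``: the 9 reported-unit ROI-median parameter columns plus
    labels/Ki-67 — the exact table the statistics stage consumes.
    ``voxel_params``: per patient, an ``(n_voxels, 4)`` array of true DP
    parameters (F, PS, Vp, Ve; internal fractions).
    """

    config: CohortConfig
    seed: int
    patients: pd.DataFrame
    cohort_table: pd.DataFrame
    voxel_params: Dict[str, np.ndarray]


def _derived_reported(f, ps, vp, ve):
    """Reported-unit parameter dict from internal-unit DP arrays, with the
    derived extended-Tofts quantities computed elementwise."""
    e = -np.expm1(-ps / f)
    ktrans = e * f
    kep = np.where(ktrans > 0, ktrans / ve, 0.0)
    return {
        "ExTofts_Ktrans": ktrans, "ExTofts_Ve": 100 * ve, "ExTofts_Vp": 100 * vp,
        "ExTofts_Kep": kep, "DP_F": 100 * f, "DP_Vp": 100 * vp, "DP_Ve": 100 * ve,
        "DP_PS": 100 * ps, "DP_E": 100 * e,
    }


def sample_cohort(config: CohortConfig, seed: int) -> SyntheticTruth:
    """Draw a full cohort: patient-level DP truth per group (correlated via a
    Gaussian copula), voxel-level jitter, derived Tofts truth, true ROI
    medians and Ki-67."""
    rng = np.random.default_rng(seed)
    r = spearman_to_pearson(config.vp_f_rank_corr)
    corr = np.eye(4)
    i_f, i_vp = _PARAM_ORDER.index("F"), _PARAM_ORDER.index("Vp")
    corr[i_f, i_vp] = corr[i_vp, i_f] = r
    chol = np.linalg.cholesky(corr)
    n_vox = int(np.prod(config.roi_shape))
    rows = []
    voxel_params: Dict[str, np.ndarray] = {}
    table_rows = []
    pid_counter = 0
    for group, n in (("wildtype", config.n_wildtype), ("intact", config.n_intact),
                     ("codeleted", config.n_codeleted)):
        specs = {name: lognormal_from_median_iqr(*config.calibration[group][name])
                 for name in _PARAM_ORDER}
        z = rng.standard_normal((n, 4)) @ chol.T
        frac = np.empty((n, 4))
        for j, name in enumerate(_PARAM_ORDER):
            frac[:, j] = np.exp(specs[name].mu + specs[name].sigma * z[:, j]) / 100.0
        # numerical sanity floors/caps on the fractional scale
        frac[:, 2] = np.clip(frac[:, 2], 1e-5, 0.5)          # vp
        frac[:, 3] = np.clip(frac[:, 3], 1e-5, None)          # ve
        over = frac[:, 2] + frac[:, 3] > 1.0
        frac[over, 3] = 1.0 - frac[over, 2]
        idh, codel = GROUP_LABELS[group]
        for i in range(n):
            pid_counter += 1
            pid = f"P{pid_counter:03d}"
            f, ps, vp, ve = frac[i]
            jitter = np.exp(config.voxel_jitter_sigma * rng.standard_normal((n_vox, 4)))
            vox = frac[i] * jitter
            vox[:, 2] = np.clip(vox[:, 2], 1e-5, 0.5)
            vox[:, 3] = np.clip(vox[:, 3], 1e-5, None)
            over = vox[:, 2] + vox[:, 3] > 1.0
            vox[over, 3] = 1.0 - vox[over, 2]
            voxel_params[pid] = vox
            med = {k: float(np.median(v)) for k, v in
                   _derived_reported(vox[:, 0], vox[:, 1], vox[:, 2], vox[:, 3]).items()}
            rows.append({
                "patient_id": pid, "group": group, "idh": idh, "codeletion": codel,
                "f_frac": f, "ps_frac": ps, "vp_frac": vp, "ve_frac": ve,
            })
            table_rows.append({"patient_id": pid, "group": group,
                               "idh": idh, "codeletion": codel, **med})
    patients = pd.DataFrame(rows)
    table = pd.DataFrame(table_rows)
    ki67 = sample_ki67(table["DP_Ve"].to_numpy(), config.ki67_rank_corr,
                       rng, median=config.ki67_median, sigma=config.ki67_sigma)
    patients["ki67"] = ki67
    table["ki67"] = ki67
    return SyntheticTruth(config=config, seed=seed, patients=patients,
                          cohort_table=table, voxel_params=voxel_params)


def sample_ki67(
    ve_values: np.ndarray,
    target_rho: float,
    rng_or_seed,
    median: float = 15.0,
    sigma: float = 0.8,
    lo: float = 1.0,
    hi: float = 90.0,
) -> np.ndarray:
    """Ki-67 labelling index (percent) rank-linked to the true interstitial
    fraction through a Gaussian copula with Spearman ``target_rho``.

    The marginal is log-normal (median 15%, log-sd 0.8 by default) clipped
    to [1, 90] percent.
    """
    rng = rng_or_seed if isinstance(rng_or_seed, np.random.Generator) \
        else np.random.default_rng(rng_or_seed)
    ve = np.asarray(ve_values, dtype=float)
    n = ve.size
    if not (-1.0 <= target_rho <= 1.0):
        raise InvalidInputError("target_rho must lie in [-1, 1]")
    r = spearman_to_pearson(target_rho)
    z_ve = st.norm.ppf((st.rankdata(ve) - 0.5) / n)
    z = r * z_ve + math.sqrt(max(0.0, 1.0 - r * r)) * rng.standard_normal(n)
    return np.clip(np.exp(math.log(median) + sigma * z), lo, hi)


# ---------------------------------------------------------------------------
# patient rendering
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RenderedPatient:
    """One patient's rendered acquisition (arrays, identity affine)."""

    patient_id: str
    grid: km.TimeGrid
    aif: km.AIFCurve
    vfa_signals: np.ndarray   # (n_angles,) + vol_shape
    dyn_signal: np.ndarray    # vol_shape + (n_frames,)
    mask: np.ndarray          # vol_shape, bool
    t10_ms: np.ndarray        # vol_shape
    conc_truth: np.ndarray    # vol_shape + (n_frames,), noiseless


def render_patient(truth: SyntheticTruth, patient_id: str, seed: int) -> RenderedPatient:
    """Render one patient: DP tissue curves for every ROI voxel, SPGR signal
    synthesis, and acquisition noise per the config."""
    config = truth.config
    if patient_id not in truth.voxel_params:
        raise InvalidInputError(f"unknown patient {patient_id!r}")
    rng = np.random.default_rng(seed)
    grid = config.grid
    aif = km.population_aif(grid, bolus_arrival=config.bolus_arrival_min)
    rs = config.roi_shape
    m = config.margin
    vol_shape = (rs[0] + 2 * m, rs[1] + 2 * m, rs[2] + 2 * m)
    mask = np.zeros(vol_shape, dtype=bool)
    mask[m:m + rs[0], m:m + rs[1], m:m + rs[2]] = True
    t10 = np.full(vol_shape, config.t10_background_ms)
    t10[mask] = config.t10_tumor_ms
    m0 = np.full(vol_shape, config.m0)
    t1map = rx.T1Map(t1_ms=t10, m0=m0, fit_ok=np.ones(vol_shape, dtype=bool))

    conc = np.zeros(vol_shape + (grid.n,))
    ev = km.DPEvaluator(aif)
    vox = truth.voxel_params[patient_id]
    for params, idx in zip(vox, np.argwhere(mask)):
        f, ps, vp, ve = params
        conc[tuple(idx)] = ev.ct(f, ps, vp, ve)

    conc_noisy = conc
    if config.noise == "gaussian_conc":
        sd = float(conc[mask].max()) / config.snr
        conc_noisy = np.clip(conc + rng.normal(0.0, sd, conc.shape), 0.0, None)
    dyn = rx.concentration_to_signal(conc_noisy, t1map, config.r1,
                                     config.tr_ms, config.dyn_flip_deg)
    vfa = np.stack([rx.spgr_signal(m0, t10, config.tr_ms, ang)
                    for ang in config.flip_angles_deg])
    if config.noise == "rician":
        s0 = float(dyn[mask, :config.n_baseline].mean())
        sd = s0 / config.snr
        dyn = np.hypot(dyn + rng.normal(0.0, sd, dyn.shape),
                       rng.normal(0.0, sd, dyn.shape))
        vfa = np.hypot(vfa + rng.normal(0.0, sd, vfa.shape),
                       rng.normal(0.0, sd, vfa.shape))
    return RenderedPatient(patient_id=patient_id, grid=grid, aif=aif,
                           vfa_signals=vfa, dyn_signal=dyn, mask=mask,
                           t10_ms=t10, conc_truth=conc)


# ---------------------------------------------------------------------------
# on-disk layout
# ---------------------------------------------------------------------------

def write_patient(rendered: RenderedPatient, outdir: Path, config: CohortConfig) -> None:
    """Write one rendered patient as NIfTI volumes plus the AIF CSV."""
    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    nib.save(nib.Nifti1Image(rendered.dyn_signal.astype(np.float32), affine),
             outdir / "dynamic.nii")
    for ang, vol in zip(config.flip_angles_deg, rendered.vfa_signals):
        nib.save(nib.Nifti1Image(vol.astype(np.float32), affine),
                 outdir / f"vfa_{ang:g}deg.nii")
    nib.save(nib.Nifti1Image(rendered.mask.astype(np.uint8), affine),
             outdir / "mask.nii")
    t_s = rendered.grid.t * 60.0
    pd.DataFrame({"time_s": t_s, "concentration_mM": rendered.aif.cp}).to_csv(
        outdir / "aif.csv", index=False)


def generate_run(config: CohortConfig, seed: int, outdir: Path,
                 render: bool = True) -> SyntheticTruth:
    """Sample a cohort and write a complete run directory: ``truth.csv``
    (reported-unit true ROI medians), ``labels.csv``, per-patient imaging
    (optional) and a manifest."""
    outdir = Path(outdir)
    if not outdir.parent.exists():
        raise InvalidInputError(f"output location {outdir.parent} does not exist")
    outdir.mkdir(parents=True, exist_ok=True)
    truth = sample_cohort(config, seed)
    truth.cohort_table.to_csv(outdir / "truth.csv", index=False)
    truth.patients[["patient_id", "group", "idh", "codeletion", "ki67"]].to_csv(
        outdir / "labels.csv", index=False)
    if render:
        child = np.random.SeedSequence(seed).spawn(len(truth.voxel_params))
        for ss, pid in zip(child, truth.voxel_params):
            rendered = render_patient(truth, pid, seed=ss.generate_state(1)[0] % (2**31))
            write_patient(rendered, outdir / pid, config)
    manifest = {
        "seed": int(seed),
        "config_hash": config_hash(config),
        "config": config.to_dict(),
        "n_patients": len(truth.patients),
        "rendered": bool(render),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return truth


def fixture_config(**overrides) -> CohortConfig:
    """Miniature 3-patient configuration used by the test suite: one patient
    per subtype, a 3x3x1 ROI and a shortened (90-frame) acquisition."""
    defaults = dict(n_wildtype=1, n_intact=1, n_codeleted=1,
                    roi_shape=(3, 3, 1), margin=1, n_dynamic=80,
                    n_baseline=10, snr=60.0)
    defaults.update(overrides)
    return CohortConfig(**defaults)
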