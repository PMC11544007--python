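"""Cohort-level statistics for DCE-MRI parameter tables.

The battery mirrors a typical molecular-neuroimaging analysis of glioma:

* two-group comparisons of ROI-median parameters by Mann-Whitney U
  (the parameter distributions are heavily skewed, so no normality gating),
  with Benjamini-Hochberg correction within each 9-parameter family;
* ROC analysis per parameter with DeLong variance, a Wald 95% CI, a test of
  AUC against 0.5, and a Youden-index operating point;
* a paired DeLong test between the best parameter of each model;
* Spearman rank correlation of every parameter with the Ki-67 labelling
  index.

Comparisons are run for IDH genotype (mutation vs wild-type, all patients)
and for 1p/19q codeletion status (codeleted vs intact) within IDH-mutant
patients only, where the question is biologically defined.

Conventions
-----------
``mann_whitney_u(x, y)`` reports U = #{(i,j): x_i > y_j} (+0.5 per tie), with
x the mutation (resp. codeleted) group, so parameters elevated in that group
give large U.  Each ROC is oriented with the *higher-median group as the
positive class*; the orientation is fixed by the data's direction of effect,
not forced, so an AUC below 0.5 is possible when median and rank order
disagree.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
import warnings
from typing import Dict, Sequence

import numpy as np
import pandas as pd
from scipy import stats as st
from statsmodels.stats.multitest import multipletests

from .exceptions import InvalidInputError

#: the nine parameters reported per patient (reported units)
PARAM_COLUMNS = (
    "ExTofts_Ktrans", "ExTofts_Ve", "ExTofts_Vp", "ExTofts_Kep",
    "DP_F", "DP_Vp", "DP_Ve", "DP_PS", "DP_E",
)

#: default thresholds of the two-stage subtype decision rule
#: (reported units: extended-Tofts Ve in mL/100 mL, DP blood flow in
#: mL/min/100 mL), taken from the glioma study cohort this pipeline models
IDH_VE_CUTOFF = 1.670
CODELETION_F_CUTOFF = 7.154

SUBTYPE_WILDTYPE = "IDH wild-type"
SUBTYPE_INTACT = "IDH mutation, 1p/19q intact"
SUBTYPE_CODELETED = "IDH mutation, 1p/19q codeleted"


def classify_glioma_subtype(
    extofts_ve: float,
    dp_f: float,
    ve_cutoff: float = IDH_VE_CUTOFF,
    f_cutoff: float = CODELETION_F_CUTOFF,
) -> str:
    """Two-stage threshold rule for the three molecular subtypes.

    A large interstitial fraction (Ve at or above ``ve_cutoff``) calls the
    tumor IDH wild-type; otherwise high blood flow (F at or above
    ``f_cutoff``) separates the 1p/19q-codeleted oligodendroglioma from the
    1p/19q-intact astrocytoma.
    """
    if extofts_ve >= ve_cutoff:
        return SUBTYPE_WILDTYPE
    return SUBTYPE_CODELETED if dp_f >= f_cutoff else SUBTYPE_INTACT


# ---------------------------------------------------------------------------
# elementary procedures
# ---------------------------------------------------------------------------

def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann-Whitney U of ``x`` versus ``y`` with a two-sided p value.

    U counts pairs with ``x_i > y_j`` (ties scored 0.5).  The p value is by
    exact enumeration when ``n1 + n2 <= 12`` and the pooled sample is
    tie-free, else by the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise InvalidInputError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    if x.size + y.size <= 12 and no_ties:
        res = st.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = st.mannwhitneyu(x, y, alternative="two-sided",
                              method="asymptotic", use_continuity=False)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (input order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise InvalidInputError("p_values must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InvalidInputError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _split_scores(scores, labels, positive):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == positive]
    neg = scores[labels != positive]
    if pos.size == 0 or neg.size == 0:
        raise InvalidInputError("both classes must be present")
    return pos, neg


def _structural_components(pos: np.ndarray, neg: np.ndarray):
    """DeLong structural components: per-positive and per-negative means of
    the Mann-Whitney kernel, and the empirical AUC (ties credited 0.5)."""
    diff = pos[:, None] - neg[None, :]
    psi = (diff > 0).astype(float) + 0.5 * (diff == 0)
    return psi.mean(axis=1), psi.mean(axis=0), float(psi.mean())


@dataclasses.dataclass(frozen=True)
class ROCResult:
    auc: float
    variance: float
    ci95: tuple
    p_vs_half: float
    n_pos: int
    n_neg: int


def roc_auc(scores, labels, positive=1) -> ROCResult:
    """Empirical AUC with DeLong variance, Wald 95% CI and a two-sided test
    of AUC = 0.5.

    The orientation is the caller's: ``positive`` names the positive class
    and higher scores vote for it, so the AUC may fall below 0.5.
    """
    pos, neg = _split_scores(scores, labels, positive)
    v10, v01, auc = _structural_components(pos, neg)
    var = 0.0
    if pos.size > 1:
        var += float(np.var(v10, ddof=1)) / pos.size
    if neg.size > 1:
        var += float(np.var(v01, ddof=1)) / neg.size
    half = 1.959963984540054 * math.sqrt(max(var, 0.0))
    ci = (max(0.0, auc - half), min(1.0, auc + half))
    if var > 0:
        p = 2.0 * st.norm.sf(abs(auc - 0.5) / math.sqrt(var))
    else:
        p = 1.0 if auc == 0.5 else 0.0
    return ROCResult(auc=auc, variance=var, ci95=ci, p_vs_half=float(p),
                     n_pos=int(pos.size), n_neg=int(neg.size))


@dataclasses.dataclass(frozen=True)
class YoudenResult:
    cutoff: float
    sensitivity: float
    specificity: float
    accuracy: float
    youden: float
    degenerate: bool


def youden_cutoff(scores, labels, positive=1) -> YoudenResult:
    """Operating point maximizing Youden's J = sens + spec - 1.

    Candidate thresholds are the midpoints between adjacent distinct scores
    (a score at or above the cutoff votes for the positive class); ties in J
    break toward the smaller cutoff.  If every score is identical the cutoff
    is degenerate and J = 0.
    """
    pos, neg = _split_scores(scores, labels, positive)
    scores = np.asarray(scores, dtype=float)
    distinct = np.unique(scores)
    if distinct.size == 1:
        sens = 1.0  # everything at the (degenerate) cutoff is called positive
        spec = 0.0
        acc = pos.size / scores.size
        return YoudenResult(float(distinct[0]), sens, spec, acc, 0.0, True)
    cands = 0.5 * (distinct[:-1] + distinct[1:])
    sens = (pos[None, :] >= cands[:, None]).mean(axis=1)
    spec = (neg[None, :] < cands[:, None]).mean(axis=1)
    j = sens + spec - 1.0
    k = int(np.argmax(j))  # first (= smallest cutoff) among ties
    acc = (float((pos >= cands[k]).sum()) + float((neg < cands[k]).sum())) / scores.size
    return YoudenResult(float(cands[k]), float(sens[k]), float(spec[k]),
                        float(acc), float(j[k]), False)


def delong_paired_test(scores_a, scores_b, labels, positive=1) -> tuple[float, float]:
    """Paired DeLong test of two correlated AUCs measured on the same
    subjects; returns ``(z, two-sided p)``."""
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    if sa.shape != sb.shape:
        raise InvalidInputError("paired score vectors must have equal length")
    pos_a, neg_a = _split_scores(sa, labels, positive)
    pos_b, neg_b = _split_scores(sb, labels, positive)
    v10a, v01a, auc_a = _structural_components(pos_a, neg_a)
    v10b, v01b, auc_b = _structural_components(pos_b, neg_b)
    m, n = pos_a.size, neg_a.size
    var = 0.0
    if m > 1:
        s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
        var += (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
    if n > 1:
        s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
        var += (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    d = auc_a - auc_b
    if var <= 0:
        return (0.0, 1.0) if abs(d) < 1e-12 else (math.copysign(math.inf, d), 0.0)
    z = d / math.sqrt(var)
    return float(z), float(2.0 * st.norm.sf(abs(z)))


def spearman_corr(x, y) -> tuple[float, float]:
    """Spearman rank correlation with an exact permutation p for n <= 10
    and the t approximation otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size or n < 3:
        raise InvalidInputError("need paired samples of length >= 3")
    rho = float(st.spearmanr(x, y).statistic)
    if n <= 10:
        rx = st.rankdata(x)
        ry = st.rankdata(y)
        rxc = rx - rx.mean()
        denom = math.sqrt(float(np.sum(rxc**2)) * float(np.sum((ry - ry.mean()) ** 2)))
        if denom == 0:
            return 0.0, 1.0
        count = 0
        total = 0
        chunk = []
        for perm in itertools.permutations(ry):
            chunk.append(perm)
            if len(chunk) == 40320:
                arr = np.asarray(chunk)
                r = (arr - ry.mean()) @ rxc / denom
                count += int(np.sum(np.abs(r) >= abs(rho) - 1e-12))
                total += arr.shape[0]
                chunk = []
        if chunk:
            arr = np.asarray(chunk)
            r = (arr - ry.mean()) @ rxc / denom
            count += int(np.sum(np.abs(r) >= abs(rho) - 1e-12))
            total += arr.shape[0]
        return rho, count / total
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return rho, float(2.0 * st.t.sf(abs(t), df=n - 2))


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

def _median_iqr(v: np.ndarray) -> str:
    q25, q50, q75 = np.percentile(v, [25, 50, 75])
    return f"{q50:.3f} ({q25:.3f},{q75:.3f})"


def _comparison_frames(cohort: pd.DataFrame, group_col: str, test_group: str,
                       ref_group: str, comparison: str, params: Sequence[str]):
    """One family: Mann-Whitney per parameter + BH across the family, and the
    matching ROC/Youden table oriented by the higher-median group."""
    g_test = cohort[cohort[group_col] == test_group]
    g_ref = cohort[cohort[group_col] == ref_group]
    for name, g in ((test_group, g_test), (ref_group, g_ref)):
        if len(g) == 0:
            raise InvalidInputError(f"empty stratum: no patients with {group_col} = {name!r}")
    comp_rows, roc_rows, p_raw = [], [], []
    for param in params:
        x = g_test[param].to_numpy(dtype=float)
        y = g_ref[param].to_numpy(dtype=float)
        u, p = mann_whitney_u(x, y)
        p_raw.append(p)
        comp_rows.append({
            "comparison": comparison, "parameter": param,
            f"median_iqr_{test_group}": _median_iqr(x),
            f"median_iqr_{ref_group}": _median_iqr(y),
            "U": u, "p_raw": p,
        })
        # orientation: the higher-median group is the positive class
        positive = test_group if np.median(x) >= np.median(y) else ref_group
        scores = cohort.loc[cohort[group_col].isin([test_group, ref_group]), param].to_numpy(dtype=float)
        labels = cohort.loc[cohort[group_col].isin([test_group, ref_group]), group_col].to_numpy()
        roc = roc_auc(scores, labels, positive=positive)
        yj = youden_cutoff(scores, labels, positive=positive)
        roc_rows.append({
            "comparison": comparison, "parameter": param, "positive_class": positive,
            "auc": roc.auc, "ci95_low": roc.ci95[0], "ci95_high": roc.ci95[1],
            "p": roc.p_vs_half, "cutoff": yj.cutoff, "sensitivity": yj.sensitivity,
            "specificity": yj.specificity, "accuracy": yj.accuracy,
        })
    adj = bh_adjust(p_raw)
    for row, pa in zip(comp_rows, adj):
        row["p_adj"] = float(pa)
    return pd.DataFrame(comp_rows), pd.DataFrame(roc_rows)


def build_report(
    cohort: pd.DataFrame,
    params: Sequence[str] = PARAM_COLUMNS,
    ki67_col: str = "ki67",
) -> Dict[str, pd.DataFrame]:
    """Run the full statistical battery on a cohort table.

    Expects one row per patient with columns ``idh`` ('mutation' /
    'wild-type'), ``codeletion`` ('intact' / 'codeleted' /
    'not-applicable'), the nine parameter columns and optionally Ki-67.

    Returns a dict of DataFrames: ``comparisons`` (both families, BH within
    each 9-parameter family), ``roc`` and — when Ki-67 is available —
    ``correlations``; plus ``model_comparison`` with the paired DeLong test
    between each model's best-AUC parameter in the IDH comparison.
    """
    missing = [c for c in (*params, "idh", "codeletion") if c not in cohort.columns]
    if missing:
        raise InvalidInputError(f"cohort table lacks columns: {missing}")
    comp_idh, roc_idh = _comparison_frames(
        cohort, "idh", "mutation", "wild-type", "IDH", params)
    mutants = cohort[cohort["idh"] == "mutation"]
    comp_cod, roc_cod = _comparison_frames(
        mutants, "codeletion", "codeleted", "intact", "1p19q", params)
    report = {
        "comparisons": pd.concat([comp_idh, comp_cod], ignore_index=True),
        "roc": pd.concat([roc_idh, roc_cod], ignore_index=True),
    }
    # paired DeLong: best Tofts parameter vs best DP parameter (IDH task)
    idh_roc = roc_idh.set_index("parameter")
    tofts_best = idh_roc.loc[[p for p in params if p.startswith("ExTofts")], "auc"].idxmax()
    dp_best = idh_roc.loc[[p for p in params if p.startswith("DP")], "auc"].idxmax()

    def _oriented(param):
        pos = idh_roc.loc[param, "positive_class"]
        s = cohort[param].to_numpy(dtype=float)
        return s if pos == "wild-type" else -s

    z, p = delong_paired_test(
        _oriented(tofts_best), _oriented(dp_best),
        cohort["idh"].to_numpy(), positive="wild-type")
    report["model_comparison"] = pd.DataFrame([{
        "comparison": "IDH", "parameter_a": tofts_best, "parameter_b": dp_best,
        "z": z, "p": p,
    }])
    if ki67_col in cohort.columns and cohort[ki67_col].notna().all():
        corr_rows = []
        for param in params:
            rho, p = spearman_corr(cohort[param].to_numpy(dtype=float),
                                   cohort[ki67_col].to_numpy(dtype=float))
            corr_rows.append({"parameter": param, "rho": rho, "p": p})
        report["correlations"] = pd.DataFrame(corr_rows)
    else:
        warnings.warn("cohort table has no complete Ki-67 column; "
                      "correlation table skipped", stacklevel=2)
    return report
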