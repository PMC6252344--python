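"""Retinol isotope dilution (RID): coefficients, predictions, evaluation.

RID estimates vitamin A total body stores from plasma retinol specific
activity after an oral labeled dose:

    TBS (µmol) = Fa x S x 1 / SA_p

where ``Fa`` is the fraction of the dose absorbed and residing in the
storage pool at time t, ``S`` is the ratio of plasma to storage-pool
specific activity at t, and ``SA_p = FD_p / M(5)`` is the plasma retinol
specific activity (fraction of dose per µmol).  From a compartmental model
the composite coefficient is

    Fa x S = F(6) x { [F(5) / M(5)] / [F(6) / M(6)] } = M(6) F(5) / M(5),

with F(I) the tracer fraction in compartment I.  Using a child's own
model-computed coefficients reproduces the assigned TBS exactly at every
time; the population strategy instead applies one model-derived Fa x S to
every child's measured SA_p.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Child, Cohort, child_truth_curve
from .kinetics import ModelSpec, SteadyState, simulate_tracer_all_compartments

__all__ = [
    "RIDCoefficients",
    "RIDEvaluation",
    "CoefficientCV",
    "coefficients_from_model",
    "child_coefficients",
    "sap",
    "rid_predict",
    "evaluate",
    "coefficient_cv_over_time",
    "variance_shares",
    "predict_cohort",
]


@dataclass
class RIDCoefficients:
    """Time-variant RID equation coefficients from a model."""

    times: np.ndarray
    fa: np.ndarray      # F(6): dose fraction absorbed and in stores
    s: np.ndarray       # plasma-to-store specific-activity ratio
    fas: np.ndarray     # composite coefficient Fa x S

    def at(self, t: float) -> float:
        """Composite coefficient at one requested time."""
        j = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[j] - t) > 1e-9:
            raise KeyError(f"no coefficient computed at t={t}")
        return float(self.fas[j])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_d": self.times, "Fa": self.fa, "S": self.s, "FaS": self.fas}
        )


def coefficients_from_model(spec: ModelSpec, steady: SteadyState,
                            times) -> RIDCoefficients:
    """Fa, S and Fa x S at ``times`` from a model and its steady state.

    Times must exceed the pre-plasma lag so that F(6) > 0.
    """
    times = np.asarray(times, dtype=float)
    comps = simulate_tracer_all_compartments(spec, times)
    f5, f6 = comps[5], comps[6]
    if np.any(f6 <= 0):
        bad = times[f6 <= 0]
        raise ValueError(f"F(6) = 0 at t={bad}: coefficients undefined")
    m5, m6 = steady.masses[5], steady.masses[6]
    s = (f5 / m5) / (f6 / m6)
    return RIDCoefficients(times=times, fa=f6.copy(), s=s, fas=f6 * s)


def child_coefficients(child: Child, times) -> RIDCoefficients:
    """A child's own (true) coefficients from its generating model."""
    from .kinetics import steady_state

    return coefficients_from_model(
        child.spec, steady_state(child.spec, child.M5), times
    )


def sap(m5: float, fdp) -> float | np.ndarray:
    """Plasma retinol specific activity: FD_p / M(5), per µmol."""
    if not m5 > 0:
        raise ValueError("plasma pool size must be positive")
    fdp = np.asarray(fdp, dtype=float)
    if np.any(fdp < 0):
        raise ValueError("FD_p must be non-negative")
    out = fdp / m5
    return float(out) if out.ndim == 0 else out


def rid_predict(fas, sap_value):
    """TBS (µmol) from the composite coefficient and specific activity."""
    sap_value = np.asarray(sap_value, dtype=float)
    if np.any(sap_value <= 0):
        raise ValueError("specific activity must be positive")
    out = np.asarray(fas, dtype=float) / sap_value
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# evaluation against assigned values
# ---------------------------------------------------------------------------

def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation; exact permutation P for tiny n, else the
    t-approximation."""
    rs = float(stats.spearmanr(x, y).statistic)
    n = len(x)
    if n <= 8:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            total += 1
            if abs(np.corrcoef(rx, perm)[0, 1]) >= obs - 1e-12:
                count += 1
        return rs, count / total
    return rs, float(stats.spearmanr(x, y).pvalue)


@dataclass
class RIDEvaluation:
    """Accuracy of per-child TBS predictions against assigned values."""

    per_child: pd.DataFrame      # id, assigned, predicted, ratio
    pct_within_25: float
    pct_within_50: float
    pct_within_75: float
    mean_ratio: float            # arithmetic mean of predicted/assigned
    ratio_range: tuple[float, float]
    geo_mean_predicted: float
    spearman_rs: float
    spearman_p: float
    r_squared: float
    slope: float
    intercept: float
    adequate: bool               # >= 75% of children within 25%

    def summary(self) -> str:
        lines = [
            "RID outcome evaluation",
            "-" * 40,
            f"children:                 {len(self.per_child)}",
            f"within 25% of assigned:   {self.pct_within_25:.0f}%",
            f"within 50% of assigned:   {self.pct_within_50:.0f}%",
            f"within 75% of assigned:   {self.pct_within_75:.0f}%",
            f"mean predicted/assigned:  {self.mean_ratio:.2f} "
            f"(range {self.ratio_range[0]:.2f}-{self.ratio_range[1]:.2f})",
            f"geometric mean predicted: {self.geo_mean_predicted:.0f} µmol",
            f"Spearman Rs:              {self.spearman_rs:.2f} (P = {self.spearman_p:.2g})",
            f"R^2 (predicted~assigned): {self.r_squared:.2f} "
            f"(slope {self.slope:.2f}, intercept {self.intercept:.3g})",
            f"adequate (>=75% within 25%): {self.adequate}",
        ]
        return "\n".join(lines)


def evaluate(predicted, assigned, ids=None) -> RIDEvaluation:
    """Band coverage, ratio statistics, rank and least-squares agreement."""
    predicted = np.asarray(predicted, dtype=float)
    assigned = np.asarray(assigned, dtype=float)
    if predicted.shape != assigned.shape:
        raise ValueError("predicted and assigned must have equal length")
    if np.any(assigned <= 0):
        raise ValueError("assigned TBS must be positive")
    ids = np.arange(1, len(assigned) + 1) if ids is None else np.asarray(ids)
    rel = np.abs(predicted - assigned) / assigned
    ratio = predicted / assigned
    pct = lambda b: float(100.0 * np.mean(rel <= b))
    rs, p = _spearman(predicted, assigned)
    reg = stats.linregress(assigned, predicted)
    per_child = pd.DataFrame({
        "id": ids, "assigned_tbs": assigned, "predicted_tbs": predicted,
        "ratio": ratio,
    })
    return RIDEvaluation(
        per_child=per_child,
        pct_within_25=pct(0.25), pct_within_50=pct(0.50), pct_within_75=pct(0.75),
        mean_ratio=float(np.mean(ratio)),
        ratio_range=(float(ratio.min()), float(ratio.max())),
        geo_mean_predicted=float(np.exp(np.mean(np.log(predicted)))),
        spearman_rs=rs, spearman_p=p,
        r_squared=float(reg.rvalue ** 2),
        slope=float(reg.slope), intercept=float(reg.intercept),
        adequate=pct(0.25) >= 75.0,
    )


def predict_cohort(fas_pop: float, cohort: Cohort, t: float
                   ) -> pd.DataFrame:
    """Per-child RID predictions from one population coefficient.

    Each child's SA_p at ``t`` comes from the child's own simulated FD_p
    (the sample every child contributes by design); the same population
    Fa x S is applied to all.
    """
    rows = []
    for child in cohort.children:
        fdp = float(child_truth_curve(child, [t]).fdp[0])
        sap_t = sap(child.M5, fdp)
        rows.append({
            "id": child.id,
            "assigned_tbs": child.TBS,
            "sap": sap_t,
            "predicted_tbs": rid_predict(fas_pop, sap_t),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# coefficient dispersion
# ---------------------------------------------------------------------------

@dataclass
class CoefficientCV:
    """Per-time dispersion of the per-child composite coefficient."""

    table: pd.DataFrame          # time_d, cv, cv_one_pool, cv_two_pool
    argmin_time: float           # time of lowest whole-cohort CV

    def cv_at(self, t: float) -> float:
        j = int(np.argmin(np.abs(self.table.time_d.to_numpy() - t)))
        return float(self.table.cv.iloc[j])


def coefficient_cv_over_time(cohort: Cohort, times) -> CoefficientCV:
    """Arithmetic CV (SD/mean) of per-child Fa x S at each time.

    Reported for the whole cohort and separately for the one- and two-pool
    subgroups; the time of minimum whole-cohort CV identifies the most
    robust time for applying a single population coefficient.
    """
    if len(cohort) < 2:
        raise ValueError("need at least two children for a CV")
    times = np.asarray(times, dtype=float)
    fas = np.array([
        c.TBS * child_truth_curve(c, times).fdp / c.M5 for c in cohort.children
    ])
    pools = np.array([c.variant_pools for c in cohort.children])

    def cv(mat: np.ndarray) -> np.ndarray:
        if mat.shape[0] < 2:
            return np.full(mat.shape[1], np.nan)
        return mat.std(axis=0, ddof=1) / mat.mean(axis=0)

    table = pd.DataFrame({
        "time_d": times,
        "cv": cv(fas),
        "cv_one_pool": cv(fas[pools == 1]),
        "cv_two_pool": cv(fas[pools == 2]),
    })
    argmin_time = float(times[int(np.argmin(table.cv.to_numpy()))])
    return CoefficientCV(table=table, argmin_time=argmin_time)


def variance_shares(fas_child, sap_child) -> dict[str, float]:
    """Share of the variance in log RID-predicted TBS attributable to the
    measured specific activity (1/SA_p) versus the composite coefficient.

    Uses the covariance decomposition of log TBS = log FaS + log(1/SA_p):
    each component's share is cov(component, total)/var(total).
    """
    log_fas = np.log(np.asarray(fas_child, dtype=float))
    log_inv_sap = -np.log(np.asarray(sap_child, dtype=float))
    total = log_fas + log_inv_sap
    var_total = np.var(total, ddof=1)
    return {
        "inv_sap": float(np.cov(log_inv_sap, total)[0, 1] / var_total),
        "fas": float(np.cov(log_fas, total)[0, 1] / var_total),
    }
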