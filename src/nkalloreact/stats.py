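"""Model-comparison statistics and competing-risks outcome analysis.

Spearman rank correlations (midrank ties, pairwise-complete deletion)
compare the ordinal-coded model outputs; clinical event incidence is
estimated with the Aalen-Johansen cause-specific cumulative incidence
estimator and compared across model levels with Gray's K-sample test of
subdistribution hazards (rho = 0 weighting), death acting as the
competing risk for the non-fatal events.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genotypes import OutcomeRecord
from .models import ScoreMatrix

__all__ = [
    "CorrelationMatrix",
    "CIFCurve",
    "GrayTestResult",
    "encode_scores",
    "spearman_matrix",
    "aalen_johansen",
    "records_to_arrays",
    "gray_test",
    "compare_cohorts",
]


# ---------------------------------------------------------------------------
# ordinal encoding and correlation
# ---------------------------------------------------------------------------

def encode_scores(
    matrix: ScoreMatrix,
    coding: Mapping[str, Mapping[str, float]] | None = None,
) -> pd.DataFrame:
    """Numeric pairs x models matrix under the documented ordinal coding.

    Without ``coding`` the codes attached at scoring time are used.  With
    ``coding`` (model_id -> {label: value}) the listed models are re-coded
    from their labels; a label missing from the override is a hard error.
    Missing cells stay missing (NaN).
    """
    codes = matrix.codes_frame()
    if coding:
        labels = matrix.labels_frame()
        for model, levels in coding.items():
            if model not in labels.columns:
                raise KeyError(f"unknown model {model!r} in coding")
            col = []
            for pid, lab in labels[model].items():
                if lab is None:
                    col.append(np.nan)
                elif lab not in levels:
                    raise KeyError(
                        f"model {model!r}: level {lab!r} absent from coding"
                    )
                else:
                    col.append(float(levels[lab]))
            codes[model] = col
    return codes


@dataclass
class CorrelationMatrix:
    model_ids: list[str]
    rho: pd.DataFrame          # NaN where undefined
    n_effective: pd.DataFrame

    def to_csv(self, rho_path, n_path=None) -> None:
        self.rho.rename_axis("model").to_csv(rho_path)
        if n_path is not None:
            self.n_effective.rename_axis("model").to_csv(n_path)


def spearman_matrix(encoded: pd.DataFrame, min_n: int = 3) -> CorrelationMatrix:
    """Spearman correlation matrix with pairwise-complete observations.

    Midranks handle ties.  A cell is undefined (NaN, never imputed 0)
    when either column is constant on the pairwise-complete subset or
    fewer than ``min_n`` complete pairs exist; the diagonal is 1 for
    non-constant columns.
    """
    cols = list(encoded.columns)
    if len(cols) < 2:
        raise ValueError("need at least two model columns")
    k = len(cols)
    rho = np.full((k, k), np.nan)
    neff = np.zeros((k, k), dtype=int)
    values = encoded.to_numpy(dtype=float)
    for i in range(k):
        for j in range(i, k):
            mask = ~np.isnan(values[:, i]) & ~np.isnan(values[:, j])
            n = int(mask.sum())
            neff[i, j] = neff[j, i] = n
            if n < min_n:
                continue
            x, y = values[mask, i], values[mask, j]
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            if i == j:
                rho[i, i] = 1.0
                continue
            r = sps.spearmanr(x, y).statistic
            rho[i, j] = rho[j, i] = r
    return CorrelationMatrix(
        model_ids=cols,
        rho=pd.DataFrame(rho, index=cols, columns=cols),
        n_effective=pd.DataFrame(neff, index=cols, columns=cols),
    )


# ---------------------------------------------------------------------------
# cumulative incidence (Aalen-Johansen)
# ---------------------------------------------------------------------------

@dataclass
class CIFCurve:
    event: str
    group: str
    times: np.ndarray       # distinct observed times, increasing
    cif: np.ndarray         # cumulative incidence of the cause at each time
    n_at_risk: np.ndarray

    def at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 0.0 if idx < 0 else float(self.cif[idx])


_STATUS_CODE = {"censored": 0, "event": 1, "competing_death": 2}


def records_to_arrays(
    records: Sequence[OutcomeRecord],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(times, status codes 0/1/2, pair_ids) from outcome records of one
    event type."""
    events = {r.event for r in records}
    if len(events) > 1:
        raise ValueError(f"records mix event types: {sorted(events)}")
    times = np.array([r.time for r in records], dtype=float)
    status = np.array([_STATUS_CODE[r.status] for r in records], dtype=int)
    ids = np.array([r.pair_id for r in records])
    return times, status, ids


def aalen_johansen(
    times: np.ndarray, status: np.ndarray, event: str = "", group: str = ""
) -> CIFCurve:
    """Cause-specific cumulative incidence (cause = status 1, competing =
    status 2, censored = 0).

    CIF(t) = sum over event times u <= t of S(u-) d1(u) / Y(u), with S the
    all-cause Kaplan-Meier estimator.  With no competing events this is
    exactly 1 - KM.
    """
    times = np.asarray(times, dtype=float)
    status = np.asarray(status, dtype=int)
    if times.size == 0:
        raise ValueError("empty group")
    order = np.argsort(times, kind="mergesort")
    t, s = times[order], status[order]
    uniq, first = np.unique(t, return_index=True)
    n = t.size
    y = n - first                               # at risk just before each time
    d_all = np.add.reduceat((s > 0).astype(int), first)
    d1 = np.add.reduceat((s == 1).astype(int), first)
    surv_factors = 1.0 - d_all / y
    s_minus = np.concatenate([[1.0], np.cumprod(surv_factors)[:-1]])  # S(t-)
    cif = np.cumsum(s_minus * d1 / y)
    return CIFCurve(event=event, group=group, times=uniq, cif=cif, n_at_risk=y)


# ---------------------------------------------------------------------------
# Gray's K-sample test
# ---------------------------------------------------------------------------

@dataclass
class GrayTestResult:
    statistic: float
    df: int
    p_value: float
    group_events: dict[str, int] = field(default_factory=dict)
    degenerate: bool = False


def _censoring_km_left(times: np.ndarray, censored: np.ndarray,
                       eval_times: np.ndarray) -> np.ndarray:
    """Left-continuous Kaplan-Meier of the censoring distribution G(t-),
    evaluated at ``eval_times`` (events censor the censoring process)."""
    order = np.argsort(times, kind="mergesort")
    t, c = times[order], censored[order]
    uniq, first = np.unique(t, return_index=True)
    n = t.size
    y = n - first
    dc = np.add.reduceat(c.astype(int), first)
    g = np.cumprod(1.0 - dc / y)
    # G(t-): last value strictly before t
    idx = np.searchsorted(uniq, eval_times, side="left") - 1
    out = np.where(idx >= 0, g[np.clip(idx, 0, None)], 1.0)
    return out


def _censoring_km_at(times: np.ndarray, censored: np.ndarray,
                     eval_times: np.ndarray) -> np.ndarray:
    """Right-continuous censoring KM G(t) at ``eval_times``."""
    order = np.argsort(times, kind="mergesort")
    t, c = times[order], censored[order]
    uniq, first = np.unique(t, return_index=True)
    n = t.size
    y = n - first
    dc = np.add.reduceat(c.astype(int), first)
    g = np.cumprod(1.0 - dc / y)
    idx = np.searchsorted(uniq, eval_times, side="right") - 1
    return np.where(idx >= 0, g[np.clip(idx, 0, None)], 1.0)


def gray_test(
    times: np.ndarray,
    status: np.ndarray,
    groups: np.ndarray,
    cause: int = 1,
) -> GrayTestResult:
    """Gray's K-sample test of equality of subdistribution hazards.

    Unweighted (rho = 0) comparison of the cause-specific cumulative
    incidence across groups.  Subjects failing from the competing cause
    stay in the subdistribution risk set, weighted by the within-group
    censoring survival ratio G(t-)/G(X_i); the score's variance is
    estimated from per-subject influence residuals and referred to a
    chi-square distribution with K-1 degrees of freedom.

    ``status``: 0 censored, ``cause`` the event of interest, anything
    else a competing event.
    """
    times = np.asarray(times, dtype=float)
    status = np.asarray(status)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    k = labels.size
    if k < 2:
        raise ValueError("Gray's test needs at least two groups")
    if any((groups == g).sum() < 1 for g in labels):
        raise ValueError("empty group")

    is_cause = status == cause
    is_competing = (status != cause) & (status != 0)
    is_censored = status == 0
    group_events = {str(g): int(is_cause[groups == g].sum()) for g in labels}

    tau = np.unique(times[is_cause])
    if tau.size == 0:
        return GrayTestResult(0.0, k - 1, 1.0, group_events, degenerate=True)

    n, m = times.size, tau.size
    w = np.zeros((n, m))
    at_risk = times[:, None] >= tau[None, :]
    w[at_risk] = 1.0
    # competing failures stay at risk, censoring-weighted within their group
    for g in labels:
        sel = groups == g
        gt_minus = _censoring_km_left(times[sel], is_censored[sel], tau)
        gx = _censoring_km_at(times[sel], is_censored[sel], times[sel])
        comp = sel & is_competing
        if not comp.any():
            continue
        gx_comp = _censoring_km_at(times[sel], is_censored[sel], times[comp])
        rows = np.where(comp)[0]
        past = times[comp][:, None] < tau[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(gx_comp[:, None] > 0, gt_minus[None, :] / gx_comp[:, None], 0.0)
        w[rows[:, None], np.arange(m)[None, :]] = np.where(past, ratio, 1.0)

    gmat = (groups[:, None] == labels[None, :]).astype(float)  # n x k
    d1_i = (is_cause[:, None] & (times[:, None] == tau[None, :])).astype(float)
    r_k = gmat.T @ w                       # k x m
    r_tot = r_k.sum(axis=0)                # m
    d1 = d1_i.sum(axis=0)                  # m
    d1k = gmat.T @ d1_i                    # k x m
    pi = r_k / r_tot[None, :]
    z = (d1k - pi * d1[None, :]).sum(axis=1)

    # influence residuals: eta_ik = sum_j (1{g_i=k} - pi_kj) (dN_1ij - w_ij dLam_j)
    dlam = d1 / r_tot
    a = d1_i - w * dlam[None, :]           # n x m
    eta = gmat * a.sum(axis=1)[:, None] - a @ pi.T   # n x k
    v = eta.T @ eta

    z_red = z[: k - 1]
    v_red = v[: k - 1, : k - 1]
    stat = float(z_red @ np.linalg.pinv(v_red) @ z_red)
    stat = max(stat, 0.0)
    p = float(sps.chi2.sf(stat, k - 1))
    return GrayTestResult(stat, k - 1, p, group_events)


def gray_test_records(
    records: Sequence[OutcomeRecord], groups: Mapping[str, object]
) -> GrayTestResult:
    """Gray's test from outcome records of one event type, grouped by a
    pair_id -> level mapping (pairs without a level are dropped)."""
    kept = [r for r in records if groups.get(r.pair_id) is not None]
    times, status, ids = records_to_arrays(kept)
    glab = np.array([str(groups[i]) for i in ids])
    return gray_test(times, status, glab)


# ---------------------------------------------------------------------------
# cohort comparison tests
# ---------------------------------------------------------------------------

def compare_cohorts(
    values: Sequence, labels: Sequence, kind: str
) -> tuple[str, float]:
    """Two-cohort comparison: chi-square (Fisher's exact for sparse 2x2
    tables) for categorical features, Student's t or Mann-Whitney U
    (normality-driven switch, Shapiro p < 0.05 on either cohort) for
    continuous ones.  Returns (test name, p-value)."""
    values = pd.Series(list(values))
    labels = pd.Series(list(labels))
    cohorts = labels.unique()
    if len(cohorts) != 2:
        raise ValueError("compare_cohorts needs exactly two cohorts")
    if kind == "categorical":
        table = pd.crosstab(values, labels).to_numpy()
        if table.size == 0 or table.shape[0] < 2:
            return ("degenerate", float("nan"))
        chi2, p, _, expected = sps.chi2_contingency(table, correction=False)
        if table.shape == (2, 2) and (expected < 5).any():
            _, p = sps.fisher_exact(table)
            return ("fisher_exact", float(p))
        return ("chi2", float(p))
    if kind == "continuous":
        a = values[labels == cohorts[0]].astype(float).dropna()
        b = values[labels == cohorts[1]].astype(float).dropna()
        normal = True
        for sample in (a, b):
            if len(sample) >= 3 and len(sample.unique()) > 1:
                if sps.shapiro(sample).pvalue < 0.05:
                    normal = False
            else:
                normal = False
        if normal:
            return ("student_t", float(sps.ttest_ind(a, b).pvalue))
        if (a.nunique() <= 1 and b.nunique() <= 1
                and a.min() == b.min()):
            return ("mann_whitney", 1.0)
        return ("mann_whitney", float(sps.mannwhitneyu(a, b).pvalue))
    raise ValueError(f"unknown kind {kind!r}")
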