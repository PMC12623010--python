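"""Relative tables, index-clustered odds ratios and demographic reports.

The primary estimator is a marginal logistic regression

    logit P(relative affected) = b0 + b1 * index_is_case (+ b2 * female)

fit by iteratively reweighted least squares, with a cluster-robust
(sandwich) variance whose clusters are the index probands — relatives of
the same index share genes and environment, so their outcomes are
correlated and the classical variance would be anti-conservative.  Because
people are counted in multiple pedigrees, related probands contribute
reciprocal rows to each other's clusters; the default variance therefore
adds a symmetric-dyad term to the index-clustered sandwich (see
``_index_dyad_cov``), without which the Wald test is anti-conservative
under the package's own null simulations.  Odds
ratios are exp(b) with Wald 95% CIs on the log-odds scale.  A
random-intercept-per-index variant fitted by adaptive Gauss-Hermite
quadrature is available as an alternative, not the default.

With a single binary predictor and no clustering the fit reduces exactly to
the 2x2 cross-product odds ratio with the Woolf standard error; that closed
form (`or_from_2x2`) serves as an independent oracle for the IRLS path.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, norm

from .errors import DegenerateFitError, SeparationError, UndefinedORError
from .genealogy import Genealogy
from .pedigree import KinshipCalculator, relatives_of, spouses_of
from .types import FEMALE, MALE, MatchSet, RiskEstimate

log = logging.getLogger(__name__)

Z95 = float(norm.isf(0.025))
SEPARATION_BOUND = 15.0  # |beta| beyond this is treated as separation

ROW_COLUMNS = ["index_id", "index_is_case", "index_sex", "relative_id",
               "relative_sex", "relative_affected", "degree", "relationship"]


# -- relative tables -------------------------------------------------------


def build_relative_table(genealogy: Genealogy, matchsets: List[MatchSet],
                         case_flags_by_person: Dict[str, bool],
                         degree_filter) -> pd.DataFrame:
    """Long-format outcome table for one analysis.

    One row per (index, relative) pair where the index is a matched case or
    one of its controls and the relative sits at ``degree_filter`` (1, 2, 3
    or ``"spouse"``).  ``case_flags_by_person`` is the diagnosis rule
    applied to the relatives' records (no pedigree-size filter).  A person
    related to several indexes contributes one row per index.
    """
    if degree_filter not in (1, 2, 3, "spouse"):
        raise ValueError(f"degree_filter must be 1, 2, 3 or 'spouse', got {degree_filter!r}")
    full = _relative_rows(genealogy, matchsets, case_flags_by_person,
                          spouse=(degree_filter == "spouse"))
    if full.empty:
        return full
    return full[full["degree"] == degree_filter].reset_index(drop=True)


def _relative_rows(genealogy: Genealogy, matchsets: List[MatchSet],
                   flags: Dict[str, bool], spouse: bool = False,
                   _kin: Optional[KinshipCalculator] = None) -> pd.DataFrame:
    kin = _kin if _kin is not None else KinshipCalculator(genealogy)
    rows = []
    for ms in matchsets:
        for index_id, is_case in [(ms.case_id, True)] + [(c, False) for c in ms.control_ids]:
            isex = genealogy.people[index_id].sex
            if spouse:
                it = [(rid, "spouse", "spouse") for rid in spouses_of(genealogy, index_id)]
            else:
                it = [(p.relative_id, p.degree, p.relationship)
                      for p in relatives_of(genealogy, index_id, 3, _kin=kin)]
            for rid, degree, relationship in it:
                r = genealogy.people[rid]
                rows.append((index_id, is_case, isex, rid, r.sex,
                             bool(flags.get(rid, False)), degree, relationship))
    return pd.DataFrame(rows, columns=ROW_COLUMNS)


def build_all_relative_tables(genealogy: Genealogy, matchsets: List[MatchSet],
                              case_flags_by_person: Dict[str, bool],
                              include_spouse: bool = True) -> Dict[object, pd.DataFrame]:
    """Tables for degrees 1-3 (and spouses) sharing one enumeration pass."""
    kin = KinshipCalculator(genealogy)
    full = _relative_rows(genealogy, matchsets, case_flags_by_person, _kin=kin)
    out: Dict[object, pd.DataFrame] = {}
    for d in (1, 2, 3):
        out[d] = (full[full["degree"] == d].reset_index(drop=True)
                  if not full.empty else full)
    if include_spouse:
        out["spouse"] = _relative_rows(genealogy, matchsets, case_flags_by_person,
                                       spouse=True, _kin=kin)
    return out


# -- logistic fitting ------------------------------------------------------


def _irls_logistic(X: np.ndarray, y: np.ndarray, weights: Optional[np.ndarray] = None,
                   tol: float = 1e-10, max_iter: int = 100) -> Tuple[np.ndarray, np.ndarray, float]:
    """Weighted logistic IRLS; returns (beta, unscaled bread (X'WX)^-1, ll)."""
    n, k = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if y.min() == y.max():
        raise DegenerateFitError("outcome has a single class")
    beta = np.zeros(k)
    ll_prev = -np.inf
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        ll = float(np.sum(w * (y * np.log(p) + (1 - y) * np.log(1 - p))))
        converged = np.abs(ll - ll_prev) < tol * (np.abs(ll_prev) + tol)
        ll_prev = ll
        W = w * p * (1 - p)
        XtW = X.T * W
        H = XtW @ X
        g = X.T @ (w * (y - p))
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            raise DegenerateFitError("singular information matrix (collinear design)")
        beta = beta + step
        if np.max(np.abs(beta)) > SEPARATION_BOUND:
            raise SeparationError(
                f"coefficient magnitude exceeded {SEPARATION_BOUND}; "
                "quasi-complete separation")
        # the trailing Newton step after the log-likelihood stabilizes is
        # essentially free and pins the estimate to quadratic-convergence
        # accuracy (~1e-12 on the log-odds scale)
        if converged and np.max(np.abs(step)) < 1e-9:
            break
    eta = X @ beta
    p = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
    W = w * p * (1 - p)
    bread = np.linalg.inv((X.T * W) @ X)
    ll = float(np.sum(w * (y * np.log(p) + (1 - y) * np.log(1 - p))))
    return beta, bread, ll


def _meat(scores: np.ndarray, clusters: np.ndarray) -> np.ndarray:
    codes, inv = np.unique(clusters, return_inverse=True)
    sums = np.zeros((len(codes), scores.shape[1]))
    np.add.at(sums, inv, scores)
    return sums.T @ sums


def _cluster_robust_cov(X: np.ndarray, y: np.ndarray, beta: np.ndarray,
                        bread: np.ndarray, clusters: np.ndarray,
                        weights: Optional[np.ndarray] = None) -> np.ndarray:
    """CR0 sandwich: bread @ (sum_g s_g s_g') @ bread with score sums per
    cluster.  With every row its own cluster this equals the model-based
    inverse information at the logistic MLE."""
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    p = 1.0 / (1.0 + np.exp(-(X @ beta)))
    scores = X * (w * (y - p))[:, None]
    return bread @ _meat(scores, clusters) @ bread


def _index_dyad_cov(X: np.ndarray, y: np.ndarray, beta: np.ndarray,
                    bread: np.ndarray, index_ids: np.ndarray,
                    relative_ids: np.ndarray,
                    weights: Optional[np.ndarray] = None) -> np.ndarray:
    """Index-clustered sandwich with a symmetric-dyad correction.

    Relatives can themselves be probands of other matched sets, so a
    related proband pair (A, B) contributes two reciprocal rows — B in A's
    cluster and A in B's — whose outcomes are jointly determined.  The plain
    index-clustered sandwich misses that cross-cluster dependence and is
    anti-conservative whenever probands are dense in the pedigree.  The
    multiway estimator V(index) + V(unordered pair) - V(row) adds exactly
    the reciprocal-dyad covariance; when no person appears both as a
    relative and as a proband it reduces to the index-clustered sandwich.
    """
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    p = 1.0 / (1.0 + np.exp(-(X @ beta)))
    scores = X * (w * (y - p))[:, None]
    idx = index_ids.astype(str)
    rel = relative_ids.astype(str)
    swap = idx > rel
    lo = np.where(swap, rel, idx)
    hi = np.where(swap, idx, rel)
    dyad = np.char.add(np.char.add(lo, "|"), hi)
    meat = (_meat(scores, idx)
            + _meat(scores, dyad)
            - scores.T @ scores)
    cov = bread @ meat @ bread
    d = np.diag(cov)
    if (d <= 0).any():  # multiway CR estimators are not guaranteed PSD
        log.warning("non-positive variance in multiway sandwich; "
                    "falling back to index clustering for those terms")
        fallback = bread @ _meat(scores, idx) @ bread
        cov = cov.copy()
        bad = np.where(d <= 0)[0]
        cov[bad, bad] = np.diag(fallback)[bad]
    return cov


def fit_clustered_logistic(rows: pd.DataFrame, include_sex: bool = True,
                           cluster_on_index: bool = True,
                           weights: Optional[np.ndarray] = None) -> List[RiskEstimate]:
    """Fit the index-clustered logistic model on a relative table.

    Returns one :class:`RiskEstimate` per non-intercept term:
    ``relative_of_case`` (the familial-risk OR) and, when ``include_sex``,
    ``female`` (the female-vs-male OR), both with cluster-robust Wald CIs.
    """
    if rows.empty:
        raise DegenerateFitError("empty relative table")
    y = rows["relative_affected"].to_numpy(dtype=float)
    case = rows["index_is_case"].to_numpy(dtype=float)
    cols = [np.ones(len(rows)), case]
    names = ["intercept", "relative_of_case"]
    if include_sex:
        cols.append((rows["relative_sex"] == FEMALE).to_numpy(dtype=float))
        names.append("female")
    X = np.column_stack(cols)
    if case.min() == case.max():
        raise DegenerateFitError("all rows share one index arm (case or control only)")
    beta, bread, _ = _irls_logistic(X, y, weights=weights)
    if cluster_on_index:
        cov = _index_dyad_cov(X, y, beta, bread,
                              rows["index_id"].to_numpy(),
                              rows["relative_id"].to_numpy(), weights=weights)
    else:
        cov = _cluster_robust_cov(X, y, beta, bread, np.arange(len(rows)),
                                  weights=weights)
    se = np.sqrt(np.diag(cov))
    w = np.ones(len(rows)) if weights is None else np.asarray(weights, dtype=float)
    n_case = int(round(float(w[case == 1].sum())))
    n_ctrl = int(round(float(w[case == 0].sum())))
    out = []
    for j, name in enumerate(names):
        if name == "intercept":
            continue
        z = beta[j] / se[j]
        out.append(RiskEstimate(
            term=name,
            odds_ratio=float(np.exp(beta[j])),
            ci_low=float(np.exp(beta[j] - Z95 * se[j])),
            ci_high=float(np.exp(beta[j] + Z95 * se[j])),
            p_value=float(2.0 * norm.sf(abs(z))),
            n_case_relatives=n_case,
            n_control_relatives=n_ctrl,
        ))
    return out


def or_from_2x2(a: float, b: float, c: float, d: float) -> RiskEstimate:
    """Closed-form 2x2 odds ratio oracle.

    Cells: a = affected case-relatives, b = unaffected case-relatives,
    c = affected control-relatives, d = unaffected control-relatives.
    Haldane-Anscombe 0.5 is added to every cell iff any cell is zero;
    the CI is Woolf's on the log scale.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if (cells < 0).any():
        raise ValueError("cell counts must be >= 0")
    if min(a + b, c + d, a + c, b + d) == 0:
        raise UndefinedORError("a full margin of the 2x2 table is zero")
    if (cells == 0).any():
        cells = cells + 0.5
    aa, bb, cc, dd = cells
    log_or = float(np.log(aa * dd / (bb * cc)))
    se = float(np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd))
    z = log_or / se
    return RiskEstimate(
        term="2x2",
        odds_ratio=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - Z95 * se)),
        ci_high=float(np.exp(log_or + Z95 * se)),
        p_value=float(2.0 * norm.sf(abs(z))),
        n_case_relatives=int(a + b),
        n_control_relatives=int(c + d),
    )


# -- stratified / spousal analyses ----------------------------------------

_PARENT_LABEL = {MALE: "father", FEMALE: "mother"}
_CHILD_LABEL = {MALE: "son", FEMALE: "daughter"}
_SIB_LABEL = {MALE: "brother", FEMALE: "sister"}


def _stratum_label(relationship: str, relative_sex: str, index_sex: str) -> str:
    if relationship == "parent":  # relative is the index's parent
        return f"{_PARENT_LABEL[relative_sex]}|{_CHILD_LABEL[index_sex]}-index"
    if relationship == "child":
        return f"{_CHILD_LABEL[relative_sex]}|{_PARENT_LABEL[index_sex]}-index"
    return f"{_SIB_LABEL[relative_sex]}|{_SIB_LABEL[index_sex]}-index"


def stratified_fdr_analysis(genealogy: Genealogy, matchsets: List[MatchSet],
                            case_flags_by_person: Dict[str, bool],
                            rows: Optional[pd.DataFrame] = None,
                            ) -> Tuple[List[RiskEstimate], Dict[str, str]]:
    """First-degree odds ratios per (relationship x relative sex x index
    sex) stratum — e.g. the risk in sons of affected fathers vs sons of
    unaffected fathers is the ``son|father-index`` stratum.  Returns the
    estimates plus a mapping of skipped stratum -> reason."""
    if rows is None:
        rows = build_relative_table(genealogy, matchsets, case_flags_by_person, 1)
    estimates: List[RiskEstimate] = []
    skipped: Dict[str, str] = {}
    if rows.empty:
        return estimates, {"all": "no first-degree rows"}
    for (rel, rsex, isex), grp in rows.groupby(
            ["relationship", "relative_sex", "index_sex"], sort=True):
        label = _stratum_label(rel, rsex, isex)
        try:
            est = fit_clustered_logistic(grp, include_sex=False)[0]
        except (DegenerateFitError, SeparationError) as exc:
            skipped[label] = str(exc)
            log.info("stratum %s skipped: %s", label, exc)
            continue
        est.term = label
        estimates.append(est)
    estimates.sort(key=lambda e: e.term)
    return estimates, skipped


def spousal_analysis(genealogy: Genealogy, matchsets: List[MatchSet],
                     case_flags_by_person: Dict[str, bool],
                     rows: Optional[pd.DataFrame] = None,
                     ) -> Tuple[List[RiskEstimate], Dict[str, str]]:
    """Spousal odds ratios split by index sex: husbands of (affected vs
    unaffected) wives, and wives of (affected vs unaffected) husbands."""
    if rows is None:
        rows = build_relative_table(genealogy, matchsets, case_flags_by_person, "spouse")
    estimates: List[RiskEstimate] = []
    skipped: Dict[str, str] = {}
    if rows.empty:
        return estimates, {
            "husband_of_index_wife": "no spouse pairs",
            "wife_of_index_husband": "no spouse pairs",
        }
    for label, isex in (("husband_of_index_wife", FEMALE),
                        ("wife_of_index_husband", MALE)):
        grp = rows[rows["index_sex"] == isex]
        if grp.empty:
            skipped[label] = "no spouse pairs"
            continue
        try:
            est = fit_clustered_logistic(grp, include_sex=False)[0]
        except (DegenerateFitError, SeparationError) as exc:
            skipped[label] = str(exc)
            continue
        est.term = label
        estimates.append(est)
    return estimates, skipped


# -- demographics report ---------------------------------------------------

DEFAULT_BIRTH_YEAR_BINS = ((1906, 1919), (1920, 1939), (1940, 1959),
                           (1960, 1979), (1980, 2004))


def format_percent(n: int, total: int) -> str:
    """Whole-percent formatting with one decimal kept below 10%."""
    if total == 0:
        return "0%"
    pct = 100.0 * n / total
    return f"{pct:.0f}%" if pct >= 10 else f"{pct:.1f}%"


def _year_bin(year: int, bins) -> str:
    for lo, hi in bins:
        if lo <= year <= hi:
            return f"{lo}-{hi}"
    return "other"


def demographics_report(cases: Iterable[str], controls: Iterable[str],
                        genealogy: Genealogy,
                        metrics: Optional[dict] = None,
                        birth_year_bins=DEFAULT_BIRTH_YEAR_BINS,
                        ) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Cohort-balance table: per-variable level counts and percentages for
    cases vs controls, with a Pearson chi-squared p-value per variable.
    Levels empty in both cohorts are shown with zero counts but excluded
    from the chi-squared."""
    from .pedigree import pedigree_metrics_all
    from .types import size_stratum

    cases, controls = sorted(set(cases)), sorted(set(controls))
    if not cases or not controls:
        raise ValueError("both cohorts must be nonempty")
    if metrics is None:
        metrics = pedigree_metrics_all(genealogy)

    def level_of(pid, var):
        p = genealogy.people[pid]
        if var == "sex":
            return p.sex
        if var == "birth_year":
            return _year_bin(p.birth_year, birth_year_bins)
        if var == "birth_place":
            return p.birth_place
        if var == "pedigree_size":
            return size_stratum(metrics[pid].pedigree_size)
        return str(metrics[pid].max_degree)

    variables = {
        "sex": [FEMALE, MALE],
        "birth_year": [f"{lo}-{hi}" for lo, hi in birth_year_bins] + ["other"],
        "birth_place": ["in_state", "out_of_state"],
        "pedigree_size": ["0-4", "5-9", "10+"],
        "max_degree": ["0", "1", "2", "3"],
    }
    records = []
    pvals: Dict[str, float] = {}
    for var, levels in variables.items():
        case_counts = {lv: 0 for lv in levels}
        ctrl_counts = {lv: 0 for lv in levels}
        for pid in cases:
            case_counts[level_of(pid, var)] += 1
        for pid in controls:
            ctrl_counts[level_of(pid, var)] += 1
        table = [[case_counts[lv] for lv in levels if case_counts[lv] + ctrl_counts[lv] > 0],
                 [ctrl_counts[lv] for lv in levels if case_counts[lv] + ctrl_counts[lv] > 0]]
        if len(table[0]) >= 2:
            pvals[var] = float(chi2_contingency(np.asarray(table))[1])
        else:
            pvals[var] = float("nan")
        for lv in levels:
            if var == "birth_year" and lv == "other" and \
                    case_counts[lv] + ctrl_counts[lv] == 0:
                continue
            records.append((
                var, lv,
                case_counts[lv], format_percent(case_counts[lv], len(cases)),
                ctrl_counts[lv], format_percent(ctrl_counts[lv], len(controls)),
            ))
    table1 = pd.DataFrame(records, columns=[
        "variable", "level", "case_n", "case_pct", "control_n", "control_pct"])
    return table1, pvals


# -- random-intercept variant ---------------------------------------------


def fit_random_intercept_logistic(rows: pd.DataFrame, include_sex: bool = True,
                                  n_quad: int = 15) -> Tuple[List[RiskEstimate], float]:
    """Random-intercept-per-index logistic model, fitted by maximizing the
    marginal likelihood with adaptive Gauss-Hermite quadrature (``n_quad``
    nodes, centered and scaled at each cluster's posterior mode).

    Returns (estimates, random-intercept SD).  Estimates are
    subject-specific (conditional) ORs, which exceed the marginal ones when
    the intercept variance is large; with small clusters and rare outcomes
    the two are close.
    """
    if rows.empty:
        raise DegenerateFitError("empty relative table")
    y = rows["relative_affected"].to_numpy(dtype=float)
    case = rows["index_is_case"].to_numpy(dtype=float)
    cols = [np.ones(len(rows)), case]
    names = ["intercept", "relative_of_case"]
    if include_sex:
        cols.append((rows["relative_sex"] == FEMALE).to_numpy(dtype=float))
        names.append("female")
    X = np.column_stack(cols)
    _, inv = np.unique(rows["index_id"].to_numpy(), return_inverse=True)
    n_clusters = inv.max() + 1
    nodes, qw = np.polynomial.hermite.hermgauss(n_quad)
    logqw = np.log(qw)

    order = np.argsort(inv, kind="mergesort")
    Xs, ys, invs = X[order], y[order], inv[order]
    starts = np.searchsorted(invs, np.arange(n_clusters))
    stops = np.append(starts[1:], len(ys))

    def neg_marginal_ll(theta: np.ndarray) -> float:
        beta, log_tau = theta[:-1], theta[-1]
        tau = np.exp(log_tau)
        eta = Xs @ beta
        total = 0.0
        for g in range(n_clusters):
            sl = slice(starts[g], stops[g])
            e, yy = eta[sl], ys[sl]

            def f_and_derivs(b):
                z = e + b
                p = 1.0 / (1.0 + np.exp(-z))
                f = float(np.sum(yy * z - np.log1p(np.exp(z))) - 0.5 * b * b / tau**2)
                d1 = float(np.sum(yy - p) - b / tau**2)
                d2 = float(-np.sum(p * (1 - p)) - 1.0 / tau**2)
                return f, d1, d2

            b = 0.0
            for _ in range(25):  # Newton for the cluster mode
                f, d1, d2 = f_and_derivs(b)
                step = d1 / d2
                b -= step
                if abs(step) < 1e-9:
                    break
            f_hat, _, d2 = f_and_derivs(b)
            scale = np.sqrt(2.0 / max(-d2, 1e-10))
            bs = b + scale * nodes
            zs = e[:, None] + bs[None, :]
            logf = (np.sum(yy[:, None] * zs - np.log1p(np.exp(zs)), axis=0)
                    - 0.5 * bs**2 / tau**2)
            contrib = logf + nodes**2 + logqw
            m = contrib.max()
            total += m + np.log(np.sum(np.exp(contrib - m))) + np.log(scale) \
                - 0.5 * np.log(2 * np.pi * tau**2)
        return -total

    from scipy.optimize import minimize

    beta0, _, _ = _irls_logistic(X, y)
    theta0 = np.append(beta0, np.log(0.5))
    res = minimize(neg_marginal_ll, theta0, method="BFGS",
                   options={"gtol": 1e-6, "maxiter": 200})
    theta = res.x
    # finite-difference Hessian for Wald SEs
    k = len(theta)
    h = 1e-4 * np.maximum(1.0, np.abs(theta))
    H = np.zeros((k, k))
    f0 = neg_marginal_ll(theta)
    for i in range(k):
        for j in range(i, k):
            ti = theta.copy(); ti[i] += h[i]
            tj = theta.copy(); tj[j] += h[j]
            tij = theta.copy(); tij[i] += h[i]; tij[j] += h[j]
            H[i, j] = H[j, i] = (
                neg_marginal_ll(tij) - neg_marginal_ll(ti)
                - neg_marginal_ll(tj) + f0) / (h[i] * h[j])
    cov = np.linalg.pinv(H)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    n_case = int((case == 1).sum())
    n_ctrl = int((case == 0).sum())
    out = []
    for j, name in enumerate(names):
        if name == "intercept":
            continue
        z = theta[j] / se[j] if se[j] > 0 else np.inf
        out.append(RiskEstimate(
            term=name,
            odds_ratio=float(np.exp(theta[j])),
            ci_low=float(np.exp(theta[j] - Z95 * se[j])),
            ci_high=float(np.exp(theta[j] + Z95 * se[j])),
            p_value=float(2.0 * norm.sf(abs(z))),
            n_case_relatives=n_case,
            n_control_relatives=n_ctrl,
        ))
    return out, float(np.exp(theta[-1]))


def estimates_frame(estimates: List[RiskEstimate]) -> pd.DataFrame:
    """Risk estimates as a tidy table (one row per fitted term)."""
    return pd.DataFrame(
        [(e.term, e.n_case_relatives, e.n_control_relatives, e.odds_ratio,
          e.ci_low, e.ci_high, e.p_value) for e in estimates],
        columns=["term", "n_case_relatives", "n_control_relatives",
                 "odds_ratio", "ci_low", "ci_high", "p_value"],
    )
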