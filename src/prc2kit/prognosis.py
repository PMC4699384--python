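"""Proliferation-metagene adjustment and survival analysis.

The central idea: a marker transcript's association with outcome mixes a
proliferation-driven component with a proliferation-independent one.  We
summarise proliferation as a metagene (per-sample median of a proliferation
gene set), residualise the marker on it by OLS, and re-run the survival
comparison on the residuals.  Everything downstream (Kaplan-Meier, log-rank,
univariate Cox, BH-FDR, per-gene copy-number scans, ROC AUC) is implemented
from first principles so that each step is auditable against textbook
formulas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "compute_metagene",
    "adjust_to_metagene",
    "median_stratify",
    "km_estimate",
    "logrank_test",
    "cox_univariate",
    "bh_fdr",
    "chromosome_scan",
    "stratify_by_cnv",
    "roc_auc",
    "AdjustedExpression",
    "SurvivalCurve",
    "LogRankResult",
    "CoxResult",
    "ScanResult",
]

CNV_STATES = (-2, -1, 0, 1)


# ---------------------------------------------------------------------------
# metagene / adjustment
# ---------------------------------------------------------------------------

def compute_metagene(expr: pd.DataFrame, prolif_genes) -> pd.Series:
    """Per-sample median expression over a proliferation gene set.

    Parameters
    ----------
    expr
        genes x samples log2 expression, indexed by gene id.
    prolif_genes
        iterable of gene ids; all must be present in ``expr``.

    Returns
    -------
    pandas.Series indexed by sample id.
    """
    prolif_genes = list(prolif_genes)
    if not prolif_genes:
        raise ValueError("empty proliferation gene set")
    missing = [g for g in prolif_genes if g not in expr.index]
    if missing:
        raise KeyError(f"proliferation genes absent from expression matrix: {missing}")
    return expr.loc[prolif_genes].median(axis=0)


@dataclass
class AdjustedExpression:
    """Residuals of a marker on the metagene plus the fitted line."""

    sample_ids: np.ndarray
    residuals: np.ndarray
    slope: float
    intercept: float

    def as_series(self) -> pd.Series:
        return pd.Series(self.residuals, index=self.sample_ids)


def adjust_to_metagene(marker: pd.Series, metagene: pd.Series) -> AdjustedExpression:
    """OLS residualisation of ``marker`` on ``metagene`` (matched sample ids)."""
    if not marker.index.equals(metagene.index):
        common = marker.index.intersection(metagene.index)
        if len(common) != len(marker) or len(common) != len(metagene):
            raise ValueError("marker and metagene sample ids do not match")
        metagene = metagene.loc[marker.index]
    x = metagene.to_numpy(dtype=float)
    y = marker.to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("metagene is constant: degenerate adjustment")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    return AdjustedExpression(
        sample_ids=marker.index.to_numpy(),
        residuals=resid,
        slope=float(slope),
        intercept=float(intercept),
    )


def median_stratify(values: pd.Series) -> pd.Series:
    """Split samples at the median: 'high' strictly above, ties go to 'low'."""
    v = values.to_numpy(dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 samples to stratify")
    if np.ptp(v) == 0:
        raise ValueError("all values identical: no stratification possible")
    med = np.median(v)
    labels = np.where(v > med, "high", "low")
    return pd.Series(labels, index=values.index)


def stratify_by_cnv(states: pd.Series) -> pd.Series:
    """Map integer copy states to {loss, neutral, gain}; -2 counts as loss."""
    mapping = {-2: "loss", -1: "loss", 0: "neutral", 1: "gain"}
    out = []
    for s in states:
        si = int(s)
        if si not in mapping:
            raise ValueError(f"unknown copy-number state {s!r}")
        out.append(mapping[si])
    return pd.Series(out, index=states.index)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class SurvivalCurve:
    """Product-limit estimate tabulated at distinct observed times."""

    times: np.ndarray       # distinct observed times, ascending
    at_risk: np.ndarray     # n_i just before each time
    events: np.ndarray      # d_i events at each time
    survival: np.ndarray    # S(t_i)

    def survival_at(self, t: float) -> float:
        """Right-continuous step-function value S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        if idx < 0:
            return 1.0
        return float(self.survival[idx])


def _check_surv(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty survival input")
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if np.any(times < 0):
        raise ValueError("negative follow-up time")
    if not np.all(np.isin(events, (0, 1))):
        raise ValueError("event indicator must be 0 or 1")
    return times, events


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator S(t) = prod(1 - d_i/n_i)."""
    times, events = _check_surv(times, events)
    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    e_sorted = events[order]
    uniq = np.unique(t_sorted)
    n = len(t_sorted)
    at_risk = np.empty(len(uniq))
    d = np.empty(len(uniq))
    surv = np.empty(len(uniq))
    s = 1.0
    for i, t in enumerate(uniq):
        mask = t_sorted == t
        n_i = n - np.searchsorted(t_sorted, t, side="left")
        d_i = int(e_sorted[mask].sum())
        if d_i > 0:
            s *= 1.0 - d_i / n_i
        at_risk[i] = n_i
        d[i] = d_i
        surv[i] = s
    return SurvivalCurve(times=uniq, at_risk=at_risk, events=d, survival=surv)


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

@dataclass
class LogRankResult:
    groups: list
    observed: dict
    expected: dict
    chi2: float
    p_value: float
    hazard_ratio: float      # worse-vs-better by KM at last event time
    worse_group: object
    better_group: object

    def hr(self, a, b) -> float:
        """(O_a/E_a) / (O_b/E_b) for two group labels."""
        return (self.observed[a] / self.expected[a]) / (
            self.observed[b] / self.expected[b]
        )


def logrank_test(times, events, groups) -> LogRankResult:
    """k-sample log-rank test with hypergeometric moments per event time.

    The chi-square uses the full covariance of the (O - E) vector over the
    first k-1 groups; for two groups this reduces to the familiar
    (O1 - E1)^2 / V.  The reported hazard ratio is the ratio of O/E for the
    group with the lower Kaplan-Meier value at the last event time over the
    other ("worse over better"), the convention used for two-group survival
    figures.
    """
    times, events = _check_surv(times, events)
    groups = np.asarray(groups)
    if groups.shape != times.shape:
        raise ValueError("groups must match times in length")
    labels = [g for g in pd.unique(groups)]
    k = len(labels)
    if k < 2:
        raise ValueError("need at least 2 non-empty groups")
    if events.sum() == 0:
        raise ValueError("need at least 1 event")
    gidx = np.array([labels.index(g) for g in groups])

    event_times = np.unique(times[events == 1])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t in event_times:
        at_risk = times >= t
        n = at_risk.sum()
        nj = np.bincount(gidx[at_risk], minlength=k).astype(float)
        dead = at_risk & (times == t) & (events == 1)
        d = dead.sum()
        dj = np.bincount(gidx[dead], minlength=k).astype(float)
        O += dj
        E += d * nj / n
        if n > 1:
            frac = nj / n
            V += (d * (n - d) / (n - 1)) * (np.diag(frac) - np.outer(frac, frac))

    diff = (O - E)[: k - 1]
    cov = V[: k - 1, : k - 1]
    chi2 = float(diff @ np.linalg.pinv(cov) @ diff)
    p = float(stats.chi2.sf(chi2, df=k - 1))

    # orient the HR by the group-wise KM at the last event time
    t_last = event_times[-1]
    km_vals = {}
    for j, lab in enumerate(labels):
        sel = gidx == j
        km_vals[lab] = km_estimate(times[sel], events[sel]).survival_at(t_last)
    ordered = sorted(labels, key=lambda lab: km_vals[lab])
    worse, better = ordered[0], ordered[-1]
    observed = {lab: float(O[j]) for j, lab in enumerate(labels)}
    expected = {lab: float(E[j]) for j, lab in enumerate(labels)}
    hr = (observed[worse] / expected[worse]) / (observed[better] / expected[better])
    return LogRankResult(
        groups=labels,
        observed=observed,
        expected=expected,
        chi2=chi2,
        p_value=p,
        hazard_ratio=float(hr),
        worse_group=worse,
        better_group=better,
    )


# ---------------------------------------------------------------------------
# Cox partial likelihood
# ---------------------------------------------------------------------------

@dataclass
class CoxResult:
    beta: float
    se: float
    p_value: float
    converged: bool
    n_iter: int
    log_likelihood: float = field(default=np.nan)


def _cox_loglik_terms(beta, x, event_blocks, risk_blocks, ties):
    """Log-likelihood, gradient and information for a scalar covariate."""
    w = np.exp(beta * x)
    xw = x * w
    x2w = x * xw
    ll = 0.0
    grad = 0.0
    info = 0.0
    for D, R in zip(event_blocks, risk_blocks):
        d = len(D)
        s0R = w[R].sum()
        s1R = xw[R].sum()
        s2R = x2w[R].sum()
        if ties == "efron":
            s0D = w[D].sum()
            s1D = xw[D].sum()
            s2D = x2w[D].sum()
            ll += beta * x[D].sum()
            for el in range(d):
                f = el / d
                phi = s0R - f * s0D
                psi = s1R - f * s1D
                chi = s2R - f * s2D
                ll -= np.log(phi)
                grad_term = psi / phi
                grad -= grad_term
                info += chi / phi - grad_term**2
            grad += x[D].sum()
        else:  # breslow
            ll += beta * x[D].sum() - d * np.log(s0R)
            grad += x[D].sum() - d * s1R / s0R
            info += d * (s2R / s0R - (s1R / s0R) ** 2)
    return ll, grad, info


def cox_univariate(times, events, covariate, ties: str = "efron",
                   tol: float = 1e-8, max_iter: int = 50) -> CoxResult:
    """Univariate Cox PH fit by Newton-Raphson with step-halving.

    Efron's approximation handles tied event times by default; Breslow is
    available via ``ties="breslow"``.  Monotone partial likelihoods (perfect
    separation) are reported as non-converged with no coefficient.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    times, events = _check_surv(times, events)
    x = np.asarray(covariate, dtype=float)
    if x.shape != times.shape:
        raise ValueError("covariate must match times in length")
    sd = x.std()
    if sd == 0:
        raise ValueError("constant covariate: Cox model undefined")
    z = (x - x.mean()) / sd  # standardized for numerical stability

    order = np.argsort(times, kind="stable")
    t_s = times[order]
    e_s = events[order]
    z_s = z[order]
    event_times = np.unique(t_s[e_s == 1])
    event_blocks = []
    risk_blocks = []
    for t in event_times:
        event_blocks.append(np.flatnonzero((t_s == t) & (e_s == 1)))
        risk_blocks.append(np.flatnonzero(t_s >= t))

    beta = 0.0
    ll, grad, info = _cox_loglik_terms(beta, z_s, event_blocks, risk_blocks, ties)
    n_iter = 0
    converged = False
    BETA_CAP = 30.0  # |beta| on the standardized scale => monotone likelihood
    for n_iter in range(1, max_iter + 1):
        if info <= 0:
            break
        step = grad / info
        new_beta = beta + step
        new_ll, new_grad, new_info = _cox_loglik_terms(
            new_beta, z_s, event_blocks, risk_blocks, ties)
        halvings = 0
        while new_ll < ll and halvings < 20:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_grad, new_info = _cox_loglik_terms(
                new_beta, z_s, event_blocks, risk_blocks, ties)
            halvings += 1
        delta = abs(new_beta - beta)
        beta, ll, grad, info = new_beta, new_ll, new_grad, new_info
        if abs(beta) > BETA_CAP:
            break
        if delta < tol:
            converged = True
            break

    if not converged or abs(beta) > BETA_CAP or info <= 0:
        return CoxResult(beta=np.nan, se=np.nan, p_value=np.nan,
                         converged=False, n_iter=n_iter, log_likelihood=ll)
    se_z = 1.0 / np.sqrt(info)
    beta_x = beta / sd
    se_x = se_z / sd
    pval = float(2 * stats.norm.sf(abs(beta / se_z)))
    return CoxResult(beta=float(beta_x), se=float(se_x), p_value=pval,
                     converged=True, n_iter=n_iter, log_likelihood=float(ll))


# ---------------------------------------------------------------------------
# multiple testing / scans / ROC
# ---------------------------------------------------------------------------

def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with enforced monotonicity."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class ScanResult:
    table: pd.DataFrame  # gene, position, p, q, significant, skipped
    threshold: float

    @property
    def significant_genes(self):
        t = self.table
        return set(t.loc[t["significant"].fillna(False), "gene"])


def chromosome_scan(cnv: pd.DataFrame, clinical: pd.DataFrame, genes,
                    positions=None, fdr_threshold: float = 0.15,
                    ties: str = "efron") -> ScanResult:
    """Per-gene Cox scan of genetic loss (state <= -1) vs the rest.

    ``cnv`` is samples x genes; ``clinical`` must carry 'time' and 'event'
    aligned on the same sample index.  Genes with no loss carrier (or all
    carriers) are skipped and get missing p/q.
    """
    genes = list(genes)
    clinical = clinical.loc[cnv.index]
    times = clinical["time"].to_numpy(dtype=float)
    events = clinical["event"].to_numpy(dtype=int)
    if positions is None:
        positions = list(range(len(genes)))
    rows = []
    for gene, pos in zip(genes, positions):
        state = cnv[gene].to_numpy(dtype=int)
        loss = (state <= -1).astype(float)
        if loss.sum() == 0 or loss.sum() == len(loss):
            rows.append((gene, pos, np.nan, True, np.nan))
            continue
        res = cox_univariate(times, events, loss, ties=ties)
        if not res.converged:
            rows.append((gene, pos, np.nan, True, np.nan))
        else:
            rows.append((gene, pos, res.p_value, False, res.beta))
    table = pd.DataFrame(rows, columns=["gene", "position", "p", "skipped", "beta"])
    tested = ~table["skipped"]
    q = np.full(len(table), np.nan)
    if tested.any():
        q[tested.to_numpy()] = bh_fdr(table.loc[tested, "p"].to_numpy())
    table["q"] = q
    table["significant"] = pd.array(
        [bool(qi < fdr_threshold) if np.isfinite(qi) else None for qi in q],
        dtype="boolean",
    )
    return ScanResult(table=table, threshold=fdr_threshold)


def roc_auc(marker, outcome) -> float:
    """Rank-based (Mann-Whitney) AUC with half credit for ties."""
    marker = np.asarray(marker, dtype=float)
    outcome = np.asarray(outcome, dtype=int)
    if not np.all(np.isin(outcome, (0, 1))):
        raise ValueError("outcome must be binary 0/1")
    n1 = outcome.sum()
    n0 = len(outcome) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome classes must be present")
    ranks = stats.rankdata(marker)
    r1 = ranks[outcome == 1].sum()
    return float((r1 - n1 * (n1 + 1) / 2) / (n1 * n0))
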