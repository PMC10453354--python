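"""Diagnostic accuracy of cognitive screening tools against the NTB gold standard.

Per cohort and sex, screening scores are cross-tabulated against the
neuropsychological (NTB) PSCI verdict using the standard cutoffs
(MMSE < 25, MoCA < 26 screen positive).  Sensitivities and
specificities are pooled with random-effects meta-analysis in which the
within-study variance is modeled as binomial:

    x_i ~ Binomial(n_i, invlogit(mu + u_i)),   u_i ~ Normal(0, tau^2)

fitted by maximum marginal likelihood with adaptive Gauss-Hermite
quadrature.  When an ROC plot of the study points shows a threshold
effect (sensitivity trading off against specificity across studies),
the bivariate model is used instead: the paired study logits of
sensitivity and specificity share a bivariate normal random effect with
correlation rho, and both margins keep their exact binomial
within-study likelihoods.  Zero cells need no continuity correction
because the binomial likelihood handles them exactly.

Sex differences in a pooled margin are tested by meta-regression: a
fixed sex effect on the pooled logit with independent study random
effects per cohort-sex arm and a shared between-study SD.  The Wald
statistic for the sex coefficient is referred to a t distribution with
(number of arms - 2) degrees of freedom, the usual small-sample
reference in random-effects meta-regression, because the normal
reference is anticonservative with a handful of studies.  The
construction of this test is a modelling choice of this package.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, special, stats

from .config import MMSE_CUTOFF, MOCA_CUTOFF
from .errors import ConvergenceError

__all__ = [
    "TwoByTwoTable",
    "MetaEstimate",
    "BivariateFit",
    "SexComparison",
    "build_2x2",
    "build_all_2x2",
    "sens_spec",
    "univariate_re_meta",
    "bivariate_re_meta",
    "threshold_effect_check",
    "compare_sex_accuracy",
    "forest_data",
    "clopper_pearson",
]

logger = logging.getLogger(__name__)

_TAU_FLOOR = 1e-6  # below this the random effect is numerically degenerate


# ---------------------------------------------------------------------------
# 2x2 tables
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class TwoByTwoTable:
    """Screening test vs gold standard counts for one cohort-sex stratum."""

    cohort: str
    sex: str
    test: str
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("2x2 cell counts must be nonnegative")

    @property
    def n_diseased(self) -> int:
        return self.tp + self.fn

    @property
    def n_nondiseased(self) -> int:
        return self.fp + self.tn


def build_2x2(records: pd.DataFrame, test: str) -> TwoByTwoTable:
    """Cross-tabulate one cohort-sex stratum of classified participants.

    ``records`` needs columns ``psci`` ('present'/'absent'; no
    indeterminates), ``cohort``, ``sex`` and the score column (``mmse``
    or ``moca``).  A screen is positive strictly below the standard
    cutoff (MMSE < 25, MoCA < 26).  Rows with a missing score are
    excluded and counted in the log.
    """
    test = test.upper().replace("MOCA", "MoCA")
    col = "mmse" if test == "MMSE" else "moca"
    cutoff = MMSE_CUTOFF if test == "MMSE" else MOCA_CUTOFF
    if records.empty:
        raise ValueError(f"empty stratum for {test}")
    cohorts = records["cohort"].unique()
    sexes = records["sex"].unique()
    if len(cohorts) != 1 or len(sexes) != 1:
        raise ValueError("build_2x2 expects a single cohort-sex stratum")
    if (records["psci"] == "indeterminate").any():
        raise ValueError("indeterminate PSCI verdicts must be excluded upstream")
    usable = records[records[col].notna()]
    n_missing = len(records) - len(usable)
    if n_missing:
        logger.info("%s %s/%s: %d records without %s score excluded",
                    test, cohorts[0], sexes[0], n_missing, test)
    if usable.empty:
        raise ValueError(f"no usable {test} scores in stratum "
                         f"{cohorts[0]}/{sexes[0]}")
    positive = usable[col] < cutoff
    disease = usable["psci"] == "present"
    return TwoByTwoTable(
        cohort=str(cohorts[0]), sex=str(sexes[0]), test=test,
        tp=int((positive & disease).sum()),
        fp=int((positive & ~disease).sum()),
        fn=int((~positive & disease).sum()),
        tn=int((~positive & ~disease).sum()),
    )


def build_all_2x2(records: pd.DataFrame, test: str) -> list[TwoByTwoTable]:
    """One 2x2 table per cohort-sex stratum with any usable score."""
    col = "mmse" if test.upper() == "MMSE" else "moca"
    tables = []
    for (cohort, sex), sub in records.groupby(["cohort", "sex"], observed=True):
        if sub[col].notna().any():
            tables.append(build_2x2(sub, test))
    return tables


def sens_spec(t: TwoByTwoTable) -> tuple[float, float]:
    """(sensitivity, specificity); NaN marks an undefined margin (zero denominator)."""
    sens = t.tp / t.n_diseased if t.n_diseased > 0 else float("nan")
    spec = t.tn / t.n_nondiseased if t.n_nondiseased > 0 else float("nan")
    return sens, spec


# ---------------------------------------------------------------------------
# Adaptive Gauss-Hermite machinery
# ---------------------------------------------------------------------------

def _binom_logpmf(x, n, eta):
    """log Binomial(x | n, invlogit(eta)) with the constant included."""
    return (special.gammaln(n + 1) - special.gammaln(x + 1)
            - special.gammaln(n - x + 1)
            + x * eta - n * np.logaddexp(0.0, eta))


def _agq_study_loglik(x, n, offset, tau, nodes, weights):
    """Vector of per-study log marginal likelihoods, adaptive 1-D quadrature.

    Integrates Binomial(x_i | n_i, invlogit(offset_i + u)) * N(u; 0, tau^2)
    over u for every study at once.  ``offset`` carries mu (plus any
    fixed covariate effect).  For tau below the floor the integral
    collapses to the binomial at u = 0.
    """
    x = np.asarray(x, float)
    n = np.asarray(n, float)
    offset = np.broadcast_to(np.asarray(offset, float), x.shape).copy()
    if tau < _TAU_FLOOR:
        return _binom_logpmf(x, n, offset)
    inv_t2 = 1.0 / tau**2
    # Newton for the mode of h(u) = log f(u) - u^2/(2 tau^2) per study
    u = np.zeros_like(x)
    for _ in range(50):
        p = special.expit(offset + u)
        grad = x - n * p - u * inv_t2
        hess = -n * p * (1 - p) - inv_t2
        step = grad / hess
        u -= step
        if np.max(np.abs(step)) < 1e-10:
            break
    p = special.expit(offset + u)
    sigma = 1.0 / np.sqrt(n * p * (1 - p) + inv_t2)
    # u_j = mode + sqrt(2) sigma z_j;  integral = sqrt(2) sigma sum w_j e^{z^2} e^{h}
    uj = u[:, None] + np.sqrt(2.0) * sigma[:, None] * nodes[None, :]
    h = (_binom_logpmf(x[:, None], n[:, None], offset[:, None] + uj)
         - 0.5 * uj**2 * inv_t2 - np.log(tau) - 0.5 * np.log(2 * np.pi))
    logint = special.logsumexp(
        h + nodes[None, :] ** 2 + np.log(weights)[None, :], axis=1)
    return logint + 0.5 * np.log(2.0) + np.log(sigma)


def _fd_hessian(fun, theta, eps=1e-5):
    """Central finite-difference Hessian of a scalar function."""
    theta = np.asarray(theta, float)
    k = len(theta)
    H = np.empty((k, k))
    f0 = fun(theta)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = eps
            ej = np.zeros(k); ej[j] = eps
            if i == j:
                H[i, i] = (fun(theta + ei) - 2 * f0 + fun(theta - ei)) / eps**2
            else:
                H[i, j] = H[j, i] = (
                    fun(theta + ei + ej) - fun(theta + ei - ej)
                    - fun(theta - ei + ej) + fun(theta - ei - ej)
                ) / (4 * eps**2)
    return H


def _empirical_logits(x, n):
    return np.log((x + 0.5) / (n - x + 0.5))


def _minimize_polished(fun, theta0, bounds, max_iter=500):
    """L-BFGS-B followed by a Nelder-Mead polish.

    The marginal likelihood is smooth but its finite-difference gradient
    is noisy near machine precision, which can end the L-BFGS-B line
    search abnormally at an essentially converged point; the
    simplex polish settles the optimum without gradients and clips to
    the bounds.
    """
    res = optimize.minimize(fun, theta0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": max_iter})
    start = res.x if np.isfinite(res.fun) else theta0
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    def clipped(theta):
        return fun(np.clip(theta, lo, hi))

    polish = optimize.minimize(
        clipped, start, method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    if polish.fun <= res.fun:
        polish.x = np.clip(polish.x, lo, hi)
        best = polish
    else:
        best = res
    if not (res.success or polish.success):
        raise ConvergenceError(
            f"fit failed: {res.message}; polish: {polish.message}")
    return best


# ---------------------------------------------------------------------------
# Univariate binomial-normal meta-analysis
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MetaEstimate:
    """Pooled proportion from the univariate binomial-normal model."""

    mu: float
    tau: float
    pooled: float
    ci_low: float
    ci_high: float
    k_studies: int
    log_likelihood: float
    se_mu: float
    tau_at_boundary: bool


def univariate_re_meta(
    events, totals, n_nodes: int = 21, max_iter: int = 500
) -> MetaEstimate:
    """Pool per-study proportions under the binomial-normal model.

    Maximum marginal likelihood over (mu, tau) with adaptive
    Gauss-Hermite quadrature (``n_nodes`` nodes, default 21); the CI is
    Wald on mu, back-transformed.  A single study reproduces its
    observed proportion exactly with tau = 0.
    """
    x = np.asarray(events, float)
    n = np.asarray(totals, float)
    if len(x) != len(n) or len(x) < 1:
        raise ValueError("events and totals must be equal-length, nonempty")
    if (n <= 0).any() or (x < 0).any() or (x > n).any():
        raise ValueError("need 0 <= events <= totals and totals > 0")
    k = len(x)
    nodes, weights = hermgauss(n_nodes)

    if k == 1:
        p_hat = float(x[0] / n[0])
        mu = float(_empirical_logits(x, n)[0]) if p_hat in (0.0, 1.0) \
            else float(special.logit(p_hat))
        se = float(1.0 / np.sqrt(n[0] * max(p_hat * (1 - p_hat), 1e-12)))
        lo, hi = special.expit(mu - 1.959964 * se), special.expit(mu + 1.959964 * se)
        ll = float(_binom_logpmf(x, n, mu)[0])
        return MetaEstimate(mu=mu, tau=0.0, pooled=p_hat, ci_low=float(lo),
                            ci_high=float(hi), k_studies=1, log_likelihood=ll,
                            se_mu=se, tau_at_boundary=True)

    def negll(theta):
        mu, tau = theta
        return -float(np.sum(_agq_study_loglik(x, n, mu, tau, nodes, weights)))

    el = _empirical_logits(x, n)
    theta0 = np.array([el.mean(), max(el.std(ddof=1), 0.01)])
    res = _minimize_polished(negll, theta0,
                             bounds=[(-20.0, 20.0), (0.0, 10.0)],
                             max_iter=max_iter)
    mu_hat, tau_hat = float(res.x[0]), float(res.x[1])
    boundary = tau_hat < 1e-4

    if boundary:
        # profile out tau at the boundary; 1-D curvature in mu
        def neg_mu(m):
            return negll(np.array([float(m), 0.0]))
        eps = 1e-5
        d2 = (neg_mu(mu_hat + eps) - 2 * neg_mu(mu_hat) + neg_mu(mu_hat - eps)) / eps**2
        se_mu = float(1.0 / np.sqrt(max(d2, 1e-12)))
    else:
        H = _fd_hessian(negll, res.x)
        cov = np.linalg.inv(H)
        se_mu = float(np.sqrt(max(cov[0, 0], 0.0)))
    lo = float(special.expit(mu_hat - 1.959964 * se_mu))
    hi = float(special.expit(mu_hat + 1.959964 * se_mu))
    return MetaEstimate(mu=mu_hat, tau=(0.0 if boundary else tau_hat),
                        pooled=float(special.expit(mu_hat)), ci_low=lo,
                        ci_high=hi, k_studies=k, log_likelihood=-float(res.fun),
                        se_mu=se_mu, tau_at_boundary=boundary)


# ---------------------------------------------------------------------------
# Bivariate (Reitsma-type) model
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class BivariateFit:
    """Joint pooled sensitivity/specificity with correlated random effects."""

    mu_sens: float
    mu_spec: float
    tau_sens: float
    tau_spec: float
    rho: float
    pooled_sens: float
    pooled_spec: float
    cov_params: np.ndarray | None
    log_likelihood: float
    converged: bool


def _bivariate_negll(theta, tp, nd, tn, nn, nodes, weights):
    mu_s, mu_p, t_s, t_p, rho = theta
    t_s = max(t_s, _TAU_FLOOR)
    t_p = max(t_p, _TAU_FLOOR)
    cov = np.array([[t_s**2, rho * t_s * t_p],
                    [rho * t_s * t_p, t_p**2]])
    try:
        prec = np.linalg.inv(cov)
        _, logdet = np.linalg.slogdet(cov)
    except np.linalg.LinAlgError:
        return 1e10
    total = 0.0
    nn_nodes = len(nodes)
    Z1, Z2 = np.meshgrid(nodes, nodes, indexing="ij")
    W = np.outer(weights, weights)
    zsq = Z1**2 + Z2**2
    for i in range(len(tp)):
        # per-study 2-D Laplace mode of log f_s + log f_p + log N(u; 0, cov)
        u = np.zeros(2)
        for _ in range(60):
            ps = special.expit(mu_s + u[0])
            pp = special.expit(mu_p + u[1])
            grad = np.array([tp[i] - nd[i] * ps, tn[i] - nn[i] * pp]) - prec @ u
            hess = -np.diag([nd[i] * ps * (1 - ps), nn[i] * pp * (1 - pp)]) - prec
            step = np.linalg.solve(hess, grad)
            u -= step
            if np.abs(step).max() < 1e-10:
                break
        ps = special.expit(mu_s + u[0])
        pp = special.expit(mu_p + u[1])
        H = np.diag([nd[i] * ps * (1 - ps), nn[i] * pp * (1 - pp)]) + prec
        try:
            L = np.linalg.cholesky(np.linalg.inv(H))
        except np.linalg.LinAlgError:
            return 1e10
        # u = mode + sqrt(2) L z over the node grid
        U1 = u[0] + np.sqrt(2.0) * (L[0, 0] * Z1 + L[0, 1] * Z2)
        U2 = u[1] + np.sqrt(2.0) * (L[1, 0] * Z1 + L[1, 1] * Z2)
        quad = (prec[0, 0] * U1**2 + 2 * prec[0, 1] * U1 * U2 + prec[1, 1] * U2**2)
        h = (_binom_logpmf(tp[i], nd[i], mu_s + U1)
             + _binom_logpmf(tn[i], nn[i], mu_p + U2)
             - 0.5 * quad - 0.5 * logdet - np.log(2 * np.pi))
        logint = special.logsumexp(h + zsq + np.log(W))
        total += logint + np.log(2.0) + np.log(L[0, 0] * L[1, 1])
    return -total


def bivariate_re_meta(
    tables: list[TwoByTwoTable], n_nodes: int = 15, max_iter: int = 500
) -> BivariateFit:
    """Fit the bivariate random-effects model to per-study 2x2 tables.

    Joint maximum likelihood for (mu_sens, mu_spec, tau_sens, tau_spec,
    rho) with exact binomial within-study likelihoods and 2-D adaptive
    Gauss-Hermite quadrature (``n_nodes`` per dimension).  Requires at
    least three studies with both margins nonzero; with fewer, use
    :func:`univariate_re_meta` per margin.
    """
    if len(tables) < 3:
        raise ValueError(
            "bivariate model needs >= 3 studies; use univariate_re_meta")
    tp = np.array([t.tp for t in tables], float)
    nd = np.array([t.n_diseased for t in tables], float)
    tn = np.array([t.tn for t in tables], float)
    nn = np.array([t.n_nondiseased for t in tables], float)
    if (nd == 0).any() or (nn == 0).any():
        raise ValueError("every study needs diseased and non-diseased subjects")
    nodes, weights = hermgauss(n_nodes)

    el_s = _empirical_logits(tp, nd)
    el_p = _empirical_logits(tn, nn)
    theta0 = np.array([el_s.mean(), el_p.mean(),
                       max(el_s.std(ddof=1), 0.05), max(el_p.std(ddof=1), 0.05),
                       0.0])
    args = (tp, nd, tn, nn, nodes, weights)
    res = _minimize_polished(
        lambda th: _bivariate_negll(th, *args), theta0,
        bounds=[(-15, 15), (-15, 15), (0.0, 5.0), (0.0, 5.0), (-0.99, 0.99)],
        max_iter=max_iter)
    mu_s, mu_p, t_s, t_p, rho = (float(v) for v in res.x)
    if t_s < 1e-4 or t_p < 1e-4:
        rho = 0.0 if min(t_s, t_p) < 1e-4 else rho  # unidentified at the boundary
    cov_params = None
    try:
        H = _fd_hessian(lambda th: _bivariate_negll(th, *args), res.x, eps=1e-4)
        cov_params = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        pass
    return BivariateFit(
        mu_sens=mu_s, mu_spec=mu_p,
        tau_sens=(0.0 if t_s < 1e-4 else t_s),
        tau_spec=(0.0 if t_p < 1e-4 else t_p),
        rho=rho,
        pooled_sens=float(special.expit(mu_s)),
        pooled_spec=float(special.expit(mu_p)),
        cov_params=cov_params,
        log_likelihood=-float(res.fun),
        converged=bool(res.success),
    )


# ---------------------------------------------------------------------------
# Threshold effect, sex comparison, forest data
# ---------------------------------------------------------------------------

def threshold_effect_check(
    points: pd.DataFrame, criterion: float = 0.5
) -> tuple[str, float, pd.DataFrame]:
    """Assess a between-study threshold effect from ROC-space points.

    ``points`` needs columns ``sens`` and either ``spec`` or ``fpr``.
    The statistic is the Spearman rank correlation between
    logit(sensitivity) and logit(false-positive rate) across studies
    (midranks under ties); a correlation at or above ``criterion``
    (default 0.5) is read as evidence of a threshold effect, which
    motivates the bivariate model.  Returns (verdict, correlation,
    plot-ready coordinates).
    """
    df = points.copy()
    if "fpr" not in df.columns:
        df["fpr"] = 1.0 - df["spec"]
    if len(df) < 3:
        raise ValueError("threshold check needs >= 3 points")
    clip = lambda p: np.clip(p, 1e-6, 1 - 1e-6)  # noqa: E731
    ls = special.logit(clip(df["sens"].to_numpy(float)))
    lf = special.logit(clip(df["fpr"].to_numpy(float)))
    if np.ptp(ls) == 0 or np.ptp(lf) == 0:
        rho = 0.0
        logger.info("threshold check: degenerate ranks, correlation set to 0")
    else:
        rho = float(stats.spearmanr(ls, lf).statistic)
    verdict = "evidence" if rho >= criterion else "little_evidence"
    return verdict, rho, df[["sens", "fpr"]].reset_index(drop=True)


@dataclasses.dataclass
class SexComparison:
    """Meta-regression comparison of one accuracy margin between sexes."""

    margin: str
    pooled_women: float
    pooled_men: float
    beta_sex: float
    se_beta: float
    p_value: float
    tau: float
    df: int


def compare_sex_accuracy(
    tables_women: list[TwoByTwoTable],
    tables_men: list[TwoByTwoTable],
    margin: str = "sens",
    n_nodes: int = 21,
) -> SexComparison:
    """Test whether pooled sensitivity (or specificity) differs by sex.

    Joint binomial-normal model over all cohort-sex arms with a fixed
    sex effect on the pooled logit and a shared between-study SD;
    two-sided p for the sex coefficient from the Wald statistic against
    a t reference with (arms - 2) degrees of freedom.
    """
    if margin not in ("sens", "spec"):
        raise ValueError("margin must be 'sens' or 'spec'")
    if not tables_women or not tables_men:
        raise ValueError("need at least one study per sex")

    def arm(t: TwoByTwoTable) -> tuple[float, float]:
        return (t.tp, t.n_diseased) if margin == "sens" else (t.tn, t.n_nondiseased)

    xw, nw = zip(*(arm(t) for t in tables_women))
    xm, nm = zip(*(arm(t) for t in tables_men))
    x = np.array(xw + xm, float)
    n = np.array(nw + nm, float)
    man = np.array([0.0] * len(xw) + [1.0] * len(xm))
    if (n == 0).any():
        raise ValueError("a stratum has a zero denominator for this margin")
    nodes, weights = hermgauss(n_nodes)

    def negll(theta):
        mu, beta, tau = theta
        return -float(np.sum(
            _agq_study_loglik(x, n, mu + beta * man, tau, nodes, weights)))

    el = _empirical_logits(x, n)
    theta0 = np.array([el[man == 0].mean(),
                       el[man == 1].mean() - el[man == 0].mean(),
                       max(np.std(el, ddof=1), 0.01)])
    res = _minimize_polished(
        negll, theta0, bounds=[(-20, 20), (-20, 20), (0.0, 10.0)])
    mu, beta, tau = (float(v) for v in res.x)
    if tau < 1e-4:
        def neg2(th):
            return negll(np.array([th[0], th[1], 0.0]))
        H = _fd_hessian(neg2, np.array([mu, beta]))
    else:
        H = _fd_hessian(negll, res.x)
    try:
        cov = np.linalg.inv(H)
        se_beta = float(np.sqrt(max(cov[1, 1], 0.0)))
    except np.linalg.LinAlgError:
        raise ConvergenceError("sex-comparison information matrix singular")
    df = max(len(x) - 2, 1)
    if se_beta == 0.0:
        p = 1.0
    else:
        p = float(2.0 * stats.t.sf(abs(beta) / se_beta, df))
    return SexComparison(
        margin=margin,
        pooled_women=float(special.expit(mu)),
        pooled_men=float(special.expit(mu + beta)),
        beta_sex=beta, se_beta=se_beta, p_value=p,
        tau=(0.0 if tau < 1e-4 else tau),
        df=df,
    )


def clopper_pearson(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval for x/n."""
    if not 0 <= x <= n or n <= 0:
        raise ValueError("need 0 <= x <= n, n > 0")
    alpha = 1.0 - level
    lo = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    hi = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return lo, hi


def forest_data(
    tables: list[TwoByTwoTable], margin: str = "sens"
) -> pd.DataFrame:
    """Plot-ready forest table: per-study exact CIs plus the pooled row.

    Per-study rows carry the observed proportion with its
    Clopper-Pearson 95% interval; the pooled row comes from the
    univariate binomial-normal meta-analysis of the same counts.
    """
    if margin not in ("sens", "spec"):
        raise ValueError("margin must be 'sens' or 'spec'")
    rows = []
    xs, ns = [], []
    for t in tables:
        x, n = (t.tp, t.n_diseased) if margin == "sens" else (t.tn, t.n_nondiseased)
        lo, hi = clopper_pearson(x, n)
        rows.append({"study": f"{t.cohort} ({t.sex})", "events": x, "total": n,
                     "proportion": x / n if n else float("nan"),
                     "ci_low": lo, "ci_high": hi, "pooled": False})
        xs.append(x)
        ns.append(n)
    meta = univariate_re_meta(xs, ns)
    rows.append({"study": "pooled (random effects)", "events": sum(xs),
                 "total": sum(ns), "proportion": meta.pooled,
                 "ci_low": meta.ci_low, "ci_high": meta.ci_high, "pooled": True})
    return pd.DataFrame(rows)
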