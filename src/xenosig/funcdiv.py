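"""Type-I functional divergence between two protein subfamilies.

Type-I divergence means site-specific evolutionary rates have shifted after
the split of two clusters: a site tightly conserved in one family but free to
vary in the other. It is quantified by the coefficient theta in [0, 1] — the
proportion of sites whose rates are independent between clusters rather than
shared.

The model operates on per-site minimum substitution counts (Fitch small
parsimony within each cluster's subtree). Site rates are Gamma(a, b)
distributed; counts are Poisson with mean rate x cluster depth d_k, giving
closed-form Poisson-gamma (negative binomial) marginals:

    P1(x; d) = Gamma(x+a) / (x! Gamma(a)) * d^x b^a / (d+b)^(x+a)

for rate-independent sites, and a shared-rate bivariate marginal

    P0(x1, x2) = Gamma(x1+x2+a) / (x1! x2! Gamma(a))
                 * d1^x1 d2^x2 b^a / (d1+d2+b)^(x1+x2+a)

for non-diverged sites. The likelihood mixes the two with weight theta; the
null theta = 0 is tested by a likelihood-ratio statistic 2*deltaLnL referred
to chi-square with 1 df, and each site receives a posterior probability Q_k
of belonging to the diverged class (reported at the > 0.7 and > 0.95
thresholds).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.special import gammaln

from .io import ClusteredAlignment

MISSING_SITE_FRACTION = 0.5  # mask a site if > this fraction missing in a cluster


@dataclass(frozen=True)
class SiteChangeCounts:
    """Per-site minimum substitution counts for the two clusters.

    ``included`` masks out sites too gappy to count (more than half of a
    cluster missing). ``d1``/``d2`` are the cluster evolutionary depths; with
    the default 1.0 the overall rate scale is absorbed into the gamma scale b.
    """

    x1: np.ndarray
    x2: np.ndarray
    d1: float = 1.0
    d2: float = 1.0
    included: np.ndarray | None = None

    def __post_init__(self) -> None:
        x1 = np.asarray(self.x1, dtype=np.int64)
        x2 = np.asarray(self.x2, dtype=np.int64)
        if x1.shape != x2.shape or x1.ndim != 1:
            raise ValueError("x1 and x2 must be 1-D arrays of equal length")
        if (x1 < 0).any() or (x2 < 0).any():
            raise ValueError("substitution counts must be non-negative")
        if self.d1 <= 0 or self.d2 <= 0:
            raise ValueError("cluster depths must be positive")
        object.__setattr__(self, "x1", x1)
        object.__setattr__(self, "x2", x2)
        inc = (
            np.ones(len(x1), dtype=bool)
            if self.included is None
            else np.asarray(self.included, dtype=bool)
        )
        if inc.shape != x1.shape:
            raise ValueError("included mask length mismatch")
        object.__setattr__(self, "included", inc)

    @property
    def n_sites(self) -> int:
        return len(self.x1)

    def swapped(self) -> "SiteChangeCounts":
        return SiteChangeCounts(
            x1=self.x2, x2=self.x1, d1=self.d2, d2=self.d1, included=self.included
        )


# ---------------------------------------------------------------------------
# Fitch parsimony site counts


def _fitch_fold(child_results):
    """Fold child (state-set, changes) pairs; None state-sets are pruned."""
    live = [(s, c) for s, c in child_results if s is not None]
    dead_changes = sum(c for s, c in child_results if s is None)
    if not live:
        return None, dead_changes
    acc, changes = live[0]
    changes += dead_changes
    for s, c in live[1:]:
        changes += c
        inter = acc & s
        if inter:
            acc = inter
        else:
            acc = acc | s
            changes += 1
    return acc, changes


def _fitch_node(node, states: dict[str, str | None]):
    if node.is_leaf():
        s = states.get(node.taxon.label)
        return ({s}, 0) if s is not None else (None, 0)
    return _fitch_fold([_fitch_node(ch, states) for ch in node.child_nodes()])


def fitch_site_changes(ca: ClusteredAlignment) -> SiteChangeCounts:
    """Minimum substitution counts per site within each cluster's subtree.

    Gapped/unknown residues are treated as missing: the count at a site is
    computed over the induced subtree of the cluster's non-missing leaves
    (a missing leaf constrains nothing). Sites missing in more than half of
    a cluster's members are masked out; a fully missing site counts 0 and is
    masked.
    """
    roots = {}
    sizes = {}
    for k in (1, 2):
        members = ca.cluster_members(k)
        sizes[k] = len(members)
        taxa = [t.taxon for t in ca.tree.leaf_node_iter() if t.taxon.label in members]
        if len(taxa) > 1:
            roots[k] = ca.tree.mrca(taxa=taxa)
        else:
            roots[k] = next(
                n for n in ca.tree.leaf_node_iter() if n.taxon.label == members[0]
            )
    L = ca.n_sites
    counts = {1: np.zeros(L, dtype=np.int64), 2: np.zeros(L, dtype=np.int64)}
    included = np.ones(L, dtype=bool)
    for site in range(L):
        for k in (1, 2):
            states = ca.site_states(k, site)
            n_missing = sum(1 for v in states.values() if v is None)
            if n_missing > MISSING_SITE_FRACTION * sizes[k]:
                included[site] = False
            _, changes = _fitch_node(roots[k], states)
            counts[k][site] = changes
    masked = int((~included).sum())
    if masked:
        warnings.warn(f"{masked} gappy site(s) masked out of {L}", stacklevel=2)
    return SiteChangeCounts(x1=counts[1], x2=counts[2], included=included)


# ---------------------------------------------------------------------------
# Likelihood


def _log_p1(x: np.ndarray, d: float, a: float, b: float) -> np.ndarray:
    """Log Poisson-gamma marginal (negative binomial), mean a*d/b."""
    return (
        gammaln(x + a)
        - gammaln(x + 1)
        - gammaln(a)
        + x * np.log(d)
        + a * np.log(b)
        - (x + a) * np.log(d + b)
    )


def _log_p0(
    x1: np.ndarray, x2: np.ndarray, d1: float, d2: float, a: float, b: float
) -> np.ndarray:
    """Log shared-rate bivariate Poisson-gamma marginal."""
    return (
        gammaln(x1 + x2 + a)
        - gammaln(x1 + 1)
        - gammaln(x2 + 1)
        - gammaln(a)
        + x1 * np.log(d1)
        + x2 * np.log(d2)
        + a * np.log(b)
        - (x1 + x2 + a) * np.log(d1 + d2 + b)
    )


def type1_loglik(
    counts: SiteChangeCounts, theta: float, a: float, b: float
) -> float:
    """Mixture log-likelihood over the included sites.

    lnL = sum_k log[(1-theta) P0(x1k, x2k) + theta P1(x1k) P1(x2k)].
    """
    if not np.isfinite([theta, a, b]).all() or a <= 0 or b <= 0:
        raise ValueError("parameters must be finite with a, b > 0")
    if not 0.0 <= theta <= 1.0:
        raise ValueError("theta must lie in [0, 1]")
    x1 = counts.x1[counts.included]
    x2 = counts.x2[counts.included]
    lp0 = _log_p0(x1, x2, counts.d1, counts.d2, a, b)
    lp1 = _log_p1(x1, counts.d1, a, b) + _log_p1(x2, counts.d2, a, b)
    if theta == 0.0:
        return float(lp0.sum())
    if theta == 1.0:
        return float(lp1.sum())
    site = np.logaddexp(np.log1p(-theta) + lp0, np.log(theta) + lp1)
    return float(site.sum())


@dataclass(frozen=True)
class FuncDivModel:
    theta: float
    a: float
    b: float
    lnl: float


@dataclass(frozen=True)
class FuncDivResult:
    model: FuncDivModel
    null_model: FuncDivModel
    theta_se: float
    lrt: float
    p: float
    qk: np.ndarray  # per original site; NaN where masked
    critical_sites_070: list[int]
    critical_sites_095: list[int]
    converged: bool


_THETA_STARTS = (0.1, 0.5, 0.9)
_A_STARTS = (0.5, 1.0, 2.0)
_LOG_BOUND = (np.log(1e-4), np.log(1e4))


def _fit(counts: SiteChangeCounts, theta_fixed: float | None, starts) -> tuple:
    def nll(params: np.ndarray) -> float:
        if theta_fixed is None:
            theta, loga, logb = params
        else:
            theta = theta_fixed
            loga, logb = params
        try:
            return -type1_loglik(counts, float(theta), float(np.exp(loga)), float(np.exp(logb)))
        except (ValueError, FloatingPointError):
            return 1e12

    bounds = ([(0.0, 1.0)] if theta_fixed is None else []) + [_LOG_BOUND, _LOG_BOUND]
    best = None
    ok = False
    for x0 in starts:
        res = optimize.minimize(nll, np.asarray(x0), method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
            ok = bool(res.success)
    return best, ok


def estimate_type1(
    counts: SiteChangeCounts,
    boundary_correction: bool = False,
    q_thresholds: tuple[float, float] = (0.7, 0.95),
) -> FuncDivResult:
    """Maximum-likelihood theta, the LRT against theta = 0, and site posteriors.

    Optimization is a bounded quasi-Newton over (theta, log a, log b) from a
    small deterministic multi-start grid; the null refits (a, b) with theta
    fixed at 0. The LRT is clipped at zero (the null lies on the boundary of
    the alternative) and referred to chi-square with 1 df; with
    ``boundary_correction`` the 50:50 chi0/chi1 mixture is used instead.
    theta's standard error comes from the observed-information curvature at
    the optimum (NaN at the boundary).
    """
    n_inc = int(counts.included.sum())
    if n_inc == 0 or (counts.x1[counts.included].max(initial=0) == 0
                      and counts.x2[counts.included].max(initial=0) == 0):
        raise ValueError("no usable substitution counts (all zero or masked)")
    if n_inc < 20:
        warnings.warn(
            f"only {n_inc} usable sites; theta estimates will be unstable",
            stacklevel=2,
        )
    mean_total = float(counts.x1[counts.included].mean()
                       + counts.x2[counts.included].mean())
    d_sum = counts.d1 + counts.d2

    def b0(a: float) -> float:
        return max(a * d_sum / max(mean_total, 1e-6), 1e-3)

    null_starts = [np.array([np.log(a), np.log(b0(a))]) for a in _A_STARTS]
    null_res, null_ok = _fit(counts, 0.0, null_starts)
    lnl0 = -null_res.fun
    a0, b0_ = np.exp(null_res.x)
    null_model = FuncDivModel(theta=0.0, a=float(a0), b=float(b0_), lnl=float(lnl0))

    alt_starts = [
        np.array([t, np.log(a), np.log(b0(a))])
        for t in _THETA_STARTS
        for a in _A_STARTS
    ]
    # also start from the null optimum with a small theta
    alt_starts.append(np.array([0.05, null_res.x[0], null_res.x[1]]))
    alt_res, alt_ok = _fit(counts, None, alt_starts)
    lnl1 = -alt_res.fun
    theta, a, b = float(alt_res.x[0]), float(np.exp(alt_res.x[1])), float(np.exp(alt_res.x[2]))
    if lnl1 < lnl0:  # numerical: alternative can never fit worse
        lnl1 = lnl0
        theta, a, b = 0.0, null_model.a, null_model.b
    model = FuncDivModel(theta=theta, a=a, b=b, lnl=float(lnl1))

    lrt = max(2.0 * (lnl1 - lnl0), 0.0)
    if boundary_correction:
        p = 1.0 if lrt == 0.0 else float(0.5 * stats.chi2.sf(lrt, 1))
    else:
        p = float(stats.chi2.sf(lrt, 1))

    theta_se = _theta_se(counts, theta, a, b)

    qk = np.full(counts.n_sites, np.nan)
    if theta >= 1.0 - 1e-12:
        qk[counts.included] = 1.0
    elif theta > 0.0:
        x1, x2 = counts.x1, counts.x2
        lp0 = _log_p0(x1, x2, counts.d1, counts.d2, a, b)
        lp1 = _log_p1(x1, counts.d1, a, b) + _log_p1(x2, counts.d2, a, b)
        log_num = np.log(theta) + lp1
        log_den = np.logaddexp(np.log1p(-theta) + lp0, log_num)
        q = np.exp(log_num - log_den)
        qk[counts.included] = q[counts.included]
    else:
        qk[counts.included] = 0.0

    crit70, crit95 = critical_sites(qk, q_thresholds)
    return FuncDivResult(
        model=model,
        null_model=null_model,
        theta_se=theta_se,
        lrt=lrt,
        p=p,
        qk=qk,
        critical_sites_070=crit70,
        critical_sites_095=crit95,
        converged=null_ok and alt_ok,
    )


def _theta_se(counts: SiteChangeCounts, theta: float, a: float, b: float) -> float:
    """SE of theta from the inverse observed information (3x3 numeric Hessian)."""
    if theta <= 1e-6 or theta >= 1 - 1e-6:
        return float("nan")

    def ll(p: np.ndarray) -> float:
        t = min(max(p[0], 1e-9), 1 - 1e-9)
        return type1_loglik(counts, t, float(np.exp(p[1])), float(np.exp(p[2])))

    x = np.array([theta, np.log(a), np.log(b)])
    h = np.array([1e-4, 1e-4, 1e-4])
    H = np.zeros((3, 3))
    for i in range(3):
        for j in range(i, 3):
            ei = np.zeros(3)
            ej = np.zeros(3)
            ei[i] = h[i]
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                ll(x + ei + ej) - ll(x + ei - ej) - ll(x - ei + ej) + ll(x - ei - ej)
            ) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        return float("nan")
    var = cov[0, 0]
    return float(np.sqrt(var)) if var > 0 else float("nan")


def critical_sites(
    qk: np.ndarray, thresholds: tuple[float, float] = (0.7, 0.95)
) -> tuple[list[int], list[int]]:
    """1-based alignment columns with Q_k strictly above each threshold."""
    lo, hi = sorted(thresholds)
    with np.errstate(invalid="ignore"):
        crit_lo = [int(i) + 1 for i in np.nonzero(qk > lo)[0]]
        crit_hi = [int(i) + 1 for i in np.nonzero(qk > hi)[0]]
    return crit_lo, crit_hi


def site_posteriors(
    result: FuncDivResult, thresholds: tuple[float, float] = (0.7, 0.95)
) -> tuple[list[int], list[int]]:
    """Critical-site lists of a fitted result at arbitrary thresholds."""
    return critical_sites(result.qk, thresholds)
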