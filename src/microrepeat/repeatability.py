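"""Repeatability (reproducibility) estimation: the package's core statistic.

For replicated measurements of hosts, repeatability is the fraction of total
variance attributable to among-host differences,

    r = s2_A / (s2_A + s2_W),

with s2_A the among-group (among-fish, biological) and s2_W the within-group
(within-fish, technical) variance component. Components come from one-way
ANOVA mean squares (moment estimator, Lessels & Boag style, with the n0
correction for unequal group sizes), from an ML/REML random-effects fit, or
— for community dissimilarities — from the nested nonparametric-MANOVA
sums-of-squares partition of a distance matrix. Uncertainty is by
bootstrap over whole hosts. Per-taxon repeatability of counts uses an
overdispersed Poisson (Poisson-lognormal) mixed model with an
observation-level random effect, and the dependence of per-taxon
repeatability on mean abundance is summarised by a three-parameter logistic
curve fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .diversity import DistanceMatrix

__all__ = [
    "VarianceDecomposition",
    "RepeatabilityEstimate",
    "anova_variance_components",
    "reml_variance_components",
    "repeatability_from_components",
    "distance_variance_components",
    "bootstrap_repeatability",
    "RepeatabilityModel",
    "RepeatabilityResults",
    "PoissonLognormalRepeatability",
    "PoissonLognormalResults",
    "per_taxon_repeatability",
    "LogisticCurveModel",
    "LogisticCurveFit",
    "abundance_reproducibility_curve",
]


@dataclass
class VarianceDecomposition:
    """One-way variance decomposition into among/within components."""

    s2_A: float
    s2_W: float
    MS_A: float
    MS_W: float
    n0: float
    n_groups: int
    n_obs: int

    @property
    def r(self) -> float:
        return repeatability_from_components(self.s2_A, self.s2_W)


@dataclass
class RepeatabilityEstimate:
    """Point estimate of r with a bootstrap percentile CI."""

    decomposition: VarianceDecomposition | None
    r: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int | None
    n_dropped_boot: int = 0
    diagnostics: dict | None = None


# --------------------------------------------------------------------------
# moment / likelihood estimators
# --------------------------------------------------------------------------

def _group_stats(values, groups):
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels, inv = np.unique(groups, return_inverse=True)
    k = len(levels)
    n_g = np.bincount(inv, minlength=k).astype(float)
    sum_g = np.bincount(inv, weights=values, minlength=k)
    sumsq_g = np.bincount(inv, weights=values**2, minlength=k)
    return levels, inv, n_g, sum_g, sumsq_g


def anova_variance_components(values, groups) -> VarianceDecomposition:
    """Moment estimator of (s2_A, s2_W) from one-way ANOVA mean squares.

    n0 = (N - sum(n_i^2)/N) / (k - 1) handles unequal group sizes;
    s2_W = MS_W, s2_A = max(0, (MS_A - MS_W) / n0). Negative among-group
    moment estimates are truncated at zero so r stays in [0, 1].
    """
    levels, _, n_g, sum_g, sumsq_g = _group_stats(values, groups)
    k = len(levels)
    N = n_g.sum()
    if k < 2:
        raise ValueError("need at least 2 groups")
    if N - k < 1:
        raise ValueError("within-group variance undefined: all groups are singletons")
    ss_within = float((sumsq_g - sum_g**2 / n_g).sum())
    grand = sum_g.sum()
    ss_among = float((sum_g**2 / n_g).sum() - grand**2 / N)
    ms_a = ss_among / (k - 1)
    ms_w = ss_within / (N - k)
    n0 = (N - (n_g**2).sum() / N) / (k - 1)
    s2_w = ms_w
    s2_a = max(0.0, (ms_a - ms_w) / n0)
    return VarianceDecomposition(s2_a, s2_w, ms_a, ms_w, n0, k, int(N))


def reml_variance_components(values, groups, reml: bool = True) -> VarianceDecomposition:
    """(RE)ML variance components of the one-way random-effects model.

    Profile likelihood in the ratio gamma = s2_A / s2_W, maximised on a log
    grid then polished; closed-form s2_W given gamma. For balanced groups the
    REML solution coincides with the ANOVA moment estimator (when interior).
    Provided alongside the moment estimator because mixed-model fitters are
    the common route in practice and the two differ slightly off balance.
    """
    values = np.asarray(values, dtype=float)
    levels, inv, n_g, sum_g, _ = _group_stats(values, groups)
    k = len(levels)
    N = n_g.sum()
    if k < 2 or N - k < 1:
        raise ValueError("insufficient replication")

    ybar_g = sum_g / n_g
    resid_w = values - ybar_g[inv]
    ssw = float(resid_w @ resid_w)

    def neg_ll(log_gamma):
        g = np.exp(log_gamma)
        w = n_g / (1.0 + g * n_g)       # effective weights of group means
        mu = (w * ybar_g).sum() / w.sum()
        q = ssw + float((w * (ybar_g - mu) ** 2).sum())
        dof = (N - 1) if reml else N
        s2w = q / dof
        ll = -0.5 * (dof * np.log(s2w) + np.log(1.0 + g * n_g).sum() + dof)
        if reml:
            ll -= 0.5 * np.log(w.sum())
        return -ll

    grid = np.linspace(-14, 10, 121)
    best = grid[np.argmin([neg_ll(lg) for lg in grid])]
    res = optimize.minimize_scalar(neg_ll, bracket=(best - 0.5, best, best + 0.5)
                                   if best > grid[0] else None,
                                   bounds=(-16, 12), method="bounded")
    g = float(np.exp(res.x))
    w = n_g / (1.0 + g * n_g)
    mu = (w * ybar_g).sum() / w.sum()
    q = ssw + float((w * (ybar_g - mu) ** 2).sum())
    dof = (N - 1) if reml else N
    s2w = q / dof
    s2a = g * s2w
    if g < 1e-7:
        s2a = 0.0
    n0 = (N - (n_g**2).sum() / N) / (k - 1)
    return VarianceDecomposition(float(s2a), float(s2w), np.nan, np.nan,
                                 float(n0), k, int(N))


def repeatability_from_components(s2_A: float, s2_W: float) -> float:
    """r = s2_A / (s2_A + s2_W), in [0, 1]."""
    if s2_A < 0 or s2_W < 0:
        raise ValueError("variance components must be >= 0")
    total = s2_A + s2_W
    if total == 0:
        raise ValueError("repeatability undefined: both components zero")
    return float(s2_A / total)


def distance_variance_components(D: DistanceMatrix | np.ndarray,
                                 groups) -> VarianceDecomposition:
    """Variance components from a dissimilarity matrix (distance ANOVA).

    Sums of squares follow the nonparametric-MANOVA partition:
    SS_total = (1/N) sum_{i<j} d_ij^2, SS_within = sum_g (1/n_g)
    sum_{i<j in g} d_ij^2; mean squares and the n0 correction as in the
    univariate ANOVA. On Euclidean distances of univariate data this is
    identical to `anova_variance_components` — the module's central oracle.
    """
    d = D.data if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    groups = np.asarray(groups)
    N = d.shape[0]
    if len(groups) != N:
        raise ValueError("groups length must match matrix size")
    levels, inv = np.unique(groups, return_inverse=True)
    k = len(levels)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if N - k < 1:
        raise ValueError("within-group mean square undefined")
    d2 = d**2
    iu = np.triu_indices(N, k=1)
    ss_total = d2[iu].sum() / N
    n_g = np.bincount(inv, minlength=k).astype(float)
    ss_within = 0.0
    for g in range(k):
        idx = np.flatnonzero(inv == g)
        block = d2[np.ix_(idx, idx)]
        ss_within += block.sum() / 2.0 / n_g[g]
    ss_among = ss_total - ss_within
    ms_a = ss_among / (k - 1)
    ms_w = ss_within / (N - k)
    n0 = (N - (n_g**2).sum() / N) / (k - 1)
    s2_w = ms_w
    s2_a = max(0.0, (ms_a - ms_w) / n0)
    if s2_a + s2_w == 0:
        raise ValueError("degenerate distance matrix: all dissimilarities zero")
    return VarianceDecomposition(float(s2_a), float(s2_w), float(ms_a),
                                 float(ms_w), float(n0), k, int(N))


# --------------------------------------------------------------------------
# bootstrap over hosts
# --------------------------------------------------------------------------

def _components_from_group_sums(n_g, sum_g, sumsq_g):
    """Vectorised ANOVA components from stacked per-group sufficient stats.

    Inputs have shape (n_boot, k). Returns (s2_A, s2_W) arrays of length
    n_boot; entries where MS_W is undefined come out NaN.
    """
    N = n_g.sum(axis=1)
    k = n_g.shape[1]
    ss_within = (sumsq_g - sum_g**2 / n_g).sum(axis=1)
    grand = sum_g.sum(axis=1)
    ss_among = (sum_g**2 / n_g).sum(axis=1) - grand**2 / N
    with np.errstate(invalid="ignore", divide="ignore"):
        ms_a = ss_among / (k - 1)
        ms_w = ss_within / (N - k)
        n0 = (N - (n_g**2).sum(axis=1) / N) / (k - 1)
        s2_w = ms_w
        s2_a = np.maximum(0.0, (ms_a - ms_w) / n0)
    return s2_a, s2_w


def bootstrap_repeatability(data, groups, n_boot: int = 500, seed: int = 0,
                            mode: str = "univariate") -> RepeatabilityEstimate:
    """Bootstrap r by resampling whole hosts (groups) with replacement.

    A host drawn twice contributes two independent groups whose between-copy
    dissimilarities are read from the original matrix (zero-distance
    cross-copy pairs land between, not within, groups). Replicates with an
    undefined r (e.g. zero total variance) are dropped and counted.
    Percentile 2.5/97.5 CI; deterministic under the seed.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)

    if mode == "univariate":
        values = np.asarray(data, dtype=float)
        levels, inv, n_g, sum_g, sumsq_g = _group_stats(values, groups)
        k = len(levels)
        if k < 3:
            raise ValueError("bootstrap needs at least 3 groups")
        point = anova_variance_components(values, groups)
        draws = rng.integers(0, k, size=(n_boot, k))
        s2a, s2w = _components_from_group_sums(
            n_g[draws], sum_g[draws], sumsq_g[draws])
    elif mode == "distance":
        D = data.data if isinstance(data, DistanceMatrix) else np.asarray(data)
        groups = np.asarray(groups)
        levels, inv = np.unique(groups, return_inverse=True)
        k = len(levels)
        if k < 3:
            raise ValueError("bootstrap needs at least 3 groups")
        point = distance_variance_components(D, groups)
        d2 = D**2
        n_g = np.bincount(inv, minlength=k).astype(float)
        # block sums of squared distances between (and within) original hosts
        M = np.zeros((k, len(groups)))
        M[inv, np.arange(len(groups))] = 1.0
        S = M @ d2 @ M.T                      # S[g,h] = sum_{i in g, j in h} d2
        w_g = np.diag(S) / 2.0                # within-host pair sums
        draws = rng.integers(0, k, size=(n_boot, k))
        nb = n_g[draws]
        N = nb.sum(axis=1)
        total_pairsum = np.einsum("buv->b",
                                  S[draws[:, :, None], draws[:, None, :]]) / 2.0
        ss_total = total_pairsum / N
        ss_within = (w_g[draws] / nb).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            ms_a = (ss_total - ss_within) / (k - 1)
            ms_w = ss_within / (N - k)
            n0 = (N - (nb**2).sum(axis=1) / N) / (k - 1)
            s2w = ms_w
            s2a = np.maximum(0.0, (ms_a - ms_w) / n0)
    else:
        raise ValueError("mode must be 'univariate' or 'distance'")

    with np.errstate(invalid="ignore", divide="ignore"):
        total = s2a + s2w
        r_boot = np.where(total > 0, s2a / total, np.nan)
    ok = np.isfinite(r_boot)
    n_dropped = int(n_boot - ok.sum())
    if ok.sum() == 0:
        # degenerate data (e.g. zero within-variance everywhere -> r = 1)
        r_boot_ok = np.array([point.r])
    else:
        r_boot_ok = r_boot[ok]
    lo, hi = np.percentile(r_boot_ok, [2.5, 97.5])
    return RepeatabilityEstimate(point, point.r, float(lo), float(hi),
                                 n_boot, seed, n_dropped)


# --------------------------------------------------------------------------
# model / results objects
# --------------------------------------------------------------------------

class RepeatabilityModel:
    """Repeatability of one response (metric values or a distance matrix).

    Parameters
    ----------
    data : 1-D array or DistanceMatrix
        Per-library metric values, or a library x library dissimilarity
        matrix.
    groups : array of labels
        Host (fish) label per library, aligned with `data`.
    name : str
        Label carried into summaries.
    """

    def __init__(self, data, groups, name: str = "metric"):
        self.mode = ("distance"
                     if isinstance(data, (DistanceMatrix,)) or
                     (hasattr(data, "ndim") and np.asarray(data).ndim == 2)
                     else "univariate")
        self.data = data
        self.groups = np.asarray(groups)
        self.name = name

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, value_col: str, group_col: str,
                       name: str | None = None) -> "RepeatabilityModel":
        return cls(df[value_col].to_numpy(), df[group_col].to_numpy(),
                   name or value_col)

    def fit(self, n_boot: int = 500, seed: int = 0,
            method: str = "anova") -> "RepeatabilityResults":
        if self.mode == "univariate" and method == "reml":
            point = reml_variance_components(self.data, self.groups)
            est = bootstrap_repeatability(self.data, self.groups, n_boot,
                                          seed, mode=self.mode)
            est = RepeatabilityEstimate(point, point.r, est.ci_low,
                                        est.ci_high, n_boot, seed,
                                        est.n_dropped_boot)
        else:
            est = bootstrap_repeatability(self.data, self.groups, n_boot,
                                          seed, mode=self.mode)
        return RepeatabilityResults(self, est)


class RepeatabilityResults:
    """Fitted repeatability: components, r, bootstrap CI, summary table."""

    def __init__(self, model: RepeatabilityModel, estimate: RepeatabilityEstimate):
        self.model = model
        self.estimate = estimate
        d = estimate.decomposition
        self.s2_A = d.s2_A
        self.s2_W = d.s2_W
        self.r = estimate.r
        self.ci_low = estimate.ci_low
        self.ci_high = estimate.ci_high

    def summary(self) -> pd.DataFrame:
        d = self.estimate.decomposition
        return pd.DataFrame([{
            "metric": self.model.name,
            "s2_A": self.s2_A,
            "s2_W": self.s2_W,
            "r": self.r,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_groups": d.n_groups,
            "n_obs": d.n_obs,
            "n_boot": self.estimate.n_boot,
            "seed": self.estimate.seed,
        }]).set_index("metric")

    def __repr__(self):
        return (f"<RepeatabilityResults {self.model.name}: r={self.r:.3f} "
                f"({self.ci_low:.3f}, {self.ci_high:.3f})>")


# --------------------------------------------------------------------------
# Poisson-lognormal mixed model (per-taxon repeatability)
# --------------------------------------------------------------------------

class PoissonLognormalRepeatability:
    """Overdispersed-Poisson repeatability of one taxon's counts.

    Model: count_ij ~ Poisson(exp(eta_ij + a_i + o_ij)) with host effects
    a_i ~ N(0, s2_A) and an observation-level effect o_ij ~ N(0, s2_O)
    capturing overdispersion (Poisson-lognormal). eta_ij = x_ij' beta
    (intercept only by default). The marginal likelihood integrates both
    random effects by nested adaptive Gauss-Hermite quadrature (mode and
    curvature re-centred per host and per observation). Latent-scale
    repeatability is r = s2_A / (s2_A + s2_O).
    """

    def __init__(self, counts, groups, exog=None, n_quad: int = 20):
        self.counts = np.asarray(counts, dtype=float)
        if np.any(self.counts < 0) or np.any(self.counts != np.round(self.counts)):
            raise ValueError("counts must be non-negative integers")
        self.groups = np.asarray(groups)
        if exog is None:
            exog = np.ones((len(self.counts), 1))
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.shape[0] != len(self.counts):
            raise ValueError("exog rows must match counts")
        self.n_quad = int(n_quad)
        if self.n_quad < 5:
            raise ValueError("n_quad too small")
        levels, inv = np.unique(self.groups, return_inverse=True)
        self._levels = levels
        self._inv = inv
        self._z, self._w = special.roots_hermite(self.n_quad)

        # pad observations into a (hosts x max-replicates) layout
        k = len(levels)
        counts_per = np.bincount(inv, minlength=k)
        J = counts_per.max()
        self._y = np.zeros((k, J))
        self._mask = np.zeros((k, J), dtype=bool)
        self._obs_index = np.full((k, J), -1, dtype=int)
        fill = np.zeros(k, dtype=int)
        for idx, g in enumerate(inv):
            j = fill[g]
            self._y[g, j] = self.counts[idx]
            self._mask[g, j] = True
            self._obs_index[g, j] = idx
            fill[g] += 1

    # -------------------------------------------------------------- kernels
    def _eta_pad(self, beta):
        eta = self.exog @ beta
        out = np.zeros_like(self._y)
        out[self._mask] = eta[self._obs_index[self._mask]]
        return out

    @staticmethod
    def _inner_mode(y, c, s2o, o0=None, n_iter=40):
        """Mode of o -> y*o - exp(c+o) - o^2/(2 s2o), damped Newton."""
        o = np.zeros_like(c) if o0 is None else o0.copy()
        for _ in range(n_iter):
            lam = np.exp(np.clip(c + o, -700, 700))
            grad = y - lam - o / s2o
            hess = -lam - 1.0 / s2o
            step = np.clip(-grad / hess, -4.0, 4.0)
            o = o + step
            if np.max(np.abs(step)) < 1e-12:
                break
        return o

    def _log_inner(self, y, c, mask, s2o):
        """log of the observation-level integral, adaptive GH over o.

        y, c broadcastable arrays; returns same shape (0 where masked out).
        """
        o_star = self._inner_mode(y, c, s2o)
        lam_star = np.exp(np.clip(c + o_star, -700, 700))
        s_in = 1.0 / np.sqrt(lam_star + 1.0 / s2o)
        # nodes: (..., K)
        o_k = o_star[..., None] + np.sqrt(2.0) * s_in[..., None] * self._z
        lin = c[..., None] + o_k
        logf = (y[..., None] * lin - np.exp(np.clip(lin, -700, 700))
                - special.gammaln(y[..., None] + 1.0)
                - 0.5 * np.log(2 * np.pi * s2o) - o_k**2 / (2 * s2o))
        logw = np.log(np.sqrt(2.0) * s_in)[..., None] + np.log(self._w) \
            + self._z**2 + logf
        out = special.logsumexp(logw, axis=-1)
        return np.where(mask, out, 0.0)

    def loglike(self, beta, s2a, s2o) -> float:
        """Marginal log-likelihood via nested adaptive quadrature."""
        s2a = max(float(s2a), 1e-10)
        s2o = max(float(s2o), 1e-10)
        y, mask = self._y, self._mask
        eta = self._eta_pad(beta)
        k = y.shape[0]

        # joint mode of (a, o_.) per host, by alternating Newton blocks
        a = np.zeros(k)
        o = np.zeros_like(y)
        for _ in range(60):
            o = self._inner_mode(y, eta + a[:, None], s2o, o0=o, n_iter=3)
            lam = np.exp(np.clip(eta + a[:, None] + o, -700, 700)) * mask
            grad = (y * mask - lam).sum(axis=1) - a / s2a
            hess = -lam.sum(axis=1) - 1.0 / s2a
            step = np.clip(-grad / hess, -4.0, 4.0)
            a = a + step
            if np.max(np.abs(step)) < 1e-10:
                break
        o = self._inner_mode(y, eta + a[:, None], s2o, o0=o, n_iter=25)
        lam = np.exp(np.clip(eta + a[:, None] + o, -700, 700)) * mask
        # profile curvature of a after o adjusts (Schur complement)
        info_a = 1.0 / s2a + (lam / (1.0 + lam * s2o) * mask).sum(axis=1)
        s_out = 1.0 / np.sqrt(info_a)

        a_k = a[:, None] + np.sqrt(2.0) * s_out[:, None] * self._z  # (k, K)
        # inner integrals at every outer node: (k, J, K)
        c = eta[:, :, None] + a_k[:, None, :]
        y3 = np.broadcast_to(y[:, :, None], c.shape)
        m3 = np.broadcast_to(mask[:, :, None], c.shape)
        log_g = self._log_inner(y3, c, m3, s2o)
        h = (log_g.sum(axis=1)
             - 0.5 * np.log(2 * np.pi * s2a) - a_k**2 / (2 * s2a))
        log_Li = special.logsumexp(
            np.log(np.sqrt(2.0) * s_out)[:, None] + np.log(self._w)
            + self._z**2 + h, axis=1)
        return float(log_Li.sum())

    # ------------------------------------------------------------------ fit
    def fit(self, start=None, maxiter: int = 200) -> "PoissonLognormalResults":
        p = self.exog.shape[1]
        if start is None:
            # moment start on log counts
            z = np.log(self.counts + 0.5)
            beta0 = np.zeros(p)
            beta0[0] = float(np.mean(z))
            try:
                vc = anova_variance_components(z, self.groups)
                s2a0 = max(vc.s2_A, 1e-3)
                s2o0 = max(vc.s2_W, 1e-3)
            except ValueError:
                s2a0, s2o0 = 0.3, 0.3
            start = np.concatenate([beta0, [np.log(s2a0), np.log(s2o0)]])

        trace = []

        def nll(theta):
            beta = theta[:p]
            s2a = np.exp(theta[p])
            s2o = np.exp(theta[p + 1])
            ll = self.loglike(beta, s2a, s2o)
            trace.append(ll)
            return -ll

        bounds = [(None, None)] * p + [(-14.0, 6.0), (-14.0, 6.0)]
        res = optimize.minimize(nll, start, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": maxiter, "ftol": 1e-9,
                                         "gtol": 1e-7})
        beta = res.x[:p]
        s2a = float(np.exp(res.x[p]))
        s2o = float(np.exp(res.x[p + 1]))
        boundary = bool(res.x[p] <= -13.5 or res.x[p + 1] <= -13.5)
        if res.x[p] <= -13.5:
            s2a = 0.0
        if res.x[p + 1] <= -13.5:
            s2o = 0.0
        return PoissonLognormalResults(self, beta, s2a, s2o, float(-res.fun),
                                       bool(res.success), boundary,
                                       int(res.nit), trace)


class PoissonLognormalResults:
    """Fitted Poisson-lognormal repeatability model."""

    def __init__(self, model, beta, s2_A, s2_O, llf, converged, boundary,
                 n_iter, trace=None):
        self.model = model
        self.beta = np.asarray(beta)
        self.s2_A = s2_A
        self.s2_O = s2_O
        self.llf = llf
        self.converged = converged
        self.boundary = boundary
        self.n_iter = n_iter
        self.trace = trace or []

    @property
    def k_params(self) -> int:
        return len(self.beta) + 2

    @property
    def aic(self) -> float:
        return -2 * self.llf + 2 * self.k_params

    @property
    def bic(self) -> float:
        return -2 * self.llf + self.k_params * np.log(len(self.model.counts))

    @property
    def r(self) -> float:
        total = self.s2_A + self.s2_O
        return float(self.s2_A / total) if total > 0 else 0.0

    def simulate(self, rng) -> np.ndarray:
        """Draw a synthetic count vector from the fitted model."""
        eta = self.model.exog @ self.beta
        a = rng.normal(0, np.sqrt(max(self.s2_A, 0.0)), len(self.model._levels))
        o = rng.normal(0, np.sqrt(max(self.s2_O, 0.0)), len(eta))
        lam = np.exp(np.clip(eta + a[self.model._inv] + o, -700, 50))
        return rng.poisson(lam)

    def parametric_bootstrap(self, n_boot: int = 500, seed: int = 0,
                             alpha: float = 0.05) -> RepeatabilityEstimate:
        """Percentile CI for r: simulate from the fit, refit, repeat."""
        rng = np.random.default_rng(seed)
        rs, dropped = [], 0
        for _ in range(n_boot):
            y = self.simulate(rng)
            try:
                fit = PoissonLognormalRepeatability(
                    y, self.model.groups, self.model.exog,
                    self.model.n_quad).fit()
                rs.append(fit.r)
            except Exception:
                dropped += 1
        rs = np.asarray(rs)
        lo, hi = np.percentile(rs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        return RepeatabilityEstimate(None, self.r, float(lo), float(hi),
                                     n_boot, seed, dropped,
                                     {"boundary": self.boundary,
                                      "converged": self.converged})

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "s2_A": self.s2_A, "s2_O": self.s2_O, "r": self.r,
            "llf": self.llf, "aic": self.aic, "bic": self.bic,
            "converged": self.converged, "boundary": self.boundary,
        }])


def per_taxon_repeatability(counts_for_taxon, fish_labels, n_boot: int = 500,
                            seed: int = 0, n_quad: int = 20) -> RepeatabilityEstimate:
    """Latent-scale repeatability of one taxon's counts across hosts.

    Fits the Poisson-lognormal mixed model (intercept only) and builds the CI
    by parametric bootstrap. Counts should come from equal-depth (rarefied)
    libraries so the intercept absorbs sequencing effort.
    """
    fit = PoissonLognormalRepeatability(counts_for_taxon, fish_labels,
                                        n_quad=n_quad).fit()
    if not fit.converged:
        warnings.warn("Poisson-lognormal fit did not converge; estimate flagged",
                      RuntimeWarning, stacklevel=2)
    est = fit.parametric_bootstrap(n_boot=n_boot, seed=seed)
    return est


# --------------------------------------------------------------------------
# abundance-reproducibility logistic curve
# --------------------------------------------------------------------------

@dataclass
class LogisticCurveFit:
    """Three-parameter logistic fit y = alpha / (1 + exp((beta - x)/gamma))."""

    alpha: float
    beta: float
    gamma: float
    se_gamma: float
    t_gamma: float
    rss: float
    n_points: int

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        z = np.clip((self.beta - x) / self.gamma, -700, 700)
        return self.alpha / (1.0 + np.exp(z))


class LogisticCurveModel:
    """Least-squares logistic curve of repeatability vs log10 mean abundance.

    x is log10 of the across-library mean (rarefied) count of each taxon; y
    is its repeatability point estimate (or a CI bound — fit one model per
    column). alpha is the asymptote, beta the inflection location in x units,
    gamma the steepness at inflection.
    """

    def __init__(self, x, y):
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        ok = np.isfinite(self.x) & np.isfinite(self.y)
        self.x, self.y = self.x[ok], self.y[ok]
        if len(self.x) < 10:
            raise ValueError("need at least 10 points for the curve fit")

    @staticmethod
    def _f(x, alpha, beta, gamma):
        return alpha / (1.0 + np.exp(np.clip((beta - x) / gamma, -700, 700)))

    def fit(self, n_starts: int = 7) -> LogisticCurveFit:
        """Multi-start Levenberg-Marquardt; the lowest-RSS fit wins."""
        x, y = self.x, self.y
        lo, hi = x.min(), x.max()
        spread = max(hi - lo, 1e-3)
        alpha0 = max(y.max(), 0.1)
        starts = [(alpha0, lo + frac * spread, g)
                  for frac, g in zip(np.linspace(0.15, 0.85, n_starts),
                                     np.geomspace(0.05, 2.0, n_starts) * spread / 2)]
        best = None
        for p0 in starts:
            try:
                popt, pcov = optimize.curve_fit(
                    self._f, x, y, p0=p0, maxfev=20000,
                    bounds=([1e-6, -np.inf, 1e-6], [np.inf, np.inf, np.inf]))
            except (RuntimeError, ValueError):
                continue
            rss = float(((y - self._f(x, *popt)) ** 2).sum())
            if best is None or rss < best[1]:
                best = (popt, rss, pcov)
        if best is None:
            raise RuntimeError("logistic curve fit failed from all starts")
        (alpha, beta, gamma), rss, pcov = best
        se_gamma = float(np.sqrt(pcov[2, 2])) if np.isfinite(pcov[2, 2]) else np.nan
        t_gamma = float(gamma / se_gamma) if se_gamma > 0 else np.inf
        return LogisticCurveFit(float(alpha), float(beta), float(gamma),
                                se_gamma, t_gamma, rss, len(x))


def abundance_reproducibility_curve(points: pd.DataFrame) -> dict:
    """Fit the logistic curve to r, and optionally its CI bounds, vs x.

    `points` columns: x (log10 mean abundance), y (repeatability), and
    optionally y_lo / y_hi (CI bounds). Returns one LogisticCurveFit per
    fitted column.
    """
    fits = {"y": LogisticCurveModel(points["x"], points["y"]).fit()}
    for col in ("y_lo", "y_hi"):
        if col in points.columns:
            fits[col] = LogisticCurveModel(points["x"], points[col]).fit()
    return fits


def log10_mean_abundance(counts_row) -> float:
    """x coordinate for the curve: log10 of the across-library mean count.

    Zeros participate in the mean (they are not excluded).
    """
    m = float(np.mean(counts_row))
    if m <= 0:
        return -np.inf
    return float(np.log10(m))
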