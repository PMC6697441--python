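"""Hypothesis tests for protocol, population and interaction effects.

Covers the full battery used around the repeatability framework: Gaussian
mixed-model likelihood-ratio tests for alpha-diversity metrics,
Poisson-lognormal count-model tests per taxon with AIC/BIC/FDR decision
rules, PERMANOVA (factorial with stratified permutation, and nested),
Mantel tests between protocol-specific distance matrices, median-based
Levene tests and distance-to-centroid dispersion for precision comparisons,
and the Feltz-Miller asymptotic test for equality of coefficients of
variation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diversity import DistanceMatrix
from .repeatability import PoissonLognormalRepeatability

__all__ = [
    "TestResult",
    "lmm_lrt_alpha",
    "pln_taxon_tests",
    "bh_fdr",
    "permanova",
    "nested_permanova",
    "mantel",
    "levene_median",
    "centroid_distances",
    "feltz_miller_cv_test",
    "STRONG_RULE",
    "WEAK_RULE",
]


@dataclass
class TestResult:
    statistic: float
    df: float | tuple
    p_value: float
    method: str
    n_permutations: int | None = None
    auxiliary: dict = field(default_factory=dict)

    def __repr__(self):
        return (f"<TestResult {self.method}: stat={self.statistic:.4g} "
                f"df={self.df} p={self.p_value:.4g}>")


def _design_frame(design):
    """Accept a StudyDesign or a plain DataFrame."""
    return design.table if hasattr(design, "table") else design


# --------------------------------------------------------------------------
# Gaussian mixed-model LRTs for alpha metrics
# --------------------------------------------------------------------------

_EFFECT_DF = {"protocol": None, "population": None, "interaction": None}


def lmm_lrt_alpha(values, design, effect: str) -> TestResult:
    """LRT for a fixed effect on an alpha metric under a Gaussian LMM.

    Random effects: family intercept and fish nested within family. Models
    are fitted by full maximum likelihood (not REML), as required for
    comparing fixed-effect structures. For `effect` in {protocol,
    population}, the full model carries both main effects and the reduced
    model drops the tested one; for "interaction" the full model adds the
    protocol x population term. The statistic is 2*dlogL against chi^2 with
    df = number of dropped columns (protocol 2, population 1, interaction 2
    in the three-protocol, two-population design).
    """
    import statsmodels.formula.api as smf

    df_tab = _design_frame(design).copy()
    df_tab["value"] = np.asarray(values, dtype=float)
    if effect not in ("protocol", "population", "interaction"):
        raise ValueError("effect must be protocol, population, or interaction")
    if effect == "interaction":
        full_f = "value ~ C(protocol) * C(population)"
        red_f = "value ~ C(protocol) + C(population)"
    elif effect == "protocol":
        full_f = "value ~ C(protocol) + C(population)"
        red_f = "value ~ C(population)"
    else:
        full_f = "value ~ C(protocol) + C(population)"
        red_f = "value ~ C(protocol)"

    n_proto = df_tab["protocol"].nunique()
    n_pop = df_tab["population"].nunique()
    if (effect == "protocol" and n_proto < 2) or \
       (effect == "population" and n_pop < 2):
        raise ValueError(f"tested factor {effect} needs >= 2 levels")
    dof = {"protocol": n_proto - 1, "population": n_pop - 1,
           "interaction": (n_proto - 1) * (n_pop - 1)}[effect]

    def _fit(formula):
        singular = False
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            md = smf.mixedlm(formula, df_tab, groups="family_id",
                             re_formula="1",
                             vc_formula={"fish": "0 + C(fish_id)"})
            res = md.fit(reml=False, method=["lbfgs", "bfgs"], maxiter=500)
            singular = any("singular" in str(w.message).lower()
                           or "converge" in str(w.message).lower()
                           for w in rec)
        return res, singular

    full, sing_f = _fit(full_f)
    red, sing_r = _fit(red_f)
    lrt = max(0.0, 2.0 * (full.llf - red.llf))
    p = float(stats.chi2.sf(lrt, dof))
    return TestResult(float(lrt), dof, p, f"lmm_lrt[{effect}]",
                      auxiliary={"llf_full": float(full.llf),
                                 "llf_reduced": float(red.llf),
                                 "singular_fit": bool(sing_f or sing_r)})


# --------------------------------------------------------------------------
# Poisson-lognormal taxon tests
# --------------------------------------------------------------------------

STRONG_RULE = "dAIC>2 & dBIC>0 & p_fdr<0.1"
WEAK_RULE = "p_raw<0.05"


def _fixed_design(df_tab: pd.DataFrame, effect: str):
    """Full/reduced fixed-effect design matrices and the tested-term df."""
    proto = pd.get_dummies(df_tab["protocol"], drop_first=True, dtype=float)
    pop = pd.get_dummies(df_tab["population"], drop_first=True, dtype=float)
    inter = pd.DataFrame(
        {f"{a}:{b}": proto[a] * pop[b] for a in proto for b in pop})
    ones = pd.DataFrame({"const": np.ones(len(df_tab))})
    if effect == "interaction":
        full = pd.concat([ones, proto, pop, inter], axis=1)
        red = pd.concat([ones, proto, pop], axis=1)
    elif effect == "protocol":
        full = pd.concat([ones, proto, pop], axis=1)
        red = pd.concat([ones, pop], axis=1)
    elif effect == "population":
        full = pd.concat([ones, proto, pop], axis=1)
        red = pd.concat([ones, proto], axis=1)
    else:
        raise ValueError("effect must be protocol, population, or interaction")
    return full.to_numpy(), red.to_numpy(), full.shape[1] - red.shape[1]


def pln_taxon_tests(table, design, effect: str, q: float = 0.1,
                    n_quad: int = 20) -> pd.DataFrame:
    """Per-taxon Poisson-lognormal LRTs for a fixed effect.

    For each taxon, full and reduced Poisson-lognormal mixed models (random
    fish intercept plus observation-level effect) are fitted by maximum
    marginal likelihood; the table reports the LRT statistic, dAIC / dBIC
    (reduced minus full; positive favours the full model), raw and BH-FDR
    adjusted p-values, and two named decision rules: the strong joint rule
    (dAIC>2 and dBIC>0 and FDR p<q) and the weak rule (raw p<0.05). Taxa are
    expected to be pre-filtered (e.g. >=5 counts in >=9 libraries);
    non-converging taxa are kept with a reason code and excluded from FDR.
    """
    df_tab = _design_frame(design)
    X_full, X_red, dof = _fixed_design(df_tab, effect)
    fish = df_tab["fish_id"].to_numpy()

    rows = []
    for i, taxon in enumerate(table.taxon_ids):
        y = table.counts[i]
        rec = {"taxon": taxon, "effect": effect, "df": dof}
        try:
            full = PoissonLognormalRepeatability(y, fish, X_full,
                                                 n_quad=n_quad).fit()
            red = PoissonLognormalRepeatability(y, fish, X_red,
                                                n_quad=n_quad).fit()
            if not (full.converged and red.converged):
                raise RuntimeError("optimizer did not converge")
            lrt = max(0.0, 2.0 * (full.llf - red.llf))
            rec.update({
                "lrt": lrt,
                "p_raw": float(stats.chi2.sf(lrt, dof)),
                "dAIC": red.aic - full.aic,
                "dBIC": red.bic - full.bic,
                "status": "ok",
            })
        except Exception as exc:  # per-taxon failure must not kill the scan
            rec.update({"lrt": np.nan, "p_raw": np.nan, "dAIC": np.nan,
                        "dBIC": np.nan, "status": f"failed: {exc}"})
        rows.append(rec)
    out = pd.DataFrame(rows)

    ok = out["status"] == "ok"
    out["p_fdr"] = np.nan
    if ok.any():
        adj, _ = bh_fdr(out.loc[ok, "p_raw"].to_numpy(), q)
        out.loc[ok, "p_fdr"] = adj
    out["flag_strong"] = ok & (out["dAIC"] > 2) & (out["dBIC"] > 0) & \
        (out["p_fdr"] < q)
    out["flag_weak"] = ok & (out["p_raw"] < 0.05)
    return out


def bh_fdr(p_values, q: float = 0.1):
    """Benjamini-Hochberg step-up: adjusted p-values and rejection mask."""
    from statsmodels.stats.multitest import multipletests
    p = np.asarray(p_values, dtype=float)
    reject, adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return adj, reject


# --------------------------------------------------------------------------
# PERMANOVA and friends
# --------------------------------------------------------------------------

def _gower(D: np.ndarray) -> np.ndarray:
    A = -0.5 * D**2
    n = A.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ A @ J


def _hat(X: np.ndarray):
    """Projection matrix onto col(X) and its rank (via thin SVD)."""
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    rank = int((s > s.max() * max(X.shape) * np.finfo(float).eps).sum()) \
        if s.size else 0
    Ur = U[:, :rank]
    return Ur @ Ur.T, rank


def _factor_dummies(values) -> np.ndarray:
    return pd.get_dummies(pd.Series(values), dtype=float).to_numpy()


def _interaction_dummies(a, b) -> np.ndarray:
    combo = [f"{x}||{y}" for x, y in zip(a, b)]
    return _factor_dummies(combo)


def _sequential_ss(G, design_cols):
    """Sequential (Type-I) sums of squares on the Gower matrix.

    design_cols: ordered list of (name, dummy-matrix). Returns per-term SS
    and df plus the residual SS and df.
    """
    n = G.shape[0]
    X = np.ones((n, 1))
    H_prev, rank_prev = _hat(X)
    terms = []
    for name, Z in design_cols:
        X = np.hstack([X, Z])
        H, rank = _hat(X)
        terms.append((name, float(np.trace((H - H_prev) @ G)),
                      rank - rank_prev))
        H_prev, rank_prev = H, rank
    ss_res = float(np.trace((np.eye(n) - H_prev) @ G))
    df_res = n - rank_prev
    return terms, ss_res, df_res


def _permute_within_strata(rng, n, strata=None):
    perm = np.arange(n)
    if strata is None:
        rng.shuffle(perm)
        return perm
    strata = np.asarray(strata)
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        perm[idx] = rng.permutation(idx)
    return perm


def permanova(D, design, factors, strata=None, n_perm: int = 999,
              seed: int = 0, interactions=()) -> list:
    """Sequential-SS PERMANOVA on a distance matrix, optionally stratified.

    `factors` is the ordered list of design columns (Type-I order matters);
    `interactions` lists (a, b) column pairs added after the main effects.
    Permutation p-values shuffle object labels, restricted within `strata`
    (a design column name, e.g. "fish_id") when given. pseudo-F for a term is
    (SS_term/df_term)/(SS_res/df_res); on Euclidean embeddings of scalar
    data with one factor this equals the classical ANOVA F. Returns one
    TestResult per term.
    """
    Dm = D.data if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    df_tab = _design_frame(design)
    if isinstance(design, pd.DataFrame) or hasattr(design, "table"):
        df_tab = df_tab.set_index("library_id").loc[
            list(D.ids) if isinstance(D, DistanceMatrix) else df_tab["library_id"]
        ].reset_index() if "library_id" in df_tab.columns else df_tab
    n = Dm.shape[0]
    G = _gower(Dm)

    def columns_for(tab):
        cols = [(f, _factor_dummies(tab[f])) for f in factors]
        for a, b in interactions:
            cols.append((f"{a}:{b}", _interaction_dummies(tab[a], tab[b])))
        return cols

    terms, ss_res, df_res = _sequential_ss(G, columns_for(df_tab))
    if df_res <= 0 or ss_res <= 1e-12:
        # saturated or label-invariant data: no residual variation to test against
        return [TestResult(0.0, (t_df, df_res), 1.0, f"permanova[{name}]",
                           n_perm, {"ss": ss, "ss_res": ss_res,
                                    "degenerate": True})
                for name, ss, t_df in terms]

    F_obs = np.array([(ss / t_df) / (ss_res / df_res)
                      for _, ss, t_df in terms])
    strata_vals = df_tab[strata].to_numpy() if strata else None

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        perm = _permute_within_strata(rng, n, strata_vals)
        Gp = G[np.ix_(perm, perm)]
        terms_p, ss_res_p, _ = _sequential_ss(Gp, columns_for(df_tab))
        if ss_res_p <= 1e-12:
            continue
        F_p = np.array([(ss / t_df) / (ss_res_p / df_res)
                        for _, ss, t_df in terms_p])
        exceed += F_p >= F_obs - 1e-12
    p = (exceed + 1.0) / (n_perm + 1.0)
    return [TestResult(float(F_obs[i]), (terms[i][2], df_res), float(p[i]),
                       f"permanova[{terms[i][0]}]", n_perm,
                       {"ss": terms[i][1], "ss_res": ss_res})
            for i in range(len(terms))]


def nested_permanova(D, design, between: str = "population",
                     nested: str = "family_id", n_perm: int = 999,
                     seed: int = 0) -> TestResult:
    """Nested PERMANOVA: between-group effect tested against nested units.

    F = MS_between / MS_nested-within-between; the permutation null
    reassigns whole nested units (families) to between-group levels,
    respecting the design's family sizes. With 3+3 families only C(6,3) = 20
    whole-family relabelings exist, so the achievable p has a discrete
    floor — reported in the auxiliary data.
    """
    Dm = D.data if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    df_tab = _design_frame(design)
    n = Dm.shape[0]
    G = _gower(Dm)
    fam = df_tab[nested].to_numpy()
    pop = df_tab[between].to_numpy()

    fam_levels = pd.unique(fam)
    fam_pop = {f: pop[fam == f][0] for f in fam_levels}
    pops_of_fams = np.array([fam_pop[f] for f in fam_levels])
    n_pop = len(pd.unique(pop))
    n_fam = len(fam_levels)
    if min(pd.Series(pops_of_fams).value_counts()) < 2:
        raise ValueError("nested test impossible: < 2 families per population")

    def F_stat(pop_vec):
        H_pop, r_pop = _hat(np.hstack([np.ones((n, 1)),
                                       _factor_dummies(pop_vec)]))
        H_fam, r_fam = _hat(np.hstack([np.ones((n, 1)),
                                       _factor_dummies(fam)]))
        H_0 = np.ones((n, n)) / n
        ss_pop = float(np.trace((H_pop - H_0) @ G))
        ss_fam = float(np.trace((H_fam - H_pop) @ G))
        df_pop = r_pop - 1
        df_fam = r_fam - r_pop
        if df_fam <= 0 or ss_fam <= 1e-12:
            return np.nan, df_pop, df_fam, ss_pop, ss_fam
        return (ss_pop / df_pop) / (ss_fam / df_fam), df_pop, df_fam, \
            ss_pop, ss_fam

    F_obs, df_pop, df_fam, ss_pop, ss_fam = F_stat(pop)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm_pops = rng.permutation(pops_of_fams)
        fam_to_pop = dict(zip(fam_levels, perm_pops))
        pop_perm = np.array([fam_to_pop[f] for f in fam])
        F_p = F_stat(pop_perm)[0]
        if np.isnan(F_p):
            continue
        if F_p >= F_obs - 1e-12:
            exceed += 1
    p = (exceed + 1.0) / (n_perm + 1.0)
    from math import comb
    distinct = comb(n_fam, int(pd.Series(pops_of_fams).value_counts().iloc[0]))
    return TestResult(float(F_obs), (df_pop, df_fam), float(p),
                      f"nested_permanova[{between}/{nested}]", n_perm,
                      {"ss_between": ss_pop, "ss_nested": ss_fam,
                       "distinct_relabelings": distinct,
                       "note": "family and tank are confounded in this design"})


def mantel(D1, D2, n_perm: int = 999, seed: int = 0) -> TestResult:
    """Mantel correlation between two distance matrices over the same ids.

    Pearson r of the off-diagonal entries; p by jointly permuting one
    matrix's rows and columns.
    """
    if isinstance(D1, DistanceMatrix) and isinstance(D2, DistanceMatrix):
        if set(D1.ids) != set(D2.ids):
            raise ValueError("Mantel requires matching id sets")
        D2 = D2.subset(D1.ids)
        A, B = D1.data, D2.data
    else:
        A = D1.data if isinstance(D1, DistanceMatrix) else np.asarray(D1, float)
        B = D2.data if isinstance(D2, DistanceMatrix) else np.asarray(D2, float)
    n = A.shape[0]
    iu = np.triu_indices(n, k=1)

    def corr(M):
        return float(np.corrcoef(A[iu], M[iu])[0, 1])

    r_obs = corr(B)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if corr(B[np.ix_(perm, perm)]) >= r_obs - 1e-12:
            exceed += 1
    p = (exceed + 1.0) / (n_perm + 1.0)
    return TestResult(r_obs, n - 2, float(p), "mantel", n_perm)


# --------------------------------------------------------------------------
# precision: Levene / dispersion / CV equality
# --------------------------------------------------------------------------

def levene_median(values, groups, compare) -> TestResult:
    """Median-based Levene test across protocols, centred per host.

    Each observation becomes |value - median(its host)|; a one-way ANOVA F
    then compares these absolute deviations across `compare` (protocol)
    levels. Degenerate inputs (all deviations zero) are reported as such
    with p = 1.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    compare = np.asarray(compare)
    dev = np.empty_like(values)
    for g in np.unique(groups):
        m = groups == g
        dev[m] = np.abs(values[m] - np.median(values[m]))
    levels = np.unique(compare)
    if len(levels) < 2:
        raise ValueError("need >= 2 comparison levels")
    if np.allclose(dev, 0):
        return TestResult(0.0, (len(levels) - 1, len(values) - len(levels)),
                          1.0, "levene_median", auxiliary={"degenerate": True})
    F, p = stats.f_oneway(*(dev[compare == l] for l in levels))
    return TestResult(float(F), (len(levels) - 1, len(values) - len(levels)),
                      float(p), "levene_median")


def centroid_distances(D, groups) -> np.ndarray:
    """Distance from each observation to its group centroid in PCoA space.

    The matrix is embedded by principal coordinates keeping all axes;
    negative-eigenvalue axes are retained separately and their squared
    contribution subtracted (squared distance = real part - imaginary part,
    truncated at 0 before the square root), the standard correction for
    non-Euclidean dissimilarities. Singleton groups get distance 0.
    """
    Dm = D.data if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    groups = np.asarray(groups)
    G = _gower(Dm)
    G = (G + G.T) / 2
    evals, evecs = np.linalg.eigh(G)
    tol = 1e-10 * max(1.0, np.abs(evals).max())
    pos = evals > tol
    neg = evals < -tol
    X = evecs[:, pos] * np.sqrt(evals[pos])        # real axes
    Y = evecs[:, neg] * np.sqrt(-evals[neg])       # imaginary axes
    out = np.zeros(len(groups))
    for g in np.unique(groups):
        m = groups == g
        if m.sum() == 1:
            out[m] = 0.0
            continue
        cx = X[m].mean(axis=0)
        cy = Y[m].mean(axis=0)
        d2 = ((X[m] - cx) ** 2).sum(axis=1) - ((Y[m] - cy) ** 2).sum(axis=1)
        out[m] = np.sqrt(np.maximum(d2, 0.0))
    return out


def feltz_miller_cv_test(cvs=None, ns=None, values=None, groups=None) -> TestResult:
    """Feltz-Miller asymptotic test of equal coefficients of variation.

    Either pass per-group CVs `cvs` with sample sizes `ns`, or raw `values`
    with `groups` (CVs are then sample SD / mean per group). The statistic

        D'AD = sum_i (n_i - 1)(k_i - kbar)^2 / (kbar^2 (0.5 + kbar^2)),

    with kbar the (n_i - 1)-weighted mean CV, is referred to chi^2 with
    (groups - 1) df.
    """
    if values is not None:
        values = np.asarray(values, dtype=float)
        groups = np.asarray(groups)
        levels = pd.unique(groups)
        cvs, ns = [], []
        for l in levels:
            v = values[groups == l]
            cvs.append(np.std(v, ddof=1) / np.mean(v))
            ns.append(len(v))
    cvs = np.asarray(cvs, dtype=float)
    ns = np.asarray(ns, dtype=float)
    if len(cvs) < 2:
        raise ValueError("need >= 2 groups")
    if np.any(ns < 2):
        raise ValueError("each group needs n >= 2")
    if np.any(cvs <= 0):
        raise ValueError("CVs must be > 0")
    nu = ns - 1.0
    kbar = float((nu * cvs).sum() / nu.sum())
    if kbar == 0:
        raise ValueError("pooled CV is zero")
    dad = float((nu * (cvs - kbar) ** 2).sum() / (kbar**2 * (0.5 + kbar**2)))
    dof = len(cvs) - 1
    p = float(stats.chi2.sf(dad, dof))
    return TestResult(dad, dof, p, "feltz_miller_cv",
                      auxiliary={"kbar": kbar, "cvs": list(map(float, cvs))})
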