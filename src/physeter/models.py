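"""Binomial GEE seasonal models with blocked AR-1 working correlation.

Workflow: size blocks where GLM residual autocorrelation drops below 0.1,
screen covariates with VIF, fit a binomial GEE (logit link, within-block
AR-1, sandwich errors), select covariates backwards by QICa, prune by
robust Wald tests, and evaluate with Tjur's R-squared and binned residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from patsy import build_design_matrices, dmatrix
from scipy import stats
from statsmodels.genmod.cov_struct import Autoregressive, Independence
from statsmodels.tsa.stattools import acf as _acf

__all__ = [
    "CyclicBasis",
    "cyclic_basis",
    "ModelSpec",
    "GeeFit",
    "SelectionTrace",
    "block_size_from_acf",
    "vif_screen",
    "fit_gee",
    "qica",
    "backward_select",
    "wald_prune",
    "tjur_r2",
    "binned_residuals",
    "diagnostics",
]

JD_LO, JD_HI = 1.0, 366.0


# ---------------------------------------------------------------------------
# cyclic seasonal basis
# ---------------------------------------------------------------------------


class CyclicBasis:
    """Cyclic cubic regression spline on [1, 366] with ``df`` columns.

    Built from evenly spaced knots; a fixed sum-to-zero constraint (over a
    uniform reference grid) absorbs the constant so the basis can sit next to
    an intercept.  Every basis function and its first derivative match at
    day 1 and day 366.
    """

    def __init__(self, df: int = 2, lower: float = JD_LO, upper: float = JD_HI):
        if df < 2:
            raise ValueError("df must be >= 2")
        self.df = df
        self.lower, self.upper = lower, upper
        grid = np.linspace(lower, upper, 1000)
        raw = dmatrix(
            f"cc(x, df={df + 1}, lower_bound={lower}, upper_bound={upper}) - 1",
            {"x": grid},
        )
        self._design_info = raw.design_info
        # null space of the grid column means -> sum-to-zero constraint
        c = np.asarray(raw).mean(axis=0, keepdims=True)
        _, _, vt = np.linalg.svd(c)
        self._z = vt[1:].T  # (df+1, df)

    def transform(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if np.any((x < self.lower) | (x > self.upper)):
            raise ValueError(f"values outside [{self.lower}, {self.upper}]")
        raw = np.asarray(build_design_matrices([self._design_info], {"x": x})[0])
        return raw @ self._z


def cyclic_basis(julian_day, df: int = 2) -> np.ndarray:
    """Convenience wrapper: evaluate a fresh ``CyclicBasis(df)``."""
    return CyclicBasis(df).transform(julian_day)


# ---------------------------------------------------------------------------
# blocking and collinearity
# ---------------------------------------------------------------------------


def block_size_from_acf(residuals, cutoff: float = 0.1, max_lag: int | None = None) -> int:
    """Smallest lag (hours) at which |ACF| of the residuals drops below cutoff."""
    x = np.asarray(residuals, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("residual series too short")
    hi = max_lag or min(n - 1, 1000)
    nlags = min(64, hi)
    while True:
        a = _acf(x, nlags=nlags, fft=True)
        below = np.nonzero(np.abs(a[1:]) < cutoff)[0]
        if below.size:
            return int(below[0]) + 1
        if nlags >= hi:
            raise ValueError(f"autocorrelation never drops below {cutoff} within {hi} lags")
        nlags = min(nlags * 2, hi)


def vif_screen(design: pd.DataFrame, flag_threshold: float = 2.0) -> pd.DataFrame:
    """Variance inflation factor per covariate column (intercept added
    internally); columns with VIF above ``flag_threshold`` are flagged."""
    from statsmodels.stats.outliers_influence import variance_inflation_factor

    if design.shape[1] < 2:
        raise ValueError("need at least two covariates for a VIF screen")
    X = sm.add_constant(np.asarray(design, dtype=float), has_constant="add")
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for j, name in enumerate(design.columns):
            try:
                v = variance_inflation_factor(X, j + 1)
            except Exception:
                v = np.inf
            if not np.isfinite(v):
                v = np.inf
            rows.append({"covariate": name, "vif": v, "flag": v > flag_threshold})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model specification and design
# ---------------------------------------------------------------------------

FACTOR_COVARIATES = ("year", "site", "region")
SPLINE_COVARIATE = "julian_day"


@dataclass
class ModelSpec:
    response: str
    covariates: list[str]
    df: int = 2
    block_len_h: int = 24
    corstr: str = "ar1"  # "ar1" | "independence"

    def __post_init__(self):
        if self.df < 2:
            raise ValueError("df must be >= 2")
        if self.block_len_h < 1:
            raise ValueError("block_len_h must be >= 1")
        if self.corstr not in ("ar1", "independence"):
            raise ValueError("corstr must be 'ar1' or 'independence'")
        for c in self.covariates:
            if c != SPLINE_COVARIATE and c not in FACTOR_COVARIATES:
                raise ValueError(f"unknown covariate {c!r}")


def _build_design(
    data: pd.DataFrame, covariates: list[str], df: int, basis: CyclicBasis | None = None
) -> tuple[pd.DataFrame, dict[str, list[str]], CyclicBasis | None]:
    cols = {"Intercept": np.ones(len(data))}
    terms: dict[str, list[str]] = {}
    for cov in covariates:
        if cov == SPLINE_COVARIATE:
            basis = basis or CyclicBasis(df)
            B = basis.transform(data[cov])
            names = [f"jd_cc{k + 1}" for k in range(B.shape[1])]
            for k, nm in enumerate(names):
                cols[nm] = B[:, k]
            terms[cov] = names
        else:
            dummies = pd.get_dummies(
                data[cov].astype("category"), prefix=cov, drop_first=True, dtype=float
            )
            for nm in dummies.columns:
                cols[nm] = dummies[nm].to_numpy()
            terms[cov] = list(dummies.columns)
    X = pd.DataFrame(cols, index=data.index)
    return X, terms, basis


@dataclass
class GeeFit:
    """A fitted blocked GEE with its design metadata."""

    spec: ModelSpec
    result: object  # statsmodels GEEResults
    X: pd.DataFrame
    y: np.ndarray
    groups: np.ndarray
    terms: dict[str, list[str]]
    basis: CyclicBasis | None
    data: pd.DataFrame = field(repr=False, default=None)

    @property
    def params(self) -> pd.Series:
        return self.result.params

    @property
    def cov_robust(self) -> np.ndarray:
        return np.asarray(self.result.cov_params())

    @property
    def ar1_param(self) -> float:
        dp = self.result.cov_struct.dep_params
        return float(dp) if np.isscalar(dp) else float(np.nan)

    @property
    def fittedvalues(self) -> np.ndarray:
        return np.asarray(self.result.fittedvalues)

    def qic(self) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            q = self.result.qic(scale=1.0)
        return float(q[0]) if np.ndim(q) else float(q)

    # -- inference ---------------------------------------------------------

    def wald_table(self) -> pd.DataFrame:
        """Robust Wald test per covariate block: X2, Df, P."""
        names = list(self.X.columns)
        C = self.cov_robust
        b = np.asarray(self.params)
        rows = []
        for term, term_cols in self.terms.items():
            idx = [names.index(c) for c in term_cols]
            bj = b[idx]
            Cj = C[np.ix_(idx, idx)]
            w = float(bj @ np.linalg.solve(Cj, bj))
            df_ = len(idx)
            rows.append(
                {"term": term, "X2": w, "Df": df_, "P": float(stats.chi2.sf(w, df_))}
            )
        return pd.DataFrame(rows)

    def partial_fit(
        self,
        term: str = SPLINE_COVARIATE,
        grid: np.ndarray | None = None,
        n_draws: int = 1000,
        seed: int = 0,
        level: float = 0.95,
    ) -> pd.DataFrame:
        """Partial-fit curve for one term, others at baseline.

        Confidence bands come from ``n_draws`` simulations from the robust
        coefficient covariance.  Returns columns x, eta, fit, lo, hi (fit and
        bands on the probability scale).
        """
        if term not in self.terms:
            raise ValueError(f"term {term!r} not in model")
        names = list(self.X.columns)
        if term == SPLINE_COVARIATE:
            x = grid if grid is not None else np.arange(1.0, 366.1, 1.0)
            Xg = np.zeros((len(x), len(names)))
            Xg[:, names.index("Intercept")] = 1.0
            B = self.basis.transform(x)
            for k, nm in enumerate(self.terms[term]):
                Xg[:, names.index(nm)] = B[:, k]
        else:
            levels = self.terms[term]
            x = np.arange(len(levels) + 1)  # baseline + each dummy level
            Xg = np.zeros((len(x), len(names)))
            Xg[:, names.index("Intercept")] = 1.0
            for k, nm in enumerate(levels):
                Xg[k + 1, names.index(nm)] = 1.0
        b = np.asarray(self.params)
        eta = Xg @ b
        rng = np.random.default_rng(seed)
        draws = rng.multivariate_normal(b, self.cov_robust, size=n_draws)
        etas = draws @ Xg.T
        alpha = (1 - level) / 2
        lo_eta, hi_eta = np.quantile(etas, [alpha, 1 - alpha], axis=0)
        expit = lambda v: 1 / (1 + np.exp(-v))
        return pd.DataFrame(
            {"x": x, "eta": eta, "fit": expit(eta), "lo": expit(lo_eta), "hi": expit(hi_eta)}
        )

    def seasonal_peak_day(self, **kwargs) -> float:
        pf = self.partial_fit(SPLINE_COVARIATE, **kwargs)
        return float(pf.loc[pf["eta"].idxmax(), "x"])


def fit_gee(data: pd.DataFrame, spec: ModelSpec, basis: CyclicBasis | None = None) -> GeeFit:
    """Fit a binomial logit GEE with contiguous fixed-length blocks.

    Rows are assumed time-ordered hourly observations; blocks are
    ``spec.block_len_h``-row windows (remainder rows form a short final
    block), independent between blocks, AR-1 within unless
    ``spec.corstr == "independence"``.
    """
    y = np.asarray(data[spec.response], dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("response must be binary")
    X, terms, basis = _build_design(data, spec.covariates, spec.df, basis)
    n = len(y)
    groups = np.arange(n) // spec.block_len_h
    cov = Autoregressive(grid=True) if spec.corstr == "ar1" else Independence()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GEE(y, X, groups=groups, family=sm.families.Binomial(), cov_struct=cov)
        result = model.fit(maxiter=200)
    if not getattr(result, "converged", True):
        raise RuntimeError(
            f"GEE did not converge for spec {spec}; params trace: {result.params}"
        )
    return GeeFit(spec, result, X, y, groups, terms, basis, data)


def qica(fit: GeeFit) -> float:
    """Quasilikelihood-under-independence criterion (scale fixed at 1)."""
    return fit.qic()


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------


@dataclass
class SelectionTrace:
    steps: list[dict]
    final_covariates: list[str]
    final_order: list[str]
    final_fit: GeeFit


def backward_select(data: pd.DataFrame, full_spec: ModelSpec) -> SelectionTrace:
    """Manual backwards stepwise selection by QICa.

    At each step the full current model and all leave-one-out reductions are
    fitted; the lowest-QICa candidate is carried forward.  Selection stops
    when no deletion lowers the QICa.  Ties break toward the earlier
    declaration order (reductions considered in covariate order; the current
    model wins exact ties).  The final covariate order ranks covariates by
    how much their removal increases the QICa.
    """
    covs = list(full_spec.covariates)
    basis = CyclicBasis(full_spec.df) if SPLINE_COVARIATE in covs else None
    cache: dict[tuple[str, ...], tuple[GeeFit, float]] = {}

    def _fit(c: list[str]) -> tuple[GeeFit, float]:
        key = tuple(c)
        if key not in cache:
            s = ModelSpec(full_spec.response, c, full_spec.df, full_spec.block_len_h,
                          full_spec.corstr)
            f = fit_gee(data, s, basis if SPLINE_COVARIATE in c else None)
            cache[key] = (f, qica(f))
        return cache[key]

    steps: list[dict] = []
    current_fit, current_q = _fit(covs)
    while covs:
        candidates: dict[str, float] = {}
        best_drop, best_q, best_fit = None, current_q, current_fit
        for c in covs:
            reduced = [x for x in covs if x != c]
            if not reduced:
                continue
            f, q = _fit(reduced)
            candidates[c] = q
            if q < best_q:  # strict: current model wins ties
                best_drop, best_q, best_fit = c, q, f
        steps.append(
            {"covariates": list(covs), "qica": current_q, "drop_candidates": candidates,
             "dropped": best_drop}
        )
        if best_drop is None:
            break
        covs = [x for x in covs if x != best_drop]
        current_fit, current_q = best_fit, best_q

    # order by QICa increase on removal (largest first)
    increases: dict[str, float] = {}
    for c in covs:
        reduced = [x for x in covs if x != c]
        if reduced:
            increases[c] = _fit(reduced)[1] - current_q
        else:
            increases[c] = np.inf  # single-covariate model: removal undefined
    order = sorted(covs, key=lambda c: (-increases[c], covs.index(c)))
    return SelectionTrace(steps, covs, order, current_fit)


def wald_prune(fit: GeeFit, alpha: float = 0.05) -> GeeFit:
    """Iteratively drop the least-significant covariate (robust Wald p >=
    alpha, largest first) and refit, until every remaining covariate is
    significant.  With nothing significant, an intercept-only fit returns."""
    current = fit
    while current.terms:
        table = current.wald_table()
        worst = table.loc[table["P"].idxmax()]
        if worst["P"] < alpha:
            return current
        remaining = [c for c in current.spec.covariates if c != worst["term"]]
        spec = ModelSpec(
            current.spec.response, remaining, current.spec.df,
            current.spec.block_len_h, current.spec.corstr,
        )
        current = fit_gee(current.data, spec, current.basis)
    return current


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def tjur_r2(y, p) -> float:
    """Coefficient of discrimination: mean(p | y=1) - mean(p | y=0)."""
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if not (y == 1).any() or not (y == 0).any():
        raise ValueError("need both successes and failures")
    return float(p[y == 1].mean() - p[y == 0].mean())


def binned_residuals(y, p, n_bins: int | None = None) -> pd.DataFrame:
    """Binned-residual table: observations ordered by fitted probability,
    split into ceil(sqrt(n)) equal-count bins; per bin the mean residual and
    the +/-2 SE band (SE = sqrt(mean(p(1-p))/n_bin))."""
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    n = y.size
    if n_bins is None:
        n_bins = int(np.ceil(np.sqrt(n)))
    order = np.argsort(p, kind="stable")
    splits = np.array_split(order, n_bins)
    rows = []
    for s in splits:
        if s.size == 0:
            continue
        pb, yb = p[s], y[s]
        resid = float((yb - pb).mean())
        se = float(np.sqrt(np.mean(pb * (1 - pb)) / s.size))
        rows.append(
            {"p_mean": float(pb.mean()), "resid_mean": resid, "band": 2 * se,
             "n": int(s.size), "inside": abs(resid) <= 2 * se}
        )
    return pd.DataFrame(rows)


def diagnostics(fit: GeeFit) -> dict:
    """Tjur R-squared and binned-residual coverage for a fitted model."""
    p = fit.fittedvalues
    br = binned_residuals(fit.y, p)
    return {
        "tjur_r2": tjur_r2(fit.y, p),
        "binned_residual_coverage": float(br["inside"].mean()),
        "n_bins": int(len(br)),
    }
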