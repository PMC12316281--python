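"""Statistical stage: screened, weighted regression of exposure indicators
on household characteristics.

The public surface follows the Model/Results idiom: build an
:class:`ExposureModel` from a coded profile table with
:meth:`ExposureModel.from_dataframe`, call :meth:`~ExposureModel.fit`, and
read estimates, Wald 95 % confidence intervals, GVIF collinearity
diagnostics and a ``summary()`` table off the returned
:class:`ExposureResults`.

Families
--------
* 3-class coded counts / diversity  → weighted baseline-category multinomial
  logit (baseline = lowest class), odds ratios per covariate level;
* binary 50 %-cutoff densities      → weighted logistic regression
  (statsmodels GLM-Binomial with frequency weights);
* exposure-area size (km²)          → weighted least squares, with a
  Shapiro–Wilk residual-normality statistic replacing a visual qq-plot.

Covariates are screened univariably by a weighted likelihood-ratio test and
kept when p < 0.2; multivariable models report model-based (not sandwich)
variances on the calibrated weights, so confidence intervals treat the
weights as frequency weights — a deliberate, documented simplification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import (
    RankDeficiencyError,
    SeparationWarning,
    SingularDesignError,
)
from .mnlogit import fit_intercept_only, fit_mnlogit

#: reference level per covariate (first level of each factor)
DEFAULT_REFERENCES: dict[str, str] = {
    "age": "<35",
    "education": "high_school_or_lower",
    "employment": "employed",
    "composition": "one_adult",
    "income": "q1",
    "car": "no",
    "home_location": "center",
}

COVARIATES = tuple(DEFAULT_REFERENCES)

SCREEN_ALPHA = 0.2
SIG_ALPHA = 0.05


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: outcome, covariates, references, area kind."""

    outcome: str
    covariates: tuple[str, ...]
    area_kind: str = "home_buffer"
    reference_levels: dict = field(default_factory=lambda: dict(DEFAULT_REFERENCES))


@dataclass
class ScreenResult:
    covariate: str
    p_value: float
    keep: bool
    flag: Optional[str] = None  # 'degenerate' | 'penalized'


# -------------------------------------------------------------- design build
def build_design(
    data: pd.DataFrame,
    covariates: Sequence[str],
    reference_levels: Optional[dict] = None,
) -> tuple[np.ndarray, list[str], dict[str, list[int]]]:
    """Dummy-coded design matrix with intercept.

    Returns the matrix, column names, and the column indices belonging to
    each covariate (for GVIF grouping).
    """
    refs = dict(DEFAULT_REFERENCES)
    if reference_levels:
        refs.update(reference_levels)
    cols = [np.ones(len(data))]
    names = ["intercept"]
    groups: dict[str, list[int]] = {}
    for cov in covariates:
        series = data[cov]
        if pd.api.types.is_numeric_dtype(series) and series.nunique() > 6:
            groups[cov] = [len(names)]
            cols.append(series.to_numpy(dtype=float))
            names.append(cov)
            continue
        levels = sorted(series.astype(str).unique())
        ref = refs.get(cov)
        if ref in levels:
            levels = [ref] + [l for l in levels if l != ref]
        groups[cov] = []
        for lev in levels[1:]:
            groups[cov].append(len(names))
            cols.append((series.astype(str) == lev).to_numpy(dtype=float))
            names.append(f"{cov}[{lev}]")
    X = np.column_stack(cols)
    return X, names, groups


def _normalize_weights(
    data: pd.DataFrame, weights
) -> np.ndarray:
    if weights is None:
        w = np.ones(len(data))
    else:
        w = np.asarray(weights, dtype=float)
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    return w / w.mean()


def _outcome_codes(series: pd.Series, order: Optional[Sequence[str]] = None):
    """Integer-code a categorical outcome; class 0 is the baseline."""
    vals = series.astype(str)
    if order is None:
        order = sorted(vals.unique())
    lookup = {c: i for i, c in enumerate(order)}
    unknown = set(vals.unique()) - set(order)
    if unknown:
        raise ValueError(f"outcome levels {sorted(unknown)} not in order")
    return vals.map(lookup).to_numpy(dtype=int), list(order)


OUTCOME_ORDERS = {
    "n_stores_class": ("T1", "T2", "T3"),
    "n_restaurants_class": ("T1", "T2", "T3"),
    "diversity_class": ("0-2", "3-5", "6-8"),
    "fv_class": ("lt50", "ge50"),
    "fastfood_class": ("lt50", "ge50"),
}


# ----------------------------------------------------------------- screening
def bivariate_screen(
    data: pd.DataFrame,
    outcome: str,
    covariate: str,
    weights=None,
    alpha: float = SCREEN_ALPHA,
) -> ScreenResult:
    """Weighted likelihood-ratio screen of one covariate against one outcome.

    The single-covariate weighted multinomial (or logistic, when the outcome
    is binary) model is compared with the intercept-only model; ``keep`` is
    true when p < ``alpha``.  A constant covariate cannot be tested and is
    dropped with the ``degenerate`` flag; an empty outcome x covariate cell
    triggers a tiny-ridge fallback and a :class:`SeparationWarning`.
    """
    w = _normalize_weights(data, weights)
    if data[covariate].nunique() < 2:
        return ScreenResult(covariate, float("nan"), False, flag="degenerate")
    if data[outcome].nunique() < 2:
        return ScreenResult(
            covariate, float("nan"), False, flag="degenerate_outcome"
        )
    y, order = _outcome_codes(data[outcome], OUTCOME_ORDERS.get(outcome))
    X, names, _ = build_design(data, [covariate])
    ridge = 0.0
    flag = None
    cell = pd.crosstab(data[outcome], data[covariate])
    if (cell == 0).any().any():
        warnings.warn(
            f"empty cell in {outcome} x {covariate}; penalized screen",
            SeparationWarning,
        )
        ridge = 1e-4
        flag = "penalized"
    fit = fit_mnlogit(y, X, w, ridge=ridge)
    ll0 = fit_intercept_only(y, w)
    lr = max(0.0, 2.0 * (fit.llf - ll0))
    df = (len(order) - 1) * (X.shape[1] - 1)
    p = float(stats.chi2.sf(lr, df))
    return ScreenResult(covariate, p, bool(p < alpha), flag=flag)


def screen_covariates(
    data: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str],
    weights=None,
    alpha: float = SCREEN_ALPHA,
) -> list[ScreenResult]:
    return [
        bivariate_screen(data, outcome, c, weights, alpha) for c in covariates
    ]


# ------------------------------------------------------------- Model/Results
class ExposureModel:
    """A weighted regression of one exposure outcome on covariates."""

    def __init__(
        self,
        data: pd.DataFrame,
        outcome: str,
        covariates: Sequence[str],
        weights=None,
        area_kind: str = "home_buffer",
        reference_levels: Optional[dict] = None,
        outcome_order: Optional[Sequence[str]] = None,
    ):
        self.data = data.reset_index(drop=True)
        self.outcome = outcome
        self.covariates = list(covariates)
        self.area_kind = area_kind
        self.weights = _normalize_weights(self.data, weights)
        self.reference_levels = dict(DEFAULT_REFERENCES)
        if reference_levels:
            self.reference_levels.update(reference_levels)
        self.X, self.exog_names, self.groups = build_design(
            self.data, self.covariates, self.reference_levels
        )
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise RankDeficiencyError(
                "design matrix is rank deficient (collinear covariates)"
            )
        series = self.data[outcome]
        order = outcome_order or OUTCOME_ORDERS.get(outcome)
        if pd.api.types.is_numeric_dtype(series) and order is None:
            self.family = "linear"
            self.y = series.to_numpy(dtype=float)
            self.outcome_levels = None
        else:
            self.y, self.outcome_levels = _outcome_codes(series, order)
            self.family = (
                "logistic" if len(self.outcome_levels) == 2 else "multinomial"
            )

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        outcome: str,
        covariates: Optional[Sequence[str]] = None,
        weights=None,
        screen: bool = False,
        **kwargs,
    ) -> "ExposureModel":
        """Build from a coded profile table; optionally screen covariates
        at p < 0.2 before the multivariable fit."""
        covs = list(covariates) if covariates else [
            c for c in COVARIATES if c in data.columns
        ]
        if screen:
            results = screen_covariates(data, outcome, covs, weights)
            covs = [r.covariate for r in results if r.keep]
        return cls(data, outcome, covs, weights=weights, **kwargs)

    def fit(self, ridge: float = 0.0) -> "ExposureResults":
        """Fit the model.

        ``ridge`` adds a tiny L2 penalty to the multinomial likelihood; it is
        the documented fallback for quasi-separated categorical designs and
        leaves well-identified fits essentially unchanged.
        """
        if self.family == "linear":
            res = sm.WLS(self.y, self.X, weights=self.weights).fit()
            resid = self.y - res.fittedvalues
            if np.allclose(resid, 0.0, atol=1e-10):
                shapiro = (1.0, 1.0)  # degenerate: perfect fit
            else:
                shapiro = stats.shapiro(resid)
            return ExposureResults(
                model=self,
                params=res.params,
                cov=np.asarray(res.cov_params()),
                llf=float(res.llf),
                converged=True,
                extra={
                    "r_squared": float(res.rsquared),
                    "shapiro_stat": float(shapiro[0]),
                    "shapiro_p": float(shapiro[1]),
                    "resid": resid,
                },
            )
        if self.family == "logistic":
            glm = sm.GLM(
                self.y,
                self.X,
                family=sm.families.Binomial(),
                freq_weights=self.weights,
            )
            res = glm.fit()
            return ExposureResults(
                model=self,
                params=np.asarray(res.params),
                cov=np.asarray(res.cov_params()),
                llf=float(res.llf),
                converged=bool(res.converged),
            )
        fit = fit_mnlogit(self.y, self.X, self.weights, ridge=ridge)
        return ExposureResults(
            model=self,
            params=fit.params,  # (K-1, p)
            cov=fit.cov,
            llf=fit.llf,
            converged=fit.converged,
        )


class ExposureResults:
    """Estimates, uncertainties and diagnostics of a fitted exposure model."""

    def __init__(self, model, params, cov, llf, converged, extra=None):
        self.model = model
        self.params = params
        self.cov = cov
        self.llf = llf
        self.converged = converged
        self.extra = extra or {}

    # ------------------------------------------------------------- estimates
    @property
    def estimates(self) -> pd.DataFrame:
        """Tidy effect table: one row per covariate level (x outcome contrast).

        Linear models report coefficients (``or_`` column holds the
        coefficient, CI on the identity scale); logit-family models report
        odds ratios with Wald 95 % CIs.  Reference levels appear with
        OR = 1 and a degenerate CI.
        """
        m = self.model
        rows = []
        if m.family == "multinomial":
            K = len(m.outcome_levels)
            p = m.X.shape[1]
            bse = np.sqrt(np.diag(self.cov)).reshape(K - 1, p)
            for k in range(1, K):
                contrast = f"{m.outcome_levels[k]} vs {m.outcome_levels[0]}"
                rows.extend(
                    self._family_rows(
                        self.params[k - 1], bse[k - 1], contrast, log_scale=True
                    )
                )
        else:
            bse = np.sqrt(np.diag(self.cov))
            if m.family == "logistic":
                contrast = f"{m.outcome_levels[1]} vs {m.outcome_levels[0]}"
                rows = self._family_rows(self.params, bse, contrast, True)
            else:
                rows = self._family_rows(self.params, bse, "coef", False)
        df = pd.DataFrame(rows)
        df.insert(0, "outcome", m.outcome)
        df.insert(1, "area_kind", m.area_kind)
        return df

    def _family_rows(self, beta, bse, contrast, log_scale):
        m = self.model
        z = stats.norm.ppf(0.975)
        rows = []
        for cov_name, idxs in m.groups.items():
            ref = m.reference_levels.get(cov_name)
            if ref is not None and any(
                m.exog_names[i].startswith(f"{cov_name}[") for i in idxs
            ):
                rows.append(
                    {
                        "covariate": cov_name,
                        "level": ref,
                        "contrast": contrast,
                        "or_": 1.0 if log_scale else 0.0,
                        "ci_low": 1.0 if log_scale else 0.0,
                        "ci_high": 1.0 if log_scale else 0.0,
                        "p": np.nan,
                        "reference": True,
                    }
                )
            for i in idxs:
                b, se = beta[i], bse[i]
                lo, hi = b - z * se, b + z * se
                name = m.exog_names[i]
                level = name.split("[", 1)[1][:-1] if "[" in name else name
                rows.append(
                    {
                        "covariate": cov_name,
                        "level": level,
                        "contrast": contrast,
                        "or_": float(np.exp(b)) if log_scale else float(b),
                        "ci_low": float(np.exp(lo)) if log_scale else float(lo),
                        "ci_high": float(np.exp(hi)) if log_scale else float(hi),
                        "p": float(2 * stats.norm.sf(abs(b / se)))
                        if se > 0
                        else np.nan,
                        "reference": False,
                    }
                )
        return rows

    # ----------------------------------------------------------- diagnostics
    def gvif(self) -> pd.DataFrame:
        """Generalized variance-inflation factors of the fitted design."""
        return gvif(self.model.X[:, 1:],
                    {c: [i - 1 for i in idxs]
                     for c, idxs in self.model.groups.items()})

    def summary(self) -> str:
        m = self.model
        lines = [
            f"Exposure model: {m.outcome} ({m.family}), area={m.area_kind}",
            f"n = {len(m.data)}, weighted n = {m.weights.sum():.1f}, "
            f"log-likelihood = {self.llf:.2f}, converged = {self.converged}",
        ]
        if "r_squared" in self.extra:
            lines.append(
                f"R^2 = {self.extra['r_squared']:.4f}, Shapiro-Wilk W = "
                f"{self.extra['shapiro_stat']:.4f} "
                f"(p = {self.extra['shapiro_p']:.3g})"
            )
        est = self.estimates
        hdr = ("covariate", "level", "contrast", "or_", "ci_low", "ci_high", "p")
        lines.append("-" * 86)
        lines.append(
            f"{'covariate':<14}{'level':<22}{'contrast':<14}"
            f"{'OR/coef':>9}{'2.5%':>9}{'97.5%':>9}{'p':>9}"
        )
        for _, r in est.iterrows():
            ptxt = "" if np.isnan(r["p"]) else f"{r['p']:.4f}"
            lines.append(
                f"{r['covariate']:<14}{str(r['level'])[:21]:<22}"
                f"{str(r['contrast'])[:13]:<14}{r['or_']:>9.3f}"
                f"{r['ci_low']:>9.3f}{r['ci_high']:>9.3f}{ptxt:>9}"
            )
        return "\n".join(lines)


# ------------------------------------------------------- functional wrappers
def fit_multinomial(
    data: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str],
    weights=None,
    **kwargs,
) -> ExposureResults:
    return ExposureModel(data, outcome, covariates, weights, **kwargs).fit()


def fit_logistic(
    data: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str],
    weights=None,
    **kwargs,
) -> ExposureResults:
    res = ExposureModel(data, outcome, covariates, weights, **kwargs)
    if res.family != "logistic":
        raise ValueError(f"outcome {outcome!r} is not binary")
    return res.fit()


def fit_linear_area(
    data: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str],
    weights=None,
    **kwargs,
) -> ExposureResults:
    model = ExposureModel(data, outcome, covariates, weights, **kwargs)
    if model.family != "linear":
        raise ValueError(f"outcome {outcome!r} is not numeric")
    return model.fit()


# ------------------------------------------------------------------- GVIF
def gvif(
    design: np.ndarray, groups: dict[str, list[int]]
) -> pd.DataFrame:
    """GVIF per covariate via determinant ratios of correlation submatrices.

    ``design`` excludes the intercept; ``groups`` maps covariate name to its
    column indices.  GVIF_j = det(R_j) det(R_-j) / det(R); the adjusted value
    GVIF^(1/(2 df)) is comparable across covariates with different numbers of
    dummy columns, with < 5 conventionally acceptable.
    """
    X = np.asarray(design, dtype=float)
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    if (sd == 0).any():
        raise SingularDesignError("constant column in design")
    Z = Xc / sd
    R = np.corrcoef(Z, rowvar=False)
    R = np.atleast_2d(R)
    detR = np.linalg.det(R)
    if abs(detR) < 1e-12:
        raise SingularDesignError(
            "design correlation matrix is singular (aliased covariates)"
        )
    rows = []
    all_idx = np.arange(X.shape[1])
    for cov_name, idxs in groups.items():
        idxs = np.asarray(idxs)
        rest = np.setdiff1d(all_idx, idxs)
        det1 = np.linalg.det(np.atleast_2d(R[np.ix_(idxs, idxs)]))
        det2 = (
            np.linalg.det(np.atleast_2d(R[np.ix_(rest, rest)]))
            if len(rest)
            else 1.0
        )
        g = float(det1 * det2 / detR)
        g = max(g, 1.0) if g > 1 - 1e-9 else g  # clip numerical dips below 1
        df = len(idxs)
        adj = g ** (1.0 / (2.0 * df))
        rows.append(
            {
                "covariate": cov_name,
                "gvif": g,
                "df": df,
                "adjusted_gvif": adj,
                "acceptable": bool(adj < 5.0),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------- comparison
def compare_measures(
    home: pd.DataFrame,
    activity: pd.DataFrame,
    alpha: float = SIG_ALPHA,
) -> pd.DataFrame:
    """Side-by-side effects for the two exposure measures with a flip flag.

    A *flip* is a covariate level significant (p < alpha) under one measure
    but not the other.
    """
    keys = ["outcome", "covariate", "level", "contrast"]
    h = home.rename(
        columns={c: f"{c}_home" for c in ("or_", "ci_low", "ci_high", "p")}
    ).drop(columns=["area_kind"], errors="ignore")
    a = activity.rename(
        columns={c: f"{c}_activity" for c in ("or_", "ci_low", "ci_high", "p")}
    ).drop(columns=["area_kind"], errors="ignore")
    merged = h.merge(a, on=keys + ["reference"], how="inner")
    sig_h = merged["p_home"] < alpha
    sig_a = merged["p_activity"] < alpha
    merged["significant_home"] = sig_h.fillna(False)
    merged["significant_activity"] = sig_a.fillna(False)
    merged["flip"] = merged["significant_home"] ^ merged["significant_activity"]
    merged.loc[merged["reference"], "flip"] = False
    return merged
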