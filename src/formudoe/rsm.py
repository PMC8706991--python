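"""Full-quadratic response-surface regression with RSM diagnostics.

The model for a response :math:`y` over :math:`k` factors is the
second-order polynomial

.. math::

    y = b_0 + \\sum_i b_i x_i + \\sum_{i<j} b_{ij} x_i x_j
        + \\sum_i b_{ii} x_i^2 + \\varepsilon,

fitted by ordinary least squares (p = 1 + k + k(k-1)/2 + k parameters;
p = 10 at k = 3).  Beyond the usual OLS output the results object carries
the diagnostics response-surface software reports alongside the ANOVA:

* PRESS, the prediction error sum of squares from leave-one-out residuals
  ``e_i / (1 - h_ii)``, and the predicted R^2 = 1 - PRESS/SST;
* *adequate precision*, a signal-to-noise ratio comparing the range of
  predicted values at the design points to the average prediction
  standard error, ``(max(yhat) - min(yhat)) / sqrt(p * MSE / n)``; values
  above 4 are conventionally read as an adequate signal.

Fits may be performed on the coded (-1..+1) or actual (laboratory-unit)
scale.  The two are linear reparameterizations of each other, so R^2,
adjusted/predicted R^2, the overall F test and the fitted values are
identical; only the coefficients differ.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .design import DesignMatrix, FactorDef
from .errors import DegenerateResponseError, LeverageError, SingularDesignError

__all__ = [
    "quadratic_row",
    "quadratic_terms",
    "quadratic_matrix",
    "ResponseSurface",
    "ResponseSurfaceResults",
]


def quadratic_terms(names) -> list[str]:
    """Term labels of the full quadratic model, in canonical column order:
    intercept, linear, interactions (lexicographic pairs), pure quadratics."""
    names = list(names)
    terms = ["Intercept"] + names
    terms += [f"{a}*{b}" for i, a in enumerate(names) for b in names[i + 1 :]]
    terms += [f"{n}^2" for n in names]
    return terms


def quadratic_row(x) -> np.ndarray:
    """Model row [1, x1..xk, x1x2, x1x3, ..., x1^2, ..., xk^2] for one point."""
    return quadratic_matrix(np.atleast_2d(np.asarray(x, dtype=float)))[0]


def quadratic_matrix(X: np.ndarray) -> np.ndarray:
    """Stacked quadratic rows for a (n, k) array of factor settings."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, k = X.shape
    cols = [np.ones(n)]
    cols += [X[:, i] for i in range(k)]
    cols += [X[:, i] * X[:, j] for i in range(k) for j in range(i + 1, k)]
    cols += [X[:, i] ** 2 for i in range(k)]
    return np.column_stack(cols)


class ResponseSurface:
    """Quadratic response-surface model of one response over a design.

    Parameters
    ----------
    design : DesignMatrix
        Factor settings plus response columns.
    response : str
        Name of the response column to model.
    scale : {"coded", "actual"}
        Whether the polynomial is expressed in coded units (the default,
        used for diagnostics) or in actual laboratory units (the scale on
        which practitioners print the model equation).
    terms : sequence of str, optional
        Subset of the full-quadratic term labels (see
        :func:`quadratic_terms`) to retain; default keeps all p terms.
    """

    def __init__(self, design: DesignMatrix, response: str, scale: str = "coded",
                 terms=None):
        if scale not in ("coded", "actual"):
            raise ValueError("scale must be 'coded' or 'actual'")
        self.design = design
        self.response_name = response
        self.scale = scale
        self._all_terms = quadratic_terms(design.factor_names)
        if terms is None:
            self.terms = list(self._all_terms)
        else:
            unknown = [t for t in terms if t not in self._all_terms]
            if unknown:
                raise ValueError(f"unknown model terms: {unknown}")
            self.terms = [t for t in self._all_terms if t in set(terms)]
        self.y = design.response(response)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, factors, response: str,
                       scale: str = "coded", terms=None) -> "ResponseSurface":
        """Build from a plain table of actual factor values and responses."""
        return cls(DesignMatrix.from_frame(df, factors), response, scale, terms)

    # -- model matrix --------------------------------------------------------
    def _points(self, coded_points=None) -> np.ndarray:
        if coded_points is None:
            coded_points = self.design.coded
        coded_points = np.atleast_2d(np.asarray(coded_points, dtype=float))
        if self.scale == "coded":
            return coded_points
        centers = np.array([f.center for f in self.design.factors])
        widths = np.array([f.half_width for f in self.design.factors])
        return centers + coded_points * widths

    def exog(self, coded_points=None) -> np.ndarray:
        full = quadratic_matrix(self._points(coded_points))
        keep = [self._all_terms.index(t) for t in self.terms]
        return full[:, keep]

    def fit(self) -> "ResponseSurfaceResults":
        """OLS fit; raises on rank deficiency or a constant response."""
        X = self.exog()
        n, p = X.shape
        if n < p:
            raise SingularDesignError(
                f"{n} runs cannot identify {p} parameters"
            )
        if np.linalg.matrix_rank(X) < p:
            raise SingularDesignError("model matrix is rank deficient")
        sst = float(np.sum((self.y - self.y.mean()) ** 2))
        if sst == 0.0:
            raise DegenerateResponseError(
                f"response {self.response_name!r} is constant"
            )
        ols = sm.OLS(self.y, X).fit()
        return ResponseSurfaceResults(self, ols)


class ResponseSurfaceResults:
    """Fitted quadratic surface: coefficients, diagnostics, prediction.

    Mirrors the statsmodels results idiom: ``params``, ``bse``,
    ``pvalues`` are pandas Series indexed by term label; ``summary()``
    renders a plain-text report.
    """

    def __init__(self, model: ResponseSurface, ols):
        self.model = model
        self._ols = ols
        self.nobs = int(ols.nobs)
        self.df_model = int(ols.df_model)
        self.df_resid = int(ols.df_resid)
        idx = pd.Index(model.terms, name="term")
        self.params = pd.Series(ols.params, index=idx)
        self.bse = pd.Series(ols.bse, index=idx)
        self.tvalues = pd.Series(ols.tvalues, index=idx)
        self.pvalues = pd.Series(ols.pvalues, index=idx)
        self.fittedvalues = np.asarray(ols.fittedvalues)
        self.resid = np.asarray(ols.resid)
        self.mse_resid = float(ols.mse_resid) if self.df_resid > 0 else 0.0
        self.rsquared = float(ols.rsquared)
        self.rsquared_adj = float(ols.rsquared_adj)
        self.fvalue = float(ols.fvalue) if self.df_resid > 0 else np.inf
        self.f_pvalue = float(ols.f_pvalue) if self.df_resid > 0 else np.nan
        self._sst = float(np.sum((model.y - model.y.mean()) ** 2))

    # -- aliases matching field vocabulary -----------------------------------
    @property
    def response_name(self) -> str:
        return self.model.response_name

    @property
    def factors(self):
        return self.model.design.factors

    @property
    def r2(self) -> float:
        return self.rsquared

    @property
    def adj_r2(self) -> float:
        return self.rsquared_adj

    @property
    def n(self) -> int:
        return self.nobs

    @property
    def p(self) -> int:
        return len(self.params)

    @property
    def _is_exact_fit(self) -> bool:
        # residual variance indistinguishable from floating-point noise
        scale = self._sst / max(self.nobs - 1, 1)
        return self.df_resid <= 0 or self.mse_resid <= 1e-12 * scale

    # -- leave-one-out diagnostics --------------------------------------------
    @property
    def leverages(self) -> np.ndarray:
        X = self.model.exog()
        # hat diag via economic QR: h_ii = ||Q_i.||^2
        q, _ = np.linalg.qr(X)
        return np.sum(q**2, axis=1)

    @property
    def press(self) -> float:
        """Prediction error sum of squares, Sum (e_i / (1 - h_ii))^2."""
        h = self.leverages
        if np.any(h >= 1.0 - 1e-12):
            raise LeverageError(
                "a run has leverage 1: its leave-one-out residual is undefined"
            )
        return float(np.sum((self.resid / (1.0 - h)) ** 2))

    @property
    def pred_r2(self) -> float:
        """Predicted R^2 = 1 - PRESS/SST; <= R^2 on the fitting data."""
        return 1.0 - self.press / self._sst

    @property
    def adequate_precision(self) -> float:
        """Signal-to-noise: predicted range over sqrt(p * MSE / n).

        With an exactly interpolating fit (MSE = 0) the statistic is
        infinite; ``inf`` is returned rather than raising.
        """
        if self._is_exact_fit:
            return np.inf
        signal = float(self.fittedvalues.max() - self.fittedvalues.min())
        return signal / np.sqrt(self.p * self.mse_resid / self.nobs)

    def term_significance(self) -> pd.Series:
        """Two-sided t-test p-value per coefficient, (n - p) residual dof.

        With zero residual variance the tests are undefined and every
        entry is NaN (the sentinel for "exact fit, nothing to test").
        """
        if self.df_resid <= 0:
            raise DegenerateResponseError("no residual degrees of freedom")
        if self._is_exact_fit:
            return pd.Series(np.nan, index=self.params.index)
        return self.pvalues.copy()

    # -- prediction ------------------------------------------------------------
    def predict(self, coded_points) -> np.ndarray:
        """Predicted response at coded factor settings (any scale fit)."""
        return self.model.exog(coded_points) @ self.params.to_numpy()

    # -- reporting ---------------------------------------------------------------
    def equation(self, ndigits: int = 2) -> str:
        """The fitted polynomial as a one-line equation string."""
        parts = [f"{self.params['Intercept']:.{ndigits}f}"]
        for term, b in self.params.items():
            if term == "Intercept":
                continue
            sign = "-" if b < 0 else "+"
            parts.append(f"{sign} {abs(b):.{ndigits}f}·{term}")
        return f"{self.model.response_name} = " + " ".join(parts)

    def diagnostics(self) -> dict:
        return {
            "response": self.model.response_name,
            "scale": self.model.scale,
            "n": self.nobs,
            "p": self.p,
            "r2": self.rsquared,
            "adj_r2": self.rsquared_adj,
            "press": self.press,
            "pred_r2": self.pred_r2,
            "adequate_precision": self.adequate_precision,
            "model_f_p": self.f_pvalue,
            "mse": self.mse_resid,
        }

    def to_json(self, path=None) -> str:
        payload = {
            "coefficients": {t: float(v) for t, v in self.params.items()},
            "term_p": {t: float(v) for t, v in self.pvalues.items()},
            "factors": [
                {"name": f.name, "center": f.center, "half_width": f.half_width,
                 "unit_label": f.unit_label}
                for f in self.factors
            ],
            **{k: (None if isinstance(v, float) and not np.isfinite(v) else v)
               for k, v in self.diagnostics().items()},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    def summary(self) -> str:
        d = self.diagnostics()
        lines = [
            f"Quadratic response surface: {d['response']}  [{d['scale']} units]",
            f"  n = {d['n']}, p = {d['p']}",
            f"  R^2 = {d['r2']:.4f}   adj R^2 = {d['adj_r2']:.4f}   "
            f"pred R^2 = {d['pred_r2']:.4f}",
            f"  PRESS = {d['press']:.4f}   adequate precision = "
            f"{d['adequate_precision']:.4f}",
            f"  model F p-value = {d['model_f_p']:.3g}",
            "",
            f"  {'term':<16}{'coef':>12}{'std err':>12}{'t':>10}{'P>|t|':>10}",
        ]
        for term in self.params.index:
            lines.append(
                f"  {term:<16}{self.params[term]:>12.4f}{self.bse[term]:>12.4f}"
                f"{self.tvalues[term]:>10.3f}{self.pvalues[term]:>10.4f}"
            )
        lines += ["", "  " + self.equation()]
        return "\n".join(lines)

    def __repr__(self):
        return (
            f"<ResponseSurfaceResults {self.model.response_name!r} "
            f"R2={self.rsquared:.4f}>"
        )


class StoredSurface:
    """A fitted quadratic surface reconstructed from its JSON report.

    Carries just enough (coefficients, scale, factor definitions) to
    predict and to drive desirability optimization, without the original
    data.
    """

    def __init__(self, response_name: str, scale: str, factors, coefficients: dict):
        self.response_name = response_name
        self.scale = scale
        self.factors = tuple(factors)
        all_terms = quadratic_terms([f.name for f in self.factors])
        unknown = [t for t in coefficients if t not in all_terms]
        if unknown:
            raise ValueError(f"unknown model terms: {unknown}")
        self.terms = [t for t in all_terms if t in coefficients]
        self._keep = [all_terms.index(t) for t in self.terms]
        self._beta = np.array([coefficients[t] for t in self.terms], dtype=float)

    @classmethod
    def from_json(cls, path) -> "StoredSurface":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        factors = [FactorDef(**f) for f in payload["factors"]]
        return cls(payload["response"], payload["scale"], factors,
                   payload["coefficients"])

    def predict(self, coded_points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(coded_points, dtype=float))
        if self.scale == "actual":
            centers = np.array([f.center for f in self.factors])
            widths = np.array([f.half_width for f in self.factors])
            pts = centers + pts * widths
        return quadratic_matrix(pts)[:, self._keep] @ self._beta
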