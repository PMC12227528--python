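"""Two-part (hurdle) differential-expression test.

Zero-inflated single-cell expression is modelled with two components on a
shared design: a logistic *detection* model for the indicator ``y > 0`` and a
Gaussian *continuous* model for the positive log-normalized values.  The test
statistic for a term is the sum of the two components' likelihood-ratio
chi-squares, referred to a chi-square with as many degrees of freedom as
components were estimable (2, or 1 when one component is degenerate).

The combined model fold change follows the two-part convention: predicted mean
expression is detection probability times the positive-component mean, both
evaluated at covariate means, and the case-minus-control difference is
reported on the log2 scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .fitters import SingularDesignError, logit_fit, ols_fit

__all__ = ["HurdleModel", "HurdleResults", "fit_hurdle", "bh_adjust"]

_LN2 = np.log(2.0)


class NotDetectedError(ValueError):
    """The gene has no positive observation: nothing to test."""


class CollinearDesignError(ValueError):
    """The test term is constant or collinear after degeneracy handling."""


@dataclass
class HurdleResults:
    """Per-gene hurdle test output.

    ``df`` counts the estimable components; degenerate components (fewer than
    3 usable cells, constant response, or inestimable coefficients) contribute
    a zero chi-square with reduced df rather than aborting the gene.
    """

    beta_det: float
    beta_cont: float
    chi2_det: float
    chi2_cont: float
    df: int
    p: float
    log2fc_model: float
    n_cells_used: int
    status: str = "ok"

    @property
    def chi2(self) -> float:
        return self.chi2_det + self.chi2_cont

    def summary(self) -> str:
        lines = [
            "Hurdle likelihood-ratio test",
            "----------------------------",
            f"cells used          {self.n_cells_used}",
            f"detection beta      {self.beta_det: .4f}   chi2 {self.chi2_det:.4f}",
            f"continuous beta     {self.beta_cont: .4f}   chi2 {self.chi2_cont:.4f}",
            f"combined chi2 (df={self.df})  {self.chi2:.4f}",
            f"p-value             {self.p:.4g}",
            f"model log2 FC       {self.log2fc_model: .4f}",
            f"status              {self.status}",
        ]
        return "\n".join(lines)


def _drop_constant(X: np.ndarray, keep: np.ndarray) -> np.ndarray:
    """Indices of columns to retain: intercept plus non-constant columns."""
    const = np.all(X == X[0], axis=0)
    const[0] = False  # intercept always kept
    return keep & ~const


def _component_lrt(X: np.ndarray, y: np.ndarray, test_idx: int, kind: str):
    """LRT chi-square for dropping one column; returns (chi2, beta, fit, cols)."""
    keep = _drop_constant(X, np.ones(X.shape[1], dtype=bool))
    if not keep[test_idx]:
        raise CollinearDesignError("test term constant within component")
    Xk = X[:, keep]
    t_pos = int(np.flatnonzero(np.flatnonzero(keep) == test_idx)[0])
    red = np.ones(Xk.shape[1], dtype=bool)
    red[t_pos] = False
    if kind == "logit":
        full = logit_fit(Xk, y)
        reduced = logit_fit(Xk[:, red], y)
    else:
        full = ols_fit(Xk, y)
        reduced = ols_fit(Xk[:, red], y)
    chi2 = max(0.0, 2.0 * (full.llf - reduced.llf))
    return chi2, float(full.beta[t_pos]), full, keep


class HurdleModel:
    """Hurdle model for one gene: ``HurdleModel(y, X, test_term).fit()``.

    Parameters
    ----------
    endog
        Per-cell normalized expression (non-negative).
    exog
        Design matrix as a DataFrame with named columns; must contain an
        intercept column (any constant column works) first and ``test_term``.
    test_term
        Column whose likelihood-ratio chi-square is reported (the contrast).
    """

    def __init__(self, endog, exog: pd.DataFrame, test_term: str = "diagnosis"):
        self.endog = np.asarray(endog, dtype=float)
        if (self.endog < 0).any():
            raise ValueError("endog must be non-negative")
        if test_term not in exog.columns:
            raise ValueError(f"test term {test_term!r} not in design")
        self.exog = exog
        self.test_term = test_term
        self._X = exog.to_numpy(dtype=float)
        self._test_idx = int(exog.columns.get_loc(test_term))

    def fit(self) -> HurdleResults:
        y = self.endog
        X = self._X
        t_idx = self._test_idx
        detected = (y > 0).astype(float)
        n = len(y)
        if detected.sum() == 0:
            raise NotDetectedError("gene has no positive observation")
        if np.all(X[:, t_idx] == X[0, t_idx]):
            raise CollinearDesignError("test term constant across cells")

        status = "ok"
        # detection component -------------------------------------------------
        chi2_det, beta_det, df_det = 0.0, 0.0, 0
        det_fit = None
        n_det_classes = len(np.unique(detected))
        if n_det_classes == 2 and n >= 3:
            try:
                chi2_det, beta_det, det_fit, _ = _component_lrt(X, detected, t_idx, "logit")
                df_det = 1
            except (CollinearDesignError, SingularDesignError):
                status = "detection-degenerate"
        # continuous component ------------------------------------------------
        chi2_cont, beta_cont, df_cont = 0.0, 0.0, 0
        cont_fit, cont_keep = None, None
        pos = y > 0
        ypos = y[pos]
        if pos.sum() >= 3 and np.ptp(ypos) > 0:
            try:
                chi2_cont, beta_cont, cont_fit, cont_keep = _component_lrt(
                    X[pos], ypos, t_idx, "ols"
                )
                df_cont = 1
            except (CollinearDesignError, SingularDesignError):
                status = "continuous-degenerate" if status == "ok" else "degenerate"

        df = df_det + df_cont
        chi2 = chi2_det + chi2_cont
        p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
        if df == 0:
            status = "degenerate"
        p = min(max(p, np.nextafter(0, 1)), 1.0)

        log2fc = self._log2fc(X, y, detected, t_idx, det_fit, cont_fit, cont_keep, pos)
        return HurdleResults(
            beta_det=beta_det,
            beta_cont=beta_cont,
            chi2_det=chi2_det,
            chi2_cont=chi2_cont,
            df=df,
            p=p,
            log2fc_model=log2fc,
            n_cells_used=n,
            status=status,
        )

    def _log2fc(self, X, y, detected, t_idx, det_fit, cont_fit, cont_keep, pos):
        """MAST-style combined fold change: (p1*m1 - p0*m0) / log 2 at covariate means."""
        x_mean = X.mean(axis=0)

        def _at(level: float, keep_mask, beta, fallback):
            if beta is None:
                return fallback
            xv = x_mean.copy()
            xv[t_idx] = level
            return float(xv[keep_mask] @ beta)

        if det_fit is not None:
            keep = _drop_constant(X, np.ones(X.shape[1], dtype=bool))
            eta1 = np.clip(_at(1.0, keep, det_fit.beta, 0.0), -35, 35)
            eta0 = np.clip(_at(0.0, keep, det_fit.beta, 0.0), -35, 35)
            p1 = 1.0 / (1.0 + np.exp(-eta1))
            p0 = 1.0 / (1.0 + np.exp(-eta0))
        else:
            p1 = p0 = float(detected.mean())
        if cont_fit is not None:
            m1 = _at(1.0, cont_keep, cont_fit.beta, 0.0)
            m0 = _at(0.0, cont_keep, cont_fit.beta, 0.0)
        else:
            m1 = m0 = float(y[pos].mean()) if pos.any() else 0.0
        return (p1 * m1 - p0 * m0) / _LN2


def fit_hurdle(y, X: pd.DataFrame, test_term: str = "diagnosis") -> HurdleResults:
    """Convenience wrapper: fit the hurdle model and return its results."""
    return HurdleModel(y, X, test_term=test_term).fit()


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone in p-rank, <= 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
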