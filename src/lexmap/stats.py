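"""Model classes for the distance and coordinate analyses.

Two fitted-model families, organised the way statsmodels organises its
estimators (a model object built from data; ``fit()`` returns a results
object carrying estimates, uncertainties and a ``summary()`` table):

* :class:`CrossedLMM` — a Gaussian linear mixed model with two *crossed*
  random intercepts, ``y = X b + Z1 u1 + Z2 u2 + e`` with
  ``u1 ~ N(0, s1^2 I)``, ``u2 ~ N(0, s2^2 I)``, ``e ~ N(0, se^2 I)``.
  This is the structure of the pair-distance analyses: every observation is
  an unordered station pair and carries intercepts for both of its stations.
  Estimation is REML (or ML) with the deviance profiled over the two
  variance *ratios* ``g_k = s_k^2 / se^2``; for fixed ratios the fixed
  effects are generalised least squares and ``se^2`` has a closed form, so
  the optimisation is a 2-D derivative-free search. All linear algebra is
  reduced from n x n to q x q (q = number of random-intercept levels) via
  the Woodbury identity, so tables with tens of thousands of pairs fit in
  milliseconds.

* :class:`GroupInteractionOLS` — ordinary least squares for
  ``y ~ x * group`` with sum-to-zero group contrasts, the coordinate-model
  family (one continuous predictor, a city factor, their interaction;
  2G parameters for G groups). Term tests are marginal (Type-III-style)
  F tests, which sum coding makes meaningful.

Both results objects expose per-group *simple slopes* (the slope of the
continuous predictor within one group level, with a delta-method SE from the
coefficient covariance), the post-hoc summary the pair analyses report.

Inference convention: the mixed model reports Wald z / chi-square and
likelihood-ratio tests rather than F tests with approximated denominator
degrees of freedom; at the sample sizes these analyses run at the two are
asymptotically equivalent, and approximate-df machinery for crossed designs
is deliberately out of scope.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import scipy.stats
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "DesignInfo",
    "SimpleSlope",
    "interaction_design",
    "GroupInteractionOLS",
    "GroupInteractionOLSResults",
    "CrossedLMM",
    "CrossedLMMResults",
    "ConvergenceError",
    "fit_lm_interaction",
    "fit_crossed_lmm",
    "term_tests",
    "simple_slopes",
    "parse_mixed_formula",
]

_LOG2PI = float(np.log(2.0 * np.pi))

#: variance ratios below this are snapped to the zero boundary
_BOUNDARY_TOL = 1e-6


class ConvergenceError(RuntimeError):
    """REML/ML optimisation failed; carries the best deviance trace seen."""

    def __init__(self, message: str, trace: list[tuple[float, float, float]]):
        super().__init__(message)
        self.trace = trace


@dataclass
class SimpleSlope:
    """Per-group slope of the continuous predictor (post-hoc contrast)."""

    group: str
    slope: float
    se: float
    z: float
    p: float


@dataclass
class DesignInfo:
    """Bookkeeping for an ``x * group`` fixed-effects design."""

    x_name: str
    group_name: str
    levels: list[str]
    coding: str
    columns: list[str]
    x_col: int
    group_cols: list[int]
    inter_cols: list[int]
    terms: dict[str, list[int]] = field(default_factory=dict)

    def slope_contrast(self, level_index: int) -> np.ndarray:
        """Contrast vector c with c'b = simple slope in the given group."""
        c = np.zeros(len(self.columns))
        c[self.x_col] = 1.0
        G = len(self.levels)
        for j, col in enumerate(self.inter_cols):
            if self.coding == "sum":
                if level_index == j:
                    c[col] = 1.0
                elif level_index == G - 1:
                    c[col] = -1.0
            else:  # treatment: reference level is levels[0]
                if level_index == j + 1:
                    c[col] = 1.0
        return c


def interaction_design(
    x: Sequence[float],
    groups: Sequence[str] | None,
    coding: str = "sum",
    x_name: str = "x",
    group_name: str = "group",
) -> tuple[np.ndarray, DesignInfo]:
    """Build the ``1 + x + group + x:group`` design matrix.

    ``coding="sum"`` (default) uses sum-to-zero contrasts so that the ``x``
    coefficient is the slope averaged over group levels and marginal term
    tests are interpretable; ``coding="treatment"`` uses the first level as
    reference for coefficient-level replication. With one group level (or
    ``groups=None``) the design degenerates to ``1 + x``.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if groups is None:
        groups = np.array(["all"] * n)
    groups = np.asarray(groups).astype(str)
    if len(groups) != n:
        raise ValueError("x and groups must be parallel")
    if coding not in ("sum", "treatment"):
        raise ValueError(f"coding must be 'sum' or 'treatment', got {coding!r}")
    levels = sorted(pd.unique(groups))
    G = len(levels)
    cols = [np.ones(n), x]
    names = ["Intercept", x_name]
    info = DesignInfo(
        x_name=x_name,
        group_name=group_name,
        levels=list(levels),
        coding=coding,
        columns=names,
        x_col=1,
        group_cols=[],
        inter_cols=[],
        terms={"Intercept": [0], x_name: [1]},
    )
    if G > 1:
        level_idx = {lev: k for k, lev in enumerate(levels)}
        gi = np.array([level_idx[g] for g in groups])
        contrasts = np.zeros((G, G - 1))
        if coding == "sum":
            for j in range(G - 1):
                contrasts[j, j] = 1.0
            contrasts[G - 1, :] = -1.0
            tags = [f"[S.{lev}]" for lev in levels[:-1]]
        else:
            for j in range(G - 1):
                contrasts[j + 1, j] = 1.0
            tags = [f"[T.{lev}]" for lev in levels[1:]]
        gmat = contrasts[gi]  # (n, G-1)
        for j in range(G - 1):
            cols.append(gmat[:, j])
            names.append(f"{group_name}{tags[j]}")
            info.group_cols.append(len(names) - 1)
        for j in range(G - 1):
            cols.append(x * gmat[:, j])
            names.append(f"{x_name}:{group_name}{tags[j]}")
            info.inter_cols.append(len(names) - 1)
        info.terms[group_name] = list(info.group_cols)
        info.terms[f"{x_name}:{group_name}"] = list(info.inter_cols)
    info.columns = names
    return np.column_stack(cols), info


def _std_params(
    params: np.ndarray, X: np.ndarray, y: np.ndarray, names: Sequence[str]
) -> pd.Series:
    """Standardised coefficients: b * sd(x_col) / sd(y); NaN for the intercept."""
    sy = y.std(ddof=1)
    out = np.full(len(params), np.nan)
    for j, name in enumerate(names):
        sx = X[:, j].std(ddof=1)
        if sx > 0 and sy > 0:
            out[j] = params[j] * sx / sy
    return pd.Series(out, index=list(names))


def _slopes_from_cov(
    params: np.ndarray,
    cov: np.ndarray,
    info: DesignInfo,
    pdist,
) -> list[SimpleSlope]:
    out = []
    for k, lev in enumerate(info.levels):
        c = info.slope_contrast(k)
        b = float(c @ params)
        se = float(np.sqrt(c @ cov @ c))
        z = b / se
        out.append(SimpleSlope(group=lev, slope=b, se=se, z=z, p=float(pdist(abs(z)) * 2)))
    return out


# ---------------------------------------------------------------------------
# OLS interaction model
# ---------------------------------------------------------------------------


class GroupInteractionOLS:
    """OLS for ``y ~ x * group`` (continuous predictor x categorical factor)."""

    def __init__(
        self,
        endog: Sequence[float],
        x: Sequence[float],
        groups: Sequence[str] | None = None,
        coding: str = "sum",
        x_name: str = "x",
        group_name: str = "group",
    ):
        self.endog = np.asarray(endog, dtype=float)
        self.exog, self.design_info = interaction_design(
            x, groups, coding=coding, x_name=x_name, group_name=group_name
        )
        n, p = self.exog.shape
        if n <= p:
            raise ValueError(f"{n} observations cannot identify {p} parameters")
        levels = self.design_info.levels
        if groups is not None and len(levels) > 1:
            groups = np.asarray(groups).astype(str)
            xarr = np.asarray(x, dtype=float)
            for lev in levels:
                block = xarr[groups == lev]
                if len(block) < 3:
                    raise ValueError(f"group {lev!r} has fewer than 3 observations")
                if block.std() == 0.0:
                    raise ValueError(f"predictor is constant within group {lev!r}")

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        y: str,
        x: str,
        group: str | None = None,
        coding: str = "sum",
    ) -> "GroupInteractionOLS":
        return cls(
            endog=data[y].to_numpy(),
            x=data[x].to_numpy(),
            groups=None if group is None else data[group].to_numpy(),
            coding=coding,
            x_name=x,
            group_name=group or "group",
        )

    def fit(self) -> "GroupInteractionOLSResults":
        res = sm.OLS(self.endog, self.exog).fit()
        rank = np.linalg.matrix_rank(self.exog)
        if rank < self.exog.shape[1]:
            # name the first aliased column for the error message
            _, r = np.linalg.qr(self.exog)
            bad = int(np.argmin(np.abs(np.diag(r))))
            raise ValueError(
                f"design is rank deficient; aliased term near column "
                f"{self.design_info.columns[bad]!r}"
            )
        return GroupInteractionOLSResults(self, res)


class GroupInteractionOLSResults:
    """OLS results with marginal term tests and per-group simple slopes."""

    def __init__(self, model: GroupInteractionOLS, smres):
        self.model = model
        self._smres = smres
        names = model.design_info.columns
        self.params = pd.Series(smres.params, index=names)
        self.bse = pd.Series(smres.bse, index=names)
        self.tvalues = pd.Series(smres.tvalues, index=names)
        self.pvalues = pd.Series(smres.pvalues, index=names)
        self.df_resid = int(smres.df_resid)
        self.nobs = int(smres.nobs)
        self.rsquared = float(smres.rsquared)
        self.resid = np.asarray(smres.resid)
        self.std_params = _std_params(
            np.asarray(smres.params), model.exog, model.endog, names
        )

    def cov_params(self) -> np.ndarray:
        return np.asarray(self._smres.cov_params())

    def term_tests(self) -> pd.DataFrame:
        """Marginal (Type-III-style) F test for each non-intercept term."""
        rows = []
        p = len(self.params)
        for term, cols in self.model.design_info.terms.items():
            if term == "Intercept":
                continue
            R = np.zeros((len(cols), p))
            for i, c in enumerate(cols):
                R[i, c] = 1.0
            ft = self._smres.f_test(R)
            rows.append(
                (term, float(ft.fvalue), int(ft.df_num), int(ft.df_denom), float(ft.pvalue))
            )
        return pd.DataFrame(rows, columns=["term", "F", "df_num", "df_den", "p"])

    def simple_slopes(self) -> list[SimpleSlope]:
        """Slope of x within each group level (t-based p values)."""
        pdist = lambda a: scipy.stats.t.sf(a, self.df_resid)
        return _slopes_from_cov(
            np.asarray(self.params), self.cov_params(), self.model.design_info, pdist
        )

    def summary(self) -> str:
        info = self.model.design_info
        lines = [
            "Group-interaction OLS",
            f"  response ~ {info.x_name} * {info.group_name}"
            f"  [{info.coding} coding, {len(info.levels)} level(s)]",
            f"  nobs = {self.nobs}, df_resid = {self.df_resid}, R^2 = {self.rsquared:.4f}",
            "",
            f"  {'term':<28}{'coef':>12}{'se':>11}{'t':>9}{'P>|t|':>9}{'beta':>9}",
        ]
        for name in self.params.index:
            b = self.std_params[name]
            lines.append(
                f"  {name:<28}{self.params[name]:>12.6g}{self.bse[name]:>11.4g}"
                f"{self.tvalues[name]:>9.3f}{self.pvalues[name]:>9.4f}"
                + (f"{b:>9.4f}" if np.isfinite(b) else f"{'--':>9}")
            )
        tt = self.term_tests()
        if len(tt):
            lines += ["", "  Marginal term tests (Type III, sum-to-zero contrasts)"]
            for r in tt.itertuples(index=False):
                lines.append(
                    f"    {r.term:<26}F({r.df_num}, {r.df_den}) = {r.F:.3f}, p = {r.p:.4g}"
                )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Crossed random-intercepts mixed model
# ---------------------------------------------------------------------------


class _CrossedSuffStats:
    """Sufficient statistics for the profiled crossed-intercepts deviance.

    Everything a deviance evaluation needs is a handful of q x q, q x p and
    p x p cross-products; per-evaluation cost is one Cholesky of
    ``M = G^{-1} + Z'Z``.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, i1: np.ndarray, i2: np.ndarray):
        self.y, self.X = y, X
        self.n, self.p = X.shape
        self.q1 = int(i1.max()) + 1
        self.q2 = int(i2.max()) + 1
        self.c1 = np.bincount(i1, minlength=self.q1).astype(float)
        self.c2 = np.bincount(i2, minlength=self.q2).astype(float)
        C12 = np.zeros((self.q1, self.q2))
        np.add.at(C12, (i1, i2), 1.0)
        self.C12 = C12
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        Z1tX = np.zeros((self.q1, self.p))
        np.add.at(Z1tX, i1, X)
        Z2tX = np.zeros((self.q2, self.p))
        np.add.at(Z2tX, i2, X)
        self.Z1tX, self.Z2tX = Z1tX, Z2tX
        self.Z1ty = np.bincount(i1, weights=y, minlength=self.q1)
        self.Z2ty = np.bincount(i2, weights=y, minlength=self.q2)

    def gls(self, g1: float, g2: float):
        """GLS pieces at variance ratios (g1, g2).

        Returns ``beta, rss, logdet_Sigma, XtSiX`` where
        ``Sigma = I + g1 Z1 Z1' + g2 Z2 Z2'`` and ``rss = r' Sigma^{-1} r``.
        """
        if g1 <= 0.0 and g2 <= 0.0:
            XtSiX, XtSiy, ytSiy, logdet = self.XtX, self.Xty, self.yty, 0.0
        elif g2 <= 0.0:
            d = 1.0 / g1 + self.c1
            XtSiX = self.XtX - self.Z1tX.T @ (self.Z1tX / d[:, None])
            XtSiy = self.Xty - self.Z1tX.T @ (self.Z1ty / d)
            ytSiy = self.yty - float(self.Z1ty @ (self.Z1ty / d))
            logdet = float(np.sum(np.log1p(g1 * self.c1)))
        elif g1 <= 0.0:
            d = 1.0 / g2 + self.c2
            XtSiX = self.XtX - self.Z2tX.T @ (self.Z2tX / d[:, None])
            XtSiy = self.Xty - self.Z2tX.T @ (self.Z2ty / d)
            ytSiy = self.yty - float(self.Z2ty @ (self.Z2ty / d))
            logdet = float(np.sum(np.log1p(g2 * self.c2)))
        else:
            M = np.block(
                [
                    [np.diag(1.0 / g1 + self.c1), self.C12],
                    [self.C12.T, np.diag(1.0 / g2 + self.c2)],
                ]
            )
            L = scipy.linalg.cho_factor(M, lower=True, check_finite=False)
            B = np.vstack([self.Z1tX, self.Z2tX])
            b = np.concatenate([self.Z1ty, self.Z2ty])
            MB = scipy.linalg.cho_solve(L, B, check_finite=False)
            Mb = scipy.linalg.cho_solve(L, b, check_finite=False)
            XtSiX = self.XtX - B.T @ MB
            XtSiy = self.Xty - B.T @ Mb
            ytSiy = self.yty - float(b @ Mb)
            logdet = (
                2.0 * float(np.sum(np.log(np.diag(L[0]))))
                + self.q1 * np.log(g1)
                + self.q2 * np.log(g2)
            )
        beta = np.linalg.solve(XtSiX, XtSiy)
        rss = max(ytSiy - float(XtSiy @ beta), 1e-300)
        return beta, rss, logdet, XtSiX

    def oneway_score(self, which: int, g: float, reml: bool = True) -> float:
        """d/dg of the profiled criterion along the single-factor axis.

        With only factor ``which`` active, Sigma^{-1} contracts to diagonal
        corrections, so the derivative (trace terms and quadratic form) is
        exact and cheap; fit() root-finds this score to pin boundary fits to
        machine precision, which a derivative-free search cannot.
        """
        if which == 1:
            c, A, Zty = self.c1, self.Z1tX, self.Z1ty
        else:
            c, A, Zty = self.c2, self.Z2tX, self.Z2ty
        d = 1.0 / g + c
        XtSiX = self.XtX - A.T @ (A / d[:, None])
        XtSiy = self.Xty - A.T @ (Zty / d)
        ytSiy = self.yty - float(Zty @ (Zty / d))
        beta = np.linalg.solve(XtSiX, XtSiy)
        rss = max(ytSiy - float(XtSiy @ beta), 1e-300)
        w = 1.0 / (1.0 + g * c)
        t1 = float(np.sum(c * w))
        u = w * (Zty - A @ beta)
        if reml:
            Aw2A = A.T @ (A * (w**2)[:, None])
            t2 = float(np.trace(np.linalg.solve(XtSiX, Aw2A)))
            return t1 - t2 - (self.n - self.p) * float(u @ u) / rss
        return t1 - self.n * float(u @ u) / rss

    def criterion(self, g1: float, g2: float, reml: bool = True) -> float:
        """-2 log (restricted) likelihood, profiled over beta and se^2."""
        _, rss, logdet, XtSiX = self.gls(g1, g2)
        if reml:
            nmp = self.n - self.p
            sign, logdet_X = np.linalg.slogdet(XtSiX)
            if sign <= 0:
                return np.inf
            return (
                nmp * np.log(rss / nmp) + logdet + logdet_X + nmp * (1.0 + _LOG2PI)
            )
        return self.n * np.log(rss / self.n) + logdet + self.n * (1.0 + _LOG2PI)


# deterministic Nelder-Mead starting points on the log variance-ratio plane
_NM_STARTS = [
    (0.0, 0.0),
    (-2.0, -2.0),
    (2.0, 2.0),
    (-2.0, 2.0),
    (2.0, -2.0),
    (-5.0, -5.0),
    (1.0, -1.0),
    (-1.0, 1.0),
    (4.0, 0.0),
    (0.0, 4.0),
]
_LOG_RATIO_BOUNDS = (-18.0, 12.0)


class CrossedLMM:
    """Linear mixed model with two crossed random intercepts.

    Parameters
    ----------
    endog : response vector.
    exog : fixed-effects design matrix (with intercept column).
    id1, id2 : the two crossed grouping factors, one label per observation
        (for pair data: the first and second station of each pair).
    exog_names, terms, design_info : optional design bookkeeping; supplied
        automatically by :meth:`from_formula` / :meth:`from_pairs`.
    """

    def __init__(
        self,
        endog: Sequence[float],
        exog: np.ndarray,
        id1: Sequence,
        id2: Sequence,
        exog_names: Sequence[str] | None = None,
        terms: Mapping[str, list[int]] | None = None,
        design_info: DesignInfo | None = None,
    ):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        n, p = self.exog.shape
        if len(self.endog) != n:
            raise ValueError("endog and exog have different lengths")
        if np.linalg.matrix_rank(self.exog) < p:
            raise ValueError("fixed-effects design is not full rank")
        id1 = np.asarray(id1)
        id2 = np.asarray(id2)
        if len(id1) != n or len(id2) != n:
            raise ValueError("id1/id2 must be parallel to endog")
        if np.any(id1.astype(str) == id2.astype(str)):
            raise ValueError("each row must reference two distinct ids")
        self.id1_levels, self._i1 = np.unique(id1, return_inverse=True)
        self.id2_levels, self._i2 = np.unique(id2, return_inverse=True)
        self.exog_names = (
            list(exog_names)
            if exog_names is not None
            else [f"x{j}" for j in range(p)]
        )
        self.terms = dict(terms) if terms is not None else None
        self.design_info = design_info
        self._suff = _CrossedSuffStats(self.endog, self.exog, self._i1, self._i2)

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_pairs(
        cls,
        data: pd.DataFrame,
        y: str,
        x: str,
        group: str | None = None,
        id1: str = "station_i",
        id2: str = "station_j",
        coding: str = "sum",
    ) -> "CrossedLMM":
        """Build the pair-distance model ``y ~ x [* group] + (1|id1) + (1|id2)``."""
        X, info = interaction_design(
            data[x].to_numpy(),
            None if group is None else data[group].to_numpy(),
            coding=coding,
            x_name=x,
            group_name=group or "group",
        )
        return cls(
            endog=data[y].to_numpy(),
            exog=X,
            id1=data[id1].to_numpy(),
            id2=data[id2].to_numpy(),
            exog_names=info.columns,
            terms=info.terms,
            design_info=info,
        )

    @classmethod
    def from_formula(
        cls, formula: str, data: pd.DataFrame, coding: str = "sum"
    ) -> "CrossedLMM":
        """Build from the tilde dialect, e.g.
        ``"geo_km ~ ling_dist*city + (1|station_i) + (1|station_j)"``.

        Supported fixed parts: a single continuous predictor, optionally
        interacted (``*`` or the multiplication sign) with one categorical
        factor; exactly two ``(1|factor)`` random-intercept terms.
        """
        y, x, group, rand = parse_mixed_formula(formula)
        if len(rand) != 2:
            raise ValueError(
                f"expected exactly two (1|factor) terms, got {len(rand)}"
            )
        return cls.from_pairs(
            data, y=y, x=x, group=group, id1=rand[0], id2=rand[1], coding=coding
        )

    # -- estimation ---------------------------------------------------------

    def fit(
        self,
        reml: bool = True,
        n_restarts: int = 10,
        tol: float = 1e-8,
    ) -> "CrossedLMMResults":
        """Estimate by REML (default) or ML.

        The profiled deviance is minimised over the two log variance ratios
        by Nelder-Mead from ``n_restarts`` deterministic starting points,
        together with the three boundary candidates (each single-factor model
        by 1-D bounded search, and the OLS fit with both variances at zero);
        the best candidate wins. Variance ratios within ``1e-8`` of zero are
        snapped to the boundary and flagged, not errored.
        """
        suff = self._suff
        trace: list[tuple[float, float, float]] = []

        def objective(theta: np.ndarray) -> float:
            th = np.clip(theta, *_LOG_RATIO_BOUNDS)
            val = suff.criterion(np.exp(th[0]), np.exp(th[1]), reml=reml)
            trace.append((float(th[0]), float(th[1]), float(val)))
            return val

        candidates: list[tuple[float, float, float, bool]] = []
        any_ok = False
        for start in _NM_STARTS[: max(1, n_restarts)]:
            res = scipy.optimize.minimize(
                objective,
                np.array(start, dtype=float),
                method="Nelder-Mead",
                options={"xatol": 1e-7, "fatol": tol, "maxiter": 500},
            )
            th = np.clip(res.x, *_LOG_RATIO_BOUNDS)
            candidates.append(
                (float(res.fun), float(np.exp(th[0])), float(np.exp(th[1])), bool(res.success))
            )
            any_ok = any_ok or res.success
        # boundary candidates: one factor only, and pure OLS
        for which in (1, 2):
            f1 = (
                (lambda t: suff.criterion(np.exp(t), 0.0, reml=reml))
                if which == 1
                else (lambda t: suff.criterion(0.0, np.exp(t), reml=reml))
            )
            r1 = scipy.optimize.minimize_scalar(
                f1, bounds=_LOG_RATIO_BOUNDS, method="bounded",
                options={"xatol": 1e-9},
            )
            g = float(np.exp(np.clip(r1.x, *_LOG_RATIO_BOUNDS)))
            # polish by root-finding the analytic score around the optimum
            try:
                lo, hi = g / 4.0, g * 4.0
                slo = suff.oneway_score(which, lo, reml=reml)
                shi = suff.oneway_score(which, hi, reml=reml)
                if slo < 0.0 < shi:
                    g = float(
                        scipy.optimize.brentq(
                            lambda t: suff.oneway_score(which, t, reml=reml),
                            lo, hi, xtol=1e-14, rtol=1e-14,
                        )
                    )
                    r1.fun = f1(np.log(g))
            except Exception:
                pass
            candidates.append(
                (float(r1.fun), g if which == 1 else 0.0, g if which == 2 else 0.0, bool(r1.success))
            )
            any_ok = any_ok or r1.success
        candidates.append((suff.criterion(0.0, 0.0, reml=reml), 0.0, 0.0, True))
        if not any_ok:
            raise ConvergenceError("no optimiser run converged", trace)
        best = min(candidates, key=lambda c: c[0])
        crit, g1, g2, _ = best
        boundary = {"id1": g1 < _BOUNDARY_TOL, "id2": g2 < _BOUNDARY_TOL}
        g1 = 0.0 if boundary["id1"] else g1
        g2 = 0.0 if boundary["id2"] else g2
        if any(boundary.values()):
            logger.info("variance component(s) at zero boundary: %s", boundary)
            crit = suff.criterion(g1, g2, reml=reml)
        return CrossedLMMResults(
            self, g1=g1, g2=g2, crit=float(crit), reml=reml, converged=True,
            boundary=boundary,
        )

    def criterion(self, g1: float, g2: float, reml: bool = True) -> float:
        """-2 profiled (RE)ML log-likelihood at given variance ratios (for
        diagnostics and grid checks)."""
        return self._suff.criterion(g1, g2, reml=reml)


class CrossedLMMResults:
    """Fitted crossed random-intercepts model.

    Attributes
    ----------
    params, bse, zvalues, pvalues : fixed-effect estimates (Series by name).
    std_params : standardised coefficients b * sd(x)/sd(y).
    sigma2_id1, sigma2_id2, sigma2_resid : variance components.
    deviance : -2 (restricted) log-likelihood at the optimum.
    boundary : which variance components sit on the zero boundary.
    """

    def __init__(self, model, g1, g2, crit, reml, converged, boundary):
        self.model = model
        self.reml = reml
        self.method = "reml" if reml else "ml"
        self.converged = converged
        self.boundary = boundary
        self.deviance = crit
        self.llf = -0.5 * crit
        suff = model._suff
        beta, rss, _, XtSiX = suff.gls(g1, g2)
        dof = suff.n - suff.p if reml else suff.n
        self.scale = rss / dof  # sigma_e^2
        self.sigma2_resid = float(self.scale)
        self.sigma2_id1 = float(g1 * self.scale)
        self.sigma2_id2 = float(g2 * self.scale)
        self._g = (float(g1), float(g2))
        self.nobs = suff.n
        self.df_resid = suff.n - suff.p
        cov = self.scale * np.linalg.inv(XtSiX)
        names = model.exog_names
        self._cov = cov
        self.params = pd.Series(beta, index=names)
        self.bse = pd.Series(np.sqrt(np.diag(cov)), index=names)
        self.zvalues = self.params / self.bse
        self.pvalues = pd.Series(
            2.0 * scipy.stats.norm.sf(np.abs(self.zvalues)), index=names
        )
        self.std_params = _std_params(beta, model.exog, model.endog, names)

    @property
    def vcomp(self) -> dict[str, float]:
        return {
            "id1": self.sigma2_id1,
            "id2": self.sigma2_id2,
            "resid": self.sigma2_resid,
        }

    def cov_params(self) -> np.ndarray:
        return self._cov

    # -- inference ----------------------------------------------------------

    def term_tests(self, method: str = "wald") -> pd.DataFrame:
        """Marginal test per fixed-effect term.

        ``wald``: chi-square on the term's coefficient block (df = block
        size). ``lrt``: likelihood-ratio against the term-deleted model; LRT
        on a REML fit triggers an automatic ML refit of both models (logged),
        since REML likelihoods are not comparable across fixed designs.
        """
        if self.model.terms is None:
            raise ValueError("model carries no term structure")
        if method not in ("wald", "lrt"):
            raise ValueError(f"method must be 'wald' or 'lrt', got {method!r}")
        rows = []
        if method == "wald":
            beta = self.params.to_numpy()
            for term, cols in self.model.terms.items():
                if term == "Intercept":
                    continue
                sub = np.ix_(cols, cols)
                stat = float(beta[cols] @ np.linalg.solve(self._cov[sub], beta[cols]))
                df = len(cols)
                rows.append((term, stat, df, float(scipy.stats.chi2.sf(stat, df))))
        else:
            if self.reml:
                logger.info("LRT requested on a REML fit; refitting both models by ML")
            full = self._refit_ml()
            for term, cols in self.model.terms.items():
                if term == "Intercept":
                    continue
                reduced = self._drop_term_model(cols).fit(reml=False)
                stat = max(reduced.deviance - full.deviance, 0.0)
                df = len(cols)
                rows.append((term, stat, df, float(scipy.stats.chi2.sf(stat, df))))
        return pd.DataFrame(rows, columns=["term", "chi2", "df", "p"])

    def _refit_ml(self) -> "CrossedLMMResults":
        if not self.reml:
            return self
        return self.model.fit(reml=False)

    def _drop_term_model(self, cols: list[int]) -> "CrossedLMM":
        keep = [j for j in range(self.model.exog.shape[1]) if j not in cols]
        m = self.model
        return CrossedLMM(
            endog=m.endog,
            exog=m.exog[:, keep],
            id1=m.id1_levels[m._i1],
            id2=m.id2_levels[m._i2],
            exog_names=[m.exog_names[j] for j in keep],
        )

    def simple_slopes(self) -> list[SimpleSlope]:
        """Per-group slope of the continuous predictor (Wald z tests)."""
        if self.model.design_info is None:
            raise ValueError("model was not built from an x*group design")
        return _slopes_from_cov(
            self.params.to_numpy(), self._cov, self.model.design_info,
            scipy.stats.norm.sf,
        )

    def summary(self) -> str:
        m = self.model
        lines = [
            "Crossed random-intercepts linear mixed model",
            f"  method = {self.method.upper()}, nobs = {self.nobs}, "
            f"q1 = {len(m.id1_levels)}, q2 = {len(m.id2_levels)}",
            f"  deviance (-2 logLik) = {self.deviance:.4f}, "
            f"converged = {self.converged}"
            + (", boundary fit" if any(self.boundary.values()) else ""),
            "",
            "  Variance components",
            f"    id1 intercept  {self.sigma2_id1:>12.6g}",
            f"    id2 intercept  {self.sigma2_id2:>12.6g}",
            f"    residual       {self.sigma2_resid:>12.6g}",
            "",
            f"  {'term':<28}{'coef':>12}{'se':>11}{'z':>9}{'P>|z|':>9}{'beta':>9}",
        ]
        for name in self.params.index:
            b = self.std_params[name]
            lines.append(
                f"  {name:<28}{self.params[name]:>12.6g}{self.bse[name]:>11.4g}"
                f"{self.zvalues[name]:>9.3f}{self.pvalues[name]:>9.4f}"
                + (f"{b:>9.4f}" if np.isfinite(b) else f"{'--':>9}")
            )
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        """Tidy coefficient table (term, estimate, se, z, p, beta_std)."""
        return pd.DataFrame(
            {
                "term": self.params.index,
                "estimate": self.params.to_numpy(),
                "se": self.bse.to_numpy(),
                "z": self.zvalues.to_numpy(),
                "p": self.pvalues.to_numpy(),
                "beta_std": self.std_params.to_numpy(),
            }
        )


# ---------------------------------------------------------------------------
# formula dialect and convenience wrappers
# ---------------------------------------------------------------------------

_RAND_RE = re.compile(r"\(\s*1\s*[|∣]\s*([^)|∣]+?)\s*\)")


def parse_mixed_formula(formula: str) -> tuple[str, str, str | None, list[str]]:
    """Parse ``y ~ x [* group] + (1|f1) + (1|f2) ...``.

    Returns ``(response, x, group_or_None, random_factors)``. Accepts ``*``
    or the multiplication sign for the interaction and the unicode divider in
    random terms.
    """
    if "~" not in formula:
        raise ValueError(f"formula needs '~': {formula!r}")
    lhs, rhs = formula.split("~", 1)
    y = lhs.strip()
    rand = [m.strip() for m in _RAND_RE.findall(rhs)]
    fixed = _RAND_RE.sub("", rhs)
    fixed_terms = [t.strip() for t in fixed.split("+") if t.strip()]
    if len(fixed_terms) != 1:
        raise ValueError(
            f"expected one fixed term ('x' or 'x*group'), got {fixed_terms!r}"
        )
    term = fixed_terms[0].replace("×", "*")
    if "*" in term:
        x, group = (p.strip() for p in term.split("*", 1))
    else:
        x, group = term, None
    if not y or not x:
        raise ValueError(f"could not parse formula {formula!r}")
    return y, x, group, rand


def fit_lm_interaction(
    y: Sequence[float],
    x: Sequence[float],
    groups: Sequence[str] | None = None,
    coding: str = "sum",
) -> GroupInteractionOLSResults:
    """Fit ``y ~ x * group`` by OLS (sum-to-zero contrasts by default)."""
    return GroupInteractionOLS(y, x, groups, coding=coding).fit()


def fit_crossed_lmm(
    y: Sequence[float],
    X: np.ndarray,
    id1: Sequence,
    id2: Sequence,
    exog_names: Sequence[str] | None = None,
    reml: bool = True,
    **fit_kwargs,
) -> CrossedLMMResults:
    """Fit ``y = X b + (1|id1) + (1|id2) + e`` by REML (or ML)."""
    return CrossedLMM(y, X, id1, id2, exog_names=exog_names).fit(reml=reml, **fit_kwargs)


def term_tests(result, method: str = "wald"):
    """Per-term marginal tests for either results class."""
    if isinstance(result, CrossedLMMResults):
        return result.term_tests(method=method)
    if method != "wald":
        raise ValueError("OLS term tests are F tests; method flag applies to mixed fits")
    return result.term_tests()


def simple_slopes(result) -> list[SimpleSlope]:
    """Per-group simple slopes for either results class."""
    return result.simple_slopes()
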