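"""Comparative statistics: Pearson correlation, one-way ANOVA with
normality pre-checks and Tukey-Kramer pairwise comparisons, and phylogenetic
generalized least squares (PGLS) under Brownian-motion covariance with
Pagel's lambda.

The PGLS model
--------------

For trait vector ``y`` and design matrix ``X`` over the leaves of a rooted
tree, the error covariance is ``sigma^2 * V(lambda)`` where ``V(1)`` is the
Brownian-motion covariance (shared root-to-MRCA path lengths) and Pagel's
lambda multiplies its off-diagonal entries: lambda = 0 removes phylogenetic
signal, lambda = 1 is pure Brownian motion.  Coefficients are the GLS
estimates

    beta_hat = (X' V^-1 X)^-1 X' V^-1 y

and, in ``ml`` mode, lambda maximises the profile log-likelihood

    ll(lambda) = -1/2 [ n ln(2 pi sigma^2_ml) + ln|V(lambda)| + n ],
    sigma^2_ml = resid' V^-1 resid / n

over [0, 1] (101-point grid followed by bounded refinement to 1e-6).
Reported sigma^2 uses the unbiased n - p denominator; t statistics and
two-sided p-values use n - p degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats as sps


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation with the two-sided t-test p-value
    (t = r sqrt((n-2)/(1-r^2)), n-2 df)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def bm_covariance(tree: dendropy.Tree) -> pd.DataFrame:
    """Brownian-motion covariance of a rooted tree: V[i, j] is the shared
    path length from the root to the MRCA of leaves i and j; the diagonal is
    the root-to-leaf depth.  Raises on unrooted input."""
    if not tree.is_rooted or len(tree.seed_node.child_nodes()) > 2:
        raise ValueError(
            "bm_covariance requires a rooted tree; apply midpoint_root() "
            "or supply a rooted phylogeny"
        )
    depths: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
    leaves = [lf for lf in tree.leaf_node_iter()]
    labels = [lf.taxon.label for lf in leaves]
    index = {lf: k for k, lf in enumerate(leaves)}
    n = len(leaves)
    V = np.zeros((n, n))
    for lf in leaves:
        V[index[lf], index[lf]] = depths[lf]
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._leafidx = [index[node]]
            continue
        kids = node.child_nodes()
        node._leafidx = [i for c in kids for i in c._leafidx]
        d = depths[node]
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                for i in kids[a]._leafidx:
                    for j in kids[b]._leafidx:
                        V[i, j] = V[j, i] = d
    return pd.DataFrame(V, index=labels, columns=labels)


def lambda_transform(V, lam: float):
    """Pagel's lambda: multiply off-diagonal covariance entries by lambda,
    leaving the diagonal unchanged."""
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    if isinstance(V, pd.DataFrame):
        out = V.values * lam
        np.fill_diagonal(out, np.diag(V.values))
        return pd.DataFrame(out, index=V.index, columns=V.columns)
    out = np.asarray(V, float) * lam
    np.fill_diagonal(out, np.diag(np.asarray(V, float)))
    return out


@dataclass
class PGLSResults:
    """Fit results; attribute names follow statsmodels conventions."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    lambda_: float
    lambda_mode: str
    sigma2: float
    llf: float
    nobs: int
    df_resid: int
    resid: np.ndarray = field(repr=False)
    fittedvalues: np.ndarray = field(repr=False)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        q = sps.t.ppf(1 - alpha / 2, self.df_resid)
        return pd.DataFrame(
            {"lower": self.params - q * self.bse, "upper": self.params + q * self.bse}
        )

    def summary(self) -> str:
        lines = [
            "PGLS regression results",
            "=" * 58,
            f"No. observations: {self.nobs:<8d} df resid: {self.df_resid}",
            f"lambda ({self.lambda_mode}): {self.lambda_:.4f}   "
            f"sigma2: {self.sigma2:.6g}   logLik: {self.llf:.4f}",
            "-" * 58,
            f"{'':<14s}{'coef':>10s}{'std err':>10s}{'t':>9s}{'P>|t|':>10s}",
        ]
        for name in self.params.index:
            lines.append(
                f"{name:<14s}{self.params[name]:>10.4f}{self.bse[name]:>10.4f}"
                f"{self.tvalues[name]:>9.3f}{self.pvalues[name]:>10.3g}"
            )
        lines.append("=" * 58)
        return "\n".join(lines)


class PGLS:
    """Phylogenetic generalized least squares model.

    Parameters
    ----------
    endog : 1-d array or Series
        Response per species, ordered as ``labels``.
    exog : 2-d array or DataFrame
        Design matrix including the intercept column.
    tree : dendropy.Tree, optional
        Rooted phylogeny whose leaves cover the labels.  Either ``tree`` or a
        precomputed covariance ``V`` must be given.
    labels : sequence of str, optional
        Species order of endog/exog rows; defaults to DataFrame/Series index
        or the tree's leaf order.
    """

    def __init__(self, endog, exog, tree=None, V=None, labels=None):
        if labels is None:
            if isinstance(endog, pd.Series):
                labels = list(endog.index)
            elif tree is not None:
                labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
            else:
                raise ValueError("labels required when endog is unlabelled")
        self.labels = list(labels)
        self.endog = np.asarray(endog, float).ravel()
        X = exog.values if isinstance(exog, pd.DataFrame) else np.asarray(exog, float)
        if X.ndim == 1:
            X = X[:, None]
        self.exog = X
        self.exog_names = (
            list(exog.columns)
            if isinstance(exog, pd.DataFrame)
            else [f"x{i}" for i in range(X.shape[1])]
        )
        n, p = X.shape
        if len(self.endog) != n or len(self.labels) != n:
            raise ValueError("endog, exog and labels must agree in length")
        if n <= p:
            raise ValueError("need more observations than design columns")
        if V is None:
            if tree is None:
                raise ValueError("either tree or V must be supplied")
            V = bm_covariance(tree)
        if isinstance(V, pd.DataFrame):
            missing = [l for l in self.labels if l not in V.index]
            if missing:
                raise ValueError(f"labels absent from tree/covariance: {missing}")
            V = V.loc[self.labels, self.labels].values
        self.V0 = np.asarray(V, float)

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        response: str,
        predictors: Sequence[str],
        tree: dendropy.Tree,
        add_intercept: bool = True,
    ) -> "PGLS":
        cols = list(predictors)
        X = data[cols].astype(float).copy()
        if add_intercept:
            X.insert(0, "intercept", 1.0)
        return cls(data[response].astype(float), X, tree=tree, labels=list(data.index))

    # -- likelihood machinery -------------------------------------------------

    def _solve(self, lam: float):
        V = lambda_transform(self.V0, lam)
        try:
            cho = linalg.cho_factor(V, lower=True)
        except linalg.LinAlgError as exc:
            raise ValueError(f"covariance not positive definite: {exc}") from exc
        Vinv_X = linalg.cho_solve(cho, self.exog)
        Vinv_y = linalg.cho_solve(cho, self.endog)
        XtVX = self.exog.T @ Vinv_X
        XtVy = self.exog.T @ Vinv_y
        try:
            beta = linalg.solve(XtVX, XtVy, assume_a="sym")
        except linalg.LinAlgError as exc:
            raise ValueError(f"singular X' V^-1 X: {exc}") from exc
        resid = self.endog - self.exog @ beta
        rss = float(resid @ linalg.cho_solve(cho, resid))
        logdet = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
        return beta, resid, rss, logdet, XtVX

    def profile_loglik(self, lam: float) -> float:
        """Profile log-likelihood of lambda (beta and sigma^2 profiled out)."""
        n = len(self.endog)
        _, _, rss, logdet, _ = self._solve(lam)
        sigma2_ml = rss / n
        return -0.5 * (n * np.log(2 * np.pi * sigma2_ml) + logdet + n)

    def fit(
        self,
        lambda_mode: Literal["ml", "fixed"] = "ml",
        lambda_fixed: Optional[float] = None,
        grid_size: int = 101,
        tol: float = 1e-6,
    ) -> PGLSResults:
        if lambda_mode == "fixed":
            if lambda_fixed is None:
                raise ValueError("lambda_fixed required in fixed mode")
            lam = float(lambda_fixed)
            if not (0.0 <= lam <= 1.0):
                raise ValueError("lambda_fixed must lie in [0, 1]")
        elif lambda_mode == "ml":
            grid = np.linspace(0.0, 1.0, grid_size)
            lls = np.array([self.profile_loglik(g) for g in grid])
            k = int(np.argmax(lls))
            lo = grid[max(k - 1, 0)]
            hi = grid[min(k + 1, grid_size - 1)]
            lam = grid[k]
            if hi > lo:
                res = optimize.minimize_scalar(
                    lambda l: -self.profile_loglik(l),
                    bounds=(lo, hi),
                    method="bounded",
                    options={"xatol": tol},
                )
                if -res.fun >= lls[k]:
                    lam = float(res.x)
        else:
            raise ValueError(f"unknown lambda_mode {lambda_mode!r}")

        n, p = self.exog.shape
        beta, resid, rss, logdet, XtVX = self._solve(lam)
        sigma2 = rss / (n - p)
        cov_beta = sigma2 * linalg.inv(XtVX)
        bse = np.sqrt(np.diag(cov_beta))
        tvals = beta / bse
        pvals = 2.0 * sps.t.sf(np.abs(tvals), n - p)
        sigma2_ml = rss / n
        llf = -0.5 * (n * np.log(2 * np.pi * sigma2_ml) + logdet + n)
        idx = self.exog_names
        return PGLSResults(
            params=pd.Series(beta, index=idx),
            bse=pd.Series(bse, index=idx),
            tvalues=pd.Series(tvals, index=idx),
            pvalues=pd.Series(pvals, index=idx),
            lambda_=float(lam),
            lambda_mode=lambda_mode,
            sigma2=float(sigma2),
            llf=float(llf),
            nobs=n,
            df_resid=n - p,
            resid=resid,
            fittedvalues=self.exog @ beta,
        )


def pgls_fit(
    y,
    X,
    tree: dendropy.Tree,
    lambda_mode: Literal["ml", "fixed"] = "ml",
    lambda_fixed: Optional[float] = None,
    labels=None,
) -> PGLSResults:
    """Functional wrapper around :class:`PGLS`."""
    return PGLS(y, X, tree=tree, labels=labels).fit(
        lambda_mode=lambda_mode, lambda_fixed=lambda_fixed
    )


@dataclass(frozen=True)
class NormalityCheck:
    classification: str  # "normal" | "lognormal" | "neither"
    stat_raw: float
    p_raw: float
    stat_log: Optional[float]
    p_log: Optional[float]


def normality_check(x, alpha: float = 0.05) -> NormalityCheck:
    """D'Agostino-Pearson omnibus test on raw and log10-transformed values.

    Returns "normal" if the raw data pass at ``alpha``, else "lognormal" if
    the (positive-valued) data pass after log10, else "neither".  The
    lognormal branch is skipped when nonpositive values are present.
    """
    x = np.asarray(x, float)
    if len(x) < 8:
        raise ValueError("need n >= 8 for the omnibus normality test")
    stat_raw, p_raw = sps.normaltest(x)
    if p_raw >= alpha:
        return NormalityCheck("normal", float(stat_raw), float(p_raw), None, None)
    if np.all(x > 0):
        stat_log, p_log = sps.normaltest(np.log10(x))
        cls = "lognormal" if p_log >= alpha else "neither"
        return NormalityCheck(
            cls, float(stat_raw), float(p_raw), float(stat_log), float(p_log)
        )
    return NormalityCheck("neither", float(stat_raw), float(p_raw), None, None)


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    pairwise: pd.DataFrame  # group_i, group_j, mean_diff, adjusted_p
    transform: str


def anova_oneway(
    groups: Sequence, labels: Optional[Sequence[str]] = None, transform: str = "none"
) -> AnovaResult:
    """Classical one-way ANOVA with Tukey-Kramer pairwise comparisons.

    ``transform="log10"`` applies a log10 transform first (all values must be
    positive); pick it when :func:`normality_check` selects "lognormal".
    """
    arrs = [np.asarray(g, float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(a) < 2 for a in arrs):
        raise ValueError("every group needs at least 2 values")
    if transform == "log10":
        if any(np.any(a <= 0) for a in arrs):
            raise ValueError("log10 transform requires positive values")
        arrs = [np.log10(a) for a in arrs]
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    if all(np.ptp(a) == 0 for a in arrs) and len({a[0] for a in arrs}) == 1:
        raise ValueError("all values identical: ANOVA undefined")
    labels = list(labels) if labels is not None else [f"g{i}" for i in range(len(arrs))]
    F, p = sps.f_oneway(*arrs)
    k = len(arrs)
    n = sum(len(a) for a in arrs)
    tk = sps.tukey_hsd(*arrs)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            rows.append(
                {
                    "group_i": labels[i],
                    "group_j": labels[j],
                    "mean_diff": float(np.mean(arrs[i]) - np.mean(arrs[j])),
                    "adjusted_p": float(tk.pvalue[i, j]),
                }
            )
    return AnovaResult(
        F=float(F),
        df_between=k - 1,
        df_within=n - k,
        p=float(p),
        pairwise=pd.DataFrame(rows),
        transform=transform,
    )
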