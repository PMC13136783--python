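"""Additive-model machinery for driver attribution.

Fits a Gaussian additive model by least squares: each continuous predictor
enters through a small centred cubic B-spline basis (default five basis
functions, i.e. limited wiggliness at event-level sample sizes) and a
categorical predictor through centred treatment dummies.  On top of the
fit it provides the three quantities the stepwise driver analysis needs:

* per-term significance via partial F-tests (drop one term, compare
  residual sums of squares with rank-aware degrees of freedom);
* per-term importance as the drop in explained variance when the term is
  removed while all others stay;
* pairwise concurvity, the additive-model analogue of collinearity: the
  share of a fitted smooth component's variance that the basis of another
  term can reproduce, in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline


@dataclass(frozen=True)
class SmoothTerm:
    """Cubic B-spline smooth for one continuous predictor."""

    name: str
    df: int = 5  # number of basis functions before centring

    kind: str = "smooth"


@dataclass(frozen=True)
class FactorTerm:
    """Categorical predictor entering through treatment dummies."""

    name: str

    kind: str = "factor"


def _spline_knots(x: np.ndarray, df: int, degree: int = 3) -> np.ndarray:
    """Knot vector with interior knots at quantiles of the data."""
    if df < degree:
        raise ValueError(f"spline df must be >= {degree}")
    n_interior = df - degree  # df+1 raw columns, one dropped for the intercept
    lo, hi = float(np.min(x)), float(np.max(x))
    span = max(hi - lo, 1e-12)
    lo -= 1e-9 * span
    hi += 1e-9 * span
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(x, qs)
        interior = np.clip(interior, lo + 1e-12 * span, hi - 1e-12 * span)
    else:
        interior = np.array([])
    return np.concatenate([[lo] * (degree + 1), np.sort(interior),
                           [hi] * (degree + 1)])


class _TermBasis:
    """Realized (centred) design block for one term."""

    def __init__(self, term, x: np.ndarray):
        self.term = term
        self.name = term.name
        if term.kind == "smooth":
            x = np.asarray(x, dtype=float)
            self.knots = _spline_knots(x, term.df)
            self.lo = self.knots[0]
            self.hi = self.knots[-1]
            raw = self._raw(x)
            self.col_means = raw.mean(axis=0)
            self.X = raw - self.col_means
            self.levels = None
        else:
            s = pd.Series(x).astype(str)
            self.levels = sorted(s.unique())
            raw = self._dummies(s)
            self.col_means = raw.mean(axis=0)
            self.X = raw - self.col_means
            self.knots = None

    def _raw(self, x: np.ndarray) -> np.ndarray:
        xc = np.clip(x, self.lo, self.hi)
        B = BSpline.design_matrix(xc, self.knots, 3).toarray()
        return B[:, 1:]  # drop one column: basis sums to 1 (intercept)

    def _dummies(self, s: pd.Series) -> np.ndarray:
        return np.column_stack([(s == lev).to_numpy(dtype=float)
                                for lev in self.levels[1:]]) \
            if len(self.levels) > 1 else np.zeros((len(s), 0))

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        """Centred basis at new values (smooth terms only)."""
        return self._raw(np.asarray(x, dtype=float)) - self.col_means

    @property
    def ncol(self) -> int:
        return self.X.shape[1]


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, int]:
    """Least squares fit returning (coefficients, SSR, numerical rank)."""
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid), int(rank)


@dataclass
class AdditiveFit:
    """Fitted additive model with term-level inference."""

    terms: list
    bases: dict[str, _TermBasis]
    coefs: dict[str, np.ndarray]
    intercept: float
    r2: float
    ssr: float
    sst: float
    n: int
    rank: int
    pvalues: dict[str, float]
    importance_raw: dict[str, float]  # R2 drop when the term is removed
    data: pd.DataFrame = field(repr=False, default=None)

    def term_names(self) -> list[str]:
        return [t.name for t in self.terms]

    def fitted_component(self, name: str) -> np.ndarray:
        """In-sample contribution of one term (centred)."""
        return self.bases[name].X @ self.coefs[name]

    def partial_effect(self, name: str, ngrid: int = 100) -> pd.DataFrame:
        """Partial-effect curve of a smooth term over its observed range."""
        basis = self.bases[name]
        if basis.term.kind != "smooth":
            raise ValueError("partial_effect is defined for smooth terms")
        x = self.data[name].to_numpy(dtype=float)
        grid = np.linspace(np.min(x), np.max(x), ngrid)
        effect = basis.evaluate(grid) @ self.coefs[name]
        return pd.DataFrame({"value": grid, "effect": effect})

    def max_pairwise_concurvity(self) -> float:
        """Worst pairwise concurvity among fitted components."""
        worst = 0.0
        for i, j, c in self.pairwise_concurvity():
            worst = max(worst, c)
        return worst

    def pairwise_concurvity(self):
        """Yield (term_i, term_j, concurvity of i's component on j's basis)."""
        names = self.term_names()
        for ni in names:
            g = self.fitted_component(ni)
            sst = float(np.sum((g - g.mean()) ** 2))
            for nj in names:
                if nj == ni:
                    continue
                if sst <= 1e-12:
                    yield ni, nj, 0.0
                    continue
                Xj = np.column_stack([np.ones(self.n), self.bases[nj].X])
                _, ssr, _ = _ols(Xj, g)
                yield ni, nj, max(0.0, 1.0 - ssr / sst)


def fit_additive(data: pd.DataFrame, response: str, terms: list) -> AdditiveFit:
    """Fit the additive model of ``response`` on ``terms`` over ``data``."""
    y = data[response].to_numpy(dtype=float)
    n = len(y)
    if n == 0:
        raise ValueError("empty dataset")
    bases = {t.name: _TermBasis(t, data[t.name].to_numpy()) for t in terms}
    blocks = [bases[t.name].X for t in terms]
    X = np.column_stack([np.ones(n)] + blocks) if blocks else np.ones((n, 1))
    beta, ssr, rank = _ols(X, y)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ssr / sst if sst > 0 else 0.0

    coefs, pos = {}, 1
    for t in terms:
        k = bases[t.name].ncol
        coefs[t.name] = beta[pos:pos + k]
        pos += k

    pvalues, importance = {}, {}
    for t in terms:
        others = [bases[u.name].X for u in terms if u.name != t.name]
        Xr = np.column_stack([np.ones(n)] + others) if others else np.ones((n, 1))
        _, ssr_r, rank_r = _ols(Xr, y)
        q = rank - rank_r
        dof = n - rank
        if q <= 0 or dof <= 0 or ssr <= 0:
            pvalues[t.name] = 1.0
        else:
            F = ((ssr_r - ssr) / q) / (ssr / dof)
            pvalues[t.name] = float(stats.f.sf(max(F, 0.0), q, dof))
        r2_r = 1.0 - ssr_r / sst if sst > 0 else 0.0
        importance[t.name] = r2 - r2_r

    return AdditiveFit(terms=list(terms), bases=bases, coefs=coefs,
                       intercept=float(beta[0]), r2=float(r2), ssr=ssr,
                       sst=sst, n=n, rank=rank, pvalues=pvalues,
                       importance_raw=importance, data=data)


def importance_shares(fit: AdditiveFit) -> dict[str, float]:
    """Importance of each retained term as a percentage summing to 100.

    Each term's share is its drop in explained variance when removed
    (others held), floored at zero before normalization.  If every drop is
    zero the shares are uniform.
    """
    if not fit.terms:
        raise ValueError("importance_shares needs a fitted model with terms")
    raw = {k: max(0.0, v) for k, v in fit.importance_raw.items()}
    total = sum(raw.values())
    if total <= 0:
        import warnings
        warnings.warn("all importance drops are zero; returning uniform shares")
        return {k: 100.0 / len(raw) for k in raw}
    return {k: 100.0 * v / total for k, v in raw.items()}
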