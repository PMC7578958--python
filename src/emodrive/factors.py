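"""Observable selection by principal-component factor analysis.

The eight candidate observation variables (dve, dde, v1, v2, ac2, d, dv,
dac) are factor-analyzed to find a small set of near-orthogonal carriers of
the information in a window: principal-component extraction on the
correlation matrix, varimax rotation with Kaiser normalization, and one
representative variable per retained factor (the variable with the largest
absolute rotated loading; ties break by canonical variable order).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: candidate variables entering factor analysis, in canonical order
#: (the following car's own acceleration is the behaviour being explained,
#: so it is not a candidate observable)
CANDIDATE_VARS: tuple[str, ...] = ("dve", "dde", "v1", "v2", "ac2", "d", "dv", "dac")


def varimax_criterion(loadings: np.ndarray) -> float:
    """Raw varimax objective: sum of within-factor variances of squared loadings."""
    L2 = np.asarray(loadings, dtype=float) ** 2
    return float(np.sum(L2**2) - np.sum(L2.sum(axis=0) ** 2) / L2.shape[0])


def varimax_rotate(
    loadings: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 500,
    kaiser: bool = True,
) -> np.ndarray:
    """Orthogonal varimax rotation of a variables x factors loading matrix.

    Uses the SVD-based fixed-point iteration; with ``kaiser`` the rows are
    normalized to unit communality during rotation and rescaled afterwards.
    A single-factor matrix is returned unchanged.  Row norms (communalities)
    are preserved by construction.
    """
    L = np.asarray(loadings, dtype=float).copy()
    if L.ndim != 2:
        raise ValueError("loadings must be 2-D")
    p, k = L.shape
    if k < 2:
        return L
    h = np.sqrt((L**2).sum(axis=1))
    if kaiser:
        scale = np.where(h > 0, h, 1.0)
        L = L / scale[:, None]
    R = np.eye(k)
    d_old = 0.0
    for _ in range(max_iter):
        Lr = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (Lr**3 - Lr @ np.diag((Lr**2).sum(axis=0)) / p)
        )
        R = u @ vt
        d_new = s.sum()
        if d_new <= d_old * (1 + tol):
            break
        d_old = d_new
    out = L @ R
    if kaiser:
        out = out * scale[:, None]
    return out


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Flip factor signs so each column's largest-|loading| entry is positive."""
    L = loadings.copy()
    for j in range(L.shape[1]):
        i = int(np.argmax(np.abs(L[:, j])))
        if L[i, j] < 0:
            L[:, j] = -L[:, j]
    return L


@dataclass
class FactorReport:
    variables: list[str]
    eigenvalues: np.ndarray
    communalities: pd.Series
    variance_table: pd.DataFrame
    rotated_loadings: pd.DataFrame
    selected_variables: list[str]


def select_representatives(rotated_loadings: pd.DataFrame) -> list[str]:
    """One representative variable per factor: max |rotated loading|.

    Exact ties break toward the variable appearing earlier in the table's
    row order (the canonical variable order).
    """
    out = []
    for col in rotated_loadings.columns:
        v = rotated_loadings[col].abs().to_numpy()
        out.append(str(rotated_loadings.index[int(np.argmax(v))]))
    return out


class FactorSelector:
    """Principal-component factor extraction with varimax, sklearn-style.

    Parameters
    ----------
    n_factors : int or "auto"
        Number of retained factors; "auto" keeps eigenvalues > 1 (Kaiser
        criterion).  The pipeline default is 3.
    kaiser_normalize : row-normalize communalities during varimax.

    Attributes (after fit)
    ----------------------
    eigenvalues_, loadings_, rotated_loadings_, communalities_,
    variance_table_, selected_variables_, report_
    """

    def __init__(self, n_factors: int | str = 3, kaiser_normalize: bool = True):
        self.n_factors = n_factors
        self.kaiser_normalize = kaiser_normalize

    def get_params(self, deep: bool = True) -> dict:
        return {"n_factors": self.n_factors, "kaiser_normalize": self.kaiser_normalize}

    def set_params(self, **kwargs) -> "FactorSelector":
        for k, v in kwargs.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: pd.DataFrame, y=None) -> "FactorSelector":
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
        n, p = X.shape
        if p < 2:
            raise ValueError("need at least two variables")
        if n <= p:
            raise ValueError("need more rows than variables")
        values = X.to_numpy(dtype=float)
        sd = values.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = [str(c) for c, s in zip(X.columns, sd) if s == 0]
            raise ValueError(f"constant column(s): {bad}")
        corr = np.corrcoef(values, rowvar=False)
        eigval, eigvec = np.linalg.eigh(corr)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        if self.n_factors == "auto":
            k = max(1, int(np.sum(eigval > 1.0)))
        else:
            k = int(self.n_factors)
            if not 1 <= k <= p:
                raise ValueError("n_factors must lie in 1..n_variables")
        loadings = eigvec[:, :k] * np.sqrt(np.maximum(eigval[:k], 0.0))
        rotated = _fix_signs(
            varimax_rotate(loadings, kaiser=self.kaiser_normalize)
        )
        loadings = _fix_signs(loadings)
        cols = [f"factor{j + 1}" for j in range(k)]
        names = [str(c) for c in X.columns]
        self.eigenvalues_ = eigval
        self.loadings_ = pd.DataFrame(loadings, index=names, columns=cols)
        self.rotated_loadings_ = pd.DataFrame(rotated, index=names, columns=cols)
        self.communalities_ = pd.Series(
            (loadings**2).sum(axis=1), index=names, name="communality"
        )
        pct = eigval / p * 100.0
        rot_ss = (rotated**2).sum(axis=0)
        rot_pct = rot_ss / p * 100.0
        self.variance_table_ = pd.DataFrame(
            {
                "eigenvalue": eigval,
                "pct_variance": pct,
                "cum_pct": np.cumsum(pct),
                "rotated_ss_loadings": np.concatenate([rot_ss, np.full(p - k, np.nan)]),
                "rotated_pct": np.concatenate([rot_pct, np.full(p - k, np.nan)]),
                "rotated_cum_pct": np.concatenate(
                    [np.cumsum(rot_pct), np.full(p - k, np.nan)]
                ),
            },
            index=pd.RangeIndex(1, p + 1, name="factor"),
        )
        self.selected_variables_ = select_representatives(self.rotated_loadings_)
        self.report_ = FactorReport(
            variables=names,
            eigenvalues=eigval,
            communalities=self.communalities_,
            variance_table=self.variance_table_,
            rotated_loadings=self.rotated_loadings_,
            selected_variables=self.selected_variables_,
        )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "selected_variables_"):
            raise RuntimeError("FactorSelector instance is not fitted yet")
        return X[self.selected_variables_]

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)


def fit_factors(data: pd.DataFrame, n_factors: int | str = 3) -> FactorReport:
    """Functional wrapper over :class:`FactorSelector`."""
    return FactorSelector(n_factors=n_factors).fit(data).report_
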