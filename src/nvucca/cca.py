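"""Canonical correlation analysis with loadings and redundancy analysis.

The solver whitens each variable set through a symmetric inverse square root
of its sample covariance (eigendecomposition with an eigenvalue floor) and
takes the singular value decomposition of the whitened cross-covariance

    M = Sxx^{-1/2} Sxy Syy^{-1/2} = A diag(r) B',

whose singular values are the canonical correlations.  Weights are the
whitening-back-transformed singular vectors, variates have unit sample
variance by construction, and canonical loadings are the Pearson
correlations between each variable and its set's variate.

Interpretation quantities follow the classical redundancy analysis:
``shared variance`` is the squared canonical correlation, ``variance
extracted`` the mean squared loading of a set on one of its variates, and
the Stewart-Love ``redundancy`` their product — the proportion of a set's
variance explainable through the other set via that mode.

Usage follows the model/results pattern::

    model = CanonicalCorrelation.from_dataframe(df, x_cols, y_cols)
    res = model.fit()
    print(res.summary())
    perm = res.permutation_test(n_permutations=1000, seed=42)
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._linalg import EIG_FLOOR, sym_inv_sqrt

__all__ = [
    "CanonicalCorrelation",
    "CCAResults",
    "canonical_loadings",
    "shared_variance",
    "variance_extracted",
    "redundancy",
]

logger = logging.getLogger(__name__)


def _standardize(M: np.ndarray) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    sd = M.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        raise ValueError("zero-variance column in input")
    return (M - M.mean(axis=0)) / sd


def canonical_loadings(M: np.ndarray, variates: np.ndarray) -> np.ndarray:
    """Pearson correlation of each column of ``M`` with each variate."""
    M = np.asarray(M, dtype=float)
    V = np.asarray(variates, dtype=float)
    if M.shape[0] != V.shape[0]:
        raise ValueError("row counts differ")
    Ms = _standardize(M)
    Vs = _standardize(V)
    return (Ms.T @ Vs) / (M.shape[0] - 1)


def shared_variance(r: float) -> float:
    """Proportion of variance shared by paired canonical variates: r^2."""
    if not 0.0 <= r <= 1.0:
        raise ValueError("canonical correlation must lie in [0, 1]")
    return float(r) ** 2


def variance_extracted(loadings_column: np.ndarray) -> float:
    """Mean squared loading: variance of a set extracted by one variate."""
    L = np.asarray(loadings_column, dtype=float)
    if L.size == 0:
        raise ValueError("empty loadings")
    if np.any(np.abs(L) > 1 + 1e-8):
        raise ValueError("loadings must lie in [-1, 1]")
    return float(np.mean(L**2))


def redundancy(var_extracted: float, r: float) -> float:
    """Stewart-Love redundancy index: variance extracted times r^2."""
    if not 0.0 <= var_extracted <= 1.0:
        raise ValueError("variance extracted must lie in [0, 1]")
    return var_extracted * shared_variance(r)


class CanonicalCorrelation:
    """CCA model for two aligned variable sets.

    Parameters
    ----------
    X : (n, p) array — first set (e.g. NVU function measures).
    Y : (n, q) array — second set (e.g. cognitive test scores).
        Both are standardized internally; canonical correlations are
        invariant to per-column affine rescaling.
    x_names, y_names : optional variable names for reporting.
    reg_epsilon : ridge added to each within-set correlation matrix when its
        smallest eigenvalue falls below the floor (logged when applied).
    """

    def __init__(self, X, Y, x_names=None, y_names=None, reg_epsilon: float = 0.0):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y must be 2-D with equal row counts")
        n, p = X.shape
        q = Y.shape[1]
        if n <= max(p, q):
            raise ValueError(f"n={n} too small for p={p}, q={q}")
        if np.isnan(X).any() or np.isnan(Y).any():
            raise ValueError("inputs must be complete (no missing entries)")
        self.X, self.Y = X, Y
        self.nobs, self.p, self.q = n, p, q
        self.x_names = list(x_names) if x_names is not None else [f"x{j}" for j in range(p)]
        self.y_names = list(y_names) if y_names is not None else [f"y{j}" for j in range(q)]
        self.reg_epsilon = float(reg_epsilon)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, x_cols, y_cols, **kwargs):
        return cls(
            df[list(x_cols)].to_numpy(dtype=float),
            df[list(y_cols)].to_numpy(dtype=float),
            x_names=list(x_cols),
            y_names=list(y_cols),
            **kwargs,
        )

    def _whitened(self):
        Xs, Ys = _standardize(self.X), _standardize(self.Y)
        n = self.nobs
        Sxx = (Xs.T @ Xs) / (n - 1)
        Syy = (Ys.T @ Ys) / (n - 1)
        for name, S in (("X", Sxx), ("Y", Syy)):
            lam_min = float(np.linalg.eigvalsh(S)[0])
            if lam_min < EIG_FLOOR:
                if self.reg_epsilon > 0:
                    S += self.reg_epsilon * np.eye(S.shape[0])
                    logger.warning(
                        "%s within-set covariance near-singular (min eig %.2e); "
                        "ridge epsilon %.1e applied", name, lam_min, self.reg_epsilon,
                    )
                else:
                    logger.warning(
                        "%s within-set covariance near-singular (min eig %.2e); "
                        "eigenvalue floor %.0e active", name, lam_min, EIG_FLOOR,
                    )
        Wx_half = sym_inv_sqrt(Sxx)
        Wy_half = sym_inv_sqrt(Syy)
        return Xs, Ys, Wx_half, Wy_half

    def fit(self) -> "CCAResults":
        Xs, Ys, Wx_half, Wy_half = self._whitened()
        n = self.nobs
        Sxy = (Xs.T @ Ys) / (n - 1)
        M = Wx_half @ Sxy @ Wy_half
        A, s, Bt = np.linalg.svd(M, full_matrices=False)
        K = min(self.p, self.q)
        r = np.clip(s[:K], 0.0, 1.0)
        Wx = Wx_half @ A[:, :K]
        Wy = Wy_half @ Bt[:K].T
        U = Xs @ Wx
        V = Ys @ Wy
        # Exact unit sample variance for the variates (the whitening already
        # gives ~1; renormalising makes it exact even when the floor binds).
        su = U.std(axis=0, ddof=1)
        sv = V.std(axis=0, ddof=1)
        U /= su
        V /= sv
        Wx = Wx / su
        Wy = Wy / sv
        Lx = (Xs.T @ U) / (n - 1)
        Ly = (Ys.T @ V) / (n - 1)
        # Deterministic sign convention: the X variable with the largest
        # absolute loading is positive within each mode.
        for k in range(K):
            j = int(np.argmax(np.abs(Lx[:, k])))
            if Lx[j, k] < 0:
                for Mx in (Wx, Wy, U, V, Lx, Ly):
                    Mx[:, k] *= -1.0
        return CCAResults(model=self, r=r, Wx=Wx, Wy=Wy, U=U, V=V, Lx=Lx, Ly=Ly)


@dataclass
class CCAResults:
    """Fitted canonical modes with loadings and redundancy analysis.

    Attributes
    ----------
    r : canonical correlations, non-increasing, length K = min(p, q).
    Wx, Wy : canonical weight matrices (p x K, q x K).
    U, V : canonical variates (n x K), unit sample variance.
    Lx, Ly : canonical loadings — correlations between variables and their
        set's variates.
    """

    model: CanonicalCorrelation
    r: np.ndarray
    Wx: np.ndarray
    Wy: np.ndarray
    U: np.ndarray
    V: np.ndarray
    Lx: np.ndarray
    Ly: np.ndarray
    permutation_result: object | None = field(default=None, repr=False)

    @property
    def n_modes(self) -> int:
        return int(self.r.size)

    @property
    def shared_var(self) -> np.ndarray:
        return self.r**2

    @property
    def var_extracted_x(self) -> np.ndarray:
        return np.mean(self.Lx**2, axis=0)

    @property
    def var_extracted_y(self) -> np.ndarray:
        return np.mean(self.Ly**2, axis=0)

    @property
    def redundancy_x_given_y(self) -> np.ndarray:
        """Per-mode proportion of X-set variance explainable through Y."""
        return self.var_extracted_x * self.shared_var

    @property
    def redundancy_y_given_x(self) -> np.ndarray:
        return self.var_extracted_y * self.shared_var

    @property
    def total_redundancy_x(self) -> float:
        return float(self.redundancy_x_given_y.sum())

    @property
    def total_redundancy_y(self) -> float:
        return float(self.redundancy_y_given_x.sum())

    def permutation_test(self, n_permutations: int = 1000, seed=None, scheme: str = "simultaneous"):
        """Mode-wise Wilks-lambda permutation test (rows of Y permuted)."""
        from .inference import permutation_test as _perm

        res = _perm(
            self.model.X, self.model.Y,
            n_permutations=n_permutations, seed=seed, scheme=scheme,
        )
        self.permutation_result = res
        return res

    # -- reporting ---------------------------------------------------------

    def loadings_frame(self) -> pd.DataFrame:
        """Long-format loadings table (variable x mode), Fig-2 style."""
        rows = []
        for names, L, which in (
            (self.model.x_names, self.Lx, "X"),
            (self.model.y_names, self.Ly, "Y"),
        ):
            for j, name in enumerate(names):
                for k in range(self.n_modes):
                    rows.append(
                        {"set": which, "variable": name, "mode": k + 1,
                         "loading": float(L[j, k])}
                    )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        from .inference import wilks_lambda_all

        d = {
            "n": self.model.nobs,
            "n_modes": self.n_modes,
            "canonical_correlations": self.r.tolist(),
            "shared_variance": self.shared_var.tolist(),
            "wilks_lambda": wilks_lambda_all(self.r).tolist(),
            "variance_extracted_x": self.var_extracted_x.tolist(),
            "variance_extracted_y": self.var_extracted_y.tolist(),
            "redundancy_x_given_y": self.redundancy_x_given_y.tolist(),
            "redundancy_y_given_x": self.redundancy_y_given_x.tolist(),
            "total_redundancy_x": self.total_redundancy_x,
            "total_redundancy_y": self.total_redundancy_y,
            "x_names": self.model.x_names,
            "y_names": self.model.y_names,
            "loadings_x": self.Lx.tolist(),
            "loadings_y": self.Ly.tolist(),
            "weights_x": self.Wx.tolist(),
            "weights_y": self.Wy.tolist(),
        }
        if self.permutation_result is not None:
            d["permutation"] = self.permutation_result.to_dict()
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    def summary(self) -> str:
        """Plain-text summary table of all canonical modes."""
        from .inference import wilks_lambda_all

        lam = wilks_lambda_all(self.r)
        pvals = None
        if self.permutation_result is not None:
            pvals = self.permutation_result.p_values
        lines = [
            "Canonical Correlation Analysis",
            f"  n = {self.model.nobs}, p = {self.model.p}, q = {self.model.q}, "
            f"modes = {self.n_modes}",
            "",
            "  mode      r      r^2   Wilks   VE(X)   VE(Y)   Rd(X|Y) Rd(Y|X)"
            + ("   p-perm" if pvals is not None else ""),
        ]
        for k in range(self.n_modes):
            row = (
                f"  {k + 1:>4}  {self.r[k]:6.3f}  {self.shared_var[k]:6.3f}  "
                f"{lam[k]:6.3f}  {self.var_extracted_x[k]:6.3f}  "
                f"{self.var_extracted_y[k]:6.3f}   {self.redundancy_x_given_y[k]:6.3f}  "
                f"{self.redundancy_y_given_x[k]:6.3f}"
            )
            if pvals is not None:
                row += f"   {pvals[k]:6.4f}"
            lines.append(row)
        lines += [
            "",
            f"  total redundancy X|Y = {self.total_redundancy_x:.3f}, "
            f"Y|X = {self.total_redundancy_y:.3f}",
        ]
        return "\n".join(lines)

    def plot_loadings(self, mode: int = 1, ax=None):
        """Horizontal bar chart of the loadings of one canonical mode."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.35 * (self.model.p + self.model.q) + 1))
        names = self.model.x_names + self.model.y_names
        vals = np.concatenate([self.Lx[:, mode - 1], self.Ly[:, mode - 1]])
        colors = ["tab:blue"] * self.model.p + ["tab:orange"] * self.model.q
        ax.barh(range(len(names)), vals, color=colors)
        ax.set_yticks(range(len(names)), names)
        ax.axvline(0, color="k", lw=0.8)
        ax.set_xlabel(f"canonical loading (mode {mode}, r = {self.r[mode - 1]:.2f})")
        ax.invert_yaxis()
        return ax
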