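"""Multiple Correspondence Analysis of the complete disjunctive table.

MCA here is plain correspondence analysis of the N x 21 indicator (one-hot)
matrix Z of the nine observational variables, with no eigenvalue
correction.  Writing Q = 9 for the number of variables and
P = Z / (N * Q):

* row masses are uniform, r_i = 1/N; column masses c_j are the category
  frequencies colsum(Z) / (N * Q);
* the standardized residual matrix is
  S = D_r^{-1/2} (P - r c^T) D_c^{-1/2}; its SVD U Sigma V^T yields
  principal coordinates F = D_r^{-1/2} U Sigma for individuals and
  G = D_c^{-1/2} V Sigma for categories, with eigenvalues
  lambda_s = sigma_s^2;
* total inertia is sum(lambda_s) = J/Q - 1 (= 4/3 for 21 categories of 9
  variables) whenever every row is a complete disjunctive row.

The first three dimensions form the acceptability map.  Supplementary
individuals are projected through the transition formula
f_s = (1/sqrt(lambda_s)) * sum_j (z_j / Q) g_{j,s}, which is linear in
the (possibly fractional, i.e. imputed) indicator row — the property the
population-barycenter oracle relies on.

Axis orientation is fixed by a sign convention: each axis is flipped, if
needed, so that the category coordinate of largest absolute value on
that axis is positive.  Fitting is then fully deterministic.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .codebook import DEFAULT_CODEBOOK, Codebook
from .schema import EvaluationSet

__all__ = ["MCA", "build_indicator", "fit_mca", "project_supplementary"]


class MCAError(ValueError):
    """Raised for degenerate inputs (too few rows/positive dimensions)."""


def build_indicator(
    data: EvaluationSet | pd.DataFrame, codebook: Codebook | None = None
) -> pd.DataFrame:
    """One-hot encode evaluations into the N x 21 indicator matrix.

    Accepts an :class:`EvaluationSet` or a categorical N x 9 frame.  Rows
    with missing cells are rejected: impute first (see
    :mod:`acceptmap.impute`).  Columns are a MultiIndex of
    (variable, category) pairs in codebook order; row order is preserved.
    """
    codebook = codebook or DEFAULT_CODEBOOK
    if isinstance(data, EvaluationSet):
        cat = data.observational
        codebook = data.codebook
    else:
        cat = data[codebook.variable_names]
    if cat.isna().any().any():
        n_bad = int(cat.isna().any(axis=1).sum())
        raise MCAError(
            f"{n_bad} evaluation(s) contain missing cells; run imputation "
            "(acceptmap.impute) before building the indicator matrix"
        )
    cols = pd.MultiIndex.from_tuples(codebook.columns, names=["variable", "category"])
    Z = pd.DataFrame(0.0, index=cat.index, columns=cols)
    for var in codebook.variable_names:
        for cat_name in codebook.categories(var):
            Z[(var, cat_name)] = (cat[var] == cat_name).astype(float)
    return Z


class MCA(BaseEstimator, TransformerMixin):
    """Multiple correspondence analysis with supplementary projection.

    Parameters
    ----------
    n_components : int, default 3
        Dimensions retained for the map.

    Attributes (after ``fit``)
    --------------------------
    eigenvalues_ : ndarray, all positive eigenvalues (descending)
    explained_inertia_ : ndarray, eigenvalues_ / total inertia
    row_coordinates_ : ndarray (N, n_components), principal coordinates
    column_coordinates_ : DataFrame (J_kept, n_components)
    column_masses_ : Series over kept columns
    columns_ : list of kept (variable, category) pairs
    dropped_columns_ : categories never observed, excluded with a warning
    """

    def __init__(self, n_components: int = 3):
        self.n_components = n_components

    # -- fitting ---------------------------------------------------------
    def fit(self, Z: pd.DataFrame, y=None) -> "MCA":
        Z = self._as_frame(Z)
        N = len(Z)
        if N < 3:
            raise MCAError(f"need at least 3 evaluations to fit MCA, got {N}")
        col_sums = Z.sum(axis=0)
        dropped = list(col_sums.index[col_sums <= 0])
        if dropped:
            warnings.warn(
                f"dropping {len(dropped)} never-observed categories: {dropped}",
                stacklevel=2,
            )
            Z = Z.loc[:, col_sums > 0]
            col_sums = col_sums[col_sums > 0]
        self.dropped_columns_ = dropped
        self.columns_ = list(Z.columns)

        Zv = Z.to_numpy(dtype=float)
        row_sums = Zv.sum(axis=1)
        self.n_active_ = int(round(row_sums[0]))  # Q, number of variables
        total = Zv.sum()
        P = Zv / total
        r = P.sum(axis=1)  # = 1/N for complete rows
        c = P.sum(axis=0)
        S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
        U, sig, Vt = np.linalg.svd(S, full_matrices=False)

        keep = sig**2 > 1e-12
        sig, U, Vt = sig[keep], U[:, keep], Vt[keep, :]
        if keep.sum() < self.n_components:
            raise MCAError(
                f"only {int(keep.sum())} positive eigenvalues; "
                f"cannot retain {self.n_components} dimensions"
            )

        F = U * sig / np.sqrt(r)[:, None]
        G = (Vt.T * sig) / np.sqrt(c)[:, None]
        # sign convention: largest-|loading| category positive on each axis
        for s in range(len(sig)):
            j = int(np.argmax(np.abs(G[:, s])))
            if G[j, s] < 0:
                G[:, s] *= -1.0
                F[:, s] *= -1.0

        self.eigenvalues_ = sig**2
        self.total_inertia_ = float((sig**2).sum())
        self.explained_inertia_ = self.eigenvalues_ / self.total_inertia_
        S_keep = self.n_components
        self.row_coordinates_ = F[:, :S_keep]
        self.column_coordinates_ = pd.DataFrame(
            G[:, :S_keep],
            index=pd.MultiIndex.from_tuples(self.columns_),
            columns=[f"dim{s + 1}" for s in range(S_keep)],
        )
        self.column_masses_ = pd.Series(c, index=self.column_coordinates_.index)
        self.n_rows_ = N
        return self

    def fit_transform(self, Z, y=None) -> np.ndarray:
        return self.fit(Z).row_coordinates_

    # -- projection ------------------------------------------------------
    def transform(self, Z: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Project supplementary (possibly fractional) indicator rows.

        Uses the transition formula; active individuals re-projected this
        way reproduce their own fitted coordinates.
        """
        self._check_fitted()
        if isinstance(Z, pd.DataFrame):
            extra = [c for c in Z.columns if tuple(c) not in set(map(tuple, self.columns_))]
            if extra:
                nonzero = Z[extra].to_numpy(dtype=float)
                if np.any(np.abs(nonzero) > 1e-12):
                    bad = [e for e in extra if np.any(np.abs(Z[e].to_numpy()) > 1e-12)]
                    raise MCAError(
                        f"supplementary rows carry mass on categories absent "
                        f"from the fitted model: {bad}"
                    )
            Zv = Z.reindex(columns=pd.MultiIndex.from_tuples(self.columns_)).to_numpy(dtype=float)
        else:
            Zv = np.asarray(Z, dtype=float)
            if Zv.ndim == 1:
                Zv = Zv[None, :]
            if Zv.shape[1] != len(self.columns_):
                raise MCAError(
                    f"expected {len(self.columns_)} columns, got {Zv.shape[1]}"
                )
        row_tot = Zv.sum(axis=1, keepdims=True)
        if np.any(row_tot <= 0):
            raise MCAError("supplementary rows must have positive total")
        profile = Zv / row_tot
        G = self.column_coordinates_.to_numpy()
        lam = self.eigenvalues_[: self.n_components]
        return (profile @ G) / np.sqrt(lam)[None, :]

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        self._check_fitted()
        return {
            "n_components": self.n_components,
            "eigenvalues": self.eigenvalues_.tolist(),
            "total_inertia": self.total_inertia_,
            "columns": [list(c) for c in self.columns_],
            "dropped_columns": [list(c) for c in self.dropped_columns_],
            "column_masses": self.column_masses_.to_numpy().tolist(),
            "column_coordinates": self.column_coordinates_.to_numpy().tolist(),
            "n_rows": self.n_rows_,
            "n_active": self.n_active_,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "MCA":
        model = cls(n_components=payload["n_components"])
        model.eigenvalues_ = np.asarray(payload["eigenvalues"])
        model.total_inertia_ = payload["total_inertia"]
        model.explained_inertia_ = model.eigenvalues_ / model.total_inertia_
        model.columns_ = [tuple(c) for c in payload["columns"]]
        model.dropped_columns_ = [tuple(c) for c in payload["dropped_columns"]]
        idx = pd.MultiIndex.from_tuples(model.columns_)
        model.column_coordinates_ = pd.DataFrame(
            np.asarray(payload["column_coordinates"]),
            index=idx,
            columns=[f"dim{s + 1}" for s in range(model.n_components)],
        )
        model.column_masses_ = pd.Series(np.asarray(payload["column_masses"]), index=idx)
        model.n_rows_ = payload["n_rows"]
        model.n_active_ = payload["n_active"]
        model.row_coordinates_ = None  # not serialized; refit to recover
        return model

    def _check_fitted(self) -> None:
        if not hasattr(self, "eigenvalues_"):
            raise RuntimeError("MCA instance is not fitted")

    @staticmethod
    def _as_frame(Z) -> pd.DataFrame:
        if isinstance(Z, EvaluationSet):
            return build_indicator(Z)
        if isinstance(Z, pd.DataFrame):
            return Z
        raise TypeError("fit expects an indicator DataFrame or an EvaluationSet")


def fit_mca(Z: pd.DataFrame, n_components: int = 3) -> MCA:
    """Functional wrapper: fit an :class:`MCA` on an indicator matrix."""
    return MCA(n_components=n_components).fit(Z)


def project_supplementary(model: MCA, data) -> np.ndarray:
    """Project supplementary evaluations (EvaluationSet or indicator rows)."""
    if isinstance(data, EvaluationSet):
        data = build_indicator(data)
    return model.transform(data)
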