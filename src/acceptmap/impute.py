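"""Regularized iterative MCA imputation of missing observational measures.

Missing categorical cells are filled with fractional category memberships
by alternating between (a) a correspondence analysis of the current fuzzy
indicator matrix and (b) reconstruction of that matrix from the leading
dimensions with singular-value shrinkage.  The procedure exploits both the
similarities between evaluations (rows) and the relationships between the
nine observational variables (columns); it assumes values are missing
completely at random.

Scheme (defaults: S = 3 dimensions, tol = 1e-6, max_iter = 1000):

1. initialize each missing cell with the observed category proportion of
   its variable;
2. repeat until the largest change on an originally-missing cell is below
   ``tol``: run CA on the fuzzy indicator; shrink the leading S singular
   values by the mean of the trailing (noise) eigenvalues, floored at
   zero; rebuild the table from the rank-S reconstruction; overwrite only
   the originally-missing cells; clip to [0, 1] and renormalize each
   missing per-variable block to sum to one.

Observed cells are never modified, the result is deterministic, and it is
equivariant under row permutation.  Hard calls take the per-variable
argmax, ties broken by codebook category order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .codebook import DEFAULT_CODEBOOK, Codebook
from .schema import EvaluationSet

__all__ = ["ImputationResult", "IterativeMCAImputer", "impute"]


@dataclass
class ImputationResult:
    fuzzy_indicator: pd.DataFrame
    hard_calls: EvaluationSet
    n_iter: int
    converged: bool


class IterativeMCAImputer(BaseEstimator, TransformerMixin):
    """Impute missing categories of an N x 9 categorical frame.

    ``transform`` returns the fuzzy indicator (N x 21, fractional entries
    only in originally-missing blocks, each per-variable block summing
    to 1).
    """

    def __init__(
        self,
        n_components: int = 3,
        tol: float = 1e-6,
        max_iter: int = 1000,
        codebook: Codebook | None = None,
    ):
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter
        self.codebook = codebook

    def fit(self, X: pd.DataFrame, y=None) -> "IterativeMCAImputer":
        self.fit_transform(X)
        return self

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        codebook = self.codebook or DEFAULT_CODEBOOK
        cat = X[codebook.variable_names]
        n = len(cat)
        for var in codebook.variable_names:
            if cat[var].isna().all():
                raise ValueError(f"variable {var!r} has no observed value")
        if cat.notna().sum(axis=1).min() == 0:
            raise ValueError("every evaluation needs at least one observed value")

        cols = pd.MultiIndex.from_tuples(codebook.columns, names=["variable", "category"])
        Z = np.zeros((n, len(cols)))
        miss = np.zeros((n, len(cols)), dtype=bool)
        blocks: list[np.ndarray] = []  # column indices per variable
        start = 0
        for var in codebook.variable_names:
            cats = codebook.categories(var)
            idx = np.arange(start, start + len(cats))
            blocks.append(idx)
            col = cat[var].to_numpy()
            observed = ~pd.isna(col)
            for k, c in enumerate(cats):
                Z[observed, start + k] = (col[observed] == c).astype(float)
            # initialize the missing block with observed proportions
            props = Z[observed][:, idx].sum(axis=0)
            props = props / props.sum()
            Z[~observed[:, None] & np.isin(np.arange(len(cols)), idx)[None, :]] = 0
            Z[np.ix_(~observed, idx)] = props
            miss[np.ix_(~observed, idx)] = True
            start += len(cats)

        self.missing_mask_ = miss
        if not miss.any():
            self.n_iter_, self.converged_ = 0, True
            self.fuzzy_ = pd.DataFrame(Z, index=cat.index, columns=cols)
            return self.fuzzy_

        Q = len(codebook.variable_names)
        S_dim = self.n_components
        n_iter, converged = 0, False
        for n_iter in range(1, self.max_iter + 1):
            Z_old_missing = Z[miss]
            total = n * Q
            c = Z.sum(axis=0) / total
            keep = c > 0
            r = np.full(n, 1.0 / n)
            P = Z[:, keep] / total
            ck = c[keep]
            Sres = (P - np.outer(r, ck)) / np.sqrt(np.outer(r, ck))
            U, sig, Vt = np.linalg.svd(Sres, full_matrices=False)
            lam = sig**2
            noise = lam[S_dim:].mean() if len(lam) > S_dim else 0.0
            sig_shrunk = np.maximum(sig[:S_dim] - noise, 0.0)
            recon = np.outer(r, ck) + np.sqrt(np.outer(r, ck)) * (
                (U[:, :S_dim] * sig_shrunk) @ Vt[:S_dim, :]
            )
            Z_hat = np.zeros_like(Z)
            Z_hat[:, keep] = recon * total
            Z[miss] = Z_hat[miss]
            np.clip(Z, 0.0, 1.0, out=Z)
            # renormalize imputed per-variable blocks to sum to one
            for idx in blocks:
                block_missing = miss[:, idx[0]]
                if not block_missing.any():
                    continue
                sub = Z[np.ix_(block_missing, idx)]
                sums = sub.sum(axis=1, keepdims=True)
                fallback = Z[np.ix_(~block_missing, idx)].mean(axis=0)
                sub = np.where(sums > 1e-12, sub / np.where(sums == 0, 1, sums), fallback)
                Z[np.ix_(block_missing, idx)] = sub
            delta = np.max(np.abs(Z[miss] - Z_old_missing))
            if delta < self.tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"iterative MCA imputation did not converge in {self.max_iter} "
                "iterations; returning last iterate",
                stacklevel=2,
            )
        self.n_iter_, self.converged_ = n_iter, converged
        self.fuzzy_ = pd.DataFrame(Z, index=cat.index, columns=cols)
        return self.fuzzy_

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return self.fit_transform(X)


def impute(
    evalset: EvaluationSet,
    n_components: int = 3,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> ImputationResult:
    """Impute an :class:`EvaluationSet`; returns fuzzy table and hard calls."""
    imputer = IterativeMCAImputer(
        n_components=n_components, tol=tol, max_iter=max_iter, codebook=evalset.codebook
    )
    fuzzy = imputer.fit_transform(evalset.observational)
    completed = evalset.copy()
    codebook = evalset.codebook
    for var in codebook.variable_names:
        cats = codebook.categories(var)
        block = fuzzy[var].to_numpy()
        calls = np.asarray(cats)[block.argmax(axis=1)]
        col = completed.evaluations[var]
        filled = col.to_numpy(dtype=object)
        was_missing = pd.isna(col).to_numpy()
        filled[was_missing] = calls[was_missing]
        completed.evaluations[var] = filled
    return ImputationResult(
        fuzzy_indicator=fuzzy,
        hard_calls=completed,
        n_iter=imputer.n_iter_,
        converged=imputer.converged_,
    )
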