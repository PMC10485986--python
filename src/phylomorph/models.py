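"""Inference engines: multivariate PGLS with residual randomization,
univariate GLS with per-term Wald tests, and phylogenetic two-block
partial least squares.

All three engines realize the phylogenetic fit as ordinary least squares
on data premultiplied by the symmetric inverse square root of the
Brownian covariance. With an identity covariance they therefore reduce
exactly to their non-phylogenetic counterparts.

Caution: the multivariate ANOVA uses sequential (Type I) sums of squares,
so results depend on the order in which terms are supplied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import EcologyTable
from .errors import NumericalError, ValidationError
from .phylo_engine import PhyloCovariance, inverse_sqrt

_RANK_RTOL = 1e-9

TermSpec = tuple[str, np.ndarray]


def ecology_design(eco: EcologyTable, log_size: np.ndarray) -> list[TermSpec]:
    """The standard three-term model: habitat + primary diet + size."""
    return [
        ("habitat", np.asarray(eco.habitat, dtype=object)),
        ("diet", np.asarray(eco.primary_diet, dtype=object)),
        ("size", np.asarray(log_size, dtype=float)),
    ]


def _term_columns(name: str, values: np.ndarray, n: int) -> np.ndarray:
    """Design columns for one term: treatment-coded dummies or the covariate."""
    values = np.asarray(values)
    if values.shape[0] != n:
        raise ValidationError(f"term {name!r} has {values.shape[0]} rows, expected {n}")
    if values.dtype.kind in "OUSb":
        levels = sorted({str(v) for v in values})
        if len(levels) < 2:
            raise ValidationError(
                f"factor {name!r} has a single level ({levels[0]!r}) among these taxa"
            )
        cols = np.zeros((n, len(levels) - 1))
        index = {lv: j for j, lv in enumerate(levels)}
        for i, v in enumerate(values):
            j = index[str(v)]
            if j > 0:
                cols[i, j - 1] = 1.0
        return cols
    vals = values.astype(float)
    if vals.ndim == 1:
        vals = vals[:, None]
    return vals


def _sequential_bases(
    blocks: list[np.ndarray], names: list[str]
) -> tuple[list[np.ndarray], list[int]]:
    """Nested orthonormal bases for cumulative designs, plus per-block rank gains."""
    n = blocks[0].shape[0]
    B = np.zeros((n, 0))
    bases: list[np.ndarray] = []
    dfs: list[int] = []
    for name, blk in zip(names, blocks):
        resid = blk - B @ (B.T @ blk)
        U, s, _ = np.linalg.svd(resid, full_matrices=False)
        rank = int((s > _RANK_RTOL * max(s[0] if s.size else 0.0, 1.0)).sum())
        if rank < blk.shape[1] and name != "(intercept)":
            raise ValidationError(
                f"singular design: term {name!r} is confounded with earlier terms"
            )
        if rank == 0 and name != "(intercept)":
            raise ValidationError(f"singular design: term {name!r} adds no information")
        B = np.hstack([B, U[:, :rank]])
        bases.append(B.copy())
        dfs.append(rank)
    return bases, dfs


@dataclass
class AnovaTable:
    """Sequential (Type I) ANOVA table for one PGLS fit with RRPP inference."""

    terms: pd.DataFrame  # columns: term, df, SS, MS, F, Z, p
    df_residual: int
    SS_residual: float
    SS_total: float
    n_perm: int
    seed: int | None = None

    def p(self, term: str) -> float:
        return float(self.terms.set_index("term").loc[term, "p"])

    def z(self, term: str) -> float:
        return float(self.terms.set_index("term").loc[term, "Z"])

    def to_frame(self) -> pd.DataFrame:
        df = self.terms.copy()
        resid = pd.DataFrame(
            [
                {
                    "term": "residual",
                    "df": self.df_residual,
                    "SS": self.SS_residual,
                    "MS": self.SS_residual / max(self.df_residual, 1),
                    "F": np.nan,
                    "Z": np.nan,
                    "p": np.nan,
                }
            ]
        )
        return pd.concat([df, resid], ignore_index=True)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "terms": self.terms.to_dict(orient="records"),
            "df_residual": self.df_residual,
            "SS_residual": self.SS_residual,
            "SS_total": self.SS_total,
            "n_perm": self.n_perm,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def fit_pgls_rrpp(
    Y: np.ndarray,
    terms: Sequence[TermSpec],
    C: PhyloCovariance | np.ndarray | None,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> AnovaTable:
    """Multivariate PGLS ANOVA with residual-randomization permutation tests.

    The response and design are premultiplied by ``inverse_sqrt(C)``
    (``C=None`` means an identity covariance, i.e. a star phylogeny) and
    each term's sequential sum of squares is tested by permuting the
    residuals of its reduced model: ``n_perm`` random permutations plus
    the observed arrangement, ``p`` = fraction of the ``n_perm + 1``
    F values at least as large as the observed one. The effect size ``Z``
    is the standard deviate of log F within its permutation distribution.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = Y.shape[0]
    if not terms:
        raise ValidationError("no model terms supplied")

    names = ["(intercept)"] + [name for name, _ in terms]
    blocks = [np.ones((n, 1))] + [_term_columns(nm, v, n) for nm, v in terms]

    if C is None:
        P = None
        Yt = Y
        blocks_t = blocks
    else:
        P = inverse_sqrt(C)
        if P.shape[0] != n:
            raise ValidationError("C does not match the number of observations")
        Yt = P @ Y
        blocks_t = [P @ b for b in blocks]

    bases, dfs = _sequential_bases(blocks_t, names)
    rank_full = bases[-1].shape[1]
    df_res = n - rank_full
    if df_res < 2:
        raise ValidationError(
            f"model consumes {rank_full} of {n} df; need n >= total model df + 2"
        )

    B_full = bases[-1]
    k_terms = len(terms)
    total_sq = float((Yt**2).sum())
    s_cum = [float(((b.T @ Yt) ** 2).sum()) for b in bases]
    SS = np.array([s_cum[k + 1] - s_cum[k] for k in range(k_terms)])
    SS = np.maximum(SS, 0.0)
    RSS_obs = max(total_sq - s_cum[-1], 0.0)
    if RSS_obs <= 0:
        raise NumericalError("saturated fit: zero residual sum of squares")
    F_obs = (SS / np.array(dfs[1:])) / (RSS_obs / df_res)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # reduced-model fit and residuals per term (reduced model = earlier terms)
    fitted_red = [bases[k] @ (bases[k].T @ Yt) for k in range(k_terms)]
    resid_red = [Yt - f for f in fitted_red]

    F_perm = np.empty((n_perm, k_terms))
    for r in range(n_perm):
        perm = rng.permutation(n)
        for k in range(k_terms):
            Yp = fitted_red[k] + resid_red[k][perm]
            s_red = float(((bases[k].T @ Yp) ** 2).sum())
            s_thru = float(((bases[k + 1].T @ Yp) ** 2).sum())
            s_full = float(((B_full.T @ Yp) ** 2).sum())
            ss_k = max(s_thru - s_red, 0.0)
            rss = max(float((Yp**2).sum()) - s_full, 1e-300)
            F_perm[r, k] = (ss_k / dfs[1 + k]) / (rss / df_res)

    eps = 1e-12
    p_vals = (1.0 + (F_perm >= F_obs[None, :] - eps).sum(axis=0)) / (n_perm + 1.0)
    logs = np.log(np.vstack([F_perm, F_obs[None, :]]).clip(1e-300))
    sd = logs.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = np.where(sd > 0, (np.log(F_obs.clip(1e-300)) - logs.mean(axis=0)) / sd, 0.0)

    table = pd.DataFrame(
        {
            "term": [nm for nm, _ in terms],
            "df": dfs[1:],
            "SS": SS,
            "MS": SS / np.array(dfs[1:]),
            "F": F_obs,
            "Z": Z,
            "p": p_vals,
        }
    )
    return AnovaTable(
        terms=table,
        df_residual=df_res,
        SS_residual=RSS_obs,
        SS_total=float(SS.sum() + RSS_obs),
        n_perm=n_perm,
    )


@dataclass
class GlsFit:
    """Univariate GLS fit with per-term Wald chi-square tests."""

    coef: pd.Series
    term_tests: pd.DataFrame  # columns: term, df, chisq, p
    sigma2: float
    df_residual: int

    def p(self, term: str) -> float:
        return float(self.term_tests.set_index("term").loc[term, "p"])

    def to_frame(self) -> pd.DataFrame:
        return self.term_tests.copy()


def fit_gls_terms(
    y: np.ndarray,
    terms: Sequence[TermSpec],
    C: PhyloCovariance | np.ndarray | None,
    test: str = "wald",
) -> GlsFit:
    """Univariate phylogenetic GLS with Type II Wald chi-square term tests.

    Coefficients are the GLS solution ``(X' C^-1 X)^-1 X' C^-1 y``; each
    term is tested given all others (marginal for a main-effects model)
    against a chi-square reference distribution.
    """
    if test != "wald":
        raise ValidationError("only Wald term tests are implemented")
    y = np.asarray(y, dtype=float).ravel()
    n = y.shape[0]
    names = [name for name, _ in terms]
    cols = [_term_columns(nm, v, n) for nm, v in terms]
    X = np.hstack([np.ones((n, 1))] + cols)
    col_names = ["(intercept)"]
    slices: list[tuple[str, slice]] = []
    start = 1
    for nm, c in zip(names, cols):
        stop = start + c.shape[1]
        slices.append((nm, slice(start, stop)))
        col_names += [f"{nm}[{j}]" for j in range(c.shape[1])]
        start = stop

    if C is None:
        Xt, yt = X, y
    else:
        P = inverse_sqrt(C)
        if P.shape[0] != n:
            raise ValidationError("C does not match the number of observations")
        Xt, yt = P @ X, P @ y

    XtX = Xt.T @ Xt
    rank = np.linalg.matrix_rank(XtX, tol=_RANK_RTOL * max(np.abs(XtX).max(), 1.0))
    if rank < XtX.shape[0]:
        raise NumericalError("singular design matrix in GLS fit")
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ (Xt.T @ yt)
    resid = yt - Xt @ beta
    df_res = n - XtX.shape[0]
    if df_res < 1:
        raise ValidationError("no residual degrees of freedom")
    sigma2 = float(resid @ resid) / df_res
    cov_beta = sigma2 * XtX_inv

    rows = []
    for nm, sl in slices:
        b = beta[sl]
        V = cov_beta[sl, sl]
        try:
            W = float(b @ np.linalg.solve(V, b))
        except np.linalg.LinAlgError as exc:
            raise NumericalError(f"singular covariance for term {nm!r}") from exc
        df = b.shape[0]
        rows.append(
            {"term": nm, "df": df, "chisq": W, "p": float(stats.chi2.sf(W, df))}
        )
    return GlsFit(
        coef=pd.Series(beta, index=col_names),
        term_tests=pd.DataFrame(rows),
        sigma2=sigma2,
        df_residual=df_res,
    )


@dataclass
class PlsResult:
    """First-axis correlation of a phylogenetic two-block PLS."""

    r_pls: float
    p: float
    left_vector: np.ndarray
    right_vector: np.ndarray
    n_perm: int
    singular_values: np.ndarray = field(default_factory=lambda: np.array([]))


def ppls_integration(
    Y1: np.ndarray,
    Y2: np.ndarray,
    C: PhyloCovariance | np.ndarray | None,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> PlsResult:
    """Two-block partial least squares on phylogenetically transformed data.

    Both blocks are premultiplied by ``inverse_sqrt(C)`` and centered; the
    cross-block covariance is decomposed by singular values; ``r_pls`` is
    the correlation between the two blocks' projections on the first
    singular-vector pair. Significance comes from permuting rows of the
    transformed second block (transform once, permute after).
    """
    Y1 = np.atleast_2d(np.asarray(Y1, dtype=float))
    Y2 = np.atleast_2d(np.asarray(Y2, dtype=float))
    if Y1.shape[0] == 1:
        Y1 = Y1.T
    if Y2.shape[0] == 1:
        Y2 = Y2.T
    n = Y1.shape[0]
    if Y2.shape[0] != n:
        raise ValidationError("blocks must have the same number of rows")
    if C is not None:
        P = inverse_sqrt(C)
        if P.shape[0] != n:
            raise ValidationError("C does not match the number of observations")
        Y1, Y2 = P @ Y1, P @ Y2
    Y1 = Y1 - Y1.mean(axis=0)
    Y2 = Y2 - Y2.mean(axis=0)
    if float((Y1**2).sum()) <= 0 or float((Y2**2).sum()) <= 0:
        raise ValidationError("constant block: zero variance after centering")

    def first_axis_r(A: np.ndarray, B: np.ndarray) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
        S12 = A.T @ B / (n - 1)
        U, s, Vt = np.linalg.svd(S12, full_matrices=False)
        u, v = U[:, 0], Vt[0]
        a, b = A @ u, B @ v
        sa, sb = a.std(), b.std()
        if sa <= 0 or sb <= 0:
            return 0.0, u, v, s
        r = float(np.corrcoef(a, b)[0, 1])
        return r, u, v, s

    r_obs, u, v, s = first_axis_r(Y1, Y2)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    count = 1
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p, *_ = first_axis_r(Y1, Y2[perm])
        if r_p >= r_obs - 1e-12:
            count += 1
    return PlsResult(
        r_pls=r_obs,
        p=count / (n_perm + 1.0),
        left_vector=u,
        right_vector=v,
        n_perm=n_perm,
        singular_values=s,
    )
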