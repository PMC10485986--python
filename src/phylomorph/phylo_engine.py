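"""Phylogenetic linear algebra under Brownian motion.

Brownian covariance from a tree, symmetric inverse square root,
phylogenetic (GLS) mean, evolutionary rate-matrix estimation, and seeded
multivariate Brownian-motion simulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .data_io import Phylogeny
from .errors import NumericalError, ValidationError

_EIG_CLAMP = 1e-12


@dataclass
class PhyloCovariance:
    """Expected cross-species covariance (shared branch lengths) under BM."""

    C: np.ndarray
    taxa: list[str]

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        n = len(self.taxa)
        if self.C.shape != (n, n):
            raise ValidationError("C must be square and match taxa")
        if np.abs(self.C - self.C.T).max() > 1e-10 * max(1.0, np.abs(self.C).max()):
            raise ValidationError("C must be symmetric")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def subset(self, taxa: Sequence[str]) -> "PhyloCovariance":
        pos = {t: i for i, t in enumerate(self.taxa)}
        missing = [t for t in taxa if t not in pos]
        if missing:
            raise ValidationError(f"taxa not in covariance: {missing[:10]}")
        idx = np.array([pos[t] for t in taxa])
        return PhyloCovariance(C=self.C[np.ix_(idx, idx)], taxa=list(taxa))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.C, index=self.taxa, columns=self.taxa)


@dataclass
class RateMatrix:
    """Trait covariance per unit branch length, plus the root-state estimate."""

    R: np.ndarray
    phylo_mean: np.ndarray

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        self.phylo_mean = np.asarray(self.phylo_mean, dtype=float)
        m = self.R.shape[0]
        if self.R.shape != (m, m):
            raise ValidationError("R must be square")
        if np.abs(self.R - self.R.T).max() > 1e-10 * max(1.0, np.abs(self.R).max()):
            raise ValidationError("R must be symmetric")
        w = np.linalg.eigvalsh(self.R)
        if w.min() < -1e-10 * max(1.0, w.max()):
            raise ValidationError("R must be positive semidefinite")

    @property
    def n_traits(self) -> int:
        return self.R.shape[0]


def bm_covariance(tree: Phylogeny, taxa: Sequence[str] | None = None) -> PhyloCovariance:
    """C_ab = branch length shared by the root-to-tip paths of a and b.

    Rows/columns follow the given taxon order (default: tree tip order).
    """
    labels = tree.tip_labels
    if taxa is None:
        taxa = labels
    missing = [t for t in taxa if t not in set(labels)]
    if missing:
        raise ValidationError(f"taxa not in tree: {missing[:10]}")

    # depth of each node from the root, then C_ab = depth(MRCA(a, b))
    depth: dict[int, float] = {}
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            depth[id(node)] = node.edge.length or 0.0
        else:
            depth[id(node)] = depth[id(node.parent_node)] + (node.edge.length or 0.0)

    n = len(taxa)
    C = np.zeros((n, n))
    pos = {t: i for i, t in enumerate(taxa)}
    # postorder accumulation: for each node, tips below each child subtree
    tips_below: dict[int, list[int]] = {}
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            lbl = node.taxon.label
            tips_below[id(node)] = [pos[lbl]] if lbl in pos else []
            if lbl in pos:
                C[pos[lbl], pos[lbl]] = depth[id(node)]
        else:
            children = [tips_below[id(c)] for c in node.child_nodes()]
            d = depth[id(node)]
            for i, left in enumerate(children):
                for right in children[i + 1 :]:
                    for a in left:
                        for b in right:
                            C[a, b] = C[b, a] = d
            tips_below[id(node)] = [t for ch in children for t in ch]
    return PhyloCovariance(C=C, taxa=list(taxa))


def _check_pd(C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    w, V = np.linalg.eigh(C)
    if w.min() <= _EIG_CLAMP * w.max():
        raise NumericalError(
            "phylogenetic covariance is numerically singular; the tree may "
            "have zero-length terminal branches or duplicated tips"
        )
    return w, V


def inverse_sqrt(C: PhyloCovariance | np.ndarray) -> np.ndarray:
    """Symmetric P with P @ C @ P = I, via eigendecomposition.

    The symmetric (not Cholesky) root is used so the transform is unique
    and invariant to taxon reordering up to conjugation.
    """
    M = C.C if isinstance(C, PhyloCovariance) else np.asarray(C, dtype=float)
    w, V = _check_pd(M)
    return (V * (1.0 / np.sqrt(w))) @ V.T


def matrix_sqrt_psd(M: np.ndarray) -> np.ndarray:
    """Symmetric PSD square root, clamping tiny negative eigenvalues to zero."""
    M = np.asarray(M, dtype=float)
    w, V = np.linalg.eigh(M)
    if w.min() < -1e-8 * max(w.max(), 1.0):
        raise ValidationError("matrix is not positive semidefinite")
    w = np.clip(w, 0.0, None)
    return (V * np.sqrt(w)) @ V.T


def phylo_mean(Y: np.ndarray, C: PhyloCovariance | np.ndarray) -> np.ndarray:
    """GLS intercept (1' C^-1 1)^-1 1' C^-1 Y; the BM root-state estimate."""
    M = C.C if isinstance(C, PhyloCovariance) else np.asarray(C, dtype=float)
    Y = np.asarray(Y, dtype=float)
    squeeze = Y.ndim == 1
    if squeeze:
        Y = Y[:, None]
    if Y.shape[0] != M.shape[0]:
        raise ValidationError("Y rows must match C")
    _check_pd(M)
    cho = scipy.linalg.cho_factor(M)
    ones = np.ones(M.shape[0])
    Ci1 = scipy.linalg.cho_solve(cho, ones)
    a = (Ci1 @ Y) / (ones @ Ci1)
    return a[0] if squeeze and a.shape == (1,) else a


def estimate_rate_matrix(
    Y: np.ndarray,
    tree_or_C: Phylogeny | PhyloCovariance | np.ndarray,
    taxa: Sequence[str] | None = None,
    divisor: str = "n",
) -> RateMatrix:
    """Evolutionary rate matrix R = (Y - 1a')' C^-1 (Y - 1a') / n under BM.

    ``divisor`` is the maximum-likelihood ``"n"`` (default) or ``"n-1"``.
    """
    if isinstance(tree_or_C, Phylogeny):
        C = bm_covariance(tree_or_C, taxa)
    elif isinstance(tree_or_C, PhyloCovariance):
        C = tree_or_C
    else:
        C = PhyloCovariance(
            C=np.asarray(tree_or_C, dtype=float),
            taxa=[f"t{i}" for i in range(np.asarray(tree_or_C).shape[0])],
        )
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] == 1 and C.n_taxa != 1:
        Y = Y.T
    n = Y.shape[0]
    if n != C.n_taxa:
        raise ValidationError("Y rows must match covariance taxa")
    if divisor not in {"n", "n-1"}:
        raise ValidationError("divisor must be 'n' or 'n-1'")
    a = phylo_mean(Y, C)
    Z = Y - a[None, :]
    cho = scipy.linalg.cho_factor(C.C)
    CiZ = scipy.linalg.cho_solve(cho, Z)
    denom = n if divisor == "n" else n - 1
    R = (Z.T @ CiZ) / denom
    R = 0.5 * (R + R.T)
    return RateMatrix(R=R, phylo_mean=a)


def simulate_multivariate_bm(
    tree_or_C: Phylogeny | PhyloCovariance | np.ndarray,
    rate: RateMatrix | np.ndarray,
    root: np.ndarray | float = 0.0,
    seed: int | np.random.Generator | None = None,
    taxa: Sequence[str] | None = None,
) -> np.ndarray:
    """Draw one multivariate BM realization: Y = root + L_C Z L_R'.

    ``L_C`` and ``L_R`` are symmetric square-root factors of the
    phylogenetic covariance and the trait rate matrix; ``Z`` is an
    ``n x m`` array of independent standard normals. The seed fully
    determines the output.
    """
    if isinstance(tree_or_C, Phylogeny):
        C = bm_covariance(tree_or_C, taxa).C
    elif isinstance(tree_or_C, PhyloCovariance):
        C = tree_or_C.C
    else:
        C = np.asarray(tree_or_C, dtype=float)
    R = rate.R if isinstance(rate, RateMatrix) else np.asarray(rate, dtype=float)
    if R.ndim == 0:
        R = R[None, None]
    m = R.shape[0]
    n = C.shape[0]
    root = np.broadcast_to(np.asarray(root, dtype=float), (m,))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L_C = matrix_sqrt_psd(C)
    L_R = matrix_sqrt_psd(R)
    Z = rng.standard_normal((n, m))
    return root[None, :] + L_C @ Z @ L_R.T
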