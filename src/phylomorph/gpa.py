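"""Procrustes geometry: centroid size, pairwise superposition, and GPA.

Full Procrustes alignment is used (translation, rotation, and scaling are
removed); size re-enters downstream models only as log centroid size.
Reflections are excluded everywhere (proper rotations only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_io import LandmarkSet
from .errors import NumericalError, ValidationError

_DEGENERATE_RTOL = 1e-12


def centroid_size(config: np.ndarray) -> float:
    """sqrt of the summed squared distances of the landmarks to their centroid.

    Translation- and rotation-invariant; scales linearly with the
    configuration. A degenerate all-identical configuration returns 0 with
    a warning.
    """
    config = np.asarray(config, dtype=float)
    if config.ndim != 2 or config.shape[0] < 1:
        raise ValidationError(f"config must be p x d with p >= 1, got {config.shape}")
    centered = config - config.mean(axis=0)
    cs = float(np.sqrt((centered**2).sum()))
    if cs == 0.0:
        warnings.warn("degenerate configuration: all landmarks identical", stacklevel=2)
    return cs


def optimal_superposition(
    A: np.ndarray, B: np.ndarray, allow_scale: bool = False
) -> tuple[np.ndarray, float, float]:
    """Optimal rigid (optionally scaled) superposition of B onto A.

    Both configurations must be centered. Returns ``(R, s, residual)``
    where the proper rotation ``R`` (det +1; reflections excluded) and
    scale ``s`` minimize ``sum ||A_i - s * (B @ R)_i||^2`` and ``residual``
    is the minimized root-sum-of-squares.

    For degenerate (coplanar/collinear) configurations where the optimum
    is non-unique, the candidate with the smallest rotation angle is
    chosen deterministically, with a warning.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.ndim != 2:
        raise ValidationError("A and B must be equal-shape p x d arrays")
    if A.shape[0] < 3:
        raise ValidationError("need at least 3 landmarks for superposition")
    for name, X in (("A", A), ("B", B)):
        if np.abs(X.mean(axis=0)).max() > 1e-8 * max(1.0, np.abs(X).max()):
            raise ValidationError(f"{name} is not centered")

    M = B.T @ A
    U, sv, Vt = np.linalg.svd(M)
    d = np.sign(np.linalg.det(U @ Vt))
    if d == 0:
        d = 1.0
    flip = np.ones(M.shape[0])
    flip[-1] = d
    R = U @ np.diag(flip) @ Vt
    trace = float((sv * flip).sum())

    if sv[-1] <= _DEGENERATE_RTOL * max(sv[0], 1.0) and M.shape[0] == 3:
        # optimum non-unique: flipping the null singular vector gives an
        # equally good rotation; pick the one closer to the identity.
        alt_flip = flip.copy()
        alt_flip[-1] *= -1
        alt_flip[-2] *= -1  # keep det +1
        R_alt = U @ np.diag(alt_flip) @ Vt
        warnings.warn("degenerate configuration: rotation non-unique", stacklevel=2)
        if np.trace(R_alt) > np.trace(R):
            R, trace = R_alt, float((sv * alt_flip).sum())

    bb = float((B**2).sum())
    if allow_scale:
        if bb == 0:
            raise ValidationError("B has zero size; cannot scale")
        s = max(trace / bb, 0.0)
    else:
        s = 1.0
    resid_sq = float((A**2).sum()) + s * s * bb - 2.0 * s * trace
    residual = float(np.sqrt(max(resid_sq, 0.0)))
    return R, s, residual


@dataclass
class ShapeAlignment:
    """Result of a Generalized Procrustes Analysis.

    ``aligned`` holds tangent-space-projected Procrustes coordinates with
    each configuration centered at the origin; ``centroid_size`` is the
    pre-scaling size of each specimen; ``consensus`` is the mean shape.
    """

    taxa: list[str]
    aligned: np.ndarray  # n x p x 3
    centroid_size: np.ndarray  # n
    consensus: np.ndarray  # p x 3
    n_iterations: int
    converged: bool
    objective_trace: list[float] = field(default_factory=list)

    @property
    def log_centroid_size(self) -> np.ndarray:
        return np.log(self.centroid_size)

    @property
    def n_taxa(self) -> int:
        return self.aligned.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.aligned.shape[1]

    def flatten(self) -> np.ndarray:
        """Aligned coordinates as an n x (3p) matrix (x1,y1,z1,x2,...)."""
        return self.aligned.reshape(self.n_taxa, -1)

    def procrustes_distances(self) -> np.ndarray:
        """Pairwise Euclidean distances between aligned specimens."""
        flat = self.flatten()
        diff = flat[:, None, :] - flat[None, :, :]
        return np.sqrt((diff**2).sum(axis=2))


def _principal_axis_rotation(consensus: np.ndarray) -> np.ndarray:
    """Proper rotation taking the consensus onto its principal axes.

    Sign convention: on each of the first two principal axes the
    largest-magnitude *projected consensus coordinate* is made positive
    (a frame-invariant criterion, so outputs are reproducible no matter
    how the input was oriented); the third axis completes a right-handed
    frame.
    """
    cov = consensus.T @ consensus
    _, vecs = np.linalg.eigh(cov)
    vecs = vecs[:, ::-1].copy()  # descending variance
    proj = consensus @ vecs
    for j in range(2):
        k = int(np.argmax(np.abs(proj[:, j])))
        if proj[k, j] < 0:
            vecs[:, j] *= -1
    vecs[:, 2] = np.cross(vecs[:, 0], vecs[:, 1])
    return vecs


def generalized_procrustes(
    lm: LandmarkSet | np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 200,
    project: bool = True,
) -> ShapeAlignment:
    """Generalized Procrustes Analysis of all configurations in ``lm``.

    Iteratively centers each configuration, scales to unit centroid size,
    rotates each onto the current consensus, and renormalizes the
    consensus to unit size, until the root-summed-squared consensus change
    drops below ``tol`` (or ``max_iter`` is hit, in which case
    ``converged`` is False and a warning is emitted). Aligned shapes are
    finally projected orthogonally onto the tangent space at the consensus
    and rotated to the consensus principal axes.
    """
    if isinstance(lm, LandmarkSet):
        taxa = list(lm.taxa)
        coords = lm.coords
    else:
        coords = np.asarray(lm, dtype=float)
        taxa = [f"s{i}" for i in range(coords.shape[0])]
    if coords.ndim != 3:
        raise ValidationError("expected an n x p x 3 coordinate array")
    n, p, _ = coords.shape
    if n < 2:
        raise ValidationError("GPA needs at least 2 specimens")
    if p < 3:
        raise ValidationError("GPA needs at least 3 landmarks")

    centered = coords - coords.mean(axis=1, keepdims=True)
    sizes = np.sqrt((centered**2).sum(axis=(1, 2)))
    if (sizes <= 0).any():
        bad = taxa[int(np.argmin(sizes))]
        raise ValidationError(f"zero centroid size for taxon {bad!r}")
    shapes = centered / sizes[:, None, None]

    consensus = shapes[0].copy()
    consensus /= np.sqrt((consensus**2).sum())
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for i in range(n):
            R, _, _ = optimal_superposition(consensus, shapes[i])
            shapes[i] = shapes[i] @ R
        new_consensus = shapes.mean(axis=0)
        new_consensus /= np.sqrt((new_consensus**2).sum())
        trace.append(float(((shapes - new_consensus) ** 2).sum()))
        delta = float(np.sqrt(((new_consensus - consensus) ** 2).sum()))
        consensus = new_consensus
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"GPA did not converge in {max_iter} iterations", stacklevel=2
        )

    if project:
        flat = shapes.reshape(n, -1)
        c = consensus.ravel()
        c = c / np.linalg.norm(c)
        flat = flat + np.outer(1.0 - flat @ c, c)
        shapes = flat.reshape(n, p, 3)

    consensus = shapes.mean(axis=0)
    rot = _principal_axis_rotation(consensus)
    shapes = shapes @ rot
    consensus = consensus @ rot

    return ShapeAlignment(
        taxa=taxa,
        aligned=shapes,
        centroid_size=sizes,
        consensus=consensus,
        n_iterations=it,
        converged=converged,
        objective_trace=trace,
    )


def module_alignments(
    lm: LandmarkSet, tol: float = 1e-10, max_iter: int = 200
) -> dict[str, ShapeAlignment]:
    """Independent GPA per skull module; centroid sizes are module-local."""
    if not lm.module_of:
        raise ValidationError("LandmarkSet has no module assignments")
    out: dict[str, ShapeAlignment] = {}
    for module in lm.module_names:
        idx = lm.module_indices(module)
        if idx.size < 3:
            raise ValidationError(
                f"module {module!r} has only {idx.size} landmarks; need >= 3"
            )
        out[module] = generalized_procrustes(
            lm.coords[:, idx, :], tol=tol, max_iter=max_iter
        )
        out[module].taxa = list(lm.taxa)
    return out
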