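"""Shape PCA and morphospace summaries.

Covariance-based PCA on Procrustes-aligned coordinates, so component
"variance explained" statements refer to fractions of total Procrustes
variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import EcologyTable
from .errors import ValidationError
from .gpa import ShapeAlignment

_VAR_RTOL = 1e-12


@dataclass
class PCAResult:
    """Scores, loadings and variance fractions of a shape PCA.

    Only positive-variance components are retained; ``variance_fraction``
    is relative to the total variance of the input (so it sums to 1 up to
    the discarded numerically-zero axes).
    """

    taxa: list[str]
    scores: np.ndarray  # n x k
    loadings: np.ndarray  # (3p) x k
    variance_fraction: np.ndarray  # k
    mean: np.ndarray  # 3p

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def to_frame(self, n_axes: int | None = None) -> pd.DataFrame:
        k = self.n_components if n_axes is None else min(n_axes, self.n_components)
        return pd.DataFrame(
            self.scores[:, :k],
            index=self.taxa,
            columns=[f"PC{j + 1}" for j in range(k)],
        )


def shape_pca(alignment: ShapeAlignment | np.ndarray, taxa: list[str] | None = None) -> PCAResult:
    """PCA of aligned shapes via singular value decomposition.

    Flattens aligned coordinates to n x (3p), column-centers, and
    decomposes. Components with variance <= 1e-12 of the total are
    dropped. Sign convention: the largest-magnitude loading of each
    component is positive.
    """
    if isinstance(alignment, ShapeAlignment):
        X = alignment.flatten()
        taxa = list(alignment.taxa)
    else:
        X = np.asarray(alignment, dtype=float)
        if X.ndim == 3:
            X = X.reshape(X.shape[0], -1)
        if taxa is None:
            taxa = [f"s{i}" for i in range(X.shape[0])]
    n = X.shape[0]
    if n < 3:
        raise ValidationError("shape PCA needs at least 3 specimens")
    mean = X.mean(axis=0)
    Xc = X - mean
    total_var = float((Xc**2).sum()) / (n - 1)
    if total_var <= 0:
        raise ValidationError("zero total shape variance")

    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    variances = s**2 / (n - 1)
    keep = variances > _VAR_RTOL * total_var
    U, s, Vt = U[:, keep], s[keep], Vt[keep]
    loadings = Vt.T
    scores = U * s
    # deterministic signs
    for j in range(loadings.shape[1]):
        k = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[k, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return PCAResult(
        taxa=taxa,
        scores=scores,
        loadings=loadings,
        variance_fraction=variances[: scores.shape[1]] / total_var,
        mean=mean,
    )


def morphospace_table(
    pca: PCAResult,
    eco: EcologyTable,
    axes: tuple[int, int] = (0, 1),
    group_columns: tuple[str, ...] = ("habitat", "primary_diet"),
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Join PC scores with ecological labels and summarize group clustering.

    Returns the joined per-taxon table and, for each grouping column, a
    per-group table of centroids and within-group dispersion (RMS distance
    to the group centroid) in the chosen pair of axes.
    """
    a, b = axes
    if max(a, b) >= pca.n_components:
        raise ValidationError(
            f"axis index {max(a, b)} out of range (n_components={pca.n_components})"
        )
    if [t for t in pca.taxa] != list(eco.taxa):
        eco = eco.subset(pca.taxa)
    table = pd.DataFrame(
        {
            "taxon": pca.taxa,
            f"PC{a + 1}": pca.scores[:, a],
            f"PC{b + 1}": pca.scores[:, b],
            "habitat": eco.habitat,
            "primary_diet": eco.primary_diet,
        }
    )
    summaries: dict[str, pd.DataFrame] = {}
    xy = pca.scores[:, [a, b]]
    for col in group_columns:
        rows = []
        for level, sub in table.groupby(col, sort=True):
            pts = xy[sub.index.to_numpy()]
            centroid = pts.mean(axis=0)
            disp = float(np.sqrt(((pts - centroid) ** 2).sum(axis=1).mean()))
            rows.append(
                {
                    col: level,
                    "n": len(sub),
                    f"centroid_PC{a + 1}": centroid[0],
                    f"centroid_PC{b + 1}": centroid[1],
                    "dispersion": disp,
                }
            )
        summaries[col] = pd.DataFrame(rows)
    return table, summaries


def plot_morphospace(
    table: pd.DataFrame,
    color_by: str,
    path: str,
    axes_labels: tuple[str, str] | None = None,
) -> None:
    """Scatter plot of two PC columns colored by an ecology column (file output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pc_cols = [c for c in table.columns if c.startswith("PC")][:2]
    fig, ax = plt.subplots(figsize=(6, 5))
    for level, sub in table.groupby(color_by, sort=True):
        ax.scatter(sub[pc_cols[0]], sub[pc_cols[1]], label=str(level), s=18)
    ax.set_xlabel(axes_labels[0] if axes_labels else pc_cols[0])
    ax.set_ylabel(axes_labels[1] if axes_labels else pc_cols[1])
    ax.legend(fontsize=7, loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
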