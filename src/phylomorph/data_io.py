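"""Readers, writers, ecological coding rules, and the taxon-matched data model.

The module owns four domain types -- :class:`LandmarkSet`,
:class:`EcologyTable`, :class:`Phylogeny`, :class:`MatchedDataset` -- plus
the file dialects used to move them around:

* a TPS landmark dialect (``LM3=<n>`` blocks, one ``x y z`` line per
  landmark, an ``ID=<taxon>`` line, optional ``SCALE=`` ignored),
* a wide CSV landmark dialect (one row per taxon, columns
  ``x1,y1,z1,...``),
* an ecology CSV (``taxon,habitat,primary_diet,n_diet_records,prop_<cat>...``),
* Newick trees (via dendropy),
* a landmark->module assignment file (YAML or two-column CSV).

Taxon names are compared after replacing spaces with underscores and
case-folding; original spellings are preserved on every object.
"""

from __future__ import annotations

import csv
import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, ValidationError

#: The seven habitat-use categories, in the order used for factor coding.
HABITAT_LEVELS: tuple[str, ...] = (
    "semi-fossorial",
    "cryptozoic",
    "terrestrial",
    "semi-arboreal",
    "arboreal",
    "semi-aquatic",
    "aquatic",
)

#: Default prey categories. Nine named groups plus a catch-all tenth slot.
DIET_CATEGORIES: tuple[str, ...] = (
    "amphibians",
    "reptiles",
    "birds",
    "mammals",
    "fish",
    "reptile_eggs",
    "bird_eggs",
    "annelids",
    "mollusks",
    "other_invertebrates",
)

GENERALIST = "generalist"

_FLOAT_FMT = "%.17g"


def normalize_name(name: str) -> str:
    """Canonical form used for taxon-name matching (spaces->underscores, casefold)."""
    return name.strip().replace(" ", "_").casefold()


# ---------------------------------------------------------------------------
# LandmarkSet
# ---------------------------------------------------------------------------


@dataclass
class LandmarkSet:
    """3-D landmark configurations for a set of taxa.

    Parameters
    ----------
    taxa
        Ordered taxon names; must be unique.
    coords
        Array of shape ``(n_taxa, n_landmarks, 3)``; NaNs are rejected.
    landmark_labels
        Optional labels, one per landmark (defaults to ``lm000``...).
    module_of
        Map from 0-based landmark index to module name. Every landmark
        must be assigned to exactly one module.
    units
        Free-text record of the original coordinate units (metadata only;
        coordinates are treated as dimensionless after reading).
    """

    taxa: list[str]
    coords: np.ndarray
    landmark_labels: list[str] = field(default_factory=list)
    module_of: dict[int, str] = field(default_factory=dict)
    units: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValidationError(
                f"coords must have shape (n_taxa, n_landmarks, 3), got {self.coords.shape}"
            )
        if self.coords.shape[0] != len(self.taxa):
            raise ValidationError("number of taxa does not match coords.shape[0]")
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise ValidationError(f"duplicate taxon names: {dupes}")
        if np.isnan(self.coords).any():
            raise ValidationError("coords contain NaN values")
        if not self.landmark_labels:
            self.landmark_labels = [f"lm{i:03d}" for i in range(self.n_landmarks)]
        if len(self.landmark_labels) != self.n_landmarks:
            raise ValidationError("landmark_labels length mismatch")
        if self.module_of:
            missing = [i for i in range(self.n_landmarks) if i not in self.module_of]
            if missing:
                raise ValidationError(
                    f"landmarks without a module assignment: {missing[:10]}"
                )
            extra = [i for i in self.module_of if not 0 <= i < self.n_landmarks]
            if extra:
                raise ValidationError(f"module assignments for unknown landmarks: {extra}")

    @property
    def n_taxa(self) -> int:
        return self.coords.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[1]

    @property
    def module_names(self) -> list[str]:
        seen: list[str] = []
        for i in range(self.n_landmarks):
            m = self.module_of.get(i)
            if m is not None and m not in seen:
                seen.append(m)
        return seen

    def module_indices(self, module: str) -> np.ndarray:
        idx = np.array(
            [i for i in range(self.n_landmarks) if self.module_of.get(i) == module],
            dtype=int,
        )
        if idx.size == 0:
            raise ValidationError(f"unknown module: {module!r}")
        return idx

    def module_slice(self, module: str) -> "LandmarkSet":
        """A new LandmarkSet restricted to one module's landmarks."""
        idx = self.module_indices(module)
        return LandmarkSet(
            taxa=list(self.taxa),
            coords=self.coords[:, idx, :].copy(),
            landmark_labels=[self.landmark_labels[i] for i in idx],
            module_of={j: module for j in range(idx.size)},
            units=self.units,
        )

    def subset_taxa(self, taxa: Sequence[str]) -> "LandmarkSet":
        pos = {t: i for i, t in enumerate(self.taxa)}
        missing = [t for t in taxa if t not in pos]
        if missing:
            raise ValidationError(f"taxa not in LandmarkSet: {missing[:10]}")
        rows = [pos[t] for t in taxa]
        return LandmarkSet(
            taxa=list(taxa),
            coords=self.coords[rows].copy(),
            landmark_labels=list(self.landmark_labels),
            module_of=dict(self.module_of),
            units=self.units,
        )


def read_landmark_file(path: str | Path, format: str | None = None) -> LandmarkSet:
    """Read a landmark file; ``format`` is ``"tps"``/``"csv"`` or inferred from suffix."""
    path = Path(path)
    if format is None:
        format = "tps" if path.suffix.lower() == ".tps" else "csv"
    if format == "tps":
        return _read_tps(path)
    if format == "csv":
        return _read_landmark_csv(path)
    raise ValidationError(f"unknown landmark format: {format!r}")


def _read_tps(path: Path) -> LandmarkSet:
    taxa: list[str] = []
    configs: list[np.ndarray] = []
    n_expected: int | None = None
    cur_points: list[list[float]] = []
    cur_n: int | None = None
    cur_id: str | None = None

    def flush(lineno: int) -> None:
        nonlocal cur_points, cur_n, cur_id, n_expected
        if cur_n is None:
            return
        if cur_id is None:
            raise FormatError(f"{path}: block ending near line {lineno} has no ID= line")
        if len(cur_points) != cur_n:
            raise FormatError(
                f"{path}: taxon {cur_id!r} declares LM3={cur_n} but has "
                f"{len(cur_points)} coordinate lines"
            )
        if n_expected is None:
            n_expected = cur_n
        elif cur_n != n_expected:
            raise FormatError(
                f"{path}: taxon {cur_id!r} has {cur_n} landmarks, expected {n_expected}"
            )
        if cur_id in taxa:
            raise FormatError(f"{path}: duplicate taxon {cur_id!r}")
        taxa.append(cur_id)
        configs.append(np.array(cur_points, dtype=float))
        cur_points, cur_n, cur_id = [], None, None

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM3="):
                flush(lineno)
                try:
                    cur_n = int(line.split("=", 1)[1])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: bad LM3 line {line!r}") from exc
            elif upper.startswith("ID="):
                cur_id = line.split("=", 1)[1].strip()
            elif upper.startswith("SCALE="):
                warnings.warn(f"{path}:{lineno}: SCALE= line ignored", stacklevel=2)
            elif upper.startswith("LM="):
                raise FormatError(f"{path}:{lineno}: 2-D TPS (LM=) not supported; need LM3=")
            else:
                parts = line.split()
                if len(parts) != 3:
                    raise FormatError(
                        f"{path}:{lineno}: expected 3 coordinates, got {line!r}"
                    )
                try:
                    cur_points.append([float(p) for p in parts])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: bad coordinate {line!r}") from exc
    flush(lineno=-1)
    if not taxa:
        raise FormatError(f"{path}: no landmark blocks found")
    return LandmarkSet(taxa=taxa, coords=np.stack(configs))


def write_landmark_tps(lm: LandmarkSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for t, config in zip(lm.taxa, lm.coords):
            fh.write(f"LM3={lm.n_landmarks}\n")
            for row in config:
                fh.write(" ".join(_FLOAT_FMT % v for v in row) + "\n")
            fh.write(f"ID={t}\n\n")


def _read_landmark_csv(path: Path) -> LandmarkSet:
    df = pd.read_csv(path)
    if df.shape[1] < 4:
        raise FormatError(f"{path}: need a taxon column plus x1,y1,z1,... columns")
    taxon_col = df.columns[0]
    coord_cols = list(df.columns[1:])
    if len(coord_cols) % 3 != 0:
        raise FormatError(
            f"{path}: {len(coord_cols)} coordinate columns is not a multiple of 3"
        )
    taxa = [str(t) for t in df[taxon_col]]
    if len(set(taxa)) != len(taxa):
        raise FormatError(f"{path}: duplicate taxon names")
    try:
        values = df[coord_cols].to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric coordinate values") from exc
    if np.isnan(values).any():
        bad = taxa[int(np.argwhere(np.isnan(values))[0, 0])]
        raise FormatError(f"{path}: missing coordinate values for taxon {bad!r}")
    coords = values.reshape(len(taxa), -1, 3)
    return LandmarkSet(taxa=taxa, coords=coords)


def write_landmark_csv(lm: LandmarkSet, path: str | Path) -> None:
    header = ["taxon"]
    for i in range(lm.n_landmarks):
        header += [f"x{i + 1}", f"y{i + 1}", f"z{i + 1}"]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for t, config in zip(lm.taxa, lm.coords):
            w.writerow([t] + [_FLOAT_FMT % v for v in config.ravel()])


def read_module_assignments(path: str | Path) -> dict[int, str]:
    """Read a landmark->module map from YAML (``index: module``) or 2-column CSV."""
    path = Path(path)
    if path.suffix.lower() in {".yml", ".yaml"}:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, Mapping):
            raise FormatError(f"{path}: expected a mapping of landmark index to module")
        return {int(k): str(v) for k, v in raw.items()}
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected columns landmark,module")
    return {int(r[0]): str(r[1]) for r in df.itertuples(index=False)}


def write_module_assignments(module_of: Mapping[int, str], path: str | Path) -> None:
    path = Path(path)
    items = sorted((int(k), str(v)) for k, v in module_of.items())
    if path.suffix.lower() in {".yml", ".yaml"}:
        with open(path, "w") as fh:
            for k, v in items:
                fh.write(f"{k}: {v}\n")
    else:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["landmark", "module"])
            w.writerows(items)


# ---------------------------------------------------------------------------
# EcologyTable and coding rules
# ---------------------------------------------------------------------------


@dataclass
class EcologyTable:
    """Per-taxon habitat category, primary diet, and optional quantitative diet data.

    ``diet_proportions`` is an ``n_taxa x n_categories`` array (rows may be
    all-NaN for taxa without quantitative data); present rows must each sum
    to 1 within 1e-9.
    """

    taxa: list[str]
    habitat: list[str]
    primary_diet: list[str]
    diet_categories: tuple[str, ...] = DIET_CATEGORIES
    diet_proportions: np.ndarray | None = None
    n_diet_records: np.ndarray | None = None
    habitat_levels: tuple[str, ...] = HABITAT_LEVELS

    def __post_init__(self) -> None:
        n = len(self.taxa)
        if len(set(self.taxa)) != n:
            raise ValidationError("duplicate taxon names in EcologyTable")
        if len(self.habitat) != n or len(self.primary_diet) != n:
            raise ValidationError("habitat/primary_diet length mismatch")
        bad = sorted({h for h in self.habitat if h not in self.habitat_levels})
        if bad:
            raise ValidationError(
                f"unknown habitat values {bad}; allowed: {list(self.habitat_levels)}"
            )
        if self.diet_proportions is not None:
            self.diet_proportions = np.asarray(self.diet_proportions, dtype=float)
            if self.diet_proportions.shape != (n, len(self.diet_categories)):
                raise ValidationError(
                    "diet_proportions must be n_taxa x n_categories "
                    f"({n} x {len(self.diet_categories)}), got "
                    f"{self.diet_proportions.shape}"
                )
            present = ~np.isnan(self.diet_proportions).any(axis=1)
            sums = self.diet_proportions[present].sum(axis=1)
            if present.any() and np.abs(sums - 1.0).max() > 1e-9:
                raise ValidationError("diet_proportions rows must sum to 1 within 1e-9")
            if present.any() and (self.diet_proportions[present] < 0).any():
                raise ValidationError("diet_proportions must be nonnegative")
        if self.n_diet_records is not None:
            self.n_diet_records = np.asarray(self.n_diet_records, dtype=float)
            if self.n_diet_records.shape != (n,):
                raise ValidationError("n_diet_records length mismatch")
            ok = np.isnan(self.n_diet_records) | (self.n_diet_records >= 0)
            if not ok.all():
                raise ValidationError("n_diet_records must be nonnegative")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def subset(self, taxa: Sequence[str]) -> "EcologyTable":
        pos = {t: i for i, t in enumerate(self.taxa)}
        missing = [t for t in taxa if t not in pos]
        if missing:
            raise ValidationError(f"taxa not in EcologyTable: {missing[:10]}")
        rows = [pos[t] for t in taxa]
        return EcologyTable(
            taxa=list(taxa),
            habitat=[self.habitat[i] for i in rows],
            primary_diet=[self.primary_diet[i] for i in rows],
            diet_categories=self.diet_categories,
            diet_proportions=None
            if self.diet_proportions is None
            else self.diet_proportions[rows].copy(),
            n_diet_records=None
            if self.n_diet_records is None
            else self.n_diet_records[rows].copy(),
            habitat_levels=self.habitat_levels,
        )

    def to_frame(self) -> pd.DataFrame:
        data: dict[str, object] = {
            "taxon": self.taxa,
            "habitat": self.habitat,
            "primary_diet": self.primary_diet,
        }
        if self.n_diet_records is not None:
            data["n_diet_records"] = self.n_diet_records
        if self.diet_proportions is not None:
            for j, cat in enumerate(self.diet_categories):
                data[f"prop_{cat}"] = self.diet_proportions[:, j]
        return pd.DataFrame(data)


def assign_primary_diet(
    proportions: Mapping[str, float] | Sequence[float],
    categories: Sequence[str] | None = None,
) -> str:
    """Primary-diet category: the one with proportion strictly > 0.5, else generalist.

    ``proportions`` is a mapping category->proportion or a sequence aligned
    with ``categories`` (default :data:`DIET_CATEGORIES`). Entries must be
    nonnegative and sum to 1.
    """
    if isinstance(proportions, Mapping):
        cats = list(proportions.keys())
        vals = np.array([proportions[c] for c in cats], dtype=float)
    else:
        cats = list(categories if categories is not None else DIET_CATEGORIES)
        vals = np.asarray(proportions, dtype=float)
        if vals.shape != (len(cats),):
            raise ValidationError(
                f"expected {len(cats)} proportions, got shape {vals.shape}"
            )
    if (vals < 0).any():
        raise ValidationError("diet proportions must be nonnegative")
    if abs(vals.sum() - 1.0) > 1e-8:
        raise ValidationError(f"diet proportions must sum to 1, got {vals.sum()!r}")
    top = int(np.argmax(vals))
    if vals[top] > 0.5:
        return cats[top]
    return GENERALIST


def filter_quantitative_diet(eco: EcologyTable, min_records: int = 10) -> EcologyTable:
    """Taxa with strictly more than ``min_records`` diet records (default >10)."""
    if eco.n_diet_records is None:
        raise ValidationError("EcologyTable has no n_diet_records column")
    keep = [
        t
        for t, n in zip(eco.taxa, eco.n_diet_records)
        if not np.isnan(n) and n > min_records
    ]
    return eco.subset(keep)


def read_ecology_csv(
    path: str | Path,
    diet_categories: Sequence[str] | None = None,
    habitat_levels: Sequence[str] = HABITAT_LEVELS,
) -> EcologyTable:
    """Read an ecology CSV (``taxon,habitat,primary_diet[,n_diet_records][,prop_*...]``)."""
    df = pd.read_csv(path)
    required = {"taxon", "habitat", "primary_diet"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    prop_cols = [c for c in df.columns if c.startswith("prop_")]
    if diet_categories is None:
        diet_categories = (
            tuple(c[len("prop_") :] for c in prop_cols) if prop_cols else DIET_CATEGORIES
        )
    props = None
    if prop_cols:
        props = df[[f"prop_{c}" for c in diet_categories]].to_numpy(dtype=float)
    records = None
    if "n_diet_records" in df.columns:
        records = df["n_diet_records"].to_numpy(dtype=float)
    return EcologyTable(
        taxa=[str(t) for t in df["taxon"]],
        habitat=[str(h) for h in df["habitat"]],
        primary_diet=[str(d) for d in df["primary_diet"]],
        diet_categories=tuple(diet_categories),
        diet_proportions=props,
        n_diet_records=records,
        habitat_levels=tuple(habitat_levels),
    )


def write_ecology_csv(eco: EcologyTable, path: str | Path) -> None:
    df = eco.to_frame()
    with open(path, "w", newline="") as fh:
        cols = list(df.columns)
        w = csv.writer(fh)
        w.writerow(cols)
        for _, row in df.iterrows():
            out = []
            for c in cols:
                v = row[c]
                if isinstance(v, float):
                    out.append("" if np.isnan(v) else _FLOAT_FMT % v)
                else:
                    out.append(v)
            w.writerow(out)


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------


@dataclass
class Phylogeny:
    """A rooted tree with branch lengths, thinly wrapping a dendropy Tree."""

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = self.tip_labels
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate tip labels in tree")
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValidationError("negative branch length in tree")

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    def root_to_tip_depths(self) -> dict[str, float]:
        depths: dict[str, float] = {}
        for leaf in self.tree.leaf_node_iter():
            d = 0.0
            node = leaf
            while node.parent_node is not None:
                d += node.edge.length or 0.0
                node = node.parent_node
            depths[leaf.taxon.label] = d
        return depths

    @property
    def is_ultrametric(self, tol: float = 1e-6) -> bool:
        d = np.array(list(self.root_to_tip_depths().values()))
        return bool(d.max() - d.min() <= tol * max(d.max(), 1.0))

    def prune_to(self, taxa: Sequence[str]) -> "Phylogeny":
        """Prune to the given tips, preserving path lengths among them."""
        keep = set(taxa)
        have = set(self.tip_labels)
        missing = sorted(keep - have)
        if missing:
            raise ValidationError(f"tips not in tree: {missing[:10]}")
        clone = self.tree.clone(depth=1)
        clone.retain_taxa_with_labels(list(keep))
        # retain_taxa suppresses unifurcations, summing edge lengths, so
        # patristic distances among kept tips are unchanged.
        return Phylogeny(tree=clone)

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    @classmethod
    def from_newick(cls, source: str | Path, is_path: bool = True) -> "Phylogeny":
        if is_path:
            tree = dendropy.Tree.get(path=str(source), schema="newick")
        else:
            tree = dendropy.Tree.get(data=str(source), schema="newick")
        return cls(tree=tree)


def read_newick(path: str | Path) -> Phylogeny:
    return Phylogeny.from_newick(path, is_path=True)


def write_newick(phy: Phylogeny, path: str | Path) -> None:
    Path(path).write_text(phy.as_newick() + "\n")


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------


@dataclass
class MatchedDataset:
    """Landmarks, ecology, and tree restricted to their common taxa, same order."""

    landmarks: LandmarkSet
    ecology: EcologyTable
    phylogeny: Phylogeny
    dropped: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        t1 = [normalize_name(t) for t in self.landmarks.taxa]
        t2 = [normalize_name(t) for t in self.ecology.taxa]
        t3 = sorted(normalize_name(t) for t in self.phylogeny.tip_labels)
        if t1 != t2 or sorted(t1) != t3:
            raise ValidationError("MatchedDataset components disagree on taxa")

    @property
    def taxa(self) -> list[str]:
        return list(self.landmarks.taxa)

    @property
    def n_taxa(self) -> int:
        return self.landmarks.n_taxa


def match_and_prune(
    lm: LandmarkSet,
    eco: EcologyTable,
    tree: Phylogeny,
    normalize: bool = True,
) -> MatchedDataset:
    """Intersect the three taxon sets and prune each component to the overlap.

    Names are compared exactly after optional normalization (spaces vs
    underscores, case). The result keeps the landmark set's taxon order and
    records dropped names per source in ``dropped``.
    """
    norm = normalize_name if normalize else (lambda s: s)
    lm_map = {norm(t): t for t in lm.taxa}
    eco_map = {norm(t): t for t in eco.taxa}
    tree_map = {norm(t): t for t in tree.tip_labels}
    common = [norm(t) for t in lm.taxa if norm(t) in eco_map and norm(t) in tree_map]
    if len(common) < 4:
        raise ValidationError(
            f"only {len(common)} taxa shared by landmarks, ecology and tree; "
            "need at least 4"
        )
    dropped = {
        "landmarks": [lm_map[k] for k in lm_map if k not in set(common)],
        "ecology": [eco_map[k] for k in eco_map if k not in set(common)],
        "tree": [tree_map[k] for k in tree_map if k not in set(common)],
    }
    lm_sub = lm.subset_taxa([lm_map[k] for k in common])
    eco_sub = eco.subset([eco_map[k] for k in common])
    tree_sub = tree.prune_to([tree_map[k] for k in common])
    if normalize:
        # unify spellings on the landmark set's originals
        rename = {norm(t): t for t in lm_sub.taxa}
        eco_sub = EcologyTable(
            taxa=[rename[norm(t)] for t in eco_sub.taxa],
            habitat=eco_sub.habitat,
            primary_diet=eco_sub.primary_diet,
            diet_categories=eco_sub.diet_categories,
            diet_proportions=eco_sub.diet_proportions,
            n_diet_records=eco_sub.n_diet_records,
            habitat_levels=eco_sub.habitat_levels,
        )
        for leaf in tree_sub.tree.leaf_node_iter():
            leaf.taxon.label = rename[norm(leaf.taxon.label)]
    return MatchedDataset(
        landmarks=lm_sub, ecology=eco_sub, phylogeny=tree_sub, dropped=dropped
    )
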