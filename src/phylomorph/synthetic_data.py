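"""Synthetic trees, ecology tables, and landmark datasets.

Everything here is seeded and deterministic, producing data with the
statistical structure the analysis pipeline assumes: a time-calibrated
ultrametric tree, habitat with phylogenetic signal, habitat-linked diet
proportions, and 3-D landmark configurations whose shape deviations
evolve along the tree under Brownian motion or a heavy-tailed
(Student-t scale-mixture) alternative. Raw specimens are corrupted with
random rotations, translations and scales so that Procrustes alignment
is non-trivial.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

from .data_io import (
    DIET_CATEGORIES,
    HABITAT_LEVELS,
    EcologyTable,
    LandmarkSet,
    Phylogeny,
    assign_primary_diet,
    write_ecology_csv,
    write_landmark_csv,
    write_landmark_tps,
    write_module_assignments,
    write_newick,
)
from .errors import ValidationError

#: Names for the eight skull modules used by the paper-scale profile.
MODULE_NAMES: tuple[str, ...] = (
    "non_trophic",
    "maxilla",
    "ectopterygoid",
    "supratemporal",
    "quadrate",
    "mandible",
    "pterygoid",
    "palatine",
)


def default_partition(n_landmarks: int, n_modules: int) -> dict[int, str]:
    """Contiguous partition of landmark indices into named modules."""
    if n_modules > len(MODULE_NAMES):
        raise ValidationError(f"at most {len(MODULE_NAMES)} modules supported")
    if n_landmarks < 3 * n_modules:
        raise ValidationError("each module needs at least 3 landmarks")
    sizes = np.full(n_modules, n_landmarks // n_modules)
    sizes[: n_landmarks % n_modules] += 1
    module_of: dict[int, str] = {}
    i = 0
    for name, size in zip(MODULE_NAMES, sizes):
        for _ in range(size):
            module_of[i] = name
            i += 1
    return module_of


@dataclass
class SimulationConfig:
    """Knobs for the synthetic generator.

    The default profile (48 taxa, 20 landmarks, 3 modules) keeps the test
    suite fast; :meth:`paper_scale` matches the study's dimensions
    (160 taxa, 73 landmarks, 8 modules, 12 taxa absent from the tree).
    """

    n_taxa: int = 48
    n_landmarks: int = 20
    n_modules: int = 3
    habitat_levels: tuple[str, ...] = HABITAT_LEVELS
    diet_categories: tuple[str, ...] = DIET_CATEGORIES
    habitat_effect: float = 0.0  # mean-shape displacement per habitat (Procrustes units)
    allometry_slope: float = 0.0
    diet_shape_cov: float = 0.0
    evolution_model: str = "bm"  # or "heavy_tailed"
    heavy_tail_df: float = 3.0
    tip_jump: float = 1.5  # tip-specific heavy-tailed deviation, x rate_scale
    rate_scale: float = 0.05  # RMS BM deviation per landmark coordinate at unit depth
    size_rate: float = 0.3  # BM rate of log size
    birth_rate: float = 1.0
    habitat_jump_rate: float = 3.0
    diet_habitat_link: float = 2.0
    diet_alpha_base: float = 0.3
    mean_diet_records: float = 12.0
    n_missing_from_tree: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.evolution_model not in {"bm", "heavy_tailed"}:
            raise ValidationError("evolution_model must be 'bm' or 'heavy_tailed'")
        for name in ("habitat_effect", "allometry_slope", "diet_shape_cov"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.heavy_tail_df <= 2:
            raise ValidationError("heavy_tail_df must exceed 2 (finite variance)")

    @property
    def module_of(self) -> dict[int, str]:
        return default_partition(self.n_landmarks, self.n_modules)

    @classmethod
    def paper_scale(cls, **overrides) -> "SimulationConfig":
        base = dict(
            n_taxa=160, n_landmarks=73, n_modules=8, n_missing_from_tree=12
        )
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["habitat_levels"] = list(self.habitat_levels)
        d["diet_categories"] = list(self.diet_categories)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("habitat_levels", "diet_categories"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# Tree simulation
# ---------------------------------------------------------------------------


def simulate_tree(
    n_taxa: int,
    birth_rate: float = 1.0,
    seed: int | np.random.Generator | None = None,
    scale_to_unit_depth: bool = True,
) -> Phylogeny:
    """Pure-birth (Yule) tree with ``n_taxa`` tips, scaled to unit depth.

    The root splits at time zero (no stem edge); waiting times between
    successive births are exponential with rate ``k * birth_rate`` for
    ``k`` extant lineages, and a final waiting time is appended after the
    last birth so terminal branches have positive length. The result is ultrametric, with root-to-tip depth 1 unless
    ``scale_to_unit_depth`` is disabled (in which case depths retain the
    pure-birth time scale).
    """
    if n_taxa < 4:
        raise ValidationError("need at least 4 taxa")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    birth_time: dict[int, float] = {}
    active: list[dendropy.Node] = []
    t = 0.0
    for _ in range(2):  # the root splits at time zero (no stem edge)
        child = dendropy.Node()
        root.add_child(child)
        birth_time[id(child)] = 0.0
        active.append(child)
    while len(active) < n_taxa:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        node = active.pop(int(rng.integers(k)))
        node.edge.length = t - birth_time[id(node)]
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            birth_time[id(child)] = t
            active.append(child)
    t_end = t + rng.exponential(1.0 / (birth_rate * n_taxa))
    width = len(str(n_taxa))
    labels = [f"t{i + 1:0{width}d}" for i in range(n_taxa)]
    for node, label in zip(active, labels):
        node.edge.length = t_end - birth_time[id(node)]
        node.taxon = tns.new_taxon(label=label)
    if scale_to_unit_depth:
        for node in tree.preorder_node_iter():
            if node.edge.length is not None:
                node.edge.length /= t_end
    root.edge.length = None
    return Phylogeny(tree=tree)


def _evolve_states_on_tree(
    phy: Phylogeny,
    states: Sequence[str],
    jump_rate: float,
    rng: np.random.Generator,
) -> dict[str, str]:
    """Symmetric Markov jump process on the tree; returns tip states."""
    states = list(states)
    k = len(states)
    node_state: dict[int, str] = {}
    out: dict[str, str] = {}
    for node in phy.tree.preorder_node_iter():
        if node.parent_node is None:
            node_state[id(node)] = states[int(rng.integers(k))]
        else:
            s = node_state[id(node.parent_node)]
            n_jumps = rng.poisson(jump_rate * (node.edge.length or 0.0))
            for _ in range(n_jumps):
                others = [x for x in states if x != s]
                s = others[int(rng.integers(k - 1))]
            node_state[id(node)] = s
        if node.is_leaf():
            out[node.taxon.label] = node_state[id(node)]
    return out


def simulate_ecology(
    phy: Phylogeny,
    config: SimulationConfig,
    seed: int | np.random.Generator | None = None,
) -> EcologyTable:
    """Habitat with phylogenetic signal, habitat-linked diet, record counts.

    Habitat evolves along the tree under a symmetric Markov jump process;
    per-taxon diet proportions are Dirichlet draws whose concentration is
    boosted for a habitat-specific preferred prey category; the primary
    diet is derived from the proportions via the strict >50% rule; record
    counts are overdispersed (negative binomial).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    taxa = phy.tip_labels
    habitat_of = _evolve_states_on_tree(
        phy, config.habitat_levels, config.habitat_jump_rate, rng
    )
    cats = config.diet_categories
    preferred = {
        h: cats[i % len(cats)] for i, h in enumerate(config.habitat_levels)
    }
    props = np.zeros((len(taxa), len(cats)))
    primary: list[str] = []
    for i, t in enumerate(taxa):
        alpha = np.full(len(cats), config.diet_alpha_base)
        alpha[cats.index(preferred[habitat_of[t]])] += config.diet_habitat_link
        p = rng.dirichlet(alpha)
        props[i] = p
        primary.append(assign_primary_diet(p, cats))
    # NB with dispersion r=3 around the configured mean
    r = 3.0
    mean = config.mean_diet_records
    records = rng.negative_binomial(r, r / (r + mean), size=len(taxa)).astype(float)
    return EcologyTable(
        taxa=taxa,
        habitat=[habitat_of[t] for t in taxa],
        primary_diet=primary,
        diet_categories=cats,
        diet_proportions=props,
        n_diet_records=records,
        habitat_levels=config.habitat_levels,
    )


# ---------------------------------------------------------------------------
# Landmark simulation
# ---------------------------------------------------------------------------


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q


def _evolve_bm_deviations(
    phy: Phylogeny,
    L: np.ndarray,
    rng: np.random.Generator,
    heavy_df: float | None,
) -> dict[str, np.ndarray]:
    """Per-tip trait deviations from the root under (possibly heavy-tailed) BM.

    ``L`` is a square-root factor of the per-unit-length rate matrix. In
    the heavy-tailed regime each branch's increment is multiplied by a
    shared inverse-chi scale (a multivariate-t scale mixture, normalized
    to unit variance) -- entire branches, and hence entire clades, can
    take outlying steps, which is the kind of non-Brownian behaviour that
    breaks BM-based covariance assumptions downstream.
    """
    d = L.shape[0]
    vals: dict[int, np.ndarray] = {}
    out: dict[str, np.ndarray] = {}
    for node in phy.tree.preorder_node_iter():
        if node.parent_node is None:
            vals[id(node)] = np.zeros(d)
        else:
            elen = node.edge.length or 0.0
            z = rng.standard_normal(d)
            step = L @ z * np.sqrt(elen)
            if heavy_df is not None:
                u = np.sqrt(heavy_df / rng.chisquare(heavy_df))
                step *= u * np.sqrt((heavy_df - 2.0) / heavy_df)
            vals[id(node)] = vals[id(node.parent_node)] + step
        if node.is_leaf():
            out[node.taxon.label] = vals[id(node)]
    return out


def simulate_landmark_dataset(
    phy: Phylogeny,
    eco: EcologyTable,
    config: SimulationConfig,
    seed: int | np.random.Generator | None = None,
) -> LandmarkSet:
    """Raw (unaligned) landmark configurations for every tip of the tree.

    Deviations from a fixed base configuration evolve along the tree
    (BM or heavy-tailed); habitat-specific displacements, a diet-linked
    component, and an allometric component proportional to a simulated
    log size are added on top; finally each specimen is corrupted with a
    random rotation, a translation, and a positive scale. The corruption
    scale is ``exp(log size)`` (times small jitter) so that measured
    centroid size carries the simulated size signal.

    In the heavy-tailed regime two violations of Brownian motion are
    combined: branch increments get a shared Student-t scale (clade-level
    excursions) and each tip receives an additional heavy-tailed
    species-specific jump of magnitude ``tip_jump * rate_scale``. The tip
    component weakens the phylogenetic covariance relative to what the
    BM model assumes, which is what drives the Type-I inflation of
    BM-based GLS on label-permuted data; pure branch-wise t increments
    leave BM second moments intact and do not reproduce it.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    taxa = phy.tip_labels
    if list(eco.taxa) != taxa:
        eco = eco.subset(taxa)
    p = config.n_landmarks
    d = 3 * p
    module_of = config.module_of

    # base mean configuration: modules occupy distinct spatial offsets
    base = rng.standard_normal((p, 3))
    names = list(dict.fromkeys(module_of.values()))
    for j, name in enumerate(names):
        idx = [i for i, m in module_of.items() if m == name]
        base[idx] += np.array([4.0 * j, 0.0, 0.0])
    base -= base.mean(axis=0)
    base /= np.sqrt((base**2).sum())

    # random PSD rate matrix with RMS per-coordinate deviation ~ rate_scale
    if config.rate_scale > 0:
        W = rng.standard_normal((d, max(d // 4, 2)))
        R = W @ W.T
        R *= (config.rate_scale**2) * d / np.trace(R)
        L = np.linalg.cholesky(R + 1e-12 * np.eye(d))
    else:
        L = np.zeros((d, d))
    heavy_df = config.heavy_tail_df if config.evolution_model == "heavy_tailed" else None
    deviations = _evolve_bm_deviations(phy, L, rng, heavy_df)

    log_size = _evolve_bm_deviations(
        phy, np.array([[config.size_rate]]), rng, None
    )
    hab_dirs = {
        h: (v := rng.standard_normal(d)) / np.linalg.norm(v)
        for h in config.habitat_levels
    }
    diet_dirs = {
        c: (v := rng.standard_normal(d)) / np.linalg.norm(v)
        for c in config.diet_categories
    }
    allo_dir = rng.standard_normal(d)
    allo_dir /= np.linalg.norm(allo_dir)

    ls = np.array([log_size[t][0] for t in taxa])
    ls_centered = ls - ls.mean()

    configs = np.empty((len(taxa), p, 3))
    for i, t in enumerate(taxa):
        vec = base.ravel() + deviations[t]
        if heavy_df is not None and config.tip_jump > 0:
            u = np.sqrt(heavy_df / rng.chisquare(heavy_df))
            u *= np.sqrt((heavy_df - 2.0) / heavy_df)
            vec = vec + config.tip_jump * u * (L @ rng.standard_normal(d))
        vec = vec + config.habitat_effect * hab_dirs[eco.habitat[i]]
        if eco.diet_proportions is not None and config.diet_shape_cov > 0:
            mix = sum(
                prop * diet_dirs[c]
                for c, prop in zip(eco.diet_categories, eco.diet_proportions[i])
            )
            vec = vec + config.diet_shape_cov * mix
        vec = vec + config.allometry_slope * ls_centered[i] * allo_dir
        shape = vec.reshape(p, 3)
        scale = float(np.exp(ls[i]) * np.exp(rng.normal(0.0, 0.05)))
        shape = scale * (shape @ _random_rotation(rng))
        shape = shape + rng.normal(0.0, 5.0, size=3)
        configs[i] = shape
    return LandmarkSet(
        taxa=list(taxa),
        coords=configs,
        module_of=dict(module_of),
        units="simulated",
    )


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[Phylogeny, EcologyTable, LandmarkSet]:
    """Convenience wrapper: tree, ecology, landmarks from one config/seed."""
    rng = np.random.default_rng(config.seed)
    phy = simulate_tree(config.n_taxa, config.birth_rate, rng)
    eco = simulate_ecology(phy, config, rng)
    lm = simulate_landmark_dataset(phy, eco, config, rng)
    return phy, eco, lm


def write_fixture_bundle(outdir: str | Path, config: SimulationConfig) -> dict[str, Path]:
    """Write a complete, re-readable fixture bundle plus a manifest.

    Emits tree (Newick), landmarks (TPS and CSV), ecology CSV, module
    assignment YAML, and a JSON manifest carrying the generating
    configuration. Re-running with the same config reproduces every file
    byte-identically. ``config.n_missing_from_tree`` tips are dropped
    from the written tree (not the landmark/ecology files) to exercise
    taxon matching.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    phy, eco, lm = simulate_dataset(config)
    if config.n_missing_from_tree > 0:
        drop_rng = np.random.default_rng(config.seed + 1)
        tips = phy.tip_labels
        drop = drop_rng.choice(
            len(tips), size=config.n_missing_from_tree, replace=False
        )
        keep = [t for i, t in enumerate(tips) if i not in set(drop.tolist())]
        phy = phy.prune_to(keep)
    paths = {
        "tree": outdir / "tree.nwk",
        "landmarks_tps": outdir / "landmarks.tps",
        "landmarks_csv": outdir / "landmarks.csv",
        "ecology": outdir / "ecology.csv",
        "modules": outdir / "modules.yaml",
        "manifest": outdir / "manifest.json",
    }
    write_newick(phy, paths["tree"])
    write_landmark_tps(lm, paths["landmarks_tps"])
    write_landmark_csv(lm, paths["landmarks_csv"])
    write_ecology_csv(eco, paths["ecology"])
    write_module_assignments(lm.module_of, paths["modules"])
    manifest = {
        "config": config.to_dict(),
        "files": {k: v.name for k, v in paths.items() if k != "manifest"},
        "n_taxa": lm.n_taxa,
        "n_tree_tips": phy.n_tips,
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return paths


def read_fixture_manifest(path: str | Path) -> SimulationConfig:
    manifest = json.loads(Path(path).read_text())
    return SimulationConfig.from_dict(manifest["config"])
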