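"""Synthetic phylogenies, trait tables and ecological attributes.

Every downstream stage of the pipeline is exercised on data from this
module, so the generators expose the knobs the analyses are sensitive to:
the number and depth of basal clades, the strength of phylogenetic signal
in traits and group membership (``conservatism``), and the correlation
structure of the functional variables.

Trees are pure-birth (Yule) with an optional forced basal split into
``n_deep_clades`` clades and depth normalization (ultrametric by
construction). Quantitative traits evolve by Brownian motion on the tree;
binary traits threshold a latent Brownian variable; the ``conservatism``
dial in [0, 1] mixes the Brownian component with tree-independent noise.

All generators are pure functions of (config, seed): identical inputs give
bit-identical outputs. Sub-streams are derived from the master seed by
stable hashing of stage names, so stages can be re-run independently.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from phyloniche.errors import InvalidParameterError
from phyloniche.groups import GROUP_LABELS, GroupAssignment
from phyloniche.io import (
    ACTIVITY_PERIODS,
    DIMENSIONS,
    FORAGING_MODES,
    HABITAT_CATEGORIES,
    EcologyTable,
    TraitTable,
)
from phyloniche.phylo import phylo_correlation

#: Default per-dimension trait counts, mirroring the mixed binary /
#: quantitative composition of real lizard functional-trait compilations
#: (binary habitat and defense flags, quantitative life-history, diet and
#: morphometric measurements).
DEFAULT_DIMENSION_SPEC: dict[str, dict[str, int]] = {
    "habitat": {"binary": 6, "quantitative": 0},
    "trophic": {"binary": 0, "quantitative": 7},
    "life_history": {"binary": 2, "quantitative": 7},
    "metabolic": {"binary": 2, "quantitative": 2},
    "defense": {"binary": 8, "quantitative": 0},
    "ecomorphology": {"binary": 0, "quantitative": 8},
}


def substream(seed: int | None, stage: str) -> np.random.Generator:
    """Independent random stream for a named stage of a master seed."""
    key = zlib.crc32(stage.encode("utf-8"))
    return np.random.default_rng(
        np.random.SeedSequence(entropy=0 if seed is None else seed, spawn_key=(key,))
    )


@dataclass
class SimulationConfig:
    """Knobs for the synthetic study system.

    Parameters
    ----------
    n_species
        Number of tips (>= 2).
    birth_rate
        Per-lineage speciation rate of the pure-birth process (1/time).
    n_deep_clades
        Number of forced basal clades (>= 1); with more than one, the tree
        has a controllable deepest split.
    conservatism
        Strength of phylogenetic signal in traits, ecological attributes
        and group membership, in [0, 1]: 0 = independent of the tree,
        1 = fully tree-determined.
    trait_correlation
        Target pairwise correlation of traits within a dimension (and of
        directly generated functional variables), |rho| < 1.
    dimension_spec
        Mapping dimension -> {"binary": nb, "quantitative": nq}; every
        dimension needs at least one trait.
    seed
        Master seed; all stage streams derive from it.
    depth
        Root-to-tip depth after normalization (default 1).
    basal_window
        Fraction of the depth spanned by the forced basal splits (the
        backbone); small values put all deep splits near the root.
    clade_depth_fraction
        Fraction of the depth occupied by each clade's own radiation; the
        remainder is the clade stem, which carries the shared history that
        makes clade members similar.
    binary_prevalence
        Fraction of 1s in each binary trait (thresholded latent quantile).
    n_groups, group_size
        Defaults for :func:`simulate_groups`.
    multi_state_margin
        Latent-score margin within which secondary ecological states are
        retained, producing multi-group membership.
    """

    n_species: int = 64
    birth_rate: float = 1.0
    n_deep_clades: int = 2
    conservatism: float = 0.5
    trait_correlation: float = 0.0
    dimension_spec: Mapping[str, Mapping[str, int]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_DIMENSION_SPEC.items()}
    )
    seed: int = 0
    depth: float = 1.0
    basal_window: float = 0.05
    clade_depth_fraction: float = 0.7
    binary_prevalence: float = 0.5
    n_groups: int = 8
    group_size: int = 10
    multi_state_margin: float = 0.25

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise InvalidParameterError(f"n_species must be >= 2, got {self.n_species}")
        if self.birth_rate <= 0:
            raise InvalidParameterError("birth_rate must be positive")
        if self.n_deep_clades < 1 or self.n_deep_clades > self.n_species:
            raise InvalidParameterError(
                "n_deep_clades must be in [1, n_species]"
            )
        if not 0.0 <= self.conservatism <= 1.0:
            raise InvalidParameterError("conservatism must lie in [0, 1]")
        if not abs(self.trait_correlation) < 1.0:
            raise InvalidParameterError("|trait_correlation| must be < 1")
        if not self.dimension_spec:
            raise InvalidParameterError("dimension_spec must be non-empty")
        for dim, counts in self.dimension_spec.items():
            if dim not in DIMENSIONS:
                raise InvalidParameterError(f"unknown niche dimension {dim!r}")
            total = int(counts.get("binary", 0)) + int(counts.get("quantitative", 0))
            if total < 1:
                raise InvalidParameterError(f"dimension {dim!r} has zero traits")
        if self.depth <= 0:
            raise InvalidParameterError("depth must be positive")
        if not 0.0 < self.clade_depth_fraction <= 1.0:
            raise InvalidParameterError("clade_depth_fraction must be in (0, 1]")
        if self.n_deep_clades > 1 and (
            self.basal_window <= 0
            or self.basal_window + self.clade_depth_fraction >= 1.0
        ):
            raise InvalidParameterError(
                "with multiple deep clades, basal_window must be positive and "
                "basal_window + clade_depth_fraction < 1"
            )
        if not 0.0 < self.binary_prevalence < 1.0:
            raise InvalidParameterError("binary_prevalence must be in (0, 1)")
        if not 1 <= self.n_groups <= len(GROUP_LABELS):
            raise InvalidParameterError(
                f"n_groups must be in [1, {len(GROUP_LABELS)}]"
            )
        if self.group_size < 2:
            raise InvalidParameterError("group_size must be >= 2")


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------


def _yule(n: int, rate: float, rng: np.random.Generator) -> dendropy.Node:
    """Pure-birth subtree with n tips; tips equidistant from the subtree root."""
    root = dendropy.Node()
    if n == 1:
        return root
    active = [root]
    pending = {id(root): 0.0}
    while len(active) < n:
        k = len(active)
        dt = rng.exponential(1.0 / (rate * k))
        for nd in active:
            pending[id(nd)] += dt
        i = int(rng.integers(k))
        nd = active.pop(i)
        nd.edge.length = pending.pop(id(nd))
        for _ in range(2):
            child = dendropy.Node()
            nd.add_child(child)
            pending[id(child)] = 0.0
            active.append(child)
    dt = rng.exponential(1.0 / (rate * n))
    for nd in active:
        nd.edge.length = pending.pop(id(nd)) + dt
    return root


def _subtree_height(node: dendropy.Node) -> float:
    h = 0.0
    nd = node
    while nd.child_nodes():
        nd = nd.child_nodes()[0]
        h += nd.edge.length
    return h


def _scale_subtree(node: dendropy.Node, factor: float) -> None:
    for child in node.preorder_iter():
        if child is node:
            continue
        child.edge.length *= factor


def simulate_phylogeny(config: SimulationConfig) -> dendropy.Tree:
    """Ultrametric pure-birth tree, optionally with forced basal clades.

    Every tip sits at distance ``config.depth`` from the root. With
    ``n_deep_clades > 1``, the basal splits are confined to the first
    ``basal_window`` fraction of the depth and each clade's own radiation to
    the last ``clade_depth_fraction``; the clade stems in between carry the
    shared history that downstream conservatism relies on. The returned
    tree exposes ``tree.clade_tips`` (clade index -> tip labels).
    """
    rng = substream(config.seed, "phylogeny")
    n, k = config.n_species, config.n_deep_clades
    sizes = [n // k + (1 if i < n % k else 0) for i in range(k)]

    ns = dendropy.TaxonNamespace()
    clade_tips: dict[int, list[str]] = {}
    counter = 0

    def _finalize(node: dendropy.Node, clade: int) -> None:
        nonlocal counter
        for leaf in node.leaf_iter():
            counter += 1
            label = f"s{counter:04d}"
            leaf.taxon = ns.require_taxon(label)
            clade_tips.setdefault(clade, []).append(label)

    if k == 1:
        root = _yule(n, config.birth_rate, rng)
        h = _subtree_height(root)
        _scale_subtree(root, config.depth / h)
        root.edge.length = None
        _finalize(root, 0)
    else:
        step = config.basal_window * config.depth / max(k - 1, 1)
        h = config.clade_depth_fraction * config.depth
        clade_roots = []
        for i, size in enumerate(sizes):
            sub = _yule(size, config.birth_rate, rng)
            if size > 1:
                _scale_subtree(sub, h / _subtree_height(sub))
            clade_roots.append(sub)
        root = dendropy.Node()
        backbone = root
        backbone_depth = 0.0
        for i in range(k):
            sub = clade_roots[i]
            attach_depth = backbone_depth
            if sizes[i] > 1:
                sub.edge.length = config.depth - attach_depth - h
            else:
                sub.edge.length = config.depth - attach_depth
            backbone.add_child(sub)
            if i < k - 2:
                nxt = dendropy.Node()
                nxt.edge.length = step
                backbone.add_child(nxt)
                backbone = nxt
                backbone_depth += step
            elif i == k - 2:
                # last two clades share the deepest backbone node
                pass
        root.edge.length = None
        _finalize(root, -1)
        # clade membership follows construction order of the clade subtrees
        clade_tips = {}
        counter = 0
        offset = 0
        for i, size in enumerate(sizes):
            clade_tips[i] = [f"s{j + 1:04d}" for j in range(offset, offset + size)]
            offset += size

    tree = dendropy.Tree(seed_node=root, taxon_namespace=ns)
    tree.is_rooted = True
    tree.clade_tips = clade_tips if k > 1 else {0: [t.label for t in ns]}
    return tree


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------


def _equicorr_cholesky(m: int, rho: float) -> np.ndarray:
    if m == 1 or rho == 0.0:
        return np.eye(m)
    if rho <= -1.0 / (m - 1):
        raise InvalidParameterError(
            f"pairwise correlation {rho} is not positive definite for {m} traits"
        )
    R = np.full((m, m), rho)
    np.fill_diagonal(R, 1.0)
    return np.linalg.cholesky(R)


def _latent_block(
    n: int,
    m: int,
    conservatism: float,
    L_tree: np.ndarray | None,
    rho: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """n x m latent matrix: Brownian (via L_tree) / iid mixture, trait-correlated."""
    A = _equicorr_cholesky(m, rho)
    iid = rng.standard_normal((n, m))
    if conservatism > 0.0:
        if L_tree is None:
            raise InvalidParameterError("tree factor required when conservatism > 0")
        bm = L_tree @ rng.standard_normal((n, m))
        latent = np.sqrt(conservatism) * bm + np.sqrt(1.0 - conservatism) * iid
    else:
        latent = iid
    return latent @ A.T


def _tree_factor(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    C = phylo_correlation(tree)
    M = C.matrix + 1e-10 * np.eye(len(C.ids))
    return C.ids, np.linalg.cholesky(M)


def simulate_traits(tree: dendropy.Tree, config: SimulationConfig) -> TraitTable:
    """Mixed binary/quantitative trait table evolved on the tree.

    Quantitative traits are (mixtures of) Brownian-motion realizations;
    binary traits threshold a latent Brownian variable at the
    ``binary_prevalence`` quantile. At ``conservatism = 0`` all traits are
    drawn independently of the tree.
    """
    if config.conservatism > 0.0:
        ids, L = _tree_factor(tree)
    else:
        ids = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        L = None
    n = len(ids)
    if n < 2:
        raise InvalidParameterError("tree must have at least 2 tips")
    rng = substream(config.seed, "traits")

    data: dict[str, np.ndarray] = {}
    meta_rows = []
    for dim, counts in config.dimension_spec.items():
        nb = int(counts.get("binary", 0))
        nq = int(counts.get("quantitative", 0))
        latent = _latent_block(
            n, nb + nq, config.conservatism, L, config.trait_correlation, rng
        )
        for j in range(nq):
            name = f"{dim}_q{j + 1}"
            data[name] = latent[:, j]
            meta_rows.append({"trait": name, "type": "quantitative", "dimension": dim})
        for j in range(nb):
            name = f"{dim}_b{j + 1}"
            x = latent[:, nq + j]
            thr = np.quantile(x, 1.0 - config.binary_prevalence)
            data[name] = (x >= thr).astype(int)
            meta_rows.append({"trait": name, "type": "binary", "dimension": dim})

    frame = pd.DataFrame(data, index=pd.Index(ids, name="species"))
    meta = pd.DataFrame(meta_rows).set_index("trait")
    return TraitTable(frame, meta)


# ---------------------------------------------------------------------------
# Groups and ecology
# ---------------------------------------------------------------------------


def _clades_of(tree: dendropy.Tree) -> list[list[str]]:
    clade_tips = getattr(tree, "clade_tips", None)
    if clade_tips:
        return [sorted(v) for _, v in sorted(clade_tips.items())]
    return [
        sorted(leaf.taxon.label for leaf in child.leaf_iter())
        for child in tree.seed_node.child_nodes()
    ]


def simulate_groups(
    tree: dendropy.Tree,
    config: SimulationConfig,
    n_groups: int | None = None,
    group_sizes: Sequence[int] | int | None = None,
    conservatism: float | None = None,
) -> GroupAssignment:
    """Group memberships with tunable phylogenetic clustering.

    Each group has a focal basal clade (cycling through the clades); every
    member slot is filled from the focal clade with probability
    ``conservatism`` and from the whole pool otherwise, without replacement
    within a group. At conservatism 1, members come exclusively from the
    focal clade; at 0 they are uniform draws from the pool. Groups may share
    species (multi-membership, as in the observed data).
    """
    c = config.conservatism if conservatism is None else float(conservatism)
    if not 0.0 <= c <= 1.0:
        raise InvalidParameterError("conservatism must lie in [0, 1]")
    G = config.n_groups if n_groups is None else int(n_groups)
    if not 1 <= G <= len(GROUP_LABELS):
        raise InvalidParameterError(f"number of groups must be in [1, {len(GROUP_LABELS)}]")
    pool = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    if group_sizes is None:
        sizes = [config.group_size] * G
    elif isinstance(group_sizes, int):
        sizes = [group_sizes] * G
    else:
        sizes = [int(s) for s in group_sizes]
        if len(sizes) != G:
            raise InvalidParameterError("group_sizes length must equal the group count")
    for s in sizes:
        if s < 2:
            raise InvalidParameterError("every group needs at least 2 members")
        if s > len(pool):
            raise InvalidParameterError(
                f"group size {s} exceeds the species pool ({len(pool)})"
            )

    rng = substream(config.seed, "groups")
    clades = _clades_of(tree)
    membership = pd.DataFrame(
        0, index=pd.Index(pool, name="species"), columns=list(GROUP_LABELS)
    )
    for g in range(G):
        label = GROUP_LABELS[g]
        focal = clades[g % len(clades)]
        chosen: set[str] = set()
        for _ in range(sizes[g]):
            from_clade = rng.random() < c
            candidates = [s for s in (focal if from_clade else pool) if s not in chosen]
            if not candidates:
                candidates = [s for s in pool if s not in chosen]
            chosen.add(candidates[int(rng.integers(len(candidates)))])
        membership.loc[sorted(chosen), label] = 1
    return GroupAssignment(membership)


def _families_from_tree(tree: dendropy.Tree, max_size: int) -> dict[str, str]:
    """Cut the tree into maximal subtrees of <= max_size tips as 'families'."""
    fam: dict[str, str] = {}
    counter = 0

    def n_tips(node) -> int:
        return sum(1 for _ in node.leaf_iter())

    def assign(node) -> None:
        nonlocal counter
        if node.is_leaf() or n_tips(node) <= max_size:
            counter += 1
            for leaf in node.leaf_iter():
                fam[leaf.taxon.label] = f"fam{counter:02d}"
            return
        for child in node.child_nodes():
            assign(child)

    assign(tree.seed_node)
    return fam


def simulate_ecology(tree: dendropy.Tree, config: SimulationConfig) -> EcologyTable:
    """Phylogenetically conserved ecological attributes with mixed states.

    Each attribute (foraging mode, activity period, habitat category) gets a
    per-state latent score from the Brownian/iid mixture; the top-scoring
    state is always kept, and secondary states within ``multi_state_margin``
    of the top are retained, producing cathemeral, mixed-foraging and
    habitat-generalist species. Families are maximal subtrees (about a tenth
    of the pool each), so family labels are themselves clades.
    """
    if config.conservatism > 0.0:
        ids, L = _tree_factor(tree)
    else:
        ids = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        L = None
    n = len(ids)
    rng = substream(config.seed, "ecology")

    def states_for(vocab: tuple[str, ...]) -> list[frozenset]:
        latent = _latent_block(n, len(vocab), config.conservatism, L, 0.0, rng)
        out = []
        for i in range(n):
            row = latent[i]
            top = row.max()
            states = {
                vocab[j]
                for j in range(len(vocab))
                if row[j] >= top - config.multi_state_margin
            }
            out.append(frozenset(states))
        return out

    fam = _families_from_tree(tree, max_size=max(4, n // 10))
    frame = pd.DataFrame(
        {
            "foraging": states_for(FORAGING_MODES),
            "activity": states_for(ACTIVITY_PERIODS),
            "habitat": states_for(HABITAT_CATEGORIES),
            "family": [fam[s] for s in ids],
        },
        index=pd.Index(ids, name="species"),
    )
    return EcologyTable(frame)


# ---------------------------------------------------------------------------
# Direct functional-variable generator
# ---------------------------------------------------------------------------


def make_functional_variables(
    n: int,
    correlation: float = 0.0,
    model: str = "independent-normal",
    seed: int | None = None,
) -> pd.DataFrame:
    """n x 6 functional-variable matrix from a known distribution family.

    ``independent-uniform`` and ``independent-normal`` have zero population
    correlation between columns; ``correlated-normal`` has every pairwise
    correlation equal to ``correlation``. Used for power and type-I-error
    studies of the hypervolume null-model test, where the generating process
    must be known exactly.
    """
    d = len(DIMENSIONS)
    if n <= d:
        raise InvalidParameterError(
            f"n must exceed the dimensionality ({d}) for a nondegenerate hull"
        )
    if abs(correlation) >= 1.0:
        raise InvalidParameterError("|correlation| must be < 1")
    rng = substream(seed, f"fv:{model}")
    if model == "independent-uniform":
        X = rng.uniform(size=(n, d))
    elif model == "independent-normal":
        X = rng.standard_normal((n, d))
    elif model == "correlated-normal":
        A = _equicorr_cholesky(d, correlation)
        X = rng.standard_normal((n, d)) @ A.T
    else:
        raise InvalidParameterError(f"unknown model {model!r}")
    return pd.DataFrame(
        X,
        index=pd.Index([f"s{i + 1:04d}" for i in range(n)], name="species"),
        columns=list(DIMENSIONS),
    )
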