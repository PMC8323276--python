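"""Readers, writers and validators for the pipeline's data.

Formats are deliberately plain: delimited text (CSV) for trait tables,
ecological attributes and group assignments; Newick for trees; JSON for
reports.  Readers reject malformed values rather than coercing them, and
every writer produces files its reader accepts bit-identically.

Species names are matched exactly after trimming whitespace and unifying
underscores/spaces (the Newick convention); no fuzzy matching is attempted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd

from phyloniche.errors import ValidationError

#: The five fundamental niche dimensions plus ecomorphology.
DIMENSIONS = (
    "habitat",
    "trophic",
    "life_history",
    "metabolic",
    "defense",
    "ecomorphology",
)

TRAIT_TYPES = ("binary", "quantitative")

#: Controlled vocabularies for the ecological attributes used in
#: functional-group classification.
FORAGING_MODES = ("sit_and_wait", "widely_foraging")
ACTIVITY_PERIODS = ("diurnal", "nocturnal")
HABITAT_CATEGORIES = (
    "semi_aquatic",
    "fossorial",
    "cryptic",
    "terrestrial",
    "saxicolous",
    "arboreal",
)


def canonical_name(name: str) -> str:
    """Canonical species label: trimmed, spaces unified to underscores."""
    return str(name).strip().replace(" ", "_")


# ---------------------------------------------------------------------------
# Trait tables
# ---------------------------------------------------------------------------


@dataclass
class TraitTable:
    """Species x trait table with per-trait type and niche-dimension tags.

    Parameters
    ----------
    data
        DataFrame indexed by species id, one column per trait. Binary traits
        hold only {0, 1}; quantitative traits hold finite reals.
    meta
        DataFrame indexed by trait name with columns ``type``
        (``binary``/``quantitative``) and ``dimension`` (one of
        :data:`DIMENSIONS`).
    """

    data: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    @property
    def species_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def dimension_map(self) -> dict[str, str]:
        return dict(self.meta["dimension"])

    def traits_for(self, dimension: str) -> list[str]:
        if dimension not in DIMENSIONS:
            raise ValidationError(f"unknown niche dimension {dimension!r}")
        return list(self.meta.index[self.meta["dimension"] == dimension])

    def subset(self, species: Iterable[str]) -> "TraitTable":
        return TraitTable(self.data.loc[list(species)].copy(), self.meta.copy())

    def validate(self) -> None:
        idx = pd.Index([canonical_name(s) for s in self.data.index])
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate species ids: {dupes}")
        self.data.index = idx
        self.data.index.name = "species"
        missing = [c for c in self.data.columns if c not in self.meta.index]
        if missing:
            raise ValidationError(f"traits without metadata: {missing}")
        extra = [t for t in self.meta.index if t not in self.data.columns]
        if extra:
            raise ValidationError(f"metadata for absent traits: {extra}")
        for trait, row in self.meta.iterrows():
            if row["type"] not in TRAIT_TYPES:
                raise ValidationError(
                    f"trait {trait!r}: unknown type {row['type']!r}"
                )
            if row["dimension"] not in DIMENSIONS:
                raise ValidationError(
                    f"trait {trait!r}: unknown dimension tag {row['dimension']!r}"
                )
            col = self.data[trait]
            if col.isna().any():
                bad = col.index[col.isna()][0]
                raise ValidationError(
                    f"missing value in trait {trait!r}, species {bad!r} "
                    "(missing trait values are not supported)"
                )
            if row["type"] == "binary":
                vals = set(pd.unique(col))
                if not vals <= {0, 1, 0.0, 1.0, False, True}:
                    bad_mask = ~col.isin([0, 1])
                    bad = col.index[bad_mask][0]
                    raise ValidationError(
                        f"binary trait {trait!r}, species {bad!r}: "
                        f"value {col.loc[bad]!r} is not in {{0, 1}}"
                    )
                self.data[trait] = col.astype(int)
            else:
                vals = pd.to_numeric(col, errors="coerce")
                if not np.isfinite(vals.to_numpy(dtype=float)).all():
                    bad = col.index[~np.isfinite(vals.to_numpy(dtype=float))][0]
                    raise ValidationError(
                        f"quantitative trait {trait!r}, species {bad!r}: "
                        f"value {col.loc[bad]!r} is not finite"
                    )
                self.data[trait] = vals.astype(float)


def read_trait_table(path: str | Path, metadata_path: str | Path) -> TraitTable:
    """Read a trait CSV and its sidecar metadata CSV into a validated table.

    The sidecar has columns ``trait,type,dimension`` and must cover every
    trait column of the main file.
    """
    path, metadata_path = Path(path), Path(metadata_path)
    data = pd.read_csv(path, index_col=0)
    meta = pd.read_csv(metadata_path, index_col=0)
    for col in ("type", "dimension"):
        if col not in meta.columns:
            raise ValidationError(
                f"{metadata_path}: metadata must have a {col!r} column"
            )
    return TraitTable(data, meta[["type", "dimension"]])


def write_trait_table(
    table: TraitTable, path: str | Path, metadata_path: str | Path
) -> None:
    table.data.to_csv(path)
    meta = table.meta.copy()
    meta.index.name = "trait"
    meta.to_csv(metadata_path)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def read_tree(path: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree with branch lengths.

    Raises
    ------
    ValidationError
        If any non-root edge lacks a branch length (cophenetic distances
        would be undefined) or tip labels are duplicated.
    """
    tree = dendropy.Tree.get(
        path=str(path),
        schema="newick",
        preserve_underscores=True,
        rooting="force-rooted",
    )
    return _validate_tree(tree, source=str(path))


def tree_from_string(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(
        data=newick,
        schema="newick",
        preserve_underscores=True,
        rooting="force-rooted",
    )
    return _validate_tree(tree, source="<string>")


def _validate_tree(tree: dendropy.Tree, source: str) -> dendropy.Tree:
    labels = []
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise ValidationError(f"{source}: unlabeled tip")
        leaf.taxon.label = canonical_name(leaf.taxon.label)
        labels.append(leaf.taxon.label)
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValidationError(f"{source}: duplicate tip labels {dupes}")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValidationError(
                f"{source}: edge above "
                f"{edge.head_node.taxon.label if edge.head_node.taxon else 'an internal node'} "
                "has no branch length"
            )
        if edge.length < 0:
            raise ValidationError(f"{source}: negative branch length {edge.length}")
    return tree


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )


def tree_tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


# ---------------------------------------------------------------------------
# Ecological attributes
# ---------------------------------------------------------------------------


@dataclass
class EcologyTable:
    """Per-species ecological attribute sets for functional classification.

    ``data`` is indexed by species with columns ``foraging``, ``activity``,
    ``habitat`` (each a frozenset drawn from the controlled vocabulary,
    non-empty; multi-state species carry more than one element) and
    ``family`` (free text).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    @property
    def species_ids(self) -> list[str]:
        return list(self.data.index)

    def subset(self, species: Iterable[str]) -> "EcologyTable":
        return EcologyTable(self.data.loc[list(species)].copy())

    def validate(self) -> None:
        idx = pd.Index([canonical_name(s) for s in self.data.index])
        if idx.has_duplicates:
            raise ValidationError(
                f"duplicate species ids: {idx[idx.duplicated()].unique().tolist()}"
            )
        self.data.index = idx
        self.data.index.name = "species"
        required = {"foraging", "activity", "habitat", "family"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(f"ecology table missing columns: {sorted(missing)}")
        vocab = {
            "foraging": set(FORAGING_MODES),
            "activity": set(ACTIVITY_PERIODS),
            "habitat": set(HABITAT_CATEGORIES),
        }
        for col, allowed in vocab.items():
            converted = []
            for sp, value in self.data[col].items():
                states = _as_state_set(value)
                if not states:
                    raise ValidationError(
                        f"species {sp!r}: empty {col} set (every species needs "
                        f"at least one {col} state)"
                    )
                unknown = states - allowed
                if unknown:
                    raise ValidationError(
                        f"species {sp!r}: unknown {col} state(s) {sorted(unknown)}; "
                        f"allowed: {sorted(allowed)}"
                    )
                converted.append(frozenset(states))
            self.data[col] = converted


def _as_state_set(value) -> set[str]:
    if isinstance(value, (set, frozenset, list, tuple)):
        return {str(v).strip() for v in value if str(v).strip()}
    if pd.isna(value):
        return set()
    return {part.strip() for part in str(value).split("|") if part.strip()}


def read_ecology_table(path: str | Path) -> EcologyTable:
    """Read per-species ecological attributes.

    Multi-state attributes are pipe-delimited within one CSV cell, e.g. a
    cathemeral species has ``activity`` = ``"diurnal|nocturnal"``.
    """
    return EcologyTable(pd.read_csv(path, index_col=0))


def write_ecology_table(eco: EcologyTable, path: str | Path) -> None:
    out = eco.data.copy()
    for col in ("foraging", "activity", "habitat"):
        out[col] = [
            "|".join(sorted(states)) for states in out[col]
        ]
    out.to_csv(path)


# ---------------------------------------------------------------------------
# Reconciliation
# ---------------------------------------------------------------------------


@dataclass
class ReconcileReport:
    """Which species were kept and which were dropped from which input."""

    retained: list[str]
    dropped: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    def to_dict(self) -> dict:
        return {
            "n_retained": self.n_retained,
            "retained": self.retained,
            "dropped": self.dropped,
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def reconcile(
    traits: TraitTable | None,
    tree: dendropy.Tree | None,
    eco: EcologyTable | None,
) -> tuple[TraitTable | None, dendropy.Tree | None, EcologyTable | None, ReconcileReport]:
    """Align inputs on the intersection of their species sets.

    Any input may be ``None`` (e.g. the trait-table pipeline without a
    phylogeny); present inputs are subset to the common species and returned
    in a consistent order, and the report lists every dropped species with
    the input(s) it was missing from.
    """
    sets: dict[str, set[str]] = {}
    if traits is not None:
        sets["traits"] = set(traits.species_ids)
    if tree is not None:
        sets["tree"] = set(tree_tip_labels(tree))
    if eco is not None:
        sets["ecology"] = set(eco.species_ids)
    if not sets:
        raise ValidationError("reconcile needs at least one input")

    common = set.intersection(*sets.values())
    if not common:
        raise ValidationError(
            "no species shared across inputs — check species name conventions"
        )
    retained = sorted(common)
    dropped: dict[str, list[str]] = {}
    everything = set.union(*sets.values())
    for sp in sorted(everything - common):
        missing_from = sorted(name for name, s in sets.items() if sp not in s)
        dropped[sp] = missing_from

    out_traits = traits.subset(retained) if traits is not None else None
    out_eco = eco.subset(retained) if eco is not None else None
    out_tree = tree
    if tree is not None and set(tree_tip_labels(tree)) != common:
        out_tree = tree.extract_tree_with_taxa_labels(retained)
    return out_traits, out_tree, out_eco, ReconcileReport(retained, dropped)
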