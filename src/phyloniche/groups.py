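"""Rule-based classification of species into functional groups.

A functional group is a combination of foraging strategy (sit-and-wait SW /
widely-foraging WF), habitat category (semi-aquatic AQ, fossorial F, cryptic
C, terrestrial T, saxicolous S, arboreal A) and activity period (diurnal D /
nocturnal N), giving a fixed label space of 2 x 6 x 2 = 24 groups. Species
with mixed strategies (cathemeral, mixed foraging, habitat generalists)
belong to every group in the Cartesian product of their attribute sets.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from phyloniche.errors import ValidationError
from phyloniche.io import (
    ACTIVITY_PERIODS,
    FORAGING_MODES,
    HABITAT_CATEGORIES,
    EcologyTable,
    canonical_name,
)

FORAGING_CODE = {"sit_and_wait": "SW", "widely_foraging": "WF"}
HABITAT_CODE = {
    "semi_aquatic": "AQ",
    "fossorial": "F",
    "cryptic": "C",
    "terrestrial": "T",
    "saxicolous": "S",
    "arboreal": "A",
}
ACTIVITY_CODE = {"diurnal": "D", "nocturnal": "N"}

#: The full, fixed 24-label space (enumeration is not data-driven).
GROUP_LABELS: tuple[str, ...] = tuple(
    f"{FORAGING_CODE[f]}-{HABITAT_CODE[h]}-{ACTIVITY_CODE[a]}"
    for f, h, a in itertools.product(
        FORAGING_MODES, HABITAT_CATEGORIES, ACTIVITY_PERIODS
    )
)

_DASHES = {"–": "-", "—": "-", "−": "-"}


def normalize_label(label: str) -> str:
    """Normalize a group label to its canonical uppercase form.

    Published sources spell labels inconsistently ("SW-Aq-N", "SW-S–N"
    with an en-dash); this maps them onto the canonical alias.
    """
    s = str(label).strip()
    for bad, good in _DASHES.items():
        s = s.replace(bad, good)
    s = s.replace(" ", "").upper()
    if s not in GROUP_LABELS:
        raise ValidationError(
            f"unknown functional-group label {label!r} (normalized {s!r})"
        )
    return s


@dataclass
class GroupAssignment:
    """Species x functional-group incidence (multi-label allowed).

    ``membership`` is a 0/1 DataFrame indexed by species over the fixed
    24-label space; ``family`` is an optional per-species family label used
    by :func:`group_summary`.
    """

    membership: pd.DataFrame
    family: pd.Series | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        m = self.membership
        missing = [c for c in m.columns if c not in GROUP_LABELS]
        if missing:
            raise ValidationError(f"unknown group labels: {missing}")
        # widen to the full label space so the enumeration is always 24
        m = m.reindex(columns=list(GROUP_LABELS), fill_value=0)
        vals = m.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError("membership values must be 0/1")
        m.index = pd.Index([canonical_name(s) for s in m.index], name="species")
        if m.index.has_duplicates:
            raise ValidationError("duplicate species in group assignment")
        self.membership = m.astype(int)
        if self.family is not None:
            fam = self.family.copy()
            fam.index = pd.Index([canonical_name(s) for s in fam.index])
            self.family = fam.reindex(self.membership.index)

    @property
    def species_ids(self) -> list[str]:
        return list(self.membership.index)

    @property
    def labels(self) -> tuple[str, ...]:
        return GROUP_LABELS

    def members(self, label: str) -> list[str]:
        label = normalize_label(label)
        col = self.membership[label]
        return list(col.index[col == 1])

    def groups_of(self, species: str) -> list[str]:
        row = self.membership.loc[canonical_name(species)]
        return list(row.index[row == 1])

    def group_sizes(self) -> pd.Series:
        return self.membership.sum(axis=0)

    def membership_counts(self) -> pd.Series:
        return self.membership.sum(axis=1)

    def subset(self, species: Iterable[str]) -> "GroupAssignment":
        sp = [canonical_name(s) for s in species]
        fam = self.family.loc[sp] if self.family is not None else None
        return GroupAssignment(self.membership.loc[sp].copy(), fam)


def classify(eco: EcologyTable) -> GroupAssignment:
    """Assign every species to the Cartesian product of its attribute sets.

    A species scored sit-and-wait + widely-foraging, cryptic, and cathemeral
    therefore lands in four groups: WF-C-D, WF-C-N, SW-C-D, SW-C-N.
    """
    rows = np.zeros((len(eco.data), len(GROUP_LABELS)), dtype=int)
    col_index = {label: i for i, label in enumerate(GROUP_LABELS)}
    for i, (_, rec) in enumerate(eco.data.iterrows()):
        for f, h, a in itertools.product(
            sorted(rec["foraging"]), sorted(rec["habitat"]), sorted(rec["activity"])
        ):
            label = f"{FORAGING_CODE[f]}-{HABITAT_CODE[h]}-{ACTIVITY_CODE[a]}"
            rows[i, col_index[label]] = 1
    membership = pd.DataFrame(rows, index=eco.data.index, columns=list(GROUP_LABELS))
    family = eco.data["family"].astype(str)
    return GroupAssignment(membership, family)


def group_summary(ga: GroupAssignment) -> dict:
    """Per-group and per-family diversity summaries.

    Reports species and family counts per group, group counts and species
    richness per family, unrepresented groups, the number of species in more
    than one group, and the Pearson correlation (with p-value) between
    family richness and the number of functional groups a family occupies.
    """
    if ga.family is None:
        raise ValidationError("group_summary requires family labels")
    m = ga.membership
    fam = ga.family

    per_group = {}
    for label in GROUP_LABELS:
        members = m.index[m[label] == 1]
        per_group[label] = {
            "n_species": int(len(members)),
            "n_families": int(fam.loc[members].nunique()),
        }
    unrepresented = [l for l in GROUP_LABELS if per_group[l]["n_species"] == 0]

    per_family = {}
    for family, sp in m.groupby(fam).groups.items():
        block = m.loc[sp]
        per_family[str(family)] = {
            "richness": int(len(sp)),
            "n_groups": int((block.sum(axis=0) > 0).sum()),
        }

    richness = np.array([v["richness"] for v in per_family.values()], dtype=float)
    n_groups = np.array([v["n_groups"] for v in per_family.values()], dtype=float)
    if len(richness) >= 3 and np.std(richness) > 0 and np.std(n_groups) > 0:
        r, p = stats.pearsonr(richness, n_groups)
        corr = {"r": float(r), "p_value": float(p)}
    else:
        corr = {"r": float("nan"), "p_value": float("nan")}

    counts = ga.membership_counts()
    return {
        "n_species": int(len(m)),
        "n_groups_represented": int(len(GROUP_LABELS) - len(unrepresented)),
        "per_group": per_group,
        "per_family": per_family,
        "unrepresented_groups": unrepresented,
        "n_multi_group_species": int((counts > 1).sum()),
        "richness_group_correlation": corr,
    }


def write_group_assignment(ga: GroupAssignment, path: str | Path) -> None:
    """Write long-format CSV: species, group_label[, family]."""
    records = []
    for sp in ga.species_ids:
        fam = str(ga.family.loc[sp]) if ga.family is not None else ""
        for label in ga.groups_of(sp):
            records.append({"species": sp, "group_label": label, "family": fam})
    pd.DataFrame(records, columns=["species", "group_label", "family"]).to_csv(
        path, index=False
    )


def read_group_assignment(path: str | Path) -> GroupAssignment:
    long = pd.read_csv(path)
    for col in ("species", "group_label"):
        if col not in long.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    species = [canonical_name(s) for s in pd.unique(long["species"])]
    membership = pd.DataFrame(
        0, index=pd.Index(species, name="species"), columns=list(GROUP_LABELS)
    )
    for _, rec in long.iterrows():
        membership.loc[canonical_name(rec["species"]), normalize_label(rec["group_label"])] = 1
    family = None
    if "family" in long.columns and long["family"].notna().any():
        family = (
            long.assign(species=[canonical_name(s) for s in long["species"]])
            .groupby("species")["family"]
            .first()
            .reindex(species)
            .astype(str)
        )
    return GroupAssignment(membership, family)
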