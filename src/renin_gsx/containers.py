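"""Core in-memory containers shared by every pipeline stage.

The pipeline operates on two kinds of objects: a dense log2-intensity
expression table with a two-group sample design (:class:`ExpressionMatrix`),
and named gene-set catalogs tagged by their collection of origin
(:class:`GeneSetCollection`).  Results of downstream stages (differential
expression, ORA, GSEA, integration) are plain :class:`pandas.DataFrame`
objects with documented columns, which keeps them easy to persist as TSV
and to slice interactively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

CATALOG_TAGS = ("TFT", "CP", "HALLMARK", "OTHER")


class FormatError(ValueError):
    """Raised when an on-disk file violates its declared layout."""


class ConfigError(ValueError):
    """Raised when inputs are inconsistent with each other or with parameters."""


@dataclass
class ExpressionMatrix:
    """Probes-or-genes x samples table of log2 intensities with group labels.

    Parameters
    ----------
    values
        Dense numeric table; rows are probe or gene identifiers, columns are
        sample names.  Duplicate row identifiers are permitted before probe
        collapsing and forbidden after.
    groups
        Optional mapping sample -> group label (e.g. ``baseline`` / ``day5``).
        Differential-expression and enrichment stages require exactly two
        distinct labels; the first label in sample order is treated as the
        reference (baseline) group.
    """

    values: pd.DataFrame
    groups: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        arr = self.values.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise FormatError("expression values must be numeric")
        if arr.size and not np.isfinite(arr.astype(float)).all():
            raise FormatError("expression values must be finite (no NaN/inf)")
        if self.groups is not None:
            missing = [s for s in self.sample_ids if s not in self.groups]
            if missing:
                raise ConfigError(f"samples without a group label: {missing}")

    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def group_labels(self) -> list[str]:
        """Distinct group labels in order of first appearance over samples."""
        if self.groups is None:
            raise ConfigError("matrix carries no group labels")
        seen: list[str] = []
        for s in self.sample_ids:
            g = self.groups[s]
            if g not in seen:
                seen.append(g)
        return seen

    def two_groups(self) -> tuple[str, str]:
        """The (reference, test) pair; errors unless exactly two labels exist."""
        labels = self.group_labels()
        if len(labels) != 2:
            raise ConfigError(
                f"exactly two groups required, found {len(labels)}: {labels}"
            )
        return labels[0], labels[1]

    def samples_in(self, label: str) -> list[str]:
        if self.groups is None:
            raise ConfigError("matrix carries no group labels")
        return [s for s in self.sample_ids if self.groups[s] == label]

    def with_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        """A copy of this matrix with replaced values but the same design."""
        return ExpressionMatrix(values, None if self.groups is None else dict(self.groups))


@dataclass(frozen=True)
class GeneSet:
    """One named gene set: catalog tag, free-text description, member symbols.

    Members are stored de-duplicated and uppercased, in first-appearance order.
    """

    name: str
    catalog: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.catalog not in CATALOG_TAGS:
            raise ConfigError(f"unknown catalog tag {self.catalog!r}")
        if not self.members:
            raise FormatError(f"gene set {self.name!r} has no members")

    @property
    def size(self) -> int:
        return len(self.members)

    def member_set(self) -> frozenset[str]:
        return frozenset(self.members)


def _dedupe_upper(symbols: Iterable[str]) -> tuple[str, ...]:
    out: list[str] = []
    seen: set[str] = set()
    for s in symbols:
        u = str(s).upper()
        if u and u not in seen:
            seen.add(u)
            out.append(u)
    return tuple(out)


@dataclass
class GeneSetCollection:
    """An ordered mapping of uniquely named gene sets."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    @classmethod
    def from_dict(
        cls,
        members_by_name: Mapping[str, Iterable[str]],
        catalog: str = "OTHER",
        descriptions: Mapping[str, str] | None = None,
    ) -> "GeneSetCollection":
        coll = cls()
        for name, members in members_by_name.items():
            desc = (descriptions or {}).get(name, "")
            coll.add(GeneSet(name, catalog, desc, _dedupe_upper(members)))
        return coll

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.name in self.sets:
            raise FormatError(f"duplicate gene set name {gene_set.name!r}")
        self.sets[gene_set.name] = gene_set

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)

    def members_by_name(self) -> dict[str, tuple[str, ...]]:
        return {s.name: s.members for s in self}

    def merge(self, other: "GeneSetCollection") -> "GeneSetCollection":
        """Union of two collections; duplicate names raise."""
        merged = GeneSetCollection()
        for s in self:
            merged.add(s)
        for s in other:
            merged.add(s)
        return merged

    def restrict(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Intersect every set with a gene universe, dropping emptied sets."""
        uni = {str(g).upper() for g in universe}
        out = GeneSetCollection()
        for s in self:
            kept = tuple(m for m in s.members if m in uni)
            if kept:
                out.add(GeneSet(s.name, s.catalog, s.description, kept))
        return out
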