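"""Phenotype tables, category registries, merges, and category-set enumeration."""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "PhenotypeVector",
    "MergeRule",
    "read_phenotypes",
    "merge_categories",
    "enumerate_category_sets",
]


@dataclass
class PhenotypeVector:
    """Species -> category map with an ordered category registry."""

    assignments: dict[str, str]
    categories: list[str]

    def __post_init__(self) -> None:
        seen = set(self.categories)
        if len(seen) != len(self.categories):
            raise ValueError("duplicate category labels in registry")
        missing = {c for c in self.assignments.values() if c not in seen}
        if missing:
            raise ValueError(f"unregistered categories: {sorted(missing)}")

    @classmethod
    def from_assignments(cls, assignments: dict[str, str]) -> "PhenotypeVector":
        registry: list[str] = []
        for cat in assignments.values():
            if cat not in registry:
                registry.append(cat)
        return cls(dict(assignments), registry)

    @property
    def species(self) -> list[str]:
        return list(self.assignments)

    @property
    def k(self) -> int:
        return len(self.categories)

    def counts(self) -> dict[str, int]:
        out = {c: 0 for c in self.categories}
        for cat in self.assignments.values():
            out[cat] += 1
        return out

    def index_of(self, category: str) -> int:
        return self.categories.index(category)

    def state_indices(self) -> dict[str, int]:
        """Species -> integer category index (registry order)."""
        pos = {c: i for i, c in enumerate(self.categories)}
        return {sp: pos[c] for sp, c in self.assignments.items()}

    def restrict(self, species: Iterable[str]) -> "PhenotypeVector":
        keep = set(species)
        sub = {s: c for s, c in self.assignments.items() if s in keep}
        registry = [c for c in self.categories if c in set(sub.values())]
        return PhenotypeVector(sub, registry)


@dataclass(frozen=True)
class MergeRule:
    """Combine >=2 base categories into one merged label (e.g. Vertivore)."""

    merged: str
    constituents: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.constituents) < 2:
            raise ValueError("a merge needs at least two constituent categories")
        if self.merged in self.constituents:
            raise ValueError("merged label may not be one of its constituents")

    @classmethod
    def parse(cls, text: str) -> "MergeRule":
        """Parse ``Merged=A+B`` notation."""
        merged, _, rhs = text.partition("=")
        parts = tuple(p.strip() for p in rhs.split("+"))
        return cls(merged.strip(), parts)


_HEADER_HINTS = {"species", "sp", "taxon", "tip", "category", "phenotype", "diet", "state", "label"}


def read_phenotypes(source: str | io.TextIOBase) -> PhenotypeVector:
    """Read a two-column species/category table (TSV or CSV, header optional)."""
    if isinstance(source, str):
        source = io.StringIO(source)
    text = source.read()
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    df = pd.read_csv(io.StringIO(text), sep=sep, header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError("phenotype table must have two columns (species, category)")
    df = df.iloc[:, :2]
    first = [str(x).strip().lower() for x in df.iloc[0]]
    if any(x in _HEADER_HINTS for x in first):
        df = df.iloc[1:]
    df = df.apply(lambda s: s.str.strip())
    if df.isna().any().any() or (df == "").any().any():
        bad = df[df.isna().any(axis=1) | (df == "").any(axis=1)]
        raise ValueError(f"empty species or category cell in rows: {bad.index.tolist()}")
    dupes = df.iloc[:, 0][df.iloc[:, 0].duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate species in phenotype table: {sorted(set(dupes))}")
    assignments = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    return PhenotypeVector.from_assignments(assignments)


def write_phenotypes(pheno: PhenotypeVector) -> str:
    return "".join(f"{s}\t{c}\n" for s, c in pheno.assignments.items())


def merge_categories(pheno: PhenotypeVector, rule: MergeRule) -> PhenotypeVector:
    """Relabel all species in the rule's constituent categories to the merged label.

    The merged label takes the registry position of the first constituent;
    total species count is conserved.
    """
    unknown = [c for c in rule.constituents if c not in pheno.categories]
    if unknown:
        raise ValueError(f"unknown constituent categories: {unknown}")
    if rule.merged in pheno.categories:
        raise ValueError(f"merged label {rule.merged!r} already registered")
    cset = set(rule.constituents)
    assignments = {
        s: (rule.merged if c in cset else c) for s, c in pheno.assignments.items()
    }
    registry: list[str] = []
    for c in pheno.categories:
        if c in cset:
            if rule.merged not in registry:
                registry.append(rule.merged)
        else:
            registry.append(c)
    return PhenotypeVector(assignments, registry)


def enumerate_category_sets(
    base: Sequence[str],
    merges: Sequence[MergeRule] = (),
    sizes: Iterable[int] = (),
) -> list[tuple[str, ...]]:
    """All category subsets of the given sizes, excluding merged/constituent mixes.

    A set may not contain a merged label together with any of its constituents;
    two merged labels with disjoint constituents may co-occur.  Output order is
    deterministic: sizes ascending, then lexicographic in registry order
    (base labels first, then merged labels).
    """
    labels = list(base) + [m.merged for m in merges]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels across base categories and merges")
    constituents = {m.merged: set(m.constituents) for m in merges}
    for m in merges:
        unknown = constituents[m.merged] - set(base)
        if unknown:
            raise ValueError(f"merge {m.merged!r} references unknown base labels {sorted(unknown)}")
    sizes = sorted(set(sizes))
    if any(s < 2 or s > len(labels) for s in sizes):
        raise ValueError(f"sizes must lie in [2, {len(labels)}]")

    def valid(subset: tuple[str, ...]) -> bool:
        s = set(subset)
        return not any(
            m in s and (constituents[m] & s) for m in constituents
        )

    out: list[tuple[str, ...]] = []
    for size in sizes:
        out.extend(c for c in itertools.combinations(labels, size) if valid(c))
    return out
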