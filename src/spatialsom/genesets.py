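"""Gene-set collections (GMT), eligibility filtering, combination enumeration
and the shuffled-control generator.

Gene sets are consumed as Broad-dialect GMT files (set id, description,
member genes; tab-separated) and are assumed to be already propagated down
the GO graph — building propagated GMTs from an annotation database is a
preprocessing step outside this package (see docs/methods.md for a recipe).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DataFormatError, ParseError

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "parse_gmt",
    "select_eligible_sets",
    "feature_union",
    "enumerate_combinations",
    "shuffle_collection",
]


@dataclass(frozen=True)
class GeneSet:
    """A named gene set: id (e.g. a GO accession), description, member genes."""

    set_id: str
    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise DataFormatError(f"gene set {self.set_id!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise DataFormatError(f"gene set {self.set_id!r} contains duplicate genes")

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    """An ordered collection of uniquely-identified gene sets."""

    sets: list[GeneSet]
    universe: frozenset[str] | None = None
    _by_id: dict[str, GeneSet] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_id = {}
        for gs in self.sets:
            if gs.set_id in self._by_id:
                raise DataFormatError(f"duplicate set id: {gs.set_id!r}")
            self._by_id[gs.set_id] = gs

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __contains__(self, set_id: str) -> bool:
        return set_id in self._by_id

    def __getitem__(self, set_id: str) -> GeneSet:
        try:
            return self._by_id[set_id]
        except KeyError:
            raise KeyError(f"unknown set id: {set_id!r}") from None

    @property
    def set_ids(self) -> list[str]:
        return [gs.set_id for gs in self.sets]

    def sizes(self) -> list[int]:
        return [len(gs) for gs in self.sets]

    def to_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for gs in self.sets:
                fh.write("\t".join((gs.set_id, gs.name, *gs.genes)) + "\n")


def parse_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``id<TAB>name<TAB>gene...``."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"line {lineno}: expected at least 3 tab-separated fields")
            set_id, name, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise ParseError(f"line {lineno}: gene set {set_id!r} has no members")
            sets.append(GeneSet(set_id, name, tuple(genes)))
    return GeneSetCollection(sets)


def select_eligible_sets(
    c: GeneSetCollection,
    measured_genes: set[str],
    max_size: int = 1000,
    min_overlap: int = 3,
) -> GeneSetCollection:
    """Keep sets of at most ``max_size`` genes with >= ``min_overlap`` measured genes.

    The size criterion counts the set as annotated (before intersecting with
    the measured genes); the overlap criterion counts measured members only.
    Enlarging ``measured_genes`` can therefore only add eligible sets.
    """
    if not measured_genes:
        raise ValueError("measured_genes must be non-empty")
    measured = frozenset(measured_genes)
    kept = [
        gs
        for gs in c
        if len(gs) <= max_size and len(gs.gene_set & measured) >= min_overlap
    ]
    return GeneSetCollection(kept, universe=measured)


def feature_union(
    c: GeneSetCollection, ids: list[str], measured_genes: set[str]
) -> list[str]:
    """Sorted union of the measured members of the named sets."""
    union: set[str] = set()
    for set_id in ids:
        union.update(c[set_id].gene_set & set(measured_genes))
    return sorted(union)


def enumerate_combinations(
    anchor: str, pool: list[str], k: int
) -> list[tuple[str, ...]]:
    """All ``C(len(pool), k)`` k-combinations of ``pool``, each prefixed by ``anchor``.

    The pool is sorted first so the output order is lexicographic regardless
    of input order.
    """
    if anchor in pool:
        raise ValueError("anchor must not appear in the pool")
    if not 1 <= k <= len(pool):
        raise ValueError(f"k={k} out of range for pool of {len(pool)}")
    return [(anchor, *combo) for combo in itertools.combinations(sorted(pool), k)]


def shuffle_collection(
    c: GeneSetCollection, n_swaps: int = 1_000_000, seed: int = 0
) -> GeneSetCollection:
    """Size-preserving randomized control collection.

    Repeatedly (``n_swaps`` times) picks two member slots uniformly at random
    across the whole collection and swaps their gene labels; a swap that
    would duplicate a gene inside either set is skipped (the attempt still
    counts).  Every output set keeps its original cardinality and the
    multiset of gene occurrences over the collection is preserved exactly.
    """
    if len(c) == 0:
        raise ValueError("cannot shuffle an empty collection")
    if n_swaps < 0:
        raise ValueError("n_swaps must be >= 0")
    members = [list(gs.genes) for gs in c.sets]
    member_sets = [set(gl) for gl in members]
    slots = [(si, gi) for si, gl in enumerate(members) for gi in range(len(gl))]
    n_slots = len(slots)
    rng = np.random.default_rng(seed)
    # draw positions in chunks; the attempt sequence is fixed by the seed
    remaining = int(n_swaps)
    chunk = 65536
    while remaining > 0:
        take = min(chunk, remaining)
        draws = rng.integers(0, n_slots, size=(take, 2))
        for a, b in draws:
            sa, ga = slots[a]
            sb, gb = slots[b]
            gene_a = members[sa][ga]
            gene_b = members[sb][gb]
            if gene_a == gene_b:
                continue
            if sa != sb:
                if gene_b in member_sets[sa] or gene_a in member_sets[sb]:
                    continue
                member_sets[sa].discard(gene_a)
                member_sets[sa].add(gene_b)
                member_sets[sb].discard(gene_b)
                member_sets[sb].add(gene_a)
            members[sa][ga] = gene_b
            members[sb][gb] = gene_a
        remaining -= take
    shuffled = [
        GeneSet(gs.set_id, gs.name, tuple(gl)) for gs, gl in zip(c.sets, members)
    ]
    return GeneSetCollection(shuffled, universe=c.universe)
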