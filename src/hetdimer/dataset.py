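"""Labeled-example construction.

Positive examples are heterodimeric (size-2) complexes whose pair is an
interaction edge and is not a proper subset of any other catalogued complex.
Negative examples are interacting pairs co-occurring inside a complex of size
greater than two, excluding any pair that is itself catalogued as a size-2
complex — those are removed from the dataset entirely, whether or not they
qualified as positives. Negatives built this way sit inside dense, strongly
weighted subgraphs and are deliberately hard.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

from .containers import ComplexCatalog, WeightedPPINetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True, order=True)
class ProteinPair:
    """Unordered pair of two distinct proteins; equality ignores order."""

    a: str
    b: str

    def __init__(self, a: str, b: str) -> None:
        if a == b:
            raise ValueError(f"pair members must be distinct, got {a!r} twice")
        lo, hi = sorted((str(a), str(b)))
        object.__setattr__(self, "a", lo)
        object.__setattr__(self, "b", hi)

    def __iter__(self):
        yield self.a
        yield self.b

    def as_set(self) -> frozenset[str]:
        return frozenset((self.a, self.b))

    def __str__(self) -> str:
        return f"{self.a}--{self.b}"


@dataclass(frozen=True)
class LabeledExample:
    """A protein pair with its heterodimer label (+1) or non-heterodimer (-1).

    ``provenance`` records the catalog complexes the example came from.
    """

    pair: ProteinPair
    label: int
    provenance: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.label not in (+1, -1):
            raise ValueError(f"label must be +1 or -1, got {self.label}")


def select_positives(catalog: ComplexCatalog, network: WeightedPPINetwork) -> list[LabeledExample]:
    """Heterodimer complexes that are network edges and not proper subsets of
    any other complex. Deterministically sorted by pair identifiers."""
    by_pair: dict[ProteinPair, list[str]] = {}
    complexes = catalog.complexes
    for name, members in complexes.items():
        if len(members) != 2:
            continue
        pair = ProteinPair(*members)
        if not network.has_edge(pair.a, pair.b):
            continue
        # proper subset of a *different* complex disqualifies; an identical
        # member set under another name is not a proper subset and does not
        if any(members < other for oname, other in complexes.items() if oname != name):
            continue
        by_pair.setdefault(pair, []).append(name)
    return [
        LabeledExample(pair, +1, tuple(sorted(names)))
        for pair, names in sorted(by_pair.items())
    ]


def select_negatives(
    catalog: ComplexCatalog,
    network: WeightedPPINetwork,
    positives: list[LabeledExample] | None = None,
) -> list[LabeledExample]:
    """Interacting pairs inside complexes of size > 2 that are not themselves
    catalogued heterodimers. Deduplicated across complexes, sorted by pair."""
    size2 = catalog.size2_pairs()
    by_pair: dict[ProteinPair, set[str]] = {}
    for name, members in catalog.items():
        if len(members) <= 2:
            continue
        for a, b in combinations(sorted(members), 2):
            if not network.has_edge(a, b):
                continue
            if frozenset((a, b)) in size2:
                continue
            by_pair.setdefault(ProteinPair(a, b), set()).add(name)
    negatives = [
        LabeledExample(pair, -1, tuple(sorted(names)))
        for pair, names in sorted(by_pair.items())
    ]
    if positives is not None:
        overlap = {ex.pair for ex in positives} & {ex.pair for ex in negatives}
        if overlap:  # cannot happen under the size-2 exclusion; guard anyway
            raise RuntimeError(f"positive/negative overlap: {sorted(map(str, overlap))}")
    return negatives


def build_dataset(catalog: ComplexCatalog, network: WeightedPPINetwork) -> list[LabeledExample]:
    """Positives followed by negatives, with a disjointness consistency check."""
    positives = select_positives(catalog, network)
    negatives = select_negatives(catalog, network, positives)
    pos_pairs = {ex.pair for ex in positives}
    neg_pairs = {ex.pair for ex in negatives}
    if pos_pairs & neg_pairs:
        raise RuntimeError("internal consistency error: positives and negatives overlap")
    logger.info("dataset: %d positives, %d negatives", len(positives), len(negatives))
    return positives + negatives


def example_labels(examples: list[LabeledExample]) -> list[int]:
    return [ex.label for ex in examples]


def example_pairs(examples: list[LabeledExample]) -> list[ProteinPair]:
    return [ex.pair for ex in examples]
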