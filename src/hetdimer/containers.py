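"""Core data containers: weighted PPI network, complex catalog, domain annotation.

Protein and domain identifiers are opaque, case-sensitive strings; no alias or
ortholog mapping is attempted.
"""

from __future__ import annotations

import math
from collections import Counter
from collections.abc import Iterable, Iterator, Mapping

import networkx as nx


class FormatError(ValueError):
    """An input table violates its declared format."""


class ConfigError(ValueError):
    """A configuration object violates its declared constraints."""


class WeightedPPINetwork:
    """Undirected protein-protein interaction graph with positive edge weights.

    Vertices are protein identifiers; each edge carries a finite weight > 0
    interpreted as the reliability/strength of the interaction. Self-loops are
    rejected and at most one weight exists per unordered pair.
    """

    def __init__(self) -> None:
        self._g = nx.Graph()
        #: counters filled by the table reader (self-loops dropped, duplicate
        #: rows collapsed, header-like rows skipped)
        self.parse_stats: dict[str, int] = {}

    # -- construction ---------------------------------------------------

    def add_vertex(self, protein: str) -> None:
        self._g.add_node(str(protein))

    def add_edge(self, a: str, b: str, weight: float, on_duplicate: str = "max") -> None:
        """Insert the undirected edge {a, b} with the given weight.

        ``on_duplicate`` controls collision handling: "max" keeps the larger
        weight (order-independent), "error" raises.
        """
        a, b = str(a), str(b)
        if a == b:
            raise ValueError(f"self-loop rejected: {a!r}")
        w = float(weight)
        if not math.isfinite(w) or w <= 0:
            raise ValueError(f"edge weight must be positive and finite, got {weight!r}")
        if self._g.has_edge(a, b):
            if on_duplicate == "error":
                raise ValueError(f"duplicate edge {{{a}, {b}}}")
            w = max(w, self._g[a][b]["weight"])
        self._g.add_edge(a, b, weight=w)

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str, float]]) -> "WeightedPPINetwork":
        net = cls()
        for a, b, w in edges:
            net.add_edge(a, b, w)
        return net

    # -- queries --------------------------------------------------------

    @property
    def vertices(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def n_vertices(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def edges(self) -> Iterator[tuple[str, str, float]]:
        """Iterate edges as (a, b, weight) with a < b lexicographically."""
        for u, v, data in self._g.edges(data=True):
            a, b = sorted((u, v))
            yield a, b, data["weight"]

    def has_vertex(self, protein: str) -> bool:
        return self._g.has_node(protein)

    def has_edge(self, a: str, b: str) -> bool:
        return self._g.has_edge(a, b)

    def weight(self, a: str, b: str) -> float:
        if not self._g.has_edge(a, b):
            raise KeyError(f"no edge {{{a}, {b}}}")
        return self._g[a][b]["weight"]

    def neighbors(self, protein: str) -> set[str]:
        if not self._g.has_node(protein):
            return set()
        return set(self._g.neighbors(protein))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WeightedPPINetwork):
            return NotImplemented
        return self.vertices == other.vertices and sorted(self.edges()) == sorted(other.edges())

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"WeightedPPINetwork({self.n_vertices} proteins, {self.n_edges} interactions)"


class ComplexCatalog:
    """Named protein complexes, each a set of at least two distinct proteins."""

    def __init__(self, complexes: Mapping[str, Iterable[str]] | None = None) -> None:
        self._complexes: dict[str, frozenset[str]] = {}
        if complexes:
            for name, members in complexes.items():
                self.add(name, members)

    def add(self, name: str, members: Iterable[str]) -> None:
        name = str(name)
        if name in self._complexes:
            raise ValueError(f"duplicate complex name {name!r}")
        members = frozenset(str(m) for m in members)
        if len(members) < 2:
            raise ValueError(f"complex {name!r} has fewer than 2 distinct members")
        self._complexes[name] = members

    @property
    def complexes(self) -> dict[str, frozenset[str]]:
        return dict(self._complexes)

    def members(self, name: str) -> frozenset[str]:
        return self._complexes[name]

    def names(self) -> list[str]:
        return sorted(self._complexes)

    def __len__(self) -> int:
        return len(self._complexes)

    def __contains__(self, name: str) -> bool:
        return name in self._complexes

    def items(self) -> Iterator[tuple[str, frozenset[str]]]:
        yield from sorted(self._complexes.items())

    def size2_pairs(self) -> set[frozenset[str]]:
        """Member sets of all heterodimeric (size-2) complexes."""
        return {m for m in self._complexes.values() if len(m) == 2}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ComplexCatalog):
            return NotImplemented
        return self._complexes == other._complexes

    def __repr__(self) -> str:  # pragma: no cover
        n2 = len(self.size2_pairs())
        return f"ComplexCatalog({len(self)} complexes, {n2} heterodimeric)"


class DomainAnnotation:
    """Protein → multiset of domain identifiers (domain → count ≥ 1).

    Proteins absent from the mapping are *unannotated*; how they behave under
    the composition equivalence is decided by the kernel layer.
    """

    def __init__(self, composition: Mapping[str, Mapping[str, int]] | None = None) -> None:
        self._comp: dict[str, Counter] = {}
        if composition:
            for protein, domains in composition.items():
                for domain, count in domains.items():
                    self.add(protein, domain, count)

    def add(self, protein: str, domain: str, count: int = 1) -> None:
        count = int(count)
        if count <= 0:
            raise ValueError(f"domain count must be >= 1, got {count} for {protein!r}/{domain!r}")
        self._comp.setdefault(str(protein), Counter())[str(domain)] += count

    def composition(self, protein: str) -> Counter:
        """Domain multiset of the protein; empty Counter when unannotated."""
        return Counter(self._comp.get(protein, Counter()))

    def is_annotated(self, protein: str) -> bool:
        return protein in self._comp

    def n_domains(self, protein: str) -> int:
        """Total number of domains counted with multiplicity (0 if unannotated)."""
        return sum(self._comp.get(protein, Counter()).values())

    @property
    def proteins(self) -> set[str]:
        return set(self._comp)

    def items(self) -> Iterator[tuple[str, Counter]]:
        for protein in sorted(self._comp):
            yield protein, Counter(self._comp[protein])

    def __len__(self) -> int:
        return len(self._comp)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DomainAnnotation):
            return NotImplemented
        return self._comp == other._comp

    def __repr__(self) -> str:  # pragma: no cover
        return f"DomainAnnotation({len(self)} annotated proteins)"
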