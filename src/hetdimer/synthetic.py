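"""Synthetic weighted PPI networks with planted heterodimers and complexes.

The generator emulates the statistical structure the classifier relies on:

* planted heterodimers — one strong internal edge, otherwise weak background
  neighbourhood;
* planted larger complexes (size 3-6) — dense cliques of strong edges, whose
  internal pairs become *hard* negative examples (high F1/F2/F4);
* a sprinkle of "bridged" heterodimers that also share one strong common
  partner inside a large complex, so a fraction of positives genuinely look
  complex-like in the weight features;
* log-normal edge weights (positive, right-skewed, like reliability scores
  built from log-odds association indices);
* domain multisets per protein, with a configured fraction of heterodimers
  reusing exact domain-composition classes — the signal the
  domain-composition kernel exploits.

Membership of heterodimers and large complexes is disjoint, so the rule-based
dataset builder recovers the planted labels exactly.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from typing import NamedTuple

import numpy as np

from .containers import ComplexCatalog, ConfigError, DomainAnnotation, WeightedPPINetwork
from .dataset import LabeledExample, ProteinPair


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generator.

    Weight medians are in the same arbitrary reliability units as the network
    weights; ``*_sigma`` are log-space standard deviations of the log-normal
    draws. ``bridge_attachment_prob`` is the probability that a heterodimer
    also gains one strong shared partner inside a large complex (making it a
    feature-ambiguous positive). ``shared_composition_fraction`` is the
    fraction of heterodimers assigned to repeated exact domain-composition
    classes of size ``shared_class_size``.
    """

    n_background_proteins: int = 300
    n_heterodimers: int = 40
    n_large_complexes: int = 20
    large_complex_size: tuple[int, int] = (3, 6)
    in_complex_weight_median: float = 40.0
    in_complex_weight_sigma: float = 0.4
    background_weight_median: float = 8.0
    background_weight_sigma: float = 0.6
    background_edge_prob: float = 0.01
    bridge_attachment_prob: float = 0.2
    n_domain_types: int = 60
    domains_per_protein: tuple[int, int] = (1, 4)
    shared_composition_fraction: float = 0.8
    shared_class_size: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_background_proteins", "n_heterodimers", "n_large_complexes",
                     "n_domain_types"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        lo, hi = self.large_complex_size
        if not (3 <= lo <= hi):
            raise ConfigError(f"large_complex_size must satisfy 3 <= lo <= hi, got {(lo, hi)}")
        lo, hi = self.domains_per_protein
        if not (1 <= lo <= hi):
            raise ConfigError(f"domains_per_protein must satisfy 1 <= lo <= hi, got {(lo, hi)}")
        for name in ("in_complex_weight_median", "background_weight_median"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        for name in ("in_complex_weight_sigma", "background_weight_sigma"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("background_edge_prob", "bridge_attachment_prob",
                     "shared_composition_fraction"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.shared_class_size < 2:
            raise ConfigError("shared_class_size must be >= 2")
        if self.shared_composition_fraction > 0 and self.n_heterodimers == 0:
            raise ConfigError(
                "shared_composition_fraction > 0 requires at least one heterodimer"
            )
        if self.n_domain_types == 0 and (
            self.n_heterodimers or self.n_large_complexes or self.n_background_proteins
        ):
            raise ConfigError("n_domain_types must be > 0 when proteins exist")


class SyntheticData(NamedTuple):
    network: WeightedPPINetwork
    catalog: ComplexCatalog
    domains: DomainAnnotation
    examples: list[LabeledExample]  # planted truth labels


def _lognormal(rng: np.random.Generator, median: float, sigma: float, size=None):
    return rng.lognormal(mean=math.log(median), sigma=sigma, size=size)


def _random_composition(rng: np.random.Generator, config: SyntheticConfig) -> Counter:
    lo, hi = config.domains_per_protein
    k = int(rng.integers(lo, hi + 1))
    vocab = rng.integers(0, config.n_domain_types, size=k)
    return Counter(f"d{v:03d}" for v in vocab)


def generate(config: SyntheticConfig | None = None) -> SyntheticData:
    """Draw one synthetic instance; deterministic given ``config.seed``."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)

    network = WeightedPPINetwork()
    catalog = ComplexCatalog()
    domains = DomainAnnotation()

    # planted heterodimers: one strong internal edge each
    het_pairs: list[ProteinPair] = []
    for i in range(config.n_heterodimers):
        a, b = f"hd{i:03d}a", f"hd{i:03d}b"
        network.add_edge(a, b, _lognormal(rng, config.in_complex_weight_median,
                                          config.in_complex_weight_sigma))
        catalog.add(f"HET{i:03d}", (a, b))
        het_pairs.append(ProteinPair(a, b))

    # planted large complexes: dense strong cliques
    complex_members: list[list[str]] = []
    lo, hi = config.large_complex_size
    for i in range(config.n_large_complexes):
        size = int(rng.integers(lo, hi + 1))
        members = [f"cx{i:03d}m{j}" for j in range(size)]
        for a, b in combinations(members, 2):
            network.add_edge(a, b, _lognormal(rng, config.in_complex_weight_median,
                                              config.in_complex_weight_sigma))
        catalog.add(f"CPX{i:03d}", members)
        complex_members.append(members)

    all_complex_proteins = [p for members in complex_members for p in members]

    # composition classes: groups of heterodimers that will reuse the same
    # exact pair of domain compositions
    n_shared = round(config.shared_composition_fraction * config.n_heterodimers)
    shared_idx = sorted(rng.choice(config.n_heterodimers, size=n_shared, replace=False)) \
        if n_shared else []
    classes = [
        shared_idx[start:start + config.shared_class_size]
        for start in range(0, len(shared_idx), config.shared_class_size)
    ]
    singletons = [[i] for i in range(config.n_heterodimers) if i not in set(shared_idx)]

    # bridged heterodimers: both members gain a strong shared partner inside a
    # large complex, so the positive looks complex-like in F2/F4. Bridging is
    # decided per composition class — proteins with identical domain
    # architecture share interaction behaviour — so the composition kernel
    # carries real information about the ambiguous positives.
    if all_complex_proteins:
        for group in classes + singletons:
            if rng.random() < config.bridge_attachment_prob:
                for het_index in group:
                    target = all_complex_proteins[
                        int(rng.integers(len(all_complex_proteins)))
                    ]
                    for member in het_pairs[het_index]:
                        network.add_edge(member, target,
                                         _lognormal(rng, config.in_complex_weight_median,
                                                    config.in_complex_weight_sigma))

    # background proteins and weak background edges over everything
    background = [f"bg{i:03d}" for i in range(config.n_background_proteins)]
    for protein in background:
        network.add_vertex(protein)
    proteins = sorted(network.vertices)
    if config.background_edge_prob > 0 and len(proteins) > 1:
        pairs = list(combinations(proteins, 2))
        mask = rng.random(len(pairs)) < config.background_edge_prob
        weights = _lognormal(rng, config.background_weight_median,
                             config.background_weight_sigma, size=int(mask.sum()))
        for (a, b), w in zip((p for p, m in zip(pairs, mask) if m), weights):
            if not network.has_edge(a, b):  # planted edges keep their strength
                network.add_edge(a, b, w)

    # domain annotations: repeated exact compositions across the class groups
    assigned: dict[str, Counter] = {}
    for klass in classes:
        comp_a = _random_composition(rng, config)
        comp_b = _random_composition(rng, config)
        for het_index in klass:
            pair = het_pairs[het_index]
            first, second = (pair.a, pair.b) if rng.random() < 0.5 else (pair.b, pair.a)
            assigned[first] = Counter(comp_a)
            assigned[second] = Counter(comp_b)
    for protein in proteins:
        comp = assigned.get(protein) or _random_composition(rng, config)
        for domain, count in sorted(comp.items()):
            domains.add(protein, domain, count)

    # planted truth, ordered like the rule-based dataset builder's output
    positives = sorted(
        (LabeledExample(pair, +1, (f"HET{i:03d}",)) for i, pair in enumerate(het_pairs)),
        key=lambda ex: ex.pair,
    )
    negatives = sorted(
        (
            LabeledExample(ProteinPair(a, b), -1, (f"CPX{i:03d}",))
            for i, members in enumerate(complex_members)
            for a, b in combinations(sorted(members), 2)
        ),
        key=lambda ex: ex.pair,
    )
    return SyntheticData(network, catalog, domains, positives + negatives)
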