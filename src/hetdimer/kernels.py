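"""Domain-composition kernel, linear feature kernel, and their combination.

Two proteins are *equivalent* when their domain multisets are identical
(same domains, same counts). Two protein sets of equal size are equivalent
when some permutation matches every protein to an equivalent partner; since
protein equivalence is plain multiset equality this reduces to comparing the
sorted tuples of per-protein canonical forms. The domain-composition kernel
K_dc(X, Y) is the indicator of this set equivalence — an indicator of an
equivalence relation, hence positive semidefinite (its Gram is a block
matrix of ones over the equivalence classes).

The combined kernel mixes a base kernel k on the real-valued feature vectors
(linear here) with K_dc, either convexly, (1-a)*k + a*K_dc with a in [0, 1]
(default), or additively, k + a*K_dc with a >= 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Iterable, Sequence

import numpy as np

from .containers import ConfigError, DomainAnnotation
from .dataset import ProteinPair

UNANNOTATED_MODES = ("pseudo", "empty")

#: canonical form of one protein: sorted ((domain, count), ...) tuple
CanonicalComposition = tuple[tuple[str, int], ...]


def canonical_composition(
    protein: str, domains: DomainAnnotation, unannotated: str = "pseudo"
) -> CanonicalComposition:
    """Order-independent canonical form of a protein's domain multiset.

    Unannotated proteins get, by default, a pseudo-domain unique to the
    protein itself ("pseudo" mode): that keeps equivalence reflexive without
    collapsing all unannotated proteins into one class. "empty" mode makes
    every unannotated protein mutually equivalent instead.
    """
    if unannotated not in UNANNOTATED_MODES:
        raise ConfigError(f"unknown unannotated mode {unannotated!r}")
    comp = domains.composition(protein)
    if not comp:
        if unannotated == "pseudo":
            return ((f"__unannotated__:{protein}", 1),)
        return ()
    return tuple(sorted(comp.items()))


def set_canonical_form(
    proteins: Iterable[str], domains: DomainAnnotation, unannotated: str = "pseudo"
) -> tuple[CanonicalComposition, ...]:
    """Canonical form of a protein set: the sorted tuple of member forms."""
    return tuple(sorted(canonical_composition(p, domains, unannotated) for p in proteins))


def protein_equivalent(
    a: str, b: str, domains: DomainAnnotation, unannotated: str = "pseudo"
) -> bool:
    """True iff the two proteins have identical domain multisets."""
    return canonical_composition(a, domains, unannotated) == canonical_composition(
        b, domains, unannotated
    )


def set_equivalent(
    x: Iterable[str],
    y: Iterable[str],
    domains: DomainAnnotation,
    unannotated: str = "pseudo",
) -> bool:
    """True iff some permutation matches the two protein sets into pairwise
    equivalent proteins. Works for any set size; sets of unequal size are
    never equivalent."""
    x, y = list(x), list(y)
    if len(x) != len(y):
        return False
    return set_canonical_form(x, domains, unannotated) == set_canonical_form(
        y, domains, unannotated
    )


def set_equivalent_bruteforce(
    x: Iterable[str],
    y: Iterable[str],
    domains: DomainAnnotation,
    unannotated: str = "pseudo",
) -> bool:
    """Literal definition via explicit permutation enumeration (reference
    implementation for testing; exponential in the set size)."""
    x, y = list(x), list(y)
    if len(x) != len(y):
        return False
    return any(
        all(protein_equivalent(a, b, domains, unannotated) for a, b in zip(x, perm))
        for perm in permutations(y)
    )


def kdc(
    x: Iterable[str],
    y: Iterable[str],
    domains: DomainAnnotation,
    unannotated: str = "pseudo",
) -> int:
    """Domain-composition kernel: 1 if the protein sets are equivalent, else 0."""
    return int(set_equivalent(x, y, domains, unannotated))


@dataclass(frozen=True)
class KernelConfig:
    """Mixing configuration for the combined kernel.

    ``form="convex"``: (1-alpha)*k + alpha*K_dc, alpha in [0, 1].
    ``form="additive"``: k + alpha*K_dc, alpha >= 0.
    The base kernel k is linear on the (scaled) feature vectors.
    """

    alpha: float = 0.0
    form: str = "convex"
    unannotated: str = "pseudo"

    def __post_init__(self) -> None:
        if self.form not in ("convex", "additive"):
            raise ConfigError(f"unknown kernel form {self.form!r}")
        if self.unannotated not in UNANNOTATED_MODES:
            raise ConfigError(f"unknown unannotated mode {self.unannotated!r}")
        if self.form == "convex" and not (0.0 <= self.alpha <= 1.0):
            raise ConfigError(f"convex form requires alpha in [0, 1], got {self.alpha}")
        if self.form == "additive" and self.alpha < 0.0:
            raise ConfigError(f"additive form requires alpha >= 0, got {self.alpha}")


def combined_kernel(
    fx: np.ndarray, fy: np.ndarray, kdc_xy: float, config: KernelConfig
) -> float:
    """Combined kernel value for one pair of examples."""
    base = float(np.dot(np.asarray(fx, dtype=float), np.asarray(fy, dtype=float)))
    if config.form == "convex":
        return (1.0 - config.alpha) * base + config.alpha * kdc_xy
    return base + config.alpha * kdc_xy


def combine_gram(
    linear_gram: np.ndarray, kdc_gram: np.ndarray, config: KernelConfig
) -> np.ndarray:
    """Vectorised combination of a linear Gram and a K_dc Gram (also valid for
    rectangular test-vs-train blocks)."""
    linear_gram = np.asarray(linear_gram, dtype=float)
    kdc_gram = np.asarray(kdc_gram, dtype=float)
    if linear_gram.shape != kdc_gram.shape:
        raise ValueError(
            f"Gram shape mismatch: {linear_gram.shape} vs {kdc_gram.shape}"
        )
    if config.form == "convex":
        return (1.0 - config.alpha) * linear_gram + config.alpha * kdc_gram
    return linear_gram + config.alpha * kdc_gram


def kdc_gram(
    examples: Sequence[ProteinPair | Iterable[str]],
    domains: DomainAnnotation,
    unannotated: str = "pseudo",
) -> np.ndarray:
    """K_dc Gram over examples via equivalence-class bucketing.

    Examples are grouped by canonical form (O(N log N)); the kernel is 1
    within a bucket and 0 across buckets — equal to the pairwise permutation
    test but without the N^2 set comparisons.
    """
    keys = [set_canonical_form(ex, domains, unannotated) for ex in examples]
    buckets: dict[tuple, list[int]] = {}
    for idx, key in enumerate(keys):
        buckets.setdefault(key, []).append(idx)
    n = len(keys)
    gram = np.zeros((n, n))
    for idx in buckets.values():
        ix = np.asarray(idx)
        gram[np.ix_(ix, ix)] = 1.0
    return gram


def build_gram(
    examples: Sequence[ProteinPair | Iterable[str]],
    feature_rows: np.ndarray,
    domains: DomainAnnotation,
    config: KernelConfig,
) -> np.ndarray:
    """Full combined Gram matrix over a set of examples.

    ``feature_rows`` must be indexed consistently with ``examples`` (row i is
    the — typically scaled — feature vector of example i).
    """
    feature_rows = np.asarray(feature_rows, dtype=float)
    if feature_rows.ndim != 2 or feature_rows.shape[0] != len(examples):
        raise ValueError(
            f"feature rows ({feature_rows.shape}) inconsistent with {len(examples)} examples"
        )
    linear = feature_rows @ feature_rows.T
    indicator = kdc_gram(examples, domains, config.unannotated)
    return combine_gram(linear, indicator, config)


def min_eigenvalue(gram: np.ndarray) -> float:
    """Smallest eigenvalue of a symmetric Gram matrix (PSD diagnostic)."""
    return float(np.linalg.eigvalsh(np.asarray(gram, dtype=float))[0])
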