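"""Readers and writers for the delimited input tables and intermediate artifacts.

Input formats (all plain delimited text; delimiter auto-detected among tab,
semicolon and comma on the first data row, falling back to whitespace):

* network  — 3 columns: proteinA, proteinB, weight
* catalog  — 2 columns: protein, complex name
* domains  — 2-3 columns: protein, domain[, count]

Intermediates:

* feature table — header ``protein_a  protein_b  label  F1..F7``
* Gram matrix   — square numeric matrix plus a side-car index file (one
  example identifier per line)
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ComplexCatalog, DomainAnnotation, FormatError, WeightedPPINetwork

logger = logging.getLogger(__name__)

_CANDIDATE_DELIMITERS = ("\t", ";", ",")

FEATURE_COLUMNS = ["F1", "F2", "F3", "F4", "F5", "F6", "F7"]


def _detect_delimiter(line: str, hint: str | None) -> str | None:
    """Pick the delimiter: explicit hint wins, else first of tab/;/, present,
    else None meaning 'split on any whitespace'."""
    if hint is not None:
        return hint
    for cand in _CANDIDATE_DELIMITERS:
        if cand in line:
            return cand
    return None


def _iter_rows(path: str | Path, delimiter: str | None):
    """Yield (line_number, fields) for non-empty, non-comment lines."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    detected = delimiter
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if detected is None and delimiter is None:
                detected = _detect_delimiter(line, None)
            fields = line.split(detected) if detected else line.split()
            yield lineno, [f.strip() for f in fields if f.strip() != ""]


def read_network(path: str | Path, delimiter: str | None = None) -> WeightedPPINetwork:
    """Parse a weighted PPI edge table.

    Self-interaction rows are dropped (counted in ``parse_stats``), duplicate
    unordered pairs are collapsed to the maximum weight, and rows whose weight
    field is non-numeric are skipped as header lines (counted). A file with no
    valid data row raises :class:`FormatError`.
    """
    net = WeightedPPINetwork()
    self_loops = duplicates = skipped = valid = 0
    for lineno, fields in _iter_rows(path, delimiter):
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: expected >=3 columns, got {len(fields)}")
        a, b, weight_field = fields[0], fields[1], fields[2]
        try:
            weight = float(weight_field)
        except ValueError:
            skipped += 1
            logger.debug("%s:%d: non-numeric weight %r, skipping as header", path, lineno, weight_field)
            continue
        if a == b:
            self_loops += 1
            continue
        if not np.isfinite(weight) or weight <= 0:
            raise FormatError(f"{path}:{lineno}: weight must be positive and finite, got {weight_field}")
        if net.has_edge(a, b):
            duplicates += 1
            logger.debug("%s:%d: duplicate pair {%s, %s}, keeping max weight", path, lineno, a, b)
        net.add_edge(a, b, weight, on_duplicate="max")
        valid += 1
    if valid == 0:
        raise FormatError(f"{path}: no valid network rows found")
    net.parse_stats = {
        "self_loops_dropped": self_loops,
        "duplicates_collapsed": duplicates,
        "header_rows_skipped": skipped,
    }
    logger.info(
        "read %d proteins / %d interactions from %s (%d self-loops dropped, "
        "%d duplicates collapsed, %d header rows skipped)",
        net.n_vertices, net.n_edges, path, self_loops, duplicates, skipped,
    )
    return net


def write_network(network: WeightedPPINetwork, path: str | Path, delimiter: str = "\t") -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for a, b, w in sorted(network.edges()):
            handle.write(f"{a}{delimiter}{b}{delimiter}{w!r}\n")


def read_catalog(path: str | Path, delimiter: str | None = None) -> ComplexCatalog:
    """Parse a one-membership-per-row complex table (protein, complex name).

    Duplicate (protein, complex) rows are deduplicated with a warning;
    complexes left with a single member are dropped with a warning.
    """
    memberships: dict[str, set[str]] = {}
    seen: set[tuple[str, str]] = set()
    any_row = False
    for lineno, fields in _iter_rows(path, delimiter):
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: expected >=2 columns, got {len(fields)}")
        protein, name = fields[0], fields[1]
        any_row = True
        if (protein, name) in seen:
            logger.warning("%s:%d: duplicate membership (%s, %s) ignored", path, lineno, protein, name)
            continue
        seen.add((protein, name))
        memberships.setdefault(name, set()).add(protein)
    if not any_row:
        raise FormatError(f"{path}: no valid catalog rows found")
    catalog = ComplexCatalog()
    for name in sorted(memberships):
        members = memberships[name]
        if len(members) < 2:
            logger.warning("complex %r has a single member after parsing; dropped", name)
            continue
        catalog.add(name, members)
    return catalog


def write_catalog(catalog: ComplexCatalog, path: str | Path, delimiter: str = "\t") -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for name, members in catalog.items():
            for protein in sorted(members):
                handle.write(f"{protein}{delimiter}{name}\n")


def read_domains(path: str | Path, delimiter: str | None = None) -> DomainAnnotation:
    """Parse a protein→domain table; counts default to 1 and accumulate across
    repeated rows. An empty file yields an empty annotation (everything
    unannotated)."""
    annotation = DomainAnnotation()
    for lineno, fields in _iter_rows(path, delimiter):
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: expected >=2 columns, got {len(fields)}")
        protein, domain = fields[0], fields[1]
        count = 1
        if len(fields) >= 3:
            try:
                count = int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer count {fields[2]!r}") from exc
        if count <= 0:
            raise FormatError(f"{path}:{lineno}: count must be >= 1, got {count}")
        annotation.add(protein, domain, count)
    return annotation


def write_domains(annotation: DomainAnnotation, path: str | Path, delimiter: str = "\t") -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for protein, comp in annotation.items():
            for domain in sorted(comp):
                handle.write(f"{protein}{delimiter}{domain}{delimiter}{comp[domain]}\n")


# -- feature tables ------------------------------------------------------


def write_feature_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table (``protein_a``, ``protein_b``, ``label``, F1..F7)."""
    required = ["protein_a", "protein_b", "label", *FEATURE_COLUMNS]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    frame.to_csv(path, sep="\t", index=False, columns=required)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    required = ["protein_a", "protein_b", "label", *FEATURE_COLUMNS]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: feature table missing columns {missing}")
    return frame


# -- Gram matrices -------------------------------------------------------


def write_gram(matrix: np.ndarray, index: list[str], path: str | Path) -> None:
    """Write a square kernel matrix as TSV plus ``<path>.index`` with one
    example identifier per line."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"Gram matrix must be square, got shape {matrix.shape}")
    if len(index) != matrix.shape[0]:
        raise ValueError("index length does not match Gram dimension")
    np.savetxt(path, matrix, delimiter="\t", fmt="%.12g")
    with open(f"{path}.index", "w", encoding="utf-8") as handle:
        for name in index:
            handle.write(f"{name}\n")


def read_gram(path: str | Path) -> tuple[np.ndarray, list[str]]:
    matrix = np.loadtxt(path, delimiter="\t", ndmin=2)
    index_path = Path(f"{path}.index")
    if not index_path.exists():
        raise FormatError(f"missing Gram index file {index_path}")
    index = [line.strip() for line in index_path.read_text(encoding="utf-8").splitlines() if line.strip()]
    if len(index) != matrix.shape[0]:
        raise FormatError(f"{path}: index length {len(index)} != matrix dimension {matrix.shape[0]}")
    return matrix, index
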