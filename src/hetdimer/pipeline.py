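"""End-to-end wiring: dataset construction → features → Gram → cross-validation.

Stateless composition of the module operations; every intermediate artifact
(labeled-example table, feature table, Gram matrix) is written to the output
directory for auditability unless ``write_intermediates`` is off.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io
from .classifier import CVConfig, TrainingConfig, cross_validate
from .containers import DomainAnnotation, WeightedPPINetwork
from .dataset import LabeledExample, ProteinPair, build_dataset
from .features import feature_matrix, scale_features
from .kernels import KernelConfig, build_gram, kdc_gram

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    network_path: str
    catalog_path: str
    domains_path: str
    out_dir: str
    feature_set: str = "F1-7"
    kernel: KernelConfig = field(default_factory=lambda: KernelConfig(alpha=0.6))
    c_plus: float = 1.0
    c_minus: float = 1.0
    cv: CVConfig = field(default_factory=CVConfig)
    f5_mode: str = "common_abs_diff"
    write_intermediates: bool = True


def examples_to_frame(examples: list[LabeledExample]) -> pd.DataFrame:
    return pd.DataFrame({
        "protein_a": [ex.pair.a for ex in examples],
        "protein_b": [ex.pair.b for ex in examples],
        "label": [ex.label for ex in examples],
        "provenance": [";".join(ex.provenance) for ex in examples],
    })


def frame_to_pairs(frame: pd.DataFrame) -> list[ProteinPair]:
    return [ProteinPair(a, b) for a, b in zip(frame["protein_a"], frame["protein_b"])]


def featurize_examples(
    network: WeightedPPINetwork,
    domains: DomainAnnotation,
    examples: list[LabeledExample],
    f5_mode: str = "common_abs_diff",
) -> pd.DataFrame:
    """Feature table (pair ids, label, F1..F7) for a list of labeled examples."""
    pairs = [ex.pair for ex in examples]
    matrix = feature_matrix(network, domains, pairs, f5_mode)
    frame = pd.DataFrame(matrix, columns=list(io.FEATURE_COLUMNS))
    frame.insert(0, "protein_a", [p.a for p in pairs])
    frame.insert(1, "protein_b", [p.b for p in pairs])
    frame.insert(2, "label", [ex.label for ex in examples])
    return frame


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Execute the full pipeline and return the one-row results table
    (feature_set, alpha, c_plus, c_minus, precision, recall, fmeasure)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    network = io.read_network(config.network_path)
    catalog = io.read_catalog(config.catalog_path)
    domains = io.read_domains(config.domains_path)
    logger.info("loaded %s, %s, %s", network, catalog, domains)

    examples = build_dataset(catalog, network)
    if not examples:
        raise ValueError("dataset construction produced no labeled examples")
    n_pos = sum(1 for ex in examples if ex.label == 1)
    logger.info("dataset: %d positives / %d negatives", n_pos, len(examples) - n_pos)

    table = featurize_examples(network, domains, examples, config.f5_mode)
    if config.write_intermediates:
        examples_to_frame(examples).to_csv(out_dir / "dataset.tsv", sep="\t", index=False)
        io.write_feature_table(table, out_dir / "features.tsv")

    features = table[list(io.FEATURE_COLUMNS)].to_numpy(dtype=float)
    labels = table["label"].to_numpy(dtype=int)
    pairs = [ex.pair for ex in examples]
    indicator = kdc_gram(pairs, domains, config.kernel.unannotated)
    if config.write_intermediates:
        # audit Gram on globally scaled features (CV itself rescales per fold)
        scaled, _, _ = scale_features(features)
        gram = build_gram(pairs, scaled, domains, config.kernel)
        io.write_gram(gram, [str(p) for p in pairs], out_dir / "gram.tsv")

    training = TrainingConfig(config.c_plus, config.c_minus, config.kernel)
    result = cross_validate(
        features, labels, indicator, training, config.cv, feature_set=config.feature_set
    )
    results = pd.DataFrame([{
        "feature_set": config.feature_set,
        "alpha": config.kernel.alpha,
        "c_plus": config.c_plus,
        "c_minus": config.c_minus,
        "precision": result.precision,
        "recall": result.recall,
        "fmeasure": result.fmeasure,
    }])
    results.to_csv(out_dir / "results.tsv", sep="\t", index=False)
    return results
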