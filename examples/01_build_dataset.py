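"""Construct labeled heterodimer examples from a catalog and a weighted network.

The toy instance is a four-protein complex C1 with five internal interaction
edges, one of which ({A, B}) is also catalogued as the heterodimer C2, plus a
free-standing heterodimer {X, Y}. The selection rules make {X, Y} the only
positive, turn the four other C1 edges into negatives, and remove {A, B}
from the dataset entirely (it is a catalogued heterodimer nested inside C1).
"""

import hetdimer as hd

catalog = hd.ComplexCatalog({
    "C1": {"A", "B", "C", "D"},
    "C2": {"A", "B"},
    "C3": {"X", "Y"},
})
network = hd.WeightedPPINetwork.from_edges([
    ("A", "B", 5.0), ("A", "C", 4.0), ("B", "C", 3.0),
    ("B", "D", 2.0), ("C", "D", 6.0), ("X", "Y", 9.0),
])

dataset = hd.build_dataset(catalog, network)
for example in dataset:
    kind = "heterodimer" if example.label == +1 else "non-heterodimer"
    print(f"{example.pair}  label={example.label:+d}  ({kind}, from {','.join(example.provenance)})")

n_pos = sum(1 for ex in dataset if ex.label == +1)
print(f"\n{n_pos} positive / {len(dataset) - n_pos} negative examples; "
      "the nested heterodimer {A, B} appears in neither class.")
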