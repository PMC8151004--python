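"""AP-score and AP attribute-score matrices.

The AP-score of a document is its relative-frequency vector over the AP
vocabulary (row sums to 1).  The attribute-score is, for each of four
theoretical attributes — distant, extra_meridian, five_transport, source —
the fraction of the document's mention instances carrying that attribute
(values in [0, 1]; rows do not sum to 1 because attributes overlap and are
non-exhaustive).

Distant points ("far from the disease site") have no single canonical
operationalization, so the rule is pluggable: the default region heuristic
marks an AP distant iff it lies in the distal-limb region while the disease
site does not; an explicit per-(disease, AP) table or disabling the
attribute entirely are alternatives.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .corpus_io import AttributeTable, Corpus, parse_ap_code

__all__ = [
    "ATTRIBUTES",
    "DistantRule",
    "ap_scores",
    "attribute_scores",
    "write_score_matrix",
]

#: Fixed attribute column order for reproducible downstream feature indices.
ATTRIBUTES = ("distant", "extra_meridian", "five_transport", "source")


@dataclass(frozen=True)
class DistantRule:
    """How to decide whether an AP counts as distant for a disease.

    mode:
      * ``region_heuristic`` — distant iff the AP's region is distal_limb
        and the disease's annotated site region is not distal_limb; needs
        ``disease_region``.
      * ``explicit_table`` — look up ``pairs[(disease, ap_code)]``; must
        cover every (disease, AP) combination in the corpus.
      * ``disabled`` — the distant column is identically 0.
    """

    mode: str = "region_heuristic"
    disease_region: Mapping[str, str] = field(default_factory=dict)
    pairs: Mapping[tuple[str, str], bool] = field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in ("region_heuristic", "explicit_table", "disabled"):
            raise ValueError(f"unknown distant-rule mode {self.mode!r}")

    def indicator(self, disease: str, ap_code: str, region: str) -> float:
        if self.mode == "disabled":
            return 0.0
        if self.mode == "explicit_table":
            key = (disease, ap_code)
            if key not in self.pairs:
                raise KeyError(
                    f"explicit distant table lacks entry for {key}; "
                    "explicit_table mode requires full corpus coverage"
                )
            return float(bool(self.pairs[key]))
        if disease not in self.disease_region:
            raise KeyError(
                f"region_heuristic distant rule has no site region for "
                f"disease {disease!r}"
            )
        site = self.disease_region[disease]
        return float(region == "distal_limb" and site != "distal_limb")


def ap_scores(corpus: Corpus, *, binary: bool = False) -> pd.DataFrame:
    """Documents x vocabulary relative-frequency matrix (rows sum to 1).

    With ``binary=True``, each distinct AP counts once regardless of how
    many times it was selected (sensitivity-analysis mode); the default
    weights mentions with multiplicity.
    """
    counts = corpus.counts_frame()
    if binary:
        counts = (counts > 0).astype(float)
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        empty = list(totals.index[totals == 0])
        raise ValueError(f"documents with no mentions: {empty}")
    return counts.div(totals, axis=0)


def attribute_scores(
    corpus: Corpus,
    table: AttributeTable,
    rule: DistantRule | None = None,
    *,
    binary: bool = False,
) -> pd.DataFrame:
    """Documents x 4 attribute-score matrix in the fixed ATTRIBUTES order.

    Each entry is the fraction of the document's mention instances whose AP
    carries the attribute.  Equivalent to ap_scores @ indicator for the
    per-AP attributes; the distant indicator additionally depends on the
    document's disease through the rule.
    """
    rule = rule if rule is not None else DistantRule(mode="disabled")
    vocab = [str(ap) for ap in corpus.vocabulary]
    missing = [c for c in vocab if c not in table]
    if missing:
        raise KeyError(f"APs missing from attribute table: {missing}")

    scores = ap_scores(corpus, binary=binary)
    ind = table.indicator_matrix().loc[vocab]  # extra_meridian/five_transport/source
    regions = table.frame.loc[vocab, "region"]

    base = scores.to_numpy() @ ind.to_numpy()  # (n_docs, 3)
    distant = np.empty(len(corpus))
    for i, doc in enumerate(corpus.documents):
        flags = np.array(
            [rule.indicator(doc.disease, code, regions[code]) for code in vocab]
        )
        distant[i] = float(scores.to_numpy()[i] @ flags)

    out = pd.DataFrame(
        np.column_stack([distant, base]),
        index=scores.index,
        columns=list(ATTRIBUTES),
    )
    out.index.name = "doc_id"
    return out


def corpus_hash(corpus: Corpus) -> str:
    """Stable content hash of the aggregated corpus records."""
    from .corpus_io import corpus_to_csv_text

    return hashlib.sha256(corpus_to_csv_text(corpus).encode()).hexdigest()[:16]


def write_score_matrix(
    matrix: pd.DataFrame,
    path,
    *,
    corpus: Corpus | None = None,
    rule: DistantRule | None = None,
) -> None:
    """Write a score matrix to CSV with a JSON sidecar of provenance metadata."""
    matrix.to_csv(path)
    meta = {
        "columns": list(matrix.columns),
        "n_documents": int(matrix.shape[0]),
        "distant_rule": rule.mode if rule is not None else None,
        "corpus_hash": corpus_hash(corpus) if corpus is not None else None,
    }
    sidecar = str(path) + ".meta.json"
    with open(sidecar, "w") as fh:
        json.dump(meta, fh, indent=2)
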