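"""Synthetic prescription corpora with planted style and disease effects.

The generator emulates the study design the analysis assumes: one document
per textbook x disease cell (42 documents for 3 textbooks x 14 diseases),
each a bag of AP mentions.  A corpus-level baseline AP distribution is
drawn once from a Dirichlet; each textbook multiplicatively up-weights the
points carrying its preferred theoretical attribute (style strength s) and
each disease up-weights its signature point set (disease strength g).  At
s = g = 0 all documents are i.i.d. draws from the baseline — the exact
exchangeable null the permutation test assumes — and the planted ground
truth is returned alongside the corpus for calibration, power, and
recovery studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .corpus_io import AttributeTable, Corpus, Document, default_attribute_table
from .permtest import pairwise_distances, permutation_test
from .scoring import ATTRIBUTES, ap_scores

__all__ = [
    "SynthConfig",
    "SynthTruth",
    "simulate_corpus",
    "null_rejection_rate",
    "rejection_rate",
]

#: Default planted style preferences, mirroring the three-textbook design.
DEFAULT_PREFERRED = {
    "textbook1": "five_transport",
    "textbook2": "extra_meridian",
    "textbook3": "source",
}

_SITE_REGIONS = ("head", "trunk", "proximal_limb")


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters; the defaults are the study conditions.

    ``style_strength`` s and ``disease_strength`` g tilt sampling weights
    multiplicatively: weight(a | t, d) ∝ b_a (1 + s·[a carries
    preferred_attribute(t)]) (1 + g·[a ∈ signature(d)]).  s = g = 0 is the
    exchangeable null.
    """

    n_textbooks: int = 3
    n_diseases: int = 14
    mentions_per_doc: int = 30
    style_strength: float = 0.0
    disease_strength: float = 0.0
    signature_size: int = 8
    base_concentration: float = 0.5
    seed: int | None = None
    preferred_attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.n_textbooks < 1 or self.n_diseases < 1:
            raise ValueError("need at least one textbook and one disease")
        if self.mentions_per_doc < 1:
            raise ValueError("mentions_per_doc must be >= 1")
        if not (
            np.isfinite(self.style_strength)
            and np.isfinite(self.disease_strength)
            and self.style_strength >= 0
            and self.disease_strength >= 0
        ):
            raise ValueError("strengths must be finite and nonnegative")
        if self.signature_size < 1:
            raise ValueError("signature_size must be >= 1")
        if self.base_concentration <= 0:
            raise ValueError("base_concentration must be > 0")
        for tb, attr in self.preferred_attributes.items():
            if attr not in ATTRIBUTES:
                raise ValueError(
                    f"unknown preferred attribute {attr!r} for {tb!r}"
                )

    @property
    def textbook_names(self) -> list[str]:
        return [f"textbook{i + 1}" for i in range(self.n_textbooks)]

    @property
    def disease_names(self) -> list[str]:
        return [f"disease{i + 1:02d}" for i in range(self.n_diseases)]

    def resolved_preferences(self) -> dict[str, str]:
        if self.preferred_attributes:
            return dict(self.preferred_attributes)
        cycle = ("five_transport", "extra_meridian", "source")
        return {
            name: cycle[i % len(cycle)]
            for i, name in enumerate(self.textbook_names)
        }


@dataclass(frozen=True)
class SynthTruth:
    """Planted ground truth; with the seed it determines the sampler exactly."""

    baseline: np.ndarray                      # length-361 probability vector
    signatures: dict[str, list[str]]          # disease -> signature AP codes
    preferred: dict[str, str]                 # textbook -> planted attribute
    disease_region: dict[str, str]            # disease -> site region
    config: SynthConfig


def _attribute_indicator(
    table: AttributeTable, attribute: str, codes: list[str]
) -> np.ndarray:
    f = table.frame.loc[codes]
    if attribute == "extra_meridian":
        return f["is_extra_meridian"].to_numpy(dtype=float)
    if attribute == "five_transport":
        return (f["transport_class"] != "none").to_numpy(dtype=float)
    if attribute == "source":
        return f["is_source_point"].to_numpy(dtype=float)
    if attribute == "distant":
        # disease-independent proxy: the points capable of being distant
        return (f["region"] == "distal_limb").to_numpy(dtype=float)
    raise ValueError(f"unknown attribute {attribute!r}")


def simulate_corpus(config: SynthConfig) -> tuple[Corpus, SynthTruth]:
    """Draw one corpus (one document per textbook x disease cell).

    Deterministic under ``config.seed``: the same config yields a
    bit-identical corpus.
    """
    table = default_attribute_table()
    codes = list(table.frame.index)
    aps = {c: i for i, c in enumerate(codes)}
    rng = np.random.default_rng(config.seed)

    baseline = rng.dirichlet(np.full(len(codes), config.base_concentration))
    signatures = {
        d: sorted(
            rng.choice(codes, size=config.signature_size, replace=False).tolist()
        )
        for d in config.disease_names
    }
    preferred = config.resolved_preferences()
    disease_region = {
        d: _SITE_REGIONS[i % len(_SITE_REGIONS)]
        for i, d in enumerate(config.disease_names)
    }

    attr_ind = {
        tb: _attribute_indicator(table, attr, codes)
        for tb, attr in preferred.items()
    }
    sig_ind = {}
    for d, sig in signatures.items():
        vec = np.zeros(len(codes))
        vec[[aps[c] for c in sig]] = 1.0
        sig_ind[d] = vec

    from .corpus_io import parse_ap_code

    documents = []
    s, g = config.style_strength, config.disease_strength
    for tb in config.textbook_names:
        for d in config.disease_names:
            weights = baseline * (1.0 + s * attr_ind[tb]) * (1.0 + g * sig_ind[d])
            weights = weights / weights.sum()
            draws = rng.multinomial(config.mentions_per_doc, weights)
            mentions = {
                parse_ap_code(codes[i]): int(n)
                for i, n in enumerate(draws)
                if n > 0
            }
            documents.append(
                Document(
                    doc_id=f"{tb}-{d}",
                    textbook=tb,
                    disease=d,
                    mentions=mentions,
                )
            )
    truth = SynthTruth(baseline, signatures, preferred, disease_region, config)
    return Corpus(documents), truth


def rejection_rate(
    config: SynthConfig,
    n_reps: int,
    alpha: float,
    B: int,
    *,
    grouping: str = "textbook",
    tail: str = "below",
    seed: int | None = None,
) -> float:
    """Fraction of simulated replicates whose permutation p crosses alpha.

    ``tail='below'`` counts p < alpha (rejections); ``tail='above'`` counts
    p > alpha (non-rejections), useful for checking planted-null patterns.
    Each replicate redraws the corpus with a derived seed and runs the
    grouping's permutation test on AP-scores.
    """
    if alpha >= 1.0 and tail == "below":
        return 1.0
    if alpha <= 0.0 and tail == "below":
        return 0.0
    root = np.random.SeedSequence(seed if seed is not None else config.seed)
    children = root.generate_state(2 * n_reps)
    hits = 0
    for r in range(n_reps):
        cfg = replace(config, seed=int(children[2 * r] % (2**31)))
        corpus, _ = simulate_corpus(cfg)
        D = pairwise_distances(ap_scores(corpus))
        res = permutation_test(
            D,
            corpus.labels(grouping),
            B=B,
            seed=int(children[2 * r + 1] % (2**31)),
            grouping=grouping,
            mode="monte_carlo",
        )
        if tail == "below":
            hits += res.p_empirical < alpha
        else:
            hits += res.p_empirical > alpha
    return hits / n_reps


def null_rejection_rate(
    config: SynthConfig,
    n_reps: int = 200,
    alpha: float = 0.05,
    B: int = 2000,
    *,
    seed: int | None = None,
) -> float:
    """Same-textbook rejection rate under the exchangeable null (s = g = 0)."""
    if config.style_strength != 0 or config.disease_strength != 0:
        raise ValueError("null calibration requires s = g = 0")
    return rejection_rate(
        config, n_reps, alpha, B, grouping="textbook", tail="below", seed=seed
    )
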