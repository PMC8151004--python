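"""Data model for acupuncture-point (AP) prescription corpora.

An AP is coded by a meridian abbreviation plus a point number ("SP3",
"BL13").  A *document* is one textbook chapter: a bag of AP mentions with
multiplicities, labeled by the textbook (style) and the disease it treats.
A *corpus* is an ordered collection of documents over a shared vocabulary.

The module also ships the reference annotation table for all 361
standard-code APs: extra-meridian membership (governor/conception vessel),
five-transport class (well/brook/stream/river/sea), source-point flag, and a
coarse body-region class used by distant-point rules.  The annotations
follow the WHO standard acupuncture nomenclature.
"""

from __future__ import annotations

import io
import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import pandas as pd

logger = logging.getLogger("apstyle")

__all__ = [
    "MERIDIANS",
    "MERIDIAN_RANGES",
    "YIN_MERIDIANS",
    "APCode",
    "APCodeError",
    "parse_ap_code",
    "AttributeTable",
    "default_attribute_table",
    "Document",
    "Corpus",
    "CorpusError",
    "read_corpus",
    "write_corpus",
]

# ---------------------------------------------------------------------------
# AP codes
# ---------------------------------------------------------------------------

#: Canonical meridian enumeration order; fixes vocabulary column order.
MERIDIANS: tuple[str, ...] = (
    "LU", "LI", "ST", "SP", "HT", "SI", "BL",
    "KI", "PC", "TE", "GB", "LR", "GV", "CV",
)

#: Highest point number on each meridian (WHO standard ranges; 361 total).
MERIDIAN_RANGES: dict[str, int] = {
    "LU": 11, "LI": 20, "ST": 45, "SP": 21, "HT": 9, "SI": 19, "BL": 67,
    "KI": 27, "PC": 9, "TE": 23, "GB": 44, "LR": 14, "GV": 28, "CV": 24,
}

#: Yin meridians of the twelve regular channels (source point = stream point).
YIN_MERIDIANS: frozenset[str] = frozenset({"LU", "SP", "HT", "KI", "PC", "LR"})

#: The twelve regular meridians (everything except the two vessel channels).
REGULAR_MERIDIANS: tuple[str, ...] = MERIDIANS[:12]

#: Accepted input aliases, normalized on parse.
_MERIDIAN_ALIASES = {"TB": "TE"}

_MERIDIAN_INDEX = {m: i for i, m in enumerate(MERIDIANS)}

_AP_RE = re.compile(r"^\s*([A-Za-z]{2})\s*0*([0-9]+)\s*$")


class APCodeError(ValueError):
    """Raised for an unparseable or out-of-range AP code."""


class APCode(NamedTuple):
    """An acupuncture point: meridian abbreviation + point number.

    The canonical string form is the meridian code immediately followed by
    the number, e.g. ``"SP3"``; :func:`parse_ap_code` inverts it.
    """

    meridian: str
    number: int

    def __str__(self) -> str:
        return f"{self.meridian}{self.number}"

    @property
    def sort_key(self) -> tuple[int, int]:
        """(meridian enumeration index, point number) — vocabulary order."""
        return (_MERIDIAN_INDEX[self.meridian], self.number)

    @property
    def is_extra_meridian(self) -> bool:
        """True iff the point lies on the governor or conception vessel."""
        return self.meridian in ("GV", "CV")


def parse_ap_code(text: str) -> APCode:
    """Parse an AP code such as ``"SP3"`` (case-insensitive, whitespace-tolerant).

    Raises
    ------
    APCodeError
        If the meridian prefix is unknown or the number is out of the
        meridian's standard range.
    """
    if not isinstance(text, str) or not text.strip():
        raise APCodeError(f"empty or non-string AP code: {text!r}")
    m = _AP_RE.match(text)
    if m is None:
        raise APCodeError(f"malformed AP code: {text!r}")
    prefix = m.group(1).upper()
    prefix = _MERIDIAN_ALIASES.get(prefix, prefix)
    if prefix not in MERIDIAN_RANGES:
        raise APCodeError(f"unknown meridian prefix {prefix!r} in {text!r}")
    number = int(m.group(2))
    if not 1 <= number <= MERIDIAN_RANGES[prefix]:
        raise APCodeError(
            f"point number {number} out of range 1-{MERIDIAN_RANGES[prefix]} "
            f"for meridian {prefix} in {text!r}"
        )
    return APCode(prefix, number)


def all_ap_codes() -> list[APCode]:
    """All 361 standard AP codes in canonical vocabulary order."""
    return [
        APCode(m, n)
        for m in MERIDIANS
        for n in range(1, MERIDIAN_RANGES[m] + 1)
    ]


# ---------------------------------------------------------------------------
# Attribute reference table
# ---------------------------------------------------------------------------

# Five transport points per regular meridian (well, brook, stream, river, sea),
# WHO standard nomenclature.  All lie distal to the elbow or knee.
_TRANSPORT_POINTS: dict[str, tuple[int, int, int, int, int]] = {
    "LU": (11, 10, 9, 8, 5),
    "LI": (1, 2, 3, 5, 11),
    "ST": (45, 44, 43, 41, 36),
    "SP": (1, 2, 3, 5, 9),
    "HT": (9, 8, 7, 4, 3),
    "SI": (1, 2, 3, 5, 8),
    "BL": (67, 66, 65, 60, 40),
    "KI": (1, 2, 3, 7, 10),
    "PC": (9, 8, 7, 5, 3),
    "TE": (1, 2, 3, 6, 10),
    "GB": (44, 43, 41, 38, 34),
    "LR": (1, 2, 3, 4, 8),
}

_TRANSPORT_CLASSES = ("well", "brook", "stream", "river", "sea")

# One source point per regular meridian; on yin meridians it is the stream
# point, on yang meridians a separate point.
_SOURCE_POINTS: dict[str, int] = {
    "LU": 9, "LI": 4, "ST": 42, "SP": 3, "HT": 7, "SI": 4,
    "BL": 64, "KI": 3, "PC": 7, "TE": 4, "GB": 40, "LR": 3,
}

# Coarse body-region class per meridian, as (last point number, region) runs
# walking up the point numbers.  Four classes only — the minimum a
# distant-point rule needs; transport points all fall in distal_limb.
_REGION_RUNS: dict[str, tuple[tuple[int, str], ...]] = {
    "LU": ((2, "trunk"), (4, "proximal_limb"), (11, "distal_limb")),
    "LI": ((11, "distal_limb"), (16, "proximal_limb"), (20, "head")),
    "ST": ((12, "head"), (30, "trunk"), (34, "proximal_limb"), (45, "distal_limb")),
    "SP": ((9, "distal_limb"), (11, "proximal_limb"), (21, "trunk")),
    "HT": ((2, "proximal_limb"), (9, "distal_limb")),
    "SI": ((8, "distal_limb"), (15, "proximal_limb"), (19, "head")),
    "BL": ((10, "head"), (35, "trunk"), (39, "proximal_limb"), (67, "distal_limb")),
    "KI": ((10, "distal_limb"), (27, "trunk")),
    "PC": ((1, "trunk"), (2, "proximal_limb"), (9, "distal_limb")),
    "TE": ((10, "distal_limb"), (15, "proximal_limb"), (23, "head")),
    "GB": ((20, "head"), (29, "trunk"), (33, "proximal_limb"), (44, "distal_limb")),
    "LR": ((8, "distal_limb"), (11, "proximal_limb"), (14, "trunk")),
    "GV": ((14, "trunk"), (28, "head")),
    "CV": ((22, "trunk"), (24, "head")),
}

REGIONS = ("distal_limb", "proximal_limb", "head", "trunk")


def _region_of(ap: APCode) -> str:
    for last, region in _REGION_RUNS[ap.meridian]:
        if ap.number <= last:
            return region
    raise AssertionError(f"region runs do not cover {ap}")  # pragma: no cover


class AttributeTable:
    """Per-AP theoretical annotations backing the four attribute scores.

    Wraps a DataFrame indexed by canonical code string with columns
    ``is_extra_meridian`` (bool), ``transport_class`` (one of well/brook/
    stream/river/sea/none), ``is_source_point`` (bool) and ``region``.
    """

    COLUMNS = ("is_extra_meridian", "transport_class", "is_source_point", "region")

    def __init__(self, frame: pd.DataFrame):
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"attribute table missing columns: {sorted(missing)}")
        self.frame = frame.loc[:, list(self.COLUMNS)].copy()
        self.validate()

    def __len__(self) -> int:
        return len(self.frame)

    def __contains__(self, code: object) -> bool:
        return str(code) in self.frame.index

    def validate(self) -> None:
        """Check structural invariants; raise ValueError on violation."""
        f = self.frame
        codes = [parse_ap_code(c) for c in f.index]
        extra = pd.Series([c.is_extra_meridian for c in codes], index=f.index)
        if not (f["is_extra_meridian"] == extra).all():
            raise ValueError("extra-meridian flags disagree with GV/CV membership")
        bad = f.loc[(f["transport_class"] != "none") & extra]
        if len(bad):
            raise ValueError(f"transport class set on vessel points: {list(bad.index)}")
        transport = f[f["transport_class"] != "none"]
        if not (transport["region"] == "distal_limb").all():
            raise ValueError("transport points must lie in distal_limb region")
        n_source = int(f["is_source_point"].sum())
        if n_source != 12:
            raise ValueError(f"expected 12 source points, found {n_source}")
        for code, row in f[f["is_source_point"]].iterrows():
            ap = parse_ap_code(str(code))
            if ap.meridian not in REGULAR_MERIDIANS:
                raise ValueError(f"source point {code} on a vessel channel")
            if ap.meridian in YIN_MERIDIANS and row["transport_class"] != "stream":
                raise ValueError(f"yin source point {code} is not the stream point")

    def annotation(self, ap: APCode | str) -> pd.Series:
        key = str(ap)
        if key not in self.frame.index:
            raise KeyError(f"AP {key} not in attribute table")
        return self.frame.loc[key]

    def indicator_matrix(self) -> pd.DataFrame:
        """0/1 matrix: APs x (extra_meridian, five_transport, source).

        The distant attribute is disease-dependent and handled by the
        scoring module's distant rule, not here.
        """
        f = self.frame
        return pd.DataFrame(
            {
                "extra_meridian": f["is_extra_meridian"].astype(float),
                "five_transport": (f["transport_class"] != "none").astype(float),
                "source": f["is_source_point"].astype(float),
            },
            index=f.index,
        )

    # -- I/O -----------------------------------------------------------------

    @classmethod
    def from_csv(cls, path) -> "AttributeTable":
        frame = pd.read_csv(path, dtype={"ap_code": str})
        frame["ap_code"] = [str(parse_ap_code(c)) for c in frame["ap_code"]]
        frame = frame.set_index("ap_code")
        for col in ("is_extra_meridian", "is_source_point"):
            frame[col] = frame[col].astype(bool)
        return cls(frame)

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out.index.name = "ap_code"
        out.to_csv(path)


def default_attribute_table() -> AttributeTable:
    """The packaged reference table over all 361 standard-code APs."""
    records = []
    for ap in all_ap_codes():
        tclass = "none"
        if ap.meridian in _TRANSPORT_POINTS:
            pts = _TRANSPORT_POINTS[ap.meridian]
            if ap.number in pts:
                tclass = _TRANSPORT_CLASSES[pts.index(ap.number)]
        records.append(
            {
                "ap_code": str(ap),
                "is_extra_meridian": ap.is_extra_meridian,
                "transport_class": tclass,
                "is_source_point": _SOURCE_POINTS.get(ap.meridian) == ap.number,
                "region": _region_of(ap),
            }
        )
    frame = pd.DataFrame.from_records(records).set_index("ap_code")
    return AttributeTable(frame)


# ---------------------------------------------------------------------------
# Documents and corpora
# ---------------------------------------------------------------------------


class CorpusError(ValueError):
    """Raised for structurally invalid corpus input."""


@dataclass(frozen=True)
class Document:
    """One chapter: a labeled bag of AP mentions.

    ``mentions`` maps APCode -> positive integer count; a point "selected
    six times" carries count 6.
    """

    doc_id: str
    textbook: str
    disease: str
    mentions: Mapping[APCode, int]

    def __post_init__(self):
        if not self.mentions:
            raise CorpusError(f"document {self.doc_id!r} has no AP mentions")
        for ap, count in self.mentions.items():
            if not isinstance(count, (int,)) or count <= 0:
                raise CorpusError(
                    f"document {self.doc_id!r}: count for {ap} must be a "
                    f"positive integer, got {count!r}"
                )

    @property
    def total_mentions(self) -> int:
        return sum(self.mentions.values())

    @property
    def n_distinct(self) -> int:
        return len(self.mentions)

    def argmax_mention(self) -> APCode:
        """The most-mentioned AP (ties broken by vocabulary order)."""
        return min(self.mentions, key=lambda ap: (-self.mentions[ap], ap.sort_key))


@dataclass
class Corpus:
    """Ordered documents plus the deterministic union vocabulary."""

    documents: list[Document]
    vocabulary: list[APCode] = field(default_factory=list)

    def __post_init__(self):
        ids = [d.doc_id for d in self.documents]
        dupes = [i for i, c in Counter(ids).items() if c > 1]
        if dupes:
            raise CorpusError(f"duplicate doc_ids: {dupes}")
        if not self.vocabulary:
            seen = {ap for d in self.documents for ap in d.mentions}
            self.vocabulary = sorted(seen, key=lambda ap: ap.sort_key)

    def __len__(self) -> int:
        return len(self.documents)

    @property
    def doc_ids(self) -> list[str]:
        return [d.doc_id for d in self.documents]

    @property
    def textbooks(self) -> list[str]:
        """Distinct textbook labels in first-appearance order."""
        return list(dict.fromkeys(d.textbook for d in self.documents))

    @property
    def diseases(self) -> list[str]:
        return list(dict.fromkeys(d.disease for d in self.documents))

    def labels(self, grouping: str) -> list[str]:
        """Per-document label vector for 'textbook' or 'disease' grouping."""
        if grouping not in ("textbook", "disease"):
            raise ValueError(f"grouping must be 'textbook' or 'disease', got {grouping!r}")
        return [getattr(d, grouping) for d in self.documents]

    def subset(self, textbooks: Iterable[str]) -> "Corpus":
        """Documents restricted to the given textbooks (vocabulary recomputed)."""
        keep = set(textbooks)
        docs = [d for d in self.documents if d.textbook in keep]
        if not docs:
            raise CorpusError(f"no documents for textbooks {sorted(keep)}")
        return Corpus(docs)

    def counts_frame(self) -> pd.DataFrame:
        """Dense documents x vocabulary mention-count matrix."""
        cols = [str(ap) for ap in self.vocabulary]
        data = pd.DataFrame(0, index=self.doc_ids, columns=cols, dtype=float)
        for doc in self.documents:
            for ap, count in doc.mentions.items():
                data.at[doc.doc_id, str(ap)] = count
        data.index.name = "doc_id"
        return data


_CORPUS_COLUMNS = ("doc_id", "textbook", "disease", "ap_code")


def read_corpus(path) -> Corpus:
    """Read a corpus from tidy CSV (doc_id,textbook,disease,ap_code[,count]).

    Repeated (doc_id, ap_code) rows are summed; a missing count column
    defaults to 1 per row.  Logs a design-completeness report of which
    textbook x disease cells are present.
    """
    frame = pd.read_csv(path, dtype={"doc_id": str, "textbook": str, "disease": str})
    missing = set(_CORPUS_COLUMNS) - set(frame.columns)
    if missing:
        raise CorpusError(f"corpus CSV missing columns: {sorted(missing)}")
    if "count" not in frame.columns:
        frame["count"] = 1
    if frame["count"].isna().any() or (frame["count"] <= 0).any():
        raise CorpusError("count column must contain positive integers")
    frame["count"] = frame["count"].astype(int)

    parsed = []
    for row_num, raw in zip(frame.index, frame["ap_code"]):
        try:
            parsed.append(parse_ap_code(raw))
        except APCodeError as exc:
            raise CorpusError(f"row {row_num + 2}: {exc}") from exc
    frame["_ap"] = parsed

    # doc_id -> (textbook, disease) must be a function
    label_map = frame.groupby("doc_id")[["textbook", "disease"]].nunique()
    bad = label_map[(label_map > 1).any(axis=1)]
    if len(bad):
        raise CorpusError(
            f"inconsistent textbook/disease labels for doc_ids: {list(bad.index)}"
        )

    documents = []
    for doc_id in dict.fromkeys(frame["doc_id"]):  # first-appearance order
        sub = frame[frame["doc_id"] == doc_id]
        mentions = Counter()
        for ap, count in zip(sub["_ap"], sub["count"]):
            mentions[ap] += int(count)
        documents.append(
            Document(
                doc_id=doc_id,
                textbook=sub["textbook"].iloc[0],
                disease=sub["disease"].iloc[0],
                mentions=dict(mentions),
            )
        )
    corpus = Corpus(documents)

    cells = {(d.textbook, d.disease) for d in documents}
    n_cells = len(corpus.textbooks) * len(corpus.diseases)
    logger.info(
        "corpus: %d documents, %d textbooks x %d diseases, %d/%d design cells filled",
        len(documents), len(corpus.textbooks), len(corpus.diseases),
        len(cells), n_cells,
    )
    absent = [
        (t, d)
        for t in corpus.textbooks
        for d in corpus.diseases
        if (t, d) not in cells
    ]
    if absent:
        logger.warning("missing design cells: %s", absent)
    return corpus


def write_corpus(corpus: Corpus, path) -> None:
    """Write the aggregated records back to tidy CSV (round-trips read_corpus)."""
    rows = []
    for doc in corpus.documents:
        for ap in sorted(doc.mentions, key=lambda a: a.sort_key):
            rows.append(
                {
                    "doc_id": doc.doc_id,
                    "textbook": doc.textbook,
                    "disease": doc.disease,
                    "ap_code": str(ap),
                    "count": doc.mentions[ap],
                }
            )
    pd.DataFrame(rows, columns=list(_CORPUS_COLUMNS) + ["count"]).to_csv(
        path, index=False
    )


def corpus_to_csv_text(corpus: Corpus) -> str:
    buf = io.StringIO()
    write_corpus(corpus, buf)
    return buf.getvalue()
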