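"""Reading, normalizing and filtering semantic predications.

A *predication* is a subject-predicate-object triple asserting a gene-gene
relation (e.g. ``p53 STIMULATES BIK``) extracted from a citation. This module
turns tables of raw predication instances into a reliable set of unique,
symbol-normalized predications through four stages:

1. argument-predicate distance filtering (keep precise extractions),
2. duplicate removal (merge identical triples, pooling their citations),
3. symbol normalization (map free-text gene names to official symbols,
   pruning unmappable arguments),
4. document-frequency filtering (keep triples asserted in >= ``min_docs``
   distinct citations).

Stage counts are reported in a :class:`FilterReport` whose columns are
monotonically non-increasing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO, Union

import pandas as pd

logger = logging.getLogger(__name__)

#: The closed set of gene-gene relations consumed by the pipeline.
PREDICATES = ("STIMULATES", "INHIBITS", "INTERACTS_WITH")

#: Default column names of a predication table.
DEFAULT_DIALECT = {
    "pmid": "pmid",
    "subject": "subject",
    "predicate": "predicate",
    "object": "object",
    "subject_distance": "subject_distance",
    "object_distance": "object_distance",
}


class FormatError(ValueError):
    """A delimited input file does not match the expected layout."""


class ValidationError(ValueError):
    """A record violates a precondition of a filtering stage."""


@dataclass
class Predication:
    """One extracted predication instance from a single citation."""

    pmid: str
    subject_name: str
    predicate: str
    object_name: str
    subject_distance: int | None = None
    object_distance: int | None = None
    subject_symbol: str | None = None
    object_symbol: str | None = None

    def __post_init__(self) -> None:
        if not self.pmid:
            raise ValidationError("pmid must be non-empty")
        if self.predicate not in PREDICATES:
            raise ValidationError(f"unknown predicate {self.predicate!r}")
        for d in (self.subject_distance, self.object_distance):
            if d is not None and d < 0:
                raise ValidationError("argument distances must be >= 0")


@dataclass
class AggregatedPredication:
    """A deduplicated triple keyed on raw names, pooling source citations."""

    subject_name: str
    predicate: str
    object_name: str
    pmids: frozenset[str]


@dataclass
class UniquePredication:
    """A normalized unique triple with its supporting citation set."""

    subject_symbol: str
    predicate: str
    object_symbol: str
    pmids: frozenset[str]

    @property
    def doc_frequency(self) -> int:
        """Number of distinct citations asserting this predication."""
        return len(self.pmids)


@dataclass
class FilterReport:
    """Per-stage survivor counts of the filtering pipeline."""

    raw: int
    after_distance: int
    after_dedup: int
    after_normalization: int
    after_frequency: int

    STAGES = ("raw", "after_distance", "after_dedup",
              "after_normalization", "after_frequency")

    def __post_init__(self) -> None:
        counts = [getattr(self, s) for s in self.STAGES]
        if any(c < 0 for c in counts):
            raise ValidationError("stage counts must be non-negative")
        if any(a < b for a, b in zip(counts, counts[1:])):
            raise ValidationError(
                f"stage counts must be non-increasing, got {counts}")

    def to_frame(self) -> pd.DataFrame:
        """One-row table with the conventional column names."""
        return pd.DataFrame([{
            "Raw": self.raw, "Dist.": self.after_distance,
            "Uniq.": self.after_dedup, "Norm.": self.after_normalization,
            "Freq.": self.after_frequency,
        }])

    def write(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


class SymbolMap:
    """Case-insensitive map from gene-name aliases to official symbols.

    Official symbols always map to themselves; symbols are emitted uppercase.
    """

    def __init__(self, entries: Mapping[str, str]):
        self._entries: dict[str, str] = {}
        for alias, symbol in entries.items():
            symbol = symbol.upper()
            self._entries[alias.lower()] = symbol
            self._entries.setdefault(symbol.lower(), symbol)
        if not self._entries:
            raise ValidationError("symbol map must be non-empty")

    @classmethod
    def from_tsv(cls, source: Union[str, Path, TextIO]) -> "SymbolMap":
        df = pd.read_csv(source, sep="\t", comment="#", dtype=str)
        if df.shape[1] < 2:
            raise FormatError("symbol map needs two columns: alias, symbol")
        alias_col, symbol_col = df.columns[:2]
        return cls(dict(zip(df[alias_col], df[symbol_col])))

    def lookup(self, name: str) -> str | None:
        """Official symbol for ``name``, or None if unmappable."""
        return self._entries.get(name.lower())

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, name: str) -> bool:
        return name.lower() in self._entries

    def to_tsv(self, path: Union[str, Path]) -> None:
        pd.DataFrame(
            sorted(self._entries.items()), columns=["alias", "symbol"]
        ).to_csv(path, sep="\t", index=False)


def read_predications(
    source: Union[str, Path, TextIO],
    dialect: Mapping[str, str] | None = None,
) -> list[Predication]:
    """Read a predication table.

    The table is tab-separated with a header row; ``#`` lines are comments.
    Rows whose predicate is outside :data:`PREDICATES` are dropped and the
    count is logged. Missing distances are tolerated at read time (the
    distance filter rejects them later).
    """
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    df = pd.read_csv(source, sep="\t", comment="#", dtype=str)
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    preds: list[Predication] = []
    n_rejected = 0
    for row in df.itertuples(index=False):
        rec = {k: getattr(row, cols[k]) for k in cols}
        if rec["predicate"] not in PREDICATES:
            n_rejected += 1
            continue
        preds.append(Predication(
            pmid=str(rec["pmid"]),
            subject_name=rec["subject"],
            predicate=rec["predicate"],
            object_name=rec["object"],
            subject_distance=_parse_distance(rec["subject_distance"]),
            object_distance=_parse_distance(rec["object_distance"]),
        ))
    if n_rejected:
        logger.info("rejected %d rows with out-of-scope predicates", n_rejected)
    return preds


def _parse_distance(value) -> int | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or \
            (isinstance(value, str) and not value.strip()):
        return None
    return int(value)


def write_predications(preds: Iterable[Predication],
                       path: Union[str, Path]) -> None:
    rows = [{
        "pmid": p.pmid, "subject": p.subject_name, "predicate": p.predicate,
        "object": p.object_name, "subject_distance": p.subject_distance,
        "object_distance": p.object_distance,
    } for p in preds]
    pd.DataFrame(rows, columns=list(DEFAULT_DIALECT.values())).to_csv(
        path, sep="\t", index=False)


def filter_by_distance(preds: Sequence[Predication],
                       max_distance: int = 1) -> list[Predication]:
    """Keep predications whose subject AND object distances are small.

    Smaller argument-predicate distance (number of intervening noun phrases)
    correlates with extraction precision, so by default only distance-1
    arguments are trusted.
    """
    for i, p in enumerate(preds):
        if p.subject_distance is None or p.object_distance is None:
            raise ValidationError(
                f"row {i} ({p.subject_name} {p.predicate} {p.object_name}): "
                "missing argument distance")
    return [p for p in preds
            if p.subject_distance <= max_distance
            and p.object_distance <= max_distance]


def deduplicate(preds: Sequence[Predication]) -> list[AggregatedPredication]:
    """Merge identical triples (case-insensitive names), pooling PMIDs.

    The first-seen capitalization of each name is kept as representative.
    Output order is first occurrence of each triple.
    """
    merged: dict[tuple[str, str, str], dict] = {}
    for p in preds:
        key = (p.subject_name.lower(), p.predicate, p.object_name.lower())
        rec = merged.setdefault(key, {
            "subject_name": p.subject_name, "predicate": p.predicate,
            "object_name": p.object_name, "pmids": set(),
        })
        rec["pmids"].add(p.pmid)
    return [AggregatedPredication(
        subject_name=r["subject_name"], predicate=r["predicate"],
        object_name=r["object_name"], pmids=frozenset(r["pmids"]))
        for r in merged.values()]


def normalize_symbols(
    aggs: Sequence[AggregatedPredication],
    symbol_map: SymbolMap,
) -> tuple[list[UniquePredication], int]:
    """Map names to official symbols; prune unmappables; merge collisions.

    A predication with an argument absent from the symbol map is pruned.
    Triples that become identical after normalization are merged with a
    union of their PMID sets. Returns the surviving unique predications and
    the number of pruned input records.
    """
    merged: dict[tuple[str, str, str], set[str]] = {}
    order: list[tuple[str, str, str]] = []
    pruned = 0
    for a in aggs:
        subj = symbol_map.lookup(a.subject_name)
        obj = symbol_map.lookup(a.object_name)
        if subj is None or obj is None:
            pruned += 1
            continue
        key = (subj, a.predicate, obj)
        if key not in merged:
            merged[key] = set()
            order.append(key)
        merged[key].update(a.pmids)
    out = [UniquePredication(subject_symbol=s, predicate=p, object_symbol=o,
                             pmids=frozenset(merged[(s, p, o)]))
           for (s, p, o) in order]
    return out, pruned


def filter_by_doc_frequency(
    upreds: Sequence[UniquePredication],
    min_docs: int = 2,
) -> list[UniquePredication]:
    """Keep unique predications asserted in at least ``min_docs`` citations."""
    if min_docs < 1:
        raise ValidationError("min_docs must be >= 1")
    if min_docs == 1:
        return list(upreds)
    return [u for u in upreds if u.doc_frequency >= min_docs]


def run_filter_pipeline(
    preds: Sequence[Predication],
    symbol_map: SymbolMap,
    max_distance: int = 1,
    min_docs: int = 2,
    distance_filter: bool = True,
    frequency_filter: bool = True,
) -> tuple[list[UniquePredication], FilterReport]:
    """Run the fixed-order pipeline: distance -> dedup -> normalize -> frequency.

    ``distance_filter`` / ``frequency_filter`` disable the corresponding
    stages (as in the yeast configuration, where the initial predication set
    is small); deduplication and normalization always run.
    """
    raw = len(preds)
    after_dist = filter_by_distance(preds, max_distance) if distance_filter \
        else list(preds)
    aggs = deduplicate(after_dist)
    upreds, _ = normalize_symbols(aggs, symbol_map)
    final = filter_by_doc_frequency(upreds, min_docs) if frequency_filter \
        else list(upreds)
    report = FilterReport(
        raw=raw,
        after_distance=len(after_dist),
        after_dedup=len(aggs),
        after_normalization=len(upreds),
        after_frequency=len(final),
    )
    return final, report


def pooled_retention(stage_counts: pd.DataFrame,
                     numerator: str = "dist",
                     denominator: str = "raw") -> float:
    """Percentage of predications surviving a stage, pooled over pathways.

    ``100 * sum(numerator column) / sum(denominator column)`` over all rows
    of a per-pathway stage-count table.
    """
    num = stage_counts[numerator].sum()
    den = stage_counts[denominator].sum()
    if den == 0:
        raise ValidationError("denominator column sums to zero")
    return 100.0 * num / den
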