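"""Reading, cleaning and binarizing verbal-fluency response lists.

A fluency study arrives as a long table with one row per produced word:
participant id, the raw response string and its 1-based production order.
This module turns that table into the binary participant x word incidence
matrix on which group-level semantic networks are estimated:

* surface forms are lemmatized through a user-supplied map (plural -> singular,
  spelling variants, translations), with an optional fallback heuristic;
* within-participant repetitions are dropped (first occurrence kept);
* non-category intrusions are dropped when a category lexicon is supplied;
* idiosyncratic words -- produced by fewer than ``min_producers`` participants
  in the whole sample -- are dropped, which defines the unique-response
  universe used by the discordant-word (McNemar) analysis;
* two group matrices are *equated* to the words produced by at least
  ``min_per_group`` participants in each group, so that both groups' networks
  are built over the identical node set.

Incidence matrices are plain :class:`pandas.DataFrame` objects with
participant ids as the index and canonical word tokens as (sorted) columns,
cells in {0, 1}.
"""

from __future__ import annotations

import logging
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import ConfigurationError, EmptyMatrixError, EquatingError, ValidationError

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("participant", "response", "order")


@dataclass(frozen=True)
class ResponseRecord:
    """One produced word: who said it, what was said, and when."""

    participant_id: str
    token: str
    position: int

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(f"position must be >= 1, got {self.position}")
        if not self.token.strip():
            raise ValidationError("response token is empty after trimming")


def _normalize_token(raw: str) -> str:
    return unicodedata.normalize("NFC", str(raw).strip().lower())


@dataclass
class LemmaMap:
    """Surface-form to canonical-form mapping with an optional category lexicon.

    The mapping must be idempotent: every canonical form maps to itself.  When a
    token is missing from the mapping and a lexicon is available, a single
    fallback heuristic is tried -- strip a final ``s`` if the stripped form is a
    lexicon member -- otherwise the token is returned unchanged.
    """

    mapping: dict[str, str] = field(default_factory=dict)
    lexicon: frozenset[str] | None = None

    def __post_init__(self) -> None:
        self.mapping = {_normalize_token(k): _normalize_token(v) for k, v in self.mapping.items()}
        if self.lexicon is not None:
            self.lexicon = frozenset(_normalize_token(w) for w in self.lexicon)
        for surface, canonical in self.mapping.items():
            if self.mapping.get(canonical, canonical) != canonical:
                raise ValidationError(
                    f"lemma map is not idempotent: {surface!r} -> {canonical!r} "
                    f"-> {self.mapping[canonical]!r}"
                )

    @classmethod
    def from_csv(cls, mapping_path: str | Path | None = None,
                 lexicon_path: str | Path | None = None) -> "LemmaMap":
        """Load the map from a two-column CSV (surface, canonical) and a
        one-token-per-line lexicon file."""
        mapping: dict[str, str] = {}
        if mapping_path is not None:
            table = pd.read_csv(mapping_path, header=None, names=["surface", "canonical"])
            mapping = dict(zip(table["surface"].astype(str), table["canonical"].astype(str)))
        lexicon = None
        if lexicon_path is not None:
            lines = Path(lexicon_path).read_text(encoding="utf-8").splitlines()
            lexicon = frozenset(w for w in (line.strip() for line in lines) if w)
        return cls(mapping=mapping, lexicon=lexicon)

    def canonicalize(self, token: str) -> str:
        token = _normalize_token(token)
        if token in self.mapping:
            return self.mapping[token]
        if self.lexicon is not None and token not in self.lexicon:
            stripped = token[:-1] if token.endswith("s") else token
            if stripped in self.lexicon:
                return stripped
        return token

    def in_lexicon(self, canonical: str) -> bool:
        return self.lexicon is None or canonical in self.lexicon


def load_responses(source: str | Path, sep: str | None = None) -> list[ResponseRecord]:
    """Read a long-format fluency table (CSV or TSV) into response records.

    The file must carry a header with columns ``participant``, ``response`` and
    ``order``.  Blank response rows are skipped; tokens are lower-cased and
    trimmed; the file's row order is preserved.

    Raises
    ------
    ConfigurationError
        If a required column is absent.
    ValidationError
        If the same (participant, order) slot appears twice.
    """
    table = pd.read_csv(source, sep=sep, engine="python" if sep is None else "c",
                        dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ConfigurationError(f"input table lacks required column(s): {', '.join(missing)}")
    table = table[table["response"].str.strip() != ""]
    if len(table):
        dupes = table.duplicated(subset=["participant", "order"], keep=False)
        if dupes.any():
            bad = table.loc[dupes, ["participant", "order"]].iloc[0]
            raise ValidationError(
                f"duplicate (participant, order) pair: ({bad['participant']}, {bad['order']})"
            )
    return [
        ResponseRecord(str(row.participant), _normalize_token(row.response), int(row.order))
        for row in table.itertuples()
    ]


def records_from_frame(frame: pd.DataFrame) -> list[ResponseRecord]:
    """Convert a (participant, response, order) DataFrame to response records."""
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ConfigurationError(f"frame lacks required column(s): {', '.join(missing)}")
    return [
        ResponseRecord(str(p), _normalize_token(r), int(o))
        for p, r, o in zip(frame["participant"], frame["response"], frame["order"])
    ]


def preprocess(
    records: Iterable[ResponseRecord],
    lemma_map: LemmaMap | None = None,
    min_producers: int = 2,
) -> pd.DataFrame:
    """Clean responses and build the binary participant x word incidence matrix.

    Cleaning applies, in order: lemmatization through ``lemma_map``; removal of
    tokens outside the map's category lexicon (when one is supplied); removal of
    within-participant repetitions (the first occurrence of each canonical token
    is kept); removal of idiosyncratic tokens produced by fewer than
    ``min_producers`` participants across the whole sample.

    Returns a DataFrame indexed by participant id (order of first appearance)
    with lexicographically sorted word columns, so the result is invariant to
    row permutations of the input up to row order.

    Raises
    ------
    EmptyMatrixError
        If no response survives; the message carries stage-wise attrition counts.
    """
    lemma_map = lemma_map or LemmaMap()
    attrition = {"input": 0, "non_word": 0, "repetition": 0, "idiosyncratic": 0}

    produced: dict[str, list[str]] = {}
    seen: dict[str, set[str]] = {}
    for rec in sorted(records, key=lambda r: r.position):
        attrition["input"] += 1
        canonical = lemma_map.canonicalize(rec.token)
        if not lemma_map.in_lexicon(canonical):
            attrition["non_word"] += 1
            continue
        bag = seen.setdefault(rec.participant_id, set())
        if canonical in bag:
            attrition["repetition"] += 1
            continue
        bag.add(canonical)
        produced.setdefault(rec.participant_id, []).append(canonical)

    producer_counts: dict[str, int] = {}
    for tokens in produced.values():
        for tok in tokens:
            producer_counts[tok] = producer_counts.get(tok, 0) + 1
    keep = {tok for tok, cnt in producer_counts.items() if cnt >= min_producers}
    attrition["idiosyncratic"] = sum(
        cnt for tok, cnt in producer_counts.items() if tok not in keep
    )

    words = sorted(keep)
    participants = sorted(produced)
    if not words:
        raise EmptyMatrixError(
            "all responses were eliminated during preprocessing; attrition: "
            + ", ".join(f"{k}={v}" for k, v in attrition.items())
        )
    matrix = pd.DataFrame(0, index=pd.Index(participants, name="participant"),
                          columns=words, dtype=int)
    for pid, tokens in produced.items():
        for tok in tokens:
            if tok in keep:
                matrix.at[pid, tok] = 1
    logger.info("preprocess attrition: %s; matrix %d x %d",
                attrition, *matrix.shape)
    return matrix


def split_matrix(matrix: pd.DataFrame, labels: Mapping[str, str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split an incidence matrix into (low, high) row blocks by group label."""
    low_ids = [p for p in matrix.index if labels.get(p) == "low"]
    high_ids = [p for p in matrix.index if labels.get(p) == "high"]
    return matrix.loc[low_ids], matrix.loc[high_ids]


def equate_groups(
    mat_low: pd.DataFrame,
    mat_high: pd.DataFrame,
    min_per_group: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict both group matrices to words produced by >= ``min_per_group``
    participants in *each* group.

    Both outputs share the identical, identically ordered word columns, so the
    two estimated networks are defined over the same node set.  Participant
    rows are untouched.

    Raises
    ------
    EquatingError
        If fewer than 4 shared words survive (a planar-filter network needs
        at least 4 nodes).
    """
    universe = sorted(set(mat_low.columns) | set(mat_high.columns))
    low = mat_low.reindex(columns=universe, fill_value=0)
    high = mat_high.reindex(columns=universe, fill_value=0)
    keep = [w for w in universe
            if low[w].sum() >= min_per_group and high[w].sum() >= min_per_group]
    if len(keep) < 4:
        raise EquatingError(
            f"equating left only {len(keep)} shared words; at least 4 are needed"
        )
    logger.info("equated word set: %d of %d words retained", len(keep), len(universe))
    return low[keep], high[keep]


def unique_token_counts(matrices: Sequence[pd.DataFrame]) -> int:
    """Number of distinct word columns across a collection of incidence matrices."""
    words: set[str] = set()
    for m in matrices:
        words.update(m.columns)
    return len(words)
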