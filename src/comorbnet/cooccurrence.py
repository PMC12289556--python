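"""Patient-year aggregation and disease co-occurrence counting.

The unit of analysis is the *patient-year*: all diagnosis codes (primary and
secondary) recorded for one patient within one calendar year collapse into a
single set, so a disease pair is counted at most once per patient per year no
matter how many claims mention it.  The same patient observed in two years
contributes two observations.  Twelve-month windows are calendar years
(Jan 1 - Dec 31); a rolling per-patient window is deliberately not
implemented.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .claims_io import ClaimsTable

__all__ = [
    "DiagnosisSetTable",
    "CooccurrenceMatrix",
    "aggregate_patient_windows",
    "count_cooccurrence",
    "pair_counts_by_year",
]

Window = int | str  # a calendar year, or "pooled" for the whole span


@dataclasses.dataclass(frozen=True)
class DiagnosisSetTable:
    """Mapping (patient_id, year) → set of normalized codes present that year."""

    entries: dict[tuple[str, int], frozenset[str]]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(sorted({year for _, year in self.entries}))

    @property
    def codes(self) -> tuple[str, ...]:
        seen: set[str] = set()
        for codes in self.entries.values():
            seen.update(codes)
        return tuple(sorted(seen))

    def restrict(self, window: Window) -> "DiagnosisSetTable":
        """Entries for one calendar year, or all entries for "pooled"."""
        if window == "pooled":
            return self
        if not isinstance(window, (int, np.integer)):
            raise ValueError(f"unknown window label: {window!r}")
        return DiagnosisSetTable(
            {k: v for k, v in self.entries.items() if k[1] == int(window)}
        )

    def presence_frame(
        self, vocabulary: Sequence[str] | None = None, window: Window = "pooled"
    ) -> pd.DataFrame:
        """Binary patient-year × code presence matrix (0/1 ints).

        Rows are the (patient, year) entries in the window in sorted order;
        columns follow ``vocabulary`` order (default: all codes observed,
        sorted).  Vocabulary codes never observed appear as all-zero columns.
        """
        sub = self.restrict(window)
        vocab = tuple(vocabulary) if vocabulary is not None else sub.codes
        keys = sorted(sub.entries)
        data = np.zeros((len(keys), len(vocab)), dtype=np.int8)
        col = {c: i for i, c in enumerate(vocab)}
        for row, key in enumerate(keys):
            for code in sub.entries[key]:
                j = col.get(code)
                if j is not None:
                    data[row, j] = 1
        return pd.DataFrame(
            data,
            index=pd.MultiIndex.from_tuples(keys, names=["patient_id", "year"]),
            columns=list(vocab),
        )


def aggregate_patient_windows(
    table: ClaimsTable, vocabulary: Sequence[str] | None = None
) -> DiagnosisSetTable:
    """Collapse claims into per-patient calendar-year diagnosis sets.

    Every diagnosis position contributes (primary and secondary alike);
    repeated codes collapse to one set element.  If ``vocabulary`` is given,
    codes outside it are dropped; a patient-year whose codes are all dropped
    disappears from the table (it no longer corresponds to any retained
    diagnosis).
    """
    df = table.frame[["patient_id", "service_date", "dx"]].copy()
    df["year"] = df["service_date"].dt.year
    long = df.explode("dx")
    if vocabulary is not None:
        long = long[long["dx"].isin(set(vocabulary))]
    if len(long) == 0:
        return DiagnosisSetTable({})
    grouped = long.groupby(["patient_id", "year"], sort=True)["dx"].agg(frozenset)
    return DiagnosisSetTable(
        {(str(pid), int(year)): codes for (pid, year), codes in grouped.items()}
    )


@dataclasses.dataclass(frozen=True)
class CooccurrenceMatrix:
    """Symmetric pair-count matrix over a code vocabulary.

    ``counts[i, j]`` is the number of patient-year entries containing both
    ``codes[i]`` and ``codes[j]`` (zero on the diagonal); ``diagonal[i]`` is
    the number of entries containing ``codes[i]`` at all.  By construction
    ``counts[i, j] <= min(diagonal[i], diagonal[j])``.
    """

    codes: tuple[str, ...]
    counts: np.ndarray
    diagonal: np.ndarray
    window: Window

    def __post_init__(self) -> None:
        k = len(self.codes)
        if self.counts.shape != (k, k) or self.diagonal.shape != (k,):
            raise ValueError("matrix dimensions do not match the vocabulary")
        if not np.array_equal(self.counts, self.counts.T):
            raise ValueError("co-occurrence counts must be symmetric")
        if (self.counts < 0).any() or (self.diagonal < 0).any():
            raise ValueError("co-occurrence counts must be non-negative")

    def pair_count(self, code_a: str, code_b: str) -> int:
        i, j = self.codes.index(code_a), self.codes.index(code_b)
        return int(self.counts[i, j]) if i != j else int(self.diagonal[i])

    def to_frame(self) -> pd.DataFrame:
        """Square labelled matrix with single-code counts on the diagonal."""
        full = self.counts.copy()
        np.fill_diagonal(full, self.diagonal)
        return pd.DataFrame(full, index=list(self.codes), columns=list(self.codes))

    def to_long(self) -> pd.DataFrame:
        """Long format: one row per unordered pair (code_a < code_b)."""
        rows = [
            (a, b, self.window, int(self.counts[i, j]))
            for (i, a), (j, b) in itertools.combinations(enumerate(self.codes), 2)
        ]
        return pd.DataFrame(rows, columns=["code_a", "code_b", "window", "count"])


def count_cooccurrence(
    sets: DiagnosisSetTable,
    window: Window = "pooled",
    vocabulary: Sequence[str] | None = None,
) -> CooccurrenceMatrix:
    """Count deduplicated pairwise co-occurrence over patient-year entries.

    ``counts[a][b]`` = number of entries in the window whose set contains both
    a and b; ``diagonal[a]`` = number containing a.  ``window`` is a calendar
    year or ``"pooled"`` (all years); anything else fails.

    Raises
    ------
    ValueError
        On an empty table or an unknown window label.
    """
    if len(sets) == 0:
        raise ValueError("cannot count co-occurrence on an empty table")
    presence = sets.presence_frame(vocabulary=vocabulary, window=window)
    B = presence.to_numpy().astype(np.int64)
    gram = B.T @ B
    diagonal = np.diag(gram).copy()
    counts = gram.copy()
    np.fill_diagonal(counts, 0)
    return CooccurrenceMatrix(
        codes=tuple(presence.columns), counts=counts, diagonal=diagonal, window=window
    )


def pair_counts_by_year(
    sets: DiagnosisSetTable,
    pairs: Sequence[tuple[str, str]],
    years: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Yearly co-occurrence counts for selected code pairs.

    Returns a DataFrame indexed by the (sorted) pairs with one column per
    year; years with no qualifying entries report 0, not missing.  ``years``
    defaults to the contiguous span of observed years.
    """
    if years is None:
        observed = sets.years
        if not observed:
            raise ValueError("diagnosis-set table is empty")
        years = range(observed[0], observed[-1] + 1)
    years = [int(y) for y in years]
    norm_pairs = [tuple(sorted(p)) for p in pairs]

    counts = {pair: {y: 0 for y in years} for pair in norm_pairs}
    for (_pid, year), codes in sets.entries.items():
        for pair in norm_pairs:
            if year in counts[pair] and pair[0] in codes and pair[1] in codes:
                counts[pair][year] += 1
    out = pd.DataFrame(
        [[counts[p][y] for y in years] for p in norm_pairs],
        index=pd.MultiIndex.from_tuples(norm_pairs, names=["code_a", "code_b"]),
        columns=years,
    )
    return out
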