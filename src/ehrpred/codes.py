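"""Hierarchical diagnosis-code alphabet and category projections.

Diagnosis coding schemes such as ICD-9 organise codes in a hierarchy:
every full-specificity code rolls up to a three-digit category, those to
a coarser block of related conditions, and the blocks to a small number
of chapters.  Analysing a cohort at a coarser level simply replaces each
code in a patient's history with its ancestor at that level; the
hierarchy itself is supplied as data (a TSV table), never hard-coded,
so synthetic hierarchies and real ICD tables are handled identically.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from typing import TYPE_CHECKING, Mapping

if TYPE_CHECKING:  # pragma: no cover
    from .corpus_io import PatientHistory

__all__ = [
    "Level",
    "DiseaseCode",
    "CodeHierarchy",
    "load_hierarchy",
    "save_hierarchy",
    "project_code",
    "project_history",
]

#: Disease codes are opaque strings; no numeric-range parsing is attempted
#: (ICD-9 V/E code dialects make that fragile).
DiseaseCode = str


class Level(str, Enum):
    """Specificity level of a hierarchy stratum.

    ``FULL`` is the full-specificity code (the finest level, sometimes
    called CAT_4 in a four-level scheme), ``CAT_3`` and ``CAT_2`` are
    successively coarser category levels, ``CHAPTER`` is the top level.
    """

    FULL = "full"
    CAT_3 = "cat3"
    CAT_2 = "cat2"
    CHAPTER = "chapter"


#: Alias: in the four-level naming the finest category level IS the full code.
CAT_4 = Level.FULL

# ordering from finest to coarsest, used to validate projection targets
_ORDER = [Level.FULL, Level.CAT_3, Level.CAT_2, Level.CHAPTER]


class UnknownCodeError(KeyError):
    """A code was not found in the hierarchy table."""

    def __init__(self, code: str):
        super().__init__(code)
        self.code = code

    def __str__(self) -> str:  # pragma: no cover - trivial
        return f"code {self.code!r} not present in the hierarchy"


@dataclass
class CodeHierarchy:
    """Mapping from full codes to their ancestors at each coarser level.

    Parameters
    ----------
    entries
        ``full code -> (cat3 id, cat2 id, chapter id)``.  Every full code
        maps to exactly one parent per level: projection is a function.
    """

    entries: Mapping[str, tuple[str, str, str]]
    level_sizes: dict[Level, int] = field(init=False)

    def __post_init__(self) -> None:
        cat3 = {v[0] for v in self.entries.values()}
        cat2 = {v[1] for v in self.entries.values()}
        chap = {v[2] for v in self.entries.values()}
        self.level_sizes = {
            Level.FULL: len(self.entries),
            Level.CAT_3: len(cat3),
            Level.CAT_2: len(cat2),
            Level.CHAPTER: len(chap),
        }

    def parent(self, code: str, target: Level) -> str:
        if target is Level.FULL:
            if code not in self.entries:
                raise UnknownCodeError(code)
            return code
        try:
            cat3, cat2, chap = self.entries[code]
        except KeyError:
            raise UnknownCodeError(code) from None
        return {Level.CAT_3: cat3, Level.CAT_2: cat2, Level.CHAPTER: chap}[target]

    def __contains__(self, code: str) -> bool:
        return code in self.entries


_COLUMNS = ("code", "cat3", "cat2", "chapter")


def load_hierarchy(path) -> CodeHierarchy:
    """Read a hierarchy table from a TSV file.

    The file must be UTF-8, tab-separated, with a header row
    ``code  cat3  cat2  chapter`` and a unique ``code`` column.

    Raises
    ------
    ValueError
        On a missing column or a duplicated full code (the offending
        code is named in the message).
    """
    entries: dict[str, tuple[str, str, str]] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in _COLUMNS if c not in header]
        if missing:
            raise ValueError(f"hierarchy TSV missing column(s): {', '.join(missing)}")
        for row in reader:
            code = row["code"]
            if code in entries:
                raise ValueError(f"duplicate full code in hierarchy: {code!r}")
            entries[code] = (row["cat3"], row["cat2"], row["chapter"])
    return CodeHierarchy(entries)


def save_hierarchy(h: CodeHierarchy, path) -> None:
    """Write a hierarchy to TSV in the same format ``load_hierarchy`` reads."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_COLUMNS)
        for code in sorted(h.entries):
            cat3, cat2, chap = h.entries[code]
            writer.writerow([code, cat3, cat2, chap])


def project_code(h: CodeHierarchy, code: DiseaseCode, target: Level) -> DiseaseCode:
    """Project a full code onto its unique ancestor at ``target`` level."""
    return h.parent(code, target)


def project_history(h: CodeHierarchy, ph: "PatientHistory", target: Level) -> "PatientHistory":
    """Replace every code in a history by its ancestor at ``target`` level.

    Sequence length and event order are unchanged; only the symbols
    coarsen, so the number of distinct symbols can only shrink.
    """
    from .corpus_io import PatientHistory

    events = [(t, h.parent(c, target)) for t, c in ph.events]
    return PatientHistory(patient_id=ph.patient_id, events=events, presorted=True)
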