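"""Celiac-disease epitope catalog.

The catalog holds non-deamidated (glutamine-form) peptides in three groups:

* DQ2.5 T-cell epitopes (alpha-gliadin, gamma-gliadin and secalin classes) —
  the 9-mers counted by the amplicon "type" classifier;
* the p31-43 peptide, which triggers the innate (non-T-cell) response and is
  quantified separately from the DQ2.5 epitopes;
* multi-epitope "region" peptides (the protease-resistant 33-mer and 26-mer),
  convenient for planting several overlapping epitopes at once.

Epitopes whose sequence is shared across prolamin registries (omega-gliadin /
hordein / secalin) are stored once with multi-source annotation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib.resources import files
from typing import Iterable, Iterator

import pandas as pd

__all__ = [
    "EpitopeEntry",
    "EpitopeCatalog",
    "DQ25_CLASSES",
    "VALID_CLASSES",
]

#: classes that count toward the DQ2.5 epitope total of an amplicon "type"
DQ25_CLASSES = frozenset({"alpha-DQ2.5", "gamma-DQ2.5", "secalin-DQ2.5"})

VALID_CLASSES = DQ25_CLASSES | {"innate-peptide", "region-peptide"}

_AMINO = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class EpitopeEntry:
    """A single catalog peptide."""

    epitope_id: str
    peptide: str
    epitope_class: str
    score: float | None = None
    sources: str = ""

    def __post_init__(self) -> None:
        if not self.peptide or not set(self.peptide) <= _AMINO:
            raise ValueError(
                f"{self.epitope_id}: peptide must be uppercase amino acids, "
                f"got {self.peptide!r}"
            )
        if self.epitope_class not in VALID_CLASSES:
            raise ValueError(
                f"{self.epitope_id}: unknown class {self.epitope_class!r}"
            )

    @property
    def is_dq25(self) -> bool:
        return self.epitope_class in DQ25_CLASSES


class EpitopeCatalog:
    """Ordered, id-unique collection of :class:`EpitopeEntry`."""

    def __init__(self, entries: Iterable[EpitopeEntry]):
        self._entries = list(entries)
        ids = [e.epitope_id for e in self._entries]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate epitope ids: {dup}")
        self._by_id = {e.epitope_id: e for e in self._entries}

    # -- construction -------------------------------------------------

    @classmethod
    def from_tsv(cls, path) -> "EpitopeCatalog":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        entries = []
        for row in df.to_dict("records"):
            score = row.get("immunogenicity_score")
            score = None if score is None or pd.isna(score) else float(score)
            sources = row.get("sources", "")
            entries.append(
                EpitopeEntry(
                    epitope_id=row["epitope_id"],
                    peptide=row["peptide"],
                    epitope_class=row["class"],
                    score=score,
                    sources="" if pd.isna(sources) else sources,
                )
            )
        return cls(entries)

    @classmethod
    def default(cls) -> "EpitopeCatalog":
        """The packaged catalog (illustrative scores; see the data file)."""
        return cls.from_tsv(files("gliascan.data") / "epitope_catalog.tsv")

    # -- access -------------------------------------------------------

    def __iter__(self) -> Iterator[EpitopeEntry]:
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, epitope_id: str) -> bool:
        return epitope_id in self._by_id

    def __getitem__(self, epitope_id: str) -> EpitopeEntry:
        return self._by_id[epitope_id]

    @property
    def ids(self) -> list[str]:
        return [e.epitope_id for e in self._entries]

    def select(self, classes: Iterable[str]) -> list[EpitopeEntry]:
        classes = set(classes)
        return [e for e in self._entries if e.epitope_class in classes]

    @property
    def dq25(self) -> list[EpitopeEntry]:
        return [e for e in self._entries if e.is_dq25]

    def scores(self, ids: Iterable[str] | None = None) -> pd.Series:
        """Immunogenicity scores for ``ids`` (default: DQ2.5 entries).

        Entries without a score get the median of the available scores, so a
        partially filled screening table still yields usable leaf weights.
        """
        if ids is None:
            ids = [e.epitope_id for e in self.dq25]
        ids = list(ids)
        raw = {i: self._by_id[i].score for i in ids if i in self._by_id}
        known = [v for v in raw.values() if v is not None]
        if not known:
            return pd.Series(1.0, index=ids)
        med = float(pd.Series(known).median())
        vals = [raw.get(i, med) if raw.get(i) is not None else med for i in ids]
        assert all(not math.isnan(v) for v in vals)
        return pd.Series(vals, index=ids, dtype=float)
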