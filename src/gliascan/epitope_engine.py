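"""Translation, pseudogene calling, epitope scanning and abundance tables.

The prolamin amplicons studied here sit mid-gene between primer anchors, so
the reading frame is a panel-level property inferred by minimizing in-frame
stop codons across the panel (pseudogenes are a minority and keep their stops
in the chosen frame).  An amplicon whose translation contains a premature stop
is called a pseudogene; stops at TAA/TAG are additionally classified by
whether a T->C reversion at codon position 1 restores a glutamine codon
(CAA/CAG), the canonical C->T transition route by which Q/P-rich prolamin
genes acquire stops.  TGA is excluded: reversion gives CGA (arginine).

Epitope scanning slides every window (overlaps counted) against the catalog
with a Hamming tolerance of 0 or 1.  A window matching an epitope exactly is
never additionally reported as a one-mismatch variant of another epitope of
the same length at the same window.

Abundance semantics are presence-based: the abundance of an epitope in a
genotype is the summed abundance of (by default putative, i.e. non-pseudogene)
amplicons that contain at least one exact occurrence of it; amplicon "types"
(Alpha_0..., Gamma_0..., by total exact DQ2.5 occurrence count) partition the
amplicons, so type abundances sum to the putative total per genotype.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .amplicon_db import AmpliconRecord
from .catalog import DQ25_CLASSES, EpitopeCatalog, EpitopeEntry

__all__ = [
    "EpitopeOccurrence",
    "infer_panel_frame",
    "translate",
    "call_pseudogene",
    "classify_ct_stop",
    "find_epitopes",
    "classify_type",
    "epitope_abundance",
    "type_abundance",
    "variant_abundance",
    "variant_log2fc",
    "pseudogene_percent",
]

_CODON = dict(standard_dna_table.forward_table)
_CODON.update({c: "*" for c in standard_dna_table.stop_codons})

#: pseudocount (in percent) protecting log2 fold changes against zeros
LOG2FC_EPS = 1e-6


@dataclass(frozen=True)
class EpitopeOccurrence:
    """A catalog peptide found in a translated amplicon."""

    amplicon_id: str
    epitope_id: str
    start: int          # 0-based offset in the peptide
    mismatches: int     # 0 or 1
    observed: str       # the window actually seen


# -------------------------------------------------------------- translation


def translate(dna: str, frame: int = 0) -> str:
    """Standard-code translation; '*' for stops, 'X' for ambiguous codons."""
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    dna = dna.upper()
    return "".join(
        _CODON.get(dna[i : i + 3], "X")
        for i in range(frame, len(dna) - 2, 3)
    )


def infer_panel_frame(
    sequences: Iterable[str | AmpliconRecord],
) -> int:
    """Frame offset minimizing total in-frame stops across the panel.

    Majority vote over the panel: the true frame has stops only in the
    pseudogene minority, while wrong frames hit stops pervasively.  Ties go to
    the smallest offset.
    """
    seqs = [s.sequence if isinstance(s, AmpliconRecord) else s for s in sequences]
    if not seqs:
        raise ValueError("empty panel")
    totals = [
        sum(translate(s, f).count("*") for s in seqs) for f in (0, 1, 2)
    ]
    return int(np.argmin(totals))  # argmin takes the first (smallest) on ties


def call_pseudogene(peptide: str) -> bool:
    """True when the translation carries a premature stop."""
    return "*" in peptide


def classify_ct_stop(dna: str, frame: int = 0) -> list[int]:
    """Codon indices of in-frame stops revertible to glutamine by T->C.

    TAA and TAG revert to CAA/CAG (glutamine) when the first T is restored to
    C — the signature of pseudogenization by C->T transition.  TGA reverts to
    CGA (arginine) and is excluded.
    """
    dna = dna.upper()
    out = []
    for codon_idx, i in enumerate(range(frame, len(dna) - 2, 3)):
        if dna[i : i + 3] in ("TAA", "TAG"):
            out.append(codon_idx)
    return out


# ----------------------------------------------------------------- scanning


def _hamming_leq(a: str, b: str, limit: int) -> int:
    """Hamming distance, or limit+1 as soon as it is exceeded."""
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return mm
    return mm


def find_epitopes(
    peptide: str,
    catalog: EpitopeCatalog | Iterable[EpitopeEntry],
    max_mismatch: int = 0,
    amplicon_id: str = "",
) -> list[EpitopeOccurrence]:
    """Scan every window of ``peptide`` against the catalog.

    Overlapping occurrences are all reported.  With ``max_mismatch=1``, a
    window that matches some epitope exactly suppresses one-mismatch reports
    of other same-length epitopes at that window (exact-first suppression).
    """
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    entries = list(catalog)
    occs: list[EpitopeOccurrence] = []
    exact_windows: set[tuple[int, int]] = set()
    for entry in entries:
        m = len(entry.peptide)
        for start in range(len(peptide) - m + 1):
            window = peptide[start : start + m]
            mm = _hamming_leq(window, entry.peptide, max_mismatch)
            if mm <= max_mismatch:
                if mm == 0:
                    exact_windows.add((start, m))
                occs.append(
                    EpitopeOccurrence(amplicon_id, entry.epitope_id, start, mm, window)
                )
    if max_mismatch > 0:
        occs = [
            o for o in occs
            if o.mismatches == 0 or (o.start, len(o.observed)) not in exact_windows
        ]
    occs.sort(key=lambda o: (o.start, o.epitope_id, o.mismatches))
    return occs


def classify_type(
    occurrences: Iterable[EpitopeOccurrence],
    catalog: EpitopeCatalog,
    panel: str = "alpha",
) -> str:
    """Amplicon 'type' label: total count of exact DQ2.5 epitope occurrences.

    Overlapping occurrences each count; p31-43 (innate peptide) and the
    33-mer/26-mer region peptides are not DQ epitopes and never contribute.
    """
    n = sum(
        1
        for o in occurrences
        if o.mismatches == 0
        and o.epitope_id in catalog
        and catalog[o.epitope_id].epitope_class in DQ25_CLASSES
    )
    return f"{panel.capitalize()}_{n}"


# ------------------------------------------------------------------ tables


def _abundance_columns(
    matrix: pd.DataFrame,
    groups: Mapping[str, list[str]],
    keep: Sequence[str],
) -> pd.DataFrame:
    """Sum matrix rows (amplicons) into columns keyed by group membership."""
    out = {}
    keep_set = set(keep)
    for key, amplicon_ids in groups.items():
        ids = [a for a in amplicon_ids if a in matrix.index and a in keep_set]
        out[key] = (
            matrix.loc[ids].sum(axis=0) if ids
            else pd.Series(0.0, index=matrix.columns)
        )
    return pd.DataFrame(out)


def _putative_ids(records: Sequence[AmpliconRecord], putative_only: bool) -> list[str]:
    return [
        r.id for r in records
        if not (putative_only and r.pseudogene)
    ]


def epitope_abundance(
    matrix: pd.DataFrame,
    occurrences: Mapping[str, Sequence[EpitopeOccurrence]],
    catalog: EpitopeCatalog,
    records: Sequence[AmpliconRecord],
    putative_only: bool = True,
    copy_weighted: bool = False,
) -> pd.DataFrame:
    """Genotype x epitope percent table (presence-based by default).

    ``matrix`` is an amplicon x genotype (or x sample) percent table.  Each
    DQ2.5 epitope and the p31-43 peptide gets the summed abundance of the
    amplicons containing at least one exact occurrence; with
    ``copy_weighted=True`` each amplicon instead contributes its abundance
    multiplied by its occurrence count (sensitivity mode).
    """
    wanted = [
        e.epitope_id
        for e in catalog
        if e.epitope_class in DQ25_CLASSES or e.epitope_class == "innate-peptide"
    ]
    keep = _putative_ids(records, putative_only)
    if copy_weighted:
        cols = {}
        keep_set = set(keep)
        for eid in wanted:
            acc = pd.Series(0.0, index=matrix.columns)
            for amp_id, occs in occurrences.items():
                if amp_id not in keep_set or amp_id not in matrix.index:
                    continue
                n = sum(1 for o in occs if o.epitope_id == eid and o.mismatches == 0)
                if n:
                    acc = acc + n * matrix.loc[amp_id]
            cols[eid] = acc
        return pd.DataFrame(cols)  # genotype x epitope
    groups = {
        eid: [
            amp_id
            for amp_id, occs in occurrences.items()
            if any(o.epitope_id == eid and o.mismatches == 0 for o in occs)
        ]
        for eid in wanted
    }
    return _abundance_columns(matrix, groups, keep)


def type_abundance(
    matrix: pd.DataFrame,
    type_labels: Mapping[str, str],
    records: Sequence[AmpliconRecord],
    putative_only: bool = True,
) -> pd.DataFrame:
    """Genotype x type percent table; types partition the amplicons."""
    groups: dict[str, list[str]] = defaultdict(list)
    for amp_id, label in type_labels.items():
        groups[label].append(amp_id)
    keep = _putative_ids(records, putative_only)
    ordered = sorted(groups, key=lambda t: (t.rsplit("_", 1)[0], int(t.rsplit("_", 1)[1])))
    return _abundance_columns(matrix, {t: groups[t] for t in ordered}, keep)


def variant_abundance(
    matrix: pd.DataFrame,
    occurrences: Mapping[str, Sequence[EpitopeOccurrence]],
    records: Sequence[AmpliconRecord],
    putative_only: bool = True,
) -> pd.DataFrame:
    """Genotype x (epitope, observed-variant) table for one-mismatch hits."""
    groups: dict[tuple[str, str], list[str]] = defaultdict(list)
    for amp_id, occs in occurrences.items():
        for o in occs:
            if o.mismatches == 1 and amp_id not in groups[(o.epitope_id, o.observed)]:
                groups[(o.epitope_id, o.observed)].append(amp_id)
    keep = _putative_ids(records, putative_only)
    df = _abundance_columns(matrix, groups, keep)
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["epitope_id", "observed"])
    return df


def variant_log2fc(
    variant: float | np.ndarray | pd.Series,
    canonical: float | np.ndarray | pd.Series,
    eps: float = LOG2FC_EPS,
) -> float | np.ndarray | pd.Series:
    """log2((v + eps) / (c + eps)) — the variant-vs-canonical fold change.

    The pseudocount (in percent, far below any reportable abundance) makes the
    degenerate 0/0 case return exactly 0.
    """
    v = np.asarray(variant, dtype=float)
    c = np.asarray(canonical, dtype=float)
    out = np.log2((v + eps) / (c + eps))
    if np.isscalar(variant) or np.ndim(variant) == 0:
        return float(out)
    if isinstance(variant, pd.Series):
        return pd.Series(out, index=variant.index)
    return out


def pseudogene_percent(n_pseudogenes: int, n_total: int, ndigits: int = 1) -> float:
    """Percent of amplicons with premature stops, at reporting precision."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round(100.0 * n_pseudogenes / n_total, ndigits)
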