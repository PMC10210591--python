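"""Primer trimming, non-redundant amplicon database, and annotation.

Amplicons are anchored by degenerate PCR primers (IUPAC codes allowed), so
primer matching expands ambiguity codes.  The database collapses exact
duplicates across per-sample denoised sets and optional reference panels,
assigns deterministic hash-based ids, and records full provenance.  Subgenome
annotation is done two ways, mirroring common practice for homoeologous gene
families: nearest reference by global-alignment identity, and peptide motif
lookup (with conflicting motif hits reported rather than resolved).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib.resources import files
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._align import global_identity
from ._seq import IUPAC, revcomp

__all__ = [
    "PrimerPair",
    "ALPHA_PRIMERS",
    "GAMMA_PRIMERS",
    "AmpliconRecord",
    "ReferenceSeq",
    "match_iupac",
    "trim_primers",
    "TrimRejected",
    "build_database",
    "assign_nearest_reference",
    "assign_subgenome_by_motif",
    "load_motif_table",
    "write_database",
]


@dataclass(frozen=True)
class PrimerPair:
    """Forward/reverse amplification primers in IUPAC notation."""

    forward: str
    reverse: str
    panel: str = "alpha"

    def __post_init__(self) -> None:
        for p in (self.forward, self.reverse):
            bad = set(p) - set(IUPAC)
            if bad:
                raise ValueError(f"invalid IUPAC codes {sorted(bad)} in {p!r}")


# The amplification primers for the two gliadin immunogenic complexes: the
# alpha pair brackets the first repetitive domain (p31-43 and 33-mer region);
# the gamma pair covers part of the N-terminal plus first repetitive domain
# and co-amplifies the homologous rye 40k-gamma-secalins.
ALPHA_PRIMERS = PrimerPair("GTTAGAGTTCCAGTGCCACAA", "GGTTGTTGTGGTTGCGRATA", "alpha")
GAMMA_PRIMERS = PrimerPair("GCCAATATRCAGGTCGACCC", "GGGTTCAWCTGTTGTTGTAG", "gamma")


@dataclass
class AmpliconRecord:
    """A primer-free amplicon with provenance and downstream annotations."""

    id: str
    sequence: str
    panel: str = "alpha"
    provenance: list[str] = field(default_factory=list)
    aggregate_size: int = 0
    frame: int | None = None
    pseudogene: bool | None = None
    subgenome: str = "unknown"
    type_label: str | None = None
    secalin: bool = False


@dataclass(frozen=True)
class ReferenceSeq:
    """A primer-free reference amplicon carrying curated annotations."""

    id: str
    sequence: str
    subgenome: str = "unknown"
    secalin: bool = False
    provenance: str = "reference-NCBI"


class TrimRejected(Exception):
    """Raised (or returned as reason) when a primer cannot be located."""


def amplicon_id(sequence: str, panel: str = "amp") -> str:
    return f"{panel[0]}amp_{hashlib.sha1(sequence.encode()).hexdigest()[:10]}"


# ------------------------------------------------------------ IUPAC matching


def _compile(pattern: str) -> list[frozenset]:
    try:
        return [IUPAC[c] for c in pattern]
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC code {exc.args[0]!r} in {pattern!r}")


def _mismatches(compiled: list[frozenset], text: str, limit: int) -> int:
    mm = 0
    for allowed, base in zip(compiled, text):
        if base not in allowed:
            mm += 1
            if mm > limit:
                break
    return mm


def match_iupac(pattern: str, text: str, max_mismatch: int = 0) -> list[int]:
    """All start positions where ``pattern`` matches ``text``.

    IUPAC ambiguity codes in the pattern count as matches for any of their
    expansion bases; up to ``max_mismatch`` residual mismatches are allowed.
    """
    if not pattern:
        raise ValueError("empty pattern")
    compiled = _compile(pattern)
    m = len(compiled)
    return [
        i
        for i in range(len(text) - m + 1)
        if _mismatches(compiled, text[i : i + m], max_mismatch) <= max_mismatch
    ]


# ------------------------------------------------------------ primer trimming


def _trim_oriented(
    seq: str, primers: PrimerPair, max_mismatch: int
) -> str | None:
    fwd = _compile(primers.forward)
    rev_rc = _compile(revcomp(primers.reverse))
    nf, nr = len(fwd), len(rev_rc)
    if len(seq) < nf + nr:
        return None
    if _mismatches(fwd, seq[:nf], max_mismatch) > max_mismatch:
        return None
    if _mismatches(rev_rc, seq[-nr:], max_mismatch) > max_mismatch:
        return None
    return seq[nf : len(seq) - nr]


def trim_primers(
    seq: str, primers: PrimerPair, max_mismatch: int = 2
) -> tuple[str | None, str]:
    """Strip both primers; returns ``(insert, reason)``.

    The read orientation is normalized first: if the forward primer is not at
    the 5' end, the reverse complement is tried.  ``insert`` is None when
    either primer is absent, with ``reason`` explaining which.
    """
    insert = _trim_oriented(seq, primers, max_mismatch)
    if insert is not None:
        return insert, "ok"
    insert = _trim_oriented(revcomp(seq), primers, max_mismatch)
    if insert is not None:
        return insert, "ok:revcomp"
    # diagnose on the forward orientation for the rejection log
    compiled = _compile(primers.forward)
    if (len(seq) >= len(compiled)
            and _mismatches(compiled, seq[: len(compiled)], max_mismatch)
            <= max_mismatch):
        return None, "reverse primer not found"
    return None, "forward primer not found"


# ------------------------------------------------------------ database build


def build_database(
    denoised: Mapping[str, Iterable[tuple[str, int]]],
    references: Sequence[ReferenceSeq] = (),
    panel: str = "alpha",
) -> list[AmpliconRecord]:
    """Pool primer-free denoised sequences across samples into unique records.

    Exact duplicates are collapsed; every contributing sample (and any
    duplicating reference) is listed in the record's provenance.  References
    that duplicate a denoised amplicon annotate it in place; novel reference
    sequences are appended as zero-abundance records.  Output order and ids
    are deterministic and independent of sample input order.
    """
    if not denoised and not references:
        raise ValueError("no input sequences")
    by_seq: dict[str, AmpliconRecord] = {}
    for sample_id in sorted(denoised):
        for seq, size in denoised[sample_id]:
            rec = by_seq.get(seq)
            if rec is None:
                rec = by_seq[seq] = AmpliconRecord(
                    id=amplicon_id(seq, panel), sequence=seq, panel=panel
                )
            rec.provenance.append(f"denoised:{sample_id}")
            rec.aggregate_size += size
    for ref in references:
        rec = by_seq.get(ref.sequence)
        if rec is None:
            rec = by_seq[ref.sequence] = AmpliconRecord(
                id=amplicon_id(ref.sequence, panel),
                sequence=ref.sequence,
                panel=panel,
            )
        rec.provenance.append(f"{ref.provenance}:{ref.id}")
        if ref.subgenome != "unknown":
            rec.subgenome = ref.subgenome
        rec.secalin = rec.secalin or ref.secalin
    if not by_seq:
        raise ValueError("no input sequences")
    return sorted(by_seq.values(), key=lambda r: (-r.aggregate_size, r.sequence))


# --------------------------------------------------------------- annotation


def assign_nearest_reference(
    record: AmpliconRecord | str, references: Sequence[ReferenceSeq]
) -> tuple[str, float, bool]:
    """Best reference by global-alignment identity.

    Returns ``(reference_id, identity, ambiguous)``; ``ambiguous`` is set when
    two references tie for the best identity.  This replaces tree-based
    proximity assignment with a directly testable criterion of the same
    intent.
    """
    if not references:
        raise ValueError("empty reference set")
    seq = record.sequence if isinstance(record, AmpliconRecord) else record
    scored = sorted(
        ((global_identity(seq, ref.sequence)[0], ref.id) for ref in references),
        key=lambda t: (-t[0], t[1]),
    )
    best_ident, best_id = scored[0]
    ambiguous = len(scored) > 1 and abs(scored[1][0] - best_ident) < 1e-12
    return best_id, best_ident, ambiguous


def load_motif_table(path=None) -> dict[str, str]:
    """Peptide motif -> subgenome mapping (default: packaged illustrative table)."""
    if path is None:
        path = files("gliascan.data") / "subgenome_motifs.tsv"
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    table = dict(zip(df["motif"], df["subgenome"]))
    if not table:
        raise ValueError("empty motif table")
    return table


def assign_subgenome_by_motif(
    peptide: str, motif_table: Mapping[str, str]
) -> tuple[str, list[str]]:
    """Assign a subgenome from peptide motifs.

    A unique motif class hit assigns that subgenome; zero hits or hits from
    several classes give ``"unknown"`` (the conflicting motifs are returned so
    inhomogeneous assignments can be reported rather than silently dropped).
    """
    if not motif_table:
        raise ValueError("empty motif table")
    hits = sorted({sg for motif, sg in motif_table.items() if motif in peptide})
    if len(hits) == 1:
        return hits[0], []
    if len(hits) > 1:
        return "unknown", [m for m in motif_table if m in peptide]
    return "unknown", []


def write_database(records: Sequence[AmpliconRecord], fasta_path, tsv_path) -> None:
    """FASTA plus TSV sidecar with provenance and annotations."""
    with open(fasta_path, "w") as fh:
        for r in records:
            desc = (
                f"panel={r.panel} size={r.aggregate_size} frame={r.frame} "
                f"pseudogene={r.pseudogene} subgenome={r.subgenome} "
                f"type={r.type_label} secalin={r.secalin}"
            )
            fh.write(f">{r.id} {desc}\n{r.sequence}\n")
    rows = [
        {
            "id": r.id,
            "panel": r.panel,
            "aggregate_size": r.aggregate_size,
            "frame": r.frame,
            "pseudogene": r.pseudogene,
            "subgenome": r.subgenome,
            "type": r.type_label,
            "secalin": r.secalin,
            "provenance": ";".join(r.provenance),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
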