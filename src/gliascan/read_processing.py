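"""Paired-read merging, expected-error filtering, dereplication and denoising.

This reimplements the classic amplicon preprocessing cascade:

1. :func:`merge_pairs` — best ungapped overlap between read 1 and the reverse
   complement of read 2, with posterior base qualities at the overlap;
2. :func:`quality_filter` — discard merged reads whose expected number of
   errors, ``E = sum(10^(-Q/10))``, exceeds a threshold;
3. :func:`dereplicate` — exact full-length collapse with size annotation;
4. :func:`denoise` — greedy abundance-ordered centroid clustering in which a
   unique sequence is absorbed into a more abundant centroid at edit distance
   ``d`` when its abundance skew does not exceed ``beta(d) = 1/2^(alpha*d+1)``.

Denoising is applied per sample; pooling across samples is done explicitly by
the database builder.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np

from ._seq import revcomp

__all__ = [
    "MergedRead",
    "UniqueSequence",
    "Centroid",
    "DenoiseParams",
    "merge_pairs",
    "expected_errors",
    "quality_filter",
    "dereplicate",
    "denoise",
    "beta_threshold",
    "write_denoised_fasta",
]

_MAX_Q = 41
_EE_SLACK = 1e-9  # float slack so e.g. 100 bases at Q20 give E == 1.0 exactly


@dataclass(frozen=True)
class MergedRead:
    sequence: str
    qualities: tuple[int, ...]
    sample_id: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError("sequence and qualities differ in length")


@dataclass(frozen=True)
class UniqueSequence:
    sequence: str
    size: int
    sample_id: str = ""


@dataclass
class Centroid:
    """A denoised amplicon: founding unique plus everything absorbed into it."""

    sequence: str
    size: int                 # size of the founding unique sequence
    aggregate_size: int       # founding size + absorbed sizes
    members: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class DenoiseParams:
    """Denoiser knobs (published defaults of the zero-radius OTU method)."""

    alpha: float = 2.0
    minsize: int = 8
    max_dist: int = 10  # edit-distance cap; beyond it nothing is absorbable

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.minsize < 1:
            raise ValueError("minsize must be >= 1")


# ----------------------------------------------------------------- merging


def _candidate_shifts(r1: str, r2rc: str, min_overlap: int) -> list[int]:
    """Seed-based candidate placements of r2rc along r1 (r1-anchored)."""
    shifts: set[int] = set()
    seed_len = 16
    n2 = len(r2rc)
    for seed_pos in range(0, max(1, n2 - seed_len + 1), 40):
        seed = r2rc[seed_pos : seed_pos + seed_len]
        if len(seed) < seed_len:
            break
        start = 0
        while True:
            hit = r1.find(seed, start)
            if hit < 0:
                break
            shifts.add(hit - seed_pos)
            start = hit + 1
    return sorted(s for s in shifts if s >= 0 and len(r1) - s >= min_overlap)


def merge_pairs(
    r1_seq: str,
    r1_qual: Sequence[int],
    r2_seq: str,
    r2_qual: Sequence[int],
    min_overlap: int = 16,
    max_diffs: int = 5,
    sample_id: str = "",
) -> MergedRead | None:
    """Merge a read pair, or return None when no admissible overlap exists.

    Read 2 is reverse-complemented, then every ungapped placement with overlap
    >= ``min_overlap`` and <= ``max_diffs`` mismatches is considered; the one
    with the fewest mismatches (longest overlap on ties) wins.  At overlap
    positions that agree the posterior quality is ``min(Q1+Q2, 41)``; where
    they disagree the higher-quality base is kept with quality ``|Q1-Q2|``.
    """
    r2rc = revcomp(r2_seq)
    q2 = np.asarray(r2_qual[::-1], dtype=np.int16)
    q1 = np.asarray(r1_qual, dtype=np.int16)
    a1 = np.frombuffer(r1_seq.encode(), dtype=np.uint8)
    a2 = np.frombuffer(r2rc.encode(), dtype=np.uint8)
    n1, n2 = len(a1), len(a2)

    def _scan(shifts: Iterable[int]) -> tuple[int, int, int] | None:
        best: tuple[int, int, int] | None = None  # (diffs, -overlap, shift)
        for shift in shifts:
            overlap = min(n1 - shift, n2)
            if overlap < min_overlap:
                continue
            diffs = int((a1[shift : shift + overlap] != a2[:overlap]).sum())
            if diffs > max_diffs:
                continue
            key = (diffs, -overlap, shift)
            if best is None or key < best:
                best = key
        return best

    # seeded candidates first; exhaustive fallback when seeds miss
    best = _scan(_candidate_shifts(r1_seq, r2rc, min_overlap))
    if best is None:
        best = _scan(range(0, n1 - min_overlap + 1))
    if best is None:
        return None

    _, neg_overlap, shift = best
    overlap = -neg_overlap
    s1 = a1[shift : shift + overlap]
    s2 = a2[:overlap]
    o_q1 = q1[shift : shift + overlap]
    o_q2 = q2[:overlap]
    agree = s1 == s2
    cons = np.where(agree | (o_q1 >= o_q2), s1, s2)
    qual = np.where(
        agree,
        np.minimum(o_q1 + o_q2, _MAX_Q),
        np.abs(o_q1 - o_q2),
    )

    merged_seq = r1_seq[:shift] + cons.tobytes().decode() + r2rc[overlap:]
    merged_q = np.concatenate([q1[:shift], qual, q2[overlap:]])
    return MergedRead(merged_seq, tuple(int(q) for q in merged_q), sample_id)


# ---------------------------------------------------------------- filtering


def expected_errors(qualities: Sequence[int]) -> float:
    """Expected number of errors implied by Phred qualities."""
    if len(qualities) == 0:
        return 0.0
    q = np.asarray(qualities, dtype=float)
    return float(np.power(10.0, -q / 10.0).sum())


def quality_filter(read: MergedRead | Sequence[int], max_ee: float = 1.0) -> bool:
    """True when the read's expected error count is within ``max_ee``."""
    quals = read.qualities if isinstance(read, MergedRead) else read
    return expected_errors(quals) <= max_ee + _EE_SLACK


# ------------------------------------------------------------ dereplication


def dereplicate(
    sequences: Iterable[str] | Mapping[str, int], sample_id: str = ""
) -> list[UniqueSequence]:
    """Collapse exact duplicates; sort by size descending, then sequence."""
    counts = (
        Counter(dict(sequences))
        if isinstance(sequences, Mapping)
        else Counter(sequences)
    )
    return [
        UniqueSequence(seq, size, sample_id)
        for seq, size in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


# ----------------------------------------------------------------- denoise


def beta_threshold(d: int, alpha: float) -> float:
    """Maximum abundance skew at which a distance-``d`` variant is absorbed."""
    return 1.0 / 2.0 ** (alpha * d + 1.0)


def denoise(
    uniques: Sequence[UniqueSequence], params: DenoiseParams | None = None
) -> list[Centroid]:
    """Greedy abundance-ordered centroid clustering of dereplicated reads.

    Uniques are visited in decreasing size.  Each is absorbed into the
    qualifying centroid with the smallest edit distance (largest centroid on
    ties); a unique with no qualifying centroid founds a new centroid if its
    size reaches ``minsize``, otherwise it is discarded.
    """
    params = params or DenoiseParams()
    ordered = sorted(uniques, key=lambda u: (-u.size, u.sequence))
    centroids: list[Centroid] = []
    for u in ordered:
        best: tuple[int, int, int] | None = None  # (d, -size, index)
        for idx, c in enumerate(centroids):
            res = edlib.align(
                u.sequence, c.sequence, mode="NW", task="distance",
                k=params.max_dist,
            )
            d = res["editDistance"]
            if d <= 0:  # -1: beyond cap; 0 impossible among uniques
                continue
            if u.size / c.size <= beta_threshold(d, params.alpha):
                key = (d, -c.size, idx)
                if best is None or key < best:
                    best = key
        if best is not None:
            c = centroids[best[2]]
            c.aggregate_size += u.size
            c.members.append(u.sequence)
        elif u.size >= params.minsize:
            centroids.append(Centroid(u.sequence, u.size, u.size, []))
        # else: discarded low-abundance singleton-like unique
    return centroids


def write_denoised_fasta(centroids: Sequence[Centroid], path) -> None:
    """Write centroids as FASTA with classic ``;size=N`` annotations."""
    with open(path, "w") as fh:
        for i, c in enumerate(centroids, start=1):
            fh.write(f">centroid{i};size={c.aggregate_size}\n{c.sequence}\n")
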