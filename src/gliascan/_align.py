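"""Global alignment identity.

Needleman–Wunsch with match +1 / mismatch -1 / gap -2 and end gaps penalized
(full global mode); identity is matches divided by alignment columns.  The
dynamic programming is delegated to :class:`Bio.Align.PairwiseAligner`.
"""

from __future__ import annotations

from functools import lru_cache

from Bio import Align

__all__ = ["global_identity"]


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(mode="global")
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


_ALIGNER = _make_aligner()


@lru_cache(maxsize=65536)
def global_identity(a: str, b: str) -> tuple[float, int]:
    """Return ``(identity, columns)`` for the best global alignment of a and b.

    identity = matches / alignment columns (gap columns included), so identical
    sequences give 1.0 and a single substitution over L aligned columns gives
    (L-1)/L.
    """
    if a == b:
        return 1.0, len(a)
    alignment = _ALIGNER.align(a, b)[0]
    counts = alignment.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / columns, columns
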