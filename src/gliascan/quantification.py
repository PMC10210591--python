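"""Read-to-database mapping, normalization, prevalence filter, replicates.

Reads (in practice their dereplicated uniques, which is equivalent and much
cheaper) are assigned to the best database amplicon at >= 99% global-alignment
identity; per-sample counts are normalized to percent of mapped reads; rare
amplicons are removed with a prevalence filter; and biological replicates are
averaged per genotype.

The prevalence filter retains an amplicon when it reaches the abundance
threshold in at least ``min_samples`` samples — the standard low-abundance
filter.  The literal alternative reading ("discard if below the threshold in
at least N samples") is selectable via ``mode="discard_literal"`` but is so
strict on panels with many samples that it removes almost everything real.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

from .amplicon_db import AmpliconRecord
from .read_processing import UniqueSequence

__all__ = [
    "AbundanceMatrix",
    "map_reads",
    "normalize",
    "prevalence_filter",
    "average_replicates",
]

_CIGAR_OP = re.compile(r"(\d+)([=XIDM])")


@dataclass
class AbundanceMatrix:
    """Amplicon x sample (or x genotype) table with a processing-stage tag."""

    values: pd.DataFrame
    stage: str  # raw_counts | normalized | filtered | genotype_mean
    flags: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# stage={self.stage}")
            for k, v in self.flags.items():
                fh.write(f" {k}={v}")
            fh.write("\n")
            self.values.to_csv(fh, sep="\t")


def _alignment_identity(query: str, target: str, k: int) -> float:
    """Identity = matches / alignment columns for the min-edit NW alignment."""
    res = edlib.align(query, target, mode="NW", task="path", k=k)
    if res["editDistance"] < 0:
        return 0.0
    columns = sum(int(n) for n, _ in _CIGAR_OP.findall(res["cigar"]))
    return (columns - res["editDistance"]) / columns


def map_reads(
    uniques_by_sample: Mapping[str, Sequence[UniqueSequence | tuple[str, int]]],
    database: Sequence[AmpliconRecord],
    min_identity: float = 0.99,
) -> tuple[pd.DataFrame, pd.Series]:
    """Assign unique read sequences to database amplicons.

    Each unique sequence goes to the best-identity amplicon with identity >=
    ``min_identity``; ties are broken by larger aggregate size, then
    lexicographic id.  Returns ``(counts, unmapped)`` where counts is an
    amplicon x sample DataFrame and unmapped counts reads below threshold.
    """
    if not database:
        raise ValueError("empty database")
    exact = {r.sequence: r.id for r in database}
    ranked = sorted(database, key=lambda r: (-r.aggregate_size, r.id))
    samples = sorted(uniques_by_sample)
    counts = pd.DataFrame(
        0, index=[r.id for r in database], columns=samples, dtype=int
    )
    unmapped = pd.Series(0, index=samples, dtype=int)
    max_len = max(len(r.sequence) for r in database)
    k = int(np.ceil((1.0 - min_identity) * max_len * 2)) + 2
    assign_cache: dict[str, str | None] = {}
    for sample in samples:
        for u in uniques_by_sample[sample]:
            seq, size = (u.sequence, u.size) if isinstance(u, UniqueSequence) else u
            hit = exact.get(seq)
            if hit is None:
                if seq in assign_cache:
                    hit = assign_cache[seq]
                else:
                    best_ident, hit = 0.0, None
                    for rec in ranked:
                        ident = _alignment_identity(seq, rec.sequence, k)
                        # strict > plus ranked order: ties resolve to the
                        # larger aggregate_size, then lexicographic id
                        if ident >= min_identity and ident > best_ident:
                            best_ident, hit = ident, rec.id
                    assign_cache[seq] = hit
            if hit is None:
                unmapped[sample] += size
            else:
                counts.loc[hit, sample] += size
    return counts, unmapped


def normalize(counts: pd.DataFrame) -> AbundanceMatrix:
    """Column-wise percent of mapped reads; all-zero samples stay zero."""
    if (counts.values < 0).any():
        raise ValueError("negative counts")
    totals = counts.sum(axis=0)
    zero_cols = totals[totals == 0].index.tolist()
    safe = totals.replace(0, 1)
    values = 100.0 * counts.astype(float) / safe
    return AbundanceMatrix(values, "normalized", {"zero_samples": zero_cols})


def prevalence_filter(
    matrix: AbundanceMatrix,
    min_abund: float = 0.25,
    min_samples: int = 4,
    mode: str = "retain",
    renormalize: bool = True,
) -> tuple[AbundanceMatrix, pd.DataFrame]:
    """Remove low-prevalence amplicons from a normalized matrix.

    ``mode="retain"`` (default): keep an amplicon iff it reaches
    ``min_abund`` percent in at least ``min_samples`` samples.
    ``mode="discard_literal"``: drop an amplicon iff it is below ``min_abund``
    in at least ``min_samples`` samples.
    Retained columns are re-normalized to 100 unless ``renormalize=False``.
    """
    if matrix.stage != "normalized":
        raise ValueError("prevalence filter expects a normalized matrix")
    values = matrix.values
    if min_samples > values.shape[1]:
        raise ValueError(
            f"min_samples={min_samples} exceeds sample count {values.shape[1]}"
        )
    n_hits = (values >= min_abund).sum(axis=1)
    if mode == "retain":
        keep = n_hits >= min_samples if min_abund > 0 else pd.Series(True, index=values.index)
    elif mode == "discard_literal":
        keep = (values < min_abund).sum(axis=1) < min_samples
    else:
        raise ValueError(f"unknown mode {mode!r}")
    kept = values.loc[keep]
    discarded = pd.DataFrame(
        {
            "amplicon_id": values.index[~keep],
            "reason": [
                f"<{min_abund}% in all but {int(h)} samples (mode={mode})"
                for h in n_hits[~keep]
            ],
        }
    )
    if renormalize:
        totals = kept.sum(axis=0).replace(0, 1)
        kept = 100.0 * kept / totals
    out = AbundanceMatrix(
        kept,
        "filtered",
        {"min_abund": min_abund, "min_samples": min_samples,
         "mode": mode, "renormalized": renormalize},
    )
    return out, discarded


def average_replicates(
    matrix: AbundanceMatrix, sample_to_genotype: Mapping[str, str]
) -> AbundanceMatrix:
    """Arithmetic mean of replicate columns per genotype (no re-normalization).

    Means of percentages are reported as-is, matching the convention of
    averaging the two biological replicates per genotype.
    """
    missing = [s for s in matrix.values.columns if s not in sample_to_genotype]
    if missing:
        raise KeyError(f"samples without genotype assignment: {missing}")
    grouped = matrix.values.T.groupby(
        [sample_to_genotype[s] for s in matrix.values.columns]
    ).mean().T
    return AbundanceMatrix(grouped, "genotype_mean", dict(matrix.flags))
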