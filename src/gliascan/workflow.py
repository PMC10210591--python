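"""End-to-end amplicon pipeline: FASTQ pairs to abundance and epitope tables.

Per sample: merge pairs, expected-error filter, dereplicate, denoise.  Across
samples: trim primers from denoised centroids, pool into the non-redundant
database (optionally augmented with annotated references), infer the panel
reading frame, annotate pseudogenes / C->T stops / subgenomes / epitope
occurrences / types, map each sample's (primer-trimmed) uniques to the
database at 99% identity, normalize, prevalence-filter, average replicates,
and compute epitope, type and one-mismatch-variant abundance tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .amplicon_db import (
    ALPHA_PRIMERS,
    AmpliconRecord,
    PrimerPair,
    ReferenceSeq,
    assign_subgenome_by_motif,
    build_database,
    trim_primers,
)
from .catalog import EpitopeCatalog
from .epitope_engine import (
    classify_ct_stop,
    classify_type,
    epitope_abundance,
    find_epitopes,
    infer_panel_frame,
    translate,
    type_abundance,
    variant_abundance,
)
from .quantification import (
    AbundanceMatrix,
    average_replicates,
    map_reads,
    normalize,
    prevalence_filter,
)
from .read_processing import (
    Centroid,
    DenoiseParams,
    denoise,
    dereplicate,
    merge_pairs,
    quality_filter,
)

__all__ = ["PipelineParams", "PipelineResult", "process_sample", "run_pipeline"]


@dataclass(frozen=True)
class PipelineParams:
    primers: PrimerPair = ALPHA_PRIMERS
    panel: str = "alpha"
    min_overlap: int = 16
    max_diffs: int = 5
    max_ee: float = 1.0
    denoise: DenoiseParams = field(default_factory=DenoiseParams)
    primer_max_mismatch: int = 2
    min_identity: float = 0.99
    min_abund: float = 0.25
    min_samples: int = 4
    filter_mode: str = "retain"
    scan_variants: bool | None = None  # default: alpha panel only
    frame: int | None = None           # override inferred frame


@dataclass
class PipelineResult:
    database: list[AmpliconRecord]
    frame: int
    counts: pd.DataFrame
    unmapped: pd.Series
    normalized: AbundanceMatrix
    filtered: AbundanceMatrix
    genotype_mean: AbundanceMatrix
    occurrences: dict
    ct_stops: dict
    epitope_abundance: pd.DataFrame
    type_abundance: pd.DataFrame
    variant_abundance: pd.DataFrame | None
    discarded: pd.DataFrame
    sample_log: pd.DataFrame


def process_sample(
    r1_path,
    r2_path,
    sample_id: str,
    params: PipelineParams,
    merge_cache: dict | None = None,
) -> tuple[list, list[Centroid], dict]:
    """Merge, filter, dereplicate and denoise one sample's read pairs.

    Returns ``(uniques, centroids, log)``.  A shared ``merge_cache`` lets
    identical read pairs (ubiquitous in amplicon data) merge only once.
    """
    cache = merge_cache if merge_cache is not None else {}
    ee_cache: dict[str, bool] = {}
    retained: list[str] = []
    n_pairs = n_merged = 0
    with open(r1_path) as fh1, open(r2_path) as fh2:
        for (t1, s1, q1), (t2, s2, q2) in zip(
            FastqGeneralIterator(fh1), FastqGeneralIterator(fh2)
        ):
            n_pairs += 1
            key = (s1, q1, s2, q2)
            hit = cache.get(key)
            if hit is None and key not in cache:
                merged = merge_pairs(
                    s1,
                    [ord(c) - 33 for c in q1],
                    s2,
                    [ord(c) - 33 for c in q2],
                    min_overlap=params.min_overlap,
                    max_diffs=params.max_diffs,
                )
                if merged is None:
                    cache[key] = None
                else:
                    keep = quality_filter(merged, params.max_ee)
                    cache[key] = (merged.sequence, keep)
                hit = cache[key]
            if hit is None:
                continue
            n_merged += 1
            seq, keep = hit
            if keep:
                retained.append(seq)
    uniques = dereplicate(retained, sample_id)
    centroids = denoise(uniques, params.denoise)
    log = {
        "sample_id": sample_id,
        "pairs": n_pairs,
        "merged": n_merged,
        "retained": len(retained),
        "uniques": len(uniques),
        "centroids": len(centroids),
    }
    return uniques, centroids, log


def run_pipeline(
    sample_sheet: pd.DataFrame,
    params: PipelineParams | None = None,
    catalog: EpitopeCatalog | None = None,
    references: Sequence[ReferenceSeq] = (),
    motif_table: Mapping[str, str] | None = None,
) -> PipelineResult:
    """Run the full analysis for the samples listed in ``sample_sheet``.

    The sheet needs columns ``sample_id, genotype, fastq_r1, fastq_r2``.
    """
    params = params or PipelineParams()
    catalog = catalog or EpitopeCatalog.default()

    merge_cache: dict = {}
    trim_cache: dict[str, str | None] = {}

    def trimmed(seq: str) -> str | None:
        if seq not in trim_cache:
            insert, _reason = trim_primers(seq, params.primers, params.primer_max_mismatch)
            trim_cache[seq] = insert
        return trim_cache[seq]

    uniques_by_sample: dict[str, list] = {}
    denoised_by_sample: dict[str, list[tuple[str, int]]] = {}
    logs = []
    for row in sample_sheet.itertuples(index=False):
        uniques, centroids, log = process_sample(
            row.fastq_r1, row.fastq_r2, row.sample_id, params, merge_cache
        )
        trimmed_centroids = []
        n_rejected = 0
        for c in centroids:
            insert = trimmed(c.sequence)
            if insert is None:
                n_rejected += 1
            else:
                trimmed_centroids.append((insert, c.aggregate_size))
        log["primer_rejected_centroids"] = n_rejected
        logs.append(log)
        denoised_by_sample[row.sample_id] = trimmed_centroids
        trimmed_uniques = []
        for u in uniques:
            insert = trimmed(u.sequence)
            if insert is not None:
                trimmed_uniques.append((insert, u.size))
        uniques_by_sample[row.sample_id] = trimmed_uniques

    database = build_database(denoised_by_sample, references, params.panel)

    frame = params.frame if params.frame is not None else infer_panel_frame(database)
    occurrences = {}
    ct_stops = {}
    for rec in database:
        rec.frame = frame
        peptide = translate(rec.sequence, frame)
        rec.pseudogene = "*" in peptide
        ct_stops[rec.id] = classify_ct_stop(rec.sequence, frame)
        occs = find_epitopes(peptide, catalog, max_mismatch=0, amplicon_id=rec.id)
        occurrences[rec.id] = occs
        rec.type_label = classify_type(occs, catalog, params.panel)
        if motif_table is not None and rec.subgenome == "unknown":
            rec.subgenome, _conflicts = assign_subgenome_by_motif(peptide, motif_table)

    scan_variants = (
        params.scan_variants
        if params.scan_variants is not None
        else params.panel == "alpha"
    )
    variant_occurrences = None
    if scan_variants:
        variant_occurrences = {
            rec.id: find_epitopes(
                translate(rec.sequence, frame), catalog, max_mismatch=1,
                amplicon_id=rec.id,
            )
            for rec in database
        }

    counts, unmapped = map_reads(uniques_by_sample, database, params.min_identity)
    normalized = normalize(counts)
    filtered, discarded = prevalence_filter(
        normalized, params.min_abund, params.min_samples, params.filter_mode
    )
    sample_to_genotype = dict(
        zip(sample_sheet["sample_id"], sample_sheet["genotype"])
    )
    genotype_mean = average_replicates(filtered, sample_to_genotype)

    epi_table = epitope_abundance(
        genotype_mean.values, occurrences, catalog, database, putative_only=True
    )
    typ_table = type_abundance(
        genotype_mean.values, {r.id: r.type_label for r in database}, database,
        putative_only=True,
    )
    var_table = None
    if scan_variants:
        var_table = variant_abundance(
            genotype_mean.values, variant_occurrences, database, putative_only=True
        )

    return PipelineResult(
        database=database,
        frame=frame,
        counts=counts,
        unmapped=unmapped,
        normalized=normalized,
        filtered=filtered,
        genotype_mean=genotype_mean,
        occurrences=occurrences,
        ct_stops=ct_stops,
        epitope_abundance=epi_table,
        type_abundance=typ_table,
        variant_abundance=var_table,
        discarded=discarded,
        sample_log=pd.DataFrame(logs),
    )


def write_results(result: PipelineResult, out_dir) -> None:
    """Dump the pipeline tables as TSV under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from .amplicon_db import write_database

    write_database(result.database, out / "database.fasta", out / "database.tsv")
    result.counts.to_csv(out / "counts.tsv", sep="\t")
    result.normalized.to_tsv(out / "abundance_normalized.tsv")
    result.filtered.to_tsv(out / "abundance_filtered.tsv")
    result.genotype_mean.to_tsv(out / "abundance_genotype_mean.tsv")
    result.epitope_abundance.to_csv(out / "epitope_abundance.tsv", sep="\t")
    result.type_abundance.to_csv(out / "type_abundance.tsv", sep="\t")
    if result.variant_abundance is not None:
        result.variant_abundance.to_csv(out / "variant_abundance.tsv", sep="\t")
    result.discarded.to_csv(out / "discarded_amplicons.tsv", sep="\t", index=False)
    result.sample_log.to_csv(out / "sample_log.tsv", sep="\t", index=False)
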