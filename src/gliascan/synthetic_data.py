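"""Synthetic gliadin-like amplicon panels, genotype profiles, and reads.

The generator emulates the statistical structure of a prolamin amplicon
sequencing study without any plant material:

* a panel of repetitive Q/P-rich amplicons with celiac-disease epitopes
  planted at known positions (tandem-overlapping when an epitope's
  self-overlap period allows it, as in the natural 33-mer repeat);
* pseudogenized copies carrying a premature stop created by the canonical
  C->T transition in a glutamine codon (CAA/CAG -> TAA/TAG);
* secalin-like amplicons restricted to genotypes carrying the rye
  translocation, and D-subgenome amplicons absent from the tetraploid-derived
  classes (durum, tritordeum);
* per-genotype amplicon proportions drawn from a Dirichlet over the class'
  allowed amplicons, with two biological replicates per genotype drawn
  multinomially from the same proportions;
* paired-end reads with primer sequences, uniform substitution errors, and
  two-level Phred qualities (high for correct bases, low at error positions).

Ground truth — the panel, all epitope occurrences the scanner itself finds
(planted plus incidental), the proportion matrix, and the expected epitope /
type abundance tables — is returned alongside, so every downstream stage is
testable by recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

from ._seq import IUPAC, revcomp
from .amplicon_db import ALPHA_PRIMERS, AmpliconRecord, PrimerPair, amplicon_id
from .catalog import EpitopeCatalog
from .epitope_engine import (
    EpitopeOccurrence,
    classify_type,
    epitope_abundance,
    find_epitopes,
    translate,
    type_abundance,
)

__all__ = [
    "SynthConfig",
    "SynthTruth",
    "InfeasiblePlanError",
    "generate_panel",
    "generate_profiles",
    "simulate_reads",
    "generate_dataset",
    "simulate_monotone_abundance",
]

#: genotype classes and their secalin / D-subgenome permissions
CLASSES = {
    "bread_wheat": {"secalin": False, "subgenome_d": True, "species": "bread wheat"},
    "bread_wheat_translocation": {
        "secalin": True, "subgenome_d": True, "species": "bread wheat"},
    "durum": {"secalin": False, "subgenome_d": False, "species": "durum wheat"},
    "tritordeum": {"secalin": False, "subgenome_d": False, "species": "tritordeum"},
}

_CLASS_PREFIX = {
    "bread_wheat": "BWN",
    "bread_wheat_translocation": "BWY",
    "durum": "DUR",
    "tritordeum": "TRI",
}

# Q/P-rich backbone tiles with interrupting residues (N/H/S/T) so that
# incidental epitope matches are rare but remain possible; whatever the
# scanner finds in the finished amplicon — planted or incidental — is truth.
_TILES = ("QPSNQHQPT", "SQHNPQTLS", "NPQHSQTQP")

_MOTIF_BY_SUBGENOME = {"A": "PQQQVPQ", "B": "PQQLVPQ", "D": "PQQSVPQ"}

_CODON_CHOICES = {
    "A": ["GCT", "GCC", "GCA"], "C": ["TGT", "TGC"], "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"], "F": ["TTT", "TTC"], "G": ["GGT", "GGC", "GGA"],
    "H": ["CAT", "CAC"], "I": ["ATT", "ATC", "ATA"], "K": ["AAA", "AAG"],
    "L": ["CTT", "CTC", "CTA", "CTG", "TTA", "TTG"], "M": ["ATG"],
    "N": ["AAT", "AAC"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"], "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "AGT", "AGC"], "T": ["ACT", "ACC", "ACA"],
    "V": ["GTT", "GTC", "GTA", "GTG"], "W": ["TGG"], "Y": ["TAT", "TAC"],
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class InfeasiblePlanError(ValueError):
    """The epitope plan does not fit in the amplicon sequence capacity."""


@dataclass(frozen=True)
class SynthConfig:
    """Study-design parameters of the synthetic dataset.

    The defaults are the package's standing model of a desk-scale study: 12
    genotypes in the four genotype classes with two biological replicates, a
    20-amplicon panel within the alpha-panel length range, a quarter of
    non-secalin amplicons pseudogenized, Dirichlet(1) genotype profiles, and
    50k read pairs of 2x280 bp per sample at a 1e-3 substitution error rate.
    """

    seed: int = 0
    n_genotypes_per_class: Mapping[str, int] = field(
        default_factory=lambda: {
            "bread_wheat": 5,
            "bread_wheat_translocation": 3,
            "durum": 2,
            "tritordeum": 2,
        }
    )
    panel_size: int = 20
    amplicon_length_range: tuple[int, int] = (201, 279)
    epitope_plan: Sequence[Sequence[tuple[str, int]]] | None = None
    pseudogene_prob: float = 0.25
    secalin_fraction: float = 0.15
    dirichlet_alpha: float = 1.0
    reads_per_sample: int = 50_000
    per_base_error: float = 0.001
    read_length: int = 280
    overlap_min: int = 16
    frame_offset: int = 0
    primers: PrimerPair = ALPHA_PRIMERS
    panel: str = "alpha"

    def __post_init__(self) -> None:
        for name in ("pseudogene_prob", "secalin_fraction", "per_base_error"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        lo, hi = self.amplicon_length_range
        if not (201 <= lo <= hi <= 507):
            raise ValueError("amplicon_length_range must lie within [201, 507]")
        if self.dirichlet_alpha <= 0:
            raise ValueError("dirichlet_alpha must be positive")
        if self.frame_offset not in (0, 1, 2):
            raise ValueError("frame_offset must be 0, 1 or 2")
        full_max = hi + len(self.primers.forward) + len(self.primers.reverse)
        if 2 * self.read_length < full_max + self.overlap_min:
            raise ValueError(
                "read_length x 2 must cover the longest amplicon plus overlap_min"
            )
        unknown = set(self.n_genotypes_per_class) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown genotype classes: {sorted(unknown)}")


@dataclass
class SynthTruth:
    """Planted panel plus everything needed for recovery tests."""

    panel: list[AmpliconRecord]
    occurrences: dict[str, list[EpitopeOccurrence]]
    type_labels: dict[str, str]
    full_sequences: dict[str, str]  # primer-flanked amplicon per record id
    proportions: pd.DataFrame = None  # genotype x amplicon simplex rows
    genotype_classes: pd.Series = None
    expected_epitope_abundance: pd.DataFrame = None
    expected_type_abundance: pd.DataFrame = None
    realized_counts: pd.DataFrame = None  # amplicon x sample multinomial draws

    def write_tables(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.proportions.to_csv(out / "truth_proportions.tsv", sep="\t")
        self.expected_epitope_abundance.to_csv(
            out / "truth_epitope_abundance.tsv", sep="\t"
        )
        self.expected_type_abundance.to_csv(
            out / "truth_type_abundance.tsv", sep="\t"
        )
        with open(out / "truth_panel.fasta", "w") as fh:
            for rec in self.panel:
                fh.write(
                    f">{rec.id} frame={rec.frame} pseudogene={rec.pseudogene} "
                    f"subgenome={rec.subgenome} secalin={rec.secalin} "
                    f"type={rec.type_label}\n{rec.sequence}\n"
                )


# ------------------------------------------------------------------- panel


def _self_overlap_shift(peptide: str) -> int:
    """Tandem-planting shift: length minus the longest border (suffix==prefix)."""
    n = len(peptide)
    for border in range(n - 1, 0, -1):
        if peptide[:border] == peptide[n - border:]:
            return n - border
    return n


def _tandem_block(peptide: str, copies: int) -> str:
    """``copies`` occurrences, overlapped at the peptide's self-overlap period."""
    shift = _self_overlap_shift(peptide)
    return peptide[:shift] * (copies - 1) + peptide


def _place_blocks(
    length: int, blocks: list[str], rng: np.random.Generator
) -> list[tuple[int, str]]:
    """Place blocks at non-overlapping positions; raise when they cannot fit."""
    if sum(len(b) for b in blocks) > length:
        raise InfeasiblePlanError(
            f"plan needs {sum(len(b) for b in blocks)} residues, capacity {length}"
        )
    placed: list[tuple[int, str]] = []

    def overlaps(start: int, m: int) -> bool:
        return any(start < p + len(b) and p < start + m for p, b in placed)

    for block in sorted(blocks, key=len, reverse=True):
        m = len(block)
        spot = None
        for _ in range(200):
            cand = int(rng.integers(0, length - m + 1))
            if not overlaps(cand, m):
                spot = cand
                break
        if spot is None:  # deterministic sweep fallback
            for cand in range(0, length - m + 1):
                if not overlaps(cand, m):
                    spot = cand
                    break
        if spot is None:
            raise InfeasiblePlanError("epitope plan does not fit the amplicon")
        placed.append((spot, block))
    return sorted(placed)


def _reverse_translate(peptide: str, rng: np.random.Generator) -> str:
    return "".join(
        _CODON_CHOICES[aa][rng.integers(0, len(_CODON_CHOICES[aa]))]
        for aa in peptide
    )


def _instantiate_primer(primer: str, rng: np.random.Generator) -> str:
    return "".join(
        c if len(IUPAC[c]) == 1 else sorted(IUPAC[c])[rng.integers(0, len(IUPAC[c]))]
        for c in primer
    )


def _default_plan(
    config: SynthConfig, rng: np.random.Generator
) -> list[dict]:
    """Panel composition emulating the study's amplicon families.

    Roughly 40% of non-secalin amplicons carry no epitopes (mostly
    B-subgenome), two carry the full 33-mer region plus a downstream alpha-3
    (the 7-epitope D-subgenome amplicons), and the rest carry small epitope
    sets; the p31-43 innate peptide travels mostly with A-subgenome amplicons.
    Secalin amplicons are epitope-free except one carrying the sec2/gamma
    combination.
    """
    n_sec = int(round(config.secalin_fraction * config.panel_size))
    n_gli = config.panel_size - n_sec
    plans: list[dict] = []
    for i in range(n_sec):
        plan = [("DQ2.5_sec2", 1), ("DQ2.5_glia_g4c", 1)] if i == 0 else []
        plans.append({"plan": plan, "subgenome": "R", "secalin": True})
    templates = [
        ([("region_33mer", 1), ("DQ2.5_glia_a3", 1), ("p31_43", 1)], "D"),
        ([("DQ2.5_glia_a1a", 1), ("DQ2.5_glia_a3", 1), ("p31_43", 1)], "A"),
        ([("DQ2.5_glia_a2", 2)], "D"),
        ([("DQ2.5_glia_a3", 1)], "A"),
        ([("DQ2.5_glia_g1", 1), ("region_26mer", 1)], "D"),
        ([], "B"),
    ]
    # two 33-mer amplicons, ~40% empty, remainder cycles the small templates
    n_33mer = min(2, n_gli)
    n_empty = max(0, int(round(0.4 * n_gli)))
    idx = 0
    for i in range(n_gli):
        if i < n_33mer:
            plan, sg = templates[0]
        elif i < n_33mer + n_empty:
            plan, sg = templates[5]
            sg = "B" if i % 3 else "A"
        else:
            plan, sg = templates[1 + idx % 4]
            idx += 1
        plans.append({"plan": list(plan), "subgenome": sg, "secalin": False})
    return plans


def generate_panel(
    config: SynthConfig,
    catalog: EpitopeCatalog | None = None,
    rng: np.random.Generator | None = None,
) -> SynthTruth:
    """Build the amplicon panel with planted epitopes and pseudogenes.

    Panel amplicons are kept at pairwise edit distance > 10 so that distinct
    planted sequences can never absorb each other during denoising.
    """
    catalog = catalog or EpitopeCatalog.default()
    rng = rng or np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    if config.epitope_plan is not None:
        n_sec = int(round(config.secalin_fraction * len(config.epitope_plan)))
        subgenomes = "ABD"
        plans = [
            {
                "plan": list(p),
                "subgenome": "R" if i < n_sec else subgenomes[i % 3],
                "secalin": i < n_sec,
            }
            for i, p in enumerate(config.epitope_plan)
        ]
    else:
        plans = _default_plan(config, rng)

    for spec_ in plans:
        for eid, copies in spec_["plan"]:
            if eid not in catalog:
                raise KeyError(f"epitope plan references unknown id {eid!r}")
            if copies < 1:
                raise InfeasiblePlanError(f"copies must be >= 1 for {eid}")

    f = config.frame_offset
    lo, hi = config.amplicon_length_range
    m_lo = math.ceil((lo - f) / 3)
    m_hi = (hi - f) // 3

    records: list[AmpliconRecord] = []
    occurrences: dict[str, list[EpitopeOccurrence]] = {}
    type_labels: dict[str, str] = {}
    full_sequences: dict[str, str] = {}
    inserts: list[str] = []

    for spec_ in plans:
        for _attempt in range(50):
            m = int(rng.integers(m_lo, m_hi + 1))
            backbone = "".join(
                _TILES[rng.integers(0, len(_TILES))]
                for _ in range(m // len(_TILES[0]) + 2)
            )[:m]
            blocks = [
                _tandem_block(catalog[eid].peptide, copies)
                for eid, copies in spec_["plan"]
            ]
            if not spec_["secalin"]:
                blocks.append(_MOTIF_BY_SUBGENOME[spec_["subgenome"]])
            try:
                placed = _place_blocks(m, blocks, rng)
            except InfeasiblePlanError:
                if sum(len(b) for b in blocks) > m_hi:
                    raise  # cannot fit at any admissible length
                continue  # unlucky packing at this length: redraw
            peptide = list(backbone)
            for start, block in placed:
                peptide[start : start + len(block)] = block
            peptide = "".join(peptide)

            dna = _reverse_translate(peptide, rng)
            pseudo = (not spec_["secalin"]) and rng.random() < config.pseudogene_prob
            if pseudo:
                planted_spans = [
                    (s, s + len(b)) for s, b in placed
                ]
                q_positions = [
                    i for i, aa in enumerate(peptide)
                    if aa == "Q"
                    and not any(a <= i < b for a, b in planted_spans)
                ]
                if not q_positions:  # fall back to any glutamine
                    q_positions = [i for i, aa in enumerate(peptide) if aa == "Q"]
                pos = q_positions[rng.integers(0, len(q_positions))]
                codon = dna[3 * pos : 3 * pos + 3]
                assert codon in ("CAA", "CAG")
                dna = dna[: 3 * pos] + "T" + dna[3 * pos + 1 :]

            pad = "".join("ACGT"[rng.integers(0, 4)] for _ in range(f))
            insert = pad + dna
            # reject near-duplicates of earlier panel members
            if any(
                edlib.align(insert, prev, mode="NW", task="distance", k=10)[
                    "editDistance"
                ] >= 0
                for prev in inserts
            ):
                continue
            break
        else:
            raise InfeasiblePlanError(
                "could not generate a distinct amplicon satisfying the plan"
            )

        inserts.append(insert)
        translated = translate(insert, f)
        occs = find_epitopes(translated, catalog, max_mismatch=0)
        rec = AmpliconRecord(
            id=amplicon_id(insert, config.panel),
            sequence=insert,
            panel=config.panel,
            provenance=["synthetic"],
            frame=f,
            pseudogene="*" in translated,
            subgenome=spec_["subgenome"],
            secalin=spec_["secalin"],
        )
        occs = [replace(o, amplicon_id=rec.id) for o in occs]
        rec.type_label = classify_type(occs, catalog, config.panel)
        records.append(rec)
        occurrences[rec.id] = occs
        type_labels[rec.id] = rec.type_label
        fwd = _instantiate_primer(config.primers.forward, rng)
        rev = _instantiate_primer(config.primers.reverse, rng)
        full_sequences[rec.id] = fwd + insert + revcomp(rev)

    return SynthTruth(records, occurrences, type_labels, full_sequences)


# ------------------------------------------------------------------ profiles


def generate_profiles(
    truth: SynthTruth,
    config: SynthConfig,
    rng: np.random.Generator | None = None,
    catalog: EpitopeCatalog | None = None,
) -> SynthTruth:
    """Dirichlet genotype proportions restricted by genotype class.

    Secalin amplicons are only allowed in translocation carriers, and
    D-subgenome amplicons are excluded from durum and tritordeum; each
    genotype's allowed amplicons get a Dirichlet(``dirichlet_alpha``) row.
    """
    if not truth.panel:
        raise ValueError("empty panel")
    rng = rng or np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    amp_ids = [r.id for r in truth.panel]
    rows = {}
    classes = {}
    for cls, count in config.n_genotypes_per_class.items():
        perm = CLASSES[cls]
        allowed = [
            r.id
            for r in truth.panel
            if (perm["secalin"] or not r.secalin)
            and (perm["subgenome_d"] or r.subgenome != "D")
        ]
        if not allowed:
            raise ValueError(f"class {cls}: no amplicons allowed by its mask")
        for g in range(count):
            name = f"{_CLASS_PREFIX[cls]}_g{g + 1:02d}"
            draw = rng.dirichlet([config.dirichlet_alpha] * len(allowed))
            row = pd.Series(0.0, index=amp_ids)
            row[allowed] = draw
            rows[name] = row
            classes[name] = cls
    proportions = pd.DataFrame(rows).T
    truth.proportions = proportions
    truth.genotype_classes = pd.Series(classes)

    catalog = catalog or EpitopeCatalog.default()
    matrix = (100.0 * proportions).T  # amplicon x genotype percent
    truth.expected_epitope_abundance = epitope_abundance(
        matrix, truth.occurrences, catalog, truth.panel, putative_only=True
    )
    truth.expected_type_abundance = type_abundance(
        matrix, truth.type_labels, truth.panel, putative_only=True
    )
    return truth


# -------------------------------------------------------------------- reads


def _apply_errors(
    template: str, qual_hi: str, rng: np.random.Generator, p: float
) -> tuple[str, str]:
    n_err = rng.binomial(len(template), p)
    if n_err == 0:
        return template, qual_hi
    pos = rng.choice(len(template), size=n_err, replace=False)
    seq = np.frombuffer(template.encode(), dtype=np.uint8).copy()
    qual = np.frombuffer(qual_hi.encode(), dtype=np.uint8).copy()
    for i in pos:
        choices = _BASES[_BASES != seq[i]]
        seq[i] = choices[rng.integers(0, 3)]
        qual[i] = 15 + 33
    return seq.tobytes().decode(), qual.tobytes().decode()


def simulate_reads(
    truth: SynthTruth,
    config: SynthConfig,
    out_dir,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Write paired FASTQ files and truth tables; return the sample sheet.

    Two replicate samples per genotype; each sample's reads are drawn
    multinomially from the genotype's amplicon proportions.  Substitution
    errors hit each sequenced base independently at ``per_base_error``;
    correct bases get Q35, error positions Q15.
    """
    if truth.proportions is None:
        raise ValueError("run generate_profiles first")
    rng = rng or np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    L = config.read_length
    p = config.per_base_error
    amp_ids = list(truth.proportions.columns)
    templates = {}
    for amp_id in amp_ids:
        full = truth.full_sequences[amp_id]
        r1 = full[:L]
        r2 = revcomp(full)[:L]
        templates[amp_id] = (r1, "D" * len(r1), r2, "D" * len(r2))  # 'D' = Q35

    sheet_rows = []
    realized: dict[str, np.ndarray] = {}
    for genotype in truth.proportions.index:
        cls = truth.genotype_classes[genotype]
        for rep in (1, 2):
            sample = f"{genotype}_rep{rep}"
            counts = rng.multinomial(
                config.reads_per_sample, truth.proportions.loc[genotype].to_numpy()
            )
            realized[sample] = counts
            r1_path = out / f"{sample}_R1.fastq"
            r2_path = out / f"{sample}_R2.fastq"
            lines1: list[str] = []
            lines2: list[str] = []
            serial = 0
            for amp_id, c in zip(amp_ids, counts):
                if c == 0:
                    continue
                r1, q1, r2, q2 = templates[amp_id]
                for _ in range(int(c)):
                    serial += 1
                    name = f"@{sample}:{serial} {amp_id}"
                    if p > 0:
                        s1, e1 = _apply_errors(r1, q1, rng, p)
                        s2, e2 = _apply_errors(r2, q2, rng, p)
                    else:
                        s1, e1, s2, e2 = r1, q1, r2, q2
                    lines1 += (name, s1, "+", e1)
                    lines2 += (name, s2, "+", e2)
            try:
                r1_path.write_text("\n".join(lines1) + ("\n" if lines1 else ""))
                r2_path.write_text("\n".join(lines2) + ("\n" if lines2 else ""))
            except OSError as exc:
                raise OSError(f"failed writing reads for {sample}: {exc}") from exc
            sheet_rows.append(
                {
                    "sample_id": sample,
                    "genotype": genotype,
                    "replicate": rep,
                    "species": CLASSES[cls]["species"],
                    "rye_translocation": "Y" if CLASSES[cls]["secalin"] else "N",
                    "fastq_r1": str(r1_path),
                    "fastq_r2": str(r2_path),
                }
            )
    sheet = pd.DataFrame(sheet_rows)
    sheet.to_csv(out / "sample_sheet.tsv", sep="\t", index=False)
    truth.realized_counts = pd.DataFrame(realized, index=amp_ids)
    truth.write_tables(out)
    return sheet


def generate_dataset(config: SynthConfig, out_dir) -> tuple[SynthTruth, pd.DataFrame]:
    """Panel + profiles + reads in one call (all randomness from config.seed)."""
    truth = generate_panel(config)
    truth = generate_profiles(truth, config)
    sheet = simulate_reads(truth, config, out_dir)
    return truth, sheet


# --------------------------------------------------- AHP recovery simulation


def simulate_monotone_abundance(
    n_genotypes: int = 10,
    epitope_ids: Sequence[str] | None = None,
    type_ids: Sequence[str] = ("Alpha_0", "Alpha_1", "Alpha_2", "Alpha_7"),
    seed: int = 0,
    noise_sd: float = 0.25,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Genotypes with planted monotone immunogenicity for ranking recovery.

    Genotype g's abundance on every immunogenic leaf scales with a monotone
    multiplier (log-normal noise on top); the epitope-free Alpha_0 type scales
    inversely.  Returns (epitope table, type table, genotypes ordered from
    most to least immunogenic).
    """
    rng = np.random.default_rng(seed)
    if epitope_ids is None:
        epitope_ids = [e.epitope_id for e in EpitopeCatalog.default().dq25]
    genotypes = [f"G{i + 1:02d}" for i in range(n_genotypes)]
    mult = np.linspace(1.0, 6.0, n_genotypes)
    epi = {}
    for eid in epitope_ids:
        base = rng.uniform(1.0, 8.0)
        epi[eid] = base * mult * np.exp(rng.normal(0, noise_sd, n_genotypes))
    typ = {}
    for tid in type_ids:
        base = rng.uniform(1.0, 8.0)
        immunogenic = not tid.endswith("_0")
        scale = mult if immunogenic else mult[::-1]
        typ[tid] = base * scale * np.exp(rng.normal(0, noise_sd, n_genotypes))
    epitope_table = pd.DataFrame(epi, index=genotypes)
    type_table = pd.DataFrame(typ, index=genotypes)
    order = list(reversed(genotypes))  # G{n} most immunogenic
    return epitope_table, type_table, order
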