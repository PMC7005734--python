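"""Cohort mutation-profile summaries.

Operates on flat per-variant records (one row per called mutation per
sample, MAF-file style).  Two frequency denominators are kept side by
side because both appear in practice: variants per enrolled patient, and
variants per patient carrying at least one mutation.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = [
    "CONSEQUENCES",
    "CohortVariant",
    "ConsequenceSummary",
    "GeneSummary",
    "OncoplotResult",
    "consequence_summary",
    "gene_frequencies",
    "hotspot_tally",
    "oncoplot_matrix",
]

CONSEQUENCES = (
    "missense",
    "nonsense",
    "frameshift",
    "in_frame_ins",
    "in_frame_del",
    "splice",
    "other",
)

_PPOS_RE = re.compile(r"(\d+)")


@dataclass(frozen=True)
class CohortVariant:
    """One somatic mutation observed in one cohort sample."""

    sample_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: str
    protein_change: str = ""
    maf: float | None = None

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence class {self.consequence!r}")
        if self.maf is not None and not (0 <= self.maf <= 1):
            raise ValueError("maf must be in [0, 1]")

    @property
    def protein_pos(self) -> int | None:
        """First integer of the HGVS-like p. string (range events are
        attributed to their start residue); None when unparseable."""
        m = _PPOS_RE.search(self.protein_change or "")
        return int(m.group(1)) if m else None


@dataclass(frozen=True)
class GeneSummary:
    gene: str
    n_variants: int
    n_mutated_samples: int
    freq_per_patient: float
    freq_per_mutated_patient: float
    class_counts: dict[str, int]


@dataclass(frozen=True)
class ConsequenceSummary:
    gene: str
    class_counts: dict[str, int]
    modal_classes: tuple[str, ...]
    modal_fraction: float


@dataclass(frozen=True)
class OncoplotResult:
    matrix: pd.DataFrame
    per_sample_counts: pd.Series
    per_gene_counts: pd.Series
    n_samples_with_any_mutation: int


def gene_frequencies(
    cohort: Sequence[CohortVariant],
    n_patients: int,
    n_mutated_patients: int | None = None,
) -> list[GeneSummary]:
    """Per-gene variant tallies with both frequency denominators.

    ``freq_per_patient`` divides a gene's variant count by the cohort
    size; ``freq_per_mutated_patient`` divides it by the number of
    patients with at least one mutation anywhere.  Sorted by variant
    count, descending.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    distinct = {v.sample_id for v in cohort}
    if n_patients < len(distinct):
        raise ValueError(
            f"n_patients ({n_patients}) is fewer than distinct samples "
            f"in the cohort ({len(distinct)})"
        )
    if n_mutated_patients is None:
        n_mutated_patients = len(distinct)
    summaries = []
    by_gene: dict[str, list[CohortVariant]] = {}
    for v in cohort:
        by_gene.setdefault(v.gene, []).append(v)
    for gene, variants in by_gene.items():
        counts = Counter(v.consequence for v in variants)
        summaries.append(
            GeneSummary(
                gene=gene,
                n_variants=len(variants),
                n_mutated_samples=len({v.sample_id for v in variants}),
                freq_per_patient=len(variants) / n_patients,
                freq_per_mutated_patient=(
                    len(variants) / n_mutated_patients if n_mutated_patients else 0.0
                ),
                class_counts=dict(counts),
            )
        )
    summaries.sort(key=lambda s: (-s.n_variants, s.gene))
    return summaries


def consequence_summary(
    cohort: Sequence[CohortVariant], gene: str
) -> ConsequenceSummary:
    """Consequence-class breakdown for one gene with the modal class.

    Ties for the mode are all reported, in lexicographic order.  A gene
    absent from the cohort yields empty counts.
    """
    counts = Counter(v.consequence for v in cohort if v.gene == gene)
    if not counts:
        return ConsequenceSummary(gene, {}, (), 0.0)
    top = max(counts.values())
    modal = tuple(sorted(c for c, n in counts.items() if n == top))
    total = sum(counts.values())
    return ConsequenceSummary(gene, dict(counts), modal, top / total)


def hotspot_tally(
    cohort: Sequence[CohortVariant],
    gene: str,
    denominator: int | None = None,
) -> list[tuple[int, int, float]]:
    """Residue-level mutation tally for one gene.

    Returns ``(protein_pos, count, fraction)`` rows sorted by count
    descending then position.  The fraction denominator defaults to the
    number of the gene's variants with a parseable protein position;
    pass ``denominator`` explicitly to reproduce published percentages
    computed over a different base.  Variants without a parseable
    position are excluded from the tally.
    """
    positions = [
        v.protein_pos
        for v in cohort
        if v.gene == gene and v.protein_pos is not None
    ]
    counts = Counter(positions)
    denom = denominator if denominator is not None else len(positions)
    if denom <= 0:
        return []
    rows = [(pos, n, n / denom) for pos, n in counts.items()]
    rows.sort(key=lambda r: (-r[1], r[0]))
    return rows


def oncoplot_matrix(
    cohort: Sequence[CohortVariant],
    samples: Sequence[str],
    top_n: int = 10,
) -> OncoplotResult:
    """Sample-by-gene consequence matrix for the most mutated genes.

    Cells hold the variant's consequence class, ``"multi_hit"`` when a
    sample carries two or more variants in the gene, and ``""`` when wild
    type.  Genes are ranked by total variant count; samples are ordered
    by their mutation count (descending) then id.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    samples = list(samples)
    gene_counts = Counter(v.gene for v in cohort)
    top_genes = [
        g for g, _ in sorted(gene_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ][:top_n]

    per_sample = Counter(v.sample_id for v in cohort)
    sample_order = sorted(samples, key=lambda s: (-per_sample.get(s, 0), s))
    matrix = pd.DataFrame("", index=sample_order, columns=top_genes, dtype=object)
    cell: dict[tuple[str, str], list[str]] = {}
    for v in cohort:
        if v.gene in matrix.columns:
            cell.setdefault((v.sample_id, v.gene), []).append(v.consequence)
    for (sid, gene), classes in cell.items():
        if sid in matrix.index:
            matrix.at[sid, gene] = "multi_hit" if len(classes) > 1 else classes[0]
    per_sample_counts = pd.Series(
        [per_sample.get(s, 0) for s in sample_order], index=sample_order, dtype=int
    )
    per_gene_counts = pd.Series(
        [gene_counts[g] for g in top_genes], index=top_genes, dtype=int
    )
    n_any = len({v.sample_id for v in cohort if v.sample_id in set(samples)})
    return OncoplotResult(matrix, per_sample_counts, per_gene_counts, n_any)
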