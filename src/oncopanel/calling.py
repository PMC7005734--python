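"""Minimal per-site somatic variant caller.

The caller operates on per-site allele-count pileups rather than aligned
reads.  It applies the panel's published filter rules — a minimum mutant
allele frequency (MAF, default 5%), a minimum site depth and a minimum
absolute alternate-read count — and left-normalizes indels so that every
equivalent spelling of a variant collapses to a single canonical
``(chrom, pos, ref, alt)`` identity (1-based, VCF-style anchor bases).

Alignment, base-quality recalibration and joint genotyping are out of
scope: multi-allelic sites simply emit one candidate call per non-reference
allele.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

__all__ = [
    "CallerConfig",
    "FilterStatus",
    "SitePileup",
    "VariantCall",
    "call_sample",
    "call_site",
    "left_align",
    "trim_alleles",
    "variant_class",
]

_DNA = frozenset("ACGT")


class FilterStatus(str, Enum):
    PASS = "PASS"
    LOW_MAF = "LOW_MAF"
    LOW_DEPTH = "LOW_DEPTH"
    LOW_ALT_READS = "LOW_ALT_READS"


@dataclass(frozen=True)
class CallerConfig:
    """Filter thresholds for the per-site caller.

    maf_threshold
        Minimum mutant allele frequency for a PASS call.  The assay's
        published cut-off is 5% for both SNVs and indels.
    min_depth
        Minimum total site depth; sites below it are uncallable.
    min_alt_reads
        Absolute floor on supporting reads, which dominates the MAF rule
        at low coverage (4 reads at 50x is 8%).
    """

    maf_threshold: float = 0.05
    min_depth: int = 20
    min_alt_reads: int = 4

    def __post_init__(self) -> None:
        if not (0 < self.maf_threshold < 1):
            raise ValueError("maf_threshold must be in (0, 1)")
        if self.min_depth < 1 or self.min_alt_reads < 1:
            raise ValueError("min_depth and min_alt_reads must be positive")


@dataclass
class SitePileup:
    """Allele counts observed at one panel position.

    ``allele_counts`` maps allele keys to read counts.  Keys are single
    bases for substitution alleles (the reference base included),
    ``ins:<SEQ>`` for an insertion of SEQ immediately after ``pos`` and
    ``del:<L>`` for a deletion of L bases starting immediately after
    ``pos``.
    """

    chrom: str
    pos: int
    ref: str
    allele_counts: dict[str, int] = field(default_factory=dict)
    sample_id: str = ""
    run_id: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref not in _DNA:
            raise ValueError(f"ref must be a single base, got {self.ref!r}")
        self.allele_counts.setdefault(self.ref, 0)
        for allele, count in self.allele_counts.items():
            if count < 0:
                raise ValueError(f"negative count for allele {allele!r}")

    @property
    def depth(self) -> int:
        return sum(self.allele_counts.values())


@dataclass(frozen=True)
class VariantCall:
    chrom: str
    pos: int
    ref: str
    alt: str
    depth: int
    alt_count: int
    filter: FilterStatus
    sample_id: str = ""
    run_id: str = ""

    @property
    def maf(self) -> float:
        return self.alt_count / self.depth if self.depth else 0.0

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Normalized variant identity used for truth matching."""
        return (self.chrom, self.pos, self.ref, self.alt)


def variant_class(ref: str, alt: str) -> str:
    """Classify a normalized allele pair as SNV / INS / DEL / DELINS."""
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    if len(ref) < len(alt) and alt.startswith(ref):
        return "INS"
    if len(ref) > len(alt) and ref.startswith(alt):
        return "DEL"
    return "DELINS"


def trim_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Context-free parsimony trimming of an allele pair.

    Shared suffix bases are removed first, then shared prefix bases
    (always retaining one base in each allele).  This yields the minimal
    representation but does not shift indels left — use :func:`left_align`
    when the reference context is available.
    """
    if ref == alt:
        raise ValueError("ref and alt are identical")
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def left_align(
    ref_context: str,
    context_offset: int,
    pos: int,
    ref: str,
    alt: str,
) -> tuple[int, str, str]:
    """Left-normalize a variant within a reference context window.

    ``ref_context`` is the reference sequence whose first base sits at
    1-based genomic position ``context_offset``.  The variant is trimmed
    to its parsimonious form and indels are shifted to their leftmost
    equivalent position, keeping a single VCF-style anchor base.  The
    operation is idempotent and collapses every equivalent spelling of a
    variant (e.g. an insertion anywhere inside a homopolymer run) to one
    canonical ``(pos, ref, alt)``.

    Raises ``ValueError`` when ``ref`` disagrees with the context or the
    variant cannot be shifted without leaving the window.
    """
    ref, alt = ref.upper(), alt.upper()
    if ref == alt:
        raise ValueError("ref and alt are identical")
    i = pos - context_offset
    if i < 0 or i + len(ref) > len(ref_context):
        raise ValueError(
            f"variant at {pos} (ref {ref!r}) outside context "
            f"[{context_offset}, {context_offset + len(ref_context)})"
        )
    if ref_context[i : i + len(ref)] != ref:
        raise ValueError(
            f"ref allele {ref!r} does not match context "
            f"{ref_context[i:i + len(ref)]!r} at pos {pos}"
        )

    # vt-style normalization: trim right, extending left from the context
    # whenever an allele empties; then trim redundant leading bases.  An
    # indel that reaches the start of the window keeps its anchor there
    # (right-anchored edge representation, as VCF uses at position 1).
    while True:
        changed = False
        if ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            if min(len(ref), len(alt)) == 1 and pos - 1 < context_offset:
                break  # leftmost within the window; cannot extend further
            ref, alt = ref[:-1], alt[:-1]
            changed = True
        if not ref or not alt:
            base = ref_context[pos - 1 - context_offset]
            ref, alt = base + ref, base + alt
            pos -= 1
            changed = True
        if not changed:
            break
    while len(ref) >= 2 and len(alt) >= 2 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def _allele_to_variant(
    pileup: SitePileup,
    allele: str,
    ref_context: str | None,
    context_offset: int | None,
) -> tuple[int, str, str]:
    """Expand a pileup allele key into a (pos, ref, alt) triple."""
    pos = pileup.pos
    if allele in _DNA:
        return pos, pileup.ref, allele
    if allele.startswith("ins:"):
        seq = allele[4:]
        return pos, pileup.ref, pileup.ref + seq
    if allele.startswith("del:"):
        length = int(allele[4:])
        if ref_context is None or context_offset is None:
            raise ValueError(
                f"deletion allele {allele!r} at {pileup.chrom}:{pos} needs a "
                "reference context to reconstruct the deleted bases"
            )
        i = pos - context_offset
        deleted = ref_context[i + 1 : i + 1 + length]
        if len(deleted) != length:
            raise ValueError(
                f"context too short for {allele!r} at {pileup.chrom}:{pos}"
            )
        return pos, pileup.ref + deleted, pileup.ref
    if allele.startswith("delins:"):
        ref, alt = allele[7:].split(">")
        return pos, ref, alt
    raise ValueError(f"unrecognized allele key {allele!r}")


def call_site(
    pileup: SitePileup,
    config: CallerConfig | None = None,
    ref_context: str | None = None,
    context_offset: int | None = None,
) -> list[VariantCall]:
    """Call every non-reference allele with at least one read at a site.

    Each candidate receives a filter status; PASS calls honour every
    threshold in ``config`` and are left-normalized when a reference
    context is supplied.  A depth-0 site yields no calls (uncallable).
    """
    config = config or CallerConfig()
    depth = pileup.depth
    calls: list[VariantCall] = []
    for allele, count in sorted(pileup.allele_counts.items()):
        if allele == pileup.ref or count <= 0:
            continue
        if depth < config.min_depth:
            status = FilterStatus.LOW_DEPTH
        elif count / depth < config.maf_threshold:
            status = FilterStatus.LOW_MAF
        elif count < config.min_alt_reads:
            status = FilterStatus.LOW_ALT_READS
        else:
            status = FilterStatus.PASS
        pos, ref, alt = _allele_to_variant(pileup, allele, ref_context, context_offset)
        if ref_context is not None and context_offset is not None:
            pos, ref, alt = left_align(ref_context, context_offset, pos, ref, alt)
        else:
            pos, ref, alt = trim_alleles(pos, ref, alt)
        calls.append(
            VariantCall(
                chrom=pileup.chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                depth=depth,
                alt_count=count,
                filter=status,
                sample_id=pileup.sample_id,
                run_id=pileup.run_id,
            )
        )
    return calls


def call_sample(
    pileups: Iterable[SitePileup],
    config: CallerConfig | None = None,
    contexts: Mapping[tuple[str, int], tuple[str, int]] | None = None,
) -> tuple[dict[tuple[str, int, str, str], VariantCall], float]:
    """Call a whole sample and report its median per-site coverage.

    ``contexts`` optionally maps ``(chrom, pos)`` to a
    ``(ref_context, context_offset)`` pair used for indel normalization.
    Returns the PASS calls keyed by normalized variant identity and the
    median of per-site depths (mean of the middle two for even counts,
    the usual convention).
    """
    config = config or CallerConfig()
    pileup_list = list(pileups)
    if not pileup_list:
        raise ValueError("call_sample requires at least one pileup")
    depths: list[int] = []
    passing: dict[tuple[str, int, str, str], VariantCall] = {}
    for pileup in pileup_list:
        depths.append(pileup.depth)
        ctx = contexts.get((pileup.chrom, pileup.pos)) if contexts else None
        calls = call_site(
            pileup,
            config,
            ref_context=ctx[0] if ctx else None,
            context_offset=ctx[1] if ctx else None,
        )
        for call in calls:
            if call.filter is FilterStatus.PASS:
                passing[call.key] = call
    return passing, float(statistics.median(depths))
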