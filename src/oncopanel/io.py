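"""Readers and writers for the pipeline's plain-text formats.

Conventions: variant positions are 1-based everywhere (VCF style); the
BED-like panel format is 0-based half-open on disk and converted at the
boundary (the conversion is logged).  Missing clinical values are
spelled ``NA``.  Readers validate rather than coerce: malformed records
raise with the offending line number.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import yaml

from .association import CHARACTERISTICS, ClinicalRecord
from .calling import SitePileup, VariantCall
from .profiling import CONSEQUENCES, CohortVariant
from .synthetic import PanelTarget, TruthSet, TruthVariant

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "read_clinical",
    "read_cohort",
    "read_panel",
    "read_pileups",
    "read_truth",
    "write_clinical",
    "write_cohort",
    "write_panel",
    "write_pileups",
    "write_truth",
    "write_vcf",
]

TRUTH_COLUMNS = ("chrom", "pos", "ref", "alt", "class", "expected_maf", "standard")

# MAF-format column synonyms accepted by the cohort reader.
DEFAULT_COHORT_COLUMNS: dict[str, tuple[str, ...]] = {
    "sample_id": ("sample_id", "Tumor_Sample_Barcode", "sample"),
    "gene": ("gene", "Hugo_Symbol"),
    "chrom": ("chrom", "Chromosome"),
    "pos": ("pos", "Start_Position"),
    "ref": ("ref", "Reference_Allele"),
    "alt": ("alt", "Tumor_Seq_Allele2"),
    "consequence": ("consequence", "Variant_Classification"),
    "protein_change": ("protein_change", "HGVSp_Short"),
    "maf": ("maf", "t_AF"),
}

CONSEQUENCE_SYNONYMS = {
    "missense_mutation": "missense",
    "nonsense_mutation": "nonsense",
    "frame_shift_ins": "frameshift",
    "frame_shift_del": "frameshift",
    "in_frame_ins": "in_frame_ins",
    "in_frame_del": "in_frame_del",
    "splice_site": "splice",
}


def _error(path: Path, lineno: int, message: str) -> ValueError:
    return ValueError(f"{path}:{lineno}: {message}")


# ---------------------------------------------------------------------------
# Panel (BED-like, 0-based half-open on disk)
# ---------------------------------------------------------------------------

def read_panel(path: str | Path) -> list[PanelTarget]:
    path = Path(path)
    targets = []
    with path.open() as handle:
        header = handle.readline().rstrip("\n").split("\t")
        required = ["chrom", "start", "end", "target_id", "ref_context"]
        if header != required:
            raise _error(path, 1, f"expected columns {required}, got {header}")
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            chrom, start, end, target_id, ctx = line.rstrip("\n").split("\t")
            pos = int(start) + 1  # 0-based half-open -> 1-based
            targets.append(
                PanelTarget(target_id=target_id, chrom=chrom, pos=pos, ref_context=ctx)
            )
    logger.info("read %d panel targets from %s (BED 0-based converted to 1-based)",
                len(targets), path)
    return targets


def write_panel(targets: Sequence[PanelTarget], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as handle:
        handle.write("chrom\tstart\tend\ttarget_id\tref_context\n")
        for t in targets:
            handle.write(
                f"{t.chrom}\t{t.pos - 1}\t{t.pos}\t{t.target_id}\t{t.ref_context}\n"
            )


# ---------------------------------------------------------------------------
# Truth sets
# ---------------------------------------------------------------------------

def read_truth(path: str | Path, name: str | None = None) -> TruthSet:
    path = Path(path)
    variants = []
    with path.open() as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header != list(TRUTH_COLUMNS):
            raise _error(path, 1, f"expected columns {TRUTH_COLUMNS}, got {header}")
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(TRUTH_COLUMNS):
                raise _error(path, lineno, f"expected {len(TRUTH_COLUMNS)} fields")
            chrom, pos_s, ref, alt, _cls, maf_s, standard = fields
            try:
                pos = int(pos_s)
                maf = float(maf_s)
            except ValueError as exc:
                raise _error(path, lineno, f"malformed number: {exc}") from None
            if pos < 1:
                raise _error(path, lineno, "pos must be >= 1 (1-based)")
            if not (0 < maf <= 1):
                raise _error(path, lineno, f"expected_maf {maf} outside (0, 1]")
            variants.append(
                TruthVariant(chrom, pos, ref, alt, expected_maf=maf,
                             source_standard=standard)
            )
    return TruthSet(name=name or path.stem, variants=tuple(variants))


def write_truth(truth: TruthSet, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as handle:
        handle.write("\t".join(TRUTH_COLUMNS) + "\n")
        for v in truth.variants:
            handle.write(
                f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.variant_class}\t"
                f"{v.expected_maf:.6g}\t{v.source_standard}\n"
            )


# ---------------------------------------------------------------------------
# Pileups
# ---------------------------------------------------------------------------

def write_pileups(pileups: Sequence[SitePileup], path: str | Path) -> None:
    """TSV with fixed base columns and a packed column for indel alleles
    (``ins:SEQ:count;del:LEN:count`` or ``.``)."""
    path = Path(path)
    with path.open("w") as handle:
        handle.write("chrom\tpos\tref\tdepth\tA\tC\tG\tT\tindels\tsample_id\trun_id\n")
        for p in pileups:
            bases = [str(p.allele_counts.get(b, 0)) for b in "ACGT"]
            extras = ";".join(
                f"{allele}:{count}"
                for allele, count in sorted(p.allele_counts.items())
                if allele not in "ACGT" and count > 0
            )
            handle.write(
                f"{p.chrom}\t{p.pos}\t{p.ref}\t{p.depth}\t"
                + "\t".join(bases)
                + f"\t{extras or '.'}\t{p.sample_id}\t{p.run_id}\n"
            )


def read_pileups(path: str | Path) -> list[SitePileup]:
    path = Path(path)
    pileups = []
    with path.open() as handle:
        header = handle.readline().rstrip("\n").split("\t")
        expected = ["chrom", "pos", "ref", "depth", "A", "C", "G", "T",
                    "indels", "sample_id", "run_id"]
        if header != expected:
            raise _error(path, 1, f"expected columns {expected}, got {header}")
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            chrom, pos_s, ref, depth_s = f[0], f[1], f[2], f[3]
            counts = {b: int(f[4 + i]) for i, b in enumerate("ACGT") if int(f[4 + i])}
            counts.setdefault(ref, 0)
            if f[8] != ".":
                for item in f[8].split(";"):
                    allele, _, count = item.rpartition(":")
                    counts[allele] = int(count)
            pileup = SitePileup(
                chrom=chrom, pos=int(pos_s), ref=ref, allele_counts=counts,
                sample_id=f[9], run_id=f[10],
            )
            if pileup.depth != int(depth_s):
                raise _error(
                    path, lineno,
                    f"depth {depth_s} does not equal the allele-count sum {pileup.depth}",
                )
            pileups.append(pileup)
    return pileups


# ---------------------------------------------------------------------------
# Cohort variants (MAF-like) and clinical covariates
# ---------------------------------------------------------------------------

def read_cohort(
    path: str | Path,
    column_map: Mapping[str, Sequence[str]] | None = None,
) -> list[CohortVariant]:
    """Read a MAF-like cohort TSV, resolving column-name synonyms.

    Unknown consequence terms are recorded as ``other`` with a warning;
    duplicated rows are kept (legitimate multi-hit) with a warning.
    """
    path = Path(path)
    synonyms = dict(DEFAULT_COHORT_COLUMNS)
    if column_map:
        for key, names in column_map.items():
            synonyms[key] = tuple(names)
    variants = []
    seen_rows: set[tuple] = set()
    with path.open() as handle:
        header = handle.readline().rstrip("\n").split("\t")
        index: dict[str, int] = {}
        for canonical, names in synonyms.items():
            for name in names:
                if name in header:
                    index[canonical] = header.index(name)
                    break
            else:
                if canonical in ("maf", "protein_change"):
                    continue  # optional columns
                raise _error(path, 1, f"no column found for {canonical!r} "
                                      f"(accepted: {list(names)})")
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            raw_cons = f[index["consequence"]]
            cons = raw_cons.strip().lower()
            cons = CONSEQUENCE_SYNONYMS.get(cons, cons)
            if cons not in CONSEQUENCES:
                logger.warning("%s:%d: unknown consequence %r recorded as 'other'",
                               path, lineno, raw_cons)
                cons = "other"
            maf = None
            if "maf" in index and f[index["maf"]] not in ("", "NA", "."):
                maf = float(f[index["maf"]])
            variant = CohortVariant(
                sample_id=f[index["sample_id"]],
                gene=f[index["gene"]],
                chrom=f[index["chrom"]],
                pos=int(f[index["pos"]]),
                ref=f[index["ref"]],
                alt=f[index["alt"]],
                consequence=cons,
                protein_change=f[index["protein_change"]] if "protein_change" in index else "",
                maf=maf,
            )
            row_key = (variant.sample_id, variant.gene, variant.chrom, variant.pos,
                       variant.ref, variant.alt)
            if row_key in seen_rows:
                logger.warning("%s:%d: duplicated variant row kept (multi-hit)",
                               path, lineno)
            seen_rows.add(row_key)
            variants.append(variant)
    return variants


def write_cohort(variants: Sequence[CohortVariant], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as handle:
        handle.write(
            "Tumor_Sample_Barcode\tHugo_Symbol\tChromosome\tStart_Position\t"
            "Reference_Allele\tTumor_Seq_Allele2\tVariant_Classification\t"
            "HGVSp_Short\tt_AF\n"
        )
        for v in variants:
            maf = "" if v.maf is None else f"{v.maf:.4f}"
            handle.write(
                f"{v.sample_id}\t{v.gene}\t{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t"
                f"{v.consequence}\t{v.protein_change}\t{maf}\n"
            )


def read_clinical(path: str | Path) -> list[ClinicalRecord]:
    path = Path(path)
    records = []
    chars = list(CHARACTERISTICS)
    with path.open() as handle:
        header = handle.readline().rstrip("\n").split("\t")
        expected = ["sample_id"] + chars
        if header != expected:
            raise _error(path, 1, f"expected columns {expected}, got {header}")
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != len(expected):
                raise _error(path, lineno, f"expected {len(expected)} fields")
            values = {
                char: (None if val == "NA" else val)
                for char, val in zip(chars, f[1:])
            }
            try:
                records.append(ClinicalRecord(sample_id=f[0], **values))
            except ValueError as exc:
                raise _error(path, lineno, str(exc)) from None
    return records


def write_clinical(records: Sequence[ClinicalRecord], path: str | Path) -> None:
    path = Path(path)
    chars = list(CHARACTERISTICS)
    with path.open("w") as handle:
        handle.write("sample_id\t" + "\t".join(chars) + "\n")
        for r in records:
            values = [getattr(r, c) or "NA" for c in chars]
            handle.write(r.sample_id + "\t" + "\t".join(values) + "\n")


# ---------------------------------------------------------------------------
# VCF (sites-only 4.2) writer
# ---------------------------------------------------------------------------

def write_vcf(calls: Iterable[VariantCall], path: str | Path) -> None:
    """Write calls as a minimal sites-only VCF 4.2 with DP/AO/AF INFO."""
    path = Path(path)
    lines = [
        "##fileformat=VCFv4.2",
        "##source=oncopanel",
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Site read depth">',
        '##INFO=<ID=AO,Number=1,Type=Integer,Description="Alternate allele observations">',
        '##INFO=<ID=AF,Number=1,Type=Float,Description="Alternate allele frequency">',
        '##FILTER=<ID=LOW_MAF,Description="Allele frequency below threshold">',
        '##FILTER=<ID=LOW_DEPTH,Description="Site depth below threshold">',
        '##FILTER=<ID=LOW_ALT_READS,Description="Too few supporting reads">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    ordered = sorted(calls, key=lambda c: (c.chrom, c.pos, c.ref, c.alt))
    for c in ordered:
        lines.append(
            f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\t{c.filter.value}\t"
            f"DP={c.depth};AO={c.alt_count};AF={c.maf:.4f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Resolved configuration for a pipeline run.

    Loadable from YAML or JSON; a resolved copy is written beside each
    run's outputs for provenance.
    """

    seed: int = 0
    maf_threshold: float = 0.05
    min_depth: int = 20
    min_alt_reads: int = 4
    median_depth: int = 1000
    error_rate: float = 0.001
    depth_dispersion: float = 20.0
    depth_grid: list[int] = field(default_factory=lambda: list(range(50, 1001, 50)))
    reps_low: int = 10
    reps_high: int = 3
    low_high_boundary: int = 500
    n_patients: int = 422
    n_truth_snvs: int = 40
    n_panel_sites: int = 60
    paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.maf_threshold < 1):
            raise ValueError("maf_threshold must be in (0, 1)")
        if self.median_depth < 1 or self.min_depth < 1:
            raise ValueError("depths must be positive")
        if not (0 <= self.error_rate <= 0.05):
            raise ValueError("error_rate must be in [0, 0.05]")
        if sorted(set(self.depth_grid)) != list(self.depth_grid):
            raise ValueError("depth_grid must be strictly increasing")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data: dict[str, Any]
        if path.suffix == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def write_resolved(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))
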