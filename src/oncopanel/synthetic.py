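"""Synthetic reference standards, amplicon pileups and patient cohorts.

Real analytical validation of a hotspot panel relies on engineered
reference standards (multiplexed DNA with known variants at known allele
fractions, typically 1-70%) sequenced to >1000x, and on a clinical FFPE
cohort.  Neither kind of raw data travels with this package, so this
module generates statistically faithful stand-ins:

* truth sets that mimic multiplex standards and their 1:1 mixtures
  (mixing dilutes each variant's expected MAF by exact weighted average);
* per-site allele-count pileups with overdispersed (negative-binomial)
  depth, binomial sampling of mutant reads and a uniform substitution
  error floor — enough structure to exercise sensitivity, PPV and MAF
  concordance end to end;
* patient cohorts with programmed gene mutation rates, covariate odds
  effects, hotspot positions and consequence-class mixes, plus
  missing-data rates matching a retrospective FFPE archive.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .calling import SitePileup, left_align, trim_alleles, variant_class
from .profiling import CohortVariant
from .association import CHARACTERISTICS, ClinicalRecord

__all__ = [
    "PanelTarget",
    "TruthVariant",
    "TruthSet",
    "CohortSimParams",
    "build_reference_standard",
    "mix_standards",
    "simulate_pileups",
    "simulate_cohort",
    "default_cohort_params",
    "calibrate_baseline_rates",
    "make_snv_panel",
    "make_validation_study",
]

_DNA = "ACGT"
_AA = "ARNDCQEGHILKMFPSTWYV"


@dataclass(frozen=True)
class PanelTarget:
    """One hotspot site of a targeted panel.

    ``ref_context`` is a short uppercase reference window centred on
    ``pos`` (1-based); it supplies the bases needed for indel
    left-normalization.
    """

    target_id: str
    chrom: str
    pos: int
    ref_context: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if not self.ref_context or set(self.ref_context) - set(_DNA):
            raise ValueError("ref_context must be a non-empty ACGT string")

    @property
    def context_offset(self) -> int:
        """1-based genomic position of the first context base."""
        return self.pos - (len(self.ref_context) - 1) // 2

    @property
    def ref_base(self) -> str:
        return self.ref_context[(len(self.ref_context) - 1) // 2]


@dataclass(frozen=True)
class TruthVariant:
    chrom: str
    pos: int
    ref: str
    alt: str
    expected_maf: float
    source_standard: str = ""

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt are identical")
        if not (0 < self.expected_maf <= 1):
            raise ValueError(
                f"expected_maf must be in (0, 1], got {self.expected_maf}"
            )
        if self.pos < 1:
            raise ValueError("pos must be >= 1")

    @property
    def variant_class(self) -> str:
        return variant_class(self.ref, self.alt)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class TruthSet:
    """A named set of known variants with expected allele fractions."""

    name: str
    variants: tuple[TruthVariant, ...]

    def __post_init__(self) -> None:
        keys = [v.key for v in self.variants]
        if len(keys) != len(set(keys)):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate variants in truth set: {dupes}")

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def keys(self) -> set[tuple[str, int, str, str]]:
        return {v.key for v in self.variants}

    def by_key(self) -> dict[tuple[str, int, str, str], TruthVariant]:
        return {v.key: v for v in self.variants}


def build_reference_standard(
    spec: Iterable[tuple[tuple[str, int, str, str], float]],
    name: str,
    panel: Sequence[PanelTarget] | None = None,
) -> TruthSet:
    """Assemble a truth set from ``((chrom, pos, ref, alt), expected_maf)`` pairs.

    Variants are left-normalized against the panel context when a panel is
    supplied, otherwise parsimony-trimmed.  Duplicate identities and MAFs
    outside (0, 1] are rejected.
    """
    contexts = (
        {(t.chrom, t.pos): (t.ref_context, t.context_offset) for t in panel}
        if panel
        else {}
    )
    variants = []
    for (chrom, pos, ref, alt), maf in spec:
        ctx = contexts.get((chrom, pos))
        if ctx is not None:
            pos, ref, alt = left_align(ctx[0], ctx[1], pos, ref, alt)
        else:
            pos, ref, alt = trim_alleles(pos, ref, alt)
        variants.append(
            TruthVariant(chrom, pos, ref, alt, expected_maf=maf, source_standard=name)
        )
    return TruthSet(name=name, variants=tuple(variants))


def mix_standards(
    a: TruthSet, b: TruthSet, ratio: tuple[float, float] = (0.5, 0.5)
) -> TruthSet:
    """Mix two standards; each variant's MAF is the exact weighted average.

    A variant absent from one parent contributes MAF 0 from that parent,
    so a 1:1 mix with a wild-type standard halves every MAF.
    """
    wa, wb = ratio
    if wa <= 0 or wb <= 0 or not math.isclose(wa + wb, 1.0):
        raise ValueError("ratio must be two positive fractions summing to 1")
    maf_a = {v.key: v.expected_maf for v in a.variants}
    maf_b = {v.key: v.expected_maf for v in b.variants}
    name = f"{a.name}+{b.name}({wa:g}:{wb:g})"
    variants = []
    for key in sorted(set(maf_a) | set(maf_b)):
        maf = wa * maf_a.get(key, 0.0) + wb * maf_b.get(key, 0.0)
        variants.append(TruthVariant(*key, expected_maf=maf, source_standard=name))
    return TruthSet(name=name, variants=tuple(variants))


def _allele_key(ref: str, alt: str) -> str:
    cls = variant_class(ref, alt)
    if cls == "SNV":
        return alt
    if cls == "INS":
        return f"ins:{alt[len(ref):]}"
    if cls == "DEL":
        return f"del:{len(ref) - len(alt)}"
    return f"delins:{ref}>{alt}"


def simulate_pileups(
    truth: TruthSet,
    panel: Sequence[PanelTarget],
    median_depth: int,
    error_rate: float = 0.001,
    depth_dispersion: float = 20.0,
    seed: int = 0,
    indel_error_rate: float | None = None,
    sample_id: str = "sim",
    run_id: str = "run1",
) -> list[SitePileup]:
    """Simulate one pileup per panel site with known allele fractions.

    Depth is negative-binomial with mean ``median_depth`` and shape
    ``depth_dispersion`` (amplicon coverage is overdispersed; the median
    of this distribution tracks its mean closely).  At truth sites mutant
    reads are Binomial(depth, expected_maf); every site then receives
    substitution noise of Binomial(remaining, error_rate/3) per non-ref
    base, and insertion noise at ``indel_error_rate`` (default 10x lower
    than ``error_rate``).  Counts always sum to depth.  Per-site random
    streams are derived from ``(seed, site_index)`` so any subset is
    reproducible.
    """
    if median_depth < 1:
        raise ValueError("median_depth must be >= 1")
    if not (0 <= error_rate <= 0.05):
        raise ValueError("error_rate must be in [0, 0.05]")
    if indel_error_rate is None:
        indel_error_rate = error_rate / 10.0

    by_site: dict[tuple[str, int], list[TruthVariant]] = {}
    for v in truth.variants:
        by_site.setdefault((v.chrom, v.pos), []).append(v)
    panel_sites = {(t.chrom, t.pos) for t in panel}
    orphans = sorted(set(by_site) - panel_sites)
    if orphans:
        raise ValueError(f"truth variants outside the panel: {orphans}")

    pileups: list[SitePileup] = []
    for i, target in enumerate(panel):
        rng = np.random.default_rng(np.random.SeedSequence((seed, i)))
        mean = float(median_depth)
        k = float(depth_dispersion)
        depth = int(rng.negative_binomial(k, k / (k + mean)))
        counts: dict[str, int] = {target.ref_base: 0}
        remaining = depth
        for v in sorted(
            by_site.get((target.chrom, target.pos), []), key=lambda v: v.key
        ):
            n_alt = min(int(rng.binomial(depth, v.expected_maf)), remaining)
            counts[_allele_key(v.ref, v.alt)] = n_alt
            remaining -= n_alt
        noise_pool = remaining
        if error_rate > 0:
            for base in _DNA:
                if base == target.ref_base or base in counts:
                    continue
                e = min(int(rng.binomial(noise_pool, error_rate / 3.0)), remaining)
                if e:
                    counts[base] = e
                    remaining -= e
        if indel_error_rate > 0 and noise_pool > 0:
            e = min(int(rng.binomial(noise_pool, indel_error_rate)), remaining)
            if e:
                ins = f"ins:{rng.choice(list(_DNA))}"
                counts[ins] = counts.get(ins, 0) + e
                remaining -= e
        counts[target.ref_base] = remaining
        pileups.append(
            SitePileup(
                chrom=target.chrom,
                pos=target.pos,
                ref=target.ref_base,
                allele_counts=counts,
                sample_id=sample_id,
                run_id=run_id,
            )
        )
    return pileups


def make_snv_panel(
    n_sites: int,
    chrom: str = "chr1",
    start: int = 1000,
    spacing: int = 200,
    context_len: int = 11,
    seed: int = 0,
) -> list[PanelTarget]:
    """Generate a small synthetic hotspot panel with random contexts."""
    rng = np.random.default_rng(seed)
    targets = []
    for i in range(n_sites):
        ctx = "".join(rng.choice(list(_DNA), size=context_len))
        targets.append(
            PanelTarget(
                target_id=f"T{i:04d}",
                chrom=chrom,
                pos=start + i * spacing,
                ref_context=ctx,
            )
        )
    return targets


DEFAULT_STUDY_MAFS = (0.10, 0.125, 0.15, 0.20, 0.25, 0.35)


def make_validation_study(
    seed: int,
    n_snvs: int = 40,
    mafs: Sequence[float] = DEFAULT_STUDY_MAFS,
    n_panel_sites: int = 48,
    median_depth: int = 1200,
    error_rate: float = 0.001,
) -> tuple[list[PanelTarget], TruthSet, list[SitePileup]]:
    """Standard desk-scale validation study: panel, truth set and pileups.

    Emulates a multiplexed reference standard sequenced past the top of
    the 50-1000x titration grid (real validation libraries land at
    1025-1469x median; targeting 1200x keeps the overdispersed median
    safely above 1000x so every grid depth is reachable): 40 SNVs
    with expected MAFs drawn from the given grid placed on a hotspot
    panel (the extra wild-type sites exercise specificity), simulated
    with a 0.1% substitution error floor.
    """
    if n_snvs > n_panel_sites:
        raise ValueError("panel must have at least as many sites as truth SNVs")
    panel = make_snv_panel(n_panel_sites, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 7001)))
    chosen = rng.choice(list(mafs), size=n_snvs)
    spec = []
    for target, maf in zip(panel[:n_snvs], chosen):
        alt = next(b for b in _DNA if b != target.ref_base)
        spec.append(((target.chrom, target.pos, target.ref_base, alt), float(maf)))
    truth = build_reference_standard(spec, "validation-standard", panel=panel)
    pileups = simulate_pileups(
        truth, panel, median_depth, error_rate=error_rate, seed=seed
    )
    return panel, truth, pileups


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

# Plausible gene anchors (chrom, coding-start) used to synthesize genomic
# coordinates from protein positions; values only need to be internally
# consistent, not biologically exact.
_GENE_ANCHORS: dict[str, tuple[str, int]] = {
    "EGFR": ("chr7", 55086725),
    "TP53": ("chr17", 7571720),
    "KRAS": ("chr12", 25358180),
    "PIK3CA": ("chr3", 178866311),
    "PTEN": ("chr10", 89623195),
    "NFE2L2": ("chr2", 178095031),
    "BRAF": ("chr7", 140433813),
    "CTNNB1": ("chr3", 41236328),
    "MET": ("chr7", 116312459),
    "ERBB2": ("chr17", 37844393),
    "ALK": ("chr2", 29415640),
    "STK11": ("chr19", 1205798),
}

_PROTEIN_FORMATS = {
    "missense": "p.{a}{pos}{b}",
    "nonsense": "p.{a}{pos}*",
    "frameshift": "p.{a}{pos}fs*{n}",
    "in_frame_del": "p.{a}{pos}_{b}{pos2}del",
    "in_frame_ins": "p.{a}{pos}_{b}{pos2}ins{a}{b}",
    "splice": "p.?",
    "other": "p.?",
}


@dataclass(frozen=True)
class CohortSimParams:
    """Generative settings for a synthetic clinical cohort.

    ``covariate_effects`` maps ``(gene, characteristic, level)`` to an
    odds multiplier applied on top of the gene's baseline mutation odds;
    ``covariate_level_probs`` gives each characteristic's level
    distribution among non-missing records and ``na_rates`` the missing
    fraction.  A mutated gene carries ``1 + Poisson(multi_hit_lambda)``
    variants, echoing real panels where some tumours carry two hits in
    one gene.
    """

    n_patients: int
    gene_baseline_rates: Mapping[str, float]
    covariate_effects: Mapping[tuple[str, str, str], float] = field(
        default_factory=dict
    )
    hotspot_distribution: Mapping[str, Mapping[int, float]] = field(
        default_factory=dict
    )
    consequence_mix: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    na_rates: Mapping[str, float] = field(default_factory=dict)
    covariate_level_probs: Mapping[str, Mapping[str, float]] = field(
        default_factory=dict
    )
    multi_hit_lambda: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        for gene, rate in self.gene_baseline_rates.items():
            if not (0 <= rate <= 1):
                raise ValueError(f"baseline rate for {gene} outside [0, 1]")
        for (gene, char, level), mult in self.covariate_effects.items():
            if gene not in self.gene_baseline_rates:
                raise ValueError(f"covariate effect references unknown gene {gene!r}")
            if char not in CHARACTERISTICS:
                raise ValueError(
                    f"covariate effect references unknown characteristic {char!r}"
                )
            if level not in CHARACTERISTICS[char]:
                raise ValueError(
                    f"covariate effect references unknown level {level!r} of {char!r}"
                )
            if mult <= 0:
                raise ValueError("odds multipliers must be > 0")
        for char, rate in self.na_rates.items():
            if char not in CHARACTERISTICS:
                raise ValueError(f"na_rates references unknown characteristic {char!r}")
            if not (0 <= rate <= 1):
                raise ValueError("NA rates must be in [0, 1]")


_DEFAULT_EFFECTS = {
    ("EGFR", "gender", "female"): 4.0,
    ("TP53", "gender", "female"): 0.35,
    ("PTEN", "gender", "female"): 0.25,
    ("EGFR", "age_group", "(45,65]"): 2.4,
    ("TP53", "age_group", "(17,45]"): 0.27,
    ("KRAS", "smoking", "yes"): 8.0,
    ("PIK3CA", "smoking", "yes"): 6.0,
    ("EGFR", "tumor_type", "metastatic"): 3.1,
    ("EGFR", "lymphatic_spread", "yes"): 2.4,
    ("TP53", "lymphatic_spread", "yes"): 2.2,
    ("EGFR", "grade", "moderate"): 2.0,
    ("TP53", "grade", "well"): 0.45,
    ("EGFR", "subtype", "SCC"): 0.15,
    ("TP53", "subtype", "SCC"): 6.0,
    ("PIK3CA", "subtype", "SCC"): 3.7,
    ("NFE2L2", "subtype", "SCC"): 16.0,
}

# Missing-data rates and level mixes of a retrospective FFPE archive.
_DEFAULT_NA_RATES = {
    "gender": 33 / 422,
    "age_group": 33 / 422,
    "smoking": 327 / 422,
    "tumor_type": 210 / 422,
    "lymphatic_spread": 191 / 422,
    "tumor_site": 377 / 422,
    "grade": 152 / 422,
    "subtype": 144 / 422,
}

_DEFAULT_LEVEL_PROBS = {
    "gender": {"female": 198 / 389, "male": 191 / 389},
    "age_group": {"(17,45]": 116 / 389, "(45,65]": 190 / 389, "(65,86]": 83 / 389},
    "smoking": {"no": 82 / 95, "yes": 13 / 95},
    "tumor_type": {"primary": 190 / 212, "metastatic": 22 / 212},
    "lymphatic_spread": {"no": 158 / 231, "yes": 73 / 231},
    "tumor_site": {"left_lung": 26 / 45, "right_lung": 19 / 45},
    "grade": {"poor": 51 / 270, "moderate": 136 / 270, "well": 83 / 270},
    "subtype": {"ACA": 217 / 278, "adenosquamous": 4 / 278,
                "large_cell": 1 / 278, "SCC": 56 / 278},
}


def calibrate_baseline_rates(
    target_rates: Mapping[str, float],
    covariate_effects: Mapping[tuple[str, str, str], float],
    covariate_level_probs: Mapping[str, Mapping[str, float]],
    na_rates: Mapping[str, float],
) -> dict[str, float]:
    """Solve per-gene logistic intercepts so marginal rates hit targets.

    Covariate odds multipliers shift most patients away from the
    intercept, so a gene's marginal mutation rate exceeds its baseline
    unless the intercept is lowered to compensate.  For each gene the
    expected rate under the (independent) covariate distribution is
    matched to ``target_rates[gene]`` by bisection on the intercept.
    Returns baseline rates (expit of the solved intercepts).
    """
    import itertools

    out: dict[str, float] = {}
    for gene, target in target_rates.items():
        chars = sorted({c for (g, c, _l) in covariate_effects if g == gene})
        if not chars or not (0 < target < 1):
            out[gene] = target
            continue
        level_sets = []
        for char in chars:
            na = na_rates.get(char, 0.0)
            probs = covariate_level_probs.get(char, {})
            levels = CHARACTERISTICS[char]
            ps = np.array([probs.get(lv, 0.0) for lv in levels], dtype=float)
            ps = ps / ps.sum() if ps.sum() else np.full(len(levels), 1 / len(levels))
            level_sets.append(
                [(char, lv, (1 - na) * p) for lv, p in zip(levels, ps)]
                + [(char, None, na)]
            )
        combos = []
        for combo in itertools.product(*level_sets):
            weight = math.prod(p for _c, _l, p in combo)
            if weight == 0:
                continue
            shift = sum(
                math.log(covariate_effects.get((gene, c, lv), 1.0))
                for c, lv, _p in combo
                if lv is not None
            )
            combos.append((weight, shift))

        def marginal(b: float) -> float:
            return sum(w / (1 + math.exp(-(b + s))) for w, s in combos)

        lo, hi = -20.0, 20.0
        for _ in range(100):
            mid = 0.5 * (lo + hi)
            if marginal(mid) < target:
                lo = mid
            else:
                hi = mid
        out[gene] = 1 / (1 + math.exp(-0.5 * (lo + hi)))
    return out


def default_cohort_params(n_patients: int = 422, seed: int = 0) -> CohortSimParams:
    """Study-condition defaults for the cohort generator.

    Baseline per-patient mutation rates follow the observed NSCLC panel
    frequencies (EGFR mutated in ~42% of patients, TP53 ~32%, KRAS ~5%,
    ...), covariate odds effects encode the reported clinicopathological
    associations (EGFR enriched in women, adenocarcinoma and
    lymphatic-spread tumours; TP53 in men, squamous and older patients;
    KRAS in smokers), hotspot weights follow the published residue
    tallies (EGFR L858/E746/T790, TP53 R273/G266/R213/..., KRAS G12) and
    the missing-data rates mirror a retrospective FFPE archive.
    Baseline intercepts are calibrated so each gene's marginal
    per-patient rate matches its target despite the covariate effects.
    """
    marginal_rates = {
        "EGFR": 0.42,
        "TP53": 0.30,
        "KRAS": 0.055,
        "PIK3CA": 0.048,
        "PTEN": 0.036,
        "NFE2L2": 0.012,
        "BRAF": 0.010,
        "CTNNB1": 0.012,
        "MET": 0.010,
        "ERBB2": 0.010,
    }
    return CohortSimParams(
        n_patients=n_patients,
        seed=seed,
        gene_baseline_rates=calibrate_baseline_rates(
            marginal_rates, _DEFAULT_EFFECTS, _DEFAULT_LEVEL_PROBS, _DEFAULT_NA_RATES
        ),
        covariate_effects=dict(_DEFAULT_EFFECTS),
        hotspot_distribution={
            "EGFR": {858: 0.35, 746: 0.28, 790: 0.04, 719: 0.05, 768: 0.03},
            "TP53": {273: 0.071, 266: 0.057, 213: 0.050, 175: 0.043, 280: 0.043,
                     248: 0.036, 282: 0.036, 245: 0.014, 249: 0.007},
            "KRAS": {12: 0.80, 13: 0.10, 61: 0.10},
            "PIK3CA": {542: 0.30, 545: 0.30, 1047: 0.30},
            "PTEN": {333: 0.50, 130: 0.15},
            "NFE2L2": {29: 0.60, 34: 0.30},
            "BRAF": {600: 0.70},
            "CTNNB1": {41: 0.40, 45: 0.40},
        },
        consequence_mix={
            "EGFR": {"missense": 0.60, "in_frame_del": 0.30, "in_frame_ins": 0.06,
                     "other": 0.04},
            "TP53": {"missense": 0.74, "nonsense": 0.14, "frameshift": 0.08,
                     "splice": 0.04},
            "KRAS": {"missense": 1.0},
            "PIK3CA": {"missense": 1.0},
            "PTEN": {"in_frame_ins": 0.45, "missense": 0.30, "frameshift": 0.25},
            "NFE2L2": {"missense": 1.0},
            "CTNNB1": {"missense": 1.0},
        },
        na_rates=dict(_DEFAULT_NA_RATES),
        covariate_level_probs={k: dict(v) for k, v in _DEFAULT_LEVEL_PROBS.items()},
    )


def _sample_covariates(
    params: CohortSimParams, rng: np.random.Generator
) -> dict[str, list[str | None]]:
    """Sample per-patient characteristic levels (None encodes NA)."""
    n = params.n_patients
    out: dict[str, list[str | None]] = {}
    for char, levels in CHARACTERISTICS.items():
        na = params.na_rates.get(char, 0.0)
        probs = params.covariate_level_probs.get(char)
        if probs is None:
            level_p = np.full(len(levels), 1.0 / len(levels))
        else:
            level_p = np.array([probs.get(lv, 0.0) for lv in levels], dtype=float)
            level_p = level_p / level_p.sum()
        full_p = np.concatenate([(1 - na) * level_p, [na]])
        full_p = full_p / full_p.sum()
        choices = list(levels) + [None]
        idx = rng.choice(len(choices), size=n, p=full_p)
        out[char] = [choices[i] for i in idx]
    return out


def simulate_cohort(
    params: CohortSimParams,
) -> tuple[list[CohortVariant], list[ClinicalRecord]]:
    """Draw a synthetic cohort with programmed associations.

    Per patient, each gene's mutation indicator follows a logistic model:
    baseline odds times the product of the odds multipliers matching the
    patient's non-missing covariate levels.  Mutated genes receive
    ``1 + Poisson(multi_hit_lambda)`` variants whose protein positions,
    consequence classes and allele fractions are drawn from the
    configured distributions.  Deterministic under ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_patients
    sample_ids = [f"S{i + 1:05d}" for i in range(n)]
    covars = _sample_covariates(params, rng)

    records = [
        ClinicalRecord(
            sample_id=sample_ids[i],
            **{char: covars[char][i] for char in CHARACTERISTICS},
        )
        for i in range(n)
    ]

    variants: list[CohortVariant] = []
    genes = sorted(params.gene_baseline_rates)
    for gene in genes:
        base = params.gene_baseline_rates[gene]
        if base <= 0:
            continue
        logit = np.full(n, math.log(base / (1 - base)) if base < 1 else math.inf)
        for (g, char, level), mult in params.covariate_effects.items():
            if g != gene:
                continue
            mask = np.array([covars[char][i] == level for i in range(n)])
            logit = logit + mask * math.log(mult)
        p = 1.0 / (1.0 + np.exp(-logit))
        mutated = rng.random(n) < p
        chrom, anchor = _GENE_ANCHORS.get(gene, ("chrX", 1_000_000))
        hotspots = params.hotspot_distribution.get(gene)
        mix = params.consequence_mix.get(gene, {"missense": 1.0})
        classes = sorted(mix)
        class_p = np.array([mix[c] for c in classes], dtype=float)
        class_p = class_p / class_p.sum()
        if hotspots:
            hs_pos = sorted(hotspots)
            hs_w = np.array([hotspots[q] for q in hs_pos], dtype=float)
            # leftover weight spreads uniformly over a background window
            background = max(0.0, 1.0 - hs_w.sum())
        for i in np.flatnonzero(mutated):
            k = 1 + rng.poisson(params.multi_hit_lambda)
            for _ in range(k):
                if hotspots and rng.random() >= background:
                    ppos = int(hs_pos[rng.choice(len(hs_pos), p=hs_w / hs_w.sum())])
                else:
                    ppos = int(rng.integers(1, 501))
                cons = classes[rng.choice(len(classes), p=class_p)]
                a, b = rng.choice(list(_AA), size=2, replace=False)
                span = int(rng.integers(1, 6))
                protein_change = _PROTEIN_FORMATS[cons].format(
                    a=a, b=b, pos=ppos, pos2=ppos + span, n=int(rng.integers(2, 30))
                )
                ref, alt = rng.choice(list(_DNA), size=2, replace=False)
                variants.append(
                    CohortVariant(
                        sample_id=sample_ids[i],
                        gene=gene,
                        chrom=chrom,
                        pos=anchor + 3 * ppos,
                        ref=str(ref),
                        alt=str(alt),
                        consequence=cons,
                        protein_change=protein_change,
                        maf=round(float(rng.uniform(0.05, 0.60)), 4),
                    )
                )
    return variants, records
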