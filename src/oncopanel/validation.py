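"""Analytical validation of the panel: depth titration, sensitivity/PPV
per MAF stratum, allele-fraction concordance, cross-platform concordance
and replicate reproducibility.

The central procedure mirrors how targeted assays are validated against
engineered reference standards: sequence deep (>1000x), computationally
thin the coverage to a grid of target depths (10 replicates per depth up
to 500x, 3 above), re-call variants at each depth, and score every
(variant, replicate) trial against the truth set.  Sensitivity pools
detected trials over trials; PPV is TP / (TP + FP) over called variants.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from statistics import median
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as _stats

from .calling import CallerConfig, SitePileup, VariantCall, call_sample
from .synthetic import TruthSet, TruthVariant

__all__ = [
    "ConcordanceResult",
    "TitrationPlan",
    "ValidationCell",
    "classify_calls",
    "downsample_pileups",
    "maf_concordance",
    "maf_stratum",
    "method_concordance",
    "replicate_count",
    "reproducibility",
    "run_titration",
    "titration_frame",
]

STRATA = ("lt5", "5to10", "ge10")


@dataclass(frozen=True)
class TitrationPlan:
    """Depth grid and replicate scheme for the downsampling titration.

    Defaults follow the standard design: target median depths 50, 100,
    ..., 1000 with 10 subsampling replicates per depth up to and
    including ``low_high_boundary`` (500x) and 3 replicates above it.
    """

    depth_grid: tuple[int, ...] = tuple(range(50, 1001, 50))
    reps_low: int = 10
    reps_high: int = 3
    low_high_boundary: int = 500

    def __post_init__(self) -> None:
        if list(self.depth_grid) != sorted(set(self.depth_grid)):
            raise ValueError("depth_grid must be strictly increasing")
        if self.reps_low < 1 or self.reps_high < 1:
            raise ValueError("replicate counts must be >= 1")


@dataclass(frozen=True)
class ValidationCell:
    """Aggregated detection performance at one (depth, MAF stratum)."""

    depth_target: int
    maf_stratum: str
    n_trials: int
    n_detected: int
    tp: int
    fp: int

    @property
    def sensitivity(self) -> float:
        return self.n_detected / self.n_trials if self.n_trials else float("nan")

    @property
    def ppv(self) -> float | None:
        """TP/(TP+FP); None (undefined) when no calls landed in the cell."""
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else None


@dataclass(frozen=True)
class ConcordanceResult:
    shared: int
    only_a: int
    only_b: int

    @property
    def concordance(self) -> float:
        total = self.shared + self.only_a + self.only_b
        return self.shared / total if total else float("nan")


def maf_stratum(expected_maf: float) -> str:
    """Half-open MAF strata: [0, 5%), [5%, 10%), [10%, 100%]."""
    if expected_maf < 0.05:
        return "lt5"
    if expected_maf < 0.10:
        return "5to10"
    return "ge10"


def replicate_count(depth: int, plan: TitrationPlan | None = None) -> int:
    """Subsampling replicates at a grid depth (10 up to 500x, 3 above)."""
    plan = plan or TitrationPlan()
    if depth not in plan.depth_grid:
        raise ValueError(f"depth {depth} is not on the titration grid")
    return plan.reps_low if depth <= plan.low_high_boundary else plan.reps_high


def downsample_pileups(
    pileups: Sequence[SitePileup], target_median: int, seed: int = 0
) -> list[SitePileup]:
    """Thin pileups to a target median depth by binomial subsampling.

    Each read is retained independently with probability
    ``target_median / current_median``, which at pileup granularity is a
    binomial thinning of every allele count — the exact marginal of
    subsampling read records.  Allele fractions are unbiased.
    Deterministic for a fixed seed (per-site streams derive from
    ``(seed, site_index)``).
    """
    if not pileups:
        raise ValueError("no pileups to downsample")
    current = median(p.depth for p in pileups)
    if target_median > current:
        raise ValueError(
            f"target median {target_median} exceeds current median {current:g}"
        )
    retain = target_median / current
    out = []
    for i, p in enumerate(pileups):
        rng = np.random.default_rng(np.random.SeedSequence((seed, i)))
        counts = {
            allele: int(rng.binomial(count, retain))
            for allele, count in sorted(p.allele_counts.items())
        }
        counts[p.ref] = counts.get(p.ref, 0)
        out.append(
            SitePileup(
                chrom=p.chrom,
                pos=p.pos,
                ref=p.ref,
                allele_counts=counts,
                sample_id=p.sample_id,
                run_id=p.run_id,
            )
        )
    return out


def classify_calls(
    calls: Iterable[VariantCall] | Mapping[tuple, VariantCall],
    truth: TruthSet,
) -> tuple[list[VariantCall], list[VariantCall], list[TruthVariant]]:
    """Partition calls into TP / FP and truth into detected / FN.

    Matching is exact on the normalized (chrom, pos, ref, alt) identity —
    a call at the right position with the wrong allele is an FP and
    leaves its truth variant undetected.
    """
    call_list = list(calls.values()) if isinstance(calls, Mapping) else list(calls)
    truth_keys = truth.keys
    tp = [c for c in call_list if c.key in truth_keys]
    fp = [c for c in call_list if c.key not in truth_keys]
    detected = {c.key for c in tp}
    fn = [v for v in truth.variants if v.key not in detected]
    return tp, fp, fn


def _cell_seed(master: int, depth: int, rep: int) -> int:
    """Deterministic per-(depth, replicate) seed derived from the master."""
    return int(np.random.SeedSequence((master, depth, rep)).generate_state(1)[0])


def run_titration(
    pileups: Sequence[SitePileup],
    truth: TruthSet,
    plan: TitrationPlan | None = None,
    config: CallerConfig | None = None,
    seed: int = 0,
    contexts: Mapping[tuple[str, int], tuple[str, int]] | None = None,
) -> list[ValidationCell]:
    """Full depth titration: downsample, re-call and score per stratum.

    For each grid depth and replicate the pileups are binomially thinned,
    called with ``config`` and classified against ``truth``.  Cells pool
    (variant x replicate) trials per (depth, expected-MAF stratum); false
    positives are binned by their observed MAF so every call is accounted
    for exactly once per cell row.
    """
    plan = plan or TitrationPlan()
    config = config or CallerConfig()
    cells = []
    truth_strata = {v.key: maf_stratum(v.expected_maf) for v in truth.variants}
    n_in_stratum = {
        s: sum(1 for v in truth.variants if maf_stratum(v.expected_maf) == s)
        for s in STRATA
    }
    for depth in plan.depth_grid:
        reps = replicate_count(depth, plan)
        detected = {s: 0 for s in STRATA}
        fp_by_stratum = {s: 0 for s in STRATA}
        for rep in range(reps):
            thin = downsample_pileups(pileups, depth, seed=_cell_seed(seed, depth, rep))
            calls, _ = call_sample(thin, config, contexts=contexts)
            tp, fp, _fn = classify_calls(calls, truth)
            for c in tp:
                detected[truth_strata[c.key]] += 1
            for c in fp:
                fp_by_stratum[maf_stratum(c.maf)] += 1
        for s in STRATA:
            if n_in_stratum[s] == 0 and fp_by_stratum[s] == 0:
                continue
            cells.append(
                ValidationCell(
                    depth_target=depth,
                    maf_stratum=s,
                    n_trials=n_in_stratum[s] * reps,
                    n_detected=detected[s],
                    tp=detected[s],
                    fp=fp_by_stratum[s],
                )
            )
    return cells


def titration_frame(cells: Sequence[ValidationCell]):
    """Tabulate titration cells (TSV-ready pandas frame)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "depth": c.depth_target,
                "stratum": c.maf_stratum,
                "n_trials": c.n_trials,
                "n_detected": c.n_detected,
                "sensitivity": c.sensitivity,
                "tp": c.tp,
                "fp": c.fp,
                "ppv": c.ppv,
            }
            for c in cells
        ]
    )


def pooled_sensitivity(
    cells: Sequence[ValidationCell],
    depth: int | None = None,
    strata: Sequence[str] = ("5to10", "ge10"),
) -> float:
    """Detected trials / total trials pooled over the selected cells."""
    chosen = [
        c
        for c in cells
        if c.maf_stratum in strata and (depth is None or c.depth_target == depth)
    ]
    trials = sum(c.n_trials for c in chosen)
    return sum(c.n_detected for c in chosen) / trials if trials else float("nan")


def pooled_ppv(cells: Sequence[ValidationCell]) -> float | None:
    """Total TP / (TP + FP) over all cells; None when nothing was called."""
    tp = sum(c.tp for c in cells)
    fp = sum(c.fp for c in cells)
    return tp / (tp + fp) if tp + fp else None


def maf_concordance(
    pairs: Sequence[tuple[float, float]],
) -> tuple[float, float, float]:
    """Least-squares agreement of observed vs expected allele fractions.

    Returns (pearson_r, slope, intercept) of observed on expected.
    Requires at least 3 pairs with non-constant expected values.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 (expected, observed) pairs")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("expected MAFs are constant; fit is degenerate")
    fit = _stats.linregress(x, y)
    return float(fit.rvalue), float(fit.slope), float(fit.intercept)


def method_concordance(
    calls_a: Iterable,
    calls_b: Iterable,
    tested_sites: Sequence[tuple[str, int]] | None = None,
) -> ConcordanceResult:
    """Overlap of two platforms' positive calls at commonly tested sites.

    Inputs are call sets (anything with a ``key`` attribute, or raw
    identity tuples).  Concordance = shared / (shared + only in A + only
    in B).  Symmetric in its arguments.
    """

    def keyset(calls: Iterable) -> set:
        out = set()
        for c in calls:
            out.add(c.key if hasattr(c, "key") else tuple(c))
        return out

    a, b = keyset(calls_a), keyset(calls_b)
    if tested_sites is not None:
        sites = set(tested_sites)
        a = {k for k in a if (k[0], k[1]) in sites}
        b = {k for k in b if (k[0], k[1]) in sites}
    return ConcordanceResult(
        shared=len(a & b), only_a=len(a - b), only_b=len(b - a)
    )


def reproducibility(
    replicates: Sequence[tuple[str, Iterable]],
    expected: TruthSet,
) -> tuple[float, float, float]:
    """Replicate agreement against an expected variant set.

    ``replicates`` is a sequence of (run_id, call set) pairs — e.g. five
    library replicates spread over three runs.  Returns
    ``(overall, inter_run, intra_run)``:

    * overall — detected (expected variant, replicate) events divided by
      ``len(expected) * n_replicates``;
    * inter_run / intra_run — mean pairwise agreement (fraction of
      expected variants both detected or both missed) over replicate
      pairs from different runs / the same run; NaN when a partition has
      no pairs.
    """
    if len(replicates) < 2:
        raise ValueError("need at least 2 replicates")
    if not expected.variants:
        raise ValueError("expected variant set is empty")
    exp_keys = sorted(expected.keys)
    detection = []
    runs = []
    for run_id, calls in replicates:
        keys = {c.key if hasattr(c, "key") else tuple(c) for c in calls}
        detection.append(np.array([k in keys for k in exp_keys]))
        runs.append(run_id)
    overall = float(np.mean(detection))

    def mean_agreement(pairs: list[tuple[int, int]]) -> float:
        if not pairs:
            return float("nan")
        return float(
            np.mean([np.mean(detection[i] == detection[j]) for i, j in pairs])
        )

    inter = [
        (i, j)
        for i, j in itertools.combinations(range(len(runs)), 2)
        if runs[i] != runs[j]
    ]
    intra = [
        (i, j)
        for i, j in itertools.combinations(range(len(runs)), 2)
        if runs[i] == runs[j]
    ]
    return overall, mean_agreement(inter), mean_agreement(intra)
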