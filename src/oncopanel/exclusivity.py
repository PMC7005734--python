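"""Pairwise mutual-exclusivity / co-occurrence analysis.

Collapses the cohort to a binary sample x gene event matrix and tests
every unordered gene pair with a two-sided Fisher exact test on the
sample-level 2x2 (both, A only, B only, neither).  The odds ratio uses
exact 0 / infinity conventions for zero cells (no continuity
correction), and a pair is labelled mutually exclusive (OR < 1) or
co-occurring (OR > 1) only when its p-value clears the significance
threshold.  Unadjusted p-values are reported by default — the usual
convention for pairwise displays — with optional Bonferroni or
Benjamini–Hochberg adjustment.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .association import fisher_2x2
from .profiling import CohortVariant

__all__ = ["ExclusivityResult", "event_matrix", "pairwise_exclusivity"]


@dataclass(frozen=True)
class ExclusivityResult:
    gene_a: str
    gene_b: str
    both: int
    a_only: int
    b_only: int
    neither: int
    odds_ratio: float
    p_value: float
    direction: str  # mutually_exclusive | co_occurring | none


def event_matrix(
    cohort: Sequence[CohortVariant], samples: Sequence[str]
) -> pd.DataFrame:
    """Binary sample x gene matrix; multi-hit collapses to a single 1."""
    samples = list(samples)
    if len(samples) != len(set(samples)):
        raise ValueError("sample list contains duplicates")
    index = set(samples)
    unknown = sorted({v.sample_id for v in cohort} - index)
    if unknown:
        raise ValueError(f"cohort variants reference unknown samples: {unknown}")
    genes = sorted({v.gene for v in cohort})
    matrix = pd.DataFrame(0, index=samples, columns=genes, dtype=np.int8)
    for v in cohort:
        matrix.at[v.sample_id, v.gene] = 1
    return matrix


def _odds_ratio(both: int, a_only: int, b_only: int, neither: int) -> float:
    num = both * neither
    den = a_only * b_only
    if den == 0:
        return float("nan") if num == 0 else math.inf
    return num / den


def pairwise_exclusivity(
    matrix: pd.DataFrame,
    genes: Sequence[str] | None = None,
    alpha: float = 0.05,
    adjust: str | None = None,
) -> list[ExclusivityResult]:
    """Exact test for every unordered gene pair with >= 1 event each.

    ``adjust`` may be ``None`` (raw p, default), ``"bonferroni"`` or
    ``"bh"``; direction labels use the adjusted value when adjustment is
    requested.  Sub-setting ``genes`` never changes a retained pair's
    counts or p-value (each pair's 2x2 depends only on its two columns).
    """
    cols = list(genes) if genes is not None else list(matrix.columns)
    cols = [g for g in cols if matrix[g].sum() > 0]
    if len(cols) < 2:
        raise ValueError("need >= 2 genes with >= 1 event each")
    raw: list[tuple[str, str, int, int, int, int, float, float]] = []
    for ga, gb in itertools.combinations(cols, 2):
        a = matrix[ga].to_numpy(dtype=bool)
        b = matrix[gb].to_numpy(dtype=bool)
        both = int((a & b).sum())
        a_only = int((a & ~b).sum())
        b_only = int((~a & b).sum())
        neither = int((~a & ~b).sum())
        p = fisher_2x2([[both, a_only], [b_only, neither]])
        raw.append((ga, gb, both, a_only, b_only, neither, _odds_ratio(both, a_only, b_only, neither), p))

    pvals = np.array([r[7] for r in raw])
    if adjust is None:
        adjusted = pvals
    elif adjust == "bonferroni":
        adjusted = np.minimum(1.0, pvals * len(pvals))
    elif adjust == "bh":
        order = np.argsort(pvals)
        m = len(pvals)
        adj = np.empty(m)
        running = 1.0
        for rank in range(m - 1, -1, -1):
            i = order[rank]
            running = min(running, pvals[i] * m / (rank + 1))
            adj[i] = running
        adjusted = adj
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")

    results = []
    for (ga, gb, both, a_only, b_only, neither, oratio, p), p_adj in zip(raw, adjusted):
        if p_adj <= alpha and not math.isnan(oratio) and oratio < 1:
            direction = "mutually_exclusive"
        elif p_adj <= alpha and oratio > 1:
            direction = "co_occurring"
        else:
            direction = "none"
        results.append(
            ExclusivityResult(ga, gb, both, a_only, b_only, neither, oratio, float(p_adj), direction)
        )
    return results
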