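"""Clinicopathological association testing.

Builds gene x characteristic contingency tables from a mutation cohort
and clinical covariates (listwise NA exclusion per characteristic), runs
two-sided Fisher exact tests — 2x2 via scipy, r x 2 via an exact
Freeman–Halton enumeration — and Bonferroni-adjusted pairwise
comparisons for multi-level characteristics.

The two-sided rule throughout is the minimum-likelihood convention used
by R's ``fisher.test``: sum the point probabilities of every table (with
the observed margins) whose probability does not exceed the observed
table's, with a ``1 + 1e-7`` relative tolerance on the comparison.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln
from scipy.stats import fisher_exact as _scipy_fisher

from .profiling import CohortVariant

__all__ = [
    "CHARACTERISTICS",
    "AssociationResult",
    "ClinicalRecord",
    "ContingencyTable",
    "association_report",
    "contingency",
    "fisher_2x2",
    "fisher_rx2",
    "mutated_sample_sets",
    "pairwise_bonferroni",
    "stars",
]

logger = logging.getLogger(__name__)

# Characteristic -> ordered levels (NA encoded as None on the records).
CHARACTERISTICS: dict[str, tuple[str, ...]] = {
    "gender": ("male", "female"),
    "age_group": ("(17,45]", "(45,65]", "(65,86]"),
    "smoking": ("yes", "no"),
    "tumor_type": ("metastatic", "primary"),
    "lymphatic_spread": ("yes", "no"),
    "tumor_site": ("left_lung", "right_lung"),
    "grade": ("poor", "moderate", "well"),
    "subtype": ("ACA", "SCC", "adenosquamous", "large_cell"),
}

# Histologic subtypes actually contrasted in association tests; the rare
# mixed/large-cell categories are excluded as groups too small to test.
SUBTYPE_TEST_LEVELS = ("ACA", "SCC")

_REL_TOL = 1 + 1e-7


@dataclass(frozen=True)
class ClinicalRecord:
    """Per-sample clinicopathological covariates; ``None`` means NA."""

    sample_id: str
    gender: str | None = None
    age_group: str | None = None
    smoking: str | None = None
    tumor_type: str | None = None
    lymphatic_spread: str | None = None
    tumor_site: str | None = None
    grade: str | None = None
    subtype: str | None = None

    def __post_init__(self) -> None:
        for char, levels in CHARACTERISTICS.items():
            value = getattr(self, char)
            if value is not None and value not in levels:
                raise ValueError(
                    f"unknown level {value!r} for characteristic {char!r}"
                )


@dataclass(frozen=True)
class ContingencyTable:
    """Rows of (wild-type count, mutant count), one per group level."""

    group_labels: tuple[str, ...]
    rows: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.rows) < 2 or len(self.rows) != len(self.group_labels):
            raise ValueError("need >= 2 labelled rows")
        if any(wt < 0 or mut < 0 for wt, mut in self.rows):
            raise ValueError("counts must be non-negative")

    @property
    def frequencies(self) -> tuple[float, ...]:
        """Mutation frequency per level: mutant / (wild type + mutant)."""
        return tuple(
            mut / (wt + mut) if wt + mut else float("nan") for wt, mut in self.rows
        )


@dataclass(frozen=True)
class AssociationResult:
    gene: str
    characteristic: str
    table: ContingencyTable
    p_value: float
    pairwise_adjusted: dict[tuple[str, str], float] = field(default_factory=dict)

    @property
    def stars(self) -> str:
        return stars(self.p_value)

    @property
    def significant(self) -> bool:
        return self.p_value <= 0.05


def stars(p: float) -> str:
    """Significance marker: *, **, *** at p <= 0.05 / 0.01 / 0.001."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def mutated_sample_sets(cohort: Iterable[CohortVariant]) -> dict[str, set[str]]:
    """Gene -> set of samples carrying >= 1 variant in that gene."""
    out: dict[str, set[str]] = {}
    for v in cohort:
        out.setdefault(v.gene, set()).add(v.sample_id)
    return out


def contingency(
    mutated_samples: set[str],
    clinical: Sequence[ClinicalRecord],
    characteristic: str,
    level_filter: Sequence[str] | None = None,
) -> ContingencyTable:
    """Build the (wild type, mutant) table for one gene and characteristic.

    Samples whose value for the characteristic is NA are excluded
    (listwise per characteristic).  For histologic subtype only the two
    major groups are contrasted unless ``level_filter`` overrides.
    Raises when fewer than two non-empty levels remain.
    """
    if characteristic not in CHARACTERISTICS:
        raise ValueError(f"unknown characteristic {characteristic!r}")
    levels = level_filter or (
        SUBTYPE_TEST_LEVELS
        if characteristic == "subtype"
        else CHARACTERISTICS[characteristic]
    )
    rows = []
    labels = []
    for level in levels:
        members = [r for r in clinical if getattr(r, characteristic) == level]
        mut = sum(1 for r in members if r.sample_id in mutated_samples)
        wt = len(members) - mut
        if members:
            labels.append(level)
            rows.append((wt, mut))
    if len(rows) < 2:
        raise ValueError(
            f"fewer than 2 non-empty levels for {characteristic!r} after NA exclusion"
        )
    return ContingencyTable(tuple(labels), tuple(rows))


def fisher_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    A table with a zero row or column margin carries no information about
    association; by convention p = 1 is returned (with a warning).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("fisher_2x2 needs a non-negative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        logger.warning("fisher_2x2: zero margin in %s; returning p=1", t.tolist())
        return 1.0
    return float(_scipy_fisher(t).pvalue)


def _log_table_prob(xs: np.ndarray, margins: np.ndarray, n: int, c1: int) -> np.ndarray:
    """Log multivariate-hypergeometric probability of r x 2 tables whose
    first-column entries are the rows of ``xs``."""
    logp = -(gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    for i, m in enumerate(margins):
        x = xs[:, i]
        logp = logp + (
            gammaln(m + 1) - gammaln(x + 1) - gammaln(m - x + 1)
        )
    return logp


def fisher_rx2(
    table: Sequence[Sequence[int]], max_tables: int = 5_000_000
) -> float:
    """Freeman–Halton exact test for an r x 2 table.

    Enumerates every table sharing the observed margins and sums the
    multivariate hypergeometric probabilities not exceeding the observed
    table's (minimum-likelihood two-sided rule).  Reduces to
    :func:`fisher_2x2` at r = 2.  Raises when the enumeration would
    exceed ``max_tables`` (use a Monte-Carlo approach for such tables).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or t.shape[1] != 2 or t.shape[0] < 2 or (t < 0).any():
        raise ValueError("fisher_rx2 needs a non-negative r x 2 table (r >= 2)")
    margins = t.sum(axis=1)
    n = int(t.sum())
    c1 = int(t[:, 0].sum())
    if n == 0 or c1 == 0 or c1 == n or (margins == 0).all():
        logger.warning("fisher_rx2: degenerate margins; returning p=1")
        return 1.0

    bound = 1
    for m in margins:
        bound *= min(int(m), c1) + 1
        if bound > max_tables:
            raise ValueError(
                f"enumeration bound exceeds {max_tables} tables; "
                "consider a Monte-Carlo approximation"
            )

    ranges = [range(int(m) + 1) for m in margins[:-1]]
    tables = []
    for head in itertools.product(*ranges):
        last = c1 - sum(head)
        if 0 <= last <= margins[-1]:
            tables.append(head + (last,))
    xs = np.array(tables, dtype=np.int64)
    logps = _log_table_prob(xs, margins, n, c1)
    obs = np.array([t[:, 0]], dtype=np.int64)
    logp_obs = _log_table_prob(obs, margins, n, c1)[0]
    probs = np.exp(logps)
    return float(min(1.0, probs[probs <= math.exp(logp_obs) * _REL_TOL].sum()))


def pairwise_bonferroni(
    table: ContingencyTable,
) -> dict[tuple[str, str], float]:
    """Bonferroni-adjusted pairwise 2x2 Fisher tests between row levels.

    The multiplier is the number of pairwise comparisons, C(r, 2);
    adjusted p-values are capped at 1.
    """
    r = len(table.rows)
    if r < 3:
        raise ValueError("pairwise comparisons need >= 3 levels")
    n_pairs = r * (r - 1) // 2
    out: dict[tuple[str, str], float] = {}
    for (la, ra), (lb, rb) in itertools.combinations(
        zip(table.group_labels, table.rows), 2
    ):
        raw = fisher_2x2([list(ra), list(rb)])
        out[(la, lb)] = min(1.0, raw * n_pairs)
    return out


def association_report(
    cohort: Sequence[CohortVariant],
    clinical: Sequence[ClinicalRecord],
    genes: Sequence[str] | None = None,
    characteristics: Sequence[str] | None = None,
    alpha: float = 0.05,
    show_all: bool = False,
) -> list[AssociationResult]:
    """Test every gene x characteristic combination.

    Multi-level characteristics get a Freeman–Halton omnibus test plus
    Bonferroni-adjusted pairwise comparisons; two-level ones a plain 2x2
    Fisher test.  Unless ``show_all`` is set, only results with
    p <= alpha are returned (the convention of the published table);
    untestable combinations (all-NA, single level) are skipped.
    """
    mutated = mutated_sample_sets(cohort)
    genes = list(genes) if genes is not None else sorted(mutated)
    characteristics = (
        list(characteristics) if characteristics is not None else list(CHARACTERISTICS)
    )
    results = []
    for gene in genes:
        carriers = mutated.get(gene, set())
        for char in characteristics:
            try:
                table = contingency(carriers, clinical, char)
            except ValueError:
                continue
            if len(table.rows) == 2:
                p = fisher_2x2(table.rows)
                pairwise: dict[tuple[str, str], float] = {}
            else:
                p = fisher_rx2(table.rows)
                pairwise = pairwise_bonferroni(table)
            if show_all or p <= alpha:
                results.append(AssociationResult(gene, char, table, p, pairwise))
    return results
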