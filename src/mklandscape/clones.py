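"""Statistics for single-cell clone assays and progenitor-depletion data.

Single sorted cells (HSC-like ESLAMs, the megakaryocyte-biased intermediate
population, and megakaryocyte progenitors) are observed daily in culture and
each well classified by its content of enlarged cells (presumptive
megakaryocytes, MKs) and small cells.  This module implements the
four-category classification, the category consolidations used for testing,
first-megakaryopoiesis timing, the minimum-division calculus, marker-overlap
scores, and the summary-statistic tests (Welch/Student t from mean/SD/n,
chi-square, Fisher exact, Mann-Whitney U) that the printed figure-legend
values derive from.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CloneRecord",
    "SummaryStats",
    "ContingencyTable",
    "CATEGORIES",
    "classify_clone",
    "consolidate",
    "first_mk_day",
    "min_divisions",
    "welch_t_from_summary",
    "student_t_from_summary",
    "percent_depletion",
    "chi_square_test",
    "fisher_exact",
    "mann_whitney_u",
    "overlap_score",
    "read_clone_records",
]

CATEGORIES = ("1 MK", ">1 MK", "mixed", "proliferation only", "dead")


@dataclass
class Observation:
    day: int
    n_large: int
    n_small: int
    alive: bool = True


@dataclass
class CloneRecord:
    well: str
    population: str    # e.g. ESLAM, pMKP, MkP
    genotype: str      # e.g. WT, HOM
    observations: list = field(default_factory=list)

    def __post_init__(self):
        days = [o.day for o in self.observations]
        if days != sorted(days) or len(set(days)) != len(days):
            raise ValueError(f"well {self.well}: day indices must strictly increase")
        dead_seen = False
        for o in self.observations:
            if o.n_large < 0 or o.n_small < 0:
                raise ValueError(f"well {self.well}: negative cell counts")
            if dead_seen:
                raise ValueError(
                    f"well {self.well}: observations recorded after death"
                )
            if not o.alive:
                dead_seen = True

    def on_day(self, day: int) -> Observation:
        for o in self.observations:
            if o.day == day:
                return o
        raise KeyError(f"well {self.well}: no observation for day {day}")


def classify_clone(record: CloneRecord, day: int) -> str:
    """Four-category classification of a well on a given day.

    Exactly one enlarged cell -> "1 MK"; several enlarged cells only ->
    ">1 MK"; both enlarged and small cells -> "mixed"; small cells only ->
    "proliferation only"; a well whose cells have died -> "dead".
    """
    o = record.on_day(day)
    if not o.alive:
        return "dead"
    if o.n_large >= 1 and o.n_small >= 1:
        return "mixed"
    if o.n_large == 1:
        return "1 MK"
    if o.n_large > 1:
        return ">1 MK"
    if o.n_small >= 1:
        return "proliferation only"
    return "dead"


@dataclass
class ContingencyTable:
    counts: np.ndarray       # rows = categories, columns = groups
    row_labels: tuple
    col_labels: tuple

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("label/shape mismatch")


def consolidate(table: ContingencyTable, scheme: str) -> ContingencyTable:
    """Regroup the four-category rows; column totals are conserved.

    ``"MK/noMK"``: {1 MK, >1 MK, mixed} -> MK, {proliferation only} -> no MK.
    ``"threeway"``: {1 MK}, {>1 MK}, {mixed + proliferation only}.
    """
    want = ("1 MK", ">1 MK", "mixed", "proliferation only")
    if tuple(table.row_labels)[: len(want)] != want:
        raise ValueError(f"input rows must be the four categories {want}")
    c = table.counts[: len(want)]
    if scheme == "MK/noMK":
        rows = np.vstack([c[0] + c[1] + c[2], c[3]])
        labels = ("MK", "no MK")
    elif scheme == "threeway":
        rows = np.vstack([c[0], c[1], c[2] + c[3]])
        labels = ("1 MK", ">1 MK", "mixed + prolif only")
    else:
        raise ValueError(f"unknown consolidation scheme {scheme!r}")
    return ContingencyTable(rows, labels, tuple(table.col_labels))


def first_mk_day(record: CloneRecord):
    """Smallest observed day with at least one enlarged cell, else None."""
    for o in record.observations:
        if o.alive and o.n_large >= 1:
            return o.day
    return None


def min_divisions(n_cells: int) -> int:
    """Minimum number of binary divisions from one founder to n_cells."""
    if n_cells < 1:
        raise ValueError("n_cells must be at least 1")
    return math.ceil(math.log2(n_cells))


@dataclass
class SummaryStats:
    label: str
    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")
        if self.n < 2:
            raise ValueError("n must be at least 2 for testing")


def welch_t_from_summary(a: SummaryStats, b: SummaryStats):
    """Welch unequal-variance t-test from summary statistics.

    Returns ``(t, df, two-sided p)`` with Welch-Satterthwaite degrees of
    freedom; the sign of t follows mean_b - mean_a.
    """
    va, vb = a.sd ** 2 / a.n, b.sd ** 2 / b.n
    se = math.sqrt(va + vb)
    if se == 0:
        if a.mean == b.mean:
            return 0.0, float(a.n + b.n - 2), 1.0
        return math.inf, float(a.n + b.n - 2), 0.0
    t = (b.mean - a.mean) / se
    df = (va + vb) ** 2 / (va ** 2 / (a.n - 1) + vb ** 2 / (b.n - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, df, p


def student_t_from_summary(a: SummaryStats, b: SummaryStats):
    """Pooled-variance (Student) variant; returns ``(t, df, two-sided p)``."""
    t, p = stats.ttest_ind_from_stats(
        b.mean, b.sd, b.n, a.mean, a.sd, a.n, equal_var=True
    )
    return float(t), float(a.n + b.n - 2), float(p)


def percent_depletion(mean_control: float, mean_depleted: float) -> float:
    """Percent reduction relative to control: 100 * (1 - depleted/control)."""
    if mean_control <= 0:
        raise ValueError("control mean must be positive")
    return 100.0 * (1.0 - mean_depleted / mean_control)


def chi_square_test(table: ContingencyTable):
    """Pearson chi-square test of independence on an r x c table.

    Returns ``(statistic, df, p)``; warns when any expected count is below 5.
    """
    c = table.counts
    if c.shape[0] < 2 or c.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if (c.sum(axis=0) == 0).any() or (c.sum(axis=1) == 0).any():
        raise ValueError("degenerate margins: empty row or column")
    res = stats.chi2_contingency(c, correction=False)
    if (res.expected_freq < 5).any():
        import warnings

        warnings.warn("expected counts below 5; chi-square approximation is weak")
    return float(res.statistic), int(res.dof), float(res.pvalue)


def fisher_exact(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p for a 2x2 table (probability-mass method:
    sum of hypergeometric probabilities of margin-fixed tables no more likely
    than the observed one)."""
    c = table.counts
    if c.shape != (2, 2):
        raise ValueError("Fisher exact test requires a 2x2 table")
    if not np.issubdtype(c.dtype, np.integer):
        if not np.allclose(c, np.round(c)):
            raise ValueError("counts must be integers")
        c = np.round(c).astype(int)
    return float(stats.fisher_exact(c, alternative="two-sided")[1])


def mann_whitney_u(x, y):
    """Two-sided Mann-Whitney U test.

    Exact by enumeration (tie-aware) when n + m <= 12, tie-corrected normal
    approximation with continuity correction otherwise.  Returns ``(U_x, p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2.0
    if n + m <= 12:
        mu = n * m / 2.0
        dev = abs(u_obs - mu)
        total = extreme = 0
        for comb in combinations(range(n + m), n):
            u = ranks[list(comb)].sum() - n * (n + 1) / 2.0
            total += 1
            if abs(u - mu) >= dev - 1e-9:
                extreme += 1
        return u_obs, extreme / total
    p = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")[1]
    return u_obs, float(p)


def overlap_score(cd41_pos: bool, sca1_neg: bool, ckit_pos: bool):
    """Marker-overlap score: number of overlapping MkP markers out of three.

    Returns ``(score, in_domain)``; a score of 0/3 is outside the observed
    domain and flagged rather than rejected.
    """
    score = (int(bool(cd41_pos)) + int(bool(sca1_neg)) + int(bool(ckit_pos))) / 3.0
    return score, score > 0.0


def read_clone_records(path: str) -> list:
    """Read clone records from a tidy TSV with columns
    well, population, genotype, day, n_large, n_small, alive."""
    df = pd.read_csv(path, sep="\t")
    records = []
    for (well, pop, geno), sub in df.groupby(["well", "population", "genotype"],
                                             sort=True):
        sub = sub.sort_values("day")
        obs = [
            Observation(int(r.day), int(r.n_large), int(r.n_small), bool(r.alive))
            for r in sub.itertuples()
        ]
        records.append(CloneRecord(str(well), str(pop), str(geno), obs))
    return records
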