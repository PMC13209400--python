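"""Environment association of accessory and unique gene clusters.

Each non-core cluster's presence/absence pattern across the two
environment groups (HTV vs non-HTV) forms a 2x2 contingency table that
is tested with a two-sided Fisher exact test; Benjamini-Hochberg
adjusted values are reported alongside.  With very small group sizes
(2 vs 14 genomes in the reference design) the smallest attainable
two-sided p is 1/120, which can never survive an FDR correction across
thousands of clusters, so significance is called on the raw p (< alpha)
by default and both thresholds are configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io import Environment, MetadataTable

logger = logging.getLogger("pankit")

#: relative tolerance treating near-equal point probabilities as ties.
TIE_RTOL = 1e-7


def is_below_alpha(p: float, alpha: float) -> bool:
    """Strict p < alpha, robust to float roundoff of an exact p.

    Exact-test p-values are rationals; when the log-space sum lands
    within 1e-9 relative of alpha the true value is taken to equal alpha
    and the strict inequality fails (e.g. p = 1/20 vs alpha = 0.05).
    """
    return p < alpha * (1.0 - 1e-9)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Presence/absence counts of one cluster in the two groups.

    a/b: present/absent among HTV genomes; c/d: present/absent among
    non-HTV genomes.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency table cells must be non-negative")

    @property
    def n_htv(self) -> int:
        return self.a + self.b

    @property
    def n_nonhtv(self) -> int:
        return self.c + self.d


@dataclass(frozen=True)
class AssociationResult:
    cluster_id: str
    table: ContingencyTable2x2
    p: float
    q: float
    direction: Environment | None  # HTV / NONHTV when significant, else None
    significant: bool


def _log_hypergeom_pmf(a: np.ndarray, r1: int, r2: int, k: int) -> np.ndarray:
    """log P(A = a) for A ~ Hypergeom(population r1 + r2, successes k, draws r1)."""

    def logC(n, r):
        return gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)

    return logC(r1, a) + logC(r2, k - a) - logC(r1 + r2, k)


def fisher_exact_2x2(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p for one 2x2 table.

    Computed in log space by summing the hypergeometric point
    probabilities that do not exceed the observed table's probability,
    with a small relative tolerance so numerically tied tables are
    included (the convention of mainstream statistical software).
    """
    r1, r2 = table.n_htv, table.n_nonhtv
    k = table.a + table.c
    lo, hi = max(0, k - r2), min(r1, k)
    support = np.arange(lo, hi + 1)
    log_pmf = _log_hypergeom_pmf(support, r1, r2, k)
    pmf = np.exp(log_pmf)
    observed = pmf[support == table.a][0]
    p = float(pmf[pmf <= observed * (1.0 + TIE_RTOL)].sum())
    return min(p, 1.0)


def bh_adjust(p_values: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted values, in input order.

    q_(i) = min_{j >= i} min(1, m * p_(j) / j) over the sorted p-values,
    mapped back to the original order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q.tolist()


def environment_association(
    matrix: pd.DataFrame,
    metadata: MetadataTable,
    alpha: float = 0.05,
) -> list[AssociationResult]:
    """Test every accessory/unique cluster for environment association.

    Core clusters (present in every genome) carry no signal and are
    excluded before testing.  A cluster is significant when its raw
    two-sided Fisher p is below ``alpha``; its direction is the group
    with the higher presence fraction.  A significant cluster with equal
    presence fractions cannot be directed and is demoted to
    non-significant (logged).  BH-adjusted q values are reported for all
    tested clusters.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    htv = [g for g in metadata.group(Environment.HTV) if g in matrix.columns]
    nonhtv = [g for g in metadata.group(Environment.NONHTV) if g in matrix.columns]
    if not htv or not nonhtv:
        raise ValueError("both environment groups must be non-empty")

    values = matrix.to_numpy(dtype=bool)
    htv_idx = [matrix.columns.get_loc(g) for g in htv]
    non_idx = [matrix.columns.get_loc(g) for g in nonhtv]
    present_htv = values[:, htv_idx].sum(axis=1)
    present_non = values[:, non_idx].sum(axis=1)
    n_genomes = len(htv) + len(nonhtv)
    tested = np.flatnonzero(present_htv + present_non < n_genomes)

    p_cache: dict[tuple[int, int], float] = {}
    tables, p_values = [], []
    for i in tested:
        a, c = int(present_htv[i]), int(present_non[i])
        table = ContingencyTable2x2(a, len(htv) - a, c, len(nonhtv) - c)
        key = (a, c)
        if key not in p_cache:
            p_cache[key] = fisher_exact_2x2(table)
        tables.append(table)
        p_values.append(p_cache[key])
    q_values = bh_adjust(p_values)

    results = []
    for i, table, p, q in zip(tested, tables, p_values, q_values):
        cluster_id = matrix.index[i]
        significant = is_below_alpha(p, alpha)
        direction: Environment | None = None
        if significant:
            frac_htv = table.a / table.n_htv
            frac_non = table.c / table.n_nonhtv
            if frac_htv > frac_non:
                direction = Environment.HTV
            elif frac_non > frac_htv:
                direction = Environment.NONHTV
            else:
                logger.info(
                    "cluster %s: tied presence fractions, no direction", cluster_id
                )
                significant = False
        results.append(
            AssociationResult(
                cluster_id=cluster_id,
                table=table,
                p=p,
                q=q,
                direction=direction,
                significant=significant,
            )
        )
    return results


def association_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Long-format table of association results for TSV output."""
    return pd.DataFrame(
        {
            "cluster_id": [r.cluster_id for r in results],
            "present_htv": [r.table.a for r in results],
            "absent_htv": [r.table.b for r in results],
            "present_nonhtv": [r.table.c for r in results],
            "absent_nonhtv": [r.table.d for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
            "direction": [
                r.direction.value if r.direction else "none" for r in results
            ],
            "significant": [r.significant for r in results],
        }
    )
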