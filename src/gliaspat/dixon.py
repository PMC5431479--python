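"""Dixon's nearest-neighbour contingency-table test of spatial segregation.

For a two-type marked pattern (types i = 'low', j = 'high' activity) each
point contributes one nearest-neighbour pair (own type → neighbour type).
Under random labelling — holding positions fixed and permuting labels — the
expected counts and their (co)variances depend only on the label totals and
on two structural constants of the NN graph: R, the number of points in
reflexive (mutual) NN pairs, and Q = Σ_points indeg·(indeg−1), which
captures shared nearest neighbours. The within-type z-scores

    z_aa = (N_aa − E[N_aa]) / √Var(N_aa)

test self-association of each type, and the overall statistic C is the
quadratic form of (N_ii − E, N_jj − E) with the inverse of its 2×2
covariance matrix, asymptotically χ² with 2 degrees of freedom. Retina-level
results aggregate across a treatment group by summing statistics and
degrees of freedom (C: 2 df per retina; Σz² : 1 df per retina).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import chi2

from .patterns import MARK_HIGH, MARK_LOW, PointPattern


@dataclass
class NNContingencyTable:
    """Nearest-neighbour type-pair counts plus the NN-graph constants
    needed for the random-labelling variances."""

    n_i: int  # points of type i ('low')
    n_j: int
    n_ii: int  # i-points whose NN is type i
    n_ij: int
    n_ji: int
    n_jj: int
    reflexive: int  # R: points in mutual NN pairs
    shared: float  # Q: Σ indeg·(indeg−1) over points

    @property
    def n(self) -> int:
        return self.n_i + self.n_j

    def __post_init__(self) -> None:
        if self.n_ii + self.n_ij != self.n_i or self.n_ji + self.n_jj != self.n_j:
            raise ValueError("row sums must equal label counts")
        if min(self.n_i, self.n_j, self.n_ii, self.n_ij,
               self.n_ji, self.n_jj) < 0:
            raise ValueError("counts must be non-negative")


def nearest_neighbour_indices(points: np.ndarray) -> np.ndarray:
    """Index of each point's nearest neighbour; exact ties are broken
    toward the smaller index (with a warning), duplicates are rejected."""
    n = len(points)
    if n < 2:
        raise ValueError("need at least 2 points")
    k = min(n, 4)
    d, idx = cKDTree(points).query(points, k=k)
    if np.any(d[:, 1] == 0.0):
        raise ValueError("duplicate coordinates are not allowed")
    nn = idx[:, 1].copy()
    # resolve exact distance ties deterministically by point index
    tied_rows = np.where(np.any(d[:, 2:] == d[:, 1][:, None], axis=1))[0]
    if len(tied_rows):
        warnings.warn(
            f"{len(tied_rows)} exact nearest-neighbour ties broken by index",
            stacklevel=2,
        )
        for row in tied_rows:
            tied = idx[row, 1:][d[row, 1:] == d[row, 1]]
            nn[row] = tied.min()
    return nn


def build_nn_table(pattern: PointPattern) -> NNContingencyTable:
    """Nearest-neighbour contingency table of a two-type pattern."""
    if pattern.marks is None:
        raise ValueError("pattern has no marks")
    labels = np.asarray(pattern.marks)
    present = set(labels)
    for lab in (MARK_LOW, MARK_HIGH):
        if (labels == lab).sum() < 2:
            raise ValueError(f"label {lab!r} needs at least 2 points")
    if present - {MARK_LOW, MARK_HIGH}:
        raise ValueError(f"unexpected labels {present - {MARK_LOW, MARK_HIGH}}")
    nn = nearest_neighbour_indices(pattern.points)
    is_i = labels == MARK_LOW
    nn_is_i = is_i[nn]
    n_ii = int(np.sum(is_i & nn_is_i))
    n_ij = int(np.sum(is_i & ~nn_is_i))
    n_ji = int(np.sum(~is_i & nn_is_i))
    n_jj = int(np.sum(~is_i & ~nn_is_i))
    reflexive = int(np.sum(nn[nn] == np.arange(len(nn))))
    indeg = np.bincount(nn, minlength=len(nn))
    shared = float(np.sum(indeg * (indeg - 1)))
    return NNContingencyTable(
        n_i=int(is_i.sum()), n_j=int((~is_i).sum()),
        n_ii=n_ii, n_ij=n_ij, n_ji=n_ji, n_jj=n_jj,
        reflexive=reflexive, shared=shared,
    )


def chi_square_p(statistic: float, df: int) -> float:
    """Upper-tail χ² probability; monotone decreasing in the statistic."""
    if df < 1:
        raise ValueError("df must be at least 1")
    if statistic < 0:
        raise ValueError("statistic must be non-negative")
    return float(chi2.sf(statistic, df))


def format_p(p: float, floor: float = 1e-6) -> str:
    """Display form with small p-values floored (e.g. '<0.000001')."""
    return f"<{floor:g}" if p < floor else f"{p:.4f}"


def _moments(table: NNContingencyTable):
    """Expectations, variances and covariance of (N_ii, N_jj) under random
    labelling (Dixon's two-type formulas, validated against label
    permutation)."""
    n, ni, nj = float(table.n), float(table.n_i), float(table.n_j)
    R, Q = float(table.reflexive), float(table.shared)

    def falling(m, k):
        out = 1.0
        for t in range(k):
            out *= m - t
        return out

    moments = {}
    for name, m in (("ii", ni), ("jj", nj)):
        p2 = falling(m, 2) / falling(n, 2)
        p3 = falling(m, 3) / falling(n, 3)
        p4 = falling(m, 4) / falling(n, 4)
        e = n * p2
        var = (
            (n + R) * p2
            + (2 * n - 2 * R + Q) * p3
            + (n**2 - 3 * n - Q + R) * p4
            - e**2
        )
        moments[name] = (e, var)
    p_iijj = (falling(ni, 2) * falling(nj, 2)) / falling(n, 4)
    cov = (n**2 - 3 * n - Q + R) * p_iijj - (n * falling(ni, 2) / falling(n, 2)) * (
        n * falling(nj, 2) / falling(n, 2)
    )
    return moments["ii"], moments["jj"], cov


@dataclass
class DixonResult:
    """Per-retina segregation test: within-type z-scores and overall C."""

    table: NNContingencyTable
    z_ii: float
    z_jj: float
    c: float
    df_c: int
    p_c: float
    p_z_ii: float  # two-sided
    p_z_jj: float
    expected_ii: float
    expected_jj: float


def dixon_test(table: NNContingencyTable) -> DixonResult:
    """Dixon's test on one contingency table.

    z_aa compares the observed self-neighbour count with its random-
    labelling expectation; C is the 2-df quadratic-form overall statistic.
    A degenerate geometry with zero variance raises.
    """
    (e_ii, var_ii), (e_jj, var_jj), cov = _moments(table)
    if var_ii <= 0 or var_jj <= 0:
        raise ValueError("zero variance: degenerate configuration")
    z_ii = (table.n_ii - e_ii) / np.sqrt(var_ii)
    z_jj = (table.n_jj - e_jj) / np.sqrt(var_jj)
    sigma = np.array([[var_ii, cov], [cov, var_jj]])
    delta = np.array([table.n_ii - e_ii, table.n_jj - e_jj])
    det = np.linalg.det(sigma)
    if det <= 0:
        raise ValueError("singular covariance: degenerate configuration")
    c = float(delta @ np.linalg.solve(sigma, delta))
    return DixonResult(
        table=table,
        z_ii=float(z_ii),
        z_jj=float(z_jj),
        c=c,
        df_c=2,
        p_c=chi_square_p(c, 2),
        p_z_ii=chi_square_p(float(z_ii) ** 2, 1),
        p_z_jj=chi_square_p(float(z_jj) ** 2, 1),
        expected_ii=e_ii,
        expected_jj=e_jj,
    )


@dataclass
class AggregateDixonResult:
    """Group-level test: statistics and df summed over retinas."""

    n_retinas: int
    n_i_total: int
    n_j_total: int
    c_sum: float
    df_c: int
    p_c: float
    z_ii_sq_sum: float
    df_z: int
    p_z_ii: float
    z_jj_sq_sum: float
    p_z_jj: float


def aggregate(results: list[DixonResult]) -> AggregateDixonResult:
    """Sum per-retina statistics into a process-wide test: ΣC on Σdf
    (2 per retina), Σz² on one df per retina."""
    if not results:
        raise ValueError("no per-retina results to aggregate")
    c_sum = float(sum(r.c for r in results))
    z_ii_sq = float(sum(r.z_ii**2 for r in results))
    z_jj_sq = float(sum(r.z_jj**2 for r in results))
    m = len(results)
    return AggregateDixonResult(
        n_retinas=m,
        n_i_total=sum(r.table.n_i for r in results),
        n_j_total=sum(r.table.n_j for r in results),
        c_sum=c_sum,
        df_c=2 * m,
        p_c=chi_square_p(c_sum, 2 * m),
        z_ii_sq_sum=z_ii_sq,
        df_z=m,
        p_z_ii=chi_square_p(z_ii_sq, m),
        z_jj_sq_sum=z_jj_sq,
        p_z_jj=chi_square_p(z_jj_sq, m),
    )
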