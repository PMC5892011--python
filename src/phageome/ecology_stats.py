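"""Community ecology statistics for storage / freeze-thaw / operator designs.

Beta diversity is measured as Spearman distance, d = 1 - rho (rank
correlation with average ranks for ties), between per-sample relative
abundance profiles; d lies in [0, 2] and is invariant to any strictly
monotone transform of the abundances. Ordination is classical PCoA
(Torgerson scaling) on the possibly non-Euclidean Spearman distance matrix:
negative eigenvalues are retained in the report but excluded from the
coordinates, and proportion explained is taken over the positive eigenvalues.

Variance partitioning uses PERMANOVA with sequential (Type I) sums of squares
over the factors in the user-given order, computed on the Gower-centred
matrix G = -1/2 C D^2 C via projection (hat) matrices; significance comes
from permuting sample labels (whole rows/columns of D) with the
(count + 1)/(n_perm + 1) p-value estimator, or from exhaustive enumeration of
all label permutations on small designs. Alpha diversity: Shannon entropy
(natural log) and the classic Chao1 richness estimator. Two-group
comparisons use the Mann-Whitney U test, multi-group the Kruskal-Wallis H
test, both with average-rank tie handling.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, Mapping, NamedTuple, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import CountMatrix

__all__ = [
    "DistanceMatrix",
    "PcoaResult",
    "PermanovaResult",
    "GroupTestResult",
    "WithinBetweenResult",
    "relative_abundance",
    "shannon",
    "chao1",
    "spearman_distance",
    "pcoa",
    "permanova",
    "within_between_distances",
    "recruitment_rate",
    "group_test",
    "alpha_diversity_table",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric sample-by-sample distances with a zero diagonal."""

    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        n = len(self.sample_ids)
        if values.shape != (n, n):
            raise ValueError(f"distance matrix shape {values.shape} != ({n}, {n})")
        if not np.all(np.isfinite(values)):
            raise ValueError("distances must be finite")
        if np.abs(values - values.T).max(initial=0.0) > 1e-12:
            raise ValueError("distance matrix must be symmetric to 1e-12")
        if np.abs(np.diag(values)).max(initial=0.0) != 0.0:
            raise ValueError("distance matrix diagonal must be exactly zero")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


class PcoaResult(NamedTuple):
    coordinates: np.ndarray        # (n, k) over positive eigenvalues
    eigenvalues: np.ndarray        # all n, descending (negatives retained)
    proportion_explained: np.ndarray  # over positive eigenvalues
    sample_ids: tuple[str, ...]


@dataclass(frozen=True)
class FactorResult:
    name: str
    df: int
    sum_squares: float
    r_squared: float
    pseudo_f: float
    p_value: float


@dataclass(frozen=True)
class PermanovaResult:
    """Sequential variance partitioning of a distance matrix over factors."""

    factors: tuple[FactorResult, ...]
    residual_df: int
    residual_ss: float
    residual_r_squared: float
    total_ss: float
    n_permutations: int
    seed: Optional[int]

    def r_squared(self, name: str) -> float:
        for f in self.factors:
            if f.name == name:
                return f.r_squared
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "factor": f.name,
                "df": f.df,
                "sum_squares": f.sum_squares,
                "r_squared": f.r_squared,
                "pseudo_f": f.pseudo_f,
                "p_value": f.p_value,
            }
            for f in self.factors
        ]
        rows.append(
            {
                "factor": "residual",
                "df": self.residual_df,
                "sum_squares": self.residual_ss,
                "r_squared": self.residual_r_squared,
                "pseudo_f": float("nan"),
                "p_value": float("nan"),
            }
        )
        return pd.DataFrame(rows)


class GroupTestResult(NamedTuple):
    statistic: float
    p_value: float
    test: str
    degenerate: bool = False


class WithinBetweenResult(NamedTuple):
    within: np.ndarray
    between: np.ndarray
    u_statistic: float
    p_value: float


# ---------------------------------------------------------------------------
# Alpha diversity


def relative_abundance(counts: CountMatrix) -> np.ndarray:
    """Per-sample proportions (rows sum to 1)."""
    totals = counts.counts.sum(axis=1)
    zero = np.nonzero(totals == 0)[0]
    if zero.size:
        raise ValueError(f"sample {counts.sample_ids[zero[0]]!r} has zero total reads")
    return counts.counts / totals[:, None]


def shannon(proportions: np.ndarray, base: Optional[float] = None) -> float:
    """Shannon entropy H = -sum p ln p (natural log by default; 0 ln 0 := 0)."""
    p = np.asarray(proportions, dtype=float)
    if (p < 0).any():
        raise ValueError("proportions must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    nz = p[p > 0]
    h = float(-(nz * np.log(nz)).sum())
    if base is not None:
        h /= math.log(base)
    return h


def chao1(counts: np.ndarray) -> float:
    """Classic Chao1 richness: S_obs + F1^2/(2 F2), with the bias-corrected
    S_obs + F1(F1-1)/2 branch when there are no doubletons."""
    c = np.asarray(counts)
    if not np.issubdtype(c.dtype, np.integer):
        if not np.all(np.equal(np.mod(c, 1), 0)):
            raise ValueError("chao1 requires integer counts")
        c = c.astype(np.int64)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    s_obs = int((c > 0).sum())
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def alpha_diversity_table(counts: CountMatrix) -> pd.DataFrame:
    """Shannon, Chao1 and observed richness per sample."""
    props = relative_abundance(counts)
    return pd.DataFrame(
        {
            "sample_id": counts.sample_ids,
            "shannon": [shannon(p) for p in props],
            "chao1": [chao1(row) for row in counts.counts],
            "observed": (counts.counts > 0).sum(axis=1),
        }
    )


# ---------------------------------------------------------------------------
# Beta diversity


def spearman_distance(
    abundances: Union[CountMatrix, np.ndarray],
    sample_ids: Optional[Sequence[str]] = None,
) -> DistanceMatrix:
    """d(x, y) = 1 - Spearman rho between sample abundance profiles.

    Average ranks resolve ties (essential for sparse count data); distances
    lie in [0, 2]. Rank correlation is undefined for a constant profile, which
    is reported as an error naming the sample.
    """
    if isinstance(abundances, CountMatrix):
        data = relative_abundance(abundances)
        ids = tuple(abundances.sample_ids)
    else:
        data = np.asarray(abundances, dtype=float)
        if data.ndim != 2:
            raise ValueError("abundance matrix must be 2-D (samples x features)")
        ids = tuple(sample_ids) if sample_ids is not None else tuple(
            f"s{i}" for i in range(data.shape[0])
        )
    if data.shape[1] < 2:
        raise ValueError("need >= 2 features per sample for rank correlation")
    ranks = np.vstack([stats.rankdata(row, method="average") for row in data])
    sds = ranks.std(axis=1)
    constant = np.nonzero(sds == 0)[0]
    if constant.size:
        raise ValueError(
            f"sample {ids[constant[0]]!r} has a constant abundance profile; "
            "Spearman correlation undefined"
        )
    rho = np.corrcoef(ranks)
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # enforce exact symmetry against FP round-off
    return DistanceMatrix(sample_ids=ids, values=d)


def pcoa(distance: DistanceMatrix) -> PcoaResult:
    """Classical (Torgerson) scaling of a distance matrix.

    Double-centres -1/2 D^2, eigendecomposes, and returns coordinates over
    the positive eigenvalues (descending). Negative eigenvalues — possible
    for non-Euclidean distances like 1 - rho — appear in ``eigenvalues`` but
    contribute no axes; ``proportion_explained`` is relative to the positive
    eigenvalue sum.
    """
    d = distance.values
    n = d.shape[0]
    a = -0.5 * d**2
    centering = np.eye(n) - np.ones((n, n)) / n
    g = centering @ a @ centering
    eigvals, eigvecs = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(1e-12, 1e-10 * abs(eigvals).max(initial=0.0))
    positive = eigvals > tol
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    pos_sum = eigvals[positive].sum()
    proportion = eigvals[positive] / pos_sum if pos_sum > 0 else eigvals[positive]
    return PcoaResult(
        coordinates=coords,
        eigenvalues=eigvals,
        proportion_explained=proportion,
        sample_ids=distance.sample_ids,
    )


# ---------------------------------------------------------------------------
# PERMANOVA


def _hat_matrix(x: np.ndarray) -> tuple[np.ndarray, int]:
    """Projection onto the column space of x, and its rank."""
    q, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    rank = int((diag > 1e-10 * max(1.0, diag.max(initial=0.0))).sum())
    q = q[:, :rank]
    return q @ q.T, rank


def _dummy_code(levels: Sequence[str]) -> np.ndarray:
    uniq = sorted(set(levels))
    return np.column_stack([[1.0 if l == u else 0.0 for l in levels] for u in uniq])


def _sequential_stats(
    g: np.ndarray, factor_levels: list[list[str]]
) -> tuple[list[float], list[int], float, int, float]:
    """Sequential (Type I) SS per factor plus residual SS/df on a Gower matrix."""
    n = g.shape[0]
    x = np.ones((n, 1))
    hat_prev, rank_prev = _hat_matrix(x)
    ss_total = float(np.trace(g))
    ss_factors: list[float] = []
    df_factors: list[int] = []
    explained_prev = float(np.trace(hat_prev @ g))  # 0 for centred g
    for levels in factor_levels:
        x = np.hstack([x, _dummy_code(levels)])
        hat, rank = _hat_matrix(x)
        explained = float(np.trace(hat @ g))
        ss_factors.append(explained - explained_prev)
        df_factors.append(rank - rank_prev)
        hat_prev, rank_prev, explained_prev = hat, rank, explained
    ss_res = ss_total - explained_prev
    df_res = n - rank_prev
    return ss_factors, df_factors, ss_res, df_res, ss_total


def permanova(
    distance: DistanceMatrix,
    factors: Mapping[str, Sequence[str]],
    n_permutations: Union[int, str] = 999,
    seed: Optional[int] = None,
    sequential: bool = True,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    Parameters
    ----------
    distance
        Sample distance matrix.
    factors
        Ordered mapping factor name -> level per sample (aligned to
        ``distance.sample_ids``). With ``sequential=True`` (default) factors
        are fitted in the given order with Type I sums of squares, so the
        factor R^2 values plus residual R^2 sum to 1. With
        ``sequential=False`` each factor is fitted in its own single-factor
        model (marginal R^2; no additivity guarantee).
    n_permutations
        Number of random label permutations (>= 99), 0 to skip the
        permutation test (p = NaN), or ``"exact"`` to enumerate all n!
        permutations (small n only) and report the exact permutation p-value
        without the +1 correction.
    seed
        Seed for the permutation stream; required for reproducible p-values.

    Permuting sample labels permutes whole rows/columns of D. p-values use
    the (count >= observed + 1)/(n_permutations + 1) estimator in random
    mode.

    With strongly non-Euclidean distances and near noise-free designs the
    residual mean square can reach zero or below (the fitted terms exhaust
    the total inertia); the pseudo-F is then off-scale and reported as
    ``inf``, while R^2 values and permutation p-values remain well defined.
    """
    n = distance.n
    names = list(factors.keys())
    if not names:
        raise ValueError("need at least one factor")
    levels_by_factor: list[list[str]] = []
    for name in names:
        levels = [str(l) for l in factors[name]]
        if len(levels) != n:
            raise ValueError(f"factor {name!r} has {len(levels)} levels for {n} samples")
        levels_by_factor.append(levels)

    exact = n_permutations == "exact"
    if not exact:
        n_perm = int(n_permutations)
        if n_perm != 0 and n_perm < 99:
            raise ValueError("n_permutations must be 0, >= 99, or 'exact'")

    a = -0.5 * distance.values**2
    centering = np.eye(n) - np.ones((n, n)) / n
    g = centering @ a @ centering

    def stats_for(gm: np.ndarray):
        if sequential:
            return _sequential_stats(gm, levels_by_factor)
        # marginal: each factor alone; residual from the joint model
        ss_factors, df_factors = [], []
        for levels in levels_by_factor:
            ss_f, df_f, _, _, _ = _sequential_stats(gm, [levels])
            ss_factors.append(ss_f[0])
            df_factors.append(df_f[0])
        _, _, ss_res, df_res, ss_total = _sequential_stats(gm, levels_by_factor)
        return ss_factors, df_factors, ss_res, df_res, ss_total

    ss_factors, df_factors, ss_res, df_res, ss_total = stats_for(g)
    if df_res <= 0:
        raise ValueError("zero residual degrees of freedom: factors are confounded "
                         "with samples")
    if any(df == 0 for df in df_factors):
        bad = names[df_factors.index(0)]
        raise ValueError(f"factor {bad!r} is constant or confounded with earlier factors")

    ms_res = ss_res / df_res
    f_obs = [
        (ss / df) / ms_res if ms_res > 0 else math.inf
        for ss, df in zip(ss_factors, df_factors)
    ]

    def f_stats_for_order(order: np.ndarray) -> list[float]:
        gp = g[np.ix_(order, order)]
        ss_f, df_f, ss_r, df_r, _ = stats_for(gp)
        ms_r = ss_r / df_r
        return [
            (ss / df) / ms_r if ms_r > 0 else math.inf
            for ss, df in zip(ss_f, df_f)
        ]

    if exact:
        counts = [0] * len(names)
        total = 0
        for perm in itertools.permutations(range(n)):
            order = np.asarray(perm)
            f_perm = f_stats_for_order(order)
            for k, (fp, fo) in enumerate(zip(f_perm, f_obs)):
                if fp >= fo - 1e-12:
                    counts[k] += 1
            total += 1
        p_values = [c / total for c in counts]
        n_perm_report = total
    elif n_permutations == 0:
        p_values = [float("nan")] * len(names)
        n_perm_report = 0
    else:
        rng = np.random.default_rng(seed)
        counts = [0] * len(names)
        for _ in range(n_perm):
            order = rng.permutation(n)
            f_perm = f_stats_for_order(order)
            for k, (fp, fo) in enumerate(zip(f_perm, f_obs)):
                if fp >= fo - 1e-12:
                    counts[k] += 1
        p_values = [(c + 1) / (n_perm + 1) for c in counts]
        n_perm_report = n_perm

    factor_results = tuple(
        FactorResult(
            name=name,
            df=df,
            sum_squares=ss,
            r_squared=ss / ss_total,
            pseudo_f=f,
            p_value=p,
        )
        for name, df, ss, f, p in zip(names, df_factors, ss_factors, f_obs, p_values)
    )
    return PermanovaResult(
        factors=factor_results,
        residual_df=df_res,
        residual_ss=ss_res,
        residual_r_squared=ss_res / ss_total,
        total_ss=ss_total,
        n_permutations=n_perm_report,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Distance comparisons and group tests


def within_between_distances(
    distance: DistanceMatrix, grouping: Mapping[str, str]
) -> WithinBetweenResult:
    """Split pairwise distances into within- and between-subject sets and
    compare them with a two-sided Mann-Whitney U test.

    Exact enumeration is used when both sets have <= 8 values and no ties
    span the two sets; otherwise the tie-corrected normal approximation.
    """
    subjects = [grouping[s] for s in distance.sample_ids]
    if len(set(subjects)) < 2:
        raise ValueError("need >= 2 subjects")
    within, between = [], []
    n = distance.n
    for i in range(n):
        for j in range(i + 1, n):
            (within if subjects[i] == subjects[j] else between).append(
                distance.values[i, j]
            )
    if not within:
        raise ValueError("no within-subject sample pairs")
    within_arr = np.asarray(within)
    between_arr = np.asarray(between)
    use_exact = (
        len(within_arr) <= 8
        and len(between_arr) <= 8
        and len(np.unique(np.concatenate([within_arr, between_arr])))
        == len(within_arr) + len(between_arr)
    )
    res = stats.mannwhitneyu(
        within_arr,
        between_arr,
        alternative="two-sided",
        method="exact" if use_exact else "asymptotic",
    )
    return WithinBetweenResult(
        within=within_arr,
        between=between_arr,
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
    )


def recruitment_rate(
    total_reads: Sequence[int], recruited_reads: Sequence[int]
) -> tuple[np.ndarray, float]:
    """Per-sample and pooled fraction of reads recruited to the curated
    database. Pooled = sum(recruited)/sum(total), the count-weighted mean."""
    total = np.asarray(total_reads, dtype=np.int64)
    recruited = np.asarray(recruited_reads, dtype=np.int64)
    if total.shape != recruited.shape:
        raise ValueError("total and recruited must align")
    if (total <= 0).any():
        raise ValueError("total reads must be positive")
    if (recruited < 0).any() or (recruited > total).any():
        raise ValueError("recruited reads must be in [0, total]")
    per_sample = recruited / total
    pooled = float(recruited.sum() / total.sum())
    return per_sample, pooled


def group_test(values: Sequence[float], groups: Sequence[str]) -> GroupTestResult:
    """Nonparametric location test across groups.

    Two groups: two-sided Mann-Whitney U. Three or more: Kruskal-Wallis H
    with tie correction. All-equal observations are a degenerate case
    (H = 0, p = 1, flagged) rather than an error.
    """
    vals = np.asarray(values, dtype=float)
    labels = [str(g) for g in groups]
    if len(vals) != len(labels):
        raise ValueError("values and groups must align")
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    split = [vals[[i for i, l in enumerate(labels) if l == u]] for u in uniq]
    if any(len(s) == 0 for s in split):
        raise ValueError("empty group")
    if np.ptp(vals) == 0:
        return GroupTestResult(0.0, 1.0, "degenerate", degenerate=True)
    if len(uniq) == 2:
        res = stats.mannwhitneyu(split[0], split[1], alternative="two-sided")
        return GroupTestResult(float(res.statistic), float(res.pvalue), "mann-whitney")
    res = stats.kruskal(*split)
    return GroupTestResult(float(res.statistic), float(res.pvalue), "kruskal-wallis")
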