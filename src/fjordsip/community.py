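"""Community summaries and cross-substrate incorporator comparison.

Composite communities are built per incubation (reads pooled over its
sequenced fractions), since ordination at fraction level would mix density
structure with composition.  Ordination is classical PCoA on Bray-Curtis
dissimilarities; group separation is tested with a one-way PERMANOVA
(seeded label permutations, optionally exhaustive for small n).  Incorporator
sets across substrates are compared through Venn-style disjoint regions,
ordinary least-squares EAF-EAF regression, and a central-subset
(rainbow-type) linearity check.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .data_model import FeatureCountMatrix, TaxonomyTable
from .qsip import EAFEstimate

__all__ = [
    "DistanceMatrix",
    "PCoAResult",
    "PermanovaResult",
    "VennPartition",
    "RegressionResult",
    "composite_communities",
    "relative_abundance",
    "shannon",
    "bray_curtis",
    "pcoa",
    "permanova",
    "venn_partition",
    "pair_eaf",
    "eaf_regression",
    "rainbow_linearity_test",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative dissimilarities with a zero diagonal."""

    ids: tuple[str, ...]
    data: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        n = len(self.ids)
        if d.shape != (n, n):
            raise ValueError(f"distance matrix shape {d.shape} != ({n}, {n})")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(d < 0):
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "data", d)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=list(self.ids), columns=list(self.ids))


def composite_communities(m: FeatureCountMatrix) -> pd.DataFrame:
    """Pool reads over each treatment's sequenced fractions: treatment x ASV."""
    pooled = m.df.T.groupby(level="treatment").sum()
    return pooled


def relative_abundance(
    m: FeatureCountMatrix,
    tax: TaxonomyTable,
    rank: str = "phylum",
    hybrid_proteobacteria: bool = False,
) -> pd.DataFrame:
    """Per-sample proportions aggregated by taxon at ``rank``.

    With ``hybrid_proteobacteria`` (the phylum/class hybrid mode) ASVs whose
    phylum is Proteobacteria are reported at class level (Alpha-, Gamma-...)
    while everything else stays at phylum level.
    """
    if hybrid_proteobacteria:
        labels = {
            a: (
                tax.rank_value(a, "class")
                if "proteobacteria" in tax.rank_value(a, "phylum").lower()
                else tax.rank_value(a, "phylum")
            )
            for a in m.asv_ids
        }
    else:
        labels = {a: tax.rank_value(a, rank) for a in m.asv_ids}
    grouped = m.df.groupby(pd.Series(labels), sort=True).sum()
    col_totals = grouped.sum(axis=0)
    zero = col_totals == 0
    if zero.any():
        bad = list(grouped.columns[zero])
        raise ValueError(f"zero-read sample(s): proportions undefined for {bad[:5]}")
    return grouped.div(col_totals, axis=1)


def shannon(counts: Sequence[float]) -> float:
    """Shannon diversity H = -sum p_i ln p_i (nats), zero-count taxa ignored."""
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total == 0:
        raise ValueError("all-zero sample: Shannon index undefined")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum())


def bray_curtis(abundances: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between rows (samples) of an abundance table."""
    x = abundances.to_numpy(dtype=float)
    if np.any(x < 0):
        raise ValueError("abundances must be non-negative")
    row_sums = x.sum(axis=1)
    if np.sum(row_sums == 0) >= 2:
        zero = list(abundances.index[row_sums == 0])
        raise ValueError(f"Bray-Curtis undefined between all-zero samples: {zero}")
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(tuple(str(i) for i in abundances.index), d)


@dataclass(frozen=True)
class PCoAResult:
    coordinates: pd.DataFrame            # samples x axes
    explained: np.ndarray                # per-axis proportion of positive inertia
    eigenvalues: np.ndarray              # all eigenvalues, descending
    negative_eigenvalues: np.ndarray     # diagnostics, not corrected


def pcoa(d: DistanceMatrix, k: int = 2) -> PCoAResult:
    """Classical metric scaling of a distance matrix.

    Double-centers -1/2 D^2, eigendecomposes, and returns the top-k axes by
    eigenvalue.  Negative eigenvalues (non-Euclidean input) are reported in
    the diagnostics but not corrected.
    """
    D2 = d.data**2
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    tol = max(1e-10, 1e-10 * abs(eigvals[0]) if n else 0.0)
    positive = eigvals > tol
    rank = int(positive.sum())
    if k > rank:
        warnings.warn(
            f"requested {k} axes but the configuration has rank {rank}; "
            f"returning {rank}",
            stacklevel=2,
        )
        k = rank
    coords = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    pos_sum = eigvals[positive].sum()
    explained = eigvals[:k] / pos_sum if pos_sum > 0 else np.zeros(k)
    return PCoAResult(
        coordinates=pd.DataFrame(
            coords, index=list(d.ids), columns=[f"PCo{i+1}" for i in range(k)]
        ),
        explained=explained,
        eigenvalues=eigvals,
        negative_eigenvalues=eigvals[eigvals < -tol],
    )


@dataclass(frozen=True)
class PermanovaResult:
    r2: float
    pseudo_f: float
    p_value: float
    n_permutations: int


def _permanova_stats(
    d2: np.ndarray, labels: np.ndarray, groups: np.ndarray
) -> tuple[float, float]:
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
    ss_between = ss_total - ss_within
    g = groups.size
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    f = (ss_between / (g - 1)) / (ss_within / (n - g))
    return r2, f


def permanova(
    d: DistanceMatrix,
    groups: Sequence[str],
    n_perm: int = 999,
    seed: Optional[int] = None,
    exhaustive: bool = False,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    ``p = (1 + #{permuted F >= observed F}) / (1 + n_perm)`` under seeded
    random label permutations; with ``exhaustive=True`` all distinct label
    arrangements are enumerated instead (identity included) and
    ``p = #{F_perm >= F_obs} / N``.
    """
    labels = np.asarray([str(g) for g in groups])
    if labels.size != len(d.ids):
        raise ValueError("one group label per sample required")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("PERMANOVA needs >= 2 groups")
    if labels.size - uniq.size < 1:
        raise ValueError("all groups are singletons: residual df is zero")
    d2 = d.data**2
    r2, f_obs = _permanova_stats(d2, labels, uniq)

    if exhaustive:
        perms = {p for p in itertools.permutations(labels)}
        count = sum(
            _permanova_stats(d2, np.asarray(p), uniq)[1] >= f_obs for p in perms
        )
        return PermanovaResult(r2, f_obs, count / len(perms), len(perms))

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _permanova_stats(d2, perm, uniq)[1] >= f_obs:
            count += 1
    return PermanovaResult(r2, f_obs, (1 + count) / (1 + n_perm), n_perm)


@dataclass(frozen=True)
class VennPartition:
    """Disjoint region membership over n incorporator sets."""

    sets: dict[str, frozenset[str]]
    regions: dict[str, frozenset[str]] = field(default_factory=dict)

    @property
    def region_counts(self) -> dict[str, int]:
        return {label: len(members) for label, members in self.regions.items()}


def venn_partition(sets: dict[str, set[str]]) -> VennPartition:
    """Partition incorporator sets into the 2^n - 1 disjoint Venn regions.

    Region labels join the member set names with an intersection sign in the
    input order, e.g. ``taurine∩methionine``.
    """
    names = list(sets)
    regions: dict[str, frozenset[str]] = {}
    for r in range(len(names), 0, -1):
        for combo in itertools.combinations(names, r):
            inside = frozenset.intersection(*(frozenset(sets[n]) for n in combo))
            outside = set().union(*(sets[n] for n in names if n not in combo), set())
            regions["∩".join(combo)] = frozenset(inside - outside)
    union = set().union(*(sets[n] for n in names), set())
    covered = set().union(*regions.values(), set())
    assert covered == union, "Venn regions must cover the union exactly"
    return VennPartition(
        sets={n: frozenset(s) for n, s in sets.items()}, regions=regions
    )


def pair_eaf(
    estimates_x: Sequence[EAFEstimate],
    estimates_y: Sequence[EAFEstimate],
    mode: str = "co-incorporators",
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Pair median EAFs of the two treatments by ASV.

    ``co-incorporators`` keeps only ASVs called incorporators in BOTH
    treatments; ``shared`` keeps every ASV estimated in both (sensitivity
    analysis).
    """
    if mode not in ("co-incorporators", "shared"):
        raise ValueError("mode must be 'co-incorporators' or 'shared'")
    ex = {e.asv_id: e for e in estimates_x}
    ey = {e.asv_id: e for e in estimates_y}
    shared = sorted(set(ex) & set(ey))
    if mode == "co-incorporators":
        shared = [a for a in shared if ex[a].is_incorporator and ey[a].is_incorporator]
    x = np.array([ex[a].median_eaf for a in shared])
    y = np.array([ey[a].median_eaf for a in shared])
    return x, y, shared


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    adj_r2: float
    f_stat: float
    p_value: float
    residuals: np.ndarray
    n: int


def eaf_regression(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """OLS of y on x with R^2, adjusted R^2 and the slope F-test."""
    import statsmodels.api as sm

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    if x.size < 3:
        raise ValueError(f"regression needs >= 3 points, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("x is constant: slope undefined")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    n = x.size
    r2 = float(fit.rsquared)
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r2=r2,
        adj_r2=1.0 - (1.0 - r2) * (n - 1) / (n - 2),
        f_stat=float(fit.fvalue),
        p_value=float(fit.f_pvalue),
        residuals=np.asarray(fit.resid),
        n=n,
    )


def rainbow_linearity_test(
    x: Sequence[float], y: Sequence[float], center_fraction: float = 0.5
) -> tuple[float, float]:
    """Rainbow-type linearity check: full fit vs central-subset fit.

    Pairs are ordered by x; an OLS line is fit to the central
    ``ceil(center_fraction * n)`` points and to all n, and
    ``F = ((RSS_full - RSS_sub) / (n - n_sub)) / (RSS_sub / (n_sub - 2))``
    is referred to F(n - n_sub, n_sub - 2).  Numerically flat data
    (RSS_full <= RSS_sub) yields F = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size:
        raise ValueError("x and y must be paired")
    if n < 6:
        raise ValueError(f"linearity check needs n >= 6, got {n}")
    n_sub = int(np.ceil(center_fraction * n))
    if n_sub < 3:
        raise ValueError(f"central subset of {n_sub} points is too small")
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    lo = (n - n_sub) // 2
    xc, yc = xs[lo : lo + n_sub], ys[lo : lo + n_sub]

    def rss(xv: np.ndarray, yv: np.ndarray) -> float:
        X = np.column_stack([np.ones_like(xv), xv])
        beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
        r = yv - X @ beta
        return float(r @ r)

    rss_full = rss(xs, ys)
    rss_sub = rss(xc, yc)
    df1, df2 = n - n_sub, n_sub - 2
    if rss_full <= rss_sub:
        return 0.0, 1.0
    if rss_sub == 0.0:  # central subset exactly linear, flanks are not
        return float("inf"), 0.0
    f = ((rss_full - rss_sub) / df1) / (rss_sub / df2)
    p = float(stats.f.sf(f, df1, df2))
    return float(f), p
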