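"""Normalization, alpha/beta diversity, ordination and permutation tests.

Counts are first converted to within-library relative abundances (Total
Sum Normalization).  Alpha diversity reports richness, Shannon entropy
(natural log) and the Gini-Simpson index 1 - sum(p^2).  Beta diversity is
the Bray-Curtis dissimilarity on abundances and the Sorensen dissimilarity
on presence/absence; the latter is algebraically Bray-Curtis applied to
binarized data, which the test suite exploits as a cross-check.

PERMANOVA partitions the Gower-centered squared-dissimilarity matrix into
sequential (order-of-entry) terms and tests each pseudo-F against
whole-library label permutations (Anderson 2001).  Ordination is
non-metric multidimensional scaling minimising Kruskal stress-1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from scipy.special import gammaln

from .io import CountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "RelAbundanceMatrix",
    "DissimilarityMatrix",
    "PermanovaResult",
    "NmdsResult",
    "tss_normalize",
    "alpha_diversity",
    "beta_dissimilarity",
    "mean_between_group_dissimilarity",
    "permanova",
    "nmds",
    "rarefaction_curve",
    "mann_whitney_test",
    "kruskal_wallis_test",
    "spearman_association",
    "group_test",
]

METRICS = ("sorensen", "bray_curtis")


@dataclass
class RelAbundanceMatrix:
    """Relative abundances, taxa x libraries; each column sums to 1.

    Libraries whose raw total was zero stay all-zero and are listed in
    ``zero_libraries``.
    """

    data: pd.DataFrame
    zero_libraries: list[str] = field(default_factory=list)

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def libraries(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class DissimilarityMatrix:
    """Symmetric library x library dissimilarities in [0, 1]."""

    values: np.ndarray
    ids: list[str]
    metric: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValueError("dissimilarity matrix shape does not match ids")
        if not np.all(np.isfinite(v)):
            raise ValueError("dissimilarity matrix contains non-finite values")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("dissimilarity matrix is not symmetric")
        if not np.allclose(np.diag(v), 0, atol=1e-12):
            raise ValueError("dissimilarity matrix diagonal is not zero")
        if v.size and (v.min() < -1e-12 or v.max() > 1 + 1e-12):
            raise ValueError("dissimilarities outside [0, 1]")
        self.values = np.clip((v + v.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(self.values, 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_long(self) -> pd.DataFrame:
        """Long format: one row per unordered library pair."""
        rows = []
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append({"lib_a": self.ids[i], "lib_b": self.ids[j],
                             "metric": self.metric, "value": self.values[i, j]})
        return pd.DataFrame(rows, columns=["lib_a", "lib_b", "metric", "value"])


def tss_normalize(counts: CountMatrix) -> RelAbundanceMatrix:
    """Total Sum Normalization: divide each library by its read total."""
    df = counts.data.astype(float)
    totals = df.sum(axis=0)
    zero = [str(c) for c in totals.index[totals == 0]]
    if zero:
        logger.warning("TSS: %d all-zero libraries left as zeros: %s", len(zero), zero)
    safe = totals.replace(0, 1.0)
    return RelAbundanceMatrix(df.div(safe, axis=1), zero_libraries=zero)


def alpha_diversity(rel: RelAbundanceMatrix) -> pd.DataFrame:
    """Per-library richness, Shannon (ln) and Gini-Simpson indices."""
    out = {}
    for lib in rel.libraries:
        p = rel.data[lib].to_numpy()
        p = p[p > 0]
        out[lib] = {
            "richness": int(p.size),
            "shannon": float(-(p * np.log(p)).sum()) if p.size else 0.0,
            "simpson": float(1.0 - (p ** 2).sum()) if p.size else 0.0,
        }
    df = pd.DataFrame(out).T
    df.index.name = "library_id"
    df["richness"] = df["richness"].astype(int)
    return df


def beta_dissimilarity(rel: RelAbundanceMatrix, metric: str = "bray_curtis") -> DissimilarityMatrix:
    """Pairwise Bray-Curtis (abundance) or Sorensen (presence/absence).

    Sorensen is computed as Bray-Curtis on the binarized matrix, which is
    the (b + c) / (2a + b + c) form exactly.  A pair of all-zero libraries
    gets dissimilarity 0 with a warning.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    if len(rel.libraries) < 2:
        raise ValueError("need at least two libraries")
    X = rel.data.to_numpy().T  # libraries x taxa
    if metric == "sorensen":
        X = (X > 0).astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        cond = pdist(X, metric="braycurtis")
    if np.isnan(cond).any():
        logger.warning("all-zero library pair(s): dissimilarity set to 0")
        cond = np.nan_to_num(cond, nan=0.0)
    return DissimilarityMatrix(squareform(cond), list(rel.libraries), metric)


def mean_between_group_dissimilarity(
    D: DissimilarityMatrix, groups: Mapping[str, str] | pd.Series
) -> float:
    """Mean dissimilarity over library pairs with different group labels."""
    labels = [groups[i] for i in D.ids]
    if len(set(labels)) < 2:
        raise ValueError("need at least two groups for a between-group mean")
    vals = []
    n = len(D.ids)
    for i in range(n):
        for j in range(i + 1, n):
            if labels[i] != labels[j]:
                vals.append(D.values[i, j])
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    table: pd.DataFrame  # index: terms + Residual + Total
    n_permutations: int
    seed: int

    def p_value(self, term: str) -> float:
        return float(self.table.loc[term, "p_value"])


def _gower_center(D: np.ndarray) -> np.ndarray:
    A = -0.5 * D ** 2
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ A @ J


def _term_columns(design: pd.DataFrame, term: str) -> np.ndarray:
    """Dummy columns for a main effect or a ':'-interaction term."""
    factors = term.split(":")
    for f in factors:
        if f not in design.columns:
            raise ValueError(f"PERMANOVA: factor {f!r} not in design table")
        if design[f].astype(str).nunique() < 2:
            raise ValueError(f"PERMANOVA: factor {f!r} is constant")
    combined = design[factors[0]].astype(str)
    for f in factors[1:]:
        combined = combined + "\x1f" + design[f].astype(str)
    return pd.get_dummies(combined, dtype=float).to_numpy()


def _projector(X: np.ndarray) -> np.ndarray:
    """Orthogonal projector onto the column space of X (rank-safe)."""
    from scipy.linalg import orth
    U = orth(X)
    return U @ U.T


def permanova(
    D: DissimilarityMatrix,
    design: pd.DataFrame,
    terms: Sequence[str],
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Permutational multivariate ANOVA with sequential sums of squares.

    ``design`` is indexed (or ordered) like ``D.ids``; ``terms`` are factor
    names or ``a:b`` interactions, fitted in the given order.  The p-value
    for each term is ``(1 + #{F_perm >= F_obs}) / (1 + n_perm)`` under
    unrestricted whole-library permutations, reproducible for a given seed.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    n = len(D.ids)
    if set(D.ids).issubset(set(design.index.astype(str))):
        design = design.loc[D.ids]
    elif len(design) != n:
        raise ValueError("design table does not align with dissimilarity ids")

    G = _gower_center(D.values)
    ss_total = float(np.trace(G))

    # nested projectors: intercept, then cumulative terms
    ones = np.ones((n, 1))
    X = ones
    projectors = [_projector(X)]
    dfs = []
    rank_prev = 1
    for term in terms:
        X = np.hstack([X, _term_columns(design, term)])
        P = _projector(X)
        rank = int(np.linalg.matrix_rank(X))
        if rank == rank_prev:
            raise ValueError(f"PERMANOVA: term {term!r} adds no degrees of freedom "
                             "(aliased with earlier terms)")
        dfs.append(rank - rank_prev)
        rank_prev = rank
        projectors.append(P)

    df_resid = n - rank_prev
    if df_resid <= 0:
        raise ValueError("PERMANOVA: saturated design (no residual df)")
    # hat-difference matrices: trace(M_j G) = SS of term j; residual uses I-P_full
    M_terms = [projectors[k + 1] - projectors[k] for k in range(len(terms))]
    M_resid = np.eye(n) - projectors[-1]

    def _ss(Gmat: np.ndarray) -> tuple[np.ndarray, float]:
        term_ss = np.array([float(np.sum(M * Gmat)) for M in M_terms])
        return term_ss, float(np.sum(M_resid * Gmat))

    obs_ss, obs_res = _ss(G)
    obs_F = (obs_ss / np.array(dfs)) / (obs_res / df_resid)

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    G_perms = G[perms[:, :, None], perms[:, None, :]]
    term_ss_p = np.stack([
        np.einsum("ij,pij->p", M, G_perms) for M in M_terms
    ])  # (n_terms, n_perm)
    res_p = np.einsum("ij,pij->p", M_resid, G_perms)
    F_p = (term_ss_p / np.array(dfs)[:, None]) / (res_p[None, :] / df_resid)

    eps = 1e-12  # count permutation ties as exceedances
    exceed = (F_p >= obs_F[:, None] - eps).sum(axis=1)
    p_vals = (1.0 + exceed) / (1.0 + n_perm)

    rows = []
    for k, term in enumerate(terms):
        rows.append({
            "df": dfs[k], "sum_sq": obs_ss[k], "pseudo_F": obs_F[k],
            "R2": obs_ss[k] / ss_total, "p_value": p_vals[k],
        })
    rows.append({"df": df_resid, "sum_sq": obs_res, "pseudo_F": np.nan,
                 "R2": obs_res / ss_total, "p_value": np.nan})
    rows.append({"df": n - 1, "sum_sq": ss_total, "pseudo_F": np.nan,
                 "R2": 1.0, "p_value": np.nan})
    table = pd.DataFrame(rows, index=[*terms, "Residual", "Total"])
    return PermanovaResult(table=table, n_permutations=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

@dataclass
class NmdsResult:
    coordinates: pd.DataFrame  # libraries x axes
    stress: float  # Kruskal stress-1 of the best restart
    n_restarts: int
    seed: int


def nmds(
    D: DissimilarityMatrix,
    k: int = 2,
    n_restarts: int = 20,
    seed: int = 0,
    max_iter: int = 300,
    eps: float = 1e-6,
) -> NmdsResult:
    """Non-metric MDS; returns the best of ``n_restarts`` seeded starts."""
    from sklearn.manifold import MDS

    n = len(D.ids)
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} libraries for {k}-d NMDS")
    model = MDS(
        n_components=k, metric=False, dissimilarity="precomputed",
        n_init=n_restarts, random_state=seed, max_iter=max_iter, eps=eps,
        normalized_stress=True,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords = model.fit_transform(D.values)
    cols = [f"NMDS{i + 1}" for i in range(k)]
    return NmdsResult(
        coordinates=pd.DataFrame(coords, index=D.ids, columns=cols),
        stress=float(model.stress_), n_restarts=n_restarts, seed=seed,
    )


# ---------------------------------------------------------------------------
# rarefaction
# ---------------------------------------------------------------------------

def rarefaction_curve(
    counts: Sequence[int] | np.ndarray,
    depths: Sequence[int],
    mode: str = "analytic",
    seed: int = 0,
    n_iter: int = 100,
) -> pd.DataFrame:
    """Expected taxon richness at each subsampling depth for one library.

    Analytic mode uses the hypergeometric expectation
    ``E[S(m)] = sum_i (1 - C(N - N_i, m) / C(N, m))``; resample mode is the
    mean over seeded subsamples without replacement.
    """
    x = np.asarray(counts, dtype=np.int64)
    if (x < 0).any():
        raise ValueError("negative counts")
    x = x[x > 0]
    N = int(x.sum())
    depths = np.asarray(depths, dtype=np.int64)
    if (depths < 1).any() or (depths > N).any():
        raise ValueError(f"depths must lie in [1, {N}]")

    if mode == "analytic":
        # log-space binomial ratios to stay finite at large N
        def expected(m: int) -> float:
            keep = x > N - m  # these taxa are always captured
            rest = x[~keep]
            if rest.size:
                log_ratio = (
                    gammaln(N - rest + 1) - gammaln(N - rest - m + 1)
                    - gammaln(N + 1) + gammaln(N - m + 1)
                )
                miss = np.exp(log_ratio)
            else:
                miss = np.array([])
            return float(keep.sum() + (1.0 - miss).sum())

        rich = [expected(int(m)) for m in depths]
    elif mode == "resample":
        rng = np.random.default_rng(seed)
        pool = np.repeat(np.arange(x.size), x)
        rich = []
        for m in depths:
            vals = []
            for _ in range(n_iter):
                sub = rng.choice(pool, size=int(m), replace=False)
                vals.append(len(np.unique(sub)))
            rich.append(float(np.mean(vals)))
    else:
        raise ValueError("mode must be 'analytic' or 'resample'")
    return pd.DataFrame({"depth": depths, "expected_richness": rich})


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------

@dataclass
class GroupTestResult:
    test: str
    statistic: float
    p_value: float


def mann_whitney_test(values: pd.Series, factor: pd.Series) -> GroupTestResult:
    """Two-sided Mann-Whitney U; exact null distribution for n_total <= 20."""
    levels = sorted(pd.unique(factor))
    if len(levels) != 2:
        raise ValueError("Mann-Whitney needs exactly two groups")
    x = values[factor == levels[0]].to_numpy(dtype=float)
    y = values[factor == levels[1]].to_numpy(dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty group")
    method = "exact" if (x.size + y.size) <= 20 else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return GroupTestResult("mann_whitney", float(res.statistic), float(res.pvalue))


def kruskal_wallis_test(values: pd.Series, factor: pd.Series) -> GroupTestResult:
    groups = [values[factor == lv].to_numpy(dtype=float) for lv in pd.unique(factor)]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("Kruskal-Wallis needs >= 2 non-empty groups")
    res = stats.kruskal(*groups)
    return GroupTestResult("kruskal_wallis", float(res.statistic), float(res.pvalue))


def spearman_association(x: Sequence[float], y: Sequence[float]) -> GroupTestResult:
    res = stats.spearmanr(x, y)
    return GroupTestResult("spearman", float(res.statistic), float(res.pvalue))


def group_test(values: pd.Series, factor: pd.Series) -> GroupTestResult:
    """Dispatch: Mann-Whitney for 2 levels, Kruskal-Wallis for more."""
    n_levels = pd.unique(factor).size
    if n_levels < 2:
        raise ValueError("factor must have at least two levels")
    if n_levels == 2:
        return mann_whitney_test(values, factor)
    return kruskal_wallis_test(values, factor)
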