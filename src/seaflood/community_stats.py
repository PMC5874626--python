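"""Community statistics: Bray–Curtis, UPGMA, NMDS, PERMANOVA, vector fits.

The statistical layer consumes the OTU table produced by the fragment
pipeline.  Dissimilarity between communities is Bray–Curtis,
d(a,b) = 1 − 2·Σ min(a_i, b_i) / (Σ a_i + Σ b_i).  Sample structure is
summarised three ways: agglomerative UPGMA clustering, non-metric
multidimensional scaling (Kruskal stress-1, best of seeded restarts), and a
PERMANOVA (adonis-style) partition of the distance matrix's sum of squares
into sequential model terms with free-permutation p-values.  Environmental
covariates are related to an ordination by least-squares vector fitting, and
OTU-level structure is summarised by presence sharing across sample groups
and by "module" detection — UPGMA over OTU abundance profiles cut into k
groups of co-occurring OTUs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import MDS

from .errors import InputError
from .trflp_pipeline import OtuTable

#: Exhaustive-permutation cap: enumerate all n! permutations when n! <= this.
EXHAUSTIVE_CAP = 10_000


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric Bray–Curtis dissimilarity matrix with ordered labels."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise InputError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise InputError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise InputError("distance matrix diagonal is not zero")

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


@dataclass(frozen=True)
class Dendrogram:
    """UPGMA merge tree (scipy linkage encoding) over labelled leaves."""

    labels: tuple[str, ...]
    linkage: np.ndarray

    def cophenetic(self) -> np.ndarray:
        """Cophenetic distance matrix in label order."""
        return squareform(hierarchy.cophenet(self.linkage))

    def cut(self, k: int) -> pd.Series:
        flat = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(flat, index=list(self.labels))


@dataclass(frozen=True)
class Ordination:
    """NMDS scores with the best-restart Kruskal stress-1."""

    labels: tuple[str, ...]
    scores: np.ndarray          # n × k, centered
    stress: float
    restart_stresses: tuple[float, ...]
    n_restarts: int
    seed: int
    converged: bool


@dataclass(frozen=True)
class PermanovaResult:
    """Sequential (Type I) distance-based ANOVA table."""

    terms: tuple[str, ...]
    df: tuple[int, ...]
    ss: tuple[float, ...]
    r2: tuple[float, ...]
    f: tuple[float, ...]
    p: tuple[float, ...]
    residual_df: int
    residual_ss: float
    residual_r2: float
    total_ss: float
    n_permutations: int
    exhaustive: bool
    seed: int | None
    singleton_groups: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        rows = [(t, d, s, r, f_, p_) for t, d, s, r, f_, p_ in
                zip(self.terms, self.df, self.ss, self.r2, self.f, self.p)]
        rows.append(("Residual", self.residual_df, self.residual_ss,
                     self.residual_r2, math.nan, math.nan))
        rows.append(("Total", self.residual_df + sum(self.df), self.total_ss,
                     1.0, math.nan, math.nan))
        return pd.DataFrame(rows, columns=["term", "df", "SS", "R2", "F", "p"])


@dataclass(frozen=True)
class VectorFit:
    """Per-variable direction cosines, R² and permutation p on an ordination."""

    variables: tuple[str, ...]
    directions: np.ndarray        # m × k, unit rows
    r2: tuple[float, ...]
    p: tuple[float, ...]
    skipped: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        k = self.directions.shape[1] if len(self.variables) else 2
        cols = [f"axis{i + 1}" for i in range(k)]
        df = pd.DataFrame(self.directions, index=list(self.variables), columns=cols)
        df["r2"] = self.r2
        df["p"] = self.p
        df.index.name = "variable"
        return df


# ---------------------------------------------------------------------------
# Distances and clustering
# ---------------------------------------------------------------------------

def bray_curtis(table: OtuTable | pd.DataFrame, axis: str = "samples",
                ) -> DistanceMatrix:
    """Bray–Curtis dissimilarities between samples (rows) or OTUs (columns)."""
    data = table.data if isinstance(table, OtuTable) else table
    mat = data.to_numpy(float)
    labels = list(data.index)
    if axis == "otus":
        mat = mat.T
        labels = list(data.columns)
    elif axis != "samples":
        raise InputError(f"axis must be 'samples' or 'otus', got {axis!r}")
    if (mat < 0).any():
        raise InputError("Bray-Curtis requires non-negative abundances")
    sums = mat.sum(axis=1)
    zero = [labels[i] for i in np.flatnonzero(sums == 0)]
    if zero:
        raise InputError(f"zero-sum row(s) on axis {axis!r}: {zero}")
    d = squareform(pdist(mat, metric="braycurtis"))
    return DistanceMatrix(labels=tuple(labels), values=d)


def hierarchical_cluster(d: DistanceMatrix) -> Dendrogram:
    """UPGMA (average-linkage) agglomeration of a distance matrix."""
    if len(d.labels) < 2:
        raise InputError("hierarchical clustering needs >= 2 items")
    z = hierarchy.linkage(d.condensed(), method="average")
    return Dendrogram(labels=d.labels, linkage=z)


def nmds(d: DistanceMatrix, k: int = 2, n_restarts: int = 20,
         seed: int = 0, max_iter: int = 300, eps: float = 1e-7) -> Ordination:
    """Non-metric MDS, best of ``n_restarts`` seeded random starts.

    Stress is Kruskal stress-1; scores are centered.  Implemented over
    sklearn's SMACOF non-metric solver, one random initialisation per
    restart, all seeded from ``seed`` so the result is reproducible.
    """
    if k < 1:
        raise InputError(f"k must be >= 1, got {k}")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_restarts)
    best_scores, stresses = None, []
    for s in child_seeds:
        model = MDS(n_components=k, metric_mds=False, metric="precomputed",
                    n_init=1, init="random", random_state=int(s % (2 ** 31)),
                    max_iter=max_iter, eps=eps, normalized_stress=True)
        scores = model.fit_transform(d.values)
        stresses.append(float(model.stress_))
        if best_scores is None or model.stress_ <= min(stresses[:-1], default=np.inf):
            best_scores = scores
    best = float(min(stresses))
    converged = math.isfinite(best)
    centered = best_scores - best_scores.mean(axis=0, keepdims=True)
    return Ordination(labels=d.labels, scores=centered, stress=best,
                      restart_stresses=tuple(stresses), n_restarts=n_restarts,
                      seed=seed, converged=converged)


# ---------------------------------------------------------------------------
# PERMANOVA (adonis): sequential SS partition of a distance matrix
# ---------------------------------------------------------------------------

def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d ** 2
    n = d.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    return j @ a @ j


def _design_columns(values: pd.Series) -> np.ndarray:
    """Model columns for one factor: dummies for categoricals, the centered
    values for numeric factors."""
    if pd.api.types.is_numeric_dtype(values):
        v = values.to_numpy(float)
        return (v - v.mean())[:, None]
    levels = pd.unique(values)
    if len(levels) < 2:
        raise InputError(f"constant factor {values.name!r}")
    return (values.to_numpy()[:, None] == levels[None, :]).astype(float)


def _hat(x: np.ndarray) -> tuple[np.ndarray, int]:
    q, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    rank = int(np.sum(diag > diag.max() * 1e-10))
    q = q[:, :rank]
    return q @ q.T, rank


def permanova(d: DistanceMatrix, factors: pd.DataFrame,
              terms: list[str] | None = None, n_perm: int = 999,
              seed: int | None = 0, exhaustive_cap: int = EXHAUSTIVE_CAP,
              ) -> PermanovaResult:
    """Distance-based multivariate ANOVA with sequential sums of squares.

    The Gower-centered matrix G of squared distances is partitioned into
    terms by nested hat matrices of the cumulative model designs (Type I, in
    ``terms`` order); pseudo-F per term uses the residual mean square.
    p-values come from free row/column permutation of the distance matrix:
    all n! permutations are enumerated when n! <= ``exhaustive_cap``
    (p = #(F* >= F)/n!, identity included); otherwise ``n_perm`` random
    permutations with the +1 correction, p = (#(F* >= F) + 1)/(n_perm + 1).
    """
    if n_perm < 99:
        raise InputError(f"n_perm must be >= 99, got {n_perm}")
    n = len(d.labels)
    factors = factors.loc[list(d.labels)]
    if terms is None:
        terms = list(factors.columns)
    singleton = []
    for t in terms:
        col = factors[t]
        if not pd.api.types.is_numeric_dtype(col):
            counts = col.value_counts()
            if counts.min() == 1:
                singleton.append(t)

    g = _gower_center(d.values)
    total_ss = float(np.trace(g))

    ones = np.ones((n, 1))
    cumulative = [ones]
    hats, ranks = [], []
    for t in terms:
        cumulative.append(_design_columns(factors[t]))
        h, r = _hat(np.hstack(cumulative))
        hats.append(h)
        ranks.append(r)
    h0_rank = 1
    dfs = tuple(int(r - prev) for r, prev in zip(ranks, [h0_rank] + ranks[:-1]))
    if any(df == 0 for df in dfs):
        raise InputError("a term adds no rank to the design (aliased factor)")
    resid_df = n - ranks[-1]
    if resid_df <= 0:
        raise InputError("no residual degrees of freedom")

    # tr(H G) for a symmetric H equals sum(H * G); H of the intercept-only
    # model contributes nothing because G is doubly centered.
    ss_tol = 1e-12 * max(total_ss, 1.0)

    def term_stats(gmat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        traces = np.array([float(np.sum(h * gmat)) for h in hats])
        ss = np.diff(np.concatenate([[0.0], traces]))
        ss_res = float(np.trace(gmat)) - traces[-1]
        if ss_res <= ss_tol:
            # perfect fit: the model absorbs all variation; pseudo-F is
            # infinite for any term with signal, so permutations that also
            # fit perfectly tie with the observed statistic
            f = np.where(ss > ss_tol, np.inf, 0.0)
        else:
            f = (ss / np.array(dfs)) / (ss_res / resid_df)
        return ss, f

    ss_obs, f_obs = term_stats(g)
    ss_res = total_ss - float(ss_obs.sum())

    n_fact = math.factorial(n)
    exhaustive = n_fact <= exhaustive_cap
    if exhaustive:
        perms = itertools.permutations(range(n))
        count_ge = np.zeros(len(terms))
        n_done = 0
        for p in perms:
            idx = np.array(p)
            _, f_p = term_stats(g[np.ix_(idx, idx)])
            count_ge += f_p >= f_obs - 1e-12
            n_done += 1
        pvals = count_ge / n_done
        n_perm_used = n_done
    else:
        rng = np.random.default_rng(seed)
        count_ge = np.zeros(len(terms))
        for _ in range(n_perm):
            idx = rng.permutation(n)
            _, f_p = term_stats(g[np.ix_(idx, idx)])
            count_ge += f_p >= f_obs - 1e-12
        pvals = (count_ge + 1) / (n_perm + 1)
        n_perm_used = n_perm

    r2 = tuple(float(s / total_ss) for s in ss_obs)
    return PermanovaResult(
        terms=tuple(terms), df=dfs, ss=tuple(map(float, ss_obs)), r2=r2,
        f=tuple(map(float, f_obs)), p=tuple(map(float, pvals)),
        residual_df=resid_df, residual_ss=float(ss_res),
        residual_r2=float(ss_res / total_ss), total_ss=total_ss,
        n_permutations=n_perm_used, exhaustive=exhaustive, seed=seed,
        singleton_groups=tuple(singleton))


# ---------------------------------------------------------------------------
# Vector fitting, sharing counts, modules
# ---------------------------------------------------------------------------

def fit_env_vectors(ordination: Ordination, env: pd.DataFrame,
                    n_perm: int = 999, seed: int = 0) -> VectorFit:
    """Least-squares fit of each environmental variable onto the ordination.

    Each numeric variable is regressed on the score columns; R² is the fit's
    coefficient of determination, the direction is the unit-normalised
    coefficient vector, and p comes from permuting the variable across
    samples.  Zero-variance variables are flagged and skipped.
    """
    env = env.loc[list(ordination.labels)]
    x = ordination.scores - ordination.scores.mean(axis=0, keepdims=True)
    rng = np.random.default_rng(seed)
    variables, dirs, r2s, ps, skipped = [], [], [], [], []
    for name in env.columns:
        y = env[name].to_numpy(float)
        if np.ptp(y) == 0 or not np.all(np.isfinite(y)):
            skipped.append(name)
            continue
        yc = y - y.mean()
        sst = float(yc @ yc)

        def r2_of(yvec: np.ndarray) -> tuple[float, np.ndarray]:
            beta, *_ = np.linalg.lstsq(x, yvec, rcond=None)
            resid = yvec - x @ beta
            return 1.0 - float(resid @ resid) / sst, beta

        r2, beta = r2_of(yc)
        norm = np.linalg.norm(beta)
        direction = beta / norm if norm > 0 else np.zeros_like(beta)
        count = 0
        for _ in range(n_perm):
            yp = rng.permutation(yc)
            r2p, _ = r2_of(yp)
            count += r2p >= r2 - 1e-12
        variables.append(name)
        dirs.append(direction)
        r2s.append(r2)
        ps.append((count + 1) / (n_perm + 1))
    directions = np.array(dirs) if dirs else np.empty((0, x.shape[1]))
    return VectorFit(variables=tuple(variables), directions=directions,
                     r2=tuple(r2s), p=tuple(ps), skipped=tuple(skipped))


def sharing_counts(groups: dict[str, set[str]]) -> pd.DataFrame:
    """Count OTUs present in exactly each non-empty combination of groups.

    Returns a frame with one row per Venn cell (combination, count); counts
    sum to the number of distinct OTUs present in at least one group.
    """
    names = list(groups)
    cells: dict[tuple[str, ...], int] = {}
    for otu in set().union(*groups.values()) if groups else set():
        combo = tuple(n for n in names if otu in groups[n])
        cells[combo] = cells.get(combo, 0) + 1
    rows = []
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            rows.append(("+".join(combo), cells.get(combo, 0)))
    return pd.DataFrame(rows, columns=["groups", "n_otus"])


def detect_modules(table: OtuTable, k: int) -> pd.Series:
    """Group OTUs into k modules of similar abundance pattern.

    UPGMA over Bray–Curtis distances between OTU abundance profiles, cut
    into k flat clusters.  Module labels (1..k) are ordered by the first
    sample (in table order) where any member OTU is nonzero, so module 1
    "appears" earliest along the sample ordering.
    """
    n_otus = len(table.otu_ids)
    if n_otus < 2:
        raise InputError("detect_modules needs >= 2 OTUs")
    if k > n_otus:
        raise InputError(f"k={k} exceeds number of OTUs ({n_otus})")
    d = bray_curtis(table, axis="otus")
    tree = hierarchical_cluster(d)
    raw = tree.cut(k)

    first_idx = {}
    mat = table.data.to_numpy()
    for label in raw.unique():
        members = [i for i, o in enumerate(table.otu_ids) if raw[o] == label]
        nz = np.flatnonzero(mat[:, members].sum(axis=1) > 0)
        first_idx[label] = int(nz[0]) if len(nz) else len(table.sample_ids)
    order = sorted(raw.unique(), key=lambda lb: (first_idx[lb], lb))
    relabel = {old: new + 1 for new, old in enumerate(order)}
    return raw.map(relabel).rename("module")
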