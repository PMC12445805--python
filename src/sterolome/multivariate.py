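"""Ordination and permutation statistics for compositional dissimilarities.

Implemented here rather than delegated: non-metric multidimensional
scaling (Kruskal stress-1 minimised by majorization with isotonic
regression of configuration distances on the input dissimilarities),
PERMANOVA with pairwise contrasts and a dispersion (homogeneity) test,
indicator-value analysis, the Kruskal-Wallis rank test with Dunn post hoc
comparisons, and the Benjamini-Hochberg step-up adjustment. Permutation
p-values use the (1 + b) / (1 + m) estimator so a p-value is never zero,
and every test is reproducible from its seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

from .exceptions import DegenerateInputError, SterolomeError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up false-discovery-rate adjustment.

    adjusted p_(i) = min over j >= i of p_(j) * m / j, capped at 1,
    returned in the original order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise SterolomeError("p_values must be one-dimensional")
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise SterolomeError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty_like(adjusted)
    out[order] = adjusted
    return out


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame
    stress: float
    k: int
    converged: bool
    n_tries: int


def _pcoa_coords(d: np.ndarray, k: int) -> np.ndarray:
    """Classical principal-coordinate configuration used to seed NMDS."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(g)
    idx = np.argsort(vals)[::-1][:k]
    vals_k = np.clip(vals[idx], 0.0, None)
    return vecs[:, idx] * np.sqrt(vals_k)


def _nmds_single(
    diss: np.ndarray, x0: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, float]:
    """One monotone-regression majorization run from configuration x0."""
    n = x0.shape[0]
    iu = np.triu_indices(n, 1)
    diss_flat = diss[iu]
    order = np.argsort(diss_flat, kind="stable")
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    x = x0 - x0.mean(axis=0)
    last_stress = np.inf
    for _ in range(max_iter):
        dist = squareform(pdist(x))
        dist_flat = dist[iu]
        denom = float(np.sum(dist_flat**2))
        if denom <= 0:
            return x, 1.0
        # primary approach to ties: isotonic regression averages equal
        # dissimilarities
        dhat_flat = iso.fit_transform(diss_flat[order], dist_flat[order])
        dhat_sorted = np.empty_like(dhat_flat)
        dhat_sorted[order] = dhat_flat
        stress = float(np.sqrt(np.sum((dist_flat - dhat_sorted) ** 2) / denom))
        if abs(last_stress - stress) < tol:
            last_stress = stress
            break
        last_stress = stress
        # Guttman transform toward the fitted monotone distances
        dhat = np.zeros_like(dist)
        dhat[iu] = dhat_sorted
        dhat = dhat + dhat.T
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 0, dhat / dist, 0.0)
        b = -ratio
        np.fill_diagonal(b, 0.0)
        np.fill_diagonal(b, -b.sum(axis=1))
        x = (b @ x) / n
        x = x - x.mean(axis=0)
    return x, last_stress


def nmds(
    d: pd.DataFrame,
    k: int = 2,
    max_tries: int = 20,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-9,
) -> OrdinationResult:
    """Non-metric multidimensional scaling into k dimensions.

    The best (lowest Kruskal stress-1) configuration is kept across a
    principal-coordinate-seeded start plus ``max_tries - 1`` random
    restarts. Deterministic for a fixed seed.
    """
    arr = d.to_numpy(dtype=float)
    n = arr.shape[0]
    if arr.shape[0] != arr.shape[1] or not np.allclose(arr, arr.T):
        raise SterolomeError("dissimilarity matrix must be square and symmetric")
    if n <= k:
        raise SterolomeError(f"need more than k={k} points, got {n}")
    iu = np.triu_indices(n, 1)
    if np.all(arr[iu] < 1e-12):
        raise DegenerateInputError("all points identical; NMDS undefined")
    rng = np.random.default_rng(seed)
    logger.info("NMDS: k=%d, %d restarts, seed=%d", k, max_tries, seed)

    best_x, best_stress = _nmds_single(arr, _pcoa_coords(arr, k), max_iter, tol)
    for _ in range(max_tries - 1):
        x0 = rng.standard_normal((n, k))
        x, stress = _nmds_single(arr, x0, max_iter, tol)
        if stress < best_stress - 1e-12:
            best_x, best_stress = x, stress
    coords = pd.DataFrame(
        best_x - best_x.mean(axis=0),
        index=d.index,
        columns=[f"NMDS{i + 1}" for i in range(k)],
    )
    return OrdinationResult(
        coordinates=coords,
        stress=best_stress,
        k=k,
        converged=bool(np.isfinite(best_stress)),
        n_tries=max_tries,
    )


def nmds_auto(
    d: pd.DataFrame,
    stress_cutoff: float = 0.2,
    max_k: int = 4,
    max_tries: int = 20,
    seed: int = 0,
) -> OrdinationResult:
    """Escalate NMDS dimensionality from k=2 until stress <= cutoff,
    returning the lowest-k acceptable solution (or the best attempt)."""
    result = None
    for k in range(2, max_k + 1):
        if d.shape[0] <= k:
            break
        result = nmds(d, k=k, max_tries=max_tries, seed=seed)
        if result.stress <= stress_cutoff:
            return result
    return result


# ---------------------------------------------------------------------------
# PERMANOVA family
# ---------------------------------------------------------------------------

@dataclass
class PermTestResult:
    statistic: float
    r_squared: float
    p_value: float
    n_permutations: int
    seed: int
    df_between: int | None = None
    df_within: int | None = None
    extras: dict = field(default_factory=dict)


def _group_arrays(d: pd.DataFrame, groups) -> tuple[np.ndarray, np.ndarray]:
    arr = d.to_numpy(dtype=float)
    g = pd.Series(groups)
    if len(g) != len(d):
        g = g.loc[d.index]
    codes, _ = pd.factorize(g.to_numpy())
    return arr, codes


def _permanova_stats(d2: np.ndarray, codes: np.ndarray) -> tuple[float, float]:
    """Pseudo-F and R^2 from squared dissimilarities and group codes."""
    n = d2.shape[0]
    n_groups = codes.max() + 1
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    df_b = n_groups - 1
    df_w = n - n_groups
    f = (ss_between / df_b) / (ss_within / df_w)
    return f, ss_between / ss_total


def permanova(
    d: pd.DataFrame, groups, n_permutations: int = 999, seed: int = 0
) -> PermTestResult:
    """Permutational multivariate ANOVA on a dissimilarity matrix.

    The pseudo-F partitions the total sum of squared dissimilarities
    (sum d^2 / n) into between- and within-group components; the p-value
    permutes group labels, using (1 + b) / (1 + m).
    """
    arr, codes = _group_arrays(d, groups)
    n_groups = codes.max() + 1
    if n_groups < 2:
        raise SterolomeError("PERMANOVA needs >= 2 groups")
    counts = np.bincount(codes)
    if (counts < 2).any():
        raise SterolomeError("every group needs >= 2 members")
    d2 = arr**2
    f_obs, r2 = _permanova_stats(d2, codes)
    rng = np.random.default_rng(seed)
    logger.info("PERMANOVA: %d permutations, seed=%d", n_permutations, seed)
    hits = 0
    for _ in range(n_permutations):
        f_perm, _ = _permanova_stats(d2, rng.permutation(codes))
        if f_perm >= f_obs:
            hits += 1
    return PermTestResult(
        statistic=float(f_obs),
        r_squared=float(r2),
        p_value=(1 + hits) / (1 + n_permutations),
        n_permutations=n_permutations,
        seed=seed,
        df_between=int(n_groups - 1),
        df_within=int(len(codes) - n_groups),
    )


def pairwise_permanova(
    d: pd.DataFrame, groups, n_permutations: int = 999, seed: int = 0
) -> pd.DataFrame:
    """PERMANOVA on every pair of groups, Benjamini-Hochberg adjusted."""
    g = pd.Series(groups)
    if len(g) != len(d):
        g = g.loc[d.index]
    g.index = d.index
    levels = sorted(map(str, g.astype(str).unique()))
    rows = []
    for i, (a, b) in enumerate(combinations(levels, 2)):
        mask = g.astype(str).isin([a, b]).to_numpy()
        sub = d.loc[mask, mask]
        res = permanova(
            sub, g[mask], n_permutations=n_permutations, seed=seed + i
        )
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "pseudo_f": res.statistic,
                "r_squared": res.r_squared,
                "p_value": res.p_value,
            }
        )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = benjamini_hochberg(out["p_value"].to_numpy())
    return out


def _betadisper_distances(arr: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Per-sample distance to its group centroid in principal-coordinate
    space, with the usual correction for negative eigenvalue axes
    (squared contributions from imaginary axes are subtracted)."""
    n = arr.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (arr**2) @ j
    vals, vecs = np.linalg.eigh(g)
    keep = np.abs(vals) > 1e-8 * np.abs(vals).max()
    vals, vecs = vals[keep], vecs[:, keep]
    pos = vals > 0
    x_pos = vecs[:, pos] * np.sqrt(vals[pos])
    x_neg = vecs[:, ~pos] * np.sqrt(-vals[~pos])
    dist2 = np.zeros(n)
    for code in range(codes.max() + 1):
        idx = codes == code
        c_pos = x_pos[idx].mean(axis=0)
        dist2[idx] += ((x_pos[idx] - c_pos) ** 2).sum(axis=1)
        if x_neg.shape[1]:
            c_neg = x_neg[idx].mean(axis=0)
            dist2[idx] -= ((x_neg[idx] - c_neg) ** 2).sum(axis=1)
    return np.sqrt(np.clip(dist2, 0.0, None))


def _anova_f(values: np.ndarray, codes: np.ndarray) -> float:
    grand = values.mean()
    ss_b = ss_w = 0.0
    for code in range(codes.max() + 1):
        v = values[codes == code]
        ss_b += len(v) * (v.mean() - grand) ** 2
        ss_w += ((v - v.mean()) ** 2).sum()
    df_b = codes.max()
    df_w = len(values) - codes.max() - 1
    if ss_w == 0:
        return np.inf if ss_b > 0 else 0.0
    return (ss_b / df_b) / (ss_w / df_w)


def dispersion_test(
    d: pd.DataFrame, groups, n_permutations: int = 999, seed: int = 0
) -> PermTestResult:
    """Homogeneity of multivariate dispersions.

    Embeds the dissimilarities by principal coordinates, measures each
    sample's distance to its group centroid, and applies a one-way F test
    to those distances, with a permutation p-value (classical F p-value
    also reported in ``extras``).
    """
    arr, codes = _group_arrays(d, groups)
    if codes.max() + 1 < 2:
        raise SterolomeError("dispersion test needs >= 2 groups")
    if (np.bincount(codes) < 2).any():
        raise SterolomeError("every group needs >= 2 members")
    dists = _betadisper_distances(arr, codes)
    f_obs = _anova_f(dists, codes)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        if _anova_f(dists, rng.permutation(codes)) >= f_obs:
            hits += 1
    df_b = int(codes.max())
    df_w = int(len(codes) - codes.max() - 1)
    classical_p = float(stats.f.sf(f_obs, df_b, df_w)) if np.isfinite(f_obs) else 0.0
    grand_ss = ((dists - dists.mean()) ** 2).sum()
    ss_b = sum(
        (codes == c).sum() * (dists[codes == c].mean() - dists.mean()) ** 2
        for c in range(codes.max() + 1)
    )
    return PermTestResult(
        statistic=float(f_obs),
        r_squared=float(ss_b / grand_ss) if grand_ss > 0 else 0.0,
        p_value=(1 + hits) / (1 + n_permutations),
        n_permutations=n_permutations,
        seed=seed,
        df_between=df_b,
        df_within=df_w,
        extras={"classical_p": classical_p, "distances": dists},
    )


# ---------------------------------------------------------------------------
# Indicator value analysis
# ---------------------------------------------------------------------------

def _indval_components(
    x: np.ndarray, codes: np.ndarray, n_groups: int
) -> tuple[np.ndarray, np.ndarray]:
    """A (specificity) and B (fidelity) matrices, shape (n_vars, n_groups)."""
    n_vars = x.shape[1]
    means = np.zeros((n_vars, n_groups))
    fidelity = np.zeros((n_vars, n_groups))
    for g in range(n_groups):
        idx = codes == g
        means[:, g] = x[idx].mean(axis=0)
        fidelity[:, g] = (x[idx] > 0).mean(axis=0)
    total = means.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(total > 0, means / total, 0.0)
    return a, fidelity


def indval(
    x: pd.DataFrame, groups, n_permutations: int = 999, seed: int = 0
) -> pd.DataFrame:
    """Indicator value analysis for single groups.

    For each variable (sterol) and group: A = group mean abundance over
    the sum of group means (specificity), B = occurrence fraction within
    the group (fidelity), stat = sqrt(A * B). The permutation p-value
    (group labels shuffled) is attached to each variable's best group,
    comparing the observed maximum-group statistic with its permutation
    distribution.
    """
    g = pd.Series(groups)
    if len(g) != len(x):
        g = g.loc[x.index]
    codes, levels = pd.factorize(g.to_numpy())
    n_groups = len(levels)
    if n_groups < 2:
        raise SterolomeError("IndVal needs >= 2 groups")
    arr = x.to_numpy(dtype=float)
    present = arr.sum(axis=0) > 0
    skipped = [c for c, keep in zip(x.columns, present) if not keep]
    if skipped:
        logger.warning("IndVal: variables absent everywhere skipped: %s", skipped)
    cols = [c for c, keep in zip(x.columns, present) if keep]
    arr = arr[:, present]

    a, b = _indval_components(arr, codes, n_groups)
    stat = np.sqrt(a * b)
    best_group = stat.argmax(axis=1)
    obs_max = stat.max(axis=1)

    rng = np.random.default_rng(seed)
    hits = np.zeros(len(cols))
    for _ in range(n_permutations):
        pa, pb = _indval_components(arr, rng.permutation(codes), n_groups)
        hits += np.sqrt(pa * pb).max(axis=1) >= obs_max - 1e-12
    p_best = (1 + hits) / (1 + n_permutations)

    rows = []
    for j, col in enumerate(cols):
        for gi, level in enumerate(levels):
            rows.append(
                {
                    "sterol": col,
                    "group": level,
                    "A": float(a[j, gi]),
                    "B": float(b[j, gi]),
                    "stat": float(stat[j, gi]),
                    "best": gi == best_group[j],
                    "p_value": float(p_best[j]) if gi == best_group[j] else np.nan,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn
# ---------------------------------------------------------------------------

def kruskal_dunn(values, groups) -> dict:
    """Kruskal-Wallis rank-sum test with tie correction and Dunn post hoc
    z-tests (Benjamini-Hochberg adjusted across pairs)."""
    v = np.asarray(values, dtype=float)
    g = pd.Series(list(groups))
    codes, levels = pd.factorize(g.to_numpy())
    n_groups = len(levels)
    if n_groups < 2:
        raise SterolomeError("Kruskal-Wallis needs >= 2 groups")
    counts = np.bincount(codes)
    if (counts < 2).any():
        raise SterolomeError("every group needs >= 2 observations")
    n = len(v)
    if np.all(v == v[0]):
        pairs = pd.DataFrame(
            [
                {"group_a": str(levels[i]), "group_b": str(levels[j]),
                 "z": 0.0, "p_value": 1.0, "p_adjusted": 1.0}
                for i, j in combinations(range(n_groups), 2)
            ]
        )
        return {"H": 0.0, "df": n_groups - 1, "p_value": 1.0, "dunn": pairs}

    ranks = stats.rankdata(v)
    mean_ranks = np.array([ranks[codes == c].mean() for c in range(n_groups)])
    h = 12.0 / (n * (n + 1)) * np.sum(counts * mean_ranks**2) - 3 * (n + 1)
    _, tie_counts = np.unique(v, return_counts=True)
    tie_sum = float(np.sum(tie_counts**3 - tie_counts))
    correction = 1.0 - tie_sum / (n**3 - n)
    h /= correction
    p = float(stats.chi2.sf(h, n_groups - 1))

    var_base = n * (n + 1) / 12.0 - tie_sum / (12.0 * (n - 1))
    rows = []
    for i, j in combinations(range(n_groups), 2):
        se = np.sqrt(var_base * (1.0 / counts[i] + 1.0 / counts[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        rows.append(
            {
                "group_a": str(levels[i]),
                "group_b": str(levels[j]),
                "z": float(z),
                "p_value": float(2 * stats.norm.sf(abs(z))),
            }
        )
    pairs = pd.DataFrame(rows)
    pairs["p_adjusted"] = benjamini_hochberg(pairs["p_value"].to_numpy())
    return {"H": float(h), "df": n_groups - 1, "p_value": p, "dunn": pairs}
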