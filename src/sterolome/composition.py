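"""Taxon-level compositional summaries of sterol profiles.

Profiles are pandas DataFrames (rows = samples or taxa, columns = sterols)
holding proportions on the 0-1 scale. Outlier screening runs on raw
proportions; ordination-bound dissimilarities use arcsine-square-root
transformed proportions — both paths are exposed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .exceptions import DegenerateInputError, SterolomeError


def taxon_means(
    profiles: pd.DataFrame,
    taxa: pd.Series,
    totals: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.Series | None]:
    """Average per-sample proportions within taxa.

    Returns the taxon x sterol mean-proportion matrix (rows renormalised
    to sum to 1, guarding against per-sample rounding drift) and, when
    per-sample totals are given, the per-taxon mean total in mg/kg.
    """
    taxa = taxa.loc[profiles.index]
    means = profiles.groupby(taxa).mean()
    sums = means.sum(axis=1)
    if (sums <= 0).any():
        raise DegenerateInputError("taxon with all-zero mean profile")
    means = means.div(sums, axis=0)
    mean_totals = None
    if totals is not None:
        mean_totals = totals.loc[profiles.index].groupby(taxa).mean()
        mean_totals = mean_totals.loc[means.index]
    return means, mean_totals


def arcsine_sqrt(p):
    """Arcsine square-root transform of proportions, asin(sqrt(p)).

    Monotone on [0, 1]; maps 0 -> 0 and 1 -> pi/2. Accepts scalars,
    arrays, Series or DataFrames.
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise SterolomeError("arcsine_sqrt requires proportions in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    if isinstance(p, pd.DataFrame):
        return pd.DataFrame(out, index=p.index, columns=p.columns)
    if isinstance(p, pd.Series):
        return pd.Series(out, index=p.index)
    if np.isscalar(p):
        return float(out)
    return out


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y) between two
    non-negative abundance vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise SterolomeError("vectors must have equal length")
    if np.any(x < 0) or np.any(y < 0):
        raise SterolomeError("Bray-Curtis requires non-negative entries")
    denom = float(np.sum(x + y))
    if denom == 0:
        raise DegenerateInputError("Bray-Curtis undefined for two all-zero vectors")
    return float(np.sum(np.abs(x - y)) / denom)


def dissimilarity_matrix(
    profiles: pd.DataFrame, transform: bool = False
) -> pd.DataFrame:
    """Square symmetric Bray-Curtis matrix over rows of ``profiles``.

    With ``transform=True`` proportions are arcsine-square-root
    transformed first (the ordination-bound path).
    """
    data = arcsine_sqrt(profiles) if transform else profiles
    arr = data.to_numpy(dtype=float)
    if np.any(arr.sum(axis=1) == 0):
        raise DegenerateInputError("all-zero row in profile matrix")
    condensed = pdist(arr, metric="braycurtis")
    return pd.DataFrame(
        squareform(condensed), index=profiles.index, columns=profiles.index
    )


def detect_outliers(
    profiles: pd.DataFrame, threshold: float = 0.5
) -> list[str]:
    """Flag samples whose minimum Bray-Curtis dissimilarity (raw
    proportions) to every other sample exceeds ``threshold``."""
    if len(profiles) < 2:
        raise SterolomeError("outlier detection needs >= 2 samples")
    d = dissimilarity_matrix(profiles, transform=False).to_numpy()
    np.fill_diagonal(d, np.inf)
    min_d = d.min(axis=1)
    return [str(s) for s, m in zip(profiles.index, min_d) if m > threshold]


def simpson_index(p) -> float:
    """Simpson's diversity index 1 - sum(p_i^2) of a proportion vector."""
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0):
        raise SterolomeError("proportions must be non-negative")
    total = arr.sum()
    if total <= 0:
        raise DegenerateInputError("empty profile")
    arr = arr / total
    return float(1.0 - np.sum(arr**2))


def group_by_class(
    profile: pd.Series, classes: dict[str, str]
) -> pd.Series:
    """Sum sterol proportions within structural classes.

    ``classes`` maps every sterol name to its class label (e.g. B-ring
    class CPR/D0/D5/D7/D8/NA, or a carbon count). Level-2 sterols and
    ergosterol belong to NA for B-ring grouping. Class sums conserve the
    profile total.
    """
    unmapped = [s for s in profile.index if s not in classes]
    if unmapped:
        raise SterolomeError(f"sterols without a class mapping: {unmapped}")
    grouped = profile.groupby(profile.index.map(classes)).sum()
    return grouped


def dominance(
    profile: pd.Series, k: int = 3, dominant_threshold: float = 0.65
) -> dict:
    """Top-k sterols, sterol richness, and the single-sterol dominance flag.

    Ranking is by descending proportion with alphabetical tie-break;
    richness counts sterols with proportion > 0; a profile is flagged
    dominated when its top sterol reaches ``dominant_threshold``.
    """
    if profile.empty:
        raise SterolomeError("dominance of an empty profile")
    order = sorted(profile.items(), key=lambda kv: (-kv[1], kv[0]))
    top = [(name, float(p)) for name, p in order[:k]]
    return {
        "top": top,
        "richness": int((profile > 0).sum()),
        "dominant": top[0][1] >= dominant_threshold if top else False,
        "dominant_sterol": top[0][0] if top and top[0][1] >= dominant_threshold else None,
    }
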