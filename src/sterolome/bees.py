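"""Honeybee sterol-sufficiency scoring.

Honeybee tissues carry six sterols — 24-methylenecholesterol,
beta-sitosterol, isofucosterol, campesterol, cholesterol and desmosterol —
and a pollen is scored against minimum-proportion thresholds for each
(defaults: > 30%, > 19%, > 10%, > 5%, > 0.5% and > 0.5% respectively,
strict inequalities, stored as fractions). Scoring always uses the
sterol's proportion of the *whole* pollen profile: the six-sterol subset
is extracted without renormalisation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import SterolomeError

#: canonical order of the six bee-relevant sterols
BEE_STEROLS = (
    "24-methylenecholesterol",
    "beta-sitosterol",
    "isofucosterol",
    "campesterol",
    "cholesterol",
    "desmosterol",
)

DEFAULT_THRESHOLDS = {
    "24-methylenecholesterol": 0.30,
    "beta-sitosterol": 0.19,
    "isofucosterol": 0.10,
    "campesterol": 0.05,
    "cholesterol": 0.005,
    "desmosterol": 0.005,
}

#: Representative mean honeybee six-sterol composition (synthetic default).
#: The published prepupal measurements behind the thresholds are not
#: reprinted here; this stand-in places every component strictly above its
#: threshold, consistent with thresholds having been set below the bee
#: means, and is fully configurable.
DEFAULT_BEE_MEAN = pd.Series(
    {
        "24-methylenecholesterol": 0.50,
        "beta-sitosterol": 0.25,
        "isofucosterol": 0.13,
        "campesterol": 0.07,
        "cholesterol": 0.03,
        "desmosterol": 0.02,
    }
)


class BeeRequirement:
    """Named sterol -> minimum proportion threshold, plus the reference
    bee composition the thresholds derive from."""

    def __init__(
        self,
        thresholds: dict[str, float] | None = None,
        bee_mean: pd.Series | None = None,
    ):
        self.thresholds = dict(thresholds or DEFAULT_THRESHOLDS)
        if set(self.thresholds) != set(BEE_STEROLS):
            raise SterolomeError(
                f"thresholds must cover exactly the six bee sterols {BEE_STEROLS}"
            )
        if any(v <= 0 for v in self.thresholds.values()):
            raise SterolomeError("thresholds must be > 0")
        self.bee_mean = (
            bee_mean.copy() if bee_mean is not None else DEFAULT_BEE_MEAN.copy()
        )
        self.bee_mean = self.bee_mean.reindex(BEE_STEROLS)
        if self.bee_mean.isna().any():
            raise SterolomeError("bee_mean must cover the six bee sterols")


def subset_bee_sterols(profile: pd.Series) -> pd.Series:
    """Extract the six bee-relevant sterols' whole-profile proportions.

    Missing sterols contribute 0; the vector is *not* renormalised, so
    its sum is at most 1.
    """
    return pd.Series(
        {s: float(profile.get(s, 0.0)) for s in BEE_STEROLS}, name=profile.name
    )


def score_requirements(
    profile: pd.Series, requirement: BeeRequirement | None = None
) -> dict:
    """Score one pollen profile against the bee thresholds.

    A requirement is met when the whole-profile proportion is strictly
    greater than the threshold. ``contains_all_six`` asks only for
    presence at any level.
    """
    requirement = requirement or BeeRequirement()
    sub = subset_bee_sterols(profile)
    met = {s: bool(sub[s] > requirement.thresholds[s]) for s in BEE_STEROLS}
    return {
        "met": met,
        "count_met": sum(met.values()),
        "contains_all_six": bool((sub > 0).all()),
    }


def cohort_summary(reports: dict[str, dict]) -> dict:
    """Histogram of requirements-met counts plus per-sterol pass tallies
    over a cohort of per-taxon score reports."""
    if not reports:
        raise SterolomeError("cohort_summary needs >= 1 report")
    histogram = {k: 0 for k in range(7)}
    per_sterol = {s: 0 for s in BEE_STEROLS}
    n_all_six = 0
    for rep in reports.values():
        histogram[rep["count_met"]] += 1
        for s in BEE_STEROLS:
            per_sterol[s] += int(rep["met"][s])
        n_all_six += int(rep["contains_all_six"])
    return {
        "n_taxa": len(reports),
        "histogram": histogram,
        "per_sterol_pass": per_sterol,
        "n_contains_all_six": n_all_six,
    }


def score_cohort(
    profiles: pd.DataFrame, requirement: BeeRequirement | None = None
) -> tuple[pd.DataFrame, dict]:
    """Score every row of a taxon x sterol proportion table.

    Returns the per-taxon report table and the cohort summary.
    """
    requirement = requirement or BeeRequirement()
    reports = {
        str(taxon): score_requirements(profiles.loc[taxon], requirement)
        for taxon in profiles.index
    }
    rows = []
    for taxon, rep in reports.items():
        row = {"taxon": taxon}
        row.update({f"met_{s}": rep["met"][s] for s in BEE_STEROLS})
        row["count_met"] = rep["count_met"]
        row["contains_all_six"] = rep["contains_all_six"]
        rows.append(row)
    return pd.DataFrame(rows).set_index("taxon"), cohort_summary(reports)


def bee_pollen_dataset(
    pollen_profiles: pd.DataFrame, bee_samples: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Combined six-sterol matrix for the bee-vs-pollen comparison.

    Pollen rows are the unrenormalised six-sterol subsets of the whole
    profiles; bee rows are used as given (they must live on the
    six-sterol simplex). Returns (matrix, labels) with labels in
    {"pollen", "bee"} ready for ordination / PERMANOVA.
    """
    bees = bee_samples.reindex(columns=list(BEE_STEROLS))
    if bees.isna().any().any():
        raise SterolomeError("bee samples must cover the six bee sterols")
    if not np.allclose(bees.sum(axis=1), 1.0, atol=1e-6):
        raise SterolomeError("bee samples must lie on the six-sterol simplex")
    pollen = pd.DataFrame(
        [subset_bee_sterols(pollen_profiles.loc[t]) for t in pollen_profiles.index],
        index=pollen_profiles.index,
    ).reindex(columns=list(BEE_STEROLS))
    combined = pd.concat([pollen, bees], axis=0)
    labels = pd.Series(
        ["pollen"] * len(pollen) + ["bee"] * len(bees),
        index=combined.index,
        name="origin",
    )
    return combined, labels
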