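"""Synthetic study generator.

Emulates the structure of a pollen-sterolome campaign so the whole
pipeline is testable without the deposited raw data: an ultrametric
birth-death phylogeny, species-level sterol compositions with tunable
phylogenetic signal (latent traits evolve under lambda-scaled Brownian
motion and are pushed through a softmax onto the simplex), per-sample MS
signal areas proportional to amount with multiplicative lognormal noise,
a fixed-molar internal-standard spike in every non-blank sample, a QC
dilution series at relative loads 1.0 / 0.5 / 0.25, and method blanks
carrying only background features.

The generated areas invert exactly through the quantification formula at
zero noise: area = per-sterol mg/kg * (weight_mg / 1000) / (MW * n_IS *
1e6) * IS_area, so quantify_total recovers the simulated truth.
"""

from __future__ import annotations

import logging
import random as _random
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .config import RunConfig
from .exceptions import SterolomeError
from .msquant import ReferenceSterol, formula_mass
from .phylosignal import phylo_vcv, _lambda_cov

logger = logging.getLogger(__name__)

# Background (non-sterol) contaminant features present in blanks and,
# at comparable level, in every sample: the first sits on the sterol
# composition grid (so only the blank filter can remove it), the second
# falls off-grid.
_BACKGROUND = (
    {"mz": 427.42983, "rt": 10.5, "area": 8.0e5},  # ~ST(31:0) contaminant
    {"mz": 380.2000, "rt": 9.7, "area": 7.0e5},    # off-grid background
)

_COUNTIES = ("Oxfordshire", "Greater London", "County Durham",
             "North Yorkshire", "Sussex")


def default_reference() -> list[ReferenceSterol]:
    """A compact authenticated-reference panel (plus the IS) spanning the
    B-ring classes; retention times are plausible for a C18 sterol
    gradient and are synthetic."""
    rows = [
        # name, formula, rt, carbons, double_bonds, bring_class
        ("ergosterol", "C28H44O", 4.5, 28, 3, "NA"),
        ("desmosterol", "C27H44O", 4.9, 27, 2, "D5"),
        ("d7-cholesterol", "C27H39D7O", 5.6, 27, 1, "D5"),
        ("cholesterol", "C27H46O", 5.6, 27, 1, "D5"),
        ("24-methylenecholesterol", "C28H46O", 5.9, 28, 2, "D5"),
        ("stigmasterol", "C29H48O", 6.4, 29, 2, "D5"),
        ("campesterol", "C28H48O", 6.6, 28, 1, "D5"),
        ("isofucosterol", "C29H48O", 6.9, 29, 2, "D5"),
        ("schottenol", "C29H50O", 7.2, 29, 1, "D7"),
        ("beta-sitosterol", "C29H50O", 7.6, 29, 1, "D5"),
        ("sitostanol", "C29H52O", 7.9, 29, 0, "D0"),
        ("cycloartenol", "C30H50O", 8.3, 30, 2, "CPR"),
    ]
    return [
        ReferenceSterol(
            name=name,
            formula=formula,
            monoisotopic_mass=formula_mass(formula),
            expected_rt=rt,
            carbons=c,
            double_bonds=d,
            bring_class=bc,
        )
        for name, formula, rt, c, d, bc in rows
    ]


DEFAULT_STEROLS = (
    "cholesterol",
    "desmosterol",
    "campesterol",
    "24-methylenecholesterol",
    "beta-sitosterol",
    "isofucosterol",
    "stigmasterol",
    "cycloartenol",
)


@dataclass
class SimulationTruth:
    """Ground truth behind one synthetic cohort."""

    tree: dendropy.Tree
    lambda_true: float
    sigma2: float
    baseline_profiles: pd.DataFrame  # taxa x sterols, rows sum to 1
    totals_true: pd.Series  # taxon -> total sterol mg/kg
    noise_cv: float
    seed: int

    def __post_init__(self) -> None:
        sums = self.baseline_profiles.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise SterolomeError("baseline profiles must sum to 1")
        if (self.totals_true <= 0).any():
            raise SterolomeError("totals_true must be positive")
        if not 0 <= self.lambda_true <= 1:
            raise SterolomeError("lambda_true must lie in [0, 1]")


def gen_tree(
    n_tips: int,
    birth_rate: float = 1.0,
    death_rate: float = 0.0,
    seed: int = 0,
) -> dendropy.Tree:
    """Ultrametric birth-death tree with tips relabelled t1..tn.

    Conditioning on tip count uses the general sampling approach (grow
    past ``n_tips`` and sample a time slice during which exactly
    ``n_tips`` lineages existed), which avoids the zero-length terminal
    cherry that cutting exactly at the n-th speciation would create.
    """
    if n_tips < 3:
        raise SterolomeError(f"n_tips must be >= 3, got {n_tips}")
    if not birth_rate > death_rate >= 0:
        raise SterolomeError("need birth_rate > death_rate >= 0")
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=death_rate,
        num_extant_tips=n_tips,
        gsa_ntax=n_tips + max(2, n_tips // 5),
        rng=_random.Random(seed),
    )
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"t{i}"
    tree.seed_node.edge.length = None
    tree.is_rooted = True
    return tree


def simulate_traits(
    tree: dendropy.Tree,
    lambda_true: float,
    sigma2: float,
    n_traits: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Zero-mean multivariate-normal tip traits with covariance
    sigma2 * C(lambda): off-diagonal shared branch lengths scaled by
    ``lambda_true``, diagonal unchanged. Returns taxa x traits."""
    if not 0 <= lambda_true <= 1:
        raise SterolomeError(f"lambda_true must lie in [0, 1], got {lambda_true}")
    if sigma2 < 0:
        raise SterolomeError("sigma2 must be >= 0")
    labels, c = phylo_vcv(tree)
    n = len(labels)
    if sigma2 == 0:
        return pd.DataFrame(
            np.zeros((n, n_traits)), index=labels,
            columns=[f"trait{j + 1}" for j in range(n_traits)],
        )
    cov = sigma2 * _lambda_cov(c, lambda_true)
    jitter = 1e-12 * np.trace(cov) / n
    chol = np.linalg.cholesky(cov + jitter * np.eye(n))
    rng = np.random.default_rng(seed)
    z = chol @ rng.standard_normal((n, n_traits))
    return pd.DataFrame(
        z, index=labels, columns=[f"trait{j + 1}" for j in range(n_traits)]
    )


def traits_to_profiles(
    latent: pd.DataFrame, sterols: list[str] | None = None
) -> pd.DataFrame:
    """Map unconstrained latent traits onto the composition simplex via a
    per-taxon softmax; column j becomes sterol j's proportion."""
    arr = latent.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise SterolomeError("latent traits must be finite")
    arr = arr - arr.max(axis=1, keepdims=True)
    ex = np.exp(arr)
    props = ex / ex.sum(axis=1, keepdims=True)
    cols = list(sterols) if sterols is not None else list(latent.columns)
    if len(cols) != latent.shape[1]:
        raise SterolomeError("sterol name count must match trait count")
    return pd.DataFrame(props, index=latent.index, columns=cols)


def make_truth(
    n_tips: int = 20,
    sterols: tuple[str, ...] = DEFAULT_STEROLS,
    lambda_true: float = 1.0,
    sigma2: float = 1.0,
    mean_total: float = 5000.0,
    total_sd_log10: float = 0.4,
    noise_cv: float = 0.15,
    seed: int = 0,
) -> SimulationTruth:
    """Convenience constructor: tree + latent traits + simplex profiles +
    per-taxon totals (lognormal around ``mean_total`` mg/kg, spanning the
    roughly two orders of magnitude seen across real pollens)."""
    tree = gen_tree(n_tips, seed=seed)
    latent = simulate_traits(
        tree, lambda_true, sigma2, n_traits=len(sterols), seed=seed + 1
    )
    profiles = traits_to_profiles(latent, list(sterols))
    rng = np.random.default_rng(seed + 2)
    totals = pd.Series(
        10 ** (np.log10(mean_total) + total_sd_log10 * rng.standard_normal(n_tips)),
        index=profiles.index,
        name="total_mg_kg",
    )
    return SimulationTruth(
        tree=tree,
        lambda_true=lambda_true,
        sigma2=sigma2,
        baseline_profiles=profiles,
        totals_true=totals,
        noise_cv=noise_cv,
        seed=seed,
    )


def _lognormal_noise(rng: np.random.Generator, cv: float, size=None):
    """Mean-one multiplicative lognormal noise with coefficient of
    variation ``cv``; identically 1 when cv == 0."""
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.standard_normal(size) * sigma - sigma**2 / 2)


def gen_sample_tables(
    truth: SimulationTruth,
    reference: list[ReferenceSterol],
    replicates: int = 3,
    seed: int = 0,
    config: RunConfig | None = None,
    is_area: float = 1.0e7,
    qc_replicates: int = 2,
    n_blanks: int = 3,
    n_families: int = 4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Raw feature tables and sample metadata for a synthetic cohort.

    Returns (signals, metadata). Signals carry columns sample/mz/rt/area;
    metadata carries sample, taxon, family, genus, county, weight_mg,
    sample_type (pollen / qc / blank) and qc_load.
    """
    config = config or RunConfig()
    refs = {r.name: r for r in reference}
    missing = [s for s in truth.baseline_profiles.columns if s not in refs]
    if missing:
        raise SterolomeError(f"sterols missing from the reference table: {missing}")
    if config.is_name not in refs:
        raise SterolomeError(f"internal standard {config.is_name!r} not in reference")
    is_ref = refs[config.is_name]

    rng = np.random.default_rng(seed)
    taxa = list(truth.baseline_profiles.index)
    fam_of = {
        t: f"Family{(i * n_families) // len(taxa) + 1}" for i, t in enumerate(taxa)
    }
    genus_of = {t: f"Genus{i // 2 + 1}" for i, t in enumerate(taxa)}

    sig_rows: list[dict] = []
    meta_rows: list[dict] = []

    def emit(sample_id: str, mz: float, rt: float, area: float) -> None:
        sig_rows.append({"sample": sample_id, "mz": mz, "rt": rt, "area": area})

    def emit_background(sample_id: str, noisy: bool) -> None:
        for bg in _BACKGROUND:
            factor = _lognormal_noise(rng, truth.noise_cv) if noisy else 1.0
            emit(sample_id, bg["mz"], bg["rt"], bg["area"] * factor)

    # --- pollen samples ---------------------------------------------------
    for taxon in taxa:
        props = truth.baseline_profiles.loc[taxon]
        total = float(truth.totals_true.loc[taxon])
        for rep in range(1, replicates + 1):
            sample_id = f"{taxon}_r{rep}"
            weight_mg = float(rng.uniform(9.5, 16.5))
            emit(sample_id, is_ref.ion_mz, is_ref.expected_rt, is_area)
            for sterol, prop in props.items():
                ref = refs[sterol]
                mg_kg = total * float(prop)
                signal = (
                    mg_kg * (weight_mg / 1000.0)
                    / (ref.monoisotopic_mass * config.is_moles * 1e6)
                )
                area = signal * is_area * float(_lognormal_noise(rng, truth.noise_cv))
                emit(sample_id, ref.ion_mz, ref.expected_rt, area)
            emit_background(sample_id, noisy=True)
            meta_rows.append(
                {
                    "sample": sample_id,
                    "taxon": taxon,
                    "family": fam_of[taxon],
                    "genus": genus_of[taxon],
                    "county": _COUNTIES[int(rng.integers(len(_COUNTIES)))],
                    "weight_mg": weight_mg,
                    "sample_type": "pollen",
                    "qc_load": np.nan,
                }
            )

    # --- QC dilution series ----------------------------------------------
    # the QC stock pools material across taxa; signal scales with load
    stock_mg_kg = (
        truth.baseline_profiles.mul(truth.totals_true, axis=0).mean(axis=0)
    )
    qc_weight = 12.0
    for load in (1.0, 0.5, 0.25):
        for rep in range(1, qc_replicates + 1):
            sample_id = f"QC{int(load * 100)}_{rep}"
            emit(sample_id, is_ref.ion_mz, is_ref.expected_rt, is_area)
            for sterol, mg_kg in stock_mg_kg.items():
                ref = refs[sterol]
                signal = (
                    load * float(mg_kg) * (qc_weight / 1000.0)
                    / (ref.monoisotopic_mass * config.is_moles * 1e6)
                )
                area = signal * is_area * float(_lognormal_noise(rng, truth.noise_cv))
                emit(sample_id, ref.ion_mz, ref.expected_rt, area)
            emit_background(sample_id, noisy=True)
            meta_rows.append(
                {
                    "sample": sample_id,
                    "taxon": "QC",
                    "family": "",
                    "genus": "",
                    "county": "",
                    "weight_mg": qc_weight,
                    "sample_type": "qc",
                    "qc_load": load,
                }
            )

    # --- blanks: background only, no internal standard --------------------
    for rep in range(1, n_blanks + 1):
        sample_id = f"blank_{rep}"
        emit_background(sample_id, noisy=False)
        meta_rows.append(
            {
                "sample": sample_id,
                "taxon": "blank",
                "family": "",
                "genus": "",
                "county": "",
                "weight_mg": np.nan,
                "sample_type": "blank",
                "qc_load": np.nan,
            }
        )

    signals = pd.DataFrame(sig_rows)
    metadata = pd.DataFrame(meta_rows)
    logger.info(
        "generated %d signals across %d samples (seed=%d)",
        len(signals), len(metadata), seed,
    )
    return signals, metadata


def gen_bee_samples(
    mean_profile: pd.Series,
    concentration: float = 200.0,
    n: int = 18,
    seed: int = 0,
) -> pd.DataFrame:
    """Dirichlet-distributed bee sterol compositions with the given mean.

    ``concentration`` is the Dirichlet precision: draws concentrate on
    ``mean_profile`` as it grows. Defaults to 18 samples, the cohort size
    of the reference prepupal honeybee dataset.
    """
    if n < 1:
        raise SterolomeError("n must be >= 1")
    mean = mean_profile.to_numpy(dtype=float)
    if np.any(mean <= 0) or not np.isclose(mean.sum(), 1.0, atol=1e-9):
        raise SterolomeError("mean_profile must be strictly positive and sum to 1")
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(mean * concentration, size=n)
    return pd.DataFrame(
        draws,
        index=[f"bee_{i + 1}" for i in range(n)],
        columns=mean_profile.index,
    )
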