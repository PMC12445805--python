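"""MS feature filtering, internal-standard quantification and sterol annotation.

The sterol assay this module supports detects sterols under APCI as the
dehydrated protonated ion [M - H2O + H]+, so a neutral sterol C_c H_h O is
observed as the cation C_c H_(h-1). Identification is two-tiered:

* level 1 — accurate mass *and* retention time match an authenticated
  reference sterol, so a trivial name is assigned;
* level 2 — accurate mass alone places the ion on the sterol composition
  grid, yielding a carbon count and a count of double-bond equivalents
  beyond the four fused rings of the steroid core, coded ``ST(C:D)``;
  co-eluting-mass isomers are disambiguated with letters A, B, C ... in
  ascending retention-time order.

Absolute amounts come from a d7-cholesterol internal standard of known
molar amount: every analyte area is divided by the IS area, and the
relative signal is converted to mg sterol per kg fresh pollen as

    mg/kg = MW[g/mol] * signal * n_IS[mol] * 1e6 / (weight[mg] / 1000)
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .exceptions import FormatError, SterolomeError

logger = logging.getLogger(__name__)

# Monoisotopic atomic masses (Da) and the electron mass.
MASS_C = 12.000_000
MASS_H = 1.007_825_031_9
MASS_D = 2.014_101_8
MASS_O = 15.994_914_6
MASS_ELECTRON = 0.000_548_58

#: closed set of B-ring double-bond classes: cyclopropane-ring sterols,
#: saturated stanols, Delta-5 / Delta-7 / Delta-8, and not-assignable.
BRING_CLASSES = ("CPR", "D0", "D5", "D7", "D8", "NA")

# Sterol composition grid searched by decompose_mass.
CARBON_RANGE = range(26, 33)
DB_RANGE = range(0, 8)
CORE_DBE = 4  # double-bond equivalents of the tetracyclic steroid core


_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental formula like ``C27H39D7O`` into element counts."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise FormatError(f"cannot parse formula {formula!r}")
        pos = m.end()
        if not m.group(1):
            continue
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(formula) or not counts:
        raise FormatError(f"cannot parse formula {formula!r}")
    unknown = set(counts) - {"C", "H", "D", "O"}
    if unknown:
        raise FormatError(f"unsupported elements {sorted(unknown)} in {formula!r}")
    return counts


def formula_mass(formula: str | dict[str, int]) -> float:
    """Neutral monoisotopic mass of a C/H/D/O formula in Da."""
    counts = parse_formula(formula) if isinstance(formula, str) else formula
    return (
        counts.get("C", 0) * MASS_C
        + counts.get("H", 0) * MASS_H
        + counts.get("D", 0) * MASS_D
        + counts.get("O", 0) * MASS_O
    )


def theoretical_mz(
    carbons: int,
    hydrogens: int,
    deuteriums: int = 0,
    oxygens: int = 0,
    radical: bool = False,
) -> float:
    """Theoretical m/z of a +1 cation with the given atomic composition.

    The composition is that of the *ion itself* (for [M - H2O + H]+ pass
    the dehydrated, protonated counts). ``radical`` is informational: a
    radical cation (e.g. the fluoranthene lock mass C16H10+.) keeps its
    hydrogen count as given, exactly like an even-electron ion, so the
    arithmetic is identical — one electron mass is subtracted either way.
    """
    if min(carbons, hydrogens, deuteriums, oxygens) < 0:
        raise ValueError("atom counts must be non-negative")
    mass = (
        carbons * MASS_C
        + hydrogens * MASS_H
        + deuteriums * MASS_D
        + oxygens * MASS_O
    )
    return mass - MASS_ELECTRON


def sterol_cation_mz(carbons: int, double_bonds: int) -> float:
    """m/z of the dehydrated sterol cation with ``double_bonds`` DBE beyond
    the tetracyclic core: C_c H_(2c+1-2*(4+d)) +."""
    h = 2 * carbons + 1 - 2 * (CORE_DBE + double_bonds)
    return theoretical_mz(carbons, h)


def implied_neutral_mass(carbons: int, double_bonds: int) -> float:
    """Monoisotopic mass of the neutral sterol C_c H_(2c+2-2*(4+d)) O implied
    by a level-2 (carbons, double_bonds) assignment."""
    h = 2 * carbons + 2 - 2 * (CORE_DBE + double_bonds)
    return formula_mass({"C": carbons, "H": h, "O": 1})


@dataclass(frozen=True)
class ReferenceSterol:
    """An authenticated reference sterol used for level-1 annotation."""

    name: str
    formula: str
    monoisotopic_mass: float
    expected_rt: float
    carbons: int
    double_bonds: int
    bring_class: str

    def __post_init__(self) -> None:
        if self.monoisotopic_mass <= 0:
            raise SterolomeError(f"{self.name}: mass must be > 0")
        if not 26 <= self.carbons <= 32:
            raise SterolomeError(f"{self.name}: carbons {self.carbons} outside [26, 32]")
        if self.double_bonds < 0:
            raise SterolomeError(f"{self.name}: double_bonds must be >= 0")
        if self.bring_class not in BRING_CLASSES:
            raise SterolomeError(
                f"{self.name}: bring_class {self.bring_class!r} not in {BRING_CLASSES}"
            )

    @property
    def ion_mz(self) -> float:
        """m/z of the [M - H2O + H]+ ion of this sterol."""
        counts = parse_formula(self.formula)
        counts = dict(counts)
        counts["H"] = counts.get("H", 0) - 1  # -H2O +H net: lose OH
        counts["O"] = counts.get("O", 0) - 1
        if counts["H"] < 0 or counts["O"] < 0:
            raise SterolomeError(f"{self.name}: formula {self.formula} cannot dehydrate")
        return formula_mass(counts) - MASS_ELECTRON


@dataclass
class SterolFeature:
    """One annotated consensus chromatographic feature."""

    mz: float
    rt: float
    level: int
    name: str
    carbons: int | None = None
    double_bonds: int | None = None
    bring_class: str = "NA"
    monoisotopic_mass: float | None = None
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.level not in (1, 2):
            raise SterolomeError(f"annotation level must be 1 or 2, got {self.level}")
        if self.level == 2 and self.bring_class != "NA":
            raise SterolomeError("level-2 features must have bring_class NA")

    @property
    def neutral_mass(self) -> float | None:
        """Monoisotopic neutral mass: the reference mass for level 1, the
        composition-implied mass for level 2."""
        if self.monoisotopic_mass is not None:
            return self.monoisotopic_mass
        if self.carbons is not None and self.double_bonds is not None:
            return implied_neutral_mass(self.carbons, self.double_bonds)
        return None


# ---------------------------------------------------------------------------
# Signal-level operations
# ---------------------------------------------------------------------------

def filter_signals(signals: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Keep signals inside the extraction windows (all bounds inclusive):
    rt in rt_window, m/z in mz_window, area >= area_threshold."""
    rt_lo, rt_hi = config.rt_window
    mz_lo, mz_hi = config.mz_window
    mask = (
        signals["rt"].between(rt_lo, rt_hi)
        & signals["mz"].between(mz_lo, mz_hi)
        & (signals["area"] >= config.area_threshold)
    )
    return signals.loc[mask].reset_index(drop=True)


def ppm_error(observed: float, theoretical: float) -> float:
    return (observed - theoretical) / theoretical * 1e6


@dataclass(frozen=True)
class MassDecomposition:
    carbons: int
    double_bonds: int
    ppm: float
    ambiguous: bool = False


def decompose_mass(mz: float, ppm_tolerance: float = 3.0) -> MassDecomposition | None:
    """Place an observed m/z on the dehydrated-sterol composition grid.

    Searches carbons in [26, 32] and double bonds (beyond the core) in
    [0, 7] for the cation C_c H_(2c+1-2*(4+d))+ minimising the ppm error;
    returns None when nothing falls within tolerance. If a second
    composition also lies within tolerance the best one is returned with
    ``ambiguous=True``.
    """
    hits: list[MassDecomposition] = []
    for c in CARBON_RANGE:
        for d in DB_RANGE:
            if 2 * c + 1 - 2 * (CORE_DBE + d) <= 0:
                continue
            err = ppm_error(mz, sterol_cation_mz(c, d))
            if abs(err) <= ppm_tolerance:
                hits.append(MassDecomposition(c, d, err))
    if not hits:
        return None
    hits.sort(key=lambda h: abs(h.ppm))
    best = hits[0]
    if len(hits) > 1:
        logger.warning(
            "m/z %.4f matches %d sterol compositions within %.1f ppm; "
            "keeping ST(%d:%d)", mz, len(hits), ppm_tolerance,
            best.carbons, best.double_bonds,
        )
        return MassDecomposition(best.carbons, best.double_bonds, best.ppm, True)
    return best


def consensus_features(
    signals: pd.DataFrame, config: RunConfig
) -> pd.DataFrame:
    """Group per-sample signals into cross-sample consensus features.

    Signals agree when their m/z lie within ``ppm_tolerance`` and their
    retention times within ``rt_tolerance`` of the feature's running
    medians; greedy agglomeration over mz-sorted signals. Returns one row
    per feature with median mz, median rt and n_samples.
    """
    if signals.empty:
        return pd.DataFrame(columns=["feature_id", "mz", "rt", "n_samples"])
    df = signals.sort_values(["mz", "rt"]).reset_index(drop=True)
    groups: list[dict] = []
    for row in df.itertuples():
        placed = False
        for g in groups:
            med_mz = g["mz_sum"] / g["n"]
            med_rt = g["rt_sum"] / g["n"]
            if (
                abs(ppm_error(row.mz, med_mz)) <= config.ppm_tolerance
                and abs(row.rt - med_rt) <= config.rt_tolerance
            ):
                g["mz"].append(row.mz)
                g["rt"].append(row.rt)
                g["mz_sum"] += row.mz
                g["rt_sum"] += row.rt
                g["n"] += 1
                g["samples"].add(row.sample)
                placed = True
                break
        if not placed:
            groups.append(
                {
                    "mz": [row.mz],
                    "rt": [row.rt],
                    "mz_sum": row.mz,
                    "rt_sum": row.rt,
                    "n": 1,
                    "samples": {row.sample},
                }
            )
    out = pd.DataFrame(
        {
            "mz": [float(np.median(g["mz"])) for g in groups],
            "rt": [float(np.median(g["rt"])) for g in groups],
            "n_samples": [len(g["samples"]) for g in groups],
        }
    ).sort_values(["mz", "rt"]).reset_index(drop=True)
    out.insert(0, "feature_id", [f"F{i:04d}" for i in range(len(out))])
    return out


def annotate(
    features: pd.DataFrame,
    reference: list[ReferenceSterol],
    config: RunConfig,
) -> list[SterolFeature]:
    """Two-level annotation of consensus features.

    Level 1 when both the accurate mass (within ppm_tolerance of a
    reference's [M-H2O+H]+ m/z) and the retention time (within
    rt_tolerance) match an authenticated reference; a feature matching
    several references resolves to the nearest retention time with a
    logged warning. Everything else is decomposed by accurate mass to a
    level-2 ST(C:D) code; features sharing (C, D) receive suffix letters
    in ascending retention-time order.
    """
    annotated: list[SterolFeature] = []
    level2: list[SterolFeature] = []
    for row in features.itertuples():
        cands = [
            ref
            for ref in reference
            if abs(ppm_error(row.mz, ref.ion_mz)) <= config.ppm_tolerance
            and abs(row.rt - ref.expected_rt) <= config.rt_tolerance
        ]
        if cands:
            if len(cands) > 1:
                logger.warning(
                    "feature m/z %.4f rt %.2f matches %d references; "
                    "resolving by nearest retention time",
                    row.mz, row.rt, len(cands),
                )
            ref = min(cands, key=lambda r: abs(row.rt - r.expected_rt))
            annotated.append(
                SterolFeature(
                    mz=row.mz,
                    rt=row.rt,
                    level=1,
                    name=ref.name,
                    carbons=ref.carbons,
                    double_bonds=ref.double_bonds,
                    bring_class=ref.bring_class,
                    monoisotopic_mass=ref.monoisotopic_mass,
                )
            )
            continue
        hit = decompose_mass(row.mz, config.ppm_tolerance)
        if hit is None:
            logger.info(
                "feature m/z %.4f rt %.2f outside the sterol composition grid; "
                "left unannotated", row.mz, row.rt,
            )
            continue
        level2.append(
            SterolFeature(
                mz=row.mz,
                rt=row.rt,
                level=2,
                name=f"ST({hit.carbons}:{hit.double_bonds})",
                carbons=hit.carbons,
                double_bonds=hit.double_bonds,
                bring_class="NA",
                ambiguous=hit.ambiguous,
            )
        )

    # suffix letters for level-2 isomer groups, ascending retention time;
    # singletons keep the bare ST(C:D) code.
    by_cd: dict[tuple[int, int], list[SterolFeature]] = {}
    for feat in level2:
        by_cd.setdefault((feat.carbons, feat.double_bonds), []).append(feat)
    for (c, d), group in by_cd.items():
        group.sort(key=lambda f: f.rt)
        if len(group) == 1:
            continue
        for letter_idx, feat in enumerate(group):
            feat.name = f"ST({c}:{d}){chr(ord('A') + letter_idx)}"
    annotated.extend(level2)
    annotated.sort(key=lambda f: (f.rt, f.mz))
    return annotated


# ---------------------------------------------------------------------------
# Sample-level operations
# ---------------------------------------------------------------------------

def match_signals_to_features(
    sample_signals: pd.DataFrame,
    features: pd.DataFrame,
    config: RunConfig,
) -> dict[str, float]:
    """Area per consensus feature for one sample's signals (summing areas of
    signals that land on the same feature)."""
    areas: dict[str, float] = {}
    for row in sample_signals.itertuples():
        for feat in features.itertuples():
            if (
                abs(ppm_error(row.mz, feat.mz)) <= config.ppm_tolerance
                and abs(row.rt - feat.rt) <= config.rt_tolerance
            ):
                areas[feat.feature_id] = areas.get(feat.feature_id, 0.0) + row.area
                break
    return areas


def normalize_to_is(
    areas: dict[str, float], is_feature_id: str
) -> dict[str, float] | None:
    """Divide analyte areas by the internal-standard area; the IS itself is
    excluded from the analyte set. Returns None (sample invalid) when the
    IS is missing or has zero area."""
    is_area = areas.get(is_feature_id, 0.0)
    if is_area <= 0:
        logger.warning("internal standard missing or zero; sample excluded")
        return None
    return {k: v / is_area for k, v in areas.items() if k != is_feature_id}


def internal_standard_moles(
    volume_ul: float, conc_mg_ml: float, molecular_mass: float
) -> float:
    """Molar amount of an internal-standard spike.

    ``volume_ul`` microlitres of a ``conc_mg_ml`` mg/ml solution of a
    compound with the given molecular mass (g/mol); e.g. the assay's
    20 ul of 0.1 mg/ml d7-cholesterol is 5.08 nmol.
    """
    if volume_ul <= 0 or conc_mg_ml <= 0 or molecular_mass <= 0:
        raise SterolomeError("volume, concentration and mass must be > 0")
    grams = volume_ul * 1e-3 * conc_mg_ml * 1e-3
    return grams / molecular_mass


def quantify_total(
    rel_abundance: dict[str, float],
    molecular_masses: dict[str, float],
    is_moles: float,
    weight_mg: float,
) -> tuple[float, dict[str, float]]:
    """Convert IS-relative signals to mg sterol per kg fresh pollen.

    Per sterol: mg/kg = MW * signal * is_moles * 1e6 / (weight_mg / 1000);
    the total is the sum. Analytes without a molecular mass are skipped
    from the mg/kg tally with a warning (they still count for proportions
    upstream).
    """
    if weight_mg <= 0:
        raise SterolomeError(f"weight_mg must be > 0, got {weight_mg}")
    per_sterol: dict[str, float] = {}
    for name, signal in rel_abundance.items():
        mw = molecular_masses.get(name)
        if mw is None:
            logger.warning("no molecular mass for %s; excluded from mg/kg total", name)
            continue
        per_sterol[name] = mw * signal * is_moles * 1e6 / (weight_mg / 1000.0)
    return sum(per_sterol.values()), per_sterol


def qc_filter(
    qc_table: pd.DataFrame,
    loads: dict[str, float],
    threshold: float = 0.75,
) -> list[str]:
    """Retain features whose IS-normalised signal tracks the QC dilution.

    ``qc_table`` is QC-samples x features (IS-normalised); ``loads`` maps
    QC sample id to its nominal relative load (1.0 / 0.5 / 0.25). Per
    feature the Pearson correlation between load and signal is computed
    across QC samples; features with r >= threshold are kept. Features
    absent from (or constant across) all QC samples have an undefined
    correlation and are discarded.
    """
    x = np.array([loads[s] for s in qc_table.index], dtype=float)
    if len(set(np.round(x, 12))) < 3:
        raise SterolomeError("QC filter needs >= 3 distinct dilution levels")
    kept: list[str] = []
    for col in qc_table.columns:
        y = qc_table[col].to_numpy(dtype=float)
        if np.all(y == 0):
            logger.info("QC filter: %s absent from all QC samples; discarded", col)
            continue
        if np.std(y) == 0 or np.std(x) == 0:
            logger.info("QC filter: %s constant across QC loads; discarded", col)
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        if r >= threshold:
            kept.append(col)
    return kept


def blank_filter(
    sample_table: pd.DataFrame,
    blank_table: pd.DataFrame,
    factor: float = 3.0,
) -> list[str]:
    """Drop background features: a feature is kept only when its median
    signal across real samples is >= ``factor`` times its median signal
    across blanks. Features absent from the blanks are always kept."""
    kept: list[str] = []
    for col in sample_table.columns:
        blank_med = (
            float(blank_table[col].median()) if col in blank_table.columns else 0.0
        )
        if blank_med == 0:
            kept.append(col)
            continue
        sample_med = float(sample_table[col].median())
        if sample_med >= factor * blank_med:
            kept.append(col)
        else:
            logger.info(
                "blank filter: %s median %.3g < %gx blank median %.3g; dropped",
                col, sample_med, factor, blank_med,
            )
    return kept
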