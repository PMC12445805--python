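"""End-to-end orchestration: raw feature tables to result bundle.

Stage order mirrors the assay's processing logic: window/threshold signal
filtering, cross-sample consensus features, two-level annotation,
internal-standard normalisation, QC-dilution and blank filtering,
absolute quantification, compositional summaries, ordination and
PERMANOVA, phylogenetic signal, and bee sterol-sufficiency scoring.
Every stochastic stage logs its seed; a fixed seed gives byte-identical
JSON output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bees as bees_mod
from . import composition as comp
from . import io as io_mod
from . import msquant as ms
from . import multivariate as mv
from . import phylosignal as ps
from .config import RunConfig
from .exceptions import SterolomeError

logger = logging.getLogger(__name__)


class StageError(SterolomeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class SampleProfile:
    """Per-sample quantification record."""

    sample_id: str
    taxon: str
    weight_mg: float
    is_area: float
    rel_abundance: dict[str, float]
    proportions: dict[str, float]
    total_mg_kg: float


@dataclass
class ProfilesResult:
    """Output of the quantification stages."""

    features: pd.DataFrame
    annotations: list[ms.SterolFeature]
    kept_features: list[str]
    qc_dropped: list[str]
    blank_dropped: list[str]
    sample_profiles: list[SampleProfile]
    proportions: pd.DataFrame  # samples x sterols
    rel_abundance: pd.DataFrame
    totals: pd.Series
    per_sterol_mg_kg: pd.DataFrame
    invalid_samples: list[str]
    class_map: dict[str, str] = field(default_factory=dict)
    carbon_map: dict[str, int] = field(default_factory=dict)


def build_profiles(
    signals: pd.DataFrame,
    metadata: pd.DataFrame,
    reference: list[ms.ReferenceSterol],
    config: RunConfig,
) -> ProfilesResult:
    """Run the MS stages and return per-sample sterol profiles."""
    meta = metadata.set_index("sample")
    kept_signals = ms.filter_signals(signals, config)
    logger.info(
        "signal filter kept %d / %d signals", len(kept_signals), len(signals)
    )

    features = ms.consensus_features(kept_signals, config)
    annotations = ms.annotate(features, reference, config)

    # map feature_id -> annotation by (mz, rt) identity
    ann_by_key = {(round(a.mz, 6), round(a.rt, 6)): a for a in annotations}
    feat_ann: dict[str, ms.SterolFeature] = {}
    for row in features.itertuples():
        a = ann_by_key.get((round(row.mz, 6), round(row.rt, 6)))
        if a is not None:
            feat_ann[row.feature_id] = a
    is_ids = [fid for fid, a in feat_ann.items() if a.name == config.is_name]
    if not is_ids:
        raise SterolomeError(
            f"internal standard {config.is_name!r} not found among features"
        )
    is_id = is_ids[0]

    # per-sample area vectors over consensus features
    areas_by_sample: dict[str, dict[str, float]] = {}
    for sample_id, group in kept_signals.groupby("sample"):
        areas_by_sample[str(sample_id)] = ms.match_signals_to_features(
            group, features, config
        )
    all_fids = list(features["feature_id"])
    area_table = pd.DataFrame(
        [
            {fid: areas_by_sample.get(s, {}).get(fid, 0.0) for fid in all_fids}
            for s in meta.index
        ],
        index=meta.index,
    )

    sample_types = meta.get(
        "sample_type", pd.Series("pollen", index=meta.index)
    ).fillna("pollen")
    pollen_ids = list(meta.index[sample_types == "pollen"])
    qc_ids = list(meta.index[sample_types == "qc"])
    blank_ids = list(meta.index[sample_types == "blank"])

    # IS normalisation (IS excluded from analytes; samples without IS invalid)
    rel_rows: dict[str, dict[str, float]] = {}
    invalid: list[str] = []
    for s in pollen_ids + qc_ids:
        rel = ms.normalize_to_is(dict(area_table.loc[s]), is_id)
        if rel is None:
            invalid.append(s)
            logger.warning("sample %s excluded: internal standard missing", s)
        else:
            rel_rows[s] = rel
    analyte_fids = [f for f in all_fids if f != is_id]
    rel_table = pd.DataFrame(
        [
            {fid: rel_rows[s].get(fid, 0.0) for fid in analyte_fids}
            for s in rel_rows
        ],
        index=list(rel_rows),
    )

    # QC dilution-correlation filter on IS-normalised signals
    qc_valid = [s for s in qc_ids if s in rel_table.index]
    if len(qc_valid) >= 3 and "qc_load" in meta.columns:
        loads = {s: float(meta.loc[s, "qc_load"]) for s in qc_valid}
        qc_kept = ms.qc_filter(
            rel_table.loc[qc_valid], loads, threshold=config.qc_threshold
        )
    else:
        logger.warning("no usable QC series; QC filter skipped")
        qc_kept = analyte_fids
    qc_dropped = [f for f in analyte_fids if f not in qc_kept]

    # blank filter on raw areas (blanks carry no IS)
    if blank_ids:
        blank_kept = ms.blank_filter(
            area_table.loc[pollen_ids, analyte_fids],
            area_table.loc[blank_ids, analyte_fids],
            factor=config.blank_factor,
        )
    else:
        blank_kept = analyte_fids
    blank_dropped = [f for f in analyte_fids if f not in blank_kept]

    kept = [
        f for f in analyte_fids
        if f in qc_kept and f in blank_kept and f in feat_ann
    ]
    logger.info(
        "feature filters: %d QC-dropped, %d blank-dropped, %d unannotated, %d kept",
        len(qc_dropped), len(blank_dropped),
        len([f for f in analyte_fids if f not in feat_ann]), len(kept),
    )

    names = {fid: feat_ann[fid].name for fid in kept}
    masses = {
        feat_ann[fid].name: feat_ann[fid].neutral_mass
        for fid in kept
        if feat_ann[fid].neutral_mass is not None
    }

    profiles: list[SampleProfile] = []
    for s in pollen_ids:
        if s not in rel_table.index:
            continue
        rel = {names[f]: float(rel_table.loc[s, f]) for f in kept}
        total_rel = sum(rel.values())
        props = (
            {k: v / total_rel for k, v in rel.items()} if total_rel > 0 else rel
        )
        weight = float(meta.loc[s].get("weight_mg", np.nan))
        if np.isfinite(weight) and weight > 0:
            total, per_sterol = ms.quantify_total(
                rel, masses, config.is_moles, weight
            )
        else:
            total, per_sterol = np.nan, {}
            logger.warning("sample %s has no weight; mg/kg not computed", s)
        profiles.append(
            SampleProfile(
                sample_id=s,
                taxon=str(meta.loc[s].get("taxon", s)),
                weight_mg=weight,
                is_area=float(area_table.loc[s, is_id]),
                rel_abundance=rel,
                proportions=props,
                total_mg_kg=total,
            )
        )

    sterol_names = sorted({names[f] for f in kept})
    prop_df = pd.DataFrame(
        [
            {n: p.proportions.get(n, 0.0) for n in sterol_names}
            for p in profiles
        ],
        index=[p.sample_id for p in profiles],
    )
    mgkg_rows = []
    for p in profiles:
        _, per = (
            ms.quantify_total(p.rel_abundance, masses, config.is_moles, p.weight_mg)
            if np.isfinite(p.weight_mg) and p.weight_mg > 0
            else (np.nan, {})
        )
        mgkg_rows.append({n: per.get(n, np.nan) for n in sterol_names})
    per_sterol_df = pd.DataFrame(mgkg_rows, index=[p.sample_id for p in profiles])
    totals = pd.Series(
        {p.sample_id: p.total_mg_kg for p in profiles}, name="total_mg_kg"
    )

    class_map = {}
    carbon_map = {}
    for fid in kept:
        a = feat_ann[fid]
        class_map[a.name] = a.bring_class
        if a.carbons is not None:
            carbon_map[a.name] = a.carbons
    rel_named = pd.DataFrame(
        [
            {names[f]: float(rel_table.loc[p.sample_id, f]) for f in kept}
            for p in profiles
        ],
        index=[p.sample_id for p in profiles],
    )
    return ProfilesResult(
        features=features,
        annotations=annotations,
        kept_features=kept,
        qc_dropped=qc_dropped,
        blank_dropped=blank_dropped,
        sample_profiles=profiles,
        proportions=prop_df,
        rel_abundance=rel_named,
        totals=totals,
        per_sterol_mg_kg=per_sterol_df,
        invalid_samples=invalid,
        class_map=class_map,
        carbon_map=carbon_map,
    )


def run_pipeline(
    config: RunConfig,
    signals: pd.DataFrame,
    metadata: pd.DataFrame,
    reference: list[ms.ReferenceSterol],
    tree=None,
    outdir: str | Path | None = None,
    bee_requirement: bees_mod.BeeRequirement | None = None,
    nmds_max_tries: int | None = None,
) -> dict:
    """Run all stages and (optionally) write the result bundle.

    Returns the result document; raises :class:`StageError` naming the
    failing stage on any error.
    """
    results: dict = {"config": config.to_dict(), "stages": []}
    stage = "setup"

    def enter(name: str) -> None:
        nonlocal stage
        stage = name
        logger.info("stage: %s", name)
        results["stages"].append(name)

    try:
        enter("quantify")
        prof = build_profiles(signals, metadata, reference, config)
        results["n_features_kept"] = len(prof.kept_features)
        results["qc_dropped"] = sorted(prof.qc_dropped)
        results["blank_dropped"] = sorted(prof.blank_dropped)
        results["invalid_samples"] = sorted(prof.invalid_samples)

        enter("outliers")
        if len(prof.proportions) >= 2:
            outliers = comp.detect_outliers(
                prof.proportions, threshold=config.outlier_threshold
            )
        else:
            outliers = []
        results["outliers"] = sorted(outliers)
        kept_samples = [s for s in prof.proportions.index if s not in outliers]
        props = prof.proportions.loc[kept_samples]
        totals = prof.totals.loc[kept_samples]

        enter("taxon_means")
        meta = metadata.set_index("sample")
        taxa = meta.loc[props.index, "taxon"]
        taxon_props, taxon_totals = comp.taxon_means(props, taxa, totals)
        results["n_taxa"] = int(len(taxon_props))

        enter("diversity")
        simpson = {
            str(t): comp.simpson_index(taxon_props.loc[t])
            for t in taxon_props.index
        }
        results["simpson"] = simpson
        dominance = {
            str(t): comp.dominance(taxon_props.loc[t])
            for t in taxon_props.index
        }
        results["n_dominated_65pct"] = int(
            sum(d["dominant"] for d in dominance.values())
        )

        enter("class_proportions")
        bring = pd.DataFrame(
            {
                t: comp.group_by_class(taxon_props.loc[t], prof.class_map)
                for t in taxon_props.index
            }
        ).T.fillna(0.0)
        carbons = pd.DataFrame(
            {
                t: comp.group_by_class(
                    taxon_props.loc[t],
                    {k: str(v) for k, v in prof.carbon_map.items()},
                )
                for t in taxon_props.index
            }
        ).T.fillna(0.0)

        enter("ordination")
        tries = nmds_max_tries or config.nmds_max_tries
        d_taxa = comp.dissimilarity_matrix(taxon_props, transform=True)
        ord_res = mv.nmds_auto(
            d_taxa,
            stress_cutoff=config.stress_cutoff,
            max_tries=tries,
            seed=config.random_seed,
        )
        if ord_res is not None:
            results["nmds"] = {
                "stress": ord_res.stress,
                "k": ord_res.k,
                "n_tries": ord_res.n_tries,
            }

        enter("permanova")
        fam_of_taxon = (
            meta.loc[props.index].groupby("taxon")["family"].first()
            if "family" in meta.columns
            else None
        )
        if fam_of_taxon is not None:
            fams = fam_of_taxon.loc[taxon_props.index]
            counts = fams.value_counts()
            usable = fams.isin(counts[counts >= 2].index) & (fams != "")
            if usable.sum() >= 4 and fams[usable].nunique() >= 2:
                sub = d_taxa.loc[usable.to_numpy(), usable.to_numpy()]
                pmv = mv.permanova(
                    sub, fams[usable],
                    n_permutations=config.n_permutations,
                    seed=config.random_seed,
                )
                disp = mv.dispersion_test(
                    sub, fams[usable],
                    n_permutations=config.n_permutations,
                    seed=config.random_seed + 1,
                )
                results["permanova_family"] = {
                    "pseudo_f": pmv.statistic,
                    "r_squared": pmv.r_squared,
                    "p_value": pmv.p_value,
                }
                results["dispersion_family"] = {
                    "f": disp.statistic,
                    "p_value": disp.p_value,
                }

        signal_table = None
        if tree is not None:
            enter("physignal")
            signal_table = ps.signal_screen(
                taxon_props,
                tree,
                totals=taxon_totals,
                class_tables={"bring": bring, "carbons": carbons},
                n_permutations=config.n_permutations,
                seed=config.random_seed,
            )
            results["physignal"] = signal_table.round(6).to_dict("records")

        enter("beescore")
        bee_table, bee_summary = bees_mod.score_cohort(
            taxon_props, bee_requirement
        )
        results["bee_summary"] = bee_summary

        enter("write")
        if outdir is not None:
            outdir = Path(outdir)
            outdir.mkdir(parents=True, exist_ok=True)
            prof.proportions.rename_axis("sample").to_csv(
                outdir / "sample_proportions.csv"
            )
            taxon_props.rename_axis("taxon").to_csv(outdir / "taxon_proportions.csv")
            bring.rename_axis("taxon").to_csv(outdir / "bring_class_proportions.csv")
            carbons.rename_axis("taxon").to_csv(outdir / "carbon_class_proportions.csv")
            io_mod.write_matrix(d_taxa, outdir / "taxon_dissimilarity.csv")
            bee_table.to_csv(outdir / "bee_sufficiency.csv")
            if signal_table is not None:
                signal_table.to_csv(outdir / "phylo_signal.csv", index=False)
            if ord_res is not None:
                ord_res.coordinates.rename_axis("taxon").round(10).to_csv(
                    outdir / "nmds_coordinates.csv"
                )
            io_mod.write_json(results, outdir / "results.json")
        return results
    except StageError:
        raise
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise StageError(stage, exc) from exc
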