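"""Readers and writers for the on-disk formats.

Feature tables are CSV/TSV with columns ``sample, mz, rt, area`` (one row
per detected signal). The reference sterol table is CSV with columns
``name, formula, mass, rt, carbons, double_bonds, bring_class`` (``mass``
may be left blank when ``formula`` is given). Trees are Newick with branch
lengths; results are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .exceptions import FormatError, ParseError
from .msquant import ReferenceSterol, formula_mass

FEATURE_COLUMNS = ("sample", "mz", "rt", "area")


def _read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    # round-trip parsing keeps write(read(x)) bit-exact for floats
    return pd.read_csv(path, sep=sep, float_precision="round_trip", **kwargs)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a raw MS feature table (sample, mz, rt, area)."""
    df = _read_table(path)
    for col in FEATURE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    df = df.loc[:, list(FEATURE_COLUMNS)].copy()
    for col in ("mz", "rt", "area"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ParseError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} "
                f"in column {col!r}, row {row}"
            )
        if coerced.isna().any():
            row = int(np.flatnonzero(coerced.isna())[0])
            raise ParseError(f"{path}: missing value in column {col!r}, row {row}")
        df[col] = coerced.astype(float)
    if not np.isfinite(df[["mz", "rt", "area"]].to_numpy()).all():
        raise ParseError(f"{path}: non-finite numeric value in feature table")
    if (df[["mz", "rt", "area"]].to_numpy() < 0).any():
        raise ParseError(f"{path}: negative mz/rt/area in feature table")
    df["sample"] = df["sample"].astype(str)
    return df


def write_feature_table(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df.to_csv(path, sep=sep, index=False)


def read_reference_table(path: str | Path) -> list[ReferenceSterol]:
    """Read the authenticated reference sterol table."""
    # keep_default_na: the B-ring class "NA" is a real category, not a
    # missing value
    df = _read_table(path, keep_default_na=False, na_values=[""])
    required = ("name", "formula", "rt", "carbons", "double_bonds", "bring_class")
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    refs = []
    for _, row in df.iterrows():
        mass = row.get("mass")
        if mass is None or (isinstance(mass, float) and np.isnan(mass)):
            mass = formula_mass(str(row["formula"]))
        refs.append(
            ReferenceSterol(
                name=str(row["name"]),
                formula=str(row["formula"]),
                monoisotopic_mass=float(mass),
                expected_rt=float(row["rt"]),
                carbons=int(row["carbons"]),
                double_bonds=int(row["double_bonds"]),
                bring_class=str(row["bring_class"]),
            )
        )
    return refs


def write_reference_table(refs: list[ReferenceSterol], path: str | Path) -> None:
    pd.DataFrame(
        {
            "name": [r.name for r in refs],
            "formula": [r.formula for r in refs],
            "mass": [r.monoisotopic_mass for r in refs],
            "rt": [r.expected_rt for r in refs],
            "carbons": [r.carbons for r in refs],
            "double_bonds": [r.double_bonds for r in refs],
            "bring_class": [r.bring_class for r in refs],
        }
    ).to_csv(path, index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata (sample, taxon, ... plus optional family,
    genus, county, weight_mg, sample_type)."""
    df = _read_table(path)
    for col in ("sample", "taxon"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    df["sample"] = df["sample"].astype(str)
    return df


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def read_tree(source: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree with branch lengths.

    ``source`` may be a path or a Newick string. Duplicate tip labels and
    missing branch lengths are errors.
    """
    text = str(source)
    if not text.lstrip().startswith("("):
        text = Path(source).read_text()
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        if "DuplicateTaxon" in type(exc).__name__ or "Multiple occurrences" in str(exc):
            raise FormatError(f"duplicate tip labels in tree: {exc}") from exc
        raise FormatError(f"cannot parse Newick tree: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = sorted({lab for lab in labels if labels.count(lab) > 1})
    if dupes:
        raise FormatError(f"duplicate tip labels in tree: {dupes}")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise FormatError("tree has edges without branch lengths")
        if edge.length < 0:
            raise FormatError(f"negative branch length {edge.length}")
    tree.is_rooted = True
    return tree


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )


# ---------------------------------------------------------------------------
# Matrices and JSON results
# ---------------------------------------------------------------------------

def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialise {type(obj)}")


def write_json(data: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
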