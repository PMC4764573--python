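"""Readers and writers for every tabular artifact.

Dialect: tab-separated, UTF-8, ``NA`` for missing values.  Intensity tables
are stored wide (protein-groups style, one ``iBAQ <sample>`` column per
sample) with a sample manifest assigning a role and replicate to every
intensity column; in memory they are long-form pandas data frames with one
row per (protein, sample).  MaxQuant-style metadata column names (``PEP``,
``Unique peptides``, ``Only identified by site``) are accepted as aliases.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .config import ROLES, MACHINERY_CLASSES
from .errors import ConfigError, FormatError
from .simulate import INTENSITY_COLUMNS

logger = logging.getLogger(__name__)

_NA = "NA"

_META_ALIASES = {
    "min_pep": ("min_pep", "PEP"),
    "unique_peptides": ("unique_peptides", "Unique peptides"),
    "only_by_site": ("only_by_site", "Only identified by site"),
}

_TRUE_STRINGS = {"+", "true", "True", "TRUE", "1"}


def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed TSV
        raise FormatError(f"cannot parse {path}: {exc}") from exc


def validate_intensity_table(table: pd.DataFrame) -> pd.DataFrame:
    """Enforce the long-form intensity-table invariants."""
    missing = set(INTENSITY_COLUMNS) - set(table.columns)
    if missing:
        raise FormatError(f"intensity table lacks columns {sorted(missing)}")
    dup = table.duplicated(subset=["protein_id", "sample_id"])
    if dup.any():
        first = table.loc[dup, ["protein_id", "sample_id"]].iloc[0].tolist()
        raise FormatError(f"duplicate (protein, sample) rows, e.g. {first}")
    if (table["intensity"].dropna() < 0).any():
        raise FormatError("negative intensities are not allowed")
    bad_roles = set(table["role"]) - ROLES
    if bad_roles:
        raise FormatError(f"unknown sample roles {sorted(bad_roles)}")
    per_sample = table.groupby("sample_id")[["role", "replicate"]].nunique()
    if (per_sample > 1).any().any():
        raise FormatError("a sample_id must carry exactly one role and replicate")
    return table


# -- sample manifests ---------------------------------------------------


def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, sep="\t", index=False)


def read_manifest(path) -> pd.DataFrame:
    manifest = _read_tsv(path)
    required = {"column", "sample_id", "role", "replicate"}
    if not required.issubset(manifest.columns):
        raise FormatError(f"manifest {path} needs columns {sorted(required)}")
    manifest["replicate"] = manifest["replicate"].astype(int)
    return manifest


# -- intensity tables ---------------------------------------------------


def write_intensity_table(table: pd.DataFrame, path, manifest_path=None) -> pd.DataFrame:
    """Write a long-form table as a wide protein-groups-style TSV.

    Identification metadata must be constant per protein across samples
    (as produced by the simulator).  Returns the sample manifest, which is
    also written next to the table unless ``manifest_path`` is given.
    """
    validate_intensity_table(table)
    path = Path(path)
    wide = table.pivot(index="protein_id", columns="sample_id", values="intensity")
    meta = table.groupby("protein_id")[["min_pep", "unique_peptides", "only_by_site"]].first()
    check = table.groupby("protein_id")[["min_pep", "unique_peptides", "only_by_site"]].nunique()
    if (check > 1).any().any():
        raise FormatError("per-protein metadata differs across samples; cannot write wide")

    samples = (
        table[["sample_id", "role", "replicate"]]
        .drop_duplicates()
        .sort_values("sample_id")
        .reset_index(drop=True)
    )
    manifest = pd.DataFrame(
        {
            "column": "iBAQ " + samples["sample_id"],
            "sample_id": samples["sample_id"],
            "role": samples["role"],
            "replicate": samples["replicate"],
        }
    )

    out = wide.rename(columns=lambda s: f"iBAQ {s}")
    out = out.join(meta)
    out = out.reset_index().sort_values("protein_id")
    out["only_by_site"] = np.where(out["only_by_site"], "+", "")
    out.to_csv(path, sep="\t", index=False, na_rep=_NA)
    write_manifest(manifest, manifest_path or path.with_suffix(".manifest.tsv"))
    return manifest


def read_intensity_table(path, sample_manifest: pd.DataFrame) -> pd.DataFrame:
    """Read a wide protein-groups-style TSV into the long form.

    ``sample_manifest`` assigns a ``sample_id``, ``role`` and ``replicate``
    to every intensity column.  Intensities of exactly zero are converted to
    missing, matching the convention that an absent iBAQ value is exported
    as 0.
    """
    raw = _read_tsv(path)
    if "protein_id" not in raw.columns:
        if "Protein IDs" in raw.columns:  # MaxQuant alias
            raw = raw.rename(columns={"Protein IDs": "protein_id"})
        else:
            raise FormatError(f"{path}: no 'protein_id' column")

    missing_cols = set(sample_manifest["column"]) - set(raw.columns)
    if missing_cols:
        raise FormatError(f"{path}: manifest columns absent from file: {sorted(missing_cols)}")

    meta = pd.DataFrame(index=raw.index)
    for canon, aliases in _META_ALIASES.items():
        found = [a for a in aliases if a in raw.columns]
        if not found:
            raise FormatError(f"{path}: missing metadata column {canon!r} (aliases {aliases})")
        meta[canon] = raw[found[0]]
    meta["min_pep"] = pd.to_numeric(meta["min_pep"].replace(_NA, np.nan))
    meta["unique_peptides"] = pd.to_numeric(meta["unique_peptides"].replace(_NA, "0")).astype(int)
    meta["only_by_site"] = meta["only_by_site"].isin(_TRUE_STRINGS)

    frames = []
    for row in sample_manifest.itertuples(index=False):
        intensity = pd.to_numeric(raw[row.column].replace({_NA: np.nan, "": np.nan}))
        if (intensity.dropna() < 0).any():
            raise FormatError(f"{path}: negative intensity in column {row.column!r}")
        intensity = intensity.mask(intensity == 0)  # zero means undetected
        frames.append(
            pd.DataFrame(
                {
                    "protein_id": raw["protein_id"],
                    "sample_id": row.sample_id,
                    "role": row.role,
                    "replicate": int(row.replicate),
                    "intensity": intensity,
                    "min_pep": meta["min_pep"],
                    "unique_peptides": meta["unique_peptides"],
                    "only_by_site": meta["only_by_site"],
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)[INTENSITY_COLUMNS]
    return validate_intensity_table(table)


# -- simple lists and mappings ------------------------------------------


def read_lists(path) -> set[str]:
    """One identifier per line -> deduplicated set.  Blank lines ignored."""
    ids: set[str] = set()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            token = line.strip()
            if not token:
                continue
            if "\t" in token:
                raise FormatError(f"{path}:{lineno}: expected a single identifier")
            ids.add(token)
    if not ids:
        logger.warning("list file %s is empty", path)
    logger.info("read %d identifiers from %s", len(ids), path)
    return ids


def write_list(ids, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for token in sorted(ids):
            fh.write(f"{token}\n")


def read_spike_table(path) -> pd.DataFrame:
    """``standard_id<TAB>amount_fmol`` -> spike table; amounts must be > 0."""
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
        if header.strip() != "standard_id\tamount_fmol":
            raise FormatError(f"{path}:1: expected header 'standard_id\\tamount_fmol'")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 fields")
            try:
                amount = float(parts[1])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: bad amount {parts[1]!r}") from None
            if amount <= 0:
                raise FormatError(f"{path}:{lineno}: amount must be > 0, got {amount}")
            rows.append((parts[0], amount))
    return pd.DataFrame(rows, columns=["standard_id", "amount_fmol"])


def write_spike_table(spike: pd.DataFrame, path) -> None:
    spike.to_csv(path, sep="\t", index=False)


def read_proteoform_map(path) -> pd.DataFrame:
    df = _read_tsv(path)
    if not {"proteoform_id", "protein_id"}.issubset(df.columns):
        raise FormatError(f"{path}: need columns proteoform_id, protein_id")
    if df["proteoform_id"].duplicated().any():
        raise FormatError(f"{path}: proteoform mapped more than once")
    return df[["proteoform_id", "protein_id"]]


def read_machinery(path) -> dict[str, str]:
    """``protein_id<TAB>class`` -> mapping onto transport-machinery classes."""
    mapping: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 'id<TAB>class'")
            pid, cls = parts
            if cls not in MACHINERY_CLASSES:
                raise ConfigError(
                    f"{path}:{lineno}: unknown machinery class {cls!r} "
                    f"(known: {sorted(MACHINERY_CLASSES)})"
                )
            mapping[pid] = cls
    return mapping


# -- truth tables -------------------------------------------------------


def write_truth_table(truth: pd.DataFrame, path) -> None:
    """Companion truth TSV with a ``truth_`` column prefix (protein_id kept)."""
    out = truth.rename(
        columns={c: f"truth_{c}" for c in truth.columns if c != "protein_id"}
    )
    out.to_csv(path, sep="\t", index=False, na_rep=_NA)


def read_truth_table(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", na_values=[_NA], keep_default_na=False,
        float_precision="round_trip",
    )
    return df.rename(columns=lambda c: c.removeprefix("truth_"))


# -- reports ------------------------------------------------------------

PARTITION_REPORT_COLUMNS = [
    "protein_id",
    "conc_nuc",
    "conc_cyt",
    "nc_ratio",
    "log10_nc",
    "status",
    "flagged",
    "kept_override",
]

CARGO_REPORT_COLUMNS = [
    "protein_id",
    "molar_fraction_bound",
    "molar_fraction_input",
    "input_enrichment",
    "ran_stimulation",
    "enrichment_is_bound_estimate",
    "stimulation_is_bound_estimate",
    "detected_in",
    "category",
]

_BOOL_COLUMNS = {
    "flagged",
    "kept_override",
    "enrichment_is_bound_estimate",
    "stimulation_is_bound_estimate",
}


def _write_report(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = set(columns) - set(df.columns)
    if missing:
        raise FormatError(f"report lacks columns {sorted(missing)}")
    out = df[columns].sort_values("protein_id").reset_index(drop=True)
    out.to_csv(path, sep="\t", index=False, na_rep=_NA)


def _read_report(path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", na_values=[_NA], keep_default_na=False,
        float_precision="round_trip",
    )
    if list(df.columns) != columns:
        raise FormatError(f"{path}: unexpected report schema {list(df.columns)}")
    for col in df.columns:
        if col in _BOOL_COLUMNS:
            df[col] = df[col].astype(bool)
    return df


def write_reports(partition: pd.DataFrame | None, cargo: pd.DataFrame | None,
                  outdir) -> dict[str, Path]:
    """Write ``partition_report.tsv`` and/or ``cargo_report.tsv`` with a
    deterministic column order.  N:C ratios are carried both linearly and on
    a log10 scale.  Round-trip reading returns identical values."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    if partition is not None:
        p = outdir / "partition_report.tsv"
        _write_report(partition, PARTITION_REPORT_COLUMNS, p)
        written["partition"] = p
    if cargo is not None:
        p = outdir / "cargo_report.tsv"
        _write_report(cargo, CARGO_REPORT_COLUMNS, p)
        written["cargo"] = p
    return written


def read_partition_report(path) -> pd.DataFrame:
    return _read_report(path, PARTITION_REPORT_COLUMNS)


def read_cargo_report(path) -> pd.DataFrame:
    return _read_report(path, CARGO_REPORT_COLUMNS)


def write_filter_log(log: pd.DataFrame, path) -> None:
    log.to_csv(path, sep="\t", index=False, na_rep=_NA)
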