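"""Identification filtering, proteoform merging, spike-in calibration and
absolute nucleocytoplasmic quantitation.

The calibration regresses log10(known amount) on log10(measured intensity)
over the detected spike-in standards of each biological replicate; the
fitted line is then a direct plug-in predictor of molar amount from
intensity.  Amounts divided by compartment volumes give concentrations, and
the N:C partition coefficient is the ratio of replicate-averaged nuclear to
cytosolic concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig
from .errors import CalibrationError

PARTITION_ROLES = ("nuclear", "cytosolic")


# -- filtering ----------------------------------------------------------


def filter_records(
    table: pd.DataFrame, config: RunConfig, mode: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the identification-quality filters and return the surviving
    records plus a log with one row per (protein, rule) removal.

    ``mode='partition'``: rows with min peptide PEP above ``config.max_pep``
    are dropped, and proteins carrying an 'only identified by site' flag that
    were detected in only one compartment are removed entirely (the flag is
    tolerated when the protein is seen in both compartments).

    ``mode='cargo'``: proteins site-flagged in the RanGTP-bound sample are
    excluded from further analysis; for the frog species profile, rows with
    PEP above threshold are dropped and proteins need at least
    ``config.min_unique_peptides`` unique peptides.
    """
    if mode not in ("partition", "cargo"):
        raise ValueError(f"mode must be 'partition' or 'cargo', got {mode!r}")
    log_rows: list[tuple[str, str]] = []
    table = table.copy()

    def drop_proteins(pids, rule):
        log_rows.extend((pid, rule) for pid in sorted(set(pids)))
        return table[~table["protein_id"].isin(set(pids))]

    if mode == "partition":
        bad_pep = table["min_pep"] > config.max_pep
        log_rows.extend(
            (pid, "pep") for pid in sorted(table.loc[bad_pep, "protein_id"].unique())
        )
        table = table[~bad_pep]

        flagged = table.groupby("protein_id")["only_by_site"].agg("all")
        detected = table[table["intensity"].notna()]
        n_comp = detected.groupby("protein_id")["role"].nunique()
        site_ids = [
            pid
            for pid in flagged.index[flagged]
            if n_comp.get(pid, 0) <= 1
        ]
        table = drop_proteins(site_ids, "site_single_compartment")
    else:
        in_plus = table["role"] == "bait_plus_ran"
        site_plus = table.loc[in_plus & table["only_by_site"], "protein_id"].unique()
        table = drop_proteins(site_plus, "site_in_bait_plus_ran")

        if config.species == "xenopus":
            bad_pep = table["min_pep"] > config.max_pep
            log_rows.extend(
                (pid, "pep")
                for pid in sorted(table.loc[bad_pep, "protein_id"].unique())
            )
            table = table[~bad_pep]
            peptides = table.groupby("protein_id")["unique_peptides"].max()
            few = peptides.index[peptides < config.min_unique_peptides]
            table = drop_proteins(few, "unique_peptides")

    log = pd.DataFrame(log_rows, columns=["protein_id", "rule"])
    return table.reset_index(drop=True), log


def merge_proteoforms(table: pd.DataFrame, proteoform_map: pd.DataFrame) -> pd.DataFrame:
    """Collapse proteoforms (chiefly allelic variants) onto unique proteins.

    Per (protein, sample): intensities are summed with missing treated as
    zero, except that an all-missing group stays missing; unique peptides
    add up; the PEP is the best (minimum) member PEP; the site flag survives
    only if every member carries it.  Proteoforms absent from the map are
    mapped to themselves (total mapping).
    """
    mapping = dict(
        zip(proteoform_map["proteoform_id"], proteoform_map["protein_id"])
    )
    merged = table.copy()
    merged["protein_id"] = merged["protein_id"].map(lambda p: mapping.get(p, p))
    grouped = merged.groupby(["protein_id", "sample_id"], as_index=False).agg(
        role=("role", "first"),
        replicate=("replicate", "first"),
        intensity=("intensity", lambda s: s.sum(min_count=1)),
        min_pep=("min_pep", "min"),
        unique_peptides=("unique_peptides", "sum"),
        only_by_site=("only_by_site", "all"),
    )
    return grouped[table.columns.tolist()]


# -- calibration --------------------------------------------------------


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted log10(amount) ~ log10(intensity) line for one replicate."""

    replicate_id: int
    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def predict_amount_fmol(self, intensity) -> np.ndarray:
        """Plug-in prediction of molar amount (fmol) from intensity."""
        return 10.0 ** (self.slope * np.log10(np.asarray(intensity, dtype=float))
                        + self.intercept)


def fit_calibration(
    spike: pd.DataFrame, table: pd.DataFrame, replicate: int
) -> CalibrationCurve:
    """Fit the spike-in calibration for one biological replicate by OLS of
    log10(amount) on log10(intensity), using detected standards only."""
    amounts = spike.set_index("standard_id")["amount_fmol"]
    rows = table[
        (table["replicate"] == replicate)
        & table["protein_id"].isin(amounts.index)
        & table["intensity"].notna()
    ]
    if len(rows) < 2:
        raise CalibrationError(
            f"replicate {replicate}: {len(rows)} detected standards (need >= 2)"
        )
    x = np.log10(rows["intensity"].to_numpy(dtype=float))
    y = np.log10(amounts.loc[rows["protein_id"]].to_numpy(dtype=float))
    fit = stats.linregress(x, y)
    r_squared = 1.0 if np.allclose(y, fit.slope * x + fit.intercept) else fit.rvalue**2
    return CalibrationCurve(
        replicate_id=int(replicate),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(r_squared),
        n_points=int(len(rows)),
    )


def fit_all_calibrations(spike: pd.DataFrame, table: pd.DataFrame) -> dict[int, CalibrationCurve]:
    reps = sorted(table.loc[table["role"].isin(PARTITION_ROLES), "replicate"].unique())
    return {int(r): fit_calibration(spike, table, r) for r in reps}


# -- concentrations and partitioning ------------------------------------

_ROLE_TO_COMPARTMENT = {"nuclear": "nucleus", "cytosolic": "cytosol"}


def estimate_concentrations(
    table: pd.DataFrame,
    curves: dict[int, CalibrationCurve],
    config: RunConfig,
) -> pd.DataFrame:
    """Convert intensities to molar concentrations per replicate.

    amount_fmol = 10^(slope * log10(intensity) + intercept); concentration
    (mol/L) = amount / compartment volume.  Missing intensities stay missing
    (rows are omitted).  Raises ``LookupError`` for a replicate without a
    fitted curve.
    """
    rows = table[table["role"].isin(PARTITION_ROLES) & table["intensity"].notna()]
    out = []
    for rep, chunk in rows.groupby("replicate"):
        if int(rep) not in curves:
            raise LookupError(f"no calibration curve for replicate {rep}")
        curve = curves[int(rep)]
        amounts = curve.predict_amount_fmol(chunk["intensity"])
        volumes = chunk["role"].map(
            lambda r: config.volumes[_ROLE_TO_COMPARTMENT[r]]
        ).to_numpy(dtype=float)
        # fmol / nl = 1e-15 mol / 1e-9 L = 1e-6 mol/L
        conc = amounts / volumes * 1e-6
        out.append(
            pd.DataFrame(
                {
                    "protein_id": chunk["protein_id"].to_numpy(),
                    "compartment": chunk["role"].map(_ROLE_TO_COMPARTMENT).to_numpy(),
                    "replicate": int(rep),
                    "conc_mol_l": conc,
                }
            )
        )
    return pd.concat(out, ignore_index=True) if out else pd.DataFrame(
        columns=["protein_id", "compartment", "replicate", "conc_mol_l"]
    )


def compute_partition(concentrations: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Average per-compartment concentrations over the replicates in which a
    protein was detected, and derive the N:C partition coefficient.

    Proteins detected in a single compartment get status ``nuc_only`` /
    ``cyt_only`` and no finite ratio (unless ``config.pseudo_conc`` supplies
    a detection-limit stand-in concentration for the censored compartment).
    """
    if config.averaging == "linear":
        mean = concentrations.groupby(["protein_id", "compartment"])["conc_mol_l"].mean()
    else:
        mean = np.exp(
            np.log(concentrations.set_index(["protein_id", "compartment"])["conc_mol_l"])
            .groupby(level=[0, 1])
            .mean()
        )
    wide = mean.unstack("compartment").reindex(columns=["nucleus", "cytosol"])
    conc_nuc = wide["nucleus"]
    conc_cyt = wide["cytosol"]

    status = pd.Series("both", index=wide.index)
    status[conc_nuc.notna() & conc_cyt.isna()] = "nuc_only"
    status[conc_nuc.isna() & conc_cyt.notna()] = "cyt_only"

    num, den = conc_nuc.copy(), conc_cyt.copy()
    if config.pseudo_conc is not None:
        num = num.fillna(config.pseudo_conc)
        den = den.fillna(config.pseudo_conc)
    nc_ratio = num / den

    return pd.DataFrame(
        {
            "protein_id": wide.index,
            "conc_nuc": conc_nuc.to_numpy(),
            "conc_cyt": conc_cyt.to_numpy(),
            "nc_ratio": nc_ratio.to_numpy(),
            "log10_nc": np.log10(nc_ratio.to_numpy()),
            "status": status.to_numpy(),
            "flagged": False,
            "kept_override": False,
        }
    ).reset_index(drop=True)


def apply_contaminant_flags(
    records: pd.DataFrame, flags: set[str], keeplist: set[str]
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Remove flagged contaminant candidates unless manually kept.

    removed = flagged \\ keeplist, kept = flagged & keeplist, so the counts
    always satisfy flagged = removed + kept.  Keep-list entries that were
    never flagged are counted separately (``keep_not_flagged``) and warned
    about, not applied.
    """
    present = set(records["protein_id"])
    flagged = flags & present
    kept = flagged & keeplist
    removed = flagged - keeplist
    keep_not_flagged = (keeplist & present) - flags

    out = records[~records["protein_id"].isin(removed)].copy()
    out["flagged"] = out["protein_id"].isin(flagged)
    out["kept_override"] = out["protein_id"].isin(kept)
    counts = {
        "flagged": len(flagged),
        "removed": len(removed),
        "kept": len(kept),
        "keep_not_flagged": len(keep_not_flagged),
    }
    return out.reset_index(drop=True), counts


def format_ratio(nc_ratio: float, sig: int = 1) -> str:
    """Present an N:C ratio in the conventional 'N:1' / '1:C' style at
    ``sig`` significant figures (presentation only; reports keep full
    precision)."""
    if not np.isfinite(nc_ratio) or nc_ratio <= 0:
        raise ValueError(f"ratio must be positive and finite, got {nc_ratio}")

    def round_sig(x: float) -> float:
        exponent = math.floor(math.log10(x))
        return round(x, -exponent + sig - 1)

    if nc_ratio >= 1:
        return f"{round_sig(nc_ratio):g}:1"
    return f"1:{round_sig(1.0 / nc_ratio):g}"
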