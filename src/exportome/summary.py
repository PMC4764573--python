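"""Compartment accounting and per-functional-group N:C distributions.

``venn_counts`` reproduces the Venn-style bookkeeping of the fractionation
experiment (nuclear-only / cytosolic-only / both), and ``group_densities``
builds the density-plot summaries: a Gaussian-kernel density of log10 N:C
per functional group on a shared grid, rescaled by group size so that a
group's curve integrates to its share of the total — a subgroup's curve is
therefore pointwise below the all-protein curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FormatError


def venn_counts(records: pd.DataFrame) -> dict[str, int]:
    """Disjoint compartment counts from partition records (deduplicated by
    protein id): total = nuc_only + cyt_only + both, which equals the union
    identity |N| + |C| - |N ∩ C|."""
    if records["protein_id"].duplicated().any():
        raise ValueError("records must be deduplicated by protein_id")
    counts = records["status"].value_counts()
    out = {
        "nuc_only": int(counts.get("nuc_only", 0)),
        "cyt_only": int(counts.get("cyt_only", 0)),
        "both": int(counts.get("both", 0)),
    }
    out["total"] = out["nuc_only"] + out["cyt_only"] + out["both"]
    return out


def venn_from_sets(nuclear_ids: set[str], cytosolic_ids: set[str]) -> dict[str, int]:
    """Same counts straight from per-compartment identification sets."""
    both = nuclear_ids & cytosolic_ids
    return {
        "nuc_only": len(nuclear_ids - cytosolic_ids),
        "cyt_only": len(cytosolic_ids - nuclear_ids),
        "both": len(both),
        "total": len(nuclear_ids | cytosolic_ids),
    }


def read_groups(path) -> pd.DataFrame:
    """``protein_id<TAB>group`` rows (repeated ids allowed: multi-membership)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if not {"protein_id", "group"}.issubset(df.columns):
        raise FormatError(f"{path}: need columns protein_id, group")
    if (df["group"].str.len() == 0).any():
        raise FormatError(f"{path}: empty group label")
    return df[["protein_id", "group"]].drop_duplicates()


@dataclass(frozen=True)
class DensityCurve:
    """Rescaled KDE of log10 N:C for one functional group.  Censored
    (single-compartment) members are reported as end-of-axis counts, not
    folded into the kernel."""

    group: str
    grid: np.ndarray
    density: np.ndarray
    n_proteins: int
    n_nuc_only: int = 0
    n_cyt_only: int = 0


_FALLBACK_BANDWIDTH = 0.2  # log10 units, for degenerate (zero-spread) groups


def _silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule of thumb on the log10 N:C scale."""
    if len(values) < 2:
        return _FALLBACK_BANDWIDTH
    sd = float(np.std(values, ddof=1))
    iqr = float(np.subtract(*np.percentile(values, [75, 25])))
    sigma = min(s for s in (sd, iqr / 1.34) if s > 0) if max(sd, iqr) > 0 else 0.0
    if sigma == 0:
        return _FALLBACK_BANDWIDTH
    return 0.9 * sigma * len(values) ** (-0.2)


def _kde(values: np.ndarray, grid: np.ndarray, bandwidth: float) -> np.ndarray:
    sd = float(np.std(values, ddof=1)) if len(values) >= 2 else 0.0
    if sd > 0:
        # scalar bw_method is a factor on the data sd, so this pins the
        # kernel width to exactly `bandwidth` log10 units
        kde = stats.gaussian_kde(values, bw_method=bandwidth / sd)
        return kde(grid)
    # single point or zero variance: gaussian_kde cannot factorise the
    # covariance, so place the kernel by hand
    return stats.norm.pdf(grid[:, None], loc=values[None, :], scale=bandwidth).mean(axis=1)


def group_densities(
    records: pd.DataFrame,
    groups: pd.DataFrame,
    bandwidth: float | None = None,
    grid: np.ndarray | None = None,
) -> dict[str, DensityCurve]:
    """Per-group density curves of log10 N:C on one fixed grid.

    ``bandwidth`` is an absolute Gaussian kernel width in log10 units
    (default: Silverman's rule per group).  Only finite ratios (status
    ``both``) enter a kernel; one-compartment members are counted
    separately.  Each curve is rescaled by n_group / n_total (finite
    ratios), so curve masses add up like group sizes; the default grid
    extends eight bandwidths beyond the data, which keeps every curve's
    mass on-grid to well below 1e-9.  The special group ``"all"`` covering
    every finite record is always included.
    """
    finite = records[np.isfinite(records["log10_nc"])]
    total = len(finite)
    if total == 0:
        raise ValueError("no finite N:C ratios to summarise")

    member_values: dict[str, np.ndarray] = {}
    member_status: dict[str, pd.Series] = {}
    member_values["all"] = finite["log10_nc"].to_numpy(dtype=float)
    member_status["all"] = records["status"].value_counts()
    for label, members in groups.groupby("group"):
        sub = records[records["protein_id"].isin(set(members["protein_id"]))]
        fin = sub[np.isfinite(sub["log10_nc"])]
        member_values[str(label)] = fin["log10_nc"].to_numpy(dtype=float)
        member_status[str(label)] = sub["status"].value_counts()

    bandwidths = {
        label: (bandwidth if bandwidth is not None else _silverman_bandwidth(v))
        for label, v in member_values.items()
    }
    if grid is None:
        bw_max = max(bandwidths.values())
        bw_min = min(bandwidths.values())
        lo = member_values["all"].min() - 8.0 * bw_max
        hi = member_values["all"].max() + 8.0 * bw_max
        n_grid = int(min(8001, max(1001, np.ceil((hi - lo) / (bw_min / 3.0)) + 1)))
        grid = np.linspace(lo, hi, n_grid)

    curves: dict[str, DensityCurve] = {}
    for label, values in member_values.items():
        status = member_status[label]
        if len(values) == 0:
            density = np.zeros_like(grid)
        else:
            density = _kde(values, grid, bandwidths[label]) * (len(values) / total)
        curves[label] = DensityCurve(
            group=label,
            grid=grid,
            density=density,
            n_proteins=len(values),
            n_nuc_only=int(status.get("nuc_only", 0)),
            n_cyt_only=int(status.get("cyt_only", 0)),
        )
    return curves


def write_densities(curves: dict[str, DensityCurve], outdir) -> list[Path]:
    """One TSV per group holding the grid, the rescaled density and the
    censored end-bin counts (as constant columns)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for label, curve in sorted(curves.items()):
        df = pd.DataFrame({"log10_nc": curve.grid, "density": curve.density})
        df["n_proteins"] = curve.n_proteins
        df["n_nuc_only"] = curve.n_nuc_only
        df["n_cyt_only"] = curve.n_cyt_only
        safe = "".join(c if c.isalnum() or c in "-_" else "_" for c in label)
        path = outdir / f"density_{safe}.tsv"
        df.to_csv(path, sep="\t", index=False)
        paths.append(path)
    return paths
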