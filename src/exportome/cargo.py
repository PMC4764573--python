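"""Scoring and categorisation of RanGTP-dependent CRM1 binders.

Every protein detected in the RanGTP-bound eluate is scored by three
parameters derived from iBAQ-like intensities:

* molar fraction in the bound sample (intensity over the summed intensity of
  all detected proteins in that sample),
* enrichment from input (bound molar fraction over input molar fraction),
* RanGTP-stimulation (bound intensity over the minus-Ran bait intensity).

When a protein is undetected in the input or the minus-Ran sample, the
missing quantity is replaced by a conservative detectability baseline (the
median intensity of the k least abundant detected proteins of that sample,
k=30 by default) and the resulting score is flagged as a bound estimate:
enrichment and stimulation become lower bounds, never silently mixed with
measured values.

Categories are assigned by a first-match ordered rule list
A1 -> A2 -> B -> low_abundant -> non_binder -> ambiguous; transport-machinery
proteins (NUPs, NTRs, NPC constituents, CRM1 cofactors) bypass scoring and
keep their machinery class.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .config import MACHINERY_CLASSES, CategoryThresholds, RunConfig
from .errors import ConfigError

AFFINITY_ROLES = ("input", "bait_minus_ran", "bait_plus_ran")


# -- elementary scores --------------------------------------------------


def compute_molar_fractions(intensities: pd.Series) -> pd.Series:
    """Molar fraction of every detected protein in one sample: intensity
    divided by the summed intensity over detected proteins.  Missing values
    stay missing; detected fractions sum to 1."""
    detected = intensities.dropna()
    if detected.empty:
        raise ValueError("sample has no detected protein")
    return intensities / detected.sum()


def impute_baseline(intensities: pd.Series, k: int) -> float:
    """Conservative baseline intensity for detectability: the median of the
    ``k`` smallest detected intensities (all of them if fewer than ``k`` are
    detected).  Ties are resolved by a stable sort on (intensity, protein
    id), so the result is deterministic."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    detected = intensities.dropna()
    if detected.empty:
        raise ValueError("sample has no detected protein")
    ordered = detected.sort_index(kind="stable").sort_values(kind="stable")
    return float(ordered.iloc[: min(k, len(ordered))].median())


def compute_enrichment(
    fraction_bound: float,
    fraction_input: float | None,
    baseline_input_fraction: float,
) -> tuple[float, bool]:
    """Enrichment from input; falls back to the baseline-derived input
    fraction (returning a lower bound, flagged as estimate) when the protein
    was undetected in the input extract."""
    if fraction_input is None or (isinstance(fraction_input, float) and np.isnan(fraction_input)):
        return fraction_bound / baseline_input_fraction, True
    return fraction_bound / fraction_input, False


def compute_stimulation(
    intensity_plus: float,
    intensity_minus: float | None,
    baseline_minus: float,
) -> tuple[float, bool]:
    """RanGTP-stimulation of CRM1 binding; baseline-substituted (lower
    bound, flagged) when undetected in the minus-Ran sample."""
    if intensity_minus is None or (isinstance(intensity_minus, float) and np.isnan(intensity_minus)):
        return intensity_plus / baseline_minus, True
    return intensity_plus / intensity_minus, False


# -- categorisation -----------------------------------------------------


def assign_category(
    score: Mapping,
    thresholds: CategoryThresholds,
    machinery: Mapping[str, str] | None = None,
) -> str:
    """Assign a category to one scored protein (first matching rule wins).

    ``score`` must provide ``protein_id``, ``ran_stimulation``,
    ``input_enrichment``, ``molar_fraction_bound``, ``molar_fraction_input``
    and ``detected_in`` (an iterable or '|'-joined string of sample roles).
    Scores may be NaN for proteins undetected in the bound sample; NaN never
    passes a gate.
    """
    machinery = machinery or {}
    pid = score["protein_id"]
    if pid in machinery:
        cls = machinery[pid]
        if cls not in MACHINERY_CLASSES:
            raise ConfigError(f"unknown machinery class {cls!r} for {pid}")
        return cls

    detected = score["detected_in"]
    if isinstance(detected, str):
        detected = frozenset(d for d in detected.split("|") if d)
    else:
        detected = frozenset(detected)

    stim = score["ran_stimulation"]
    enr = score["input_enrichment"]
    mf = score["molar_fraction_bound"]
    mf_input = score["molar_fraction_input"]

    def ge(value, gate) -> bool:
        return bool(np.isfinite(value) and value >= gate)

    a1_gates = [
        ge(stim, thresholds.a1_min_stimulation),
        ge(enr, thresholds.a1_min_enrichment),
        ge(mf, thresholds.a1_min_molar_fraction),
    ]
    if all(a1_gates):
        return "A1"
    if ge(enr, thresholds.a2_min_enrichment) and ge(stim, thresholds.a2_min_stimulation):
        return "A2"
    if sum(a1_gates) == 2:
        relaxed = [
            ge(stim, thresholds.a1_min_stimulation * thresholds.b_relaxation),
            ge(enr, thresholds.a1_min_enrichment * thresholds.b_relaxation),
            ge(mf, thresholds.a1_min_molar_fraction * thresholds.b_relaxation),
        ]
        failing = a1_gates.index(False)
        if relaxed[failing]:
            return "B"
    if detected == frozenset({"bait_plus_ran"}) and not ge(
        mf, thresholds.a1_min_molar_fraction
    ):
        return "low_abundant"
    if (
        "input" in detected
        and ge(mf_input, thresholds.nonbinder_min_input_molar_fraction)
        and np.isfinite(enr)
        and enr <= thresholds.nonbinder_max_enrichment
    ):
        return "non_binder"
    return "ambiguous"


def classify_experiment(
    table: pd.DataFrame,
    config: RunConfig,
    machinery: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score and categorise every protein of an affinity experiment.

    ``table`` is a long-form intensity table (already filtered and merged to
    unique proteins) holding exactly one sample for each of the roles
    ``input``, ``bait_minus_ran`` and ``bait_plus_ran``.  Returns the score
    table and a census of category counts per detection pattern.

    Proteins undetected in the bound sample are classified ``non_binder``
    when the input extract supports that call (input molar fraction above
    the judgeability floor, baseline-bounded enrichment at or below the
    depletion ceiling) and ``ambiguous`` otherwise.
    """
    k = config.thresholds.k_baseline
    by_role: dict[str, pd.Series] = {}
    for role in AFFINITY_ROLES:
        rows = table[table["role"] == role]
        if rows.empty:
            raise ConfigError(f"affinity experiment lacks a sample with role {role!r}")
        if rows["sample_id"].nunique() > 1:
            raise ConfigError(f"multiple samples with role {role!r}; merge replicates first")
        by_role[role] = rows.set_index("protein_id")["intensity"]

    fractions = {role: compute_molar_fractions(s) for role, s in by_role.items()}
    baseline_minus = impute_baseline(by_role["bait_minus_ran"], k)
    baseline_input = impute_baseline(by_role["input"], k)
    baseline_plus = impute_baseline(by_role["bait_plus_ran"], k)
    baseline_input_fraction = baseline_input / by_role["input"].dropna().sum()
    baseline_plus_fraction = baseline_plus / by_role["bait_plus_ran"].dropna().sum()

    all_ids = sorted(set().union(*(s.index for s in by_role.values())))
    rows = []
    for pid in all_ids:
        i_input = by_role["input"].get(pid, np.nan)
        i_minus = by_role["bait_minus_ran"].get(pid, np.nan)
        i_plus = by_role["bait_plus_ran"].get(pid, np.nan)
        detected = frozenset(
            role
            for role, val in (
                ("input", i_input),
                ("bait_minus_ran", i_minus),
                ("bait_plus_ran", i_plus),
            )
            if np.isfinite(val)
        )
        if not detected:
            continue
        mf_input = fractions["input"].get(pid, np.nan)
        mf_bound = fractions["bait_plus_ran"].get(pid, np.nan)

        if "bait_plus_ran" in detected:
            enrichment, enr_est = compute_enrichment(
                mf_bound, mf_input, baseline_input_fraction
            )
            stimulation, stim_est = compute_stimulation(i_plus, i_minus, baseline_minus)
        elif "input" in detected:
            # undetected in the bound eluate: the baseline bounds its
            # enrichment from above, which is what the depletion call needs
            enrichment, enr_est = baseline_plus_fraction / mf_input, True
            stimulation, stim_est = np.nan, False
        else:
            enrichment, enr_est = np.nan, False
            stimulation, stim_est = np.nan, False

        rows.append(
            {
                "protein_id": pid,
                "molar_fraction_bound": mf_bound,
                "molar_fraction_input": mf_input,
                "input_enrichment": enrichment,
                "ran_stimulation": stimulation,
                "enrichment_is_bound_estimate": enr_est,
                "stimulation_is_bound_estimate": stim_est,
                "detected_in": "|".join(sorted(detected)),
            }
        )
    scores = pd.DataFrame(rows)
    scores["category"] = [
        assign_category(row, config.thresholds, machinery)
        for row in scores.to_dict("records")
    ]
    census = (
        scores.groupby(["category", "detected_in"])
        .size()
        .rename("n_proteins")
        .reset_index()
        .sort_values(["category", "detected_in"])
        .reset_index(drop=True)
    )
    return scores, census
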