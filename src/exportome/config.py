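"""Run configuration: compartment volumes, identification filters, and the
per-species category thresholds used to classify CRM1 binders.

Only three threshold values are anchored in published numbers (the frog A1
gates of >=500-fold RanGTP-stimulation and >=3-fold input enrichment, and the
A2 input-enrichment gate of >=100).  Everything else is a package default and
can be overridden per species, either programmatically or through a YAML
config file (see :func:`RunConfig.from_yaml`).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping

import yaml

from .errors import ConfigError

#: canonical sample roles accepted in intensity tables
ROLES = frozenset(
    {"nuclear", "cytosolic", "input", "bait_minus_ran", "bait_plus_ran", "standard"}
)

#: transport-machinery classes that bypass score-based categorisation
MACHINERY_CLASSES = frozenset({"NUPs", "NTRs", "NPC", "CRM1_cofactor"})

#: score-based categories, ordered from strictest to residual
SCORE_CATEGORIES = ("A1", "A2", "B", "low_abundant", "non_binder", "ambiguous")


@dataclass(frozen=True)
class CategoryThresholds:
    """Gates of the three-parameter cargo categorisation.

    A1 requires all three gates (RanGTP-stimulation, input enrichment, and a
    molar-fraction abundance gate in the RanGTP-bound eluate).  A2 trades a
    much stricter enrichment gate for a relaxed stimulation gate.  B is the A1
    rule with exactly one criterion relaxed by ``b_relaxation``.  Non-binders
    must be judgeable (abundant enough in the input) and depleted from the
    bound fraction.  ``k_baseline`` is the window for the conservative
    baseline imputation of undetected intensities (median of the k least
    abundant detected proteins of a sample).
    """

    a1_min_stimulation: float = 500.0
    a1_min_enrichment: float = 3.0
    a1_min_molar_fraction: float = 1e-4
    a2_min_enrichment: float = 100.0
    a2_min_stimulation: float = 10.0
    b_relaxation: float = 1.0 / 3.0
    nonbinder_max_enrichment: float = 0.2
    nonbinder_min_input_molar_fraction: float = 1e-5
    k_baseline: int = 30

    def __post_init__(self) -> None:
        numeric = {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if f.name != "k_baseline"
        }
        for name, value in numeric.items():
            if not math.isfinite(value) or value <= 0:
                raise ConfigError(f"threshold {name!r} must be finite and > 0, got {value}")
        if self.a1_min_enrichment > self.a2_min_enrichment:
            raise ConfigError(
                "A2 is the stricter enrichment gate: require "
                "a1_min_enrichment <= a2_min_enrichment"
            )
        if not 0 < self.b_relaxation <= 1:
            raise ConfigError("b_relaxation must lie in (0, 1]")
        if self.k_baseline < 1:
            raise ConfigError("k_baseline must be >= 1")


def species_profile(species: str) -> CategoryThresholds:
    """Return the category thresholds for ``species``.

    Only the frog (*Xenopus laevis*) profile carries published gate values;
    the human and yeast profiles default to the frog profile until their
    supplementary threshold tables are supplied by the user.
    """
    profiles = {
        "xenopus": CategoryThresholds(),
        "human": CategoryThresholds(),
        "yeast": CategoryThresholds(),
    }
    try:
        return profiles[species]
    except KeyError:
        raise ConfigError(f"unknown species profile {species!r}") from None


@dataclass
class RunConfig:
    """All tunable constants of a quantitation / classification run.

    Volumes are in nanolitres; the defaults (nucleus 50 nl, yolk-free
    cytosol 500 nl) encode the stage-VI oocyte volume model, i.e. a
    cytosol:nucleus volume ratio of 10.
    """

    volumes: Mapping[str, float] = field(
        default_factory=lambda: {"nucleus": 50.0, "cytosol": 500.0}
    )
    max_pep: float = 0.01
    min_unique_peptides: int = 2
    species: str = "xenopus"
    thresholds: CategoryThresholds = field(default_factory=CategoryThresholds)
    averaging: str = "linear"  # or "geometric": scale on which replicates are averaged
    pseudo_conc: float | None = None  # optional detection-limit stand-in for censored ratios
    seed: int = 0

    def __post_init__(self) -> None:
        for comp, vol in self.volumes.items():
            if not math.isfinite(vol) or vol <= 0:
                raise ConfigError(f"volume for {comp!r} must be > 0, got {vol}")
        if set(self.volumes) != {"nucleus", "cytosol"}:
            raise ConfigError("volumes must name exactly 'nucleus' and 'cytosol'")
        if not 0 <= self.max_pep <= 1:
            raise ConfigError("max_pep must lie in [0, 1]")
        if self.min_unique_peptides < 0:
            raise ConfigError("min_unique_peptides must be >= 0")
        if self.averaging not in ("linear", "geometric"):
            raise ConfigError("averaging must be 'linear' or 'geometric'")
        if isinstance(self.thresholds, dict):
            self.thresholds = CategoryThresholds(**self.thresholds)

    # -- serialisation --------------------------------------------------

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["volumes"] = dict(self.volumes)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Load a config with full defaulting: absent keys keep defaults,
        unknown keys are an error."""
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "thresholds" in data and data["thresholds"] is not None:
            data["thresholds"] = CategoryThresholds(**data["thresholds"])
        return cls(**data)
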