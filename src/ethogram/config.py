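"""Species configuration for the classification pipeline.

A :class:`SpeciesConfig` bundles every species- and stage-specific constant
used downstream: the flapping-flight frequency band, the dive-depth
threshold (murres only), which activity metric summarises dynamic
acceleration, the GPS labeling thresholds, the evaluation grid, the HMM
binning interval, and the behavior-specific metabolic coefficients of the
daily energy expenditure model.

Presets for the four study groups (murre/kittiwake x egg/chick) ship as
YAML files under ``ethogram/presets`` and are loaded with
:func:`get_config`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Optional

import yaml

__all__ = ["SpeciesConfig", "get_config", "load_config", "dump_config", "PRESETS"]

PRESETS = ("murre_egg", "murre_chick", "kittiwake_egg", "kittiwake_chick")


@dataclass
class SpeciesConfig:
    """All species/stage constants needed by the pipeline.

    Thresholds are strict inequalities exactly as used in the labeling
    rules: a ground speed equal to ``gps_flight_speed`` does *not* count
    as flying, and a depth equal to ``dive_depth_threshold`` does not
    count as diving.
    """

    species: str                      # "murre" | "kittiwake"
    stage: str                        # "egg" | "chick"
    behaviors: tuple[str, ...]        # behavior label set
    sampling_rate: float = 25.0       # accelerometer rate, Hz
    flight_wbf_band: tuple[float, float] = (6.0, 9.0)   # Hz
    dive_depth_threshold: Optional[float] = -1.0        # m, None = no depth channel
    activity_metric: str = "SD_ODBA"  # "SD_ODBA" | "SD_Z"
    gps_speed_error_cutoff: float = 30.0   # m/s, above = GPS error
    gps_flight_speed: float = 2.0          # m/s, above = flying
    gps_max_gap: Optional[float] = None    # s, fix gap above which fix excluded
    colony_radius: float = 250.0           # m (murre colony / kittiwake exclusion)
    fix_interval: float = 60.0             # s between GPS fixes
    transition_window: float = 60.0        # s excluded around behavior changes
    eval_subsample: float = 60.0           # s, scoring grid
    hmm_bin: float = 5.0                   # s, HMM observation interval
    dee_coefficients: dict = field(default_factory=dict)  # kJ/h per behavior

    def __post_init__(self) -> None:
        if self.species not in ("murre", "kittiwake"):
            raise ValueError(f"unknown species {self.species!r}")
        if self.species == "murre" and "diving" not in self.behaviors:
            raise ValueError("murre configuration must include diving")
        if self.species == "kittiwake" and "diving" in self.behaviors:
            raise ValueError("kittiwake configuration has no diving behavior")
        lo, hi = self.flight_wbf_band
        if not 0 < lo < hi:
            raise ValueError("flight WBF band must be a positive interval")
        if self.sampling_rate < 2.0 * hi:
            raise ValueError(
                "sampling rate must be at least twice the upper edge of the "
                "flight WBF band (Nyquist)"
            )
        for name in ("gps_speed_error_cutoff", "gps_flight_speed",
                     "colony_radius", "fix_interval", "transition_window",
                     "eval_subsample", "hmm_bin"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        missing = set(self.behaviors) - set(self.dee_coefficients)
        if missing:
            raise ValueError(f"DEE coefficients missing for {sorted(missing)}")

    @property
    def has_depth(self) -> bool:
        return self.dive_depth_threshold is not None


def _from_mapping(d: dict) -> SpeciesConfig:
    d = dict(d)
    d["behaviors"] = tuple(d["behaviors"])
    d["flight_wbf_band"] = tuple(d["flight_wbf_band"])
    return SpeciesConfig(**d)


def load_config(path) -> SpeciesConfig:
    """Load a :class:`SpeciesConfig` from a YAML file."""
    with open(path) as fh:
        return _from_mapping(yaml.safe_load(fh))


def dump_config(config: SpeciesConfig, path) -> None:
    d = asdict(config)
    d["behaviors"] = list(config.behaviors)
    d["flight_wbf_band"] = list(config.flight_wbf_band)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def get_config(species: str, stage: str = "chick") -> SpeciesConfig:
    """Return the shipped preset for a species/stage combination."""
    name = f"{species}_{stage}"
    if name not in PRESETS:
        raise ValueError(f"no preset {name!r}; choose from {PRESETS}")
    ref = resources.files("ethogram").joinpath(f"presets/{name}.yaml")
    with ref.open() as fh:
        return _from_mapping(yaml.safe_load(fh))
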