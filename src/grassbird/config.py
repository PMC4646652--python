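"""Configuration loading, validation, and run manifests.

A run is configured by a single YAML file.  Unset keys fall back to the
packaged defaults; unknown keys are rejected with their dotted path, and
every value is validated against the invariants of the typed object it
feeds (utility entries in [0, 1], probabilities in [0, 1], non-negative
weights, and so on).

Every run writes a manifest carrying the configuration hash, base seed,
package version, timestamp, and a checksum per output file, so outputs can
be reproduced byte-for-byte from the manifest inputs.
"""

from __future__ import annotations

import copy
import datetime
import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Union

import yaml

from . import __version__
from .abm import (
    ChoiceModel,
    LandownerType,
    Objective,
    PolicyAlternative,
    PreferenceWeights,
    UtilityMatrix,
)
from .birds import DemographicParams

__all__ = ["RunConfig", "RunManifest", "load_config", "default_config_dict"]


def default_config_dict() -> dict:
    """A deep copy of the packaged default configuration."""
    with resources.files("grassbird.data").joinpath("defaults.yaml").open() as fh:
        return yaml.safe_load(fh)


def _merge(defaults: dict, override: Mapping, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in override.items():
        dotted = f"{path}.{key}" if path else str(key)
        if key not in defaults:
            raise KeyError(f"unknown configuration key: {dotted}")
        if isinstance(defaults[key], dict):
            if not isinstance(value, Mapping):
                raise ValueError(f"{dotted}: expected a mapping")
            out[key] = _merge(defaults[key], value, dotted)
        else:
            out[key] = value
    return out


def _validate_weights_override(weights: Mapping) -> dict:
    """Validate an optional inline weight-table override."""
    lts = {t.value for t in LandownerType}
    pols = {p.value for p in PolicyAlternative}
    objs = {o.value for o in Objective}
    out: dict = {}
    for lt, by_policy in weights.items():
        if lt not in lts:
            raise KeyError(f"weights.{lt}: unknown landowner type")
        out[lt] = {}
        for pol, by_obj in by_policy.items():
            if pol not in pols:
                raise KeyError(f"weights.{lt}.{pol}: unknown policy")
            for obj, v in by_obj.items():
                if obj not in objs:
                    raise KeyError(
                        f"weights.{lt}.{pol}.{obj}: unknown objective"
                    )
                if v < 0:
                    raise ValueError(
                        f"weights.{lt}.{pol}.{obj} = {v!r}: "
                        "weights must be >= 0"
                    )
            out[lt][pol] = PreferenceWeights(
                **{o: float(by_obj[o]) for o in by_obj}
            )
    return out


@dataclass
class RunConfig:
    """Fully validated effective configuration of a run."""

    n_rows: int
    n_cols: int
    pixel_size_m: float
    choice: ChoiceModel
    utility: UtilityMatrix
    demography: DemographicParams
    n0: float
    horizon: int
    replicates: int
    stochastic: bool
    curve_agriculture_share: float
    weights_override: dict = field(default_factory=dict)
    raw: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_dict(cls, cfg: Mapping) -> "RunConfig":
        cfg = dict(cfg)
        # the weight-table override has data-dependent keys, validated apart
        weights_in = cfg.pop("weights", {}) or {}
        merged = _merge(default_config_dict(), cfg)
        ls = merged["landscape"]
        if ls["n_rows"] < 1 or ls["n_cols"] < 1:
            raise ValueError("landscape.n_rows and landscape.n_cols must be >= 1")
        try:
            utility = UtilityMatrix.from_nested_dict(merged["utility"])
        except ValueError as err:
            raise ValueError(f"utility: {err}") from None
        try:
            demography = DemographicParams.from_dict(merged["demography"])
        except (TypeError, ValueError) as err:
            raise ValueError(f"demography: {err}") from None
        sim = merged["simulation"]
        if sim["n0"] < 0:
            raise ValueError("simulation.n0 must be >= 0")
        if sim["horizon"] < 0:
            raise ValueError("simulation.horizon must be >= 0")
        if sim["replicates"] < 1:
            raise ValueError("simulation.replicates must be >= 1")
        share = merged["response_curve"]["agriculture_share"]
        if not (0.0 <= share <= 1.0):
            raise ValueError("response_curve.agriculture_share must be in [0, 1]")
        weights_override = _validate_weights_override(weights_in)
        effective = dict(merged)
        if weights_in:
            effective["weights"] = copy.deepcopy(weights_in)
        return cls(
            n_rows=int(ls["n_rows"]),
            n_cols=int(ls["n_cols"]),
            pixel_size_m=float(ls["pixel_size_m"]),
            choice=ChoiceModel(
                temperature=float(merged["choice"]["temperature"]),
                deterministic=bool(merged["choice"]["deterministic"]),
            ),
            utility=utility,
            demography=demography,
            n0=float(sim["n0"]),
            horizon=int(sim["horizon"]),
            replicates=int(sim["replicates"]),
            stochastic=bool(sim["stochastic"]),
            curve_agriculture_share=float(share),
            weights_override=weights_override,
            raw=effective,
        )

    def to_dict(self) -> dict:
        """Effective configuration as plain types (round-trips via from_dict)."""
        return copy.deepcopy(self.raw)

    def config_hash(self) -> str:
        """Stable SHA-256 hash of the effective configuration."""
        canon = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(canon.encode()).hexdigest()

    def dump(self, path: Union[str, Path]) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8"
        )


def load_config(path: Optional[Union[str, Path]] = None) -> RunConfig:
    """Load and validate a YAML config; ``None`` or an empty file = defaults."""
    if path is None:
        return RunConfig.from_dict({})
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"config file not found: {p}")
    loaded = yaml.safe_load(p.read_text(encoding="utf-8"))
    if loaded is None:
        loaded = {}
    if not isinstance(loaded, Mapping):
        raise ValueError(f"{p}: top level of config must be a mapping")
    return RunConfig.from_dict(loaded)


def _sha256_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record written next to every run's outputs."""

    config_hash: str
    seed: int
    version: str
    timestamp: str
    outputs: dict[str, str]

    @classmethod
    def create(
        cls, config: RunConfig, seed: int, outputs: list[Union[str, Path]]
    ) -> "RunManifest":
        return cls(
            config_hash=config.config_hash(),
            seed=int(seed),
            version=__version__,
            timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
            outputs={Path(p).name: _sha256_file(Path(p)) for p in outputs},
        )

    def write(self, path: Union[str, Path]) -> None:
        Path(path).write_text(
            json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )
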