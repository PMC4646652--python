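"""Landowner land-cover choice model.

Each simulated landowner belongs to one of three archetypes — a
profit-maximizing producer, a small-scale farmer, and a conservationist —
with a value system expressed as importance weights over five objectives:
grassland birds, carbon storage, water quality, financial profit, and
biodiversity.  Policy alternatives shift those weights (the packaged
expert-elicited weight table gives one row per landowner type per policy).

A landowner scores each land-cover option by a simple multi-attribute rating:
the weighted sum of per-objective utilities of that cover.  Scores are turned
into per-pixel choice probabilities either deterministically (argmax, ties
split evenly) or through a softmax with a temperature controlling how sharply
the best option dominates.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .landscape import CoverDistribution, LandCover

__all__ = [
    "Objective",
    "LandownerType",
    "PolicyAlternative",
    "PreferenceWeights",
    "UtilityMatrix",
    "ChoiceModel",
    "apply_policy",
    "normalize_weights",
    "total_utility",
    "choice_probabilities",
    "raw_weight_table",
]


class Objective(enum.Enum):
    """The five objectives landowners weigh against each other."""

    BIRDS = "birds"
    CARBON = "carbon"
    WATER_QUALITY = "water_quality"
    FINANCIAL_PROFIT = "financial_profit"
    BIODIVERSITY = "biodiversity"


class LandownerType(enum.Enum):
    PROFIT_MAXIMIZING_PRODUCER = "profit_maximizing_producer"
    SMALL_SCALE_FARMER = "small_scale_farmer"
    CONSERVATIONIST = "conservationist"


class PolicyAlternative(enum.Enum):
    """Seven policy alternatives, status quo being the no-action baseline."""

    OUTREACH_MARKETING = "outreach_marketing"
    REGULATORY_ENFORCEMENT = "regulatory_enforcement"
    PUBLIC_LAND_ACQUISITION = "public_land_acquisition"
    BEST_MANAGEMENT_PRACTICES = "best_management_practices"
    ECOSYSTEM_SERVICES_PAYMENTS = "ecosystem_services_payments"
    ECONOMIC_INCENTIVES = "economic_incentives"
    STATUS_QUO = "status_quo"


_OBJECTIVES = tuple(Objective)
_COVERS = (LandCover.GRASSLAND, LandCover.AGRICULTURE, LandCover.FOREST)


@dataclass(frozen=True)
class PreferenceWeights:
    """Importance weights over the five objectives, in [0, inf).

    Raw (as-elicited) rows may sum to slightly off 1 from rounding; call
    :func:`normalize_weights` before computing utilities.
    """

    birds: float
    carbon: float
    water_quality: float
    financial_profit: float
    biodiversity: float

    def __post_init__(self) -> None:
        for o in _OBJECTIVES:
            w = getattr(self, o.value)
            if w < 0 or not np.isfinite(w):
                raise ValueError(f"weight {o.value}={w!r} must be finite and >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, o.value) for o in _OBJECTIVES])

    @property
    def total(self) -> float:
        return float(self.as_array().sum())

    @property
    def is_normalized(self) -> bool:
        return abs(self.total - 1.0) <= 1e-9

    def __getitem__(self, o: Objective) -> float:
        return getattr(self, o.value)

    @classmethod
    def from_array(cls, w: np.ndarray) -> "PreferenceWeights":
        return cls(*(float(x) for x in w))


@dataclass(frozen=True)
class UtilityMatrix:
    """Utility in [0, 1] of every land-cover class for every objective."""

    values: Mapping[LandCover, Mapping[Objective, float]]

    def __post_init__(self) -> None:
        for c in _COVERS:
            if c not in self.values:
                raise ValueError(f"utility matrix missing cover {c.name}")
            for o in _OBJECTIVES:
                if o not in self.values[c]:
                    raise ValueError(
                        f"utility matrix missing entry ({c.name}, {o.name})"
                    )
                u = self.values[c][o]
                if not (0.0 <= u <= 1.0):
                    raise ValueError(
                        f"utility U[{c.name}][{o.name}]={u!r} outside [0, 1]"
                    )

    def row(self, cover: LandCover) -> np.ndarray:
        """Utilities of ``cover`` ordered as :class:`Objective`."""
        return np.array([self.values[cover][o] for o in _OBJECTIVES])

    def as_array(self) -> np.ndarray:
        """3 x 5 array, rows ordered (grassland, agriculture, forest)."""
        return np.stack([self.row(c) for c in _COVERS])

    @classmethod
    def from_array(cls, u: np.ndarray) -> "UtilityMatrix":
        u = np.asarray(u, dtype=float)
        return cls(
            {
                c: {o: float(u[i, j]) for j, o in enumerate(_OBJECTIVES)}
                for i, c in enumerate(_COVERS)
            }
        )

    @classmethod
    def from_nested_dict(cls, d: Mapping[str, Mapping[str, float]]) -> "UtilityMatrix":
        """Build from string-keyed nested dict (cover name -> objective name)."""
        return cls(
            {
                LandCover[c.upper()]: {
                    Objective[o.upper()]: float(v) for o, v in row.items()
                }
                for c, row in d.items()
            }
        )

    def to_nested_dict(self) -> dict[str, dict[str, float]]:
        return {
            c.name.lower(): {o.name.lower(): self.values[c][o] for o in _OBJECTIVES}
            for c in _COVERS
        }


@dataclass(frozen=True)
class ChoiceModel:
    """How utility scores become a cover distribution.

    deterministic=True puts all probability on the argmax cover (ties split
    uniformly); otherwise a softmax with the given temperature is used, the
    deterministic rule being its temperature -> 0 limit.
    """

    temperature: float = 0.15
    deterministic: bool = False

    def __post_init__(self) -> None:
        if not self.deterministic and not self.temperature > 0:
            raise ValueError("softmax temperature must be > 0")


# ---------------------------------------------------------------------------
# packaged weight table

_weight_table: pd.DataFrame | None = None


def raw_weight_table() -> pd.DataFrame:
    """The packaged elicited weight table, one row per (landowner, policy).

    Rows are as transcribed (pre-normalization), so rounding in the source
    survives until :func:`normalize_weights` is applied.
    """
    global _weight_table
    if _weight_table is None:
        with resources.files("grassbird.data").joinpath(
            "preference_weights.csv"
        ).open() as fh:
            _weight_table = pd.read_csv(fh).set_index(["landowner", "policy"])
    return _weight_table


def apply_policy(
    lt: LandownerType, policy: PolicyAlternative
) -> PreferenceWeights:
    """Look up the elicited weight row for a landowner type under a policy.

    Returns the raw (un-normalized) weights.
    """
    if not isinstance(lt, LandownerType):
        raise KeyError(f"unknown landowner type {lt!r}")
    if not isinstance(policy, PolicyAlternative):
        raise KeyError(f"unknown policy alternative {policy!r}")
    table = raw_weight_table()
    try:
        row = table.loc[(lt.value, policy.value)]
    except KeyError:
        raise KeyError(
            f"no weight row for ({lt.value}, {policy.value})"
        ) from None
    return PreferenceWeights(
        **{o.value: float(row[o.value]) for o in _OBJECTIVES}
    )


def normalize_weights(w: PreferenceWeights) -> PreferenceWeights:
    """Rescale weights to sum exactly to 1, preserving proportions."""
    total = w.total
    if total <= 0:
        raise ValueError("cannot normalize all-zero preference weights")
    return PreferenceWeights.from_array(w.as_array() / total)


def total_utility(
    w: PreferenceWeights, U: UtilityMatrix, cover: LandCover
) -> float:
    """Multi-attribute score of one cover: sum_o w[o] * U[cover][o]."""
    return float(w.as_array() @ U.row(cover))


def choice_probabilities(
    w: PreferenceWeights, U: UtilityMatrix, cm: ChoiceModel = ChoiceModel()
) -> CoverDistribution:
    """Convert utility scores into a per-pixel cover distribution.

    Softmax probabilities are shift-invariant in the utilities; the
    deterministic mode returns the argmax cover (ties split uniformly).
    """
    scores = np.array([total_utility(w, U, c) for c in _COVERS])
    if cm.deterministic:
        best = scores == scores.max()
        p = best / best.sum()
    else:
        z = (scores - scores.max()) / cm.temperature
        e = np.exp(z)
        p = e / e.sum()
    # guard against float drift so CoverDistribution's sum check passes
    p = p / p.sum()
    return CoverDistribution.from_array(p)
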