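"""Spatially explicit full-annual-cycle grassland bird population model.

The population is censused at the start of the breeding season each year and
updated through the recursion

    N_t = N_{t-1} (1 + R_b) S_f S_w S_s

where R_b is per-capita reproductive output on the breeding landscape and
S_f, S_w, S_s are survival probabilities through fall migration (three
sequential stopovers), winter, and spring migration (the same stopovers in
reverse).  Every term is a function of the land-cover composition and
configuration of the landscape it plays out on.

Habitat sets carrying capacity in every season: each grassland pixel
contributes a fixed number of "slots", and birds in excess of the seasonal
ceiling fall back on a low matrix survival floor (breeding overflow simply
does not breed).  Below capacity all rates are abundance-free, so on static
landscapes the trajectory is exactly geometric — a property the test suite
exploits as a closed-form oracle.

Demography is expected-value (deterministic) by default; demographic
stochasticity (Poisson births, binomial survival) can be switched on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .landscape import (
    LandCover,
    Landscape,
    LandscapeRole,
    neighbor_mean,
    patch_mean,
)

__all__ = [
    "DemographicParams",
    "Trajectory",
    "reproduction",
    "stopover_survival",
    "migration_survival",
    "winter_survival",
    "step_population",
    "simulate_annual_cycle",
    "growth_rate",
]

_COVER_KEYS = ("grassland", "agriculture", "forest")
_COVER_BY_KEY = {
    "grassland": LandCover.GRASSLAND,
    "agriculture": LandCover.AGRICULTURE,
    "forest": LandCover.FOREST,
}


def _cover_map(d: Mapping) -> dict[LandCover, float]:
    """Accept either LandCover-keyed or lower-case-string-keyed mappings."""
    out: dict[LandCover, float] = {}
    for k, v in d.items():
        c = _COVER_BY_KEY[k] if isinstance(k, str) else LandCover(k)
        out[c] = float(v)
    missing = [c.name for c in LandCover if c not in out]
    if missing:
        raise ValueError(f"cover-keyed mapping missing {missing}")
    return out


@dataclass
class DemographicParams:
    """All parameters of the bird population model.

    Attributes
    ----------
    nest_density_per_grass_pixel : float
        Expected nests per grassland pixel when the landscape is saturated.
    nest_survival_base : float
        Probability an egg survives to independence in unbroken grassland.
    edge_penalty : float
        Multiplicative reduction of nest survival per unit non-grassland
        fraction in the radius-1 Moore neighborhood (0 = no edge effect,
        1 = total failure in a fully non-grass neighborhood).
    fledglings_per_successful_nest : float
        Young fledged by a successful nest.
    occupancy_by_cover : mapping LandCover -> [0, 1]
        Probability a migrating/wintering bird locates and uses a pixel of
        each cover class.
    stopover_survival_by_cover : mapping LandCover -> [0, 1]
        Forage-driven per-stop survival contribution of each cover class;
        realized survival is this value averaged over the one-hectare patch.
    winter_survival_by_cover : mapping LandCover -> [0, 1]
        Over-winter survival on a pixel of each cover class (pixel-level
        only; no neighborhood effect).
    k_breeding_per_grass_pixel, k_stopover_per_grass_pixel,
    k_winter_per_grass_pixel : float
        Seasonal carrying capacity contributed by each grassland pixel
        (birds per pixel).
    matrix_survival_floor : float
        Survival of birds that exceed seasonal capacity and are forced into
        non-habitat ("the matrix").
    """

    nest_density_per_grass_pixel: float = 0.35
    nest_survival_base: float = 0.40
    edge_penalty: float = 0.50
    fledglings_per_successful_nest: float = 3.0
    occupancy_by_cover: Mapping[LandCover, float] = field(
        default_factory=lambda: {
            LandCover.GRASSLAND: 1.0,
            LandCover.AGRICULTURE: 0.2,
            LandCover.FOREST: 0.4,
        }
    )
    stopover_survival_by_cover: Mapping[LandCover, float] = field(
        default_factory=lambda: {
            LandCover.GRASSLAND: 0.98,
            LandCover.AGRICULTURE: 0.75,
            LandCover.FOREST: 0.90,
        }
    )
    winter_survival_by_cover: Mapping[LandCover, float] = field(
        default_factory=lambda: {
            LandCover.GRASSLAND: 0.92,
            LandCover.AGRICULTURE: 0.55,
            LandCover.FOREST: 0.80,
        }
    )
    k_breeding_per_grass_pixel: float = 1.0
    k_stopover_per_grass_pixel: float = 3.0
    k_winter_per_grass_pixel: float = 2.0
    matrix_survival_floor: float = 0.10

    def __post_init__(self) -> None:
        self.occupancy_by_cover = _cover_map(self.occupancy_by_cover)
        self.stopover_survival_by_cover = _cover_map(
            self.stopover_survival_by_cover
        )
        self.winter_survival_by_cover = _cover_map(self.winter_survival_by_cover)
        for name in (
            "nest_survival_base",
            "edge_penalty",
            "matrix_survival_floor",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v!r} must lie in [0, 1]")
        for d_name in (
            "occupancy_by_cover",
            "stopover_survival_by_cover",
            "winter_survival_by_cover",
        ):
            for c, v in getattr(self, d_name).items():
                if not (0.0 <= v <= 1.0):
                    raise ValueError(
                        f"{d_name}[{c.name}]={v!r} must lie in [0, 1]"
                    )
        for name in (
            "nest_density_per_grass_pixel",
            "fledglings_per_successful_nest",
            "k_breeding_per_grass_pixel",
            "k_stopover_per_grass_pixel",
            "k_winter_per_grass_pixel",
        ):
            v = getattr(self, name)
            if v < 0 or not np.isfinite(v):
                raise ValueError(f"{name}={v!r} must be finite and >= 0")

    def to_dict(self) -> dict:
        """Plain-type dict (string cover keys) suitable for YAML/JSON."""
        d = asdict(self)
        for key in (
            "occupancy_by_cover",
            "stopover_survival_by_cover",
            "winter_survival_by_cover",
        ):
            d[key] = {c.name.lower(): v for c, v in getattr(self, key).items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "DemographicParams":
        return cls(**dict(d))


@dataclass
class Trajectory:
    """A simulated population trajectory and its per-year vital rates.

    ``n`` has length horizon+1 (year 0 is the initial abundance); the rate
    arrays have length horizon.
    """

    n: np.ndarray
    r_b: np.ndarray
    s_f: np.ndarray
    s_w: np.ndarray
    s_s: np.ndarray

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=float)
        for name in ("r_b", "s_f", "s_w", "s_s"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != (len(self.n) - 1,):
                raise ValueError(
                    f"{name} must have length horizon={len(self.n) - 1}"
                )
        if not np.all(np.isfinite(self.n)) or np.any(self.n < 0):
            raise ValueError("abundances must be finite and >= 0")

    @property
    def horizon(self) -> int:
        return len(self.n) - 1

    @property
    def mean_annual_rate_arithmetic(self) -> float:
        """Arithmetic mean of per-year proportional changes."""
        with np.errstate(divide="ignore", invalid="ignore"):
            rates = self.n[1:] / self.n[:-1] - 1.0
        rates = rates[np.isfinite(rates)]
        return float(rates.mean()) if rates.size else float("nan")

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: year, N, and the vital rates applied during year."""
        h = self.horizon
        pad = [np.nan]
        return pd.DataFrame(
            {
                "year": np.arange(h + 1),
                "N": self.n,
                "R_b": np.concatenate([self.r_b, pad]) if h else pad,
                "S_f": np.concatenate([self.s_f, pad]) if h else pad,
                "S_w": np.concatenate([self.s_w, pad]) if h else pad,
                "S_s": np.concatenate([self.s_s, pad]) if h else pad,
            }
        )


def _require_role(ls: Landscape, role: LandscapeRole, op: str) -> None:
    if ls.role is not role:
        raise ValueError(
            f"{op} requires a {role.value} landscape, got {ls.role.value}"
        )


# ---------------------------------------------------------------------------
# per-landscape summaries
#
# On a static landscape every vital rate is a simple function of abundance
# and a handful of landscape aggregates; precomputing those aggregates makes
# the 30-year loop O(1) per year.


@dataclass(frozen=True)
class _BreedingSummary:
    f_pot: float  # fledgling potential at saturation
    k_b: float  # breeding capacity

    def rate(self, n: float) -> float:
        if n <= 0 or self.k_b <= 0:
            return 0.0
        return self.f_pot * min(n, self.k_b) / (self.k_b * n)


@dataclass(frozen=True)
class _SurvivalSummary:
    settled_mean: float  # mean survival of settled birds
    capacity: float
    floor: float
    habitable: bool  # any positive occupancy weight

    def rate(self, n: float) -> float:
        if not self.habitable or self.capacity <= 0:
            return self.floor
        if n <= self.capacity:
            return self.settled_mean
        settled = self.capacity / n
        return settled * self.settled_mean + (1.0 - settled) * self.floor


def _breeding_summary(
    breeding: Landscape, p: DemographicParams
) -> _BreedingSummary:
    grass = breeding.mask(LandCover.GRASSLAND).astype(float)
    n_grass = float(grass.sum())
    k_b = p.k_breeding_per_grass_pixel * n_grass
    if n_grass == 0:
        return _BreedingSummary(0.0, k_b)
    f_non_grass = neighbor_mean(1.0 - grass)
    per_pixel = (
        grass
        * p.nest_density_per_grass_pixel
        * p.fledglings_per_successful_nest
        * p.nest_survival_base
        * (1.0 - p.edge_penalty * f_non_grass)
    )
    f_pot = float(np.clip(per_pixel, 0.0, None).sum())
    return _BreedingSummary(f_pot, k_b)


def _stopover_summary(
    stop: Landscape, p: DemographicParams
) -> _SurvivalSummary:
    occ = stop.value_map(p.occupancy_by_cover)
    weights = occ * neighbor_mean(occ)
    total_w = float(weights.sum())
    quality = patch_mean(stop.value_map(p.stopover_survival_by_cover))
    capacity = p.k_stopover_per_grass_pixel * float(
        stop.mask(LandCover.GRASSLAND).sum()
    )
    settled_mean = (
        float((weights * quality).sum() / total_w) if total_w > 0 else 0.0
    )
    return _SurvivalSummary(
        settled_mean, capacity, p.matrix_survival_floor, total_w > 0
    )


def _winter_summary(win: Landscape, p: DemographicParams) -> _SurvivalSummary:
    weights = win.value_map(p.occupancy_by_cover)
    total_w = float(weights.sum())
    survival = win.value_map(p.winter_survival_by_cover)
    capacity = p.k_winter_per_grass_pixel * float(
        win.mask(LandCover.GRASSLAND).sum()
    )
    settled_mean = (
        float((weights * survival).sum() / total_w) if total_w > 0 else 0.0
    )
    return _SurvivalSummary(
        settled_mean, capacity, p.matrix_survival_floor, total_w > 0
    )


def reproduction(breeding: Landscape, n: float, p: DemographicParams) -> float:
    """Per-capita reproductive output R_b on the breeding landscape.

    Each grassland pixel can hold nests; expected fledglings on a pixel are
    nest density x fledglings per successful nest x base nest survival,
    discounted by the edge penalty times the non-grassland fraction of the
    pixel's Moore neighborhood.  Summing over pixels gives the landscape's
    fledgling potential at saturation, F_pot; the breeding capacity is
    K_b = k_breeding_per_grass_pixel x (number of grassland pixels).

    Only min(N, K_b) birds breed (overflow does not breed), each producing
    F_pot / K_b fledglings, so R_b = F_pot/K_b below capacity and declines
    as F_pot/N above it.  R_b = 0 when N = 0 or there is no grassland.
    """
    _require_role(breeding, LandscapeRole.BREEDING, "reproduction")
    if n < 0:
        raise ValueError("abundance must be >= 0")
    return _breeding_summary(breeding, p).rate(n)


def stopover_survival(stop: Landscape, n: float, p: DemographicParams) -> float:
    """Survival probability through a single migratory stopover.

    Occupancy — the probability a pixel is located and used — is the pixel's
    own occupancy value times the mean occupancy of its Moore neighborhood.
    Birds settle across pixels in proportion to occupancy weight, up to the
    stopover capacity provided by grassland pixels; overflow birds survive
    at the matrix floor.  A settled bird's survival is the forage quality of
    its one-hectare patch (3x3 window mean of the per-cover survival values).
    """
    _require_role(stop, LandscapeRole.STOPOVER, "stopover_survival")
    if n < 0:
        raise ValueError("abundance must be >= 0")
    return _stopover_summary(stop, p).rate(n)


def migration_survival(
    stops: Sequence[Landscape], n: float, p: DemographicParams
) -> float:
    """Survival through a migration leg of exactly three sequential stopovers.

    Losses compound: the abundance arriving at each stop is discounted by
    survival at the previous ones, which matters when a stop's capacity
    binds.  Southbound (fall) order should be reversed for the northbound
    (spring) leg.
    """
    if len(stops) != 3:
        raise ValueError(f"migration requires exactly 3 stopovers, got {len(stops)}")
    for stop in stops:
        _require_role(stop, LandscapeRole.STOPOVER, "migration_survival")
    return _migration_rate([_stopover_summary(s, p) for s in stops], n)


def _migration_rate(summaries: Sequence[_SurvivalSummary], n: float) -> float:
    surv = 1.0
    for summary in summaries:
        surv *= summary.rate(n * surv)
    return surv


def winter_survival(win: Landscape, n: float, p: DemographicParams) -> float:
    """Over-winter survival: pixel-level only, no neighborhood effect.

    Birds settle in proportion to per-cover occupancy up to winter capacity;
    a settled bird survives with its own pixel's per-cover winter survival,
    overflow at the matrix floor.
    """
    _require_role(win, LandscapeRole.WINTERING, "winter_survival")
    if n < 0:
        raise ValueError("abundance must be >= 0")
    return _winter_summary(win, p).rate(n)


def step_population(
    n: float, r_b: float, s_f: float, s_w: float, s_s: float
) -> float:
    """One year of the recursion: N (1 + R_b) S_f S_w S_s."""
    if n < 0 or r_b < 0:
        raise ValueError("abundance and reproductive output must be >= 0")
    for name, s in (("S_f", s_f), ("S_w", s_w), ("S_s", s_s)):
        if not (0.0 <= s <= 1.0):
            raise ValueError(f"{name}={s!r} must lie in [0, 1]")
    return n * (1.0 + r_b) * s_f * s_w * s_s


def simulate_annual_cycle(
    breeding: Landscape,
    stopovers: Sequence[Landscape],
    wintering: Landscape,
    params: DemographicParams,
    n0: float = 100.0,
    horizon: int = 30,
    seed: Union[int, np.random.SeedSequence, None] = None,
    stochastic: bool = False,
) -> Trajectory:
    """Iterate the annual cycle over a fixed set of landscapes.

    Order of events each year: breed on the breeding landscape, migrate south
    through the three stopovers, overwinter, migrate north through the same
    stopovers in reverse.  The census point is the start of breeding.

    With ``stochastic=True`` births are Poisson and each survival phase is
    binomial; otherwise the update is the deterministic expected value and
    ``seed`` is inert.
    """
    _require_role(breeding, LandscapeRole.BREEDING, "simulate")
    if len(stopovers) != 3:
        raise ValueError(
            f"simulate requires exactly 3 stopovers, got {len(stopovers)}"
        )
    for s in stopovers:
        _require_role(s, LandscapeRole.STOPOVER, "simulate")
    _require_role(wintering, LandscapeRole.WINTERING, "simulate")
    if n0 < 0:
        raise ValueError("initial abundance must be >= 0")
    if horizon < 0:
        raise ValueError("horizon must be >= 0")

    rng = np.random.default_rng(seed)
    breed_sum = _breeding_summary(breeding, params)
    stop_sums = [_stopover_summary(s, params) for s in stopovers]
    winter_sum = _winter_summary(wintering, params)

    n = float(n0)
    ns = [n]
    r_bs, s_fs, s_ws, s_ss = [], [], [], []
    for _ in range(horizon):
        r_b = breed_sum.rate(n)
        if stochastic and n > 0:
            births = float(rng.poisson(n * r_b))
            n_post_breed = n + births
            r_b = births / n
        else:
            n_post_breed = n * (1.0 + r_b)

        def _survive(n_in: float, s: float) -> float:
            if stochastic:
                return float(rng.binomial(int(round(n_in)), s))
            return n_in * s

        s_f = _migration_rate(stop_sums, n_post_breed)
        n_post_fall = _survive(n_post_breed, s_f)
        s_w = winter_sum.rate(n_post_fall)
        n_post_winter = _survive(n_post_fall, s_w)
        s_s = _migration_rate(stop_sums[::-1], n_post_winter)
        n = _survive(n_post_winter, s_s)

        r_bs.append(r_b)
        s_fs.append(s_f)
        s_ws.append(s_w)
        s_ss.append(s_s)
        ns.append(n)
    return Trajectory(
        n=np.array(ns),
        r_b=np.array(r_bs),
        s_f=np.array(s_fs),
        s_w=np.array(s_ws),
        s_s=np.array(s_ss),
    )


def growth_rate(tr: Trajectory) -> float:
    """Geometric mean annual growth rate (N_T / N_0)^(1/T) - 1.

    Returns -1 for extinction (N_T = 0); requires N_0 > 0 and at least one
    simulated year.
    """
    if tr.horizon < 1:
        raise ValueError("growth rate needs a trajectory of length >= 2")
    n0, nt = float(tr.n[0]), float(tr.n[-1])
    if n0 <= 0:
        raise ValueError("growth rate undefined for N_0 = 0")
    if nt == 0:
        return -1.0
    return float((nt / n0) ** (1.0 / tr.horizon) - 1.0)
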