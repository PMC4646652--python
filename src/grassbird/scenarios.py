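"""Policy scenarios and consequence tables.

This module wires the chain together: a policy alternative shifts a landowner
type's objective weights, the choice model turns those weights into a land
cover distribution, five landscapes (one breeding, three stopover, one
wintering) are drawn from that distribution, and the annual-cycle bird model
returns the mean annual population growth rate.  Repeating this over
replicates for all 7 policies x 3 landowner types yields the consequence
table used to compare alternatives.

Because the exact utility and demographic values behind the reference
consequence table are not published, the module also provides a bounded
derivative-free calibration that searches the parameter box for values whose
consequence table best matches a target (Chebyshev / max-abs-cell-error
objective, with sign agreement as a hard requirement).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd
from scipy import optimize

from ._seeds import derive_seed
from .abm import (
    ChoiceModel,
    LandownerType,
    PolicyAlternative,
    PreferenceWeights,
    UtilityMatrix,
    apply_policy,
    choice_probabilities,
    normalize_weights,
)
from .birds import DemographicParams, Trajectory, growth_rate, simulate_annual_cycle
from .config import RunConfig
from .landscape import CoverDistribution, Landscape, LandscapeRole, generate_landscape

__all__ = [
    "Scenario",
    "ConsequenceTable",
    "CalibrationResult",
    "build_scenario",
    "simulate_scenario",
    "run_consequence_table",
    "rank_policies",
    "calibrate_defaults",
    "grassland_response_curve",
    "reference_growth_table",
    "DEFAULT_CALIBRATION_BOUNDS",
]

_POLICIES = tuple(PolicyAlternative)
_LANDOWNERS = tuple(LandownerType)

#: role layout of the five landscapes of a scenario
_ROLE_SLOTS = (
    LandscapeRole.BREEDING,
    LandscapeRole.STOPOVER,
    LandscapeRole.STOPOVER,
    LandscapeRole.STOPOVER,
    LandscapeRole.WINTERING,
)


@dataclass
class Scenario:
    """One fully specified simulation: who owns the land, under which policy."""

    landowner: LandownerType
    policy: PolicyAlternative
    landscapes: list[Landscape]
    params: DemographicParams
    utility: UtilityMatrix
    choice: ChoiceModel
    cover_distribution: CoverDistribution
    n0: float = 100.0
    horizon: int = 30
    seed: int = 0
    stochastic: bool = False

    def __post_init__(self) -> None:
        roles = [ls.role for ls in self.landscapes]
        if roles != list(_ROLE_SLOTS):
            raise ValueError(
                "scenario requires 5 landscapes with roles "
                "[breeding, stopover x3, wintering]; got "
                f"{[r.value for r in roles]}"
            )

    @property
    def breeding(self) -> Landscape:
        return self.landscapes[0]

    @property
    def stopovers(self) -> list[Landscape]:
        return self.landscapes[1:4]

    @property
    def wintering(self) -> Landscape:
        return self.landscapes[4]


def _weights_for(cfg: RunConfig, lt: LandownerType, policy: PolicyAlternative) -> PreferenceWeights:
    override = cfg.weights_override.get(lt.value, {}).get(policy.value)
    return override if override is not None else apply_policy(lt, policy)


def policy_cover_distribution(
    cfg: RunConfig, lt: LandownerType, policy: PolicyAlternative
) -> CoverDistribution:
    """The land-cover distribution a landowner type adopts under a policy."""
    w = normalize_weights(_weights_for(cfg, lt, policy))
    return choice_probabilities(w, cfg.utility, cfg.choice)


def build_scenario(
    lt: LandownerType,
    policy: PolicyAlternative,
    cfg: RunConfig,
    seed: int,
) -> Scenario:
    """Generate the five role-assigned landscapes for one (landowner, policy).

    All five landscapes are drawn from the same policy-conditioned cover
    distribution, each with its own role-slot sub-seed, so the scenario is a
    pure function of (cfg, lt, policy, seed).
    """
    dist = policy_cover_distribution(cfg, lt, policy)
    landscapes = [
        generate_landscape(
            dist,
            n_rows=cfg.n_rows,
            n_cols=cfg.n_cols,
            role=role,
            seed=derive_seed(seed, slot),
            pixel_size_m=cfg.pixel_size_m,
            label=f"{lt.value}/{policy.value}/slot{slot}",
        )
        for slot, role in enumerate(_ROLE_SLOTS)
    ]
    return Scenario(
        landowner=lt,
        policy=policy,
        landscapes=landscapes,
        params=cfg.demography,
        utility=cfg.utility,
        choice=cfg.choice,
        cover_distribution=dist,
        n0=cfg.n0,
        horizon=cfg.horizon,
        seed=seed,
        stochastic=cfg.stochastic,
    )


def simulate_scenario(scen: Scenario) -> Trajectory:
    """Run the annual-cycle population model for one scenario."""
    return simulate_annual_cycle(
        scen.breeding,
        scen.stopovers,
        scen.wintering,
        scen.params,
        n0=scen.n0,
        horizon=scen.horizon,
        seed=derive_seed(scen.seed, 99),
        stochastic=scen.stochastic,
    )


@dataclass
class ConsequenceTable:
    """Policy x landowner matrix of mean annual growth rates.

    ``mean`` and ``se`` are DataFrames with policies as rows (canonical
    order) and landowner types as columns; ``n`` is the replicate count.
    """

    mean: pd.DataFrame
    se: pd.DataFrame
    n: int

    def cell(self, policy: PolicyAlternative, lt: LandownerType) -> float:
        return float(self.mean.loc[policy.value, lt.value])

    def to_csv(self, mean_path: Union[str, Path], se_path: Union[str, Path]) -> None:
        """Write mean and SE tables as CSV with bit-stable ordering."""
        self.mean.to_csv(mean_path, float_format="%.10g", lineterminator="\n")
        self.se.to_csv(se_path, float_format="%.10g", lineterminator="\n")


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(
        index=pd.Index([p.value for p in _POLICIES], name="policy"),
        columns=[t.value for t in _LANDOWNERS],
        dtype=float,
    )


def _replicate_growth(
    cfg: RunConfig, lt: LandownerType, policy: PolicyAlternative, rep_seed: int
) -> float:
    scen = build_scenario(lt, policy, cfg, rep_seed)
    return growth_rate(simulate_scenario(scen))


def run_consequence_table(
    cfg: RunConfig, replicates: int = 100, base_seed: int = 0
) -> ConsequenceTable:
    """Replicate means and standard errors for all 21 (policy, landowner) cells.

    Each replicate's seed is derived from (base_seed, cell index, replicate
    index), so the table is a pure function of its arguments and adding
    replicates never perturbs earlier ones.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    mean, se = _empty_table(), _empty_table()
    for pi, policy in enumerate(_POLICIES):
        for li, lt in enumerate(_LANDOWNERS):
            cell = pi * len(_LANDOWNERS) + li
            rates = np.array(
                [
                    _replicate_growth(cfg, lt, policy, derive_seed(base_seed, cell, r))
                    for r in range(replicates)
                ]
            )
            mean.loc[policy.value, lt.value] = rates.mean()
            se.loc[policy.value, lt.value] = (
                rates.std(ddof=1) / np.sqrt(replicates) if replicates > 1 else 0.0
            )
    return ConsequenceTable(mean=mean, se=se, n=replicates)


def rank_policies(
    tbl: ConsequenceTable, lt: LandownerType
) -> list[PolicyAlternative]:
    """Policies sorted by descending mean growth rate for one landowner type.

    Ties are broken by canonical policy order (the order of the
    :class:`PolicyAlternative` enumeration).
    """
    col = tbl.mean[lt.value]
    if col.isna().any():
        raise ValueError("consequence table has missing cells")
    return sorted(
        _POLICIES, key=lambda p: (-float(col[p.value]), _POLICIES.index(p))
    )


def reference_growth_table() -> pd.DataFrame:
    """The packaged reference consequence table (policy rows, landowner cols)."""
    with resources.files("grassbird.data").joinpath("reference_growth.csv").open() as fh:
        return pd.read_csv(fh).set_index("policy")


# ---------------------------------------------------------------------------
# calibration

#: parameters searched by default: the full utility matrix and the softmax
#: temperature.  Demographic parameters can be added by key.
DEFAULT_CALIBRATION_BOUNDS: dict[str, tuple[float, float]] = {
    **{
        f"utility.{cover}.{obj}": (0.0, 1.0)
        for cover in ("grassland", "agriculture", "forest")
        for obj in (
            "birds",
            "carbon",
            "water_quality",
            "financial_profit",
            "biodiversity",
        )
    },
    "choice.temperature": (0.02, 0.60),
}


def _set_dotted(d: dict, dotted: str, value: float) -> None:
    keys = dotted.split(".")
    node = d
    for k in keys[:-1]:
        node = node[k]
    node[keys[-1]] = float(value)


def _get_dotted(d: Mapping, dotted: str) -> float:
    node = d
    for k in dotted.split("."):
        node = node[k]
    return float(node)


@dataclass
class CalibrationResult:
    """Outcome of a consequence-table calibration."""

    config: RunConfig
    params: DemographicParams
    utility: UtilityMatrix
    choice: ChoiceModel
    table: ConsequenceTable
    max_abs_error: float
    signs_ok: bool
    within_tolerance: bool
    n_evaluations: int

    @property
    def success(self) -> bool:
        """Sign agreement is the hard requirement for a usable calibration."""
        return self.signs_ok


def _table_error(tbl: ConsequenceTable, target: pd.DataFrame) -> tuple[float, int]:
    """(max abs cell error, number of sign mismatches) vs the target table."""
    err = 0.0
    mismatches = 0
    for policy in _POLICIES:
        for lt in _LANDOWNERS:
            t = float(target.loc[policy.value, lt.value])
            v = tbl.cell(policy, lt)
            err = max(err, abs(v - t))
            if t != 0.0 and np.sign(v) != np.sign(t):
                mismatches += 1
    return err, mismatches


def calibrate_defaults(
    target: Union[pd.DataFrame, ConsequenceTable],
    cfg: Optional[RunConfig] = None,
    bounds: Optional[Mapping[str, tuple[float, float]]] = None,
    tolerance: float = 0.005,
    budget: int = 200,
    seed: int = 0,
    replicates: int = 16,
) -> CalibrationResult:
    """Search a bounded parameter box for a consequence table matching a target.

    Minimizes the Chebyshev (max absolute cell) error of the 21-cell table
    against ``target``, with sign mismatches added as a large penalty so no
    cell's direction is sacrificed for another's magnitude.  The search is
    Powell's derivative-free method within the box, started from the current
    configuration values and capped at ``budget`` objective evaluations;
    the objective uses common random numbers (a fixed seed shared by every
    evaluation) so it is deterministic.

    ``budget=0`` evaluates the starting configuration without searching.
    A result whose table disagrees with the target's signs is reported as a
    failed calibration (``success=False``), never silently accepted.
    """
    if isinstance(target, ConsequenceTable):
        target = target.mean
    if not np.isfinite(target.to_numpy(dtype=float)).all():
        raise ValueError("calibration target must be finite in every cell")
    cfg = cfg if cfg is not None else RunConfig.from_dict({})
    bounds = dict(bounds) if bounds is not None else dict(DEFAULT_CALIBRATION_BOUNDS)
    if budget < 0:
        raise ValueError("calibration budget must be >= 0")
    for key, (lo, hi) in bounds.items():
        if not lo < hi:
            raise ValueError(f"infeasible bounds for {key}: ({lo}, {hi})")

    base = cfg.to_dict()
    keys = sorted(bounds)
    x0 = np.array([np.clip(_get_dotted(base, k), *bounds[k]) for k in keys])
    table_seed = derive_seed(seed, 17)
    evals = {"n": 0}

    def build(x: np.ndarray) -> RunConfig:
        d = cfg.to_dict()
        for k, v in zip(keys, x):
            _set_dotted(d, k, float(np.clip(v, *bounds[k])))
        return RunConfig.from_dict(d)

    def objective(x: np.ndarray) -> float:
        evals["n"] += 1
        tbl = run_consequence_table(build(x), replicates=replicates, base_seed=table_seed)
        err, mismatches = _table_error(tbl, target)
        return err + 1.0 * mismatches

    x_best = x0
    if budget > 0:
        res = optimize.minimize(
            objective,
            x0,
            method="Powell",
            bounds=[bounds[k] for k in keys],
            options={"maxfev": budget, "xtol": 1e-3, "ftol": 1e-5},
        )
        x_best = np.clip(res.x, [bounds[k][0] for k in keys], [bounds[k][1] for k in keys])
        # keep the starting point if the search somehow ended worse
        if objective(x_best) > objective(x0):
            x_best = x0

    best_cfg = build(x_best)
    final = run_consequence_table(best_cfg, replicates=replicates, base_seed=table_seed)
    err, mismatches = _table_error(final, target)
    return CalibrationResult(
        config=best_cfg,
        params=best_cfg.demography,
        utility=best_cfg.utility,
        choice=best_cfg.choice,
        table=final,
        max_abs_error=err,
        signs_ok=mismatches == 0,
        within_tolerance=err <= tolerance,
        n_evaluations=evals["n"],
    )


def grassland_response_curve(
    cfg: RunConfig,
    steps: int = 11,
    replicates: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean growth rate as a function of forced grassland proportion.

    Sweeps the grassland share of every landscape from 0 to 1 in ``steps``
    even increments; the remaining cover mass is split between agriculture
    and forest according to ``cfg.curve_agriculture_share``.  Returns a
    DataFrame with columns (grassland_proportion, mean_growth_rate, se).
    """
    if steps < 2:
        raise ValueError("steps must be >= 2")
    rows = []
    for si, p_grass in enumerate(np.linspace(0.0, 1.0, steps)):
        rest = 1.0 - p_grass
        dist = CoverDistribution(
            p_grassland=float(p_grass),
            p_agriculture=float(rest * cfg.curve_agriculture_share),
            p_forest=float(rest * (1.0 - cfg.curve_agriculture_share)),
        )
        rates = []
        for r in range(replicates):
            rep_seed = derive_seed(seed, 1000 + si, r)
            landscapes = [
                generate_landscape(
                    dist,
                    n_rows=cfg.n_rows,
                    n_cols=cfg.n_cols,
                    role=role,
                    seed=derive_seed(rep_seed, slot),
                    pixel_size_m=cfg.pixel_size_m,
                )
                for slot, role in enumerate(_ROLE_SLOTS)
            ]
            tr = simulate_annual_cycle(
                landscapes[0],
                landscapes[1:4],
                landscapes[4],
                cfg.demography,
                n0=cfg.n0,
                horizon=cfg.horizon,
                seed=derive_seed(rep_seed, 99),
                stochastic=cfg.stochastic,
            )
            rates.append(growth_rate(tr))
        rates = np.array(rates)
        rows.append(
            {
                "grassland_proportion": float(p_grass),
                "mean_growth_rate": float(rates.mean()),
                "se": float(rates.std(ddof=1) / np.sqrt(len(rates)))
                if len(rates) > 1
                else 0.0,
            }
        )
    return pd.DataFrame(rows)
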