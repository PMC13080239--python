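"""Metabolic capacity readouts computed on per-sample model instances.

Implements the three readouts used throughout the analysis:

* substrate-utilization capacity: the maximal steady-state uptake flux of one
  substrate class as its plasma concentration is titrated supraphysiologically
  with all other plasma metabolites fixed and a saturating ancillary ATP
  demand applied;
* ATP production capacity: the plateau ATP production rate under a stepwise
  increased hyperbolic ATP demand ``v_ATP = load * ATP / (ATP + Km)``,
  together with the ATP/O2 ratio and per-substrate ATP-equivalent
  contributions along the load ramp;
* whole-heart scaling of per-gram capacities by cardiac mass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .network import (
    NetworkModel,
    SteadyState,
    o2_consumption,
    solve_steady_state,
    total_atp_production,
)

logger = logging.getLogger(__name__)

SUBSTRATE_CLASSES = ("glucose", "ffa", "lactate", "ketones", "bcaa")


@dataclass(frozen=True)
class PlasmaProfile:
    """Boundary plasma concentrations (mM) plus hormone levels.

    The two built-ins (:data:`FASTED`, :data:`POSTPRANDIAL`) are the
    physiological evaluation states: overnight fasted (high fatty acids, low
    glucose, insulin 100 pM) and postprandial (high glucose and lactate, low
    fatty acids, no ketones, insulin 600 pM).
    """

    glucose: float
    fatty_acids: float
    lactate: float
    valine: float
    leucine: float
    isoleucine: float
    bhb: float
    acac: float
    insulin: float  # pM
    catecholamines: float = 0.75  # nM
    label: str = ""

    def __post_init__(self) -> None:
        for f in (
            "glucose",
            "fatty_acids",
            "lactate",
            "valine",
            "leucine",
            "isoleucine",
            "bhb",
            "acac",
            "insulin",
            "catecholamines",
        ):
            if getattr(self, f) < 0:
                raise ValueError(f"plasma profile field {f} must be >= 0")

    def boundary_map(self) -> dict[str, float]:
        """Map to the model's plasma metabolite ids."""
        return {
            "glc_p": self.glucose,
            "nefa": self.fatty_acids,
            "lac": self.lactate,
            "val": self.valine,
            "leu": self.leucine,
            "ile": self.isoleucine,
            "bhb": self.bhb,
            "acac": self.acac,
        }

    def with_boundary(self, **species: float) -> "PlasmaProfile":
        inverse = {
            "glc_p": "glucose",
            "nefa": "fatty_acids",
            "lac": "lactate",
            "val": "valine",
            "leu": "leucine",
            "ile": "isoleucine",
            "bhb": "bhb",
            "acac": "acac",
        }
        return replace(self, **{inverse[k]: v for k, v in species.items()})


FASTED = PlasmaProfile(
    glucose=5.8,
    fatty_acids=0.5,
    lactate=0.8,
    valine=0.2,
    leucine=0.15,
    isoleucine=0.06,
    bhb=0.08,
    acac=0.04,
    insulin=100.0,
    catecholamines=0.75,
    label="fasted",
)

POSTPRANDIAL = PlasmaProfile(
    glucose=7.8,
    fatty_acids=0.1,
    lactate=2.0,
    valine=0.4,
    leucine=0.4,
    isoleucine=0.2,
    bhb=0.0,
    acac=0.0,
    insulin=600.0,
    catecholamines=0.75,
    label="postprandial",
)

BUILTIN_PROFILES = {"fasted": FASTED, "postprandial": POSTPRANDIAL}


@dataclass
class RampConfig:
    """Stepwise load-ramp settings (loads in mM ATP/min/g)."""

    initial_load: float | None = None  # default: 10% of the model's resting demand
    step: float = 1.25
    max_steps: int = 60
    plateau_rtol: float = 1e-3

    def grid_start(self, model: NetworkModel) -> float:
        if self.initial_load is not None:
            return self.initial_load
        return 0.1 * model.resting_demand


@dataclass
class LoadScanResult:
    loads: np.ndarray  # multiples of resting demand
    atp_production: np.ndarray  # mM/min/g
    o2_consumption: np.ndarray
    contributions: list[dict[str, float]]  # ATP-equivalent rate per class
    max_atp: float
    atp_o2_at_max: float
    converged_at: float  # load (multiples of resting) where the plateau was hit

    def shares(self) -> list[dict[str, float]]:
        out = []
        for total, contrib in zip(self.atp_production, self.contributions):
            if total > 0:
                out.append({k: v / total for k, v in contrib.items()})
            else:
                out.append({k: 0.0 for k in contrib})
        return out

    def mean_share(self, substrate: str) -> float:
        """Share of one substrate class averaged over ramp points with
        positive total production."""
        vals = [s[substrate] for s, p in zip(self.shares(), self.atp_production) if p > 0]
        return float(np.mean(vals)) if vals else 0.0

    def share_at_max(self, substrate: str) -> float:
        if len(self.atp_production) == 0 or self.atp_production[-1] <= 0:
            return 0.0
        i = int(np.argmax(self.atp_production))
        return self.contributions[i][substrate] / self.atp_production[i]


def substrate_contributions(
    state: SteadyState, model: NetworkModel
) -> dict[str, float]:
    """ATP-equivalent production rate attributed to each substrate class.

    Each class contributes its net uptake flux times the network's own
    stoichiometric ATP yield; because the yield modes span the steady-state
    flux space, the contributions sum exactly to total net ATP production
    (glycolytic and oxidative glucose ATP are both attributed to glucose, and
    lactate efflux shows up as a negative lactate contribution).
    """
    out: dict[str, float] = {}
    for name, cls in model.substrate_classes.items():
        total = 0.0
        for species, rxn in zip(cls.species, cls.reactions):
            coef = -model.reaction(rxn).stoichiometry.get(species, -1.0)
            uptake = state.flux[rxn] * coef
            total += uptake * model.atp_yield[species]
        out[name] = total
    return out


def atp_load_scan(
    instance,
    profile: PlasmaProfile,
    ramp: RampConfig | None = None,
) -> LoadScanResult:
    """Stepwise increase the ATP demand until production plateaus.

    `instance` is a :class:`~myoflux.instantiate.SampleInstance` or a bare
    :class:`NetworkModel`.  The load is raised multiplicatively from 10% of
    resting demand; the scan stops when the relative production gain over one
    step drops below the plateau tolerance (or on non-convergence, in which
    case the previous plateau is reported).  ``max_atp`` is confirmed with one
    far-saturating solve beyond the stopping load.
    """
    model = getattr(instance, "model", instance)
    ramp = ramp or RampConfig()
    load = ramp.grid_start(model)
    if load < 0 or ramp.step <= 1 or ramp.max_steps < 1:
        raise ValueError("ramp needs nonnegative initial load, step > 1, max steps >= 1")

    loads: list[float] = []
    prod: list[float] = []
    o2: list[float] = []
    contribs: list[dict[str, float]] = []
    x_prev = None
    last_state = None
    for step in range(ramp.max_steps):
        state = solve_steady_state(model, profile, load=load, x0=x_prev)
        if not state.converged:
            if step == 0:
                raise RuntimeError(
                    f"load ramp failed at the first load {load:g}: model/profile incompatible"
                )
            logger.warning("ramp stopped at load %.4g: non-convergence", load)
            break
        x_prev = state.conc_vector(model)
        p = total_atp_production(model, state)
        if prod and p < prod[-1] - 1e-9:
            # past the plateau: do not record the declining point
            break
        loads.append(load)
        prod.append(p)
        o2.append(o2_consumption(model, state))
        contribs.append(substrate_contributions(state, model))
        last_state = state
        if (
            len(prod) >= 2
            and prod[-2] > 0
            and (prod[-1] - prod[-2]) < ramp.plateau_rtol * prod[-2]
        ):
            break
        load = load * ramp.step if load > 0 else 0.1 * (model.resting_demand or 1.0)
    # confirm the plateau far up the demand curve
    max_atp = max(prod) if prod else 0.0
    atp_o2 = float("nan")
    if last_state is not None and loads:
        confirm = solve_steady_state(model, profile, load=loads[-1] * 20.0, x0=x_prev)
        if confirm.converged:
            p_c = total_atp_production(model, confirm)
            if p_c >= max_atp:
                max_atp = p_c
                o2_c = o2_consumption(model, confirm)
                atp_o2 = max_atp / o2_c if o2_c > 0 else float("nan")
        if not np.isfinite(atp_o2):
            i = int(np.argmax(prod))
            atp_o2 = prod[i] / o2[i] if o2[i] > 0 else float("nan")
    resting = model.resting_demand or 1.0
    return LoadScanResult(
        loads=np.array(loads) / resting,
        atp_production=np.array(prod),
        o2_consumption=np.array(o2),
        contributions=contribs,
        max_atp=float(max_atp),
        atp_o2_at_max=float(atp_o2),
        converged_at=float(loads[-1] / resting) if loads else float("nan"),
    )


@dataclass
class TitrationConfig:
    n_points: int = 12
    fold: float = 50.0  # titrate to fold x base concentration
    zero_base_max: float = 10.0  # mM grid ceiling when the base level is 0
    demand_multiple: float = 10.0  # ancillary ATP demand, multiples of resting
    plateau_rtol: float = 1e-3


def substrate_capacity(
    instance,
    substrate: str,
    base: PlasmaProfile,
    titration: TitrationConfig | None = None,
) -> float:
    """Maximal steady-state uptake flux of one substrate class (mM/min/g).

    The class's plasma species are raised jointly (ketone bodies at a fixed
    2:1 bhb:acac ratio, BCAAs at the base profile's proportions) over a
    geometric grid up to ``fold`` times the base level while all other plasma
    metabolites stay fixed; a high ancillary ATP demand keeps uptake from
    being demand-limited.
    """
    model = getattr(instance, "model", instance)
    titration = titration or TitrationConfig()
    if substrate not in model.substrate_classes:
        raise ValueError(
            f"unknown substrate class {substrate!r}; expected one of {SUBSTRATE_CLASSES}"
        )
    cls = model.substrate_classes[substrate]
    base_map = base.boundary_map()
    base_levels = np.array([base_map[s] for s in cls.species], float)
    base_total = float(base_levels.sum())
    if base_total > 0:
        fractions = base_levels / base_total
        grid = np.geomspace(base_total, titration.fold * base_total, titration.n_points)
    else:
        # no physiological anchor (e.g. postprandial ketones): default ratios
        if substrate == "ketones":
            fractions = np.array([2.0, 1.0]) / 3.0
        else:
            fractions = np.full(len(cls.species), 1.0 / len(cls.species))
        grid = np.linspace(0.0, titration.zero_base_max, titration.n_points)

    demand = titration.demand_multiple * model.resting_demand
    best = 0.0
    x_prev = None
    prev = None
    n_fail = 0
    for level in grid:
        prof = base.with_boundary(
            **{s: float(level * f) for s, f in zip(cls.species, fractions)}
        )
        state = solve_steady_state(model, prof, load=demand, x0=x_prev)
        if not state.converged:
            logger.warning(
                "titration of %s skipped grid point %.3g mM: non-convergence",
                substrate,
                level,
            )
            n_fail += 1
            continue
        x_prev = state.conc_vector(model)
        uptake = 0.0
        for species, rxn in zip(cls.species, cls.reactions):
            coef = -model.reaction(rxn).stoichiometry.get(species, -1.0)
            uptake += state.flux[rxn] * coef
        best = max(best, uptake)
        if (
            prev is not None
            and prev > 0
            and (uptake - prev) < titration.plateau_rtol * prev
        ):
            prev = uptake
            break
        prev = uptake
    if n_fail == len(grid):
        raise RuntimeError(f"titration of {substrate} failed at every grid point")
    return float(best)


def whole_heart_capacity(per_gram: float, heart_mass_mg: float) -> float:
    """Scale a per-gram capacity to the whole heart (mM/min per heart)."""
    if heart_mass_mg <= 0:
        raise ValueError("heart mass must be > 0 mg")
    return per_gram * heart_mass_mg / 1000.0


# individualized plasma profiles -------------------------------------------

#: plasma panel fields the model can use, mapped to profile fields
_PANEL_FIELDS = {
    "glucose": "glucose",
    "nefa": "fatty_acids",
    "lactate": "lactate",
    "bhb": "bhb",
    "acac": "acac",
    "valine": "valine",
    "leucine": "leucine",
    "isoleucine": "isoleucine",
}
#: measured panel fields with no model substrate (ignored, logged)
_PANEL_IGNORED = ("tg",)


def merge_profile(
    panel: Mapping[str, float], defaults: PlasmaProfile, label: str | None = None
) -> PlasmaProfile:
    """Overlay a per-sample measured plasma panel onto a default profile.

    Missing or NaN fields fall back to the default; plasma triglycerides have
    no model substrate and are ignored.  Every merge decision is logged.
    """
    updates: dict[str, float] = {}
    for key, value in panel.items():
        if value is None or (isinstance(value, float) and np.isnan(value)):
            continue
        if key in _PANEL_IGNORED:
            logger.info("panel field %s ignored: no model substrate", key)
            continue
        if key not in _PANEL_FIELDS:
            logger.warning("panel field %s unknown: ignored", key)
            continue
        if value < 0:
            raise ValueError(f"panel field {key} is negative ({value})")
        updates[_PANEL_FIELDS[key]] = float(value)
        logger.info("panel field %s -> %.4g mM (replaces default)", key, value)
    for field_name in _PANEL_FIELDS.values():
        if field_name not in updates:
            logger.info(
                "panel field %s missing: default %.4g used",
                field_name,
                getattr(defaults, field_name),
            )
    if not updates:
        logger.warning("empty plasma panel: defaults used throughout")
    return replace(defaults, label=label or f"{defaults.label}-individualized", **updates)


def individualized_scan(
    instance,
    plasma_panel: Mapping[str, float],
    defaults: PlasmaProfile,
    ramp: RampConfig | None = None,
) -> LoadScanResult:
    """ATP load scan under a per-sample measured plasma profile."""
    return atp_load_scan(instance, merge_profile(plasma_panel, defaults), ramp)


@dataclass
class CapacityPanel:
    """All capacity readouts for one sample."""

    sample_id: str
    substrate_capacity: dict[str, float]  # per class, mM/min/g
    max_atp: dict[str, float]  # per condition label
    atp_o2: dict[str, float]
    whole_heart_max_atp: float = float("nan")


def compute_capacity_panel(
    instance,
    heart_mass_mg: float | None = None,
    profiles: Mapping[str, PlasmaProfile] | None = None,
    plasma_panel: Mapping[str, float] | None = None,
    titration: TitrationConfig | None = None,
    ramp: RampConfig | None = None,
    substrates: Sequence[str] = SUBSTRATE_CLASSES,
) -> CapacityPanel:
    """Substrate capacities and ATP capacities for one sample instance."""
    profiles = dict(profiles or BUILTIN_PROFILES)
    sample_id = getattr(instance, "sample_id", "reference")
    caps = {
        s: substrate_capacity(instance, s, profiles.get("fasted", FASTED), titration)
        for s in substrates
    }
    max_atp: dict[str, float] = {}
    atp_o2: dict[str, float] = {}
    for label, prof in profiles.items():
        scan = atp_load_scan(instance, prof, ramp)
        max_atp[label] = scan.max_atp
        atp_o2[label] = scan.atp_o2_at_max
    if plasma_panel is not None:
        scan = individualized_scan(
            instance, plasma_panel, profiles.get("fasted", FASTED), ramp
        )
        max_atp["individualized"] = scan.max_atp
        atp_o2["individualized"] = scan.atp_o2_at_max
    wh = float("nan")
    if heart_mass_mg is not None:
        wh = whole_heart_capacity(max_atp.get("fasted", float("nan")), heart_mass_mg)
    return CapacityPanel(
        sample_id=sample_id,
        substrate_capacity=caps,
        max_atp=max_atp,
        atp_o2=atp_o2,
        whole_heart_max_atp=wh,
    )
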