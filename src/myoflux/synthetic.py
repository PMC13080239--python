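"""Synthetic three-group mouse cohorts with planted ground truth.

Generates protein abundance matrices, sample metadata (masses and
echocardiographic parameters), and per-sample plasma panels with the
statistical structure the analysis pipeline assumes: a control group, a
diet-stressed group with down-regulated mitochondrial energy production, and
a genetically obese group with up-regulated fatty-acid handling and
collagen/inflammation together with shifted plasma metabolites.  Every draw
is reproducible from the seed, and the planted truth (regulated proteins,
pathway scales, causal markers) is returned alongside the data so recovery
tests can score themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .instantiate import ProteinAbundanceMatrix
from .network import NetworkModel, load_default_model

GROUPS = ("control", "diet", "obese")

#: capacity class -> model pathway tags that limit it
CAPACITY_PATHWAYS = {
    "glucose": ("glycolysis",),
    "ffa": ("fao",),
    "lactate": ("lactate-exchange",),
    "ketones": ("ketolysis",),
    "bcaa": ("bcaa",),
    "atp": ("oxphos", "tca"),
}


class ConfigError(ValueError):
    """Invalid cohort configuration (unknown protein set, bad sizes...)."""


@dataclass
class CohortConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults mirror the three-group design: control n=4, diet-stressed n=5,
    genetically obese n=5; 2470 proteins of which ~300 are metabolic;
    log-normal intensity noise with sd 0.25 on the log2 scale; regulated
    fractions among metabolic proteins of 7.4% up / 34.6% down (diet) and
    10.7% up / 22.8% down (obese) planted at fold changes 2.0 / 0.5.
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"control": 4, "diet": 5, "obese": 5}
    )
    n_proteins: int = 2470
    n_metabolic: int = 300
    noise_sd_log2: float = 0.25
    fold_up: float = 2.0
    fold_down: float = 0.5
    # fraction of metabolic proteins regulated per group (up, down)
    metabolic_fractions: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"diet": (0.074, 0.346), "obese": (0.107, 0.228)}
    )
    # fraction of the remaining (non-metabolic) proteome regulated per group,
    # chosen so whole-proteome fractions approximate the printed 3.2/12.5%
    # (diet) and 6.5/7% (obese)
    other_fractions: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"diet": (0.026, 0.094), "obese": (0.059, 0.041)}
    )
    # extra named-set plans: group -> list of (set name, fold)
    extra_plan: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    missing_rate: float = 0.0
    # plasma panel group multipliers (relative to control means)
    plasma_shift: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "obese": {"tg": 2.0, "leucine": 1.5, "isoleucine": 1.5, "bhb": 0.5}
        }
    )
    body_weight_g: dict[str, float] = field(
        default_factory=lambda: {"control": 30.0, "diet": 38.0, "obese": 55.0}
    )
    heart_weight_mg: dict[str, float] = field(
        default_factory=lambda: {"control": 150.0, "diet": 135.0, "obese": 210.0}
    )
    mass_cv: float = 0.05
    echo_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.n_per_group.items():
            if n < 3:
                raise ConfigError(f"group {g}: n >= 3 required, got {n}")
        if self.fold_up <= 0 or self.fold_down <= 0:
            raise ConfigError("fold changes must be > 0")
        if self.n_metabolic > self.n_proteins:
            raise ConfigError("n_metabolic cannot exceed n_proteins")

    @classmethod
    def tiny(cls, seed: int = 0, **kw) -> "CohortConfig":
        """Small, fast cohort for tests and the tiny CLI preset."""
        return cls(
            n_per_group={"control": 3, "diet": 3, "obese": 3},
            n_proteins=130,
            n_metabolic=60,
            seed=seed,
            **kw,
        )

    def null(self) -> "CohortConfig":
        """Same cohort structure with every group effect removed."""
        return replace(
            self,
            metabolic_fractions={g: (0.0, 0.0) for g in self.metabolic_fractions},
            other_fractions={g: (0.0, 0.0) for g in self.other_fractions},
            extra_plan={},
            plasma_shift={},
            body_weight_g={g: self.body_weight_g["control"] for g in self.body_weight_g},
            heart_weight_mg={
                g: self.heart_weight_mg["control"] for g in self.heart_weight_mg
            },
        )


@dataclass
class GroundTruth:
    regulated: dict[str, dict[str, float]]  # group -> protein -> fold
    pathway_scales: pd.DataFrame  # samples x pathway tags (planted group fold)
    markers: dict[str, list[str]]  # capacity class -> causal protein ids
    protein_sets: dict[str, list[str]]


@dataclass
class SyntheticCohort:
    matrix: ProteinAbundanceMatrix
    metadata: pd.DataFrame  # index sample: group, masses, echo
    plasma: pd.DataFrame  # index sample: per-sample plasma panel (mM; tg in mM)
    truth: GroundTruth
    config: CohortConfig


#: control-group plasma panel means (mM), fasted-state anchored
PLASMA_MEANS = {
    "glucose": 5.8,
    "tg": 1.0,
    "nefa": 0.5,
    "lactate": 0.8,
    "bhb": 0.08,
    "valine": 0.2,
    "leucine": 0.15,
    "isoleucine": 0.06,
}
PLASMA_CV = 0.12


def _protein_universe(model: NetworkModel, cfg: CohortConfig) -> dict[str, list[str]]:
    """Named protein sets; model-mapped enzymes first among the metabolic."""
    sets: dict[str, list[str]] = {}
    by_pathway: dict[str, list[str]] = {}
    mapped: list[str] = []
    for r in model.reactions:
        for p in r.proteins:
            if p not in mapped:
                mapped.append(p)
            by_pathway.setdefault(r.pathway, [])
            if p not in by_pathway[r.pathway]:
                by_pathway[r.pathway].append(p)
    n_fill = max(cfg.n_metabolic - len(mapped), 0)
    metabolic = mapped + [f"MET{i:04d}" for i in range(n_fill)]
    collagen = [f"COL{i:03d}" for i in range(15)]
    inflammation = [f"INFL{i:03d}" for i in range(25)]
    n_other = cfg.n_proteins - len(metabolic) - len(collagen) - len(inflammation)
    if n_other < 0:
        raise ConfigError("n_proteins too small for the structural protein sets")
    other = [f"PROT{i:04d}" for i in range(n_other)]
    sets["metabolic"] = metabolic
    sets["mapped"] = mapped
    sets["collagen"] = collagen
    sets["inflammation"] = inflammation
    sets["other"] = other
    for tag, prots in by_pathway.items():
        sets[f"pathway:{tag}"] = prots
    return sets


def _default_plan(
    cfg: CohortConfig, sets: dict[str, list[str]], rng: np.random.Generator
) -> dict[str, dict[str, float]]:
    """Planted fold change per protein per group."""
    plan: dict[str, dict[str, float]] = {g: {} for g in cfg.n_per_group}

    def plant(group: str, proteins: list[str], fold: float) -> None:
        for p in proteins:
            plan[group].setdefault(p, fold)

    # diet group: mitochondrial energy production down
    if "diet" in plan and cfg.metabolic_fractions.get("diet", (0, 0)) != (0.0, 0.0):
        plant("diet", sets.get("pathway:oxphos", []), cfg.fold_down)
        plant("diet", sets.get("pathway:tca", []), cfg.fold_down)
    # obese group: fatty-acid handling and fibrosis/inflammation up,
    # lactate/ketone/BCAA machinery down
    if "obese" in plan and cfg.metabolic_fractions.get("obese", (0, 0)) != (0.0, 0.0):
        plant("obese", sets.get("pathway:fao", []), cfg.fold_up)
        plant("obese", sets["collagen"], cfg.fold_up)
        plant("obese", sets["inflammation"], cfg.fold_up)
        for tag in ("lactate-exchange", "ketolysis", "bcaa"):
            plant("obese", sets.get(f"pathway:{tag}", []), cfg.fold_down)

    for group, (f_up, f_down) in cfg.metabolic_fractions.items():
        if group not in plan:
            continue
        pool = sets["metabolic"]
        n_up = round(f_up * len(pool))
        n_down = round(f_down * len(pool))
        planted_up = [p for p in pool if plan[group].get(p, 1.0) > 1.0]
        planted_down = [p for p in pool if plan[group].get(p, 1.0) < 1.0]
        free = [p for p in pool if p not in plan[group]]
        free = list(rng.permutation(free))
        for p in free[: max(n_down - len(planted_down), 0)]:
            plan[group][p] = cfg.fold_down
        free = [p for p in free if p not in plan[group]]
        for p in free[: max(n_up - len(planted_up), 0)]:
            plan[group][p] = cfg.fold_up
    for group, (f_up, f_down) in cfg.other_fractions.items():
        if group not in plan:
            continue
        pool = list(rng.permutation(sets["other"]))
        n_up = round(f_up * len(pool))
        n_down = round(f_down * len(pool))
        for p in pool[:n_down]:
            plan[group][p] = cfg.fold_down
        for p in pool[n_down : n_down + n_up]:
            plan[group][p] = cfg.fold_up
    for group, items in cfg.extra_plan.items():
        if group not in plan:
            raise ConfigError(f"extra plan references unknown group {group!r}")
        for set_name, fold in items:
            if set_name not in sets:
                raise ConfigError(f"unknown protein set {set_name!r} in plan")
            for p in sets[set_name]:
                plan[group][p] = fold
    return plan


def generate_cohort(
    config: CohortConfig | None = None, model: NetworkModel | None = None
) -> SyntheticCohort:
    """Draw one cohort: intensities, metadata, plasma panels, ground truth.

    Intensities are ``baseline x group fold x 2^N(0, sd_log2)``; plasma and
    mass/echo values are normal around group means; echocardiographic
    function is linearly coupled to the latent metabolic (OXPHOS) scale with
    an extra fibrosis penalty in the obese group.
    """
    cfg = config or CohortConfig()
    model = model or load_default_model()
    rng = np.random.default_rng(cfg.seed)
    sets = _protein_universe(model, cfg)
    plan = _default_plan(cfg, sets, rng)

    proteins = (
        sets["metabolic"] + sets["collagen"] + sets["inflammation"] + sets["other"]
    )
    samples = [
        f"{g}_{i + 1:02d}" for g in cfg.n_per_group for i in range(cfg.n_per_group[g])
    ]
    groups = {s: s.rsplit("_", 1)[0] for s in samples}

    baseline = pd.Series(
        np.exp(rng.normal(np.log(1e6), 1.2, len(proteins))), index=proteins
    )
    intensity = pd.DataFrame(index=proteins, columns=samples, dtype=float)
    for s in samples:
        g = groups[s]
        fold = np.array([plan[g].get(p, 1.0) for p in proteins])
        noise = (
            np.exp2(rng.normal(0.0, cfg.noise_sd_log2, len(proteins)))
            if cfg.noise_sd_log2 > 0
            else 1.0
        )
        intensity[s] = baseline.to_numpy() * fold * noise
    if cfg.missing_rate > 0:
        holes = rng.random(intensity.shape) < cfg.missing_rate
        intensity = intensity.mask(holes)

    # planted pathway scales (group-level truth)
    tags = sorted({r.pathway for r in model.reactions if r.proteins})
    scale_rows = []
    for s in samples:
        g = groups[s]
        row = {}
        for tag in tags:
            prots = sets.get(f"pathway:{tag}", [])
            row[tag] = (
                float(np.exp(np.mean([np.log(plan[g].get(p, 1.0)) for p in prots])))
                if prots
                else 1.0
            )
        scale_rows.append(row)
    pathway_scales = pd.DataFrame(scale_rows, index=samples)

    # masses
    meta = pd.DataFrame(index=samples)
    meta["group"] = [groups[s] for s in samples]
    for col, means in (
        ("body_weight_g", cfg.body_weight_g),
        ("heart_weight_mg", cfg.heart_weight_mg),
    ):
        mu = np.array([means[groups[s]] for s in samples])
        meta[col] = mu * (1.0 + rng.normal(0.0, cfg.mass_cv, len(samples)))

    # echo parameters: EF coupled to the latent OXPHOS scale, with a
    # fibrosis penalty in the obese group (a toy coupling, not physiology)
    latent = pathway_scales.get("oxphos", pd.Series(1.0, index=samples))
    fibrosis = np.array(
        [max(plan[groups[s]].get(sets["collagen"][0], 1.0) - 1.0, 0.0) for s in samples]
    )
    ef = 35.0 + 25.0 * latent.to_numpy() - 8.0 * fibrosis
    ef = ef + rng.normal(0.0, cfg.echo_noise_sd, len(samples))
    meta["ef_pct"] = np.clip(ef, 5.0, 90.0)
    meta["fs_pct"] = meta["ef_pct"] * 0.5 + rng.normal(0.0, 1.0, len(samples))
    co = 10.0 * latent.to_numpy() + rng.normal(0.0, 0.8, len(samples))
    meta["co_ml_min"] = np.clip(co, 1.0, None)

    # plasma panels
    plasma = pd.DataFrame(index=samples, columns=list(PLASMA_MEANS), dtype=float)
    for s in samples:
        g = groups[s]
        shift = cfg.plasma_shift.get(g, {})
        mu = np.array([PLASMA_MEANS[k] * shift.get(k, 1.0) for k in PLASMA_MEANS])
        plasma.loc[s] = np.clip(
            mu * (1.0 + rng.normal(0.0, PLASMA_CV, len(mu))), 0.0, None
        )

    markers = {
        cap: sorted({p for tag in tags_ for p in sets.get(f"pathway:{tag}", [])})
        for cap, tags_ in CAPACITY_PATHWAYS.items()
    }
    truth = GroundTruth(
        regulated={g: dict(plan[g]) for g in plan if plan[g]},
        pathway_scales=pathway_scales,
        markers=markers,
        protein_sets=sets,
    )
    matrix = ProteinAbundanceMatrix(intensity=intensity, group=groups)
    return SyntheticCohort(
        matrix=matrix, metadata=meta, plasma=plasma, truth=truth, config=cfg
    )


def generate_null(
    config: CohortConfig | None = None, model: NetworkModel | None = None
) -> SyntheticCohort:
    """Cohort with identical structure and no group effects (calibration)."""
    cfg = (config or CohortConfig()).null()
    return generate_cohort(cfg, model)
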