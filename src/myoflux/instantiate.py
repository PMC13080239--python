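"""Per-sample model instantiation from protein abundances.

Each reaction's Vmax is scaled by the ratio of the sample's enzyme abundance
to the control-group reference, aggregated over the reaction's protein set
(geometric mean by default).  Reactions whose proteins were not measured in a
sample keep the reference Vmax (scale 1) -- "not detected" is not treated as
absent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .network import NetworkModel

logger = logging.getLogger(__name__)

AGGREGATIONS = ("geometric-mean", "minimum", "sum")
SCALE_CLIP = (0.01, 100.0)


@dataclass
class ProteinAbundanceMatrix:
    """Wide protein x sample intensity matrix with group labels.

    Intensities are strictly positive where measured; missing values are NaN.
    """

    intensity: pd.DataFrame  # index: protein ids, columns: sample ids
    group: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = self.intensity.index
        cols = self.intensity.columns
        if idx.duplicated().any():
            dupes = sorted(idx[idx.duplicated()].unique())
            raise ValueError(f"duplicate protein ids: {dupes}")
        if cols.duplicated().any():
            dupes = sorted(cols[cols.duplicated()].unique())
            raise ValueError(f"duplicate sample ids: {dupes}")
        vals = self.intensity.to_numpy(float)
        if np.any(vals[~np.isnan(vals)] <= 0):
            raise ValueError("intensities must be strictly positive where present")

    @property
    def proteins(self) -> list[str]:
        return list(self.intensity.index)

    @property
    def samples(self) -> list[str]:
        return list(self.intensity.columns)

    def samples_in_group(self, label: str) -> list[str]:
        return [s for s in self.samples if self.group.get(s) == label]


@dataclass
class EnzymeMapping:
    """reaction-id -> protein ids, with an abundance aggregation rule."""

    reactions: dict[str, list[str]]
    aggregation: str = "geometric-mean"

    def __post_init__(self) -> None:
        if self.aggregation not in AGGREGATIONS:
            raise ValueError(f"aggregation must be one of {AGGREGATIONS}")
        for rid, prots in self.reactions.items():
            for p in prots:
                if not p or not isinstance(p, str) or any(c.isspace() for c in p):
                    raise ValueError(f"mapping for {rid}: invalid protein id {p!r}")

    @classmethod
    def from_model(cls, model: NetworkModel, aggregation: str = "geometric-mean") -> "EnzymeMapping":
        return cls(
            reactions={r.id: list(r.proteins) for r in model.reactions if r.proteins},
            aggregation=aggregation,
        )

    @classmethod
    def from_tsv(cls, path: str | Path, aggregation: str = "geometric-mean") -> "EnzymeMapping":
        df = pd.read_csv(path, sep="\t", comment="#")
        if list(df.columns[:2]) != ["reaction_id", "protein_id"]:
            raise ValueError("mapping TSV needs columns reaction_id, protein_id")
        out: dict[str, list[str]] = {}
        for rid, pid in zip(df["reaction_id"], df["protein_id"]):
            out.setdefault(str(rid), []).append(str(pid))
        return cls(reactions=out, aggregation=aggregation)

    def aggregate(self, values: np.ndarray) -> float:
        if self.aggregation == "geometric-mean":
            return float(np.exp(np.mean(np.log(values))))
        if self.aggregation == "minimum":
            return float(np.min(values))
        return float(np.sum(values))


@dataclass
class SampleInstance:
    """A network model with Vmax values scaled to one sample's proteome."""

    sample_id: str
    model: NetworkModel
    scale: dict[str, float]
    n_missing: int


def reference_abundance(
    matrix: ProteinAbundanceMatrix, control_group: str
) -> tuple[pd.Series, list[str]]:
    """Per-protein mean intensity over the control group.

    Returns the reference series and the list of proteins with no control
    measurement at all (flagged; excluded from scaling downstream).
    """
    controls = matrix.samples_in_group(control_group)
    if not controls:
        raise ValueError(f"control group {control_group!r} has no samples")
    if len(controls) < 2:
        raise ValueError(
            f"control group {control_group!r} needs >= 2 samples, has {len(controls)}"
        )
    ref = matrix.intensity[controls].mean(axis=1, skipna=True)
    flagged = sorted(ref.index[ref.isna()])
    if flagged:
        logger.warning(
            "%d proteins unmeasured in all control samples: excluded from scaling",
            len(flagged),
        )
    return ref, flagged


def _reaction_scale(
    proteins: list[str],
    sample_values: pd.Series,
    reference: pd.Series,
    mapping: EnzymeMapping,
) -> float | None:
    """Abundance ratio agg(sample)/agg(reference), or None if unusable."""
    usable = [
        p
        for p in proteins
        if p in reference.index
        and np.isfinite(reference[p])
        and p in sample_values.index
        and np.isfinite(sample_values[p])
    ]
    if not usable:
        return None
    s = mapping.aggregate(sample_values[usable].to_numpy(float))
    r = mapping.aggregate(reference[usable].to_numpy(float))
    if r <= 0:
        return None
    return s / r


def instantiate(
    model: NetworkModel,
    mapping: EnzymeMapping,
    matrix: ProteinAbundanceMatrix,
    sample: str,
    reference: pd.Series,
) -> SampleInstance:
    """Build one sample's model by Vmax scaling against the reference.

    For each mapped reaction ``vmax_sample = vmax_ref * agg(E_sample) /
    agg(E_ref)``; reactions whose proteins are all missing in the sample fall
    back to scale 1 (counted in ``n_missing``, logged).  Scales are clipped to
    [0.01, 100] with a warning.
    """
    if sample not in matrix.intensity.columns:
        raise KeyError(f"unknown sample {sample!r}")
    values = matrix.intensity[sample]
    scales: dict[str, float] = {}
    n_missing = 0
    for rxn in model.reactions:
        prots = mapping.reactions.get(rxn.id, [])
        if not prots:
            continue
        s = _reaction_scale(prots, values, reference, mapping)
        if s is None:
            n_missing += 1
            logger.info(
                "sample %s reaction %s: no measured proteins, kept at reference",
                sample,
                rxn.id,
            )
            continue
        if not (SCALE_CLIP[0] <= s <= SCALE_CLIP[1]):
            clipped = float(np.clip(s, *SCALE_CLIP))
            logger.warning(
                "sample %s reaction %s: scale %.3g clipped to %.3g",
                sample,
                rxn.id,
                s,
                clipped,
            )
            s = clipped
        scales[rxn.id] = float(s)
    inst_model = model.scale_vmax(scales)
    return SampleInstance(
        sample_id=sample, model=inst_model, scale=scales, n_missing=n_missing
    )


def instantiate_cohort(
    model: NetworkModel,
    mapping: EnzymeMapping,
    matrix: ProteinAbundanceMatrix,
    control_group: str,
) -> list[SampleInstance]:
    """One instance per sample (controls included), ordered by sample id."""
    reference, _ = reference_abundance(matrix, control_group)
    return [
        instantiate(model, mapping, matrix, s, reference)
        for s in sorted(matrix.samples)
    ]


def median_scale(matrix: ProteinAbundanceMatrix) -> ProteinAbundanceMatrix:
    """Optional median normalization across samples (for real data; the
    synthetic generator emits comparably scaled intensities already)."""
    med = matrix.intensity.median(axis=0, skipna=True)
    target = float(np.median(med))
    return ProteinAbundanceMatrix(
        intensity=matrix.intensity * (target / med), group=dict(matrix.group)
    )
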