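"""File readers/writers, run configuration and the reproducibility manifest.

Canonical tabular format is TSV (UTF-8, '.' decimal, empty cell = missing).
Output tables carry a comment header naming units.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .capacity import BUILTIN_PROFILES, PlasmaProfile
from .instantiate import EnzymeMapping, ProteinAbundanceMatrix

logger = logging.getLogger(__name__)

METADATA_COLUMNS = ("sample", "group")


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# abundance matrix
# ---------------------------------------------------------------------------


def read_abundance(path: str | Path, metadata: pd.DataFrame | None = None) -> ProteinAbundanceMatrix:
    """Read a wide protein x sample TSV (first column: protein id).

    Duplicate protein or sample ids and non-positive intensities are
    rejected with the offending id / line number.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 2:
        raise FormatError(f"{path}: need a protein column plus >= 1 sample column")
    sample_cols = header[1:]
    dupes = {c for c in sample_cols if sample_cols.count(c) > 1}
    if dupes:
        raise FormatError(f"{path}: duplicate sample column(s) {sorted(dupes)}")
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        bad = sorted(df.index[df.index.duplicated()].unique())
        raise FormatError(f"{path}: duplicate protein id(s) {bad}")
    vals = df.to_numpy(float)
    bad_rows = np.where(np.any(np.nan_to_num(vals, nan=1.0) <= 0, axis=1))[0]
    if bad_rows.size:
        # +2: header line and 1-based numbering
        raise FormatError(
            f"{path}: non-positive intensity at line {int(bad_rows[0]) + 2} "
            f"(protein {df.index[bad_rows[0]]})"
        )
    group = {}
    if metadata is not None:
        group = dict(zip(metadata.index.astype(str), metadata["group"].astype(str)))
    return ProteinAbundanceMatrix(intensity=df, group=group)


def write_abundance(matrix: ProteinAbundanceMatrix, path: str | Path) -> None:
    path = Path(path)
    df = matrix.intensity.copy()
    df.index.name = "protein"
    df.to_csv(path, sep="\t", na_rep="")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata TSV (sample, group, masses, echo fields)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing metadata column(s) {missing}")
    df["sample"] = df["sample"].astype(str)
    if df["sample"].duplicated().any():
        bad = sorted(df["sample"][df["sample"].duplicated()].unique())
        raise FormatError(f"{path}: duplicate sample id(s) {bad}")
    return df.set_index("sample")


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    out = meta.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t", na_rep="")


def read_plasma_panels(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    return df


def read_protein_list(path: str | Path) -> list[str]:
    """Plain list file: one protein id per line, '#' comments allowed."""
    out = []
    for line in Path(path).read_text().splitlines():
        s = line.split("#", 1)[0].strip()
        if s:
            out.append(s)
    return out


# ---------------------------------------------------------------------------
# plasma profile configs
# ---------------------------------------------------------------------------


def read_profiles(path: str | Path | None) -> dict[str, PlasmaProfile]:
    """Profiles from a YAML config, always including the two built-ins."""
    profiles = dict(BUILTIN_PROFILES)
    if path is None:
        return profiles
    doc = yaml.safe_load(Path(path).read_text()) or {}
    for name, fields in doc.get("profiles", {}).items():
        profiles[name] = PlasmaProfile(label=name, **fields)
    return profiles


# ---------------------------------------------------------------------------
# run configuration & manifest
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Paths, stage toggles and analysis settings for one pipeline run."""

    matrix: str | None = None
    metadata: str | None = None
    plasma: str | None = None
    mapping: str | None = None  # default: mapping embedded in the model
    model: str | None = None  # default: shipped reduced cardiac model
    profile_config: str | None = None
    control_group: str = "control"
    alpha: float = 0.05
    alpha_norm: float = 0.05
    fc_low: float = 0.5
    fc_high: float = 2.0
    run_capacities: bool = True
    run_stats: bool = True
    seed: int = 0
    outdir: str = "results"
    schema_version: int = 1

    def validate_paths(self) -> None:
        for name in ("matrix", "metadata", "plasma", "mapping", "model", "profile_config"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config path {name} = {p} does not exist")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in doc.items() if k in cls.__dataclass_fields__}
        return cls(**known)


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(
    config: RunConfig, outdir: str | Path, warnings: list[str] | None = None
) -> Path:
    """Write the run manifest: config (and its hash), seed, versions,
    machine-readable warnings.  The manifest suffices to reproduce any
    output table exactly."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config.to_dict(),
        "config_hash": config_hash(config),
        "seed": config.seed,
        "versions": {
            "myoflux": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "warnings": warnings or [],
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def write_table(df: pd.DataFrame, path: str | Path, units: str = "") -> None:
    """TSV export with a comment header naming units."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if units:
            fh.write(f"# units: {units}\n")
        df.to_csv(fh, sep="\t", na_rep="")
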