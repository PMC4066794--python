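"""Configuration loading and bit-stable tabular I/O.

Configs are YAML or JSON documents validated against a strict schema
(unknown keys rejected, probabilities bounded to [0, 1]).  Tables are
tab-separated with LF line endings and '.' decimals so that reruns with the
same seed diff cleanly; percentages are emitted with one decimal
(round-half-even) always alongside the raw fraction.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .assay import (
    AssayCounts,
    MarkerMap,
    Phenotype,
    RateEstimates,
    TALELAT_MARKERS,
    ZFN_MARKERS,
)
from .genetics import Allele, DriveParams
from .population import ReleaseSpec, SimConfig

__all__ = [
    "RunConfig",
    "load_config",
    "ConfigError",
    "marker_map_by_name",
    "percent",
    "read_progeny_table",
    "read_counts_table",
    "read_f2_table",
    "write_table",
    "read_table",
    "write_rates_table",
    "write_manifest",
]


class ConfigError(ValueError):
    """A configuration file failed to parse or validate."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DriveParamsConfig(_Strict):
    c: float = Field(ge=0.0, le=1.0)
    h: float = Field(ge=0.0, le=1.0)
    phi: float = Field(ge=0.0, le=1.0)

    def build(self) -> DriveParams:
        return DriveParams(c=self.c, h=self.h, phi=self.phi)


class ReleaseConfig(_Strict):
    n_trans_het_males: int = Field(ge=0)
    n_target_males: int = Field(ge=0)
    n_target_females: int = Field(ge=0)
    target_allele: str = "T"

    def build(self) -> ReleaseSpec:
        if self.target_allele not in ("T", "N"):
            raise ConfigError("sim.release.target_allele must be 'T' or 'N'")
        return ReleaseSpec(
            n_trans_het_males=self.n_trans_het_males,
            n_target_males=self.n_target_males,
            n_target_females=self.n_target_females,
            target_allele=Allele(self.target_allele),
        )


class SimBlockConfig(_Strict):
    release: ReleaseConfig
    cap: int = Field(ge=2)
    generations: int = Field(ge=0)
    iterations: int = Field(ge=1, default=1)
    eggs_per_female: int = Field(ge=1, default=40)
    seed: int = 0

    def build(self) -> SimConfig:
        return SimConfig(
            release=self.release.build(),
            cap=self.cap,
            generations=self.generations,
            iterations=self.iterations,
            eggs_per_female=self.eggs_per_female,
            seed=self.seed,
        )


class AssayBlockConfig(_Strict):
    input: str
    marker_map: str = "talelat"
    n_homing_assayed: Optional[int] = None


class F2BlockConfig(_Strict):
    input: str
    alpha: float = Field(gt=0.0, lt=1.0, default=0.05)


class RunConfig(_Strict):
    """Validated run configuration; blocks are per subcommand."""

    drive_params: Optional[DriveParamsConfig] = None
    sim: Optional[SimBlockConfig] = None
    assay: Optional[AssayBlockConfig] = None
    f2: Optional[F2BlockConfig] = None
    output_dir: Optional[str] = None


def marker_map_by_name(name: str) -> MarkerMap:
    maps = {"talelat": TALELAT_MARKERS, "zfn": ZFN_MARKERS}
    try:
        return maps[name.lower()]
    except KeyError:
        raise ConfigError(
            f"unknown marker map {name!r}; expected one of {sorted(maps)}"
        ) from None


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if raw is None:
        raise ConfigError(f"config file is empty: {path}")
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping: {path}")
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        locs = "; ".join(
            ".".join(str(p) for p in err["loc"]) + ": " + err["msg"]
            for err in exc.errors()
        )
        raise ConfigError(f"invalid config {path}: {locs}") from exc


def percent(fraction: float, decimals: int = 1) -> float:
    """Fraction as a percentage rounded half-even to ``decimals``."""
    return round(fraction * 100.0, decimals)


# ---------------------------------------------------------------------------
# tables


def _read_frame(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", comment="#")


def read_progeny_table(path: str | Path) -> List[Phenotype]:
    """One row per progeny fly: columns white_plus, curled, gfp, rfp_or_pcr."""
    df = _read_frame(path)
    required = ["white_plus", "curled", "gfp", "rfp_or_pcr"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigError(f"progeny table missing columns: {missing}")
    return [
        Phenotype(
            white_plus=bool(r.white_plus),
            curled=bool(r.curled),
            gfp=bool(r.gfp),
            rfp_or_pcr=bool(r.rfp_or_pcr),
        )
        for r in df.itertuples(index=False)
    ]


def read_counts_table(path: str | Path) -> List[AssayCounts]:
    """Pre-aggregated counts: one row per cross with the four count columns."""
    df = _read_frame(path)
    required = ["n_target_total", "n_gfp_loss", "n_homed", "n_homing_assayed"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigError(f"counts table missing columns: {missing}")
    return [
        AssayCounts(
            n_target_total=int(r.n_target_total),
            n_gfp_loss=int(r.n_gfp_loss),
            n_homed=int(r.n_homed),
            n_homing_assayed=int(r.n_homing_assayed),
        )
        for r in df.itertuples(index=False)
    ]


def read_f2_table(path: str | Path) -> List[Tuple[int, int]]:
    """F2 crosses: columns gfp_pos, gfp_neg (a cross_id column is allowed)."""
    df = _read_frame(path)
    missing = [c for c in ("gfp_pos", "gfp_neg") if c not in df.columns]
    if missing:
        raise ConfigError(f"F2 table missing columns: {missing}")
    return [
        (int(r.gfp_pos), int(r.gfp_neg)) for r in df.itertuples(index=False)
    ]


def write_table(df: pd.DataFrame, path: str | Path, header_comment: str = "") -> None:
    """Write a DataFrame as canonical TSV (tab-separated, LF, '.' decimals)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="\n") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def rates_to_frame(rates: Sequence[RateEstimates]) -> pd.DataFrame:
    """One row per assay with raw fractions, percentages and Wilson CIs."""
    rows = []
    for i, r in enumerate(rates):
        a = r.counts
        rows.append(
            {
                "cross": i,
                "n_target_total": a.n_target_total,
                "n_gfp_loss": a.n_gfp_loss,
                "n_homed": a.n_homed,
                "n_homing_assayed": a.n_homing_assayed,
                "cleavage_rate": r.cleavage_rate,
                "cleavage_pct": percent(r.cleavage_rate),
                "cleavage_ci_low": r.cleavage_ci[0],
                "cleavage_ci_high": r.cleavage_ci[1],
                "homing_fraction": r.homing_fraction,
                "homing_pct": (
                    percent(r.homing_fraction)
                    if r.homing_fraction is not None
                    else None
                ),
                "homing_ci_low": r.homing_ci[0] if r.homing_ci else None,
                "homing_ci_high": r.homing_ci[1] if r.homing_ci else None,
                "total_homed": r.total_homed,
                "total_homed_pct": (
                    percent(r.total_homed) if r.total_homed is not None else None
                ),
                "nhej_fraction": r.nhej_fraction,
            }
        )
    return pd.DataFrame(rows)


def write_rates_table(
    rates: Sequence[RateEstimates], path: str | Path, header_comment: str = ""
) -> None:
    write_table(rates_to_frame(rates), path, header_comment)


def write_manifest(path: str | Path, payload: Dict) -> None:
    """JSON run manifest: seed, parameters and package version."""
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {"package": "ssedrive", "version": __version__, **payload}
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
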