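"""CSV readers/writers and run configuration.

Serial samples travel in a long (tidy) CSV with one row per replicate
measurement and an explicit ``position_datum`` column, because profiles
are plotted both as "mm from tooth root" and in growth order
(occlusal to root); making the datum explicit prevents silent axis
flips.  Machine CSVs keep full precision; human-facing reports round to
one decimal.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .conversions import ConversionConstants, vpdb_to_vsmow
from .core import IsotopeSeries, MonthlyWaterSeries, ToothGeometry
from .errors import ConfigError, ParseError
from .inverse_model import InversionConfig, InversionResult
from .synthetic_data import BodyWaterParams, CohortScenario, WaterYearParams

__all__ = [
    "SAMPLE_COLUMNS",
    "RunConfig",
    "read_serial_samples",
    "write_serial_samples",
    "read_water_monthly",
    "write_water_monthly",
    "write_inversion_result",
    "write_run_metadata",
    "load_config",
]

logger = logging.getLogger(__name__)

SAMPLE_COLUMNS = [
    "specimen_id",
    "cohort",
    "position_mm",
    "position_datum",
    "analyte",
    "scale",
    "replicate",
    "d18O",
]


def read_serial_samples(path) -> list[IsotopeSeries]:
    """Read a long-format serial-sample CSV into one series per specimen.

    Positions given ``from_root`` are reversed onto the occlusal-origin
    convention using each specimen's maximum extent; carbonate values on
    the VPDB scale are converted to VSMOW with a logged notice.
    """
    df = pd.read_csv(path)
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    bad_datum = ~df["position_datum"].isin(["from_root", "from_occlusal"])
    if bad_datum.any():
        line = int(df.index[bad_datum][0]) + 2
        raise ParseError(f"{path}:{line}: unknown position_datum")
    series_list = []
    for spec_id, g in df.groupby("specimen_id", sort=True):
        scales = g["scale"].unique()
        if len(scales) > 1:
            raise ParseError(f"{path}: specimen {spec_id} mixes scales {scales.tolist()}")
        analytes = g["analyte"].unique()
        if len(analytes) > 1:
            raise ParseError(
                f"{path}: specimen {spec_id} mixes analytes {analytes.tolist()}"
            )
        scale, analyte = scales[0], analytes[0]
        if scale == "VPDB" and analyte != "CO3":
            line = int(g.index[0]) + 2
            raise ParseError(f"{path}:{line}: VPDB scale is only valid for CO3")
        dup = g.duplicated(subset=["position_mm", "replicate"])
        if dup.any():
            line = int(g.index[dup][0]) + 2
            raise ParseError(
                f"{path}:{line}: duplicated (position, replicate) for specimen {spec_id}"
            )
        g = g.copy()
        datums = g["position_datum"].unique()
        if len(datums) > 1:
            raise ParseError(f"{path}: specimen {spec_id} mixes position datums")
        if datums[0] == "from_root":
            g["position_mm"] = g["position_mm"].max() - g["position_mm"]
        values = g["d18O"].to_numpy(dtype=float)
        if scale == "VPDB":
            values = vpdb_to_vsmow(values)
            scale = "VSMOW"
            logger.info("specimen %s: converted CO3 values from VPDB to VSMOW", spec_id)
        g["d18O_vsmow"] = values
        positions = np.sort(g["position_mm"].unique())
        replicates = [
            g.loc[np.isclose(g["position_mm"], p), "d18O_vsmow"].to_numpy(dtype=float)
            for p in positions
        ]
        series_list.append(
            IsotopeSeries(
                specimen_id=str(spec_id),
                positions=positions,
                replicates=replicates,
                analyte=str(analyte),
                scale=scale,
                cohort=str(g["cohort"].iloc[0]),
            )
        )
    return series_list


def write_serial_samples(series_list: list[IsotopeSeries], path) -> None:
    """Write series back to the long CSV format (occlusal datum)."""
    rows = []
    for s in series_list:
        for pos, reps in zip(s.positions, s.replicates):
            for j, v in enumerate(reps, start=1):
                rows.append(
                    {
                        "specimen_id": s.specimen_id,
                        "cohort": s.cohort,
                        "position_mm": pos,
                        "position_datum": "from_occlusal",
                        "analyte": s.analyte,
                        "scale": s.scale,
                        "replicate": j,
                        "d18O": v,
                    }
                )
    pd.DataFrame(rows, columns=SAMPLE_COLUMNS).to_csv(path, index=False)


def read_water_monthly(path) -> MonthlyWaterSeries:
    """Read a 12-row monthly water CSV (columns ``month``, ``d18O_w``)."""
    df = pd.read_csv(path)
    for col in ("month", "d18O_w"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    months = df["month"].to_numpy(dtype=int)
    present = set(months.tolist())
    missing = sorted(set(range(1, 13)) - present)
    if missing:
        raise ParseError(f"{path}: missing month(s) {missing}")
    if len(months) != 12:
        dups = sorted({m for m in months if (months == m).sum() > 1})
        raise ParseError(f"{path}: duplicate month(s) {dups}")
    return MonthlyWaterSeries(months=months, values=df["d18O_w"].to_numpy(dtype=float))


def write_water_monthly(water: MonthlyWaterSeries, path) -> None:
    pd.DataFrame({"month": water.months, "d18O_w": water.values}).to_csv(path, index=False)


def write_inversion_result(
    result: InversionResult, path, metadata: dict | None = None
) -> None:
    """Write the estimate (and bands) to CSV with a JSON metadata sidecar."""
    result.to_frame().to_csv(path, index=False)
    sidecar = Path(path).with_suffix(".meta.json")
    meta = {
        "version": __version__,
        "damping": result.damping_used,
        "rms_misfit": result.rms_misfit,
    }
    if metadata:
        meta.update(metadata)
    sidecar.write_text(json.dumps(meta, indent=2, default=_json_default))


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_run_metadata(path, seed, config, warnings_list=None) -> None:
    """Log the fully resolved configuration next to every run's outputs."""
    payload = {
        "version": __version__,
        "seed": seed,
        "config": dataclasses.asdict(config),
        "warnings": warnings_list or [],
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=_json_default))


@dataclass
class RunConfig:
    """Fully resolved configuration for a pipeline run.

    Every block has working defaults, so a run needs no user input; the
    YAML loader rejects unknown keys to catch typos early.
    """

    geometry: ToothGeometry = field(default_factory=ToothGeometry)
    inversion: InversionConfig = field(default_factory=InversionConfig)
    constants: ConversionConstants = field(default_factory=ConversionConstants)
    water: WaterYearParams = field(default_factory=WaterYearParams)
    body_water: BodyWaterParams = field(default_factory=BodyWaterParams)
    modern: CohortScenario = field(default_factory=CohortScenario)
    historical: CohortScenario = field(
        default_factory=lambda: CohortScenario(
            n_individuals=3, summer_shift=1.0, winter_shift=-2.0, label="historical"
        )
    )
    seed: int = 0


_BLOCK_TYPES = {
    "geometry": ToothGeometry,
    "inversion": InversionConfig,
    "constants": ConversionConstants,
    "water": WaterYearParams,
    "body_water": BodyWaterParams,
    "modern": CohortScenario,
    "historical": CohortScenario,
}


def _build_block(cls, block: dict, name: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - fields
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in block {name!r}")
    coerced = {k: tuple(v) if isinstance(v, list) else v for k, v in block.items()}
    return cls(**coerced)


def load_config(path) -> RunConfig:
    """Load a YAML run configuration, filling defaults for absent blocks."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    unknown = set(raw) - set(_BLOCK_TYPES) - {"seed"}
    if unknown:
        raise ConfigError(f"{path}: unknown top-level key(s) {sorted(unknown)}")
    kwargs = {}
    for name, cls in _BLOCK_TYPES.items():
        if name in raw:
            if not isinstance(raw[name], dict):
                raise ConfigError(f"{path}: block {name!r} must be a mapping")
            kwargs[name] = _build_block(cls, raw[name], name)
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    return RunConfig(**kwargs)
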