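"""Reading and writing the tool's tables, configs and reports.

CSV tables are UTF-8 with a header row; count tables are TSV because
lineages contain semicolons and commas-free fields keep them greppable.
Row-level validation failures are reported with the offending line number
(header = line 1). JSON reports carry a ``schema_version``.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from ekss.core import EKSSConfig, bands_from_spec
from ekss.energy import RequirementConfig
from ekss.errors import SchemaError
from ekss.bcs import REGIONS
from ekss.microbiome import AbundanceTable

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = "1.0"

HORSES_COLUMNS = ("horse_id", "bw_kg", "workload")
SCORES_COLUMNS = ("horse_id", "scorer_id") + REGIONS
RATIONS_COLUMNS = (
    "horse_id", "feed_name", "kg_per_day", "de_mcal_per_kg", "cp_g_per_kg",
    "ad_libitum", "access_hours",
)

#: Output column order for assignment results (stable across runs).
RESULTS_COLUMNS = (
    "horse_id", "overall_bcs", "bcs_rank", "etbf_percent", "de_m", "dei",
    "dei_percent", "cpi_percent", "total_intake_percent", "b", "c",
    "rdi5_percent", "ekss_group", "ekss_level", "orks", "agree_flag",
)


def _read_csv(path: Union[str, Path], required: tuple[str, ...],
              sep: str = ",") -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing column(s) {missing}; found {list(df.columns)}"
        )
    return df


def _row_errors(df: pd.DataFrame, checks, name: str) -> None:
    problems = []
    for idx, row in df.iterrows():
        for message in checks(row):
            problems.append(f"line {idx + 2}: {message}")  # +2: header + 1-based
    if problems:
        raise SchemaError(f"{name}: " + "; ".join(problems[:20]))


def read_horses(path: Union[str, Path]) -> pd.DataFrame:
    """Horse records: horse_id, bw_kg, workload [, tier, horse_type, orks]."""
    df = _read_csv(path, HORSES_COLUMNS)

    def checks(row):
        if not pd.notna(row["bw_kg"]) or float(row["bw_kg"]) <= 0:
            yield f"horse {row['horse_id']!r}: bw_kg must be > 0"

    _row_errors(df, checks, Path(path).name)
    if "tier" not in df.columns:
        df["tier"] = "average"
    return df


def read_scores(path: Union[str, Path]) -> pd.DataFrame:
    """Regional condition scores: one row per horse per scorer."""
    df = _read_csv(path, SCORES_COLUMNS)

    def checks(row):
        for region in REGIONS:
            v = row[region]
            if not pd.notna(v) or not 1.0 <= float(v) <= 9.0:
                yield (
                    f"horse {row['horse_id']!r} scorer {row['scorer_id']!r}: "
                    f"region '{region}' score {v!r} outside the 1-9 scale"
                )

    _row_errors(df, checks, Path(path).name)
    return df


def read_rations(path: Union[str, Path]) -> pd.DataFrame:
    """Feed items: one row per horse per feed."""
    df = _read_csv(path, RATIONS_COLUMNS)

    def checks(row):
        if float(row["kg_per_day"]) < 0:
            yield f"feed {row['feed_name']!r}: negative kg_per_day"
        if float(row["de_mcal_per_kg"]) < 0 or float(row["cp_g_per_kg"]) < 0:
            yield f"feed {row['feed_name']!r}: negative nutrient density"
        if not 0.0 <= float(row["access_hours"]) <= 24.0:
            yield f"feed {row['feed_name']!r}: access_hours outside [0, 24]"

    _row_errors(df, checks, Path(path).name)
    df["ad_libitum"] = df["ad_libitum"].astype(bool)
    return df


def read_counts(
    path: Union[str, Path], labels_path: Optional[Union[str, Path]] = None
) -> AbundanceTable:
    """TSV count table (first column lineage) with optional sample labels CSV."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise SchemaError(f"{path.name}: need a lineage column plus >= 1 sample")
    df = df.set_index(df.columns[0])
    df.index.name = "lineage"
    try:
        counts = df.astype(float)
    except ValueError as exc:
        raise SchemaError(f"{path.name}: non-numeric counts ({exc})") from None
    labels = None
    if labels_path is not None:
        ldf = _read_csv(labels_path, ("sample_id", "group"))
        labels = ldf.set_index("sample_id")["group"]
    return AbundanceTable(counts=counts, sample_labels=labels)


def load_config(
    path: Union[str, Path]
) -> tuple[EKSSConfig, RequirementConfig]:
    """Load scale + requirement configuration from one YAML file.

    Recognized top-level keys: ``ideal_bcs``, ``delta_de``, ``level_bands``
    (list of band dicts), ``de_coefficients``, ``workload_multipliers``,
    ``cp_coefficients``, ``adlib_rate``, ``special_type_overrides``. Any
    subset may be given; the rest fall back to defaults.
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    ekss_kwargs = {}
    if "ideal_bcs" in raw:
        ekss_kwargs["ideal_bcs"] = float(raw["ideal_bcs"])
    if "delta_de" in raw:
        ekss_kwargs["delta_de"] = float(raw["delta_de"])
    if "level_bands" in raw:
        ekss_kwargs["level_bands"] = bands_from_spec(raw["level_bands"])
    req_kwargs = {}
    for key in ("de_coefficients", "workload_multipliers", "cp_coefficients",
                "special_type_overrides"):
        if key in raw:
            req_kwargs[key] = raw[key]
    if "adlib_rate" in raw:
        req_kwargs["adlib_rate"] = float(raw["adlib_rate"])
    return EKSSConfig(**ekss_kwargs), RequirementConfig(**req_kwargs)


def write_results(results: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write an assignment results table with a stable column order.

    Full-precision floats are kept; an empty frame writes a header-only
    file with a warning rather than failing.
    """
    if len(results) == 0:
        logger.warning("writing header-only results file: no rows")
    cols = [c for c in RESULTS_COLUMNS if c in results.columns]
    cols += [c for c in results.columns if c not in cols]
    results.loc[:, cols].to_csv(path, index=False)


def _jsonable(obj):
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="records"))
    if isinstance(obj, pd.Series):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        return None if not np.isfinite(obj) else float(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(payload: dict, path: Union[str, Path]) -> None:
    """Write a schema-versioned JSON report (NaN-free, deterministic keys)."""
    body = {"schema_version": REPORT_SCHEMA_VERSION}
    body.update({k: _jsonable(v) for k, v in payload.items()})
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(body, fh, indent=2, sort_keys=False)
        fh.write("\n")
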