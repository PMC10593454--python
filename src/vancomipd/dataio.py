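"""Dataset, parameter-file and nomogram readers/writers.

Datasets use a NONMEM-style CSV event format: one row per dose event
(EVID=1, MDV=1, AMT/RATE set) or observation (EVID=0, MDV=0, DV set),
with covariate columns repeated on every row.  All files written by this
package begin with '#' comment lines recording the package version, the
seed and a configuration hash, and every reader skips such lines.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from . import __version__
from .doseopt import NomogramTable
from .synthetic import DATASET_COLUMNS
from .types import PDParameters, PKParameters

__all__ = [
    "DatasetError",
    "read_dataset",
    "write_dataset",
    "load_pk_parameters",
    "load_pd_parameters",
    "save_parameters",
    "write_nomogram",
    "default_parameter_path",
]

_NUMERIC_COLS = [c for c in DATASET_COLUMNS if c not in ("CMT", "STYPE")]


class DatasetError(ValueError):
    """Raised when an event dataset fails validation."""


def _config_hash(obj) -> str:
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header_lines(seed: Optional[int], config) -> str:
    lines = [f"# vancomipd v{__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config is not None:
        lines.append(f"# config-hash: {_config_hash(config)}")
    return "\n".join(lines) + "\n"


def read_dataset(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate an event dataset; rows sorted per subject by time."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"{path.name}: missing required columns {missing}")
    for col in _NUMERIC_COLS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if col != "DV":
            bad = df.index[coerced.isna() & df[col].notna()]
            if len(bad) > 0:
                raise DatasetError(f"{path.name}: non-numeric {col} at row {bad[0] + 1}")
        df[col] = coerced
    if (df["TIME"] < 0).any():
        row = int(df.index[df["TIME"] < 0][0]) + 1
        raise DatasetError(f"{path.name}: negative TIME at row {row}")
    doses = df["EVID"] == 1
    bad = df.index[doses & (df["MDV"] != 1)]
    if len(bad) > 0:
        raise DatasetError(f"{path.name}: dose row with MDV=0 at row {bad[0] + 1}")
    bad = df.index[doses & ~(df["AMT"] > 0)]
    if len(bad) > 0:
        raise DatasetError(f"{path.name}: dose row without positive AMT at row {bad[0] + 1}")
    bad = df.index[(df["EVID"] == 0) & (df["AMT"] != 0)]
    if len(bad) > 0:
        raise DatasetError(f"{path.name}: observation row with AMT at row {bad[0] + 1}")
    return (
        df.sort_values(["ID", "TIME", "EVID"], kind="stable")
        .reset_index(drop=True)[DATASET_COLUMNS]
    )


def write_dataset(
    df: pd.DataFrame,
    path: Union[str, Path],
    seed: Optional[int] = None,
    config=None,
) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header_lines(seed, config))
        df.to_csv(fh, index=False)
    return path


# ---------------------------------------------------------------------------
# parameter files

def default_parameter_path(which: str) -> Path:
    """Path of the shipped default parameter file ('pk' or 'pd')."""
    return Path(__file__).parent / "data" / f"{which}_params.yaml"


def _load_mapping(path: Union[str, Path]) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def load_pk_parameters(path: Optional[Union[str, Path]] = None) -> PKParameters:
    """Load PK parameters from YAML/JSON (shipped defaults when no path)."""
    mapping = _load_mapping(path or default_parameter_path("pk"))
    return PKParameters(**mapping)


def load_pd_parameters(path: Optional[Union[str, Path]] = None) -> PDParameters:
    mapping = _load_mapping(path or default_parameter_path("pd"))
    return PDParameters(**mapping)


def save_parameters(
    params: Union[PKParameters, PDParameters], path: Union[str, Path]
) -> Path:
    path = Path(path)
    payload = params.model_dump(by_alias=True)
    with open(path, "w") as fh:
        if path.suffix in (".yaml", ".yml"):
            yaml.safe_dump(payload, fh, sort_keys=False)
        else:
            json.dump(payload, fh, indent=2)
    return path


# ---------------------------------------------------------------------------
# nomograms

def write_nomogram(
    table: NomogramTable,
    path: Union[str, Path],
    layout: str = "long",
    seed: Optional[int] = None,
    config=None,
) -> Path:
    """Write a nomogram as long (one scenario per row) or wide CSV.

    The wide layout nests (age or PMA) x weight on rows and creatinine x
    BUN on columns, mirroring the published table shape.
    """
    path = Path(path)
    if layout not in ("long", "wide"):
        raise ValueError("layout must be 'long' or 'wide'")
    with open(path, "w") as fh:
        fh.write(_header_lines(seed, config))
        fh.write(f"# population: {table.population}; dose units: {table.dose_units}\n")
        if layout == "long":
            table.long.to_csv(fh, index=False)
        else:
            table.wide().to_csv(fh)
    return path
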