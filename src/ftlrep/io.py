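"""Readers and writers for the package's delimited-text interfaces.

Schemas (CSV, header required):

* readout table:        ``construct,mean,sd,n``
* replicate table:      ``construct,replicate,value``
* time course:          ``time_min,bound_fraction[,replicate]``
* dose response:        ``fold_excess,response[,replicate]``

Sequences are FASTA; configuration is YAML or JSON; results are JSON with
floats serialized at 12 significant digits for cross-platform
reproducibility.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import __version__
from .kinetics import DoseResponse, TimeCourse
from .occupancy import ConstraintError, ConstructReadouts, Readout, canonical_construct

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "load_readouts",
    "load_reporter_table",
    "load_timecourse",
    "load_doseresponse",
    "load_fasta",
    "write_json",
    "provenance",
]


class ParseError(ValueError):
    """A malformed input file; the message names the file and line."""


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file does not exist")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: file is empty") from None
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from None
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(
            f"{path}: missing required column(s) {', '.join(missing)}; "
            f"found {', '.join(df.columns)}"
        )
    extra = [c for c in df.columns if c not in required and c != "replicate"]
    if extra:
        logger.warning("%s: ignoring extra column(s) %s", path, ", ".join(extra))
    if df.empty:
        raise ParseError(f"{path}: no data rows")
    return df


def _numeric(df: pd.DataFrame, col: str, path: Path) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() & df[col].notna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # header + 1-based
        raise ParseError(
            f"{path}: non-numeric value {df[col][bad.idxmax()]!r} in column "
            f"{col!r} at line {line}"
        )
    if vals.isna().any():
        line = int(vals.isna().idxmax()) + 2
        raise ParseError(f"{path}: missing value in column {col!r} at line {line}")
    return vals.to_numpy(dtype=float)


def load_readouts(path: str | Path) -> ConstructReadouts:
    """Load a per-construct readout summary table (construct, mean, sd, n)."""
    path = Path(path)
    df = _read_csv(path, ["construct", "mean", "sd", "n"])
    means = _numeric(df, "mean", path)
    sds = _numeric(df, "sd", path)
    ns = _numeric(df, "n", path)
    entries = {}
    for i, name in enumerate(df["construct"]):
        try:
            key = canonical_construct(str(name))
            entries[key] = Readout(mean=float(means[i]), sd=float(sds[i]), n=int(ns[i]))
        except ConstraintError as exc:
            raise ParseError(f"{path}: line {i + 2}: {exc}") from None
    return ConstructReadouts(entries)


def load_reporter_table(path: str | Path) -> pd.DataFrame:
    """Load a replicate-level reporter table (construct, replicate, value)."""
    path = Path(path)
    df = _read_csv(path, ["construct", "replicate", "value"])
    df["value"] = _numeric(df, "value", path)
    for i, name in enumerate(df["construct"]):
        try:
            canonical_construct(str(name))
        except ConstraintError as exc:
            raise ParseError(f"{path}: line {i + 2}: {exc}") from None
    df["construct"] = [canonical_construct(str(n)) for n in df["construct"]]
    return df


def load_timecourse(path: str | Path) -> TimeCourse:
    """Load a bound-fraction time course (time_min, bound_fraction)."""
    path = Path(path)
    df = _read_csv(path, ["time_min", "bound_fraction"])
    try:
        return TimeCourse(
            times=_numeric(df, "time_min", path),
            bound_fraction=_numeric(df, "bound_fraction", path),
        )
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None


def load_doseresponse(path: str | Path) -> DoseResponse:
    """Load a competition dose-response table (fold_excess, response)."""
    path = Path(path)
    df = _read_csv(path, ["fold_excess", "response"])
    rep = None
    if "replicate" in df.columns:
        rep = _numeric(df, "replicate", path).astype(int)
    try:
        return DoseResponse(
            folds=_numeric(df, "fold_excess", path),
            response=_numeric(df, "response", path),
            replicate=rep,
        )
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None


def load_fasta(path: str | Path) -> dict[str, str]:
    """Load FASTA sequences as ``{record id: sequence string}``."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file does not exist")
    records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def _round_floats(obj: Any) -> Any:
    """Serialize floats at 12 significant digits for stable JSON output."""
    if isinstance(obj, float):
        return float(f"{obj:.12g}")
    if isinstance(obj, (np.floating,)):
        return float(f"{float(obj):.12g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_round_floats(v) for v in obj.tolist()]
    if isinstance(obj, dict):
        return {str(k): _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    return obj


def write_json(obj: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_round_floats(obj), indent=2, sort_keys=True) + "\n")


def provenance(seed: int | None = None, **inputs: Any) -> dict:
    """Provenance block attached to every result document."""
    out: dict[str, Any] = {"package": "ftlrep", "version": __version__}
    if seed is not None:
        out["seed"] = seed
    out.update({k: str(v) for k, v in inputs.items()})
    return out
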