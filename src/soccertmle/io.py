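"""Reading, validating and writing per-period observation tables.

The observed dataset is a delimited table with one row per team-period and
columns for the period index (W1), substitutes present (W2), current-period
substitution (W3), previous-period substitution (A) and team distance (Y).
Column names in the source file are mapped onto these canonical roles by an
:class:`ObservedSchema`; mismatches fail loudly rather than being guessed.

The outcome column may hold raw meters or an already-normalised value; the
reader auto-detects (any value outside [0, 1] means raw), min-max
normalises over the loaded dataset as a whole, and logs the decision.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .simulate import SimConfig, minmax_normalize, simulate, validate_table

__all__ = ["ObservedSchema", "SchemaError", "read_observed", "write_fixture"]

log = logging.getLogger("soccertmle")

CANONICAL = ("W1", "W2", "W3", "A", "Y")


class SchemaError(ValueError):
    """Raised when the source file does not match the declared schema."""


@dataclass
class ObservedSchema:
    """Mapping from source column names to canonical roles.

    ``columns`` maps canonical name -> source column name; ``y_is_raw``
    forces the outcome-scale decision (None = auto-detect).
    """

    columns: dict = field(default_factory=lambda: {c: c for c in CANONICAL})
    delimiter: str = ","
    y_is_raw: bool | None = None

    def __post_init__(self):
        missing = [c for c in CANONICAL if c not in self.columns]
        if missing:
            raise SchemaError(f"schema does not map canonical roles {missing}")

    def to_yaml(self, path=None):
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source):
        if hasattr(source, "read"):
            d = yaml.safe_load(source.read())
        else:
            with open(source, "r", encoding="utf-8") as fh:
                d = yaml.safe_load(fh.read())
        return cls(**d)


def read_observed(path, schema: ObservedSchema | None = None) -> pd.DataFrame:
    """Load and validate an observed per-period table.

    Returns the canonical observation table with Y min-max normalised over
    the dataset (bounds stored in ``attrs['y_min'] / attrs['y_max']``,
    ``attrs['y_was_raw']`` records the auto-detection, and
    ``attrs['n_dropped']`` the number of rows rejected for missing values).
    """
    schema = schema or ObservedSchema()
    raw = pd.read_csv(path, delimiter=schema.delimiter)
    if len(raw) == 0:
        raise ValueError(f"empty input: {path} has no data rows")
    missing = [src for src in schema.columns.values() if src not in raw.columns]
    if missing:
        raise SchemaError(
            f"{path}: mapped columns {missing} not found; available: {list(raw.columns)}"
        )
    data = raw[[schema.columns[c] for c in CANONICAL]].copy()
    data.columns = list(CANONICAL)

    n_before = len(data)
    data = data.dropna()
    n_dropped = n_before - len(data)
    if n_dropped:
        log.warning("dropped %d rows with missing values", n_dropped)
    if len(data) == 0:
        raise ValueError(f"empty input: {path} has no complete rows")

    for col in ("A", "W3"):
        bad = ~data[col].isin([0, 1])
        if bad.any():
            raise ValueError(
                f"{path}: non-binary {col} values in rows {data.index[bad].tolist()[:10]}"
            )

    y = data["Y"].to_numpy(dtype=float)
    y_is_raw = schema.y_is_raw
    if y_is_raw is None:
        y_is_raw = bool((y < 0).any() or (y > 1).any())
        log.info(
            "outcome auto-detected as %s", "raw units" if y_is_raw else "normalised"
        )
    y_norm, lo, hi = minmax_normalize(y)
    out = pd.DataFrame(
        {
            "W1": data["W1"].to_numpy(dtype=np.int64),
            "W2": data["W2"].to_numpy(dtype=np.int64),
            "W3": data["W3"].to_numpy(dtype=np.int64),
            "A": data["A"].to_numpy(dtype=np.int64),
            "Y": y_norm,
            "Y_raw": y,
        }
    )
    out.attrs.update(
        y_min=lo, y_max=hi, y_was_raw=y_is_raw, n_dropped=int(n_dropped)
    )
    validate_table(out)
    log.info("loaded %d rows from %s", len(out), path)
    return out


def write_fixture(config: SimConfig, n: int, seed: int, path) -> str:
    """Write a simulated dataset in the observed-schema CSV dialect.

    The outcome column holds the raw (meters-scale) value, as in the source
    data; two calls with identical arguments produce byte-identical files.
    """
    data = simulate(config, n, seed)
    out = data[["W1", "W2", "W3", "A"]].copy()
    out["Y"] = data["Y_raw"].map(lambda v: repr(float(v)))
    try:
        out.to_csv(path, index=False, lineterminator="\n")
    except OSError as exc:
        raise OSError(f"cannot write fixture to {path}: {exc}") from exc
    return str(path)
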