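"""Delimited-file readers and report writers.

All on-disk data are comma-separated UTF-8 text with "." decimals. Each
reader validates against a named column schema and preserves row order;
the round-trip read(write(x)) == x holds up to 12 significant digits of
float formatting.
"""

from __future__ import annotations

import sys
from pathlib import Path

import pandas as pd

from .config import RunConfig, SchemaError, TableParseError, logger

#: column name -> pandas dtype kind ("f" float, "i" int, "s" string)
SCHEMAS: dict[str, dict[str, str]] = {
    "design": {
        "run": "i",
        "ethanol_pct": "f",
        "temp_C": "f",
        "time_min": "f",
        "replicate": "i",
        "response": "f",
    },
    "timecourse": {"ethanol_pct": "f", "temp_C": "f", "time_min": "f", "response": "f"},
    "rates": {"series_id": "s", "temp_C": "f", "k": "f"},
    "doseresponse": {"sample_id": "s", "concentration_ug_ml": "f", "inhibition_pct": "f"},
    "dilution": {"strain": "s", "concentration_ug_ml": "f", "inhibited": "i"},
    "panel": {"condition_id": "s", "assay_id": "s", "ic50_ug_ml": "f"},
}

FLOAT_FORMAT = "%.12g"


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read a CSV file and validate it against a named schema.

    Raises
    ------
    SchemaError
        Unknown schema, or a missing/duplicated column (named in the message).
    TableParseError
        A non-numeric cell in a numeric column (row index in the message).
    """
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    spec = SCHEMAS[schema]
    # pandas mangles duplicate headers (col, col.1, ...), so check raw header
    with open(path, encoding="utf-8") as fh:
        header = [c.strip() for c in fh.readline().rstrip("\n").split(",")]
    dups = {c for c in header if header.count(c) > 1}
    if dups:
        raise SchemaError(f"duplicated column(s) {sorted(dups)} in {path}")
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    cols = list(raw.columns)
    missing = [c for c in spec if c not in cols]
    if missing:
        raise SchemaError(f"missing column(s) {missing} in {path} (schema {schema!r})")

    out = pd.DataFrame(index=raw.index)
    for col, kind in spec.items():
        if kind == "s":
            out[col] = raw[col].astype(str)
            continue
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any() or converted.isna().any():
            row = int(converted.index[converted.isna()][0])
            raise TableParseError(
                f"non-numeric value {raw[col].iloc[row]!r} in column {col!r}, row {row} of {path}"
            )
        out[col] = converted.astype(int) if kind == "i" else converted.astype(float)
    return out


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_report(
    results: dict[str, pd.DataFrame],
    out_dir: str | Path,
    config: RunConfig | None = None,
) -> list[Path]:
    """Write one CSV per result table plus a run log echoing the config.

    An empty bundle still produces the run log; empty tables are written
    with headers only.
    """
    config = config or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, df in results.items():
        p = out / f"{name}.csv"
        write_table(df, p)
        written.append(p)
        logger.info("wrote %s (%d rows)", p, len(df))
    log = out / "run_log.txt"
    log.write_text(
        "ecx run log\nconfig: " + config.echo() + "\ntables: " + ", ".join(sorted(results)) + "\n",
        encoding="utf-8",
    )
    written.append(log)
    return written


def setup_logging(verbose: bool = False) -> None:
    """Route package logs to standard error at info or debug level."""
    import logging

    logging.basicConfig(
        stream=sys.stderr,
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )
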