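"""Table and JSON I/O with strict column contracts.

CSV dialect: comma-separated, UTF-8, "." decimal, header row required and
matched exactly (extra or missing columns are contract errors). The qPCR
table encodes undetected wells as empty cells, mapped to/from NaN.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_data import DOSE_COLUMNS, DOX_COLUMNS, GRID_COLUMNS, QPCR_COLUMNS

__all__ = [
    "TableContractError",
    "TABLE_CONTRACTS",
    "read_measurement_table",
    "write_measurement_table",
    "read_qpcr_plate",
    "write_qpcr_plate",
]


class TableContractError(ValueError):
    """A delimited table does not match its declared column contract."""


TABLE_CONTRACTS: dict[str, tuple[str, ...]] = {
    "grid": GRID_COLUMNS,
    "dose": DOSE_COLUMNS,
    "dox": DOX_COLUMNS,
    "qpcr": QPCR_COLUMNS,
}

_NUMERIC = {
    "grid": ("adaptor_level", "ligand_dose", "gfp", "adaptor_readout"),
    "dose": ("ligand_dose", "gfp"),
    "dox": ("dox_level", "gfp"),
}


def _check_header(path: Path, columns, expected, kind: str) -> None:
    if tuple(columns) != tuple(expected):
        raise TableContractError(
            f"{path}: header {list(columns)} does not match the {kind!r} "
            f"contract; expected exactly {list(expected)}"
        )


def read_measurement_table(path: str | Path, kind: str = "grid") -> pd.DataFrame:
    """Read a well-level measurement CSV, validating the column contract.

    ``kind`` selects the contract: ``grid`` (adaptor x dose), ``dose``
    (single-variable dose series) or ``dox`` (dox titration). Malformed rows
    are reported with their 1-based file line numbers.
    """
    if kind not in _NUMERIC:
        raise ValueError(f"unknown table kind {kind!r}")
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    _check_header(path, raw.columns, TABLE_CONTRACTS[kind], kind)
    out = pd.DataFrame(index=raw.index)
    bad_lines: list[int] = []
    for col in TABLE_CONTRACTS[kind]:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            bad_lines.extend(int(i) + 2 for i in raw.index[bad])  # +2: header + 1-based
        out[col] = converted
    if bad_lines:
        raise TableContractError(
            f"{path}: non-numeric values on line(s) {sorted(set(bad_lines))}"
        )
    out["replicate"] = out["replicate"].astype(int)
    return out


def write_measurement_table(
    data: pd.DataFrame, path: str | Path, kind: str = "grid"
) -> None:
    expected = TABLE_CONTRACTS[kind]
    _check_header(Path(path), data.columns, expected, kind)
    data.to_csv(path, index=False)


def read_qpcr_plate(path: str | Path) -> pd.DataFrame:
    """Read a qPCR Ct CSV; empty ct cells become NaN (undetected)."""
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    _check_header(path, raw.columns, QPCR_COLUMNS, "qpcr")
    ct = pd.to_numeric(raw["ct"].replace("", np.nan), errors="coerce")
    bad = ct.isna() & (raw["ct"].str.strip() != "")
    if bad.any():
        lines = [int(i) + 2 for i in raw.index[bad]]
        raise TableContractError(f"{path}: non-numeric ct on line(s) {lines}")
    replicate = pd.to_numeric(raw["replicate"], errors="coerce")
    if replicate.isna().any():
        lines = [int(i) + 2 for i in raw.index[replicate.isna()]]
        raise TableContractError(f"{path}: non-numeric replicate on line(s) {lines}")
    return pd.DataFrame(
        {
            "sample": raw["sample"],
            "gene": raw["gene"],
            "replicate": replicate.astype(int),
            "ct": ct,
        }
    )


def write_qpcr_plate(plate: pd.DataFrame, path: str | Path) -> None:
    _check_header(Path(path), plate.columns[: len(QPCR_COLUMNS)], QPCR_COLUMNS, "qpcr")
    plate[list(QPCR_COLUMNS)].to_csv(path, index=False)
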