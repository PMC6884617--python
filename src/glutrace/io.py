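"""CSV dialects: MID tables, feature tables, rates tables.

MID table dialect (UTF-8, strict header):
    sample, group, metabolite, tracer, shift, abundance, corrected

Feature tables come as two files: an intensity CSV (first column the
``mass@rt`` feature id, remaining columns samples) and a group map CSV
(``sample, group``).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .mid import MIDVector
from .screen import FeatureTable

__all__ = [
    "MID_TABLE_COLUMNS",
    "read_mid_table",
    "write_mid_table",
    "mid_vectors_from_table",
    "mid_table_from_vectors",
    "read_feature_table",
    "write_feature_table",
    "write_rates_table",
]

MID_TABLE_COLUMNS = ["sample", "group", "metabolite", "tracer", "shift", "abundance", "corrected"]

#: Uncorrected MIDs must still sum to ~1 after instrument normalization.
_SUM_RANGE = (0.98, 1.02)


class TableFormatError(ValueError):
    """Malformed input table (bad header, row, or normalization)."""


def read_mid_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a MID table CSV.

    Raises :class:`TableFormatError` with the offending line number for
    malformed rows, duplicated (sample, metabolite, shift) entries, or
    per-spectrum abundance sums outside [0.98, 1.02].
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != MID_TABLE_COLUMNS:
        raise TableFormatError(
            f"{path}: header {list(df.columns)} does not match {MID_TABLE_COLUMNS}"
        )
    rows = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            shift = int(row["shift"])
            abundance = float(row["abundance"])
            corrected = {"true": True, "false": False}[row["corrected"].strip().lower()]
        except (KeyError, ValueError) as exc:
            raise TableFormatError(f"{path}:{line}: malformed row ({exc})") from None
        if shift < 0 or abundance < 0:
            raise TableFormatError(f"{path}:{line}: negative shift or abundance")
        rows.append(
            {
                "sample": row["sample"],
                "group": row["group"],
                "metabolite": row["metabolite"],
                "tracer": row["tracer"],
                "shift": shift,
                "abundance": abundance,
                "corrected": corrected,
                "line": line,
            }
        )
    out = pd.DataFrame(rows, columns=MID_TABLE_COLUMNS + ["line"])
    dup = out.duplicated(subset=["sample", "metabolite", "shift"], keep=False)
    if dup.any():
        lines = out.loc[dup, "line"].tolist()
        raise TableFormatError(f"{path}: duplicate (sample, metabolite, shift) at lines {lines}")
    for (sample, met), grp in out.groupby(["sample", "metabolite"]):
        total = grp["abundance"].sum()
        if not _SUM_RANGE[0] <= total <= _SUM_RANGE[1]:
            raise TableFormatError(
                f"{path}: MID for sample={sample!r} metabolite={met!r} sums to {total:.4f}, "
                f"outside [{_SUM_RANGE[0]}, {_SUM_RANGE[1]}]"
            )
    return out.drop(columns="line")


def write_mid_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a MID table in the canonical dialect."""
    missing = set(MID_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise TableFormatError(f"MID table missing columns: {sorted(missing)}")
    out = table[MID_TABLE_COLUMNS].copy()
    out["corrected"] = out["corrected"].map(lambda v: "true" if bool(v) else "false")
    out.to_csv(path, index=False)


def mid_vectors_from_table(table: pd.DataFrame) -> list[tuple[str, str, MIDVector]]:
    """Group a MID table into (sample, group, MIDVector) triples."""
    out = []
    for (sample, group, met, tracer, corrected), grp in table.groupby(
        ["sample", "group", "metabolite", "tracer", "corrected"], sort=False
    ):
        grp = grp.sort_values("shift")
        shifts = grp["shift"].to_numpy()
        if not np.array_equal(shifts, np.arange(shifts.size)):
            raise TableFormatError(
                f"sample={sample!r} metabolite={met!r}: shifts {shifts.tolist()} "
                "are not contiguous from 0"
            )
        ab = grp["abundance"].to_numpy(dtype=float)
        out.append(
            (
                sample,
                group,
                MIDVector(
                    metabolite=met,
                    tracer=tracer,
                    abundances=ab / ab.sum(),
                    corrected=bool(corrected),
                ),
            )
        )
    return out


def mid_table_from_vectors(records: list[tuple[str, str, MIDVector]]) -> pd.DataFrame:
    rows = []
    for sample, group, mid in records:
        for shift, ab in enumerate(mid.abundances):
            rows.append(
                {
                    "sample": sample,
                    "group": group,
                    "metabolite": mid.metabolite,
                    "tracer": mid.tracer,
                    "shift": shift,
                    "abundance": ab,
                    "corrected": mid.corrected,
                }
            )
    return pd.DataFrame(rows, columns=MID_TABLE_COLUMNS)


def read_feature_table(intensities_path: str | Path, groups_path: str | Path) -> FeatureTable:
    """Read an untargeted feature matrix plus its sample-group map."""
    intens = pd.read_csv(intensities_path, index_col=0)
    gmap = pd.read_csv(groups_path)
    if list(gmap.columns) != ["sample", "group"]:
        raise TableFormatError(
            f"{groups_path}: header must be ['sample', 'group'], got {list(gmap.columns)}"
        )
    groups = pd.Series(gmap["group"].to_numpy(), index=gmap["sample"])
    return FeatureTable(intens, groups)


def write_feature_table(
    table: FeatureTable, intensities_path: str | Path, groups_path: str | Path
) -> None:
    table.intensities.to_csv(intensities_path, index_label="feature")
    pd.DataFrame({"sample": table.groups.index, "group": table.groups.to_numpy()}).to_csv(
        groups_path, index=False
    )


def write_rates_table(rows: list[dict], path: str | Path) -> None:
    """Rates CSV: condition, metabolite, rate_umol_per_mg_day, direction."""
    df = pd.DataFrame(rows, columns=["condition", "metabolite", "rate_umol_per_mg_day", "direction"])
    df.to_csv(path, index=False)
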