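"""Reading and writing the pipeline's tabular inputs and outputs.

All tables are comma- or tab-delimited text with a header row, UTF-8, with the
empty string or ``NA`` as the missing-value token.  Methylation dosage ratios
(Dm) live on [0, ~1.2]: the ratio statistic can slightly exceed 1, so values up
to 1.2 are accepted and anything above that is flagged with a warning.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .panels import Panel, PanelDef, ProbeDef, parse_probe_id

__all__ = [
    "Cohort",
    "Tissue",
    "DmMatrix",
    "ValidationError",
    "load_panel",
    "load_dm_table",
    "load_sample_meta",
    "load_ihc_table",
    "write_dm_table",
    "write_reports",
]

DM_CEILING = 1.2
_NA_TOKENS = ["", "NA"]

PathLike = Union[str, Path]


class ValidationError(ValueError):
    """An input table violates the format contract."""


class Cohort(str, enum.Enum):
    CA_CRC = "CA_CRC"
    LS = "LS"
    SPORADIC_PMMR = "SPORADIC_PMMR"


class Tissue(str, enum.Enum):
    NORMAL = "NORMAL"
    ADENOMA = "ADENOMA"
    CARCINOMA = "CARCINOMA"


@dataclass
class DmMatrix:
    """Samples x probes matrix of methylation dosage ratios.

    ``values`` is a float DataFrame (index = sample ids, columns = probe ids);
    missing measurements are NaN.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(dtype=float, na_value=np.nan)
        if (vals < 0).any():
            raise ValidationError("negative Dm values are not allowed")
        if np.nansum(vals > DM_CEILING):
            warnings.warn(
                f"Dm values above {DM_CEILING} present; ratio statistic is "
                "expected to stay below this ceiling",
                stacklevel=2,
            )
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate sample ids in Dm table")
        if self.values.columns.has_duplicates:
            raise ValidationError("duplicate probe ids in Dm table")
        self.values = self.values.rename_axis(index="sample_id", columns=None)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, sample_ids) -> "DmMatrix":
        return DmMatrix(self.values.loc[list(sample_ids)])


def _read_delimited(path: PathLike) -> pd.DataFrame:
    import csv

    try:
        return pd.read_csv(
            path,
            sep=None,
            engine="python",
            na_values=_NA_TOKENS,
            keep_default_na=False,
        )
    except (pd.errors.EmptyDataError, csv.Error) as exc:
        raise ValidationError(f"cannot parse delimited file {path}: {exc}") from None


def load_panel(path: PathLike) -> PanelDef:
    """Read a panel-definition table into a validated :class:`PanelDef`.

    Required columns: ``probe_id``, ``gene``, ``panel``; optional
    ``probe_index`` (defaults to the numeral parsed from the probe id) and
    ``technical_floor`` (defaults to 0.15).
    """
    df = _read_delimited(path)
    required = {"probe_id", "gene", "panel"}
    if not required <= set(df.columns):
        raise ValidationError(
            f"panel file missing columns: {sorted(required - set(df.columns))}"
        )
    if df.empty:
        raise ValidationError(f"panel file has no probes: {path}")
    probes = []
    for row in df.itertuples(index=False):
        try:
            panel = Panel(str(row.panel))
        except ValueError:
            raise ValidationError(f"unknown panel label: {row.panel!r}") from None
        if hasattr(row, "probe_index") and not pd.isna(row.probe_index):
            idx = int(row.probe_index)
        else:
            idx = parse_probe_id(str(row.probe_id))[1]
        floor = (
            float(row.technical_floor)
            if hasattr(row, "technical_floor") and not pd.isna(row.technical_floor)
            else 0.15
        )
        try:
            probes.append(
                ProbeDef(
                    probe_id=str(row.probe_id),
                    gene=str(row.gene),
                    panel=panel,
                    probe_index=idx,
                    technical_floor=floor,
                )
            )
        except ValueError as exc:
            raise ValidationError(str(exc)) from None
    try:
        return PanelDef(probes=tuple(probes))
    except ValueError as exc:
        raise ValidationError(str(exc)) from None


def load_dm_table(path: PathLike, panel: PanelDef) -> DmMatrix:
    """Read a Dm table (wide samples x probes, or long sample/probe/dm).

    Probes absent from ``panel`` are dropped with a warning; the result keeps
    the panel's probe order.  Missing cells stay missing.
    """
    df = _read_delimited(path)
    cols = [c.lower() for c in df.columns]
    if {"sample_id", "probe_id", "dm"} <= set(cols):
        df.columns = cols
        wide = df.pivot(index="sample_id", columns="probe_id", values="dm")
    else:
        first = df.columns[0]
        wide = df.set_index(first)
        wide.index.name = "sample_id"
    wide.index = wide.index.astype(str)
    known = [p for p in wide.columns if p in set(panel.probe_ids)]
    unknown = [p for p in wide.columns if p not in set(panel.probe_ids)]
    if not known:
        raise ValidationError("no probes in the Dm table overlap the panel")
    if unknown:
        warnings.warn(f"dropping probes not in panel: {unknown}", stacklevel=2)
    wide = wide[known].astype(float)
    # keep panel probe order for the probes present
    order = [p for p in panel.probe_ids if p in wide.columns]
    return DmMatrix(wide[order])


_META_ENUMS = {
    "cohort": {c.value for c in Cohort},
    "tissue": {t.value for t in Tissue},
}
_TRISTATE = {"stable": False, "unstable": True, "unknown": None}


def load_sample_meta(path: PathLike) -> pd.DataFrame:
    """Read per-sample metadata; validates enums and tri-state MSI flags.

    Returns a DataFrame indexed by ``sample_id`` with object-dtype boolean
    columns ``bat25_unstable``/``bat26_unstable`` (True/False/None).
    """
    df = _read_delimited(path)
    if "sample_id" not in df.columns:
        raise ValidationError("metadata requires a sample_id column")
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        raise ValidationError("duplicate sample ids in metadata")
    for col, allowed in _META_ENUMS.items():
        if col in df.columns:
            bad = set(df[col].dropna().astype(str)) - allowed
            if bad:
                raise ValidationError(f"unknown {col} labels: {sorted(bad)}")
    for col in ("bat25_unstable", "bat26_unstable"):
        if col in df.columns:
            raw = df[col].astype(object)
            out = []
            for v in raw:
                if pd.isna(v):
                    out.append(None)
                elif str(v).lower() in _TRISTATE:
                    out.append(_TRISTATE[str(v).lower()])
                elif str(v) in {"True", "False"}:
                    out.append(str(v) == "True")
                else:
                    raise ValidationError(f"bad tri-state flag in {col}: {v!r}")
            df[col] = pd.Series(out, index=df.index, dtype=object)
    if {"tissue", "stage"} <= set(df.columns):
        normals = df["tissue"] == Tissue.NORMAL.value
        staged = normals & df["stage"].notna() & (df["stage"].astype(str) != "NA")
        if staged.any():
            raise ValidationError(
                f"normal-tissue samples carry a stage: {list(df.index[staged])}"
            )
    return df


_IHC_DENSITY_COLS = ["cd3_tc", "cd3_im", "cd8_tc", "cd8_im", "pdcd1_tc", "pdcd1_im"]
_IHC_PCT_COLS = ["cd274_tc_pct", "cd274_ic_pct"]
_INTENSITIES = {"none", "weak", "moderate", "strong"}


def load_ihc_table(path: PathLike) -> pd.DataFrame:
    """Read per-sample IHC measurements (densities in cells/mm², CD274 % and
    intensity grade); validates ranges and intensity labels."""
    df = _read_delimited(path)
    if "sample_id" not in df.columns:
        raise ValidationError("IHC table requires a sample_id column")
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    for col in _IHC_DENSITY_COLS:
        if col in df.columns and (df[col].dropna() < 0).any():
            raise ValidationError(f"negative density in {col}")
    for col in _IHC_PCT_COLS:
        if col in df.columns:
            vals = df[col].dropna()
            if ((vals < 0) | (vals > 100)).any():
                raise ValidationError(f"{col} outside [0, 100]")
    for col in ("cd274_tc_intensity", "cd274_ic_intensity"):
        if col in df.columns:
            bad = set(df[col].dropna().astype(str)) - _INTENSITIES
            if bad:
                raise ValidationError(f"unknown intensity labels: {sorted(bad)}")
    return df


def write_dm_table(dm: DmMatrix, path: PathLike) -> None:
    """Write a Dm matrix as wide TSV (full repr precision, round-trip safe)."""
    out = dm.values.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep="NA", float_format=lambda v: format(v, ".17g"))


def write_reports(
    calls: pd.DataFrame,
    frequencies: pd.DataFrame,
    comparisons: pd.DataFrame,
    out_dir: PathLike,
) -> dict[str, Path]:
    """Write the per-sample call table, frequency tables and comparison table.

    Files are TSV with ``NA`` for missing; empty inputs yield header-only
    files.  Returns the mapping of report name to written path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "calls": out / "sample_calls.tsv",
        "frequencies": out / "frequencies.tsv",
        "comparisons": out / "comparisons.tsv",
    }
    calls.to_csv(paths["calls"], sep="\t", na_rep="NA", index=False)
    frequencies.to_csv(paths["frequencies"], sep="\t", na_rep="NA", index=False)
    comparisons.to_csv(paths["comparisons"], sep="\t", na_rep="NA", index=False)
    return paths
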