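"""Immune cell scoring (ICS), PDCD1/CD274 classification, and the four
tumor-immunity types.

The immune cell score awards one point per stained section — CD3 and CD8, each
in the tumor center (TC) and the invasive margin (IM) — whose lymphocyte
density strictly exceeds a fixed cut-off, giving a 0-4 score dichotomized into
low (0-2) and high (3-4).  The default cut-offs (cells/mm²) come from ROC
analysis against 5-year disease-specific survival in a large colorectal
reference series: CD3 815 / CD8 384 in the tumor center, CD3 1144 / CD8 496 at
the invasive margin; PDCD1 57 (TC) and 38 (IM).

CD274 (PD-L1) staining is positive when the proportion of stained cells with
moderate or strong intensity exceeds 5% (strictly).

Joining the ICS dichotomy with CD274 positivity on immune cells yields the
four canonical tumor-microenvironment types: I high/pos (adaptive immune
resistance), II low/neg (immunological ignorance), III high/neg (tolerance),
IV low/pos (intrinsic induction).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ICSCutoffs",
    "PDCD1Cutoffs",
    "ICSLevel",
    "TengType",
    "ICSResult",
    "compute_ics",
    "classify_pdcd1",
    "classify_cd274",
    "assign_teng_type",
    "score_ihc_table",
    "ics_distribution",
]

CD274_PCT_CUTOFF = 5.0  # strictly greater than
CD274_POSITIVE_INTENSITIES = frozenset({"moderate", "strong"})
ICS_HIGH_MIN_SCORE = 3


@dataclass(frozen=True)
class ICSCutoffs:
    """Density cut-offs (cells/mm²) for the four ICS sections."""

    cd3_tc: float = 815.0
    cd8_tc: float = 384.0
    cd3_im: float = 1144.0
    cd8_im: float = 496.0

    def __post_init__(self) -> None:
        if min(self.cd3_tc, self.cd8_tc, self.cd3_im, self.cd8_im) <= 0:
            raise ValueError("ICS cut-offs must be positive")


@dataclass(frozen=True)
class PDCD1Cutoffs:
    """PDCD1-positive lymphocyte density cut-offs (cells/mm²)."""

    tc: float = 57.0
    im: float = 38.0


class ICSLevel(str, enum.Enum):
    LOW = "LOW"  # scores 0-2
    HIGH = "HIGH"  # scores 3-4


class TengType(str, enum.Enum):
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"


@dataclass(frozen=True)
class ICSResult:
    score: int | None
    level: ICSLevel | None
    reason: str | None = None  # set when the score is not computable


def compute_ics(
    cd3_tc: float,
    cd8_tc: float,
    cd3_im: float,
    cd8_im: float,
    cutoffs: ICSCutoffs = ICSCutoffs(),
) -> ICSResult:
    """Immune cell score from the four section densities.

    One point per density strictly above its cut-off.  Any missing density
    makes the score non-computable (no-call with reason).
    """
    vals = {"cd3_tc": cd3_tc, "cd8_tc": cd8_tc, "cd3_im": cd3_im, "cd8_im": cd8_im}
    missing = [k for k, v in vals.items() if v is None or pd.isna(v)]
    if missing:
        return ICSResult(None, None, reason=f"missing density: {', '.join(missing)}")
    score = sum(
        int(vals[k] > getattr(cutoffs, k)) for k in ("cd3_tc", "cd8_tc", "cd3_im", "cd8_im")
    )
    level = ICSLevel.HIGH if score >= ICS_HIGH_MIN_SCORE else ICSLevel.LOW
    return ICSResult(score, level)


def classify_pdcd1(
    density: float, region: str, cutoffs: PDCD1Cutoffs = PDCD1Cutoffs()
) -> str | None:
    """PDCD1 LOW/HIGH for one region ('tc' or 'im'); strict > at the cut-off.

    Returns None (no-call) on a missing density.
    """
    if region not in ("tc", "im"):
        raise ValueError(f"region must be 'tc' or 'im', got {region!r}")
    if density is None or pd.isna(density):
        return None
    return "HIGH" if density > getattr(cutoffs, region) else "LOW"


def classify_cd274(pct: float, intensity: str) -> str | None:
    """CD274 NEG/POS: positive iff stained-cell percentage exceeds 5 (strict)
    with moderate or strong intensity.  None on missing input."""
    if pct is None or pd.isna(pct) or intensity is None or pd.isna(intensity):
        return None
    positive = pct > CD274_PCT_CUTOFF and str(intensity) in CD274_POSITIVE_INTENSITIES
    return "POS" if positive else "NEG"


_TENG_MAP = {
    (ICSLevel.HIGH, "POS"): TengType.I,
    (ICSLevel.LOW, "NEG"): TengType.II,
    (ICSLevel.HIGH, "NEG"): TengType.III,
    (ICSLevel.LOW, "POS"): TengType.IV,
}


def assign_teng_type(ics_level: ICSLevel | None, cd274_ic: str | None) -> TengType | None:
    """Four-type tumor-immunity class from ICS dichotomy x CD274 on immune
    cells; any no-call input propagates to a no-call type."""
    if ics_level is None or cd274_ic is None:
        return None
    return _TENG_MAP[(ICSLevel(ics_level), cd274_ic)]


def score_ihc_table(
    ihc: pd.DataFrame,
    ics_cutoffs: ICSCutoffs = ICSCutoffs(),
    pdcd1_cutoffs: PDCD1Cutoffs = PDCD1Cutoffs(),
) -> pd.DataFrame:
    """Vectorised per-sample immunoprofile over an IHC table.

    Expects the column layout of :func:`colotype.io.load_ihc_table`; returns a
    DataFrame indexed like ``ihc`` with ics_score, ics_level, pdcd1_tc,
    pdcd1_im, cd274_tc, cd274_ic and teng_type columns (NA = no-call).
    """
    rows = []
    for sample_id, rec in ihc.iterrows():
        ics = compute_ics(
            rec.get("cd3_tc"), rec.get("cd8_tc"), rec.get("cd3_im"), rec.get("cd8_im"),
            ics_cutoffs,
        )
        cd274_tc = classify_cd274(rec.get("cd274_tc_pct"), rec.get("cd274_tc_intensity"))
        cd274_ic = classify_cd274(rec.get("cd274_ic_pct"), rec.get("cd274_ic_intensity"))
        teng = assign_teng_type(ics.level, cd274_ic)
        rows.append(
            {
                "sample_id": sample_id,
                "ics_score": ics.score,
                "ics_level": ics.level.value if ics.level else pd.NA,
                "ics_reason": ics.reason,
                "pdcd1_tc": classify_pdcd1(rec.get("pdcd1_tc"), "tc", pdcd1_cutoffs) or pd.NA,
                "pdcd1_im": classify_pdcd1(rec.get("pdcd1_im"), "im", pdcd1_cutoffs) or pd.NA,
                "cd274_tc": cd274_tc or pd.NA,
                "cd274_ic": cd274_ic or pd.NA,
                "teng_type": teng.value if teng else pd.NA,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def ics_distribution(scores) -> pd.DataFrame:
    """Counts and integer-rounded percentages per ICS score 0-4, plus the
    low/high dichotomy rows."""
    scores = pd.Series(list(scores)).dropna().astype(int)
    if scores.empty:
        raise ValueError("no ICS scores")
    if not scores.between(0, 4).all():
        raise ValueError("ICS scores must be in 0..4")
    n = int(scores.size)
    rows = []
    for s in range(5):
        k = int((scores == s).sum())
        rows.append({"category": f"ics_{s}", "count": k, "pct": round(100 * k / n)})
    low = int((scores <= 2).sum())
    high = n - low
    rows.append({"category": "ics_low", "count": low, "pct": round(100 * low / n)})
    rows.append({"category": "ics_high", "count": high, "pct": round(100 * high / n)})
    return pd.DataFrame(rows)
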