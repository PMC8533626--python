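"""MSI calling from mononucleotide markers and mutation-burden grouping.

MSI is called from the BAT25/BAT26 marker pair: at least one unstable marker
diagnoses MSI; all observed markers stable gives MSS; no observed marker gives
UNKNOWN.  Hypermutated means strictly more than 10 nonsynonymous somatic
mutations per megabase; rates at or above 100/Mb additionally carry an
"ultramutated-range" annotation (an annotation, not a separate group).

The joint MSI x burden classification defines three molecular groups:
G1 hypermutated-MSI, G2 hypermutated-MSS, G3 non-hypermutated-MSS.  The
combination non-hypermutated MSI, and any unknown input, is UNGROUPED.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "MSIStatus",
    "BurdenClass",
    "MolecularGroup",
    "BurdenCall",
    "call_msi",
    "classify_burden",
    "assign_group",
    "group_table",
]

HYPERMUTATION_CUTOFF = 10.0  # strictly greater, mutations/Mb
ULTRAMUTATED_CUTOFF = 100.0  # annotation threshold, mutations/Mb


class MSIStatus(str, enum.Enum):
    MSI = "MSI"
    MSS = "MSS"
    UNKNOWN = "UNKNOWN"


class BurdenClass(str, enum.Enum):
    NON_HYPERMUTATED = "NON_HYPERMUTATED"
    HYPERMUTATED = "HYPERMUTATED"
    UNKNOWN = "UNKNOWN"


class MolecularGroup(str, enum.Enum):
    G1_HYPER_MSI = "G1_HYPER_MSI"
    G2_HYPER_MSS = "G2_HYPER_MSS"
    G3_NONHYPER_MSS = "G3_NONHYPER_MSS"
    UNGROUPED = "UNGROUPED"


def call_msi(bat25_unstable: bool | None, bat26_unstable: bool | None) -> MSIStatus:
    """MSI status from the two marker flags (True unstable / False stable /
    None not assessed)."""
    observed = [f for f in (bat25_unstable, bat26_unstable) if f is not None]
    if not observed:
        return MSIStatus.UNKNOWN
    return MSIStatus.MSI if any(observed) else MSIStatus.MSS


@dataclass(frozen=True)
class BurdenCall:
    burden_class: BurdenClass
    ultramutated_range: bool = False


def classify_burden(nonsyn_mut_per_mb: float | None) -> BurdenCall:
    """Hypermutation class from the nonsynonymous mutation rate."""
    if nonsyn_mut_per_mb is None or pd.isna(nonsyn_mut_per_mb):
        return BurdenCall(BurdenClass.UNKNOWN)
    if nonsyn_mut_per_mb < 0:
        raise ValueError("mutation rate must be non-negative")
    cls = (
        BurdenClass.HYPERMUTATED
        if nonsyn_mut_per_mb > HYPERMUTATION_CUTOFF
        else BurdenClass.NON_HYPERMUTATED
    )
    return BurdenCall(cls, ultramutated_range=nonsyn_mut_per_mb >= ULTRAMUTATED_CUTOFF)


_GROUP_MAP = {
    (MSIStatus.MSI, BurdenClass.HYPERMUTATED): MolecularGroup.G1_HYPER_MSI,
    (MSIStatus.MSS, BurdenClass.HYPERMUTATED): MolecularGroup.G2_HYPER_MSS,
    (MSIStatus.MSS, BurdenClass.NON_HYPERMUTATED): MolecularGroup.G3_NONHYPER_MSS,
}


def assign_group(msi_status: MSIStatus, burden_class: BurdenClass) -> MolecularGroup:
    """Deterministic MSI x burden mapping; non-hypermutated MSI and unknown
    inputs fall outside the three groups (UNGROUPED)."""
    return _GROUP_MAP.get(
        (MSIStatus(msi_status), BurdenClass(burden_class)), MolecularGroup.UNGROUPED
    )


def group_table(meta: pd.DataFrame) -> pd.DataFrame:
    """Per-sample molecular grouping from a metadata table.

    Uses columns ``bat25_unstable``, ``bat26_unstable`` (tri-state) and
    ``nonsyn_mut_per_mb``; returns sample_id-indexed msi_status, burden_class,
    ultramutated_range and group columns.
    """
    rows = []
    for sample_id, rec in meta.iterrows():
        msi = call_msi(rec.get("bat25_unstable"), rec.get("bat26_unstable"))
        burden = classify_burden(rec.get("nonsyn_mut_per_mb"))
        rows.append(
            {
                "sample_id": sample_id,
                "msi_status": msi.value,
                "burden_class": burden.burden_class.value,
                "ultramutated_range": burden.ultramutated_range,
                "group": assign_group(msi, burden.burden_class).value,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")
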