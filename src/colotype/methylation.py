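"""Normal-reference thresholding and hypermethylation calling.

The calling cascade has three levels:

1. *Probe level* — a probe is methylated in a sample when its methylation
   dosage ratio (Dm) is at or above a probe-specific threshold.  The threshold
   is the mean Dm of reference normal mucosae plus two (sample) standard
   deviations, clamped up to the assay's technical floor (0.15 by default)
   when the reference-derived value falls below it.
2. *Gene level* — a gene is hypermethylated when at least one-fourth of its
   observed probes are methylated.
3. *Sample level (CIMP)* — a tumor is CIMP-positive when at least 3 of the 5
   score genes (CACNA1G, IGF2, NEUROG1, RUNX3, SOCS1) are hypermethylated
   (Weisenberger criterion).

All threshold comparisons are inclusive ("equal to or higher" counts as
methylated); the same convention defines the continuous hyper-/normo-/hypo-
methylated subgroups at gene level (mean ± 2 SD of the normal reference,
boundaries inclusive).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import DmMatrix
from .panels import Panel, PanelDef

__all__ = [
    "CIMPStatus",
    "MethSubgroup",
    "derive_thresholds",
    "call_probe_methylation",
    "call_gene_hypermethylation",
    "call_cimp",
    "gene_dm",
    "gene_reference_stats",
    "classify_meth_subgroup",
    "hypermethylation_frequency",
]

GENE_CALL_FRACTION = 0.25  # >= 1/4 of observed probes methylated
CIMP_MIN_SCORE = 3  # >= 3/5 score genes methylated
LOW_COVERAGE_FRACTION = 0.5  # flag gene calls made on < half the panel probes


class CIMPStatus(str, enum.Enum):
    CIMP_POS = "CIMP_POS"
    CIMP_NEG = "CIMP_NEG"
    INDETERMINATE = "INDETERMINATE"


class MethSubgroup(str, enum.Enum):
    HYPER = "HYPER"
    NORMO = "NORMO"
    HYPO = "HYPO"


def derive_thresholds(
    normals: DmMatrix, panel: PanelDef, min_normals: int = 2
) -> pd.DataFrame:
    """Per-probe hypermethylation thresholds from a normal-reference cohort.

    Returns a DataFrame indexed by probe_id with columns ``mean_normal``,
    ``sd_normal`` (sample SD, ddof=1), ``threshold``
    (= max(mean + 2*SD, technical_floor)), ``n_normals`` and ``usable``.
    Probes with fewer than ``min_normals`` non-missing reference values are
    flagged unusable and get no threshold.

    Raises ``ValueError`` on an empty reference cohort.
    """
    if normals.values.shape[0] == 0:
        raise ValueError("empty normal reference cohort")
    rows = []
    for probe in panel.probes:
        if probe.probe_id in normals.values.columns:
            vals = normals.values[probe.probe_id].dropna().to_numpy(float)
        else:
            vals = np.array([])
        n = vals.size
        if n >= min_normals:
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1))
            thr = max(mean + 2.0 * sd, probe.technical_floor)
            usable = True
        else:
            mean = float(vals.mean()) if n else np.nan
            sd = np.nan
            thr = np.nan
            usable = False
        rows.append(
            {
                "probe_id": probe.probe_id,
                "mean_normal": mean,
                "sd_normal": sd,
                "threshold": thr,
                "n_normals": n,
                "usable": usable,
            }
        )
    return pd.DataFrame(rows).set_index("probe_id")


def call_probe_methylation(dm: DmMatrix, thresholds: pd.DataFrame) -> pd.DataFrame:
    """Binary probe-level calls: 1.0 methylated (Dm >= threshold, boundary
    inclusive), 0.0 unmethylated, NaN missing Dm or unusable probe.

    Raises ``KeyError`` if any probe in ``dm`` has no row in ``thresholds``.
    """
    missing = [p for p in dm.values.columns if p not in thresholds.index]
    if missing:
        raise KeyError(f"probes without thresholds: {missing}")
    thr = thresholds.loc[dm.values.columns, "threshold"]
    calls = (dm.values >= thr).astype(float)
    calls[dm.values.isna() | thr.isna()] = np.nan
    return calls


def call_gene_hypermethylation(
    probe_calls: pd.DataFrame, panel: PanelDef
) -> pd.DataFrame:
    """Gene-level hypermethylation calls from a binary probe-call matrix.

    A gene is hypermethylated when methylated probes make up at least
    ``GENE_CALL_FRACTION`` of its *observed* probes.  Genes with no observed
    probes get no call (``hypermethylated`` = NA).  Calls resting on fewer
    than half the gene's panel probes are flagged ``low_coverage``.

    Returns a long DataFrame: sample_id, gene, panel, n_probes_panel,
    n_probes_observed, n_probes_methylated, hypermethylated, low_coverage.
    """
    gene_probes = panel.gene_to_probe_ids()
    gene_panel = {p.gene: p.panel.value for p in panel.probes}
    rows = []
    for sample_id, sample_calls in probe_calls.iterrows():
        for gene, probes in gene_probes.items():
            present = [p for p in probes if p in sample_calls.index]
            vals = sample_calls[present].dropna()
            n_obs = int(vals.size)
            n_meth = int(vals.sum())
            if n_obs == 0:
                hyper = pd.NA
                lowcov = True
            else:
                hyper = (n_meth / n_obs) >= GENE_CALL_FRACTION
                lowcov = n_obs < LOW_COVERAGE_FRACTION * len(probes)
            rows.append(
                {
                    "sample_id": sample_id,
                    "gene": gene,
                    "panel": gene_panel[gene],
                    "n_probes_panel": len(probes),
                    "n_probes_observed": n_obs,
                    "n_probes_methylated": n_meth,
                    "hypermethylated": hyper,
                    "low_coverage": lowcov,
                }
            )
    out = pd.DataFrame(rows)
    out["hypermethylated"] = out["hypermethylated"].astype("boolean")
    return out


def call_cimp(gene_calls: pd.DataFrame, panel: PanelDef) -> pd.DataFrame:
    """CIMP status per sample from gene-level calls.

    Only the 5 score genes enter the count; the other CIMP-panel genes never
    do.  CIMP_POS when >= 3 score genes are hypermethylated; a sample with any
    uncalled score gene (no observed probes) is INDETERMINATE.

    Returns a DataFrame: sample_id, n_score_genes_called,
    n_score_genes_methylated, status.
    """
    score_genes = panel.cimp_score_genes
    sub = gene_calls[gene_calls["gene"].isin(score_genes)]
    rows = []
    for sample_id, grp in sub.groupby("sample_id", sort=False):
        called = grp["hypermethylated"].dropna()
        n_called = int(called.size)
        n_meth = int(called.sum())
        if n_called < len(score_genes):
            status = CIMPStatus.INDETERMINATE
        elif n_meth >= CIMP_MIN_SCORE:
            status = CIMPStatus.CIMP_POS
        else:
            status = CIMPStatus.CIMP_NEG
        rows.append(
            {
                "sample_id": sample_id,
                "n_score_genes_called": n_called,
                "n_score_genes_methylated": n_meth,
                "status": status.value,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "n_score_genes_called",
            "n_score_genes_methylated",
            "status",
        ],
    )


def gene_dm(dm: DmMatrix, panel: PanelDef, gene: str) -> pd.Series:
    """Per-sample gene-level Dm: arithmetic mean over the gene's observed
    probes; NaN when no probe is observed."""
    probes = [p.probe_id for p in panel.probes_for_gene(gene)]
    if not probes:
        raise KeyError(f"gene not in panel: {gene}")
    present = [p for p in probes if p in dm.values.columns]
    if not present:
        return pd.Series(np.nan, index=dm.values.index, name=gene)
    return dm.values[present].mean(axis=1, skipna=True).rename(gene)


def gene_reference_stats(normals: DmMatrix, panel: PanelDef) -> pd.DataFrame:
    """Gene-level normal-reference mean/SD of Dm (for subgroup classification).

    Gene-level Dm is the mean over observed probes per sample; the reference
    statistics are mean and sample SD of those per-sample values.
    """
    rows = []
    for gene in panel.genes():
        vals = gene_dm(normals, panel, gene).dropna()
        rows.append(
            {
                "gene": gene,
                "mean_normal": float(vals.mean()) if vals.size else np.nan,
                "sd_normal": float(vals.std(ddof=1)) if vals.size >= 2 else np.nan,
                "n_normals": int(vals.size),
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def classify_meth_subgroup(
    gene_dm_value: float, mean_normal: float, sd_normal: float
) -> MethSubgroup | None:
    """HYPER / NORMO / HYPO relative to the normal reference, mean ± 2 SD,
    boundaries inclusive.  Returns None when the value or reference is
    missing."""
    if any(pd.isna(v) for v in (gene_dm_value, mean_normal, sd_normal)):
        return None
    # inclusive boundaries up to floating-point noise in mean +/- 2*sd
    eps = 1e-12 * max(1.0, abs(mean_normal) + 2.0 * sd_normal)
    if gene_dm_value >= mean_normal + 2.0 * sd_normal - eps:
        return MethSubgroup.HYPER
    if gene_dm_value <= mean_normal - 2.0 * sd_normal + eps:
        return MethSubgroup.HYPO
    return MethSubgroup.NORMO


@dataclass(frozen=True)
class Frequency:
    """A hypermethylation frequency with its counts."""

    numerator: int
    denominator: int

    @property
    def fraction(self) -> float:
        return self.numerator / self.denominator


def hypermethylation_frequency(gene_calls: pd.DataFrame, gene: str) -> Frequency:
    """Fraction of called samples hypermethylated for ``gene``.

    Raises ``ValueError`` when no sample carries a call for the gene.
    """
    sub = gene_calls[gene_calls["gene"] == gene]["hypermethylated"].dropna()
    if sub.empty:
        raise ValueError(f"no samples with a call for {gene}")
    return Frequency(numerator=int(sub.sum()), denominator=int(sub.size))
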