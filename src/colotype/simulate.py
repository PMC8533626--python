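"""Synthetic cohort generation.

Produces complete, reproducible cohorts — Dm matrices, IHC tables and sample
metadata in exactly the dialects the loaders read — with the statistical
structure the analysis assumes: per-probe normal-reference methylation around
a low baseline, CIMP-positive tumors with coordinated score-gene
hypermethylation, an additive "field defect" shift in the normal mucosa of
colitis-associated patients, immune-marker densities straddling the ICS
cut-offs, and a mutation-burden mixture spanning the non-hypermutated,
hypermutated and ultramutated ranges.

Default group sizes and effect scales mirror the study conditions the package
models: 31 colitis-associated carcinomas with 17 paired normals; 14 Lynch
adenomas, 15 Lynch carcinomas, 11 Lynch normals; NTSR1 normal-mucosa Dm of
0.21 +/- 0.15 in Lynch patients shifted by +0.08 in colitis-associated
patients; CIMP-positive tumor fractions 0.39 (colitis-associated) and 0.24
(Lynch); ICS-high probability 0.55; CD274 immune-cell positivity 0.52.

Dm values are drawn from Gaussians truncated to [0, 1.2] (the generator's
distributional family; only means/SDs are scientifically constrained).
Ground-truth labels are emitted in a sidecar table the pipeline never reads.

Seeding: one master seed; each output table draws from its own deterministic
substream, so adding a table does not perturb the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import Cohort, DmMatrix, Tissue, write_dm_table
from .panels import CIMP_SCORE_GENES, PanelDef, default_panel

__all__ = ["CohortConfig", "SimulatedCohort", "generate_cohort"]

DM_BOUNDS = (0.0, 1.2)


def _default_group_sizes() -> dict[tuple[str, str], int]:
    return {
        (Cohort.CA_CRC.value, Tissue.NORMAL.value): 17,
        (Cohort.CA_CRC.value, Tissue.CARCINOMA.value): 31,
        (Cohort.LS.value, Tissue.NORMAL.value): 11,
        (Cohort.LS.value, Tissue.ADENOMA.value): 14,
        (Cohort.LS.value, Tissue.CARCINOMA.value): 15,
    }


def _default_normal_dm() -> dict[str, tuple[float, float]]:
    # gene -> (mean, sd) of normal-mucosa Dm; NTSR1 at the Lynch-normal scale,
    # CIMP markers and the rest at a low baseline under the technical floor
    return {"NTSR1": (0.21, 0.15), "__default__": (0.05, 0.03)}


def _default_hyper_probs() -> dict[str, float]:
    # per-gene probability that a tumor carries the hypermethylation shift
    # (inflammation panel; scaled to the frequently-methylated genes)
    return {
        "NTSR1": 0.42,
        "SOCS2": 0.35,
        "SOCS1_custom": 0.32,
        "PTGS2": 0.20,
        "PYCARD": 0.10,
        "CD274": 0.10,
        "PPARG": 0.10,
        "__default__": 0.10,
    }


@dataclass(frozen=True)
class CohortConfig:
    """All knobs of the generator; defaults are the modelled study conditions."""

    group_sizes: dict[tuple[str, str], int] = field(default_factory=_default_group_sizes)
    normal_dm: dict[str, tuple[float, float]] = field(default_factory=_default_normal_dm)
    #: additive Dm shift in CA-CRC normal mucosa (field defect), applied to
    #: NTSR1 and all CIMP marker genes except MLH1
    field_defect_shift: float = 0.08
    #: fraction of tumors that are CIMP-positive, per cohort
    cimp_pos_fraction: dict[str, float] = field(
        default_factory=lambda: {Cohort.CA_CRC.value: 0.39, Cohort.LS.value: 0.24}
    )
    #: Dm shift added to a hypermethylated gene in a tumor
    tumor_hyper_shift: float = 0.40
    #: probability a score gene is hypermethylated in a CIMP+ / CIMP- tumor
    cimp_gene_prob: tuple[float, float] = (0.85, 0.12)
    inflammation_hyper_probs: dict[str, float] = field(default_factory=_default_hyper_probs)
    #: probability an NTSR1 tumor is in the hypomethylated subset, and its shift
    ntsr1_hypo_prob: float = 0.13
    ntsr1_hypo_shift: float = -0.15
    #: immune profile probabilities (tumors only)
    ics_high_prob: float = 0.55
    cd274_ic_pos_prob: float = 0.52
    cd274_tc_pos_prob: float = 0.0
    pdcd1_tc_high_prob: float = 0.58
    pdcd1_im_high_prob: float = 0.68
    #: section-high probabilities given the latent immune-active state
    section_high_prob: tuple[float, float] = (0.9, 0.15)
    #: mutation burden mixture: (weight, low, high) per component, tumors with
    #: sequencing data only
    burden_mixture: tuple[tuple[float, float, float], ...] = (
        (17 / 27, 1.0, 10.0),
        (8 / 27, 10.5, 60.0),
        (2 / 27, 85.0, 120.0),
    )
    sequenced_fraction: float = 27 / 31
    #: probability a tumor is MSI, per cohort
    msi_prob: dict[str, float] = field(
        default_factory=lambda: {Cohort.CA_CRC.value: 1 / 31, Cohort.LS.value: 1.0}
    )
    male_prob: float = 0.55
    age_mean: float = 51.4
    age_sd: float = 11.0

    def __post_init__(self) -> None:
        probs = [
            self.ics_high_prob,
            self.cd274_ic_pos_prob,
            self.cd274_tc_pos_prob,
            self.pdcd1_tc_high_prob,
            self.pdcd1_im_high_prob,
            self.ntsr1_hypo_prob,
            *self.cimp_pos_fraction.values(),
            *self.msi_prob.values(),
            *self.cimp_gene_prob,
            *self.inflammation_hyper_probs.values(),
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if any(n < 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be non-negative")

    def scaled(self, factor: int) -> "CohortConfig":
        """Same conditions with every group size multiplied by ``factor``."""
        return replace(
            self,
            group_sizes={k: n * factor for k, n in self.group_sizes.items()},
        )


@dataclass
class SimulatedCohort:
    dm: DmMatrix
    ihc: pd.DataFrame
    meta: pd.DataFrame
    truth: pd.DataFrame
    panel: PanelDef

    def write(self, out_dir) -> dict[str, Path]:
        """Write the cohort in the pipeline's input dialects (plus the
        ground-truth sidecar, which the pipeline never reads)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "dm": out / "dm.tsv",
            "ihc": out / "ihc.tsv",
            "meta": out / "meta.tsv",
            "truth": out / "truth.tsv",
            "panel": out / "panel.tsv",
        }
        write_dm_table(self.dm, paths["dm"])
        self.ihc.to_csv(paths["ihc"], sep="\t", na_rep="NA")
        self.meta.to_csv(paths["meta"], sep="\t", na_rep="NA")
        self.truth.to_csv(paths["truth"], sep="\t", na_rep="NA")
        pd.DataFrame(
            {
                "probe_id": [p.probe_id for p in self.panel.probes],
                "gene": [p.gene for p in self.panel.probes],
                "panel": [p.panel.value for p in self.panel.probes],
                "probe_index": [p.probe_index for p in self.panel.probes],
                "technical_floor": [p.technical_floor for p in self.panel.probes],
            }
        ).to_csv(paths["panel"], sep="\t", index=False)
        return paths


def _truncnorm(rng: np.random.Generator, mean, sd, size, bounds=DM_BOUNDS):
    """Gaussian draws truncated to ``bounds`` by redrawing (vectorised)."""
    lo, hi = bounds
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    # redraw a bounded number of times, then clip the stragglers
    for _ in range(20):
        if not bad.any():
            break
        out[bad] = rng.normal(
            mean if np.isscalar(mean) else np.broadcast_to(mean, out.shape)[bad],
            sd if np.isscalar(sd) else np.broadcast_to(sd, out.shape)[bad],
            int(bad.sum()),
        )
        bad = (out < lo) | (out > hi)
    return np.clip(out, lo, hi)


def _substream(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def generate_cohort(
    config: CohortConfig = CohortConfig(),
    seed: int = 0,
    panel: PanelDef | None = None,
) -> SimulatedCohort:
    """Generate a full synthetic cohort under ``config``.

    Paired design: every normal-mucosa sample shares its ``patient_id`` with a
    tumor of the same cohort where one exists.  Returns in-memory tables; use
    :meth:`SimulatedCohort.write` for the on-disk dialects.
    """
    if panel is None:
        panel = default_panel()
    rng_meta = _substream(seed, 0)
    rng_dm = _substream(seed, 1)
    rng_ihc = _substream(seed, 2)

    cimp_genes_shifted = {
        g for g in CIMP_SCORE_GENES | {"CDKN2A", "CRABP1"}
    }  # field defect spares MLH1
    field_genes = cimp_genes_shifted | {"NTSR1"}

    # ---- metadata and latent truth ----------------------------------------
    meta_rows = []
    truth_rows = []
    sample_counter = 0
    for (cohort, tissue), n in sorted(config.group_sizes.items()):
        is_tumor = tissue != Tissue.NORMAL.value
        for i in range(n):
            sample_counter += 1
            sid = f"S{sample_counter:05d}"
            pid = f"{cohort}_P{i + 1:05d}"  # pairs normals with tumors by index
            age = float(np.round(rng_meta.normal(config.age_mean, config.age_sd), 1))
            sex = "M" if rng_meta.random() < config.male_prob else "F"
            row = {
                "sample_id": sid,
                "patient_id": pid,
                "cohort": cohort,
                "tissue": tissue,
                "age": age,
                "sex": sex,
                "stage": None,
                "location": rng_meta.choice(["PROXIMAL", "DISTAL"]),
                "bat25_unstable": None,
                "bat26_unstable": None,
                "nonsyn_mut_per_mb": None,
                "tumor_cell_fraction": None,
            }
            truth = {
                "sample_id": sid,
                "true_cimp_pos": False,
                "true_field_defect": False,
                "true_ics_high": None,
                "true_teng_type": None,
            }
            if is_tumor:
                row["stage"] = rng_meta.choice(["I", "II", "III", "IV"], p=[0.45, 0.2, 0.25, 0.1])
                row["tumor_cell_fraction"] = float(
                    np.round(np.clip(rng_meta.normal(0.46, 0.13), 0.1, 0.9), 2)
                )
                msi = rng_meta.random() < config.msi_prob.get(cohort, 0.0)
                b25 = bool(msi and rng_meta.random() < 0.9)
                b26 = bool(msi and rng_meta.random() < 0.9)
                if msi and not (b25 or b26):
                    b25 = True  # MSI requires at least one unstable marker
                row["bat25_unstable"] = b25
                row["bat26_unstable"] = b26
                if rng_meta.random() < config.sequenced_fraction:
                    weights = [w for w, _, _ in config.burden_mixture]
                    comp = rng_meta.choice(len(weights), p=np.asarray(weights) / sum(weights))
                    _, lo, hi = config.burden_mixture[comp]
                    row["nonsyn_mut_per_mb"] = float(np.round(rng_meta.uniform(lo, hi), 1))
                truth["true_cimp_pos"] = bool(
                    rng_meta.random() < config.cimp_pos_fraction.get(cohort, 0.0)
                )
            else:
                truth["true_field_defect"] = (
                    cohort == Cohort.CA_CRC.value and config.field_defect_shift != 0.0
                )
            meta_rows.append(row)
            truth_rows.append(truth)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    truth = pd.DataFrame(truth_rows).set_index("sample_id")

    # ---- methylation ------------------------------------------------------
    def normal_params(gene: str) -> tuple[float, float]:
        return config.normal_dm.get(gene, config.normal_dm["__default__"])

    dm = pd.DataFrame(
        index=meta.index, columns=[p.probe_id for p in panel.probes], dtype=float
    )
    for sid, mrow in meta.iterrows():
        is_tumor = mrow["tissue"] != Tissue.NORMAL.value
        is_ca_normal = (
            mrow["tissue"] == Tissue.NORMAL.value and mrow["cohort"] == Cohort.CA_CRC.value
        )
        cimp_pos = bool(truth.loc[sid, "true_cimp_pos"])
        gene_shift: dict[str, float] = {}
        for gene in panel.genes():
            shift = 0.0
            if is_ca_normal and gene in field_genes:
                shift += config.field_defect_shift
            if is_tumor:
                probes_panel = panel.probes_for_gene(gene)[0].panel.value
                if probes_panel == "CIMP":
                    p_hyper = config.cimp_gene_prob[0 if cimp_pos else 1]
                else:
                    p_hyper = config.inflammation_hyper_probs.get(
                        gene, config.inflammation_hyper_probs["__default__"]
                    )
                if rng_dm.random() < p_hyper:
                    shift += config.tumor_hyper_shift
                elif gene == "NTSR1" and rng_dm.random() < config.ntsr1_hypo_prob:
                    shift += config.ntsr1_hypo_shift
            gene_shift[gene] = shift
        means = np.array(
            [normal_params(p.gene)[0] + gene_shift[p.gene] for p in panel.probes]
        )
        sds = np.array([normal_params(p.gene)[1] for p in panel.probes])
        dm.loc[sid] = _truncnorm(rng_dm, means, sds, len(panel.probes))

    # ---- IHC (tumors only) ------------------------------------------------
    from .immune import ICSCutoffs, PDCD1Cutoffs

    ics_cut = ICSCutoffs()
    pdcd1_cut = PDCD1Cutoffs()
    ihc_rows = []
    for sid, mrow in meta.iterrows():
        if mrow["tissue"] == Tissue.NORMAL.value:
            continue
        active = rng_ihc.random() < config.ics_high_prob
        truth.loc[sid, "true_ics_high"] = bool(active)
        p_hi = config.section_high_prob[0 if active else 1]

        def density(cutoff: float) -> float:
            high = rng_ihc.random() < p_hi
            scale = rng_ihc.lognormal(mean=np.log(1.8 if high else 0.45), sigma=0.25)
            return float(np.round(cutoff * scale, 1))

        cd274_ic = rng_ihc.random() < config.cd274_ic_pos_prob
        cd274_tc = rng_ihc.random() < config.cd274_tc_pos_prob
        truth.loc[sid, "true_teng_type"] = {
            (True, True): "I",
            (False, False): "II",
            (True, False): "III",
            (False, True): "IV",
        }[(active, cd274_ic)]
        ihc_rows.append(
            {
                "sample_id": sid,
                "cd3_tc": density(ics_cut.cd3_tc),
                "cd8_tc": density(ics_cut.cd8_tc),
                "cd3_im": density(ics_cut.cd3_im),
                "cd8_im": density(ics_cut.cd8_im),
                "pdcd1_tc": float(
                    np.round(
                        pdcd1_cut.tc
                        * rng_ihc.lognormal(
                            np.log(2.0 if rng_ihc.random() < config.pdcd1_tc_high_prob else 0.4),
                            0.3,
                        ),
                        1,
                    )
                ),
                "pdcd1_im": float(
                    np.round(
                        pdcd1_cut.im
                        * rng_ihc.lognormal(
                            np.log(2.0 if rng_ihc.random() < config.pdcd1_im_high_prob else 0.4),
                            0.3,
                        ),
                        1,
                    )
                ),
                "cd274_tc_pct": float(np.round(rng_ihc.uniform(6, 60) if cd274_tc else rng_ihc.uniform(0, 4), 1)),
                "cd274_tc_intensity": "moderate" if cd274_tc else "weak",
                "cd274_ic_pct": float(np.round(rng_ihc.uniform(6, 60) if cd274_ic else rng_ihc.uniform(0, 4), 1)),
                "cd274_ic_intensity": rng_ihc.choice(["moderate", "strong"]) if cd274_ic else "weak",
            }
        )
    ihc_cols = [
        "sample_id", "cd3_tc", "cd8_tc", "cd3_im", "cd8_im", "pdcd1_tc",
        "pdcd1_im", "cd274_tc_pct", "cd274_tc_intensity", "cd274_ic_pct",
        "cd274_ic_intensity",
    ]
    ihc = pd.DataFrame(ihc_rows, columns=ihc_cols).set_index("sample_id")

    return SimulatedCohort(dm=DmMatrix(dm), ihc=ihc, meta=meta, truth=truth, panel=panel)
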