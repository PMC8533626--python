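"""End-to-end orchestration: inputs -> thresholds -> calls -> immunoprofiles
-> molecular groups -> cohort comparisons -> reports.

A run is driven by a single YAML config (see :func:`run`) and writes TSV
reports plus a JSON manifest recording config hash, input digests, seed,
version and per-stage record counts.  Failures inside an individual
comparison are recorded as errored rows rather than aborting the run; missing
inputs or an impossible threshold stage fail fast with the stage name.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genomics import group_table
from .immune import ICSCutoffs, PDCD1Cutoffs, score_ihc_table
from .io import (
    Cohort,
    DmMatrix,
    Tissue,
    load_dm_table,
    load_ihc_table,
    load_panel,
    load_sample_meta,
    write_reports,
)
from .methylation import (
    call_cimp,
    call_gene_hypermethylation,
    call_probe_methylation,
    classify_meth_subgroup,
    derive_thresholds,
    gene_dm,
    gene_reference_stats,
)
from .panels import PanelDef
from .simulate import CohortConfig, generate_cohort
from .stats import bonferroni, compare_groups, fisher_2x2

log = logging.getLogger("colotype")

__all__ = ["PipelineError", "RunResult", "run", "classify_samples"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunResult:
    calls: pd.DataFrame
    thresholds: pd.DataFrame
    frequencies: pd.DataFrame
    comparisons: pd.DataFrame
    manifest: dict
    out_dir: Path | None = None


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _load_inputs(cfg: dict, seed: int):
    if "simulate" in cfg:
        overrides = dict(cfg["simulate"].get("config") or {})
        if "group_sizes" in overrides and not isinstance(
            next(iter(overrides["group_sizes"])), tuple
        ):
            # YAML-friendly form: list of [cohort, tissue, n]
            overrides["group_sizes"] = {
                (str(c), str(t)): int(n) for c, t, n in overrides["group_sizes"]
            }
        sim_cfg = CohortConfig(**overrides)
        cohort = generate_cohort(sim_cfg, seed=seed)
        return cohort.panel, cohort.dm, cohort.ihc, cohort.meta, {}
    inputs = cfg.get("inputs")
    if not inputs:
        raise PipelineError("inputs", "config needs an 'inputs' or 'simulate' section")
    digests = {}
    for key in ("panel", "dm", "meta"):
        if key not in inputs:
            raise PipelineError("inputs", f"missing input path: {key}")
        p = Path(inputs[key])
        if not p.exists():
            raise PipelineError("inputs", f"input file not found: {p}")
        digests[key] = _digest(p)
    panel = load_panel(inputs["panel"])
    dm = load_dm_table(inputs["dm"], panel)
    meta = load_sample_meta(inputs["meta"])
    ihc = None
    if "ihc" in inputs:
        p = Path(inputs["ihc"])
        if not p.exists():
            raise PipelineError("inputs", f"input file not found: {p}")
        digests["ihc"] = _digest(p)
        ihc = load_ihc_table(inputs["ihc"])
    return panel, dm, ihc, meta, digests


def classify_samples(
    panel: PanelDef,
    dm: DmMatrix,
    meta: pd.DataFrame,
    ihc: pd.DataFrame | None = None,
    pooled_reference: bool = False,
    ics_cutoffs: ICSCutoffs = ICSCutoffs(),
    pdcd1_cutoffs: PDCD1Cutoffs = PDCD1Cutoffs(),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-sample classification across all rule sets.

    Thresholds are derived from the normal mucosae of each sample's own
    cohort by default (``pooled_reference=True`` pools all normals).  Returns
    (per-sample call table, threshold table, gene-level call table).
    """
    meta = meta.loc[[s for s in dm.sample_ids if s in meta.index]]
    normals_mask = meta["tissue"] == Tissue.NORMAL.value
    if not normals_mask.any():
        raise PipelineError("thresholds", "no normal-mucosa samples to derive thresholds")

    cohorts = sorted(meta["cohort"].dropna().unique())
    thr_frames = []
    gene_call_frames = []
    subgroup_frames = []
    gene_dm_frames = []
    cimp_frames = []
    for cohort in cohorts:
        in_cohort = meta.index[meta["cohort"] == cohort]
        if pooled_reference:
            ref_ids = meta.index[normals_mask]
        else:
            ref_ids = meta.index[normals_mask & (meta["cohort"] == cohort)]
        if len(ref_ids) == 0:
            raise PipelineError(
                "thresholds", f"no normal reference samples for cohort {cohort}"
            )
        ref = dm.subset(ref_ids)
        thresholds = derive_thresholds(ref, panel)
        thr = thresholds.reset_index()
        thr.insert(0, "cohort", cohort)
        thr_frames.append(thr)

        cohort_dm = dm.subset(in_cohort)
        probe_calls = call_probe_methylation(cohort_dm, thresholds)
        gene_calls = call_gene_hypermethylation(probe_calls, panel)
        gene_call_frames.append(gene_calls)
        cimp_frames.append(call_cimp(gene_calls, panel))

        ref_stats = gene_reference_stats(ref, panel)
        for gene in panel.genes():
            gdm = gene_dm(cohort_dm, panel, gene)
            gene_dm_frames.append(
                pd.DataFrame(
                    {"sample_id": gdm.index, "gene": gene, "gene_dm": gdm.values}
                )
            )
            mean_n = ref_stats.loc[gene, "mean_normal"]
            sd_n = ref_stats.loc[gene, "sd_normal"]
            subgroups = [
                (sg.value if sg is not None else pd.NA)
                for sg in (classify_meth_subgroup(v, mean_n, sd_n) for v in gdm)
            ]
            subgroup_frames.append(
                pd.DataFrame(
                    {"sample_id": gdm.index, "gene": gene, "subgroup": subgroups}
                )
            )

    thresholds_all = pd.concat(thr_frames, ignore_index=True)
    gene_calls_all = pd.concat(gene_call_frames, ignore_index=True)
    cimp_all = pd.concat(cimp_frames, ignore_index=True).set_index("sample_id")
    gene_dm_all = pd.concat(gene_dm_frames, ignore_index=True)
    subgroups_all = pd.concat(subgroup_frames, ignore_index=True)

    groups = group_table(meta)
    calls = meta.copy()
    calls["cimp_status"] = cimp_all["status"]
    calls["n_cimp_score_genes_methylated"] = cimp_all["n_score_genes_methylated"]
    calls = calls.join(groups[["msi_status", "burden_class", "ultramutated_range", "group"]])
    if ihc is not None and len(ihc):
        profile = score_ihc_table(ihc, ics_cutoffs, pdcd1_cutoffs)
        calls = calls.join(profile.drop(columns=["ics_reason"]))

    gene_long = gene_calls_all.merge(gene_dm_all, on=["sample_id", "gene"], how="left")
    gene_long = gene_long.merge(subgroups_all, on=["sample_id", "gene"], how="left")
    return calls.reset_index(), thresholds_all, gene_long


def _frequency_tables(calls: pd.DataFrame, gene_long: pd.DataFrame) -> pd.DataFrame:
    meta_cols = calls.set_index("sample_id")[["cohort", "tissue"]]
    df = gene_long.merge(meta_cols, left_on="sample_id", right_index=True)
    rows = []
    for (cohort, tissue, gene), grp in df.groupby(["cohort", "tissue", "gene"]):
        called = grp["hypermethylated"].dropna()
        if called.empty:
            continue
        k, n = int(called.sum()), int(called.size)
        rows.append(
            {
                "cohort": cohort,
                "tissue": tissue,
                "gene": gene,
                "panel": grp["panel"].iloc[0],
                "n_hypermethylated": k,
                "n_called": n,
                "frequency": k / n,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cohort",
            "tissue",
            "gene",
            "panel",
            "n_hypermethylated",
            "n_called",
            "frequency",
        ],
    )


def _default_comparisons(
    calls: pd.DataFrame, gene_long: pd.DataFrame, frequencies: pd.DataFrame,
    alpha_normality: float,
) -> pd.DataFrame:
    """The standard comparison set: per-gene tumor-vs-normal hypermethylation
    within each cohort (Fisher, Bonferroni over the panel's genes), CIMP
    between cohorts, and per-gene normal-mucosa methylation level between
    cohorts (field-defect check; gated location test, Bonferroni)."""
    meta_cols = calls.set_index("sample_id")[["cohort", "tissue"]]
    gl = gene_long.merge(meta_cols, left_on="sample_id", right_index=True)
    gl["is_tumor"] = gl["tissue"] != Tissue.NORMAL.value
    rows = []

    def add_row(comparison, gene, method, p_raw, family, extra=""):
        rows.append(
            {
                "comparison": comparison,
                "gene": gene,
                "method": method,
                "p_raw": p_raw,
                "family_size": family,
                "p_corrected": bonferroni(p_raw, family) if p_raw == p_raw else np.nan,
                "note": extra,
            }
        )

    # tumor vs normal hypermethylation frequency, per cohort and gene
    for cohort, chunk in gl.groupby("cohort"):
        genes = sorted(chunk["gene"].unique())
        for gene in genes:
            sub = chunk[chunk["gene"] == gene]
            called = sub.dropna(subset=["hypermethylated"])
            tab = pd.crosstab(called["is_tumor"], called["hypermethylated"].astype(bool))
            tab = tab.reindex(index=[True, False], columns=[True, False], fill_value=0)
            try:
                p = fisher_2x2(tab.to_numpy())
                add_row(
                    f"hypermethylation_tumor_vs_normal[{cohort}]",
                    gene,
                    "FISHER_2x2",
                    p,
                    len(genes),
                )
            except ValueError as exc:
                add_row(
                    f"hypermethylation_tumor_vs_normal[{cohort}]",
                    gene, "FISHER_2x2", np.nan, len(genes), f"error: {exc}",
                )

    # CIMP+ between cohorts (tumors only)
    tumors = calls[calls["tissue"] != Tissue.NORMAL.value]
    cohorts = sorted(tumors["cohort"].dropna().unique())
    if len(cohorts) == 2:
        determinate = tumors[tumors["cimp_status"].isin(["CIMP_POS", "CIMP_NEG"])]
        tab = pd.crosstab(determinate["cohort"], determinate["cimp_status"])
        tab = tab.reindex(index=cohorts, columns=["CIMP_POS", "CIMP_NEG"], fill_value=0)
        try:
            p = fisher_2x2(tab.to_numpy())
            add_row("cimp_between_cohorts", "", "FISHER_2x2", p, 1)
        except ValueError as exc:
            add_row("cimp_between_cohorts", "", "FISHER_2x2", np.nan, 1, f"error: {exc}")

    # normal-mucosa methylation level between cohorts (field defect)
    normals = gl[~gl["is_tumor"]]
    if len(cohorts) == 2 and not normals.empty:
        genes = sorted(normals["gene"].unique())
        for gene in genes:
            sub = normals[normals["gene"] == gene]
            a = sub.loc[sub["cohort"] == cohorts[0], "gene_dm"].dropna()
            b = sub.loc[sub["cohort"] == cohorts[1], "gene_dm"].dropna()
            try:
                res = compare_groups(a, b, alpha_normality=alpha_normality)
                add_row(
                    f"normal_mucosa_level[{cohorts[0]}_vs_{cohorts[1]}]",
                    gene,
                    res.test_used,
                    res.p_raw,
                    len(genes),
                )
            except ValueError as exc:
                add_row(
                    f"normal_mucosa_level[{cohorts[0]}_vs_{cohorts[1]}]",
                    gene, "", np.nan, len(genes), f"error: {exc}",
                )
    return pd.DataFrame(rows)


def run(config: dict | str | Path, out_dir: str | Path | None = None, seed: int | None = None) -> RunResult:
    """Execute the full pipeline from a config mapping or YAML path.

    Config keys: ``inputs`` (panel/dm/meta[/ihc] paths) or ``simulate``
    (``config``: CohortConfig overrides); ``seed``; ``out_dir``;
    ``thresholds: {pooled_reference: bool}``; ``statistics:
    {alpha_normality: float}``; ``cutoffs`` (ICS/PDCD1 overrides).
    Arguments override config values.
    """
    if isinstance(config, (str, Path)):
        cfg_text = Path(config).read_text()
        cfg = yaml.safe_load(cfg_text) or {}
    else:
        cfg = dict(config)
        cfg_text = yaml.safe_dump(cfg, sort_keys=True)
    seed = seed if seed is not None else int(cfg.get("seed", 0))
    out = Path(out_dir) if out_dir else (Path(cfg["out_dir"]) if "out_dir" in cfg else None)

    panel, dm, ihc, meta, digests = _load_inputs(cfg, seed)
    log.info("inputs: %d samples x %d probes", len(dm.sample_ids), len(dm.probe_ids))

    cut_cfg = cfg.get("cutoffs", {})
    ics_cutoffs = ICSCutoffs(**cut_cfg.get("ics", {}))
    pdcd1_cutoffs = PDCD1Cutoffs(**cut_cfg.get("pdcd1", {}))
    pooled = bool(cfg.get("thresholds", {}).get("pooled_reference", False))
    alpha_norm = float(cfg.get("statistics", {}).get("alpha_normality", 0.05))

    calls, thresholds, gene_long = classify_samples(
        panel, dm, meta, ihc,
        pooled_reference=pooled,
        ics_cutoffs=ics_cutoffs,
        pdcd1_cutoffs=pdcd1_cutoffs,
    )
    frequencies = _frequency_tables(calls, gene_long)
    comparisons = _default_comparisons(calls, gene_long, frequencies, alpha_norm)

    manifest = {
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest()[:16],
        "input_digests": digests,
        "seed": seed,
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "records": {
            "samples": len(calls),
            "gene_calls": len(gene_long),
            "frequencies": len(frequencies),
            "comparisons": len(comparisons),
        },
    }
    result = RunResult(calls, thresholds, frequencies, comparisons, manifest, out)
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        write_reports(calls, frequencies, comparisons, out)
        thresholds.to_csv(out / "thresholds.tsv", sep="\t", na_rep="NA", index=False)
        gene_long.to_csv(out / "gene_calls.tsv", sep="\t", na_rep="NA", index=False)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        log.info("reports written to %s", out)
    return result
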