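"""Deterministic reference cohort reproducing the published summary counts.

The study this package models published per-cohort summary tables (sample
characteristics and immunoprofile distributions) but not the underlying
per-sample data.  This module materialises *one* per-sample assignment that is
consistent with every published count, so the classification and comparison
stages can be exercised end to end against known totals:

* 31 colitis-associated carcinomas (CA-CRC): ICS scores 0/1/2/3/4 in
  7/3/4/5/12 tumors (17 ICS-high), CD274 positive on immune cells in 16 and on
  tumor cells in 0, PDCD1-high in 18 (tumor center) and 21 (invasive margin),
  four-type distribution 11/9/6/5 (types I-IV), 1 MSI tumor, 12 CIMP-positive,
  27 sequenced (1 hypermutated-MSI, 9 hypermutated-MSS, 17 non-hypermutated,
  two in the ultramutated range at 118 and 85 mutations/Mb, both ICS-low and
  late-stage), stages 13/6/9/3 (I-IV), locations 13 proximal / 15 distal /
  3 unknown, 20 of 31 patients male.
* 29 Lynch-syndrome (LS) tumors (14 adenomas + 15 carcinomas): all MSI,
  7 CIMP-positive (2 adenomas + 5 carcinomas), carcinoma stages 10/3/1/0 with
  one unknown, locations 17 proximal / 12 distal, 9 of 24 patients male.
* Marginal count vectors for the two external comparison cohorts
  (MMR-proficient sporadic CRC, n=100, and LS-CRC, n=48) as published.

Joint cells the publications do not pin down (e.g. which ICS-low tumors are
CD274-positive) are filled by a fixed documented convention: samples are
ordered by ICS score and attributes are assigned to contiguous index ranges.
All tables are synthetic reconstructions, not measured data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .immune import ICSCutoffs, PDCD1Cutoffs

__all__ = ["PrintedCohort", "printed_cohort"]

# pMMR-CRC (n=100) and LS-CRC (n=48) published marginals
PMMR_MARGINALS = {
    "pdcd1_tc": {"LOW": 51, "HIGH": 49},
    "cd274_tc": {"NEG": 99, "POS": 1},
    "cd274_ic": {"NEG": 70, "POS": 30},
    "ics": {"LOW": 60, "HIGH": 40},
    "teng_type": {"I": 16, "II": 52, "III": 25, "IV": 7},
}
LS_CRC_MARGINALS = {
    "pdcd1_tc": {"LOW": 17, "HIGH": 31},
    "cd274_tc": {"NEG": 45, "POS": 3},
    "cd274_ic": {"NEG": 18, "POS": 30},
    "ics": {"LOW": 13, "HIGH": 35},
    "teng_type": {"I": 21, "II": 9, "III": 14, "IV": 4},
}


def _ca_samples() -> pd.DataFrame:
    n = 31
    ids = [f"CA{i:02d}" for i in range(1, n + 1)]
    scores = [0] * 7 + [1] * 3 + [2] * 4 + [3] * 5 + [4] * 12
    ics_level = ["HIGH" if s >= 3 else "LOW" for s in scores]
    # CD274-IC positive: 11 of the 17 ICS-high (samples 21-31) and 5 of the
    # 14 ICS-low (samples 1-5) -> 16 positive, types 11/9/6/5
    pos_idx = set(range(20, 31)) | set(range(0, 5))
    cd274_ic = ["POS" if i in pos_idx else "NEG" for i in range(n)]
    teng = [
        {"HIGH,POS": "I", "LOW,NEG": "II", "HIGH,NEG": "III", "LOW,POS": "IV"}[
            f"{lvl},{cd}"
        ]
        for lvl, cd in zip(ics_level, cd274_ic)
    ]
    pdcd1_tc = ["HIGH" if i >= 13 else "LOW" for i in range(n)]  # 18 high
    pdcd1_im = ["HIGH" if i >= 10 else "LOW" for i in range(n)]  # 21 high
    # mutation burden: MSI ultramutated tumor CA06 (118/Mb, ICS 0, type II),
    # MSS ultramutated CA08 (85/Mb, ICS 1, type II); hypermutated MSS also
    # CA07 and the first four type-I (CA21-24) + CA15,CA16 (III) + CA01 (IV);
    # CA02, CA03, CA09, CA17 not sequenced; everything else non-hypermutated.
    burden = {i: 5.0 for i in range(n)}
    for i in (6, 20, 21, 22, 23, 14, 15, 0):
        burden[i] = 25.0
    burden[5] = 118.0
    burden[7] = 85.0
    for i in (1, 2, 8, 16):
        burden[i] = np.nan
    msi = [i == 5 for i in range(n)]
    cimp_pos_idx = {20, 21, 22, 23, 24, 25, 14, 15, 0, 5, 6, 8}  # 12 CIMP+
    # stages: CA06 -> IV, CA08 -> III; remaining 29 get 13 I, 6 II, 8 III, 2 IV
    stage_pool = ["I"] * 13 + ["II"] * 6 + ["III"] * 8 + ["IV"] * 2
    stages, k = [], 0
    for i in range(n):
        if i == 5:
            stages.append("IV")
        elif i == 7:
            stages.append("III")
        else:
            stages.append(stage_pool[k])
            k += 1
    location = ["PROXIMAL"] * 13 + ["DISTAL"] * 15 + [None] * 3
    return pd.DataFrame(
        {
            "sample_id": ids,
            "patient_id": [f"CA_P{i:02d}" for i in range(1, n + 1)],
            "cohort": "CA_CRC",
            "tissue": "CARCINOMA",
            "sex": ["M"] * 20 + ["F"] * 11,
            "age": 51.4,
            "stage": stages,
            "location": location,
            "bat25_unstable": msi,
            "bat26_unstable": False,
            "nonsyn_mut_per_mb": [burden[i] for i in range(n)],
            "ics_score": scores,
            "ics_level": ics_level,
            "pdcd1_tc": pdcd1_tc,
            "pdcd1_im": pdcd1_im,
            "cd274_tc": "NEG",
            "cd274_ic": cd274_ic,
            "teng_type": teng,
            "cimp_pos": [i in cimp_pos_idx for i in range(n)],
        }
    ).set_index("sample_id")


def _ls_samples() -> pd.DataFrame:
    ids = [f"LS{i:02d}" for i in range(1, 30)]
    tissue = ["ADENOMA"] * 14 + ["CARCINOMA"] * 15
    cimp = [i in {0, 1, 14, 15, 16, 17, 18} for i in range(29)]  # 2 + 5
    stage = [None] * 14 + ["I"] * 10 + ["II"] * 3 + ["III"] + [None]
    location = (
        ["PROXIMAL"] * 6 + ["DISTAL"] * 8 + ["PROXIMAL"] * 11 + ["DISTAL"] * 4
    )
    return pd.DataFrame(
        {
            "sample_id": ids,
            "patient_id": [f"LS_P{i:02d}" for i in range(1, 30)],
            "cohort": "LS",
            "tissue": tissue,
            "stage": stage,
            "location": location,
            "bat25_unstable": True,
            "bat26_unstable": True,
            "cimp_pos": cimp,
        }
    ).set_index("sample_id")


def _ca_ihc(ca: pd.DataFrame) -> pd.DataFrame:
    """Synthetic IHC measurements that reproduce the fixture's calls through
    the scoring rules (densities placed well clear of every cut-off)."""
    ics_cut = ICSCutoffs()
    pdcd1_cut = PDCD1Cutoffs()
    rows = []
    section_cuts = [
        ("cd3_tc", ics_cut.cd3_tc),
        ("cd8_tc", ics_cut.cd8_tc),
        ("cd3_im", ics_cut.cd3_im),
        ("cd8_im", ics_cut.cd8_im),
    ]
    for sid, rec in ca.iterrows():
        row = {"sample_id": sid}
        score = int(rec["ics_score"])
        # award the first `score` sections, in the fixed order above
        for j, (col, cut) in enumerate(section_cuts):
            row[col] = round(cut * (1.5 if j < score else 0.5), 1)
        row["pdcd1_tc"] = round(
            pdcd1_cut.tc * (1.5 if rec["pdcd1_tc"] == "HIGH" else 0.5), 1
        )
        row["pdcd1_im"] = round(
            pdcd1_cut.im * (1.5 if rec["pdcd1_im"] == "HIGH" else 0.5), 1
        )
        row["cd274_tc_pct"] = 2.0
        row["cd274_tc_intensity"] = "weak"
        if rec["cd274_ic"] == "POS":
            row["cd274_ic_pct"] = 20.0
            row["cd274_ic_intensity"] = "moderate"
        else:
            row["cd274_ic_pct"] = 2.0
            row["cd274_ic_intensity"] = "weak"
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")


@dataclass(frozen=True)
class PrintedCohort:
    """Per-sample reconstruction plus external marginals; see module docs."""

    ca_samples: pd.DataFrame
    ca_ihc: pd.DataFrame
    ls_samples: pd.DataFrame
    pmmr_marginals: dict
    ls_crc_marginals: dict
    n_ca_patients_male: int = 20
    n_ca_patients: int = 31
    n_ls_patients_male: int = 9
    n_ls_patients: int = 24

    # -- contingency tables for the published cohort comparisons ------------

    def cd274_ic_table(self) -> np.ndarray:
        """CA-CRC vs pMMR-CRC, CD274 on immune cells (POS/NEG columns)."""
        ca_pos = int((self.ca_samples["cd274_ic"] == "POS").sum())
        pm = self.pmmr_marginals["cd274_ic"]
        return np.array(
            [[ca_pos, len(self.ca_samples) - ca_pos], [pm["POS"], pm["NEG"]]]
        )

    def cimp_table(self) -> np.ndarray:
        """CA-CRC vs LS tumors, CIMP positive/negative."""
        ca = int(self.ca_samples["cimp_pos"].sum())
        ls = int(self.ls_samples["cimp_pos"].sum())
        return np.array(
            [[ca, len(self.ca_samples) - ca], [ls, len(self.ls_samples) - ls]]
        )

    def sex_table(self) -> np.ndarray:
        """CA-CRC vs LS patients, male/female."""
        return np.array(
            [
                [self.n_ca_patients_male, self.n_ca_patients - self.n_ca_patients_male],
                [self.n_ls_patients_male, self.n_ls_patients - self.n_ls_patients_male],
            ]
        )

    def location_table(self) -> np.ndarray:
        """CA-CRC vs LS tumors, proximal/distal (unknown excluded)."""
        rows = []
        for df in (self.ca_samples, self.ls_samples):
            loc = df["location"].dropna()
            rows.append([int((loc == "PROXIMAL").sum()), int((loc == "DISTAL").sum())])
        return np.array(rows)

    def msi_table(self, msi_calls_ca: pd.Series, msi_calls_ls: pd.Series) -> np.ndarray:
        """CA-CRC vs LS tumors, MSI/MSS, from computed per-sample MSI calls."""
        rows = []
        for calls in (msi_calls_ca, msi_calls_ls):
            rows.append([int((calls == "MSI").sum()), int((calls == "MSS").sum())])
        return np.array(rows)

    def teng_table(self, teng_calls_ca: pd.Series) -> np.ndarray:
        """Four-type distribution, CA-CRC (computed calls) vs pMMR marginals."""
        pm = self.pmmr_marginals["teng_type"]
        return np.array(
            [[int((teng_calls_ca == t).sum()), pm[t]] for t in ("I", "II", "III", "IV")]
        )

    def stage_table(self) -> np.ndarray:
        """Stage I-IV, CA-CRC vs LS carcinomas (unknown excluded)."""
        ls_carc = self.ls_samples[self.ls_samples["tissue"] == "CARCINOMA"]
        return np.array(
            [
                [
                    int((self.ca_samples["stage"] == s).sum()),
                    int((ls_carc["stage"] == s).sum()),
                ]
                for s in ("I", "II", "III", "IV")
            ]
        )


def printed_cohort() -> PrintedCohort:
    """Build the deterministic published-count reconstruction."""
    ca = _ca_samples()
    return PrintedCohort(
        ca_samples=ca,
        ca_ihc=_ca_ihc(ca),
        ls_samples=_ls_samples(),
        pmmr_marginals=PMMR_MARGINALS,
        ls_crc_marginals=LS_CRC_MARGINALS,
    )
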