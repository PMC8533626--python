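"""Threshold derivation and the three-level hypermethylation calling cascade."""

import itertools
import statistics

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from colotype.io import DmMatrix
from colotype.methylation import (
    CIMPStatus,
    MethSubgroup,
    call_cimp,
    call_gene_hypermethylation,
    call_probe_methylation,
    classify_meth_subgroup,
    derive_thresholds,
    gene_dm,
    hypermethylation_frequency,
)
from colotype.panels import Panel, PanelDef, ProbeDef


def _dm(panel, rows, sample_ids=None):
    """Build a DmMatrix from a list of per-sample probe-value lists."""
    sample_ids = sample_ids or [f"s{i}" for i in range(len(rows))]
    return DmMatrix(
        pd.DataFrame(rows, index=sample_ids, columns=list(panel.probe_ids))
    )


def _one_probe_panel():
    return PanelDef(
        probes=(ProbeDef("NTSR1 I", "NTSR1", Panel.INFLAMMATION),),
        cimp_score_genes=frozenset(),
    )


class TestDeriveThresholds:
    def test_technical_floor_binds_below_it(self):
        panel = _one_probe_panel()
        thr = derive_thresholds(_dm(panel, [[0.05], [0.07], [0.09]]), panel)
        assert thr.loc["NTSR1 I", "threshold"] == 0.15

    def test_mean_plus_two_sample_sd(self):
        # independent oracle: statistics.mean / statistics.stdev (n-1)
        vals = [0.20, 0.30, 0.40]
        expected = statistics.mean(vals) + 2 * statistics.stdev(vals)
        panel = _one_probe_panel()
        thr = derive_thresholds(_dm(panel, [[v] for v in vals]), panel)
        assert thr.loc["NTSR1 I", "threshold"] == pytest.approx(expected)
        assert thr.loc["NTSR1 I", "threshold"] == pytest.approx(0.5)

    def test_single_observation_flagged_unusable(self):
        panel = _one_probe_panel()
        thr = derive_thresholds(_dm(panel, [[0.2], [np.nan]]), panel)
        assert not thr.loc["NTSR1 I", "usable"]
        assert np.isnan(thr.loc["NTSR1 I", "threshold"])

    def test_empty_cohort_rejected(self):
        panel = _one_probe_panel()
        with pytest.raises(ValueError, match="empty"):
            derive_thresholds(_dm(panel, []), panel)

    @given(
        vals=st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=2, max_size=30
        ),
        floor=st.floats(min_value=0.0, max_value=0.5),
    )
    @settings(max_examples=200, deadline=None)
    def test_threshold_never_below_floor(self, vals, floor):
        panel = PanelDef(
            probes=(ProbeDef("G I", "G", Panel.INFLAMMATION, technical_floor=floor),),
            cimp_score_genes=frozenset(),
        )
        thr = derive_thresholds(_dm(panel, [[v] for v in vals]), panel)
        t = thr.loc["G I", "threshold"]
        assert t >= floor
        assert t == pytest.approx(
            max(statistics.mean(vals) + 2 * statistics.stdev(vals), floor)
        )

    def test_false_positive_rate_on_held_out_normals_below_10pct(self, panel):
        """Applying mean+2SD thresholds to fresh null normals rarely calls
        hypermethylation (expected ~2% for Gaussian data, floor helps)."""
        rng = np.random.default_rng(11)
        n_ref, n_test = 20, 400
        ref = _dm(panel, rng.normal(0.1, 0.04, (n_ref, len(panel.probe_ids))).clip(0))
        held = _dm(
            panel,
            rng.normal(0.1, 0.04, (n_test, len(panel.probe_ids))).clip(0),
            sample_ids=[f"t{i}" for i in range(n_test)],
        )
        thr = derive_thresholds(ref, panel)
        calls = call_probe_methylation(held, thr)
        assert calls.stack().mean() < 0.10


class TestProbeCalls:
    def test_boundary_inclusive_and_missing_propagates(self):
        panel = _one_probe_panel()
        thr = derive_thresholds(_dm(panel, [[0.1], [0.1], [0.1]]), panel)
        assert thr.loc["NTSR1 I", "threshold"] == 0.15
        calls = call_probe_methylation(
            _dm(panel, [[0.16], [0.15], [0.1499], [np.nan]]), thr
        )
        col = calls["NTSR1 I"]
        assert col.iloc[0] == 1.0
        assert col.iloc[1] == 1.0  # Dm equal to the threshold is methylated
        assert col.iloc[2] == 0.0
        assert np.isnan(col.iloc[3])

    def test_probe_without_threshold_rejected(self):
        panel = _one_probe_panel()
        thr = pd.DataFrame({"threshold": [0.15]}, index=["OTHER I"])
        with pytest.raises(KeyError, match="NTSR1"):
            call_probe_methylation(_dm(panel, [[0.2]]), thr)


def _gene_panel(n_probes):
    probes = tuple(
        ProbeDef(f"G {i}", "G", Panel.INFLAMMATION, probe_index=1)
        for i in range(1, n_probes + 1)
    )
    return PanelDef(probes=probes, cimp_score_genes=frozenset())


class TestGeneCalls:
    @pytest.mark.parametrize(
        "n_probes,n_meth,expected",
        [(4, 1, True), (6, 1, False), (4, 0, False), (6, 2, True), (1, 1, True)],
    )
    def test_quarter_rule(self, n_probes, n_meth, expected):
        panel = _gene_panel(n_probes)
        calls = pd.DataFrame(
            [[1.0] * n_meth + [0.0] * (n_probes - n_meth)],
            index=["s0"],
            columns=panel.probe_ids,
        )
        out = call_gene_hypermethylation(calls, panel)
        assert bool(out.loc[0, "hypermethylated"]) is expected

    def test_rule_over_observed_probes_with_low_coverage_flag(self):
        panel = _gene_panel(6)
        row = [1.0, 0.0] + [np.nan] * 4  # 2 observed of 6, 1 methylated
        out = call_gene_hypermethylation(
            pd.DataFrame([row], index=["s0"], columns=panel.probe_ids), panel
        )
        assert bool(out.loc[0, "hypermethylated"]) is True  # 1/2 >= 1/4
        assert bool(out.loc[0, "low_coverage"]) is True

    def test_no_observed_probes_gives_no_call(self):
        panel = _gene_panel(3)
        out = call_gene_hypermethylation(
            pd.DataFrame([[np.nan] * 3], index=["s0"], columns=panel.probe_ids), panel
        )
        assert pd.isna(out.loc[0, "hypermethylated"])


class TestCimp:
    def test_score_set_restriction(self, panel):
        """Methylation of non-score CIMP genes (MLH1, CDKN2A, CRABP1) never
        contributes to the CIMP score."""
        calls = pd.DataFrame(
            {
                "sample_id": ["s0"] * 8,
                "gene": list(
                    ("CACNA1G", "CDKN2A", "CRABP1", "IGF2", "NEUROG1", "MLH1", "RUNX3", "SOCS1")
                ),
                "hypermethylated": [False, True, True, False, False, True, False, False],
            }
        )
        calls["hypermethylated"] = calls["hypermethylated"].astype("boolean")
        out = call_cimp(calls, panel)
        assert out.loc[0, "status"] == CIMPStatus.CIMP_NEG.value
        assert out.loc[0, "n_score_genes_methylated"] == 0

    @pytest.mark.parametrize("n_meth,status", [(3, "CIMP_POS"), (5, "CIMP_POS"), (2, "CIMP_NEG"), (0, "CIMP_NEG")])
    def test_three_of_five_rule(self, panel, n_meth, status):
        genes = sorted(panel.cimp_score_genes)
        calls = pd.DataFrame(
            {
                "sample_id": ["s0"] * 5,
                "gene": genes,
                "hypermethylated": pd.array(
                    [i < n_meth for i in range(5)], dtype="boolean"
                ),
            }
        )
        assert call_cimp(calls, panel).loc[0, "status"] == status

    def test_uncalled_score_gene_gives_indeterminate(self, panel):
        genes = sorted(panel.cimp_score_genes)
        calls = pd.DataFrame(
            {
                "sample_id": ["s0"] * 5,
                "gene": genes,
                "hypermethylated": pd.array(
                    [True, True, pd.NA, False, False], dtype="boolean"
                ),
            }
        )
        assert call_cimp(calls, panel).loc[0, "status"] == "INDETERMINATE"


class TestOracleEquivalence:
    """The cascade matches a literal brute-force re-implementation on small
    binary matrices (all 2-probe patterns exhaustively; all per-gene count
    patterns for 3 and 4 probes)."""

    @staticmethod
    def _brute_force(matrix, genes, probes_per_gene):
        """Literal rules on complete data: gene methylated iff methylated
        probes >= 1/4 of all its probes; CIMP+ iff >= 3/5 score genes."""
        gene_calls = {}
        for gi, gene in enumerate(genes):
            probes = matrix[gi * probes_per_gene : (gi + 1) * probes_per_gene]
            gene_calls[gene] = sum(probes) >= len(probes) / 4
        n = sum(gene_calls.values())
        return gene_calls, ("CIMP_POS" if n >= 3 else "CIMP_NEG")

    def _run_equivalence(self, patterns, probes_per_gene, cimp_only_panel_factory):
        genes = ("CACNA1G", "IGF2", "NEUROG1", "RUNX3", "SOCS1")
        probes = tuple(
            ProbeDef(f"{g} p{i}", g, Panel.CIMP, probe_index=1)
            for g in genes
            for i in range(probes_per_gene)
        )
        panel = PanelDef(probes=probes)
        mat = pd.DataFrame(
            [list(p) for p in patterns],
            index=[f"m{i}" for i in range(len(patterns))],
            columns=[p.probe_id for p in probes],
            dtype=float,
        )
        gene_calls = call_gene_hypermethylation(mat, panel)
        cimp = call_cimp(gene_calls, panel).set_index("sample_id")
        gc_indexed = gene_calls.set_index(["sample_id", "gene"])["hypermethylated"]
        for i, pattern in enumerate(patterns):
            expected_genes, expected_status = self._brute_force(
                pattern, genes, probes_per_gene
            )
            sid = f"m{i}"
            assert cimp.loc[sid, "status"] == expected_status
            for gene in genes:
                assert bool(gc_indexed.loc[(sid, gene)]) == expected_genes[gene]

    def test_exhaustive_two_probes(self):
        patterns = list(itertools.product([0, 1], repeat=10))
        self._run_equivalence(patterns, 2, None)

    @pytest.mark.parametrize("probes_per_gene", [3, 4])
    def test_all_count_patterns(self, probes_per_gene):
        # gene calls depend only on per-gene methylated counts: enumerating
        # all count combinations is exhaustive over distinguishable inputs
        patterns = []
        for counts in itertools.product(range(probes_per_gene + 1), repeat=5):
            row = []
            for k in counts:
                row += [1] * k + [0] * (probes_per_gene - k)
            patterns.append(tuple(row))
        self._run_equivalence(patterns, probes_per_gene, None)


class TestGeneDmAndSubgroups:
    def test_gene_dm_mean_over_observed(self):
        panel = _gene_panel(3)
        dm = _dm(panel, [[0.2, np.nan, 0.4], [0.29, np.nan, np.nan]])
        vals = gene_dm(dm, panel, "G")
        assert vals.iloc[0] == pytest.approx(0.3)
        assert vals.iloc[1] == pytest.approx(0.29)

    @pytest.mark.parametrize(
        "value,expected",
        [
            (0.53, MethSubgroup.HYPER),  # 0.53 >= 0.29 + 2*0.12
            (0.29, MethSubgroup.NORMO),
            (0.04, MethSubgroup.HYPO),  # 0.04 <= 0.29 - 2*0.12
            (0.05, MethSubgroup.HYPO),  # boundary inclusive
            (0.52, MethSubgroup.NORMO),
        ],
    )
    def test_two_sd_subgroups(self, value, expected):
        assert classify_meth_subgroup(value, 0.29, 0.12) is expected

    def test_missing_reference_gives_no_call(self):
        assert classify_meth_subgroup(0.5, np.nan, 0.1) is None


class TestFrequency:
    def test_counts_and_fraction(self):
        calls = pd.DataFrame(
            {
                "gene": ["NTSR1"] * 31,
                "hypermethylated": pd.array([True] * 13 + [False] * 18, dtype="boolean"),
            }
        )
        f = hypermethylation_frequency(calls, "NTSR1")
        assert (f.numerator, f.denominator) == (13, 31)
        assert f.fraction == pytest.approx(0.419, abs=5e-4)

    def test_zero_and_full(self):
        calls = pd.DataFrame(
            {"gene": ["G"] * 4, "hypermethylated": pd.array([False] * 4, dtype="boolean")}
        )
        assert hypermethylation_frequency(calls, "G").fraction == 0.0
        calls["hypermethylated"] = pd.array([True] * 4, dtype="boolean")
        assert hypermethylation_frequency(calls, "G").fraction == 1.0

    def test_empty_subset_rejected(self):
        calls = pd.DataFrame({"gene": [], "hypermethylated": []})
        with pytest.raises(ValueError):
            hypermethylation_frequency(calls, "G")


class TestMonotonicity:
    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_increasing_dm_never_flips_calls_down(self, data):
        """Raising any probe's Dm can only move calls toward methylated,
        the CIMP score up, and the subgroup toward HYPER."""
        panel = _gene_panel(4)
        base = data.draw(
            st.lists(st.floats(0, 1, allow_nan=False), min_size=4, max_size=4)
        )
        bump_idx = data.draw(st.integers(0, 3))
        bump = data.draw(st.floats(0.0, 0.5, allow_nan=False))
        thr = pd.DataFrame(
            {"threshold": [0.3, 0.3, 0.3, 0.3]}, index=list(panel.probe_ids)
        )
        raised = list(base)
        raised[bump_idx] = min(raised[bump_idx] + bump, 1.2)
        dm_lo = _dm(panel, [base])
        dm_hi = _dm(panel, [raised])
        calls_lo = call_probe_methylation(dm_lo, thr)
        calls_hi = call_probe_methylation(dm_hi, thr)
        assert (calls_hi.values >= calls_lo.values).all()
        g_lo = call_gene_hypermethylation(calls_lo, panel)
        g_hi = call_gene_hypermethylation(calls_hi, panel)
        assert int(g_hi["n_probes_methylated"].iloc[0]) >= int(
            g_lo["n_probes_methylated"].iloc[0]
        )
        order = {MethSubgroup.HYPO: 0, MethSubgroup.NORMO: 1, MethSubgroup.HYPER: 2}
        s_lo = classify_meth_subgroup(float(np.mean(base)), 0.4, 0.1)
        s_hi = classify_meth_subgroup(float(np.mean(raised)), 0.4, 0.1)
        assert order[s_hi] >= order[s_lo]
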