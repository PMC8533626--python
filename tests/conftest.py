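import pandas as pd
import pytest
from hypothesis import settings as hyp_settings

hyp_settings.register_profile("deterministic", derandomize=True)
hyp_settings.load_profile("deterministic")

from colotype.panels import Panel, PanelDef, ProbeDef, default_panel
from colotype.printed import printed_cohort


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def printed():
    return printed_cohort()


@pytest.fixture()
def cimp_only_panel():
    """A minimal panel: the five CIMP score genes, two probes each."""
    probes = []
    for gene in ("CACNA1G", "IGF2", "NEUROG1", "RUNX3", "SOCS1"):
        for i, rom in enumerate(("I", "II"), start=1):
            probes.append(
                ProbeDef(f"{gene} {rom}", gene, Panel.CIMP, probe_index=i)
            )
    return PanelDef(probes=tuple(probes))


@pytest.fixture()
def tmp_tsv(tmp_path):
    """Write a DataFrame to a temp TSV and return the path."""

    def _write(df: pd.DataFrame, name: str = "table.tsv", index: bool = False):
        path = tmp_path / name
        df.to_csv(path, sep="\t", na_rep="NA", index=index)
        return path

    return _write
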