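"""Probe-panel definitions for MS-MLPA methylation analysis.

Three panels are modelled: the eight-gene CIMP marker panel (of which five
genes carry the Weisenberger CIMP score), a seven-gene inflammation-associated
custom panel, and the six-probe MGMT promoter panel.  Probes are labelled
``"GENE ROMAN"`` (e.g. ``"RUNX3 II"``), the convention used on MS-MLPA probe
sheets; the roman numeral orders probes within a gene.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping

__all__ = [
    "Panel",
    "ProbeDef",
    "PanelDef",
    "CIMP_PANEL_GENES",
    "CIMP_SCORE_GENES",
    "INFLAMMATION_GENES",
    "default_panel",
    "roman",
    "parse_probe_id",
]

DEFAULT_TECHNICAL_FLOOR = 0.15


class Panel(str, enum.Enum):
    """Which probe mix a probe belongs to."""

    CIMP = "CIMP"
    INFLAMMATION = "INFLAMMATION"
    MGMT = "MGMT"


CIMP_PANEL_GENES = (
    "CACNA1G",
    "CDKN2A",
    "CRABP1",
    "IGF2",
    "NEUROG1",
    "MLH1",
    "RUNX3",
    "SOCS1",
)

#: The five genes entering the Weisenberger CIMP score (>=3/5 methylated => CIMP+).
CIMP_SCORE_GENES = frozenset({"CACNA1G", "IGF2", "NEUROG1", "RUNX3", "SOCS1"})

INFLAMMATION_GENES = (
    "CD274",
    "NTSR1",
    "PPARG",
    "PTGS2",
    "PYCARD",
    "SOCS1",
    "SOCS2",
)

_ROMANS = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X")


def roman(index: int) -> str:
    """Roman numeral for a 1-based probe index (supports 1..10)."""
    if not 1 <= index <= len(_ROMANS):
        raise ValueError(f"probe index out of supported range: {index}")
    return _ROMANS[index - 1]


def parse_probe_id(probe_id: str) -> tuple[str, int]:
    """Split a ``"GENE ROMAN"`` probe label into (gene, 1-based index).

    A bare gene name is treated as its single probe (index 1).
    """
    parts = probe_id.rsplit(" ", 1)
    if len(parts) == 2 and parts[1] in _ROMANS:
        return parts[0], _ROMANS.index(parts[1]) + 1
    return probe_id, 1


@dataclass(frozen=True)
class ProbeDef:
    """One MS-MLPA probe: identity, target gene, panel and technical floor.

    ``technical_floor`` is the minimum hypermethylation threshold the assay
    supports; reference-derived cut-offs below it are clamped up to it.
    """

    probe_id: str
    gene: str
    panel: Panel
    probe_index: int = 1
    technical_floor: float = DEFAULT_TECHNICAL_FLOOR

    def __post_init__(self) -> None:
        if not 0.0 <= self.technical_floor <= 1.0:
            raise ValueError(
                f"technical_floor must be in [0, 1], got {self.technical_floor}"
            )
        if self.probe_index < 1:
            raise ValueError("probe_index is 1-based")


@dataclass(frozen=True)
class PanelDef:
    """An ordered probe collection plus the CIMP score-gene set.

    Invariants (checked on construction): probe ids unique; score genes are a
    subset of the CIMP panel's genes.
    """

    probes: tuple[ProbeDef, ...]
    cimp_score_genes: frozenset[str] = CIMP_SCORE_GENES

    def __post_init__(self) -> None:
        if not self.probes:
            raise ValueError("panel has no probes")
        ids = [p.probe_id for p in self.probes]
        seen: set[str] = set()
        for pid in ids:
            if pid in seen:
                raise ValueError(f"duplicate probe_id: {pid!r}")
            seen.add(pid)
        cimp_genes = {p.gene for p in self.probes if p.panel is Panel.CIMP}
        if cimp_genes and not self.cimp_score_genes <= cimp_genes:
            missing = sorted(self.cimp_score_genes - cimp_genes)
            raise ValueError(
                f"CIMP score genes not covered by CIMP panel probes: {missing}"
            )

    @property
    def probe_ids(self) -> tuple[str, ...]:
        return tuple(p.probe_id for p in self.probes)

    def genes(self, panel: Panel | None = None) -> tuple[str, ...]:
        """Genes covered, in probe order, optionally restricted to one panel."""
        out: list[str] = []
        for p in self.probes:
            if panel is not None and p.panel is not panel:
                continue
            if p.gene not in out:
                out.append(p.gene)
        return tuple(out)

    def probes_for_gene(self, gene: str) -> tuple[ProbeDef, ...]:
        return tuple(p for p in self.probes if p.gene == gene)

    def probe(self, probe_id: str) -> ProbeDef:
        for p in self.probes:
            if p.probe_id == probe_id:
                return p
        raise KeyError(probe_id)

    def gene_to_probe_ids(self, panel: Panel | None = None) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for p in self.probes:
            if panel is not None and p.panel is not panel:
                continue
            out.setdefault(p.gene, []).append(p.probe_id)
        return out


def _make_probes(
    genes: Iterable[str],
    panel: Panel,
    n_probes: Mapping[str, int],
    floor: float,
) -> list[ProbeDef]:
    probes = []
    for gene in genes:
        for i in range(1, n_probes.get(gene, 1) + 1):
            probes.append(
                ProbeDef(
                    probe_id=f"{gene} {roman(i)}",
                    gene=gene,
                    panel=panel,
                    probe_index=i,
                    technical_floor=floor,
                )
            )
    return probes


def default_panel(technical_floor: float = DEFAULT_TECHNICAL_FLOOR) -> PanelDef:
    """The default joint panel used by the simulator and worked examples.

    Two probes per CIMP marker gene, one or two per inflammation gene (two for
    NTSR1 and SOCS2, the genes analysed most closely), and six MGMT promoter
    probes (I-VI).  Probe counts per gene are a design choice of this package;
    the calling rules are count-agnostic.  SOCS1 appears in both the CIMP and
    the inflammation panel, targeting different promoter regions, so the two
    probe sets are kept distinct (inflammation probes are suffixed ``custom``).
    """
    probes: list[ProbeDef] = []
    probes += _make_probes(
        CIMP_PANEL_GENES, Panel.CIMP, {g: 2 for g in CIMP_PANEL_GENES}, technical_floor
    )
    n_inflam = {g: 1 for g in INFLAMMATION_GENES}
    n_inflam["NTSR1"] = 2
    n_inflam["SOCS2"] = 2
    for gene in INFLAMMATION_GENES:
        # SOCS1 is on both mixes but targets a different promoter region in
        # the custom panel; keep it as a distinct gene entity.
        label = "SOCS1_custom" if gene == "SOCS1" else gene
        for i in range(1, n_inflam[gene] + 1):
            probes.append(
                ProbeDef(
                    probe_id=f"{label} {roman(i)}",
                    gene=label,
                    panel=Panel.INFLAMMATION,
                    probe_index=i,
                    technical_floor=technical_floor,
                )
            )
    probes += _make_probes(["MGMT"], Panel.MGMT, {"MGMT": 6}, technical_floor)
    return PanelDef(probes=tuple(probes))
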