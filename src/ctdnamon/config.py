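"""Shared configuration objects: thresholds, panel definition, run config.

All classification cutoffs used throughout the pipeline live in
:class:`ThresholdConfig`; the defaults are the clinically applied values
(CNV gain fold 1.4, loss fold 0.65, TMB 8.5 mut/Mb, TCL 2, CEA 5 ng/mL).
The targeted panel is described by :class:`PanelDefinition`: the gene list,
the coding footprint in megabases (the TMB denominator) and an editable
catalogue of known driver alterations excluded from TMB.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable

import yaml

#: Variant effect classes recognised in variant tables.
EFFECT_CLASSES = (
    "missense",
    "nonsense",
    "synonymous",
    "frameshift_indel",
    "inframe_indel",
    "splice",
    "other",
)

#: Effect classes counted in TMB by default: coding substitutions and indels,
#: synonymous included to reduce sampling noise; splice/"other" excluded.
TMB_EFFECTS = (
    "missense",
    "nonsense",
    "synonymous",
    "frameshift_indel",
    "inframe_indel",
)


@dataclass(frozen=True)
class ThresholdConfig:
    """Fixed classification cutoffs.

    cnv_gain_fold / cnv_loss_fold are inclusive boundaries (fold >= 1.4 is a
    gain, fold <= 0.65 a loss); tmb_high_cutoff and tcl_high_cutoff are
    inclusive (>= is "high"); cea_cutoff is the standard clinical 5 ng/mL.
    """

    cnv_gain_fold: float = 1.4
    cnv_loss_fold: float = 0.65
    tmb_high_cutoff: float = 8.5
    tcl_high_cutoff: int = 2
    cea_cutoff: float = 5.0

    def __post_init__(self) -> None:
        if not (self.cnv_gain_fold > 1.0 > self.cnv_loss_fold > 0):
            raise ValueError("need gain fold > 1 > loss fold > 0")
        if self.tmb_high_cutoff <= 0 or self.tcl_high_cutoff <= 0 or self.cea_cutoff <= 0:
            raise ValueError("cutoffs must be positive")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


# A compact default gene list standing in for a large pan-cancer panel; the
# real panel is configurable.  ERBB2 is mandatory for HER2-status calling.
DEFAULT_PANEL_GENES = (
    "ERBB2", "TP53", "KRAS", "PIK3CA", "CDK12", "CCNE1", "TERC", "ALK",
    "APC", "FLT1", "NOTCH2", "XPC", "ERBB4", "STAG2", "BCR", "MYC",
    "CCND1", "FGFR2", "MET", "EGFR", "KIT", "SMAD4", "ARID1A", "CDH1",
)

#: Small editable catalogue of recurrent driver hotspots excluded from TMB,
#: keyed by (gene, protein_change).
DEFAULT_DRIVER_CATALOGUE = frozenset(
    {
        ("TP53", "p.R175H"),
        ("TP53", "p.R273H"),
        ("KRAS", "p.G12D"),
        ("KRAS", "p.G12V"),
        ("PIK3CA", "p.E545K"),
        ("PIK3CA", "p.H1047R"),
        ("ERBB2", "p.S310F"),
    }
)


@dataclass(frozen=True)
class PanelDefinition:
    """Targeted sequencing panel: genes, coding footprint, driver catalogue.

    ``coding_footprint_mb`` is the megabases of assayed coding sequence and is
    the TMB denominator; it must be stated explicitly for TMB to be
    well-defined.  ``driver_sites`` lists variant keys (chrom, pos, ref, alt)
    and ``driver_hotspots`` (gene, protein_change) pairs; variants matching
    either are excluded from the TMB count.
    """

    genes: tuple[str, ...] = DEFAULT_PANEL_GENES
    coding_footprint_mb: float = 1.2
    driver_sites: frozenset = frozenset()
    driver_hotspots: frozenset = DEFAULT_DRIVER_CATALOGUE

    def __post_init__(self) -> None:
        if self.coding_footprint_mb <= 0:
            raise ValueError("coding footprint must be positive")
        if not self.genes:
            raise ValueError("panel gene list must be non-empty")

    def with_driver_sites(self, keys: Iterable[tuple]) -> "PanelDefinition":
        return PanelDefinition(
            genes=self.genes,
            coding_footprint_mb=self.coding_footprint_mb,
            driver_sites=frozenset(keys),
            driver_hotspots=self.driver_hotspots,
        )


def load_threshold_config(path: str | Path | None) -> ThresholdConfig:
    """Load cutoff overrides from a YAML/JSON mapping; missing keys default."""
    if path is None:
        return ThresholdConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(ThresholdConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
    return ThresholdConfig(**data)
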