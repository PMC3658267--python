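"""Shared domain types for the kinase-substrate pipeline.

Coordinates are 1-based inclusive residue positions throughout (the biology
convention: "Ser688" is position 688). A kinase-substrate relationship (KSR)
is a directed kinase -> substrate pair; edges progress through stages:
``raw`` (microarray hit), ``refined`` (Bayes-filtered), ``known`` (literature
curated) and ``combined`` (member of the merged set).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

CONTROL = "CONTROL"

STAGES = ("raw", "refined", "known", "combined")
SOURCES = ("MS", "literature")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein with its amino-acid sequence (unknown letters mapped to X)."""

    protein_id: str
    sequence: str

    def __post_init__(self):
        if not self.protein_id:
            raise ValueError("empty protein_id")
        if len(self.sequence) < 1:
            raise ValueError(f"{self.protein_id}: empty sequence")


@dataclass(frozen=True)
class Phosphosite:
    """An in-vivo phosphorylated residue: protein, 1-based position, S/T/Y."""

    protein_id: str
    position: int
    residue: str
    source: str = "MS"

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.residue not in ("S", "T", "Y"):
            raise ValueError(f"residue must be S, T or Y, got {self.residue!r}")
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")

    @property
    def residue_class(self) -> str:
        return "Y" if self.residue == "Y" else "ST"


@dataclass
class IntensityTable:
    """Mean spot intensities of one kinase assay (or the no-kinase control)."""

    kinase_id: str
    values: Mapping[str, float]

    def __post_init__(self):
        bad = [p for p, v in self.values.items() if v < 0]
        if bad:
            raise ValueError(f"negative intensities for {bad[:3]} ...")

    @property
    def is_control(self) -> bool:
        return self.kinase_id == CONTROL


@dataclass
class KSREdge:
    """A kinase -> substrate pair with its provenance stage and scores."""

    kinase_id: str
    substrate_id: str
    stage: str
    array_z: Optional[float] = None
    l_score: Optional[float] = None
    p_value: Optional[float] = None
    known_overlap: bool = False

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.p_value is not None and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value out of [0,1]: {self.p_value}")

    @property
    def pair(self) -> tuple:
        return (self.kinase_id, self.substrate_id)


@dataclass
class SiteEdge:
    """A kinase assigned to a specific phosphosite on a substrate."""

    kinase_id: str
    substrate_id: str
    position: int
    residue: str
    match_score: float
    status: str = "novel"

    def __post_init__(self):
        if self.status not in ("known", "novel"):
            raise ValueError(f"status must be known|novel, got {self.status!r}")

    @property
    def triple(self) -> tuple:
        return (self.kinase_id, self.substrate_id, self.position)


@dataclass
class DropReport:
    """Bookkeeping for rows filtered while mapping phosphosites to proteins."""

    retained: int = 0
    unmapped: int = 0
    mismatched: int = 0
    unmapped_ids: list = field(default_factory=list)

    @property
    def dropped(self) -> int:
        return self.unmapped + self.mismatched

    @property
    def total(self) -> int:
        return self.retained + self.dropped
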