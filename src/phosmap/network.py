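"""Assemble the high-resolution map: kinases -> specific phosphosites.

For every combined-set kinase-substrate pair, each in-vivo phosphosite on
the substrate is scored with the kinase's residue-class-matched motif
(log-odds against the class background PWM). Sites scoring at or above the
motif's random-score cutoff — the operational reading of "unambiguously
assigned" — become site edges. A site may be claimed by several kinases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .metrics import percent
from .motif import (Motif, PWMMatrix, frequency_matrix, match_scores,
                    site_window)
from .types import KSREdge, Phosphosite, ProteinRecord, SiteEdge

logger = logging.getLogger(__name__)


@dataclass
class MapMetrics:
    """The map's evaluation arithmetic, reported in percent.

    recovery_rate + false_negative_rate = 100 by construction;
    true_positive_rate = 100 * recovered_known / total_site_edges.
    """

    recovered_known: int
    known_total: Optional[int]
    total_site_edges: int

    @property
    def recovery_rate(self) -> Optional[float]:
        if not self.known_total:
            return None
        return percent(self.recovered_known, self.known_total)

    @property
    def false_negative_rate(self) -> Optional[float]:
        if not self.known_total:
            return None
        return round(100.0 - 100.0 * self.recovered_known / self.known_total,
                     1)

    @property
    def true_positive_rate(self) -> Optional[float]:
        if not self.total_site_edges:
            return None
        return percent(self.recovered_known, self.total_site_edges)

    def as_dict(self) -> dict:
        return {
            "recovered_known": self.recovered_known,
            "known_total": self.known_total,
            "total_site_edges": self.total_site_edges,
            "recovery_rate": self.recovery_rate,
            "false_negative_rate": self.false_negative_rate,
            "true_positive_rate": self.true_positive_rate,
        }

    @classmethod
    def from_counts(cls, recovered_known: int, known_total: Optional[int],
                    total_site_edges: int) -> "MapMetrics":
        return cls(recovered_known, known_total, total_site_edges)


@dataclass
class AssignmentReport:
    """Edges skipped during site assignment, by reason."""

    no_motif: int = 0
    siteless: int = 0


def assign_sites(
    comksr: Sequence[KSREdge],
    motifs: Dict[Tuple[str, str], Motif],
    phosphosites: Sequence[Phosphosite],
    proteome: Dict[str, ProteinRecord],
    min_score: Optional[float] = None,
    backgrounds: Optional[Dict[str, PWMMatrix]] = None,
    pseudocount: float = 0.5,
) -> Tuple[List[SiteEdge], AssignmentReport]:
    """Score every in-vivo site on each pair's substrate with the kinase's
    class-matched motif; keep sites scoring >= ``min_score`` (default: the
    motif's own random cutoff).

    ``motifs`` is keyed by (kinase_id, residue_class). ``backgrounds`` maps
    residue class to the background PWM used for scoring; when absent it is
    rebuilt from all class-matched phosphosite windows.
    """
    sites_by_protein: Dict[str, List[Phosphosite]] = {}
    for s in phosphosites:
        if s.protein_id in proteome:
            sites_by_protein.setdefault(s.protein_id, []).append(s)

    if backgrounds is None:
        backgrounds = class_backgrounds(phosphosites, proteome,
                                        pseudocount=pseudocount)

    report = AssignmentReport()
    out: List[SiteEdge] = []
    for edge in comksr:
        classes = [c for c in ("ST", "Y") if (edge.kinase_id, c) in motifs]
        if not classes:
            report.no_motif += 1
            continue
        sites = sites_by_protein.get(edge.substrate_id, [])
        if not sites:
            report.siteless += 1
            continue
        for cls in classes:
            motif = motifs[(edge.kinase_id, cls)]
            class_sites = [s for s in sites if s.residue_class == cls]
            if not class_sites or cls not in backgrounds:
                continue
            seq = proteome[edge.substrate_id].sequence
            windows = [site_window(seq, s.position, motif.pwm.width)
                       for s in class_sites]
            scores = match_scores(windows, motif.pwm, backgrounds[cls])
            cut = motif.final_cutoff if min_score is None else min_score
            for s, sc in zip(class_sites, scores):
                if sc >= cut:
                    out.append(SiteEdge(edge.kinase_id, edge.substrate_id,
                                        s.position, s.residue,
                                        match_score=float(sc)))
    if report.no_motif:
        logger.warning("%d combined edges skipped: kinase lacks a motif",
                       report.no_motif)
    return out, report


def class_backgrounds(phosphosites: Sequence[Phosphosite],
                      proteome: Dict[str, ProteinRecord],
                      width: int = 15,
                      pseudocount: float = 0.5) -> Dict[str, PWMMatrix]:
    """Background PWMs per residue class from all mappable site windows."""
    windows: Dict[str, list] = {"ST": [], "Y": []}
    for s in phosphosites:
        rec = proteome.get(s.protein_id)
        if rec is None or s.position > len(rec.sequence):
            continue
        windows[s.residue_class].append(
            site_window(rec.sequence, s.position, width))
    return {cls: frequency_matrix(w, pseudocount)
            for cls, w in windows.items() if w}


def flag_known(site_edges: Sequence[SiteEdge],
               known_site_specific: Set[Tuple[str, str, int]]
               ) -> List[SiteEdge]:
    """Mark edges whose (kinase, substrate, position) triple is known."""
    return [
        SiteEdge(e.kinase_id, e.substrate_id, e.position, e.residue,
                 e.match_score,
                 status="known" if e.triple in known_site_specific
                 else "novel")
        for e in site_edges
    ]


def map_metrics(site_edges: Sequence[SiteEdge],
                known_site_specific: Set[Tuple[str, str, int]]) -> MapMetrics:
    """Recovery / false-negative / true-positive rates of the site map."""
    flagged = flag_known(site_edges, known_site_specific)
    recovered = sum(1 for e in flagged if e.status == "known")
    return MapMetrics(recovered_known=recovered,
                      known_total=len(known_site_specific),
                      total_site_edges=len(flagged))


def pathway_intermediates(comksr: Sequence[KSREdge],
                          pathway_edges: Sequence[Tuple[str, str]]
                          ) -> Dict[Tuple[str, str], List[str]]:
    """Candidate intermediate kinases K with A -> K and K -> C in the set.

    The classic example: an indirect Btk -> ARID3A connection resolved by
    PKA, which is both a Btk substrate and an ARID3A kinase.
    """
    downstream: Dict[str, set] = {}
    upstream: Dict[str, set] = {}
    for e in comksr:
        downstream.setdefault(e.kinase_id, set()).add(e.substrate_id)
        upstream.setdefault(e.substrate_id, set()).add(e.kinase_id)
    out: Dict[Tuple[str, str], List[str]] = {}
    for a, c in pathway_edges:
        mids = downstream.get(a, set()) & upstream.get(c, set())
        out[(a, c)] = sorted(mids)
    return out
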