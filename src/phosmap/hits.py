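"""Microarray hit calling: intensity tables -> raw kinase-substrate edges.

A protein is a hit for a kinase when its spot intensity lies at least
``sd_multiplier`` standard deviations above the mean of that assay (the
classic 3-SD rule). Proteins that light up on the no-kinase control array —
autophosphorylation or tight ATP binding — are blacklisted first, and the
per-array mean/SD are computed over the non-blacklisted spots only, so the
rule is invariant under affine rescaling of an array.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .types import CONTROL, IntensityTable, KSREdge

logger = logging.getLogger(__name__)


@dataclass
class HitCallConfig:
    """Hit-calling thresholds in units of per-array standard deviations."""

    sd_multiplier: float = 3.0
    control_sd_multiplier: float = 3.0
    log_transform: bool = False  # log1p intensities before z-scoring

    def __post_init__(self):
        if self.sd_multiplier <= 0 or self.control_sd_multiplier <= 0:
            raise ValueError("SD multipliers must be positive")


def _maybe_log(values: np.ndarray, config: HitCallConfig) -> np.ndarray:
    return np.log1p(values) if config.log_transform else values


def blacklist_from_control(control: IntensityTable,
                           config: Optional[HitCallConfig] = None) -> Set[str]:
    """Proteins whose control intensity exceeds mean + k * SD of the control
    array; these autophosphorylate or bind ATP and are excluded downstream."""
    config = config or HitCallConfig()
    if not control.values:
        raise ValueError("control table is empty")
    ids = sorted(control.values)
    v = _maybe_log(np.array([control.values[p] for p in ids]), config)
    sd = v.std()  # population SD; negligible vs n-1 at array scale
    if sd == 0:
        warnings.warn("control array has zero SD; empty blacklist")
        return set()
    cut = v.mean() + config.control_sd_multiplier * sd
    return {p for p, x in zip(ids, v) if x > cut}


def call_hits(table: IntensityTable, blacklist: Set[str],
              config: Optional[HitCallConfig] = None) -> List[KSREdge]:
    """Raw KSR edges of one kinase assay: z >= sd_multiplier over the
    non-blacklisted spots of this array."""
    config = config or HitCallConfig()
    if table.is_control:
        raise ValueError("call_hits expects a kinase assay, not the control")
    ids = sorted(p for p in table.values if p not in blacklist)
    if not ids:
        return []
    v = _maybe_log(np.array([table.values[p] for p in ids]), config)
    sd = v.std()
    if sd == 0:
        warnings.warn(f"{table.kinase_id}: zero intensity SD; no hits")
        return []
    z = (v - v.mean()) / sd
    return [
        KSREdge(table.kinase_id, pid, stage="raw", array_z=float(zi))
        for pid, zi in zip(ids, z) if zi >= config.sd_multiplier
    ]


def replicate_correlation(table_a: IntensityTable,
                          table_b: IntensityTable) -> float:
    """Pearson correlation of log1p intensities over shared proteins."""
    shared = sorted(set(table_a.values) & set(table_b.values))
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared proteins, got {len(shared)}")
    a = np.log1p([table_a.values[p] for p in shared])
    b = np.log1p([table_b.values[p] for p in shared])
    return float(stats.pearsonr(a, b).statistic)


class HitCaller(BaseEstimator):
    """Estimator facade: fit on the control array, call hits per assay.

    Fitted attributes: ``blacklist_`` (control-flagged proteins),
    ``control_mean_``, ``control_sd_``.
    """

    def __init__(self, sd_multiplier: float = 3.0,
                 control_sd_multiplier: float = 3.0,
                 log_transform: bool = False):
        self.sd_multiplier = sd_multiplier
        self.control_sd_multiplier = control_sd_multiplier
        self.log_transform = log_transform

    def _config(self) -> HitCallConfig:
        return HitCallConfig(self.sd_multiplier, self.control_sd_multiplier,
                             self.log_transform)

    def fit(self, X: IntensityTable, y=None) -> "HitCaller":
        """Learn the blacklist from the no-kinase control table ``X``."""
        config = self._config()
        self.blacklist_ = blacklist_from_control(X, config)
        v = _maybe_log(np.array(list(X.values.values()), dtype=float), config)
        self.control_mean_ = float(v.mean())
        self.control_sd_ = float(v.std())
        return self

    def predict(self, X: IntensityTable) -> List[KSREdge]:
        """Raw KSR edges for one kinase assay."""
        if not hasattr(self, "blacklist_"):
            raise ValueError("HitCaller is not fitted")
        return call_hits(X, self.blacklist_, self._config())

    def predict_many(self, tables: Sequence[IntensityTable]) -> List[KSREdge]:
        edges: List[KSREdge] = []
        for t in tables:
            edges.extend(self.predict(t))
        return edges
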