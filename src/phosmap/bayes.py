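"""Naive-Bayes refinement of raw kinase-substrate relationships.

Microarray hits are in-vitro events; many are not physiologically relevant.
A kinase and its in-vivo substrate tend to share tissue expression, live in
the same subcellular compartment, and interact (directly or through a common
partner) in the PPI network. A naive-Bayes model trained on literature-known
kinase-substrate pairs (positives) versus kinase-free protein pairs
(negatives) turns these three features into an additive log-likelihood-ratio
score (the L-score). Each raw edge receives an empirical p-value against the
negative-set score distribution; edges with p < alpha form the refined set,
which is then merged with the literature-known pairs into the combined set.

Features are discretized: the tissue-coexpression Pearson correlation into
equal-width bins on [-1, 1], binary features into {0, 1}; every feature has
an explicit missing bin (annotation coverage itself is informative). Bin
probabilities carry a Laplace pseudocount of 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .types import KSREdge

logger = logging.getLogger(__name__)

FEATURES = ("tissue_coexpr", "coloc", "ppi")

_MISSING = -1  # sentinel bin index before offsetting; NaN in frames


@dataclass(frozen=True)
class PairFeatures:
    """Features of one (kinase, substrate) pair; ``None`` marks missing."""

    tissue_coexpr: Optional[float] = None
    coloc: Optional[int] = None
    ppi: Optional[int] = None

    def as_row(self) -> dict:
        return {
            "tissue_coexpr": np.nan if self.tissue_coexpr is None
            else float(self.tissue_coexpr),
            "coloc": np.nan if self.coloc is None else float(self.coloc),
            "ppi": np.nan if self.ppi is None else float(self.ppi),
        }


@dataclass
class Annotations:
    """Protein annotations backing the three pair features.

    ``expression``: protein x tissue matrix (NaN = unmeasured);
    ``compartments``: protein id -> set of compartment labels;
    ``ppi``: undirected protein-protein interaction graph.
    """

    expression: pd.DataFrame
    compartments: Dict[str, set]
    ppi: nx.Graph

    @classmethod
    def from_tables(cls, expression: pd.DataFrame,
                    compartments: Dict[str, set],
                    ppi_edges: Sequence[Tuple[str, str]]) -> "Annotations":
        g = nx.Graph()
        g.add_edges_from(ppi_edges)
        return cls(expression, compartments, g)


def compute_features(kinase_id: str, substrate_id: str,
                     annotations: Annotations,
                     min_shared_tissues: int = 3) -> PairFeatures:
    """Feature vector of one pair; absent annotation yields missing."""
    coexpr = None
    expr = annotations.expression
    if kinase_id in expr.index and substrate_id in expr.index:
        a = expr.loc[kinase_id].to_numpy(dtype=float)
        b = expr.loc[substrate_id].to_numpy(dtype=float)
        mask = ~(np.isnan(a) | np.isnan(b))
        if mask.sum() >= min_shared_tissues:
            aa, bb = a[mask], b[mask]
            sa, sb = aa.std(), bb.std()
            if sa > 0 and sb > 0:
                coexpr = float(np.clip(
                    np.corrcoef(aa, bb)[0, 1], -1.0, 1.0))

    coloc = None
    comp = annotations.compartments
    if kinase_id in comp and substrate_id in comp:
        coloc = int(bool(comp[kinase_id] & comp[substrate_id]))

    ppi = None
    g = annotations.ppi
    if g.has_node(kinase_id) and g.has_node(substrate_id):
        if g.has_edge(kinase_id, substrate_id):
            ppi = 1
        else:
            ka = set(g.adj[kinase_id])
            sa = set(g.adj[substrate_id])
            ppi = int(bool(ka & sa))

    return PairFeatures(coexpr, coloc, ppi)


def features_frame(pairs: Sequence[Tuple[str, str]],
                   annotations: Annotations) -> pd.DataFrame:
    """Feature table (NaN = missing) for a list of (kinase, substrate)."""
    rows = [compute_features(k, s, annotations).as_row() for k, s in pairs]
    return pd.DataFrame(rows, columns=list(FEATURES))


# ---------------------------------------------------------------------------
# The model
# ---------------------------------------------------------------------------

@dataclass
class BayesModel:
    """Binned log-likelihood ratios plus the negative score distribution."""

    bin_edges: np.ndarray                 # tissue_coexpr bin edges on [-1, 1]
    llr: Dict[str, np.ndarray]            # per feature: llr per bin (+ missing)
    neg_scores: np.ndarray                # sorted ascending
    n_pos: int
    n_neg: int
    probs: Dict[str, Tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict)             # per feature: (P(bin|pos), P(bin|neg))


def _bin_indices(x: pd.Series, feature: str,
                 bin_edges: np.ndarray) -> np.ndarray:
    """Map raw feature values to bin indices; the last bin is 'missing'."""
    v = x.to_numpy(dtype=float)
    if feature == "tissue_coexpr":
        n_bins = len(bin_edges) - 1
        idx = np.clip(np.digitize(v, bin_edges[1:-1]), 0, n_bins - 1)
        idx[np.isnan(v)] = n_bins
    else:
        idx = np.where(v > 0.5, 1, 0)
        idx[np.isnan(v)] = 2
    return idx.astype(int)


def _n_bins(feature: str, bin_edges: np.ndarray) -> int:
    return len(bin_edges) if feature == "tissue_coexpr" else 3


def train(positive: pd.DataFrame, negative: pd.DataFrame,
          n_bins: int = 5, pseudocount: float = 1.0) -> BayesModel:
    """Learn per-bin log2 likelihood ratios from feature tables.

    ``positive`` and ``negative`` are frames with columns
    (tissue_coexpr, coloc, ppi); NaN marks a missing feature.
    """
    if len(positive) < 10 or len(negative) < 10:
        raise ValueError("need >= 10 positive and negative training pairs")
    bin_edges = np.linspace(-1.0, 1.0, n_bins + 1)
    llr: Dict[str, np.ndarray] = {}
    probs: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for f in FEATURES:
        total = _n_bins(f, bin_edges)
        pi = _bin_indices(positive[f], f, bin_edges)
        ni = _bin_indices(negative[f], f, bin_edges)
        cp = np.bincount(pi, minlength=total).astype(float)
        cn = np.bincount(ni, minlength=total).astype(float)
        p_pos = (cp + pseudocount) / (len(positive) + total * pseudocount)
        p_neg = (cn + pseudocount) / (len(negative) + total * pseudocount)
        probs[f] = (p_pos, p_neg)
        if len(np.unique(np.concatenate([pi, ni]))) == 1:
            warnings.warn(f"feature {f!r} is degenerate (one value "
                          "everywhere); its llr is set to 0")
            llr[f] = np.zeros(total)
        else:
            llr[f] = np.log2(p_pos) - np.log2(p_neg)
    model = BayesModel(bin_edges=bin_edges, llr=llr,
                       neg_scores=np.empty(0), n_pos=len(positive),
                       n_neg=len(negative), probs=probs)
    model.neg_scores = np.sort(l_scores(negative, model))
    return model


def l_scores(features: pd.DataFrame, model: BayesModel) -> np.ndarray:
    """Additive L-score: sum over features of the llr of the observed bin."""
    total = np.zeros(len(features))
    for f in FEATURES:
        idx = _bin_indices(features[f], f, model.bin_edges)
        total += model.llr[f][idx]
    return total


def l_score(features: PairFeatures, model: BayesModel) -> float:
    return float(l_scores(pd.DataFrame([features.as_row()]), model)[0])


def empirical_p(L, model: BayesModel) -> np.ndarray:
    """p = (1 + #{negative scores >= L}) / (n_neg + 1).

    The +1 smoothing keeps p in (0, 1] and makes the p-values of draws from
    the negative distribution super-uniform.
    """
    if model.neg_scores.size == 0:
        raise ValueError("model has no negative scores")
    L = np.atleast_1d(np.asarray(L, dtype=float))
    n = model.neg_scores.size
    ge = n - np.searchsorted(model.neg_scores, L, side="left")
    return (1.0 + ge) / (n + 1.0)


# ---------------------------------------------------------------------------
# Refinement and combination
# ---------------------------------------------------------------------------

def refine(raw_edges: Sequence[KSREdge], model: BayesModel,
           annotations: Annotations, alpha: float = 0.05) -> List[KSREdge]:
    """Keep raw edges whose empirical p-value beats ``alpha``."""
    if not raw_edges:
        return []
    feats = features_frame([e.pair for e in raw_edges], annotations)
    L = l_scores(feats, model)
    p = empirical_p(L, model)
    out = []
    for e, li, pi in zip(raw_edges, L, p):
        if pi < alpha:
            out.append(KSREdge(e.kinase_id, e.substrate_id, stage="refined",
                               array_z=e.array_z, l_score=float(li),
                               p_value=float(pi)))
    return out


def combine(ref_edges: Sequence[KSREdge],
            known_edges: Sequence[KSREdge]) -> List[KSREdge]:
    """Union refined and known edges by pair; known wins, overlaps flagged."""
    refined_by_pair = {e.pair: e for e in ref_edges}
    out: List[KSREdge] = []
    known_pairs = set()
    for e in known_edges:
        if e.pair in known_pairs:
            continue
        known_pairs.add(e.pair)
        overlap = e.pair in refined_by_pair
        r = refined_by_pair.get(e.pair)
        out.append(KSREdge(e.kinase_id, e.substrate_id, stage="known",
                           array_z=r.array_z if r else None,
                           l_score=r.l_score if r else None,
                           p_value=r.p_value if r else None,
                           known_overlap=overlap))
    for e in ref_edges:
        if e.pair not in known_pairs:
            out.append(e)
    return out


def rank_edges(raw_edges: Sequence[KSREdge], model: BayesModel,
               annotations: Annotations) -> List[Tuple[KSREdge, float]]:
    """Edges with L-scores, stably sorted by (-L, kinase, substrate)."""
    feats = features_frame([e.pair for e in raw_edges], annotations)
    L = l_scores(feats, model)
    pairs = list(zip(raw_edges, (float(x) for x in L)))
    pairs.sort(key=lambda t: (-t[1], t[0].kinase_id, t[0].substrate_id))
    return pairs


def cross_validate(known_edges: Sequence[KSREdge],
                   raw_edges: Sequence[KSREdge],
                   annotations: Annotations,
                   negative_pool: Sequence[Tuple[str, str]],
                   k_folds: int = 5, alpha: float = 0.05,
                   n_bins: int = 5,
                   rng: Optional[np.random.Generator] = None) -> float:
    """Fold-enrichment of held-out known-KSR recovery over random ranking.

    Positives are split into ``k_folds`` folds; per fold, the model is
    trained on the remaining positives (negatives bootstrap-resampled from
    ``negative_pool``), raw edges are ranked by L-score, and recovery of the
    held-out positives within the top n is compared with the random
    expectation n / |raw|, where n is the refined-set size at ``alpha``
    (floored at ceil(alpha * |raw|) so an uninformative model is scored
    against a non-empty top list). Returns the mean enrichment over folds.
    """
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    positives = [e.pair for e in known_edges]
    if len(positives) < k_folds:
        raise ValueError("fewer positives than folds")
    rng = rng if rng is not None else np.random.default_rng(0)
    order = rng.permutation(len(positives))
    folds = np.array_split(order, k_folds)
    raw_pairs = [e.pair for e in raw_edges]
    raw_set = set(raw_pairs)
    neg_pool = list(negative_pool)

    enrichments = []
    for fold in folds:
        held = {positives[i] for i in fold}
        train_pos = [positives[i] for i in order if positives[i] not in held]
        neg_idx = rng.integers(0, len(neg_pool), size=len(neg_pool))
        train_neg = [neg_pool[i] for i in neg_idx]
        model = train(features_frame(train_pos, annotations),
                      features_frame(train_neg, annotations), n_bins=n_bins)
        ranked = rank_edges(raw_edges, model, annotations)
        p = empirical_p(np.array([L for _, L in ranked]), model)
        n_top = max(int((p < alpha).sum()),
                    int(np.ceil(alpha * len(raw_edges))))
        top_pairs = {e.pair for e, _ in ranked[:n_top]}
        recoverable = held & raw_set
        if not recoverable:
            continue
        recovery = len(recoverable & top_pairs) / len(recoverable)
        expectation = n_top / len(raw_edges)
        enrichments.append(recovery / expectation)
    if not enrichments:
        raise ValueError("no fold had recoverable held-out positives")
    return float(np.mean(enrichments))


# ---------------------------------------------------------------------------
# Estimator facade
# ---------------------------------------------------------------------------

class KSRBayesRefiner(BaseEstimator):
    """Sklearn-style classifier over pair-feature frames.

    ``fit(X, y)`` takes a feature frame (columns tissue_coexpr, coloc, ppi;
    NaN = missing) and binary labels (1 = known KSR, 0 = kinase-free pair).
    ``decision_function`` returns L-scores, ``predict_proba``-style
    ``pvalues`` returns empirical p-values, and ``predict`` thresholds them
    at ``alpha``.
    """

    def __init__(self, n_bins: int = 5, pseudocount: float = 1.0,
                 alpha: float = 0.05):
        self.n_bins = n_bins
        self.pseudocount = pseudocount
        self.alpha = alpha

    def fit(self, X: pd.DataFrame, y) -> "KSRBayesRefiner":
        y = np.asarray(y)
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("y must be binary (1 = known KSR)")
        X = X[list(FEATURES)]
        self.model_ = train(X[y == 1], X[y == 0], n_bins=self.n_bins,
                            pseudocount=self.pseudocount)
        self.classes_ = np.array([0, 1])
        return self

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        self._check_fitted()
        return l_scores(X[list(FEATURES)], self.model_)

    def pvalues(self, X: pd.DataFrame) -> np.ndarray:
        self._check_fitted()
        return empirical_p(self.decision_function(X), self.model_)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.pvalues(X) < self.alpha).astype(int)

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise ValueError("KSRBayesRefiner is not fitted")
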