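"""Position weight matrices and the M3 iterative phospho-motif finder.

M3 derives a kinase's consensus phosphorylation motif from the in-vivo
phosphosites found on its microarray-identified substrates. Because a
substrate's sites are a mixture (other kinases phosphorylate it too), the
algorithm grows a seed set greedily: start from the peptides that best match
the whole-foreground frequency matrix, then repeatedly admit the single best
remaining peptide as long as it scores above what random background peptides
achieve against the current seed matrix, or until the seed set reaches the
kinase's substrate count.

Scores are log-odds in bits against a background PWM built from all
phosphosite windows of the same residue class (pS/pT motifs and pY motifs are
modeled separately, so a dual-specificity kinase yields two motifs).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from sklearn.base import BaseEstimator

from .alphabet import AA_INDEX, AMINO_ACIDS, FULL_ALPHABET, PAD, encode_windows
from .types import KSREdge, Phosphosite, ProteinRecord

logger = logging.getLogger(__name__)

N_LETTERS = len(FULL_ALPHABET)  # 20 amino acids + terminal pad


# ---------------------------------------------------------------------------
# PWM container
# ---------------------------------------------------------------------------

@dataclass
class PWMMatrix:
    """A (21, W) per-position probability matrix anchored at the center.

    Rows follow :data:`phosmap.alphabet.FULL_ALPHABET`; row 20 is the
    terminal-padding symbol ``-``. Every column sums to 1.
    """

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != N_LETTERS:
            raise ValueError(
                f"PWM must be ({N_LETTERS}, W), got {self.values.shape}"
            )
        if np.any(self.values < 0):
            raise ValueError("PWM entries must be nonnegative")
        sums = self.values.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError(f"PWM columns must sum to 1, got {sums}")

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def center(self) -> int:
        return (self.width - 1) // 2

    def without_pad(self) -> np.ndarray:
        """Drop the pad row and renormalize columns to 20-dim distributions."""
        v = self.values[: len(AMINO_ACIDS)].copy()
        sums = v.sum(axis=0)
        sums[sums == 0] = 1.0
        return v / sums

    def __eq__(self, other):
        return isinstance(other, PWMMatrix) and np.array_equal(
            self.values, other.values
        )


@dataclass(frozen=True)
class Phosphopeptide:
    """A W-mer window centered on a phosphosite, ``-``-padded at termini."""

    protein_id: str
    position: int  # 1-based position of the phospho residue
    residue: str
    window: str

    def __post_init__(self):
        w = len(self.window)
        if self.window[(w - 1) // 2] != self.residue:
            raise ValueError(
                f"window center {self.window[(w - 1) // 2]!r} != residue "
                f"{self.residue!r} for {self.protein_id}:{self.position}"
            )

    @property
    def sort_key(self) -> tuple:
        return (self.window, self.protein_id, self.position)


@dataclass
class M3Config:
    """Tunable knobs of the iterative motif search."""

    width: int = 15
    seed_size: int = 10
    pseudocount: float = 0.5
    cutoff_percentile: float = 0.99
    n_random: int = 10_000
    rng_seed: int = 0

    def __post_init__(self):
        if self.seed_size < 2:
            raise ValueError("seed_size must be >= 2")
        if not (0.0 < self.cutoff_percentile < 1.0):
            raise ValueError("cutoff_percentile must be in (0, 1)")
        if self.width % 2 != 1:
            raise ValueError("width must be odd (center-anchored windows)")


@dataclass
class Motif:
    """A kinase's discovered motif: PWM, the seed peptides behind it, and
    the random-score cutoff used both to stop the search and, downstream,
    to call a site an unambiguous match."""

    kinase_id: str
    residue_class: str  # "ST" or "Y"
    pwm: PWMMatrix
    seed_peptides: List[str]
    consensus: str
    final_cutoff: float
    n_foreground: int = 0


# ---------------------------------------------------------------------------
# Window extraction
# ---------------------------------------------------------------------------

def site_window(sequence: str, position: int, width: int = 15) -> str:
    """W-mer centered on 1-based ``position``, padded with '-' at termini."""
    half = (width - 1) // 2
    i = position - 1
    if not (0 <= i < len(sequence)):
        raise ValueError(f"position {position} outside sequence of length "
                         f"{len(sequence)}")
    left = sequence[max(0, i - half): i]
    right = sequence[i + 1: i + 1 + half]
    return (PAD * (half - len(left)) + left + sequence[i] + right
            + PAD * (half - len(right)))


def extract_foreground_background(
    ksr_edges: Sequence[KSREdge],
    phosphosites: Sequence[Phosphosite],
    proteome: Dict[str, ProteinRecord],
    config: Optional[M3Config] = None,
) -> Tuple[Dict[Tuple[str, str], List[Phosphopeptide]],
           Dict[str, List[Phosphopeptide]]]:
    """Bin phosphosite windows per kinase and residue class.

    The foreground of kinase k, class c holds the windows of every class-c
    site on k's substrates (duplicates retained: two kinases sharing a
    substrate each see its sites). The background of class c holds the
    windows of every class-c site on any protein.
    """
    config = config or M3Config()
    sites_by_protein: Dict[str, List[Phosphosite]] = {}
    for s in phosphosites:
        sites_by_protein.setdefault(s.protein_id, []).append(s)

    peptide_cache: Dict[Tuple[str, int], Phosphopeptide] = {}

    def peptide(site: Phosphosite) -> Phosphopeptide:
        key = (site.protein_id, site.position)
        if key not in peptide_cache:
            seq = proteome[site.protein_id].sequence
            peptide_cache[key] = Phosphopeptide(
                site.protein_id, site.position, site.residue,
                site_window(seq, site.position, config.width),
            )
        return peptide_cache[key]

    background: Dict[str, List[Phosphopeptide]] = {"ST": [], "Y": []}
    for pid, sites in sorted(sites_by_protein.items()):
        if pid not in proteome:
            continue
        for s in sorted(sites, key=lambda s: s.position):
            background[s.residue_class].append(peptide(s))

    substrates: Dict[str, set] = {}
    for e in ksr_edges:
        substrates.setdefault(e.kinase_id, set()).add(e.substrate_id)

    foreground: Dict[Tuple[str, str], List[Phosphopeptide]] = {}
    for kinase, subs in sorted(substrates.items()):
        per_class: Dict[str, List[Phosphopeptide]] = {"ST": [], "Y": []}
        for sub in sorted(subs):
            for s in sorted(sites_by_protein.get(sub, []),
                            key=lambda s: s.position):
                if sub in proteome:
                    per_class[s.residue_class].append(peptide(s))
        for cls, peps in per_class.items():
            if peps:
                foreground[(kinase, cls)] = peps
        if not per_class["ST"] and not per_class["Y"]:
            logger.warning("kinase %s has no mappable foreground sites; "
                           "skipped", kinase)
    return foreground, background


# ---------------------------------------------------------------------------
# Matrices and scoring
# ---------------------------------------------------------------------------

def _windows_of(peptides: Sequence) -> List[str]:
    return [p.window if isinstance(p, Phosphopeptide) else p for p in peptides]


def frequency_matrix(peptides: Sequence, pseudocount: float = 0.5) -> PWMMatrix:
    """Per-position letter frequencies with a Laplace pseudocount.

    entry(a, j) = (count(a at j) + pseudocount) / (n + 21 * pseudocount)
    """
    windows = _windows_of(peptides)
    if not windows:
        raise ValueError("frequency_matrix needs at least one peptide")
    idx = encode_windows(windows)
    n, width = idx.shape
    counts = np.zeros((N_LETTERS, width))
    for j in range(width):
        np.add.at(counts[:, j], idx[:, j], 1.0)
    return PWMMatrix((counts + pseudocount) / (n + N_LETTERS * pseudocount))


def _log_ratio(fg: PWMMatrix, bg: PWMMatrix) -> np.ndarray:
    if fg.width != bg.width:
        raise ValueError(f"width mismatch: {fg.width} vs {bg.width}")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.log2(fg.values) - np.log2(bg.values)
    # letters absent from both fg and bg never occur in scored windows with
    # matched pseudocounts; but a zero bg against nonzero fg is ill-posed
    if np.any(np.isposinf(r)):
        raise ValueError("zero background probability where foreground is "
                         "nonzero; use a positive pseudocount")
    r[np.isnan(r)] = 0.0  # 0/0: letter unseen everywhere
    return r


def match_scores(windows, fg: PWMMatrix, bg: PWMMatrix) -> np.ndarray:
    """Vectorized log-odds (bits) of windows under fg vs bg."""
    if isinstance(windows, np.ndarray) and windows.dtype == np.intp:
        idx = windows
    else:
        idx = encode_windows(_windows_of(windows))
    ratio = _log_ratio(fg, bg)
    cols = np.arange(idx.shape[1])
    return ratio[idx, cols].sum(axis=1)


def match_score(window: Union[str, Phosphopeptide], fg: PWMMatrix,
                bg: PWMMatrix) -> float:
    """Log-odds score (bits) of one window: sum_j log2(fg[w_j, j]/bg[w_j, j])."""
    return float(match_scores([window], fg, bg)[0])


def random_cutoff(
    bg_peptides: Sequence,
    fg: PWMMatrix,
    bg: PWMMatrix,
    config: M3Config,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Score threshold: the ``cutoff_percentile`` quantile of match scores of
    ``n_random`` windows resampled with replacement from the background."""
    if config.n_random < 100:
        raise ValueError("n_random must be >= 100")
    windows = _windows_of(bg_peptides)
    if not windows:
        raise ValueError("empty background")
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    idx = encode_windows(windows)
    pick = rng.integers(0, idx.shape[0], size=config.n_random)
    scores = match_scores(idx[pick], fg, bg)
    return float(np.quantile(scores, config.cutoff_percentile))


# ---------------------------------------------------------------------------
# Consensus rendering
# ---------------------------------------------------------------------------

def consensus_string(pwm: PWMMatrix, residue_class: Optional[str] = None) -> str:
    """Compact summary: uppercase when the top letter holds >= 0.5 of a
    column, lowercase in [0.25, 0.5), 'x' otherwise; the center is rendered
    as the lowercase phosphoacceptor class letter (s/t/y)."""
    out = []
    aa_probs = pwm.values[: len(AMINO_ACIDS)]
    for j in range(pwm.width):
        if j == pwm.center:
            sty = {r: pwm.values[AA_INDEX[r], j] for r in "STY"}
            if residue_class == "Y":
                out.append("y")
            elif residue_class == "ST":
                out.append("s" if sty["S"] >= sty["T"] else "t")
            else:
                out.append(max(sty, key=sty.get).lower())
            continue
        best = int(np.argmax(aa_probs[:, j]))
        p = aa_probs[best, j]
        if p >= 0.5:
            out.append(AMINO_ACIDS[best])
        elif p >= 0.25:
            out.append(AMINO_ACIDS[best].lower())
        else:
            out.append("x")
    return "".join(out)


# ---------------------------------------------------------------------------
# The iterative search
# ---------------------------------------------------------------------------

def m3(
    foreground: Sequence,
    background: Sequence,
    substrate_count: int,
    config: Optional[M3Config] = None,
    kinase_id: str = "kinase",
    residue_class: str = "ST",
) -> Motif:
    """Run the iterative motif search for one kinase and residue class.

    Step 1: build a frequency matrix from ALL foreground windows and score
    every window against it (log-odds vs the class background PWM).
    Step 2: the top ``seed_size`` windows (ties broken lexicographically on
    the window string, then protein id and position) become the seed set.
    Step 3+: rebuild the seed PWM, rescore the remaining windows, and admit
    the single best one — provided its score is strictly positive and at
    least the random-background cutoff recomputed against the current seed
    PWM. Stop when no candidate qualifies, the seed count reaches
    ``substrate_count``, or no windows remain.
    """
    config = config or M3Config()
    if not foreground:
        raise ValueError("empty foreground")
    rng = np.random.default_rng(config.rng_seed)

    bg_pwm = frequency_matrix(background, config.pseudocount)

    fg_list = list(foreground)
    keys = [p.sort_key if isinstance(p, Phosphopeptide) else (p,)
            for p in fg_list]
    windows = _windows_of(fg_list)

    def ranked(indices: List[int], scores: np.ndarray) -> List[int]:
        return sorted(indices, key=lambda i: (-scores[i], keys[i]))

    if len(fg_list) < config.seed_size:
        warnings.warn(
            f"{kinase_id}/{residue_class}: foreground smaller than seed_size "
            f"({len(fg_list)} < {config.seed_size}); using all windows as "
            "seeds without iteration"
        )
        seed_idx = list(range(len(fg_list)))
        remaining: List[int] = []
    else:
        initial = frequency_matrix(fg_list, config.pseudocount)
        scores = match_scores(windows, initial, bg_pwm)
        order = ranked(list(range(len(fg_list))), scores)
        n_seed = min(config.seed_size, substrate_count)
        seed_idx = order[:n_seed]
        remaining = order[n_seed:]

        while remaining and len(seed_idx) < substrate_count:
            seed_pwm = frequency_matrix([windows[i] for i in seed_idx],
                                        config.pseudocount)
            cutoff = random_cutoff(background, seed_pwm, bg_pwm, config, rng)
            rem_scores = match_scores([windows[i] for i in remaining],
                                      seed_pwm, bg_pwm)
            local = sorted(range(len(remaining)),
                           key=lambda i: (-rem_scores[i],
                                          keys[remaining[i]]))[0]
            best = rem_scores[local]
            if best < cutoff or best <= 0.0:
                break
            seed_idx.append(remaining.pop(local))

    final_pwm = frequency_matrix([windows[i] for i in seed_idx],
                                 config.pseudocount)
    final_cutoff = random_cutoff(background, final_pwm, bg_pwm, config, rng)
    return Motif(
        kinase_id=kinase_id,
        residue_class=residue_class,
        pwm=final_pwm,
        seed_peptides=[windows[i] for i in seed_idx],
        consensus=consensus_string(final_pwm, residue_class),
        final_cutoff=final_cutoff,
        n_foreground=len(fg_list),
    )


class M3MotifFinder(BaseEstimator):
    """Estimator facade over :func:`m3`.

    Parameters mirror :class:`M3Config`. ``fit`` consumes foreground and
    background peptide windows and exposes the discovered motif through
    fitted attributes (``pwm_``, ``consensus_``, ``cutoff_``, ``seeds_``).
    """

    def __init__(self, width: int = 15, seed_size: int = 10,
                 pseudocount: float = 0.5, cutoff_percentile: float = 0.99,
                 n_random: int = 10_000, random_state: int = 0,
                 kinase_id: str = "kinase", residue_class: str = "ST"):
        self.width = width
        self.seed_size = seed_size
        self.pseudocount = pseudocount
        self.cutoff_percentile = cutoff_percentile
        self.n_random = n_random
        self.random_state = random_state
        self.kinase_id = kinase_id
        self.residue_class = residue_class

    def _config(self) -> M3Config:
        return M3Config(width=self.width, seed_size=self.seed_size,
                        pseudocount=self.pseudocount,
                        cutoff_percentile=self.cutoff_percentile,
                        n_random=self.n_random, rng_seed=self.random_state)

    def fit(self, X: Sequence, background: Sequence,
            substrate_count: Optional[int] = None) -> "M3MotifFinder":
        """Discover a motif from foreground windows ``X`` vs ``background``."""
        substrate_count = (substrate_count if substrate_count is not None
                           else len(X))
        self.motif_ = m3(X, background, substrate_count, self._config(),
                         kinase_id=self.kinase_id,
                         residue_class=self.residue_class)
        self.background_pwm_ = frequency_matrix(background, self.pseudocount)
        self.pwm_ = self.motif_.pwm
        self.consensus_ = self.motif_.consensus
        self.cutoff_ = self.motif_.final_cutoff
        self.seeds_ = self.motif_.seed_peptides
        return self

    def transform(self, X: Sequence) -> np.ndarray:
        """Log-odds match scores (bits) of windows against the fitted motif."""
        if not hasattr(self, "pwm_"):
            raise ValueError("M3MotifFinder is not fitted")
        return match_scores(X, self.pwm_, self.background_pwm_)

    def predict(self, X: Sequence) -> np.ndarray:
        """Boolean: does each window score at or above the motif cutoff."""
        return self.transform(X) >= self.cutoff_
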