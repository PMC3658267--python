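"""Synthetic phosphoproteome benchmark with planted ground truth.

Every pipeline input is generated under one seeded RNG: an arrayed proteome
drawn from proteome-average amino-acid frequencies, per-kinase planted
motifs (PWMs with a configurable probability mass on a consensus letter per
column), true substrate sites whose windows are drawn from the planted PWM
and spliced into the sequences, decoy sites at naturally occurring S/T/Y
residues, spot-intensity tables with Gaussian noise (true pairs and
autophosphorylating blacklist proteins carry added signal), and annotation
tables whose pair features are statistically enriched on true pairs.

The generator's defaults are the package's reference benchmark; see
docs/methods.md for what they emulate and what they deliberately do not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from . import io as pio
from .alphabet import AA_FREQS, AA_INDEX, AMINO_ACIDS
from .bayes import Annotations
from .compare import pwm_similarity
from .motif import Motif, PWMMatrix, site_window
from .types import (CONTROL, IntensityTable, KSREdge, Phosphosite,
                    ProteinRecord, SiteEdge)

COMPARTMENTS = ("nucleus", "cytosol", "membrane", "mitochondrion",
                "ER", "golgi", "secreted", "cytoskeleton")
_COMPARTMENT_WEIGHTS = np.array([0.28, 0.18, 0.14, 0.10, 0.10, 0.08,
                                 0.06, 0.06])


@dataclass
class FeatureEnrichment:
    """Target pair-feature rates on true versus random pairs."""

    coloc_pos: float = 0.8
    coloc_neg: float = 0.2
    ppi_pos: float = 0.7
    ppi_neg: float = 0.1
    coexpr_pos: Tuple[float, float] = (0.6, 0.2)   # (mean, sd) of Pearson r
    coexpr_neg: Tuple[float, float] = (0.0, 0.3)


@dataclass
class SimConfig:
    """Study conditions of the synthetic benchmark."""

    n_kinases: int = 6
    n_proteins: int = 300
    protein_length_range: Tuple[int, int] = (80, 160)
    substrates_per_kinase: int = 10
    sites_per_substrate: int = 3
    decoy_sites_per_protein: int = 6
    motif_sharpness: float = 0.9
    array_noise_sd: float = 1.0
    baseline: float = 10.0
    signal: float = 8.0          # absolute; 8x the default noise SD
    n_blacklist: int = 10
    n_tissues: int = 15
    annotation_missing_rate: float = 0.1
    known_fraction: float = 0.3
    width: int = 15
    feature_enrichment: FeatureEnrichment = field(
        default_factory=FeatureEnrichment)
    rng_seed: int = 0

    def __post_init__(self):
        if min(self.n_kinases, self.n_proteins, self.substrates_per_kinase,
               self.sites_per_substrate) < 1:
            raise ValueError("counts must be >= 1")
        if not (0.0 < self.motif_sharpness <= 1.0):
            raise ValueError("motif_sharpness must be in (0, 1]")
        if self.protein_length_range[0] < self.width:
            raise ValueError("proteins shorter than the window width")
        need = self.n_kinases * self.substrates_per_kinase + self.n_blacklist
        if need > self.n_proteins:
            raise ValueError("not enough proteins for substrates + blacklist")


@dataclass
class GroundTruth:
    """What the generator planted, for scoring pipeline output."""

    planted_pwms: Dict[Tuple[str, str], PWMMatrix]
    true_ksr: Set[Tuple[str, str]]
    true_sites: Set[Tuple[str, str, int]]
    blacklist: Set[str]


@dataclass
class SimData:
    """All generated inputs plus the planted truth."""

    config: SimConfig
    proteome: Dict[str, ProteinRecord]
    phosphosites: List[Phosphosite]
    tables: Dict[str, IntensityTable]
    control: IntensityTable
    annotations: Annotations
    known_ksr: List[KSREdge]
    known_sites: Set[Tuple[str, str, int]]
    ground_truth: GroundTruth
    # public metadata (kinome family knowledge), not ground truth:
    kinase_classes: Dict[str, str] = field(default_factory=dict)

    def write(self, outdir) -> None:
        """Emit exactly the formats the readers consume (plus truth tables)."""
        out = Path(outdir)
        (out / "arrays").mkdir(parents=True, exist_ok=True)
        pio.write_fasta(self.proteome, out / "proteome.fa")
        pio.write_phosphosites(self.phosphosites, out / "sites.tsv")
        for k in sorted(self.tables):
            pio.write_intensity_table(self.tables[k],
                                      out / "arrays" / f"{k}.tsv")
        pio.write_intensity_table(self.control, out / "control.tsv")
        pio.write_expression(self.annotations.expression,
                             out / "expression.tsv")
        pio.write_compartments(self.annotations.compartments,
                               out / "compartments.tsv")
        pio.write_ppi_edges(sorted(self.annotations.ppi.edges()),
                            out / "ppi.tsv")
        pio.write_ksr(self.known_ksr, out / "known_ksr.tsv")
        pio.write_known_sites(self.known_sites, out / "known_sites.tsv")
        pio.write_known_sites(self.ground_truth.true_sites,
                              out / "true_sites.tsv")
        with open(out / "true_ksr.tsv", "w") as fh:
            fh.write("kinase\tsubstrate\n")
            for k, s in sorted(self.ground_truth.true_ksr):
                fh.write(f"{k}\t{s}\n")
        with open(out / "kinases.tsv", "w") as fh:
            fh.write("kinase\tresidue_class\n")
            for k in sorted(self.kinase_classes):
                fh.write(f"{k}\t{self.kinase_classes[k]}\n")


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

def random_sequence(length: int, rng: np.random.Generator) -> str:
    idx = rng.choice(len(AMINO_ACIDS), size=length, p=AA_FREQS)
    return "".join(AMINO_ACIDS[i] for i in idx)


def planted_pwm(acceptor: str, sharpness: float, width: int,
                rng: np.random.Generator) -> PWMMatrix:
    """A planted motif: per non-center column, probability ``sharpness`` on
    a random consensus letter, the rest spread over the other letters in
    proportion to background frequencies. The center is one-hot at the
    phosphoacceptor residue."""
    values = np.zeros((len(AMINO_ACIDS) + 1, width))
    center = (width - 1) // 2
    for j in range(width):
        if j == center:
            values[AA_INDEX[acceptor], j] = 1.0
            continue
        consensus = int(rng.integers(0, len(AMINO_ACIDS)))
        rest = AA_FREQS.copy()
        rest[consensus] = 0.0
        rest /= rest.sum()
        col = (1.0 - sharpness) * rest
        col[consensus] = sharpness
        values[: len(AMINO_ACIDS), j] = col
    return PWMMatrix(values)


def random_class_windows(n: int, residue_class: str,
                         rng: np.random.Generator,
                         width: int = 15) -> List[str]:
    """Random background phosphopeptide windows: letters drawn from the
    proteome amino-acid frequencies, center fixed to the residue class
    (S/T in a 70/30 mix, or Y)."""
    center = (width - 1) // 2
    out = []
    for _ in range(n):
        chars = [AMINO_ACIDS[int(i)]
                 for i in rng.choice(len(AMINO_ACIDS), size=width,
                                     p=AA_FREQS)]
        if residue_class == "Y":
            chars[center] = "Y"
        else:
            chars[center] = "S" if rng.random() < 0.7 else "T"
        out.append("".join(chars))
    return out


def sample_windows_from_pwm(pwm: PWMMatrix, n: int,
                            rng: np.random.Generator) -> List[str]:
    """Draw n windows column-independently from a PWM."""
    letters = AMINO_ACIDS + "-"
    out = []
    for _ in range(n):
        chars = []
        for j in range(pwm.width):
            i = int(rng.choice(len(letters), p=pwm.values[:, j]))
            chars.append(letters[i])
        out.append("".join(chars))
    return out


def simulate_pair_features(
    n_pos: int, n_neg: int,
    enrichment: Optional[FeatureEnrichment] = None,
    missing_rate: float = 0.2,
    rng: Optional[np.random.Generator] = None,
    uninformative: bool = False,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Pair-feature tables drawn directly at the stated rates.

    With ``uninformative=True`` both tables are drawn from the negative
    (random-pair) distribution — the null for calibration checks.
    """
    e = enrichment or FeatureEnrichment()
    rng = rng if rng is not None else np.random.default_rng(0)

    def draw(n, coloc_rate, ppi_rate, coexpr):
        mean, sd = coexpr
        df = pd.DataFrame({
            "tissue_coexpr": np.clip(rng.normal(mean, sd, n), -1.0, 1.0),
            "coloc": (rng.random(n) < coloc_rate).astype(float),
            "ppi": (rng.random(n) < ppi_rate).astype(float),
        })
        for c in df.columns:
            df.loc[rng.random(n) < missing_rate, c] = np.nan
        return df

    if uninformative:
        pos = draw(n_pos, e.coloc_neg, e.ppi_neg, e.coexpr_neg)
    else:
        pos = draw(n_pos, e.coloc_pos, e.ppi_pos, e.coexpr_pos)
    neg = draw(n_neg, e.coloc_neg, e.ppi_neg, e.coexpr_neg)
    return pos, neg


# ---------------------------------------------------------------------------
# The generator
# ---------------------------------------------------------------------------

def simulate(config: Optional[SimConfig] = None) -> SimData:
    """Generate the full benchmark; fully determined by ``config.rng_seed``."""
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.rng_seed)
    enrich = cfg.feature_enrichment
    half = (cfg.width - 1) // 2

    kinases = [f"K{i + 1:02d}" for i in range(cfg.n_kinases)]
    # every fifth kinase models a tyrosine kinase; ST kinases get a fixed
    # acceptor letter (mostly serine)
    classes = {k: ("Y" if i % 5 == 4 else "ST")
               for i, k in enumerate(kinases)}
    acceptor = {k: ("Y" if classes[k] == "Y"
                    else ("S" if rng.random() < 0.8 else "T"))
                for k in kinases}

    protein_ids = [f"P{i + 1:04d}" for i in range(cfg.n_proteins)]
    sequences = {p: list(random_sequence(
        int(rng.integers(cfg.protein_length_range[0],
                         cfg.protein_length_range[1] + 1)), rng))
        for p in protein_ids}

    order = rng.permutation(cfg.n_proteins)
    n_sub = cfg.n_kinases * cfg.substrates_per_kinase
    substrate_ids = [protein_ids[i] for i in order[:n_sub]]
    blacklist = {protein_ids[i]
                 for i in order[n_sub:n_sub + cfg.n_blacklist]}
    substrates = {
        k: substrate_ids[i * cfg.substrates_per_kinase:
                         (i + 1) * cfg.substrates_per_kinase]
        for i, k in enumerate(kinases)
    }

    planted = {(k, classes[k]): planted_pwm(acceptor[k], cfg.motif_sharpness,
                                            cfg.width, rng)
               for k in kinases}

    # --- plant true sites -------------------------------------------------
    true_ksr: Set[Tuple[str, str]] = set()
    true_sites: Set[Tuple[str, str, int]] = set()
    site_records: List[Phosphosite] = []
    true_positions: Dict[str, Set[int]] = {p: set() for p in protein_ids}
    for k in kinases:
        pwm = planted[(k, classes[k])]
        for sub in substrates[k]:
            true_ksr.add((k, sub))
            seq = sequences[sub]
            slots = np.arange(half + 1, len(seq) - half + 1, cfg.width)
            n_sites = min(cfg.sites_per_substrate, len(slots))
            chosen = rng.choice(len(slots), size=n_sites, replace=False)
            for pos in sorted(int(slots[c]) for c in chosen):
                window = sample_windows_from_pwm(pwm, 1, rng)[0]
                seq[pos - 1 - half: pos + half] = list(window)
                true_sites.add((k, sub, pos))
                true_positions[sub].add(pos)
                site_records.append(Phosphosite(sub, pos, acceptor[k], "MS"))

    proteome = {p: ProteinRecord(p, "".join(sequences[p]))
                for p in protein_ids}

    # --- decoy sites at naturally occurring S/T/Y -------------------------
    for p in protein_ids:
        seq = proteome[p].sequence
        cand = [i + 1 for i, ch in enumerate(seq)
                if ch in "STY" and (i + 1) not in true_positions[p]]
        if not cand:
            continue
        n = min(cfg.decoy_sites_per_protein, len(cand))
        picks = rng.choice(len(cand), size=n, replace=False)
        for i in sorted(int(x) for x in picks):
            pos = cand[i]
            src = "literature" if rng.random() < 0.1 else "MS"
            site_records.append(Phosphosite(p, pos, seq[pos - 1], src))
    site_records.sort(key=lambda s: (s.protein_id, s.position))

    # --- intensity tables -------------------------------------------------
    def table(kinase: Optional[str]) -> IntensityTable:
        values = {}
        for p in protein_ids:
            mu = cfg.baseline
            if p in blacklist:
                mu += cfg.signal          # lights up on every array
            elif kinase is not None and (kinase, p) in true_ksr:
                mu += cfg.signal
            values[p] = max(0.0, mu + rng.normal(0.0, cfg.array_noise_sd)
                            if cfg.array_noise_sd > 0 else mu)
        return IntensityTable(kinase if kinase else CONTROL, values)

    tables = {k: table(k) for k in kinases}
    control = table(None)

    # --- annotations ------------------------------------------------------
    all_ids = kinases + protein_ids
    expr = pd.DataFrame(rng.normal(size=(len(all_ids), cfg.n_tissues)),
                        index=all_ids,
                        columns=[f"T{i + 1:02d}"
                                 for i in range(cfg.n_tissues)])
    for k in kinases:
        zk = expr.loc[k].to_numpy()
        for sub in substrates[k]:
            rho = float(np.clip(rng.normal(*enrich.coexpr_pos), -0.95, 0.95))
            eps = rng.normal(size=cfg.n_tissues)
            expr.loc[sub] = rho * zk + np.sqrt(1.0 - rho ** 2) * eps
    hidden = rng.random(len(all_ids)) < cfg.annotation_missing_rate
    expr.loc[hidden] = np.nan

    base_share = float((_COMPARTMENT_WEIGHTS ** 2).sum())
    p_force = max(0.0, (enrich.coloc_pos - base_share) / (1.0 - base_share))
    comp: Dict[str, set] = {}
    for pid in all_ids:
        if rng.random() < cfg.annotation_missing_rate:
            continue
        c = rng.choice(len(COMPARTMENTS), p=_COMPARTMENT_WEIGHTS)
        comp[pid] = {COMPARTMENTS[int(c)]}
    for k in kinases:
        if k not in comp:
            continue
        for sub in substrates[k]:
            if sub in comp and rng.random() < p_force:
                comp[sub] = comp[sub] | comp[k]

    g = nx.Graph()
    n_nodes = len(all_ids)
    # mean degree d so that the random shared-neighbor rate 1-exp(-d^2/n)
    # plus the direct-edge rate lands near the configured negative rate
    mean_degree = np.sqrt(-np.log(max(1.0 - enrich.ppi_neg, 1e-9))
                          * n_nodes) * 0.85
    draws = max(1, int(round(mean_degree / 2)))
    annotated = [pid for pid in all_ids
                 if rng.random() >= cfg.annotation_missing_rate]
    g.add_nodes_from(annotated)
    for pid in annotated:
        partners = rng.choice(len(annotated), size=draws, replace=False)
        for j in partners:
            other = annotated[int(j)]
            if other != pid:
                g.add_edge(pid, other)
    p_direct = max(0.0, (enrich.ppi_pos - enrich.ppi_neg)
                   / (1.0 - enrich.ppi_neg))
    for k in kinases:
        for sub in substrates[k]:
            if g.has_node(k) and g.has_node(sub) and \
                    rng.random() < p_direct:
                g.add_edge(k, sub)

    annotations = Annotations(expression=expr, compartments=comp, ppi=g)

    # --- known KSRs and site-specific triples ------------------------------
    known_ksr: List[KSREdge] = []
    known_sites: Set[Tuple[str, str, int]] = set()
    for k, sub in sorted(true_ksr):
        if rng.random() < cfg.known_fraction:
            known_ksr.append(KSREdge(k, sub, stage="known"))
            known_sites |= {t for t in true_sites if t[0] == k
                            and t[1] == sub}

    truth = GroundTruth(planted_pwms=planted, true_ksr=true_ksr,
                        true_sites=true_sites, blacklist=blacklist)
    return SimData(config=cfg, proteome=proteome, phosphosites=site_records,
                   tables=tables, control=control, annotations=annotations,
                   known_ksr=known_ksr, known_sites=known_sites,
                   ground_truth=truth, kinase_classes=dict(classes))


# ---------------------------------------------------------------------------
# Scoring a pipeline run against the planted truth
# ---------------------------------------------------------------------------

def _pr(predicted: set, truth: set) -> dict:
    tp = len(predicted & truth)
    return {
        "precision": tp / len(predicted) if predicted else None,
        "recall": tp / len(truth) if truth else None,
        "n_predicted": len(predicted),
        "n_true": len(truth),
    }


def score_pipeline_run(
    ground_truth: GroundTruth,
    raw_edges: Optional[Sequence[KSREdge]] = None,
    refined_edges: Optional[Sequence[KSREdge]] = None,
    motifs: Optional[Dict[Tuple[str, str], Motif]] = None,
    site_edges: Optional[Sequence[SiteEdge]] = None,
    site_input_pairs: Optional[Set[Tuple[str, str]]] = None,
) -> dict:
    """Precision/recall per stage against the planted truth.

    Site-assignment ``recall`` is computed over the true sites whose pair is
    present in the KSR set handed to the mapper (``site_input_pairs``) —
    the mapping stage cannot assign sites for pairs upstream stages dropped —
    while ``recall_overall`` is against all planted sites.
    """
    out: dict = {}
    if raw_edges is not None:
        out["raw"] = _pr({e.pair for e in raw_edges}, ground_truth.true_ksr)
    if refined_edges is not None:
        out["refined"] = _pr({e.pair for e in refined_edges},
                             ground_truth.true_ksr)
    if motifs is not None:
        sims = {}
        for key, motif in motifs.items():
            if key in ground_truth.planted_pwms:
                sims[key[0]] = pwm_similarity(motif.pwm,
                                              ground_truth.planted_pwms[key])
        out["motifs"] = {
            "mean_similarity": float(np.mean(list(sims.values())))
            if sims else None,
            "min_similarity": float(min(sims.values())) if sims else None,
            "n_scored": len(sims),
        }
    if site_edges is not None:
        predicted = {e.triple for e in site_edges}
        stage = _pr(predicted, ground_truth.true_sites)
        out["sites"] = stage
        stage["recall_overall"] = stage.pop("recall")
        if site_input_pairs is not None:
            reachable = {t for t in ground_truth.true_sites
                         if (t[0], t[1]) in site_input_pairs}
            tp = len(predicted & reachable)
            stage["recall"] = tp / len(reachable) if reachable else None
            stage["n_reachable"] = len(reachable)
        else:
            stage["recall"] = stage["recall_overall"]
    return out
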