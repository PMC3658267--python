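"""End-to-end orchestration: simulate -> hits -> refine -> motifs -> map.

One seed drives every stochastic stage; intermediate artifacts are plain
TSV/MEME files for inspectability when an output directory is given.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import yaml

from . import io as pio
from .bayes import combine, features_frame, refine, train
from .hits import HitCallConfig, HitCaller
from .motif import M3Config, Motif, extract_foreground_background, m3
from .network import assign_sites, class_backgrounds, flag_known, map_metrics
from .simulate import SimConfig, simulate, score_pipeline_run
from .types import KSREdge

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Stage parameters plus the single global seed they all derive from."""

    sim: SimConfig = field(default_factory=SimConfig)
    hit: HitCallConfig = field(default_factory=HitCallConfig)
    m3: M3Config = field(default_factory=M3Config)
    n_bins: int = 5
    alpha: float = 0.05
    n_negative: int = 10_000
    min_foreground: int = 3   # fewest peptides worth fitting a motif to
    refine_enabled: bool = True
    rng_seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kw = {}
        if "sim" in raw:
            kw["sim"] = SimConfig(**raw["sim"])
        if "hit" in raw:
            kw["hit"] = HitCallConfig(**raw["hit"])
        if "m3" in raw:
            kw["m3"] = M3Config(**raw["m3"])
        for k in ("n_bins", "alpha", "n_negative", "min_foreground",
                  "refine_enabled", "rng_seed"):
            if k in raw:
                kw[k] = raw[k]
        return cls(**kw)


def sample_negative_pairs(protein_ids, kinase_ids, n: int,
                          rng: np.random.Generator):
    """Random ordered pairs of distinct non-kinase proteins."""
    pool = sorted(set(protein_ids) - set(kinase_ids))
    if len(pool) < 2:
        raise ValueError("need >= 2 non-kinase proteins")
    a = rng.integers(0, len(pool), size=n)
    b = rng.integers(0, len(pool) - 1, size=n)
    b = np.where(b >= a, b + 1, b)
    return [(pool[i], pool[j]) for i, j in zip(a, b)]


def run_all(config: Optional[PipelineConfig] = None,
            outdir=None) -> dict:
    """Execute every stage in order and return the metrics dictionary."""
    cfg = config or PipelineConfig()
    seed = cfg.rng_seed
    sim_cfg = dataclasses.replace(cfg.sim, rng_seed=seed)
    m3_cfg = dataclasses.replace(cfg.m3, rng_seed=seed + 1)

    stage = "simulate"
    try:
        sim = simulate(sim_cfg)

        stage = "hits"
        caller = HitCaller(cfg.hit.sd_multiplier,
                           cfg.hit.control_sd_multiplier,
                           cfg.hit.log_transform).fit(sim.control)
        raw = caller.predict_many([sim.tables[k]
                                   for k in sorted(sim.tables)])
        logger.info("rawKSR: %d edges, blacklist %d",
                    len(raw), len(caller.blacklist_))

        stage = "refine"
        kinase_ids = sorted(sim.tables)
        if cfg.refine_enabled:
            rng = np.random.default_rng(seed + 2)
            negatives = sample_negative_pairs(sim.proteome, kinase_ids,
                                              cfg.n_negative, rng)
            model = train(
                features_frame([e.pair for e in sim.known_ksr],
                               sim.annotations),
                features_frame(negatives, sim.annotations),
                n_bins=cfg.n_bins)
            refined = refine(raw, model, sim.annotations, alpha=cfg.alpha)
        else:
            refined = list(raw)
        comksr = combine(refined, sim.known_ksr)
        logger.info("refKSR: %d edges; comKSR: %d edges",
                    len(refined) if cfg.refine_enabled else 0, len(comksr))

        stage = "m3"
        motif_edges = raw + sim.known_ksr
        foreground, background = extract_foreground_background(
            motif_edges, sim.phosphosites, sim.proteome, m3_cfg)
        subs_by_kinase: Dict[str, set] = {}
        for e in motif_edges:
            subs_by_kinase.setdefault(e.kinase_id, set()).add(e.substrate_id)
        motifs: Dict[Tuple[str, str], Motif] = {}
        skipped = 0
        for (kinase, cls), peps in sorted(foreground.items()):
            # respect known kinase specificity (kinome-family metadata):
            # an S/T kinase gets no Y motif and vice versa
            declared = sim.kinase_classes.get(kinase)
            if declared is not None and cls not in declared.split("/"):
                skipped += 1
                continue
            if len(peps) < cfg.min_foreground:
                skipped += 1
                continue
            motifs[(kinase, cls)] = m3(
                peps, background[cls], len(subs_by_kinase[kinase]),
                m3_cfg, kinase_id=kinase, residue_class=cls)
        logger.info("motifs: %d (%d kinase/class foregrounds skipped)",
                    len(motifs), skipped)

        stage = "map"
        backgrounds = class_backgrounds(sim.phosphosites, sim.proteome,
                                        width=m3_cfg.width,
                                        pseudocount=m3_cfg.pseudocount)
        site_edges, report = assign_sites(comksr, motifs, sim.phosphosites,
                                          sim.proteome,
                                          backgrounds=backgrounds)
        site_edges = flag_known(site_edges, sim.known_sites)
        metrics = map_metrics(site_edges, sim.known_sites)
        logger.info("site edges: %d (%d edges siteless, %d without motif)",
                    len(site_edges), report.siteless, report.no_motif)

        stage = "score"
        scores = score_pipeline_run(
            sim.ground_truth, raw_edges=raw,
            refined_edges=refined if cfg.refine_enabled else None,
            motifs=motifs, site_edges=site_edges,
            site_input_pairs={e.pair for e in comksr})
    except Exception as exc:  # noqa: BLE001 - name the failing stage
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") \
            from exc

    result = {
        "seed": seed,
        "counts": {
            "blacklist": len(caller.blacklist_),
            "raw_ksr": len(raw),
            "refined_ksr": len(refined) if cfg.refine_enabled else 0,
            "com_ksr": len(comksr),
            "motifs": len(motifs),
            "site_edges": len(site_edges),
        },
        "map": metrics.as_dict(),
        "truth_scores": scores,
    }

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        sim.write(out / "inputs")
        pio.write_ksr(raw, out / "rawksr.tsv")
        pio.write_ksr(refined, out / "refksr.tsv")
        pio.write_ksr(comksr, out / "comksr.tsv")
        pio.write_pwm_meme([motifs[k] for k in sorted(motifs)],
                           out / "motifs.meme")
        pio.write_network(site_edges, out / "map.sif", out / "map.tsv")
        with open(out / "metrics.json", "w") as fh:
            json.dump(result, fh, indent=2, sort_keys=True)
    return result
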