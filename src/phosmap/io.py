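"""Readers and writers for every external format the pipeline touches.

All tabular formats are tab-separated UTF-8 with ``#`` comment lines
ignored. Motifs are serialized in MEME minimal format (20-letter protein
alphabet); networks as SIF plus an edge-attribute TSV.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO

from .alphabet import AMINO_ACIDS
from .motif import Motif, PWMMatrix, consensus_string
from .types import (CONTROL, DropReport, IntensityTable, KSREdge, Phosphosite,
                    ProteinRecord, SiteEdge)

logger = logging.getLogger(__name__)

_VALID_LETTERS = set(AMINO_ACIDS)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> Dict[str, ProteinRecord]:
    """Read protein sequences; the header token before the first whitespace
    is the protein id. Non-standard letters are mapped to 'X' (warned);
    duplicate ids raise."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: Dict[str, ProteinRecord] = {}
    n_mapped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id
        if pid in records:
            raise ValueError(f"duplicate protein id {pid!r} in {path}")
        seq = str(rec.seq).upper()
        cleaned = "".join(c if c in _VALID_LETTERS else "X" for c in seq)
        if cleaned != seq:
            n_mapped += sum(a != b for a, b in zip(seq, cleaned))
        records[pid] = ProteinRecord(pid, cleaned)
    if n_mapped:
        logger.warning("mapped %d non-standard letters to 'X'", n_mapped)
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(proteome: Dict[str, ProteinRecord], path) -> None:
    with open(path, "w") as fh:
        for pid in proteome:
            rec = proteome[pid]
            fh.write(f">{rec.protein_id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i:i + 60] + "\n")


# ---------------------------------------------------------------------------
# TSV helpers
# ---------------------------------------------------------------------------

def _read_tsv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kw)


# ---------------------------------------------------------------------------
# Phosphosites
# ---------------------------------------------------------------------------

def read_phosphosites(
    path, proteome: Dict[str, ProteinRecord]
) -> Tuple[List[Phosphosite], DropReport]:
    """Read a phosphosite table and validate rows against the proteome.

    Rows on proteins absent from the proteome, or whose residue disagrees
    with the sequence at that position, are dropped and counted.
    """
    df = _read_tsv(path, dtype={"protein_id": str, "residue": str,
                                "source": str})
    required = {"protein_id", "position", "residue", "source"}
    if not required.issubset(df.columns):
        raise ValueError(f"phosphosite table needs columns {sorted(required)}")
    report = DropReport()
    sites: List[Phosphosite] = []
    for row in df.itertuples(index=False):
        try:
            pos = int(row.position)
            if pos != float(row.position):
                raise ValueError
        except (TypeError, ValueError):
            raise ValueError(f"malformed position {row.position!r}") from None
        if pos < 1:
            raise ValueError(f"position must be >= 1, got {pos}")
        if row.protein_id not in proteome:
            report.unmapped += 1
            report.unmapped_ids.append(row.protein_id)
            continue
        seq = proteome[row.protein_id].sequence
        if (row.residue not in ("S", "T", "Y") or pos > len(seq)
                or seq[pos - 1] != row.residue):
            report.mismatched += 1
            continue
        sites.append(Phosphosite(row.protein_id, pos, row.residue, row.source))
        report.retained += 1
    if report.dropped:
        logger.warning("phosphosites: dropped %d unmapped and %d mismatched "
                       "of %d rows", report.unmapped, report.mismatched,
                       report.total)
    return sites, report


def write_phosphosites(sites: Sequence[Phosphosite], path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tposition\tresidue\tsource\n")
        for s in sites:
            fh.write(f"{s.protein_id}\t{s.position}\t{s.residue}\t{s.source}\n")


# ---------------------------------------------------------------------------
# Intensity tables
# ---------------------------------------------------------------------------

def read_intensity_table(path, kinase_id: Optional[str] = None) -> IntensityTable:
    """Read a two-column (protein_id, intensity) assay table.

    The kinase id comes from a ``# kinase: X`` comment line if present,
    otherwise the file stem. Replicate rows for a protein are averaged.
    """
    path = Path(path)
    if kinase_id is None:
        kinase_id = path.stem
        with open(path) as fh:
            for line in fh:
                m = re.match(r"#\s*kinase:\s*(\S+)", line)
                if m:
                    kinase_id = m.group(1)
                if not line.startswith("#"):
                    break
    df = _read_tsv(path, dtype={"protein_id": str})
    if not {"protein_id", "intensity"}.issubset(df.columns):
        raise ValueError("intensity table needs protein_id and intensity")
    values = df.groupby("protein_id", sort=True)["intensity"].mean()
    return IntensityTable(kinase_id, values.to_dict())


def write_intensity_table(table: IntensityTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# kinase: {table.kinase_id}\n")
        fh.write("protein_id\tintensity\n")
        for pid in sorted(table.values):
            fh.write(f"{pid}\t{table.values[pid]:.6g}\n")


# ---------------------------------------------------------------------------
# KSR tables
# ---------------------------------------------------------------------------

def write_ksr(edges: Sequence[KSREdge], path) -> None:
    with open(path, "w") as fh:
        fh.write("kinase\tsubstrate\tstage\tz\tl_score\tp_value\n")
        for e in edges:
            z = "" if e.array_z is None else f"{e.array_z:.6g}"
            l = "" if e.l_score is None else f"{e.l_score:.6g}"
            p = "" if e.p_value is None else f"{e.p_value:.6g}"
            fh.write(f"{e.kinase_id}\t{e.substrate_id}\t{e.stage}\t{z}\t{l}\t{p}\n")


def read_ksr(path, default_stage: str = "known") -> List[KSREdge]:
    """Read a KSR pair list; columns beyond (kinase, substrate) optional."""
    df = _read_tsv(path, dtype={"kinase": str, "substrate": str})
    if not {"kinase", "substrate"}.issubset(df.columns):
        raise ValueError("KSR table needs kinase and substrate columns")
    edges = []
    for row in df.itertuples(index=False):
        d = row._asdict()

        def opt(name):
            v = d.get(name)
            return None if v is None or (isinstance(v, float) and np.isnan(v)) \
                else float(v)

        edges.append(KSREdge(
            kinase_id=row.kinase, substrate_id=row.substrate,
            stage=str(d.get("stage", default_stage) or default_stage),
            array_z=opt("z"), l_score=opt("l_score"), p_value=opt("p_value"),
        ))
    return edges


def read_known_sites(path) -> set:
    """Known site-specific (kinase, substrate, position) triples."""
    df = _read_tsv(path, dtype={"kinase": str, "substrate": str})
    need = {"kinase", "substrate", "position"}
    if not need.issubset(df.columns):
        raise ValueError(f"known-sites table needs columns {sorted(need)}")
    return {(r.kinase, r.substrate, int(r.position))
            for r in df.itertuples(index=False)}


def write_known_sites(triples: Iterable[tuple], path) -> None:
    with open(path, "w") as fh:
        fh.write("kinase\tsubstrate\tposition\n")
        for k, s, p in sorted(triples):
            fh.write(f"{k}\t{s}\t{p}\n")


# ---------------------------------------------------------------------------
# Annotation tables
# ---------------------------------------------------------------------------

def read_expression(path) -> pd.DataFrame:
    """Protein x tissue expression matrix; empty cells = unmeasured."""
    df = _read_tsv(path, index_col=0)
    return df.astype(float)


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="protein_id", float_format="%.6g")


def read_compartments(path) -> Dict[str, set]:
    df = _read_tsv(path, dtype=str)
    if not {"protein_id", "compartment"}.issubset(df.columns):
        raise ValueError("compartment table needs protein_id and compartment")
    out: Dict[str, set] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.protein_id, set()).add(row.compartment)
    return out


def write_compartments(comp: Dict[str, set], path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tcompartment\n")
        for pid in sorted(comp):
            for c in sorted(comp[pid]):
                fh.write(f"{pid}\t{c}\n")


def read_ppi_edges(path) -> List[Tuple[str, str]]:
    df = _read_tsv(path, dtype=str)
    if not {"protein_a", "protein_b"}.issubset(df.columns):
        raise ValueError("PPI table needs protein_a and protein_b")
    return [(r.protein_a, r.protein_b) for r in df.itertuples(index=False)]


def write_ppi_edges(edges: Iterable[Tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_a\tprotein_b\n")
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# MEME minimal motif format
# ---------------------------------------------------------------------------

def write_pwm_meme(motifs: Sequence[Motif], path) -> None:
    """Serialize motifs in MEME minimal format over the 20-letter protein
    alphabet (the pad row is dropped and columns renormalized)."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\n")
        fh.write(f"ALPHABET= {AMINO_ACIDS}\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{a} {1 / 20:.6f}" for a in AMINO_ACIDS) + "\n\n")
        for m in motifs:
            sums = m.pwm.values.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-6):
                raise ValueError(
                    f"unnormalized PWM column for {m.kinase_id}: {sums}")
            probs = m.pwm.without_pad()
            fh.write(f"MOTIF {m.kinase_id}.{m.residue_class}\n")
            fh.write(f"letter-probability matrix: alength= 20 w= {m.pwm.width} "
                     f"nsites= {max(len(m.seed_peptides), 1)} E= 0\n")
            for j in range(m.pwm.width):
                fh.write(" ".join(f"{probs[i, j]:.6f}" for i in range(20))
                         + "\n")
            fh.write("\n")


def read_pwm_meme(path) -> List[Motif]:
    """Read back a MEME minimal file written by :func:`write_pwm_meme`.

    Columns are renormalized to absorb 6-decimal rounding; the pad row is
    restored as zeros.
    """
    motifs: List[Motif] = []
    name = None
    width = nsites = None
    rows: List[List[float]] = []

    def flush():
        nonlocal name, width, nsites, rows
        if name is None:
            return
        mat = np.array(rows, dtype=float).T  # (20, W)
        if width is not None and mat.shape[1] != width:
            raise ValueError(f"motif {name}: expected w= {width}, got "
                             f"{mat.shape[1]} rows")
        sums = mat.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-4):
            raise ValueError(f"motif {name}: columns do not sum to 1")
        full = np.vstack([mat / sums, np.zeros((1, mat.shape[1]))])
        pwm = PWMMatrix(full)
        kinase, _, cls = name.rpartition(".")
        if cls not in ("ST", "Y"):
            kinase, cls = name, "ST"
        motifs.append(Motif(kinase_id=kinase or name, residue_class=cls,
                            pwm=pwm, seed_peptides=[],
                            consensus=consensus_string(pwm, cls),
                            final_cutoff=float("nan"),
                            n_foreground=nsites or 0))
        name, width, nsites, rows = None, None, None, []

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                flush()
                name = line.split()[1]
                rows = []
            elif line.startswith("letter-probability matrix"):
                m = re.search(r"w=\s*(\d+)", line)
                width = int(m.group(1)) if m else None
                m = re.search(r"nsites=\s*(\d+)", line)
                nsites = int(m.group(1)) if m else None
            elif name is not None and line and \
                    (line[0].isdigit() or line[0] == "."):
                rows.append([float(x) for x in line.split()])
    flush()
    return motifs


# ---------------------------------------------------------------------------
# Network export
# ---------------------------------------------------------------------------

def write_network(site_edges: Sequence[SiteEdge], path_sif, path_tsv) -> None:
    """SIF (pair-level, deduplicated) plus an edge-attribute TSV."""
    pairs = []
    seen = set()
    for e in site_edges:
        if (e.kinase_id, e.substrate_id) not in seen:
            seen.add((e.kinase_id, e.substrate_id))
            pairs.append((e.kinase_id, e.substrate_id))
    with open(path_sif, "w") as fh:
        for k, s in pairs:
            fh.write(f"{k} pp {s}\n")
    with open(path_tsv, "w") as fh:
        fh.write("kinase\tsubstrate\tposition\tresidue\tmatch_score\tstatus\n")
        for e in site_edges:
            fh.write(f"{e.kinase_id}\t{e.substrate_id}\t{e.position}\t"
                     f"{e.residue}\t{e.match_score:.6g}\t{e.status}\n")
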