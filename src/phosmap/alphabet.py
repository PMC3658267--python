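"""Amino-acid alphabet and background composition constants.

The motif machinery works over a 21-letter alphabet: the 20 standard amino
acids plus ``-``, the terminal-padding symbol used when a phosphosite window
runs off the end of a protein. Treating the pad as a first-class letter with
its own background frequency keeps near-terminal sites from biasing log-odds
scores.
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PAD = "-"
FULL_ALPHABET = AMINO_ACIDS + PAD

AA_INDEX = {a: i for i, a in enumerate(FULL_ALPHABET)}

# Proteome-wide amino-acid frequencies (UniProt/Swiss-Prot averages, rounded).
# Used as the i.i.d. sequence background in the synthetic generator and as a
# fallback scoring background; normalized at import time.
_AA_FREQ_TABLE = {
    "A": 0.0826, "C": 0.0138, "D": 0.0546, "E": 0.0672, "F": 0.0386,
    "G": 0.0708, "H": 0.0227, "I": 0.0593, "K": 0.0581, "L": 0.0965,
    "M": 0.0241, "N": 0.0406, "P": 0.0474, "Q": 0.0393, "R": 0.0553,
    "S": 0.0659, "T": 0.0535, "V": 0.0686, "W": 0.0110, "Y": 0.0292,
}

AA_FREQS = np.array([_AA_FREQ_TABLE[a] for a in AMINO_ACIDS], dtype=float)
AA_FREQS /= AA_FREQS.sum()

PHOSPHO_RESIDUES = frozenset("STY")


def encode_windows(windows) -> np.ndarray:
    """Encode equal-width peptide windows as an (n, W) index array."""
    windows = list(windows)
    if not windows:
        raise ValueError("no windows to encode")
    width = len(windows[0])
    out = np.empty((len(windows), width), dtype=np.intp)
    for i, w in enumerate(windows):
        if len(w) != width:
            raise ValueError(f"mixed window widths: {len(w)} vs {width}")
        for j, ch in enumerate(w):
            if ch == "X":
                # unknown residue: scored like the uninformative pad symbol
                out[i, j] = AA_INDEX[PAD]
                continue
            try:
                out[i, j] = AA_INDEX[ch]
            except KeyError:
                raise ValueError(
                    f"letter {ch!r} outside alphabet {FULL_ALPHABET!r}"
                ) from None
    return out
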