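"""Low-level sequence helpers shared across the pipeline.

Plain ``str`` sequences over the DNA alphabet (IUPAC codes allowed in
primers only).  Distances come from edlib; the pure-Python fallbacks used
by test oracles live in the test suite, not here.
"""

from __future__ import annotations

import numpy as np

import edlib

DNA = "ACGT"

# IUPAC nucleotide code -> set of bases it matches
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_mismatches(primer: str, prefix: str) -> int:
    """Number of primer positions whose IUPAC code does not match ``prefix``.

    ``prefix`` must be at least as long as ``primer``; only the first
    ``len(primer)`` bases are examined.
    """
    mm = 0
    for p, b in zip(primer, prefix):
        if b not in IUPAC.get(p, ""):
            mm += 1
    return mm


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance (global, end gaps penalized)."""
    if a == b:
        return 0
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def identity(a: str, b: str) -> float:
    """Pairwise identity: 1 - levenshtein / max(len).

    Unique (no dependence on which co-optimal alignment an aligner picks)
    and equal to matches/columns for equal-length substitution-only pairs.
    """
    n = max(len(a), len(b))
    if n == 0:
        return 1.0
    return 1.0 - edit_distance(a, b) / n


def hamming(a: str, b: str) -> int:
    """Substitution distance; falls back to edit distance on length mismatch."""
    if len(a) == len(b):
        return sum(x != y for x, y in zip(a, b))
    return edit_distance(a, b)


def infix_distance(query: str, target: str) -> int:
    """Best edit distance of ``query`` against any infix of ``target``."""
    return edlib.align(query, target, mode="HW", task="distance")["editDistance"]


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(DNA), size=length))


def mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    """Introduce exactly ``n_subs`` substitutions at distinct positions."""
    pos = rng.choice(len(seq), size=n_subs, replace=False)
    out = list(seq)
    for p in pos:
        out[p] = rng.choice([b for b in DNA if b != out[p]])
    return "".join(out)
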