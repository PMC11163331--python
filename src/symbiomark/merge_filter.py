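"""Pair merging, expected-error filtering, dereplication, singleton removal.

Merging is a best ungapped overlap alignment of the forward read against the
reverse-complemented reverse read.  Two geometries occur with 2x300 chemistry:

* normal      — insert longer than one read; the merged contig is the union
                (fwd-left, rev-right) with the overlap called by quality;
* staggered   — insert shorter than one read, so each mate reads through the
                opposite primer; the merged contig is the overlap consensus
                only, which trims the read-through overhangs.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np

from ._seq import revcomp
from .demux_io import ReadPair


@dataclass(frozen=True)
class Contig:
    sequence: str
    quality: str
    expected_errors: float
    sample_id: str = ""
    marker: str = ""


@dataclass(frozen=True)
class MergeRejection:
    reason: str


@dataclass
class UniqueSeq:
    sequence: str
    total_abundance: int
    per_sample_counts: dict
    marker: str = ""


def expected_errors(quality: str) -> float:
    """Sum over bases of the Phred error probability 10^(-Q/10)."""
    q = np.frombuffer(quality.encode(), dtype=np.uint8).astype(float) - 33.0
    return float(np.sum(10.0 ** (-q / 10.0)))


def _count_mismatch(a: np.ndarray, b: np.ndarray) -> int:
    return int(np.count_nonzero(a != b))


def _seed_candidates(fwd: str, rc: str, seed_len: int = 24) -> set[tuple[str, int]]:
    """Candidate (geometry, overlap) pairs from exact seed lookups."""
    lf, lr = len(fwd), len(rc)
    cands: set[tuple[str, int]] = set()
    for s in range(0, min(lr, 3 * seed_len), seed_len):
        seed = rc[s : s + seed_len]
        if len(seed) < seed_len:
            break
        i = fwd.find(seed)
        while i != -1:
            ov = lf - (i - s)
            if 0 < ov <= min(lf, lr):
                cands.add(("normal", ov))
            i = fwd.find(seed, i + 1)
    for s in range(0, min(lf, 3 * seed_len), seed_len):
        seed = fwd[s : s + seed_len]
        if len(seed) < seed_len:
            break
        j = rc.find(seed)
        while j != -1:
            ov = lr - (j - s)
            if 0 < ov <= min(lf, lr):
                cands.add(("staggered", ov))
            j = rc.find(seed, j + 1)
    return cands


def merge_pair(
    pair: ReadPair,
    min_overlap: int = 20,
    max_overlap_mismatch_frac: float = 0.15,
    sample_id: str = "",
    marker: str = "",
) -> Contig | MergeRejection:
    """Merge a primer-trimmed read pair into an amplicon contig.

    The overlap maximizing (matches - mismatches) over both geometries wins;
    disagreeing overlap bases resolve to the higher-quality base and the
    merged quality at each overlap position is the max of the two mates.
    """
    fwd, fq = pair.fwd
    rc, rq = revcomp(pair.rev[0]), pair.rev[1][::-1]
    lf, lr = len(fwd), len(rc)
    if min(lf, lr) < min_overlap:
        return MergeRejection("read shorter than min_overlap")

    a = np.frombuffer(fwd.encode(), dtype=np.uint8)
    b = np.frombuffer(rc.encode(), dtype=np.uint8)

    def _overlap_slices(geom: str, ov: int):
        if geom == "normal":  # fwd suffix vs rc prefix
            return a[lf - ov :], b[:ov]
        return a[:ov], b[lr - ov :]  # staggered: fwd prefix vs rc suffix

    cands = _seed_candidates(fwd, rc)
    if not cands:  # errors broke every seed: exhaustive scan
        cands = {(g, ov) for g in ("normal", "staggered") for ov in range(1, min(lf, lr) + 1)}

    best = None  # (score, geom, ov, mismatches)
    for geom, ov in cands:
        sa, sb = _overlap_slices(geom, ov)
        mm = _count_mismatch(sa, sb)
        score = (ov - mm) - mm
        if best is None or score > best[0] or (score == best[0] and ov > best[2]):
            best = (score, geom, ov, mm)

    _, geom, ov, mm = best
    if ov < min_overlap:
        return MergeRejection("short overlap")
    if mm / ov > max_overlap_mismatch_frac:
        return MergeRejection("overlap mismatch rate too high")

    if geom == "normal":
        f_off, r_off = lf - ov, 0
        left_seq, left_q = fwd[: lf - ov], fq[: lf - ov]
        right_seq, right_q = rc[ov:], rq[ov:]
    else:
        f_off, r_off = 0, lr - ov
        left_seq = left_q = right_seq = right_q = ""

    cons, consq = [], []
    for k in range(ov):
        fb, fqc = fwd[f_off + k], fq[f_off + k]
        rb, rqc = rc[r_off + k], rq[r_off + k]
        if fb == rb or fqc >= rqc:
            cons.append(fb)
        else:
            cons.append(rb)
        consq.append(max(fqc, rqc))
    seq = left_seq + "".join(cons) + right_seq
    qual = left_q + "".join(consq) + right_q
    return Contig(seq, qual, expected_errors(qual), sample_id, marker)


def quality_filter(
    contig: Contig, max_ee: float = 1.0, length_range: tuple[int, int] | None = None
) -> bool:
    """Keep a contig iff its expected errors and length pass the thresholds."""
    if max_ee <= 0:
        raise ValueError("max_ee must be positive")
    if length_range is not None:
        lo, hi = length_range
        if not (lo <= len(contig.sequence) <= hi):
            return False
    return contig.expected_errors <= max_ee


def dereplicate(contigs: list[Contig], min_abundance: int = 2) -> list[UniqueSeq]:
    """Collapse identical contigs across samples; drop singletons.

    Output is sorted by decreasing total abundance, ties broken
    lexicographically by sequence, so downstream greedy passes are
    deterministic.
    """
    counts: dict[str, Counter] = defaultdict(Counter)
    markers: dict[str, str] = {}
    for c in contigs:
        counts[c.sequence][c.sample_id] += 1
        markers.setdefault(c.sequence, c.marker)
    uniques = [
        UniqueSeq(seq, sum(per.values()), dict(per), markers[seq])
        for seq, per in counts.items()
        if sum(per.values()) >= min_abundance
    ]
    uniques.sort(key=lambda u: (-u.total_abundance, u.sequence))
    return uniques


def merge_and_filter(
    pairs: list[ReadPair],
    length_range: tuple[int, int],
    sample_id: str = "",
    marker: str = "",
    min_overlap: int = 20,
    max_overlap_mismatch_frac: float = 0.15,
    max_ee: float = 1.0,
) -> tuple[list[Contig], dict]:
    """Merge and quality-filter one sample/marker bin; returns kept contigs
    and a tally of rejection reasons."""
    kept, reasons = [], Counter()
    for p in pairs:
        res = merge_pair(p, min_overlap, max_overlap_mismatch_frac, sample_id, marker)
        if isinstance(res, MergeRejection):
            reasons[res.reason] += 1
        elif not quality_filter(res, max_ee, length_range):
            reasons["quality/length filter"] += 1
        else:
            kept.append(res)
    return kept, dict(reasons)
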