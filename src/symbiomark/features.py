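"""Denoising into zOTUs, chimera screening, 97% OTU clustering, taxonomy.

The denoiser is a greedy UNOISE-style pass: in decreasing abundance order a
unique sequence is absorbed into an established centroid when it is both
close (<= ``d_max`` substitutions) and rare relative to the centroid
(abundance ratio <= skew(d) = 1/2^(alpha*d + 1)).  A genuine minor variant —
a heteroplasmic haplotype, a divergent rRNA operon copy — rises above the
skew curve and founds its own centroid; sequencing-error clouds fall below
it and are absorbed.  Denoising runs per sample (each library carries an
independent error realization) and centroids are merged across samples by
exact sequence.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import hamming, identity
from .merge_filter import UniqueSeq
from .refdb import RANKS, RefDB


@dataclass
class Taxonomy:
    lineage: tuple[str, ...]      # domain..species; "" beyond the assigned rank
    match_identity: float
    assignment_rank: str
    best_ref_id: str = ""

    def rank(self, name: str) -> str:
        return self.lineage[RANKS.index(name)]

    def label(self) -> str:
        return ";".join(self.lineage).rstrip(";")


@dataclass
class ZOTU:
    id: str
    centroid: str
    total_abundance: int
    per_sample_counts: dict
    marker: str = ""
    taxonomy: Taxonomy | None = None
    chimera_flag: bool = False


@dataclass
class OTU:
    id: str
    representative: str           # zOTU id of the most abundant member
    members: list                 # zOTU ids
    total_abundance: int
    per_sample_counts: dict
    taxonomy: Taxonomy | None = None
    representative_seq: str = ""


@dataclass
class FeatureTable:
    """Samples x features count matrix with per-feature metadata."""

    marker: str
    level: str                    # "zOTU" | "OTU"
    counts: pd.DataFrame          # features (rows) x samples (cols), ints
    meta: pd.DataFrame            # indexed by feature id

    def relative_abundance(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=0)
        return self.counts.div(totals.where(totals > 0, 1), axis=1)

    def write_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t")


def skew(d: int, alpha: float) -> float:
    """UNOISE abundance-skew threshold for distance ``d``."""
    return 1.0 / 2.0 ** (alpha * d + 1.0)


def denoise(
    uniques: list[UniqueSeq],
    alpha: float = 3.0,
    d_max: int = 10,
    min_parent_abundance: int = 1,
) -> list[tuple[str, int]]:
    """One greedy denoising pass over a single abundance-sorted pool.

    Returns (centroid sequence, absorbed abundance) pairs in founding order.
    Raises if the input is not sorted by decreasing abundance.
    """
    abunds = [u.total_abundance for u in uniques]
    if any(a < b for a, b in zip(abunds, abunds[1:])):
        raise ValueError("denoise requires uniques sorted by decreasing abundance")
    centroids: list[str] = []
    totals: list[int] = []
    for u in uniques:
        best = None  # (d, -abundance, index)
        for i, c in enumerate(centroids):
            d = hamming(u.sequence, c)
            if d <= d_max and u.total_abundance / totals[i] <= skew(d, alpha):
                key = (d, -totals[i], i)
                if best is None or key < best:
                    best = key
        if best is not None:
            totals[best[2]] += u.total_abundance
        elif u.total_abundance >= min_parent_abundance:
            centroids.append(u.sequence)
            totals.append(u.total_abundance)
    return list(zip(centroids, totals))


def denoise_per_sample(
    uniques: list[UniqueSeq],
    alpha: float = 3.0,
    d_max: int = 10,
    min_parent_abundance: int = 1,
    marker: str = "",
) -> list[ZOTU]:
    """Denoise each sample's pool independently and merge centroids.

    zOTU ids are assigned by decreasing pooled abundance (ties by sequence),
    matching the convention that zOTU1 is the dominant variant.
    """
    per_sample: dict[str, list[UniqueSeq]] = defaultdict(list)
    for u in uniques:
        for s, n in u.per_sample_counts.items():
            if n > 0:
                per_sample[s].append(UniqueSeq(u.sequence, n, {s: n}, u.marker))
    merged: dict[str, Counter] = defaultdict(Counter)
    for s in sorted(per_sample):
        pool = sorted(per_sample[s], key=lambda u: (-u.total_abundance, u.sequence))
        for seq, n in denoise(pool, alpha, d_max, min_parent_abundance):
            merged[seq][s] += n
    ranked = sorted(merged.items(), key=lambda kv: (-sum(kv[1].values()), kv[0]))
    return [
        ZOTU(f"zOTU{i + 1}", seq, sum(per.values()), dict(per), marker)
        for i, (seq, per) in enumerate(ranked)
    ]


def recruit_reads(
    zotus: list[ZOTU],
    uniques: list[UniqueSeq],
    d_max: int = 10,
    marker: str = "",
) -> list[ZOTU]:
    """Rebuild zOTU counts by mapping every unique sequence — including
    singletons dropped before denoising — onto the final centroids.

    A sequence maps to its exact centroid when one exists, otherwise to the
    closest same-length centroid within ``d_max`` substitutions (ties to
    the more abundant centroid); anything further is left unmapped.  This
    restores the reads that sequencing error scattered into rare uniques,
    so per-sample counts reflect template abundance rather than the
    error-free fraction.  Returns fresh abundance-ranked zOTUs.
    """
    exact = {z.centroid: z.centroid for z in zotus}
    by_len: dict[int, tuple[list[str], np.ndarray]] = {}
    for L in {len(z.centroid) for z in zotus}:
        seqs = [z.centroid for z in zotus if len(z.centroid) == L]
        mat = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), L)
        by_len[L] = (seqs, mat)

    counts: dict[str, Counter] = defaultdict(Counter)
    for u in uniques:
        target = exact.get(u.sequence)
        if target is None:
            group = by_len.get(len(u.sequence))
            if group is None:
                continue
            seqs, mat = group
            q = np.frombuffer(u.sequence.encode(), dtype=np.uint8)
            mm = (mat != q).sum(axis=1)
            best = int(mm.argmin())
            if mm[best] > d_max:
                continue
            target = seqs[best]
        counts[target].update(u.per_sample_counts)

    ranked = sorted(counts.items(), key=lambda kv: (-sum(kv[1].values()), kv[0]))
    mk = marker or (zotus[0].marker if zotus else "")
    return [
        ZOTU(f"zOTU{i + 1}", seq, sum(per.values()), dict(per), mk)
        for i, (seq, per) in enumerate(ranked)
    ]


def screen_chimeras(
    zotus: list[ZOTU],
    min_parent_ratio: float = 2.0,
    score_min: float = 0.005,
    max_residual: float = 0.02,
    max_parents: int = 64,
) -> list[bool]:
    """Flag two-parent (bimera) artifacts among abundance-sorted zOTUs.

    For each query, every ordered pair of more-abundant candidates (each
    >= ``min_parent_ratio`` x the query) is fit with a single-crossover
    two-segment model.  The query is flagged iff the best model beats the
    best single parent by >= ``score_min`` mismatches per base AND explains
    the query to within ``max_residual`` mismatches per base.  Flags are
    recorded on the zOTUs and returned.
    """
    abunds = [z.total_abundance for z in zotus]
    if any(a < b for a, b in zip(abunds, abunds[1:])):
        raise ValueError("screen_chimeras requires abundance-sorted zOTUs")
    flags = [False] * len(zotus)
    for qi, q in enumerate(zotus):
        L = len(q.centroid)
        qarr = np.frombuffer(q.centroid.encode(), dtype=np.uint8)
        cand_idx = [
            j
            for j in range(qi)
            if not flags[j]
            and len(zotus[j].centroid) == L
            and zotus[j].total_abundance >= min_parent_ratio * q.total_abundance
        ][:max_parents]
        if len(cand_idx) < 2:
            continue
        # prefix mismatch cumsums query-vs-candidate
        cums, totals = [], []
        for j in cand_idx:
            mm = (np.frombuffer(zotus[j].centroid.encode(), dtype=np.uint8) != qarr)
            c = np.concatenate(([0], np.cumsum(mm)))
            cums.append(c)
            totals.append(int(c[-1]))
        best_single = min(totals)
        best_two = best_single
        interior = slice(1, L)  # crossover strictly inside the sequence
        for ai in range(len(cand_idx)):
            for bi in range(len(cand_idx)):
                if ai == bi:
                    continue
                tot = cums[ai][interior] + (totals[bi] - cums[bi][interior])
                m = int(tot.min())
                if m < best_two:
                    best_two = m
        if (
            best_two < best_single
            and (best_single - best_two) / L >= score_min
            and best_two / L <= max_residual
        ):
            flags[qi] = True
            q.chimera_flag = True
    return flags


def cluster_97(zotus: list[ZOTU], min_identity: float = 0.97) -> list[OTU]:
    """Greedy centroid clustering of non-chimeric zOTUs at 97% identity.

    In decreasing abundance order each zOTU joins the first established OTU
    whose representative is >= ``min_identity`` identical, else founds one.
    OTU ids are re-ranked by total member abundance after the pass.
    """
    keep = [z for z in zotus if not z.chimera_flag]
    otus: list[dict] = []
    for z in keep:
        placed = False
        for o in otus:
            if identity(z.centroid, o["rep_seq"]) >= min_identity:
                o["members"].append(z)
                placed = True
                break
        if not placed:
            otus.append({"rep_seq": z.centroid, "rep_id": z.id, "members": [z]})
    built = []
    for o in otus:
        per: Counter = Counter()
        for z in o["members"]:
            per.update(z.per_sample_counts)
        built.append(
            OTU(
                id="",
                representative=o["rep_id"],
                members=[z.id for z in o["members"]],
                total_abundance=sum(per.values()),
                per_sample_counts=dict(per),
                taxonomy=o["members"][0].taxonomy,
                representative_seq=o["rep_seq"],
            )
        )
    built.sort(key=lambda o: (-o.total_abundance, o.representative_seq))
    for i, o in enumerate(built):
        o.id = f"OTU{i + 1}"
    return built


DEFAULT_RANK_CUTOFFS = {"genus": 0.95, "family": 0.90, "order": 0.85}


def assign_taxonomy(
    sequence: str,
    refdb: RefDB,
    rank_cutoffs: dict | None = None,
) -> Taxonomy:
    """Best-hit classification against a reference database.

    The lineage of the top hit (ties broken toward the lexicographically
    smallest reference id) is truncated to the deepest rank whose identity
    cutoff the hit passes; below the shallowest cutoff only the domain is
    kept.
    """
    if len(refdb) == 0:
        raise ValueError("empty reference database")
    cutoffs = DEFAULT_RANK_CUTOFFS if rank_cutoffs is None else rank_cutoffs
    best_id, best_ref = None, None
    for rec in refdb:
        ident = identity(sequence, rec.seq)
        if best_id is None or ident > best_id or (ident == best_id and rec.id < best_ref.id):
            best_id, best_ref = ident, rec
    depth = 0  # keep domain only by default
    for rank, cut in sorted(cutoffs.items(), key=lambda kv: RANKS.index(kv[0])):
        if best_id >= cut:
            depth = RANKS.index(rank)
    lineage = tuple(
        best_ref.lineage[i] if i <= depth else "" for i in range(len(RANKS))
    )
    return Taxonomy(lineage, best_id, RANKS[depth], best_ref.id)


def assign_taxonomy_all(
    features, refdb: RefDB, rank_cutoffs: dict | None = None, seq_attr: str = "centroid"
) -> None:
    """Annotate a list of zOTUs/OTUs in place."""
    for f in features:
        f.taxonomy = assign_taxonomy(getattr(f, seq_attr), refdb, rank_cutoffs)


def build_tables(
    zotus: list[ZOTU], otus: list[OTU], samples: list[str], marker: str
) -> tuple[FeatureTable, FeatureTable]:
    """Emit the zOTU and OTU count tables over a fixed sample universe.

    Chimera-flagged zOTUs are excluded; OTU counts are sums over members.
    """
    def _table(feats, level, seq_attr):
        ids = [f.id for f in feats]
        mat = pd.DataFrame(0, index=ids, columns=list(samples), dtype=int)
        for f in feats:
            for s, n in f.per_sample_counts.items():
                if s in mat.columns:
                    mat.loc[f.id, s] = n
        meta = pd.DataFrame(
            {
                "sequence": [getattr(f, seq_attr) for f in feats],
                "taxonomy": [f.taxonomy.label() if f.taxonomy else "" for f in feats],
                "total_abundance": [f.total_abundance for f in feats],
            },
            index=ids,
        )
        return FeatureTable(marker, level, mat, meta)

    keep = [z for z in zotus if not z.chimera_flag]
    return _table(keep, "zOTU", "centroid"), _table(otus, "OTU", "representative_seq")
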