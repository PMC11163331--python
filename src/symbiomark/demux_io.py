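"""Sample manifests, FASTQ input, and primer-based marker binning.

Each sequencing library multiplexes three amplicons — the host COI barcode
(BF3/BR2) and two 16S rRNA regions (V1-V2 via 27F/338R, V4 via 515F/806R).
Reads are routed to marker bins by matching both primers at the 5' ends of
the mates, IUPAC-aware, with primers trimmed on assignment.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._seq import IUPAC, iupac_mismatches

CONTROL_ROLES = ("control_extraction", "control_pcr", "control_index")
ROLES = ("specimen",) + CONTROL_ROLES

MANIFEST_COLUMNS = (
    "sample_id", "role", "species_morph", "site", "year", "sex", "nested_pcr_status",
)


@dataclass(frozen=True)
class MarkerDef:
    """One target amplicon: primer pair plus the expected merged-insert length."""

    name: str
    fwd_primer: str
    rev_primer: str
    length_range: tuple[int, int]  # merged amplicon without primers, inclusive

    def __post_init__(self) -> None:
        if not self.fwd_primer or not self.rev_primer:
            raise ValueError("primers must be non-empty")
        if not self.length_range[0] < self.length_range[1]:
            raise ValueError("length_range must satisfy min < max")


# Primer sequences from the cited metabarcoding primer literature.
DEFAULT_MARKERS = (
    MarkerDef("COI", "CCHGAYATRGCHTTYCCHCG", "TCDGGRTGNCCRAARAAYCA", (380, 460)),
    MarkerDef("16S-V1V2", "AGAGTTTGATCMTGGCTCAG", "TGCTGCCTCCCGTAGGAGT", (260, 360)),
    MarkerDef("16S-V4", "GTGYCAGCMGCCGCGGTAA", "GGACTACNVGGGTWTCTAAT", (230, 280)),
)


@dataclass(frozen=True)
class ReadPair:
    id: str
    fwd: tuple[str, str]  # (sequence, quality)
    rev: tuple[str, str]

    def __post_init__(self) -> None:
        if len(self.fwd[0]) != len(self.fwd[1]) or len(self.rev[0]) != len(self.rev[1]):
            raise ValueError(f"sequence/quality length mismatch in read {self.id}")


@dataclass
class SampleLibrary:
    """One specimen or negative-control library with its per-marker read bins."""

    sample_id: str
    role: str
    metadata: dict = field(default_factory=dict)
    bins: dict = field(default_factory=dict)        # marker name -> list[ReadPair]
    unassigned: list = field(default_factory=list)  # (ReadPair, reason)

    @property
    def is_control(self) -> bool:
        return self.role in CONTROL_ROLES

    def n_reads(self) -> int:
        return sum(len(v) for v in self.bins.values()) + len(self.unassigned)


def parse_manifest(path: str | Path) -> list[SampleLibrary]:
    """Read the sample manifest TSV into per-sample library shells."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in MANIFEST_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"manifest is missing required column: {col!r}")
    if df["sample_id"].duplicated().any():
        dups = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"])
        raise ValueError(f"duplicate sample_id in manifest: {dups}")
    bad = set(df["role"]) - set(ROLES)
    if bad:
        raise ValueError(f"unknown roles in manifest: {sorted(bad)}")
    libs = []
    for row in df.itertuples(index=False):
        meta = {c: getattr(row, c) for c in df.columns if c not in ("sample_id", "role")}
        libs.append(SampleLibrary(sample_id=row.sample_id, role=row.role, metadata=meta))
    return libs


def read_fastq_pair(r1_path: str | Path, r2_path: str | Path) -> list[ReadPair]:
    """Load a paired FASTQ file set (plain or gzip) into ReadPairs."""
    def _open(p):
        p = str(p)
        return gzip.open(p, "rt") if p.endswith(".gz") else open(p)

    pairs = []
    with _open(r1_path) as f1, _open(r2_path) as f2:
        for (t1, s1, q1), (t2, s2, q2) in zip(
            FastqGeneralIterator(f1), FastqGeneralIterator(f2), strict=True
        ):
            rid = t1.split()[0]
            if rid != t2.split()[0]:
                raise ValueError(f"R1/R2 read id mismatch: {t1} vs {t2}")
            pairs.append(ReadPair(rid, (s1, q1), (s2, q2)))
    return pairs


class _PrimerMatcher:
    """IUPAC-aware prefix matcher: compiled regex fast path for 0 mismatches,
    per-base counting fallback up to ``max_mismatch``."""

    def __init__(self, primer: str, max_mismatch: int):
        self.primer = primer
        self.max_mismatch = max_mismatch
        self._re = re.compile(
            "".join("[" + IUPAC[c] + "]" if len(IUPAC[c]) > 1 else c for c in primer)
        )

    def matches(self, read_seq: str) -> bool:
        if len(read_seq) < len(self.primer):
            return False
        if self._re.match(read_seq):
            return True
        if self.max_mismatch == 0:
            return False
        return iupac_mismatches(self.primer, read_seq) <= self.max_mismatch


def bin_reads(
    pairs: list[ReadPair],
    markers: tuple[MarkerDef, ...] = DEFAULT_MARKERS,
    max_mismatch: int = 2,
    allow_swapped: bool = True,
) -> tuple[dict, list]:
    """Partition read pairs into marker bins by 5' primer matching.

    A pair is assigned to marker ``m`` iff the forward mate starts with
    ``m.fwd_primer`` and the reverse mate with ``m.rev_primer`` (or, when
    ``allow_swapped``, the mirror-image orientation, in which case mates are
    swapped on assignment).  Primers are trimmed.  Pairs matching no pair of
    primers, conflicting primer pairs, or more than one marker end up in
    ``unassigned`` with a reason code.

    Returns ``(bins, unassigned)`` where bins maps marker name to trimmed
    ReadPairs and unassigned holds ``(pair, reason)`` tuples.
    """
    fwd_m = {m.name: _PrimerMatcher(m.fwd_primer, max_mismatch) for m in markers}
    rev_m = {m.name: _PrimerMatcher(m.rev_primer, max_mismatch) for m in markers}
    bins: dict[str, list[ReadPair]] = {m.name: [] for m in markers}
    unassigned: list[tuple[ReadPair, str]] = []

    for pair in pairs:
        fseq, rseq = pair.fwd[0], pair.rev[0]
        hits = []  # (marker, swapped)
        any_fwd_hit = any_rev_hit = False
        for m in markers:
            f_on_f = fwd_m[m.name].matches(fseq)
            r_on_r = rev_m[m.name].matches(rseq)
            any_fwd_hit |= f_on_f
            any_rev_hit |= r_on_r
            if f_on_f and r_on_r:
                hits.append((m, False))
            elif allow_swapped:
                if fwd_m[m.name].matches(rseq) and rev_m[m.name].matches(fseq):
                    hits.append((m, True))
        if len(hits) == 1:
            m, swapped = hits[0]
            a, b = (pair.rev, pair.fwd) if swapped else (pair.fwd, pair.rev)
            nf, nr = len(m.fwd_primer), len(m.rev_primer)
            bins[m.name].append(
                ReadPair(pair.id, (a[0][nf:], a[1][nf:]), (b[0][nr:], b[1][nr:]))
            )
        elif len(hits) > 1:
            unassigned.append((pair, "ambiguous_marker"))
        elif any_fwd_hit and any_rev_hit:
            unassigned.append((pair, "primer_pair_conflict"))
        else:
            unassigned.append((pair, "no_primer_match"))
    return bins, unassigned


def load_run(
    run_dir: str | Path,
    manifest_name: str = "manifest.tsv",
    markers: tuple[MarkerDef, ...] = DEFAULT_MARKERS,
    max_mismatch: int = 2,
) -> list[SampleLibrary]:
    """Load a whole run directory: manifest plus one FASTQ pair per sample."""
    run_dir = Path(run_dir)
    libs = parse_manifest(run_dir / manifest_name)
    for lib in libs:
        r1 = run_dir / f"{lib.sample_id}_R1.fastq.gz"
        r2 = run_dir / f"{lib.sample_id}_R2.fastq.gz"
        if not r1.exists():
            r1, r2 = run_dir / f"{lib.sample_id}_R1.fastq", run_dir / f"{lib.sample_id}_R2.fastq"
        pairs = read_fastq_pair(r1, r2)
        lib.bins, lib.unassigned = bin_reads(pairs, markers, max_mismatch)
    return libs
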