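"""Miniature taxonomy-annotated reference databases.

Two on-disk dialects are supported, mirroring the common community formats:

* 16S, SILVA-like: one FASTA with headers ``>id taxonomy=d;p;c;o;f;g;s``.
* COI, MIDORI-like: FASTA headers ``>id species_name`` plus a sidecar TSV
  mapping record id to the ranked lineage.

In memory both collapse to the same thing: records with a 7-rank lineage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")


@dataclass(frozen=True)
class RefRecord:
    id: str
    seq: str
    lineage: tuple[str, ...]  # 7 ranks, domain..species; "" for unassigned

    def rank(self, name: str) -> str:
        return self.lineage[RANKS.index(name)]


@dataclass
class RefDB:
    records: list[RefRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for r in self.records:
            if r.id in seen:
                raise ValueError(f"duplicate reference id: {r.id}")
            seen.add(r.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    # --- SILVA-like dialect -------------------------------------------------
    def write_silva(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                fh.write(f">{r.id} taxonomy={';'.join(r.lineage)}\n{r.seq}\n")

    @classmethod
    def read_silva(cls, path: str | Path) -> "RefDB":
        records = []
        for head, seq in _iter_fasta(path):
            rid, _, rest = head.partition(" ")
            tax = rest.split("taxonomy=", 1)[1].strip() if "taxonomy=" in rest else ""
            lineage = tuple((tax.split(";") + [""] * 7)[:7])
            records.append(RefRecord(rid, seq, lineage))
        return cls(records)

    # --- MIDORI-like dialect ------------------------------------------------
    def write_midori(self, fasta_path: str | Path, lineage_path: str | Path) -> None:
        with open(fasta_path, "w") as fh:
            for r in self.records:
                fh.write(f">{r.id} {r.rank('species') or r.rank('genus')}\n{r.seq}\n")
        with open(lineage_path, "w") as fh:
            fh.write("id\t" + "\t".join(RANKS) + "\n")
            for r in self.records:
                fh.write(r.id + "\t" + "\t".join(r.lineage) + "\n")

    @classmethod
    def read_midori(cls, fasta_path: str | Path, lineage_path: str | Path) -> "RefDB":
        lineages: dict[str, tuple[str, ...]] = {}
        with open(lineage_path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            assert header[0] == "id"
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                lineages[parts[0]] = tuple((parts[1:] + [""] * 7)[:7])
        records = []
        for head, seq in _iter_fasta(fasta_path):
            rid = head.split(" ", 1)[0]
            records.append(RefRecord(rid, seq, lineages.get(rid, ("",) * 7)))
        return cls(records)


def _iter_fasta(path: str | Path):
    head, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if head is not None:
                    yield head, "".join(chunks)
                head, chunks = line[1:], []
            elif line:
                chunks.append(line)
    if head is not None:
        yield head, "".join(chunks)
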