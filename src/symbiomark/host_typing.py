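"""Host barcode selection, species verification, numt and heteroplasmy
calls, and off-target COI detections.

The COI bin of each specimen mixes the true mitochondrial barcode with
low-abundance nuclear pseudogene copies (numts), occasional parasitoid
reads, and COI of intracellular Rickettsiales (Wolbachia, Rickettsia).
The barcode is the most abundant host-genus zOTU; everything else is
classified by lineage and abundance behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ._seq import hamming
from .features import FeatureTable
from .refdb import RANKS


def _rank_of(tax_label: str, rank: str) -> str:
    parts = (tax_label.split(";") + [""] * 7)[:7]
    return parts[RANKS.index(rank)]


@dataclass
class Detection:
    sample_id: str
    category: str            # "parasitoid" | "endosymbiont_coi" | "other"
    taxon: str
    otu_id: str
    read_count: int
    tier: str                # "detected" | "trace"
    corroborated_16s: bool | None = None

    def __post_init__(self) -> None:
        if self.read_count <= 0:
            raise ValueError("Detection requires read_count > 0")


@dataclass
class HostCall:
    sample_id: str
    barcode_zotu: str | None = None
    barcode_seq: str = ""
    barcode_count: int = 0
    barcode_otu: str | None = None
    species_molecular: str = ""
    species_morph: str = ""
    id_match: bool | None = None
    heteroplasmy_variants: list = field(default_factory=list)  # (zotu, d, frac, note)
    numt_otus: list = field(default_factory=list)              # (otu, max_frac)
    offtarget: list = field(default_factory=list)

    @property
    def heteroplasmic(self) -> bool:
        return len(self.heteroplasmy_variants) > 0


def select_barcode(
    sample_counts: dict, taxonomy: dict, target_genus: str
) -> str | None:
    """Most abundant zOTU of the host genus in one sample, else None.

    Ties break toward the lower zOTU rank (zOTU ids are abundance-ranked).
    """
    def _rank_key(zid: str) -> int:
        digits = "".join(ch for ch in zid if ch.isdigit())
        return int(digits) if digits else 0

    host = [
        z for z, n in sample_counts.items()
        if n > 0 and _rank_of(taxonomy.get(z, ""), "genus") == target_genus
    ]
    if not host:
        return None
    return min(host, key=lambda z: (-sample_counts[z], _rank_key(z)))


def verify_identity(call: HostCall, species_morph: str) -> HostCall:
    """Compare molecular and morphological species; molecular wins downstream."""
    call.species_morph = species_morph
    call.id_match = bool(call.species_molecular) and call.species_molecular == species_morph
    return call


def flag_numts(
    otu_table: FeatureTable,
    barcode_otu_by_sample: dict,
    target_genus: str,
    max_frac: float = 0.10,
) -> tuple[list, list]:
    """Flag host-genus OTUs behaving like nuclear pseudogene copies.

    A non-barcode host-genus OTU is numt-like iff, in every library where it
    occurs, that library's barcode OTU also occurs and the candidate stays
    <= ``max_frac`` of the library.  A candidate that dominates a library is
    logged as an anomaly instead (the tool cannot tell a biological
    explanation from a laboratory artifact there).

    Returns ``(numt_list, anomalies)`` where numt_list holds
    ``(otu_id, max_library_fraction)``.
    """
    rel = otu_table.relative_abundance()
    barcode_otus = set(v for v in barcode_otu_by_sample.values() if v)
    numts, anomalies = [], []
    for o in otu_table.counts.index:
        if o in barcode_otus:
            continue
        if _rank_of(str(otu_table.meta.loc[o, "taxonomy"]), "genus") != target_genus:
            continue
        present = [s for s in otu_table.counts.columns if otu_table.counts.loc[o, s] > 0]
        if not present:
            continue
        co_occurs = all(
            barcode_otu_by_sample.get(s)
            and otu_table.counts.loc[barcode_otu_by_sample[s], s] > 0
            for s in present
        )
        max_obs = float(rel.loc[o, present].max())
        if co_occurs and max_obs <= max_frac:
            numts.append((o, max_obs))
        elif max_obs > max_frac:
            anomalies.append(
                (o, f"host-genus secondary OTU at {max_obs:.1%} of a library; "
                    "not a numt call")
            )
    return numts, anomalies


def call_heteroplasmy(
    sample_id: str,
    barcode_zotu: str,
    member_counts: dict,
    sequences: dict,
    min_reads: int = 100,
    min_frac: float = 0.05,
    denominator: str = "otu",
    library_total: int | None = None,
) -> list:
    """Heteroplasmy variants among the barcode OTU's zOTUs in one sample.

    ``member_counts`` maps the barcode OTU's member zOTU ids to their read
    counts in this sample.  A non-barcode member is called iff its reads
    >= ``min_reads`` and its fraction of the denominator (the barcode OTU's
    reads by default; the whole library with ``denominator='library'``)
    >= ``min_frac``.  Each call carries the substitution distance to the
    barcode; indel-bearing variants are annotated as possible artifacts.
    """
    if denominator not in ("otu", "library"):
        raise ValueError("denominator must be 'otu' or 'library'")
    total = sum(member_counts.values()) if denominator == "otu" else (library_total or 0)
    if total <= 0:
        return []
    bseq = sequences[barcode_zotu]
    variants = []
    for z, n in member_counts.items():
        if z == barcode_zotu or n <= 0:
            continue
        frac = n / total
        if n >= min_reads and frac >= min_frac:
            vseq = sequences[z]
            note = "possible_indel_artifact" if len(vseq) != len(bseq) else ""
            variants.append((z, hamming(vseq, bseq), frac, note))
    variants.sort(key=lambda v: -v[2])
    return variants


def detect_offtarget(
    sample_id: str,
    otu_counts: dict,
    otu_taxonomy: dict,
    host_genus: str,
    host_family: str,
    insect_class: str = "Insecta",
    rickettsiales_order: str = "Rickettsiales",
    min_detected_reads: int = 100,
) -> tuple[list, list]:
    """Categorize non-host COI OTUs in one sample.

    Insect lineages outside the host family are parasitoid candidates;
    Rickettsiales lineages are endosymbiont COI signals; anything else
    (plant, fungal, unassigned) is logged as other.  Returns
    ``(detections, other_log)``.
    """
    detections, other = [], []
    for o, n in otu_counts.items():
        if n <= 0:
            continue
        tax = otu_taxonomy.get(o, "")
        genus = _rank_of(tax, "genus")
        if genus == host_genus:
            continue
        tier = "detected" if n >= min_detected_reads else "trace"
        cls, order, family = (_rank_of(tax, r) for r in ("class", "order", "family"))
        if order == rickettsiales_order:
            taxon = genus or order
            detections.append(Detection(sample_id, "endosymbiont_coi", taxon, o, n, tier))
        elif cls == insect_class and family and family != host_family:
            taxon = _rank_of(tax, "species") or genus or family
            detections.append(Detection(sample_id, "parasitoid", taxon, o, n, tier))
        else:
            other.append((o, tax, n))
    return detections, other


def cross_marker_codetection(
    coi_detections: list,
    table_16s: FeatureTable,
    genera: tuple = ("Wolbachia", "Rickettsia"),
) -> tuple[pd.DataFrame, float]:
    """Per sample x genus concordance between COI and 16S detections.

    Returns a long-format table with status in
    {both, coi_only, 16s_only, neither} and the overall agreement fraction
    (cells where the two markers agree).
    """
    samples = list(table_16s.counts.columns)
    genus_rows = {
        g: [
            f for f in table_16s.counts.index
            if _rank_of(str(table_16s.meta.loc[f, "taxonomy"]), "genus") == g
        ]
        for g in genera
    }
    coi_hits = {
        (d.sample_id, d.taxon)
        for d in coi_detections
        if d.category == "endosymbiont_coi"
    }
    rows = []
    for s in samples:
        for g in genera:
            in_coi = (s, g) in coi_hits
            in_16s = bool(genus_rows[g]) and table_16s.counts.loc[genus_rows[g], s].sum() > 0
            status = (
                "both" if in_coi and in_16s
                else "coi_only" if in_coi
                else "16s_only" if in_16s
                else "neither"
            )
            rows.append((s, g, in_coi, in_16s, status))
    df = pd.DataFrame(rows, columns=["sample_id", "genus", "in_coi", "in_16s", "status"])
    agreement = float((df["in_coi"] == df["in_16s"]).mean()) if len(df) else 1.0
    for d in coi_detections:
        if d.category == "endosymbiont_coi":
            key = df[(df.sample_id == d.sample_id) & (df.genus == d.taxon)]
            if len(key):
                d.corroborated_16s = bool(key.iloc[0]["in_16s"])
    return df, agreement


def call_hosts(
    coi_zotu_table: FeatureTable,
    coi_otu_table: FeatureTable,
    zotu_to_otu: dict,
    manifest_meta: dict,
    target_genus: str,
    host_family: str,
    het_min_reads: int = 100,
    het_min_frac: float = 0.05,
    numt_max_frac: float = 0.10,
) -> tuple[dict, list, list, list]:
    """Run the full per-sample host-typing pass.

    Returns ``(host_calls, numt_list, anomalies, all_detections)``.
    ``manifest_meta`` maps specimen sample id to its metadata dict (needs
    ``species_morph``).
    """
    ztax = {z: str(coi_zotu_table.meta.loc[z, "taxonomy"]) for z in coi_zotu_table.counts.index}
    zseq = {z: str(coi_zotu_table.meta.loc[z, "sequence"]) for z in coi_zotu_table.counts.index}
    otax = {o: str(coi_otu_table.meta.loc[o, "taxonomy"]) for o in coi_otu_table.counts.index}
    otu_members: dict[str, list] = {}
    for z, o in zotu_to_otu.items():
        otu_members.setdefault(o, []).append(z)

    calls: dict[str, HostCall] = {}
    barcode_otu_by_sample: dict[str, str | None] = {}
    all_detections: list[Detection] = []
    for s in coi_zotu_table.counts.columns:
        if manifest_meta.get(s) is None:
            continue
        counts = coi_zotu_table.counts[s].to_dict()
        call = HostCall(sample_id=s)
        bz = select_barcode(counts, ztax, target_genus)
        if bz is not None:
            call.barcode_zotu = bz
            call.barcode_seq = zseq[bz]
            call.barcode_count = int(counts[bz])
            call.barcode_otu = zotu_to_otu.get(bz)
            call.species_molecular = _rank_of(ztax[bz], "species")
            members = {
                z: int(counts.get(z, 0)) for z in otu_members.get(call.barcode_otu, [bz])
            }
            call.heteroplasmy_variants = call_heteroplasmy(
                s, bz, members, zseq, het_min_reads, het_min_frac
            )
        verify_identity(call, manifest_meta[s].get("species_morph", ""))
        det, _ = detect_offtarget(
            s, coi_otu_table.counts[s].to_dict(), otax, target_genus, host_family
        )
        call.offtarget = det
        all_detections.extend(det)
        barcode_otu_by_sample[s] = call.barcode_otu
        calls[s] = call

    numts, anomalies = flag_numts(
        coi_otu_table, barcode_otu_by_sample, target_genus, numt_max_frac
    )
    numt_set = {o for o, _ in numts}
    for call in calls.values():
        call.numt_otus = [
            (o, f) for o, f in numts
            if coi_otu_table.counts.loc[o, call.sample_id] > 0
        ] if call.sample_id in coi_otu_table.counts.columns else []
        _ = numt_set
    return calls, numts, anomalies, all_detections


def host_call_frame(calls: dict) -> pd.DataFrame:
    """Flatten HostCalls into the one-row-per-sample report table."""
    rows = []
    for s, c in sorted(calls.items()):
        rows.append(
            {
                "sample_id": s,
                "barcode_zotu": c.barcode_zotu or "",
                "barcode_count": c.barcode_count,
                "barcode_otu": c.barcode_otu or "",
                "species_molecular": c.species_molecular,
                "species_morph": c.species_morph,
                "id_match": c.id_match,
                "n_heteroplasmy_variants": len(c.heteroplasmy_variants),
                "heteroplasmic": c.heteroplasmic,
                "n_numt_otus": len(c.numt_otus),
                "n_offtarget": len(c.offtarget),
            }
        )
    return pd.DataFrame(rows)
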