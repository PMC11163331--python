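"""End-to-end orchestration: run directory in, feature tables and calls out.

Order of operations per marker: primer binning -> pair merging and
expected-error filtering -> global dereplication with singleton removal ->
per-sample denoising into zOTUs -> chimera screening (16S only) -> greedy
97% OTU clustering -> best-hit taxonomy -> count tables.  Then the COI
tables drive host typing, the 16S tables are decontaminated against the
water controls and stripped of non-target lineages, and the two per-sample
depth floors decide which specimens enter comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .decontam_filter import (
    ContaminantReport,
    FilterParams,
    decontaminate,
    exclude_samples,
    remove_non_target,
    threshold_zotus,
)
from .demux_io import DEFAULT_MARKERS, load_run
from .features import (
    FeatureTable,
    assign_taxonomy_all,
    build_tables,
    cluster_97,
    denoise_per_sample,
    recruit_reads,
    screen_chimeras,
)
from .host_typing import call_hosts
from .merge_filter import dereplicate, merge_and_filter
from .refdb import RefDB

COI_RANK_CUTOFFS = {"species": 0.97, "genus": 0.95, "family": 0.90, "order": 0.85}
S16_RANK_CUTOFFS = {"genus": 0.95, "family": 0.90, "order": 0.85}


@dataclass
class PipelineResult:
    samples: list
    roles: dict
    tables: dict = field(default_factory=dict)    # marker -> {"zOTU": FT, "OTU": FT}
    zotu_to_otu: dict = field(default_factory=dict)  # marker -> {zotu id: otu id}
    cleaned: dict = field(default_factory=dict)   # 16S marker -> {"zOTU": FT, "OTU": FT}
    contaminant_reports: dict = field(default_factory=dict)
    host_calls: dict = field(default_factory=dict)
    numts: list = field(default_factory=list)
    anomalies: list = field(default_factory=list)
    detections: list = field(default_factory=list)
    retained_samples: list = field(default_factory=list)
    exclusion_log: object = None
    focal_v4: FeatureTable | None = None
    merge_stats: dict = field(default_factory=dict)


def run_pipeline(
    run_dir: str | Path,
    coi_refdb: RefDB | None = None,
    s16_refdb: RefDB | None = None,
    markers=DEFAULT_MARKERS,
    params: FilterParams | None = None,
    target_genus: str = "Macrosteles",
    host_family: str = "Cicadellidae",
    alpha: float = 3.0,
    d_max: int = 10,
    max_ee: float = 1.0,
    max_mismatch: int = 2,
) -> PipelineResult:
    """Process a demultiplexed run directory into tables, calls, and reports."""
    run_dir = Path(run_dir)
    params = params or FilterParams()
    if coi_refdb is None:
        coi_refdb = RefDB.read_midori(run_dir / "coi_refdb.fasta", run_dir / "coi_lineages.tsv")
    if s16_refdb is None:
        s16_refdb = RefDB.read_silva(run_dir / "16s_refdb.fasta")

    libs = load_run(run_dir, markers=markers, max_mismatch=max_mismatch)
    roles = {lib.sample_id: lib.role for lib in libs}
    samples = [lib.sample_id for lib in libs]
    result = PipelineResult(samples=samples, roles=roles)

    marker_defs = {m.name: m for m in markers}
    for mname, mdef in marker_defs.items():
        contigs = []
        stats = {}
        for lib in libs:
            kept, reasons = merge_and_filter(
                lib.bins.get(mname, []), mdef.length_range,
                sample_id=lib.sample_id, marker=mname, max_ee=max_ee,
            )
            contigs.extend(kept)
            stats[lib.sample_id] = {"kept": len(kept), **reasons}
        result.merge_stats[mname] = stats

        uniques_all = dereplicate(contigs, min_abundance=1)
        uniques = [u for u in uniques_all if u.total_abundance >= 2]
        zotus = denoise_per_sample(uniques, alpha=alpha, d_max=d_max, marker=mname)
        zotus = recruit_reads(zotus, uniques_all, d_max=d_max, marker=mname)
        if mname != "COI":
            screen_chimeras(zotus)
        refdb = coi_refdb if mname == "COI" else s16_refdb
        cutoffs = COI_RANK_CUTOFFS if mname == "COI" else S16_RANK_CUTOFFS
        assign_taxonomy_all([z for z in zotus if not z.chimera_flag], refdb, cutoffs)
        otus = cluster_97(zotus)
        zt, ot = build_tables(zotus, otus, samples, mname)
        result.tables[mname] = {"zOTU": zt, "OTU": ot}
        result.zotu_to_otu[mname] = {z: o.id for o in otus for z in o.members}

    # --- host typing from COI ---------------------------------------------
    manifest_meta = {
        lib.sample_id: lib.metadata for lib in libs if lib.role == "specimen"
    }
    calls, numts, anomalies, detections = call_hosts(
        result.tables["COI"]["zOTU"],
        result.tables["COI"]["OTU"],
        result.zotu_to_otu["COI"],
        manifest_meta,
        target_genus,
        host_family,
        het_min_reads=params.min_zotu_reads,
        het_min_frac=params.min_zotu_frac,
    )
    result.host_calls = calls
    result.numts, result.anomalies, result.detections = numts, anomalies, detections

    # --- 16S decontamination, propagated zOTU -> OTU ----------------------
    for mname in marker_defs:
        if mname == "COI":
            continue
        zt = result.tables[mname]["zOTU"]
        cleaned_z, report = decontaminate(zt, roles, params)
        cleaned_z = remove_non_target(cleaned_z, report)
        cleaned_o = _propagate_to_otus(
            cleaned_z, result.tables[mname]["OTU"], result.zotu_to_otu[mname]
        )
        result.cleaned[mname] = {"zOTU": cleaned_z, "OTU": cleaned_o}
        result.contaminant_reports[mname] = report

    # --- sample exclusion and zOTU thresholds ------------------------------
    if "16S-V4" in result.cleaned:
        barcode_reads = {
            s: c.barcode_count for s, c in calls.items() if c.barcode_zotu
        }
        retained, log = exclude_samples(
            barcode_reads, result.cleaned["16S-V4"]["zOTU"], params
        )
        result.retained_samples = retained
        result.exclusion_log = log
        v4z = result.cleaned["16S-V4"]["zOTU"]
        retained_cols = [s for s in v4z.counts.columns if s in retained]
        v4_retained = FeatureTable(
            v4z.marker, v4z.level, v4z.counts[retained_cols].copy(), v4z.meta.copy()
        )
        result.focal_v4 = threshold_zotus(v4_retained, params)
    return result


def _propagate_to_otus(cleaned_z: FeatureTable, otu_table: FeatureTable,
                       zotu_to_otu: dict) -> FeatureTable:
    """Rebuild OTU counts from the decontaminated member zOTUs."""
    import pandas as pd

    groups: dict[str, list] = {}
    for z in cleaned_z.counts.index:
        o = zotu_to_otu.get(z)
        if o:
            groups.setdefault(o, []).append(z)
    otus = [o for o in otu_table.counts.index if o in groups]
    counts = pd.DataFrame(
        {o: cleaned_z.counts.loc[groups[o]].sum(axis=0) for o in otus}
    ).T.astype(int)
    counts = counts.reindex(columns=cleaned_z.counts.columns, fill_value=0)
    return FeatureTable(
        otu_table.marker, otu_table.level, counts, otu_table.meta.loc[otus].copy()
    )
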