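"""Negative-control decontamination and abundance/depth filtering.

Water-only control libraries carried through extraction, first PCR, and
indexing trace reagent and cross-over contamination.  A feature whose mean
relative abundance across controls reaches that in true specimens is called
a contaminant; non-target lineages (mitochondria, chloroplast, Eukaryota,
Archaea) are dropped from 16S tables; low-evidence zOTUs fold into an
"Others" aggregate; and under-sequenced samples are excluded outright.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .features import FeatureTable

NON_TARGET_KEYWORDS = ("mitochondria", "chloroplast", "eukaryota", "archaea")


@dataclass
class FilterParams:
    min_zotu_reads: int = 100       # zOTU read floor for "focal" status
    min_zotu_frac: float = 0.05     # zOTU relative-abundance floor in >=1 library
    min_coi_barcode_reads: int = 100  # sample exclusion: barcode depth floor
    min_16s_reads: int = 1000       # sample exclusion: 16S-V4 library floor
    display_frac: float = 0.01      # OTU display threshold
    contam_ratio: float = 1.0       # control/specimen mean-abundance ratio

    def __post_init__(self) -> None:
        for name in ("min_zotu_reads", "min_zotu_frac", "min_coi_barcode_reads",
                     "min_16s_reads", "display_frac", "contam_ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ContaminantReport:
    """Per-feature decontamination decisions with their evidence."""

    rows: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows,
            columns=["feature", "decision", "mean_control_frac",
                     "mean_specimen_frac", "ratio", "note"],
        )

    def decisions(self) -> dict:
        return {r[0]: r[1] for r in self.rows}


def decontaminate(
    table: FeatureTable,
    roles: dict,
    params: FilterParams | None = None,
    skip_no_controls: bool = False,
) -> tuple[FeatureTable, ContaminantReport]:
    """Flag features over-represented in negative controls and drop them.

    A feature is a contaminant iff
    ``mean relative abundance in controls >= contam_ratio * mean in specimens``;
    features absent from every control are never flagged.  The returned table
    keeps specimen columns only.
    """
    params = params or FilterParams()
    controls = [s for s in table.counts.columns if roles.get(s, "") != "specimen"]
    specimens = [s for s in table.counts.columns if roles.get(s, "") == "specimen"]
    if not controls:
        if not skip_no_controls:
            raise ValueError(
                "no control libraries in table; pass skip_no_controls=True "
                "to bypass decontamination explicitly"
            )
        report = ContaminantReport(
            [(f, "retained", 0.0, 0.0, 0.0, "no controls") for f in table.counts.index]
        )
        return FeatureTable(table.marker, table.level,
                            table.counts[specimens].copy(), table.meta.copy()), report

    rel = table.relative_abundance()
    ctrl_mean = rel[controls].mean(axis=1)
    spec_mean = rel[specimens].mean(axis=1) if specimens else ctrl_mean * 0.0
    report = ContaminantReport()
    contaminants = []
    for f in table.counts.index:
        c, s = float(ctrl_mean[f]), float(spec_mean[f])
        ratio = c / s if s > 0 else float("inf") if c > 0 else 0.0
        if c > 0 and c >= params.contam_ratio * s:
            contaminants.append(f)
            report.rows.append((f, "contaminant", c, s, ratio, ""))
        else:
            report.rows.append((f, "retained", c, s, ratio, ""))
    keep = [f for f in table.counts.index if f not in set(contaminants)]
    cleaned = FeatureTable(
        table.marker, table.level,
        table.counts.loc[keep, specimens].copy(), table.meta.loc[keep].copy(),
    )
    return cleaned, report


def remove_non_target(
    table: FeatureTable, report: ContaminantReport | None = None
) -> FeatureTable:
    """Drop features whose lineage names a non-target group (16S tables)."""
    keep, dropped = [], []
    for f in table.counts.index:
        tax = str(table.meta.loc[f, "taxonomy"]).lower()
        if any(k in tax for k in NON_TARGET_KEYWORDS):
            dropped.append((f, table.meta.loc[f, "taxonomy"]))
        else:
            keep.append(f)
    if report is not None:
        for f, tax in dropped:
            report.rows.append((f, "non_target", 0.0, 0.0, 0.0, tax))
    return FeatureTable(table.marker, table.level,
                        table.counts.loc[keep].copy(), table.meta.loc[keep].copy())


def threshold_zotus(
    table: FeatureTable, params: FilterParams | None = None, others_label: str = "Others"
) -> FeatureTable:
    """Keep focal zOTUs; sum the rest into one "Others" feature per sample.

    Focal means total reads >= ``min_zotu_reads`` AND relative abundance
    >= ``min_zotu_frac`` in at least one library (both inclusive).
    Per-sample totals are conserved exactly.
    """
    params = params or FilterParams()
    rel = table.relative_abundance()
    totals = table.counts.sum(axis=1)
    focal = [
        f for f in table.counts.index
        if totals[f] >= params.min_zotu_reads and rel.loc[f].max() >= params.min_zotu_frac
    ]
    rest = [f for f in table.counts.index if f not in set(focal)]
    others_row = table.counts.loc[rest].sum(axis=0).to_frame(others_label).T
    counts = pd.concat([table.counts.loc[focal], others_row])
    meta_row = pd.DataFrame(
        {c: [""] for c in table.meta.columns}, index=[others_label]
    )
    meta_row["total_abundance"] = int(table.counts.loc[rest].values.sum())
    meta = pd.concat([table.meta.loc[focal], meta_row])
    return FeatureTable(table.marker, table.level, counts.astype(int), meta)


def exclude_samples(
    barcode_reads: dict,
    v4_table: FeatureTable,
    params: FilterParams | None = None,
) -> tuple[list, pd.DataFrame]:
    """Apply the two per-sample depth floors.

    ``barcode_reads`` maps sample id to the read count of its selected host
    barcode zOTU (0 / missing when no barcode was found).  A sample is
    retained iff barcode reads >= ``min_coi_barcode_reads`` and its 16S-V4
    library total >= ``min_16s_reads``.  Returns the retained sample list
    and a per-sample exclusion log.
    """
    params = params or FilterParams()
    v4_totals = v4_table.counts.sum(axis=0)
    rows, retained = [], []
    for s in v4_table.counts.columns:
        bc = int(barcode_reads.get(s, 0))
        v4 = int(v4_totals.get(s, 0))
        reasons = []
        if bc < params.min_coi_barcode_reads:
            reasons.append(f"barcode reads {bc} < {params.min_coi_barcode_reads}")
        if v4 < params.min_16s_reads:
            reasons.append(f"16S-V4 reads {v4} < {params.min_16s_reads}")
        if not reasons:
            retained.append(s)
        rows.append((s, bc, v4, "retained" if not reasons else "; ".join(reasons)))
    log = pd.DataFrame(rows, columns=["sample_id", "barcode_reads", "v4_reads", "status"])
    return retained, log


def display_filter(
    table: FeatureTable, params: FilterParams | None = None
) -> tuple[FeatureTable, float]:
    """Restrict an OTU table to OTUs >= ``display_frac`` in >= 1 library.

    Returns the view plus the mean per-library fraction of reads it covers.
    """
    params = params or FilterParams()
    rel = table.relative_abundance()
    keep = [f for f in table.counts.index if rel.loc[f].max() >= params.display_frac]
    view = FeatureTable(table.marker, table.level,
                        table.counts.loc[keep].copy(), table.meta.loc[keep].copy())
    totals = table.counts.sum(axis=0)
    pos = totals > 0
    coverage = float((view.counts.sum(axis=0)[pos] / totals[pos]).mean()) if pos.any() else 0.0
    return view, coverage
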