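"""Ground-truthed synthetic multi-marker amplicon runs.

Emulates a leafhopper host/symbiont survey sequenced as a pooled MiSeq
2x300 run: every library multiplexes a COI host barcode (BF3/BR2) and two
16S rRNA regions (27F/338R and 515F/806R).  The generator draws, per
specimen, a host species with a dominant mitochondrial haplotype,
occasional 1-2-substitution minor haplotypes (heteroplasmy), low-abundance
numt paralogs, obligate endosymbionts present in everyone, patchy
facultative symbionts (some with divergent multi-operon 16S copies at fixed
ratios), a low-titer plant pathogen, reagent contaminants shared with
water-only controls, PCR chimeras, and occasional parasitoid COI reads.
Everything emitted is recorded in a truth object so each downstream stage
can be checked read-for-read.

Count model: library sizes are negative binomial per sample and marker;
within-library composition is Dirichlet-multinomial around the configured
mean weights.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import IUPAC, mutate, random_seq, revcomp
from .demux_io import CONTROL_ROLES, DEFAULT_MARKERS, MarkerDef
from .refdb import RefDB, RefRecord

MARKER_16S = ("16S-V1V2", "16S-V4")
INSERT_LEN = {"COI": 418, "16S-V1V2": 310, "16S-V4": 253}
READ_LEN = 300


# --------------------------------------------------------------------------
# pool definitions
# --------------------------------------------------------------------------

@dataclass
class SymbiontDef:
    """A 16S source: possibly multiple divergent rRNA operon copies at fixed
    copy-number ratios, optionally also detectable in COI (Rickettsiales)."""

    name: str
    lineage: tuple                       # 7 ranks
    operon_weights: tuple = (1.0,)
    seqs: dict = field(default_factory=dict)       # marker -> [seq per operon]
    fulllength: list = field(default_factory=list)  # one per operon
    coi_seq: str = ""                    # non-empty for Rickettsiales
    dropout_markers: frozenset = frozenset()

    def __post_init__(self) -> None:
        w = np.asarray(self.operon_weights, dtype=float)
        if (w <= 0).any():
            raise ValueError("operon weights must be positive")
        self.operon_weights = tuple(w / w.sum())

    @property
    def genus(self) -> str:
        return self.lineage[5]


@dataclass
class ContaminantDef:
    """A bacterial source defined by where it lives: reagent contaminants
    have control_weight > 0; benign specimen-only bacteria have 0."""

    name: str
    lineage: tuple
    seqs: dict = field(default_factory=dict)       # marker -> seq
    control_weight: float = 0.0
    specimen_weight: float = 0.0


@dataclass
class ParasitoidDef:
    name: str
    lineage: tuple
    coi_seq: str = ""
    prevalence: float = 0.0
    mean_weight: float = 0.05


@dataclass
class SpeciesDef:
    """One host species: COI haplotypes plus its symbiont complement."""

    name: str
    lineage: tuple
    dominant_haplotype: str
    # (label, sequence, within-individual fraction of mito reads, carrier prevalence)
    minor_haplotypes: list = field(default_factory=list)
    numts: list = field(default_factory=list)      # (label, sequence, library fraction)
    obligate_symbionts: dict = field(default_factory=dict)   # name -> mean weight
    facultative_symbionts: list = field(default_factory=list)  # (name, prevalence, weight)
    mito_16s_weight: float = 0.02
    chloroplast_weight: float = 0.005

    def __post_init__(self) -> None:
        dom = 1.0 - sum(f for _, _, f, _ in self.minor_haplotypes)
        for _, _, f, _ in self.minor_haplotypes:
            if not f < dom:
                raise ValueError("minor haplotype fraction must be below dominant")
        for _, _, f in self.numts:
            if f > 0.10:
                raise ValueError("numt per-library fraction must be <= 0.10")


@dataclass
class SimConfig:
    n_specimens: int = 20
    n_controls: int = 1                 # per control role (3 roles)
    markers: tuple = DEFAULT_MARKERS
    species_pool: list = field(default_factory=list)
    species_weights: list = field(default_factory=list)
    symbiont_pool: dict = field(default_factory=dict)
    contaminant_pool: list = field(default_factory=list)
    parasitoid_pool: list = field(default_factory=list)
    error_rate: float = 0.0
    chimera_rate: float = 0.0
    reads_mean: dict = field(default_factory=lambda: {"COI": 3000, "16S-V1V2": 600, "16S-V4": 3000})
    reads_dispersion: float = 10.0      # negative binomial shape; larger = tighter
    control_reads_mean: float = 300.0
    composition_concentration: float = 200.0
    morph_mislabel_rate: float = 0.03
    nested_pcr_sensitivity: float = 0.8
    nested_pcr_false_positive: float = 0.02
    cross_talk_rate: float = 0.0        # index hopping between samples; off by default
    sites: tuple = ("Szczecinek", "Sosnicowice")
    years: tuple = (2015, 2016, 2017, 2018)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate must be in [0, 0.05]")
        if not 0.0 <= self.chimera_rate <= 0.2:
            raise ValueError("chimera_rate must be in [0, 0.2]")
        names = {m.name for m in self.markers}
        if "COI" not in names or not names & set(MARKER_16S):
            raise ValueError("need at least one COI and one 16S marker")
        if self.species_pool and not self.species_weights:
            self.species_weights = [1.0] * len(self.species_pool)


# --------------------------------------------------------------------------
# truth
# --------------------------------------------------------------------------

@dataclass
class SimulationTruth:
    """Everything the generator decided, keyed the way tests need it."""

    sources: dict = field(default_factory=dict)
    # source name -> {"seq","marker","lineage","category","base"}
    per_sample: dict = field(default_factory=dict)
    # sample -> marker -> {source name: count}
    chimeras: dict = field(default_factory=dict)
    # sample -> marker -> [(read_id, parentA, parentB, breakpoint, degenerate)]
    specimens: dict = field(default_factory=dict)
    # sample -> {"species","species_morph","site","year","sex","infections",
    #            "heteroplasmy_carrier","parasitoid","nested_pcr_status"}
    emitted: dict = field(default_factory=dict)
    # sample -> marker -> emitted read count

    def source_set(self, marker: str, min_total: int = 1) -> set:
        totals: dict[str, int] = {}
        for per_marker in self.per_sample.values():
            for name, n in per_marker.get(marker, {}).items():
                totals[name] = totals.get(name, 0) + n
        return {
            self.sources[name]["seq"]
            for name, n in totals.items()
            if n >= min_total
        }

    def composition_table(self, marker: str) -> pd.DataFrame:
        """Truth counts, sources (rows, keyed by sequence) x samples."""
        data: dict[str, dict[str, int]] = {}
        for sample, per_marker in self.per_sample.items():
            for name, n in per_marker.get(marker, {}).items():
                seq = self.sources[name]["seq"]
                data.setdefault(seq, {})[sample] = data.setdefault(seq, {}).get(sample, 0) + n
        df = pd.DataFrame(data).T.fillna(0).astype(int)
        return df.reindex(columns=sorted(self.per_sample), fill_value=0)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, default=_jsonable)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(**raw)


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (set, frozenset, tuple)):
        return list(o)
    raise TypeError(f"not JSON-serializable: {type(o)}")


# --------------------------------------------------------------------------
# default study-like pools
# --------------------------------------------------------------------------

_HOST_LINEAGE = ("Eukaryota", "Arthropoda", "Insecta", "Hemiptera", "Cicadellidae", "Macrosteles")


def _bacterial_lineage(genus: str, order: str = "Enterobacterales",
                       cls: str = "Gammaproteobacteria",
                       phylum: str = "Proteobacteria") -> tuple:
    return ("Bacteria", phylum, cls, order, f"{order}aceae", genus, "")


def _make_symbiont(rng, name, lineage, markers, n_operons=1, weights=None,
                   operon_divergence=12, coi=False, dropout=()):
    seqs = {m: [] for m in markers}
    fulllength = []
    base = {m: random_seq(rng, INSERT_LEN[m]) for m in markers}
    for op in range(n_operons):
        for m in markers:
            seqs[m].append(base[m] if op == 0 else mutate(rng, base[m], operon_divergence))
        fulllength.append(
            random_seq(rng, 50) + seqs["16S-V1V2"][op] + random_seq(rng, 150)
            + seqs["16S-V4"][op] + random_seq(rng, 50)
        )
    return SymbiontDef(
        name=name,
        lineage=lineage,
        operon_weights=tuple(weights or [1.0] * n_operons),
        seqs=seqs,
        fulllength=fulllength,
        coi_seq=random_seq(rng, INSERT_LEN["COI"]) if coi else "",
        dropout_markers=frozenset(dropout),
    )


def default_config(
    n_specimens: int = 20,
    n_controls: int = 1,
    seed: int = 0,
    error_rate: float = 0.001,
    chimera_rate: float = 0.01,
    heteroplasmy_prevalence: float = 0.159,
    heteroplasmy_fraction: float = 0.10,
    arsenophonus_prevalence: float = 0.822,
    phytoplasma_prevalence: float = 0.38,
    n_species: int = 3,
    nasuia_v1v2_dropout: bool = True,
    **overrides,
) -> SimConfig:
    """A study-like configuration with concrete sequences.

    Defaults mirror the surveyed system: obligate Sulcia (~45% of the
    community) and Nasuia (~27%, absent from V1-V2 through a 27F primer
    mismatch), Arsenophonus with four 16S operon copies at 0.4/0.3/0.2/0.1
    prevalent in 82.2% of the main species, Phytoplasma as a low-titer
    two-operon (50/50) pathogen, rare Wolbachia/Rickettsia also visible in
    COI, heteroplasmy in 15.9% of individuals as a 1-substitution minor
    haplotype at 10% of the mitochondrial pool, and ~1%-of-library numts.
    """
    rng = np.random.default_rng(seed)
    markers16 = list(MARKER_16S)

    symbionts = {}
    symbionts["Sulcia"] = _make_symbiont(
        rng, "Sulcia", ("Bacteria", "Bacteroidota", "Flavobacteriia",
                        "Flavobacteriales", "Blattabacteriaceae", "Sulcia", ""),
        markers16)
    symbionts["Nasuia"] = _make_symbiont(
        rng, "Nasuia", _bacterial_lineage("Nasuia", "Nasuia-order", "Betaproteobacteria"),
        markers16, dropout=("16S-V1V2",) if nasuia_v1v2_dropout else ())
    symbionts["Arsenophonus"] = _make_symbiont(
        rng, "Arsenophonus", _bacterial_lineage("Arsenophonus"),
        markers16, n_operons=4, weights=[0.4, 0.3, 0.2, 0.1])
    symbionts["Phytoplasma"] = _make_symbiont(
        rng, "Phytoplasma", ("Bacteria", "Tenericutes", "Mollicutes",
                             "Acholeplasmatales", "Acholeplasmataceae", "Phytoplasma", ""),
        markers16, n_operons=2, weights=[0.5, 0.5])
    symbionts["Wolbachia"] = _make_symbiont(
        rng, "Wolbachia", ("Bacteria", "Proteobacteria", "Alphaproteobacteria",
                           "Rickettsiales", "Anaplasmataceae", "Wolbachia", ""),
        markers16, coi=True)
    symbionts["Rickettsia"] = _make_symbiont(
        rng, "Rickettsia", ("Bacteria", "Proteobacteria", "Alphaproteobacteria",
                            "Rickettsiales", "Rickettsiaceae", "Rickettsia", ""),
        markers16, coi=True)
    symbionts["Cardinium"] = _make_symbiont(
        rng, "Cardinium", ("Bacteria", "Bacteroidota", "Cytophagia",
                           "Cytophagales", "Amoebophilaceae", "Cardinium", ""),
        markers16)

    contaminants = [
        ContaminantDef(
            "Ralstonia-reagent",
            _bacterial_lineage("Ralstonia", "Burkholderiales", "Betaproteobacteria"),
            {m: random_seq(rng, INSERT_LEN[m]) for m in markers16},
            control_weight=0.5, specimen_weight=0.002),
        ContaminantDef(
            "Pseudomonas-reagent",
            _bacterial_lineage("Pseudomonas", "Pseudomonadales"),
            {m: random_seq(rng, INSERT_LEN[m]) for m in markers16},
            control_weight=0.3, specimen_weight=0.001),
        ContaminantDef(
            "Methylobacterium-reagent",
            _bacterial_lineage("Methylobacterium", "Rhizobiales", "Alphaproteobacteria"),
            {m: random_seq(rng, INSERT_LEN[m]) for m in markers16},
            control_weight=0.2, specimen_weight=0.0005),
        ContaminantDef(
            "Pantoea",
            _bacterial_lineage("Pantoea"),
            {m: random_seq(rng, INSERT_LEN[m]) for m in markers16},
            control_weight=0.0, specimen_weight=0.004),
        ContaminantDef(
            "Other-bacteria",
            ("Bacteria", "", "", "", "", "", ""),
            {m: random_seq(rng, INSERT_LEN[m]) for m in markers16},
            control_weight=0.0, specimen_weight=0.01),
    ]

    parasitoids = [
        ParasitoidDef(
            "Eudorylas fuscipes",
            ("Eukaryota", "Arthropoda", "Insecta", "Diptera", "Pipunculidae",
             "Eudorylas", "Eudorylas fuscipes"),
            coi_seq=random_seq(rng, INSERT_LEN["COI"]),
            prevalence=0.04, mean_weight=0.05),
    ]

    species_names = ["Macrosteles laevis", "Macrosteles cristatus",
                     "Macrosteles sexnotatus", "Macrosteles maculosus",
                     "Macrosteles viridigreseus", "Macrosteles quadrilineatus",
                     "Macrosteles frontalis"][:max(1, n_species)]
    base_hap = random_seq(rng, INSERT_LEN["COI"])
    species = []
    for i, name in enumerate(species_names):
        dom = base_hap if i == 0 else mutate(rng, base_hap, 33 + 5 * i)
        is_main = i == 0
        minor = []
        if is_main and heteroplasmy_prevalence > 0:
            minor = [("minor1", mutate(rng, dom, 1), heteroplasmy_fraction,
                      heteroplasmy_prevalence)]
        facs = [
            ("Arsenophonus", arsenophonus_prevalence if is_main else 0.4, 0.20),
            ("Wolbachia", 0.02, 0.03),
            ("Rickettsia", 0.01, 0.02),
            ("Phytoplasma", phytoplasma_prevalence if is_main else 0.05, 0.003),
        ]
        if not is_main:
            facs.append(("Cardinium", 0.8, 0.05))
        species.append(
            SpeciesDef(
                name=name,
                lineage=_HOST_LINEAGE + (name,),
                dominant_haplotype=dom,
                minor_haplotypes=minor,
                numts=[("numt1", mutate(rng, dom, 15), 0.01)],
                obligate_symbionts={"Sulcia": 0.453, "Nasuia": 0.266},
                facultative_symbionts=facs,
            )
        )
    weights = [0.8] + [0.2 / (len(species) - 1)] * (len(species) - 1) if len(species) > 1 else [1.0]

    cfg = SimConfig(
        n_specimens=n_specimens,
        n_controls=n_controls,
        species_pool=species,
        species_weights=weights,
        symbiont_pool=symbionts,
        contaminant_pool=contaminants,
        parasitoid_pool=parasitoids,
        error_rate=error_rate,
        chimera_rate=chimera_rate,
        seed=seed,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


# --------------------------------------------------------------------------
# reference databases
# --------------------------------------------------------------------------

def build_reference_db(config: SimConfig) -> tuple[RefDB, RefDB]:
    """Miniature COI (MIDORI-style) and 16S (SILVA-style) reference sets.

    Every simulated source lineage is represented, plus decoy records for
    the non-target categories (mitochondria, chloroplast, Eukaryota,
    Archaea) so the removal filter is exercised.
    """
    if not config.species_pool or not config.symbiont_pool:
        raise ValueError("species_pool and symbiont_pool must be non-empty")
    names = [s.name for s in config.species_pool]
    if len(set(names)) != len(names):
        raise ValueError("duplicate taxon labels in species_pool")

    rng = np.random.default_rng(config.seed + 917)
    coi_records = [
        RefRecord(f"COI_{s.name.replace(' ', '_')}", s.dominant_haplotype, s.lineage)
        for s in config.species_pool
    ]
    for p in config.parasitoid_pool:
        coi_records.append(
            RefRecord(f"COI_{p.name.replace(' ', '_')}", p.coi_seq, p.lineage))
    for sym in config.symbiont_pool.values():
        if sym.coi_seq:
            coi_records.append(
                RefRecord(f"COI_{sym.name}", sym.coi_seq, sym.lineage))
    coi_records.append(
        RefRecord("COI_plant_decoy", random_seq(rng, INSERT_LEN["COI"]),
                  ("Eukaryota", "Streptophyta", "Magnoliopsida", "Poales",
                   "Poaceae", "Poa", "Poa annua")))

    markers16 = [m.name for m in config.markers if m.name in MARKER_16S]
    s16_records = []
    for sym in config.symbiont_pool.values():
        for op in range(len(sym.operon_weights)):
            for m in markers16:
                s16_records.append(
                    RefRecord(f"{sym.name}_op{op + 1}_{m}", sym.seqs[m][op], sym.lineage))
    for c in config.contaminant_pool:
        for m in markers16:
            if m in c.seqs:
                s16_records.append(RefRecord(f"{c.name}_{m}", c.seqs[m], c.lineage))
    for m in markers16:
        s16_records.append(
            RefRecord(f"host_mitochondria_{m}", _host_decoy_seq(config, "mito", m),
                      ("Bacteria", "Proteobacteria", "Alphaproteobacteria",
                       "Rickettsiales", "Mitochondria", "Mitochondria", "")))
        s16_records.append(
            RefRecord(f"chloroplast_decoy_{m}", _host_decoy_seq(config, "chloro", m),
                      ("Bacteria", "Cyanobacteria", "Cyanobacteriia",
                       "Chloroplast", "Chloroplast", "Chloroplast", "")))
        s16_records.append(
            RefRecord(f"eukaryota_decoy_{m}", random_seq(rng, INSERT_LEN[m]),
                      ("Eukaryota", "Ascomycota", "Saccharomycetes", "", "", "", "")))
        s16_records.append(
            RefRecord(f"archaea_decoy_{m}", random_seq(rng, INSERT_LEN[m]),
                      ("Archaea", "Euryarchaeota", "", "", "", "", "")))
    return RefDB(coi_records), RefDB(s16_records)


def _host_decoy_seq(config: SimConfig, kind: str, marker: str) -> str:
    """Host organelle 16S amplicons, deterministic per config seed."""
    rng = np.random.default_rng(config.seed + (101 if kind == "mito" else 202))
    return random_seq(rng, INSERT_LEN[marker])


def fulllength_refdb(config: SimConfig) -> RefDB:
    """Full-length-style 16S references (one per symbiont operon plus the
    bacterial contaminants), used for cross-region genus mapping."""
    records = []
    for sym in config.symbiont_pool.values():
        for op, fl in enumerate(sym.fulllength):
            records.append(RefRecord(f"FL_{sym.name}_op{op + 1}", fl, sym.lineage))
    for c in config.contaminant_pool:
        fl = (c.seqs.get("16S-V1V2", "") + "N" * 0 + c.seqs.get("16S-V4", ""))
        if fl:
            records.append(RefRecord(f"FL_{c.name}", fl, c.lineage))
    return RefDB(records)


# --------------------------------------------------------------------------
# chimeras and the error model
# --------------------------------------------------------------------------

def form_chimera(parent_a: str, parent_b: str, breakpoint: int) -> str:
    """Single-crossover bimera: prefix of A up to ``breakpoint`` + suffix of B."""
    if not (0 < breakpoint < len(parent_a)) or not (0 < breakpoint < len(parent_b)):
        raise ValueError("breakpoint must be interior to both parents")
    return parent_a[:breakpoint] + parent_b[breakpoint:]


def apply_error_model(read: str, error_rate: float, rng: np.random.Generator) -> tuple[str, str]:
    """Independent per-base substitutions plus a flat, consistent quality.

    The per-read Phred value is drawn around -10*log10(error_rate)
    (capped at Q40), so expected-error filtering sees qualities that match
    the realized substitution process.
    """
    if not 0.0 <= error_rate <= 0.05:
        raise ValueError("error_rate must be in [0, 0.05]")
    q_mean = 40.0 if error_rate <= 0 else min(40.0, -10.0 * np.log10(error_rate))
    q = int(np.clip(np.rint(rng.normal(q_mean, 1.0)), 2, 40))
    qual = chr(q + 33) * len(read)
    if error_rate <= 0:
        return read, qual
    mask = rng.random(len(read)) < error_rate
    if not mask.any():
        return read, qual
    out = list(read)
    for p in np.where(mask)[0]:
        out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
    return "".join(out), qual


# --------------------------------------------------------------------------
# the run generator
# --------------------------------------------------------------------------

def _concrete_primer(primer: str) -> str:
    """Fix each degenerate primer position to one concrete base."""
    return "".join(sorted(IUPAC[c])[0] for c in primer)


def _negbin(rng, mean: float, shape: float) -> int:
    return int(rng.negative_binomial(shape, shape / (shape + mean)))


def _register(sources: dict, name: str, seq: str, marker: str, lineage, category: str):
    if name not in sources:
        sources[name] = {
            "seq": seq, "marker": marker, "lineage": list(lineage), "category": category,
        }
    return name


def _sym_group(config, sym: SymbiontDef, marker: str, sources: dict, category: str):
    """One biological unit: operon copies split at fixed within-genome ratios."""
    members = []
    for op, opw in enumerate(sym.operon_weights):
        name = _register(sources, f"sym:{sym.name}|op{op + 1}|{marker}",
                         sym.seqs[marker][op], marker, sym.lineage, category)
        members.append((name, float(opw)))
    return members


def _specimen_groups(config, sp: SpeciesDef, infections: dict, het: dict,
                     parasitized: str | None, marker: str, sources: dict) -> dict:
    """Composition groups for one specimen/marker.

    Returns group name -> (mean weight, [(source, within-group frac)]).
    The Dirichlet noise acts between groups; within a multi-operon group
    the split is multinomial at the fixed copy-number ratios.
    """
    g: dict[str, tuple[float, list]] = {}
    tag = sp.name.replace(" ", "_")
    if marker == "COI":
        minor_total = sum(f for lbl, _, f, _ in sp.minor_haplotypes if het.get(lbl))
        name = _register(sources, f"sp:{tag}|dominant|COI", sp.dominant_haplotype,
                         marker, sp.lineage, "haplotype")
        g[name] = (1.0 - minor_total, [(name, 1.0)])
        for lbl, seq, f, _ in sp.minor_haplotypes:
            if het.get(lbl):
                name = _register(sources, f"sp:{tag}|{lbl}|COI", seq, marker,
                                 sp.lineage, "minor_haplotype")
                g[name] = (f, [(name, 1.0)])
        for lbl, seq, f in sp.numts:
            name = _register(sources, f"sp:{tag}|{lbl}|COI", seq, marker,
                             sp.lineage, "numt")
            g[name] = (f, [(name, 1.0)])
        if parasitized:
            p = next(p for p in config.parasitoid_pool if p.name == parasitized)
            name = _register(sources, f"par:{p.name.replace(' ', '_')}|COI", p.coi_seq,
                             marker, p.lineage, "parasitoid")
            g[name] = (p.mean_weight, [(name, 1.0)])
        for sym_name, infected in infections.items():
            sym = config.symbiont_pool[sym_name]
            if infected and sym.coi_seq:
                name = _register(sources, f"sym:{sym.name}|COI", sym.coi_seq, marker,
                                 sym.lineage, "symbiont_coi")
                g[name] = (0.02, [(name, 1.0)])
        return g

    # 16S markers
    for sym_name, mean in sp.obligate_symbionts.items():
        sym = config.symbiont_pool[sym_name]
        if marker in sym.dropout_markers:
            continue
        g[f"sym:{sym.name}|{marker}"] = (
            mean, _sym_group(config, sym, marker, sources, "symbiont"))
    for sym_name, _, mean in sp.facultative_symbionts:
        if not infections.get(sym_name):
            continue
        sym = config.symbiont_pool[sym_name]
        if marker in sym.dropout_markers:
            continue
        g[f"sym:{sym.name}|{marker}"] = (
            mean, _sym_group(config, sym, marker, sources, "symbiont"))
    for c in config.contaminant_pool:
        if c.specimen_weight > 0 and marker in c.seqs:
            name = _register(sources, f"cont:{c.name}|{marker}", c.seqs[marker],
                             marker, c.lineage, "other" if c.control_weight == 0 else "contaminant")
            g[name] = (c.specimen_weight, [(name, 1.0)])
    name = _register(sources, f"host:mito|{marker}", _host_decoy_seq(config, "mito", marker),
                     marker, ("Bacteria", "Proteobacteria", "Alphaproteobacteria",
                              "Rickettsiales", "Mitochondria", "Mitochondria", ""), "mito")
    g[name] = (sp.mito_16s_weight, [(name, 1.0)])
    name = _register(sources, f"host:chloroplast|{marker}",
                     _host_decoy_seq(config, "chloro", marker), marker,
                     ("Bacteria", "Cyanobacteria", "Cyanobacteriia", "Chloroplast",
                      "Chloroplast", "Chloroplast", ""), "chloroplast")
    g[name] = (sp.chloroplast_weight, [(name, 1.0)])
    return g


def _control_groups(config, marker: str, sources: dict) -> dict:
    g = {}
    for c in config.contaminant_pool:
        if c.control_weight > 0 and marker in c.seqs:
            name = _register(sources, f"cont:{c.name}|{marker}", c.seqs[marker],
                             marker, c.lineage, "contaminant")
            g[name] = (c.control_weight, [(name, 1.0)])
    return g


def simulate_run(
    config: SimConfig,
    out_dir: str | Path | None = None,
    write_fastq: bool = True,
) -> SimulationTruth:
    """Generate one complete synthetic run.

    With ``out_dir`` set, writes ``<sample>_R1.fastq.gz`` / ``_R2.fastq.gz``
    per sample, ``manifest.tsv``, ``truth.json``, and the reference
    databases; always returns the in-memory truth.  Deterministic for a
    fixed config (byte-identical outputs).
    """
    rng = np.random.default_rng(config.seed)
    truth = SimulationTruth()
    marker_by_name = {m.name: m for m in config.markers}

    # --- assign specimens -------------------------------------------------
    sample_plan = []  # (sample_id, role)
    n_spec = config.n_specimens
    sp_idx = rng.choice(len(config.species_pool), size=n_spec,
                        p=np.asarray(config.species_weights) / np.sum(config.species_weights))
    site_year = [(s, y) for s in config.sites for y in config.years]
    all_species = [s.name for s in config.species_pool]
    for i in range(n_spec):
        sid = f"SPEC{i + 1:04d}"
        sp = config.species_pool[int(sp_idx[i])]
        site, year = site_year[i % len(site_year)]
        infections = {}
        for sym_name, prev, _ in sp.facultative_symbionts:
            infections[sym_name] = bool(rng.random() < prev)
        for sym_name in sp.obligate_symbionts:
            infections[sym_name] = True
        het = {lbl: bool(rng.random() < prev) for lbl, _, _, prev in sp.minor_haplotypes}
        parasitized = None
        for p in config.parasitoid_pool:
            if rng.random() < p.prevalence:
                parasitized = p.name
                break
        morph = sp.name
        if len(all_species) > 1 and rng.random() < config.morph_mislabel_rate:
            morph = str(rng.choice([s for s in all_species if s != sp.name]))
        phyto = infections.get("Phytoplasma", False)
        if phyto:
            pcr = "positive" if rng.random() < config.nested_pcr_sensitivity else "negative"
        else:
            pcr = "positive" if rng.random() < config.nested_pcr_false_positive else "negative"
        truth.specimens[sid] = {
            "species": sp.name, "species_morph": morph, "site": site, "year": int(year),
            "sex": str(rng.choice(["F", "M"])), "infections": infections,
            "heteroplasmy_carrier": het, "parasitoid": parasitized,
            "nested_pcr_status": pcr,
        }
        sample_plan.append((sid, "specimen"))
    for role in CONTROL_ROLES:
        for j in range(config.n_controls):
            sample_plan.append((f"CTRL_{role.split('_')[1]}{j + 1}", role))

    # --- draw compositions and reads --------------------------------------
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    manifest_rows = []

    for sid, role in sample_plan:
        truth.per_sample[sid] = {}
        truth.chimeras[sid] = {}
        truth.emitted[sid] = {}
        if role == "specimen":
            info = truth.specimens[sid]
            sp = next(s for s in config.species_pool if s.name == info["species"])
            manifest_rows.append((sid, role, info["species_morph"], info["site"],
                                  info["year"], info["sex"], info["nested_pcr_status"]))
        else:
            manifest_rows.append((sid, role, "", "", "", "", ""))

        reads_out: list[tuple[str, str, str]] = []  # (read_id, r1..., r2...) built below
        emit: list[tuple[str, str]] = []            # (source name or CHIM tag, amplicon seq)
        for mname, marker in marker_by_name.items():
            if role == "specimen":
                info = truth.specimens[sid]
                groups = _specimen_groups(config, sp, info["infections"],
                                          info["heteroplasmy_carrier"], info["parasitoid"],
                                          mname, truth.sources)
                depth = _negbin(rng, config.reads_mean.get(mname, 1000), config.reads_dispersion)
            else:
                groups = _control_groups(config, mname, truth.sources)
                depth = _negbin(rng, config.control_reads_mean, config.reads_dispersion)
            if not groups or depth == 0:
                truth.per_sample[sid][mname] = {}
                truth.chimeras[sid][mname] = []
                truth.emitted[sid][mname] = 0
                continue
            gnames = sorted(groups)
            mean_w = np.array([groups[n][0] for n in gnames], dtype=float)
            mean_w /= mean_w.sum()
            p = rng.dirichlet(config.composition_concentration * mean_w)
            n_chim = int(rng.binomial(depth, config.chimera_rate))
            gcounts = rng.multinomial(depth - n_chim, p)
            src_counts: dict[str, int] = {}
            for gname, gc in zip(gnames, gcounts):
                members = groups[gname][1]
                if gc == 0:
                    continue
                if len(members) == 1:
                    src_counts[members[0][0]] = src_counts.get(members[0][0], 0) + int(gc)
                else:
                    fr = np.array([f for _, f in members], dtype=float)
                    sub = rng.multinomial(gc, fr / fr.sum())
                    for (srcname, _), c in zip(members, sub):
                        if c > 0:
                            src_counts[srcname] = src_counts.get(srcname, 0) + int(c)
            truth.per_sample[sid][mname] = src_counts
            # chimeras between realized sources
            chim_records = []
            realized = sorted(src_counts)
            if n_chim > 0 and realized:
                probs = np.array([truth.per_sample[sid][mname][n] for n in realized], float)
                probs /= probs.sum()
                for k in range(n_chim):
                    pa, pb = rng.choice(realized, size=2, p=probs)
                    bp = int(rng.integers(1, INSERT_LEN[mname]))
                    seq = form_chimera(truth.sources[pa]["seq"], truth.sources[pb]["seq"], bp)
                    rid = f"{sid}.chim.{mname}.{k}"
                    chim_records.append((rid, pa, pb, bp, bool(pa == pb)))
                    emit.append((rid, _with_primers(marker, seq)))
            truth.chimeras[sid][mname] = chim_records
            truth.emitted[sid][mname] = int(depth)
            for n in truth.per_sample[sid][mname]:
                amp = _with_primers(marker, truth.sources[n]["seq"])
                for _ in range(truth.per_sample[sid][mname][n]):
                    emit.append((n, amp))

        if out_dir is not None and write_fastq:
            order = rng.permutation(len(emit))
            lines1, lines2 = [], []
            for serial, idx in enumerate(order):
                tag, amp = emit[idx]
                rid = tag if tag.startswith(f"{sid}.chim.") else f"{sid}.{serial}"
                r1 = amp[:READ_LEN]
                r2 = revcomp(amp)[:READ_LEN]
                s1, q1 = apply_error_model(r1, config.error_rate, rng)
                s2, q2 = apply_error_model(r2, config.error_rate, rng)
                lines1.append(f"@{rid}\n{s1}\n+\n{q1}\n")
                lines2.append(f"@{rid}\n{s2}\n+\n{q2}\n")
            _write_gz_text(out_dir / f"{sid}_R1.fastq.gz", "".join(lines1))
            _write_gz_text(out_dir / f"{sid}_R2.fastq.gz", "".join(lines2))

    if out_dir is not None:
        pd.DataFrame(
            manifest_rows,
            columns=["sample_id", "role", "species_morph", "site", "year", "sex",
                     "nested_pcr_status"],
        ).to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
        truth.to_json(out_dir / "truth.json")
        coi_db, s16_db = build_reference_db(config)
        coi_db.write_midori(out_dir / "coi_refdb.fasta", out_dir / "coi_lineages.tsv")
        s16_db.write_silva(out_dir / "16s_refdb.fasta")
        fulllength_refdb(config).write_silva(out_dir / "fulllength_16s.fasta")
    return truth


def _write_gz_text(path: Path, text: str) -> None:
    """Gzip with a zeroed header timestamp so fixed seeds give
    byte-identical files."""
    with open(path, "wb") as raw:
        with gzip.GzipFile(fileobj=raw, mode="wb", mtime=0) as gz:
            gz.write(text.encode())


def _with_primers(marker: MarkerDef, insert: str) -> str:
    return (_concrete_primer(marker.fwd_primer) + insert
            + revcomp(_concrete_primer(marker.rev_primer)))


def truth_feature_table(truth: SimulationTruth, marker: str):
    """Truth composition as a FeatureTable (one feature per source sequence).

    The noise-free upper bound of what the pipeline can reconstruct; used
    for parameter-recovery checks that do not need read-level processing.
    """
    from .features import FeatureTable
    import pandas as pd

    counts = truth.composition_table(marker)
    seq_to_lineage = {
        v["seq"]: ";".join(v["lineage"])
        for v in truth.sources.values()
        if v["marker"] == marker
    }
    ids = [f"T{i + 1}" for i in range(len(counts.index))]
    meta = pd.DataFrame(
        {
            "sequence": list(counts.index),
            "taxonomy": [seq_to_lineage.get(s, "") for s in counts.index],
            "total_abundance": counts.sum(axis=1).to_numpy(),
        },
        index=ids,
    )
    mat = counts.copy()
    mat.index = ids
    return FeatureTable(marker, "zOTU", mat.astype(int), meta)
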