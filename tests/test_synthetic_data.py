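"""The synthetic run generator: determinism, conservation, truth fidelity."""

import gzip
import json
from pathlib import Path

import numpy as np
import pytest

import symbiomark as sm
from symbiomark._seq import hamming, random_seq
from symbiomark.demux_io import CONTROL_ROLES
from symbiomark.synthetic_data import INSERT_LEN, _with_primers


def _small_cfg(seed=5, **kw):
    kw.setdefault("n_specimens", 4)
    kw.setdefault("n_controls", 1)
    return sm.default_config(seed=seed, **kw)


def _read_fastq_ids(path):
    with gzip.open(path, "rt") as fh:
        return [line.strip() for i, line in enumerate(fh) if i % 4 == 0]


# --- determinism and output layout -----------------------------------------

def test_fixed_seed_gives_byte_identical_outputs(tmp_path):
    cfg = _small_cfg(error_rate=0.005, chimera_rate=0.02)
    d1, d2 = tmp_path / "a", tmp_path / "b"
    sm.simulate_run(cfg, d1)
    sm.simulate_run(cfg, d2)
    for f in sorted(p.name for p in d1.iterdir()):
        assert (d1 / f).read_bytes() == (d2 / f).read_bytes(), f


def test_run_layout_and_manifest_roles(tmp_path):
    cfg = _small_cfg()
    sm.simulate_run(cfg, tmp_path)
    libs = sm.parse_manifest(tmp_path / "manifest.tsv")
    roles = [l.role for l in libs]
    assert roles.count("specimen") == 4
    for role in CONTROL_ROLES:
        assert roles.count(role) == 1
    for lib in libs:
        assert (tmp_path / f"{lib.sample_id}_R1.fastq.gz").exists()
        assert (tmp_path / f"{lib.sample_id}_R2.fastq.gz").exists()


def test_truth_json_roundtrip(tmp_path):
    cfg = _small_cfg()
    truth = sm.simulate_run(cfg, tmp_path)
    loaded = sm.SimulationTruth.from_json(tmp_path / "truth.json")
    assert loaded.per_sample == json.loads(json.dumps(truth.per_sample))
    assert set(loaded.sources) == set(truth.sources)


# --- no-noise limit and conservation ---------------------------------------

def test_error_free_reads_are_exact_truth_amplicons(tmp_path):
    cfg = _small_cfg(error_rate=0.0, chimera_rate=0.0)
    truth = sm.simulate_run(cfg, tmp_path)
    markers = {m.name: m for m in cfg.markers}
    amplicons = set()
    for name, info in truth.sources.items():
        amplicons.add(_with_primers(markers[info["marker"]], info["seq"])[:300])
    sid = sorted(truth.specimens)[0]
    with gzip.open(tmp_path / f"{sid}_R1.fastq.gz", "rt") as fh:
        lines = fh.read().splitlines()
    reads = lines[1::4]
    assert reads and all(r in amplicons for r in reads)


def test_conservation_per_sample_and_marker(tmp_path):
    """Emitted read count equals the sum of truth source counts plus
    chimeras, for every sample and marker."""
    cfg = _small_cfg(error_rate=0.01, chimera_rate=0.05)
    truth = sm.simulate_run(cfg, tmp_path)
    for sid in truth.per_sample:
        n_reads = len(_read_fastq_ids(tmp_path / f"{sid}_R1.fastq.gz"))
        total = 0
        for m in truth.per_sample[sid]:
            srcs = sum(truth.per_sample[sid][m].values())
            chim = len(truth.chimeras[sid][m])
            assert truth.emitted[sid][m] == srcs + chim
            total += srcs + chim
        assert n_reads == total


def test_controls_carry_only_contaminants():
    cfg = _small_cfg()
    truth = sm.simulate_run(cfg, None)
    for sid, per_marker in truth.per_sample.items():
        if sid.startswith("CTRL"):
            for m, counts in per_marker.items():
                for src in counts:
                    assert truth.sources[src]["category"] == "contaminant"


def test_facultative_prevalence_recorded_in_truth():
    cfg = sm.default_config(n_specimens=40, seed=9, arsenophonus_prevalence=0.822)
    truth = sm.simulate_run(cfg, None)
    laevis = [s for s, v in truth.specimens.items()
              if v["species"] == "Macrosteles laevis"]
    carriers = sum(truth.specimens[s]["infections"]["Arsenophonus"] for s in laevis)
    from scipy.stats import binom
    lo, hi = binom.interval(0.999, len(laevis), 0.822)
    assert lo <= carriers <= hi


# --- chimeras ---------------------------------------------------------------

def test_form_chimera_prefix_suffix():
    assert sm.form_chimera("AAAAAAAA", "CCCCCCCC", 4) == "AAAACCCC"
    assert sm.form_chimera("AAAA", "AAAA", 2) == "AAAA"  # degenerate identity
    with pytest.raises(ValueError, match="interior"):
        sm.form_chimera("AAAA", "CCCC", 0)
    with pytest.raises(ValueError, match="interior"):
        sm.form_chimera("AAAA", "CCCCCCCC", 6)


def test_form_chimera_divergence_split(rng):
    """Parents 5% divergent with a central breakpoint: the chimera's
    divergence to each parent is the divergence falling in the other half."""
    from symbiomark._seq import mutate

    a = random_seq(rng, 200)
    b = mutate(rng, a, 10)
    chim = sm.form_chimera(a, b, 100)
    assert hamming(chim, a) + hamming(chim, b) == 10
    assert hamming(chim, a) == sum(x != y for x, y in zip(a[100:], b[100:]))


# --- error model ------------------------------------------------------------

def test_error_model_zero_rate_identity(rng):
    seq = random_seq(rng, 120)
    out, qual = sm.apply_error_model(seq, 0.0, rng)
    assert out == seq and len(qual) == len(seq)
    assert all(ord(c) - 33 >= 35 for c in qual)  # ~Q40


def test_error_model_binomial_rate(rng):
    """Realized substitution fraction over 100kb matches the nominal rate
    within 3 standard errors, and quality tracks the rate."""
    seq = random_seq(rng, 1000)
    n, total = 0, 0
    quals = []
    for _ in range(100):
        out, qual = sm.apply_error_model(seq, 0.01, rng)
        n += sum(a != b for a, b in zip(seq, out))
        total += len(seq)
        quals.append(ord(qual[0]) - 33)
    se = np.sqrt(0.01 * 0.99 / total)
    assert abs(n / total - 0.01) < 3 * se
    assert abs(np.mean(quals) - 20) < 1.0  # -10 log10(0.01)


def test_error_model_validates_rate(rng):
    with pytest.raises(ValueError):
        sm.apply_error_model("ACGT", 0.2, rng)


# --- reference databases ----------------------------------------------------

def test_build_reference_db_minimal_and_decoys():
    cfg = _small_cfg(n_species=1)
    cfg.symbiont_pool = {k: cfg.symbiont_pool[k] for k in ("Sulcia", "Nasuia")}
    cfg.species_pool[0].facultative_symbionts = []
    coi, s16 = sm.build_reference_db(cfg)
    assert len(coi) >= 1
    assert len(s16) >= 2
    tax_blob = " ".join(";".join(r.lineage).lower() for r in s16)
    for decoy in ("mitochondria", "chloroplast", "eukaryota", "archaea"):
        assert decoy in tax_blob


def test_build_reference_db_operon_records_share_genus():
    cfg = _small_cfg()
    _, s16 = sm.build_reference_db(cfg)
    ars = [r for r in s16 if r.rank("genus") == "Arsenophonus" and r.id.endswith("16S-V4")]
    assert len(ars) == 4


def test_build_reference_db_seven_species():
    cfg = sm.default_config(n_specimens=2, n_species=7, seed=1)
    coi, _ = sm.build_reference_db(cfg)
    macrosteles = [r for r in coi if r.rank("genus") == "Macrosteles"]
    assert len(macrosteles) == 7
    assert len({r.rank("species") for r in macrosteles}) == 7


def test_build_reference_db_rejects_duplicate_taxa():
    cfg = _small_cfg()
    cfg.species_pool = [cfg.species_pool[0], cfg.species_pool[0]]
    with pytest.raises(ValueError, match="duplicate"):
        sm.build_reference_db(cfg)


def test_refdb_dialect_roundtrip(tmp_path):
    cfg = _small_cfg()
    coi, s16 = sm.build_reference_db(cfg)
    s16.write_silva(tmp_path / "s.fasta")
    back = sm.RefDB.read_silva(tmp_path / "s.fasta")
    assert [(r.id, r.seq, r.lineage) for r in back] == [
        (r.id, r.seq, r.lineage) for r in s16
    ]
    coi.write_midori(tmp_path / "c.fasta", tmp_path / "c.tsv")
    back = sm.RefDB.read_midori(tmp_path / "c.fasta", tmp_path / "c.tsv")
    assert [(r.id, r.seq, r.lineage) for r in back] == [
        (r.id, r.seq, r.lineage) for r in coi
    ]


# --- config validation ------------------------------------------------------

def test_simconfig_validates_rates():
    with pytest.raises(ValueError):
        _small_cfg(error_rate=0.2)
    with pytest.raises(ValueError):
        _small_cfg(chimera_rate=0.5)


def test_speciesdef_validates_fractions(rng):
    hap = random_seq(rng, INSERT_LEN["COI"])
    with pytest.raises(ValueError, match="numt"):
        sm.SpeciesDef("x", ("E",) * 7, hap, numts=[("n", hap, 0.5)])
    with pytest.raises(ValueError, match="minor"):
        sm.SpeciesDef("x", ("E",) * 7, hap,
                      minor_haplotypes=[("m", hap, 0.6, 0.5)])
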