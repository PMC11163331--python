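"""Denoising, chimera screening, clustering, taxonomy, tables."""

import numpy as np
import pytest

import symbiomark as sm
from symbiomark._seq import edit_distance, mutate, random_seq
from symbiomark.features import assign_taxonomy_all
from symbiomark.merge_filter import UniqueSeq
from symbiomark.refdb import RefDB, RefRecord

from _oracles import greedy_cluster_oracle, identity_oracle, levenshtein_oracle


def _uniq(seq, n, sample="s1"):
    return UniqueSeq(seq, n, {sample: n})


def _zotu(i, seq, n, sample="s1"):
    return sm.ZOTU(f"zOTU{i}", seq, n, {sample: n})


# --- denoise ---------------------------------------------------------------

def test_denoise_single_unique_is_its_own_zotu(rng):
    s = random_seq(rng, 50)
    assert sm.denoise([_uniq(s, 7)]) == [(s, 7)]


def test_denoise_skew_rule_absorbs_and_preserves(rng):
    """At alpha=2 the skew threshold at d=1 is 1/8: a 10/1000 variant is
    absorbed, a 200/1000 one survives as a real minor variant."""
    c = random_seq(rng, 100)
    u = mutate(rng, c, 1)
    assert sm.skew(1, 2.0) == pytest.approx(1 / 8)
    absorbed = sm.denoise([_uniq(c, 1000), _uniq(u, 10)], alpha=2.0)
    assert absorbed == [(c, 1010)]
    kept = sm.denoise([_uniq(c, 1000), _uniq(u, 200)], alpha=2.0)
    assert kept == [(c, 1000), (u, 200)]


def test_denoise_default_alpha_keeps_ten_percent_minor_variant(rng):
    """The pipeline default must retain a 1-substitution heteroplasmy
    variant at 10% of the mitochondrial pool (ratio 1/9 > skew(1))."""
    c = random_seq(rng, 100)
    u = mutate(rng, c, 1)
    out = sm.denoise([_uniq(c, 900), _uniq(u, 100)])
    assert (u, 100) in out


def test_denoise_requires_sorted_input_and_conserves_reads(rng):
    c, u = random_seq(rng, 60), random_seq(rng, 60)
    with pytest.raises(ValueError, match="sorted"):
        sm.denoise([_uniq(c, 5), _uniq(u, 50)])
    uniques = [_uniq(random_seq(rng, 60), n) for n in (500, 120, 40, 7, 2)]
    out = sm.denoise(uniques)
    assert sum(n for _, n in out) == sum(u.total_abundance for u in uniques)


def test_denoise_per_sample_merges_centroids(rng):
    c = random_seq(rng, 80)
    u = mutate(rng, c, 1)
    uniques = [
        UniqueSeq(c, 1800, {"s1": 900, "s2": 900}),
        UniqueSeq(u, 101, {"s1": 100, "s2": 1}),  # real in s1, noise in s2
    ]
    zotus = sm.denoise_per_sample(uniques)
    by_seq = {z.centroid: z for z in zotus}
    assert by_seq[u].per_sample_counts == {"s1": 100}
    assert by_seq[c].per_sample_counts == {"s1": 900, "s2": 901}
    total = sum(z.total_abundance for z in zotus)
    assert total == 1901
    assert zotus[0].id == "zOTU1" and zotus[0].total_abundance >= zotus[-1].total_abundance


# --- chimera screen --------------------------------------------------------

def test_screen_chimeras_flags_bimera_not_parents(rng):
    a = random_seq(rng, 200)
    b = mutate(rng, a, 10)  # 5% divergent parents
    q = a[:100] + b[100:]
    zotus = [_zotu(1, a, 1600), _zotu(2, b, 1600), _zotu(3, q, 100)]
    flags = sm.screen_chimeras(zotus)
    assert flags == [False, False, True]
    assert zotus[2].chimera_flag


def test_screen_chimeras_identity_and_insufficient_parents(rng):
    a = random_seq(rng, 200)
    b = mutate(rng, a, 10)
    # query identical to a parent: never flagged
    zotus = [_zotu(1, a, 1600), _zotu(2, b, 1600), _zotu(3, a, 100)]
    assert sm.screen_chimeras(zotus) == [False, False, False]
    # only one sufficiently abundant candidate: not flagged
    q = a[:100] + b[100:]
    zotus = [_zotu(1, a, 1600), _zotu(2, q, 1000)]
    assert sm.screen_chimeras(zotus) == [False, False]


# --- clustering ------------------------------------------------------------

def test_cluster_examples(rng):
    base = random_seq(rng, 100)
    near = mutate(rng, base, 1)    # 0.99 identity
    far = mutate(rng, base, 10)    # 0.90 identity
    zotus = [_zotu(1, base, 100), _zotu(2, near, 50), _zotu(3, far, 20)]
    otus = sm.cluster_97(zotus)
    assert len(otus) == 2
    assert set(otus[0].members) == {"zOTU1", "zOTU2"}
    assert otus[0].total_abundance == 150  # additivity
    assert otus[0].representative == "zOTU1"


def test_cluster_excludes_chimeras(rng):
    a, b = random_seq(rng, 100), random_seq(rng, 100)
    z = [_zotu(1, a, 100), _zotu(2, b, 50)]
    z[1].chimera_flag = True
    assert len(sm.cluster_97(z)) == 1


def _random_instance(rng, n_max=50, length=50):
    n_fam = int(rng.integers(1, 6))
    seqs = []
    for _ in range(n_fam):
        base = random_seq(rng, length)
        seqs.append(base)
        for _ in range(int(rng.integers(0, 6))):
            seqs.append(mutate(rng, base, int(rng.integers(1, 6))))
    seqs = list(dict.fromkeys(seqs))[:n_max]  # dedupe, keep order
    abunds = rng.integers(1, 1000, size=len(seqs))
    return sorted(zip(seqs, abunds), key=lambda t: (-t[1], t[0]))


def test_greedy_clustering_matches_oracle_small(rng):
    """Greedy 97% clustering agrees with the from-scratch oracle."""
    for _ in range(10):
        pool = _random_instance(rng)
        zotus = [_zotu(i + 1, s, int(n)) for i, (s, n) in enumerate(pool)]
        otus = sm.cluster_97(zotus)
        got = sorted(sorted(o.members) for o in otus)
        oracle = greedy_cluster_oracle([s for s, _ in pool])
        ids = {s: f"zOTU{i + 1}" for i, (s, _) in enumerate(pool)}
        exp = sorted(sorted(ids[s] for s in cl) for cl in oracle)
        assert got == exp


def test_identity_definition_matches_oracle(rng):
    from symbiomark._seq import identity

    for _ in range(50):
        a = random_seq(rng, int(rng.integers(5, 60)))
        b = mutate(rng, a, int(rng.integers(0, 4))) if rng.random() < 0.7 else random_seq(
            rng, int(rng.integers(5, 60)))
        assert edit_distance(a, b) == levenshtein_oracle(a, b)
        assert identity(a, b) == pytest.approx(identity_oracle(a, b))


# --- taxonomy --------------------------------------------------------------

def _refdb(rng):
    sulcia = random_seq(rng, 100)
    return RefDB([
        RefRecord("R1_sulcia", sulcia,
                  ("Bacteria", "Bacteroidota", "Flavobacteriia",
                   "Flavobacteriales", "Blattabacteriaceae", "Sulcia", "")),
        RefRecord("R2_other", random_seq(rng, 100),
                  ("Bacteria", "Proteobacteria", "Gammaproteobacteria",
                   "Enterobacterales", "Enterobacteraceae", "Arsenophonus", "")),
    ]), sulcia


def test_assign_taxonomy_exact_hit(rng):
    db, sulcia = _refdb(rng)
    tax = sm.assign_taxonomy(sulcia, db)
    assert tax.rank("genus") == "Sulcia"
    assert tax.match_identity == 1.0
    assert tax.assignment_rank == "genus"


def test_assign_taxonomy_truncates_at_family(rng):
    db, sulcia = _refdb(rng)
    query = mutate(rng, sulcia, 8)  # identity 0.92: family but not genus
    tax = sm.assign_taxonomy(query, db)
    assert tax.assignment_rank == "family"
    assert tax.rank("family") == "Blattabacteriaceae"
    assert tax.rank("genus") == ""


def test_assign_taxonomy_below_cutoffs_keeps_domain_only(rng):
    db, sulcia = _refdb(rng)
    tax = sm.assign_taxonomy(random_seq(rng, 100), db)
    assert tax.assignment_rank == "domain"
    assert tax.rank("phylum") == ""


def test_assign_taxonomy_tie_breaks_and_empty_db(rng):
    seq = random_seq(rng, 60)
    db = RefDB([
        RefRecord("B_ref", seq, ("Bacteria", "", "", "", "", "GenB", "")),
        RefRecord("A_ref", seq, ("Bacteria", "", "", "", "", "GenA", "")),
    ])
    assert sm.assign_taxonomy(seq, db).best_ref_id == "A_ref"
    with pytest.raises(ValueError, match="empty"):
        sm.assign_taxonomy(seq, RefDB([]))


# --- tables ----------------------------------------------------------------

def test_build_tables_single_feature():
    z = _zotu(1, "ACGT", 10)
    z.taxonomy = None
    otus = sm.cluster_97([z])
    zt, ot = sm.build_tables([z], otus, ["s1"], "COI")
    assert zt.counts.shape == (1, 1) and zt.counts.iloc[0, 0] == 10
    assert ot.counts.iloc[0, 0] == 10


def test_build_tables_otu_sums_members(rng):
    base = random_seq(rng, 100)
    z1, z2 = _zotu(1, base, 7), _zotu(2, mutate(rng, base, 1), 3)
    otus = sm.cluster_97([z1, z2])
    zt, ot = sm.build_tables([z1, z2], otus, ["s1"], "COI")
    assert ot.counts.loc[otus[0].id, "s1"] == 10
    # column sums of the zOTU table match feature totals
    assert (zt.counts.sum(axis=1) == zt.meta["total_abundance"]).all()
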