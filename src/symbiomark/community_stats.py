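"""Population-level summaries and statistics.

Covers symbiont prevalence by host group, grouping of divergent rRNA-operon
copies into single-strain candidates, 16S region concordance, Jaccard /
Bray-Curtis distance matrices, distance-based redundancy analysis (dbRDA)
with a permutation ANOVA, the 2x2 chi-square association test, and the
nested-PCR vs amplicon detection concordance table.

dbRDA convention: the squared distance matrix is Gower-centered,
G = -1/2 J D^2 J; explanatory factors enter as centered one-hot designs;
the explained fraction is tr(H G H) over the sum of positive eigenvalues of
G (Jaccard and Bray-Curtis are non-Euclidean, so negative eigenvalues are
excluded from the denominator).  Factors are tested sequentially in the
order given, PERMANOVA-style, by freely permuting sample labels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2 as chi2_dist

import edlib

from .features import FeatureTable
from .refdb import RANKS, RefDB


# --------------------------------------------------------------------------
# distance matrices
# --------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    metric: str                  # "jaccard" | "bray_curtis"
    frame: pd.DataFrame          # square, symmetric, samples x samples

    @property
    def samples(self) -> list:
        return list(self.frame.index)

    def values(self) -> np.ndarray:
        return self.frame.to_numpy()


def distance_matrix(table: FeatureTable | pd.DataFrame, metric: str) -> DistanceMatrix:
    """Jaccard (presence/absence) or Bray-Curtis (counts) sample distances."""
    counts = table.counts if isinstance(table, FeatureTable) else table
    X = counts.to_numpy(dtype=float).T  # samples x features
    totals = X.sum(axis=1)
    if (totals == 0).any():
        bad = [counts.columns[i] for i in np.where(totals == 0)[0]]
        raise ValueError(f"all-zero sample(s): {bad}")
    if metric == "jaccard":
        D = squareform(pdist(X > 0, metric="jaccard"))
    elif metric == "bray_curtis":
        D = squareform(pdist(X, metric="braycurtis"))
    else:
        raise ValueError(f"unknown metric: {metric}")
    return DistanceMatrix(metric, pd.DataFrame(D, index=counts.columns, columns=counts.columns))


# --------------------------------------------------------------------------
# dbRDA / permutation ANOVA
# --------------------------------------------------------------------------

@dataclass
class ConstrainedVarianceResult:
    metric: str
    factors: list
    variance_explained_fraction: float
    anova: pd.DataFrame          # factor, df, ss, pseudo_F, p
    n_permutations: int
    seed: int | None


def _gower_center(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * J @ (D ** 2) @ J


def _projection(X: np.ndarray) -> tuple[np.ndarray, int]:
    """Orthogonal projection onto the column space of centered X, plus rank."""
    if X.size == 0:
        n = X.shape[0]
        return np.zeros((n, n)), 0
    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    keep = diag > 1e-10 * max(1.0, diag.max() if diag.size else 1.0)
    Q = Q[:, keep]
    return Q @ Q.T, int(keep.sum())


def _design(factors: pd.DataFrame) -> tuple[list[np.ndarray], list[str]]:
    """Centered one-hot design blocks, one per non-constant factor."""
    blocks, names = [], []
    for col in factors.columns:
        vals = factors[col].astype(str)
        if vals.nunique() < 2:
            continue  # constant factor: intercept only, explains nothing
        dummies = pd.get_dummies(vals, dtype=float).to_numpy()
        blocks.append(dummies - dummies.mean(axis=0))
        names.append(col)
    return blocks, names


def constrained_variance(
    dist: DistanceMatrix,
    factors: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ConstrainedVarianceResult:
    """dbRDA variance partition with sequential permutation ANOVA.

    ``factors`` is indexed by sample id (same universe as ``dist``), one
    categorical column per explanatory factor, tested in column order.
    p-values are ``(1 + #{F_perm >= F_obs}) / (1 + n_perm)``.
    """
    factors = factors.loc[dist.samples]
    G = _gower_center(dist.values())
    n = G.shape[0]
    eig = np.linalg.eigvalsh(G)
    total_pos = float(eig[eig > 1e-10].sum())
    trace_G = float(np.trace(G))

    blocks, names = _design(factors)
    if not blocks:
        anova = pd.DataFrame(columns=["factor", "df", "ss", "pseudo_F", "p"])
        return ConstrainedVarianceResult(dist.metric, [], 0.0, anova, 0, seed)

    def _sequential_ss(Gm: np.ndarray) -> tuple[list[float], float]:
        prev_tr, prev_rank = 0.0, 0
        ss_terms = []
        for k in range(len(blocks)):
            X = np.hstack(blocks[: k + 1])
            H, rank = _projection(X)
            tr = float(np.sum(Gm * H))  # = trace(G H), H symmetric
            ss_terms.append(tr - prev_tr)
            prev_tr, prev_rank = tr, rank
        return ss_terms, prev_tr

    # degrees of freedom from ranks of the nested designs
    dfs, prev_rank = [], 0
    for k in range(len(blocks)):
        _, rank = _projection(np.hstack(blocks[: k + 1]))
        dfs.append(rank - prev_rank)
        prev_rank = rank
    df_res = n - 1 - prev_rank

    ss_obs, tr_full = _sequential_ss(G)
    ss_res = trace_G - tr_full
    explained = tr_full / total_pos if total_pos > 0 else 0.0

    def _fstats(ss_terms, ss_resid):
        denom = ss_resid / df_res if df_res > 0 else np.nan
        return [
            (ss / df) / denom if df > 0 and denom and denom > 0 else np.nan
            for ss, df in zip(ss_terms, dfs)
        ]

    f_obs = _fstats(ss_obs, ss_res)
    exceed = np.zeros(len(blocks))
    if rng is None:
        rng = np.random.default_rng(seed)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Gp = G[np.ix_(perm, perm)]
        ss_p, tr_p = _sequential_ss(Gp)
        f_p = _fstats(ss_p, trace_G - tr_p)
        for i in range(len(blocks)):
            if not np.isnan(f_p[i]) and f_p[i] >= f_obs[i]:
                exceed[i] += 1
    pvals = (1 + exceed) / (1 + n_perm)

    anova = pd.DataFrame(
        {"factor": names, "df": dfs, "ss": ss_obs, "pseudo_F": f_obs, "p": pvals}
    )
    return ConstrainedVarianceResult(
        dist.metric, names, float(explained), anova, n_perm, seed
    )


def exhaustive_permutation_p(
    dist: DistanceMatrix, factors: pd.DataFrame
) -> list[float]:
    """Exact permutation p-values by enumerating all n! label permutations.

    Small-n reference for the Monte-Carlo test; same sequential pseudo-F as
    ``constrained_variance``.
    """
    factors = factors.loc[dist.samples]
    G = _gower_center(dist.values())
    n = G.shape[0]
    trace_G = float(np.trace(G))
    blocks, _ = _design(factors)
    dfs, prev_rank = [], 0
    for k in range(len(blocks)):
        _, rank = _projection(np.hstack(blocks[: k + 1]))
        dfs.append(rank - prev_rank)
        prev_rank = rank
    df_res = n - 1 - prev_rank

    def _f(Gm):
        prev = 0.0
        fs, ss_terms = [], []
        for k in range(len(blocks)):
            H, _ = _projection(np.hstack(blocks[: k + 1]))
            tr = float(np.sum(Gm * H))
            ss_terms.append(tr - prev)
            prev = tr
        ss_res = trace_G - prev
        denom = ss_res / df_res if df_res > 0 else np.nan
        for ss, df in zip(ss_terms, dfs):
            fs.append((ss / df) / denom if df > 0 and denom > 0 else np.nan)
        return fs

    f_obs = _f(G)
    counts = np.zeros(len(blocks))
    total = 0
    for perm in itertools.permutations(range(n)):
        Gp = G[np.ix_(perm, perm)]
        f_p = _f(Gp)
        total += 1
        for i in range(len(blocks)):
            if not np.isnan(f_p[i]) and f_p[i] >= f_obs[i] - 1e-12:
                counts[i] += 1
    return [c / total for c in counts]


# --------------------------------------------------------------------------
# chi-square and concordance
# --------------------------------------------------------------------------

@dataclass
class ChiSquareResult:
    counts: np.ndarray
    chi2: float
    df: int
    p: float


def chi_square_2x2(counts, correction: bool = False) -> ChiSquareResult:
    """Pearson chi-square on a 2x2 table: N(ad-bc)^2 / (r1 r2 c1 c2), df=1."""
    t = np.asarray(counts, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("counts must be a non-negative 2x2 table")
    a, b, c, d = t.ravel()
    n = t.sum()
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("chi-square undefined: zero row or column margin")
    delta = abs(a * d - b * c)
    if correction:
        delta = max(delta - n / 2.0, 0.0)
    stat = n * delta ** 2 / (r1 * r2 * c1 * c2)
    return ChiSquareResult(t.astype(int), float(stat), 1, float(chi2_dist.sf(stat, 1)))


@dataclass
class ConcordanceTable:
    counts: np.ndarray           # rows: label +/-, cols: amplicon detected/not
    cells: dict                  # (label, detected) -> sample list
    excluded: list               # samples lacking a label

    def chi_square(self, correction: bool = False) -> ChiSquareResult:
        return chi_square_2x2(self.counts, correction)


def detection_concordance(
    amplicon_detected: dict, external_labels: dict
) -> ConcordanceTable:
    """Cross-tabulate an external binary screen against amplicon detection.

    ``external_labels`` maps sample to "positive"/"negative" (or bool);
    samples with missing labels are excluded and listed.
    """
    cells = {(lab, det): [] for lab in (True, False) for det in (True, False)}
    excluded = []
    for s, det in sorted(amplicon_detected.items()):
        lab = external_labels.get(s, "")
        if isinstance(lab, str):
            lab = {"positive": True, "negative": False}.get(lab.strip().lower(), None)
        if lab is None or lab == "":
            excluded.append(s)
            continue
        cells[(bool(lab), bool(det))].append(s)
    counts = np.array(
        [
            [len(cells[(True, True)]), len(cells[(True, False)])],
            [len(cells[(False, True)]), len(cells[(False, False)])],
        ]
    )
    return ConcordanceTable(counts, cells, excluded)


# --------------------------------------------------------------------------
# prevalence and strain grouping
# --------------------------------------------------------------------------

def _rank_from_label(tax_label: str, rank: str) -> str:
    parts = (str(tax_label).split(";") + [""] * 7)[:7]
    return parts[RANKS.index(rank)]


def prevalence(
    table: FeatureTable,
    sample_groups: dict,
    detection_floor: int = 0,
    taxon_rank: str | None = "genus",
) -> pd.DataFrame:
    """Infected fraction and mean relative abundance per taxon and host group.

    ``sample_groups`` maps retained sample ids to a hashable group key
    (e.g. (species, site, year)).  A specimen counts as infected with a
    taxon iff its post-filter reads exceed ``detection_floor``.  With
    ``taxon_rank`` set, features sharing that rank are pooled; unassigned
    features keep their feature id.  Empty groups yield prevalence NaN.
    """
    samples = [s for s in table.counts.columns if s in sample_groups]
    rel = table.relative_abundance()[samples]
    cnt = table.counts[samples]
    if taxon_rank:
        taxa = {}
        for f in cnt.index:
            t = _rank_from_label(table.meta.loc[f, "taxonomy"], taxon_rank) or f
            taxa.setdefault(t, []).append(f)
    else:
        taxa = {f: [f] for f in cnt.index}

    groups: dict = {}
    for s in samples:
        groups.setdefault(sample_groups[s], []).append(s)

    rows = []
    for taxon, feats in sorted(taxa.items()):
        t_counts = cnt.loc[feats].sum(axis=0)
        t_rel = rel.loc[feats].sum(axis=0)
        for g, members in sorted(groups.items(), key=lambda kv: str(kv[0])):
            n = len(members)
            if n == 0:
                rows.append((taxon, g, 0, float("nan"), float("nan")))
                continue
            infected = int((t_counts[members] > detection_floor).sum())
            rows.append(
                (taxon, g, n, infected / n, float(t_rel[members].mean()))
            )
    return pd.DataFrame(
        rows, columns=["taxon", "group", "n", "prevalence", "mean_relative_abundance"]
    )


@dataclass
class StrainGroup:
    members: list
    mean_copresence: float
    max_ratio_cv: float
    verdict: str                 # "single_strain_candidate" | "independent"


def group_operon_variants(
    table: FeatureTable | pd.DataFrame,
    copresence_min: float = 0.9,
    ratio_cv_max: float = 0.5,
    min_shared: int = 2,
) -> list[StrainGroup]:
    """Group same-genus features that behave like rRNA operon copies of one
    genome: near-perfect co-occurrence and a stable abundance ratio.

    Two features link iff they co-occur in >= ``copresence_min`` of the
    samples where either occurs and the coefficient of variation of their
    per-sample abundance ratio (sd/mean over shared samples) is
    <= ``ratio_cv_max``.  Connected components of size >= 2 are
    single-strain candidates.
    """
    counts = table.counts if isinstance(table, FeatureTable) else table
    feats = list(counts.index)
    present = counts > 0
    parent = {f: f for f in feats}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    stats: dict[tuple, tuple[float, float]] = {}
    for i, fi in enumerate(feats):
        for fj in feats[i + 1 :]:
            either = present.loc[fi] | present.loc[fj]
            both = present.loc[fi] & present.loc[fj]
            n_either = int(either.sum())
            if n_either == 0:
                continue
            cop = int(both.sum()) / n_either
            if int(both.sum()) < min_shared or cop < copresence_min:
                continue
            shared = counts.columns[both]
            r = counts.loc[fi, shared].to_numpy(float) / counts.loc[fj, shared].to_numpy(float)
            cv = float(r.std() / r.mean()) if r.mean() > 0 else float("inf")
            if cv <= ratio_cv_max:
                stats[(fi, fj)] = (cop, cv)
                parent[find(fi)] = find(fj)

    components: dict = {}
    for f in feats:
        components.setdefault(find(f), []).append(f)
    groups = []
    for members in components.values():
        if len(members) >= 2:
            pair_stats = [
                stats[k] for k in stats if k[0] in members and k[1] in members
            ]
            cop = float(np.mean([s[0] for s in pair_stats])) if pair_stats else 0.0
            cv = float(np.max([s[1] for s in pair_stats])) if pair_stats else 0.0
            groups.append(StrainGroup(sorted(members), cop, cv, "single_strain_candidate"))
        else:
            groups.append(StrainGroup(members, 0.0, 0.0, "independent"))
    groups.sort(key=lambda g: (-len(g.members), g.members))
    return groups


# --------------------------------------------------------------------------
# 16S region concordance
# --------------------------------------------------------------------------

def _best_fulllength_genus(seq: str, ref: RefDB) -> str:
    best_d, best_rec = None, None
    for rec in ref:
        d = edlib.align(seq, rec.seq, mode="HW", task="distance")["editDistance"]
        if best_d is None or d < best_d or (d == best_d and rec.id < best_rec.id):
            best_d, best_rec = d, rec
    return best_rec.rank("genus")


def compare_regions(
    v4_table: FeatureTable,
    v1v2_table: FeatureTable,
    fulllength_ref: RefDB,
    min_reads: int = 1000,
) -> dict:
    """Genus-level concordance between the V4 and V1-V2 16S datasets.

    Region features map to full-length reference sequences by best infix
    alignment; the comparison runs on samples whose library totals pass
    ``min_reads`` in both regions.  Reports shared and region-exclusive
    genera and per-genus mean relative abundances.
    """
    if len(fulllength_ref) == 0:
        raise ValueError("empty full-length reference set")
    shared_samples = [
        s
        for s in v4_table.counts.columns
        if s in v1v2_table.counts.columns
        and v4_table.counts[s].sum() >= min_reads
        and v1v2_table.counts[s].sum() >= min_reads
    ]

    def _genus_table(table: FeatureTable) -> pd.DataFrame:
        rows: dict[str, np.ndarray] = {}
        rel = table.relative_abundance()[shared_samples]
        for f in table.counts.index:
            seq = str(table.meta.loc[f, "sequence"])
            if not seq:
                continue
            g = _best_fulllength_genus(seq, fulllength_ref)
            rows[g] = rows.get(g, 0) + rel.loc[f].to_numpy(float)
        return pd.DataFrame(rows, index=shared_samples).T

    g4 = _genus_table(v4_table)
    g12 = _genus_table(v1v2_table)
    present4 = set(g4.index[(g4 > 0).any(axis=1)]) if len(g4) else set()
    present12 = set(g12.index[(g12 > 0).any(axis=1)]) if len(g12) else set()
    return {
        "samples": shared_samples,
        "genera_v4": sorted(present4),
        "genera_v1v2": sorted(present12),
        "shared": sorted(present4 & present12),
        "v4_only": sorted(present4 - present12),
        "v1v2_only": sorted(present12 - present4),
        "mean_abundance_v4": g4.mean(axis=1).to_dict() if len(g4) else {},
        "mean_abundance_v1v2": g12.mean(axis=1).to_dict() if len(g12) else {},
    }
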