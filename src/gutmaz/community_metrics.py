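"""Community ecology statistics.

Read QC, rare-OTU prevalence filtering, averaged rarefaction, alpha
diversity indices, Bray-Curtis / PCoA ordination, PERMANOVA and the
Mantel test, plus a pairwise Wilcoxon utility with Bonferroni-Holm
correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import mannwhitneyu, pearsonr, wilcoxon

from gutmaz.io_core import OtuTable, relative_abundance

__all__ = [
    "RarefiedTable",
    "DistanceMatrix",
    "PermanovaResult",
    "qc_filter_reads",
    "filter_rare_otus",
    "rarefy_averaged",
    "alpha_diversity",
    "bray_curtis",
    "bray_curtis_pcoa",
    "pcoa",
    "permanova",
    "mantel_test",
    "pairwise_wilcoxon_holm",
]


@dataclass
class RarefiedTable:
    """Resample-averaged, rounded OTU table at a common target depth.

    ``raw_mean`` is the pre-rounding resample mean; its rows sum to the
    target depth exactly (without-replacement sampling conserves totals).
    """

    sample_ids: list[str]
    otu_ids: list[str]
    values: np.ndarray
    target_depth: int
    raw_mean: np.ndarray | None = None

    def __post_init__(self) -> None:
        if (self.values < 0).any():
            raise ValueError("rarefied values must be non-negative")

    def to_otu_table(self) -> OtuTable:
        return OtuTable(self.sample_ids, self.otu_ids, self.values.astype(np.int64))


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.sample_ids), len(self.sample_ids)):
            raise ValueError("distance matrix shape inconsistent with sample ids")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if (np.diag(m) != 0).any():
            raise ValueError("distance matrix diagonal must be zero")
        if (m < 0).any():
            raise ValueError("distances must be non-negative")
        self.matrix = m

    @property
    def condensed(self) -> np.ndarray:
        return squareform(self.matrix, checks=False)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            self.matrix, index=self.sample_ids, columns=self.sample_ids
        ).to_csv(path, sep="\t")


@dataclass
class PermanovaResult:
    factor: str
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int


# ---------------------------------------------------------------------------
# Read QC
# ---------------------------------------------------------------------------


def _longest_mononucleotide_run(seq: str) -> int:
    best = run = 1
    for i in range(1, len(seq)):
        run = run + 1 if seq[i] == seq[i - 1] else 1
        best = max(best, run)
    return best if seq else 0


def qc_filter_reads(
    fastq_in: str | Path,
    fastq_out: str | Path | None = None,
    min_length: int = 150,
    min_mean_quality: float = 20.0,
    max_homopolymer: int = 8,
) -> dict[str, int]:
    """Filter FASTQ reads by length, mean Phred, ambiguity and homopolymers.

    Discards reads shorter than ``min_length``, with mean Phred quality
    below ``min_mean_quality``, containing any ambiguous base (non-ACGT),
    or with a mononucleotide run longer than ``max_homopolymer``.
    Survivors are written to ``fastq_out`` when given.  Returns tallies:
    ``kept``, ``discarded``, and per-criterion counts (a read failing
    several criteria is tallied under each).
    """
    from Bio import SeqIO

    tallies = {
        "kept": 0,
        "discarded": 0,
        "too_short": 0,
        "low_quality": 0,
        "ambiguous": 0,
        "homopolymer": 0,
    }
    out_handle = open(fastq_out, "w") if fastq_out is not None else None
    try:
        for idx, rec in enumerate(SeqIO.parse(str(fastq_in), "fastq")):
            try:
                seq = str(rec.seq).upper()
                quals = rec.letter_annotations["phred_quality"]
            except (KeyError, ValueError) as e:
                raise ValueError(f"truncated or malformed FASTQ record {idx}: {e}")
            fail = False
            if len(seq) < min_length:
                tallies["too_short"] += 1
                fail = True
            if quals and float(np.mean(quals)) < min_mean_quality:
                tallies["low_quality"] += 1
                fail = True
            if set(seq) - set("ACGT"):
                tallies["ambiguous"] += 1
                fail = True
            if _longest_mononucleotide_run(seq) > max_homopolymer:
                tallies["homopolymer"] += 1
                fail = True
            if fail:
                tallies["discarded"] += 1
            else:
                tallies["kept"] += 1
                if out_handle is not None:
                    SeqIO.write(rec, out_handle, "fastq")
    finally:
        if out_handle is not None:
            out_handle.close()
    return tallies


# ---------------------------------------------------------------------------
# Table filtering and rarefaction
# ---------------------------------------------------------------------------


def filter_rare_otus(table: OtuTable, min_fraction: float = 1e-5) -> OtuTable:
    """Drop OTUs whose grand total is below ``min_fraction`` of all counts.

    The default 1e-5 corresponds to discarding OTUs containing less than
    0.001% of the total sequences across all samples.
    """
    grand_total = int(table.counts.sum())
    if grand_total <= 0:
        raise ValueError("table has zero total count")
    otu_totals = table.counts.sum(axis=0)
    keep = otu_totals >= min_fraction * grand_total
    kept_ids = [o for o, k in zip(table.otu_ids, keep) if k]
    return OtuTable(list(table.sample_ids), kept_ids, table.counts[:, keep])


def rarefy_averaged(
    table: OtuTable,
    n_resamples: int = 100,
    depth_fraction: float = 0.9,
    seed: int = 0,
) -> RarefiedTable:
    """Averaged, rounded, rarefied table.

    Target depth ``d = floor(depth_fraction * min sample depth)``.  Each
    resample subsamples ``d`` reads per sample without replacement
    (multivariate hypergeometric); entries are the mean over
    ``n_resamples`` resamples, rounded half-to-even at the end.
    """
    depths = table.depths
    if (depths <= 0).any():
        bad = [table.sample_ids[i] for i in np.flatnonzero(depths <= 0)]
        raise ValueError(f"zero-depth samples: {bad}")
    d = int(np.floor(depth_fraction * depths.min()))
    if d < 1:
        raise ValueError(
            f"target depth {d} < 1 (min depth {depths.min()}, "
            f"fraction {depth_fraction})"
        )
    rng = np.random.default_rng(seed)
    acc = np.zeros(table.counts.shape, dtype=float)
    for _ in range(n_resamples):
        for i in range(table.n_samples):
            acc[i] += rng.multivariate_hypergeometric(table.counts[i], d)
    mean = acc / n_resamples
    return RarefiedTable(
        list(table.sample_ids), list(table.otu_ids), np.round(mean), d, mean
    )


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------


def _shannon(row: np.ndarray, base: float) -> float:
    p = row[row > 0] / row.sum()
    return float(-(p * np.log(p)).sum() / np.log(base))


def _chao1(row: np.ndarray) -> float:
    s_obs = int((row > 0).sum())
    f1 = int((row == 1).sum())
    f2 = int((row == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def _ace(row: np.ndarray, rare_threshold: int = 10) -> float:
    row = row[row > 0]
    rare = row[row <= rare_threshold]
    s_abund = int((row > rare_threshold).sum())
    s_rare = len(rare)
    if s_rare == 0:
        return float(s_abund)
    n_rare = int(rare.sum())
    f1 = int((rare == 1).sum())
    if n_rare == f1:
        # all rare species are singletons; ACE undefined, fall back to Chao1
        return _chao1(row)
    c_ace = 1.0 - f1 / n_rare
    fis = np.array([(rare == i).sum() for i in range(1, rare_threshold + 1)])
    top = sum(i * (i - 1) * fis[i - 1] for i in range(1, rare_threshold + 1))
    gamma = max(s_rare / c_ace * top / (n_rare * (n_rare - 1.0)) - 1.0, 0.0)
    return s_abund + s_rare / c_ace + f1 / c_ace * gamma


def alpha_diversity(
    table: OtuTable | RarefiedTable, shannon_base: float = 2.0
) -> pd.DataFrame:
    """Per-sample Shannon (base-2 by default), Simpson, Chao1, ACE, observed."""
    if isinstance(table, RarefiedTable):
        counts = table.values
        ids = table.sample_ids
    else:
        counts = table.counts
        ids = table.sample_ids
    out = []
    for i in range(counts.shape[0]):
        row = counts[i].astype(float)
        total = row.sum()
        if total <= 0:
            raise ValueError(f"zero-depth sample {ids[i]!r}")
        p = row / total
        out.append(
            {
                "shannon": _shannon(row, shannon_base),
                "simpson": float(1.0 - (p**2).sum()),
                "chao1": _chao1(row),
                "ace": _ace(row),
                "observed": int((row > 0).sum()),
            }
        )
    return pd.DataFrame(out, index=pd.Index(ids, name="sample_id"))


# ---------------------------------------------------------------------------
# Beta diversity / ordination
# ---------------------------------------------------------------------------


def bray_curtis(table: OtuTable | np.ndarray) -> DistanceMatrix:
    """Bray-Curtis dissimilarity on relative abundances."""
    if isinstance(table, OtuTable):
        rel = relative_abundance(table)
        ids = table.sample_ids
    else:
        rel = np.asarray(table, dtype=float)
        ids = [str(i) for i in range(rel.shape[0])]
    mat = squareform(pdist(rel, metric="braycurtis"))
    return DistanceMatrix(list(ids), mat)


def pcoa(dist: DistanceMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Principal coordinate analysis via double-centering eigendecomposition.

    Returns ``(coordinates, eigenvalues)`` with axes ordered by
    decreasing eigenvalue; negative eigenvalues are reported as-is and
    their axes carry zero coordinates.
    """
    d = dist.matrix
    n = d.shape[0]
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    evals, evecs = np.linalg.eigh(g)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    coords = np.zeros((n, n))
    pos = evals > 1e-12
    coords[:, pos] = evecs[:, pos] * np.sqrt(evals[pos])
    return coords, evals


def bray_curtis_pcoa(
    table: OtuTable,
) -> tuple[DistanceMatrix, np.ndarray, np.ndarray]:
    """Bray-Curtis distances and their PCoA ordination."""
    if table.n_samples < 3:
        raise ValueError("PCoA requires at least 3 samples")
    dist = bray_curtis(table)
    coords, evals = pcoa(dist)
    return dist, coords, evals


# ---------------------------------------------------------------------------
# PERMANOVA / Mantel
# ---------------------------------------------------------------------------


def _permanova_f(d2: np.ndarray, groups: np.ndarray, n_groups: int) -> tuple[float, float]:
    """Pseudo-F and R^2 from squared distances and integer group codes."""
    n = d2.shape[0]
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        mask = groups == g
        ng = int(mask.sum())
        sub = d2[np.ix_(mask, mask)]
        ss_within += sub[np.triu_indices(ng, 1)].sum() / ng
    ss_among = ss_total - ss_within
    f = (ss_among / (n_groups - 1)) / (ss_within / (n - n_groups))
    r2 = ss_among / ss_total
    return float(f), float(r2)


def permanova(
    dist: DistanceMatrix,
    labels: Sequence,
    n_perm: int | str = 999,
    seed: int = 0,
    factor: str = "group",
) -> PermanovaResult:
    """One-factor PERMANOVA with free label permutations.

    ``p = (1 + #{permuted F >= observed F}) / (n_perm + 1)``.  With
    ``n_perm="all"`` every permutation is enumerated and
    ``p = #{F >= observed F} / n!`` (the identity permutation included,
    so p >= 1/n!).
    """
    labels = np.asarray(labels)
    if len(labels) != len(dist.sample_ids):
        raise ValueError("labels length does not match distance matrix")
    uniq, groups = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(groups)
    if (counts < 2).any():
        small = [str(uniq[i]) for i in np.flatnonzero(counts < 2)]
        raise ValueError(f"groups with fewer than 2 members: {small}")
    d2 = dist.matrix**2
    f_obs, r2 = _permanova_f(d2, groups, len(uniq))
    if n_perm == "all":
        from itertools import permutations as _perms

        n_tot = 0
        n_ge = 0
        for perm in _perms(groups.tolist()):
            n_tot += 1
            f_perm, _ = _permanova_f(d2, np.asarray(perm), len(uniq))
            if f_perm >= f_obs - 1e-12:
                n_ge += 1
        return PermanovaResult(factor, f_obs, r2, n_ge / n_tot, n_tot)
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(groups)
        f_perm, _ = _permanova_f(d2, perm, len(uniq))
        if f_perm >= f_obs:
            n_ge += 1
    p = (1 + n_ge) / (n_perm + 1)
    return PermanovaResult(factor, f_obs, r2, p, n_perm)


def mantel_test(
    dist_a: DistanceMatrix,
    dist_b: DistanceMatrix,
    n_perm: int | str = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Mantel test: Pearson r of upper triangles, permutation p-value.

    Two-sided: permutations with ``|r| >= |r_obs|`` count as extreme.
    ``n_perm="all"`` enumerates every sample permutation of the second
    matrix (p = #extreme / n!).
    """
    if dist_a.sample_ids != dist_b.sample_ids:
        if len(dist_a.sample_ids) != len(dist_b.sample_ids):
            raise ValueError("distance matrices have different sizes")
        raise ValueError("distance matrices cover different samples")
    n = len(dist_a.sample_ids)
    iu = np.triu_indices(n, 1)
    x = dist_a.matrix[iu]
    y = dist_b.matrix[iu]
    r_obs = pearsonr(x, y).statistic
    b = dist_b.matrix
    if n_perm == "all":
        from itertools import permutations as _perms

        n_tot = 0
        n_ge = 0
        for perm in _perms(range(n)):
            n_tot += 1
            y_perm = b[np.ix_(perm, perm)][iu]
            if abs(pearsonr(x, y_perm).statistic) >= abs(r_obs) - 1e-12:
                n_ge += 1
        return float(r_obs), n_ge / n_tot
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        y_perm = b[np.ix_(perm, perm)][iu]
        if abs(pearsonr(x, y_perm).statistic) >= abs(r_obs):
            n_ge += 1
    p = (1 + n_ge) / (n_perm + 1)
    return float(r_obs), float(p)


# ---------------------------------------------------------------------------
# Pairwise Wilcoxon utility
# ---------------------------------------------------------------------------


def pairwise_wilcoxon_holm(
    values: Sequence[float],
    groups: Sequence,
    paired: bool = False,
) -> pd.DataFrame:
    """All pairwise Wilcoxon tests with Bonferroni-Holm correction.

    Uses the signed-rank test when ``paired`` (equal group sizes
    required), else the rank-sum (Mann-Whitney U) test.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = sorted(set(groups.tolist()))
    rows = []
    for g1, g2 in combinations(uniq, 2):
        x = values[groups == g1]
        y = values[groups == g2]
        if paired:
            if len(x) != len(y):
                raise ValueError(f"paired test needs equal sizes for {g1}/{g2}")
            stat, p = wilcoxon(x, y)
        else:
            stat, p = mannwhitneyu(x, y, alternative="two-sided")
        rows.append({"group1": g1, "group2": g2, "statistic": stat, "p": p})
    df = pd.DataFrame(rows)
    # Bonferroni-Holm step-down
    m = len(df)
    order = np.argsort(df["p"].to_numpy())
    adj = np.empty(m)
    running_max = 0.0
    for rank, idx in enumerate(order):
        val = min((m - rank) * df["p"].iloc[idx], 1.0)
        running_max = max(running_max, val)
        adj[idx] = running_max
    df["p_holm"] = adj
    return df
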