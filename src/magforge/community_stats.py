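"""Diversity and differential statistics implemented from first principles.

Covers the full downstream statistics of a genome-resolved incubation
study: bin abundance from contig depths, Bray-Curtis and (normalized)
weighted / unweighted UniFrac distances, principal coordinate analysis,
PERMANOVA and PERMDISP permutation tests, redundancy analysis against
forage chemistry, a Pearson correlation screen, ANCOM differential
abundance, and Spearman/average-linkage heatmap ordering.

These are the package's own implementations (library equivalents serve as
independent cross-checks in the test suite, never as the computation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .errors import MagforgeError


@dataclass
class DistanceMatrix:
    labels: list[str]
    data: np.ndarray
    method: str

    def __post_init__(self):
        d = np.asarray(self.data, float)
        if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-12):
            raise MagforgeError("distance matrix must be symmetric")
        np.fill_diagonal(d, 0.0)
        if (d < -1e-12).any():
            raise MagforgeError("negative distances")
        self.data = d

    def to_skbio(self):
        from skbio import DistanceMatrix as SkbioDM
        return SkbioDM(self.data, ids=self.labels)


@dataclass
class PermutationTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    seed: int
    method: str


@dataclass
class AncomResult:
    w: pd.Series                 # per-taxon W statistic
    detected: pd.Series          # W >= cutoff * (m - 1)
    detected_bonferroni: pd.Series
    cutoff: float
    n_taxa: int


# ---------------------------------------------------------------------------
# abundance quantification


def quantify_bins(depths: pd.DataFrame, contig_lengths: pd.Series,
                  membership: pd.Series) -> pd.DataFrame:
    """Genome abundance = length-weighted mean depth of its contigs.

    `depths` is contigs x samples, `membership` maps contig -> genome.
    """
    genomes = sorted(set(membership))
    out = {}
    for g in genomes:
        contigs = membership[membership == g].index
        w = contig_lengths.loc[contigs].to_numpy(float)
        if w.sum() <= 0:
            raise MagforgeError(f"genome {g} has zero total contig length")
        out[g] = (depths.loc[contigs].to_numpy(float) * w[:, None]).sum(0) \
            / w.sum()
    return pd.DataFrame(out, index=depths.columns).T


# ---------------------------------------------------------------------------
# beta diversity


def _tree_branches(tree, taxa: list[str]):
    """(lengths, membership matrix) for every non-root branch.

    membership[b, t] == 1 iff taxon t descends through branch b.
    """
    index = {t: i for i, t in enumerate(taxa)}
    leaves = {t.name for t in tree.tips()}
    missing = sorted(set(taxa) - leaves)
    if missing:
        raise MagforgeError(f"taxa missing from tree: {missing}")
    lengths, rows = [], []
    masks: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            mask = np.zeros(len(taxa))
            if node.name in index:
                mask[index[node.name]] = 1.0
        else:
            mask = np.zeros(len(taxa))
            for child in node.children:
                mask += masks[id(child)]
        masks[id(node)] = mask
        if node.parent is not None:
            lengths.append(float(node.length or 0.0))
            rows.append(mask)
    return np.array(lengths), np.array(rows)


def beta_diversity(table: pd.DataFrame, method: str = "bray_curtis",
                   tree=None) -> DistanceMatrix:
    """Pairwise sample dissimilarity.

    * ``bray_curtis``: 1 - 2 sum(min(x, y)) / sum(x + y).
    * ``weighted_unifrac`` (normalized): sum_b l_b |A_b - B_b| /
      sum_b l_b (A_b + B_b) on clade *relative* abundances, bounded [0, 1].
    * ``unweighted_unifrac``: unique / total branch length over branches
      with any descendant present.
    """
    x = table.to_numpy(float)
    samples = list(table.columns)
    sums = x.sum(axis=0)
    if (sums <= 0).any():
        bad = [s for s, t in zip(samples, sums) if t <= 0]
        raise MagforgeError(f"all-zero samples: {bad}")
    n = len(samples)
    d = np.zeros((n, n))
    if method == "bray_curtis":
        for i in range(n):
            for j in range(i + 1, n):
                shared = np.minimum(x[:, i], x[:, j]).sum()
                d[i, j] = d[j, i] = 1.0 - 2.0 * shared / (sums[i] + sums[j])
    elif method in ("weighted_unifrac", "unweighted_unifrac"):
        if tree is None:
            raise MagforgeError("UniFrac requires a tree")
        lengths, member = _tree_branches(tree, list(table.index))
        if method == "weighted_unifrac":
            rel = x / sums
            clade = member @ rel  # branches x samples
            for i in range(n):
                for j in range(i + 1, n):
                    num = lengths @ np.abs(clade[:, i] - clade[:, j])
                    den = lengths @ (clade[:, i] + clade[:, j])
                    d[i, j] = d[j, i] = num / den if den > 0 else 0.0
        else:
            present = (member @ (x > 0)) > 0
            for i in range(n):
                for j in range(i + 1, n):
                    either = present[:, i] | present[:, j]
                    unique = present[:, i] ^ present[:, j]
                    tot = lengths @ either
                    d[i, j] = d[j, i] = (lengths @ unique) / tot \
                        if tot > 0 else 0.0
    else:
        raise MagforgeError(f"unknown beta-diversity method {method!r}")
    return DistanceMatrix(labels=samples, data=d, method=method)


# ---------------------------------------------------------------------------
# ordination


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame     # samples x axes (positive eigenvalues)
    eigenvalues: np.ndarray       # all, nonincreasing (negatives reported)
    variance_fractions: np.ndarray  # over positive eigenvalues only


def pcoa(dist: DistanceMatrix, k: int | None = None) -> PCoAResult:
    """Classical (metric) multidimensional scaling of a distance matrix."""
    d = dist.data
    n = d.shape[0]
    if k is None:
        k = n - 1
    if k > n - 1:
        raise MagforgeError("k must be <= n - 1")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    vals, vecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > 1e-12
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    coords = coords[:, :k]
    frac = np.zeros(coords.shape[1])
    if pos.any():
        frac = (vals[pos] / vals[pos].sum())[:coords.shape[1]]
    axes = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return PCoAResult(
        coordinates=pd.DataFrame(coords, index=dist.labels, columns=axes),
        eigenvalues=vals, variance_fractions=frac)


# ---------------------------------------------------------------------------
# permutation tests


def _group_indicators(labels: np.ndarray) -> list[np.ndarray]:
    return [labels == g for g in np.unique(labels)]


def _permanova_f(d2: np.ndarray, labels: np.ndarray) -> float:
    n = d2.shape[0]
    groups = _group_indicators(labels)
    a = len(groups)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = sum(d2[np.ix_(m, m)].sum() / (2 * m.sum()) for m in groups)
    ss_among = ss_total - ss_within
    return (ss_among / (a - 1)) / (ss_within / (n - a))


def permanova(dist: DistanceMatrix, groups, n_perm: int = 999,
              seed: int = 0) -> PermutationTestResult:
    """Pseudo-F from the among/within partition of squared distances;
    p = (1 + #{F_perm >= F_obs}) / (n_perm + 1) under free label
    permutation."""
    labels = np.asarray(pd.Series(groups).loc[dist.labels])
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise MagforgeError("PERMANOVA needs >= 2 groups")
    if (counts < 2).any():
        raise MagforgeError("every group needs >= 2 samples")
    d2 = dist.data ** 2
    f_obs = _permanova_f(d2, labels)
    rng = np.random.default_rng(seed)
    n = len(labels)
    count = 0
    for _ in range(n_perm):
        perm = labels[rng.permutation(n)]
        if _permanova_f(d2, perm) >= f_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return PermutationTestResult(statistic=float(f_obs), p_value=float(p),
                                 n_permutations=n_perm, seed=seed,
                                 method="permanova")


def _anova_f(values: np.ndarray, groups: list[np.ndarray]) -> float:
    grand = values.mean()
    a = len(groups)
    n = len(values)
    ss_b = sum(m.sum() * (values[m].mean() - grand) ** 2 for m in groups)
    ss_w = sum(((values[m] - values[m].mean()) ** 2).sum() for m in groups)
    if ss_w <= 0:
        return 0.0
    return (ss_b / (a - 1)) / (ss_w / (n - a))


def permdisp(dist: DistanceMatrix, groups, n_perm: int = 999,
             seed: int = 0) -> PermutationTestResult:
    """Homogeneity of multivariate dispersion.

    Per-sample distances to the own-group centroid are computed in the
    positive-eigenvalue PCoA space; the ANOVA F on those distances is
    permuted by shuffling which samples carry which residual distance.
    """
    labels = np.asarray(pd.Series(groups).loc[dist.labels])
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise MagforgeError("PERMDISP needs >= 2 groups")
    if (counts < 2).any():
        raise MagforgeError("every group needs >= 2 samples")
    coords = pcoa(dist).coordinates.to_numpy()
    masks = _group_indicators(labels)
    z = np.zeros(len(labels))
    for m in masks:
        centroid = coords[m].mean(axis=0)
        z[m] = np.linalg.norm(coords[m] - centroid, axis=1)
    f_obs = _anova_f(z, masks)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        zp = z[rng.permutation(len(z))]
        if _anova_f(zp, masks) >= f_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return PermutationTestResult(statistic=float(f_obs), p_value=float(p),
                                 n_permutations=n_perm, seed=seed,
                                 method="permdisp")


# ---------------------------------------------------------------------------
# constrained ordination


@dataclass
class RDAResult:
    site_scores: pd.DataFrame
    species_scores: pd.DataFrame
    biplot_scores: pd.DataFrame
    axis_variance: np.ndarray       # fraction of total response variance
    total_variance_explained: float


def rda(response: pd.DataFrame, constraints: pd.DataFrame,
        cond_max: float = 1e8) -> RDAResult:
    """Redundancy analysis: PCA of the response fitted on the constraints.

    Response rows are samples, columns taxa (centered internally);
    constraint columns are standardized.  Raises when constraints are
    collinear beyond `cond_max`, naming the variables.
    """
    y = response.to_numpy(float)
    y = y - y.mean(axis=0)
    xraw = constraints.loc[response.index].to_numpy(float)
    sd = xraw.std(axis=0, ddof=0)
    if (sd == 0).any():
        bad = [c for c, s in zip(constraints.columns, sd) if s == 0]
        raise MagforgeError(f"constant constraints: {bad}")
    x = (xraw - xraw.mean(axis=0)) / sd
    if np.linalg.cond(x) > cond_max:
        raise MagforgeError(
            f"collinear constraints: {list(constraints.columns)}")
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    fitted = x @ beta
    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    total_ss = (y ** 2).sum()
    k = min(x.shape[1], y.shape[1])
    axis_var = (s[:k] ** 2) / total_ss if total_ss > 0 else np.zeros(k)
    axes = [f"RDA{i + 1}" for i in range(k)]
    site = pd.DataFrame(u[:, :k] * s[:k], index=response.index,
                        columns=axes)
    species = pd.DataFrame(vt[:k].T, index=response.columns, columns=axes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-variance axes yield nan corr
        biplot = np.array([[np.corrcoef(x[:, q], site.iloc[:, i])[0, 1]
                            if s[i] > 1e-12 else 0.0
                            for i in range(k)]
                           for q in range(x.shape[1])])
    biplot = pd.DataFrame(np.nan_to_num(biplot),
                          index=constraints.columns, columns=axes)
    return RDAResult(site_scores=site, species_scores=species,
                     biplot_scores=biplot, axis_variance=axis_var,
                     total_variance_explained=float(axis_var.sum()))


# ---------------------------------------------------------------------------
# correlation screen


def chemistry_by_sample(sample_meta: pd.DataFrame,
                        chemistry: pd.DataFrame) -> pd.DataFrame:
    """Per-sample NDF/ADF/ADL, joined on (substrate, time point)."""
    merged = sample_meta.merge(chemistry, on=["substrate", "time_h"],
                               how="left")
    return merged.set_index("sample_id")[["ndf", "adf", "adl"]]


def correlation_screen(abundance: pd.DataFrame, sample_chem: pd.DataFrame,
                       r_min: float = 0.38, p_max: float = 0.01
                       ) -> pd.DataFrame:
    """Pearson correlation of each taxon with each fiber variable.

    Significant iff |r| > `r_min` AND p < `p_max` (two-sided).
    """
    samples = [s for s in abundance.columns if s in sample_chem.index]
    if len(samples) < 3:
        raise MagforgeError("correlation screen needs >= 3 paired samples")
    rows = []
    chem = sample_chem.loc[samples]
    for taxon, vec in abundance[samples].iterrows():
        for var in chem.columns:
            r, p = stats.pearsonr(vec.to_numpy(float),
                                  chem[var].to_numpy(float))
            rows.append((taxon, var.upper(), r, p,
                         abs(r) > r_min and p < p_max))
    return pd.DataFrame(rows, columns=["taxon", "variable", "r", "p",
                                       "significant"])


# ---------------------------------------------------------------------------
# ANCOM


def ancom(counts: pd.DataFrame, groups, alpha: float = 0.05,
          cutoff: float = 0.7, pseudocount: float = 1.0,
          seed: int = 0) -> AncomResult:
    """Compositionally aware differential abundance via pairwise log-ratios.

    For each taxon i, ``W_i`` counts the other taxa j for which a rank test
    on log((x_i + pc) / (x_j + pc)) across groups rejects at `alpha`
    (Mann-Whitney for 2 groups, Kruskal-Wallis otherwise); taxon i is
    detected when ``W_i >= cutoff * (m - 1)``.  ``detected_bonferroni``
    repeats the call with the per-ratio alpha divided by the number of taxa.
    """
    m = counts.shape[0]
    if m < 3:
        raise MagforgeError("ANCOM needs >= 3 taxa")
    labels = np.asarray(pd.Series(groups).loc[counts.columns])
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise MagforgeError("ANCOM needs >= 2 groups")
    logx = np.log(counts.to_numpy(float) + pseudocount)
    ii, jj = np.triu_indices(m, 1)
    ratios = logx[ii] - logx[jj]  # pairs x samples
    masks = [labels == g for g in uniq]
    if len(uniq) == 2:
        _, p = stats.mannwhitneyu(ratios[:, masks[0]], ratios[:, masks[1]],
                                  axis=1, alternative="two-sided")
    else:
        p = np.array([stats.kruskal(*(row[mk] for mk in masks)).pvalue
                      for row in ratios])
    w = np.zeros(m, dtype=int)
    w_bonf = np.zeros(m, dtype=int)
    for thresh, acc in ((alpha, w), (alpha / m, w_bonf)):
        rej = p < thresh
        np.add.at(acc, ii[rej], 1)
        np.add.at(acc, jj[rej], 1)
    w_ser = pd.Series(w, index=counts.index, name="W")
    return AncomResult(
        w=w_ser,
        detected=w_ser >= cutoff * (m - 1),
        detected_bonferroni=pd.Series(w_bonf, index=counts.index)
        >= cutoff * (m - 1),
        cutoff=cutoff, n_taxa=m)


# ---------------------------------------------------------------------------
# heatmap ordering


@dataclass
class HeatmapOrder:
    row_order: list
    col_order: list
    row_linkage: np.ndarray
    col_linkage: np.ndarray = field(default=None)


def _spearman_distance(mat: np.ndarray, labels) -> np.ndarray:
    if mat.shape[0] < 2:
        raise MagforgeError("heatmap ordering needs >= 2 rows")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = stats.spearmanr(mat, axis=1).statistic
    if mat.shape[0] == 2:  # scipy returns a scalar for two rows
        rho = np.array([[1.0, rho], [rho, 1.0]])
    d = 1.0 - rho
    d = np.nan_to_num(d, nan=1.0)
    const = np.array([np.ptp(row) == 0 for row in mat])
    if const.any():
        warnings.warn(f"constant rows set to distance 1: "
                      f"{[l for l, c in zip(labels, const) if c]}")
        d[const, :] = 1.0
        d[:, const] = 1.0
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2


def heatmap_order(matrix: pd.DataFrame, cluster_columns: bool = True
                  ) -> HeatmapOrder:
    """Average-linkage ordering on 1 - Spearman rho (range [0, 2]).

    Rows are pre-sorted by label so scipy's deterministic agglomeration
    breaks ties by label.
    """
    matrix = matrix.sort_index()
    d = _spearman_distance(matrix.to_numpy(float), list(matrix.index))
    row_link = linkage(squareform(d, checks=False), method="average")
    row_order = [matrix.index[i] for i in leaves_list(row_link)]
    col_link, col_order = None, list(matrix.columns)
    if cluster_columns and matrix.shape[1] >= 2:
        mt = matrix.T.sort_index()
        dc = _spearman_distance(mt.to_numpy(float), list(mt.index))
        col_link = linkage(squareform(dc, checks=False), method="average")
        col_order = [mt.index[i] for i in leaves_list(col_link)]
    return HeatmapOrder(row_order=row_order, col_order=col_order,
                        row_linkage=row_link, col_linkage=col_link)
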