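"""CAZyme domain-table analytics.

Raw dbCAN-style domain hits are filtered at the e-value/coverage gates
(defaults 1e-15 and 35% query coverage), de-overlapped within each protein,
and summarized into class compositions, per-megabase densities, modular
domain architectures (including cohesin-repeat scaffoldin candidates),
secretory fractions, BGC family tabulations and TPM-based differential
feature tests.

Because it is ambiguous whether class percentages should count CAZyme
*domains* or CAZyme-bearing *genes*, :func:`summarize_cazymes` reports both,
explicitly labelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bundle_io import CAZY_CLASSES
from .errors import MagforgeError

DEFAULT_EVALUE_MAX = 1e-15
DEFAULT_COVERAGE_MIN = 0.35


# ---------------------------------------------------------------------------
# hit filtering


def filter_domain_hits(hits: pd.DataFrame,
                       evalue_max: float = DEFAULT_EVALUE_MAX,
                       coverage_min: float = DEFAULT_COVERAGE_MIN
                       ) -> pd.DataFrame:
    """Gate hits on e-value and query coverage, then resolve overlaps.

    Within each protein, hits overlapping a better (lower e-value; ties ->
    longer) retained hit by more than 50% of the shorter domain are dropped.
    Idempotent: filtering a filtered table is a no-op.
    """
    hits = hits.reset_index(drop=True)
    kept = hits[(hits["evalue"] <= evalue_max)
                & (hits["query_coverage"] >= coverage_min)].copy()
    if not len(kept):
        return kept.reset_index(drop=True)
    kept["_len"] = kept["qend"] - kept["qstart"] + 1
    out_idx = []
    for _, sub in kept.groupby("gene_id", sort=False):
        order = sub.sort_values(["evalue", "_len", "qstart"],
                                ascending=[True, False, True])
        retained: list[tuple[int, int]] = []
        for idx, row in order.iterrows():
            ok = True
            for qs, qe in retained:
                ov = min(qe, row.qend) - max(qs, row.qstart) + 1
                shorter = min(qe - qs + 1, row.qend - row.qstart + 1)
                if ov > 0.5 * shorter:
                    ok = False
                    break
            if ok:
                retained.append((row.qstart, row.qend))
                out_idx.append(idx)
    out = kept.loc[sorted(out_idx)].drop(columns="_len")
    return out.sort_values(["gene_id", "qstart", "family"]).reset_index(
        drop=True)


# ---------------------------------------------------------------------------
# summaries


@dataclass
class CAZymeSummary:
    per_genome: pd.DataFrame        # counts + densities per class per genome
    class_fractions: pd.DataFrame   # domain-level and gene-level fractions
    per_group: pd.DataFrame         # mean densities per taxon group


def summarize_cazymes(filtered: pd.DataFrame, genome_sizes: pd.Series,
                      gene_to_genome: pd.Series,
                      grouping: dict | pd.Series | None = None
                      ) -> CAZymeSummary:
    """Class counts, per-Mb densities, and class fractions.

    ``density(class, genome) = count / (size_bp / 1e6)``; group densities
    are unweighted means over member genomes.
    """
    if (genome_sizes <= 0).any():
        raise MagforgeError("zero-size genome in CAZyme summary")
    df = filtered.copy()
    df["genome_id"] = df["gene_id"].map(gene_to_genome)

    counts = (df.groupby(["genome_id", "clazz"]).size()
              .unstack(fill_value=0)
              .reindex(index=genome_sizes.index, fill_value=0)
              .reindex(columns=list(CAZY_CLASSES), fill_value=0))
    mb = genome_sizes / 1e6
    densities = counts.div(mb, axis=0)
    per_genome = pd.concat(
        {"count": counts, "per_mb": densities}, axis=1)

    dom_counts = df["clazz"].value_counts().reindex(CAZY_CLASSES, fill_value=0)
    gene_cls = df.groupby("gene_id")["clazz"].first()
    gene_counts = gene_cls.value_counts().reindex(CAZY_CLASSES, fill_value=0)
    frac = pd.DataFrame({
        "domain_count": dom_counts,
        "domain_fraction": dom_counts / max(dom_counts.sum(), 1),
        "gene_count": gene_counts,
        "gene_fraction": gene_counts / max(gene_counts.sum(), 1),
    })
    frac.index.name = "clazz"

    if grouping is not None:
        gser = pd.Series(grouping)
        per_group = densities.groupby(
            densities.index.map(gser)).mean()
        per_group.index.name = "group"
    else:
        per_group = pd.DataFrame(columns=list(CAZY_CLASSES))
    return CAZymeSummary(per_genome=per_genome, class_fractions=frac,
                         per_group=per_group)


# ---------------------------------------------------------------------------
# modular architectures


@dataclass
class ArchitectureReport:
    architectures: dict[str, list[str]]   # gene -> ordered families
    multidomain_genes: list[str]
    cooccurrence: pd.DataFrame  # family_a, family_b, n_proteins, appended_fraction
    scaffoldin_candidates: list[str]


def modular_architectures(filtered: pd.DataFrame) -> ArchitectureReport:
    """Multidomain proteins, domain co-occurrence, scaffoldin candidates.

    ``appended_fraction(a -> b)`` = (# proteins containing both a and b) /
    (total domain count of a), the statistic behind claims like "58% of all
    CBM48 domains are appended to GH13_9".  A scaffoldin candidate carries
    >= 2 cohesin domains in tandem.
    """
    arch: dict[str, list[str]] = {}
    for gid, sub in filtered.groupby("gene_id", sort=True):
        arch[gid] = list(sub.sort_values(["qstart", "family"])["family"])
    multi = sorted(g for g, fams in arch.items() if len(fams) >= 2)

    fam_totals = filtered["family"].value_counts()
    pair_counts: dict[tuple[str, str], int] = {}
    for fams in arch.values():
        for a in set(fams):
            for b in set(fams):
                if a != b:
                    pair_counts[(a, b)] = pair_counts.get((a, b), 0) + 1
    rows = [(a, b, n, n / fam_totals[a])
            for (a, b), n in sorted(pair_counts.items())]
    cooc = pd.DataFrame(rows, columns=["family_a", "family_b", "n_proteins",
                                       "appended_fraction"])

    scaffoldins = []
    for g, fams in arch.items():
        run = best = 0
        for f in fams:
            run = run + 1 if f == "cohesin" else 0
            best = max(best, run)
        if best >= 2:
            scaffoldins.append(g)
    return ArchitectureReport(architectures=arch, multidomain_genes=multi,
                              cooccurrence=cooc,
                              scaffoldin_candidates=sorted(scaffoldins))


def secretory_fractions(filtered: pd.DataFrame, signals: pd.DataFrame,
                        gene_to_genome: pd.Series,
                        grouping: dict | pd.Series | None = None
                        ) -> pd.DataFrame:
    """Secretory share of CAZyme-bearing genes per genome (and group).

    A gene is secretory if flagged in either Gram mode; genes without a flag
    row count as non-secretory.
    """
    caz_genes = pd.Index(sorted(set(filtered["gene_id"])))
    flagged = set(signals[signals["secretory"].astype(bool)]["gene_id"])
    df = pd.DataFrame({
        "gene_id": caz_genes,
        "genome_id": caz_genes.map(gene_to_genome),
        "secretory": [g in flagged for g in caz_genes],
    })
    per_genome = df.groupby("genome_id")["secretory"].agg(
        n_cazyme_genes="size", n_secretory="sum", fraction="mean")
    if grouping is not None:
        gser = pd.Series(grouping)
        df["group"] = df["genome_id"].map(gser)
        per_group = df.groupby("group")["secretory"].agg(
            n_cazyme_genes="size", n_secretory="sum", fraction="mean")
        per_genome = pd.concat([per_genome, per_group])
    return per_genome.reset_index(names="unit")


# ---------------------------------------------------------------------------
# TPM + differential features


def tpm_normalize(counts: pd.DataFrame, lengths_bp: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million: length-normalized rates scaled to 1e6."""
    rate = counts.div(lengths_bp.loc[counts.index] / 1000.0, axis=0)
    return rate.div(rate.sum(axis=0), axis=1) * 1e6


def differential_features(counts: pd.DataFrame, lengths_bp: pd.Series,
                          groups: pd.Series, alpha: float = 0.01
                          ) -> pd.DataFrame:
    """Per-feature rank test on TPM with Bonferroni control.

    Two groups use Mann-Whitney U, more use Kruskal-Wallis; this rank-based
    test stands in for a negative-binomial package fit and is recorded in
    the output's ``test`` column.
    """
    groups = pd.Series(groups).loc[counts.columns]
    sizes = groups.value_counts()
    if len(sizes) < 2:
        raise MagforgeError("differential test needs >= 2 groups")
    if (sizes < 2).any():
        small = sorted(sizes[sizes < 2].index)
        raise MagforgeError(f"groups with < 2 samples: {small}")
    tpm = tpm_normalize(counts, lengths_bp)
    labels = sorted(sizes.index)
    arrays = {g: tpm.loc[:, groups[groups == g].index].to_numpy()
              for g in labels}
    if len(labels) == 2:
        test = "mann_whitney_u"
        stat, p = stats.mannwhitneyu(arrays[labels[0]], arrays[labels[1]],
                                     axis=1, alternative="two-sided")
    else:
        test = "kruskal_wallis"
        stat = np.empty(len(tpm))
        p = np.empty(len(tpm))
        for i in range(len(tpm)):
            stat[i], p[i] = stats.kruskal(*(a[i] for a in arrays.values()))
    p_corr = np.minimum(p * len(tpm), 1.0)  # Bonferroni
    out = pd.DataFrame({
        "feature": tpm.index,
        "statistic": stat,
        "p_value": p,
        "p_bonferroni": p_corr,
        "significant": p_corr < alpha,
        "test": test,
    })
    for g in labels:
        out[f"tpm_mean_{g}"] = arrays[g].mean(axis=1)
    return out


def summarize_bgcs(bgc: pd.DataFrame, grouping: dict | pd.Series
                   ) -> tuple[pd.DataFrame, pd.Series]:
    """Family x phylum count table and family frequencies over all BGCs."""
    if bgc is None or not len(bgc):
        empty = pd.DataFrame()
        return empty, pd.Series(dtype=float)
    gser = pd.Series(grouping)
    df = bgc.copy()
    df["group"] = df["genome_id"].map(gser)
    table = (df.groupby(["bgc_family", "group"]).size()
             .unstack(fill_value=0).sort_index())
    freqs = df["bgc_family"].value_counts(normalize=True).sort_index()
    return table, freqs
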