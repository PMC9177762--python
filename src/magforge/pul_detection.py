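"""SusC/SusD-anchored polysaccharide utilization locus (PUL) calling.

Bacteroidota organize glycan catabolism into PULs: a tandem pair of genes
for a TonB-dependent transporter (susC) and a surface glycan-binding
protein (susD), flanked by degradative CAZymes.  This module finds
same-strand susC/susD pairs on a contig, grows each pair into a locus by
walking outward over further sus genes and CAZyme-bearing genes (tolerating
short runs of unannotated genes), merges touching loci, and tests which
CAZyme families are enriched inside PULs versus the genomic background.

susC/susD recognition relies on annotation labels carried by the bundle
(gene symbols ``susC``/``susD`` or the corresponding KOs); upstream HMM
detection is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import MagforgeError

#: fold-change sentinel for families absent from the background
FOLD_CAP = 1e6

SUSC_KOS = {"K21573"}
SUSD_KOS = {"K21572"}


@dataclass(frozen=True)
class SusPair:
    genome_id: str
    contig_id: str
    susc_gene: str
    susd_gene: str
    strand: str
    susc_index: int
    susd_index: int


@dataclass
class PULocus:
    pul_id: str
    genome_id: str
    contig_id: str
    first_index: int
    last_index: int
    member_genes: list[str]   # qualifying genes inside the range
    n_sus_pairs: int
    cazyme_families: list[str]

    @property
    def has_cazyme(self) -> bool:
        return bool(self.cazyme_families)


def sus_roles_from_ko(ko: pd.DataFrame) -> dict[str, str]:
    """gene_id -> 'susC' | 'susD' from symbols or KO ids."""
    roles: dict[str, str] = {}
    for gid, kos, syms in zip(ko["gene_id"], ko["ko_ids"],
                              ko["gene_symbols"]):
        symset = set(str(syms).split(",")) if syms else set()
        koset = set(str(kos).split(",")) if kos else set()
        if "susC" in symset or koset & SUSC_KOS:
            roles[gid] = "susC"
        elif "susD" in symset or koset & SUSD_KOS:
            roles[gid] = "susD"
    return roles


def _contig_orders(genes: pd.DataFrame):
    """Yield (genome, contig, ordered gene DataFrame) per contig."""
    for (gid, cid), sub in genes.groupby(["genome_id", "contig_id"],
                                         sort=True):
        yield gid, cid, sub.sort_values(["start", "gene_id"]).reset_index(
            drop=True)


def find_sus_pairs(genes: pd.DataFrame, roles: dict[str, str],
                   max_intervening: int = 1) -> list[SusPair]:
    """Greedy left-to-right pairing of susC with a nearby susD.

    A pair requires the same contig and strand and at most `max_intervening`
    genes between the two; each gene joins at most one pair.
    """
    pairs: list[SusPair] = []
    for gid, cid, sub in _contig_orders(genes):
        used: set[int] = set()
        n = len(sub)
        for i in range(n):
            role_i = roles.get(sub.loc[i, "gene_id"])
            if role_i is None or i in used:
                continue
            for j in range(i + 1, min(n, i + 2 + max_intervening)):
                if j in used:
                    continue
                role_j = roles.get(sub.loc[j, "gene_id"])
                if role_j is None or role_j == role_i:
                    continue
                if sub.loc[i, "strand"] != sub.loc[j, "strand"]:
                    continue
                ci, di = (i, j) if role_i == "susC" else (j, i)
                pairs.append(SusPair(
                    genome_id=gid, contig_id=cid,
                    susc_gene=sub.loc[ci, "gene_id"],
                    susd_gene=sub.loc[di, "gene_id"],
                    strand=sub.loc[i, "strand"],
                    susc_index=ci, susd_index=di))
                used.update((i, j))
                break
    return pairs


def call_puls(pairs: list[SusPair], filtered_hits: pd.DataFrame,
              genes: pd.DataFrame, roles: dict[str, str] | None = None,
              max_gap: int = 2) -> list[PULocus]:
    """Grow each sus pair into a locus and merge touching loci.

    Extension walks outward gene-by-gene while the next gene is
    susC/susD/CAZyme-bearing, tolerating up to `max_gap` consecutive
    unannotated genes before another qualifying gene.  Loci whose extended
    index ranges overlap or touch are merged; ``has_cazyme`` reflects the
    extended locus itself ("vicinity" = the locus).
    """
    roles = roles or {}
    caz_families = (filtered_hits.groupby("gene_id")["family"]
                    .apply(list).to_dict())
    by_contig: dict[tuple[str, str], list[SusPair]] = {}
    for p in pairs:
        by_contig.setdefault((p.genome_id, p.contig_id), []).append(p)

    loci: list[PULocus] = []
    counter = 0
    for gid, cid, sub in _contig_orders(genes):
        contig_pairs = by_contig.get((gid, cid))
        if not contig_pairs:
            continue
        gene_ids = list(sub["gene_id"])
        qualifying = [g in caz_families or roles.get(g) in ("susC", "susD")
                      for g in gene_ids]
        spans = []
        for p in contig_pairs:
            lo = min(p.susc_index, p.susd_index)
            hi = max(p.susc_index, p.susd_index)
            # extend right
            gap, j = 0, hi + 1
            while j < len(gene_ids) and gap < max_gap + 1:
                if qualifying[j]:
                    hi, gap = j, 0
                else:
                    gap += 1
                j += 1
            # extend left
            gap, j = 0, lo - 1
            while j >= 0 and gap < max_gap + 1:
                if qualifying[j]:
                    lo, gap = j, 0
                else:
                    gap += 1
                j -= 1
            spans.append([lo, hi, 1])
        spans.sort()
        merged = [spans[0]]
        for lo, hi, ns in spans[1:]:
            if lo <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], hi)
                merged[-1][2] += ns
            else:
                merged.append([lo, hi, ns])
        for lo, hi, ns in merged:
            members = [gene_ids[k] for k in range(lo, hi + 1)
                       if qualifying[k]]
            fams = sorted(f for g in members
                          for f in caz_families.get(g, []))
            counter += 1
            loci.append(PULocus(
                pul_id=f"PUL{counter:04d}", genome_id=gid, contig_id=cid,
                first_index=lo, last_index=hi, member_genes=members,
                n_sus_pairs=ns, cazyme_families=fams))
    return loci


def puls_to_frame(loci: list[PULocus]) -> pd.DataFrame:
    return pd.DataFrame([{
        "pul_id": p.pul_id, "genome_id": p.genome_id,
        "contig_id": p.contig_id, "first_index": p.first_index,
        "last_index": p.last_index, "n_genes": len(p.member_genes),
        "n_sus_pairs": p.n_sus_pairs,
        "members": ",".join(p.member_genes),
        "cazyme_families": ",".join(p.cazyme_families),
        "has_cazyme": p.has_cazyme,
    } for p in loci])


def pul_family_enrichment(loci: list[PULocus],
                          filtered_hits: pd.DataFrame) -> pd.DataFrame:
    """Fisher-exact enrichment of each CAZyme family inside PULs.

    Each family's in-PUL domain count is tested against the rest of the
    genome-wide filtered domain table in a 2x2 Fisher exact test with
    Benjamini-Hochberg correction.  Families absent from the background get
    the capped fold sentinel ``FOLD_CAP``.
    """
    if not loci:
        raise MagforgeError("no PULs supplied to enrichment test")
    pul_genes = {g for p in loci for g in p.member_genes}
    in_pul = filtered_hits["gene_id"].isin(pul_genes)
    fam = filtered_hits["family"]
    in_counts = fam[in_pul].value_counts()
    out_counts = fam[~in_pul].value_counts()
    n_in, n_out = int(in_counts.sum()), int(out_counts.sum())
    rows = []
    for family in sorted(set(fam)):
        a = int(in_counts.get(family, 0))
        c = int(out_counts.get(family, 0))
        table = [[a, n_in - a], [c, n_out - c]]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        if n_in == 0 or a == 0:
            fold = 0.0
        elif c == 0:
            fold = FOLD_CAP
        else:
            fold = (a / n_in) / (c / n_out)
        rows.append((family, a, c, fold, p))
    out = pd.DataFrame(rows, columns=["family", "in_pul", "background",
                                      "fold", "p_value"])
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out
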