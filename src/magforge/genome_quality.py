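"""Genome summary statistics, quality tiering, ANI/AF estimation and
quality-aware dereplication.

Quality tiers follow MIMAG-style thresholds: genomes below 75% completeness
or above 10% contamination fail outright; >=90% completeness with <=5%
contamination plus at least 18 tRNAs reaches ``near_high``; a full
5S/16S/23S rRNA complement upgrades that to ``high``.

The ANI estimator is a deliberately simplified fragment-mapping analogue of
FastANI: the smaller genome is cut into non-overlapping windows (default
2000 bp), each window is placed on the subject by k-mer seed voting on
diagonals and scored gap-free at the best diagonal (with a banded-alignment
fallback when the gap-free identity is poor, i.e. when indels shifted the
frame).  ANI is the mean identity of mapped windows; AF is the mapped
fraction of the smaller genome, maximized over subject orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import MagforgeError

# ---------------------------------------------------------------------------
# summary statistics


@dataclass(frozen=True)
class GenomeStats:
    genome_id: str
    size_bp: int
    n50_bp: int
    n_contigs: int
    longest_bp: int
    shortest_bp: int


def genome_stats(contig_lengths, genome_id: str = "") -> GenomeStats:
    """Assembly statistics; N50 is the smallest length L such that contigs
    of length >= L sum to at least half the assembly."""
    lengths = sorted(int(x) for x in contig_lengths)
    if not lengths:
        raise MagforgeError("genome has no contigs")
    if lengths[0] < 1:
        raise MagforgeError("contig lengths must be >= 1")
    total = sum(lengths)
    acc = 0
    n50 = lengths[-1]
    for ln in reversed(lengths):
        acc += ln
        if acc * 2 >= total:
            n50 = ln
            break
    return GenomeStats(genome_id=genome_id, size_bp=total, n50_bp=n50,
                       n_contigs=len(lengths), longest_bp=lengths[-1],
                       shortest_bp=lengths[0])


# ---------------------------------------------------------------------------
# quality tiering


@dataclass(frozen=True)
class QualityTier:
    tier: str  # fail | medium | near_high | high
    reasons: tuple


FULL_RRNA = frozenset({"5S", "16S", "23S"})


def quality_tier(completeness: float, contamination: float, rrnas,
                 trna_count: int) -> QualityTier:
    """Tier one genome; `reasons` records every threshold crossed/missed."""
    rrnas = frozenset(rrnas)
    reasons = []
    if completeness < 75:
        reasons.append(f"completeness {completeness:g} < 75")
    if contamination > 10:
        reasons.append(f"contamination {contamination:g} > 10")
    if reasons:
        return QualityTier("fail", tuple(reasons))
    if completeness < 90:
        reasons.append(f"completeness {completeness:g} < 90")
    if contamination > 5:
        reasons.append(f"contamination {contamination:g} > 5")
    if trna_count < 18:
        reasons.append(f"tRNA count {trna_count} < 18")
    if reasons:
        return QualityTier("medium", tuple(reasons))
    if rrnas != FULL_RRNA:
        missing = sorted(FULL_RRNA - rrnas)
        return QualityTier("near_high",
                           (f"incomplete rRNA set, missing {missing}",))
    return QualityTier("high", ("completeness >= 90", "contamination <= 5",
                                ">= 18 tRNAs", "full rRNA complement"))


def tier_bundle(metadata: pd.DataFrame) -> pd.DataFrame:
    """Quality tier for every genome of a bundle metadata table."""
    rows = []
    for r in metadata.itertuples(index=False):
        rrnas = set(str(r.rrnas).split(",")) - {""}
        qt = quality_tier(r.completeness, r.contamination, rrnas,
                          r.trna_count)
        rows.append((r.genome_id, qt.tier, "; ".join(qt.reasons)))
    return pd.DataFrame(rows, columns=["genome_id", "tier", "reasons"])


# ---------------------------------------------------------------------------
# ANI / AF estimation

_COMP = bytes.maketrans(b"ACGT", b"TGCA")


def _revcomp(seq: str) -> str:
    return seq.encode().translate(_COMP)[::-1].decode()


@dataclass(frozen=True)
class ANIRecord:
    genome_a: str
    genome_b: str
    ani: float  # percent
    af: float   # aligned fraction of the smaller genome


def _kmer_index(seq: np.ndarray, k: int, max_pos: int = 8) -> dict:
    index: dict = {}
    view = seq.tobytes()
    for i in range(len(view) - k + 1):
        km = view[i:i + k]
        lst = index.get(km)
        if lst is None:
            index[km] = [i]
        elif len(lst) < max_pos:
            lst.append(i)
    return index


def _banded_identity(q: np.ndarray, s: np.ndarray, band: int = 8) -> float:
    """Approximate alignment identity allowing small indels.

    Match-count DP over a +-band diagonal corridor with a 0.5 match penalty
    per gap column; returns matched fraction of the query length.
    """
    n, m = len(q), len(s)
    prev = np.full(2 * band + 1, -np.inf)
    prev[band] = 0.0
    for i in range(n):
        cur = np.full(2 * band + 1, -np.inf)
        j0 = i - band
        js = np.arange(j0, i + band + 1)
        valid = (js >= 0) & (js < m)
        eq = np.zeros(2 * band + 1)
        eq[valid] = (s[js[valid]] == q[i]).astype(float)
        diag = prev + eq
        up = np.full_like(prev, -np.inf)      # gap in subject
        up[:-1] = prev[1:] - 0.5
        cur = np.maximum(diag, up)
        left = np.full_like(cur, -np.inf)     # gap in query
        left[1:] = cur[:-1] - 0.5
        cur = np.maximum(cur, left)
        cur[~valid] = -np.inf
        prev = cur
    best = prev.max()
    return max(0.0, min(1.0, best / n))


def _map_fragments(query: np.ndarray, index: dict, subject: np.ndarray,
                   frag_len: int, k: int, min_votes: int,
                   min_identity: float) -> list[float]:
    identities = []
    n_frags = len(query) // frag_len
    stride = 40
    for f in range(n_frags):
        frag = query[f * frag_len:(f + 1) * frag_len]
        frag_bytes = frag.tobytes()
        votes: dict[int, int] = {}
        for off in range(0, frag_len - k + 1, stride):
            for pos in index.get(frag_bytes[off:off + k], ()):
                d = pos - off
                votes[d] = votes.get(d, 0) + 1
        if not votes:
            continue
        best = 0.0
        for d, v in sorted(votes.items(), key=lambda kv: -kv[1])[:3]:
            if v < min_votes:
                continue
            lo = max(0, -d)
            hi = min(frag_len, len(subject) - d)
            if hi - lo < frag_len // 2:
                continue
            ident = float(np.mean(frag[lo:hi] == subject[d + lo:d + hi])) \
                * (hi - lo) / frag_len
            if ident < 0.75:  # possible indel shift: banded fallback
                s_lo = max(0, d - 16)
                s_hi = min(len(subject), d + frag_len + 16)
                ident = max(ident, _banded_identity(
                    frag, subject[s_lo:s_hi], band=16))
            best = max(best, ident)
        if best >= min_identity:
            identities.append(best)
    return identities


def estimate_ani(genome_a, genome_b, frag_len: int = 2000, k: int = 16,
                 min_votes: int = 2, min_identity: float = 0.5,
                 ids: tuple[str, str] = ("a", "b")) -> ANIRecord:
    """Fragment-mapping ANI/AF between two contig sets (sequence strings)."""
    if not genome_a or not genome_b:
        raise MagforgeError("empty genome in ANI estimation")
    seq_a = "".join(genome_a)
    seq_b = "".join(genome_b)
    if len(seq_a) <= len(seq_b):
        q_seq, s_seq = seq_a, seq_b
    else:
        q_seq, s_seq = seq_b, seq_a
    query = np.frombuffer(q_seq.encode(), dtype=np.uint8)
    n_frags = len(query) // frag_len
    if n_frags == 0:
        return ANIRecord(ids[0], ids[1], 0.0, 0.0)
    best_ani, best_af = 0.0, 0.0
    for orient_seq in (s_seq, _revcomp(s_seq)):
        subject = np.frombuffer(orient_seq.encode(), dtype=np.uint8)
        index = _kmer_index(subject, k)
        idents = _map_fragments(query, index, subject, frag_len, k,
                                min_votes, min_identity)
        af = len(idents) / n_frags
        if af > best_af:
            best_af = af
            best_ani = 100.0 * float(np.mean(idents)) if idents else 0.0
    return ANIRecord(ids[0], ids[1], best_ani, best_af)


# ---------------------------------------------------------------------------
# dereplication


@dataclass
class DereplicationResult:
    stage: str  # strain_99 | species_90
    clusters: list[list[str]]          # each sorted, representative first
    representatives: dict[str, str] = field(default_factory=dict)

    def cluster_of(self) -> dict[str, str]:
        """genome_id -> representative id."""
        return {g: c[0] for c in self.clusters for g in c}


def _single_linkage(nodes: list[str], edges) -> list[set[str]]:
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups: dict[str, set] = {}
    for n in nodes:
        groups.setdefault(find(n), set()).add(n)
    return list(groups.values())


def _pick_representative(members: set[str], score: dict[str, tuple]) -> str:
    # score = (completeness - 5*contamination, size_bp); ties -> lexicographic
    return min(members, key=lambda g: (-score[g][0], -score[g][1], g))


def dereplicate(metadata: pd.DataFrame, ani_records,
                stage_thresholds: tuple[float, float] = (99.0, 90.0),
                af_min: float = 0.65) -> dict[str, DereplicationResult]:
    """Two-stage single-linkage dereplication (strain 99%, species 90% ANI).

    `metadata` needs columns genome_id, completeness, contamination and
    size_bp.  `ani_records` is an iterable of :class:`ANIRecord` or a
    DataFrame with genome_a/genome_b/ani/af; an absent pair counts as below
    threshold.  The representative of a cluster maximizes
    ``completeness - 5 x contamination`` (ties: larger genome, then id);
    the species stage clusters only the strain-stage representatives.
    """
    for thr in stage_thresholds:
        if not 0 < thr <= 100:
            raise MagforgeError(f"ANI threshold {thr} outside (0, 100]")
    if isinstance(ani_records, pd.DataFrame):
        recs = [ANIRecord(r.genome_a, r.genome_b, float(r.ani), float(r.af))
                for r in ani_records.itertuples(index=False)]
    else:
        recs = list(ani_records)
    score = {r.genome_id: (r.completeness - 5 * r.contamination,
                           int(getattr(r, "size_bp", 0)))
             for r in metadata.itertuples(index=False)}
    nodes = sorted(score)
    stage_names = ("strain_99", "species_90")
    results: dict[str, DereplicationResult] = {}
    active = nodes
    for name, thr in zip(stage_names, stage_thresholds):
        active_set = set(active)
        edges = [(r.genome_a, r.genome_b) for r in recs
                 if r.ani >= thr and r.af >= af_min
                 and r.genome_a in active_set and r.genome_b in active_set]
        groups = _single_linkage(active, edges)
        clusters = []
        for members in groups:
            rep = _pick_representative(members, score)
            clusters.append([rep] + sorted(members - {rep}))
        clusters.sort(key=lambda c: c[0])
        results[name] = DereplicationResult(
            stage=name, clusters=clusters,
            representatives={c[0]: c[0] for c in clusters})
        active = sorted(c[0] for c in clusters)
    return results


def reference_overlap(cross_records, ani_min: float = 95.0,
                      af_min: float = 0.65) -> tuple[int, list[tuple]]:
    """Genomes sharing species-level identity with an external genome set.

    `cross_records` carry (query genome, external genome, ani, af); returns
    the number of distinct query genomes with at least one partner passing
    both gates, plus the deterministic qualifying pair list.
    """
    if isinstance(cross_records, pd.DataFrame):
        it = [ANIRecord(r.genome_a, r.genome_b, float(r.ani), float(r.af))
              for r in cross_records.itertuples(index=False)]
    else:
        it = list(cross_records)
    pairs = sorted((r.genome_a, r.genome_b, r.ani, r.af) for r in it
                   if r.ani > ani_min and r.af >= af_min)
    return len({p[0] for p in pairs}), pairs
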