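"""Synthetic annotation-bundle generator with planted, machine-readable truth.

The generator emulates a fiber-incubation study of rumen microbiota: a
community of genomes from a configurable phylum mixture is annotated with
marker genes that realize a planted :class:`CapabilityProfile` per genome,
SusC/SusD-anchored polysaccharide utilization loci on Bacteroidota-like
genomes, multidomain CAZymes and cohesin-repeat scaffoldins, secretory
flags, and a genome-by-sample abundance matrix over a substrates x
time-points x replicates design with log-normal noise, planted differential
taxa and taxa whose abundance tracks forage NDF content.

Genomes are then *degraded* to a target completeness by uniform gene
dropout (a CheckM-style proxy) and contaminated by duplicating retained
genes, so quality tiering and recall-vs-completeness behaviour can be
tested against known truth.  Everything derives from a single integer seed;
two runs with the same design are byte-identical after writing.

Deliberate non-realism: no nucleotide-level sequences are emitted for the
annotation tables (contig *lengths* only), gene dropout is independent and
uniform rather than spatially clustered, and abundance noise is a plain
log-normal without replicate (animal) random effects.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from . import metabolic_inference as mi
from .bundle_io import AnnotationBundle, validate_bundle
from .errors import DesignError

#: the study's 11 lignocellulosic substrate codes
DEFAULT_SUBSTRATES = ("WS", "CS", "RS", "CR", "KS", "DP", "SG", "SC", "AP",
                      "SS", "SB")
DEFAULT_TIME_POINTS = (24, 48, 72, 96)

DEFAULT_PHYLA = {
    "Bacteroidota": 0.30,
    "Firmicutes_A": 0.30,
    "Verrucomicrobiota": 0.10,
    "Spirochaetota": 0.10,
    "Fibrobacterota": 0.10,
    "Patescibacteria": 0.10,
}

#: CAZyme families never matching any polymer rule — safe background noise
_BACKGROUND_FAMILIES = ("GH2", "GH3", "GH20", "GH25", "GH29", "GH32", "GH36",
                        "GH38", "GH43", "GH127", "GT2", "GT4", "GT35", "CE6",
                        "CBM6", "CBM13", "CBM50")
_BACKGROUND_SYMBOLS = ("dnaA", "gyrA", "recA", "rpoB", "ftsZ", "secY")
_BGC_FAMILIES = ("NRPS", "sactipeptide", "arylpolyene", "bacteriocin",
                 "betalactone", "terpene", "lassopeptide", "proteusin",
                 "lanthipeptide")
_BGC_WEIGHTS = (0.44, 0.15, 0.15, 0.10, 0.08, 0.04, 0.02, 0.01, 0.01)

#: (GH13_9, CBM48)-style appended-domain pairs used for multidomain planting
_MODULAR_PAIRS = (("GH13_9", "CBM48"), ("GH78", "CBM67"), ("GH9", "CBM4"))


@dataclass
class CommunityDesign:
    """Stated world of one synthetic study."""

    n_genomes: int = 30
    phylum_mixture: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PHYLA))
    substrates: tuple = DEFAULT_SUBSTRATES
    time_points: tuple = DEFAULT_TIME_POINTS
    replicates: int = 2  # two fistulated animals
    n_genes: int = 400
    completeness_range: tuple[float, float] = (75.0, 100.0)
    contamination_range: tuple[float, float] = (0.0, 8.0)
    #: genome_id -> (substrate code, fold change) planted enrichment
    differential_taxa: dict[str, tuple[str, float]] = field(default_factory=dict)
    #: genome_id -> +1 / -1 target sign of Pearson r with NDF
    chemistry_correlated_taxa: dict[str, int] = field(default_factory=dict)
    abundance_sigma: float = 0.5
    detection_floor: float = 0.01
    secretory_fraction: float = 0.23
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.phylum_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise DesignError(f"phylum mixture sums to {total}, not 1")
        lo, hi = self.completeness_range
        if not (50 <= lo <= hi <= 100):
            raise DesignError("completeness range must lie within [50, 100]")
        lo, hi = self.contamination_range
        if not (0 <= lo <= hi <= 25):
            raise DesignError("contamination range must lie within [0, 25]")
        for g, (sub, fold) in self.differential_taxa.items():
            if fold <= 0:
                raise DesignError(f"effect size for {g} must be > 0")
            if sub not in self.substrates:
                raise DesignError(f"unknown substrate {sub!r} for {g}")
        if self.differential_taxa and len(self.substrates) < 2:
            raise DesignError(
                "differential taxa require at least 2 substrates")


@dataclass
class PlantedPUL:
    genome_id: str
    contig_id: str
    first_index: int  # gene index within contig, 0-based
    last_index: int
    gene_ids: list[str]
    has_cazyme: bool


@dataclass
class SyntheticTruth:
    """Everything the generator planted, keyed by generated ids."""

    profiles: dict[str, mi.CapabilityProfile]
    puls: list[PlantedPUL]
    multidomain_genes: set[str]
    scaffoldin_genes: set[str]
    secretory_genes: set[str]
    differential_taxa: dict[str, tuple[str, float]]
    chemistry_correlated_taxa: dict[str, int]
    realized_completeness: dict[str, float]
    intended_genes: dict[str, list[str]]
    retained_genes: dict[str, list[str]]

    def to_json(self) -> str:
        payload = {
            "profiles": {
                g: {"sugars": p.sugars, "fermentation": p.fermentation,
                    "polymers": p.polymers,
                    "pathways": {k: list(v) for k, v in p.pathways.items()},
                    "trophic": p.trophic, "flags": p.flags}
                for g, p in self.profiles.items()},
            "puls": [vars(p) for p in self.puls],
            "multidomain_genes": sorted(self.multidomain_genes),
            "scaffoldin_genes": sorted(self.scaffoldin_genes),
            "secretory_genes": sorted(self.secretory_genes),
            "differential_taxa": self.differential_taxa,
            "chemistry_correlated_taxa": self.chemistry_correlated_taxa,
            "realized_completeness": self.realized_completeness,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# nucleotide helpers (used by the ANI estimator tests/acceptance)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_genome_sequence(length: int, rng: np.random.Generator) -> str:
    """Uniform random nucleotide sequence of `length` bp."""
    return rng.choice(_BASES, size=length).tobytes().decode()


def mutate_sequence(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Apply uniform substitutions at `rate`; every pick changes the base."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    pos = np.nonzero(rng.random(arr.size) < rate)[0]
    if pos.size:
        offsets = rng.integers(1, 4, size=pos.size)
        idx = np.searchsorted(_BASES, arr[pos])
        arr[pos] = _BASES[(idx + offsets) % 4]
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# genome generation


def _plant_profile(genome_id: str, phylum: str, rng) -> mi.CapabilityProfile:
    degradey = phylum in ("Bacteroidota", "Fibrobacterota", "Spirochaetota",
                          "Verrucomicrobiota")
    if phylum == "Patescibacteria":
        sugars = {s: False for s in mi.SUGARS}
        ferm = {p: False for p in mi.FERMENTATION_PRODUCTS}
        ferm["lactate"] = bool(rng.random() < 0.5)
        polymers = {p: False for p in mi.POLYMERS}
        pathways = {"glycolysis": False, "PPP": False,
                    "TCA": bool(rng.random() < 0.3)}
    else:
        sugars = {s: bool(rng.random() < 0.5) for s in mi.SUGARS}
        ferm = {p: bool(rng.random() < 0.4) for p in mi.FERMENTATION_PRODUCTS}
        ferm["methanogenesis"] = bool(rng.random() < 0.05)
        p_poly = 0.45 if degradey else 0.15
        polymers = {p: bool(rng.random() < p_poly) for p in mi.POLYMERS}
        pathways = {pw: bool(rng.random() < 0.7) for pw in mi.PATHWAYS}
    profile = mi.CapabilityProfile(
        genome_id=genome_id, sugars=sugars, fermentation=ferm,
        pathways={pw: (v, 1.0 if v else 0.0) for pw, v in pathways.items()},
        polymers=polymers)
    return mi.assign_trophic(profile)


def _marker_payloads(profile: mi.CapabilityProfile, rules: mi.MarkerRuleSet,
                     rng) -> list[dict]:
    """One payload dict (kos / symbols / family) per marker gene to plant."""
    payloads = []
    for sugar, present in profile.sugars.items():
        if present:
            payloads.append({"kos": [rules.sugar_markers[sugar]]})
    for product, present in profile.fermentation.items():
        if not present:
            continue
        groups = rules.fermentation_rules[product]
        group = groups[rng.integers(len(groups))]
        payloads.extend({"symbols": [sym]} for sym in group)
    for pw, (present, _) in profile.pathways.items():
        markers = rules.pathway_markers[pw]
        if present:
            chosen = markers
        else:
            # stay strictly below the presence threshold
            k_max = int(np.ceil(rules.pathway_threshold * len(markers))) - 1
            k = int(rng.integers(0, max(k_max, 0) + 1))
            chosen = list(rng.choice(markers, size=k, replace=False))
        payloads.extend({"kos": [m]} for m in chosen)
    for polymer, present in profile.polymers.items():
        if present:
            fams = rules.polymer_families[polymer]
            for fam in rng.choice(fams, size=int(rng.integers(1, 3)),
                                  replace=False):
                payloads.append({"family": fam})
    return payloads


def generate_genomes(design: CommunityDesign,
                     rules: mi.MarkerRuleSet | None = None
                     ) -> tuple[AnnotationBundle, SyntheticTruth]:
    """Generate gene tables, annotations and metadata with planted truth.

    Marker genes realizing each planted capability are placed first, PUL
    blocks are reserved on Bacteroidota-like genomes, background noise is
    drawn only from families/KOs that can never satisfy a rule, and finally
    each genome is degraded to its drawn completeness and contaminated by
    duplicating retained genes.
    """
    design.validate()
    rules = rules or mi.MarkerRuleSet()
    rng = np.random.default_rng(design.seed)

    phyla = sorted(design.phylum_mixture)
    probs = np.array([design.phylum_mixture[p] for p in phyla])

    genes_rows, ko_rows, dom_rows, sig_rows = [], [], [], []
    meta_rows, clen_rows, bgc_rows = [], [], []
    profiles, puls = {}, []
    multidomain, scaffoldins, secretory = set(), set(), set()
    realized_comp, intended, retained = {}, {}, {}

    for gi in range(design.n_genomes):
        gid = f"G{gi + 1:03d}"
        phylum = phyla[rng.choice(len(phyla), p=probs)]
        profile = _plant_profile(gid, phylum, rng)
        profiles[gid] = profile

        completeness = float(rng.uniform(*design.completeness_range))
        contamination = float(rng.uniform(*design.contamination_range))

        n_genes = design.n_genes
        n_contigs = max(4, n_genes // 25)
        # genes per contig, at least 1 each
        alloc = rng.multinomial(n_genes - n_contigs,
                                np.full(n_contigs, 1 / n_contigs)) + 1
        contig_ids = [f"{gid}_c{ci + 1:03d}" for ci in range(n_contigs)]

        # slot grid: (contig index, index within contig) for every gene
        slots = [(ci, k) for ci in range(n_contigs) for k in range(alloc[ci])]
        annotations: dict[int, dict] = {}  # slot idx -> payload
        reserved = np.zeros(len(slots), dtype=bool)
        slot_offset = np.cumsum([0] + list(alloc[:-1]))

        def slot_id(ci, k):
            return int(slot_offset[ci] + k)

        # --- plant PULs on Bacteroidota-like genomes -------------------
        if phylum == "Bacteroidota":
            n_puls = int(rng.integers(2, 6))
            margin = 4
            for _ in range(n_puls):
                ci = int(rng.integers(n_contigs))
                room = alloc[ci]
                if room < 12 + 2 * margin:
                    continue
                span = int(rng.integers(2, 7))  # genes in the locus
                start_k = int(rng.integers(margin, room - span - margin))
                block = range(slot_id(ci, start_k - margin),
                              slot_id(ci, start_k + span + margin))
                if reserved[list(block)].any():
                    continue
                reserved[list(block)] = True
                members, has_caz = [], False
                annotations[slot_id(ci, start_k)] = {"symbols": ["susC"],
                                                     "kos": ["K21573"],
                                                     "strand": "+"}
                annotations[slot_id(ci, start_k + 1)] = {"symbols": ["susD"],
                                                         "kos": ["K21572"],
                                                         "strand": "+"}
                members = [start_k, start_k + 1]
                if span > 2 and rng.random() < 0.55:
                    k = start_k + 2
                    while k < start_k + span:
                        fam = _BACKGROUND_FAMILIES[
                            int(rng.integers(0, 8))]  # GH/GT background fams
                        annotations[slot_id(ci, k)] = {"family": fam,
                                                       "strand": "+"}
                        members.append(k)
                        has_caz = True
                        k += int(rng.integers(1, 3))  # gaps of 0-1 genes
                puls.append(PlantedPUL(
                    genome_id=gid, contig_id=contig_ids[ci],
                    first_index=members[0], last_index=members[-1],
                    gene_ids=[f"{gid}_g{slot_id(ci, k) + 1:04d}"
                              for k in members],
                    has_cazyme=has_caz))

        # --- capability markers + modular/scaffoldin/background --------
        payloads = _marker_payloads(profile, rules, rng)
        # modular CAZyme pairs on degraders; scaffoldins on Firmicutes_A
        pair_for = {"GH13_9": "starch", "GH78": "pectin", "GH9": "cellulose"}
        eligible = [pair for pair in _MODULAR_PAIRS
                    if profile.polymers[pair_for[pair[0]]]]
        if eligible and rng.random() < 0.7:
            fam_a, fam_b = eligible[int(rng.integers(len(eligible)))]
            payloads.append({"families": [fam_a, fam_b], "multidomain": True})
        if phylum == "Firmicutes_A" and rng.random() < 0.15:
            n_coh = int(rng.integers(2, 5))
            payloads.append({"families": ["cohesin"] * n_coh,
                             "scaffoldin": True})
        n_bg_caz = int(rng.integers(5, 15))
        payloads.extend({"family": _BACKGROUND_FAMILIES[
            int(rng.integers(len(_BACKGROUND_FAMILIES)))]}
            for _ in range(n_bg_caz))
        n_bg_ko = int(rng.integers(20, 40))
        payloads.extend({"kos": [f"K9{int(rng.integers(0, 10000)):04d}"],
                         "symbols": [_BACKGROUND_SYMBOLS[
                             int(rng.integers(len(_BACKGROUND_SYMBOLS)))]]}
                        for _ in range(n_bg_ko))

        free = np.nonzero(~reserved)[0]
        if len(payloads) > len(free):
            raise DesignError(
                f"genome {gid}: n_genes={n_genes} too small for "
                f"{len(payloads)} planted genes")
        chosen = rng.choice(free, size=len(payloads), replace=False)
        for slot, payload in zip(chosen, payloads):
            annotations[int(slot)] = payload

        # --- materialize gene rows -------------------------------------
        from .bundle_io import cazy_class_of

        genome_gene_rows = []
        g_ko, g_dom, g_sig = [], [], []
        for s, (ci, k) in enumerate(slots):
            gene_id = f"{gid}_g{s + 1:04d}"
            payload = annotations.get(s, {})
            strand = payload.get("strand") or ("+" if rng.random() < 0.5
                                               else "-")
            start = 101 + k * 1200
            end = start + 899
            genome_gene_rows.append(
                (gene_id, gid, contig_ids[ci], start, end, strand, 300))
            kos = payload.get("kos", [])
            symbols = payload.get("symbols", [])
            if kos or symbols:
                g_ko.append((gene_id, ",".join(sorted(kos)),
                             ",".join(sorted(symbols))))
            families = payload.get("families") or (
                [payload["family"]] if "family" in payload else [])
            for di, fam in enumerate(families):
                qs = 10 + di * 120
                g_dom.append((gene_id, fam, cazy_class_of(fam), qs,
                              qs + 99, 1e-30, 0.9))
            if families:
                if len(families) > 1 and payload.get("multidomain"):
                    multidomain.add(gene_id)
                if payload.get("scaffoldin"):
                    scaffoldins.add(gene_id)
                    multidomain.add(gene_id)
                if rng.random() < design.secretory_fraction:
                    secretory.add(gene_id)
                    mode = ("gram_negative" if phylum == "Bacteroidota"
                            else "gram_positive")
                    g_sig.append((gene_id, True, mode))

        # --- degrade: uniform dropout + duplicate-gene contamination ---
        gene_ids_full = [r[0] for r in genome_gene_rows]
        intended[gid] = gene_ids_full
        keep = rng.random(len(genome_gene_rows)) < completeness / 100.0
        kept_rows = [r for r, k in zip(genome_gene_rows, keep) if k]
        kept_ids = {r[0] for r in kept_rows}
        retained[gid] = sorted(kept_ids)
        realized_comp[gid] = 100.0 * len(kept_rows) / len(genome_gene_rows)
        n_dup = int(round(contamination / 100.0 * len(kept_rows)))
        dup_rows = []
        if n_dup and kept_rows:
            ko_by_gene = {r[0]: r for r in g_ko}
            dup_src = rng.choice(len(kept_rows), size=n_dup, replace=False)
            contam_contig = f"{gid}_cX"
            for j, si in enumerate(sorted(dup_src)):
                src = kept_rows[si]
                dup_id = f"{src[0]}d"
                dup_rows.append((dup_id, gid, contam_contig, 101 + j * 1200,
                                 1000 + j * 1200, src[5], src[6]))
                if src[0] in ko_by_gene:  # replicate KO annotations
                    row = ko_by_gene[src[0]]
                    g_ko.append((dup_id, row[1], row[2]))
        genes_rows.extend(kept_rows)
        genes_rows.extend(dup_rows)
        surviving = kept_ids | {r[0] for r in dup_rows}
        ko_rows.extend(r for r in g_ko if r[0] in surviving)
        dom_rows.extend(r for r in g_dom if r[0] in surviving)
        sig_rows.extend(r for r in g_sig if r[0] in surviving)

        # --- metadata + contig lengths ---------------------------------
        lengths = np.maximum(
            rng.lognormal(10.2, 0.5, size=n_contigs).astype(int),
            alloc * 1200 + 400)
        for cid, ln in zip(contig_ids, lengths):
            clen_rows.append((gid, cid, int(ln)))
        if dup_rows:
            clen_rows.append((gid, f"{gid}_cX", n_dup * 1200 + 400))
        rr_full = rng.random() < 0.1
        rrnas = {"5S", "16S", "23S"} if rr_full else set(
            np.array(["5S", "16S", "23S"])[rng.random(3) < 0.4])
        taxonomy = (f"d__Bacteria;p__{phylum};c__{phylum}_c;o__{phylum}_o;"
                    f"f__{phylum}_f;g__{phylum}_g{gi % 7};s__")
        meta_rows.append((gid, taxonomy, round(completeness, 4),
                          round(contamination, 4),
                          ",".join(sorted(rrnas)), int(rng.integers(12, 26))))

        for b in range(rng.poisson(0.8)):
            fam = rng.choice(_BGC_FAMILIES, p=_BGC_WEIGHTS)
            bgc_rows.append((gid, f"{gid}_bgc{b + 1}", str(fam)))

    bundle = AnnotationBundle(
        genes=pd.DataFrame(genes_rows, columns=[
            "gene_id", "genome_id", "contig_id", "start", "end", "strand",
            "protein_length"]),
        ko=pd.DataFrame(ko_rows, columns=["gene_id", "ko_ids",
                                          "gene_symbols"]),
        domains=pd.DataFrame(dom_rows, columns=[
            "gene_id", "family", "clazz", "qstart", "qend", "evalue",
            "query_coverage"]),
        metadata=pd.DataFrame(meta_rows, columns=[
            "genome_id", "taxonomy", "completeness", "contamination",
            "rrnas", "trna_count"]),
        contig_lengths=pd.DataFrame(clen_rows, columns=[
            "genome_id", "contig_id", "length_bp"]),
        signals=pd.DataFrame(sig_rows, columns=["gene_id", "secretory",
                                                "mode"]),
        bgc=pd.DataFrame(bgc_rows, columns=["genome_id", "cluster_id",
                                            "bgc_family"]),
    )
    truth = SyntheticTruth(
        profiles=profiles, puls=puls, multidomain_genes=multidomain,
        scaffoldin_genes=scaffoldins, secretory_genes=secretory,
        differential_taxa=dict(design.differential_taxa),
        chemistry_correlated_taxa=dict(design.chemistry_correlated_taxa),
        realized_completeness=realized_comp, intended_genes=intended,
        retained_genes=retained)
    # secretory truth only meaningful for genes that survived degradation
    all_genes = set(bundle.genes["gene_id"])
    truth.multidomain_genes &= all_genes
    truth.scaffoldin_genes &= all_genes
    truth.secretory_genes &= all_genes
    return bundle, truth


def random_tree(leaf_names: list[str], rng: np.random.Generator) -> TreeNode:
    """Random binary rooted tree with exponential branch lengths."""
    nodes = [f"{name}:{rng.exponential(0.4):.6f}" for name in leaf_names]
    nodes = list(nodes)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        if len(nodes) == 0:
            nodes.append(f"({a},{b});")
        else:
            nodes.append(f"({a},{b}):{rng.exponential(0.4):.6f}")
    newick = nodes[0] if nodes[0].endswith(";") else f"({nodes[0]});"
    tree = TreeNode.read(io.StringIO(newick))
    return tree


def generate_abundance_and_chemistry(
        design: CommunityDesign, truth: SyntheticTruth
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Abundance matrix, sample metadata and forage chemistry.

    Abundances follow ``log x = baseline + group effect + c * z(NDF) +
    N(0, sigma)``; the group effect is ``log(fold)`` for planted
    differential taxa in their target substrate, and ``c = +/-1`` for taxa
    designed to track NDF.  Values below the detection floor are zeroed.
    Chemistry curves decay exponentially with a per-substrate rate shared by
    NDF/ADF/ADL, preserving ADL <= ADF <= NDF and monotonicity.
    """
    design.validate()
    if design.differential_taxa and len(design.substrates) < 2:
        raise DesignError("differential taxa require >= 2 substrates")
    rng = np.random.default_rng(design.seed + 1_000_003)
    genomes = sorted(truth.profiles)

    chem_rows = []
    ndf_lookup: dict[tuple[str, int], float] = {}
    for sub in design.substrates:
        ndf0 = rng.uniform(45, 75)
        adf0 = ndf0 * rng.uniform(0.55, 0.8)
        adl0 = adf0 * rng.uniform(0.15, 0.45)
        rate = rng.uniform(0.25, 0.8)
        for t in (0, *design.time_points):
            decay = np.exp(-rate * t / 96.0)
            chem_rows.append((sub, t, ndf0 * decay, adf0 * decay,
                              adl0 * decay))
            ndf_lookup[(sub, t)] = ndf0 * decay
    chemistry = pd.DataFrame(chem_rows, columns=["substrate", "time_h",
                                                 "ndf", "adf", "adl"])

    samples = [(f"{sub}_{t}h_r{r + 1}", sub, t, r + 1)
               for sub in design.substrates
               for t in design.time_points
               for r in range(design.replicates)]
    sample_meta = pd.DataFrame(samples, columns=["sample_id", "substrate",
                                                 "time_h", "replicate"])
    ndf = np.array([ndf_lookup[(s[1], s[2])] for s in samples])
    ndf_z = (ndf - ndf.mean()) / ndf.std()

    baseline = rng.normal(0.0, 1.0, size=len(genomes))
    log_x = baseline[:, None] + rng.normal(
        0.0, design.abundance_sigma, size=(len(genomes), len(samples)))
    for i, g in enumerate(genomes):
        if g in design.differential_taxa:
            sub, fold = design.differential_taxa[g]
            in_group = np.array([s[1] == sub for s in samples])
            log_x[i, in_group] += np.log(fold)
        if g in design.chemistry_correlated_taxa:
            sign = design.chemistry_correlated_taxa[g]
            log_x[i, :] += sign * ndf_z + 1.0  # lift above detection floor
    values = np.exp(log_x)
    values[values < design.detection_floor] = 0.0
    abundance = pd.DataFrame(values, index=pd.Index(genomes, name="genome_id"),
                             columns=[s[0] for s in samples])
    return abundance, sample_meta, chemistry


def simulate_bundle(design: CommunityDesign,
                    rules: mi.MarkerRuleSet | None = None
                    ) -> tuple[AnnotationBundle, SyntheticTruth]:
    """Full bundle: genomes + tree + abundance + chemistry, validated."""
    bundle, truth = generate_genomes(design, rules)
    abundance, sample_meta, chemistry = generate_abundance_and_chemistry(
        design, truth)
    bundle.abundance = abundance
    bundle.sample_meta = sample_meta
    bundle.chemistry = chemistry
    tree_rng = np.random.default_rng(design.seed + 2_000_003)
    bundle.tree = random_tree(sorted(truth.profiles), tree_rng)
    validate_bundle(bundle)
    return bundle, truth
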