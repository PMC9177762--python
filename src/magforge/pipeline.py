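"""Sequential orchestration of simulate -> quality -> capabilities ->
CAZy/PUL -> diversity with provenance.

A :class:`RunConfig` captures every threshold plus one global seed; the
seed is fanned out to per-stage seeds by fixed offsets recorded in the
summary, so a rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import (bundle_io, cazyme_profiling, community_stats, genome_quality,
               metabolic_inference, pul_detection, synthetic_data)
from .errors import ConfigurationError

STAGE_SEED_OFFSETS = {"simulate": 0, "diversity": 11, "ancom": 13}


@dataclass
class RunConfig:
    out_dir: str = "magforge_run"
    bundle_dir: str | None = None      # load an existing bundle ...
    design: dict = field(default_factory=dict)  # ... or simulate one
    seed: int = 0
    stages: tuple = ("quality", "capabilities", "cazy", "puls", "diversity")
    evalue_max: float = 1e-15
    coverage_min: float = 0.35
    max_intervening: int = 1
    max_gap: int = 2
    r_min: float = 0.38
    p_max: float = 0.01
    n_permutations: int = 999
    af_min: float = 0.65
    ani_stages: tuple = (99.0, 90.0)

    def validate(self) -> None:
        if not 0 < self.af_min <= 1:
            raise ConfigurationError(f"af_min {self.af_min} outside (0, 1]")
        if not 0 < self.coverage_min <= 1:
            raise ConfigurationError("coverage_min outside (0, 1]")
        if self.evalue_max < 0:
            raise ConfigurationError("evalue_max must be >= 0")
        if self.max_gap < 0 or self.max_intervening < 0:
            raise ConfigurationError("gap parameters must be >= 0")
        for thr in self.ani_stages:
            if not 0 < thr <= 100:
                raise ConfigurationError(f"ANI stage {thr} outside (0, 100]")
        if not (0 < self.r_min < 1 and 0 < self.p_max < 1):
            raise ConfigurationError("correlation gates outside (0, 1)")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order.

    Writes stage TSVs plus ``summary.json`` (per-stage counts, the exact
    config and the fanned-out seeds) into ``config.out_dir`` and returns
    the summary dict.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "stage_seeds": {k: config.seed + v
                        for k, v in STAGE_SEED_OFFSETS.items()},
        "stages": {},
    }

    if config.bundle_dir:
        bundle = bundle_io.load_bundle(config.bundle_dir)
        truth = None
    else:
        design = synthetic_data.CommunityDesign(
            **{**config.design, "seed": config.seed})
        bundle, truth = synthetic_data.simulate_bundle(design)
        manifest = bundle_io.write_bundle(bundle, out / "bundle")
        (out / "bundle" / "truth.json").write_text(truth.to_json())
        summary["stages"]["simulate"] = {
            "n_genomes": int(len(bundle.metadata)),
            "n_genes": int(len(bundle.genes)),
            "files": manifest["files"],
        }

    gene_to_genome = bundle.genes.set_index("gene_id")["genome_id"]
    phylum = {
        r.genome_id: (r.taxonomy.split(";")[1].removeprefix("p__")
                      if ";" in str(r.taxonomy) else "unknown")
        for r in bundle.metadata.itertuples(index=False)}

    if "quality" in config.stages:
        tiers = genome_quality.tier_bundle(bundle.metadata)
        tiers.to_csv(out / "quality_tiers.tsv", sep="\t", index=False)
        summary["stages"]["quality"] = {
            "tier_counts": tiers["tier"].value_counts().to_dict()}

    filtered = cazyme_profiling.filter_domain_hits(
        bundle.domains, config.evalue_max, config.coverage_min)

    if "capabilities" in config.stages:
        profiles = metabolic_inference.infer_bundle_profiles(
            bundle, filtered_domains=filtered)
        cap_frame = metabolic_inference.profiles_to_frame(profiles)
        cap_frame.to_csv(out / "capabilities.tsv", sep="\t", index=False)
        summary["stages"]["capabilities"] = {
            "trophic_counts": cap_frame["trophic"].value_counts().to_dict()}

    if "cazy" in config.stages:
        sizes = bundle.genome_sizes()
        caz = cazyme_profiling.summarize_cazymes(
            filtered, sizes, gene_to_genome, grouping=phylum)
        caz.class_fractions.to_csv(out / "cazyme_class_fractions.tsv",
                                   sep="\t")
        caz.per_group.to_csv(out / "cazyme_group_densities.tsv", sep="\t")
        arch = cazyme_profiling.modular_architectures(filtered)
        arch.cooccurrence.to_csv(out / "cazyme_cooccurrence.tsv", sep="\t",
                                 index=False)
        secretory = cazyme_profiling.secretory_fractions(
            filtered, bundle.signals, gene_to_genome, grouping=phylum)
        secretory.to_csv(out / "secretory_fractions.tsv", sep="\t",
                         index=False)
        summary["stages"]["cazy"] = {
            "n_cazyme_domains": int(len(filtered)),
            "n_multidomain_genes": len(arch.multidomain_genes),
            "n_scaffoldin_candidates": len(arch.scaffoldin_candidates),
        }
        if bundle.bgc is not None and len(bundle.bgc):
            table, freqs = cazyme_profiling.summarize_bgcs(bundle.bgc, phylum)
            table.to_csv(out / "bgc_families.tsv", sep="\t")
            summary["stages"]["cazy"]["n_bgcs"] = int(len(bundle.bgc))

    if "puls" in config.stages:
        roles = pul_detection.sus_roles_from_ko(bundle.ko)
        pairs = pul_detection.find_sus_pairs(
            bundle.genes, roles, max_intervening=config.max_intervening)
        loci = pul_detection.call_puls(pairs, filtered, bundle.genes,
                                       roles=roles, max_gap=config.max_gap)
        pul_detection.puls_to_frame(loci).to_csv(
            out / "puls.tsv", sep="\t", index=False)
        summary["stages"]["puls"] = {
            "n_sus_pairs": len(pairs),
            "n_puls": len(loci),
            "n_without_cazyme": sum(not p.has_cazyme for p in loci),
        }
        if loci and len(filtered):
            enrich = pul_detection.pul_family_enrichment(loci, filtered)
            enrich.to_csv(out / "pul_enrichment.tsv", sep="\t", index=False)

    if "diversity" in config.stages and bundle.abundance is not None:
        seed = config.seed + STAGE_SEED_OFFSETS["diversity"]
        groups = bundle.sample_meta.set_index("sample_id")["substrate"]
        div_summary: dict = {}
        for method in ("bray_curtis", "weighted_unifrac"):
            dm = community_stats.beta_diversity(
                bundle.abundance, method=method, tree=bundle.tree)
            pd.DataFrame(dm.data, index=dm.labels, columns=dm.labels).to_csv(
                out / f"distance_{method}.tsv", sep="\t")
            pa = community_stats.permanova(dm, groups,
                                           n_perm=config.n_permutations,
                                           seed=seed)
            pdisp = community_stats.permdisp(dm, groups,
                                            n_perm=config.n_permutations,
                                            seed=seed)
            div_summary[method] = {
                "permanova_F": pa.statistic, "permanova_p": pa.p_value,
                "permdisp_F": pdisp.statistic, "permdisp_p": pdisp.p_value,
            }
        res = community_stats.ancom(
            bundle.abundance, groups,
            seed=config.seed + STAGE_SEED_OFFSETS["ancom"])
        div_summary["ancom_detected"] = sorted(
            res.detected[res.detected].index)
        if bundle.chemistry is not None and bundle.sample_meta is not None:
            chem = community_stats.chemistry_by_sample(
                bundle.sample_meta, bundle.chemistry)
            hits = community_stats.correlation_screen(
                bundle.abundance, chem, r_min=config.r_min,
                p_max=config.p_max)
            hits.to_csv(out / "chemistry_correlations.tsv", sep="\t",
                        index=False)
            div_summary["n_significant_correlations"] = int(
                hits["significant"].sum())
        summary["stages"]["diversity"] = div_summary

    (out / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True))
    return summary
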