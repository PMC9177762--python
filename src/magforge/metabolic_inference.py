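"""Marker-gene rule engine for per-genome metabolic capability calls.

Capabilities are inferred from three evidence layers of an annotation bundle:

* **Sugar utilization** — one diagnostic isomerase/kinase KO per monomer
  (e.g. xylose isomerase K01805 for xylose).
* **Fermentation end products** — boolean rules over gene symbols, e.g.
  butyrate requires the phosphotransbutyrylase/butyrate-kinase pair
  (``ptb`` AND ``buk``) or the CoA-transferase route (``but``).
* **Central pathways** — fraction of a core marker-KO list found; a pathway
  is called present when the fraction reaches a configurable threshold
  (default 0.75).
* **Polymer degradation** — presence of at least one CAZyme family from the
  polymer's family set, with subfamily-aware prefix matching (``GH13_9``
  satisfies ``GH13``).

A genome is then layered into trophic-like levels: primary degraders (I),
sugar/metabolite utilizers (II), pure SCFA/methane producers (III_only), and
genomes with none of these capabilities (dependent), mirroring how
fiber-adherent communities partition carbon flow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .errors import ConfigurationError

SUGARS = ("glucose_6P", "fructose", "galactose", "arabinose", "fucose",
          "xylose", "mannose", "rhamnose")
FERMENTATION_PRODUCTS = ("butyrate", "lactate", "acetate", "succinate",
                         "propionate", "methanogenesis")
PATHWAYS = ("glycolysis", "PPP", "TCA")
POLYMERS = ("cellulose", "xylan", "xyloglucan", "chitin", "pectin", "starch")
TROPHIC_LEVELS = ("I", "II", "III_only", "dependent")

#: one diagnostic KO per monomeric sugar
DEFAULT_SUGAR_MARKERS: dict[str, str] = {
    "glucose_6P": "K01810",   # glucose-6-phosphate isomerase
    "fructose": "K00847",     # fructokinase
    "galactose": "K00849",    # galactokinase
    "arabinose": "K01804",    # L-arabinose isomerase
    "fucose": "K01818",       # L-fucose/D-arabinose isomerase
    "xylose": "K01805",       # xylose isomerase
    "mannose": "K01809",      # mannose-6-phosphate isomerase
    "rhamnose": "K01813",     # L-rhamnose isomerase
}

#: fermentation rules in disjunctive normal form: list of AND-groups
DEFAULT_FERMENTATION_RULES: dict[str, list[list[str]]] = {
    "butyrate": [["ptb", "buk"], ["but"]],
    "lactate": [["ldh"]],
    "acetate": [["pta", "ackA"]],
    "succinate": [["men", "fum", "frd"]],
    "propionate": [["mmdA", "mutA", "mce"]],
    "methanogenesis": [["mcrA"]],
}

#: optional rules disabled by default (formate via pyruvate formate-lyase)
OPTIONAL_FERMENTATION_RULES: dict[str, list[list[str]]] = {
    "formate": [["pflB"], ["pflD"]],
}

#: core marker KOs per central pathway; stand-in lists, fully configurable.
#: kept disjoint from the sugar diagnostic KOs so capability calls stay
#: independent (K01810/pgi is the glucose-6P sugar marker, hence pgm here)
DEFAULT_PATHWAY_MARKERS: dict[str, list[str]] = {
    "glycolysis": ["K00845", "K01835", "K00850", "K01623", "K01803",
                   "K00134", "K00927", "K01834", "K01689", "K00873"],
    "PPP": ["K00036", "K01057", "K00033", "K01783", "K01808", "K00615",
            "K00616"],
    "TCA": ["K01647", "K01681", "K00031", "K00164", "K01902", "K00239",
            "K01679", "K00024"],
}

DEFAULT_POLYMER_FAMILIES: dict[str, list[str]] = {
    "cellulose": ["GH5", "GH9", "GH44", "GH45", "GH48"],
    "xylan": ["GH10", "GH11", "GH8", "CE1", "CE2", "CE4"],
    "xyloglucan": ["GH16", "GH74", "GH31"],
    "chitin": ["GH18", "GH19"],
    "pectin": ["GH28", "PL1", "PL9", "CE8", "GH78"],
    "starch": ["GH13", "GH57", "GH97", "GH77"],
}


@dataclass
class MarkerRuleSet:
    """Serializable container of all capability rules."""

    sugar_markers: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_SUGAR_MARKERS))
    fermentation_rules: dict[str, list[list[str]]] = field(
        default_factory=lambda: {k: [list(g) for g in v]
                                 for k, v in DEFAULT_FERMENTATION_RULES.items()})
    pathway_markers: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v)
                                 for k, v in DEFAULT_PATHWAY_MARKERS.items()})
    pathway_threshold: float = 0.75
    polymer_families: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v)
                                 for k, v in DEFAULT_POLYMER_FAMILIES.items()})

    def validate(self) -> None:
        for pw, markers in self.pathway_markers.items():
            if not markers:
                raise ConfigurationError(f"empty marker list for pathway {pw}")
        if not 0 < self.pathway_threshold <= 1:
            raise ConfigurationError("pathway_threshold must be in (0, 1]")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({
                "sugar_markers": self.sugar_markers,
                "fermentation_rules": self.fermentation_rules,
                "pathway_markers": self.pathway_markers,
                "pathway_threshold": self.pathway_threshold,
                "polymer_families": self.polymer_families,
            }, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "MarkerRuleSet":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        rules = cls(**raw)
        rules.validate()
        return rules


@dataclass
class CapabilityProfile:
    genome_id: str
    sugars: dict[str, bool]
    fermentation: dict[str, bool]
    pathways: dict[str, tuple[bool, float]]
    polymers: dict[str, bool]
    trophic: str = "dependent"
    flags: dict[str, bool] = field(default_factory=dict)


def infer_sugars(ko_set: set, rules: MarkerRuleSet | None = None
                 ) -> dict[str, bool]:
    """Sugar ``s`` is utilizable iff its diagnostic marker KO is present."""
    rules = rules or MarkerRuleSet()
    return {s: (ko in ko_set) for s, ko in rules.sugar_markers.items()}


def infer_fermentation(symbol_set: set, rules: MarkerRuleSet | None = None
                       ) -> dict[str, bool]:
    """Evaluate each fermentation rule (OR of AND-groups) on gene symbols."""
    rules = rules or MarkerRuleSet()
    return {
        product: any(all(sym in symbol_set for sym in group)
                     for group in groups)
        for product, groups in rules.fermentation_rules.items()
    }


def infer_pathways(ko_set: set, rules: MarkerRuleSet | None = None
                   ) -> dict[str, tuple[bool, float]]:
    """Per-pathway (present, marker completeness fraction)."""
    rules = rules or MarkerRuleSet()
    rules.validate()
    out = {}
    for pw, markers in rules.pathway_markers.items():
        frac = sum(1 for m in markers if m in ko_set) / len(markers)
        out[pw] = (frac >= rules.pathway_threshold, frac)
    return out


def _family_matches(family: str, rule_family: str) -> bool:
    # subfamily-aware prefix match: GH13_9 satisfies GH13 but GH130 does not
    if family == rule_family:
        return True
    return family.startswith(rule_family + "_")


def infer_polymers(families: set, rules: MarkerRuleSet | None = None
                   ) -> dict[str, bool]:
    """Polymer degradable iff >=1 configured CAZyme family is present."""
    rules = rules or MarkerRuleSet()
    return {
        polymer: any(_family_matches(f, rf) for f in families
                     for rf in rule_families)
        for polymer, rule_families in rules.polymer_families.items()
    }


def assign_trophic(profile: CapabilityProfile) -> CapabilityProfile:
    """Derive summary flags and the trophic-like level, in place.

    ``degrader`` requires a structural-polymer family (starch alone does not
    qualify a genome as a fiber degrader); level I = degrader, II = sugar
    utilizer that is not a degrader, III_only = SCFA producer or methanogen
    with neither, dependent = none of the above.
    """
    polymers = profile.polymers
    degrader = any(v for k, v in polymers.items() if k != "starch")
    sugar_utilizer = any(profile.sugars.values())
    ferm = profile.fermentation
    scfa = bool(ferm.get("acetate") or ferm.get("butyrate")
                or ferm.get("propionate"))
    methanogen = bool(ferm.get("methanogenesis"))
    if degrader:
        level = "I"
    elif sugar_utilizer:
        level = "II"
    elif scfa or methanogen:
        level = "III_only"
    else:
        level = "dependent"
    profile.flags = {"degrader": degrader, "sugar_utilizer": sugar_utilizer,
                     "scfa_producer": scfa, "methanogen": methanogen}
    profile.trophic = level
    return profile


def infer_profile(genome_id: str, ko_set: set, symbol_set: set,
                  families: set, rules: MarkerRuleSet | None = None
                  ) -> CapabilityProfile:
    """Run the full rule engine for one genome."""
    rules = rules or MarkerRuleSet()
    profile = CapabilityProfile(
        genome_id=genome_id,
        sugars=infer_sugars(ko_set, rules),
        fermentation=infer_fermentation(symbol_set, rules),
        pathways=infer_pathways(ko_set, rules),
        polymers=infer_polymers(families, rules),
    )
    return assign_trophic(profile)


def infer_bundle_profiles(bundle, rules: MarkerRuleSet | None = None,
                          filtered_domains=None) -> dict[str, CapabilityProfile]:
    """Capability profiles for every genome in a bundle.

    `filtered_domains` should be the output of
    :func:`magforge.cazyme_profiling.filter_domain_hits`; raw hits are used
    as-is when not provided.
    """
    rules = rules or MarkerRuleSet()
    ko_sets = bundle.ko_sets_by_genome()
    symbol_sets = bundle.symbol_sets_by_genome()
    domains = bundle.domains if filtered_domains is None else filtered_domains
    gmap = bundle.genes.set_index("gene_id")["genome_id"]
    fam_sets: dict[str, set] = {g: set() for g in bundle.metadata["genome_id"]}
    for gid, fam in zip(domains["gene_id"], domains["family"]):
        fam_sets[gmap[gid]].add(fam)
    return {
        g: infer_profile(g, ko_sets[g], symbol_sets[g], fam_sets[g], rules)
        for g in bundle.metadata["genome_id"]
    }


def profiles_to_frame(profiles: dict[str, CapabilityProfile]):
    """Flatten profiles into a tidy DataFrame (one row per genome)."""
    import pandas as pd

    rows = []
    for g in sorted(profiles):
        p = profiles[g]
        row: dict = {"genome_id": g, "trophic": p.trophic}
        row.update({f"sugar_{k}": v for k, v in p.sugars.items()})
        row.update({f"ferm_{k}": v for k, v in p.fermentation.items()})
        row.update({f"polymer_{k}": v for k, v in p.polymers.items()})
        for pw, (present, frac) in p.pathways.items():
            row[f"pathway_{pw}"] = present
            row[f"pathway_{pw}_fraction"] = frac
        row.update(p.flags)
        rows.append(row)
    return pd.DataFrame(rows)
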