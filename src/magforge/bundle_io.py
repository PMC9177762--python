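"""Readers, writers and validation for annotation bundles.

An *annotation bundle* is the directory of plain-text tables that the rest of
the package consumes: per-gene coordinates, KEGG-ortholog assignments, CAZyme
domain hits, signal-peptide flags, genome metadata (taxonomy, completeness,
contamination, rRNA/tRNA inventory), contig lengths, a genome-by-sample
abundance matrix with sample metadata, forage fiber chemistry, a genome
phylogeny in Newick, and an optional table of biosynthetic gene cluster calls.

Conventions
-----------
* Gene coordinates are 1-based and inclusive on both ends (GFF3 convention).
* All tables are UTF-8 TSV with a single ``#``-prefixed header line and no
  quoting; floats are written with 6 significant digits so that rewriting a
  loaded bundle is byte-stable.
* Set-valued columns (KO ids, gene symbols, rRNA inventory) are comma-joined
  in sorted order.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .errors import BundleLoadError, BundleValidationError

CAZY_CLASSES = ("GH", "GT", "PL", "CE", "AA", "CBM", "SLH", "cohesin")

#: file names of each bundle component; order fixes manifest order
BUNDLE_FILES = {
    "genes": "genes.tsv",
    "ko": "ko.tsv",
    "domains": "cazyme_hits.tsv",
    "signals": "signal_flags.tsv",
    "metadata": "genome_metadata.tsv",
    "contig_lengths": "contig_lengths.tsv",
    "abundance": "abundance.tsv",
    "sample_meta": "sample_meta.tsv",
    "chemistry": "chemistry.tsv",
    "bgc": "bgc.tsv",
}
MANDATORY = ("genes", "ko", "domains", "metadata", "contig_lengths")
TREE_FILE = "tree.nwk"

_COLUMNS = {
    "genes": ["gene_id", "genome_id", "contig_id", "start", "end", "strand",
              "protein_length"],
    "ko": ["gene_id", "ko_ids", "gene_symbols"],
    "domains": ["gene_id", "family", "clazz", "qstart", "qend", "evalue",
                "query_coverage"],
    "signals": ["gene_id", "secretory", "mode"],
    "metadata": ["genome_id", "taxonomy", "completeness", "contamination",
                 "rrnas", "trna_count"],
    "contig_lengths": ["genome_id", "contig_id", "length_bp"],
    "sample_meta": ["sample_id", "substrate", "time_h", "replicate"],
    "chemistry": ["substrate", "time_h", "ndf", "adf", "adl"],
    "bgc": ["genome_id", "cluster_id", "bgc_family"],
}
_SORT_KEYS = {
    "genes": ["gene_id"],
    "ko": ["gene_id"],
    "domains": ["gene_id", "qstart", "family"],
    "signals": ["gene_id"],
    "metadata": ["genome_id"],
    "contig_lengths": ["genome_id", "contig_id"],
    "sample_meta": ["sample_id"],
    "chemistry": ["substrate", "time_h"],
    "bgc": ["genome_id", "cluster_id"],
}


def cazy_class_of(family: str) -> str:
    """CAZy class implied by a family name (``GH13_9`` -> ``GH``)."""
    if family in ("SLH", "cohesin") or family.startswith("SLH"):
        return "cohesin" if family == "cohesin" else "SLH"
    for cls in ("CBM", "GH", "GT", "PL", "CE", "AA"):
        if family.startswith(cls):
            return cls
    raise BundleValidationError(f"cannot infer CAZy class for family {family!r}")


# ---------------------------------------------------------------------------
# record-level domain types


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    protein_length: int


@dataclass(frozen=True)
class DomainHit:
    gene_id: str
    family: str
    clazz: str
    qstart: int
    qend: int
    evalue: float
    query_coverage: float


@dataclass(frozen=True)
class KOAssignment:
    gene_id: str
    ko_ids: frozenset
    gene_symbols: frozenset


@dataclass(frozen=True)
class SignalFlag:
    gene_id: str
    secretory: bool
    mode: str  # gram_positive | gram_negative | either


@dataclass(frozen=True)
class GenomeMetadata:
    genome_id: str
    taxonomy: str  # 7 semicolon-separated ranks, empty ranks allowed
    completeness: float
    contamination: float
    rrnas: frozenset
    trna_count: int


@dataclass
class AnnotationBundle:
    """All tables of one study, cross-validated and handed downstream."""

    genes: pd.DataFrame
    ko: pd.DataFrame
    domains: pd.DataFrame
    metadata: pd.DataFrame
    contig_lengths: pd.DataFrame
    signals: pd.DataFrame = field(default_factory=lambda: _empty("signals"))
    abundance: pd.DataFrame | None = None
    sample_meta: pd.DataFrame | None = None
    chemistry: pd.DataFrame | None = None
    tree: TreeNode | None = None
    bgc: pd.DataFrame | None = None

    # -- convenience accessors -------------------------------------------

    def genome_ids(self) -> list[str]:
        return sorted(self.metadata["genome_id"])

    def ko_sets_by_genome(self) -> dict[str, set]:
        """genome_id -> union of KO ids over its genes."""
        return self._sets_by_genome("ko_ids")

    def symbol_sets_by_genome(self) -> dict[str, set]:
        """genome_id -> union of gene symbols over its genes."""
        return self._sets_by_genome("gene_symbols")

    def _sets_by_genome(self, col: str) -> dict[str, set]:
        gmap = self.genes.set_index("gene_id")["genome_id"]
        out: dict[str, set] = {g: set() for g in self.metadata["genome_id"]}
        for gid, val in zip(self.ko["gene_id"], self.ko[col]):
            if val:
                out[gmap[gid]].update(val.split(","))
        return out

    def genome_sizes(self) -> pd.Series:
        return self.contig_lengths.groupby("genome_id")["length_bp"].sum()

    def equals(self, other: "AnnotationBundle", rtol: float = 1e-5) -> bool:
        """Field-wise equality, floats compared to `rtol`."""
        for name in _COLUMNS:
            a, b = getattr(self, name), getattr(other, name)
            if (a is None) != (b is None):
                return False
            if a is not None and not _frames_close(_canon(a, name),
                                                   _canon(b, name), rtol):
                return False
        if (self.abundance is None) != (other.abundance is None):
            return False
        if self.abundance is not None:
            a = self.abundance.sort_index().sort_index(axis=1)
            b = other.abundance.sort_index().sort_index(axis=1)
            if not (a.index.equals(b.index) and a.columns.equals(b.columns)
                    and np.allclose(a.values, b.values, rtol=rtol)):
                return False
        if (self.tree is None) != (other.tree is None):
            return False
        if self.tree is not None:
            if str(self.tree) != str(other.tree):
                return False
        return True


def _empty(name: str) -> pd.DataFrame:
    return pd.DataFrame(columns=_COLUMNS[name])


def _canon(df: pd.DataFrame, name: str) -> pd.DataFrame:
    df = df[_COLUMNS[name]].sort_values(_SORT_KEYS[name]).reset_index(drop=True)
    return df


def _frames_close(a: pd.DataFrame, b: pd.DataFrame, rtol: float) -> bool:
    if len(a) != len(b) or list(a.columns) != list(b.columns):
        return False
    for col in a.columns:
        x, y = a[col].to_numpy(), b[col].to_numpy()
        if np.issubdtype(np.asarray(x).dtype, np.floating) or \
                np.issubdtype(np.asarray(y).dtype, np.floating):
            if not np.allclose(np.asarray(x, float), np.asarray(y, float),
                               rtol=rtol, equal_nan=True):
                return False
        elif not all(str(u) == str(v) for u, v in zip(x, y)):
            return False
    return True


# ---------------------------------------------------------------------------
# validation


def validate_bundle(bundle: AnnotationBundle) -> None:
    """Check every schema invariant; raise :class:`BundleValidationError`.

    Checks referential integrity (annotation tables and abundance rows point
    at known genes/genomes), coordinate sanity, value domains, and the
    lignocellulose nesting ADL <= ADF <= NDF of the chemistry table.
    """
    genes = bundle.genes
    dup = genes["gene_id"][genes["gene_id"].duplicated()]
    if len(dup):
        raise BundleValidationError(f"duplicate gene ids: {sorted(set(dup))}")
    bad = genes[(genes["end"] < genes["start"]) | (genes["start"] < 1)]
    if len(bad):
        raise BundleValidationError(
            f"malformed coordinates for genes: {sorted(bad['gene_id'])}")
    bad_strand = genes[~genes["strand"].isin(["+", "-"])]
    if len(bad_strand):
        raise BundleValidationError(
            f"invalid strand for genes: {sorted(bad_strand['gene_id'])}")

    genome_ids = set(bundle.metadata["genome_id"])
    unknown = sorted(set(genes["genome_id"]) - genome_ids)
    if unknown:
        raise BundleValidationError(
            f"gene table references unknown genome ids: {unknown}")
    unknown = sorted(set(bundle.contig_lengths["genome_id"]) - genome_ids)
    if unknown:
        raise BundleValidationError(
            f"contig-length table references unknown genome ids: {unknown}")

    gene_ids = set(genes["gene_id"])
    for name in ("ko", "domains", "signals"):
        tab = getattr(bundle, name)
        unknown = sorted(set(tab["gene_id"]) - gene_ids)
        if unknown:
            raise BundleValidationError(
                f"{name} table references unknown gene ids: {unknown}")

    for gid, ko_ids in zip(bundle.ko["gene_id"], bundle.ko["ko_ids"]):
        for ko in str(ko_ids).split(",") if ko_ids else []:
            if not (len(ko) == 6 and ko[0] == "K" and ko[1:].isdigit()):
                raise BundleValidationError(
                    f"gene {gid}: malformed KO identifier {ko!r}")

    d = bundle.domains
    if len(d):
        bad = d[d["qend"] < d["qstart"]]
        if len(bad):
            raise BundleValidationError(
                f"domain qend < qstart for genes: {sorted(bad['gene_id'])}")
        if (d["evalue"] < 0).any():
            raise BundleValidationError("negative e-values in domain table")
        for fam, cls in zip(d["family"], d["clazz"]):
            if cazy_class_of(fam) != cls:
                raise BundleValidationError(
                    f"family {fam!r} inconsistent with class {cls!r}")

    s = bundle.signals
    if len(s):
        bad = s[s["secretory"].astype(bool)
                & ~s["mode"].isin(["gram_positive", "gram_negative", "either"])]
        if len(bad):
            raise BundleValidationError(
                f"secretory genes without mode: {sorted(bad['gene_id'])}")

    m = bundle.metadata
    if (m["completeness"] > 100).any() or (m["completeness"] < 0).any():
        raise BundleValidationError("completeness outside [0, 100]")
    if (m["contamination"] < 0).any():
        raise BundleValidationError("negative contamination")
    for gid, rr in zip(m["genome_id"], m["rrnas"]):
        extra = set(str(rr).split(",")) - {"5S", "16S", "23S", ""}
        if extra:
            raise BundleValidationError(
                f"genome {gid}: unknown rRNA labels {sorted(extra)}")

    if bundle.abundance is not None:
        ab = bundle.abundance
        if (ab.values < 0).any():
            raise BundleValidationError("negative abundance entries")
        unknown = sorted(set(ab.index) - genome_ids)
        if unknown:
            raise BundleValidationError(
                f"abundance table references unknown genome ids: {unknown}")
        if ab.index.duplicated().any() or ab.columns.duplicated().any():
            raise BundleValidationError("duplicate abundance labels")
        if bundle.sample_meta is not None:
            missing = sorted(set(ab.columns)
                             - set(bundle.sample_meta["sample_id"]))
            if missing:
                raise BundleValidationError(
                    f"samples without metadata: {missing}")

    if bundle.chemistry is not None and len(bundle.chemistry):
        c = bundle.chemistry
        ok = (c["adl"] <= c["adf"] + 1e-9) & (c["adf"] <= c["ndf"] + 1e-9) \
            & (c["ndf"] <= 100) & (c["adl"] >= 0)
        if not ok.all():
            bad_rows = c[~ok][["substrate", "time_h"]].values.tolist()
            raise BundleValidationError(
                f"chemistry rows violating ADL<=ADF<=NDF<=100: {bad_rows}")

    if bundle.tree is not None and bundle.abundance is not None:
        leaves = {t.name for t in bundle.tree.tips()}
        missing = sorted(set(bundle.abundance.index) - leaves)
        if missing:
            raise BundleValidationError(
                f"abundance genomes missing from tree: {missing}")


# ---------------------------------------------------------------------------
# I/O


def _fmt(v) -> str:
    if isinstance(v, (float, np.floating)):
        return f"{v:.6g}"
    if isinstance(v, (bool, np.bool_)):
        return "1" if v else "0"
    return str(v)


def _write_tsv(df: pd.DataFrame, path: Path, columns: list[str]) -> int:
    with io.StringIO() as buf:
        buf.write("#" + "\t".join(columns) + "\n")
        for row in df[columns].itertuples(index=False):
            buf.write("\t".join(_fmt(v) for v in row) + "\n")
        path.write_text(buf.getvalue(), encoding="utf-8")
    return len(df)


def _read_tsv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df.columns = [df.columns[0].lstrip("#")] + list(df.columns[1:])
    return df


_DTYPES = {
    "start": int, "end": int, "protein_length": int, "qstart": int,
    "qend": int, "evalue": float, "query_coverage": float,
    "completeness": float, "contamination": float, "trna_count": int,
    "length_bp": int, "time_h": int, "replicate": int,
    "ndf": float, "adf": float, "adl": float,
}


def _coerce(df: pd.DataFrame, name: str) -> pd.DataFrame:
    df = df.copy()
    for col in df.columns:
        if col in _DTYPES:
            df[col] = df[col].astype(_DTYPES[col])
    if name == "signals" and len(df):
        df["secretory"] = df["secretory"].astype(int).astype(bool)
    return df


def write_bundle(bundle: AnnotationBundle, directory) -> dict:
    """Write every present component as deterministic TSV/Newick files.

    Rows are emitted in a fixed sort order and floats with 6 significant
    digits, so two writes of the same bundle are byte-identical.  Returns a
    manifest ``{"files": {name: n_rows}, "absent": [component, ...]}``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"files": {}, "absent": []}
    for name, fname in BUNDLE_FILES.items():
        if name == "abundance":
            continue
        df = getattr(bundle, name)
        if df is None or (name in ("bgc",) and len(df) == 0):
            manifest["absent"].append(name)
            continue
        n = _write_tsv(_canon(df, name), directory / fname, _COLUMNS[name])
        manifest["files"][fname] = n
    if bundle.abundance is not None:
        ab = bundle.abundance.sort_index().sort_index(axis=1)
        with io.StringIO() as buf:
            buf.write("#genome_id\t" + "\t".join(ab.columns) + "\n")
            for gid, row in zip(ab.index, ab.values):
                buf.write(gid + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")
            (directory / BUNDLE_FILES["abundance"]).write_text(
                buf.getvalue(), encoding="utf-8")
        manifest["files"][BUNDLE_FILES["abundance"]] = ab.shape[0]
    else:
        manifest["absent"].append("abundance")
    if bundle.tree is not None:
        (directory / TREE_FILE).write_text(str(bundle.tree), encoding="utf-8")
        manifest["files"][TREE_FILE] = bundle.tree.count(tips=True)
    else:
        manifest["absent"].append("tree")
    return manifest


def load_bundle(directory, schema_version: str = "1") -> AnnotationBundle:
    """Load and validate an annotation bundle from `directory`.

    Mandatory components (genes, KO, domain hits, metadata, contig lengths)
    raise :class:`BundleLoadError` when missing; optional components are
    simply absent from the returned bundle.
    """
    directory = Path(directory)
    parts: dict = {}
    for name in MANDATORY:
        path = directory / BUNDLE_FILES[name]
        if not path.exists():
            raise BundleLoadError(f"missing mandatory bundle file: "
                                  f"{BUNDLE_FILES[name]}")
        parts[name] = _coerce(_read_tsv(path), name)
    for name in ("signals", "sample_meta", "chemistry", "bgc"):
        path = directory / BUNDLE_FILES[name]
        if path.exists():
            parts[name] = _coerce(_read_tsv(path), name)
    ab_path = directory / BUNDLE_FILES["abundance"]
    if ab_path.exists():
        raw = _read_tsv(ab_path)
        ab = raw.set_index("genome_id").astype(float)
        parts["abundance"] = ab
    tree_path = directory / TREE_FILE
    if tree_path.exists():
        parts["tree"] = read_tree(tree_path)
    bundle = AnnotationBundle(**parts)
    validate_bundle(bundle)
    return bundle


def read_tree(path, default_branch_length: float = 1.0) -> TreeNode:
    """Parse a rooted Newick tree; absent branch lengths default to 1.0.

    The default keeps weighted UniFrac defined on trees written without
    lengths; a warning is emitted whenever the default is applied.
    """
    try:
        tree = TreeNode.read(str(path), convert_underscores=False)
    except Exception as exc:  # skbio raises several parse error types
        raise BundleLoadError(f"cannot parse Newick from {path}: {exc}") from exc
    defaulted = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = default_branch_length
            defaulted += 1
    if defaulted:
        warnings.warn(f"{defaulted} branches without length set to "
                      f"{default_branch_length}", stacklevel=2)
    tree.length = None
    return tree
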