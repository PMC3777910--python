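"""Data model and readers/writers for expression tables, region ontologies,
GO annotations and DAG, ortholog maps and protein FASTA.

The universal in-memory container is :class:`ExpressionDataset`, a dense
``gene x region x timepoint`` array of non-negative expression densities with
NaN marking cells that were never measured (regions absent at an age, failed
assays).  All downstream statistics treat missingness explicitly; a missing
cell is never silently read as zero.

File dialect: UTF-8 TSV with a header row, '.' decimal, one row per observed
(gene, region, timepoint) cell; a missing cell is encoded by row absence.
Gene and region identifiers match exactly and case-sensitively.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationError",
    "ParseError",
    "ExpressionDataset",
    "RegionOntology",
    "GeneAnnotation",
    "OrthologMap",
    "read_expression",
    "write_expression",
    "read_ontology",
    "read_annotations",
    "read_orthologs",
    "read_fasta",
]


class ValidationError(ValueError):
    """Input violates a documented contract (negative value, cycle, ...)."""


class ParseError(ValueError):
    """Input file is malformed; the message names the offending line."""


# ---------------------------------------------------------------------------
# Expression dataset
# ---------------------------------------------------------------------------

@dataclass
class ExpressionDataset:
    """Dense gene x region x timepoint tensor of expression densities.

    Parameters
    ----------
    genes, regions, timepoints
        Axis labels.  ``timepoints`` is in declared developmental order
        (e.g. E11.5 ... P56); labels are opaque ordered strings.
    values
        float array of shape ``(len(genes), len(regions), len(timepoints))``;
        NaN marks missing cells; all present values must be >= 0.
    species
        Free-text species label.
    """

    genes: list[str]
    regions: list[str]
    timepoints: list[str]
    values: np.ndarray
    species: str = "unknown"

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        self.regions = list(self.regions)
        self.timepoints = list(self.timepoints)
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.genes), len(self.regions), len(self.timepoints))
        if self.values.shape != expected:
            raise ValidationError(
                f"values shape {self.values.shape} does not match axis "
                f"lengths {expected}"
            )
        for name, labels in (("genes", self.genes), ("regions", self.regions),
                             ("timepoints", self.timepoints)):
            if len(set(labels)) != len(labels):
                raise ValidationError(f"duplicate labels on axis {name!r}")
        present = self.values[~np.isnan(self.values)]
        if present.size and present.min() < 0:
            raise ValidationError("expression density must be non-negative")

    # -- indexing helpers ---------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_timepoints(self) -> int:
        return len(self.timepoints)

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene {gene!r}") from None

    def region_index(self, region: str) -> int:
        try:
            return self.regions.index(region)
        except ValueError:
            raise KeyError(f"unknown region {region!r}") from None

    def timepoint_index(self, timepoint: str) -> int:
        try:
            return self.timepoints.index(timepoint)
        except ValueError:
            raise KeyError(f"unknown timepoint {timepoint!r}") from None

    def matrix_at(self, timepoint: str) -> np.ndarray:
        """gene x region slice at one timepoint (view, do not mutate)."""
        return self.values[:, :, self.timepoint_index(timepoint)]

    def regions_present_at(self, timepoint: str) -> list[str]:
        """Regions with at least one observed gene at the timepoint."""
        m = self.matrix_at(timepoint)
        keep = ~np.all(np.isnan(m), axis=0)
        return [r for r, k in zip(self.regions, keep) if k]

    # -- subsetting ---------------------------------------------------------

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionDataset":
        idx = [self.gene_index(g) for g in genes]
        return ExpressionDataset(list(genes), self.regions, self.timepoints,
                                 self.values[idx], self.species)

    def drop_genes(self, genes: Iterable[str]) -> "ExpressionDataset":
        drop = set(genes)
        keep = [g for g in self.genes if g not in drop]
        return self.subset_genes(keep)

    def subset_regions(self, regions: Sequence[str]) -> "ExpressionDataset":
        idx = [self.region_index(r) for r in regions]
        return ExpressionDataset(self.genes, list(regions), self.timepoints,
                                 self.values[:, idx], self.species)

    def drop_regions(self, regions: Iterable[str]) -> "ExpressionDataset":
        drop = set(regions)
        keep = [r for r in self.regions if r not in drop]
        return self.subset_regions(keep)

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame with one row per observed cell (canonical order)."""
        rows = []
        for i, g in enumerate(self.genes):
            for j, r in enumerate(self.regions):
                for k, t in enumerate(self.timepoints):
                    v = self.values[i, j, k]
                    if not np.isnan(v):
                        rows.append((g, r, t, v))
        return pd.DataFrame(rows, columns=["gene", "region", "timepoint", "value"])


def read_expression(path: str | Path, species: str = "unknown") -> ExpressionDataset:
    """Read a long-format expression TSV/CSV into an :class:`ExpressionDataset`.

    Columns ``gene, region, timepoint, value`` are required.  Axis label order
    is the order of first appearance in the file.  Duplicate
    (gene, region, timepoint) rows are an error; absent combinations are
    missing cells.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, dtype={"gene": str, "region": str,
                                               "timepoint": str},
                         float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise ParseError(f"{path}: cannot parse: {exc}") from exc
    required = ["gene", "region", "timepoint", "value"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ParseError(f"{path}: missing columns {missing_cols}")
    bad = df[required[:3]].isna().any(axis=1) | pd.to_numeric(
        df["value"], errors="coerce").isna()
    if bad.any():
        # +2: header line and 1-based numbering
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise ParseError(f"{path}: malformed row at line {line}")
    df["value"] = df["value"].astype(float)
    if (df["value"] < 0).any():
        line = int(np.flatnonzero((df["value"] < 0).to_numpy())[0]) + 2
        raise ValidationError(f"{path}: negative expression value at line {line}")
    key = df[["gene", "region", "timepoint"]]
    if key.duplicated().any():
        dup = key[key.duplicated()].iloc[0]
        raise ValidationError(
            f"{path}: duplicate row for ({dup['gene']}, {dup['region']}, "
            f"{dup['timepoint']})")

    genes = list(dict.fromkeys(df["gene"]))
    regions = list(dict.fromkeys(df["region"]))
    timepoints = list(dict.fromkeys(df["timepoint"]))
    values = np.full((len(genes), len(regions), len(timepoints)), np.nan)
    gi = {g: i for i, g in enumerate(genes)}
    ri = {r: i for i, r in enumerate(regions)}
    ti = {t: i for i, t in enumerate(timepoints)}
    values[df["gene"].map(gi), df["region"].map(ri),
           df["timepoint"].map(ti)] = df["value"].to_numpy()
    return ExpressionDataset(genes, regions, timepoints, values, species)


def write_expression(dataset: ExpressionDataset, path: str | Path) -> None:
    """Write the canonical long-format TSV (row-absence encodes missingness).

    ``read_expression(write_expression(ds))`` reproduces every cell exactly:
    values are printed with :func:`repr`, which round-trips float64.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("gene\tregion\ttimepoint\tvalue\n")
        for g, r, t, v in self_rows(dataset):
            fh.write(f"{g}\t{r}\t{t}\t{v!r}\n")


def self_rows(dataset: ExpressionDataset):
    for i, g in enumerate(dataset.genes):
        for j, r in enumerate(dataset.regions):
            for k, t in enumerate(dataset.timepoints):
                v = dataset.values[i, j, k]
                if not np.isnan(v):
                    yield g, r, t, float(v)


# ---------------------------------------------------------------------------
# Region ontology
# ---------------------------------------------------------------------------

ORIGIN_TAGS = (
    "forebrain-telencephalon",
    "forebrain-diencephalon",
    "midbrain",
    "hindbrain",
)


@dataclass
class RegionOntology:
    """Rooted tree of brain regions with embryonic-origin tags.

    ``parent`` maps every non-root node to its parent; ``origin`` tags each
    node with one of the embryonic vesicle labels (leaves inherit from the
    nearest tagged ancestor at load time).
    """

    nodes: list[str]
    parent: dict[str, str]
    origin: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        roots = [n for n in self.nodes if n not in self.parent]
        if len(roots) != 1:
            raise ValidationError(f"expected a single root, found {roots}")
        self._root = roots[0]
        # cycle check: every node must reach the root
        for n in self.nodes:
            seen = set()
            cur = n
            while cur != self._root:
                if cur in seen:
                    raise ValidationError(f"cycle involving node {cur!r}")
                seen.add(cur)
                cur = self.parent[cur]

    @property
    def root(self) -> str:
        return self._root

    @property
    def leaves(self) -> list[str]:
        parents = set(self.parent.values())
        return [n for n in self.nodes if n not in parents]

    def children(self, node: str) -> list[str]:
        return [c for c, p in self.parent.items() if p == node]

    def ancestor_at_level(self, leaf: str, level: int) -> str:
        """Node reached from ``leaf`` by ``level - 1`` parent steps (capped
        at the root); level 1 is the leaf itself."""
        if level < 1:
            raise ValueError("level must be >= 1")
        cur = leaf
        for _ in range(level - 1):
            if cur == self._root:
                break
            cur = self.parent[cur]
        return cur

    def level_cut(self, level: int) -> dict[str, list[str]]:
        """Partition of the leaves at the given level.

        Maps each level-``level`` ancestor to the leaves it covers; at level 1
        every leaf maps to itself.
        """
        groups: dict[str, list[str]] = {}
        for leaf in self.leaves:
            groups.setdefault(self.ancestor_at_level(leaf, level), []).append(leaf)
        return groups

    def origin_of(self, node: str) -> str:
        try:
            return self.origin[node]
        except KeyError:
            raise KeyError(f"node {node!r} has no origin tag") from None


def read_ontology(path: str | Path) -> RegionOntology:
    """Read a ``child<TAB>parent<TAB>origin`` table into a RegionOntology.

    The root appears as a child with an empty parent field.  Empty origin
    fields inherit from the nearest tagged ancestor.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("child", "parent"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    if "origin" not in df.columns:
        df["origin"] = ""
    nodes = list(dict.fromkeys(df["child"]))
    parent: dict[str, str] = {}
    origin: dict[str, str] = {}
    for _, row in df.iterrows():
        child, par, org = row["child"], row["parent"], row["origin"]
        if par:
            if par not in nodes and par not in parent:
                nodes.append(par)
            parent[child] = par
        if org:
            origin[child] = org
    onto = RegionOntology(nodes, parent, origin)
    # inherit origin tags downward
    for leaf in onto.nodes:
        if leaf in onto.origin:
            continue
        cur = leaf
        while cur not in onto.origin and cur != onto.root:
            cur = onto.parent[cur]
        if cur in onto.origin:
            onto.origin[leaf] = onto.origin[cur]
    untagged = [l for l in onto.leaves if l not in onto.origin]
    if untagged:
        raise ValidationError(f"{path}: leaves without origin tag: {untagged}")
    return onto


# ---------------------------------------------------------------------------
# GO annotations
# ---------------------------------------------------------------------------

@dataclass
class GeneAnnotation:
    """Gene -> GO categories mapping plus the GO DAG.

    ``gene_to_terms`` is ancestor-closed after :func:`read_annotations` (a
    gene annotated to a term is annotated to all of the term's ancestors).
    ``parents`` maps each term to its direct ``is_a`` parents.
    """

    gene_to_terms: dict[str, set[str]]
    parents: dict[str, set[str]]
    names: dict[str, str] = field(default_factory=dict)

    def ancestors(self, term: str) -> set[str]:
        out: set[str] = set()
        stack = list(self.parents.get(term, ()))
        while stack:
            cur = stack.pop()
            if cur not in out:
                out.add(cur)
                stack.extend(self.parents.get(cur, ()))
        return out

    def descendants(self, term: str) -> set[str]:
        children: dict[str, set[str]] = {}
        for c, ps in self.parents.items():
            for p in ps:
                children.setdefault(p, set()).add(c)
        out: set[str] = set()
        stack = list(children.get(term, ()))
        while stack:
            cur = stack.pop()
            if cur not in out:
                out.add(cur)
                stack.extend(children.get(cur, ()))
        return out

    def term_to_genes(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for g, terms in self.gene_to_terms.items():
            for t in terms:
                out.setdefault(t, set()).add(g)
        return out

    def propagate(self) -> "GeneAnnotation":
        """Close annotations under the ancestor relation (idempotent)."""
        g2t = {g: set(ts) for g, ts in self.gene_to_terms.items()}
        for g, terms in g2t.items():
            extra: set[str] = set()
            for t in terms:
                extra |= self.ancestors(t)
            terms |= extra
        return GeneAnnotation(g2t, self.parents, self.names)


def _read_obo(obo_path: str | Path) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Parse an OBO 1.2 DAG into (term -> is_a parents, term -> name)."""
    import obonet

    graph = obonet.read_obo(str(obo_path))
    parents: dict[str, set[str]] = {n: set() for n in graph.nodes}
    names: dict[str, str] = {}
    for node, data in graph.nodes(data=True):
        if "name" in data:
            names[node] = data["name"]
    # obonet edges run child -> parent, keyed by relation type
    for child, par, key in graph.edges(keys=True):
        if key == "is_a":
            parents[child].add(par)
    return parents, names


def read_annotations(path: str | Path, obo_path: str | Path) -> GeneAnnotation:
    """Load gene->GO annotations (two-column TSV or GAF 2.x) plus an OBO DAG.

    Annotations are propagated to all ancestors.  Terms absent from the DAG
    are dropped with a logged warning.
    """
    parents, names = _read_obo(obo_path)
    path = Path(path)
    gene_to_terms: dict[str, set[str]] = {}
    dropped: set[str] = set()
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            fields = line.split("\t")
            if len(fields) >= 5 and fields[4].startswith("GO:"):
                gene, term = fields[1], fields[4]  # GAF columns 2 and 5
            elif len(fields) >= 2:
                gene, term = fields[0], fields[1]  # two-column TSV
            else:
                continue
            if gene == "gene" and not term.startswith("GO:"):
                continue  # header row
            if term not in parents:
                dropped.add(term)
                continue
            gene_to_terms.setdefault(gene, set()).add(term)
    if dropped:
        logger.warning("dropped %d annotation term(s) absent from the DAG: %s",
                       len(dropped), sorted(dropped))
    ann = GeneAnnotation(gene_to_terms, parents, names)
    return ann.propagate()


# ---------------------------------------------------------------------------
# Orthologs and sequences
# ---------------------------------------------------------------------------

@dataclass
class OrthologMap:
    """Deduplicated list of (species-A gene, species-B gene) pairs."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.pairs = list(dict.fromkeys(tuple(p) for p in self.pairs))

    def restrict(self, genes_a: Iterable[str], genes_b: Iterable[str]) -> "OrthologMap":
        sa, sb = set(genes_a), set(genes_b)
        return OrthologMap([(a, b) for a, b in self.pairs if a in sa and b in sb])

    def __len__(self) -> int:
        return len(self.pairs)


def read_orthologs(path: str | Path) -> OrthologMap:
    """Two-column TSV of ortholog gene pairs (header optional)."""
    pairs: list[tuple[str, str]] = []
    with Path(path).open(encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}: line {i + 1}: expected 2 columns")
            if i == 0 and fields[:2] in (["gene_a", "gene_b"], ["source", "target"]):
                continue
            pairs.append((fields[0], fields[1]))
    return OrthologMap(pairs)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Amino-acid FASTA -> {gene id: sequence}; duplicate ids are an error
    (one protein sequence per gene id is required)."""
    from Bio import SeqIO

    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValidationError(f"{path}: duplicate sequence id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs
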