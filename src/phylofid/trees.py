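"""Phylogeny I/O, validation and the phylogenetic variance-covariance matrix.

Trees are rooted, with branch lengths in arbitrary (but consistent) units.
Under Brownian motion a rooted tree with branch lengths implies an expected
variance-covariance matrix for a trait measured at the tips: entry (i, j) is
the shared root-to-MRCA path length of tips i and j, and the diagonal holds
total root-to-tip depths.  That matrix is the foundation of every GLS fit in
this package.

Parsing and tree surgery are delegated to :mod:`dendropy`; this module adds
validation (unique tip labels, branch lengths present), taxon-name matching
against trait tables, and the covariance construction.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "PhyloCovariance",
    "TreeValidationError",
    "TreeParseError",
    "TaxonMatchError",
    "normalize_label",
    "match_taxa",
]


class TreeParseError(ValueError):
    """Raised when Newick/NEXUS text cannot be parsed."""


class TreeValidationError(ValueError):
    """Raised when a parsed tree violates a structural invariant."""


class TaxonMatchError(KeyError):
    """Raised when tree tips and trait-table species cannot be reconciled."""


def normalize_label(label: str) -> str:
    """Canonical form used to match tree tips to trait-table species.

    Whitespace is trimmed and underscores are treated as spaces (the two
    conventions Newick files mix freely).  Case is preserved.
    """
    return " ".join(str(label).strip().replace("_", " ").split())


def match_taxa(tree_labels, table_species):
    """Map each table species to its tree tip label.

    Returns ``dict`` of ``species -> tip label``.  Raises
    :class:`TaxonMatchError` listing *all* table species with no matching
    tip; species are never silently dropped.
    """
    lookup = {}
    for lab in tree_labels:
        lookup.setdefault(normalize_label(lab), lab)
    mapping, missing = {}, []
    for sp in table_species:
        key = normalize_label(sp)
        if key in lookup:
            mapping[sp] = lookup[key]
        else:
            missing.append(str(sp))
    if missing:
        raise TaxonMatchError(
            "species absent from tree: " + ", ".join(sorted(missing))
        )
    return mapping


@dataclass
class PhyloCovariance:
    """Phylogenetic variance-covariance matrix with its taxon order.

    ``matrix[i, j]`` is the shared root-to-MRCA path length of taxa i and j;
    ``matrix[i, i]`` the root-to-tip depth of taxon i.  Symmetric and
    positive semi-definite by construction.
    """

    taxa: list[str]
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.taxa)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match number of taxa")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("covariance matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.taxa)

    def lambda_transform(self, lam: float) -> "PhyloCovariance":
        """Pagel's λ transform: multiply off-diagonal entries by ``lam``.

        λ=1 leaves the matrix untouched (full Brownian signal); λ=0 collapses
        all shared history, leaving a diagonal matrix (no signal, equivalent
        to independent observations for ultrametric trees).
        """
        if not 0.0 <= lam <= 1.0:
            raise ValueError(f"lambda must lie in [0, 1], got {lam}")
        out = self.matrix * lam
        np.fill_diagonal(out, np.diag(self.matrix))
        return PhyloCovariance(list(self.taxa), out)

    def align(self, order) -> "PhyloCovariance":
        """Reorder rows/columns to ``order`` (labels matched after
        normalization); raises :class:`TaxonMatchError` on missing taxa."""
        mapping = match_taxa(self.taxa, order)
        pos = {lab: i for i, lab in enumerate(self.taxa)}
        idx = [pos[mapping[sp]] for sp in order]
        return PhyloCovariance([str(s) for s in order],
                               self.matrix[np.ix_(idx, idx)])


class Phylogeny:
    """A validated rooted phylogeny (thin wrapper over ``dendropy.Tree``).

    Invariants enforced at construction: unique tip labels, every non-root
    edge has a (non-negative) branch length.  Zero-length branches are legal
    — consensus trees produce them — and any resulting covariance singularity
    is the GLS layer's problem to detect, not this one's.
    """

    def __init__(self, tree: dendropy.Tree, label: str | None = None):
        self._tree = tree
        self.label = label
        self._validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_string(cls, text: str, schema: str | None = None,
                    label: str | None = None) -> "Phylogeny":
        """Parse a single tree from Newick or NEXUS text.

        ``schema`` is auto-detected from a leading ``#NEXUS`` when omitted.
        """
        if schema is None:
            schema = "nexus" if text.lstrip().upper().startswith("#NEXUS") else "newick"
        try:
            tree = dendropy.Tree.get(data=text, schema=schema,
                                     rooting="force-rooted")
        except Exception as exc:  # dendropy raises several error types
            raise TreeParseError(f"could not parse {schema} tree: {exc}") from exc
        return cls(tree, label=label)

    @classmethod
    def from_file(cls, path, schema: str | None = None,
                  index: int = 0, label: str | None = None) -> "Phylogeny":
        """Read one tree from a (possibly multi-tree) Newick/NEXUS file.

        ``index`` selects within a multi-tree file; ``label`` (if the file
        names its trees) takes precedence over ``index``.
        """
        with open(path) as fh:
            text = fh.read()
        if schema is None:
            schema = "nexus" if text.lstrip().upper().startswith("#NEXUS") else "newick"
        try:
            trees = dendropy.TreeList.get(data=text, schema=schema,
                                          rooting="force-rooted")
        except Exception as exc:
            raise TreeParseError(f"could not parse {schema} file {path}: {exc}") from exc
        if not trees:
            raise TreeParseError(f"no trees found in {path}")
        if label is not None:
            for t in trees:
                if t.label == label:
                    return cls(t, label=label)
            raise TreeParseError(f"no tree labelled {label!r} in {path}")
        try:
            tree = trees[index]
        except IndexError:
            raise TreeParseError(
                f"tree index {index} out of range ({len(trees)} trees in {path})"
            ) from None
        return cls(tree, label=tree.label)

    def _validate(self):
        labels = self.tips
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeValidationError(f"duplicate tip labels: {dupes}")
        missing = [
            self._node_name(nd)
            for nd in self._tree.preorder_node_iter()
            if nd.parent_node is not None and nd.edge.length is None
        ]
        if missing:
            raise TreeValidationError(
                f"{len(missing)} branch(es) lack a length (first few: "
                f"{missing[:5]}); assign lengths explicitly, they are not defaulted"
            )
        for nd in self._tree.preorder_node_iter():
            if nd.parent_node is not None and nd.edge.length < 0:
                raise TreeValidationError(
                    f"negative branch length on edge above {self._node_name(nd)}"
                )

    @staticmethod
    def _node_name(nd) -> str:
        if nd.taxon is not None and nd.taxon.label:
            return nd.taxon.label
        return nd.label or "<internal>"

    # -- basic queries -------------------------------------------------

    @property
    def tips(self) -> list[str]:
        """Tip labels in the tree's leaf-iteration order."""
        return [lf.taxon.label for lf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    def is_bifurcating(self) -> bool:
        return all(
            len(nd.child_nodes()) in (0, 2)
            for nd in self._tree.preorder_node_iter()
        )

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        depths = np.array(list(self._depths().values()))
        return bool(np.ptp(depths) <= tol * max(1.0, depths.max()))

    def _depths(self) -> dict[str, float]:
        out = {}
        for lf in self._tree.leaf_node_iter():
            d, nd = 0.0, lf
            while nd.parent_node is not None:
                d += nd.edge.length
                nd = nd.parent_node
            out[lf.taxon.label] = d
        return out

    def _clone(self) -> dendropy.Tree:
        return self._tree.clone(depth=1)

    # -- transforms ----------------------------------------------------

    def resolve_polytomies(self, rng=None) -> "Phylogeny":
        """Return a strictly bifurcating copy.

        Multifurcations are broken arbitrarily; every inserted internal
        branch gets length exactly 0, so the implied covariance matrix is
        unchanged by the resolution.
        """
        tree = self._clone()
        tree.resolve_polytomies(rng=rng)
        for nd in tree.preorder_node_iter():
            if nd.parent_node is not None and nd.edge.length is None:
                nd.edge.length = 0.0
        return Phylogeny(tree, label=self.label)

    def with_equal_branch_lengths(self, length: float = 1.0) -> "Phylogeny":
        """Copy with every branch set to ``length`` (topology untouched).

        The standard fallback when a source tree carries no usable branch
        lengths."""
        tree = self._clone()
        for nd in tree.preorder_node_iter():
            if nd.parent_node is not None:
                nd.edge.length = float(length)
        return Phylogeny(tree, label=self.label)

    def scaled(self, factor: float) -> "Phylogeny":
        """Copy with every branch length multiplied by ``factor``."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        tree = self._clone()
        for nd in tree.preorder_node_iter():
            if nd.parent_node is not None:
                nd.edge.length *= factor
        return Phylogeny(tree, label=self.label)

    def pruned_to(self, species) -> "Phylogeny":
        """Copy restricted to the given species (matched after
        normalization); errors list every species absent from the tree."""
        mapping = match_taxa(self.tips, species)
        tree = self._clone()
        tree.retain_taxa_with_labels(list(mapping.values()))
        return Phylogeny(tree, label=self.label)

    # -- covariance ----------------------------------------------------

    def vcv(self) -> PhyloCovariance:
        """Phylogenetic variance-covariance matrix.

        Built by accumulating each branch length onto every pair of tips
        descending from it; (i, j) ends up as the root-to-MRCA shared path,
        (i, i) as the root-to-tip depth.
        """
        taxa = self.tips
        idx = {lab: i for i, lab in enumerate(taxa)}
        C = np.zeros((len(taxa), len(taxa)))
        for nd in self._tree.preorder_node_iter():
            if nd.parent_node is None:
                continue
            below = [idx[lf.taxon.label] for lf in nd.leaf_iter()]
            C[np.ix_(below, below)] += nd.edge.length
        return PhyloCovariance(taxa, C)

    # -- serialization -------------------------------------------------

    def to_newick(self) -> str:
        """Canonical Newick string (branch lengths at full precision)."""
        return self._tree.as_string(
            schema="newick", suppress_rooting=True, real_value_format_specifier=".17g"
        ).strip()

    def write_newick(self, path):
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    def __repr__(self):
        lab = f" {self.label!r}" if self.label else ""
        return f"<Phylogeny{lab}: {self.n_tips} tips>"
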