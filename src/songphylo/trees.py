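"""Phylogenies, pure-birth tree simulation, and Brownian-motion trait evolution.

A :class:`Phylogeny` wraps a rooted :class:`dendropy.Tree` and exposes the two
matrices comparative analyses need:

* the **patristic distance** matrix (sum of branch lengths between tips), which
  plays the role of phylogenetic distance in Mantel-family tests;
* the **shared-path** matrix (root-to-MRCA path length per tip pair), which is
  the covariance kernel of Brownian motion on the tree: under BM with rate
  ``sigma2``, ``cov(x_i, x_j) = sigma2 * shared_path(i, j)``.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Phylogeny",
    "EXAMPLE_SPECIES",
    "EXAMPLE_TREE_NEWICK",
    "example_tree",
    "simulate_tree",
    "simulate_bm_traits",
    "bm_trait_replicates",
]

#: Species codes for the seven estrildid finches used in the worked examples:
#: three Australian (ZF, LF, DF), three African (RF, CB, GW), one Southeast
#: Asian (BF).
EXAMPLE_SPECIES = ("ZF", "LF", "DF", "RF", "CB", "GW", "BF")

#: Example 7-species topology with the three biogeographical clades and
#: placeholder (unit-scale, ultrametric) branch lengths. Real analyses should
#: supply a tree with estimated branch lengths; this one encodes topology only.
EXAMPLE_TREE_NEWICK = (
    "(((ZF:1.0,(LF:0.5,DF:0.5):0.5):1.0,"
    "((RF:0.5,CB:0.5):0.5,GW:1.0):1.0):1.0,BF:3.0);"
)


@dataclass
class Phylogeny:
    """A rooted phylogeny with branch lengths, keyed by unique tip names."""

    tree: dendropy.Tree
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "Phylogeny":
        tree = dendropy.Tree.get(path=str(path), schema="newick")
        return cls(tree)

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()

    @property
    def tip_names(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tip_names)

    def _root_paths(self):
        """Per tip: dict mapping each ancestor node id -> its root distance."""
        if "paths" in self._cache:
            return self._cache["paths"]
        paths: dict[str, dict[int, float]] = {}
        depths: dict[str, float] = {}
        for leaf in self.tree.leaf_node_iter():
            d = 0.0
            node = leaf
            chain = []
            while node is not None:
                chain.append(node)
                node = node.parent_node
            # root distance of each ancestor, computed root-down
            anc = {}
            dist = 0.0
            for node in reversed(chain):
                if node.edge.length is not None:
                    dist += node.edge.length
                anc[id(node)] = dist
            paths[leaf.taxon.label] = anc
            depths[leaf.taxon.label] = dist
        self._cache["paths"] = (paths, depths)
        return paths, depths

    def shared_path_matrix(self) -> pd.DataFrame:
        """Root-to-MRCA path length for every tip pair (BM covariance kernel)."""
        paths, depths = self._root_paths()
        names = self.tip_names
        k = len(names)
        out = np.zeros((k, k))
        for i, a in enumerate(names):
            out[i, i] = depths[a]
            for j in range(i + 1, k):
                b = names[j]
                common = paths[a].keys() & paths[b].keys()
                shared = max(paths[a][n] for n in common)
                out[i, j] = out[j, i] = shared
        return pd.DataFrame(out, index=names, columns=names)

    def patristic_matrix(self) -> pd.DataFrame:
        """Pairwise sum of branch lengths between tips."""
        shared = self.shared_path_matrix()
        depths = np.diag(shared.to_numpy())
        d = depths[:, None] + depths[None, :] - 2.0 * shared.to_numpy()
        np.fill_diagonal(d, 0.0)
        return pd.DataFrame(d, index=shared.index, columns=shared.columns)


def example_tree() -> Phylogeny:
    """The bundled 7-species example topology with placeholder branch lengths."""
    return Phylogeny.from_newick(EXAMPLE_TREE_NEWICK)


def simulate_tree(n_tips: int, seed: int) -> Phylogeny:
    """Simulate a pure-birth (Yule) tree with ``n_tips`` extant tips.

    Tips are labelled ``sp01 .. spNN``. Deterministic given ``seed``.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    from dendropy.model import birthdeath

    rng = random.Random(int(seed))
    tree = birthdeath.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=rng,
    )
    # the simulator stops at the n-th birth, leaving zero-length tip edges;
    # extend all extant tips by the waiting time to the next (uncounted) event
    # so the tree stays ultrametric with distinct tip positions
    extra = rng.expovariate(n_tips * 1.0)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    width = max(2, len(str(n_tips)))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        label = f"sp{i:0{width}d}"
        leaf.taxon = tree.taxon_namespace.new_taxon(label=label) if leaf.taxon is None else leaf.taxon
        leaf.taxon.label = label
    return Phylogeny(tree)


def _bm_chol(tree: Phylogeny) -> tuple[np.ndarray, list[str]]:
    shared = tree.shared_path_matrix()
    cov = shared.to_numpy()
    # tiny jitter keeps Cholesky stable when two tips share ~all their path
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(cov.shape[0]))
    return chol, list(shared.index)


def simulate_bm_traits(tree: Phylogeny, sigma2: float, seed: int) -> pd.Series:
    """One draw of a univariate trait evolving by Brownian motion on the tree.

    Tip values are jointly Gaussian, zero-mean at the root, with
    ``cov(i, j) = sigma2 * shared_path(i, j)``. Scaling ``sigma2`` by ``c``
    scales the same-seed draw by ``sqrt(c)``.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    chol, names = _bm_chol(tree)
    rng = np.random.default_rng(int(seed))
    z = rng.standard_normal(len(names))
    values = np.sqrt(sigma2) * (chol @ z)
    return pd.Series(values, index=names, name="trait")


def bm_trait_replicates(
    tree: Phylogeny, n: int, sigma2: float = 1.0, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """``n`` independent BM trait draws (rows) over the tree tips (columns)."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    rng = np.random.default_rng() if rng is None else rng
    chol, names = _bm_chol(tree)
    z = rng.standard_normal((n, len(names)))
    return pd.DataFrame(np.sqrt(sigma2) * (z @ chol.T), columns=names)
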