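"""Blomberg's K phylogenetic-signal test on dated phylogenies.

Blomberg's K compares the observed ratio of the trait's non-phylogenetic
mean squared error (MSE0, about the phylogenetically weighted mean) to its
phylogenetic MSE (under the tree's variance-covariance structure) against
the ratio expected under Brownian motion:

    K = (MSE0 / MSE)_observed / (MSE0 / MSE)_expected

with the phylogenetic mean  a = (1' V^-1 1)^-1 1' V^-1 x,
MSE0 = (x - a)'(x - a) / (n - 1),  MSE = (x - a)' V^-1 (x - a) / (n - 1)
and expected ratio (tr(V) - n / (1' V^-1 1)) / (n - 1),
where V[i, j] is the branch length shared by the root-to-tip paths of tips
i and j (in the tree's time units, e.g. million years).  K = 1 matches
Brownian motion; K > 1 indicates stronger-than-Brownian conservation.
Significance comes from shuffling trait values across tips and counting
permuted K at least as large as the observed one, with the (count + 1) /
(n_perm + 1) estimator (one-sided: the test is for presence of signal).

Tree utilities cover Newick round-trips, pruning, genus-level tip addition
(for species absent from a reference phylogeny) and rename maps for
taxonomic updates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd

from .errors import TreeError


# ---------------------------------------------------------------------------
# tree I/O and editing
# ---------------------------------------------------------------------------

def read_newick(source: str) -> dendropy.Tree:
    """Parse a Newick string (or path ending in .nwk/.tre/.newick/.txt).

    Requires branch lengths on all non-root edges and unique tip labels;
    the tree is treated as rooted at its first node.
    """
    import os

    kwargs = {"schema": "newick", "preserve_underscores": True}
    try:
        if isinstance(source, str) and not source.lstrip().startswith("(") \
                and os.path.exists(source):
            tree = dendropy.Tree.get(path=source, **kwargs)
        else:
            tree = dendropy.Tree.get(data=source, **kwargs)
    except Exception as exc:  # dendropy raises schema-specific errors
        raise TreeError(f"invalid Newick input: {exc}") from exc
    tree.is_rooted = True
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise TreeError("duplicate tip labels")
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if node.edge.length is None:
            raise TreeError("missing branch length")
        if node.edge.length < 0:
            raise TreeError("negative branch length")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True,
                          unquoted_underscores=True).strip()


def tip_labels(tree: dendropy.Tree) -> list:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def prune(tree: dendropy.Tree, tips: Iterable[str]) -> dendropy.Tree:
    """Retain exactly the requested tips; unary nodes are collapsed with
    branch lengths summed, so patristic distances are preserved."""
    tips = list(tips)
    have = set(tip_labels(tree))
    missing = sorted(set(tips) - have)
    if missing:
        raise TreeError(f"tips not in tree: {missing}")
    pruned = tree.clone(depth=1)
    pruned.retain_taxa_with_labels(tips)
    pruned.purge_taxon_namespace()
    return pruned


def rename_tips(tree: dendropy.Tree, rename_map: Mapping[str, str]) -> dendropy.Tree:
    """Relabel tips via an explicit old -> new map (taxonomic updates)."""
    out = tree.clone(depth=1)
    for lf in out.leaf_node_iter():
        if lf.taxon.label in rename_map:
            lf.taxon.label = rename_map[lf.taxon.label]
    return out


def _genus(label: str) -> str:
    """Genus = first token of a binomial tip label (space- or
    underscore-delimited, matching Newick conventions)."""
    import re

    parts = re.split(r"[\s_]+", label.strip())
    return parts[0] if parts else ""


def _find_leaf(tree: dendropy.Tree, label: str):
    for lf in tree.leaf_node_iter():
        if lf.taxon.label == label:
            return lf
    raise TreeError(f"tip {label!r} not in tree")


def add_tip_to_genus(tree: dendropy.Tree, species_name: str) -> dendropy.Tree:
    """Attach a species to its genus clade (genus = first word of the tip
    label).

    With two or more congeners the new tip hangs from their MRCA with a
    pendant branch equal to the mean depth of the clade below it, so an
    ultrametric tree stays ultrametric.  With a single congener the new tip
    attaches at the midpoint of that terminal branch (avoiding a basal
    trichotomy), again preserving tip depths.  A species already present
    returns the tree unchanged; a genus with no congeners raises.
    """
    out = tree.clone(depth=1)
    labels = tip_labels(out)
    if species_name in labels:
        return out
    genus = _genus(species_name)
    congeners = [lb for lb in labels if _genus(lb) == genus]
    if not congeners:
        raise TreeError(f"no congeneric tip for {species_name!r} (genus {genus!r})")
    taxon = dendropy.Taxon(label=species_name)
    out.taxon_namespace.add_taxon(taxon)
    if len(congeners) == 1:
        leaf = _find_leaf(out, congeners[0])
        length = leaf.edge.length
        parent = leaf.parent_node
        parent.remove_child(leaf)
        mid = parent.new_child(edge_length=length / 2.0)
        mid.add_child(leaf)
        leaf.edge.length = length / 2.0
        mid.new_child(taxon=taxon, edge_length=length / 2.0)
    else:
        mrca = out.mrca(taxon_labels=congeners)
        mrca_depth = mrca.distance_from_root()
        depths = [lf.distance_from_root() - mrca_depth
                  for lf in mrca.leaf_iter()]
        mrca.new_child(taxon=taxon, edge_length=float(np.mean(depths)))
    return out


def exclude_genera(tree: dendropy.Tree, genera: Sequence[str]) -> dendropy.Tree:
    """Prune away every tip belonging to the given genera (e.g. the
    Pinaceae-exclusion analysis drops Pinus and Picea)."""
    keep = [lb for lb in tip_labels(tree) if _genus(lb) not in set(genera)]
    if not keep:
        raise TreeError("excluding these genera would empty the tree")
    return prune(tree, keep)


# ---------------------------------------------------------------------------
# variance-covariance matrix and K
# ---------------------------------------------------------------------------

def phylo_vcv(tree: dendropy.Tree) -> pd.DataFrame:
    """Shared-branch-length matrix V over tips.

    ``V[i, j]`` is the depth of the MRCA of tips i and j below the root
    (the branch length their root-to-tip paths share); the diagonal holds
    tip depths.  Symmetric positive semi-definite for valid trees.
    """
    leaves = list(tree.leaf_node_iter())
    if len(leaves) < 2:
        raise TreeError("V needs at least 2 tips")
    labels = [lf.taxon.label for lf in leaves]
    index = {lf: i for i, lf in enumerate(leaves)}
    n = len(leaves)
    depth = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            # a root stem (e.g. left by pruning) is shared by all tips
            depth[node] = float(node.edge.length or 0.0)
        else:
            el = node.edge.length
            if el is None:
                raise TreeError("missing branch length")
            depth[node] = depth[node.parent_node] + el
    V = np.zeros((n, n))
    tipsets = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[node]
            tipsets[node] = [i]
            V[i, i] = depth[node]
            continue
        children = [tipsets[c] for c in node.child_nodes()]
        for a in range(len(children)):
            for b in range(a + 1, len(children)):
                ia = np.asarray(children[a])
                ib = np.asarray(children[b])
                V[np.ix_(ia, ib)] = depth[node]
                V[np.ix_(ib, ia)] = depth[node]
        tipsets[node] = [i for sub in children for i in sub]
    return pd.DataFrame(V, index=labels, columns=labels)


def _k_batch(V: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Blomberg's K for each row of X (traits aligned with V's tips)."""
    n = V.shape[0]
    try:
        Vinv = np.linalg.inv(V)
    except np.linalg.LinAlgError as exc:
        raise TreeError("singular phylogenetic covariance matrix") from exc
    ones = np.ones(n)
    Vinv1 = Vinv @ ones
    denom = float(ones @ Vinv1)
    w = Vinv1 / denom
    ahat = X @ w
    D = X - ahat[:, None]
    mse0 = np.einsum("mi,mi->m", D, D) / (n - 1)
    mse = np.einsum("mi,ij,mj->m", D, Vinv, D) / (n - 1)
    if np.any(mse <= 0) or np.any(mse0 <= 0):
        raise ValueError("constant trait: K undefined")
    expected = (np.trace(V) - n / denom) / (n - 1)
    return (mse0 / mse) / expected


def _aligned_trait(tree: dendropy.Tree, trait) -> Tuple[pd.DataFrame, np.ndarray]:
    V = phylo_vcv(tree)
    trait = pd.Series(trait, dtype=float)
    missing = [lb for lb in V.index if lb not in trait.index]
    if missing:
        raise TreeError(f"trait missing for tips: {missing[:5]}")
    x = trait.reindex(V.index).to_numpy()
    if not np.all(np.isfinite(x)):
        raise ValueError("trait contains non-finite values")
    if np.ptp(x) == 0:
        raise ValueError("constant trait: K undefined")
    return V, x


def blombergs_k(tree: dendropy.Tree, trait) -> float:
    """Observed Blomberg's K for a trait keyed by tip label."""
    V, x = _aligned_trait(tree, trait)
    return float(_k_batch(V.to_numpy(), x[None, :])[0])


@dataclass
class KResult:
    """Blomberg's K with its randomization test."""

    k_observed: float
    p_value: float
    n_permutations: int
    seed: int
    permuted_mean: float
    permuted_sd: float
    permuted_q95: float

    def as_dict(self) -> dict:
        return {
            "k_observed": self.k_observed,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "permuted_mean": self.permuted_mean,
            "permuted_sd": self.permuted_sd,
            "permuted_q95": self.permuted_q95,
        }


def k_randomization_test(
    tree: dendropy.Tree,
    trait,
    n_perm: int = 1000,
    seed: int = 0,
) -> KResult:
    """One-sided randomization test for phylogenetic signal.

    Trait values are shuffled across tips ``n_perm`` times;
    ``p = (1 + #{K_perm >= K_obs}) / (n_perm + 1)`` (never exactly zero).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    V, x = _aligned_trait(tree, trait)
    Vm = V.to_numpy()
    k_obs = float(_k_batch(Vm, x[None, :])[0])
    rng = np.random.default_rng(int(seed))
    perms = rng.permuted(np.tile(x, (int(n_perm), 1)), axis=1)
    k_perm = _k_batch(Vm, perms)
    p = (1.0 + float(np.sum(k_perm >= k_obs))) / (n_perm + 1.0)
    return KResult(
        k_observed=k_obs,
        p_value=p,
        n_permutations=int(n_perm),
        seed=int(seed),
        permuted_mean=float(k_perm.mean()),
        permuted_sd=float(k_perm.std(ddof=1)),
        permuted_q95=float(np.quantile(k_perm, 0.95)),
    )


def read_trait_csv(path, species_col: str = "species", value_col: str = "value") -> pd.Series:
    """Read a trait CSV (species, value) into a Series keyed by species."""
    df = pd.read_csv(path)
    if species_col not in df.columns or value_col not in df.columns:
        species_col, value_col = df.columns[:2]
    s = pd.Series(df[value_col].to_numpy(dtype=float),
                  index=df[species_col].astype(str))
    if s.index.duplicated().any():
        raise TreeError("duplicate species in trait table")
    return s
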