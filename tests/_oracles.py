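"""Independent oracles used by the test suite.

Each oracle recomputes a quantity by a route unrelated to the package's
own implementation: exhaustive enumeration, closed forms, or an external
fitter (statsmodels GLM).  They are deliberately slow and simple.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# Logistic detection model: statsmodels GLM on the masked cells
# ---------------------------------------------------------------------------


def statsmodels_probs(detection) -> pd.DataFrame:
    """Fitted p_ij for every (gene, species) via statsmodels' binomial GLM
    with gene and species factor dummies."""
    import statsmodels.api as sm

    rows = []
    for g in detection.genes:
        for s in detection.species:
            if detection.mask.at[g, s]:
                rows.append((g, s, detection.data.at[g, s]))
    frame = pd.DataFrame(rows, columns=["gene", "species", "y"])
    X = pd.get_dummies(frame[["gene", "species"]], drop_first=False)
    # drop one species dummy: corner identifiability, intercept absorbed in genes
    species_cols = [c for c in X.columns if c.startswith("species_")]
    X = X.drop(columns=species_cols[:1]).astype(float)
    model = sm.GLM(frame["y"], X, family=sm.families.Binomial()).fit(maxiter=200)
    coefs = model.params
    alphas = {c.removeprefix("gene_"): coefs[c] for c in X.columns if c.startswith("gene_")}
    betas = {c.removeprefix("species_"): coefs[c] for c in X.columns if c.startswith("species_")}
    ref_species = species_cols[0].removeprefix("species_")
    betas[ref_species] = 0.0
    out = pd.DataFrame(index=detection.genes, columns=detection.species, dtype=float)
    for g in alphas:
        for s in betas:
            out.at[g, s] = 1.0 / (1.0 + np.exp(-(alphas[g] + betas[s])))
    return out


def is_separated(detection) -> bool:
    """True if any masked gene or species row is all-0 or all-1 (no finite MLE)."""
    for axis, ids in ((1, detection.genes), (0, detection.species)):
        for k, _ in enumerate(ids):
            vals = (
                detection.data.iloc[k][detection.mask.iloc[k]]
                if axis == 1
                else detection.data.iloc[:, k][detection.mask.iloc[:, k]]
            )
            if len(vals) and (vals.min() == 1.0 or vals.max() == 0.0):
                return True
    return False


# ---------------------------------------------------------------------------
# Mk model: exhaustive enumeration over ancestral assignments
# ---------------------------------------------------------------------------


def _edges_and_nodes(tree):
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    leaves = list(tree.leaf_node_iter())
    return internals, leaves


def enumeration_likelihood_and_marginals(tree, traits, model):
    """Total likelihood and per-internal-node marginals by brute force:
    sum the joint probability over every assignment of states to the
    internal nodes."""
    from symbiodrop.ancestral import _STATE_INDEX, _branch_length

    internals, leaves = _edges_and_nodes(tree)
    prior = model.prior()
    total = 0.0
    marg = {id(n): np.zeros(2) for n in internals}
    for assign in product(range(2), repeat=len(internals)):
        states = {id(n): a for n, a in zip(internals, assign)}
        for leaf in leaves:
            states[id(leaf)] = _STATE_INDEX[traits[leaf.taxon.label]]
        p = prior[states[id(tree.seed_node)]]
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            P = model.transition_matrix(_branch_length(node))
            p *= P[states[id(node.parent_node)], states[id(node)]]
        total += p
        for n in internals:
            marg[id(n)][states[id(n)]] += p
    marginals = {id(n): marg[id(n)] / total for n in internals}
    return total, marginals


def enumeration_min_changes(tree, traits) -> int:
    """Parsimony minimum by exhaustive minimization over assignments."""
    from symbiodrop.ancestral import _STATE_INDEX

    internals, leaves = _edges_and_nodes(tree)
    best = None
    for assign in product(range(2), repeat=len(internals)):
        states = {id(n): a for n, a in zip(internals, assign)}
        for leaf in leaves:
            states[id(leaf)] = _STATE_INDEX[traits[leaf.taxon.label]]
        changes = sum(
            states[id(n.parent_node)] != states[id(n)]
            for n in tree.preorder_node_iter()
            if n.parent_node is not None
        )
        best = changes if best is None else min(best, changes)
    return best


# ---------------------------------------------------------------------------
# Ortholog groups: clade enumeration + subset maximality
# ---------------------------------------------------------------------------


def brute_force_ogs(family) -> set[frozenset]:
    """Maximal species-unique clades found by enumerating every clade's
    tip set and discarding those contained in a larger unique clade."""
    tree = family.tree
    clade_tipsets = []
    for node in tree.preorder_node_iter():
        tips = frozenset(l.taxon.label for l in node.leaf_iter())
        clade_tipsets.append(tips)
    unique = [
        ts
        for ts in clade_tipsets
        if len({family.species_map[g] for g in ts}) == len(ts)
    ]
    maximal = [
        ts for ts in unique if not any(ts < other for other in unique)
    ]
    return {
        frozenset((family.species_map[g], g) for g in ts) for ts in maximal
    }


# ---------------------------------------------------------------------------
# Background gene loss: probability propagation down a fixed tree
# ---------------------------------------------------------------------------


def expected_absent_species(tree, loss_rate: float) -> float:
    """Expected number of tips lacking a gene under irreversible
    per-branch loss: each tip at edge-depth d is lost with probability
    1 - (1 - r)^d."""
    total = 0.0
    depth = {id(tree.seed_node): 0}
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            depth[id(node)] = depth[id(node.parent_node)] + 1
        if node.is_leaf():
            total += 1.0 - (1.0 - loss_rate) ** depth[id(node)]
    return total


# ---------------------------------------------------------------------------
# Random tree generators for property tests
# ---------------------------------------------------------------------------


def random_gene_family_newick(rng: np.random.Generator, max_tips: int = 12,
                              n_species: int = 5) -> str:
    """Random binary topology whose tips are genes labeled g{i}_s{j}
    with species drawn from a small pool (duplications likely)."""
    n_tips = int(rng.integers(1, max_tips + 1))
    labels = [
        f"g{i+1}_s{int(rng.integers(1, n_species + 1))}" for i in range(n_tips)
    ]

    def build(items: list[str]) -> str:
        if len(items) == 1:
            return items[0]
        split = int(rng.integers(1, len(items)))
        return f"({build(items[:split])},{build(items[split:])})"

    order = list(rng.permutation(labels))
    return build(order) + ";"


def random_species_newick(rng: np.random.Generator, n_tips: int) -> str:
    labels = [f"t{i+1}" for i in range(n_tips)]

    def build(items: list[str]) -> str:
        if len(items) == 1:
            return items[0] + ":1.0"
        split = int(rng.integers(1, len(items)))
        return f"({build(items[:split])},{build(items[split:])}):1.0"

    return build(list(rng.permutation(labels)))[: -len(":1.0")] + ";"
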