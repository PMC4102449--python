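"""Maximum-likelihood ancestral reconstruction of a binary trait.

The host/non-host character evolves under a two-state continuous-time
Markov (Mk) model with instantaneous rates q01 (host -> non-host) and
q10 (back), either constrained equal (ER) or free (ARD).  The transition
matrix over a branch of length t has the closed form

    P(t) = pi + exp(-(q01+q10) t) * (I - pi)       (rows: from-state)

with pi the stationary distribution.  Tip data enter through the
standard pruning recursion; marginal ancestral state probabilities come
from an inside-outside pass and equal the re-rooted pruning computation
at every node.  Transition branches are edges whose endpoint
maximum-a-posteriori states differ, cross-checked against the Fitch
parsimony minimum.

Trees without branch lengths are given unit lengths.  The root prior is
equal by default (stationary optional).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import dendropy
import numpy as np
from scipy import optimize

from .io_formats import HOST, NON_HOST

STATES = (HOST, NON_HOST)
_STATE_INDEX = {HOST: 0, NON_HOST: 1}


class AncestralError(ValueError):
    pass


@dataclass(frozen=True)
class MkModel:
    q01: float
    q10: float
    kind: str = "ER"  # ER (equal rates) | ARD (all rates different)
    root_prior: str = "equal"  # equal | stationary

    def __post_init__(self) -> None:
        if self.q01 < 0 or self.q10 < 0:
            raise AncestralError("rates must be non-negative")
        if self.kind == "ER" and self.q01 != self.q10:
            raise AncestralError("equal-rates model requires q01 == q10")

    def transition_matrix(self, t: float) -> np.ndarray:
        a, b = self.q01, self.q10
        total = a + b
        if total == 0:
            return np.eye(2)
        pi = np.array([b, a]) / total
        decay = np.exp(-total * t)
        return np.array(
            [
                [pi[0] + pi[1] * decay, pi[1] * (1 - decay)],
                [pi[0] * (1 - decay), pi[1] + pi[0] * decay],
            ]
        )

    def prior(self) -> np.ndarray:
        if self.root_prior == "stationary" and self.q01 + self.q10 > 0:
            return np.array([self.q10, self.q01]) / (self.q01 + self.q10)
        return np.array([0.5, 0.5])


def _branch_length(node: dendropy.Node) -> float:
    return node.edge.length if node.edge.length is not None else 1.0


def _check_traits(tree: dendropy.Tree, traits: Mapping[str, str]) -> None:
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        if label not in traits:
            raise AncestralError(f"no trait value for tip {label!r}")
        if traits[label] not in _STATE_INDEX:
            raise AncestralError(f"trait for {label!r} must be host/non-host")


def _inside_pass(
    tree: dendropy.Tree, traits: Mapping[str, str], model: MkModel
) -> tuple[dict[int, np.ndarray], float]:
    """Pruning recursion: per node, P(tip data below node | node state)."""
    inside: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            vec = np.zeros(2)
            vec[_STATE_INDEX[traits[node.taxon.label]]] = 1.0
        else:
            vec = np.ones(2)
            for child in node.child_nodes():
                P = model.transition_matrix(_branch_length(child))
                vec = vec * (P @ inside[id(child)])
        inside[id(node)] = vec
    likelihood = float(model.prior() @ inside[id(tree.seed_node)])
    if likelihood <= 0:
        raise AncestralError("zero likelihood: conflicting states on zero branches")
    return inside, np.log(likelihood)


def mk_loglik(tree: dendropy.Tree, traits: Mapping[str, str], model: MkModel) -> float:
    _check_traits(tree, traits)
    return _inside_pass(tree, traits, model)[1]


def fit_mk(
    tree: dendropy.Tree,
    traits: Mapping[str, str],
    kind: str = "ER",
    root_prior: str = "equal",
    max_rate: float = 100.0,
) -> tuple[MkModel, float]:
    """Maximum-likelihood Mk rates via bounded deterministic search.

    With all tips in one state the rate MLE sits at the boundary 0 (no
    change ever observed); this is returned directly with a warning.
    """
    _check_traits(tree, traits)
    observed = {traits[leaf.taxon.label] for leaf in tree.leaf_node_iter()}
    if len(observed) == 1:
        warnings.warn(
            "all tips share one state; rate MLE at the 0 boundary", stacklevel=2
        )
        model = MkModel(0.0, 0.0, kind=kind, root_prior=root_prior)
        return model, mk_loglik(tree, traits, model)

    if kind == "ER":
        def nll(logq: float) -> float:
            q = float(np.exp(logq))
            return -mk_loglik(tree, traits, MkModel(q, q, "ER", root_prior))

        res = optimize.minimize_scalar(
            nll, bounds=(np.log(1e-8), np.log(max_rate)), method="bounded",
            options={"xatol": 1e-10},
        )
        q = float(np.exp(res.x))
        model = MkModel(q, q, "ER", root_prior)
    elif kind == "ARD":
        def nll2(logqs: np.ndarray) -> float:
            q01, q10 = np.exp(logqs)
            return -mk_loglik(
                tree, traits, MkModel(float(q01), float(q10), "ARD", root_prior)
            )

        res = optimize.minimize(
            nll2,
            x0=np.zeros(2),
            method="L-BFGS-B",
            bounds=[(np.log(1e-8), np.log(max_rate))] * 2,
        )
        q01, q10 = (float(v) for v in np.exp(res.x))
        model = MkModel(q01, q10, "ARD", root_prior)
    else:
        raise AncestralError(f"unknown model kind {kind!r}")
    return model, mk_loglik(tree, traits, model)


@dataclass
class AncestralReconstruction:
    """Marginal state probabilities and inferred transitions."""

    node_probs: dict[str, np.ndarray]  # node id -> (P(host), P(non-host))
    node_states: dict[str, str]  # MAP state per node (ties -> parent state)
    model: MkModel
    loglik: float
    transitions: list[tuple[str, str]] = field(default_factory=list)
    n_transitions: int = 0
    parsimony_changes: int = 0
    node_ids: dict[int, str] = field(repr=False, default_factory=dict)


def _node_id_map(tree: dendropy.Tree) -> dict[int, str]:
    ids: dict[int, str] = {}
    counter = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            ids[id(node)] = node.taxon.label
        elif node.label:
            ids[id(node)] = node.label
        else:
            ids[id(node)] = f"n{counter}"
            counter += 1
    return ids


def marginal_states(
    tree: dendropy.Tree, traits: Mapping[str, str], model: MkModel
) -> AncestralReconstruction:
    """Marginal ancestral probabilities via the inside-outside pass.

    ``outside[v]`` accumulates prior, transition and sibling terms from
    the rest of the tree, so ``outside * inside`` is proportional to the
    joint probability of the data with node v in each state; normalizing
    gives the marginal, identical to re-rooted pruning at v.
    """
    _check_traits(tree, traits)
    inside, loglik = _inside_pass(tree, traits, model)
    outside: dict[int, np.ndarray] = {id(tree.seed_node): model.prior()}
    for node in tree.preorder_node_iter():
        children = node.child_nodes()
        for child in children:
            sib = np.ones(2)
            for other in children:
                if other is not child:
                    P_o = model.transition_matrix(_branch_length(other))
                    sib = sib * (P_o @ inside[id(other)])
            P_c = model.transition_matrix(_branch_length(child))
            outside[id(child)] = P_c.T @ (outside[id(node)] * sib)

    ids = _node_id_map(tree)
    node_probs: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        joint = outside[id(node)] * inside[id(node)]
        node_probs[ids[id(node)]] = joint / joint.sum()

    # MAP states, resolving exact ties toward the parent's state
    node_states: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        probs = node_probs[ids[id(node)]]
        if np.isclose(probs[0], probs[1]):
            if node.parent_node is not None:
                state = node_states[ids[id(node.parent_node)]]
            else:
                state = STATES[0]
        else:
            state = STATES[int(np.argmax(probs))]
        node_states[ids[id(node)]] = state

    recon = AncestralReconstruction(
        node_probs=node_probs,
        node_states=node_states,
        model=model,
        loglik=loglik,
        node_ids=ids,
    )
    transitions = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        pid, cid = ids[id(node.parent_node)], ids[id(node)]
        if node_states[pid] != node_states[cid]:
            transitions.append((pid, cid))
    recon.transitions = transitions
    recon.n_transitions = len(transitions)
    recon.parsimony_changes = fitch_parsimony(tree, traits)
    return recon


def infer_transitions(recon: AncestralReconstruction) -> tuple[list[tuple[str, str]], int]:
    """Edges whose endpoint MAP states differ, with the count."""
    return recon.transitions, recon.n_transitions


def reconstruct(
    tree: dendropy.Tree,
    traits: Mapping[str, str],
    kind: str = "ER",
    root_prior: str = "equal",
) -> AncestralReconstruction:
    """Fit the Mk model and produce the full marginal reconstruction."""
    model, _ = fit_mk(tree, traits, kind=kind, root_prior=root_prior)
    return marginal_states(tree, traits, model)


def fitch_parsimony(tree: dendropy.Tree, traits: Mapping[str, str]) -> int:
    """Minimum number of state changes (standard Fitch down-pass)."""
    _check_traits(tree, traits)
    changes = 0
    sets: dict[int, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sets[id(node)] = frozenset({traits[node.taxon.label]})
        else:
            kids = [sets[id(c)] for c in node.child_nodes()]
            current = kids[0]
            for other in kids[1:]:
                inter = current & other
                if inter:
                    current = inter
                else:
                    current = current | other
                    changes += 1
            sets[id(node)] = current
    return changes
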