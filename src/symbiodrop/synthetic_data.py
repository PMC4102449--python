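"""Synthetic studies with the structure the gene-loss analyses assume.

A simulated study consists of a species tree with a single trait-loss
event (one clade of non-host species), three gene classes, genome
incompleteness, and a Bernoulli transcript-detection layer with
gene-level (expression) and species-level (coverage) effects on the
log-odds scale:

* ``conserved`` genes are present in every species;
* ``symbiosis-specific`` genes are present in every host species and
  absent from every species of the loss clade;
* ``background`` genes start present at the root and are lost
  irreversibly along branches at a fixed per-branch probability.

Every species carries a transcriptome (a column of the detection
matrix); genome-tagged species additionally contribute genome presence
calls.  In the observed matrix, genome cells are blanked to ``unknown``
at the incompleteness rate, and transcriptome-only columns hold
``present`` where a transcript was detected and ``unknown`` otherwise —
non-detection in a transcriptome is never evidence of absence.

All randomness flows through one ``numpy.random.default_rng`` (PCG64)
instance derived from the config seed, so identical configs give
bit-identical studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .detection_model import DetectionMatrix
from .io_formats import GENOME, HOST, NON_HOST, TRANSCRIPTOME, PresenceMatrix

CONSERVED = "conserved"
SYMBIOSIS = "symbiosis-specific"
BACKGROUND = "background"


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one synthetic study.

    Defaults emulate the scale of the study design this package targets:
    a panel of about 30 species with one clade of 5 that lost the trait,
    a small conserved reference set, a symbiotic toolkit of 20 genes and
    a few hundred background gene families.  Gene effects ``alpha`` and
    species effects ``beta`` are Normal on the log-odds scale; their
    defaults give conserved-gene detection rates in the high range
    typical of deep transcriptomes.
    """

    n_species: int = 30
    loss_clade_size: int = 5
    n_conserved: int = 10
    n_symbiosis: int = 20
    n_background: int = 300
    background_loss_rate: float = 0.05
    genome_mask_rate: float = 0.02
    alpha_mean: float = 1.0
    alpha_sd: float = 1.5
    beta_sd: float = 1.0
    false_positive_rate: float = 0.0
    transcriptome_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 4:
            raise ValueError("n_species must be >= 4")
        if not 1 <= self.loss_clade_size < self.n_species:
            raise ValueError("loss_clade_size must be in [1, n_species)")
        for name in ("background_loss_rate", "genome_mask_rate",
                     "false_positive_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        if not 0.0 <= self.transcriptome_fraction <= 1.0:
            raise ValueError("transcriptome_fraction must be in [0, 1]")


@dataclass
class SyntheticStudy:
    tree: dendropy.Tree
    traits: dict[str, str]
    loss_clade: list[str]
    truth: PresenceMatrix
    observed: PresenceMatrix
    detection: DetectionMatrix
    labels: dict[str, str]
    alpha: pd.Series
    beta: pd.Series
    config: ScenarioConfig = field(repr=False, default=None)

    @property
    def species(self) -> list[str]:
        return list(self.truth.species)

    @property
    def genes(self) -> list[str]:
        return list(self.truth.genes)


# ---------------------------------------------------------------------------
# Tree simulation
# ---------------------------------------------------------------------------


def _grow_yule(n_tips: int, rng: np.random.Generator) -> dendropy.Tree:
    """Pure-birth topology with unit branch lengths: split a uniformly
    chosen extant lineage until ``n_tips`` are present."""
    tree = dendropy.Tree()
    tree.is_rooted = True
    leaves = [tree.seed_node]
    if n_tips == 1:
        tree.seed_node.edge.length = 1.0
        return tree
    while len(leaves) < n_tips:
        idx = int(rng.integers(len(leaves)))
        node = leaves.pop(idx)
        for _ in range(2):
            child = dendropy.Node()
            child.edge.length = 1.0
            node.add_child(child)
            leaves.append(child)
    return tree


def simulate_species_tree(
    n_species: int, loss_clade_size: int, rng: np.random.Generator
) -> tuple[dendropy.Tree, list[str]]:
    """Yule topology with a guaranteed monophyletic loss clade.

    A Yule tree is grown on ``n_species - loss_clade_size + 1`` lineages
    and one uniformly chosen tip is then expanded into a Yule subtree of
    ``loss_clade_size`` tips, so the non-host clade always exists as a
    single clade with a stem branch.  Branch lengths are 1.
    """
    backbone = _grow_yule(n_species - loss_clade_size + 1, rng)
    backbone_leaves = backbone.leaf_nodes()
    attach = backbone_leaves[int(rng.integers(len(backbone_leaves)))]
    if loss_clade_size > 1:
        sub = _grow_yule(loss_clade_size, rng)
        for child in sub.seed_node.child_nodes():
            attach.add_child(child)

    taxon_ns = dendropy.TaxonNamespace()
    loss_tips = sorted(attach.leaf_iter(), key=id) if loss_clade_size > 1 else [attach]
    loss_set = set(id(n) for n in loss_tips)
    host_names = iter(f"h{i+1:02d}" for i in range(n_species))
    nh_names = iter(f"nh{i+1:02d}" for i in range(loss_clade_size))
    loss_names = []
    for leaf in backbone.leaf_node_iter():
        name = next(nh_names) if id(leaf) in loss_set else next(host_names)
        leaf.taxon = taxon_ns.new_taxon(label=name)
        if id(leaf) in loss_set:
            loss_names.append(name)
    backbone.taxon_namespace = taxon_ns
    return backbone, sorted(loss_names)


# ---------------------------------------------------------------------------
# Gene content and detection
# ---------------------------------------------------------------------------


def _simulate_background_gene(
    tree: dendropy.Tree, loss_rate: float, rng: np.random.Generator
) -> dict[str, bool]:
    """Dollo-style irreversible loss: present at the root, each branch
    loses the gene with probability ``loss_rate``; once lost, lost."""
    state: dict[int, bool] = {id(tree.seed_node): True}
    tips: dict[str, bool] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            present = True
        else:
            present = state[id(node.parent_node)]
            if present and rng.random() < loss_rate:
                present = False
        state[id(node)] = present
        if node.is_leaf():
            tips[node.taxon.label] = present
    return tips


def simulate_detection(
    truth: PresenceMatrix,
    alpha: pd.Series,
    beta: pd.Series,
    fp_rate: float,
    rng: np.random.Generator | int,
) -> DetectionMatrix:
    """Bernoulli transcript detections: a truly present gene i in species
    j is detected with probability ``logistic(alpha_i + beta_j)``; a
    truly absent gene with probability ``fp_rate``; unknown truth yields
    unknown detection."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if list(alpha.index) != list(truth.genes) or list(beta.index) != list(truth.species):
        raise ValueError("alpha/beta indices must match the truth matrix axes")
    eta = alpha.to_numpy()[:, None] + beta.to_numpy()[None, :]
    p_present = 1.0 / (1.0 + np.exp(-eta))
    t = truth.data.to_numpy()
    u = rng.random(t.shape)
    det = np.where(t == 1.0, (u < p_present).astype(float),
                   np.where(t == 0.0, (u < fp_rate).astype(float), np.nan))
    data = pd.DataFrame(det, index=truth.genes, columns=truth.species)
    mask = pd.DataFrame(False, index=truth.genes, columns=truth.species)
    return DetectionMatrix(data, mask)


def simulate_study(config: ScenarioConfig) -> SyntheticStudy:
    """Generate one full synthetic study from a scenario config."""
    rng = np.random.default_rng(config.seed)
    tree, loss_clade = simulate_species_tree(
        config.n_species, config.loss_clade_size, rng
    )
    species = sorted(t.label for t in tree.taxon_namespace)
    traits = {s: (NON_HOST if s in loss_clade else HOST) for s in species}

    genes: list[str] = []
    labels: dict[str, str] = {}
    rows: list[np.ndarray] = []
    hosts = [s for s in species if traits[s] == HOST]

    for i in range(config.n_conserved):
        g = f"cons{i+1:03d}"
        genes.append(g)
        labels[g] = CONSERVED
        rows.append(np.ones(len(species)))
    for i in range(config.n_symbiosis):
        g = f"symb{i+1:03d}"
        genes.append(g)
        labels[g] = SYMBIOSIS
        rows.append(np.array([1.0 if traits[s] == HOST else 0.0 for s in species]))
    for i in range(config.n_background):
        g = f"bg{i+1:03d}"
        genes.append(g)
        labels[g] = BACKGROUND
        tips = _simulate_background_gene(tree, config.background_loss_rate, rng)
        rows.append(np.array([1.0 if tips[s] else 0.0 for s in species]))

    # loss-clade species always carry genomes (the screen's focal set);
    # a fraction of host species are transcriptome-only
    source: dict[str, str] = {}
    stride = (
        max(1, round(1 / config.transcriptome_fraction))
        if config.transcriptome_fraction > 0
        else 0
    )
    for k, s in enumerate(species):
        if s in loss_clade or stride == 0:
            source[s] = GENOME
        else:
            source[s] = TRANSCRIPTOME if k % stride == 0 else GENOME

    truth = PresenceMatrix(
        pd.DataFrame(np.array(rows), index=genes, columns=species), dict(source)
    )

    alpha = pd.Series(
        rng.normal(config.alpha_mean, config.alpha_sd, len(genes)), index=genes
    )
    beta = pd.Series(rng.normal(0.0, config.beta_sd, len(species)), index=species)
    detection = simulate_detection(
        truth, alpha, beta, config.false_positive_rate, rng
    )

    observed_data = truth.data.copy()
    for s in species:
        if source[s] == GENOME:
            if config.genome_mask_rate > 0:
                blank = rng.random(len(genes)) < config.genome_mask_rate
                observed_data.loc[blank, s] = np.nan
        else:
            det_col = detection.data[s]
            observed_data[s] = np.where(det_col == 1.0, 1.0, np.nan)
    observed = PresenceMatrix(observed_data, dict(source))

    return SyntheticStudy(
        tree=tree,
        traits=traits,
        loss_clade=loss_clade,
        truth=truth,
        observed=observed,
        detection=detection,
        labels=labels,
        alpha=alpha,
        beta=beta,
        config=config,
    )


def simulate_refinement_datasets(
    study: SyntheticStudy,
    candidates: list[str],
    n_datasets: int = 4,
    present_fraction: float = 0.3,
    seed: int = 0,
) -> list[tuple[str, str, dict[str, float]]]:
    """Presence calls from additional non-host datasets for the
    refinement cascade.

    Emulates extra independent trait-loss lineages: every
    symbiosis-specific candidate is truly absent from each dataset, while
    each background candidate is present with probability
    ``present_fraction`` (a lineage-specific, not convergent, loss).
    Returns ``(label, source_kind, calls)`` triples with calls encoded
    1/0/NaN.
    """
    rng = np.random.default_rng(seed)
    datasets = []
    for d in range(n_datasets):
        kind = GENOME if d % 2 == 0 else TRANSCRIPTOME
        calls: dict[str, float] = {}
        for g in candidates:
            if study.labels.get(g) == SYMBIOSIS:
                calls[g] = 0.0
            else:
                present = rng.random() < present_fraction
                if kind == GENOME:
                    calls[g] = 1.0 if present else 0.0
                else:
                    # transcriptome non-detection is unknown, not absence
                    calls[g] = 1.0 if present else np.nan
        datasets.append((f"nonhost_{kind}_{d+1}", kind, calls))
    return datasets
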