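"""Logistic detection-probability model for transcriptome absence calls.

The probability of observing gene *i*'s transcript in species *j*'s
transcriptome, given the gene is present, is modeled as

    p_ij = logistic(alpha_i + beta_j)

where ``alpha_i`` is a gene (expression-level) effect and ``beta_j`` a
species (transcriptome-coverage) effect, both on the log-odds scale.
The model is fitted by maximum likelihood on the cells where presence is
assumed a priori: conserved genes everywhere, symbiosis-specific genes
in host species.  Fitted probabilities then quantify whether
non-detection of a gene across a set of species is evidence of absence:
if present in all of them, the gene would have been detected in at least
one with probability ``P_i = 1 - prod_j (1 - p_ij)``.

A gene never detected in any training cell carries no information about
its own detectability; its predictions are forced to 0 and flagged
"presence cannot be rejected" rather than given a finite alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .io_formats import HOST, PresenceMatrix

PARAM_CLIP = 15.0  # log-odds assigned to separated (all-one / all-zero) levels


class ModelError(ValueError):
    pass


@dataclass
class DetectionMatrix:
    """Binary transcript detections plus the presence-assumed training mask.

    ``data`` holds 1 (detected), 0 (undetected) or NaN (unknown);
    ``mask`` is True exactly on the cells used to fit the model, and may
    only be True where the detection is 0 or 1.
    """

    data: pd.DataFrame
    mask: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.shape != self.mask.shape:
            raise ModelError("detection data and mask shapes differ")
        if bool((self.mask.to_numpy() & np.isnan(self.data.to_numpy())).any()):
            raise ModelError("training mask set on an unknown detection cell")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def species(self) -> list[str]:
        return list(self.data.columns)


def build_training_mask(
    detection: DetectionMatrix,
    traits: Mapping[str, str],
    gene_classes: Mapping[str, str],
    conserved_label: str = "conserved",
    symbiosis_label: str = "symbiosis-specific",
) -> DetectionMatrix:
    """Mark the cells where gene presence is strongly supported.

    Presence is assumed (mask True) for every conserved gene in every
    species and for every symbiosis-specific gene in host species; cells
    with unknown detections stay unmasked, as do background genes
    entirely.  Every gene must carry a class label.
    """
    unlabeled = [g for g in detection.genes if g not in gene_classes]
    if unlabeled:
        raise ModelError(f"genes without class labels: {unlabeled[:5]}")
    mask = pd.DataFrame(False, index=detection.genes, columns=detection.species)
    observed = ~detection.data.isna()
    for g in detection.genes:
        cls = gene_classes[g]
        if cls == conserved_label:
            mask.loc[g] = observed.loc[g]
        elif cls == symbiosis_label:
            for s in detection.species:
                if traits.get(s) == HOST and observed.at[g, s]:
                    mask.at[g, s] = True
    return DetectionMatrix(detection.data.copy(), mask)


class DetectionPrediction(NamedTuple):
    probability: float
    cannot_reject_presence: bool


@dataclass
class DetectionModel:
    """Fitted gene effects alpha and species effects beta (log-odds).

    The linear predictor alpha_i + beta_j is invariant to a constant
    shift (alpha + c, beta - c); identifiability is fixed by setting the
    reference species' beta to 0.  Degenerate genes (never detected in
    the mask) carry NaN alpha; saturated genes (always detected) and
    separated species are flagged — their effects have no finite MLE and
    the reported values are large iterates whose predictions saturate.
    """

    alpha: pd.Series
    beta: pd.Series
    reference_species: str
    loglik: float
    loglik_path: list[float] = field(repr=False)
    converged: bool = True
    degenerate_genes: set[str] = field(default_factory=set)
    saturated_genes: set[str] = field(default_factory=set)
    degenerate_species: set[str] = field(default_factory=set)

    def predict(self, gene: str, species: str) -> float:
        return predict_detection(self, gene, species).probability


def _bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_detection_model(
    detection: DetectionMatrix,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> DetectionModel:
    """Maximize the masked-cell Bernoulli likelihood by Newton/IRLS.

    Step-halving guarantees the log-likelihood never decreases across
    iterations; convergence is declared when the improvement drops below
    ``tol``.  Genes with all-zero masked detections are flagged
    degenerate and excluded from the fit (their predictions are 0 with
    the cannot-reject-presence flag).  All-one genes and all-one/all-zero
    species are completely separated — their MLE sits at infinity — so
    they are flagged but kept in the fit, where Newton leaves them at a
    large finite iterate whose predicted probabilities saturate.
    """
    mask = detection.mask.to_numpy(dtype=bool)
    if not mask.any():
        raise ModelError("empty training mask")
    data = detection.data.to_numpy(dtype=float)
    genes = list(detection.genes)
    species = list(detection.species)

    degenerate_genes: set[str] = set()
    saturated_genes: set[str] = set()
    degenerate_species: set[str] = set()
    fit_genes = [g for k, g in enumerate(genes) if mask[k].any()]
    fit_species = [s for k, s in enumerate(species) if mask[:, k].any()]

    gidx = {g: k for k, g in enumerate(genes)}
    sidx = {s: k for k, s in enumerate(species)}

    # a gene never detected in its masked cells carries no information on
    # its own detectability (absence can never be rejected); an always-
    # detected gene has no finite alpha.  Both are set aside; species are
    # all kept and runaway effects are clipped after the fit.
    for g in list(fit_genes):
        row = data[gidx[g]][mask[gidx[g]]]
        if row.max() == 0:
            degenerate_genes.add(g)
            fit_genes.remove(g)
        elif row.min() == 1:
            saturated_genes.add(g)  # flagged, kept in the fit; the MLE for
            # its alpha sits at +inf so the fitted value is a large finite
            # iterate whose predictions saturate at 1
    grows = [gidx[g] for g in fit_genes]
    for s in list(fit_species):
        col = data[grows, sidx[s]][mask[grows, sidx[s]]]
        if col.size == 0:
            fit_species.remove(s)
            degenerate_species.add(s)
        elif col.min() == 1 or col.max() == 0:
            degenerate_species.add(s)  # flagged, still fitted, clipped below

    if not fit_genes or not fit_species:
        raise ModelError("model unidentifiable: all cells degenerate")

    reference = fit_species[0]
    free_species = fit_species[1:]
    gpos = {g: k for k, g in enumerate(fit_genes)}
    spos = {s: k for k, s in enumerate(free_species)}

    cells = [
        (gpos[g], spos.get(s), data[gidx[g], sidx[s]])
        for g in fit_genes
        for s in fit_species
        if mask[gidx[g], sidx[s]]
    ]
    y = np.array([c[2] for c in cells])
    n_params = len(fit_genes) + len(free_species)
    X = np.zeros((len(cells), n_params))
    for r, (gi, si, _) in enumerate(cells):
        X[r, gi] = 1.0
        if si is not None:
            X[r, len(fit_genes) + si] = 1.0

    params = np.zeros(n_params)
    eta = X @ params
    ll = _bernoulli_loglik(y, eta)
    path = [ll]
    converged = False
    for _ in range(max_iter):
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(p * (1.0 - p), 1e-12, None)
        grad = X.T @ (y - p)
        hess = (X * w[:, None]).T @ X
        hess[np.diag_indices_from(hess)] += 1e-10
        delta = np.linalg.solve(hess, grad)
        step = 1.0
        for _ in range(60):
            trial = params + step * delta
            ll_new = _bernoulli_loglik(y, X @ trial)
            if ll_new >= ll - 1e-13:
                break
            step /= 2.0
        else:
            trial, ll_new = params, ll
        params, eta = trial, X @ trial
        improvement = ll_new - ll
        ll = ll_new
        path.append(ll)
        if abs(improvement) < tol:
            converged = True
            break
    if not converged:
        warnings.warn("detection model did not converge", stacklevel=2)

    alpha = pd.Series(np.nan, index=genes, dtype=float)
    beta = pd.Series(np.nan, index=species, dtype=float)
    for g in fit_genes:
        alpha[g] = params[gpos[g]]
    beta[reference] = 0.0
    for s in free_species:
        beta[s] = params[len(fit_genes) + spos[s]]
    for s in degenerate_species:
        if np.isnan(beta[s]):  # no masked cell among fitted genes
            col = data[:, sidx[s]][mask[:, sidx[s]]]
            beta[s] = PARAM_CLIP if (col.size and col.min() == 1) else -PARAM_CLIP
    if degenerate_species:
        warnings.warn(
            "separated species effects (no finite MLE): "
            f"{sorted(degenerate_species)}",
            stacklevel=2,
        )

    return DetectionModel(
        alpha=alpha,
        beta=beta,
        reference_species=reference,
        loglik=ll,
        loglik_path=path,
        converged=converged,
        degenerate_genes=degenerate_genes,
        saturated_genes=saturated_genes,
        degenerate_species=degenerate_species,
    )


def predict_detection(model: DetectionModel, gene: str, species: str) -> DetectionPrediction:
    """p_ij = logistic(alpha_i + beta_j); degenerate genes return 0 with
    the "presence cannot be rejected" flag."""
    if gene in model.degenerate_genes:
        return DetectionPrediction(0.0, True)
    if gene not in model.alpha.index or np.isnan(model.alpha[gene]):
        raise ModelError(f"gene {gene!r} not fitted")
    if species not in model.beta.index or np.isnan(model.beta[species]):
        raise ModelError(f"species {species!r} not fitted")
    eta = model.alpha[gene] + model.beta[species]
    return DetectionPrediction(float(1.0 / (1.0 + np.exp(-eta))), False)


def combined_detection_probability(probs: Iterable[float]) -> float:
    """1 - prod(1 - p): probability of detection in at least one species
    if the gene is present in all of them.  Empty input gives 0."""
    out = 1.0
    for p in probs:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability {p} outside [0, 1]")
        out *= 1.0 - p
    return 1.0 - out


@dataclass
class AbsenceCalls:
    """Per-gene combined probabilities and absence calls at threshold theta."""

    p_ij: pd.DataFrame
    combined: pd.Series
    call: pd.Series  # "absence-supported" | "inconclusive"
    per_cell_supported: pd.DataFrame
    theta: float


def call_absence(
    model: DetectionModel,
    detection: DetectionMatrix,
    query_genes: Sequence[str],
    species_set: Sequence[str],
    theta: float = 0.95,
) -> AbsenceCalls:
    """Decide which undetected genes are convincingly absent.

    For each query gene (undetected in every queried species) the
    combined probability P_i = 1 - prod_j (1 - p_ij) is compared with
    theta: absence is supported when the gene *should* have been seen
    somewhere.  Degenerate genes have P_i = 0 and stay inconclusive.
    A per-cell view (p_ij >= theta) is reported alongside.
    """
    if not 0.0 < theta < 1.0:
        raise ValueError("theta must be in (0, 1)")
    for g in query_genes:
        for s in species_set:
            if detection.data.at[g, s] == 1.0:
                raise ModelError(
                    f"gene {g!r} is detected in {s!r}; absence question ill-posed"
                )
    p = pd.DataFrame(0.0, index=list(query_genes), columns=list(species_set))
    for g in query_genes:
        for s in species_set:
            p.at[g, s] = predict_detection(model, g, s).probability
    combined = pd.Series(
        [combined_detection_probability(p.loc[g]) for g in query_genes],
        index=list(query_genes),
    )
    call = pd.Series(
        np.where(combined >= theta, "absence-supported", "inconclusive"),
        index=list(query_genes),
    )
    return AbsenceCalls(p, combined, call, p >= theta, theta)


@dataclass
class FdrResult:
    """Hold-out validation of the absence-calling procedure.

    ``evaluated`` genes are present in the validation species' genome yet
    undetected in its transcriptome — every absence call on them is a
    false call.  ``false_call_rate`` divides supported calls by the
    number of evaluated genes (the headline rate); among the calls
    themselves all are false by construction.
    """

    evaluated: list[str]
    supported: list[str]
    n_evaluated: int
    n_supported: int
    false_call_rate: float | None
    calls: AbsenceCalls | None = field(repr=False, default=None)


def validate_fdr(
    model: DetectionModel,
    genome_presence: PresenceMatrix,
    detection: DetectionMatrix,
    validation_species: str,
    theta: float = 0.95,
    genes: Sequence[str] | None = None,
) -> FdrResult:
    """Estimate the false-call rate on a species with both genome and
    transcriptome: genes known present from the genome but undetected in
    the transcriptome are evaluated, and the fraction whose absence the
    model supports at theta is the error rate."""
    if genes is not None:
        pool = list(genes)
    else:  # only genes the model can speak about
        pool = [
            g
            for g in detection.genes
            if not np.isnan(model.alpha.get(g, np.nan))
            or g in model.degenerate_genes
        ]
    evaluated = [
        g
        for g in pool
        if genome_presence.is_present(g, validation_species)
        and detection.data.at[g, validation_species] == 0.0
    ]
    if not evaluated:
        return FdrResult([], [], 0, 0, None)
    calls = call_absence(model, detection, evaluated, [validation_species], theta)
    supported = [g for g in evaluated if calls.call[g] == "absence-supported"]
    return FdrResult(
        evaluated, supported, len(evaluated), len(supported),
        len(supported) / len(evaluated), calls,
    )
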