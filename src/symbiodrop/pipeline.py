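"""End-to-end composition of the gene-loss workflow on one study.

The stages mirror the analysis narrative: simulate (or load) a study,
screen the presence matrix for convergent loss against the resampled
background, fit the detection model and validate its absence calls on a
hold-out species with both genome and transcriptome, refine the
candidate list against further non-host datasets, test enrichment in
the symbiosis reference set, and reconstruct the ancestral trait.  All
stage outputs are plain TSV/JSON so each stage can be re-run alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import ancestral, detection_model, enrichment, loss_screen, synthetic_data
from .io_formats import (
    GENOME,
    HOST,
    write_newick,
    write_presence_matrix,
    write_trait_table,
)


@dataclass
class PipelineConfig:
    scenario: synthetic_data.ScenarioConfig = field(
        default_factory=synthetic_data.ScenarioConfig
    )
    n_min: int = 13
    n_background_sets: int = 2000
    theta: float = 0.95
    enrichment_m: int = 10
    n_refinement_datasets: int = 4
    refinement_present_fraction: float = 0.3
    screen_seed: int = 1
    enrichment_seed: int = 2
    refinement_seed: int = 3

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        scenario = synthetic_data.ScenarioConfig(**raw.pop("scenario", {}))
        return cls(scenario=scenario, **raw)

    def to_dict(self) -> dict:
        return asdict(self)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage on a simulated study and write a summary.

    Returns the summary dict; files written: tree.nwk, traits.tsv,
    truth.tsv, observed.tsv, detection.tsv, screen.json, refine.json,
    enrich.json, ancestral.json, summary.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    study = synthetic_data.simulate_study(config.scenario)
    (out / "tree.nwk").write_text(write_newick(study.tree) + "\n")
    write_trait_table(study.traits, out / "traits.tsv")
    write_presence_matrix(study.truth, out / "truth.tsv")
    write_presence_matrix(study.observed, out / "observed.tsv")
    study.detection.data.to_csv(out / "detection.tsv", sep="\t")

    screen_result = loss_screen.screen(
        study.observed,
        focal_set=study.loss_clade,
        n_min=config.n_min,
        n_background_sets=config.n_background_sets,
        seed=config.screen_seed,
    )

    masked = detection_model.build_training_mask(
        study.detection, study.traits, study.labels
    )
    model = detection_model.fit_detection_model(masked)
    validation_species = next(
        s
        for s in study.species
        if study.traits[s] == HOST and study.observed.source[s] == GENOME
    )
    fdr = detection_model.validate_fdr(
        model, study.truth, study.detection, validation_species, theta=config.theta
    )

    datasets = synthetic_data.simulate_refinement_datasets(
        study,
        screen_result.candidates,
        n_datasets=config.n_refinement_datasets,
        present_fraction=config.refinement_present_fraction,
        seed=config.refinement_seed,
    )
    trace = loss_screen.refine(screen_result.candidates, datasets)

    reference = {g for g, c in study.labels.items() if c == synthetic_data.SYMBIOSIS}
    enrich = enrichment.chi2_enrichment(
        screen_result.candidates,
        reference,
        universe=study.genes,
        m=config.enrichment_m,
        seed=config.enrichment_seed,
    )

    recon = ancestral.reconstruct(study.tree, study.traits, kind="ER")

    summary = {
        "config": config.to_dict(),
        "screen": {
            "observed_count": screen_result.observed_count,
            "n_candidates": len(screen_result.candidates),
            "background_mean": screen_result.background_mean,
            "background_sd": screen_result.background_sd,
            "z": screen_result.z,
            "significant": screen_result.significant,
        },
        "detection": {
            "converged": model.converged,
            "loglik": model.loglik,
            "n_degenerate_genes": len(model.degenerate_genes),
            "validation_species": validation_species,
            "fdr_evaluated": fdr.n_evaluated,
            "fdr_supported": fdr.n_supported,
            "false_call_rate": fdr.false_call_rate,
        },
        "refinement": {
            "counts": trace.counts,
            "initial": len(screen_result.candidates),
            "final": len(trace.final_candidates),
            "partition_sizes": {k: len(v) for k, v in trace.partition.items()},
        },
        "enrichment": {
            "L": enrich.list_size,
            "s": enrich.observed_overlap,
            "percent": enrich.percent,
            "chi2": enrich.chi2,
            "p_value": enrich.p_value,
        },
        "ancestral": {
            "q01": recon.model.q01,
            "q10": recon.model.q10,
            "loglik": recon.loglik,
            "n_transitions": recon.n_transitions,
            "transitions": recon.transitions,
            "parsimony_changes": recon.parsimony_changes,
        },
    }
    for name, payload in (
        ("screen", summary["screen"]),
        ("refine", summary["refinement"]),
        ("enrich", summary["enrichment"]),
        ("ancestral", summary["ancestral"]),
        ("summary", summary),
    ):
        (out / f"{name}.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    return summary
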