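"""The convergent gene-loss screen and its resampled background null.

A gene (or OG) shows *apparent loss* for a focal species set when it is
absent from every focal species yet present in at least ``n_min``
species outside the set.  Because genome incompleteness alone produces
such patterns, the observed count for the focal set is compared with the
distribution of the same statistic over random species sets of equal
size; a focal count more than two standard deviations above the
background mean indicates loss in excess of chance.  Candidates may
additionally be required to occur in designated clades (distant hosts),
and are then whittled down by a stepwise refinement cascade against
further non-host datasets.

Unknown cells are conservative throughout: unknown never counts as
absent inside the focal set nor as present outside it, so missing data
cannot manufacture loss signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Mapping, Sequence

import numpy as np

from .io_formats import PresenceMatrix

EXHAUSTIVE_LIMIT = 100_000


def apparent_loss_count(
    matrix: PresenceMatrix, species_set: Sequence[str], n_min: int
) -> int:
    """Rows absent in every species of the set and present in >= n_min
    species outside it."""
    return len(apparent_loss_rows(matrix, species_set, n_min))


def apparent_loss_rows(
    matrix: PresenceMatrix, species_set: Sequence[str], n_min: int
) -> list[str]:
    species_set = list(species_set)
    if not species_set:
        raise ValueError("species set must be non-empty")
    missing = [s for s in species_set if s not in matrix.data.columns]
    if missing:
        raise ValueError(f"species not in matrix: {missing}")
    outside = [s for s in matrix.data.columns if s not in set(species_set)]
    if n_min > len(outside):
        return []
    inside = matrix.data[species_set]
    absent_all = (inside == 0.0).all(axis=1)
    present_out = (matrix.data[outside] == 1.0).sum(axis=1) >= n_min
    return list(matrix.data.index[absent_all & present_out])


def background_distribution(
    matrix: PresenceMatrix,
    k: int,
    n_min: int,
    n_sets: int = 10_000,
    seed: int | None = None,
    mode: str = "monte-carlo",
    exclude: Sequence[str] = (),
) -> tuple[float, float, np.ndarray]:
    """Distribution of the apparent-loss count over random k-species sets.

    Exhaustive mode enumerates all C(S, k) subsets (refused above
    100 000); monte-carlo mode draws ``n_sets`` uniform subsets without
    replacement within each subset.  Returns the sample mean, the
    population standard deviation and the per-subset counts.  ``exclude``
    optionally removes species (e.g. the focal set) from the sampling
    frame; by default subsets are drawn from the full panel.
    """
    pool = [s for s in matrix.data.columns if s not in set(exclude)]
    if k >= len(matrix.data.columns):
        raise ValueError("k must be smaller than the species panel")
    if k > len(pool):
        raise ValueError(f"k={k} too large for sampling pool of {len(pool)}")
    col_pos = {s: j for j, s in enumerate(matrix.data.columns)}
    pool_idx = np.array([col_pos[s] for s in pool])
    if mode == "exhaustive":
        total = comb(len(pool), k)
        if total > EXHAUSTIVE_LIMIT:
            raise ValueError(
                f"{total} subsets exceed the exhaustive limit; use monte-carlo"
            )
        subsets = np.array(list(combinations(pool_idx, k)))
    elif mode == "monte-carlo":
        rng = np.random.default_rng(seed)
        subsets = np.array(
            [rng.choice(pool_idx, size=k, replace=False) for _ in range(n_sets)]
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    counts = _subset_counts(matrix.data.to_numpy(dtype=float), subsets, n_min)
    return float(counts.mean()), float(counts.std()), counts


def _subset_counts(values: np.ndarray, subsets: np.ndarray, n_min: int) -> np.ndarray:
    """Apparent-loss counts for many species subsets at once.  Presence
    outside a subset equals total presence minus presence inside it, so
    each subset costs O(genes * k)."""
    absent = values == 0.0
    present = values == 1.0
    total_present = present.sum(axis=1)
    out = np.empty(len(subsets), dtype=float)
    for r, idx in enumerate(subsets):
        inside_absent = absent[:, idx].all(axis=1)
        outside_present = total_present - present[:, idx].sum(axis=1)
        out[r] = np.count_nonzero(inside_absent & (outside_present >= n_min))
    return out


@dataclass
class LossScreenResult:
    focal_set: list[str]
    n_min: int
    required_clades: list[list[str]]
    candidates: list[str]
    candidates_pre_clade: list[str] = field(repr=False, default_factory=list)
    observed_count: int = 0
    background_mean: float = 0.0
    background_sd: float = 0.0
    z: float = float("nan")
    significant: bool = False
    n_background_sets: int = 0
    seed: int | None = None


def screen(
    matrix: PresenceMatrix,
    focal_set: Sequence[str],
    n_min: int,
    required_clades: Sequence[Sequence[str]] = (),
    n_background_sets: int = 10_000,
    seed: int | None = None,
    mode: str = "monte-carlo",
    exclude_focal_from_background: bool = False,
) -> LossScreenResult:
    """Run the loss screen against a resampled background null.

    The z score compares the focal apparent-loss count with the
    background distribution *before* the required-clade filter, which is
    applied afterwards as an additional requirement.  The two-SD rule is
    one-sided: only an excess of apparent loss is of interest.
    """
    focal_set = list(focal_set)
    panel = set(matrix.data.columns)
    for clade in required_clades:
        if not set(clade) & panel:
            raise ValueError(f"required clade {list(clade)} disjoint from panel")
    pre = apparent_loss_rows(matrix, focal_set, n_min)
    candidates = [
        g
        for g in pre
        if all(
            any(matrix.data.at[g, s] == 1.0 for s in clade if s in panel)
            for clade in required_clades
        )
    ]
    mean, sd, counts = background_distribution(
        matrix,
        k=len(focal_set),
        n_min=n_min,
        n_sets=n_background_sets,
        seed=seed,
        mode=mode,
        exclude=focal_set if exclude_focal_from_background else (),
    )
    z = (len(pre) - mean) / sd if sd > 0 else float("inf") if len(pre) > mean else 0.0
    return LossScreenResult(
        focal_set=focal_set,
        n_min=n_min,
        required_clades=[list(c) for c in required_clades],
        candidates=candidates,
        candidates_pre_clade=pre,
        observed_count=len(pre),
        background_mean=mean,
        background_sd=sd,
        z=float(z),
        significant=bool(z > 2.0),
        n_background_sets=len(counts),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Stepwise refinement cascade
# ---------------------------------------------------------------------------


@dataclass
class RefinementStep:
    label: str
    source_kind: str  # genome | transcriptome
    removed: list[str]
    remaining_count: int


@dataclass
class RefinementTrace:
    steps: list[RefinementStep]
    final_candidates: list[str]
    partition: dict[str, list[str]]  # absent/present in the final dataset

    @property
    def counts(self) -> list[int]:
        return [s.remaining_count for s in self.steps]


def _normalize_call(value) -> float:
    if isinstance(value, str):
        return {"present": 1.0, "absent": 0.0, "unknown": np.nan}[value]
    v = float(value)
    if np.isnan(v) or v in (0.0, 1.0):
        return v
    raise ValueError(f"presence call must be 1/0/NaN, got {value!r}")


def refine(
    candidates: Sequence[str],
    datasets: Sequence[tuple[str, str, Mapping[str, object]]],
) -> RefinementTrace:
    """Remove candidates present in each successive non-host dataset.

    ``datasets`` are ``(label, source_kind, calls)`` triples applied in
    order; calls map gene id to present (1), absent (0) or unknown
    (NaN).  Unknown retains the candidate; a candidate missing from a
    dataset is treated as unknown with a warning.  The last dataset's
    present/absent split is reported as the final partition (the
    AM-specific versus shared-pathway candidates).
    """
    remaining = list(candidates)
    steps: list[RefinementStep] = []
    last_present: list[str] = []
    for label, kind, calls in datasets:
        missing = [g for g in remaining if g not in calls]
        if missing:
            warnings.warn(
                f"dataset {label!r} lacks calls for {len(missing)} candidates; "
                "treated as unknown",
                stacklevel=2,
            )
        removed = [
            g for g in remaining if g in calls and _normalize_call(calls[g]) == 1.0
        ]
        remaining = [g for g in remaining if g not in set(removed)]
        steps.append(RefinementStep(label, kind, removed, len(remaining)))
        last_present = removed
    return RefinementTrace(
        steps=steps,
        final_candidates=remaining,
        partition={
            "absent_in_final_dataset": list(remaining),
            "present_in_final_dataset": list(last_present),
        },
    )
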