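"""High-level glue: fragments -> weights -> profiles -> feature matrix.

These helpers chain the per-module operations in the order the method
prescribes (filter, GC-annotate, stratify, weight against a shared target,
profile, arm z-score) so that cohort-level callers (CLI, tests, analyses)
do not repeat the plumbing.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .classifier import FeatureMatrix
from .fragments import FragmentSet, GenomeResource, annotate_gc, filter_fragments
from .gc_correction import (
    FragmentWeights,
    TargetDistribution,
    assign_weights,
    build_target,
    stratify_by_gc,
)
from .profiles import (
    BinSet,
    ReferencePanel,
    arm_weighted_counts,
    arm_zscores,
    fragmentation_profile,
)

__all__ = ["prepare_sample", "build_panel_resources", "cohort_features"]


def prepare_sample(
    fs: FragmentSet,
    genome: GenomeResource,
    target: TargetDistribution,
    min_mapq: int = 30,
    n_strata: int = 100,
) -> tuple[FragmentSet, FragmentWeights]:
    """Filter, GC-annotate, and weight one sample against a fixed target."""
    if not fs.filtered:
        fs = filter_fragments(fs, genome, min_mapq=min_mapq)
    if not fs.gc_annotated:
        fs = annotate_gc(fs, genome)
    counts = stratify_by_gc(fs, n_strata=n_strata)
    weights = assign_weights(fs, counts, target)
    return fs, weights


def build_panel_resources(
    panel: Sequence[FragmentSet],
    genome: GenomeResource,
    arms: pd.DataFrame,
    min_mapq: int = 30,
    n_strata: int = 100,
) -> tuple[TargetDistribution, ReferencePanel]:
    """Target distribution (panel-median GC strata) and arm statistics from a
    non-cancer reference panel."""
    prepared = []
    for fs in panel:
        if not fs.filtered:
            fs = filter_fragments(fs, genome, min_mapq=min_mapq)
        if not fs.gc_annotated:
            fs = annotate_gc(fs, genome)
        prepared.append(fs)
    target = build_target([stratify_by_gc(fs, n_strata=n_strata) for fs in prepared])
    counts = []
    for fs in prepared:
        w = assign_weights(fs, stratify_by_gc(fs, n_strata=n_strata), target)
        counts.append(arm_weighted_counts(fs, w, arms))
    table = pd.DataFrame(counts, index=[fs.sample_id for fs in prepared])
    return target, ReferencePanel.from_counts(table, target=target)


def cohort_features(
    samples: Sequence[FragmentSet],
    labels: Sequence[int],
    genome: GenomeResource,
    bins: BinSet,
    arms: pd.DataFrame,
    target: TargetDistribution,
    panel: ReferencePanel,
    min_mapq: int = 30,
) -> FeatureMatrix:
    """Standardized profile matrix X and arm z-score matrix Z for a cohort."""
    X, Z, ids = [], [], []
    for fs in samples:
        fs, w = prepare_sample(fs, genome, target, min_mapq=min_mapq)
        X.append(fragmentation_profile(fs, w, bins).standardized)
        Z.append(arm_zscores(fs, w, arms, panel).z.to_numpy())
        ids.append(fs.sample_id)
    return FeatureMatrix(
        X=np.vstack(X), Z=np.vstack(Z), labels=np.asarray(labels, int), sample_ids=tuple(ids)
    )
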