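"""Fragment-level GC-bias correction by stratum reweighting.

PCR preferentially amplifies fragments by GC content, distorting coverage.
Rather than smoothing bin counts, each fragment is placed in one of 100
equal-width GC strata on [0, 1] and given a weight w = t_i / N_i, where N_i
is the sample's fragment count in stratum i and t_i the count in a fixed
target distribution (the element-wise median over a reference panel of
non-cancer samples). Weighted counts then share the target's GC composition
and library size, so downstream bin counts are comparable across samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .fragments import FragmentSet

__all__ = [
    "GCStratumCounts",
    "TargetDistribution",
    "FragmentWeights",
    "stratify_by_gc",
    "build_target",
    "assign_weights",
    "weighted_count",
]


def gc_stratum_index(gc: np.ndarray, n_strata: int = 100) -> np.ndarray:
    """0-based stratum index: equal-width bins on [0, 1], gc = 1 in the top
    stratum."""
    gc = np.asarray(gc, dtype=float)
    return np.minimum(np.floor(gc * n_strata).astype(np.int64), n_strata - 1)


@dataclass(frozen=True)
class GCStratumCounts:
    sample_id: str
    counts: np.ndarray  # length n_strata, integer

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if (c < 0).any():
            raise ValueError("stratum counts must be non-negative")

    @property
    def n_strata(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class TargetDistribution:
    """Target fragment counts per GC stratum (panel median)."""

    t: np.ndarray
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if (np.asarray(self.t) < 0).any():
            raise ValueError("target counts must be non-negative")

    @property
    def n_strata(self) -> int:
        return len(self.t)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"stratum": np.arange(1, self.n_strata + 1), "t": self.t}).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TargetDistribution":
        df = pd.read_csv(path, sep="\t")
        return cls(t=df["t"].to_numpy(dtype=float))


@dataclass(frozen=True)
class FragmentWeights:
    """Per-fragment weights aligned with a FragmentSet, plus each fragment's
    stratum index and the target mass unservable because its stratum was
    empty in the sample."""

    w: np.ndarray
    stratum: np.ndarray
    dropped_target_mass: float = 0.0

    def __post_init__(self) -> None:
        if len(self.w) != len(self.stratum):
            raise ValueError("weights and stratum indices misaligned")
        if (np.asarray(self.w) < 0).any():
            raise ValueError("weights must be non-negative")

    def __len__(self) -> int:
        return len(self.w)


def stratify_by_gc(fs: FragmentSet, n_strata: int = 100) -> GCStratumCounts:
    """Tally fragments into equal-width GC strata."""
    if len(fs) and fs.records["gc"].isna().any():
        raise ValueError("fragments must be GC-annotated before stratification")
    idx = gc_stratum_index(fs.records["gc"].to_numpy(dtype=float), n_strata) if len(fs) else np.empty(0, dtype=np.int64)
    counts = np.bincount(idx, minlength=n_strata)
    return GCStratumCounts(sample_id=fs.sample_id, counts=counts)


def build_target(panel: Sequence[GCStratumCounts]) -> TargetDistribution:
    """Element-wise median of panel stratum counts (even panel: midpoint of
    the two central order statistics)."""
    if len(panel) == 0:
        raise ValueError("panel must be non-empty")
    n = panel[0].n_strata
    if any(p.n_strata != n for p in panel):
        raise ValueError("panel members disagree on number of strata")
    stack = np.stack([p.counts for p in panel]).astype(float)
    return TargetDistribution(
        t=np.median(stack, axis=0), provenance=tuple(p.sample_id for p in panel)
    )


def assign_weights(
    fs: FragmentSet, counts: GCStratumCounts, target: TargetDistribution
) -> FragmentWeights:
    """Weight every fragment in stratum i by t_i / N_i.

    Stratum weight sums then equal t_i exactly on all non-empty strata.
    Target mass in strata the sample never sampled (N_i = 0, t_i > 0) cannot
    be assigned; it is dropped and reported via a warning.
    """
    if counts.n_strata != target.n_strata:
        raise ValueError("sample and target use different numbers of strata")
    n_strata = counts.n_strata
    idx = gc_stratum_index(fs.records["gc"].to_numpy(dtype=float), n_strata) if len(fs) else np.empty(0, dtype=np.int64)
    observed = np.bincount(idx, minlength=n_strata)
    if not np.array_equal(observed, counts.counts):
        raise ValueError("stratum counts do not match the fragment set")
    per_stratum = np.zeros(n_strata)
    nonempty = counts.counts > 0
    per_stratum[nonempty] = target.t[nonempty] / counts.counts[nonempty]
    dropped = float(target.t[~nonempty].sum())
    if dropped > 0:
        warnings.warn(
            f"{fs.sample_id}: {dropped:g} target fragments fall in GC strata "
            "with no observed fragments; that mass is dropped",
            stacklevel=2,
        )
    return FragmentWeights(w=per_stratum[idx], stratum=idx, dropped_target_mass=dropped)


def weighted_count(
    fs: FragmentSet,
    weights: FragmentWeights,
    predicate: Callable[[pd.DataFrame], np.ndarray] | None = None,
) -> float:
    """Sum of weights over fragments satisfying ``predicate`` (a vectorized
    mask function over the records table; None selects everything)."""
    if len(weights) != len(fs):
        raise ValueError("weights not aligned to fragment set")
    if predicate is None:
        return float(weights.w.sum())
    mask = np.asarray(predicate(fs.records), dtype=bool)
    if mask.shape != (len(fs),):
        raise ValueError("predicate must return one boolean per fragment")
    return float(weights.w[mask].sum())
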