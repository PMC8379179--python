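"""Genome binning, fragmentation profiles, arm z-scores, and copy-number bins.

The genome is tiled into non-overlapping fixed-size bins (5 Mb for a human
reference; toy genomes may use smaller tiles), bins with low GC or low
mappability are excluded, and for each bin the GC-weighted count of short
(100-150 bp) and long (151-220 bp) fragments gives a short/long ratio. The
ratio vector is standardized to mean 0 / SD 1 across the genome within each
sample. Arm-level representation is summarized as a z-score of the weighted
arm count against a non-cancer reference panel. A segment-to-bin rule labels
bins gained/lost from copy-number segmentation tables for cohort frequency
summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .fragments import FragmentSet, GenomeResource
from .gc_correction import FragmentWeights, TargetDistribution

__all__ = [
    "BinSet",
    "FragmentationProfile",
    "ArmZScores",
    "ReferencePanel",
    "NON_ACROCENTRIC_ARMS",
    "tile_genome",
    "filter_bins",
    "fragmentation_profile",
    "arm_weighted_counts",
    "arm_zscores",
    "bin_copy_number_status",
    "cohort_alteration_frequency",
]

SHORT_RANGE = (100, 150)
LONG_RANGE = (151, 220)

# 22 autosomes x 2 arms minus the acrocentric p-arms 13p/14p/15p/21p/22p.
NON_ACROCENTRIC_ARMS: tuple[str, ...] = tuple(
    f"{c}{a}"
    for c in range(1, 23)
    for a in ("p", "q")
    if not (a == "p" and c in (13, 14, 15, 21, 22))
)


@dataclass
class BinSet:
    """Ordered non-overlapping genomic bins with GC/mappability annotations."""

    bins: pd.DataFrame  # chrom, start, end, mean_gc, mean_mappability
    bin_size: int
    genome_build: str = "toy"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        b = self.bins.reset_index(drop=True)
        for chrom, grp in b.groupby("chrom", sort=False):
            s = grp["start"].to_numpy()
            e = grp["end"].to_numpy()
            if not (np.all(np.diff(s) > 0) and np.all(e[:-1] <= s[1:])):
                raise ValueError(f"bins on {chrom} must be sorted and non-overlapping")
        self.bins = b

    def __len__(self) -> int:
        return len(self.bins)

    @property
    def total_span(self) -> int:
        return int((self.bins["end"] - self.bins["start"]).sum())

    def assign_positions(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Bin index containing each (chrom, pos), or -1 if none."""
        out = np.full(len(pos), -1, dtype=np.int64)
        b = self.bins
        for c, grp in b.groupby("chrom", sort=False):
            mask = chrom == c
            if not mask.any():
                continue
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            p = pos[mask]
            j = np.searchsorted(starts, p, side="right") - 1
            ok = (j >= 0) & (p < ends[np.clip(j, 0, len(ends) - 1)])
            idx = np.where(ok, grp.index.to_numpy()[np.clip(j, 0, len(ends) - 1)], -1)
            out[mask] = idx
        return out

    def to_bed(self, path: str | Path) -> None:
        self.bins[["chrom", "start", "end", "mean_gc", "mean_mappability"]].to_csv(
            path, sep="\t", header=False, index=False
        )


def tile_genome(genome: GenomeResource, bin_size: int = 5_000_000) -> BinSet:
    """Consecutive fixed-size tiles per chromosome; a terminal partial tile is
    dropped so every bin has identical length."""
    rows = []
    for chrom, length in genome.chrom_lengths.items():
        n_full = length // bin_size
        for k in range(n_full):
            start, end = k * bin_size, (k + 1) * bin_size
            gc = (
                float(genome.gc_fraction(chrom, np.array([start]), np.array([end]))[0])
                if chrom in genome.is_gc
                else np.nan
            )
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "mean_gc": gc,
                    "mean_mappability": genome.mean_mappability(chrom, start, end),
                }
            )
    cols = ["chrom", "start", "end", "mean_gc", "mean_mappability"]
    bins = pd.DataFrame(rows, columns=cols)
    return BinSet(bins=bins, bin_size=int(bin_size))


def filter_bins(bins: BinSet, min_gc: float = 0.3, min_mappability: float = 0.9) -> BinSet:
    """Keep bins with mean GC >= min_gc and mean mappability >= min_mappability."""
    b = bins.bins
    if b["mean_gc"].isna().any() or b["mean_mappability"].isna().any():
        raise ValueError("bins must be GC/mappability annotated before filtering")
    keep = (b["mean_gc"] >= min_gc) & (b["mean_mappability"] >= min_mappability)
    out = BinSet(
        bins=b.loc[keep].reset_index(drop=True),
        bin_size=bins.bin_size,
        genome_build=bins.genome_build,
        provenance={**bins.provenance, "min_gc": min_gc, "min_mappability": min_mappability},
    )
    return out


@dataclass
class FragmentationProfile:
    """Per-bin weighted short/long fragment counts and standardized ratios."""

    sample_id: str
    table: pd.DataFrame  # chrom, start, end, short, long, ratio, standardized

    @property
    def standardized(self) -> np.ndarray:
        return self.table["standardized"].to_numpy()

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def fragmentation_profile(
    fs: FragmentSet,
    weights: FragmentWeights,
    bins: BinSet,
    short: tuple[int, int] = SHORT_RANGE,
    long: tuple[int, int] = LONG_RANGE,
) -> FragmentationProfile:
    """GC-weighted short/long ratio per bin, standardized genome-wide.

    Fragments are assigned to the bin containing their midpoint (a partition:
    nothing is counted twice). Lengths outside both windows contribute to
    neither count. Raises if any bin has zero weighted long count, naming it.
    """
    if len(weights) != len(fs):
        raise ValueError("weights not aligned to fragment set")
    lengths = fs.lengths
    mid = fs.midpoints
    bidx = bins.assign_positions(fs.records["chrom"].to_numpy(), mid)
    inside = bidx >= 0
    nb = len(bins)

    def wsum(lo: int, hi: int) -> np.ndarray:
        sel = inside & (lengths >= lo) & (lengths <= hi)
        return np.bincount(bidx[sel], weights=weights.w[sel], minlength=nb)

    s = wsum(*short)
    l = wsum(*long)
    if (l == 0).any():
        i = int(np.flatnonzero(l == 0)[0])
        row = bins.bins.iloc[i]
        raise ValueError(
            f"bin {row['chrom']}:{row['start']}-{row['end']} has zero weighted "
            "long-fragment count; ratio undefined (insufficient depth?)"
        )
    ratio = s / l
    std = (ratio - ratio.mean()) / ratio.std(ddof=1)
    table = bins.bins[["chrom", "start", "end"]].copy()
    table["short"] = s
    table["long"] = l
    table["ratio"] = ratio
    table["standardized"] = std
    return FragmentationProfile(sample_id=fs.sample_id, table=table)


# ---------------------------------------------------------------------------
# Arm-level representation


def arm_weighted_counts(
    fs: FragmentSet, weights: FragmentWeights, arms: pd.DataFrame
) -> pd.Series:
    """Total GC-weighted fragment count per chromosome arm (midpoint rule).

    ``arms`` has columns arm/chrom/start/end, one row per arm.
    """
    if len(weights) != len(fs):
        raise ValueError("weights not aligned to fragment set")
    mid = fs.midpoints
    chrom = fs.records["chrom"].to_numpy()
    out = {}
    for _, row in arms.iterrows():
        sel = (chrom == row["chrom"]) & (mid >= row["start"]) & (mid < row["end"])
        out[row["arm"]] = float(weights.w[sel].sum())
    return pd.Series(out, name=fs.sample_id)


@dataclass
class ReferencePanel:
    """Arm-count statistics (and the GC target) from a non-cancer panel."""

    sample_ids: tuple[str, ...]
    arm_means: pd.Series
    arm_sds: pd.Series
    target: TargetDistribution | None = None

    def __post_init__(self) -> None:
        if len(self.sample_ids) < 2:
            raise ValueError("reference panel needs >= 2 samples")
        if (self.arm_sds <= 0).any():
            bad = self.arm_sds.index[self.arm_sds <= 0].tolist()
            raise ValueError(f"panel arm SD not positive for arms: {bad}")

    @classmethod
    def from_counts(
        cls, panel_counts: pd.DataFrame, target: TargetDistribution | None = None
    ) -> "ReferencePanel":
        """``panel_counts``: samples x arms table of weighted arm counts."""
        return cls(
            sample_ids=tuple(str(i) for i in panel_counts.index),
            arm_means=panel_counts.mean(axis=0),
            arm_sds=panel_counts.std(axis=0, ddof=1),
            target=target,
        )


@dataclass
class ArmZScores:
    sample_id: str
    counts: pd.Series
    z: pd.Series

    def __post_init__(self) -> None:
        if not np.isfinite(self.z.to_numpy(dtype=float)).all():
            raise ValueError("arm z-scores must be finite")


def arm_zscores(
    fs: FragmentSet,
    weights: FragmentWeights,
    arms: pd.DataFrame,
    panel: ReferencePanel,
) -> ArmZScores:
    """z = (weighted arm count - panel mean) / panel SD for every arm."""
    counts = arm_weighted_counts(fs, weights, arms)
    missing = [a for a in counts.index if a not in panel.arm_means.index]
    if missing:
        raise KeyError(f"arms missing from reference panel: {missing}")
    z = (counts - panel.arm_means[counts.index]) / panel.arm_sds[counts.index]
    return ArmZScores(sample_id=fs.sample_id, counts=counts, z=z)


# ---------------------------------------------------------------------------
# Copy-number segment -> bin status


def bin_copy_number_status(
    segments: pd.DataFrame,
    bins: BinSet,
    gain_threshold: float,
    loss_threshold: float,
    min_covered_frac: float = 0.9,
) -> pd.Series:
    """Label each bin gain/loss/neutral from one sample's copy segments.

    A bin is a gain (loss) iff segments with log ratio above the gain
    threshold (below the loss threshold) cover >= ``min_covered_frac`` of it.
    ``segments`` columns: chrom, start, end, log2ratio; segments must not
    overlap within the sample.
    """
    seg = segments.sort_values(["chrom", "start"]).reset_index(drop=True)
    if (seg["start"] >= seg["end"]).any():
        raise ValueError("segments must satisfy start < end")
    if not np.isfinite(seg["log2ratio"].to_numpy(dtype=float)).all():
        raise ValueError("segment log ratios must be finite")
    for chrom, grp in seg.groupby("chrom"):
        if (grp["end"].to_numpy()[:-1] > grp["start"].to_numpy()[1:]).any():
            raise ValueError(f"overlapping segments on {chrom}")

    def covered(bin_row, sub: pd.DataFrame) -> float:
        lo = np.maximum(sub["start"].to_numpy(), bin_row["start"])
        hi = np.minimum(sub["end"].to_numpy(), bin_row["end"])
        return float(np.clip(hi - lo, 0, None).sum())

    statuses = []
    for _, b in bins.bins.iterrows():
        sub = seg[seg["chrom"] == b["chrom"]]
        binlen = b["end"] - b["start"]
        gain_cov = covered(b, sub[sub["log2ratio"] > gain_threshold])
        loss_cov = covered(b, sub[sub["log2ratio"] < loss_threshold])
        if gain_cov / binlen >= min_covered_frac:
            statuses.append("gain")
        elif loss_cov / binlen >= min_covered_frac:
            statuses.append("loss")
        else:
            statuses.append("neutral")
    return pd.Series(statuses, index=bins.bins.index, name="status")


def cohort_alteration_frequency(statuses: Sequence[pd.Series]) -> pd.DataFrame:
    """Fraction of samples with gain / loss status per bin."""
    if len(statuses) == 0:
        raise ValueError("empty cohort")
    mat = pd.concat(statuses, axis=1)
    return pd.DataFrame(
        {
            "gain_freq": (mat == "gain").mean(axis=1),
            "loss_freq": (mat == "loss").mean(axis=1),
        }
    )
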