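"""Transcription-factor-binding-site fragmentomics.

Nucleosome-free DNA at active TF binding sites is under-protected in plasma,
so cfDNA coverage dips at sites bound in the tumor's cell of origin. Given a
tissue-specific factor (ranked from expression: unexpressed in off-tissue
groups, highest median TPM in the target group) and its ChIP-seq peaks, we
aggregate fragment coverage by position in a +/-3000 bp window around peak
centers and summarize each sample by (i) relative coverage, the center/flank
coverage ratio, and (ii) relative fragment size, the center/flank mean
length ratio among sub-200 bp fragments. These separate histologic subtypes
(e.g. ASCL1 for small-cell lung cancer).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .fragments import FragmentSet

__all__ = [
    "PositionalCoverage",
    "rank_group_specific_tfs",
    "restrict_autosomal",
    "peak_centers",
    "positional_coverage",
    "positional_size_profile",
    "peak_mean_coverage",
    "exclude_high_coverage_peaks",
    "relative_coverage",
    "relative_fragment_size",
    "call_overexpressed",
]

AUTOSOMES = {f"chr{i}" for i in range(1, 23)} | {str(i) for i in range(1, 23)}


def rank_group_specific_tfs(
    expr: pd.DataFrame,
    groups: pd.Series,
    tf_list: Sequence[str],
    off_groups: Sequence[str],
    target_group: str,
    unexpressed_threshold: float = 1.0,
) -> pd.DataFrame:
    """Rank TFs specific to one tissue group by expression.

    ``expr`` is genes x samples TPM; ``groups`` maps sample -> group. Keeps
    TFs with median TPM strictly below the threshold in every off-group and
    sorts by descending median TPM in the target group. Returns a table with
    one median-TPM column per group, target group's first.
    """
    tfs = [g for g in tf_list if g in expr.index]
    if not tfs:
        raise ValueError("no TF in the list is present in the expression matrix")
    sub = expr.loc[tfs]
    medians = sub.T.groupby(groups).median().T  # tfs x groups
    for g in list(off_groups) + [target_group]:
        if g not in medians.columns:
            raise ValueError(f"group {g!r} absent from expression matrix")
    keep = (medians[list(off_groups)] < unexpressed_threshold).all(axis=1)
    out = medians.loc[keep].sort_values(target_group, ascending=False)
    return out[[target_group] + [g for g in medians.columns if g != target_group]]


def restrict_autosomal(peaks: pd.DataFrame) -> pd.DataFrame:
    """Keep peaks on chromosomes 1-22 ('chrN' or bare 'N' naming)."""
    return peaks[peaks["chrom"].astype(str).isin(AUTOSOMES)].reset_index(drop=True)


def peak_centers(peaks: pd.DataFrame) -> np.ndarray:
    """Peak center = floor((start + end) / 2)."""
    return ((peaks["start"].to_numpy(np.int64) + peaks["end"].to_numpy(np.int64)) // 2)


@dataclass
class PositionalCoverage:
    """Mean fragment coverage per offset (-halfwidth..+halfwidth) across
    peaks for one sample."""

    sample_id: str
    offsets: np.ndarray
    coverage: np.ndarray
    n_peaks: int

    def __post_init__(self) -> None:
        if len(self.offsets) != len(self.coverage):
            raise ValueError("offsets/coverage misaligned")
        if (np.asarray(self.coverage) < 0).any():
            raise ValueError("coverage must be non-negative")


def _chrom_pileups(
    fs: FragmentSet, value: np.ndarray | None = None, max_length: int | None = None
) -> dict[str, np.ndarray]:
    """Per-chromosome per-base pileup: count of overlapping fragments (or sum
    of ``value`` over overlapping fragments)."""
    r = fs.records
    lengths = fs.lengths
    out: dict[str, np.ndarray] = {}
    for chrom, grp in r.groupby("chrom", sort=False):
        i = grp.index.to_numpy()
        if max_length is not None:
            i = i[lengths[i] < max_length]
        s = r["start"].to_numpy()[i]
        e = r["end"].to_numpy()[i]
        L = int(e.max()) if len(e) else 1
        diff = np.zeros(L + 1)
        v = np.ones(len(i)) if value is None else np.asarray(value, float)[i]
        np.add.at(diff, s, v)
        np.add.at(diff, e, -v)
        out[str(chrom)] = np.cumsum(diff)[:-1]
    return out


def _window_sum(
    pile: dict[str, np.ndarray],
    peaks: pd.DataFrame,
    halfwidth: int,
    chrom_lengths: dict[str, int] | None,
) -> tuple[np.ndarray, int]:
    """Sum pileup windows across peaks; skips out-of-bounds windows."""
    width = 2 * halfwidth + 1
    acc = np.zeros(width)
    used = 0
    centers = peak_centers(peaks)
    for chrom, c in zip(peaks["chrom"].astype(str), centers):
        lo, hi = c - halfwidth, c + halfwidth + 1
        bound = chrom_lengths.get(chrom) if chrom_lengths else None
        if lo < 0 or (bound is not None and hi > bound):
            import warnings

            warnings.warn(f"peak window {chrom}:{lo}-{hi} exceeds chromosome bounds; skipped")
            continue
        track = pile.get(chrom)
        if track is None:
            acc += 0.0
        else:
            seg = track[max(lo, 0): hi]
            if len(seg) < width:  # window extends past last covered base
                seg = np.pad(seg, (0, width - len(seg)))
            acc += seg
        used += 1
    return acc, used


def positional_coverage(
    fs: FragmentSet,
    peaks: pd.DataFrame,
    halfwidth: int = 3000,
    chrom_lengths: dict[str, int] | None = None,
) -> PositionalCoverage:
    """Mean overlap-pileup coverage per offset across all peak windows."""
    pile = _chrom_pileups(fs)
    acc, used = _window_sum(pile, peaks, halfwidth, chrom_lengths)
    if used == 0:
        raise ValueError("no usable peaks (all windows out of bounds or none given)")
    return PositionalCoverage(
        sample_id=fs.sample_id,
        offsets=np.arange(-halfwidth, halfwidth + 1),
        coverage=acc / used,
        n_peaks=used,
    )


def positional_size_profile(
    fs: FragmentSet,
    peaks: pd.DataFrame,
    halfwidth: int = 3000,
    max_length: int = 200,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-offset pooled fragment-length sums and counts (fragments shorter
    than ``max_length`` only). Columns: offset, length_sum, count."""
    lengths = fs.lengths.astype(float)
    size_pile = _chrom_pileups(fs, value=lengths, max_length=max_length)
    count_pile = _chrom_pileups(fs, max_length=max_length)
    ssum, used = _window_sum(size_pile, peaks, halfwidth, chrom_lengths)
    cnt, _ = _window_sum(count_pile, peaks, halfwidth, chrom_lengths)
    if used == 0:
        raise ValueError("no usable peaks")
    return pd.DataFrame(
        {"offset": np.arange(-halfwidth, halfwidth + 1), "length_sum": ssum, "count": cnt}
    )


def peak_mean_coverage(
    samples: Sequence[FragmentSet],
    peaks: pd.DataFrame,
    halfwidth: int = 3000,
    chrom_lengths: dict[str, int] | None = None,
) -> np.ndarray:
    """Per-peak coverage averaged over window positions, then over samples."""
    centers = peak_centers(peaks)
    per_sample = np.zeros((len(samples), len(peaks)))
    for si, fs in enumerate(samples):
        pile = _chrom_pileups(fs)
        for pi, (chrom, c) in enumerate(zip(peaks["chrom"].astype(str), centers)):
            track = pile.get(chrom)
            lo, hi = c - halfwidth, c + halfwidth + 1
            if track is None or lo < 0:
                continue
            seg = track[lo:hi]
            per_sample[si, pi] = seg.sum() / (2 * halfwidth + 1)
    return per_sample.mean(axis=0)


def exclude_high_coverage_peaks(
    peaks: pd.DataFrame, per_peak_mean: np.ndarray, max_mean: float = 3.0
) -> pd.DataFrame:
    """Drop peaks whose cross-sample average coverage strictly exceeds
    ``max_mean`` (repeat-like pileup artifacts)."""
    per_peak_mean = np.asarray(per_peak_mean, dtype=float)
    if len(per_peak_mean) != len(peaks):
        raise ValueError("per-peak means not aligned to peak table")
    return peaks[per_peak_mean <= max_mean].reset_index(drop=True)


def _window_mask(offsets: np.ndarray, lo: int, hi: int, symmetric: bool) -> np.ndarray:
    if symmetric:
        a = np.abs(offsets)
        return (a >= lo) & (a <= hi)
    return (offsets >= lo) & (offsets <= hi)


def relative_coverage(
    pc: PositionalCoverage,
    center_halfwidth: int = 100,
    flank_center: int = 2750,
    flank_halfwidth: int = 250,
) -> float:
    """Center/flank coverage ratio: mean over offsets within +/-100 bp of the
    site center divided by the mean over both 2750 +/- 250 bp flanks."""
    center = _window_mask(pc.offsets, 0, center_halfwidth, symmetric=True)
    flank = _window_mask(
        pc.offsets, flank_center - flank_halfwidth, flank_center + flank_halfwidth, symmetric=True
    )
    flank_mean = pc.coverage[flank].mean()
    if flank_mean <= 0:
        raise ValueError("zero flank coverage; relative coverage undefined")
    return float(pc.coverage[center].mean() / flank_mean)


def relative_fragment_size(
    sizes: pd.DataFrame,
    center_halfwidth: int = 100,
    flank_center: int = 1250,
    flank_halfwidth: int = 250,
) -> float:
    """Center/flank mean fragment-length ratio from a positional size profile
    (flanks at 1250 +/- 250 bp, pooled)."""
    off = sizes["offset"].to_numpy()
    center = _window_mask(off, 0, center_halfwidth, symmetric=True)
    flank = _window_mask(
        off, flank_center - flank_halfwidth, flank_center + flank_halfwidth, symmetric=True
    )
    c_cnt = sizes["count"].to_numpy()[center].sum()
    f_cnt = sizes["count"].to_numpy()[flank].sum()
    if c_cnt == 0 or f_cnt == 0:
        raise ValueError("empty center or flank window; fragment-size ratio undefined")
    c_mean = sizes["length_sum"].to_numpy()[center].sum() / c_cnt
    f_mean = sizes["length_sum"].to_numpy()[flank].sum() / f_cnt
    return float(c_mean / f_mean)


def call_overexpressed(expr: pd.DataFrame, gene: str) -> pd.Series:
    """Flag samples whose TPM for ``gene`` exceeds mean + 3 SD across all
    samples (SD over samples, ddof=1); all-False when variance is zero."""
    if gene not in expr.index:
        raise KeyError(f"gene {gene!r} not in expression matrix")
    if expr.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    vals = expr.loc[gene]
    sd = vals.std(ddof=1)
    if sd == 0:
        return pd.Series(False, index=vals.index, name=gene)
    return vals > vals.mean() + 3 * sd
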