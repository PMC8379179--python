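"""Synthetic cfDNA fragment data with the statistical structure the
pipeline assumes.

The generator emulates, at desk scale, the features of plasma whole-genome
fragment data the method exploits: a nucleosomal fragment-size distribution
(non-tumor fragments ~ truncated normal, mode 167 bp; tumor-derived
fragments shorter and more variable, mode 145 bp), tumor-fraction mixtures
in which tumor fragment positions are weighted by arm-level copy ratios,
PCR-style GC amplification bias (acceptance proportional to exp(beta * gc)),
and nucleosome-footprint depletion of tumor fragments at TF binding sites.
Every draw flows from one seed; each sample carries a truth record.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .fragments import FragmentSet, GenomeResource
from .profiles import BinSet, tile_genome

__all__ = [
    "SimulationConfig",
    "SyntheticSample",
    "make_toy_genome",
    "simulate_sample",
    "simulate_panel",
    "simulate_cohort",
]


def _default_gc_landscape(chrom_index: int, frac: np.ndarray) -> np.ndarray:
    """Smooth GC probability along the chromosome, varying ~0.35-0.55."""
    return 0.45 + 0.10 * np.sin(2 * np.pi * (3 * frac + 0.37 * chrom_index))


def make_toy_genome(
    n_chrom: int = 2,
    chrom_length: int = 5_000_000,
    bin_size: int = 50_000,
    centromere_fraction: float = 0.5,
    gc_landscape: Callable[[int, np.ndarray], np.ndarray] | None = None,
    seed: int = 0,
) -> tuple[GenomeResource, BinSet, pd.DataFrame]:
    """Deterministic toy genome: per-base GC drawn from a smooth landscape,
    uniform mappability, arms split at a centromere fraction.

    Returns (genome, full-tile BinSet, arms table with arm/chrom/start/end).
    """
    if chrom_length < 2 * bin_size:
        raise ValueError("chromosomes must span at least two bins")
    if not 0 < centromere_fraction < 1:
        raise ValueError("centromere_fraction must be in (0, 1)")
    landscape = gc_landscape or _default_gc_landscape
    rng = np.random.default_rng(seed)
    is_gc: dict[str, np.ndarray] = {}
    lengths: dict[str, int] = {}
    arm_rows = []
    for i in range(n_chrom):
        chrom = f"chr{i + 1}"
        frac = np.arange(chrom_length) / chrom_length
        p = np.clip(landscape(i, frac), 0.0, 1.0)
        is_gc[chrom] = rng.random(chrom_length) < p
        lengths[chrom] = chrom_length
        cen = int(chrom_length * centromere_fraction)
        arm_rows.append({"arm": f"{i + 1}p", "chrom": chrom, "start": 0, "end": cen})
        arm_rows.append({"arm": f"{i + 1}q", "chrom": chrom, "start": cen, "end": chrom_length})
    genome = GenomeResource(chrom_lengths=lengths, is_gc=is_gc)
    bins = tile_genome(genome, bin_size=bin_size)
    return genome, bins, pd.DataFrame(arm_rows)


@dataclass
class SimulationConfig:
    """Per-sample generator settings.

    tf: tumor fraction of fragments; depth: accepted fragments per sample;
    beta_gc: GC amplification bias exponent (acceptance prop. to
    exp(beta*gc)); sizes: (mean, sd) of the normal/tumor components,
    truncated to ``size_bounds``; cna_segments: chrom/start/end/copy_ratio
    table weighting tumor fragment positions; tfbs_sites: chrom/center table
    where tumor fragments overlapping center +/- tfbs_halfwidth are thinned
    by tfbs_depletion.
    """

    tf: float = 0.0
    depth: int = 100_000
    beta_gc: float = 0.0
    normal_size: tuple[float, float] = (167.0, 10.0)
    tumor_size: tuple[float, float] = (145.0, 15.0)
    size_bounds: tuple[int, int] = (50, 400)
    cna_segments: pd.DataFrame | None = None
    tfbs_sites: pd.DataFrame | None = None
    tfbs_depletion: float = 0.0
    tfbs_halfwidth: int = 100
    mapq: int = 60
    position_resolution: int = 1_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.tf <= 1.0:
            raise ValueError("tumor fraction must be in [0, 1]")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0.0 <= self.tfbs_depletion <= 1.0:
            raise ValueError("depletion factor must be in [0, 1]")


@dataclass
class SyntheticSample:
    fragments: FragmentSet
    truth: dict = field(default_factory=dict)


def _position_weights(
    genome: GenomeResource, segments: pd.DataFrame | None, resolution: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Genome discretized into cells with relative sampling weight 1 (normal)
    and the local copy ratio (tumor)."""
    chroms, cell_starts, cell_lens = [], [], []
    for ci, (chrom, L) in enumerate(genome.chrom_lengths.items()):
        starts = np.arange(0, L, resolution)
        ends = np.minimum(starts + resolution, L)
        chroms.append(np.full(len(starts), ci))
        cell_starts.append(starts)
        cell_lens.append(ends - starts)
    chrom_idx = np.concatenate(chroms)
    starts = np.concatenate(cell_starts)
    lens = np.concatenate(cell_lens).astype(float)
    ratio = np.ones(len(starts))
    if segments is not None:
        names = list(genome.chrom_lengths)
        for _, seg in segments.iterrows():
            ci = names.index(seg["chrom"])
            mid = starts + lens / 2
            sel = (chrom_idx == ci) & (mid >= seg["start"]) & (mid < seg["end"])
            ratio[sel] = seg["copy_ratio"]
    return chrom_idx, starts, lens, ratio


def simulate_sample(
    genome: GenomeResource,
    cfg: SimulationConfig,
    seed: int,
    sample_id: str = "synthetic",
) -> SyntheticSample:
    """Draw one sample of ``cfg.depth`` accepted fragments.

    Each candidate fragment is tumor-derived with probability tf (position
    weighted by local copy ratio, size from the tumor component, thinned at
    TFBS windows), otherwise non-tumor; acceptance with probability
    exp(beta_gc * (gc - 1)) injects the amplification bias.
    """
    rng = np.random.default_rng(seed)
    chrom_names = list(genome.chrom_lengths)
    chrom_idx, cell_starts, cell_lens, ratio = _position_weights(
        genome, cfg.cna_segments, cfg.position_resolution
    )
    p_normal = cell_lens / cell_lens.sum()
    w_tumor = cell_lens * ratio
    p_tumor = w_tumor / w_tumor.sum()
    chrom_length = np.array([genome.chrom_lengths[c] for c in chrom_names])

    sites_by_chrom: dict[int, np.ndarray] = {}
    if cfg.tfbs_sites is not None and len(cfg.tfbs_sites):
        for chrom, grp in cfg.tfbs_sites.groupby("chrom"):
            sites_by_chrom[chrom_names.index(str(chrom))] = np.sort(
                grp["center"].to_numpy(np.int64)
            )

    lo, hi = cfg.size_bounds
    out_chrom: list[np.ndarray] = []
    out_start: list[np.ndarray] = []
    out_end: list[np.ndarray] = []
    out_gc: list[np.ndarray] = []
    accepted = 0
    for _ in range(200):
        if accepted >= cfg.depth:
            break
        need = cfg.depth - accepted
        batch = int(min(max(need * np.exp(cfg.beta_gc * 0.5) * 1.3, 10_000), 4_000_000))
        tumor = rng.random(batch) < cfg.tf
        cells = np.empty(batch, dtype=np.int64)
        nt = int(tumor.sum())
        if nt:
            cells[tumor] = rng.choice(len(p_tumor), size=nt, p=p_tumor)
        if batch - nt:
            cells[~tumor] = rng.choice(len(p_normal), size=batch - nt, p=p_normal)
        ci = chrom_idx[cells]
        center = cell_starts[cells] + rng.integers(0, np.maximum(cell_lens[cells], 1))
        mean = np.where(tumor, cfg.tumor_size[0], cfg.normal_size[0])
        sd = np.where(tumor, cfg.tumor_size[1], cfg.normal_size[1])
        length = np.clip(np.rint(rng.normal(mean, sd)), lo, hi).astype(np.int64)
        start = np.clip(center - length // 2, 0, chrom_length[ci] - length)
        end = start + length

        keep = np.ones(batch, dtype=bool)
        if cfg.tfbs_depletion > 0 and sites_by_chrom:
            for cix, centers in sites_by_chrom.items():
                sel = tumor & (ci == cix)
                if not sel.any():
                    continue
                # fragment overlaps the depleted window center +/- halfwidth
                j = np.searchsorted(centers, start[sel] - cfg.tfbs_halfwidth, side="left")
                j = np.clip(j, 0, len(centers) - 1)
                near = (centers[j] - cfg.tfbs_halfwidth < end[sel]) & (
                    centers[j] + cfg.tfbs_halfwidth + 1 > start[sel]
                )
                thin = near & (rng.random(int(sel.sum())) < cfg.tfbs_depletion)
                k = keep[sel]
                k[thin] = False
                keep[sel] = k

        gc = np.empty(batch)
        for cix, chrom in enumerate(chrom_names):
            m = ci == cix
            if m.any():
                gc[m] = genome.gc_fraction(chrom, start[m], end[m])
        if cfg.beta_gc != 0.0:
            keep &= rng.random(batch) < np.exp(cfg.beta_gc * (gc - 1.0))

        out_chrom.append(ci[keep])
        out_start.append(start[keep])
        out_end.append(end[keep])
        out_gc.append(gc[keep])
        accepted += int(keep.sum())
    if accepted < cfg.depth:
        raise RuntimeError(
            "fragment acceptance too low to reach requested depth; "
            "increase depth budget or reduce |beta_gc| / depletion"
        )
    ci = np.concatenate(out_chrom)[: cfg.depth]
    start = np.concatenate(out_start)[: cfg.depth]
    end = np.concatenate(out_end)[: cfg.depth]
    gc = np.concatenate(out_gc)[: cfg.depth]
    df = pd.DataFrame(
        {
            "chrom": pd.Series(np.array(chrom_names, dtype=object)[ci]),
            "start": start,
            "end": end,
            "mapq": float(cfg.mapq),
            "gc": gc,
        }
    )
    truth = {
        "tf": cfg.tf,
        "beta_gc": cfg.beta_gc,
        "tfbs_depletion": cfg.tfbs_depletion,
        "cna_segments": None if cfg.cna_segments is None else cfg.cna_segments.copy(),
        "seed": seed,
    }
    fs = FragmentSet(sample_id=sample_id, records=df, filtered=False, gc_annotated=True)
    return SyntheticSample(fragments=fs, truth=truth)


def simulate_panel(
    genome: GenomeResource,
    cfg: SimulationConfig,
    n: int,
    seed: int,
    prefix: str = "panel",
) -> list[SyntheticSample]:
    """Reference panel: n tumor-free samples sharing the base configuration."""
    base = replace(cfg, tf=0.0, cna_segments=None, tfbs_depletion=0.0)
    root = np.random.default_rng(seed)
    seeds = root.integers(0, 2**31 - 1, size=n)
    return [
        simulate_sample(genome, base, int(s), sample_id=f"{prefix}{i:03d}")
        for i, s in enumerate(seeds)
    ]


_COVARIATE_DEFAULTS = {
    "age": {"control": (62.0, 8.0), "case": (69.0, 9.0)},  # normal(mean, sd)
    "pack_years": {"control": (26.0, 15.0), "case": (42.0, 20.0)},
    "copd_rate": {"control": 0.15, "case": 0.35},
    "log_cea": {"control": (0.7, 0.6), "case": (1.5, 1.0)},  # CEA ~ lognormal
}


def simulate_cohort(
    genome: GenomeResource,
    n_cases: int,
    n_controls: int,
    case_cfg: SimulationConfig,
    tf_distribution: float | Callable[[np.random.Generator], float] = 0.3,
    seed: int = 0,
    covariates: bool = False,
    covariate_params: dict | None = None,
) -> tuple[list[SyntheticSample], pd.DataFrame]:
    """Labeled cohort: controls at tf = 0, cases at tf from the given value
    or sampler, all sharing the case configuration otherwise.

    Returns (samples, truth table indexed by sample id with label, tf, and
    optional clinical covariates drawn with class-conditional shifts).
    """
    if n_cases < 1 or n_controls < 1:
        raise ValueError("need at least one case and one control")
    root = np.random.default_rng(seed)
    params = {**_COVARIATE_DEFAULTS, **(covariate_params or {})}
    samples: list[SyntheticSample] = []
    rows = []
    for i in range(n_cases + n_controls):
        is_case = i < n_cases
        sid = f"{'case' if is_case else 'ctrl'}{i:03d}"
        if is_case:
            tf = tf_distribution(root) if callable(tf_distribution) else float(tf_distribution)
            cfg_i = replace(case_cfg, tf=tf)
        else:
            tf = 0.0
            cfg_i = replace(case_cfg, tf=0.0, cna_segments=None, tfbs_depletion=0.0)
        s = simulate_sample(genome, cfg_i, int(root.integers(0, 2**31 - 1)), sample_id=sid)
        samples.append(s)
        row = {"sample_id": sid, "label": int(is_case), "tf": tf}
        if covariates:
            grp = "case" if is_case else "control"
            row["age"] = max(30.0, root.normal(*params["age"][grp]))
            row["pack_years"] = max(0.0, root.normal(*params["pack_years"][grp]))
            row["copd"] = int(root.random() < params["copd_rate"][grp])
            row["cea"] = float(np.expm1(root.normal(*params["log_cea"][grp])).clip(0.0))
        rows.append(row)
    truth = pd.DataFrame(rows).set_index("sample_id")
    return samples, truth
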