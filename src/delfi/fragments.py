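"""Reading, filtering, and GC-annotating cfDNA fragment intervals.

A "fragment" is the genomic interval covered by a sequenced cfDNA molecule
(both mates of an aligned pair collapsed to one interval). Coordinates are
BED-style 0-based half-open throughout; MAPQ rides in BED column 5.
Alignment, deduplication and pairing are assumed to have happened upstream.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FragmentSet",
    "GenomeResource",
    "read_fragments",
    "write_fragments",
    "filter_fragments",
    "annotate_gc",
]

FRAGMENT_COLUMNS = ["chrom", "start", "end", "mapq", "gc"]


@dataclass
class FragmentSet:
    """One sample's cfDNA fragments in columnar form.

    ``records`` is a DataFrame with columns chrom/start/end/mapq/gc; ``mapq``
    and ``gc`` are NaN until supplied/annotated. ``filtered`` and
    ``gc_annotated`` track pipeline state.
    """

    sample_id: str
    records: pd.DataFrame
    filtered: bool = False
    gc_annotated: bool = False

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        df = self.records
        missing = [c for c in ("chrom", "start", "end") if c not in df.columns]
        if missing:
            raise ValueError(f"records missing columns: {missing}")
        for c in ("mapq", "gc"):
            if c not in df.columns:
                df[c] = np.nan
            elif df[c].dtype != float:
                df[c] = df[c].astype(float)
        if len(df):
            bad = df["start"] >= df["end"]
            if bad.any():
                i = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValueError(
                    f"fragment {i}: start {df['start'].iloc[i]} >= end {df['end'].iloc[i]}"
                )
            gc = df["gc"].to_numpy(dtype=float)
            ok = np.isnan(gc) | ((gc >= 0.0) & (gc <= 1.0))
            if not ok.all():
                raise ValueError("gc values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def lengths(self) -> np.ndarray:
        return (self.records["end"] - self.records["start"]).to_numpy()

    @property
    def midpoints(self) -> np.ndarray:
        r = self.records
        return ((r["start"].to_numpy() + r["end"].to_numpy()) // 2).astype(np.int64)


def _merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if len(starts) == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    ms, me = [s[0]], [e[0]]
    for a, b in zip(s[1:], e[1:]):
        if a <= me[-1]:
            me[-1] = max(me[-1], b)
        else:
            ms.append(a)
            me.append(b)
    return np.asarray(ms, dtype=np.int64), np.asarray(me, dtype=np.int64)


@dataclass
class GenomeResource:
    """Reference context: chromosome sizes, sequence GC, mappability, blacklist.

    Sequence is held as one boolean is-G/C array per chromosome (built from a
    FASTA or from in-memory strings); ambiguous bases count as non-GC so GC
    fractions are always defined. Mappability is an optional per-chromosome
    step function from a bedGraph. Blacklist intervals are merged on load.
    """

    chrom_lengths: dict[str, int]
    is_gc: dict[str, np.ndarray] = field(default_factory=dict)
    mappability: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(default_factory=dict)
    blacklist: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    _gc_cumsum: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for chrom, n in self.chrom_lengths.items():
            if n <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length {n}")
        for chrom, (bs, be) in self.blacklist.items():
            n = self.chrom_lengths.get(chrom)
            if n is not None and len(bs) and (bs.min() < 0 or be.max() > n):
                raise ValueError(f"blacklist interval outside bounds on {chrom}")

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_sequences(cls, sequences: dict[str, str], **kw) -> "GenomeResource":
        is_gc = {
            c: np.isin(np.frombuffer(s.upper().encode(), dtype=np.uint8), [ord("G"), ord("C")])
            for c, s in sequences.items()
        }
        lengths = {c: len(s) for c, s in sequences.items()}
        return cls(chrom_lengths=lengths, is_gc=is_gc, **kw)

    @classmethod
    def from_fasta(cls, path: str | Path, **kw) -> "GenomeResource":
        from pyfaidx import Fasta

        fa = Fasta(str(path))
        return cls.from_sequences({name: str(fa[name][:]) for name in fa.keys()}, **kw)

    def with_blacklist(self, bed_path: str | Path) -> "GenomeResource":
        df = pd.read_csv(bed_path, sep="\t", header=None, comment="#",
                         usecols=[0, 1, 2], names=["chrom", "start", "end"])
        bl: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, grp in df.groupby("chrom"):
            bl[str(chrom)] = _merge_intervals(
                grp["start"].to_numpy(np.int64), grp["end"].to_numpy(np.int64)
            )
        return replace(self, blacklist=bl)

    def with_mappability(self, bedgraph_path: str | Path) -> "GenomeResource":
        df = pd.read_csv(bedgraph_path, sep="\t", header=None, comment="#",
                         usecols=[0, 1, 2, 3], names=["chrom", "start", "end", "value"])
        mp = {
            str(c): (g["start"].to_numpy(np.int64), g["end"].to_numpy(np.int64),
                     g["value"].to_numpy(float))
            for c, g in df.groupby("chrom")
        }
        return replace(self, mappability=mp)

    # -- queries -----------------------------------------------------------
    def _cumsum(self, chrom: str) -> np.ndarray:
        cs = self._gc_cumsum.get(chrom)
        if cs is None:
            if chrom not in self.is_gc:
                raise KeyError(f"no sequence available for chromosome {chrom}")
            cs = np.concatenate([[0], np.cumsum(self.is_gc[chrom], dtype=np.int64)])
            self._gc_cumsum[chrom] = cs
        return cs

    def gc_fraction(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """GC fraction of [start, end) intervals; N and other ambiguity codes
        count as non-GC."""
        n = self.chrom_lengths[chrom]
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if len(starts) and (starts.min() < 0 or ends.max() > n):
            raise ValueError(f"interval outside chromosome {chrom} bounds [0, {n})")
        cs = self._cumsum(chrom)
        return (cs[ends] - cs[starts]) / (ends - starts)

    def mean_mappability(self, chrom: str, start: int, end: int) -> float:
        """Length-weighted mean of the mappability step function over
        [start, end); positions not covered by the track count as 0. Returns
        1.0 when no track is loaded (every base assumed uniquely mappable)."""
        if chrom not in self.mappability:
            return 1.0
        ms, me, mv = self.mappability[chrom]
        lo = np.clip(ms, start, end)
        hi = np.clip(me, start, end)
        return float(np.sum((hi - lo) * mv) / (end - start))

    def overlaps_blacklist(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Boolean mask: does each [start, end) overlap any blacklist interval
        by >= 1 bp."""
        if chrom not in self.blacklist:
            return np.zeros(len(starts), dtype=bool)
        bs, be = self.blacklist[chrom]
        if len(bs) == 0:
            return np.zeros(len(starts), dtype=bool)
        idx = np.searchsorted(bs, ends, side="left") - 1
        hit = idx >= 0
        hit[hit] = be[idx[hit]] > np.asarray(starts)[hit]
        return hit


def read_fragments(path: str | Path | io.TextIOBase, sample_id: str) -> FragmentSet:
    """Read a fragment BED (3-6 columns) into a FragmentSet.

    Column 5 (the BED score slot), when present, is interpreted as MAPQ.
    Coordinates are kept 0-based half-open. Malformed lines raise ValueError
    naming the 1-based line number.
    """
    if isinstance(path, (str, Path)):
        with open(path) as fh:
            lines = fh.read().splitlines()
    else:
        lines = path.read().splitlines()
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    mapqs: list[float] = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"line {lineno}: expected >= 3 tab-separated columns")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: non-integer coordinates") from exc
        if start < 0 or start >= end:
            raise ValueError(f"line {lineno}: invalid interval [{start}, {end})")
        mq = np.nan
        if len(parts) >= 5 and parts[4] not in (".", ""):
            try:
                mq = float(parts[4])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-numeric MAPQ {parts[4]!r}") from exc
        chroms.append(parts[0])
        starts.append(start)
        ends.append(end)
        mapqs.append(mq)
    df = pd.DataFrame(
        {
            "chrom": pd.Series(chroms, dtype=object),
            "start": pd.Series(starts, dtype=np.int64),
            "end": pd.Series(ends, dtype=np.int64),
            "mapq": pd.Series(mapqs, dtype=float),
            "gc": pd.Series(np.nan, index=range(len(chroms)), dtype=float),
        }
    )
    return FragmentSet(sample_id=sample_id, records=df)


def write_fragments(fs: FragmentSet, path: str | Path) -> None:
    """Write fragments as 5-column BED (name '.', MAPQ in the score slot)."""
    r = fs.records
    mapq = r["mapq"].map(lambda v: "." if pd.isna(v) else str(int(v)))
    out = pd.DataFrame(
        {"chrom": r["chrom"], "start": r["start"], "end": r["end"], "name": ".", "score": mapq}
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def filter_fragments(
    fs: FragmentSet, genome: GenomeResource, min_mapq: int = 30
) -> FragmentSet:
    """Drop fragments with MAPQ < min_mapq or any (>= 1 bp) blacklist overlap.

    Idempotent; raises if MAPQ is missing while a positive threshold is set.
    """
    r = fs.records
    keep = np.ones(len(r), dtype=bool)
    if min_mapq > 0:
        mq = r["mapq"].to_numpy(dtype=float)
        if len(r) and np.isnan(mq).any():
            raise ValueError("fragments lack MAPQ but min_mapq > 0")
        keep &= mq >= min_mapq
    for chrom, grp in r.groupby("chrom", sort=False):
        hits = genome.overlaps_blacklist(
            str(chrom), grp["start"].to_numpy(), grp["end"].to_numpy()
        )
        keep[grp.index.to_numpy()] &= ~hits
    out = r.loc[keep].reset_index(drop=True)
    return FragmentSet(fs.sample_id, out, filtered=True, gc_annotated=fs.gc_annotated)


def annotate_gc(fs: FragmentSet, genome: GenomeResource) -> FragmentSet:
    """Set each fragment's gc to its reference-base GC fraction.

    gc = (# G or C in [start, end)) / length; ambiguous bases are non-GC.
    The result is independent of record order.
    """
    r = fs.records.copy()
    gc = np.empty(len(r), dtype=float)
    for chrom, grp in r.groupby("chrom", sort=False):
        gc[grp.index.to_numpy()] = genome.gc_fraction(
            str(chrom), grp["start"].to_numpy(), grp["end"].to_numpy()
        )
    r["gc"] = gc
    return FragmentSet(fs.sample_id, r, filtered=fs.filtered, gc_annotated=True)
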