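"""Permutation-based QTL detection on the circularized genome.

To obtain a genome-wide significance threshold that respects linkage, the
windowed per-pair difference profiles are concatenated chromosome by
chromosome into a single ring (the end of the last chromosome joined to the
beginning of the first).  Each permutation rotates every pair's ring by an
independent uniform offset — preserving each profile's autocorrelation while
breaking the between-pair alignment — averages the rotated rings and records
the maximal absolute deviation.  The observed averaged track is then
thresholded at the upper quantile of this max-deviation distribution (the
level conventionally labelled an FDR; the construction is family-wise).

Significant windows form contiguous runs (QTL calls); each call is extended
into a QTL interval by walking outward from the peak while at least one of
``block_len`` consecutive windows stays within ``similarity_delta`` of the
peak value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from hapbsa._rng import substream
from hapbsa.config import DegParams, IntervalParams, PermutationParams
from hapbsa.layout import GenomeLayout
from hapbsa.scan import PairedDiffTrack, WindowTrack

__all__ = [
    "CircularRings",
    "NullMaxDistribution",
    "QtlCall",
    "QtlInterval",
    "circularize",
    "rotate",
    "permutation_null",
    "call_qtls",
    "qtl_interval",
    "subsidiary_peaks",
    "count_degs_in_intervals",
]


@dataclass
class CircularRings:
    """Per-pair window values on the circularized genome.

    Windows missing in any pair are removed before rotation (their linear
    positions are remembered in ``window_index`` so ring positions can be
    mapped back to the grid).
    """

    rings: np.ndarray  # (n_pairs, n_windows)
    window_index: np.ndarray  # ring position -> index into the linear grid
    grid: WindowTrack

    @property
    def n_pairs(self) -> int:
        return self.rings.shape[0]

    def __len__(self) -> int:
        return self.rings.shape[1]

    def to_linear(self, ring_values: np.ndarray) -> np.ndarray:
        """Place ring-ordered values back on the linear grid (NaN where the
        ring has no window); inverse of the circularization for retained
        windows."""
        out = np.full(len(self.grid), np.nan)
        out[self.window_index] = ring_values
        return out


def circularize(diffs: PairedDiffTrack, layout: GenomeLayout) -> CircularRings:
    """Concatenate the window grid in layout order into one ring per pair.

    The grid produced by the scan already follows layout order, so ring
    neighbours across the seam are the last window of the last chromosome
    and the first window of the first.
    """
    grid = diffs.mean
    if len(grid) == 0:
        raise ValueError("empty track cannot be circularized")
    expected = [c for c, _ in layout.chromosomes]
    seen = list(pd.unique(grid.chrom))
    if seen != [c for c in expected if c in seen]:
        raise ValueError("track windows are not in layout chromosome order")
    stacked = np.vstack([t.value for t in diffs.per_pair])
    keep = ~np.isnan(stacked).any(axis=0)
    if not keep.any():
        raise ValueError("no window is non-missing in every pair")
    return CircularRings(
        rings=stacked[:, keep], window_index=np.flatnonzero(keep), grid=grid
    )


def rotate(ring: np.ndarray, offset: int) -> np.ndarray:
    """Circular rotation by ``offset`` windows (the permutation move)."""
    return np.roll(ring, offset)


@dataclass
class NullMaxDistribution:
    """Maximal absolute deviations of the pair-averaged ring, one per
    permutation, and the derived significance threshold."""

    maxima: np.ndarray  # sorted ascending
    fdr: float

    @property
    def n_permutations(self) -> int:
        return len(self.maxima)

    def threshold_at(self, fdr: float) -> float:
        """Empirical upper quantile: the value exceeded by exactly
        floor(fdr * n) permutation maxima."""
        if not (0.0 < fdr < 1.0):
            raise ValueError("fdr must lie in (0, 1)")
        k = int(np.floor(fdr * self.n_permutations))
        return float(np.sort(self.maxima)[::-1][k])

    @property
    def threshold(self) -> float:
        return self.threshold_at(self.fdr)


def permutation_null(
    rings: CircularRings,
    params: PermutationParams | None = None,
    rng: np.random.Generator | None = None,
) -> NullMaxDistribution:
    """Null distribution of the maximal deviation under independent uniform
    circular rotations of each pair's ring."""
    if params is None:
        params = PermutationParams()
    if rng is None:
        rng = substream(params.seed, "permute")
    r = rings.rings
    n_pairs, w = r.shape
    n_perm = params.n_permutations
    offsets = rng.integers(0, w, size=(n_perm, n_pairs))
    maxima = np.empty(n_perm)
    base = np.arange(w)
    chunk = max(1, min(n_perm, int(2e7) // max(w, 1)))
    for lo in range(0, n_perm, chunk):
        hi = min(lo + chunk, n_perm)
        acc = np.zeros((hi - lo, w))
        for p in range(n_pairs):
            idx = (offsets[lo:hi, p, None] + base[None, :]) % w
            acc += r[p][idx]
        maxima[lo:hi] = np.abs(acc / n_pairs).max(axis=1)
    return NullMaxDistribution(maxima=np.sort(maxima), fdr=params.fdr)


@dataclass
class QtlCall:
    """A maximal contiguous run of significant windows with its peak."""

    chrom: str
    peak_index: int  # index into the linear grid
    peak_start: int
    peak_end: int
    peak_value: float
    run_first: int
    run_last: int


def call_qtls(mean_track: WindowTrack, threshold: float) -> list[QtlCall]:
    """Call QTL as maximal runs of windows with |mean difference| >=
    ``threshold`` on the linear (de-circularized) grid.

    Runs never span chromosome boundaries; missing windows break runs; the
    peak is the window of largest absolute value, leftmost on ties.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    v = mean_track.value
    sig = ~np.isnan(v) & (np.abs(v) >= threshold)
    calls: list[QtlCall] = []
    i, n = 0, len(mean_track)
    while i < n:
        if not sig[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and sig[j + 1] and mean_track.chrom[j + 1] == mean_track.chrom[i]:
            j += 1
        run = np.abs(v[i : j + 1])
        peak = i + int(np.argmax(run))  # argmax returns the leftmost maximum
        calls.append(
            QtlCall(
                chrom=str(mean_track.chrom[i]),
                peak_index=peak,
                peak_start=int(mean_track.start[peak]),
                peak_end=int(mean_track.end[peak]),
                peak_value=float(v[peak]),
                run_first=i,
                run_last=j,
            )
        )
        i = j + 1
    return calls


@dataclass
class QtlInterval:
    """Peak-similarity-delimited genomic interval of a QTL call
    (1-based inclusive bp; exported half-open)."""

    chrom: str
    start: int
    end: int
    window_first: int
    window_last: int
    call: QtlCall

    @property
    def span(self) -> int:
        return self.end - self.start + 1


def qtl_interval(
    mean_track: WindowTrack, call: QtlCall, params: IntervalParams | None = None
) -> QtlInterval:
    """Delimit the QTL interval around a peak.

    A window is peak-similar when its value lies within
    ``similarity_delta`` of the peak value.  Walking outward from the peak,
    extension continues while the most recent block of ``block_len``
    consecutive windows contains at least one peak-similar window; the
    interval spans from the outermost similar window reached leftward to the
    outermost reached rightward.
    """
    if params is None:
        params = IntervalParams()
    v = mean_track.value
    on_chrom = mean_track.chrom == mean_track.chrom[call.peak_index]
    lo_bound = int(np.flatnonzero(on_chrom)[0])
    hi_bound = int(np.flatnonzero(on_chrom)[-1])
    similar = ~np.isnan(v) & (np.abs(v - call.peak_value) <= params.similarity_delta)

    def walk(direction: int) -> int:
        outermost = call.peak_index
        i = call.peak_index + direction
        gap = 0
        while lo_bound <= i <= hi_bound and gap < params.block_len:
            if similar[i]:
                outermost = i
                gap = 0
            else:
                gap += 1
            i += direction
        return outermost

    first = walk(-1)
    last = walk(+1)
    return QtlInterval(
        chrom=call.chrom,
        start=int(mean_track.start[first]),
        end=int(mean_track.end[last]),
        window_first=first,
        window_last=last,
        call=call,
    )


def subsidiary_peaks(
    mean_track: WindowTrack,
    threshold: float,
    k: int = 2,
    min_separation: int = 15,
) -> list[QtlCall]:
    """The top-k sub-threshold local maxima of |mean difference|.

    Reported without any significance claim; ``min_separation`` (windows)
    keeps the reported peaks in distinct regions.
    """
    v = mean_track.value
    absv = np.abs(v)
    ok = ~np.isnan(v) & (absv < threshold)
    order = np.argsort(-np.where(ok, absv, -np.inf))
    picked: list[int] = []
    for i in order:
        if not ok[i] or len(picked) >= k:
            break
        if all(abs(i - p) >= min_separation for p in picked):
            picked.append(int(i))
    return [
        QtlCall(
            chrom=str(mean_track.chrom[i]),
            peak_index=i,
            peak_start=int(mean_track.start[i]),
            peak_end=int(mean_track.end[i]),
            peak_value=float(v[i]),
            run_first=i,
            run_last=i,
        )
        for i in sorted(picked)
    ]


def count_degs_in_intervals(
    de_table: pd.DataFrame,
    annotation: pd.DataFrame,
    qtls: list[QtlInterval],
    params: DegParams | None = None,
) -> dict:
    """Count differentially expressed genes inside QTL intervals.

    A gene is a DEG when |fold change| >= ``fc_cutoff`` and adjusted p-value
    <= ``padj_cutoff``; it lies within an interval when its span overlaps it
    by at least 1 bp.  Returns per-interval counts, the total number of
    distinct DEGs inside any interval, the overall DEG count, and the
    fraction inside.
    """
    if params is None:
        params = DegParams()
    if de_table["gene"].duplicated().any():
        dup = de_table.loc[de_table["gene"].duplicated(), "gene"].iloc[0]
        raise ValueError(f"duplicate gene id in DE table: {dup!r}")
    merged = de_table.merge(annotation[["gene", "chrom", "start", "end"]], on="gene", how="left")
    if merged["chrom"].isna().any():
        missing = merged.loc[merged["chrom"].isna(), "gene"].iloc[0]
        raise ValueError(f"gene {missing!r} missing from annotation")
    is_deg = (merged["fc"].abs() >= params.fc_cutoff) & (merged["padj"] <= params.padj_cutoff)
    degs = merged[is_deg]
    per_qtl = []
    inside = pd.Series(False, index=degs.index)
    for iv in qtls:
        hit = (
            (degs["chrom"] == iv.chrom) & (degs["start"] <= iv.end) & (degs["end"] >= iv.start)
        )
        per_qtl.append(int(hit.sum()))
        inside |= hit
    n_deg = int(is_deg.sum())
    n_inside = int(inside.sum())
    return {
        "per_qtl": per_qtl,
        "n_degs_in_intervals": n_inside,
        "n_degs_total": n_deg,
        "fraction_in_intervals": (n_inside / n_deg) if n_deg else float("nan"),
        "genes_in_intervals": degs.loc[inside, "gene"].tolist(),
    }
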