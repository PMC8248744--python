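"""Sliding-window allele-frequency tracks and paired differences.

The DNA scan averages the transmitted-allele frequency of the informative
sites within 75 kb windows advanced in 5 kb steps (windows with fewer than
38 sites are set to missing), subtracts control from selected within each
population pair, and averages the per-pair differences.  The RNA variant
works at exonic biallelic positions passing coverage and control
major-allele-frequency filters and averages absolute per-pair differences in
500 kb non-overlapping windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hapbsa.config import RnaScanParams
from hapbsa.layout import GenomeLayout, WindowParams

__all__ = [
    "WindowTrack",
    "PairedDiffTrack",
    "windowed_frequency",
    "paired_difference",
    "average_pairs",
    "rna_bsa_scan",
]


@dataclass
class WindowTrack:
    """Per-window values on a fixed grid (1-based inclusive coordinates).

    ``value`` is NaN for windows failing the site-count criterion; ``n_sites``
    records how many sites informed each window.
    """

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    n_sites: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.chrom)
        for name in ("start", "end", "n_sites", "value"):
            if len(getattr(self, name)) != n:
                raise ValueError("window arrays must have equal length")

    def __len__(self) -> int:
        return len(self.chrom)

    def same_grid(self, other: "WindowTrack") -> bool:
        return (
            len(self) == len(other)
            and bool(np.all(self.chrom == other.chrom))
            and bool(np.all(self.start == other.start))
            and bool(np.all(self.end == other.end))
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.start,
                "end": self.end,
                "n_sites": self.n_sites,
                "value": self.value,
            }
        )

    def copy_with(self, value: np.ndarray, n_sites: np.ndarray | None = None) -> "WindowTrack":
        return WindowTrack(
            self.chrom,
            self.start,
            self.end,
            self.n_sites if n_sites is None else n_sites,
            np.asarray(value, dtype=float),
        )


@dataclass
class PairedDiffTrack:
    """Per-pair selected-minus-control window tracks plus their mean.

    The mean at a window is taken over the pairs with a non-missing value
    there (``n_pairs_used``); it is missing only where every pair is.
    """

    per_pair: list[WindowTrack]
    mean: WindowTrack
    n_pairs_used: np.ndarray
    pair_names: list[str] = field(default_factory=list)


def _check_sorted(sites: pd.DataFrame, layout: GenomeLayout) -> None:
    order = {c: i for i, c in enumerate(layout.names)}
    idx = sites["chrom"].map(order)
    if idx.isna().any():
        bad = sites.loc[idx.isna(), "chrom"].unique()
        raise ValueError(f"sites on chromosomes absent from layout: {list(bad)}")
    key = idx.to_numpy() * (max(layout.total_length, int(sites["pos"].max())) + 1) + sites[
        "pos"
    ].to_numpy()
    if np.any(np.diff(key) < 0):
        raise ValueError("sites must be sorted by (chrom, pos) in layout order")


def _window_means(
    pos: np.ndarray, values: np.ndarray, starts: np.ndarray, size: int
) -> tuple[np.ndarray, np.ndarray]:
    """Unweighted mean of ``values`` (NaN = absent site) over each window
    [start, start+size-1], via prefix sums."""
    valid = ~np.isnan(values)
    cs = np.concatenate([[0.0], np.cumsum(np.where(valid, values, 0.0))])
    cn = np.concatenate([[0], np.cumsum(valid.astype(np.int64))])
    lo = np.searchsorted(pos, starts, side="left")
    hi = np.searchsorted(pos, starts + size, side="left")
    n = cn[hi] - cn[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n > 0, (cs[hi] - cs[lo]) / np.maximum(n, 1), np.nan)
    return n, mean


def windowed_frequency(
    sites: pd.DataFrame,
    value_col: str,
    layout: GenomeLayout,
    params: WindowParams | None = None,
) -> WindowTrack:
    """Windowed unweighted mean of a per-site quantity.

    ``sites`` needs ``chrom``, ``pos`` and ``value_col`` columns, sorted by
    (chrom, pos) in layout order.  Windows start at position 1, advance by
    ``params.step``, and are dropped (not truncated) at chromosome ends;
    a window's value is missing when it holds fewer than ``min_sites``
    usable sites.
    """
    if params is None:
        params = WindowParams()
    _check_sorted(sites, layout)
    chroms, starts_all, n_all, v_all = [], [], [], []
    for name, _ in layout.chromosomes:
        sub = sites[sites["chrom"] == name]
        starts = layout.window_starts(name, params.size, params.step)
        n, mean = _window_means(
            sub["pos"].to_numpy(),
            sub[value_col].to_numpy(dtype=float),
            starts,
            params.size,
        )
        mean = np.where(n >= params.min_sites, mean, np.nan)
        chroms.append(np.repeat(name, len(starts)))
        starts_all.append(starts)
        n_all.append(n)
        v_all.append(mean)
    start = np.concatenate(starts_all)
    return WindowTrack(
        chrom=np.concatenate(chroms),
        start=start,
        end=start + params.size - 1,
        n_sites=np.concatenate(n_all),
        value=np.concatenate(v_all),
    )


def paired_difference(selected: WindowTrack, control: WindowTrack) -> WindowTrack:
    """Per-window selected minus control; missing wherever either is."""
    if not selected.same_grid(control):
        raise ValueError("selected and control tracks are on different window grids")
    value = selected.value - control.value
    n = np.minimum(selected.n_sites, control.n_sites)
    return selected.copy_with(value, n)


def average_pairs(
    diffs: list[WindowTrack], pair_names: list[str] | None = None
) -> PairedDiffTrack:
    """Replicate-average of per-pair difference tracks.

    The mean ignores pairs with a missing value at a window rather than
    propagating missingness; a window is missing only if every pair is.
    """
    if not diffs:
        raise ValueError("need at least one pair")
    grid = diffs[0]
    for d in diffs[1:]:
        if not d.same_grid(grid):
            raise ValueError("pair tracks are on different window grids")
    stacked = np.vstack([d.value for d in diffs])
    n_used = (~np.isnan(stacked)).sum(axis=0)
    total = np.nansum(stacked, axis=0)
    mean = np.where(n_used > 0, total / np.maximum(n_used, 1), np.nan)
    mean_track = grid.copy_with(mean, n_used)
    return PairedDiffTrack(
        per_pair=list(diffs),
        mean=mean_track,
        n_pairs_used=n_used,
        pair_names=list(pair_names) if pair_names else [],
    )


def rna_bsa_scan(
    rna_sites: pd.DataFrame,
    pairs: list[tuple[str, str]],
    layout: GenomeLayout,
    params: RnaScanParams | None = None,
) -> PairedDiffTrack:
    """BSA scan from RNA reads at exonic biallelic positions.

    ``rna_sites`` carries ``chrom``, ``pos`` and per-population ``ref_<pop>``
    / ``alt_<pop>`` count columns.  Per pair, a position is used when read
    coverage is at least ``min_coverage`` in both members and the control
    major allele frequency is below ``max_control_major_af``; the absolute
    selected-control allele-frequency difference is then averaged within
    non-overlapping windows of ``params.window`` bp, and finally across
    pairs.
    """
    if params is None:
        params = RnaScanParams()
    _check_sorted(rna_sites, layout)
    wp = WindowParams(size=params.window, step=params.window, min_sites=1)
    per_pair = []
    for sel, con in pairs:
        cov_s = rna_sites[f"ref_{sel}"].to_numpy() + rna_sites[f"alt_{sel}"].to_numpy()
        cov_c = rna_sites[f"ref_{con}"].to_numpy() + rna_sites[f"alt_{con}"].to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            f_s = rna_sites[f"alt_{sel}"].to_numpy() / cov_s
            f_c = rna_sites[f"alt_{con}"].to_numpy() / cov_c
        major_c = np.maximum(f_c, 1.0 - f_c)
        keep = (
            (cov_s >= params.min_coverage)
            & (cov_c >= params.min_coverage)
            & (major_c < params.max_control_major_af)
        )
        absdiff = np.where(keep, np.abs(f_s - f_c), np.nan)
        tmp = rna_sites[["chrom", "pos"]].copy()
        tmp["absdiff"] = absdiff
        per_pair.append(windowed_frequency(tmp, "absdiff", layout, wp))
    return average_pairs(per_pair, [f"{s}-{c}" for s, c in pairs])
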