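"""Copy-number and dosage analysis from read depth, qPCR and expression.

Libraries are made comparable with median-of-ratios size factors (the
normalization used by standard count-based differential-expression tools).
Relative DNA coverage against single-copy baseline samples reveals
copy-number-variable gene runs; the copy number of a specific gene is
independently estimated from qPCR with efficiency-corrected relative
quantification; and expression fold changes test whether extra genomic
copies propagate proportionally to mRNA (a dosage effect).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "size_factors",
    "relative_coverage",
    "call_cnv_segments",
    "qpcr_copy_number",
    "expression_fold_change",
    "CnvSegment",
]

from dataclasses import dataclass


def size_factors(matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    ``matrix`` is genes x samples (non-negative counts).  The reference is
    the per-gene geometric mean over samples, computed over genes with no
    zero count; each sample's factor is the median over those genes of
    count / reference.
    """
    if matrix.shape[1] < 2:
        raise ValueError("size factors need at least 2 samples")
    counts = matrix.to_numpy(dtype=float)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene with all-positive counts; cannot estimate size factors")
    log_counts = np.log(counts[positive])
    log_ref = log_counts.mean(axis=1)
    factors = np.exp(np.median(log_counts - log_ref[:, None], axis=0))
    return pd.Series(factors, index=matrix.columns, name="size_factor")


def relative_coverage(
    matrix: pd.DataFrame, factors: pd.Series, baseline_samples: list[str]
) -> pd.DataFrame:
    """Per-gene coverage relative to the mean of single-copy baseline samples.

    Counts are divided by their sample's size factor, then by the per-gene
    mean of the normalized baseline samples (genes with a zero baseline mean
    get NaN).  A single-copy gene sits at ~1, an n-copy gene at ~n,
    independent of library size.
    """
    if not baseline_samples:
        raise ValueError("baseline sample set must be non-empty")
    missing = [s for s in baseline_samples if s not in matrix.columns]
    if missing:
        raise ValueError(f"baseline samples not in matrix: {missing}")
    normalized = matrix.div(factors, axis=1)
    base = normalized[baseline_samples].mean(axis=1)
    rel = normalized.div(base.where(base > 0), axis=0)
    return rel


@dataclass
class CnvSegment:
    """A maximal run of consecutive genes with elevated relative coverage."""

    chrom: str
    start: int
    end: int
    genes: list[str]
    copies: int  # rounded mean relative coverage, floor 1
    mean_relative_coverage: float


def call_cnv_segments(
    relative: pd.Series,
    annotation: pd.DataFrame,
    gain_threshold: float = 1.5,
) -> list[CnvSegment]:
    """Detect copy-number-gained segments at gene resolution.

    ``relative`` maps gene id -> relative coverage (one sample or a group
    mean); ``annotation`` provides gene coordinates and must be ordered by
    (chrom, start).  Maximal runs of consecutive genes with relative
    coverage >= ``gain_threshold`` become segments; the copy estimate is the
    rounded mean over member genes (floor 1), and the segment spans from the
    first member's start to the last member's end.
    """
    ann = annotation.reset_index(drop=True)
    if not (ann.groupby("chrom", sort=False)["start"].apply(lambda s: s.is_monotonic_increasing)).all():
        raise ValueError("annotation must be ordered by coordinate within chromosomes")
    rel = ann["gene"].map(relative).to_numpy(dtype=float)
    gained = np.nan_to_num(rel, nan=0.0) >= gain_threshold
    segments: list[CnvSegment] = []
    i, n = 0, len(ann)
    while i < n:
        if not gained[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and gained[j + 1] and ann.loc[j + 1, "chrom"] == ann.loc[i, "chrom"]:
            j += 1
        members = ann.iloc[i : j + 1]
        mean_rel = float(rel[i : j + 1].mean())
        segments.append(
            CnvSegment(
                chrom=str(members["chrom"].iloc[0]),
                start=int(members["start"].min()),
                end=int(members["end"].max()),
                genes=members["gene"].tolist(),
                copies=max(1, int(round(mean_rel))),
                mean_relative_coverage=mean_rel,
            )
        )
        i = j + 1
    return segments


def qpcr_copy_number(
    run: pd.DataFrame,
    efficiencies: dict[str, float],
    calibrator: str,
    target: str,
    reference: str,
) -> pd.Series:
    """Efficiency-corrected relative copy number from qPCR Ct values.

    Replicate Cts are averaged per (sample, amplicon); the copy number of
    ``target`` in sample *s*, relative to the ``calibrator`` sample (defined
    as copy number 1) and normalized by the single-copy ``reference``
    amplicon, is::

        CN_s = E_t ** (Ct_t,cal - Ct_t,s) / E_r ** (Ct_r,cal - Ct_r,s)

    with per-amplicon amplification efficiencies E in (1, 2] taken from the
    standard curves.
    """
    for amp in (target, reference):
        if amp not in efficiencies:
            raise ValueError(f"no efficiency for amplicon {amp!r}")
        if not (1.0 < efficiencies[amp] <= 2.0):
            raise ValueError(f"efficiency of {amp!r} must lie in (1, 2]")
    mean_ct = run.groupby(["sample", "amplicon"])["ct"].mean()
    samples = run["sample"].unique()
    if calibrator not in samples:
        raise ValueError(f"calibrator sample {calibrator!r} missing from run")
    for amp in (target, reference):
        if (calibrator, amp) not in mean_ct.index:
            raise ValueError(f"calibrator lacks Ct values for amplicon {amp!r}")
    e_t, e_r = efficiencies[target], efficiencies[reference]
    out = {}
    for s in samples:
        try:
            d_t = mean_ct[(calibrator, target)] - mean_ct[(s, target)]
            d_r = mean_ct[(calibrator, reference)] - mean_ct[(s, reference)]
        except KeyError as exc:
            raise ValueError(f"sample {s!r} lacks Ct values for an amplicon") from exc
        out[s] = e_t**d_t / e_r**d_r
    return pd.Series(out, name="copy_number")


def expression_fold_change(
    matrix: pd.DataFrame,
    factors: pd.Series,
    group_a: list[str],
    group_b: list[str],
) -> pd.Series:
    """Per-gene fold change a/b of size-factor-normalized mean counts.

    Genes with zero mean in group b are reported as NaN rather than
    infinite.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    normalized = matrix.div(factors, axis=1)
    mean_a = normalized[group_a].mean(axis=1)
    mean_b = normalized[group_b].mean(axis=1)
    return (mean_a / mean_b.where(mean_b > 0)).rename("fold_change")
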