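"""Transmitted-allele inference and segregation filtering.

In a cross between a homozygous inbred mother strain and a single haploid
male, each marker site carries at most two segregating alleles in the
descendants: the maternal one and the one the sire transmitted.  At sites
where the sire's source strain is heterozygous his allele is unknown a
priori and is inferred from the offspring pools: if the non-maternal allele
appears at an appreciable frequency in at least one pool, the sire must have
transmitted it.  Sites where the transmitted allele equals the maternal one
are uninformative for mapping.

A site is *non-segregating* for a selected/control pair when the same allele
sits at or above a high frequency threshold (default 0.95) in both members;
such sites carry no contrast and are excluded, globally so when every pair
drops them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from hapbsa.config import SiteFilterParams

__all__ = [
    "assign_transmitted_alleles",
    "filter_nonsegregating",
    "transmitted_frequencies",
]

_MOTHER_HOM = {"0/0": 0, "1/1": 1}
_STRAIN_GT = {"0/0": (0, 0), "0/1": (0, 1), "1/0": (0, 1), "1/1": (1, 1)}


def assign_transmitted_alleles(
    parents: pd.DataFrame,
    alt_freq: pd.DataFrame,
    params: SiteFilterParams | None = None,
) -> pd.DataFrame:
    """Assign the transmitted (paternal) allele at every marker site.

    Parameters
    ----------
    parents
        One row per biallelic site with columns ``chrom``, ``pos``,
        ``mother_gt`` and ``strain_gt`` (genotype strings such as ``0/0``,
        ``0/1``; allele 0 is the reference).
    alt_freq
        Alternative-allele frequency per offspring pool; one column per
        population, rows aligned with ``parents``.
    params
        Filter settings; only ``min_pool_freq_for_inference`` is used here.

    Returns
    -------
    DataFrame with ``chrom``, ``pos``, ``transmitted_allele`` ("ref"/"alt"),
    ``informative`` and ``excluded_reason`` (``low_quality`` for sites where
    the mother is not homozygous — flagged, never silently used).
    """
    if params is None:
        params = SiteFilterParams()
    pops = list(alt_freq.columns)
    if len(parents) != len(alt_freq):
        raise ValueError("parents and alt_freq must be row-aligned")

    mother = parents["mother_gt"].map(_MOTHER_HOM)
    low_quality = mother.isna().to_numpy()
    mother_allele = mother.fillna(0).to_numpy(dtype=int)

    strain = parents["strain_gt"].map(_STRAIN_GT)
    if strain.isna().any():
        bad = parents.loc[strain.isna(), "strain_gt"].unique()
        raise ValueError(f"unrecognized strain genotypes: {list(bad)}; sites must be biallelic")
    strain_het = np.array([a != b for a, b in strain])
    strain_hom_allele = np.array([a for a, _ in strain])

    freq = alt_freq.to_numpy(dtype=float)
    non_maternal = 1 - mother_allele
    # frequency of the non-maternal allele in each pool
    f_nm = np.where(non_maternal[:, None] == 1, freq, 1.0 - freq)
    seen = np.nansum(f_nm > params.min_pool_freq_for_inference, axis=1) > 0

    transmitted = np.where(
        strain_het,
        np.where(seen, non_maternal, mother_allele),
        strain_hom_allele,
    )
    informative = (transmitted != mother_allele) & ~low_quality

    out = parents[["chrom", "pos"]].copy()
    out["transmitted_allele"] = np.where(transmitted == 1, "alt", "ref")
    out.loc[low_quality, "transmitted_allele"] = pd.NA
    out["informative"] = informative
    out["excluded_reason"] = pd.array(
        np.where(low_quality, "low_quality", None), dtype="string"
    )
    # frequency of the transmitted allele per pool
    f_t = np.where(transmitted[:, None] == 1, freq, 1.0 - freq)
    for j, pop in enumerate(pops):
        out[f"freq_{pop}"] = f_t[:, j]
    return out


def transmitted_frequencies(records: pd.DataFrame, populations: list[str]) -> pd.DataFrame:
    """Extract the per-population transmitted-allele frequency columns."""
    cols = [f"freq_{p}" for p in populations]
    missing = [c for c in cols if c not in records.columns]
    if missing:
        raise ValueError(f"missing frequency columns: {missing}")
    return records[cols].rename(columns=dict(zip(cols, populations)))


def filter_nonsegregating(
    records: pd.DataFrame,
    pairs: list[tuple[str, str]],
    params: SiteFilterParams | None = None,
) -> pd.DataFrame:
    """Apply the per-pair non-segregation filter.

    A site is dropped *for a pair* when the same allele is at frequency
    >= ``nonseg_threshold`` in both the selected and the control member
    (either allele fixed drops the site; the boundary value is dropped).
    It is excluded *globally* only when dropped for every pair.

    Returns a copy of ``records`` with one boolean ``keep_<selected>``
    column per pair and ``excluded_reason`` set to ``nonsegregating`` for
    globally dropped sites.  Idempotent and order-independent over pairs.
    """
    if params is None:
        params = SiteFilterParams()
    out = records.copy()
    thr = params.nonseg_threshold
    dropped_all = np.ones(len(records), dtype=bool)
    for sel, con in pairs:
        for member in (sel, con):
            if f"freq_{member}" not in records.columns:
                raise ValueError(f"pair ({sel}, {con}): missing frequencies for {member!r}")
        f_sel = records[f"freq_{sel}"].to_numpy(dtype=float)
        f_con = records[f"freq_{con}"].to_numpy(dtype=float)
        high_t = (f_sel >= thr) & (f_con >= thr)  # transmitted allele fixed in both
        high_o = (f_sel <= 1 - thr) & (f_con <= 1 - thr)  # other allele fixed in both
        keep = ~(high_t | high_o)
        out[f"keep_{sel}"] = keep
        dropped_all &= ~keep
    if "excluded_reason" not in out.columns:
        out["excluded_reason"] = pd.array([None] * len(out), dtype="string")
    newly = dropped_all & out["excluded_reason"].isna().to_numpy()
    out.loc[newly, "excluded_reason"] = "nonsegregating"
    return out
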