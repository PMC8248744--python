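"""Parameterization of the simulated cross/selection experiment and of the
analysis stages.

``SimConfig`` holds the full design of the synthetic experiment: an inbred
homozygous mother strain crossed to a single haploid male drawn from a
heterozygous resistant strain, 11 paired selected/control populations of 650
census females propagated for 35 generations, pooled DNA sequencing of the
females of each population, one RNA replicate per population with cis-eQTL
and copy-number dosage effects, duplicate qPCR reactions, and probit-shaped
dose-response mortality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "CausalLocus",
    "CnvLocus",
    "QpcrSettings",
    "DoseResponseClass",
    "SimConfig",
    "SiteFilterParams",
    "RnaScanParams",
    "PermutationParams",
    "IntervalParams",
    "DegParams",
]


@dataclass(frozen=True)
class CausalLocus:
    """A locus under viability selection in the selected treatment.

    ``s`` is the selection coefficient against susceptible genotypes and
    ``h`` the dominance of the resistance allele (h=0 fully recessive,
    h=1 fully dominant).  Female fitness: 1-s with 0 resistant alleles,
    1-s(1-h) with one, 1 with two; haploid males: 1-s or 1.
    """

    chrom: str
    pos: int
    s: float
    h: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.s <= 1.0):
            raise ValueError("selection coefficient s must lie in [0, 1]")
        if not (0.0 <= self.h <= 1.0):
            raise ValueError("dominance h must lie in [0, 1]")
        if self.pos < 1:
            raise ValueError("position must be 1-based positive")


@dataclass(frozen=True)
class CnvLocus:
    """A tandem-amplified region carried by the resistant-strain haplotype.

    Genes inside ``[start, end]`` are present in ``copies`` copies on the
    resistant haplotype and a single copy on the susceptible one, so both the
    DNA coverage and (by dosage) the RNA output of those genes scale with the
    resistant-haplotype dose in a pool.
    """

    chrom: str
    start: int
    end: int
    copies: int

    def __post_init__(self) -> None:
        if self.copies < 1:
            raise ValueError("copies must be >= 1")
        if not (1 <= self.start <= self.end):
            raise ValueError("require 1 <= start <= end")


@dataclass(frozen=True)
class QpcrSettings:
    """Emission model for quantitative PCR cycle-threshold values.

    Ct = ct0 - log_E(template x copies) + Normal(0, noise_sd), in duplicate.
    ``efficiency`` is the per-cycle amplification factor E in (1, 2].
    """

    efficiency: float = 1.9
    ct0: float = 34.0
    noise_sd: float = 0.15
    template: float = 1.0
    n_replicates: int = 2

    def __post_init__(self) -> None:
        if not (1.0 < self.efficiency <= 2.0):
            raise ValueError("efficiency must lie in (1, 2]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.template <= 0:
            raise ValueError("template must be positive")


@dataclass(frozen=True)
class DoseResponseClass:
    """Probit dose-response of one genotype class: slope on log10 dose and
    log10 of the LC50 (mg/L)."""

    slope: float
    log10_lc50: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("probit slope must be positive")


def _default_dose_response() -> dict[str, DoseResponseClass]:
    # susceptible LC50 ~5 mg/L, resistant ~2000 mg/L, F1 placed by an
    # incompletely recessive degree of dominance D ~ -0.6
    log_s, log_r, dom = 0.699, 3.301, -0.6
    log_f1 = 0.5 * (dom * (log_r - log_s) + log_r + log_s)
    return {
        "S": DoseResponseClass(2.0, log_s),
        "R": DoseResponseClass(2.0, log_r),
        "F1": DoseResponseClass(2.0, log_f1),
    }


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of the synthetic cross-and-selection experiment.

    Defaults mirror the design being emulated: 11 paired populations of 650
    census females, ~35 generations of propagation, DNA pooled from up to
    1,000 females (the whole population when smaller), three selected loci of
    incompletely recessive resistance, and a ~14 kb amplified block of genes
    present in three copies on the resistant haplotype.  The toy genome
    (7.5/5/2.5 Mb, 2 informative sites per kb) keeps runtimes at desk scale
    while preserving multi-window linkage.
    """

    chromosome_lengths: tuple[int, ...] = (7_500_000, 5_000_000, 2_500_000)
    snp_density: float = 0.002  # informative-site candidates per bp (2 / kb)
    strain_het_fraction: float = 0.5  # fraction of marker sites heterozygous in the resistant strain
    n_pairs: int = 11
    n_females: int = 650
    male_census: int | None = None  # default n_females // 3 (female-biased sex ratio)
    pool_size: int = 1000
    n_generations: int = 35
    # neutral generations between the cross and the onset of selection:
    # population expansion plus the early, weakly selective low doses of an
    # escalating-dose regime
    burn_in_generations: int = 8
    # s = 0.2 per generation completes the sweeps near the end of the ~35
    # propagation generations, as under gradually increasing exposure;
    # resistance is incompletely recessive (h = 0.1)
    causal_loci: tuple[CausalLocus, ...] = (
        CausalLocus("chr1", 1_500_000, 0.2, 0.1),
        CausalLocus("chr1", 5_500_000, 0.2, 0.1),
        CausalLocus("chr2", 2_500_000, 0.2, 0.1),
    )
    cnv_locus: CnvLocus | None = CnvLocus("chr2", 2_493_201, 2_507_200, 3)
    gene_length: int = 2_000
    gene_spacing: int = 2_800  # start-to-start distance of tiled gene models
    dna_depth_mean: float = 80.0
    rna_depth_mean: float = 200.0  # baseline expected RNA count per gene
    rna_site_depth_mean: float = 40.0  # expected RNA read depth at an exonic site
    nb_dispersion: float = 0.01  # ~10% CV per gene, typical of deep pooled libraries
    cis_eqtl: tuple[tuple[str, float], ...] | None = None  # None -> 5x / 2x at loci 1-2
    qpcr: QpcrSettings = field(default_factory=QpcrSettings)
    dose_response: dict[str, DoseResponseClass] = field(default_factory=_default_dose_response)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(l <= 0 for l in self.chromosome_lengths):
            raise ValueError("chromosome lengths must be positive")
        if self.snp_density <= 0:
            raise ValueError("snp_density must be positive")
        if not (0.0 < self.strain_het_fraction <= 1.0):
            raise ValueError("strain_het_fraction must lie in (0, 1]")
        for name, v in [
            ("n_pairs", self.n_pairs),
            ("n_females", self.n_females),
            ("pool_size", self.pool_size),
            ("n_generations", self.n_generations),
            ("gene_length", self.gene_length),
            ("gene_spacing", self.gene_spacing),
        ]:
            if v <= 0:
                raise ValueError(f"{name} must be positive")
        if self.burn_in_generations < 0:
            raise ValueError("burn_in_generations must be >= 0")
        for name, v in [
            ("dna_depth_mean", self.dna_depth_mean),
            ("rna_depth_mean", self.rna_depth_mean),
            ("rna_site_depth_mean", self.rna_site_depth_mean),
            ("nb_dispersion", self.nb_dispersion),
        ]:
            if v <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def n_males(self) -> int:
        return self.male_census if self.male_census is not None else max(1, self.n_females // 3)


@dataclass(frozen=True)
class SiteFilterParams:
    """Segregation filters applied to informative sites.

    A site is non-segregating for a pair when the same allele sits at
    frequency >= ``nonseg_threshold`` in both the selected and the control
    member (the boundary value itself is dropped).  ``min_pool_freq_for_inference``
    is the floor an allele must exceed in at least one offspring pool before
    it is accepted as the transmitted (paternal) allele.
    """

    nonseg_threshold: float = 0.95
    min_pool_freq_for_inference: float = 0.05

    def __post_init__(self) -> None:
        if not (0.5 < self.nonseg_threshold <= 1.0):
            raise ValueError("nonseg_threshold must lie in (0.5, 1]")
        if not (0.0 <= self.min_pool_freq_for_inference < 0.5):
            raise ValueError("min_pool_freq_for_inference must lie in [0, 0.5)")


@dataclass(frozen=True)
class RnaScanParams:
    """Filters and window size for the RNA-read BSA scan: exonic biallelic
    positions with coverage >= 20 in both pair members and a control major
    allele frequency < 0.95, averaged in 500 kb non-overlapping windows."""

    min_coverage: int = 20
    max_control_major_af: float = 0.95
    window: int = 500_000

    def __post_init__(self) -> None:
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        if not (0.5 < self.max_control_major_af <= 1.0):
            raise ValueError("max_control_major_af must lie in (0.5, 1]")
        if self.window <= 0:
            raise ValueError("window must be positive")


@dataclass(frozen=True)
class PermutationParams:
    """Circular-permutation null of the averaged difference track: 10^4
    independent rotations per pair by default, thresholded at level 0.05 of
    the max-deviation distribution."""

    n_permutations: int = 10_000
    fdr: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if not (0.0 < self.fdr < 1.0):
            raise ValueError("fdr must lie in (0, 1)")


@dataclass(frozen=True)
class IntervalParams:
    """Peak-similarity interval rule: extension continues while at least one
    of ``block_len`` consecutive windows has a value within
    ``similarity_delta`` of the peak value."""

    similarity_delta: float = 0.005
    block_len: int = 5

    def __post_init__(self) -> None:
        if self.similarity_delta < 0:
            raise ValueError("similarity_delta must be >= 0")
        if self.block_len < 1:
            raise ValueError("block_len must be >= 1")


@dataclass(frozen=True)
class DegParams:
    """Differential-expression call cutoffs applied to a provided DE table:
    absolute fold change >= 2 and adjusted p-value <= 0.05."""

    fc_cutoff: float = 2.0
    padj_cutoff: float = 0.05

    def __post_init__(self) -> None:
        if self.fc_cutoff < 1:
            raise ValueError("fc_cutoff must be >= 1")
        if not (0.0 < self.padj_cutoff <= 1.0):
            raise ValueError("padj_cutoff must lie in (0, 1]")
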