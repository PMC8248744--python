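"""Forward simulator of a haplodiploid cross-and-selection experiment.

The simulated design mirrors a bulked-segregant mapping experiment in an
arrhenotokous arthropod: diploid females of an inbred, homozygous mother
strain are crossed to a *single haploid male* drawn from a genetically
heterogeneous resistant strain.  Because the sire is haploid, every marker
where his allele differs from the mother's homozygous allele segregates as a
two-haplotype system in the descendants: each F1 female carries exactly one
maternal and one paternal (resistant-strain) haplotype.  Replicated sister
populations are then propagated for ~35 generations with and without
pesticide selection, and each population is sequenced as a pool.

Genomes are therefore encoded as 0/1 arrays over the informative sites
(1 = the allele transmitted by the haploid sire).  Transmission follows
arrhenotoky: daughters receive a recombinant maternal gamete plus the
haplotype of a random father; sons arise from unfertilized eggs and carry a
recombinant maternal gamete only.  Meiosis places exactly one crossover per
chromosome at a uniform position.

Emission models
---------------
* pooled DNA: per-site depth ~ Poisson, alt reads ~ Binomial(depth, pooled
  read-level allele frequency); inside a copy-number-variable (CNV) region
  the resistant haplotype contributes proportionally more reads.
* per-gene DNA coverage and RNA counts: negative binomial around a mean that
  scales with local copy number and, for RNA, with a cis-regulatory fold
  multiplier per resistant-haplotype dose.
* qPCR: Ct = ct0 - log_E(template x copies) + Gaussian replicate noise.
* bioassay mortality: Binomial deaths under a probit dose-response mixture
  over genotype classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from hapbsa._rng import substream
from hapbsa.config import SimConfig
from hapbsa.layout import GenomeLayout

__all__ = [
    "FounderGenomes",
    "PopulationState",
    "PooledSample",
    "SimResult",
    "ExtinctionError",
    "make_founders",
    "f1_population",
    "advance_generation",
    "emit_pool_reads",
    "emit_qpcr",
    "emit_dose_response",
    "gene_annotation",
    "simulate_experiment",
]


class ExtinctionError(RuntimeError):
    """Raised when viability selection leaves no survivors."""


# ---------------------------------------------------------------------------
# founders


@dataclass
class FounderGenomes:
    """Founder genotypes and the marker-site scaffold of the simulation.

    ``male_allele`` is the allele the single haploid sire carries at every
    marker site (0 = same as the homozygous mother, 1 = alternative).  Sites
    with ``male_allele == 1`` are the informative sites: only there does the
    paternal (resistant-strain) haplotype differ from the maternal one, and
    the downstream population genetics is tracked over exactly these sites.
    """

    layout: GenomeLayout
    chrom: np.ndarray  # per marker site
    pos: np.ndarray  # 1-based bp
    strain_is_het: np.ndarray  # resistant strain heterozygous at this marker
    male_allele: np.ndarray  # transmitted allele (ground truth), 0/1

    _chrom_slices: list[tuple[slice, float, np.ndarray]] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if self.informative.sum() == 0:
            raise ValueError("degenerate founders: male haplotype carries no allele "
                             "differing from the mother at any marker site")
        # per-chromosome views over the informative sites, used by meiosis
        inf_chrom = self.chrom[self.informative]
        inf_pos = self.pos[self.informative]
        self._chrom_slices = []
        offset = 0
        for name, length in self.layout.chromosomes:
            n = int((inf_chrom == name).sum())
            sl = slice(offset, offset + n)
            self._chrom_slices.append((sl, float(length), inf_pos[sl].astype(np.float64)))
            offset += n

    @property
    def informative(self) -> np.ndarray:
        return self.male_allele == 1

    @property
    def n_informative(self) -> int:
        return int(self.informative.sum())

    @property
    def inf_chrom(self) -> np.ndarray:
        return self.chrom[self.informative]

    @property
    def inf_pos(self) -> np.ndarray:
        return self.pos[self.informative]

    def informative_index(self, chrom: str, pos: int) -> int:
        """Index (within the informative-site arrays) of the site nearest
        ``pos`` on ``chrom``."""
        for (sl, _, positions), (name, _) in zip(self._chrom_slices, self.layout.chromosomes):
            if name == chrom:
                if len(positions) == 0:
                    raise ValueError(f"no informative sites on {chrom}")
                j = int(np.argmin(np.abs(positions - pos)))
                return sl.start + j
        raise KeyError(f"unknown chromosome {chrom!r}")

    def sites_table(self) -> pd.DataFrame:
        """All marker sites with the ground-truth transmitted allele."""
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.pos,
                "strain_het": self.strain_is_het,
                "transmitted_allele": np.where(self.male_allele == 1, "alt", "ref"),
                "informative": self.informative,
            }
        )


def make_founders(config: SimConfig, rng: np.random.Generator | None = None) -> FounderGenomes:
    """Draw the founder genomes of the cross.

    Marker sites are placed uniformly at ``snp_density`` per bp.  At each
    marker the resistant strain is heterozygous (with probability
    ``strain_het_fraction``) or homozygous for the alternative allele; the
    mother strain is homozygous reference everywhere.  The single haploid
    sire receives one allele per site: at strain-heterozygous sites a fair
    draw between the two, so about half of those sites end up informative.
    Causal and CNV-anchor positions are forced to be informative so that
    selection and dosage act on tracked sites.
    """
    if rng is None:
        rng = substream(config.seed, "founders")
    layout = GenomeLayout.from_lengths(list(config.chromosome_lengths))

    forced: dict[str, set[int]] = {name: set() for name in layout.names}
    for locus in config.causal_loci:
        forced[locus.chrom].add(int(locus.pos))
    if config.cnv_locus is not None:
        mid = (config.cnv_locus.start + config.cnv_locus.end) // 2
        forced[config.cnv_locus.chrom].add(int(mid))

    chroms, positions, het, male = [], [], [], []
    for name, length in layout.chromosomes:
        n = int(round(config.snp_density * length))
        pos = np.unique(rng.integers(1, length + 1, size=n))
        pos = np.union1d(pos, np.array(sorted(forced[name]), dtype=np.int64))
        is_forced = np.isin(pos, np.array(sorted(forced[name]), dtype=np.int64))
        is_het = rng.random(len(pos)) < config.strain_het_fraction
        allele = np.where(is_het, rng.integers(0, 2, size=len(pos)), 1).astype(np.uint8)
        # forced sites: strain homozygous-alt, hence certainly informative
        is_het[is_forced] = False
        allele[is_forced] = 1
        chroms.append(np.repeat(name, len(pos)))
        positions.append(pos.astype(np.int64))
        het.append(is_het)
        male.append(allele)

    return FounderGenomes(
        layout=layout,
        chrom=np.concatenate(chroms),
        pos=np.concatenate(positions),
        strain_is_het=np.concatenate(het),
        male_allele=np.concatenate(male),
    )


# ---------------------------------------------------------------------------
# population dynamics


@dataclass
class PopulationState:
    """One population at one generation.

    ``female_h`` has shape (n_females, 2, S) and ``male_h`` (n_males, S)
    over the informative sites, values 0/1 (1 = resistant-parent allele).
    """

    female_h: np.ndarray
    male_h: np.ndarray
    generation: int
    treatment: str  # "selected" | "control"
    founders: FounderGenomes = field(repr=False)

    def __post_init__(self) -> None:
        if self.female_h.ndim != 3 or self.female_h.shape[1] != 2:
            raise ValueError("females must carry exactly 2 haplotypes")
        if self.male_h.ndim != 2:
            raise ValueError("males must carry exactly 1 haplotype")
        if self.treatment not in ("selected", "control"):
            raise ValueError("treatment must be 'selected' or 'control'")

    @property
    def n_females(self) -> int:
        return self.female_h.shape[0]

    def allele_frequency(self) -> np.ndarray:
        """Per-informative-site frequency of the resistant-parent allele
        among females."""
        return self.female_h.mean(axis=(0, 1))


def _make_gametes(
    haps: np.ndarray, mothers: np.ndarray, founders: FounderGenomes, rng: np.random.Generator
) -> np.ndarray:
    """Recombinant maternal gametes: one obligate crossover per chromosome
    at a uniform bp position, independent assortment across chromosomes."""
    a = haps[mothers, 0, :]
    diff = a ^ haps[mothers, 1, :]
    g = len(mothers)
    for sl, length, pos in founders._chrom_slices:
        start_b = rng.random(g) < 0.5
        cut = rng.random(g) * length
        take_b = (start_b[:, None] ^ (pos[None, :] > cut[:, None])).view(np.uint8)
        diff[:, sl] &= take_b
    a ^= diff  # a is a fresh fancy-indexed copy, safe to mutate
    return a


def f1_population(
    founders: FounderGenomes, config: SimConfig, rng: np.random.Generator, treatment: str = "control"
) -> PopulationState:
    """Generation 0: F1 females uniformly heterozygous at every informative
    site (maternal haplotype all-0, paternal all-1) plus sons drawn from
    their gametes."""
    s = founders.n_informative
    female_h = np.zeros((config.n_females, 2, s), dtype=np.uint8)
    female_h[:, 1, :] = 1
    mothers = rng.integers(0, config.n_females, size=config.n_males)
    male_h = _make_gametes(female_h, mothers, founders, rng)
    return PopulationState(female_h, male_h, 0, treatment, founders)


def _causal_tables(
    config: SimConfig, founders: FounderGenomes
) -> list[tuple[int, np.ndarray, np.ndarray]]:
    """(site index, female fitness by dose, male fitness by allele) per
    causal locus with s > 0."""
    out = []
    for locus in config.causal_loci:
        if locus.s == 0:
            continue
        idx = founders.informative_index(locus.chrom, locus.pos)
        wf = np.array([1 - locus.s, 1 - locus.s * (1 - locus.h), 1.0])
        wm = np.array([1 - locus.s, 1.0])
        out.append((idx, wf, wm))
    return out


def advance_generation(
    state: PopulationState, config: SimConfig, rng: np.random.Generator
) -> PopulationState:
    """One haplodiploid generation: reproduction, then (in the selected
    treatment) viability selection on the offspring, then resampling of the
    survivors back to the census sizes."""
    if state.n_females == 0 or state.male_h.shape[0] == 0:
        raise ValueError("non-empty population required")
    founders = state.founders
    nf_next, nm_next = config.n_females, config.n_males

    mothers_d = rng.integers(0, state.n_females, size=nf_next)
    fathers = rng.integers(0, state.male_h.shape[0], size=nf_next)
    eggs = _make_gametes(state.female_h, mothers_d, founders, rng)
    daughters = np.stack([eggs, state.male_h[fathers]], axis=1)

    mothers_s = rng.integers(0, state.n_females, size=nm_next)
    sons = _make_gametes(state.female_h, mothers_s, founders, rng)

    if state.treatment == "selected":
        causal = _causal_tables(config, founders)
        if causal:
            wf = np.ones(nf_next)
            wm = np.ones(nm_next)
            for idx, wf_tab, wm_tab in causal:
                dose = daughters[:, 0, idx].astype(np.intp) + daughters[:, 1, idx]
                wf *= wf_tab[dose]
                wm *= wm_tab[sons[:, idx].astype(np.intp)]
            alive_f = np.flatnonzero(rng.random(nf_next) < wf)
            alive_m = np.flatnonzero(rng.random(nm_next) < wm)
            if len(alive_f) == 0 or len(alive_m) == 0:
                raise ExtinctionError(
                    f"population extinct after selection at generation {state.generation + 1}"
                )
            daughters = daughters[rng.choice(alive_f, size=nf_next)]
            sons = sons[rng.choice(alive_m, size=nm_next)]

    return PopulationState(daughters, sons, state.generation + 1, state.treatment, founders)


# ---------------------------------------------------------------------------
# gene models


def gene_annotation(config: SimConfig) -> pd.DataFrame:
    """Gene models tiled along the genome: spans of ``gene_length`` bp every
    ``gene_spacing`` bp (1-based inclusive coordinates), with a flag for
    membership in the CNV region."""
    layout = GenomeLayout.from_lengths(list(config.chromosome_lengths))
    rows = []
    for name, length in layout.chromosomes:
        starts = np.arange(1, length - config.gene_length + 2, config.gene_spacing, dtype=np.int64)
        for i, s in enumerate(starts):
            rows.append((f"gene-{name}-{i:04d}", name, int(s), int(s + config.gene_length - 1)))
    ann = pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])
    cnv = config.cnv_locus
    if cnv is None:
        ann["in_cnv"] = False
    else:
        ann["in_cnv"] = (
            (ann["chrom"] == cnv.chrom) & (ann["start"] <= cnv.end) & (ann["end"] >= cnv.start)
        )
    return ann


def resolve_cis_eqtl(config: SimConfig, annotation: pd.DataFrame) -> dict[str, float]:
    """Map the configured cis-eQTL effects to gene ids.

    With ``config.cis_eqtl is None`` the defaults emulate the mapped
    architecture: a ~5x cis-upregulated gene at the first causal locus and a
    ~2x one at the second; the third locus carries its dosage effect through
    the CNV region instead.
    """
    if config.cis_eqtl is not None:
        return {gene: float(m) for gene, m in config.cis_eqtl}
    folds = [5.0, 2.0]
    out: dict[str, float] = {}
    for locus, fold in zip(config.causal_loci[:2], folds):
        on_chrom = annotation[annotation["chrom"] == locus.chrom]
        if on_chrom.empty:
            continue
        mid = (on_chrom["start"] + on_chrom["end"]) / 2
        gene = on_chrom.loc[(mid - locus.pos).abs().idxmin(), "gene"]
        out[str(gene)] = fold
    return out


# ---------------------------------------------------------------------------
# emission


@dataclass
class PooledSample:
    """Sequencing read-outs of one pooled population.

    Site-level arrays are aligned with the founder marker table
    (``founders.sites_table()``); gene-level arrays with the annotation.
    """

    name: str
    treatment: str
    # site-level DNA
    dna_ref: np.ndarray
    dna_alt: np.ndarray
    # site-level RNA (0 depth outside exons)
    rna_ref: np.ndarray
    rna_alt: np.ndarray
    exonic: np.ndarray
    # gene-level
    gene_dna_coverage: np.ndarray
    gene_rna_counts: np.ndarray
    # ground truth
    true_freq: np.ndarray  # pooled frequency of the transmitted allele, all marker sites

    def __post_init__(self) -> None:
        for arr in (self.dna_ref, self.dna_alt, self.rna_ref, self.rna_alt,
                    self.gene_dna_coverage, self.gene_rna_counts):
            if np.any(arr < 0):
                raise ValueError("read counts must be non-negative")


def _nb_counts(mean: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    """Negative-binomial counts via the gamma-Poisson mixture; variance
    mean + dispersion * mean^2."""
    mean = np.asarray(mean, dtype=float)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def emit_pool_reads(
    state: PopulationState,
    config: SimConfig,
    rng: np.random.Generator,
    annotation: pd.DataFrame | None = None,
    cis_eqtl: dict[str, float] | None = None,
    name: str = "pop",
) -> PooledSample:
    """Sequence a pooled sample of the population's females.

    Up to ``pool_size`` females are pooled (all of them when the census is
    smaller).  DNA depth is Poisson around ``dna_depth_mean``; inside the
    CNV region both the depth and the read-level allele frequency reflect
    the extra copies carried by the resistant haplotype.  RNA site depth and
    per-gene counts additionally scale with the cis multiplier raised to the
    mean resistant-haplotype dose, and RNA reads are allele-specific: the
    overexpressed resistant haplotype contributes proportionally more reads.
    """
    founders = state.founders
    if annotation is None:
        annotation = gene_annotation(config)
    if cis_eqtl is None:
        cis_eqtl = resolve_cis_eqtl(config, annotation)

    n_pool = min(config.pool_size, state.n_females)
    if n_pool < state.n_females:
        pool_idx = rng.choice(state.n_females, size=n_pool, replace=False)
        pooled = state.female_h[pool_idx]
    else:
        pooled = state.female_h
    freq_inf = pooled.mean(axis=(0, 1))  # informative sites only

    n_sites = len(founders.pos)
    true_freq = np.zeros(n_sites)
    true_freq[founders.informative] = freq_inf

    cnv = config.cnv_locus
    copies = 1 if cnv is None else cnv.copies
    in_cnv_site = np.zeros(n_sites, dtype=bool)
    if cnv is not None:
        in_cnv_site = (
            (founders.chrom == cnv.chrom) & (founders.pos >= cnv.start) & (founders.pos <= cnv.end)
        )

    # read-level frequency: resistant haplotypes carry `copies` templates in the CNV
    site_copy_factor = np.where(in_cnv_site, 1.0 + true_freq * (copies - 1), 1.0)
    read_freq = np.where(
        in_cnv_site, true_freq * copies / site_copy_factor, true_freq
    )

    dna_depth = rng.poisson(config.dna_depth_mean * site_copy_factor)
    dna_alt = rng.binomial(dna_depth, read_freq)
    dna_ref = dna_depth - dna_alt

    # gene-level local resistant-haplotype frequency: nearest informative site
    gene_mid = ((annotation["start"] + annotation["end"]) // 2).to_numpy()
    gene_freq = np.zeros(len(annotation))
    inf_chrom, inf_pos = founders.inf_chrom, founders.inf_pos
    for chrom in founders.layout.names:
        gmask = (annotation["chrom"] == chrom).to_numpy()
        smask = inf_chrom == chrom
        if not gmask.any() or not smask.any():
            continue
        pos_c = inf_pos[smask]
        j = np.clip(np.searchsorted(pos_c, gene_mid[gmask]), 0, len(pos_c) - 1)
        j_lo = np.clip(j - 1, 0, len(pos_c) - 1)
        nearer_lo = np.abs(pos_c[j_lo] - gene_mid[gmask]) < np.abs(pos_c[j] - gene_mid[gmask])
        jj = np.where(nearer_lo, j_lo, j)
        gene_freq[gmask] = freq_inf[smask][jj]

    gene_copy_factor = np.where(
        annotation["in_cnv"].to_numpy(), 1.0 + gene_freq * (copies - 1), 1.0
    )
    gene_dna = _nb_counts(config.dna_depth_mean * gene_copy_factor, config.nb_dispersion, rng)

    cis_mult = np.ones(len(annotation))
    for gene, fold in cis_eqtl.items():
        cis_mult[(annotation["gene"] == gene).to_numpy()] = fold
    mean_dose = 2.0 * gene_freq  # resistant haplotypes per female, in [0, 2]
    # multiplier is expressed per extra resistant-haplotype dose relative to
    # the susceptible baseline, normalized so a half-and-half pool sits at
    # the geometric mid-point
    rna_mean = config.rna_depth_mean * cis_mult ** (mean_dose / 2.0) * gene_copy_factor
    gene_rna = _nb_counts(rna_mean, config.nb_dispersion, rng)

    # site-level RNA at exonic positions
    exonic = np.zeros(n_sites, dtype=bool)
    site_gene_idx = np.full(n_sites, -1)
    for chrom in founders.layout.names:
        gsub = annotation[annotation["chrom"] == chrom]
        smask = founders.chrom == chrom
        if gsub.empty or not smask.any():
            continue
        starts = gsub["start"].to_numpy()
        ends = gsub["end"].to_numpy()
        pos_c = founders.pos[smask]
        j = np.searchsorted(starts, pos_c, side="right") - 1
        ok = (j >= 0) & (pos_c <= ends[np.clip(j, 0, None)])
        idx = np.flatnonzero(smask)
        exonic[idx[ok]] = True
        site_gene_idx[idx[ok]] = gsub.index.to_numpy()[j[ok]]

    rna_site_mult = np.ones(n_sites)
    rna_site_copy = np.ones(n_sites)
    ex = exonic
    rna_site_mult[ex] = cis_mult[site_gene_idx[ex]]
    rna_site_copy[ex] = np.where(
        in_cnv_site[ex], 1.0 + true_freq[ex] * (copies - 1), 1.0
    )
    site_dose = 2.0 * true_freq
    rna_depth_mean = np.where(
        ex,
        config.rna_site_depth_mean * rna_site_mult ** (site_dose / 2.0) * rna_site_copy,
        0.0,
    )
    # allele-specific expression: resistant-haplotype reads are inflated by
    # the cis multiplier (and by extra copies inside the CNV)
    allele_weight = np.where(in_cnv_site, float(copies), 1.0) * rna_site_mult
    with np.errstate(invalid="ignore", divide="ignore"):
        rna_read_freq = np.where(
            ex,
            true_freq * allele_weight / (1.0 - true_freq + true_freq * allele_weight),
            0.0,
        )
    rna_depth = rng.poisson(rna_depth_mean)
    rna_alt = rng.binomial(rna_depth, np.nan_to_num(rna_read_freq))
    rna_ref = rna_depth - rna_alt

    return PooledSample(
        name=name,
        treatment=state.treatment,
        dna_ref=dna_ref,
        dna_alt=dna_alt,
        rna_ref=rna_ref,
        rna_alt=rna_alt,
        exonic=exonic,
        gene_dna_coverage=np.asarray(gene_dna),
        gene_rna_counts=np.asarray(gene_rna),
        true_freq=true_freq,
    )


def emit_qpcr(
    copy_numbers: dict[str, float],
    config: SimConfig,
    rng: np.random.Generator,
    target: str = "CPR",
    reference: str = "VGSC",
) -> pd.DataFrame:
    """qPCR Ct table for a multi-copy target and a single-copy reference.

    Ct = ct0 - log_E(template x copies) + Normal(0, sd), in
    ``n_replicates`` replicate wells per (sample, amplicon).
    """
    q = config.qpcr
    rows = []
    for sample, copies in copy_numbers.items():
        if copies <= 0:
            raise ValueError(f"non-positive copy number for sample {sample!r}")
        for amplicon, c in ((target, float(copies)), (reference, 1.0)):
            ct_true = q.ct0 - np.log(q.template * c) / np.log(q.efficiency)
            for rep in range(1, q.n_replicates + 1):
                ct = ct_true + (rng.normal(0.0, q.noise_sd) if q.noise_sd > 0 else 0.0)
                rows.append((sample, amplicon, rep, ct))
    return pd.DataFrame(rows, columns=["sample", "amplicon", "replicate", "ct"])


def emit_dose_response(
    genotype_mix: list[tuple[str, float]],
    config: SimConfig,
    doses: list[float],
    n_per_dose: int,
    rng: np.random.Generator,
    population: str = "pop",
) -> pd.DataFrame:
    """Bioassay mortality for a mixture of genotype classes.

    Deaths ~ Binomial(n, sum_class proportion * Phi(slope * (log10 dose -
    log10 LC50_class))).
    """
    props = np.array([p for _, p in genotype_mix], dtype=float)
    if not np.isclose(props.sum(), 1.0):
        raise ValueError("genotype proportions must sum to 1")
    rows = []
    for dose in doses:
        if dose <= 0:
            raise ValueError("dose must be positive")
        p = 0.0
        for cls, prop in genotype_mix:
            dr = config.dose_response[cls]
            p += prop * norm.cdf(dr.slope * (np.log10(dose) - dr.log10_lc50))
        dead = int(rng.binomial(n_per_dose, p))
        rows.append((population, dose, n_per_dose, dead))
    return pd.DataFrame(rows, columns=["population", "dose", "n", "dead"])


# ---------------------------------------------------------------------------
# whole experiment


@dataclass
class SimResult:
    """All emitted data of one simulated experiment plus ground truth."""

    config: SimConfig
    founders: FounderGenomes
    annotation: pd.DataFrame
    cis_eqtl: dict[str, float]
    pools: dict[str, PooledSample]  # selected "R1".."Rk", control "S1".."Sk"
    pairs: list[tuple[str, str]]  # (selected, control) names
    causal_truth: pd.DataFrame  # final resistant-allele frequency at causal loci

    @property
    def layout(self) -> GenomeLayout:
        return self.founders.layout


def simulate_experiment(config: SimConfig, emit_rna: bool = True) -> SimResult:
    """Run the full design: cross, neutral burn-in, paired selected/control
    propagation, and pooled sequencing of every population.

    Both members of a pair are founded from the same bootstrap sample of the
    expanded base population, mirroring sister populations split from a
    common source; they then evolve independently, one under viability
    selection and one without.
    """
    founders = make_founders(config)
    annotation = gene_annotation(config)
    cis = resolve_cis_eqtl(config, annotation)

    base = f1_population(founders, config, substream(config.seed, "f1"))
    rng_burn = substream(config.seed, "burnin")
    for _ in range(config.burn_in_generations):
        base = advance_generation(base, config, rng_burn)

    pools: dict[str, PooledSample] = {}
    pairs: list[tuple[str, str]] = []
    truth_rows = []
    causal_idx = [
        (locus, founders.informative_index(locus.chrom, locus.pos)) for locus in config.causal_loci
    ]
    for k in range(1, config.n_pairs + 1):
        rng_pair = substream(config.seed, "pair", k)
        fem = base.female_h[rng_pair.integers(0, base.n_females, size=config.n_females)]
        mal = base.male_h[rng_pair.integers(0, base.male_h.shape[0], size=config.n_males)]
        for treatment, label in (("selected", f"R{k}"), ("control", f"S{k}")):
            state = PopulationState(fem.copy(), mal.copy(), 0, treatment, founders)
            rng_pop = substream(config.seed, "evolve", k, 0 if treatment == "selected" else 1)
            for _ in range(config.n_generations):
                state = advance_generation(state, config, rng_pop)
            sample = emit_pool_reads(
                state,
                config,
                substream(config.seed, "reads", k, 0 if treatment == "selected" else 1),
                annotation,
                cis,
                name=label,
            )
            if not emit_rna:
                sample.rna_ref = np.zeros_like(sample.rna_ref)
                sample.rna_alt = np.zeros_like(sample.rna_alt)
                sample.exonic = np.zeros_like(sample.exonic)
            pools[label] = sample
            freq = state.allele_frequency()
            for locus, idx in causal_idx:
                truth_rows.append((label, treatment, locus.chrom, locus.pos, float(freq[idx])))
        pairs.append((f"R{k}", f"S{k}"))

    causal_truth = pd.DataFrame(
        truth_rows, columns=["population", "treatment", "chrom", "pos", "frequency"]
    )
    return SimResult(config, founders, annotation, cis, pools, pairs, causal_truth)
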