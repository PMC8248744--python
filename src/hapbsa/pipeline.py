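"""End-to-end orchestration: simulate -> site inference -> windowed scans ->
permutation threshold -> QTL calls/intervals -> CNV & dosage -> inheritance.

The module also exposes the intermediate adapters (building the parent and
pool tables from a simulation, running the DNA or RNA scan alone) so each
stage can be driven separately, and :func:`drift_calibration`, which
measures the pipeline's false-call rate over replicate no-selection
experiments.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from hapbsa import __version__, io
from hapbsa._rng import substream
from hapbsa.config import (
    DegParams,
    IntervalParams,
    PermutationParams,
    RnaScanParams,
    SimConfig,
    SiteFilterParams,
)
from hapbsa.layout import WindowParams
from hapbsa.qtl import (
    NullMaxDistribution,
    QtlCall,
    QtlInterval,
    call_qtls,
    circularize,
    permutation_null,
    qtl_interval,
    subsidiary_peaks,
)
from hapbsa.scan import (
    PairedDiffTrack,
    average_pairs,
    paired_difference,
    rna_bsa_scan,
    windowed_frequency,
)
from hapbsa.simulate import SimResult, simulate_experiment
from hapbsa.sites import assign_transmitted_alleles, filter_nonsegregating

__all__ = [
    "PipelineConfig",
    "ScanResult",
    "pool_count_table",
    "parent_table",
    "infer_sites",
    "dna_scan",
    "rna_site_table",
    "detect_qtls",
    "analyze_experiment",
    "drift_calibration",
    "run_pipeline",
]


def parent_table(result: SimResult) -> pd.DataFrame:
    """Parent genotype table of the simulated cross: the inbred mother is
    homozygous reference, the resistant strain het or hom-alt per marker."""
    f = result.founders
    return pd.DataFrame(
        {
            "chrom": f.chrom,
            "pos": f.pos,
            "mother_gt": "0/0",
            "strain_gt": np.where(f.strain_is_het, "0/1", "1/1"),
        }
    )


def pool_count_table(result: SimResult, kind: str = "dna") -> pd.DataFrame:
    """Per-site ref/alt read counts of every pool (``ref_<pop>`` /
    ``alt_<pop>`` columns)."""
    f = result.founders
    out = pd.DataFrame({"chrom": f.chrom, "pos": f.pos})
    for name, sample in result.pools.items():
        if kind == "dna":
            out[f"ref_{name}"] = sample.dna_ref
            out[f"alt_{name}"] = sample.dna_alt
        elif kind == "rna":
            out[f"ref_{name}"] = sample.rna_ref
            out[f"alt_{name}"] = sample.rna_alt
        else:
            raise ValueError("kind must be 'dna' or 'rna'")
    return out


def infer_sites(
    result: SimResult, params: SiteFilterParams | None = None
) -> pd.DataFrame:
    """Transmitted-allele assignment plus segregation filtering on the
    simulated DNA pools."""
    if params is None:
        params = SiteFilterParams()
    counts = pool_count_table(result, "dna")
    pops = list(result.pools)
    freq = pd.DataFrame(index=counts.index)
    for p in pops:
        depth = counts[f"ref_{p}"] + counts[f"alt_{p}"]
        freq[p] = counts[f"alt_{p}"] / depth.where(depth > 0)
    records = assign_transmitted_alleles(parent_table(result), freq, params)
    for p in pops:
        records[f"depth_{p}"] = counts[f"ref_{p}"] + counts[f"alt_{p}"]
    informative = records[records["informative"]].reset_index(drop=True)
    return filter_nonsegregating(informative, result.pairs, params)


@dataclass
class ScanResult:
    """A paired-difference track with its permutation null and QTL calls."""

    diff: PairedDiffTrack
    null: NullMaxDistribution | None = None
    threshold: float | None = None
    calls: list[QtlCall] = field(default_factory=list)
    intervals: list[QtlInterval] = field(default_factory=list)
    subsidiary: list[QtlCall] = field(default_factory=list)


def dna_scan(
    result: SimResult,
    records: pd.DataFrame,
    window_params: WindowParams | None = None,
) -> PairedDiffTrack:
    """Windowed transmitted-allele frequencies per population, paired
    selected-minus-control differences, and the replicate average.

    Sites dropped by the non-segregation filter for a pair are excluded
    from that pair's windows only.
    """
    if window_params is None:
        window_params = WindowParams()
    layout = result.layout
    diffs, names = [], []
    for sel, con in result.pairs:
        keep = records[f"keep_{sel}"].to_numpy(dtype=bool)
        sub = records[keep]
        tracks = {}
        for member in (sel, con):
            sites = sub[["chrom", "pos"]].copy()
            sites["freq"] = sub[f"freq_{member}"].to_numpy(dtype=float)
            tracks[member] = windowed_frequency(sites, "freq", layout, window_params)
        diffs.append(paired_difference(tracks[sel], tracks[con]))
        names.append(f"{sel}-{con}")
    return average_pairs(diffs, names)


def rna_site_table(result: SimResult) -> pd.DataFrame:
    """RNA read counts at exonic marker positions, for the RNA-based scan."""
    counts = pool_count_table(result, "rna")
    exonic = next(iter(result.pools.values())).exonic
    return counts[exonic].reset_index(drop=True)


def detect_qtls(
    diff: PairedDiffTrack,
    result: SimResult,
    perm_params: PermutationParams | None = None,
    interval_params: IntervalParams | None = None,
    n_subsidiary: int = 2,
) -> ScanResult:
    """Permutation threshold on the circularized genome, QTL calls and
    peak-similarity intervals."""
    if perm_params is None:
        perm_params = PermutationParams()
    if interval_params is None:
        interval_params = IntervalParams()
    rings = circularize(diff, result.layout)
    null = permutation_null(rings, perm_params)
    threshold = null.threshold
    calls = call_qtls(diff.mean, threshold)
    intervals = [qtl_interval(diff.mean, c, interval_params) for c in calls]
    subs = subsidiary_peaks(diff.mean, threshold, k=n_subsidiary)
    return ScanResult(
        diff=diff, null=null, threshold=threshold, calls=calls,
        intervals=intervals, subsidiary=subs,
    )


def analyze_experiment(
    result: SimResult,
    site_params: SiteFilterParams | None = None,
    window_params: WindowParams | None = None,
    perm_params: PermutationParams | None = None,
    interval_params: IntervalParams | None = None,
    rna_params: RnaScanParams | None = None,
    run_rna: bool = True,
) -> dict:
    """Run site inference, the DNA scan and QTL detection (and optionally
    the RNA scan) on one simulated experiment."""
    records = infer_sites(result, site_params)
    diff = dna_scan(result, records, window_params)
    scan = detect_qtls(diff, result, perm_params, interval_params)
    out = {"records": records, "dna": scan}
    if run_rna:
        out["rna"] = rna_bsa_scan(rna_site_table(result), result.pairs, result.layout, rna_params)
    return out


def drift_calibration_conditions() -> tuple[SimConfig, PermutationParams]:
    """Reduced desk-scale conditions for the drift (no-selection) calibration
    of the pipeline's false-call rate: a 2 Mb three-chromosome genome at one
    informative site per kb, 11 pairs of 650-female populations, pooled depth
    60x, and 500 rotations per experiment at level 0.05."""
    cfg = SimConfig(
        chromosome_lengths=(1_000_000, 600_000, 400_000),
        snp_density=0.001,
        causal_loci=(),
        cnv_locus=None,
        dna_depth_mean=60.0,
    )
    return cfg, PermutationParams(n_permutations=500, fdr=0.05)


def drift_calibration(
    n_sims: int,
    config: SimConfig,
    perm_params: PermutationParams,
    site_params: SiteFilterParams | None = None,
    window_params: WindowParams | None = None,
    seed: int = 1,
) -> dict:
    """False-call rate of the pipeline under pure drift.

    Runs ``n_sims`` independent no-selection experiments (every selection
    coefficient forced to 0), derives each experiment's own permutation
    threshold, and reports the fraction of experiments with at least one
    QTL call — the realized genome-wide error rate of the thresholding
    rule.
    """
    neutral_loci = tuple(dataclasses.replace(l, s=0.0) for l in config.causal_loci)
    calls_per_sim = []
    for i in range(1, n_sims + 1):
        sim_seed = int((seed * 100_003 + i) % 2**31)
        cfg = dataclasses.replace(config, causal_loci=neutral_loci, seed=sim_seed)
        result = simulate_experiment(cfg, emit_rna=False)
        records = infer_sites(result, site_params)
        diff = dna_scan(result, records, window_params)
        pp = dataclasses.replace(perm_params, seed=sim_seed)
        scan = detect_qtls(diff, result, pp)
        calls_per_sim.append(len(scan.calls))
    calls_per_sim = np.array(calls_per_sim)
    frac = float((calls_per_sim > 0).mean())
    return {
        "n_sims": n_sims,
        "n_with_calls": int((calls_per_sim > 0).sum()),
        "fraction_with_calls": frac,
        "calls_per_sim": calls_per_sim.tolist(),
    }


# ---------------------------------------------------------------------------
# file-writing pipeline


@dataclass
class PipelineConfig:
    """Configuration of a full file-writing run."""

    sim: SimConfig = field(default_factory=SimConfig)
    site_params: SiteFilterParams = field(default_factory=SiteFilterParams)
    window_params: WindowParams = field(default_factory=WindowParams)
    perm_params: PermutationParams = field(default_factory=PermutationParams)
    interval_params: IntervalParams = field(default_factory=IntervalParams)
    rna_params: RnaScanParams = field(default_factory=RnaScanParams)
    deg_params: DegParams = field(default_factory=DegParams)
    gain_threshold: float = 1.5
    skip: tuple[str, ...] = ()  # subset of {"rna", "cnv", "inherit"}
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.skip) - {"rna", "cnv", "inherit"}
        if unknown:
            raise ValueError(f"unknown skip stages: {sorted(unknown)}")


def _call_frame(calls: list[QtlCall], intervals: list[QtlInterval]) -> pd.DataFrame:
    rows = []
    for c, iv in zip(calls, intervals):
        rows.append(
            {
                "chrom": c.chrom,
                "start": iv.start,
                "end": iv.end,
                "peak_start": c.peak_start,
                "peak_end": c.peak_end,
                "peak_value": c.peak_value,
                "interval_bp": iv.span,
            }
        )
    return pd.DataFrame(rows, columns=[
        "chrom", "start", "end", "peak_start", "peak_end", "peak_value", "interval_bp",
    ])


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the full pipeline, writing every stage output plus a run
    manifest (tool version, config echo, seeds, per-file checksums) to
    ``out_dir``.  Re-running with the same config and seed reproduces the
    checksums."""
    from hapbsa.cnv import expression_fold_change, qpcr_copy_number, relative_coverage, size_factors
    from hapbsa.inherit import classify_inheritance, monogenic_test, probit_fit
    from hapbsa.simulate import emit_dose_response, emit_qpcr

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_cfg = dataclasses.replace(config.sim, seed=config.seed)
    stages: dict[str, float] = {}
    files: dict[str, str] = {}

    def _write(name: str, writer, *args) -> None:
        path = out / name
        writer(*args, path)
        files[name] = io.sha256_of(path)

    t0 = time.time()
    result = simulate_experiment(sim_cfg)
    stages["simulate"] = time.time() - t0

    io.write_layout(result.layout, out / "layout.tsv")
    files["layout.tsv"] = io.sha256_of(out / "layout.tsv")
    _write("parents.tsv", io.write_sites, parent_table(result))
    _write("pool_counts_dna.tsv", io.write_sites, pool_count_table(result, "dna"))
    _write("annotation.bed", io.write_bed, result.annotation[["chrom", "start", "end", "gene"]])
    _write("annotation.gff3", io.write_gff3, result.annotation)
    gene_dna = pd.DataFrame(
        {name: s.gene_dna_coverage for name, s in result.pools.items()},
        index=result.annotation["gene"],
    )
    gene_rna = pd.DataFrame(
        {name: s.gene_rna_counts for name, s in result.pools.items()},
        index=result.annotation["gene"],
    )
    _write("gene_dna_coverage.tsv", io.write_counts, gene_dna)
    _write("gene_rna_counts.tsv", io.write_counts, gene_rna)

    t0 = time.time()
    records = infer_sites(result, config.site_params)
    stages["infer_sites"] = time.time() - t0
    _write("informative_sites.tsv", io.write_sites, records)

    t0 = time.time()
    diff = dna_scan(result, records, config.window_params)
    scan = detect_qtls(diff, result, config.perm_params, config.interval_params)
    stages["dna_scan"] = time.time() - t0
    _write("mean_difference_track.tsv", io.write_track, scan.diff.mean)
    null_df = pd.DataFrame({"max_deviation": scan.null.maxima})
    null_path = out / "permutation_null.tsv"
    null_df.to_csv(null_path, sep="\t", index=False)
    files["permutation_null.tsv"] = io.sha256_of(null_path)
    calls_df = _call_frame(scan.calls, scan.intervals)
    _write("qtl_calls.bed", io.write_bed, calls_df)
    qtl_json = {
        "threshold": scan.threshold,
        "fdr": config.perm_params.fdr,
        "n_permutations": config.perm_params.n_permutations,
        "calls": calls_df.to_dict(orient="records"),
        "subsidiary_peaks": [
            {"chrom": s.chrom, "peak_start": s.peak_start, "peak_end": s.peak_end,
             "peak_value": s.peak_value}
            for s in scan.subsidiary
        ],
    }
    (out / "qtl_calls.json").write_text(json.dumps(qtl_json, indent=2))
    files["qtl_calls.json"] = io.sha256_of(out / "qtl_calls.json")

    report: dict = {"threshold": scan.threshold, "n_qtl": len(scan.calls)}

    if "rna" not in config.skip:
        t0 = time.time()
        rna = rna_bsa_scan(rna_site_table(result), result.pairs, result.layout, config.rna_params)
        stages["rna_scan"] = time.time() - t0
        _write("rna_mean_track.tsv", io.write_track, rna.mean)

    if "cnv" not in config.skip:
        t0 = time.time()
        factors = size_factors(gene_dna)
        controls = [s for s, _ in ((n, p) for n, p in result.pools.items()) if s.startswith("S")]
        rel = relative_coverage(gene_dna, factors, controls)
        selected = [n for n in result.pools if n.startswith("R")]
        from hapbsa.cnv import call_cnv_segments

        rel_sel = rel[selected].mean(axis=1)
        segments = call_cnv_segments(rel_sel, result.annotation, config.gain_threshold)
        rna_factors = size_factors(gene_rna)
        fc = expression_fold_change(gene_rna, rna_factors, selected, controls)
        # qPCR emission at the true pooled copy dose of the CNV anchor gene
        cnv = sim_cfg.cnv_locus
        copy_numbers = {}
        if cnv is not None:
            mid_idx = result.founders.informative_index(cnv.chrom, (cnv.start + cnv.end) // 2)
            for name, sample in result.pools.items():
                f_r = sample.true_freq[result.founders.informative][mid_idx]
                copy_numbers[name] = 1.0 + f_r * (cnv.copies - 1)
            qpcr_table = emit_qpcr(copy_numbers, sim_cfg, substream(config.seed, "qpcr"))
            qpcr_table.to_csv(out / "qpcr.tsv", sep="\t", index=False)
            files["qpcr.tsv"] = io.sha256_of(out / "qpcr.tsv")
            cn = qpcr_copy_number(
                qpcr_table,
                {"CPR": sim_cfg.qpcr.efficiency, "VGSC": sim_cfg.qpcr.efficiency},
                calibrator=controls[0],
                target="CPR",
                reference="VGSC",
            )
            cn.to_frame().to_csv(out / "qpcr_copy_number.tsv", sep="\t", index_label="sample")
            files["qpcr_copy_number.tsv"] = io.sha256_of(out / "qpcr_copy_number.tsv")
        seg_df = pd.DataFrame(
            [
                {"chrom": s.chrom, "start": s.start, "end": s.end, "copies": s.copies,
                 "n_genes": len(s.genes), "mean_relative_coverage": s.mean_relative_coverage}
                for s in segments
            ],
            columns=["chrom", "start", "end", "copies", "n_genes", "mean_relative_coverage"],
        )
        if len(seg_df):
            _write("cnv_segments.bed", io.write_bed, seg_df)
        fc.to_frame().to_csv(out / "expression_fc.tsv", sep="\t", index_label="gene")
        files["expression_fc.tsv"] = io.sha256_of(out / "expression_fc.tsv")
        stages["cnv"] = time.time() - t0
        report["n_cnv_segments"] = len(segments)

    if "inherit" not in config.skip:
        t0 = time.time()
        rng = substream(config.seed, "bioassay")
        doses = [5.0, 20.0, 100.0, 500.0, 2000.0, 8000.0]
        tables = {}
        for strain, mix in (
            ("R", [("R", 1.0)]),
            ("S", [("S", 1.0)]),
            ("F1_rm", [("F1", 1.0)]),
            ("F1_sm", [("F1", 1.0)]),
            ("BC", [("F1", 0.5), ("R", 0.5)]),
        ):
            tables[strain] = emit_dose_response(mix, sim_cfg, doses, 200, rng, population=strain)
        mortality = pd.concat(tables.values(), ignore_index=True)
        mortality.to_csv(out / "mortality.tsv", sep="\t", index=False)
        files["mortality.tsv"] = io.sha256_of(out / "mortality.tsv")
        fits = {s: probit_fit(tables[s]) for s in ("R", "S", "F1_rm", "F1_sm")}
        inh = classify_inheritance(fits["R"], fits["S"], fits["F1_rm"], fits["F1_sm"])
        w_f1 = dict(zip(tables["F1_rm"]["dose"], tables["F1_rm"]["dead"] / tables["F1_rm"]["n"]))
        w_r = dict(zip(tables["R"]["dose"], tables["R"]["dead"] / tables["R"]["n"]))
        mono = monogenic_test(w_f1, w_r, tables["BC"])
        inh["monogenic_chi2"] = mono.chi2
        inh["monogenic_df"] = mono.df
        inh["monogenic_p"] = mono.p_value
        (out / "inheritance.json").write_text(json.dumps(inh, indent=2))
        files["inheritance.json"] = io.sha256_of(out / "inheritance.json")
        stages["inherit"] = time.time() - t0
        report["inheritance"] = inh

    manifest = {
        "tool": "hapbsa",
        "version": __version__,
        "seed": config.seed,
        "config": {
            "sim": dataclasses.asdict(sim_cfg),
            "window": dataclasses.asdict(config.window_params),
            "permutation": dataclasses.asdict(config.perm_params),
            "site_filter": dataclasses.asdict(config.site_params),
            "interval": dataclasses.asdict(config.interval_params),
            "skip": list(config.skip),
        },
        "stage_seconds": stages,
        "checksums": files,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    report["manifest"] = manifest
    report["scan"] = scan
    return report
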