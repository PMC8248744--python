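# hapbsa

Bulked-segregant QTL mapping for haplodiploid experimental-evolution
designs: a forward simulator of the cross-and-selection experiment, and the
full analysis pipeline from pooled allele counts to significant QTL,
copy-number dosage, and mode-of-inheritance statistics.

## The problem

Pesticide-resistance loci in haplodiploid pests (spider mites and other
arrhenotokous arthropods) can be mapped with striking resolution by an
experimental-evolution BSA design: cross an inbred susceptible mother strain
to a **single haploid male** of a resistant strain, propagate many paired
selected/control populations for dozens of generations, and sequence each
population as a pool. Because the sire is haploid, every informative marker
segregates as a clean two-haplotype system, and the selected−control
difference in the frequency of the sire's allele, averaged over replicate
pairs, points at the loci under selection.

`hapbsa` is for researchers running or evaluating such designs. It
implements:

* **Site inference** — which allele the haploid sire transmitted at each
  marker, inferred from offspring pools, with the non-segregation filter
  (same allele at frequency ≥ 0.95 in both members of a pair drops the site
  for that pair).
* **Windowed scans** — mean transmitted-allele frequency in 75 kb windows
  at 5 kb steps (≥ 38 sites per window), paired selected−control
  differences, replicate averages; an RNA-read variant on exonic sites in
  500 kb windows.
* **Significance by circular permutation** — chromosomes are concatenated
  into a ring; each replicate's difference profile is rotated by an
  independent uniform offset 10⁴ times; the observed average is thresholded
  at the upper 5% of the null max-deviation distribution. Contiguous
  significant runs become QTL; intervals extend while one of five
  consecutive windows stays within 0.005 of the peak value.
* **CNV and dosage** — median-of-ratios size factors, relative DNA
  coverage against single-copy baselines, gene-resolution CNV segments,
  efficiency-corrected qPCR copy number
  (CN = E_t^ΔCt_t / E_r^ΔCt_r against a calibrator and a single-copy
  reference), and expression fold changes to test dosage effects.
* **Mode of inheritance** — probit regression of mortality on log₁₀ dose
  (LC50 with delta-method CI), Stone's degree of dominance
  D = (2·logLC50_F1 − logLC50_R − logLC50_S)/(logLC50_R − logLC50_S), and
  the monogenic-recessive backcross test against
  c = 0.5·W(F1) + 0.5·W(R) by χ² goodness of fit.
* **A forward simulator** of the whole design — haplodiploid transmission
  with one obligate crossover per chromosome, viability selection,
  pooled-read emission with CNV and cis-eQTL effects, qPCR and bioassay
  tables — so the entire pipeline runs with known ground truth and no
  external data.

See `docs/methods.md` for models, parameter defaults and design choices.

## Worked example

Simulate a reduced experiment (1 Mb genome, 3 pairs, a single selected
locus at chr1:250,000) and run the full pipeline:

```
hapbsa run --config examples/tiny.yaml --seed 5 --n-perm 2000 --out runs/tiny
```

with `examples/tiny.yaml`:

```yaml
chromosome_lengths: [500000, 300000, 200000]
snp_density: 0.002
n_pairs: 3
n_females: 120
pool_size: 120
n_generations: 10
burn_in_generations: 2
causal_loci:
  - [chr1, 250000, 0.5, 0.1]
cnv_locus: [chr2, 100801, 114000, 3]
```

The run prints

```
{"n_qtl": 1, "threshold": 0.42687478796877826}
```

meaning the permutation null put the genome-wide significance line at a
mean allele-frequency difference of ~0.43, and exactly one region exceeds
it. `runs/tiny/qtl_calls.json` holds the call:

```json
{
  "chrom": "chr1",
  "start": 230001,
  "end": 320000,
  "peak_start": 240001,
  "peak_end": 315000,
  "peak_value": 0.4780780657169445,
  "interval_bp": 90000
}
```

— the peak window (chr1:240,001–315,000) covers the true selected locus at
chr1:250,000 with a mean selected−control difference of ~0.48 at the peak,
and the peak-similarity interval spans 90 kb. `runs/tiny/inheritance.json`
summarizes the simulated bioassays:

```json
{
  "maternal_effect": false,
  "lc50_r": 2061.69,
  "lc50_s": 5.55,
  "lc50_f1_pooled": 17.71,
  "dominance": -0.608,
  "dominance_label": "incompletely recessive",
  "monogenic_chi2": 7.674,
  "monogenic_df": 6,
  "monogenic_p": 0.263
}
```

— parental LC50s of ~2,062 and ~5.5 mg/L, an incompletely recessive degree
of dominance D ≈ −0.61, no maternal effect, and a backcross that fits the
monogenic expectation (p = 0.26), as it should: this tiny design simulates
one causal locus. `runs/tiny/qpcr_copy_number.tsv` shows copy numbers near
1 for every pool relative to the control calibrator — in this config the
copy-number-variable block on chr2 is not under selection, so selected and
control pools carry it at similar drifted frequencies. (With the default
configuration, where the third selected locus coincides with the CNV block,
selected pools fix the amplified haplotype; the triplication is then
recovered both by coverage segments and by qPCR — see the test suite's
dosage scenarios.) A `manifest.json` with per-file checksums makes re-runs
verifiable: the same config and seed reproduce every file exactly.

The same stages are available as library functions
(`hapbsa.pipeline.analyze_experiment` and friends) and as individual
subcommands (`hapbsa simulate | infer-sites | scan | permute | call-qtl |
cnv | qpcr | inherit`).

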