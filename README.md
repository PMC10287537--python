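# dosagecomp

Gene-dosage and transcriptional-compensation analysis for fragmented
bacterial endosymbiont genomes.

Some long-term intracellular bacteria — the cicada endosymbiont
*Hodgkinia cicadicola* is the canonical case — split into several
interdependent cell lineages, each retaining only a complementary subset
of the ancestral gene set. Because the lineages live at very unequal cell
abundances, a gene kept by only a rare lineage may be present in a small
percentage of cells while its pathway partners sit at full dosage. Does
the symbiont transcriptionally compensate for this imbalance, or does
transcript abundance simply track gene dosage? `dosagecomp` provides the
simulation and statistical machinery to ask that question quantitatively,
for researchers working on endosymbiont genomics, metagenomic coverage
analysis, or stranded bacterial RNA-seq.

## The statistics at its core

For a split symbiont with lineages *l* at cell abundances *aₗ* (one contig
per lineage), the **relative dosage** of gene family *f* is

> *d_f* = Σ over contigs carrying a copy of *f* of that contig's share of
> the symbiont's DNA sequencing coverage,

so *d_f* = 1 for a universally retained family and *d_f* = *aₗ* for a
family exclusive to lineage *l*. Transcript abundance per family is the
summed TPM of its copies (sense-strand fractional counts, length
normalized over the protein-coding universe). Four transcriptional
responses to splitting are modeled per copy with per-cell rate ρ:

| scenario         | per-cell rate                 | signature                      |
| ---------------- | ----------------------------- | ------------------------------ |
| subdivision      | ρ = β (unchanged)             | total TPM tracks *d_f*         |
| complementation  | ρ = β / *d_f*                 | negative semipartial τ         |
| overcompensation | ρ = *k*·β, *k* > 1            | inflated RNA:DNA ratio R       |
| disruption       | ρ = β·ε, mean-one lognormal ε | no dosage signal, R not raised |

Hypotheses are tested with tie-corrected Kendall τ_b (normal Z
approximation), and with a **semipartial Kendall correlation** between
per-copy TPM and family dosage that removes each copy's DNA abundance from
the TPM side: sp = (τ_xy − τ_yz τ_xz)/√(1 − τ_xz²), with
Z = sp·√(9(n−1)(n−2)/(2(2(n−1)+5))). A rule-ordered classifier turns
(R, total test, semipartial test) into one of the four scenario labels.

## Worked example

Simulate a two-lineage symbiont at a 60:40 abundance split transcribing
under subdivision (no compensation), alongside an unsplit reference
symbiont and a host background, then quantify and test:

```python
from dosagecomp import RunConfig
from dosagecomp.pipeline import simulate_experiment, analyze_experiment

cfg = RunConfig(scenario="subdivision", abundances="T_undata", seed=2)
systems, rates, dna, rna, truth = simulate_experiment(cfg)
report = analyze_experiment(systems, dna, rna)

t, sp = report["total_test"], report["sp_test"]
print(f"dosage-expression: tau={t.estimate:.3f} Z={t.statistic:.3f} p={t.p:.3g}")
print(f"semipartial:       sp={sp.estimate:.3f} p={sp.p:.2f}")
print(f"RNA:DNA ratio quotient R={report['ratios']['R']:.3f}")
print(f"antisense fraction: {report['antisense_pct']:.2f}%")
print("label:", report["classification"].label)
```

prints

```
dosage-expression: tau=0.445 Z=6.850 p=7.38e-12
semipartial:       sp=-0.027 p=0.52
RNA:DNA ratio quotient R=0.926
antisense fraction: 5.06%
label: subdivision
```

Read: total transcript abundance rises significantly with gene dosage
(τ = 0.445) while per-cell transcription shows no residual dosage
dependence after controlling for copy DNA abundance (sp ≈ 0), and the
split symbiont produces RNA in proportion to its genome abundance
(R ≈ 1) — exactly the subdivision signature the simulation encoded.

The same pipeline is scriptable from the shell:

```sh
dosagecomp run --outdir out/ --seed 2 --scenario subdivision
dosagecomp simulate --outdir sim/ --seed 2
dosagecomp quantify --gff sim/genes.gff3 --bed sim/rna.bed \
    --antisense --rrna-filter --out counts.tsv
```

## Layout

- `dosagecomp.synthetic` — split-genome simulator: retention sampling,
  abundance presets, scenario rate tables, multinomial DNA/RNA fragments
  with analytic truth tables.
- `dosagecomp.quantify` — fractional sense/antisense counting, TPM, rRNA
  depletion, per-base strand coverage, downsampling.
- `dosagecomp.dosage` — coverage proportions, relative dosage, dosage
  Z scores, RNA:DNA ratios.
- `dosagecomp.inference` — Kendall/Pearson/semipartial tests, homolog
  aggregation, cross-species correlation, the scenario classifier.
- `dosagecomp.io`, `dosagecomp.pipeline`, `dosagecomp.cli` — GFF3/BED/
  FASTA/TSV/YAML surfaces and the orchestrated end-to-end run.

See `docs/methods.md` for the model, parameter defaults and their
calibration, numerical conventions, and known limitations.
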