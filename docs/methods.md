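# Methods

## The system being modeled

A bacteriome-style symbiosis with three sequence sources:

1. a **focal symbiont** whose ancestral genome has split into `L` cell
   lineages (one circular-mapping contig each) at unequal cell abundances
   `a_l`, with complementary gene loss: every ancestral protein-coding
   family is retained by at least one lineage, so the union of the
   lineages' gene sets reconstitutes the ancestral set;
2. an **unsplit reference symbiont** co-resident in the same organ, whose
   structural stability makes it the internal control for library
   composition and overall transcriptional output;
3. a **host background** absorbing a fixed share of reads.

Sequencing is abstracted to stranded fragments already resolved to the
transcript strand; there is no read-level error model, no quality scores
and no alignment step — fragment placement is the alignment.

## Generative model

**Splitting.** Each of `n_families` protein-coding families receives a
retention set: with probability `core_fraction` (default 0.05) it is kept
by every lineage (chaperone-like universally retained genes); with
probability `single_lineage_prob` (default 0.30) by exactly one uniformly
chosen lineage; otherwise by a uniformly sized (≥ 2) random subset. The
complementarity constraint only fixes the union, so this sampling scheme
is a modeling choice; it is repaired minimally so every lineage keeps at
least one family. Gene copies are laid on one contig per lineage on
alternating strands with 50–200 bp spacers; protein gene lengths are
uniform in [300, 1500] bp and shared across a family's copies. Each
lineage also carries 2 rRNA and 4 tRNA copies, which are excluded from
every expression universe downstream.

**Abundances.** Lineage cell abundances come from named presets matching
documented genome abundance distributions of real multi-lineage systems
(e.g. `T_undata` = 60:40, `O_oregona` = 45:35:18:2, `T_limbata` =
75:10:8:5:2), from explicit fractions (normalized), or from a symmetric
Dirichlet. The most fragmented documented system (12+ lineages) has no
preset because its published distribution is truncated.

**Transcription.** Family baselines are lognormal:
`beta_f ~ exp(N(mu_beta, sigma_beta))`, identical across a family's
copies. Scenario transforms per copy:

- *subdivision* — `rho = beta` (each cell keeps its presplit rate);
- *complementation* — `rho = beta / d_f`, rescuing the presplit
  population total for dosage-depleted families;
- *overcompensation* — `rho = k * beta`, genome-wide up-regulation;
- *disruption* — `rho = beta * eps`, `eps ~ exp(N(-sigma_d^2/2, sigma_d))`
  i.i.d. per copy. The noise is **mean-one**, not median-one: with
  median-one noise the expected total output grows by `exp(sigma_d^2/2)`,
  which is the overcompensation signature, not regulatory decay.
  Mean-one noise scrambles per-gene rates while leaving the expected
  total at its presplit level; because the realized sum of heavy-tailed
  draws is dominated by a few genes, realized total output is typically
  *below* expectation, reproducing the RNA-underrepresentation seen in
  the most fragmented natural systems.

rRNA copies transcribe at `rrna_multiplier` (default 20) times the mean
baseline — post-depletion libraries still carry substantial rRNA — and
tRNA copies at the mean baseline.

**Fragments.** DNA fragments are multinomial over contigs with weight
`a_l * length`, host share fixed at `host_dna_fraction` (default 0.50);
placement is uniform, strand random. RNA fragments are multinomial over
gene copies with weight `a_l * rho * length`, host share
`host_rna_fraction` (default 0.30); each gene fragment is placed
uniformly inside its gene (capped at the gene length for genes shorter
than `fragment_length`, so fragments never spill into neighbors), carries
the gene's strand, and is flipped to the opposite strand with probability
`antisense` (default 0.05) — the expected antisense share of
gene-overlapping fragments is exactly that parameter. With probability
`readthrough` (default 0, qualitative use only) the placement window
slides past the 3′ end to mimic run-on transcription. Closed-form truth
tables (dosage, rates, expected fragment shares, expected TPM) accompany
every draw.

## Quantification conventions

- **Fractional counting.** A fragment's unit weight is split among the
  genes it overlaps on the queried strand (sense: same strand;
  antisense: opposite) proportionally to overlap length; fragments
  hitting no qualifying gene contribute nothing. No
  expectation-maximization reassignment is performed — proportional
  splitting is deterministic, order-independent and sufficient at
  simulation scale, a documented divergence from EM-based quantifiers.
- **TPM.** `rate_c = count_c / length_c`, normalized to 1e6 over the
  symbiont's protein-coding copies. Effective length is the annotated
  length (no fragment-length correction), consistent with the
  simulator's weighting, and each symbiont is normalized separately.
- **rRNA depletion** removes any fragment overlapping an rRNA copy by
  ≥ 1 bp on either strand, emulating bioinformatic rRNA read removal.
- **Coverage** is the plain length-weighted mean depth per contig;
  outlier-trimmed ("adjusted") coverage is not replicated because
  simulated coverage has no outlier bases. Within-symbiont contig
  proportions are renormalized to 1 before dosage computation.
- Dosage lives on [0, 1] internally; percent appears only at I/O edges.

## Statistical conventions

- **Kendall tau-b** with tie-corrected denominator; the test statistic is
  the normal approximation `Z = S / sqrt(Var S)` with the full
  tie-adjusted variance of the concordance score (the convention of R's
  `cor.test`); p-values are two-sided normal. No exact enumeration.
- **Semipartial Kendall**: `sp = (t_xy − t_yz·t_xz) / sqrt(1 − t_xz²)`,
  removing the control (per-copy DNA abundance) from the TPM side only;
  `Z = sp·sqrt(9(n−gn)(n−1−gn)/(2(2(n−gn)+5)))` with `gn = 1` — the
  convention of the standard partial/semipartial rank-correlation
  packages. Rank methods make prior log-transformation of TPM moot.
  Copies with zero TPM stay in the input (as ties); zeros are dropped
  only before explicit log10 transforms (cross-species Pearson).
- **Pearson** reports `t = r·sqrt(nu)/sqrt(1−r²)`, `nu = n − 2`.
- **Replicates** are combined by a plain unweighted mean of dosage and
  of family TPM before testing.
- **Classifier** rule order, with `alpha = 0.05`, `theta_over = 2.0`:
  (1) `R ≥ theta_over` → overcompensation; (2) semipartial significantly
  negative → complementation; (3) semipartial non-significant and total
  dosage-expression test significantly positive → subdivision;
  (4) otherwise → disruption/indeterminate. A significantly *positive*
  semipartial is annotated, not classified: it arises naturally when
  lineage-specific losses are biased toward lowly expressed genes.
  `theta_over = 2` separates a 3%→23% DNA→RNA shift (ratio ≈ 7.7, flags)
  from a 21%→10% shift (ratio ≈ 0.48, does not). No multiple-testing
  correction is applied across systems.

## Default parameters and their calibration

| parameter            | default | rationale                                         |
| -------------------- | ------- | ------------------------------------------------- |
| `n_families`         | 150     | order of a reduced endosymbiont proteome          |
| `sigma_beta`         | 0.45    | see below                                         |
| `k` (overcomp.)      | 4.0     | clearly above `theta_over` after sampling noise   |
| `sigma_d`            | 6.0     | see below                                         |
| `antisense`          | 0.05    | baseline antisense transcription                  |
| `rrna_multiplier`    | 20      | ~40% residual rRNA in symbiont RNA                |
| depths (DNA/RNA)     | 1e5/2e5 | desk-scale libraries resolving all tests          |
| host DNA/RNA share   | 0.5/0.3 | typical bacteriome library composition            |

`sigma_beta` (baseline spread, natural-log scale) was fixed by a design
calibration run before the test suite was written: under subdivision at
the 60:40 preset the dosage-expression tau should land in the 0.44–0.58
range observed in real split systems; `sigma_beta = 0.45` yields
tau ≈ 0.45–0.53. `sigma_d` must make disruption distinguishable from
subdivision, and the classifier's only separator is the loss of total-test
significance; with four-lineage abundance spreads (dosage spanning
0.02–1.0, ~1 natural-log unit of spread) the noise must dominate that
spread by several fold, hence `sigma_d = 6`. This is deliberately
caricatural — disruption here means rank-destroying decay, not mild
dysregulation; milder decay is statistically indistinguishable from
subdivision under this design, which is itself an informative property of
the method.

## What the simulator does and does not emulate

It emulates: unequal lineage abundances with complementary retention,
lognormal baseline transcription, scenario-specific per-cell responses,
stranded fragments with antisense contamination, rRNA load, a stable
reference symbiont and host background — everything the downstream
statistics consume. It does **not** emulate sequencing error, mapping
ambiguity between paralogs, GC or positional coverage bias, operon
structure (beyond optional read-through), replicate-level biological
variation, or multi-contig lineages (available as a config option in
principle but off by default: one contig per lineage keeps the dosage
definition unambiguous). Passing tests therefore demonstrate the
correctness and calibration of the statistical machinery under the stated
generative model, not robustness to the full messiness of real
metagenomic data; the external count-table entry point exists so real
quantifications can be fed directly to the inference layer.

## Numerical and degenerate-input conventions

Internal coordinates are 0-based half-open everywhere; GFF3 (1-based
inclusive) is converted at the I/O boundary only. All randomness flows
from named integer seeds through `numpy` Generators; sub-seeds are
derived with `SeedSequence`, and regenerating with the same seed is
byte-identical across FASTA/GFF3/BED/TSV outputs. Zero-variance inputs
to correlation tests, all-zero count vectors entering TPM, zero total
coverage, and perfectly collinear semipartial controls raise typed
errors rather than returning silent zeros or NaNs. A symbiont with a
single lineage has no dosage variance; the pipeline records tables but
skips the tests and classification for it.

## Known limitations

- The semipartial test on a two-lineage system works with very coarse
  rank structure (three dosage levels, two abundance levels); its
  finite-sample null distribution is noticeably wider there than the
  normal approximation suggests, so occasional significant-positive
  draws occur under pure subdivision (~5–10% at default scale). The
  classifier annotates rather than reclassifies these.
- `R` (RNA:DNA ratio quotient) is a coverage-mass statistic and is
  sensitive to a few highly expressed genes; under heavy-tailed
  disruption noise its realized value is volatile.
- The named abundance presets describe *approximate* published
  distributions; they are inputs, not estimates.
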