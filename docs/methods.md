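# Methods

This note documents the models and procedures implemented in `longevol`,
their assumptions, the parameters that matter, and the design choices made
where the design was genuinely open.

## Clonality model

The clonality rate (cancer cell fraction, CCF) of a somatic mutation is the
fraction of tumor cells carrying it. The observed variant allele frequency
mixes tumor and normal reads according to sample purity ρ and the local copy
state:

    E[VAF] = ρ · m · CCF / (ρ·c_t + (1 − ρ)·c_n)

with m the number of mutant copies per carrying cell, c_t the local tumor
total copy number and c_n the normal copy number. Assumptions: one mutation
per locus, a single tumor copy state per segment, purity known from upstream
estimation (purity is an input here, not estimated), and c_n = 2 on
autosomes (configurable for sex chromosomes; the default keeps 2, appropriate
for XX genomes and for X in males only after adjusting the input copy
numbers).

Multiplicity is estimated per variant by rounding (half away from zero) the
implied mutant copy count `VAF·(ρ·c_t + (1−ρ)·c_n)/ρ` and clipping to
[1, max(1, round(c_t))]. Joint estimation across variants is out of scope.
Inverting the VAF model with the estimated m gives the raw CCF; values above
1.2 are flagged as purity/copy-number inconsistencies, and reported values
are capped at 1.5 so that outliers cannot dominate the downstream mixture
fit while the >1 signal remains visible.

### The clonality matrix

Rows are the union of mutations called at any timepoint. A mutation uncalled
at timepoint t is confidently absent (CCF 0) only when the site is covered at
depth ≥ `min_depth` (default 20, matching the common ≥20× coverage QC
convention) in that sample; coverage is supplied through an optional per-site
depth table (from a pileup over the union sites, or from the simulator).
Without coverage evidence the cell is masked `absent_lowdepth` and the row is
excluded from clustering, because dropout and true absence cannot be
distinguished there. Zero-depth sites for *called* variants cannot occur;
a called variant with no overlapping segment is an error unless a
`default_cn` is configured.

## Clone tracking

Rows of the clonality matrix are clustered with a finite Gaussian mixture
fitted by EM. Implementation choices:

- **Covariance families**: spherical, diagonal and full — the volume/shape
  spectrum that matters for 2–4 dimensional CCF data. (The R reference for
  model-based clustering fits 14 parameterisations; the three implemented
  span the same qualitative range.)
- **Initialisation**: k-means++ seeding, 10 restarts, restart seeds derived
  deterministically from the base seed via `SeedSequence`; the best restart
  by final log-likelihood wins. Fits are exactly reproducible given a seed.
- **Convergence**: relative total log-likelihood change < 1e-6 or 500
  iterations; per-iteration log-likelihoods are retained and are
  non-decreasing (EM guarantee, asserted in tests).
- **Numerical floor**: 1e-6 added to covariance diagonals. Lost clones have
  exactly-zero CCF columns; the floor keeps those fits well-posed.
- **Model selection**: BIC = p·ln(n) − 2·log L, minimised over k = 1..k_max
  (default 6) and the three families; ties break toward smaller k, then
  spherical < diagonal < full. Degenerate (k, family) combinations are
  skipped. Note that on very small n (≈10 rows) BIC-selected mixtures
  legitimately overfit — both this implementation and the R reference pick
  k > 1 on 10 rows of pure noise — so model selection should be interpreted
  with n ≳ a few dozen mutations per expected clone.
- **Hard assignments**: maximum posterior responsibility, ties to the lowest
  component id. The E/M steps are those of scikit-learn's
  `GaussianMixture`; restart control, convergence bookkeeping and BIC live
  here.

Each component's mean trajectory is classified with a presence threshold
(default CCF ≥ 0.10; the boundary between "present" and "very low clonality"
is not sharply defined biologically, so the threshold is configurable):
present at all timepoints → `preserved`; present first, absent last →
`lost`; absent before t, present from t on → `emerged@t`; anything else →
`transient`. Components attracting no hard-assigned mutations are dropped.

## Substitution spectra and hypermutation

SNVs are collapsed to the pyrimidine reference strand (G>A becomes C>T with
reverse-complemented context), yielding 6-class counts and, where
trinucleotide contexts are annotated (INFO `TNC`), 96-class counts. Contexts
come from annotation or the simulator, never from a reference FASTA — the
package is download-free by design; a context whose middle base contradicts
the ref excludes that variant from the 96-class counts only. The C>T
transition fraction is reported rounded to integer percent. Indels are
retained for burden counting but never enter spectra.

Hypermutation is flagged at ≥ 500 coding SNVs (inclusive). The threshold
separates the two regimes seen in treated gliomas — thousands of coding
mutations after acquired MMR deficiency versus tens otherwise — by more than
a factor of two on either side; `mut_per_mb` uses a 30 Mb capture footprint
by default. The MMR screen returns non-synonymous (missense, nonsense,
frameshift, splice) variants in {MLH1, MSH2, MSH6, PMS2}; deleteriousness
prediction is out of scope — effect classes are taken from annotation.

## Chromothripsis detection

Evidence for chromothripsis in exome-derived data is oscillating copy
states plus many clustered, high-read-support breakpoints, with either
high-level amplification (double-minute route) or extensive deletion. The
detector makes that operational with five gates (all configurable):

| parameter | default | role |
|---|---|---|
| `support_min` | 100 reads | a breakpoint counts only at this support |
| `amp_min` | 20 copies | high-level amplification level |
| `switch_min` | 10 | adjacent rounded-copy-state changes per chromosome |
| `break_min` | 10 | supported breaks per chromosome |
| `del_frac_min` | 0.30 | deleted (CN ≤ 1) length fraction, deleting events |
| `merge_tol` | 10 kb | breakpoint-end to segment matching slack |

The two evidence levels printed in the source study (>20 copies, >100
supporting reads) anchor `amp_min` and `support_min`; the remaining gates are
this package's operationalisation. Copy states are rounded to integers
before oscillation counting, absorbing segmentation noise. Deleting
chromosomes may count supported inter-chromosomal links toward `break_min`
(deletion-type events are often joined across chromosomes). The
lesser-allele-frequency shift (length-weighted mean |0.5 − LAF|) is reported
as supporting evidence and never gates a call. Positive chromosomes joined
by ≥ 1 supported inter-chromosomal breakpoint merge into a single
multi-chromosome call, typed amplifying if any member passes the amplifying
gate.

Double-minute candidates are connected components of the graph whose nodes
are segments with rounded CN ≥ `amp_min` and whose edges are supported
breakpoints with both ends inside (± `merge_tol`) node segments; isolated
high-copy segments do not qualify. Sequencing alone cannot distinguish
double minutes from homogeneously staining regions (that requires FISH), so
these are candidates, not calls.

## Cohort reporting

A sample is screen-positive with ≥ 1 chromothripsis call. Percents are
rendered to match the printed cohort statistics under one convention:
values ≥ 10% round to the nearest integer, values < 10% keep one truncated
decimal, exact integers print bare (16/52 → "31%", 1/57 → "1.7%",
1/52 → "1.9%"). `run_patient` executes clonality → clustering →
classification → spectra → hypermutation → chromothripsis from a single
config (YAML or mapping) and emits a deterministic report: identical config
and seed give byte-identical JSON.

## Synthetic data: what it emulates, and what it does not

The generators plant known structure on a miniature genome (22 chromosomes
of 10 Mb) so that fixtures are tiny and every statistic can be checked
against truth:

- **Serial tumors** (`simulate_patient`): default study conditions are four
  clones of 50 mutations each with trajectories (0.9,0.9,0.9), (0.6,0,0),
  (0,0.6,0.6), (0,0,0.6); purity 0.5 at every timepoint; depth ~
  Poisson(200); alt reads ~ Binomial(depth, model VAF); mutations with < 3
  alt reads at a timepoint are dropped from that timepoint's calls (caller
  dropout) while their site depth is recorded in a coverage table. Diploid
  copy number and multiplicity 1 everywhere by default. The lost clone
  carries an EGFR A289V-style missense marker, the late clone an MSH6
  T767I-style marker. The showcase variant (`showcase_patient_clones`)
  scales the late clone to 2 900 mutations with a 0.97 C>T-mass profile and
  sets early-clone C>T masses so the emitted per-timepoint C>T ratios sit
  near the study's printed 68 / 54 / 97% pattern.
- **Chromothriptic chromosomes**: amplifying mode alternates CN 2 with CN
  20–30 over 20–60 segments and emits ≥ n_segments supported (110–300 read)
  intra breaks between amplified segments; deleting mode puts ≥ 30% of the
  length at CN ≤ 1; quiet mode is one diploid segment with ≤ 2 low-support
  breaks.
- **Cohort**: per-subtype positive counts are `round(rate · n)` — planted
  deterministically, not sampled — so screen results are exactly checkable.

What the generator does **not** model: germline contamination and sequencing
error (alt reads at non-mutated sites), mapping artifacts, subclonal copy
number, overlapping mutations, indel signatures, purity mis-estimation, and
real genomic context (replication timing, capture bias). Passing tests
therefore demonstrate correctness of the estimators and detectors under the
generative model's assumptions — binomial sampling noise, caller dropout,
segmentation-level CN — not robustness to every artifact of real exomes.

## Problem sizes and determinism

Test-suite and acceptance-run sizes were chosen to exercise the statistics
at meaningful scale while staying desk-sized: 20 seeded patients × 200
mutations for clone recovery, 50 + 50 chromosomes for the detector
benchmark, 100 seeds × 2 079 draws for the spectrum band, one 109-sample
cohort screen. Every stochastic component takes an explicit seed;
`scripts/acceptance.py` derives all sub-seeds from its `--seed` argument.

## Known limitations

- Purity and copy-number segmentation are inputs; errors in them propagate
  directly into CCFs (flagged only when raw CCF > 1.2).
- Per-variant CCFs at depth ~200 and purity 0.5 carry binomial noise of
  ~0.1 sd; clone-level trajectories (cluster means over ≥ 50 mutations) are
  accurate to ~0.015, and that is the level at which results should be read.
- Evolution classes are threshold rules on mean trajectories; no phylogeny
  or clone tree is inferred, and classes can flip for clusters sitting near
  the presence threshold.
- The chromothripsis gates are heuristics tuned to the high-evidence regime
  (deep WES); subtle events below the amplification/break thresholds are
  missed by design, and no statistical test of breakpoint randomness is
  performed.
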