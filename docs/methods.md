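# Methods

## Model

A biopsy is modeled as a dose mixture over haplotypes. Every SNP carries
doses of the four parental haplotypes (plus contaminant haplotypes); the
expected embryo BAF is the dose-weighted B-allele proportion and the
expected Log2R is `log2(total dose / 2)`. Genotype *categories* are a
total, deterministic function of the parental calls (and, on the Y
chromosome, of maternal signal intensity): both parents homozygous for
different alleles (category 1), one parent heterozygous (categories 2/3),
both homozygous for the same allele (category 4). Any other combination —
AB×AB, or a parental no-call outside the Y rule — is excluded. Hemizygous
A/− and B/− are encoded AA/BB because arrays cannot distinguish them.

With maternal dose *m* and paternal dose *p*, category-1 BAF values sit at
`p/(m+p)` (1A) and `m/(m+p)` (1B), so `delta_BAF = (m−p)/(m+p)`. The
mixture closed forms used for the mosaic-fraction estimate assume each
aneuploid cell adds exactly *k* chromatid-equivalent doses (gain) or
removes one (loss):

* gain: `|d| = kf/(2+kf)` inverted as `f = 2|d|/(k(1−|d|))`, bounded by
  `k/(2+k)` (1/3 for a single extra dose);
* loss: `|d| = f/(2−f)` inverted as `f = 2|d|/(1+|d|)`.

The two parameterizations `(k, f)` and `(2k, f/2)` produce identical
`(delta, Log2R)` pairs, so *k* is chosen parsimoniously: the smallest *k*
whose implied fraction is ≤ 1 plus a noise slack (`dose_tol`, default
0.25). Confidence intervals propagate the delta standard error through
the inversion (delta method, 95%).

## Decision logic

Each interval is classified from three signals: delta_BAF (trimmed means,
5% per tail, of the two category-1 subcategories), mean Log2R, and the
BPH pattern per parent. The decision table (defaults in
`ClassifierConfig`):

* |d| ≤ 0.08 and Log2R in the normal band → disomy;
* Log2R ≥ +0.10 with |d| > 0.08 → gain of the excess parent; BPH if that
  parent's informative track shows a run of ≥ 20 informative SNPs outside
  the homozygous BAF bands (≤ 0.15 / ≥ 0.85), else SPH. Under disomy or
  SPH roughly half the informative SNPs are homozygous, so a 20-SNP clean
  run has probability ≈ 0.52²⁰ ≈ 2·10⁻⁶ per position — the flag is
  essentially noise-free evidence; allele dropout breaks runs in true BPH
  regions only at the ADO rate, which leaves expected clean runs of ≈ 30+
  SNPs at the default 5% ADO.
* Log2R ≤ −0.12 with |d| > 0.08 → loss of the deficit parent
  (whole-chromosome: monosomy; partial: deletion);
* |d| ≥ 0.80 at normal Log2R → uniparental disomy (hetero- vs isodisomy
  by the BPH flag); |d| ≥ 0.80 with *elevated* Log2R is contradictory and
  returns no_call, as does an elevated/reduced Log2R without any parental
  imbalance;
* intermediate |d| at normal Log2R with a BPH pattern on the excess
  parent → low-grade BPH gain; without it → no_call.

Meiosis stage: homozygous stretches (rolling homozygote fraction ≥ 0.3
over 10 informative SNPs, trimmed to the actual homozygous SNPs, each
with ≥ 10 of them) are intersected with the centromere interval
(configurable margin, default 0 — the trimmed stretch bounds are precise
to the informative-SNP spacing, and a wider margin misattributes
meiosis-I gains whose first crossover lands near the centromere). No
overlap → meiosis I; overlap → meiosis II. SPH gains are labelled
`mitotic_or_MII_no_recomb` since the two are indistinguishable.

Segmentation: non-overlapping windows of 16 category-1 SNPs (≈ 6 Mb at
the default simulated density) carry (delta, mean Log2R); in-package
binary segmentation with a BIC-style penalty (12 · σ̂² · log n, robust σ̂
from lag-1 differences) splits the series; segments are re-measured
exactly, and adjacent segments merge only when both the verdict and the
evidence level agree (delta within 0.08, Log2R within 0.2), so a full
deletion stays separate from a surrounding mosaic loss. Intervals longer
than 12 Mb without any category-1 SNP but covered by other SNPs (the
consanguinity/IBD situation) are carved out and reported `no_call` —
nothing can be asserted there.

Genome-wide verdicts use the autosome-wide delta distribution and BPH
flags, never Log2R (array normalization can mask whole-ploidy shifts):
≥ 80% of autosomes at |d| ≥ 0.8 → haploidy (the verdict cannot be
distinguished from genome-wide UPD by allele frequencies alone);
d ∈ [0.2, 0.5] genome-wide with BPH flags on ≥ 50% → triploidy;
d ∈ [0.04, 0.2) genome-wide → underrepresented extra haplotype. The
polar-body signature compares the deviation of near-homozygous
category-2 SNPs off the 0/1 rails between pericentromeric (centromere
± 5 Mb) and distal windows: a second polar body is the non-transmitted
sister chromatid, identical to the transmitted one around the centromere
and divergent beyond crossovers, so the deviation appears only distally
(chromosome positive when max distal window deviation ≥ 0.05 while the
pericentromeric mean is ≤ 0.03; signature when ≥ 50% of scorable
autosomes are positive). Contamination QC reports the fraction of
category-4 SNPs inside the open (0.2, 0.8) BAF band plus a rough dose
estimate from the mean rail deviation assuming the contaminant carries
the opposite allele at a configurable rate (0.5); polar-body and cumulus
DNA are invisible here (the mother is homozygous at category-4 SNPs by
construction), which is why the signature above exists separately.

Sex is inferred from the Y-rule category-1 SNPs (signal present and
concordant → XY; silent Y with a balanced X → XX; otherwise
undetermined), and a hemizygous X/Y in an XY embryo is reported as
normal rather than as maternal monosomy.

## Simulator

Parents are phased diploids drawn per SNP from Hardy–Weinberg at a
population B-allele frequency ~ U(0.05, 0.95); an optional IBD region
copies one paternal haplotype into the mother, which removes category-1
SNPs there by construction. Meiosis places Poisson(1) crossovers per
chromosome arm, uniformly. Mechanistic events: meiosis-I gains transmit
two chromatids with different centromeric homologs; meiosis-II gains two
sister chromatids (same centromeric homolog, independent crossovers —
resampled until the sisters actually differ somewhere, because an MII
error with zero recombination divergence *is* an SPH event); SPH gains
duplicate the transmitted chromatid; UPD hetero/iso combine these with
loss of the other parent. Mosaicism mixes euploid and aneuploid doses at
the cell fraction, per chromosome. Haploidy/triploidy expand to
per-chromosome losses/gains (the triploid extra complement is sister-type,
matching polar-body-retention digyny). Contamination adds haplotype dose
`g = 2c/(1−c)` for DNA fraction `c`: the actual non-transmitted sister
(second polar body — the pericentromeric gap emerges mechanistically),
the other homolog's dyad (first polar body), the maternal genome
(cumulus), or a fresh individual (unrelated).

Noise emulates MDA-amplified array data: allele dropout at the allele
level (5%, flipping heterozygous signals to a rail) applied before BAF
jitter (truncated normal, SD 0.03 at homozygous and 0.07 at heterozygous
clusters, linearly interpolated), Gaussian Log2R noise (SD 0.30), small
parental no-call rate (0.2%), genotype calls thresholded at 0.2/0.8 with
NC below Log2R −4. No public noise figures exist for this chemistry;
these values were fixed once to make simulated profiles resemble real
MDA biopsy plots qualitatively, and all are exposed in `NoiseModel`.
The genome is human-scaled (approximate lengths and centromeres, 1-based
coordinates) with a default density of 40 SNPs/Mb — a desk-scale stand-in
for a ~300k genotyping array chosen so the full validation suite runs in
minutes on one CPU; real manifests can be supplied via the annotation
file. Log2R is emitted as `log2(dose/2)` without renormalization, so
simulated triploids show elevated Log2R even though the classifier
deliberately ignores that signal for ploidy calls.

What passing simulations do **not** show: the generator draws SNPs
uniformly (no manifest clustering, no GC waves — a config hook exists),
assumes a single contaminant source, treats multiple events on different
chromosomes as independent cell populations, and knows nothing about
signal-intensity artifacts of real scanners. Results on it validate the
statistics and the decision logic, not array chemistry.

## Validation experiments

`apcad.validation` (used by `scripts/acceptance.py` and the acceptance
tests) runs: 200 simulated embryos × 2 events each drawn from {disomy,
BPH-MI, BPH-MII, SPH, monosomy, 10–80 Mb deletion, 30–70% mosaic
(mitotic-type gain/loss — meiotic events are uniform by construction)}
for recovery rates; 50 seeds per fraction on a ~10k-SNP autosome for
mosaic calibration; 30 + 30 genomes for the polar-body signature; and the
IBD scenario. Problem sizes are arguments; the defaults above are what
the shipped suite runs.

## Known limitations

* Consanguine/IBD regions carry no category-1 information; they are
  reported `no_call`, and category-2/3 profiles there can resemble BPH.
* Low-grade (≲ 15–20%) gains produce BPH runs broken by the residual
  homozygous signal, so the run-based BPH flag saturates; genome-wide
  low-grade haplotypes are handled by the deviation statistic instead,
  and small low-grade segmental BPH events are callable but get no
  mechanism.
* Segment boundaries are window-quantized (± one window span).
* Balanced abnormalities (equal doses of both parents) are invisible to
  delta_BAF by construction; conflicting-signal intervals return
  `no_call` rather than a guess.
* The mosaic inversion assumes a single aneuploid subpopulation per
  chromosome.
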