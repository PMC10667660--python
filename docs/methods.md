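# Methods

## Internal-standard design

An internal-standard gene (ISG) is a synthetic molecule carrying the
binding sites of several amplicon primer pairs, so one spike-in calibrates
several assays at once. The designer works in two stages.

**Layout solving.** Each primer pair imposes one equality — (end of the
reverse-primer site) − (start of the forward site) + 1 = published product
length — and every pair of sites must be separated by at least `min_gap`
non-primer bases (default 1). Shared primers (805R serves both 16S pairs;
189f both *pmoA* pairs) occupy a single site, coupling the constraints.
The solver is a deterministic depth-first search that assigns sites in
input order at the smallest feasible coordinate and propagates the
equalities; since only product lengths are constrained, any satisfying
placement is acceptable and the smallest-coordinate rule makes the result
reproducible. Infeasibility (e.g. a product longer than the molecule) is
reported with the violated constraint. Coordinates are 1-based inclusive
throughout, and product lengths include both primer sites (the 291-bp
515F/805R product is the standard V4 amplicon-with-primers length).

**Spacer generation.** Degenerate IUPAC codes inside the embedded sites
are concretized with a fixed first-of-class policy (A < C < G < T); since
in-silico PCR always matches IUPAC classes, any choice of class member
still binds. Gaps are filled randomly per variant: the number of G/C
spacer bases is chosen so the whole molecule lands on the GC target
(default 0.50 ± 0.03, motivated by the GC sensitivity of PCR and
sequencing), positions are permuted by a seeded generator, and the
candidate is rejected and redrawn (bounded retries) if any primer matches
outside its declared site within the screening tolerance (default 2
mismatches, both strands, IUPAC-aware) or if it duplicates an earlier
variant. Variants therefore share the layout and differ only in spacers,
which is what makes them distinguishable as separate amplicon sequence
variants (ASVs) at different spike levels. Published spacer sequences can
be used instead by supplying them as FASTA; the generator exists so the
design is reproducible from a seed alone.

In-silico PCR reports every forward-site/reverse-site combination with the
forward site strictly upstream; on a well-designed ISG each pair yields
exactly one product, which the test suite asserts for every generated
variant.

## Calibration model

Spiked standard observation *i* has known reaction concentration
`c_i` (copies µL-reaction⁻¹) and read count `Y_i`. The dose-response is a
negative-binomial GLM with log link and the dose coefficient fixed at 1:

    ln E[Y_i] = ln c_i + b,    Var(Y_i) = µ_i + µ_i²/θ,

i.e. `ln c_i` enters as an offset and only the intercept `b` and the NB
size parameter `θ` are estimated. The fixed slope encodes the physical
assumption that reads are proportional to template copies; `exp(b)` is the
detection efficiency in reads per copy. Conversion of a biological count
is the inverse: `z = y / exp(b)` (0 reads map to 0, not −∞; below-LOQ
values are flagged, never censored, so tables remain total-preserving).

**Estimation.** Alternating profile maximum likelihood: the intercept by
Newton/Fisher scoring at fixed θ (the fixed-slope log-likelihood is
strictly concave in `b`), then θ by bounded 1-D maximization of the
log-likelihood over `ln θ ∈ [−7, 16]`, until successive log-likelihoods
differ by < 10⁻⁸ (at most 100 outer iterations, error on non-convergence).
The closed-form Poisson intercept `b = ln(Σy / Σc)` and a moment estimate
of θ initialize the search; a coarse profiled scan over `ln θ` guards the
alternating scheme against the coordinate-wise trap at the Poisson
boundary, and each θ step compares the Brent optimum against the interval
endpoints and the current value so the iteration is monotone and stable
when the data carry no overdispersion (the fit then reduces exactly to the
Poisson solution). The intercept SE comes from the expected Fisher
information Σ θµ/(θ+µ) at the optimum. Correctness is checked two ways in
the tests: the Poisson-limit closed form, and a dense independent grid
search of the written log-likelihood that the fitted optimum must match
within 10⁻⁶.

**Free-slope diagnostic.** The quantification model has no slope to test,
so a companion free-slope NB model (statsmodels) is fitted solely to
report the Wald p-value of the dose coefficient — the conventional check
that the standards actually show a dose-response. The fixed-slope model is
always the one used for conversion (a `--free-slope` mode reports the
companion model's coefficients instead).

**Calibration points.** Each (variant, level) standard observation is one
point; zero-read levels are excluded from the fit but define the limit of
quantification: the LOQ threshold is the mean read count of the
lowest-concentration level that was detected, and ASVs with fewer reads
are flagged `above_loq = False`. Pooling variants per level is supported
by supplying per-level rows; separate points are the default.

## Unit-conversion chain

All conversions are explicit volume-ratio products and exact inverses of
each other (round-trip identity to 1 part in 10¹², property-tested):

- mass to copies: `C = M · 6.02×10²³ / (660 g mol⁻¹ bp⁻¹ · 10⁹ ng g⁻¹ · L bp)`;
- mixed gradient standard: `n` per-variant dilutions mixed at equal
  volumes leave each variant at level/`n` (the default 4.0×10⁶…4.0×10³
  series totals 1.111×10⁶ copies µL⁻¹);
- sample chain (copies µL-DNA⁻¹ → copies µL-reaction⁻¹):
  `Z = Y · D/E · F/G · H/I` with dilution volumes D/E, sample fraction F/G
  of the sample+standard template mix, and template fraction H/I of the
  reaction; without the F/G term this is the qPCR chain;
- standard chain: the spiked standards enter the template at the
  complementary fraction `(G−F)/G` and are not subject to D/E (they are
  added after dilution); default mixing is 1 volume standard : 3 volumes
  sample, configurable since the protocol direction is ambiguous;
- sample amount: `X = Y · C/A` per g or L, with DNA-extraction efficiency
  assumed 100% (exposed as a multiplier defaulting to 1).

Defaults: D=E=1, F=3, G=4, H=2.5 µL, I=50 µL.

## Synthetic-data generator

The generator emulates exactly what the calibration model sees — counts:
for every standard (variant, level) pair and every taxon, reads are drawn
NB(mean, size) via a seeded Gamma-Poisson mixture with
`mean = detection_efficiency × amplification_efficiency × reaction
concentration`. Defaults are the reference study conditions: a 4-variant,
4-level gradient (16 calibration points per library, one per
variant-level pair), five taxa at 3.0×10⁴ copies µL⁻¹ DNA each
(a mock community mixed at equivalent amounts), detection efficiency 8
reads/copy, dispersion (NB size) 5. Per-taxon amplification efficiency in
(0, 1] summarizes primer-mismatch and processing biases; the model
faithfully propagates it, so a taxon at efficiency 0.21 is recovered at
≈21% of truth — amplicon calibration corrects sequencing depth, not
amplification bias, and the generator reproduces that limitation rather
than hiding it.

A companion routine emits synthetic genome-like templates with planted
primer-flanked amplicons (labelled synthetic; they are structural stand-ins,
not real genomes) to exercise the in-silico PCR → partition → quantify
path end to end.

What the generator does **not** model: base-level sequencer error,
chimeras, the paired-end merge loss mechanism, taxonomic structure, or
library-size competition between taxa. Passing recovery tests therefore
demonstrates the estimator's statistical correctness under the NB model,
not robustness to real-data artifacts.

With these conditions, the intercept's Fisher information is ≈ 16·θ = 80
(sd ≈ 0.112 on the log scale) and the five-taxon total read count has
log-scale sd ≈ 1/√(5θ) ≈ 0.20, so the recovered total concentration
carries an irreducible median absolute relative error of ≈ 16–17% per
library; the recovery tests document this (coverage of the intercept
interval is ≈ 90%). Larger communities or more standard levels tighten it.

## QC metrics

- Read recovery = read-out / read-in of a processing pipeline; the
  increment factor is the single-end/paired-end recovery ratio, computed
  per category (standard vs biological) so category-differential loss is
  visible. Both are scale-invariant.
- Partitioning labels an ASV `ISG` on exact match to a reference standard
  over the compared length (references truncated to the read length for
  single-end data), `discard` within 2 substitutions (standard-derived
  error reads, removed from quantification), else `biological`. Indel
  variants are not treated as standard-derived; the rule is Hamming-based
  because denoised ASVs are fixed-length.
- GGC profiling counts every occurrence of the GGC trinucleotide on the
  sense strand (overlap-aware) and splits occurrence start positions at a
  boundary (default 251 bp, the single-end forward read length): motifs
  behind the boundary are only traversed by the reverse read, where
  GGC-associated dephasing errors concentrate. Whether a motif straddling
  the boundary counts as front (start ≤ boundary, the choice here) is a
  documented convention, not an asserted fact.
- Amplicon GC tables run in-silico PCR per (template, primer set) and
  report product GC%, the covariate used to compare standard and
  biological amplicons.

## Problem sizes and determinism

Stochastic checks use 200 replicate libraries (recovery, bias) — enough to
pin a median to ±1–2 points — and 50 random instances for the grid-search
oracle; all randomness flows from explicit integer seeds through
`numpy.random.SeedSequence`, so every result in the test suite and the
acceptance script is bit-reproducible across platforms.

## Known limitations

- The designer screens cross-binding by Hamming distance with IUPAC
  classes, not thermodynamics (no Tm, dimer or hairpin modelling).
- One dispersion is shared across calibration points of a curve (matching
  the fitting model); per-row overrides exist in the generator only.
- 16S copy-number-per-genome correction is out of scope; concentrations
  are gene copies, not cell counts.
- The read-processing stages upstream of the ASV table (trimming,
  denoising, merging) are consumed as counts, never re-implemented.
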