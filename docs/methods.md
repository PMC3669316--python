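# Methods

## Model and procedure

The pipeline tests whether predefined metabolic pathways are coordinately
shifted between two phenotype classes of an expression study. Its one
departure from gene-level set enrichment is the unit of analysis: probe-level
scores are collapsed to Enzyme Commission (EC) activities before ranking, so
that isozymes — several genes catalysing one reaction — contribute a single
entry. The intended reading of a positive result is therefore about
potential flux through a reaction node, not about any individual gene.

Stages, in execution order:

1. **SNR ranking.** For each probeset, `s = (μ_t − μ_c)/(σ_t + σ_c)` with
   each class SD floored at `max(0.2·|μ|, 1e-8)`. The floor is the
   established convention for this ranking metric; it guards against
   near-constant probes dominating the extremes of the list. Scores are
   computed per probeset *before* collapse — the collapse acts on SNR
   values, never on intensities.
2. **EC collapse.** Probesets resolve through three partial map layers
   (probeset→UniGene→gene symbol→EC set). Failures at any layer go to an
   unmapped report naming the failing layer; nothing is silently dropped.
   A multifunctional gene carrying several ECs fans its probesets out to
   every EC: each catalytic activity is a separate node of the network and
   receives the full evidence from the probe (the alternative — electing a
   single primary EC — would hide real activities; the fan-out is recorded
   in the provenance so downstream counts remain auditable). Collapse modes:
   `average` (arithmetic mean; feeds the ranked list) and `max_abs` (the
   signed score of the largest-|score| probeset; feeds heat-map tables).
   `max_abs` ties break toward the lexicographically smallest probeset id
   and are logged.
3. **Enrichment score.** Weighted running sum over the EC-ranked list:
   `+|s_i|^p / Σ_hits |s_j|^p` at members, `−1/(N − N_hits)` at
   non-members; ES is the signed maximum deviation, the leading edge the
   members at/before (after, for negative ES) the extremum. Default weight
   `p = 1`, exposed as a flag. If every member score is exactly zero the
   weights degenerate to the unweighted (`p = 0`) form rather than 0/0.
4. **Permutation null.** Either `phenotype` (class labels permuted;
   ranking *and* collapse recomputed per permutation) or `set` (random
   same-size EC sets on the fixed observed ranking). `auto` picks phenotype
   when both classes have ≥ 7 samples, else set — the standard guidance,
   since with 3v3 designs only 20 distinct relabelings exist. Requesting
   phenotype below that limit logs a warning and falls back (overridable).
   Default 1,000 permutations.
5. **NES, p, q.** `NES = ES / mean(|null ES| of matching sign)`. Nominal
   p uses the same-sign portion of the null with a plus-one rule,
   `p = (1 + #extreme)/(1 + #same-sign)`, so p is never zero and is
   uniformly calibrated under the null. FDR q is the sign-stratified
   null-ratio: the fraction of pooled null NES at least as extreme divided
   by the fraction of observed NES at least as extreme, clipped to [0, 1]
   and made monotone in |NES| within each sign stratum (Benjamini–Hochberg
   on nominal p is deliberately *not* used; the choice is recorded in the
   run metadata). Pathways are filtered to 5–500 mapped members by default.
6. **Assay rates.** Consumption rate `(fresh − final)·V·1000/((cells/10⁶)·Δt)`
   in nmol·h⁻¹ per 10⁶ cells; production is the negative reported positive.
   OCR is reading/protein (pmol·min⁻¹·µg⁻¹). Proliferation is
   mean(treated)/mean(vehicle) with a first-order delta-method SD on the
   ratio of means (an approximation; validated against Monte-Carlo within
   5% at the CVs in play). Group comparisons use a two-tailed pooled-variance
   Student t-test by default (Welch by flag); two constant equal groups give
   p = 1 by convention. Stars: `**` iff p ≤ 0.01, `*` iff 0.01 < p ≤ 0.05.

## Numerical choices

- Ranking ties break by (score desc, id asc) for platform-stable output.
- ES is clipped to [−1, 1] to trim float accumulation overshoot (the
  statistic is bounded by construction); exact |max-deviation| ties between
  the positive and negative extremum resolve positive, with a 1e-12 slack
  so the O(N) scan and the O(k) hit-position evaluation (used for the
  permutation nulls) always agree on the sign. The two routes are checked
  against each other and against an exhaustive prefix-sum oracle in the
  test suite.
- Swapping the class roles negates every SNR and every ES exactly (the SD
  floor is symmetric in the classes), which the tests assert bit-for-bit.
- A pathway disjoint from the ranked list, below/above the size filters, or
  covering the entire list is skipped with a recorded reason; an empty
  surviving catalog is an error.
- When a sign stratum has no null samples, NES is NaN and p = 1; such
  entries are excluded from the FDR pool.

## Synthetic-data generator

The generator emulates a two-condition log2-intensity microarray
comparison and its companion plate assays; its defaults are the study
conditions the tests run under.

Expression: 2,000 genes, 1–4 probesets each, baseline log2 intensity
N(7, 1.5²) per gene with a N(0, 0.5²) per-probe offset, additive Gaussian
per-sample noise (SD 0.25), three arrays per class by default (matching the
experimental-triplicate convention of the assays; the replicate count is a
free parameter, not a reconstruction of any particular deposited dataset).
20% of genes form isozyme pairs sharing one EC — this is what makes EC
collapse non-trivial and is on by default. The catalog partitions the EC
pool into 50 disjoint 30-member pathways, so a planted effect belongs to
exactly one pathway and the truth table round-trips. Planting shifts every
gene of a pathway's ECs by `delta · noise_sd` in the treated class,
identically for all probesets of a gene.

Plates: doses 0–5 µg/mL including a vehicle; exponential growth from
50,000 seeded cells at a per-dose rate (0.020/h at vehicle falling to
0.012/h at the top dose); linear dose-responses with lactate rising
(300 + 40·dose nmol·h⁻¹/10⁶ cells), glucose consumption rising
(200 + 25·dose, kept at or above lactate/2 — one glucose yields at most
two lactates — and validated at config time), and protein-normalized OCR
falling (6 − 1·dose pmol·min⁻¹·µg⁻¹); the fresh-media interval is drawn
per well from 20–24 h; measurement noise is multiplicative lognormal
(CV 5%) applied to the realized per-well rate, and final concentrations
are derived from that noisy rate and the endpoint cell count, so a
zero-CV plate round-trips exactly through the rate calculations.
Concentrations that would go negative are clipped to zero with a note in
the plate metadata (clip-and-warn rather than resampling: simpler and
auditable). Rate magnitudes are typical of cultured epithelial lines
(glucose uptake of order 10²–10³ nmol·h⁻¹ per 10⁶ cells; basal OCR of a
few pmol·min⁻¹·µg⁻¹ protein).

What the generator does **not** emulate: probe-level hybridization
physics, batch or array-position effects, intensity-dependent variance,
CEL-file preprocessing, or correlated gene co-expression beyond the planted
sets. Passing tests therefore demonstrate the statistical machinery —
calibration of the null, power against coordinated mean shifts, exactness
of the arithmetic — not robustness to every artifact of real microarray
data.

The cell-number denominator for metabolite rates is the count at
collection (media and cells are harvested together); a time-averaged
exponential denominator is available behind a flag for users who prefer to
integrate growth over the interval. Which convention original wet-lab
analyses of this kind used is generally unstated; the endpoint default is
declared in the output metadata.

## Problem sizes

The statistical checks run at sizes chosen to make their Monte-Carlo error
small relative to the asserted bands: null calibration uses ten independent
3v3 null studies of 2,500 genes with 100 twenty-EC sets and 1,000 set
permutations each (1,000 p-values); power uses twenty 10v10 studies of
2,000 genes with one planted 30-EC pathway among 50 and 1,000 phenotype
permutations each. Both complete in well under a minute apiece on one core
thanks to the vectorized permutation path (class statistics by matrix
product, collapse by sparse matrix, ES from hit positions in O(k)).

## Known limitations

- With log2-intensity data the 0.2·|μ| SD floor usually binds, so SNR
  magnitudes are compressed and effectively mean-difference-driven; this is
  inherent to applying the conventional floor on the log scale.
- The set-permutation null ignores inter-gene correlation and is known to
  be anti-conservative on strongly correlated real data; the phenotype
  scheme is preferred whenever the design allows it.
- The FDR q is the null-ratio estimator, which can be noisy for small
  catalogs; q values for catalogs of a handful of pathways should be read
  qualitatively.
- The delta-method SD for normalized proliferation underestimates the
  spread when the vehicle CV is large (ratio distributions are heavy-tailed).
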