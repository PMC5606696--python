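# Methods

## Rate model

Each Accumulibacter population is described by substrate-inhibition
(Haldane) kinetics for phosphate:

    nu(S) = Vmax * S / ((Km + S) * (1 + S / Ki))

- `Vmax` — maximum specific substrate-utilization rate. Its time unit is
  deliberately carried as an opaque "per unit time": the model's dominance
  predictions depend only on rate *ratios*, which are unit-free. Where a
  concrete unit is needed (the competition simulator multiplies `nu` by
  hours), h⁻¹ is assumed; changing that convention rescales the time axis
  but never the winner.
- `Km` (mg P L⁻¹) — half-saturation constant; governs low-substrate
  affinity.
- `Ki` (mg P L⁻¹) — inhibition constant; high phosphate depresses the rate
  by the factor 1/(1 + S/Ki). As Ki → ∞ the law reduces to
  Michaelis–Menten (verified to |Δν| < 10⁻⁶·Vmax over 0–1000 mg P L⁻¹ at
  Ki = 10⁹).

The curve is unimodal with its maximum at S = √(Km·Ki) (from dν/dS = 0).
The built-in reference set (Type I: 0.95/0.48/2000, Type II: 1.0/0.5/300)
encodes the qualitative biology: nearly equal affinities, slightly faster
Type II, and roughly sevenfold stronger high-phosphate inhibition of
Type II. All concentrations throughout the package are mg P L⁻¹.

## Dominance, crossover, and the trial-and-error search

The population with the highest ν at the operating concentration is
predicted dominant. `dominant_label` applies a *relative* tie tolerance
(default 10⁻³): below it the rates are experimentally indistinguishable and
"tie" is returned. At 0.05 mg P L⁻¹ the reference curves differ by ~1.4 %,
a documented near-tie — enrichment outcomes at trace phosphate are not
resolvable by this model, and the package reports them as such rather than
forcing a winner.

Crossovers solve ν_a(S) = ν_b(S) for S > 0. The primary path brackets sign
changes of the rate difference on a 1000-point log-spaced scan of
(0, 1000] and refines each bracket by bisection (scipy `brentq`,
10⁻⁹ relative). Cross-multiplying the two rate laws and cancelling the
shared S = 0 root leaves the quadratic

    (Va/Kib − Vb/Kia)·S² + (Va(1+Kmb/Kib) − Vb(1+Kma/Kia))·S + (Va·Kmb − Vb·Kma) = 0,

kept as an independent cross-check, not the primary path (the bracketing
scan generalizes unchanged to non-quadratic rate differences). A pair of
curves can therefore cross at most twice; identical parameter sets raise a
"degenerate" error instead of returning infinitely many roots. For the
reference set the unique crossover is 18.348 mg P L⁻¹.

`search_explaining_params` formalizes choosing constants by trial and
error: it scans the full cross-product of per-parameter candidate grids and
retains exactly those parameter-set combinations whose predicted dominant
type matches every supplied observation (ties match nothing). Exhaustive
and deterministic; an empty result is a valid answer.

## Parameter fitting

`fit_params` is a bounded least-squares fit (scipy `least_squares`) of the
Haldane law to (S, rate) observations, requiring ≥4 points not all at one
concentration. Two residual options: absolute (default) and logarithmic —
rates span decades across the S range, so log residuals model
multiplicative errors and weight low-concentration points fairly.
Non-convergence is flagged in the result, not raised. Identifiability is as
expected for this model family: with zero noise all three parameters are
recovered to 10⁻⁶ relative; with 1 % multiplicative noise and n = 50
log-spaced points on 0.01–1000 mg P L⁻¹, Vmax and Km recover within 5 %
while Ki — which only shapes the curve near and beyond the peak — is weakly
identified (tested within 25 %).

## Competition simulator

A deliberately minimal discrete-cycle model: per cycle each population's
biomass multiplies by exp(k·ν_i(S_aer)·t_aer) with t_aer = 9 h by default,
then a uniform washout fraction is removed and fractions renormalized.
Assumptions: substrate utilization is proportional to growth (coupling
constant k, default 1, exposed because the mapping is not quantified); the
anaerobic phase contributes no *differential* growth (no anaerobic kinetics
are modelled); washout is population-blind (biofilm detachment unmodelled)
and hence cancels in relative abundances — it exists only to keep absolute
biomass bounded. Consequence, used as a test oracle: the log-ratio of two
populations' fractions is exactly linear in cycle number with slope
k·Δν·t_aer.

## Reactor mass balances

Per sampled cycle: aerobic uptake = flow · (aerobic h/24) · (influent −
effluent) mg P; anaerobic release = fill volume · end-of-phase P − retained
volume · aerobic effluent P (the carry-over correction: the sponge enters
the anaerobic phase already holding aerobic liquor); COD consumed = fill
volume · (influent − end COD), with the fraction remaining end/influent.
Specific rates divide amounts by sponge volume (cm³) and phase hours.
Defaults mirror a bench DHS unit: 3.24 L d⁻¹, 9 h + 3 h phases, 70 mL
anaerobic fill, 200 mg COD L⁻¹, 6 cm³ sponge. The retained liquid volume,
when unmeasured, defaults to the sponge's own volume (open-pore foam holds
roughly its volume of liquid). Negative balances (effluent above influent,
release below carry-over) are returned as computed with explicit flags,
never clipped — they flag measurement or operational anomalies.

## Clone-library processing

"99 % identity" alone does not pin an algorithm, so the conventions are
fixed and documented:

- **Identity** = identical columns / global-alignment length, gaps counting
  as mismatches (Needleman–Wunsch via biopython; match +1, mismatch −1, gap
  open −2, extend −0.5, chosen so a point substitution is never traded for
  a gap pair). Symmetric; equals the simple match fraction for equal-length
  ungapped alignments.
- **OTU clustering** is greedy and incremental in input order: a clone
  joins the first OTU whose representative it matches at ≥ threshold
  (default 0.99), else founds a new OTU. Deterministic; order sensitivity
  is accepted and tested rather than hidden. Raising the threshold never
  decreases the OTU count.
- **Clade assignment** takes the highest-identity panel reference if it
  reaches `min_identity` (default 0.85 — references of *different* clades
  sit at ~0.70–0.92 identity, so a genuine clone clears the bar for its own
  clade only); exact ties break by panel order and carry a flag. Tree
  placement is out of scope.
- **Composition** rounds percentages half-away-from-zero to integers
  (8/13 → 62 %), so clade percents can sum to 100 ± a small rounding
  remainder; type percentages sum clades by label prefix ("II" vs "I").

## Synthetic data

The generators produce every pipeline input as a pure function of
(spec, seed), with numpy `default_rng` substreams per data product:

- **Rate observations**: ν_truth(S)·(1+ε), ε ~ N(0, noise_sd), default 1 %
  — multiplicative because measured rates span decades.
- **Clone libraries**: clade counts ~ Multinomial(n, composition_truth);
  each clone is its clade reference with i.i.d. substitutions (default
  0.5 %, bounded below 5 %). Default per-run truths follow the canonical
  enrichment pattern (mostly IA at trace and at high phosphate, IIA/IIB
  rising in between, IIB dominating near 5 mg P L⁻¹) with library sizes of
  13–24 clones.
- **Reference panel**: 300-nt "ppk1-like" sequences built from a Type I
  ancestor, a Type II ancestor diverged at 15 % per site, and per-clade
  substitutions at 4–7 % — giving within-type reference identities of
  ~0.84–0.92 and between-type ~0.70–0.80. This preserves exactly the
  discrimination structure clade assignment needs while remaining fully
  synthetic (no indels, no rate heterogeneity, no real marker-gene
  phylogeny).
- **Reactor time series**: weekly records whose aerobic concentration drop
  follows a logistic enrichment curve (default plateau 1.2 mg P L⁻¹ drop,
  midpoint day 40, rate 0.15 d⁻¹ — an ~85-day approach to plateau);
  anaerobic end-phase concentrations are back-computed so release equals
  uptake (ratio 1 at steady state) times noise, and COD consumption is
  8 mg COD per mg P released, capped by the available substrate.

What passing tests therefore show: the *analysis* correctly recovers known
truth under the stated noise model. What they do not show: robustness to
real-data features the generators omit — sequencing indels and chimeras,
non-Gaussian rate errors, biofilm diffusion gradients, GAO competition, or
P in detached biomass.

## Numerical and design notes

- Crossover scan resolution (1000 log points) resolves root pairs closer
  than one scan step would miss; the closed-form quadratic bounds the root
  count at two, and oracle tests compare against a 10⁻³-spaced uniform scan.
- Rounding of percentages is half-away-from-zero, not banker's.
- CSV writers emit `repr` floats and readers parse with round-trip
  precision, so write→read is an exact identity.
- Seeds: any integer; per-run clone substreams derive from
  (seed, crc32(run_id)) so libraries are independent yet reproducible.
- Test problem sizes (20-pair and 100-pair crossover oracles, 1000
  multinomial draws, 200-day simulated horizons) were chosen as the
  smallest sizes at which the checked statistics are stable.

## Known limitations

- Kinetic constants for these uncultured organisms are assumed, not
  measured; the grid search returns *all* consistent parameter sets, and
  the reference set is one example, not an estimate.
- The competition model has no GAO–PAO interaction, no anaerobic
  selection, and no storage-polymer dynamics.
- The trace-phosphate regime (≲0.1 mg P L⁻¹) is a near-tie; the model
  makes no dominance claim there.
- Clade assignment is nearest-reference, not phylogenetic placement.
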