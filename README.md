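# paok — phosphate-dependent Accumulibacter competition kinetics

`paok` is a toolkit for analyzing how the aerobic phosphate concentration
selects between the two major types of "*Candidatus* Accumulibacter
phosphatis", the polyphosphate-accumulating organism (PAO) that drives
enhanced biological phosphorus removal (EBPR). It is aimed at environmental
microbiologists and bioprocess engineers who run PAO enrichments (e.g. in
down-flow hanging sponge reactors with alternating 9 h aerobic / 3 h
anaerobic cycles) and want to connect three data streams:

1. **Kinetics** — a substrate-inhibition (Haldane) rate model per population,

   ν(S) = V<sub>max</sub>·S / ((K<sub>m</sub> + S)(1 + S/K<sub>i</sub>)),

   with S the phosphate concentration (mg P L⁻¹). The curve peaks at
   S = √(K<sub>m</sub>K<sub>i</sub>) and falls at high substrate, so two
   populations can swap rank: the concentration where their curves intersect
   (the *crossover*) predicts a switch in which type dominates the
   enrichment. The package computes rate curves, dominance per
   concentration, crossover roots (bracketed bisection, cross-checked
   against the closed-form quadratic), least-squares parameter recovery from
   noisy rate observations, and an exhaustive "trial-and-error" grid search
   for parameter pairs consistent with observed dominance outcomes.
2. **Reactor bookkeeping** — per-cycle phosphate uptake (aerobic), release
   (anaerobic, with carry-over correction for the liquid retained in the
   sponge), COD consumption, and specific rates normalized to sponge volume.
3. **Community structure** — *ppk1* clone libraries clustered into OTUs at
   99 % identity, clade assignment (IA–IE, IIA–II-I) against a labelled
   reference panel, and integer-percent clade/type composition tables.

A cycle-level competition simulator links (1) to enrichment outcomes, and a
fully seeded synthetic-data module generates every input the pipeline
consumes, so the whole analysis runs and is tested without any external
data.

## Worked example

With the built-in reference parameter set (Type I: V<sub>max</sub> 0.95,
K<sub>m</sub> 0.48, K<sub>i</sub> 2000; Type II: V<sub>max</sub> 1.0,
K<sub>m</sub> 0.5, K<sub>i</sub> 300 — similar affinities, slightly faster
Type II, much stronger high-phosphate inhibition of Type II):

```bash
$ paok reproduce
{"dominance": {"Run1": "Type II", "Run2": "Type II", "Run3": "Type II",
 "Run4": "Type I", "Run5": "Type I"},
 "crossovers_mg_P_per_L": [18.348438532098417]}
```

The five "runs" are enrichments held at 0.05, 0.5, 5, 50 and 500 mg P L⁻¹:
Type II is predicted dominant at and below 5 mg P L⁻¹, Type I at 50 and
above, and the two rate curves cross at ≈18.3 mg P L⁻¹ — between 5 and 50,
where enrichment experiments place the transition. (At 0.05 mg P L⁻¹ the two
rates differ by <2 %, a near-tie; the model cannot resolve a winner there.)

```bash
$ paok kinetics rate --params params.csv --grid 0.05:500:log:5
s,Type I,Type II,dominant
0.05,0.08962040099940898,0.0908939419187711,Type II
0.49999999999999994,0.4845727343674285,0.4991680532445923,Type II
4.999999999999999,0.8646267542821778,0.8941877794336812,Type II
49.99999999999999,0.9180163117003597,0.8486562942008488,Type I
500.0,0.7592710997442454,0.3746253746253746,Type I
```

Each column is a population's specific substrate-utilization rate ν (per
unit time) on the concentration grid; `dominant` applies a 10⁻³ relative tie
tolerance. Other entry points: `paok simulate` (cycle-by-cycle competition
trajectories), `paok balance` (cycle mass balances from a records CSV),
`paok community` (FASTA library + panel → composition CSV), `paok synth all`
(seeded synthetic inputs + truth JSON), `paok kinetics crossover|fit`.
Everything is importable from Python as well (`import paok`).

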