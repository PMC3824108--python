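# panbalance

Compositional diagnosis of plant ionomes: isometric log-ratio (ilr)
balances, a robust Mahalanobis imbalance index, an iterative ROC
calibration of yield cut-off and critical distance, and pan-balance
diagnostic reports — with legacy DRIS/CND comparators and a synthetic
ionome generator for testing end to end without field data.

## The problem

Foliar nutrient concentrations are compositional: strictly positive parts
of a fixed dry-mass total. Analysing them as if they were unconstrained
variables produces redundant, subcompositionally incoherent and
non-normal statistics — the classical failure mode of concentration
ranges and DRIS nutrient ratios. `panbalance` is for agronomists and
biostatisticians who want tissue-test diagnosis done in the Aitchison
geometry of the simplex, where those biases vanish.

## The model

A `D`-part composition `c` (11 nutrients + a filling value
`Fv = κ − Σ cᵢ`, with `κ = 10⁶ mg kg⁻¹` dry mass) is expressed as `D−1`
orthonormal balances via a sequential binary partition (SBP). Row *i* of
the SBP contrasts a `+1` group against a `−1` group:

    ilrᵢ = √(n₊ n₋ / (n₊ + n₋)) · ln( g(c₊) / g(c₋) )

where `g(·)` is the geometric mean and `n₊`, `n₋` the group sizes. A
specimen's nutritional imbalance is its Mahalanobis distance from the
spatial median of a reference population of balanced high-yielders,
`d = √((z − z̄)ᵀ COV⁻ (z − z̄))` with a pseudo-inverted covariance — a
quantity invariant to the choice of SBP.

Because the reference population is itself defined by the diagnosis, it is
calibrated iteratively: high-yielders seed the reference, a ROC sweep of
the distance against the low/high-yield split picks the Youden-optimal
critical distance, the true negatives (balanced high-yielders) become the
new reference, and the loop repeats until the classification is stable.
The yield cut-off is chosen by scanning candidates for maximal ROC step
AUC subject to a minimum reference size (20 by default).

## Worked example

Diagnose a specimen pushed toward relative P shortage and Mn excess —
the two misbalances typical of low-yield mango orchards — against the
packaged reference norms (`examples/03_diagnose_specimen.py`):

```text
global distance 9.15 vs critical 4.08 -> imbalanced
[Fv | S,N,P,K,Ca,Mg,B,Cu,Zn,Mn,Fe]           -7.086 in [-7.153, -7.000]
...
[P | S,N]                                     1.654 in [1.227, 1.338]  <-- above
[Mn | Cu,Zn]                                 -3.730 in [-2.554, -2.131]  <-- below
...
weighing pans (mg/kg dry mass):
                S        N      P       K       Ca      Mg     B    Cu    Zn      Mn    Fe
specimen   1587.4  15870.2  662.0  9057.6  18375.6  1917.7  27.9  16.3  12.0  1349.4  64.6
reference  1378.0  13776.2  886.6  9084.9  18431.1  1923.5  27.9  28.5  20.9   447.3  64.8
```

The global verdict (distance 9.15 > 4.08) says the ionome is imbalanced;
the per-balance verdicts localise it to the protein/energy balance
[P | S,N] (leaning to S,N: relative P shortage, 662 vs 887 mg/kg in the
pans) and to [Mn | Cu,Zn] (leaning to Mn: 1349 vs 447 mg/kg). All other
fulcrums sit inside the reference ranges.

Calibration on a synthetic 175-orchard survey
(`examples/02_simulate_and_calibrate.py`) prints the selected cut-off,
critical distance, AUCs, quadrant counts and confusion metrics; the other
examples cover balance computation from raw concentrations and the
comparison with legacy DRIS/CND/log-concentration indices.

A thin CLI wraps the same functions:

```sh
panbalance simulate --n 175 --seed 1 --out tissue.csv
panbalance calibrate --tissue tissue.csv --min-tn 20 --out norms.json
panbalance diagnose --tissue tissue.csv --norms norms.json --row 0 --out report.json
panbalance compare-methods --tissue tissue.csv --out methods.csv
```

## Layout

- `src/panbalance/` — `sbp` (partitions and bases), `transforms`
  (closure/alr/clr/ilr), `distance` (robust Mahalanobis, norms),
  `roc` (quadrants, AUCs, iterative calibration), `diagnosis`
  (pan-balance reports, group comparison), `legacy` (DRIS, CND-clr,
  log-distance), `simulate` (synthetic surveys and soil), `datasets`
  (packaged mango SBP and norms), `io`, `cli`.
- `examples/` — one narrative script per capability.
- `docs/methods.md` — models, assumptions, numerical choices, limitations.
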