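# Methods

## Data model

Concentrations are µg/g and always carry an explicit basis, wet weight
(`ww`) or dry weight (`dw`); nothing in the package ever infers a basis.
Conversion uses the tissue moisture fraction `m`:

    C_dw = C_ww / (1 − m),        C_ww = C_dw · (1 − m)

with `m = 0.832` for muscle and `m = 0.805` for liver. Gills and guts have
no reported moisture, so converting them requires the caller to supply a
fraction explicitly — the package never invents one. Overrides of the
reported fractions are accepted but logged.

The packaged fixtures are the study's summary tables: reservoir metadata
for the 11 dams and per-dam mean ± SD muscle/liver concentrations of Cd,
Cu and Zn on a dry-weight basis. Their integrity is asserted on every load
through aggregate totals (capacity 20,512 × 10⁶ m³; area 71,417 ha;
fishermen 1,928; mining sites 139). Dams 1–3 each list 55 mining sites in
a shared upstream basin; the fixture stores a `basin_group` so the 55 is
counted once — the only reading consistent with the printed total of 139.
Missing metadata (dam 4's fishermen/production) is stored as absent and
excluded from sums, and production ranges are kept verbatim as strings.

## Exposure model

Non-carcinogenic risk per metal:

    THQ = (EF · ED · FIR · C) · 10⁻³ / (RfD · BW · AT),    HI = Σ THQ

EF = 365 days/yr, ED = 70 yr, AT = 25,500 days, FIR in g/day (the 10⁻³
converts grams to kilograms), C in mg/kg ww, RfD in mg/kg BW/day, BW in
kg. The formula is the standard chronic-dietary-exposure form with the
source's constants kept verbatim — including AT = 25,500 days even though
EF·ED = 25,550; the ≈0.2 % difference is immaterial at reported precision
but the constant is not "corrected". A THQ or HI above 1 flags risk.

Carcinogenic risk uses the chronic daily intake without the EF·ED/AT
factor, per the source's definition (verified to reproduce its published
values):

    CDI = C · FIR · 10⁻³ / BW,        CR = CDI · SF

RfD: Cd 0.001, Zn 0.3 mg/kg BW/day; Pb uses the elected protective value
0.01 µg/kg BW/day (serving as both RfD and PTI); Cu has no RfD ("not
evaluated") — a THQ request for Cu returns an explicit `Unevaluated`
outcome, never 0 or NaN, and HI sums only evaluated metals, listing the
exclusions. Slope factors: Cd 1.5, Pb 0.0085 (mg/kg BW/day)⁻¹; CR for
other metals returns `Unevaluated`.

Maximum tolerable weekly intake inverts the provisional tolerable intake
(PTI): weekly allowance = `PTI_daily · 7 · BW` (µg), intake =
allowance / C (g of edible tissue). PTIs: Cd 25 µg/kg BW/month, Cu 0.5 and
Zn 0.3 mg/kg BW/day, Pb 0.01 µg/kg BW/day. The month→day normalisation
uses 30 days/month (configurable); this choice reproduces the published
adult/teen Cd intakes to 3 significant figures. C = 0 yields an explicit
"no constraint" (infinite allowance), not an exception.

Exposure concentration C is the **grand mean**: the unweighted mean of the
11 per-dam means. Specimen-level data are unavailable, so per-dam means
cannot be re-weighted by sample size; comparisons against values computed
from the (unpublished) specimen-level means therefore carry a ≤ 2–3 %
discrepancy, which the tests absorb with a ±3 % tolerance. The Pb muscle
mean is published nowhere; where a Pb concentration is needed it is
back-derived at run time from the published risk indices
(`back_derived_pb_grand_mean`), and Pb results are otherwise checked as
scaling properties (THQ ∝ FIR, ∝ 1/BW; CR/THQ = SF·RfD·AT/(EF·ED)) rather
than as point values. The three independent back-derivations (from THQ,
CR and safe-intake figures) agree within 10 %, which also documents the
internal spread of the published Pb numbers.

Consumption scenarios: both the daily and weekly printed rates derive from
the annual per-capita figure (FIR1: 2.08 kg/yr → 5.7 g/day, 39.9 g/week;
FIR2: 12.07 kg/yr → 33.1 g/day, 231.5 g/week); the scenario validator
checks both against the annual rate (note 33.1 × 7 = 231.7 ≠ 231.5 — the
weekly figure is annual-derived).

Display conventions: THQ/HI at two decimals with a "< 0.01" floor below
0.005; CR at two significant figures in scientific notation; weekly
intakes at 0.1 kg (grams below 1 kg). Raw full-precision values are always
carried alongside; properties are tested on raw values and published
comparisons on display values.

Known inconsistencies in the published table are preserved as data, not
reproduced as results: the children/FIR1 CR_Cd cell (2.9 × 10⁻⁶) conflicts
with the text's 1.9 × 10⁻⁶ (the arithmetically consistent value, which the
pipeline reproduces); the CR_Cd row prints 7 values for 8 cells; and the
children Cd safe intake (28.6 kg) is not BW-proportional to the adult
figures (which imply ≈26.7 kg; the pipeline gives 26.5 kg). The expected
table fixture carries these as annotated cells.

## Regulatory compliance

Limits are stored wet-weight with a per-limit display precision, because
the conventionally quoted dry-weight forms are rounded irregularly (EU Cd
1.8 at 2 s.f., US-FDA Pb 7.74 at 3 s.f., Australia Zn 900 at 1 s.f.).
Compliance is non-strict (value exactly at the limit passes, matching the
"did not exceed" reading), is computed on a common basis with automatic
conversion, and the verdict is invariant to the basis the concentration is
supplied in.

## Statistical battery

Concentrations are positive, skewed and non-normal, so the pipeline is
rank-based throughout; a Lilliefors normality screen is available for
reporting but never switches the analysis to parametric tests.

* **Kruskal–Wallis** (≥ 2 groups, each n ≥ 2): tie-corrected H; p from the
  χ² approximation (df = k−1), or by exhaustive enumeration of group
  relabelings when the pooled n ≤ 12 (multinomial enumeration is desk-scale
  there).
* **Mann–Whitney U** (two-sided): exact null distribution when pooled
  n ≤ 20 without ties, otherwise normal approximation with tie correction
  and continuity correction.
* **Spearman** (n ≥ 4): rho on mid-ranks; exact p by full permutation for
  n ≤ 8, t-approximation otherwise. Constant vectors raise an explicit
  `ConstantInputError`.

All three are backed by scipy where an implementation exists; the exact
Kruskal–Wallis and Spearman permutation modes are implemented here. Unit
tests check every test against an independent brute-force enumeration
oracle on small instances and verify the nominal 5 % size within two
binomial standard errors over 500 null simulations.

The **correlation census** computes Spearman correlations of each
(dam, tissue, metal) concentration with total length and weight,
requiring n ≥ 4 per cell (smaller or constant cells are skipped and
logged), and counts cells significant at α = 0.05 per test, uncorrected —
matching the source design, which applied no multiplicity correction.
Benjamini–Hochberg q-values can be attached as a clearly-labelled
extension; significance still uses raw p. Correlations are pooled across
seasons within a dam by default (the source does not state per-season
computation; a per-season option exists via filtering).

**Seasonal verdicts** run Mann–Whitney dry-vs-rainy per dam and emit
compact letter pairs: ('a','b') when the seasons differ at α = 0.05,
('a','a') otherwise, "not assessable" when a season is missing or has
n < 2.

## Synthetic generator

The generator emulates the sampling design: 11 dams × 2 seasons × 4
tissues × 4 metals, 12–15 fish per dam (default 13, alternating seasons so
each has ≥ 6). Concentrations are lognormal — chosen because the data are
positive and non-normal — moment-matched in closed form
(σ² = ln(1 + CV²), µ = ln(mean) − σ²/2) to a per-cell mean/SD table whose
muscle/liver Cd/Cu/Zn defaults are the published per-dam summaries. A
gamma noise model is available by configuration.

Synthetic defaults (labelled as such, not study values): Pb muscle mean
0.226 µg/g dw (the back-derived grand mean / 0.168) with CV 0.5; liver Pb
at half the dam's liver Cd (Pb sits below Cd in the reported liver
ordering Cu > Zn > Cd > Pb); gills and guts scaled from muscle (×1.5 and
×4, capped below liver) following the reported qualitative ordering
liver > guts > gills > muscle. Total length is normal per dam (means 20 cm
for dams 2 and 6, 32 cm for dams 10 and 11, 26 cm elsewhere — interpolated
within the reported adult ranges — SD 3 cm, truncated above the 13-cm
maturity size); weight follows the allometric W = 0.0169·TL³ with 10 %
lognormal noise. Plantable structure: a multiplicative dry-season factor
per (tissue, metal) and a log-linear TL slope per (dam, tissue, metal).
Dry-weight draws are converted to wet weight for muscle/liver (known
moisture); gills/guts stay dw.

What the generator does **not** emulate: analytical measurement error and
detection limits, within-fish correlation between tissues, and any real
spatial structure among dams. Passing recovery tests therefore shows the
pipeline is internally consistent under the assumed lognormal model, not
that the field data satisfy it. In particular the published count of 41
significant size–concentration correlations depends on the real data's
correlation structure and cannot be reproduced from summaries; the census
is instead validated on planted effects and null calibration.

`parameter_recovery` checks: oversampled (n ≈ 2000) moments within 3
standard errors of the table; a planted 2-log-SD seasonal shift with 7
fish per season detected with power ≥ 0.8 (the shift is a location shift
on the log scale, the natural effect-size scale for lognormal data); null
seasonal flag rate near α; and a planted TL slope found by the census.

## Problem sizes and numerical choices

Exhaustive oracles are enumerated only where that is cheap (≤ 10
observations: ≤ 1,680 Kruskal–Wallis partitions, ≤ C(8,4) Mann–Whitney
splits, 720 Spearman permutations); calibration runs use 500 null
replicates and 150–200 power replicates; generator moment checks pool ~2,000
specimens. Ties in permutation comparisons use an absolute 10⁻¹² guard on
the statistic. Exact-vs-approximate thresholds (KW n ≤ 12, MWU n ≤ 20,
Spearman n ≤ 8) are desk-scale tractability choices, stored as module
constants.

## Limitations

* Grand means weight each dam equally; without specimen counts per dam no
  better weighting is possible, and all published-value comparisons
  inherit the resulting ≤ 3 % offset.
* Pb point values are unrecoverable from published material; all Pb
  checks are structural (scaling laws, cross-cell consistency).
* The risk model is the deterministic chronic-exposure form: no
  Monte-Carlo uncertainty propagation, no dermal/inhalation routes, no
  metal speciation or bioaccessibility adjustment.
* Regulatory registry covers exactly the limits the analysis compares
  against; it is not a general food-standards database.
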