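# Methods

This note documents the models, estimators and design choices behind
`lineagepump`, and what the synthetic-data tests do and do not establish
about real recordings.

## Data model

An experiment is a *lineage forest*: tracked cells linked
mother → daughters. Generation 0 is the starting population (cells
present at the first frame; their birth was not observed, so intermitotic
time is undefined for them). A division produces exactly two daughters
whose birth time equals the mother's end time within one phase frame
(0.25 h). Fates are `divided`, `incomplete-division` (a division that did
not complete; no daughters exist, so such cells count as non-dividing in
mitosis analyses), `apoptosis`, and `incomplete` (lost from view or
reached the end of the recording).

Observations live on three interleaved grids matching the acquisition
protocol: phase contrast every 0.25 h (events), centroids every 2 h, and
fluorescence every 4 h (kept sparse to limit photobleaching). Shape and
fluorescence are only measured at fluorescence frames; a cell's terminal
measurement is taken at the fluorescence frame at or immediately before
its end event.

Track tables are long/tidy CSV or TSV (one row per cell-observation,
hours and micrometres, empty cells for missing values — never sentinel
numbers). Floats are written with 9 significant digits so
write → read → write is byte-identical; a spreadsheet export from a
tracking tool maps onto this schema by repeating the cell-level columns
on each of the cell's rows.

## Fluorescence accounting

* **Normalization.** All fluorescence is rescaled so that the median
  reference value of co-cultured starting-generation acceptors is exactly
  100 units. The per-cell reference is the *first* fluorescence-frame
  value (a `reference="final"` option exists). The first frame precedes
  transfer-driven drift and does not depend on how long a cell happened
  to be tracked; it does require a nonzero red-channel signal at the
  start, which real images have (background and spectral bleed-through)
  and which the simulator reproduces as a per-cell baseline fluorescence.
  Normalization is idempotent and invariant to rescaling the raw data.
* **Fa** is a single scalar per cell — the normalized value at its final
  fluorescence frame — not a time series; phenotypes used in correlations
  are measured at that same frame, giving the one-row-per-cell analysis
  table.
* **Fmc** adds exactly half of the immediate mother's Fa (equal split at
  division is assumed); compensation deliberately stops at one
  generation, because measurement variance grows faster than the signal
  recovered by deeper (grandmother+) corrections. The accounting identity
  `(Fmc₁ − Fa₁) + (Fmc₂ − Fa₂) = Fa(mother)` holds exactly for every
  division.
* **Rates** divide Fa and Fmc by the cell's observation span in days,
  making dividing and non-dividing cells comparable despite asynchronous
  mitosis and very different tracking windows.

## Morphometrics

Circularity is `4πA/P²`. From rasters, area is the foreground pixel
count × pixel area, and the perimeter is the length of the
marching-squares iso-0.5 contour after *staircase relaxation*: vertices
whose neighbouring turns alternate in sign (the signature of
digitization zigzag) are iteratively moved to their neighbours' midpoint,
while same-sign corners are left in place. This keeps a rendered
rectangle at its exact contour length while a digital disk of radius 50
px converges to `2πr` within ~0.5%; plain contour length would
overestimate smooth perimeters by ~6% and systematically deflate
circularity. Discrete estimates slightly above 1 (tiny masks) are
clipped to 1 with a warning. No background subtraction is applied to
masked fluorescence sums by default; a constant-offset option exists for
synthetic tests.

## Migration velocity

Velocity is total path length divided by total tracked time (µm/day),
over centroid samples thinned to at least 2 h apart — below that,
displacements are comparable to stage-relocation error and denser
sampling would inflate path length with noise. The grid anchors at each
cell's own first observation (daughters are born off any global grid).
The final observed point is always kept; if it falls less than 2 h after
the last retained grid point, that grid point is dropped so the final
interval exceeds 2 h. Tracks spanning under 2 h in total get a velocity
over their actual span plus a `short_track` flag (excluded from
correlation tables by default, configurable) rather than a silently
invented value.

## Association statistics

* **Kendall's tau-b** is used throughout (measurement rounding produces
  ties; tau-b is the standard tie-corrected variant). The two-sided
  p-value uses the normal approximation with the tie-adjusted variance of
  the S statistic and a ±1 continuity correction. Constant inputs yield
  an undefined-correlation marker (`nan`), logged and skipped.
* Correlations are computed per generation, for cumulative generation
  groups (0+1, 0+1+2, …) and for all generations together; groupings
  with n < 5 are flagged `low_n` but never dropped.
* **Sister-pair differences**: within each pair the sisters are ordered
  so ΔFa ≥ 0 (ties broken lexicographically by cell id), Δphenotype keeps
  its sign relative to that ordering, and tau is computed over pairs
  (≥ 3 pairs required). The ordering is a convention; swapping both
  members of every pair leaves tau unchanged.
* **Mitosis comparison**: dividing vs non-dividing cells are compared on
  `Fa/day` and `Fmc/day` medians (Mann–Whitney U, two-sided), yielding
  `pFa` and `pFmc` (dividing median / non-dividing median).
  Non-dividing cells observed for less than the experiment's median
  intermitotic time are excluded — they had insufficient time to
  demonstrate a division — and late generations can be excluded
  explicitly per experiment.
* Cross-experiment summaries use the one-sample Wilcoxon test (tau vs 0),
  the paired Wilcoxon signed-rank test (Fa vs Fmc across experiments)
  and Mann–Whitney for unpaired contrasts; exact distributions where n
  and ties permit. Significance is 0.05 two-sided; no multiple-testing
  correction (matching the analysis design this mirrors).

## Persistence index

For each experiment, the (tau_Fa, tau_Fmc) pair is scored +1 if the Fmc
correlation is stronger, 0 if equal, −1 if weaker; when tau_Fa is
negative *both* values are sign-flipped first, so strength is compared in
the direction set by Fa. The flip triggers on tau_Fa alone (not on
either value, and not per table): this is the only reading consistent
with all of the published index values at once, including the experiment
with a weak positive Fa tau and stronger positive Fmc tau (scores +1
unflipped) and the one with a small positive Fa tau against a small
negative Fmc tau (scores −1 unflipped). Scores average to a final score
in [−1, 1]; index = (1 + score)/2. When scoring *printed* tables, tau
equality is judged at the 2-decimal reporting precision; full-precision
pipeline values use exact equality (spurious ties are measure-zero
there). For mitosis, +1 iff pFmc > pFa, ties −1. The index measures the
proportion of experiments showing persistence, not its strength, and is
always reported with its score vector so that claim is auditable.

## Synthetic co-cultures

The simulator generates what the pipeline consumes — including writing
and re-reading the track-table schema, so file I/O is exercised end to
end. Per acceptor cell:

* label content follows a gamma process (shape 2 per 4-h frame) with
  per-cell propensity drawn log-normal (median 20 raw units/day, log-sd
  0.8); sisters share a correlated random effect (ρ = 0.7) on
  log-propensity, encoding sister similarity;
* every cell carries a baseline red-channel signal (log-normal, median
  50 raw units) representing bleed-through/background — this anchors the
  first-frame normalization and makes raw scales arbitrary, as in real
  imaging;
* intermitotic times are log-normal (median 76 h, log-sd 0.35), shortened
  proportionally by relative uptake propensity (coefficient 0.5) — a
  minimal monotone coupling standing in for an unknown mechanism;
  apoptosis (0.02/day) and loss-from-view (0.15/day) hazards produce the
  observed fate mix; divisions split content exactly in half by default
  (asymmetric splits are configurable to probe robustness, the
  *accounting* always adds exactly half);
* each phenotype is baseline ± coefficient × driver + Gaussian noise,
  where the driver is the current label content (`reset`) or the
  mother's final driver plus own uptake (`inherit`). The `inherit`
  mechanism is precisely the state of affairs Fmc compensation is meant
  to detect. Defaults: area reset, circularity inherit, velocity reset.

Defaults were calibrated once, by Monte-Carlo at fixed seeds, so the
emergent data land on the scales the real system shows — all-generation
area tau ≈ 0.5, uptake rates of tens of normalized units/day, tracked ≈
3–3.5 × starting cells over 4 days, generations 0–3 with a rare fourth —
and then frozen. The seven-experiment batch uses the study design's
durations (4, 2, 3.6, 4, 4, 5, 4 days) with 100 starting acceptors and
75 donors per experiment.

What passing the synthetic recovery tests shows: the full pipeline
(normalization → accounting → velocity → correlation → scoring) detects
a known inheritance mechanism and a known division-uptake link at
realistic noise, sample sizes and observation grids, and its indices hit
the correct extreme bands (≤ 0.3 reset, ≥ 0.7 inherit) in ≥ 90% of 20
replicate batches. What it does not show: anything about geometry-driven
transfer (contact networks are not modelled — transfer is
propensity-driven), segmentation error structure, crowding effects at
late time points, or photobleaching; real-data indices near the middle
of [0, 1] remain genuinely ambiguous, as the score-vector reporting makes
visible.

## Numerical and engineering choices

* All randomness flows from a single integer seed; each simulated cell
  draws from a sub-stream keyed by (seed, cell id), so output is
  independent of processing order and byte-identical across runs.
* Event times are quantized to the 0.25-h phase grid; observation series
  are strictly increasing by construction and validated on read.
* Division exactly at the recording end still counts as a division; the
  daughters appear with a single observation and fate `incomplete`.
* A population guard rejects configurations whose expected cell count
  exceeds 10⁵ before running.
* Reports round taus and indices to 2 decimals and medians to 1 decimal
  for display; machine-readable outputs keep full precision and contain
  no timestamps, so identical runs produce identical bytes.

## Known limitations

* Normalization via first-frame baselines ties the unit scale to the
  background level; comparisons across experiments assume similar
  imaging conditions (true of the emulated design, not of arbitrary
  data).
* The tau-b p-value is asymptotic; for very small groupings (n < 5,
  flagged) it is indicative only.
* The perimeter estimator is tuned for convex-ish cell profiles;
  filament-rich shapes will still be under-resolved at 4-h sampling.
* `incomplete-division` cells are classified as non-dividing in mitosis
  analyses (they leave no daughters to inherit anything); the
  classification is overridable via the feature table's `fate` column.
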