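# Methods

## The scoring model

A kinome screen is a compound × kinase matrix of percent inhibition in
[0, 100]; missing cells mean the pair was never profiled and are excluded
from every computation (no imputation). For a chosen target set
$T$ (1–10 kinases) and one compound row, the selectivity score is

$$S = G - P_b - P_n$$

with $G$ the geometric mean of the measured target inhibitions, $P_b$ the
mean inhibition over the $M$ measured off-target kinases, and
$P_n = \tfrac1M \sum_j I_j^2/(I_j + G)$.

Assumptions and rationale:

* **Units.** All three components are in percent-inhibition units, so $S$
  is interpretable as "on-target percent inhibition net of off-target
  cost"; $S \le G \le 100$, with $S = 100$ only for a perfectly potent,
  perfectly clean compound, and $S \ge -200$ in the worst case.
* **Geometric mean for multi-target sets.** A compound intended to hit a
  kinase group should hit *all* of it: the geometric mean collapses to 0 if
  any chosen target is untouched, where an arithmetic mean would reward
  lopsided potency.
* **Two penalties for two failure modes.** $P_b$ grows with panel-wide
  background activity (a compound at 10% against everything pays 10 points
  regardless of panel size). $P_n$ isolates off-targets *near or above* the
  target's own potency through the weight $I_j/(I_j+G)$, which rises
  smoothly from 0 (when $I_j \ll G$) to 1 (when $I_j \gg G$). The weight is
  continuous and threshold-free — no cutoffs, no binning — which is the
  design constraint that distinguishes this score from S(x)-style counts.
  An off-target with $I_j = 0$ contributes 0 by convention even when
  $G = 0$ (the 0/0 case), so a dead compound on a dead panel scores 0, not
  NaN.
* **Single dose, single screen.** Each matrix entry is one compound at one
  dose; the same chemical at another dose is a separate row. Screens are
  never merged: panels, conditions and doses differ between vendors, so
  scores are comparable only within one matrix.

**Significant off-targets** are the measured off-target kinases with
$I_j \ge 0.5\,G$ ("at least half" read inclusively); when $G = 0$, any
off-target with $I_j > 0$ is reported. They are listed with the ratio
$I_j/G$ (undefined when $G = 0$) in descending order of inhibition.

**Ranking.** Compounds sort by descending $S$, ties by descending $G$, then
lexicographic compound id (an arbitrary but deterministic tie-break).
Compounds with no measured target are flagged `defined = False` and listed
last rather than dropped, so the ranked table always covers the whole
screen.

## Input handling

* Files are wide delimited matrices (comma or tab, sniffed from the header
  or forced); the transpose is accepted via an orientation flag. Tokens
  `""`, `NA`, `NaN`, `ND` parse as missing by default (configurable — the
  public screens use different dialects); any other non-numeric cell is an
  error naming the cell.
* Percent-of-control data (residual activity, 0 = full inhibition) is
  converted on ingest as $100 - \text{PoC}$ and clamped to [0, 100].
  Clamping activation (PoC > 100) to 0 inhibition rather than a negative
  value keeps the geometric mean defined and reads naturally as "does not
  inhibit".
* Kinase names are standardized through a user-supplied alias table
  (case- and whitespace-insensitive lookup, idempotent by construction).
  No default table ships — panels disagree on naming and no canonical
  mapping is bundled — so unknown labels pass through with a logged
  warning. If two columns standardize to the same name, the caller chooses
  between rejection and per-compound averaging of non-missing cells.
* Dataset statistics report entries (rows), distinct base compounds (via an
  optional entry → compound dose map), kinases, and pairwise coverage
  $= 100 \cdot \text{measured cells} / (\text{rows} \times \text{columns})$.

## Comparison metrics

The population Gini coefficient
$\sum_{ij} |x_i - x_j| / (2 n^2 \bar x)$ is computed over a compound's full
measured profile (targets included), without the $n/(n-1)$ sample
correction; published selectivity uses vary on both points, so the output
column is labelled `gini_population`. The all-zero profile returns 0 by
convention. The implementation uses the sorted-rank identity
($O(n \log n)$) and is tested against the naive double loop to $10^{-12}$.
$S(x)$ is the fraction of measured kinases with inhibition $\ge x$, with
$x \in (0, 100]$. Both are offered as optional extra columns, not as part
of the score.

## Synthetic screens

The generator emulates the compound archetypes that motivate the two
penalties, with defaults chosen once for archetype contrast and kept fixed:

| archetype | on-target | off-targets |
|---|---|---|
| clean_selective | 90 | all at baseline 2 |
| pan_weak | 90 | all at level 10 |
| few_strong | 90 | `count` = 5 at magnitude 90, rest at 2 |
| random | — | uniform(0, 100) everywhere |

The panel is the target names plus numbered filler kinases (default 51
total, so 50 off-target slots). Optional additive Gaussian noise on the
percent scale is truncated to [0, 100] — the simplest noise model
consistent with bounded percent data — and cells are then masked missing
independently at a configurable rate. Generation is fully deterministic
given the spec (one `numpy` generator seeded from the spec's seed drives
strong-off-target placement, noise and masking in a fixed order), so
fixtures are bitwise-reproducible.

`archetype_expectations` evaluates the noiseless scores in closed form from
the archetype parameters alone and returns the expected ranking; the test
suite asserts that ranking the generated matrix reproduces it exactly. The
default trio orders clean_selective ($S \approx 87.96$) > pan_weak
($S = 79$) > few_strong ($S \approx 74.66$) on the 51-kinase panel.

What the synthetic screens do *not* emulate: kinase family structure and
the correlated off-target patterns it causes, realistic compound chemotype
clusters, dose–response relationships, and assay-specific error models.
Passing the archetype tests therefore shows the score discriminates the
intended failure modes, not that it has been validated against any real
screen.

## Numerical choices and degenerate inputs

* The geometric mean is computed in log space for multiple targets; a
  single target returns its value exactly and any zero target short-circuits
  to 0 (no `log(0)`).
* An empty off-target panel ($M = 0$, possible only on a fully-missing row
  of a 2-kinase matrix) yields $P_b = P_n = 0$ with a logged warning rather
  than an error.
* Matrix values are validated to [0, 100]; infinities and out-of-range
  values are rejected at construction, so scoring never sees them.
* The 10-target cap mirrors the intended interactive use and is a UI
  convention, not a mathematical limit; the CLI exposes
  `--max-targets-override` to lift it.

## Reporting

The heatmap shows the first page (default 10) of the ranked table, rows in
table order, columns the full panel, colored black (0) → yellow (50) →
red (100) with missing cells grey; yellow's anchor at the midpoint is a
configurable reading of "moderate inhibition". Output formats are static
raster/vector images (png, svg, pdf); interactive browser-style exploration
(mouse-over, zoom) is out of scope. Every figure is written
together with a CSV twin of the exact displayed submatrix, untransformed,
so the visual always has a downloadable numeric counterpart.

## Known limitations

Scores are single-dose, in-vitro quantities: they do not model cellular
context, compound availability or metabolism, and are guidelines for
inhibitor choice rather than predictions of in-vivo selectivity. Scores
from different screens are not comparable. The Gini and S(x) comparators
are implemented in one commonly used variant each; other published variants
differ by normalization and threshold choice.
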