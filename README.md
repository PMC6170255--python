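# kinoselect

Selectivity scoring and ranking for kinase inhibitor screens.

Small-molecule kinase inhibitors are notoriously promiscuous: because the
>500 human kinases share a highly conserved ATP-binding fold, almost every
"selective" compound also inhibits off-target kinases. Large public kinome
profiling screens quantify this as a compound × kinase matrix of percent
inhibition, but choosing the *most selective* compound for a given target
from such a matrix is not obvious — a compound that weakly touches the whole
panel and a compound with five off-targets as strong as the target both look
bad in different ways, and classic one-number summaries (Gini coefficient,
threshold-based S(x) scores) conflate or miss these cases.

This package implements a composite selectivity score for a user-chosen set
of up to 10 on-target kinases. For a compound with measured percent
inhibitions $I_t$ on the targets and $I_j$ on the $M$ profiled off-target
kinases:

$$G = \Big(\prod_t I_t\Big)^{1/|T|}, \qquad
  P_b = \frac{1}{M}\sum_j I_j, \qquad
  P_n = \frac{1}{M}\sum_j \frac{I_j^2}{I_j + G}, \qquad
  S = G - P_b - P_n .$$

* **G** (inhibition score) rewards on-target potency — a single target's
  inhibition, or the geometric mean over several targets.
* **P_b** (broad penalty) charges for panel-wide weak inhibition.
* **P_n** (near penalty) charges specifically for off-targets *comparable to
  or stronger than* the target, through the smooth, threshold-free weight
  $I_j/(I_j+G)$.
* **S** ranks compounds; *significant off-targets* are kinases inhibited at
  least half as much as $G$.

Only profiled (non-missing) cells enter any sum; percent-of-control exports
are converted to percent inhibition ($100 - \text{PoC}$, clamped to
$[0,100]$) on ingest. Comparison metrics (population Gini coefficient, S(x)
threshold scores) and a synthetic-screen generator for the motivating
compound archetypes are included.

## Worked example

Generate a synthetic 3-compound, 51-kinase screen (one clean-selective, one
pan-weak, one few-strong archetype, all with 90% on-target inhibition of
AKT1) and rank it:

```bash
kinoselect simulate --seed 5 --targets AKT1 --out screen.csv
kinoselect score --matrix screen.csv --targets AKT1 --with-alt-metrics --out-dir results
head -4 results/ranked_table.csv
```

```
compound_id,inhibition_score,penalty_broad,penalty_near,selectivity_score,n_targets_measured,n_offtargets_measured,n_significant_offtargets,defined,gini_population,s_score@50
clean_selective,90,2,0.0434783,87.9565,1,50,0,True,0.454076,0.0196078
pan_weak,90,10,1,79,1,50,0,True,0.132935,0.0196078
few_strong,90,10.8,4.53913,74.6609,1,50,5,True,0.739496,0.117647
```

All three compounds hit AKT1 equally ($G = 90$), so the ranking is decided
entirely by the off-target penalties. The clean compound keeps almost all of
its on-target score ($S = 88.0$). The pan-weak compound (every off-target at
10%) loses 10 points of broad penalty but only 1 point of near penalty
($S = 79$). The few-strong compound (five off-targets at 90%, the rest near
zero) is hit hardest by the near penalty and ranks last ($S = 74.7$), with
its 5 significant off-targets counted in the table — exactly the ordering a
pharmacologist would want. Note how the comparison columns can mislead:
S(50) cannot distinguish the clean compound from the pan-weak one (both
0.0196), and the Gini coefficient scores the dangerous few-strong compound
as the *most* "selective" profile (0.739).

`kinoselect offtargets --compound few_strong ...` lists the significant
off-targets with their ratio to the target score;
`kinoselect coverage --matrix screen.csv` prints dataset statistics
(entries, compounds, kinases, pairwise coverage);
`kinoselect heatmap ... --format svg` renders the top-ranked compounds'
inhibition profiles black→yellow→red (missing cells grey) and writes the
exact displayed submatrix alongside as CSV.

Real screens are consumed as wide CSV/TSV exports (rows = compound or
compound+dose entries, columns = kinases); a two-column alias file
standardizes kinase names across vendors, and each screen is scored on its
own (screens use different conditions, panels and doses, so their scores are
not merged or compared).

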