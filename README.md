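# neosep

Analysis pipeline for an immune signature of sepsis in very preterm babies
(<32 weeks gestation). Late-onset sepsis in this population is common,
hard to diagnose — no single test, including C-reactive protein (CRP),
reliably rules it out when a baby first shows clinical signs — and drives
heavy empirical antibiotic use. `neosep` implements, as a tested library
plus a set of narrative analysis drivers, the chain of analyses such a
study runs over longitudinal per-sample immune data:

1. **Clinical classification** (`neosep.classify`) — every blood draw is
   assigned to one of five categories from contemporaneous clinical and
   microbiological metadata: MCS (microbiologically confirmed sepsis),
   ClinSep (culture-negative clinical sepsis: ≥3 criteria for invasive
   infection and a ≥5-day antibiotic course), NSC (suspected, ruled out:
   antibiotics stopped within 72 h), Stable, and NEC (Bell stage II/III
   necrotising enterocolitis). Coagulase-negative staphylococci need
   supporting clinical evidence to count as true sepsis. MCS+ClinSep form
   the composite *Sepsis* group and NSC+Stable the composite *No-Sepsis*
   group; repeat samples within one sepsis episode are deduplicated to the
   first; flow parameters with <30 parent-gate events are blanked.
2. **Biomarker screening** (`neosep.screen`) — a volcano screen of ~105
   flow-derived immune parameters, Sepsis vs No-Sepsis: effect size
   log2(median_S / median_NS), two-tailed Mann–Whitney p, Benjamini–
   Hochberg FDR, significance at |log2FC| > 0.6 and BH p < 0.01. Plus
   15-day age-bracket comparisons of developmental trends, age-stratified
   re-screens (days 1–30 vs >30), CRP-rise episode stratification
   (>10 mg/L), Kruskal–Wallis/Dunn plasma comparisons, and linear
   mixed-model confounder adjustment (random intercept per baby, REML).
3. **Temporal paired analysis** (`neosep.pairing`) — pre/sepsis/post
   triplets by temporal proximity (~1 week each side) and exact Wilcoxon
   matched-pairs tests, calling traits "sepsis-transient" when they fall
   acutely and rebound.
4. **Rule-out diagnostics** (`neosep.diagnostic`) — within 48 h of a blood
   culture for suspected sepsis, a combined test: negative iff
   CRP ≤ 10 mg/L **and** plasma amphiregulin ≤ 38.7 pg/mL (the
   amphiregulin cutoff from the maximal Youden index, J = sens + spec − 1,
   on the ROC curve), positive otherwise. Confusion metrics are exact
   rationals; NPV/PPV re-project to an external prevalence by Bayes' rule:
   NPV′ = spec·(1−π) / (spec·(1−π) + (1−sens)·π).
5. **DEG set post-processing** (`neosep.degsets`) — fixed haemoglobin-gene
   filter, thresholding (BH p < 0.05, |log2FC| > 0.95), top-N selection,
   and multi-condition Venn-region partition with direction concordance.

Because the study's per-sample clinical tables are not deposited, the
pipeline is exercised end to end on a **synthetic cohort generator**
(`neosep.simulate`): 19 babies sampled roughly weekly (median ~9
draws/baby), ten signature parameters suppressed 2-fold at sepsis onset
with a ~7-day rebound, amphiregulin baseline calibrated to median 19
(IQR 14–27.9) pg/mL with sepsis-contemporaneous spikes, and CRP remaining
low (≤10 mg/L) in a quarter of sepsis episodes. Every cohort ships a
ground-truth sidecar, so recovery is checkable.

## Worked example

```bash
python analysis/01_simulate_cohort.py --seed 7 --out results
python analysis/02_classify_samples.py --out results
python analysis/03_volcano_screen.py   --out results
python analysis/04_temporal_rebound.py --out results
python analysis/05_diagnostic_rule_out.py --out results
python analysis/06_deg_overlap.py --seed 7 --out results
```

At seed 7 this prints (abridged):

```
cohort: 172 samples from 19 babies (median 10/baby)
composite groups: Sepsis=26, NoSepsis=113, NEC excluded=1 (32 repeat-episode samples removed)
significant parameters (10/105): ['CD4_T_cells_per_uL', ..., 'pDC_freq_pct']
planted signature recovered exactly: True
age brackets with significant neighbour differences: [(1, 2)]
matched 26 episodes; median gap pre=5 d, post=9 d
sepsis-transient parameters: 10/10
amphiregulin threshold at maximal Youden J=0.94: 39.7 pg/mL
combined rule: sens=1.0 spec=0.94 ppv=0.96 npv=1.0; NPV at prior 0.22 = 1.0
```

Reading this: the volcano screen recovers exactly the ten planted
signature traits (T-cell lymphopenia, reduced dendritic-cell frequencies
and counts, diminished HLA-DR on DC and monocytes) and nothing else; the
developmental ramp is detectable only across the first 15-day age-bracket
transition; every signature trait is called sepsis-transient (falls
acutely, rebounds within a week); and on the 48-h suspected-sepsis window
set the combined CRP/amphiregulin rule dominates either analyte alone as a
rule-out test, with a data-derived amphiregulin threshold landing near
40 pg/mL. The same pipeline is available as a CLI
(`neosep simulate|classify|screen|pair|diagnose|degsets|run`).

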