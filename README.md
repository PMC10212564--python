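# cmlpipe

A feedback/feedforward branched-lineage model of normal and chronic
myeloid leukemia (CML) hematopoiesis, implemented as a tested analysis
pipeline:

1. **Design-space model selection** (`cmlpipe.design_space`) — enumerate
   all 59,049 candidate feedback architectures (each of p0, p1, q1,
   eta1, eta2 unregulated or regulated ± by one of the four cell
   types), decompose each into dominant power-law subsystems
   (S-systems), and keep only architectures with a robust,
   self-consistent, stable, establishable equilibrium.  The screening
   returns exactly four classes, all requiring negative regulation of
   stem-cell self-renewal.
2. **Virtual cohorts** (`cmlpipe.cohort`) — uniform/log-uniform
   parameter sampling with steady-state acceptance (`1e4 < HSC < MPP`,
   MPP anchored near `1e5`, `MPP < TDl < TDm`), the feedforward filter
   (`gamma5 > 0.01`), and clinic-style transcript sampling.
3. **Perturbation experiments** (`cmlpipe.perturb`) — compartment
   depletions and stem/progenitor transplants with the
   transplant-consistency cohort filter.
4. **CML and therapy** (`cmlpipe.leukemia`, `cmlpipe.therapy`) — dual
   normal/leukemic lineages coupled through total-population feedback;
   TKI therapy as proliferation-dependent leukemic kill plus stem
   division slowdown; combination differentiation therapy via a
   constant addition to both stem self-renewal denominators; BCR-ABL1
   transcripts as `(TDlL+TDmL)/(TDlL+TDmL+2(TDl+TDm))`.
5. **Prognostics** (`cmlpipe.prognostics`) — the relative-change
   statistic `PF(t1,t2) = (B(t2)-B(t1))/B(t2)`, transcript halving
   time, early-molecular-response thresholds, and ROC evaluation with
   Youden-optimal thresholds.

## Command line

```sh
cmlpipe dsa enumerate --constrain-p0-negative
cmlpipe dsa filter --out verdicts.csv          # full 59,049 screening
cmlpipe cohort sample --n 1000000 --seed 1 --out cohort.csv
cmlpipe cohort filter-ff cohort.csv --out ff.csv
cmlpipe transplant ff.csv --out tx.csv
cmlpipe therapy run tx.csv --start-month 5 --delta 0.24
cmlpipe therapy sweep-delta tx.csv --grid 0:0.5:0.06
cmlpipe prognose score transcripts.csv --stat pf --window 3 6
cmlpipe all --seed 1 --n 200000 --outdir out/   # end-to-end pipeline
```

Real patient transcript CSVs (columns `patient_id, month, bcr_abl_pct`)
can be scored with `cmlpipe prognose score|roc`.

## Model summary

State `[S, P, TDl, TDm]` (stem, progenitor, terminal lymphoid/myeloid):

```
S'   = (2 p0 - 1) eta1 S
P'   = 2 (1 - p0) eta1 S + (2 p1 - 1) eta2 P
TDl' = 2 q1 eta2 P - d_l TDl
TDm' = 2 (1 - p1 - q1) eta2 P - d_m TDm
```

with Hill-type regulation `p0 = p0_max/(1 + gamma1 P + Delta)`,
`p1 = p1_max/(1 + gamma3 TDm)`, `q1 = q1_max/(1 + gamma4 TDm)`,
`eta1 = eta1_max/(1 + gamma2 S)`, `eta2 = eta2_max/(1 + gamma5 S)`.
The leukemic lineage duplicates the structure with its own parameters
(by default only a weaker `gamma1`), regulated by compartment totals.
Times are in days; a reporting month is 30 days.
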