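# gradenet

Grade-specific transcription-factor (TF) regulatory networks: construction,
motif structure, hierarchy, feedforward loops and survival screening.

## The problem

Cross-regulation among TFs forms a core subnetwork that shifts as a tumour
progresses. Given (a) a *binding prior* — candidate regulator → target edges
from TF-binding-motif occurrences in target promoters — and (b) expression
of the same TFs in patient cohorts stratified by tumour grade, the pipeline
asks: which prior edges are functionally active in each grade, how is each
grade's network organized, and do any of its circuit motifs predict patient
survival?

It is written for computational biologists who want each stage as a plain,
tested Python function: network construction from replicated coexpression,
an exact directed triad census with a switching-randomization null, a
hierarchy-height layering of regulators, feedforward-loop (FFL) enumeration,
and a Cox/log-rank biomarker screen. A synthetic-data generator with planted
ground truth makes every stage verifiable without access to patient data.

## The model

**Grade networks.** A prior edge u → v enters the grade-g network iff the
two TFs are co-expressed — |r| > 0.5 with p < 0.01 (Spearman by default,
t-approximation with n − 2 df) — in at least two independent datasets of
that grade, with a consistent correlation sign. Direction is inherited from
the prior; self-loops are removed.

**Triad significance profiles.** All 13 isomorphism classes of weakly
connected three-node digraphs are enumerated from the 64 labeled digraphs;
the census counts induced subgraphs per unordered triple. For each class,
Z = (N_real − ⟨N_rand⟩) / σ_rand over an ensemble of degree-preserving
edge-switching randomizations (in/out degrees preserved exactly, mutual
dyads preserved by default); the Z vector normalized to unit length is the
network's triad significance profile (TSP). Classes with normalized Z > 0
are enriched, < 0 depleted.

**Hierarchy.** Each TF with out-degree O and in-degree I gets a hierarchy
height h = (O − I)/(O + I) ∈ [−1, 1]; h > 1/3 ⇒ master regulator,
h < −1/3 ⇒ low-level regulator, otherwise intermediate.

**FFLs and survival.** An FFL is the triad top → middle, top → bottom,
middle → bottom (induced match by default). For each candidate FFL, the
risk score of patient j is Σᵢ βᵢ·xᵢⱼ where βᵢ are univariate Cox
coefficients of the three TFs fit on the training half (Breslow ties, Wald
p); patients are dichotomized at the training-median score, groups are
compared by the log-rank test, and training coefficients and threshold are
applied unchanged to the test half. FFLs with p < 0.05 in both halves are
prognostic; they are validated in an independent cohort by k-means (k = 2)
clustering of the three TFs' expression, and risk groups are tested against
IDH mutation status by Fisher's exact test.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data with planted truth (500 TFs, grades II/III/IV, two datasets of 60
samples per grade, 50 planted coexpressed edges plus 21 planted FFLs per
grade, survival in the last grade driven by one planted FFL):

```bash
python analysis/01_simulate.py --seed 0
python analysis/02_build_networks.py
python analysis/03_topology.py
python analysis/04_motifs.py
python analysis/05_hierarchy.py
python analysis/06_ffls.py
python analysis/07_survival_screen.py
```

Selected output (seed 0):

```
grade II: 113 regulations among 163 TFs (0.15% of the prior activated); recall 1.000, precision 1.000 vs planted truth
20.22% of the 277 union edges occur in >=2 grades; 7 hub TFs shared by all three grades
TSP cosine similarity grade II vs IV: 0.993
TSP cosine grade IV vs binding prior alone: -0.032 (coexpression filtering, not the prior, shapes the profile)
grade IV: 43.6% master, 12.9% intermediate, 43.6% low-level (163 TFs assigned)
1.85% of all observed FFL triples are common to the three grades
1 of 21 grade-IV FFLs prognostic in D1 (log-rank p < 0.05 in train and test)
  TF272-TF465-TF376 (planted): p_train = 8.52e-06, p_test = 2.60e-08, betas = (1.06, 1.06, 1.09)
    k-means validation in D2: p = 3.64e-10; IDH association (Fisher): p = 0.79
bidirectional protocol: 1 FFLs D1->D2, 1 D2->D1, 1 final
```

Reading it: the coexpression filter recovers exactly the planted active
edges (recall = precision = 1); the three grade networks share a near-
identical motif profile (TSP cosine 0.99) that the raw binding prior does
not produce; networks are highly grade-specific at the edge (≈20% shared)
and FFL-triple (≈2% shared) level while the architecture is conserved; and
the survival screen retains exactly the planted prognostic FFL, confirms it
in the independent dataset in both directions, and finds no IDH association
(none was planted).

A `gradenet` CLI exposes the same stages
(`gradenet simulate|build|topology|motifs|hierarchy|ffl|screen|run`).

## Layout

- `src/gradenet/` — the library: `synth` (generator + planted truth),
  `preprocess`, `netbuild`, `topology`, `motifs`, `hierarchy`, `ffl`,
  `survival`, `io`, `pipeline`, `cli`
- `analysis/` — numbered narrative drivers writing under `results/`
- `tests/` — unit, property and end-to-end acceptance tests
- `docs/methods.md` — modelling choices, parameters and limitations
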