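# pdac-clonevo

Quantitative machinery for matched primary/metastatic pancreatic ductal
adenocarcinoma (PDAC) scRNA-seq cohorts — built for computational biologists
who want the statistics of such a study as a tested, reusable library rather
than a one-off notebook:

* **Malignant subtype decomposition** by consensus non-negative matrix
  factorization: expression of malignant ductal cells factored as
  `X ≈ W H` with non-negative usages `W` (cells × K) and spectra `H`
  (K × genes); K chosen by restart stability (mean silhouette of clustered
  components) against reconstruction error.
* **Expression-inferred CNV**: per-cell copy-number proxies from
  log2-normalized expression centered on a normal reference, clipped and
  smoothed along the genome (101-gene windows per chromosome), with
  malignant-cell calling, per-gene dosage scores and sample-level event
  calling with group frequency tests.
* **Clonal dynamics**: clonal homogeneity as the mean pairwise Pearson
  correlation of malignant-cell CNV profiles per sample; Ward clustering of
  clones; rooted graph pseudotime; dosage-vs-pseudotime trends with
  top-decile origin composition.
* **Clinical outcomes**: Kaplan–Meier, log-rank, Cox proportional hazards
  (Newton–Raphson on the Breslow partial likelihood), the
  lowest-significant-cutoff scan over basal-like proportions
  (range 10–35%, both groups ≥10% of patients), and treatment-response
  association (RECIST best % change).
* **Composition & crosstalk**: NNLS deconvolution of bulk/spot mixtures
  into subtype fractions, subtype↔immune proportion correlations, and
  permutation-scored ligand–receptor interactions per origin stratum.
* **A synthetic cohort generator** that plants all of the above signals
  (programs, origin-structured clones, a survival threshold, immune
  couplings, a metastasis-restricted ligand–receptor pair) with exact
  ground truth, so every statistic is validated by recovery tests.

Origin labels follow the matched-cohort design: `Pn` adjacent normal
pancreas, `Pm0` primary tumour without metastasis, `Pm1` primary with
metastasis, `Lm` liver metastasis.

## Worked example

Run the full pipeline on a simulated cohort (31 samples, 21 patients,
800 genes — desk scale):

```python
from pdac_clonevo import RunConfig, run_pipeline

cfg = RunConfig(
    outdir="run_out", seed=1,
    simulation=dict(
        n_genes=800, n_cells_per_sample=60,
        samples_per_origin={"Pn": 3, "Pm0": 6, "Pm1": 15, "Lm": 7},
        n_signature_genes_per_program=30),
    n_top_genes=600, k_range=(2, 6), n_restarts=10, window=51)
report = run_pipeline(cfg)
for stage, r in report.stages.items():
    print(stage, r["status"])
```

Key numbers from `run_out/report.json` for seed 1 (your machine will
reproduce them exactly — the pipeline is bit-deterministic given config and
seed):

```
subtypes   selected_K = 4        stability: {2: 0.45, 3: 0.72, 4: 0.95, 5: 0.66, 6: 0.57}
cnv        845 cells called malignant, 141 sample-level events
clonal     homogeneity by origin: Pm0 0.51 < Pm1 0.59 < Lm 0.85
crosstalk  basal↔cytotoxic r = -0.79, basal↔Treg r = +0.83
           planted Lm-only ligand–receptor pair: present in Lm only
           pseudobulk deconvolution MAE = 0.018
survival   chosen cutoff 0.17 (planted 0.22), Cox HR(basal) = 49.8
```

Reading these: the consensus scan recovers the four planted programs
(stability peaks sharply at K = 4); clonal homogeneity increases from
non-metastatic primaries to liver metastases, mirroring the planted clone
counts 5 > 3 > 1; the immune couplings and the Lm-restricted interaction
are recovered with the planted signs. The cutoff scan illustrates a real
property of lowest-significant-cutoff procedures: with a strong hazard
ratio, cutoffs *below* the true threshold still split survival and the
chosen cutoff lands low — see `docs/methods.md` (Known limitations) for
the analysis.

The same stages are exposed on the command line:

```bash
pdac-clonevo simulate --seed 1 --out cohort_dir
pdac-clonevo run --config run.yaml --seed 1 --out run_out
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's end-to-end analysis from scratch: it simulates a
fresh synthetic cohort with the given seed, runs every pipeline stage
(consensus NMF, CNV inference and event calling, clonal homogeneity,
pseudotime and dosage trends, the survival cutoff scan and Cox model,
deconvolution and interaction scoring) and writes the results JSON to
`--out`, exiting non-zero if any stage fails.

## Layout

```
src/pdac_clonevo/
  synthetic_data.py        cohort generator + planted truth + MTX/TSV io
  subtype_programs.py      NMF, consensus K selection, assignment, proportions
  cnv_profile.py           CNV inference, gene scores, malignant calls, events
  clonal_dynamics.py       homogeneity, rank-sum, pseudotime, trends, clones
  clinical_outcomes.py     KM, log-rank, Cox, cutoff scan, RECIST association
  composition_crosstalk.py NNLS deconvolution, correlations, LR scoring
  pipeline.py, cli.py      orchestration, report, thin CLI
docs/methods.md            models, defaults, numerical choices, limitations
tests/                     unit + property tests and the acceptance suite
```
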