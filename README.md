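# methylseg

Cell-type-specific modeling of CpG methylation susceptibility from DNA
sequence, at three resolutions: individual CpG sites, DNA segments and
whole promoters.

DNA methylation levels vary block-wise along a promoter and differ
between cell types, but which stretches of sequence form a
methylation-susceptible "segment" is not observable directly.
`methylseg` is for computational epigenomics work on amplicon-style
bisulfite summaries (per-CpG methylation levels plus the underlying
sequences): it jointly searches for a segmentation of each amplicon's CpG
sites and a sequence-based predictive model of segment methylation
status.

The core model is a **k-mer mixture logistic regression**

    y = 1 / (1 + e^(−f(x))),    f(x) = β₀ + Σᵢ βᵢ xᵢ,

where xᵢ are occurrence counts of a small set of selected k-mers (4–6 bp,
chosen by Welch t-test or by consensus random-forest importance over
k = 30 runs × 100 trees, keeping k-mers in ≥ 90% of runs). Segmentations
are scored by the weighted squared error

    O(S) = Σᵢ (S̄/|Sᵢ|) (ŷᵢ − tᵢ)²,

with S̄ the mean segment size, tᵢ the majority (+/−) label of segment i
and ŷᵢ the model's prediction. A randomized hill climber starts from the
finest label-consistent segmentation and repeatedly merges adjacent
segments — candidates drawn with probability proportional to their
error — accepting a merge only if it reduces O(S), refitting the model
after every tentative merge during training. Evaluation is 10-fold
cross-validated AUC with the amplicon as fold unit, and a synthetic
generator with planted k-mer-driven block structure makes the whole
method exercisable without external data.

## Worked example

```python
import methylseg as ms

# 30 synthetic amplicons, noisy site levels (kappa=3), planted 6-mers
spec = ms.SyntheticSpec.strong_signal(seed=7, n_amplicons=30, kappa=3.0)
amplicons, records, truth = ms.generate(spec)
dataset = ms.assemble_dataset(amplicons, records)

table = ms.build_site_table(dataset, "CT0")
init = ms.initial_configuration(table, cell_type="CT0")
res = ms.hill_climbing_search(table, ["GATTAC", "TCATGA"],
                              N_restarts=2, seed=1, cell_type="CT0")
print("initial segments  ", len(init.segments))
print("final segments    ", len(res.configuration.segments))
print("boundary F1       ",
      round(ms.boundary_recovery_score(res.configuration, truth)["f1"], 3))

cfg = ms.ExperimentConfig(k=6, selection="ttest", n_kmers=30, folds=5,
                          seed=1, cell_type="CT0", resolution="segment",
                          restarts=1)
rep = ms.run_segment_experiment(dataset, cfg)
print("CV AUC (initial segments)", round(rep.mean_auc_initial, 3))
print("CV AUC (final segments)  ", round(rep.mean_auc_final, 3))
```

prints

```
initial segments   149
final segments     117
boundary F1        0.795
CV AUC (initial segments) 0.824
CV AUC (final segments)   0.953
```

The search merged noise-induced fragments (149 → 117 segments),
recovering most planted block boundaries (F1 0.80), and the
cross-validated AUC of the frozen training model rises from 0.82 on the
test amplicons' initial label-change segmentation to 0.95 on the final
segmentation found by the merge search — the improvement the segment
model is designed to deliver. On held-out data whose labels carry no
sequence signal, the initial-segmentation AUC sits at 0.5 (see
`docs/methods.md` for why the final-segmentation AUC is not a null
calibration).

A command-line interface wraps the same steps:

```bash
methylseg simulate --n-amplicons 60 --planted GATTAC=4.0 --seed 1 --out sim/
methylseg select-features --fasta sim/amplicons.fasta --table sim/methylation.tsv \
    --cell-type CT0 --method rf --runs 30 --trees 100 --top 100 --consensus-pct 90
methylseg fit-segments --fasta sim/amplicons.fasta --table sim/methylation.tsv \
    --cell-type CT0 --kmers GATTAC --restarts 10 --seed 1 --out fit/
methylseg evaluate --fasta sim/amplicons.fasta --table sim/methylation.tsv \
    --cell-type CT0 --resolution segment --k 6 --folds 10 --seed 1
```

## Layout

- `src/methylseg/io_data.py` — FASTA/TSV/BED readers and writers, dataset assembly
- `src/methylseg/kmer_features.py` — k-mer counting, flank extraction, t-test and RF-consensus selection
- `src/methylseg/mixture_logistic.py` — the penalized logistic mixture model
- `src/methylseg/segment_search.py` — boundary/segment/configuration types and the hill-climbing merge search
- `src/methylseg/evaluation.py` — cross-validated AUC at site/segment/promoter resolution
- `src/methylseg/synthetic_data.py` — the planted-signal generator and boundary-recovery scoring
- `docs/methods.md` — model, algorithm, generator and design notes
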