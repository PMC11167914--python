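# foldpath

Predicting a protein's **folding pathway** — which regions reach their
native arrangement first — from the structural record of its evolutionary
family.

Structure-prediction models give a single end state and say nothing about
how the chain gets there, while folding experiments (HDX-MS, CD, FRET)
and long MD runs are expensive and one protein at a time. `foldpath`
exploits a simple observation: regions that keep the same structure across
remote homologs tend to be the regions that fold first. Given a target
model and a set of homologous structures, it

1. builds a multiple structure alignment (MSTA), keeping homologs with
   TM-score ≥ λ = 0.3;
2. computes a per-residue conservation profile
   `F_i = (1/N) Σ_n sco_n(i)`, where the binned score `sco_n(i)` is
   1 / 0.75 / 0.25 / 0 for CA deviations ≤ 2, ≤ 4, ≤ 5, > 5 Å;
3. derives a restraint potential
   `E_stat = Σ_{i<j} w_ij |d_ij − d̄_ij| / ln(ε+|i−j|)` with pair weights
   `w_ij = 2 F_i F_j / (F_i + F_j)`, plus position-specific 3-/6-mer
   torsion fragment libraries after removing the
   `M = ⌊N·min_i F_i⌋` most target-identical homologs;
4. runs three Monte Carlo fragment-assembly stages — initialization
   (20·L 3-mer moves, steric + backbone H-bond scoring, kT = 5),
   folding nucleation (6- then 3-mer moves; weighted restraints at
   kT = 2 AND an 8-term centroid physical potential at kT = 5) and
   finalization (unweighted restraints first, physical fallback) — and
   emits the full snapshot trajectory;
5. clusters nucleation-stage snapshots into intermediate ensembles and
   scores the folding order with CA-lDDT over annotated early-/late-folded
   regions (EFR/LFR): the order is *consistent* when
   `lDDT(EFR) − lDDT(LFR) ≥ 0.10`.

A synthetic-data module generates complete benchmark cases (blueprint
natives, homolog families with calibrated region-specific structural
noise, Foldseek-style hit tables, EFR annotations), so the entire pipeline
runs with no downloads. See `docs/methods.md` for the model in detail.

## Worked example

Generate a two-region benchmark case — a 40-residue helix/strand protein
whose N-terminal half is structurally conserved across its 20 synthetic
homologs (σ = 0.5 Å) and whose C-terminal half is variable (σ = 3.0 Å) —
then fold it and score the predicted order:

```
$ foldpath synth --kind mixed --seed 1 --out case
$ foldpath analyze --target case/model.pdb --hits case/hits.tsv \
    --homologs case/homologs --native case/native.pdb \
    --annotation case/annotation.tsv --seed 1 --out results
INFO lDDT EFR 0.882 vs LFR 0.712 -> consistent=True
```

`results/report.json` then contains (abridged):

```
n_intermediates   6          # nucleation-stage ensembles, largest 167 members
lddt_efr          0.882      # conserved half of the leading intermediate
lddt_lfr          0.712      # variable half
consistent        true       # 0.882 − 0.712 ≥ 0.10
final_tm_score    0.424      # final state vs native
```

Reading: the conserved (early-folded) half of the leading intermediate is
already near-native (lDDT 0.88) while the variable half lags (0.71), so
the predicted folding order matches the annotation built into the case.
The trajectory's radius of gyration falls from 40.0 Å (extended chain) to
20.7 Å, and initialization-stage conformations carry more helix than sheet
(42 % vs 16 %) — individual helices form quickly, sheets need tertiary
contacts. With fragments from a noisy family the final state reaches
TM ≈ 0.4–0.5; in the identical-homolog limit the sampler recovers the
native at TM ≈ 1.0.

The same steps are available as library calls (`make_benchmark_case`,
`build_msta`, `run_pipeline`, `analyze_trajectory`); `foldpath fold`
writes the raw trajectory (multi-model PDB + per-snapshot CSV + replay
manifest).

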