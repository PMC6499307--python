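# methylctcf

Integrative analysis of CTCF binding, DNA methylation and nucleosome
occupancy dynamics between wild-type (WT) and Tet1/2 double-knockout (DKO)
cells — as one tested pipeline, exercised end-to-end on a synthetic epigenome
generator that plants known ground truth.

TET1/2 oxidize 5-methylcytosine; removing them deregulates the methylome,
and a subset of CTCF sites loses binding. This package implements the
computational side of dissecting that cascade:

- **`trap`** — biophysical CTCF affinity prediction from sequence (TRAP
  model): mismatch energy βE(w) = (1/λ) Σ_j ln(p(j,b_max)/p(j,w_j)) and
  occupancy p = R0·e^(−βE)/(1 + R0·e^(−βE)), with R0 = 10⁹, λ = 1.5 and the
  19-bp JASPAR CTCF matrix (packaged).
- **`methylome`** — per-CpG methylation classes (commonly methylated ≥ 0.8 in
  both; gained < 0.2 WT, > 0.5 DKO; lost > 0.5 WT, < 0.2 DKO; unmethylated
  < 0.2 in both), 500-bp landscape smoothing, and DMR calling (1000-bp
  sliding windows deviating by > 10% between conditions, merged by
  direction).
- **`nucleosomes`** — occupancy tracks from mononucleosome fragments, 100-bp
  differential-occupancy regions, WT/DKO fragment-shift classes (> 95%
  overlap stable, < 95% shifted, < 70% shifted by > 30%), and nucleosome
  repeat length (NRL) estimation from dyad periodograms with
  autocorrelation-peak regression.
- **`ctcf_sites`** — replicate-consensus site categories (common = in all
  replicates of both conditions; lost = all WT, no DKO; gained = all DKO, no
  WT), PWM motif scanning inside peaks, and motif/flank CpG composition.
- **`profiles`** — anchor-centered metaplots with replicate averaging and SD,
  cross-condition normalization to equal occupancy at common sites,
  periodicity estimation of affinity landscapes, k-means profile clustering
  with asymmetry scores.
- **`stats`** — fold enrichment (analytic and permutation), ROC/AUC
  (Mann–Whitney with ties, exact), predictor tables for CTCF loss, and
  expression linkage across the eight boundary-defined transcript categories.
- **`synthetic`** — the two-condition epigenome generator and its
  machine-readable truth manifest.

See `docs/methods.md` for the models, parameter defaults and their
rationale, and what the synthetic data does and does not emulate.

## Worked example

Run the packaged end-to-end demo (simulate → affinity → methylome →
nucleosomes → sites → profiles → stats) on a 2-Mb synthetic genome:

```bash
methylctcf run --seed 7 --outdir demo_out
```

which prints (abridged):

```json
{
 "n_common": 84,
 "n_lost": 36,
 "n_gained": 3,
 "n_dmrs": 341,
 "nrl_bp": 176.14,
 "auc": {
  "flank_cpg_density": 0.828,
  "motif_score": 0.587,
  "delta_nuc_occupancy": 1.0,
  "methylation_level": 0.772
 },
 "common_motif_island_fold_enrichment": 11.59
}
```

Reading the numbers: the replicate-consensus rule recovered the planted
common/lost/gained partition exactly (84/36/3 sites). The NRL estimate
(176.1 bp) matches the generator's planted 176-bp phasing. The predictor
comparison reproduces the study's qualitative ordering: the CpG density of
the 1000-bp region around a site is the best predictor of CTCF loss
(AUC 0.83), the motif score a weaker one (AUC 0.59) — CTCF is retained in
CpG-rich context and lost from CpG-poor context. Common motifs are strongly
enriched in CpG islands (11.6-fold). The DMR count includes, besides the
planted blocks, regions produced by methylation spreading around lost sites
and — because the caller implements the plain > 10% deviation rule with no
significance filtering — counting-noise calls in CpG-poor background (see
`docs/methods.md`).

Every output lands in `demo_out/` as plain text (FASTA, BED, bedGraph, TSV,
JSON) with a `provenance.json` recording parameters and seed; re-running
with the same seed reproduces every file byte-identically.

Library use mirrors the CLI:

```python
import methylctcf as m

sim = m.simulate_all(m.SyntheticConfig(seed=7))
calls = m.consensus_sites(
    [sim.peaks[("WT", r)] for r in range(2)],
    [sim.peaks[("DKO", r)] for r in range(2)],
)
dmrs = m.call_dmrs(sim.meth_wt, sim.meth_dko,
                   chrom_lengths=sim.bundle.chrom_lengths)
```

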