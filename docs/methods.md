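# Methods

`methylctcf` analyzes how the loss of TET1/2 dioxygenase activity reshapes the
interplay of CTCF binding, DNA methylation and nucleosome occupancy, by
comparing a wild-type (WT) condition against a Tet1/2 double-knockout (DKO)
condition. Because full-genome bisulfite/ChIP/MNase datasets are far beyond
desk scale, the package pairs every analysis stage with a synthetic epigenome
generator that plants known ground truth, so each stage can be validated for
recovery of what was planted.

## The TRAP binding model

CTCF-DNA binding affinity is predicted from sequence alone with the TRAP
occupancy model. Given a position probability matrix p(j, b) of width 19
(the JASPAR CTCF matrix MA0139.1 is packaged), the mismatch energy of a
window w is

    βE(w) = (1/λ) Σ_j ln( p(j, b_max) / p(j, w_j) ),

zero exactly at the per-column consensus, and the expected occupancy is the
two-state isotherm

    p = R0 e^{−βE} / (1 + R0 e^{−βE}).

Defaults are R0 = 10⁹ (dimensionless concentration/association constant) and
λ = 1.5 (energy mismatch scale). A pseudocount of 1 per matrix cell keeps all
energies finite. Each window is scored on both strands; the two probabilities
are summed and capped at 1 (a site binds CTCF in one orientation, but either
strand may carry the motif; whether the original implementations summed or
max-pooled strands is not documented, so the choice is ours and is isolated in
one code path). The window value is assigned to the window-center coordinate.
Windows containing non-ACGT symbols are reported missing rather than zero, so
assembly gaps do not fabricate affinity valleys. The vectorized scanner is
verified against an explicit-loop reference implementation to 10⁻⁹ relative
error.

Note that at R0 = 10⁹ the isotherm saturates: any window within ~20 natural
log units of the consensus energy scores ≈ 1. Random background windows
therefore carry non-negligible affinity; landscape-level structure emerges
from averaging over many anchors, exactly as in metaplot analyses of real
genomes.

## Methylome analysis

Methylation is handled as strand-collapsed per-CpG records (ratio, coverage);
symmetric +/− measurements of one CpG dinucleotide are merged
coverage-weighted at read time. CpG change classes use fixed thresholds:
commonly methylated (≥ 0.8 in both conditions), gained (< 0.2 WT and > 0.5
DKO), lost (> 0.5 WT and < 0.2 DKO), unmethylated (< 0.2 in both), else
"other". Boundary semantics follow the printed definitions: ≥ 0.8 inclusive,
the rest strict.

DMRs are called with a 1000-bp sliding window (step 100 bp, our choice; the
step is not fixed by the deviation rule): a window qualifies when both
conditions have ≥ 4 CpGs covered ≥ 4× inside it and the window means deviate
by strictly more than 10%. Overlapping/bookended qualified windows of equal
direction merge; means are recomputed over the merged interval. This is the
plain deviation rule only — no beta-binomial or permutation significance
filtering is layered on top (the reference workflow used a DMR caller whose
additional filtering options are not documented; we implement the stated rule
and note the divergence). Consequence: at 20× coverage the rule is reliable
only where windows carry enough CpGs. The window mean-difference SD is
√(2 p(1−p)/(cov·n)) for n CpGs per window; at n ≈ 10 (CpG-poor background,
1 CpG/100 bp) the 10% threshold sits at ~2σ and noise calls are frequent,
while at n ≈ 50 it sits at ~4.5σ and the rule is essentially deterministic.
The DMR validation configuration (`SyntheticConfig.dmr_benchmark`) therefore
uses a CpG density of 0.05/bp, equal background baselines, no spreading, and
50 planted blocks of |Δ| = 0.35 at 20× — conditions under which sensitivity
≥ 0.95 with zero calls outside planted regions ± 1 window is an achievable,
and achieved, contract.

## Nucleosome occupancy and the repeat length

Occupancy tracks are per-bp fragment coverage, pooled across replicates
before per-million scaling. Differential occupancy tiles the genome in
non-overlapping 100-bp windows (tiles make region counts well defined);
a tile is called when max(WT, DKO mean) ≥ min_signal (default half the WT
genome mean) and |log2(DKO/WT)| ≥ 1. Both thresholds are package choices —
no threshold is documented for the original region counts — and are exposed
as arguments.

Fragment-level dynamics compare each WT fragment with its best DKO partner,
the fragment maximizing reciprocal overlap f = |intersection| / max(lengths)
(the denominator choice is ours; "overlap between the bodies" does not fix
one). Classes: stable (f > 0.95), shifted by > 5% (f < 0.95), additionally
shifted by > 30% (f < 0.70), unmatched when no partner overlaps.

The nucleosome repeat length (NRL) is estimated in two stages: dyads
(fragment midpoints) are binned at 1 bp, and the periodogram of the
mean-removed density is scanned over the 100–400 bp band. Significance is the
peak-to-median band power ratio (threshold 25): for unstructured positions
band powers are roughly exponential, keeping the ratio near ln m ≈ 10–15,
while planted phasing exceeds 300 in the default generator. The point
estimate is then refined by locating the first five autocorrelation maxima
(parabolic interpolation on a lightly smoothed ACF) and regressing peak
position on peak order through the origin — the multi-order spacing fit,
which recovers planted NRLs of 150–200 bp to within ±0.5 bp at default
simulation depth (the ±2–3 bp contract in the tests leaves headroom). Profile
periodicity (e.g. of sequence-encoded affinity landscapes) uses the same band
periodogram after subtracting a 300-bp running mean; missing positions are
zero-filled post-detrending.

## CTCF site categories and composition

Candidate sites are single-linkage overlap clusters of the pooled peaks of
all replicates, which makes the procedure independent of replicate ordering.
A replicate supports a candidate when it contributes a peak with reciprocal
overlap ≥ 50% of the cluster span (the matching criterion is not documented
in the reference workflow; 50% reciprocal overlap is our default, exposed).
Categories follow the strict replicate-consensus rule: common = present in
every replicate of both conditions; lost = every WT replicate and no DKO
replicate; gained = every DKO replicate and no WT replicate; everything else
is uncategorized. The representative interval is the intersection of
supporting peaks.

Motif-level sites are log-odds PWM matches (uniform background) inside peaks,
reported on the better-scoring strand (ties → +), inheriting the peak
category. The default threshold is 60% of the maximum attainable score —
a permissive setting that accepts genuinely weaker variants of the motif
while random 19-mers stay far below it. Composition summaries report the
fraction of motifs containing a CG dinucleotide, flank CpG density (CpGs/kb
over ± 500 bp), and strand-oriented base frequencies over ± 2000 bp.

## Profiles, normalization, clustering

Anchor-centered profiles are computed per replicate and then averaged; the
reported SD is the sample SD (n−1) across replicate means, matching the
convention of shading the variability of the replicate averaging. Stranded
anchors are orientation-flipped. Cross-condition comparison uses
`normalize_to_common`: all DKO profiles are multiplied by
s = mean(WT common) / mean(DKO common), which makes the common-site means
equal exactly and is idempotent. Profile clustering is k-means
(scikit-learn) on per-anchor log-affinity rows, subsampled to a 200,000-row
cap, with a per-centroid asymmetry score |mean left − mean right| / SD and an
optional random-region control clustered with identical settings; k defaults
to 6 with a fixed seed (k is not documented in the reference analysis; both
are exposed).

## Predictors, enrichment, expression linkage

The predictor table assembles, per categorized motif site: motif log-odds
score, Δ nucleosome occupancy (DKO − WT mean over the site ± 100 bp), WT
methylation level (± 500 bp), and CpG density of the 1000-bp region around
the site. AUC is the Mann–Whitney statistic with half-credit ties, reported
as-is (no forced ≥ 0.5), verified exactly against an all-pairs count and
against scikit-learn. Fold enrichment counts query *elements* overlapping a
feature (≥ 1 bp); the analytic expectation n_query × coverage/genome treats
elements as points and is exact in that limit, while the permutation method
(length-preserving, chromosome-matched uniform placement) gives an empirical
expectation and p-value. Expression linkage computes the eight
boundary-defined transcript categories (genome-wide; inside TADs; within
10 kb of loop/TAD boundaries; the same restricted to *lost* boundaries — a
boundary is lost when a lost CTCF site lies within 10 kb; and lost CTCF at
the promoter, TSS ± 1 kb — the promoter window is our choice) with per
category up/down counts, down/up ratio, and a chi-square (no continuity
correction, large-count use case) against the genome-wide counts. The
chi-square reference is genome-wide, not each category's complement; the
alternative is not fully specified in the source analysis, and the
genome-wide reference matches how the bars are drawn.

## The synthetic epigenome

No generative model is documented for the real data, so every generator
parameter is an artifact choice of this package. The defaults describe a
2-Mb single-chromosome genome, desk-scale but structured like the real
problem:

- **Sequence**: background CpG rate 0.01/bp with 40 CpG islands of 2 kb at
  0.10/bp. CpGs are planted explicitly (rate r → plant probability
  r/(1−r), so the realized per-bp CpG rate is r); single bases never create
  accidental CGs, making the island/background contrast exact.
- **Sites**: 40 island + 80 background CTCF sites, ≥ 400 bp apart (keeps
  replicate peaks disjoint so consensus recovery is well defined), half
  "strong" (consensus) and half "weak" (two columns flipped to their
  second-best base — a weaker but genuine match). Site loss is logistic:
  p = σ(2.9 − 0.25·density/kb − 1.4·[strong]). The density term dominates by
  construction: island sites (≈ 100 CpGs/kb) essentially never lose CTCF,
  background sites (≈ 10/kb) lose it often, and the tier term adds a smaller
  protective effect. This encodes the study's central structure — retention
  in CpG-rich context, with motif strength a weaker secondary predictor — and
  makes the expected AUC ordering (flank CpG density > motif score > 0.5)
  hold with wide margins across seeds.
- **Methylomes**: islands at 0.05 in both conditions; background 0.60 (WT) /
  0.62 (DKO) — a modest global gain kept below the DMR threshold so that
  differential regions are localized. Around each lost site the DKO level
  gains amplitude·exp(−d/500 bp) on a recorded side (left/right/both),
  amplitude 0.25 — the "bifurcation point" geometry of methylation spreading
  from lost CTCF boundaries. Twenty explicit DMR blocks of 2 kb, |Δ| = 0.35,
  are planted in island/site-free background. Observed ratios are
  Binomial(coverage, truth)/coverage at 20×, the bisulfite counting-noise
  model.
- **Nucleosomes**: 70% of fragments come from phased arrays — dyads at
  ±k·NRL (k = 1..5, SD 20 bp) around site centers, the simplest mixture that
  yields NRL-periodic oscillations — leaving a depleted region over each
  CTCF-bound motif. At sites unbound in a condition (lost sites in DKO) the
  k = 0 position carries its uniform share, restoring occupancy over the
  motif. Fragment lengths are Normal(147, 15) truncated to [100, 200] bp;
  150,000 fragments per replicate, two replicates per condition.
- **Peaks**: site center ± 150 bp with ± 10 bp per-replicate jitter; lost
  sites peak in every WT and no DKO replicate; three "gained" DKO-only peaks;
  a false-negative probability (default 0) can drop peaks.
- **Expression**: 100-kb TADs tile the genome; loop anchors sit at alternate
  interior boundaries; 500 transcripts (2–20 kb) with baseline up/down
  probabilities 0.10/0.10. The down probability gains
  0.35·exp(−d/10 kb) near lost boundaries and the full 0.35 for transcripts
  with a lost site at the promoter.

Ground truth (site fates with spreading sides, DMR intervals with realized Δ,
true NRL, lost boundaries, down-regulated transcript ids) is emitted as a
separate JSON manifest that the analysis never reads.

**What the generator does not emulate**: sequencing reads and their error
modes, mappability, MNase sequence bias, replicate-specific batch effects,
non-CpG methylation, 5hmC/5fC as separate base-resolution tracks, inter-site
cooperativity, and realistic genome-scale heterogeneity. Passing recovery
tests therefore demonstrates the correctness and calibration of the analysis
logic under the stated noise models, not performance on real sequencing data.

## Numerical and size choices

Desk-scale problem sizes were chosen once as the package's validation
conditions: 2-Mb genomes, 120 planted sites, 150k fragments/replicate, 20×
methylation coverage, 500 transcripts; the NRL sweep uses 500-kb genomes at
60k fragments/replicate and the affinity-landscape sweep 200-kb sequences
with 66 echo anchors. All randomness flows from explicit integer seeds
through `numpy.random.default_rng`; identical configs yield byte-identical
outputs. The DMR caller guards its strict ">" threshold with a 10⁻⁹ epsilon
against float accumulation. Degenerate inputs (zero anchors, empty replicate
sets, single-class labels, flat profiles, zero-mean normalization references)
raise explicit errors or return explicit "no periodicity" results rather than
numbers.

## Known limitations

- The headline full-genome counts of the motivating study (hundreds of
  thousands of differential-occupancy regions, thousands of consensus sites)
  require full sequencing datasets; desk-scale runs reproduce the *structure*
  and *orderings*, not those absolute numbers.
- The deviation-only DMR rule is noisy in CpG-poor background at 20×
  coverage (see above); real analyses should add statistical filtering.
- TRAP with R0 = 10⁹ saturates near-consensus windows, so affinity-based
  discrimination of common vs lost sites is weaker at desk scale than with
  genome-scale averaging.
- The permutation enrichment method treats the whole chromosome as mappable.
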