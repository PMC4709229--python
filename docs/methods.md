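# Methods

## Scope and model

`dgepipe` implements the classic single-replicate digital gene expression
(DGE) workflow for comparing two pooled sequencing libraries — for example a
male and a female expression-profile library sequenced on an Illumina
HiSeq-class instrument. Because each condition is one pooled library, there
is no replicate-based dispersion estimate; inference rests on the Poisson
sampling model for tag counts.

### Read filtering

Reads are discarded whole (never trimmed) when any rule fires, evaluated in
the order adaptor → ambiguous bases → quality so that a multiply-failing
read is attributed to exactly one tally:

| rule | transcriptome (assembly) stage | expression-profile stage |
|---|---|---|
| ambiguous bases | N fraction > 5% | N fraction > 10% |
| low quality | > 20% of bases with Phred ≤ 10 | > 50% of bases with Phred ≤ 5 |
| adaptor | 10 bp 5' prefix of the adaptor found anywhere in the read | same |

All thresholds are strict inequalities: a 100 bp read with exactly 5 Ns, or
exactly 20 bases at quality 10, is retained under the transcriptome rules.
Quality strings are Sanger/Phred+33. N bases are judged by their recorded
quality like any other base; the two fraction rules are independent and
both use the full read length as denominator. "Adaptor contamination" is
operationalised as an exact match of the adaptor's 5' prefix
(`adaptor_min_match`, default 10 bp) anywhere in the read — the simplest
testable definition; both the probe length and the adaptor are
configurable.

### Quantification

RPKM = 10⁹ · C / (N · L) for a gene with C uniquely mapped reads, length L
bp, in a library of N uniquely mapped reads. Library totals default to the
count-column sums; externally supplied totals are accepted (and must be at
least the sums) for tables that exclude some mapped genes.

### The exact test

With x tags for a gene in library 1 (depth N₁) and y in library 2 (depth
N₂), and tag counts Poisson around a shared latent transcript abundance,
the count in library 2 conditional on x follows

    p(y|x) = (N₂/N₁)^y · (x+y)!/(x!·y!) · (1 + N₂/N₁)^−(x+y+1),

which is a negative binomial with r = x+1 and success probability
N₁/(N₁+N₂) — a fact the tests exploit as an independent cross-check. The
two-sided p-value doubles the smaller tail at y:
p = min(1, 2S) with S = Σ_{i≤y} p(i|x) when S ≤ ½, else min(1, 2(1−S)).

Numerics: each term is evaluated in log space via `gammaln`; the lower tail
is combined with `logsumexp`. When S > ½ the complement 1−S is *not* formed
by subtraction — the upper tail Σ_{i>y} is summed directly, in vectorised
blocks, stopping when the geometric bound on the remaining tail
(term ratio q·(x+i+1)/(i+1) → q = N₂/(N₁+N₂) < 1) drops below 10⁻¹² of the
accumulated sum. A rational-arithmetic brute force over the full
x, y ≤ 30 grid at depth ratios {1, 2, ½} agrees to < 10⁻¹⁰ (observed
≈ 9·10⁻¹³).

### DEG calling

Benjamini–Hochberg step-up q-values across all genes (delegated to
statsmodels); a gene is `up` when q ≤ 0.001 and log₂(expression₁/expression₂)
≥ 1, `down` for ≤ −1, both thresholds configurable. The ratio uses RPKM by
default (gene length cancels, so this equals the depth-normalised count
ratio); a raw-count basis is available by flag. A zero count in exactly one
library is replaced by 0.5 reads *for the ratio only* — the exact test
always sees the true zeros — and flagged `pseudocount`; genes at zero in
both libraries get p = 1, an undefined ratio, and the flag `both_zero`.
BH was chosen over Storey's π₀-estimated q-value because it is
parameter-free and reproducible; output rows are ordered by (q, gene id)
for deterministic files.

### Term enrichment

For each term, margins (N, n, M, m) are: N genes carrying ≥ 1 annotation in
the background, n DEGs among them, M genes annotated to the term, m DEGs in
M. The enrichment p is the upper hypergeometric tail P(X ≥ m) =
1 − Σ_{i<m} C(M,i)C(N−M,n−i)/C(N,n); it is computed as the direct sum of
the complementary tail Σ_{i=m}^{min(n,M)} with log-gamma binomials and
`math.fsum`, because the one-minus form cancels catastrophically exactly
where enrichment is interesting (small p). GO-style mode corrects with
Bonferroni, KEGG-style mode with BH q-values; either way significance is
corrected P ≤ 0.05. Genes with multiple terms count once per term; the
annotation map is tested as given (no ontology-ancestor propagation). An
exhaustive enumeration of all draws for every margin combination with
N ≤ 15 agrees to < 10⁻¹⁰.

### RT-qPCR relative quantification

Per sample, technical replicates are averaged first; then
ΔCT = CT_target − mean(CT of the reference genes) — the arithmetic mean of
reference CTs, i.e. the geometric mean of reference expression, the
standard multi-reference convention. ΔΔCT = mean ΔCT(case) − mean
ΔCT(control); the reported ratio is 2^−ΔΔCT. The standard error combines
per-group SEs of the biological-replicate ΔCT values and maps to the ratio
scale by the delta method (ln 2 · ratio · se). Group difference is a
two-sample Student's t-test on ΔCT at α = 0.05. Because every sample is
normalised against its own references, adding a constant to all CTs of a
sample cancels exactly, and swapping the group labels inverts the ratio.

## Synthetic data: what it emulates and what it does not

`generate_count_tables` draws per-gene relative expression log-uniformly
over three decades (default 1–1000) so RPKM spans realistic magnitudes,
multiplies the designated DE genes' library-1 level by their true fold
change, rescales both libraries so expected counts sum to the requested
depths, and draws Poisson counts. The rescaling mirrors the compositional
constraint of real libraries: asymmetric DE shifts every null gene's
expected ratio slightly. Counts are Poisson by default because that is the
sampling model of the exact test; a gamma–Poisson `overdispersion` knob
exists but defaults off, and real pooled libraries may well be
overdispersed — passing calibration tests here therefore validates the
implementation, not the Poisson assumption for any particular data set.
The generator does not simulate mapping ambiguity, isoforms, positional
biases, or sequencing error profiles.

`generate_fastq` plants adaptor insertions (per-read Bernoulli), N calls
(per-base Bernoulli), and a two-component read-quality mixture (default
mean 38, sd 2; low-quality reads mean 4), then labels each read with the
fate the filter rules assign it, evaluated in the same rule order — so
filter output can be checked against labels with zero tolerance.
`generate_annotation` annotates each (gene, term) pair independently at a
background rate (default 0.05), elevated (default 0.5) for DEG × enriched-
term pairs; setting the rates equal yields an exact null map.

Default study-shaped scales used by the acceptance checks: null
calibration at 5 000 genes × 20 replicates with 10⁶-read libraries (mean
count ≈ 200); recovery at 1 000 genes, 10% DE with balanced 4-fold
up/down changes, 1.5·10⁶-read libraries and a 10–1000 expression range so
every gene's expected count is ≥ 50; filtering at 10⁴ reads of 91 bp.

## Numerical and degenerate-input choices

- Two-sided p at S exactly ½ returns 1 (both branches agree).
- p-values are capped at 1; enrichment tails clipped to [0, 1] after
  compensated summation.
- Empty read → rejected as malformed; sequence/quality length mismatch →
  abort naming the record; scientific-notation counts in TSVs → rejected
  (counts are integers); duplicate gene ids → rejected.
- Empty DEG list in enrichment: valid, warned, all p = 1. Terms with no
  background member are skipped with a warning.
- qPCR with a single biological replicate per group: ratio is computed,
  SE and p are NaN (no dispersion estimate exists).
- All generators require an explicit seed; the pipeline derives stage
  seeds from one root seed via `SeedSequence.spawn`, records them in
  `manifest.json` together with package/library versions, every stage
  parameter, and SHA-256 checksums of all artifacts, and writes TSVs with
  fixed float formatting so reruns are byte-identical.

## Known limitations

- No replicate-aware inference (negative-binomial GLMs are out of scope by
  design); the test's Poisson assumption understates biological variance.
- Enrichment treats terms independently — no ontology structure, no
  term-term overlap modelling.
- The filter discards whole reads; pipelines that trim adaptors instead
  will retain more data.
- qPCR analysis assumes 100% amplification efficiency (no Pfaffl
  correction) and equal-variance t-tests.
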