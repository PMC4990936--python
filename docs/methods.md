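# Methods

## The analysis model

The pipeline treats a regulator-knockout RNA-seq design — wild type,
*nodD1*⁻ and *ttsI*⁻, each ± genistein, two biological replicates — as
evidence about which promoter boxes are functional and which responsive
genes depend on which regulator. Three assumptions carry the analysis:

1. **Counts are proportional to expression** after per-library scaling.
   Size factors use the median-of-ratios estimator over genes positive in
   every library, rescaled to geometric mean 1; if no gene is positive
   everywhere the estimator falls back to total-count scaling with a
   warning. The estimator assumes most genes are unchanged between
   libraries (see *Desk-scale caveats*).
2. **Within-condition counts are Poisson-like once pooled.** With n = 2
   replicates no per-gene dispersion is estimable, so replicates are pooled
   within sides and significance comes from an exact conditioned-binomial
   test: given the two-sided total N, the treatment total is
   Binomial(N, q) under the null with q the treatment share of the summed
   size factors; the two-sided p-value sums the probabilities of all
   outcomes no more likely than the observed one (computed via
   `scipy.stats.binomtest`; the test suite checks it against exhaustive
   enumeration for all N ≤ 50). Raw counts enter the test; size factors
   only shape q. Fold changes use replicate means of normalized counts
   with a pseudocount (default 0.5) that never enters the test.
   Overdispersion is not modelled; robustness to it is probed by
   simulation at the generator's default dispersion.
3. **Epistasis identifies box function.** Writing I(s) for "the box's
   downstream transcription unit is up-induced by genistein in strain s"
   (the lead gene is an up-DEG, or — majority rule — at least half of the
   operon members are): a nod box is active iff I(WT) ∧ I(ttsI⁻) ∧
   ¬I(nodD1⁻); a tts box is active iff I(WT) ∧ ¬I(nodD1⁻) ∧ ¬I(ttsI⁻).
   Both fold-change and p-value requirements apply to "induced"
   (config-overridable). A box matching the sign pattern whose wild-type
   fold change sits in [weak_fc, fc) is *weakly active*; a box whose unit
   stays induced without its regulator is *non-functional*; a box without
   a downstream gene, or whose unit's normalized baseline and treatment
   means both fall below the coverage floor, is *not testable*.

Gene-set assembly adds to the direct wild-type DEGs (any direction) the
non-DEG members of operons containing a DEG (*operon rescue*) and genes
directly behind a 0-mismatch box with wild-type FC at or above the rescue
threshold (*conserved-box rescue*). Two discard rules then remove genes
antisense to a nod box and sequence-identical duplicates of box-controlled
genes (the box-linked copy is kept). Remaining genes belong to the regulon
of an active/weakly-active NB, of an active TB, or to group *other*; for
group-other direct DEGs, NodD1 (TtsI) dependence means the gene is a DEG
in the wild type but not in that knockout, so a gene differential in all
three strains is independent of both. Genes repressed in both mutant
backgrounds regardless of genistein (the *fbpA* pattern) are reported in a
separate table, not folded into the three groups. A gene claimed by both
an active NB and an active TB is assigned to the nearer box with a logged
conflict warning.

## Thresholds and defaults

| parameter | default | meaning |
|---|---|---|
| fc | 3.0 | DEG fold-change cutoff (|log₂FC| > 1.6) |
| alpha | 0.05 | raw p-value cutoff (BH adjustment available, off by default) |
| weak_fc | 2.0 | lower edge of the weakly-active band [2, 3) |
| rescue_fc | 2.0 | conserved-box rescue fold-change floor |
| coverage_floor | 10 | min normalized mean (baseline or treated) for testability |
| operon max gap | 200 bp | intergenic gap joining same-strand genes; explicit tags always win |
| box→gene link distance | 1000 bp | how far 3′ of a box its target may start |
| upstream window | 900 bp | scan window 5′ of the translation start |
| mismatch budget | 1 | scanner default over informative positions |

The weakly-active band has no published cutoff; [2, 3) was fixed once so
that a ~2.5-fold NodD1-dependent unit is reported as active-but-inefficient
rather than silent. The 1000-bp link distance generously covers all
reported box offsets (largest ≈ −820 bp); how far a controlled gene may
really sit is unknown, so the value lives in config. Which gene speaks for
a polycistron is likewise unstated in the literature; the lead gene speaks,
with the majority rule as fallback. Offsets follow the convention −1 = base
immediately 5′ of the translation start, so a 66-bp box ending 62 bp
upstream spans −127..−62.

Motif patterns are literal IUPAC blocks separated by fixed-length N
spacers. N positions are pure length constraints (0 mismatch weight);
degenerate literals match their base set. A pattern may declare a
mandatory core (the TB `CGN2AG`): any core mismatch rejects the window
regardless of budget, encoding the observation that non-functional tts
boxes fail precisely there. The SyrM-box consensus is not redistributed
here; the bundled 66-bp `SyrM` pattern is a synthetic stand-in (length
matching reported SyrM boxes) used by the simulator and demos, and real
analyses should supply the genuine consensus through the pattern file.
SyrM boxes get no epistasis call — the pipeline only flags their presence
upstream of group-other genes.

## What the generator emulates — and what it does not

`simulate_genome`/`simulate_counts` plant, at desk scale, the structure the
analysis is meant to recover: a 7-replicon genome (~220 kb, ~270 genes,
the pSym analogue carrying most boxes), operons of 1–3 genes, exact or
k-mismatch box instances placed 60–160 bp upstream of operon leads, and
per-class induction patterns (NB-class genes induced in WT and ttsI⁻;
TB-class in WT only; SyrM-class TtsI-independently by default; independent
classes in all strains; a mutant-background gene repressed in all four
mutant cells). Defaults mirror the study design: 15 NB = 11 active + 1
weak (2.5×) + 1 silent + 1 without a downstream gene + 1 opposed to an
antisense gene; 18 TB = 11 active + 1 TtsI-independent decoy + 6 with
corrupted cores; 30 boxless responsive genes = 24 NodD1-dependent (7 of
them also TtsI-dependent) + 4 up and 2 down in all strains; plus one
duplicate-copy and one antisense decoy exercising the discard rules.
Induction defaults to 8-fold, baselines of responsive genes to
U(200, 500), background baselines to a clipped lognormal (median ≈ 80),
dispersion to 0.05, library depths to log-uniform [0.7, 1.4] so the
normalization stage genuinely matters. Counts are negative binomial in
mean–dispersion form (variance μ + φμ²; φ = 0 recovers Poisson) with
mean = baseline × effect × length/1 kb × depth. Everything is
deterministic given (config, seed), and unit placement is exact-footprint
packed with a hard error when a design cannot fit its replicons.

Two focused designs are first-class: `tts_box_design()` (the 18-TB
functional screen, nothing else planted) and `boxless_design()` (the
30-gene dependence screen, no boxes). `scripts/acceptance.py` runs both
and reports the recovered counts.

**Desk-scale caveats.** Real stimulons involve ~1–2 % of a 6960-CDS
genome; the reduced genome concentrates ~30 % responsive genes, so
median-of-ratios factors for induced cells are biased high (~1.2×) and
realized fold changes shrink (8× plants register ≈ 6×). Calls are
unaffected at the default effect sizes, and a focused test verifies
recovery of an 8.2-fold plant once DE genes are a minority — but
normalization accuracy on real data should be expected to be better than
in the dense default simulation, not worse. The generator also draws
independent NB noise per library (no replicate correlation, no batch
structure), plants boxes only upstream of leads (no nested or antisense
transcription), and simulates no read-level artefacts (mapping, GC,
duplicates). Passing tests therefore demonstrate the *logic* of the
pipeline — normalization, testing, scanning, epistasis calls, set
algebra — not robustness to alignment-level noise.

qPCR fold changes assume perfect amplification efficiency (doubling per
cycle); technical replicates are averaged within biological replicates
before conditions are compared, and the reported spread is the range of
per-biological-replicate fold changes. Concordance with RNA-seq is a
Pearson correlation on the log₂ scale with sign-discordance flags.

## Numerical and design choices

* Exact-test ties: outcomes with probability ≤ p(observed)·(1+1e-9) are
  included in the two-sided sum (guards float round-off); N = 0 yields
  p = 1.
* Multiple testing follows the raw p < 0.05 decision rule of the original
  design; Benjamini–Hochberg is available behind a flag.
* Scanner ties: hits sort by position, + strand first; reverse-strand
  hits are computed on the reverse complement and mapped back.
* The size-factor example "one library doubled → factor 2" holds as a
  ratio; after geometric-mean-1 rescaling the absolute factors are
  2^(1−1/m) and 2^(−1/m).
* Problem sizes in the test suite (5-kb scanner oracles, N ≤ 50
  enumeration, 10⁴-gene null calibration, 10-seed recovery screens) were
  chosen as the smallest scales at which each property is decisively
  measurable.
* Test sizes of the planted-recovery guarantee: effects ≥ 5-fold and
  baselines ≥ 200. The weakly-active plant (2.5×) is deliberately outside
  the guarantee — its realized fold change straddles the weak band edge at
  the default dispersion, which is the behaviour the band is meant to
  expose, so recovery tests assert it only for active/non-functional/
  no-downstream plants.

## Known limitations

* No PWM/log-odds scoring; mismatch counting only.
* No dispersion estimation or GLM machinery; the exact test is
  Poisson-conditioned and anti-conservative under strong overdispersion
  (the null calibration test pins the type-I rate at the generator's
  dispersion 0).
* Operon inference is a same-strand gap heuristic; real transcription
  units with long internal gaps or internal promoters are out of reach.
* The discard rules implement the two documented reasons (antisense to an
  NB; identical copies); other curation reasons from the original study's
  supplementary material are not modelled.
* SyrM regulation is flagged, never called.
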