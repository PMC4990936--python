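# stimulon

Flavonoid-stimulon analysis for multi-replicon rhizobial genomes.

Rhizobia such as *Sinorhizobium fredii* sense legume-root flavonoids (e.g.
genistein) through the transcriptional activator NodD1, which binds *nod*
boxes (NB) and switches on nodulation genes — among them *ttsI*, whose
product TtsI in turn binds *tts* boxes (TB) and fires the type 3 secretion
system. The full genistein **stimulon** therefore decomposes into genes
driven by NB, genes driven by TB, and responsive genes preceded by neither.
Comparing induction across the wild type and the *nodD1*⁻ and *ttsI*⁻
knockouts separates these layers by epistasis.

`stimulon` packages that analysis as a tested pipeline for anyone working
with bacterial regulator-knockout RNA-seq designs:

* **Differential expression** of each strain × ±genistein cell against the
  wild-type no-genistein baseline. Libraries are normalized with
  median-of-ratios size factors *ŝⱼ* = median₍g₎ (*k₍gj₎* / (∏ⱼ′ *k₍gj′₎*)^{1/m}),
  rescaled to geometric mean 1. Significance comes from an exact
  conditioned-binomial test: pooling replicates within sides, the treatment
  total *k_t* given *N = k_t + k_b* is Binomial(*N*, *q*) under H₀ with
  *q* = Σŝ_treatment / Σŝ_both; the two-sided *p* sums all outcomes no more
  likely than the observed one. A gene is a DEG when FC ≥ 3 or ≤ 1/3
  (|log₂ FC| > 1.6) and *p* < 0.05.
* **Promoter-box scanning**, fuzznuc-style, for degenerate consensus
  patterns of literal IUPAC blocks and fixed-length N spacers — the NB
  consensus `ATCN9GATN7ATCN6ATCGATN6AAT` (46 bp, 18 informative positions)
  and the TB consensus `GTCAGN5CGN2AGN10TA` with its mandatory `CGN2AG`
  core — with a mismatch budget over informative positions only.
* **Epistasis classification** of each box:
  NB active ⇔ induced in WT ∧ induced in *ttsI*⁻ ∧ ¬induced in *nodD1*⁻;
  TB active ⇔ induced in WT ∧ ¬induced in either mutant. Boxes matching the
  sign pattern with wild-type FC in [2, 3) are *weakly active*; boxes whose
  downstream unit stays induced without their regulator are
  *non-functional*; boxes without a testable downstream gene are *not
  testable*. The affected gene set is assembled from direct DEGs plus
  operon rescue (sub-threshold members of DEG-containing operons) and
  conserved-box rescue (FC ≥ 2 behind a 0-mismatch box), then pruned of
  genes antisense to an NB and of duplicate copies of box-controlled genes.
  Every retained gene lands in group NB, group TB, or group *other* with
  NodD1/TtsI dependence flags.
* **qPCR validation**: ΔΔCt fold changes against a 16S reference
  (FC = 2^(−ΔΔCt)) and their log-scale Pearson concordance with RNA-seq.
* **A synthetic-data generator** that plants the full regulatory structure
  (active/weak/broken boxes, boxless responsive genes, a
  mutant-background gene, decoys for every discard rule) in a 7-replicon
  genome with negative-binomial counts and emits a machine-readable truth
  table, so every stage is verifiable without any downloads.

## Worked example

```bash
cat > demo.yaml <<'YAML'
seed: 7
output_dir: demo_out
simulate: {}
YAML
stimulon run --config demo.yaml
```

This simulates the default design — 12 libraries = 3 strains × ±genistein
× 2 replicates over ~270 genes, with 15 planted NB (11 active, 1 weak,
1 silent, 2 without testable downstream genes), 18 planted TB (11 active,
1 TtsI-independent decoy, 6 with a corrupted core) and 30 boxless
responsive genes — then normalizes, calls DEGs, scans upstream windows and
classifies. The report it prints starts:

```json
{
  "box_calls": {
    "NB": {"active": 11, "non_functional": 2, "not_testable": 2},
    "TB": {"active": 11, "non_functional": 7}
  },
  "dependence": {"independent": 6, "nodD1_dependent": 31,
                 "ttsI_dependent": 9},
  "groups": {"NB": 23, "TB": 23, "other": 38},
  ...
}
```

All 11 planted-active nod boxes and 11 planted-active tts boxes are
recovered; the TtsI-independent decoy and the 6 corrupted-core boxes are
called non-functional; the weak box and the two boxes without usable
downstream genes fall into the remaining categories. 85 genes are DEGs in
the wild type (81 up / 4 down), two genes are discarded (one antisense to
a nod box, one duplicate copy), and the planted mutant-background gene is
reported separately. `demo_out/` holds every stage's tables (DE per
contrast, box calls, group assignments, discard log, truth tables,
`report.json`), each stamped with the config hash and seed; rerunning the
same config is byte-identical.

The stages are also available individually (`stimulon simulate | de |
scan | classify | qpcr | report`) and as library functions
(`stimulon.run_de`, `stimulon.classify`, `stimulon.scan_upstream`, ...).

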