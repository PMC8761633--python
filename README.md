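# mirproc

Structural and sequence determinants of miRNA processing, as a tested,
reusable analysis pipeline.

Animal microRNAs are cropped from primary transcripts (pri-miRNAs) by the
Microprocessor (Drosha–DGCR8) and diced from precursor hairpins
(pre-miRNAs) by Dicer. Both enzymes discriminate among their substrates:
a pri-miRNA folds into a hairpin whose parts — the apical **terminal loop
region**, the **miRNA duplex**, the **proximal domain** (basal stem, the
12-nt extensions beyond the pre-miRNA ends) and the **distal domain**
(remaining flanks) — each contribute to how efficiently it is processed, as
do short sequence motifs at canonical positions (basal **UG**, apical
**UGU**, flanking **CNNC**, and the bulged basal **mGHG**). `mirproc`
implements the complete quantitative workflow that links these features to
in-vitro cleavage efficiency and in-vivo miRNA expression:

* a self-contained nearest-neighbor **minimum-free-energy folding engine**
  (Watson–Crick + GU stacking, Jacobson–Stockmayer loop penalties, affine
  multiloops; no pseudoknots or dangles) with exact loop-decomposition
  energy evaluation and **region-attributed ΔG**;
* **domain demarcation**: the terminal loop region runs from the first
  nucleotide after the miR-5p 3′ end to its base-pairing correspondent on
  the 3′ arm; duplex ΔG is obtained by subtraction,
  ΔG(duplex) = ΔG(pre) − ΔG(loop); proximal/distal ΔG are attributed on the
  pri-miRNA structure;
* **motif scanning** at configurable windows (UG at −14/−13 from the
  pre-miRNA 5′ end; UGU in the first 4 loop nt; CNNC with first C 16–18 nt
  past the pre-miRNA 3′ end) plus a pluggable mGHG score lookup table;
* **cleavage quantification**: raw ratio = product / (product + substrate)
  band intensity, normalized so the control RNA in every experiment sits at
  exactly 100;
* **statistics**: tie-corrected Spearman rank correlation (N, ρ, p per
  feature–response pair, pairwise deletion) and two-tailed Mann–Whitney U
  group comparisons, with exact small-sample enumeration;
* a **synthetic cohort generator** with planted effects, so every stage is
  testable end to end without any external data.

## Worked example

Generate a 150-hairpin cohort with the default planted effects (effect
sizes are on z-scored features: proximal −0.5, loop +0.5, duplex −0.3,
distal +0.2, motif count +0.3, mGHG +0.5; Gaussian noise SD 0.5), run the
full analysis, and print the Drosha rows of the correlation report:

```python
from mirproc.synthetic_data import GeneratorConfig, generate_cohort
from mirproc.pipeline import analyze_cohort

cohort = generate_cohort(GeneratorConfig(n_mirnas=150, seed=1))
bundle = analyze_cohort(cohort.records, cohort.lanes, None, cohort.mghg_table)
rep = bundle["correlations"]
rows = rep[rep.response == "Drosha efficiency"]
print(rows[["feature", "n", "rho", "p"]].round(4).to_string(index=False))
```

```
    feature   n     rho      p
    dg_loop 150  0.2959 0.0002
  dg_duplex 150 -0.1726 0.0347
     dg_pre 150  0.0456 0.5792
dg_proximal 150 -0.4727 0.0000
  dg_distal 150 -0.0011 0.9893
     dg_pri 150 -0.1666 0.0416
 mghg_score 142  0.5207 0.0000
motif_count 150  0.2341 0.0039
```

Reading the table: a *negative* ρ for the proximal domain means more stable
basal stems (lower ΔG) are cleaved better; a *positive* ρ for the terminal
loop means floppier loops (ΔG nearer 0) are cleaved better; mGHG scores
correlate positively (N drops to 142 because windows whose key is absent
from the lookup table are scored as missing and deleted pairwise). These
are exactly the planted directions.

The same workflow is available from the shell:

```bash
mirproc simulate --seed 1 --n 150 --out cohort/
mirproc run config.yaml         # fasta/annotation/lanes/expression paths
mirproc fold hairpins.fasta     # dot-bracket + ΔG per sequence
```

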