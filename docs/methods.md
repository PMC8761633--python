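# Methods

## Folding model

Structures are nested (pseudoknot-free) secondary structures over the pairs
AU/UA, GC/CG, GU/UG. The free energy of a structure is the sum of its loop
decomposition terms:

* **stacks** — a 6×6 table of ΔG°37 values (kcal/mol). Watson–Crick
  entries follow the standard published nearest-neighbor set; GU-containing
  entries are plausible values of the right magnitude. The table is
  completed and verified under strand-flip symmetry
  (`stack[p1][p2] == stack[flip(p2)][flip(p1)]`).
* **hairpin / bulge / internal loops** — size-dependent penalties,
  tabulated to size 30 and extended by Jacobson–Stockmayer extrapolation
  `E(n) = E(n_max) + 1.75·RT·ln(n/n_max)` with RT = 0.616 kcal/mol (37 °C).
  Minimum hairpin loop: 3 unpaired nt. Bulges do not receive the adjacent
  stack bonus; 1×1 internal loops use the generic size-2 penalty (no
  special tables).
* **multiloops** — affine: offset 3.4, per-branch 0.4, per-unpaired
  0.1 kcal/mol. The per-unpaired cost is deliberately nonzero so that
  sliding an unpaired base around a multiloop changes the energy, which
  sharply reduces co-optimal degeneracy.
* **exterior loop** — free.

There are no dangling ends, coaxial stacks, or special hairpin sequences.
The model is intentionally desk-scale: small enough that exhaustive
enumeration can certify optimality on short sequences, while preserving the
*relative* ΔG ordering that every downstream analysis consumes. A test
cross-checks that ΔG ordering on hairpin cohorts agrees with a reference
thermodynamic folder (Spearman ρ ≈ 0.93 on 130-nt hairpins).

The MFE search is a Zuker-style dynamic program (interior loops capped at
30 unpaired total, the standard restriction) carried out on integer
centi-kcal energies so ties are exact. Tie-break among co-optimal
structures: most pairs first, then the lexicographically smallest
dot-bracket (`'(' < ')' < '.'`, plain ASCII order). The DP fill tracks the
(energy, −pairs) pair; the traceback resolves residual ties by comparing
candidate substrings, memoized per span, so the folder is a pure function
of sequence and model.

## Region-attributed ΔG

Every decomposition term carries a participant set (both closing pairs for
stacks and two-sided loops; the entire enclosed span for hairpin loops; the
loop-facing positions for multiloops). A term belongs to a coordinate
region only if **all** its participants lie inside; boundary-crossing terms
can be reported separately. This makes two identities exact by
construction, and both are asserted cohort-wide in the tests: the full
region reproduces the total ΔG, and regions tiling the molecule along
decomposition boundaries sum to it.

## Domain demarcation

With k = 3′ end of the (annotated or predicted) miR-5p, the terminal loop
region is [k+1, q−1] where q is the pairing partner of the last paired
position at or 5′-ward of k (scan-inward rule; an entirely unpaired miR-5p
is an error). Both anchor positions are excluded from the region — so a
fully unstructured loop region has ΔG exactly 0, and loop ΔG becomes
negative only through internal structure. The pre-miRNA spans miR-5p start
through miR-3p end; when one arm is unannotated it is predicted from the
pairing partners of the annotated arm's ends with the canonical 2-nt 3′
overhang register. The proximal domain is the 12-nt extensions beyond both
pre-miRNA ends (clipped at sequence bounds, with a warning); the distal
domain is everything further out.

Per-domain ΔG: loop, proximal and distal are region-attributed on the
pri-miRNA MFE structure (flanks are *not* refolded in isolation — refolded
flanks adopt non-native structures); the pre-miRNA ΔG refolds the pre-miRNA
subsequence (mirroring how pre-miRNAs are folded as their own molecules);
duplex ΔG is defined by subtraction, so ΔG(duplex) + ΔG(loop) = ΔG(pre)
holds to machine precision for every record.

## Motif windows and the mGHG table

Window defaults (all configurable): UG dinucleotide at −14/−13 relative to
the pre-miRNA 5′ end; UGU starting within the first 4 nt of the terminal
loop region; CNNC with its first C 16–18 nt downstream of the pre-miRNA 3′
end (presence/absence; overlapping occurrences count once; given strand
only). The mGHG determinant is scored by lookup on a structural key of the
3-nt window on the 3′ strand centered 5 nt below the 3′-side Drosha site;
each position contributes base plus partner base (or `.` if unpaired) from
the pri-miRNA structure. Published score values are external data supplied
as a TSV (`key`, `score`); the package ships only a synthetic placeholder
table covering the generator's planted window variants. Unknown keys return
a missing score — there is no nearest-key imputation — and analyses degrade
to pairwise-complete samples.

## Quantification and statistics

Raw cleavage ratio = product / (product + substrate) band intensity (an
empty lane is an error); relative efficiency = 100 × raw / control-raw
within each (enzyme, batch), so the control is exactly 100 and the scale is
invariant to overall lane intensity. Replicates are combined by mean
(median available). Expression per miRNA = 5p + 3p read sum after tissue
columns are combined (sum by default, mean available).

Spearman correlations are Pearson on midranks; p-values use the
t-approximation, replaced by full permutation enumeration at n ≤ 9.
Mann–Whitney U is two-tailed, tie-corrected normal approximation, replaced
by exact enumeration of labelings when both groups have ≤ 8 members (the
exact two-sided p counts labelings whose U deviates from its mean at least
as much as observed; symmetric under group swap by construction). Missing
values are deleted pairwise per comparison, so N differs across report
rows. No multiple-testing correction is applied to calls; a
Benjamini–Hochberg column is emitted for reference.

## Synthetic cohorts

The generator emulates the statistical structure of a processing study,
not sequencing reads or real energy distributions. Defaults (the study
conditions): 150 hairpins; mature arms 20–24 nt; terminal loops 4–28 nt;
basal stems 6–12 bp; 0–3 duplex mismatches; flanks 30 nt 5′ / 40 nt 3′
(matching how in-vitro pri-miRNA substrates are designed); motif planting
probabilities 0.5 each; eight mGHG window variants drawn uniformly.

Identifiability was a design requirement: a fully unpaired designed loop
or flank would make loop/distal ΔG constant, so large loops carry an inner
GC stem (≥ 4 bp) with probability 0.7 and the 3′ distal flank a small
hairpin with probability 0.5; and the synthetic mGHG scores are balanced
across paired/unpaired middle variants so the score is approximately
orthogonal to basal-stem stability (otherwise the planted mGHG and
proximal effects cancel along their shared axis).

Latent log-efficiency = β·z + ε, with z the cohort-z-scored ground-truth
features (domain ΔG of the *designed* structure, motif count, mGHG score),
β = (−0.5 proximal, +0.5 loop, −0.3 duplex, +0.2 distal, +0.3 motif,
+0.5 mGHG) and ε ~ N(0, 0.5²); the raw cleavage ratio is the logistic of
the latent, and lane intensities are back-computed from it under lognormal
lane totals. Expression is negative-binomial (dispersion 5) around
20 × relative efficiency / 100, split into 5p/3p arms and two tissue
columns. One `numpy` generator seeded once is threaded through all draws
in a fixed order, so a seed fixes the full output byte stream.

What passing tests show — and don't: recovery of planted effect directions
demonstrates that the pipeline's demarcation, attribution and statistics
are faithful to a known data-generating process whose rank structure they
should recover. It does not validate the energy model against experiment,
nor the biological magnitudes of the effects; real hairpins have isomiR end
heterogeneity, annotation error and cross-gel variation the generator does
not emulate.

## Evaluation harness sizes

The operating-characteristic checks use 100 independently seeded cohorts of
150 hairpins for null calibration (expected false-positive rate 0.05 at
α = 0.05, judged inside a three-sigma binomial band with a conservative
effective test count of four per cohort, since feature columns are
correlated) and for signed recovery (significant with the planted sign in
≥ 90/100 cohorts); 100 time-course cohorts of 20 substrates for
end-point/AUC agreement (per-cohort agreement means Spearman ≥ 0.9 between
the last-timepoint ratio and the trapezoidal AUC; ≥ 95/100 required); and
200 generated pre-miRNAs for the T7 rule (position-1 pair preserved after
refolding in ≥ 95%, idempotence always).

## Known limitations and open choices

* Only the single MFE structure is used; co-optimal alternatives and the
  thermodynamic ensemble are ignored.
* Whether the terminal loop region should include the anchoring pair's
  positions is ambiguous on biological grounds; both anchors are excluded
  here (the subtraction identity is unaffected either way).
* "Combined" multi-tissue expression is summed by default; a mean switch
  exists because the aggregation rule is not uniquely determined.
* Flank ΔG via region attribution (rather than refolding flanks alone) is
  a deliberate reading; the alternative is available for sensitivity
  analysis by folding subsequences directly.
* The human name/number < 1000 filter is a pragmatic annotation-quality
  proxy and parses ids of the `hsa-mir-N`/`hsa-let-N` shape only;
  unparsable human ids are excluded with a warning.
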