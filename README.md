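# lncwave

Classify transcripts as **long non-coding RNA (lncRNA)** or **protein-coding
RNA (pcRNA)** directly from sequence, using multi-scale wavelet features of
the transcript's charge-like signal together with classic coding-potential
features, fed to a random forest.

Long non-coding RNAs (> 200 bp, limited coding capability) resemble mRNAs in
length and composition, and annotation-free discrimination is a standard need
in transcriptome analysis, especially for poorly annotated species. lncwave
is for bioinformaticians who want a self-contained, reproducible classifier
that works from a FASTA file alone — no homology databases, genome
annotation, or ribosome profiling.

## Method

1. **Encoding.** Each base is mapped to a real amplitude (default: base
   pKa-derived values; an EIIP table is also shipped), turning the transcript
   into a numeric signal.
2. **Morse wavelet scalogram.** The signal's continuous wavelet transform is
   computed with the analytic generalized Morse wavelet

   φ(β, γ; ω) = U(ω) · a<sub>β,γ</sub> · ω<sup>β</sup> e<sup>−ω^γ</sup>,  (β, γ) = (20, 3),

   over 35 linearly spaced scales chosen so layer *j* reads as a *j*-base
   footprint.
3. **SCWS / SCWSS.** Coefficient magnitudes of layers 1–20 are summed
   column-wise into one power profile per base (SCWS); maximal runs strictly
   above the profile mean form the segment set (SCWSS). Seven features
   summarize it: segment count, length mean and variance, the mean of the
   corrected midpoint statistic FMid = ½(P<sub>end</sub> − P<sub>start</sub>)/P<sub>end</sub>,
   and three statistics gated by a 30-base length floor and a top-third
   length rank.
4. **Classic features.** Sequence length, GC%, stop-codon count dispersion,
   ORF integrity, a CDS score, CDS percentage, the isoelectric point of the
   longest-ORF peptide, and the Fickett TESTCODE statistic.
5. **Screen + classify.** Features with pairwise Pearson |r| > 0.8 on the
   training data are reduced to one representative; a 500-tree random forest
   does the classification. Evaluation reports ACC, SEN, SPE, MCC and the
   rank-sum (Mann–Whitney) AUC.

## Worked example

Because real training corpora are large downloads, the package ships a seeded
generator of two separable transcript classes — codon-biased long-ORF
"coding-like" vs GC-matched, ORF-suppressed "noncoding-like" — so the whole
pipeline runs out of the box:

```python
import lncwave as lw

cfg = lw.SynthConfig(n_per_class=50, seed=7)
seqs = lw.generate_dataset(cfg)
table = lw.assemble(seqs)                      # 100 x 15 feature table
kept = lw.correlation_filter(table, threshold=0.8)
print("retained:", len(kept), "features")
metrics, _ = lw.cross_validate(table, table["label"], feature_names=kept,
                               n_splits=5, seed=7)
print({k: round(v, 3) for k, v in metrics.as_dict().items()})
```

prints

```
retained: 12 features
{'tp': 50, 'fp': 0, 'tn': 50, 'fn': 0, 'acc': 1.0, 'sen': 1.0, 'spe': 1.0, 'mcc': 1.0, 'auc': 1.0}
```

i.e. the correlation screen removed three redundant columns, and 5-fold
out-of-fold classification of the 100 synthetic transcripts is perfect —
while GC content alone scores near chance (AUC ≈ 0.55), so the separation
comes from ORF and wavelet structure, not base composition.

The same workflow is available as a CLI:

```bash
lncwave simulate --n 500 --seed 7 --out synth.fa --labels synth.tsv
lncwave extract  --fasta synth.fa --out features.tsv
lncwave train    --features features.tsv --labels synth.tsv --out model.bin --seed 7
lncwave predict  --model model.bin --fasta synth.fa --out pred.tsv
lncwave evaluate --pred pred.tsv --labels synth.tsv
```

Every command writes a JSON manifest (resolved config + seed + version) next
to its output, and identical seeds give byte-identical outputs.

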