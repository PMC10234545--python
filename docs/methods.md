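# Methods

## Signal model

A transcript is treated as a non-stationary, charge-like one-dimensional
signal: each base contributes a real amplitude from a four-entry encoding
table. Two tables ship with the package:

- `pk_default` — pKa of the most acidic/basic ring nitrogen of each free
  base (A 3.5, C 4.2, G 9.2, T 9.7). This follows the idea of a
  pH-property translation of nucleotides; the exact numeric table used in
  prior art is unpublished, so the values are our documented choice.
- `eiip` — electron–ion interaction pseudopotentials
  (A 0.1260, C 0.1340, G 0.0806, T 0.1335).

All correctness guarantees (oracle agreements, invariances) are independent
of the table; the table only rescales and re-weights the signal, and the
table actually used is snapshotted into every trained model. U is unified to
T on input so RNA and DNA FASTA behave identically. Ambiguity codes are
dropped by default (`n_policy="drop"`); a seeded length-preserving random
replacement and a strict error mode exist for workflows that need them.

## Generalized Morse wavelet transform

The analytic generalized Morse wavelet is used in the frequency domain:

    phi(omega) = U(omega) * a * omega**beta * exp(-omega**gamma),
    (beta, gamma) = (20, 3)

- **Normalization.** `a` is fixed so the frequency-domain peak value is 2
  (the usual analytic-wavelet convention); the peak sits at
  `omega_p = (beta/gamma)**(1/gamma)`. Any positive constant would do — it
  cancels in the above-mean segmentation and only scales one feature
  (`30PwMean`), which the forest is insensitive to up to monotone rescaling.
- **Layer → scale map.** Layer j (1-based, 35 layers) gets scale
  `s_j = j * omega_p / (2*pi)`, i.e. the layer-j filter peaks at a j-base
  period, so layer indices read directly as base-length footprints. Spacing
  is linear, not dyadic, because layers are interpreted as base-length units.
  A consequence: layers 1–2 peak at or above the one-sample Nyquist
  frequency, so their on-grid response is only the filter's rising flank and
  is numerically negligible — sub-2-base periods are unresolvable at one
  sample per base. The informative band is layers ≈ 3–20.
- **Computation.** The signal is zero-meaned, padded, transformed with the
  FFT, multiplied by each layer's filter (negative frequencies zeroed — the
  wavelet is analytic), inverted and trimmed. L1 scale normalization (time
  domain `psi(t/s)/s`) keeps peak magnitudes comparable across layers.
- **Padding.** Default is reflection padding out to a power of two at least
  twice the signal length, which suppresses wrap-around leakage in the
  position features; `zero` and `periodic` (pure circular, used by the
  shift-covariance and convolution-oracle tests) are available via
  `wavelet.padding`.
- **Edge behavior.** Impulse energy localizes exactly (±2 samples at every
  layer) for positions at least one deep-layer kernel half-width (~60
  samples at layer 35) from either end; inside that margin, reflected
  boundary images can shift the deepest layers' maxima by a few samples.
  This only affects positional features of very short transcripts' extreme
  ends.

## SCWS profile and segment features

Magnitudes of layers 1–20 are summed per column (one power value per base,
SCWS). Segments (SCWSS) are the maximal runs of positions **strictly** above
the profile mean — strict, so a constant profile yields no segments rather
than one transcript-long segment. Seven features:

| feature | definition |
|---|---|
| Count | number of segments |
| LenMean | mean segment length (bases) |
| LenVar | population variance of segment lengths (`features.variance_mode` switches to sample variance) |
| MidMean | mean of FMid = ½(P_end − P_start)/P_end over segments |
| 30Count | segments in the top-third length rank with length > 30 |
| 30PwMean | mean segment power over that same subset |
| 30LenCount | mean length of all segments with length > 30 |

FMid uses 0-based positions with exclusive end; P_end is the segment's end
coordinate in the transcript, which is what bounds FMid in (0, 0.5] and makes
a whole-span segment score exactly 0.5. It needs no dataset-level
standardization, so a single transcript can be scored in isolation. The name
is historical — the quantity is half the segment's relative span, not a
literal midpoint.

The 30-base floor (strict `> 30`) reflects the nucleotide length of the
shortest known proteins, decoupling the gated features from transcript
length. "Top third" is read as: rank segments by length descending (ties:
earlier start first) and keep the top ⌈Count/3⌉. A literal alternative
reading (length > Count/3) is implemented behind
`features.third_rule = length_vs_count`; the top-rank reading is the default
because the high-energy short fragments it excludes come from the shortest
third of the 20 summed layers. All means over empty sets are 0, never NaN,
so feature vectors stay finite.

## Classic features

- **seq_len, GC_content** — direct.
- **Stop_std** — population standard deviation of the (overlapping)
  substring counts of TAA, TAG, TGA over the whole transcript
  (`features.stop_count_mode = per_frame_sum` restricts to codon-aligned
  counts summed over the three frames).
- **ORF detection** — forward-strand, three frames, ATG-only starts:
  candidates are each earliest unclosed ATG to its first in-frame stop, plus
  a terminal ATG-run without a stop; the longest span wins (ties: earlier
  start). Transcripts are assumed sense-strand, as is standard for
  coding-potential tools.
- **Orf_fullness** — 1.0 with both start and stop, 0.5 with exactly one,
  0.0 with no ORF. The three-level coding is our scheme.
- **CDS_Score** — a documented surrogate for the external txCdsPredict
  program: ORF span + 50 per present start/stop + 25 when the Kozak context
  (R at −3, G at +4) matches − 10 per in-frame internal stop (zero by
  construction). Strictly increasing in ORF length for complete ORFs. An
  adapter (`features.cds_mode = txcdspredict`) shells out to an installed
  txCdsPredict binary instead; scores from the two modes are **not**
  comparable, so the mode is recorded in the model bundle and prediction
  refuses a mismatched mode.
- **CDS_percent** — ORF span / transcript length × 100.
- **PI** — isoelectric point of the longest-ORF peptide (0.0 sentinel when
  there is none): Henderson–Hasselbalch net charge over N/C termini and
  D, E, C, Y, H, K, R with the EMBOSS-convention pKa set (shipped as an
  editable JSON data file), zero-crossing found by bisection on [0, 14] to
  1e−3 pH. Computed on the peptide because the feature is peptide-related;
  a nucleotide-level pI is not well defined.
- **Fickett_Score** — TESTCODE statistic: per base, codon-position
  asymmetry max/(min+1) and overall composition, each binned through the
  published lookup tables (shipped as JSON with explicit bin edges) and
  combined with the published weights.

## Feature screen and classifier

The 8 + 7 = 15 features are assembled in a fixed canonical column order.
Pairwise Pearson correlations are computed on the **training** data only;
scanning pairs in canonical order, the later-ordered member of any pair with
|r| > 0.8 is dropped (absolute value — an anticorrelated duplicate is
equally redundant; the fixed order makes the screen deterministic and
idempotent). Zero-variance columns have undefined correlations, treated as
r = 0 and logged. The retained set is frozen into the model bundle and
reused verbatim at prediction time, preventing test-set leakage.

The classifier is a 500-tree random forest with sqrt-features per split and
a fixed seed; lncRNA is the positive class. Hyperparameters are deliberately
plain — the features, not the model, carry the method. Metrics: ACC, SEN,
SPE, MCC from the thresholded confusion counts (threshold 0.5, exposed as a
flag) and AUC in the rank-sum form
`(Σ positive ranks − ½M(M+1)) / (MN)` with ascending midranks for ties,
which equals Mann–Whitney pair counting with half credit for tied scores.
Degenerate single-class inputs give NaN AUC/MCC with a warning rather than
an exception.

## Synthetic benchmark

The generator emulates the one property that separates the classes
biologically — coding structure — while deliberately matching composition:

- **Coding-like** (label pcRNA): uniform length in 250–3000 bp; a planted
  complete ORF covering ~60% of the transcript (ATG + codons drawn from a
  skewed human-like usage table blended 0.75:0.25 with uniform, stops
  excluded + stop codon), flanked by i.i.d. UTRs at GC 0.5. The last three
  5'UTR bases are an in-frame stop, so upstream chance ATGs cannot extend
  the planted ORF (without this guard ~1/3 of transcripts would grow a
  longer fused ORF).
- **Noncoding-like** (label lncRNA): i.i.d. bases at the coding class's
  analytically expected GC (compensated for the AT-rich planted stops), with
  a stop codon seeded into every ≤90 bp block of every frame, capping chance
  ORFs near twice the 30-codon floor.

On the default seeded set the classes' mean GC differs by < 0.5 percentage
points and GC alone scores AUC ≈ 0.55, while the full pipeline's 5-fold CV
accuracy and AUC are ≈ 1.0 — i.e. the tests certify that ORF and wavelet
structure, not composition, drive the classification. What this does **not**
show: performance on real transcriptomes, where lncRNAs carry residual
ORFs, splice isoforms, repeats and homology structure the generator does not
model; the synthetic task is intentionally cleaner than NONCODE-scale data,
and published per-species accuracies cannot be verified without those
corpora.

## Problem sizes and numerical choices

The shipped tests and the acceptance script use 500 transcripts per class
(5-fold CV, ~1000 CWTs of up-to-3000-bp signals), segmentation/ORF/AUC
oracle sweeps of 500–1000 random instances, and convolution-oracle checks on
signals ≤ 128 samples — sizes chosen so the full suite runs in well under a
minute per stage on one CPU while exercising every code path. Bisection
tolerance 1e−3 pH; CWT oracle agreement 1e−8 relative; all RNG flows from
explicit integer seeds (numpy `default_rng`), and every artifact-producing
command records its resolved configuration in a manifest, making runs
byte-reproducible.

## Known limitations

- Forward-strand ATG-initiated ORFs only; no CUG/GUG starts.
- The Morlet wavelet alternative is a reserved config hook, not implemented.
- Surrogate CDS scores are on a different scale from txCdsPredict's; models
  trained under one mode refuse features from the other but cannot convert.
- Layer scales are a designed map (layer ≈ base footprint), not a claim of
  bit-compatibility with any other scalogram implementation.
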