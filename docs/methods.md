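# Methods

## Model and assumptions

The method assumes that common-variant genotype structure is locally
block-like: recombination is rare within a haploblock, so a block's
dosage rows concentrate on a small number of haplotype-pair clusters.
Compression then factorizes per block — one autoencoder per block, no
parameters shared across blocks — which keeps the embedding
interpretable at the block level and the training embarrassingly
parallel. Long-range dependence beyond the scan window is deliberately
out of scope.

Inputs are unphased diploid dosages. Filtering is fixed and ordered:
drop variants with any missing call, recode additively so each column
counts the minor allele (ties at frequency exactly 0.5 keep the ALT
allele as counted), then drop variants with MAF ≤ 0.01. MAF is computed
once on the full sample set, before any train/test split.

## Pairwise LD and block detection

Two-locus haplotype frequencies come from an EM over the 3×3 dosage
table; only the double-heterozygote cell is phase-ambiguous.
Convergence: max frequency change < 1e-7 or 1000 iterations. From the
fitted frequencies, D = p_AB − p_A·p_B, D′ = |D|/D_max, and
r² = D²/(p_A(1−p_A)p_B(1−p_B)).

The D′ confidence interval profiles the multinomial likelihood over a
101-point grid on [0, 1] with allele frequencies fixed at their sample
MLEs and the sign of D taken from the EM estimate; likelihoods are
normalized to a unit mass and the central 90% interval is read from the
cumulative mass. No small-sample shortcut tables are used — the full
profile is always computed (simpler, testable, asymptotically
equivalent). Pairs with a monomorphic locus are non-informative rather
than errors.

Classification thresholds (calibrated for long blocks): strong LD when
ci_low ≥ 0.5 and ci_high ≥ 0.85; strong recombination when
ci_high < 0.7; window 10 Mb; informative-fraction threshold 0.95
(detector default); blocks need ≥ 2 SNPs. Candidate spans must have a
strong-LD outermost pair; acceptance requires the strong-LD share of
informative pairs to reach the threshold; candidates are taken greedily
by descending SNP count with ties to the leftmost start, discarding
overlaps. The implementation precomputes the pair-class matrix within
the window and evaluates span acceptance with 2-D prefix sums; a
brute-force enumerator over all contiguous spans serves as the test
oracle on small panels.

"Average pairwise LD" of a block is the mean r² over all within-block
pairs (r² is the correlation measure used for pruning decisions in this
field; mean D′ is available behind a flag).

## Autoencoder family

Widths follow n(l) = bn + (input_dim − bn)·(|l|/(hl+1))^p with
n(0) = bn and n(±(hl+1)) = input_dim exactly; p = 0 (rectangular) or
0.5 (elliptic); rounding is half-away-from-zero. The bottleneck is set
to bn by definition, which also sidesteps 0⁰ at p = 0.

Layers are fully connected, He-uniform initialized from a per-block seed
derived as adler32(global_seed, block_id) (reproducible and independent
across blocks). Hidden activations are leaky ReLU with slope 0.3. The
slope matters: with a small slope (e.g. 0.01), a bottleneck unit whose
pre-activations start all-negative passes ~1% of its gradient and can
stay dead for an entire training run, collapsing the embedding — we
observed exactly this on easy high-LD blocks. Slope 0.3 (the common
Keras default) keeps gradient flowing through the narrow bottleneck.
The output activation is r(x) = tanh(x) + 1, so raw reconstructions lie
in the open interval (0, 2); inputs are raw dosages 0/1/2 with no
scaling, matching that range.

Training: Adam (lr 1e-4, β = 0.9/0.999, ε = 1e-8) on MSE, batch 32,
samples reshuffled every epoch from the per-block seed, no early stopping,
schedule or weight decay. The default recipe runs 50 epochs — adequate
at cohort scale (where one epoch is thousands of updates). The backward
pass was verified against finite differences (max relative error
~4e-8).

Blocks no wider than their bottleneck pass through uncompressed
(ratio 1.0) and are excluded from training, as are singleton SNPs,
whose raw dosages are appended to the embedding.

## Evaluation protocol and desk-scale calibration

All reported evaluations run on synthetic panels with n = 2000 samples
and an 80/20 train/held-out split; test samples are never seen by any
autoencoder fit or PCA basis (verified by a leakage test). At this
scale one epoch is only 50 updates, so the evaluation protocol trains
each block for 150 epochs — the point where loss curves plateau on
these panels, and still ~16× fewer updates than the 50-epoch recipe
performs at cohort scale. The recipe default remains 50 epochs; the
protocol passes its epoch count explicitly.

SNP accuracy rounds predictions half-up to {0, 1, 2} and compares
entry-wise, with per-dosage and (when labels exist) per-phenotype
breakdowns. Chromosome accuracy is the block-size-weighted mean of
block accuracies, equal to pooled per-variant accuracy. The PCA
baseline fits the top-k principal directions (k = bn) on the training
samples only, reconstructs with training means, and clips to [0, 2]
before rounding so both methods share the accuracy domain (an unclipped
mode exists for sensitivity analysis).

## Hyperparameter protocol

The grid spans bn 1–10 × hl 1–5 × {elliptic, rectangular} (100 cells)
under 5-fold CV with seeded, unstratified folds; cells with bn wider
than the block are skipped and flagged. Ties prefer smaller hl, then
elliptic — cheaper models at equal accuracy. The elbow over bn is
formalized as the first bn whose marginal accuracy gain falls below
0.002 (bracketing the ~0.0016 gain observed where the trade-off levels
off); the published analysis identifies the elbow visually, so this
threshold rule is an explicit stand-in. The standardized selection is
elliptic, hl = 4, bn = 2 if average pairwise r² > 0.4 else 3 (strictly
"above": the boundary value takes the wider bottleneck). One-tailed
paired t-tests (same blocks under both settings) back the
simplification; zero-variance difference vectors are degenerate and
reported not significant by convention.

## Synthetic data

The generator instantiates the few-distinct-haplotypes structure
directly rather than through a coalescent simulation: each block draws
K founder haplotypes, every individual samples two founders i.i.d. from
the founder frequencies (a symmetric Dirichlet draw by default), and
each inherited allele flips with rate ε (default 0.002, consistent with
sub-1% genotyping-error rates in imputed panels). Crucially, each SNP's
minor allele is carried by a *clade of a random founder genealogy*, so
founders form a perfect phylogeny and within-block |D′| = 1 before
noise — the same property real haploblocks owe to their shared mutation
history, and the property the confidence-interval criterion detects.
(Assigning alleles to arbitrary founder subsets instead violates the
four-gamete condition so often that the detector — correctly —
fragments the blocks.) Columns whose realized MAF falls below the floor
(default 0.05) are redrawn; frequency/genealogy draws are jointly
rejected when the floor is unattainable.

Panels concatenate independent blocks with 1 Mb gaps and 1 kb SNP
spacing (so a 10 Mb window spans several blocks) and carry ground-truth
boundaries. The chromosome-scale fixture uses 50 blocks with
log-normal sizes (mean ≈ 25 SNPs, positively skewed, as real block-size
distributions are) and K uniform on [2, 6] so average pairwise r² spans
both sides of the 0.4 selection threshold. `calibrate_ld` bisects ε
(scanning K upward) to hit a target average r² within ±0.05.

What the simulator does *not* model: population structure and
relatedness, rare variants, genotyping-error correlation, recombinant
haplotypes within blocks, and inter-block LD leakage. Passing tests on
these panels therefore demonstrate correctness of the machinery and the
qualitative claims (nonlinear beats linear on multi-cluster blocks;
high-LD blocks compress to 2 dimensions), not cohort-scale accuracy
figures.

## Numerical choices and degenerate inputs

- Width and prediction rounding: half-away-from-zero ("nearest").
- CI grid 101 points; values at the grid resolution (0.01) are exact.
- EM tolerance 1e-7, cap 1000 iterations; frequencies sum to 1 within
  1e-9.
- Dosage ties at exactly x.5 round up.
- Monomorphic loci, singleton blocks and blocks narrower than bn are
  flagged/pass-through, never errors mid-pipeline.
- All randomness flows from explicit integer seeds; per-block seeds are
  hashes of (global seed, block id), keeping block results independent
  of panel composition.

## Known limitations

- At n = 2000 the hardest (lowest-LD, K = 6) blocks plateau near
  98–98.5% held-out accuracy even with extended training: rare
  founder-pair clusters are underrepresented in 1600 training samples,
  and the ε noise ceiling (~1 − 2ε ≈ 99.6%) caps all reconstructors.
  Cohort-scale sample sizes are what push such blocks above 99%.
- Block boundaries may differ from PLINK's Haploview implementation on
  edge cases (PLINK applies small-sample CI heuristics this package
  replaces with the full likelihood profile).
- Training is single-threaded numpy; the per-block independence makes
  coarse parallelism trivial but none is built in.
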