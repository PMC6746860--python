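# Methods

This note records the models, conventions, numerical choices and known
limitations of the package, in the order data flows through the pipeline.

## Genotype space conventions

A genotype over `N` biallelic positions is an index in `[0, 2^N)`; bit
`k` encodes position `k+1`, so position 1 is the least-significant bit and
vectors "in binary order" are ordered by ascending index.  Allele 0 is the
blue-parent state and allele 1 the red-parent state: the blue parent is
index 0 and the red parent index `2^N − 1`.  This orientation is a
convention — the underlying mathematics is symmetric under relabelling —
but every sign-sensitive result in the package (first-order term signs,
alignment encoding, the single-reference default reference) is stated and
tested against it.  Genotype strings in files put position 1 leftmost.

## Epistasis operators

The operator recursions index the most-significant bit in the outer 2×2
block, which makes each generator the `N`-fold Kronecker power of its
2×2 block: `V = diag(1/2, −1)^{⊗N}`, `H = [[1,1],[1,−1]]^{⊗N}`,
`X = [[1,0],[1,1]]^{⊗N}`.  Hence

* background-averaged `Ω = VH = [[1/2,1/2],[−1,1]]^{⊗N}` with inverse
  `Ω⁻¹ = H V⁻¹ / 2^N = [[1,−1/2],[1,1/2]]^{⊗N}`,
* single-reference `Ω = VXᵀH = [[1,0],[−1,1]]^{⊗N}` with inverse exactly
  `X`.

The Kronecker structure gives an O(N·2^N) in-place butterfly for all
forward and inverse transforms (`fast_transform`); the dense operators
(used as the independent oracle in tests, N ≤ 8) contain only dyadic
rationals, so dense and fast routes agree to machine precision and
inverses are analytic, never numerically inverted.  The verification
anchor is the hand-computed N = 1 pair: `Ω_ba = [[1/2,1/2],[−1,1]]`,
`Ω_sr = [[1,0],[−1,1]]`.

A single-reference transform around a reference `r ≠ 0` is computed by
XOR-relabelling the cube (`rereference`, an involution) and applying the
index-0 operator, rather than rebuilding `X` — one operator, one testable
permutation.

Sign convention consequence (tested by brute force): the
background-averaged first-order term of position `j` equals the average
over all `2^(N−1)` backgrounds of `y(bit_j = 1) − y(bit_j = 0)` — i.e.
positive terms mean the red-parent allele raises the phenotype.

### Term ranking

"Contribution" of term `i` is `c_i = ω_i² · ‖col_i(Ω⁻¹)‖²` with
`‖col_i‖² = 2^(N−2·order)`.  Because the columns of the
background-averaged `Ω⁻¹` are mutually orthogonal, contributions are
exactly additive: the SSE of a reconstruction from any kept set equals
the sum of `c_i` over dropped terms, so ranking by `c_i` makes top-`k`
R² non-decreasing in `k`.  Ties (rare in data, common in degenerate
fixtures) break by ascending order then ascending index, for determinism.
Whether this metric replicates any particular published ordering of terms
is unknowable from printed material; it is the unique ordering that is
exactly greedy for nested reconstruction error.

## Significance

Per-variant measurement SDs propagate linearly:
`sd(term_i)² = Σ_j Ω_ij² σ_j²`, computed without densifying via the
butterfly of the elementwise-squared block.  For homoscedastic σ this
collapses to `σ·2^(o−N/2)`, the closed form the tests pin to 1e−12.
Terms are scored `z = value/sd` with two-sided normal p-values and
selected at raw `p < 0.01` — deliberately uncorrected, matching the
published procedure; a Benjamini–Hochberg option exists but is off by
default.  The order-0 term (mean or reference phenotype) is never tested.
Type-I calibration is verified by simulation: on pure-noise landscapes the
selected fraction sits at the nominal rate within 3 binomial SDs.

## Compressed-sensing recovery

Observed phenotypes are linear functionals of the spectrum through the
sampled rows of `Ω⁻¹`.  The estimator solves basis-pursuit denoising

    min ‖ω‖₁   s.t.   ‖A ω − y_obs‖₂ ≤ ε.

Column norms of the weighted basis scale as `2^((N−2o)/2)`, which would
bias the L1 objective against high-order terms; columns are therefore
normalised to unit norm before solving and the scaling undone afterwards
(a raw-basis mode exists; which variant the original analysis used is not
determinable, so the restricted-isometry-friendly normalised mode is the
default).  Solvers: ε = 0 is the classical basis-pursuit linear program
(HiGHS); ε > 0 is solved on the lasso path by bisecting the coordinate-
descent penalty to the smallest value whose residual meets ε — the BPDN
solution lies on that path, and the bisection brackets it to 1% in the
penalty.  Default ε = `sd·sqrt(n_sampled)` when the noise SD is known
(the expected residual norm of pure noise).

Recovered support is read in the unit-column basis (term magnitudes
weighted by `2^((N−2o)/2)`), with a relative floor of 2% of the largest
weighted magnitude: "in the support" means "contributes detectably to the
observations", which is the scale on which both the solver and the data
operate.

The reference recovery experiment (also in the acceptance script):
N = 10, 20 planted terms of equal magnitude and random sign spread over
orders 1–5, observation noise at a signal-to-noise *amplitude* ratio of
20 (≈26 dB — equal-magnitude spikes and amplitude-ratio SNR are the
standard compressed-sensing benchmark design), 15% uniform sampling.
Median support precision and recall and median held-out GoP over 20 seeds
are the reported statistics.  With Gaussian rather than fixed magnitudes
many planted terms are arbitrarily small and no method can recover them;
that regime is exercised in unit tests but not used as a recovery
benchmark.

## Alignment estimators

Thresholding at `y > t` (strictly, matching the published `y > 0.73`
usage) and encoding allele 0 → +1, allele 1 → −1 gives an alignment of
functional sequences.  The estimators
`ω_i^aln = φ_i·2N_func/N_tot` and `ω_ij^aln = φ_ij·4N_func/N_tot` are,
up to a factor `(−1)^order` induced by the −1 encoding of allele 1,
*exactly* the order-1 and order-2 background-averaged terms of the
indicator landscape `F(g) = 1{y(g) > t}` — an identity, not an
approximation, and the module's central test.  The convention-adjusted
values (default) multiply order-`o` terms by `(−1)^o` so both modules
report the same quantity; raw values are available because the published
axis convention for these plots is not stated.  FASTA export uses a
two-letter alphabet with `n_total` and the threshold in a `;` comment
line, since an alignment alone determines neither.

## Trajectory topology

The functional subgraph keeps genotypes with `y > t` (default t = 0.73,
the red-parent brightness) and hypercube edges between them.  `m`-step
trajectory counts are entries of the `m`-th adjacency power, computed by
propagating an integer indicator vector through the edge set in exact
Python-integer arithmetic — at `N = 13` the unpruned antipodal count is
13! = 6,227,020,800, beyond what float matrix powers represent exactly.
These counts are walk counts (revisits allowed for `m` beyond the Hamming
distance, as the matrix-power definition implies); for antipodal endpoints
at `m = N` walks coincide with direct paths.

Per-layer connectivity between antipodal parents uses two monotone
dynamic-programming passes (paths counted from each end); a genotype is
"on a path" when both its incoming and outgoing functional direct-path
counts are positive.  The layer fraction divides by the full layer size
`C(N,k)`, not by its functional subset, so the fractions express absolute
constriction of the solution space.

Pairwise epistasis classes on a 2×2 sub-square (fixed background) compare
the two conditional effects of each mutation with tolerance 1e−9:
both flip sign → reciprocal sign; one flips → sign; neither flips but
effects differ → magnitude; else none.  Aggregation over backgrounds
reports per-class fractions and the modal class (ties resolved toward the
more severe class), since whether published per-pair statistics were
computed per-background or on averaged squares is not stated.

## FACS-seq preprocessing

Enrichment `E_a` is the pooled ratio Σout/Σin over retained uniqueness
barcodes: the Z-score formula treats `E_a` as a common rate applied to
each barcode's input, which the pooled ratio estimates; the printed
summation is typographically ambiguous and a mean-of-ratios mode sits
behind a flag.  Outlier rejection iterates (default 3 rounds): score each
barcode `Z = (n_out − E_a·n_in)/(E_a·n_in)^(1/β)` with β = 1/0.35 and
reject outside `(−c₂, c₁) = (−15, 35)`.  One deviation from a literal
reading: the rate used for *scoring* is the median of per-barcode ratios
(falling back to the pooled ratio where the median is zero, near the
detection limit) rather than the pooled ratio itself — a single ×100
barcode otherwise drags the pooled rate enough to mask itself partially
and swamp every clean barcode in its group (a standard failure of
simultaneous outlier deletion).  The final reported enrichment remains
the pooled ratio over retained barcodes.  Bootstrap-over-barcodes SDs
accompany each enrichment.

Channel normalization rescales red-channel enrichments by one factor so
the red parent's red enrichment over the blue parent's blue enrichment
equals `(25.0e3/32.4e3)·0.222` (= 0.772·0.222 ≈ 0.172; the printed
product is a rounding of unrounded intermediates, so the package carries
the factors, not the rounded product).  Channels then combine as
`x = sqrt(E_blue² + E_red²)`, and phenotypes are reported relative to the
blue parent's combined value — no attempt is made to anchor the absolute
scale of published brightness values, which is not derivable from the
printed constants.

The global assay nonlinearity is removed by `y = x^α`, α chosen by
bounded scalar minimisation (tolerance 1e−4, bounds 0.05–2.0) of
`‖f(x) − Ω⁻¹SΩ f(x)‖²/var(f(x))` with `S` keeping orders ≤ 2: the
exponent under which the landscape is closest to low-order-epistatic.
Pseudocount regularisation is a deterministic clamp of values below a
detection floor to that floor (monotone, reproducible); the published
pseudocount scheme is described only qualitatively, and a clamp is the
simplest monotone regulariser consistent with it.

The 4-base segment barcode check validates the parity base (sum of the
first three base values mod 4) under the alphabetical map A=0, C=1, G=2,
T=3 (configurable; the published map is not stated).  Parity detects
every single-base substitution.

## Synthetic data

`simulate_sparse_landscape` plants `K` distinct nonzero terms with order
probabilities proportional to `order_weights` (default: triangular
profile peaking at order 3–4, echoing the observed unimodal shape of
significant-term counts), magnitudes fixed/normal/laplace at a given
scale, inverts to phenotypes, and adds Gaussian noise; the noiseless
transform returns the planted truth exactly (tested).

`simulate_counts_experiment` emulates the sorting assay: clone abundances
from one Dirichlet draw (concentration 5 — moderate library imbalance);
input reads multinomial over clones; per-cell log-fluorescence normal
around the allele's channel brightness with SD 0.8 (per-cell FP
expression noise in bacteria is large, of order one natural-log unit);
the channel gate at the top 1% (the published gating fraction) of a
2×10⁵-cell Monte-Carlo draw from the population mixture; output counts
Poisson around `n_in · tail_mass/gate_fraction`; planted outlier barcodes
multiply the expected output by 100.  A genotype fluoresces red iff the
chromophore bit (position 3) and one co-required bit (position 5) carry
allele 1 — purely a fixture convention imitating a chromophore mutation
that is necessary but not sufficient; the off channel keeps a 2% residual.
What the simulator does *not* model: sequencing error, barcode collisions,
growth-rate differences, cell doublets, and spectral overlap beyond the
constant residual — so passing end-to-end tests demonstrates correctness
of the estimator chain under the stated noise model, not robustness to
every artefact of real sequencing data.

An outlier planted on a barcode whose clean expected output is ≈0 changes
nothing observable (100 × 0 = 0); end-to-end checks therefore quantify
removal over outliers with clean expected output ≥ 1 read, and rank
fidelity (Spearman vs true brightness) over a landscape spanning two
decades of brightness — below the sorting detection limit ranks are
unidentifiable in principle, a property of single-gate FACS-seq rather
than of the estimator.

`simulate_two_parent_landscape` interpolates between a smooth symmetric
ridge (both parents bright, shallow dip mid-cube) and heavily pruned
landscapes: each intermediate genotype is independently demoted below
threshold with probability equal to `ruggedness`.  Parents always stay
functional; connectivity between them is deliberately not guaranteed.

## Problem sizes and determinism

Dense-operator oracles run at N ≤ 8, DFS path-enumeration oracles at
N ≤ 6, the CS benchmark at N = 10 with 20 seeds, significance
calibration over 200 null landscapes at N = 8, and the preprocessing
simulation at N = 8 with 20 barcodes/allele and 10⁶ reads per channel —
sizes at which every statistical check is comfortably resolved while the
whole suite runs in seconds.  Every stochastic routine takes an explicit
seed, and the acceptance script derives all of its per-trial seeds from
the single `--seed` argument.

## Known limitations

* Published dataset-bound numbers (260 significant terms, R² = 0.98,
  2032 functional sequences, 1.36×10⁵ functional paths, α = 0.44) require
  the deposited raw reads and are not reproduced; the package verifies the
  corresponding *procedures* on synthetic ground truth instead.
* The originally used error-propagation recipe and pseudocount scheme are
  not described at a level of detail that fixes an implementation; linear
  propagation with normal theory and a deterministic clamp are this
  package's choices.
* Single-reference spectra for references other than a hypercube vertex,
  multi-allelic positions and indels are out of scope.
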