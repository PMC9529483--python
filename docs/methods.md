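# Methods

This note describes the models and procedures implemented in `netplast`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic validation does and does not establish about real data.

## Analysis model

The pipeline treats the brain as an undirected graph: atlas regions (ROIs) are
nodes; statistical dependence between regional time series defines edges.

**Connectivity.** For each subject, the functional connectivity (FC) matrix is
the Pearson correlation `r_ij` between the ROI time series, with the diagonal
fixed at 0 (the self-correlation carries no information and has an infinite
Fisher transform). The Fisher transform `z = atanh(r)` is applied before any
t-testing, since z-values are approximately normal with variance depending
only on the effective number of independent time points.

**Binarization.** An absolute threshold `T` defines edges: `(i, j)` is an edge
iff `r_ij > T` (strict inequality). Negative correlations never form edges by
default; an `|r|` mode exists but is off. Thresholding operates on the
Pearson-space matrix (a monotone transform, so thresholding the z-matrix at
`atanh(T)` is identical — a property the tests verify). Sweeping
`T ∈ [0.02, 0.58]` in steps of 0.02 gives 29 networks per subject.

**Graph metrics** (binary, undirected; implemented from first principles and
cross-checked exactly against networkx and brute-force path enumeration):

- degree `k_i = Σ_j e_ij`;
- clustering `C_i = e_i / (k_i(k_i−1)/2)` with `C_i = 0` when `k_i < 2`;
- geodesic distances by simultaneous breadth-first search; unreachable pairs
  are infinite;
- per-node and characteristic path length averaged **over reachable pairs
  only**, with the count of unreachable pairs reported — sparse high-threshold
  networks are routinely disconnected and the textbook formulas silently
  assume connectedness;
- betweenness `B_i = Σ φ_jm(i)/φ_jm` over unordered pairs, raw (unnormalized)
  fractional counts, computed with Brandes single-source accumulation; a
  normalized variant divides by `(n−1)(n−2)/2`;
- global efficiency `E_glob = mean of 1/l_ij` with `1/∞ = 0`; the per-node
  mean of inverse distances is the nodal efficiency used for rankings;
- local efficiency: `E_glob` of the subgraph induced by each node's
  neighbours, 0 when `k_i < 2`.

**Small-world coefficients.** `γ = C_net/C_random`, `λ = L_net/L_random`,
`σ = γ/λ`, with the random reference an ensemble of degree-preserving
double-edge-swap rewirings (the field-standard null when no generator is
specified): default 10 swap attempts per edge, 20 nulls (5 in the sweep, where
many networks are processed). Null path lengths use the same reachable-pairs
convention. On networks where no valid swap exists (e.g. a triangle) the input
is returned unchanged with a warning flag. Degenerate cases (zero null
clustering, undefined path length) yield a flagged undefined result rather
than an exception. Null seeds are shared across groups per threshold so group
contrasts are never null-sampling noise.

**Modularity.** `Q = (1/2m) Σ_vw [A_vw − k_v k_w/2m] δ(c_v, c_w)`. Detection
uses Newman's leading-eigenvector method: recursive bisection by the sign of
the leading eigenvector of the generalized modularity matrix, each bisection
refined by a Kernighan–Lin pass (every node tentatively moved once, best gain
first, best prefix kept), recursion stopping when no split increases Q,
followed by a greedy merge pass that undoes unprofitable over-splitting.
Components of a disconnected network are treated independently (under the
global null model, merging two components always lowers Q). Tie-breaks:
eigenvector entries that are exactly zero go to the positive side; scans are
in ascending node index; the dense symmetric eigensolver is deterministic —
so partitions are bitwise reproducible. Greedy agglomeration is not offered;
the spectral method was chosen because it is deterministic and testable.
Partition similarity is quantified by NMI and adjusted Rand index
(scikit-learn) plus a module-overlap contingency table and greedy best-match
Jaccard overlaps.

**Group statistics.**

- *Sweep comparisons*: per-threshold Welch two-sample t-tests on
  subject-level global metrics; the Bonferroni family is the 29-threshold
  grid. Welch is the default because real cohorts have unequal group sizes;
  the pooled test is selectable and agrees with Welch to 1e−10 on balanced
  equal-variance data (tested).
- *Threshold gate*: admissible thresholds keep group-mean degree `⟨k⟩ ≥ ln N`
  and `σ > 1` in both groups; the maximal admissible threshold is the natural
  single analysis threshold. An empty admissible set is an explicit result
  and single-threshold stages refuse to run.
- *Statistical network* (within group, one threshold): an edge survives iff a
  one-sample t-test of the subjects' Fisher-Z values against 0 rejects at the
  Bonferroni-corrected level over all `n(n−1)/2` pairs **and** the group-mean
  correlation exceeds the threshold. The conjunction reproduces both stated
  ingredients of the design (edge-level significance; `T = 0.4`) without
  inventing a third; each component can be disabled individually. The
  Bonferroni family is recorded in the network metadata.
- *Nodal rankings*: top-k (default 50) nodes per metric, ties broken by
  ascending node index, displayed values affinely normalized to [0.1, 0.9]
  over the displayed set (constant sets map to 0.5).
- *Differential network* (between groups): per-edge Welch t on Fisher-Z,
  Benjamini–Hochberg FDR across all node pairs at q < 0.05; surviving edges
  labelled enhanced/weakened for group B by the sign of the mean difference.
  Swapping group labels negates every t and flips every label while leaving
  p and q unchanged (tested).

## Synthetic cohorts

The generator emulates preprocessed resting-state ROI signals — the pipeline's
entry point — not raw fMRI: band-limited Gaussian fluctuations (0.01–0.08 Hz
at TR = 2 s, 230 timepoints by default) with a planted modular correlation
structure.

Each group's target correlation matrix is built from a modular factor
parameterization: node `i` in module `m` has loading `a_i` evenly spread
(±15% by default) around `sqrt(c_m)` where `c_m` is the module's intra
coupling; within-module correlations are `a_i a_j` and between-module
correlations `a_i a_j ρ_mm'` with the latent correlation `ρ` set to hit the
requested mean inter coupling. Group effects add deltas at intra-, inter-, or
explicit-pair scope. Signals are drawn as `x = M w` with `M Mᵀ = C` (symmetric
matrix square root) and `w` independent unit-variance Gaussian series
band-limited by FFT masking — so the population correlation matrix equals the
target exactly and all power stays in the band (> 95% verified by
periodogram). For pure block targets the matrix square root reduces to the
classic mixing `x = a·s_module + sqrt(1−a²)·noise`; the matrix form is used
because pair-level effects cannot be expressed through shared module factors.
Non-PSD parameterizations raise an error naming the offending module block.
Per-subject seeds derive counter-style from the master seed (master, group
index, subject index) and are recorded in the cohort manifest, so any subject
is reproducible in isolation.

Default conditions: 30 subjects per group; 128 nodes in 8 equal modules (a
desk-scale stand-in for a 1024-ROI parcellation; node count is a knob); intra
coupling 0.45, inter coupling 0.10. These were fixed once, by design
computation: with ~230 band-limited timepoints the sampling SD of a subject
correlation is ≈ 0.12, so intra 0.45 puts subject-level mean degree at
`T = 0.4` above the `ln(128) ≈ 4.85` gate while group-mean intra correlations
straddle 0.4 (so the statistical network is non-empty and block-connected),
and the ±15% loading spread provides the heterogeneity of edge strengths that
real FC matrices show.

**Canonical patient-like contrast** (`adhd_like_spec`). Group "adhd" differs
from "control" by: (i) globally weakened long-range inter-module coupling
(0.10 → 0.02); (ii) mildly strengthened short-range intra-module coupling in
the six surviving modules (+0.03); (iii) dissolution of the last two modules —
intra coupling drops toward background (0.45 → 0.15) and only diffuse residual
coupling (0.08) to the surviving modules remains. Component (iii) is the
reorganization mechanism: purely weakening inter coupling cannot change the
detected module count (inter coupling never approaches the analysis
threshold, so both groups' statistical networks decompose into the same
planted blocks), whereas dissolving modules removes their statistical-network
edges entirely and the patient group presents fewer modules of two or more
nodes, lower clustering, and lower degree simultaneously. Module counts are
compared over modules with ≥ 2 nodes, because isolated statistical-network
nodes carry no modular information.

The sweep-band assertions of the end-to-end test use thresholds
`T ∈ [0.04, 0.16]`: design simulation shows this is the regime in which
inter-module edges are prevalent in the average network (T below the intra
coupling), where the planted contrast expresses as lower clustering, lower
degree and a larger σ in the patient-like group; at high thresholds only
intra-module edges survive and the control group's intact eight-module
structure dominates σ instead.

**What the generator does not emulate** — and hence what passing tests do not
establish about real data: no head motion, scanner drift or physiological
artifacts; no hemodynamic response convolution or autocorrelation structure
beyond band-limiting; no spatial geometry (module assignment is arbitrary, so
"long-range" means inter-module, not Euclidean distance); no heavy-tailed or
negative-correlation FC structure; equal group sizes and homogeneous subjects
(no covariates such as age, sex or motion). Passing the suite establishes that
the statistics are calibrated and the topology measures correct, not that the
planted effect sizes match any clinical population.

## Numerical and operational choices

- Sweep σ and the threshold gate are computed on each group's binarized
  mean-correlation network (5 nulls per threshold, shared seeds); per-subject
  rewiring across the whole cohort × grid would cost orders of magnitude more
  swap operations for the same gate decision. Per-subject σ remains available
  through `small_world` on any network.
- Metric sweeps, by contrast, are strictly per subject: metrics are computed
  on each subject's networks and averaged, which is what gives the two-sample
  tests their sample size.
- Problem sizes in the validation suite (128-node cohorts, 16-node calibration
  replicates, n ≤ 8 oracle graphs) were chosen so the whole suite completes in
  a few minutes while keeping every statistical check at conventional
  replicate counts (500–1000).
- Monte-Carlo checks of nominal error rates (family-wise error, FDR) assert
  `rate ≤ α + 2.33·SE`, a one-sided 99% binomial allowance fixed in advance;
  exact-agreement checks use 1e−12 tolerances.
- Fisher transform of |r| = 1 raises by default; pipeline stages clip at
  0.999999 (z ≈ 7.6), far above any attainable group effect.
- Floating-point text round-trips use 17 significant digits on write and
  pandas' `round_trip` parser on read, so written matrices reload bitwise.

## Known limitations

- The spectral modularity heuristic is not globally optimal; the suite bounds
  the gap at ≥ 95% of the exhaustive optimum on small graphs, not in general.
- σ magnitudes depend on the null ensemble and on the reachable-pairs path
  convention for fragmented networks; only orderings and threshold trends are
  interpretable, not absolute σ values.
- Betweenness is reported raw (as defined); comparing across networks of
  different size requires the normalized variant.
- The rewiring null treats the number of swap *attempts* as the budget;
  highly constrained graphs may mix poorly and are flagged only in the
  zero-successful-swap case.
- `--threads` in the CLI is reserved; computation is single-process
  vectorized numpy.
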