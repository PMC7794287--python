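# Methods

## Pipeline model

The package analyses ROI-level BOLD time series as time-varying weighted
networks. Nodes are ROIs (or networks, after `network_average`); edge
weights are Pearson correlations that survive Benjamini–Hochberg FDR
control. The statistical model behind the edge test is the exact null
distribution of the sample correlation for bivariate-normal noise:
t = r·√((n−2)/(1−r²)) with df = n−2, two-sided. FDR is applied to the
m = R(R−1)/2 upper-triangle p-values of each matrix independently (each
sliding window is corrected on its own), with q = 0.05 by default.
Surviving edges keep their signed r; matrices are never binarized.

Sliding windows are rectangular, length 44 s or 66 s at TR = 2 s, stepped
by 1 TR. The window count is floor((n_vols − window_vols)/step) + 1: 105
and 94 windows for a 126-volume (252 s) task half, 69 and 58 for a
90-volume (180 s) rest session. For coarse inspection, windows are grouped
into contiguous quarters of size round-half-away-from-zero(n/4) for the
first three groups and the remainder in the fourth — the only grouping rule
consistent with all four window counts above — and labelled by the 1-based
start-second of their first and last member (e.g. "1-51" for the first
quarter of 105). Quarter averaging takes the element-wise mean of the
member windows' *raw* r matrices, combines their p-values with Fisher's
method, and re-applies FDR. Averaging before thresholding avoids the
zero-inflation bias that averaging already-thresholded matrices would
introduce; this ordering was a genuinely open design choice.

### Group-level windowing

The group analysis concatenates subjects: for window w, the window-w
volumes of every subject are row-stacked and correlated once, so a 44 s
window over 19 subjects carries 19 × 22 = 418 samples and df = 416.
Single-subject mode is the same code path with a one-element list.
Concatenation without per-subject normalisation can let mean offsets leak
into correlations; the `zscore` step (per-column mean 0, sample SD 1,
ddof = 1 — Pearson r is invariant to the ddof choice) is exposed for that
reason, and the synthetic generator produces zero-mean signals so the
planted targets are unaffected either way.

## Community detection

Modularity follows the standard weighted form
Q = 1/(2m) Σᵢⱼ [Aᵢⱼ − kᵢkⱼ/(2m)] δ(cᵢ,cⱼ). Detection is fast-greedy
agglomeration: start from singletons, repeatedly merge the community pair
with the largest gain ΔQ = 2(e_ij − a_i a_j), record the dendrogram, and
return the cut with maximal Q. Merges continue past negative best gains so
the dendrogram always reaches a single community; the best cut can
therefore never be worse than either trivial partition. Ties in ΔQ are
broken by the lexicographically smallest pair of community representatives
(minimal member label), which makes the algorithm deterministic across
platforms. Incremental gains are exact rational updates of the same Q, and
the suite verifies them against full recomputation at every merge.

Negative surviving correlations are excluded from graphs by default
(`positive_only`): Q's null model is ill-defined for signed weights. An
`absolute` mode (|r| as weight) is provided. Nodes isolated by thresholding
stay in the graph as singleton communities — FDR can empty a node's row in
a sparse window, and those nodes must still count in flexibility
denominators. Windows whose thresholded matrix is entirely empty get the
all-singleton partition rather than an error when run through
`detect_window_communities`.

`brute_force_partition` enumerates all set partitions (≤ 10 nodes,
Bell(10) = 115 975) and is the independent optimality oracle. On small
unstructured random graphs greedy agglomeration is usually optimal (median
greedy/optimal Q ratio 1.0) but can stall at the merged partition when the
optimal Q is small; this is a known property of the algorithm, shared
bit-for-bit by the networkx reference implementation.

## Label alignment and flexibility

Per-window detection leaves community ids arbitrary, so window t+1's ids
are renamed to maximize node overlap with window t — greedy largest-overlap
matching by default (ties broken by smallest ids), optimal linear-sum
assignment as an alternative mode. Communities with no overlap receive
fresh ids. Alignment is pure renaming: pairwise co-membership is untouched,
which the suite checks on random sequences.

Node flexibility is fᵢ = (#transitions with a community change)/(n_windows − 1);
the denominator counts the 1-TR-step sliding windows, not quarter averages.
Network flexibility is the arithmetic mean of member fᵢ, and whole-brain
flexibility the mean over all nodes. The per-transition trace (fraction of
nodes changing at each transition) satisfies mean_t(trace) = mean_i(fᵢ)
exactly — a double-counting identity the tests assert to 1e-12.

## Synthetic data

`simulate_roi_bold` draws, per schedule segment,
x_i(t) = a·g(t) + c·z_{c(i)}(t) + σ·ε_i(t) with independent standard-normal
factors: g global, z per community, ε per ROI, σ = `noise_sd`. The weights
are solved analytically so the *achieved* correlations (noise included) hit
the targets: a² = s²·between_r/within_r, c² = s² − a², with
s² = σ²·within_r/(1 − within_r). With σ = 0 the construction degenerates to
perfectly correlated columns, so within_r = 1 is required (and sufficient)
there. Community structure switches instantaneously at segment boundaries;
no smoothing, so planted ground truth is unambiguous. Defaults mirror the
study conditions: 32 ROIs, TR = 2 s, 252 s duration, noise_sd = 1.

What the generator does **not** emulate: haemodynamic convolution and
autocorrelation, physiological noise, scanner drift, or spatial structure.
Passing recovery tests therefore demonstrate that the pipeline's inference
chain is correct for block-correlated signals of the right geometry — not
that real fMRI, with its autocorrelated noise and preprocessing artefacts,
would yield the same detection rates.

Simulated motion is a reflected Gaussian random walk on the six rigid-body
parameters (translation step SD = amplitude mm, rotation step SD =
amplitude/50 rad, reflected at ±5 mm / ±0.1 rad). Because each of the six
difference streams contributes E|N(0,sd²)| = sd·√(2/π) to Power FD,
`amplitude_for_mean_fd` inverts mean FD = 6·√(2/π)·amplitude; an amplitude
targeting 0.18 mm (a typical task-session mean) lands within a few percent
over 20 seeds.

## Statistics and QC

Power FD uses the conventional 50 mm head radius (Σ|Δtrans| + 50·Σ|Δrot|);
Jenkinson FD is the RMS displacement of the relative rigid transform over a
ball of radius 80 mm, computed in closed form
√((R²/5)·tr(AᵀA) + |t|²) with A, t from M − I, M = T_t·T_{t−1}⁻¹, and
validated against a Monte-Carlo sphere-sampling oracle. Rotation matrices
compose as Rx·Ry·Rz; FD magnitudes are insensitive to this convention for
the small angles of head motion.

The repeated-measures ANOVA is the textbook one-way within-subject
decomposition (windows as the measurement unit): F = MS_cond/MS_err with
df = (k−1, (k−1)(n−1)), implemented directly because the degenerate
identical-columns case (SS_cond = SS_err = 0) must return F = 0 rather than
NaN; pingouin serves as the oracle on non-degenerate inputs. No sphericity
correction is applied. Paired t-tests delegate to scipy with an explicit
zero-variance guard that treats pure-rounding-noise differences (SD below
1e−10 of the mean difference) as zero variance.

FD–BOLD correlation is provided in two modes, since "mean FD against the
BOLD series" is ambiguous: per-volume FD series against each ROI column
(default), and across-subject scalar mean FD against per-subject mean ROI
signal.

## Numerical choices and limitations

- Correlations within 1e−14 of ±1 are snapped to ±1 so exact linear
  dependence reports p = 0.
- Text writers use `%.17g` and readers parse with exact float conversion,
  so every writer/reader pair round-trips at full double precision.
- Problem sizes in the test suite and acceptance script (10–20 simulation
  seeds, 100 oracle graphs, 10⁴ Monte-Carlo points) were chosen so each
  check is statistically decisive while the whole suite completes in well
  under a minute.
- The pipeline starts at ROI time series; image-space preprocessing,
  tapered windows, surrogate-data null models for dynamic connectivity,
  multilayer (temporally coupled) modularity, and consensus clustering are
  out of scope.
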