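# Methods

This note documents the models, defaults and numerical choices behind
`coexnet`, in the order the pipeline runs them, followed by the design of
the synthetic-data generator and the limitations of both.

## Preprocessing

Bead-array software reports, per probe and sample, a detection p-value
against the negative-control bead distribution. A probe is kept when it is
detected (p < `detection_alpha`, default 0.01) in at least one sample
(`any_sample`, the common BeadStudio convention) or, optionally, in at
least `min_fraction` of samples. The aggregation rule is genuinely
underdetermined by array vendors' documentation, so both are exposed; the
filter is idempotent and order-preserving either way.

The proper bead-level variance-stabilizing transform requires per-probe
bead variance parameters that summary matrices do not carry. The default
proxy is log2 with values floored at 1 (a warning counts floored cells);
asinh is available, as is `none` for input already on a log-like scale.
Both proxies are monotone per sample, so they cannot reorder ranks.
Normalization is quantile normalization (each sample's sorted values are
replaced by the across-sample rank means, ties receiving interpolated
values) or `none`; quantile normalization was chosen over spline-based
alternatives because it is deterministic and has no knot-placement
ambiguity. Finally the `top_k` (default 5000) most variable probes are
kept, with variance ties broken by probe ID so the selection is invariant
to input order.

## Network construction

Unsigned soft-threshold adjacency `a_ij = |cor(x_i, x_j)|^β` with β = 8.
The unsigned form groups up- and down-regulated probes into one module,
which is what a trait-responsive module with effects in both directions
requires. β is fixed rather than tuned by a scale-free-fit sweep; module
assignments are empirically robust between β = 6 and β = 8 (adjusted Rand
index ≈ 0.97–0.99 on the default synthetic design), which the test suite
asserts at ≥ 0.8.

Weakly connected probes are removed before module detection: probe `i` is
kept when `k_i / max(k) ≥ τ` (default τ = 0.1, raw-`k` thresholding
available). The topological overlap matrix is then recomputed on the
retained subset (recomputing, rather than subsetting a larger TOM, keeps
the shared-neighbour sums consistent with the working probe set). The TOM
uses the standard unsigned form with `a_ii` treated as 0 inside sums and
`TOM_ii` defined as 1; a brute-force triple-loop oracle in the tests pins
the matrix implementation to 1e-12.

## Module detection

Average-linkage hierarchical clustering of `d = 1 − TOM`, then a dynamic
branch decomposition:

1. an absolute top cut at `cut_height = 0.99` on the `d` scale — pairs of
   uncorrelated probes sit at `d ≈ 1`, so unstructured probes fragment
   into sub-minimum clusters and fall to grey;
2. each surviving branch of ≥ `min_module_size` (default 50) probes is
   recursively re-cut at 0.99 of its *own* merge-height range;
3. a candidate split is accepted only if the parts are topologically
   separated: the mean between-part TOM must be below `separation = 0.75`
   times the smaller of the mean within-part TOMs.

Step 3 is the load-bearing choice. Two distinct modules that share a trait
response (for example two regional expression programs) are substantially
inter-correlated, so their branches join below any single global cut —
only a within-branch re-cut can separate them. Conversely, a homogeneous
module re-cut near its top always yields sub-branches; the separation test
rejects those splits because their cross-TOM is essentially equal to their
within-TOM. A single absolute-height cut (`cut_method="static_height"`) is
available for comparison. Linkage ties are resolved by scipy's
deterministic merge order; module labels are the conventional color
palette assigned by decreasing size, with exact ties broken by first
appearance.

## Eigengenes and trait relationships

Each module's probes are standardized across samples and the first right
singular vector of the submatrix (SVD; numerically stable and
deterministic up to sign) gives the eigengene, scaled to unit variance and
oriented so it correlates non-negatively with the module's mean
standardized profile. Eigengene significance is the Pearson correlation
with a trait — binary traits encoded 0/1, i.e. a point-biserial
correlation — with the two-sided p-value from `t = r·√((n−2)/(1−r²))` on
n − 2 degrees of freedom. kME is defined for all probes, including probes
outside the network subset; zero-variance probes yield missing values.

The interaction scan fits, per probe, ordinary least squares of expression
on strain, tissue and their product, tests the interaction coefficient
with a two-sided t-test, and adjusts across probes by Benjamini–Hochberg,
calling adjusted p < 0.01 significant.

## Preservation

For a module and two sample subsets, adjacency is rebuilt within each
subset among the module's probes only (same β) and the statistic is the
Pearson correlation of the two intramodular-connectivity vectors: a hub in
one strain should be a hub in the other if the wiring is real. The
one-sided permutation p-value compares the observed statistic with
`n_perm` random probe sets of the same size; `p = (1 + #{null ≥ obs}) /
(n_perm + 1)`, seeded and reproducible.

Null sets are drawn from the probes *not assigned to any module*. Drawing
from the full network universe — dominated by members of other modules —
produces null sets containing a module-vs-background connectivity split
that is itself perfectly preserved, so the null could essentially never be
beaten regardless of how real the tested module is. Against the
background-only null the test is calibrated (the fraction of null modules
with p < 0.05 lands in [0.02, 0.10] over 200 replicates) and has power
(planted modules reach the permutation floor at n_perm = 1000).

Subset eigengene significance re-derives eigengenes inside a subset using
the reference (all-sample) module labels, skipping modules left with fewer
than two probes.

## SNP artifact diagnostics

Gene regions are 1-based inclusive externally (half-open internally) and
extended by `margin` (default 10 kb) on both sides, clipped at position 1;
`bp_checked` sums region lengths additively, so overlapping regions are
double-counted — a documented simplification that matches additive
published summaries. A probe is SNP-flagged when ≥ 1 catalog SNP lies
within its 50-bp interval, boundaries inclusive. Percentage summaries are
rounded half away from zero to 2 decimals to match printed-table
formatting.

`fisher_exact_2x2` is the conditional hypergeometric exact test with the
two-sided p-value by minimum-likelihood summation (the count-data
convention of standard statistical software; scipy's implementation stands
behind it, pinned by a brute-force enumeration oracle in the tests).
Exact-test p-values under the null are discrete and conservative — they
are *not* uniform, and the tests assert calibration as bounds on rejection
rates rather than distributional uniformity.

The per-module verdict in the pipeline report tests each module's flagged
probes against the rest of the network: SNP-enrichment with odds ratio > 1
and p < 0.05 marks the module `suspect: probe-SNP enrichment`; otherwise a
trait correlation with p < 0.01 marks it `trait-associated: <trait>`.

## The synthetic-data generator

The generator emulates a 35-sample, two-strain (A/J, C57BL/6J), two-region
(amygdala, hippocampus) bead-array study: 8/9 strain-split in amygdala,
9/9 in hippocampus. Defaults (the study conditions used throughout the
tests and the acceptance script): 2000 probes; tissue-driven modules of
200 and 80 probes with bidirectional effects (`direction_mix = 0.5`); an
80-probe strain-artifact module; baseline 9.0 (typical log2 bead
intensity); noise σ = 0.2 log2 units; SNP-flag rates 0.4 inside the
artifact module and 0.02 elsewhere; 5% of background probes "undetected".

Module probe `i` in sample `s` follows
`x_is = baseline + s_i·l_i·f_s + s_i·(l_i/l̄)·effect·g_s + ε_is`, with
loadings `l_i ~ U(0.5, 1)`, signs `s_i` per `direction_mix`, module factor
`f`, group indicator `g` (hippocampus for tissue modules; A/J, subtracted,
for the artifact module) and `ε ~ N(0, σ)`. Three choices deserve note:

* **Trait share.** Driver modules split their shared signal between the
  trait effect and a module-specific factor via `trait_share` (defaults
  0.93, 0.65, 0.95). The factor is what keeps two modules responding to
  the same trait statistically distinguishable; the trait effect is what
  makes the eigengene track the trait. A single within-module-correlation
  knob cannot satisfy both at once: the defaults emulate a strong and a
  weaker regional module (eigengene |r| ≈ 0.93 and ≈ 0.8) plus a
  near-perfectly strain-separating artifact module.
  `within_module_cor` (default 0.7) governs driver-free modules, with the
  factor variance calibrated against E[l²] so the expected pairwise
  correlation matches.
* **Artifact scope.** *Every* artifact-module probe is attenuated in the
  non-reference strain; the SNP catalog flags only the
  `snp_flag_rate_artifact` fraction as *known* SNPs. This mirrors how such
  artifacts arise physically — the module exists because its probes'
  targets are polymorphic, whether or not a catalog knows the variant —
  and it is what makes the enrichment diagnostic, which only sees known
  SNPs, a fair test.
* **Hub structure.** The per-probe effect magnitude follows the loading
  (normalized to mean 1, so the average planted shift equals `effect`).
  Without this, all module probes are exchangeable, the true intramodular
  connectivity is constant, and the kIM-preservation correlation of a
  perfectly preserved module is 0 by construction. With it, modules have
  the kME gradient (≈ 0.5–0.95) real modules show, and preservation
  statistics land near 0.5 for modules preserved across strains.

The synthetic genome places each module's genes on its own chromosome
(20 kb genes, 30 kb start-to-start, one 50-bp probe per gene). Background
SNPs fall as a Poisson process (default 1/1500 bp) over gene bodies,
avoiding unflagged probe intervals so the probe flags stay authoritative;
flagged probes receive one in-probe SNP; artifact-module genes draw
non-synonymous classes at 0.8% versus 0.2% elsewhere. cis-eQTL status
labels are drawn so that flagged artifact probes skew to apparent
("false") cis signals and unflagged ones to real cis effects, at rates
matching the observed concordance counts. Detection p-values are
U(0, 0.005) for expressed probes and U(0.1, 1) for undetected ones.

What the generator does **not** emulate: probe sequences or thermodynamic
hybridization (attenuation is a mean shift), between-sample technical
effects (batch, chip position), heavy-tailed intensity noise,
correlated background structure, or more than two levels per trait.
Passing tests therefore demonstrate that the pipeline recovers the
statistical structure it assumes — block-correlated modules with trait
effects and a flag-enriched artifact — not that it is robust to every
failure mode of real arrays.

## Problem sizes and determinism

The test suite and acceptance script run the full pipeline on 2000-probe,
35-sample datasets (about 0.5 s per run), five replicate seeds per
stochastic claim, 100–1000 permutations per preservation p-value, and
200–500 replicates for null-calibration checks. Every stochastic stage
takes an explicit seed; the pipeline fans a single global seed out to
stages by fixed offsets, and identical configurations reproduce reports
byte-for-byte (timestamps are never written).
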