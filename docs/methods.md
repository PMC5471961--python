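# Methods

## Model

For one condition with `G` genes, `F` TFs and `S` samples, logged
expression is modeled as

    e_gs = mu_g + sum_f T_gf W_gf c_fs + v_gs,    v_gs ~ N(0, sigma^2)

with `T` a fixed binary binding topology, `W` the TF–gene interaction
strengths (activities), `c` the TF concentrations (one column per
sample), `mu` a per-gene baseline and spherical Gaussian noise. Each
condition (wild-type, knock-out, each time point) is fitted
independently; no temporal coupling between datasets is modeled.

The connected entries of `W` carry independent `N(0, alpha)` priors and
are treated as latent variables; `c`, `mu` and `sigma^2` are parameters.
Conditional on `c`, genes decouple, so the E-step is an exact Gaussian
(ridge-type) posterior per gene:

    Sigma_g = (X_g^T X_g / sigma^2 + I/alpha)^-1,
    m_g     = Sigma_g X_g^T (e_g - mu_g) / sigma^2,

with `X_g` the sample × connected-TF design built from `c`. The M-step
is closed form: one generalized-least-squares solve for all columns of
`c` using the posterior second moments `E[w_g w_g^T]`, then `mu` as the
mean residual and `sigma^2` as the expected mean squared residual
(including the posterior W-variance term), floored at `min_sigma2`.
Each update is a coordinate ascent step of the evidence lower bound, so
the objective trace is non-decreasing — a property the test suite
checks on randomized instances.

Numerically, the E-step moments are obtained from a batched SVD of the
per-gene designs rather than by factorizing the posterior precision:
each spectral direction is regularized and inverted separately. This
matters when `sigma^2` sits at its floor (noiseless data, single
samples), where the precision matrix's condition number explodes while
the spectral form stays exact to machine precision.

## Identifiability and gauge conventions

The bilinear product `(T o W) c` is what the data determine; three
transformations leave the likelihood unchanged and are resolved by
convention after convergence:

1. **Sign.** `(W_f, c_f) -> (-W_f, -c_f)`. Each TF is flipped so its
   mean concentration over samples is >= 0.
2. **Mean.** Adding a constant to a concentration row and subtracting
   `W d` from `mu` changes nothing, so the data cannot locate the mean
   of `c`. The baseline is therefore defined as the component of mean
   expression *orthogonal to the regulatory directions*: after EM a
   least-squares solve moves everything in `mu` explicable through the
   columns of `W` into `c`. Without this convention the reported
   concentrations retain an arbitrary offset inherited from the random
   initialization, and any statistic dividing by `c` is meaningless.
3. **Scale.** `(a W_f, c_f / a)` is likelihood-flat; the fixed prior
   variance `alpha` pins the scale of `W` softly (it is not optimized).
   Consequently the *attribution* of a uniform change of a TF's column
   between "activity" and "concentration" is soft: a knockout that
   triples every weight of one TF is partially reported as a
   concentration increase. Both the per-TF activity table and the
   concentration table should be read together for this reason.

Concentrations are real-valued — no positivity constraint beyond the
sign convention — and on the arbitrary scale induced by `alpha`.

## Differential analysis

Two fitted conditions are compared through the concentration-normalized
activity `A_gf = |W_gf| / max(|c_f|, epsilon)` on the support of `T`
(`c_f` = mean concentration over samples; `epsilon = 1e-6` guards the
division, and clamped TFs are reported). The difference
`D = A_ref - A_alt` is thresholded at

    cutoff = k * sample SD (ddof 1) of the support entries of D,

`k = 2` by default, i.e. the two-sided 95% band of a Gaussian. The SD is
taken over support entries only — the structural zeros off the topology
would otherwise deflate it. Both directions are flagged (`|D| >`
cutoff, strict), with `D > 0` labeled Down (stronger in the reference)
and `D < 0` labeled Up. The cutoff is computed jointly over all pairs;
`significance_cutoff` can be applied per TF column by the caller if a
per-regulon reference is preferred.

TF-level calls compute `delta_f = v_ref - v_alt` for a per-TF summary
`v` — average strength `S_f = mean_{g: T_gf=1} |W_gf|` for activity,
mean concentration for abundance — and flag TFs with
`|delta_f - median(delta)| > k * SD(delta)`. The median center keeps a
handful of strongly responding TFs from dragging the reference point.

No multiple-testing correction is applied beyond the SD cutoff; the
procedure is a calibrated screen, not a hypothesis test with controlled
FWER.

## Synthetic benchmarks

`simulate` draws: Bernoulli(`density`) topology with empty TF columns
repaired to one random target; connected weights `N(0, w_scale^2)`;
concentrations `N(0, c_scale^2)` i.i.d. per TF and sample; baselines
`N(mu_scale, 1)`; expression from the model with noise SD `sigma`. A
perturbation multiplies chosen TFs' weight columns (`activity_factor`)
and/or concentration rows (`concentration_factor`) in the alternate
condition. A scaled-t option (`tail_df`) provides heavier-tailed truth
for misspecification checks. All randomness derives from one seed
through independent child streams, so a dataset regenerates bit-exactly
from its manifest.

Defaults — 200 genes, 20 TFs, density 0.2, 8 samples per condition,
`sigma = 0.1`, 3 TFs perturbed at 3× activity — are a scaled-down
regulon (real catalogues are on the order of 2 × 10^4 genes × ~170 TFs
with ~10^5 bindings) chosen so that a full fit takes seconds and the
complete suite minutes on one CPU.

What the generator does *not* emulate: platform-specific noise of
microarray/RNA-seq pipelines (the model's i.i.d. Gaussian is an
idealization), correlated TF concentrations, combinatorial TF logic,
and false edges in the topology. Passing recovery tests therefore
demonstrates correctness of the inference under its own assumptions,
not robustness to real-data violations of them.

## Numerical and convergence choices

* `alpha = 1` (prior variance), fixed — matches the generator's unit
  weight scale and pins the W/c split.
* Convergence: relative objective change `< 1e-6`; `max_iterations =
  3000`. The scale gauge equilibrates along a nearly flat ridge, so
  loose iteration caps leave the activity/concentration attribution
  drifting even when the product `(T o W) c` has long stabilized; at
  the default benchmark size convergence typically takes 700–2000
  iterations (a few seconds).
* `sigma^2` floored at `1e-8`; the floor also keeps the bound finite on
  noiseless data.
* EM on a bilinear model has local optima. Different initial seeds can
  land on fits differing in `sigma^2` by a factor ~3 while the
  recovered regulatory signal stays highly correlated with the truth
  (r > 0.97 in the cases examined). Multi-start selection by final
  objective is a straightforward extension left to the caller.
* Non-convergence returns a result flagged `converged=False` with a
  warning rather than an error.

## Calibration

On null benchmarks (no planted perturbation) the flagged fraction of
support pairs averages close to the Gaussian two-sided 2-SD tail
(2·Phi(−2) ≈ 4.55%). Per replicate, however, `D` is leptokurtic:
whenever a TF's summary concentration is near zero (its true mean over
8 samples is `N(0, 1/8)`), the normalization `|W/c|` amplifies that
TF's whole column, producing clustered outliers. Individual replicates
can therefore keep as little as ~92–93% of support entries inside the
±2 SD band instead of the Gaussian 95.4%. This is a property of the
normalized-activity statistic itself, not of the fitting — the
`epsilon` floor bounds, but cannot remove, the sensitivity of a ratio
to a small denominator.

## Visualization

SVG is the canonical output; figures are built as primitive shape lists
serialized with fixed formatting, so identical inputs give byte-identical
files (the pipeline manifest records SHA-256 checksums of every
artifact). `<line>` elements are reserved for data chords — the circular
plot contains exactly one per flagged pair, blue for Down and red for Up
— while axes and guides are paths. PNG output rasterizes the same scene
via matplotlib. Functional-group ordering and colors come from the
optional TF annotation table; unannotated TFs fall into a trailing
"Unknown" group. The paper-style group palette being unspecified, an
8-color colorblind-safe cycle (Okabe–Ito) is used.
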