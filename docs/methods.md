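# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
generators do and do not emulate.

## The residue-tree model of fructans

A fructan is represented as a rooted tree of hexose residues (`fructans.structures`).
Every glycosidic bond is an edge `(donor, acceptor, position)` in which the donor
engages its anomeric carbon — C2 for fructose, C1 for glucose — and the acceptor is
substituted at the named carbon (C1 or C6 on fructose, C6 on glucose). The sucrose
moiety is the unique edge donated by the (at most one) glucose; since it joins the
two anomeric carbons it never counts as a substitution. The model ignores ring
conformation, anomeric chemistry beyond the α/β labels implicit in linkage names,
and 3-D geometry.

A residue's substitution pattern determines its PMAA linkage class:

| substitutions | fructose | glucose |
|---|---|---|
| none | t-Fruf | t-Glcp |
| C1 | 2-1-Fruf | — |
| C6 | 2-6-Fruf | i-Glcp |
| C1 + C6 | 1,6-di-Fruf | — |

so the linkage census of a molecule is a pure function of its tree, and the census
of a mixture is additive over molecules. Two invariants follow from tree counting
and are enforced everywhere:

1. the census of a molecule sums to its degree of polymerization (DP);
2. summing child edges over classes and equating with `n − 1` edges forces
   **#t-Fruf = #1,6-di-Fruf + 1 (+ 1 if the glucose is internal)**.

Identity 2 is the exact realizability condition for a census. It has a practical
consequence: an "agavin" (internal-glucose) variant of a census measured on a
terminal-glucose core requires one extra terminal fructose. `propose_structures`
therefore builds the same-DP agavin core by reassigning one β(2→1) fructose as the
neo-terminal cap on glucose C6 — the minimal edit that keeps the DP and the branch
count while internalising the glucose. This is the package's reading of the
"average agavin" companion structure; it is a modelling choice, not a measured
object.

**Canonical assembly.** `assemble_core` maps any realizable census to one
deterministic layout: glucose at the root, a single backbone holding all 2-1
residues with branch (di) residues spaced evenly along it (glucose-proximal
first), each di carrying a levan chain at C6 (2-6 residues split evenly across
branches; when there is no branch residue the 2-6 run sits at the distal end of
the backbone), a terminal fructose capping every open chain, and — in internal
mode — one terminal fructose at glucose C6. Alternative isomers realizing the same
census exist; the canonical layout makes assembly testable (census round-trip) and
mirrors the way average structures are conventionally drawn.

**DP extension.** Two modes grow a core toward the chromatographically observed
maximum DP. `backbone` splices β(2→1) units just below the sucrose fructose until
the target DP is met exactly; existing residues keep their substitution patterns,
so only the 2-1 count grows. `proportional` multiplies every non-glucose class
count by `target/dp(core)`, applies the molecule-assignment rounding and then
canonicalises the terminal count to identity 2, exchanging surplus (or deficit)
terminals with 2-1 units so the scaled DP is conserved; the result round-trips
against that canonical census but does not land on the target DP exactly — naive
proportional scaling of class counts generally violates identity 2, which is why
the repair step exists.

## PMAA classification and quantification

The packaged reference library (`fructans/data/pmaa_reference.msp`) transcribes
the eight GC peaks of the bulb-extract analysis: retention time, derivative name
(peak 3's name is kept verbatim, including an apparent "tetra-O-thylglucitol"
typo) and the printed fragmentation pattern. Classification uses the
diagnostic-ion cascade described in the module docstring; it depends only on ion
presence and the base-peak identity, hence is invariant to uniform intensity
rescaling. Ambiguous spectra fall back to the best cosine match against the
library; a cosine below 0.5 yields `unclassified` rather than an exception. m/z
matching is exact-integer (the library is unit-mass).

Quantification assumes equal molar GC response across derivatives (no response
factors are available for these PMAA species). The terminal-fructose epimer pair
(peaks 1 + 2) is summed; the convolved glucitol peak 6 is split between the 2→1
and 2→6 classes in proportion to the resolved mannitol-epimer peaks 5 and 4
(50/50 when both are absent); output is normalised to 100%.

## The glucose-normalised inference procedure

Because a fructan holds at most one glucose, dividing each class's molar
percentage by the summed glucose percentage expresses composition as residues per
molecule. The procedure (`fructans.inference`) is:

1. **ratios** — `pct(class) / (pct(t-Glcp) + pct(i-Glcp))`; glucose term 1.0.
   F-series inputs (no glucose) are rejected rather than silently renormalised to
   another denominator.
2. **core-DP** — the sum of the five ratios; reported to one decimal.
3. **molecule assignment** — 0 stays 0; any value in (0, 1) counts as one
   molecule; values ≥ 1 round half-up (2.5 → 3, deliberately not banker's
   rounding — the rule is verbal, "decimals ≥ 0.5 round up").
4. **summaries** — means reported to one decimal. Both standard-deviation
   conventions (n−1 and n) are computed and shown side by side, because reported
   spreads of such tables mix conventions in practice; the sample (n−1) form is
   the default in reports.
5. **scaling** — factor = HPAEC max DP / mean assigned DP; non-glucose counts are
   multiplied and re-rounded with rule 3, glucose stays 1. The mean assigned DP
   defaults to its one-decimal reported value (20 / 7.2 = 2.78 for the packaged
   table), matching the convention of the source tables; a factor below 1 is
   clamped with a warning.
6. **derived quantities** — branching frequency = ratio(2-1)/ratio(di), the
   number of β(2→1) linkages per branch point (infinite flag when unbranched);
   neo fraction = i-Glcp/(t-Glcp + i-Glcp), the share of molecules with internal
   glucose.

Internal arithmetic is full precision; rounding happens only at reporting
boundaries. `LinkageInference(...).fit()` returns a results object carrying the
per-sample tables, summaries, scaled counts and proposed structures.

## Chemometrics

`pareto_scale` centers each band column and divides by the square root of its
sample standard deviation; zero-variance columns are dropped with a warning. PCA
delegates to scikit-learn and reports per-component and cumulative explained
variance.

**OPLS-DA.** Single-response NIPALS: orthogonal components (default 1,
configurable) are estimated and deflated from X, then one predictive component is
fit on the filtered matrix; the predictive score is oriented toward the
configured positive class. Q² comes from stratified 7-fold cross-validation.
Seven folds are the convention of the commercial software family for this
analysis; with six samples per class that exceeds the per-class count, so fold
assignment is a seeded per-class shuffle interleaved and dealt round-robin —
every fold is as balanced as sizes allow and every training split keeps both
classes (scikit-learn's `StratifiedKFold` refuses this configuration, which is
why the assigner is written here). The split derives from the class labels, not
the ±1 coding, so it is invariant to the positive-class choice. The response is
train-centered within each fold; `Q² = 1 − PRESS/SSY`.

**Validation.** The permutation test shuffles labels only, refits the whole
CV pipeline per permutation and returns `p = (1 + #{Q²perm ≥ Q²obs})/(nperm+1)`
(100 permutations by default; the attainable floor is 1/101). CV-ANOVA compares
the cross-validated residuals against the total response variation:
`F = ((SSY − PRESS)/d1)/(PRESS/d2)` with `d1` = number of model components
(predictive + orthogonal) and `d2 = N − 1 − d1`; degenerate residuals return
p = 1 with a warning. The conventional validity gates Q² ≥ 0.40 and p ≤ 0.05 are
report defaults only, not hard-coded decisions.

**S-plot.** For each scaled variable, the covariance and the Pearson correlation
with the predictive score; marker selection thresholds |covariance| (default 0)
and |correlation| (default 0.8), signed by class direction.

**Rf → DP calibration.** Monotone piecewise-linear interpolation through the
plate anchors (0.57, DP 1), (0.51, DP 2), (0.40, DP 3), (0.09, DP 11), rounded to
the nearest integer; retention above the fructose anchor clamps to DP 1, bands
below 0.09 belong to the unresolved application point and are reported as such
rather than extrapolated.

## Synthetic data

**Mixture generator.** Each molecule starts from sucrose; the backbone gains a
geometric number of β(2→1) units (mean `mean_backbone_len`); every backbone unit
independently sprouts a levan chain at C6 with probability `branch_prob`, of
geometric length (mean `levan_branch_len_mean` ≥ 1); with probability
`neo_fraction` a terminal fructose occupies glucose C6. Geometric lengths are the
simplest elongation law consistent with an average-composition picture; the
per-molecule census expectation is closed-form (`expected_census`), and the
population ratio of 2-1 to di residues is `(1 − q)/q`.

Defaults — backbone 2.8, branch probability 0.21, levan length 1.1, neo fraction
0.5, 2000 molecules — are set so the expected census reproduces the measured
average composition of the bulb extracts (≈ 2.1 t-Fruf, 2.2 β(2→1), 0.3 β(2→6),
0.6 branch residues per glucose, core-DP ≈ 6, glucose split 1:1 between terminal
and internal).

**Noise.** Compositional tables and band intensities are perturbed by
multiplicative lognormal noise parameterised by a coefficient of variation
(mean-1 correction applied), then renormalised — positive by construction, which
is how GC/HPTLC intensities scatter. The default table CV of 5% matches the
spread of the measured ratio table.

**HPTLC simulator.** A 14-band grid: the three simple-sugar anchors (0.57, 0.51,
0.40), four neutral mid-range bands, and seven low-Rf bands (0.062–0.163)
mirroring the fructooligosaccharide window. Old-class samples multiply the
baseline by class effects (default 0.6 on the sugar anchors, 1.8 on the low-Rf
window, 1.0 elsewhere), encoding the expectation that younger bulbs are richer in
simple sugars and older bulbs in higher-DP oligosaccharides.

**What the simulators do not emulate** — and hence what passing tests do not
show about real data: GC/HPAEC/plate chromatography itself (co-elution, baseline,
response factors), within-species biological covariance between linkage classes
(noise is independent per class), DP-dependent band broadening, isomer diversity
beyond the canonical layout, and any systematic derivatization bias. Recovery
results demonstrate the *procedure's* correctness under its own assumptions, not
instrument performance.

## Numerical conventions and problem sizes

All randomness flows through `numpy.random.default_rng` seeds; generators are
bit-reproducible and all CLI entry points log their seed and config hash.
Reported decimals default to one (the source-table convention) with full
precision available. The standard test and acceptance runs use 1,000 structures
for round-trip checks, 10,000 draws for Monte-Carlo census validation, 6 samples
per simulated mixture, 12 samples per band table, 100 permutations, and 20 null
replicates — sizes at which every stochastic check is stable across seeds while
the whole suite runs in seconds.

## Known limitations

* The canonical assembly returns one isomer per census; real mixtures contain
  many. Censuses, not structures, are the measured objects.
* The proportional extension mode inherits the arithmetic of the scaling rule;
  its DP only approximates the target (see above). The backbone mode is exact
  and is the default in reports.
* The equal-response assumption in GC quantification is a stand-in; with
  published response factors it should be replaced.
* CV-ANOVA degrees of freedom follow the conventional cross-validated residual
  ANOVA; other df choices exist and p-values near the threshold should not be
  over-read with n = 12.
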