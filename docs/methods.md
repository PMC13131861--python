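# Methods

This note documents the models implemented in `sundown`, the conventions
chosen where several were defensible, the synthetic-data generators and
what passing tests on them do and do not demonstrate.

## Behavioral PLSC

Given aligned subject tables — a behavior block X (n × p) and a brain
block Y (n × q of region activity densities) — both blocks are
column-standardized (mean 0, SD 1, ddof = 1) and the cross-correlation
matrix R = Zxᵀ Zy/(n − 1) is decomposed by SVD, R = U diag(δ) Vᵀ. "Center,
scale, then decompose" is implemented as standardization of the blocks
before forming R, so every entry of R is a Pearson correlation and the
saliences weight correlations, not covariances; re-centering R itself was
rejected because it would destroy that interpretation.

*Imputation.* A region missing more than `max_missing_per_group` (default
2) values in any group is dropped; remaining missing values are replaced
by the median of that region within the subject's group. This assumes
missingness unrelated to the unobserved value (missing at random), which
the MCAR generator satisfies by construction.

*Permutation test.* Subject rows of Y are permuted relative to X
(`n_perm` = 10,000 by default), preserving both within-block covariance
structures while destroying the cross-block link. Per-LV p-values use the
add-one estimator (k + 1)/(n_perm + 1), so the smallest reportable p at
10,000 permutations is ≈ 0.0001; an LV is flagged significant when its
observed singular value exceeds the 95th percentile of its own null
distribution. An omnibus p on the inertia Σδ² is computed the same way.

*Bootstrap ratios.* Subjects are resampled with replacement (`n_boot` =
10,000 by default); replicates containing a zero-variance column are
redrawn (counted, capped). Each replicate's saliences are sign-aligned to
the original per LV by the sign of the combined dot product
Uᵦᵀu + Vᵦᵀv — rank-wise alignment only, no Procrustes rotation, which is a
known limitation when singular values are closely spaced. BR = original
salience / SD (ddof = 1) of the aligned replicate saliences; the
reliability flag uses strict |BR| > 2. SVD sign indeterminacy is fixed by
making the largest-magnitude element of each U column positive.

*Latent projections.* Subject scores are Zx·u and Zy·v; group-mean 95%
CIs are percentile bootstrap (2.5/97.5) over within-group resamples.
Percentile rather than normal-approximation intervals were chosen because
they need no symmetry assumption at n = 6–8 per group.

## Co-activation networks

Per group, pairwise-complete Pearson correlations between regions; pairs
with fewer than `min_n` = 4 complete observations are undefined. The
"one-sample t-test" on a correlation is the standard r→t transform
t = r√(n−2)/√(1−r²) with df = n − 2, two-sided (the Fisher-z alternative
was rejected to match the stated test). Joined networks share the node set
of regions fully defined in every group; each group independently keeps
the round(density · n(n−1)/2) most significant edges, ranked by p
ascending with ties broken by |r| descending then lexicographic pair
label — the tie-break is a determinism convention, not a statistical
claim. Topology metrics are unweighted/undirected: mean degree 2E/N;
global efficiency as the mean of 1/d(u, v) over ordered pairs with
1/∞ = 0; mean local clustering (0 for degree < 2); mean betweenness
normalized by (N−1)(N−2)/2. The sweep thresholds edges at p < α (strict)
over a default grid of 40 log-spaced alphas in [0.001, 1].

## Hierarchical clustering

Dissimilarity d = 1 − |r| treats strong positive and negative co-activity
as equally proximal; its maximum is 1 at r = 0. Regions with any undefined
correlation are dropped (and reported) before clustering. UPGMA is
implemented directly (O(n³), unweighted average of all member-pair
distances) so the tie-break is explicit: among minimal-distance cluster
pairs, the pair whose sorted member-label tuples compare lexicographically
smallest merges first. Trees are cut by undoing the last k − 1 merges in
merge order, which yields exactly k clusters even under tied heights. The
elbow curve sums all within-cluster pairwise dissimilarities per k —
pairwise sums rather than distances to a centroid, because the former is
the only definition requiring no embedding of the regions — and the
advisory elbow (largest second difference) is a suggestion only; k remains
a user choice.

## Behavioral classification

Multinomial logistic regression fitted by maximum likelihood with a
negligible L2 ridge (1e−8, i.e. C = 1e8) purely to stabilize the fit on
linearly separable data. Folds are stratified by class; a fresh 8-fold
split is drawn per repeat (200 repeats by default) and each subject is
held out exactly once per repeat. Feature standardization uses
training-fold statistics only. The shuffle null permutes class labels per
shuffle and runs 4 repeats per shuffle (50 × 4 = 200 pooled null repeats).
Confusion matrices are row-normalized counts pooled over repeats; ROC
curves pool held-out probabilities across repeats (one curve per class)
rather than averaging per-repeat curves. Precision/recall/F1 are computed
per repeat per class and summarized as mean ± t₍₁₋α/₂, n−1₎·SE with
α = 0.01; a repeat with no predicted or no true positives for a class
scores F1 = 0 and is counted in `n_undefined` (small held-out folds can
lack a class entirely).

## Rhythms and sleep architecture

The cosinor model y = M + A·cos(2π(t − φ)/τ) is fitted by the linearized
least squares y = M + β₁cos(ωt) + β₂sin(ωt), A = √(β₁² + β₂²),
φ = atan2(β₂, β₁)/ω wrapped into [0, τ); τ defaults to 24 h and time is in
zeitgeber hours. A fit with amplitude below 1e−12 (relative to the mesor
scale) reports amplitude 0 with an undefined acrophase. Phase boundaries
are fixed at ZT0/ZT12 (12 h:12 h light cycle); a bout crossing a boundary
is split, contributing its in-phase part to each phase. The piezo system's
proprietary sleep/wake classifier is not re-implemented; the module
consumes already-classified traces or hypnograms.

## EEG spectra and staging

The spectrogram is a Hann-tapered one-sided periodogram per 5 s window
stepped by 2 s (0.2 Hz resolution; bin count floor((T − 5)/2) + 1).
Staging features per 2 s bin — delta power, theta/delta ratio, EMG RMS
over the matching window — are z-scored over the record; the rule is:
EMG z > 0.5 → Wake, else theta/delta z > 1.0 → REM, else NREM, with an
optional 3-bin majority smoother. The published criteria are qualitative
("high"/"low"), so the thresholds are configurable SD units and the
staging is validated by synthetic recovery (below) rather than manual
scoring. Spectra are averaged over a state mask, normalized so the mean
power over the 0.1–50 Hz grid points is exactly 1, then log2-transformed.
Band AUCs integrate the log2-normalized spectrum by trapezoid over each
band's grid points; the pre-log quantity is available behind a flag
(`pre_log=True`), and the printed band gaps (30–30.1 Hz etc.) are
preserved — grid points inside a gap belong to no band.

## Ethology

Arenas are axis-aligned rectangles in cm. The OF center is the central
3 × 3 block of the 5 × 5 grid of a 50 × 50 cm box; the EPM has an
8 × 8 cm center, 26.5 × 8 cm arms, and 2 cm-wide edge-bordering strips
along the open arms' long edges and distal ends for head-dip detection
(the strip width is a convention; it is configurable). Zone assignment is
first-match with listed-order priority (center before periphery); points
outside all zones snap to the nearest zone and are counted. The
absent-explorer screen excludes a trial only when both criteria hold: a
maximal run of ≥ 180 s during which the centroid stays within 1 cm
(configurable) of the run's start position, and a single zone holding
> 95% of the session and > 285 s. Syllable frequency is onset events per
second (occupancy fractions are also reported); normalized values are
log2(raw/reference-group mean), undefined when the reference is 0.
Syllable transition matrices exclude self-transitions and row-normalize
over syllable changes only.

## Synthetic-data generators

The generators are first-class, tested code defining the conditions under
which the pipeline is validated.

*Brain/behavior tables* use a Gaussian factor model: per group, subjects
draw `latent_rank` shared standard-normal factors loading (scaled by
`latent_strength`) on designated behavior and region subsets, plus
independent N(0, σ²) noise and a positive baseline. PLSC and Pearson
networks are second-moment methods, so matching second moments is the
whole requirement. A cluster entry (indices, r) adds a common factor with
scale s = σ√(r/(1 − r)), the closed-form choice giving within-cluster
correlation s²/(s² + σ²) = r. Missingness is MCAR on the brain table.
Defaults mirror the study design: 2 groups × 8 subjects, 137 regions, 11
behavioral features, a rank-1 dimension on 3 behaviors and 5 regions,
5% missingness, σ = 1; activity magnitudes are arbitrary units (per-region
variance scales for the real densities are not published).

*Hypnograms* are three-state semi-Markov chains with geometric dwell times
(means: Wake 240 s, NREM 160 s, REM 60 s — minute-scale bouts typical of
mice) and light/dark entry-weight multipliers; REM is reachable only from
NREM, so generated records contain only the transitions W-N, N-R, N-W,
R-N, R-W. *EEG* sums band-limited unit-RMS noise per canonical band,
scaled per epoch by the state's band profile (NREM delta:theta 4:1, REM
theta-dominant 3:1, Wake flat) with EMG RMS 30/8/5 µV for Wake/NREM/REM.
*Activity traces* are clipped noisy cosines in 10-min bins over 5 days
(amplitude 0.1, mesor 0.15 in 0–0.3 arbitrary units, acrophase ZT18 —
nocturnal activity peaking mid dark phase). *Trajectories* are Metropolis
random walks against a piecewise-constant density ∝ weight/area, so
long-run zone occupancy converges to the normalized preference; nose
points sit 2 cm ahead of the centroid along a smoothed heading.

One integer seed fans out to independent child streams via
`numpy.random.SeedSequence.spawn`, making every generator bit-reproducible.

*What passing does not show.* The generators match second moments, dwell
distributions and band power — not heavy-tailed densities, inter-region
anatomical covariance, EEG artifacts/arousals, or goal-directed locomotor
structure. Calibration results on them validate the statistical machinery
(null behavior, planted-structure recovery, algebraic identities), not
biological effect sizes.

## Problem sizes used in the calibration suite

The permutation-calibration run uses 200 null datasets (16 subjects,
10 behaviors × 30 regions) at 1,000 permutations each; the bootstrap-
coverage run uses 50 planted datasets (100 subjects) at 2,000 resamples;
staging recovery uses 20 half-hour recordings at 200 Hz. These sizes give
Monte-Carlo error small enough for the stated tolerances (binomial SE
≈ 1.5 percentage points for the rejection rate at n = 200) while keeping
the default suite fast to run.

## Known limitations

- Bootstrap alignment is per-LV sign only; closely spaced singular values
  can rotate across replicates and inflate bootstrap SEs (conservative
  BRs).
- The r→t p-values are asymptotic and anti-conservative at very small n;
  pairs with fewer than 4 complete cases are refused rather than tested.
- Staging thresholds are global z-scores per record, so extreme state
  imbalance (e.g. a near-sleepless record) shifts the operating point.
- The trajectory generator's occupancy converges at the Metropolis mixing
  rate; very short sessions can deviate from the target preference.
- The elbow suggestion is a second-difference heuristic on the within-
  cluster curve and is advisory; it is sensitive to near-ties.
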