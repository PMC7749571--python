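# Methods

`megconn` implements a resting-state, source-level MEG functional-connectivity
analysis for two-group (patient vs control) studies, together with a synthetic
cohort generator that gives every stage a known ground truth. This note
documents the models, the parameters that matter, the numerical choices, and
what the validation experiments do and do not establish.

## Pipeline model

The unit of analysis is one subject's virtual-sensor matrix (channels ×
samples, amplitudes in picotesla). Stages:

1. **Screening.** Samples where any channel exceeds an absolute amplitude
   bound (default 6 pT) are flagged. Mains interference is removed with a
   zero-phase second-order IIR notch at 50 Hz (−3 dB bandwidth 2 Hz; ≥20 dB
   attenuation at the notch after the forward-backward pass). Spike-like
   transients are flagged on the 1–70 Hz filtered signal wherever any
   channel exceeds `z` robust deviations (median ± z·1.4826·MAD, default
   z = 8), dilated by ±200 ms. Clinical practice marks spikes visually; the
   robust z-score is an algorithmic stand-in chosen for reproducibility, and
   its threshold is exposed in the config. The earliest contiguous window of
   the configured length (default 60 s) containing no flagged sample becomes
   the analysis window; earliest-window selection makes the choice
   deterministic. A subject with no clean window is excluded and reported,
   not silently dropped.

2. **Band decomposition.** The window is filtered into seven canonical bands
   — δ 1–4, θ 4–8, α 8–12, β 12–30, γ 30–80 Hz, ripple 80–250, fast ripple
   250–500 Hz — with 4th-order Butterworth band-passes applied
   forward-backward (`sosfiltfilt`), i.e. zero phase and |H|² magnitude.
   Zero phase matters because the connectivity statistic is a zero-lag
   correlation. Bands whose upper edge reaches the Nyquist frequency at the
   configured sampling rate are skipped with a logged warning so that
   desk-scale runs at reduced rates remain possible. Filter edge padding is
   scaled to the low cutoff (3/lo seconds), without which the 1 Hz cutoff
   leaves large boundary transients.

3. **Connectivity.** For each band and unordered channel pair the
   correlation factor R = cov(Xa,Xb)/(sd(Xa)·sd(Xb)) is computed over the
   window's K samples (the 1/K vs 1/(K−1) convention cancels in the ratio).
   Each R maps to a Student t with K−2 degrees of freedom,
   TP = R·√(K−2)/√(1−R²), and an edge is retained when its two-sided p is
   below α (default .05, deliberately uncorrected: multiplicity control in
   this design belongs to the group-level comparisons). Retained edges keep
   their signed weight; positive and negative (excitatory/inhibitory)
   connections are reported separately, e.g. in the seed-to-target
   subnetwork extraction (PCC → frontal via the per-channel region labels).

   **Effective sample size.** Band-limited signals are autocorrelated, so
   the raw K overstates the information in the window: for an ideal band of
   width B the correlation's variance is ≈ fs/(2B·K), not 1/K. At the
   seven-band defaults this inflates the per-edge false-positive rate of the
   raw-K threshold far above α. `threshold_graph_effective` therefore
   offers a per-pair effective-K correction — K divided by the
   Bayley–Hammersley variance inflation factor 1 + 2·Σ ρa(τ)ρb(τ), with the
   autocorrelations estimated from the two channels (lags up to min(K/4,
   1000), K_eff floored at 8). It is **off by default**: the plain raw-K
   rule is the reference behaviour, and the correction is used where the
   goal is calibrated edge detection (the planted-recovery experiment).

4. **Graph metrics.** Metrics consume |W| (negative lengths and complex
   cube roots are otherwise ill-defined). Strength S_i = Σ_j w_ij with
   network average SA; degree d_i with average DA; characteristic path
   length with edge length 1/w_ij, shortest paths by Dijkstra, and the
   harmonic-form network average LA = 1/[(1/(N(N−1)))·Σ_{i≠j} 1/L_ij], in
   which a disconnected pair contributes 0 (an entirely disconnected graph
   has LA = +∞); clustering by the geometric-mean (Onnela) form after
   rescaling weights by the maximum weight, C_i = Σ_{j,k}(ŵ_ij ŵ_jk
   ŵ_ki)^{1/3}/(d_i(d_i−1)) with C_i = 0 for d_i < 2. Max-weight
   normalization keeps C_i ≤ 1; it also makes C invariant to uniform weight
   rescaling, which is why the synthetic group effect is planted as edge
   *removal* rather than uniform attenuation. On binary weights C reduces
   to the unweighted clustering coefficient.

5. **Group statistics.** Each variable (five WISC-IV indices; each metric ×
   band) is screened per group with a one-sample Kolmogorov–Smirnov test
   against a normal with the sample's own mean/SD; variables normal in both
   groups use the pooled-variance two-sample t (the pooled form, not Welch,
   exactly reproduces the published fixture t-values), others the
   Mann–Whitney U (exact enumeration when n₁+n₂ ≤ 12 and tie-free,
   tie-corrected normal approximation otherwise). Routing can be forced
   either way. Correlations are Pearson or Spearman by the same logic.
   Multiplicity is controlled per family — the five scores form one family,
   each metric's bands another — by the rank-indexed FDR rule: p-values
   sorted ascending, rank index i (ties receive the average of their
   ranks), rank-wise threshold α·i/N, step-up decision (the largest p at or
   below its threshold becomes the realized cutoff p*, and everything ≤ p*
   is significant). With distinct p-values this is exactly
   Benjamini–Hochberg. The reported `fdr_threshold` is p*, so
   `significant == (p ≤ fdr_threshold)` holds row by row; the rank-wise
   bound is exported separately, because under step-up an item can be
   significant while exceeding its own rank threshold.

## Synthetic cohorts

Each channel is a sum of per-band unit-variance carriers (white noise passed
through the *same* band filters the pipeline uses, normalized by the
filter's noise power gain) scaled by band amplitudes, plus white sensor
noise, globally rescaled to a target RMS of 0.5 pT. Default band amplitudes
fall off with frequency (δ 1.0, θ 0.8, α 0.9, β 0.6, γ 0.4, ripple 0.2,
fast ripple 0.1; sensor noise SD 0.3), a coarse 1/f-like profile.

A planted edge (i, j, band, r) requests expected correlation r *after the
pipeline re-filters the data into that band*. Within each band the carriers
are mixed through the Cholesky factor of a target correlation matrix with
off-diagonal mixing weights w = r·V_b/(a_b²·X_bb), where X_bb is the
fraction of carrier power surviving re-filtering and V_b the total variance
landing in the band (all carriers' cross-band leakage plus filtered sensor
noise). All gain factors are 2/fs·∫|H|⁴-type integrals of the actual filter
responses, computed on an 8192-point frequency grid — calibration is
analytic, not fitted; Monte-Carlo checks show the mean empirical R within
±0.01 of target at K = 18000. Requests pushing |w| to 1 or making the
target matrix indefinite raise an error (that correlation is unreachable
under the configured noise); indefiniteness within −0.05, as occasionally
produced by subject-level weight jitter on a feasible configuration, is
repaired by eigenvalue flooring with diagonal renormalization. Records are
synthesized with a 3/lo-second burn-in beyond both edges and trimmed, so
delivered samples carry no filter boundary transients.

The default planted topology is triangle modules (every within-module pair
at r = 0.5), which guarantees feasibility and provides the closed triangles
the clustering coefficient needs. Group structure: patients lose a
configurable fraction of planted edges per band (default 35% in β),
lowering CA and SA and raising LA. Subject heterogeneity: each subject
retains each edge with probability drawn uniformly from 0.8–1.0 and jitters
weights (subject-level SD 0.08, edge-level 0.05). Cognitive scores are
score = intercept + slope·metric_true + N(0, σ), clipped to the WISC-IV
range [40, 160], where metric_true comes from the subject's realized
planted graph via the same metric code the pipeline uses; the default
couples FSIQ to the true β-band CA (slope 40, intercept 69, noise SD 7),
placing patients near 85 and controls near 103 with a within-group
correlation in the 0.6–0.7 range typical of strong reported
metric–cognition couplings. Uncoupled scores are N(100, 12²). Artifact
injection adds Gaussian deflections exceeding the 6 pT screen; spike
injection adds 70–200 ms biphasic transients, both at seed-reproducible
positions.

What the generator does *not* emulate: realistic epileptiform morphology,
1/f-exact spectra, source leakage and field spread, volume conduction,
head movement, or physiological (cardiac/ocular) artifacts. Passing the
recovery experiments therefore certifies the statistical machinery — edge
detection calibration, metric computation, test routing, FDR behaviour —
under the stated signal model, not performance on real MEG.

## Validation experiments and problem sizes

Desk-scale study conditions (all configurable):

* **Null edge retention**: 30 unfiltered i.i.d. channels, K = 2000, 10
  replicates — the only regime where raw K is the true sample count, hence
  where the nominal α retention rate is the correct expectation.
* **Planted-edge recovery**: 20 channels (six triangle modules + 2
  uncoupled), β band, fs 300 Hz, 60 s (K = 18000), r = 0.5, 50 seeds,
  effective-K thresholding; reports sensitivity and per-edge FPR.
* **Cohort recovery**: 50 planted + 50 null replicate cohorts of 22
  patients vs 18 controls, 9 channels, θ/α/β bands, fs 300 Hz, 20 s
  windows; full screening → connectivity → metrics → FDR-corrected CA
  comparison per band, plus the within-patient FSIQ~CA Spearman sign.
* **Graph-metric oracles**: every connected topology on ≤6 nodes (142
  graphs, random weights) against exhaustive simple-path enumeration and
  direct triple summation, plus 100 random 8–12-node graphs against
  Floyd–Warshall (and a networkx cross-check in the tests), at 1e-10.

Published-table fixtures pin exact values: the demographic summaries of the
22-patient cohort (age 8.14 ± 1.73, 11:11 sex ratio) and the pooled t for
VCI (−7.2), PRI (−5.6) and FSIQ (−7.8) from the printed group summaries.
The printed PSI and WMI t-values are inconsistent with their own printed
means/SDs under any standard two-sample formula (WMI's recomputed value
matches PSI's printed one, suggesting a column swap at publication) and are
not used as fixtures.

## Known limitations

* Zero-lag correlation only; no coherence, phase-locking, lagged or partial
  measures, and no source-leakage correction.
* The raw-K edge threshold is anticonservative on band-limited data; the
  effective-K option mitigates but assumes stationarity.
* The FDR family structure (scores; per-metric bands) is a design choice;
  other partitions are defensible and configurable.
* The KS normality screen with estimated parameters is conservative
  (Lilliefors-uncorrected); it is a router, not an inferential claim.
* LA's harmonic form tolerates disconnected graphs but is not comparable
  with the arithmetic-mean path length used by some other packages.
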