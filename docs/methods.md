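# Methods

## Deletion-library model

A loop scan is defined by three inclusive intervals in full-length
numbering: the `loop_span` used for length accounting (fixture 308–321,
14 residues), the `rebuild_span` of residues remodelled per variant
(311–321) and the `scan_span` eligible for deletion (313–321, sequence
`QSRKVGDSP`). One variant exists per (window size, start); the canonical
ordering — ascending size, then ascending N→C start, indexed from 1 — is
the identity used everywhere downstream. The default size set is {1..6},
which over a 9-residue scan yields Σₖ(9−k+1) = 39 variants; {1..7} is a
configuration flag away. A 14-residue loop with a size-k deletion leaves
a loop of 14−k residues.

Sequence-level deduplication (`dedupe_identical`) is off by default: in
repeat-containing loops different windows can excise identical
substrings. The packaged scan itself contains one such pair — windows
314–319 (`SRKVGD`) and 315–320 (`RKVGDS`) read identically because both
boundaries are serines — but the two remain distinct structural variants
(different residues deleted, different remaining residue ids), so the
library keeps both.

Deletion variants keep wild-type residue numbering with gaps. A contact
defined at a wild-type position p is re-addressed in a variant by the
N-anchor ordinal rule: the residue occupying p's ordinal position
counted from the N-terminal loop anchor. This makes slot resolution the
identity whenever the window lies C-terminal of the slot, and returns
the C-terminal anchor (with a warning) when the truncated loop is
shorter than the ordinal. The rule is a convention; a
nearest-neighbour-in-space resolver would be a reasonable alternative,
but the ordinal rule is deterministic, needs no structure, and matches
how shifted residues are discussed in the field.

## Ensemble statistics

Conformer ensembles are N poses of the same molecule in one rigid-body
frame (loops rebuilt on a fixed protease body), with one score (REU) per
pose. Statistics therefore use **no re-superposition**; a Kabsch
superposition onto body Cα atoms (`superpose_to_body`) exists for
foreign ensembles. All arithmetic is done in float64 regardless of the
float32 PDB coordinates.

* **Mean structure** — per-atom arithmetic mean of coordinates ("the
  geometric mean structure" in common usage; a true geometric median is
  out of scope).
* **RMSF** — per atom, √(meanₙ|xₙ−⟨x⟩|²); the scalar summary is the
  average over the selection (default: heavy atoms of the rebuild span).
  Single-pose ensembles are degenerate and report zeros.
* **Funnel** — per-pose RMSD to the lowest-scoring pose (ties break to
  the lowest pose index) against score; heavy atoms of the rebuild span.
  The funnel summary statistic is the Spearman correlation.
* **Low-energy selections** — the n lowest-scoring poses (stable
  tie-break by index), and representatives from "RMSD groupings":
  equal-width bins over the RMSD axis, per-group lowest scores, empty
  bins reported rather than back-filled. Equal-width binning is the
  simplest defensible reading of grouping on an RMSD axis; k-medoids
  would be an alternative but adds a stochastic dependency.
* **Hydrogen bonds** — heavy-atom donor–acceptor distances only (the
  criteria in this field's loop analyses are N···O distances, not
  angles). A series is summarised by mean and population SD; the
  `stable` flag keys on the mean lying in the 2.5–3.8 Å window (±1e-9
  boundary tolerance for float round-off), the SD is reported
  unthresholded. Histograms use fixed 0.1 Å bins over 2.5–4.0 Å, and
  `in_range_frequency` counts poses inside that range (inclusive).
* **Contacts** — frequency of per-pose distance strictly below 3.5 Å.
* **Helix tilt** — angle between the first principal component of the
  helix Cα set (oriented N→C) and the vector between two selection
  centroids, in [0, 180]°. All selections are configuration. For real
  crystal structures `helix_angle_from_structure` reads the first model,
  drops hetero atoms/hydrogens and auto-detects the chain; the packaged
  reference selections (helix 164–169, loop-insert 170, body 223–225 in
  chymotrypsin numbering) are checked against the two reference entries
  in a network-dependent test.

All thresholds above are surfaced as `PipelineConfig` fields, not
constants buried in logic.

## Kinetics models

Model classes follow the Model → `fit()` → Results pattern: each is
constructed from a `RateSeries` (x strictly increasing, ≥4 points; ≥5
levels for the titration models) and returns a `KineticsResults` with
point estimates, asymptotic standard errors, residuals, R² and a
`summary()` table.

* Michaelis–Menten: v = V_max·S/(K_M+S); k_cat = V_max/[E].
* Competitive inhibition (fixed S, K_M supplied from the substrate
  titration): v = V·S/(K_M(1+I/K_i)+S). A series whose rates do not fall
  below 80 % of the uninhibited rate is rejected as having no
  inhibition signal.
* Hyperbolic binding: v = v₀+(v∞−v₀)·T/(K_d+T), with a tight-binding
  quadratic variant behind a flag for titrations where the titrant does
  not greatly exceed the enzyme (the default is hyperbolic because
  cofactor titrations run in µM against nM–pM enzyme). A fitted K_d
  beyond the titration range attaches a non-saturation warning.
* Initial rate: OLS slope over progress-curve points with t ≤ 5 min
  (window configurable), requiring ≥3 points.

Fitting is unweighted nonlinear least squares (the loss a bench
scientist's fitting software applies by default); positive parameters
are fitted on the log scale, with delta-method standard errors, and
starting values come from linearisations (Hanes–Woolf for
Michaelis–Menten). Replicates are averaged before fitting by default —
reported assay values in this field are typically means of duplicates —
with per-replicate fitting available by simply fitting each series.

WT-normalisation multiplies each metric by 100/reference. For K_i the
emitted `pct_ki` is variant/reference ("percentage K_i of the
reference", >100 % = weaker binding); because the opposite convention
also appears in the literature, the reciprocal is emitted alongside as
`pct_ki_inverse`. Normalisation is scale-invariant by construction. The
heatmap table sorts reference-first, then descending loop length, then
deletion position, and renders percentage columns on a log-scaled
diverging colour map centred at 100 %.

## Synthetic data generator

The generator's role is to produce every pipeline input with known
ground truth, at the scale of the packaged study conditions: 250 poses
per variant; substrate titration 0–12.5 mM (8 levels); inhibition at
1 mM fixed substrate; cofactor titration 0–3 µM; 10-minute progress
curves read over the first 5 minutes; duplicate replicates;
multiplicative Gaussian noise of 2 %.

**Backbone construction.** Chains are built in torsion space (NeRF
placement) with fixed ideal geometry (N–CA 1.458 Å, CA–C 1.525 Å,
C–N 1.329 Å, C=O 1.231 Å, standard angles, ω = 180°); carbonyl O and CB
are placed analytically from the mainchain, side chains are represented
by CB only (sufficient for N/O/CB contact statistics).

**Loop closure.** Cyclic coordinate descent (CCD) over the loop's φ/ψ
torsions closes each chain onto a fixed three-atom C-anchor target
(C of the last loop residue, N and CA of the next body residue), each
sweep applying the closed-form optimal rotation per torsion.
Torsion-only moves leave bond lengths and angles exactly invariant
(verified to 1e-9 Å). Convergence is anchor-atom RMSD < 0.1 Å within
1000 sweeps; the inner loop is numba-compiled when numba is available,
with an identical pure-Python fallback. CCD here is a simple,
well-defined sampler for generating valid closed ensembles — it is
explicitly not a reimplementation of any production loop-modelling
protocol, and the conformational distribution it produces carries no
physical energy model.

**The synthetic body.** A deterministic stand-in protease environment:
an α-helical segment (residues 305–310) from which the loop grows, a
C-side strand (322–324) defining the closure target, and a contact
shelf (residues 366, 372, 373, 374) placed so that the wild-type native
loop forms a 3.0 Å hydrogen bond from the 315 backbone N to the 372
carbonyl O and 3.2–3.4 Å contacts around the 319 side chain. The native
wild-type loop is hairpin-like (two extended strands around a turn),
chosen so the anchor separation (~9 Å) remains reachable by the
shortest (5-residue) rebuilt variants. Per pose, native torsions are
perturbed by Normal(0, 25°) and re-closed; failed closures are
resampled, and a failure rate above 50 % raises an error suggesting a
larger tolerance.

**Ground truth.** Pseudo-energies are score = 1.0 REU/Å × RMSD-to-native
+ Normal(0, 0.2 REU), which guarantees funnel-shaped score/RMSD plots
(Spearman ≥ 0.9 at these defaults). Planted contacts draw a Bernoulli(f)
mask per pose and move the loop-side atom along the pair axis into
2.8–3.3 Å (contact) or 4.6–6.0 Å (apart); the realised mask is recorded,
so the frequency estimator can be checked for exactness, not just
consistency. The single-atom move trades local ideal geometry for an
exactly known contact fraction — it is a statistical truth-maker, not a
physical model. The Gaussian test ensemble (iid per-axis displacement,
E[RMSF] → σ√3) is the closed-form oracle for fluctuation statistics.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: no physical force field or Ramachandran
statistics (pseudo-energies are linear in RMSD by construction, so
funnel checks validate the statistics code, not any modelling
protocol); no side chains beyond CB, no solvent, no crystal-contact or
glycan effects; kinetic noise is iid multiplicative Gaussian, without
plate-position or day effects; variant kinetic parameters in the
end-to-end panel are seeded log-normal multipliers around the reference
values (geometric SD ≈ 1.6 for K_M/K_i/K_d, ≈ 1.4 for k_cat), a
realistic spread that asserts nothing about any particular variant's
biology.

## Pipeline and determinism

`run_pipeline(config, out_dir)` is a pure function of (config, seed):
one master `SeedSequence` derives per-variant generator seeds, and the
manifest records package version, seed, config, collected warnings and
SHA-256 checksums of every output file. Stage failures halt with partial
outputs retained. Config is YAML with strict unknown-key rejection.

Problem sizes: the acceptance script runs the full 39-variant × 250-pose
panel (about a minute on one CPU, numba-accelerated closure); the test
suite exercises the same code path at 40 poses per variant plus a
determinism check on a sub-panel, keeping the default suite fast.

## Known limitations

* The helix-angle calibration against the two reference crystal
  structures needs network access to fetch them; offline runs exercise
  the angle computation on synthetic geometry only.
* CCD convergence degrades for very short loops far from their anchors;
  the generator resamples failures, so heavily truncated variants are
  drawn from the conditional distribution of closable perturbations.
* Score tables are joined strictly on `pose_<n>` tags in model order;
  arbitrary external tag schemes must be renamed to `tag`/`reu` columns.
* `variant_sequence` rendering requires a context sequence covering the
  scan span; libraries built without one skip sequence-level dedupe.
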