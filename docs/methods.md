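# Methods

`unzipmap` models a single-molecule DNA-unzipping "roadblock" assay: an
optical trap mechanically separates the two strands of a dsDNA construct,
and proteins bound along the segment (a transcription elongation complex
stalled by nucleotide starvation at position A20, a catalytically dead Cas
effector held on DNA by its gRNA) perturb the unzipping force relative to
the naked-DNA baseline.  After a chase in which the motor (RNAP, or the
Mfd translocase loaded at the stalled complex) translocates toward the
bound dCas, the re-unzipped tethers fall into discrete outcome categories,
and a conditional-probability estimator converts per-chamber category
fractions into the probability that a collision-competent motor read
through (or removed) the roadblock.

## Equilibrium unzipping theory

The naked-DNA baseline treats the fork position j (base pairs unzipped) as
an equilibrium degree of freedom at each controlled end-to-end extension
z.  The energy of state j is

  E(j; z) = Σ_{k<j} ΔG_open(k) + A_stretch(j, z)

where ΔG_open(k) is the opening cost of base pair k and A_stretch is the
Helmholtz stretching free energy of the dsDNA arms plus the 2j released
ssDNA nucleotides held at extension z.  The force at (j, z) solves
z = N_arm·x_ds(f) + 2j·x_ss(f); A_stretch is recovered from tabulated
work integrals by Legendre back-transform (A = f·z − N_arm·w_ds(f) −
2j·w_ss(f), w = ∫ x df).  The observable curve is the Boltzmann-weighted
mean force and mean fork position versus z (weight truncation 1e-12).
Averaging over j — rather than taking the minimum-energy fork — is what
produces the thermal "breathing" softening ahead of weakly paired regions.

Opening costs come from a unified nearest-neighbor ΔH/ΔS table (1 M NaCl
reference), ΔG(T) = ΔH − TΔS, with a per-base-pair monovalent-salt
correction ΔG(c) = ΔG(1 M) − 0.114·ln(c) kcal/mol.  Defaults: T = 298.15 K
(the trap runs ~2 K above room temperature from local laser heating) and
c = 100 mM, the transcription-buffer KCl concentration.  The literature
does not pin a unique parameter set for this conversion, so the table,
salt coefficient and temperature are all fields of `ThermoParams`.

Elasticity: ssDNA is an extensible freely-jointed chain (contour
0.56 nm/nt, Kuhn length 1.5 nm, stretch modulus 800 pN); dsDNA is an
extensible worm-like chain via the Marko–Siggia interpolation plus an
enthalpic f/S term (0.338 nm/bp, persistence length 43 nm, stretch modulus
1200 pN); kT = 4.116 pN·nm.  These are standard optical-tweezers values
and are configurable through `ElasticParams`.  Trap compliance is ignored:
"extension" means the DNA end-to-end distance.

With these defaults the mixed-sequence demo construct unzips on a
~15 pN plateau with a ±1.3 pN sequence sawtooth, and homopolymer plateaus
agree with the two-state work balance ΔG_open = 2∫₀^{f*} x_ss df to better
than 0.2 % (the test tolerance is 2 %).

## The demo construct

A 560-bp random segment at 50 % GC (fixed internal seed, so the construct
is stable across sessions) between dsDNA arms totalling 800 bp, emulating
the assay geometry: promoter and A20 stall site early in the segment, a
20-bp protospacer ~309 bp downstream with the PAM on its far (distal)
side.  Coordinates are 0-based, half-open, increasing along fork
progression; both unzipping directions are expressed by re-indexing the
same physical sequence (`UnzipConstruct.flipped()`).  The arms are kept
deliberately short relative to typical experimental constructs: the
differential compliance of arms + released ssDNA (~2.5 nm/pN at 15 pN)
sets both how much stored elastic energy a protein barrier must absorb and
how far the fork slips forward when the barrier yields, and short arms
keep protein peaks sharp enough that the ±6-bp clamp-matching window of
the classifier is meaningful at realistic noise.

## Trace rendering (synthetic data)

A rendered trace is the same equilibrium calculation run on a modified
energy landscape, so force, extension and fork position remain mutually
consistent under the downstream conversion:

* A clamped protein adds a Gaussian barrier (FWHM 8 bp) to the per-bp
  opening costs.  Its total energy is sized against the construct
  compliance — ½·C·Δf² plus the ssDNA release work across the footprint —
  so the rendered force rise reaches the requested amplitude (default
  8 pN above baseline).  The barrier is centered 1 bp downstream of the
  nominal site because the observed force peak sits at the stall point
  slightly upstream of the barrier centroid; with this calibration the
  called peak is unbiased (±~1 bp).
* The R-loop bubble removes pairing cost across the gRNA-DNA hybrid (the
  strands are already separated), tapering upstream over the 5-bp
  breathing offset.  The energy removed is 1.6× the naive work-balance
  equivalent of the requested dip amplitude (default 2.5 pN) because
  Boltzmann averaging shallows the equilibrium dip.
* dCas clamp placement: for PAM-proximal-first unzipping the clamp rise
  sits 6 bp past the PAM, matching the tight-binding site adjacent to the
  PAM; for PAM-distal-first unzipping it sits at the PAM-proximal end of
  the hybrid.  A colliding motor stalls with its front edge ~10 bp
  upstream of the hybrid (or 30 bp before the PAM on proximal-first
  templates); removal-then-stall traces place the motor peak inside the
  hybrid window at a half-normal invasion depth (mean 5 bp, s.d. 2 bp).
  An optional dual-conformation mode for dCas12a adds a second rise at the
  distal hybrid end with probability 0.57 (off by default; classification
  does not depend on it).

The modified curve is resampled uniformly in extension at 10 kHz for a
500 nm/s constant-velocity pull and Gaussian force noise (0.75 pN per raw
sample) is added; the processing chain decimates to 1 kHz by block
averaging, as the instrument does.  Per-sample force noise propagates into
fork-position noise through the construct compliance; after decimation and
1-bp binning the effective position scatter is well under 1 bp.

What the generator does **not** emulate: kinetics (elongation, pausing,
backtracking, GreB rescue, Mfd stepping — chase time and the 2.2 bp/s Mfd
rate are metadata only), re-zipping curves, instrument drift, bead-trap
hydrodynamics, multi-protein templates, and annealing of the nascent
transcript (the tether-shortening corrector is exercised on synthetic
injections).  Passing tests therefore demonstrate the correctness of the
measurement chain and estimator under the stated signature model, not
robustness to every artifact of real data.

## Outcome tree and estimator

Each chase trace draws: initial occupancy state (defaults 0.90 / 0.04 /
0.04 / 0.02 for both-bound / motor-only / dCas-only / naked, matching the
>90 % co-occupancy of the controls); motor noncollision dissociation
(p_motor_diss); collision competence (p_coll_comp — did the motor leave
A20 and reach the target); dCas spontaneous dissociation (p_dcas_diss);
and, when a competent motor meets a still-bound dCas, one of
read-through / removal-then-stall / blocked.  Motors that run unopposed
(dCas absent or lost) reach the template end; read-through and unopposed
runs end as naked DNA with probability p_runoff, else as a downstream
motor peak.  A motor that stalls upstream after its dCas dissociated
counts as motor-upstream-only, since categories are positional.

`expected_fractions` is the closed-form leaf distribution of this tree;
the estimator inverts it exactly:

  P_coll_comp = 1 − (F_TEC_up,dCas_f + F_TEC_up_only_f) /
                    [(F_A20,dCas_i + F_A20_only_i)(1 − P_motor_diss)]

  P_read_through = [F_Nak_f + F_TEC_dn_f − F_Nak_i
                    − F_A20,dCas_i (P_cc(1−P_m)+P_m) P_d
                    − F_A20_only_i (P_cc(1−P_m)+P_m)
                    − F_dCas_only_i P_d]
                   / [F_A20,dCas_i P_cc (1−P_m)(1−P_d)]

with P_m = P_motor_diss, P_d = P_dcas_diss; P_removal adds F_dCas_rem_f to
the bracket.  The identity estimator∘expected_fractions =
(p_coll_comp, p_read_through, p_read_through + p_removal_stall) holds to
machine precision for any valid configuration with nonzero denominators,
and is independent of p_runoff (the Nak/TEC_dn split cancels in the sum) —
this is the suite's centerpiece property test.  For Mfd the same equations
apply with P_Mfd_diss in place of P_RNAP_diss and no removal-stall
population.  Sampling noise can push plug-in estimates slightly outside
[0, 1]; they are flagged but never clipped, since clipping would bias the
cross-chamber mean.  Aggregation is the unweighted chamber mean with
s.e.m. = sample s.d. (n−1) / √n; nuisance uncertainty is not propagated.

## Trace processing and classification

* Conversion: j = (extension − N_arm·x_ds(f)) / (2·x_ss(f)); samples below
  3 pN are masked (the ssDNA model is degenerate near zero force); j < 0
  is clipped with a flag.
* Alignment: offset ∈ [−20, 20] bp (0.5-bp grid) and scale ∈ [0.95, 1.05]
  (0.005 grid) minimizing the 10 %-trimmed mean squared force residual on
  a 1-bp grid, so protein peaks do not bias the fit.  Residual r.m.s.
  above 1.5 pN flags the trace as unalignable (excluded downstream).
* Peak calling: maximal runs with force − baseline > +2 pN (rise) or
  < −1.5 pN (dip), minimum width 3 bp, runs merged across gaps < 3 bp;
  position is the bp of maximum |deviation|.  The outer 10 bp of the
  covered range are excluded (baseline poorly constrained at the start of
  unzipping and past the segment end).  Thresholds were chosen so the
  simulated null (naked traces at default noise) calls a false peak in
  < 5 % of traces; the source experiments do not state numeric thresholds,
  so all are configurable.
* Tether-shortening correction: the nascent transcript can anneal to the
  exposed ssDNA, registering as a backward jump in apparent bp at
  near-constant force and offsetting every later position.  The detector
  median-filters the bp series, estimates the local fork velocity and
  scatter robustly, and reports only jumps significant against that
  scatter (≥ 3 bp and ≥ 5 local s.e.); detected shifts are added back to
  calls in the dCas window.  On rendered traces (which contain no true
  events) the detector is silent.
* Classification: dCas presence requires the clamp rise within ±6 bp of
  its precisely known position — deliberately tighter than the generic
  15-bp site tolerance, because a motor that invaded the R-loop after
  removing the dCas peaks only ~10–15 bp away; the R-loop dip corroborates
  but is neither required (a colliding motor masks it) nor sufficient.
  The motor is the most advanced remaining rise.  Distance is measured to
  the PAM-proximal edge of the protospacer; a motor ≤ 60 bp upstream
  (70 bp for Mfd, its larger footprint) has collided, with the boundary
  inclusive ("more than the cutoff" is strictly greater).  Traces that fit
  no branch of the decision tree (e.g. a motor downstream of a still-bound
  dCas) are flagged and excluded rather than forced into a category, and
  label counts plus flags always conserve the trace count.

On rendered traces at default noise the pipeline recovers the generating
category at ≥ 95 % per category (typically ≈ 99 % overall) with called
positions within 3 bp of the truth for ≥ 95 % of calls.

## Benchmark conditions and problem sizes

`unzipmap.conditions` fixes one generator configuration per experimental
condition — dCas9/dCas12a approached from either side, ±GreB, modified
gRNAs (3-nt mismatch with its faster spontaneous dissociation, 5/6/7-nt
inverted repeats) and Mfd — with the condition's reported efficiency as
the generating truth, ~40 control and ~60 chase tethers per chamber
(80 chase for the slower Mfd reaction, with its higher noncollision loss
of 0.15), and the per-condition chamber counts of the experiments.  The
recovery tests run outcome-level (categories sampled directly, the
estimator's own regime) at this scale and accept within 3× the simulated
s.e.m., plus a 100×-trace-count run that must land within 1 % absolute.
Rendered-trace checks use 30 traces per category; these sizes keep the
full suite around two minutes on one core while leaving the statistical
assertions well-powered.

## Known limitations

* The equilibrium renderer slightly smears sharp features (two-state
  mixing across barrier crossings), so rendered rise amplitudes and the
  post-yield slip distance depend on arm length; the calibrations above
  are specific to order-hundreds-of-bp arms.
* The estimator is a plug-in ratio: with ~60 chase traces per chamber its
  per-chamber spread is several percentage points, and cross-chamber
  s.e.m. with 5–8 chambers is ~3 points.  This matches the scale of the
  emulated experiments; it is not a limitation of the algebra (the
  identity test is exact).
* Alignment assumes the theory baseline is correct up to a small offset
  and gentle stretch; gross miscalibration of the elastic parameters would
  surface as alignment failures, not silently wrong positions.
* Only single-dCas templates are classified; unannotated binding sites are
  out of scope.
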