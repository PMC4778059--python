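# Methods

## The model

The analysis treats the 3D position of one marker atom per ligand (for a
lipid inhibitor, the phosphate phosphorus) as the reaction coordinate of the
binding process, after every frame has been rigid-body superposed onto a
reference receptor structure. Binding pathways of lipid-like ligands are
slow, multi-basin processes — leaflet ↔ leaflet, leaflet ↔ surface vestibule,
vestibule ↔ bound pose — so the kinetics are modelled with a Markov state
model (MSM): discretize space, count transitions at a lag time Δt, estimate
a transition matrix, and read thermodynamics (stationary distribution) and
kinetics (implied timescales) off its spectrum.

Conventions used throughout: coordinates in Å, times in ns (μs only in
reporting), energies in kcal/mol. The transition matrix is stored
row-stochastically, `T[i, j] = P(j at t+Δt | i at t)`; the master-equation
form `P(t) = T_col(t) P(0)` with column-stochastic `T_col = exp(K t)` is the
transpose, and rate matrices `K` are stored in the column convention
(`K[i, j]` = rate j→i, columns sum to zero).

## Synthetic ground truth

Real trajectory data for this class of problem is rarely deposited, so the
package's test surface is a reversible continuous-time Markov jump process
with exactly known answers. The `"paper-hierarchy"` preset is a 4-state
chain L ↔ U ↔ V ↔ B (lower leaflet, upper leaflet, membrane vestibule,
bound) with:

- **Geometry** (fabricated for testability; no structural meaning):
  L = (0, 0, −20), U = (0, 0, 20), V = (20, 10, 25), B = (15, 5, 5) Å, with
  isotropic Gaussian jitter σ = 2 Å in every basin. Inter-center distances
  (≥ 21 Å) are far above the jitter, so basins are cleanly separable by
  distance clustering, and equal jitter makes voxel-density ratios equal
  stationary-probability ratios.
- **Thermodynamics**: π_B/π_U = exp(ΔG/kT) with ΔG = 2.0 kcal/mol and
  kT = 0.596 kcal/mol (300 K; configurable), π_L = π_U, and a vestibule
  weight π_V/π_U = 0.46 (≈ 0.47 kcal/mol above a leaflet). The first two
  are planted values; π_V is a free parameter of the construction, chosen
  once so that the timescale calibration below has an exact solution on the
  physically intended branch (see "Calibration").
- **Kinetics**: for each connected pair (i, j), k(j→i) = a_pair · π_i and
  k(i→j) = a_pair · π_j, which satisfies detailed balance identically. The
  three pair prefactors are calibrated so the exact relaxation times
  −1/μ_s of the rate matrix are 100 μs, 5 μs and 500 ns.

**Calibration.** The map from the three prefactors to the three timescales
is solved by damped least squares on log-prefactors, initialized from
two-state exchange estimates across each link (cut the chain at the link,
equate the link flux to the exchange rate between the two halves). This
initialization selects the solution branch on which the slowest mode is the
leaflet flip (eigenvector: L against everything else), the middle mode is
the membrane → vestibule capture and the fastest is the vestibule ↔ bound
exchange — the same process assignment the motivating study reports. The
system is degenerate in a non-obvious way: with an arbitrary π_V the three
targets may be unattainable (residuals stall at ~1%); π_V/π_U = 0.46 lies
on the exact-solution manifold, and the calibrated prefactors are frozen in
the code to machine precision (a regression test re-runs the calibration).

**Sampling.** Trajectories are exact Gillespie realizations started from π,
observed every `frame_interval` (default 10 ns), with positions
`center[state] + N(0, σ²I₃)`. Because emissions are i.i.d. given the hidden
state and basins do not overlap, the observed cluster process is *exactly*
Markov at every lag: recovery errors in the tests are purely statistical,
never discretization artifacts. The default study plan is 100 trajectories
× 300 μs (3·10⁶ frames, ≈30 ms aggregate).

**What the generator does not emulate**: molecular structure, membrane
chemistry, intra-basin diffusive memory (real MD positions decorrelate over
finite times; here jitter is white), anisotropic basins, and respawn-biased
sampling. Passing recovery tests therefore demonstrates the correctness of
the estimators on data that satisfies their assumptions, not robustness to
non-Markovian discretization error in real trajectories.

## Statistical resolution at the default plan

The planted thermodynamics make membrane states rare (π_L = π_U ≈ 0.032),
so the equilibrium flux across the L–U link at the planted 100 μs flip time
yields only ≈ 20 flip events in 30 ms of aggregate data. The slowest
timescale and π_L are therefore information-limited: across independent
replicates their recovery scatters by ≈ ±25% and ±40% respectively
(unbiased), while the 5 μs and 500 ns timescales (≈ 700–800 crossing events)
recover within a few percent and the 2.0 kcal/mol basin gap within
≈ 0.1 kcal/mol. Run-to-run scatter on the slow quantities is expected
behavior at this sampling depth, not an estimator defect; resolving the
flip to a few percent would need an order of magnitude more aggregate time.

## Estimation choices

- **Regular-space clustering**, cutoff 4 Å by default: below the ≥ 21 Å
  basin separation and above the 2 Å jitter. At 4 Å each basin splits into
  many microstates (the Gaussian cloud radius exceeds the cutoff); that is
  standard MSM practice and harmless here because intra-basin relaxation is
  instantaneous by construction. A single basin collapses to one center only
  when the cutoff exceeds the sampled cloud diameter (~9–13 Å depending on
  sample size).
- **Counting**: sliding window by default (uses all data); strided counting
  available where independence matters. Counting never crosses trajectory
  boundaries. Estimation is restricted to the largest strongly connected
  set; dropped states are reported, never silently discarded.
- **Reversible MLE**: fixed-point iteration on symmetric flows, initialized
  from symmetrized counts, stopping when the largest relative flow change
  falls below 1e−10 (at most 1e6 iterations; non-convergence is an error
  carrying the last iterate). The iteration ascends the likelihood; tests
  verify agreement with direct constrained optimization to 1e−5 on
  exhaustive small count matrices.
- **Spectra** are computed on the π-symmetrized matrix
  D^{1/2} T D^{−1/2} with a symmetric eigensolver, which guarantees real
  eigenvalues and π-orthogonal eigenvectors for reversible models.
  Eigenvalues numerically at 1 report an infinite ("beyond horizon")
  timescale; non-positive eigenvalues are excluded with a warning.
- **Process assignment**: states are ranked by |v_i|·π_i and only the top
  90% of that cumulative mass participates in the sign split (the remainder
  are spectators); the source is the side with lower stationary mass.
  Centroids are π-weighted means of member cluster centers. Note that for
  the flip mode the sink centroid lies near the bound basin, not the upper
  leaflet center: the upper side's stationary mass is dominated by B.
- **Ties and determinism**: nearest-center assignment breaks ties toward
  the lowest center index; all stochastic steps take explicit seeds; reports
  are byte-reproducible for a fixed configuration.

## Maps and free energies

Voxels are half-open boxes, lower edge inclusive, 0-based indices, voxel
centers at `origin + (i + 0.5)·spacing`; default spacing 1 Å with bounds
auto-fitted at a 3 Å margin. Frames outside the grid are counted and
reported (weight is conserved). Equilibrium reweighting assigns a frame in
cluster i the weight π_i/n_i — the simplest stationary-density estimator
given the MSM; frames in trimmed states get zero weight and are reported.
Free energy is G_v = −kT ln(w_v/w_max) (minimum 0, empty voxels +inf);
basin gaps use the region-population definition ΔG = −kT ln(W_b/W_a), with
the voxel-minimum difference reported as a secondary statistic. OpenDX
output is z-fastest, exports voxel centers as grid positions, and encodes
+inf as 9.999e+30 (documented in the file header).

## Featurization conventions

RMSD is mass-unweighted over the named selection after Kabsch superposition
on a receptor selection (the ligand itself is never fitted); the default
helix selection for flexibility analyses is residues 34–48. Hydration
counts water *molecules* (once each) with any atom strictly closer than the
cutoff (default 5 Å, strict `<`). Water residue names default to
{HOH, TIP3, WAT, SOL}. Ligand identity is tracked by atom index across
frames, never re-assigned by proximity: chemically indistinguishable
ligands are topologically distinct. With orthorhombic box lengths provided,
coordinates can be re-imaged by minimum image about the receptor centroid
before alignment; without box information coordinates are used as-is.
Degenerate alignment selections (< 3 points, collinear or coincident) are
rejected rather than silently fitted.

## Pipeline

Raw counts are pooled across all input trajectories. For adaptively
respawned datasets this biases raw populations toward the seeded regions;
the stationary reweighting of the maps corrects occupancies but not the
transition statistics, and the run report flags this rather than applying a
correction. Bootstrap intervals resample whole trajectories with
replacement (200 replicates by default, seeded) — an artifact of this
implementation, labelled as such in the report, since the motivating
analyses report no uncertainties. Stage resumption is content-hash based:
a stage re-runs iff its parameters or upstream hashes changed.

## Known limitations

- The slowest-process statistics at the default plan are information-limited
  (see above); headline slow-timescale values carry ~25% sampling scatter.
- The reversible MLE assumes the input counts come from a single stationary
  process; no hidden-state, coarse-graining (PCCA), Bayesian-posterior or
  committor machinery is included.
- The OpenDX reader supports uniform axis-aligned grids only.
- Binary trajectory input (DCD/XTC) requires the optional mdtraj extra and
  is a thin adapter; periodic-image handling assumes orthorhombic boxes.
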