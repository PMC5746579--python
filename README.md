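# glycoflow

Coarse-grained simulation and analysis of wall-bounded micro-flow over a
tethered-chain brush layer.

The package has two halves that communicate only through a trajectory file
contract:

* **Simulator** (`glycoflow.synthetic_microflow`): a reduced-unit particle
  model of thermally noisy solvent driven by a constant x-direction body
  force past wall-anchored stiff core oligomers bearing flexible tethered
  chains, confined between a frozen lower wall lattice and a frozen ceiling
  lattice.  Velocity-Verlet integration with a pairwise momentum-conserving
  Lowe–Andersen thermostat; WCA repulsion, harmonic bonds/tethers, angle
  stiffening on cores only.  Deterministic for a fixed (config, seed).
* **Analysis stack**:
  * `region_binning` — three stacked z-regions (near-wall `wg`, dendritic
    `d`, flow `f`), sliced/binned velocity profiles with time averaging,
    temporal layer contours, regional velocity series with dispersion, and
    a second-difference roughness statistic with K–S comparison.
  * `planar_field` — horizontal-layer velocity fields on a periodic grid,
    fixed-step RK4 streamlines with arc lengths, discrete vorticity, and
    histogram PDFs with an L1 convergence trace.
  * `shear_stats` — forward-difference shear stress `tau = mu * dv_x/dz`,
    per-instant regional series, two-sample Kolmogorov–Smirnov tests,
    ratio-exceedance reports, scenario comparison, Reynolds-number check.
  * `segment_dynamics` — translation alignment on a reference COM,
    polar-coordinate `(x, R, theta)` segment tracks, winding/swirl counts,
    block-bootstrap motion correlation, end-to-end/radius-of-gyration
    uncoiling series.
  * `trajectory_io` — extended-XYZ trajectories with velocities, topology
    TSV sidecars, TSV tables, single-frame PDB export.
  * `pipeline_cli` — end-to-end orchestration for multi-scenario runs
    (control / one-core / three-core) with a manifest.

## CLI

```bash
# simulate (TOML config mirrors SimConfig field names)
glycoflow simulate --config sim.toml --seed 1 --out traj.xyz

# analyses on any trajectory in the same format
glycoflow profile  --traj traj.xyz --topology traj.topology.tsv \
                   --slices 2,5,8 --bins 25 --out out/profile
glycoflow field    --traj traj.xyz --topology traj.topology.tsv --out out/field
glycoflow shear    --traj traj.xyz --topology traj.topology.tsv --mu 1.0 \
                   --out out/shear
glycoflow segments --traj traj.xyz --topology traj.topology.tsv --out out/segments
glycoflow compare  --a a/shear_series.tsv --b b/shear_series.tsv --out out/cmp

# full pipeline: simulate -> analyse -> report for several scenarios
glycoflow run --config pipeline.toml --out out/
```

Minimal `pipeline.toml`:

```toml
seed = 1

[simulation]
n_steps = 20000

[scenarios.three_core]
n_cores = 3

[scenarios.control]
n_cores = 0
```

## Units

The simulator runs in reduced units (epsilon = sigma = m = k_B = 1); every
trajectory carries a unit-scale map (default 1 length = 1 nm, 1 time =
1 ps).  Physical-unit shear-stress reporting uses the TIP3P water viscosity
constant 0.321 mPa s (`glycoflow.shear_stats.TIP3P_WATER_VISCOSITY`).

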