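# hjdimer

Trajectory analysis for cyanine dye dimers templated on DNA Holliday
junctions.

Covalently tethering two dyes (e.g. Cy5, Cy5.5) to the strands of a
four-arm DNA Holliday junction is a route to strongly coupled dye
aggregates whose optical behavior — H-like (stacked, blue-shifted) versus
J-like (end-to-end, red-shifted) — is set by the mutual geometry of the
dyes' transition dipoles. Molecular-dynamics trajectories of such
constructs are the natural way to study that geometry, but the analysis
layer between "trajectory" and "excitonic picture" is surprisingly
fiddly: dipole end-point extraction, orientation factors, screened
couplings, contact statistics, junction conformation. `hjdimer` packages
that layer as tested, reusable code.

## What it computes

Per frame, for a dye pair (m, n) with unit transition-dipole directions
μ̂ and inter-center unit vector R̂:

* **Orientation factor**
  κ_mn = μ̂_m·μ̂_n − 3(R̂·μ̂_m)(R̂·μ̂_n), with |κ| ≤ 2.
  |κ| ≤ 1 indicates predominantly stacked (H-like) dyes, |κ| > 1
  end-to-end (J-like) ones.
* **Center-to-center distance** R_mn (nm).
* **Excitonic coupling** J_mn (meV) in the extended dipole
  approximation: each dipole of magnitude μ_i (Debye) and length l_i is
  replaced by charges ±μ_i/l_i at the dye ends, and
  J_mn = J₀ [1/|r_m−r_n| + 1/|s_m−s_n| − 1/|r_m−s_n| − 1/|s_m−r_n|]
  with J₀ = μ_m μ_n / (4π ε₀ n² l_m l_n) and n the solvent refractive
  index (1.33). A point-dipole (κ μ_m μ_n / 4π ε₀ n² R³) form is included
  as the far-field cross-check.
* **Contact maps** over 26 residue groups (six central bases per strand +
  the dyes), contact = shortest representative-point distance ≤ 1.2 nm,
  with dyes represented by their center of mass *and* both ends.
* **Ensemble statistics**: |κ| vs R and |J| vs R heatmaps, H/J dimer
  classification, pooled multi-trial means ± SDs.
* **Junction geometry**: inter-duplex angle (IDA) and twist-angle time
  series from principal-axis fits to base-pair centroids.

A seed-controlled synthetic generator (rigid-rod dimer ensembles and a
pseudo-atom mock junction in Iso I / Iso II-like arrangements) provides
ground-truth inputs, so the entire pipeline is testable without running
MD.

## Worked example

```python
import hjdimer as h
from hjdimer.synthetic_data import dimer_dye_definitions

# a stacked Cy5-like dimer ensemble: R ~ N(0.5 nm, 0.04 nm), 10 deg
# orientational noise, 3000 frames at 100 ps
spec = h.SyntheticSpec(mode="H_dimer", n_frames=3000, seed=42)
traj, truth = h.generate_dimer_trajectory(spec)
dye_m, dye_n = dimer_dye_definitions(spec)

obs = h.observe_dimer(traj, dye_m, dye_n, coupling=h.CouplingConfig())
summary = h.summarize_trials([obs], with_J=True)
print(f"mean R      = {summary.mean('R'):.3f} +/- {summary.sd('R'):.3f} nm")
print(f"mean |kappa| = {summary.mean('abs_kappa'):.3f}")
print(f"mean |J|    = {summary.mean('abs_J'):.1f} +/- {summary.sd('abs_J'):.1f} meV")
print(f"class       = {h.classify(summary.mean('abs_kappa'), summary.mean('R')).label}")
```

prints

```
mean R      = 0.499 +/- 0.040 nm
mean |kappa| = 0.942
mean |J|    = 126.8 +/- 52.0 meV
class       = H_like_dimer
```

i.e. the analysis recovers the generator's construction: a closely
spaced (≈0.5 nm) stacked pair, |κ| just under 1 because of orientational
jitter, strong coupling on the 10²-meV scale, classified H-like dimer.

## Command line

The `hjdimer` console script ties the stages together around a single
YAML run configuration (see `hjdimer.config` for the schema):

```sh
hjdimer synth    --config run.yaml --out-prefix work/run     # synthetic inputs
hjdimer analyze  --config run.yaml --out-prefix work/out     # per-frame table + summary
hjdimer contacts --config run.yaml --out-prefix work/out     # contact maps
hjdimer heatmap  --config run.yaml --out-prefix work/out     # 2-D histograms
hjdimer junction --config run.yaml --out-prefix work/out     # IDA / twist series
```

Outputs are TSV/JSON; every file embeds the configuration hash and the
thresholds used. Repeated runs with the same config and seed are
byte-identical. Exit codes: 0 ok, 1 user error, 2 internal error.

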