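# smforce

Analysis of single-molecule FRET force-sensor data: how strongly, and how
often, do T-cell receptors (TCRs) pull on their pMHC ligands inside the
immunological synapse?

Peptide-based molecular force sensors (MFS) anchored in a supported lipid
bilayer report piconewton tension through FRET: the sensor is an entropic
spring flanked by a dye pair, so pulling extends it, separates the dyes,
and lowers the FRET efficiency. `smforce` turns single-molecule trajectory
tables (track id, frame, position, donor/acceptor intensities or
efficiency) into the quantities that matter:

- **Sensor calibration** — the linear spring law `F(r) = (r − b·n − c)/(a·n)`
  combined with the Förster relation `E(r) = (1 + (r/R0)^6)^−1` gives the
  closed-form map `F(E)` (defaults: `a = 0.0122 nm/pN`, `b = 0.044 nm`,
  `c = 2.4 nm`, `n = 29` residues, `R0 = 5.1 nm`), plus propagation of
  efficiency uncertainty into force uncertainty.
- **High-force fraction** — an empirical quantile threshold `q_f` at
  false-positive rate `f = 0.05` from cell-free data, the corrected
  fraction `n_low/n_total − f`, and a bootstrap that resamples whole
  tracks (observations within a track are correlated).
- **Force PDF** — average-shifted-histogram efficiency densities, scaled
  subtraction of the cell-free PDF (width-scaled about E = 0.87 and
  height-scaled by least squares on the no-force window E > 0.75), and
  conversion of the residual to a force PDF with quartiles.
- **Mobility classification** — smallest enclosing circle per track;
  tracks with reduced radius `radius/√duration < 0.35 μm·s^−0.5` are
  immobilized (TCR-bound proxy on fluid bilayers).
- **Hypothesis tests** — one-sided KS statistic with a track-preserving
  permutation null (9999 resamples; exact enumeration for small samples).
- **Bond lifetimes** — survival analysis of binding-event durations at
  multiple recording intervals and a global fit of
  `τ_app(Δt) = 1/(1/τ_bond + k_b/Δt)` that separates unbinding from
  photobleaching.
- **Synthetic data** — generators that emulate the statistical structure of
  sensor data (zero-force efficiency noise `N(0.865, 0.164)`, free
  diffusion at `D ≈ 0.7 μm²/s`, geometric track lengths, competing
  bleaching/unbinding), with per-track ground truth for validation.

## Worked example

Twenty percent of simulated tracks carry 5 pN; the rest are force-free
(`examples/03_force_pdf.py`):

```python
from smforce import SyntheticScenario, estimate_force_pdf, generate_force_dataset

cell = generate_force_dataset(
    SyntheticScenario(n_tracks=2000, phi_force=0.20, force_pN=5.0,
                      phi_immobile=0.2, cell_present=True, seed=11))
nocell = generate_force_dataset(SyntheticScenario(n_tracks=2000, seed=12))
pdf = estimate_force_pdf(cell.data["efficiency"], nocell.data["efficiency"])
```

prints

```
fitted scales: width 0.992, height 0.819
residual mass: 0.191
force quartiles: Q1 4.04  median 5.12  Q3 6.45 pN
```

The fitted height ≈ 0.82 is the unloaded share of the cell data (1 − φ),
the residual mass ≈ 0.19 is the loaded share, and the PDF median recovers
the injected 5 pN within half a piconewton; the interquartile range
reflects the sensor's efficiency noise, not force heterogeneity.

The other scripts in `examples/` walk through calibration and uncertainty
(`01`), the corrected high-force fraction with its track bootstrap (`02`),
mobility classification (`04`), the track-preserving permutation KS test
(`05`), bleaching-corrected bond lifetimes (`06`) and the full configured
pipeline with QC gates (`07`). The same stages are available from the
shell via the `smforce` CLI (`simulate`, `preprocess`, `force`, `mobility`,
`test`, `lifetime`, `run-all`, `qc`), configured by a YAML file written
with `smforce init-config config.yaml`.

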