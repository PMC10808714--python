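# flimmix

Fractional contributions of mixed fluorophores from TCSPC
fluorescence-lifetime decays.

When several fluorophores with overlapping emission spectra are excited
together, the recorded intensity decays as a multi-exponential

    I(t) = Σ_i α_i exp(-t / τ_i),

and the quantity of interest is each fluorophore's fractional contribution
to the emitted signal,

    P_i = α_i τ_i / Σ_j α_j τ_j.

Free multi-exponential fitting of the α_i, τ_i is notoriously ill-posed.
`flimmix` implements the direct route: a small fully connected neural
network maps a measured decay histogram straight to the fraction vector,
trained on Monte-Carlo simulated decays with known fractions.  The package
is aimed at users of time-resolved fluorescence instrumentation (FLIM,
lifetime cytometry, lifetime multiplex assays) who need fast, fit-free
unmixing and design rules for how far apart fluorophore lifetimes must be.

It contains:

* `flimmix.decay` — the decay model and a Monte-Carlo TCSPC simulator
  (312.5 ps bins over a 1.28 µs window by default, laser pulse with
  Gaussian core + exponential turn-off, SPAD jitter, Poisson background at
  a configured peak-to-background SNR);
* `flimmix.ann` — the feed-forward estimator: hidden layers (40, 20, 10)
  for two fluorophores, (70, 50, 30, 10) for more, ReLU, Adam, MSE loss,
  batch 500, 20 epochs, learning rate 1e-3; plus two-step `fine_tune` for
  labelled experimental curves;
* `flimmix.lsq` — a fixed-lifetime non-negative least-squares baseline;
* `flimmix.metrics` — accuracy ⟨ΔP⟩, precision σ, and R² per fluorophore;
* `flimmix.spacing` — lifetime-spacing sweeps, the minimal-spacing search
  at a 5 % precision target, and the fitted design law
  log10(Δτ_min) = slope · N + intercept;
* a `flimmix` command-line interface (`simulate`, `train`, `predict`,
  `evaluate`, `sweep`, `law`) over plain CSV/JSON/YAML artifacts.

## Worked example

```python
import flimmix as fm

instrument = fm.InstrumentConfig()          # 312.5 ps bins, SNR 100, 5e4 photons
lifetimes = [4.0, 9.0]                      # ns, two fluorophores 5 ns apart

train = fm.generate_dataset(10_000, lifetimes, instrument, seed=1)
test = fm.generate_dataset(2_000, lifetimes, instrument, seed=2)

model = fm.train(fm.build_estimator(2, seed=3), train)
report = fm.evaluate(fm.predict(model, test), test.labels)

comp = report.per_fluorophore[0]
print(f"mean offset {comp.mean_offset_signed:+.4f}")
print(f"precision   {comp.offset_std_signed:.4f}")
print(f"R^2         {comp.r_squared:.4f}")
```

Output:

```
mean offset -0.0041
precision   0.0121
R^2         0.9983
```

So at a 5 ns lifetime spacing the network recovers fractions essentially
without bias, with a precision of about 1.2 percentage points, and the
estimates track the reference fractions almost perfectly.  Rerunning with
`lifetimes = [4.0, 4.05]` (near-identical lifetimes) shows the opposite
regime: predictions collapse to the prior mean, the mean absolute offset
rises to ≈ 0.25, its spread to ≈ 0.145, and R² drops to ≈ 0 — unmixing is
impossible without lifetime contrast.

The same pipeline from the shell:

```sh
flimmix simulate --config sim.yaml --out data/ --seed 1
flimmix train    --data data/ --out model.npz --seed 3
flimmix predict  --model model.npz --data data/ --out predictions.csv
flimmix evaluate --pred predictions.csv --data data/ --out report.json
```

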