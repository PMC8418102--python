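# gammarkov

A Markovian model hierarchy for stochastic gamma oscillations in small
excitatory–inhibitory spiking networks, for computational neuroscientists
studying how gamma-band rhythms (25–140 Hz) emerge from the competition of
recurrent excitation and inhibition, and how far that emergence survives
aggressive model reduction.

The package implements three nested models of one 100-neuron network
(75 E, 25 I) and the machinery to compare them:

1. **MIF** — a Markovian integrate-and-fire network. Membrane potentials
   live on the integer lattice `{V_I, …, V_th} ∪ {R}`
   (`V_I = −66, V_r = 0, V_th = 100`); external Poisson kicks
   (`λ = 7000` Hz/neuron) raise `v` by 1; recurrent spikes join pending
   pools `H_i^{E,I}` and act after exponential delays
   (`τ_EE, τ_IE, τ_I`); E-kicks add `S_{QE}`, I-kicks subtract
   `(v−V_I)/(V_th−V_I)·S_{QI}`. Simulation is an exact exponential race,
   JIT-compiled.
2. **RN** — a reduced network of two-state neurons. Each neuron is *base*
   or *gate* (`v ≥ V_c`); per-kick flip probabilities
   `P̄_κ^{sQ}(N)` are learned from MIF event logs as conditional flip
   frequencies given the population's base/gate count.
3. **CG/SCG** — a four-variable Markov chain `(N_GE, N_GI, H_E, H_I)`
   with ≤ 12 transitions per state, its sparse generator over a truncated
   box, the stationary distribution π (solving `πQ = 0`), and a lumped
   ("shrunk") variant merging every K pending-kick counts.

Around the models: spike statistics (firing rates, spike synchrony index,
population PSD/spectrogram, spike-timing correlograms, multiple-firing-
event detection) and trajectory geometry (local-PCA participation-ratio
dimensionality, grid entropy, locally linear embedding, density maps).
Three regime presets — `Hom`, `Reg`, `Syn` — differ only in `(τ_EE, τ_IE)`
and span near-Poisson firing to strong gamma synchrony.

See `docs/methods.md` for the models, estimators, numerical choices and
known limitations.

## Worked example

```python
from gammarkov import make_regime
from gammarkov.mif import run_mif
from gammarkov.stats import firing_rates, ssi, psd, psd_peak, detect_mfes

params = make_regime("Reg")                      # tau_EE = 1.7 ms preset
res = run_mif(params, 3000.0, seed=1)            # 3 s, exact event-driven
fr_e, fr_i = firing_rates(res.train, params.N_E, params.N_I)
spectrum = psd(res.train, interval=(1000.0, 3000.0))
mfes = detect_mfes(res.train)
print(f"firing rates: E {fr_e:.1f} Hz, I {fr_i:.1f} Hz")
print(f"synchrony index (5 ms window): {ssi(res.train):.3f}")
print(f"PSD peak: {psd_peak(spectrum):.1f} Hz")
print(f"{len(mfes)} spiking volleys, mean waiting {mfes.waiting_times.mean():.1f} ms")
```

prints

```
firing rates: E 40.7 Hz, I 72.4 Hz
synchrony index (5 ms window): 0.410
PSD peak: 41.0 Hz
175 spiking volleys, mean waiting 17.1 ms
```

i.e. in the regular regime inhibition fires faster than excitation, spikes
cluster into volleys recurring every ~17–20 ms, and the population
spectrum peaks in the low gamma band. `res.projection` holds the
trajectory projected onto `(N_GE, N_GI, H_E, H_I)` for the manifold
analyses, and `run_mif(..., record_events=True)` additionally returns the
kick-effect log that `gammarkov.rn.estimate_table` turns into a reduced-
network flip table.

The same pipeline runs from the shell:

```sh
gammarkov simulate-mif --regime Syn --T 3000 --seed 1 --out-dir runs/mif
gammarkov estimate-rn  --regime Syn --T 3000 --seed 1 --out-dir runs/table
gammarkov simulate-rn  --regime Syn --T 3000 --seed 2 \
    --table runs/table/table.json --out-dir runs/rn
gammarkov simulate-cg  --regime Syn --T 3000 --seed 3 \
    --table runs/table/table.json --out-dir runs/cg
gammarkov stats --spikes runs/mif/spikes.tsv --out-dir runs/stats
```

Every command writes TSV/JSON data plus a `manifest.json` (config, seed,
version, outputs, wall clock) sufficient to re-run bit-identically.

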