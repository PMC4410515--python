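#!/usr/bin/env python
"""Generate the default synthetic participant dataset.

Simulates 26 participants watching 10 without-replacement draws from a
coin-selected urn, computes the objective posterior and explanatory-power
scores under all five study measures, and draws credences from the published
generating coefficients with Gaussian noise.  Writes
results/synthetic_trials.csv.
"""

from pathlib import Path

from explanationism import GeneratorConfig, generate_dataset, write_trials

out_dir = Path(__file__).resolve().parents[1] / "results"
out_dir.mkdir(exist_ok=True)

config = GeneratorConfig(seed=20260927)
table = generate_dataset(config)
write_trials(table, out_dir / "synthetic_trials.csv", float_format="%.6g")

n_a = sum(1 for u in table.attrs["selected_urns"] if u == "A")
print(f"Generated {len(table)} rows ({config.n_participants} participants x "
      f"{config.n_draws} draws); urn A selected for {n_a} participants.")
print(f"Credence truncation rate: {table.attrs['truncation_rate']:.2%} "
      "(resampled, not clipped).")
print(table.head(10).round(4).to_string())
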