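#!/usr/bin/env python
"""Simulate SPR sensorgram sets at the measured rates and re-fit them.

For the wild type and the two strongly improved double mutants:
noiseless self-consistency (the fit must return the generating rates)
and a noisy recovery study at 2 RU Gaussian noise over the experimental
protocol (90 s association, 30 min dissociation, 4 nM - 2 uM ladder).
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from affmat.kinetics import fit_langmuir, sensorgrams_to_frame
from affmat.synthetic import make_sensorgram_set

RATES = {
    "Wild-type": (2.84e4, 2.22e-3),
    "M41E/F63W": (2.01e4, 5.23e-7),
    "V134L/H159Q": (4.41e4, 6.12e-6),
}

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--noise-sd", type=float, default=2.0)
parser.add_argument("--outdir", default="results")
args = parser.parse_args()

outdir = Path(args.outdir)
outdir.mkdir(parents=True, exist_ok=True)

rows = []
ss = np.random.SeedSequence(args.seed)
for (name, (ka, kd)), child in zip(RATES.items(), ss.spawn(len(RATES))):
    clean = make_sensorgram_set(ka, kd, 100.0)
    fit0 = fit_langmuir(clean)
    noisy = make_sensorgram_set(
        ka, kd, 100.0, noise_sd=args.noise_sd,
        seed=int(child.generate_state(1)[0] % (2 ** 31)))
    fit1 = fit_langmuir(noisy)
    rows.append({
        "mutant": name, "true_ka": ka, "true_kd": kd, "true_KD": kd / ka,
        "noiseless_ka": fit0.ka, "noiseless_kd": fit0.kd,
        "noisy_ka": fit1.ka, "noisy_kd": fit1.kd, "noisy_KD": fit1.KD,
        "noisy_KD_rel_err": abs(fit1.KD - kd / ka) / (kd / ka),
    })
    if name == "Wild-type":
        sensorgrams_to_frame(noisy).to_csv(
            outdir / "sensorgrams_wildtype_noisy.csv", index=False)

frame = pd.DataFrame(rows)
frame.to_csv(outdir / "spr_recovery.csv", index=False)
print(frame.to_string(index=False))
print("\nNote: ultra-slow dissociation (kd ~ 5e-7 /s) decays <0.1% within "
      "the 30 min window, so its noisy-fit KD is identified only weakly - "
      "the same limitation the instrument protocol has.")
print(f"wrote {outdir/'spr_recovery.csv'}")
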