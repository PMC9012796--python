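#!/usr/bin/env python
"""Effect of carrier-liquid viscosity: saline vs. Icodextrin 4% / 7.5%.

The three carriers nebulize to the same ~30 um droplets; in this one-way
coupled model the liquid enters the transport only through droplet density,
so differences between carriers are expected to be small (the stronger
experimental effect runs through atomization, outside this model's scope).
Writes results/viscosity_sweep.csv.
"""

from pathlib import Path

from pipacsim import SimulationConfig, SweepSpec, run_sweep

RESULTS = Path(__file__).resolve().parents[1] / "results"
N_PARCELS = 5000
SEEDS = (0, 1, 2)


def main():
    base = SimulationConfig(n_parcels=N_PARCELS)
    spec = SweepSpec(axis="viscosity", base=base,
                     replicates=len(SEEDS), seeds=SEEDS)
    table = run_sweep(spec)
    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "viscosity_sweep.csv"
    table.to_csv(out, index=False)
    summary = table.groupby("value")[["region1_pct", "homogeneity"]].mean()
    print("mean over seeds by carrier viscosity (mPa s):")
    print(summary.round(3).to_string())
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
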