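#!/usr/bin/env python
"""Generate the synthetic cadaver study analysed by the following steps.

Simulates 10 specimens with the default error models (mandibular condylar
repositioning error, intrinsic splint error, anisotropic screw-deformation
noise) and writes the landmark CSV, the ground-truth transform JSON and the
simulation config under results/study/.
"""

from pathlib import Path

from splintacc.io import write_landmarks
from splintacc.simulate import SimulationConfig, simulate_study

SEED = 42
OUT = Path(__file__).resolve().parent.parent / "results" / "study"


def main() -> None:
    config = SimulationConfig()
    specimen_set, truth = simulate_study(config, seed=SEED)
    OUT.mkdir(parents=True, exist_ok=True)
    write_landmarks(specimen_set, OUT / f"landmarks_seed{SEED}.csv")
    (OUT / f"ground_truth_seed{SEED}.json").write_text(truth.to_json() + "\n")
    (OUT / f"sim_config_seed{SEED}.json").write_text(config.to_json() + "\n")
    print(
        f"simulated {specimen_set.n_heads} heads "
        f"({len(specimen_set.triads)} triads, seed {SEED}) -> {OUT}"
    )


if __name__ == "__main__":
    main()
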