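#!/usr/bin/env python
"""Simulate one high-shock animal's full experiment and write it to disk.

Generates every session of the retrospective memory-linking paradigm
(neutral/aversive encoding, two offline periods, three recall sessions, a
CNO chemotag session) with planted ground truth, and writes the manifest
under results/example_mouse/. Later scripts analyse this animal.
"""

from pathlib import Path

from coreact import io as io_mod
from coreact.simulate import SimulationConfig, simulate_experiment

OUT = Path(__file__).resolve().parent.parent / "results" / "example_mouse"
SEED = 42


def main() -> None:
    config = SimulationConfig.high_shock()
    exp, truth = simulate_experiment(config, seed=SEED)
    manifest = io_mod.write_experiment(exp, OUT)
    print(f"wrote {manifest}")
    print(f"group: {exp.group_label}; sessions: {sorted(exp.sessions)}")
    counts = {
        k: sum(v == k for v in truth.ensembles["offline2"].values())
        for k in ("neutral", "aversive", "overlap", "remaining")
    }
    print(f"offline-2 ensembles: {counts}")
    print(f"planted offline-2 bursts: "
          f"{truth.bursts['offline2']['windows'].shape[0]}")


if __name__ == "__main__":
    main()
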