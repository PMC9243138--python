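#!/usr/bin/env python
"""Simulate the demo recording session.

Generates a paired Dys/BF session (400 units over 8 region x layer strata,
balanced archetype mixture, region-specific suppression probabilities
echoing the stronger noxious-heat suppression of barrel-field units) and
writes the session tables plus ground truth under results/session/.
"""

import argparse
from pathlib import Path

from noxtact import SessionConfig, simulate_session, write_session

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--out", type=Path, default=Path("results/session"))
args = parser.parse_args()

config = SessionConfig(
    n_units_per_stratum=50,
    # compositional asymmetry of the two subregions: the dysgranular zone is
    # nociception-preferring, the barrel field tactile-preferring
    region_mixture={
        "Dys": {"nociceptive": 0.45, "tactile": 0.10,
                "integrative": 0.25, "none": 0.20},
        "BF": {"nociceptive": 0.05, "tactile": 0.50,
               "integrative": 0.15, "none": 0.30},
    },
    suppressed_prob={"Dys": 0.22, "BF": 0.60},
    suppression_factor=0.3,
)
session, truth = simulate_session(config, seed=args.seed)
write_session(session, args.out)
truth.units.to_csv(args.out / "ground_truth.csv", index=False)

n_spikes = sum(u.n_spikes for u in session.units)
print(f"wrote {len(session.units)} units ({n_spikes} spikes, "
      f"{session.heat.duration:.1f} s) to {args.out}")
print(truth.units["label"].value_counts().to_string())
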