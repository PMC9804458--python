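"""Random-but-valid parameter sets for property-based testing.

Each set jitters every primitive around the packaged defaults by a uniform
+/-30% factor (proportions clipped away from their bounds), which keeps all
structural invariants (positive durations, life span exceeding maturity,
diet budgets) satisfied by construction while exploring a wide region of
parameter space.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .parameters import default_config

__all__ = ["generate_parameter_sets", "write_fixture"]

_PROPORTION_KEYS = (
    "nu", "mu_A", "mu_J",
    "preypref_A_C", "preypref_H_C", "preypref_H_R", "preypref_E_R",
)


def generate_parameter_sets(seed: int, n_sets: int) -> list[dict[str, float]]:
    """``n_sets`` jittered primitive-parameter mappings, deterministic per
    seed.  Each mapping is a valid ``load_parameters`` configuration."""
    if n_sets < 1:
        raise ValueError(f"n_sets must be >= 1, got {n_sets}")
    rng = np.random.default_rng(seed)
    base = default_config()
    sets: list[dict[str, float]] = []
    for _ in range(n_sets):
        out: dict[str, float] = {}
        for key, mean in base.items():
            v = float(mean) * rng.uniform(0.7, 1.3)
            if key in _PROPORTION_KEYS:
                v = float(np.clip(v, 1e-3, 0.98))
            out[key] = v
        sets.append(out)
    return sets


def write_fixture(path, seed: int, n_sets: int) -> Path:
    """Write the jittered parameter sets to a YAML file (a list of
    configuration mappings)."""
    path = Path(path)
    sets = generate_parameter_sets(seed, n_sets)
    path.write_text(yaml.safe_dump(sets, sort_keys=True))
    return path
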