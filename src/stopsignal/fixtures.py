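"""Deterministic canned cohorts for tests and examples.

Three small synthetic cohorts, each fully determined by a fixed seed:

* ``no_slowing``  — stationary participants, one environment;
* ``lab_like``    — individual + group lab environments, mild drift;
* ``online_like`` — online environment with pronounced strategic slowing.
"""

from __future__ import annotations

import pandas as pd

from .simulate import CohortSpec, EnvironmentSpec, SessionDesign, simulate_cohort
from .trial_model import DisplayModel

__all__ = ["canned_cohort", "CANNED_COHORTS"]

_FIXED_SEEDS = {"no_slowing": 11, "lab_like": 22, "online_like": 33}

CANNED_COHORTS = tuple(_FIXED_SEEDS)


def canned_cohort(name: str, n_per_environment: int = 6) -> pd.DataFrame:
    """Return one of the canned cohorts as a trial table."""
    if name not in _FIXED_SEEDS:
        raise KeyError(f"unknown cohort {name!r}; choose from {CANNED_COHORTS}")
    seed = _FIXED_SEEDS[name]
    if name == "no_slowing":
        envs = {
            "individual": EnvironmentSpec(
                n=n_per_environment, go_mu_ms=(360.0, 80.0), slowing_slope=(0.0, 0.0)
            )
        }
    elif name == "lab_like":
        envs = {
            "individual": EnvironmentSpec(
                n=n_per_environment, go_mu_ms=(362.0, 90.0), slowing_slope=(0.2, 0.5)
            ),
            "group": EnvironmentSpec(
                n=n_per_environment, go_mu_ms=(383.0, 100.0), slowing_slope=(0.3, 0.5)
            ),
        }
    else:
        envs = {
            "online": EnvironmentSpec(
                n=n_per_environment, go_mu_ms=(464.0, 110.0), slowing_slope=(0.9, 0.9)
            )
        }
    cohort = CohortSpec(environments=envs, seed=seed)
    return simulate_cohort(cohort, SessionDesign(), DisplayModel(60.0))
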