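"""Packaged reference values: the published comparator table and the
published longitudinal estimates (used as generating truth for synthetic
trials and as the precision-summary fixture)."""

from __future__ import annotations

import json
from importlib import resources

import numpy as np

from .longitudinal import ETA_NAMES, ArmFixedEffects, CovariateEffects


def _read(name: str) -> dict:
    return json.loads(resources.files("promirt._assets").joinpath(name).read_text())


def load_mmrm_reference() -> dict:
    """Raw published mean (95% CI) CFB table for both analysis methods."""
    return _read("mmrm_reference.json")


def load_longitudinal_reference() -> dict:
    """Raw published longitudinal-model estimates with RSEs."""
    return _read("longitudinal_reference.json")


def reference_rse_entries(ref: dict | None = None) -> list[float]:
    """All reported relative standard errors of the longitudinal model
    (fixed effects, variances on the SD scale, correlations, residual,
    covariate effects) in table order."""
    ref = ref or load_longitudinal_reference()
    out = []
    for arm in ref["arms"].values():
        for key in ("theta0", "t_prog", "r_max", "gamma", "offset",
                    "omega2_theta0", "omega2_t_prog", "omega2_r_max", "omega2_offset"):
            out.append(arm[key]["rse"])
        for c in arm["corr"]:
            out.append(c["rse"])
    sh = ref["shared"]
    out.append(sh["sigma2"]["rse"])
    out.append(sh["smoking"]["rse"])
    for k in sorted(sh["region"]):
        if sh["region"][k]["rse"] is not None:
            out.append(sh["region"][k]["rse"])
    return out


def _arm_omega(arm: dict) -> np.ndarray:
    sd = np.sqrt([arm[f"omega2_{e}"]["value"] for e in ETA_NAMES])
    C = np.eye(4)
    for c in arm["corr"]:
        i, j = (ETA_NAMES.index(p) for p in c["pair"])
        C[i, j] = C[j, i] = c["value"]
    return sd[:, None] * C * sd[None, :]


def reference_trial_params(ref: dict | None = None):
    """Published estimates as a :class:`~promirt.longitudinal.TrialParams`-style
    generating-truth structure."""
    from .uncertainty import ArmParams, TrialParams  # local import to avoid a cycle

    ref = ref or load_longitudinal_reference()
    arms = {}
    for name, arm in ref["arms"].items():
        fixed = ArmFixedEffects(theta0=arm["theta0"]["value"], t_prog=arm["t_prog"]["value"],
                                r_max=arm["r_max"]["value"], gamma=arm["gamma"]["value"],
                                offset=arm["offset"]["value"])
        arms[name] = ArmParams(fixed=fixed, omega=_arm_omega(arm))
    cov = CovariateEffects(
        smoking=ref["shared"]["smoking"]["value"],
        region={int(k): v["value"] for k, v in ref["shared"]["region"].items() if int(k) != 2},
    )
    return TrialParams(arms=arms, cov_effects=cov, sigma2=ref["shared"]["sigma2"]["value"])
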