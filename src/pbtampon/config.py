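"""Flat key-value configuration for the release model.

The config dialect is a flat YAML mapping whose keys are the canonical
parameter names (``R_release``, ``Q_abs``, ``Papp``, ``Area``, ``V_menses``,
``f_unbound``, ``RBC_part_coef``) plus the schedule keys
(``tampon_content_ng``, ``fraction_released``, ``release_duration_h``,
``wear_time_h``, ``sim_end_h``).  Unspecified keys fall back to the baseline
defaults, and a resolved config round-trips unchanged through
:func:`dump_config` / :func:`load_config`.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .model import ModelParams, ReleaseSchedule

__all__ = ["PARAM_KEYS", "SCHEDULE_KEYS", "resolve_config", "load_config", "dump_config"]

#: config key -> ModelParams attribute
PARAM_KEYS: dict[str, str] = {
    "R_release": "r_release",
    "Q_abs": "q_abs",
    "Papp": "papp",
    "Area": "area",
    "V_menses": "v_menses",
    "f_unbound": "f_unbound",
    "RBC_part_coef": "k_rbc_plasma",
}

#: config key -> ReleaseSchedule attribute
SCHEDULE_KEYS: dict[str, str] = {
    "tampon_content_ng": "tampon_content",
    "fraction_released": "fraction_released",
    "release_duration_h": "release_duration",
    "wear_time_h": "wear_time",
    "sim_end_h": "sim_end",
}


def resolve_config(overrides: dict | None = None) -> tuple[ModelParams, ReleaseSchedule]:
    """Build params and schedule from a flat override mapping.

    Raises
    ------
    ValueError
        naming the offending key for unknown keys or invalid values.
    """
    overrides = dict(overrides or {})
    p_kw, s_kw = {}, {}
    for key, value in overrides.items():
        if key in PARAM_KEYS:
            p_kw[PARAM_KEYS[key]] = float(value)
        elif key in SCHEDULE_KEYS:
            s_kw[SCHEDULE_KEYS[key]] = float(value)
        else:
            raise ValueError(
                f"unknown config key {key!r}; expected one of "
                f"{sorted(PARAM_KEYS) + sorted(SCHEDULE_KEYS)}"
            )
    try:
        params = ModelParams(**p_kw)
        schedule = ReleaseSchedule(**s_kw)
    except ValueError as exc:
        raise ValueError(f"invalid configuration: {exc}") from exc
    return params, schedule


def load_config(path: str | Path) -> tuple[ModelParams, ReleaseSchedule]:
    """Read a flat YAML config file; absent keys keep their defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a flat key-value mapping")
    return resolve_config(data)


def dump_config(params: ModelParams, schedule: ReleaseSchedule) -> dict[str, float]:
    """Fully resolved flat mapping (for embedding in reports)."""
    out: dict[str, float] = {}
    for key, attr in PARAM_KEYS.items():
        out[key] = getattr(params, attr)
    for key, attr in SCHEDULE_KEYS.items():
        out[key] = getattr(schedule, attr)
    return out
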