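"""Shipped parameter presets: channel kinetics, I_NaT fits, cohort tables.

All presets live in YAML files under ``arcophys/params`` and are loaded
lazily.  Users can load their own files with the same schema through
:func:`load_resurgent_channel` / :func:`load_nat_preset`.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import yaml

from .gating import RateLaw, ResurgentChannelParams
from .nat import TransientNaParams

__all__ = [
    "resurgent_channel",
    "nat_preset",
    "nat_gate_kinetics",
    "cohort_table",
    "cohort_group_names",
    "load_resurgent_channel",
    "load_nat_preset",
    "NAT_PRESETS",
]

NAT_PRESETS = ("adult_24C", "juvenile_20dph_24C")


def _read_params_yaml(name: str) -> dict:
    ref = resources.files("arcophys").joinpath("params", name)
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


def _channel_from_dict(d: dict) -> ResurgentChannelParams:
    def law(block):
        return RateLaw(form=block["form"], A=float(block["A"]),
                       V0=float(block["V0"]), K=float(block["K"]),
                       Q=float(block.get("Q", 1.0)))
    return ResurgentChannelParams(
        alpha_s=law(d["alpha_s"]), beta_s=law(d["beta_s"]),
        alpha_f=law(d["alpha_f"]), beta_f=law(d["beta_f"]),
        g_NaR=float(d.get("g_NaR", 1.0)), E_NaR=float(d.get("E_NaR", 67.0)),
        dt_default=float(d.get("dt", 0.03)))


@lru_cache(maxsize=None)
def resurgent_channel(g_NaR: float | None = None) -> ResurgentChannelParams:
    """The shipped (synthetic, calibrated) resurgent channel parameter set.

    ``g_NaR`` overrides the maximal conductance (uS); the default is the
    adult-calibrated value.  The juvenile calibration uses
    ``resurgent_channel(g_NaR=0.0005)``.
    """
    ch = _channel_from_dict(_read_params_yaml("resurgent_rates_synthetic.yaml"))
    if g_NaR is not None:
        ch = ch.with_conductance(g_NaR)
    return ch


#: juvenile-calibrated resurgent conductance (uS): near-absent I_NaR
G_NAR_JUVENILE = 0.0005


def load_resurgent_channel(path) -> ResurgentChannelParams:
    """Load a resurgent-channel parameter file (YAML, same schema as shipped)."""
    with open(path) as fh:
        return _channel_from_dict(yaml.safe_load(fh))


def _nat_from_dict(d: dict) -> TransientNaParams:
    keys = ("g_max", "V_rev", "V_half", "k", "tau_a", "N", "tau_h")
    return TransientNaParams(**{k: float(d[k]) for k in keys})


@lru_cache(maxsize=None)
def nat_preset(name: str) -> TransientNaParams:
    """Named I_NaT preset ('adult_24C' or 'juvenile_20dph_24C')."""
    table = _read_params_yaml("nat_presets.yaml")
    if name not in table:
        raise KeyError(f"unknown I_NaT preset {name!r}; have {sorted(table)}")
    return _nat_from_dict(table[name])


def nat_preset_extras(name: str) -> dict:
    """Auxiliary preset fields (onset_latency, h_half, h_slope)."""
    table = _read_params_yaml("nat_presets.yaml")
    d = table[name]
    return {"onset_latency": float(d.get("onset_latency", 0.0)),
            "h_half": float(d.get("h_half", -65.0)),
            "h_slope": float(d.get("h_slope", 6.0))}


def nat_gate_kinetics(name: str):
    """Gate-ODE simulator for a named I_NaT preset (for multi-step protocols)."""
    from .vc import NaTGateKinetics
    extras = nat_preset_extras(name)
    return NaTGateKinetics(nat_preset(name), h_half=extras["h_half"],
                           h_slope=extras["h_slope"])


def load_nat_preset(path, name: str | None = None) -> TransientNaParams:
    with open(path) as fh:
        table = yaml.safe_load(fh)
    if name is None:
        if len(table) != 1:
            raise ValueError("file holds several presets; pass name=")
        name = next(iter(table))
    return _nat_from_dict(table[name])


@lru_cache(maxsize=None)
def cohort_table() -> dict:
    """Per-group (mean, SEM, N) statistics for the synthetic cohort generator."""
    return _read_params_yaml("cohort_tables.yaml")


def cohort_group_names() -> list:
    return sorted(cohort_table().keys())
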