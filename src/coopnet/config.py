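"""YAML configuration round-trip for network simulations.

The config file is a plain key-value YAML document mirroring
:class:`coopnet.network_sim.NetworkConfig`, with nested sections ``ou``,
``gains`` and ``coop``. Omitted keys take the package defaults (the
published parameter tables).
"""

from __future__ import annotations

from dataclasses import asdict

import yaml

from .cooperative_nmda import CooperativityParams, GainTable
from .external_drive import OUParams
from .network_sim import NetworkConfig

__all__ = ["config_to_dict", "config_from_dict", "load_config", "save_config"]


def config_to_dict(config: NetworkConfig) -> dict:
    d = asdict(config)
    d["profile_modes"] = list(config.profile_modes)
    return d


def config_from_dict(d: dict) -> NetworkConfig:
    d = dict(d)
    if "ou" in d and isinstance(d["ou"], dict):
        d["ou"] = OUParams(**d["ou"])
    if "gains" in d and isinstance(d["gains"], dict):
        d["gains"] = GainTable(**d["gains"])
    if "coop" in d and isinstance(d["coop"], dict):
        d["coop"] = CooperativityParams(**d["coop"])
    if "profile_modes" in d:
        d["profile_modes"] = tuple(d["profile_modes"])
    return NetworkConfig(**d)


def load_config(path) -> NetworkConfig:
    """Read a NetworkConfig from a YAML file (missing keys -> defaults)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def save_config(config: NetworkConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)
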