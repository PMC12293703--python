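"""YAML run-configuration loading for the command-line interface.

Expected layout::

    exposure: {path: exposure.tsv, name: SHBG, type: quantitative, n: 312215,
               schema: {variant_id: SNP, pvalue: P}}   # schema optional
    outcomes:
      - {path: stroke.tsv, name: any_stroke, type: binary, n: 446696}
    mediators:
      - name: WC
        discovery:   {path: wc_giant.tsv, type: quantitative, n: 232101}
        replication: {path: wc_ukb.tsv,   type: quantitative, n: 336639}
    ld: ld.tsv                      # optional
    params: {p_instr: 5e-8, clump_r2: 0.001, proxy_r2: 0.8,
             palindrome_window: 0.08, alpha: 0.05, n_sim: 1000, seed: 7}
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .exceptions import ConfigurationError
from .io import read_ld_table, read_summary_table
from .network import MediatorPair, NetworkConfig, StepConfig

_PARAM_MAP = {
    "p_instr": "p_threshold",
    "clump_r2": "clump_r2",
    "proxy_r2": "proxy_r2_min",
    "palindrome_window": "palindrome_window",
    "alpha": "alpha",
    "n_sim": "presso_nsim",
    "seed": "seed",
}


def _load_dataset(entry: dict, default_name: str, base: Path):
    if "path" not in entry:
        raise ConfigurationError(f"dataset entry missing 'path': {entry}")
    path = Path(entry["path"])
    if not path.is_absolute():
        path = base / path
    return read_summary_table(
        path,
        schema=entry.get("schema"),
        trait_name=entry.get("name", default_name),
        trait_type=entry.get("type", "quantitative"),
        sample_size=int(entry.get("n", 0)),
    )


def load_run_config(path) -> NetworkConfig:
    """Parse a YAML run configuration into a :class:`NetworkConfig`."""
    path = Path(path)
    base = path.parent
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict) or "exposure" not in raw:
        raise ConfigurationError(f"{path}: configuration must define an 'exposure'")

    exposure = _load_dataset(raw["exposure"], "exposure", base)
    outcomes = [_load_dataset(o, f"outcome{i}", base)
                for i, o in enumerate(raw.get("outcomes", []), 1)]
    if not outcomes:
        raise ConfigurationError(f"{path}: at least one outcome is required")

    mediators = []
    for m in raw.get("mediators", []):
        name = m.get("name")
        if not name or "discovery" not in m or "replication" not in m:
            raise ConfigurationError(f"mediator entry needs name/discovery/replication: {m}")
        mediators.append(MediatorPair(
            name,
            _load_dataset({**m["discovery"], "name": name}, name, base),
            _load_dataset({**m["replication"], "name": name}, name, base),
        ))

    ld = None
    if raw.get("ld"):
        ld_path = Path(raw["ld"])
        ld = read_ld_table(ld_path if ld_path.is_absolute() else base / ld_path)

    params = raw.get("params", {}) or {}
    unknown = set(params) - set(_PARAM_MAP)
    if unknown:
        raise ConfigurationError(f"unknown params: {sorted(unknown)}")
    step = StepConfig(**{_PARAM_MAP[k]: type(getattr(StepConfig(), _PARAM_MAP[k]))(v)
                         for k, v in params.items()})

    return NetworkConfig(exposure=exposure, outcomes=outcomes, mediators=mediators,
                         ld=ld, step=step, bonferroni=bool(raw.get("bonferroni", False)))
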