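"""CSV and config-file input/output.

Response matrices travel as CSV with one row per person and columns
item1..itemJ; missing cells are written as empty fields and read back from
either empty fields or "NA". An optional leading person-id column is
accepted and ignored on read. Configs are flat key: value text files
(YAML-compatible).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import ItemBank, ResponseData, SimulationConfig

__all__ = ["read_responses", "write_responses", "read_config", "write_config"]


def read_responses(path: str | Path) -> ResponseData:
    """Read a response matrix from CSV (empty fields or NA = missing)."""
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=True)
    item_cols = [c for c in df.columns if c.lower().startswith("item")]
    if not item_cols:
        # no item-named header: every non-id column is an item
        item_cols = [c for c in df.columns if c.lower() not in ("id", "person", "person_id")]
    values = df[item_cols].to_numpy(dtype=float)
    return ResponseData(values, labels=tuple(item_cols))


def write_responses(data: ResponseData, path: str | Path) -> None:
    """Write a response matrix to CSV with empty fields for missing cells."""
    df = pd.DataFrame(data.values, columns=list(data.labels))
    # keep observed cells as integers in the file
    df = df.astype("Int64")
    df.to_csv(path, index=False, na_rep="")


def read_config(path: str | Path) -> SimulationConfig:
    """Parse a flat key-value config file into a SimulationConfig.

    Recognized keys: N, J, difficulties, mu, sigma2, rho, w, pi,
    replications, seed. When difficulties are given J is implied; with J
    alone the default five-item bank must match.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: dict = {}
    if "difficulties" in raw:
        diffs = raw["difficulties"]
        if isinstance(diffs, str):
            diffs = [float(x) for x in diffs.replace(",", " ").split()]
        kwargs["bank"] = ItemBank(np.asarray(diffs, dtype=float))
    elif "J" in raw and int(raw["J"]) != 5:
        raise ValueError("give explicit difficulties when J != 5")
    coerce = {"N": ("n_persons", int), "mu": ("mu", float),
              "sigma2": ("sigma2", float), "rho": ("rho", float),
              "w": ("w", int), "pi": ("pi", float),
              "replications": ("replications", int), "seed": ("seed", int)}
    for src, (dst, cast) in coerce.items():
        if src in raw:
            kwargs[dst] = cast(raw[src])
    return SimulationConfig(**kwargs)


def write_config(config: SimulationConfig, path: str | Path) -> None:
    payload = {
        "N": config.n_persons,
        "J": config.bank.n_items,
        "difficulties": [float(d) for d in config.bank.difficulties],
        "mu": config.mu,
        "sigma2": config.sigma2,
        "rho": config.rho,
        "w": config.w,
        "pi": config.pi,
        "replications": config.replications,
        "seed": config.seed,
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
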