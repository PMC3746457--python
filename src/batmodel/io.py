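"""Readers/writers for trial tables, posterior samples and run configs.

The single table dialect is comma-separated UTF-8 text with an explicit
header and "." decimals. A trial table carries one row per trial with the
canonical schema (subject_id, prime, session, trial_index, trial_type,
outcome, rt_ms, latent_c); missing RTs and latent states are empty fields.
Posterior samples are written as one column per parameter, one row per
retained draw, with a YAML sidecar holding the run metadata (seed,
iterations, burn-in, acceptance rate).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fitting import PosteriorSamples
from .synthetic import TRIAL_TABLE_COLUMNS

__all__ = [
    "RunConfig",
    "read_trials",
    "write_trials",
    "write_posterior",
    "read_posterior",
]

_REQUIRED = [c for c in TRIAL_TABLE_COLUMNS if c not in ("rt_ms", "latent_c")]
_PRIMES = {"clever", "stupid"}
_TRIAL_TYPES = {"bivalent", "univalent"}


@dataclass
class RunConfig:
    """Defaults for a full pipeline run; round-trips through YAML.

    Holds the study's analysis constants: epoch lengths (20 CC / 3 EC
    trials), the MCMC budget (20,000 iterations, 10,000 burn-in), the fixed
    RT noise used in subject fits, and analysis toggles.
    """

    n_iter: int = 20_000
    n_burn: int = 10_000
    seed: int = 0
    sigma_rt: float = 100.0
    n_cc: int = 20
    n_ec: int = 3
    tail: str = "two"
    rt_policy: str = "all"

    def __post_init__(self) -> None:
        if not 0 <= self.n_burn < self.n_iter:
            raise ValueError("need 0 <= n_burn < n_iter")
        if self.tail not in ("one", "two"):
            raise ValueError("tail must be 'one' or 'two'")
        if self.rt_policy not in ("all", "correct_only"):
            raise ValueError("rt_policy must be 'all' or 'correct_only'")
        if self.sigma_rt <= 0:
            raise ValueError("sigma_rt must be positive")
        if self.n_cc < 1 or self.n_ec < 1:
            raise ValueError("epoch lengths must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def read_trials(path) -> pd.DataFrame:
    """Read and validate a canonical trial table.

    Raises ValueError naming the first offending row and field for missing
    columns, non-binary outcomes, non-positive RTs, or unknown labels.
    Missing ``rt_ms`` fields are parsed as absent (NaN), never as zero.
    """
    table = pd.read_csv(path)
    missing = [c for c in _REQUIRED if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if "rt_ms" not in table.columns:
        table["rt_ms"] = np.nan
    if "latent_c" not in table.columns:
        table["latent_c"] = pd.array([pd.NA] * len(table), dtype="Int64")

    def _offend(mask, field_name, reason):
        if mask.any():
            row = int(np.flatnonzero(mask.to_numpy())[0])
            raise ValueError(
                f"{path}: row {row + 2} field {field_name!r} {reason} "
                f"(value {table.iloc[row][field_name]!r})"
            )

    _offend(~table["outcome"].isin((0, 1)), "outcome", "must be 0 or 1")
    _offend(~table["prime"].isin(_PRIMES), "prime", "must be clever/stupid")
    _offend(~table["trial_type"].isin(_TRIAL_TYPES), "trial_type",
            "must be bivalent/univalent")
    _offend(table["rt_ms"].notna() & (table["rt_ms"] <= 0), "rt_ms",
            "must be positive where present")
    _offend(table["session"] < 1, "session", "must be a positive integer")
    _offend(table["trial_index"] < 1, "trial_index", "must be a positive integer")
    lat = table["latent_c"]
    _offend(lat.notna() & ~lat.isin((0, 1)), "latent_c", "must be 0/1 where present")
    table["latent_c"] = table["latent_c"].astype("Int64")
    return table[TRIAL_TABLE_COLUMNS]


def write_trials(table: pd.DataFrame, path) -> None:
    """Write a trial table in the canonical delimited-text format."""
    table.to_csv(path, index=False)


def write_posterior(samples: PosteriorSamples, path) -> None:
    """Write retained draws as CSV plus a ``<path>.meta.yaml`` sidecar."""
    path = Path(path)
    samples.to_dataframe().to_csv(path, index=False)
    path.with_suffix(path.suffix + ".meta.yaml").write_text(
        yaml.safe_dump(samples.metadata(), sort_keys=False)
    )


def read_posterior(path) -> PosteriorSamples:
    """Read a posterior written by :func:`write_posterior`."""
    path = Path(path)
    frame = pd.read_csv(path)
    meta = yaml.safe_load(path.with_suffix(path.suffix + ".meta.yaml").read_text())
    names = list(meta["parameters"])
    return PosteriorSamples(
        names=names,
        draws=frame[names].to_numpy(),
        log_scores=frame["log_score"].to_numpy(),
        n_total=meta["n_total"],
        n_burn=meta["n_burn"],
        acceptance_rate=meta["acceptance_rate"],
        seed=meta["seed"],
    )
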