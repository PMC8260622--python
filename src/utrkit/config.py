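"""Flat key=value run configuration.

Every stochastic operation in the toolkit takes its randomness from the
single ``seed`` entry, so two runs with an identical config (seed included)
produce byte-identical outputs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

from .io import UtrkitError

DEFAULTS: dict[str, Any] = {
    "seed": 0,
    # te_quant
    "te.min_rna_count": 10,
    "te.min_rpf_count": 10,
    # utr_prep
    "prep.target_len": 100,
    "prep.linker": "CAACAA",
    # features
    "features.k_set": "1,2,3",
    "features.engine": "nussinov",
    # surrogate
    "surrogate.model": "random_forest",
    "surrogate.n_folds": 5,
    "surrogate.n_estimators": 500,
    "surrogate.log_transform": True,
    # ga_design
    "ga.pop_size": 100,
    "ga.max_generations": 50,
    "ga.n_keep": 5,
    "ga.min_hamming": 5,
    "ga.min_improvement": 0.05,
    "ga.mutation_rate": 0.02,
    "ga.crossover_rate": 0.5,
    "ga.elitism_count": 2,
    "ga.tournament_size": 3,
    # screen_analysis
    "screen.max_mismatch": 0,
    "screen.pseudocount": 0.5,
    "screen.min_fold": 1.5,
    "screen.alpha": 0.05,
    "screen.log2_line": 0.52,
    # simdata
    "sim.utr_len_min": 30,
    "sim.utr_len_max": 300,
    "sim.depth": 1_000_000,
    "sim.dispersion": 0.1,
    "sim.snr": 2.0,
    "sim.cell_noise_sd": 0.5,
    "sim.replicates": 2,
}


class RunConfig:
    """Typed flat configuration with seed-driven determinism.

    Values are coerced to the type of the corresponding default.  Serializes
    to and parses from a flat ``key = value`` file.
    """

    def __init__(self, **overrides: Any) -> None:
        self._values = dict(DEFAULTS)
        for key, val in overrides.items():
            self[key] = val

    def __getitem__(self, key: str) -> Any:
        return self._values[key]

    def __setitem__(self, key: str, value: Any) -> None:
        if key not in DEFAULTS:
            raise UtrkitError(f"unknown config key {key!r}")
        self._values[key] = _coerce(key, value, DEFAULTS[key])

    def get(self, key: str, default: Any = None) -> Any:
        return self._values.get(key, default)

    @property
    def seed(self) -> int:
        return self._values["seed"]

    def k_set(self) -> tuple[int, ...]:
        return tuple(
            int(tok) for tok in str(self._values["features.k_set"]).split(",")
        )

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for key in sorted(self._values):
                fh.write(f"{key} = {self._values[key]}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        cfg = cls()
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise UtrkitError(
                        f"{path} line {lineno}: expected 'key = value'"
                    )
                key, _, val = line.partition("=")
                cfg[key.strip()] = val.strip()
        return cfg

    def __eq__(self, other: object) -> bool:
        return isinstance(other, RunConfig) and self._values == other._values

    def __repr__(self) -> str:
        return f"RunConfig({self._values!r})"


def _coerce(key: str, value: Any, default: Any) -> Any:
    if isinstance(default, bool):
        if isinstance(value, bool):
            return value
        token = str(value).strip().lower()
        if token in ("true", "1", "yes"):
            return True
        if token in ("false", "0", "no"):
            return False
        raise UtrkitError(f"config {key!r}: cannot parse bool from {value!r}")
    if isinstance(default, int):
        return int(value)
    if isinstance(default, float):
        return float(value)
    return str(value)
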