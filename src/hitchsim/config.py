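"""Run configuration, validation and result serialization.

Configs are YAML with two optional blocks::

    params:            # SimulationParams fields (defaults filled in)
      sigma: 1.8
      s_b: 0.2
    experiment:
      n_trials: 5000
      sigma_grid: [0.56, 1.0, 1.33, 1.8]
      master_seed: 42
      trajectory: false
      log_level: info

Unknown keys anywhere are errors, so typos cannot silently fall back to
defaults.  Trial tables round-trip through CSV and batch summaries through
JSON; every artifact embeds the master seed and the full parameter set.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .dynamics import Outcome, TrialResult, Winner
from .experiments import OutcomeSummary
from .model import SimulationParams

__all__ = [
    "RunConfig",
    "load_config",
    "params_to_dict",
    "write_trials",
    "read_trials",
    "write_summary",
    "read_summary",
]

_PARAM_FIELDS = {f.name for f in dataclasses.fields(SimulationParams)}
_EXPERIMENT_FIELDS = {"n_trials", "sigma_grid", "master_seed", "trajectory",
                      "log_level"}

TRIAL_COLUMNS = ["trial_id", "seed", "sigma", "outcome", "winner",
                 "established_wt", "established_mut", "generations",
                 "cycles", "extinct"]


@dataclass
class RunConfig:
    """Validated simulation parameters plus experiment settings."""

    params: SimulationParams = field(default_factory=SimulationParams)
    n_trials: int = 1000
    sigma_grid: list[float] | None = None
    master_seed: int = 0
    trajectory: bool = False
    log_level: str = "info"

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("experiment.n_trials must be >= 1")
        if self.sigma_grid is not None:
            if not self.sigma_grid:
                raise ValueError("experiment.sigma_grid must be non-empty")
            for s in self.sigma_grid:
                if s <= 0:
                    raise ValueError("experiment.sigma_grid values must be positive")
        if self.log_level not in ("debug", "info", "quiet"):
            raise ValueError("experiment.log_level must be debug, info or quiet")


def _build_params(mapping: dict) -> SimulationParams:
    unknown = set(mapping) - _PARAM_FIELDS
    if unknown:
        raise ValueError(f"unknown params key(s): {sorted(unknown)}")
    try:
        return SimulationParams(**mapping)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid params block: {exc}") from exc


def load_config(path: str | Path) -> RunConfig:
    """Load and fully validate a YAML run configuration.

    An empty file yields all defaults.  Validation errors name the offending
    key.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(raw) - {"params", "experiment"}
    if unknown:
        raise ValueError(f"{path}: unknown top-level key(s): {sorted(unknown)}")
    params = _build_params(raw.get("params") or {})
    exp = raw.get("experiment") or {}
    unknown = set(exp) - _EXPERIMENT_FIELDS
    if unknown:
        raise ValueError(f"{path}: unknown experiment key(s): {sorted(unknown)}")
    return RunConfig(params=params, **exp)


def params_to_dict(p: SimulationParams) -> dict:
    return dataclasses.asdict(p)


def write_trials(results: list[TrialResult], path: str | Path) -> None:
    """Write trial records as CSV, one row per trial."""
    if not results:
        raise ValueError("no trial results to write")
    df = pd.DataFrame([
        {"trial_id": i, "seed": t.seed, "sigma": t.sigma,
         "outcome": t.outcome.value, "winner": t.winner.value,
         "established_wt": t.established_wt,
         "established_mut": t.established_mut,
         "generations": t.generations, "cycles": t.cycles,
         "extinct": t.extinct}
        for i, t in enumerate(results)
    ], columns=TRIAL_COLUMNS)
    df.to_csv(path, index=False)


def read_trials(path: str | Path) -> list[TrialResult]:
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        TrialResult(outcome=Outcome(r.outcome), winner=Winner(r.winner),
                    established_wt=bool(r.established_wt),
                    established_mut=bool(r.established_mut),
                    generations=int(r.generations), cycles=int(r.cycles),
                    seed=int(r.seed), sigma=float(r.sigma),
                    extinct=bool(r.extinct))
        for r in df.itertuples()
    ]


def _summary_to_dict(s: OutcomeSummary) -> dict:
    return {
        "sigma": s.sigma,
        "n_trials": s.n_trials,
        "n_classified": s.n_classified,
        "n_unclassified": s.n_unclassified,
        "case_counts": s.case_counts,
        "case_freqs": s.case_freqs,
        "freq_escape_mut": s.freq_escape_mut,
        "freq_fix_mut": s.freq_fix_mut,
        "n_escape_mut": s.n_escape_mut,
        "n_fix_mut": s.n_fix_mut,
        "ci": {k: list(v) for k, v in s.ci.items()},
    }


def write_summary(summaries: list[OutcomeSummary], path: str | Path,
                  params: SimulationParams, master_seed: int) -> None:
    """Write batch summaries as JSON with full parameter provenance."""
    payload = {
        "master_seed": master_seed,
        "params": params_to_dict(params),
        "summaries": [_summary_to_dict(s) for s in summaries],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_summary(path: str | Path) -> dict:
    payload = json.loads(Path(path).read_text())
    for key in ("master_seed", "params", "summaries"):
        if key not in payload:
            raise ValueError(f"{path}: missing key {key!r}")
    payload["summaries"] = [
        OutcomeSummary(
            sigma=d["sigma"], n_trials=d["n_trials"],
            n_classified=d["n_classified"],
            n_unclassified=d["n_unclassified"],
            case_counts=d["case_counts"], case_freqs=d["case_freqs"],
            freq_escape_mut=d["freq_escape_mut"],
            freq_fix_mut=d["freq_fix_mut"],
            n_escape_mut=d["n_escape_mut"], n_fix_mut=d["n_fix_mut"],
            ci={k: tuple(v) for k, v in d["ci"].items()},
        )
        for d in payload["summaries"]
    ]
    return payload
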