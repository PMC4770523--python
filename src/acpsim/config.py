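"""Run configuration: strict-schema loading, validation, serialization.

A run is either a named preset or a YAML document based on one.  The schema is
strict — unknown keys are rejected with their path — so a misspelled parameter
name can never silently fall back to a default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .engine import ModelParams
from .experiments import preset, preset_names
from .ttm import BaselineSchedule, PointSchedule, ThresholdSchedule


class ConfigError(ValueError):
    """Invalid run configuration; the message carries the offending key path."""


# schema: nested dict of allowed keys; leaves are None
_SCHEMA = {
    "preset": None,
    "run": {"ticks": None, "n_agents": None, "seed": None, "replicates": None},
    "grid": {"width": None, "height": None},
    "patches": {
        kind: {"anchor": None, "width": None, "height": None, "effect_probability": None}
        for kind in ("icu", "loved_one", "primary_care")
    },
    "points": {"icu": None, "loved": None, "pcp": None},
    "stages": {"thresholds": None, "baselines": None, "initial_distribution": None},
    "susceptibility_percent": None,
    "movement": {"mode": None, "rate": None},
    "social": {"enabled": None, "pts_up": None, "pts_down": None, "gap_scaling": None},
    "relapse": {"annual_check": None, "p_skip_update": None},
}


def _check_keys(doc: dict, schema: dict, path: str = "") -> None:
    for key, value in doc.items():
        here = f"{path}.{key}" if path else str(key)
        if key not in schema:
            raise ConfigError(f"unknown config key: {here}")
        sub = schema[key]
        if sub is not None:
            if not isinstance(value, dict):
                raise ConfigError(f"{here}: expected a mapping")
            _check_keys(value, sub, here)


@dataclass
class RunConfig:
    """A validated, runnable configuration."""

    params: ModelParams
    preset_name: str | None = None
    replicates: int = 1
    base_seed: int = 0
    out_dir: Path | None = None
    plot: bool = False

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")

    def to_dict(self) -> dict:
        """Full explicit dump; reloading it reproduces this config exactly."""
        p = self.params
        doc: dict = {
            "run": {
                "ticks": p.ticks,
                "n_agents": p.n_agents,
                "seed": self.base_seed,
                "replicates": self.replicates,
            },
            "points": {
                "icu": p.points.pts_icu,
                "loved": p.points.pts_loved,
                "pcp": p.points.pts_pcp,
            },
            "stages": {
                "thresholds": [
                    p.thresholds.enter_contemplation,
                    p.thresholds.enter_preparation,
                    p.thresholds.enter_action,
                ],
                "baselines": list(p.baselines.as_tuple()),
                "initial_distribution": list(p.initial_distribution),
            },
            "susceptibility_percent": p.susceptibility_percent,
            "movement": {"mode": p.movement_mode, "rate": p.movement_rate},
            "social": {
                "enabled": p.social_enabled,
                "pts_up": p.points.pts_social_up,
                "pts_down": p.points.pts_social_down,
                "gap_scaling": p.points.gap_scaling,
            },
            "relapse": {"annual_check": p.annual_relapse, "p_skip_update": p.p_skip_update},
        }
        if self.preset_name is not None:
            doc["preset"] = self.preset_name
        wc = p.world_config
        if wc is not None:
            doc["grid"] = dict(wc["grid"])
            doc["patches"] = {
                kind: {
                    "anchor": list(patch["anchor"]),
                    "width": patch["width"],
                    "height": patch["height"],
                }
                for kind, patch in wc["patches"].items()
            }
        probs = {"icu": p.p_icu, "loved_one": p.p_loved, "primary_care": p.p_pcp}
        for kind, patch in doc.get("patches", {}).items():
            patch["effect_probability"] = probs[kind]
        return doc

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _apply_overrides(params: ModelParams, doc: dict) -> ModelParams:
    """Return params with every value present in ``doc`` applied."""
    points = params.points
    thresholds = params.thresholds
    baselines = params.baselines
    updates: dict = {}

    if "run" in doc:
        run = doc["run"]
        if "ticks" in run:
            updates["ticks"] = int(run["ticks"])
        if "n_agents" in run:
            updates["n_agents"] = int(run["n_agents"])
    if "points" in doc:
        pts = doc["points"]
        points = replace(
            points,
            pts_icu=int(pts.get("icu", points.pts_icu)),
            pts_loved=int(pts.get("loved", points.pts_loved)),
            pts_pcp=int(pts.get("pcp", points.pts_pcp)),
        )
    if "social" in doc:
        soc = doc["social"]
        points = replace(
            points,
            pts_social_up=int(soc.get("pts_up", points.pts_social_up)),
            pts_social_down=int(soc.get("pts_down", points.pts_social_down)),
            gap_scaling=soc.get("gap_scaling", points.gap_scaling),
        )
        if "enabled" in soc:
            updates["social_enabled"] = bool(soc["enabled"])
    if "stages" in doc:
        st = doc["stages"]
        if "thresholds" in st:
            t = st["thresholds"]
            if len(t) != 3:
                raise ConfigError("stages.thresholds must list three values")
            thresholds = ThresholdSchedule(*(int(v) for v in t))
        if "baselines" in st:
            b = st["baselines"]
            if len(b) != 4:
                raise ConfigError("stages.baselines must list four values")
            baselines = BaselineSchedule(*(int(v) for v in b))
        if "initial_distribution" in st:
            d = st["initial_distribution"]
            if len(d) != 4:
                raise ConfigError("stages.initial_distribution must list four values")
            updates["initial_distribution"] = tuple(float(v) for v in d)
    if "susceptibility_percent" in doc:
        updates["susceptibility_percent"] = float(doc["susceptibility_percent"])
    if "movement" in doc:
        mv = doc["movement"]
        if "mode" in mv:
            updates["movement_mode"] = mv["mode"]
        if "rate" in mv:
            updates["movement_rate"] = float(mv["rate"])
    if "relapse" in doc:
        rl = doc["relapse"]
        if "annual_check" in rl:
            updates["annual_relapse"] = bool(rl["annual_check"])
        if "p_skip_update" in rl:
            updates["p_skip_update"] = float(rl["p_skip_update"])

    if "grid" in doc or "patches" in doc:
        wc = {
            "grid": dict(doc.get("grid") or (params.world_config or {}).get("grid", {})),
            "patches": {},
        }
        src_patches = doc.get("patches") or (params.world_config or {}).get("patches", {})
        probs: dict = {}
        for kind, patch in src_patches.items():
            entry = {
                "anchor": tuple(patch["anchor"]),
                "width": int(patch["width"]),
                "height": int(patch["height"]),
            }
            if "effect_probability" in patch:
                probs[kind] = float(patch["effect_probability"])
            wc["patches"][kind] = entry
        updates["world_config"] = wc
        for kind, attr in (("icu", "p_icu"), ("loved_one", "p_loved"), ("primary_care", "p_pcp")):
            if kind in probs:
                updates[attr] = probs[kind]

    try:
        new = replace(params, points=points, thresholds=thresholds, baselines=baselines, **updates)
        new.build_world()  # surface geometry errors at load time
    except ConfigError:
        raise
    except ValueError as exc:  # ModelParams/schedule/world validation
        raise ConfigError(str(exc)) from exc
    return new


def load_config(source: str | Path) -> RunConfig:
    """Load a :class:`RunConfig` from a preset name or a YAML file path.

    YAML documents must name a base ``preset``; every other key overrides the
    corresponding preset value.  Unknown keys and out-of-range values raise
    :class:`ConfigError` identifying the offending key.
    """
    if isinstance(source, str) and source in preset_names():
        return RunConfig(params=preset(source), preset_name=source)

    path = Path(source)
    if not path.exists():
        raise ConfigError(
            f"{source!r} is neither a known preset ({', '.join(preset_names())}) "
            "nor an existing config file"
        )
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    _check_keys(doc, _SCHEMA)

    if "preset" not in doc:
        raise ConfigError("config file must name a base 'preset'")
    name = doc["preset"]
    try:
        base = preset(name)
    except KeyError:
        raise ConfigError(f"preset: unknown preset {name!r}") from None

    params = _apply_overrides(base, doc)
    run = doc.get("run", {})
    return RunConfig(
        params=params,
        preset_name=name,
        replicates=int(run.get("replicates", 1)),
        base_seed=int(run.get("seed", 0)),
    )
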