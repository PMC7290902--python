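"""YAML/JSON round-tripping of the model configuration."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .game import GameParams
from .calibration import CalibrationSpec
from .experiments import first_set_game, first_set_population
from .population import PopulationParams

__all__ = ["Config", "load_config", "save_config"]


@dataclass
class Config:
    """Complete run configuration: game, population, calibration, ensemble."""

    game: GameParams = field(default_factory=first_set_game)
    population: PopulationParams = field(default_factory=first_set_population)
    calibration: CalibrationSpec = field(default_factory=CalibrationSpec)
    eta: int = 100

    def to_dict(self) -> dict:
        return {
            "game": asdict(self.game),
            "population": asdict(self.population),
            "calibration": asdict(self.calibration),
            "eta": self.eta,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "Config":
        return cls(
            game=GameParams(**data.get("game", {})) if data.get("game") else first_set_game(),
            population=PopulationParams(**data.get("population", {})),
            calibration=CalibrationSpec(**data.get("calibration", {})),
            eta=int(data.get("eta", 100)),
        )


def load_config(path: str | Path) -> Config:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return Config.from_dict(data or {})


def save_config(config: Config, path: str | Path) -> None:
    path = Path(path)
    data = config.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
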