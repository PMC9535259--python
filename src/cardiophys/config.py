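"""Run configuration: one object bundling every analysis tunable plus the
random seed and output directory, serializable verbatim into results files."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .ap import APConfig
from .ecg import ECGConfig
from .errors import FormatError
from .respiration import RespConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    ecg: ECGConfig = field(default_factory=ECGConfig)
    ap: APConfig = field(default_factory=APConfig)
    resp: RespConfig = field(default_factory=RespConfig)
    seed: int = 0
    output_dir: str = "results"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2,
                                         sort_keys=True, default=list) + "\n")

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        def build(factory, section):
            fields = {f.name for f in dataclasses.fields(factory)}
            unknown = set(section) - fields
            if unknown:
                raise FormatError(f"unknown config keys: {sorted(unknown)}")
            kwargs = {k: tuple(v) if isinstance(v, list) else v
                      for k, v in section.items()}
            return factory(**kwargs)

        return cls(
            ecg=build(ECGConfig, doc.get("ecg", {})),
            ap=build(APConfig, doc.get("ap", {})),
            resp=build(RespConfig, doc.get("resp", {})),
            seed=int(doc.get("seed", 0)),
            output_dir=str(doc.get("output_dir", "results")),
        )

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))
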