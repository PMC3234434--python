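"""Analysis parameters bundled with a project.

Everything needed to reproduce a run — the cell-width rule, the EOO/AOO
flooring flag, display caps and the fixture seed — is serialized verbatim
into the ``.geocat`` file so a reloaded project re-analyses identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .aoo import CellWidthKind, CellWidthRule

#: per-source display caps; 0 means unlimited
DEFAULT_CAPS = {"gbif": 500, "flickr": 250}


@dataclass
class AnalysisParams:
    cell_width_rule: CellWidthRule = field(default_factory=CellWidthRule)
    eoo_floor_aoo: bool = False
    caps: dict = field(default_factory=lambda: dict(DEFAULT_CAPS))
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "cell_width_rule": self.cell_width_rule.kind.value,
            "user_width_km": self.cell_width_rule.user_width_km,
            "eoo_floor_aoo": self.eoo_floor_aoo,
            "caps": dict(self.caps),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisParams":
        rule = CellWidthRule(
            kind=CellWidthKind(d.get("cell_width_rule", "default")),
            user_width_km=d.get("user_width_km"),
        )
        return cls(
            cell_width_rule=rule,
            eoo_floor_aoo=bool(d.get("eoo_floor_aoo", False)),
            caps=dict(d.get("caps", DEFAULT_CAPS)),
            seed=d.get("seed"),
        )
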