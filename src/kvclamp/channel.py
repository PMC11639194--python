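"""Channel presets: a state scheme, its rate parameters and a conductance flag,
with JSON (de)serialization for preset files."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

from .scheme import RateParams, StateScheme

__all__ = ["ChannelPreset", "preset_to_json", "preset_from_json"]


@dataclass(frozen=True)
class ChannelPreset:
    """A named channel model: topology + rates + unit conductance (0 for
    non-conducting, gating-current constructs)."""

    name: str
    scheme: StateScheme
    params: RateParams
    g: float = 1.0

    def with_params(self, **kw) -> "ChannelPreset":
        return replace(self, params=replace(self.params, **kw))


def preset_to_json(preset: ChannelPreset, path: str | Path | None = None) -> str:
    rp = asdict(preset.params)
    modulators = {
        k: rp.pop(k)
        for k in ("K_K", "K_Kr", "theta_push", "g_K", "K_Zn", "eta_Zn", "u_type", "Vcr")
    }
    doc = {
        "name": preset.name,
        "g": preset.g,
        "states": list(preset.scheme.states),
        "conducting": sorted(preset.scheme.conducting),
        "transitions": [
            {"from": frm, "to": to, "rate": rate, "z": z}
            for frm, to, rate, z in preset.scheme.transitions
        ],
        "rates": rp,
        "modulators": modulators,
    }
    text = json.dumps(doc, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text


def preset_from_json(src: str | Path) -> ChannelPreset:
    text = Path(src).read_text() if Path(str(src)).exists() else str(src)
    doc = json.loads(text)
    scheme = StateScheme(
        name=doc["name"],
        states=tuple(doc["states"]),
        conducting=frozenset(doc["conducting"]),
        transitions=tuple(
            (t["from"], t["to"], t["rate"], float(t["z"])) for t in doc["transitions"]
        ),
    )
    params = RateParams(**doc["rates"], **doc["modulators"])
    return ChannelPreset(
        name=doc["name"], scheme=scheme, params=params, g=float(doc.get("g", 1.0))
    )
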