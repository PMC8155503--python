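"""Typed 0D circuit description (netlist) with JSON round-trip.

Components live on named nodes; ``"ground"`` is the absolute zero-pressure
reference. Parameter values are CGS throughout (dyn, cm, s).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Any

__all__ = ["Component", "Netlist", "GROUND", "SchemaError"]

GROUND = "ground"
SCHEMA = "norwoodlpn-netlist-1"

#: kind -> required parameter keys (a subset; optional keys noted in docs)
KINDS: dict[str, set[str]] = {
    "resistor": {"R"},
    "capacitor": {"C"},
    "inductor": {"L"},                      # optional series "R"
    "diode_valve": {"R_open", "L"},
    "elastance_chamber": {"E_max", "E_min", "V0", "T"},
    "pressure_source": {"P"},
    "flow_source": set(),                   # "value" | "profile" | "fn"
    "nonlinear_resistor": {"a_quad", "r_lin", "L"},
}


class SchemaError(ValueError):
    """Netlist violates the component/connectivity schema."""


@dataclass
class Component:
    id: str
    kind: str
    a: str
    b: str
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise SchemaError(f"{self.id}: unknown component kind {self.kind!r}")
        missing = KINDS[self.kind] - self.params.keys()
        if missing:
            raise SchemaError(f"{self.id}: missing params {sorted(missing)}")
        positive = {"R", "C", "L", "R_open", "E_max", "E_min", "T"}
        for key in positive & self.params.keys():
            if not self.params[key] > 0 and not (key == "R" and self.kind == "inductor"):
                raise SchemaError(f"{self.id}: parameter {key} must be > 0")
        if self.kind == "elastance_chamber" and self.params["V0"] < 0:
            raise SchemaError(f"{self.id}: V0 must be >= 0")

    def copy(self) -> "Component":
        return replace(self, params=dict(self.params))


@dataclass
class Netlist:
    components: list[Component] = field(default_factory=list)
    inlet: str | None = None
    outlets: list[str] = field(default_factory=list)
    meta: dict[str, Any] = field(default_factory=dict)

    # -- construction ---------------------------------------------------------
    def add(self, kind: str, cid: str, a: str, b: str, **params) -> Component:
        if any(c.id == cid for c in self.components):
            raise SchemaError(f"duplicate component id {cid!r}")
        comp = Component(cid, kind, a, b, params)
        self.components.append(comp)
        return comp

    def __getitem__(self, cid: str) -> Component:
        for c in self.components:
            if c.id == cid:
                return c
        raise KeyError(cid)

    def __contains__(self, cid: str) -> bool:
        return any(c.id == cid for c in self.components)

    def remove(self, cid: str) -> None:
        self.components = [c for c in self.components if c.id != cid]

    def copy(self) -> "Netlist":
        return Netlist(
            components=[c.copy() for c in self.components],
            inlet=self.inlet,
            outlets=list(self.outlets),
            meta=json.loads(json.dumps(self.meta, default=str)),
        )

    # -- inspection -----------------------------------------------------------
    @property
    def nodes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.components:
            seen.setdefault(c.a)
            seen.setdefault(c.b)
        seen.pop(GROUND, None)
        return list(seen)

    def node_capacitance(self) -> dict[str, float]:
        caps: dict[str, float] = {}
        for c in self.components:
            if c.kind == "capacitor":
                if c.b != GROUND:
                    raise SchemaError(f"{c.id}: capacitors must connect to ground")
                caps[c.a] = caps.get(c.a, 0.0) + c.params["C"]
        return caps

    def validate_connected(self) -> None:
        """Every node must be reachable from every other through components."""
        nodes = self.nodes
        if not nodes:
            return
        adj: dict[str, set[str]] = {}
        for c in self.components:
            adj.setdefault(c.a, set()).add(c.b)
            adj.setdefault(c.b, set()).add(c.a)
        stack, seen = [nodes[0]], {nodes[0]}
        while stack:
            for nb in adj.get(stack.pop(), ()):
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        dangling = set(nodes) - seen
        if dangling:
            raise SchemaError(f"disconnected nodes: {sorted(dangling)}")

    # -- serialisation --------------------------------------------------------
    def to_dict(self) -> dict:
        comps = []
        for c in self.components:
            params = {k: v for k, v in c.params.items() if not callable(v)}
            comps.append({"id": c.id, "kind": c.kind, "a": c.a, "b": c.b, "params": params})
        return {
            "schema": SCHEMA,
            "nodes": self.nodes,
            "components": comps,
            "inlet": self.inlet,
            "outlets": self.outlets,
            "meta": self.meta,
        }

    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, data: dict) -> "Netlist":
        if data.get("schema") != SCHEMA:
            raise SchemaError(f"unsupported schema {data.get('schema')!r}")
        nl = cls(inlet=data.get("inlet"), outlets=list(data.get("outlets", [])),
                 meta=dict(data.get("meta", {})))
        for c in data["components"]:
            nl.add(c["kind"], c["id"], c["a"], c["b"], **c["params"])
        return nl

    @classmethod
    def from_json(cls, source) -> "Netlist":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            return cls.from_dict(json.loads(source))
        with open(source) as fh:
            return cls.from_dict(json.load(fh))

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.components:
            out[c.kind] = out.get(c.kind, 0) + 1
        return out
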