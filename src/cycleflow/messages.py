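"""Lightweight control messages exchanged with the orchestrator."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

__all__ = ["Event", "ControlAction", "EVENT_KINDS", "ACTION_KINDS"]

EVENT_KINDS = {"iteration-complete", "data-available", "update-request", "heartbeat"}
ACTION_KINDS = {"start-iteration", "exit", "reconfigure"}


@dataclass
class Event:
    """A control-plane message from a service node to the orchestrator."""

    wf_id: str
    node_id: str
    iteration: int
    kind: str
    payload: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.iteration < 1:
            raise ValueError("iteration must be >= 1")

    def to_dict(self) -> dict:
        return {
            "wf_id": self.wf_id,
            "node_id": self.node_id,
            "iteration": self.iteration,
            "kind": self.kind,
            "payload": self.payload,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Event":
        return cls(d["wf_id"], d["node_id"], d["iteration"], d["kind"], d.get("payload", {}))


@dataclass
class ControlAction:
    """A control-plane instruction from the orchestrator to a service node."""

    target_node: str
    kind: str
    iteration: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ACTION_KINDS:
            raise ValueError(f"unknown action kind {self.kind!r}")

    def to_dict(self) -> dict:
        return {"target_node": self.target_node, "kind": self.kind, "iteration": self.iteration}

    @classmethod
    def from_dict(cls, d: dict) -> "ControlAction":
        return cls(d["target_node"], d["kind"], d.get("iteration", 0))
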