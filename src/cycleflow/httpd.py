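"""REST/JSON transport for the orchestrator.

The orchestrator runs as a small threaded HTTP server; service nodes act as
lightweight REST clients.  Endpoints:

* ``POST /workflows``                    register a transformed workflow
* ``POST /workflows/{id}/events``        submit an event, returns actions
* ``PUT  /workflows/{id}``               hot-update the workflow definition
* ``GET  /workflows/{id}/status``        progress counters and exit state
* ``GET  /workflows/{id}/nodes/{n}/mail``  drain pending data deliveries
* ``DELETE /workflows/{id}``             deregister

Exit predicates are in-process callables and do not travel over HTTP; remote
registrations are limited to iteration-bound exit conditions.
"""

from __future__ import annotations

import json
import threading
import urllib.error
import urllib.request
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer

from .messages import ControlAction, Event
from .model import ValidationError
from .orchestrator import Orchestrator, RegistrationError, RoutingError
from .transform import DataChannel, ExitCondition, TransformedWorkflow, insert_orchestrator
from .xmlio import graph_from_dict, graph_to_dict

__all__ = [
    "OrchestratorServer",
    "HttpOrchestratorClient",
    "tw_to_dict",
    "tw_from_dict",
]


def tw_to_dict(tw: TransformedWorkflow) -> dict:
    return {
        "original": graph_to_dict(tw.original),
        "max_iterations": tw.exit_condition.max_iterations,
    }


def tw_from_dict(d: dict) -> TransformedWorkflow:
    graph = graph_from_dict(d["original"])
    exit_cond = ExitCondition(max_iterations=d["max_iterations"])
    return insert_orchestrator(graph, exit_cond)


class _Handler(BaseHTTPRequestHandler):
    orch: Orchestrator  # set by server factory
    protocol_version = "HTTP/1.1"

    def log_message(self, fmt, *args):  # quiet by default
        pass

    def _send(self, code: int, body: dict) -> None:
        payload = json.dumps(body).encode("utf-8")
        self.send_response(code)
        self.send_header("Content-Type", "application/json")
        self.send_header("Content-Length", str(len(payload)))
        self.end_headers()
        self.wfile.write(payload)

    def _body(self) -> dict:
        length = int(self.headers.get("Content-Length", 0))
        raw = self.rfile.read(length) if length else b"{}"
        return json.loads(raw or b"{}")

    def _route(self) -> list[str]:
        return [p for p in self.path.split("/") if p]

    def do_POST(self) -> None:
        parts = self._route()
        try:
            if parts == ["workflows"]:
                body = self._body()
                tw = tw_from_dict(body["workflow"])
                rec = self.orch.register_workflow(
                    body["wf_id"], tw, mode=body.get("mode", "via-orchestrator")
                )
                self._send(201, {"wf_id": rec.wf_id, "status": rec.status})
            elif len(parts) == 3 and parts[0] == "workflows" and parts[2] == "events":
                ev = Event.from_dict({**self._body(), "wf_id": parts[1]})
                actions = self.orch.handle_event(ev)
                self._send(200, {"actions": [a.to_dict() for a in actions]})
            else:
                self._send(404, {"error": f"no route {self.path}"})
        except RegistrationError as exc:
            self._send(409, {"error": str(exc)})
        except RoutingError as exc:
            self._send(404, {"error": str(exc)})
        except (ValidationError, KeyError, ValueError) as exc:
            self._send(400, {"error": str(exc)})

    def do_PUT(self) -> None:
        parts = self._route()
        try:
            if len(parts) == 2 and parts[0] == "workflows":
                body = self._body()
                ack = self.orch.update_workflow(
                    parts[1],
                    graph_from_dict(body["graph"]),
                    after_iteration=body.get("after_iteration", 0),
                )
                self._send(200, ack)
            else:
                self._send(404, {"error": f"no route {self.path}"})
        except RoutingError as exc:
            self._send(404, {"error": str(exc)})
        except ValidationError as exc:
            self._send(400, {"error": str(exc)})

    def do_GET(self) -> None:
        parts = self._route()
        try:
            if len(parts) == 3 and parts[0] == "workflows" and parts[2] == "status":
                self._send(200, self.orch.status(parts[1]))
            elif (
                len(parts) == 5
                and parts[0] == "workflows"
                and parts[2] == "nodes"
                and parts[4] == "mail"
            ):
                self._send(200, {"mail": self.orch.fetch_mail(parts[1], parts[3])})
            else:
                self._send(404, {"error": f"no route {self.path}"})
        except RoutingError as exc:
            self._send(404, {"error": str(exc)})

    def do_DELETE(self) -> None:
        parts = self._route()
        if len(parts) == 2 and parts[0] == "workflows":
            self.orch.deregister(parts[1])
            self._send(200, {"wf_id": parts[1], "status": "deregistered"})
        else:
            self._send(404, {"error": f"no route {self.path}"})


class OrchestratorServer:
    """Threaded HTTP front for an :class:`Orchestrator`."""

    def __init__(self, host: str = "127.0.0.1", port: int = 0):
        self.orch = Orchestrator()
        handler = type("BoundHandler", (_Handler,), {"orch": self.orch})
        self._httpd = ThreadingHTTPServer((host, port), handler)
        self._thread: threading.Thread | None = None

    @property
    def url(self) -> str:
        host, port = self._httpd.server_address[:2]
        return f"http://{host}:{port}"

    def start(self) -> "OrchestratorServer":
        self._thread = threading.Thread(target=self._httpd.serve_forever, daemon=True)
        self._thread.start()
        return self

    def stop(self) -> None:
        self._httpd.shutdown()
        self._httpd.server_close()
        if self._thread:
            self._thread.join(2.0)

    def __enter__(self) -> "OrchestratorServer":
        return self.start()

    def __exit__(self, *exc) -> None:
        self.stop()


class HttpOrchestratorClient:
    """Same surface as :class:`Orchestrator`, spoken over HTTP/JSON."""

    remote = True

    def __init__(self, url: str, timeout: float = 10.0):
        self.url = url.rstrip("/")
        self.timeout = timeout

    def _request(self, method: str, path: str, body: dict | None = None) -> dict:
        data = json.dumps(body).encode("utf-8") if body is not None else None
        req = urllib.request.Request(
            self.url + path,
            data=data,
            method=method,
            headers={"Content-Type": "application/json"},
        )
        try:
            with urllib.request.urlopen(req, timeout=self.timeout) as resp:
                return json.loads(resp.read() or b"{}")
        except urllib.error.HTTPError as exc:
            detail = exc.read().decode("utf-8", "replace")
            raise RuntimeError(f"{method} {path} -> {exc.code}: {detail}") from exc

    def register_workflow(self, wf_id, tw, mode="via-orchestrator", hub=None) -> dict:
        return self._request(
            "POST",
            "/workflows",
            {"wf_id": wf_id, "workflow": tw_to_dict(tw), "mode": mode},
        )

    def handle_event(self, ev: Event) -> list[ControlAction]:
        out = self._request(
            "POST", f"/workflows/{ev.wf_id}/events", ev.to_dict()
        )
        return [ControlAction.from_dict(a) for a in out["actions"]]

    def update_workflow(self, wf_id, new_graph, after_iteration: int = 0) -> dict:
        return self._request(
            "PUT",
            f"/workflows/{wf_id}",
            {"graph": graph_to_dict(new_graph), "after_iteration": after_iteration},
        )

    def status(self, wf_id: str) -> dict:
        return self._request("GET", f"/workflows/{wf_id}/status")

    def fetch_mail(self, wf_id: str, node_id: str) -> list[dict]:
        return self._request("GET", f"/workflows/{wf_id}/nodes/{node_id}/mail")["mail"]

    def deregister(self, wf_id: str) -> None:
        self._request("DELETE", f"/workflows/{wf_id}")
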