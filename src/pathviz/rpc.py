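"""XML-RPC service exposing the library surface under "PathVisio." names.

A client on any language binds to the server (default port 7777, loopback
only by default) and drives pathway construction, data import, linking,
scoring and export remotely, e.g.::

    xml.rpc(server, "PathVisio.createPathway", "Glycolysis")

Documents, tables and mapping stores cannot travel over XML-RPC, so the
service hands out opaque string handles ("doc-1", "table-2", ...) that
name objects in a per-server session store; handles expire when the
server stops.  Domain errors surface as XML-RPC faults with a code and
the original message.
"""

from __future__ import annotations

import threading
from dataclasses import dataclass, field
from typing import Any, Optional
from xmlrpc.client import Fault
from xmlrpc.server import SimpleXMLRPCServer

from . import dataset, idmapper, model, stats
from .pipeline import run_analysis
from .visualize import ColorRule, VisualizationSpec, gradient_from_text

__all__ = [
    "DEFAULT_PORT",
    "RpcApi",
    "ServerHandle",
    "ServerStateError",
    "start_server",
    "stop_server",
    "dispatch",
    "FAULT_DOMAIN_ERROR",
    "FAULT_UNKNOWN_METHOD",
    "FAULT_BAD_ARGUMENTS",
]

DEFAULT_PORT = 7777

FAULT_UNKNOWN_METHOD = 1
FAULT_BAD_ARGUMENTS = 2
FAULT_DOMAIN_ERROR = 3


class ServerStateError(Exception):
    """Server lifecycle misuse (double start/stop, port busy)."""


# ---------------------------------------------------------------------------
# Session + API

class _Session:
    """Opaque-handle store for documents, tables and mapping stores."""

    def __init__(self):
        self._objects: dict[str, Any] = {}
        self._counter = 0

    def put(self, kind: str, obj) -> str:
        self._counter += 1
        handle = f"{kind}-{self._counter}"
        self._objects[handle] = obj
        return handle

    def get(self, handle: str, expect: type):
        obj = self._objects.get(handle)
        if obj is None:
            raise KeyError(f"unknown handle {handle!r}")
        if not isinstance(obj, expect):
            raise TypeError(f"handle {handle!r} is a {type(obj).__name__}, not {expect.__name__}")
        return obj

    def clear(self):
        self._objects.clear()


def _spec_from_struct(struct) -> VisualizationSpec:
    """Build a VisualizationSpec from a marshallable list of entries.

    Each entry is a struct with ``column`` and either ``gradient`` (text
    like ``"blue@-1,white@0,red@1"``) or ``rules`` (list of
    [criterion_text, colour] pairs).
    """
    entries = []
    for item in struct:
        column = item["column"]
        if "gradient" in item:
            entries.append((column, gradient_from_text(item["gradient"])))
        elif "rules" in item:
            entries.append(
                (column, [ColorRule.from_text(text, color) for text, color in item["rules"]])
            )
        else:
            raise ValueError(f"spec entry for {column!r} needs 'gradient' or 'rules'")
    return VisualizationSpec(entries)


class RpcApi:
    """The exposed method surface.  Every public method maps 1:1 onto a
    library operation; results are XML-RPC scalars/arrays/structs."""

    def __init__(self):
        self.session = _Session()

    # -- pathway construction ---------------------------------------------
    def createPathway(self, name: str, organism: str = "") -> str:
        return self.session.put("doc", model.create_pathway(name, organism))

    def openPathway(self, path: str) -> str:
        return self.session.put("doc", model.read_gpml(path))

    def savePathway(self, doc_handle: str, path: str) -> bool:
        model.write_gpml(self.session.get(doc_handle, model.PathwayDoc), path)
        return True

    def addDataNode(
        self,
        doc_handle: str,
        label: str,
        node_type: str = "GeneProduct",
        identifier: str = "",
        system_code: str = "",
    ) -> str:
        doc = self.session.get(doc_handle, model.PathwayDoc)
        xref = model.Xref(identifier, system_code) if identifier else None
        return model.add_data_node(doc, label, node_type, xref)

    def addInteraction(
        self, doc_handle: str, source_id: str, target_id: str, interaction_type: str = "line"
    ) -> str:
        doc = self.session.get(doc_handle, model.PathwayDoc)
        return model.add_interaction(doc, source_id, target_id, interaction_type)

    def removeElement(self, doc_handle: str, element_id: str) -> bool:
        model.remove_element(self.session.get(doc_handle, model.PathwayDoc), element_id)
        return True

    def getElementCount(self, doc_handle: str) -> int:
        return len(self.session.get(doc_handle, model.PathwayDoc).elements)

    # -- data and mapping ---------------------------------------------------
    def importData(self, path: str, id_column: str, syscode: str) -> str:
        return self.session.put("table", dataset.import_data(path, id_column, syscode))

    def loadMappings(self, path: str, species: str = "") -> str:
        return self.session.put("store", idmapper.load_mapping_table(path, species))

    def mapIdentifier(self, store_handle: str, identifier: str, source: str, target: str) -> list:
        store = self.session.get(store_handle, idmapper.MappingStore)
        return sorted(idmapper.map_identifier(store, identifier, source, target))

    def isKnownIdentifier(self, store_handle: str, identifier: str, code: str) -> bool:
        return idmapper.is_known(
            self.session.get(store_handle, idmapper.MappingStore), identifier, code
        )

    # -- statistics ----------------------------------------------------------
    def calculateZScores(
        self, pathway_source: str, table_handle: str, store_handle: str, criterion: str
    ) -> list:
        from .pipeline import collect_pathway_files

        table = self.session.get(table_handle, dataset.MeasurementTable)
        store = self.session.get(store_handle, idmapper.MappingStore)
        docs = [(model.read_gpml(f), str(f)) for f in collect_pathway_files(pathway_source)]
        ranked = stats.rank_pathways(docs, table, store, criterion)
        return [
            {
                "pathway": s.name,
                "file": s.source,
                "n": s.counts.n,
                "r": s.counts.r,
                "N": s.counts.N,
                "R": s.counts.R,
                "z": s.z if s.z_defined else "NaN",
            }
            for s in ranked.scores
        ]

    # -- end-to-end -----------------------------------------------------------
    def analyse(
        self,
        data_path: str,
        id_column: str,
        syscode: str,
        pathway_source: str,
        mapping_path: str,
        criterion: str,
        spec_struct: list,
        out_dir: str,
    ) -> dict:
        spec = _spec_from_struct(spec_struct) if spec_struct else None
        result = run_analysis(
            data_path, id_column, syscode, pathway_source, mapping_path,
            criterion or None, spec, out_dir,
        )
        out = {"out_dir": out_dir}
        if result.ranked is not None:
            out["top_pathway"] = result.ranked.scores[0].name
            out["results_tsv"] = str(result.results_tsv)
        return out

    # introspection helper (also exercised by the namespace tests)
    def listMethods(self) -> list:
        return sorted(
            f"PathVisio.{name}"
            for name in dir(self)
            if not name.startswith("_") and callable(getattr(self, name))
        )


# ---------------------------------------------------------------------------
# Dispatch (usable with or without a network server)

def dispatch(api: RpcApi, method: str, params: tuple | list) -> Any:
    """Call a namespaced method; domain errors become XML-RPC Faults."""
    prefix = "PathVisio."
    if not method.startswith(prefix):
        raise Fault(FAULT_UNKNOWN_METHOD, f"unknown method {method!r}")
    name = method[len(prefix):]
    fn = getattr(api, name, None)
    if fn is None or name.startswith("_") or not callable(fn):
        raise Fault(FAULT_UNKNOWN_METHOD, f"unknown method {method!r}")
    try:
        return fn(*params)
    except TypeError as exc:
        raise Fault(FAULT_BAD_ARGUMENTS, f"{method}: {exc}") from exc
    except Fault:
        raise
    except Exception as exc:
        raise Fault(FAULT_DOMAIN_ERROR, f"{method}: {type(exc).__name__}: {exc}") from exc


# ---------------------------------------------------------------------------
# Server lifecycle

@dataclass
class ServerHandle:
    port: int
    host: str
    api: RpcApi
    state: str = "running"  # or "stopped"
    _server: Optional[SimpleXMLRPCServer] = None
    _thread: Optional[threading.Thread] = None

    @property
    def url(self) -> str:
        return f"http://{self.host}:{self.port}/"


def start_server(port: Optional[int] = None, host: str = "127.0.0.1") -> ServerHandle:
    """Bind an XML-RPC listener (default port 7777, loopback only) and serve
    in a daemon thread.  Raises ServerStateError when the port is busy."""
    port = DEFAULT_PORT if port is None else int(port)
    api = RpcApi()
    try:
        server = SimpleXMLRPCServer((host, port), logRequests=False, allow_none=False)
    except OSError as exc:
        raise ServerStateError(f"cannot bind {host}:{port}: {exc}") from exc

    def _dispatcher(method, params):
        return dispatch(api, method, params)

    server.register_instance(_InstanceShim(_dispatcher))
    thread = threading.Thread(target=server.serve_forever, daemon=True, name=f"pathviz-rpc-{port}")
    thread.start()
    return ServerHandle(port=port, host=host, api=api, _server=server, _thread=thread)


class _InstanceShim:
    """Routes every incoming call through :func:`dispatch`."""

    def __init__(self, dispatcher):
        self._dispatcher = dispatcher

    def _dispatch(self, method, params):
        return self._dispatcher(method, params)


def stop_server(handle: ServerHandle) -> None:
    """Shut the listener down and expire all session handles."""
    if handle.state != "running":
        raise ServerStateError("server is not running")
    handle._server.shutdown()
    handle._server.server_close()
    handle._thread.join(timeout=5)
    handle.api.session.clear()
    handle.state = "stopped"
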