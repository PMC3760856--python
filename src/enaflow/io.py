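"""Readers and writers for flow networks.

Supported formats:

* delimited edge lists (``from, to, flux``; comma or tab, autodetected),
* Pajek ``.net`` files (``*Vertices`` / ``*Arcs`` with weights), the format
  the public food-web flux databases are distributed in,
* a JSON round-trip of the full :class:`~enaflow.network.FlowNetwork`.

Respiration and export are merged into the single sink column on read; the
split is kept in ``meta`` for provenance.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .network import FlowNetwork

__all__ = [
    "read_edgelist",
    "write_edgelist",
    "read_pajek",
    "write_pajek",
    "to_json",
    "from_json",
    "DEFAULT_SOURCE",
    "DEFAULT_SINKS",
]

DEFAULT_SOURCE = "INPUT"
DEFAULT_SINKS = ("RESPIRATION", "OUTPUT")


def _edges_to_network(
    edges: Iterable[tuple[str, str, float]],
    source_label: str,
    sink_labels: Sequence[str],
    meta: dict | None = None,
    node_order: Sequence[str] | None = None,
) -> FlowNetwork:
    """Assemble a FlowNetwork from (from, to, flux) triples.

    Living compartments are ordered by first appearance (or by ``node_order``
    when given); all sink labels are merged into the single sink column.
    """
    sinks = set(sink_labels)
    if source_label in sinks:
        raise ValueError("source label cannot also be a sink label")
    order: dict[str, int] = (
        {} if node_order is None else {n: k for k, n in enumerate(node_order)}
    )
    cleaned: list[tuple[str, str, float]] = []
    seen: set[tuple[str, str]] = set()
    sink_split: dict[str, float] = {}
    for row, (u, v, w) in enumerate(edges, start=1):
        w = float(w)
        if w < 0:
            raise ValueError(f"row {row}: negative flux {w} on edge {u!r}->{v!r}")
        if v == source_label:
            raise ValueError(f"row {row}: edge into the source {u!r}->{v!r}")
        if u in sinks:
            raise ValueError(f"row {row}: edge out of a sink {u!r}->{v!r}")
        if (u, v) in seen:
            raise ValueError(f"row {row}: duplicate edge {u!r}->{v!r} (ambiguous)")
        seen.add((u, v))
        for name in (u, v):
            if name != source_label and name not in sinks and name not in order:
                order[name] = len(order)
        if v in sinks:
            sink_split[v] = sink_split.get(v, 0.0) + w
        cleaned.append((u, v, w))
    labels = list(order)
    S = len(labels)
    if S < 1:
        raise ValueError("no living compartments found")
    flux = np.zeros((S + 2, S + 2))

    def idx(name: str) -> int:
        if name == source_label:
            return 0
        if name in sinks:
            return S + 1
        return order[name] + 1

    for u, v, w in cleaned:
        flux[idx(u), idx(v)] += w
    full_meta = dict(meta or {})
    full_meta.setdefault("source_label", source_label)
    full_meta.setdefault("sink_labels", ",".join(sink_labels))
    if len(sink_split) > 1:
        full_meta["sink_split"] = json.dumps(sink_split)
    return FlowNetwork(labels, flux, full_meta)


def read_edgelist(
    path,
    source_label: str = DEFAULT_SOURCE,
    sink_labels: Sequence[str] = DEFAULT_SINKS,
) -> FlowNetwork:
    """Read a delimited ``from,to,flux`` table into a FlowNetwork.

    The delimiter (comma or tab) is autodetected from the header line; a
    header is required.  All rows pointing at any of ``sink_labels`` are
    merged into the sink column.  Node order is first-appearance order unless
    the file carries a ``# nodes: ...`` comment (written by
    :func:`write_edgelist` so that round-trips preserve the matrix exactly).
    """
    text = Path(path).read_text()
    node_order: list[str] | None = None
    for ln in text.splitlines():
        if ln.lstrip().startswith("# nodes:"):
            node_order = [s.strip() for s in ln.split(":", 1)[1].split(",") if s.strip()]
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise ValueError(f"{path}: empty edge list")
    delim = "\t" if "\t" in lines[0] else ","
    header = [h.strip().lower() for h in lines[0].split(delim)]
    if header[:3] != ["from", "to", "flux"]:
        raise ValueError(f"{path}: expected header 'from{delim}to{delim}flux', got {lines[0]!r}")

    def parse(ln: str) -> tuple[str, str, float]:
        parts = [p.strip() for p in ln.split(delim)]
        if len(parts) < 3:
            raise ValueError(f"{path}: malformed row {ln!r}")
        return parts[0], parts[1], float(parts[2])

    return _edges_to_network(
        (parse(ln) for ln in lines[1:]),
        source_label,
        sink_labels,
        meta={"path": str(path)},
        node_order=node_order,
    )


def write_edgelist(net: FlowNetwork, path, delim: str = ",") -> Path:
    """Write a FlowNetwork as a ``from,to,flux`` table (17 significant digits).

    The source is written under its recorded label (``meta['source_label']``,
    default ``INPUT``) and the merged sink under the first recorded sink label
    so that ``read_edgelist`` round-trips the flux matrix exactly.
    """
    path = Path(path)
    src = net.meta.get("source_label", DEFAULT_SOURCE)
    sink = net.meta.get("sink_labels", ",".join(DEFAULT_SINKS)).split(",")[0]
    names = [src] + net.labels + [sink]
    rows = ["# nodes: " + ",".join(net.labels), "from%sto%sflux" % (delim, delim)]
    for i, j in zip(*np.nonzero(net.flux)):
        rows.append(f"{names[i]}{delim}{names[j]}{delim}{net.flux[i, j]:.17g}")
    path.write_text("\n".join(rows) + "\n")
    return path


_PAJEK_VERT = re.compile(r"^\s*(\d+)\s+\"([^\"]*)\"")


def read_pajek(
    path,
    source_label: str = DEFAULT_SOURCE,
    sink_labels: Sequence[str] = DEFAULT_SINKS,
    source_vertex: str | None = None,
    sink_vertices: Sequence[str] | None = None,
) -> FlowNetwork:
    """Read a weighted directed Pajek ``.net`` file.

    Requires ``*Vertices`` and ``*Arcs`` sections with arc weights.  An
    undirected ``*Edges`` section is rejected (flows are directed).  Vertex
    labels matching ``source_vertex`` / ``sink_vertices`` (defaults: the
    ``source_label`` / ``sink_labels`` arguments, case-insensitively) are
    mapped to the boundary compartments.
    """
    lines = Path(path).read_text().splitlines()
    names: dict[int, str] = {}
    arcs: list[tuple[str, str, float]] = []
    section = None
    for ln in lines:
        stripped = ln.strip()
        if not stripped or stripped.startswith("%"):
            continue
        low = stripped.lower()
        if low.startswith("*vertices"):
            section = "vertices"
            continue
        if low.startswith("*arcs"):
            section = "arcs"
            continue
        if low.startswith("*edges"):
            raise ValueError(f"{path}: undirected *Edges section; flows must be directed arcs")
        if low.startswith("*"):
            section = None
            continue
        if section == "vertices":
            m = _PAJEK_VERT.match(ln)
            if m:
                names[int(m.group(1))] = m.group(2)
            else:
                parts = stripped.split()
                names[int(parts[0])] = parts[1] if len(parts) > 1 else parts[0]
        elif section == "arcs":
            parts = stripped.split()
            if len(parts) < 3:
                raise ValueError(f"{path}: arc without weight: {stripped!r}")
            arcs.append((names[int(parts[0])], names[int(parts[1])], float(parts[2])))
    if not arcs:
        raise ValueError(f"{path}: no *Arcs found")
    src = source_vertex if source_vertex is not None else source_label
    snk = list(sink_vertices) if sink_vertices is not None else list(sink_labels)
    # Case-insensitive match of boundary vertex names.
    lower_map = {n.lower(): n for n in names.values()}
    src = lower_map.get(src.lower(), src)
    snk = [lower_map.get(s.lower(), s) for s in snk]
    # Node order comes from the *Vertices section, not from arc appearance.
    ordered = [names[k] for k in sorted(names)]
    living_order = [n for n in ordered if n != src and n not in set(snk)]
    net = _edges_to_network(
        arcs, src, snk, meta={"path": str(path)}, node_order=living_order
    )
    net.meta["source_label"] = source_label
    net.meta["sink_labels"] = ",".join(sink_labels)
    return net


def write_pajek(net: FlowNetwork, path) -> Path:
    """Write a FlowNetwork as a Pajek ``.net`` with quoted labels and weights."""
    path = Path(path)
    src = net.meta.get("source_label", DEFAULT_SOURCE)
    sink = net.meta.get("sink_labels", ",".join(DEFAULT_SINKS)).split(",")[0]
    names = [src] + net.labels + [sink]
    out = [f"*Vertices {len(names)}"]
    out += [f'{i + 1} "{name}"' for i, name in enumerate(names)]
    out.append("*Arcs")
    for i, j in zip(*np.nonzero(net.flux)):
        out.append(f"{i + 1} {j + 1} {net.flux[i, j]:.17g}")
    path.write_text("\n".join(out) + "\n")
    return path


def to_json(net: FlowNetwork, path=None) -> str:
    """Serialize a FlowNetwork (labels, sparse flux triples, meta) to JSON."""
    i, j = np.nonzero(net.flux)
    payload = {
        "labels": net.labels,
        "n_living": net.n_living,
        "flux": [[int(a), int(b), net.flux[a, b]] for a, b in zip(i, j)],
        "meta": net.meta,
    }
    text = json.dumps(payload, indent=1)
    if path is not None:
        Path(path).write_text(text)
    return text


def from_json(source) -> FlowNetwork:
    """Inverse of :func:`to_json`; accepts a JSON string or a path."""
    if isinstance(source, (str, bytes)) and source.lstrip().startswith("{"):
        payload = json.loads(source)
    else:
        payload = json.loads(Path(source).read_text())
    S = payload["n_living"]
    flux = np.zeros((S + 2, S + 2))
    for a, b, w in payload["flux"]:
        flux[a, b] = w
    return FlowNetwork(payload["labels"], flux, payload.get("meta", {}))
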