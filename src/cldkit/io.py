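"""Reading and writing causal loop diagrams.

Formats
-------
native
    A JSON document with top-level keys ``name``, ``provenance``,
    ``variables`` (array of ``{id, label, domain, definition}``) and
    ``connections`` (array of ``{source, target, polarity,
    mechanism_note, references, proposer_count}``).  Lossless; the
    package's canonical interchange format.
graphml
    GraphML via networkx, node attribute ``domain`` and edge attribute
    ``polarity`` plus the remaining fields.  ``references`` is stored as
    a JSON-encoded string (GraphML has no list attributes).  Lossless.
csv
    A bare edge list ``source,target,polarity``.  Lossy: domains and
    metadata are not representable, so importing assigns
    ``default_domain`` to every inferred variable.
dot
    Graphviz DOT, export only, one edge statement per connection with
    solid styling for positive, dashed for negative and bold for
    ambiguous polarity (mirroring the usual CLD legend).
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import networkx as nx

from .core import CausalLoopDiagram, CldValidationError, Connection, Variable

FORMATS = ("native", "graphml", "csv", "dot")

_DOT_STYLE = {"positive": "solid", "negative": "dashed", "ambiguous": "bold"}
_DOT_COLOR = {"positive": "gray40", "negative": "red3", "ambiguous": "blue3"}


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    return {
        ".json": "native",
        ".graphml": "graphml",
        ".csv": "csv",
        ".dot": "dot",
        ".gv": "dot",
    }.get(suffix, "native")


def load_cld(
    path: str | Path,
    format: str | None = None,
    default_domain: str = "behavioral",
) -> CausalLoopDiagram:
    """Load and validate a diagram; invalid input raises before return.

    ``format`` defaults to a guess from the file suffix.  CSV input has
    no domain column, so every variable gets ``default_domain``.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "native":
        return _load_native(path)
    if fmt == "graphml":
        return _load_graphml(path)
    if fmt == "csv":
        return _load_csv(path, default_domain)
    raise ValueError(f"unsupported load format {fmt!r}; expected one of ('native', 'graphml', 'csv')")


def save_cld(cld: CausalLoopDiagram, path: str | Path, format: str | None = None) -> None:
    """Write a diagram so that :func:`load_cld` recovers an equal one.

    Round-trip equality (all fields) holds for native and GraphML;
    CSV and DOT are lossy/presentation formats.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "native":
        _save_native(cld, path)
    elif fmt == "graphml":
        _save_graphml(cld, path)
    elif fmt == "csv":
        _save_csv(cld, path)
    elif fmt == "dot":
        _save_dot(cld, path)
    else:
        raise ValueError(f"unsupported save format {fmt!r}; expected one of {FORMATS}")


# ---- native JSON ---------------------------------------------------


def cld_to_dict(cld: CausalLoopDiagram) -> dict:
    return {
        "name": cld.name,
        "provenance": cld.provenance,
        "variables": [
            {"id": v.id, "label": v.label, "domain": v.domain, "definition": v.definition}
            for v in cld.variables
        ],
        "connections": [
            {
                "source": c.source,
                "target": c.target,
                "polarity": c.polarity,
                "mechanism_note": c.mechanism_note,
                "references": list(c.references),
                "proposer_count": c.proposer_count,
            }
            for c in cld.connections
        ],
    }


def cld_from_dict(doc: dict) -> CausalLoopDiagram:
    try:
        variables = [
            Variable(
                id=v["id"],
                label=v.get("label", v["id"]),
                domain=v["domain"],
                definition=v.get("definition", ""),
            )
            for v in doc["variables"]
        ]
        connections = [
            Connection(
                source=c["source"],
                target=c["target"],
                polarity=c["polarity"],
                mechanism_note=c.get("mechanism_note", ""),
                references=tuple(c.get("references", ())),
                proposer_count=int(c.get("proposer_count", 0)),
            )
            for c in doc["connections"]
        ]
    except (KeyError, TypeError) as exc:
        raise CldValidationError(f"malformed diagram document: {exc}") from exc
    return CausalLoopDiagram(
        variables,
        connections,
        name=doc.get("name", ""),
        provenance=doc.get("provenance", ""),
    )


def _save_native(cld: CausalLoopDiagram, path: Path) -> None:
    path.write_text(json.dumps(cld_to_dict(cld), indent=2, sort_keys=True) + "\n")


def _load_native(path: Path) -> CausalLoopDiagram:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise CldValidationError(f"{path}: not valid JSON: {exc}") from exc
    return cld_from_dict(doc)


# ---- GraphML -------------------------------------------------------


def _save_graphml(cld: CausalLoopDiagram, path: Path) -> None:
    g = cld.to_networkx()
    for _, _, data in g.edges(data=True):
        data["references"] = json.dumps(data["references"])
    nx.write_graphml(g, path)


def _load_graphml(path: Path) -> CausalLoopDiagram:
    try:
        g = nx.read_graphml(path)
    except Exception as exc:  # networkx raises several parser types
        raise CldValidationError(f"{path}: GraphML parse failed: {exc}") from exc
    variables = [
        Variable(
            id=str(n),
            label=data.get("label", str(n)),
            domain=data.get("domain", ""),
            definition=data.get("definition", ""),
        )
        for n, data in g.nodes(data=True)
    ]
    connections = [
        Connection(
            source=str(u),
            target=str(v),
            polarity=data.get("polarity", ""),
            mechanism_note=data.get("mechanism_note", ""),
            references=tuple(json.loads(data.get("references", "[]"))),
            proposer_count=int(data.get("proposer_count", 0)),
        )
        for u, v, data in g.edges(data=True)
    ]
    return CausalLoopDiagram(
        variables,
        connections,
        name=g.graph.get("name", ""),
        provenance=g.graph.get("provenance", ""),
    )


# ---- CSV edge list -------------------------------------------------


def _save_csv(cld: CausalLoopDiagram, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source", "target", "polarity"])
        for c in cld.connections:
            writer.writerow([c.source, c.target, c.polarity])


def _load_csv(path: Path, default_domain: str) -> CausalLoopDiagram:
    ids: list[str] = []
    connections: list[Connection] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"source", "target", "polarity"} <= set(
            reader.fieldnames
        ):
            raise CldValidationError(
                f"{path}: CSV edge list needs columns source,target,polarity"
            )
        for row in reader:
            connections.append(
                Connection(row["source"], row["target"], row["polarity"])
            )
            for endpoint in (row["source"], row["target"]):
                if endpoint not in ids:
                    ids.append(endpoint)
    variables = [Variable(i, i, default_domain) for i in ids]
    return CausalLoopDiagram(variables, connections, name=path.stem)


# ---- DOT export ----------------------------------------------------


def _save_dot(cld: CausalLoopDiagram, path: Path) -> None:
    lines = [f'digraph "{cld.name or "cld"}" {{']
    for v in cld.variables:
        lines.append(f'  "{v.id}" [label="{v.label}", domain="{v.domain}"];')
    for c in cld.connections:
        lines.append(
            f'  "{c.source}" -> "{c.target}" '
            f'[style={_DOT_STYLE[c.polarity]}, color={_DOT_COLOR[c.polarity]}];'
        )
    lines.append("}")
    path.write_text("\n".join(lines) + "\n")
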