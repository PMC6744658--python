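"""Readers and writers for the plain-text formats the tool touches.

Edge lists: one interaction per line, ``<idA>\\t<idB>[\\t<weight>]``, tab- or
whitespace-separated (the public DIP/BioGRID-derived files vary).  Lines
starting with ``#`` are comments.  Complex sets: one complex per line,
members tab/whitespace-separated (CYC2008-style flat file).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Union

from .network import ComplexSet, PPINetwork, edge_key

log = logging.getLogger(__name__)

PathLike = Union[str, Path]


class ParseError(ValueError):
    """Raised for a malformed input line; message names the line number."""


def _split(line: str, delimiter: str) -> List[str]:
    if delimiter == "tab":
        return [f for f in line.split("\t") if f != ""]
    # "auto" and "whitespace": runs of any whitespace
    return line.split()


def read_edge_list(path: PathLike, delimiter: str = "auto") -> PPINetwork:
    """Read an undirected edge list into a :class:`PPINetwork`.

    Duplicate lines and reversed duplicates collapse to a single edge;
    self-loop lines are dropped with a warning.  A numeric third field
    populates ``edge_weight`` (preserved, not used by the pipeline).
    """
    if delimiter not in ("auto", "tab", "whitespace"):
        raise ValueError(f"unknown delimiter mode {delimiter!r}")
    vertices: set = set()
    edges: set = set()
    weights: Dict = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = _split(line, delimiter)
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected at least 2 fields, got {len(fields)}")
            u, v = fields[0], fields[1]
            if u == v:
                log.warning("%s:%d: dropping self-loop on %r", path, lineno, u)
                vertices.add(u)
                continue
            vertices.update((u, v))
            key = edge_key(u, v)
            edges.add(key)
            if len(fields) >= 3:
                try:
                    w = float(fields[2])
                except ValueError as exc:
                    raise ParseError(
                        f"{path}:{lineno}: non-numeric weight field {fields[2]!r}"
                    ) from exc
                weights[key] = w
    return PPINetwork(vertices=vertices, edges=edges, edge_weight=weights or None)


def write_edge_list(net: PPINetwork, path: PathLike, weights: Dict = None) -> None:
    """Write an edge list; ``weights`` (pair → float) adds a third column."""
    with open(path, "wt", encoding="utf-8") as fh:
        for u, v in sorted(net.edges):
            if weights is not None and edge_key(u, v) in weights:
                fh.write(f"{u}\t{v}\t{weights[edge_key(u, v)]:.8g}\n")
            elif weights is None and edge_key(u, v) in net.edge_weight:
                fh.write(f"{u}\t{v}\t{net.edge_weight[edge_key(u, v)]:.8g}\n")
            else:
                fh.write(f"{u}\t{v}\n")


def read_complex_set(path: PathLike) -> ComplexSet:
    """Read a flat one-complex-per-line file.

    Duplicate members within a line are collapsed; identical lines stay as
    separate complexes (deduplication is the assembly stage's job).  Member
    tokens of the form ``name:role`` produced by
    :func:`write_complex_set` with role annotation are split back apart.
    """
    complexes = []
    roles: List[Dict[str, str]] = []
    any_roles = False
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line.startswith("#"):
                continue
            if not line:
                log.warning("%s:%d: skipping empty line", path, lineno)
                continue
            members = []
            role_map: Dict[str, str] = {}
            for token in line.split():
                if ":" in token:
                    name, role = token.rsplit(":", 1)
                    if role in ("core", "peripheral", "overlapping"):
                        members.append(name)
                        role_map[name] = role
                        any_roles = True
                        continue
                members.append(token)
            complexes.append(frozenset(members))
            roles.append(role_map)
    return ComplexSet(complexes=complexes, roles=roles if any_roles else None)


def write_complex_set(cs: ComplexSet, path: PathLike, annotate_roles: bool = False) -> None:
    """Write one complex per line, members tab-separated and sorted.

    With ``annotate_roles`` and role information attached, each member is
    written as ``name:role`` (a sidecar suffix readable by
    :func:`read_complex_set`).
    """
    with open(path, "wt", encoding="utf-8") as fh:
        for i, members in enumerate(cs.complexes):
            names = sorted(members)
            if annotate_roles and cs.roles is not None:
                role_map = cs.roles[i]
                fields = [f"{m}:{role_map[m]}" if m in role_map else m for m in names]
            else:
                fields = names
            fh.write("\t".join(fields) + "\n")


def read_annotations(path: PathLike) -> Dict[str, set]:
    """Read a two-column protein → functional-group table.

    Returns group → set-of-proteins.  A protein may appear under several
    groups (one line per membership).
    """
    groups: Dict[str, set] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
            protein, group = fields[0], fields[1]
            groups.setdefault(group, set()).add(protein)
    return groups
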