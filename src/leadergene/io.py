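"""Readers and writers for gene panels, alias maps and interaction score files.

Interaction scores use the STRING links dialect: whitespace-separated
``node node combined_score`` records, with scores either 0–1000 integers
(as STRING ships them) or 0–1 reals.  Scores are normalised to the unit
interval at load time so every downstream threshold lives on one scale.
Gene symbols are compared case-insensitively and stored uppercase, the
HGNC convention.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "AliasMap",
    "PanelError",
    "ScoreFileError",
    "PanelLoadResult",
    "file_sha256",
    "load_gene_list",
    "load_interaction_scores",
    "normalize_symbol",
    "read_assignments",
    "write_assignments",
    "write_gene_list",
    "write_links",
    "write_wnl",
]


class PanelError(ValueError):
    """Raised for unusable gene panel files."""


class ScoreFileError(ValueError):
    """Raised for malformed interaction score files."""


def normalize_symbol(token: str) -> str:
    """Validate and canonicalise a gene symbol (uppercase, no whitespace)."""
    sym = str(token).strip()
    if not sym:
        raise ValueError("empty gene symbol")
    if any(c.isspace() for c in sym):
        raise ValueError(f"gene symbol contains whitespace: {token!r}")
    return sym.upper()


class AliasMap:
    """Mapping from alias/previous symbols to approved symbols.

    Every approved symbol maps to itself, and no alias may resolve to two
    different approved symbols; both are enforced at construction.
    """

    def __init__(self, entries: Mapping[str, str]):
        resolved: dict[str, str] = {}
        for alias, approved in entries.items():
            a = normalize_symbol(alias)
            ap = normalize_symbol(approved)
            if a in resolved and resolved[a] != ap:
                raise ValueError(
                    f"alias {a} maps to both {resolved[a]} and {ap}"
                )
            resolved[a] = ap
        for ap in set(resolved.values()):
            if ap in resolved and resolved[ap] != ap:
                raise ValueError(
                    f"approved symbol {ap} maps to {resolved[ap]}, not itself"
                )
            resolved.setdefault(ap, ap)
        self._map = resolved

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AliasMap":
        """Read a 2-column TSV (alias, approved_symbol); header optional."""
        entries: dict[str, str] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise ValueError(
                    f"{path}, line {lineno}: expected 2 columns, got {len(parts)}"
                )
            if lineno == 1 and parts[0].lower() in {"alias", "symbol", "previous"}:
                continue
            entries[parts[0]] = parts[1]
        return cls(entries)

    def resolve(self, token: str) -> str | None:
        """Approved symbol for ``token``, or None when unknown."""
        return self._map.get(normalize_symbol(token))

    def __contains__(self, token: str) -> bool:
        return normalize_symbol(token) in self._map

    def __len__(self) -> int:
        return len(self._map)


@dataclass(frozen=True)
class PanelLoadResult:
    """Normalised gene panel plus the tokens an alias map could not resolve."""

    genes: frozenset[str]
    unresolved: tuple[str, ...] = ()


def load_gene_list(
    path: str | Path, alias_map: AliasMap | None = None
) -> PanelLoadResult:
    """Load a gene panel: one symbol per line, ``#`` comments, blank lines skipped.

    With an alias map, tokens are projected onto approved symbols; tokens
    absent from the map are reported as unresolved, never silently dropped.
    """
    tokens: list[str] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if any(c.isspace() for c in line):
            raise PanelError(
                f"{path}, line {lineno}: expected one symbol per line, got {line!r}"
            )
        tokens.append(line)
    if not tokens:
        raise PanelError("empty gene panel")

    genes: set[str] = set()
    unresolved: list[str] = []
    for tok in tokens:
        sym = normalize_symbol(tok)
        if alias_map is None:
            genes.add(sym)
        else:
            approved = alias_map.resolve(sym)
            if approved is None:
                if sym not in unresolved:
                    unresolved.append(sym)
            else:
                genes.add(approved)
    return PanelLoadResult(frozenset(genes), tuple(unresolved))


def _detect_scale(scores: Iterable[float]) -> str:
    return "milli" if any(s > 1 for s in scores) else "unit"


def load_interaction_scores(path: str | Path, scale: str = "auto") -> nx.Graph:
    """Read a STRING-dialect links file into an undirected scored graph.

    Parameters
    ----------
    path : file with whitespace-separated ``node node combined_score`` rows.
        An optional first line whose third field is non-numeric is treated
        as a header and skipped.
    scale : {"auto", "unit", "milli"}
        "milli" divides scores by 1000; "auto" infers "milli" whenever any
        score exceeds 1, else "unit".

    Duplicate and reciprocal records collapse to one undirected edge keeping
    the maximum score; self-loops are dropped (count logged).  Scores must
    land in [0, 1] after scaling.
    """
    if scale not in {"auto", "unit", "milli"}:
        raise ValueError(f"unknown scale {scale!r}")
    records: list[tuple[str, str, float]] = []
    self_loops = 0
    first_content = True
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ScoreFileError(
                f"{path}, line {lineno}: expected 3 fields, got {len(parts)}"
            )
        try:
            score = float(parts[2])
        except ValueError:
            if first_content:
                first_content = False
                continue  # header line
            raise ScoreFileError(
                f"{path}, line {lineno}: non-numeric score {parts[2]!r}"
            ) from None
        first_content = False
        a, b = normalize_symbol(parts[0]), normalize_symbol(parts[1])
        if a == b:
            self_loops += 1
            continue
        records.append((a, b, score))

    if self_loops:
        log.info("dropped %d self-loop record(s) from %s", self_loops, path)
    if not records:
        log.warning("no interaction records found in %s", path)
        return nx.Graph()

    effective = _detect_scale(s for _, _, s in records) if scale == "auto" else scale
    edges: dict[tuple[str, str], float] = {}
    for a, b, s in records:
        if effective == "milli":
            s = s / 1000.0
        if not 0.0 <= s <= 1.0:
            raise ScoreFileError(
                f"{path}: score {s} outside [0, 1] after {effective!r} scaling"
                f" for pair ({a}, {b})"
            )
        key = (a, b) if a < b else (b, a)
        edges[key] = max(edges.get(key, 0.0), s)

    net = nx.Graph()
    for (a, b), s in edges.items():
        net.add_edge(a, b, score=s)
    return net


def write_links(net: nx.Graph, path: str | Path, scale: str = "unit") -> None:
    """Write a graph back to the STRING links dialect.

    ``unit`` writes full-precision reals (lossless round-trip); ``milli``
    writes 0–1000 integers as STRING does.
    """
    if scale not in {"unit", "milli"}:
        raise ValueError(f"unknown scale {scale!r}")
    lines = ["node1\tnode2\tcombined_score"]
    for a, b in sorted(tuple(sorted(e)) for e in net.edges):
        s = net.edges[a, b]["score"]
        val = f"{round(s * 1000):d}" if scale == "milli" else f"{s:.17g}"
        lines.append(f"{a}\t{b}\t{val}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    """Write a gene panel, one symbol per line, sorted."""
    Path(path).write_text("\n".join(sorted(genes)) + "\n")


def write_wnl(wnl: Mapping[str, float] | pd.Series, path: str | Path) -> None:
    """Write a 2-column TSV (gene, wnl), sorted by descending WNL then symbol."""
    ser = pd.Series(dict(wnl), name="wnl")
    df = ser.rename_axis("gene").reset_index()
    df = df.sort_values(["wnl", "gene"], ascending=[False, True])
    df.to_csv(path, sep="\t", index=False)


def write_assignments(
    labels: Mapping[str, str],
    wnl: Mapping[str, float] | pd.Series,
    path: str | Path,
) -> None:
    """Write the cluster assignment TSV (gene, wnl, cluster).

    Rows are sorted by descending WNL, ties broken by symbol; every labeled
    gene must have a WNL entry.
    """
    wnl = dict(pd.Series(dict(wnl)))
    rows = []
    for gene, label in labels.items():
        if gene not in wnl:
            raise ValueError(f"no WNL value for labeled gene {gene}")
        rows.append((gene, float(wnl[gene]), label))
    df = pd.DataFrame(rows, columns=["gene", "wnl", "cluster"])
    df = df.sort_values(["wnl", "gene"], ascending=[False, True])
    df.to_csv(path, sep="\t", index=False)


def read_assignments(path: str | Path) -> pd.DataFrame:
    """Read an assignment TSV back into a (gene, wnl, cluster) frame."""
    df = pd.read_csv(
        path, sep="\t", dtype={"gene": str, "cluster": str}, keep_default_na=False
    )
    df["wnl"] = df["wnl"].astype(float)
    return df


def file_sha256(path: str | Path) -> str:
    """Hex SHA-256 of a file, for run-report provenance."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
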