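"""Edge-list, trace and manifest serialisation.

The interchange format is a headered TSV/CSV edge list with columns
``source``, ``target``, ``weight``.  Node identifiers may be integers
or strings; they are mapped to a stable 0-based index (numeric sort
when all ids are integral, lexicographic otherwise) and the mapping is
kept on the network object.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .network import DirectedWeightedNetwork

log = logging.getLogger("neurodecay")


class EdgeListFormatError(ValueError):
    """Malformed edge-list file."""


def _sep_for(path: Path, dialect: str | None) -> str:
    if dialect == "tsv":
        return "\t"
    if dialect == "csv":
        return ","
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


def read_edgelist(path, dialect: str | None = None,
                  normalize: bool | None = None) -> DirectedWeightedNetwork:
    """Read a directed weighted edge list into a network.

    Self-loops are dropped (with a logged count); duplicate ordered
    pairs keep the first occurrence with a warning; non-positive
    weights are rejected.  Raw interaction strengths larger than 1 are
    rescaled into ``(0, 1]`` by division by the file's maximum weight
    (``normalize=None`` applies this only when needed, so files already
    in ``(0, 1]`` round-trip unchanged; pass True/False to force).
    """
    path = Path(path)
    sep = _sep_for(path, dialect)
    try:
        df = pd.read_csv(path, sep=sep, dtype={"source": str, "target": str},
                         float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise EdgeListFormatError(f"{path}: cannot parse: {exc}") from exc
    required = {"source", "target", "weight"}
    if not required.issubset(df.columns):
        raise EdgeListFormatError(
            f"{path}: missing columns {sorted(required - set(df.columns))}")
    bad = df.index[pd.to_numeric(df["weight"], errors="coerce").isna()]
    if len(bad):
        raise EdgeListFormatError(
            f"{path}: malformed weight on line {int(bad[0]) + 2}")
    df["weight"] = df["weight"].astype(float)
    if (df["weight"] <= 0).any():
        line = int(df.index[df["weight"] <= 0][0]) + 2
        raise EdgeListFormatError(
            f"{path}: non-positive weight on line {line}")

    n_loops = int((df["source"] == df["target"]).sum())
    if n_loops:
        log.warning("%s: removed %d self-loop(s)", path, n_loops)
        df = df[df["source"] != df["target"]]
    n_dup = int(df.duplicated(subset=["source", "target"]).sum())
    if n_dup:
        log.warning("%s: %d duplicate edge(s), keeping first occurrence",
                    path, n_dup)
        df = df.drop_duplicates(subset=["source", "target"], keep="first")
    if df.empty:
        raise EdgeListFormatError(f"{path}: no usable edges")

    ids = pd.unique(pd.concat([df["source"], df["target"]]))
    try:
        order = np.argsort([int(x) for x in ids], kind="stable")
    except ValueError:
        order = np.argsort(ids.astype(str), kind="stable")
    ids = [ids[i] for i in order]
    index = {x: i for i, x in enumerate(ids)}

    w = df["weight"].to_numpy()
    if normalize is None:
        normalize = bool(w.max() > 1.0)
    if normalize:
        w = w / w.max()
    return DirectedWeightedNetwork(
        n=len(ids),
        src=np.array([index[x] for x in df["source"]], dtype=np.int64),
        dst=np.array([index[x] for x in df["target"]], dtype=np.int64),
        eps0=w,
        node_ids=list(ids),
    )


def write_edgelist(network: DirectedWeightedNetwork, path,
                   dialect: str | None = None) -> None:
    """Write the functional edges as a deterministic headered edge list.

    Rows are sorted by (source, target); weights are the *current*
    strengths at full precision, so write/read/write is byte-stable.
    """
    path = Path(path)
    sep = _sep_for(path, dialect)
    mask = network.functional_mask
    src, dst, eps = network.src[mask], network.dst[mask], network.eps[mask]
    order = np.lexsort((dst, src))
    labels = network.node_ids if network.node_ids else None
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"source{sep}target{sep}weight\n")
        for s, d, w in zip(src[order], dst[order], eps[order]):
            a = labels[s] if labels else s
            b = labels[d] if labels else d
            fh.write(f"{a}{sep}{b}{sep}{float(w)!r}\n")


def write_manifest(path, entries: dict) -> None:
    """Flat key=value manifest recording every run parameter and seed."""
    with open(path, "w", encoding="utf-8") as fh:
        for key in sorted(entries):
            fh.write(f"{key}={entries[key]}\n")


def read_manifest(path) -> dict:
    out = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if line.strip():
            key, _, value = line.partition("=")
            out[key] = value
    return out
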