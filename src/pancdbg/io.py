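"""FASTA reading, artifact serialization and graph export formats."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

from pancdbg.build import ImplicitGraph, ImplicitNode, node_string
from pancdbg.explicit import ExplicitGraph
from pancdbg.kmer_marks import KmerMarks, build_kmer_marks
from pancdbg.text_index import (
    FMIndex,
    PanGenomeText,
    build_fm_index,
    encode_and_concatenate,
)

CONTAINER_VERSION = 1


class FastaError(ValueError):
    pass


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Records in file order, uppercased, whitespace stripped.

    Rejects malformed input (data before the first header, records with
    empty sequences) with the offending line number.
    """
    records: list[tuple[str, list[str]]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0] if line[1:].strip() else f"seq{len(records) + 1}"
                records.append((name, []))
            else:
                if not records:
                    raise FastaError(
                        f"{path}:{lineno}: sequence data before first header"
                    )
                records[-1][1].append(line.upper())
    if not records:
        raise FastaError(f"{path}: no FASTA records found")
    out = []
    for name, chunks in records:
        seq = "".join(chunks)
        if not seq:
            raise FastaError(f"{path}: record {name!r} has an empty sequence")
        out.append((name, seq))
    return out


def write_fasta(path: str | Path, records: Sequence[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def save_container(
    path: str | Path,
    fm: FMIndex,
    marks: KmerMarks | None = None,
    G: ImplicitGraph | None = None,
) -> None:
    """Versioned JSON container for the index and (optionally) the graph.

    The suffix array, BWT and bit vectors are stored explicitly; derived
    structures (wavelet trees, rank tables) are rebuilt deterministically
    on load, so reloaded indexes answer queries bit-identically.
    """
    text = fm.text
    doc: dict = {
        "version": CONTAINER_VERSION,
        "text": {
            "names": list(text.names),
            "seq_lengths": list(text.seq_lengths),
            "S": text.S,
        },
        "sa": [int(v) for v in fm.sa],
        "bwt": fm.bwt,
    }
    if marks is not None:
        doc["marks"] = {
            "k": marks.k,
            "rightMax": marks.rightMax,
            "leftMax": marks.leftMax,
            "B_r": "".join(str(b) for b in marks.B_r.bits),
            "B_l": "".join(str(b) for b in marks.B_l.bits),
            "seeds": [list(s) for s in marks.seeds],
        }
    if G is not None:
        doc["graph"] = {
            "k": G.k,
            "d": G.d,
            "rightMax": G.rightMax,
            "leftMax": G.leftMax,
            "nodes": [list(nd.as_tuple()) for nd in G.nodes],
        }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_container(
    path: str | Path,
) -> tuple[FMIndex, KmerMarks | None, ImplicitGraph | None]:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("version") != CONTAINER_VERSION:
        raise ValueError(
            f"unsupported container version {doc.get('version')!r}"
        )
    names = doc["text"]["names"]
    lengths = doc["text"]["seq_lengths"]
    S = doc["text"]["S"]
    seqs = []
    pos = 0
    for ln in lengths:
        seqs.append(S[pos : pos + ln])
        pos += ln + 1
    text = encode_and_concatenate(list(zip(names, seqs)))
    if text.S != S:
        raise ValueError("container text metadata is inconsistent")
    fm = build_fm_index(text)
    if [int(v) for v in fm.sa] != doc["sa"] or fm.bwt != doc["bwt"]:
        raise ValueError("container index does not match its text")
    marks = None
    if "marks" in doc:
        m = doc["marks"]
        marks = build_kmer_marks(fm, m["k"])
        stored_br = [int(c) for c in m["B_r"]]
        stored_bl = [int(c) for c in m["B_l"]]
        if (
            list(marks.B_r.bits) != stored_br
            or list(marks.B_l.bits) != stored_bl
            or marks.rightMax != m["rightMax"]
            or marks.leftMax != m["leftMax"]
        ):
            raise ValueError("container marks do not match the index")
    G = None
    if "graph" in doc:
        g = doc["graph"]
        G = ImplicitGraph(
            nodes=[ImplicitNode(*row) for row in g["nodes"]],
            k=g["k"],
            d=g["d"],
            rightMax=g["rightMax"],
            leftMax=g["leftMax"],
        )
    return fm, marks, G


def implicit_to_tsv(fm: FMIndex, G: ImplicitGraph) -> str:
    """Table of node records, one row per identifier."""
    lines = [
        f"#k={G.k}\td={G.d}\trightMax={G.rightMax}\tleftMax={G.leftMax}",
        "id\tlen\tlb\tsize\tsuffix_lb",
    ]
    for ident in G.ids():
        nd = G[ident]
        lines.append(
            f"{ident}\t{nd.len}\t{nd.lb}\t{nd.size}\t{nd.suffix_lb}"
        )
    return "\n".join(lines) + "\n"


def explicit_to_tsv(explicit: ExplicitGraph) -> str:
    lines = ["id\tlen\tposList\tadjList\tstart"]
    starts = set(explicit.StartNodes)
    for nd in explicit.nodes:
        lines.append(
            "\t".join(
                (
                    str(nd.id),
                    str(nd.len),
                    ",".join(map(str, nd.posList)),
                    ",".join(map(str, nd.adjList)),
                    "1" if nd.id in starts else "0",
                )
            )
        )
    return "\n".join(lines) + "\n"


def explicit_to_dot(
    fm: FMIndex, G: ImplicitGraph, explicit: ExplicitGraph
) -> str:
    """DOT digraph with "id:len" labels; multi-edges are preserved."""
    lines = ["digraph cdbg {"]
    for nd in explicit.nodes:
        lines.append(f'  n{nd.id} [label="{nd.id}:{nd.len}"];')
    for nd in explicit.nodes:
        for succ in nd.adjList:
            lines.append(f"  n{nd.id} -> n{succ};")
    lines.append("}")
    return "\n".join(lines) + "\n"


def explicit_to_gfa(
    fm: FMIndex, G: ImplicitGraph, explicit: ExplicitGraph
) -> str:
    """GFA1: S-lines with node strings, L-lines with (k-1)M overlaps.

    Stop-node strings have their terminator stripped from the sequence
    field; the removed symbol is recorded in an ``XT`` tag.
    """
    k = G.k
    lines = ["H\tVN:Z:1.0"]
    for ident in G.ids():
        s = node_string(fm, G, ident)
        if G.is_stop(ident):
            term = s[-1]
            body = s[:-1] if len(s) > 1 else "*"
            lines.append(f"S\t{ident}\t{body}\tXT:Z:{term}")
        else:
            lines.append(f"S\t{ident}\t{s}")
    seen: dict[tuple[int, int], int] = {}
    for nd in explicit.nodes:
        for succ in nd.adjList:
            seen[(nd.id, succ)] = seen.get((nd.id, succ), 0) + 1
    for (a, b), count in sorted(seen.items()):
        for _ in range(count):
            lines.append(f"L\t{a}\t+\t{b}\t+\t{k - 1}M")
    return "\n".join(lines) + "\n"
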