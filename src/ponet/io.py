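"""Readers and writers for every on-disk format.

All tabular formats are TSV; coordinates are 0-based half-open; expression
headers encode samples as ``<stage>_<fraction>_<rep>`` with fraction T or P.
PWMs use MEME minimal format, networks GraphML (via networkx), ontologies a
``child<TAB>parent`` edge list.
"""
from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .consensus import ConsensusNetwork
from .errors import FormatError
from .expression import ExpressionMatrix
from .features import PWM, TranscriptRecord

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    df = matrix.data.copy()
    df.columns = [f"{s}_{f}_{r}" for s, f, r in df.columns]
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


def read_expression_tsv(path, stage_order=None) -> ExpressionMatrix:
    """Parse an expression TSV; rejects duplicate genes and malformed cells
    with the offending line number. CRLF and LF files parse identically."""
    path = Path(path)
    with open(path, newline="") as fh:
        lines = [ln.rstrip("\r\n") for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    if header[0] != "gene":
        raise FormatError(f"{path}:1: first column must be 'gene'")
    columns = []
    for col in header[1:]:
        parts = col.rsplit("_", 2)
        if len(parts) != 3 or parts[1] not in ("T", "P") or not parts[2].isdigit():
            raise FormatError(f"{path}:1: malformed sample header {col!r} "
                              "(expected <stage>_<T|P>_<rep>)")
        columns.append((parts[0], parts[1], int(parts[2])))
    genes, values = [], []
    seen = set()
    for i, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(header):
            raise FormatError(f"{path}:{i}: expected {len(header)} fields, got {len(fields)}")
        gene = fields[0]
        if gene in seen:
            raise FormatError(f"{path}:{i}: duplicate gene id {gene!r}")
        seen.add(gene)
        try:
            row = [float(v) for v in fields[1:]]
        except ValueError as exc:
            raise FormatError(f"{path}:{i}: non-numeric cell ({exc})") from None
        genes.append(gene)
        values.append(row)
    cols = pd.MultiIndex.from_tuples(columns, names=["stage", "fraction", "replicate"])
    if stage_order is None:
        stage_order = tuple(dict.fromkeys(c[0] for c in columns))
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=cols), stage_order)


def write_po_tsv(po, path) -> None:
    df = po.data.copy()
    df.columns = [f"{s}_{r}" for s, r in df.columns]
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


def read_po_tsv(path, stage_order=None):
    from .expression import POProfile

    df = pd.read_csv(path, sep="\t", index_col=0)
    cols = [tuple(c.rsplit("_", 1)) for c in df.columns]
    cols = [(s, int(r)) for s, r in cols]
    df.columns = pd.MultiIndex.from_tuples(cols, names=["stage", "replicate"])
    if stage_order is None:
        stage_order = tuple(dict.fromkeys(c[0] for c in cols))
    return POProfile(df, stage_order)


# ---------------------------------------------------------------------------
# transcripts / regions / structure tracks
# ---------------------------------------------------------------------------

def write_transcripts(transcripts, fasta_path, regions_path) -> None:
    records = [
        SeqRecord(Seq(tr.sequence), id=tr.gene, description="")
        for tr in transcripts
    ]
    SeqIO.write(records, fasta_path, "fasta")
    rows = [
        (tr.gene, tr.utr5[1] - tr.utr5[0], tr.cds[1] - tr.cds[0], tr.utr3[1] - tr.utr3[0])
        for tr in transcripts
    ]
    pd.DataFrame(rows, columns=["gene", "utr5_len", "cds_len", "utr3_len"]).to_csv(
        regions_path, sep="\t", index=False
    )


def read_transcripts(fasta_path, regions_path):
    regions = pd.read_csv(regions_path, sep="\t").set_index("gene")
    out = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in regions.index:
            raise FormatError(f"{rec.id}: present in FASTA but not in region table")
        u5, cds, u3 = (int(regions.loc[rec.id, c]) for c in ("utr5_len", "cds_len", "utr3_len"))
        out.append(
            TranscriptRecord(rec.id, str(rec.seq), (0, u5), (u5, u5 + cds), (u5 + cds, u5 + cds + u3))
        )
    return out


def write_structure_tsv(tracks: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tpos\tscore\n")
        for gene, scores in tracks.items():
            for pos, s in enumerate(scores):
                fh.write(f"{gene}\t{pos}\t{s:.6g}\n")


def read_structure_tsv(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for gene, grp in df.groupby("gene", sort=False):
        grp = grp.sort_values("pos")
        if not np.array_equal(grp["pos"].to_numpy(), np.arange(len(grp))):
            raise FormatError(f"{gene}: structure positions must be 0..len-1")
        out[gene] = grp["score"].to_numpy()
    return out


# ---------------------------------------------------------------------------
# PWMs (MEME minimal format)
# ---------------------------------------------------------------------------

def write_meme(pwms, path, background=None) -> None:
    pwms = [pwms] if isinstance(pwms, PWM) else list(pwms)
    bg = pwms[0].background if background is None else np.asarray(background)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: +\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A {:.5f} C {:.5f} G {:.5f} T {:.5f}\n\n".format(*bg))
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.motif_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                f"nsites= 20 E= 0\n"
            )
            for col in pwm.matrix.T:
                fh.write(" " + "  ".join(f"{v:.6f}" for v in col) + "\n")
            fh.write("\n")


def read_meme(path) -> list:
    """Parse MEME minimal format into PWM objects."""
    pwms = []
    background = np.full(4, 0.25)
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            fields = lines[i + 1].split()
            background = np.array([float(fields[k]) for k in (1, 3, 5, 7)])
            i += 2
            continue
        if line.startswith("MOTIF"):
            motif_id = line.split()[1]
            i += 1
            while i < len(lines) and not lines[i].strip().startswith("letter-probability"):
                i += 1
            header = lines[i].strip()
            w = int(header.split("w=")[1].split()[0])
            rows = []
            for j in range(w):
                rows.append([float(v) for v in lines[i + 1 + j].split()])
            pwms.append(PWM(motif_id, np.array(rows).T, background))
            i += 1 + w
            continue
        i += 1
    if not pwms:
        raise FormatError(f"{path}: no MOTIF entries found")
    return pwms


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def write_network_graphml(net: ConsensusNetwork, path, hierarchy=None, threshold: float = 0.0) -> None:
    """GraphML export; nodes carry module attributes when a hierarchy is
    given, every edge carries score/directed, and a re-read yields an
    isomorphic attributed graph."""
    g = nx.DiGraph()
    part = hierarchy.partition(1) if hierarchy is not None else {}
    sub = net.subnetwork(threshold)
    nodes = set(sub["source"]) | set(sub["target"])
    for n in sorted(nodes):
        attrs = {}
        if n in part:
            attrs["module"] = ":".join(map(str, part[n]))
        g.add_node(n, **attrs)
    for row in sub.itertuples(index=False):
        g.add_edge(row.source, row.target, score=float(row.score),
                   directed=bool(row.directed), methods=row.methods)
    nx.write_graphml(g, path)


def read_network_graphml(path) -> ConsensusNetwork:
    g = nx.read_graphml(path)
    rows = [
        (u, v, d.get("score", 0.0), bool(d.get("directed", False)), d.get("methods", ""))
        for u, v, d in g.edges(data=True)
    ]
    edges = pd.DataFrame(rows, columns=["source", "target", "score", "directed", "methods"])
    return ConsensusNetwork(sorted(g.nodes), edges)


def write_edges_tsv(net: ConsensusNetwork, path) -> None:
    net.edges.to_csv(path, sep="\t", index=False)


def read_edges_tsv(path) -> ConsensusNetwork:
    edges = pd.read_csv(path, sep="\t")
    if "methods" in edges.columns:
        edges["methods"] = edges["methods"].fillna("")
    nodes = sorted(set(edges["source"]) | set(edges["target"]))
    return ConsensusNetwork(nodes, edges)


def write_score_table_tsv(table, path) -> None:
    rows = []
    genes = list(table.genes)
    m = table.scores.to_numpy()
    for i, gi in enumerate(genes):
        for j, gj in enumerate(genes):
            if i == j or (table.symmetric and j < i) or m[i, j] == 0:
                continue
            rows.append((gi, gj, table.method, m[i, j], table.symmetric))
    pd.DataFrame(rows, columns=["source", "target", "method", "score", "symmetric"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# ontology / annotations / traces
# ---------------------------------------------------------------------------

def read_ontology_tsv(path) -> list:
    df = pd.read_csv(path, sep="\t", header=None, names=["child", "parent"], comment="#")
    return list(df.itertuples(index=False, name=None))


def read_annotations_tsv(path) -> dict:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"], comment="#")
    out: dict[str, list] = {}
    for gene, term in df.itertuples(index=False, name=None):
        out.setdefault(gene, []).append(term)
    return out


def read_trace_tsv(path):
    from .expression import AbsorbanceTrace

    df = pd.read_csv(path, sep="\t")
    return AbsorbanceTrace(df["position"].to_numpy(), df["absorbance"].to_numpy())
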