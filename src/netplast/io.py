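"""Reading and writing TF networks and tabular results.

Networks are directed simple graphs (``networkx.DiGraph``): nodes are TF
names, an edge regulator -> regulated means the regulator's motif was found
in an accessible footprint near the target's TSS.  Self-loops are dropped
and duplicate edges collapsed at load time (flag-reversible); the reported
densities of such networks follow the loopless directed convention
m / (N(N-1)), and all percolation/distance machinery downstream assumes
simple loopless graphs.

Node order is fixed by first appearance in the file, so seeded operations
are reproducible across runs and platforms.
"""

from __future__ import annotations

import glob as _glob
import logging
import os
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class NetworkPanel:
    """An ordered collection of uniquely named networks (one per cell type)."""

    networks: list = field(default_factory=list)
    species_tag: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        names = [g.graph["name"] for g in self.networks]
        if len(names) != len(set(names)):
            raise ValueError("network names must be unique within a panel")

    @property
    def names(self):
        return [g.graph["name"] for g in self.networks]

    def __len__(self):
        return len(self.networks)

    def __iter__(self):
        return iter(self.networks)


def read_edge_list(path, name=None, drop_self_loops=True):
    """Read a whitespace-delimited regulator/regulated edge list.

    The first two tokens of each line are regulator and regulated TF labels;
    extra columns are ignored (some releases carry a third column) and lines
    starting with '#' are skipped.  Returns a simple directed graph.
    """
    if name is None:
        name = os.path.splitext(os.path.basename(path))[0]
    net = nx.DiGraph(name=name)
    n_self, n_dup, n_extra_cols = 0, 0, 0
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise ValueError(
                    f"{path}:{lineno}: malformed line (fewer than 2 tokens): {line!r}"
                )
            if len(tokens) > 2:
                n_extra_cols += 1
            u, v = tokens[0], tokens[1]
            n_lines += 1
            if u == v:
                if drop_self_loops:
                    n_self += 1
                    # still register the node so isolated self-regulators count
                    net.add_node(u)
                    continue
            if net.has_edge(u, v):
                n_dup += 1
                continue
            net.add_edge(u, v)
    if net.number_of_edges() == 0:
        raise ValueError(f"{path}: no edges after cleaning ({n_lines} records read)")
    if n_self or n_dup or n_extra_cols:
        logger.info(
            "%s: dropped %d self-loop(s), collapsed %d duplicate edge(s), "
            "ignored extra columns on %d line(s)",
            path, n_self, n_dup, n_extra_cols,
        )
    net.graph["n_self_loops_dropped"] = n_self
    net.graph["n_duplicates_collapsed"] = n_dup
    return net


def write_edge_list(net, path):
    """Write a two-column whitespace-delimited edge list (round-trips)."""
    with open(path, "w") as fh:
        for u, v in net.edges():
            fh.write(f"{u}\t{v}\n")


def write_graphml(net, path):
    nx.write_graphml(net, path)


def load_panel(directory, pattern="*.txt", species_tag="", drop_self_loops=True):
    """Load every matching edge list (lexicographic order) into a panel."""
    paths = sorted(_glob.glob(os.path.join(directory, pattern)))
    if not paths:
        raise FileNotFoundError(
            f"no files matching {pattern!r} under {directory!r}"
        )
    networks, provenance = [], {}
    for p in paths:
        net = read_edge_list(p, drop_self_loops=drop_self_loops)
        networks.append(net)
        provenance[net.graph["name"]] = p
    return NetworkPanel(networks=networks, species_tag=species_tag,
                        provenance=provenance)


def write_table(records, path, columns=None):
    """Write keyed rows as TSV, floats at 6 significant digits.

    ``records`` is a list of dicts sharing one key set; an empty list needs
    ``columns`` for the header-only file.
    """
    if records:
        keys = list(records[0].keys())
        for i, rec in enumerate(records):
            if list(rec.keys()) != keys:
                raise ValueError(f"record {i} has keys {list(rec)} != {keys}")
        df = pd.DataFrame.from_records(records, columns=keys)
    else:
        if columns is None:
            raise ValueError("empty record list needs explicit columns")
        df = pd.DataFrame(columns=list(columns))
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def read_table(path):
    return pd.read_csv(path, sep="\t")
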