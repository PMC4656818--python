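"""Hypergeometric pathway over-representation with R = O/E and polarity scores.

For a differential gene list of size n drawn from a measured universe of
size N, a pathway with K members in the universe and O members in the list
has expected count E = n*K/N, enrichment ratio R = O/E, and upper-tail
hypergeometric probability p = P(X >= O) with X ~ Hypergeom(N, K, n).
A pathway is flagged significant when R > 1 and p < 0.05 (raw p by
default — an optional BH adjustment across pathways can be switched on),
and only pathways populated by at least ``min_members`` list genes are
reported.

The polarity score summarises the direction of regulation of a pathway:
100 * U/(U+D) - 100 * D/(U+D), where U and D count pathway members in the
up- and down-regulated lists; a pathway populated only by elevated genes
scores +100, only by decreased genes -100.  The bimodal classifier crosses
two enrichment runs (up-only and down-only lists) and labels a pathway
bimodal when it is significant in both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PathwayCollection",
    "hypergeometric_enrichment",
    "polarity_score",
    "bimodal_classification",
    "read_gmt",
    "write_gmt",
]

logger = logging.getLogger(__name__)


@dataclass
class PathwayCollection:
    """Named gene sets over a background universe.

    Pathway memberships are restricted to the universe on construction, so
    every stored pathway is a subset of the background.
    """

    pathways: dict[str, frozenset]
    universe: frozenset

    def __init__(self, pathways: Mapping[str, Iterable[str]], universe: Iterable[str]):
        self.universe = frozenset(universe)
        if not self.universe:
            raise ValueError("universe must be non-empty")
        self.pathways = {pid: frozenset(genes) & self.universe for pid, genes in pathways.items()}

    def __len__(self) -> int:
        return len(self.pathways)

    @classmethod
    def from_gmt(cls, path, universe: Iterable[str] | None = None) -> "PathwayCollection":
        pathways = read_gmt(path)
        if universe is None:
            universe = set().union(*pathways.values()) if pathways else set()
        return cls(pathways, universe)

    def to_gmt(self, path) -> None:
        write_gmt(self.pathways, path)


def read_gmt(path) -> dict[str, set]:
    """Read a GMT gene-set file (set name, description, member symbols)."""
    try:
        from gseapy.parser import read_gmt as _read

        return {name: set(genes) for name, genes in _read(str(path)).items()}
    except ImportError:
        out: dict[str, set] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) >= 2 and parts[0]:
                    out[parts[0]] = set(g for g in parts[2:] if g)
        return out


def write_gmt(pathways: Mapping[str, Iterable[str]], path) -> None:
    with open(path, "w") as fh:
        for pid in pathways:
            fh.write("\t".join([pid, "na", *sorted(pathways[pid])]) + "\n")


def hypergeometric_enrichment(
    gene_list: Iterable[str],
    coll: PathwayCollection,
    min_members: int = 2,
    p_threshold: float = 0.05,
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Test each pathway for over-representation of ``gene_list``.

    Returns one row per pathway with O >= ``min_members``, with columns
    ``O, E, R, p, significant`` (and ``q`` when ``bh_adjust``).  List
    identifiers outside the universe are dropped with a warning.
    """
    genes = set(gene_list)
    if not genes:
        raise ValueError("gene_list must be non-empty")
    outside = genes - coll.universe
    if outside:
        logger.warning("dropping %d identifier(s) outside the universe", len(outside))
        genes &= coll.universe
        if not genes:
            raise ValueError("no gene_list identifiers remain inside the universe")

    N, n = len(coll.universe), len(genes)
    rows = []
    for pid, members in coll.pathways.items():
        K = len(members)
        O = len(genes & members)
        if O < min_members:
            continue
        E = n * K / N
        R = O / E
        p = float(stats.hypergeom.sf(O - 1, N, K, n))
        rows.append({"pathway_id": pid, "O": O, "E": E, "R": R, "p": p})
    records = pd.DataFrame(rows, columns=["pathway_id", "O", "E", "R", "p"]).set_index("pathway_id")
    if bh_adjust and len(records):
        from .microarray_de import bh_fdr

        records["q"] = bh_fdr(records["p"].to_numpy())
        records["significant"] = (records["R"] > 1) & (records["q"] < p_threshold)
    elif len(records):
        records["significant"] = (records["R"] > 1) & (records["p"] < p_threshold)
    else:
        records["significant"] = pd.Series(dtype=bool)
    return records.sort_values("p")


def polarity_score(pathway: Iterable[str], up_set: Iterable[str], down_set: Iterable[str]) -> float:
    """Percent of populated pathway members elevated minus percent decreased.

    The denominator is the number of pathway members present in either
    significant list (U + D), so the score spans the full [-100, 100]
    range; an unpopulated pathway scores 0.
    """
    members = set(pathway)
    up, down = set(up_set), set(down_set)
    if up & down:
        raise ValueError(f"up/down sets overlap: {sorted(up & down)}")
    U = len(members & up)
    D = len(members & down)
    if U + D == 0:
        return 0.0
    return 100.0 * U / (U + D) - 100.0 * D / (U + D)


def bimodal_classification(up_records: pd.DataFrame, down_records: pd.DataFrame) -> pd.Series:
    """Classify pathways by which directional enrichment runs hit significance.

    ``bimodal`` pathways are significant in both the up-only and the
    down-only run — enriched for elevated and decreased genes at once.
    """
    up_sig = set(up_records.index[up_records["significant"]]) if len(up_records) else set()
    down_sig = set(down_records.index[down_records["significant"]]) if len(down_records) else set()
    all_ids = sorted(set(up_records.index) | set(down_records.index))
    classes = []
    for pid in all_ids:
        in_up, in_down = pid in up_sig, pid in down_sig
        if in_up and in_down:
            classes.append("bimodal")
        elif in_up:
            classes.append("up_only")
        elif in_down:
            classes.append("down_only")
        else:
            classes.append("none")
    return pd.Series(classes, index=pd.Index(all_ids, name="pathway_id"), name="class")
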