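"""Prior regulatory networks: enhancer -> target genes and TF -> enhancer.

An enhancer's feature set for the openness regression is the union of its
binding transcription factors (E_T, derived from TF binding-site intervals
overlapping the enhancer) and its associated target genes (E_G, taken from a
curated association table).  A degree filter keeps only enhancers with
enough of both to support a regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .genomic_io import GenomicInterval, ParseError, bulk_overlap

logger = logging.getLogger(__name__)


@dataclass
class EnhancerRecord:
    """One enhancer with its gene (E_G) and TF (E_T) priors."""

    enhancer_id: str
    interval: GenomicInterval
    target_genes: frozenset[str] = frozenset()
    binding_tfs: frozenset[str] = frozenset()


@dataclass
class RegulatoryNetwork:
    """The two prior networks over a common enhancer universe."""

    enhancers: list[EnhancerRecord]

    @property
    def gene_universe(self) -> frozenset[str]:
        out: set[str] = set()
        for e in self.enhancers:
            out |= e.target_genes
        return frozenset(out)

    @property
    def tf_universe(self) -> frozenset[str]:
        out: set[str] = set()
        for e in self.enhancers:
            out |= e.binding_tfs
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.enhancers)

    def get(self, enhancer_id: str) -> EnhancerRecord:
        for e in self.enhancers:
            if e.enhancer_id == enhancer_id:
                return e
        raise KeyError(enhancer_id)


def build_enhancer_gene_network(association_table: pd.DataFrame) -> RegulatoryNetwork:
    """Build enhancer records from an (enhancer_id, chrom, start, end, gene) table.

    Duplicate (enhancer, gene) rows collapse to one association; two rows
    giving the same enhancer_id different coordinates are an error.
    """
    required = {"enhancer_id", "chrom", "start", "end", "gene"}
    missing = required - set(association_table.columns)
    if missing:
        raise ValueError(f"association table missing columns {sorted(missing)}")

    records: dict[str, EnhancerRecord] = {}
    genes: dict[str, set[str]] = {}
    for row in association_table.itertuples():
        eid = str(row.enhancer_id)
        iv = GenomicInterval(str(row.chrom), int(row.start), int(row.end))
        if eid in records:
            if records[eid].interval != iv:
                raise ParseError(
                    f"conflicting coordinates for enhancer {eid!r}: "
                    f"{records[eid].interval} vs {iv}"
                )
        else:
            records[eid] = EnhancerRecord(enhancer_id=eid, interval=iv)
            genes[eid] = set()
        genes[eid].add(str(row.gene))

    enhancers = [replace(rec, target_genes=frozenset(genes[eid])) for eid, rec in records.items()]
    return RegulatoryNetwork(enhancers=enhancers)


def build_tf_enhancer_network(
    network: RegulatoryNetwork,
    tf_sites: Sequence[tuple[GenomicInterval, str]],
    mode: str = "overlap",
) -> RegulatoryNetwork:
    """Attach binding TFs to each enhancer from binding-site intervals.

    A TF joins E_T of an enhancer when at least one of its sites overlaps the
    enhancer interval (``mode="overlap"``, any shared base qualifies) or lies
    fully inside it (``mode="containment"``).  Multiple sites of one TF in
    one enhancer count once; existing E_T entries are replaced, so the
    operation is idempotent.
    """
    if mode not in ("overlap", "containment"):
        raise ValueError(f"mode must be overlap|containment, got {mode!r}")

    enh_ivs = [e.interval for e in network.enhancers]
    site_ivs = [iv for iv, _ in tf_sites]
    tf_sets: list[set[str]] = [set() for _ in network.enhancers]
    for ei, si in bulk_overlap(enh_ivs, site_ivs):
        site, tf = tf_sites[si]
        if mode == "containment":
            enh = enh_ivs[ei]
            if not (site.start >= enh.start and site.end <= enh.end):
                continue
        tf_sets[ei].add(tf)

    enhancers = [
        replace(e, binding_tfs=frozenset(tfs)) for e, tfs in zip(network.enhancers, tf_sets)
    ]
    return RegulatoryNetwork(enhancers=enhancers)


def filter_by_degree(
    network: RegulatoryNetwork, min_genes: int = 2, min_tfs: int = 2
) -> RegulatoryNetwork:
    """Keep enhancers with |E_G| >= min_genes and |E_T| >= min_tfs.

    The default of two on each side guarantees every retained enhancer
    yields at least four regression features.
    """
    if min_genes < 1 or min_tfs < 1:
        raise ValueError("min_genes and min_tfs must be >= 1")
    kept = [
        e
        for e in network.enhancers
        if len(e.target_genes) >= min_genes and len(e.binding_tfs) >= min_tfs
    ]
    removed = len(network.enhancers) - len(kept)
    logger.info(
        "degree filter (genes>=%d, tfs>=%d): kept %d of %d enhancers (%d removed)",
        min_genes, min_tfs, len(kept), len(network.enhancers), removed,
    )
    return RegulatoryNetwork(enhancers=kept)


# ---------------------------------------------------------------------------
# I/O


def read_association_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_edge_list(network: RegulatoryNetwork, path: str | Path) -> None:
    """Export both networks as a TSV edge list (enhancer_id, partner, role)."""
    rows = []
    for e in network.enhancers:
        for tf in sorted(e.binding_tfs):
            rows.append({"enhancer_id": e.enhancer_id, "partner": tf, "role": "TF"})
        for g in sorted(e.target_genes):
            rows.append({"enhancer_id": e.enhancer_id, "partner": g, "role": "TG"})
    pd.DataFrame(rows, columns=["enhancer_id", "partner", "role"]).to_csv(
        path, sep="\t", index=False
    )


def write_network_files(network: RegulatoryNetwork, assoc_path: str | Path,
                        tf_edges_path: str | Path | None = None) -> None:
    """Write the association table (and optionally TF edges) for round-tripping."""
    rows = []
    for e in network.enhancers:
        for g in sorted(e.target_genes):
            rows.append(
                {
                    "enhancer_id": e.enhancer_id,
                    "chrom": e.interval.chrom,
                    "start": e.interval.start,
                    "end": e.interval.end,
                    "gene": g,
                }
            )
    pd.DataFrame(rows).to_csv(assoc_path, sep="\t", index=False)
    if tf_edges_path is not None:
        write_edge_list(network, tf_edges_path)


def read_network(assoc_path: str | Path, edges_path: str | Path | None = None) -> RegulatoryNetwork:
    """Rebuild a network from an association table plus an optional edge list.

    The edge list restores E_T (role == TF); E_G always comes from the
    association table.
    """
    net = build_enhancer_gene_network(read_association_table(assoc_path))
    if edges_path is not None:
        edges = pd.read_csv(edges_path, sep="\t")
        tf_edges = edges[edges["role"] == "TF"]
        by_enh: dict[str, set[str]] = {}
        for row in tf_edges.itertuples():
            by_enh.setdefault(str(row.enhancer_id), set()).add(str(row.partner))
        net = RegulatoryNetwork(
            enhancers=[
                replace(e, binding_tfs=frozenset(by_enh.get(e.enhancer_id, set())))
                for e in net.enhancers
            ]
        )
    return net
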