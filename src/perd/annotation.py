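"""Annotate drug-responsive enhancers with motifs, perturbed genes, and variants.

The evidence chain for a diffEnhancer links three observations: TF motif
sites overlapping its interval, target genes that are also drug-perturbed,
and significant regulatory variants (eQTLs) located inside it.  A variant is
"consistent" when its associated gene is both a target gene of the enhancer
and a drug-perturbed gene — the strongest candidate for a variant that
modulates drug response through that enhancer.

Variants whose associated gene matches a perturbed target gene but whose
position falls outside every enhancer (e.g. gene-body pharmacogenomic
variants) are reported in a separate gene-linked tier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .genomic_io import GenomicInterval, VariantRecord, bulk_overlap, point_in_interval
from .networks import RegulatoryNetwork

Q_THRESHOLD = 0.05


@dataclass
class AnnotationRecord:
    enhancer_id: str
    motif_hits: int
    motif_names: list[str]
    concordant_genes: set[str]
    variants_in: list[VariantRecord]
    consistent_variants: list[VariantRecord]


def annotate_motifs(
    diff_enhancers: Sequence[tuple[str, GenomicInterval]],
    motif_sites: Sequence[tuple[GenomicInterval, str]],
) -> dict[str, tuple[int, list[str]]]:
    """Count motif-site intervals overlapping each diffEnhancer.

    Every enhancer appears in the output, with count 0 when nothing overlaps.
    """
    enh_ivs = [iv for _, iv in diff_enhancers]
    site_ivs = [iv for iv, _ in motif_sites]
    hits: dict[str, list[str]] = {eid: [] for eid, _ in diff_enhancers}
    for ei, si in bulk_overlap(enh_ivs, site_ivs):
        hits[diff_enhancers[ei][0]].append(motif_sites[si][1])
    return {eid: (len(names), names) for eid, names in hits.items()}


def concordant_perturbed_genes(
    diff_enhancer_ids: Iterable[str],
    network: RegulatoryNetwork,
    perturbed_genes: set[str],
) -> dict[str, set[str]]:
    """Per-enhancer intersection of target genes with the drug-perturbed set."""
    out: dict[str, set[str]] = {}
    for eid in diff_enhancer_ids:
        out[eid] = set(network.get(eid).target_genes) & perturbed_genes
    return out


def variants_in_enhancers(
    diff_enhancers: Sequence[tuple[str, GenomicInterval]],
    variants: Sequence[VariantRecord],
    q_threshold: float = Q_THRESHOLD,
) -> dict[str, list[VariantRecord]]:
    """Significant variants (q strictly below threshold) located inside each enhancer."""
    passing = [v for v in variants if v.qvalue < q_threshold]
    out: dict[str, list[VariantRecord]] = {eid: [] for eid, _ in diff_enhancers}
    for eid, iv in diff_enhancers:
        out[eid] = [v for v in passing if point_in_interval(v.chrom, v.pos, iv)]
    return out


def build_evidence_chain(
    diff_enhancers: Sequence[tuple[str, GenomicInterval]],
    network: RegulatoryNetwork,
    perturbed_genes: set[str],
    variants: Sequence[VariantRecord],
    motif_sites: Sequence[tuple[GenomicInterval, str]] = (),
    q_threshold: float = Q_THRESHOLD,
) -> tuple[list[AnnotationRecord], dict]:
    """Full annotation per diffEnhancer plus drug-level summary counts.

    The summary reports how many diffEnhancers carry at least one motif hit,
    at least one concordant (perturbed) target gene, at least one in-enhancer
    variant, and at least one consistent variant, together with the
    gene-linked tier of variants outside all enhancers whose gene is a
    perturbed target gene of some diffEnhancer.
    """
    ids = [eid for eid, _ in diff_enhancers]
    motifs = annotate_motifs(diff_enhancers, motif_sites)
    concordant = concordant_perturbed_genes(ids, network, perturbed_genes)
    in_enh = variants_in_enhancers(diff_enhancers, variants, q_threshold)

    records: list[AnnotationRecord] = []
    for eid, iv in diff_enhancers:
        genes = concordant[eid]
        vin = in_enh[eid]
        consistent = [v for v in vin if v.gene in genes]
        count, names = motifs[eid]
        records.append(
            AnnotationRecord(
                enhancer_id=eid,
                motif_hits=count,
                motif_names=sorted(names),
                concordant_genes=genes,
                variants_in=vin,
                consistent_variants=consistent,
            )
        )

    # gene-linked tier: significant variants outside all enhancers matching a
    # perturbed target gene of some diffEnhancer (gene-body PGx variants)
    all_in = {v.id for vs in in_enh.values() for v in vs}
    linked_genes = {g for r in records for g in r.concordant_genes}
    gene_linked = [
        v
        for v in variants
        if v.qvalue < q_threshold and v.id not in all_in and v.gene in linked_genes
    ]

    summary = {
        "n_diff_enhancers": len(records),
        "n_with_motif": sum(1 for r in records if r.motif_hits > 0),
        "n_with_concordant_gene": sum(1 for r in records if r.concordant_genes),
        "n_with_variant_in": sum(1 for r in records if r.variants_in),
        "n_with_consistent_variant": sum(1 for r in records if r.consistent_variants),
        "n_gene_linked_variants": len(gene_linked),
        "gene_linked_variant_ids": sorted(v.id for v in gene_linked),
    }
    return records, summary


def records_to_frame(records: list[AnnotationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "enhancer_id": r.enhancer_id,
                "motif_count": r.motif_hits,
                "concordant_genes": ",".join(sorted(r.concordant_genes)),
                "variant_ids": ",".join(v.id for v in r.variants_in),
                "consistent_variant_ids": ",".join(v.id for v in r.consistent_variants),
            }
            for r in records
        ]
    )
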