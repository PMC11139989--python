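"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the structure of the real inputs — a prior network of
enhancers with target genes and binding TFs, paired expression/openness
training data across cell types, drug-perturbation expression profiles for
one cell line, and an eQTL-style variant table — while planting the exact
quantities the pipeline is supposed to recover:

* per-enhancer linear openness models (coefficients, intercept, noise sd),
* per-drug responsive enhancer sets and perturbed gene sets,
* consistent variant-gene-enhancer triples.

Expression lives on a log2-like scale (cell-type means ~ Uniform(2, 10),
within-type Gaussian noise), so the default model preprocessing is a
near-no-op.  Openness is the planted linear combination of the enhancer's
standardized TF/TG expression plus truncated Gaussian noise; the intercept
is shifted per enhancer so the noise-free signal stays positive, keeping
openness on a DNase-hypersensitivity-like nonnegative scale.

Target-gene sets are sampled disjointly across enhancers (each gene drives
at most one enhancer) so that a planted drug effect propagates to exactly
the designated responsive enhancers; TFs are shared freely, as in real
regulatory networks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .genomic_io import GenomicInterval, SampleMetadata, VariantRecord
from .networks import EnhancerRecord, RegulatoryNetwork

WITHIN_TYPE_NOISE_SD = 1.0  # expression noise around each cell-type mean
TYPE_MEAN_LOW, TYPE_MEAN_HIGH = 2.0, 10.0
COEF_LOW, COEF_HIGH = 0.5, 1.5
OPENNESS_FLOOR = 0.5  # noise-free planted openness stays above this


@dataclass
class GroundTruth:
    """Everything needed to score the pipeline without re-reading generator internals."""

    coefficients: dict[str, dict[str, float]] = field(default_factory=dict)
    intercepts: dict[str, float] = field(default_factory=dict)
    feature_means: dict[str, float] = field(default_factory=dict)
    feature_sds: dict[str, float] = field(default_factory=dict)
    noise_sd: dict[str, float] = field(default_factory=dict)  # absolute, per enhancer
    pre_truncation_openness: Optional[pd.DataFrame] = None
    cell_types: dict[str, str] = field(default_factory=dict)
    responsive: dict[str, set[str]] = field(default_factory=dict)  # drug -> enhancer ids
    perturbed_genes: dict[str, dict[str, float]] = field(default_factory=dict)  # drug -> gene -> shift
    planted_triples: dict[str, list[tuple[str, str, str]]] = field(default_factory=dict)
    # drug -> [(variant_id, gene, enhancer_id)]

    def planted_signal_sd(self, enhancer_id: str) -> float:
        """Cross-cell sd of the planted linear signal (standardized features)."""
        coefs = self.coefficients[enhancer_id]
        return float(np.sqrt(sum(c * c for c in coefs.values())))

    def within_type_openness_sd(self, enhancer_id: str) -> float:
        """Openness sd driven by within-cell-type expression noise alone."""
        coefs = self.coefficients[enhancer_id]
        return float(
            np.sqrt(
                sum(
                    (c * WITHIN_TYPE_NOISE_SD / self.feature_sds[f]) ** 2
                    for f, c in coefs.items()
                )
            )
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "coefficients": self.coefficients,
            "intercepts": self.intercepts,
            "feature_means": self.feature_means,
            "feature_sds": self.feature_sds,
            "noise_sd": self.noise_sd,
            "cell_types": self.cell_types,
            "responsive": {d: sorted(s) for d, s in self.responsive.items()},
            "perturbed_genes": self.perturbed_genes,
            "planted_triples": self.planted_triples,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            coefficients=payload["coefficients"],
            intercepts=payload["intercepts"],
            feature_means=payload["feature_means"],
            feature_sds=payload["feature_sds"],
            noise_sd=payload["noise_sd"],
            cell_types=payload["cell_types"],
            responsive={d: set(v) for d, v in payload["responsive"].items()},
            perturbed_genes=payload["perturbed_genes"],
            planted_triples={
                d: [tuple(t) for t in v] for d, v in payload["planted_triples"].items()
            },
        )


# ---------------------------------------------------------------------------
# network


def generate_network(
    n_enhancers: int = 100,
    n_genes: int = 400,
    n_tfs: int = 30,
    genes_per_enhancer: int = 3,
    tfs_per_enhancer: int = 3,
    genome_length: int = 10_000_000,
    seed: int = 0,
) -> tuple[RegulatoryNetwork, list[tuple[GenomicInterval, str]]]:
    """A toy single-chromosome regulatory network plus TF binding-site intervals.

    Enhancers are non-overlapping intervals of 2-20 kb on "chrS".  Each
    enhancer draws ``genes_per_enhancer`` target genes from a globally
    disjoint pool and ``tfs_per_enhancer`` TFs (shared across enhancers); one
    binding site per (enhancer, TF) pair is placed inside the enhancer so
    rebuilding E_T from the sites reproduces the network exactly.
    """
    if genes_per_enhancer < 2 or tfs_per_enhancer < 2:
        raise ValueError("genes_per_enhancer and tfs_per_enhancer must be >= 2")
    if n_enhancers * genes_per_enhancer > n_genes:
        raise ValueError(
            f"need {n_enhancers * genes_per_enhancer} genes for disjoint target sets, "
            f"have {n_genes}"
        )
    rng = np.random.default_rng(seed)

    lengths = rng.integers(2_000, 20_000, size=n_enhancers)
    gaps = rng.integers(1_000, 50_000, size=n_enhancers)
    total = int(lengths.sum() + gaps.sum())
    if total > genome_length:
        raise ValueError(
            f"cannot pack {n_enhancers} enhancers into genome of length {genome_length}"
        )
    starts = np.cumsum(gaps) + np.concatenate([[0], np.cumsum(lengths)[:-1]])

    genes = [f"G{i:04d}" for i in range(n_genes)]
    tfs = [f"TF{i:03d}" for i in range(n_tfs)]
    gene_order = rng.permutation(n_genes)

    enhancers: list[EnhancerRecord] = []
    tf_sites: list[tuple[GenomicInterval, str]] = []
    for m in range(n_enhancers):
        eid = f"ENH{m:04d}"
        iv = GenomicInterval("chrS", int(starts[m]), int(starts[m] + lengths[m]))
        idx = gene_order[m * genes_per_enhancer : (m + 1) * genes_per_enhancer]
        e_genes = frozenset(genes[i] for i in idx)
        e_tfs = frozenset(rng.choice(tfs, size=tfs_per_enhancer, replace=False))
        enhancers.append(
            EnhancerRecord(enhancer_id=eid, interval=iv, target_genes=e_genes, binding_tfs=e_tfs)
        )
        for tf in sorted(e_tfs):
            site_len = int(rng.integers(10, 30))
            offset = int(rng.integers(0, len(iv) - site_len))
            tf_sites.append(
                (GenomicInterval("chrS", iv.start + offset, iv.start + offset + site_len), tf)
            )
    return RegulatoryNetwork(enhancers=enhancers), tf_sites


# ---------------------------------------------------------------------------
# paired training data


def _block_expression(
    features: list[str],
    type_means: pd.DataFrame,
    sample_types: list[str],
    sample_ids: list[str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw features x samples expression from the cell-type block model."""
    means = type_means.loc[features, sample_types].to_numpy()
    noise = rng.normal(0.0, WITHIN_TYPE_NOISE_SD, size=means.shape)
    return pd.DataFrame(means + noise, index=features, columns=sample_ids)


def generate_paired_training(
    network: RegulatoryNetwork,
    n_cells: int = 120,
    n_cell_types: int = 12,
    noise_sd: float = 0.1,
    seed: int = 0,
    relative_noise: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str], GroundTruth]:
    """Paired expression and openness matrices across cell types.

    Openness of enhancer m in cell n is

        O_nm = b0_m + sum_f coef_mf * z_nf + eps,   eps ~ N(0, sigma_m),

    where z are expression values standardized by the training-cohort
    feature means/sds and b0_m is shifted so the noise-free signal stays
    above ``OPENNESS_FLOOR``.  With ``relative_noise`` (default) sigma_m =
    noise_sd x the planted signal sd of that enhancer; otherwise sigma_m =
    noise_sd absolutely.  Negative noisy values are truncated at 0; the
    pre-truncation matrix is kept in the returned GroundTruth.
    """
    if n_cells < 3:
        raise ValueError("need at least 3 cells")
    rng = np.random.default_rng(seed)

    features = sorted(network.gene_universe | network.tf_universe)
    type_names = [f"type{t:02d}" for t in range(n_cell_types)]
    type_means = pd.DataFrame(
        rng.uniform(TYPE_MEAN_LOW, TYPE_MEAN_HIGH, size=(len(features), n_cell_types)),
        index=features,
        columns=type_names,
    )
    sample_ids = [f"cell{n:03d}" for n in range(n_cells)]
    sample_types = [type_names[n % n_cell_types] for n in range(n_cells)]
    expr = _block_expression(features, type_means, sample_types, sample_ids, rng)

    feat_means = expr.mean(axis=1)
    feat_sds = expr.std(axis=1, ddof=0).replace(0.0, 1.0)
    z = expr.sub(feat_means, axis=0).div(feat_sds, axis=0)

    truth = GroundTruth(
        feature_means={f: float(feat_means[f]) for f in features},
        feature_sds={f: float(feat_sds[f]) for f in features},
        cell_types=dict(zip(sample_ids, sample_types)),
    )

    rows_pre: dict[str, np.ndarray] = {}
    rows_noisy: dict[str, np.ndarray] = {}
    for enh in network.enhancers:
        feats = sorted(enh.binding_tfs) + sorted(enh.target_genes)
        coefs = rng.uniform(COEF_LOW, COEF_HIGH, size=len(feats)) * rng.choice(
            [-1.0, 1.0], size=len(feats)
        )
        signal = z.loc[feats].to_numpy().T @ coefs  # per sample
        b0 = float(rng.uniform(4.0, 8.0))
        b0 = max(b0, OPENNESS_FLOOR - float(signal.min()))
        pre = b0 + signal
        truth.coefficients[enh.enhancer_id] = dict(zip(feats, coefs.tolist()))
        truth.intercepts[enh.enhancer_id] = b0
        sigma = noise_sd * float(np.sqrt((coefs**2).sum())) if relative_noise else noise_sd
        truth.noise_sd[enh.enhancer_id] = sigma
        noisy = pre + rng.normal(0.0, sigma, size=pre.shape) if sigma > 0 else pre.copy()
        rows_pre[enh.enhancer_id] = pre
        rows_noisy[enh.enhancer_id] = np.clip(noisy, 0.0, None)

    enh_ids = [e.enhancer_id for e in network.enhancers]
    truth.pre_truncation_openness = pd.DataFrame(rows_pre, index=sample_ids).T.loc[enh_ids]
    openness = pd.DataFrame(rows_noisy, index=sample_ids).T.loc[enh_ids]
    return expr, openness, dict(zip(sample_ids, sample_types)), truth


# ---------------------------------------------------------------------------
# perturbation data


def generate_perturbation(
    network: RegulatoryNetwork,
    truth: GroundTruth,
    drug_name: str = "drugA",
    n_control: int = 20,
    n_treated: int = 20,
    effect_size: float = 2.0,
    frac_responsive: float = 0.3,
    seed: int = 0,
    cell_line: str = "CL1",
) -> tuple[pd.DataFrame, pd.DataFrame, list[SampleMetadata], GroundTruth]:
    """Control/treated expression for one (drug, cell line) block.

    ``round(frac_responsive * n_enhancers)`` enhancers are designated
    responsive.  Each of their target genes is shifted in treated samples in
    the direction of its planted coefficient, scaled so the enhancer's
    planted openness moves by ``effect_size`` times its within-cell-line
    openness noise sd.  Shifted genes are recorded as the drug's planted
    perturbed gene set; all other genes are untouched.  The truth object is
    updated in place and returned.
    """
    if not (0.0 < frac_responsive < 1.0):
        raise ValueError("frac_responsive must be in (0, 1)")
    if not truth.coefficients:
        raise ValueError("truth lacks planted coefficients; run generate_paired_training first")
    rng = np.random.default_rng(seed)

    features = sorted(network.gene_universe | network.tf_universe)
    line_means = pd.DataFrame(
        {cell_line: rng.uniform(TYPE_MEAN_LOW, TYPE_MEAN_HIGH, size=len(features))},
        index=features,
    )
    ctrl_ids = [f"{drug_name}_ctl{n:02d}" for n in range(n_control)]
    trt_ids = [f"{drug_name}_trt{n:02d}" for n in range(n_treated)]
    expr_control = _block_expression(features, line_means, [cell_line] * n_control, ctrl_ids, rng)
    expr_treated = _block_expression(features, line_means, [cell_line] * n_treated, trt_ids, rng)

    enh_ids = [e.enhancer_id for e in network.enhancers]
    n_responsive = round(frac_responsive * len(enh_ids))
    responsive = sorted(rng.choice(enh_ids, size=n_responsive, replace=False))

    perturbed: dict[str, float] = {}
    for eid in responsive:
        enh = network.get(eid)
        coefs = truth.coefficients[eid]
        tgs = sorted(enh.target_genes)
        sigma_line = truth.within_type_openness_sd(eid)
        # per-unit expression shift of each TG moves openness by |coef|/feature_sd
        leverage = sum(abs(coefs[g]) / truth.feature_sds[g] for g in tgs)
        delta = effect_size * sigma_line / leverage
        if delta == 0.0:
            continue  # a zero effect perturbs nothing
        for g in tgs:
            shift = delta * np.sign(coefs[g])
            expr_treated.loc[g] = expr_treated.loc[g] + shift
            perturbed[g] = float(shift)

    meta = [
        SampleMetadata(sample_id=s, cell_line=cell_line, drug=None, condition="control")
        for s in ctrl_ids
    ] + [
        SampleMetadata(sample_id=s, cell_line=cell_line, drug=drug_name, condition="treated")
        for s in trt_ids
    ]
    truth.responsive[drug_name] = set(responsive)
    truth.perturbed_genes[drug_name] = perturbed
    return expr_control, expr_treated, meta, truth


# ---------------------------------------------------------------------------
# variants


def generate_variant_table(
    network: RegulatoryNetwork,
    truth: GroundTruth,
    n_decoys: int = 60,
    seed: int = 0,
    drug_name: Optional[str] = None,
) -> list[VariantRecord]:
    """An eQTL-style variant table with one consistent variant per responsive enhancer.

    Each responsive enhancer gets a variant inside its interval whose
    associated gene is one of its perturbed target genes, with q < 0.05.
    Decoys come in three kinds, cycled: outside every enhancer, inside an
    enhancer but with a non-perturbed gene, and non-significant (q >= 0.05).
    Planted (variant, gene, enhancer) triples are recorded in the truth.
    """
    rng = np.random.default_rng(seed)
    if drug_name is None:
        if len(truth.responsive) != 1:
            raise ValueError("drug_name required when truth holds multiple drugs")
        drug_name = next(iter(truth.responsive))
    responsive = sorted(truth.responsive[drug_name])
    perturbed = set(truth.perturbed_genes[drug_name])
    all_genes = sorted(network.gene_universe)
    non_perturbed = [g for g in all_genes if g not in perturbed]

    by_id = {e.enhancer_id: e for e in network.enhancers}
    intervals = [e.interval for e in network.enhancers]
    genome_end = max(iv.end for iv in intervals) + 100_000

    variants: list[VariantRecord] = []
    triples: list[tuple[str, str, str]] = []
    k = 0
    for eid in responsive:
        enh = by_id[eid]
        genes = sorted(set(enh.target_genes) & perturbed)
        if not genes:
            continue
        gene = genes[int(rng.integers(0, len(genes)))]
        pos = int(rng.integers(enh.interval.start + 1, enh.interval.end + 1))
        vid = f"rsP{k:04d}"
        variants.append(
            VariantRecord(
                id=vid, chrom=enh.interval.chrom, pos=pos, gene=gene,
                qvalue=float(rng.uniform(0.001, 0.045)),
            )
        )
        triples.append((vid, gene, eid))
        k += 1

    def outside_position() -> int:
        while True:
            pos = int(rng.integers(1, genome_end))
            if not any(iv.start < pos <= iv.end for iv in intervals):
                return pos

    for j in range(n_decoys):
        kind = j % 3
        if kind == 0:  # outside any enhancer, significant
            variants.append(
                VariantRecord(
                    id=f"rsD{j:04d}", chrom="chrS", pos=outside_position(),
                    gene=all_genes[int(rng.integers(0, len(all_genes)))],
                    qvalue=float(rng.uniform(0.001, 0.045)),
                )
            )
        elif kind == 1:  # inside a random enhancer, but a non-perturbed gene
            enh = network.enhancers[int(rng.integers(0, len(network.enhancers)))]
            pos = int(rng.integers(enh.interval.start + 1, enh.interval.end + 1))
            variants.append(
                VariantRecord(
                    id=f"rsD{j:04d}", chrom=enh.interval.chrom, pos=pos,
                    gene=non_perturbed[int(rng.integers(0, len(non_perturbed)))],
                    qvalue=float(rng.uniform(0.001, 0.045)),
                )
            )
        else:  # non-significant
            enh = network.enhancers[int(rng.integers(0, len(network.enhancers)))]
            pos = int(rng.integers(enh.interval.start + 1, enh.interval.end + 1))
            gene = sorted(enh.target_genes)[0]
            variants.append(
                VariantRecord(
                    id=f"rsD{j:04d}", chrom=enh.interval.chrom, pos=pos, gene=gene,
                    qvalue=float(rng.uniform(0.05, 0.9)),
                )
            )

    truth.planted_triples[drug_name] = triples
    return variants
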