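"""Synthetic study generator with planted ground truth.

Emulates the data shapes the pipeline consumes — a genome panel with
orthogroup membership, a focal-genome annotation, NB-distributed count
matrices, a COG map and a qPCR Ct table — while planting operons whose
member genes are, by construction, identically inherited across the panel,
contiguous on the same strand within the proximity window, and regulated
with a common fold-change sign.  Every downstream stage can therefore be
scored against known truth without any external download.

Defaults reflect a desk-scale version of the study design this emulates:
a panel of 40 genomes (163 is a supported setting), 500 focal genes,
12 planted operons of 2-6 genes, |log2 fold change| 2, NB dispersion 0.1,
and triplicate libraries per condition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .de import CountMatrix, CONTROL, TREATED
from .profiles import GenomePanel, write_orthogroups

__all__ = [
    "SimConfig",
    "GroundTruth",
    "generate_pangenome",
    "generate_annotation",
    "generate_counts",
    "generate_qpcr",
    "generate_cog_map",
    "generate_study",
]

COG_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic generator.

    Units: lengths in bp, expression in expected read counts, fold changes
    on the log2 scale, Ct noise in cycles.
    """

    n_genomes: int = 40
    n_focal_genes: int = 500
    n_planted_operons: int = 12
    operon_size_range: tuple[int, int] = (2, 6)
    planted_log2fc: float = 2.0  # magnitude; sign drawn per operon
    nb_dispersion: float = 0.1
    mean_expression: float = 200.0
    n_replicates: int = 3
    intergenic_gap_bp: int = 200
    gene_length_bp: int = 900
    profile_noise_flips: int = 0
    ct_noise_sd: float = 0.15
    qpcr_efficiency: float = 2.0
    focal_genome: str = "focal"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genomes", "n_focal_genes", "n_planted_operons",
                     "n_replicates", "intergenic_gap_bp", "gene_length_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.operon_size_range
        if lo < 2 or hi < lo:
            raise ValueError("operon_size_range must satisfy 2 <= min <= max")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.mean_expression <= 0:
            raise ValueError("mean_expression must be positive")
        if self.profile_noise_flips < 0:
            raise ValueError("profile_noise_flips must be >= 0")
        if self.intergenic_gap_bp > 10_000:
            raise ValueError(
                "intergenic_gap_bp must keep consecutive operon genes within "
                "the 10,000 bp proximity window"
            )
        # worst case: n_operons * max_size operon genes plus separators
        if self.n_planted_operons * hi + self.n_planted_operons + 1 > self.n_focal_genes:
            raise ValueError(
                "n_focal_genes too small for the requested operons plus "
                "background separators"
            )

    def rng(self, stream: int) -> np.random.Generator:
        """Independent, reproducible generator per output stream."""
        return np.random.default_rng([self.rng_seed, stream])


@dataclass
class GroundTruth:
    """Planted truth: operon membership and true per-gene log2 fold change."""

    operon_membership: dict[str, str | None]
    gene_log2fc_true: dict[str, float]
    operon_genes: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.operon_genes:
            ops: dict[str, list[str]] = {}
            for gene, op in self.operon_membership.items():
                if op is not None:
                    ops.setdefault(op, []).append(gene)
            self.operon_genes = ops
        for op, genes in self.operon_genes.items():
            if len(genes) < 2:
                raise ValueError(f"planted operon {op} has < 2 members")
            signs = {np.sign(self.gene_log2fc_true[g]) for g in genes}
            if len(signs) != 1:
                raise ValueError(f"planted operon {op} mixes fold-change signs")

    def to_json(self, path) -> None:
        with open(path, "wt") as fh:
            json.dump(
                {
                    "operon_membership": self.operon_membership,
                    "gene_log2fc_true": self.gene_log2fc_true,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path, "rt") as fh:
            d = json.load(fh)
        return cls(d["operon_membership"], d["gene_log2fc_true"])


def _gene_ids(cfg: SimConfig) -> list[str]:
    width = len(str(cfg.n_focal_genes))
    return [f"gene_{i + 1:0{width}d}" for i in range(cfg.n_focal_genes)]


def _plan_layout(cfg: SimConfig, rng: np.random.Generator) -> dict[str, str | None]:
    """Assign genes (in genomic order) to planted operons or background.

    Operon blocks are consecutive runs of gene indices; at least one
    background gene separates successive blocks (and pads both ends where
    the budget allows).
    """
    lo, hi = cfg.operon_size_range
    sizes = rng.integers(lo, hi + 1, size=cfg.n_planted_operons)
    n_bg = cfg.n_focal_genes - int(sizes.sum())
    k = cfg.n_planted_operons
    # k+1 gaps; interior gaps need >= 1 background gene
    gaps = np.ones(k + 1, dtype=int)
    gaps[0] = gaps[-1] = 0
    spare = n_bg - gaps.sum()
    if spare < 0:
        raise ValueError("not enough background genes to separate planted operons")
    gaps += rng.multinomial(spare, np.full(k + 1, 1.0 / (k + 1)))

    genes = _gene_ids(cfg)
    membership: dict[str, str | None] = {}
    pos = 0
    for i in range(k):
        for _ in range(gaps[i]):
            membership[genes[pos]] = None
            pos += 1
        op_id = f"planted_{i + 1:02d}"
        for _ in range(sizes[i]):
            membership[genes[pos]] = op_id
            pos += 1
    for _ in range(gaps[k]):
        membership[genes[pos]] = None
        pos += 1
    assert pos == cfg.n_focal_genes
    return membership


def generate_pangenome(
    cfg: SimConfig,
) -> tuple[dict[str, dict[str, set[str]]], GenomePanel, GroundTruth]:
    """Panel + orthogroup table with planted identically-inherited groups.

    One orthogroup per focal gene.  Genes of one planted operon share a
    single presence/absence pattern over the panel (before optional noise
    flips); background genes get independent Bernoulli(0.5) patterns.  The
    focal genome carries every orthogroup.
    """
    rng = cfg.rng(1)
    width = len(str(cfg.n_genomes))
    others = [f"genome_{i + 1:0{width}d}" for i in range(cfg.n_genomes - 1)]
    panel = GenomePanel((cfg.focal_genome, *others))

    membership = _plan_layout(cfg, rng)
    genes = _gene_ids(cfg)

    # one shared pattern per operon, independent per background gene
    op_ids = sorted({m for m in membership.values() if m is not None})
    op_pattern = {
        op: rng.integers(0, 2, size=len(others)) for op in op_ids
    }
    sign = {op: (1.0 if rng.random() < 0.5 else -1.0) for op in op_ids}

    table: dict[str, dict[str, set[str]]] = {}
    lfc_true: dict[str, float] = {}
    for idx, gene in enumerate(genes):
        op = membership[gene]
        if op is None:
            pattern = rng.integers(0, 2, size=len(others))
            lfc_true[gene] = 0.0
        else:
            pattern = op_pattern[op].copy()
            if cfg.profile_noise_flips:
                flip = rng.choice(len(others), size=cfg.profile_noise_flips,
                                  replace=False)
                pattern[flip] = 1 - pattern[flip]
            lfc_true[gene] = sign[op] * cfg.planted_log2fc
        og = f"OG{idx + 1:07d}"
        row: dict[str, set[str]] = {cfg.focal_genome: {gene}}
        for g, present in zip(others, pattern):
            row[g] = {f"{g}|{og}"} if present else set()
        table[og] = row

    truth = GroundTruth(membership, lfc_true)
    return table, panel, truth


def generate_annotation(cfg: SimConfig, truth: GroundTruth):
    """Single-contig GFF3 layout honouring the planted operon structure.

    Genes are placed left-to-right in gene-ID order with the configured
    length and inter-gene gap, so consecutive planted-operon genes sit well
    inside the proximity window.  Each planted operon gets one random
    strand shared by all members; background genes get independent strands.
    """
    from .operons import GeneFeature

    rng = cfg.rng(2)
    op_strand = {
        op: ("+" if rng.random() < 0.5 else "-") for op in sorted(truth.operon_genes)
    }
    feats = []
    pos = 1
    for gene in sorted(truth.operon_membership):
        op = truth.operon_membership[gene]
        strand = op_strand[op] if op else ("+" if rng.random() < 0.5 else "-")
        start, end = pos, pos + cfg.gene_length_bp - 1
        feats.append(GeneFeature(gene, "contig_1", start, end, strand))
        pos = end + 1 + cfg.intergenic_gap_bp
    return feats


def generate_counts(cfg: SimConfig, truth: GroundTruth) -> CountMatrix:
    """NB count matrix: control at a per-gene baseline, treated shifted by
    the planted log2 fold change.

    Baselines are log-normal around ``mean_expression`` (sdlog 0.5);
    dispersion 0 yields Poisson marginals.
    """
    rng = cfg.rng(3)
    genes = sorted(truth.operon_membership)
    n = cfg.n_replicates
    samples = [f"{CONTROL}_{i + 1}" for i in range(n)] + [
        f"{TREATED}_{i + 1}" for i in range(n)
    ]
    base = np.exp(rng.normal(np.log(cfg.mean_expression), 0.5, size=len(genes)))
    lfc = np.array([truth.gene_log2fc_true[g] for g in genes])
    mu = np.empty((len(genes), 2 * n))
    mu[:, :n] = base[:, None]
    mu[:, n:] = (base * 2.0 ** lfc)[:, None]

    if cfg.nb_dispersion <= 0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / cfg.nb_dispersion
        p = r / (r + mu)
        counts = rng.negative_binomial(r, p)

    df = pd.DataFrame(counts.astype(np.int64), index=genes, columns=samples)
    condition = {s: (CONTROL if s.startswith(CONTROL) else TREATED) for s in samples}
    return CountMatrix(df, condition)


def generate_qpcr(
    cfg: SimConfig,
    truth: GroundTruth,
    control_genes: list[str],
    target_genes: list[str] | None = None,
    *,
    noise_sd: float | None = None,
) -> pd.DataFrame:
    """Ct table for target + control genes under the standard Ct model.

    Ct = baseline - log_E(relative expression) + Gaussian noise, with
    amplification efficiency E per gene (default 2: one cycle per doubling).
    Control genes must be planted at true log2 fold change 0.
    """
    rng = cfg.rng(4)
    sd = cfg.ct_noise_sd if noise_sd is None else noise_sd
    for g in control_genes:
        if truth.gene_log2fc_true.get(g, 0.0) != 0.0:
            raise ValueError(f"control gene {g} has nonzero true fold change")
    if target_genes is None:
        de_genes = [g for g in sorted(truth.gene_log2fc_true)
                    if truth.gene_log2fc_true[g] != 0.0]
        target_genes = list(rng.choice(de_genes, size=min(5, len(de_genes)),
                                       replace=False))

    E = cfg.qpcr_efficiency
    rows = []
    for gene in [*target_genes, *control_genes]:
        base_ct = rng.uniform(18.0, 25.0)
        lfc = truth.gene_log2fc_true.get(gene, 0.0)
        for cond in (CONTROL, TREATED):
            shift = -lfc * np.log(2.0) / np.log(E) if cond == TREATED else 0.0
            for rep in range(cfg.n_replicates):
                ct = base_ct + shift + (rng.normal(0.0, sd) if sd > 0 else 0.0)
                rows.append(
                    {
                        "gene_id": gene,
                        "sample_id": f"{cond}_{rep + 1}",
                        "condition": cond,
                        "ct": round(float(ct), 6),
                        "efficiency": E,
                        "is_control": gene in control_genes,
                    }
                )
    return pd.DataFrame(rows)


def generate_cog_map(cfg: SimConfig, truth: GroundTruth) -> pd.DataFrame:
    """Random functional-category map: 1-2 COG letters per gene.

    Genes of one planted operon share a category (operons are functional
    units), background genes draw independently.
    """
    rng = cfg.rng(5)
    letters = np.array(list(COG_ALPHABET))
    op_letter = {
        op: str(rng.choice(letters)) for op in sorted(truth.operon_genes)
    }
    rows = []
    for gene in sorted(truth.operon_membership):
        op = truth.operon_membership[gene]
        if op is not None:
            cats = op_letter[op]
        else:
            k = 1 + int(rng.random() < 0.2)
            cats = "".join(rng.choice(letters, size=k, replace=False))
        rows.append({"gene_id": gene, "cog": cats})
    return pd.DataFrame(rows)


def generate_study(cfg: SimConfig, outdir) -> dict[str, str]:
    """Emit the full synthetic study to ``outdir``; returns emitted paths."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "orthogroups": os.path.join(outdir, "orthogroups.tsv"),
        "gff3": os.path.join(outdir, "genes.gff3"),
        "counts": os.path.join(outdir, "counts.tsv"),
        "conditions": os.path.join(outdir, "conditions.tsv"),
        "truth": os.path.join(outdir, "truth.json"),
        "qpcr": os.path.join(outdir, "qpcr.tsv"),
        "cog_map": os.path.join(outdir, "cog_map.tsv"),
    }
    from .operons import write_gff3

    table, panel, truth = generate_pangenome(cfg)
    write_orthogroups(table, panel, paths["orthogroups"])
    write_gff3(generate_annotation(cfg, truth), paths["gff3"])
    cm = generate_counts(cfg, truth)
    cm.write_tsv(paths["counts"], paths["conditions"])
    truth.to_json(paths["truth"])

    controls = [g for g, l in sorted(truth.gene_log2fc_true.items()) if l == 0.0][:2]
    generate_qpcr(cfg, truth, controls).to_csv(paths["qpcr"], sep="\t", index=False)
    generate_cog_map(cfg, truth).to_csv(paths["cog_map"], sep="\t", index=False)

    with open(os.path.join(outdir, "sim_config.json"), "wt") as fh:
        json.dump(asdict(cfg), fh, indent=2)
    return paths
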