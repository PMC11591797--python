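"""Binary phylogenetic profiles and Jaccard distances.

A phylogenetic profile records, for one gene of the focal strain, whether its
orthogroup has at least one member in each genome of a fixed panel.  Genes
whose profiles co-occur across the panel (small Jaccard distance between
their presence sets) are candidates for shared function — here, candidate
operon members.

Presence is binary: an orthogroup with several paralogs in a genome still
contributes a single 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenomePanel",
    "ProfileMatrix",
    "DistanceMatrix",
    "read_orthogroups",
    "build_profiles",
    "jaccard_distance",
    "distance_matrix",
]


@dataclass(frozen=True)
class GenomePanel:
    """Ordered panel of genome identifiers (the profile columns)."""

    genome_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genome_ids:
            raise ValueError("genome panel must be non-empty")
        if len(set(self.genome_ids)) != len(self.genome_ids):
            raise ValueError("genome panel contains duplicate identifiers")

    def __len__(self) -> int:
        return len(self.genome_ids)

    def index_of(self, genome_id: str) -> int:
        return self.genome_ids.index(genome_id)


@dataclass
class ProfileMatrix:
    """Presence/absence profiles for a set of genes over one genome panel.

    ``bits`` is a (genes x genomes) uint8 array of 0/1.
    """

    gene_ids: list[str]
    panel: GenomePanel
    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 2:
            raise ValueError("bits must be a 2-D array")
        if self.bits.shape != (len(self.gene_ids), len(self.panel)):
            raise ValueError(
                f"bits shape {self.bits.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.panel)} genomes"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene_ids in profile matrix")
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("profile entries must be 0 or 1")

    def profile(self, gene_id: str) -> np.ndarray:
        return self.bits[self.gene_ids.index(gene_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.bits, index=self.gene_ids, columns=list(self.panel.genome_ids)
        )

    def write_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise Jaccard distance matrix over gene profiles."""

    gene_ids: list[str]
    d: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.gene_ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match gene list")
        self._index = {g: i for i, g in enumerate(self.gene_ids)}
        if len(self._index) != n:
            raise ValueError("duplicate gene_ids in distance matrix")

    def distance(self, a: str, b: str) -> float:
        return float(self.d[self._index[a], self._index[b]])

    def subset(self, gene_ids: list[str]) -> "DistanceMatrix":
        idx = [self._index[g] for g in gene_ids]
        return DistanceMatrix(list(gene_ids), self.d[np.ix_(idx, idx)])

    def write_tsv(self, path) -> None:
        df = pd.DataFrame(self.d, index=self.gene_ids, columns=self.gene_ids)
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float))


def read_orthogroups(path) -> tuple[dict[str, dict[str, set[str]]], GenomePanel]:
    """Read an orthogroup membership table (OrthoFinder ``Orthogroups.tsv`` dialect).

    Column 1 names the orthogroup; every further column is a genome whose cell
    holds the comma-separated member gene IDs in that genome (empty = absent).

    Returns the mapping ``orthogroup -> genome -> set of gene IDs`` together
    with the genome panel in column order.
    """
    with open(path, "rt", newline="") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty orthogroups file (missing header)")
    header = lines[0].split("\t")
    if len(header) < 2:
        raise ValueError(f"{path}: header must name at least one genome column")
    genomes = header[1:]
    panel = GenomePanel(tuple(genomes))
    ncol = len(header)

    table: dict[str, dict[str, set[str]]] = {}
    seen_per_genome: dict[str, set[str]] = {g: set() for g in genomes}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != ncol:
            raise ValueError(
                f"{path}, line {lineno}: expected {ncol} columns, found {len(cells)}"
            )
        og = cells[0]
        if og in table:
            raise ValueError(f"{path}, line {lineno}: duplicate orthogroup ID {og!r}")
        row: dict[str, set[str]] = {}
        for genome, cell in zip(genomes, cells[1:]):
            genes = {g.strip() for g in cell.split(",") if g.strip()}
            dup = genes & seen_per_genome[genome]
            if dup:
                raise ValueError(
                    f"{path}, line {lineno}: gene ID(s) {sorted(dup)} appear more "
                    f"than once in genome column {genome!r}"
                )
            seen_per_genome[genome] |= genes
            row[genome] = genes
        table[og] = row
    return table, panel


def write_orthogroups(
    table: dict[str, dict[str, set[str]]], panel: GenomePanel, path
) -> None:
    """Serialize an orthogroup mapping back to the Orthogroups.tsv dialect."""
    with open(path, "wt", newline="\n") as fh:
        fh.write("Orthogroup\t" + "\t".join(panel.genome_ids) + "\n")
        for og in table:
            cells = [
                ", ".join(sorted(table[og].get(g, set()))) for g in panel.genome_ids
            ]
            fh.write(og + "\t" + "\t".join(cells) + "\n")


def build_profiles(
    orthogroups: dict[str, dict[str, set[str]]],
    panel: GenomePanel,
    focal_genome: str,
    *,
    exclude_focal_column: bool = False,
    extra_focal_genes: list[str] | None = None,
) -> ProfileMatrix:
    """Build one presence/absence profile per focal-genome gene.

    Bit g of a gene's profile is 1 iff the gene's orthogroup has at least one
    member in genome g.  All focal genes of one orthogroup share a profile.

    ``extra_focal_genes`` lists focal genes absent from every orthogroup; each
    receives a singleton profile (present only in the focal genome), keeping
    the gene universe aligned with the annotation and DE table.

    ``exclude_focal_column`` drops the focal genome's own column, which is
    constant 1 across focal genes and therefore shifts all similarities
    uniformly.
    """
    if focal_genome not in panel.genome_ids:
        raise ValueError(f"focal genome {focal_genome!r} not in panel")

    out_genomes = tuple(
        g for g in panel.genome_ids if not (exclude_focal_column and g == focal_genome)
    )
    out_panel = GenomePanel(out_genomes)

    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    for og, by_genome in orthogroups.items():
        focal_members = sorted(by_genome.get(focal_genome, set()))
        if not focal_members:
            continue
        bits = np.fromiter(
            (1 if by_genome.get(g) else 0 for g in out_genomes),
            dtype=np.uint8,
            count=len(out_genomes),
        )
        for gene in focal_members:
            gene_ids.append(gene)
            rows.append(bits)

    for gene in extra_focal_genes or []:
        if gene in gene_ids:
            continue
        logger.warning(
            "focal gene %s is in no orthogroup; assigning singleton profile", gene
        )
        bits = np.zeros(len(out_genomes), dtype=np.uint8)
        if not exclude_focal_column:
            bits[out_genomes.index(focal_genome)] = 1
        gene_ids.append(gene)
        rows.append(bits)

    if not gene_ids:
        raise ValueError(f"no genes of focal genome {focal_genome!r} in any orthogroup")
    return ProfileMatrix(gene_ids, out_panel, np.vstack(rows))


def jaccard_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard distance 1 - |A∩B| / |A∪B| between two binary profiles.

    Computed in exact integer arithmetic with a single final division, so
    comparisons against a cutoff are reproducible.  Two all-zero vectors are
    at distance 0 (the 0/0 case; cannot occur for focal genes, whose focal
    bit is always 1).
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"profile length mismatch: {a.shape} vs {b.shape}")
    inter = int(np.sum((a != 0) & (b != 0)))
    union = int(np.sum((a != 0) | (b != 0)))
    if union == 0:
        logger.warning("Jaccard distance of two all-zero profiles defined as 0")
        return 0.0
    return 1.0 - inter / union


def distance_matrix(profiles: ProfileMatrix) -> DistanceMatrix:
    """Full symmetric Jaccard distance matrix over all gene profiles.

    Intersections and unions are accumulated as integers (via a boolean
    Gram matrix) before the single division, matching :func:`jaccard_distance`
    exactly.
    """
    if len(profiles.gene_ids) < 2:
        raise ValueError("need at least two profiles")
    b = profiles.bits.astype(np.int64)
    inter = b @ b.T
    ones = b.sum(axis=1)
    union = ones[:, None] + ones[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - inter / union
    d[union == 0] = 0.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(profiles.gene_ids), d)
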