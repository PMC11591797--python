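"""Putative-operon inference from profiles, proximity and co-regulation.

Bacterial operons are runs of adjacent, same-strand genes transcribed as one
unit.  Because operon members are inherited together, their orthogroups tend
to co-occur across related genomes (near-identical phylogenetic profiles)
and they respond coordinately to a stimulus.  This module combines those
three signals: two genes may belong to one candidate operon only if

  (a) the Jaccard distance between their profiles is strictly below a cutoff
      (default 0.001 — with binary profiles over a panel of <= a few hundred
      genomes this effectively requires identical profiles, since the
      smallest nonzero Jaccard distance is ~1/n_genomes),
  (b) they sit on the same contig and strand,
  (c) the closest-edge gap between them is within a window (default 10 kb),
  (d) both are differentially expressed in the same direction.

Discovery is single-linkage chaining over the pairwise criterion, followed
by an all-pairs profile-distance verification of each group (with greedy
splitting when chaining alone would violate the cutoff).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from urllib.parse import unquote

import numpy as np

from .de import DERecord, DEThresholds
from .profiles import DistanceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GeneFeature",
    "OperonParams",
    "OperonCandidate",
    "read_gff3",
    "write_gff3",
    "infer_operons",
    "write_operons",
    "read_operons",
]


@dataclass(frozen=True)
class GeneFeature:
    """A focal-genome gene: contig, 1-based inclusive coordinates, strand."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"{self.gene_id}: invalid coordinates {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")

    def gap_to(self, other: "GeneFeature") -> int:
        """Closest-edge gap in bp (0 if the features touch or overlap)."""
        if self.contig != other.contig:
            raise ValueError("gap undefined across contigs")
        lo, hi = (self, other) if self.start <= other.start else (other, self)
        return max(0, hi.start - lo.end - 1)


@dataclass(frozen=True)
class OperonParams:
    """Grouping parameters for candidate-operon inference."""

    distance_cutoff: float = 0.001
    window_bp: int = 10_000
    de_thresholds: DEThresholds = field(default_factory=DEThresholds)
    require_direction_concordance: bool = True
    require_significance: bool = True
    proximity_all_pairs: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.distance_cutoff < 1:
            raise ValueError("distance_cutoff must lie in (0, 1)")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")


@dataclass
class OperonCandidate:
    """An inferred operon: >=2 genes in genomic order on one contig/strand."""

    operon_id: str
    member_genes: list[str]
    contig: str
    strand: str
    direction: str  # UP | DOWN
    max_internal_distance: float
    max_gap_bp: int

    def __post_init__(self) -> None:
        if len(self.member_genes) < 2:
            raise ValueError("operon candidate needs >= 2 members")


# ---------------------------------------------------------------------------
# GFF3 I/O
#
# Deliberately minimal: the method needs only `gene` features with an ID,
# strand and coordinates, and the error contract requires line-located
# messages for the fields the method depends on.

def read_gff3(path, *, feature_type: str = "gene") -> list[GeneFeature]:
    """Read gene features from a GFF3 file, sorted by (contig, start).

    Only rows of ``feature_type`` are kept.  Strand must be '+' or '-' (the
    method is strand-aware, so '.' is an error), coordinates 1-based
    inclusive with start <= end, and every feature needs an ID attribute.
    """
    feats: list[GeneFeature] = []
    seen: set[str] = set()
    with open(path, "rt", newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}, line {lineno}: expected 9 columns")
            contig, _src, ftype, start_s, end_s, _score, strand, _phase, attrs = cols
            if ftype != feature_type:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(f"{path}, line {lineno}: non-integer coordinates")
            if start < 1 or end < start:
                raise ValueError(
                    f"{path}, line {lineno}: invalid coordinates {start}..{end}"
                )
            if strand not in ("+", "-"):
                raise ValueError(
                    f"{path}, line {lineno}: strand {strand!r} (must be '+' or '-')"
                )
            gene_id = None
            for kv in attrs.split(";"):
                kv = kv.strip()
                if kv.startswith("ID="):
                    gene_id = unquote(kv[3:])
                    break
            if not gene_id:
                raise ValueError(f"{path}, line {lineno}: missing ID attribute")
            if gene_id in seen:
                raise ValueError(f"{path}, line {lineno}: duplicate ID {gene_id!r}")
            seen.add(gene_id)
            feats.append(GeneFeature(gene_id, contig, start, end, strand))
    feats.sort(key=lambda f: (f.contig, f.start))
    return feats


def write_gff3(features: list[GeneFeature], path, *, source: str = "ppoperon") -> None:
    with open(path, "wt", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        for f in sorted(features, key=lambda f: (f.contig, f.start)):
            fh.write(
                f"{f.contig}\t{source}\tgene\t{f.start}\t{f.end}\t.\t{f.strand}\t.\t"
                f"ID={f.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# Inference

def infer_operons(
    dm: DistanceMatrix,
    genes: list[GeneFeature],
    de: list[DERecord],
    params: OperonParams = OperonParams(),
) -> list[OperonCandidate]:
    """Group focal genes into candidate operons.

    Works on the intersection of the three gene universes (profile distance
    matrix, annotation, DE results); mismatches are logged and dropped.
    Only genes with a significant DE call participate (unless
    ``require_significance`` is off, in which case the sign of the fold
    change supplies the direction).  Candidates are connected components of
    the pairwise-criterion graph, then verified so that ALL member pairs
    respect the profile-distance cutoff; failing components are split by
    repeatedly removing the member with the largest mean internal distance.
    """
    feat_by_id = {f.gene_id: f for f in genes}
    de_by_id = {r.gene_id: r for r in de}

    dm_ids = set(dm.gene_ids)
    universe = dm_ids & set(feat_by_id) & set(de_by_id)
    for missing in sorted(dm_ids - universe):
        logger.debug("gene %s lacks annotation or DE record; excluded", missing)

    def direction_of(r: DERecord) -> str | None:
        if params.require_significance:
            return r.call if r.call in ("UP", "DOWN") else None
        if r.log2fc > 0:
            return "UP"
        if r.log2fc < 0:
            return "DOWN"
        return None

    nodes = []
    direction = {}
    for gid in universe:
        d = direction_of(de_by_id[gid])
        if d is not None:
            nodes.append(gid)
            direction[gid] = d
    nodes.sort(key=lambda g: (feat_by_id[g].contig, feat_by_id[g].start))
    if not nodes:
        return []

    def compatible(a: str, b: str) -> bool:
        fa, fb = feat_by_id[a], feat_by_id[b]
        if fa.contig != fb.contig or fa.strand != fb.strand:
            return False
        if fa.gap_to(fb) > params.window_bp:
            return False
        if dm.distance(a, b) >= params.distance_cutoff:
            return False
        if params.require_direction_concordance and direction[a] != direction[b]:
            return False
        return True

    # single-linkage components via union-find over compatible pairs
    parent = {g: g for g in nodes}

    def find(g):
        while parent[g] != g:
            parent[g] = parent[parent[g]]
            g = parent[g]
        return g

    for i, a in enumerate(nodes):
        fa = feat_by_id[a]
        for b in nodes[i + 1:]:
            fb = feat_by_id[b]
            if fb.contig != fa.contig:
                break  # nodes sorted by contig, start
            if fb.start - fa.end - 1 > params.window_bp:
                break  # no later gene on this contig can be within the window
            if compatible(a, b):
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra

    components: dict[str, list[str]] = {}
    for g in nodes:
        components.setdefault(find(g), []).append(g)

    candidates: list[OperonCandidate] = []
    for comp in components.values():
        if len(comp) < 2:
            continue
        candidates.extend(
            _verify_and_split(comp, dm, feat_by_id, direction, params)
        )

    candidates.sort(key=lambda c: (c.contig, feat_by_id[c.member_genes[0]].start))
    for i, c in enumerate(candidates, start=1):
        c.operon_id = f"OP{i:03d}"
    return candidates


def _verify_and_split(
    members: list[str],
    dm: DistanceMatrix,
    feat_by_id: dict[str, GeneFeature],
    direction: dict[str, str],
    params: OperonParams,
) -> list[OperonCandidate]:
    """All-pairs distance verification with greedy splitting.

    Chaining can connect genes whose mutual distance violates the cutoff
    (a-b and b-c close, a-c not).  While any pair fails, drop the member
    with the largest mean distance to the rest, then re-form components
    among the survivors (removal can disconnect the chain).
    """
    members = sorted(members, key=lambda g: feat_by_id[g].start)
    sub = dm.subset(members)
    n = len(members)
    mask = np.ones(n, dtype=bool)
    while mask.sum() >= 2:
        idx = np.where(mask)[0]
        d = sub.d[np.ix_(idx, idx)]
        if (d < params.distance_cutoff).all():
            break
        mean_d = d.mean(axis=1)
        worst = idx[int(np.argmax(mean_d))]
        mask[worst] = False
    kept = [members[i] for i in np.where(mask)[0]]
    if len(kept) < 2:
        return []

    # re-split on proximity/adjacency within the kept set
    out: list[OperonCandidate] = []
    runs: list[list[str]] = [[kept[0]]]
    for g in kept[1:]:
        prev = runs[-1][-1]
        if feat_by_id[prev].gap_to(feat_by_id[g]) <= params.window_bp:
            runs[-1].append(g)
        else:
            runs.append([g])
    for run in runs:
        if len(run) < 2:
            continue
        if params.proximity_all_pairs:
            ok = all(
                feat_by_id[a].gap_to(feat_by_id[b]) <= params.window_bp
                for i, a in enumerate(run)
                for b in run[i + 1:]
            )
            if not ok:
                continue
        sub_run = dm.subset(run)
        gaps = [
            feat_by_id[a].gap_to(feat_by_id[b]) for a, b in zip(run, run[1:])
        ]
        out.append(
            OperonCandidate(
                operon_id="",
                member_genes=run,
                contig=feat_by_id[run[0]].contig,
                strand=feat_by_id[run[0]].strand,
                direction=direction[run[0]],
                max_internal_distance=float(sub_run.d.max()),
                max_gap_bp=int(max(gaps)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Candidate I/O

_TSV_HEADER = (
    "operon_id\tgene_id\trank\tcontig\tstrand\tdirection\t"
    "max_internal_distance\tmax_gap_bp"
)


def write_operons(candidates: list[OperonCandidate], tsv_path, json_path=None) -> None:
    """Write candidates as a per-gene TSV plus an optional JSON mirror."""
    with open(tsv_path, "wt", newline="\n") as fh:
        fh.write(_TSV_HEADER + "\n")
        for c in candidates:
            for rank, gene in enumerate(c.member_genes, start=1):
                fh.write(
                    f"{c.operon_id}\t{gene}\t{rank}\t{c.contig}\t{c.strand}\t"
                    f"{c.direction}\t{c.max_internal_distance:.12g}\t{c.max_gap_bp}\n"
                )
    if json_path is not None:
        payload = [
            {
                "operon_id": c.operon_id,
                "member_genes": c.member_genes,
                "contig": c.contig,
                "strand": c.strand,
                "direction": c.direction,
                "max_internal_distance": c.max_internal_distance,
                "max_gap_bp": c.max_gap_bp,
            }
            for c in candidates
        ]
        with open(json_path, "wt") as fh:
            json.dump(payload, fh, indent=2)


def read_operons(tsv_path) -> list[OperonCandidate]:
    with open(tsv_path, "rt") as fh:
        header = fh.readline().rstrip("\n")
        if header != _TSV_HEADER:
            raise ValueError(f"{tsv_path}: unexpected header")
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    by_id: dict[str, list[list[str]]] = {}
    for row in rows:
        by_id.setdefault(row[0], []).append(row)
    out = []
    for oid, group in by_id.items():
        group.sort(key=lambda r: int(r[2]))
        out.append(
            OperonCandidate(
                operon_id=oid,
                member_genes=[r[1] for r in group],
                contig=group[0][3],
                strand=group[0][4],
                direction=group[0][5],
                max_internal_distance=float(group[0][6]),
                max_gap_bp=int(group[0][7]),
            )
        )
    return out
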