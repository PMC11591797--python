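"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from ppoperon.simulate import SimConfig, GroundTruth, generate_pangenome


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """Desk-scale study: 40 genomes, 500 genes, 12 planted operons."""
    return SimConfig(rng_seed=101)


@pytest.fixture(scope="session")
def small_study(small_cfg):
    table, panel, truth = generate_pangenome(small_cfg)
    return {"table": table, "panel": panel, "truth": truth, "cfg": small_cfg}


def null_truth(cfg: SimConfig) -> GroundTruth:
    """Ground truth with every fold change 0 (for null-count simulation)."""
    from ppoperon.simulate import _gene_ids

    genes = _gene_ids(cfg)
    membership: dict[str, str | None] = {g: None for g in genes}
    membership[genes[0]] = membership[genes[1]] = "planted_01"
    return GroundTruth(
        membership,
        {g: 0.0 for g in genes},
        operon_genes={"planted_01": [genes[0], genes[1]]},
    )


# ---------------------------------------------------------------------------
# Independent oracles (set arithmetic / exhaustive search), kept free of the
# implementation paths they check.

def jaccard_oracle(a, b) -> float:
    """Jaccard distance via explicit Python set operations."""
    sa = {i for i, v in enumerate(a) if v}
    sb = {i for i, v in enumerate(b) if v}
    union = sa | sb
    if not union:
        return 0.0
    return 1.0 - len(sa & sb) / len(union)


def bh_oracle(pvalues) -> list[float]:
    """Step-up BH by literal definition: q_i = min_{j>=i} p_(j) * m / j."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q_sorted = []
    for i in range(m):
        q = min(pvalues[order[j]] * m / (j + 1) for j in range(i, m))
        q_sorted.append(min(1.0, q))
    out = [0.0] * m
    for rank, idx in enumerate(order):
        out[idx] = q_sorted[rank]
    return out


def brute_force_operons(dm, features, records, params) -> set[frozenset]:
    """Maximal gene groups satisfying all operon criteria, by enumeration.

    Within each (contig, strand, direction) cell, every subset of DE genes
    is tested against: all pairwise profile distances strictly below the
    cutoff, and every consecutive pair (genomic order) within the proximity
    window.  Only maximal valid subsets are kept.
    """
    feat = {f.gene_id: f for f in features}
    de = {r.gene_id: r for r in records}
    universe = set(dm.gene_ids) & set(feat) & set(de)
    cells: dict[tuple, list[str]] = {}
    for g in universe:
        call = de[g].call
        if call not in ("UP", "DOWN"):
            continue
        key = (feat[g].contig, feat[g].strand, call)
        cells.setdefault(key, []).append(g)

    def valid(subset: tuple[str, ...]) -> bool:
        for a, b in combinations(subset, 2):
            if dm.distance(a, b) >= params.distance_cutoff:
                return False
        ordered = sorted(subset, key=lambda g: feat[g].start)
        for a, b in zip(ordered, ordered[1:]):
            if feat[a].gap_to(feat[b]) > params.window_bp:
                return False
        return True

    groups: set[frozenset] = set()
    for genes in cells.values():
        assert len(genes) <= 20, "cell too large for exhaustive enumeration"
        valids = []
        for r in range(2, len(genes) + 1):
            for subset in combinations(genes, r):
                if valid(subset):
                    valids.append(frozenset(subset))
        for s in valids:
            if not any(s < t for t in valids):
                groups.add(s)
    return groups


@pytest.fixture
def rng():
    return np.random.default_rng(20240931)
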