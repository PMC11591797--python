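"""Functional summaries of DEG sets by COG category.

Genes carrying several one-letter categories contribute once to each
(documented multi-counting, not fractional); genes without an assignment
are tallied under "-".  Counts only — no enrichment statistic is attached.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .de import DERecord

logger = logging.getLogger(__name__)

__all__ = ["CogMap", "read_cog_map", "summarize_by_category", "plot_category_bars"]

COG_ALPHABET = set("ABCDEFGHIJKLMNOPQRSTUVWXYZ")
UNASSIGNED = "-"


@dataclass
class CogMap:
    """gene_id -> set of COG one-letter categories."""

    assignments: dict[str, set[str]]

    def __post_init__(self) -> None:
        for gene, cats in self.assignments.items():
            bad = cats - COG_ALPHABET
            if bad:
                raise ValueError(f"{gene}: invalid COG letter(s) {sorted(bad)}")

    def categories(self, gene_id: str) -> set[str]:
        return self.assignments.get(gene_id, set())


def read_cog_map(path) -> CogMap:
    """Two-column TSV gene_id -> letters (multi-letter cells split per letter)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (gene_id, letters)")
    gene_col, cat_col = df.columns[:2]
    assignments: dict[str, set[str]] = {}
    for i, row in df.iterrows():
        gene = str(row[gene_col])
        raw = "" if pd.isna(row[cat_col]) else str(row[cat_col]).strip()
        cats = set()
        for ch in raw:
            if ch in ",; ":
                continue
            up = ch.upper()
            if up not in COG_ALPHABET:
                raise ValueError(
                    f"{path}, data row {i + 1}: {ch!r} is not a COG category letter"
                )
            if ch != up:
                logger.warning("%s, row %d: lowercase %r normalized to %r",
                               path, i + 1, ch, up)
            cats.add(up)
        assignments[gene] = cats
    return CogMap(assignments)


def summarize_by_category(
    de: list[DERecord],
    cog: CogMap,
    de2: list[DERecord] | None = None,
) -> pd.DataFrame:
    """Per-category UP/DOWN counts over the DEGs of one (or two) DE sets.

    With a second DE set, additional columns count genes differentially
    expressed in the SAME direction in both sets (the shared-response view).
    """
    def degs(records):
        return {r.gene_id: r.call for r in records if r.call in ("UP", "DOWN")}

    primary = degs(de)
    shared: dict[str, str] = {}
    if de2 is not None:
        other = degs(de2)
        shared = {g: c for g, c in primary.items() if other.get(g) == c}

    rows: dict[str, dict[str, int]] = {}

    def bump(cat: str, col: str) -> None:
        rows.setdefault(cat, {"n_up": 0, "n_down": 0,
                              "n_up_shared": 0, "n_down_shared": 0})
        rows[cat][col] += 1

    for gene, call in primary.items():
        cats = cog.categories(gene) or {UNASSIGNED}
        for cat in cats:
            bump(cat, "n_up" if call == "UP" else "n_down")
            if gene in shared:
                bump(cat, "n_up_shared" if call == "UP" else "n_down_shared")

    df = pd.DataFrame(
        [{"category": cat, **counts} for cat, counts in sorted(rows.items())]
    )
    if df.empty:
        df = pd.DataFrame(columns=["category", "n_up", "n_down",
                                   "n_up_shared", "n_down_shared"])
    if de2 is None:
        df = df.drop(columns=["n_up_shared", "n_down_shared"])
    return df.reset_index(drop=True)


def plot_category_bars(summary: pd.DataFrame, path) -> None:
    """Simple horizontal bar chart of per-category UP/DOWN counts."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, max(2, 0.4 * len(summary))))
    y = range(len(summary))
    ax.barh(y, summary["n_down"], color="steelblue", label="down")
    ax.barh(y, summary["n_up"], left=summary["n_down"], color="indianred",
            label="up")
    ax.set_yticks(list(y), summary["category"])
    ax.set_xlabel("DEGs")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
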