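"""Relative qPCR quantification by the ddCt method.

For each condition the target gene's mean Ct is referenced to the
arithmetic mean Ct of the control (reference) genes — equivalent to the
geometric mean of their expression levels; the between-condition difference
of those deltas (ddCt) converts to a fold change through the target's
amplification efficiency, E^(-ddCt).  E = 2 (perfect doubling per cycle)
reproduces the classic 2^-ddCt formula.  Given reference-gene variability,
a change is flagged significant only when 2-fold or greater (up or down).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .de import DERecord, CONTROL, TREATED

__all__ = ["CtTable", "read_ct_table", "ddct_ratio", "compare_to_rnaseq"]

REQUIRED_COLUMNS = ("gene_id", "sample_id", "condition", "ct", "efficiency")


@dataclass
class CtTable:
    """Long-format Ct measurements plus the designated control genes."""

    data: pd.DataFrame
    control_genes: list[str]

    def __post_init__(self) -> None:
        missing = set(REQUIRED_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"Ct table missing column(s): {sorted(missing)}")
        if not self.control_genes:
            raise ValueError("at least one control gene is required")
        if (self.data["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")
        eff = self.data["efficiency"]
        if ((eff <= 1) | (eff > 2.2)).any():
            raise ValueError("amplification efficiency must lie in (1, 2.2]")
        bad = set(self.data["condition"]) - {CONTROL, TREATED}
        if bad:
            raise ValueError(f"unknown condition label(s): {sorted(bad)}")
        absent = set(self.control_genes) - set(self.data["gene_id"])
        if absent:
            raise ValueError(f"control gene(s) not measured: {sorted(absent)}")

    @property
    def target_genes(self) -> list[str]:
        ctrl = set(self.control_genes)
        return [g for g in self.data["gene_id"].unique() if g not in ctrl]

    def mean_ct(self, gene: str, condition: str) -> float:
        sel = self.data[
            (self.data["gene_id"] == gene) & (self.data["condition"] == condition)
        ]
        if sel.empty:
            raise ValueError(f"no Ct measurements for {gene} in {condition}")
        return float(sel["ct"].mean())


def read_ct_table(path, control_genes: list[str] | None = None) -> CtTable:
    """Read a Ct TSV; controls come from an ``is_control`` column or the caller."""
    df = pd.read_csv(path, sep="\t")
    if control_genes is None:
        if "is_control" not in df.columns:
            raise ValueError(
                f"{path}: no 'is_control' column and no control genes supplied"
            )
        control_genes = sorted(df.loc[df["is_control"].astype(bool), "gene_id"].unique())
    return CtTable(df, list(control_genes))


def ddct_ratio(tbl: CtTable, target: str) -> tuple[float, bool]:
    """Fold change (treated vs control) and the 2-fold significance flag."""
    if target in tbl.control_genes:
        raise ValueError(f"{target} is a designated control gene")
    gaps = []
    for cond in (CONTROL, TREATED):
        for gene in (target, *tbl.control_genes):
            sel = tbl.data[
                (tbl.data["gene_id"] == gene) & (tbl.data["condition"] == cond)
            ]
            if sel.empty:
                gaps.append(f"{gene}/{cond}")
    if gaps:
        raise ValueError(f"missing Ct measurements for: {gaps}")

    def delta_ct(cond: str) -> float:
        ref = float(np.mean([tbl.mean_ct(g, cond) for g in tbl.control_genes]))
        return tbl.mean_ct(target, cond) - ref

    ddct = delta_ct(TREATED) - delta_ct(CONTROL)
    eff = float(
        tbl.data.loc[tbl.data["gene_id"] == target, "efficiency"].iloc[0]
    )
    fold_change = float(eff ** (-ddct))
    significant = fold_change >= 2.0 or fold_change <= 0.5
    return fold_change, significant


def compare_to_rnaseq(
    qpcr_results: dict[str, float], de: list[DERecord]
) -> pd.DataFrame:
    """Sign-concordance table between qPCR fold changes and RNA-seq calls.

    ``qpcr_results`` maps gene -> linear fold change (>1 up, <1 down).
    Genes absent from the DE table get a missing marker, not a row error.
    No statistical test is attached: this is a confirmation view.
    """
    de_by_id = {r.gene_id: r for r in de}
    rows = []
    for gene, fc_q in qpcr_results.items():
        rec = de_by_id.get(gene)
        if rec is None:
            rows.append({"gene_id": gene, "fc_qpcr": fc_q,
                         "fc_rnaseq": np.nan, "sign_agrees": pd.NA})
            continue
        up_q = fc_q > 1.0
        up_r = rec.log2fc > 0.0
        rows.append(
            {
                "gene_id": gene,
                "fc_qpcr": fc_q,
                "fc_rnaseq": rec.fc_signed,
                "sign_agrees": bool(up_q == up_r),
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "fc_qpcr", "fc_rnaseq",
                                       "sign_agrees"])
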