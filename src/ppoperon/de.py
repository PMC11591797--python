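"""Differential expression for small-replicate bacterial RNA-seq counts.

The stage mirrors the classic count-based workflow for two-group designs:
TMM (trimmed mean of M-values) normalization, a single common negative-
binomial dispersion shared by all genes, and a conditional exact test on the
per-condition count sums, followed by Benjamini-Hochberg FDR control.  It is
a from-scratch reimplementation of that workflow, not a bit-exact clone of
any particular package; its contract is statistical calibration (type-I
error, power, parameter recovery), which the test suite checks.

A gene is called differentially expressed when its fold change strictly
exceeds the threshold (default 2-fold, 1.5 supported) and its FDR is
strictly below 0.05; boundary values are not significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from scipy.stats import nbinom, rankdata

__all__ = [
    "CountMatrix",
    "DERecord",
    "DEThresholds",
    "tmm_factors",
    "estimate_common_dispersion",
    "nb_exact_test",
    "bh_adjust",
    "call_degs",
    "run_de",
    "read_counts",
    "read_de_table",
    "write_de_table",
]

CONTROL = "control"
TREATED = "treated"


@dataclass
class CountMatrix:
    """Gene x sample integer counts with a sample -> condition map."""

    counts: pd.DataFrame  # genes x samples, non-negative integers
    condition: dict[str, str]  # sample -> "control" | "treated"

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene_ids in count matrix")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integers")
        missing = set(self.counts.columns) - set(self.condition)
        if missing:
            raise ValueError(f"samples without condition assignment: {sorted(missing)}")
        bad = set(self.condition.values()) - {CONTROL, TREATED}
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def samples_in(self, cond: str) -> list[str]:
        return [s for s in self.samples if self.condition[s] == cond]

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def write_tsv(self, counts_path, conditions_path) -> None:
        df = self.counts.copy()
        df.index.name = "gene_id"
        df.to_csv(counts_path, sep="\t")
        cond = pd.DataFrame(
            {"sample_id": self.samples,
             "condition": [self.condition[s] for s in self.samples]}
        )
        cond.to_csv(conditions_path, sep="\t", index=False)


def read_counts(counts_path, conditions_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    cond_df = pd.read_csv(conditions_path, sep="\t")
    for col in ("sample_id", "condition"):
        if col not in cond_df.columns:
            raise ValueError(f"{conditions_path}: missing column {col!r}")
    condition = dict(zip(cond_df["sample_id"].astype(str), cond_df["condition"]))
    return CountMatrix(counts, condition)


@dataclass(frozen=True)
class DEThresholds:
    """Significance thresholds: linear |fold change| and FDR ceiling."""

    min_abs_fc: float = 2.0
    max_fdr: float = 0.05

    def __post_init__(self) -> None:
        if not self.min_abs_fc > 1:
            raise ValueError("min_abs_fc must exceed 1")
        if not 0 < self.max_fdr < 1:
            raise ValueError("max_fdr must lie in (0, 1)")


@dataclass
class DERecord:
    """Per-gene DE result.

    ``fc_signed`` is the signed linear fold change, sign(log2fc)*2^|log2fc|
    (e.g. -1.61 means 1.61-fold down); ``call`` is UP, DOWN or NS.
    """

    gene_id: str
    log2fc: float
    pvalue: float
    fdr: float = float("nan")
    call: str = "NS"
    fc_signed: float = field(init=False)

    def __post_init__(self) -> None:
        sign = -1.0 if self.log2fc < 0 else 1.0
        self.fc_signed = sign * 2.0 ** abs(self.log2fc)


# ---------------------------------------------------------------------------
# TMM normalization

def _quantile_factor(counts: np.ndarray, lib: np.ndarray, p: float = 0.75) -> np.ndarray:
    return np.quantile(counts, p, axis=0) / lib


def tmm_factors(cm: CountMatrix, *, m_trim: float = 0.30, a_trim: float = 0.05) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors, one per sample.

    The reference sample is the one whose library-size-scaled upper quartile
    is closest to the mean upper quartile.  For each sample, per-gene
    log-ratios M (vs the reference, after library-size adjustment) and
    average log-abundances A are formed on genes nonzero in both samples;
    the extreme 30% of M and 5% of A are trimmed from each tail and the
    remaining M averaged with inverse-variance (delta-method) weights.
    Factors are rescaled to geometric mean 1.
    """
    counts = cm.counts.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        bad = [s for s, l in zip(cm.samples, lib) if l == 0]
        raise ValueError(f"all-zero sample(s): {bad}")
    f75 = _quantile_factor(counts, lib)
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    factors = np.ones(len(cm.samples))
    for k in range(len(cm.samples)):
        factors[k] = _tmm_pair(
            counts[:, k], counts[:, ref], lib[k], lib[ref], m_trim, a_trim
        )
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=cm.samples, name="tmm_factor")


def _tmm_pair(obs, ref, n_obs, n_ref, m_trim, a_trim) -> float:
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep], ref[keep]
    if obs.size == 0:
        return 1.0
    p_obs, p_ref = obs / n_obs, ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # delta-method variance of M; weight = 1/var
    v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = np.floor(n * m_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * a_trim) + 1
    hi_a = n + 1 - lo_a
    rm, ra = rankdata(m), rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return float(2.0 ** f)


# ---------------------------------------------------------------------------
# Common dispersion

def _conditional_loglik(groups: list[np.ndarray], phi: float) -> float:
    """Summed conditional NB log-likelihood given per-gene group totals.

    Each array in ``groups`` holds one condition's (genes x replicates)
    counts on a common library size.  Conditioning on the per-gene total
    removes the unknown mean from the likelihood, so the dispersion is
    estimated without the downward bias that plugging in fitted means
    incurs at 3+3 replicates.  Terms free of phi are dropped.
    """
    r = 1.0 / phi
    ll = 0.0
    for y in groups:
        n = y.shape[1]
        z = y.sum(axis=1)
        ll += float(
            np.sum(gammaln(y + r))
            - y.size * gammaln(r)
            + z.size * gammaln(n * r)
            - np.sum(gammaln(z + n * r))
        )
    return ll


def estimate_common_dispersion(
    cm: CountMatrix,
    factors: pd.Series,
    *,
    grid: tuple[float, float] = (1e-4, 4.0),
    n_grid: int = 25,
) -> float:
    """Single NB dispersion shared by all genes, by conditional likelihood.

    Counts are rescaled to a common effective library size (geometric mean)
    and rounded; within each condition the likelihood conditions on each
    gene's replicate total.  The summed conditional likelihood is maximised
    on a log-spaced grid over ``grid`` and refined with bounded scalar
    minimisation in the bracketing interval.  Requires replication in both
    conditions.
    """
    for cond in (CONTROL, TREATED):
        if len(cm.samples_in(cond)) < 2:
            raise ValueError(
                f"condition {cond!r} has <2 replicates; common dispersion cannot "
                "be estimated — supply a dispersion value explicitly"
            )
    counts = cm.counts.to_numpy(dtype=float)
    eff = cm.library_sizes().to_numpy() * factors.reindex(cm.samples).to_numpy()
    common = float(np.exp(np.mean(np.log(eff))))
    scaled = np.rint(counts * (common / eff)[None, :])

    groups = []
    for cond in (CONTROL, TREATED):
        idx = [cm.samples.index(s) for s in cm.samples_in(cond)]
        y = scaled[:, idx]
        y = y[y.sum(axis=1) > 0]
        groups.append(y)

    lo, hi = grid
    phis = np.geomspace(lo, hi, n_grid)
    lls = np.array([_conditional_loglik(groups, p) for p in phis])
    i = int(np.argmax(lls))
    lo_b = phis[max(i - 1, 0)]
    hi_b = phis[min(i + 1, n_grid - 1)]
    res = minimize_scalar(
        lambda lp: -_conditional_loglik(groups, np.exp(lp)),
        bounds=(np.log(lo_b), np.log(hi_b)),
        method="bounded",
        options={"xatol": 1e-4},
    )
    return float(np.exp(res.x))


# ---------------------------------------------------------------------------
# Exact test

def _cond_log_pmf(total: int, r1: float, r2: float) -> np.ndarray:
    """Log conditional pmf of the group-1 sum given the total.

    For two NB sums with a common probability parameter the conditional law
    is negative hypergeometric and does not depend on that parameter.
    """
    a = np.arange(total + 1)
    lp = (
        gammaln(a + r1) - gammaln(a + 1)
        + gammaln(total - a + r2) - gammaln(total - a + 1)
    )
    return lp - logsumexp(lp)


def _exact_pvalue(s1: int, s2: int, n1: int, n2: int, phi: float) -> float:
    """Two-sided conditional exact p-value, doubling the smaller tail."""
    total = s1 + s2
    if total == 0:
        return 1.0
    if phi <= 1e-10:
        # Poisson limit: conditional law is binomial(total, n1/(n1+n2))
        from scipy.stats import binom

        frac = n1 / (n1 + n2)
        lo = binom.cdf(s1, total, frac)
        hi = binom.sf(s1 - 1, total, frac)
    else:
        r = 1.0 / phi
        lp = _cond_log_pmf(total, n1 * r, n2 * r)
        p = np.exp(lp)
        lo = p[: s1 + 1].sum()
        hi = p[s1:].sum()
    return float(min(1.0, 2.0 * min(lo, hi)))


def nb_exact_test(
    cm: CountMatrix,
    factors: pd.Series,
    phi: float,
    *,
    prior_count: float = 0.125,
) -> list[DERecord]:
    """Conditional NB exact test of treated vs control, gene by gene.

    Counts are rescaled to a common effective library size (the geometric
    mean), summed per condition and rounded; the two-sided p-value doubles
    the smaller conditional tail.  log2 fold changes come from the
    normalized per-condition means with a stabilizing prior count per
    sample (avoids log 0).
    """
    if phi < 0:
        raise ValueError("dispersion must be >= 0")
    ctrl = cm.samples_in(CONTROL)
    trt = cm.samples_in(TREATED)
    if not ctrl or not trt:
        raise ValueError("both conditions must have at least one sample")

    counts = cm.counts.to_numpy(dtype=float)
    eff = cm.library_sizes().to_numpy() * factors.reindex(cm.samples).to_numpy()
    common = float(np.exp(np.mean(np.log(eff))))
    scaled = counts * (common / eff)[None, :]

    ic = [cm.samples.index(s) for s in ctrl]
    it = [cm.samples.index(s) for s in trt]
    s_c = np.rint(scaled[:, ic].sum(axis=1)).astype(np.int64)
    s_t = np.rint(scaled[:, it].sum(axis=1)).astype(np.int64)
    n_c, n_t = len(ic), len(it)

    mean_c = (s_c + prior_count * n_c) / n_c
    mean_t = (s_t + prior_count * n_t) / n_t
    log2fc = np.log2(mean_t / mean_c)

    out = []
    for g, gene in enumerate(cm.gene_ids):
        p = _exact_pvalue(int(s_c[g]), int(s_t[g]), n_c, n_t, phi)
        out.append(DERecord(gene_id=gene, log2fc=float(log2fc[g]), pvalue=p))
    return out


# ---------------------------------------------------------------------------
# FDR and calls

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1) | np.isnan(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def call_degs(records: list[DERecord], th: DEThresholds) -> list[DERecord]:
    """Fill FDR and classify each record as UP, DOWN or NS.

    Strict inequalities on both axes: a gene must change by strictly more
    than ``min_abs_fc``-fold and have FDR strictly below ``max_fdr``.
    """
    fdrs = bh_adjust([r.pvalue for r in records])
    cut = np.log2(th.min_abs_fc)
    for r, q in zip(records, fdrs):
        r.fdr = float(q)
        if q < th.max_fdr and r.log2fc > cut:
            r.call = "UP"
        elif q < th.max_fdr and r.log2fc < -cut:
            r.call = "DOWN"
        else:
            r.call = "NS"
    return records


def run_de(
    cm: CountMatrix,
    th: DEThresholds = DEThresholds(),
    *,
    dispersion: float | None = None,
) -> list[DERecord]:
    """Full stage: TMM factors, common dispersion, exact test, BH, calls."""
    factors = tmm_factors(cm)
    phi = estimate_common_dispersion(cm, factors) if dispersion is None else dispersion
    records = nb_exact_test(cm, factors, phi)
    return call_degs(records, th)


# ---------------------------------------------------------------------------
# DE table I/O

_LOGFC_ALIASES = ("log2FC", "logFC", "log2fc", "logfc")


def read_de_table(path, th: DEThresholds = DEThresholds()) -> list[DERecord]:
    """Ingest a precomputed DE table (gene_id, log2FC/logFC, PValue, FDR).

    Calls are recomputed from the thresholds, never trusted from the file.
    """
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "gene_id" not in cols:
        raise ValueError(f"{path}: missing column 'gene_id'")
    lfc_col = next((c for c in _LOGFC_ALIASES if c.lower() in cols), None)
    if lfc_col is None:
        raise ValueError(f"{path}: missing log2FC/logFC column")
    for name in ("pvalue", "fdr"):
        if name not in cols:
            raise ValueError(f"{path}: missing column {name!r} (PValue/FDR)")

    records = []
    for i, row in df.iterrows():
        try:
            lfc = float(row[cols[lfc_col.lower()]])
            p = float(row[cols["pvalue"]])
            q = float(row[cols["fdr"]])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}, data row {i + 1}: non-numeric cell ({exc})")
        records.append(DERecord(gene_id=str(row[cols["gene_id"]]), log2fc=lfc, pvalue=p))
        records[-1].fdr = q
    # re-derive calls from the supplied FDR column
    cut = np.log2(th.min_abs_fc)
    for r in records:
        if r.fdr < th.max_fdr and r.log2fc > cut:
            r.call = "UP"
        elif r.fdr < th.max_fdr and r.log2fc < -cut:
            r.call = "DOWN"
        else:
            r.call = "NS"
    return records


def write_de_table(records: list[DERecord], path) -> None:
    df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "log2FC": [r.log2fc for r in records],
            "FC_signed": [r.fc_signed for r in records],
            "PValue": [r.pvalue for r in records],
            "FDR": [r.fdr for r in records],
            "call": [r.call for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)
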