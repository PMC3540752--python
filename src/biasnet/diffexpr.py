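"""Sex-biased differential expression by a moderated Welch test.

The test compares male vs female expression per gene within one
tissue/stage condition. Replicate counts on pooled-sample microarrays are
tiny (typically three pools per sex), so per-gene variance estimates are
unstable; the moderated Welch test shrinks each per-gene, per-sex variance
toward a common value pooled across the whole gene set:

    s~^2_g = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

where ``s_g^2`` is the sample variance of gene *g* within one sex with
``d_g = n_g - 1`` degrees of freedom, ``s0^2`` is the mean per-gene variance
of that sex across all genes, and ``d0 >= 0`` is the shrinkage weight (the
prior degrees of freedom). The statistic is the Welch *t* on shrunk
variances,

    t = (mean_M - mean_F) / sqrt(s~^2_M / n_M + s~^2_F / n_F),

with a Satterthwaite df computed on the shrunk variances using d0 + d_g
per-group degrees of freedom. ``d0 = 0`` recovers the classical Welch test;
``d0 -> inf`` gives the fully pooled equal-shrinkage limit. By default d0 is
estimated from the spread of the observed per-gene variances by a
method-of-moments fit on the log scale (the scaled-F model: if the true
variances are inverse-gamma distributed, log s_g^2 has variance
psi'(d_g/2) + psi'(d0/2), which is inverted for d0).

Intensities are MAS5-like positive values; they are floored at 1 and
log2-transformed internally. Positive statistics and fold changes mean
male-biased expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.optimize import brentq
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: FDR cutoff separating sex-biased from unbiased genes.
DEFAULT_FDR_CUTOFF = 0.1

SEXES = ("male", "female")
BIAS_LABELS = ("male", "female", "unbiased")


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of positive intensities with sample metadata.

    ``values`` is a DataFrame indexed by gene id with one column per sample;
    ``sample_meta`` is indexed by sample name with columns ``sex`` (male or
    female), ``tissue``, ``stage`` and ``replicate``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self):
        if not self.values.index.is_unique:
            raise ValueError("gene ids must be unique")
        missing = set(self.values.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")
        if (self.values.to_numpy() <= 0).any():
            raise ValueError("intensities must be strictly positive (MAS5-like)")
        bad_sex = set(self.sample_meta["sex"]) - set(SEXES)
        if bad_sex:
            raise ValueError(f"unknown sex labels: {sorted(bad_sex)}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def conditions(self) -> list[tuple[str, str]]:
        """Distinct (tissue, stage) pairs present in the metadata."""
        pairs = self.sample_meta[["tissue", "stage"]].drop_duplicates()
        return sorted(map(tuple, pairs.to_numpy()))

    def condition_samples(self, tissue: str, stage: str, sex: str) -> list[str]:
        meta = self.sample_meta
        mask = (meta["tissue"] == tissue) & (meta["stage"] == stage) & (
            meta["sex"] == sex
        )
        return [s for s in self.values.columns if s in set(meta.index[mask])]


def read_expression(values_path, meta_path) -> ExpressionMatrix:
    """Read an expression TSV (first column gene id) plus a sample-metadata
    TSV (sample, sex, tissue, stage, replicate)."""
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype=str)
    return ExpressionMatrix(values=values, sample_meta=meta)


def write_expression(matrix: ExpressionMatrix, values_path, meta_path) -> None:
    matrix.values.to_csv(values_path, sep="\t", index_label="gene_id")
    matrix.sample_meta.to_csv(meta_path, sep="\t", index_label="sample")


@dataclass
class DEResult:
    """Per-gene moderated Welch results for one condition.

    ``table`` columns: t (moderated Welch statistic; positive = male-biased),
    df (Satterthwaite degrees of freedom), p (two-sided), fdr (BH-adjusted),
    log2fc (male minus female mean on log2 scale), direction.
    """

    table: pd.DataFrame
    condition: tuple[str, str]
    d0: float
    n_male: int
    n_female: int


def _log2_floor(values: np.ndarray) -> np.ndarray:
    return np.log2(np.maximum(values, 1.0))


def estimate_prior(sample_vars: np.ndarray, d_resid: float) -> tuple[float, float]:
    """Method-of-moments fit of the variance prior (d0, s0^2) on log scale.

    Under the scaled-F model (true variances scaled-inverse-chi-square with
    d0 df and scale s0^2), log s^2 has variance psi'(d/2) + psi'(d0/2) and
    mean log s0^2 + [psi(d/2) - log(d/2)] - [psi(d0/2) - log(d0/2)]. The
    observed spread of log sample variances in excess of the chi-square
    sampling noise is inverted for d0, then the mean equation for s0^2.
    Returns ``(inf, mean variance)`` when the observed spread does not
    exceed pure sampling noise (variances look homogeneous).
    """
    v = np.asarray(sample_vars, dtype=float)
    v = v[v > 0]
    if v.size < 2:
        return np.inf, float(np.mean(sample_vars))
    z = np.log(v)
    half_d = d_resid / 2.0
    excess = z.var(ddof=1) - float(special.polygamma(1, half_d))
    if excess <= 1e-8:
        return np.inf, float(np.exp(z.mean() - special.digamma(half_d) + np.log(half_d)))
    f = lambda half: float(special.polygamma(1, half)) - excess
    lo, hi = 1e-6, 1e8  # psi'(x) is decreasing; bracket d0/2
    if f(lo) < 0:  # spread larger than psi'(1e-6): essentially d0 -> 0
        return 0.0, float(np.mean(sample_vars))
    if f(hi) > 0:
        return np.inf, float(np.exp(z.mean() - special.digamma(half_d) + np.log(half_d)))
    half_d0 = brentq(f, lo, hi, xtol=1e-12, rtol=1e-12)
    log_s0 = (
        z.mean()
        - (special.digamma(half_d) - np.log(half_d))
        + (special.digamma(half_d0) - np.log(half_d0))
    )
    return 2.0 * half_d0, float(np.exp(log_s0))


def estimate_d0(sample_vars: np.ndarray, d_resid: float) -> float:
    """Prior degrees of freedom from :func:`estimate_prior`."""
    return estimate_prior(sample_vars, d_resid)[0]


def _prior_scale(sample_vars: np.ndarray, d_resid: float, d0: float) -> float:
    """Prior scale s0^2 from the log-moment equation, given d0."""
    v = np.asarray(sample_vars, dtype=float)
    v = v[v > 0]
    if v.size == 0:
        return float(np.mean(sample_vars)) if len(sample_vars) else 0.0
    z = np.log(v)
    half_d = d_resid / 2.0
    base = z.mean() - (special.digamma(half_d) - np.log(half_d))
    if np.isinf(d0):
        return float(np.exp(base))
    if d0 <= 0:
        return float(np.mean(sample_vars))
    half_d0 = d0 / 2.0
    return float(np.exp(base + special.digamma(half_d0) - np.log(half_d0)))


def moderated_welch(
    matrix: ExpressionMatrix,
    condition: tuple[str, str],
    d0: float | None = None,
    fdr_cutoff: float = DEFAULT_FDR_CUTOFF,
) -> DEResult:
    """Moderated Welch test of male vs female expression in one condition.

    Parameters
    ----------
    matrix
        Expression matrix with metadata.
    condition
        ``(tissue, stage)`` selecting the samples to test.
    d0
        Shrinkage weight (prior degrees of freedom). ``None`` (default)
        estimates it from the data; ``0`` gives the classical Welch test;
        ``numpy.inf`` fully pools the variance.

    Returns a :class:`DEResult` whose p-values come from a t distribution
    with per-gene Satterthwaite degrees of freedom; FDR is BH across all
    genes of the condition.
    """
    tissue, stage = condition
    groups = {}
    for sex in SEXES:
        cols = matrix.condition_samples(tissue, stage, sex)
        if len(cols) < 2:
            raise ValueError(
                f"condition {condition} needs >= 2 {sex} samples, got {len(cols)}"
            )
        groups[sex] = _log2_floor(matrix.values[cols].to_numpy(dtype=float))

    xm, xf = groups["male"], groups["female"]
    nm, nf = xm.shape[1], xf.shape[1]
    mean_m, mean_f = xm.mean(axis=1), xf.mean(axis=1)
    var_m, var_f = xm.var(axis=1, ddof=1), xf.var(axis=1, ddof=1)
    dm, df_ = nm - 1, nf - 1

    estimated = d0 is None
    if estimated:
        # pool both sexes' per-gene variances for a single d0 when replicate
        # counts match; otherwise estimate per sex and combine conservatively
        if dm == df_:
            d0 = estimate_d0(np.concatenate([var_m, var_f]), dm)
        else:
            d0 = min(estimate_d0(var_m, dm), estimate_d0(var_f, df_))
    if d0 < 0:
        raise ValueError("d0 must be nonnegative")

    if estimated:
        # prior scale from the log-moment equation (calibrated under the
        # scaled-F model); per sex, with the shared d0
        s0_m = _prior_scale(var_m, dm, d0)
        s0_f = _prior_scale(var_f, df_, d0)
    else:
        s0_m = float(var_m.mean())
        s0_f = float(var_f.mean())
    if np.isinf(d0):
        sv_m = np.full_like(var_m, s0_m)
        sv_f = np.full_like(var_f, s0_f)
        dtot_m = dtot_f = np.inf
    else:
        sv_m = (d0 * s0_m + dm * var_m) / (d0 + dm)
        sv_f = (d0 * s0_f + df_ * var_f) / (d0 + df_)
        dtot_m, dtot_f = d0 + dm, d0 + df_

    se2 = sv_m / nm + sv_f / nf
    diff = mean_m - mean_f
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        if np.isinf(dtot_m):
            df_sat = np.full_like(t, np.inf)
        else:
            df_sat = se2**2 / (
                (sv_m / nm) ** 2 / dtot_m + (sv_f / nf) ** 2 / dtot_f
            )
    # zero variance in both groups and zero mean difference -> t = 0, p = 1
    degenerate = se2 == 0
    t = np.where(degenerate & (diff == 0), 0.0, t)
    finite_df = np.where(np.isfinite(df_sat), df_sat, 1.0)
    p = np.where(
        np.isinf(df_sat),
        2.0 * stats.norm.sf(np.abs(t)),
        2.0 * stats.t.sf(np.abs(t), finite_df),
    )
    p = np.where(degenerate & (diff == 0), 1.0, p)
    if (degenerate & (diff != 0)).any():
        # infinite t: maximally significant
        p = np.where(degenerate & (diff != 0), 0.0, p)

    log2fc = diff
    fdr = bh_fdr(p)
    direction = np.where(
        log2fc > 0, "male", np.where(log2fc < 0, "female", "none")
    )
    table = pd.DataFrame(
        {
            "t": t,
            "df": df_sat,
            "p": p,
            "fdr": fdr,
            "log2fc": log2fc,
            "direction": direction,
        },
        index=pd.Index(matrix.genes, name="gene_id"),
    )
    return DEResult(
        table=table, condition=condition, d0=float(d0), n_male=nm, n_female=nf
    )


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def log_fold_change(
    matrix: ExpressionMatrix, condition: tuple[str, str]
) -> pd.Series:
    """Per-gene log2 ratio of male to female mean intensity (floored at 1),
    the classical fold-change measure of sex bias."""
    tissue, stage = condition
    out = {}
    for sex in SEXES:
        cols = matrix.condition_samples(tissue, stage, sex)
        if not cols:
            raise ValueError(f"no {sex} samples in condition {condition}")
        out[sex] = np.maximum(matrix.values[cols].to_numpy(dtype=float), 1.0).mean(
            axis=1
        )
    fc = np.log2(out["male"]) - np.log2(out["female"])
    return pd.Series(fc, index=pd.Index(matrix.genes, name="gene_id"), name="log2fc")


@dataclass
class BiasTable:
    """Per-gene sex-bias labels for one condition."""

    labels: pd.Series  # gene id -> {male, female, unbiased}
    condition: tuple[str, str]
    fdr_cutoff: float

    def genes_with(self, label: str) -> set[str]:
        if label not in BIAS_LABELS:
            raise KeyError(f"unknown bias label {label!r}")
        return set(self.labels.index[self.labels == label])

    def counts(self) -> dict[str, int]:
        return {lab: int((self.labels == lab).sum()) for lab in BIAS_LABELS}


def classify_bias(de: DEResult, fdr_cutoff: float = DEFAULT_FDR_CUTOFF) -> BiasTable:
    """Partition genes into male-biased / female-biased / unbiased.

    A gene is male-biased if fdr < cutoff and log2fc > 0, female-biased if
    fdr < cutoff and log2fc < 0, unbiased otherwise. A significant gene with
    log2fc exactly 0 is classified unbiased with a logged warning.
    """
    t = de.table
    sig = t["fdr"] < fdr_cutoff
    labels = np.full(len(t), "unbiased", dtype=object)
    labels[sig.to_numpy() & (t["log2fc"] > 0).to_numpy()] = "male"
    labels[sig.to_numpy() & (t["log2fc"] < 0).to_numpy()] = "female"
    odd = sig & (t["log2fc"] == 0)
    if odd.any():
        logger.warning(
            "%d genes significant at FDR < %g with zero fold change; "
            "classified unbiased",
            int(odd.sum()),
            fdr_cutoff,
        )
    return BiasTable(
        labels=pd.Series(labels, index=t.index, name="bias"),
        condition=de.condition,
        fdr_cutoff=fdr_cutoff,
    )


def write_de_table(de: DEResult, bias: BiasTable, path) -> None:
    """Write the per-condition DE table (gene, t, df, p, fdr, log2fc, label).
    Positive t and log2fc mean male-biased."""
    out = de.table.copy()
    out["label"] = bias.labels
    out.to_csv(path, sep="\t", index_label="gene_id")
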