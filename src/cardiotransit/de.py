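"""Negative-binomial differential expression from count matrices.

A self-contained engine implementing the statistical core used for the
RNA-seq arms: median-of-ratios library-size normalization, a per-gene NB
generalized-linear-model likelihood-ratio test (method-of-moments
dispersion, chi^2_1 reference), Benjamini-Hochberg FDR adjustment, and
log2FC / FDR threshold filtering.  It matches the behaviour of full DE
packages qualitatively (no dispersion shrinkage, outlier filtering, or LFC
moderation).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CountMatrix",
    "size_factors",
    "normalized_counts",
    "log2fc_median_norm",
    "estimate_dispersion",
    "nb_lrt_test",
    "bh_adjust",
    "de_table",
    "filter_degs",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_design_tsv",
    "write_design_tsv",
]

_ALPHA_FLOOR = 1e-8
_ALPHA_CAP = 100.0


@dataclass
class CountMatrix:
    """Integer gene x sample counts with a sample -> group design.

    ``counts`` is a DataFrame indexed by unique gene ids with sample
    columns; ``groups`` maps every sample to its stage label.
    """

    counts: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self) -> None:
        c = self.counts
        if not c.index.is_unique:
            raise ValueError("gene ids must be unique")
        arr = c.to_numpy()
        if np.any(arr < 0):
            raise ValueError("counts must be non-negative")
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integral")
        missing = [s for s in c.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without a group: {missing}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def samples_of(self, group: str) -> list[str]:
        return [s for s in self.counts.columns if self.groups[s] == group]


# ---------------------------------------------------------------------------
# Normalization

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    The reference is the per-gene geometric mean over samples; only genes
    expressed in every sample (positive geometric mean) contribute.  Factors
    are reported unscaled.
    """
    arr = counts.to_numpy(dtype=float)
    positive = np.all(arr > 0, axis=1)
    if not positive.any():
        raise ValueError("no gene is expressed in all samples: size factors undefined")
    log_arr = np.log(arr[positive])
    log_ref = log_arr.mean(axis=1)
    factors = np.exp(np.median(log_arr - log_ref[:, None], axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalized_counts(
    counts: pd.DataFrame, factors: pd.Series | None = None
) -> pd.DataFrame:
    if factors is None:
        factors = size_factors(counts)
    return counts / factors


def log2fc_median_norm(
    counts: pd.DataFrame,
    groups: Mapping[str, str],
    contrast: tuple[str, str],
    pseudocount: float = 1.0,
    factors: pd.Series | None = None,
) -> pd.Series:
    """log2 of the ratio of mean median-normalized counts (treatment over
    control), with a pseudocount keeping the estimate finite."""
    treat, ctrl = contrast
    norm = normalized_counts(counts, factors)
    cols_t = [s for s in counts.columns if groups[s] == treat]
    cols_c = [s for s in counts.columns if groups[s] == ctrl]
    if not cols_t or not cols_c:
        raise ValueError(f"empty group in contrast {contrast!r}")
    mt = norm[cols_t].mean(axis=1)
    mc = norm[cols_c].mean(axis=1)
    out = np.log2((mt + pseudocount) / (mc + pseudocount))
    out.name = f"log2fc_{treat}_vs_{ctrl}"
    return out


# ---------------------------------------------------------------------------
# NB likelihood-ratio test

def estimate_dispersion(
    y: np.ndarray, sf: np.ndarray, group_idx: list[np.ndarray]
) -> np.ndarray:
    """Per-gene method-of-moments NB dispersion (Var = mu + alpha mu^2).

    Moments are taken on size-factor-normalized counts z = y/sf within each
    group: E[s^2_g] ~ q_g * mean(1/sf) + alpha q_g^2.  Pooled across groups
    with df weights; floored at 1e-8.
    """
    z = y / sf[None, :]
    num = np.zeros(y.shape[0])
    den = np.zeros(y.shape[0])
    for idx in group_idx:
        n_g = idx.size
        if n_g < 2:
            continue
        zg = z[:, idx]
        q = zg.mean(axis=1)
        s2 = zg.var(axis=1, ddof=1)
        m = float(np.mean(1.0 / sf[idx]))
        num += (n_g - 1) * (s2 - q * m)
        den += (n_g - 1) * q**2
    alpha = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    return np.clip(alpha, _ALPHA_FLOOR, _ALPHA_CAP)


def _nb_loglik_kernel(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Per-gene NB log-likelihood, dropping terms constant in mu.

    kernel = sum_i [ y log mu - (y + 1/alpha) log(1 + alpha mu) ];
    stable in the Poisson limit alpha -> 0 via log1p.
    """
    mu = np.maximum(mu, 1e-300)
    a = alpha[:, None]
    term = y * np.log(mu) - (y + 1.0 / a) * np.log1p(a * mu)
    return term.sum(axis=1)


def _fit_nb_mean(
    y: np.ndarray, sf: np.ndarray, alpha: np.ndarray, max_iter: int = 60
) -> np.ndarray:
    """Maximum-likelihood log-mean beta per gene at fixed dispersion.

    The score S(beta) = sum_i (y_i - mu_i)/(1 + alpha mu_i) with
    mu_i = sf_i exp(beta) is strictly decreasing in beta, so Newton steps
    converge to the unique root.
    """
    z = y / sf[None, :]
    beta = np.log(np.maximum(z.mean(axis=1), 1e-10))
    a = alpha[:, None]
    for _ in range(max_iter):
        mu = sf[None, :] * np.exp(beta)[:, None]
        denom = 1.0 + a * mu
        score = ((y - mu) / denom).sum(axis=1)
        d_score = -(mu * (1.0 + a * y) / denom**2).sum(axis=1)
        step = score / np.where(d_score < 0, d_score, -1e-12)
        step = np.clip(step, -5.0, 5.0)
        beta -= step
        if np.max(np.abs(step)) < 1e-10:
            break
    return np.maximum(beta, np.log(1e-10))


def nb_lrt_test(
    counts: pd.DataFrame,
    groups: Mapping[str, str],
    contrast: tuple[str, str],
    factors: pd.Series | None = None,
    prior_df: float = 10.0,
) -> pd.Series:
    """Per-gene p-values from an NB GLM likelihood-ratio test.

    Dispersion is estimated by method of moments across the contrast's
    samples, then stabilised by empirical-Bayes shrinkage toward the
    ensemble median with ``prior_df`` pseudo-degrees of freedom (per-gene
    moment estimates at a handful of replicates are noisy enough to make
    the plug-in test anticonservative).  Means are fitted by ML at fixed
    dispersion under the null (one mean with size-factor offsets) and the
    alternative (one mean per group); 2 * delta-logL is referred to
    chi^2_1.  All-zero genes get p = 1.
    """
    treat, ctrl = contrast
    cols_t = [s for s in counts.columns if groups[s] == treat]
    cols_c = [s for s in counts.columns if groups[s] == ctrl]
    if len(cols_t) < 2 or len(cols_c) < 2:
        raise ValueError("each contrast group needs at least two samples")
    cols = cols_c + cols_t
    if factors is None:
        factors = size_factors(counts)
    sf = factors[cols].to_numpy(dtype=float)
    y = counts[cols].to_numpy(dtype=float)
    idx_c = np.arange(len(cols_c))
    idx_t = np.arange(len(cols_c), len(cols))

    alpha = estimate_dispersion(y, sf, [idx_c, idx_t])
    if prior_df > 0:
        resid_df = len(cols) - 2
        prior = float(np.median(alpha))
        alpha = (prior_df * prior + resid_df * alpha) / (prior_df + resid_df)
        alpha = np.clip(alpha, _ALPHA_FLOOR, _ALPHA_CAP)

    beta_null = _fit_nb_mean(y, sf, alpha)
    ll_null = _nb_loglik_kernel(y, sf[None, :] * np.exp(beta_null)[:, None], alpha)

    ll_alt = np.zeros_like(ll_null)
    for idx in (idx_c, idx_t):
        beta_g = _fit_nb_mean(y[:, idx], sf[idx], alpha)
        ll_alt += _nb_loglik_kernel(
            y[:, idx], sf[idx][None, :] * np.exp(beta_g)[:, None], alpha
        )

    lrt = np.clip(2.0 * (ll_alt - ll_null), 0.0, None)
    p = sps.chi2.sf(lrt, df=1)
    p[np.all(y == 0, axis=1)] = 1.0
    return pd.Series(p, index=counts.index, name=f"p_{treat}_vs_{ctrl}")


# ---------------------------------------------------------------------------
# Multiple testing and filtering

def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1; ties share the adjusted
    value through the rank ordering.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def de_table(
    cm: CountMatrix,
    contrast: tuple[str, str],
    pseudocount: float = 1.0,
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Full DE analysis for one contrast: normalization, fold change, NB LRT
    and BH-FDR.  Returns gene_id, base_mean, log2fc, p_value, q_value,
    contrast."""
    treat, ctrl = contrast
    if factors is None:
        factors = size_factors(cm.counts)
    cols = cm.samples_of(ctrl) + cm.samples_of(treat)
    norm = normalized_counts(cm.counts[cols], factors[cols])
    lfc = log2fc_median_norm(cm.counts, cm.groups, contrast, pseudocount, factors)
    p = nb_lrt_test(cm.counts, cm.groups, contrast, factors)
    return pd.DataFrame(
        {
            "gene_id": cm.gene_ids,
            "base_mean": norm.mean(axis=1).to_numpy(),
            "log2fc": lfc.to_numpy(),
            "p_value": p.to_numpy(),
            "q_value": bh_adjust(p.to_numpy()),
            "contrast": f"{treat}_vs_{ctrl}",
        }
    ).reset_index(drop=True)


def filter_degs(
    records: pd.DataFrame, lfc_min: float = 1.0, q_max: float = 0.05
) -> pd.DataFrame:
    """Keep records with |log2fc| > lfc_min and q < q_max; label direction."""
    if lfc_min <= 0 or q_max <= 0:
        raise ValueError("thresholds must be positive")
    keep = (records["log2fc"].abs() > lfc_min) & (records["q_value"] < q_max)
    out = records.loc[keep].copy()
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    return out


# ---------------------------------------------------------------------------
# TSV interfaces

def write_counts_tsv(cm: CountMatrix, path: str | Path) -> Path:
    path = Path(path)
    cm.counts.to_csv(path, sep="\t", index_label="gene_id")
    return path


def read_counts_tsv(counts_path: str | Path, design_path: str | Path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    design = read_design_tsv(design_path)
    return CountMatrix(counts, design)


def write_design_tsv(groups: Mapping[str, str], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"sample": list(groups), "group": [groups[s] for s in groups]}
    ).to_csv(path, sep="\t", index=False)
    return path


def read_design_tsv(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["sample"], df["group"]))
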