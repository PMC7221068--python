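"""Negative-binomial Wald differential expression with three normalization
regimes.

The engine mirrors standard bulk RNA-seq DE practice (NB count model, log
link, median-of-ratios size factors, BH adjustment) with two additions needed
for hybrid allele-specific analysis:

* cross-species contrasts use a genes x samples normalization-factor matrix
  that combines ortholog gene lengths with library size, so length differences
  between ortholog copies do not masquerade as expression differences;
* within-hybrid (homeolog) contrasts use *allele length factors only* —
  the two allele columns of a hybrid sample come from the same library, so
  library size must not be re-normalized; per gene the factors are the allele
  lengths divided by their geometric mean across samples (geometric mean 1 by
  construction).

The per-gene test is a two-group NB GLM fitted by Newton iteration on the
group log-mean with the normalization factors as offsets:
score ``U = sum (y - mu) / (1 + alpha mu)``, Fisher information
``I = sum mu / (1 + alpha mu)``; ``l2fc`` is the MLE difference of group
log2-means (no shrinkage) with a two-sided Wald p-value — normal reference for
known dispersions, t reference with the estimation df when the dispersion was
estimated from the data.

Calling uses strict inequalities: ``|l2fc| > 1.5`` and ``padj < 0.01`` by
default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

ALPHA_FLOOR = 1e-8
LN2 = np.log(2.0)


# ----------------------------------------------------------- normalization
def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Per sample, the median over all-positive genes of count / per-gene
    geometric mean.
    """
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has nonzero counts in all samples")
    sub = arr[positive]
    log_geo = np.log(sub).mean(axis=1, keepdims=True)
    ratios = sub / np.exp(log_geo)
    sf = np.median(ratios, axis=0)
    sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def allele_length_factors(lengths: pd.DataFrame) -> pd.DataFrame:
    """Per-gene length factors with no library-size component.

    ``factor[g, s] = length[g, s] / geomean_s(length[g, .])`` — the geometric
    mean of each gene's factors across samples is 1, so only relative allele
    length enters the model.
    """
    arr = lengths.to_numpy(dtype=float)
    if (arr <= 0).any():
        raise ValueError("all lengths must be > 0")
    geo = np.exp(np.log(arr).mean(axis=1, keepdims=True))
    return pd.DataFrame(arr / geo, index=lengths.index, columns=lengths.columns)


def length_and_library_factors(lengths: pd.DataFrame,
                               counts: pd.DataFrame) -> pd.DataFrame:
    """Length factors multiplied by size factors of length-corrected counts.

    The between-species regime: ortholog copies may differ in length *and*
    samples differ in depth.
    """
    lf = allele_length_factors(lengths)
    corrected = counts / lf
    sf = size_factors(corrected.round().clip(lower=0))
    return lf * sf.to_numpy()[None, :]


@dataclass
class NormalizationSpec:
    """Resolved normalization for one contrast: a genes x samples factor matrix."""

    mode: str  # library_size | length_and_library | allele_length_only
    factors: pd.DataFrame

    @classmethod
    def build(cls, mode: str, counts: pd.DataFrame,
              lengths: pd.DataFrame | None = None) -> "NormalizationSpec":
        if mode == "library_size":
            sf = size_factors(counts)
            fac = pd.DataFrame(np.tile(sf.to_numpy(), (len(counts), 1)),
                               index=counts.index, columns=counts.columns)
        elif mode == "length_and_library":
            if lengths is None:
                raise ValueError("length_and_library mode requires gene lengths")
            fac = length_and_library_factors(lengths, counts)
        elif mode == "allele_length_only":
            if lengths is None:
                raise ValueError("allele_length_only mode requires gene lengths")
            fac = allele_length_factors(lengths)
        else:
            raise ValueError(f"unknown normalization mode {mode!r}")
        return cls(mode=mode, factors=fac)


# -------------------------------------------------------------- dispersion
def estimate_dispersion(counts: pd.DataFrame, factors: pd.DataFrame,
                        groups: pd.Series, shrink: float = 0.0,
                        floor_at_trend: bool = True) -> pd.Series:
    """Per-gene NB dispersion by method of moments on normalized counts.

    Within each group (>= 2 replicates required) ``alpha = (s2 - m) / m^2`` on
    ``y / factor``; group estimates are pooled with ``n - 1`` weights and
    floored at 1e-8. A log-log mean-dispersion trend is then fitted across
    genes and, with ``floor_at_trend`` (default), gene-wise estimates below
    the trend are raised to it: at few replicates the moment estimator is
    noisy, and an underestimated dispersion makes the Wald test
    anticonservative, so only upward deviations from the trend are trusted
    (``shrink`` > 0 additionally interpolates toward the trend in log space
    before flooring, for callers that prefer symmetric pooling).
    """
    groups = pd.Series(groups, index=counts.columns)
    z = counts.to_numpy(dtype=float) / factors.to_numpy(dtype=float)
    num = np.zeros(len(counts))
    den = 0.0
    mu_all = z.mean(axis=1)
    for g in groups.unique():
        cols = np.where(groups.to_numpy() == g)[0]
        if len(cols) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 replicates")
        zg = z[:, cols]
        m = zg.mean(axis=1)
        s2 = zg.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(m > 0, (s2 - m) / np.maximum(m, 1e-12) ** 2, 0.0)
        num += a * (len(cols) - 1)
        den += len(cols) - 1
    raw = np.maximum(num / den, ALPHA_FLOOR)

    out = raw
    ok = (raw > 1e-6) & (mu_all > 0)
    if (shrink > 0 or floor_at_trend) and ok.sum() >= 10:
        slope, intercept = np.polyfit(np.log(mu_all[ok]), np.log(raw[ok]), 1)
        trend = np.maximum(
            np.exp(intercept + slope * np.log(np.maximum(mu_all, 1e-12))),
            ALPHA_FLOOR)
        if shrink > 0:
            out = np.exp((1 - shrink) * np.log(raw) + shrink * np.log(trend))
        if floor_at_trend:
            out = np.maximum(out, trend)
    return pd.Series(np.maximum(out, ALPHA_FLOOR), index=counts.index,
                     name="dispersion")


# ------------------------------------------------------------------- Wald
def _fit_group_log_mean(y: np.ndarray, f: np.ndarray, alpha: np.ndarray,
                        n_iter: int = 60, tol: float = 1e-10):
    """Vectorized Newton fit of the per-gene group log-mean with offsets.

    Returns (beta, fisher_info, flag) where ``flag`` marks groups with zero
    total counts (fitted with a half-count floor)."""
    total = y.sum(axis=1)
    fsum = f.sum(axis=1)
    zero = total <= 0
    beta = np.log(np.maximum(total, 0.5) / fsum)
    a = alpha[:, None]
    for _ in range(n_iter):
        mu = f * np.exp(beta)[:, None]
        denom = 1.0 + a * mu
        u = ((y - mu) / denom).sum(axis=1)
        info = (mu / denom).sum(axis=1)
        step = u / np.maximum(info, 1e-12)
        step = np.clip(step, -5.0, 5.0)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    beta = np.where(zero, np.log(0.5 / fsum), beta)
    mu = f * np.exp(beta)[:, None]
    info = (mu / (1.0 + a * mu)).sum(axis=1)
    return beta, info, zero


def nb_wald(counts: pd.DataFrame, groups: pd.Series, norm: NormalizationSpec,
            dispersions: pd.Series, numerator: str, denominator: str,
            name: str = "", df: float | None = None) -> pd.DataFrame:
    """Two-group NB Wald test per gene.

    Returns a ContrastResult frame with columns ``base_mean, l2fc, se, p,
    note`` (``padj`` is added by :func:`adjust_bh`). ``l2fc`` is
    log2(numerator / denominator). With known dispersions the p-value is
    two-sided normal on ``l2fc / se``; when the caller estimated the
    dispersions it should pass their residual degrees of freedom as ``df``,
    which switches the reference to a t distribution to absorb the estimation
    uncertainty. Genes with all-zero counts get l2fc 0 and p 1; genes empty on
    one side are flagged ``zero_num``/``zero_den`` and fitted against a
    half-count floor rather than failing.
    """
    groups = pd.Series(groups, index=counts.columns)
    for g in (numerator, denominator):
        if (groups == g).sum() == 0:
            raise ValueError(f"group {g!r} has no samples")
    y = counts.to_numpy(dtype=float)
    f = norm.factors.to_numpy(dtype=float)
    alpha = dispersions.reindex(counts.index).to_numpy(dtype=float)

    cols_n = groups.to_numpy() == numerator
    cols_d = groups.to_numpy() == denominator
    b1, i1, z1 = _fit_group_log_mean(y[:, cols_n], f[:, cols_n], alpha)
    b2, i2, z2 = _fit_group_log_mean(y[:, cols_d], f[:, cols_d], alpha)

    l2fc = (b1 - b2) / LN2
    se = np.sqrt(1.0 / np.maximum(i1, 1e-12) + 1.0 / np.maximum(i2, 1e-12)) / LN2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = l2fc / se
    if df is None:
        p = 2.0 * stats.norm.sf(np.abs(z))
    else:
        p = 2.0 * stats.t.sf(np.abs(z), df=df)

    used = cols_n | cols_d
    base_mean = (y[:, used] / f[:, used]).mean(axis=1)
    all_zero = z1 & z2
    l2fc = np.where(all_zero, 0.0, l2fc)
    p = np.where(all_zero, 1.0, p)
    note = np.where(all_zero, "all_zero",
                    np.where(z1, "zero_num", np.where(z2, "zero_den", "")))

    return pd.DataFrame({
        "base_mean": base_mean, "l2fc": l2fc, "se": se, "p": p, "note": note,
        "contrast": name or f"{numerator}_vs_{denominator}",
    }, index=counts.index)


# ------------------------------------------------------ multiple testing
def adjust_bh(p: pd.Series | np.ndarray) -> pd.Series:
    """Benjamini–Hochberg step-up adjusted p-values (NaNs pass through)."""
    s = pd.Series(np.asarray(p, dtype=float),
                  index=getattr(p, "index", None))
    if ((s < 0) | (s > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    out = pd.Series(np.nan, index=s.index)
    ok = s.notna()
    if ok.any():
        out[ok] = multipletests(s[ok].to_numpy(), method="fdr_bh")[1]
    return out


def call_de(result: pd.DataFrame, l2fc_min: float = 1.5,
            padj_max: float = 0.01, base_mean_min: float | None = None
            ) -> pd.DataFrame:
    """Genes passing the strict thresholds, with direction labels.

    DE iff ``|l2fc| > l2fc_min`` and ``padj < padj_max`` (both strict);
    ``base_mean_min`` adds the optional mean-normalized-expression filter.
    """
    if "padj" not in result.columns:
        raise ValueError("result has no padj column; run adjust_bh first")
    mask = (result["l2fc"].abs() > l2fc_min) & (result["padj"] < padj_max)
    if base_mean_min is not None:
        mask &= result["base_mean"] > base_mean_min
    out = result[mask.fillna(False)].copy()
    out["direction"] = np.where(out["l2fc"] > 0, "up", "down")
    return out


# ------------------------------------------------------------ convenience
def dispersion_df(groups: pd.Series) -> int:
    """Residual degrees of freedom of the grouped moment estimator."""
    groups = pd.Series(groups)
    return int(sum(n - 1 for n in groups.value_counts()))


def run_de(counts: pd.DataFrame, groups: pd.Series, numerator: str,
           denominator: str, mode: str = "library_size",
           lengths: pd.DataFrame | None = None,
           dispersions: pd.Series | None = None, shrink: float = 0.0,
           name: str = "", df: float | None = None) -> pd.DataFrame:
    """Normalize, estimate dispersion, Wald-test, and BH-adjust in one call.

    When dispersions are estimated here, the test uses a t reference with the
    estimator's residual df (see :func:`nb_wald`); caller-supplied dispersions
    are treated as known (normal reference) unless ``df`` is given.
    """
    norm = NormalizationSpec.build(mode, counts, lengths)
    if dispersions is None:
        dispersions = estimate_dispersion(counts, norm.factors, groups,
                                          shrink=shrink)
        if df is None:
            df = dispersion_df(groups)
    res = nb_wald(counts, groups, norm, dispersions, numerator, denominator,
                  name=name, df=df)
    res["padj"] = adjust_bh(res["p"])
    return res
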