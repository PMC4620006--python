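"""Mixed-model genome-wide association with kinship and structure covariates.

The model is the single-random-effect mixed linear model

.. math::

    y = W\\alpha + x\\beta + u + \\varepsilon,\\qquad
    u \\sim N(0, \\sigma_g^2 K),\\ \\varepsilon \\sim N(0, \\sigma_e^2 I)

with *W* the fixed covariates (intercept plus structure covariates, e.g.
principal components) and *K* the kinship matrix.  The variance ratio
:math:`\\lambda = \\sigma_g^2/\\sigma_e^2` is estimated once by restricted
maximum likelihood on the null model (no SNP) through the eigendecomposition
of *K*, then held fixed while each SNP is tested by generalized least
squares on the rotated data — the population-parameters-previously-
determined (P3D) scheme.  With K = I this reduces exactly to ordinary
least-squares regression.

Significance uses the Bonferroni cutoff −log10(alpha / n_markers); SNPs are
called QTNs when −log10 p strictly exceeds it.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotype_io import GenotypeMatrix

__all__ = [
    "significance_threshold",
    "mlm_gwas",
    "call_qtns",
    "colocalize",
    "genomic_inflation",
]


def significance_threshold(alpha: float, n_markers: int) -> float:
    """Bonferroni threshold on the −log10 p scale: −log10(alpha / n_markers)."""
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must lie in (0, 1]")
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    return -math.log10(alpha / n_markers)


def _psd_repair(k: np.ndarray):
    """Symmetrize and clip negative eigenvalues so K is positive semi-definite."""
    k = (k + k.T) / 2.0
    w, u = np.linalg.eigh(k)
    if w.min() < -1e-10:
        w = np.maximum(w, 0.0)
    return u, np.maximum(w, 0.0)


def _reml_neg_loglik(log_lam, w_eig, yr, wr):
    """Negative restricted log-likelihood at variance ratio λ = exp(log_lam).

    Operates in the eigenbasis of K: V = λK + I has eigenvalues λw + 1.
    """
    lam = math.exp(log_lam)
    d = lam * w_eig + 1.0
    n, q = wr.shape
    wd = wr / d[:, None]
    wtw = wr.T @ wd
    try:
        wtw_inv = np.linalg.inv(wtw)
    except np.linalg.LinAlgError:
        return np.inf
    beta = wtw_inv @ (wd.T @ yr)
    r = yr - wr @ beta
    quad = float(r @ (r / d))
    df = n - q
    sigma2 = quad / df
    _, logdet_wtw = np.linalg.slogdet(wtw)
    _, logdet_wtw0 = np.linalg.slogdet(wr.T @ wr)
    ll = -0.5 * (
        df * math.log(2.0 * math.pi * sigma2)
        + float(np.sum(np.log(d)))
        + logdet_wtw
        - logdet_wtw0
        + df
    )
    return -ll


def mlm_gwas(genotypes: GenotypeMatrix, phenotype: pd.Series, kinship,
             covariates: pd.DataFrame | None = None, snp_map: pd.DataFrame | None = None,
             alpha: float = 0.05, min_accessions: int = 30) -> pd.DataFrame:
    """P3D mixed-model association scan over all SNPs for one trait.

    ``kinship`` may be a :class:`~popdiff.popgen_stats.KinshipMatrix`, a
    DataFrame or an array (raw, unclamped values are used when available).
    Returns a table with snp_id, effect, se, p_value, neg_log10_p and a
    ``significant`` flag at the Bonferroni threshold over tested markers;
    the fitted variance ratio and threshold are stored in ``.attrs``.
    """
    from .popgen_stats import KinshipMatrix

    pheno = phenotype.reindex(genotypes.accession_ids).astype(float)
    keep = np.flatnonzero(~pheno.isna().values)
    if keep.size < min_accessions:
        raise ValueError(
            f"only {keep.size} accessions with phenotype + genotype (need >= {min_accessions})"
        )
    gm = genotypes.take_accessions(keep)
    y = pheno.values[keep]

    if isinstance(kinship, KinshipMatrix):
        kdf = pd.DataFrame(kinship.raw, index=kinship.accession_ids,
                           columns=kinship.accession_ids)
    elif isinstance(kinship, pd.DataFrame):
        kdf = kinship
    else:
        kdf = pd.DataFrame(np.asarray(kinship, dtype=float),
                           index=genotypes.accession_ids, columns=genotypes.accession_ids)
    k = kdf.loc[gm.accession_ids, gm.accession_ids].values.astype(float)

    n = len(y)
    w_cols = [np.ones(n)]
    if covariates is not None:
        cov = covariates.reindex(gm.accession_ids)
        for name in cov.columns:
            col = cov[name].values.astype(float)
            w_cols.append(col)
    w = np.column_stack(w_cols)
    # drop collinear covariates
    rank = np.linalg.matrix_rank(w)
    while rank < w.shape[1]:
        warnings.warn("singular covariate matrix; dropping the last covariate")
        w = w[:, :-1]
        rank = np.linalg.matrix_rank(w)

    u, w_eig = _psd_repair(k)
    yr = u.T @ y
    wr = u.T @ w

    res = optimize.minimize_scalar(
        _reml_neg_loglik, bounds=(math.log(1e-6), math.log(1e6)),
        args=(w_eig, yr, wr), method="bounded",
        options={"xatol": 1e-6},
    )
    lam = math.exp(res.x)
    d = lam * w_eig + 1.0
    scale = 1.0 / np.sqrt(d)

    # rotate once (P3D): V^{-1/2} = diag(1/sqrt(λw+1)) in the eigenbasis
    yt = yr * scale
    wt = wr * scale[:, None]
    x = gm.dosage_float()
    col_mean = np.nanmean(x, axis=0)
    inds = np.where(np.isnan(x))
    x[inds] = np.take(col_mean, inds[1])
    xt = (u.T @ x) * scale[:, None]

    qmat, _ = np.linalg.qr(wt)
    yres = yt - qmat @ (qmat.T @ yt)
    xres = xt - qmat @ (qmat.T @ xt)

    xx = np.einsum("ij,ij->j", xres, xres)
    xy = xres.T @ yres
    yy = float(yres @ yres)
    q = wt.shape[1]
    df = n - q - 1
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = xy / xx
        rss = yy - beta * xy
        sigma2 = rss / df
        se = np.sqrt(sigma2 / xx)
        tstat = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
    mono = xx <= 1e-12
    if mono.any():
        warnings.warn(f"{int(mono.sum())} monomorphic SNPs skipped")
    pvals = np.where(mono, np.nan, pvals)
    beta = np.where(mono, np.nan, beta)
    se = np.where(mono, np.nan, se)

    n_tested = int((~mono).sum())
    threshold = significance_threshold(alpha, max(n_tested, 1))
    with np.errstate(divide="ignore"):
        nlp = -np.log10(pvals)
    out = pd.DataFrame(
        {
            "snp_id": gm.snp_ids,
            "effect": beta,
            "se": se,
            "p_value": pvals,
            "neg_log10_p": nlp,
            "significant": nlp > threshold,
        }
    )
    if snp_map is not None:
        smap = snp_map.set_index("snp_id")
        out.insert(1, "chrom", [smap.at[s, "chrom"] for s in out["snp_id"]])
        out.insert(2, "pos", [int(smap.at[s, "pos"]) for s in out["snp_id"]])
    out.attrs["lambda"] = lam
    out.attrs["heritability_null"] = lam / (1.0 + lam)
    out.attrs["threshold"] = threshold
    out.attrs["n_tested"] = n_tested
    return out


def call_qtns(results: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """SNPs whose −log10 p strictly exceeds ``threshold``, sorted by p-value."""
    if results.empty:
        raise ValueError("results table is empty")
    hits = results[results["neg_log10_p"] > threshold]
    return hits.sort_values("p_value", kind="stable").reset_index(drop=True)


def colocalize(qtns: pd.DataFrame, regions: pd.DataFrame, snp_map: pd.DataFrame,
               window_bp: int = 0) -> pd.DataFrame:
    """Assign QTNs to differentiated regions by position.

    A QTN is ``inside`` a region when its position lies within the region's
    1-based inclusive interval; when within ``window_bp`` of a region
    boundary it is ``near``; otherwise ``none``.  QTNs without a map position
    are skipped with a warning.
    """
    smap = snp_map.set_index("snp_id")
    rows = []
    for _, qtn in qtns.iterrows():
        sid = qtn["snp_id"]
        if sid not in smap.index:
            warnings.warn(f"QTN {sid} has no map position; skipped")
            continue
        chrom = smap.at[sid, "chrom"]
        pos = int(smap.at[sid, "pos"])
        regs = regions[regions["chrom"] == chrom]
        inside = regs[(regs["start"] <= pos) & (pos <= regs["end"])]
        near = regs[(regs["start"] - window_bp <= pos) & (pos <= regs["end"] + window_bp)]
        if len(inside):
            relation, reg = "inside", inside.iloc[0]
        elif window_bp > 0 and len(near):
            relation, reg = "near", near.iloc[0]
        else:
            relation, reg = "none", None
        rows.append(
            {
                "snp_id": sid,
                "chrom": chrom,
                "pos": pos,
                "relation": relation,
                "region_start": int(reg["start"]) if reg is not None else -1,
                "region_end": int(reg["end"]) if reg is not None else -1,
            }
        )
    return pd.DataFrame(
        rows, columns=["snp_id", "chrom", "pos", "relation", "region_start", "region_end"]
    )


def genomic_inflation(p_values) -> float:
    """Genomic-control λ: median association chi-square over its null median."""
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))
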