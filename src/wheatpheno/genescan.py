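"""Marker-trait association in a biparental RIL population.

Because a biparental RIL population carries neither population structure nor
family kinship beyond the cross itself, the single-marker model reduces to a
simple regression of the line phenotype on genotype dose,

    y_i = beta_k x_ik + e,

with a two-sided t-test per marker and Bonferroni control of the family-wise
error at alpha = 0.05.  Markers significant in the scan are then tested for
all pairwise epistatic interactions with the model

    y_i = alpha_j x_ij + beta_k x_ik + eps_jk x_ij x_ik + e,

comparing the full against the additive model by F-test, with
LOD = (n/2) log10(RSS_additive / RSS_full).  The module also provides the
paper-standard marker filters (MAF, missingness, heterozygosity), the 3:1
two-gene dominant-epistasis segregation chi-square, and G-BLUP
cross-validation for polygenic traits using a VanRaden genomic relationship
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .core import GenotypeMatrix, rng_for


def marker_stats(G: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker allele frequency, MAF, missing fraction and heterozygosity."""
    dose = G.dose
    obs = ~np.isnan(dose)
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.nansum(dose, axis=0) / (2.0 * n_obs)
        het = np.nansum(dose == 1.0, axis=0) / n_obs
    maf = np.minimum(freq, 1.0 - freq)
    return pd.DataFrame(
        {
            "marker": G.marker_ids,
            "freq_b": freq,
            "maf": maf,
            "missing": 1.0 - n_obs / G.n_lines,
            "het": het,
        }
    )


def filter_markers(
    G: GenotypeMatrix,
    maf_min: float = 0.1,
    miss_max: float = 0.30,
    het_max: float = 0.06,
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Drop markers with MAF < ``maf_min``, missingness > ``miss_max`` or
    heterozygosity > ``het_max``; returns the filtered matrix and per-rule
    removal counts (a marker can count against several rules)."""
    st = marker_stats(G)
    fail_maf = (st["maf"] < maf_min) | st["maf"].isna()
    fail_miss = st["missing"] > miss_max
    fail_het = (st["het"] > het_max) & ~st["het"].isna()
    keep = ~(fail_maf | fail_miss | fail_het)
    report = {
        "n_input": G.n_markers,
        "removed_maf": int(fail_maf.sum()),
        "removed_missing": int(fail_miss.sum()),
        "removed_het": int(fail_het.sum()),
        "n_retained": int(keep.sum()),
    }
    idx = np.flatnonzero(keep.to_numpy())
    out = GenotypeMatrix(
        line_ids=list(G.line_ids),
        markers=G.markers.iloc[idx].reset_index(drop=True),
        dose=G.dose[:, idx],
    )
    return out, report


def bonferroni_threshold(alpha: float = 0.05, m: int = 1) -> float:
    """Per-test p-value threshold controlling family-wise error over m tests."""
    if m < 1:
        raise ValueError("need at least one test")
    return alpha / m


def _scan_doses(G: GenotypeMatrix, het: str) -> np.ndarray:
    X = G.dose.copy()
    if het == "missing":
        X[X == 1.0] = np.nan
    elif het != "midpoint":
        raise ValueError("het must be 'missing' or 'midpoint'")
    return X


def marker_scan(
    y: np.ndarray,
    G: GenotypeMatrix,
    alpha: float = 0.05,
    het: str = "missing",
    min_lines: int = 10,
) -> pd.DataFrame:
    """Single-marker regression scan of a per-line trait.

    Heterozygous calls are set missing by default (the tested effect is an
    allele substitution between homozygote classes); ``het="midpoint"`` keeps
    them at dose 1.  Returns per-marker effect, SE, p, -log10 p and a
    significance flag at the Bonferroni threshold alpha / m.  Monomorphic or
    under-observed markers get p = 1 and an NaN effect.
    """
    y = np.asarray(y, dtype=float)
    if y.size != G.n_lines:
        raise ValueError("phenotype length must match line count")
    X = _scan_doses(G, het)
    M = (~np.isnan(X)) & (~np.isnan(y))[:, None]
    Xz = np.where(M, X, 0.0)
    yz = np.where(np.isnan(y), 0.0, y)
    n = M.sum(axis=0).astype(float)
    sx = Xz.sum(axis=0)
    sy = M.T @ yz
    sxx = (Xz**2).sum(axis=0)
    sxy = Xz.T @ yz
    syy = M.T @ (yz**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        Sxx = sxx - sx**2 / n
        Sxy = sxy - sx * sy / n
        Syy = syy - sy**2 / n
        beta = Sxy / Sxx
        rss = Syy - beta * Sxy
        df = n - 2.0
        se = np.sqrt(np.maximum(rss, 0.0) / np.maximum(df, 1.0) / Sxx)
        tstat = beta / se
    testable = (n >= min_lines) & (Sxx > 1e-12) & (df > 0)
    p = np.ones(G.n_markers)
    p[testable] = 2.0 * stats.t.sf(np.abs(tstat[testable]), df[testable])
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    beta = np.where(testable, beta, np.nan)
    se = np.where(testable, se, np.nan)
    m_tests = int(testable.sum())
    thresh = bonferroni_threshold(alpha, max(m_tests, 1))
    out = G.markers.copy()
    out["n"] = n.astype(int)
    out["effect"] = beta
    out["se"] = se
    out["p"] = p
    out["neglog10p"] = -np.log10(p)
    out["significant"] = testable & (p < thresh)
    out.attrs["threshold"] = thresh
    out.attrs["n_tested"] = m_tests
    return out


def epistasis_scan(
    y: np.ndarray,
    G: GenotypeMatrix,
    marker_indices: list[int],
    alpha: float = 0.05,
    het: str = "missing",
) -> pd.DataFrame:
    """Two-way epistasis among a subset of (typically scan-significant) markers.

    For each unordered pair, fits the full model (intercept, two mains,
    product interaction) and the additive model, tests the interaction by
    F-test and reports LOD = (n/2) log10(RSS_additive / RSS_full), with
    Bonferroni over the number of tested pairs.  Perfectly collinear pairs
    are skipped with a flag.
    """
    idx = sorted(set(int(i) for i in marker_indices))
    if len(idx) < 2:
        raise ValueError("need at least 2 markers for an epistasis scan")
    y = np.asarray(y, dtype=float)
    X = _scan_doses(G, het) - 1.0  # symmetric {-1, 0, 1} coding
    rows = []
    for a_i, j in enumerate(idx):
        for k in idx[a_i + 1:]:
            mask = ~np.isnan(X[:, j]) & ~np.isnan(X[:, k]) & ~np.isnan(y)
            xj, xk, yy = X[mask, j], X[mask, k], y[mask]
            n = yy.size
            rec = {
                "marker_j": G.marker_ids[j], "marker_k": G.marker_ids[k],
                "index_j": j, "index_k": k, "n": n,
            }
            r = np.corrcoef(xj, xk)[0, 1] if xj.std() > 0 and xk.std() > 0 else 1.0
            if n < 5 or abs(r) > 1.0 - 1e-10:
                rows.append({**rec, "alpha_j": np.nan, "beta_k": np.nan, "epsilon": np.nan,
                             "p_interaction": np.nan, "lod": np.nan, "skipped": True})
                continue
            Xf = np.column_stack([np.ones(n), xj, xk, xj * xk])
            Xr = Xf[:, :3]
            cf, rss_f = _ols_rss(Xf, yy)
            _, rss_r = _ols_rss(Xr, yy)
            df_full = n - 4
            F = max(rss_r - rss_f, 0.0) / max(rss_f / df_full, 1e-300)
            p_int = float(stats.f.sf(F, 1, df_full))
            lod = (n / 2.0) * np.log10(max(rss_r, 1e-300) / max(rss_f, 1e-300))
            rows.append({**rec, "alpha_j": cf[1], "beta_k": cf[2], "epsilon": cf[3],
                         "p_interaction": p_int, "lod": max(lod, 0.0), "skipped": False})
    out = pd.DataFrame(rows)
    n_pairs = int((~out["skipped"]).sum())
    thresh = bonferroni_threshold(alpha, max(n_pairs, 1))
    out["significant"] = (~out["skipped"]) & (out["p_interaction"] < thresh)
    out.attrs["threshold"] = thresh
    out.attrs["n_pairs"] = n_pairs
    return out


def _ols_rss(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    coef, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if res.size:
        return coef, float(res[0])
    fit = X @ coef
    return coef, float(np.sum((y - fit) ** 2))


def segregation_test(
    n_early: int, n_late: int, probs: tuple[float, float] = (0.75, 0.25)
) -> tuple[float, float]:
    """Pearson chi-square (1 df) of an early/late count split against expected
    class proportions; the 0.75/0.25 default is the two-gene dominant-epistasis
    expectation for inbred lines."""
    total = n_early + n_late
    if total < 1:
        raise ValueError("need at least one line")
    expected = np.array(probs, dtype=float) * total
    chi2, p = stats.chisquare([n_early, n_late], f_exp=expected)
    return float(chi2), float(p)


def dominant_epistasis_proportions() -> tuple[float, float]:
    """Expected early:late proportions under two-gene dominant epistasis in
    inbred lines, by enumeration of the four equal-frequency two-locus
    homozygote classes (one class distinct, three alike)."""
    classes = [(a, b) for a in (0, 1) for b in (0, 1)]
    late = sum(1 for a, b in classes if a == 1 and b == 1)
    early = len(classes) - late
    return early / len(classes), late / len(classes)


# ---------------------------------------------------------------------------
# genomic prediction


def genomic_relationship(G: GenotypeMatrix) -> np.ndarray:
    """VanRaden genomic relationship matrix from centered, frequency-scaled
    doses; missing calls are mean-imputed for the relationship only."""
    dose = G.dose.copy()
    freq = np.nanmean(dose, axis=0) / 2.0
    inds = np.where(np.isnan(dose))
    dose[inds] = np.take(2.0 * freq, inds[1])
    W = dose - 2.0 * freq
    denom = 2.0 * np.sum(freq * (1.0 - freq))
    if denom <= 0:
        raise ValueError("all markers monomorphic; relationship undefined")
    return (W @ W.T) / denom


def gblup_solve(
    K: np.ndarray, y_train: np.ndarray, train: np.ndarray, lam: float
) -> np.ndarray:
    """Genetic-value predictions for all individuals from training phenotypes.

    Solves the single-random-effect mixed model with relationship K and
    variance ratio lam = s2_e / s2_g:  g_hat = K[:, train] (K_tt + lam I)^{-1}
    (y_train - mu), shifted by the GLS mean mu.
    """
    Ktt = K[np.ix_(train, train)]
    n_t = train.size
    A = Ktt + lam * np.eye(n_t)
    Ai_y = np.linalg.solve(A, y_train)
    Ai_1 = np.linalg.solve(A, np.ones(n_t))
    mu = float(np.ones(n_t) @ Ai_y) / float(np.ones(n_t) @ Ai_1)
    g = K[:, train] @ np.linalg.solve(A, y_train - mu)
    return mu + g


def _reml_lambda(K: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """REML variance ratio and genomic h2 for y = mu + g + e, g ~ N(0, s2_g K),
    via a single eigendecomposition of K (spectral form of the likelihood)."""
    n = y.size
    vals, vecs = np.linalg.eigh(K)
    vals = np.maximum(vals, 0.0)
    yt = vecs.T @ y
    ones_t = vecs.T @ np.ones(n)

    def nll(log_lam: float) -> float:
        lam = np.exp(log_lam)
        d = vals + lam  # V = s2_g (K + lam I); profile out s2_g
        xvx = float(np.sum(ones_t**2 / d))
        beta = float(np.sum(ones_t * yt / d)) / xvx
        quad = float(np.sum((yt - beta * ones_t) ** 2 / d))
        s2g = quad / (n - 1)
        return 0.5 * (np.sum(np.log(d)) + np.log(xvx) + (n - 1) * np.log(s2g) + (n - 1))

    res = minimize_scalar(nll, bounds=(-10.0, 10.0), method="bounded",
                          options={"xatol": 1e-8})
    lam = float(np.exp(res.x))
    # genomic h2 on the observed scale: s2_g * mean diag(K) / (s2_g * mean diag(K) + s2_e)
    mean_k = float(np.mean(np.diag(K)))
    return lam, mean_k / (mean_k + lam)


@dataclass(frozen=True)
class PredictionCV:
    """Cross-validation summary for whole-genome prediction."""

    method: str
    reps: int
    mask_fraction: float
    mean_r: float
    sd_r: float
    ci_r: tuple[float, float]
    h2: float
    variance_modeled: float  # mean predictive r^2 / H2
    per_rep_r: np.ndarray


def genomic_prediction_cv(
    y: np.ndarray,
    G: GenotypeMatrix,
    method: str = "gblup",
    mask_fraction: float = 0.10,
    reps: int = 100,
    seed: int = 0,
    h2: float | None = None,
) -> PredictionCV:
    """Repeated random-masking cross-validation of whole-genome prediction.

    Per replicate, ``mask_fraction`` of the lines are masked, a G-BLUP model
    (VanRaden relationship, REML variance ratio estimated on the training
    lines) is fit on the rest, and the masked lines are predicted.  Reports
    the mean and 95% interval of the predictive correlation r and the fraction
    of heritable variance modeled, mean(r)^2 / H2, against a supplied or
    genomic-REML H2 estimate.
    """
    if method != "gblup":
        raise ValueError("only method='gblup' is implemented")
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 30:
        raise ValueError("need at least 30 lines for cross-validation")
    K = genomic_relationship(G)
    if h2 is None:
        _, h2 = _reml_lambda(K, y)
    rng = rng_for(seed, 201)
    n_mask = max(1, int(round(mask_fraction * n)))
    rs = np.empty(reps)
    for rep in range(reps):
        perm = rng.permutation(n)
        test, train = perm[:n_mask], perm[n_mask:]
        lam, _ = _reml_lambda(K[np.ix_(train, train)], y[train])
        pred = gblup_solve(K, y[train], train, lam)
        rs[rep] = np.corrcoef(pred[test], y[test])[0, 1] if n_mask > 1 else np.nan
    mean_r = float(np.nanmean(rs))
    sd_r = float(np.nanstd(rs, ddof=1))
    ci = (float(np.nanpercentile(rs, 2.5)), float(np.nanpercentile(rs, 97.5)))
    vm = float(mean_r**2 / h2) if h2 > 0 else float("nan")
    return PredictionCV(
        method=method, reps=reps, mask_fraction=mask_fraction, mean_r=mean_r,
        sd_r=sd_r, ci_r=ci, h2=float(h2), variance_modeled=vm, per_rep_r=rs,
    )
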