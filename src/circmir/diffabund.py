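"""Negative-binomial differential abundance between clinical groups.

Counts are modelled NB with a single common dispersion phi
(variance = mu + phi * mu^2). Two tests are provided:

* an exact two-group test: after scaling every sample to the geometric-mean
  library depth ("pseudo-counts"), the two group sums are NB with sizes
  n_g / phi; conditioning on their total, the two-sided p-value doubles the
  smaller tail of the conditional distribution (observed point included),
  capped at 1. As phi -> 0 this reduces to the conditional binomial test.
* an NB log-linear model fitted by IRLS at fixed phi with log-library-size
  offsets, testing the group coefficient by a likelihood-ratio chi-square
  with 1 df against a covariate-only null — used for the 'multivariate'
  comparison adjusting for the chemotherapy regimen.

The common dispersion is estimated by maximising the conditional NB
log-likelihood summed over genes and groups on depth-equalised counts, and
multiplicity is controlled by Benjamini-Hochberg step-up FDR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln

__all__ = [
    "Dispersion",
    "group_log2_fold",
    "pseudo_counts",
    "estimate_common_dispersion",
    "nb_exact_test",
    "nb_glm_lrt",
    "bh_fdr",
    "differential_table",
]

PHI_MIN = 1e-6
PHI_MAX = 10.0
FDR_PRESETS = {"strict": 0.05, "standard": 0.1}


@dataclass(frozen=True)
class Dispersion:
    """Common NB dispersion phi; variance = mu + phi * mu^2."""

    phi: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.phi) or self.phi < 0:
            raise ValueError("phi must be finite and >= 0")


def group_log2_fold(mean_g1: float, mean_g2: float) -> float:
    """log2(mean_g1 / mean_g2); +/-inf when one mean is zero, NaN when both are.

    No pseudo-count is folded in — degenerate ratios stay flagged as
    infinities so they cannot masquerade as finite fold changes.
    """
    if mean_g1 < 0 or mean_g2 < 0:
        raise ValueError("group means must be >= 0")
    if mean_g1 == 0 and mean_g2 == 0:
        return float("nan")
    if mean_g2 == 0:
        return float("inf")
    if mean_g1 == 0:
        return float("-inf")
    return math.log2(mean_g1 / mean_g2)


def pseudo_counts(m: pd.DataFrame) -> pd.DataFrame:
    """Scale every sample to the geometric-mean library depth, rounding half-up.

    The exact-test machinery needs integer counts on a common depth; the
    half-up rounding rule is fixed for determinism.
    """
    libsizes = m.sum(axis=0).to_numpy(dtype=float)
    if (libsizes <= 0).any():
        raise ValueError("every sample needs a positive library size")
    geo = math.exp(np.mean(np.log(libsizes)))
    scaled = m.to_numpy(dtype=float) * (geo / libsizes)[None, :]
    return pd.DataFrame(
        np.floor(scaled + 0.5).astype(np.int64), index=m.index, columns=m.columns
    )


def _conditional_loglik(counts: np.ndarray, phi: float) -> float:
    """Conditional NB log-likelihood of one group's counts given their sum."""
    r = 1.0 / phi
    n = counts.size
    z = counts.sum()
    return float(
        gammaln(counts + r).sum()
        - n * gammaln(r)
        + gammaln(n * r)
        - gammaln(z + n * r)
        + gammaln(z + 1)
        - gammaln(counts + 1).sum()
    )


def estimate_common_dispersion(m: pd.DataFrame, groups: Sequence) -> Dispersion:
    """Single phi maximising the summed conditional log-likelihood over genes.

    Counts are first equalised to the geometric-mean depth. The estimate is
    clamped to [1e-6, 10]; identical replicate samples (no overdispersion)
    land on the lower clamp.
    """
    groups = np.asarray(groups)
    if m.shape[1] != groups.size:
        raise ValueError("one group label per sample required")
    pseudo = pseudo_counts(m).to_numpy()
    if pseudo.sum() == 0:
        raise ValueError("all-zero count matrix: dispersion undefined")
    blocks = [pseudo[:, groups == g] for g in np.unique(groups)]
    blocks = [b for b in blocks if b.shape[1] >= 2]
    if not blocks:
        raise ValueError("at least one group needs >= 2 samples")

    def neg_ll(log_phi: float) -> float:
        phi = math.exp(log_phi)
        total = 0.0
        for b in blocks:
            for gi in range(b.shape[0]):
                total += _conditional_loglik(b[gi], phi)
        return -total

    res = optimize.minimize_scalar(
        neg_ll,
        bounds=(math.log(PHI_MIN), math.log(PHI_MAX)),
        method="bounded",
        options={"xatol": 1e-6},
    )
    phi = min(max(math.exp(res.x), PHI_MIN), PHI_MAX)
    return Dispersion(phi)


def _group_sum_pmf(y: np.ndarray, n: int, mu: float, phi: float) -> np.ndarray:
    """pmf of the sum of n iid NB(mu, phi) counts: NB(n*mu, size n/phi)."""
    r = n / phi
    p = r / (r + n * mu)
    return stats.nbinom.pmf(y, r, p)


def nb_exact_test(
    counts_g1: Sequence[int], counts_g2: Sequence[int], phi: Dispersion | float
) -> float:
    """Exact conditional two-group NB test on depth-equalised counts.

    Conditions on the total of the two group sums; the two-sided p-value is
    twice the smaller tail probability of the conditional distribution
    (observed outcome included in both tails), capped at 1. Only the p-value's
    support that carries non-negligible mass is enumerated for large totals.
    """
    phi_val = phi.phi if isinstance(phi, Dispersion) else float(phi)
    y1 = np.asarray(counts_g1, dtype=np.int64)
    y2 = np.asarray(counts_g2, dtype=np.int64)
    if (y1 < 0).any() or (y2 < 0).any():
        raise ValueError("counts must be non-negative")
    n1, n2 = y1.size, y2.size
    s1, s2 = int(y1.sum()), int(y2.sum())
    s = s1 + s2
    if s == 0:
        return 1.0
    w1 = n1 / (n1 + n2)

    if phi_val < 1e-10:
        # Poisson limit: conditional distribution is Binomial(s, n1/(n1+n2))
        left = stats.binom.cdf(s1, s, w1)
        right = stats.binom.sf(s1 - 1, s, w1)
        return float(min(1.0, 2.0 * min(left, right)))

    mu_hat = s / (n1 + n2)  # per-sample null mean on the common depth
    mode = s * w1
    v1 = n1 * mu_hat * (1 + n1 * mu_hat * phi_val / n1)
    v2 = n2 * mu_hat * (1 + n2 * mu_hat * phi_val / n2)
    v_cond = 1.0 / (1.0 / max(v1, 1e-12) + 1.0 / max(v2, 1e-12))
    half_width = 25.0 * math.sqrt(v_cond) + 25.0
    lo = int(max(0, math.floor(min(mode - half_width, s1 - half_width))))
    hi = int(min(s, math.ceil(max(mode + half_width, s1 + half_width))))
    y = np.arange(lo, hi + 1)
    with np.errstate(over="ignore", under="ignore"):
        log_pmf = stats.nbinom.logpmf(y, n1 / phi_val, 1.0 / (1.0 + phi_val * mu_hat)) + \
            stats.nbinom.logpmf(s - y, n2 / phi_val, 1.0 / (1.0 + phi_val * mu_hat))
    log_pmf -= log_pmf.max()
    pmf = np.exp(log_pmf)
    total = pmf.sum()
    obs = s1 - lo
    left = pmf[: obs + 1].sum() / total
    right = pmf[obs:].sum() / total
    return float(min(1.0, 2.0 * min(left, right)))


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    if phi < 1e-12:
        return float(stats.poisson.logpmf(y, mu).sum())
    r = 1.0 / phi
    return float(stats.nbinom.logpmf(y, r, r / (r + mu)).sum())


def _fit_nb_glm(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    phi: float,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> tuple[np.ndarray, float, bool]:
    """IRLS fit of an NB log-linear model at fixed phi.

    Returns (beta, loglik, converged).
    """
    mu = np.maximum(y, 0.5).astype(float)
    eta = np.log(mu)
    beta = np.zeros(X.shape[1])
    converged = False
    for _ in range(max_iter):
        w = mu / (1.0 + phi * mu)
        z = eta - offset + (y - mu) / mu
        wx = X * w[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ wx, wx.T @ z)
        except np.linalg.LinAlgError:
            beta_new, *_ = np.linalg.lstsq(X.T @ wx, wx.T @ z, rcond=None)
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        eta = np.clip(X @ beta + offset, -30.0, 30.0)
        mu = np.exp(eta)
        if step < tol:
            converged = True
            break
    return beta, _nb_loglik(y, mu, phi), converged


def nb_glm_lrt(
    counts: Sequence[int],
    group: Sequence,
    phi: Dispersion | float,
    adjust: pd.DataFrame | np.ndarray | None = None,
    offsets: Sequence[float] | None = None,
) -> float:
    """Likelihood-ratio test of a two-level group effect in an NB GLM.

    Fits intercept + adjustment covariates (+/- the group indicator) with
    log-library-size offsets and compares twice the log-likelihood difference
    to chi-square with 1 df. Aliasing of the group indicator with the
    adjustment design, or IRLS non-convergence, yields NaN (flagged), never a
    crash.
    """
    phi_val = phi.phi if isinstance(phi, Dispersion) else float(phi)
    y = np.asarray(counts, dtype=float)
    if (y < 0).any():
        raise ValueError("counts must be non-negative")
    g = pd.Series(list(group))
    levels = pd.unique(g)
    if len(levels) != 2:
        raise ValueError("group must have exactly 2 levels")
    gvec = (g == levels[0]).to_numpy(dtype=float)
    n = y.size
    offset = np.zeros(n) if offsets is None else np.asarray(offsets, dtype=float)

    X_null = np.ones((n, 1))
    if adjust is not None:
        A = np.asarray(adjust, dtype=float)
        if A.ndim == 1:
            A = A[:, None]
        X_null = np.hstack([X_null, A])
    X_full = np.hstack([X_null, gvec[:, None]])
    if np.linalg.matrix_rank(X_full) <= np.linalg.matrix_rank(X_null):
        return float("nan")  # group aliased with the adjustment covariates

    _, ll_null, conv0 = _fit_nb_glm(y, X_null, offset, phi_val)
    _, ll_full, conv1 = _fit_nb_glm(y, X_full, offset, phi_val)
    if not (conv0 and conv1):
        return float("nan")
    lr = max(0.0, 2.0 * (ll_full - ll_null))
    return float(stats.chi2.sf(lr, df=1))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving.

    q_(i) = min over j >= i of m * p_(j) / j on the sorted p-values, mapped
    back to the input order and capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="stable")
    m = p.size
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _regimen_design(regimen: pd.Series) -> np.ndarray:
    """Treatment-coded dummies for an unordered regimen factor."""
    dummies = pd.get_dummies(regimen.astype(str), drop_first=True)
    return dummies.to_numpy(dtype=float)


_LEVEL_PREFERENCE = [
    (True, False),
    ("+", "-"),
    ("pCR", "non-pCR"),
    ("relapsed", "non-relapsed"),
]


def _contrast_levels(values: pd.Series, levels: tuple | None) -> tuple:
    uniq = set(values.unique())
    if levels is not None:
        if set(levels) != uniq:
            raise ValueError(f"levels {levels} do not match observed {sorted(map(str, uniq))}")
        return tuple(levels)
    for pref in _LEVEL_PREFERENCE:
        if uniq == set(pref):
            return pref
    if len(uniq) != 2:
        raise ValueError("contrast must have exactly 2 levels")
    return tuple(sorted(uniq, key=str))


def differential_table(
    m: pd.DataFrame,
    metadata: pd.DataFrame,
    contrast: str,
    adjust: str | None = None,
    levels: tuple | None = None,
    phi: Dispersion | float | None = None,
) -> pd.DataFrame:
    """Per-gene differential-abundance table for a two-level clinical contrast.

    Group means are averages of depth-equalised (normalised) counts. P-values
    come from the exact conditional NB test, or from the NB-GLM
    likelihood-ratio test when ``adjust`` names a covariate (e.g. the NCT
    regimen). FDR is Benjamini-Hochberg over all genes. Rows are sorted by
    p-value, ties broken by gene id, so output is deterministic.
    """
    missing = [s for s in m.columns if s not in metadata.index]
    if missing:
        raise ValueError(f"samples absent from metadata: {missing}")
    meta = metadata.loc[m.columns]
    if contrast not in meta.columns:
        raise ValueError(f"unknown contrast covariate {contrast!r}")
    values = meta[contrast]
    lev1, lev2 = _contrast_levels(values, levels)
    g1_mask = (values == lev1).to_numpy()
    g2_mask = (values == lev2).to_numpy()
    if g1_mask.sum() < 2 or g2_mask.sum() < 2:
        raise ValueError("each contrast level needs at least 2 samples")

    pseudo = pseudo_counts(m)
    if phi is None:
        phi = estimate_common_dispersion(m, np.where(g1_mask, "g1", "g2"))
    phi_val = phi.phi if isinstance(phi, Dispersion) else float(phi)

    raw = m.to_numpy(dtype=float)
    libsizes = raw.sum(axis=0)
    log_lib = np.log(libsizes)
    adjust_design = None
    if adjust is not None:
        if adjust not in meta.columns:
            raise ValueError(f"unknown adjustment covariate {adjust!r}")
        adjust_design = _regimen_design(meta[adjust])

    records = []
    pvals = []
    ps_np = pseudo.to_numpy()
    for gi, gene in enumerate(m.index):
        mean_g1 = float(ps_np[gi, g1_mask].mean())
        mean_g2 = float(ps_np[gi, g2_mask].mean())
        if adjust is None:
            p = nb_exact_test(ps_np[gi, g1_mask], ps_np[gi, g2_mask], phi_val)
        else:
            p = nb_glm_lrt(
                raw[gi],
                np.where(g1_mask, "g1", "g2"),
                phi_val,
                adjust=adjust_design,
                offsets=log_lib,
            )
        records.append((gene, mean_g1, mean_g2, group_log2_fold(mean_g1, mean_g2)))
        pvals.append(p)

    fdr = bh_fdr(np.nan_to_num(np.asarray(pvals), nan=1.0))
    out = pd.DataFrame(
        records, columns=["gene", "mean_g1", "mean_g2", "log2_fold"]
    )
    out["p_value"] = pvals
    out["fdr"] = fdr
    out = out.sort_values(["p_value", "gene"], kind="stable").reset_index(drop=True)
    out.attrs["contrast"] = contrast
    out.attrs["levels"] = (lev1, lev2)
    out.attrs["phi"] = phi_val
    return out
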