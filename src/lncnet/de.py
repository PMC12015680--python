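"""Two-group negative-binomial differential expression.

A transparent per-gene NB model standing in for a full DESeq2-style fit:
median-of-ratios size factors, one shared maximum-likelihood dispersion per
gene and contrast (method-of-moments start, floored at the Poisson limit),
and a two-sided Wald test on the log ratio of the two group abundances.
The dispersion likelihood carries a Cox-Reid adjustment (penalizing by half
the log determinant of the per-group information) and the Wald statistic is
referred to a Student t with n_a + n_b - 2 degrees of freedom; both choices
counter the small-sample anti-conservativeness of a plain ML/normal Wald
test at 6 replicates per group. No across-gene dispersion shrinkage, no
outlier handling, no independent filtering — calibration is checked by
simulation instead.

DEG calling follows the study thresholds: raw p < 0.01 and fold change >= 2
or <= 0.5 (boundary inclusive by default, strict mode available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .expression import CountMatrix

_ALPHA_FLOOR = 1e-8  # Poisson limit
_ALPHA_CEIL = 50.0

DE_COLUMNS = ["gene_id", "mean_a", "mean_b", "log2fc", "p_value", "direction"]


def parse_contrast(name: str) -> tuple[str, str]:
    """'PTB_vs_TL' -> (group_b='PTB', group_a='TL'): B tested against A."""
    parts = name.split("_vs_")
    if len(parts) != 2 or not all(parts):
        raise ValueError(f"contrast {name!r} must look like 'GROUPB_vs_GROUPA'")
    return parts[0], parts[1]


def size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    For genes with nonzero counts in every sample, each sample's factor is
    the median of counts[g, s] / geometric_mean_g. Factors are not rescaled
    further.
    """
    mat = counts.counts.to_numpy(dtype=float)
    allpos = (mat > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no gene has nonzero counts in all samples; "
            "pre-filter the matrix before computing size factors"
        )
    sub = mat[allpos]
    log_geomean = np.log(sub).mean(axis=1)
    factors = np.exp(np.median(np.log(sub) - log_geomean[:, None], axis=0))
    return pd.Series(factors, index=counts.samples, name="size_factor")


def _nb_loglik(counts: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    r = 1.0 / alpha
    return float(
        np.sum(
            special.gammaln(counts + r)
            - special.gammaln(r)
            - special.gammaln(counts + 1)
            + r * np.log(r / (r + mu))
            + counts * np.log(mu / (r + mu) + 1e-300)
        )
    )


def _mom_alpha(z_a: np.ndarray, z_b: np.ndarray, q_a: float, q_b: float) -> float:
    """Method-of-moments dispersion from normalized counts, pooled over groups."""
    est = []
    for z, q in ((z_a, q_a), (z_b, q_b)):
        if q > 0 and len(z) > 1:
            est.append((np.var(z, ddof=1) - q) / q**2)
    if not est:
        return _ALPHA_FLOOR
    return float(np.clip(np.mean(est), _ALPHA_FLOOR, _ALPHA_CEIL))


@dataclass(frozen=True)
class NbTestResult:
    mean_a: float
    mean_b: float
    log2fc: float
    p_value: float
    alpha: float
    flagged: bool  # all-zero gene


def nb_test(counts_a, counts_b, sf_a, sf_b) -> NbTestResult:
    """Two-sided Wald test of group B against group A for one gene.

    Counts in each group are modeled NB(mu = sf * q_group, alpha) with the
    dispersion alpha shared across both groups, estimated by maximizing the
    Cox-Reid adjusted likelihood (method-of-moments start, bounded search,
    floored at 1e-8). The Wald statistic is log(q_b/q_a) over its standard
    error from the observed information sum(mu_i / (1 + alpha*mu_i)) per
    group, referred to Student t with n_a + n_b - 2 degrees of freedom.
    When a group mean is zero, a pseudo-abundance eps = 0.5/sqrt(n_total)
    replaces it in both the fold change and the information.
    """
    ca = np.asarray(counts_a, dtype=float)
    cb = np.asarray(counts_b, dtype=float)
    fa = np.asarray(sf_a, dtype=float)
    fb = np.asarray(sf_b, dtype=float)
    if len(ca) < 2 or len(cb) < 2:
        raise ValueError("need at least 2 replicates per group")
    if (fa <= 0).any() or (fb <= 0).any():
        raise ValueError("size factors must be positive")

    q_a = float(np.mean(ca / fa))
    q_b = float(np.mean(cb / fb))
    if q_a == 0.0 and q_b == 0.0:
        return NbTestResult(0.0, 0.0, 0.0, 1.0, _ALPHA_FLOOR, True)

    n_total = len(ca) + len(cb)
    eps = 0.5 / np.sqrt(n_total) if (q_a == 0.0 or q_b == 0.0) else 0.0
    qa_eff, qb_eff = q_a + eps, q_b + eps
    log2fc = float(np.log2(qb_eff / qa_eff))

    alpha0 = _mom_alpha(ca / fa, cb / fb, q_a, q_b)
    counts = np.concatenate([ca, cb])
    mu_a, mu_b = fa * qa_eff, fb * qb_eff
    mu = np.concatenate([mu_a, mu_b])

    def neg_ll(log_alpha: float) -> float:
        alpha = float(np.exp(log_alpha))
        ll = _nb_loglik(counts, mu, alpha)
        # Cox-Reid adjustment: -1/2 log det of the per-group information
        info_a = np.sum(mu_a / (1.0 + alpha * mu_a))
        info_b = np.sum(mu_b / (1.0 + alpha * mu_b))
        return -(ll - 0.5 * (np.log(info_a) + np.log(info_b)))

    res = optimize.minimize_scalar(
        neg_ll,
        bounds=(np.log(_ALPHA_FLOOR), np.log(_ALPHA_CEIL)),
        method="bounded",
        options={"xatol": 1e-6},
    )
    alpha = float(np.exp(res.x)) if res.success else alpha0

    info_a = float(np.sum(mu_a / (1.0 + alpha * mu_a)))
    info_b = float(np.sum(mu_b / (1.0 + alpha * mu_b)))
    se = np.sqrt(1.0 / info_a + 1.0 / info_b)
    z = np.log(qb_eff / qa_eff) / se
    p = float(2.0 * stats.t.sf(abs(z), n_total - 2))
    return NbTestResult(q_a, q_b, log2fc, p, alpha, False)


def de_contrast(
    counts: CountMatrix,
    contrast: str,
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene NB Wald results for one 'B_vs_A' contrast (direction unset)."""
    group_b, group_a = parse_contrast(contrast)
    samples_a = counts.samples_of(group_a)
    samples_b = counts.samples_of(group_b)
    for grp, ss in ((group_a, samples_a), (group_b, samples_b)):
        if len(ss) < 2:
            raise ValueError(f"group {grp!r} has {len(ss)} samples; need >= 2")
    if factors is None:
        factors = size_factors(counts)
    fa = factors[samples_a].to_numpy()
    fb = factors[samples_b].to_numpy()
    mat_a = counts.counts[samples_a].to_numpy()
    mat_b = counts.counts[samples_b].to_numpy()

    rows = []
    for i, gene in enumerate(counts.genes):
        r = nb_test(mat_a[i], mat_b[i], fa, fb)
        rows.append((gene, r.mean_a, r.mean_b, r.log2fc, r.p_value, "none"))
    return pd.DataFrame(rows, columns=DE_COLUMNS)


def call_degs(
    results: pd.DataFrame,
    p_threshold: float = 0.01,
    fc_threshold: float = 2.0,
    strict_fc: bool = False,
) -> pd.DataFrame:
    """Fill the direction column: up/down DEG calls at the study thresholds.

    up: p < p_threshold and FC >= fc_threshold; down: p < p_threshold and
    FC <= 1/fc_threshold. The fold-change boundary is inclusive by default
    (strict_fc=True restores strict > / <).
    """
    if not (0.0 < p_threshold < 1.0):
        raise ValueError("p_threshold must be in (0, 1)")
    if fc_threshold <= 1.0:
        raise ValueError("fc_threshold must be > 1")
    lfc_cut = np.log2(fc_threshold)
    out = results.copy()
    sig = out["p_value"] < p_threshold
    if strict_fc:
        up = sig & (out["log2fc"] > lfc_cut)
        down = sig & (out["log2fc"] < -lfc_cut)
    else:
        up = sig & (out["log2fc"] >= lfc_cut)
        down = sig & (out["log2fc"] <= -lfc_cut)
    out["direction"] = np.where(up, "up", np.where(down, "down", "none"))
    return out


def deg_sets(called: pd.DataFrame) -> dict[str, set[str]]:
    """{'up': ids, 'down': ids} from a called results table."""
    return {
        "up": set(called.loc[called["direction"] == "up", "gene_id"]),
        "down": set(called.loc[called["direction"] == "down", "gene_id"]),
    }


def deg_count_table(called_by_contrast: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-contrast up/down/total DEG counts (one row per ordered contrast)."""
    rows = []
    for contrast, called in called_by_contrast.items():
        s = deg_sets(called)
        rows.append((contrast, len(s["up"]), len(s["down"]), len(s["up"]) + len(s["down"])))
    return pd.DataFrame(rows, columns=["contrast", "up", "down", "total"])
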