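"""Iteratively normalized differential expression of count time-series.

Normalization follows the trimmed-mean-of-M-values (TMM) method: per-sample
scaling factors are weighted means of log2 expression ratios against a
reference sample, after trimming the most extreme log-ratios (M) and
log-intensities (A), exponentiated and rescaled to geometric mean 1.

The iteration removes putative differentially expressed genes before
re-estimating factors (the DEGES strategy): normalize, test every gene for
each (condition, time vs t0) contrast, flag candidates at a permissive FDR
gate, recompute factors on the remaining genes, and repeat until the
factors stabilize or an iteration cap (default 36) is reached.  The final
significance call uses a stricter q-value threshold (default 0.01) in at
least one contrast.

The per-gene test pools replicates and conditions on the pooled total: with
effective library sizes s_A, s_B, the group-A count is Binomial(n, s_A /
(s_A + s_B)) under the null, with a two-sided p-value summing all outcome
probabilities not exceeding the observed one.  Counts from fermentation
metatranscriptomes are over-dispersed, so by default the pipeline widens
this conditional distribution to a beta-binomial whose extra variance is
moment-estimated from the within-group replicate scatter; the pure
binomial primitive is exposed as :func:`exact_count_test`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import logging

import numpy as np
import pandas as pd
from scipy.stats import betabinom, binom, rankdata
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix

logger = logging.getLogger("metaferm")


@dataclass
class DeParams:
    n_iterations: int = 36
    gate_fdr: float = 0.1
    q_threshold: float = 0.01
    tmm_logratio_trim: float = 0.30
    tmm_abs_trim: float = 0.05
    convergence_tol: float = 1e-6
    overdispersion: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.gate_fdr < 1 or not 0 < self.q_threshold < 1:
            raise ValueError("FDR thresholds must be in (0, 1)")
        if not (0 <= self.tmm_logratio_trim < 0.5 and 0 <= self.tmm_abs_trim < 0.5):
            raise ValueError("trim fractions must be in [0, 0.5)")


# ---------------------------------------------------------------------------
# TMM


def _tmm_pair(
    obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
    logratio_trim: float, abs_trim: float,
) -> float:
    both = (obs > 0) & (ref > 0)
    if not both.any():
        return 1.0
    o, r = obs[both].astype(float), ref[both].astype(float)
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    # asymptotic (delta-method) inverse variance of M
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    n = len(m)
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abs_trim) + 1
    hi_a = n + 1 - lo_a
    rm, ra = rankdata(m), rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any() or w[keep].min() <= 0:
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(
    counts: pd.DataFrame,
    reference: str = "auto",
    logratio_trim: float = 0.30,
    abs_trim: float = 0.05,
) -> pd.Series:
    """Per-sample TMM scaling factors, rescaled to geometric mean 1.

    ``reference="auto"`` picks the sample whose 75th percentile of library-
    scaled counts is closest to the mean across samples.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least two samples")
    lib = counts.sum(axis=0).astype(float)
    if (lib == 0).any():
        bad = lib.index[lib == 0].tolist()
        raise ValueError(f"all-zero sample(s): {bad}")
    # all-zero genes are inert for every pair but would shift the
    # upper-quartile reference rule, so drop them up front
    counts = counts.loc[counts.sum(axis=1) > 0]
    if reference == "auto":
        f75 = counts.quantile(0.75, axis=0) / lib
        reference = (f75 - f75.mean()).abs().idxmin()
    if reference not in counts.columns:
        raise ValueError(f"unknown reference sample {reference!r}")
    ref = counts[reference].to_numpy()
    n_ref = float(lib[reference])
    factors = {}
    for s in counts.columns:
        if s == reference:
            factors[s] = 1.0
        else:
            factors[s] = _tmm_pair(
                counts[s].to_numpy(), ref, float(lib[s]), n_ref,
                logratio_trim, abs_trim,
            )
    out = pd.Series(factors, index=counts.columns, dtype=float)
    return out / np.exp(np.log(out).mean())


# ---------------------------------------------------------------------------
# exact conditional tests


def _two_sided_discrete_p(pmf: np.ndarray, k: int) -> float:
    obs = pmf[k]
    return float(min(1.0, pmf[pmf <= obs * (1.0 + 1e-7)].sum()))


def exact_count_test(
    counts_a: Sequence[int],
    counts_b: Sequence[int],
    eff_sizes_a: Sequence[float],
    eff_sizes_b: Sequence[float],
) -> float:
    """Conditional binomial test of equal relative expression in two groups.

    Replicates are pooled per group; conditional on the pooled total n, the
    group-A count is Binomial(n, s_A / (s_A + s_B)) under the null, with
    s the summed effective library sizes.  Two-sided p-value by summing all
    outcome probabilities <= the observed one; both pools zero gives 1.
    """
    ka, kb = int(np.sum(counts_a)), int(np.sum(counts_b))
    sa, sb = float(np.sum(eff_sizes_a)), float(np.sum(eff_sizes_b))
    if sa <= 0 or sb <= 0:
        raise ValueError("effective sizes must be positive")
    n = ka + kb
    if n == 0:
        return 1.0
    pi = sa / (sa + sb)
    pmf = binom.pmf(np.arange(n + 1), n, pi)
    return _two_sided_discrete_p(pmf, ka)


def _pooled_pvalues(
    k_a: np.ndarray, k_b: np.ndarray, s_a: float, s_b: float,
    alpha: float, n_replicates: int,
) -> np.ndarray:
    """Vectorized two-sided conditional p-values for one contrast.

    With ``alpha`` > 0 the conditional law is beta-binomial: pooling R
    replicates of a negative-binomial gene (variance mu + alpha mu^2)
    yields a gamma shape of R / alpha per group, so the conditional
    distribution given the total widens to BetaBin(n, R_tot pi, R_tot
    (1 - pi)) with R_tot = n_replicates / alpha.
    """
    pi = s_a / (s_a + s_b)
    out = np.ones(len(k_a))
    use_bb = alpha > 1e-8
    if use_bb:
        r_tot = n_replicates / alpha
        a_par, b_par = r_tot * pi, r_tot * (1.0 - pi)
    for i in range(len(k_a)):
        n = int(k_a[i] + k_b[i])
        if n == 0:
            continue
        support = np.arange(n + 1)
        if use_bb:
            pmf = betabinom.pmf(support, n, a_par, b_par)
        else:
            pmf = binom.pmf(support, n, pi)
        out[i] = _two_sided_discrete_p(pmf, int(k_a[i]))
    return out


def estimate_dispersion(cm: CountMatrix, eff_sizes: pd.Series) -> float:
    """Moment estimate of the common negative-binomial dispersion.

    Counts are rescaled to the geometric-mean effective size; within each
    replicate group the mean/variance pair then satisfies E[s^2] ~ c m +
    alpha m^2, pooled over genes and groups and solved for alpha.
    """
    scale = np.exp(np.log(eff_sizes).mean()) / eff_sizes
    y = cm.counts.to_numpy(dtype=float) * scale.to_numpy()[None, :]
    groups: dict[tuple, list[int]] = {}
    for j, s in enumerate(cm.samples):
        groups.setdefault((s.condition, s.time_h), []).append(j)
    num, den = 0.0, 0.0
    for idx in groups.values():
        if len(idx) < 2:
            continue
        sub = y[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        c = float(np.mean(scale.to_numpy()[idx]))
        num += float(np.sum(v - c * m))
        # E[m^2] = mu^2 + Var/R, so subtract v/R for an unbiased mu^2
        den += float(np.sum(np.clip(m**2 - v / len(idx), 0.0, None)))
    if den <= 0:
        return 0.0
    return float(np.clip(num / den, 0.0, 10.0))


def bh_qvalues(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# DEGES pipeline


@dataclass
class DeFit:
    factors: pd.Series
    results: pd.DataFrame          # gene_id, condition, time_h, p_value, q_value, significant
    is_de: pd.Series               # per gene: q < threshold in >= 1 contrast
    n_iterations_run: int = 0
    converged: bool = False
    dispersion: float = 0.0

    def de_genes(self) -> list[str]:
        return self.is_de.index[self.is_de].tolist()


def _contrasts(cm: CountMatrix) -> list[tuple[str, float, list[int], list[int]]]:
    by_cell: dict[tuple, list[int]] = {}
    for j, s in enumerate(cm.samples):
        by_cell.setdefault((s.condition, s.time_h), []).append(j)
    conds = sorted({s.condition for s in cm.samples})
    out = []
    for cond in conds:
        times = sorted({t for c, t in by_cell if c == cond})
        if 0.0 not in times:
            raise ValueError(f"condition {cond} lacks a t0 baseline")
        for t in times:
            if t > 0:
                out.append((cond, t, by_cell[(cond, 0.0)], by_cell[(cond, t)]))
    if not out:
        raise ValueError("design has no post-t0 time points")
    return out


def deges_pipeline(cm: CountMatrix, params: DeParams | None = None) -> DeFit:
    """Iterative TMM normalization + per-contrast exact testing.

    Contrasts are every later time point vs t0 within each condition.  Each
    iteration recomputes TMM factors on the genes not currently flagged at
    the FDR gate; iteration stops when the factors move less than the
    convergence tolerance or after ``n_iterations``.  Deterministic given
    the counts.
    """
    params = params or DeParams()
    contrasts = _contrasts(cm)
    counts = cm.counts
    lib = counts.sum(axis=0).astype(float)
    factors = pd.Series(1.0, index=counts.columns)
    flagged = pd.Series(False, index=counts.index)
    alpha = 0.0
    pmat = qmat = None
    n_run = 0
    converged = False
    for it in range(params.n_iterations):
        n_run = it + 1
        sub = counts.loc[~flagged]
        if sub.shape[0] < 2:  # degenerate: nearly everything flagged
            sub = counts
        new_factors = tmm_factors(
            sub, "auto", params.tmm_logratio_trim, params.tmm_abs_trim
        )
        eff = lib * new_factors
        alpha = estimate_dispersion(cm, eff) if params.overdispersion else 0.0
        arr = counts.to_numpy()
        pcols, qcols = {}, {}
        for cond, t, idx_a, idx_b in contrasts:
            k_a = arr[:, idx_a].sum(axis=1)
            k_b = arr[:, idx_b].sum(axis=1)
            s_a = float(eff.iloc[idx_a].sum())
            s_b = float(eff.iloc[idx_b].sum())
            p = _pooled_pvalues(k_a, k_b, s_a, s_b, alpha, len(idx_a) + len(idx_b))
            pcols[(cond, t)] = p
            qcols[(cond, t)] = bh_qvalues(p)
        pmat = pd.DataFrame(pcols, index=counts.index)
        qmat = pd.DataFrame(qcols, index=counts.index)
        flagged = qmat.min(axis=1) < params.gate_fdr
        delta = float((new_factors - factors).abs().max())
        factors = new_factors
        logger.info(
            "DEGES iteration %d: max factor change %.3g, %d genes gated",
            n_run, delta, int(flagged.sum()),
        )
        if delta < params.convergence_tol:
            converged = True
            break
    rows = []
    for cond, t, _, _ in contrasts:
        rows.append(
            pd.DataFrame(
                {
                    "gene_id": counts.index,
                    "condition": cond,
                    "time_h": t,
                    "p_value": pmat[(cond, t)].to_numpy(),
                    "q_value": qmat[(cond, t)].to_numpy(),
                }
            )
        )
    results = pd.concat(rows, ignore_index=True)
    results["significant"] = results["q_value"] < params.q_threshold
    is_de = qmat.min(axis=1) < params.q_threshold
    return DeFit(
        factors=factors, results=results, is_de=is_de,
        n_iterations_run=n_run, converged=converged, dispersion=alpha,
    )
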