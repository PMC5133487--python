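"""Fuzzy Goodman-Kruskal gamma screening of genes against ordinal stages.

The Goodman-Kruskal gamma statistic, gamma = (C - D) / (C + D) over concordant
(C) and discordant (D) sample pairs, measures monotone association and is well
suited to an ordinal stage variable with many ties.  For noisy expression
data a strict ranking treats 1.300000001 as larger than 1.30; the fuzzy
variant used here instead scores the strict ordering of a pair through a
linear ramp of width r (the tie tolerance), so near-equal values contribute
only partial order credit.  Pairwise order degrees for the two variables are
aggregated with the "min" t-norm.  Per gene, r is 10% of the gene's
interquartile range by default; stage codes are compared crisply (r_y = 0)
since a tolerance on small integer codes would erase true stage distinctions.

Significance is assessed by permuting the stage labels (default B = 1000,
two-sided on |gamma|, add-one estimator so p is never 0), followed by
Benjamini-Hochberg FDR adjustment that can use a platform-wide total test
count m larger than the number of genes actually screened.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, StageDesign

__all__ = [
    "GammaParams",
    "strict_order_degree",
    "fuzzy_pair_masses",
    "gamma_statistic",
    "permutation_pvalue",
    "fdr_adjust",
    "screen_genes",
]


@dataclass
class GammaParams:
    """Tunables of the gamma screen.

    r_fraction
        Fraction of each gene's interquartile range used as the fuzzy tie
        tolerance r (default 0.10).
    similarity_family, t_norm
        Fuzzy-ordering construction; only the linear ramp / min t-norm pair
        is implemented.
    n_permutations
        Stage-label permutations per gene for the p-value (default 1000).
    gamma_threshold, fdr_threshold
        Selection rule: |gamma| > gamma_threshold and FDR q < fdr_threshold
        (strict inequalities).
    m_total
        Total number of tests for the FDR adjustment, e.g. all genes on the
        measuring platform; default None = number of genes with a defined
        gamma in this screen.
    r_y
        Tie tolerance on the stage codes; 0 (crisp) by default.
    """

    r_fraction: float = 0.10
    similarity_family: str = "linear"
    t_norm: str = "min"
    n_permutations: int = 1000
    gamma_threshold: float = 0.50
    fdr_threshold: float = 0.05
    m_total: int | None = None
    r_y: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r_fraction < 0:
            raise ValueError("r_fraction must be >= 0")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0.0 <= self.gamma_threshold:
            raise ValueError("gamma_threshold must be >= 0")
        if not 0.0 < self.fdr_threshold < 1.0:
            raise ValueError("fdr_threshold must be in (0, 1)")
        if self.similarity_family != "linear":
            raise ValueError("only the 'linear' similarity family is implemented")
        if self.t_norm != "min":
            raise ValueError("only the 'min' t-norm is implemented")
        if self.r_y < 0:
            raise ValueError("r_y must be >= 0")


def strict_order_degree(a: float, b: float, r: float) -> float:
    """Degree in [0, 1] to which ``b`` is strictly greater than ``a``.

    r = 0 gives the crisp indicator of b > a.  r > 0 gives the linear ramp
    min(1, max(0, (b - a)/r)): full credit when b - a >= r, none when b <= a.
    """
    if r < 0:
        raise ValueError("tolerance r must be >= 0")
    if r == 0:
        return 1.0 if b > a else 0.0
    return float(min(1.0, max(0.0, (b - a) / r)))


def _order_matrix(v: np.ndarray, r: float) -> np.ndarray:
    """O[i, j] = strict_order_degree(v[i], v[j], r) for all pairs."""
    diff = v[None, :] - v[:, None]
    if r == 0:
        return (diff > 0).astype(float)
    with np.errstate(over="ignore"):
        return np.clip(diff / r, 0.0, 1.0)


def fuzzy_pair_masses(
    x: np.ndarray, y: np.ndarray, r_x: float, r_y: float
) -> tuple[float, float]:
    """Fuzzy concordance and discordance masses over all ordered pairs.

    C = sum over i != j of min(O(x_i, x_j), O(y_i, y_j)) and D likewise with
    the order of the second variable reversed.  With r_x = r_y = 0 these are
    twice the classical concordant/discordant pair counts (each unordered
    pair enters in both orders); the doubling cancels in gamma.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if r_x < 0 or r_y < 0:
        raise ValueError("tolerances must be >= 0")
    ox = _order_matrix(x, r_x)
    oy = _order_matrix(y, r_y)
    # each unordered pair is credited in both reading directions (factor 2);
    # the doubling cancels in gamma
    c = 2.0 * float(np.minimum(ox, oy).sum())
    d = 2.0 * float(np.minimum(ox, oy.T).sum())
    return c, d


def gene_tolerance(x: np.ndarray, r_fraction: float) -> float:
    """Tie tolerance r = r_fraction x IQR(x), linear-interpolation percentiles."""
    q75, q25 = np.percentile(np.asarray(x, dtype=float), [75.0, 25.0])
    return float(r_fraction * (q75 - q25))


def gamma_statistic(
    x: np.ndarray, y: np.ndarray, params: GammaParams | None = None
) -> tuple[float, float, float]:
    """Fuzzy gamma of one gene against the stage codes.

    Returns (gamma, C, D); gamma is NaN when C + D = 0 (e.g. a constant
    gene), in which case the gene must be excluded from selection.
    """
    params = params or GammaParams()
    y = np.asarray(y, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("need at least 2 distinct stage codes")
    r_x = gene_tolerance(x, params.r_fraction)
    c, d = fuzzy_pair_masses(x, y, r_x, params.r_y)
    tot = c + d
    gamma = (c - d) / tot if tot > 0 else float("nan")
    return gamma, c, d


def permutation_pvalue(
    x: np.ndarray,
    y: np.ndarray,
    params: GammaParams,
    rng: np.random.Generator,
) -> float:
    """Two-sided permutation p-value for gamma, add-one estimator.

    p = (1 + #{b : |gamma_b| >= |gamma_obs|}) / (B + 1) over B uniform
    permutations of the stage codes; the gene tolerance r_x is computed once
    from x and reused for every permutation.
    """
    gamma_obs, _, _ = gamma_statistic(x, y, params)
    if np.isnan(gamma_obs):
        return float("nan")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r_x = gene_tolerance(x, params.r_fraction)
    ox = _order_matrix(x, r_x)
    b_total = params.n_permutations
    perms = rng.permuted(np.tile(y, (b_total, 1)), axis=1)
    gammas = _perm_gammas(ox, perms, params.r_y)
    exceed = int(np.sum(np.abs(gammas) >= abs(gamma_obs) - 1e-12))
    return (1 + exceed) / (b_total + 1)


def _perm_gammas(ox: np.ndarray, perms: np.ndarray, r_y: float) -> np.ndarray:
    """Gamma of a fixed expression order matrix against B permuted code
    vectors (B x n).  NaN where a permutation yields zero total mass."""
    if r_y == 0:
        oyb = (perms[:, None, :] > perms[:, :, None]).astype(float)
    else:
        oyb = np.clip((perms[:, None, :] - perms[:, :, None]) / r_y, 0.0, 1.0)
    c = np.minimum(ox[None, :, :], oyb).sum(axis=(1, 2))
    d = np.minimum(ox[None, :, :], np.swapaxes(oyb, 1, 2)).sum(axis=(1, 2))
    tot = c + d
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(tot > 0, (c - d) / np.where(tot > 0, tot, 1.0), np.nan)
    return out


def fdr_adjust(p_values: np.ndarray, m_total: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with an optional inflated total
    test count m (untested features behave as absent p-values that only
    enlarge m).  q_(i) = min_{j >= i} (m * p_(j) / j), clipped to 1."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    n = p.size
    m = n if m_total is None else int(m_total)
    if m < n:
        raise ValueError(f"m_total ({m}) smaller than number of p-values ({n})")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, n + 1)
    q_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


def screen_genes(
    expr: ExpressionMatrix, design: StageDesign, params: GammaParams | None = None
) -> pd.DataFrame:
    """Gamma-screen every gene against the disease stages.

    ``expr`` and ``design`` must be aligned (same samples, same order).
    Returns one row per gene (input order): gene_id, gamma, C, D, p_perm,
    q_fdr, direction (up/down/undefined) and the selection flag
    |gamma| > threshold AND q < fdr_threshold.  Deterministic given
    ``params.seed``; per-gene permutations are drawn from a single seeded
    stream in gene input order.
    """
    params = params or GammaParams()
    if list(expr.sample_ids) != list(design.sample_ids):
        raise ValueError("expression matrix and stage design are not aligned")
    y = design.codes_for(expr.sample_ids)
    if np.unique(y).size < 2:
        raise ValueError("need at least 2 distinct stage codes")
    n = y.size
    big = params.n_permutations
    rng = np.random.default_rng(params.seed)

    n_genes = expr.n_genes
    gammas = np.full(n_genes, np.nan)
    cs = np.zeros(n_genes)
    ds = np.zeros(n_genes)
    ps = np.full(n_genes, np.nan)

    oy = _order_matrix(y, params.r_y)
    for g in range(n_genes):
        x = expr.values[g]
        r_x = gene_tolerance(x, params.r_fraction)
        ox = _order_matrix(x, r_x)
        c = 2.0 * float(np.minimum(ox, oy).sum())
        d = 2.0 * float(np.minimum(ox, oy.T).sum())
        cs[g], ds[g] = c, d
        if c + d == 0:
            continue
        gammas[g] = (c - d) / (c + d)
        perms = rng.permuted(np.tile(y, (big, 1)), axis=1)
        perm_g = _perm_gammas(ox, perms, params.r_y)
        exceed = int(np.nansum(np.abs(perm_g) >= abs(gammas[g]) - 1e-12))
        ps[g] = (1 + exceed) / (big + 1)

    defined = ~np.isnan(ps)
    qs = np.full(n_genes, np.nan)
    if defined.any():
        m = params.m_total if params.m_total is not None else int(defined.sum())
        qs[defined] = fdr_adjust(ps[defined], m_total=m)

    direction = np.select(
        [np.isnan(gammas), gammas > 0, gammas < 0], ["undefined", "up", "down"], "undefined"
    )
    selected = (
        defined
        & (np.abs(np.where(defined, gammas, 0.0)) > params.gamma_threshold)
        & (np.where(defined, qs, 1.0) < params.fdr_threshold)
    )
    return pd.DataFrame(
        {
            "gene_id": expr.gene_ids,
            "gamma": gammas,
            "C": cs,
            "D": ds,
            "p_perm": ps,
            "q_fdr": qs,
            "direction": direction,
            "selected": selected,
        }
    )


def write_gamma_table(result: pd.DataFrame, path: str) -> None:
    result.to_csv(path, sep="\t", index=False, float_format="%.6g")
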