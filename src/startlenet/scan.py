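"""Two-step detection: prescreen, permutation thresholds, 1D/2D scans.

Step one screens every predictor with a single-locus model (main effect +
sex + locus-by-sex) at a nominal threshold (default P < 0.001).  Step two
calibrates an experiment-wise critical F by permutation: line labels of
the response are shuffled jointly across both sex slices, every scanned
term's F statistic is recomputed, and the maximum over the whole scan
family is recorded per permutation.  The critical F is the
ceil((1 - alpha_EW) * n_perm)-th order statistic of those null maxima, and
experiment-wise P values use add-one smoothing,
P_EW = (1 + #{null maxima >= F}) / (n_perm + 1).

One permutation family covers the whole scan — every hygiene-passing main
term plus the candidate epistasis pairs — so a single critical F controls
the experiment-wise type-I error of the scan at alpha_EW, regardless of
the nominal prescreen.  The scans and the permutation null use the same
marginal statistics, keeping the observed family exchangeable with the
null family.

All single-locus and pair statistics are computed from precomputed design
moments, vectorised over predictors and permutations.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .model_core import (
    DesignSpec,
    PredictorSet,
    encode_design,
    fit_fixed_model,
    partial_f,
)

logger = logging.getLogger(__name__)


@dataclass
class ScanConfig:
    """Detection settings.

    ``prescreen_alpha`` is the nominal single-locus threshold (0.001, as in
    the candidate screen); ``n_permutations`` defaults to the study's 2,000
    (reducible for desk-scale runs, but at least 19 so alpha_EW = 0.05 is
    resolvable); ``tier_high`` / ``tier_report`` are -log10 P_EW tier
    thresholds for labelling associations.
    """

    prescreen_alpha: float = 0.001
    n_permutations: int = 2_000
    alpha_ew: float = 0.05
    tier_high: float = 5.0
    tier_report: float = 3.0
    pair_budget: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.prescreen_alpha < 1:
            raise ValueError("prescreen_alpha must be in (0, 1)")
        if self.n_permutations < 19:
            raise ValueError(
                f"n_permutations={self.n_permutations} cannot resolve "
                "alpha_EW = 0.05; need at least 19"
            )


@dataclass
class PermutationNull:
    """Null distribution of the scan-family maximum F."""

    null_max: np.ndarray
    alpha_ew: float
    n_permutations: int

    @property
    def critical_f(self) -> float:
        return critical_f_from_null(self.null_max, self.alpha_ew)

    def p_ew(self, f_obs) -> np.ndarray:
        """Experiment-wise P with add-one smoothing (never exactly zero)."""
        f_obs = np.atleast_1d(np.asarray(f_obs, dtype=float))
        count = (self.null_max[None, :] >= f_obs[:, None]).sum(axis=1)
        return (1.0 + count) / (self.n_permutations + 1.0)


def critical_f_from_null(null_max: np.ndarray, alpha_ew: float) -> float:
    """The ceil((1 - alpha) * n)-th order statistic of the null maxima."""
    n = null_max.size
    k = math.ceil((1.0 - alpha_ew) * n)     # 1-based order statistic
    if not 1 <= k <= n:
        raise ValueError(f"alpha_ew={alpha_ew} unresolvable with {n} permutations")
    return float(np.sort(null_max)[k - 1])


@dataclass
class ScanResult:
    """Per-term scan statistics against one experiment-wise threshold.

    ``table`` has one row per scanned term with columns ``term_type``
    (``main`` or ``epistasis``), ``id1``, ``id2``, ``F``, ``p_nominal``,
    ``p_ew``, ``neglog10_p_ew``, ``passed``.
    """

    table: pd.DataFrame
    critical_f: float
    n_permutations: int
    alpha_ew: float


# ---------------------------------------------------------------------------
# Vectorised single-locus and pair statistics
# ---------------------------------------------------------------------------

_DEGENERATE = 1e-10

#: F statistic reported for an exact (zero-residual) fit.
_F_PERFECT = 1e12


def _f_ratio(num_ss, sse, df_num: int, df_den: int) -> np.ndarray:
    """Partial-F ratio with a finite stand-in for zero-residual fits."""
    num = np.maximum(num_ss, 0.0) / df_num
    den = np.asarray(sse) / df_den
    with np.errstate(divide="ignore", invalid="ignore"):
        f = num / den
    return np.where(den > 0, np.where(np.isfinite(f), f, _F_PERFECT),
                    np.where(num > 0, _F_PERFECT, 0.0))


def _obs_matrix(Y: np.ndarray) -> np.ndarray:
    """(R, L, 2) or (L, 2) response stacks -> (n_obs, R)."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 2:
        Y = Y[None]
    R, L, _ = Y.shape
    return Y.reshape(R, 2 * L).T


class _LocusKernel:
    """Single-locus F statistics for many predictors and many responses.

    Model per predictor: [1, sex, x, x*sex]; the locus F jointly tests the
    (x, x*sex) columns (2 df) against the sex-only null.  X-side moments
    are precomputed once; each response (observed or permuted) costs two
    matrix products.
    """

    def __init__(self, values: np.ndarray):
        # values: (L, 2, m)
        L, _, m = values.shape
        self.n = 2 * L
        self.m = m
        self.df_num = 2
        self.df_den = self.n - 4
        flat = values.reshape(self.n, m)
        s = np.tile(np.array([1.0, -1.0]), L)
        self.flat = flat
        self.flat_s = flat * s[:, None]
        self.s = s
        n = self.n
        sx = flat.sum(axis=0)
        sxs = self.flat_s.sum(axis=0)
        sxx = (flat ** 2).sum(axis=0)
        sxxs = (flat * self.flat_s).sum(axis=0)
        xtx = np.empty((m, 4, 4))
        xtx[:, 0, 0] = n;   xtx[:, 0, 1] = 0.0; xtx[:, 0, 2] = sx;   xtx[:, 0, 3] = sxs
        xtx[:, 1, 0] = 0.0; xtx[:, 1, 1] = n;   xtx[:, 1, 2] = sxs;  xtx[:, 1, 3] = sx
        xtx[:, 2, 0] = sx;  xtx[:, 2, 1] = sxs; xtx[:, 2, 2] = sxx;  xtx[:, 2, 3] = sxxs
        xtx[:, 3, 0] = sxs; xtx[:, 3, 1] = sx;  xtx[:, 3, 2] = sxxs; xtx[:, 3, 3] = sxx
        var_x = sxx - sx ** 2 / n
        self.degenerate = var_x <= _DEGENERATE * n
        safe = xtx.copy()
        safe[self.degenerate] = np.eye(4)
        self.xtx_inv = np.linalg.inv(safe)

    def f_stats(self, Y: np.ndarray) -> np.ndarray:
        """F statistics, shape (m, R)."""
        yo = _obs_matrix(Y)                      # (n, R)
        n = self.n
        sy = yo.sum(axis=0)                      # (R,)
        sys_ = (yo * self.s[:, None]).sum(axis=0)
        syy = (yo ** 2).sum(axis=0)
        sxy = self.flat.T @ yo                   # (m, R)
        sxys = self.flat_s.T @ yo
        R = yo.shape[1]
        xty = np.empty((self.m, 4, R))
        xty[:, 0, :] = sy[None, :]
        xty[:, 1, :] = sys_[None, :]
        xty[:, 2, :] = sxy
        xty[:, 3, :] = sxys
        beta = np.einsum("mij,mjr->mir", self.xtx_inv, xty)
        sse = syy[None, :] - np.einsum("mir,mir->mr", beta, xty)
        sse0 = syy - sy ** 2 / n - sys_ ** 2 / n
        sse = np.maximum(sse, 0.0)
        f = _f_ratio(sse0[None, :] - sse, sse, self.df_num, self.df_den)
        f[self.degenerate, :] = 0.0
        return f

    def p_nominal(self, f: np.ndarray) -> np.ndarray:
        return stats.f.sf(f, self.df_num, self.df_den)


class _PairKernel:
    """Epistasis F statistics for candidate pairs (2 df: qq and qq-by-sex).

    Full model per pair: [1, s, xi, xj, xi*s, xj*s, xij, xij*s]; reduced
    model drops the last two columns.
    """

    def __init__(self, values: np.ndarray, pair_idx: list):
        L, _, _ = values.shape
        self.n = 2 * L
        self.n_pairs = len(pair_idx)
        self.df_num = 2
        self.df_den = self.n - 8
        flat = values.reshape(self.n, -1)
        s = np.tile(np.array([1.0, -1.0]), L)
        designs = np.empty((self.n_pairs, self.n, 8))
        for p, (i, j) in enumerate(pair_idx):
            xi, xj = flat[:, i], flat[:, j]
            xij = xi * xj
            designs[p] = np.column_stack(
                [np.ones(self.n), s, xi, xj, xi * s, xj * s, xij, xij * s]
            )
        self.designs = designs
        eye8 = np.eye(8) * 1e-10
        eye6 = np.eye(6) * 1e-10
        xtx_full = np.einsum("pnk,pnl->pkl", designs, designs)
        xtx_red = xtx_full[:, :6, :6]
        self.inv_full = np.linalg.inv(xtx_full + eye8)
        self.inv_red = np.linalg.inv(xtx_red + eye6)
        # a pair is degenerate when its interaction column lies in the span
        # of the main-effect columns (e.g. perfectly linked loci)
        xij = designs[:, :, 6]
        cross = np.einsum("pnk,pn->pk", designs[:, :, :6], xij)
        proj = np.einsum("pk,pkl,pl->p", cross, self.inv_red, cross)
        total = np.einsum("pn,pn->p", xij, xij)
        self.degenerate = (total - proj) <= 1e-8 * np.maximum(total, 1.0)

    def f_stats(self, Y: np.ndarray) -> np.ndarray:
        """F statistics, shape (n_pairs, R)."""
        yo = _obs_matrix(Y)
        syy = (yo ** 2).sum(axis=0)
        xty = np.einsum("pnk,nr->pkr", self.designs, yo)
        beta_f = np.einsum("pij,pjr->pir", self.inv_full, xty)
        sse_f = np.maximum(
            syy[None, :] - np.einsum("pir,pir->pr", beta_f, xty), 0.0
        )
        xty_r = xty[:, :6, :]
        beta_r = np.einsum("pij,pjr->pir", self.inv_red, xty_r)
        sse_r = np.maximum(
            syy[None, :] - np.einsum("pir,pir->pr", beta_r, xty_r), 0.0
        )
        f = _f_ratio(sse_r - sse_f, sse_f, self.df_num, self.df_den)
        f[self.degenerate, :] = 0.0
        return f

    def p_nominal(self, f: np.ndarray) -> np.ndarray:
        return stats.f.sf(f, self.df_num, self.df_den)


def _permuted_responses(Y: np.ndarray, n_perm: int, seed: int) -> np.ndarray:
    """Stack of permuted responses, shape (n_perm, L, 2).

    Line labels are shuffled jointly across the two sex slices, so each
    line's male/female pairing is preserved and the sex main effect
    survives under the null.
    """
    rng = np.random.default_rng(seed)
    L = Y.shape[0]
    out = np.empty((n_perm, L, 2))
    for r in range(n_perm):
        out[r] = Y[rng.permutation(L)]
    return out


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def prescreen_candidates(
    response: np.ndarray, predictors: PredictorSet, config: ScanConfig
) -> pd.DataFrame:
    """Single-locus screen of every predictor.

    Fits main effect + sex + locus-by-sex per predictor and keeps those
    with nominal locus P below ``config.prescreen_alpha``.  Returns a
    DataFrame (id, F, p_nominal) ordered by P then genomic position.
    """
    kernel = _LocusKernel(predictors.values)
    f = kernel.f_stats(np.asarray(response))[:, 0]
    p = kernel.p_nominal(f)
    rows = [
        (pid, float(f[i]), float(p[i]))
        for i, pid in enumerate(predictors.ids)
        if p[i] < config.prescreen_alpha and not kernel.degenerate[i]
    ]
    rows.sort(key=lambda r: (r[2], predictors.sort_key(r[0])))
    return pd.DataFrame(rows, columns=["id", "F", "p_nominal"])


def candidate_pairs(
    candidates: list, predictors: PredictorSet, config: ScanConfig
) -> list:
    """All unordered candidate pairs, truncated to ``pair_budget``.

    When the budget is exceeded, the top candidates (input order, i.e.
    marginal-P order) are paired and the rest dropped with a warning.
    """
    cands = list(candidates)
    n_full = len(cands) * (len(cands) - 1) // 2
    if n_full > config.pair_budget:
        k = int((1 + math.isqrt(1 + 8 * config.pair_budget)) // 2)
        warnings.warn(
            f"{n_full} candidate pairs exceed pair_budget="
            f"{config.pair_budget}; pairing only the top {k} candidates",
            stacklevel=2,
        )
        cands = cands[:k]
    return list(combinations(cands, 2))


def permutation_critical_f(
    response: np.ndarray,
    predictors: PredictorSet,
    config: ScanConfig,
    pairs: list | None = None,
    chunk: int = 250,
) -> PermutationNull:
    """Permutation null of the scan-family maximum F.

    The family is every predictor's single-locus statistic plus (when
    ``pairs`` is given) every candidate pair's epistasis statistic; one
    maximum is recorded per permutation and a single critical F controls
    the whole scan at ``alpha_ew``.
    """
    Y = np.asarray(response, dtype=float)
    locus_kernel = _LocusKernel(predictors.values)
    idx = {pid: i for i, pid in enumerate(predictors.ids)}
    pair_kernel = None
    if pairs:
        pair_kernel = _PairKernel(
            predictors.values, [(idx[i], idx[j]) for i, j in pairs]
        )
    n_perm = config.n_permutations
    null_max = np.empty(n_perm)
    done = 0
    while done < n_perm:
        take = min(chunk, n_perm - done)
        yp = _permuted_responses(Y, take, config.seed + 7919 * done)
        fmax = locus_kernel.f_stats(yp).max(axis=0)
        if pair_kernel is not None:
            fmax = np.maximum(fmax, pair_kernel.f_stats(yp).max(axis=0))
        null_max[done:done + take] = fmax
        done += take
    return PermutationNull(null_max, config.alpha_ew, n_perm)


def _result_table(ids, f, p_nom, null: PermutationNull, term_type: str) -> pd.DataFrame:
    p_ew = null.p_ew(f)
    crit = null.critical_f
    rows = []
    for k, term in enumerate(ids):
        id1, id2 = (term, "") if isinstance(term, str) else term
        rows.append((term_type, id1, id2, float(f[k]), float(p_nom[k]),
                     float(p_ew[k]), float(-np.log10(p_ew[k])),
                     bool(f[k] >= crit)))
    return pd.DataFrame(rows, columns=[
        "term_type", "id1", "id2", "F", "p_nominal", "p_ew",
        "neglog10_p_ew", "passed",
    ])


def scan_main_effects(
    response: np.ndarray,
    predictors: PredictorSet,
    candidates: list,
    null: PermutationNull,
) -> ScanResult:
    """1D scan: each candidate's single-locus F against the critical F."""
    sub = predictors.subset(list(candidates))
    if sub.n_predictors == 0:
        table = _result_table([], np.empty(0), np.empty(0), null, "main")
    else:
        kernel = _LocusKernel(sub.values)
        f = kernel.f_stats(np.asarray(response))[:, 0]
        table = _result_table(list(candidates), f, kernel.p_nominal(f), null, "main")
    return ScanResult(table, null.critical_f, null.n_permutations, null.alpha_ew)


def scan_epistasis(
    response: np.ndarray,
    predictors: PredictorSet,
    pairs: list,
    null: PermutationNull,
) -> ScanResult:
    """2D scan: epistasis (qq + qq-by-sex) F per candidate pair."""
    if not pairs:
        table = _result_table([], np.empty(0), np.empty(0), null, "epistasis")
    else:
        idx = {pid: i for i, pid in enumerate(predictors.ids)}
        kernel = _PairKernel(predictors.values, [(idx[i], idx[j]) for i, j in pairs])
        f = kernel.f_stats(np.asarray(response))[:, 0]
        table = _result_table(
            [tuple(p) for p in pairs], f, kernel.p_nominal(f), null, "epistasis"
        )
    return ScanResult(table, null.critical_f, null.n_permutations, null.alpha_ew)


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------

def _is_collinear(a: np.ndarray, b: np.ndarray) -> bool:
    if a.std() == 0 or b.std() == 0:
        return True
    return abs(np.corrcoef(a, b)[0, 1]) > 1 - 1e-10


def select_model(
    main_result: ScanResult,
    epi_result: ScanResult | None,
    predictors: PredictorSet,
    response: np.ndarray,
    config: ScanConfig,
) -> DesignSpec:
    """Forward inclusion then backward elimination of scan-passing terms.

    Mains passing the critical F enter first (ordered by F, ties broken by
    the smaller genomic position / lexicographic id, which also resolves
    perfectly collinear survivors: the first-entered is kept).  Pairs
    passing their threshold enter next; a pair pulls its member loci into
    the locus list.  Backward elimination then refits the joint model and
    drops the weakest term whose joint-context partial F falls below the
    critical F, until every scan-selected term remains experiment-wise
    significant.  Loci present only as pair members are exempt.
    """
    crit = main_result.critical_f
    mt = main_result.table
    passing = mt[mt["passed"]]
    order = sorted(
        passing.itertuples(index=False),
        key=lambda r: (-r.F, predictors.sort_key(r.id1)),
    )
    flat = {pid: predictors.column(pid).reshape(-1) for pid in predictors.ids}
    chosen_mains: list[str] = []
    for row in order:
        if any(_is_collinear(flat[row.id1], flat[kept]) for kept in chosen_mains):
            continue
        chosen_mains.append(row.id1)

    def canonical(pid: str) -> str:
        # map perfectly linked loci onto the representative already chosen
        for kept in loci:
            if _is_collinear(flat[pid], flat[kept]):
                return kept
        return pid

    selected_on_merit = set(chosen_mains)
    loci = list(chosen_mains)
    chosen_pairs: list[tuple] = []
    epi_crit = crit
    if epi_result is not None:
        epi_crit = epi_result.critical_f
        et = epi_result.table
        for row in sorted(
            et[et["passed"]].itertuples(index=False),
            key=lambda r: (-r.F, r.id1, r.id2),
        ):
            pair = (canonical(row.id1), canonical(row.id2))
            if pair[0] == pair[1] or pair in chosen_pairs \
                    or (pair[1], pair[0]) in chosen_pairs:
                continue
            chosen_pairs.append(pair)
            for pid in pair:
                if pid not in loci:
                    loci.append(pid)

    while loci or chosen_pairs:
        spec = DesignSpec(loci=list(loci), pairs=list(chosen_pairs),
                          response="selection")
        design = encode_design(spec, predictors.subset(loci), np.asarray(response))
        model = fit_fixed_model(design)
        weakest, weakest_ratio = None, 1.0
        for locus in loci:
            if locus not in selected_on_merit:
                continue
            f, _ = partial_f(model, design.cols_for_locus(locus))
            if f / crit < weakest_ratio:
                weakest, weakest_ratio = ("locus", locus), f / crit
        for pair in chosen_pairs:
            f, _ = partial_f(model, design.cols_for_pair(pair))
            if f / epi_crit < weakest_ratio:
                weakest, weakest_ratio = ("pair", pair), f / epi_crit
        if weakest is None or weakest_ratio >= 1.0:
            break
        kind, term = weakest
        if kind == "locus":
            loci.remove(term)
            selected_on_merit.discard(term)
        else:
            chosen_pairs.remove(term)
        # drop pair-only loci orphaned by a removed pair
        needed = selected_on_merit | {p for pr in chosen_pairs for p in pr}
        loci = [l for l in loci if l in needed]

    return DesignSpec(loci=loci, pairs=chosen_pairs, response="selected")
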