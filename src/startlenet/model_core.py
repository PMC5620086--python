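"""Design encoding, fixed-effect fitting, Gibbs estimation, and heritability.

The model is a fixed-effect linear parameterisation of the additive +
epistatic + sex-interaction architecture

    y_kh = mu + sum_i q_i u_ik + sum_{i<j} qq_ij u_ijk + e_h
         + sum_i qe_ih u_ikh + sum_{i<j} qqe_ijh u_ijkh + eps_kh

observed on line x sex means (two observations per line by default; the
model has no replicate term).  SNP predictors are coded +1 for the
major-allele homozygote and -1 for the minor; transcript predictors are
standardized to mean 0, SD 1 within each sex; the sex contrast is +1 for
females and -1 for males; interaction coefficients are elementwise
products.  Frequentist F-tests drive detection, a Gibbs sampler under
weakly-informative hierarchical priors provides the reported effect
estimates, and the variance decomposition

    V_P = V_Q + V_QQ + V_QE + V_QQE + V_eps

with heritabilities h2_* = V_*/V_P uses the population (divide-by-n)
variance of each term group's fitted contribution, so a noise-free fit
gives total heritability exactly 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .io_formats import SEXES, ExpressionPanel, GenotypePanel

logger = logging.getLogger(__name__)

#: Fixed ordering of term kinds in a design matrix.
TERM_ORDER = ("mu", "sex", "q", "qq", "qe", "qqe")

#: Variance-component group for each effect kind.
GENETIC_KINDS = ("q", "qq", "qe", "qqe")


# ---------------------------------------------------------------------------
# Predictors
# ---------------------------------------------------------------------------

@dataclass
class PredictorSet:
    """Per-line, per-sex predictor values for a set of loci or transcripts.

    ``values`` has shape ``(n_lines, 2, m)`` with the sex axis ordered
    (female, male).  SNP codes are constant across the two sexes;
    transcript predictors are sex-specific.
    """

    ids: list[str]
    values: np.ndarray
    positions: pd.DataFrame | None = None   # index=id, columns chrom, pos

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        self._index = {pid: i for i, pid in enumerate(self.ids)}

    @classmethod
    def from_genotypes(cls, panel: GenotypePanel) -> "PredictorSet":
        codes = panel.codes()                       # (L, m)
        values = np.repeat(codes[:, None, :], 2, axis=1)
        return cls(panel.snp_ids, values, panel.snps[["chrom", "pos"]].copy())

    @classmethod
    def from_expression(
        cls, panel: ExpressionPanel, standardize: bool = True, exclude=()
    ) -> "PredictorSet":
        """Transcript predictors, standardized per sex (mean 0, SD 1).

        ``exclude`` removes transcripts (e.g. a mapping target from its own
        predictor set).
        """
        keep = [i for i, t in enumerate(panel.transcript_ids) if t not in set(exclude)]
        ids = [panel.transcript_ids[i] for i in keep]
        values = panel.values[:, keep, :].transpose(0, 2, 1).copy()  # (L, 2, m)
        if standardize:
            mean = values.mean(axis=0, keepdims=True)
            sd = values.std(axis=0, keepdims=True)
            safe = np.where(sd > 0, sd, 1.0)
            values = (values - mean) / safe
        return cls(ids, values)

    @property
    def n_lines(self) -> int:
        return self.values.shape[0]

    @property
    def n_predictors(self) -> int:
        return len(self.ids)

    def column(self, pid: str) -> np.ndarray:
        """Predictor values as a ``(n_lines, 2)`` array."""
        try:
            return self.values[:, :, self._index[pid]]
        except KeyError:
            raise KeyError(f"unknown predictor id {pid!r}") from None

    def sort_key(self, pid: str):
        """Deterministic ordering key: genomic position when known, else id."""
        if self.positions is not None and pid in self.positions.index:
            row = self.positions.loc[pid]
            return (0, str(row["chrom"]), int(row["pos"]), pid)
        return (1, pid, 0, pid)

    def subset(self, ids) -> "PredictorSet":
        idx = [self._index[pid] for pid in ids]
        pos = None
        if self.positions is not None:
            pos = self.positions.loc[[pid for pid in ids if pid in self.positions.index]]
        return PredictorSet(list(ids), self.values[:, :, idx], pos)

    def degenerate_ids(self, tol: float = 1e-12) -> list:
        """Predictors with (numerically) zero variance over observations."""
        flat = self.values.reshape(-1, self.n_predictors)
        return [pid for pid, v in zip(self.ids, flat.var(axis=0)) if v <= tol]


# ---------------------------------------------------------------------------
# Design
# ---------------------------------------------------------------------------

@dataclass
class DesignSpec:
    """Term structure of one model fit."""

    loci: list = field(default_factory=list)
    pairs: list = field(default_factory=list)          # [(i, j), ...]
    include_sex: bool = True
    include_qe: bool = True
    include_qqe: bool = True
    response: str = "phenotype"
    observation_unit: str = "line_sex_means"

    def __post_init__(self) -> None:
        locus_set = set(self.loci)
        for i, j in self.pairs:
            if i == j:
                raise ValueError(f"self-pair ({i}, {j}) is not allowed")
            if i not in locus_set or j not in locus_set:
                raise ValueError(
                    f"pair ({i}, {j}) references loci outside the model's locus list"
                )


@dataclass
class Design:
    """Encoded design matrix and response for one fit."""

    X: np.ndarray
    y: np.ndarray
    labels: list                      # [("mu",), ("sex",), ("q", id), ...]
    n_lines: int
    spec: DesignSpec
    dropped: list = field(default_factory=list)   # zero-variance columns removed

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def n_params(self) -> int:
        return self.X.shape[1]

    def cols(self, kind: str) -> np.ndarray:
        return np.array([i for i, lab in enumerate(self.labels) if lab[0] == kind],
                        dtype=int)

    def cols_for_locus(self, locus: str) -> np.ndarray:
        return np.array(
            [i for i, lab in enumerate(self.labels)
             if lab[0] in ("q", "qe") and lab[1] == locus], dtype=int)

    def cols_for_pair(self, pair) -> np.ndarray:
        return np.array(
            [i for i, lab in enumerate(self.labels)
             if lab[0] in ("qq", "qqe") and lab[1:] == tuple(pair)], dtype=int)


def sex_contrast(n_lines: int) -> np.ndarray:
    """Observation-level sex contrast (+1 female, -1 male), line-major order."""
    return np.tile(np.array([1.0, -1.0]), n_lines)


def encode_design(
    spec: DesignSpec, predictors: PredictorSet, response: np.ndarray
) -> Design:
    """Build the design matrix for ``spec``.

    ``response`` is a ``(n_lines, 2)`` array of line x sex observations
    (replicate means for the phenotype, raw abundance for a transcript
    target).  Columns are laid out in the fixed order intercept, sex,
    main loci, epistasis pairs, locus-by-sex, pair-by-sex.  Zero-variance
    predictor columns are excluded with a warning; unknown ids raise.
    """
    response = np.asarray(response, dtype=float)
    L = predictors.n_lines
    if response.shape != (L, 2):
        raise ValueError(f"response shape {response.shape} != ({L}, 2)")
    y = response.reshape(-1)
    s = sex_contrast(L)
    cols: list[np.ndarray] = [np.ones(2 * L)]
    labels: list[tuple] = [("mu",)]
    dropped: list[tuple] = []
    if spec.include_sex:
        cols.append(s)
        labels.append(("sex",))

    def add(lab: tuple, col: np.ndarray) -> None:
        if col.var() <= 1e-12:
            dropped.append(lab)
            return
        cols.append(col)
        labels.append(lab)

    main = {locus: predictors.column(locus).reshape(-1) for locus in spec.loci}
    for locus in spec.loci:
        add(("q", locus), main[locus])
    for i, j in spec.pairs:
        add(("qq", i, j), main[i] * main[j])
    if spec.include_qe:
        for locus in spec.loci:
            add(("qe", locus), main[locus] * s)
    if spec.include_qqe:
        for i, j in spec.pairs:
            add(("qqe", i, j), main[i] * main[j] * s)
    if dropped:
        warnings.warn(
            f"excluded zero-variance design columns: {dropped}", stacklevel=2
        )
    return Design(np.column_stack(cols), y, labels, L, spec, dropped)


# ---------------------------------------------------------------------------
# Fixed-effect fit
# ---------------------------------------------------------------------------

@dataclass
class FittedModel:
    """Least-squares fit with per-term tests and variance decomposition."""

    design: Design
    beta: np.ndarray
    se: np.ndarray
    f_stats: np.ndarray              # per-column partial F (1 df)
    p_values: np.ndarray
    sse: float
    sigma2: float                    # unbiased residual variance SSE/(n-p)
    df_resid: int
    variance_components: dict = field(default_factory=dict)
    heritabilities: dict = field(default_factory=dict)
    r2_ghat_y: float | None = None
    predicted: np.ndarray | None = None
    posterior: "GibbsResult | None" = None

    @property
    def labels(self) -> list:
        return self.design.labels

    @property
    def mu_hat(self) -> float:
        return float(self.beta[self.labels.index(("mu",))])

    def effect(self, label: tuple) -> float:
        """Point estimate for one term; posterior mean when MCMC has run."""
        i = self.labels.index(tuple(label))
        if self.posterior is not None:
            return float(self.posterior.mean[i])
        return float(self.beta[i])

    def effects_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "term": ["/".join(map(str, lab)) for lab in self.labels],
            "estimate": self.beta,
            "se": self.se,
            "F": self.f_stats,
            "neglog10_p": -np.log10(np.maximum(self.p_values, 1e-300)),
        })
        if self.posterior is not None:
            df["posterior_mean"] = self.posterior.mean
            df["posterior_sd"] = self.posterior.sd
        return df


def fit_fixed_model(design: Design) -> FittedModel:
    """Ordinary least squares with per-term F tests.

    Raises on rank deficiency (listing the aliased columns) and when the
    number of observations is below ``n_params + 2``.
    """
    X, y = design.X, design.y
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"{n} observations cannot support {p} parameters (+2)")
    q, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < p:
        aliased = [design.labels[piv[i]] for i in range(rank, p)]
        raise ValueError(
            f"design is rank deficient; aliased columns: {aliased}"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sse = float(resid @ resid)
    df_resid = n - p
    sigma2 = sse / df_resid
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    f = t ** 2
    pvals = stats.f.sf(f, 1, df_resid)
    return FittedModel(design, beta, se, f, pvals, sse, sigma2, df_resid)


def partial_f(model: FittedModel, cols) -> tuple[float, float]:
    """Partial F test for jointly dropping ``cols`` from the fitted model."""
    cols = np.atleast_1d(np.asarray(cols, dtype=int))
    if cols.size == 0:
        return 0.0, 1.0
    X, y = model.design.X, model.design.y
    keep = np.setdiff1d(np.arange(X.shape[1]), cols)
    beta_r, *_ = np.linalg.lstsq(X[:, keep], y, rcond=None)
    resid = y - X[:, keep] @ beta_r
    sse_r = float(resid @ resid)
    k = cols.size
    f = max((sse_r - model.sse) / k, 0.0) / (model.sse / model.df_resid)
    return f, float(stats.f.sf(f, k, model.df_resid))


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------

@dataclass
class GibbsConfig:
    """MCMC settings for effect estimation.

    Effects within each term group (q, qq, qe, qqe) share a normal prior
    with a group-level variance under an inverse-gamma hyperprior; the
    intercept and sex effect are effectively unshrunk.  Defaults follow
    the study's 20,000-iteration run with 10% burn-in and thinning of 10.
    """

    iterations: int = 20_000
    burn_in: int | None = None
    thin: int = 10
    prior_a: float = 0.01
    prior_b: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in is None:
            self.burn_in = self.iterations // 10
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError("burn_in must be < iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class GibbsResult:
    """Posterior summaries aligned with the design's column labels."""

    labels: list
    mean: np.ndarray
    sd: np.ndarray
    rhat: np.ndarray
    n_samples: int

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": ["/".join(map(str, lab)) for lab in self.labels],
            "posterior_mean": self.mean,
            "posterior_sd": self.sd,
            "split_rhat": self.rhat,
        })


def _split_rhat(draws: np.ndarray) -> np.ndarray:
    """Split-chain potential-scale-reduction per coefficient."""
    m = draws.shape[0] // 2
    a, b = draws[:m], draws[m:2 * m]
    mean_a, mean_b = a.mean(axis=0), b.mean(axis=0)
    var_a, var_b = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    w = (var_a + var_b) / 2
    bvar = m * (mean_a - mean_b) ** 2 / 2
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(((m - 1) / m * w + bvar / m) / w)
    return np.where(w > 0, rhat, 1.0)


def gibbs_estimate(design: Design, config: GibbsConfig | None = None) -> GibbsResult:
    """Gibbs sampler for the fixed-effect coefficients.

    Blocked updates: the full coefficient vector from its multivariate
    normal conditional, then the residual and group variances from their
    conjugate inverse-gamma conditionals.  A split-chain diagnostic above
    1.1 triggers a warning (never an error).
    """
    if config is None:
        config = GibbsConfig()
    rng = np.random.default_rng(config.seed)
    X, y = design.X, design.y
    n, p = X.shape
    xtx = X.T @ X
    xty = X.T @ y
    yty = float(y @ y)

    groups: dict[str, np.ndarray] = {}
    for kind in GENETIC_KINDS:
        cols = design.cols(kind)
        if cols.size:
            groups[kind] = cols
    flat_prior_var = 1e6 * max(float(y.var()), 1.0)

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sigma2_e = max(float(resid @ resid) / max(n - p, 1), 1e-12)
    sigma2_g = {
        kind: max(float(np.mean(beta[cols] ** 2)), 1e-6)
        for kind, cols in groups.items()
    }

    a, b = config.prior_a, config.prior_b
    kept = []
    for it in range(config.iterations):
        prec = np.full(p, 1.0 / flat_prior_var)
        for kind, cols in groups.items():
            prec[cols] = 1.0 / sigma2_g[kind]
        A = xtx / sigma2_e + np.diag(prec)
        chol = linalg.cho_factor(A, lower=True)
        mean = linalg.cho_solve(chol, xty / sigma2_e)
        z = rng.standard_normal(p)
        beta = mean + linalg.solve_triangular(chol[0], z, lower=True, trans="T")
        resid_ss = yty - 2 * beta @ xty + beta @ xtx @ beta
        sigma2_e = 1.0 / rng.gamma(a + n / 2, 1.0 / (b + max(resid_ss, 0.0) / 2))
        for kind, cols in groups.items():
            ssq = float(np.sum(beta[cols] ** 2))
            sigma2_g[kind] = 1.0 / rng.gamma(
                a + cols.size / 2, 1.0 / (b + ssq / 2)
            )
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            kept.append(beta.copy())

    draws = np.asarray(kept)
    rhat = _split_rhat(draws)
    if np.nanmax(rhat) > 1.1:
        worst = design.labels[int(np.nanargmax(rhat))]
        warnings.warn(
            f"Gibbs split-chain diagnostic {np.nanmax(rhat):.3f} > 1.1 for "
            f"term {worst}; consider more iterations", stacklevel=2,
        )
    return GibbsResult(
        design.labels, draws.mean(axis=0), draws.std(axis=0, ddof=1),
        rhat, draws.shape[0],
    )


# ---------------------------------------------------------------------------
# Variance components and heritability
# ---------------------------------------------------------------------------

def variance_components(model: FittedModel) -> dict:
    """Variance decomposition of the fitted model.

    Each genetic component is the population variance, over the line x sex
    observations, of that term group's fitted contribution; the residual
    component is SSE/n; V_P is their sum, so the decomposition identity
    holds exactly.  Results are stored on the model and returned.
    """
    X = model.design.X
    beta = model.beta
    n = model.design.n_obs
    comps = {}
    for kind in GENETIC_KINDS:
        cols = model.design.cols(kind)
        if cols.size:
            contrib = X[:, cols] @ beta[cols]
            comps[f"V_{kind.upper()}"] = float(contrib.var())
        else:
            comps[f"V_{kind.upper()}"] = 0.0
    comps["V_eps"] = model.sse / n
    comps["V_P"] = (comps["V_Q"] + comps["V_QQ"] + comps["V_QE"]
                    + comps["V_QQE"] + comps["V_eps"])
    model.variance_components = comps
    return comps


def term_variance(model: FittedModel, cols) -> float:
    """Population variance of the fitted contribution of a column subset."""
    cols = np.atleast_1d(np.asarray(cols, dtype=int))
    if cols.size == 0:
        return 0.0
    contrib = model.design.X[:, cols] @ model.beta[cols]
    return float(contrib.var())


def heritability(model: FittedModel) -> dict:
    """Heritability decomposition h2_* = V_*/V_P (plus per-term shares).

    Requires :func:`variance_components` (run automatically if absent).
    Raises when V_P is zero.
    """
    if not model.variance_components:
        variance_components(model)
    comps = model.variance_components
    vp = comps["V_P"]
    if vp <= 0:
        raise ValueError("V_P is zero; heritability undefined")
    h2 = {f"h2_{kind.upper()}": comps[f"V_{kind.upper()}"] / vp
          for kind in GENETIC_KINDS}
    h2["h2_T"] = h2["h2_Q"] + h2["h2_QQ"] + h2["h2_QE"] + h2["h2_QQE"]
    per_term = {}
    for i, lab in enumerate(model.labels):
        if lab[0] in GENETIC_KINDS:
            per_term[lab] = term_variance(model, [i]) / vp
    h2["per_term"] = per_term
    model.heritabilities = h2
    return h2


def heritability_from_components(components: dict) -> dict:
    """Heritability decomposition from explicit variance components.

    ``components`` maps ``V_Q``, ``V_QQ``, ``V_QE``, ``V_QQE``, ``V_eps``
    to values on any common scale (only ratios matter).
    """
    vals = {k: float(components.get(k, 0.0))
            for k in ("V_Q", "V_QQ", "V_QE", "V_QQE", "V_eps")}
    vp = sum(vals.values())
    if vp <= 0:
        raise ValueError("V_P is zero; heritability undefined")
    h2 = {f"h2_{k[2:]}": v / vp for k, v in vals.items() if k != "V_eps"}
    h2["h2_T"] = h2["h2_Q"] + h2["h2_QQ"] + h2["h2_QE"] + h2["h2_QQE"]
    return h2


def predict_and_r2(model: FittedModel) -> tuple[np.ndarray, float]:
    """Predicted genotypic values and the determination coefficient.

    The prediction is the model's systematic part (all fitted terms,
    excluding the residual); R2 is the squared Pearson correlation between
    prediction and observed response.  A constant prediction yields R2 = 0
    with a warning.
    """
    ghat = model.design.X @ model.beta
    y = model.design.y
    scale = max(1.0, float(np.abs(ghat).max(initial=0.0)))
    if ghat.std() <= 1e-12 * scale or y.std() == 0:
        warnings.warn("constant prediction; R2 defined as 0", stacklevel=2)
        model.r2_ghat_y = 0.0
        model.predicted = ghat
        return ghat, 0.0
    r = float(np.corrcoef(ghat, y)[0, 1])
    model.r2_ghat_y = r ** 2
    model.predicted = ghat
    return ghat, r ** 2
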