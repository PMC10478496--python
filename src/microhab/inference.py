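"""Bayesian fitting of grouped ZOIB models, DIC, and the nine-model ladder.

For each habitat category, used-vs-available selection is assessed by fitting
the quadrat proportions with ZOIB distributions whose parameters are indexed
by observation group. Nine model variants are compared:

====================  =======================  ==========================
grouping              mean-parameter groups    precision (phi) groups
====================  =======================  ==========================
null                  {all}                    {all} (shared only)
lizard                {random, lizard}         shared, or {random, lizard}
sex                   {random, female, male}   shared, or {random, lizard}
parity                {random, ovi, viv}       shared, or {random, lizard}
parity_sex            {random, ovi/viv x F/M}  shared, or {random, lizard}
====================  =======================  ==========================

Parameters are sampled on transformed scales (logit for alpha, gamma, mu; log
for phi) under independent normal priors, with an adaptive random-walk
Metropolis-within-Gibbs sampler. Because the ZOIB likelihood factorises over
atom counts and interior-value sufficient statistics (sum log y, sum
log(1-y)), every conditional evaluation is O(1) in the sample size.

Model comparison uses the deviance information criterion
DIC = D_bar + pD with pD = D_bar - D_hat, where D_bar is the posterior mean
deviance and D_hat the deviance at the posterior means of the
transformed-scale parameters. The selection rule takes the lowest-DIC model
unless a strictly simpler model lies within 2 DIC of the minimum, in which
case the simpler model is preferred.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .data_model import HabitatCategory, Parity, Sex, SiteObservation
from .zoib import GammaMode

__all__ = [
    "ModelScheme", "NINE_SCHEMES", "PriorSpec", "MCMCConfig", "PosteriorFit",
    "DICResult", "SelectionResult", "GroupAssignment", "assign_groups",
    "determine_gamma_mode", "fit_zoib", "fit_zoib_values", "compute_dic",
    "fit_all_models", "ModelComparison", "select_model", "posterior_summary",
    "scheme_complexity",
]


# --- schemes ---------------------------------------------------------------

GROUPINGS = ("null", "lizard", "sex", "parity", "parity_sex")
PRECISION_MODES = ("shared", "variable")

_MEAN_GROUPS = {
    "null": ["all"],
    "lizard": ["random", "lizard"],
    "sex": ["random", "female", "male"],
    "parity": ["random", "oviparous", "viviparous"],
    "parity_sex": [
        "random",
        "oviparous_female", "oviparous_male",
        "viviparous_female", "viviparous_male",
    ],
}


@dataclass(frozen=True, order=True)
class ModelScheme:
    """One rung of the model ladder: a grouping plus a precision mode."""

    grouping: str
    precision_mode: str = "shared"

    def __post_init__(self) -> None:
        if self.grouping not in GROUPINGS:
            raise ValueError(f"unknown grouping {self.grouping!r}")
        if self.precision_mode not in PRECISION_MODES:
            raise ValueError(f"unknown precision mode {self.precision_mode!r}")
        if self.grouping == "null" and self.precision_mode != "shared":
            raise ValueError("the null model admits only shared precision")

    @property
    def mean_groups(self) -> list[str]:
        return list(_MEAN_GROUPS[self.grouping])

    @property
    def phi_groups(self) -> list[str]:
        return ["all"] if self.precision_mode == "shared" else ["random", "lizard"]

    def __str__(self) -> str:  # e.g. "lizard/shared"
        return f"{self.grouping}/{self.precision_mode}"


#: the nine valid (grouping, precision) combinations, null/variable excluded
NINE_SCHEMES: tuple[ModelScheme, ...] = tuple(
    ModelScheme(g, p)
    for g in GROUPINGS
    for p in PRECISION_MODES
    if not (g == "null" and p == "variable")
)


def scheme_complexity(scheme: ModelScheme) -> tuple[int, int]:
    """Complexity key: (number of mean-parameter groups, precision rank).

    Ordered lexicographically: null(1) < lizard(2) < sex = parity(3) <
    parity_sex(5), with shared precision simpler than variable at equal group
    count. Sex and parity are equal-complexity; between them lower DIC decides.
    """
    return (len(scheme.mean_groups), PRECISION_MODES.index(scheme.precision_mode))


# --- priors and sampler configuration -------------------------------------

@dataclass(frozen=True)
class PriorSpec:
    """Independent normal priors on the transformed scales.

    ``Normal(0, v)`` is read with ``v`` as a VARIANCE by default (v=1000 means
    sd ~ 31.6 — genuinely minimally informative). Set
    ``interpret_as="precision"`` for the BUGS-family reading (v as 1/variance)
    for sensitivity analysis.
    """

    v_alpha: float = 1000.0
    v_gamma: float = 1.0
    v_mu: float = 1000.0
    v_phi: float = 100.0
    interpret_as: str = "variance"

    def __post_init__(self) -> None:
        for name in ("v_alpha", "v_gamma", "v_mu", "v_phi"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.interpret_as not in ("variance", "precision"):
            raise ValueError("interpret_as must be 'variance' or 'precision'")

    def sd(self, which: str) -> float:
        v = getattr(self, f"v_{which}")
        return math.sqrt(v) if self.interpret_as == "variance" else math.sqrt(1.0 / v)


@dataclass(frozen=True)
class MCMCConfig:
    chains: int = 4
    iterations: int = 10_000
    burn_in: int = 2_000
    thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations <= self.burn_in:
            raise ValueError("iterations must exceed burn_in")
        if self.chains < 2:
            raise ValueError("at least 2 chains are required for diagnostics")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return self.chains * (self.iterations - self.burn_in) // self.thin


# --- group assignment ------------------------------------------------------

@dataclass(frozen=True)
class GroupAssignment:
    """Mean-group and precision-group index for every observation."""

    mean_names: list[str]
    phi_names: list[str]
    mean_idx: np.ndarray  # (n,)
    phi_idx: np.ndarray  # (n,)
    #: phi-group index of each mean group (every mean group maps to one)
    mean_to_phi: np.ndarray  # (J,)


def _mean_group_of(obs: SiteObservation, grouping: str) -> str:
    g = obs.group
    if grouping == "null":
        return "all"
    if g.kind == "random":
        return "random"
    if grouping == "lizard":
        return "lizard"
    if grouping == "sex":
        if g.sex is Sex.NONE:
            raise ValueError(f"observation {obs.site_id}: sex required by scheme")
        return g.sex.value
    if grouping == "parity":
        if g.parity is Parity.NONE:
            raise ValueError(f"observation {obs.site_id}: parity required by scheme")
        return g.parity.value
    if g.sex is Sex.NONE or g.parity is Parity.NONE:
        raise ValueError(f"observation {obs.site_id}: sex and parity required")
    return f"{g.parity.value}_{g.sex.value}"


def assign_groups(
    observations: Sequence[SiteObservation], scheme: ModelScheme
) -> GroupAssignment:
    """Map each observation to its mean-parameter and precision groups.

    Every group the scheme defines is parameterised even if unpopulated; empty
    groups keep their prior and contribute nothing to the deviance.
    """
    mean_names = scheme.mean_groups
    phi_names = scheme.phi_groups
    mean_idx = np.array(
        [mean_names.index(_mean_group_of(o, scheme.grouping)) for o in observations],
        dtype=np.intp,
    )
    if scheme.precision_mode == "shared":
        phi_idx = np.zeros(len(observations), dtype=np.intp)
        mean_to_phi = np.zeros(len(mean_names), dtype=np.intp)
    else:
        phi_idx = np.array(
            [0 if o.group.kind == "random" else 1 for o in observations],
            dtype=np.intp,
        )
        mean_to_phi = np.array(
            [0 if name == "random" else 1 for name in mean_names], dtype=np.intp
        )
    return GroupAssignment(
        mean_names=mean_names,
        phi_names=phi_names,
        mean_idx=mean_idx,
        phi_idx=phi_idx,
        mean_to_phi=mean_to_phi,
    )


def determine_gamma_mode(values: Iterable[float]) -> GammaMode:
    """Pin gamma when an atom is absent from the data.

    No ones observed -> gamma fixed at 0; no zeros -> fixed at 1; both atoms
    present -> free. If neither atom occurs, gamma is fixed at 0 and alpha is
    interpreted as a (vanishing) zero-mass probability, with a warning.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("cannot determine gamma mode from an empty sample")
    has_zero = bool(np.any(vals == 0.0))
    has_one = bool(np.any(vals == 1.0))
    if has_zero and has_one:
        return GammaMode.FREE
    if not has_one and not has_zero:
        warnings.warn(
            "no atoms at 0 or 1 observed; fixing gamma=0 so alpha models the "
            "(empty) zero mass",
            stacklevel=2,
        )
        return GammaMode.FIXED_ZERO
    return GammaMode.FIXED_ZERO if not has_one else GammaMode.FIXED_ONE


# --- sufficient statistics -------------------------------------------------

@dataclass(frozen=True)
class _SuffStats:
    """Per-mean-group sufficient statistics of the ZOIB likelihood."""

    n0: np.ndarray
    n1: np.ndarray
    n_int: np.ndarray
    slog_y: np.ndarray
    slog_1my: np.ndarray
    mean_to_phi: np.ndarray
    n_phi: int


def _suff_stats(values: np.ndarray, assign: GroupAssignment) -> _SuffStats:
    J = len(assign.mean_names)
    n0 = np.zeros(J)
    n1 = np.zeros(J)
    n_int = np.zeros(J)
    slog_y = np.zeros(J)
    slog_1my = np.zeros(J)
    for j in range(J):
        y = values[assign.mean_idx == j]
        n0[j] = np.sum(y == 0.0)
        n1[j] = np.sum(y == 1.0)
        interior = y[(y > 0.0) & (y < 1.0)]
        n_int[j] = interior.size
        slog_y[j] = np.sum(np.log(interior))
        slog_1my[j] = np.sum(np.log1p(-interior))
    return _SuffStats(
        n0=n0, n1=n1, n_int=n_int, slog_y=slog_y, slog_1my=slog_1my,
        mean_to_phi=assign.mean_to_phi, n_phi=len(assign.phi_names),
    )


_LGAMMA = math.lgamma
_EXPIT_CLIP = 36.0  # beyond this expit saturates in double precision


def _expit(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def _log_expit(x: float) -> float:
    # log(sigmoid(x)), stable for large |x|
    return -math.log1p(math.exp(-x)) if x > -35 else x


def _beta_ll(stats: _SuffStats, j: int, mu: float, phi: float) -> float:
    n = stats.n_int[j]
    if n == 0:
        return 0.0
    a = mu * phi
    b = (1.0 - mu) * phi
    if a <= 0.0 or b <= 0.0 or not math.isfinite(a + b):
        return -math.inf
    return (
        n * (_LGAMMA(phi) - _LGAMMA(a) - _LGAMMA(b))
        + (a - 1.0) * stats.slog_y[j]
        + (b - 1.0) * stats.slog_1my[j]
    )


def _total_loglik(
    stats: _SuffStats,
    gamma_mode: GammaMode,
    alpha_logit: np.ndarray,
    gamma_logit: np.ndarray | None,
    mu_logit: np.ndarray,
    phi_log: np.ndarray,
) -> float:
    """Full-data log likelihood from sufficient statistics."""
    total = 0.0
    J = len(stats.n0)
    for j in range(J):
        n_atom = stats.n0[j] + stats.n1[j]
        n_all = n_atom + stats.n_int[j]
        if n_all == 0:
            continue  # empty group: prior only, no deviance contribution
        al = alpha_logit[j]
        total += n_atom * _log_expit(al) + stats.n_int[j] * _log_expit(-al)
        if gamma_mode is GammaMode.FREE:
            gl = gamma_logit[j]
            total += stats.n1[j] * _log_expit(gl) + stats.n0[j] * _log_expit(-gl)
        # pinned gamma: the surviving atom has conditional probability 1
        mu = _expit(mu_logit[j])
        phi = math.exp(phi_log[stats.mean_to_phi[j]])
        total += _beta_ll(stats, j, mu, phi)
    return total


# --- results containers ----------------------------------------------------

@dataclass
class PosteriorFit:
    """Posterior draws for one scheme, with deviance and diagnostics.

    Draw arrays are shaped ``(chains, n_draws, n_groups)`` on the transformed
    scale; natural-scale counterparts are exposed via :meth:`natural_draws`.
    """

    scheme: ModelScheme
    gamma_mode: GammaMode
    group_names: list[str]
    phi_group_names: list[str]
    alpha_logit: np.ndarray
    gamma_logit: np.ndarray | None
    mu_logit: np.ndarray
    phi_log: np.ndarray
    deviance_draws: np.ndarray  # (chains, n_draws)
    diagnostics: "pd.DataFrame"
    warnings: list[str]
    config: MCMCConfig
    _stats: _SuffStats = field(repr=False, default=None)

    @property
    def n_retained(self) -> int:
        return int(self.deviance_draws.size)

    def natural_draws(self, param: str) -> np.ndarray:
        """Natural-scale draws: 'alpha'|'gamma'|'mu' -> (chains, n, J); 'phi'."""
        from scipy.special import expit

        if param == "alpha":
            return expit(self.alpha_logit)
        if param == "mu":
            return expit(self.mu_logit)
        if param == "phi":
            return np.exp(self.phi_log)
        if param == "gamma":
            if self.gamma_mode is GammaMode.FIXED_ZERO:
                return np.zeros_like(self.alpha_logit)
            if self.gamma_mode is GammaMode.FIXED_ONE:
                return np.ones_like(self.alpha_logit)
            return expit(self.gamma_logit)
        raise KeyError(param)


@dataclass(frozen=True)
class DICResult:
    """Spiegelhalter-style DIC decomposition (lower is better)."""

    d_bar: float
    d_hat: float

    @property
    def p_d(self) -> float:
        return self.d_bar - self.d_hat

    @property
    def dic(self) -> float:
        return self.d_bar + self.p_d


@dataclass(frozen=True)
class SelectionResult:
    chosen: ModelScheme
    dic_table: dict[ModelScheme, float]
    rationale: str  # "lowest" | "simpler_within_2"


# --- the sampler -----------------------------------------------------------

def _init_point(stats: _SuffStats, gamma_mode: GammaMode, rng) -> dict[str, np.ndarray]:
    J = len(stats.n0)

    def logit(p):
        p = min(max(p, 0.02), 0.98)
        return math.log(p / (1 - p))

    alpha0 = np.zeros(J)
    gamma0 = np.zeros(J)
    mu0 = np.zeros(J)
    phi0 = np.zeros(stats.n_phi)
    for j in range(J):
        n_atom = stats.n0[j] + stats.n1[j]
        n = n_atom + stats.n_int[j]
        if n > 0:
            alpha0[j] = logit((n_atom + 0.5) / (n + 1.0))
        if n_atom > 0:
            gamma0[j] = logit((stats.n1[j] + 0.5) / (n_atom + 1.0))
        if stats.n_int[j] > 0:
            mean_log = stats.slog_y[j] / stats.n_int[j]
            mu0[j] = logit(math.exp(mean_log))
    for p in range(stats.n_phi):
        phi0[p] = math.log(10.0)  # data quickly dominate this rough start
    jitter = lambda arr: arr + rng.normal(0.0, 0.1, size=arr.shape)
    point = {
        "alpha_logit": jitter(alpha0),
        "mu_logit": jitter(mu0),
        "phi_log": jitter(phi0),
    }
    if gamma_mode is GammaMode.FREE:
        point["gamma_logit"] = jitter(gamma0)
    return point


def _run_chain(
    stats: _SuffStats,
    gamma_mode: GammaMode,
    priors: PriorSpec,
    config: MCMCConfig,
    rng: np.random.Generator,
):
    """One adaptive Metropolis-within-Gibbs chain over the transformed scale."""
    J = len(stats.n0)
    P = stats.n_phi
    free_gamma = gamma_mode is GammaMode.FREE

    sd_a, sd_g, sd_m, sd_p = (priors.sd(w) for w in ("alpha", "gamma", "mu", "phi"))
    point = _init_point(stats, gamma_mode, rng)
    alpha = point["alpha_logit"]
    mu = point["mu_logit"]
    phi = point["phi_log"]
    gamma = point.get("gamma_logit")

    # conditional log posteriors (likelihood factorises per parameter)
    def lp_alpha(x: float, j: int) -> float:
        n_atom = stats.n0[j] + stats.n1[j]
        return (
            n_atom * _log_expit(x)
            + stats.n_int[j] * _log_expit(-x)
            - 0.5 * (x / sd_a) ** 2
        )

    def lp_gamma(x: float, j: int) -> float:
        return (
            stats.n1[j] * _log_expit(x)
            + stats.n0[j] * _log_expit(-x)
            - 0.5 * (x / sd_g) ** 2
        )

    def lp_mu(x: float, j: int) -> float:
        m = _expit(x)
        if m <= 0.0 or m >= 1.0:
            return -math.inf
        f = math.exp(min(phi[stats.mean_to_phi[j]], 700.0))
        return _beta_ll(stats, j, m, f) - 0.5 * (x / sd_m) ** 2

    def lp_phi(x: float, p: int) -> float:
        if x > 700.0:
            return -math.inf
        f = math.exp(x)
        total = -0.5 * (x / sd_p) ** 2
        for j in range(J):
            if stats.mean_to_phi[j] == p and stats.n_int[j] > 0:
                m = _expit(mu[j])
                total += _beta_ll(stats, j, m, f)
        return total

    # parameter table: (array, index, conditional, has_data, prior sd)
    params = []
    for j in range(J):
        has = stats.n0[j] + stats.n1[j] + stats.n_int[j] > 0
        params.append((alpha, j, lp_alpha, has, sd_a))
    if free_gamma:
        for j in range(J):
            has = stats.n0[j] + stats.n1[j] > 0
            params.append((gamma, j, lp_gamma, has, sd_g))
    for j in range(J):
        params.append((mu, j, lp_mu, stats.n_int[j] > 0, sd_m))
    for p in range(P):
        has = any(
            stats.mean_to_phi[j] == p and stats.n_int[j] > 0 for j in range(J)
        )
        params.append((phi, p, lp_phi, has, sd_p))

    n_par = len(params)
    step = np.full(n_par, 0.5)

    n_keep = (config.iterations - config.burn_in) // config.thin
    out = {
        "alpha_logit": np.empty((n_keep, J)),
        "mu_logit": np.empty((n_keep, J)),
        "phi_log": np.empty((n_keep, P)),
        "deviance": np.empty(n_keep),
    }
    if free_gamma:
        out["gamma_logit"] = np.empty((n_keep, J))

    normals = rng.standard_normal((config.iterations, n_par))
    unifs = rng.random((config.iterations, n_par))
    log_unifs = np.log(unifs)
    kept = 0
    adapt_rate = 0.05

    for it in range(config.iterations):
        adapting = it < config.burn_in
        for k, (arr, i, fn, has_data, prior_sd) in enumerate(params):
            if not has_data:
                # posterior equals the prior: sample it exactly
                arr[i] = normals[it, k] * prior_sd
                continue
            # mu and phi conditionals are coupled, so evaluate the current
            # state fresh rather than caching it across updates
            prop = arr[i] + step[k] * normals[it, k]
            lp_cur = fn(arr[i], i)
            lp_new = fn(prop, i)
            accept = lp_new - lp_cur > log_unifs[it, k]
            if accept:
                arr[i] = prop
            if adapting:
                step[k] = min(
                    max(step[k] * math.exp(adapt_rate * ((1.0 if accept else 0.0) - 0.44)), 1e-3),
                    50.0,
                )
        if not adapting and (it - config.burn_in) % config.thin == 0:
            out["alpha_logit"][kept] = alpha
            out["mu_logit"][kept] = mu
            out["phi_log"][kept] = phi
            if free_gamma:
                out["gamma_logit"][kept] = gamma
            out["deviance"][kept] = -2.0 * _total_loglik(
                stats, gamma_mode, alpha, gamma, mu, phi
            )
            kept += 1
    return out


def fit_zoib_values(
    values: np.ndarray,
    assign: GroupAssignment,
    scheme: ModelScheme,
    priors: PriorSpec | None = None,
    config: MCMCConfig | None = None,
    gamma_mode: GammaMode | None = None,
) -> PosteriorFit:
    """Fit grouped ZOIB parameters to raw proportion values.

    This is the computational core behind :func:`fit_zoib`; tests and the
    synthetic-data workflows can call it with explicit group assignments.
    """
    import pandas as pd

    values = np.asarray(values, dtype=float)
    if np.any((values < 0) | (values > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    priors = priors or PriorSpec()
    config = config or MCMCConfig()
    if gamma_mode is None:
        gamma_mode = determine_gamma_mode(values)
    if gamma_mode is GammaMode.FIXED_ZERO and np.any(values == 1.0):
        raise ValueError("gamma fixed at 0 but ones are present in the data")
    if gamma_mode is GammaMode.FIXED_ONE and np.any(values == 0.0):
        raise ValueError("gamma fixed at 1 but zeros are present in the data")

    stats = _suff_stats(values, assign)
    seeds = np.random.SeedSequence(config.seed).spawn(config.chains)
    chains = [
        _run_chain(stats, gamma_mode, priors, config, np.random.default_rng(s))
        for s in seeds
    ]

    def stack(key):
        return np.stack([c[key] for c in chains])  # (chains, n_keep, dim)

    alpha_logit = stack("alpha_logit")
    mu_logit = stack("mu_logit")
    phi_log = stack("phi_log")
    gamma_logit = stack("gamma_logit") if gamma_mode is GammaMode.FREE else None
    deviance = np.stack([c["deviance"] for c in chains])

    diagnostics = _diagnostics(
        assign, gamma_mode, alpha_logit, gamma_logit, mu_logit, phi_log
    )
    fit_warnings = []
    bad = diagnostics[diagnostics["r_hat"] > 1.05]
    if len(bad):
        fit_warnings.append(
            "possible non-convergence: R-hat > 1.05 for "
            + ", ".join(bad.index.astype(str))
        )
    n_data_groups = int(np.sum(stats.n0 + stats.n1 + stats.n_int > 0))
    if n_data_groups and np.ptp(values) == 0.0:
        fit_warnings.append("degenerate data: all observed proportions identical")
    for msg in fit_warnings:
        warnings.warn(msg, stacklevel=2)

    return PosteriorFit(
        scheme=scheme,
        gamma_mode=gamma_mode,
        group_names=assign.mean_names,
        phi_group_names=assign.phi_names,
        alpha_logit=alpha_logit,
        gamma_logit=gamma_logit,
        mu_logit=mu_logit,
        phi_log=phi_log,
        deviance_draws=deviance,
        diagnostics=diagnostics,
        warnings=fit_warnings,
        config=config,
        _stats=stats,
    )


def _diagnostics(assign, gamma_mode, alpha_logit, gamma_logit, mu_logit, phi_log):
    """Split-R-hat and bulk ESS per free parameter."""
    import pandas as pd

    rows = {}
    for name, arr, labels in (
        ("alpha_logit", alpha_logit, assign.mean_names),
        ("gamma_logit", gamma_logit, assign.mean_names),
        ("mu_logit", mu_logit, assign.mean_names),
        ("phi_log", phi_log, assign.phi_names),
    ):
        if arr is None:
            continue
        for j, label in enumerate(labels):
            draws = arr[:, :, j]
            rows[f"{name}[{label}]"] = {
                "r_hat": _split_rhat(draws),
                "ess": _bulk_ess(draws),
            }
    return pd.DataFrame(rows).T


def _split_rhat(draws: np.ndarray) -> float:
    """Split-chain potential scale reduction factor."""
    c, n = draws.shape
    half = n // 2
    split = draws[:, : 2 * half].reshape(2 * c, half)
    m, n2 = split.shape
    chain_means = split.mean(axis=1)
    b = n2 * chain_means.var(ddof=1)
    w = split.var(axis=1, ddof=1).mean()
    if w == 0.0:
        return 1.0
    var_hat = (n2 - 1) / n2 * w + b / n2
    return float(math.sqrt(var_hat / w))


def _bulk_ess(draws: np.ndarray) -> float:
    """Effective sample size from pooled autocorrelations (Geyer pairs)."""
    c, n = draws.shape
    if np.ptp(draws) == 0.0:
        return float(c * n)
    acov = np.zeros(n)
    for ch in range(c):
        x = draws[ch] - draws[ch].mean()
        f = np.fft.rfft(x, 2 * n)
        acf = np.fft.irfft(f * np.conj(f))[:n].real / n
        acov += acf
    acov /= c
    if acov[0] == 0.0:
        return float(c * n)
    rho = acov / acov[0]
    # sum initial-positive pairwise autocorrelations
    tau = 1.0
    for t in range(1, n - 1, 2):
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        tau += 2.0 * pair
    return float(c * n / max(tau, 1.0))


def fit_zoib(
    observations: Sequence[SiteObservation],
    category: HabitatCategory,
    scheme: ModelScheme,
    priors: PriorSpec | None = None,
    config: MCMCConfig | None = None,
    gamma_mode: GammaMode | None = None,
) -> PosteriorFit:
    """Fit one habitat category's proportions under one scheme."""
    missing = [o.site_id for o in observations if category not in o.proportions]
    if missing:
        raise KeyError(
            f"category {category.value!r} absent from observations: {missing[:5]}"
        )
    values = np.array([o.proportions[category] for o in observations])
    assign = assign_groups(observations, scheme)
    return fit_zoib_values(values, assign, scheme, priors, config, gamma_mode)


# --- DIC and the ladder ----------------------------------------------------

def compute_dic(
    fit: PosteriorFit,
    observations: Sequence[SiteObservation] | None = None,
    category: HabitatCategory | None = None,
) -> DICResult:
    """DIC decomposition: D_bar + pD, pD = D_bar - D_hat.

    D_hat evaluates the deviance at the posterior means of the
    TRANSFORMED-scale parameters (the sampled nodes). By default the
    sufficient statistics cached on the fit are reused; passing the
    observations recomputes them.
    """
    if fit.deviance_draws is None or fit.deviance_draws.size < 2:
        raise ValueError("fit carries no per-draw deviance")
    if observations is not None:
        if category is None:
            raise ValueError("recomputing from observations requires the category")
        values = np.array([o.proportions[category] for o in observations])
        stats = _suff_stats(values, assign_groups(observations, fit.scheme))
    else:
        stats = fit._stats
    d_bar = float(fit.deviance_draws.mean())
    mean_of = lambda arr: arr.reshape(-1, arr.shape[-1]).mean(axis=0)
    d_hat = -2.0 * _total_loglik(
        stats,
        fit.gamma_mode,
        mean_of(fit.alpha_logit),
        mean_of(fit.gamma_logit) if fit.gamma_logit is not None else None,
        mean_of(fit.mu_logit),
        mean_of(fit.phi_log),
    )
    return DICResult(d_bar=d_bar, d_hat=d_hat)


@dataclass
class ModelComparison:
    """Nine fits of one habitat category with their DIC decompositions."""

    category: HabitatCategory | None
    gamma_mode: GammaMode
    dic_table: dict[ModelScheme, DICResult]
    fits: dict[ModelScheme, PosteriorFit]

    def dic_values(self) -> dict[ModelScheme, float]:
        return {s: r.dic for s, r in self.dic_table.items()}


def fit_all_models(
    observations: Sequence[SiteObservation],
    category: HabitatCategory,
    priors: PriorSpec | None = None,
    config: MCMCConfig | None = None,
    keep_fits: bool = True,
) -> ModelComparison:
    """Fit the nine-model ladder for one category and tabulate DIC.

    The gamma mode is determined once from the pooled data and applied to all
    nine schemes. Per-scheme sampler seeds are derived deterministically from
    ``config.seed``.
    """
    config = config or MCMCConfig()
    values = [o.proportions[category] for o in observations]
    gamma_mode = determine_gamma_mode(values)
    scheme_seeds = (
        np.random.SeedSequence(config.seed).generate_state(len(NINE_SCHEMES))
        % (2**31)
    )
    dic_table: dict[ModelScheme, DICResult] = {}
    fits: dict[ModelScheme, PosteriorFit] = {}
    for scheme, seed in zip(NINE_SCHEMES, scheme_seeds):
        sub_config = dataclasses.replace(config, seed=int(seed))
        fit = fit_zoib(
            observations, category, scheme,
            priors=priors, config=sub_config, gamma_mode=gamma_mode,
        )
        dic_table[scheme] = compute_dic(fit)
        if keep_fits:
            fits[scheme] = fit
    return ModelComparison(
        category=category, gamma_mode=gamma_mode, dic_table=dic_table, fits=fits
    )


def select_model(
    dic_table: Mapping[ModelScheme, "float | DICResult"],
) -> SelectionResult:
    """Lowest DIC unless a strictly simpler model lies within 2 of the minimum.

    Among all models whose DIC is strictly within 2 of the minimum, the
    simplest (fewest mean-parameter groups, then shared before variable
    precision) is chosen; complexity ties go to the lower DIC. Invariant to
    the order of table entries.
    """
    if not dic_table:
        raise ValueError("empty DIC table")
    flat = {
        s: (v.dic if isinstance(v, DICResult) else float(v))
        for s, v in dic_table.items()
    }
    best_dic = min(flat.values())
    candidates = {s: d for s, d in flat.items() if d - best_dic < 2.0}
    chosen = min(candidates, key=lambda s: (scheme_complexity(s), candidates[s], str(s)))
    minimiser = min(flat, key=lambda s: (flat[s], str(s)))
    rationale = "lowest" if chosen == minimiser else "simpler_within_2"
    return SelectionResult(chosen=chosen, dic_table=flat, rationale=rationale)


def posterior_summary(fit: PosteriorFit) -> "pd.DataFrame":
    """Natural-scale per-group posterior means, medians and 95% equal-tailed
    credible intervals.

    Means are averages of back-transformed draws (not back-transformed
    averages — the two differ whenever the posterior is skewed).
    """
    import pandas as pd

    rows = []
    for param in ("alpha", "gamma", "mu", "phi"):
        if param == "gamma" and fit.gamma_mode is not GammaMode.FREE:
            continue
        draws = fit.natural_draws(param)
        labels = fit.phi_group_names if param == "phi" else fit.group_names
        for j, label in enumerate(labels):
            d = draws[:, :, j].ravel()
            rows.append(
                {
                    "parameter": param,
                    "group": label,
                    "mean": float(d.mean()),
                    "median": float(np.median(d)),
                    "q2.5": float(np.quantile(d, 0.025)),
                    "q97.5": float(np.quantile(d, 0.975)),
                }
            )
    return pd.DataFrame(rows)
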