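"""Multinomial maximum-likelihood modelling of mother-child genotype counts.

The duo likelihood assigns each of the seven Mendelian-possible mother-child
dosage cells (m, c) a population probability under HWE and random mating,

    mu(m, c) = P_HWE(m; q) * sum_f P_HWE(f; q) * T(c | m, f),

with T the Mendelian transmission kernel, and a multiplicative disease-risk
term

    rho(m, c) = r1^c * s1^m * j^I(m, c),

where r1 is the per-copy child relative risk (two copies act as r1^2), s1
the per-copy maternal relative risk, and j multiplies the cells "exposed"
under the active interaction model (I_diff = [m != c],
I_offhet = [c = 1 and m != 1], I_mathet = [m = 1 and c != 1]).  Case duos
are distributed as mu*rho renormalized (ascertainment conditions on
affection, so the baseline risk alpha cancels and only relative risks are
identifiable); control duos follow mu itself, the rare-disease
approximation.

Nested fits differing by one free parameter give a 1-df likelihood-ratio
test: dropping s1 asks whether an apparent maternal effect is explained by
the child's own genotype; dropping j asks whether an interaction signal is
explained by the two main effects.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats

from .tg_classifiers import TE_MODELS

_LOG_BOUND = float(np.log(50.0))  # |ln r1|, |ln s1|, |ln j| <= ln 50
_Q_EPS = 1e-4

#: Mendelian transmission kernel T[c, m, f] = P(child dosage c | m, f)
_T = np.zeros((3, 3, 3))
for _m in range(3):
    for _f in range(3):
        pm = {0: (1.0, 0.0), 1: (0.5, 0.5), 2: (0.0, 1.0)}[_m]
        pf = {0: (1.0, 0.0), 1: (0.5, 0.5), 2: (0.0, 1.0)}[_f]
        for am in (0, 1):
            for af in (0, 1):
                _T[am + af, _m, _f] += pm[am] * pf[af]


@dataclass(frozen=True)
class RiskParams:
    """Multiplicative duo risk model parameters.

    alpha is the baseline probability of disease for an (m=0, c=0) duo; it
    matters for simulation but cancels out of the ascertained likelihood.
    """

    alpha: float = 0.01
    r1: float = 1.0
    s1: float = 1.0
    j: float = 1.0
    q: float = 0.5

    def __post_init__(self) -> None:
        if min(self.r1, self.s1, self.j) <= 0:
            raise ValueError("risk parameters must be positive")
        if not 0.0 < self.q < 1.0:
            raise ValueError(f"q={self.q} outside (0, 1)")

    @property
    def r2(self) -> float:
        return self.r1**2

    @property
    def s2(self) -> float:
        return self.s1**2


@dataclass
class DuoCounts:
    """3x3 (mother x child) dosage count tables for cases and controls."""

    case: np.ndarray
    control: np.ndarray

    def __post_init__(self) -> None:
        self.case = np.asarray(self.case, dtype=np.int64)
        self.control = np.asarray(self.control, dtype=np.int64)
        for name, t in (("case", self.case), ("control", self.control)):
            if t.shape != (3, 3) or (t < 0).any():
                raise ValueError(f"{name} counts must be non-negative 3x3")
            if t[0, 2] or t[2, 0]:
                raise ValueError(
                    f"{name} counts occupy Mendelian-impossible cells"
                )
            if t.sum() < 1:
                raise ValueError(f"{name} counts empty")

    @property
    def q_moment(self) -> float:
        """Allele-frequency moment estimate from control mothers+children."""
        dose = np.arange(3, dtype=float)
        n = self.control.sum()
        total = (self.control.sum(axis=1) * dose).sum() + (
            self.control.sum(axis=0) * dose
        ).sum()
        q = total / (4.0 * n)
        return float(np.clip(q, _Q_EPS, 1 - _Q_EPS))


@dataclass
class FitResult:
    params: RiskParams
    loglik: float
    converged: bool
    free: tuple[str, ...]


@dataclass
class LrtResult:
    loglik_full: float
    loglik_null: float
    lrt_stat: float
    df: int
    p_value: float
    fit_full: FitResult
    fit_null: FitResult


def interaction_indicator(model: str) -> np.ndarray:
    """3x3 0/1 matrix of cells exposed under the given interaction model."""
    if model not in TE_MODELS:
        raise ValueError(f"unknown model {model!r}")
    m, c = np.meshgrid(np.arange(3), np.arange(3), indexing="ij")
    if model == "diff":
        ind = m != c
    elif model == "offhet":
        ind = (c == 1) & (m != 1)
    else:
        ind = (m == 1) & (c != 1)
    return ind.astype(float)


def duo_population_probs(q: float) -> np.ndarray:
    """mu[m, c]: population duo distribution under HWE and random mating."""
    if not 0.0 < q < 1.0:
        raise ValueError(f"q={q} outside (0, 1)")
    hwe = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
    # child distribution given mother m, integrating the random-mate father
    child_given_m = np.einsum("cmf,f->mc", _T, hwe)
    return hwe[:, None] * child_given_m


def duo_cell_probs(
    params: RiskParams, model: str
) -> tuple[np.ndarray, np.ndarray]:
    """(case, control) 3x3 duo probability tables; each sums to 1."""
    mu = duo_population_probs(params.q)
    rho = risk_multipliers(params, model)
    case = mu * rho
    case /= case.sum()
    return case, mu


def risk_multipliers(params: RiskParams, model: str) -> np.ndarray:
    """rho[m, c] = r1^c * s1^m * j^I(m, c) (without the baseline alpha)."""
    m, c = np.meshgrid(np.arange(3), np.arange(3), indexing="ij")
    rho = params.r1**c * params.s1**m
    return rho * params.j ** interaction_indicator(model)


def _loglik(counts: DuoCounts, params: RiskParams, model: str) -> float:
    case_p, ctrl_p = duo_cell_probs(params, model)
    ll = 0.0
    for tab, p in ((counts.case, case_p), (counts.control, ctrl_p)):
        nz = tab > 0
        ll += float((tab[nz] * np.log(p[nz])).sum())
    return ll


_FREE_ORDER = ("q", "r1", "s1", "j")


def fit(
    counts: DuoCounts,
    model: str,
    free: tuple[str, ...] = ("q", "r1", "s1", "j"),
) -> FitResult:
    """Maximize the duo log-likelihood over a subset of parameters.

    Fixed risk parameters are pinned at 1; a fixed q is pinned at its moment
    estimate from the control duos.  Risk parameters are optimized on the
    log scale within |ln theta| <= ln 50 with a small multi-start grid; the
    best of all starts is returned.  Non-convergence across every start is
    flagged, not raised.
    """
    unknown = set(free) - set(_FREE_ORDER)
    if unknown:
        raise ValueError(f"unknown free parameters {sorted(unknown)}")
    free = tuple(p for p in _FREE_ORDER if p in free)
    q0 = counts.q_moment

    def unpack(x: np.ndarray) -> RiskParams:
        vals = {"q": q0, "r1": 1.0, "s1": 1.0, "j": 1.0}
        for name, xi in zip(free, x):
            vals[name] = float(
                1.0 / (1.0 + np.exp(-xi)) if name == "q" else np.exp(xi)
            )
        vals["q"] = float(np.clip(vals["q"], _Q_EPS, 1 - _Q_EPS))
        return RiskParams(alpha=0.01, **vals)

    def neg(x: np.ndarray) -> float:
        return -_loglik(counts, unpack(x), model)

    if not free:
        p = unpack(np.empty(0))
        return FitResult(p, _loglik(counts, p, model), True, free)

    bounds = []
    base_start = []
    for name in free:
        if name == "q":
            bounds.append((np.log(_Q_EPS / (1 - _Q_EPS)),
                           -np.log(_Q_EPS / (1 - _Q_EPS))))
            base_start.append(float(np.log(q0 / (1 - q0))))
        else:
            bounds.append((-_LOG_BOUND, _LOG_BOUND))
            base_start.append(0.0)

    best: optimize.OptimizeResult | None = None
    any_converged = False
    for mult in (0.5, 1.0, 2.0):
        x0 = np.array(base_start, dtype=float)
        for i, name in enumerate(free):
            if name != "q":
                x0[i] = np.log(mult)
        res = optimize.minimize(
            neg, x0, method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-12, "gtol": 1e-9, "maxiter": 500},
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun - 0.0:
            best = res
    assert best is not None
    params = unpack(best.x)
    return FitResult(params, -float(best.fun), any_converged, free)


def lrt(
    counts: DuoCounts,
    model: str,
    full_free: tuple[str, ...],
    null_free: tuple[str, ...],
) -> LrtResult:
    """1-df likelihood-ratio test between two nested duo fits.

    The null's free set must be the full set minus exactly one parameter:
    the maternal-effect test drops s1 from {q, r1, s1}; the interaction test
    drops j from {q, r1, s1, j}.
    """
    full_set, null_set = set(full_free), set(null_free)
    if not (null_set < full_set and len(full_set - null_set) == 1):
        raise ValueError(
            f"null {sorted(null_set)} must be nested one parameter below "
            f"full {sorted(full_set)}"
        )
    f_full = fit(counts, model, tuple(full_free))
    f_null = fit(counts, model, tuple(null_free))
    stat = 2.0 * (f_full.loglik - f_null.loglik)
    if stat < 0:  # optimizer noise on a boundary-null fit
        stat = 0.0
    p = float(stats.chi2.sf(stat, df=1))
    return LrtResult(
        loglik_full=f_full.loglik,
        loglik_null=f_null.loglik,
        lrt_stat=float(stat),
        df=1,
        p_value=p,
        fit_full=f_full,
        fit_null=f_null,
    )


def counts_from_duos(
    m_dosage: np.ndarray, c_dosage: np.ndarray, is_case: np.ndarray
) -> DuoCounts:
    """Tally 3x3 case/control duo tables from per-duo dosages at one marker.

    Missing or Mendelian-impossible pairs are dropped.
    """
    ok = (
        (m_dosage >= 0)
        & (c_dosage >= 0)
        & ~(((m_dosage == 0) & (c_dosage == 2))
            | ((m_dosage == 2) & (c_dosage == 0)))
    )
    case = np.zeros((3, 3), dtype=np.int64)
    ctrl = np.zeros((3, 3), dtype=np.int64)
    for m in range(3):
        for c in range(3):
            sel = ok & (m_dosage == m) & (c_dosage == c)
            case[m, c] = (sel & is_case).sum()
            ctrl[m, c] = (sel & ~is_case).sum()
    return DuoCounts(case=case, control=ctrl)
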