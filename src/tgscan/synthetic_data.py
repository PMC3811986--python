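"""Synthetic duo and trio genotype generators.

The generators emulate the statistical structure the analysis assumes:
biallelic unlinked SNPs under Hardy-Weinberg equilibrium and random mating,
mother-child pairs formed by Mendelian transmission from the mother and a
random mate, optional multi-stratum population structure under the
Balding-Nichols model (per-stratum allele frequency ~
Beta(q(1-Fst)/Fst, (1-q)(1-Fst)/Fst)), and disease risk following the
multiplicative duo model of :mod:`tgscan.mmlm_lrt`: an (m, c) duo is
affected with probability min(1, alpha * rho(m, c)), where rho carries the
child (r1), maternal (s1) and interaction (j) relative risks at a single
designated causal marker.  All other markers are null.

Case/control quotas are filled by rejection sampling on affection status at
the causal marker; null markers are then drawn conditionally on each duo's
stratum, so a dataset of any marker count costs one pass.  A per-stratum
case enrichment (``status_stratum_bias``) multiplies the baseline risk per
stratum, which confounds status with ancestry — the stress test for the
stratification stage.

Everything is driven by a single integer seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import json
import numpy as np

from .genotype_io import Duo, DuoSet, GenotypeMatrix, Marker, Trio, TrioSet
from .mmlm_lrt import RiskParams, risk_multipliers

_HWE_DOSAGE = np.arange(3)


@dataclass
class SimConfig:
    n_case_duos: int = 366
    n_control_duos: int = 369
    n_trios: int = 500
    n_markers: int = 1000
    seed: int = 0
    #: per-stratum sampling weights (must sum to 1)
    strata_weights: tuple[float, ...] = (1.0,)
    #: Balding-Nichols divergence; 0 means identical frequencies
    fst: float = 0.0
    #: ancestral a1 frequency range for per-marker uniform draws
    freq_range: tuple[float, float] = (0.05, 0.5)
    #: risk model at the causal marker (marker index 0 when any effect != 1)
    risk: RiskParams = field(default_factory=RiskParams)
    model: str = "diff"
    #: per-stratum multiplicative enrichment of the baseline risk
    status_stratum_bias: tuple[float, ...] | None = None
    #: per-call genotype missingness rate
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if abs(sum(self.strata_weights) - 1.0) > 1e-9:
            raise ValueError("strata weights must sum to 1")
        lo, hi = self.freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("freq_range must lie inside (0, 1)")
        if self.status_stratum_bias is not None and len(
            self.status_stratum_bias
        ) != len(self.strata_weights):
            raise ValueError("bias vector length must match strata")

    @property
    def n_strata(self) -> int:
        return len(self.strata_weights)

    @property
    def has_effect(self) -> bool:
        r = self.risk
        return not (r.r1 == 1.0 and r.s1 == 1.0 and r.j == 1.0)


@dataclass
class TruthRecord:
    """Generating parameters emitted alongside each dataset."""

    cfg: SimConfig
    strata: np.ndarray  # per duo/trio, 1-based
    causal_marker: str | None
    stratum_freqs: np.ndarray  # (n_strata, n_markers)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                json.dumps(
                    {
                        "seed": self.cfg.seed,
                        "model": self.cfg.model,
                        "risk": {
                            "alpha": self.cfg.risk.alpha,
                            "r1": self.cfg.risk.r1,
                            "s1": self.cfg.risk.s1,
                            "j": self.cfg.risk.j,
                        },
                        "causal_marker": self.causal_marker,
                        "strata": self.strata.tolist(),
                    }
                )
                + "\n"
            )


def _stratum_freqs(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """(n_strata, n_markers) a1 frequencies under Balding-Nichols."""
    lo, hi = cfg.freq_range
    base = rng.uniform(lo, hi, size=cfg.n_markers)
    if cfg.fst <= 0.0 or cfg.n_strata == 1 and cfg.fst == 0.0:
        return np.tile(base, (cfg.n_strata, 1))
    f = cfg.fst
    a = base * (1.0 - f) / f
    b = (1.0 - base) * (1.0 - f) / f
    freqs = rng.beta(a, b, size=(cfg.n_strata, cfg.n_markers))
    return np.clip(freqs, 1e-3, 1.0 - 1e-3)


def _hwe_genotypes(
    q: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw one HWE genotype per entry of the frequency array q."""
    u = rng.random(q.shape)
    p0 = (1.0 - q) ** 2
    p01 = p0 + 2.0 * q * (1.0 - q)
    return (u >= p0).astype(np.int8) + (u >= p01).astype(np.int8)


def _transmit(parent: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One transmitted a1-allele count per parent dosage."""
    u = rng.random(parent.shape)
    out = np.zeros(parent.shape, dtype=np.int8)
    out[parent == 2] = 1
    het = parent == 1
    out[het] = (u[het] < 0.5).astype(np.int8)
    return out


def _markers(n: int, prefix: str = "rs") -> list[Marker]:
    return [
        Marker(f"{prefix}{j + 1}", str(j % 22 + 1), 1000 * (j + 1), "A", "B")
        for j in range(n)
    ]


def _draw_causal_duos(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Rejection-sample duos at the causal marker until quotas fill.

    Returns (stratum 1-based, mother dosage, child dosage, is_case) for the
    accepted duos, cases first.
    """
    lo, hi = cfg.freq_range
    q_causal = np.full(cfg.n_strata, float(np.clip(cfg.risk.q, lo, hi)))
    if cfg.fst > 0 and cfg.n_strata > 1:
        f = cfg.fst
        q_causal = np.clip(
            rng.beta(
                cfg.risk.q * (1 - f) / f,
                (1 - cfg.risk.q) * (1 - f) / f,
                size=cfg.n_strata,
            ),
            1e-3,
            1 - 1e-3,
        )
    rho = risk_multipliers(cfg.risk, cfg.model)
    bias = (
        np.asarray(cfg.status_stratum_bias)
        if cfg.status_stratum_bias is not None
        else np.ones(cfg.n_strata)
    )
    risk_cap = cfg.risk.alpha * rho.max() * bias.max()
    if risk_cap >= 1.0:
        raise ValueError(
            f"alpha * max(rho) * max(bias) = {risk_cap:.3g} >= 1: affection "
            "probabilities saturate; lower alpha or the risk parameters"
        )
    need = {True: cfg.n_case_duos, False: cfg.n_control_duos}
    got: dict[bool, list[tuple[int, int, int]]] = {True: [], False: []}
    weights = np.asarray(cfg.strata_weights)
    max_iter = 2000
    for _ in range(max_iter):
        if all(len(got[s]) >= need[s] for s in (True, False)):
            break
        batch = 4 * (cfg.n_case_duos + cfg.n_control_duos)
        ks = rng.choice(cfg.n_strata, size=batch, p=weights)
        qk = q_causal[ks]
        mothers = _hwe_genotypes(qk, rng)
        fathers = _hwe_genotypes(qk, rng)
        children = _transmit(mothers, rng) + _transmit(fathers, rng)
        p_aff = cfg.risk.alpha * rho[mothers, children] * bias[ks]
        affected = rng.random(batch) < np.minimum(p_aff, 1.0)
        for k, m, c, a in zip(ks, mothers, children, affected):
            s = bool(a)
            if len(got[s]) < need[s]:
                got[s].append((int(k) + 1, int(m), int(c)))
    else:
        raise RuntimeError(
            "case/control quotas not reached; affection model too extreme"
        )
    rows = got[True] + got[False]
    strata = np.array([r[0] for r in rows])
    m_dose = np.array([r[1] for r in rows], dtype=np.int8)
    c_dose = np.array([r[2] for r in rows], dtype=np.int8)
    is_case = np.array(
        [True] * cfg.n_case_duos + [False] * cfg.n_control_duos
    )
    return strata, m_dose, c_dose, is_case


def _null_duo_panel(
    strata0: np.ndarray,  # 0-based stratum per duo
    freqs: np.ndarray,  # (n_strata, n_markers)
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """(mothers, children) dosage blocks for effect-free markers."""
    q = freqs[strata0]  # (n_duos, n_markers)
    mothers = _hwe_genotypes(q, rng)
    fathers = _hwe_genotypes(q, rng)
    children = _transmit(mothers, rng) + _transmit(fathers, rng)
    return mothers, children


def _apply_missing(
    calls: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    if rate <= 0:
        return calls
    mask = rng.random(calls.shape) < rate
    out = calls.copy()
    out[mask] = -1
    return out


def sim_duos(
    cfg: SimConfig,
) -> tuple[GenotypeMatrix, GenotypeMatrix, DuoSet, TruthRecord]:
    """Simulate a case-control duo dataset.

    Marker 0 is the causal marker whenever the configured risk model plants
    any effect; every other marker is null.  Mothers and children are
    returned as separate matrices sharing the marker panel, mirroring the
    separately genotyped maternal and neonatal sample sets.
    """
    rng = np.random.default_rng(cfg.seed)
    freqs = _stratum_freqs(cfg, rng)
    strata, m_causal, c_causal, is_case = _draw_causal_duos(cfg, rng)
    n = strata.size
    mothers, children = _null_duo_panel(strata - 1, freqs, rng)
    causal_name = None
    if cfg.has_effect:
        mothers[:, 0] = m_causal
        children[:, 0] = c_causal
        causal_name = "rs1"
    mothers = _apply_missing(mothers, cfg.missing_rate, rng)
    children = _apply_missing(children, cfg.missing_rate, rng)

    markers = _markers(cfg.n_markers)
    m_ids = [f"M{i + 1}" for i in range(n)]
    c_ids = [f"C{i + 1}" for i in range(n)]
    gm_m = GenotypeMatrix(m_ids, markers, mothers)
    gm_c = GenotypeMatrix(c_ids, list(markers), children)
    duos = DuoSet(
        [
            Duo(m, c, "case" if a else "control")
            for m, c, a in zip(m_ids, c_ids, is_case)
        ]
    )
    truth = TruthRecord(cfg, strata, causal_name, freqs)
    return gm_m, gm_c, duos, truth


def sim_trios(
    cfg: SimConfig, dataset: str = "rep1", paternal_s1: float = 1.0
) -> tuple[GenotypeMatrix, TrioSet, TruthRecord]:
    """Simulate affected-offspring trios under the duo risk model.

    Fathers are retained; by default they carry no risk of their own
    (``paternal_s1 = 1``), the working assumption that lets fathers serve
    as controls for mothers in replication.  Only affected-child trios are
    ascertained.
    """
    rng = np.random.default_rng(cfg.seed)
    freqs = _stratum_freqs(cfg, rng)
    lo, hi = cfg.freq_range
    q_causal = np.full(cfg.n_strata, float(np.clip(cfg.risk.q, lo, hi)))
    rho = risk_multipliers(cfg.risk, cfg.model)
    weights = np.asarray(cfg.strata_weights)
    got: list[tuple[int, int, int, int]] = []
    for _ in range(2000):
        if len(got) >= cfg.n_trios:
            break
        batch = max(1000, 4 * cfg.n_trios)
        ks = rng.choice(cfg.n_strata, size=batch, p=weights)
        qk = q_causal[ks]
        mothers = _hwe_genotypes(qk, rng)
        fathers = _hwe_genotypes(qk, rng)
        children = _transmit(mothers, rng) + _transmit(fathers, rng)
        p_aff = (
            cfg.risk.alpha
            * rho[mothers, children]
            * paternal_s1**fathers.astype(float)
        )
        affected = rng.random(batch) < np.minimum(p_aff, 1.0)
        for k, m, f, c in zip(
            ks[affected], mothers[affected], fathers[affected],
            children[affected],
        ):
            if len(got) < cfg.n_trios:
                got.append((int(k) + 1, int(m), int(f), int(c)))
    else:
        raise RuntimeError("trio quota not reached; risk model too extreme")

    n = len(got)
    strata = np.array([g[0] for g in got])
    q = freqs[strata - 1]
    mothers = _hwe_genotypes(q, rng)
    fathers = _hwe_genotypes(q, rng)
    children = _transmit(mothers, rng) + _transmit(fathers, rng)
    # causal-marker genotypes always come from the ascertainment draw (under
    # a null risk model that draw is plain HWE, so marker 0 stays null)
    mothers[:, 0] = [g[1] for g in got]
    fathers[:, 0] = [g[2] for g in got]
    children[:, 0] = [g[3] for g in got]
    markers = _markers(cfg.n_markers)
    f_ids = [f"{dataset}_F{i + 1}" for i in range(n)]
    m_ids = [f"{dataset}_M{i + 1}" for i in range(n)]
    c_ids = [f"{dataset}_C{i + 1}" for i in range(n)]
    calls = np.vstack([fathers, mothers, children])
    gm = GenotypeMatrix(f_ids + m_ids + c_ids, markers, calls)
    trios = TrioSet(
        [
            Trio(f_ids[i], m_ids[i], c_ids[i], True, dataset)
            for i in range(n)
        ]
    )
    causal = "rs1" if cfg.has_effect else None
    return gm, trios, TruthRecord(cfg, strata, causal, freqs)


def sim_null_genome(
    n_samples: int,
    n_markers: int,
    strata_weights: tuple[float, ...] = (1.0,),
    fst: float = 0.0,
    seed: int = 0,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Independent null genotypes for lambda / type-I studies.

    Returns the matrix and the per-sample 1-based stratum labels.
    """
    if n_markers < 100:
        raise ValueError("need >= 100 markers")
    cfg = SimConfig(
        n_markers=n_markers,
        seed=seed,
        strata_weights=strata_weights,
        fst=fst,
    )
    rng = np.random.default_rng(seed)
    freqs = _stratum_freqs(cfg, rng)
    ks = rng.choice(cfg.n_strata, size=n_samples, p=np.asarray(strata_weights))
    calls = _hwe_genotypes(freqs[ks], rng)
    gm = GenotypeMatrix(
        [f"S{i + 1}" for i in range(n_samples)], _markers(n_markers), calls
    )
    return gm, ks + 1
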