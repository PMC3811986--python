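"""Cochran-Mantel-Haenszel association testing and the genome-wide scan.

The CMH statistic for a 2x2 table replicated over K strata, without
continuity correction, is

    X^2 = (sum_k a_k - sum_k E_k)^2 / sum_k V_k,

with E_k = (a+b)(a+c)/n and V_k = (a+b)(c+d)(a+c)(b+d) / (n^2 (n-1)) per
stratum, referred to chi-square with 1 df; the common odds ratio is the
Mantel-Haenszel estimator sum_k(a d / n) / sum_k(b c / n).  Strata with
fewer than two observations or a zero margin carry no information and are
dropped from both sums; a marker where every stratum drops is reported
untestable (NaN statistic and P) rather than raising.

Five scan models are supported: the two allele-frequency main-effect tests
(``proband`` on child genotypes, ``maternal`` on maternal genotypes with
case status defined by having an affected child) and the three binary
mother-child interaction classifiers (``offhet``, ``mathet``, ``diff``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genotype_io import DuoSet, GenotypeMatrix, ResultRow, MODELS
from .tg_classifiers import (
    StratifiedTable,
    TE_MODELS,
    build_allele_stack,
    build_binary_stack,
)

#: reporting tiers used genome-wide
SUGGESTIVE_P = 1e-4
TOP_P = 1e-5
GENOME_WIDE_P = 5e-8


@dataclass
class AssocResult:
    statistic: float
    p_value: float
    or_mh: float
    n_effective: int

    @property
    def testable(self) -> bool:
        return np.isfinite(self.statistic)


def cmh_test(stack: StratifiedTable) -> AssocResult:
    """CMH chi-square (1 df) and Mantel-Haenszel OR for a 2x2xK stack."""
    t = stack.counts.astype(float)
    a, b = t[0, 0], t[0, 1]
    c, d = t[1, 0], t[1, 1]
    n = a + b + c + d
    row1, row2 = a + b, c + d
    col1, col2 = a + c, b + d
    keep = (n >= 2) & (row1 > 0) & (row2 > 0) & (col1 > 0) & (col2 > 0)
    if not keep.any():
        return AssocResult(float("nan"), float("nan"), float("nan"), 0)
    a, b, c, d, n = a[keep], b[keep], c[keep], d[keep], n[keep]
    row1, row2, col1, col2 = row1[keep], row2[keep], col1[keep], col2[keep]
    e = row1 * col1 / n
    v = row1 * row2 * col1 * col2 / (n * n * (n - 1.0))
    vsum = v.sum()
    if vsum <= 0:
        return AssocResult(float("nan"), float("nan"), float("nan"), 0)
    stat = (a.sum() - e.sum()) ** 2 / vsum
    p = float(stats.chi2.sf(stat, df=1))
    num = (a * d / n).sum()
    den = (b * c / n).sum()
    # undefined (NaN) when either sum is zero, so log-OR direction is usable
    or_mh = num / den if num > 0 and den > 0 else float("nan")
    return AssocResult(float(stat), p, float(or_mh), int(n.sum()))


def scan(
    gm_m: GenotypeMatrix,
    gm_c: GenotypeMatrix,
    duos: DuoSet,
    model: str,
    maternal_strata: np.ndarray,
    proband_strata: np.ndarray,
    n_strata: int,
    classifier_mode: str = "literal",
) -> list[ResultRow]:
    """Genome-wide CMH scan under one model.

    ``maternal_strata`` / ``proband_strata`` are per-duo 1-based cluster
    labels from the two cluster solutions: main-effect tests stratify each
    individual by their own solution, paired tests by the maternal one.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    duos_m = duos.with_strata(maternal_strata)
    is_case = duos.statuses
    rows: list[ResultRow] = []
    for j, marker in enumerate(gm_c.markers):
        if model == "proband":
            stack = build_allele_stack(
                gm_c, duos.children, is_case,
                np.asarray(proband_strata), j, n_strata,
            )
        elif model == "maternal":
            stack = build_allele_stack(
                gm_m, duos.mothers, is_case,
                np.asarray(maternal_strata), j, n_strata,
            )
        else:
            stack = build_binary_stack(
                gm_m, gm_c, duos_m, j, model, n_strata, classifier_mode
            )
        res = cmh_test(stack)
        rows.append(
            ResultRow(
                marker=marker,
                model=model,
                statistic=res.statistic,
                df=1,
                p_value=res.p_value,
                or_mh=res.or_mh,
                n_effective=res.n_effective,
            )
        )
    return rows


def qq_data(p_values: np.ndarray) -> np.ndarray:
    """(expected, observed) -log10 P pairs for a QQ plot, sorted."""
    p = np.sort(np.asarray(p_values, dtype=float))
    p = p[np.isfinite(p)]
    n = p.size
    exp = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    obs = -np.log10(np.clip(p, 1e-300, 1.0))
    return np.column_stack([exp, obs])
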