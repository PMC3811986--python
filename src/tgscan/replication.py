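"""Family-based (trio) replication tests and random-effects meta-analysis.

A case-control duo design has no ready-made replication cohort, so maternal
and interaction effects are checked in affected-offspring trios under the
assumption that maternal effects are distinct from paternal effects: the
fathers play the role of "controls" for the mothers.

* ``tdt`` — the transmission disequilibrium test for the child main effect:
  transmitted vs untransmitted a1 alleles from heterozygous parents,
  chi-square (b - c)^2 / (b + c).
* ``parent_freq`` — allelic chi-square of mothers vs fathers, the maternal
  main-effect analog.
* ``offhet_rep`` / ``mathet_rep`` / ``diff_rep`` — trio analogs of the three
  duo interaction classifiers: condition on offspring genotype where needed,
  then compare mothers to fathers.

The interaction analogs come in two forms.  The default ``matched`` form
scores only trios whose parents are discordant for the model's indicator
(for the offspring-het analog: one parent homozygous, one heterozygous) and
tests mother-discordant against father-discordant counts with the TDT-style
(b - c)^2 / (b + c) chi-square.  Conditioning on the child's genotype makes
the two parents' genotypes dependent, so the discordant-pair unit is the
only one with a calibrated null; only such trios are informative anyway.
The ``matched=False`` form is the naive unmatched 2x2 Pearson chi-square of
all mothers against all fathers (no continuity correction), which treats the
paired parents as independent samples — it is anticonservative for the
offspring-het analog and conservative for the maternal-het analog, and is
kept for comparison.

Per-dataset log odds ratios are pooled with DerSimonian-Laird random-effects
meta-analysis; when any dataset has a zero count for a marker, the datasets
are instead summed and tested jointly (the "merged" fallback).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genotype_io import MISSING, GenotypeMatrix, TrioSet

TRIO_TESTS = ("tdt", "parent_freq", "offhet_rep", "mathet_rep", "diff_rep")

#: duo model -> matching trio replication test
MODEL_TO_TRIO_TEST = {
    "proband": "tdt",
    "maternal": "parent_freq",
    "offhet": "offhet_rep",
    "mathet": "mathet_rep",
    "diff": "diff_rep",
}


@dataclass
class TrioTestResult:
    marker_id: str
    test: str
    chi_square: float
    p_value: float
    odds_ratio: float
    se_log_or: float
    informative_n: int
    table: np.ndarray | None = None  # 2x2 counts, or [[b, c], [0, 0]] pairs
    kind: str = "table"  # "table" (2x2 Pearson) | "pairs" (b vs c)

    @property
    def testable(self) -> bool:
        return np.isfinite(self.chi_square)


@dataclass
class MetaResult:
    pooled_log_or: float
    se: float
    tau_squared: float
    z: float
    p_value: float
    inputs: list[tuple[float, float]]
    merged: bool = False


def _untestable(marker_id: str, test: str) -> TrioTestResult:
    return TrioTestResult(
        marker_id, test, float("nan"), float("nan"), float("nan"),
        float("nan"), 0,
    )


def _trio_dosages(
    gm: GenotypeMatrix, trios: TrioSet, marker_index: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    f = gm.calls[gm.sample_indices([t.father_id for t in trios]), marker_index]
    m = gm.calls[gm.sample_indices([t.mother_id for t in trios]), marker_index]
    c = gm.calls[gm.sample_indices([t.child_id for t in trios]), marker_index]
    return f.astype(int), m.astype(int), c.astype(int)


def tdt(gm: GenotypeMatrix, trios: TrioSet, marker_index: int) -> TrioTestResult:
    """Transmission disequilibrium test at one marker.

    For each heterozygous parent with complete trio genotypes, the
    transmitted allele is scored from the allele bookkeeping b = a1
    transmissions, c = a2 transmissions.
    """
    f, m, c = _trio_dosages(gm, trios, marker_index)
    ok = (f != MISSING) & (m != MISSING) & (c != MISSING)
    f, m, c = f[ok], m[ok], c[ok]
    # number of a1 alleles the child received from het parents:
    # child dosage minus contributions forced by homozygous parents
    forced = (f == 2).astype(int) + (m == 2).astype(int)
    het_parents = (f == 1).astype(int) + (m == 1).astype(int)
    from_het = c - forced
    valid = (from_het >= 0) & (from_het <= het_parents)
    b = int(from_het[valid].sum())
    ctrans = int((het_parents[valid] - from_het[valid]).sum())
    mid = gm.markers[marker_index].id
    return _pair_result(mid, "tdt", b, ctrans)


def _pair_result(
    marker_id: str, test: str, b: int, c: int
) -> TrioTestResult:
    """(b - c)^2 / (b + c) chi-square on discordant/transmission counts."""
    if b + c == 0:
        return _untestable(marker_id, test)
    chi = (b - c) ** 2 / (b + c)
    p = float(stats.chi2.sf(chi, df=1))
    orr = b / c if b > 0 and c > 0 else float("nan")
    se = (
        float(np.sqrt(1.0 / b + 1.0 / c)) if b > 0 and c > 0 else float("nan")
    )
    return TrioTestResult(
        marker_id, test, float(chi), p, float(orr), se, b + c,
        table=np.array([[b, c], [0, 0]]), kind="pairs",
    )


def _pearson_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) for a 2x2 table."""
    a, b = float(table[0, 0]), float(table[0, 1])
    c, d = float(table[1, 0]), float(table[1, 1])
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0 or n == 0:
        return float("nan"), float("nan")
    chi = n * (a * d - b * c) ** 2 / denom
    return chi, float(stats.chi2.sf(chi, df=1))


def _table_result(
    marker_id: str, test: str, table: np.ndarray
) -> TrioTestResult:
    chi, p = _pearson_2x2(table)
    if not np.isfinite(chi):
        return _untestable(marker_id, test)
    a, b, c, d = (float(x) for x in table.ravel())
    orr = (a * d) / (b * c) if b * c > 0 and a * d > 0 else float("nan")
    se = woolf_se(table)
    return TrioTestResult(
        marker_id, test, chi, p, orr, se, int(table.sum()), table=table
    )


def woolf_se(table: np.ndarray) -> float:
    """Woolf SE of the log OR; Haldane-Anscombe 0.5 added if any cell is 0."""
    t = table.astype(float)
    if (t == 0).any():
        t = t + 0.5
    return float(np.sqrt((1.0 / t).sum()))


def parent_freq_test(
    gm: GenotypeMatrix, trios: TrioSet, marker_index: int
) -> TrioTestResult:
    """Allelic chi-square: mothers as cases, fathers as controls."""
    f, m, _c = _trio_dosages(gm, trios, marker_index)
    mm = m[m != MISSING]
    ff = f[f != MISSING]
    mid = gm.markers[marker_index].id
    if mm.size == 0 or ff.size == 0:
        return _untestable(mid, "parent_freq")
    table = np.array(
        [
            [mm.sum(), 2 * mm.size - mm.sum()],
            [ff.sum(), 2 * ff.size - ff.sum()],
        ],
        dtype=np.int64,
    )
    return _table_result(mid, "parent_freq", table)


def trio_te_test(
    model: str,
    gm: GenotypeMatrix,
    trios: TrioSet,
    marker_index: int,
    matched: bool = True,
) -> TrioTestResult:
    """Trio analog of one duo interaction model at one marker.

    The per-trio maternal/paternal indicators are — offhet_rep: parent
    homozygous, among trios with a heterozygous child; mathet_rep: parent
    heterozygous, among trios with a homozygous child; diff_rep: parent
    genotype different from the affected child's, all trios.

    With ``matched=True`` (default) only indicator-discordant parent pairs
    count: b = trios where the mother carries the indicator and the father
    does not, c = the reverse, chi-square (b - c)^2 / (b + c).  With
    ``matched=False`` all mothers are compared against all fathers in an
    unmatched 2x2 Pearson chi-square, ignoring the within-trio pairing.
    """
    if model not in ("offhet_rep", "mathet_rep", "diff_rep"):
        raise ValueError(f"unknown trio test {model!r}")
    f, m, c = _trio_dosages(gm, trios, marker_index)
    ok = (f != MISSING) & (m != MISSING) & (c != MISSING)
    f, m, c = f[ok], m[ok], c[ok]
    mid = gm.markers[marker_index].id
    if model == "offhet_rep":
        keep = c == 1
        m_ind = m[keep] != 1  # homozygous mother
        f_ind = f[keep] != 1
    elif model == "mathet_rep":
        keep = c != 1
        m_ind = m[keep] == 1  # heterozygous mother
        f_ind = f[keep] == 1
    else:
        m_ind = m != c  # opposite genotype to the proband
        f_ind = f != c
    if matched:
        b = int((m_ind & ~f_ind).sum())
        cc = int((~m_ind & f_ind).sum())
        return _pair_result(mid, model, b, cc)
    table = np.array(
        [
            [m_ind.sum(), m_ind.size - m_ind.sum()],
            [f_ind.sum(), f_ind.size - f_ind.sum()],
        ],
        dtype=np.int64,
    )
    return _table_result(mid, model, table)


def run_trio_test(
    test: str,
    gm: GenotypeMatrix,
    trios: TrioSet,
    marker_index: int,
    matched: bool = True,
) -> TrioTestResult:
    if test == "tdt":
        return tdt(gm, trios, marker_index)
    if test == "parent_freq":
        return parent_freq_test(gm, trios, marker_index)
    return trio_te_test(test, gm, trios, marker_index, matched=matched)


def dl_meta(estimates: list[tuple[float, float]]) -> MetaResult:
    """DerSimonian-Laird random-effects pooling of (log OR, SE) pairs.

    With one dataset the estimate passes through flagged (tau^2 = 0).
    """
    clean = [
        (x, s) for x, s in estimates if np.isfinite(x) and np.isfinite(s)
    ]
    if not clean:
        raise ValueError("no finite estimates to pool")
    x = np.array([e[0] for e in clean])
    se = np.array([e[1] for e in clean])
    if len(clean) == 1:
        z = x[0] / se[0]
        return MetaResult(
            float(x[0]), float(se[0]), 0.0, float(z),
            float(2 * stats.norm.sf(abs(z))), clean, merged=False,
        )
    w = 1.0 / se**2
    xbar = (w * x).sum() / w.sum()
    q = float((w * (x - xbar) ** 2).sum())
    k = len(clean)
    denom = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    wstar = 1.0 / (se**2 + tau2)
    pooled = float((wstar * x).sum() / wstar.sum())
    se_pooled = float(wstar.sum() ** -0.5)
    z = pooled / se_pooled
    return MetaResult(
        pooled, se_pooled, float(tau2), float(z),
        float(2 * stats.norm.sf(abs(z))), clean,
    )


def merged_test(
    test: str, tables: list[np.ndarray], marker_id: str
) -> TrioTestResult:
    """Sum per-dataset count tables and run the single joint test.

    Pair-form inputs (``[[b, c], [0, 0]]`` from the TDT or the matched
    interaction analogs) merge into one (b, c) comparison; 2x2 tables merge
    into one Pearson test.
    """
    total = np.zeros((2, 2), dtype=np.int64)
    for t in tables:
        total += np.asarray(t, dtype=np.int64)
    if total[1].sum() == 0:  # pair-form counts
        return _pair_result(marker_id, test, int(total[0, 0]),
                            int(total[0, 1]))
    return _table_result(marker_id, test, total)


def bonferroni_gate(
    replication_p: float,
    replication_log_or: float,
    discovery_log_or: float,
    n_tests: int,
    alpha: float = 0.05,
) -> str:
    """Classify a replication attempt: 'replicated', 'nominal' or 'no'.

    Replication requires the corrected significance level AND an effect in
    the same direction as discovery; a same-direction P < alpha that misses
    the corrected threshold is only nominal.
    """
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not (
        np.isfinite(replication_p)
        and np.isfinite(replication_log_or)
        and np.isfinite(discovery_log_or)
    ):
        return "no"
    same_dir = np.sign(replication_log_or) == np.sign(discovery_log_or)
    if not same_dir:
        return "no"
    if replication_p < alpha / n_tests:
        return "replicated"
    if replication_p < alpha:
        return "nominal"
    return "no"
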