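"""Sample-, marker- and duo-level quality control.

Filters follow the usual case-control GWAS battery adapted to mother-child
pairs: per-sample and per-marker call rates, mother-child Mendelian-error
counts per marker, a Hardy-Weinberg exact test in control mothers, the F
inbreeding coefficient for contamination flagging, and pairwise relatedness
(IBS0 / pi-hat) to confirm each duo really is a parent-offspring pair.

For a biallelic marker the only Mendelian inconsistency detectable from a
mother-child pair alone is the opposite-homozygote configuration
(mother 0, child 2 or vice versa): a heterozygous mother is compatible with
any child genotype.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, DuoSet, GenotypeMatrix

#: defaults matching the discovery study's thresholds
DEFAULT_THRESHOLDS = {
    "sample_call_rate": 0.97,  # keep iff rate > threshold (strict)
    "marker_call_rate": 0.97,  # keep iff rate >= threshold
    "mendel_max": 10,  # exclude iff errors > threshold
    "hwe_min_p": 1e-10,  # exclude iff exact P < threshold (control mothers)
    "ibs0_max": 0.01,  # duo flagged misidentified above this
    "f_min": -0.15,  # sample flagged possibly contaminated below this
}


@dataclass
class QCReport:
    """Per-sample, per-marker and per-duo QC tables with reason codes."""

    samples_m: pd.DataFrame
    samples_c: pd.DataFrame
    markers: pd.DataFrame
    duos: pd.DataFrame
    excluded: pd.DataFrame  # columns: kind, id, reason

    def write(self, prefix: str) -> None:
        self.samples_m.to_csv(f"{prefix}.samples_m.tsv", sep="\t", index=False)
        self.samples_c.to_csv(f"{prefix}.samples_c.tsv", sep="\t", index=False)
        self.markers.to_csv(f"{prefix}.markers.tsv", sep="\t", index=False)
        self.duos.to_csv(f"{prefix}.duos.tsv", sep="\t", index=False)
        self.excluded.to_csv(f"{prefix}.excluded.tsv", sep="\t", index=False)


def call_rates(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Fractions of non-missing calls per sample and per marker."""
    if gm.n_samples == 0 or gm.n_markers == 0:
        raise ValueError("empty genotype matrix")
    present = gm.calls != MISSING
    return present.mean(axis=1), present.mean(axis=0)


def duo_mendel_errors(
    gm_m: GenotypeMatrix, gm_c: GenotypeMatrix, duos: DuoSet
) -> tuple[np.ndarray, np.ndarray]:
    """Opposite-homozygote counts per marker and per duo.

    Marker lists of the two matrices must be identical (same order).
    """
    m = gm_m.calls[gm_m.sample_indices(duos.mothers)]
    c = gm_c.calls[gm_c.sample_indices(duos.children)]
    err = ((m == 0) & (c == 2)) | ((m == 2) & (c == 0))
    return err.sum(axis=0), err.sum(axis=1)


def hwe_exact_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided exact Hardy-Weinberg test on genotype counts.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count (same parity as observed) whose conditional
    probability does not exceed that of the observed count; the conditional
    probability of ``k`` heterozygotes is proportional to
    ``2**k * n! / (naa! nab! nbb!)``.  Computed in log space so totals up to
    ~1e5 are exact enough to compare at 1e-9.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("negative genotype count")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("empty sample")
    n_a = 2 * n_aa + n_ab  # copies of the rarer-or-not allele A
    if n_a == 0 or n_a == 2 * n:
        return 1.0  # monomorphic

    def log_w(k: int) -> float:
        # log unnormalized probability of k heterozygotes
        naa = (n_a - k) // 2
        nbb = n - naa - k
        return (
            k * math.log(2.0)
            + math.lgamma(n + 1)
            - math.lgamma(naa + 1)
            - math.lgamma(k + 1)
            - math.lgamma(nbb + 1)
        )

    ks = range(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2)
    logs = np.array([log_w(k) for k in ks])
    logs -= logs.max()
    w = np.exp(logs)
    w /= w.sum()
    obs = w[list(ks).index(n_ab)]
    # standard (not mid-p) tail: include every outcome as or less probable
    return float(min(1.0, w[w <= obs * (1 + 1e-12)].sum()))


def genotype_counts(calls: np.ndarray) -> tuple[int, int, int]:
    """(n_a1a1, n_het, n_a2a2) ignoring missing, for a 1-D dosage vector."""
    return (
        int((calls == 2).sum()),
        int((calls == 1).sum()),
        int((calls == 0).sum()),
    )


def allele_freqs(gm: GenotypeMatrix) -> np.ndarray:
    """Per-marker a1 allele frequency over non-missing calls (NaN if none)."""
    present = gm.calls != MISSING
    dose = np.where(present, gm.calls, 0).astype(float)
    denom = 2.0 * present.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, dose.sum(axis=0) / denom, np.nan)


def inbreeding_f(
    gm: GenotypeMatrix, sample: str, freqs: np.ndarray
) -> float:
    """Method-of-moments inbreeding coefficient for one sample.

    F = (O_hom - E_hom) / (L - E_hom) with E_hom = sum_i 1 - 2 q_i (1 - q_i)
    over the L markers with a non-missing call, using supplied allele
    frequencies.  Returns NaN when the denominator degenerates.
    """
    row = gm.sample_row(sample)
    keep = (row != MISSING) & (freqs > 0) & (freqs < 1)
    if not keep.any():
        raise ValueError(f"sample {sample}: no usable markers")
    q = freqs[keep]
    obs_hom = float(((row[keep] == 0) | (row[keep] == 2)).sum())
    exp_hom = float((1.0 - 2.0 * q * (1.0 - q)).sum())
    L = float(keep.sum())
    if abs(L - exp_hom) < 1e-12:
        return float("nan")
    return (obs_hom - exp_hom) / (L - exp_hom)


def duo_relatedness(
    gm_m: GenotypeMatrix,
    gm_c: GenotypeMatrix,
    mother_id: str,
    child_id: str,
    freqs: np.ndarray,
    min_markers: int = 100,
) -> tuple[float, float]:
    """(ibs0_rate, pihat) for one putative parent-offspring pair.

    pi-hat is the PLINK-style method-of-moments estimate: observed IBS
    0/1/2 counts are equated to their expectations given the supplied allele
    frequencies under IBD states 0/1/2, solved sequentially and clamped to
    the [0, 1] simplex.  A true parent-offspring pair has IBS0 = 0 (barring
    genotyping error) and pi-hat near 0.5.
    """
    m = gm_m.sample_row(mother_id).astype(np.int16)
    c = gm_c.sample_row(child_id).astype(np.int16)
    keep = (m != MISSING) & (c != MISSING) & (freqs > 0) & (freqs < 1)
    L = int(keep.sum())
    if L < min_markers:
        raise ValueError(
            f"duo {mother_id}/{child_id}: only {L} jointly typed markers "
            f"(need >= {min_markers})"
        )
    mm, cc, q = m[keep], c[keep], freqs[keep]
    shared = 2 - np.abs(mm - cc)
    n_ibs = np.array([(shared == k).sum() for k in (0, 1, 2)], dtype=float)

    p, r = q, 1.0 - q  # a1 and a2 frequencies
    e0_ibd0 = float((2 * p**2 * r**2).sum())
    e1_ibd0 = float((4 * p**3 * r + 4 * p * r**3).sum())
    e2_ibd0 = float((p**4 + 4 * p**2 * r**2 + r**4).sum())
    e1_ibd1 = float((2 * p**2 * r + 2 * p * r**2).sum())
    e2_ibd1 = float((p**3 + p**2 * r + p * r**2 + r**3).sum())

    k0 = n_ibs[0] / e0_ibd0 if e0_ibd0 > 0 else 0.0
    k1 = (n_ibs[1] - k0 * e1_ibd0) / e1_ibd1 if e1_ibd1 > 0 else 0.0
    k2 = (n_ibs[2] - k0 * e2_ibd0 - k1 * e2_ibd1) / L
    k = np.clip([k0, k1, k2], 0.0, 1.0)
    k /= k.sum() if k.sum() > 0 else 1.0
    pihat = float(0.5 * k[1] + k[2])
    return float(n_ibs[0] / L), pihat


def apply_qc(
    gm_m: GenotypeMatrix,
    gm_c: GenotypeMatrix,
    duos: DuoSet,
    thresholds: dict | None = None,
) -> tuple[GenotypeMatrix, GenotypeMatrix, DuoSet, QCReport]:
    """Run the full marker/sample QC battery on duo data.

    Marker filters (call rate, HWE in control mothers) are evaluated
    separately in the maternal and offspring sets; a marker excluded in
    either set is excluded from the combined (transgenerational) panel, as
    are markers with more than the allowed number of duo Mendelian errors.
    Samples failing the call-rate rule are dropped together with their duo.
    """
    th = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    excluded: list[tuple[str, str, str]] = []

    # --- sample call rate (strict >)
    sr_m, _ = call_rates(gm_m)
    sr_c, _ = call_rates(gm_c)
    bad_m = {
        s for s, r in zip(gm_m.samples, sr_m) if r <= th["sample_call_rate"]
    }
    bad_c = {
        s for s, r in zip(gm_c.samples, sr_c) if r <= th["sample_call_rate"]
    }
    for s in sorted(bad_m):
        excluded.append(("sample_m", s, "call_rate"))
    for s in sorted(bad_c):
        excluded.append(("sample_c", s, "call_rate"))
    kept_duos = [
        d
        for d in duos
        if d.mother_id not in bad_m and d.child_id not in bad_c
    ]
    for d in duos:
        if d.mother_id in bad_m or d.child_id in bad_c:
            excluded.append(("duo", d.child_id, "member_failed_call_rate"))
    duos2 = DuoSet(kept_duos)
    if len(duos2) == 0:
        raise ValueError("no duos survive sample QC")
    gm_m2 = gm_m.subset(sample_ids=duos2.mothers)
    gm_c2 = gm_c.subset(sample_ids=duos2.children)

    # --- marker call rate (>=), per set
    _, mr_m = call_rates(gm_m2)
    _, mr_c = call_rates(gm_c2)
    pass_rate = (mr_m >= th["marker_call_rate"]) & (
        mr_c >= th["marker_call_rate"]
    )

    # --- Mendelian errors across duos
    mend_marker, mend_duo = duo_mendel_errors(gm_m2, gm_c2, duos2)
    pass_mendel = mend_marker <= th["mendel_max"]

    # --- HWE in control mothers, per set
    ctrl_m = gm_m2.subset(
        sample_ids=[d.mother_id for d in duos2 if d.status == "control"]
    )
    hwe_p = np.ones(gm_m2.n_markers)
    for j in range(ctrl_m.n_markers):
        naa, nab, nbb = genotype_counts(ctrl_m.calls[:, j])
        if naa + nab + nbb > 0:
            hwe_p[j] = hwe_exact_p(naa, nab, nbb)
    pass_hwe = hwe_p >= th["hwe_min_p"]

    keep = pass_rate & pass_mendel & pass_hwe
    for j, m in enumerate(gm_m2.markers):
        if not pass_rate[j]:
            excluded.append(("marker", m.id, "call_rate"))
        elif not pass_mendel[j]:
            excluded.append(("marker", m.id, "mendel"))
        elif not pass_hwe[j]:
            excluded.append(("marker", m.id, "hwe"))
    if not keep.any():
        raise ValueError("no markers survive QC")

    gm_m3 = gm_m2.subset(marker_mask=keep)
    gm_c3 = gm_c2.subset(marker_mask=keep)

    # --- per-sample F and per-duo relatedness flags (report only)
    freqs = allele_freqs(
        gm_m3.subset(
            sample_ids=[d.mother_id for d in duos2 if d.status == "control"]
        )
    )
    usable = np.isfinite(freqs) & (freqs > 0) & (freqs < 1)
    f_m = [
        inbreeding_f(gm_m3, s, np.where(usable, freqs, np.nan))
        if usable.any()
        else float("nan")
        for s in gm_m3.samples
    ]
    f_c = [
        inbreeding_f(gm_c3, s, np.where(usable, freqs, np.nan))
        if usable.any()
        else float("nan")
        for s in gm_c3.samples
    ]
    duo_rows = []
    for d in duos2:
        try:
            ibs0, pihat = duo_relatedness(
                gm_m3, gm_c3, d.mother_id, d.child_id, freqs
            )
        except ValueError:
            ibs0, pihat = float("nan"), float("nan")
        flag = "misidentified" if ibs0 > th["ibs0_max"] else ""
        duo_rows.append((d.mother_id, d.child_id, d.status, ibs0, pihat, flag))

    report = QCReport(
        samples_m=pd.DataFrame(
            {
                "sample": gm_m3.samples,
                "call_rate": call_rates(gm_m3)[0],
                "F": f_m,
                "flag": [
                    "low_F" if np.isfinite(f) and f < th["f_min"] else ""
                    for f in f_m
                ],
            }
        ),
        samples_c=pd.DataFrame(
            {
                "sample": gm_c3.samples,
                "call_rate": call_rates(gm_c3)[0],
                "F": f_c,
                "flag": [
                    "low_F" if np.isfinite(f) and f < th["f_min"] else ""
                    for f in f_c
                ],
            }
        ),
        markers=pd.DataFrame(
            {
                "marker": [m.id for m in gm_m2.markers],
                "call_rate_m": mr_m,
                "call_rate_c": mr_c,
                "mendel_errors": mend_marker,
                "hwe_p": hwe_p,
                "pass": keep,
            }
        ),
        duos=pd.DataFrame(
            duo_rows,
            columns=["mother", "child", "status", "ibs0", "pihat", "flag"],
        ),
        excluded=pd.DataFrame(excluded, columns=["kind", "id", "reason"]),
    )
    return gm_m3, gm_c3, duos2, report


# F uses frequencies estimated once (control mothers) without a small-sample
# correction; the "inbreeding_f" formula is then a deterministic function of
# the supplied frequencies, which keeps it checkable against closed forms.
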