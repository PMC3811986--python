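"""Binary maternal-offspring genotype classifiers and stratified count stacks.

Three single-locus models of maternal-offspring genotype interaction are
scored on each mother-child pair, each reducing the 3x3 dosage table to a
binary exposure:

* ``offhet`` (offspring-heterozygous): the child carries an allele the
  mother does not — possible only when the child is heterozygous and the
  mother homozygous.  Motivated by a maternal immune response to a
  paternally inherited antigen the mother lacks.
* ``mathet`` (maternal-heterozygous): the mother carries an allele the child
  does not — heterozygous mother, homozygous child.  Motivated by maternal
  (microchimeric) cells presenting an antigen foreign to the child.
* ``diff`` (difference): the two genotypes are simply not identical.

Opposite homozygotes (mother 0 / child 2 or the reverse) are Mendelian-
impossible and treated as genotyping errors: excluded, never "exposed".

Two classifier modes exist because the discovery definition is ambiguous for
the conditioned classes: in ``literal`` mode every Mendelian-consistent
complete pair is either exposed or unexposed; in ``conditioned`` mode the
offhet model drops homozygous children (and mathet drops homozygous mothers)
as uninformative, mirroring the trio replication tests which condition on
offspring genotype.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .genotype_io import MISSING, DuoSet, GenotypeMatrix, Marker

TE_MODELS = ("offhet", "mathet", "diff")


class PairClass(Enum):
    EXPOSED = "exposed"
    UNEXPOSED = "unexposed"
    EXCLUDED_MENDEL = "excluded_mendel"
    EXCLUDED_UNINFORMATIVE = "excluded_uninformative"
    EXCLUDED_MISSING = "excluded_missing"


@dataclass
class StratifiedTable:
    """counts[status, class, stratum]: a 2x2xK stack for the CMH test.

    Row 0 = case, row 1 = control; column 0 = exposed (or allele a1),
    column 1 = unexposed (or allele a2).
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim == 2:
            self.counts = self.counts[:, :, None]
        if self.counts.shape[:2] != (2, 2) or (self.counts < 0).any():
            raise ValueError("counts must be a non-negative 2x2xK stack")

    @property
    def k(self) -> int:
        return self.counts.shape[2]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def classify_pair(
    model: str, m: int, c: int, mode: str = "literal"
) -> PairClass:
    """Classify one mother-child dosage pair under one interaction model."""
    if model not in TE_MODELS:
        raise ValueError(f"unknown model {model!r}")
    if mode not in ("literal", "conditioned"):
        raise ValueError(f"unknown mode {mode!r}")
    for d in (m, c):
        if d not in (0, 1, 2, MISSING):
            raise ValueError(f"dosage {d} outside {{0,1,2,missing}}")
    if m == MISSING or c == MISSING:
        return PairClass.EXCLUDED_MISSING
    if (m, c) in ((0, 2), (2, 0)):
        return PairClass.EXCLUDED_MENDEL
    if model == "diff":
        return PairClass.EXPOSED if m != c else PairClass.UNEXPOSED
    if model == "offhet":
        if mode == "conditioned" and c != 1:
            return PairClass.EXCLUDED_UNINFORMATIVE
        exposed = c == 1 and m in (0, 2)
    else:  # mathet
        if mode == "conditioned" and m != 1:
            return PairClass.EXCLUDED_UNINFORMATIVE
        exposed = m == 1 and c in (0, 2)
    return PairClass.EXPOSED if exposed else PairClass.UNEXPOSED


def _classify_vec(
    model: str, m: np.ndarray, c: np.ndarray, mode: str
) -> np.ndarray:
    """Vectorized classifier: 1 exposed, 0 unexposed, -1 excluded."""
    out = np.full(m.shape, -1, dtype=np.int8)
    ok = (m != MISSING) & (c != MISSING)
    mendel = ((m == 0) & (c == 2)) | ((m == 2) & (c == 0))
    valid = ok & ~mendel
    if model == "diff":
        out[valid] = (m[valid] != c[valid]).astype(np.int8)
        return out
    if model == "offhet":
        informative = valid if mode == "literal" else valid & (c == 1)
        out[informative] = (
            (c[informative] == 1) & (m[informative] != 1)
        ).astype(np.int8)
    else:
        informative = valid if mode == "literal" else valid & (m == 1)
        out[informative] = (
            (m[informative] == 1) & (c[informative] != 1)
        ).astype(np.int8)
    return out


def build_binary_stack(
    gm_m: GenotypeMatrix,
    gm_c: GenotypeMatrix,
    duos: DuoSet,
    marker_index: int,
    model: str,
    n_strata: int,
    mode: str = "literal",
) -> StratifiedTable:
    """Exposure counts by case/control status and stratum for one marker.

    Duos must carry 1-based stratum assignments (the maternal cluster
    solution, by the pipeline's convention for paired tests).
    """
    m = gm_m.calls[gm_m.sample_indices(duos.mothers), marker_index]
    c = gm_c.calls[gm_c.sample_indices(duos.children), marker_index]
    cls = _classify_vec(model, m, c, mode)
    case = duos.statuses
    strata = duos.strata
    counts = np.zeros((2, 2, n_strata), dtype=np.int64)
    for k in range(1, n_strata + 1):
        in_k = strata == k
        counts[0, 0, k - 1] = ((cls == 1) & case & in_k).sum()
        counts[0, 1, k - 1] = ((cls == 0) & case & in_k).sum()
        counts[1, 0, k - 1] = ((cls == 1) & ~case & in_k).sum()
        counts[1, 1, k - 1] = ((cls == 0) & ~case & in_k).sum()
    return StratifiedTable(counts)


def build_allele_stack(
    gm: GenotypeMatrix,
    sample_ids: list[str],
    is_case: np.ndarray,
    strata: np.ndarray,
    marker_index: int,
    n_strata: int,
) -> StratifiedTable:
    """Allele-count stack for the case-control main-effect test.

    Each non-missing individual contributes its two alleles (dosage copies
    of a1, the rest a2) to the (status, stratum) cell.
    """
    d = gm.calls[gm.sample_indices(sample_ids), marker_index].astype(np.int64)
    ok = d != MISSING
    counts = np.zeros((2, 2, n_strata), dtype=np.int64)
    for k in range(1, n_strata + 1):
        for row, grp in ((0, is_case), (1, ~is_case)):
            sel = ok & grp & (strata == k)
            counts[row, 0, k - 1] = d[sel].sum()
            counts[row, 1, k - 1] = (2 - d[sel]).sum()
    return StratifiedTable(counts)


def stack_to_long(
    table: StratifiedTable, marker: Marker, model: str
) -> list[tuple]:
    """Flatten a stack to long-format rows for debugging dumps."""
    rows = []
    for k in range(table.k):
        for row, status in ((0, "case"), (1, "control")):
            for col, cls in ((0, "exposed"), (1, "unexposed")):
                rows.append(
                    (marker.id, model, status, cls, k + 1,
                     int(table.counts[row, col, k]))
                )
    return rows
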