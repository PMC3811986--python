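"""Genotype, pair and pedigree I/O plus the shared domain types.

Genotypes are stored as dosages of a designated reference allele (``a1``)
per marker: 0, 1 or 2 copies, with ``-1`` marking a missing call.  The
reference allele is fixed per marker by an explicit allele-reference file
(or, failing that, by first observation order in the PED file) so that the
coding is identical across maternal and offspring datasets — frequency-based
coding can flip between the two generations and would silently break every
mother-child comparison downstream.

File dialects are the text PED/MAP pair of early PLINK: a 6-column sample
preamble (FID IID PAT MAT SEX PHENO) followed by two single-token allele
columns per marker, missing coded ``0 0``; MAP rows are CHR SNP CM BP.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1

#: phenotype column conventions (PLINK): 2 = case/affected, 1 = control,
#: 0 or -9 = missing
_STATUS_TOKENS = {
    "case": "case",
    "control": "control",
    "2": "case",
    "1": "control",
    "affected": "case",
    "unaffected": "control",
}


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


@dataclass(frozen=True)
class Marker:
    """A biallelic SNP with a fixed allele-1 reference coding."""

    id: str
    chrom: str
    pos: int
    a1: str
    a2: str

    def __post_init__(self) -> None:
        if self.a1 == self.a2:
            raise FormatError(f"marker {self.id}: a1 == a2 ({self.a1!r})")
        if self.pos < 1:
            raise FormatError(f"marker {self.id}: position {self.pos} < 1")


@dataclass
class GenotypeMatrix:
    """samples x markers dosage matrix of a1-allele copies.

    ``calls[i, j]`` is the number of copies of ``markers[j].a1`` carried by
    ``samples[i]``, or ``MISSING``.  ``ped_info`` holds the 6-column PED
    preamble (fid, iid, pat, mat, sex, pheno) when the matrix was read from
    a PED file.
    """

    samples: list[str]
    markers: list[Marker]
    calls: np.ndarray
    ped_info: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.samples)}, {len(self.markers)})"
            )
        ok = np.isin(self.calls, (MISSING, 0, 1, 2))
        if not ok.all():
            bad = np.unique(self.calls[~ok])
            raise ValueError(f"invalid dosage values {bad.tolist()}")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample IDs")
        ids = [m.id for m in self.markers]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate marker IDs")
        self._sample_index = {s: i for i, s in enumerate(self.samples)}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def sample_row(self, sample_id: str) -> np.ndarray:
        return self.calls[self._sample_index[sample_id]]

    def sample_indices(self, sample_ids: Iterable[str]) -> np.ndarray:
        return np.fromiter(
            (self._sample_index[s] for s in sample_ids), dtype=np.intp
        )

    def subset(
        self,
        sample_ids: Sequence[str] | None = None,
        marker_mask: np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        """Return a copy restricted to the given samples and/or markers."""
        rows = (
            self.sample_indices(sample_ids)
            if sample_ids is not None
            else np.arange(self.n_samples)
        )
        cols = (
            np.flatnonzero(marker_mask)
            if marker_mask is not None
            else np.arange(self.n_markers)
        )
        info = None
        if self.ped_info is not None:
            info = self.ped_info.iloc[rows].reset_index(drop=True)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in rows],
            markers=[self.markers[j] for j in cols],
            calls=self.calls[np.ix_(rows, cols)].copy(),
            ped_info=info,
        )


@dataclass(frozen=True)
class Duo:
    mother_id: str
    child_id: str
    status: str  # "case" | "control"
    stratum: int | None = None  # 1..K, or None when unassigned

    def __post_init__(self) -> None:
        if self.mother_id == self.child_id:
            raise ValueError(f"duo with identical IDs {self.mother_id!r}")
        if self.status not in ("case", "control"):
            raise ValueError(f"bad duo status {self.status!r}")


@dataclass
class DuoSet:
    """Mother-child pairs with case/control status and optional stratum."""

    records: list[Duo]

    def __post_init__(self) -> None:
        children = [d.child_id for d in self.records]
        if len(set(children)) != len(children):
            raise ValueError("duplicate child_id: one mother per child")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def mothers(self) -> list[str]:
        return [d.mother_id for d in self.records]

    @property
    def children(self) -> list[str]:
        return [d.child_id for d in self.records]

    @property
    def statuses(self) -> np.ndarray:
        return np.array([d.status == "case" for d in self.records])

    @property
    def strata(self) -> np.ndarray:
        return np.array(
            [0 if d.stratum is None else d.stratum for d in self.records]
        )

    def with_strata(self, strata: Sequence[int]) -> "DuoSet":
        if len(strata) != len(self.records):
            raise ValueError("stratum vector length mismatch")
        return DuoSet(
            [
                Duo(d.mother_id, d.child_id, d.status, int(k))
                for d, k in zip(self.records, strata)
            ]
        )


@dataclass(frozen=True)
class Trio:
    father_id: str
    mother_id: str
    child_id: str
    affected: bool
    dataset: str

    def __post_init__(self) -> None:
        ids = {self.father_id, self.mother_id, self.child_id}
        if len(ids) != 3:
            raise ValueError("trio members must be three distinct IDs")
        if not self.dataset:
            raise ValueError("trio dataset label must be non-empty")


@dataclass
class TrioSet:
    records: list[Trio]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def datasets(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.records:
            seen.setdefault(t.dataset, None)
        return list(seen)


MODELS = ("proband", "maternal", "offhet", "mathet", "diff")


@dataclass
class ResultRow:
    """One marker-model association result for the report writer."""

    marker: Marker
    model: str
    statistic: float
    df: int
    p_value: float
    or_mh: float  # NaN when undefined
    n_effective: int = 0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_map(map_path: str | Path) -> list[tuple[str, str, int]]:
    """Read a MAP file; returns (chrom, snp_id, bp) per marker."""
    out = []
    for ln, line in enumerate(_lines(map_path), 1):
        parts = line.split()
        if len(parts) != 4:
            raise FormatError(
                f"{map_path}: line {ln}: expected 4 MAP columns, got {len(parts)}"
            )
        chrom, snp, _cm, bp = parts
        out.append((chrom, snp, int(bp)))
    return out


def read_allele_reference(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read the marker -> (a1, a2) allele-reference file."""
    ref = {}
    for ln, line in enumerate(_lines(path), 1):
        parts = line.split()
        if len(parts) != 3:
            raise FormatError(
                f"{path}: line {ln}: expected 3 columns (marker a1 a2)"
            )
        marker, a1, a2 = parts
        if a1 == a2:
            raise FormatError(f"{path}: line {ln}: a1 == a2 for {marker}")
        ref[marker] = (a1, a2)
    return ref


def read_ped_map(
    ped_path: str | Path,
    map_path: str | Path,
    ref_path: str | Path | None = None,
) -> GenotypeMatrix:
    """Read a PED/MAP pair into a dosage matrix.

    When ``ref_path`` is given it pins a1/a2 per marker; otherwise a1 is the
    first non-missing allele observed in file order (deterministic, but not
    stable across datasets — supply the reference file for multi-dataset
    work).
    """
    map_rows = read_map(map_path)
    n_markers = len(map_rows)
    ref = read_allele_reference(ref_path) if ref_path is not None else None

    samples: list[str] = []
    info_rows: list[tuple] = []
    raw: list[list[tuple[str, str]]] = []
    for ln, line in enumerate(_lines(ped_path), 1):
        parts = line.split()
        if len(parts) != 6 + 2 * n_markers:
            raise FormatError(
                f"{ped_path}: line {ln}: expected {6 + 2 * n_markers} "
                f"columns, got {len(parts)}"
            )
        fid, iid, pat, mat, sex, pheno = parts[:6]
        samples.append(iid)
        info_rows.append((fid, iid, pat, mat, sex, pheno))
        raw.append(
            [(parts[6 + 2 * j], parts[7 + 2 * j]) for j in range(n_markers)]
        )

    # establish allele coding per marker
    alleles: list[tuple[str, str]] = []
    for j, (chrom, snp, bp) in enumerate(map_rows):
        observed: list[str] = []
        for row in raw:
            for al in row[j]:
                if al != "0" and al not in observed:
                    observed.append(al)
        if len(observed) > 2:
            raise FormatError(
                f"marker {snp}: {len(observed)} alleles observed "
                f"({observed}); only biallelic markers are supported"
            )
        if ref is not None:
            if snp not in ref:
                raise FormatError(f"marker {snp} absent from allele reference")
            a1, a2 = ref[snp]
            extra = [al for al in observed if al not in (a1, a2)]
            if extra:
                raise FormatError(
                    f"marker {snp}: allele {extra[0]!r} not in reference "
                    f"({a1}/{a2})"
                )
        else:
            pad = [al for al in ("A", "B") if al not in observed]
            both = (observed + pad)[:2]
            a1, a2 = both[0], both[1]
        alleles.append((a1, a2))

    calls = np.full((len(samples), n_markers), MISSING, dtype=np.int8)
    for i, row in enumerate(raw):
        for j, (x, y) in enumerate(row):
            if x == "0" or y == "0":
                if x != y:
                    raise FormatError(
                        f"{ped_path}: sample {samples[i]}, marker "
                        f"{map_rows[j][1]}: half-missing genotype {x} {y}"
                    )
                continue
            a1 = alleles[j][0]
            calls[i, j] = (x == a1) + (y == a1)

    markers = [
        Marker(snp, chrom, bp, a1, a2)
        for (chrom, snp, bp), (a1, a2) in zip(map_rows, alleles)
    ]
    info = pd.DataFrame(
        info_rows, columns=["fid", "iid", "pat", "mat", "sex", "pheno"]
    )
    return GenotypeMatrix(samples, markers, calls, ped_info=info)


def read_pairs(path: str | Path) -> DuoSet:
    """Read the 3-column (mother, child, status) pair file."""
    records = []
    for ln, line in enumerate(_lines(path), 1):
        parts = line.split()
        if len(parts) != 3:
            raise FormatError(
                f"{path}: line {ln}: expected 3 columns, got {len(parts)}"
            )
        mother, child, status = parts
        norm = _STATUS_TOKENS.get(status.lower())
        if norm is None:
            raise FormatError(
                f"{path}: line {ln}: unknown status token {status!r}"
            )
        records.append(Duo(mother, child, norm))
    return DuoSet(records)


def read_trio_ped(
    ped_path: str | Path,
    map_path: str | Path,
    ref_path: str | Path | None = None,
    dataset: str = "rep1",
) -> tuple[GenotypeMatrix, TrioSet]:
    """Read a family-structured PED into a genotype matrix plus TrioSet.

    A trio is emitted for every sample whose PAT and MAT columns name
    genotyped samples; the affected flag comes from the child's PHENO.
    """
    gm = read_ped_map(ped_path, map_path, ref_path)
    assert gm.ped_info is not None
    present = set(gm.samples)
    trios = []
    for row in gm.ped_info.itertuples(index=False):
        if row.pat in present and row.mat in present and row.pat != "0":
            trios.append(
                Trio(
                    father_id=row.pat,
                    mother_id=row.mat,
                    child_id=row.iid,
                    affected=row.pheno == "2",
                    dataset=dataset,
                )
            )
    return gm, TrioSet(trios)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_ped_map(
    gm: GenotypeMatrix,
    ped_path: str | Path,
    map_path: str | Path,
    ref_path: str | Path | None = None,
) -> None:
    """Write a PED/MAP pair (and optionally the allele-reference file)."""
    with open(map_path, "w") as fh:
        for m in gm.markers:
            fh.write(f"{m.chrom}\t{m.id}\t0\t{m.pos}\n")
    if ref_path is not None:
        with open(ref_path, "w") as fh:
            for m in gm.markers:
                fh.write(f"{m.id}\t{m.a1}\t{m.a2}\n")
    info = gm.ped_info
    with open(ped_path, "w") as fh:
        for i, sample in enumerate(gm.samples):
            if info is not None:
                r = info.iloc[i]
                head = [r.fid, r.iid, r.pat, r.mat, str(r.sex), str(r.pheno)]
            else:
                head = [sample, sample, "0", "0", "0", "0"]
            toks = []
            for j, m in enumerate(gm.markers):
                d = gm.calls[i, j]
                if d == MISSING:
                    toks += ["0", "0"]
                else:
                    toks += [m.a1] * int(d) + [m.a2] * int(2 - d)
            fh.write(" ".join(head + toks) + "\n")


def write_results(rows: Sequence[ResultRow], path: str | Path) -> None:
    """Write association rows as a tab-delimited report.

    Columns: CHR SNP BP A1 A2 MODEL STAT P OR; sorted by (model, chrom, pos);
    an undefined odds ratio is written as ``NA``.
    """
    if not rows:
        raise ValueError("no rows to write")
    ordered = sorted(
        rows, key=lambda r: (r.model, _chrom_key(r.marker.chrom), r.marker.pos)
    )
    with open(path, "w") as fh:
        fh.write("CHR\tSNP\tBP\tA1\tA2\tMODEL\tSTAT\tP\tOR\n")
        for r in ordered:
            or_tok = "NA" if np.isnan(r.or_mh) else f"{r.or_mh:.6g}"
            p_tok = "NA" if np.isnan(r.p_value) else f"{r.p_value:.6g}"
            s_tok = "NA" if np.isnan(r.statistic) else f"{r.statistic:.6g}"
            fh.write(
                f"{r.marker.chrom}\t{r.marker.id}\t{r.marker.pos}\t"
                f"{r.marker.a1}\t{r.marker.a2}\t{r.model}\t"
                f"{s_tok}\t{p_tok}\t{or_tok}\n"
            )


def _chrom_key(chrom: str):
    return (0, int(chrom), "") if chrom.isdigit() else (1, 0, chrom)


def _lines(path: str | Path):
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                yield line
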