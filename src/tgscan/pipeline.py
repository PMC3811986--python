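"""End-to-end discovery and replication workflow.

Discovery runs, in order: QC on the duo matrices, cluster-count selection by
genomic inflation, the five genome-wide CMH scans (proband and maternal main
effects plus the three interaction classifiers), and a multinomial
likelihood-ratio follow-up for every marker-model hit below the suggestive
threshold — dropping the maternal main effect for the maternal scan, the
interaction parameter for the interaction scans.  Replication takes the
suggestive discovery hits into trio datasets, runs the matching trio test
per dataset, pools with DerSimonian-Laird meta-analysis (or the merged
joint test when any dataset has a zero cell) and gates on Bonferroni-
corrected significance with a same-direction effect.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cmh_assoc, mmlm_lrt, qc, replication, stratification
from .genotype_io import (
    DuoSet,
    GenotypeMatrix,
    ResultRow,
    TrioSet,
    read_pairs,
    read_ped_map,
    write_results,
)
from .replication import MODEL_TO_TRIO_TEST
from .tg_classifiers import TE_MODELS

log = logging.getLogger("tgscan")


@dataclass
class PipelineConfig:
    sample_call_rate: float = 0.97
    marker_call_rate: float = 0.97
    mendel_max: int = 10
    hwe_min_p: float = 1e-10
    k_max: int = 3
    suggestive_p: float = 1e-4
    top_p: float = 1e-5
    genome_wide_p: float = 5e-8
    classifier_mode: str = "literal"  # literal | conditioned
    replication_alpha: float = 0.05
    marker_step: int = 1  # thinning for the K-selection scans
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def qc_thresholds(self) -> dict:
        return {
            "sample_call_rate": self.sample_call_rate,
            "marker_call_rate": self.marker_call_rate,
            "mendel_max": self.mendel_max,
            "hwe_min_p": self.hwe_min_p,
        }


@dataclass
class DiscoveryResult:
    rows: list[ResultRow]
    lrt_rows: pd.DataFrame
    k_selection: stratification.KSelection
    qc_report: qc.QCReport
    gm_m: GenotypeMatrix
    gm_c: GenotypeMatrix
    duos: DuoSet

    def hits(self, threshold: float) -> list[ResultRow]:
        return [
            r
            for r in self.rows
            if np.isfinite(r.p_value) and r.p_value < threshold
        ]

    def qq_tables(self) -> dict[str, np.ndarray]:
        out = {}
        for model in sorted({r.model for r in self.rows}):
            p = np.array(
                [r.p_value for r in self.rows if r.model == model]
            )
            out[model] = cmh_assoc.qq_data(p)
        return out


def run_discovery(
    gm_m: GenotypeMatrix,
    gm_c: GenotypeMatrix,
    duos: DuoSet,
    cfg: PipelineConfig | None = None,
) -> DiscoveryResult:
    cfg = cfg or PipelineConfig()
    log.info("stage qc: %d duos, %d markers", len(duos), gm_c.n_markers)
    try:
        gm_m2, gm_c2, duos2, report = qc.apply_qc(
            gm_m, gm_c, duos, cfg.qc_thresholds()
        )
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'qc' failed: {exc}") from exc

    log.info("stage select_k: k_max=%d", cfg.k_max)
    try:
        ks = stratification.select_k(
            gm_m2, gm_c2, duos2, cfg.k_max, marker_step=cfg.marker_step
        )
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'select_k' failed: {exc}") from exc
    log.info(
        "selected K=%d (lambda_p=%.3f, lambda_m=%.3f)",
        ks.k, ks.maternal.lambda_proband, ks.maternal.lambda_maternal,
    )

    strata_m = ks.maternal.labels_for(duos2.mothers)
    strata_c = ks.proband.labels_for(duos2.children)
    rows: list[ResultRow] = []
    for model in ("proband", "maternal") + TE_MODELS:
        log.info("stage scan: model=%s", model)
        try:
            rows.extend(
                cmh_assoc.scan(
                    gm_m2, gm_c2, duos2, model, strata_m, strata_c, ks.k,
                    classifier_mode=cfg.classifier_mode,
                )
            )
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"stage 'scan:{model}' failed: {exc}") from exc

    log.info("stage lrt: follow-up at P < %g", cfg.suggestive_p)
    lrt_rows = _lrt_followup(gm_m2, gm_c2, duos2, rows, cfg)
    return DiscoveryResult(
        rows=rows,
        lrt_rows=lrt_rows,
        k_selection=ks,
        qc_report=report,
        gm_m=gm_m2,
        gm_c=gm_c2,
        duos=duos2,
    )


def _lrt_followup(
    gm_m: GenotypeMatrix,
    gm_c: GenotypeMatrix,
    duos: DuoSet,
    rows: list[ResultRow],
    cfg: PipelineConfig,
) -> pd.DataFrame:
    """MMLM LRT for every suggestive hit of the maternal and TE scans."""
    marker_pos = {m.id: j for j, m in enumerate(gm_c.markers)}
    is_case = duos.statuses
    m_idx = gm_m.sample_indices(duos.mothers)
    c_idx = gm_c.sample_indices(duos.children)
    out = []
    for r in rows:
        if not (np.isfinite(r.p_value) and r.p_value < cfg.suggestive_p):
            continue
        if r.model == "proband":
            continue  # main proband effect has no nested maternal null
        j = marker_pos[r.marker.id]
        counts = mmlm_lrt.counts_from_duos(
            gm_m.calls[m_idx, j].astype(int),
            gm_c.calls[c_idx, j].astype(int),
            is_case,
        )
        if r.model == "maternal":
            res = mmlm_lrt.lrt(counts, "diff", ("q", "r1", "s1"), ("q", "r1"))
        else:
            res = mmlm_lrt.lrt(
                counts, r.model, ("q", "r1", "s1", "j"), ("q", "r1", "s1")
            )
        out.append(
            {
                "marker": r.marker.id,
                "model": r.model,
                "cmh_p": r.p_value,
                "cmh_or": r.or_mh,
                "loglik_full": res.loglik_full,
                "loglik_null": res.loglik_null,
                "lrt_stat": res.lrt_stat,
                "lrt_p": res.p_value,
            }
        )
    return pd.DataFrame(
        out,
        columns=[
            "marker", "model", "cmh_p", "cmh_or", "loglik_full",
            "loglik_null", "lrt_stat", "lrt_p",
        ],
    )


def write_discovery_report(
    result: DiscoveryResult, outdir: str | Path, cfg: PipelineConfig
) -> None:
    """Write scan, LRT, lambda and QQ outputs with a config/seed header."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"# tgscan config={cfg.config_hash()} seed={cfg.seed}\n"
    scan_path = outdir / "scan_results.tsv"
    write_results(result.rows, scan_path)
    body = scan_path.read_text()
    scan_path.write_text(header + body)
    with open(outdir / "lrt_results.tsv", "w") as fh:
        fh.write(header)
        result.lrt_rows.to_csv(fh, sep="\t", index=False, float_format="%.6g")
    with open(outdir / "clusters.tsv", "w") as fh:
        fh.write(header + "sample\tset\tcluster\n")
        for label, sol in (
            ("maternal", result.k_selection.maternal),
            ("proband", result.k_selection.proband),
        ):
            for s, k in sol.assignment.items():
                fh.write(f"{s}\t{label}\t{k}\n")
    with open(outdir / "lambda_vs_k.tsv", "w") as fh:
        fh.write(header + "K\tlambda_proband\tlambda_maternal\n")
        for k, lp, lm in result.k_selection.table:
            fh.write(f"{k}\t{lp:.6f}\t{lm:.6f}\n")
    for model, data in result.qq_tables().items():
        with open(outdir / f"qq_{model}.tsv", "w") as fh:
            fh.write(header + "expected\tobserved\n")
            for e, o in data:
                fh.write(f"{e:.6f}\t{o:.6f}\n")


@dataclass
class ReplicationRow:
    marker: str
    model: str
    test: str
    p_value: float
    log_or: float
    status: str  # replicated | nominal | no | untested
    merged: bool
    n_datasets: int


def run_replication(
    discovery: list[ResultRow] | pd.DataFrame,
    trio_datasets: list[tuple[GenotypeMatrix, TrioSet]],
    cfg: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Replicate suggestive discovery hits in trio datasets.

    ``discovery`` is the list of suggestive ResultRows (marker-model pairs
    carried into replication); the Bonferroni denominator is their count.
    """
    cfg = cfg or PipelineConfig()
    if isinstance(discovery, pd.DataFrame):
        items = [
            (row.SNP, row.MODEL, float(row.OR))
            for row in discovery.itertuples(index=False)
        ]
    else:
        items = [(r.marker.id, r.model, r.or_mh) for r in discovery]
    n_tests = len(items)
    out: list[ReplicationRow] = []
    for marker_id, model, disc_or in items:
        test = MODEL_TO_TRIO_TEST[model]
        per_ds: list[replication.TrioTestResult] = []
        for gm, trios in trio_datasets:
            idx = next(
                (j for j, m in enumerate(gm.markers) if m.id == marker_id),
                None,
            )
            if idx is None:
                log.info("marker %s absent from dataset %s", marker_id,
                         trios.records[0].dataset if len(trios) else "?")
                continue
            per_ds.append(replication.run_trio_test(test, gm, trios, idx))
        testable = [r for r in per_ds if r.testable]
        if not testable:
            out.append(
                ReplicationRow(
                    marker_id, model, test, float("nan"), float("nan"),
                    "untested", False, 0,
                )
            )
            continue
        zero_cell = any(
            r.table is not None
            and (
                (r.table[0] == 0).any()
                if r.kind == "pairs"
                else (r.table == 0).any()
            )
            for r in testable
        )
        if zero_cell or len(testable) == 1:
            merged = replication.merged_test(
                test, [r.table for r in testable], marker_id
            )
            p = merged.p_value
            log_or = (
                float(np.log(merged.odds_ratio))
                if np.isfinite(merged.odds_ratio) and merged.odds_ratio > 0
                else float("nan")
            )
            was_merged = True
        else:
            meta = replication.dl_meta(
                [(float(np.log(r.odds_ratio)), r.se_log_or) for r in testable]
            )
            p, log_or, was_merged = meta.p_value, meta.pooled_log_or, False
        disc_log_or = (
            float(np.log(disc_or))
            if np.isfinite(disc_or) and disc_or > 0
            else float("nan")
        )
        status = replication.bonferroni_gate(
            p, log_or, disc_log_or, max(n_tests, 1), cfg.replication_alpha
        )
        out.append(
            ReplicationRow(
                marker_id, model, test, p, log_or, status, was_merged,
                len(testable),
            )
        )
    return pd.DataFrame([asdict(r) for r in out]) if out else pd.DataFrame(
        columns=[
            "marker", "model", "test", "p_value", "log_or", "status",
            "merged", "n_datasets",
        ]
    )


def load_duo_inputs(
    ped_m: str, map_path: str, ped_c: str, pairs_path: str,
    ref_path: str | None = None,
) -> tuple[GenotypeMatrix, GenotypeMatrix, DuoSet]:
    gm_m = read_ped_map(ped_m, map_path, ref_path)
    gm_c = read_ped_map(ped_c, map_path, ref_path)
    duos = read_pairs(pairs_path)
    return gm_m, gm_c, duos
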