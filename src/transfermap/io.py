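"""Readers, writers, configuration, and the pipeline driver.

Coordinates are VCF-style 1-based inclusive internally; block output is
BED-like 0-based half-open.  Numeric output formatting is fixed:
4 decimals for frequencies/beta/se, scientific with 2 significant digits
for p-values.  Only biallelic records are accepted; multi-allelic
records are counted and skipped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

from . import assoc as assoc_mod
from . import ld as ld_mod
from . import qc as qc_mod
from . import transfer as transfer_mod
from .core import DataFormatError, DosageMatrix, InvalidParameterError, make_variant_table

log = logging.getLogger("transfermap")

CATALOG_COLUMNS = ["SNP", "CHR", "BP", "RISK_ALLELE", "REPORTED_OR", "PANEL", "GENE"]


def write_dosage_vcf(dm: DosageMatrix, path) -> None:
    """Write a cohort as VCF with GT and per-sample DS (A1 = ALT)."""
    v = dm.variants
    g = dm.hard_calls()
    contigs = sorted(set(str(c) for c in v["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=transfermap\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=IMP,Number=0,Type=Flag,Description="Imputed variant">\n')
        fh.write('##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation r2">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=A,Type=Float,Description="A1 (ALT) dosage">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(dm.sample_ids)
            + "\n"
        )
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j in range(dm.n_variants):
            info = []
            if bool(v.at[j, "imputed"]):
                info.append("IMP")
            if np.isfinite(v.at[j, "imp_r2"]):
                info.append(f"R2={v.at[j, 'imp_r2']:.4f}")
            fields = [
                str(v.at[j, "chrom"]),
                str(int(v.at[j, "pos"])),
                str(v.at[j, "id"]),
                str(v.at[j, "a2"]),  # REF = A2 so that DS counts A1
                str(v.at[j, "a1"]),
                ".",
                "PASS",
                ";".join(info) or ".",
                "GT:DS",
            ]
            col = dm.dosages[:, j]
            hard = g[:, j]
            for i in range(dm.n_samples):
                if np.isnan(col[i]):
                    fields.append("./.:.")
                else:
                    fields.append(f"{gt_map[hard[i]]}:{col[i]:.4f}")
            fh.write("\t".join(fields) + "\n")


def read_dosage_vcf(path) -> DosageMatrix:
    """Read a biallelic dosage VCF into a DosageMatrix.

    DS is preferred when present; otherwise the dosage is the ALT-allele
    count from GT.  Multi-allelic records are counted and skipped; a
    record with neither GT nor DS raises.
    """
    reader = VCF(str(path))
    sample_ids = list(reader.samples)
    cols, meta = [], []
    n_multi = 0
    for rec in reader:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        try:
            ds = rec.format("DS")
        except KeyError:  # DS absent from the header entirely
            ds = None
        if ds is not None:
            col = ds[:, 0].astype(float)
        else:
            gts = rec.genotypes
            if gts is None:
                raise DataFormatError(
                    f"record {rec.ID or rec.POS} has neither GT nor DS"
                )
            col = np.array(
                [np.nan if a < 0 or b < 0 else float(a + b) for a, b, *_ in gts]
            )
        cols.append(col)
        imputed = rec.INFO.get("IMP") is not None
        r2 = rec.INFO.get("R2")
        meta.append(
            (
                rec.ID or f"{rec.CHROM}:{rec.POS}",
                rec.CHROM,
                rec.POS,
                rec.ALT[0],  # A1 = ALT
                rec.REF,
                imputed,
                float(r2) if r2 is not None else np.nan,
            )
        )
    if n_multi:
        log.info("skipped %d multi-allelic records", n_multi)
    if not meta:
        raise DataFormatError(f"no usable biallelic records in {path}")
    variants = make_variant_table(
        [m[0] for m in meta],
        [m[1] for m in meta],
        [m[2] for m in meta],
        [m[3] for m in meta],
        [m[4] for m in meta],
        [m[5] for m in meta],
        [m[6] for m in meta],
    )
    return DosageMatrix(np.column_stack(cols), sample_ids, variants)


def write_sample_table(samples: pd.DataFrame, path) -> None:
    out = samples.copy()
    for c in ("age", "bmi", "xhet"):
        if c in out.columns:
            out[c] = out[c].astype(float).map(lambda x: f"{x:.4f}")
    out.to_csv(path, sep="\t", index=False)


def read_sample_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "sex": str})
    required = {"sample_id", "status", "age", "sex", "bmi"}
    missing = required - set(df.columns)
    if missing:
        raise DataFormatError(f"sample table missing columns: {sorted(missing)}")
    if not set(df["status"].unique()) <= {0, 1}:
        raise DataFormatError("status must be 0 (control) or 1 (case)")
    return df


def read_index_catalog(path):
    """Index-locus catalog TSV -> list of IndexLocus (validated)."""
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "CHR": str})
    missing = [c for c in CATALOG_COLUMNS if c not in df.columns and c != "GENE"]
    if missing:
        raise DataFormatError(f"index catalog missing columns: {missing}")
    dup = df["SNP"][df["SNP"].duplicated()]
    if len(dup):
        raise DataFormatError(f"duplicated SNP ids in catalog: {sorted(set(dup))}")
    loci = []
    for k, row in df.iterrows():
        try:
            odds = float(row["REPORTED_OR"])
        except (TypeError, ValueError):
            raise DataFormatError(
                f"unparseable REPORTED_OR {row['REPORTED_OR']!r} at line {k + 2}"
            )
        loci.append(
            transfer_mod.IndexLocus(
                snp=str(row["SNP"]),
                chrom=str(row["CHR"]),
                pos=int(row["BP"]),
                risk_allele=str(row["RISK_ALLELE"]),
                reported_or=odds,
                panel=str(row["PANEL"]),
                gene=str(row.get("GENE", "")) if "GENE" in df.columns else "",
            )
        )
    return loci


def write_index_catalog(loci, path) -> None:
    rows = [
        (l.snp, l.chrom, l.pos, l.risk_allele, f"{l.reported_or:.4f}", l.panel, l.gene)
        for l in loci
    ]
    pd.DataFrame(rows, columns=CATALOG_COLUMNS).to_csv(path, sep="\t", index=False)


def write_assoc_table(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for c in ("A1_FREQ", "BETA", "SE"):
        out[c] = out[c].map(lambda x: "NA" if pd.isna(x) else f"{x:.4f}")
    out["P"] = out["P"].map(lambda x: "NA" if pd.isna(x) else f"{x:.1e}")
    out.to_csv(path, sep="\t", index=False)


def write_blocks_bed(blocks, path) -> None:
    """BED-like: chrom, 0-based half-open start, end, block id, n SNPs."""
    with open(path, "w") as fh:
        for k, b in enumerate(blocks):
            fh.write(f"{b.chrom}\t{b.start_bp - 1}\t{b.end_bp}\tblock{k + 1}\t{len(b.members)}\n")


def write_pairwise_ld(pair_table: pd.DataFrame, path) -> None:
    out = pair_table[["ID_A", "ID_B", "DPRIME", "CI_LO", "CI_HI", "R2", "CLASS"]].copy()
    for c in ("DPRIME", "CI_LO", "CI_HI", "R2"):
        out[c] = out[c].map(lambda x: "NA" if pd.isna(x) else f"{x:.4f}")
    out.to_csv(path, sep="\t", index=False)


@dataclass
class PipelineConfig:
    vcf: str
    samples: str
    catalog: str
    ref_panels: dict = field(default_factory=dict)  # panel tag -> genotype VCF
    out_dir: str = "results"
    k_pcs: int = 3
    alpha: float = 0.05
    r2_min: float = transfer_mod.DEFAULT_R2_MIN
    locus_window_bp: int = 100_000
    max_pair_distance_bp: int = ld_mod.DEFAULT_MAX_PAIR_DISTANCE_BP
    seed: int = 0
    thresholds: qc_mod.QCThresholds = field(default_factory=qc_mod.QCThresholds)

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise InvalidParameterError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        thr = qc_mod.QCThresholds(**raw.pop("thresholds", {}))
        cfg = cls(thresholds=thr, **raw)
        base = Path(path).parent
        for name in ("vcf", "samples", "catalog"):
            p = base / getattr(cfg, name)
            if not p.exists():
                raise DataFormatError(f"config path does not exist: {p}")
            setattr(cfg, name, str(p))
        cfg.ref_panels = {k: str(base / v) for k, v in cfg.ref_panels.items()}
        for p in cfg.ref_panels.values():
            if not Path(p).exists():
                raise DataFormatError(f"config path does not exist: {p}")
        return cfg


def _region_blocks(dm: DosageMatrix, locus, window_bp: int, max_pair_bp: int):
    """Gabriel blocks in the window around a locus; returns (blocks, idx)."""
    v = dm.variants
    sel = np.flatnonzero(
        (v["chrom"].astype(str).to_numpy() == str(locus.chrom))
        & (np.abs(v["pos"].to_numpy() - locus.pos) <= window_bp)
    )
    if sel.size < 2:
        return [], sel
    g = dm.hard_calls()[:, sel]
    ids = [v.at[int(j), "id"] for j in sel]
    pos = v["pos"].to_numpy()[sel]
    pt = ld_mod.pairwise_ld(g, ids, pos, max_pair_distance_bp=max_pair_bp)
    blocks = ld_mod.gabriel_blocks(
        pt, pos, ids, chrom=str(locus.chrom), max_pair_distance_bp=max_pair_bp
    )
    return blocks, sel


def run_pipeline(config: PipelineConfig) -> dict:
    """QC → PCA → association → blocks/Neff → transferability → fine map.

    Writes all artifacts under ``config.out_dir`` and returns a summary
    dict; every stage logs sample/variant counts into ``run_log``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run_log: dict = {"stages": {}}

    def stage(name, **counts):
        run_log["stages"][name] = counts
        log.info("stage %s: %s", name, counts)

    dm = read_dosage_vcf(config.vcf)
    samples = read_sample_table(config.samples)
    loci = read_index_catalog(config.catalog)
    stage("input", samples=dm.n_samples, variants=dm.n_variants, loci=len(loci))

    retained_ids, sreport = qc_mod.sample_qc(dm, samples, config.thresholds)
    keep = np.array([sid in set(retained_ids) for sid in dm.sample_ids])
    dm = dm.take_samples(keep)
    samples = samples.set_index("sample_id").loc[dm.sample_ids].reset_index()
    kept_var, vreport = qc_mod.variant_qc(
        dm, config.thresholds, status=samples["status"].to_numpy()
    )
    vkeep = dm.variants["id"].isin(set(kept_var)).to_numpy()
    dm = dm.take_variants(vkeep)
    report = qc_mod.QCReport(sreport.samples_excluded, vreport.variants_excluded)
    report.write(out / "qc_report.tsv")
    stage("qc", samples=dm.n_samples, variants=dm.n_variants)

    pruned = assoc_mod.ld_prune(dm)
    pcs, _ = assoc_mod.genotype_pca(dm, pruned, k=config.k_pcs)
    stage("pca", pruned_variants=len(pruned), k=config.k_pcs)

    assoc_df = assoc_mod.association_scan(dm, samples, pcs=pcs)
    ok = assoc_df["CODE"] == "ok"
    chisq = (assoc_df.loc[ok, "BETA"] / assoc_df.loc[ok, "SE"]) ** 2
    lambda_gc = assoc_mod.genomic_inflation(chisq) if ok.sum() >= 1 else float("nan")
    write_assoc_table(assoc_df.drop(columns=["CODE"]), out / "assoc.tsv")
    stage("association", tested=int(ok.sum()), lambda_gc=round(lambda_gc, 4))

    ref_dms = {tag: read_dosage_vcf(p) for tag, p in config.ref_panels.items()}
    study_hard = dm.hard_calls()
    vtable = dm.variants
    calls, verdicts, all_blocks = [], [], []
    for locus in loci:
        ref_dm = ref_dms.get(locus.panel)
        block = neff = None
        r2_to_index: dict = {}
        if ref_dm is not None:
            blocks, _ = _region_blocks(
                ref_dm, locus, config.locus_window_bp, config.max_pair_distance_bp
            )
            block = transfer_mod._containing_block(blocks, locus.chrom, locus.pos)
        if block is not None:
            member_pos = set()
            sel = np.flatnonzero(
                (vtable["chrom"].astype(str).to_numpy() == str(locus.chrom))
                & (vtable["pos"].to_numpy() >= block.start_bp)
                & (vtable["pos"].to_numpy() <= block.end_bp)
            )
            if sel.size:
                ids = [vtable.at[int(j), "id"] for j in sel]
                sub = study_hard[:, sel]
                try:
                    neff = ld_mod.effective_tests(dm.dosages[:, sel], ids)
                except InvalidParameterError:
                    neff = None
                try:
                    jidx = dm.variant_index(locus.snp)
                    for sid, col in zip(ids, sub.T):
                        try:
                            f = ld_mod.two_locus_em(study_hard[:, jidx], col)
                            r2_to_index[sid] = ld_mod.ld_stats(f)[1]
                        except InvalidParameterError:
                            r2_to_index[sid] = np.nan
                except KeyError:
                    pass
                block = ld_mod.LDBlock(
                    str(locus.chrom), int(block.start_bp), int(block.end_bp), ids
                )
        call = transfer_mod.call_transferability(
            locus,
            assoc_df,
            block,
            neff,
            r2_to_index,
            alpha=config.alpha,
            r2_min=config.r2_min,
        )
        calls.append(call)

        if call.status == "exact":
            study_blocks, _ = _region_blocks(
                dm, locus, config.locus_window_bp, config.max_pair_distance_bp
            )
            all_blocks.extend(study_blocks)
            ref_fm = ref_dms.get("YRI") or ref_dms.get(locus.panel)
            ref_blocks = []
            if ref_fm is not None:
                ref_blocks, _ = _region_blocks(
                    ref_fm, locus, config.locus_window_bp, config.max_pair_distance_bp
                )
            verdicts.append(
                transfer_mod.compare_blocks(study_blocks, ref_blocks, locus, assoc_df)
            )

    write_transfer_calls(calls, out / "transfer_calls.tsv")
    write_finemap_table(verdicts, out / "finemap.tsv")
    write_blocks_bed(all_blocks, out / "study_blocks.bed")

    testable = [c for c in calls if c.direction_consistent is not None]
    n_consistent = sum(1 for c in testable if c.direction_consistent)
    sign_p = (
        transfer_mod.sign_consistency_test(n_consistent, len(testable))
        if testable
        else float("nan")
    )
    summary = {
        "n_samples": dm.n_samples,
        "n_variants": dm.n_variants,
        "lambda_gc": round(lambda_gc, 4),
        "n_loci": len(loci),
        "n_untested": sum(c.status == "untested" for c in calls),
        "n_exact": sum(c.status == "exact" for c in calls),
        "n_local": sum(c.status == "local" for c in calls),
        "n_transferable": sum(c.status in ("exact", "local") for c in calls),
        "n_direction_consistent": n_consistent,
        "n_direction_testable": len(testable),
        "sign_consistency_p": float(f"{sign_p:.3e}"),
        "n_fine_mapped": sum(v.fine_mapped for v in verdicts),
        "seed": config.seed,
    }
    stage("transferability", **{k: v for k, v in summary.items() if k.startswith("n_")})
    run_log["summary"] = summary
    with open(out / "summary.json", "w") as fh:
        json.dump(run_log, fh, indent=2, sort_keys=True)
    return summary


def write_transfer_calls(calls, path) -> None:
    def fmt(x, spec):
        return "NA" if x is None or (isinstance(x, float) and np.isnan(x)) else format(x, spec)

    rows = []
    for c in calls:
        rows.append(
            (
                c.locus.snp,
                c.locus.chrom,
                c.locus.pos,
                c.status,
                fmt(c.index_p, ".1e"),
                "NA" if c.direction_consistent is None else int(c.direction_consistent),
                c.best_snp or "NA",
                fmt(c.best_snp_p, ".1e"),
                fmt(c.p_adj, ".1e"),
                fmt(c.n_eff, ".4f"),
                fmt(c.r2_to_index, ".4f"),
                c.reason,
            )
        )
    pd.DataFrame(
        rows,
        columns=[
            "SNP",
            "CHR",
            "BP",
            "STATUS",
            "INDEX_P",
            "DIR_CONSISTENT",
            "BEST_SNP",
            "BEST_P",
            "P_ADJ",
            "NEFF",
            "R2_TO_INDEX",
            "REASON",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_finemap_table(verdicts, path) -> None:
    rows = [
        (v.locus_snp, v.study_span_bp, v.reference_span_bp, int(v.fine_mapped), int(v.refined))
        for v in verdicts
    ]
    pd.DataFrame(
        rows, columns=["SNP", "STUDY_SPAN_BP", "REF_SPAN_BP", "FINE_MAPPED", "REFINED"]
    ).to_csv(path, sep="\t", index=False)
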