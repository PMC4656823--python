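"""Bundled synthetic end-to-end scenario.

Builds a self-consistent input set for the whole pipeline: a study
cohort (VCF + sample table) with planted causal loci, imputation noise
and QC flaws; EUR-like / YRI-like reference panels with longer / shorter
blocks over the same positions; a 10-locus index catalog; a truth
ledger; and a ready-to-run YAML config.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as io_mod
from . import synth
from .transfer import IndexLocus
from .core import DosageMatrix, stage_rng
from .synth import CohortConfig, FlawSpec, HaplotypePanel


def concat_panels(panels) -> HaplotypePanel:
    """Concatenate panels with equal haplotype counts along variants."""
    h = panels[0].n_haplotypes
    assert all(p.n_haplotypes == h for p in panels)
    offset = 0
    blocks = []
    for p in panels:
        blocks.append(p.block_assignment + offset)
        offset = blocks[-1].max() + 1
    return HaplotypePanel(
        chrom_label=panels[0].chrom_label,
        positions=np.concatenate([p.positions for p in panels]),
        haplotypes=np.hstack([p.haplotypes for p in panels]),
        block_assignment=np.concatenate(blocks),
        panel_tag=panels[0].panel_tag,
        a1=sum((p.a1 for p in panels), []),
        a2=sum((p.a2 for p in panels), []),
        variant_ids=sum((p.variant_ids for p in panels), []),
    )


def _simulate_genotypes_per_block(panel: HaplotypePanel, n: int, seed: int) -> DosageMatrix:
    """Independent haplotype draws per block = free recombination between
    blocks; avoids the spurious genome-wide relatedness a small panel
    induces when whole haplotypes are reused."""
    rng = stage_rng(seed, "genotypes-per-block")
    g = np.empty((n, panel.n_variants))
    for b in np.unique(panel.block_assignment):
        cols = panel.block_assignment == b
        idx = rng.integers(0, panel.n_haplotypes, size=(n, 2))
        g[:, cols] = (
            panel.haplotypes[idx[:, 0]][:, cols].astype(float)
            + panel.haplotypes[idx[:, 1]][:, cols]
        )
    ids = [f"S{i:05d}" for i in range(n)]
    return DosageMatrix(g, ids, panel.variant_table())


def generate_fixture(
    out_dir,
    seed: int = 0,
    *,
    n_loci: int = 10,
    snps_per_locus: int = 12,
    n_cases: int = 300,
    n_controls: int = 300,
    n_background: int = 400,
    n_haplotypes: int = 400,
) -> dict:
    """Write the full synthetic scenario under ``out_dir``; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = stage_rng(seed, "fixture")
    region_gap = 300_000
    base_bp = 1_000_000

    study_regions, eur_regions = [], []
    for r in range(n_loci):
        start = base_bp + r * region_gap
        common = dict(
            n_haplotypes=n_haplotypes,
            maf_range=(0.15, 0.45),
            snp_spacing=1_000,
            block_gap=0,
            start_bp=start,
            id_prefix=f"L{r:02d}_",
        )
        # study/YRI-like: short blocks; EUR-like reference: one long block
        study_regions.append(
            synth.simulate_panel(3, snps_per_locus // 3, within_block_ld=0.95,
                                 seed=seed * 1000 + r, **common)
        )
        eur_regions.append(
            synth.simulate_panel(1, snps_per_locus, within_block_ld=1.0,
                                 seed=seed * 1000 + 500 + r, **common)
        )
    bg_start = base_bp + n_loci * region_gap
    background = synth.simulate_panel(
        n_background, 1, n_haplotypes, within_block_ld=0.0,
        maf_range=(0.1, 0.5), seed=seed * 1000 + 999,
        start_bp=bg_start, snp_spacing=5_000, block_gap=0, id_prefix="BG_",
    )
    study_panel = concat_panels(study_regions + [background])
    eur_panel = concat_panels(eur_regions + [background])

    # causal loci: the index SNP of every even-numbered region
    index_col = snps_per_locus // 2
    causal, loci = [], []
    var_ids = study_panel.variant_ids
    for r in range(n_loci):
        j = r * snps_per_locus + index_col
        odds = float(rng.uniform(1.25, 1.6)) if r % 2 == 0 else 1.0
        if odds > 1.0:
            causal.append((j, odds, study_panel.a1[j]))
        snp_id = var_ids[j] if r < n_loci - 1 else "rsABSENT"
        loci.append(
            IndexLocus(
                snp=snp_id,
                chrom=study_panel.chrom_label,
                pos=int(study_panel.positions[j]),
                risk_allele=study_panel.a1[j],
                reported_or=max(odds, float(rng.uniform(1.1, 1.4))),
                panel="EUR",
                gene=f"GENE{r}",
            )
        )

    config = CohortConfig(
        n_cases=n_cases,
        n_controls=n_controls,
        causal_loci=causal,
        covariate_effects=(0.005, 0.1, 0.01),
        intercept=-0.8,
        seed=seed,
    )
    pool = _simulate_genotypes_per_block(study_panel, 4 * (n_cases + n_controls), seed)
    table = synth.simulate_phenotypes(pool, config)
    dm, samples = synth.ascertain(pool, table)

    # imputation noise on a random half of the locus-region variants
    m = dm.n_variants
    n_locus_vars = n_loci * snps_per_locus
    imputed_cols = np.sort(
        rng.choice(n_locus_vars, size=n_locus_vars // 2, replace=False)
    )
    sub = dm.take_variants(imputed_cols)
    noisy = synth.apply_imputation_noise(
        sub, rng.uniform(0.6, 0.99, imputed_cols.size), seed
    )
    dm.dosages[:, imputed_cols] = noisy.dosages
    dm.variants.loc[imputed_cols, "imputed"] = True
    dm.variants.loc[imputed_cols, "imp_r2"] = noisy.variants["imp_r2"].to_numpy()

    flaws = FlawSpec(
        n_duplicates=1,
        n_sex_discordant=2,
        n_related=2,
        related_pihat=0.5,
        n_missing_variants=2,
        missing_rate=0.2,
        n_hwe_variants=1,
    )
    dm, samples, ledger = synth.inject_flaws(dm, samples, flaws, seed)

    eur_dm = synth.simulate_genotypes(eur_panel, 200, seed + 17)
    yri_dm = _simulate_genotypes_per_block(study_panel, 150, seed + 29)

    paths = {
        "vcf": out / "cohort.vcf",
        "samples": out / "samples.tsv",
        "catalog": out / "catalog.tsv",
        "eur": out / "ref_eur.vcf",
        "yri": out / "ref_yri.vcf",
        "ledger": out / "truth_ledger.tsv",
        "config": out / "config.yaml",
    }
    io_mod.write_dosage_vcf(dm, paths["vcf"])
    io_mod.write_sample_table(samples, paths["samples"])
    io_mod.write_index_catalog(loci, paths["catalog"])
    io_mod.write_dosage_vcf(eur_dm, paths["eur"])
    io_mod.write_dosage_vcf(yri_dm, paths["yri"])
    ledger.to_csv(paths["ledger"], sep="\t", index=False)
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(
            {
                "vcf": "cohort.vcf",
                "samples": "samples.tsv",
                "catalog": "catalog.tsv",
                "ref_panels": {"EUR": "ref_eur.vcf", "YRI": "ref_yri.vcf"},
                "out_dir": str(out / "results"),
                "seed": seed,
            },
            fh,
        )
    return {k: str(v) for k, v in paths.items()}
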