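"""End-to-end orchestration: sites -> diversity + coalescent null -> F_ST ->
LD -> association, with TSV outputs and a JSON run manifest."""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .assoc import association_scan
from .diversity import concatenate_loci, diversity_stats
from .errors import HzscanError, UndefinedStatisticError
from .fst import hudson_fst_region, wc_fst_snp
from .io import (
    LocusAlignment,
    LocusAnnotation,
    SampleMeta,
    write_results,
)
from .ld import ld_matrix, pairs_to_frame, sliding_window_decay, square_matrix
from .neutrality import neutrality_pvalue, significance_stars
from .variants import (
    MERGED_MINOR,
    GenotypeMatrix,
    call_sites,
    classify_and_condense,
    concat_matrices,
    dosage_vector,
)

logger = logging.getLogger("hzscan")


@dataclass
class RunConfig:
    maf_threshold: float = 0.05
    min_alleles: int = 40
    min_pairs: int = 10
    min_n: int = 10
    reps: int = 10_000
    alpha: float = 0.05
    window: int = 50
    seed: int = 0
    populations: tuple[str, ...] = ("favorinus", "admixed", "emma")
    run_neutrality: bool = True
    run_ld: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.maf_threshold < 0.5:
            raise HzscanError("maf_threshold outside (0, 0.5)")
        if not 0 < self.alpha < 1:
            raise HzscanError("alpha outside (0, 1)")
        if self.reps < 1 or self.window < 1:
            raise HzscanError("reps and window must be positive")


def build_genotype_matrices(
    alignments: dict[str, LocusAlignment],
    annotations: list[LocusAnnotation],
    cfg: RunConfig,
) -> dict[str, GenotypeMatrix]:
    """Call and classify sites for every locus."""
    by_name = {a.locus_name: a for a in annotations}
    matrices: dict[str, GenotypeMatrix] = {}
    for name, aln in alignments.items():
        if name not in by_name:
            raise HzscanError(f"locus {name!r} has no annotation")
        gm = call_sites(aln, by_name[name], min_alleles=cfg.min_alleles)
        classify_and_condense(gm.sites, cfg.maf_threshold)
        matrices[name] = gm
    return matrices


def site_inventory(matrices: dict[str, GenotypeMatrix]) -> pd.DataFrame:
    rows = []
    for name, gm in matrices.items():
        for s in gm.sites:
            rows.append(
                (
                    s.locus_name,
                    s.offset,
                    s.interval,
                    s.interval_coordinate,
                    ",".join(f"{a}:{c}" for a, c in sorted(s.allele_counts.items())),
                    s.n_alleles_sampled,
                    s.maf,
                    s.status,
                )
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "locus", "offset", "interval", "interval_coordinate",
            "allele_counts", "n_alleles", "maf", "status",
        ],
    )
    return df.sort_values(["interval", "interval_coordinate", "locus", "offset"]).reset_index(drop=True)


def _pop_ids(samples: list[SampleMeta], population: str) -> list[str]:
    return [s.individual_id for s in samples if s.population == population]


def diversity_table(
    matrices: dict[str, GenotypeMatrix],
    annotations: list[LocusAnnotation],
    samples: list[SampleMeta],
    cfg: RunConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-locus and per-chromosome diversity with coalescent neutrality p."""
    rows = []
    interval_of = {a.locus_name: a.interval for a in annotations}
    per_pop_stats: dict[str, dict[str, list]] = {p: {} for p in cfg.populations}
    for name, gm in matrices.items():
        for pop in cfg.populations:
            ids = _pop_ids(samples, pop)
            st = diversity_stats(gm, population=pop, individual_ids=ids, locus_name=name)
            per_pop_stats[pop].setdefault(interval_of[name], []).append(st)
            rows.append(_diversity_row(st, interval_of[name], cfg, rng))
    # concatenated per mapped interval ("chromosome")
    for pop in cfg.populations:
        for interval in ("D", "Cr"):
            group = per_pop_stats[pop].get(interval, [])
            if len(group) < 2:
                continue
            st = concatenate_loci(group, group_name=f"{interval}_concatenated")
            rows.append(_diversity_row(st, interval, cfg, rng))
    df = pd.DataFrame(
        rows,
        columns=[
            "locus", "interval", "population", "L", "S", "n",
            "pi_total", "pi_per_bp", "theta_w", "tajima_d",
            "p_neutral", "stars", "sim_reps_used", "sim_excluded",
        ],
    )
    return df.sort_values(["interval", "locus", "population"]).reset_index(drop=True)


def _diversity_row(st, interval, cfg: RunConfig, rng: np.random.Generator):
    p = stars = reps_used = excluded = None
    if cfg.run_neutrality and st.tajima_d is not None and st.theta_w > 0:
        try:
            test = neutrality_pvalue(
                st.tajima_d, st.n, st.theta_w, reps=cfg.reps, rng=rng
            )
            p, stars = test.p, test.stars
            reps_used, excluded = test.reps_used, test.n_excluded
        except UndefinedStatisticError:
            pass
    return (
        st.locus_name, interval, st.population, st.L, st.S, st.n,
        st.pi_total, st.pi_per_bp, st.theta_w, st.tajima_d,
        p, stars if stars is not None else "", reps_used, excluded,
    )


def fst_tables(
    matrices: dict[str, GenotypeMatrix],
    annotations: list[LocusAnnotation],
    samples: list[SampleMeta],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-region Hudson F_ST for all population pairs, plus the interval
    summary (mean +/- sd of the pure-population comparison by interval)."""
    interval_of = {a.locus_name: a.interval for a in annotations}
    pairs = [("favorinus", "emma"), ("favorinus", "admixed"), ("emma", "admixed")]
    rows = []
    for name, gm in matrices.items():
        for pa, pb in pairs:
            try:
                res = hudson_fst_region(
                    gm, _pop_ids(samples, pa), _pop_ids(samples, pb),
                    pop_pair=(pa, pb), unit=name,
                )
                fst, hw, hb = res.fst, res.h_within, res.h_between
            except UndefinedStatisticError:
                fst = hw = hb = np.nan
            rows.append((name, interval_of[name], pa, pb, fst, hw, hb))
    region = pd.DataFrame(
        rows, columns=["locus", "interval", "pop_a", "pop_b", "fst", "h_within", "h_between"]
    ).sort_values(["interval", "locus", "pop_a", "pop_b"]).reset_index(drop=True)

    pure = region[(region.pop_a == "favorinus") & (region.pop_b == "emma")]
    summary = (
        pure.groupby("interval")["fst"]
        .agg(["mean", "std", "count"])
        .reset_index()
        .rename(columns={"mean": "mean_fst", "std": "sd_fst", "count": "n_loci"})
    )
    return region, summary


def per_snp_fst(
    matrices: dict[str, GenotypeMatrix],
    samples: list[SampleMeta],
) -> pd.DataFrame:
    """Weir-Cockerham theta per common SNP between the pure populations."""
    ids_a = _pop_ids(samples, "favorinus")
    ids_b = _pop_ids(samples, "emma")
    rows = []
    for name, gm in matrices.items():
        idx_a = gm.individual_indices(ids_a)
        idx_b = gm.individual_indices(ids_b)
        for si, site in enumerate(gm.sites):
            if site.status not in ("biallelic_informative", "condensed_biallelic",
                                   "multiallelic_excluded"):
                continue
            if site.status == "multiallelic_excluded":
                focal = min(
                    site.minor_alleles, key=lambda a: -site.allele_counts[a]
                )
            elif site.minor_class:
                focal = MERGED_MINOR
            else:
                focal = site.minor_alleles[0]
            dos = dosage_vector(gm, si, focal)
            try:
                res = wc_fst_snp(dos[idx_a], dos[idx_b], ("favorinus", "emma"))
                theta = res.fst
            except UndefinedStatisticError:
                theta = np.nan
            rows.append(
                (f"{name}:{site.offset}", name, site.interval,
                 site.interval_coordinate, focal, theta)
            )
    return pd.DataFrame(
        rows,
        columns=["site", "locus", "interval", "interval_coordinate",
                 "focal_allele", "wc_fst"],
    ).sort_values(["interval", "interval_coordinate", "site"]).reset_index(drop=True)


def ld_tables(
    combined: GenotypeMatrix,
    samples: list[SampleMeta],
    cfg: RunConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, pd.DataFrame]]:
    """Long-format LD pairs, sliding-window decay per population, and the
    square r^2 matrix per population (pooled + each population)."""
    site_indices = [
        i for i, s in enumerate(combined.sites)
        if s.status in ("biallelic_informative", "condensed_biallelic")
    ]
    pops: list[tuple[str, list[str] | None]] = [("all", None)] + [
        (p, _pop_ids(samples, p)) for p in cfg.populations
    ]
    long_frames = []
    decay_frames = []
    matrices = {}
    for label, ids in pops:
        try:
            pairs, omitted = ld_matrix(
                combined, site_indices, individual_ids=ids, min_pairs=cfg.min_pairs
            )
        except HzscanError:
            continue
        logger.info("LD %s: %d pairs, %d omitted", label, len(pairs), omitted)
        long_frames.append(pairs_to_frame(combined, pairs, population=label))
        matrices[label] = square_matrix(combined, pairs, site_indices)
        try:
            decay = sliding_window_decay(pairs, window=cfg.window)
            decay["population"] = label
            decay_frames.append(decay)
        except HzscanError:
            pass
    long_df = pd.concat(long_frames, ignore_index=True) if long_frames else pd.DataFrame()
    decay_df = pd.concat(decay_frames, ignore_index=True) if decay_frames else pd.DataFrame()
    return long_df, decay_df, matrices


def run_full_analysis(
    alignments: dict[str, LocusAlignment],
    samples: list[SampleMeta],
    annotations: list[LocusAnnotation],
    cfg: RunConfig | None = None,
    out_dir: str | None = None,
) -> dict:
    """Run every stage and return the result bundle (tables keyed by name).

    With ``out_dir`` also writes the TSVs and the JSON manifest.
    """
    if cfg is None:
        cfg = RunConfig()
    rng = np.random.default_rng(cfg.seed)
    t0 = time.time()
    timings = {}

    def stage_done(name):
        timings[name] = round(time.time() - t0, 3)
        logger.info("stage %s done at %.2fs", name, timings[name])

    matrices = build_genotype_matrices(alignments, annotations, cfg)
    sites_df = site_inventory(matrices)
    stage_done("sites")

    diversity_df = diversity_table(matrices, annotations, samples, cfg, rng)
    stage_done("diversity")

    fst_region_df, fst_summary_df = fst_tables(matrices, annotations, samples)
    snp_fst_df = per_snp_fst(matrices, samples)
    stage_done("fst")

    combined = concat_matrices(list(matrices.values()))
    tables = {
        "sites": sites_df,
        "diversity": diversity_df,
        "fst_region": fst_region_df,
        "fst_summary": fst_summary_df,
        "fst_snp": snp_fst_df,
    }
    if cfg.run_ld:
        ld_long_df, ld_decay_df, ld_mats = ld_tables(combined, samples, cfg)
        tables["ld_pairs"] = ld_long_df
        tables["ld_decay"] = ld_decay_df
        for label, mat in ld_mats.items():
            tables[f"ld_matrix_{label}"] = mat.reset_index(names="site")
        stage_done("ld")

    assoc_df = association_scan(
        combined, samples, alpha=cfg.alpha,
        maf_threshold=cfg.maf_threshold, min_n=cfg.min_n,
    )
    # join the per-SNP F_ST (Fig-4-style data layer)
    if not assoc_df.empty and not snp_fst_df.empty:
        assoc_df = assoc_df.merge(
            snp_fst_df[["site", "wc_fst"]], on="site", how="left"
        )
    tables["association"] = assoc_df
    stage_done("association")

    logger.info("stage timings (s): %s", timings)
    # timings stay out of the manifest so identical seeds give
    # byte-identical bundles
    manifest = {
        "tool": "hzscan",
        "version": __version__,
        "config": asdict(cfg),
        "n_individuals": len(samples),
        "n_loci": len(alignments),
        "n_polymorphic_sites": int(sum(m.n_sites for m in matrices.values())),
    }
    bundle = {"tables": tables, "manifest": manifest, "matrices": matrices,
              "combined": combined}
    if out_dir is not None:
        write_results(tables, out_dir, manifest)
    return bundle
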