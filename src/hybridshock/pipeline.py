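"""One-configuration orchestration of the full synthetic pipeline.

``run_pipeline`` wires the stages in dependency order — genome simulation,
cross-mapping assessment, count simulation, the contrast battery, inheritance
classification and scenario quantification, temperature-dependent ASE, and the
ATAC occupancy/affinity/integration block — and emits a ``SummaryReport``
mapping plus TSV artifacts. Every output file starts with a header recording
the config hash, the stage seed, and the package version; rerunning the same
config reproduces the files byte-identically.

Stage seeds are derived from the master seed by fixed offsets, so stages are
independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from hybridshock import atac as atacmod
from hybridshock import contrasts as conmod
from hybridshock import degene, quant
from hybridshock import syndata
from hybridshock.intervals import PeakSet, coverage_from_peaks

SEED_OFFSETS = {"genome": 11, "crossmap": 23, "counts": 37, "lengths": 41,
                "atac": 53}

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "stages": {"crossmap": True, "rna": True, "atac": True},
    "genome": {"n_chrom": 2, "chrom_len": 60_000, "n_genes": 150,
               "divergence": 0.2},
    "crossmap": {"k": 21, "read_len": 50, "n_reads": 2000, "error_rate": 0.005,
                 "min_margin": 1},
    "counts": {"n_reps": 3, "n_genes": 300, "effect_l2fc": 3.0,
               "fractions": {"inherited_ASE": 0.04, "acquired_ASE": 0.03,
                             "attenuated": 0.05, "conserved": 0.88}},
    "thresholds": {"l2fc": 1.5, "padj": 0.01},
    "atac": {"shared_fraction": 0.88, "n_reps": 3, "min_reps": 2,
             "jitter": 15, "max_promoter_len": 1000,
             "da_l2fc": 1.0, "da_padj": 0.01},
}


# ------------------------------------------------------------------ config
def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config(overrides: dict | None = None) -> dict:
    """Default config merged with overrides; validates the result."""
    cfg = _merge(DEFAULT_CONFIG, overrides or {})
    if "seed" not in cfg:
        raise ValueError("config error at key 'seed': a master seed is required")
    for key in ("l2fc", "padj"):
        if cfg["thresholds"][key] <= 0:
            raise ValueError(f"config error at key 'thresholds.{key}': must be > 0")
    if not 0 <= cfg["atac"]["shared_fraction"] <= 1:
        raise ValueError(
            "config error at key 'atac.shared_fraction': must be in [0, 1]")
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable hash of the semantic config content (key order irrelevant)."""
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, separators=(",", ":")).encode()
    ).hexdigest()[:16]


def _stage_seed(cfg: dict, stage: str) -> int:
    return (int(cfg["seed"]) * 1000 + SEED_OFFSETS[stage]) % (2**31 - 1)


# ----------------------------------------------------------------- writing
def _write_tsv(df: pd.DataFrame, path: Path, cfg_hash: str, stage_seed: int,
               index: bool = True) -> None:
    from hybridshock import __version__

    header = (f"# hybridshock v{__version__}\n"
              f"# config_hash: {cfg_hash}\n"
              f"# stage_seed: {stage_seed}\n")
    body = df.to_csv(sep="\t", index=index, float_format="%.6g")
    path.write_text(header + body)


# ---------------------------------------------------------------- pipeline
def run_pipeline(config: dict | None = None,
                 outdir: str | Path | None = None,
                 log=print) -> dict:
    """Run every enabled stage and return the summary report mapping."""
    cfg = load_config(config)
    chash = config_hash(cfg)
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    report: dict = {"config_hash": chash, "seed": cfg["seed"],
                    "stages": dict(cfg["stages"])}

    def stage_log(name, t0, n):
        log(f"[{name}] done in {time.perf_counter() - t0:.2f}s ({n} records)")

    # ----- genomes (needed by crossmap and atac)
    t0 = time.perf_counter()
    gseed = _stage_seed(cfg, "genome")
    genomes, orthologs, annotations = syndata.generate_genome_pair(
        seed=gseed, **cfg["genome"])
    stage_log("genome", t0, len(annotations))

    # ----- cross-mapping
    if cfg["stages"].get("crossmap", True):
        t0 = time.perf_counter()
        cm = quant.crossmap_simulated(
            genomes, seed=_stage_seed(cfg, "crossmap"), **cfg["crossmap"])
        report["crossmap"] = {
            f"{which}_{src}": cm.rate(src, which)
            for src in ("A", "B")
            for which in ("cross_rate", "ambiguous_rate", "correct_rate")}
        if out is not None:
            _write_tsv(cm.table, out / "crossmap_stats.tsv", chash,
                       _stage_seed(cfg, "crossmap"))
        stage_log("crossmap", t0, len(cm.table))

    # ----- RNA block
    if cfg["stages"].get("rna", True):
        t0 = time.perf_counter()
        ccfg = dict(cfg["counts"])
        design = syndata.make_effect_design(
            n_genes=ccfg.pop("n_genes"), seed=_stage_seed(cfg, "counts"),
            fractions=ccfg.pop("fractions", None),
            effect_l2fc=ccfg.pop("effect_l2fc", 3.0))
        lengths = syndata.sample_allele_lengths(
            design, seed=_stage_seed(cfg, "lengths"))
        table = syndata.simulate_counts(
            design, seed=_stage_seed(cfg, "counts"), allele_lengths=lengths,
            **ccfg)
        thr = cfg["thresholds"]

        dispersions, ddf = conmod.table_dispersions(table)
        contrast_rows = []
        per_temp = {}
        for spec in conmod.default_contrast_specs():
            res = conmod.run_contrast(table, spec, l2fc_min=thr["l2fc"],
                                      padj_max=thr["padj"],
                                      dispersions=dispersions, df=ddf)
            if spec.family in ("parents", "homeologs"):
                per_temp.setdefault(spec.temperature, {})[spec.family] = res
            sub, groups, num, den = conmod._select(table, spec)
            mean_num = sub.counts.loc[:, (groups == num).to_numpy()].mean(axis=1)
            mean_den = sub.counts.loc[:, (groups == den).to_numpy()].mean(axis=1)
            dist = conmod.expression_distance(mean_num.rank(), mean_den.rank())
            contrast_rows.append({"contrast": spec.name, "family": spec.family,
                                  "n_de": len(res["de"]),
                                  "distance_1_minus_rho": dist})
            if out is not None:
                _write_tsv(res["result"], out / f"contrast_{spec.name}.tsv",
                           chash, _stage_seed(cfg, "counts"))
        contrast_table = pd.DataFrame(contrast_rows)
        report["contrasts"] = contrast_rows

        venn_all, scen_all = {}, {}
        for temp, pair in per_temp.items():
            cls = conmod.classify_inheritance(
                pair["parents"]["de"], pair["homeologs"]["de"],
                universe=table.genes)
            venn_all[temp] = cls["venn"]
            scen_all[temp] = conmod.quantify_modulon_scenarios(cls["calls"])
            if out is not None:
                _write_tsv(cls["calls"], out / f"inheritance_{temp}.tsv",
                           chash, _stage_seed(cfg, "counts"))
        report["venn"] = venn_all
        report["scenarios"] = scen_all

        tase = conmod.temperature_dependent_ase(
            table, l2fc_min=thr["l2fc"], padj_max=thr["padj"])
        report["temperature_ase"] = {"n_genes": len(tase["de"])}

        if out is not None:
            _write_tsv(contrast_table, out / "contrast_summary.tsv", chash,
                       _stage_seed(cfg, "counts"), index=False)
        stage_log("rna", t0, len(table.genes))
        background_de = {}
        for temp in ("warm",):
            both = pd.concat([
                conmod.run_contrast(
                    table, conmod.ContrastSpec("backgrounds", species=sp,
                                               temperature=temp),
                    l2fc_min=thr["l2fc"], padj_max=thr["padj"],
                    dispersions=dispersions, df=ddf)["de"]
                for sp in ("A", "B")])
            # a gene DE against either parental background counts once;
            # keep the stronger call when both species hit
            both = both.sort_values("padj")
            background_de[temp] = both[~both.index.duplicated(keep="first")]
    else:
        background_de = {}

    # ----- ATAC block
    if cfg["stages"].get("atac", True):
        t0 = time.perf_counter()
        acfg = dict(cfg["atac"])
        aseed = _stage_seed(cfg, "atac")
        promoters = atacmod.define_promoters(
            annotations, genomes.chrom_lengths,
            max_len=acfg.pop("max_promoter_len", 1000))
        usable = promoters[promoters["length"] > 0]
        min_reps = acfg.pop("min_reps", 2)
        da_l2fc = acfg.pop("da_l2fc", 1.0)
        da_padj = acfg.pop("da_padj", 0.01)
        peaks, coverage = syndata.simulate_atac(
            usable[["chrom", "start", "end"]], seed=aseed, **acfg)
        consensus = {bg: atacmod.replicate_consensus(reps, min_reps=min_reps,
                                                     label=f"{bg}_consensus")
                     for bg, reps in peaks.items()}
        part = atacmod.partition_peaksets(consensus["parent"], consensus["hybrid"])
        report["atac_partition"] = part["counts"]

        score_groups = {
            "parent_specific": part["parent_specific"].scores,
            "consensus": part["consensus_from_parent"].scores,
            "hybrid_specific": part["hybrid_specific"].scores,
        }
        nonempty = {k: v for k, v in score_groups.items() if len(v)}
        scores = (atacmod.score_comparison(nonempty) if len(nonempty) >= 2
                  else pd.DataFrame())
        report["atac_score_p"] = {
            f"{r.group_a}_vs_{r.group_b}": r.p for r in scores.itertuples()}

        # affinity: per-replicate promoter coverage per background
        cov_counts = {}
        for bg, reps in peaks.items():
            for i, rep in enumerate(reps, 1):
                cov = coverage_from_peaks(rep)
                cov_counts[f"{bg}_r{i}"] = atacmod.promoter_counts(cov, usable)
        da_counts = pd.DataFrame(cov_counts)
        da_groups = pd.Series([c.rsplit("_", 1)[0] for c in da_counts.columns],
                              index=da_counts.columns)
        da_lengths = pd.DataFrame(
            {c: usable.set_index("gene_id")["length"] for c in da_counts.columns})
        da = atacmod.differential_accessibility(
            da_counts, da_lengths, da_groups, numerator="hybrid",
            denominator="parent", l2fc_min=da_l2fc, padj_max=da_padj)
        n_up = int((da["de"]["l2fc"] > 0).sum())
        n_down = int((da["de"]["l2fc"] < 0).sum())
        report["atac_da"] = {"n_more_open": n_up, "n_less_open": n_down}

        # integration with expression
        spec_peaks = PeakSet(pd.concat([part["parent_specific"].df,
                                        part["hybrid_specific"].df]),
                             label="background_specific")
        links = atacmod.assign_peaks_to_genes(spec_peaks, annotations, promoters)
        de_for_join = (background_de.get("warm", pd.DataFrame())
                       if background_de else pd.DataFrame())
        integ = atacmod.integrate_expression(links, de_for_join)
        report["atac_integration"] = integ["concordance"]

        if out is not None:
            _write_tsv(da["result"], out / "differential_accessibility.tsv",
                       chash, aseed)
            _write_tsv(promoters, out / "promoters.tsv", chash, aseed,
                       index=False)
            _write_tsv(pd.DataFrame([part["counts"]]),
                       out / "peak_partition.tsv", chash, aseed, index=False)
            _write_tsv(integ["table"], out / "atac_rna_integration.tsv",
                       chash, aseed, index=False)
        stage_log("atac", t0, sum(len(c) for c in consensus.values()))

    if out is not None:
        (out / "report.txt").write_text(render_report(report))
        (out / "report.json").write_text(
            json.dumps(report, indent=2, default=str, sort_keys=True))
    return report


# ----------------------------------------------------------------- render
def _pct(num: int, den: int) -> str:
    """Whole-percent rendering (floored) with a zero-denominator guard.

    Flooring matches how such shares are conventionally printed (3091 of 3492
    reads as 88%, not 89%); raw fractions stay in the TSV artifacts.
    """
    return f"{int(100 * num / den)}%" if den else "0%"


def render_report(report: dict) -> str:
    """Human-readable summary mirroring the pipeline's headline tables."""
    lines = [f"hybridshock summary (config {report['config_hash']}, "
             f"seed {report['seed']})", ""]
    if "crossmap" in report:
        lines.append("== Cross-mapping ==")
        for key, val in report["crossmap"].items():
            lines.append(f"  {key}: {val if val is None else f'{val:.4f}'}")
        lines.append("")
    if "contrasts" in report:
        lines.append("== DE genes per contrast ==")
        for row in report["contrasts"]:
            lines.append(f"  {row['contrast']:<28s} n_DE={row['n_de']:<5d} "
                         f"1-rho={row['distance_1_minus_rho']:.4f}")
        lines.append("")
    if "venn" in report:
        lines.append("== ASE inheritance (per direction: parents-only / "
                     "both / homeologs-only) ==")
        for temp, venn in report["venn"].items():
            for direction, v in venn.items():
                overlap = _pct(v["both"], v["both"] + v["homeologs_only"])
                lines.append(
                    f"  {temp:<5s} {direction:<5s} {v['parents_only']} / "
                    f"{v['both']} / {v['homeologs_only']}  "
                    f"(inherited share of imbalance: {overlap})")
        lines.append("")
    if "scenarios" in report:
        lines.append("== Modulon scenarios ==")
        for temp, s in report["scenarios"].items():
            lines.append(f"  {temp}: (i) inherited/no-crosstalk "
                         f"{s['scenario_i']:.4f}  (ii) blended/attenuated "
                         f"{s['scenario_ii']:.4f}  (iii) novel/acquired "
                         f"{s['scenario_iii']:.4f}")
        lines.append("")
    if "temperature_ase" in report:
        lines.append(f"Temperature-dependent ASE genes: "
                     f"{report['temperature_ase']['n_genes']}")
        lines.append("")
    if "atac_partition" in report:
        c = report["atac_partition"]
        lines.append("== ATAC occupancy ==")
        lines.append(
            f"  parent peaks: {c['parent']}  consensus: "
            f"{c['consensus_from_parent']} "
            f"({_pct(c['consensus_from_parent'], c['parent'])})  "
            f"parent-specific: {c['parent_specific']}")
        lines.append(
            f"  hybrid peaks: {c['hybrid']}  consensus: "
            f"{c['consensus_from_hybrid']} "
            f"({_pct(c['consensus_from_hybrid'], c['hybrid'])})  "
            f"hybrid-specific: {c['hybrid_specific']}")
        if report.get("atac_score_p"):
            for pair, p in report["atac_score_p"].items():
                lines.append(f"  score rank-sum {pair}: p={p:.3g}")
        lines.append("")
    if "atac_da" in report:
        da = report["atac_da"]
        lines.append(f"Differentially accessible promoters: "
                     f"{da['n_more_open']} more open / {da['n_less_open']} "
                     f"less open")
    if "atac_integration" in report:
        c = report["atac_integration"]
        lines.append(f"ATAC-RNA concordance: same={c['same_direction']} "
                     f"opposite={c['opposite']} no_DE={c['no_de']}")
    return "\n".join(lines) + "\n"
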