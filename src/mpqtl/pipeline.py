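"""End-to-end pipeline: simulate -> map -> associate.

The pipeline glues the library modules into three stages with file-based
hand-off (TSV + a JSON manifest per stage):

* ``run_simulate`` writes founder panels, additive probability matrices,
  the cross design, replicated phenotypes and a marker table;
* ``run_map`` runs QC, heritability, the genome scan, permutation
  thresholds, peak calling (including the "peak of interest" rule: exceeds
  the 0.5-expected-peaks threshold, or lies in a declared candidate region
  with p < 0.01), interval estimation and founder effects;
* ``run_assoc`` tests every marker in each declared region, applies the
  per-region Bonferroni correction and the random-linked-SNP comparison.

Every tunable lives in a single nested configuration dictionary whose
defaults are the analysis's canonical values (10-kb grid, loess span 0.005,
drop threshold 4.8, 1000 permutations, peak span 50 at S/N 1, rates
0.05-3, 2-LOD and 95% Bayes intervals, control cutoff 50, block window
30-110 offspring); overrides are logged in the manifest via the config hash.
"""

from __future__ import annotations

import copy
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc as assoc_mod
from . import intervals as intervals_mod
from . import io as io_mod
from . import perm as perm_mod
from . import pheno as pheno_mod
from . import scan as scan_mod
from .genmap import GeneticMap, chromosome_of
from .synthdata import (
    HaplotypeProbSet,
    QTLEffectSpec,
    calibrate_qtl_effects,
    child_seed,
    make_crosses,
    simulate_founder_pair,
    simulate_phenotypes,
    simulate_ril_set,
)

log = logging.getLogger("mpqtl")

__all__ = ["DEFAULT_CONFIG", "load_config", "run_simulate", "run_map", "run_assoc", "run_all"]


DEFAULT_CONFIG: dict = {
    "seed": 1,
    "genome": {"arms": {"2L": 5_000_000, "2R": 5_000_000}, "cm_per_mb": 2.0},
    "simulation": {
        "n_snps": 2000,
        "n_te": 8,
        "maf": {"dist": "uniform", "low": 0.05, "high": 0.5},
        "n_rils_per_pop": 600,
        "breakpoint_rate": 50.0,  # 2 x G_effective, G_effective = 25
        "het_fraction": 0.01,
        "hmm_certainty": 0.95,
        "grid_bp": 10_000,
        "mu": 60.0,
        "subpop_effect": 5.0,
        "var_genetic": 100.0,
        "var_env": 160.0,
        "n_reps": 3,
        "n_blocks": 8,
        # four aberrant weeks: one with near-total knockdown, three with
        # almost none (counts near condo saturation, ~120-125 offspring)
        "aberrant_blocks": {"B4": -45.0, "B6": 60.0, "B7": 65.0, "B8": 60.0},
        "control_low_rate": 0.05,
        "qtls": [
            {"arm": "2L", "pos_bp": 1_500_000, "fraction": 0.15},
            {"arm": "2L", "pos_bp": 3_800_000, "fraction": 0.12},
            {"arm": "2R", "pos_bp": 2_500_000, "fraction": 0.19},
        ],
    },
    "qc": {"block_min_mean": 30.0, "block_max_mean": 110.0, "min_control": 50},
    "scan": {"span": 0.005, "drop_threshold": 4.8},
    "perm": {"n_perm": 1000, "peak_span": 50, "snr": 1.0,
             "rates": [0.05, 0.2, 0.5, 1.0, 2.0, 3.0]},
    "intervals": {"lod_drop": 2.0, "coverage": 0.95},
    "peaks_of_interest": {"rate": 0.5, "candidate_p": 0.01, "candidate_regions": []},
    "assoc": {"regions": [], "n_random": 50, "alpha": 0.05},
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            cfg = _deep_merge(cfg, yaml.safe_load(fh) or {})
    if overrides:
        cfg = _deep_merge(cfg, overrides)
    return cfg


def _genome(cfg: dict) -> GeneticMap:
    return GeneticMap.uniform(cfg["genome"]["arms"], cfg["genome"]["cm_per_mb"])


def _marker_table(pa, pb, seed: int) -> pd.DataFrame:
    """Joint marker table: SNPs (with a small nonsynonymous subset) plus TEs."""
    rng = np.random.default_rng(child_seed(seed, "marker-class"))
    a_cols = [f for f in pa.founders if f != "AB8"]
    b_cols = [f for f in pb.founders if f != "AB8"]
    snps = pa.snps[["arm", "pos_bp", *a_cols]].copy()
    snps[b_cols] = pb.snps[b_cols]
    snps["AB8"] = pa.snps["AB8"]
    snps.insert(0, "marker_id", [f"snp{i + 1}" for i in range(len(snps))])
    cls = np.where(rng.random(len(snps)) < 0.05, "nonsynonymous SNP", "other SNP")
    snps.insert(1, "class", cls)
    tables = [snps]
    if pa.tes is not None:
        tes = pa.tes[["te_id", "arm", "pos_bp", *a_cols]].rename(columns={"te_id": "marker_id"})
        tes[b_cols] = pb.tes[b_cols]
        tes["AB8"] = pa.tes["AB8"]
        tes.insert(1, "class", "TE insertion")
        tables.append(tes)
    return pd.concat(tables, ignore_index=True)


def marker_dosages(
    markers: pd.DataFrame,
    design: pd.DataFrame,
    probsA: HaplotypeProbSet,
    probsB: HaplotypeProbSet,
) -> np.ndarray:
    """(n_crosses, n_markers) dosage matrix from parental allele probabilities."""
    pa_idx = probsA.index_of(design["paternal"])
    ma_idx = probsB.index_of(design["maternal"])
    out = np.zeros((len(design), len(markers)))
    for j, (_, row) in enumerate(markers.iterrows()):
        pos_a = probsA.position_index(row["arm"], int(row["pos_bp"]))
        pos_b = probsB.position_index(row["arm"], int(row["pos_bp"]))
        alleles_a = row[probsA.founders].to_numpy(dtype=float)
        alleles_b = row[probsB.founders].to_numpy(dtype=float)
        pprob = assoc_mod.ril_allele_prob(probsA.probs[pa_idx, pos_a, :], alleles_a)
        mprob = assoc_mod.ril_allele_prob(probsB.probs[ma_idx, pos_b, :], alleles_b)
        out[:, j] = assoc_mod.cross_dosage(pprob, mprob)
    return out


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def run_simulate(cfg: dict, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    sim = cfg["simulation"]
    gmap = _genome(cfg)
    pa, pb = simulate_founder_pair(
        sim["n_snps"], gmap, sim["maf"], {"n_te": sim["n_te"]}, seed=child_seed(seed, "founders")
    )
    rils_a = simulate_ril_set(pa, gmap, sim["n_rils_per_pop"], sim["breakpoint_rate"],
                              sim["het_fraction"], seed=child_seed(seed, "rilsA"))
    rils_b = simulate_ril_set(pb, gmap, sim["n_rils_per_pop"], sim["breakpoint_rate"],
                              sim["het_fraction"], seed=child_seed(seed, "rilsB"))
    probsA = HaplotypeProbSet.from_mosaics(rils_a, gmap, sim["hmm_certainty"],
                                           sim["grid_bp"], seed=child_seed(seed, "hmmA"))
    probsB = HaplotypeProbSet.from_mosaics(rils_b, gmap, sim["hmm_certainty"],
                                           sim["grid_bp"], seed=child_seed(seed, "hmmB"))
    design = make_crosses(rils_a, rils_b)
    qtls = [
        QTLEffectSpec(q["arm"], q["pos_bp"],
                      np.random.default_rng(child_seed(seed, "qtl", k)).normal(size=8),
                      np.random.default_rng(child_seed(seed, "qtl", k, "m")).normal(size=8),
                      target_fraction=q["fraction"])
        for k, q in enumerate(sim["qtls"])
    ]
    qtls, var_poly = calibrate_qtl_effects(qtls, design, probsA, probsB, sim["var_genetic"])
    rng = np.random.default_rng(child_seed(seed, "blocks"))
    blocks = [f"B{b + 1}" for b in range(sim["n_blocks"])]
    block_assignment = {c: blocks[rng.integers(len(blocks))] for c in design["cross_id"]}
    phen = simulate_phenotypes(
        design, probsA, probsB, qtls, mu=sim["mu"], subpop_effect=sim["subpop_effect"],
        block_assignment=block_assignment, block_effects=sim["aberrant_blocks"],
        var_poly=var_poly, var_env=sim["var_env"], n_reps=sim["n_reps"],
        seed=child_seed(seed, "pheno"), control_low_rate=sim["control_low_rate"],
    )
    files = {
        "founders_pA": io_mod.write_tsv(pa.snps, outdir / "founders_pA.tsv"),
        "founders_pB": io_mod.write_tsv(pb.snps, outdir / "founders_pB.tsv"),
        "probs_pA": io_mod.write_prob_set(probsA, outdir / "probs_pA.tsv"),
        "probs_pB": io_mod.write_prob_set(probsB, outdir / "probs_pB.tsv"),
        "crosses": io_mod.write_tsv(design, outdir / "crosses.tsv"),
        "phenotypes": io_mod.write_tsv(phen.table, outdir / "phenotypes.tsv"),
        "components": io_mod.write_tsv(phen.components, outdir / "components.tsv"),
        "markers": io_mod.write_tsv(_marker_table(pa, pb, seed), outdir / "markers.tsv"),
        "qtl_truth": io_mod.write_tsv(
            pd.DataFrame(
                [{"arm": q.arm, "pos_bp": q.pos_bp, "fraction": q.target_fraction}
                 for q in qtls]
            ),
            outdir / "qtl_truth.tsv",
        ),
    }
    io_mod.write_manifest(outdir, cfg, seed, list(files.values()))
    log.info("simulate: wrote %d files to %s", len(files), outdir)
    return files


def _load_inputs(datadir: Path):
    probsA = io_mod.read_prob_set(datadir / "probs_pA.tsv", "pA")
    probsB = io_mod.read_prob_set(datadir / "probs_pB.tsv", "pB")
    design = io_mod.read_tsv(datadir / "crosses.tsv")
    phen = io_mod.read_tsv(datadir / "phenotypes.tsv")
    return probsA, probsB, design, phen


def run_map(cfg: dict, datadir: str | Path, outdir: str | Path) -> dict:
    datadir, outdir = Path(datadir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    probsA, probsB, design, phen = _load_inputs(datadir)
    qc = cfg["qc"]
    filtered, block_report = pheno_mod.filter_blocks(phen, qc["block_min_mean"],
                                                     qc["block_max_mean"])
    filtered = pheno_mod.filter_controls(filtered, qc["min_control"])
    means = pheno_mod.cross_means(filtered)
    keep = design["cross_id"].isin(means["cross_id"])
    design = design[keep].reset_index(drop=True)
    means = means.set_index("cross_id").loc[design["cross_id"]].reset_index()
    y = means["mean"].to_numpy()
    herit = pheno_mod.estimate_heritability(filtered)
    scan = scan_mod.genome_scan(design, probsA, probsB, y,
                                threshold=cfg["scan"]["drop_threshold"],
                                span=cfg["scan"]["span"])
    null = perm_mod.permute_scan(y, design, probsA, probsB,
                                 n_perm=cfg["perm"]["n_perm"], span=cfg["scan"]["span"],
                                 seed=child_seed(seed, "perm"),
                                 threshold=cfg["scan"]["drop_threshold"])
    curve = perm_mod.threshold_curve(null, span=cfg["perm"]["peak_span"],
                                     snr=cfg["perm"]["snr"])
    thresholds = {r: curve.threshold_for_rate(r) for r in cfg["perm"]["rates"]}
    peaks = perm_mod.find_peaks(scan, span=cfg["perm"]["peak_span"], snr=cfg["perm"]["snr"])
    poi_cfg = cfg["peaks_of_interest"]
    t_poi = thresholds.get(poi_cfg["rate"], curve.threshold_for_rate(poi_cfg["rate"]))
    qtl_rows, effect_rows = [], []
    for k, pk in peaks.iterrows():
        raw_p = 10 ** (-float(
            scan.loc[(scan["arm"] == pk["arm"]) & (scan["pos_bp"] == pk["pos_bp"]),
                     "neglog10p"].iloc[0]
        ))
        in_candidate = any(
            r["arm"] == pk["arm"] and r["start_bp"] <= pk["pos_bp"] <= r["end_bp"]
            for r in poi_cfg["candidate_regions"]
        )
        of_interest = pk["height"] >= t_poi or (in_candidate and raw_p < poi_cfg["candidate_p"])
        if not of_interest:
            continue
        chrom = chromosome_of(pk["arm"])
        region = np.flatnonzero(
            [chromosome_of(a) == chrom for a in probsA.grid["arm"]]
        )
        curve_lod = intervals_mod.lod_curve(y, design, probsA, probsB, region)
        ci = intervals_mod.lod_drop_interval(curve_lod, cfg["intervals"]["lod_drop"])
        bci = intervals_mod.bayes_credible_interval(curve_lod, cfg["intervals"]["coverage"])
        pct = intervals_mod.percent_heritability(
            y, design, probsA, probsB, (pk["arm"], int(pk["pos_bp"])),
            herit.h2_cross_means, cfg["scan"]["drop_threshold"])
        qtl_rows.append({
            "name": chr(ord("A") + len(qtl_rows)), "arm": pk["arm"],
            "pos_bp": int(pk["pos_bp"]), "pos_cM": float(pk["pos_cM"]),
            "neglog10p": float(pk["height"]),
            "ci2lod_start_bp": ci["start_bp"], "ci2lod_end_bp": ci["end_bp"],
            "ci2lod_start_cM": ci["start_cM"], "ci2lod_end_cM": ci["end_cM"],
            "bci_start_bp": bci["start_bp"], "bci_end_bp": bci["end_bp"],
            "bci_start_cM": bci["start_cM"], "bci_end_cM": bci["end_cM"],
            "percent_h2": pct,
        })
        fa, fb = intervals_mod.founder_effects(y, design, probsA, probsB,
                                               (pk["arm"], int(pk["pos_bp"])))
        for fe in (fa, fb):
            t = fe.table.copy()
            t.insert(0, "population", fe.population)
            t.insert(0, "peak", qtl_rows[-1]["name"])
            effect_rows.append(t)
    files = [
        io_mod.write_tsv(block_report, outdir / "qc_blocks.tsv"),
        io_mod.write_tsv(means, outdir / "cross_means.tsv"),
        io_mod.write_tsv(scan, outdir / "scan.tsv"),
        io_mod.write_tsv(
            pd.DataFrame({"threshold": curve.thresholds, "expected_peaks": curve.expected_peaks}),
            outdir / "threshold_curve.tsv"),
        io_mod.write_tsv(
            pd.DataFrame([{"rate": r, "threshold": t} for r, t in thresholds.items()]),
            outdir / "thresholds.tsv"),
        io_mod.write_tsv(peaks, outdir / "peaks.tsv"),
        io_mod.write_tsv(pd.DataFrame(qtl_rows), outdir / "qtl_table.tsv"),
        io_mod.write_tsv(
            pd.concat(effect_rows, ignore_index=True) if effect_rows
            else pd.DataFrame(columns=["peak", "population", "founder", "effect", "se",
                                       "n_confident", "included"]),
            outdir / "founder_effects.tsv"),
        io_mod.write_tsv(
            pd.DataFrame([{
                "h2_individual": herit.h2_individual, "h2_cross_means": herit.h2_cross_means,
                "var_genetic": herit.var_genetic, "var_env": herit.var_env,
                "n_crosses": herit.n_crosses}]),
            outdir / "heritability.tsv"),
    ]
    io_mod.write_manifest(outdir, cfg, seed, files)
    return {"herit": herit, "scan": scan, "thresholds": thresholds, "peaks": peaks,
            "qtl_table": pd.DataFrame(qtl_rows), "y": y, "design": design,
            "probsA": probsA, "probsB": probsB}


def run_assoc(cfg: dict, datadir: str | Path, outdir: str | Path,
              map_result: dict | None = None) -> pd.DataFrame:
    datadir, outdir = Path(datadir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    if map_result is None:
        map_result = run_map(cfg, datadir, outdir / "map")
    probsA, probsB = map_result["probsA"], map_result["probsB"]
    design, y = map_result["design"], map_result["y"]
    h2m = map_result["herit"].h2_cross_means
    markers = io_mod.read_tsv(datadir / "markers.tsv")
    subpop = scan_mod.subpop_indicator(design)
    rows = []
    verdicts = []
    for region in cfg["assoc"]["regions"]:
        sel = markers[(markers["arm"] == region["arm"])
                      & markers["pos_bp"].between(region["start_bp"], region["end_bp"])]
        if sel.empty:
            log.warning("assoc region %s has no markers", region.get("name", region["arm"]))
            continue
        dos = marker_dosages(sel, design, probsA, probsB)
        results = []
        for j, (_, mrow) in enumerate(sel.iterrows()):
            try:
                res = assoc_mod.single_marker_test(y, subpop, dos[:, j], h2m,
                                                   marker_id=str(mrow["marker_id"]))
            except ValueError:
                continue
            res_class = mrow["class"]
            results.append((res, res_class, mrow["arm"], int(mrow["pos_bp"])))
        assoc_mod.region_bonferroni([r for r, *_ in results], cfg["assoc"]["alpha"])
        for res, cls, arm, pos in results:
            rows.append({"region": region.get("name", region["arm"]), "marker_id": res.marker_id,
                         "class": cls, "arm": arm, "pos_bp": pos, "beta": res.beta,
                         "p_value": res.p_value, "varexp": res.varexp,
                         "bonferroni_sig": res.bonferroni_sig})
        cand = [r.varexp for r, cls, *_ in results if cls == "nonsynonymous SNP"]
        other_idx = [j for j, (_, m) in enumerate(sel.iterrows()) if m["class"] == "other SNP"]
        if cand and other_idx:
            null = assoc_mod.random_snp_null(
                sel.iloc[other_idx], cfg["assoc"]["n_random"], y, subpop,
                dos[:, other_idx], h2m, seed=child_seed(seed, "null", region.get("name", "")))
            verdicts.append({"region": region.get("name", region["arm"]),
                             "candidates_beat_null": assoc_mod.candidates_beat_null(
                                 cand, null["varexp"].to_numpy())})
    out = pd.DataFrame(rows, columns=["region", "marker_id", "class", "arm", "pos_bp",
                                      "beta", "p_value", "varexp", "bonferroni_sig"])
    files = [io_mod.write_tsv(out, outdir / "assoc_results.tsv"),
             io_mod.write_tsv(pd.DataFrame(verdicts, columns=["region", "candidates_beat_null"]),
                              outdir / "assoc_verdicts.tsv")]
    io_mod.write_manifest(outdir, cfg, seed, files)
    return out


def run_all(cfg: dict, outdir: str | Path) -> None:
    outdir = Path(outdir)
    run_simulate(cfg, outdir / "data")
    map_result = run_map(cfg, outdir / "data", outdir / "map")
    run_assoc(cfg, outdir / "data", outdir / "assoc", map_result)
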