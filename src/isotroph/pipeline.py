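"""End-to-end analysis over one dataset directory (or in-memory dataset).

Chains the pipeline stages: per-site species summaries, weighted trophic
ranks, isotope/diet/habitat distance matrices on a shared species ordering,
Mantel and phylogenetically permuted Mantel tests, Pagel's lambda for both
isotopes, rank concordance, and (with two or more sites) the two-way
ANOVA.  This is what the ``run-all`` CLI subcommand calls.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as iio
from .comparative import mantel, pagel_lambda, phylo_mantel
from .config import AnalysisConfig
from .core import DistanceMatrix, align_labels
from .diet import diet_distance, rank_concordance, wtr_table
from .errors import AnalysisError
from .habitat import habitat_distance, species_habitat_means, transform_matrix
from .isotopes import apply_preservation_offset, summarize_species, trophic_transfers
from .stats import two_way_anova

__all__ = ["load_dataset_dir", "isotope_distance", "run_all"]


def load_dataset_dir(path: str | Path) -> dict:
    """Read the standard dataset layout written by ``simulate``/``write_dataset``."""
    p = Path(path)
    out = {
        "measurements": iio.read_isotope_table(p / "isotopes.csv"),
        "diet": iio.read_diet_table(p / "diet.csv"),
        "coding": iio.read_trophic_coding(p / "coding.csv"),
        "tree": iio.read_newick(p / "tree.nwk"),
    }
    if (p / "traps.csv").exists():
        out["traps"] = iio.read_habitat_table(p / "traps.csv")
        out["captures"] = iio.read_captures(p / "captures.csv")
    return out


def isotope_distance(summary, isotopes=("d15N", "d13C")) -> DistanceMatrix:
    """Euclidean distances between species' mean isotope signatures."""
    df = summary.to_frame().set_index("species")
    cols = [{"d15N": "mean_d15N", "d13C": "mean_d13C"}[i] for i in isotopes]
    return DistanceMatrix.from_points(list(df.index), df[cols].to_numpy())


def _mantel_block(d_iso, d_eco, tree, cfg: AnalysisConfig, seed: int) -> dict:
    res = align_labels(d_iso, d_eco)
    a, b = res.objects
    plain = mantel(a, b, n_perm=cfg.n_permutations, tail=cfg.tail, seed=seed)
    out = {"mantel": asdict(plain), "n_species": len(res.order), "dropped": res.dropped}
    if tree is not None:
        sub = tree.reindex(res.order)
        phylo = phylo_mantel(
            a, b, sub, n_perm=cfg.n_permutations, tail=cfg.tail, seed=seed + 1
        )
        out["phylo_mantel"] = asdict(phylo)
    return out


def run_all(dataset: dict, cfg: AnalysisConfig | None = None) -> dict:
    """Run every analysis stage the dataset supports; returns a results dict."""
    cfg = cfg or AnalysisConfig()
    seed = cfg.rng_seed
    measurements = apply_preservation_offset(dataset["measurements"], cfg)
    tree = dataset.get("tree")
    results: dict = {"config": cfg.to_dict()}

    sites = sorted({m.site for m in measurements})
    summaries = {s: summarize_species(measurements, s, min_n=2) for s in sites}
    results["summaries"] = {
        s: summ.to_frame().to_dict(orient="records") for s, summ in summaries.items()
    }
    results["community_ranges"] = {
        s: {
            "d15N": summ.community_range_d15N,
            "d13C": summ.community_range_d13C,
            "trophic_transfers": trophic_transfers(summ.community_range_d15N, 0.0, cfg),
        }
        for s, summ in summaries.items()
    }

    wtrs = wtr_table(dataset["diet"], dataset["coding"], min_n=cfg.min_diet_n)
    results["wtr"] = {w.species: w.wtr for w in wtrs}

    per_site: dict = {}
    for s, summ in summaries.items():
        block: dict = {}
        d_iso = isotope_distance(summ)
        d_diet = diet_distance(dataset["diet"], min_n=cfg.min_diet_n)
        try:
            block["diet_vs_isotope"] = _mantel_block(d_iso, d_diet, tree, cfg, seed)
        except AnalysisError as e:
            block["diet_vs_isotope"] = {"error": str(e)}
        try:
            d_termite = diet_distance(
                dataset["diet"], categories=["Isoptera"], min_n=cfg.min_diet_n
            )
            block["termite_vs_isotope"] = _mantel_block(d_iso, d_termite, tree, cfg, seed + 10)
        except AnalysisError as e:
            block["termite_vs_isotope"] = {"error": str(e)}
        if "traps" in dataset:
            raw = species_habitat_means(dataset["traps"], dataset["captures"])
            mat = transform_matrix(raw)
            try:
                d_hab = habitat_distance(mat, standardize=cfg.standardize_habitat)
                block["habitat_vs_isotope"] = _mantel_block(d_iso, d_hab, tree, cfg, seed + 20)
            except AnalysisError as e:
                block["habitat_vs_isotope"] = {"error": str(e)}
        # concordance of d15N ordering with stomach-content trophic rank
        wtr_map = {w.species: w.wtr for w in wtrs}
        shared = [
            r.species for r in summ.summaries if r.species in wtr_map
        ]
        if len(shared) >= 3:
            d15 = {r.species: r.mean_d15N for r in summ.summaries}
            conc = rank_concordance(
                np.array([d15[sp] for sp in shared]),
                np.array([wtr_map[sp] for sp in shared]),
            )
            block["rank_concordance"] = asdict(conc)
        per_site[s] = block
    results["per_site"] = per_site

    if tree is not None:
        phylosig = {}
        for iso in ("d15N", "d13C"):
            trait: dict[str, float] = {}
            frames = []
            for summ in summaries.values():
                frames.append(summ.species_means(iso))
            pooled = pd.concat(frames).groupby(level=0).mean()
            try:
                lam = pagel_lambda(tree, dict(pooled))
                phylosig[iso] = {
                    "lambda": lam.lambda_hat,
                    "logL": lam.logL_hat,
                    "logL_lambda0": lam.logL_lambda0,
                    "lrt_p": lam.lrt_p,
                    "n": lam.n,
                    "effectively_zero": lam.effectively_zero,
                }
            except AnalysisError as e:
                phylosig[iso] = {"error": str(e)}
        results["phylogenetic_signal"] = phylosig

    if len(sites) >= 2:
        anova = {}
        for iso in ("d15N", "d13C"):
            vals = [getattr(m, iso) for m in measurements]
            table = two_way_anova(
                vals, [m.species for m in measurements], [m.site for m in measurements]
            )
            anova[iso] = table.to_frame().to_dict(orient="records")
        results["anova"] = anova

    return results
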