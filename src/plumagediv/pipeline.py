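"""Config-driven orchestration of the full analysis.

Stages: (1) spectra -> per-patch JND colour-distance matrices per sex (plus
the whole-body average); (2) range geometry -> pairwise distance/overlap/
sympatry; (3) rasters -> Schoener's D overlaps and species mean NDVI;
(4) assembly of the pair table, three-partition GLS, and PGLS of colour
metrics on NDVI, with BH-FDR correction.  Every run writes a manifest
(config hash, seed, output checksums) sufficient to reproduce the outputs
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import geography, niche, phylo, simulate, spectra, stats, visual

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "plumagediv_out",
    "inputs": None,  # {"spectra":..., "tree":..., "ranges":..., "ndvi":..., "suitability_dir":...}
    "synthetic": {"n_species": 30},
    "cones": {
        "lambda_max": list(visual.DEFAULT_LAMBDA_MAX),
        "densities": list(visual.DEFAULT_DENSITIES),
        "weber": visual.DEFAULT_WEBER,
    },
    "geometry_mode": "planar",
    "overlap_aggregation": "mean",
    "standardize": "predictors",
    "fdr_family": "table",
    "mean_ndvi_mode": "range",  # "range" | "suitability"
}


def merge_config(user: dict | None) -> dict:
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for k, v in (user or {}).items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def load_config(path: str | Path | None) -> dict:
    user = yaml.safe_load(Path(path).read_text()) if path else None
    return merge_config(user)


def cone_set(cfg: dict) -> visual.ConeSet:
    c = cfg["cones"]
    return visual.ConeSet(
        lambda_max=tuple(c["lambda_max"]),
        densities=tuple(c["densities"]),
        weber=float(c["weber"]),
    )


def load_inputs(cfg: dict) -> dict:
    """Resolve input objects from file paths or from the synthetic block."""
    if cfg.get("inputs"):
        paths = cfg["inputs"]
        tree = phylo.read_newick(Path(paths["tree"]))
        spectra_set = spectra.read_spectra(paths["spectra"])
        ranges = geography.read_ranges(paths["ranges"], mode=cfg["geometry_mode"])
        ndvi = niche.read_ascii_grid(paths["ndvi"], name="ndvi")
        suit_dir = Path(paths["suitability_dir"])
        suit_ndvi, suit_all = {}, {}
        for p in sorted(suit_dir.glob("suit_ndvi_*.asc")):
            sp = p.stem.removeprefix("suit_ndvi_")
            suit_ndvi[sp] = niche.read_ascii_grid(p, name=sp)
        for p in sorted(suit_dir.glob("suit_all_*.asc")):
            sp = p.stem.removeprefix("suit_all_")
            suit_all[sp] = niche.read_ascii_grid(p, name=sp)
        return {
            "tree": tree, "spectra": spectra_set, "ranges": ranges,
            "ndvi": ndvi, "suit_ndvi": suit_ndvi, "suit_all": suit_all or None,
        }
    syn = dict(cfg.get("synthetic") or {})
    syn.setdefault("seed", cfg["seed"])
    config = simulate.SyntheticConfig(**syn)
    tree = simulate.simulate_tree(config.n_species, config.seed, config.tree_depth)
    ranges = simulate.simulate_ranges(config.n_species, config)
    ndvi, suit_ndvi, suit_all = simulate.simulate_rasters(config, ranges)
    return {
        "tree": tree,
        "spectra": simulate.simulate_spectra(tree, config),
        "ranges": ranges,
        "ndvi": ndvi,
        "suit_ndvi": suit_ndvi,
        "suit_all": suit_all,
    }


def compute_distances(
    spectra_set: spectra.PatchSpectraSet, cones: visual.ConeSet
) -> dict[str, dict[str, visual.ColorDistanceMatrix]]:
    """Averaged spectra -> JND matrices per sex per patch (+ whole-body average)."""
    averaged = spectra_set.averaged()
    return {sex: visual.all_patch_matrices(averaged, sex, cones) for sex in spectra.SEXES}


def compute_niche_overlaps(
    suit: dict[str, niche.SuitabilityRaster], variable_set: str
) -> list[niche.NicheOverlap]:
    import itertools

    return [
        niche.schoeners_D(suit[a], suit[b], variable_set)
        for a, b in itertools.combinations(sorted(suit), 2)
    ]


def compute_mean_ndvi(
    ndvi: niche.SuitabilityRaster,
    ranges: list[geography.RangePolygon],
    suit: dict[str, niche.SuitabilityRaster],
    mode: str = "range",
) -> pd.Series:
    if mode == "range":
        return pd.Series({r.species: niche.mean_ndvi(ndvi, range_polygon=r) for r in ranges})
    return pd.Series({sp: niche.mean_ndvi(ndvi, suitability=s) for sp, s in suit.items()})


def compute_colour_metrics(spectra_set: spectra.PatchSpectraSet, sex: str) -> pd.DataFrame:
    """(species, patch)-indexed colorimetric table for one sex."""
    averaged = spectra_set.averaged()
    rows = {}
    for patch in spectra.PATCHES:
        for key in averaged.keys_for(sex, patch):
            spec = spectra.regrid(averaged.get(*key))
            m = spectra.colorimetrics(spec)
            rows[(key[0], patch)] = {
                **{f"S1{band}": v for band, v in m.S1.items()},
                "H1": m.H1,
                "B2": m.B2,
            }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index = pd.MultiIndex.from_tuples(df.index, names=["species", "patch"])
    return df


def run_full_analysis(cfg: dict, inputs: dict | None = None) -> dict[str, pd.DataFrame]:
    """Run every stage and return the result tables (also written to outdir)."""
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = inputs or load_inputs(cfg)
    cones = cone_set(cfg)

    distances = compute_distances(inputs["spectra"], cones)
    geo_table = geography.pairwise_geo_table(inputs["ranges"])
    ndvi_overlaps = compute_niche_overlaps(inputs["suit_ndvi"], "NDVI")
    all_overlaps = (
        compute_niche_overlaps(inputs["suit_all"], "all") if inputs.get("suit_all") else None
    )
    mean_ndvi = compute_mean_ndvi(
        inputs["ndvi"], inputs["ranges"], inputs["suit_ndvi"], cfg["mean_ndvi_mode"]
    )
    cov = phylo.vcv_from_tree(inputs["tree"])
    phylo_dist = phylo.pairwise_divergence(inputs["tree"])

    outputs: dict[str, pd.DataFrame] = {}
    patches = list(spectra.PATCHES) + ["average"]
    for sex in spectra.SEXES:
        pair_table = stats.assemble_pair_table(
            distances[sex], phylo_dist, geo_table, ndvi_overlaps, all_overlaps,
            overlap_aggregation=cfg["overlap_aggregation"],
        )
        outputs[f"pairs_{sex}"] = pair_table
        gls = stats.run_gls_tables(
            pair_table, patches, sex,
            standardize=cfg["standardize"], fdr_family=cfg["fdr_family"],
        )
        for part in gls["partition"].unique():
            outputs[f"gls_{sex}_{part}"] = gls[gls["partition"] == part].reset_index(drop=True)
        metrics = compute_colour_metrics(inputs["spectra"], sex)
        outputs[f"pgls_{sex}"] = stats.run_pgls_tables(
            metrics, mean_ndvi, cov, sex, fdr_family=cfg["fdr_family"]
        )

    for name, df in outputs.items():
        df.to_csv(outdir / f"{name}.csv", index=False)
    write_manifest(cfg, outdir, [f"{n}.csv" for n in outputs])
    return outputs


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(cfg: dict, outdir: Path, files: list[str]) -> None:
    manifest = {
        "seed": cfg["seed"],
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "outputs": {f: _sha256(outdir / f) for f in sorted(files) if (outdir / f).exists()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
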