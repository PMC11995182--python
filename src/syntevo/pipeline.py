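"""End-to-end orchestration: synteny -> Ks -> mixture fit -> rate
correction -> dating -> retention -> karyotype, driven by one validated
config, with every stage communicating through files and a manifest
recording parameters, seed and output checksums. Rerunning the same config
reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import io_core, ksrates, retention as retention_mod, synteny
from .karyotype import (
    linearize_cars,
    partition_ancestral_blocks,
    score_adjacencies,
    classify_rearrangements,
)
from .types import Genome

logger = logging.getLogger("syntevo")

__all__ = ["PipelineConfig", "ConfigError", "run_pipeline", "run_demo"]


class ConfigError(ValueError):
    """Invalid pipeline configuration (exit code 2 territory)."""


_CHAIN_DEFAULTS = {"max_gap": 25, "min_block_size": 5, "gap_penalty": 1.0}
_KS_DEFAULTS = {
    "ks_min": 0.005, "ks_max": 5.0, "max_components": 4, "gamma_prior": 1.2,
}
_RETENTION_DEFAULTS = {"window": 100, "step": 50}
_KARYOTYPE_DEFAULTS = {
    "min_support": 2, "min_genes": 1, "chain_max_gap": 0,
    "chain_min_block": 3,
}


def _merge(defaults: dict, given: dict, section: str) -> dict:
    unknown = set(given) - set(defaults)
    if unknown:
        raise ConfigError(f"unknown keys in params.{section}: {sorted(unknown)}")
    out = dict(defaults)
    out.update(given)
    return out


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    species: list of {label, bed, cds?}; pairs: list of {a, b, file}.
    Self-pairs (a == b) carry within-genome paralog pairs and feed the
    per-species gamma-peak fits used for rate correction.
    """

    species: list[dict]
    pairs: list[dict]
    out_dir: str
    seed: int = 0
    reference: str | None = None
    tree: str | None = None
    rate_r: float | None = None
    chain: dict = field(default_factory=dict)
    ks: dict = field(default_factory=dict)
    retention: dict = field(default_factory=dict)
    karyotype: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        allowed = {
            "species", "pairs", "out_dir", "seed", "reference", "tree",
            "rate_r", "params",
        }
        unknown = set(raw) - allowed
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for req in ("species", "pairs", "out_dir"):
            if req not in raw:
                raise ConfigError(f"missing required config key: {req}")
        params = raw.get("params", {})
        allowed_params = {"chain", "ks", "retention", "karyotype"}
        unknown = set(params) - allowed_params
        if unknown:
            raise ConfigError(f"unknown params sections: {sorted(unknown)}")
        labels = [s.get("label") for s in raw["species"]]
        if len(set(labels)) != len(labels) or None in labels:
            raise ConfigError("species labels must be present and unique")
        for p in raw["pairs"]:
            for side in ("a", "b"):
                if p.get(side) not in labels:
                    raise ConfigError(f"pair references unknown species {p.get(side)!r}")
        rate_r = raw.get("rate_r")
        if rate_r is not None and rate_r <= 0:
            raise ConfigError(f"rate_r must be positive, got {rate_r}")
        ref = raw.get("reference")
        if ref is not None and ref not in labels:
            raise ConfigError(f"reference {ref!r} is not a configured species")
        return cls(
            species=raw["species"],
            pairs=raw["pairs"],
            out_dir=raw["out_dir"],
            seed=int(raw.get("seed", 0)),
            reference=ref,
            tree=raw.get("tree"),
            rate_r=rate_r,
            chain=_merge(_CHAIN_DEFAULTS, params.get("chain", {}), "chain"),
            ks=_merge(_KS_DEFAULTS, params.get("ks", {}), "ks"),
            retention=_merge(_RETENTION_DEFAULTS, params.get("retention", {}), "retention"),
            karyotype=_merge(_KARYOTYPE_DEFAULTS, params.get("karyotype", {}), "karyotype"),
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping")
        return cls.from_dict(raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def _pair_ks_table(blocks, cds_a, cds_b, ks_cfg) -> tuple[list[tuple], dict]:
    rows = []
    ks_by_pair = {}
    for b in blocks:
        for a in b.anchors:
            sa, sb = cds_a.get(a.gene_a), cds_b.get(a.gene_b)
            if sa is None or sb is None:
                continue
            aln = ksrates.align_codons(sa, sb)
            est = ksrates.ks_ng86(aln)
            ks_by_pair[(a.gene_a, a.gene_b)] = est
            rows.append(
                (a.gene_a, a.gene_b, b.block_id, est.S, est.N, est.Sd, est.Nd,
                 est.ks, est.ka, int(est.saturated))
            )
    return rows, ks_by_pair


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "params": {
            "chain": config.chain, "ks": config.ks,
            "retention": config.retention, "karyotype": config.karyotype,
            "rate_r": config.rate_r,
        },
        "stages": {},
        "outputs": {},
    }
    outputs: list[Path] = []

    def emit(path: Path) -> Path:
        outputs.append(path)
        return path

    # --- load -----------------------------------------------------------
    logger.info("loading %d genomes", len(config.species))
    genomes: dict[str, Genome] = {}
    cds: dict[str, dict[str, str]] = {}
    for sp in config.species:
        label = sp["label"]
        genomes[label] = io_core.read_gene_positions(sp["bed"], species_label=label)
        cds[label] = io_core.read_cds_fasta(sp["cds"]) if sp.get("cds") else {}
    reference = config.reference or config.species[0]["label"]

    # --- synteny --------------------------------------------------------
    blocks_by_pair: dict[tuple[str, str], list] = {}
    depth_ratios = {}
    for p in config.pairs:
        a, b = p["a"], p["b"]
        pairs, rejects = io_core.read_homolog_pairs(
            p["file"], genomes[a], genomes[b]
        )
        anchors, _ = synteny.build_anchors(pairs, genomes[a], genomes[b])
        blocks = synteny.chain_anchors(anchors, **config.chain)
        synteny.classify_blocks(blocks, genomes[a], genomes[b])
        blocks_by_pair[(a, b)] = blocks
        stem = f"{a}--{b}"
        io_core.write_collinearity(blocks, emit(out / f"{stem}.collinearity"))
        with open(emit(out / f"{stem}.classes.tsv"), "w") as fh:
            fh.write("classification\tblocks\tanchors\n")
            for cls, d in sorted(synteny.classification_counts(blocks).items()):
                fh.write(f"{cls}\t{d['blocks']}\t{d['anchors']}\n")
        if a != b:
            dr = synteny.estimate_depth_ratio(blocks, genomes[a], genomes[b])
            depth_ratios[stem] = {
                "ratio": dr.ratio, "modal_a": dr.modal_a, "modal_b": dr.modal_b,
                "histogram_a": {str(k): v for k, v in dr.histogram_a.items()},
                "histogram_b": {str(k): v for k, v in dr.histogram_b.items()},
            }
        logger.info("synteny %s: %d blocks (%d rejected pairs)", stem, len(blocks), len(rejects))
    _json_dump(depth_ratios, emit(out / "depth_ratios.json"))
    manifest["stages"]["synteny"] = {
        "pairs": [f"{p['a']}--{p['b']}" for p in config.pairs],
        "depth_ratios": {k: v["ratio"] for k, v in depth_ratios.items()},
    }

    # --- Ks + mixture fits ---------------------------------------------
    ks_cfg = config.ks
    peak_by_species: dict[str, float] = {}
    ks_values: dict[str, list[float]] = {}
    for p in config.pairs:
        a, b = p["a"], p["b"]
        if not cds[a] or not cds[b]:
            continue
        rows, ks_by_pair = _pair_ks_table(blocks_by_pair[(a, b)], cds[a], cds[b], ks_cfg)
        stem = f"{a}--{b}"
        with open(emit(out / f"{stem}.ks.tsv"), "w") as fh:
            fh.write("gene_a\tgene_b\tblock\tS\tN\tSd\tNd\tks\tka\tsaturated\n")
            for row in rows:
                fh.write("\t".join("NA" if v is None else f"{v:.6g}" if isinstance(v, float) else str(v) for v in row) + "\n")
        for blk in blocks_by_pair[(a, b)]:
            blk.median_ks = ksrates.block_median_ks(blk, ks_by_pair)
        vals = [r[7] for r in rows if r[7] is not None]
        if a == b:
            ks_values[a] = vals
    fits = {}
    for sp_label, vals in sorted(ks_values.items()):
        try:
            model = ksrates.fit_peaks(
                vals, max_components=ks_cfg["max_components"],
                ks_min=ks_cfg["ks_min"], ks_max=ks_cfg["ks_max"],
                seed=config.seed, gamma_prior=ks_cfg["gamma_prior"],
            )
        except ValueError as exc:
            logger.warning("ksfit %s: %s", sp_label, exc)
            continue
        peak_by_species[sp_label] = model.gamma_peak_ks
        fits[sp_label] = {
            "n_components": model.n_components,
            "components": [
                {"weight": w, "mu": mu, "sigma": s} for w, mu, s in model.components
            ],
            "gamma_peak_ks": model.gamma_peak_ks,
            "bic": model.bic,
        }
    _json_dump(fits, emit(out / "ks_fits.json"))

    # --- rate correction + dating --------------------------------------
    correction = {}
    if reference in peak_by_species:
        ref_peak = peak_by_species[reference]
        for sp_label, peak in sorted(peak_by_species.items()):
            corrected, factor = ksrates.correct_rates(
                ks_values[sp_label], peak, ref_peak,
                species=sp_label, reference=reference,
            )
            with open(emit(out / f"{sp_label}.ks_corrected.tsv"), "w") as fh:
                fh.write("ks_corrected\n")
                for v in corrected:
                    fh.write(f"{v:.6g}\n")
            refit = ksrates.fit_peaks(
                corrected, max_components=ks_cfg["max_components"],
                ks_min=ks_cfg["ks_min"], ks_max=ks_cfg["ks_max"],
                seed=config.seed, gamma_prior=ks_cfg["gamma_prior"],
            )
            correction[sp_label] = {
                "factor": factor.factor,
                "gamma_peak_uncorrected": peak,
                "gamma_peak_corrected": refit.gamma_peak_ks,
            }
            if config.rate_r:
                correction[sp_label]["gamma_date_mya"] = ksrates.date_event(
                    refit.gamma_peak_ks, config.rate_r
                )
        _json_dump(correction, emit(out / "rate_correction.json"))
    manifest["stages"]["ks"] = {"fits": fits, "correction": correction}

    # --- retention ------------------------------------------------------
    ret_summary = {}
    for p in config.pairs:
        a, b = p["a"], p["b"]
        if a != reference or b == reference:
            continue
        blocks = blocks_by_pair[(a, b)]
        profs = retention_mod.retention_profile(
            genomes[a], blocks,
            window_size=config.retention["window"], step=config.retention["step"],
        )
        with open(emit(out / f"retention_{a}_in_{b}.tsv"), "w") as fh:
            fh.write("chromosome\tstart_rank\tend_rank\tn_genes\tn_retained\tfraction\n")
            for prof in profs:
                for (s, e, n, nr, frac) in prof.windows:
                    fh.write(f"{prof.chromosome}\t{s}\t{e}\t{n}\t{nr}\t{frac:.6g}\n")
        ret_summary[f"{a}_in_{b}"] = retention_mod.overall_retention(genomes[a], blocks)
    _json_dump(ret_summary, emit(out / "retention_summary.json"))
    manifest["stages"]["retention"] = ret_summary

    # --- karyotype ------------------------------------------------------
    cross = {
        (p["a"], p["b"]): p for p in config.pairs if p["a"] != p["b"]
    }
    kary_stats = {}
    if len(genomes) >= 3 and cross:
        kcfg = config.karyotype
        kary_blocks = {}
        for (a, b), p in sorted(cross.items()):
            pairs, _ = io_core.read_homolog_pairs(p["file"], genomes[a], genomes[b])
            anchors, _ = synteny.build_anchors(pairs, genomes[a], genomes[b])
            kary_blocks[(a, b)] = synteny.chain_anchors(
                anchors, max_gap=kcfg["chain_max_gap"],
                min_block_size=kcfg["chain_min_block"],
                gap_penalty=config.chain["gap_penalty"],
            )
        tree_text = None
        if config.tree:
            tree_path = Path(config.tree)
            tree_text = tree_path.read_text() if tree_path.exists() else config.tree
        block_set = partition_ancestral_blocks(
            kary_blocks, genomes,
            min_support=kcfg["min_support"], min_genes=kcfg["min_genes"],
        )
        graph = score_adjacencies(block_set, species_tree=tree_text)
        karyo = linearize_cars(graph)
        with open(emit(out / "cars.tsv"), "w") as fh:
            fh.write("car\tposition\tblock\torientation\tn_genes\n")
            for ci, car in enumerate(karyo.cars):
                for pos, (bid, orient) in enumerate(car):
                    fh.write(f"{ci}\t{pos}\t{bid}\t{orient}\t{block_set.block_n_genes[bid]}\n")
        with open(emit(out / "rearrangements.tsv"), "w") as fh:
            fh.write("species\tfusion\tfission\ttranslocation\tinversion\tunclassifiable\n")
            for sp_label in sorted(block_set.projections):
                s = classify_rearrangements(karyo, block_set.projections[sp_label])
                fh.write(
                    f"{sp_label}\t{s.fusion}\t{s.fission}\t{s.translocation}\t"
                    f"{s.inversion}\t{len(s.unclassifiable)}\n"
                )
        with open(emit(out / "painting.tsv"), "w") as fh:
            # each extant chromosome as a sequence of ancestral block colours
            car_of = {bid: ci for ci, car in enumerate(karyo.cars) for bid, _ in car}
            fh.write("species\tchromosome\tposition\tblock\tcar\torientation\n")
            for sp_label in sorted(block_set.projections):
                for chrom, lst in sorted(block_set.projections[sp_label].items()):
                    for pos, (bid, orient, *_rest) in enumerate(lst):
                        fh.write(f"{sp_label}\t{chrom}\t{pos}\t{bid}\t{car_of[bid]}\t{orient}\n")
        kary_stats = {
            "n_ancestral_blocks": len(block_set.block_ids),
            "n_cars": karyo.n_chromosomes,
            "n_dropped_segments": len(block_set.dropped),
        }
        logger.info("karyotype: %d CARs from %d blocks", karyo.n_chromosomes, len(block_set.block_ids))
    manifest["stages"]["karyotype"] = kary_stats

    for path in outputs:
        manifest["outputs"][path.name] = _sha256(path)
    _json_dump(manifest, out / "manifest.json")
    return manifest


def run_demo(out_dir, seed: int = 11) -> dict:
    """Simulate a small triplicated clade and run the full pipeline on the
    emitted fixture files."""
    from .simulate import SimulationConfig, simulate_clade, emit_fixtures

    out = Path(out_dir)
    fixtures = out / "fixtures"
    cfg = SimulationConfig(
        seed=seed, n_chromosomes=4, genes_per_chromosome=40,
        wgt=True, wgt_retention=0.4, tips=("pA", "pB", "pC"),
        rate_multipliers={"pA": 0.9, "pB": 1.0, "pC": 1.2},
        n_codons=150,
    )
    bundle = simulate_clade(cfg)
    emit_fixtures(bundle, fixtures, cross_pairs=True)
    tips = list(cfg.tips)
    pairs = [
        {"a": t, "b": t, "file": str(fixtures / f"{t}.pairs.tsv")} for t in tips
    ] + [
        {"a": a, "b": b, "file": str(fixtures / f"{a}--{b}.pairs.tsv")}
        for a, b in itertools.combinations(tips, 2)
    ]
    pipe_cfg = PipelineConfig.from_dict(
        {
            "seed": seed,
            "out_dir": str(out / "results"),
            "species": [
                {"label": t, "bed": str(fixtures / f"{t}.bed"),
                 "cds": str(fixtures / f"{t}.cds.fa")}
                for t in tips
            ],
            "pairs": pairs,
            "reference": "pB",
            "rate_r": 5.0e-9,
            "tree": "((pA,pB),pC);",
            "params": {"ks": {"max_components": 3}},
        }
    )
    return run_pipeline(pipe_cfg)
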