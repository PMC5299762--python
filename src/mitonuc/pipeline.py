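"""End-to-end orchestration: simulate/load → distances → MDS + NJ →
haplogroup calls → concordance → survey, with a reproducibility manifest.

A :class:`RunConfig` either embeds a :class:`~mitonuc.popsim.SimConfig`
(synthetic cohort) or points at input files (nuclear VCF, mtDNA VCF, panel,
haplogroup table) — exactly one of the two.  :func:`run` executes every
stage, writes each stage's outputs under the output directory, and returns
a manifest recording the config hash, seed and a SHA-256 checksum of every
output file; identical configs produce byte-identical outputs.  No stage
reads wall-clock time or environment state into any result file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .concord import concordance
from .embed import canonicalize_signs, classical_mds
from .gendist import pairwise_distance_matrix
from .haplocall import HaplogroupTree, HaplotypeCall, assign_haplogroup, macro_and_origin
from .njtree import neighbor_joining
from .popsim import SimConfig, simulate_cohort, write_cohort
from .survey import (
    DEFAULT_MIN_HG_DISTANCE,
    classify_matches,
    cluster_counts,
    discordant_sisters,
    haplogroup_counts,
)
from .variant_io import (
    GenotypeMatrix,
    load_default_haplogroup_tree,
    read_haplogroup_table,
    read_panel,
    read_vcf,
    write_newick,
)

logger = logging.getLogger("mitonuc.pipeline")

__all__ = ["RunConfig", "run", "demo_config", "calls_from_matrix"]

STAGES = (
    "simulate",
    "dist_nuclear",
    "dist_mtdna",
    "mds",
    "njtree",
    "haplocall",
    "concord",
    "survey",
)


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    outdir: Path
    simulate: SimConfig | None = None
    nuclear_vcf: Path | None = None
    mtdna_vcf: Path | None = None
    panel_path: Path | None = None
    haplogroup_table: Path | None = None
    mds_k: int = 2
    z_threshold: float = 3.0
    min_hg_distance: int = DEFAULT_MIN_HG_DISTANCE
    permutations: int = 0
    admixed_sources: dict[str, set[str]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        has_paths = any(
            p is not None for p in (self.nuclear_vcf, self.mtdna_vcf, self.panel_path)
        )
        if self.simulate is not None and has_paths:
            raise ValueError("give either a simulate block or input paths, not both")
        if self.simulate is None and not (
            self.nuclear_vcf and self.mtdna_vcf and self.panel_path
        ):
            raise ValueError(
                "need either a simulate block or all of nuclear_vcf, mtdna_vcf, panel_path"
            )
        if self.mds_k < 1:
            raise ValueError("mds_k must be >= 1")
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be positive")
        if self.min_hg_distance < 0:
            raise ValueError("min_hg_distance must be >= 0")
        if self.permutations < 0:
            raise ValueError("permutations must be >= 0")

    def config_dict(self) -> dict:
        d = {
            "mds_k": self.mds_k,
            "z_threshold": self.z_threshold,
            "min_hg_distance": self.min_hg_distance,
            "permutations": self.permutations,
            "admixed_sources": {k: sorted(v) for k, v in self.admixed_sources.items()},
            "seed": self.seed,
        }
        if self.simulate is not None:
            sim = self.simulate
            d["simulate"] = {
                "pops": sim.pops,
                "group_of_pop": sim.group_of_pop,
                "samples_per_pop": sim.samples_per_pop,
                "n_nuclear_sites": sim.n_nuclear_sites,
                "fst": sim.fst,
                "admix_dirichlet": sim.admix_dirichlet,
                "mt_freqs": sim.mt_freqs,
                "private_mut_rate": sim.private_mut_rate,
                "cross_mt_rate": sim.cross_mt_rate,
                "panel_mode": sim.panel_mode,
                "retained_sites": sim.retained_sites,
                "seed": sim.seed,
            }
        else:
            d["inputs"] = {
                "nuclear_vcf": str(self.nuclear_vcf),
                "mtdna_vcf": str(self.mtdna_vcf),
                "panel": str(self.panel_path),
                "haplogroup_table": str(self.haplogroup_table)
                if self.haplogroup_table
                else None,
            }
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.config_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    @classmethod
    def from_yaml(cls, path: str | Path, outdir: str | Path | None = None) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        sim = d.pop("simulate", None)
        if sim is not None:
            sim = SimConfig(**sim)
        admixed = {k: set(v) for k, v in d.pop("admixed_sources", {}).items()}
        if outdir is not None:
            d["outdir"] = outdir
        return cls(simulate=sim, admixed_sources=admixed, **d)


def demo_config(outdir: str | Path, seed: int = 0) -> RunConfig:
    """The bundled demo: 6 populations x 50 samples with planted mismatches."""
    ref = resources.files("mitonuc.data").joinpath("demo_config.yaml")
    with resources.as_file(ref) as p:
        cfg = RunConfig.from_yaml(p, outdir=outdir)
    cfg.seed = seed
    assert cfg.simulate is not None
    cfg.simulate.seed = seed
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def calls_from_matrix(
    Gm: GenotypeMatrix, tree: HaplogroupTree
) -> list[HaplotypeCall]:
    """Haplogroup calls for every sample of a haploid matrix."""
    if Gm.ploidy != 1:
        raise ValueError("haplogroup calling expects a haploid matrix")
    calls = []
    for i, sample in enumerate(Gm.samples):
        carried = Gm.dosage[i] == 1
        variants = {
            (s.pos, s.alt) for s, c in zip(Gm.sites, carried) if c
        }
        calls.append(assign_haplogroup(variants, tree, sample=sample))
    return calls


def run(config: RunConfig) -> dict:
    """Execute every stage; return (and write) the run manifest."""
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.config_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
    }

    def record(stage: str, paths: dict) -> None:
        manifest["stages"][stage] = {
            name: {"path": str(Path(p).name), "sha256": _sha256(Path(p))}
            for name, p in paths.items()
        }

    def timed(stage: str):
        t0 = time.perf_counter()

        def done() -> None:
            logger.info("stage %-12s %.2fs", stage, time.perf_counter() - t0)

        return done

    try:
        # --- stage: simulate / load -------------------------------------
        done = timed("simulate")
        if config.simulate is not None:
            hg_tree = (
                read_haplogroup_table(config.haplogroup_table)
                if config.haplogroup_table
                else load_default_haplogroup_tree()
            )
            Gn, Gm, truth, panel = simulate_cohort(config.simulate, hg_tree)
            cohort_dir = outdir / "cohort"
            paths = write_cohort(Gn, Gm, truth, panel, cohort_dir, config.simulate)
            record("simulate", {k: v for k, v in paths.items()})
        else:
            hg_tree = (
                read_haplogroup_table(config.haplogroup_table)
                if config.haplogroup_table
                else load_default_haplogroup_tree()
            )
            Gn = read_vcf(config.nuclear_vcf, ploidy=2)
            Gm = read_vcf(config.mtdna_vcf, ploidy=1)
            panel = read_panel(config.panel_path)
            record("simulate", {})
        done()

        # --- stage: distances -------------------------------------------
        done = timed("dist_nuclear")
        Dn = pairwise_distance_matrix(Gn)
        p_dn = outdir / "nuclear_dist_pairs.tsv"
        Dn.to_pair_tsv(p_dn)
        record("dist_nuclear", {"pairs": p_dn})
        done()

        done = timed("dist_mtdna")
        Dm = pairwise_distance_matrix(Gm)
        p_dm = outdir / "mtdna_dist_pairs.tsv"
        Dm.to_pair_tsv(p_dm)
        record("dist_mtdna", {"pairs": p_dm})
        done()

        # --- stage: MDS ---------------------------------------------------
        done = timed("mds")
        mds_paths = {}
        for name, D in (("nuclear", Dn), ("mtdna", Dm)):
            emb = classical_mds(D, k=config.mds_k)
            emb.coords = canonicalize_signs(emb.coords)
            p = outdir / f"mds_{name}.tsv"
            emb.to_tsv(p, panel=panel)
            mds_paths[name] = p
        record("mds", mds_paths)
        done()

        # --- stage: NJ tree (nuclear) --------------------------------------
        done = timed("njtree")
        tree = neighbor_joining(Dn)
        p_tree = outdir / "nuclear_tree.nwk"
        write_newick(tree, p_tree)
        record("njtree", {"newick": p_tree})
        done()

        # --- stage: haplogroup calls --------------------------------------
        done = timed("haplocall")
        calls = calls_from_matrix(Gm, hg_tree)
        rows = []
        for c in calls:
            macro, origin = macro_and_origin(c, hg_tree)
            rows.append(
                {
                    "sample": c.sample,
                    "haplogroup": c.haplogroup,
                    "macro": macro,
                    "origin": origin,
                    "score": c.score,
                    "n_private": c.n_private,
                }
            )
        p_calls = outdir / "haplogroup_calls.tsv"
        pd.DataFrame(rows).to_csv(p_calls, sep="\t", index=False, float_format="%.10g")
        record("haplocall", {"calls": p_calls})
        done()

        # --- stage: concordance -------------------------------------------
        done = timed("concord")
        conc = concordance(
            Dn,
            Dm,
            z_threshold=config.z_threshold,
            permutations=config.permutations,
            seed=config.seed,
        )
        p_pairs = outdir / "concordance_pairs.tsv"
        p_summ = outdir / "concordance_summary.json"
        conc.write(p_pairs, p_summ)
        record("concord", {"pairs": p_pairs, "summary": p_summ})
        done()

        # --- stage: survey -------------------------------------------------
        done = timed("survey")
        counts = haplogroup_counts(calls, panel)
        p_counts = outdir / "haplogroup_counts.tsv"
        counts.to_tsv(p_counts, tree=hg_tree)
        clus = cluster_counts(counts)
        p_order = outdir / "cluster_orders.json"
        Path(p_order).write_text(
            json.dumps(
                {
                    "row_order": list(map(str, clus["row_order"])),
                    "col_order": list(map(str, clus["col_order"])),
                },
                indent=2,
            )
            + "\n"
        )
        mism = classify_matches(
            counts,
            hg_tree,
            admixed_sources=config.admixed_sources,
            calls=calls,
            panel=panel,
        )
        p_mism = outdir / "mismatch_table.tsv"
        mism.to_tsv(p_mism)
        disc = discordant_sisters(
            tree, calls, hg_tree, min_hg_distance=config.min_hg_distance
        )
        p_disc = outdir / "discordant_pairs.tsv"
        disc.to_csv(p_disc, sep="\t", index=False, float_format="%.10g")
        record(
            "survey",
            {
                "counts": p_counts,
                "cluster_orders": p_order,
                "mismatch": p_mism,
                "discordant": p_disc,
            },
        )
        done()
    except Exception as exc:  # annotate stage failures with their stage
        completed = set(manifest["stages"])
        stage = next((s for s in STAGES if s not in completed), "unknown")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["summary"] = {
        "n_samples": Gn.n_samples,
        "n_pairs": conc.n_pairs,
        "rho": conc.rho,
        "n_outliers": int(len(conc.outliers)),
        "mismatch_fraction": mism.mismatch_fraction,
        "n_discordant_sisters": int(len(disc)),
    }
    p_manifest = outdir / "manifest.json"
    p_manifest.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
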