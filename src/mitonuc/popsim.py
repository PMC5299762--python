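"""Synthetic multi-population cohorts with planted nuclear-mito mismatches.

Stands in for a 1000 Genomes-style cohort: a diploid nuclear variant matrix
with hierarchical population structure, a haploid mtDNA matrix whose
haplogroups follow population-specific frequency vectors, and a ground-truth
table against which haplogroup calling and mismatch detection can be scored.

Nuclear model: Balding-Nichols drift.  Per site an ancestral frequency
p ~ Uniform(0.05, 0.95) is drawn, then each population's frequency

    p_pop ~ Beta(p (1-F)/F, (1-p) (1-F)/F)

so that E[p_pop] = p and Var(p_pop) = F p (1-p); F = 0 degenerates to
p_pop = p.  Unadmixed individuals draw dosages Binomial(2, p_pop); admixed
individuals first draw ancestry proportions from a Dirichlet, then draw
each of their two alleles from a population chosen by those weights.

mtDNA model: each sample's haplogroup is a categorical draw from its
population's frequency vector — except, with probability ``cross_mt_rate``
for unadmixed samples (or via a categorical draw over ancestry proportions
for admixed samples), the maternal lineage comes from a foreign group,
planting a nuclear-mitochondrial mismatch.  The haplotype is the union of
defining variants on the root-to-haplogroup path plus Poisson-many private
variants placed only at positions no tree branch uses, so planted
haplogroups stay uniquely recoverable.  A reduced panel mode masks all but
a retained site subset, emulating SNP-array (HGDP-style) resolution.

No recombination, linkage, selection or heteroplasmy is simulated.  All
randomness flows from the single integer seed in the config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .haplocall import HaplogroupTree
from .variant_io import (
    GenotypeMatrix,
    PopulationPanel,
    Site,
    write_panel,
    write_vcf,
)

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "balding_nichols_frequencies",
    "simulate_nuclear",
    "simulate_mtdna",
    "simulate_cohort",
    "write_cohort",
    "make_panel",
]

#: length of the simulated mitochondrial coordinate system (rCRS-like)
MT_LENGTH = 16569
_BASES = ("A", "C", "G", "T")


@dataclass
class SimConfig:
    """Declarative description of one synthetic cohort."""

    pops: list[str]
    group_of_pop: dict[str, str]
    samples_per_pop: int
    n_nuclear_sites: int
    fst: float | dict[str, float] = 0.1
    admix_dirichlet: dict[str, list[float]] = field(default_factory=dict)
    mt_freqs: dict[str, dict[str, float]] = field(default_factory=dict)
    private_mut_rate: float = 0.0
    cross_mt_rate: float = 0.0
    panel_mode: str = "full"
    retained_sites: list[int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.pops)) != len(self.pops):
            raise ValueError("duplicate population codes")
        missing = [p for p in self.pops if p not in self.group_of_pop]
        if missing:
            raise ValueError(f"populations without a group: {missing}")
        if self.samples_per_pop < 1:
            raise ValueError("samples_per_pop must be >= 1")
        if self.n_nuclear_sites < 1:
            raise ValueError("n_nuclear_sites must be >= 1")
        for pop in self.pops:
            f = self.fst_of(pop)
            if not 0.0 <= f < 1.0:
                raise ValueError(f"FST for {pop} must be in [0, 1), got {f}")
        if not 0.0 <= self.cross_mt_rate <= 1.0:
            raise ValueError("cross_mt_rate must be in [0, 1]")
        if self.private_mut_rate < 0:
            raise ValueError("private_mut_rate must be >= 0")
        if self.panel_mode not in ("full", "reduced"):
            raise ValueError(f"panel_mode must be full|reduced, got {self.panel_mode!r}")
        for pop, alpha in self.admix_dirichlet.items():
            if pop not in self.pops:
                raise ValueError(f"admixed pop {pop!r} not in pops")
            if len(alpha) != len(self.pops):
                raise ValueError(
                    f"admix_dirichlet[{pop}] needs one weight per population"
                )
            if any(a < 0 for a in alpha) or sum(alpha) <= 0:
                raise ValueError(f"admix_dirichlet[{pop}] must be non-negative, nonzero")
        for pop, freqs in self.mt_freqs.items():
            tot = sum(freqs.values())
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(f"mt_freqs[{pop}] sums to {tot}, expected 1")

    def fst_of(self, pop: str) -> float:
        if isinstance(self.fst, dict):
            return self.fst[pop]
        return self.fst

    @property
    def n_pops(self) -> int:
        return len(self.pops)

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for p in self.pops:
            g = self.group_of_pop[p]
            if g not in seen:
                seen.append(g)
        return seen

    def sample_names(self) -> list[str]:
        return [
            f"{pop}_{i:04d}"
            for pop in self.pops
            for i in range(self.samples_per_pop)
        ]

    def pop_of_samples(self) -> list[str]:
        return [pop for pop in self.pops for _ in range(self.samples_per_pop)]

    def to_yaml(self, path: str | Path) -> None:
        d = {
            "pops": list(self.pops),
            "group_of_pop": dict(self.group_of_pop),
            "samples_per_pop": self.samples_per_pop,
            "n_nuclear_sites": self.n_nuclear_sites,
            "fst": self.fst,
            "admix_dirichlet": {k: list(v) for k, v in self.admix_dirichlet.items()},
            "mt_freqs": {k: dict(v) for k, v in self.mt_freqs.items()},
            "private_mut_rate": self.private_mut_rate,
            "cross_mt_rate": self.cross_mt_rate,
            "panel_mode": self.panel_mode,
            "retained_sites": self.retained_sites,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Planted ground truth, one row per sample.

    Columns: sample, pop, group, ancestry_<pop> for each population
    (rows sum to 1), haplogroup, maternal_pop, maternal_origin_group,
    mismatch.  The mismatch flag is recomputable: it is True iff the
    maternal origin group differs from the group of the sample's majority
    nuclear-ancestry population (ties resolved to the lexicographically
    first group among the tied populations' groups).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        anc = self.ancestry_columns()
        if anc:
            sums = self.table[anc].sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-9):
                raise ValueError("ancestry proportions must sum to 1")

    def ancestry_columns(self) -> list[str]:
        return [c for c in self.table.columns if c.startswith("ancestry_")]

    def majority_group(self, group_of_pop: dict[str, str]) -> pd.Series:
        anc = self.table[self.ancestry_columns()].to_numpy()
        pops = [c[len("ancestry_") :] for c in self.ancestry_columns()]
        out = []
        for row in anc:
            mx = row.max()
            tied = [pops[i] for i in np.nonzero(row >= mx - 1e-12)[0]]
            out.append(min(group_of_pop[p] for p in tied))
        return pd.Series(out, index=self.table.index)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SyntheticTruth":
        return cls(pd.read_csv(path, sep="\t"))


def make_panel(config: SimConfig) -> PopulationPanel:
    samples = config.sample_names()
    pops = config.pop_of_samples()
    return PopulationPanel(
        pop_of=dict(zip(samples, pops)),
        group_of={s: config.group_of_pop[p] for s, p in zip(samples, pops)},
        pop_order=list(config.pops),
    )


def _derive_seed(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, stream)))


def balding_nichols_frequencies(
    p_anc: np.ndarray, fst: float, rng: np.random.Generator
) -> np.ndarray:
    """One population's site frequencies under Balding-Nichols drift.

    Beta(p(1-F)/F, (1-p)(1-F)/F) per site, so E = p and Var = F p (1-p);
    F = 0 bypasses the (degenerate) Beta and returns p unchanged.
    """
    if not 0.0 <= fst < 1.0:
        raise ValueError(f"FST must be in [0, 1), got {fst}")
    if fst == 0.0:
        return np.asarray(p_anc, dtype=float).copy()
    a = p_anc * (1 - fst) / fst
    b = (1 - p_anc) * (1 - fst) / fst
    return rng.beta(a, b)


def _dirichlet_with_zeros(alpha: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Dirichlet draw tolerating zero concentrations (zero weight there)."""
    alpha = np.asarray(alpha, dtype=float)
    out = np.zeros_like(alpha)
    nz = alpha > 0
    if nz.sum() == 1:
        out[nz] = 1.0
    else:
        out[nz] = rng.dirichlet(alpha[nz])
    return out


def simulate_nuclear(config: SimConfig) -> tuple[GenotypeMatrix, SyntheticTruth]:
    """Simulate the diploid nuclear matrix and the ancestry half of truth."""
    rng = _derive_seed(config.seed, 1)
    S = config.n_nuclear_sites
    K = config.n_pops
    p_anc = rng.uniform(0.05, 0.95, size=S)
    p_pop = np.empty((K, S))
    for k, pop in enumerate(config.pops):
        p_pop[k] = balding_nichols_frequencies(p_anc, config.fst_of(pop), rng)

    samples = config.sample_names()
    pops = config.pop_of_samples()
    n = len(samples)
    dosage = np.empty((n, S))
    ancestry = np.zeros((n, K))
    for i, (s, pop) in enumerate(zip(samples, pops)):
        k = config.pops.index(pop)
        alpha = config.admix_dirichlet.get(pop)
        if not alpha:
            ancestry[i, k] = 1.0
            dosage[i] = rng.binomial(2, p_pop[k])
        else:
            w = _dirichlet_with_zeros(np.asarray(alpha, dtype=float), rng)
            ancestry[i] = w
            src = rng.choice(K, size=(S, 2), p=w)
            freqs = p_pop[src, np.arange(S)[:, None]]
            dosage[i] = (rng.random((S, 2)) < freqs).sum(axis=1)

    sites = [Site("1", 1000 * (j + 1), "A", "G") for j in range(S)]
    G = GenotypeMatrix(samples=samples, sites=sites, dosage=dosage, ploidy=2)
    table = pd.DataFrame({"sample": samples, "pop": pops})
    table["group"] = [config.group_of_pop[p] for p in pops]
    for k, pop in enumerate(config.pops):
        table[f"ancestry_{pop}"] = ancestry[:, k]
    truth = SyntheticTruth(table)
    return G, truth


def _group_level_freqs(config: SimConfig) -> dict[str, dict[str, float]]:
    """Average haplogroup frequencies over the populations of each group."""
    out: dict[str, dict[str, float]] = {}
    for g in config.groups:
        members = [p for p in config.pops if config.group_of_pop[p] == g]
        acc: dict[str, float] = {}
        for p in members:
            for hg, f in config.mt_freqs[p].items():
                acc[hg] = acc.get(hg, 0.0) + f / len(members)
        out[g] = acc
    return out


def _draw_from_freqs(rng: np.random.Generator, freqs: dict[str, float]) -> str:
    labels = sorted(freqs)
    probs = np.array([freqs[l] for l in labels])
    return labels[rng.choice(len(labels), p=probs / probs.sum())]


def _site_for_variant(pos: int, alt: str) -> Site:
    ref = "A" if alt != "A" else "C"
    return Site("MT", pos, ref, alt)


def default_retained_sites(tree: HaplogroupTree) -> list[int]:
    """Macro-backbone positions used as the default reduced-panel retention.

    Keeps the defining variants of edges whose child node is the macro
    label of some node — the deep structure a sparse SNP array resolves —
    and drops everything else, emulating array- vs sequence-level calling.
    """
    backbone = set(tree.macro_map.values()) & tree.labels()
    keep: set[int] = set()
    for node in backbone:
        for pos, _ in tree.edge_variants.get(node, frozenset()):
            keep.add(pos)
        # include the path up to the root so backbone calls stay consistent
        for lab in tree.path_to_root(node):
            for pos, _ in tree.edge_variants.get(lab, frozenset()):
                keep.add(pos)
    return sorted(keep)


def simulate_mtdna(
    config: SimConfig,
    tree: HaplogroupTree,
    ancestry: SyntheticTruth | None = None,
) -> tuple[GenotypeMatrix, SyntheticTruth]:
    """Simulate the haploid mtDNA matrix and complete the truth table.

    ``ancestry`` is the truth table from :func:`simulate_nuclear`; when
    omitted the cohort must be unadmixed (all samples one-hot).  Admixed
    samples draw their maternal population from their own ancestry
    proportions (a single categorical draw — mtDNA is one lineage);
    unadmixed samples keep their own population except with probability
    ``cross_mt_rate``, when a uniformly chosen foreign group's frequency
    vector supplies the haplogroup.
    """
    for pop in config.pops:
        if pop not in config.mt_freqs:
            raise ValueError(f"mt_freqs missing for population {pop!r}")
    known = tree.labels()
    for pop, freqs in config.mt_freqs.items():
        for hg in freqs:
            if hg not in known:
                raise KeyError(
                    f"haplogroup {hg!r} in mt_freqs[{pop}] absent from tree"
                )
    if ancestry is None:
        if config.admix_dirichlet:
            raise ValueError("admixed config requires the nuclear ancestry truth")
        _, ancestry = simulate_nuclear_ancestry_only(config)
    table = ancestry.table.copy()

    rng = _derive_seed(config.seed, 2)
    samples = list(table["sample"])
    pops = list(table["pop"])
    group_freqs = _group_level_freqs(config)
    groups = config.groups

    tree_positions = tree.all_positions()
    free_positions = sorted(set(range(1, MT_LENGTH + 1)) - set(tree_positions))

    haplogroups: list[str] = []
    maternal_pops: list[str] = []
    maternal_groups: list[str] = []
    private_sets: list[list[int]] = []
    for i, (s, pop) in enumerate(zip(samples, pops)):
        own_group = config.group_of_pop[pop]
        if config.admix_dirichlet.get(pop):
            anc = np.array(
                [table.loc[i, f"ancestry_{p}"] for p in config.pops], dtype=float
            )
            k = rng.choice(config.n_pops, p=anc / anc.sum())
            mpop = config.pops[k]
            mgroup = config.group_of_pop[mpop]
            hg = _draw_from_freqs(rng, config.mt_freqs[mpop])
        elif config.cross_mt_rate > 0 and rng.random() < config.cross_mt_rate:
            foreign = [g for g in groups if g != own_group]
            if not foreign:
                raise ValueError("cross_mt_rate > 0 requires more than one group")
            mgroup = foreign[rng.choice(len(foreign))]
            mpop = mgroup  # lineage attributed to the group, not a single pop
            hg = _draw_from_freqs(rng, group_freqs[mgroup])
        else:
            mpop = pop
            mgroup = own_group
            hg = _draw_from_freqs(rng, config.mt_freqs[pop])
        n_priv = rng.poisson(config.private_mut_rate) if config.private_mut_rate else 0
        priv = sorted(
            rng.choice(len(free_positions), size=n_priv, replace=False)
        ) if n_priv else []
        haplogroups.append(hg)
        maternal_pops.append(mpop)
        maternal_groups.append(mgroup)
        private_sets.append([free_positions[j] for j in priv])

    # site universe: every tree position plus every private position drawn
    variant_alt: dict[int, str] = {}
    for vs in tree.edge_variants.values():
        for pos, alt in vs:
            variant_alt[pos] = alt
    for priv in private_sets:
        for pos in priv:
            variant_alt.setdefault(pos, "T")
    positions = sorted(variant_alt)
    col = {pos: j for j, pos in enumerate(positions)}

    dosage = np.zeros((len(samples), len(positions)))
    for i, (hg, priv) in enumerate(zip(haplogroups, private_sets)):
        for pos, _ in tree.cumulative_variants(hg):
            dosage[i, col[pos]] = 1.0
        for pos in priv:
            dosage[i, col[pos]] = 1.0

    sites = [_site_for_variant(pos, variant_alt[pos]) for pos in positions]
    G = GenotypeMatrix(samples=samples, sites=sites, dosage=dosage, ploidy=1)

    if config.panel_mode == "reduced":
        retained = (
            list(config.retained_sites)
            if config.retained_sites is not None
            else default_retained_sites(tree)
        )
        keep = [j for j, pos in enumerate(positions) if pos in set(retained)]
        G = G.subset_sites(np.array(keep, dtype=int))

    table["haplogroup"] = haplogroups
    table["maternal_pop"] = maternal_pops
    table["maternal_origin_group"] = maternal_groups
    truth = SyntheticTruth(table)
    majority = truth.majority_group(config.group_of_pop)
    table["mismatch"] = (table["maternal_origin_group"] != majority).to_numpy()
    return G, SyntheticTruth(table)


def simulate_nuclear_ancestry_only(
    config: SimConfig,
) -> tuple[None, SyntheticTruth]:
    """Truth table with one-hot ancestry for an unadmixed cohort (no genotypes)."""
    if config.admix_dirichlet:
        raise ValueError("ancestry-only shortcut is defined for unadmixed cohorts")
    samples = config.sample_names()
    pops = config.pop_of_samples()
    table = pd.DataFrame({"sample": samples, "pop": pops})
    table["group"] = [config.group_of_pop[p] for p in pops]
    for pop in config.pops:
        table[f"ancestry_{pop}"] = [1.0 if p == pop else 0.0 for p in pops]
    return None, SyntheticTruth(table)


def simulate_cohort(
    config: SimConfig, tree: HaplogroupTree
) -> tuple[GenotypeMatrix, GenotypeMatrix, SyntheticTruth, PopulationPanel]:
    """Nuclear + mtDNA matrices, completed truth, and the cohort panel."""
    Gn, truth_n = simulate_nuclear(config)
    Gm, truth = simulate_mtdna(config, tree, ancestry=truth_n)
    return Gn, Gm, truth, make_panel(config)


def write_cohort(
    nuclear: GenotypeMatrix,
    mtdna: GenotypeMatrix,
    truth: SyntheticTruth,
    panel: PopulationPanel,
    outdir: str | Path,
    config: SimConfig | None = None,
) -> dict[str, Path]:
    """Write the cohort as VCF + panel + truth TSV (+ config YAML)."""
    if nuclear.samples != mtdna.samples:
        raise ValueError("nuclear and mtDNA matrices list different samples")
    if list(truth.table["sample"]) != nuclear.samples:
        raise ValueError("truth table samples do not match the matrices")
    if set(panel.samples) != set(nuclear.samples):
        raise ValueError("panel samples do not match the matrices")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "nuclear_vcf": outdir / "nuclear.vcf",
        "mtdna_vcf": outdir / "mtdna.vcf",
        "panel": outdir / "panel.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_vcf(nuclear, paths["nuclear_vcf"])
    write_vcf(mtdna, paths["mtdna_vcf"])
    write_panel(panel, paths["panel"])
    truth.to_tsv(paths["truth"])
    if config is not None:
        paths["config"] = outdir / "sim_config.yaml"
        config.to_yaml(paths["config"])
    return paths
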