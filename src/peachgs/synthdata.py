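"""Synthetic genotype/phenotype panels with GWAS-relevant structure.

The generator emulates a diversity panel of a few hundred clonally propagated
fruit-tree accessions: biallelic SNPs on 8 chromosomes with distance-decaying
LD, mild population structure, quantitative traits driven by a handful of
QTNs at moderate heritability, a family of biochemically related traits that
share most of their QTNs (like the lactone block of peach aroma volatiles),
and qualitative traits controlled by a single major locus (like flesh color
or skin hairiness).

LD is produced by a first-order haplotype copying process: along each
chromosome an allele is copied from the previous marker with probability
``ld_rho`` and otherwise redrawn from the subpopulation allele frequency, so
adjacent-marker correlation decays geometrically with marker lag.
Population structure follows the Balding-Nichols model: subpopulation
frequencies are Beta-distributed around an ancestral frequency with variance
``fst * p * (1 - p)``, so Hudson's Fst estimator recovers ``fst_target``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genio import (
    BINOMIAL,
    GeneModel,
    GenotypeMatrix,
    PhenotypeTable,
    QUANTITATIVE,
    TRINOMIAL,
    write_gff3,
    write_phenotype_table,
    write_vcf,
)


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the genotype simulator.

    ``ld_rho`` is the per-adjacent-marker copy probability of the haplotype
    copying process (0 = linkage equilibrium); ``fst_target`` the
    Balding-Nichols differentiation between the ``n_subpops`` subpopulations;
    ``maf_floor`` the minimum realized minor allele frequency of emitted
    markers.
    """

    n_samples: int = 242
    n_chrom: int = 8
    markers_per_chrom: int = 2500
    ld_rho: float = 0.8
    n_subpops: int = 2
    fst_target: float = 0.1
    maf_floor: float = 0.05
    chrom_length_bp: int = 25_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_chrom, self.markers_per_chrom,
               self.n_subpops) < 1:
            raise SimConfigError("all counts must be >= 1")
        if self.markers_per_chrom < 2:
            raise SimConfigError("markers_per_chrom must be >= 2")
        if not 0.0 <= self.ld_rho < 1.0:
            raise SimConfigError("ld_rho must lie in [0, 1)")
        if not 0.0 <= self.fst_target < 0.5:
            raise SimConfigError("fst_target must lie in [0, 0.5)")
        if not 0.0 < self.maf_floor < 0.5:
            raise SimConfigError("maf_floor must lie in (0, 0.5)")
        if self.chrom_length_bp <= self.markers_per_chrom:
            raise SimConfigError("chrom_length_bp too small for marker count")


def assign_subpops(cfg: SimConfig) -> np.ndarray:
    """Deterministic subpopulation label per sample (contiguous blocks)."""
    return (np.arange(cfg.n_samples) * cfg.n_subpops) // cfg.n_samples


@dataclass
class TraitGenetics:
    """Genetic architecture of one simulated trait."""

    kind: str
    qtn_marker_ids: list[str]
    qtn_effects: np.ndarray
    h2_target: float
    penetrance: float = 1.0  # qualitative traits: P(phenotype matches genotype class)

    def __post_init__(self) -> None:
        self.qtn_effects = np.asarray(self.qtn_effects, dtype=float)
        if not 0.0 <= self.h2_target <= 1.0:
            raise SimConfigError("h2_target must lie in [0, 1]")
        if self.kind in (BINOMIAL, TRINOMIAL) and len(self.qtn_marker_ids) != 1:
            raise SimConfigError("qualitative traits need exactly one major locus")
        if len(self.qtn_marker_ids) != len(self.qtn_effects):
            raise SimConfigError("one effect per QTN required")


@dataclass
class TraitArchitecture:
    """QTN assignment for a set of traits, with shared-QTN groups."""

    traits: dict[str, TraitGenetics]
    shared_qtn_groups: dict[str, list[str]] = field(default_factory=dict)

    def validate_against(self, g: GenotypeMatrix) -> None:
        known = set(g.markers["id"])
        for name, tg in self.traits.items():
            missing = set(tg.qtn_marker_ids) - known
            if missing:
                raise SimConfigError(
                    f"trait {name!r} references unknown QTNs {sorted(missing)[:5]}"
                )


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Simulate a dosage matrix under the copying-process LD model.

    Markers carry 1-based positions strictly increasing within each
    chromosome; every emitted marker has realized MAF >= ``cfg.maf_floor``
    (markers drifting below the floor are repaired by flipping a minimal
    number of alleles, a perturbation confined to near-monomorphic markers).
    """
    rng = np.random.default_rng(cfg.seed)
    n, m_chr = cfg.n_samples, cfg.markers_per_chrom
    pops = assign_subpops(cfg)
    hap_pops = np.repeat(pops, 2)  # two haplotypes per sample

    dosage_cols: list[np.ndarray] = []
    marker_rows: list[tuple] = []
    idx = 0
    for c in range(cfg.n_chrom):
        chrom = f"chr{c + 1}"
        pos = np.sort(rng.choice(cfg.chrom_length_bp, size=m_chr, replace=False)) + 1
        # ancestral freqs away from the floor so the repair step is rare
        p_anc = rng.uniform(max(0.1, cfg.maf_floor * 1.5), 0.5, size=m_chr)
        if cfg.fst_target > 0 and cfg.n_subpops > 1:
            f = cfg.fst_target
            a = p_anc * (1 - f) / f
            b = (1 - p_anc) * (1 - f) / f
            p_sub = rng.beta(a[None, :].repeat(cfg.n_subpops, 0),
                             b[None, :].repeat(cfg.n_subpops, 0))
            p_sub = np.clip(p_sub, 0.01, 0.99)
        else:
            p_sub = np.tile(p_anc, (cfg.n_subpops, 1))

        hap = np.empty((2 * n, m_chr), dtype=np.int8)
        hap[:, 0] = rng.random(2 * n) < p_sub[hap_pops, 0]
        for j in range(1, m_chr):
            copy = rng.random(2 * n) < cfg.ld_rho
            fresh = rng.random(2 * n) < p_sub[hap_pops, j]
            hap[:, j] = np.where(copy, hap[:, j - 1], fresh)
        dose = hap[0::2] + hap[1::2]
        dosage_cols.append(dose.astype(float))
        for j in range(m_chr):
            marker_rows.append((f"rs{idx}", chrom, int(pos[j]), "A", "T"))
            idx += 1

    dosage = np.concatenate(dosage_cols, axis=1)
    _enforce_maf_floor(dosage, cfg.maf_floor, rng)
    markers = pd.DataFrame(marker_rows, columns=["id", "chrom", "pos", "ref", "alt"])
    sample_ids = [f"acc{i:04d}" for i in range(n)]
    return GenotypeMatrix(dosage=dosage, sample_ids=sample_ids, markers=markers)


def _enforce_maf_floor(dosage: np.ndarray, maf_floor: float,
                       rng: np.random.Generator) -> None:
    """Flip alleles in place so every column reaches the MAF floor."""
    n = dosage.shape[0]
    need = int(np.ceil(2 * n * maf_floor))
    alt_count = dosage.sum(axis=0).astype(int)
    for j in np.where(np.minimum(alt_count, 2 * n - alt_count) < need)[0]:
        k = alt_count[j]
        if k <= n:  # alt is minor: add alt alleles
            deficit = need - k
            candidates = np.where(dosage[:, j] < 2)[0]
            chosen = rng.choice(candidates, size=deficit, replace=False)
            dosage[chosen, j] += 1
        else:  # ref is minor: remove alt alleles
            deficit = need - (2 * n - k)
            candidates = np.where(dosage[:, j] > 0)[0]
            chosen = rng.choice(candidates, size=deficit, replace=False)
            dosage[chosen, j] -= 1


# ---------------------------------------------------------------------------
# Trait architecture
# ---------------------------------------------------------------------------

def simulate_architecture(genotypes: GenotypeMatrix, trait_specs: list[dict],
                          seed: int = 0) -> TraitArchitecture:
    """Assign QTNs and effects to a declarative list of trait specs.

    Each spec is a dict with keys ``name``, ``kind``, ``n_qtns``, ``h2`` and
    optionally ``group`` (shared-QTN group name), ``overlap`` (fraction of a
    group trait's QTNs drawn from the group's common core, default 1.0),
    ``effect_scale`` (multiplier on shared-core effects, default 1.0),
    ``effect_dist`` (``normal`` for standard-normal effect sizes, the
    default, or ``equal`` for unit-magnitude random-sign effects — the
    many-small-effects architecture where no single QTN dominates) and
    ``penetrance``.  Traits in one group share an identical core QTN subset;
    their remaining QTNs are private and mutually disjoint.  All QTNs are
    sampled without replacement.
    """
    names = [s["name"] for s in trait_specs]
    if len(set(names)) != len(names):
        raise SimConfigError("trait names duplicated")
    total_qtns = sum(int(s.get("n_qtns", 0)) for s in trait_specs)
    if total_qtns > genotypes.n_markers:
        raise SimConfigError("requested QTN count exceeds marker count")

    rng = np.random.default_rng(seed)
    marker_ids = genotypes.markers["id"].to_numpy()
    pool = list(rng.permutation(genotypes.n_markers))

    def draw(k: int) -> list[int]:
        taken, rest = pool[:k], pool[k:]
        pool[:] = rest
        return taken

    groups: dict[str, list[dict]] = {}
    for s in trait_specs:
        if s.get("group"):
            groups.setdefault(s["group"], []).append(s)

    def draw_effects(k: int, dist: str) -> np.ndarray:
        if dist == "equal":
            return rng.choice([-1.0, 1.0], size=k)
        if dist == "normal":
            return rng.standard_normal(k)
        raise SimConfigError(f"unknown effect_dist {dist!r}")

    core_idx: dict[str, list[int]] = {}
    core_effects: dict[str, np.ndarray] = {}
    for gname, members in groups.items():
        ks = {int(s["n_qtns"]) for s in members}
        if len(ks) != 1:
            raise SimConfigError(f"group {gname!r}: members must share n_qtns")
        k = ks.pop()
        overlap = float(members[0].get("overlap", 1.0))
        s_core = int(round(overlap * k))
        core_idx[gname] = draw(s_core)
        core_effects[gname] = draw_effects(
            s_core, members[0].get("effect_dist", "normal"))

    traits: dict[str, TraitGenetics] = {}
    for s in trait_specs:
        kind = s.get("kind", QUANTITATIVE)
        k = int(s.get("n_qtns", 0))
        dist = s.get("effect_dist", "normal")
        gname = s.get("group")
        if gname:
            core = core_idx[gname]
            private = draw(k - len(core))
            idxs = core + private
            effects = np.concatenate([
                core_effects[gname] * float(s.get("effect_scale", 1.0)),
                draw_effects(len(private), dist),
            ])
        else:
            idxs = draw(k)
            effects = draw_effects(k, dist)
        traits[s["name"]] = TraitGenetics(
            kind=kind,
            qtn_marker_ids=[str(marker_ids[i]) for i in idxs],
            qtn_effects=effects,
            h2_target=float(s.get("h2", 0.5)),
            penetrance=float(s.get("penetrance", 1.0)),
        )

    shared = {g: [str(marker_ids[i]) for i in idxs] for g, idxs in core_idx.items()}
    arch = TraitArchitecture(traits=traits, shared_qtn_groups=shared)
    arch.validate_against(genotypes)
    return arch


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(genotypes: GenotypeMatrix, arch: TraitArchitecture,
                        seed: int = 0) -> PhenotypeTable:
    """Simulate raw phenotypes from an architecture.

    Quantitative: ``y = sum(effect * dosage) + e`` with Gaussian noise scaled
    so the realized genetic-variance fraction matches ``h2_target``.
    Binomial: carrier threshold on the major-locus dosage (``dosage >= 1``).
    Trinomial: dosage classes 0/1/2 mapped to -1/0/1.  Qualitative phenotypes
    are flipped to another class with probability ``1 - penetrance``.
    """
    arch.validate_against(genotypes)
    columns: dict[str, np.ndarray] = {}
    kinds: dict[str, str] = {}
    for t_index, (name, tg) in enumerate(arch.traits.items()):
        rng = np.random.default_rng([seed, t_index])  # noise stream per trait
        if tg.kind == QUANTITATIVE:
            columns[name] = _quantitative_trait(genotypes, tg, rng, name)
        else:
            columns[name] = _qualitative_trait(genotypes, tg, rng)
        kinds[name] = tg.kind
    values = pd.DataFrame(columns, index=pd.Index(genotypes.sample_ids,
                                                  name="sample_id"))
    return PhenotypeTable(values=values, kinds=kinds)


def _quantitative_trait(g: GenotypeMatrix, tg: TraitGenetics,
                        rng: np.random.Generator, name: str) -> np.ndarray:
    h2 = tg.h2_target
    if len(tg.qtn_marker_ids) == 0 or h2 == 0.0:
        if h2 == 1.0:
            raise SimConfigError(f"trait {name!r}: h2=1 with zero QTNs is impossible")
        return rng.standard_normal(g.n_samples)
    z = g.dosage[:, g.marker_index(tg.qtn_marker_ids)]
    gv = z @ tg.qtn_effects
    var_g = gv.var()
    if var_g == 0:
        raise SimConfigError(f"trait {name!r}: genetic variance is zero")
    if h2 == 1.0:
        return gv
    noise_sd = np.sqrt(var_g * (1 - h2) / h2)
    return gv + rng.normal(0.0, noise_sd, size=g.n_samples)


def _qualitative_trait(g: GenotypeMatrix, tg: TraitGenetics,
                       rng: np.random.Generator) -> np.ndarray:
    dose = g.dosage[:, g.marker_index(tg.qtn_marker_ids)[0]]
    if tg.kind == BINOMIAL:
        y = (dose >= 1).astype(float)
        classes = np.array([0.0, 1.0])
    else:
        y = np.rint(dose) - 1.0
        classes = np.array([-1.0, 0.0, 1.0])
    if tg.penetrance < 1.0:
        flip = rng.random(len(y)) > tg.penetrance
        for i in np.where(flip)[0]:
            others = classes[classes != y[i]]
            y[i] = rng.choice(others)
    return y


# ---------------------------------------------------------------------------
# Fixture presets
# ---------------------------------------------------------------------------

_PRESETS = ("tiny", "paper_like")


def _tiny_spec() -> tuple[SimConfig, list[dict]]:
    cfg = SimConfig(n_samples=50, n_chrom=3, markers_per_chrom=100,
                    ld_rho=0.6, n_subpops=2, fst_target=0.1,
                    chrom_length_bp=2_000_000, seed=11)
    traits = [
        {"name": "aroma_a", "kind": QUANTITATIVE, "n_qtns": 5, "h2": 0.6,
         "group": "aroma", "overlap": 0.6},
        {"name": "aroma_b", "kind": QUANTITATIVE, "n_qtns": 5, "h2": 0.6,
         "group": "aroma", "overlap": 0.6},
        {"name": "skin_type", "kind": BINOMIAL, "n_qtns": 1, "h2": 1.0},
    ]
    return cfg, traits


def _paper_like_spec() -> tuple[SimConfig, list[dict]]:
    cfg = SimConfig(n_samples=242, n_chrom=8, markers_per_chrom=2500,
                    ld_rho=0.8, n_subpops=2, fst_target=0.1, seed=7)
    lactones = ["lactone_c6", "lactone_c8", "lactone_c10", "lactone_d10",
                "lactone_c12", "ester_hexenyl"]
    # equal-magnitude effects at 8 QTNs/trait put every family QTN at the
    # GWAS power boundary: rarely significant in any one trait's scan but
    # usually detected by at least one of the six relatives — the regime
    # where pooling markers across biosynthetically related traits pays off
    traits: list[dict] = [
        {"name": t, "kind": QUANTITATIVE, "n_qtns": 8, "h2": 0.6,
         "group": "lactone_family", "overlap": 0.6, "effect_dist": "equal"}
        for t in lactones
    ]
    traits += [
        {"name": "linalool", "kind": QUANTITATIVE, "n_qtns": 6, "h2": 0.5},
        {"name": "soluble_solids", "kind": QUANTITATIVE, "n_qtns": 20, "h2": 0.7},
        {"name": "flesh_color", "kind": BINOMIAL, "n_qtns": 1, "h2": 1.0,
         "penetrance": 0.97},
        {"name": "skin_hairiness", "kind": BINOMIAL, "n_qtns": 1, "h2": 1.0,
         "penetrance": 0.98},
        {"name": "fruit_shape", "kind": BINOMIAL, "n_qtns": 1, "h2": 1.0},
        {"name": "flower_type", "kind": BINOMIAL, "n_qtns": 1, "h2": 1.0},
        {"name": "pollen_sterility", "kind": BINOMIAL, "n_qtns": 1, "h2": 1.0},
        {"name": "fruit_texture", "kind": TRINOMIAL, "n_qtns": 1, "h2": 1.0},
    ]
    return cfg, traits


def synthetic_gene_models(g: GenotypeMatrix, spacing_bp: int = 40_000,
                          length_bp: int = 3_000) -> list[GeneModel]:
    """Tile synthetic gene models along each chromosome of a genotype map."""
    genes: list[GeneModel] = []
    for chrom, sub in g.markers.groupby("chrom", sort=False):
        span = int(sub["pos"].max())
        k = 0
        for start in range(1, span, spacing_bp):
            genes.append(GeneModel(id=f"gene_{chrom}_{k:04d}", chrom=str(chrom),
                                   start=start, end=start + length_bp - 1,
                                   strand="+" if k % 2 == 0 else "-"))
            k += 1
    return genes


def make_fixture_dataset(preset: str, out_dir, seed: int | None = None):
    """Generate a named fixture panel and persist it under ``out_dir``.

    Returns ``(GenotypeMatrix, PhenotypeTable, TraitArchitecture, gff_path)``.
    Files written: ``genotypes.vcf``, ``phenotypes.tsv``, ``genes.gff3``,
    ``manifest.json`` (counts, QTN assignment, seeds).
    """
    if preset == "tiny":
        cfg, trait_specs = _tiny_spec()
    elif preset == "paper_like":
        cfg, trait_specs = _paper_like_spec()
    else:
        raise ValueError(f"unknown preset {preset!r}; choose from {_PRESETS}")
    if seed is not None:
        cfg = SimConfig(**{**cfg.__dict__, "seed": seed})

    g = simulate_genotypes(cfg)
    arch = simulate_architecture(g, trait_specs, seed=cfg.seed + 1)
    pheno = simulate_phenotypes(g, arch, seed=cfg.seed + 2)
    genes = synthetic_gene_models(g)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gff_path = out / "genes.gff3"
    write_vcf(g, out / "genotypes.vcf")
    write_phenotype_table(pheno, out / "phenotypes.tsv")
    write_gff3(genes, gff_path)
    manifest = {
        "preset": preset,
        "seed": cfg.seed,
        "n_samples": g.n_samples,
        "n_markers": g.n_markers,
        "n_genes": len(genes),
        "traits": {
            name: {"kind": tg.kind, "h2_target": tg.h2_target,
                   "qtn_marker_ids": list(tg.qtn_marker_ids)}
            for name, tg in arch.traits.items()
        },
        "shared_qtn_groups": arch.shared_qtn_groups,
        "trait_kinds": {name: tg.kind for name, tg in arch.traits.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    with open(out / "phenotypes.schema.json", "w") as fh:
        json.dump({name: {"kind": tg.kind} for name, tg in arch.traits.items()},
                  fh, indent=1)
    return g, pheno, arch, gff_path
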