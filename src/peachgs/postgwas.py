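"""Post-GWAS interpretation: candidate genes, hotspots, genotype-combination
summaries, trait/expression correlations and diagnostic-marker concordance.

Coordinates are 1-based inclusive throughout (VCF/GFF3 convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .genio import GeneModel, GenotypeMatrix, PhenotypeTable, QUANTITATIVE

logger = logging.getLogger("peachgs")


@dataclass
class HotspotRegion:
    """A genomic window harboring significant SNPs for >= 2 distinct traits."""

    chrom: str
    start: int
    end: int
    snp_ids: list[str]
    traits: list[str]

    def __post_init__(self) -> None:
        if len(set(self.traits)) < 2:
            raise ValueError("hotspot requires >= 2 distinct traits")
        if self.start > self.end:
            raise ValueError("hotspot start > end")


# ---------------------------------------------------------------------------
# Trait correlations
# ---------------------------------------------------------------------------

def trait_correlation_matrix(p: PhenotypeTable, min_obs: int = 3):
    """Pairwise-complete Pearson correlations between coded traits.

    Returns ``(r, pvals)`` DataFrames with unit diagonal.  Traits with fewer
    than ``min_obs`` observations are excluded with a warning.
    """
    numeric = p.values.apply(pd.to_numeric, errors="raise")
    counts = numeric.notna().sum()
    drop = list(counts.index[counts < min_obs])
    if drop:
        logger.warning("trait_correlation_matrix: excluding %s (<%d observations)",
                       drop, min_obs)
        numeric = numeric.drop(columns=drop)
    traits = list(numeric.columns)
    k = len(traits)
    r = np.eye(k)
    pv = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            pair = numeric.iloc[:, [i, j]].dropna()
            if len(pair) < min_obs:
                r[i, j] = r[j, i] = np.nan
                pv[i, j] = pv[j, i] = np.nan
                continue
            rr, pp = stats.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
            r[i, j] = r[j, i] = rr
            pv[i, j] = pv[j, i] = pp
    idx = pd.Index(traits)
    return (pd.DataFrame(r, index=idx, columns=idx),
            pd.DataFrame(pv, index=idx, columns=idx))


# ---------------------------------------------------------------------------
# Candidate genes
# ---------------------------------------------------------------------------

def _snp_positions(marker_map, snp_ids) -> pd.DataFrame:
    """(id, chrom, pos) rows for the requested SNP ids."""
    if isinstance(marker_map, GenotypeMatrix):
        marker_map = marker_map.markers
    table = marker_map.set_index("id").loc[list(snp_ids)]
    return table.reset_index()[["id", "chrom", "pos"]]


def candidate_genes(panel, genes: list[GeneModel], marker_map,
                    flank_bp: int = 100_000) -> dict[str, list[GeneModel]]:
    """Genes overlapping the +/- ``flank_bp`` window around each panel SNP.

    ``panel`` is a MarkerPanel or an iterable of SNP ids; ``marker_map``
    supplies SNP coordinates.  A gene is kept when its span [start, end]
    overlaps [pos - flank, pos + flank] (inclusive bounds, clipped at 1) —
    overlap, not containment, so genes straddling the window edge count.
    Genes per SNP are sorted by distance from the SNP.  SNPs on chromosomes
    absent from the annotation get an empty list and a warning.
    """
    snp_ids = getattr(panel, "marker_ids", panel)
    snps = _snp_positions(marker_map, snp_ids)
    trees: dict[str, IntervalTree] = {}
    for gm in genes:
        trees.setdefault(gm.chrom, IntervalTree()).addi(gm.start, gm.end + 1, gm)
    out: dict[str, list[GeneModel]] = {}
    for _, row in snps.iterrows():
        chrom, pos = str(row["chrom"]), int(row["pos"])
        tree = trees.get(chrom)
        if tree is None:
            logger.warning("candidate_genes: chromosome %s absent from annotation",
                           chrom)
            out[row["id"]] = []
            continue
        lo = max(1, pos - flank_bp)
        hi = pos + flank_bp
        hits = [iv.data for iv in tree.overlap(lo, hi + 1)]

        def distance(gm: GeneModel) -> int:
            if gm.start <= pos <= gm.end:
                return 0
            return min(abs(pos - gm.start), abs(pos - gm.end))

        out[row["id"]] = sorted(hits, key=lambda gm: (distance(gm), gm.start, gm.id))
    return out


# ---------------------------------------------------------------------------
# Hotspots
# ---------------------------------------------------------------------------

def detect_hotspots(panels, marker_map, window_bp: int = 300_000) -> list[HotspotRegion]:
    """Multi-trait hotspot regions by single-linkage clustering.

    Significant SNPs from all panels are clustered per chromosome with a
    maximum gap of ``window_bp`` between consecutive members (strict: a gap
    larger than the window breaks the cluster); clusters containing SNPs from
    at least two distinct traits are reported with bounds at the min/max
    member positions.
    """
    if len(panels) < 2:
        raise ValueError("need at least 2 trait panels")
    rows = []
    for panel in panels:
        snps = _snp_positions(marker_map, panel.marker_ids)
        for _, row in snps.iterrows():
            rows.append((str(row["chrom"]), int(row["pos"]), str(row["id"]),
                         panel.trait))
    if not rows:
        return []
    table = pd.DataFrame(rows, columns=["chrom", "pos", "id", "trait"])
    regions: list[HotspotRegion] = []
    for chrom, sub in table.groupby("chrom", sort=True):
        sub = sub.sort_values(["pos", "id"])
        cluster: list[tuple] = []
        prev = None
        for tup in sub.itertuples(index=False):
            if prev is not None and tup.pos - prev > window_bp:
                regions.extend(_close_cluster(chrom, cluster))
                cluster = []
            cluster.append(tup)
            prev = tup.pos
        regions.extend(_close_cluster(chrom, cluster))
    return regions


def _close_cluster(chrom: str, cluster: list) -> list[HotspotRegion]:
    traits = sorted({t.trait for t in cluster})
    if len(traits) < 2:
        return []
    return [HotspotRegion(
        chrom=chrom,
        start=min(t.pos for t in cluster),
        end=max(t.pos for t in cluster),
        snp_ids=sorted({t.id for t in cluster}),
        traits=traits,
    )]


# ---------------------------------------------------------------------------
# Genotype-combination summaries
# ---------------------------------------------------------------------------

def _combo_strings(g: GenotypeMatrix, marker_ids: list[str]) -> pd.Series:
    """Per-sample allele-pair key, markers ordered by id (e.g. 'TT/GA')."""
    order = sorted(marker_ids)
    cols = g.marker_index(order)
    parts = []
    for c in cols:
        ref = str(g.markers.loc[c, "ref"])
        alt = str(g.markers.loc[c, "alt"])
        coding = {0.0: ref + ref, 1.0: ref + alt, 2.0: alt + alt}
        parts.append([coding.get(d, "..") for d in g.dosage[:, c]])
    combos = ["/".join(t) for t in zip(*parts)]
    return pd.Series(combos, index=g.sample_ids, name="combo")


def genotype_combo_percentage(g: GenotypeMatrix, pheno: PhenotypeTable,
                              trait: str, marker_ids: list[str],
                              raw_values: pd.Series | None = None) -> pd.DataFrame:
    """Phenotype summary per observed genotype combination at the given markers.

    Quantitative traits: ``100 * mean(phenotype | combination) / overall
    mean``; requires a raw (non-normalized) scale — pass ``raw_values`` if the
    table is normalized (the ratio is undefined at mean 0).  Qualitative
    traits: percentage of samples in the combination carrying that
    combination's modal phenotype class.  Returns combo, count, percent.
    """
    combos = _combo_strings(g, marker_ids)
    kind = pheno.kinds[trait]
    if kind == QUANTITATIVE and pheno.normalized:
        if raw_values is None:
            raise ValueError(
                "normalized quantitative trait: pass raw_values on the original scale"
            )
        y = raw_values.reindex(g.sample_ids)
    else:
        y = pd.Series(np.asarray(pheno.values[trait]).astype(float),
                      index=pheno.sample_ids).reindex(g.sample_ids)
    frame = pd.DataFrame({"combo": combos, "y": y}).dropna()

    rows = []
    if kind == QUANTITATIVE:
        overall = frame["y"].mean()
        if overall == 0:
            raise ValueError("overall mean is zero; percentages undefined")
        for combo, grp in frame.groupby("combo", sort=True):
            rows.append({"combo": combo, "n": len(grp),
                         "percent": 100.0 * grp["y"].mean() / overall})
    else:
        for combo, grp in frame.groupby("combo", sort=True):
            modal = grp["y"].mode().iloc[0]
            rows.append({"combo": combo, "n": len(grp),
                         "percent": 100.0 * (grp["y"] == modal).mean(),
                         "modal_class": modal})
    return pd.DataFrame(rows)


def diagnostic_marker_accuracy(combos: pd.Series, phenotype: pd.Series,
                               rule: dict):
    """Concordance between diagnostic genotype combinations and phenotype class.

    ``rule`` maps combination string -> predicted class.  Samples with
    combinations outside the rule are excluded and counted (mirroring the
    exclusion of wild relatives and unique combinations in marker-validation
    panels).  Returns ``(accuracy, confusion, n_excluded)`` where accuracy is
    concordant / classified and confusion is a predicted x observed table.
    """
    frame = pd.DataFrame({"combo": combos, "obs": phenotype}).dropna()
    if frame.empty:
        raise ValueError("empty input")
    known = frame["combo"].isin(rule)
    n_excluded = int((~known).sum())
    frame = frame[known]
    if frame.empty:
        raise ValueError("no sample matches the diagnostic rule")
    frame["pred"] = frame["combo"].map(rule)
    accuracy = float((frame["pred"] == frame["obs"]).mean())
    confusion = pd.crosstab(frame["pred"], frame["obs"],
                            rownames=["predicted"], colnames=["observed"])
    return accuracy, confusion, n_excluded


# ---------------------------------------------------------------------------
# Expression-trait correlation
# ---------------------------------------------------------------------------

def expression_trait_correlation(expr: pd.DataFrame, content: pd.Series,
                                 alpha: float = 0.05) -> pd.DataFrame:
    """Pearson correlation of each gene's expression trajectory with a
    compound-content trajectory over shared developmental stages.

    Returns per-gene r, two-sided p and a significance flag at ``alpha``.
    Genes with constant expression get nan r and are flagged, not erred.
    """
    stages = [s for s in expr.columns if s in set(content.index)]
    if len(stages) < 3:
        raise ValueError("need at least 3 shared stages")
    y = content.loc[stages].to_numpy(dtype=float)
    rows = []
    for gene, row in expr[stages].iterrows():
        x = row.to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append({"gene": gene, "r": np.nan, "p": np.nan,
                         "significant": False, "constant": True})
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"gene": gene, "r": r, "p": p,
                     "significant": bool(p < alpha), "constant": False})
    return pd.DataFrame(rows).set_index("gene")
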