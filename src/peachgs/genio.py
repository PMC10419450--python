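"""Genotype/phenotype containers, file I/O, filtering and trait coding.

Genotypes are held as minor-allele dosages (0/1/2, ``nan`` for missing) in a
samples x markers matrix, the layout used by rrBLUP-style genomic prediction
and by the association scans in :mod:`peachgs.gwas`.  Quantitative traits are
z-scored to mean 0 / variance 1; qualitative traits are coded {0,1} (binomial)
or {-1,0,1} (trinomial) according to a declared level order — trait kinds are
never guessed from the data.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("peachgs")

QUANTITATIVE = "quantitative"
BINOMIAL = "binomial"
TRINOMIAL = "trinomial"
TRAIT_KINDS = (QUANTITATIVE, BINOMIAL, TRINOMIAL)

#: codes for qualitative traits, by kind, in declared level order
QUAL_CODES = {BINOMIAL: (0.0, 1.0), TRINOMIAL: (-1.0, 0.0, 1.0)}


class GenotypeError(ValueError):
    """Malformed or inconsistent genotype data."""


class PhenotypeError(ValueError):
    """Malformed or inconsistent phenotype data."""


@dataclass(frozen=True)
class MarkerInfo:
    """A single biallelic SNP: identifier, position and alleles."""

    id: str
    chrom: str
    pos: int  # 1-based bp
    ref: str = "A"
    alt: str = "T"


@dataclass
class GenotypeMatrix:
    """Samples x markers minor-allele dosage matrix with a marker map.

    Parameters
    ----------
    dosage
        ``(n_samples, n_markers)`` float array with entries in {0, 1, 2}
        (``nan`` for missing; fractional values after mean imputation).
    sample_ids
        Unique sample labels, one per row.
    markers
        Marker map with columns ``id, chrom, pos, ref, alt``; ``pos`` is
        1-based.
    """

    dosage: np.ndarray
    sample_ids: list[str]
    markers: pd.DataFrame
    missing_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2:
            raise GenotypeError("dosage must be a 2-D samples x markers array")
        n, m = self.dosage.shape
        if n != len(self.sample_ids):
            raise GenotypeError(f"{n} dosage rows but {len(self.sample_ids)} sample ids")
        if m != len(self.markers):
            raise GenotypeError(f"{m} dosage columns but {len(self.markers)} markers")
        if len(set(self.sample_ids)) != n:
            raise GenotypeError("duplicate sample ids")
        ids = self.markers["id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise GenotypeError(f"duplicate marker id {dup!r}")
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.dosage)
        self.markers = self.markers.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    def maf(self) -> np.ndarray:
        """Per-marker minor allele frequency over non-missing calls (folded to <= 0.5)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-nan columns
            p = np.nanmean(self.dosage, axis=0) / 2.0
        return np.minimum(p, 1.0 - p)

    def subset_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix keeping the marker columns in ``index`` (order preserved)."""
        return GenotypeMatrix(
            dosage=self.dosage[:, index],
            sample_ids=list(self.sample_ids),
            markers=self.markers.iloc[index].reset_index(drop=True),
            missing_mask=self.missing_mask[:, index],
        )

    def subset_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix keeping the sample rows in ``index`` (order preserved)."""
        return GenotypeMatrix(
            dosage=self.dosage[index, :],
            sample_ids=[self.sample_ids[i] for i in np.atleast_1d(index)],
            markers=self.markers.copy(),
            missing_mask=self.missing_mask[index, :],
        )

    def marker_index(self, marker_ids) -> np.ndarray:
        """Column indices of the given marker ids (error on unknown ids)."""
        lookup = pd.Index(self.markers["id"])
        idx = lookup.get_indexer(list(marker_ids))
        if (idx < 0).any():
            missing = [m for m, i in zip(marker_ids, idx) if i < 0]
            raise GenotypeError(f"unknown marker ids: {missing[:5]}")
        return idx


@dataclass
class PhenotypeTable:
    """Samples x traits table with per-trait kind and coding state.

    ``values`` holds raw observations (floats for quantitative traits,
    arbitrary labels for qualitative ones) until :func:`normalize_traits`
    codes them; ``normalized`` flips to True afterwards.
    """

    values: pd.DataFrame  # index = sample ids, columns = trait names
    kinds: dict[str, str]
    level_orders: dict[str, list] = field(default_factory=dict)
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise PhenotypeError(f"duplicated sample row {dup!r}")
        for trait in self.values.columns:
            kind = self.kinds.get(trait)
            if kind not in TRAIT_KINDS:
                raise PhenotypeError(
                    f"trait {trait!r} has undeclared or invalid kind {kind!r}; "
                    f"kinds must be one of {TRAIT_KINDS}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def trait_names(self) -> list[str]:
        return list(self.values.columns)

    def trait_vector(self, trait: str) -> np.ndarray:
        """Numeric values for one trait (nan = missing); requires coded/numeric data."""
        col = self.values[trait]
        return pd.to_numeric(col, errors="raise").to_numpy(dtype=float)


@dataclass(frozen=True)
class GeneModel:
    """A gene feature from a GFF3 annotation (1-based inclusive coordinates)."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    annotation: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.id}: start {self.start} > end {self.end}")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF 4.x file into a dosage matrix.

    GT fields are coded 0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2, ./. -> missing.
    Multiallelic records are rejected and counted in a warning; marker order
    is preserved as in the file.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows: list[np.ndarray] = []
    markers: list[tuple] = []
    seen: set[tuple] = set()
    n_multi = 0
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        key = (var.CHROM, var.POS, var.REF, var.ALT[0])
        if key in seen:
            raise GenotypeError(
                f"duplicate record at {var.CHROM}:{var.POS} {var.REF}>{var.ALT[0]}"
            )
        seen.add(key)
        gt = np.array([g[:2] for g in var.genotypes], dtype=float)  # (n, 2) alleles
        dose = gt.sum(axis=1)
        dose[(gt < 0).any(axis=1)] = np.nan
        rows.append(dose)
        mid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        markers.append((mid, var.CHROM, var.POS, var.REF, var.ALT[0]))
    vcf.close()
    if n_multi:
        logger.warning("read_vcf: rejected %d multiallelic records", n_multi)
    dosage = np.column_stack(rows) if rows else np.empty((len(samples), 0))
    frame = pd.DataFrame(markers, columns=["id", "chrom", "pos", "ref", "alt"])
    return GenotypeMatrix(dosage=dosage, sample_ids=samples, markers=frame)


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write a GenotypeMatrix as a minimal VCF 4.2 file (GT only).

    Requires integer dosages (imputed fractional values cannot be expressed
    as genotypes) and positions strictly increasing within each chromosome
    block.
    """
    obs = g.dosage[~np.isnan(g.dosage)]
    if obs.size and not np.all(np.isin(obs, (0.0, 1.0, 2.0))):
        raise GenotypeError("write_vcf requires integer dosages in {0,1,2}")
    last: dict[str, int] = {}
    for chrom, pos in zip(g.markers["chrom"], g.markers["pos"]):
        if chrom in last and pos <= last[chrom]:
            raise GenotypeError(
                f"positions not strictly increasing on {chrom} at {pos}"
            )
        last[chrom] = int(pos)
    gt_repr = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(g.markers["chrom"]):
            sub = g.markers.loc[g.markers["chrom"] == chrom, "pos"]
            fh.write(f"##contig=<ID={chrom},length={int(sub.max()) + 1000}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.sample_ids)
            + "\n"
        )
        for j, row in g.markers.iterrows():
            calls = [
                "./." if np.isnan(d) else gt_repr[d] for d in g.dosage[:, j]
            ]
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{row['id']}\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def read_phenotype_table(path, kinds: dict[str, str] | None = None,
                         schema_path=None,
                         level_orders: dict[str, list] | None = None) -> PhenotypeTable:
    """Read a TSV phenotype table (``sample_id`` column + one column per trait).

    Trait kinds come from ``kinds`` or a JSON sidecar ``schema_path`` mapping
    trait name to kind (and optionally ``levels``); they are never inferred.
    Empty cells are missing values.  Non-numeric entries in a quantitative
    trait raise with the offending row/column.
    """
    level_orders = dict(level_orders or {})
    if schema_path is not None:
        with open(schema_path) as fh:
            schema = json.load(fh)
        kinds = {t: s["kind"] if isinstance(s, dict) else s for t, s in schema.items()}
        for t, s in schema.items():
            if isinstance(s, dict) and "levels" in s:
                level_orders.setdefault(t, list(s["levels"]))
    if kinds is None:
        raise PhenotypeError("trait kinds must be declared (kinds= or schema_path=)")
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise PhenotypeError("phenotype table must have a 'sample_id' column")
    df = df.set_index("sample_id")
    for trait in df.columns:
        if kinds.get(trait) == QUANTITATIVE:
            col = pd.to_numeric(df[trait], errors="coerce")
            bad = col.isna() & df[trait].notna()
            if bad.any():
                row = df.index[bad][0]
                raise PhenotypeError(
                    f"non-numeric value {df.loc[row, trait]!r} in quantitative "
                    f"trait {trait!r}, sample {row!r}"
                )
            df[trait] = col
    return PhenotypeTable(values=df, kinds={t: kinds[t] for t in df.columns},
                          level_orders=level_orders)


def normalize_traits(p: PhenotypeTable) -> PhenotypeTable:
    """Normalize/code a phenotype table (idempotent).

    Quantitative traits are z-scored to mean 0, variance 1 over non-missing
    entries; binomial traits are coded {0,1} and trinomial traits {-1,0,1}
    following the declared level order for each trait.
    """
    if p.normalized:
        return replace(p, values=p.values.copy())
    out = p.values.copy()
    for trait in out.columns:
        kind = p.kinds[trait]
        if kind == QUANTITATIVE:
            x = pd.to_numeric(out[trait], errors="raise").astype(float)
            mu = x.mean()
            sd = x.std(ddof=0)
            if not np.isfinite(sd) or sd == 0:
                raise PhenotypeError(f"zero-variance quantitative trait {trait!r}")
            out[trait] = (x - mu) / sd
        else:
            codes = QUAL_CODES[kind]
            observed = out[trait].dropna()
            levels = p.level_orders.get(trait)
            if levels is None:
                uniq = set(observed.unique())
                if uniq <= set(codes):  # already coded
                    out[trait] = out[trait].astype(float)
                    continue
                raise PhenotypeError(
                    f"qualitative trait {trait!r} needs a declared level order"
                )
            if len(levels) != len(codes):
                raise PhenotypeError(
                    f"trait {trait!r}: {len(levels)} levels declared for a "
                    f"{kind} trait (need {len(codes)})"
                )
            unknown = set(observed.unique()) - set(levels)
            if unknown:
                raise PhenotypeError(f"trait {trait!r}: unknown levels {unknown}")
            mapping = dict(zip(levels, codes))
            out[trait] = out[trait].map(lambda v: mapping.get(v, np.nan))
        out[trait] = out[trait].astype(float)
    return PhenotypeTable(values=out, kinds=dict(p.kinds),
                          level_orders=dict(p.level_orders), normalized=True)


def write_phenotype_table(p: PhenotypeTable, path) -> None:
    """Write a phenotype table as TSV (header: sample_id then trait names)."""
    p.values.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Genotype encoding / filtering
# ---------------------------------------------------------------------------

def encode_and_impute(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages with the per-marker mean of observed calls.

    Markers that are missing in every sample are dropped (a warning reports
    the count).  The original missingness mask is retained on the result.
    """
    dosage = g.dosage.copy()
    mask = np.isnan(dosage)
    all_missing = mask.all(axis=0)
    if all_missing.any():
        logger.warning("encode_and_impute: dropping %d all-missing markers",
                       int(all_missing.sum()))
    keep = ~all_missing
    dosage, mask = dosage[:, keep], mask[:, keep]
    col_mean = np.nanmean(np.where(mask, np.nan, dosage), axis=0)
    dosage[mask] = np.take(col_mean, np.where(mask)[1])
    return GenotypeMatrix(
        dosage=dosage,
        sample_ids=list(g.sample_ids),
        markers=g.markers.loc[keep].reset_index(drop=True),
        missing_mask=mask,
    )


def maf_filter(g: GenotypeMatrix, min_maf: float) -> GenotypeMatrix:
    """Drop markers with minor allele frequency below ``min_maf`` (order kept)."""
    if not 0.0 <= min_maf <= 0.5:
        raise ValueError("min_maf must lie in [0, 0.5]")
    keep = np.where(g.maf() >= min_maf)[0]
    return g.subset_markers(keep)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path) -> list[GeneModel]:
    """Read gene features from a GFF3 file; non-gene feature types are skipped."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", keep_order=True,
                            merge_strategy="create_unique")
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene", order_by=None):
        gid = feat.id or f"{feat.seqid}:{feat.start}"
        note = ",".join(feat.attributes.get("Note", []))
        genes.append(GeneModel(id=gid, chrom=feat.seqid, start=feat.start,
                               end=feat.end, strand=feat.strand or "+",
                               annotation=note))
    return genes


def write_gff3(genes: list[GeneModel], path) -> None:
    """Write gene models as a minimal GFF3 file."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gm in genes:
            note = f";Note={gm.annotation}" if gm.annotation else ""
            fh.write(
                f"{gm.chrom}\tpeachgs\tgene\t{gm.start}\t{gm.end}\t.\t"
                f"{gm.strand}\t.\tID={gm.id}{note}\n"
            )
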