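"""Gene models, frequency panels, and their on-disk TSV/VCF dialects.

A *gene model* is a set of cis-regulatory variants with signed linear effect
sizes on expression (the weights exported by expression-prediction models such
as JTI/PrediXcan), plus training metadata. A *frequency panel* stores the
effect-allele frequency of each variant in each of M labeled populations.

Model TSV dialect (tab separated, header row, ``#`` comment lines ignored)::

    gene_id  gene_name  tissue  training_r2  variant_id  chrom  pos  ref  effect_allele  weight

Panel TSV dialect: ``variant_id`` column, optional ``ref_freq`` column (a
reference-population frequency used for neutral-variant matching), then one
column per population. Coordinates are 1-based, as in VCF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    FormatError,
    MissingVariantError,
    ParseError,
    ValidationError,
)

logger = logging.getLogger(__name__)

MODEL_COLUMNS = [
    "gene_id",
    "gene_name",
    "tissue",
    "training_r2",
    "variant_id",
    "chrom",
    "pos",
    "ref",
    "effect_allele",
    "weight",
]

#: complementary base pairs whose strand cannot be resolved from alleles alone
_AMBIGUOUS_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass(frozen=True)
class VariantWeight:
    """One regulatory variant with its effect size (alpha, expression units
    per effect-allele dosage)."""

    variant_id: str
    chrom: str
    pos: int
    ref_allele: str
    effect_allele: str
    weight: float

    def __post_init__(self):
        if not np.isfinite(self.weight) or self.weight == 0:
            raise ValidationError(
                f"variant {self.variant_id}: weight must be finite and nonzero, got {self.weight}"
            )
        if self.pos < 1:
            raise ValidationError(f"variant {self.variant_id}: pos must be >= 1, got {self.pos}")
        if self.effect_allele == self.ref_allele:
            raise ValidationError(
                f"variant {self.variant_id}: effect allele equals reference allele"
            )


@dataclass
class GeneModel:
    """A gene's regulatory variants (ordered, L >= 1) and training metadata."""

    gene_id: str
    gene_name: str
    tissue: str
    training_r2: float
    variants: list[VariantWeight] = field(default_factory=list)

    def __post_init__(self):
        if len(self.variants) < 1:
            raise ValidationError(f"gene {self.gene_id}: model must have at least one variant")
        ids = [v.variant_id for v in self.variants]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"gene {self.gene_id}: duplicate variant ids {dup}")
        if not np.isfinite(self.training_r2) or not (0.0 <= self.training_r2 <= 1.0):
            raise ValidationError(
                f"gene {self.gene_id}: training_r2 must be in [0,1], got {self.training_r2}"
            )

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    @property
    def weights(self) -> np.ndarray:
        return np.array([v.weight for v in self.variants], dtype=float)


class FrequencyPanel:
    """Effect-allele frequencies for variants across M >= 2 populations.

    Parameters
    ----------
    freqs
        DataFrame indexed by variant_id with one float column per population
        (column order is the declared population order).
    ref_freq
        Optional per-variant reference-population frequency (used to bin
        variants for neutral matching).
    """

    def __init__(self, freqs: pd.DataFrame, ref_freq: pd.Series | None = None):
        if freqs.shape[1] < 2:
            raise ValidationError("frequency panel needs at least 2 populations")
        values = freqs.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValidationError("frequency panel contains non-finite values")
        if (values < 0).any() or (values > 1).any():
            raise ValidationError("frequencies must lie in [0, 1]")
        if freqs.index.has_duplicates:
            raise ValidationError("duplicate variant ids in frequency panel")
        self.freqs = freqs.astype(float)
        self.freqs.index = self.freqs.index.astype(str)
        if ref_freq is not None:
            ref_freq = ref_freq.astype(float).reindex(self.freqs.index)
        self.ref_freq = ref_freq

    @property
    def populations(self) -> tuple[str, ...]:
        return tuple(map(str, self.freqs.columns))

    @property
    def n_populations(self) -> int:
        return self.freqs.shape[1]

    @property
    def variant_ids(self) -> pd.Index:
        return self.freqs.index

    @property
    def mean_freq(self) -> pd.Series:
        """epsilon_l: mean frequency across populations (unweighted)."""
        return self.freqs.mean(axis=1)

    def __len__(self) -> int:
        return self.freqs.shape[0]

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self.freqs.index

    def freq_matrix(self, variant_ids: Sequence[str]) -> np.ndarray:
        """(L, M) frequency matrix for the given variants, in panel population
        order. Raises :class:`MissingVariantError` naming absent variants."""
        missing = [v for v in variant_ids if v not in self.freqs.index]
        if missing:
            raise MissingVariantError(
                f"variants absent from panel: {', '.join(map(str, missing[:10]))}"
                + (" ..." if len(missing) > 10 else "")
            )
        return self.freqs.loc[list(variant_ids)].to_numpy(dtype=float)

    def subset(self, variant_ids: Sequence[str]) -> "FrequencyPanel":
        ref = None
        if self.ref_freq is not None:
            ref = self.ref_freq.loc[list(variant_ids)]
        return FrequencyPanel(self.freqs.loc[list(variant_ids)], ref)

    def reorder_populations(self, order: Sequence[str]) -> "FrequencyPanel":
        if sorted(order) != sorted(self.populations):
            raise ValidationError("population reorder must be a permutation of the panel's labels")
        return FrequencyPanel(self.freqs[list(order)], self.ref_freq)

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_tsv(cls, path: str | Path) -> "FrequencyPanel":
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"variant_id": str})
        if "variant_id" not in df.columns:
            raise FormatError(f"{path}: missing required column 'variant_id'")
        df = df.set_index("variant_id")
        ref = None
        if "ref_freq" in df.columns:
            ref = df.pop("ref_freq")
        return cls(df, ref)

    def to_tsv(self, path: str | Path) -> None:
        out = self.freqs.copy()
        if self.ref_freq is not None:
            out.insert(0, "ref_freq", self.ref_freq)
        out.index.name = "variant_id"
        out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Gene-model TSV I/O
# ---------------------------------------------------------------------------

def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from the flat TSV dialect.

    Returns one :class:`GeneModel` per (gene_id, tissue) pair; row order
    within a gene is preserved as variant order.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    for col in MODEL_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    # line numbers: header is line 1, first data row is line 2
    lines = df.index.to_numpy() + 2

    def _numeric(col: str, kind=float) -> np.ndarray:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna().to_numpy()
        if bad.any():
            first = int(np.argmax(bad))
            raise ParseError(
                f"{path}: non-numeric {col} {df[col].iloc[first]!r}", line=int(lines[first])
            )
        return converted.to_numpy(dtype=kind)

    weights = _numeric("weight")
    r2 = _numeric("training_r2")
    pos = _numeric("pos", kind=float).astype(int)

    models: list[GeneModel] = []
    seen_pairs: set[tuple[str, str]] = set()
    for (gene_id, tissue), grp in df.groupby(["gene_id", "tissue"], sort=False):
        idx = grp.index.to_numpy()
        pairs = list(zip(grp["gene_id"], grp["variant_id"]))
        if len(set(pairs)) != len(pairs):
            dups = sorted({p for p in pairs if pairs.count(p) > 1})
            raise ValidationError(f"{path}: duplicate (gene, variant) rows: {dups}")
        variants = [
            VariantWeight(
                variant_id=str(df["variant_id"].iloc[i]),
                chrom=str(df["chrom"].iloc[i]),
                pos=int(pos[i]),
                ref_allele=str(df["ref"].iloc[i]),
                effect_allele=str(df["effect_allele"].iloc[i]),
                weight=float(weights[i]),
            )
            for i in idx
        ]
        names = set(grp["gene_name"])
        if len(names) > 1:
            raise ValidationError(f"{path}: inconsistent gene_name for {gene_id}/{tissue}")
        models.append(
            GeneModel(
                gene_id=str(gene_id),
                gene_name=grp["gene_name"].iloc[0],
                tissue=str(tissue),
                training_r2=float(r2[idx[0]]),
                variants=variants,
            )
        )
        seen_pairs.add((str(gene_id), str(tissue)))
    return models


def write_gene_models(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write models in the canonical TSV dialect (round-trips byte-identically)."""
    rows = []
    for m in models:
        for v in m.variants:
            rows.append(
                (
                    m.gene_id,
                    m.gene_name,
                    m.tissue,
                    m.training_r2,
                    v.variant_id,
                    v.chrom,
                    v.pos,
                    v.ref_allele,
                    v.effect_allele,
                    v.weight,
                )
            )
    pd.DataFrame(rows, columns=MODEL_COLUMNS).to_csv(path, sep="\t", index=False)


def select_best_models(models: Iterable[GeneModel]) -> list[GeneModel]:
    """One model per gene: highest training R^2, ties broken by the
    lexicographically smallest tissue label. Idempotent and order-independent."""
    by_gene: dict[str, GeneModel] = {}
    for m in models:
        if not np.isfinite(m.training_r2):
            raise ValidationError(f"gene {m.gene_id}: non-finite training_r2")
        cur = by_gene.get(m.gene_id)
        if (
            cur is None
            or m.training_r2 > cur.training_r2
            or (m.training_r2 == cur.training_r2 and m.tissue < cur.tissue)
        ):
            by_gene[m.gene_id] = m
    return [by_gene[g] for g in sorted(by_gene)]


# ---------------------------------------------------------------------------
# VCF-derived frequencies
# ---------------------------------------------------------------------------

def read_sample_map(path: str | Path) -> pd.DataFrame:
    """Sample-to-population map TSV with columns sample_id, population."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in ("sample_id", "population"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"{path}: samples mapped more than once: {dup}")
    return df


def frequencies_from_vcf(
    vcf_path: str | Path,
    sample_map: str | Path | pd.DataFrame,
    variants: Sequence[VariantWeight],
) -> tuple[FrequencyPanel, list[str]]:
    """Effect-allele frequencies per population from VCF genotypes.

    Frequencies are computed from observed (non-missing) haploid calls only.
    Variants are matched on (chrom, pos, ref, effect_allele); a variant whose
    effect allele is the VCF REF is counted on the REF allele. Returns the
    panel and the list of dropped variant ids (absent from the VCF, or with
    zero non-missing calls in some population).
    """
    from cyvcf2 import VCF

    if not isinstance(sample_map, pd.DataFrame):
        sample_map = read_sample_map(sample_map)
    pop_order = list(dict.fromkeys(sample_map["population"]))
    pop_index = {p: i for i, p in enumerate(pop_order)}
    sample_pop = dict(zip(sample_map["sample_id"], sample_map["population"]))

    vcf = VCF(str(vcf_path))
    unmapped = [s for s in vcf.samples if s not in sample_pop]
    if unmapped:
        raise ValidationError(
            f"samples in VCF absent from sample map: {', '.join(unmapped)}"
        )
    sample_pop_idx = np.array([pop_index[sample_pop[s]] for s in vcf.samples])

    wanted: dict[tuple[str, int], list[VariantWeight]] = {}
    for v in variants:
        wanted.setdefault((v.chrom, v.pos), []).append(v)

    n_pops = len(pop_order)
    freqs: dict[str, np.ndarray] = {}
    for rec in vcf:
        key = (rec.CHROM, rec.POS)
        if key not in wanted:
            continue
        for vw in wanted[key]:
            alleles = [rec.REF] + list(rec.ALT)
            if vw.ref_allele != rec.REF and vw.ref_allele not in rec.ALT:
                continue
            if vw.effect_allele not in alleles:
                continue
            if frozenset((vw.ref_allele, vw.effect_allele)) in _AMBIGUOUS_PAIRS:
                logger.warning(
                    "variant %s: strand-ambiguous allele pair %s/%s",
                    vw.variant_id,
                    vw.ref_allele,
                    vw.effect_allele,
                )
            target = alleles.index(vw.effect_allele)
            eff = np.zeros(n_pops)
            tot = np.zeros(n_pops)
            for si, gt in enumerate(rec.genotypes):
                p = sample_pop_idx[si]
                for allele in gt[:-1]:  # last entry is the phased flag
                    if allele < 0:
                        continue
                    tot[p] += 1
                    if allele == target:
                        eff[p] += 1
            if (tot == 0).any():
                empty = [pop_order[i] for i in np.flatnonzero(tot == 0)]
                logger.warning(
                    "variant %s dropped: no non-missing calls in population(s) %s",
                    vw.variant_id,
                    ", ".join(empty),
                )
                continue
            freqs[vw.variant_id] = eff / tot

    dropped = [v.variant_id for v in variants if v.variant_id not in freqs]
    for vid in dropped:
        logger.warning("variant %s not found in VCF; dropped", vid)
    kept = [v.variant_id for v in variants if v.variant_id in freqs]
    df = pd.DataFrame(
        [freqs[v] for v in kept], index=pd.Index(kept, name="variant_id"), columns=pop_order
    )
    if df.shape[0] == 0:
        raise ValidationError("no model variants could be matched in the VCF")
    return FrequencyPanel(df), dropped


def dosages_from_vcf(
    vcf_path: str | Path, variants: Sequence[VariantWeight]
) -> pd.DataFrame:
    """Effect-allele dosage matrix (individuals x variants) from VCF GT calls.

    Missing genotypes become NaN (downstream prediction mean-imputes them).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    wanted: dict[tuple[str, int], list[VariantWeight]] = {}
    for v in variants:
        wanted.setdefault((v.chrom, v.pos), []).append(v)
    cols: dict[str, np.ndarray] = {}
    for rec in vcf:
        key = (rec.CHROM, rec.POS)
        if key not in wanted:
            continue
        alleles = [rec.REF] + list(rec.ALT)
        for vw in wanted[key]:
            if vw.effect_allele not in alleles:
                continue
            target = alleles.index(vw.effect_allele)
            dose = np.full(len(samples), np.nan)
            for si, gt in enumerate(rec.genotypes):
                calls = [a for a in gt[:-1] if a >= 0]
                if calls:
                    dose[si] = sum(1 for a in calls if a == target)
            cols[vw.variant_id] = dose
    return pd.DataFrame(cols, index=pd.Index(samples, name="sample_id"))
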