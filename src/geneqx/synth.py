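"""Synthetic fixtures: structured population frequencies, gene models,
genotypes, and injected selection.

Population structure follows the Balding-Nichols model: each variant has an
ancestral frequency p0 ~ Beta(a, b) truncated to (0.05, 0.95), and each
population m draws its frequency independently from
Beta(p0 (1-d_m)/d_m, (1-p0)(1-d_m)/d_m), where d_m in (0, 1) is that
population's drift parameter. Standardized frequencies then have analytic
covariance diag(d_m) (off-diagonal zero), which makes the model a
closed-form ground truth for the neutral-covariance estimator. Defaults
emulate human continental-scale differentiation (FST a few percent).

Selection is injected as a coordinated frequency shift in one target
population (every variant moved in the direction of its effect sign by a
chosen number of sqrt(eps(1-eps)) units), or as a single-haplotype shift
(only the largest-|effect| variant moved) - the regime in which a test
conditioned on coordinated multi-variant differences has no power.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .models import FrequencyPanel, GeneModel, VariantWeight

logger = logging.getLogger(__name__)


@dataclass
class FrequencyModel:
    """Balding-Nichols-style hierarchical frequency generator."""

    n_pops: int = 5
    ancestral_a: float = 1.0
    ancestral_b: float = 1.0
    drift: tuple[float, ...] = (0.02, 0.04, 0.06, 0.08, 0.10)
    seed: int = 0

    def __post_init__(self):
        if self.ancestral_a <= 0 or self.ancestral_b <= 0:
            raise ValidationError("ancestral Beta parameters must be positive")
        if len(self.drift) != self.n_pops:
            raise ValidationError("need one drift value per population")
        if not all(0.0 < d < 1.0 for d in self.drift):
            raise ValidationError("drift values must lie in (0, 1)")

    @property
    def population_labels(self) -> tuple[str, ...]:
        return tuple(f"POP{i+1}" for i in range(self.n_pops))


@dataclass
class SelectionInjection:
    target_pop: str
    shift_sd_units: float
    mode: str = "coordinated"  # or "single_haplotype"

    def __post_init__(self):
        if self.mode not in ("coordinated", "single_haplotype"):
            raise ValidationError(f"unknown injection mode {self.mode!r}")


#: injected frequencies are clipped into this range to keep VA non-degenerate
CLIP_RANGE = (0.01, 0.99)


def _truncated_beta(
    rng: np.random.Generator, a: float, b: float, n: int, lo: float = 0.05, hi: float = 0.95
) -> np.ndarray:
    out = rng.beta(a, b, size=n)
    bad = (out <= lo) | (out >= hi)
    while bad.any():
        out[bad] = rng.beta(a, b, size=int(bad.sum()))
        bad = (out <= lo) | (out >= hi)
    return out


def generate_panel(
    fm: FrequencyModel,
    n_variants: int,
    seed: int | None = None,
    prefix: str = "snp",
) -> FrequencyPanel:
    """Balding-Nichols frequency panel; the ancestral frequency is stored as
    the panel's ``ref_freq`` (used for frequency-bin matching)."""
    rng = np.random.default_rng(fm.seed if seed is None else seed)
    p0 = _truncated_beta(rng, fm.ancestral_a, fm.ancestral_b, n_variants)
    freqs = np.empty((n_variants, fm.n_pops))
    for m, d in enumerate(fm.drift):
        c = (1.0 - d) / d
        freqs[:, m] = rng.beta(p0 * c, (1.0 - p0) * c)
    ids = pd.Index([f"{prefix}{i:07d}" for i in range(n_variants)], name="variant_id")
    df = pd.DataFrame(freqs, index=ids, columns=fm.population_labels)
    return FrequencyPanel(df, ref_freq=pd.Series(p0, index=ids, name="ref_freq"))


def analytic_standardized_covariance(fm: FrequencyModel) -> np.ndarray:
    """The generator's M x M covariance of (p_m - p0)/sqrt(p0(1-p0)):
    diag(drift). Ground truth for estimate_F consistency checks (up to the
    self-centering transform)."""
    return np.diag(fm.drift)


def generate_gene_model(
    L: int,
    effect_sd: float = 1.0,
    seed: int | None = None,
    gene_id: str = "GENE1",
    gene_name: str | None = None,
    tissue: str = "SYNTH",
    training_r2: float = 0.5,
    chrom: str = "1",
    start_pos: int = 1_000_000,
    variant_prefix: str | None = None,
) -> GeneModel:
    """L variants with effects ~ Normal(0, effect_sd^2); exact-zero draws are
    redrawn. Variant ids are deterministic."""
    if L < 1:
        raise ValidationError("L must be >= 1")
    rng = np.random.default_rng(seed)
    alpha = rng.normal(0.0, effect_sd, size=L)
    zero = alpha == 0.0
    while zero.any():  # pragma: no cover - measure-zero event
        alpha[zero] = rng.normal(0.0, effect_sd, size=int(zero.sum()))
        zero = alpha == 0.0
    prefix = variant_prefix if variant_prefix is not None else f"{gene_id}_v"
    variants = [
        VariantWeight(
            variant_id=f"{prefix}{i}",
            chrom=chrom,
            pos=start_pos + 1000 * i,
            ref_allele="A",
            effect_allele="G",
            weight=float(alpha[i]),
        )
        for i in range(L)
    ]
    return GeneModel(
        gene_id=gene_id,
        gene_name=gene_name or gene_id,
        tissue=tissue,
        training_r2=training_r2,
        variants=variants,
    )


def inject_selection(
    panel: FrequencyPanel, model: GeneModel, inj: SelectionInjection
) -> FrequencyPanel:
    """Shift the model's variants in the target population.

    Coordinated mode moves every variant by
    shift_sd_units * sign(alpha) * sqrt(eps(1-eps)); single-haplotype mode
    moves only the largest-|alpha| variant. Frequencies are clipped to
    [0.01, 0.99] with clip events logged.
    """
    if inj.target_pop not in panel.populations:
        raise ValidationError(f"target population {inj.target_pop!r} not in panel")
    freqs = panel.freqs.copy()
    ids = model.variant_ids
    sub = freqs.loc[ids]
    eps = sub.mean(axis=1).to_numpy()
    sd = np.sqrt(eps * (1.0 - eps))
    shift = inj.shift_sd_units * np.sign(model.weights) * sd
    if inj.mode == "single_haplotype":
        mask = np.zeros(len(ids), dtype=bool)
        mask[int(np.argmax(np.abs(model.weights)))] = True
        shift = np.where(mask, shift, 0.0)
    new = sub[inj.target_pop].to_numpy() + shift
    clipped = np.clip(new, *CLIP_RANGE)
    n_clip = int(np.sum(clipped != new))
    if n_clip:
        logger.info("inject_selection: clipped %d shifted frequencies", n_clip)
    freqs.loc[ids, inj.target_pop] = clipped
    return FrequencyPanel(freqs, panel.ref_freq)


def generate_genotypes(
    panel: FrequencyPanel,
    population_sizes: dict[str, int],
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hardy-Weinberg genotypes: dosage ~ Binomial(2, p_ml) per individual.

    Returns (dosage matrix individuals x variants, sample map with columns
    sample_id/population).
    """
    rng = np.random.default_rng(seed)
    for pop, n in population_sizes.items():
        if pop not in panel.populations:
            raise ValidationError(f"unknown population {pop!r}")
        if n < 1:
            raise ValidationError("population sizes must be >= 1")
    sample_ids, pops_col, blocks = [], [], []
    for pop in panel.populations:
        if pop not in population_sizes:
            continue
        n = population_sizes[pop]
        p = panel.freqs[pop].to_numpy()
        blocks.append(rng.binomial(2, p[None, :], size=(n, len(p))))
        sample_ids.extend(f"{pop}_{i:04d}" for i in range(n))
        pops_col.extend([pop] * n)
    dos = pd.DataFrame(
        np.vstack(blocks),
        index=pd.Index(sample_ids, name="sample_id"),
        columns=panel.variant_ids,
        dtype=float,
    )
    sample_map = pd.DataFrame({"sample_id": sample_ids, "population": pops_col})
    return dos, sample_map


def write_vcf(
    path: str | Path,
    variants: Sequence[VariantWeight],
    dosages: pd.DataFrame,
) -> None:
    """Emit a minimal VCF 4.2 with GT calls matching the dosage matrix
    (dosage d of the effect allele becomes an unphased genotype with d ALT
    alleles; NaN becomes ./.).

    The effect allele is written as ALT and the reference allele as REF.
    """
    samples = list(dosages.index)
    recs = sorted(variants, key=lambda v: (v.chrom, v.pos))
    contigs = list(dict.fromkeys(v.chrom for v in recs))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for v in recs:
            col = dosages[v.variant_id]
            gts = [
                "./." if np.isnan(d) else gt_map[int(d)] for d in col.to_numpy(dtype=float)
            ]
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.variant_id}\t{v.ref_allele}\t{v.effect_allele}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


@dataclass
class SyntheticDataset:
    models: list[GeneModel]
    panel: FrequencyPanel
    neutral_panel: FrequencyPanel
    injected: pd.Series  # gene_id -> bool


def generate_dataset(
    n_genes: int,
    fm: FrequencyModel | None = None,
    L: int = 12,
    n_neutral: int = 20_000,
    effect_sd: float = 1.0,
    injection: SelectionInjection | None = None,
    inject_fraction: float = 0.0,
    seed: int = 0,
) -> SyntheticDataset:
    """A full synthetic study: gene models with a shared structured panel of
    their variants, a neutral panel from the same frequency model, and
    (optionally) injected selection in the first ``inject_fraction`` of
    genes. L defaults to 12 variants per gene, the typical size of the
    expression models this emulates."""
    fm = fm or FrequencyModel()
    ss = np.random.SeedSequence(seed)
    s_panel, s_neutral, *s_genes = [int(x) for x in ss.generate_state(2 + n_genes)]
    models = []
    for g in range(n_genes):
        models.append(
            generate_gene_model(
                L,
                effect_sd=effect_sd,
                seed=s_genes[g],
                gene_id=f"G{g:05d}",
                start_pos=1_000_000 * (g + 1),
            )
        )
    n_model_variants = n_genes * L
    big = generate_panel(fm, n_model_variants + n_neutral, seed=s_panel, prefix="v")
    all_ids = [v.variant_id for m in models for v in m.variants]
    model_freqs = big.freqs.iloc[:n_model_variants].copy()
    model_freqs.index = pd.Index(all_ids, name="variant_id")
    model_ref = pd.Series(
        big.ref_freq.iloc[:n_model_variants].to_numpy(), index=model_freqs.index
    )
    panel = FrequencyPanel(model_freqs, model_ref)
    neutral_freqs = big.freqs.iloc[n_model_variants:]
    neutral_panel = FrequencyPanel(
        neutral_freqs, big.ref_freq.iloc[n_model_variants:]
    )

    n_inject = int(round(inject_fraction * n_genes)) if injection is not None else 0
    injected = pd.Series(False, index=[m.gene_id for m in models])
    for m in models[:n_inject]:
        panel = inject_selection(panel, m, injection)
        injected[m.gene_id] = True
    return SyntheticDataset(
        models=models, panel=panel, neutral_panel=neutral_panel, injected=injected
    )
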