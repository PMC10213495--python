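"""Gene-model / frequency-panel I/O and VCF-derived frequencies."""

import numpy as np
import pandas as pd
import pytest

from geneqx.errors import FormatError, ParseError, ValidationError
from geneqx.models import (
    FrequencyPanel,
    VariantWeight,
    frequencies_from_vcf,
    read_gene_models,
    select_best_models,
    write_gene_models,
)

from conftest import make_model, make_panel

HEADER = "gene_id\tgene_name\ttissue\ttraining_r2\tvariant_id\tchrom\tpos\tref\teffect_allele\tweight\n"


def _row(gene="G1", tissue="Lung", r2="0.5", vid="v1", w="0.3"):
    return f"{gene}\t{gene}\t{tissue}\t{r2}\t{vid}\t1\t100\tA\tG\t{w}\n"


class TestReadGeneModels:
    def test_single_gene_three_variants(self, tmp_path):
        f = tmp_path / "m.tsv"
        f.write_text(HEADER + "".join(_row(vid=f"v{i}") for i in range(3)))
        models = read_gene_models(f)
        assert len(models) == 1
        assert models[0].n_variants == 3
        assert models[0].variant_ids == ["v0", "v1", "v2"]  # row order preserved

    def test_header_only_gives_empty_collection(self, tmp_path):
        f = tmp_path / "m.tsv"
        f.write_text(HEADER)
        assert read_gene_models(f) == []

    def test_na_weight_cites_line_number(self, tmp_path):
        f = tmp_path / "m.tsv"
        f.write_text(
            HEADER + _row(vid="v1") + _row(vid="v2") + _row(vid="v3", w="NA")
        )
        with pytest.raises(ParseError, match="line 4"):
            read_gene_models(f)

    def test_missing_column_names_it(self, tmp_path):
        f = tmp_path / "m.tsv"
        f.write_text(HEADER.replace("\tweight", "") + "")
        with pytest.raises(FormatError, match="weight"):
            read_gene_models(f)

    def test_duplicate_gene_variant_rejected(self, tmp_path):
        f = tmp_path / "m.tsv"
        f.write_text(HEADER + _row(vid="v1") + _row(vid="v1"))
        with pytest.raises(ValidationError, match="duplicate"):
            read_gene_models(f)

    def test_roundtrip_byte_identical(self, tmp_path):
        f1 = tmp_path / "a.tsv"
        f2 = tmp_path / "b.tsv"
        models = [
            make_model([0.25, -1.75, 0.0625], gene_id="G1", tissue="Liver"),
            make_model([3.5], gene_id="G2", tissue="Lung", prefix="w"),
        ]
        write_gene_models(models, f1)
        write_gene_models(read_gene_models(f1), f2)
        assert f1.read_bytes() == f2.read_bytes()


class TestVariantWeightInvariants:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(weight=0.0),
            dict(weight=np.inf),
            dict(pos=0),
            dict(effect_allele="A"),  # equals ref
        ],
    )
    def test_invalid_rejected(self, kwargs):
        base = dict(
            variant_id="v", chrom="1", pos=5, ref_allele="A", effect_allele="G", weight=1.0
        )
        base.update(kwargs)
        with pytest.raises(ValidationError):
            VariantWeight(**base)


class TestSelectBestModels:
    def test_argmax_r2(self):
        ms = [
            make_model([1.0], gene_id="G", tissue="A", r2=0.3),
            make_model([1.0], gene_id="G", tissue="B", r2=0.5),
        ]
        best = select_best_models(ms)
        assert len(best) == 1 and best[0].tissue == "B"

    def test_single_model_identity(self):
        ms = [make_model([1.0], gene_id="G", tissue="A", r2=0.3)]
        assert select_best_models(ms)[0] is ms[0]

    def test_tie_breaks_lexicographically(self):
        ms = [
            make_model([1.0], gene_id="G", tissue="Lung", r2=0.4),
            make_model([1.0], gene_id="G", tissue="Liver", r2=0.4),
        ]
        assert select_best_models(ms)[0].tissue == "Liver"

    def test_idempotent_and_order_independent(self):
        ms = [
            make_model([1.0], gene_id=g, tissue=t, r2=r)
            for g, t, r in [
                ("G1", "A", 0.2), ("G1", "B", 0.9), ("G2", "C", 0.4), ("G2", "D", 0.4)
            ]
        ]
        fwd = select_best_models(ms)
        rev = select_best_models(ms[::-1])
        assert [(m.gene_id, m.tissue) for m in fwd] == [(m.gene_id, m.tissue) for m in rev]
        again = select_best_models(fwd)
        assert [(m.gene_id, m.tissue) for m in again] == [(m.gene_id, m.tissue) for m in fwd]


class TestFrequencyPanel:
    def test_mean_freq_is_exact_population_mean(self):
        panel = make_panel([[0.2, 0.4], [0.1, 0.9]])
        assert np.allclose(panel.mean_freq.to_numpy(), [0.3, 0.5])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            make_panel([[0.2, 1.4]])

    def test_tsv_roundtrip_with_ref_freq(self, tmp_path):
        panel = make_panel([[0.2, 0.4], [0.1, 0.9]], ref_freq=[0.25, 0.5])
        f = tmp_path / "p.tsv"
        panel.to_tsv(f)
        back = FrequencyPanel.from_tsv(f)
        assert back.populations == panel.populations
        assert np.allclose(back.freqs.to_numpy(), panel.freqs.to_numpy())
        assert np.allclose(back.ref_freq.to_numpy(), [0.25, 0.5])


# ---------------------------------------------------------------------------
# VCF frequencies
# ---------------------------------------------------------------------------

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##contig=<ID=1>\n"
)


def _vcf(tmp_path, body, samples=("S1", "S2", "S3", "S4")):
    path = tmp_path / "x.vcf"
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    path.write_text(VCF_HEADER + cols + "\n" + body)
    return path


def _smap(tmp_path, pairs):
    path = tmp_path / "map.tsv"
    path.write_text("sample_id\tpopulation\n" + "".join(f"{s}\t{p}\n" for s, p in pairs))
    return path


def _vw(vid="v1", pos=100, ref="A", eff="G"):
    return VariantWeight(
        variant_id=vid, chrom="1", pos=pos, ref_allele=ref, effect_allele=eff, weight=0.5
    )


class TestFrequenciesFromVcf:
    def test_allele_counting(self, tmp_path):
        # pop X: 0/1 and 1/1 -> 3 effect alleles of 4 calls
        vcf = _vcf(tmp_path, "1\t100\tv1\tA\tG\t.\tPASS\t.\tGT\t0/1\t1/1\t0/0\t0/0\n")
        smap = _smap(tmp_path, [("S1", "X"), ("S2", "X"), ("S3", "Y"), ("S4", "Y")])
        panel, dropped = frequencies_from_vcf(vcf, smap, [_vw()])
        assert dropped == []
        assert panel.freqs.loc["v1", "X"] == pytest.approx(0.75)
        assert panel.freqs.loc["v1", "Y"] == pytest.approx(0.0)

    def test_variant_absent_is_dropped(self, tmp_path):
        vcf = _vcf(tmp_path, "1\t100\tv1\tA\tG\t.\tPASS\t.\tGT\t0/1\t1/1\t0/0\t0/0\n")
        smap = _smap(tmp_path, [("S1", "X"), ("S2", "X"), ("S3", "Y"), ("S4", "Y")])
        panel, dropped = frequencies_from_vcf(vcf, smap, [_vw(), _vw(vid="v9", pos=999)])
        assert dropped == ["v9"]
        assert "v9" not in panel.freqs.index

    def test_population_all_missing_drops_variant(self, tmp_path):
        vcf = _vcf(tmp_path, "1\t100\tv1\tA\tG\t.\tPASS\t.\tGT\t0/1\t1/1\t./.\t./.\n")
        smap = _smap(tmp_path, [("S1", "X"), ("S2", "X"), ("S3", "Y"), ("S4", "Y")])
        with pytest.raises(ValidationError):
            # v1 is the only variant, so the panel would be empty
            frequencies_from_vcf(vcf, smap, [_vw()])

    def test_missing_calls_reduce_denominator(self, tmp_path):
        vcf = _vcf(tmp_path, "1\t100\tv1\tA\tG\t.\tPASS\t.\tGT\t0/1\t./.\t0/0\t1/1\n")
        smap = _smap(tmp_path, [("S1", "X"), ("S2", "X"), ("S3", "Y"), ("S4", "Y")])
        panel, _ = frequencies_from_vcf(vcf, smap, [_vw()])
        assert panel.freqs.loc["v1", "X"] == pytest.approx(0.5)  # 1 of 2 observed

    def test_all_hom_effect_gives_one_everywhere(self, tmp_path):
        vcf = _vcf(tmp_path, "1\t100\tv1\tA\tG\t.\tPASS\t.\tGT\t1/1\t1/1\t1/1\t1/1\n")
        smap = _smap(tmp_path, [("S1", "X"), ("S2", "X"), ("S3", "Y"), ("S4", "Y")])
        panel, _ = frequencies_from_vcf(vcf, smap, [_vw()])
        assert (panel.freqs.loc["v1"] == 1.0).all()

    def test_unmapped_sample_errors_with_names(self, tmp_path):
        vcf = _vcf(tmp_path, "1\t100\tv1\tA\tG\t.\tPASS\t.\tGT\t0/1\t1/1\t0/0\t0/0\n")
        smap = _smap(tmp_path, [("S1", "X"), ("S2", "X"), ("S3", "Y")])
        with pytest.raises(ValidationError, match="S4"):
            frequencies_from_vcf(vcf, smap, [_vw()])

    def test_effect_allele_on_ref_counts_ref(self, tmp_path):
        # effect allele is the VCF REF: count REF alleles
        vcf = _vcf(tmp_path, "1\t100\tv1\tG\tA\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t1/1\n")
        smap = _smap(tmp_path, [("S1", "X"), ("S2", "X"), ("S3", "Y"), ("S4", "Y")])
        panel, _ = frequencies_from_vcf(
            vcf, smap, [_vw(ref="A", eff="G")]
        )
        assert panel.freqs.loc["v1", "X"] == pytest.approx(0.75)
        assert panel.freqs.loc["v1", "Y"] == pytest.approx(0.0)

    def test_strand_ambiguous_pair_warns(self, tmp_path, caplog):
        import logging

        vcf = _vcf(tmp_path, "1\t100\tv1\tA\tT\t.\tPASS\t.\tGT\t0/1\t1/1\t0/0\t0/0\n")
        smap = _smap(tmp_path, [("S1", "X"), ("S2", "X"), ("S3", "Y"), ("S4", "Y")])
        with caplog.at_level(logging.WARNING):
            frequencies_from_vcf(vcf, smap, [_vw(ref="A", eff="T")])
        assert any("strand-ambiguous" in r.message for r in caplog.records)
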